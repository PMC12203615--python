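"""Synthetic inputs with known ground truth for every pipeline stage.

Three families of generators:

* fingerprint libraries in key space — planted similarity clusters (members
  share a core key pattern, perturbed by removals) among mutually dissimilar
  decoys, so expected within-cluster Tanimoto is controlled analytically;
* SMILES libraries built from scaffold templates, for end-to-end realism
  through the actual parser and fingerprinter;
* 96-well dose-response plates following the 7-concentration x 4-replicate
  design, with a known true IC50/Hill slope and multiplicative log-normal
  measurement noise (luminescence is positive and instrument noise is
  approximately proportional to signal, hence the log-normal choice).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .bioassay import LuminescenceWell, four_pl
from .fingerprints import N_KEYS, CompoundRecord, Fingerprint, compute_fingerprint
from .network import ReferenceSet
from .screening import QueryLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "LibrarySpec",
    "PlateSpec",
    "gen_fingerprint_library",
    "gen_smiles_library",
    "gen_query_library",
    "gen_plate",
]


@dataclass(frozen=True)
class LibrarySpec:
    """Planted-cluster compound library parameters.

    In bitvector mode each cluster has a core of ``core_keys`` set keys and
    each member independently removes ``member_flips`` of them (no additions),
    which bounds worst-case within-cluster Tanimoto at
    (core - 2*flips) / (core) from below (disjoint removals). The default
    (40, 6) guarantees >= 28/40 = 0.7, comfortably above the 0.5 screening
    threshold, while decoys are built on key blocks disjoint from every core.
    """

    n_clusters: int = 3
    cluster_size: int = 20
    n_decoys: int = 60
    core_keys: int = 40
    member_flips: int = 6
    similarity_target: float = 0.5
    mode: str = "bitvector"  # or "smiles-template"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_clusters, self.cluster_size, self.n_decoys) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 < self.similarity_target <= 1.0:
            raise ValueError("similarity target must be in (0, 1]")

    def worst_case_within(self) -> float:
        """Guaranteed lower bound on within-cluster Tanimoto (disjoint removals)."""
        k, r = self.core_keys, self.member_flips
        if k - 2 * r <= 0:
            return 0.0
        return (k - 2 * r) / k


@dataclass(frozen=True)
class PlateSpec:
    """Dose-response plate parameters with known truth."""

    true_ic50: float = 1.0e-3  # g/mL
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    concentrations: tuple[float, ...] = ()
    replicates: int = 4
    noise_cv: float = 0.05
    control_mean: float = 10000.0
    n_controls: int = 4
    series: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        concs = self.concentrations or self.default_grid()
        object.__setattr__(self, "concentrations", tuple(concs))
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be > 0")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise ValueError("concentrations must be distinct")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def default_grid(self) -> tuple[float, ...]:
        """7 log-spaced concentrations spanning a 20-fold range around the
        true IC50, mirroring the published gradient design."""
        return tuple(self.true_ic50 * r for r in (0.25, 0.4, 0.63, 1.0, 1.6, 2.5, 5.0))

    def true_inhibition(self, conc: float) -> float:
        return float(
            four_pl(np.log10(conc), self.bottom, self.top, math.log10(self.true_ic50), self.hill)
        )


# ---------------------------------------------------------------------------


def gen_fingerprint_library(
    spec: LibrarySpec,
) -> list[tuple[str, Fingerprint, str]]:
    """Key-space library: returns (id, Fingerprint, truth label) triples.

    Truth labels are ``cluster<k>`` for planted members and ``decoy`` for the
    rest. Cluster cores occupy disjoint key blocks where the 166-key budget
    allows; decoys get small key sets drawn to keep decoy-cluster and
    decoy-decoy Tanimoto well below the screening threshold.
    """
    if spec.mode != "bitvector":
        raise ValueError("gen_fingerprint_library requires bitvector mode")
    if spec.member_flips > 0 and spec.similarity_target >= 1.0:
        raise ValueError("similarity target 1.0 is infeasible with member_flips > 0")
    if spec.worst_case_within() < spec.similarity_target and spec.member_flips > 0:
        raise ValueError(
            f"core_keys={spec.core_keys}, member_flips={spec.member_flips} cannot "
            f"guarantee within-cluster similarity >= {spec.similarity_target}"
        )
    rng = np.random.default_rng(spec.seed)
    all_keys = np.arange(1, N_KEYS + 1)
    out: list[tuple[str, Fingerprint, str]] = []

    # disjoint cluster cores where possible, otherwise independent draws
    need = spec.n_clusters * spec.core_keys
    if need <= N_KEYS:
        perm = rng.permutation(all_keys)
        cores = [set(perm[i * spec.core_keys:(i + 1) * spec.core_keys].tolist())
                 for i in range(spec.n_clusters)]
        used = set().union(*cores) if cores else set()
    else:
        cores = [set(rng.choice(all_keys, size=spec.core_keys, replace=False).tolist())
                 for _ in range(spec.n_clusters)]
        used = set().union(*cores) if cores else set()
        logger.warning("cluster cores overlap: %d keys needed > %d available", need, N_KEYS)

    for k, core in enumerate(cores):
        core_arr = np.array(sorted(core))
        for m in range(spec.cluster_size):
            drop = set(rng.choice(core_arr, size=spec.member_flips, replace=False).tolist()) \
                if spec.member_flips else set()
            fp = Fingerprint.from_on_keys(core - drop)
            out.append((f"c{k}_m{m}", fp, f"cluster{k}"))

    # decoys: tiny key sets from the unused range; disjoint blocks if they fit
    free = np.array(sorted(set(all_keys.tolist()) - used))
    if spec.n_decoys > 0:
        if len(free) == 0:
            raise ValueError("no free keys left for decoys; reduce clusters or core size")
        block = max(1, min(4, len(free) // spec.n_decoys))
        if block * spec.n_decoys <= len(free):
            perm = rng.permutation(free)
            for d in range(spec.n_decoys):
                keys = perm[d * block:(d + 1) * block]
                out.append((f"d{d}", Fingerprint.from_on_keys(keys.tolist()), "decoy"))
        else:
            for d in range(spec.n_decoys):  # overlap unavoidable; keep sets tiny
                keys = rng.choice(free, size=min(2, len(free)), replace=False)
                out.append((f"d{d}", Fingerprint.from_on_keys(keys.tolist()), "decoy"))
    return out


# scaffold templates with a substitution slot; all emit RDKit-parseable SMILES
_SCAFFOLDS: dict[str, tuple[str, list[str]]] = {
    "benzene": ("c1ccc({sub})cc1", ["O", "N", "Cl", "Br", "C", "CC", "OC", "C(=O)O", "C#N", "C(=O)N", "CO", "F"]),
    "pyridine": ("c1ccnc({sub})c1", ["O", "N", "Cl", "C", "CC", "OC", "C(=O)O", "C#N", "CO", "Br", "F", "C(=O)N"]),
    "alkane": ("CCCCCC{sub}", ["C", "CC", "CCC", "O", "N", "Cl", "CO", "C(=O)O", "CC(C)C", "Br", "CCO", "C#N"]),
}


def gen_smiles_library(
    spec: LibrarySpec,
    path: str | Path | None = None,
    scaffolds: Sequence[str] = ("benzene", "alkane"),
) -> list[tuple[str, str, str]]:
    """SMILES-mode library: (id, smiles, truth label) triples, optionally
    written as a .smi file (SMILES<TAB>id). Same-scaffold members share high
    fingerprint similarity — verified post hoc in tests, not guaranteed."""
    if spec.mode != "smiles-template":
        raise ValueError("gen_smiles_library requires smiles-template mode")
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple[str, str, str]] = []
    for name in scaffolds[: spec.n_clusters] if spec.n_clusters else scaffolds:
        template, subs = _SCAFFOLDS[name]
        order = rng.permutation(len(subs))
        if spec.cluster_size > len(subs):
            raise ValueError(
                f"scaffold {name!r} exhausted: {spec.cluster_size} members > {len(subs)} substituents"
            )
        for m in range(spec.cluster_size):
            smiles = template.format(sub=subs[order[m]])
            rows.append((f"{name}_{m}", smiles, name))
    if path is not None:
        Path(path).write_text("".join(f"{s}\t{cid}\n" for cid, s, _ in rows))
    return rows


def gen_query_library(
    reference: ReferenceSet,
    n_mimics: int,
    n_decoys: int,
    mimic_flips: int = 0,
    seed: int = 0,
    name: str = "synthetic_query",
) -> tuple[QueryLibrary, dict[str, str]]:
    """Query library of perturbed reference copies (mimics) plus disjoint-key
    decoys; returns (library, truth labels) for recall/precision checks."""
    if n_mimics > 0 and len(reference) == 0:
        raise ValueError("cannot build mimics from an empty reference set")
    rng = np.random.default_rng(seed)
    components = []
    truth: dict[str, str] = {}
    backend = reference.backend if reference.members else "synthetic"
    ref_keys_union: set[int] = set()
    for _rid, _deg, fp in reference.members:
        ref_keys_union |= set(fp.on_keys())
    for i in range(n_mimics):
        src_idx = int(rng.integers(len(reference.members)))
        src_id, _deg, src_fp = reference.members[src_idx]
        on = set(src_fp.on_keys())
        if mimic_flips:
            drop = rng.choice(np.array(sorted(on)), size=min(mimic_flips, len(on) - 1), replace=False)
            on -= set(int(d) for d in drop)
        cid = f"mimic{i}"
        rec = CompoundRecord(id=cid, smiles=f"SYNTH:{cid}", source=name)
        components.append((rec, Fingerprint.from_on_keys(on, backend=backend)))
        truth[cid] = f"mimic_of:{src_id}"
    free = sorted(set(range(1, N_KEYS + 1)) - ref_keys_union)
    if n_decoys > 0 and not free:
        raise ValueError("reference keys cover all 166 slots; no disjoint decoys possible")
    block = max(1, min(3, len(free) // max(n_decoys, 1)))
    perm = rng.permutation(np.array(free)) if free else np.array([], dtype=int)
    for d in range(n_decoys):
        if (d + 1) * block <= len(perm):
            keys = perm[d * block:(d + 1) * block].tolist()
        else:
            keys = rng.choice(np.array(free), size=min(2, len(free)), replace=False).tolist()
        cid = f"qdecoy{d}"
        rec = CompoundRecord(id=cid, smiles=f"SYNTH:{cid}", source=name)
        components.append((rec, Fingerprint.from_on_keys(keys, backend=backend)))
        truth[cid] = "decoy"
    return QueryLibrary(name=name, components=components), truth


def gen_plate(spec: PlateSpec) -> list[LuminescenceWell]:
    """Simulate one series' wells: expected sample luminescence at c is
    control_mean * (1 - f(c)/100) under the true 4PL curve f, with
    multiplicative log-normal noise of the given CV on every well (controls
    included). Expected luminescence below zero is clamped at 0."""
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))  # lognormal sd for given CV
    mu = -0.5 * sigma**2  # unit-mean noise

    def noisy(mean: float) -> float:
        if spec.noise_cv == 0:
            return mean
        return mean * float(rng.lognormal(mean=mu, sigma=sigma))

    wells = []
    for r in range(spec.n_controls):
        wells.append(
            LuminescenceWell(role="control", series=spec.series,
                             luminescence=noisy(spec.control_mean), replicate=r)
        )
    for conc in spec.concentrations:
        f = spec.true_inhibition(conc)
        expected = spec.control_mean * (1.0 - f / 100.0)
        if expected < 0:
            logger.warning("inhibition %.1f%% > 100%% at %.3g g/mL; clamping luminescence to 0", f, conc)
            expected = 0.0
        for r in range(spec.replicates):
            wells.append(
                LuminescenceWell(role="sample", series=spec.series, concentration=conc,
                                 luminescence=noisy(expected), replicate=r)
            )
    return wells
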