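"""Screen query component libraries against the toxic reference set.

Each query component (an herb or formulation constituent) is matched against
every reference-set member; the component's match degree is the number of
reference compounds it resembles at Tanimoto >= tau. Components with match
degree at or above half the maximum match degree in their library — and with
at least one match — are flagged as putative toxic components. The cutoff is
computed per query library, since each formulation is screened separately.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .fingerprints import (
    CompoundRecord,
    Fingerprint,
    canonical_smiles,
    compute_fingerprint,
    tanimoto,
)
from .network import ReferenceSet, half_max_cutoff

logger = logging.getLogger(__name__)

__all__ = [
    "QueryLibrary",
    "ComponentMatches",
    "MatchTable",
    "ScreeningReport",
    "match_components",
    "select_toxic_components",
    "pool_libraries",
    "screen_library",
    "screen_formulation",
    "write_report",
]


@dataclass
class QueryLibrary:
    """A named component library with fingerprints attached."""

    name: str
    components: list[tuple[CompoundRecord, Fingerprint]]

    def __post_init__(self):
        ids = [r.id for r, _ in self.components]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.name}: duplicate component ids")

    @property
    def backend(self) -> str:
        backends = {fp.backend for _, fp in self.components}
        if len(backends) > 1:
            raise ValueError(f"{self.name}: mixed fingerprint backends {sorted(backends)}")
        return backends.pop() if backends else "unknown"

    @classmethod
    def from_records(
        cls, name: str, records: Sequence[CompoundRecord], backend: str = "rdkit-maccs"
    ) -> "QueryLibrary":
        return cls(name, [(r, compute_fingerprint(r, backend=backend)) for r in records])


@dataclass
class ComponentMatches:
    component_id: str
    matches: list[tuple[str, float]]  # (reference id, score >= tau), best first

    @property
    def match_degree(self) -> int:
        return len(self.matches)


@dataclass
class MatchTable:
    library_name: str
    tau: float
    rows: list[ComponentMatches]
    backend: str = "unknown"

    @property
    def max_match_degree(self) -> int:
        return max((r.match_degree for r in self.rows), default=0)


@dataclass
class ScreeningReport:
    library_name: str
    tau: float
    max_match_degree: int
    degree_cutoff: int
    selected: list[tuple[str, int, list[str]]]  # (component id, match_degree, top references)
    n_components: int
    rejected_count: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def selected_ids(self) -> list[str]:
        return [s[0] for s in self.selected]

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def match_components(
    library: QueryLibrary, reference: ReferenceSet, tau: float = 0.5
) -> MatchTable:
    """Bipartite similarity scan: for each component, the exact list of
    reference members with Tanimoto >= tau. Refuses to compare fingerprints
    from different key-definition backends."""
    if len(reference) == 0:
        logger.warning("empty reference set; every match degree will be 0")
    lib_backend = library.backend
    ref_backend = reference.backend
    if reference.members and lib_backend != "unknown" and ref_backend != "unknown":
        if lib_backend != ref_backend:
            raise ValueError(
                f"fingerprint backend mismatch: library={lib_backend!r} reference={ref_backend!r}"
            )
    rows = []
    for record, fp in library.components:
        hits = []
        for ref_id, _deg, ref_fp in reference.members:
            s = tanimoto(fp, ref_fp)
            if s >= tau:
                hits.append((ref_id, s))
        hits.sort(key=lambda h: (-h[1], h[0]))
        if any(s == 1.0 for _, s in hits):
            logger.info("%s: self-hit at Tanimoto 1.0 (component present in reference)", record.id)
        rows.append(ComponentMatches(record.id, hits))
    return MatchTable(library_name=library.name, tau=tau, rows=rows, backend=lib_backend)


def select_toxic_components(table: MatchTable, top_n: int = 3) -> ScreeningReport:
    """Apply the half-of-max match-degree rule within the query library.

    cutoff = ceil(max_match_degree / 2); selected components have match
    degree >= cutoff and at least one match. An all-zero table yields an
    empty (flagged) selection, never an error.
    """
    max_deg = table.max_match_degree
    cutoff = half_max_cutoff(max_deg)
    selected = []
    for row in table.rows:
        if row.match_degree >= max(cutoff, 1):
            selected.append(
                (row.component_id, row.match_degree, [rid for rid, _ in row.matches[:top_n]])
            )
    selected.sort(key=lambda s: (-s[1], s[0]))
    if max_deg == 0:
        logger.warning("%s: no toxic resemblance (all match degrees 0)", table.library_name)
    prov = {
        "tau": table.tau,
        "backend": table.backend,
        "rule": "match_degree >= ceil(max/2) and >= 1",
        "no_toxic_resemblance": max_deg == 0,
    }
    return ScreeningReport(
        library_name=table.library_name,
        tau=table.tau,
        max_match_degree=max_deg,
        degree_cutoff=cutoff,
        selected=selected,
        n_components=len(table.rows),
        provenance=prov,
    )


def pool_libraries(
    name: str, libraries: Sequence[QueryLibrary], dedup: bool = True
) -> QueryLibrary:
    """Concatenate constituent herb libraries into one formulation library,
    deduplicating by canonical structure (the same molecule occurring in two
    herbs is one chemical entity). ``dedup=False`` keeps every entry."""
    if not libraries:
        raise ValueError("no libraries to pool")
    pooled: list[tuple[CompoundRecord, Fingerprint]] = []
    seen_structs: set[str] = set()
    seen_ids: set[str] = set()
    for lib in libraries:
        for record, fp in lib.components:
            if dedup:
                try:
                    key = canonical_smiles(record.smiles)
                except ValueError:
                    key = record.smiles
                if key in seen_structs:
                    logger.info("pooling %s: dropping duplicate structure %s", name, record.id)
                    continue
                seen_structs.add(key)
            rid = record.id
            if rid in seen_ids:  # same id from two herbs with different structures
                rid = f"{lib.name}:{record.id}"
            seen_ids.add(rid)
            pooled.append(
                (CompoundRecord(id=rid, smiles=record.smiles, source=record.source, name=record.name), fp)
            )
    if not pooled:
        raise ValueError(f"{name}: pooled library is empty")
    return QueryLibrary(name=name, components=pooled)


def screen_library(
    library: QueryLibrary, reference: ReferenceSet, tau: float = 0.5
) -> ScreeningReport:
    return select_toxic_components(match_components(library, reference, tau=tau))


def screen_formulation(
    libraries: Sequence[QueryLibrary],
    formulation_name: str,
    reference: ReferenceSet,
    tau: float = 0.5,
    dedup: bool = True,
) -> ScreeningReport:
    """Pool constituent herbs' components, then screen the pooled library."""
    pooled = pool_libraries(formulation_name, libraries, dedup=dedup)
    return screen_library(pooled, reference, tau=tau)


def write_report(report: ScreeningReport, table: MatchTable, path: str | Path) -> None:
    """CSV: component, match_degree, selected flag, top matches; provenance
    JSON beside it."""
    path = Path(path)
    selected_ids = set(report.selected_ids)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["component", "match_degree", "selected", "top_matches"])
        for row in sorted(table.rows, key=lambda r: (-r.match_degree, r.component_id)):
            w.writerow(
                [
                    row.component_id,
                    row.match_degree,
                    int(row.component_id in selected_ids),
                    ";".join(rid for rid, _ in row.matches[:3]),
                ]
            )
    prov = dict(report.provenance)
    prov.update(
        {
            "library": report.library_name,
            "max_match_degree": report.max_match_degree,
            "degree_cutoff": report.degree_cutoff,
            "n_components": report.n_components,
            "n_selected": report.n_selected,
        }
    )
    path.with_suffix(path.suffix + ".prov.json").write_text(json.dumps(prov, indent=1))
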