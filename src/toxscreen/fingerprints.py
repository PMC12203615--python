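"""Compound library parsing, 166-key MACCS fingerprints, and Tanimoto similarity.

A fingerprint here is the classic MACCS dictionary of 166 substructure keys:
a molecule is reduced to the binary vector of which keys it contains, and
similarity between molecules is the Tanimoto coefficient over those key sets,

    T(A, B) = |A ∩ B| / (|A| + |B| - |A ∩ B|).

MACCS implementations differ in their exact SMARTS definitions, so the
fingerprint backend is pluggable and every fingerprint records the backend
that produced it; downstream stages refuse to mix backends.
"""

from __future__ import annotations

import csv
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

N_KEYS = 166

__all__ = [
    "N_KEYS",
    "CompoundRecord",
    "Fingerprint",
    "LibraryLoadError",
    "FingerprintError",
    "parse_library",
    "canonical_smiles",
    "compute_fingerprint",
    "fingerprint_library",
    "tanimoto",
    "write_fingerprint_matrix",
    "available_backends",
    "register_backend",
]


class LibraryLoadError(ValueError):
    """Raised when a compound library cannot be read at all."""


class FingerprintError(ValueError):
    """Raised when a single record cannot be fingerprinted; carries the id."""

    def __init__(self, compound_id: str, message: str):
        super().__init__(f"{compound_id}: {message}")
        self.compound_id = compound_id


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: unique id, source label, SMILES, optional name."""

    id: str
    smiles: str
    source: str = ""
    name: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if not self.smiles:
            raise ValueError(f"{self.id}: smiles must be non-empty")


@dataclass(frozen=True)
class Fingerprint:
    """166-key binary MACCS fingerprint.

    ``keys`` is an immutable tuple of 0/1 ints of length 166 (key 1 at
    index 0). ``backend`` names the key-definition dialect that produced it.
    """

    keys: tuple[int, ...]
    backend: str = "rdkit-maccs"

    def __post_init__(self):
        if len(self.keys) != N_KEYS:
            raise ValueError(f"fingerprint must have {N_KEYS} keys, got {len(self.keys)}")
        if any(k not in (0, 1) for k in self.keys):
            raise ValueError("fingerprint keys must be binary")

    @property
    def popcount(self) -> int:
        return sum(self.keys)

    def on_keys(self) -> frozenset[int]:
        """1-based indices of set keys."""
        return frozenset(i + 1 for i, k in enumerate(self.keys) if k)

    @classmethod
    def from_on_keys(cls, on: Iterable[int], backend: str = "synthetic") -> "Fingerprint":
        """Build from 1-based set-key indices (used by synthetic generators)."""
        bits = [0] * N_KEYS
        for i in on:
            if not 1 <= i <= N_KEYS:
                raise ValueError(f"key index {i} outside 1..{N_KEYS}")
            bits[i - 1] = 1
        return cls(keys=tuple(bits), backend=backend)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.keys, dtype=np.uint8)


# ---------------------------------------------------------------------------
# backends


def _rdkit_maccs(smiles: str) -> tuple[int, ...]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError("SMILES does not parse")
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 slots, slot 0 unused
    bits = [0] * N_KEYS
    for b in bv.GetOnBits():
        if b >= 1:
            bits[b - 1] = 1
    return tuple(bits)


def _openbabel_maccs(smiles: str) -> tuple[int, ...]:
    """MACCS via the OpenBabel `obabel` binary (the dialect used for
    reproduction runs). Requires obabel on PATH."""
    if shutil.which("obabel") is None:
        raise RuntimeError("obabel binary not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        inp = Path(td) / "in.smi"
        inp.write_text(smiles + "\tq\n")
        proc = subprocess.run(
            ["obabel", str(inp), "-ofpt", "-xfMACCS", "-xN", "166", "-xh"],
            capture_output=True,
            text=True,
        )
    if proc.returncode != 0:
        raise ValueError(f"obabel failed: {proc.stderr.strip()[:200]}")
    hexchunks = [
        tok
        for line in proc.stdout.splitlines()
        if not line.startswith(">") and line.strip()
        for tok in line.split()
    ]
    if not hexchunks:
        raise ValueError("obabel produced no fingerprint (unparseable structure?)")
    # obabel prints 32-bit words, most significant first; bit i of the set
    # corresponds to MACCS key i+1 (0-based numbering)
    words = [int(w, 16) for w in hexchunks]
    bits = [0] * N_KEYS
    for wi, w in enumerate(reversed(words)):  # word 0 = lowest bits
        for b in range(32):
            idx = wi * 32 + b
            if w >> b & 1 and idx < N_KEYS:
                bits[idx] = 1
    return tuple(bits)


_BACKENDS: dict[str, Callable[[str], tuple[int, ...]]] = {
    "rdkit-maccs": _rdkit_maccs,
}
if shutil.which("obabel") is not None:
    _BACKENDS["openbabel-maccs"] = _openbabel_maccs

DEFAULT_BACKEND = "rdkit-maccs"


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


def register_backend(name: str, func: Callable[[str], tuple[int, ...]]) -> None:
    """Register an alternative MACCS key-definition backend."""
    _BACKENDS[name] = func


# ---------------------------------------------------------------------------
# parsing


def canonical_smiles(smiles: str) -> str:
    """RDKit-canonical SMILES; raises ValueError on unparseable input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _iter_smi(path: Path) -> Iterable[tuple[str, str, str | None]]:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        cid = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
        yield cid, smiles, None


def _iter_sdf(path: Path) -> Iterable[tuple[str, str, str | None]]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            yield f"sdf_entry_{i}", "", None  # recorded as reject downstream
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf_entry_{i}"
        yield cid, Chem.MolToSmiles(mol), None


def _iter_csv(path: Path) -> Iterable[tuple[str, str, str | None]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames or "smiles" not in reader.fieldnames:
            raise LibraryLoadError(f"{path}: CSV must have 'id' and 'smiles' columns")
        for row in reader:
            yield row["id"], row["smiles"], row.get("name") or None


def parse_library(
    path: str | Path,
    format: str | None = None,
    source: str = "",
    strict: bool = False,
) -> list[CompoundRecord]:
    """Read a compound library from .smi, SDF or CSV.

    Unparseable entries are rejected with a logged id, never silently
    dropped; ``strict=True`` turns any reject into an error. Zero parseable
    records is always fatal.
    """
    path = Path(path)
    if not path.exists():
        raise LibraryLoadError(f"no such file: {path}")
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt in ("smi", "smiles"):
        entries = _iter_smi(path)
    elif fmt in ("sdf", "mol", "sd"):
        entries = _iter_sdf(path)
    elif fmt == "csv":
        entries = _iter_csv(path)
    else:
        raise LibraryLoadError(f"unknown library format: {fmt!r}")

    records: list[CompoundRecord] = []
    rejected: list[str] = []
    seen_ids: set[str] = set()
    for cid, smiles, name in entries:
        if not smiles or Chem.MolFromSmiles(smiles) is None:
            rejected.append(cid)
            logger.warning("rejected unparseable entry %r in %s", cid, path.name)
            continue
        if cid in seen_ids:
            raise LibraryLoadError(f"{path}: duplicate compound id {cid!r}")
        seen_ids.add(cid)
        records.append(CompoundRecord(id=cid, smiles=smiles, source=source, name=name))

    if rejected and strict:
        raise LibraryLoadError(f"{path}: {len(rejected)} unparseable entries: {rejected[:10]}")
    if not records:
        raise LibraryLoadError(f"{path}: no parseable records")
    logger.info("loaded %d records from %s (%d rejected)", len(records), path.name, len(rejected))
    return records


def compute_fingerprint(record: CompoundRecord, backend: str = DEFAULT_BACKEND) -> Fingerprint:
    """MACCS fingerprint of one compound; canonicalizes the structure first
    so atom ordering in the input SMILES cannot affect the result."""
    if backend not in _BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; available: {available_backends()}")
    try:
        canon = canonical_smiles(record.smiles)
        keys = _BACKENDS[backend](canon)
    except ValueError as exc:
        raise FingerprintError(record.id, str(exc)) from exc
    return Fingerprint(keys=keys, backend=backend)


def fingerprint_library(
    records: Sequence[CompoundRecord], backend: str = DEFAULT_BACKEND
) -> list[tuple[str, Fingerprint]]:
    """Fingerprint every record; per-record failures propagate with the id."""
    return [(r.id, compute_fingerprint(r, backend=backend)) for r in records]


# ---------------------------------------------------------------------------
# similarity


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over set keys.

    Two all-zero fingerprints compare as 0.0 (a structure firing no keys
    carries no similarity evidence); a warning is logged for that case.
    """
    if len(a.keys) != len(b.keys):
        raise ValueError("fingerprint length mismatch")
    inter = sum(x & y for x, y in zip(a.keys, b.keys))
    union = a.popcount + b.popcount - inter
    if union == 0:
        logger.warning("tanimoto of two empty fingerprints defined as 0.0")
        return 0.0
    return inter / union


def write_fingerprint_matrix(
    fps: Sequence[tuple[str, Fingerprint]], path: str | Path
) -> None:
    """Audit CSV: one row per compound, columns key_1..key_166."""
    import pandas as pd

    df = pd.DataFrame(
        [fp.as_array() for _, fp in fps],
        index=[cid for cid, _ in fps],
        columns=[f"key_{i}" for i in range(1, N_KEYS + 1)],
    )
    df.index.name = "id"
    df.to_csv(path)
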