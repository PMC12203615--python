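#!/usr/bin/env python
"""Screen the formulation component libraries against the toxic reference.

Pools each formulation's herb files (deduplicating identical structures),
matches every component against the reference set at Tanimoto >= 0.5, and
flags components whose match degree reaches half the per-formulation maximum.
Writes one report per formulation plus a summary under
results/analysis/screens/.
"""

import csv
import json
from pathlib import Path

from toxscreen.fingerprints import compute_fingerprint, parse_library, CompoundRecord
from toxscreen.network import ReferenceSet
from toxscreen.screening import (
    QueryLibrary,
    match_components,
    pool_libraries,
    select_toxic_components,
    write_report,
)

ROOT = Path(__file__).resolve().parents[1] / "results" / "analysis"
OUT = ROOT / "screens"


def load_reference() -> ReferenceSet:
    prov = json.loads((ROOT / "reference" / "reference.prov.json").read_text())
    members = []
    with open(ROOT / "reference" / "reference.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            rec = CompoundRecord(id=row["id"], smiles=row["smiles"])
            members.append((row["id"], int(row["degree"]),
                            compute_fingerprint(rec, backend=prov["backend"])))
    return ReferenceSet(members=members, tau=prov["tau"], max_degree=prov["max_degree"],
                        degree_cutoff=prov["degree_cutoff"], provenance=prov)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ref = load_reference()
    manifest = json.loads((ROOT / "inputs" / "manifest.json").read_text())
    for form, files in manifest.items():
        libs = []
        for f in files:
            records = parse_library(f, source=form)
            libs.append(QueryLibrary.from_records(Path(f).stem, records,
                                                  backend=ref.backend))
        pooled = pool_libraries(form, libs, dedup=True)
        table = match_components(pooled, ref, tau=ref.tau)
        report = select_toxic_components(table)
        write_report(report, table, OUT / f"{form}.screen.csv")
        print(f"{form}: {report.n_selected} of {report.n_components} components flagged "
              f"(max match degree {report.max_match_degree}, cutoff {report.degree_cutoff})")
        for cid, deg, tops in report.selected:
            print(f"  {cid}: match degree {deg}, closest references {', '.join(tops)}")


if __name__ == "__main__":
    main()
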