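#!/usr/bin/env python
"""Build the toxic reference set from the training library.

Fingerprints every training compound (166-key MACCS), links pairs at
Tanimoto >= 0.5 into a similarity network, computes degree centrality, and
keeps nodes with degree >= half the maximum as the toxic reference set.
Writes reference.csv, network.sif and provenance under
results/analysis/reference/.
"""

import csv
import json
from pathlib import Path

from toxscreen.fingerprints import fingerprint_library, parse_library
from toxscreen.network import build_network, degree_table, export_network, select_reference

ROOT = Path(__file__).resolve().parents[1] / "results" / "analysis"
OUT = ROOT / "reference"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = parse_library(ROOT / "inputs" / "toxic_training.smi")
    fps = fingerprint_library(records)
    net = build_network(fps, tau=0.5)
    degrees = degree_table(net)
    ref = select_reference(net, degrees, fingerprints=dict(fps))

    smiles = {r.id: r.smiles for r in records}
    with open(OUT / "reference.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "smiles", "degree"])
        for cid, deg, _fp in ref.members:
            w.writerow([cid, smiles[cid], deg])
    export_network(net, OUT / "network.sif", format="sif")
    (OUT / "reference.prov.json").write_text(json.dumps(ref.provenance, indent=1))

    print(f"library: {len(records)} compounds; {net.n_edges} pairs at tau=0.5")
    print(f"max degree {ref.max_degree}, cutoff {ref.degree_cutoff} "
          f"-> {len(ref)} reference compounds")
    by_scaffold = {}
    for cid in ref.ids:
        by_scaffold.setdefault(cid.rsplit("_", 1)[0], []).append(cid)
    for scaf, members in sorted(by_scaffold.items()):
        print(f"  {scaf}: {len(members)} members in the reference set")


if __name__ == "__main__":
    main()
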