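#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the two data sources the pipeline consumes: a toxic-training
compound library containing similarity clusters plus dissimilar decoys
(SMILES, so the real parser and fingerprinter are exercised), per-herb query
component files, and three 7-concentration x 4-replicate dose-response
plates with known true IC50s (5e-4, 4e-4 and 2.5e-4 g/mL, CV 5%).
Everything is seeded; outputs land under results/analysis/inputs/.
"""

import json
from pathlib import Path

from toxscreen.bioassay import write_plate_csv
from toxscreen.synthetic import LibrarySpec, PlateSpec, gen_plate, gen_smiles_library

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis" / "inputs"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    lib_spec = LibrarySpec(mode="smiles-template", n_clusters=2, cluster_size=10, seed=SEED)
    rows = gen_smiles_library(lib_spec, path=OUT / "toxic_training.smi",
                              scaffolds=("benzene", "alkane"))
    print(f"toxic-training library: {len(rows)} compounds "
          f"({len({r[2] for r in rows})} scaffold clusters) -> toxic_training.smi")

    # query herbs: herb_A carries two long-chain components resembling the
    # training library's alkane cluster (expected hits) plus polar decoys;
    # herb_B adds one more chain-family component and unrelated decoys
    (OUT / "herb_A.smi").write_text(
        "CCCCCCCO\tA_heptanol\nCCCCCCCC\tA_octane\n"
        "OC(=O)CC(O)(CC(=O)O)C(=O)O\tA_citrate\nNC(N)=N\tA_guanidine\n"
    )
    (OUT / "herb_B.smi").write_text(
        "CCCCCCCN\tB_heptylamine\nOCC(O)CO\tB_glycerol\nc1ccncc1\tB_pyridine\n"
    )
    manifest = {"FORM1": [str(OUT / "herb_A.smi")],
                "FORM2": [str(OUT / "herb_A.smi"), str(OUT / "herb_B.smi")]}
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=1))
    print("query herbs: herb_A.smi (4 components), herb_B.smi (3) + manifest.json")

    for offset, (name, true_ic50) in enumerate(
        [("BASE", 4.0e-4), ("FORM1", 5.0e-4), ("FORM2", 2.5e-4)]
    ):
        spec = PlateSpec(true_ic50=true_ic50, hill=1.2, noise_cv=0.05,
                         series=name, seed=SEED + offset)
        write_plate_csv(gen_plate(spec), OUT / f"plate_{name}.csv")
        print(f"plate_{name}.csv: true IC50 {true_ic50:.3g} g/mL, CV 5%, 7x4 design")


if __name__ == "__main__":
    main()
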