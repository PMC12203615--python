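#!/usr/bin/env python
"""Fit IC50 curves to the simulated plates and rank toxicity.

Computes per-concentration inhibition rates from each plate, fits the
four-parameter logistic on log10 concentration, reports the absolute-50%
IC50 with a bootstrap CI, and ranks the series by descending IC50 (least
toxic first) with detoxification calls against the base series. Writes
ic50.csv, ranking.json and per-series curve plots under
results/analysis/bioassay/.
"""

import csv
import json
from pathlib import Path

from toxscreen.bioassay import build_series, fit_ic50, plot_fit, rank_toxicity, read_plate_csv

ROOT = Path(__file__).resolve().parents[1] / "results" / "analysis"
OUT = ROOT / "bioassay"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fits, all_points = {}, {}
    for plate in sorted((ROOT / "inputs").glob("plate_*.csv")):
        wells = read_plate_csv(plate)
        series = wells[0].series
        points = build_series(wells, series)
        fit = fit_ic50(points, n_boot=200, seed=SEED)
        fits[series], all_points[series] = fit, points
        plot_fit(points, fit, OUT / f"{series}.curve.png", title=series)

    with open(OUT / "ic50.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["series", "ic50_g_per_ml", "ci_low", "ci_high", "hill", "top", "bottom"])
        for s, f in sorted(fits.items()):
            lo, hi = f.ci if f.ci else (float("nan"), float("nan"))
            w.writerow([s, f"{f.ic50:.4e}", f"{lo:.4e}", f"{hi:.4e}",
                        f"{f.hill:.3f}", f"{f.top:.1f}", f"{f.bottom:.1f}"])
            print(f"{s}: IC50 {f.ic50:.4g} g/mL (95% CI {lo:.3g}-{hi:.3g}), hill {f.hill:.2f}")

    ranking = rank_toxicity(fits, base="BASE")
    (OUT / "ranking.json").write_text(json.dumps(ranking, indent=1))
    print("ranking (least toxic first):", " > ".join(ranking["order"]))
    for call in ranking["calls"]:
        verdict = "detoxification trend" if call["detoxified"] else "no detoxification"
        extra = " (CIs overlap: indistinguishable)" if call["indistinguishable"] else ""
        print(f"  {call['series']} vs {call['vs']}: {verdict}{extra}")


if __name__ == "__main__":
    main()
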