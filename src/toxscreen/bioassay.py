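"""Bioluminescence inhibition rates, 4PL IC50 fits, and toxicity ranking.

The acute-toxicity readout is the fractional loss of *Vibrio fischeri* light
output in treated wells relative to untreated controls,

    inhibition% = (mean_ctrl - mean_sample) / mean_ctrl * 100,

measured over a 7-concentration gradient with 4 replicates per concentration.
Inhibition is fitted against log10 concentration with a four-parameter
logistic (bottom, top, Hill slope, midpoint); the IC50 reported is the
concentration at which the fitted curve crosses 50% absolute inhibition
(the curve midpoint is reported alongside). Smaller IC50 = greater potential
toxicity, so ranking formulations by descending IC50 lists the least toxic
first, and a formulation whose IC50 exceeds the base herb's shows a
detoxification trend.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "LuminescenceWell",
    "InhibitionPoint",
    "IC50Fit",
    "TABLE1_GRIDS",
    "read_plate_csv",
    "write_plate_csv",
    "inhibition_rate",
    "build_series",
    "four_pl",
    "fit_ic50",
    "rank_toxicity",
    "plot_fit",
]

# 7-concentration gradients used for the three test articles (g/mL):
# PF = Psoraleae Fructus, ESP = Er Shen Pills, SSP = Si Shen Pills.
TABLE1_GRIDS: dict[str, tuple[float, ...]] = {
    "PF": (2.950e-4, 4.425e-4, 5.900e-4, 1.475e-3, 2.950e-3, 4.425e-3, 5.900e-3),
    "ESP": (1.720e-4, 2.294e-4, 5.733e-4, 1.147e-3, 2.294e-3, 3.440e-3, 4.587e-3),
    "SSP": (1.003e-4, 1.338e-4, 2.007e-4, 2.676e-4, 3.344e-4, 4.682e-4, 6.689e-4),
}


@dataclass(frozen=True)
class LuminescenceWell:
    """One microplate well. Controls carry no concentration."""

    role: str  # "control" | "sample"
    series: str
    luminescence: float
    concentration: float | None = None  # g/mL
    replicate: int = 0

    def __post_init__(self):
        if self.role not in ("control", "sample"):
            raise ValueError(f"role must be control or sample, got {self.role!r}")
        if self.luminescence < 0:
            raise ValueError("luminescence must be >= 0")
        if self.role == "sample" and (self.concentration is None or self.concentration <= 0):
            raise ValueError("sample wells need a positive concentration")


@dataclass(frozen=True)
class InhibitionPoint:
    concentration: float  # g/mL
    inhibition: float  # percent; negative = stimulation
    n_replicates: int
    dispersion: float = 0.0  # sd of per-replicate inhibition
    stimulation: bool = False


@dataclass
class IC50Fit:
    """Four-parameter logistic fit summary. ``ic50`` is the absolute 50%%
    crossing; ``midpoint`` the curve's inflection concentration."""

    ic50: float  # g/mL
    midpoint: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    n_points: int
    in_range: bool = True
    ci: tuple[float, float] | None = None
    diagnostics: str = ""


def read_plate_csv(path: str | Path) -> list[LuminescenceWell]:
    """Plate schema: series,role,concentration_g_per_ml,replicate,luminescence."""
    wells = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            conc = row.get("concentration_g_per_ml", "")
            wells.append(
                LuminescenceWell(
                    role=row["role"],
                    series=row["series"],
                    concentration=float(conc) if conc not in ("", None) else None,
                    replicate=int(row.get("replicate", 0) or 0),
                    luminescence=float(row["luminescence"]),
                )
            )
    if not wells:
        raise ValueError(f"{path}: empty plate file")
    return wells


def write_plate_csv(wells: Sequence[LuminescenceWell], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["series", "role", "concentration_g_per_ml", "replicate", "luminescence"])
        for well in wells:
            w.writerow(
                [
                    well.series,
                    well.role,
                    "" if well.concentration is None else f"{well.concentration:.6e}",
                    well.replicate,
                    f"{well.luminescence:.6f}",
                ]
            )


def inhibition_rate(
    control_wells: Sequence[LuminescenceWell], sample_wells: Sequence[LuminescenceWell]
) -> InhibitionPoint:
    """Replicate luminescence is averaged before the formula; negative values
    (stimulation above control) are returned unchanged with a flag."""
    if not control_wells or not sample_wells:
        raise ValueError("need at least one control and one sample well")
    ctrl_mean = float(np.mean([w.luminescence for w in control_wells]))
    if ctrl_mean <= 0:
        raise ValueError("mean control luminescence must be > 0")
    lums = [w.luminescence for w in sample_wells]
    sample_mean = float(np.mean(lums))
    inhibition = (ctrl_mean - sample_mean) / ctrl_mean * 100.0
    per_rep = [(ctrl_mean - l) / ctrl_mean * 100.0 for l in lums]
    concs = {w.concentration for w in sample_wells}
    if len(concs) != 1:
        raise ValueError(f"sample wells span multiple concentrations: {sorted(concs)}")
    if inhibition < 0:
        logger.info("stimulation at %.3g g/mL: %.1f%%", concs.copy().pop(), inhibition)
    return InhibitionPoint(
        concentration=concs.pop(),
        inhibition=inhibition,
        n_replicates=len(sample_wells),
        dispersion=float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else 0.0,
        stimulation=inhibition < 0,
    )


def build_series(
    wells: Sequence[LuminescenceWell], series_label: str
) -> list[InhibitionPoint]:
    """One inhibition point per distinct concentration of one series, sorted
    ascending. Requires controls and >= 3 concentrations (fewer leaves the
    dose-response fit unidentifiable)."""
    controls = [w for w in wells if w.series == series_label and w.role == "control"]
    samples = [w for w in wells if w.series == series_label and w.role == "sample"]
    if not controls:
        raise ValueError(f"{series_label}: no control wells")
    by_conc: dict[float, list[LuminescenceWell]] = {}
    for w in samples:
        by_conc.setdefault(w.concentration, []).append(w)
    if len(by_conc) < 3:
        raise ValueError(
            f"{series_label}: only {len(by_conc)} distinct concentrations (need >= 3)"
        )
    return [inhibition_rate(controls, by_conc[c]) for c in sorted(by_conc)]


def four_pl(logc: np.ndarray, bottom: float, top: float, logmid: float, hill: float) -> np.ndarray:
    """Inhibition%% as a function of log10 concentration: rises from
    ``bottom`` to ``top`` with slope ``hill`` around ``logmid``."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logmid - logc) * hill))


def _absolute_ic50(bottom: float, top: float, logmid: float, hill: float) -> float | None:
    """Concentration where the fitted curve crosses 50% inhibition."""
    if not (bottom < 50.0 < top):
        return None
    ratio = (top - 50.0) / (50.0 - bottom)
    return 10.0 ** (logmid - math.log10(ratio) / hill)


def fit_ic50(
    points: Sequence[InhibitionPoint],
    constrained: bool = True,
    n_boot: int = 0,
    seed: int | None = None,
) -> IC50Fit:
    """Least-squares 4PL fit on log10 concentration.

    Default constraints (bottom in [-20, 20]%, top in [60, 110]%) stabilise
    7-point fits; ``constrained=False`` lifts them. Non-convergence and
    non-identifiable inputs come back as diagnosed failures, never a silent
    number. ``n_boot > 0`` adds a residual-bootstrap CI on the IC50.
    """
    if len(points) < 4:
        raise ValueError(f"need >= 4 points for a 4-parameter fit, got {len(points)}")
    conc = np.array([p.concentration for p in points], dtype=float)
    inh = np.array([p.inhibition for p in points], dtype=float)
    if np.ptp(inh) < 1e-9:
        raise ValueError("all inhibition values identical: fit non-identifiable")
    logc = np.log10(conc)
    monotone = bool(np.all(np.diff(inh[np.argsort(logc)]) >= -15.0))
    if not monotone:
        logger.warning("inhibition trend is strongly non-monotone; fit may be unstable")

    if constrained:
        bounds = ([-20.0, 60.0, logc.min() - 3.0, 0.1], [20.0, 110.0, logc.max() + 3.0, 10.0])
    else:
        bounds = ([-np.inf, -np.inf, logc.min() - 6.0, 0.01], [np.inf, np.inf, logc.max() + 6.0, 50.0])
    # midpoint guess: concentration nearest the half-range crossing
    half = (inh.min() + inh.max()) / 2.0
    p0 = [
        float(np.clip(inh.min(), bounds[0][0], bounds[1][0])),
        float(np.clip(inh.max(), bounds[0][1], bounds[1][1])),
        float(logc[np.argmin(np.abs(inh - half))]),
        1.0,
    ]
    try:
        popt, _ = curve_fit(four_pl, logc, inh, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return IC50Fit(
            ic50=float("nan"), midpoint=float("nan"), hill=float("nan"),
            top=float("nan"), bottom=float("nan"), rss=float("inf"),
            converged=False, n_points=len(points), diagnostics=f"optimizer failure: {exc}",
        )
    bottom, top, logmid, hill = (float(v) for v in popt)
    rss = float(np.sum((four_pl(logc, *popt) - inh) ** 2))
    ic50 = _absolute_ic50(bottom, top, logmid, hill)
    if ic50 is None:
        return IC50Fit(
            ic50=float("nan"), midpoint=10.0 ** logmid, hill=hill, top=top, bottom=bottom,
            rss=rss, converged=False, n_points=len(points),
            diagnostics="fitted curve never crosses 50% inhibition",
        )
    in_range = bool(conc.min() <= ic50 <= conc.max())
    if not in_range:
        logger.warning("IC50 %.3g g/mL lies outside the tested range [%.3g, %.3g]",
                       ic50, conc.min(), conc.max())
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        resid = inh - four_pl(logc, *popt)
        boot = []
        for _ in range(n_boot):
            y = four_pl(logc, *popt) + rng.choice(resid, size=len(resid), replace=True)
            try:
                pb, _ = curve_fit(four_pl, logc, y, p0=popt, bounds=bounds, maxfev=5000)
            except (RuntimeError, ValueError):
                continue
            b50 = _absolute_ic50(*(float(v) for v in pb))
            if b50 is not None:
                boot.append(b50)
        if len(boot) >= max(10, n_boot // 4):
            ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return IC50Fit(
        ic50=ic50, midpoint=10.0 ** logmid, hill=hill, top=top, bottom=bottom,
        rss=rss, converged=True, n_points=len(points), in_range=in_range, ci=ci,
    )


def rank_toxicity(
    fits: Mapping[str, IC50Fit], base: str | None = None
) -> dict:
    """Sort series by descending IC50 (least toxic first) and call
    detoxification trends.

    With ``base`` given, each other series is compared against it (IC50 above
    the base herb's = detoxified); otherwise all pairwise calls are reported.
    Series whose fit did not converge are excluded with a warning; overlapping
    bootstrap CIs mark a pair as indistinguishable.
    """
    usable = {k: f for k, f in fits.items() if f.converged}
    for k in fits:
        if k not in usable:
            logger.warning("excluding unconverged fit for %r from ranking", k)
    if len(usable) < 2:
        raise ValueError("need >= 2 converged fits to rank")
    order = sorted(usable, key=lambda k: -usable[k].ic50)

    def _overlap(a: IC50Fit, b: IC50Fit) -> bool:
        if a.ci is None or b.ci is None:
            return False
        return a.ci[0] <= b.ci[1] and b.ci[0] <= a.ci[1]

    calls = []
    if base is not None:
        if base not in usable:
            raise ValueError(f"base series {base!r} has no converged fit")
        for k in order:
            if k == base:
                continue
            calls.append(
                {
                    "series": k,
                    "vs": base,
                    "detoxified": usable[k].ic50 > usable[base].ic50,
                    "indistinguishable": _overlap(usable[k], usable[base]),
                }
            )
    else:
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                calls.append(
                    {
                        "series": a,
                        "vs": b,
                        "detoxified": usable[a].ic50 > usable[b].ic50,
                        "indistinguishable": _overlap(usable[a], usable[b]),
                    }
                )
    return {
        "order": order,  # least toxic first
        "ic50": {k: usable[k].ic50 for k in order},
        "calls": calls,
        "excluded": sorted(set(fits) - set(usable)),
    }


def plot_fit(
    points: Sequence[InhibitionPoint], fit: IC50Fit, path: str | Path, title: str = ""
) -> None:
    """Dose-response curve export (concentration on log axis, inhibition %)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conc = np.array([p.concentration for p in points])
    inh = np.array([p.inhibition for p in points])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.semilogx(conc, inh, "o", color="tab:blue", label="observed")
    if fit.converged:
        grid = np.logspace(np.log10(conc.min()) - 0.3, np.log10(conc.max()) + 0.3, 200)
        ax.semilogx(grid, four_pl(np.log10(grid), fit.bottom, fit.top,
                                  np.log10(fit.midpoint), fit.hill), "-", color="tab:red")
        ax.axvline(fit.ic50, ls="--", color="grey", label=f"IC50 = {fit.ic50:.3g} g/mL")
    ax.axhline(50, ls=":", color="grey", lw=0.8)
    ax.set_xlabel("concentration (g/mL)")
    ax.set_ylabel("inhibition (%)")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
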