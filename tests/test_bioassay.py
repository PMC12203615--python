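"""Inhibition rates, 4PL IC50 fitting, and toxicity ranking."""

import math

import numpy as np
import pytest

from toxscreen.bioassay import (
    TABLE1_GRIDS,
    IC50Fit,
    LuminescenceWell,
    build_series,
    fit_ic50,
    four_pl,
    inhibition_rate,
    rank_toxicity,
    read_plate_csv,
    write_plate_csv,
)
from toxscreen.synthetic import PlateSpec, gen_plate


def ctrl(lum, rep=0, series="s"):
    return LuminescenceWell(role="control", series=series, luminescence=lum, replicate=rep)


def samp(lum, conc, rep=0, series="s"):
    return LuminescenceWell(role="sample", series=series, luminescence=lum,
                            concentration=conc, replicate=rep)


class TestInhibitionRate:
    def test_quarter_signal_is_75_percent(self):
        p = inhibition_rate([ctrl(1000)], [samp(250, 1e-3)])
        assert p.inhibition == pytest.approx(75.0)

    def test_equal_means_is_zero(self):
        p = inhibition_rate([ctrl(1000)], [samp(1000, 1e-3)])
        assert p.inhibition == pytest.approx(0.0)
        assert not p.stimulation

    def test_stimulation_returned_negative_and_flagged(self):
        p = inhibition_rate([ctrl(1000)], [samp(1200, 1e-3)])
        assert p.inhibition == pytest.approx(-20.0)
        assert p.stimulation

    def test_dark_wells_are_exactly_100_percent(self):
        p = inhibition_rate([ctrl(1000), ctrl(900)], [samp(0.0, 1e-3), samp(0.0, 1e-3, rep=1)])
        assert p.inhibition == pytest.approx(100.0)

    def test_replicates_averaged_before_formula(self):
        p = inhibition_rate([ctrl(800), ctrl(1200)], [samp(400, 1e-3), samp(600, 1e-3, rep=1)])
        # means: ctrl 1000, sample 500
        assert p.inhibition == pytest.approx(50.0)
        assert p.n_replicates == 2
        assert p.dispersion > 0

    def test_zero_control_signal_is_an_error(self):
        with pytest.raises(ValueError, match="control luminescence"):
            inhibition_rate([ctrl(0.0)], [samp(10, 1e-3)])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            inhibition_rate([], [samp(10, 1e-3)])


class TestBuildSeries:
    def test_seven_point_gradient_yields_seven_sorted_points(self):
        wells = [ctrl(1000, r, "PF") for r in range(4)]
        for conc in TABLE1_GRIDS["PF"]:
            for r in range(4):
                wells.append(samp(500, conc, r, "PF"))
        points = build_series(wells, "PF")
        assert len(points) == 7
        assert [p.concentration for p in points] == sorted(TABLE1_GRIDS["PF"])
        assert all(p.n_replicates == 4 for p in points)

    def test_missing_controls_is_an_error(self):
        wells = [samp(500, c, series="X") for c in (1e-4, 2e-4, 4e-4)]
        with pytest.raises(ValueError, match="no control wells"):
            build_series(wells, "X")

    def test_fewer_than_three_concentrations_unidentifiable(self):
        wells = [ctrl(1000, series="X")] + [samp(500, c, series="X") for c in (1e-4, 2e-4)]
        with pytest.raises(ValueError, match="distinct concentrations"):
            build_series(wells, "X")

    def test_noiseless_plate_reproduces_generator_truth(self):
        spec = PlateSpec(true_ic50=1e-3, hill=1.5, noise_cv=0.0, seed=0)
        points = build_series(gen_plate(spec), spec.series)
        for p in points:
            assert p.inhibition == pytest.approx(spec.true_inhibition(p.concentration), abs=1e-9)


class TestFitIC50:
    def test_noiseless_recovery_to_point1_percent(self):
        """Exact 4PL data on a 7-point log grid: IC50 back to 0.1% relative."""
        true = 1.0e-3
        spec = PlateSpec(true_ic50=true, hill=1.0, top=100.0, bottom=0.0, noise_cv=0.0)
        points = build_series(gen_plate(spec), spec.series)
        fit = fit_ic50(points)
        assert fit.converged
        assert fit.ic50 == pytest.approx(true, rel=1e-3)
        assert fit.hill == pytest.approx(1.0, rel=1e-2)

    def test_grid_point_crossing_recovered(self):
        """50% crossing placed exactly on a tested concentration."""
        spec = PlateSpec(true_ic50=4.425e-4, hill=2.0, noise_cv=0.0,
                         concentrations=TABLE1_GRIDS["PF"])
        points = build_series(gen_plate(spec), spec.series)
        fit = fit_ic50(points)
        assert fit.ic50 == pytest.approx(4.425e-4, rel=1e-3)

    def test_absolute_ic50_differs_from_midpoint_when_baseline_shifted(self):
        """With bottom = 20%, the 50% crossing sits below the curve midpoint."""
        spec = PlateSpec(true_ic50=1e-3, hill=1.0, top=100.0, bottom=20.0, noise_cv=0.0)
        points = build_series(gen_plate(spec), spec.series)
        fit = fit_ic50(points)
        # closed form: c50 = mid * ((top-50)/(50-bottom))^(-1/hill)
        expected = 1e-3 / ((100.0 - 50.0) / (50.0 - 20.0))
        assert fit.ic50 == pytest.approx(expected, rel=1e-3)
        assert fit.ic50 < fit.midpoint

    def test_scale_equivariance(self):
        spec = PlateSpec(true_ic50=5e-4, hill=1.3, noise_cv=0.0)
        points = build_series(gen_plate(spec), spec.series)
        fit1 = fit_ic50(points)
        scaled = [type(p)(concentration=p.concentration * 10.0, inhibition=p.inhibition,
                          n_replicates=p.n_replicates) for p in points]
        fit10 = fit_ic50(scaled)
        assert fit10.ic50 == pytest.approx(10.0 * fit1.ic50, rel=1e-6)

    def test_monte_carlo_recovery_under_5pct_cv(self):
        """Noisy plates (CV 5%, 7 points, 4 replicates): median relative
        error of the recovered IC50 stays within 15%."""
        true = 4.0e-4
        errs = []
        for seed in range(40):
            spec = PlateSpec(true_ic50=true, hill=1.2, noise_cv=0.05, seed=seed)
            fit = fit_ic50(build_series(gen_plate(spec), spec.series))
            if fit.converged:
                errs.append(abs(fit.ic50 - true) / true)
        assert len(errs) >= 38
        assert float(np.median(errs)) < 0.15

    def test_flat_data_non_identifiable(self):
        points = build_series(
            [ctrl(1000, r) for r in range(2)]
            + [samp(500, c, r) for c in (1e-4, 3e-4, 1e-3, 3e-3) for r in range(2)],
            "s",
        )
        with pytest.raises(ValueError, match="non-identifiable"):
            fit_ic50(points)

    def test_too_few_points_rejected(self):
        spec = PlateSpec(noise_cv=0.0)
        points = build_series(gen_plate(spec), spec.series)[:3]
        with pytest.raises(ValueError, match=">= 4 points"):
            fit_ic50(points)

    def test_curve_never_reaching_50_is_diagnosed_not_silent(self):
        spec = PlateSpec(true_ic50=1e-3, top=100.0, bottom=0.0, hill=1.0, noise_cv=0.0,
                         concentrations=(1e-6, 2e-6, 4e-6, 8e-6, 1.6e-5, 3.2e-5, 6.4e-5))
        points = build_series(gen_plate(spec), spec.series)
        fit = fit_ic50(points, constrained=False)
        if fit.converged:  # extrapolated crossing must be flagged out of range
            assert not fit.in_range
        else:
            assert fit.diagnostics

    def test_bootstrap_ci_brackets_noiseless_truth(self):
        spec = PlateSpec(true_ic50=1e-3, noise_cv=0.03, seed=11)
        points = build_series(gen_plate(spec), spec.series)
        fit = fit_ic50(points, n_boot=100, seed=5)
        assert fit.ci is not None
        lo, hi = fit.ci
        assert lo <= fit.ic50 <= hi


class TestRankToxicity:
    def _fit(self, ic50, ci=None):
        return IC50Fit(ic50=ic50, midpoint=ic50, hill=1.0, top=100, bottom=0,
                       rss=0.0, converged=True, n_points=7, ci=ci)

    def test_descending_ic50_order_and_detox_call(self):
        fits = {"A": self._fit(5.0e-4), "B": self._fit(4.0e-4), "C": self._fit(2.5e-4)}
        r = rank_toxicity(fits, base="B")
        assert r["order"] == ["A", "B", "C"]  # least toxic first
        a_call = next(c for c in r["calls"] if c["series"] == "A")
        assert a_call["detoxified"]
        c_call = next(c for c in r["calls"] if c["series"] == "C")
        assert not c_call["detoxified"]

    def test_order_invariant_to_input_order(self):
        fits = {"A": self._fit(5.0e-4), "B": self._fit(4.0e-4), "C": self._fit(2.5e-4)}
        rev = dict(reversed(list(fits.items())))
        assert rank_toxicity(fits)["order"] == rank_toxicity(rev)["order"]

    def test_single_series_cannot_rank(self):
        with pytest.raises(ValueError, match=">= 2"):
            rank_toxicity({"A": self._fit(1e-3)})

    def test_unconverged_fit_excluded_with_warning(self, caplog):
        bad = IC50Fit(ic50=float("nan"), midpoint=float("nan"), hill=1, top=100, bottom=0,
                      rss=float("inf"), converged=False, n_points=7)
        with caplog.at_level("WARNING"):
            r = rank_toxicity({"A": self._fit(5e-4), "B": self._fit(4e-4), "X": bad})
        assert r["excluded"] == ["X"]
        assert "unconverged" in caplog.text

    def test_overlapping_cis_reported_indistinguishable(self):
        fits = {
            "A": self._fit(5.0e-4, ci=(3.5e-4, 6.5e-4)),
            "B": self._fit(4.5e-4, ci=(3.0e-4, 6.0e-4)),
        }
        r = rank_toxicity(fits)
        assert r["calls"][0]["indistinguishable"]

    def test_ranking_from_fitted_synthetic_plates(self):
        """End to end: three noiseless plates at 5e-4 / 4e-4 / 2.5e-4 rank in
        descending IC50 order with the detoxification call vs the base."""
        fits = {}
        for name, true in [("A", 5.0e-4), ("B", 4.0e-4), ("C", 2.5e-4)]:
            spec = PlateSpec(true_ic50=true, noise_cv=0.0, series=name)
            fits[name] = fit_ic50(build_series(gen_plate(spec), name))
        r = rank_toxicity(fits, base="B")
        assert r["order"] == ["A", "B", "C"]
        assert next(c for c in r["calls"] if c["series"] == "A")["detoxified"]


def test_plate_csv_roundtrip(tmp_path):
    spec = PlateSpec(noise_cv=0.02, seed=3)
    wells = gen_plate(spec)
    p = tmp_path / "plate.csv"
    write_plate_csv(wells, p)
    back = read_plate_csv(p)
    assert len(back) == len(wells)
    assert back[0].role == "control" and back[0].concentration is None
    for a, b in zip(back, wells):
        assert a.luminescence == pytest.approx(b.luminescence, rel=1e-5)
        assert (a.concentration or 0) == pytest.approx(b.concentration or 0, rel=1e-5)
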