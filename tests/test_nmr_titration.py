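import numpy as np
import pytest
from scipy.optimize import brentq

from clampdyn.nmr_titration import (
    ABSENT_BROADENED,
    TitrationPoint,
    TitrationSeries,
    binding_isotherm,
    classify_residues,
    compute_csp,
    dilution_track,
    fit_kd,
    read_titration_tsv,
    saturation_check,
    significance_threshold,
    write_titration_tsv,
)
from clampdyn.synthetic import TitrationParams, make_titration_dataset


def point(L, R, shifts, status=None):
    return TitrationPoint(ligand_total=L, receptor_total=R, shifts=shifts,
                          status=status or {})


class TestCSP:
    def test_zero_difference(self):
        p0 = point(0.0, 100.0, {"R1": (8.0, 120.0)})
        assert compute_csp(p0, p0).delta["R1"] == 0.0

    def test_hand_computed_weighting(self):
        """ΔδH=0.03, ΔδN=0.20 with α=0.2 → sqrt(0.0009+0.0016)=0.05 ppm."""
        p0 = point(0.0, 100.0, {"R1": (8.00, 120.00)})
        p1 = point(50.0, 100.0, {"R1": (8.03, 120.20)})
        assert compute_csp(p0, p1, alpha=0.2).delta["R1"] == pytest.approx(0.05)

    def test_pure_proton_shift(self):
        p0 = point(0.0, 100.0, {"R1": (8.00, 120.0)})
        p1 = point(50.0, 100.0, {"R1": (8.06, 120.0)})
        assert compute_csp(p0, p1).delta["R1"] == pytest.approx(0.06)

    def test_symmetric_in_arguments(self):
        p0 = point(0.0, 100.0, {"R1": (8.00, 120.0), "R2": (7.5, 110.0)})
        p1 = point(50.0, 100.0, {"R1": (8.04, 119.7), "R2": (7.52, 110.3)})
        fwd = compute_csp(p0, p1).delta
        rev = compute_csp(p1, p0).delta
        assert fwd == rev

    def test_missing_residue_carries_flag(self):
        p0 = point(0.0, 100.0, {"R1": (8.0, 120.0), "R2": (7.0, 115.0)})
        p1 = point(50.0, 100.0, {"R1": (8.1, 121.0)}, status={"R2": ABSENT_BROADENED})
        res = compute_csp(p0, p1)
        assert np.isnan(res.delta["R2"])
        assert res.missing["R2"] == ABSENT_BROADENED

    def test_no_common_residues_errors(self):
        p0 = point(0.0, 100.0, {"R1": (8.0, 120.0)})
        p1 = point(50.0, 100.0, {"R2": (8.0, 120.0)})
        with pytest.raises(ValueError, match="common"):
            compute_csp(p0, p1)


class TestThreshold:
    def test_zero_sd(self):
        assert significance_threshold([0.01, 0.01, 0.01]) == pytest.approx(0.01)

    def test_population_sd_hand_value(self):
        """{0.01, 0.03}: mean 0.02, population SD 0.01 → 0.04 ppm."""
        assert significance_threshold([0.01, 0.03]) == pytest.approx(0.04)

    def test_nans_ignored(self):
        assert significance_threshold([0.01, 0.03, float("nan")]) == pytest.approx(0.04)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            significance_threshold([0.01, float("nan")])


class TestClassification:
    def _series(self):
        ratios = [0.0, 0.5, 1.0, 2.0]
        pts = []
        for k, r in enumerate(ratios):
            shifts = {"fast": (8.0 + 0.02 * k, 120.0), "flat": (7.0, 110.0)}
            status = {}
            if r >= 0.5:
                status["gone"] = ABSENT_BROADENED
            else:
                shifts["gone"] = (9.0, 125.0)
            pts.append(point(100.0 * r, 100.0, shifts, status))
        return TitrationSeries(points=pts)

    def test_three_way_classes(self):
        out = classify_residues(self._series(), noise_ppm=0.005)
        assert out["gone"] == "intermediate"
        assert out["fast"] == "fast"
        assert out["flat"] == "unperturbed"

    def test_late_disappearance_is_not_intermediate(self):
        """Broadening only past the substoichiometric window doesn't count."""
        pts = [
            point(0.0, 100.0, {"r": (8.0, 120.0)}),
            point(50.0, 100.0, {"r": (8.01, 120.1)}),
            point(300.0, 100.0, {}, status={"r": ABSENT_BROADENED}),
        ]
        out = classify_residues(TitrationSeries(points=pts), noise_ppm=0.005)
        assert out["r"] == "fast"


class TestIsotherm:
    def test_limits(self):
        assert binding_isotherm(100.0, 1e-9, 35.0) == pytest.approx(0.0, abs=1e-9)
        assert binding_isotherm(100.0, 200.0, 1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_hand_value(self):
        """R=L=Kd=100 → (300−sqrt(50000))/200 = 0.381966."""
        assert binding_isotherm(100.0, 100.0, 100.0) == pytest.approx(0.3819660113)

    def test_matches_numerical_mass_action_solve(self):
        """Closed form ≡ brute-force root of the mass-action system to 1e-10
        over 4 orders of magnitude in each of R, L, Kd."""
        vals = [0.1, 1.0, 10.0, 100.0, 1000.0]
        for R in vals:
            for L in vals:
                for Kd in vals:
                    # solve for free ligand: (L-x)(R-x)/ ... root on complex x = RL bound
                    def g(x):  # x = bound complex
                        return (R - x) * (L - x) - Kd * x
                    x = brentq(g, 0.0, min(R, L), xtol=1e-16, rtol=8.9e-16)
                    assert binding_isotherm(R, L, Kd) == pytest.approx(
                        x / R, abs=1e-10, rel=1e-10
                    )


class TestDilution:
    def test_zero_additions(self):
        df = dilution_track(100.0, 400.0, 9520.0, [])
        assert len(df) == 1
        assert df["receptor_total"].iloc[0] == 100.0
        assert df["ligand_total"].iloc[0] == 0.0

    def test_seven_percent_dilution(self):
        """Additions totalling 7% of the final volume dilute the receptor by 7%."""
        v0 = 400.0
        v_add = v0 * 0.07 / 0.93  # 7% of final volume
        df = dilution_track(100.0, v0, 9520.0, [v_add])
        assert df["receptor_total"].iloc[-1] == pytest.approx(93.0)

    def test_volume_doubling_halves_receptor(self):
        df = dilution_track(100.0, 400.0, 9520.0, [400.0])
        assert df["receptor_total"].iloc[-1] == pytest.approx(50.0)
        assert df["ligand_total"].iloc[-1] == pytest.approx(9520.0 / 2)


class TestSaturation:
    def test_identical_points_saturated(self):
        p = point(640.0, 93.0, {"R1": (8.0, 120.0)})
        assert saturation_check(p, p, noise_ppm=0.005)

    def test_moving_residue_not_saturated(self):
        p0 = point(480.0, 94.0, {"R1": (8.0, 120.0)})
        p1 = point(640.0, 93.0, {"R1": (8.05, 120.0)})
        assert not saturation_check(p1, p0, noise_ppm=0.005)

    def test_boundary_inclusive(self):
        p0 = point(480.0, 94.0, {"R1": (8.0, 120.0)})
        p1 = point(640.0, 93.0, {"R1": (8.005, 120.0)})
        assert saturation_check(p1, p0, noise_ppm=0.005)


class TestKdFit:
    def test_noiseless_exact_recovery(self):
        """Kd_true=35 μM, 8 points to ratio 6.4: recovered to 1e-4 relative."""
        series, truth = make_titration_dataset(TitrationParams(noise_ppm=0.0, seed=7))
        fit = fit_kd(series, list(truth["ddmax_ppm"]))
        assert fit.converged
        assert fit.Kd == pytest.approx(35.0, rel=1e-4)
        for res, dd in truth["ddmax_ppm"].items():
            assert fit.ddmax[res] == pytest.approx(dd, rel=1e-3)

    def test_noisy_median_recovery(self):
        """σ=0.002 ppm over 20 seeds: median fitted Kd within 10%."""
        fits = []
        for seed in range(20):
            series, truth = make_titration_dataset(
                TitrationParams(noise_ppm=0.002, seed=200 + seed)
            )
            fits.append(fit_kd(series, list(truth["ddmax_ppm"])).Kd)
        assert np.median(fits) == pytest.approx(35.0, rel=0.10)

    def test_no_signal_rejected(self):
        series, truth = make_titration_dataset(
            TitrationParams(noise_ppm=0.0, ddmax_range=(0.0, 1e-15), seed=1)
        )
        with pytest.raises(ValueError, match="no signal"):
            fit_kd(series, list(truth["ddmax_ppm"]))

    def test_insufficient_points(self):
        series, truth = make_titration_dataset(
            TitrationParams(ratios=(0.5, 1.0, 2.0), seed=1)
        )
        with pytest.raises(ValueError, match="4 titration points"):
            fit_kd(series, list(truth["ddmax_ppm"]))


def test_tsv_roundtrip(tmp_path):
    params = TitrationParams(
        noise_ppm=0.002, disappearing=("R3", "R7"), disappearance_ratio=0.5, seed=5
    )
    series, _ = make_titration_dataset(params)
    path = tmp_path / "titration.tsv"
    write_titration_tsv(series, path)
    back = read_titration_tsv(path)
    assert len(back) == len(series)
    for p, q in zip(series.points, back.points):
        assert q.ligand_total == pytest.approx(p.ligand_total, rel=1e-5)
        assert set(q.shifts) == set(p.shifts)
        assert q.status == p.status
        for res in p.shifts:
            assert q.shifts[res][0] == pytest.approx(p.shifts[res][0], abs=1e-5)
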