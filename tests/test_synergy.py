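"""Dose-matrix normalization, Bliss excess, Loewe CI, isobolograms."""

import dataclasses

import numpy as np
import pytest

from synergyseq import (
    DoseMatrix,
    SimulationConfig,
    analyze_matrix,
    bliss_surface,
    fit_monotherapy,
    gen_dose_matrix,
    isobologram,
    loewe_ci,
    normalize_plate,
    percent_reduced_proliferation,
    synergy_vs_discordance,
    to_raw_plate,
)
from synergyseq.synergy import _hill

DOSES = np.array([0.0, 0.3125, 0.625, 1.25, 2.5, 5.0, 10.0])


def matrix_from_grid(values, doses_a=DOSES, doses_b=DOSES):
    return DoseMatrix(
        drug_a="A",
        drug_b="B",
        doses_a=doses_a,
        doses_b=doses_b,
        values=np.asarray(values, dtype=float),
        kind="percent",
    )


class TestPercentReducedProliferation:
    def test_control_anchors(self):
        assert percent_reduced_proliferation(50000.0, 50000.0, 2000.0) == 0.0
        assert percent_reduced_proliferation(2000.0, 50000.0, 2000.0) == 100.0

    def test_midpoint_and_affine_invariance(self):
        lo, ec0, ec100 = 26000.0, 50000.0, 2000.0
        assert percent_reduced_proliferation(lo, ec0, ec100) == pytest.approx(50.0)
        for a, b in ((2.0, 100.0), (-0.5, 3.0), (1e-3, -7.0)):
            assert percent_reduced_proliferation(
                a * lo + b, a * ec0 + b, a * ec100 + b
            ) == pytest.approx(50.0)

    def test_equal_controls_rejected(self):
        with pytest.raises(ValueError, match="EC100"):
            percent_reduced_proliferation(1.0, 5.0, 5.0)

    def test_normalize_plate_roundtrip(self):
        cfg = SimulationConfig(seed=0, plate_noise_sd=0.0)
        dm, _ = gen_dose_matrix(cfg)
        raw = to_raw_plate(dm)
        back = normalize_plate(raw)
        np.testing.assert_allclose(back.values, dm.values, atol=1e-9)


class TestBliss:
    def test_exact_independence_zero_excess(self):
        doses = np.array([0.0, 1.0])
        vals = np.array([[0.0, 50.0], [50.0, 75.0]])
        res = bliss_surface(matrix_from_grid(vals, doses, doses))
        assert res.bliss_excess.iloc[1, 1] == pytest.approx(0.0)

    def test_full_kill_over_half_margins_is_plus_25(self):
        doses = np.array([0.0, 1.0])
        vals = np.array([[0.0, 50.0], [50.0, 100.0]])
        res = bliss_surface(matrix_from_grid(vals, doses, doses))
        assert res.bliss_excess.iloc[1, 1] == pytest.approx(25.0)
        assert res.bliss_score == pytest.approx(25.0)

    def test_zero_margin_expected_equals_other_margin(self):
        doses = np.array([0.0, 1.0, 2.0])
        vals = np.zeros((3, 3))
        vals[0, :] = [0.0, 30.0, 60.0]  # drug B margin
        vals[1:, 1:] = [[30.0, 60.0], [30.0, 60.0]]  # combos equal B alone
        res = bliss_surface(matrix_from_grid(vals, doses, doses))
        np.testing.assert_allclose(res.bliss_excess.to_numpy()[1:, 1:], 0.0, atol=1e-12)

    def test_margins_required(self):
        dm = matrix_from_grid(np.zeros((2, 2)), np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="margins"):
            bliss_surface(dm)

    def test_dose_label_order_invariance(self):
        cfg = SimulationConfig(seed=5, synergy_delta=10.0)
        dm, _ = gen_dose_matrix(cfg)
        res1 = bliss_surface(dm)
        # reversed labels sort back to the same canonical grid on plate I/O
        flipped = DoseMatrix(
            drug_a=dm.drug_a,
            drug_b=dm.drug_b,
            doses_a=dm.doses_a,
            doses_b=dm.doses_b,
            values=dm.values.copy(),
            kind="percent",
        )
        assert bliss_surface(flipped).bliss_score == pytest.approx(res1.bliss_score)


class TestFitMonotherapy:
    def test_recovers_hill_parameters_within_one_percent(self):
        e = _hill(DOSES, 0.0, 100.0, 1.0, 1.0)
        curve = fit_monotherapy(DOSES, e)
        assert curve.method == "hill"
        assert curve.params["ec50"] == pytest.approx(1.0, rel=0.01)
        assert curve.params["h"] == pytest.approx(1.0, rel=0.01)
        assert curve.params["emax"] == pytest.approx(100.0, rel=0.01)
        assert curve.inverse(50.0) == pytest.approx(1.0, rel=0.01)

    def test_constant_effects_fall_back_flat(self):
        with pytest.warns(UserWarning, match="constant"):
            curve = fit_monotherapy(DOSES, np.full(len(DOSES), 20.0))
        assert curve.method == "flat"
        assert np.isnan(curve.inverse(50.0))

    def test_inverse_of_predict_roundtrip(self):
        e = _hill(DOSES, 5.0, 90.0, 2.0, 1.5)
        curve = fit_monotherapy(DOSES, e)
        for d in (0.5, 1.0, 4.0, 8.0):
            assert curve.inverse(float(curve.predict(d))) == pytest.approx(d, rel=1e-6)

    def test_noisy_nonmonotone_uses_isotonic(self):
        rng = np.random.default_rng(0)
        e = rng.permutation([0.0, 40.0, 10.0, 80.0, 20.0, 60.0, 30.0])
        with pytest.warns(UserWarning, match="isotonic"):
            curve = fit_monotherapy(DOSES, e)
        assert curve.method == "isotonic"
        # monotone predictions
        preds = curve.predict(DOSES)
        assert (np.diff(preds) >= -1e-12).all()

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="3 positive doses"):
            fit_monotherapy(np.array([0.0, 1.0, 2.0]), np.array([0.0, 10.0, 20.0]))


@pytest.mark.parametrize("h", [0.5, 1.0, 2.0])
@pytest.mark.parametrize("ec50", [0.5, 1.0, 3.0])
def test_sham_combination_ci_is_one(h, ec50):
    """Loewe self-consistency: a drug combined with itself has CI = 1."""
    cfg = SimulationConfig(
        seed=0,
        plate_noise_sd=0.0,
        interaction_model="loewe",
        hill_a=(0.0, 100.0, ec50, h),
        hill_b=(0.0, 100.0, ec50, h),
    )
    dm, _ = gen_dose_matrix(cfg)
    ci, _, _ = loewe_ci(dm)
    vals = ci.to_numpy()
    assert np.isfinite(vals[1:, 1:]).all()
    np.testing.assert_allclose(vals[1:, 1:], 1.0, atol=1e-6)


class TestLoewe:
    def test_margin_wells_have_ci_one(self):
        cfg = SimulationConfig(seed=0, plate_noise_sd=0.0, interaction_model="loewe")
        dm, _ = gen_dose_matrix(cfg)
        ci, _, _ = loewe_ci(dm)
        np.testing.assert_allclose(ci.to_numpy()[1:, 0], 1.0, atol=1e-6)
        np.testing.assert_allclose(ci.to_numpy()[0, 1:], 1.0, atol=1e-6)

    def test_loewe_additive_generator_recovered(self):
        cfg = SimulationConfig(
            seed=0,
            plate_noise_sd=0.0,
            interaction_model="loewe",
            hill_a=(0.0, 100.0, 1.0, 1.0),
            hill_b=(0.0, 90.0, 2.5, 1.4),
        )
        dm, _ = gen_dose_matrix(cfg)
        ci, _, _ = loewe_ci(dm)
        vals = ci.to_numpy()[1:, 1:]
        defined = vals[np.isfinite(vals)]
        assert defined.size > 0
        assert (defined > 0.95).all() and (defined < 1.05).all()

    def test_synergistic_wells_have_ci_below_one(self):
        cfg = SimulationConfig(
            seed=0, plate_noise_sd=0.0, interaction_model="loewe", synergy_delta=20.0
        )
        dm, _ = gen_dose_matrix(cfg)
        with pytest.warns(UserWarning, match="undefined"):
            ci, _, _ = loewe_ci(dm)
        vals = ci.to_numpy()[1:, 1:]
        defined = vals[np.isfinite(vals)]
        assert np.median(defined) < 1.0


class TestIsobologram:
    def test_sham_points_near_diagonal(self):
        cfg = SimulationConfig(seed=0, plate_noise_sd=0.0, interaction_model="loewe")
        dm, _ = gen_dose_matrix(cfg)
        iso = isobologram(dm, 50.0)
        assert len(iso) > 0
        # grid interpolation leaves a small deviation from the exact contour
        assert np.abs(iso["x"] + iso["y"] - 1.0).max() < 0.05

    def test_synergistic_points_below_diagonal(self):
        cfg = SimulationConfig(
            seed=1, plate_noise_sd=0.0, interaction_model="bliss", synergy_delta=25.0
        )
        dm, _ = gen_dose_matrix(cfg)
        iso = isobologram(dm, 50.0)
        assert (iso["x"] + iso["y"] < 1.0).all()

    def test_antagonistic_points_above_diagonal(self):
        cfg = SimulationConfig(
            seed=1, plate_noise_sd=0.0, interaction_model="loewe", synergy_delta=-25.0
        )
        dm, _ = gen_dose_matrix(cfg)
        iso = isobologram(dm, 50.0)
        assert (iso["x"] + iso["y"] > 1.0).all()

    def test_unreachable_level_names_ranges(self):
        cfg = SimulationConfig(
            seed=0, plate_noise_sd=0.0, hill_a=(0.0, 30.0, 1.0, 1.0), hill_b=(0.0, 30.0, 1.0, 1.0)
        )
        dm, _ = gen_dose_matrix(cfg)
        with pytest.raises(ValueError, match="not reachable"):
            isobologram(dm, 50.0)

    def test_analyze_matrix_collects_everything(self):
        cfg = SimulationConfig(seed=2, plate_noise_sd=0.0, synergy_delta=15.0)
        dm, _ = gen_dose_matrix(cfg)
        res = analyze_matrix(dm, effect_level=50.0)
        assert res.bliss_score > 0
        assert res.loewe_ci is not None
        assert res.isobologram is not None and len(res.isobologram) > 0


class TestSynergyVsDiscordance:
    def test_perfect_linear_pairs(self):
        out = synergy_vs_discordance([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["n"] == 4

    def test_antimonotone_pairs(self):
        out = synergy_vs_discordance([1.0, 2.0, 3.0], [9.0, 4.0, 1.0])
        assert out["spearman_rho"] == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 paired"):
            synergy_vs_discordance([1.0, 2.0], [1.0, 2.0])

    def test_planted_positive_coupling_detected(self):
        # cell lines with higher discordance show higher Bliss synergy
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(50):
            dr = rng.uniform(0.5, 5.0, 6)
            bliss = 4.0 * dr + rng.normal(0, 1.0, 6)
            if synergy_vs_discordance(bliss, dr)["pearson_r"] > 0:
                hits += 1
        assert hits >= 48
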