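"""Fiber analysis: Hill fits, k_tr fits, ATPase calibration, QC filter."""

import numpy as np
import pandas as pd
import pytest

from sarcokit.errors import CalibrationError, FitError, InvalidSpecificationError
from sarcokit.fiber import (
    ForcePCaDataset,
    atpase_rate,
    fit_hill,
    fit_ktr,
    hill_curve,
    normalize_force,
    qc_fiber,
    qc_roster,
    tension_cost,
)
from sarcokit.synthetic import PCA_GRID, gen_force_pca, gen_ktr_trace
from sarcokit.trace import Trace


class TestFitHill:
    def test_noiseless_recovery_on_standard_grid(self):
        ds, _ = gen_force_pca(pca50=5.8, n_h=2.0, noise_sd=0.0, seed=0)
        fit = fit_hill(ds)
        assert fit.pca50 == pytest.approx(5.8, abs=1e-6)
        assert fit.n_h == pytest.approx(2.0, abs=1e-6)
        assert fit.floor == pytest.approx(0.0, abs=1e-6)
        assert fit.ceiling == pytest.approx(1.0, abs=1e-6)

    def test_constant_force_is_degenerate(self):
        ds = ForcePCaDataset(pca=np.array(PCA_GRID), force=np.full(7, 0.5))
        with pytest.raises(FitError):
            fit_hill(ds)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            fit_hill(ForcePCaDataset(pca=[4.5, 5.0, 5.5], force=[1.0, 0.5, 0.1]))

    def test_invariant_to_point_order(self):
        ds, _ = gen_force_pca(noise_sd=0.02, seed=9)
        perm = np.random.default_rng(0).permutation(len(ds.pca))
        shuffled = ForcePCaDataset(pca=ds.pca[perm], force=ds.force[perm])
        assert fit_hill(shuffled).pca50 == pytest.approx(fit_hill(ds).pca50, abs=1e-8)

    def test_translation_equivariance_in_pca(self):
        ds, _ = gen_force_pca(noise_sd=0.02, seed=10)
        shifted = ForcePCaDataset(pca=ds.pca + 0.7, force=ds.force)
        assert fit_hill(shifted).pca50 == pytest.approx(
            fit_hill(ds).pca50 + 0.7, abs=1e-6
        )

    def test_mean_bias_small_at_declared_noise(self):
        errs = [
            fit_hill(gen_force_pca(noise_sd=0.02, seed=s)[0]).pca50 - 5.8
            for s in range(60)
        ]
        assert np.mean(np.abs(errs)) < 0.05


def test_normalize_force():
    out = normalize_force([12.3, 6.15], 12.3)
    assert out == pytest.approx([1.0, 0.5])
    assert np.all(normalize_force(np.zeros(3), 2.0) == 0.0)
    with pytest.raises(InvalidSpecificationError):
        normalize_force([1.0], 0.0)


class TestFitKtr:
    def test_noiseless_rate_recovery(self):
        tr, _ = gen_ktr_trace(7.0, noise_sd=0.0, seed=0)
        assert fit_ktr(tr, (0.0, 2.0)).rate == pytest.approx(7.0, abs=1e-6)

    def test_noisy_rate_within_three_percent(self):
        tr, _ = gen_ktr_trace(7.0, noise_sd=0.01, seed=3)
        assert fit_ktr(tr, (0.0, 2.0)).rate == pytest.approx(7.0, rel=0.03)

    def test_flat_record_rejected(self):
        flat = Trace(np.arange(0, 1, 1e-3), np.full(1000, 0.4))
        with pytest.raises(FitError):
            fit_ktr(flat, (0.0, 1.0))

    def test_short_window_rejected(self):
        tr, _ = gen_ktr_trace(7.0, noise_sd=0.0, seed=0)
        with pytest.raises(InvalidSpecificationError):
            fit_ktr(tr, (0.0, 0.01))


class TestAtpaseRate:
    def _trace(self, slope, step, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 60.0, 0.05)
        y = 1.2 + slope * t
        for ti in (20.0, 40.0):
            y = y + (t > ti) * step
        return Trace(t, y + rng.normal(0, noise, len(t))), [(20.0, 5e-10), (40.0, 5e-10)]

    def test_linear_algebra_oracle(self):
        # slope -0.01 A/s with -0.02 A per 5e-10 mol -> 2.5e-10 mol/s
        tr, inj = self._trace(-0.01, -0.02)
        assert atpase_rate(tr, inj) == pytest.approx(2.5e-10, rel=1e-9)

    def test_flat_baseline_gives_zero_rate(self):
        tr, inj = self._trace(0.0, -0.02)
        assert atpase_rate(tr, inj) == pytest.approx(0.0, abs=1e-15)

    def test_offset_invariance_and_slope_linearity(self):
        tr, inj = self._trace(-0.01, -0.02)
        shifted = Trace(tr.t, tr.y + 5.0)
        assert atpase_rate(shifted, inj) == pytest.approx(atpase_rate(tr, inj))
        tr2, inj2 = self._trace(-0.02, -0.02)
        assert atpase_rate(tr2, inj2) == pytest.approx(2 * atpase_rate(tr, inj))

    def test_two_equal_steps_average_to_one(self):
        tr, inj = self._trace(-0.01, -0.02)
        assert atpase_rate(tr, inj[:1]) == pytest.approx(atpase_rate(tr, inj))

    def test_positive_step_is_calibration_error(self):
        tr, inj = self._trace(-0.01, +0.02)
        with pytest.raises(CalibrationError):
            atpase_rate(tr, inj)


class TestTensionCost:
    def test_exact_line(self):
        force = np.linspace(0.1, 1.0, 8)
        slope, intercept = tension_cost(force, 2 * force)
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_noisy_ols_recovery(self):
        rng = np.random.default_rng(1)
        force = rng.uniform(0, 1, 50)
        slope, _ = tension_cost(force, 3 * force + 1 + rng.normal(0, 0.1, 50))
        assert slope == pytest.approx(3.0, rel=0.05)

    def test_constant_force_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            tension_cost(np.full(5, 0.5), np.arange(5.0))


class TestQcFiber:
    @pytest.mark.parametrize(
        "pre, post, expected",
        [(100, 85, True), (100, 80, True), (100, 79.9, False)],
    )
    def test_eighty_percent_rule_inclusive(self, pre, post, expected):
        assert qc_fiber(pre, post) is expected

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(InvalidSpecificationError):
            qc_fiber(0.0, 10.0)

    def test_roster_keeps_exactly_the_passing_subset(self):
        rng = np.random.default_rng(5)
        pre = rng.uniform(50, 150, 40)
        ratio = rng.uniform(0.5, 1.0, 40)
        df = pd.DataFrame(
            {"fiber_id": [f"f{i}" for i in range(40)], "pre": pre, "post": pre * ratio}
        )
        kept = qc_roster(df)
        assert set(kept["fiber_id"]) == set(df.loc[ratio >= 0.80, "fiber_id"])


def test_hill_curve_limits():
    assert hill_curve(np.array([-10.0]), 6.0, 2.0)[0] == pytest.approx(1.0)
    assert hill_curve(np.array([20.0]), 6.0, 2.0, floor=0.1)[0] == pytest.approx(0.1)
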