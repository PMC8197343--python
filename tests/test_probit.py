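"""Log-probit fitting: ML correctness, delta-method invariants, the 4-6
probit informative-animal rule, and the parallelism test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from isoquantal.data import DoseResponseDataset, QuantalDoseGroup
from isoquantal.probit import (NonIdentifiableError, ProbitResults,
                               QuantalProbitModel, count_informative,
                               fit_log_probit)
from isoquantal.probit import test_parallelism as parallelism_test

from _oracles import grid_ml_oracle


def _scale_doses(ds: DoseResponseDataset, k: float) -> DoseResponseDataset:
    return DoseResponseDataset(
        ds.subject_label,
        tuple(QuantalDoseGroup(g.dose * k, g.n_subjects, g.n_responders)
              for g in ds.groups))


def _fabricated_results(dataset, intercept_probit, slope, cov=None):
    """ProbitResults at chosen parameters (bypassing estimation)."""
    model = QuantalProbitModel(dataset)
    cov = np.eye(2) * 1e-4 if cov is None else cov
    return ProbitResults(model, intercept_probit - 5.0, slope, cov)


class TestFit:
    def test_symmetric_design_gives_ed50_10(self, symmetric_dataset):
        res = fit_log_probit(symmetric_dataset)
        assert res.ed50 == pytest.approx(10.0, rel=1e-9)
        assert res.slope > 0

    def test_matches_grid_likelihood_oracle(self, fixed_dataset):
        res = fit_log_probit(fixed_dataset)
        ll_oracle, m_oracle, _ = grid_ml_oracle(fixed_dataset)
        assert res.loglike() >= ll_oracle - 1e-6
        assert res.ed50 == pytest.approx(10**m_oracle, rel=1e-6)

    @pytest.mark.parametrize("k", [0.1, 3.7, 250.0])
    def test_scale_equivariance(self, fixed_dataset, k):
        base = fit_log_probit(fixed_dataset)
        scaled = fit_log_probit(_scale_doses(fixed_dataset, k))
        assert scaled.ed50 == pytest.approx(base.ed50 * k, rel=1e-7)
        assert scaled.sem_ed50 == pytest.approx(base.sem_ed50 * k, rel=1e-6)
        assert scaled.slope == pytest.approx(base.slope, rel=1e-7)
        assert scaled.se_log10_ed50 == pytest.approx(base.se_log10_ed50,
                                                     rel=1e-6)

    def test_delta_method_invariants(self, fixed_dataset):
        res = fit_log_probit(fixed_dataset)
        assert res.ed50 == pytest.approx(10**res.log10_ed50, rel=1e-12)
        assert res.sem_ed50 == pytest.approx(
            res.ed50 * math.log(10) * res.se_log10_ed50, rel=1e-12)
        # the fitted line passes through 5 probits at the ED50
        assert (res.intercept + res.slope * res.log10_ed50
                == pytest.approx(5.0, abs=1e-9))
        cov = res.covariance
        assert cov.shape == (2, 2)
        assert cov[0, 1] == pytest.approx(cov[1, 0])
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)

    def test_working_probit_agrees_roughly_with_ml(self, fixed_dataset):
        ml = fit_log_probit(fixed_dataset)
        legacy = fit_log_probit(fixed_dataset, method="working-probit")
        assert legacy.ed50 == pytest.approx(ml.ed50, rel=0.10)

    def test_all_zero_and_all_one_are_non_identifiable(self):
        for k in (0, 8):
            ds = DoseResponseDataset("X", tuple(
                QuantalDoseGroup(d, 8, k) for d in (1.0, 2.0, 4.0)))
            with pytest.raises(NonIdentifiableError):
                fit_log_probit(ds)

    def test_single_dose_rejected(self):
        ds = DoseResponseDataset("X", (QuantalDoseGroup(1.0, 8, 4),))
        with pytest.raises(NonIdentifiableError, match="2 dose levels"):
            fit_log_probit(ds)

    def test_decreasing_response_rejected(self):
        ds = DoseResponseDataset("X", (QuantalDoseGroup(1.0, 8, 7),
                                       QuantalDoseGroup(10.0, 8, 4),
                                       QuantalDoseGroup(100.0, 8, 1)))
        with pytest.raises(NonIdentifiableError, match="not monotone"):
            fit_log_probit(ds)

    def test_summary_contains_key_quantities(self, fixed_dataset):
        res = fit_log_probit(fixed_dataset)
        text = res.summary()
        assert "ED50" in text and f"{res.ed50:10.4f}" in text


class TestInformativeCount:
    def test_only_mid_band_group_counts(self):
        # probits 3.5 / 5.0 / 6.5 at the three doses: middle group only
        ds = DoseResponseDataset("X", (QuantalDoseGroup(10**-1.5, 8, 1),
                                       QuantalDoseGroup(1.0, 8, 4),
                                       QuantalDoseGroup(10**1.5, 8, 7)))
        res = _fabricated_results(ds, intercept_probit=5.0, slope=1.0)
        assert count_informative(ds, res) == 8

    def test_band_is_closed_at_4_and_6(self):
        ds = DoseResponseDataset("X", (QuantalDoseGroup(0.1, 8, 2),
                                       QuantalDoseGroup(10.0, 8, 6)))
        res = _fabricated_results(ds, intercept_probit=5.0, slope=1.0)
        assert res.predict_probit([0.1, 10.0]) == pytest.approx([4.0, 6.0])
        assert count_informative(ds, res) == 16

    def test_matches_direct_enumeration(self, fixed_dataset):
        res = fit_log_probit(fixed_dataset)
        expected = 0
        for g in fixed_dataset.groups:
            probit = 5.0 + res.slope * (math.log10(g.dose) - res.log10_ed50)
            if 4.0 <= probit <= 6.0:
                expected += g.n_subjects
        assert res.n_informative == expected
        assert expected % 8 == 0

    def test_observed_convention_skips_extreme_groups(self):
        ds = DoseResponseDataset("X", (QuantalDoseGroup(1.0, 8, 0),
                                       QuantalDoseGroup(10.0, 8, 4),
                                       QuantalDoseGroup(100.0, 8, 8)))
        res = _fabricated_results(ds, intercept_probit=4.0, slope=1.0)
        assert count_informative(ds, res, convention="observed") == 8


class TestParallelism:
    def test_identical_fits_are_parallel(self, fixed_dataset):
        res = fit_log_probit(fixed_dataset)
        par = parallelism_test(res, res)
        assert par.t == 0.0
        assert par.p == pytest.approx(1.0)
        assert par.parallel

    def test_known_slope_difference(self):
        # slopes 3.0 +/- 0.2 and 5.0 +/- 0.2, 40 animals each
        ds = DoseResponseDataset("X", tuple(
            QuantalDoseGroup(d, 8, r)
            for d, r in [(1, 0), (2, 2), (4, 4), (8, 6), (16, 8)]))
        cov = np.array([[1e-4, 0.0], [0.0, 0.2**2]])
        a = _fabricated_results(ds, 5.0, 3.0, cov)
        b = _fabricated_results(ds, 5.0, 5.0, cov)
        par = parallelism_test(a, b)
        assert par.t == pytest.approx(-7.0711, abs=5e-4)
        assert par.df == pytest.approx(76.0, rel=1e-9)
        # independent check of the two-sided tail by numerical integration
        pdf = stats.t(par.df).pdf
        tail, _ = integrate.quad(pdf, abs(par.t), np.inf)
        assert par.p == pytest.approx(2 * tail, rel=1e-6)
        assert not par.parallel

    def test_equal_slopes_give_t_zero_regardless_of_se(self):
        ds = DoseResponseDataset("X", (QuantalDoseGroup(1.0, 8, 2),
                                       QuantalDoseGroup(10.0, 8, 6)))
        a = _fabricated_results(ds, 5.0, 3.0, np.diag([1e-4, 0.3**2]))
        b = _fabricated_results(ds, 5.0, 3.0, np.diag([1e-4, 0.4**2]))
        assert parallelism_test(a, b).t == 0.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(k=st.floats(min_value=0.01, max_value=100.0,
                   allow_nan=False, allow_infinity=False))
def test_scale_equivariance_property(k):
    """Multiplying all doses by k multiplies ED50 by k, slope unchanged."""
    ds = DoseResponseDataset("X", tuple(
        QuantalDoseGroup(d, 8, r)
        for d, r in [(2, 1), (4, 2), (8, 5), (16, 7)]))
    base = fit_log_probit(ds)
    scaled = fit_log_probit(_scale_doses(ds, k))
    assert scaled.ed50 == pytest.approx(base.ed50 * k, rel=1e-6)
    assert scaled.slope == pytest.approx(base.slope, rel=1e-6)
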