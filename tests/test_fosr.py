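"""Function-on-scalar model: basis/penalty structure, REML fitting,
reduction to scalar mixed-model oracles, and pointwise inference."""

import numpy as np
import pandas as pd
import pytest

import hrvfda as h
from hrvfda import fosr, synth
from hrvfda.fosr import BasisSpec, FoSFit, FunctionalDesign

from conftest import ols_on_subject_means, single_covariate_design


# ---------------------------------------------------------------------------
# basis / penalty / design


def test_cyclic_basis_partition_of_unity_and_wrap():
    B = fosr.cyclic_bspline_design(np.linspace(0, 288, 577)[:-1], 24)
    assert np.allclose(B.sum(axis=1), 1.0)
    # continuity across the midnight wrap
    b_end = fosr.cyclic_bspline_design(np.array([287.999]), 24)
    b_zero = fosr.cyclic_bspline_design(np.array([0.0]), 24)
    assert np.allclose(b_end, fosr.cyclic_bspline_design(np.array([-0.001]) % 288, 24))
    assert np.max(np.abs(b_end - b_zero)) < 1e-3


def test_cyclic_penalty_null_space_is_constant():
    P = fosr.difference_penalty(24, order=2, cyclic=True)
    ev, V = np.linalg.eigh(P)
    assert (ev > 1e-9).sum() == 23
    const = np.ones(24) / np.sqrt(24)
    assert np.allclose(P @ const, 0.0, atol=1e-12)


def test_basis_spec_validation():
    with pytest.raises(ValueError):
        BasisSpec(n_basis=3)
    with pytest.raises(NotImplementedError):
        BasisSpec(degree=2)


def _cohort(n=12, seed=4, **kw):
    cfg = synth.full_wear_config(n_subjects=n, n_days=2, seed=seed, **kw)
    cov, params = h.simulate_cohort(cfg)
    epochs = h.simulate_epoch_table(params)
    prof, _ = h.build_profiles(epochs)
    return cov, params, prof


def test_build_design_centering_and_curve_counts():
    cov, _, prof = _cohort()
    primary = h.build_design(prof, cov, model="primary")
    assert len(primary.names) == 7  # intercept + MCI + 5 adjustment terms
    assert abs(primary.X[:, primary.names.index("age")].mean()) < 1e-10 * 100
    secondary = h.build_design(prof, cov, model="secondary")
    assert len(secondary.names) == 10
    # centering example: ages {70, 80, 90} -> {-10, 0, 10}
    centered = np.array([70.0, 80.0, 90.0])
    assert np.allclose(centered - centered.mean(), [-10.0, 0.0, 10.0])


def test_build_design_join_error_lists_ids():
    cov, _, prof = _cohort()
    with pytest.raises(fosr.JoinError, match="S001"):
        h.build_design(prof, cov[cov.subject_id != "S001"])


def test_design_rejects_collinear_covariates():
    cov, _, prof = _cohort()
    y = prof["y"].to_numpy()
    n_sub = prof["subject_id"].nunique()
    wide = prof.pivot(index="subject_id", columns="bin", values="y").to_numpy()
    x = np.ones(n_sub)  # duplicate of the intercept
    with pytest.raises(ValueError, match="collinear"):
        single_covariate_design(wide, x)


# ---------------------------------------------------------------------------
# fitting


def _flat_effect_data(seed=5, n_sub=20, gamma=(2.0, 1.0), sd_b=0.4, sd_e=0.5):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.4, n_sub).astype(float)
    b = rng.normal(0, sd_b, n_sub)
    y = gamma[0] + gamma[1] * x[:, None] + b[:, None] \
        + rng.normal(0, sd_e, (n_sub, 288))
    return y, x


def test_reduction_to_gls_oracle_under_infinite_smoothing():
    """lambda -> inf at minimal basis reduces to the scalar mixed model.

    For balanced data the GLS estimate of subject-level effects equals
    OLS on the subject means, independent of the intercept variance.
    """
    y, x = _flat_effect_data()
    design = single_covariate_design(y, x)
    fit = h.fit(design, BasisSpec(n_basis=4), fixed_curve_lambda=1e8)
    gamma = ols_on_subject_means(y, x)
    for k, name in enumerate(["intercept", "x"]):
        curve = fit.beta[name]
        assert curve.max() - curve.min() < 1e-4
        assert np.max(np.abs(curve - gamma[k])) < 1e-4


def test_constant_effect_recovered_within_half_a_tenth():
    """Free REML on flat-truth data stays within 0.05 of the scalar oracle."""
    y, x = _flat_effect_data(seed=9)
    design = single_covariate_design(y, x)
    fit = h.fit(design)
    gamma = ols_on_subject_means(y, x)
    assert np.max(np.abs(fit.beta["x"] - gamma[1])) < 0.05


def test_variance_components_recovered():
    y, x = _flat_effect_data(seed=13, n_sub=60, sd_b=0.5, sd_e=0.8)
    fit = h.fit(single_covariate_design(y, x))
    assert fit.sigma2_eps == pytest.approx(0.64, rel=0.1)
    assert fit.sigma2_b == pytest.approx(0.25, rel=0.5)


def test_fit_deterministic():
    y, x = _flat_effect_data(seed=21)
    d = single_covariate_design(y, x)
    f1, f2 = h.fit(d), h.fit(d)
    assert f1.reml_neg2 == f2.reml_neg2
    assert np.array_equal(f1.coef, f2.coef)
    for name in f1.names:
        assert np.array_equal(f1.beta[name], f2.beta[name])


def test_null_effect_stays_within_three_se():
    """With a true null MCI curve, |estimate| < 3 SE on >= 95% of bins."""
    cov, _, prof = _cohort(n=81, seed=30, sigma_b=0.3,
                           mci_effect_profile=h.RaisedCosineDip(depth=0.0))
    fit = h.fit(h.build_design(prof, cov))
    frac = np.mean(np.abs(fit.beta["mci"]) < 3 * fit.se["mci"])
    assert frac >= 0.95


def test_nonconvergence_raises_with_iterate():
    y, x = _flat_effect_data(seed=2)
    with pytest.raises(fosr.FitError) as err:
        h.fit(single_covariate_design(y, x), max_iter=1)
    assert err.value.last_rho is not None


# ---------------------------------------------------------------------------
# inference


def _toy_fit(beta, se):
    beta = {"x": np.asarray(beta, dtype=float)}
    se = {"x": np.asarray(se, dtype=float)}
    return FoSFit(
        names=["x"], basis=BasisSpec(), beta=beta, se=se, lambdas={},
        sigma2_b=0.0, sigma2_eps=1.0, edf={}, reml_neg2=0.0,
        coef=np.zeros(1), subject_effects=pd.Series(dtype=float),
        fitted=np.zeros(1), residuals=np.zeros(1), n_obs=1, n_iter=1,
    )


def test_pointwise_ci_normal_quantile_arithmetic():
    fit = _toy_fit(np.full(288, -0.6), np.full(288, 0.2))
    lo, hi = h.pointwise_ci(fit, 0.95)["x"]
    assert lo[0] == pytest.approx(-0.992, abs=1e-3)
    assert hi[0] == pytest.approx(-0.208, abs=1e-3)
    # noise-free limit: the band collapses onto the estimate
    degenerate = _toy_fit(np.full(288, -0.6), np.zeros(288))
    lo0, hi0 = h.pointwise_ci(degenerate)["x"]
    assert np.allclose(lo0, hi0)
    with pytest.raises(ValueError):
        h.pointwise_ci(fit, 1.5)


def test_significance_windows_merge_across_midnight():
    """Exclusion on bins 0-83 and 228-287 reports one 19:00-07:00 window."""
    beta = np.zeros(288)
    beta[:84] = -1.0
    beta[228:] = -1.0
    fit = _toy_fit(beta, np.full(288, 0.1))
    wins = h.significance_windows(fit, "x")
    assert len(wins) == 1
    assert wins[0].label == "19:00-07:00"
    assert wins[0].sign == "negative"
    assert wins[0].n_bins == 84 + 60


def test_significance_windows_empty_and_single_bin():
    fit = _toy_fit(np.zeros(288), np.full(288, 1.0))
    assert h.significance_windows(fit, "x") == []
    beta = np.zeros(288)
    beta[100] = 5.0
    one = h.significance_windows(_toy_fit(beta, np.full(288, 0.1)), "x")
    assert len(one) == 1
    assert one[0].n_bins == 1 and one[0].sign == "positive"
    assert one[0].label == "08:20-08:25"


def test_cohens_d_arithmetic():
    assert h.cohens_d(0.6, 0.8) == pytest.approx(0.75, abs=1e-12)
    assert h.cohens_d(0.0, 0.8) == 0.0
    assert h.cohens_d(1.2, 0.8) == pytest.approx(1.5)
    with pytest.raises(ValueError):
        h.cohens_d(0.6, 0.0)


def test_fit_serialization_round_trip():
    y, x = _flat_effect_data(seed=33, n_sub=10)
    fit = h.fit(single_covariate_design(y, x))
    tidy = fosr.fit_to_frame(fit)
    assert set(tidy["coefficient"]) == {"intercept", "x"}
    assert len(tidy) == 2 * 288
    d = fosr.fit_to_dict(fit)
    assert d["sigma2_eps"] > 0 and len(d["beta"]["x"]) == 288
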