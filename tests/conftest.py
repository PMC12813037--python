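import numpy as np
import pytest

from hrvfda.fosr import FunctionalDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def single_covariate_design(y, x_subject):
    """Balanced single-binary-covariate FunctionalDesign from a wide matrix.

    ``y`` is (n_subjects, 288); ``x_subject`` a per-subject scalar.
    """
    n_sub, n_bins = y.shape
    sid = np.repeat(np.arange(n_sub), n_bins)
    bins = np.tile(np.arange(n_bins), n_sub)
    X = np.column_stack([np.ones(n_sub), np.asarray(x_subject, float)])[sid]
    ids = np.array([f"S{i:03d}" for i in range(n_sub)])
    return FunctionalDesign(y.ravel(), bins, sid, ids, X, ["intercept", "x"])


def ols_on_subject_means(y, x_subject):
    """Independent oracle for the balanced random-intercept model.

    With balanced per-subject observations, generalized least squares for
    subject-level covariates reduces to ordinary least squares on the
    subject means, whatever the intercept variance.
    """
    ybar = y.mean(axis=1)
    W = np.column_stack([np.ones(y.shape[0]), np.asarray(x_subject, float)])
    gamma, *_ = np.linalg.lstsq(W, ybar, rcond=None)
    return gamma
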