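"""Function-on-scalar regression for 24-h Ln(HF-HRV) profiles.

Fits the functional additive mixed model

    Y_i(t) = beta_0(t) + sum_k beta_k(t) x_ik + b_i + eps_i(t),

where ``t`` indexes the 288 five-minute bins of the day, each coefficient
curve is assumed smooth and expanded in a cyclic cubic B-spline basis with
a difference penalty (cyclic so the curves are continuous across the
midnight wrap), ``b_i`` is a scalar Gaussian subject random intercept and
``eps`` is Gaussian white noise.  Smoothing parameters and variance
components are selected by restricted maximum likelihood through the
mixed-model representation of the penalties: each curve's penalty acts as
a scaled random-effect precision whose null space (the constants) is
unpenalised, and the subject intercepts form one extra ridge block.

Writing ``C = [X | Z]`` for the stacked spline/intercept design,
``S(lambda)`` for the block-diagonal penalty and ``A = C'C + S``, the
profiled (negative, doubled) restricted log-likelihood evaluated here is

    Dp/phi + (n - Mp) log(2 pi phi) + log|A| - log|S|_+

with ``Dp = y'y - y'C A^{-1} C'y``, the scale profiled as
``phi = Dp / (n - Mp)``, ``Mp`` the total penalty null-space dimension and
``|S|_+`` the product of positive penalty eigenvalues.  It is minimised
over the log smoothing parameters (one per curve, plus the subject-ridge
ratio ``lambda_b = sigma_eps^2 / sigma_b^2``) with a quasi-Newton method;
everything is deterministic given the design.

Pointwise standard errors come from the posterior covariance of the
penalized fit, ``phi * A^{-1}`` (bias-uncorrected "shading"-style bands;
no simultaneous adjustment and no multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .rr import GRID_BINS

PRIMARY_COVARIATES = ("age", "female", "black", "other_eth", "education")
SECONDARY_EXTRA = ("depression", "diabetes", "hypertension")


class FitError(RuntimeError):
    """REML optimisation failed; carries the last iterate when available."""

    def __init__(self, message: str, last_rho=None, grad_norm=None):
        super().__init__(message)
        self.last_rho = last_rho
        self.grad_norm = grad_norm


class JoinError(ValueError):
    """Profiles and covariates do not join one-to-one on subject id."""


# ---------------------------------------------------------------------------
# basis and penalty


def cyclic_bspline_design(t, n_basis: int, period: float = GRID_BINS) -> np.ndarray:
    """Design matrix of ``n_basis`` uniform periodic cubic B-splines.

    Cardinal cubic B-splines on knots ``period/n_basis`` apart, wrapped
    around the circle; rows sum to one (partition of unity).
    """
    if n_basis < 4:
        raise ValueError("cyclic cubic basis requires n_basis >= 4")
    u = np.asarray(t, dtype=float) * n_basis / period
    d = (u[:, None] - np.arange(n_basis)[None, :] + 2.0) % n_basis - 2.0
    a = np.abs(d)
    inner = (4.0 - 6.0 * a**2 + 3.0 * a**3) / 6.0
    outer = (2.0 - a) ** 3 / 6.0
    return np.where(a < 1.0, inner, np.where(a < 2.0, outer, 0.0))


def bspline_design(t, n_basis: int, period: float = GRID_BINS) -> np.ndarray:
    """Open (non-cyclic) cubic B-spline design on [0, period]."""
    from scipy.interpolate import BSpline

    if n_basis < 4:
        raise ValueError("cubic basis requires n_basis >= 4")
    interior = np.linspace(0.0, period, n_basis - 2)[1:-1]
    knots = np.r_[[0.0] * 4, interior, [period] * 4]
    x = np.asarray(t, dtype=float)
    return BSpline.design_matrix(x, knots, 3).toarray()


def difference_penalty(n_basis: int, order: int = 2, cyclic: bool = True) -> np.ndarray:
    """Penalty matrix ``D'D`` for order-``order`` coefficient differences."""
    if cyclic:
        d1 = np.roll(np.eye(n_basis), -1, axis=1) - np.eye(n_basis)
        d = np.linalg.matrix_power(d1, order)
    else:
        d = np.diff(np.eye(n_basis), n=order, axis=0)
    return d.T @ d


@dataclass(frozen=True)
class BasisSpec:
    """Spline basis for the coefficient curves.

    24 cubic basis functions with a second-order difference penalty span
    flat-to-wiggly daily shapes (one knot per hour); the cyclic default
    enforces continuity across midnight.
    """

    n_basis: int = 24
    degree: int = 3
    penalty_order: int = 2
    cyclic: bool = True

    def __post_init__(self) -> None:
        if self.degree != 3:
            raise NotImplementedError("only cubic (degree 3) bases are supported")
        if self.n_basis < self.penalty_order + 2:
            raise ValueError("n_basis must be >= penalty_order + 2")

    def design(self, t) -> np.ndarray:
        if self.cyclic:
            return cyclic_bspline_design(t, self.n_basis)
        return bspline_design(t, self.n_basis)

    def penalty(self) -> np.ndarray:
        return difference_penalty(self.n_basis, self.penalty_order, self.cyclic)


# ---------------------------------------------------------------------------
# design


@dataclass
class FunctionalDesign:
    """Observed (subject, bin, y) triples plus per-observation covariates.

    ``X`` holds the scalar covariates (intercept first) repeated per
    observation; centered covariates have sample mean zero across subjects.
    """

    y: np.ndarray
    bins: np.ndarray
    subject_idx: np.ndarray
    subject_ids: np.ndarray
    X: np.ndarray
    names: list[str]
    n_grid: int = GRID_BINS

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.bins = np.asarray(self.bins, dtype=int)
        self.subject_idx = np.asarray(self.subject_idx, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        if not (len(self.y) == len(self.bins) == len(self.subject_idx)
                == self.X.shape[0]):
            raise ValueError("design arrays must share their first dimension")
        if self.X.shape[1] != len(self.names):
            raise ValueError("names must match X columns")
        present = np.bincount(self.subject_idx, minlength=len(self.subject_ids))
        if np.any(present == 0):
            missing = np.asarray(self.subject_ids)[present == 0]
            raise ValueError(f"subjects without observations: {list(missing)}")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            raise ValueError(
                f"collinear covariate columns among {self.names} "
                f"(rank {rank} < {self.X.shape[1]})"
            )

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def build_design(
    profiles: pd.DataFrame,
    covariates: pd.DataFrame,
    model: str = "primary",
    target: str = "mci",
) -> FunctionalDesign:
    """Join long-form profiles with scalar covariates into a fit-ready design.

    ``model='primary'`` adjusts for age, sex, ethnicity and education;
    ``'secondary'`` additionally for depression, diabetes and hypertension.
    ``target`` names the exposure column: ``'mci'`` or a cognitive domain
    (mapped to its ``impaired_<domain>`` flag from the actuarial
    classifier).  Age and education are centered at the sample average.
    """
    if model not in ("primary", "secondary"):
        raise ValueError("model must be 'primary' or 'secondary'")
    cov = covariates.copy()
    if target != "mci":
        col = target if target in cov.columns else f"impaired_{target}"
        if col not in cov.columns:
            raise ValueError(f"target column for {target!r} not found")
        cov["_target"] = cov[col].astype(float)
    else:
        cov["_target"] = cov["mci"].astype(float)

    prof_ids = pd.Index(profiles["subject_id"].unique())
    cov_ids = pd.Index(cov["subject_id"])
    missing_cov = prof_ids.difference(cov_ids)
    missing_prof = cov_ids.difference(prof_ids)
    if len(missing_cov) or len(missing_prof):
        raise JoinError(
            f"unmatched subjects: no covariates for {list(missing_cov)}, "
            f"no profile for {list(missing_prof)}"
        )

    cov = cov.set_index("subject_id").loc[prof_ids.sort_values()]
    sub = pd.DataFrame(index=cov.index)
    sub["intercept"] = 1.0
    sub[target] = cov["_target"]
    sub["age"] = cov["age"] - cov["age"].mean()
    sub["female"] = cov["female"].astype(float)
    sub["black"] = (cov["ethnicity"] == "NHB").astype(float)
    sub["other_eth"] = (cov["ethnicity"] == "Other").astype(float)
    sub["education"] = cov["education"] - cov["education"].mean()
    if model == "secondary":
        for c in SECONDARY_EXTRA:
            sub[c] = cov[c].astype(float)

    ids = sub.index.to_numpy()
    pos = {sid: i for i, sid in enumerate(ids)}
    obs = profiles.dropna(subset=["y"])
    sidx = obs["subject_id"].map(pos).to_numpy()
    return FunctionalDesign(
        y=obs["y"].to_numpy(),
        bins=obs["bin"].to_numpy(),
        subject_idx=sidx,
        subject_ids=ids,
        X=sub.to_numpy()[sidx],
        names=list(sub.columns),
    )


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FoSFit:
    """Fitted coefficient curves with uncertainty and variance components."""

    names: list[str]
    basis: BasisSpec
    beta: dict[str, np.ndarray]  # name -> 288 values
    se: dict[str, np.ndarray]
    lambdas: dict[str, float]  # per-curve smoothing parameters + 'subject'
    sigma2_b: float
    sigma2_eps: float
    edf: dict[str, float]
    reml_neg2: float
    coef: np.ndarray
    subject_effects: pd.Series
    fitted: np.ndarray
    residuals: np.ndarray
    n_obs: int
    n_iter: int
    grid: np.ndarray = field(default_factory=lambda: np.arange(GRID_BINS))


def fit(
    design: FunctionalDesign,
    basis: BasisSpec | None = None,
    fixed_curve_lambda: float | None = None,
    max_iter: int = 200,
    grad_tol: float = 1e-6,
) -> FoSFit:
    """REML fit of the functional additive mixed model.

    ``fixed_curve_lambda`` pins every curve's smoothing parameter (used by
    the lambda-to-infinity reduction checks); only the subject-ridge ratio
    is then optimised.  Deterministic: no random initialisation.
    """
    basis = basis or BasisSpec()
    q = len(design.names)
    K = basis.n_basis
    m = design.n_subjects
    n = design.n_obs
    p = q * K + m
    if n < p - m + 2:  # penalized dof guard (subject block is ridged)
        raise ValueError(f"too few observations ({n}) for {q} curves of "
                         f"{K} basis functions")

    Bgrid = basis.design(np.arange(design.n_grid))
    Bobs = Bgrid[design.bins]
    C = np.zeros((n, p))
    for k in range(q):
        C[:, k * K : (k + 1) * K] = design.X[:, k, None] * Bobs
    C[np.arange(n), q * K + design.subject_idx] = 1.0

    CtC = C.T @ C
    Cty = C.T @ design.y
    yty = float(design.y @ design.y)

    P = basis.penalty()
    eig = np.linalg.eigvalsh(P)
    pos = eig[eig > eig.max() * 1e-9]
    logdet_P_plus = float(np.sum(np.log(pos)))
    rank_P = int(pos.size)
    null_P = K - rank_P
    Mp = q * null_P  # unpenalised dimensions (the per-curve constants)

    diag_idx = np.arange(p)
    # tiny ridge keeps the normal matrix positive definite in degenerate
    # corners of the smoothing-parameter search (relative size ~1e-10)
    ridge = 1e-10 * float(np.trace(CtC)) / p

    def assemble(lam_curves: np.ndarray, lam_b: float) -> np.ndarray:
        A = CtC.copy()
        for k in range(q):
            sl = slice(k * K, (k + 1) * K)
            A[sl, sl] += lam_curves[k] * P
        A[diag_idx[q * K :], diag_idx[q * K :]] += lam_b
        A[diag_idx, diag_idx] += ridge
        return A

    def unpack(rho: np.ndarray) -> tuple[np.ndarray, float]:
        if fixed_curve_lambda is None:
            return np.exp(rho[:q]), float(np.exp(rho[q]))
        return np.full(q, fixed_curve_lambda), float(np.exp(rho[0]))

    def neg2_reml(rho: np.ndarray) -> float:
        lam_curves, lam_b = unpack(rho)
        A = assemble(lam_curves, lam_b)
        try:
            L = linalg.cholesky(A, lower=True)
        except linalg.LinAlgError:
            return np.inf
        delta = linalg.cho_solve((L, True), Cty)
        Dp = max(yty - float(Cty @ delta), 1e-12)
        phi = Dp / (n - Mp)
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(L))))
        logdet_S = (
            rank_P * float(np.sum(np.log(lam_curves)))
            + q * logdet_P_plus
            + m * np.log(lam_b)
        )
        return (Dp / phi + (n - Mp) * np.log(2 * np.pi * phi)
                + logdet_A - logdet_S)

    n_rho = 1 if fixed_curve_lambda is not None else q + 1
    x0 = np.zeros(n_rho)
    res = optimize.minimize(
        neg2_reml,
        x0,
        method="L-BFGS-B",
        bounds=[(-15.0, 25.0)] * n_rho,
        options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-5, "eps": 1e-6},
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    if res.nit >= max_iter:
        raise FitError(
            f"REML did not converge within {max_iter} iterations "
            f"(|grad| = {grad_norm:.3g})",
            last_rho=res.x,
            grad_norm=grad_norm,
        )

    lam_curves, lam_b = unpack(res.x)
    A = assemble(lam_curves, lam_b)
    L = linalg.cholesky(A, lower=True)
    delta = linalg.cho_solve((L, True), Cty)
    Dp = max(yty - float(Cty @ delta), 1e-12)
    phi = Dp / (n - Mp)
    Ainv = linalg.cho_solve((L, True), np.eye(p))
    V = phi * Ainv
    F = Ainv @ CtC  # influence: edf per block from its trace

    beta, se, edf, lambdas = {}, {}, {}, {}
    for k, name in enumerate(design.names):
        sl = slice(k * K, (k + 1) * K)
        theta = delta[sl]
        beta[name] = Bgrid @ theta
        se[name] = np.sqrt(
            np.clip(np.einsum("ij,jk,ik->i", Bgrid, V[sl, sl], Bgrid), 0.0, None)
        )
        edf[name] = float(np.trace(F[sl, sl]))
        lambdas[name] = float(lam_curves[k])
    lambdas["subject"] = lam_b
    edf["subject"] = float(np.trace(F[q * K :, q * K :]))

    fitted = C @ delta
    return FoSFit(
        names=list(design.names),
        basis=basis,
        beta=beta,
        se=se,
        lambdas=lambdas,
        sigma2_b=phi / lam_b,
        sigma2_eps=phi,
        edf=edf,
        reml_neg2=float(res.fun),
        coef=delta,
        subject_effects=pd.Series(delta[q * K :], index=design.subject_ids),
        fitted=fitted,
        residuals=design.y - fitted,
        n_obs=n,
        n_iter=int(res.nit),
    )


# ---------------------------------------------------------------------------
# inference


def pointwise_ci(fit: FoSFit, level: float = 0.95) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Normal-quantile pointwise bands ``beta +/- z * SE`` per coefficient."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return {
        name: (fit.beta[name] - z * fit.se[name], fit.beta[name] + z * fit.se[name])
        for name in fit.names
    }


@dataclass(frozen=True)
class Window:
    """A maximal run of bins whose CI excludes zero (possibly wrapping)."""

    start_bin: int
    n_bins: int
    sign: str  # 'negative' or 'positive'
    label: str  # clock interval, e.g. '19:00-07:00'


def _fmt_minutes(minutes: int) -> str:
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def _circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of True runs on a circular mask."""
    n = mask.size
    if mask.all():
        return [(0, n)]
    if not mask.any():
        return []
    d = np.diff(np.r_[mask[-1], mask].astype(np.int8))
    starts = np.flatnonzero(d == 1)
    runs = []
    for s in starts:
        ln = 1
        while mask[(s + ln) % n]:
            ln += 1
        runs.append((int(s), ln))
    return runs


def significance_windows(
    fit: FoSFit, coefficient: str, level: float = 0.95
) -> list[Window]:
    """Clock-time intervals where the pointwise CI excludes zero.

    Runs are maximal over consecutive bins, merged across the midnight
    wrap, and labelled as clock intervals (bin k spans [5k, 5k+5) minutes).
    """
    lo, hi = pointwise_ci(fit, level)[coefficient]
    out: list[Window] = []
    for sign, mask in (("negative", hi < 0), ("positive", lo > 0)):
        for start, ln in _circular_runs(mask):
            end_min = ((start + ln) % GRID_BINS) * 5
            if start + ln >= GRID_BINS and (start + ln) % GRID_BINS == 0:
                end_min = 1440
            label = f"{_fmt_minutes(start * 5)}-{_fmt_minutes(end_min)}"
            if ln == GRID_BINS:
                label = "00:00-24:00"
            out.append(Window(start, ln, sign, label))
    return sorted(out, key=lambda w: w.start_bin)


def cohens_d(difference: float, sd_ref: float) -> float:
    """Standardised effect: a group difference over a reference SD.

    ``sd_ref`` is conventionally the sample SD of person-level mean
    Ln(HF-HRV), so a midnight difference of 0.6 over an SD of 0.8 gives
    d = 0.75.
    """
    if sd_ref <= 0:
        raise ValueError("sd_ref must be > 0")
    return difference / sd_ref


# ---------------------------------------------------------------------------
# serialization


def fit_to_frame(fit: FoSFit, level: float = 0.95) -> pd.DataFrame:
    """Tidy per-(coefficient, bin) table: estimate, se, lo, hi."""
    ci = pointwise_ci(fit, level)
    frames = []
    for name in fit.names:
        lo, hi = ci[name]
        frames.append(pd.DataFrame({
            "coefficient": name,
            "bin": np.arange(GRID_BINS),
            "estimate": fit.beta[name],
            "se": fit.se[name],
            "lo": lo,
            "hi": hi,
        }))
    return pd.concat(frames, ignore_index=True)


def fit_to_dict(fit: FoSFit, level: float = 0.95) -> dict:
    """JSON-ready summary of a fit (curves, bands, variance components)."""
    ci = pointwise_ci(fit, level)
    return {
        "names": fit.names,
        "beta": {k: v.tolist() for k, v in fit.beta.items()},
        "se": {k: v.tolist() for k, v in fit.se.items()},
        "ci": {k: {"lo": ci[k][0].tolist(), "hi": ci[k][1].tolist()}
               for k in fit.names},
        "lambdas": fit.lambdas,
        "sigma2_b": fit.sigma2_b,
        "sigma2_eps": fit.sigma2_eps,
        "edf": fit.edf,
        "reml_neg2": fit.reml_neg2,
        "n_obs": fit.n_obs,
        "n_iter": fit.n_iter,
        "basis": {"n_basis": fit.basis.n_basis, "degree": fit.basis.degree,
                  "penalty_order": fit.basis.penalty_order,
                  "cyclic": fit.basis.cyclic},
    }
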