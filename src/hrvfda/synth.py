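"""Synthetic multi-day ambulatory HRV cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of ~81 community-dwelling older adults (~25% MCI), each
wearing an ECG monitor for ~8 days, with 5-minute-epoch Ln(HF-HRV) values
following the additive model

    ln HF_i(t) = beta_0(t) + sum_k beta_k(t) x_ik + b_i + eps,

where beta_0 is a circadian cosinor (mesor ~4.5 ln ms^2), the MCI
coefficient curve is a nocturnal raised-cosine dip peaking at midnight,
b_i ~ N(0, sigma_b^2) is a subject random intercept and eps ~ N(0,
sigma_eps^2) is epoch noise.

Two generation paths are provided on purpose, so model tests decouple from
signal-processing tests:

* the **direct path** (:func:`simulate_epoch_table`) emits epoch-level
  Ln(HF-HRV) straight from the model equation;
* the **RR path** (:func:`simulate_rr_day` / :func:`simulate_rr_epoch`)
  emits beat-by-beat recordings whose HF band power matches the epoch
  targets - an RR sinusoid of amplitude ``A`` at the respiratory frequency
  carries HF power ``A^2/2`` - and then
  :func:`apply_wear_and_artifacts` introduces wear gaps, whole-day
  dropouts and corrupted beats for the cleaning chain to find.

Identical config (including ``seed``) always reproduces identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import cognition
from .rr import DAY_S, EPOCH_S, GRID_BINS, RRSeries, rebuild_times


class ConfigError(ValueError):
    """An invalid generator configuration field (named in the message)."""


class GenerationError(RuntimeError):
    """A requested signal is not physiologically representable."""


#: hours at the left edge of each 5-minute bin
GRID_H = np.arange(GRID_BINS) * (EPOCH_S / 3600.0)

# Cohort covariate margins emulated by simulate_cohort (marginal draws only;
# joint dependence between covariates is deliberately omitted).
AGE_MEAN, AGE_SD, AGE_MIN = 78.3, 5.2, 70.0
EDU_MEAN, EDU_SD = 14.9, 3.3
P_FEMALE = 0.815
ETHNICITIES = ("NHW", "NHB", "Other")
P_ETHNICITY = (0.383, 0.432, 0.185)
P_DEPRESSION = 0.15
P_DIABETES = 0.185
P_HYPERTENSION = 0.679

#: fitted-model covariates, in design order after the intercept
COVARIATE_NAMES = (
    "mci", "age", "female", "black", "other_eth", "education",
    "depression", "diabetes", "hypertension",
)
BETA_NAMES = ("intercept",) + COVARIATE_NAMES


@dataclass(frozen=True)
class CosineCurve:
    """Circadian cosinor: mesor + amplitude * cos(2*pi*(t - acrophase)/24)."""

    mesor: float
    amplitude: float = 0.0
    acrophase_h: float = 0.0

    def evaluate(self, t_h: np.ndarray) -> np.ndarray:
        t = np.asarray(t_h, dtype=float)
        return self.mesor + self.amplitude * np.cos(
            2 * np.pi * (t - self.acrophase_h) / 24.0
        )


@dataclass(frozen=True)
class RaisedCosineDip:
    """Nocturnal deficit curve: a raised-cosine dip of given depth.

    Zero outside a window of ``span_h`` hours centred (circularly) at
    ``center_h``; reaches ``-depth`` at the centre.  Smooth and periodic.
    """

    depth: float
    center_h: float = 0.0
    span_h: float = 12.0

    def evaluate(self, t_h: np.ndarray) -> np.ndarray:
        t = np.asarray(t_h, dtype=float)
        delta = (t - self.center_h + 12.0) % 24.0 - 12.0
        inside = np.abs(delta) <= self.span_h / 2.0
        vals = -self.depth / 2.0 * (1.0 + np.cos(2 * np.pi * delta / self.span_h))
        return np.where(inside, vals, 0.0)


@dataclass(frozen=True)
class WearModel:
    """Wear/missingness model: whole-day dropout plus per-epoch retention.

    ``day_dropout`` is the probability a recorded day carries no usable
    data at all (device off / not worn).  On worn days each epoch is
    retained independently with probability given by a cosinor retention
    curve, clipped to [0, 1].  The defaults (dropout 0.175, flat retention
    0.9) calibrate the mean count of valid recording days on 8-day
    protocols to ~6.6.
    """

    day_dropout: float = 0.175
    retention_mesor: float = 0.9
    retention_amplitude: float = 0.0
    retention_acrophase_h: float = 15.0

    def retention_curve(self, t_h: np.ndarray) -> np.ndarray:
        r = CosineCurve(self.retention_mesor, self.retention_amplitude,
                        self.retention_acrophase_h).evaluate(t_h)
        return np.clip(r, 0.0, 1.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort and its recordings."""

    n_subjects: int = 81
    prop_mci: float = 20 / 81
    mean_profile: CosineCurve = field(
        default_factory=lambda: CosineCurve(mesor=4.5, amplitude=0.5, acrophase_h=3.0)
    )
    mci_effect_profile: RaisedCosineDip = field(
        default_factory=lambda: RaisedCosineDip(depth=0.6, center_h=0.0, span_h=12.0)
    )
    #: constant effects (ln ms^2 per unit) for the remaining covariates
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    sigma_b: float = 0.79
    sigma_eps: float = 1.0
    rr_base_ms: float = 800.0
    rsa_freq_hz: float = 0.25
    n_days: int = 8
    wear_model: WearModel = field(default_factory=WearModel)
    artifact_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not 0.0 <= self.prop_mci <= 1.0:
            raise ConfigError("prop_mci must be in [0, 1]")
        if self.sigma_b < 0:
            raise ConfigError("sigma_b must be >= 0")
        if self.sigma_eps < 0:
            raise ConfigError("sigma_eps must be >= 0")
        if not 0.15 <= self.rsa_freq_hz <= 0.40:
            raise ConfigError("rsa_freq_hz must lie inside [0.15, 0.40]")
        if self.rr_base_ms <= 0:
            raise ConfigError("rr_base_ms must be > 0")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigError("artifact_rate must be in [0, 1]")
        if not 0.0 <= self.wear_model.day_dropout <= 1.0:
            raise ConfigError("wear_model.day_dropout must be in [0, 1]")
        unknown = set(self.covariate_effects) - set(COVARIATE_NAMES[1:]) - {"mci"}
        if unknown:
            raise ConfigError(f"covariate_effects: unknown names {sorted(unknown)}")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)

    def streams(self) -> list[np.random.Generator]:
        """Four deterministic child RNGs: cohort, epoch noise, rr, wear."""
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(c) for c in ss.spawn(4)]


def full_wear_config(**kw) -> GeneratorConfig:
    """Convenience: defaults with no missingness and no artifacts."""
    wm = WearModel(day_dropout=0.0, retention_mesor=1.0, retention_amplitude=0.0)
    kw.setdefault("wear_model", wm)
    kw.setdefault("artifact_rate", 0.0)
    return GeneratorConfig(**kw)


@dataclass
class TrueParameters:
    """Ground truth for recovery tests: coefficient curves on the 288-bin
    grid, the per-subject design row, and the subject random intercepts."""

    grid_h: np.ndarray
    beta_curves: dict[str, np.ndarray]
    design: pd.DataFrame  # index subject_id, columns BETA_NAMES
    subject_intercepts: pd.Series
    config: GeneratorConfig

    def curve_matrix(self) -> np.ndarray:
        return np.vstack([self.beta_curves[k] for k in BETA_NAMES])


def _simulate_scores(mci: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Instrument z-scores + Lawton-Brody counts consistent with status.

    CN subjects draw all ten scores above the -1 SD impairment cutoff and a
    Lawton-Brody count of 0 or 1.  MCI subjects additionally receive a
    pattern firing one of the three actuarial rules (weighted 0.6/0.3/0.1).
    """
    n = mci.size
    z = np.clip(rng.normal(0.3, 0.6, size=(n, 10)), -0.9, None)
    lawton = rng.choice([0, 1], size=n, p=[0.8, 0.2])
    domains = list(cognition.DOMAINS)
    for i in np.flatnonzero(mci):
        rule = rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1])
        if rule == 1:
            d = rng.integers(len(domains))
            z[i, 2 * d : 2 * d + 2] = -1.05 - np.abs(rng.normal(0.4, 0.3, 2))
        elif rule == 2:
            for d in rng.choice(len(domains), size=3, replace=False):
                m = 2 * d + rng.integers(2)
                z[i, m] = -1.05 - np.abs(rng.normal(0.4, 0.3))
        else:
            lawton[i] = 4
    cols = {name: z[:, j] for j, name in enumerate(cognition.INSTRUMENTS)}
    cols["lawton_brody"] = lawton
    return pd.DataFrame(cols)


def simulate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, TrueParameters]:
    """Draw a covariate table and the ground-truth model parameters.

    The covariate table has one row per subject (age, sex, ethnicity,
    education, MCI indicator, comorbidity flags, instrument z-scores); the
    MCI count is exactly ``round(n_subjects * prop_mci)``.
    """
    rng = config.streams()[0]
    n = config.n_subjects
    n_mci = int(round(n * config.prop_mci))
    mci = np.zeros(n, dtype=int)
    mci[rng.permutation(n)[:n_mci]] = 1

    a = (AGE_MIN - AGE_MEAN) / AGE_SD
    age = stats.truncnorm.rvs(a, np.inf, loc=AGE_MEAN, scale=AGE_SD, size=n,
                              random_state=rng)
    education = np.round(np.clip(rng.normal(EDU_MEAN, EDU_SD, n), 6, 22))
    female = rng.binomial(1, P_FEMALE, n)
    ethnicity = rng.choice(ETHNICITIES, size=n, p=P_ETHNICITY)
    depression = rng.binomial(1, P_DEPRESSION, n)
    diabetes = rng.binomial(1, P_DIABETES, n)
    hypertension = rng.binomial(1, P_HYPERTENSION, n)

    subject_id = [f"S{i + 1:03d}" for i in range(n)]
    cov = pd.DataFrame(
        {
            "subject_id": subject_id,
            "mci": mci,
            "age": age,
            "female": female,
            "ethnicity": ethnicity,
            "education": education,
            "depression": depression,
            "diabetes": diabetes,
            "hypertension": hypertension,
        }
    )
    cov = pd.concat([cov, _simulate_scores(mci, rng)], axis=1)

    effects = dict(config.covariate_effects)
    curves: dict[str, np.ndarray] = {
        "intercept": config.mean_profile.evaluate(GRID_H),
        "mci": config.mci_effect_profile.evaluate(GRID_H),
    }
    for name in COVARIATE_NAMES[1:]:
        val = effects.get(name, 0.0)
        curves[name] = (np.asarray(val, dtype=float)
                        if np.ndim(val) == 1
                        else np.full(GRID_BINS, float(val)))
        if curves[name].shape != (GRID_BINS,):
            raise ConfigError(f"covariate_effects[{name!r}] curve must have "
                              f"{GRID_BINS} values")

    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "mci": mci.astype(float),
            "age": age - age.mean(),
            "female": female.astype(float),
            "black": (ethnicity == "NHB").astype(float),
            "other_eth": (ethnicity == "Other").astype(float),
            "education": education - education.mean(),
            "depression": depression.astype(float),
            "diabetes": diabetes.astype(float),
            "hypertension": hypertension.astype(float),
        },
        index=pd.Index(subject_id, name="subject_id"),
    )
    b = pd.Series(rng.normal(0.0, config.sigma_b, n),
                  index=design.index, name="b")
    params = TrueParameters(GRID_H.copy(), curves, design, b, config)
    return cov, params


def truth_matrix(params: TrueParameters) -> np.ndarray:
    """Noise-free subject-by-bin surface: X @ beta(t) + b_i."""
    curves = params.curve_matrix()
    return params.design[list(BETA_NAMES)].to_numpy() @ curves \
        + params.subject_intercepts.to_numpy()[:, None]


def epoch_lnhf_truth(
    params: TrueParameters,
    subject_id: str,
    bin: int,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Noise-free and noisy Ln(HF-HRV) for one subject at one bin."""
    if not 0 <= bin < GRID_BINS:
        raise ValueError(f"bin must be in [0, {GRID_BINS})")
    if subject_id not in params.design.index:
        raise KeyError(f"unknown subject {subject_id!r}")
    x = params.design.loc[subject_id, list(BETA_NAMES)].to_numpy(dtype=float)
    clean = float(x @ params.curve_matrix()[:, bin]
                  + params.subject_intercepts[subject_id])
    rng = rng or np.random.default_rng(params.config.seed)
    noisy = clean + rng.normal(0.0, params.config.sigma_eps)
    return clean, noisy


def simulate_epoch_table(
    params: TrueParameters,
    rng: np.random.Generator | None = None,
    apply_wear: bool = False,
) -> pd.DataFrame:
    """Direct-path epoch table: noisy Ln(HF-HRV) per (subject, day, bin).

    Bypasses RR generation and spectral estimation entirely; every emitted
    epoch is valid with zero interpolated fraction.  With ``apply_wear``
    the wear model thins days and epochs (seed-reproducibly).
    """
    cfg = params.config
    if rng is None:
        rng = cfg.streams()[1]
    n, nd = cfg.n_subjects, cfg.n_days
    surface = truth_matrix(params)
    vals = surface[:, None, :] + rng.normal(0.0, cfg.sigma_eps, (n, nd, GRID_BINS))
    if apply_wear:
        wm = cfg.wear_model
        day_keep = rng.random((n, nd)) >= wm.day_dropout
        retention = wm.retention_curve(GRID_H)
        epoch_keep = rng.random((n, nd, GRID_BINS)) < retention
        mask = day_keep[:, :, None] & epoch_keep
    else:
        mask = np.ones(vals.shape, dtype=bool)
    si, di, bi = np.nonzero(mask)
    ids = params.design.index.to_numpy()
    return pd.DataFrame(
        {
            "subject_id": ids[si],
            "day_index": di,
            "bin": bi,
            "n_beats": int(EPOCH_S / (cfg.rr_base_ms / 1000.0)),
            "frac_interpolated": 0.0,
            "hf_ms2": np.exp(vals[si, di, bi]),
            "ln_hf": vals[si, di, bi],
            "valid": True,
            "reason": "",
        }
    )


def rsa_amplitude_ms(target_lnhf, rr_base_ms: float):
    """Sinusoid amplitude carrying the requested HF power: A = sqrt(2 P)."""
    amp = np.sqrt(2.0 * np.exp(np.asarray(target_lnhf, dtype=float)))
    if np.any(amp >= rr_base_ms):
        raise GenerationError(
            "requested HF power implies RSA amplitude >= mean RR "
            "(non-physiological)"
        )
    return amp


def simulate_rr_epoch(
    target_lnhf: float,
    config: GeneratorConfig,
    start_s: float = 0.0,
    subject_id: str = "S001",
    day_index: int = 0,
) -> RRSeries:
    """One 300-s epoch of RR intervals with HF power ``exp(target_lnhf)``.

    The interval sequence is ``rr_base_ms + A sin(2 pi f tau)`` evaluated at
    the (approximate) previous beat time, with cumulative beat times; a
    sinusoidal tachogram of amplitude A carries band power A^2/2.
    """
    if not np.isfinite(target_lnhf):
        raise GenerationError("target_lnhf must be finite")
    amp = float(rsa_amplitude_ms(target_lnhf, config.rr_base_ms))
    base_s = config.rr_base_ms / 1000.0
    n_max = int(np.ceil((EPOCH_S + 2.0) / ((config.rr_base_ms - amp) / 1000.0)))
    tau0 = start_s + np.arange(n_max) * base_s
    rr = config.rr_base_ms + amp * np.sin(2 * np.pi * config.rsa_freq_hz * tau0)
    t = start_s + np.cumsum(rr) / 1000.0
    keep = t < start_s + EPOCH_S
    return RRSeries(subject_id, day_index, t[keep], rr[keep])


def simulate_rr_day(
    subject_id: str,
    day_index: int,
    targets_lnhf: np.ndarray,
    config: GeneratorConfig,
) -> RRSeries:
    """A full 24-h RR recording hitting per-epoch Ln(HF-HRV) targets.

    ``targets_lnhf`` has one value per 5-minute bin (NaN bins produce no
    beats).  The respiratory sinusoid's phase is continuous across the day;
    only its amplitude steps at epoch boundaries.
    """
    targets = np.asarray(targets_lnhf, dtype=float)
    if targets.shape != (GRID_BINS,):
        raise ValueError(f"targets_lnhf must have {GRID_BINS} values")
    have = np.isfinite(targets)
    amp_bin = np.zeros(GRID_BINS)
    if np.any(have):
        amp_bin[have] = rsa_amplitude_ms(targets[have], config.rr_base_ms)
    base_s = config.rr_base_ms / 1000.0
    n_max = int(DAY_S / base_s) + 64
    tau0 = np.arange(n_max) * base_s  # approximate previous-beat times
    bins0 = np.minimum((tau0 / EPOCH_S).astype(int), GRID_BINS - 1)
    rr = config.rr_base_ms + amp_bin[bins0] * np.sin(
        2 * np.pi * config.rsa_freq_hz * tau0
    )
    t = np.cumsum(rr) / 1000.0
    inside = t < DAY_S
    t, rr = t[inside], rr[inside]
    bins = np.minimum((t / EPOCH_S).astype(int), GRID_BINS - 1)
    worn = have[bins]
    return RRSeries(subject_id, day_index, t[worn], rr[worn])


def apply_wear_and_artifacts(
    series: RRSeries,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[RRSeries, dict]:
    """Thin a recording per the wear model and corrupt beats.

    Returns the degraded series plus a metadata dict (``day_dropped``,
    ``retained_bins``, ``n_corrupted``).  Corrupted intervals are scaled by
    a factor drawn from U(1.4, 1.7) or U(0.3, 0.6) (equal odds, mean 1), so
    they deviate by well over 20% from the local median and are detectable
    downstream; beat times are rebuilt so intervals and times stay
    consistent within wear segments.
    """
    wm = config.wear_model
    if rng.random() < wm.day_dropout:
        empty = RRSeries(series.subject_id, series.day_index,
                         np.empty(0), np.empty(0))
        return empty, {"day_dropped": True,
                       "retained_bins": np.zeros(GRID_BINS, dtype=bool),
                       "n_corrupted": 0}
    retention = wm.retention_curve(GRID_H)
    keep_bin = rng.random(GRID_BINS) < retention
    bins = np.minimum((series.beat_time_s / EPOCH_S).astype(int), GRID_BINS - 1)
    keep = keep_bin[bins]
    t, rr = series.beat_time_s[keep], series.rr_ms[keep].copy()
    interp = series.interpolated[keep]

    n = rr.size
    corrupt = rng.random(n) < config.artifact_rate
    n_corr = int(corrupt.sum())
    if n_corr:
        up = rng.random(n_corr) < 0.5
        factors = np.where(up, rng.uniform(1.4, 1.7, n_corr),
                           rng.uniform(0.3, 0.6, n_corr))
        rr[corrupt] *= factors
        t = rebuild_times(t, rr)
    out = RRSeries(series.subject_id, series.day_index, t, rr, interp)
    return out, {"day_dropped": False, "retained_bins": keep_bin,
                 "n_corrupted": n_corr}


def write_truth_json(params: TrueParameters, path) -> None:
    """Serialize ground-truth curves and intercepts (JSON, text-only)."""
    import json

    payload = {
        "grid_h": params.grid_h.tolist(),
        "beta_curves": {k: v.tolist() for k, v in params.beta_curves.items()},
        "subject_intercepts": params.subject_intercepts.round(10).to_dict(),
        "config": {
            "n_subjects": params.config.n_subjects,
            "prop_mci": params.config.prop_mci,
            "sigma_b": params.config.sigma_b,
            "sigma_eps": params.config.sigma_eps,
            "n_days": params.config.n_days,
            "seed": params.config.seed,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
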