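"""Generator: cohort margins, model-equation truth values, RR synthesis,
wear/artifact plumbing, and seed determinism."""

import numpy as np
import pandas as pd
import pytest

import hrvfda as h
from hrvfda import rr as rr_mod, synth


def test_mci_count_matches_rounded_proportion():
    cov, _ = h.simulate_cohort(h.GeneratorConfig(n_subjects=81, prop_mci=0.247, seed=1))
    assert cov["mci"].sum() == 20
    cov0, _ = h.simulate_cohort(h.GeneratorConfig(n_subjects=10, prop_mci=0.0, seed=1))
    assert cov0["mci"].sum() == 0


def test_cohort_has_expected_columns_and_margins():
    cov, _ = h.simulate_cohort(h.GeneratorConfig(seed=3))
    for col in ("age", "female", "ethnicity", "education", "mci",
                "depression", "diabetes", "hypertension", "lawton_brody"):
        assert col in cov.columns
    assert set(cov["ethnicity"]) <= {"NHW", "NHB", "Other"}
    assert (cov["age"] >= 70).all()


def test_seed_determinism_bit_identical():
    cfg = h.GeneratorConfig(seed=11)
    cov1, p1 = h.simulate_cohort(cfg)
    cov2, p2 = h.simulate_cohort(cfg)
    pd.testing.assert_frame_equal(cov1, cov2)
    for k in synth.BETA_NAMES:
        assert np.array_equal(p1.beta_curves[k], p2.beta_curves[k])
    pd.testing.assert_series_equal(p1.subject_intercepts, p2.subject_intercepts)
    e1 = h.simulate_epoch_table(p1)
    e2 = h.simulate_epoch_table(p2)
    pd.testing.assert_frame_equal(e1, e2)


@pytest.mark.parametrize(
    "kw, field",
    [
        ({"prop_mci": 1.5}, "prop_mci"),
        ({"sigma_b": -0.1}, "sigma_b"),
        ({"sigma_eps": -1.0}, "sigma_eps"),
        ({"rsa_freq_hz": 0.5}, "rsa_freq_hz"),
        ({"artifact_rate": 2.0}, "artifact_rate"),
        ({"n_subjects": 0}, "n_subjects"),
    ],
)
def test_invalid_config_error_names_field(kw, field):
    with pytest.raises(synth.ConfigError, match=field):
        h.GeneratorConfig(**kw)


def _flat_truth_params(**kw):
    kw.setdefault("mean_profile", h.CosineCurve(mesor=4.5, amplitude=0.0))
    kw.setdefault("mci_effect_profile", h.RaisedCosineDip(depth=0.6))
    kw.setdefault("sigma_b", 0.0)
    kw.setdefault("prop_mci", 1.0)
    kw.setdefault("n_subjects", 4)
    kw.setdefault("seed", 2)
    return h.simulate_cohort(h.GeneratorConfig(**kw))


def test_epoch_truth_midnight_arithmetic():
    """beta0 = 4.5 and a 0.6 nocturnal dip give 3.9 at midnight for MCI."""
    _, params = _flat_truth_params()
    clean, _ = synth.epoch_lnhf_truth(params, "S001", bin=0)
    assert clean == pytest.approx(3.9, abs=1e-12)


def test_epoch_truth_zero_curves_gives_zero():
    _, params = _flat_truth_params(
        mean_profile=h.CosineCurve(mesor=0.0),
        mci_effect_profile=h.RaisedCosineDip(depth=0.0),
        sigma_eps=0.0,
    )
    for b in (0, 100, 287):
        clean, noisy = synth.epoch_lnhf_truth(params, "S002", bin=b)
        assert clean == 0.0 and noisy == 0.0


def test_epoch_truth_errors():
    _, params = _flat_truth_params()
    with pytest.raises(KeyError, match="unknown subject"):
        synth.epoch_lnhf_truth(params, "S999", bin=0)
    with pytest.raises(ValueError):
        synth.epoch_lnhf_truth(params, "S001", bin=288)


def test_epoch_noise_sd_monte_carlo():
    """Epoch noise SD recovers sigma_eps within 5% over ~10^4 draws."""
    _, params = _flat_truth_params(n_subjects=1, n_days=35, sigma_eps=1.0)
    epochs = h.simulate_epoch_table(params)
    truth = synth.truth_matrix(params)[0]
    resid = epochs["ln_hf"].to_numpy() - truth[epochs["bin"].to_numpy()]
    assert resid.size >= 10_000
    assert abs(resid.std() - 1.0) < 0.05


def test_rsa_amplitude_identity_and_guard():
    assert synth.rsa_amplitude_ms(np.log(450.0), 800.0) == pytest.approx(30.0)
    with pytest.raises(synth.GenerationError):
        synth.rsa_amplitude_ms(np.log(800.0**2), 800.0)


def test_rr_epoch_constant_when_amplitude_vanishes():
    cfg = synth.full_wear_config(seed=1)
    s = h.simulate_rr_epoch(-40.0, cfg)
    assert s.rr_ms.std() < 1e-6
    assert np.allclose(np.diff(s.beat_time_s), s.rr_ms[1:] / 1000.0)


def test_rr_roundtrip_recovers_target_lnhf():
    """simulate_rr_epoch -> spectral chain recovers Ln(HF) within 0.05."""
    cfg = synth.full_wear_config(seed=1)
    for target in (np.log(450.0), 3.0, 6.5):
        s = h.simulate_rr_epoch(target, cfg)
        _, ln = h.spectra.compute_epoch_lnhf(s.rr_ms)
        assert abs(ln - target) < 0.05


def test_full_retention_yields_288_clean_epochs():
    cfg = synth.full_wear_config(seed=4, n_subjects=1)
    _, params = h.simulate_cohort(cfg)
    targets = synth.truth_matrix(params)[0]
    day = h.simulate_rr_day("S001", 0, targets, cfg)
    day, meta = h.apply_wear_and_artifacts(day, cfg, np.random.default_rng(0))
    assert not meta["day_dropped"] and meta["n_corrupted"] == 0
    epochs = rr_mod.segment_epochs(day)
    assert len(epochs) == 288
    assert (epochs["frac_interpolated"] == 0).all()


def test_artifact_rate_half_flags_about_half_downstream():
    """~50% corruption of a 100-beat epoch is flagged/excised downstream."""
    cfg = h.GeneratorConfig(
        artifact_rate=0.5,
        wear_model=h.WearModel(day_dropout=0.0, retention_mesor=1.0),
        seed=9,
    )
    t = np.arange(1, 101) * 0.8
    s = rr_mod.RRSeries("S001", 0, t, np.full(100, 800.0))
    s2, meta = h.apply_wear_and_artifacts(s, cfg, np.random.default_rng(3))
    clean = rr_mod.flag_and_interpolate(s2)
    affected = int(clean.interpolated.sum()) + (s2.n - clean.n)
    assert abs(affected - 50) <= 15  # 3 SD of Binomial(100, 0.5)


def test_wear_model_day_dropout_reproducible():
    cfg = h.GeneratorConfig(seed=21, n_subjects=2, n_days=3)
    _, params = h.simulate_cohort(cfg)
    targets = synth.truth_matrix(params)[0]
    day = h.simulate_rr_day("S001", 0, targets, cfg)
    outs = []
    for _ in range(2):
        rng = np.random.default_rng(77)
        s, meta = h.apply_wear_and_artifacts(day, cfg, rng)
        outs.append((s.n, meta["retained_bins"].sum(), meta["n_corrupted"]))
    assert outs[0] == outs[1]


def test_direct_path_wear_thins_epochs():
    cfg = h.GeneratorConfig(n_subjects=20, n_days=8, seed=6)
    _, params = h.simulate_cohort(cfg)
    epochs = h.simulate_epoch_table(params, apply_wear=True)
    frac = len(epochs) / (20 * 8 * 288)
    expect = (1 - cfg.wear_model.day_dropout) * cfg.wear_model.retention_mesor
    assert abs(frac - expect) < 0.05
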