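"""Descriptives, person-level summaries, orchestration and plots."""

import json

import numpy as np
import pandas as pd
import pytest

import hrvfda as h
from hrvfda import report, synth


def _epochs_df(values, valid=None, day=0):
    n = len(values)
    return pd.DataFrame({
        "subject_id": "A",
        "day_index": day,
        "bin": range(n),
        "ln_hf": values,
        "valid": valid if valid is not None else [True] * n,
    })


def test_person_level_mean_simple():
    df = _epochs_df([4.0, 5.0, 6.0] + [5.0] * 117)
    assert h.person_level_mean(df) == pytest.approx(
        np.mean([4.0, 5.0, 6.0] + [5.0] * 117))
    single = _epochs_df([4.2] * 100)
    assert h.person_level_mean(single) == pytest.approx(4.2)


def test_person_level_mean_missing_when_nothing_valid():
    df = _epochs_df([4.0] * 120, valid=[False] * 120)
    assert np.isnan(h.person_level_mean(df))


def test_person_level_mean_skips_invalid_days():
    good = _epochs_df([4.0] * 120, day=0)
    bad = _epochs_df([9.0] * 50, day=1)  # below the 100-epoch day rule
    df = pd.concat([good, bad], ignore_index=True)
    assert h.person_level_mean(df) == pytest.approx(4.0)


def _cov(n=20, n_mci=5, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "mci": [1] * n_mci + [0] * (n - n_mci),
        "age": rng.normal(78, 5, n),
        "female": rng.binomial(1, 0.8, n),
        "ethnicity": rng.choice(["NHW", "NHB", "Other"], n),
        "education": rng.normal(15, 3, n),
        "depression": rng.binomial(1, 0.2, n),
        "diabetes": rng.binomial(1, 0.2, n),
        "hypertension": rng.binomial(1, 0.6, n),
    })


def test_summary_counts_and_percentages():
    cov, _ = h.simulate_cohort(h.GeneratorConfig(seed=1))
    summ = h.summarize_cohort(cov)
    eth = summ.table[summ.table.variable == "ethnicity"]
    # percentages per categorical variable sum to 100 up to rounding
    pct = eth["overall"].str.extract(r"\((\d+)%\)")[0].astype(int).sum()
    assert abs(pct - 100) <= 2
    # 20 of 81 MCI renders as 25%
    assert round(100 * cov["mci"].sum() / len(cov)) == 25


def test_identical_groups_give_p_value_one():
    cov = _cov(n=20, n_mci=10)
    cov["diabetes"] = [0, 1] * 10  # identical distribution in both groups
    summ = h.summarize_cohort(cov)
    row = summ.table[(summ.table.variable == "diabetes")].iloc[0]
    assert row["p_value"] == pytest.approx(1.0)


def test_fisher_selected_for_sparse_2x2():
    cov = _cov(n=12, n_mci=3, seed=2)
    cov["diabetes"] = [1, 0, 0] + [0] * 9  # tiny expected counts
    summ = h.summarize_cohort(cov)
    row = summ.table[summ.table.variable == "diabetes"].iloc[0]
    assert row["test"] == "fisher"


def test_summary_order_invariant():
    cov = _cov(seed=5)
    s1 = h.summarize_cohort(cov)
    s2 = h.summarize_cohort(cov.sample(frac=1.0, random_state=9))
    pd.testing.assert_frame_equal(
        s1.table.reset_index(drop=True), s2.table.reset_index(drop=True))


def test_empty_group_skips_tests_with_note():
    cov = _cov(n=10, n_mci=0)
    summ = h.summarize_cohort(cov)
    assert summ.table["p_value"].isna().all()
    assert any("0 members" in n for n in summ.notes)


def test_markdown_render_contains_rows():
    cov = _cov()
    md = h.summarize_cohort(cov).to_markdown()
    assert "| age |" in md and "| ethnicity |" in md


def test_run_log_writes_json_lines(tmp_path):
    path = tmp_path / "log.jsonl"
    log = report.RunLog(path)
    log.event("simulate", seed=3, n_subjects=5)
    log.event("filter", n_retained=5)
    log.close()
    lines = [json.loads(l) for l in path.read_text().splitlines()]
    assert [l["event"] for l in lines] == ["simulate", "filter"]
    assert lines[0]["seed"] == 3


def test_pipeline_smoke_on_tiny_cohort():
    cfg = h.GeneratorConfig(n_subjects=3, n_days=2, seed=14)
    res = h.run_pipeline(cfg)
    assert set(res.epochs.columns) >= {
        "subject_id", "day_index", "bin", "n_beats", "frac_interpolated",
        "hf_ms2", "ln_hf", "valid", "reason"}
    assert res.profiles["subject_id"].nunique() >= 1
    assert res.person_means.notna().all()
    # estimated Ln(HF) sits in a physiological range near the mesor
    assert 2.0 < res.person_means.mean() < 7.0


def test_plots_render_without_display():
    cfg = synth.full_wear_config(n_subjects=16, n_days=2, seed=3)
    cov, params = h.simulate_cohort(cfg)
    epochs = h.simulate_epoch_table(params)
    prof, _ = h.build_profiles(epochs)
    ax = report.plot_profiles(prof, cov)
    assert ax.get_xlabel() == "time of day (h)"
    fit = h.fit(h.build_design(prof, cov, target="mci"),
                h.BasisSpec(n_basis=8))
    axes = report.plot_coefficient_curves(fit)
    assert len(axes) >= len(fit.names)
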