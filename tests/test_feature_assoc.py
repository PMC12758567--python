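"""TSS / filtering / log transform / per-feature LMM / BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microdyad.feature_assoc import (
    FeatureAssociation,
    bh_adjust,
    filter_features,
    fit_feature_models,
    log_transform,
    tss_normalize,
)
from microdyad.simulate import TrueParams, simulate_cohort


def test_tss_basic_and_identity(rng):
    table = pd.DataFrame({"s1": [2, 2, 2], "s2": [1, 0, 3]}, index=list("abc"))
    rel = tss_normalize(table)
    assert np.allclose(rel["s1"], [1 / 3, 1 / 3, 1 / 3])
    big = pd.DataFrame(rng.integers(0, 50, (30, 10)) + 1)
    rel = tss_normalize(big)
    assert np.max(np.abs(rel.sum(axis=0) - 1.0)) < 1e-12
    # scale invariance
    doubled = big.copy()
    doubled[0] = doubled[0] * 2
    assert np.allclose(tss_normalize(doubled)[0], tss_normalize(big)[0])


def test_tss_rejects_zero_sum_sample():
    table = pd.DataFrame({"ok": [1, 2], "bad": [0, 0]})
    with pytest.raises(ValueError, match="bad"):
        tss_normalize(table)


def test_filter_prevalence_ceiling_rule():
    # 10 samples at 10% prevalence -> ceil(1.0) = 1 sample suffices
    rel = pd.DataFrame(np.zeros((2, 10)), index=["hit", "miss"])
    rel.iloc[0, 0] = 0.02
    rel.iloc[1, :] = 0.009
    kept = filter_features(rel, 0.01, 0.10)
    assert kept == ["hit"]


def test_filter_zero_prevalence_keeps_everything_nonzero():
    rel = pd.DataFrame([[0.5, 0.0], [0.0, 0.0]], index=["a", "b"])
    assert filter_features(rel, 0.01, 0.0) == ["a"]


def test_filter_rejects_bad_thresholds():
    rel = pd.DataFrame([[0.5]])
    with pytest.raises(ValueError):
        filter_features(rel, min_abundance=1.5)


def test_log_transform_half_minimum_pseudocount():
    rel = pd.DataFrame({"s1": [0.0], "s2": [0.5], "s3": [0.5]}, index=["f"])
    out = log_transform(rel, ["f"])
    assert out.loc["f", "s1"] == pytest.approx(np.log(0.25))
    assert out.loc["f", "s2"] == pytest.approx(np.log(0.75))


def test_log_transform_monotone_and_constant(rng):
    vals = np.sort(rng.random(8)) + 0.01
    rel = pd.DataFrame([vals], index=["f"], columns=[f"s{i}" for i in range(8)])
    out = log_transform(rel, ["f"]).loc["f"].to_numpy()
    assert np.all(np.diff(out) > 0)
    const = pd.DataFrame([[0.2] * 4], index=["g"], columns=list("wxyz"))
    outc = log_transform(const, ["g"]).loc["g"]
    assert outc.nunique() == 1


def test_log_transform_requires_positive_value():
    rel = pd.DataFrame([[0.0, 0.0]], index=["f"], columns=["a", "b"])
    with pytest.raises(ValueError, match="pseudocount"):
        log_transform(rel, ["f"])


def brute_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        rank = np.sum(p <= pi)
        # min over the tail of sorted p * m / rank
        candidates = [pj * m / np.sum(p <= pj) for pj in p if pj >= pi]
        q[i] = min(1.0, min(candidates))
    return q


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ],
)
def test_bh_known_values(p, expected):
    assert np.allclose(bh_adjust(p), expected)


def test_bh_matches_bruteforce_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(30):
        p = rng.random(rng.integers(1, 40))
        q = bh_adjust(p)
        assert np.allclose(q, brute_bh(p), atol=1e-12)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref, atol=1e-12)


def test_bh_monotone_in_p(rng):
    p = rng.random(50)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_bh_nan_propagates_with_warning():
    with pytest.warns(UserWarning, match="NaN"):
        q = bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(q[1])
    assert not np.isnan(q[0])


def test_duplicate_subject_wave_rejected(small_cohort):
    preds = pd.DataFrame(
        {"sample_id": ["a", "b"], "subject_id": ["s", "s"], "wave": ["T1", "T1"],
         "NEG": [1, 2], "REG": [1, 2], "MD": [1, 2], "age_months": [1, 1]}
    )
    trans = pd.DataFrame([[0.1, 0.2]], index=["f"], columns=["a", "b"])
    with pytest.raises(ValueError, match="duplicate"):
        fit_feature_models(trans, preds)


def test_signal_feature_recovered():
    params = TrueParams(
        n_dyads=70,
        missing_rate=0.0,
        signal_taxa=[(61, "REG", 0.8)],
        seed=23,
    )
    cohort = simulate_cohort(params)
    assoc = FeatureAssociation(role="infant").fit(
        cohort.counts, metadata=cohort.metadata,
        behavior=cohort.behavior, pcs=None,
    )
    res = assoc.results_
    label = cohort.counts.index[61]
    row = res[(res["feature"] == label) & (res["predictor"] == "REG")].iloc[0]
    reg = cohort.behavior["REG"].dropna()
    truth = 0.8 / reg.std()
    assert np.sign(row["coefficient"]) == np.sign(truth)
    assert abs(row["coefficient"] - truth) < 3 * row["se"]
    assert row["q"] < 0.05


def test_age_and_pcs_not_in_adjusted_family(small_cohort):
    assoc = FeatureAssociation(role="infant").fit(
        small_cohort.counts, metadata=small_cohort.metadata,
        behavior=small_cohort.behavior, pcs=None,
    )
    res = assoc.results_
    beh = res[res["predictor"].isin(["NEG", "REG", "MD"])]
    other = res[~res["predictor"].isin(["NEG", "REG", "MD"])]
    assert beh["q"].notna().all()
    assert other["q"].isna().all()
    flagged = res[res["significant"]]
    assert (flagged["q"] < 0.05).all()
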