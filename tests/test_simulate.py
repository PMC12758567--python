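"""Synthetic cohort generator: recursion, determinism, richness structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microdyad.diversity import diversity_table
from microdyad.simulate import (
    TrueParams,
    apply_missingness,
    generate_panel,
    realize_counts,
    simulate_cohort,
)


def _noise_free_params(**kw):
    return TrueParams(
        n_dyads=5,
        intercept_sd=np.zeros(4),
        resid_sd=np.zeros((4, 3)),
        covariate_effects=np.zeros((4, 4)),
        seed=3,
        **kw,
    )


def test_noise_free_panel_is_deterministic_recursion():
    p = _noise_free_params()
    panel = generate_panel(p)
    expected = np.zeros((5, 3, 4))
    expected[:, 0] = p.wave_intercepts[:, 0]
    for t in (1, 2):
        expected[:, t] = p.wave_intercepts[:, t] + expected[:, t - 1] @ p.lag_matrices[t - 1].T
    assert np.max(np.abs(panel.values - expected)) == 0.0


def test_seeded_determinism_bit_identical():
    p = TrueParams(n_dyads=15, seed=42)
    a = generate_panel(p)
    b = generate_panel(p)
    assert np.array_equal(a.values, b.values)
    ca = simulate_cohort(TrueParams(n_dyads=8, seed=9))
    cb = simulate_cohort(TrueParams(n_dyads=8, seed=9))
    pd.testing.assert_frame_equal(ca.counts, cb.counts)
    pd.testing.assert_frame_equal(ca.behavior, cb.behavior)


def test_zero_lag_matrices_give_uncorrelated_waves():
    zero = np.zeros((4, 4))
    p = TrueParams(
        n_dyads=2000,
        lag_matrices=(zero, zero),
        wave_intercepts=np.zeros((4, 3)),
        intercept_sd=np.zeros(4),  # intercepts would induce serial correlation
        covariate_effects=np.zeros((4, 4)),
        seed=21,
    )
    panel = generate_panel(p)
    for k in range(4):
        for j in range(4):
            r = np.corrcoef(panel.values[:, 0, j], panel.values[:, 1, k])[0, 1]
            assert abs(r) < 0.1


def test_nonfinite_parameter_rejected():
    with pytest.raises(ValueError, match="wave_intercepts"):
        TrueParams(wave_intercepts=np.full((4, 3), np.nan))
    with pytest.raises(ValueError, match="intercept_sd"):
        TrueParams(intercept_sd=np.array([0.5, -0.1, 0.5, 0.5]))
    with pytest.raises(ValueError, match="missing_rate"):
        TrueParams(missing_rate=1.0)


def test_missingness_rate_zero_is_noop():
    panel = generate_panel(TrueParams(n_dyads=10, seed=1))
    masked = apply_missingness(panel, 0.0, seed=1)
    assert not masked.mask.any()
    assert np.array_equal(masked.values, panel.values)


def test_missingness_binomial_rate():
    panel = generate_panel(TrueParams(n_dyads=121, seed=2))
    masked = apply_missingness(panel, 0.3, seed=7)
    frac = masked.mask.mean()
    assert abs(frac - 0.3) < 0.04  # Binomial(1452, 0.3) fluctuation band
    again = apply_missingness(panel, 0.3, seed=7)
    assert np.array_equal(masked.mask, again.mask)


def test_missingness_rejects_rate_one():
    panel = generate_panel(TrueParams(n_dyads=5, seed=0))
    with pytest.raises(ValueError, match="rate"):
        apply_missingness(panel, 1.0, seed=0)


def test_degenerate_richness_single_taxon():
    p = TrueParams(
        n_dyads=4,
        richness_profile={"infant": (1, 1, 1), "mother": (1, 1, 1)},
        richness_link=0.0,
        signal_taxa=[],
        seed=6,
    )
    panel = generate_panel(p)
    counts, meta = realize_counts(panel, p)
    nonzero = (counts > 0).sum(axis=0)
    assert (nonzero == 1).all()
    shan = diversity_table(counts, "shannon")
    assert (shan["value"] == 0.0).all()


def test_richness_ordering_under_defaults(small_cohort):
    div = diversity_table(small_cohort.counts, "chao1", metadata=small_cohort.metadata)
    mean = div.groupby(["role", "wave"])["value"].mean()
    inf = [mean[("infant", w)] for w in ("T1", "T2", "T3")]
    mom = [mean[("mother", w)] for w in ("T1", "T2", "T3")]
    assert inf[0] < inf[1] < inf[2]
    for i, m in zip(inf, mom):
        assert i < m


def test_diversity_channel_drives_observed_richness():
    p = TrueParams(n_dyads=170, missing_rate=0.0, seed=13)
    panel = generate_panel(p)
    counts, meta = realize_counts(panel, p)
    s_obs = (counts > 0).sum(axis=0)
    infant = meta[meta["role"] == "infant"]
    chan = []
    for r in infant.itertuples():
        i = panel.dyad_ids.index(r.dyad_id)
        t = panel.waves.index(r.wave)
        chan.append(panel.values[i, t, 0])
    rho = stats.spearmanr(chan, s_obs[infant["sample_id"]].to_numpy()).statistic
    assert rho > 0.5


def test_counts_are_valid_multinomial_tables(small_cohort):
    counts = small_cohort.counts
    assert (counts.to_numpy() >= 0).all()
    assert (counts.sum(axis=0) > 0).all()
    assert counts.to_numpy().dtype.kind in "iu" or np.allclose(
        counts.to_numpy(), np.round(counts.to_numpy())
    )


def test_missingness_propagates_to_tables(masked_cohort):
    panel = masked_cohort.panel
    n_cells_im = (~panel.mask[:, :, 0]).sum()
    n_infant_samples = (masked_cohort.metadata["role"] == "infant").sum()
    assert n_cells_im == n_infant_samples
    beh_inf = masked_cohort.behavior[
        masked_cohort.behavior["subject_id"].str.endswith("_inf")
    ]
    assert beh_inf["NEG"].notna().sum() == (~panel.mask[:, :, 2]).sum()
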