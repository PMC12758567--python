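"""RI-CLPM panel assembly, Gibbs sampler behavior, and summaries."""

import numpy as np
import pandas as pd
import pytest

from microdyad.covariates import reduce_covariates
from microdyad.diversity import diversity_table
from microdyad.panel import DyadPanel
from microdyad.riclpm import (
    DyadicRICLPM,
    PosteriorDraws,
    RiclpmSpec,
    build_panel,
    coverage_experiment,
    gibbs_sample,
    summarize,
)
from microdyad.simulate import TrueParams, generate_panel


def _panel_inputs(cohort):
    div = diversity_table(cohort.counts, "chao1", metadata=cohort.metadata)
    pcs = reduce_covariates(cohort.covariate_table, 4).scores
    return div[["sample_id", "value", "subject_id", "dyad_id", "role", "wave"]], pcs


def test_build_panel_complete_cohort(small_cohort):
    div, pcs = _panel_inputs(small_cohort)
    panel = build_panel(div, small_cohort.behavior, small_cohort.metadata, pcs)
    assert panel.values.shape == (30, 3, 4)
    assert not panel.mask.any()
    assert panel.covariates.shape == (30, 4)


def test_build_panel_marks_single_missing_cell(small_cohort):
    div, pcs = _panel_inputs(small_cohort)
    dyad = small_cohort.metadata["dyad_id"].iloc[0]
    drop_sid = f"{dyad}_I_T2"
    div = div[div["sample_id"] != drop_sid]
    panel = build_panel(div, small_cohort.behavior, small_cohort.metadata, pcs)
    i = panel.dyad_ids.index(dyad)
    assert panel.mask[i, 1, 0]
    assert panel.mask.sum() == 1


def test_build_panel_rejects_duplicates(small_cohort):
    div, pcs = _panel_inputs(small_cohort)
    dup = pd.concat([small_cohort.behavior, small_cohort.behavior.iloc[:1]])
    with pytest.raises(ValueError, match="duplicate"):
        build_panel(div, dup, small_cohort.metadata, pcs)


def test_build_panel_variants_differ_only_in_it_channel(small_cohort):
    div, pcs = _panel_inputs(small_cohort)
    a = build_panel(div, small_cohort.behavior, small_cohort.metadata, pcs, "NEG")
    b = build_panel(div, small_cohort.behavior, small_cohort.metadata, pcs, "REG")
    same = [0, 1, 3]  # IM, MM, MD identical across variants
    assert np.array_equal(a.values[:, :, same], b.values[:, :, same])
    assert not np.array_equal(a.values[:, :, 2], b.values[:, :, 2])


def test_panel_tsv_roundtrip(tmp_path, small_cohort):
    div, pcs = _panel_inputs(small_cohort)
    panel = build_panel(div, small_cohort.behavior, small_cohort.metadata, pcs)
    path = tmp_path / "panel.tsv"
    panel.to_tsv(path)
    back = DyadPanel.from_tsv(path)
    assert np.array_equal(panel.values, back.values)
    assert np.array_equal(panel.mask, back.mask)
    assert np.array_equal(panel.covariates, back.covariates)


def _toy_draws(beta_draws):
    """Single-channel two-wave PosteriorDraws with prescribed beta draws."""
    chains, n = beta_draws.shape
    return PosteriorDraws(
        alpha=np.zeros((chains, n, 1, 2)),
        beta=beta_draws.reshape(chains, n, 1, 1, 1),
        gamma=np.zeros((chains, n, 1, 0)),
        tau2=np.full((chains, n, 1), 0.25),
        sigma2=np.ones((chains, n, 1, 2)),
        channels=("IM",),
        waves=("T1", "T2"),
    )


def test_summary_constant_draws_excludes_zero():
    draws = _toy_draws(np.full((2, 200), 3.0))
    s = summarize(draws)
    row = s.loc["beta[IM<-IM:T1->T2]"]
    assert row["mean"] == 3.0
    assert row["q2.5"] == row["q97.5"] == 3.0
    assert row["excludes_zero"]


def test_summary_symmetric_draws_include_zero(rng):
    x = rng.standard_normal((2, 2000))
    s = summarize(_toy_draws(x))
    row = s.loc["beta[IM<-IM:T1->T2]"]
    assert not row["excludes_zero"]
    assert row["rhat"] < 1.02  # two chains from the same normal are well mixed


def test_summary_requires_enough_draws():
    with pytest.raises(ValueError, match="100"):
        summarize(_toy_draws(np.zeros((2, 50))))


def test_spec_validation():
    with pytest.raises(ValueError):
        RiclpmSpec(n_chains=1)
    with pytest.raises(ValueError):
        RiclpmSpec(n_iter=100, n_burn=100)
    with pytest.raises(ValueError):
        RiclpmSpec(c_max=0.0)


def test_all_missing_channel_rejected():
    panel = generate_panel(TrueParams(n_dyads=10, seed=1))
    panel.mask[:, :, 1] = True
    spec = RiclpmSpec(n_chains=2, n_iter=200, n_burn=50, thin=1)
    with pytest.raises(ValueError, match="MM"):
        gibbs_sample(panel, spec)


def test_prior_bounds_do_not_bind():
    """Widening the uniform coefficient box must not move the posterior."""
    panel = generate_panel(TrueParams(n_dyads=60, seed=8))
    kw = dict(n_chains=2, n_iter=400, n_burn=150, thin=1, seed=4, standardize=True)
    a = gibbs_sample(panel, RiclpmSpec(c_max=100.0, **kw))
    b = gibbs_sample(panel, RiclpmSpec(c_max=1000.0, **kw))
    assert np.array_equal(a.beta, b.beta)


def test_standardized_fit_invariant_to_affine_relabeling():
    params = TrueParams(n_dyads=60, seed=8)
    panel = generate_panel(params)
    shifted = DyadPanel(
        panel.values.copy(), panel.mask.copy(), panel.covariates.copy(),
        list(panel.dyad_ids), panel.channels, panel.waves,
    )
    shifted.values[:, :, 0] = 40.0 + 13.0 * shifted.values[:, :, 0]
    spec = RiclpmSpec(n_chains=2, n_iter=400, n_burn=150, thin=1, seed=4, standardize=True)
    a = gibbs_sample(panel, spec)
    b = gibbs_sample(shifted, spec)
    assert np.allclose(a.beta, b.beta, atol=1e-8)


def test_planted_cross_lag_detected_quickly():
    B1 = np.zeros((4, 4))
    B1[0, 2] = 0.6
    params = TrueParams(
        n_dyads=200,
        lag_matrices=(B1, np.zeros((4, 4))),
        wave_intercepts=np.zeros((4, 3)),
        covariate_effects=np.zeros((4, 4)),
        seed=17,
    )
    panel = generate_panel(params)
    spec = RiclpmSpec(n_chains=2, n_iter=700, n_burn=300, thin=1, seed=2, standardize=False)
    model = DyadicRICLPM(spec).fit(panel)
    row = model.summary_.loc["beta[IM<-IT:T1->T2]"]
    assert row["excludes_zero"]
    assert row["q2.5"] <= 0.6 <= row["q97.5"]


def test_coverage_experiment_degenerate_single_rep():
    params = TrueParams(n_dyads=40, covariate_effects=np.zeros((4, 4)), seed=3)
    spec = RiclpmSpec(n_chains=2, n_iter=300, n_burn=100, thin=1, standardize=False)
    out = coverage_experiment(params, n_reps=1, n_dyads=40, spec=spec)
    assert set(out["coverage"].unique()) <= {0.0, 1.0}
    assert len(out) == 32  # 2 transitions x 4 x 4 paths


def test_estimator_get_set_params():
    m = DyadicRICLPM(n_chains=2, n_iter=300, n_burn=100)
    m.set_params(seed=5)
    assert m.get_params()["spec"].seed == 5
    assert m.get_params()["spec"].n_chains == 2
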