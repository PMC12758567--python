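"""Synthetic dyadic longitudinal cohort generator.

Emulates a mother-infant stool-sampling cohort observed at three waves
(roughly 1, 7 and 14 months postpartum): a four-channel Gaussian panel
process with dyad-level random intercepts and cross-lagged dynamics drives
per-sample taxon richness, temperament and depression scores; count tables
are realized by stick-breaking relative abundances and multinomial
sequencing depth; observations are removed completely at random.  Every
downstream stage therefore has a ground truth to recover.

Channels: IM = infant microbiome diversity, MM = maternal microbiome
diversity, IT = infant temperament (negative emotionality on the latent
scale), MD = maternal depression.  The default parameters encode the
study conditions the package targets: 121 dyads, infant richness rising
steeply across waves while maternal richness stays flat and higher,
infant communities dominated by Bifidobacterium/Escherichia early and by
adult-type genera at the last wave, and roughly 29% of dyad-wave cells
unobserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import DyadPanel, DEFAULT_CHANNELS, DEFAULT_WAVES

__all__ = [
    "TrueParams",
    "generate_panel",
    "realize_counts",
    "apply_missingness",
    "simulate_cohort",
    "write_cohort",
    "SyntheticCohort",
]

_EARLY_GENERA = ["Bifidobacterium", "Escherichia"]
_ADULT_GENERA = [
    "Faecalibacterium", "Roseburia", "Bacteroides", "Blautia",
    "Prevotella", "Ruminococcus", "Akkermansia", "Eubacterium",
]
_MISC_GENERA = [
    "Clostridium", "Lactobacillus", "Streptococcus", "Dorea", "Collinsella",
    "Veillonella", "Parabacteroides", "Alistipes", "Coprococcus", "Dialister",
]


def _default_lag() -> np.ndarray:
    # rows = outcome channel, cols = predictor channel, order IM MM IT MD
    B = np.diag([0.3, 0.3, 0.4, 0.5]).astype(float)
    B[0, 2] = -0.25  # temperament -> later infant diversity
    B[2, 0] = -0.15  # infant diversity -> later temperament
    B[1, 3] = -0.10  # depression -> later maternal diversity
    return B


@dataclass
class TrueParams:
    """Ground-truth generator configuration.

    ``lag_matrices`` holds one coefficient matrix per transition
    (T1->T2, T2->T3); ``wave_intercepts`` / ``resid_sd`` are channels x
    waves; ``signal_taxa`` lists (feature index, behavior scale in
    {NEG, REG, MD}, log-abundance effect per SD of the scale).
    """

    n_dyads: int = 121
    waves: tuple[str, ...] = DEFAULT_WAVES
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    lag_matrices: tuple[np.ndarray, np.ndarray] = field(
        default_factory=lambda: (_default_lag(), _default_lag())
    )
    wave_intercepts: np.ndarray = field(
        default_factory=lambda: np.array(
            [[-1.0, 0.1, 0.5],  # IM rises over waves
             [1.0, 0.7, 0.7],   # MM flat around 1
             [0.0, 0.0, 0.0],   # IT
             [0.0, 0.0, 0.0]]   # MD
        )
    )
    intercept_sd: np.ndarray = field(
        default_factory=lambda: np.array([0.5, 0.5, 0.6, 0.7])
    )
    resid_sd: np.ndarray = field(default_factory=lambda: np.full((4, 3), 0.8))
    covariate_effects: np.ndarray = field(
        default_factory=lambda: np.diag([0.15, 0.15, 0.15, 0.15])
    )
    signal_taxa: list = field(
        default_factory=lambda: [
            (61, "NEG", -0.8), (62, "NEG", 0.8), (63, "REG", 0.8), (64, "REG", -0.8)
        ]
    )
    richness_profile: dict = field(
        default_factory=lambda: {"infant": (60, 110, 160), "mother": (230, 230, 230)}
    )
    library_size: float = 50_000.0
    depth_log_sd: float = 0.3
    stick_theta: dict = field(
        default_factory=lambda: {"infant": (0.8, 1.2, 2.0), "mother": (2.5, 2.5, 2.5)}
    )
    dominance_mass: dict = field(
        default_factory=lambda: {"infant": (0.85, 0.75, 0.6), "mother": (0.5, 0.5, 0.5)}
    )
    signal_base: float = 0.02  # base relative abundance of behavior-linked taxa
    signal_noise_sd: float = 0.8  # biological log-abundance variation of those taxa
    tail_shape: float = 0.5  # gamma shape of non-dominant abundances
    richness_link: float = 0.2  # relative change in S per SD of the diversity channel
    n_features: int = 400
    missing_rate: float = 0.29
    seed: int = 0

    def __post_init__(self):
        self.lag_matrices = tuple(np.asarray(B, dtype=float) for B in self.lag_matrices)
        self.wave_intercepts = np.asarray(self.wave_intercepts, dtype=float)
        self.intercept_sd = np.asarray(self.intercept_sd, dtype=float)
        self.resid_sd = np.asarray(self.resid_sd, dtype=float)
        self.covariate_effects = np.atleast_2d(
            np.asarray(self.covariate_effects, dtype=float)
        )
        self.validate()

    def validate(self) -> None:
        C, W = len(self.channels), len(self.waves)
        for name, arr in (
            ("wave_intercepts", self.wave_intercepts),
            ("intercept_sd", self.intercept_sd),
            ("resid_sd", self.resid_sd),
            ("covariate_effects", self.covariate_effects),
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in parameter '{name}'")
        for t, B in enumerate(self.lag_matrices):
            if not np.all(np.isfinite(B)):
                raise ValueError(f"non-finite values in parameter 'lag_matrices[{t}]'")
            if B.shape != (C, C):
                raise ValueError(f"lag_matrices[{t}] must be {C}x{C}")
        if len(self.lag_matrices) != W - 1:
            raise ValueError("need one lag matrix per wave transition")
        if self.wave_intercepts.shape != (C, W):
            raise ValueError("wave_intercepts must be channels x waves")
        if np.any(self.intercept_sd < 0):
            raise ValueError("parameter 'intercept_sd' must be non-negative")
        if np.any(self.resid_sd < 0):
            raise ValueError("parameter 'resid_sd' must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("parameter 'missing_rate' must lie in [0, 1)")
        if self.n_dyads < 1:
            raise ValueError("parameter 'n_dyads' must be positive")

    @property
    def n_covariates(self) -> int:
        return self.covariate_effects.shape[1]

    def to_json(self, path) -> None:
        d = asdict(self)
        d["lag_matrices"] = [B.tolist() for B in self.lag_matrices]
        for key in ("wave_intercepts", "intercept_sd", "resid_sd", "covariate_effects"):
            d[key] = np.asarray(d[key]).tolist()
        d["richness_profile"] = {k: list(v) for k, v in self.richness_profile.items()}
        d["stick_theta"] = {k: list(v) for k, v in self.stick_theta.items()}
        d["dominance_mass"] = {k: list(v) for k, v in self.dominance_mass.items()}
        d["signal_taxa"] = [list(s) for s in self.signal_taxa]
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "TrueParams":
        d = json.loads(Path(path).read_text())
        d["lag_matrices"] = tuple(np.asarray(B) for B in d["lag_matrices"])
        d["waves"] = tuple(d["waves"])
        d["channels"] = tuple(d["channels"])
        d["signal_taxa"] = [tuple(s) for s in d["signal_taxa"]]
        d["richness_profile"] = {k: tuple(v) for k, v in d["richness_profile"].items()}
        d["stick_theta"] = {k: tuple(v) for k, v in d["stick_theta"].items()}
        d["dominance_mass"] = {k: tuple(v) for k, v in d["dominance_mass"].items()}
        return cls(**d)


def _rng(params: TrueParams, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(params.seed), stream]))


def generate_panel(params: TrueParams, n_dyads: int | None = None) -> DyadPanel:
    """Draw the latent 4-channel panel process.

    Wave-1 cells are Normal(alpha_1 + gamma'x + u, sigma_1^2); later waves
    follow the lagged linear recursion with dyad random intercepts.
    Deterministic given ``params.seed``.
    """
    params.validate()
    n = int(n_dyads or params.n_dyads)
    C, W, K = len(params.channels), len(params.waves), params.n_covariates
    rng = _rng(params, 0)
    x = rng.standard_normal((n, K))
    u = rng.standard_normal((n, C)) * params.intercept_sd
    y = np.zeros((n, W, C))
    base = x @ params.covariate_effects.T + u  # (n, C), wave-invariant part
    y[:, 0] = (
        params.wave_intercepts[:, 0]
        + base
        + rng.standard_normal((n, C)) * params.resid_sd[:, 0]
    )
    for t in range(1, W):
        B = params.lag_matrices[t - 1]
        y[:, t] = (
            params.wave_intercepts[:, t]
            + y[:, t - 1] @ B.T
            + base
            + rng.standard_normal((n, C)) * params.resid_sd[:, t]
        )
    dyads = [f"D{i + 1:04d}" for i in range(n)]
    mask = np.zeros((n, W, C), dtype=bool)
    return DyadPanel(y, mask, x, dyads, params.channels, params.waves, truth=y.copy())


def apply_missingness(panel: DyadPanel, rate: float, seed: int) -> DyadPanel:
    """Mask each cell independently with probability ``rate`` (MCAR).

    Pre-masking values are kept in ``truth`` for recovery scoring only.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("missing rate must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    new_mask = panel.mask | (rng.random(panel.values.shape) < rate)
    return DyadPanel(
        panel.values.copy(), new_mask, panel.covariates.copy(), list(panel.dyad_ids),
        panel.channels, panel.waves,
        truth=panel.truth.copy() if panel.truth is not None else panel.values.copy(),
    )


def feature_labels(n_features: int) -> list[str]:
    """Deterministic last-known-taxon style labels.

    The first 20 features belong to early-infant dominant genera, the next
    40 to adult-type dominant genera, the remainder to a miscellaneous pool.
    """
    labels = []
    for i in range(n_features):
        if i < 20:
            genus = _EARLY_GENERA[i % len(_EARLY_GENERA)]
        elif i < 60:
            genus = _ADULT_GENERA[(i - 20) % len(_ADULT_GENERA)]
        else:
            genus = _MISC_GENERA[(i - 60) % len(_MISC_GENERA)]
        labels.append(f"{genus}_sp{i:03d}")
    return labels


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)


def emit_behavior(panel: DyadPanel, params: TrueParams) -> pd.DataFrame:
    """Map latent IT/MD channels to questionnaire-style scale scores.

    NEG (negative emotionality) is an affine map of the IT channel onto a
    1-7 scale; REG (regulation) is a moderately anti-correlated companion
    scale with its own subject-stable component; MD is mapped onto the
    0-30 summed depression-questionnaire range and rounded to integers.
    One row per subject-wave; temperament rows for infants, depression for
    mothers.
    """
    rng = _rng(params, 1)
    n, W = panel.n_dyads, len(panel.waves)
    it = panel.values[:, :, panel.channels.index("IT")]
    md = panel.values[:, :, panel.channels.index("MD")]
    z_it = _standardize(it)
    z_md = _standardize(md)
    a_i = rng.standard_normal(n)[:, None]
    reg_lat = -0.4 * z_it + 0.6 * a_i + 0.69 * rng.standard_normal((n, W))
    neg = np.clip(np.round(3.5 + 0.8 * z_it, 2), 1.0, 7.0)
    reg = np.clip(np.round(4.5 + 0.8 * reg_lat, 2), 1.0, 7.0)
    mds = np.clip(np.round(5.0 + 4.8 * z_md), 0, 30)
    rows = []
    for i, dyad in enumerate(panel.dyad_ids):
        for t, wave in enumerate(panel.waves):
            rows.append(
                {"subject_id": f"{dyad}_inf", "dyad_id": dyad, "wave": wave,
                 "NEG": neg[i, t], "REG": reg[i, t], "MD": np.nan}
            )
            rows.append(
                {"subject_id": f"{dyad}_mom", "dyad_id": dyad, "wave": wave,
                 "NEG": np.nan, "REG": np.nan, "MD": mds[i, t]}
            )
    return pd.DataFrame(rows)


def realize_counts(
    panel: DyadPanel,
    params: TrueParams,
    behavior: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn latent diversity into taxa count tables.

    Per sample the number of present taxa S scales the role/wave richness
    profile by the standardized diversity-channel value; relative
    abundances come from a stick-breaking (GEM) construction whose first
    sticks go to role/wave-appropriate dominant genera; counts are
    multinomial at a log-normal sequencing depth.  Behavior-linked signal
    taxa get their log relative abundance shifted by
    ``effect * standardized score``.

    Returns (counts features x samples, metadata with one row per sample).
    """
    rng = _rng(params, 2)
    if behavior is None:
        behavior = emit_behavior(panel, params)
    labels = feature_labels(params.n_features)
    n, W = panel.n_dyads, len(panel.waves)
    iIM, iMM = panel.channels.index("IM"), panel.channels.index("MM")
    z_div = {
        "infant": _standardize(panel.values[:, :, iIM]),
        "mother": _standardize(panel.values[:, :, iMM]),
    }
    # standardized behavior per (dyad, wave) for signal shifting
    beh = behavior.set_index(["dyad_id", "wave"])
    z_beh = {}
    for scale, role in (("NEG", "infant"), ("REG", "infant"), ("MD", "mother")):
        sub = behavior.dropna(subset=[scale])
        vals = sub[scale].to_numpy(dtype=float)
        mu, sd = vals.mean(), vals.std()
        z_beh[scale] = {
            (r.dyad_id, r.wave): (getattr(r, scale) - mu) / sd if sd > 0 else 0.0
            for r in sub.itertuples()
        }

    ages = {}
    age_mu, age_sd = (1.0, 7.0, 14.0), (0.15, 0.4, 0.5)
    for i, dyad in enumerate(panel.dyad_ids):
        for t, wave in enumerate(panel.waves):
            ages[(dyad, wave)] = round(float(age_mu[t] + age_sd[t] * rng.standard_normal()), 1)

    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    signal_idx = [s[0] for s in params.signal_taxa]
    for i, dyad in enumerate(panel.dyad_ids):
        for t, wave in enumerate(panel.waves):
            for role in ("infant", "mother"):
                z = z_div[role][i, t]
                base_S = params.richness_profile[role][t]
                S = max(1, int(round(base_S * (1.0 + params.richness_link * z))))
                S = min(S, params.n_features)
                role_scales = ("NEG", "REG") if role == "infant" else ("MD",)
                signal = [(f, sc, eff) for f, sc, eff in params.signal_taxa
                          if sc in role_scales]
                signal_idx_role = np.array([s[0] for s in signal], dtype=int)
                if role == "infant" and t < 2:
                    dominant_pool = np.arange(0, 20)
                else:
                    dominant_pool = np.arange(20, 60)
                dominant_pool = np.setdiff1d(dominant_pool, signal_idx_role)
                n_dom = min(12, S, len(dominant_pool))
                dom = rng.choice(dominant_pool, size=n_dom, replace=False)
                rest_pool = np.setdiff1d(
                    np.arange(params.n_features), np.concatenate([dom, signal_idx_role])
                )
                n_tail = min(S - n_dom, len(rest_pool))
                tail = rng.choice(rest_pool, size=n_tail, replace=False)

                # dominant block: stick-breaking dominance within a fixed mass share
                pi_dom = params.dominance_mass[role][t]
                s_mass = params.signal_base * len(signal)
                pi_dom = min(pi_dom, 1.0 - s_mass) if n_tail else 1.0 - s_mass
                theta = params.stick_theta[role][t]
                v = rng.beta(1.0, theta, size=n_dom)
                v[-1] = 1.0
                stick = np.concatenate([[1.0], np.cumprod(1.0 - v[:-1])])
                w_dom = v * stick
                w_dom = w_dom / w_dom.sum() * pi_dom
                p = np.zeros(params.n_features)
                p[dom] = w_dom
                if n_tail:
                    # heavy-tailed spread keeps rare taxa and singletons realistic
                    g = rng.gamma(params.tail_shape, size=n_tail)
                    p[tail] = g / g.sum() * (1.0 - pi_dom - s_mass)
                for f, sc, eff in signal:
                    zb = z_beh[sc].get((dyad, wave), 0.0)
                    noise = params.signal_noise_sd * rng.standard_normal()
                    p[f] = params.signal_base * np.exp(eff * zb + noise)
                p /= p.sum()
                mu_log = np.log(params.library_size) - 0.5 * params.depth_log_sd**2
                depth = max(1, int(round(rng.lognormal(mu_log, params.depth_log_sd))))
                cvec = rng.multinomial(depth, p)
                if cvec.sum() == 0:  # pragma: no cover - depth >= 1 guarantees mass
                    cvec[chosen[0]] = 1
                rtag = "I" if role == "infant" else "M"
                sid = f"{dyad}_{rtag}_{wave}"
                counts[sid] = cvec
                meta_rows.append(
                    {"sample_id": sid,
                     "subject_id": f"{dyad}_{'inf' if role == 'infant' else 'mom'}",
                     "dyad_id": dyad, "role": role, "wave": wave,
                     "age_months": ages[(dyad, wave)]}
                )
    table = pd.DataFrame(counts, index=labels)
    table.index.name = "feature"
    return table, pd.DataFrame(meta_rows)


@dataclass
class SyntheticCohort:
    """Bundle of all generator outputs after missingness is applied."""

    params: TrueParams
    panel: DyadPanel
    counts: pd.DataFrame
    metadata: pd.DataFrame
    behavior: pd.DataFrame
    covariate_table: pd.DataFrame


def _raw_covariate_table(panel: DyadPanel, params: TrueParams) -> pd.DataFrame:
    """Observable covariates: noisy linear images of the latent PC-like scores."""
    rng = _rng(params, 3)
    names = [
        "maternal_age", "pre_pregnancy_bmi", "income_bracket", "education_years",
        "antibiotic_exposures", "household_size", "breastfeeding_months",
        "delivery_week", "older_siblings", "pet_ownership",
    ]
    K = panel.covariates.shape[1]
    load = rng.standard_normal((len(names), K))
    obs = panel.covariates @ load.T + 0.3 * rng.standard_normal(
        (panel.n_dyads, len(names))
    )
    return pd.DataFrame(obs, index=pd.Index(panel.dyad_ids, name="dyad_id"), columns=names)


def simulate_cohort(params: TrueParams | None = None, **overrides) -> SyntheticCohort:
    """Full generator pipeline: panel -> behavior -> counts -> missingness.

    Samples whose diversity cell is masked are dropped from the count table
    and metadata; masked temperament/depression cells become empty behavior
    entries — mirroring skipped visits and unreturned questionnaires.
    """
    if params is None:
        params = TrueParams(**overrides)
    elif overrides:
        raise ValueError("pass either params or overrides, not both")
    full = generate_panel(params)
    behavior = emit_behavior(full, params)
    counts, metadata = realize_counts(full, params, behavior)
    covtab = _raw_covariate_table(full, params)
    panel = apply_missingness(full, params.missing_rate, params.seed)

    ch = {c: k for k, c in enumerate(panel.channels)}
    keep = []
    for r in metadata.itertuples():
        i = panel.dyad_ids.index(r.dyad_id)
        t = panel.waves.index(r.wave)
        k = ch["IM"] if r.role == "infant" else ch["MM"]
        keep.append(not panel.mask[i, t, k])
    metadata = metadata.loc[keep].reset_index(drop=True)
    counts = counts[metadata["sample_id"].tolist()]

    behavior = behavior.copy()
    for idx, r in behavior.iterrows():
        i = panel.dyad_ids.index(r["dyad_id"])
        t = panel.waves.index(r["wave"])
        if r["subject_id"].endswith("_inf") and panel.mask[i, t, ch["IT"]]:
            behavior.loc[idx, ["NEG", "REG"]] = np.nan
        if r["subject_id"].endswith("_mom") and panel.mask[i, t, ch["MD"]]:
            behavior.loc[idx, "MD"] = np.nan
    return SyntheticCohort(params, panel, counts, metadata, behavior, covtab)


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write counts/metadata/behavior/covariates TSVs plus the truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "behavior": out / "behavior.tsv",
        "covariates": out / "covariates.tsv",
        "truth": out / "truth.json",
    }
    cohort.counts.to_csv(paths["counts"], sep="\t")
    cohort.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    cohort.behavior.to_csv(paths["behavior"], sep="\t", index=False)
    cohort.covariate_table.to_csv(paths["covariates"], sep="\t")
    cohort.params.to_json(paths["truth"])
    return paths
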