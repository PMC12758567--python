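"""Alpha-diversity estimators for taxa and functional-term count tables.

Two within-sample metrics are provided:

* **Chao1** richness — a nonparametric estimator of the true number of
  features in a community, extrapolating the unseen fraction from singleton
  (``F1``) and doubleton (``F2``) counts.  The bias-corrected form

  .. math:: \\hat S = S_{obs} + \\frac{F_1 (F_1 - 1)}{2 (F_2 + 1)}

  is the default because it remains defined when ``F2 = 0``; the classic
  ``F1^2 / (2 F2)`` form is exposed via ``bias_corrected=False``.

* **Shannon** entropy — ``H = -sum(p log p)`` over the relative-abundance
  vector, natural log by default.

Chao1 requires genuine integer counts: singletons and doubletons are
undefined on relative abundances, so TSS-normalized input is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DiversityResult", "chao1", "shannon", "diversity_table"]


@dataclass(frozen=True)
class DiversityResult:
    """Per-sample alpha-diversity value with its supporting statistics."""

    sample_id: str
    metric: str
    value: float
    s_obs: int
    f1: int | None = None
    f2: int | None = None


def _validate_counts(counts, *, require_integer: bool) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("counts contain non-finite values")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if require_integer and not np.allclose(arr, np.round(arr)):
        raise ValueError(
            "counts must be integers: Chao1's singleton/doubleton statistics "
            "are undefined on relative abundances"
        )
    if arr.sum() <= 0:
        raise ValueError("empty sample: all counts are zero")
    return arr


def chao1(counts, *, bias_corrected: bool = True, sample_id: str = "") -> DiversityResult:
    """Chao1 richness of one sample.

    Parameters
    ----------
    counts
        Non-negative integer counts, one entry per feature.
    bias_corrected
        Use the ``F1(F1-1) / (2(F2+1))`` correction term (default).  The
        classic estimator ``F1^2 / (2 F2)`` is returned otherwise and falls
        back to the bias-corrected form when ``F2 == 0``.
    """
    arr = _validate_counts(counts, require_integer=True)
    arr = np.round(arr).astype(np.int64)
    s_obs = int(np.count_nonzero(arr))
    f1 = int(np.sum(arr == 1))
    f2 = int(np.sum(arr == 2))
    if bias_corrected or f2 == 0:
        value = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        value = s_obs + f1 * f1 / (2.0 * f2)
    return DiversityResult(sample_id, "chao1", float(value), s_obs, f1, f2)


def shannon(counts, *, base: float | None = None, sample_id: str = "") -> DiversityResult:
    """Shannon entropy ``-sum(p log p)`` of one sample (natural log default)."""
    arr = _validate_counts(counts, require_integer=False)
    p = arr[arr > 0]
    p = p / p.sum()
    h = float(-np.sum(p * np.log(p)))
    if base is not None:
        h /= np.log(base)
    return DiversityResult(sample_id, "shannon", h, int(np.count_nonzero(arr)))


def diversity_table(
    table: pd.DataFrame,
    metric: str = "chao1",
    *,
    metadata: pd.DataFrame | None = None,
    bias_corrected: bool = True,
) -> pd.DataFrame:
    """Apply one alpha-diversity metric to every sample (column) of a table.

    Parameters
    ----------
    table
        Features x samples count table (rows indexed by feature label).
    metric
        ``"chao1"`` or ``"shannon"``.
    metadata
        Optional sample records indexed by / containing ``sample_id``; when
        given, the result is joined to it and ids must match exactly.

    Returns
    -------
    DataFrame with one row per sample: ``sample_id``, ``value``, ``s_obs``
    and (for chao1) ``f1``/``f2``, plus metadata columns when supplied.
    """
    if metric not in ("chao1", "shannon"):
        raise ValueError(f"unknown metric {metric!r}")
    rows = []
    for sid in table.columns:
        col = table[sid].to_numpy()
        if metric == "chao1":
            res = chao1(col, bias_corrected=bias_corrected, sample_id=str(sid))
            rows.append(
                {"sample_id": res.sample_id, "value": res.value, "s_obs": res.s_obs,
                 "f1": res.f1, "f2": res.f2}
            )
        else:
            res = shannon(col, sample_id=str(sid))
            rows.append({"sample_id": res.sample_id, "value": res.value, "s_obs": res.s_obs})
    out = pd.DataFrame(rows)
    if metadata is not None:
        meta = metadata.reset_index() if metadata.index.name == "sample_id" else metadata
        missing = set(out["sample_id"]) - set(meta["sample_id"].astype(str))
        if missing:
            raise ValueError(
                "samples absent from metadata: " + ", ".join(sorted(missing)[:10])
            )
        out = out.merge(meta, on="sample_id", how="left")
    return out
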