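"""Back-correction of conditional-prediction bias from a CWRES bias vector.

The extended CWRES fit yields bin means b.  Expanding b to observation level
(b-acute) and colouring it with the conditional covariance inverts the CWRES
whitening:

    delta_i = -COV(Y_i)^(1/2) . b_acute_i

estimates the deviation of the misspecified model's conditional predictions
from the (unknown) true ones, so corrected predictions are E(Y_i) - delta_i.
delta and the percentage change are binned by the same IDV bins for display.
A reference "known bias" compares conditional predictions evaluated under the
data-generating model against those of the fitted model; positive values mean
the fitted model overpredicts, matching the sign of delta and %delta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._linalg import sym_sqrt_pair
from .biasmodel import CWRESGrouped
from .binning import BinSpec

__all__ = [
    "expand_bias",
    "correct_predictions",
    "known_bias",
    "CorrectionResult",
    "KnownBiasResult",
]

#: |prediction| below this fraction of the dataset-wide mean |prediction|
#: suppresses the percentage bias for that observation
NEAR_ZERO_REL = 1e-6


def expand_bias(b, bins: BinSpec, idv_per_obs) -> np.ndarray:
    """Repeat each bin-specific mean for every observation in that bin."""
    b = np.asarray(b, dtype=float)
    if b.size != bins.n_bins:
        raise ValueError(f"b has {b.size} entries for {bins.n_bins} bins")
    idv = np.asarray(idv_per_obs, dtype=float)
    if bins.idv_range is not None:
        lo, hi = bins.idv_range
        outside = (idv < lo) | (idv > hi)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} IDV value(s) outside the binning range; "
                "assigned to the nearest edge bin"
            )
    return b[bins.assign(idv)]


@dataclass(frozen=True)
class CorrectionResult:
    """Per-observation and binned prediction-bias estimates for one DV.

    Arrays are aligned with the concatenated observations of the
    :class:`CWRESGrouped` they were computed from; ``pct_delta`` is NaN where
    the prediction was too close to zero.
    """

    subject_ids: tuple
    sizes: tuple
    idv: np.ndarray
    delta: np.ndarray
    corrected: np.ndarray
    pct_delta: np.ndarray
    binned_delta: np.ndarray
    binned_pct_delta: np.ndarray
    bin_counts: np.ndarray
    bins: BinSpec

    def to_frame(self) -> pd.DataFrame:
        ids = np.concatenate(
            [np.repeat(sid, n) for sid, n in zip(self.subject_ids, self.sizes)]
        )
        return pd.DataFrame(
            {
                "ID": ids,
                "IDV": self.idv,
                "BIN": self.bins.assign(self.idv),
                "DELTA": self.delta,
                "CORRECTED": self.corrected,
                "PCT_DELTA": self.pct_delta,
            }
        )


def correct_predictions(
    grouped: CWRESGrouped,
    conds: Mapping,
    expanded: np.ndarray,
    bins: BinSpec,
    *,
    sqrt_method: str = "sym",
    weighting: str = "obs",
) -> CorrectionResult:
    """Back-correct conditional predictions via delta_i = -COV^(1/2) b_acute.

    ``conds`` maps subject id to the fitted model's conditional moments (from
    the same CWRES run the bias model was fitted to); the covariance square
    root uses the same convention as the CWRES whitening.  ``weighting``
    selects whether binned summaries average observations equally ("obs") or
    subjects equally ("subject").
    """
    expanded = np.asarray(expanded, dtype=float)
    if expanded.size != grouped.n_obs:
        raise ValueError("expanded bias not aligned with grouped observations")
    if weighting not in ("obs", "subject"):
        raise ValueError("weighting must be 'obs' or 'subject'")

    deltas, preds, sizes = [], [], []
    start = 0
    for sid, vals, obs_idx in zip(grouped.subject_ids, grouped.values, grouped.obs_index):
        n = vals.size
        b_sub = expanded[start : start + n]
        start += n
        cond = conds[sid]
        idx = np.asarray(obs_idx, dtype=int) if len(obs_idx) else np.arange(n)
        cov = cond.covariance[np.ix_(idx, idx)]
        half, _ = sym_sqrt_pair(cov, method=sqrt_method)
        deltas.append(-half @ b_sub)
        preds.append(cond.expectation[idx])
        sizes.append(n)

    delta = np.concatenate(deltas)
    pred = np.concatenate(preds)
    corrected = pred - delta
    thresh = NEAR_ZERO_REL * np.mean(np.abs(pred))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(np.abs(pred) > thresh, 100.0 * delta / pred, np.nan)
    n_suppressed = int(np.isnan(pct).sum())
    if n_suppressed:
        warnings.warn(
            f"%delta suppressed for {n_suppressed} observation(s) with "
            "near-zero predictions; use delta instead"
        )

    idv = grouped.all_idv
    assign = bins.assign(idv)
    if weighting == "obs":
        binned_delta = _bin_means(delta, assign, bins.n_bins)
        binned_pct = _bin_means(pct, assign, bins.n_bins)
    else:
        binned_delta = _subject_equal_means(delta, assign, grouped, bins.n_bins)
        binned_pct = _subject_equal_means(pct, assign, grouped, bins.n_bins)
    counts = np.bincount(assign, minlength=bins.n_bins)

    return CorrectionResult(
        subject_ids=grouped.subject_ids,
        sizes=tuple(sizes),
        idv=idv,
        delta=delta,
        corrected=corrected,
        pct_delta=pct,
        binned_delta=binned_delta,
        binned_pct_delta=binned_pct,
        bin_counts=counts,
        bins=bins,
    )


def _bin_means(values, assign, n_bins):
    out = np.full(n_bins, np.nan)
    for k in range(n_bins):
        vals = values[assign == k]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[k] = vals.mean()
    return out


def _subject_equal_means(values, assign, grouped: CWRESGrouped, n_bins):
    """Mean over subjects of the per-subject bin means."""
    out = np.zeros((len(grouped.subject_ids), n_bins))
    out.fill(np.nan)
    start = 0
    for i, vals in enumerate(grouped.values):
        n = vals.size
        sub_assign = assign[start : start + n]
        sub_vals = values[start : start + n]
        for k in np.unique(sub_assign):
            v = sub_vals[sub_assign == k]
            v = v[np.isfinite(v)]
            if v.size:
                out[i, k] = v.mean()
        start += n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(out, axis=0)


@dataclass(frozen=True)
class KnownBiasResult:
    """Reference bias from paired true/fitted conditional predictions."""

    percent: np.ndarray
    n_undefined: int
    binned_percent: np.ndarray | None = None
    bin_counts: np.ndarray | None = None


def known_bias(
    y_sim,
    y_est,
    bins: BinSpec | None = None,
    idv=None,
) -> KnownBiasResult:
    """Percent known bias of fitted conditional predictions.

    ``y_sim`` are conditional predictions under the data-generating model,
    ``y_est`` those under the fitted model, aligned per observation.  The
    percentage is reported relative to ``y_sim`` with a positive sign where
    the fitted model overpredicts, matching the sign convention of %delta.
    Entries with ``y_sim`` = 0 are undefined and excluded from binned means.
    """
    y_sim = np.asarray(y_sim, dtype=float)
    y_est = np.asarray(y_est, dtype=float)
    if y_sim.shape != y_est.shape:
        raise ValueError("y_sim and y_est must be aligned")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(y_sim != 0, 100.0 * (y_est - y_sim) / y_sim, np.nan)
    n_undef = int(np.isnan(pct).sum())
    binned = counts = None
    if bins is not None:
        if idv is None:
            raise ValueError("idv values required for binned known bias")
        assign = bins.assign(idv)
        binned = _bin_means(pct, assign, bins.n_bins)
        counts = np.bincount(assign, minlength=bins.n_bins)
    return KnownBiasResult(
        percent=pct, n_undefined=n_undef, binned_percent=binned, bin_counts=counts
    )
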