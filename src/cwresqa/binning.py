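"""IDV binning: density (quantile) bins and the randomized-binning study.

Bins partition the observed range of an independent variable (time or a DV's
population prediction) with half-open intervals [min, X_1), [X_1, X_2), ...,
[X_{N-1}, max]; the right-closed last bin keeps boundary observations.
Density bins place the N-1 cutoffs at empirical quantiles snapped to
midpoints between adjacent distinct observed values.  The randomized scheme
redraws uniform cutoffs until every bin holds at least M observations and
repeats the whole bias fit many times, tracing out an envelope of bin-mean
estimates akin to a confidence band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .biasmodel import BiasFit, CWRESGrouped

__all__ = [
    "BinSpec",
    "default_n_bins",
    "density_bins",
    "random_bins",
    "random_binning_study",
    "RandomBinReplicate",
    "RandomBinningStudy",
]

#: default bin count when time is the IDV
DEFAULT_N_TIME = 10
#: default bin count when a population prediction is the IDV
DEFAULT_N_PRED = 5
#: default minimum observations per bin
DEFAULT_MIN_PER_BIN = 25

REDRAW_CAP = 10_000


def default_n_bins(idv_name: str) -> int:
    """N = 10 for time, N = 5 for PRED-type IDVs."""
    return DEFAULT_N_TIME if idv_name.lower().startswith("time") else DEFAULT_N_PRED


@dataclass(frozen=True)
class BinSpec:
    """Ordered cutoffs defining N half-open IDV bins."""

    idv_name: str
    boundaries: np.ndarray
    n_bins: int
    min_per_bin: int
    idv_range: tuple[float, float] | None = None

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        if b.size != self.n_bins - 1:
            raise ValueError("need n_bins - 1 boundaries")
        if b.size > 1 and np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.idv_range is not None and b.size:
            lo, hi = self.idv_range
            if b[0] <= lo or b[-1] >= hi:
                raise ValueError("boundaries must lie strictly inside the IDV range")

    def assign(self, values) -> np.ndarray:
        """Bin index per value; values beyond the range go to the edge bins."""
        return np.searchsorted(self.boundaries, np.asarray(values, float), side="right")

    def counts(self, values) -> np.ndarray:
        return np.bincount(self.assign(values), minlength=self.n_bins)

    def edges(self) -> np.ndarray:
        """Full bin edges including the observed range endpoints (if known)."""
        lo, hi = self.idv_range if self.idv_range is not None else (-np.inf, np.inf)
        return np.concatenate([[lo], self.boundaries, [hi]])

    def to_dict(self) -> dict:
        return {
            "idv_name": self.idv_name,
            "boundaries": self.boundaries.tolist(),
            "n_bins": self.n_bins,
            "min_per_bin": self.min_per_bin,
            "idv_range": list(self.idv_range) if self.idv_range else None,
        }


def density_bins(
    idv_values,
    n_bins: int | None = None,
    min_per_bin: int = DEFAULT_MIN_PER_BIN,
    idv_name: str = "idv",
) -> BinSpec:
    """Equal-count quantile bins snapped to midpoints between distinct values."""
    x = np.asarray(idv_values, dtype=float)
    if n_bins is None:
        n_bins = default_n_bins(idv_name)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    distinct = np.unique(x)
    if distinct.size < n_bins:
        raise ValueError(
            f"only {distinct.size} distinct IDV values for {n_bins} bins; reduce N"
        )
    bounds = []
    for k in range(1, n_bins):
        q = np.quantile(x, k / n_bins)
        j = np.searchsorted(distinct, q, side="right")
        j = min(max(j, 1), distinct.size - 1)
        bounds.append(0.5 * (distinct[j - 1] + distinct[j]))
    bounds = np.asarray(bounds)
    if bounds.size > 1 and np.any(np.diff(bounds) <= 0):
        raise ValueError(
            f"ties in the IDV prevent {n_bins} distinct quantile bins; reduce N"
        )
    spec = BinSpec(
        idv_name=idv_name,
        boundaries=bounds,
        n_bins=n_bins,
        min_per_bin=min_per_bin,
        idv_range=(float(distinct[0]), float(distinct[-1])),
    )
    counts = spec.counts(x)
    if counts.min() < min_per_bin:
        raise ValueError(
            f"density bins infeasible: smallest bin holds {counts.min()} < "
            f"{min_per_bin} observations; reduce N"
        )
    return spec


def random_bins(
    idv_values,
    n_bins: int | None = None,
    min_per_bin: int = DEFAULT_MIN_PER_BIN,
    rng: np.random.Generator | int | None = None,
    idv_name: str = "idv",
) -> BinSpec:
    """Uniform random cutoffs over the observed IDV range, redrawn until every
    bin holds at least ``min_per_bin`` observations (cap 10,000 draws)."""
    x = np.asarray(idv_values, dtype=float)
    if n_bins is None:
        n_bins = default_n_bins(idv_name)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lo, hi = float(x.min()), float(x.max())
    for _ in range(REDRAW_CAP):
        bounds = np.sort(rng.uniform(lo, hi, size=n_bins - 1))
        if bounds.size > 1 and np.any(np.diff(bounds) <= 0):
            continue
        spec = BinSpec(
            idv_name=idv_name,
            boundaries=bounds,
            n_bins=n_bins,
            min_per_bin=min_per_bin,
            idv_range=(lo, hi),
        )
        if spec.counts(x).min() >= min_per_bin:
            return spec
    raise ValueError(
        f"no feasible random binning in {REDRAW_CAP} draws "
        f"(N={n_bins}, M={min_per_bin}); reduce N or M"
    )


@dataclass(frozen=True)
class RandomBinReplicate:
    bins: BinSpec
    b: np.ndarray
    ofv: float
    binned_delta: np.ndarray | None = None
    binned_pct_delta: np.ndarray | None = None


@dataclass(frozen=True)
class RandomBinningStudy:
    replicates: tuple
    n_failures: int

    @property
    def pooled_b(self) -> np.ndarray:
        return np.concatenate([r.b for r in self.replicates])


def random_binning_study(
    grouped: "CWRESGrouped",
    n_bins: int | None = None,
    min_per_bin: int = DEFAULT_MIN_PER_BIN,
    reps: int = 500,
    seed: int | np.random.Generator | None = None,
    conds: dict | None = None,
) -> RandomBinningStudy:
    """Repeat (draw random bins -> fit extended model -> b -> delta) ``reps`` times.

    When per-subject conditional moments ``conds`` are supplied, each
    replicate also back-transforms b into binned prediction-bias summaries.
    Individual replicate failures are skipped; more than 10% failures raise.
    """
    from .biasmodel import fit_extended
    from .correction import correct_predictions, expand_bias

    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idv = grouped.all_idv
    out = []
    failures = 0
    for _ in range(reps):
        try:
            bins = random_bins(
                idv, n_bins, min_per_bin, rng=rng, idv_name=grouped.idv_name
            )
            fit = fit_extended(grouped, bins)
            if conds is not None:
                expanded = expand_bias(fit.means, bins, idv)
                corr = correct_predictions(grouped, conds, expanded, bins)
                out.append(
                    RandomBinReplicate(
                        bins=bins,
                        b=fit.means,
                        ofv=fit.ofv,
                        binned_delta=corr.binned_delta,
                        binned_pct_delta=corr.binned_pct_delta,
                    )
                )
            else:
                out.append(RandomBinReplicate(bins=bins, b=fit.means, ofv=fit.ofv))
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures += 1
            warnings.warn(f"random-binning replicate failed: {exc}")
    if failures > 0.1 * reps:
        raise RuntimeError(
            f"{failures}/{reps} random-binning replicates failed; study aborted"
        )
    return RandomBinningStudy(replicates=tuple(out), n_failures=failures)
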