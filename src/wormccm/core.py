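"""Time-delay embedding and simplex-projection cross mapping.

This module holds the basic data containers (:class:`TimeSeries`,
:class:`EigenmodeRecord`) and the convergent cross mapping (CCM) engine
that every interaction profile is built from.

CCM logic: if a variable X drives a variable Y, then the attractor
reconstructed from lags of Y (the "shadow manifold") contains information
about X, and nearest-neighbor forecasting on that manifold can recover
contemporaneous or past values of X.  The cross-map skill is the Pearson
correlation between observed and simplex-predicted values of the putative
cause, averaged over resampled libraries of embedded points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeries",
    "EigenmodeRecord",
    "DelayEmbedding",
    "CrossMapConfig",
    "InsufficientDataError",
    "delay_embed",
    "simplex_neighbors",
    "cross_map",
]


class InsufficientDataError(ValueError):
    """Raised when a series has too few valid points for the requested analysis."""


@dataclass(frozen=True)
class TimeSeries:
    """One channel of evenly sampled values; NaN marks missing samples.

    Parameters
    ----------
    values : array-like of float
        The samples, one per frame.  NaN encodes a missing observation.
    rate_hz : float
        Sampling rate in Hz.  For map-time simulations (one step per
        sample) use ``rate_hz=1.0``.
    """

    values: np.ndarray
    rate_hz: float = 1.0

    def __post_init__(self) -> None:
        vals = np.array(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if np.isinf(vals).any():
            raise ValueError("non-missing values must be finite (inf found)")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask aligned with :attr:`values`; True where missing."""
        return np.isnan(self.values)

    @property
    def na_fraction(self) -> float:
        return float(self.missing.mean()) if len(self) else 0.0

    @classmethod
    def from_masked(cls, values: Iterable[float], missing: Iterable[bool],
                    rate_hz: float = 1.0) -> "TimeSeries":
        vals = np.array(list(values), dtype=float)
        mask = np.asarray(list(missing), dtype=bool)
        if vals.shape != mask.shape:
            raise ValueError("values and missing mask must have equal length")
        vals[mask] = np.nan
        return cls(vals, rate_hz)


@dataclass
class EigenmodeRecord:
    """An individual's aligned eigenmode channels plus metadata.

    ``modes`` maps channel names (``"a1"`` .. ``"a4"`` for the leading
    eigenworm amplitudes) to :class:`TimeSeries` of equal length and rate.
    ``truth`` optionally records a ground-truth coupling graph for
    synthetic records (used by parameter-recovery tests).
    """

    id: str
    modes: Mapping[str, TimeSeries]
    strain: str | None = None
    behavior: str | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("record needs at least one mode")
        lengths = {len(ts) for ts in self.modes.values()}
        rates = {ts.rate_hz for ts in self.modes.values()}
        if len(lengths) != 1:
            raise ValueError(f"record {self.id!r}: modes have unequal lengths {lengths}")
        if len(rates) != 1:
            raise ValueError(f"record {self.id!r}: modes have unequal rates {rates}")

    @property
    def mode_names(self) -> list[str]:
        return list(self.modes.keys())

    @property
    def length(self) -> int:
        return len(next(iter(self.modes.values())))

    @property
    def rate_hz(self) -> float:
        return next(iter(self.modes.values())).rate_hz

    @property
    def na_fraction(self) -> float:
        masks = np.concatenate([ts.missing for ts in self.modes.values()])
        return float(masks.mean())

    def window(self, start: int, stop: int, suffix: str | None = None) -> "EigenmodeRecord":
        """Return the sub-record covering sample indices [start, stop)."""
        if not (0 <= start < stop <= self.length):
            raise ValueError(f"window [{start}, {stop}) outside record of length {self.length}")
        modes = {
            name: TimeSeries(ts.values[start:stop], ts.rate_hz)
            for name, ts in self.modes.items()
        }
        new_id = self.id if suffix is None else f"{self.id}{suffix}"
        return EigenmodeRecord(new_id, modes, strain=self.strain,
                               behavior=self.behavior, truth=self.truth)


@dataclass(frozen=True)
class DelayEmbedding:
    """Shadow-manifold points [x_t, x_{t-1}, ..., x_{t-(E-1)}] with lag step 1.

    ``times`` holds the indices t at which all E lagged samples are
    non-missing; ``points[i]`` is the embedding vector at ``times[i]``.
    """

    E: int
    times: np.ndarray
    points: np.ndarray
    tau: int = 1

    def __post_init__(self) -> None:
        if self.E < 2:
            raise ValueError("embedding dimension E must be >= 2")
        if self.points.shape != (self.times.size, self.E):
            raise ValueError("points shape inconsistent with times and E")

    def point_at(self, t: int) -> np.ndarray:
        idx = np.searchsorted(self.times, t)
        if idx >= self.times.size or self.times[idx] != t:
            raise KeyError(f"no embedded point at t={t}")
        return self.points[idx]


def delay_embed(series: TimeSeries, E: int) -> DelayEmbedding:
    """Embed a series in E dimensions with unit lag.

    A point exists at index t (for t in [E-1, len-1]) only when all E
    source samples x_t .. x_{t-(E-1)} are non-missing; coordinate k of the
    point at t equals x_{t-k}.
    """
    if E < 2:
        raise ValueError("embedding dimension E must be >= 2")
    vals = series.values
    n = vals.size
    if n < E:
        raise InsufficientDataError(f"series of length {n} is shorter than E={E}")
    idx = np.arange(E - 1, n)
    points = np.column_stack([vals[idx - k] for k in range(E)])
    ok = np.isfinite(points).all(axis=1)
    return DelayEmbedding(E=E, times=idx[ok], points=points[ok])


@dataclass(frozen=True)
class CrossMapConfig:
    """Parameters of one cross-map evaluation.

    ``tp`` is the target time offset in samples (<= 0): the embedding at
    time t predicts the effect series at time t + tp, i.e. the effect's
    past.  ``library_size`` is the number of embedded indices resampled
    per repeat (or ``"all"`` to use every valid point once, as done for
    short recordings).  ``exclusion_radius`` is a Theiler window: neighbors
    closer than this many samples in time to the prediction point are
    ignored, which suppresses trivial serial-correlation matches.
    """

    E: int = 10
    tp: int = 0
    library_size: int | str = 200
    n_repeats: int = 250
    exclusion_radius: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.E < 2:
            raise ValueError("E must be >= 2")
        if self.tp > 0:
            raise ValueError(f"tp must be <= 0 (predicting the effect's past), got {self.tp}")
        if self.library_size != "all":
            if not isinstance(self.library_size, (int, np.integer)):
                raise ValueError("library_size must be an integer or 'all'")
            if self.library_size < self.E + 2:
                raise ValueError(
                    f"library_size={self.library_size} too small for E={self.E} "
                    f"(need at least E + 2 = {self.E + 2})")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")


def simplex_neighbors(points: np.ndarray, times: np.ndarray, k: int,
                      exclusion_radius: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """k nearest neighbors of every point among all points, with exclusions.

    Distances are Euclidean.  A candidate j is ineligible as a neighbor of
    i when j == i or |times[i] - times[j]| < exclusion_radius.  Ties in
    distance are broken toward the smaller row index (stable sort), which
    makes the result reproducible and directly comparable with a
    brute-force search.

    Returns
    -------
    nbr_idx : (n, k) int array of neighbor row indices, nearest first.
    nbr_dist : (n, k) float array of the matching distances.
    """
    n = len(times)
    d = cdist(points, points)
    sep = np.abs(times[:, None] - times[None, :])
    banned = sep < exclusion_radius
    np.fill_diagonal(banned, True)
    d[banned] = np.inf
    eligible = n - banned.sum(axis=1)
    short = int(eligible.min())
    if short < k:
        raise InsufficientDataError(
            f"a prediction point has only {short} eligible neighbors "
            f"(need {k}); library too small or exclusion radius too wide")
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    nd = np.take_along_axis(d, order, axis=1)
    return order, nd


def _simplex_weights(nbr_dist: np.ndarray) -> np.ndarray:
    """Exponential distance weights w_i = exp(-d_i / d_1), normalized.

    When the nearest distance is zero, zero-distance neighbors share the
    weight equally and the rest get zero.
    """
    d1 = nbr_dist[:, :1]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(d1 > 0.0,
                     np.exp(-nbr_dist / np.where(d1 > 0.0, d1, 1.0)),
                     (nbr_dist == 0.0).astype(float))
    return w / w.sum(axis=1, keepdims=True)


def _simplex_skill(points: np.ndarray, times: np.ndarray, targets: np.ndarray,
                   k: int, exclusion_radius: int) -> float:
    """Leave-one-out simplex forecast skill over one library sample."""
    nbr_idx, nbr_dist = simplex_neighbors(points, times, k, exclusion_radius)
    w = _simplex_weights(nbr_dist)
    predicted = (w * targets[nbr_idx]).sum(axis=1)
    observed = targets
    if np.std(observed) == 0.0 or np.std(predicted) == 0.0:
        warnings.warn("zero-variance observed or predicted segment; skill undefined",
                      RuntimeWarning, stacklevel=2)
        return np.nan
    return float(np.corrcoef(observed, predicted)[0, 1])


def cross_map(effect: TimeSeries, predictor: TimeSeries,
              cfg: CrossMapConfig) -> float:
    """Cross-map skill for the influence of ``effect`` on ``predictor``.

    The predictor series (the putatively driven variable) is embedded in
    ``cfg.E`` dimensions; its shadow manifold is used to forecast the
    effect series (the putative cause) at offset ``cfg.tp``.  Per repeat,
    ``cfg.library_size`` valid embedded indices are sampled without
    replacement; each sampled point is predicted from its E+1 nearest
    library neighbors (itself excluded, plus any point within
    ``cfg.exclusion_radius`` samples).  Skill is the Pearson correlation
    between observed and predicted effect values, averaged over repeats.

    Returns NaN (with a warning) when every repeat is undefined, e.g. for
    a zero-variance segment.
    """
    if len(effect) != len(predictor):
        raise ValueError(
            f"series must be aligned and equal length ({len(effect)} vs {len(predictor)})")
    emb = delay_embed(predictor, cfg.E)
    tp = cfg.tp
    reachable = emb.times + tp >= 0
    times = emb.times[reachable]
    points = emb.points[reachable]
    targets = effect.values[times + tp]
    ok = np.isfinite(targets)
    times, points, targets = times[ok], points[ok], targets[ok]
    n_valid = times.size

    k = cfg.E + 1
    if cfg.library_size == "all":
        lib_n, n_rep = n_valid, 1
    else:
        lib_n, n_rep = int(cfg.library_size), cfg.n_repeats
    needed = max(lib_n, k + 1)
    if n_valid < needed:
        raise InsufficientDataError(
            f"cross map at tp={tp} needs {needed} valid embedded points "
            f"but only {n_valid} are available")
    if np.all(points == points[0]):
        warnings.warn("degenerate embedding: predictor has zero variance; "
                      "skill undefined", RuntimeWarning, stacklevel=2)
        return float("nan")

    rng = np.random.default_rng(cfg.rng_seed)
    skills = np.empty(n_rep)
    with warnings.catch_warnings():
        warnings.simplefilter("once", RuntimeWarning)
        for r in range(n_rep):
            if cfg.library_size == "all":
                sel = np.arange(n_valid)
            else:
                sel = rng.choice(n_valid, size=lib_n, replace=False)
            skills[r] = _simplex_skill(points[sel], times[sel], targets[sel],
                                       k, cfg.exclusion_radius)
    if np.isnan(skills).all():
        warnings.warn(f"cross map at tp={tp}: skill undefined in every repeat",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.nanmean(skills))
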