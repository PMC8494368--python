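"""Surrogate nulls, profile similarity, windowing, and group distinctness.

Profile similarity between two individuals is the mean Spearman rank
correlation across the 12 corresponding pair profiles; being rank based it
is identical on raw and min-max normalized skills.  Significance of a
profile is judged against phase-randomized surrogates, which keep each
channel's power spectrum (hence its autocorrelation) while destroying any
nonlinear cross-dependence.  Group structure in a similarity matrix is
tested with a directional nearest-profile permutation test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core import CrossMapConfig, EigenmodeRecord, TimeSeries
from .profiles import ProfileSet, _child_seed, lag_profile, profile_set

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "DistinctnessResult",
    "profile_similarity",
    "similarity_matrix",
    "phase_surrogate",
    "surrogate_profiles",
    "windowed_profiles",
    "distinctness_test",
]


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of mean-Spearman profile correlations between units."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape must match the id list")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")
        if len(set(self.ids)) != n:
            raise ValueError("unit ids must be unique")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(dtype=float))


def _pair_spearman(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return float("nan")
    return float(spearmanr(a[ok], b[ok]).statistic)


def profile_similarity(a: ProfileSet, b: ProfileSet) -> float:
    """Mean Spearman correlation over corresponding pair profiles.

    Raw skills are used for the computation; by rank invariance the result
    is identical on normalized skills.
    """
    if set(a.pairs) != set(b.pairs):
        raise ValueError("profile sets cover different channel pairs")
    if not np.array_equal(a.tp, b.tp) or a.rate_hz != b.rate_hz:
        raise ValueError(
            "delay grids differ; resample both profiles onto a common grid "
            "(see wormccm.io.resample_profile) before comparing")
    vals = [_pair_spearman(a.profiles[p].skill_raw, b.profiles[p].skill_raw)
            for p in a.pairs]
    return float(np.mean(vals))


def similarity_matrix(sets: Sequence[ProfileSet]) -> SimilarityMatrix:
    """All-pairs profile similarity; diagonal is 1 by convention."""
    n = len(sets)
    ids = [s.owner for s in sets]
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = profile_similarity(sets[i], sets[j])
    return SimilarityMatrix(ids=ids, values=vals)


def phase_surrogate(series: TimeSeries, seed: int = 0) -> TimeSeries:
    """Fourier phase-randomized surrogate with the original power spectrum.

    Phases of the positive-frequency bins are drawn uniformly (DC and the
    Nyquist bin are kept, so the output is real and the mean and spectrum
    are preserved exactly up to floating point).  The input must be
    gap-free; mask or segment the series first.
    """
    if series.missing.any():
        raise ValueError("series has missing values; surrogate needs a gap-free segment")
    x = series.values
    n = x.size
    spec = np.fft.rfft(x)
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.size)
    out_spec = np.abs(spec) * np.exp(1j * phases)
    out_spec[0] = spec[0]
    if n % 2 == 0:
        out_spec[-1] = spec[-1]
    return TimeSeries(np.fft.irfft(out_spec, n), rate_hz=series.rate_hz)


def _longest_joint_segment(a: TimeSeries, b: TimeSeries) -> tuple[TimeSeries, TimeSeries]:
    """Longest stretch where both series are non-missing (for surrogates)."""
    ok = ~(a.missing | b.missing)
    if ok.all():
        return a, b
    edges = np.diff(np.r_[False, ok, False].astype(int))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    if starts.size == 0:
        raise ValueError("no jointly non-missing segment")
    i = int(np.argmax(ends - starts))
    sl = slice(int(starts[i]), int(ends[i]))
    logger.info("surrogates built from the longest gap-free segment "
                "(%d of %d samples)", ends[i] - starts[i], len(a))
    return (TimeSeries(a.values[sl], a.rate_hz),
            TimeSeries(b.values[sl], b.rate_hz))


def surrogate_profiles(effect: TimeSeries, predictor: TimeSeries,
                       delays: Sequence[int], cfg: CrossMapConfig,
                       n_surrogates: int = 50, seed: int = 0) -> np.ndarray:
    """Raw-skill profiles between independent surrogates of the two series.

    Returns an (n_surrogates, n_delays) array forming the null band
    against which a real profile's skill is judged.  Series with missing
    values are first restricted to their longest jointly gap-free stretch
    (phase randomization needs contiguous data).
    """
    effect, predictor = _longest_joint_segment(effect, predictor)
    rows = np.empty((n_surrogates, len(delays)))
    for s in range(n_surrogates):
        se = phase_surrogate(effect, seed=_child_seed(seed, 2 * s))
        sp = phase_surrogate(predictor, seed=_child_seed(seed, 2 * s + 1))
        c = replace(cfg, rng_seed=_child_seed(seed, 10_000 + s))
        rows[s] = lag_profile(se, sp, delays, c).skill_raw
    return rows


def windowed_profiles(record: EigenmodeRecord, window_s: float, n_windows: int,
                      delays: Sequence[int], cfg: CrossMapConfig) -> list[ProfileSet]:
    """Profile sets from non-overlapping windows tiled from the start.

    Windows containing only missing data are skipped with a warning; a
    record too short for the requested tiling is an error reporting the
    maximum feasible window count.
    """
    win = int(round(window_s * record.rate_hz))
    if win < 2:
        raise ValueError("window too short at this sampling rate")
    needed = win * n_windows
    if record.length < needed:
        raise ValueError(
            f"record of {record.length} samples supports at most "
            f"{record.length // win} non-overlapping {window_s:g}-s windows, "
            f"not {n_windows}")
    sets: list[ProfileSet] = []
    for w in range(n_windows):
        sub = record.window(w * win, (w + 1) * win, suffix=f"[w{w}]")
        if all(ts.missing.all() for ts in sub.modes.values()):
            logger.warning("window %d of %s contains only missing data; skipped",
                           w, record.id)
            continue
        c = replace(cfg, rng_seed=_child_seed(cfg.rng_seed, 3000 + w))
        sets.append(profile_set(sub, delays, c))
    return sets


@dataclass
class DistinctnessResult:
    """Directional nearest-profile distinctness of group A against group B."""

    group_a: list[str]
    group_b: list[str]
    observed_pct: float
    null_pcts: np.ndarray
    attained: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "group_a": list(self.group_a),
            "group_b": list(self.group_b),
            "observed_pct": self.observed_pct,
            "attained": self.attained,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def distinctness_test(sim: SimilarityMatrix, group_a: Sequence[str],
                      group_b: Sequence[str], n_perm: int = 1000,
                      seed: int = 0) -> DistinctnessResult:
    """Directional permutation test of group separation in a similarity matrix.

    For every unit in group A the most similar other unit within A union B
    is found (self excluded); the observed statistic is the percentage of
    A whose nearest profile is also in A.  Group labels are then permuted
    ``n_perm`` times (group sizes preserved) and the attained fraction is
    the share of permuted percentages strictly below the observed one.
    The test is directional: swapping A and B asks a different question.

    Nearest-neighbor ties are broken by a seeded shuffle of candidate
    order (then first maximum), and logged only implicitly through the
    seed recorded in the result.
    """
    ga, gb = [str(g) for g in group_a], [str(g) for g in group_b]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("both groups need at least 2 members")
    if set(ga) & set(gb):
        raise ValueError(f"groups overlap: {sorted(set(ga) & set(gb))}")
    pos = {u: i for i, u in enumerate(sim.ids)}
    absent = [u for u in ga + gb if u not in pos]
    if absent:
        raise ValueError(f"units not in the similarity matrix: {absent}")

    members = ga + gb
    idx = np.array([pos[u] for u in members])
    S = sim.values[np.ix_(idx, idx)].astype(float)
    n, n_a = len(members), len(ga)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)          # tie-break: seeded candidate order
    S_sh = S[:, order]
    col_of = np.empty(n, dtype=int)
    col_of[order] = np.arange(n)
    S_sh[np.arange(n), col_of] = -np.inf    # never match self
    nn = order[np.argmax(S_sh, axis=1)]

    in_a = np.zeros(n, dtype=bool)
    in_a[:n_a] = True
    observed = 100.0 * float(in_a[nn[:n_a]].mean())

    null = np.empty(n_perm)
    for p in range(n_perm):
        lab = np.zeros(n, dtype=bool)
        lab[rng.choice(n, size=n_a, replace=False)] = True
        null[p] = 100.0 * lab[nn[lab]].mean()
    attained = float((null < observed).mean())
    return DistinctnessResult(group_a=ga, group_b=gb, observed_pct=observed,
                              null_pcts=null, attained=attained,
                              n_perm=n_perm, seed=seed)
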