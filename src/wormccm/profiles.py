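"""Delay-scanned interaction profiles and the optimal-embedding scan.

An interaction profile is the curve of cross-map skill versus target
delay for one ordered channel pair; the set of all 12 ordered pairs among
four channels fingerprints an individual's dynamics.

Delay conventions
-----------------
Internally a profile is indexed by the target offset ``tp`` (samples,
<= 0): the shadow manifold of the predictor at time t forecasts the
effect series at time t + tp.  For generative benchmarks it is more
natural to speak of the *displayed delay* d of a coupling
"x_{t-d} enters y_{t+1}": because the newest coordinate of the embedding
at time t is y_t (one step after the y_{t+1} that x_{t-d} shaped), the
coupling surfaces at tp = -(d + 1), i.e. displayed delay d = -tp - 1.
:func:`displayed_delay_grid` builds tp grids from displayed delays and
:class:`InteractionProfile` exposes both axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .core import (
    CrossMapConfig,
    EigenmodeRecord,
    InsufficientDataError,
    TimeSeries,
    cross_map,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionProfile",
    "ProfileSet",
    "EmbeddingScan",
    "displayed_delay_grid",
    "lag_profile",
    "profile_set",
    "average_profiles",
    "optimal_embedding_scan",
]


def _child_seed(seed: int, index: int) -> int:
    """Deterministic per-task seed derived from a base seed."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0])


def _minmax(skill: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant (or all-NaN) profile maps to zeros."""
    out = np.full_like(skill, np.nan, dtype=float)
    ok = np.isfinite(skill)
    if not ok.any():
        return out
    lo, hi = skill[ok].min(), skill[ok].max()
    if hi - lo == 0.0:
        logger.warning("constant profile: normalized values set to 0 by convention")
        out[ok] = 0.0
    else:
        out[ok] = (skill[ok] - lo) / (hi - lo)
    return out


def displayed_delay_grid(d_min: int, d_max: int) -> np.ndarray:
    """tp grid (strictly increasing) covering displayed delays d_min..d_max."""
    if d_min > d_max or d_min < 0:
        raise ValueError("need 0 <= d_min <= d_max")
    return -(np.arange(d_min, d_max + 1)[::-1] + 1)


@dataclass
class InteractionProfile:
    """CCM skill per target delay for one ordered (effect, predictor) pair.

    ``tp`` holds the strictly increasing grid of target offsets in samples
    (all <= 0); ``skill_raw`` the resolved cross-map skill per offset (NaN
    where unresolved) and ``skill_norm`` its min-max normalization.
    """

    effect: str
    predictor: str
    tp: np.ndarray
    rate_hz: float
    skill_raw: np.ndarray

    def __post_init__(self) -> None:
        self.tp = np.asarray(self.tp)
        self.skill_raw = np.asarray(self.skill_raw, dtype=float)
        if self.tp.ndim != 1 or self.tp.shape != self.skill_raw.shape:
            raise ValueError("tp and skill_raw must be equal-length 1-D arrays")
        if np.any(np.diff(self.tp) <= 0):
            raise ValueError("delays must be strictly increasing")
        if np.any(self.tp > 0):
            raise ValueError("all tp values must be <= 0")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        self.skill_norm = _minmax(self.skill_raw)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.effect, self.predictor)

    @property
    def tp_seconds(self) -> np.ndarray:
        return self.tp / self.rate_hz

    @property
    def displayed_delays(self) -> np.ndarray:
        return -self.tp - 1

    def argmax_displayed_delay(self) -> int:
        """Displayed delay at which the raw skill peaks."""
        return int(self.displayed_delays[np.nanargmax(self.skill_raw)])

    def peaks(self, prominence: float = 0.05) -> np.ndarray:
        """Displayed delays of local maxima of the normalized profile.

        Peaks are found on the normalized skill ordered by increasing
        displayed delay; ``prominence`` (on the [0, 1] normalized scale)
        suppresses noise-level wiggles.  Endpoints are never peaks.
        """
        d = self.displayed_delays[::-1]
        y = self.skill_norm[::-1]
        if np.isnan(y).any():
            raise ValueError("peaks undefined on a profile with unresolved delays")
        idx, _props = find_peaks(y, prominence=prominence)
        return np.sort(d[idx])


@dataclass
class ProfileSet:
    """The ordered-pair profiles of one individual (or one group average)."""

    owner: str
    profiles: Mapping[tuple[str, str], InteractionProfile]
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("empty profile set")
        grids = {(tuple(p.tp), p.rate_hz) for p in self.profiles.values()}
        if len(grids) != 1:
            raise ValueError("all profiles in a set must share one delay grid")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.profiles.keys())

    @property
    def tp(self) -> np.ndarray:
        return next(iter(self.profiles.values())).tp

    @property
    def rate_hz(self) -> float:
        return next(iter(self.profiles.values())).rate_hz


def lag_profile(effect: TimeSeries, predictor: TimeSeries,
                delays: Sequence[int], cfg: CrossMapConfig) -> InteractionProfile:
    """Scan cross-map skill over a grid of target offsets.

    Each delay uses an independent deterministic substream of
    ``cfg.rng_seed``.  Delays with too few valid points are left NaN with
    a logged warning; if no delay resolves the profile is an error.
    """
    tp_grid = np.asarray(delays, dtype=int)
    skills = np.full(tp_grid.size, np.nan)
    for i, tp in enumerate(tp_grid):
        c = replace(cfg, tp=int(tp), rng_seed=_child_seed(cfg.rng_seed, i))
        try:
            skills[i] = cross_map(effect, predictor, c)
        except InsufficientDataError as err:
            logger.warning("tp=%d unresolved: %s", tp, err)
    if np.isnan(skills).all():
        raise InsufficientDataError("no delay in the grid produced a resolved skill")
    return InteractionProfile(effect="effect", predictor="predictor",
                              tp=tp_grid, rate_hz=effect.rate_hz, skill_raw=skills)


def profile_set(record: EigenmodeRecord, delays: Sequence[int],
                cfg: CrossMapConfig, modes: Sequence[str] | None = None) -> ProfileSet:
    """All ordered-pair profiles among the record's (first four) modes.

    With four modes this yields the 4 x 3 = 12 ordered pairs; the pair
    (effect, predictor) quantifies the influence of ``effect`` on
    ``predictor`` (the predictor's shadow manifold forecasts the effect).
    """
    names = list(modes) if modes is not None else record.mode_names[:4]
    if len(names) < 4:
        raise ValueError(f"record {record.id!r} has {len(names)} modes; need >= 4")
    missing = [m for m in names if m not in record.modes]
    if missing:
        raise ValueError(f"record {record.id!r} lacks mode(s) {missing}")
    profiles: dict[tuple[str, str], InteractionProfile] = {}
    ordered = [(e, p) for e in names for p in names if e != p]
    for j, (e, p) in enumerate(ordered):
        c = replace(cfg, rng_seed=_child_seed(cfg.rng_seed, 1000 + j))
        try:
            prof = lag_profile(record.modes[e], record.modes[p], delays, c)
        except InsufficientDataError as err:
            raise InsufficientDataError(f"pair ({e} -> {p}): {err}") from err
        prof.effect, prof.predictor = e, p
        profiles[(e, p)] = prof
    prov = {"cfg": cfg.__dict__ | {}, "delays": [int(t) for t in delays],
            "record": record.id}
    return ProfileSet(owner=record.id, profiles=profiles, provenance=prov)


def average_profiles(sets: Sequence[ProfileSet], owner: str = "average") -> ProfileSet:
    """Normalized average of several profile sets, re-normalized to [0, 1].

    Per pair and per delay the individuals' *normalized* skills are
    averaged (NaN-aware); the averaged curve is then min-max normalized
    again so each pair's panel spans [0, 1].
    """
    if not sets:
        raise ValueError("need at least one profile set")
    ref = sets[0]
    for s in sets[1:]:
        if set(s.pairs) != set(ref.pairs):
            raise ValueError("profile sets cover different pairs")
        if not np.array_equal(s.tp, ref.tp) or s.rate_hz != ref.rate_hz:
            raise ValueError("profile sets must share one delay grid; resample first")
    profiles = {}
    for pair in ref.pairs:
        stacked = np.vstack([s.profiles[pair].skill_norm for s in sets])
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stacked, axis=0)
        profiles[pair] = InteractionProfile(
            effect=pair[0], predictor=pair[1], tp=ref.tp.copy(),
            rate_hz=ref.rate_hz, skill_raw=mean)
    prov = {"averaged_from": [s.owner for s in sets]}
    return ProfileSet(owner=owner, profiles=profiles, provenance=prov)


@dataclass(frozen=True)
class EmbeddingScan:
    """Result of scanning embedding dimension at a fixed best delay."""

    E_values: np.ndarray
    skill: np.ndarray
    best_E: int


def optimal_embedding_scan(effect: TimeSeries, predictor: TimeSeries,
                           tp_star: int, cfg: CrossMapConfig,
                           E_values: Iterable[int] = range(2, 41)) -> EmbeddingScan:
    """Cross-map skill as a function of embedding dimension at one delay.

    ``tp_star`` is typically the delay of the peak of the (average)
    interaction profile.  The optimum is the E with the highest skill,
    ties broken toward smaller E; the scan truncates with a warning when
    the series becomes too short for larger E.
    """
    Es: list[int] = []
    skills: list[float] = []
    for j, E in enumerate(E_values):
        lib = cfg.library_size
        if lib != "all" and lib < E + 2:
            lib = E + 2
        c = replace(cfg, E=int(E), tp=int(tp_star), library_size=lib,
                    rng_seed=_child_seed(cfg.rng_seed, 2000 + j))
        try:
            skills.append(cross_map(effect, predictor, c))
        except InsufficientDataError as err:
            logger.warning("optimal-E scan truncated at E=%d: %s", E, err)
            break
        Es.append(int(E))
    if not Es:
        raise InsufficientDataError("series too short for any embedding in the scan")
    skill = np.asarray(skills)
    best = Es[int(np.nanargmax(skill))]
    return EmbeddingScan(E_values=np.asarray(Es), skill=skill, best_E=best)
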