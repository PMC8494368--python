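"""Generators for benchmark and worm-like synthetic timeseries.

Two families:

* :func:`coupled_logistic` — the classic two-variable benchmark in which a
  chaotic logistic map x drives a second logistic map y through one or
  more lagged coupling terms.  The generative lags are known exactly, so
  the pair is the canonical test bed for lag-scanned cross mapping.
* :func:`synthetic_eigenmodes` — a four-channel stand-in for eigenworm
  amplitude recordings: heterogeneous chaotic logistic units with a
  user-specified directed lagged coupling graph, Gaussian observation
  noise, and NaN gaps, sampled at a nominal camera rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import EigenmodeRecord, TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticCouplingSpec",
    "SyntheticWormSpec",
    "coupled_logistic",
    "synthetic_eigenmodes",
    "box1_record",
]


@dataclass(frozen=True)
class LogisticCouplingSpec:
    """Coupled logistic pair: x_{t+1} = x_t (r_x - r_x x_t),
    y_{t+1} = y_t (r_y - r_y y_t + sum_k c_k x_{t - L_k}).

    ``couplings`` lists (delay L in steps, strength c) terms; an empty list
    gives two independent maps.  Initial conditions are drawn uniformly in
    (0.2, 0.8) from ``seed`` and ``burn_in`` samples are discarded so the
    trajectories settle onto the attractor.
    """

    r_x: float = 3.8
    r_y: float = 3.5
    couplings: tuple[tuple[int, float], ...] = ((4, 0.1),)
    n_steps: int = 2000
    burn_in: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "couplings",
                           tuple((int(L), float(c)) for L, c in self.couplings))
        for L, _c in self.couplings:
            if L < 1:
                raise ValueError(f"coupling delay must be >= 1 step, got {L}")
        if self.n_steps < 1 or self.burn_in < 0:
            raise ValueError("n_steps must be >= 1 and burn_in >= 0")


def coupled_logistic(spec: LogisticCouplingSpec) -> tuple[TimeSeries, TimeSeries]:
    """Simulate the coupled logistic pair; returns (x, y) after burn-in.

    Raises if the trajectory leaves (0, 1), which happens when a coupling
    strength is large enough to destabilize y; the error names the total
    coupling strength so the offending spec is easy to identify.
    """
    rng = np.random.default_rng(spec.seed)
    total = spec.burn_in + spec.n_steps
    x = np.empty(total)
    y = np.empty(total)
    x[0], y[0] = rng.uniform(0.2, 0.8, size=2)
    for t in range(total - 1):
        x[t + 1] = x[t] * (spec.r_x - spec.r_x * x[t])
        drive = 0.0
        for L, c in spec.couplings:
            drive += c * x[max(t - L, 0)]
        y[t + 1] = y[t] * (spec.r_y - spec.r_y * y[t] + drive)
        if not (0.0 < x[t + 1] < 1.0) or not (0.0 < y[t + 1] < 1.0):
            strengths = [c for _L, c in spec.couplings]
            raise ValueError(
                f"trajectory left (0, 1) at step {t + 1}; coupling strengths "
                f"{strengths} (total {sum(strengths):g}) too strong for r_y={spec.r_y}")
    return (TimeSeries(x[spec.burn_in:], rate_hz=1.0),
            TimeSeries(y[spec.burn_in:], rate_hz=1.0))


@dataclass(frozen=True)
class SyntheticWormSpec:
    """Worm-like 4-channel recording specification.

    Channels evolve as chaotic logistic units with distinct growth rates
    (kept away from the periodic windows of the logistic family), coupled
    through ``couplings`` = (source mode, target mode, delay in samples,
    strength) terms added inside the target's update, exactly as in the
    two-variable benchmark.  Boundedness requires headroom in the driven
    unit: strengths into mode j must total less than 2*sqrt(r_j) - r_j
    (about 0.15 for the default a2 rate of 3.7, which leaves the most
    coupling headroom of the four).  Growth rates sit above the
    band-merging point of the logistic family (~3.68): below it the
    attractor alternates between two bands every step, and two independent
    channels share that period-2 clock, which cross mapping picks up as a
    large spurious skill.  Observations are the unit states plus Gaussian
    noise, with NaN gaps injected to emulate tracking dropouts.

    Defaults emulate a foraging-style recording: 16 Hz, 120 s (1920
    samples, comfortably past the over-200-samples filter), observation
    noise of a few percent of the signal's standard deviation, and 5%
    missing data in multi-sample gaps.
    """

    n_modes: int = 4
    rate_hz: float = 16.0
    duration_s: float = 120.0
    couplings: tuple[tuple[str, str, int, float], ...] = ()
    growth_rates: tuple[float, ...] = (3.8, 3.7, 3.9, 3.75)
    noise_sd: float = 0.01
    nan_fraction: float = 0.05
    mean_gap_len: float = 8.0
    burn_in: int = 200

    def __post_init__(self) -> None:
        if self.n_modes < 4:
            raise ValueError("need at least 4 modes (a1..a4)")
        if len(self.growth_rates) < self.n_modes:
            raise ValueError("one growth rate per mode required")
        if not (0.0 <= self.nan_fraction < 0.25):
            raise ValueError(f"nan_fraction must lie in [0, 0.25), got {self.nan_fraction}")
        if not self.rate_hz > 0 or not self.duration_s > 0:
            raise ValueError("rate_hz and duration_s must be positive")
        n = int(round(self.rate_hz * self.duration_s))
        names = self.mode_names
        for src, dst, L, _c in self.couplings:
            if src not in names or dst not in names:
                raise ValueError(f"coupling {src}->{dst} references unknown mode")
            if src == dst:
                raise ValueError("self-couplings are not supported")
            if not (1 <= L < n):
                raise ValueError(f"coupling delay {L} outside (0, {n}) samples")

    @property
    def mode_names(self) -> tuple[str, ...]:
        return tuple(f"a{i + 1}" for i in range(self.n_modes))

    @property
    def n_samples(self) -> int:
        return int(round(self.rate_hz * self.duration_s))


def _inject_gaps(values: np.ndarray, nan_fraction: float, mean_gap_len: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Set NaN runs with geometric lengths until ~nan_fraction is missing."""
    n = values.size
    target = int(round(nan_fraction * n))
    out = values.copy()
    missing = 0
    guard = 0
    while missing < target and guard < 10 * n:
        guard += 1
        start = int(rng.integers(0, n))
        length = int(rng.geometric(1.0 / mean_gap_len))
        stop = min(start + max(length, 1), n)
        before = np.isnan(out[start:stop]).sum()
        out[start:stop] = np.nan
        missing += (stop - start) - before
    return out


def synthetic_eigenmodes(spec: SyntheticWormSpec, seed: int = 0,
                         record_id: str | None = None) -> EigenmodeRecord:
    """Generate one synthetic eigenmode record with known coupling graph.

    The returned record's ``truth`` dict stores the planted couplings
    (source, target, delay in samples, strength) so recovery tests can
    compare a profile's best delay against the generative one.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    total = spec.burn_in + n
    m = spec.n_modes
    r = np.asarray(spec.growth_rates[:m])
    state = np.empty((total, m))
    state[0] = rng.uniform(0.2, 0.8, size=m)
    into: dict[int, list[tuple[int, int, float]]] = {}
    names = list(spec.mode_names)
    for src, dst, L, c in spec.couplings:
        into.setdefault(names.index(dst), []).append((names.index(src), L, c))
    for t in range(total - 1):
        drive = np.zeros(m)
        for j, terms in into.items():
            for i, L, c in terms:
                drive[j] += c * state[max(t - L, 0), i]
        state[t + 1] = state[t] * (r - r * state[t] + drive)
        if np.any(state[t + 1] <= 0.0) or np.any(state[t + 1] >= 1.0):
            bad = int(np.argmax((state[t + 1] <= 0.0) | (state[t + 1] >= 1.0)))
            raise ValueError(
                f"mode {names[bad]} left (0, 1) at step {t + 1}; "
                f"coupling strengths too strong")
    obs = state[spec.burn_in:] + rng.normal(0.0, spec.noise_sd, size=(n, m))
    modes = {}
    for j, name in enumerate(names):
        vals = obs[:, j]
        if spec.nan_fraction > 0:
            vals = _inject_gaps(vals, spec.nan_fraction, spec.mean_gap_len, rng)
        modes[name] = TimeSeries(vals, rate_hz=spec.rate_hz)
    truth = {
        "couplings": [list(c) for c in spec.couplings],
        "rate_hz": spec.rate_hz,
        "seed": int(seed),
        "noise_sd": spec.noise_sd,
        "nan_fraction": spec.nan_fraction,
    }
    rid = record_id if record_id is not None else f"synthetic-{seed}"
    return EigenmodeRecord(rid, modes, strain=None, behavior=None, truth=truth)


def box1_record(couplings: tuple[tuple[int, float], ...] = ((4, 0.1),),
                n_steps: int = 2000, seed: int = 0,
                record_id: str | None = None) -> EigenmodeRecord:
    """Coupled logistic benchmark packaged as a 4-channel record.

    a1 is the driving map x, a2 the driven map y; a3 and a4 are
    independent logistic maps so the record has the full four channels the
    profiling pipeline expects.  The truth sidecar lists the planted
    a1 -> a2 couplings in (source, target, delay, strength) form.
    """
    rng = np.random.SeedSequence(seed)
    s_main, s3, s4 = (int(s.generate_state(1)[0]) for s in rng.spawn(3))
    x, y = coupled_logistic(LogisticCouplingSpec(couplings=couplings,
                                                 n_steps=n_steps, seed=s_main))
    extras = {}
    for name, r, s in (("a3", 3.9, s3), ("a4", 3.7, s4)):
        g = np.random.default_rng(s)
        v = np.empty(n_steps + 200)
        v[0] = g.uniform(0.2, 0.8)
        for t in range(v.size - 1):
            v[t + 1] = v[t] * (r - r * v[t])
        extras[name] = TimeSeries(v[200:], rate_hz=1.0)
    modes = {"a1": x, "a2": y, "a3": extras["a3"], "a4": extras["a4"]}
    truth = {"couplings": [["a1", "a2", int(L), float(c)] for L, c in couplings],
             "rate_hz": 1.0, "seed": int(seed)}
    rid = record_id if record_id is not None else f"box1-{seed}"
    return EigenmodeRecord(rid, modes, truth=truth)
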