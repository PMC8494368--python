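"""Readers, writers, record filtering, and profile resampling.

Canonical on-disk format is a tidy CSV/TSV table with one row per frame:
optional ``id``/``strain``/``behavior`` columns, a ``time`` (seconds) or
``frame`` column, and eigenmode columns ``a1..a4`` (more modes are kept if
present).  Blank cells, ``NA`` and ``NaN`` parse as missing.  An HDF5
mirror stores each record as a group with a ``modes`` dataset and
metadata attributes, for large collections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import CrossMapConfig, EigenmodeRecord, TimeSeries
from .profiles import InteractionProfile, ProfileSet

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_eigenmodes",
    "write_eigenmodes",
    "read_eigenmodes_hdf5",
    "write_eigenmodes_hdf5",
    "read_profiles",
    "write_profiles",
    "filter_records",
    "resample_profile",
]

_REQUIRED_MODES = ("a1", "a2", "a3", "a4")


@dataclass
class RunConfig:
    """Full parameterization of a profiling run; serializes to YAML.

    Filter thresholds follow the strict readings "less than 25% NAs" and
    "over 200 indices".  ``trim_before`` drops that many leading samples
    from every record (used to cut a pre-stimulus baseline).
    """

    E: int = 10
    tp_min: int = -32
    tp_max: int = 0
    tp_step: int = 1
    library_size: int | str = 200
    n_repeats: int = 250
    exclusion_radius: int = 0
    window_s: float = 20.0
    n_perm: int = 1000
    seed: int = 0
    max_na_fraction: float = 0.25
    min_length: int = 200
    trim_before: int = 0

    def delays(self) -> np.ndarray:
        if self.tp_min > self.tp_max or self.tp_max > 0:
            raise ValueError("need tp_min <= tp_max <= 0")
        return np.arange(self.tp_min, self.tp_max + 1, self.tp_step)

    def cross_map_config(self) -> CrossMapConfig:
        return CrossMapConfig(E=self.E, tp=self.tp_max,
                              library_size=self.library_size,
                              n_repeats=self.n_repeats,
                              exclusion_radius=self.exclusion_radius,
                              rng_seed=self.seed)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def log(self) -> None:
        logger.info("run config: %s", asdict(self))


def _infer_rate(time: np.ndarray, context: str) -> float:
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise ValueError(f"{context}: time column is not strictly increasing")
    if dt.max() - dt.min() > 1e-6 * max(dt.mean(), 1e-12):
        raise ValueError(f"{context}: time column has inconsistent sampling intervals")
    return float(1.0 / dt.mean())


def read_eigenmodes(path, rate_hz: float | None = None) -> list[EigenmodeRecord]:
    """Read one or more eigenmode records from a tidy CSV/TSV table.

    Requires columns a1..a4 (case-insensitive); the sampling rate is
    inferred from a ``time`` column or must be supplied via ``rate_hz``
    when only a ``frame`` column is present.  Files with an ``id`` column
    are split into one record per id, preserving file order.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    df.columns = [str(c).strip().lower() for c in df.columns]
    mode_cols = [c for c in df.columns if c.startswith("a") and c[1:].isdigit()]
    mode_cols = sorted(mode_cols, key=lambda c: int(c[1:]))
    absent = [m for m in _REQUIRED_MODES if m not in mode_cols]
    if absent:
        raise ValueError(f"{path}: missing eigenmode column(s) {absent}")

    if "id" in df.columns:
        groups = [(str(k), g) for k, g in df.groupby("id", sort=False)]
    else:
        groups = [("record0", df)]

    records = []
    for rid, g in groups:
        if "time" in g.columns:
            rate = _infer_rate(g["time"].to_numpy(dtype=float), f"{path} id={rid}")
            if rate_hz is not None and not math.isclose(rate, rate_hz, rel_tol=1e-3):
                raise ValueError(
                    f"{path} id={rid}: time column implies {rate:.4g} Hz, "
                    f"inconsistent with supplied rate {rate_hz:.4g} Hz")
        elif rate_hz is not None:
            rate = float(rate_hz)
        else:
            raise ValueError(
                f"{path} id={rid}: no time column; supply rate_hz explicitly")
        modes = {
            m: TimeSeries(pd.to_numeric(g[m], errors="coerce").to_numpy(dtype=float),
                          rate_hz=rate)
            for m in mode_cols
        }
        strain = str(g["strain"].iloc[0]) if "strain" in g.columns and pd.notna(g["strain"].iloc[0]) else None
        behavior = str(g["behavior"].iloc[0]) if "behavior" in g.columns and pd.notna(g["behavior"].iloc[0]) else None
        records.append(EigenmodeRecord(rid, modes, strain=strain, behavior=behavior))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate record ids")
    return records


def write_eigenmodes(records: Sequence[EigenmodeRecord], path) -> None:
    """Write records to a tidy CSV (id, strain, behavior, time, modes...)."""
    frames = []
    for r in records:
        n = r.length
        data: dict = {"id": r.id}
        if r.strain is not None:
            data["strain"] = r.strain
        if r.behavior is not None:
            data["behavior"] = r.behavior
        data["time"] = np.arange(n) / r.rate_hz
        for name, ts in r.modes.items():
            data[name] = ts.values
        frames.append(pd.DataFrame(data))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_eigenmodes_hdf5(records: Sequence[EigenmodeRecord], path) -> None:
    with h5py.File(path, "w") as fh:
        root = fh.create_group("records")
        for r in records:
            g = root.create_group(r.id)
            mat = np.column_stack([ts.values for ts in r.modes.values()])
            g.create_dataset("modes", data=mat)
            g.attrs["mode_names"] = list(r.modes.keys())
            g.attrs["rate_hz"] = r.rate_hz
            g.attrs["strain"] = r.strain if r.strain is not None else ""
            g.attrs["behavior"] = r.behavior if r.behavior is not None else ""


def read_eigenmodes_hdf5(path) -> list[EigenmodeRecord]:
    records = []
    with h5py.File(path, "r") as fh:
        for rid, g in fh["records"].items():
            names = [str(n) for n in g.attrs["mode_names"]]
            rate = float(g.attrs["rate_hz"])
            mat = np.asarray(g["modes"])
            modes = {name: TimeSeries(mat[:, j], rate_hz=rate)
                     for j, name in enumerate(names)}
            strain = str(g.attrs["strain"]) or None
            behavior = str(g.attrs["behavior"]) or None
            records.append(EigenmodeRecord(str(rid), modes, strain=strain,
                                           behavior=behavior))
    return records


def write_profiles(sets: Sequence[ProfileSet], path) -> None:
    """Serialize profile sets to a tidy table (CSV, or HDF5 if path ends .h5/.hdf5).

    Columns: owner, pair_effect, pair_predictor, tp_samples, tp_seconds,
    skill_raw, skill_norm.
    """
    rows = []
    for s in sets:
        for (e, p), prof in s.profiles.items():
            rows.append(pd.DataFrame({
                "owner": s.owner,
                "pair_effect": e,
                "pair_predictor": p,
                "tp_samples": prof.tp,
                "tp_seconds": prof.tp_seconds,
                "skill_raw": prof.skill_raw,
                "skill_norm": prof.skill_norm,
                "rate_hz": prof.rate_hz,
            }))
    df = pd.concat(rows, ignore_index=True)
    if str(path).endswith((".h5", ".hdf5")):
        df.to_hdf(path, key="profiles", mode="w")
    else:
        df.to_csv(path, index=False)


def read_profiles(path) -> list[ProfileSet]:
    if str(path).endswith((".h5", ".hdf5")):
        df = pd.read_hdf(path, key="profiles")
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    sets = []
    for owner, g in df.groupby("owner", sort=False):
        profiles = {}
        for (e, p), gg in g.groupby(["pair_effect", "pair_predictor"], sort=False):
            gg = gg.sort_values("tp_samples")
            profiles[(e, p)] = InteractionProfile(
                effect=e, predictor=p,
                tp=gg["tp_samples"].to_numpy(dtype=int),
                rate_hz=float(gg["rate_hz"].iloc[0]),
                skill_raw=gg["skill_raw"].to_numpy(dtype=float))
        sets.append(ProfileSet(owner=str(owner), profiles=profiles))
    return sets


def filter_records(records: Sequence[EigenmodeRecord],
                   max_na_fraction: float = 0.25,
                   min_length: int = 200,
                   ) -> tuple[list[EigenmodeRecord], list[tuple[EigenmodeRecord, str]]]:
    """Keep records with na_fraction strictly below the cap and length
    strictly above the floor; dropped records carry a reason string."""
    kept, dropped = [], []
    for r in records:
        reasons = []
        if not r.length > min_length:
            reasons.append(f"length {r.length} not over {min_length}")
        if not r.na_fraction < max_na_fraction:
            reasons.append(f"NA fraction {r.na_fraction:.3f} not under {max_na_fraction}")
        if reasons:
            reason = "; ".join(reasons)
            logger.info("dropped record %s: %s", r.id, reason)
            dropped.append((r, reason))
        else:
            kept.append(r)
    return kept, dropped


def resample_profile(profile: InteractionProfile, grid_step_s: float = 0.1,
                     grid_s: Sequence[float] | None = None) -> InteractionProfile:
    """Linearly interpolate a profile onto a regular grid in seconds of tp.

    By default the grid contains every multiple of ``grid_step_s`` inside
    the profile's delay support; grid points coinciding with resolved
    native delays reproduce them exactly, and extrapolation beyond the
    support is an error.  The result is a profile whose sample unit is one
    grid step (rate 1 / grid_step_s).
    """
    if grid_step_s <= 0:
        raise ValueError("grid_step_s must be positive")
    rate_out = 1.0 / grid_step_s
    if math.isclose(rate_out, round(rate_out), rel_tol=1e-9):
        rate_out = float(round(rate_out))
    ts = profile.tp_seconds
    ok = np.isfinite(profile.skill_raw)
    if ok.sum() < 2:
        raise ValueError("need at least two resolved delays to interpolate")
    xs, ys = ts[ok], profile.skill_raw[ok]
    if grid_s is None:
        kmin = math.ceil(xs[0] * rate_out - 1e-9)
        kmax = math.floor(xs[-1] * rate_out + 1e-9)
        if kmin > kmax:
            raise ValueError("profile support contains no grid point")
        k = np.arange(kmin, kmax + 1)
    else:
        grid = np.asarray(grid_s, dtype=float)
        if grid.min() < xs[0] - 1e-12 or grid.max() > xs[-1] + 1e-12:
            raise ValueError(
                f"grid [{grid.min():g}, {grid.max():g}] s extends beyond the "
                f"profile support [{xs[0]:g}, {xs[-1]:g}] s; no extrapolation")
        k = np.round(grid * rate_out).astype(int)
        if not np.allclose(k / rate_out, grid, atol=1e-9):
            raise ValueError("grid_s must be multiples of grid_step_s")
    grid = k / rate_out
    vals = np.interp(grid, xs, ys)
    return InteractionProfile(effect=profile.effect, predictor=profile.predictor,
                              tp=k, rate_hz=rate_out, skill_raw=vals)
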