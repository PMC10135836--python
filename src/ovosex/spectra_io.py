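"""Domain types and readers/writers for egg impedance sweep data.

The measurement model: four carbon-epoxy electrodes on each egg
(positions 1 and 2 at the broad and narrow ends, 3 and 4 diametrically
opposite on the width circumference), a small-signal frequency sweep per
electrode pair per incubation day, |Z| in ohms recorded on a common
frequency grid spanning 20 Hz to 10 MHz.

Sweep tables are long-format CSV: one row per (egg, day, pair, frequency)
with columns ``egg_id, day, pair, frequency_hz, z_mod_ohm, phase_deg``.
Label tables map eggs to sex with columns ``egg_id, sex, source``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyGrid",
    "SweepConfig",
    "ElectrodePair",
    "SpectrumRecord",
    "RatioSpectrum",
    "Sex",
    "LabelSource",
    "SexLabel",
    "make_default_grid",
    "nearest_grid_frequency",
    "read_sweeps",
    "write_sweeps",
    "read_labels",
    "write_labels",
]

GRID_MIN_HZ = 20.0
GRID_MAX_HZ = 1.0e7
DEFAULT_GRID_POINTS = 100


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered frequency grid in Hz, confined to the analyzer range."""

    points: tuple[float, ...]

    def __post_init__(self) -> None:
        pts = tuple(float(p) for p in self.points)
        if len(pts) == 0:
            raise ValueError("frequency grid must be nonempty")
        if any(not (GRID_MIN_HZ <= p <= GRID_MAX_HZ) for p in pts):
            raise ValueError(
                f"grid points must lie in [{GRID_MIN_HZ:g}, {GRID_MAX_HZ:g}] Hz"
            )
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise ValueError("frequency grid must be strictly increasing")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, i: int) -> float:
        return self.points[i]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


def make_default_grid() -> FrequencyGrid:
    """The analyzer's sweep grid: 100 log-spaced points, 20 Hz to 10 MHz.

    Endpoints are exact; interior points follow
    ``20 * (1e7 / 20) ** (k / 99)``.
    """
    pts = np.geomspace(GRID_MIN_HZ, GRID_MAX_HZ, DEFAULT_GRID_POINTS)
    pts[0] = GRID_MIN_HZ
    pts[-1] = GRID_MAX_HZ
    return FrequencyGrid(tuple(pts))


@dataclass(frozen=True)
class SweepConfig:
    """Analyzer settings: 100 mV rms drive, 80 ms per point by default."""

    excitation_mv: float = 100.0
    grid: FrequencyGrid = field(default_factory=make_default_grid)
    dwell_ms: float = 80.0

    def __post_init__(self) -> None:
        if self.excitation_mv <= 0:
            raise ValueError("excitation_mv must be positive")
        if self.dwell_ms <= 0:
            raise ValueError("dwell_ms must be positive")


@dataclass(frozen=True, order=True)
class ElectrodePair:
    """An unordered electrode pair, canonicalized so that a < b.

    Electrodes are numbered 1-4; ``ElectrodePair(3, 2)`` normalizes to
    (2, 3).
    """

    a: int
    b: int

    def __post_init__(self) -> None:
        a, b = int(self.a), int(self.b)
        if a not in (1, 2, 3, 4) or b not in (1, 2, 3, 4):
            raise ValueError(f"electrode indices must be in 1..4, got ({a}, {b})")
        if a == b:
            raise ValueError("electrode pair must use two distinct electrodes")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @classmethod
    def parse(cls, text: str) -> "ElectrodePair":
        """Parse a pair written as e.g. ``"2-3"``."""
        try:
            a, b = text.strip().split("-")
            return cls(int(a), int(b))
        except ValueError as exc:
            raise ValueError(f"cannot parse electrode pair {text!r}") from exc

    def __str__(self) -> str:
        return f"{self.a}-{self.b}"


@dataclass(frozen=True)
class SpectrumRecord:
    """One impedance sweep: |Z| per grid point for one egg/day/pair."""

    egg_id: str
    day: int
    pair: ElectrodePair
    grid: FrequencyGrid
    z_mod: np.ndarray
    phase_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z_mod, dtype=float)
        if z.shape != (len(self.grid),):
            raise ValueError(
                f"z_mod length {z.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(z > 0):
            raise ValueError(f"|Z| must be positive (egg {self.egg_id}, day {self.day})")
        if not 0 <= int(self.day) <= 13:
            raise ValueError(f"incubation day must be 0..13, got {self.day}")
        object.__setattr__(self, "egg_id", str(self.egg_id))
        object.__setattr__(self, "day", int(self.day))
        object.__setattr__(self, "z_mod", z)
        if self.phase_deg is not None:
            ph = np.asarray(self.phase_deg, dtype=float)
            if ph.shape != z.shape:
                raise ValueError("phase_deg length must match grid length")
            object.__setattr__(self, "phase_deg", ph)

    @property
    def key(self) -> tuple[str, int, ElectrodePair]:
        return (self.egg_id, self.day, self.pair)


@dataclass(frozen=True)
class RatioSpectrum:
    """Self-normalized spectrum: |Z| of one pair over |Z| of another."""

    egg_id: str
    day: int
    num_pair: ElectrodePair
    den_pair: ElectrodePair
    grid: FrequencyGrid
    ratio: np.ndarray

    def __post_init__(self) -> None:
        if self.num_pair == self.den_pair:
            raise ValueError("numerator and denominator pairs must differ")
        r = np.asarray(self.ratio, dtype=float)
        if r.shape != (len(self.grid),):
            raise ValueError("ratio length must match grid length")
        if not np.all(r > 0):
            raise ValueError("ratio values must be positive")
        object.__setattr__(self, "egg_id", str(self.egg_id))
        object.__setattr__(self, "day", int(self.day))
        object.__setattr__(self, "ratio", r)

    def value_at(self, index: int) -> float:
        return float(self.ratio[index])


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNFERTILIZED = "unfertilized"
    UNKNOWN = "unknown"


class LabelSource(str, enum.Enum):
    PCR = "pcr"
    IMPEDANCE = "impedance"


@dataclass(frozen=True)
class SexLabel:
    egg_id: str
    sex: Sex
    source: LabelSource

    def __post_init__(self) -> None:
        sex = Sex(self.sex)
        source = LabelSource(self.source)
        if sex is Sex.UNFERTILIZED and source is not LabelSource.PCR:
            raise ValueError("unfertilized labels can come only from PCR")
        object.__setattr__(self, "egg_id", str(self.egg_id))
        object.__setattr__(self, "sex", sex)
        object.__setattr__(self, "source", source)


def nearest_grid_frequency(grid: FrequencyGrid, f_target: float) -> tuple[int, float]:
    """Index and value of the grid point log-nearest to ``f_target``.

    Distance is measured in log10(frequency); ties break toward the
    lower index, matching the lower-frequency preference used elsewhere.
    """
    if f_target <= 0:
        raise ValueError("target frequency must be positive")
    logs = np.log10(grid.as_array())
    d = np.abs(logs - math.log10(f_target))
    idx = int(np.argmin(d))  # argmin returns the first (lower) index on ties
    return idx, grid[idx]


_SWEEP_COLUMNS = ["egg_id", "day", "pair", "frequency_hz", "z_mod_ohm", "phase_deg"]


def _read_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: the default fast parser can be off by 1 ulp
    return pd.read_csv(
        path, dtype={"egg_id": str}, comment="#", float_precision="round_trip"
    )


def read_sweeps(
    path: str | Path,
    grid: FrequencyGrid | None = None,
) -> list[SpectrumRecord]:
    """Load sweep records from a long-format CSV.

    If ``grid`` is None the grid is inferred from the data and must be
    identical across all sweeps; otherwise every sweep is validated
    against the supplied grid. Duplicated (egg, day, pair, frequency)
    rows and non-positive |Z| raise, naming the offending sweep.
    """
    df = _read_table(path)
    missing = {"egg_id", "day", "pair", "frequency_hz", "z_mod_ohm"} - set(df.columns)
    if missing:
        raise ValueError(f"sweep CSV missing columns: {sorted(missing)}")
    if len(df) == 0:
        return []
    bad = df["z_mod_ohm"] <= 0
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            f"non-positive |Z| for egg {row['egg_id']} day {row['day']} "
            f"pair {row['pair']} at {row['frequency_hz']} Hz"
        )

    records: list[SpectrumRecord] = []
    inferred: FrequencyGrid | None = grid
    has_phase = "phase_deg" in df.columns and df["phase_deg"].notna().any()
    for (egg, day, pair_s), sub in df.groupby(["egg_id", "day", "pair"], sort=True):
        sub = sub.sort_values("frequency_hz", kind="mergesort")
        freqs = sub["frequency_hz"].to_numpy(dtype=float)
        if len(np.unique(freqs)) != len(freqs):
            f_dup = freqs[pd.Series(freqs).duplicated().to_numpy()][0]
            raise ValueError(
                f"duplicate frequency {f_dup} Hz for egg {egg} day {day} pair {pair_s}"
            )
        this_grid = FrequencyGrid(tuple(freqs))
        if inferred is None:
            inferred = this_grid
        elif this_grid.points != inferred.points:
            raise ValueError(
                f"sweep grid for egg {egg} day {day} pair {pair_s} does not match "
                f"the {'supplied' if grid is not None else 'inferred'} grid"
            )
        phase = (
            sub["phase_deg"].to_numpy(dtype=float) if has_phase else None
        )
        records.append(
            SpectrumRecord(
                egg_id=str(egg),
                day=int(day),
                pair=ElectrodePair.parse(str(pair_s)),
                grid=inferred,
                z_mod=sub["z_mod_ohm"].to_numpy(dtype=float),
                phase_deg=phase,
            )
        )
    return records


def write_sweeps(
    records: Iterable[SpectrumRecord],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write sweep records to CSV in deterministic order, full precision.

    Rows are sorted by (egg_id, day, pair, frequency). Floats use the
    shortest round-tripping decimal representation, so read_sweeps
    recovers values bit-exactly.
    """
    rows = []
    for rec in sorted(records, key=lambda r: (r.egg_id, r.day, r.pair)):
        for i, f in enumerate(rec.grid.points):
            rows.append(
                {
                    "egg_id": rec.egg_id,
                    "day": rec.day,
                    "pair": str(rec.pair),
                    "frequency_hz": f,
                    "z_mod_ohm": rec.z_mod[i],
                    "phase_deg": rec.phase_deg[i] if rec.phase_deg is not None else None,
                }
            )
    df = pd.DataFrame(rows, columns=_SWEEP_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


_SEX_TO_CSV = {Sex.MALE: "M", Sex.FEMALE: "F", Sex.UNFERTILIZED: "NA", Sex.UNKNOWN: "U"}
_CSV_TO_SEX = {v: k for k, v in _SEX_TO_CSV.items()}


def read_labels(path: str | Path) -> list[SexLabel]:
    """Load sex labels from CSV with columns egg_id, sex (M/F/NA/U), source."""
    df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)
    missing = {"egg_id", "sex", "source"} - set(df.columns)
    if missing:
        raise ValueError(f"label CSV missing columns: {sorted(missing)}")
    labels = []
    for _, row in df.iterrows():
        code = row["sex"].strip().upper()
        if code not in _CSV_TO_SEX:
            raise ValueError(f"unrecognized sex code {row['sex']!r} for egg {row['egg_id']}")
        labels.append(
            SexLabel(row["egg_id"], _CSV_TO_SEX[code], LabelSource(row["source"].strip()))
        )
    return labels


def write_labels(
    labels: Iterable[SexLabel], path: str | Path, header_comment: str | None = None
) -> None:
    rows = [
        {"egg_id": lab.egg_id, "sex": _SEX_TO_CSV[lab.sex], "source": lab.source.value}
        for lab in sorted(labels, key=lambda l: l.egg_id)
    ]
    df = pd.DataFrame(rows, columns=["egg_id", "sex", "source"])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)
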