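"""Self-normalized impedance ratio spectra.

The discriminative statistic is the pointwise ratio of |Z| measured on
two electrode pairs of the same egg in the same session (by convention
pair 2-3 over pair 2-4). Egg-size, shell-thickness and instrument scale
factors act multiplicatively on both pairs and cancel in the ratio,
which is why the raw spectra (which vary strongly between eggs) become
comparable across a cohort.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra_io import ElectrodePair, FrequencyGrid, RatioSpectrum, SpectrumRecord

__all__ = ["ratio_spectrum", "ratio_dataset", "read_ratios", "write_ratios"]

logger = logging.getLogger(__name__)


def ratio_spectrum(num: SpectrumRecord, den: SpectrumRecord) -> RatioSpectrum:
    """Pointwise |Z| ratio of two sweeps of the same egg on the same day."""
    if num.egg_id != den.egg_id:
        raise ValueError(f"egg mismatch: {num.egg_id} vs {den.egg_id}")
    if num.day != den.day:
        raise ValueError(f"day mismatch for egg {num.egg_id}: {num.day} vs {den.day}")
    if num.grid.points != den.grid.points:
        raise ValueError(f"grid mismatch for egg {num.egg_id} day {num.day}")
    if num.pair == den.pair:
        raise ValueError("numerator and denominator must be different electrode pairs")
    return RatioSpectrum(
        egg_id=num.egg_id,
        day=num.day,
        num_pair=num.pair,
        den_pair=den.pair,
        grid=num.grid,
        ratio=num.z_mod / den.z_mod,
    )


def ratio_dataset(
    sweeps: Iterable[SpectrumRecord],
    num_pair: ElectrodePair = ElectrodePair(2, 3),
    den_pair: ElectrodePair = ElectrodePair(2, 4),
) -> tuple[list[RatioSpectrum], list[tuple[str, int]]]:
    """One ratio spectrum per (egg, day) having both pairs.

    Returns the ratios plus the list of (egg_id, day) combinations that
    were skipped because one of the two pairs is missing; skips are also
    logged, never imputed.
    """
    if num_pair == den_pair:
        raise ValueError("numerator and denominator pairs must differ")
    by_key: dict[tuple[str, int], dict[ElectrodePair, SpectrumRecord]] = {}
    for rec in sweeps:
        slot = by_key.setdefault((rec.egg_id, rec.day), {})
        if rec.pair in slot:
            raise ValueError(
                f"duplicate sweep for egg {rec.egg_id} day {rec.day} pair {rec.pair}"
            )
        slot[rec.pair] = rec

    ratios: list[RatioSpectrum] = []
    excluded: list[tuple[str, int]] = []
    for key in sorted(by_key):
        slot = by_key[key]
        if num_pair in slot and den_pair in slot:
            ratios.append(ratio_spectrum(slot[num_pair], slot[den_pair]))
        else:
            excluded.append(key)
            logger.info(
                "excluding egg %s day %d: missing pair %s",
                key[0],
                key[1],
                num_pair if num_pair not in slot else den_pair,
            )
    return ratios, excluded


def write_ratios(
    ratios: Iterable[RatioSpectrum],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Long-format ratio CSV: egg_id, day, num_pair, den_pair, frequency_hz, ratio."""
    rows = []
    for r in sorted(ratios, key=lambda r: (r.egg_id, r.day)):
        for i, f in enumerate(r.grid.points):
            rows.append(
                {
                    "egg_id": r.egg_id,
                    "day": r.day,
                    "num_pair": str(r.num_pair),
                    "den_pair": str(r.den_pair),
                    "frequency_hz": f,
                    "ratio": r.ratio[i],
                }
            )
    df = pd.DataFrame(
        rows, columns=["egg_id", "day", "num_pair", "den_pair", "frequency_hz", "ratio"]
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_ratios(path: str | Path) -> list[RatioSpectrum]:
    df = pd.read_csv(
        path, dtype={"egg_id": str}, comment="#", float_precision="round_trip"
    )
    missing = {"egg_id", "day", "num_pair", "den_pair", "frequency_hz", "ratio"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"ratio CSV missing columns: {sorted(missing)}")
    out: list[RatioSpectrum] = []
    for (egg, day, nump, denp), sub in df.groupby(
        ["egg_id", "day", "num_pair", "den_pair"], sort=True
    ):
        sub = sub.sort_values("frequency_hz", kind="mergesort")
        grid = FrequencyGrid(tuple(sub["frequency_hz"].to_numpy(dtype=float)))
        out.append(
            RatioSpectrum(
                egg_id=str(egg),
                day=int(day),
                num_pair=ElectrodePair.parse(str(nump)),
                den_pair=ElectrodePair.parse(str(denp)),
                grid=grid,
                ratio=sub["ratio"].to_numpy(dtype=float),
            )
        )
    return out
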