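"""PCR gel banding to ground-truth sex labels.

The reference sexing method amplifies the sex-linked CHD locus and reads
fragment sizes off a 2% agarose gel: a single 552 bp band marks a male
(ZZ), double bands at 358 bp and 552 bp mark a female (ZW). Gel size
estimates are approximate, so band matching uses a configurable bp
tolerance. Eggs with no bands are unknown unless a survival flag marks
them unfertilized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .spectra_io import LabelSource, Sex, SexLabel

__all__ = [
    "BandingRecord",
    "call_sex_from_bands",
    "tally_labels",
    "read_banding",
    "labels_from_banding",
]

MALE_BAND_BP = 552
FEMALE_EXTRA_BAND_BP = 358
DEFAULT_BAND_TOL_BP = 15


@dataclass(frozen=True)
class BandingRecord:
    """Observed gel fragment sizes (bp) for one egg; empty set = no bands."""

    egg_id: str
    bands: frozenset[int]

    def __post_init__(self) -> None:
        bands = frozenset(int(b) for b in self.bands)
        if any(b <= 0 for b in bands):
            raise ValueError("band sizes must be positive integers")
        object.__setattr__(self, "egg_id", str(self.egg_id))
        object.__setattr__(self, "bands", bands)


def _matches(bands: frozenset[int], marker_bp: int, tol_bp: int) -> bool:
    return any(abs(b - marker_bp) <= tol_bp for b in bands)


def call_sex_from_bands(
    rec: BandingRecord,
    tol_bp: int = DEFAULT_BAND_TOL_BP,
    fertilized: bool | None = None,
) -> SexLabel:
    """Band-call rule: 552 bp only -> male; 552 + 358 bp -> female.

    A bandless record is unfertilized when ``fertilized`` is False,
    otherwise unknown. A 358 bp band without the 552 bp band is not a
    valid pattern and yields unknown with a warning.
    """
    has_552 = _matches(rec.bands, MALE_BAND_BP, tol_bp)
    has_358 = _matches(rec.bands, FEMALE_EXTRA_BAND_BP, tol_bp)
    if has_552 and has_358:
        sex = Sex.FEMALE
    elif has_552:
        sex = Sex.MALE
    elif has_358:
        warnings.warn(
            f"egg {rec.egg_id}: 358 bp band without 552 bp band; calling unknown",
            RuntimeWarning,
        )
        sex = Sex.UNKNOWN
    else:
        sex = Sex.UNFERTILIZED if fertilized is False else Sex.UNKNOWN
    return SexLabel(rec.egg_id, sex, LabelSource.PCR)


def tally_labels(labels: Iterable[SexLabel]) -> dict[Sex, int]:
    """Counts by sex category; duplicate egg ids raise."""
    counts = {s: 0 for s in Sex}
    seen: set[str] = set()
    for lab in labels:
        if lab.egg_id in seen:
            raise ValueError(f"duplicate egg id {lab.egg_id!r}")
        seen.add(lab.egg_id)
        counts[lab.sex] += 1
    return counts


def read_banding(path: str | Path) -> tuple[list[BandingRecord], dict[str, bool]]:
    """Load a banding CSV: egg_id, bands (semicolon-separated bp), survival.

    Returns the records and a map egg_id -> fertilized (True for '+',
    False for 'NA'); eggs without a survival column are omitted from
    the map.
    """
    df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)
    if {"egg_id", "bands"} - set(df.columns):
        raise ValueError("banding CSV needs columns egg_id, bands")
    records = []
    fertilized: dict[str, bool] = {}
    for _, row in df.iterrows():
        bands = frozenset(
            int(tok) for tok in row["bands"].split(";") if tok.strip()
        )
        records.append(BandingRecord(row["egg_id"], bands))
        if "survival" in df.columns and row["survival"].strip():
            fertilized[row["egg_id"]] = row["survival"].strip() != "NA"
    return records, fertilized


def labels_from_banding(
    records: Iterable[BandingRecord],
    fertilized: Mapping[str, bool] | None = None,
    tol_bp: int = DEFAULT_BAND_TOL_BP,
) -> list[SexLabel]:
    fertilized = fertilized or {}
    return [
        call_sex_from_bands(rec, tol_bp=tol_bp, fertilized=fertilized.get(rec.egg_id))
        for rec in records
    ]
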