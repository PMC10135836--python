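"""Published reference statistics for the 17-egg in-ovo sexing study.

Two small tables are embedded so analyses can be reproduced without the
raw sweep data, which was never deposited:

* ``REFERENCE_DAY_STATS`` — per incubation day (1-13), the group mean
  and sample SD of the 2-3/2-4 impedance ratio at 376 kHz for the eight
  male and eight female eggs, plus the published two-tailed independent
  t-test p-value. The day-9 published p (0.006125) is not reproducible
  from the day-9 summaries under a two-tailed Welch or pooled test
  (both give ~0.013; one-tailed Welch gives ~0.0066), so exact checks
  should treat that printed value with caution.

* ``REFERENCE_PCR_SURVEY`` — the per-egg survival/sex outcome of the
  PCR reference method for all 17 eggs (8 male, 8 female, 1
  unfertilized), expressed here as gel band sizes.

These are calibration inputs, not outputs of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pcr_labels import BandingRecord
from .spectra_io import Sex

__all__ = [
    "DayStats",
    "REFERENCE_DAY_STATS",
    "REFERENCE_GROUP_N",
    "REFERENCE_FREQUENCY_HZ",
    "REFERENCE_PCR_SURVEY",
    "reference_banding_records",
    "reference_p_by_day",
]

REFERENCE_GROUP_N = 8
REFERENCE_FREQUENCY_HZ = 3.76e5


@dataclass(frozen=True)
class DayStats:
    day: int
    male_mean: float
    male_sd: float
    female_mean: float
    female_sd: float
    p_published: float


REFERENCE_DAY_STATS: tuple[DayStats, ...] = (
    DayStats(1, 1.125607, 0.167139, 0.950940, 0.086574, 0.023633),
    DayStats(2, 1.023389, 0.166270, 0.957140, 0.072835, 0.326269),
    DayStats(3, 1.063620, 0.123114, 0.974016, 0.177845, 0.264056),
    DayStats(4, 1.087815, 0.127670, 0.943842, 0.070731, 0.017585),
    DayStats(5, 1.061307, 0.119568, 1.006839, 0.154494, 0.444491),
    DayStats(6, 1.117094, 0.172387, 0.959187, 0.101615, 0.047364),
    DayStats(7, 1.058761, 0.148037, 0.963327, 0.115739, 0.174494),
    DayStats(8, 1.066774, 0.125547, 0.990487, 0.119059, 0.232832),
    DayStats(9, 1.122262, 0.112674, 0.953107, 0.124892, 0.006125),
    DayStats(10, 1.083995, 0.128271, 0.928134, 0.075590, 0.012954),
    DayStats(11, 1.077437, 0.120659, 0.946580, 0.076244, 0.023521),
    DayStats(12, 1.131611, 0.167438, 0.961139, 0.102673, 0.030321),
    DayStats(13, 1.087150, 0.095502, 0.959394, 0.091049, 0.016000),
)

# Per-egg PCR outcome: sex or None for the one unfertilized egg (no bands).
REFERENCE_PCR_SURVEY: tuple[tuple[str, Sex | None], ...] = (
    ("1", Sex.MALE),
    ("2", Sex.MALE),
    ("3", Sex.MALE),
    ("4", Sex.FEMALE),
    ("5", Sex.MALE),
    ("6", Sex.FEMALE),
    ("7", Sex.FEMALE),
    ("8", Sex.FEMALE),
    ("9", Sex.MALE),
    ("10", Sex.FEMALE),
    ("11", Sex.FEMALE),
    ("12", Sex.MALE),
    ("13", Sex.MALE),
    ("14", Sex.FEMALE),
    ("15", None),
    ("16", Sex.MALE),
    ("17", Sex.FEMALE),
)


def reference_banding_records() -> tuple[list[BandingRecord], dict[str, bool]]:
    """The PCR survey as gel banding records plus fertilization flags."""
    records = []
    fertilized = {}
    for egg_id, sex in REFERENCE_PCR_SURVEY:
        if sex is Sex.MALE:
            bands = frozenset({552})
        elif sex is Sex.FEMALE:
            bands = frozenset({552, 358})
        else:
            bands = frozenset()
        records.append(BandingRecord(egg_id, bands))
        fertilized[egg_id] = sex is not None
    return records, fertilized


def reference_p_by_day() -> dict[int, float]:
    """The published per-day p-value column as a day -> p mapping."""
    return {row.day: row.p_published for row in REFERENCE_DAY_STATS}
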