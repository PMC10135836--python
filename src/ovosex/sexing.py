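"""Ratio-threshold sex classification and its evaluation.

In the discriminative window (day 9 onward, roughly 376 kHz-2.79 MHz)
male eggs show a 2-3/2-4 impedance ratio above 1 and female eggs below
1, so a single threshold on the ratio at one grid frequency classifies
an egg. The distributions overlap, so an optional symmetric margin
around the threshold declares near-threshold eggs indeterminate instead
of forcing a call. Under a normal model for each group the achievable
sensitivities have the closed form

    male sensitivity   = Phi((mu_m - thr) / sd_m)
    female sensitivity = Phi((thr - mu_f) / sd_f)

which `expected_accuracy` exposes for power/operating-point analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from scipy import stats

from .spectra_io import LabelSource, RatioSpectrum, Sex, SexLabel

__all__ = [
    "ClassifierConfig",
    "EvaluationReport",
    "classify_egg",
    "evaluate",
    "expected_accuracy",
]

DEFAULT_FREQUENCY_HZ = 3.76e5
DEFAULT_DAY = 9


@dataclass(frozen=True)
class ClassifierConfig:
    """Operating point of the threshold classifier.

    ``frequency_hz`` must be an exact grid frequency (use
    nearest_grid_frequency to map a nominal target like 376 kHz onto
    the measured grid). If ``band_hz`` is set, the mean ratio over the
    grid points inside that band is classified instead of the value at
    one point.
    """

    frequency_hz: float = DEFAULT_FREQUENCY_HZ
    day: int = DEFAULT_DAY
    threshold: float = 1.0
    margin: float = 0.0
    band_hz: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.margin < 0:
            raise ValueError("margin cannot be negative")
        if self.band_hz is not None and self.band_hz[0] >= self.band_hz[1]:
            raise ValueError("band_hz must be (low, high) with low < high")


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and accuracies of predictions vs PCR truth.

    ``confusion`` maps (true sex, predicted sex) to a count over the
    determinately classified eggs; indeterminate (unknown) predictions
    are tallied separately and excluded from accuracy denominators.
    """

    confusion: dict[tuple[Sex, Sex], int]
    n_indeterminate: int
    per_class_accuracy: dict[Sex, float | None]
    overall_accuracy: float | None
    balanced_accuracy: float | None

    @property
    def n_classified(self) -> int:
        return sum(self.confusion.values())


def _decide(r: float, cfg: ClassifierConfig) -> Sex:
    if r > cfg.threshold + cfg.margin:
        return Sex.MALE
    if r < cfg.threshold - cfg.margin:
        return Sex.FEMALE
    return Sex.UNKNOWN


def classify_egg(ratio: RatioSpectrum, cfg: ClassifierConfig = ClassifierConfig()) -> SexLabel:
    """Threshold the egg's ratio at the configured day and frequency.

    Raises if the spectrum is for a different day or the requested
    frequency is not a grid point.
    """
    if ratio.day != cfg.day:
        raise ValueError(
            f"spectrum is for day {ratio.day}, classifier configured for day {cfg.day}"
        )
    freqs = ratio.grid.as_array()
    if cfg.band_hz is not None:
        lo, hi = cfg.band_hz
        mask = (freqs >= lo) & (freqs <= hi)
        if not mask.any():
            raise ValueError(f"no grid points inside band {cfg.band_hz}")
        r = float(ratio.ratio[mask].mean())
    else:
        hits = np.flatnonzero(np.isclose(freqs, cfg.frequency_hz, rtol=1e-9))
        if len(hits) == 0:
            raise ValueError(
                f"{cfg.frequency_hz} Hz is not a grid frequency; "
                "map it with nearest_grid_frequency first"
            )
        r = ratio.value_at(int(hits[0]))
    return SexLabel(ratio.egg_id, _decide(r, cfg), LabelSource.IMPEDANCE)


def evaluate(
    predictions: Iterable[SexLabel], truth: Iterable[SexLabel]
) -> EvaluationReport:
    """Score impedance calls against PCR ground truth, id-aligned."""
    pred = {p.egg_id: p for p in predictions}
    true = {t.egg_id: t for t in truth if t.sex in (Sex.MALE, Sex.FEMALE)}
    missing = sorted(set(pred) - set(true))
    if missing:
        raise ValueError(f"predictions without matching truth labels: {missing}")

    confusion: dict[tuple[Sex, Sex], int] = {}
    n_indet = 0
    for egg_id, p in sorted(pred.items()):
        t = true[egg_id].sex
        if p.sex is Sex.UNKNOWN:
            n_indet += 1
            continue
        confusion[(t, p.sex)] = confusion.get((t, p.sex), 0) + 1

    per_class: dict[Sex, float | None] = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        n_sex = sum(c for (t, _), c in confusion.items() if t == sex)
        per_class[sex] = (
            confusion.get((sex, sex), 0) / n_sex if n_sex > 0 else None
        )
    n_total = sum(confusion.values())
    overall = (
        sum(c for (t, p), c in confusion.items() if t == p) / n_total
        if n_total > 0
        else None
    )
    both = [v for v in per_class.values() if v is not None]
    balanced = sum(both) / len(both) if len(both) == 2 else None
    return EvaluationReport(
        confusion=confusion,
        n_indeterminate=n_indet,
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        balanced_accuracy=balanced,
    )


class ExpectedAccuracy(NamedTuple):
    male_sensitivity: float
    female_sensitivity: float
    balanced_accuracy: float


def expected_accuracy(
    mu_male: float,
    sd_male: float,
    mu_female: float,
    sd_female: float,
    threshold: float = 1.0,
) -> ExpectedAccuracy:
    """Closed-form sensitivities of the threshold rule under normal groups."""
    if sd_male <= 0 or sd_female <= 0:
        raise ValueError("group standard deviations must be positive")
    male = float(stats.norm.cdf((mu_male - threshold) / sd_male))
    female = float(stats.norm.cdf((threshold - mu_female) / sd_female))
    return ExpectedAccuracy(male, female, 0.5 * (male + female))
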