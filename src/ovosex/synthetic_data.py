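"""Synthetic four-electrode egg impedance cohorts.

The generator emulates what the analysis pipeline assumes about real
incubating eggs, with a Cole-type dispersion as the carrier spectrum:

    Z(f) = R_inf + (R0 - R_inf) / (1 + (i * 2*pi*f * tau)**alpha)

(eggshell acting as the membrane capacitance). Per electrode pair the
|Z| curve is scaled by a geometric gain and a per-day drift, and
corrupted by multiplicative log-normal noise that is heteroscedastic in
frequency: noisy below ~200 kHz (the shell blocks low-frequency
current) and much cleaner above.

The sex effect is injected at the ratio level: each egg receives one
ratio multiplier drawn from its group's calibrated normal distribution
(defaults are the published day-9 values: male 1.122262 +/- 0.112674,
female 0.953107 +/- 0.124892), applied to the 2-3 trace inside the
effect band from the onset day onward. Outside the band, and before
onset, a per-day baseline ratio ~ Normal(1, baseline_ratio_sd) applies
instead, so pre-onset days carry no systematic group difference.

Randomness uses one NumPy SeedSequence substream per egg
(``SeedSequence(seed, spawn_key=(egg_index,))``), so cohorts are
reproducible bit-for-bit across platforms and egg subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectra_io import (
    ElectrodePair,
    FrequencyGrid,
    LabelSource,
    Sex,
    SexLabel,
    SpectrumRecord,
    make_default_grid,
)

__all__ = ["EggSimParams", "CohortSimConfig", "cole_magnitude", "simulate_egg", "simulate_cohort"]

logger = logging.getLogger(__name__)

RATIO_TRUNCATION = (0.5, 2.0)  # guard band for ratio draws


def _default_pair_gains() -> dict[ElectrodePair, float]:
    # illustrative geometric factors; the height-axis pair (1,2) spans
    # more egg than the width pairs
    return {
        ElectrodePair(1, 2): 1.3,
        ElectrodePair(2, 3): 1.0,
        ElectrodePair(2, 4): 1.0,
    }


@dataclass(frozen=True)
class EggSimParams:
    """Cole-circuit, gain, drift and noise parameters for one egg model.

    Circuit defaults (r0 = 10 kOhm, r_inf = 200 Ohm, tau = 1 us,
    cole_alpha = 0.85) put the dispersion inside the 20 Hz - 10 MHz
    sweep with a falling |Z|, qualitatively like measured egg spectra;
    they are illustrative, not fitted. Noise SDs are on the log scale
    (multiplicative): 5% below the 200 kHz cutoff, 0.5% above.
    """

    r_inf_ohm: float = 200.0
    r0_ohm: float = 10_000.0
    tau_s: float = 1e-6
    cole_alpha: float = 0.85
    pair_gain: Mapping[ElectrodePair, float] = field(default_factory=_default_pair_gains)
    noise_sd_low: float = 0.05
    noise_sd_high: float = 0.005
    noise_cutoff_hz: float = 2.0e5
    day_drift: float = 1.02

    def __post_init__(self) -> None:
        if not (self.r0_ohm > self.r_inf_ohm > 0):
            raise ValueError("need r0 > r_inf > 0")
        if self.tau_s <= 0:
            raise ValueError("tau must be positive")
        if not (0 < self.cole_alpha <= 1):
            raise ValueError("cole_alpha must lie in (0, 1]")
        if self.noise_sd_low < 0 or self.noise_sd_high < 0:
            raise ValueError("noise SDs cannot be negative")
        if self.day_drift <= 0:
            raise ValueError("day_drift must be positive")


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort sizes, effect placement and calibrated effect sizes."""

    n_male: int = 8
    n_female: int = 8
    effect_band_hz: tuple[float, float] = (3.76e5, 2.79e6)
    effect_onset_day: int = 9
    mu_male: float = 1.122262
    sd_male: float = 0.112674
    mu_female: float = 0.953107
    sd_female: float = 0.124892
    baseline_ratio_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 0 or self.n_female < 0:
            raise ValueError("cohort sizes cannot be negative")
        if self.effect_band_hz[0] >= self.effect_band_hz[1]:
            raise ValueError("effect band must be (low, high) with low < high")
        if min(self.sd_male, self.sd_female, self.baseline_ratio_sd) <= 0:
            raise ValueError("dispersions must be positive")


def cole_magnitude(params: EggSimParams, f: float | np.ndarray) -> float | np.ndarray:
    """|Z(f)| of the Cole dispersion; accepts scalar or array frequency."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValueError("frequency must be positive")
    s = (1j * 2.0 * np.pi * f_arr * params.tau_s) ** params.cole_alpha
    z = params.r_inf_ohm + (params.r0_ohm - params.r_inf_ohm) / (1.0 + s)
    out = np.abs(z)
    return float(out) if np.isscalar(f) else out


def _noise_sd(params: EggSimParams, freqs: np.ndarray) -> np.ndarray:
    return np.where(freqs < params.noise_cutoff_hz, params.noise_sd_low, params.noise_sd_high)


def _truncate_ratio(r: float, egg_id: str) -> float:
    lo, hi = RATIO_TRUNCATION
    if r < lo or r > hi:
        logger.warning("egg %s: ratio draw %.4f truncated to [%g, %g]", egg_id, r, lo, hi)
        return min(max(r, lo), hi)
    return r


def simulate_egg(
    params: EggSimParams,
    ratio_targets: np.ndarray,
    grid: FrequencyGrid,
    rng: np.random.Generator,
    egg_id: str = "egg",
    days: Sequence[int] = tuple(range(1, 14)),
    include_pair_12: bool = False,
) -> list[SpectrumRecord]:
    """Sweeps for pairs 2-4 and 2-3 (optionally 1-2) of one egg.

    ``ratio_targets`` has shape (len(days), len(grid)); the 2-4 trace is
    the Cole curve times gain, drift and noise, and the 2-3 trace is the
    same base curve times the ratio target (with its own noise), so the
    noise-free 2-3/2-4 ratio equals ``ratio_targets`` exactly.
    """
    targets = np.asarray(ratio_targets, dtype=float)
    if targets.shape != (len(days), len(grid)):
        raise ValueError(
            f"ratio_targets shape {targets.shape} != (n_days={len(days)}, n_freq={len(grid)})"
        )
    freqs = grid.as_array()
    sd = _noise_sd(params, freqs)
    cole = cole_magnitude(params, freqs)
    p23, p24, p12 = ElectrodePair(2, 3), ElectrodePair(2, 4), ElectrodePair(1, 2)
    records: list[SpectrumRecord] = []
    for di, day in enumerate(days):
        base = cole * params.pair_gain.get(p24, 1.0) * params.day_drift**day
        z23 = base * targets[di] * np.exp(rng.normal(0.0, sd))
        z24 = base * np.exp(rng.normal(0.0, sd))
        records.append(SpectrumRecord(egg_id, day, p23, grid, z23))
        records.append(SpectrumRecord(egg_id, day, p24, grid, z24))
        if include_pair_12:
            z12 = (
                cole
                * params.pair_gain.get(p12, 1.0)
                * params.day_drift**day
                * np.exp(rng.normal(0.0, sd))
            )
            records.append(SpectrumRecord(egg_id, day, p12, grid, z12))
    return records


def _egg_ratio_targets(
    cfg: CohortSimConfig,
    sex: Sex,
    grid: FrequencyGrid,
    days: Sequence[int],
    rng: np.random.Generator,
    egg_id: str,
) -> np.ndarray:
    freqs = grid.as_array()
    in_band = (freqs >= cfg.effect_band_hz[0]) & (freqs <= cfg.effect_band_hz[1])
    mu, sd = (cfg.mu_male, cfg.sd_male) if sex is Sex.MALE else (cfg.mu_female, cfg.sd_female)
    # one effect draw per egg, applied from the onset day onward
    effect = _truncate_ratio(float(rng.normal(mu, sd)), egg_id)
    targets = np.empty((len(days), len(grid)))
    for di, day in enumerate(days):
        baseline = _truncate_ratio(float(rng.normal(1.0, cfg.baseline_ratio_sd)), egg_id)
        row = np.full(len(grid), baseline)
        if day >= cfg.effect_onset_day:
            row[in_band] = effect
        targets[di] = row
    return targets


def simulate_cohort(
    cfg: CohortSimConfig = CohortSimConfig(),
    params: EggSimParams = EggSimParams(),
    grid: FrequencyGrid | None = None,
    days: Sequence[int] = tuple(range(1, 14)),
    include_pair_12: bool = False,
) -> tuple[list[SpectrumRecord], list[SexLabel]]:
    """A full cohort of sweeps plus PCR-sourced ground-truth labels.

    Eggs are named M01..M<n>/F01..F<n>; each egg consumes its own
    deterministic PRNG substream, so the same seed always yields a
    bit-identical dataset.
    """
    grid = grid or make_default_grid()
    roster = [(f"M{i+1:02d}", Sex.MALE) for i in range(cfg.n_male)] + [
        (f"F{i+1:02d}", Sex.FEMALE) for i in range(cfg.n_female)
    ]
    sweeps: list[SpectrumRecord] = []
    labels: list[SexLabel] = []
    for k, (egg_id, sex) in enumerate(roster):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(k,)))
        targets = _egg_ratio_targets(cfg, sex, grid, days, rng, egg_id)
        sweeps.extend(
            simulate_egg(params, targets, grid, rng, egg_id, days, include_pair_12)
        )
        labels.append(SexLabel(egg_id, sex, LabelSource.PCR))
    return sweeps, labels
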