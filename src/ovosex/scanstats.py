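"""Day-by-frequency significance scan for the impedance ratio statistic.

For every incubation day and every grid frequency, the male and female
ratio values are compared with an independent two-sample t-test (Welch
by default; the pooled-variance variant is selectable). A cell is
significant when p < alpha. A frequency is a *persistent* discriminator
from day d if it is significant on every day from d through the final
incubation day — one transiently significant day is not evidence, since
hundreds of cells are tested at alpha = 0.05. The scan reports the
earliest such onset day, the contiguous frequency band persisting from
it, and the frequency with the smallest p at onset.

No multiplicity correction is applied by default: the persistence rule
is the guard against isolated false positives. A Bonferroni option
exists for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .spectra_io import RatioSpectrum, Sex, SexLabel

__all__ = [
    "GroupSummary",
    "TTestResult",
    "ScanConfig",
    "ScanResult",
    "group_summaries",
    "t_test_raw",
    "t_test_summary",
    "persistence_onset",
    "scan",
]

_P_FLOOR = 5e-324  # smallest subnormal: keeps p in (0, 1] even for infinite t


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / sample SD of the ratio for one (day, frequency, sex) cell."""

    day: int
    frequency_hz: float
    group: Sex
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.group not in (Sex.MALE, Sex.FEMALE):
            raise ValueError("group summaries exist only for male/female")
        if self.n < 2:
            raise ValueError("group summary requires n >= 2")
        if self.sd < 0 or self.mean <= 0:
            raise ValueError("invalid summary statistics")


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_value: float
    tails: int = 2
    variant: str = "welch"

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.variant not in ("welch", "pooled"):
            raise ValueError("variant must be 'welch' or 'pooled'")


@dataclass(frozen=True)
class ScanConfig:
    alpha: float = 0.05
    variant: str = "welch"
    tails: int = 2
    final_day: int = 13
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.variant not in ("welch", "pooled"):
            raise ValueError("variant must be 'welch' or 'pooled'")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


@dataclass(frozen=True)
class ScanResult:
    """Outcome of the day-by-frequency scan.

    ``p_matrix`` is day-major with shape (n_days, n_frequencies);
    ``days`` and ``frequencies_hz`` label its axes. ``band_hz``,
    ``onset_day`` and ``best_frequency_hz`` are None when no cell
    satisfies the persistence rule.
    """

    days: tuple[int, ...]
    frequencies_hz: tuple[float, ...]
    p_matrix: np.ndarray
    alpha: float
    sig_mask: np.ndarray
    onset_day: int | None
    band_hz: tuple[float, float] | None
    best_frequency_hz: float | None

    @property
    def found(self) -> bool:
        return self.onset_day is not None


def _summary_stats(x: np.ndarray) -> tuple[float, float, int]:
    return float(np.mean(x)), float(np.std(x, ddof=1)), len(x)


def group_summaries(
    ratios: Iterable[RatioSpectrum],
    labels: Iterable[SexLabel],
) -> list[GroupSummary]:
    """Per (day, frequency, sex): n, mean, sample SD of the ratio.

    Every egg appearing in ``ratios`` must carry a male or female label;
    unlabeled eggs raise, listing the offending ids. Unfertilized or
    unknown eggs must be excluded upstream.
    """
    sex_by_egg = {lab.egg_id: lab.sex for lab in labels}
    ratios = list(ratios)
    unlabeled = sorted(
        {
            r.egg_id
            for r in ratios
            if sex_by_egg.get(r.egg_id) not in (Sex.MALE, Sex.FEMALE)
        }
    )
    if unlabeled:
        raise ValueError(f"eggs without a male/female label: {unlabeled}")

    cells: dict[tuple[int, float, Sex], list[float]] = {}
    for r in ratios:
        sex = sex_by_egg[r.egg_id]
        for i, f in enumerate(r.grid.points):
            cells.setdefault((r.day, f, sex), []).append(float(r.ratio[i]))
    out = []
    for (day, f, sex), vals in sorted(cells.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)):
        arr = np.asarray(vals)
        mean, sd, n = _summary_stats(arr)
        out.append(GroupSummary(day=day, frequency_hz=f, group=sex, n=n, mean=mean, sd=sd))
    return out


def t_test_summary(
    m1: float,
    s1: float,
    n1: int,
    m2: float,
    s2: float,
    n2: int,
    cfg: ScanConfig = ScanConfig(),
) -> TTestResult:
    """Independent two-sample t-test from group summary statistics.

    Welch: t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), with
    Welch-Satterthwaite degrees of freedom. Pooled: classical
    equal-variance t with df = n1 + n2 - 2. One-tailed p is half the
    two-tailed p for the same |t|.

    Degenerate input (both groups zero-variance with equal means)
    returns p = 1 with a warning rather than failing.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations cannot be negative")
    v1, v2 = s1 * s1, s2 * s2
    if v1 == 0 and v2 == 0:
        warnings.warn(
            "both groups have zero variance; t-test is degenerate", RuntimeWarning
        )
        df = float(n1 + n2 - 2)
        if m1 == m2:
            return TTestResult(0.0, df, 1.0, cfg.tails, cfg.variant)
        t = np.inf if m1 > m2 else -np.inf
        return TTestResult(float(t), df, _P_FLOOR, cfg.tails, cfg.variant)

    if cfg.variant == "welch":
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2 * se2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)

    p_two = 2.0 * stats.t.sf(abs(t), df)
    p = p_two / 2.0 if cfg.tails == 1 else p_two
    p = min(max(p, _P_FLOOR), 1.0)
    return TTestResult(float(t), float(df), float(p), cfg.tails, cfg.variant)


def t_test_raw(
    x: Sequence[float],
    y: Sequence[float],
    cfg: ScanConfig = ScanConfig(),
) -> TTestResult:
    """Independent two-sample t-test from raw values (see t_test_summary)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        warnings.warn(
            "both groups have zero variance; t-test is degenerate", RuntimeWarning
        )
        df = float(len(x) + len(y) - 2)
        if x[0] == y[0]:
            return TTestResult(0.0, df, 1.0, cfg.tails, cfg.variant)
        t = np.inf if x[0] > y[0] else -np.inf
        return TTestResult(float(t), df, _P_FLOOR, cfg.tails, cfg.variant)
    res = stats.ttest_ind(x, y, equal_var=(cfg.variant == "pooled"))
    p = res.pvalue / 2.0 if cfg.tails == 1 else res.pvalue
    p = min(max(float(p), _P_FLOOR), 1.0)
    return TTestResult(float(res.statistic), float(res.df), p, cfg.tails, cfg.variant)


def persistence_onset(
    p_by_day: Mapping[int, float] | Sequence[float],
    alpha: float = 0.05,
    days: Sequence[int] | None = None,
) -> int | None:
    """Earliest day from which p < alpha holds through the final day.

    ``p_by_day`` is a mapping day -> p, or a sequence of p-values with
    ``days`` giving the corresponding (contiguous) day numbers
    (defaulting to 1..len). Returns None when the final day itself is
    not significant.
    """
    if isinstance(p_by_day, Mapping):
        if days is not None:
            raise ValueError("pass days only with a sequence of p-values")
        items = sorted(p_by_day.items())
        day_list = [d for d, _ in items]
        p_list = [p for _, p in items]
    else:
        p_list = list(p_by_day)
        day_list = list(days) if days is not None else list(range(1, len(p_list) + 1))
        if len(day_list) != len(p_list):
            raise ValueError("days and p-values must have equal length")
    if not p_list:
        raise ValueError("empty p-value input")
    if any(b - a != 1 for a, b in zip(day_list, day_list[1:])):
        raise ValueError("days must be contiguous")

    onset: int | None = None
    for day, p in zip(reversed(day_list), reversed(p_list)):
        if p < alpha:
            onset = day
        else:
            break
    return onset


def _ratio_tensor(
    ratios: Sequence[RatioSpectrum],
    labels: Iterable[SexLabel],
    final_day: int,
) -> tuple[list[int], np.ndarray, np.ndarray, np.ndarray]:
    """Stack ratio spectra into (egg, day, frequency) arrays per group."""
    sex_by_egg = {lab.egg_id: lab.sex for lab in labels}
    unlabeled = sorted(
        {
            r.egg_id
            for r in ratios
            if sex_by_egg.get(r.egg_id) not in (Sex.MALE, Sex.FEMALE)
        }
    )
    if unlabeled:
        raise ValueError(f"eggs without a male/female label: {unlabeled}")
    grid = ratios[0].grid
    for r in ratios:
        if r.grid.points != grid.points:
            raise ValueError("all ratio spectra must share one frequency grid")
    days = sorted({r.day for r in ratios if r.day <= final_day})
    day_index = {d: i for i, d in enumerate(days)}
    eggs = {s: sorted({r.egg_id for r in ratios if sex_by_egg[r.egg_id] == s}) for s in (Sex.MALE, Sex.FEMALE)}
    out = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        egg_index = {e: i for i, e in enumerate(eggs[sex])}
        arr = np.full((len(eggs[sex]), len(days), len(grid)), np.nan)
        for r in ratios:
            if sex_by_egg[r.egg_id] == sex and r.day in day_index:
                arr[egg_index[r.egg_id], day_index[r.day], :] = r.ratio
        out[sex] = arr
    return days, grid.as_array(), out[Sex.MALE], out[Sex.FEMALE]


def scan(
    ratios: Sequence[RatioSpectrum],
    labels: Iterable[SexLabel],
    cfg: ScanConfig = ScanConfig(),
) -> ScanResult:
    """Fill the day-by-frequency p-value matrix and apply persistence.

    Per cell: independent t-test of male vs female ratio values
    (missing (egg, day) entries are dropped cell-wise). Onset day is
    the smallest day d such that some frequency is significant on every
    day from d to cfg.final_day; the band is the longest contiguous run
    of frequencies persisting from that onset (ties break toward lower
    frequency); best frequency minimizes p on the onset day within the
    band (ties to the lower frequency).
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("no ratio spectra supplied")
    days, freqs, male, female = _ratio_tensor(ratios, labels, cfg.final_day)
    n_days, n_freq = len(days), len(freqs)
    alpha = cfg.alpha / (n_days * n_freq) if cfg.bonferroni else cfg.alpha

    p_matrix = np.ones((n_days, n_freq))
    for di in range(n_days):
        xm = male[:, di, :]
        xf = female[:, di, :]
        xm_ok = xm[~np.isnan(xm[:, 0])]
        xf_ok = xf[~np.isnan(xf[:, 0])]
        if len(xm_ok) < 2 or len(xf_ok) < 2:
            raise ValueError(f"day {days[di]}: need >= 2 eggs per group")
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(xm_ok, xf_ok, axis=0, equal_var=(cfg.variant == "pooled"))
            p = np.asarray(res.pvalue)
        degenerate = (np.ptp(xm_ok, axis=0) == 0) & (np.ptp(xf_ok, axis=0) == 0)
        if degenerate.any():
            warnings.warn(
                f"day {days[di]}: zero-variance cells at "
                f"{int(degenerate.sum())} frequencies; p set to 1",
                RuntimeWarning,
            )
            p = np.where(degenerate, 1.0, p)
        if cfg.tails == 1:
            p = p / 2.0
        p_matrix[di] = np.clip(np.nan_to_num(p, nan=1.0), _P_FLOOR, 1.0)

    sig = p_matrix < alpha

    # per-frequency onset: last run of significant days ending at final_day
    onset_per_freq = np.full(n_freq, -1)
    run = np.zeros(n_freq, dtype=int)
    for di in range(n_days - 1, -1, -1):
        run = np.where(sig[di], run + 1, 0)
        onset_per_freq = np.where(run == n_days - di, days[di], onset_per_freq)
    has_onset = onset_per_freq > 0

    if not has_onset.any():
        return ScanResult(
            days=tuple(days),
            frequencies_hz=tuple(freqs),
            p_matrix=p_matrix,
            alpha=alpha,
            sig_mask=sig,
            onset_day=None,
            band_hz=None,
            best_frequency_hz=None,
        )

    onset_day = int(onset_per_freq[has_onset].min())
    qualifies = has_onset & (onset_per_freq <= onset_day)

    # longest contiguous run of qualifying frequencies; ties -> lower freq
    best_run: tuple[int, int] | None = None
    start = None
    for i in range(n_freq + 1):
        if i < n_freq and qualifies[i]:
            if start is None:
                start = i
        elif start is not None:
            if best_run is None or (i - start) > (best_run[1] - best_run[0] + 1):
                best_run = (start, i - 1)
            start = None
    assert best_run is not None
    lo, hi = best_run
    onset_row = p_matrix[days.index(onset_day)]
    best_idx = lo + int(np.argmin(onset_row[lo : hi + 1]))
    return ScanResult(
        days=tuple(days),
        frequencies_hz=tuple(freqs),
        p_matrix=p_matrix,
        alpha=alpha,
        sig_mask=sig,
        onset_day=onset_day,
        band_hz=(float(freqs[lo]), float(freqs[hi])),
        best_frequency_hz=float(freqs[best_idx]),
    )
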