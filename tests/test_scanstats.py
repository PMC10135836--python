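"""Group summaries, t-tests, and the day-by-frequency persistence scan."""

import math

import numpy as np
import pytest
from scipy import integrate

from ovosex.reference import REFERENCE_DAY_STATS, reference_p_by_day
from ovosex.scanstats import (
    ScanConfig,
    group_summaries,
    persistence_onset,
    scan,
    t_test_raw,
    t_test_summary,
)
from ovosex.spectra_io import ElectrodePair, LabelSource, RatioSpectrum, Sex, SexLabel


def _t_sf_by_quadrature(t_val: float, df: float) -> float:
    """Upper-tail t probability by numerical integration of the density.

    Density written from the gamma-function form, independent of
    scipy.stats.t.
    """

    def pdf(u):
        c = math.exp(
            math.lgamma((df + 1) / 2) - math.lgamma(df / 2) - 0.5 * math.log(df * math.pi)
        )
        return c * (1 + u * u / df) ** (-(df + 1) / 2)

    val, _ = integrate.quad(pdf, t_val, np.inf)
    return val


class TestTTest:
    def test_identical_groups_give_t0_p1(self):
        x = [1.0, 1.1, 0.9, 1.05]
        res = t_test_raw(x, x)
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_zero_variance_warns_p1(self):
        with pytest.warns(RuntimeWarning):
            res = t_test_raw([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0
        with pytest.warns(RuntimeWarning):
            res2 = t_test_summary(1.0, 0.0, 4, 1.0, 0.0, 4)
        assert res2.p_value == 1.0

    @pytest.mark.parametrize(
        "day, expected_p",
        [(10, 0.012572), (5, 0.444311), (12, 0.030923), (13, 0.016027)],
        ids=lambda v: str(v),
    )
    def test_published_day_summaries_welch(self, day, expected_p):
        """Welch two-tailed p from the published group summaries (n=8+8)."""
        row = REFERENCE_DAY_STATS[day - 1]
        res = t_test_summary(row.male_mean, row.male_sd, 8, row.female_mean, row.female_sd, 8)
        assert res.p_value == pytest.approx(expected_p, abs=1e-6)
        # and within the rounding slack of the published value
        assert res.p_value == pytest.approx(row.p_published, rel=0.20)

    def test_summary_equals_raw_on_random_samples(self, rng):
        cfg_w, cfg_p = ScanConfig(variant="welch"), ScanConfig(variant="pooled")
        for _ in range(200):
            nx, ny = rng.integers(2, 12, size=2)
            x = rng.normal(0, 1, nx)
            y = rng.normal(0.3, 1.5, ny)
            for cfg in (cfg_w, cfg_p):
                a = t_test_raw(x, y, cfg)
                b = t_test_summary(
                    x.mean(), x.std(ddof=1), nx, y.mean(), y.std(ddof=1), ny, cfg
                )
                assert a.t_stat == pytest.approx(b.t_stat, abs=1e-12)
                assert a.df == pytest.approx(b.df, abs=1e-12)
                assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_p_matches_quadrature_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(0, 1, int(rng.integers(3, 10)))
            y = rng.normal(0.5, 2, int(rng.integers(3, 10)))
            res = t_test_raw(x, y)
            oracle = 2.0 * _t_sf_by_quadrature(abs(res.t_stat), res.df)
            assert res.p_value == pytest.approx(oracle, abs=1e-6)

    def test_one_tail_is_half_of_two_tail(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        p2 = t_test_raw(x, y, ScanConfig(tails=2)).p_value
        p1 = t_test_raw(x, y, ScanConfig(tails=1)).p_value
        assert p1 == pytest.approx(p2 / 2, rel=1e-12)

    def test_pooled_df_is_integer_welch_fractional(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0, 3, 8)
        assert t_test_raw(x, y, ScanConfig(variant="pooled")).df == 14.0
        welch_df = t_test_raw(x, y, ScanConfig(variant="welch")).df
        assert 7 < welch_df < 14

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            t_test_raw([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            t_test_summary(1.0, 0.1, 1, 1.0, 0.1, 8)


class TestPersistenceOnset:
    def test_interrupted_significance_restarts(self):
        # day 1 significant but not continuous through the final day
        assert persistence_onset([0.04, 0.2, 0.03, 0.01]) == 3

    def test_no_persistence_when_final_day_not_significant(self):
        assert persistence_onset([0.01, 0.01, 0.2]) is None
        assert persistence_onset([0.5, 0.6, 0.7]) is None

    def test_published_p_column_onsets_at_day_9(self):
        assert persistence_onset(reference_p_by_day()) == 9

    def test_all_significant_onsets_at_first_day(self):
        assert persistence_onset([0.01] * 5, days=range(3, 8)) == 3

    def test_empty_and_noncontiguous_rejected(self):
        with pytest.raises(ValueError):
            persistence_onset([])
        with pytest.raises(ValueError):
            persistence_onset([0.01, 0.01], days=[1, 3])


def _ratio(grid, egg, day, values):
    return RatioSpectrum(
        egg, day, ElectrodePair(2, 3), ElectrodePair(2, 4), grid,
        np.asarray(values, dtype=float),
    )


def _labels(eggs_by_sex):
    return [
        SexLabel(e, sex, LabelSource.PCR) for sex, eggs in eggs_by_sex.items() for e in eggs
    ]


class TestGroupSummaries:
    def test_identical_values_give_zero_sd(self, grid):
        ratios = [_ratio(grid, f"m{i}", 1, np.full(100, 1.3)) for i in range(3)]
        labels = _labels({Sex.MALE: [f"m{i}" for i in range(3)]})
        out = group_summaries(ratios, labels)
        assert all(s.sd == 0.0 and s.mean == pytest.approx(1.3) for s in out)

    def test_hand_arithmetic_two_values(self, grid):
        ratios = [
            _ratio(grid, "m0", 1, np.full(100, 1.0)),
            _ratio(grid, "m1", 1, np.full(100, 1.2)),
        ]
        out = group_summaries(ratios, _labels({Sex.MALE: ["m0", "m1"]}))
        s = out[0]
        assert (s.n, s.mean) == (2, pytest.approx(1.1))
        assert s.sd == pytest.approx(0.1414213562, rel=1e-9)

    def test_unlabeled_egg_raises_with_ids(self, grid):
        ratios = [_ratio(grid, "mystery", 1, np.ones(100))]
        with pytest.raises(ValueError, match="mystery"):
            group_summaries(ratios, [])


def _planted_cohort(grid, n=4, days=range(1, 6), onset=3, band=(1e5, 1e6), jitter=0.01):
    """Strong, deterministic effect: male 1.5, female 0.7 in-band from onset."""
    freqs = grid.as_array()
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    ratios, labels = [], []
    for sex, base in ((Sex.MALE, 1.5), (Sex.FEMALE, 0.7)):
        for i in range(n):
            egg = f"{sex.value}{i}"
            labels.append(SexLabel(egg, sex, LabelSource.PCR))
            for d in days:
                row = np.full(len(grid), 1.0 + jitter * i)
                if d >= onset:
                    row[in_band] = base + jitter * i
                ratios.append(_ratio(grid, egg, d, row))
    return ratios, labels


class TestScan:
    def test_recovers_planted_band_and_onset(self, grid):
        ratios, labels = _planted_cohort(grid)
        res = scan(ratios, labels, ScanConfig(final_day=5))
        assert res.onset_day == 3
        freqs = grid.as_array()
        lo, hi = res.band_hz
        in_band = (freqs >= 1e5) & (freqs <= 1e6)
        assert lo == freqs[in_band][0] and hi == freqs[in_band][-1]
        assert lo <= res.best_frequency_hz <= hi

    def test_all_significant_gives_full_grid_band_from_day_one(self, grid):
        ratios, labels = _planted_cohort(grid, onset=1, band=(20, 1e7))
        res = scan(ratios, labels, ScanConfig(final_day=5))
        assert res.onset_day == 1
        assert res.band_hz == (grid[0], grid[99])

    def test_no_effect_reports_no_persistent_discriminator(self, grid):
        ratios, labels = _planted_cohort(grid, onset=99)  # never fires
        res = scan(ratios, labels, ScanConfig(final_day=5))
        assert not res.found
        assert res.onset_day is None and res.band_hz is None and res.best_frequency_hz is None

    def test_invariant_to_egg_and_ratio_ordering(self, grid, rng):
        ratios, labels = _planted_cohort(grid)
        res1 = scan(ratios, labels, ScanConfig(final_day=5))
        shuffled = list(ratios)
        rng.shuffle(shuffled)
        res2 = scan(shuffled, list(reversed(labels)), ScanConfig(final_day=5))
        assert np.array_equal(res1.p_matrix, res2.p_matrix)
        assert res1.onset_day == res2.onset_day and res1.band_hz == res2.band_hz

    def test_sig_mask_matches_p_matrix(self, grid):
        ratios, labels = _planted_cohort(grid)
        res = scan(ratios, labels, ScanConfig(final_day=5))
        assert np.array_equal(res.sig_mask, res.p_matrix < res.alpha)

    def test_null_rejection_rate_near_alpha(self, grid):
        """Without a sex effect ~5% of independent day cells reject at alpha=0.05."""
        rng = np.random.default_rng(555)
        flags = []
        for _ in range(40):
            ratios, labels = [], []
            for sex in (Sex.MALE, Sex.FEMALE):
                for i in range(8):
                    egg = f"{sex.value}{i}"
                    labels.append(SexLabel(egg, sex, LabelSource.PCR))
                    for d in range(1, 14):
                        ratios.append(
                            _ratio(grid, egg, d, np.full(100, rng.normal(1.0, 0.12)))
                        )
            res = scan(ratios, labels)
            flags.extend(res.sig_mask[:, 0].tolist())  # one frequency: independent cells
        rate = np.mean(flags)
        se = math.sqrt(0.05 * 0.95 / len(flags))
        assert abs(rate - 0.05) < 3 * se
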