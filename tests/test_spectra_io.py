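"""Grid construction, pair canonicalization, and CSV round-trips."""

import numpy as np
import pytest

from ovosex.spectra_io import (
    ElectrodePair,
    FrequencyGrid,
    LabelSource,
    Sex,
    SexLabel,
    SpectrumRecord,
    SweepConfig,
    make_default_grid,
    nearest_grid_frequency,
    read_labels,
    read_sweeps,
    write_labels,
    write_sweeps,
)


class TestDefaultGrid:
    def test_spans_analyzer_range_with_100_points(self, grid):
        assert len(grid) == 100
        assert grid[0] == 20.0
        assert grid[99] == 1.0e7

    def test_strictly_increasing(self, grid):
        pts = grid.as_array()
        assert np.all(np.diff(pts) > 0)

    def test_log_spacing_closed_form(self, grid):
        # independent closed form: 20 * (1e7/20)^(k/99)
        assert grid[50] == pytest.approx(20.0 * (1e7 / 20.0) ** (50 / 99), rel=1e-12)

    def test_rejects_out_of_range_and_unsorted(self):
        with pytest.raises(ValueError):
            FrequencyGrid((10.0, 100.0))  # below 20 Hz
        with pytest.raises(ValueError):
            FrequencyGrid((100.0, 50.0))
        with pytest.raises(ValueError):
            FrequencyGrid(())

    def test_sweep_config_defaults(self):
        cfg = SweepConfig()
        assert cfg.excitation_mv == 100.0
        assert cfg.dwell_ms == 80.0
        assert len(cfg.grid) == 100


class TestNearestGridFrequency:
    @pytest.mark.parametrize(
        "target, want_idx",
        [(20.0, 0), (1.0e7, 99)],
    )
    def test_endpoints(self, grid, target, want_idx):
        idx, f = nearest_grid_frequency(grid, target)
        assert idx == want_idx and f == grid[want_idx]

    def test_matches_bruteforce_for_random_targets(self, grid, rng):
        pts = np.log10(grid.as_array())
        for target in 10 ** rng.uniform(np.log10(20), 7, size=1000):
            idx, _ = nearest_grid_frequency(grid, target)
            brute = int(np.argmin(np.abs(pts - np.log10(target))))
            assert idx == brute

    def test_376_khz_maps_to_log_nearest_point(self, grid):
        idx, f = nearest_grid_frequency(grid, 3.76e5)
        d = np.abs(np.log10(grid.as_array()) - np.log10(3.76e5))
        assert d[idx] == d.min()
        assert f == pytest.approx(3.638e5, rel=1e-3)

    def test_rejects_nonpositive_target(self, grid):
        with pytest.raises(ValueError):
            nearest_grid_frequency(grid, 0.0)


class TestElectrodePair:
    def test_canonicalizes_order(self):
        assert ElectrodePair(3, 2) == ElectrodePair(2, 3)
        assert str(ElectrodePair(4, 1)) == "1-4"
        assert ElectrodePair.parse("2-4") == ElectrodePair(2, 4)

    @pytest.mark.parametrize("a,b", [(0, 1), (1, 5), (2, 2)])
    def test_rejects_invalid_indices(self, a, b):
        with pytest.raises(ValueError):
            ElectrodePair(a, b)


def _random_records(grid, rng, n_eggs=2, days=(1, 2), pairs=("2-3", "2-4"), phase=False):
    records = []
    for e in range(n_eggs):
        for d in days:
            for p in pairs:
                records.append(
                    SpectrumRecord(
                        egg_id=f"egg{e}",
                        day=d,
                        pair=ElectrodePair.parse(p),
                        grid=grid,
                        z_mod=np.exp(rng.normal(5, 1, size=len(grid))),
                        phase_deg=rng.uniform(-90, 0, len(grid)) if phase else None,
                    )
                )
    return records


class TestSweepRoundTrip:
    @pytest.mark.parametrize("phase", [False, True])
    def test_write_then_read_is_bit_exact(self, grid, rng, tmp_path, phase):
        records = _random_records(grid, rng, phase=phase)
        path = tmp_path / "sweeps.csv"
        write_sweeps(records, path)
        back = read_sweeps(path)
        assert len(back) == len(records)
        orig = {r.key: r for r in records}
        for r in back:
            o = orig[r.key]
            assert np.array_equal(r.z_mod, o.z_mod)
            assert r.grid.points == o.grid.points
            if phase:
                assert np.array_equal(r.phase_deg, o.phase_deg)

    def test_counts(self, grid, rng, tmp_path):
        path = tmp_path / "sweeps.csv"
        write_sweeps(_random_records(grid, rng, n_eggs=2, days=(3,)), path)
        recs = read_sweeps(path)
        assert len(recs) == 4 and all(len(r.z_mod) == 100 for r in recs)

    def test_empty_collection_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_sweeps([], path)
        assert path.read_text().startswith("egg_id,")
        assert read_sweeps(path) == []

    def test_duplicate_frequency_row_rejected_with_context(self, grid, rng, tmp_path):
        path = tmp_path / "dup.csv"
        write_sweeps(_random_records(grid, rng, n_eggs=1, days=(1,), pairs=("2-3",)), path)
        lines = path.read_text().splitlines()
        lines.append(lines[5])  # replay one data row
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="egg0.*2-3|duplicate"):
            read_sweeps(path)

    def test_nonpositive_impedance_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "egg_id,day,pair,frequency_hz,z_mod_ohm,phase_deg\n"
            "e1,1,2-3,20.0,-5.0,\n"
        )
        with pytest.raises(ValueError, match="non-positive"):
            read_sweeps(path)

    def test_inconsistent_grids_rejected(self, grid, rng, tmp_path):
        r1 = _random_records(grid, rng, n_eggs=1, days=(1,), pairs=("2-3",))
        small = FrequencyGrid(tuple(grid.as_array()[:50]))
        r2 = [
            SpectrumRecord("eggZ", 1, ElectrodePair(2, 4), small, np.full(50, 7.0))
        ]
        path = tmp_path / "mix.csv"
        write_sweeps(r1 + r2, path)
        with pytest.raises(ValueError, match="grid"):
            read_sweeps(path)

    def test_supplied_grid_is_validated(self, grid, rng, tmp_path):
        path = tmp_path / "sweeps.csv"
        write_sweeps(_random_records(grid, rng), path)
        wrong = FrequencyGrid(tuple(np.geomspace(30, 1e6, 100)))
        with pytest.raises(ValueError, match="grid"):
            read_sweeps(path, grid=wrong)


class TestRecords:
    def test_length_mismatch_rejected_not_padded(self, grid):
        with pytest.raises(ValueError, match="grid length"):
            SpectrumRecord("e", 1, ElectrodePair(2, 3), grid, np.ones(99))

    def test_nonpositive_z_rejected(self, grid):
        z = np.ones(100)
        z[3] = 0.0
        with pytest.raises(ValueError):
            SpectrumRecord("e", 1, ElectrodePair(2, 3), grid, z)


class TestLabels:
    def test_round_trip(self, tmp_path):
        labels = [
            SexLabel("a", Sex.MALE, LabelSource.PCR),
            SexLabel("b", Sex.FEMALE, LabelSource.IMPEDANCE),
            SexLabel("c", Sex.UNFERTILIZED, LabelSource.PCR),
            SexLabel("d", Sex.UNKNOWN, LabelSource.IMPEDANCE),
        ]
        path = tmp_path / "labels.csv"
        write_labels(labels, path)
        assert read_labels(path) == labels

    def test_unfertilized_requires_pcr_source(self):
        with pytest.raises(ValueError):
            SexLabel("x", Sex.UNFERTILIZED, LabelSource.IMPEDANCE)
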