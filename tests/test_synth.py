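"""Ground-truth recovery and determinism of the synthetic generators."""

import numpy as np
import pytest

import paleotrail as pt
from paleotrail.exceptions import (
    ConfigurationError,
    GenerationError,
    TaxonLookupError,
)


class TestMakeClimate:
    def test_no_cycle_no_noise_gives_time_constant_field(self):
        cfg = pt.ClimateConfig(cycle_amplitude_T=0.0, cycle_amplitude_P=0.0,
                               noise_sd=0.0, noise_sd_P=0.0)
        field = pt.make_climate(cfg)
        assert np.all(field.T == field.T[0])
        assert np.all(field.P == field.P[0])

    def test_zonal_mean_gradient_is_recovered_by_least_squares(self):
        cfg = pt.ClimateConfig(lat_gradient_T=-0.5, noise_sd=0.0,
                               noise_sd_P=0.0)
        field = pt.make_climate(cfg)
        zonal = field.T[0].mean(axis=1)  # one slice, mean over lon
        slope = np.polyfit(field.lat, zonal, 1)[0]
        assert slope == pytest.approx(-0.5, abs=1e-10)

    def test_default_window_has_121_slices(self, default_field):
        # 150 ka to 30 ka inclusive at 1,000-y steps
        assert default_field.time.size == 121
        assert default_field.time[0] == 150_000
        assert default_field.time[-1] == 30_000

    def test_default_grid_shape(self, default_field):
        assert default_field.shape == (121, 49, 63)

    def test_same_seed_is_byte_identical(self):
        a = pt.make_climate(pt.ClimateConfig(seed=11))
        b = pt.make_climate(pt.ClimateConfig(seed=11))
        assert np.array_equal(a.T, b.T) and np.array_equal(a.P, b.P)

    def test_non_positive_step_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            pt.ClimateConfig(lon_step=0.0)

    def test_time_axis_must_run_into_the_past(self):
        with pytest.raises(ConfigurationError):
            pt.ClimateConfig(time_start_ka=30, time_end_ka=150)

    def test_netcdf_round_trip(self, coarse_field, tmp_path):
        path = tmp_path / "climate.nc"
        coarse_field.to_netcdf(path)
        again = pt.ClimateField.from_netcdf(path)
        assert np.array_equal(again.T, coarse_field.T)
        assert np.array_equal(again.time, coarse_field.time)


@pytest.fixture(scope="module")
def truth():
    from paleotrail.experiments import RECOVERY_TRUTH

    return RECOVERY_TRUTH


class TestMakeOccurrences:
    def test_zero_per_box_gives_empty_table(self, default_field, truth, boxes):
        occ = pt.make_occurrences(default_field, truth, boxes, 0, 5000, seed=1)
        assert occ.empty

    def test_same_seed_gives_identical_tables(self, default_field, truth,
                                              boxes):
        a = pt.make_occurrences(default_field, truth, boxes, 5, 5000, seed=4)
        b = pt.make_occurrences(default_field, truth, boxes, 5, 5000, seed=4)
        assert a.equals(b)

    def test_true_climate_mean_approaches_truth(self, default_field, truth,
                                                boxes):
        # Monte Carlo check at n=500 (rows per box): sample mean of the
        # records' true climates within 3 standard errors of truth.mean
        occ = pt.make_occurrences(default_field, truth, boxes, 500, 5000,
                                  seed=9)
        for col, mu, var in [("true_T", truth.mean_T, truth.cov[0, 0]),
                             ("true_P", truth.mean_P, truth.cov[1, 1])]:
            se = np.sqrt(var / len(occ))
            assert abs(occ[col].mean() - mu) <= 3 * se

    def test_bounds_bracket_true_age(self, default_field, truth, boxes):
        occ = pt.make_occurrences(default_field, truth, boxes, 20, 6000,
                                  seed=2)
        assert (occ["min_age"] >= occ["true_age"]).all()
        assert (occ["max_age"] <= occ["true_age"]).all()
        assert ((occ["min_age"] - occ["max_age"]) <= 6000).all()

    def test_impossible_envelope_names_the_box(self, default_field, boxes):
        hot = pt.EnvelopeTruth(mean_T=80.0, mean_P=5000.0,
                               cov=np.array([[0.01, 0.0], [0.0, 0.01]]))
        with pytest.raises(GenerationError, match="Box 1"):
            pt.make_occurrences(default_field, hot, boxes, 5, 5000, seed=1)


class TestMakePeaklist:
    def test_dropout_e_no_jitter_gives_exact_masses(self, markers):
        peaks = pt.make_peaklist("Equus", markers, jitter_sd=0.0,
                                 dropout={"E"}, n_noise_peaks=0, seed=0)
        expected = sorted(mz for m, mz in markers["Equus"].items() if m != "E")
        assert np.allclose(peaks.mz, expected)

    def test_all_markers_dropped_no_noise_is_empty(self, markers):
        peaks = pt.make_peaklist("Equus", markers, dropout=set("ABCDEFG"),
                                 n_noise_peaks=0, seed=0)
        assert len(peaks) == 0

    def test_seeded_peaklist_is_reproducible(self, markers):
        a = pt.make_peaklist("Bovidae", markers, jitter_sd=0.05,
                             n_noise_peaks=8, seed=5)
        b = pt.make_peaklist("Bovidae", markers, jitter_sd=0.05,
                             n_noise_peaks=8, seed=5)
        assert np.array_equal(a.mz, b.mz)
        assert np.array_equal(a.intensity, b.intensity)

    def test_unknown_taxon_raises(self, markers):
        with pytest.raises(TaxonLookupError):
            pt.make_peaklist("Dinosauria", markers)


class TestMakeCalcurve:
    def test_zero_wiggle_is_identity(self):
        curve = pt.make_calcurve(1000, 2000, wiggle_amplitude=0.0)
        assert np.array_equal(curve.mu, curve.t)

    def test_seeded_curve_is_reproducible(self):
        a = pt.make_calcurve(1000, 9000, wiggle_amplitude=100, seed=6)
        b = pt.make_calcurve(1000, 9000, wiggle_amplitude=100, seed=6)
        assert np.array_equal(a.mu, b.mu)

    def test_invalid_range_rejected(self):
        with pytest.raises(ConfigurationError):
            pt.make_calcurve(5000, 1000)


class TestMakeAlignment:
    def test_no_diffs_no_masking_gives_identical_rows(self):
        aln, _ = pt.make_alignment(4, 200, [0, 0, 0], missing_frac=0, seed=1)
        assert all(row == aln.rows[0] for row in aln.rows)

    def test_planted_seven_diffs_recovered(self):
        aln, _ = pt.make_alignment(2, 300, {"B": 7}, missing_frac=0, seed=1)
        r = pt.pairwise_differences(aln, "ref", "B")
        assert (r.n_diff, r.n_comparable) == (7, 300)

    def test_full_masking_leaves_no_comparable_sites(self):
        aln, _ = pt.make_alignment(3, 100, [2, 3], missing_frac=1.0, seed=1)
        for other in aln.names[1:]:
            assert pt.pairwise_differences(aln, "ref", other).n_comparable == 0

    def test_infeasible_planted_diffs_rejected(self):
        with pytest.raises(GenerationError):
            pt.make_alignment(3, 10, [8, 8], seed=1)

    def test_cross_pair_diffs_are_sums_of_planted_counts(self):
        aln, planted = pt.make_alignment(4, 1000, [3, 7, 11],
                                         missing_frac=0, seed=3)
        names = list(planted)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                r = pt.pairwise_differences(aln, a, b)
                assert r.n_diff == planted[a] + planted[b]

    def test_same_seed_is_byte_identical(self):
        a, _ = pt.make_alignment(5, 400, [1, 2, 3, 4], missing_frac=0.1,
                                 seed=8)
        b, _ = pt.make_alignment(5, 400, [1, 2, 3, 4], missing_frac=0.1,
                                 seed=8)
        assert a.rows == b.rows
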