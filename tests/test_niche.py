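"""Climate extraction, balanced sampling, envelope fitting, suitability."""

import warnings

import numpy as np
import pandas as pd
import pytest

import paleotrail as pt
from paleotrail.exceptions import (
    GridDomainError,
    InsufficientSampleError,
    SamplingError,
)
from paleotrail.niche import RegionBox, normalize_lon


class TestLoadOccurrences:
    def test_printed_bounds_are_normalized_to_older_younger(self):
        with pytest.warns(UserWarning, match="min_age > max_age"):
            df = pt.load_occurrences(pt.datasets.starosele_occurrences())
        assert (df["older"] >= df["younger"]).all()
        d11 = df[df.specimen == "Denisova 11"].iloc[0]
        assert (d11.older, d11.younger) == (118_100, 79_300)

    def test_longitudes_are_wrapped(self):
        df = pt.datasets.starosele_occurrences()
        df.loc[0, "longitude"] = 350.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = pt.load_occurrences(df)
        assert out.loc[0, "longitude"] == pytest.approx(-10.0)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            pt.load_occurrences(pd.DataFrame({"specimen": ["x"]}))


class TestExtractClimate:
    def test_exact_cell_center_returns_that_cell(self, toy_field):
        T, P = pt.extract_climate(45.0, 90.0, 50_000.0, toy_field)
        # time index 1, lat index 1, lon index 1 -> flat index 7
        assert (T, P) == (7.0, 170.0)

    def test_dateline_wrap_picks_nearest_cell(self, toy_field):
        # 179.9 E is 90.1 degrees from +90 but only 90.1 from -90 via the
        # dateline; construct an asymmetric case instead: 170 E is 80 from
        # +90 and 100 from -90 going west, so nearest is +90
        T_a, _ = pt.extract_climate(45.0, 170.0, 50_000.0, toy_field)
        T_b, _ = pt.extract_climate(45.0, -170.0, 50_000.0, toy_field)
        assert T_a == 7.0  # lon +90 cell
        assert T_b == 6.0  # wraps to lon -90 cell

    def test_toy_grid_nearest_by_enumeration(self, toy_field):
        rng = np.random.default_rng(0)
        for _ in range(25):
            lat = rng.uniform(-60, 60)
            lon = rng.uniform(-180, 180)
            age = rng.uniform(50_000, 100_000)
            T, P = pt.extract_climate(lat, lon, age, toy_field)
            # brute-force nearest over all cells
            best, best_d = None, np.inf
            for it, t in enumerate(toy_field.time):
                for ilat, la in enumerate(toy_field.lat):
                    for ilon, lo in enumerate(toy_field.lon):
                        dlon = min(abs(lon - lo), 360 - abs(lon - lo))
                        d = (abs(lat - la) / 15.0) ** 2 + (dlon / 90.0) ** 2 \
                            + (abs(age - t) / 25_000.0) ** 2
                        if d < best_d - 1e-12:
                            best_d, best = d, (it, ilat, ilon)
            assert T == toy_field.T[best]

    def test_age_outside_span_is_clamped_with_warning(self, toy_field):
        with pytest.warns(UserWarning, match="clamped"):
            T, _ = pt.extract_climate(45.0, 90.0, 10_000.0, toy_field)
        assert T == 7.0  # nearest slice is 50 ka

    def test_point_far_outside_latitude_extent_raises(self, toy_field):
        field = pt.ClimateField(
            lon=toy_field.lon, lat=np.array([0.0, 15.0]),
            time=toy_field.time, T=toy_field.T, P=toy_field.P,
        )
        with pytest.raises(GridDomainError):
            pt.extract_climate(80.0, 0.0, 50_000.0, field)


class TestSampleEnsembleMember:
    def test_box_with_exactly_k_records_is_forced(self, records, boxes):
        # Box 2 holds exactly two records: both must always be selected
        for m in range(20):
            rng = np.random.default_rng(m)
            member = pt.sample_ensemble_member(records, boxes, 2, rng)
            box2 = member.records[member.records.location == "Box 2"]
            assert sorted(box2.specimen) == ["Mezmaiskaya 2", "Star 1"]

    def test_primary_config_gives_six_rows(self, records, boxes):
        member = pt.sample_ensemble_member(records, boxes, 2,
                                           np.random.default_rng(0))
        assert len(member.records) == 6
        assert (member.records.location.value_counts() == 2).all()

    def test_drawn_ages_are_uniform_within_bounds(self, records, boxes):
        ages = []
        row = records[records.specimen == "Star 1"].iloc[0]
        for m in range(1000):
            rng = np.random.default_rng(m)
            member = pt.sample_ensemble_member(records, boxes, 2, rng)
            star = member.records[member.records.specimen == "Star 1"].iloc[0]
            ages.append(star.drawn_age)
        ages = np.array(ages)
        assert (ages >= row.younger).all() and (ages <= row.older).all()
        midpoint = (row.older + row.younger) / 2
        width = row.older - row.younger
        se = width / np.sqrt(12 * len(ages))
        assert abs(ages.mean() - midpoint) <= 4 * se

    def test_underfilled_box_raises_naming_it(self, records, boxes):
        with pytest.raises(SamplingError, match="Box 2"):
            pt.sample_ensemble_member(records, boxes, 3,
                                      np.random.default_rng(0))


class TestFitEnvelope:
    def test_hand_computed_square(self):
        C = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        mean, inv_cov = pt.fit_envelope(C)
        assert np.allclose(mean, [1.0, 1.0])
        assert np.allclose(inv_cov, np.diag([3 / 4, 3 / 4]))  # Sigma=4/3 I

    def test_degenerate_identical_rows_are_regularized(self):
        C = np.ones((5, 2))
        with pytest.warns(UserWarning, match="regularized"):
            mean, inv_cov = pt.fit_envelope(C)
        assert np.all(np.isfinite(inv_cov))

    def test_large_sample_recovers_known_parameters(self):
        rng = np.random.default_rng(12)
        mu = np.array([-10.0, 400.0])
        cov = np.array([[9.0, 30.0], [30.0, 2500.0]])
        C = rng.multivariate_normal(mu, cov, size=10_000)
        mean, inv_cov = pt.fit_envelope(C)
        se = np.sqrt(np.diag(cov) / len(C))
        assert np.all(np.abs(mean - mu) <= 3 * se)
        assert np.allclose(np.linalg.inv(inv_cov), cov, rtol=0.1)

    def test_too_few_rows_raises(self):
        with pytest.raises(InsufficientSampleError):
            pt.fit_envelope(np.zeros((2, 2)))


class TestSuitabilityMap:
    def test_suitability_is_one_at_the_envelope_mean(self, toy_field):
        mean = np.array([toy_field.T[0, 0, 0], toy_field.P[0, 0, 0]])
        s = pt.suitability_map((mean, np.eye(2)), toy_field)
        assert s[0, 0, 0] == 1.0
        # s is in (0, 1] mathematically; exp underflows to 0.0 for cells
        # thousands of Mahalanobis units away
        assert s.max() <= 1.0 and s.min() >= 0.0

    def test_closed_form_value(self):
        field = pt.ClimateField(
            lon=np.array([0.0]), lat=np.array([0.0]),
            time=np.array([50_000.0]),
            T=np.array([[[1.0]]]), P=np.array([[[1.0]]]),
        )
        s = pt.suitability_map((np.zeros(2), np.eye(2)), field)
        assert s[0, 0, 0] == pytest.approx(np.exp(-2.0))

    def test_root_mode_takes_square_root(self):
        field = pt.ClimateField(
            lon=np.array([0.0]), lat=np.array([0.0]),
            time=np.array([50_000.0]),
            T=np.array([[[3.0]]]), P=np.array([[[4.0]]]),
        )
        s = pt.suitability_map((np.zeros(2), np.eye(2)), field,
                               distance_mode="root")
        assert s[0, 0, 0] == pytest.approx(np.exp(-5.0))

    def test_identity_inverse_covariance_matches_euclidean_oracle(self):
        from paleotrail.experiments import mahalanobis_identity_check

        assert mahalanobis_identity_check(n_cells=1000, seed=0) <= 1e-10

    def test_affine_invariance(self):
        from paleotrail.experiments import affine_invariance_check

        assert affine_invariance_check(n_transforms=20, seed=0) <= 1e-10

    def test_non_finite_climate_flagged_as_missing(self, toy_field):
        T = toy_field.T.copy()
        T[0, 0, 0] = np.nan
        field = pt.ClimateField(lon=toy_field.lon, lat=toy_field.lat,
                                time=toy_field.time, T=T, P=toy_field.P)
        with pytest.warns(UserWarning, match="non-finite"):
            s = pt.suitability_map((np.zeros(2), np.eye(2)), field)
        assert np.isnan(s[0, 0, 0])
        assert np.isfinite(s[1:]).all()


class TestRunMonteCarlo:
    def test_same_seed_twice_is_identical(self, records, boxes, coarse_field):
        kw = dict(k_per_box=2, field=coarse_field, n_members=5, seed=21)
        a = pt.run_monte_carlo(records, boxes, **kw)
        b = pt.run_monte_carlo(records, boxes, **kw)
        assert np.array_equal(a.mean_grid, b.mean_grid)
        for label in a.box_series:
            assert np.array_equal(a.box_series[label].members,
                                  b.box_series[label].members)

    def test_member_count_and_balance(self, records, boxes, coarse_field):
        ens = pt.run_monte_carlo(records, boxes, 2, coarse_field,
                                 n_members=30, seed=3, store_members=True)
        assert ens.n_members == 30
        assert len(ens.member_grids) == 30
        for member in ens.members_meta:
            assert (member.records.location.value_counts() == 2).all()

    def test_average_grid_is_arithmetic_mean_of_members(self, records, boxes,
                                                        coarse_field):
        ens = pt.run_monte_carlo(records, boxes, 2, coarse_field,
                                 n_members=10, seed=5, store_members=True)
        stacked = np.stack(ens.member_grids)
        assert np.allclose(ens.mean_grid, stacked.mean(axis=0))


class TestBoxTimeseries:
    def test_uniform_suitability_gives_constant_series(self, boxes,
                                                       coarse_field):
        field = coarse_field
        ens = pt.SuitabilityEnsemble(
            field=field, mean_grid=np.full(field.shape, 0.4),
            box_series={}, n_members=1, seed=0, distance_mode="quadratic",
        )
        series = pt.box_timeseries(ens, boxes["Box 1"])
        assert np.allclose(series.mean, 0.4)

    def test_two_cell_box_hand_mean(self, toy_field):
        grid = np.zeros(toy_field.shape)
        grid[:, 1, 0] = 0.2  # (lat 45, lon -90)
        grid[:, 1, 1] = 0.6  # (lat 45, lon 90)
        ens = pt.SuitabilityEnsemble(
            field=toy_field, mean_grid=grid, box_series={}, n_members=1,
            seed=0, distance_mode="quadratic",
        )
        box = RegionBox("both", -120.0, 120.0, 30.0, 60.0)
        series = pt.box_timeseries(ens, box)
        assert np.allclose(series.mean, 0.4)

    def test_mean_series_is_mean_of_member_series(self, records, boxes,
                                                  coarse_field):
        ens = pt.run_monte_carlo(records, boxes, 2, coarse_field,
                                 n_members=8, seed=9)
        for label, bs in ens.box_series.items():
            assert np.allclose(bs.mean, bs.members.mean(axis=0))

    def test_empty_box_raises(self, toy_field):
        ens = pt.SuitabilityEnsemble(
            field=toy_field, mean_grid=np.ones(toy_field.shape),
            box_series={}, n_members=1, seed=0, distance_mode="quadratic",
        )
        with pytest.raises(GridDomainError):
            pt.box_timeseries(ens, RegionBox("tiny", 0.0, 1.0, 0.0, 1.0))


class TestRegionBox:
    def test_normalize_lon_range(self):
        assert normalize_lon(350.0) == pytest.approx(-10.0)
        assert normalize_lon(-180.0) == -180.0
        assert normalize_lon(180.0) == -180.0

    def test_box_ending_at_180_contains_its_cells(self):
        box = RegionBox("east", 170.0, 180.0, 0.0, 10.0)
        assert box.contains(5.0, 175.0)
        assert not box.contains(5.0, 165.0)

    def test_dateline_straddling_box(self):
        box = RegionBox("pacific", 170.0, -170.0 + 360.0, 0.0, 10.0)
        assert box.contains(5.0, 175.0)
        assert box.contains(5.0, -175.0)
        assert not box.contains(5.0, 0.0)


def test_interglacial_signal_in_box_series(boxes):
    """Samples taken in warm phases make suitability peak in warm phases."""
    field = pt.make_climate(pt.ClimateConfig(noise_sd=0.2))
    warm_truth = pt.EnvelopeTruth(
        mean_T=-9.0, mean_P=560.0,
        cov=np.array([[4.0, 0.0], [0.0, 3600.0]]),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        occ = pt.make_occurrences(field, warm_truth, boxes, n_per_box=10,
                                  age_uncertainty=2000.0, seed=17)
        records = pt.load_occurrences(occ)
        ens = pt.run_monte_carlo(records, boxes, 2, field, n_members=50,
                                 seed=17)
    phase = np.cos(2 * np.pi * (field.time - 125_000.0) / 100_000.0)
    for label, bs in ens.box_series.items():
        peak_phase = phase[int(np.argmax(bs.mean))]
        assert peak_phase > 0, f"{label} peaks outside the warm phase"
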