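import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquacarb import (
    ECOSYSTEM_CATEGORIES,
    RateMeasurement,
    default_config,
    generate_dataset,
    group_by,
    read_dataset,
    write_measurements,
    write_results,
)
from aquacarb.data_io import EmptyGroupingError, SchemaError, read_summary


def _row(rate=10.0, eco="lake", **extra):
    row = {"study_id": "s1", "site_id": "x", "rate": rate, "ecosystem_raw": eco}
    row.update(extra)
    return row


class TestReadDataset:
    def test_raw_names_mapped_through_config(self, write_csv):
        path = write_csv([_row(eco="fjord"), _row(eco="fjord"), _row(eco="fjord")])
        ms, report = read_dataset(path, {"fjord": "continental_shelf"})
        assert report.n_accepted == 3
        assert all(m.ecosystem_category == "continental_shelf" for m in ms)

    def test_non_positive_rate_rejected(self, write_csv):
        path = write_csv([_row(rate=-5), _row(rate=10.0)])
        ms, report = read_dataset(path, {"lake": "lake"})
        assert report.n_rejected == 1
        assert report.n_accepted == 1
        assert "rate" in report.rejections[0][1]

    def test_missing_required_column_names_it(self, write_csv):
        path = write_csv([{"study_id": "s", "site_id": "x", "ecosystem_raw": "lake"}])
        with pytest.raises(SchemaError, match="rate"):
            read_dataset(path)

    def test_unmapped_ecosystem_name_rejected_with_name(self, write_csv):
        path = write_csv([_row(eco="swimming pool")])
        ms, report = read_dataset(path, {"lake": "lake"})
        assert report.n_rejected == 1
        assert "swimming pool" in report.rejections[0][1]

    def test_sd_reported_count_matches_input(self, write_csv):
        rows = [_row(sd=2.0), _row(), _row(sd=1.0), _row(sd="NA")]
        ms, report = read_dataset(write_csv(rows))
        assert report.n_sd_reported == 2
        assert sum(m.sd_source == "reported" for m in ms) == 2

    def test_na_tokens_are_missing(self, write_csv):
        rows = [_row(sd="NA", salinity_class="", latitude="nan")]
        ms, _ = read_dataset(write_csv(rows))
        assert ms[0].sd is None
        assert ms[0].salinity_class is None
        assert ms[0].latitude is None

    def test_coordinate_bounds_enforced(self, write_csv):
        ms, report = read_dataset(write_csv([_row(latitude=95.0), _row(latitude=45.0)]))
        assert report.n_rejected == 1
        assert ms[0].latitude == 45.0


class TestMeasurementInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rate": 0.0},
            {"rate": -1.0},
            {"rate": math.nan},
            {"rate": 10.0, "sd": -2.0, "sd_source": "reported"},
            {"rate": 10.0, "ecosystem_category": "swamp"},
            {"rate": 10.0, "salinity_class": "briny"},
            {"rate": 10.0, "longitude": 500.0},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RateMeasurement("s", "x", **kwargs)


class TestGroupBy:
    def test_counts_per_group(self):
        ms = [RateMeasurement("s", f"l{i}", 1.0, ecosystem_category="lake") for i in range(5)]
        ms += [RateMeasurement("s", f"m{i}", 2.0, ecosystem_category="mangrove") for i in range(3)]
        grouped = group_by(ms, "ecosystem_category")
        sizes = {k: len(v) for k, v in grouped.groups.items()}
        assert sizes == {"lake": 5, "mangrove": 3}

    def test_rows_missing_label_are_excluded_and_counted(self, tiny_measurements):
        grouped = group_by(tiny_measurements, "inundation_class")
        assert grouped.n_grouped == 4
        assert grouped.n_excluded == 2

    def test_all_missing_label_raises(self):
        ms = [RateMeasurement("s", "x", 1.0, ecosystem_category="lake")]
        with pytest.raises(EmptyGroupingError):
            group_by(ms, "salinity_class")

    def test_group_stats_match_scan_oracle(self):
        ms, _ = generate_dataset(default_config(seed=11))
        grouped = group_by(ms, "ecosystem_category")
        stats = grouped.stats()
        for cat in ECOSYSTEM_CATEGORIES:
            rates = [m.rate for m in ms if m.ecosystem_category == cat]
            assert stats[cat].n == len(rates)
            assert stats[cat].minimum == min(rates)
            assert stats[cat].maximum == max(rates)

    @given(labels=st.lists(st.sampled_from(["fresh", "brackish", "saline", None]),
                           min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_grouping_is_a_partition(self, labels):
        ms = [
            RateMeasurement("s", f"x{i}", 1.0, ecosystem_category="lake",
                            salinity_class=lab)
            for i, lab in enumerate(labels)
        ]
        try:
            grouped = group_by(ms, "salinity_class")
        except EmptyGroupingError:
            assert all(lab is None for lab in labels)
            return
        assert grouped.n_grouped + grouped.n_excluded == len(ms)
        seen = [m.site_id for rows in grouped.groups.values() for m in rows]
        assert len(seen) == len(set(seen))


class TestRoundTrip:
    def test_dataset_round_trips_losslessly(self, tiny_measurements, tmp_path):
        path = tmp_path / "out.csv"
        write_measurements(tiny_measurements, path)
        back, report = read_dataset(path)
        assert report.n_rejected == 0
        assert back == tiny_measurements

    def test_synthetic_round_trip_preserves_row_identity(self, tmp_path):
        ms, truth = generate_dataset(default_config(seed=3))
        path = tmp_path / "sim.csv"
        write_measurements(ms, path)
        back, _ = read_dataset(path)
        assert [m.site_id for m in back] == [m.site_id for m in ms]
        np.testing.assert_allclose([m.rate for m in back], [m.rate for m in ms])


class TestWriteResults:
    def test_posterior_summary_round_trip(self, tmp_path, quick_config):
        from aquacarb import fit_all

        ms, _ = generate_dataset(default_config(seed=5))
        grouped = group_by(ms[:50], "ecosystem_category")
        from aquacarb.sd_imputation import impute_dataset

        imputed, _ = impute_dataset(ms[:50])
        grouped = group_by(imputed, "ecosystem_category")
        result = fit_all(grouped, quick_config)
        path = tmp_path / "summary.csv"
        write_results(result, path)
        back = read_summary(path)
        np.testing.assert_array_equal(back["q50"].to_numpy(),
                                      result.summary_frame()["q50"].to_numpy())

    def test_upscale_table_has_one_row_per_group(self, tmp_path):
        from aquacarb.post_analysis import UpscaleTable, upscale

        table = UpscaleTable(
            [upscale((1.0, 2.0, 3.0), 1e12, label=f"g{i}") for i in range(3)]
        )
        path = tmp_path / "upscale.csv"
        write_results(table, path)
        assert len(read_summary(path)) == 3

    def test_missing_diagnostic_written_as_explicit_na(self, tmp_path):
        from aquacarb import ModelConfig, fit_group
        from aquacarb.bayes_model import PosteriorResult

        cfg = ModelConfig(n_chains=2, n_iter=600, n_burnin=100, seed=1, fixed_tau=5.0)
        g = fit_group([10.0, 12.0, 9.0], [1.0, 1.0, 1.0], cfg)
        assert g.rhat_tau is None  # τ was fixed: no diagnostic exists
        result = PosteriorResult("ecosystem_category", {"g": g}, cfg)
        path = tmp_path / "summary.csv"
        write_results(result, path)
        text = path.read_text()
        assert "NA" in text.splitlines()[1]
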