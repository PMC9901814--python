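"""Reading and screening of isotope sample tables."""

import numpy as np
import pandas as pd
import pytest

from paleoscape import ScreeningConfig, read_samples, screen_samples, summarize_dataset
from paleoscape.ingest import CANONICAL_COLUMNS


def _write(tmp_path, df, name="t.csv"):
    p = tmp_path / name
    df.to_csv(p, index=False)
    return p


class TestReadSamples:
    def test_roundtrip_three_rows(self, tmp_path, sample_rows):
        p = _write(tmp_path, sample_rows)
        got = read_samples(p)
        assert len(got) == 3
        assert list(got["sample_id"]) == ["a1", "a2", "a3"]
        np.testing.assert_allclose(got["d15N"], sample_rows["d15N"])
        # re-writing the canonical frame is stable
        q1, q2 = tmp_path / "o1.csv", tmp_path / "o2.csv"
        got.to_csv(q1, index=False)
        read_samples(q1).to_csv(q2, index=False)
        assert q1.read_bytes() == q2.read_bytes()

    def test_empty_cn_cell_stays_missing(self, tmp_path, sample_rows):
        rows = sample_rows.copy()
        rows.loc[1, "cn_atomic"] = np.nan
        got = read_samples(_write(tmp_path, rows))
        assert np.isnan(got.loc[1, "cn_atomic"])

    def test_missing_mandatory_column_is_named(self, tmp_path, sample_rows):
        rows = sample_rows.drop(columns=["latitude"])
        with pytest.raises(ValueError, match="latitude"):
            read_samples(_write(tmp_path, rows))

    def test_column_mapping(self, tmp_path, sample_rows):
        rows = sample_rows.rename(columns={"d15N": "d15N_permil"})
        got = read_samples(_write(tmp_path, rows), column_map={"d15N": "d15N_permil"})
        np.testing.assert_allclose(got["d15N"], sample_rows["d15N"])

    def test_xlsx_round_trip(self, tmp_path, sample_rows):
        p = tmp_path / "t.xlsx"
        sample_rows.to_excel(p, index=False)
        got = read_samples(p)
        assert len(got) == 3 and got["taxon"].iloc[2] == "Cervus elaphus"

    def test_out_of_range_coordinates_rejected(self, tmp_path, sample_rows):
        rows = sample_rows.copy()
        rows.loc[0, "latitude"] = 95.0
        with pytest.raises(ValueError):
            read_samples(_write(tmp_path, rows))


def _base_record(**kw):
    rec = {
        "sample_id": "x",
        "site_id": "s",
        "latitude": 45.0,
        "longitude": 5.0,
        "taxon": "Equus sp.",
        "element": "bone",
        "age_class": "adult",
        "d15N": 4.0,
        "cn_atomic": 3.2,
        "cn_unreliable": False,
        "taxon_certain": True,
        "duplicate_group": np.nan,
        "dating_basis": "direct",
        "c14_age": 12_000.0,
        "c14_error": 60.0,
        "context_age_bin": np.nan,
        "context_secure": True,
        "source_flag": "published",
    }
    rec.update(kw)
    return rec


def _frame(*records):
    return pd.DataFrame([_base_record(**r) for r in records])


class TestScreening:
    @pytest.mark.parametrize(
        "record, rule",
        [
            ({"cn_atomic": 2.8}, "cn_ratio"),
            ({"cn_atomic": 3.7}, "cn_ratio"),
            ({"cn_atomic": np.nan}, "cn_ratio"),
            ({"cn_unreliable": True}, "cn_ratio"),
            ({"taxon_certain": False}, "taxon_uncertain"),
            ({"age_class": "juvenile"}, "juvenile"),
            ({"taxon": "Rangifer tarandus", "element": "antler"}, "cervid_antler_tooth"),
            ({"taxon": "Cervus elaphus", "element": "tooth"}, "cervid_antler_tooth"),
            ({"latitude": 61.0}, "outside_window"),
            ({"longitude": -15.0}, "outside_window"),
        ],
    )
    def test_single_rule_exclusions(self, record, rule):
        out = screen_samples(_frame(record))
        assert out.n_retained == 0
        assert out.exclusion_counts[rule] == 1

    def test_clean_record_retained(self):
        out = screen_samples(_frame({}))
        assert out.n_retained == 1 and out.n_excluded == 0

    def test_horse_antler_not_excluded_by_cervid_rule(self):
        # the antler/tooth rule applies to cervid taxa only
        out = screen_samples(_frame({"taxon": "Equus sp.", "element": "antler"}))
        assert out.n_retained == 1

    def test_first_failing_rule_logged(self):
        out = screen_samples(_frame({"cn_atomic": 2.0, "age_class": "juvenile"}))
        assert out.exclusion_counts["cn_ratio"] == 1
        assert out.exclusion_counts["juvenile"] == 0

    def test_duplicates_keep_first_in_file_order(self):
        df = _frame(
            {"sample_id": "a", "duplicate_group": "g1", "d15N": 1.0},
            {"sample_id": "b", "duplicate_group": "g1", "d15N": 2.0},
            {"sample_id": "c", "duplicate_group": "g2"},
        )
        out = screen_samples(df)
        assert out.exclusion_counts["duplicate"] == 1
        assert "a" in set(out.samples["sample_id"]) and "b" not in set(out.samples["sample_id"])

    def test_counts_reconcile(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(60):
            r = {"sample_id": f"r{i}", "cn_atomic": float(rng.uniform(2.5, 4.0))}
            if rng.uniform() < 0.2:
                r["age_class"] = "juvenile"
            if rng.uniform() < 0.2:
                r["latitude"] = 70.0
            recs.append(r)
        out = screen_samples(_frame(*recs))
        assert out.n_retained + sum(out.exclusion_counts.values()) == 60
        assert len(out.exclusion_reasons) == out.n_excluded

    def test_screening_idempotent(self):
        df = _frame({}, {"cn_atomic": 2.0}, {"age_class": "juvenile"}, {})
        once = screen_samples(df)
        twice = screen_samples(once.samples)
        pd.testing.assert_frame_equal(
            once.samples.reset_index(drop=True), twice.samples.reset_index(drop=True)
        )
        assert twice.n_excluded == 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScreeningConfig(cn_min=3.6, cn_max=2.9)


class TestSummarize:
    def test_hand_arithmetic(self):
        df = _frame({"d15N": 2.0}, {"d15N": 4.0}, {"d15N": 6.0})
        s = summarize_dataset(df)["overall"]
        assert s == {"n": 3, "mean": 4.0, "sd": 2.0, "min": 2.0, "max": 6.0}

    def test_single_row_sd_missing(self):
        s = summarize_dataset(_frame({}))["overall"]
        assert s["sd"] is None

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            summarize_dataset(pd.DataFrame(columns=list(CANONICAL_COLUMNS)))

    def test_taxon_percentages_are_integers(self):
        df = _frame({}, {"taxon": "Bison priscus"}, {"taxon": "Bison priscus"})
        by_taxon = summarize_dataset(df)["by_taxon"]
        assert by_taxon["Bison priscus"] == {"n": 2, "percent": 67}
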