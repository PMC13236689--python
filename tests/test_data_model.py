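"""Tests for culm records, dry-biomass derivation and descriptive statistics."""

import math

import pytest

from culmfit import (
    CulmRecord,
    SchemaError,
    ValidationError,
    contrast_pct,
    correlation_matrix,
    derive_dry_biomass,
    fold_increase,
    moisture_content,
    read_culm_table,
    summarize,
    write_csv,
)
from culmfit.data_model import COMPONENTS


def make_record(**kw):
    base = dict(
        culm_id="C1",
        plot_id="P1",
        age_class=2,
        dbh_cm=4.42,
        height_m=7.85,
        fresh_total_kg={"culm": 7.0, "branch": 1.8, "leaf": 1.2},
        sub_fresh_kg={"culm": 0.5, "branch": 0.3, "leaf": 0.2},
        sub_dry_kg={"culm": 0.2, "branch": 0.1, "leaf": 0.09},
    )
    base.update(kw)
    return CulmRecord(**base)


class TestDeriveDryBiomass:
    @pytest.mark.parametrize(
        "fresh,sub_f,sub_d,expected",
        [
            (10.0, 0.5, 0.2, 4.0),
            (7.23, 1.0, 1.0, 7.23),
            (2.0, 0.8, 0.3, 0.75),  # 2.0 × 0.375
        ],
    )
    def test_ratio_application(self, fresh, sub_f, sub_d, expected):
        assert derive_dry_biomass(fresh, sub_f, sub_d) == pytest.approx(expected)

    def test_pooled_ratio_over_multiple_subsamples(self):
        # pooled Σdry/Σfresh, not the mean of per-subsample ratios
        got = derive_dry_biomass(10.0, [0.5, 1.5], [0.1, 0.9])
        assert got == pytest.approx(10.0 * 1.0 / 2.0)
        mean_of_ratios = 10.0 * (0.1 / 0.5 + 0.9 / 1.5) / 2
        assert got != pytest.approx(mean_of_ratios)

    def test_homogeneous_in_fresh_total(self):
        assert derive_dry_biomass(6.0, 0.5, 0.2) == pytest.approx(
            3 * derive_dry_biomass(2.0, 0.5, 0.2)
        )

    @pytest.mark.parametrize(
        "fresh,sub_f,sub_d",
        [(0.0, 0.5, 0.2), (10.0, 0.5, 0.6), (0.4, 0.5, 0.2), (10.0, -1.0, 0.2)],
    )
    def test_invalid_inputs_rejected(self, fresh, sub_f, sub_d):
        with pytest.raises(ValidationError):
            derive_dry_biomass(fresh, sub_f, sub_d)


class TestMoistureContent:
    @pytest.mark.parametrize(
        "fresh,dry,expected",
        [(1.0, 1.0, 0.0), (2.0, 0.5, 75.0), (10.0, 3.721, 62.79)],
    )
    def test_known_values(self, fresh, dry, expected):
        assert moisture_content(fresh, dry) == pytest.approx(expected)

    def test_dry_exceeding_fresh_rejected(self):
        with pytest.raises(ValidationError):
            moisture_content(1.0, 1.5)


class TestContrasts:
    def test_age_and_aspect_contrasts(self):
        assert contrast_pct(6.23, 3.09) == pytest.approx(101.618, abs=1e-3)
        assert contrast_pct(8.52, 7.55) == pytest.approx(12.8477, abs=1e-3)

    def test_identity_and_agreement_with_fold(self):
        assert contrast_pct(3.3, 3.3) == 0.0
        a, b = 4.83, 1.07
        assert contrast_pct(a, b) == pytest.approx(100 * fold_increase(a, b))

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationError):
            contrast_pct(1.0, 0.0)


class TestCulmRecord:
    def test_derived_fields(self):
        r = make_record()
        assert r.d2h == pytest.approx(4.42**2 * 7.85)
        assert r.agb_kg == pytest.approx(sum(r.dry_kg.values()), rel=1e-15)
        for c in COMPONENTS:
            assert 0 <= r.moisture_pct[c] < 100

    def test_invariant_violations_raise(self):
        with pytest.raises(ValidationError):
            make_record(dbh_cm=-1.0)
        with pytest.raises(ValidationError):
            make_record(sub_dry_kg={"culm": 0.6, "branch": 0.1, "leaf": 0.09})
        with pytest.raises(ValidationError):
            make_record(aspect="north")


class TestReadCulmTable:
    def test_roundtrip_from_generator(self, default_records, tmp_path):
        path = tmp_path / "culms.csv"
        write_csv(default_records, path)
        records = read_culm_table(path)
        assert len(records) == 45
        for r, orig in zip(records, default_records):
            assert r.culm_id == orig.culm_id
            assert r.agb_kg == pytest.approx(
                r.dry_kg["culm"] + r.dry_kg["branch"] + r.dry_kg["leaf"], rel=1e-12
            )
            assert r.agb_kg == pytest.approx(orig.agb_kg, rel=1e-9)

    def test_missing_column_named_in_error(self, default_records, tmp_path):
        import pandas as pd

        path = tmp_path / "culms.csv"
        write_csv(default_records, path)
        df = pd.read_csv(path).drop(columns=["dbh_cm"])
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="dbh_cm"):
            read_culm_table(path)

    def test_dialect_maps_alternative_headers(self, default_records, tmp_path):
        import pandas as pd

        path = tmp_path / "culms.csv"
        write_csv(default_records, path)
        df = pd.read_csv(path).rename(columns={"dbh_cm": "DBH", "height_m": "H"})
        df.to_csv(path, index=False)
        records = read_culm_table(path, dialect={"dbh_cm": "DBH", "height_m": "H"})
        assert len(records) == 45

    def test_invalid_row_rejected(self, default_records, tmp_path):
        import pandas as pd

        path = tmp_path / "culms.csv"
        write_csv(default_records, path)
        df = pd.read_csv(path)
        df.loc[3, "culm_sub_dry_kg"] = df.loc[3, "culm_sub_fresh_kg"] * 2
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="row 3"):
            read_culm_table(path)


class TestSummarize:
    def test_single_record_degenerate_stats(self):
        [s] = summarize([make_record()])
        st = s.stats["dbh"]
        assert st["mean"] == st["min"] == st["max"] == pytest.approx(4.42)
        assert st["sd"] == 0.0
        assert s.n == 1

    def test_two_record_sd(self):
        recs = [make_record(culm_id="A", dbh_cm=2.0), make_record(culm_id="B", dbh_cm=4.0)]
        [s] = summarize(recs)
        assert s.stats["dbh"]["mean"] == pytest.approx(3.0)
        assert s.stats["dbh"]["sd"] == pytest.approx(math.sqrt(2))

    def test_permutation_invariance(self, default_records):
        fwd = summarize(default_records, group_by="age_class")
        rev = summarize(default_records[::-1], group_by="age_class")
        for a, b in zip(fwd, rev):
            assert a.group_value == b.group_value and a.n == b.n
            for v in a.stats:
                assert a.stats[v]["mean"] == pytest.approx(b.stats[v]["mean"], rel=1e-12)

    def test_grouped_means_near_generator_targets(self, default_records):
        by_age = {s.group_value: s for s in summarize(default_records, group_by="age_class")}
        # generator cohorts are centred on DBH 6.23 / 3.09 cm; sample means of
        # ~22 culms should land well within 3 standard errors
        assert by_age[2].stats["dbh"]["mean"] == pytest.approx(6.23, abs=0.8)
        assert by_age[3].stats["dbh"]["mean"] == pytest.approx(3.09, abs=0.8)
        assert by_age[2].stats["h"]["mean"] == pytest.approx(10.84, abs=1.5)
        assert by_age[3].stats["h"]["mean"] == pytest.approx(5.67, abs=1.5)

    def test_empty_input_raises(self):
        with pytest.raises(ValidationError):
            summarize([])


class TestCorrelationMatrix:
    def test_shape_bounds_and_strength(self, default_records):
        mat = correlation_matrix(default_records)
        assert mat.shape == (4, 3)
        assert (mat.to_numpy() <= 1).all() and (mat.to_numpy() >= -1).all()
        # biomass is generated from DBH: component-DBH correlations are strong
        assert (mat["DBH"] > 0.6).all()

    def test_exact_proportionality_and_antiproportionality(self):
        # biomass exactly proportional to DBH -> r = +1; H chosen to fall
        # linearly with DBH -> r(AGB, H) = -1
        recs = [
            make_record(
                culm_id=f"C{i}",
                dbh_cm=d,
                height_m=20.0 - d,
                fresh_total_kg={"culm": 2.0 * d, "branch": 0.5 * d, "leaf": 0.25 * d},
            )
            for i, d in enumerate([2.0, 3.0, 4.0, 5.0])
        ]
        mat = correlation_matrix(recs)
        assert mat.loc["AGB", "DBH"] == pytest.approx(1.0, abs=1e-12)
        assert mat.loc["AGB", "H"] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        recs = [make_record(culm_id=f"C{i}") for i in range(4)]
        with pytest.raises(ValidationError, match="zero variance"):
            correlation_matrix(recs)
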