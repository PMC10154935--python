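"""Territory/covariate I/O, the Greater London merge and normalisation."""

import numpy as np
import pandas as pd
import pytest

from countylines.data_model import (
    CovariateTable,
    LineCounts,
    ODMatrix,
    Territory,
    merge_london,
    normalise_covariates,
    read_line_counts,
    read_od_matrix,
    read_territories,
    write_line_counts,
    write_od_matrix,
    write_territories,
)
from countylines.errors import FormatError, ReconciliationError, ValidationError


def _write_csv(path, text):
    path.write_text(text)
    return path


class TestReadTerritories:
    def test_identity_readback(self, tmp_path):
        p = _write_csv(
            tmp_path / "t.csv",
            "id,name,population,lon,lat,region_tag\n"
            "x,X,1000,0.1,0.2,south\ny,Y,2000,0.3,0.4,\nz,Z,3000,0.5,0.6,north\n",
        )
        terrs = read_territories(p)
        assert [t.id for t in terrs] == ["x", "y", "z"]
        assert terrs[0].population == 1000
        assert terrs[1].region_tag is None
        assert terrs[2].region_tag == "north"

    def test_zero_population_rejected(self, tmp_path):
        p = _write_csv(
            tmp_path / "t.csv", "id,name,population,lon,lat\nx,X,0,0,0\n"
        )
        with pytest.raises(ValidationError, match="population"):
            read_territories(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = _write_csv(
            tmp_path / "t.csv",
            "id,name,population,lon,lat\nx,X,1,0,0\nx,X2,2,0,0\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_territories(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = _write_csv(tmp_path / "t.csv", "id,name,lon,lat\nx,X,0,0\n")
        with pytest.raises(FormatError, match="population"):
            read_territories(p)

    def test_write_read_roundtrip(self, tmp_path):
        terrs = [
            Territory("a", "Alpha", 1.5e6, -1.25, 52.5, "south"),
            Territory("b", "Beta", 7.2e5, 0.75, 53.1, None),
        ]
        write_territories(terrs, tmp_path / "rt.csv")
        back = read_territories(tmp_path / "rt.csv")
        assert back == terrs


class TestODMatrixIO:
    def test_accepts_zero_diagonal(self, tmp_path):
        p = _write_csv(
            tmp_path / "od.csv", ",a,b,c\na,0,1,2\nb,1,0,3\nc,2,3,0\n"
        )
        od = read_od_matrix(p, kind="distance")
        assert od.ids == ("a", "b", "c")
        assert od.to_frame().loc["b", "c"] == 3

    def test_negative_entry_rejected(self, tmp_path):
        p = _write_csv(tmp_path / "od.csv", ",a,b\na,0,-5\nb,-5,0\n")
        with pytest.raises(ValidationError):
            read_od_matrix(p, kind="travel_time")

    def test_asymmetric_ids_rejected(self, tmp_path):
        p = _write_csv(tmp_path / "od.csv", ",a,b\nb,0,1\na,1,0\n")
        with pytest.raises(ReconciliationError):
            read_od_matrix(p, kind="distance")

    def test_roundtrip(self, tmp_path):
        od = ODMatrix(("a", "b"), np.array([[0.0, 2.5], [2.5, 0.0]]), "distance")
        write_od_matrix(od, tmp_path / "od.csv")
        back = read_od_matrix(tmp_path / "od.csv", kind="distance")
        assert back.ids == od.ids
        np.testing.assert_allclose(back.values, od.values)


class TestLineCountsIO:
    def test_long_format_totals(self, tmp_path):
        rows = ["origin,destination,year,count"]
        counts = {f"d{i:02d}": i + 1 for i in range(37)}
        for dest, c in counts.items():
            rows.append(f"london,{dest},2019,{c}")
        p = _write_csv(tmp_path / "lines.csv", "\n".join(rows) + "\n")
        lines = read_line_counts(p)
        assert set(lines) == {"2019"}
        assert lines["2019"].total == sum(counts.values())
        assert len(lines["2019"].counts) == 37

    def test_roundtrip(self, tmp_path):
        lc = {
            "2019": LineCounts("london", "2019", pd.Series({"a": 3.0, "b": 0.0})),
            "2020": LineCounts("london", "2020", pd.Series({"a": 1.0, "b": 9.0})),
        }
        write_line_counts(lc, tmp_path / "lines.csv")
        back = read_line_counts(tmp_path / "lines.csv")
        for year in lc:
            pd.testing.assert_series_equal(
                back[year].counts.sort_index(), lc[year].counts.sort_index(),
                check_names=False,
            )

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            LineCounts("london", "2019", pd.Series({"a": -1.0}))

    def test_origin_not_a_destination(self):
        with pytest.raises(ValidationError):
            LineCounts("london", "2019", pd.Series({"london": 1.0}))


def _two_london_fixture():
    terrs = [
        Territory("metropolitan-police", "Metropolitan Police", 8.9e6, 0.0, 0.0),
        Territory("city-of-london", "City of London", 1e4, 0.1, 0.0),
        Territory("a", "A", 1e6, 2.0, 2.0),
    ]
    cov = CovariateTable(
        pd.DataFrame(
            {
                "misuse_admissions": [8000.0, 50.0, 900.0],
                "poisoning_admissions": [4000.0, 30.0, 500.0],
                "police_officers": [30000.0, 700.0, 2000.0],
                "gdhi": [2.5e11, 8e8, 2.2e10],
                "knife_crimes": [14000.0, 500.0, 400.0],
                "hospital_beds": [20000.0, 300.0, 2500.0],
            },
            index=["metropolitan-police", "city-of-london", "a"],
        )
    )
    lines = {
        "2019": LineCounts("metropolitan-police", "2019", pd.Series({"a": 40.0}))
    }
    return terrs, cov, lines


class TestMergeLondon:
    def test_population_and_covariates_are_summed(self):
        terrs, cov, lines = _two_london_fixture()
        out_t, out_c, out_l = merge_london(terrs, cov, lines)
        london = next(t for t in out_t if t.id == "london")
        assert london.population == 8.9e6 + 1e4
        assert out_c.values.loc["london", "knife_crimes"] == 14000 + 500
        assert out_l["2019"].origin == "london"
        assert out_l["2019"].counts.loc["a"] == 40

    def test_conservation_of_totals(self):
        terrs, cov, lines = _two_london_fixture()
        out_t, out_c, out_l = merge_london(terrs, cov, lines)
        assert sum(t.population for t in out_t) == sum(t.population for t in terrs)
        pd.testing.assert_series_equal(
            out_c.values.sum(), cov.values.sum(), check_names=False
        )
        assert out_l["2019"].total == lines["2019"].total

    def test_rates_recomputed_from_summed_raw_counts(self):
        # per-100k rate of the merged territory must come from summed raw
        # values, never from averaging the two constituent rates
        terrs, cov, lines = _two_london_fixture()
        out_t, out_c, _ = merge_london(terrs, cov, lines)
        w = normalise_covariates(out_t, out_c)
        expected = (14000 + 500) * 1e5 / (8.9e6 + 1e4)
        assert w.loc["london", "knife_crimes"] == pytest.approx(expected)
        mean_of_rates = 0.5 * (14000 * 1e5 / 8.9e6 + 500 * 1e5 / 1e4)
        assert w.loc["london", "knife_crimes"] != pytest.approx(mean_of_rates, rel=0.5)

    def test_missing_constituent_is_noop_with_warning(self):
        terrs, cov, lines = _two_london_fixture()
        terrs = [t for t in terrs if t.id != "city-of-london"]
        with pytest.warns(UserWarning, match="no merge"):
            out_t, out_c, out_l = merge_london(
                terrs, cov, lines
            )
        assert [t.id for t in out_t] == [t.id for t in terrs]


class TestNormaliseCovariates:
    def test_per_100k_hand_value(self):
        terrs = [Territory("x", "X", 2e6, 0, 0)]
        cov = CovariateTable(
            pd.DataFrame(
                {name: [400.0] for name in
                 ("misuse_admissions", "poisoning_admissions", "police_officers",
                  "gdhi", "knife_crimes", "hospital_beds")},
                index=["x"],
            )
        )
        w = normalise_covariates(terrs, cov)
        assert w.loc["x", "knife_crimes"] == pytest.approx(400 * 1e5 / 2e6)  # 20

    def test_zero_events_give_zero_rate(self):
        terrs = [Territory("x", "X", 1e6, 0, 0)]
        cov = CovariateTable(
            pd.DataFrame(
                {name: [0.0] for name in
                 ("misuse_admissions", "poisoning_admissions", "police_officers",
                  "gdhi", "knife_crimes", "hospital_beds")},
                index=["x"],
            )
        )
        w = normalise_covariates(terrs, cov)
        assert (w.loc["x"] == 0).all()

    def test_per_bed_mode_hand_value(self):
        terrs = [Territory("x", "X", 1e6, 0, 0)]
        cov = CovariateTable(
            pd.DataFrame(
                {
                    "misuse_admissions": [500.0],
                    "poisoning_admissions": [100.0],
                    "police_officers": [2000.0],
                    "gdhi": [1e10],
                    "knife_crimes": [300.0],
                    "hospital_beds": [2000.0],
                },
                index=["x"],
            )
        )
        w = normalise_covariates(terrs, cov, admissions_mode="per_bed")
        # admissions / (beds per capita): 500 / (2000/1e6)
        assert w.loc["x", "misuse_admissions"] == pytest.approx(250_000.0)
        # non-admission covariates stay per-100k
        assert w.loc["x", "knife_crimes"] == pytest.approx(300 * 1e5 / 1e6)

    def test_per_bed_requires_positive_beds(self):
        terrs = [Territory("x", "X", 1e6, 0, 0)]
        cov = CovariateTable(
            pd.DataFrame(
                {name: [1.0] for name in
                 ("misuse_admissions", "poisoning_admissions", "police_officers",
                  "gdhi", "knife_crimes")} | {"hospital_beds": [0.0]},
                index=["x"],
            )
        )
        with pytest.raises(ValidationError, match="beds"):
            normalise_covariates(terrs, cov, admissions_mode="per_bed")

    @pytest.mark.parametrize("factor", [0.5, 3.0, 10.0])
    def test_homogeneity(self, factor):
        # scaling raw counts and population together leaves rates unchanged
        base_t = [Territory("x", "X", 1.3e6, 0, 0)]
        scaled_t = [Territory("x", "X", 1.3e6 * factor, 0, 0)]
        vals = {
            "misuse_admissions": 700.0, "poisoning_admissions": 300.0,
            "police_officers": 2500.0, "gdhi": 3e10,
            "knife_crimes": 800.0, "hospital_beds": 3000.0,
        }
        base_c = CovariateTable(pd.DataFrame({k: [v] for k, v in vals.items()}, index=["x"]))
        scaled_c = CovariateTable(
            pd.DataFrame({k: [v * factor] for k, v in vals.items()}, index=["x"])
        )
        pd.testing.assert_frame_equal(
            normalise_covariates(base_t, base_c, "per_100k"),
            normalise_covariates(scaled_t, scaled_c, "per_100k"),
        )
        # per-bed admissions are a ratio of two raw covariates times the
        # population, so joint scaling moves them by the same factor; the
        # non-admission columns stay invariant
        w_base = normalise_covariates(base_t, base_c, "per_bed")
        w_scaled = normalise_covariates(scaled_t, scaled_c, "per_bed")
        pd.testing.assert_series_equal(
            w_base.loc["x", ["police_officers", "gdhi", "knife_crimes"]],
            w_scaled.loc["x", ["police_officers", "gdhi", "knife_crimes"]],
        )
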