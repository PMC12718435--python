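import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import diatomcal as dc
from diatomcal.data_model import DataError, skewness


def _toy_csvs(tmp_path, sites=("A", "B", "C")):
    counts = pd.DataFrame(
        {"t1": [10, 5, 1], "t2": [5, 10, 9]}, index=pd.Index(sites, name="site")
    )
    env = pd.DataFrame({"temp": [10.0, 11.0, 12.0]}, index=pd.Index(sites, name="site"))
    coords = pd.DataFrame({"km": [0.0, 5.0, 10.0]}, index=pd.Index(sites, name="site"))
    paths = tmp_path / "counts.csv", tmp_path / "env.csv", tmp_path / "coords.csv"
    counts.to_csv(paths[0]); env.to_csv(paths[1]); coords.to_csv(paths[2])
    return paths


class TestLoadDataset:
    def test_round_trip_identity(self, tmp_path):
        cp, ep, xp = _toy_csvs(tmp_path)
        ds = dc.load_dataset(cp, ep, xp)
        assert ds.sites == ["A", "B", "C"]
        out = tmp_path / "out"
        out.mkdir()
        dc.save_dataset(ds, out / "c.csv", out / "e.csv", out / "x.csv")
        ds2 = dc.load_dataset(out / "c.csv", out / "e.csv", out / "x.csv")
        pd.testing.assert_frame_equal(ds.counts.counts, ds2.counts.counts)
        pd.testing.assert_frame_equal(ds.env.values, ds2.env.values)
        pd.testing.assert_frame_equal(ds.coords.values, ds2.coords.values)

    def test_site_intersection_drops_unshared(self, tmp_path, caplog):
        cp, ep, _ = _toy_csvs(tmp_path)
        env = pd.DataFrame({"temp": [1.0, 2.0, 3.0]}, index=pd.Index(["B", "C", "D"], name="site"))
        env.to_csv(ep)
        with caplog.at_level("WARNING"):
            ds = dc.load_dataset(cp, ep)
        assert ds.sites == ["B", "C"]
        assert any("dropping" in r.message for r in caplog.records)

    def test_non_numeric_cell_names_location(self, tmp_path):
        cp, ep, _ = _toy_csvs(tmp_path)
        df = pd.read_csv(cp, index_col=0).astype(object)
        df.loc["B", "t2"] = "NA?"
        df.to_csv(cp)
        with pytest.raises(DataError, match="B.*t2"):
            dc.load_dataset(cp, ep)

    def test_empty_intersection_fatal(self, tmp_path):
        cp, ep, _ = _toy_csvs(tmp_path)
        env = pd.DataFrame({"temp": [1.0]}, index=pd.Index(["Z"], name="site"))
        env.to_csv(ep)
        with pytest.raises(DataError, match="no sites"):
            dc.load_dataset(cp, ep)


class TestRelativeAbundance:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([1, 1, 2], [0.25, 0.25, 0.5]),
            ([10, 1, 489], [0.02, 0.002, 0.978]),
        ],
    )
    def test_row_proportions(self, row, expected):
        cm = dc.CountMatrix(pd.DataFrame([row], index=["s"], columns=list("abc")[: len(row)]))
        rel = dc.relative_abundance(cm)
        np.testing.assert_allclose(rel.values.iloc[0], expected, atol=1e-12)

    def test_single_taxon_is_identity(self):
        cm = dc.CountMatrix(pd.DataFrame({"a": [400]}, index=["s"]))
        assert dc.relative_abundance(cm).values.iloc[0, 0] == 1.0

    def test_rows_sum_to_one(self, rng):
        cm = dc.CountMatrix(
            pd.DataFrame(rng.integers(1, 50, (6, 9)), columns=[f"t{i}" for i in range(9)])
        )
        sums = dc.relative_abundance(cm).values.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestRareTaxonFilter:
    def _toy(self):
        df = pd.DataFrame(
            {"A": [0.02, 0.02], "B": [0.002, 0.012], "C": [0.978, 0.968]},
            index=["s1", "s2"],
        )
        return dc.AbundanceMatrix(df, "none")

    def test_one_percent_two_sites_rule(self):
        out, report = dc.rare_taxon_filter(self._toy())
        assert report.retained == ["A", "C"]
        assert report.dropped == ["B"]

    def test_single_occurrence_threshold_relaxes(self):
        out, report = dc.rare_taxon_filter(self._toy(), min_occurrences=1)
        assert report.retained == ["A", "B", "C"]

    def test_matches_exhaustive_per_taxon_check(self, rng):
        p = rng.dirichlet(np.ones(20) * 0.3, size=8)
        df = pd.DataFrame(p, columns=[f"t{i}" for i in range(20)])
        rel = dc.AbundanceMatrix(df, "none")
        out, report = dc.rare_taxon_filter(rel, min_pct=1, min_occurrences=2)
        expected = [
            t for t in df.columns if int((df[t] >= 0.01).sum()) >= 2
        ]
        assert report.retained == expected

    def test_idempotent(self, rng):
        p = rng.dirichlet(np.ones(15), size=6)
        rel = dc.AbundanceMatrix(pd.DataFrame(p, columns=[f"t{i}" for i in range(15)]), "none")
        once, _ = dc.rare_taxon_filter(rel)
        twice, _ = dc.rare_taxon_filter(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_dropped_fatal(self):
        rel = dc.AbundanceMatrix(pd.DataFrame({"a": [0.001], "b": [0.999]}, index=["s"]), "none")
        with pytest.raises(DataError):
            dc.rare_taxon_filter(rel, min_pct=1, min_occurrences=2)


class TestHellinger:
    def test_square_roots(self):
        rel = dc.AbundanceMatrix(pd.DataFrame([[0.25, 0.25, 0.5]], columns=list("abc")), "none")
        np.testing.assert_allclose(
            dc.hellinger(rel).values.iloc[0], [0.5, 0.5, np.sqrt(0.5)], atol=1e-12
        )

    def test_double_transform_fatal(self):
        rel = dc.AbundanceMatrix(pd.DataFrame([[1.0]], columns=["a"]), "none")
        with pytest.raises(DataError):
            dc.hellinger(dc.hellinger(rel))

    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=8))
    def test_rows_have_unit_sum_of_squares(self, row):
        rel = dc.AbundanceMatrix(
            pd.DataFrame([np.array(row) / sum(row)], columns=[f"t{i}" for i in range(len(row))]),
            "none",
        )
        ssq = (dc.hellinger(rel).values.iloc[0] ** 2).sum()
        assert abs(ssq - 1.0) < 1e-12


class TestTransformEnv:
    def test_symmetric_column_not_logged(self):
        env = dc.EnvTable(pd.DataFrame({"v": [1.0, 2.0, 3.0]}))
        out = dc.transform_env(env)
        assert not out.transform_log["v"]
        assert abs(out.values["v"].mean()) < 1e-9
        assert abs(out.values["v"].std(ddof=1) - 1.0) < 1e-9

    def test_extreme_skew_is_logged(self):
        env = dc.EnvTable(pd.DataFrame({"v": [0.0, 0.0, 0.0, 999.0]}))
        assert dc.transform_env(env).transform_log["v"]

    def test_log_reduces_lognormal_skewness(self, rng):
        col = np.exp(rng.normal(0, 1.5, 200))
        env = dc.EnvTable(pd.DataFrame({"v": col}))
        out = dc.transform_env(env)
        assert out.transform_log["v"]
        assert abs(skewness(np.log10(col + 1))) < abs(skewness(col))

    def test_all_columns_scaled(self, rng):
        env = dc.EnvTable(pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd")))
        out = dc.transform_env(env)
        assert np.all(np.abs(out.values.mean()) < 1e-9)
        assert np.all(np.abs(out.values.std(ddof=1) - 1) < 1e-9)
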