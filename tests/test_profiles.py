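import numpy as np
import pandas as pd
import pytest

from ageplace import profiles
from ageplace.catalogue import variable_catalogue


@pytest.fixture()
def std_matrix():
    rng = np.random.default_rng(10)
    X = pd.DataFrame(
        rng.normal(size=(120, 4)),
        columns=list("wxyz"),
        index=[f"A{i}" for i in range(120)],
    )
    return profiles.standardise(X)


class TestClusterZScores:
    def test_single_cluster_means_are_zero(self, std_matrix):
        z = profiles.cluster_zscores(std_matrix, np.zeros(120, dtype=int))
        assert np.allclose(z.to_numpy(), 0.0, atol=1e-12)

    def test_two_equal_clusters_are_symmetric(self):
        delta = 1.5
        X = pd.DataFrame({"v": np.r_[np.full(50, -delta), np.full(50, delta)]})
        X["v"] += np.tile([-0.1, 0.1], 50)  # non-degenerate SD
        z = profiles.cluster_zscores(
            profiles.standardise(X), np.repeat([0, 1], 50)
        )
        assert z.loc[0, "v"] == pytest.approx(-z.loc[1, "v"])

    def test_matches_brute_force_groupby(self, std_matrix):
        labels = np.arange(120) % 3
        z = profiles.cluster_zscores(std_matrix, labels)
        for c in range(3):
            expected = std_matrix.to_numpy()[labels == c].mean(axis=0)
            assert np.allclose(z.loc[c].to_numpy(), expected)

    def test_size_weighted_global_closure(self, std_matrix):
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 4, size=120)
        z = profiles.cluster_zscores(std_matrix, labels)
        sizes = pd.Series(labels).value_counts().sort_index()
        weighted = (z.mul(sizes, axis=0)).sum() / sizes.sum()
        assert np.allclose(weighted.to_numpy(), 0.0, atol=1e-9)

    def test_parent_frame_restandardises_within_supergroup(self, std_matrix):
        parents = np.repeat([0, 1], 60)
        groups = np.r_[np.arange(60) % 2, 2 + np.arange(60) % 2]
        z = profiles.cluster_zscores(
            std_matrix, groups, reference="parent", parent_labels=parents
        )
        # brute force for group 0 within parent 0
        sub = std_matrix.iloc[:60]
        sub_std = (sub - sub.mean()) / sub.std(ddof=0)
        expected = sub_std.to_numpy()[groups[:60] == 0].mean(axis=0)
        assert np.allclose(z.loc[0].to_numpy(), expected)
        # groups within one parent close to zero in parent-size weights
        sizes = pd.Series(groups[:60]).value_counts()
        weighted = (z.loc[[0, 1]].mul(sizes, axis=0)).sum() / sizes.sum()
        assert np.allclose(weighted.to_numpy(), 0.0, atol=1e-9)

    def test_parent_frame_requires_parent_labels(self, std_matrix):
        with pytest.raises(ValueError, match="parent_labels"):
            profiles.cluster_zscores(
                std_matrix, np.zeros(120), reference="parent"
            )


class TestOlderPersonRatio:
    def _pop(self, p65, p1864):
        return pd.DataFrame(
            {"area_id": ["A"], "pop_65_plus": [p65], "pop_18_64": [p1864]}
        )

    def test_arithmetic(self):
        assert profiles.older_person_ratio(self._pop(100, 400)).iloc[0] == pytest.approx(0.25)

    def test_zero_older_population(self):
        assert profiles.older_person_ratio(self._pop(0, 400)).iloc[0] == 0.0

    def test_zero_denominator_flagged_missing(self):
        out = profiles.older_person_ratio(self._pop(50, 0))
        assert np.isnan(out.iloc[0])


class TestSummaryTable:
    def _population(self, n, rng):
        return pd.DataFrame(
            {
                "area_id": [f"A{i}" for i in range(n)],
                "pop_50_plus": rng.integers(300, 900, n),
                "pop_65_plus": rng.integers(100, 300, n),
                "pop_18_64": rng.integers(500, 1200, n),
                "median_age": rng.uniform(30, 50, n),
            }
        )

    def _hier(self, pop, supergroups):
        return pd.DataFrame(
            {"area_id": pop["area_id"], "supergroup": supergroups}
        )

    def test_single_cluster_owns_everything(self):
        rng = np.random.default_rng(12)
        pop = self._population(10, rng)
        out = profiles.summary_table(pop, self._hier(pop, ["1"] * 10))
        assert out.loc["1", "pct_pop_50plus"] == pytest.approx(100.0)
        assert out.loc["1", "n_areas"] == 10

    def test_equal_population_split_is_50_50(self):
        pop = pd.DataFrame(
            {
                "area_id": ["A", "B"],
                "pop_50_plus": [500, 500],
                "pop_65_plus": [200, 100],
                "pop_18_64": [800, 800],
                "median_age": [40.0, 42.0],
            }
        )
        out = profiles.summary_table(pop, self._hier(pop, ["1", "2"]))
        assert np.allclose(out["pct_pop_50plus"], [50.0, 50.0])

    def test_matches_brute_force_aggregation(self):
        rng = np.random.default_rng(13)
        pop = self._population(60, rng)
        sg = rng.choice(["1", "2", "3"], size=60).tolist()
        out = profiles.summary_table(pop, self._hier(pop, sg))
        df = pop.assign(supergroup=sg)
        for code, sub in df.groupby("supergroup"):
            assert out.loc[code, "n_areas"] == len(sub)
            assert out.loc[code, "pct_pop_50plus"] == pytest.approx(
                100 * sub["pop_50_plus"].sum() / pop["pop_50_plus"].sum()
            )
            assert out.loc[code, "mean_median_age"] == pytest.approx(
                sub["median_age"].mean()
            )
            assert out.loc[code, "mean_older_person_ratio"] == pytest.approx(
                (sub["pop_65_plus"] / sub["pop_18_64"]).mean()
            )
        assert out["pct_pop_50plus"].sum() == pytest.approx(100.0, abs=0.1)
        assert out["n_areas"].sum() == 60


class TestExports:
    @pytest.fixture()
    def portraits(self):
        cat = variable_catalogue()
        rng = np.random.default_rng(14)
        return pd.DataFrame(
            rng.normal(size=(3, 71)),
            index=["1", "2", "3"],
            columns=cat.variable_ids,
        )

    def test_top_n_one_gives_one_per_domain_per_direction(self, portraits):
        cat = variable_catalogue()
        out = profiles.pen_portrait_export(portraits, cat, top_n=1)
        counts = out.groupby(["cluster", "domain", "direction"]).size()
        assert (counts == 1).all()
        assert len(out) == 3 * 9 * 2

    def test_tie_breaks_lexically(self):
        cat = variable_catalogue()
        tied = pd.DataFrame(
            0.0, index=["1"], columns=cat.variable_ids
        )
        out = profiles.pen_portrait_export(tied, cat, top_n=1)
        people_top = out[
            (out["domain"] == "People") & (out["direction"] == "top")
        ]["variable_id"].iloc[0]
        people_vars = sorted(
            cat.table.loc[cat.table["domain"] == "People", "variable_id"]
        )
        assert people_top == people_vars[0]

    def test_export_round_trips_through_csv(self, portraits, tmp_path):
        cat = variable_catalogue()
        out = profiles.pen_portrait_export(portraits, cat, top_n=2)
        path = tmp_path / "export.csv"
        out.to_csv(path, index=False)
        back = pd.read_csv(path, dtype={"cluster": str})
        pd.testing.assert_frame_equal(out.reset_index(drop=True), back)

    def test_radar_rows_are_variables_times_clusters(self, portraits):
        cat = variable_catalogue()
        radar = profiles.radar_data(portraits, cat)
        assert len(radar) == 71 * 3
        one = radar[(radar["cluster"] == "1") & (radar["domain"] == "Housing")]
        assert sorted(one["rank_in_domain"]) == list(range(1, 11))
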