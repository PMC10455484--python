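import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers_oracles import average_linkage_heights
from cypome.comparative import (average_linkage, cluster_rows_cols,
                                conserved_families, presence_matrix,
                                summary_stats, venn_partition)
from cypome.fixtures import load_fixture


class TestPresenceMatrix:
    def test_encoding(self):
        pm = presence_matrix(
            {"S1": ["CYP51"], "S2": ["CYP51", "CYP52"]},
            ["S1", "S2"], ["CYP51", "CYP52"])
        assert pm.loc["S1"].tolist() == [3, -3]
        assert pm.loc["S2"].tolist() == [3, 3]

    def test_no_assignments_all_absent(self):
        pm = presence_matrix({}, ["S1"], ["CYP51"])
        assert (pm == -3).all().all()

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            presence_matrix({"S9": ["CYP51"]}, ["S1"], ["CYP51"])

    def test_column_sums_match_family_species_counts(self, cohort):
        by_species = {
            s: list(sub[sub.family != "NEW"].family)
            for s, sub in cohort.truth[cohort.truth.category == "P450"]
            .groupby("species_id")
        }
        families = sorted({f for v in by_species.values() for f in v})
        pm = presence_matrix(by_species, sorted(by_species), families)
        present_counts = (pm == 3).sum(axis=0)
        for fam in families:
            expected = sum(fam in set(v) for v in by_species.values())
            assert present_counts[fam] == expected


class TestConservedFamilies:
    PM = None

    def _pm(self):
        return presence_matrix(
            {"S1": ["CYP51"], "S2": ["CYP51", "CYP52"]},
            ["S1", "S2"], ["CYP51", "CYP52"])

    def test_strict_conservation(self):
        assert conserved_families(self._pm(), 2) == {"CYP51"}

    def test_k_one_returns_all_present(self):
        assert conserved_families(self._pm(), 1) == {"CYP51", "CYP52"}

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            conserved_families(self._pm(), 0)

    def test_planted_conservation_structure(self, cohort):
        """A family planted in every species is found at k = n_species."""
        truth = cohort.truth[cohort.truth.category == "P450"]
        by_species = {
            s: list(sub[sub.family != "NEW"].family)
            for s, sub in truth.groupby("species_id")
        }
        families = sorted({f for v in by_species.values() for f in v})
        pm = presence_matrix(by_species, sorted(by_species), families)
        everywhere = {
            f for f in families
            if all(f in set(v) for v in by_species.values())
        }
        assert conserved_families(pm, len(by_species)) == everywhere


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        data = np.array([[3, 3, -3], [-3, -3, 3], [3, 3, -3]], dtype=float)
        z = average_linkage(data)
        assert z[0, 2] == pytest.approx(0.0)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 2}

    def test_merge_heights_match_bruteforce_oracle(self):
        """Average-linkage heights equal a recompute-from-scratch oracle on
        random presence/absence matrices up to 8x8."""
        rng = np.random.default_rng(0)
        for trial in range(25):
            n = int(rng.integers(3, 9))
            m = int(rng.integers(2, 9))
            data = rng.choice([-3.0, 3.0], size=(n, m))
            z = average_linkage(data)
            assert np.allclose(sorted(z[:, 2]),
                               sorted(average_linkage_heights(data)),
                               atol=1e-9), trial

    def test_matches_scipy_on_tie_free_matrix(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(3)
        data = rng.normal(size=(7, 5))
        z = average_linkage(data)
        z_ref = linkage(pdist(data), method="average")
        assert np.allclose(z[:, 2], z_ref[:, 2], atol=1e-9)

    def test_degenerate_single_row(self):
        pm = pd.DataFrame([[3, -3]], index=["S1"], columns=["F1", "F2"])
        rows, cols, rz, _ = cluster_rows_cols(pm)
        assert rows == ["S1"]
        assert rz is None

    def test_orderings_cover_all_labels(self, cohort):
        truth = cohort.truth[cohort.truth.category == "P450"]
        by_species = {
            s: list(sub[sub.family != "NEW"].family)
            for s, sub in truth.groupby("species_id")
        }
        families = sorted({f for v in by_species.values() for f in v})
        pm = presence_matrix(by_species, sorted(by_species), families)
        rows, cols, _, _ = cluster_rows_cols(pm)
        assert sorted(rows) == sorted(pm.index)
        assert sorted(cols) == sorted(pm.columns)


class TestVenn:
    def test_two_group_partition(self):
        vp = venn_partition({"SAP": {"A", "B"}, "ECM": {"B", "C"}})
        assert vp.shared_families == {"B"}
        assert vp.unique_to_group == {"SAP": {"A"}, "ECM": {"C"}}
        assert vp.group_totals == {"SAP": 2, "ECM": 2}

    def test_identical_sets_nothing_unique(self):
        vp = venn_partition({"SAP": {"A"}, "ECM": {"A"}})
        assert vp.unique_to_group == {"SAP": set(), "ECM": set()}
        assert vp.shared_families == {"A"}

    def test_empty_group_map_rejected(self):
        with pytest.raises(ValueError):
            venn_partition({})

    @given(st.integers(0, 10_000))
    def test_union_identity_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"F{i}" for i in range(30)]
        a = {f for f in universe if rng.random() < 0.4}
        b = {f for f in universe if rng.random() < 0.4}
        vp = venn_partition({"SAP": a, "ECM": b})
        assert len(a | b) == (vp.group_totals["SAP"]
                              + vp.group_totals["ECM"]
                              - len(vp.shared_families))
        assert vp.union_size == len(a | b)


class TestSummaryStats:
    def test_published_cohort_statistics(self):
        t4 = load_fixture("table4")
        t5 = load_fixture("table5")
        stats = summary_stats(t4, "p450s", family_counts=t5)
        assert stats.overall.total == 668
        assert stats.overall.mean == 35
        assert stats.overall.max_count == 58
        assert stats.overall.argmax_species == "Ascim1"
        assert stats.overall.min_count == 17
        assert stats.overall.argmin_species == "Tercla1"
        assert stats.per_group["SAP"].mean == 41
        assert stats.per_group["ECM"].mean == 33

    def test_bloom_families(self):
        t4 = load_fixture("table4")
        t5 = load_fixture("table5")
        stats = summary_stats(t4, "p450s", family_counts=t5)
        assert stats.bloom_families == ["CYP567", "CYP6001", "CYP52",
                                        "CYP5959"]

    def test_family_and_subfamily_means(self):
        t4 = load_fixture("table4")
        t6 = load_fixture("table6").merge(t4[["species_id", "lifestyle"]])
        fam = summary_stats(t6, "n_families")
        sub = summary_stats(t6, "n_subfamilies")
        assert fam.overall.mean == 26
        assert fam.overall.max_count == 40   # W. mikolae
        assert fam.overall.min_count == 14   # T. claveryi
        # 580/19 = 30.53 rounds half-away to 31
        assert sub.overall.mean == 31

    def test_single_species_degenerate(self):
        df = pd.DataFrame({"species_id": ["S1"], "lifestyle": ["SAP"],
                           "p450s": [7]})
        stats = summary_stats(df, "p450s")
        assert (stats.overall.mean == stats.overall.min_count
                == stats.overall.max_count == 7)

    def test_missing_lifestyle_rejected(self):
        df = pd.DataFrame({"species_id": ["S1"], "lifestyle": [None],
                           "p450s": [7]})
        with pytest.raises(ValueError):
            summary_stats(df, "p450s")
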