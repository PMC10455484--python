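import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers_oracles import gotoh_score
from cypome.io import ProteinRecord
from cypome.nomenclature import (NamedReference, assign, assign_p450s,
                                 global_align, percent_identity)
from cypome.phylo import read_newick
from cypome.synthetic import make_reference_set, mutate_to_band, SyntheticSpec

AA = list("ACDEFGHIKLMNPQRSTVWY")


class TestCypNames:
    def test_full_name_decomposes(self):
        ref = NamedReference("CYP52A3", "MKLV")
        assert ref.family == "CYP52"
        assert ref.subfamily_letter == "A"

    def test_family_only_name(self):
        ref = NamedReference("CYP5093", "MKLV")
        assert ref.family == "CYP5093"
        assert ref.subfamily_letter is None

    def test_invalid_name_rejected(self):
        with pytest.raises(ValueError, match="CYP name"):
            NamedReference("P450-52A3", "MKLV")


class TestGlobalAlign:
    def test_identical_sequences(self):
        res = global_align("HEAGAWGHEE", "HEAGAWGHEE")
        assert "-" not in res.aligned_a + res.aligned_b
        assert res.identity_pct == 100.0

    def test_single_substitution(self):
        res = global_align("ACDEFGHIK", "ACNEFGHIK")
        assert res.identity_pct == pytest.approx(100 * 8 / 9)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            global_align("AAAA", "")

    def test_scores_match_dp_oracle(self):
        """Aligner scores equal an independent Gotoh dynamic program on
        50 random pairs of length <= 40."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            la, lb = rng.integers(5, 41, size=2)
            a = "".join(rng.choice(AA, la))
            b = "".join(rng.choice(AA, lb))
            assert global_align(a, b).score == pytest.approx(
                gotoh_score(a, b), abs=1e-9)


class TestPercentIdentity:
    def test_ten_substitutions_on_hundred(self):
        rng = np.random.default_rng(7)
        s = "".join(rng.choice(AA, 100))
        t = list(s)
        for p in rng.choice(100, size=10, replace=False):
            t[p] = "W" if t[p] != "W" else "Y"
        assert percent_identity(s, "".join(t)) == pytest.approx(90.0)

    def test_prefix_full_identity_under_terminal_gap_exclusion(self):
        rng = np.random.default_rng(7)
        s = "".join(rng.choice(AA, 100))
        assert percent_identity(s, s[:50]) == pytest.approx(100.0)

    def test_internal_deletion_counts_in_denominator(self):
        rng = np.random.default_rng(9)
        s = "".join(rng.choice(AA, 100))
        deleted = s[:50] + s[55:]
        assert percent_identity(s, deleted) == pytest.approx(95.0)

    @given(st.integers(0, 10_000))
    def test_symmetry_and_self_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(AA, int(rng.integers(5, 60))))
        b = "".join(rng.choice(AA, int(rng.integers(5, 60))))
        assert percent_identity(a, a) == 100.0
        assert percent_identity(a, b) == pytest.approx(
            percent_identity(b, a))


@pytest.fixture(scope="module")
def founders():
    refs, protected = make_reference_set(
        SyntheticSpec(seed=21, n_founder_families=2))
    a = NamedReference("CYP52A3", refs[0].sequence)
    b = NamedReference("CYP52B1", refs[1].sequence)
    return a, b, protected[refs[0].cyp_name]


class TestAssign:
    def _query(self, founders, band, seed):
        a, _, protected = founders
        rng = np.random.default_rng(seed)
        seq = mutate_to_band(a.sequence, band, rng, protected)
        return ProteinRecord("query1", "S1", seq)

    def test_high_identity_keeps_subfamily(self, founders):
        a, b, _ = founders
        q = self._query(founders, (68.0, 72.0), seed=1)
        res = assign(q, [a, b])
        assert res.family_label == "CYP52"
        assert res.subfamily_label == "A"
        assert res.best_reference == "CYP52A3"
        assert not res.is_new_family

    def test_mid_identity_keeps_family_only(self, founders):
        a, b, _ = founders
        q = self._query(founders, (43.0, 47.0), seed=2)
        res = assign(q, [a, b])
        assert res.family_label == "CYP52"
        assert res.subfamily_label == "NEW"
        assert not res.is_new_family

    def test_low_identity_founds_new_family(self, founders):
        a, b, _ = founders
        q = self._query(founders, (25.0, 32.0), seed=3)
        res = assign(q, [a, b])
        assert res.is_new_family
        assert res.family_label == "NEWFAM1"

    def test_new_family_labels_count_in_query_order(self, founders):
        a, b, _ = founders
        q1 = self._query(founders, (25.0, 32.0), seed=4)
        q2 = ProteinRecord("query2", "S1",
                           self._query(founders, (25.0, 32.0), seed=5)
                           .sequence)
        out = assign_p450s([q1, q2], [a, b])
        assert [o.family_label for o in out] == ["NEWFAM1", "NEWFAM2"]

    def test_borderline_resolved_by_tree(self, founders):
        a, b, _ = founders
        q = self._query(founders, (53.5, 55.0), seed=6)
        plain = assign(q, [a, b])
        assert plain.borderline
        tree = read_newick(
            "((query1:0.1,CYP52B1:0.1):0.3,(CYP52A3:0.1,OUT1:0.1):0.3);")
        res = assign(q, [a, b], tree=tree)
        assert res.borderline
        assert res.subfamily_label == "B"
        assert res.family_label == "CYP52"

    def test_empty_reference_set_errors(self, founders):
        q = self._query(founders, (68.0, 72.0), seed=7)
        with pytest.raises(ValueError, match="empty"):
            assign(q, [])


def test_band_members_recover_planted_labels(cohort, cohort_assignments):
    """Members generated in the same-subfamily band get family+subfamily;
    family-band members get family only; low-band members found new
    families.  Bands avoid the thresholds, so recovery must be total."""
    truth = cohort.truth.set_index("protein_id")
    by_id = {a.query_id: a for a in cohort_assignments}
    for pid, row in truth[truth.category == "P450"].iterrows():
        a = by_id[pid]
        if row.band == "same_subfamily":
            assert a.family_label == row.family
            assert a.subfamily_label == "A"
        elif row.band == "same_family":
            assert a.family_label == row.family
            assert a.subfamily_label == "NEW"
        else:
            assert a.is_new_family
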