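import pytest
from hypothesis import given, settings, strategies as st

from indelred.grouping import GroupingConfig, cluster_candidates
from indelred.io_model import ComputationError, IndelType, ReferenceGenome
from indelred.redundancy import (
    apply_indel,
    build_variant_pair,
    find_clusters,
    nonredundant_records,
    pair_redundant,
    summarize,
)

from conftest import rec


class TestBuildVariantPair:
    def test_insertion_branch(self, ref8):
        # CA insertions at pos 2 and 4 on GCACACAG share the variant "CACA"
        pair = build_variant_pair(rec("a", 2, "INS", "CA"), rec("b", 4, "INS", "CA"), ref8)
        assert pair.template == "CA"
        assert pair.v_a == "CACA" == pair.v_b

    def test_deletion_branch(self, ref8):
        a, b = rec("a", 3, "DEL", "A", "chr2"), rec("b", 6, "DEL", "A", "chr2")
        pair = build_variant_pair(a, b, ref8)
        assert pair.template == "AAAA"
        assert pair.v_a == "AAA" == pair.v_b

    def test_equal_positions_empty_insertion_template(self, ref8):
        pair = build_variant_pair(rec("a", 3, "INS", "TT"), rec("b", 3, "INS", "TT"), ref8)
        assert pair.template == "" and pair.v_a == "TT" == pair.v_b

    def test_length_invariants(self, ref8):
        ins = build_variant_pair(rec("a", 2, "INS", "CA"), rec("b", 6, "INS", "GG"), ref8)
        assert len(ins.v_a) == len(ins.v_b) == len(ins.template) + 2
        dele = build_variant_pair(
            rec("a", 3, "DEL", "AA", "chr2"), rec("b", 5, "DEL", "AA", "chr2"), ref8
        )
        assert len(dele.v_a) == len(dele.v_b) == len(dele.template) - 2

    def test_precondition_violation(self, ref8):
        with pytest.raises(ComputationError):
            build_variant_pair(rec("a", 2, "INS", "CA"), rec("b", 4, "DEL", "CA"), ref8)


class TestPairRedundant:
    def test_shifted_repeat_insertions_are_redundant(self, ref8):
        assert pair_redundant(rec("a", 2, "INS", "CA"), rec("b", 4, "INS", "CA"), ref8)

    def test_distinct_deletions_not_redundant(self):
        ref = ReferenceGenome({"chr1": "ACGT"})
        assert not pair_redundant(rec("a", 2, "DEL", "C"), rec("b", 3, "DEL", "G"), ref)

    def test_reflexive(self, ref8):
        r = rec("a", 3, "DEL", "A", "chr2")
        assert pair_redundant(r, r, ref8)

    def test_symmetric_under_argument_order(self, ref8):
        a, b = rec("a", 2, "INS", "CA"), rec("b", 4, "INS", "CA")
        assert pair_redundant(a, b, ref8) == pair_redundant(b, a, ref8)

    def test_mismatched_type_or_length_defined_false(self, ref8):
        assert not pair_redundant(rec("a", 2, "INS", "CA"), rec("b", 4, "DEL", "CA"), ref8)
        assert not pair_redundant(rec("a", 2, "INS", "CA"), rec("b", 4, "INS", "C"), ref8)


class TestApplyIndel:
    def test_insertion(self):
        ref = ReferenceGenome({"chr1": "ACGT"})
        assert apply_indel(rec("a", 3, "INS", "TT"), ref) == "ACTTGT"

    def test_deletion(self):
        ref = ReferenceGenome({"chr1": "ACGT"})
        assert apply_indel(rec("a", 2, "DEL", "CG"), ref) == "AT"

    def test_deletion_allele_mismatch_raises(self):
        ref = ReferenceGenome({"chr1": "ACGT"})
        with pytest.raises(ComputationError, match="does not match"):
            apply_indel(rec("a", 2, "DEL", "GG"), ref)

    def test_delete_then_reinsert_restores_reference(self, ref8):
        deleted = apply_indel(rec("a", 3, "DEL", "AA", "chr2"), ref8)
        restored = apply_indel(
            rec("b", 3, "INS", "AA", "chr2"), ReferenceGenome({"chr2": deleted})
        )
        assert restored == ref8.sequence("chr2")

    def test_insertion_at_end_appends(self):
        ref = ReferenceGenome({"chr1": "ACGT"})
        assert apply_indel(rec("a", 5, "INS", "TT"), ref) == "ACGTTT"


# --- the module's central theorem: template comparison == full-sequence oracle

repeatish_seq = st.builds(
    lambda parts: "".join(parts)[:80] or "A",
    st.lists(
        st.one_of(
            st.text(alphabet="ACGT", min_size=1, max_size=6),
            st.builds(
                lambda unit, n: unit * n,
                st.text(alphabet="ACGT", min_size=1, max_size=3),
                st.integers(2, 8),
            ),
        ),
        min_size=1,
        max_size=12,
    ),
)


@settings(max_examples=400, derandomize=True)
@given(
    seq=repeatish_seq,
    data=st.data(),
    is_ins=st.booleans(),
    length=st.integers(1, 4),
)
def test_oracle_equivalence_property(seq, data, is_ins, length):
    """Template-substring redundancy agrees with full-sequence comparison."""
    ref = ReferenceGenome({"c": seq})
    n = len(seq)
    if is_ins:
        pos_a = data.draw(st.integers(1, n + 1))
        pos_b = data.draw(st.integers(pos_a, n + 1))
        allele_a = data.draw(st.text(alphabet="ACGT", min_size=length, max_size=length))
        allele_b = data.draw(st.text(alphabet="ACGT", min_size=length, max_size=length))
        a = rec("a", pos_a, "INS", allele_a, "c")
        b = rec("b", pos_b, "INS", allele_b, "c")
    else:
        if n < length:
            return
        pos_a = data.draw(st.integers(1, n - length + 1))
        pos_b = data.draw(st.integers(pos_a, n - length + 1))
        a = rec("a", pos_a, "DEL", seq[pos_a - 1 : pos_a - 1 + length], "c")
        b = rec("b", pos_b, "DEL", seq[pos_b - 1 : pos_b - 1 + length], "c")
    assert pair_redundant(a, b, ref) == (apply_indel(a, ref) == apply_indel(b, ref))


class TestFindClusters:
    def test_transitive_chain_forms_one_cluster(self):
        ref = ReferenceGenome({"chr1": "TT" + "A" * 10 + "TT"})
        records = [rec(f"d{i}", 3 + i, "DEL", "A") for i in range(3)]
        groups = cluster_candidates(records, GroupingConfig(100))
        clusters = find_clusters(groups, ref)
        assert len(clusters) == 1 and len(clusters[0]) == 3
        assert clusters[0].representative.id == "d0"

    def test_non_redundant_group_yields_no_cluster(self):
        ref = ReferenceGenome({"chr1": "ACGTACGT"})
        records = [rec("a", 2, "DEL", "C"), rec("b", 3, "DEL", "G")]
        groups = cluster_candidates(records, GroupingConfig(100))
        assert find_clusters(groups, ref) == []

    def test_two_disjoint_pairs_in_one_group(self):
        # AAA at 3-5 and CCC at 9-11: 1-bp DELs inside each run are
        # equivalent within the run but not across runs.
        ref = ReferenceGenome({"chr1": "GT" + "AAA" + "GTC" + "CCC" + "GT"})
        records = [
            rec("a1", 3, "DEL", "A"), rec("a2", 4, "DEL", "A"),
            rec("c1", 9, "DEL", "C"), rec("c2", 10, "DEL", "C"),
        ]
        groups = cluster_candidates(records, GroupingConfig(100))
        assert len(groups) == 1 and len(groups[0]) == 4
        clusters = find_clusters(groups, ref)
        assert [len(c) for c in clusters] == [2, 2]
        assert {c.representative.id for c in clusters} == {"a1", "c1"}

    def test_input_order_invariance(self, ref8):
        records = [rec("a", 2, "INS", "CA"), rec("b", 4, "INS", "CA"),
                   rec("c", 6, "INS", "CA")]
        groups_fwd = cluster_candidates(records, GroupingConfig(100))
        groups_rev = cluster_candidates(records[::-1], GroupingConfig(100))
        ids = lambda cl: [[m.id for m in c.members] for c in cl]
        assert ids(find_clusters(groups_fwd, ref8)) == ids(find_clusters(groups_rev, ref8))


class TestSummarize:
    def _clustered(self, sizes):
        clusters = []
        pos = 1
        from indelred.redundancy import RedundancyCluster

        for i, size in enumerate(sizes):
            members = [rec(f"c{i}m{j}", pos + j, "DEL", "A") for j in range(size)]
            clusters.append(RedundancyCluster(i, members))
            pos += 100
        return clusters

    def test_rate_definition(self):
        all_indels = [rec(f"x{i}", 1000 + i * 10, "DEL", "A") for i in range(5)]
        clusters = self._clustered([3, 2])
        for c in clusters:
            all_indels.extend(c.members)
        report = summarize(clusters, all_indels, GroupingConfig(100))
        assert report.overall.total == 10
        assert report.overall.redundant == 3
        assert report.overall.rate == pytest.approx(0.30)

    def test_no_clusters_zero_rates(self):
        report = summarize([], [rec("a", 1, "INS", "T")], GroupingConfig(100))
        assert report.overall.rate == 0.0 and report.ins.rate == 0.0

    def test_all_in_one_cluster_limit(self):
        clusters = self._clustered([6])
        report = summarize(clusters, clusters[0].members, GroupingConfig(100))
        assert report.overall.rate == pytest.approx(5 / 6)

    def test_per_type_totals_sum_to_overall(self):
        all_indels = [rec("i1", 5, "INS", "T"), rec("d1", 9, "DEL", "A"),
                      rec("d2", 11, "DEL", "A")]
        report = summarize([], all_indels, GroupingConfig(100))
        assert report.ins.total + report.dels.total == report.overall.total == 3


def test_nonredundant_records_keeps_representatives(ref8):
    records = [rec("a", 2, "INS", "CA"), rec("b", 4, "INS", "CA"),
               rec("z", 8, "DEL", "G")]
    groups = cluster_candidates(records, GroupingConfig(100))
    clusters = find_clusters(groups, ref8)
    kept = nonredundant_records(clusters, records)
    assert [r.id for r in kept] == ["a", "z"]
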