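import pytest

from lncterplay.interplay import common_pathways, mode_breakdown, overlap_analysis
from lncterplay.types import (
    DEResult,
    EnrichmentResult,
    GeneSetCollection,
    TargetPair,
    ValidationError,
)


def enr(set_id, p_perm):
    return EnrichmentResult(set_id=set_id, overlap=5, set_size=10, query_size=10,
                            universe_size=100, p_hypergeom=p_perm,
                            p_permutation=p_perm, q_value=p_perm)


def de(feature_id, direction):
    fc = {"up": 3.0, "down": 1 / 3.0, "unchanged": 1.0}[direction]
    return DEResult(feature_id=feature_id, mean_control=10, mean_case=10 * fc,
                    fold_change=fc, log2_fc=0.0, p_value=0.01, q_value=0.02,
                    direction=direction)


class TestCommonPathways:
    def test_intersection_of_significant(self):
        et = [enr("A", 0.01), enr("B", 0.2), enr("C", 0.03)]
        em = [enr("A", 0.04), enr("B", 0.01), enr("C", 0.3)]
        assert common_pathways(et, em) == {"A"}

    def test_disjoint_significance_empty(self):
        et = [enr("A", 0.01), enr("B", 0.5)]
        em = [enr("A", 0.5), enr("B", 0.01)]
        assert common_pathways(et, em) == set()

    def test_mismatched_collections_error(self):
        with pytest.raises(ValidationError):
            common_pathways([enr("A", 0.01)], [enr("B", 0.01)])


def scaled_fixture():
    """Five predicted targets, six DE mRNAs, five overlapping, four pairs
    concordant and one opposite — a scaled analog of a common-pathway
    integration with a handful of genes."""
    genes = [f"G{i}" for i in range(1, 8)]
    genesets = GeneSetCollection(sets={"P1": set(genes)})
    pairs = [
        TargetPair("L1", "G1", "cis", distance=100, lnc_direction="up"),
        TargetPair("L2", "G2", "cis", distance=50, lnc_direction="down"),
        TargetPair("L3", "G3", "trans", energy=-25.0, lnc_direction="up"),
        TargetPair("L4", "G4", "trans", energy=-30.0, lnc_direction="up"),
        TargetPair("L5", "G5", "trans", energy=-22.0, lnc_direction="down"),
    ]
    des = [
        de("G1", "up"),        # concordant with L1
        de("G2", "down"),      # concordant with L2
        de("G3", "up"),        # concordant with L3
        de("G4", "down"),      # opposite to L4
        de("G5", "down"),      # concordant with L5
        de("G6", "up"),        # DE mRNA but not a target
        de("G7", "unchanged"),
    ]
    return genesets, pairs, des


class TestOverlapAnalysis:
    def test_scaled_fixture_counts_exact(self):
        genesets, pairs, des = scaled_fixture()
        rep = overlap_analysis({"P1"}, pairs, des, genesets)
        assert (rep.n_targets, rep.n_mrnas, rep.n_overlap) == (5, 6, 5)
        assert (rep.n_same_direction, rep.n_opposite) == (4, 1)
        assert rep.n_cis_pairs + rep.n_trans_pairs == rep.n_overlap_pairs == 5
        assert mode_breakdown(rep) == {"P1": (2, 3)}

    def test_no_common_pathways_all_zero(self):
        genesets, pairs, des = scaled_fixture()
        rep = overlap_analysis(set(), pairs, des, genesets)
        assert (rep.n_targets, rep.n_mrnas, rep.n_overlap,
                rep.n_same_direction, rep.n_opposite) == (0, 0, 0, 0, 0)

    def test_up_up_pair_is_concordant(self):
        genesets = GeneSetCollection(sets={"P": {"G1"}})
        pairs = [TargetPair("L1", "G1", "cis", distance=1, lnc_direction="up")]
        rep = overlap_analysis({"P"}, pairs, [de("G1", "up")], genesets)
        assert (rep.n_same_direction, rep.n_opposite) == (1, 0)

    def test_unchanged_gene_excluded_from_concordance(self):
        genesets = GeneSetCollection(sets={"P": {"G1", "G2"}})
        pairs = [
            TargetPair("L1", "G1", "cis", distance=1, lnc_direction="up"),
        ]
        # G1 is a target but not DE: target-only, no concordance pair
        rep = overlap_analysis({"P"}, pairs, [de("G1", "unchanged"),
                                              de("G2", "up")], genesets)
        assert rep.n_targets == 1 and rep.n_mrnas == 1
        assert rep.n_overlap == 0
        assert rep.n_same_direction + rep.n_opposite == 0

    def test_pair_without_direction_error(self):
        genesets = GeneSetCollection(sets={"P": {"G1"}})
        with pytest.raises(ValidationError):
            overlap_analysis({"P"}, [TargetPair("L1", "G1", "cis", distance=1)],
                             [de("G1", "up")], genesets)

    def test_gene_label_permutation_invariance(self):
        genesets, pairs, des = scaled_fixture()
        rep = overlap_analysis({"P1"}, pairs, des, genesets)
        relabel = {f"G{i}": f"X{i * 7 % 13}" for i in range(1, 8)}
        genesets2 = GeneSetCollection(
            sets={"P1": {relabel[g] for g in genesets["P1"]}}
        )
        pairs2 = [
            TargetPair(p.lnc_id, relabel[p.gene_id], p.mode, p.distance,
                       p.energy, p.lnc_direction)
            for p in pairs
        ]
        des2 = [
            DEResult(relabel[r.feature_id], r.mean_control, r.mean_case,
                     r.fold_change, r.log2_fc, r.p_value, r.q_value, r.direction)
            for r in des
        ]
        rep2 = overlap_analysis({"P1"}, pairs2, des2, genesets2)
        assert (rep.n_targets, rep.n_mrnas, rep.n_overlap, rep.n_overlap_pairs,
                rep.n_same_direction, rep.n_opposite, rep.n_cis_pairs,
                rep.n_trans_pairs) == (
            rep2.n_targets, rep2.n_mrnas, rep2.n_overlap, rep2.n_overlap_pairs,
            rep2.n_same_direction, rep2.n_opposite, rep2.n_cis_pairs,
            rep2.n_trans_pairs,
        )

    def test_gene_in_two_pathways_counted_once_globally(self):
        genesets = GeneSetCollection(sets={"P1": {"G1"}, "P2": {"G1"}})
        pairs = [TargetPair("L1", "G1", "cis", distance=1, lnc_direction="up")]
        rep = overlap_analysis({"P1", "P2"}, pairs, [de("G1", "up")], genesets)
        assert rep.n_overlap == 1          # gene-level, deduplicated
        assert rep.n_overlap_pairs == 2    # pair-level, per pathway
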