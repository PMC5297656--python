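import numpy as np
import pytest

from lncterplay.duplex import duplex_mfe
from lncterplay.synthetic import (
    SimulationConfig,
    simulate_annotation,
    simulate_dataset,
    simulate_de_benchmark,
    simulate_expression,
    simulate_genesets,
    simulate_sequences,
)
from lncterplay.targets import interval_gap
from lncterplay.types import SimulationTruth, ValidationError


def nearest_gene_gap(lnc, annotation):
    return min(
        interval_gap(lnc.start, lnc.end, g.start, g.end)
        for g in annotation.genes
        if g.chrom == lnc.chrom
    ) if any(g.chrom == lnc.chrom for g in annotation.genes) else None


class TestSimulateAnnotation:
    def test_requested_cis_fraction_planted(self):
        ann, truth = simulate_annotation(n_genes=40, n_lncrnas=10,
                                         cis_fraction=0.5, seed=0)
        assert len(truth.cis_pairs) == 5
        for lnc_id, gene_id in truth.cis_pairs:
            lnc, gene = ann[lnc_id], ann[gene_id]
            assert lnc.chrom == gene.chrom
            assert interval_gap(lnc.start, lnc.end, gene.start, gene.end) <= 10_000

    def test_non_cis_lncrnas_beyond_window(self):
        ann, truth = simulate_annotation(n_genes=40, n_lncrnas=10,
                                         cis_fraction=0.5, window=10_000, seed=1)
        cis_lncs = {l for l, _ in truth.cis_pairs}
        for lnc in ann.lncrnas:
            if lnc.feature_id in cis_lncs:
                continue
            gap = nearest_gene_gap(lnc, ann)
            assert gap is None or gap >= 10_001

    def test_same_seed_identical(self):
        a1, t1 = simulate_annotation(30, 8, seed=5)
        a2, t2 = simulate_annotation(30, 8, seed=5)
        assert t1.cis_pairs == t2.cis_pairs
        assert [(f.feature_id, f.chrom, f.start, f.end) for f in a1] == [
            (f.feature_id, f.chrom, f.start, f.end) for f in a2
        ]

    def test_chromosome_too_short_error(self):
        with pytest.raises(ValidationError, match="too short"):
            simulate_annotation(50, 5, n_chroms=1, chrom_length=100_000, seed=0)


@pytest.fixture(scope="module")
def ann_truth():
    return simulate_annotation(n_genes=20, n_lncrnas=6, n_chroms=3,
                               cis_fraction=0.0, seed=3)


class TestSimulateSequences:
    def test_planted_pair_clears_screen_cutoff(self, ann_truth):
        ann, truth = ann_truth
        lnc = next(l for l in ann.lncrnas if l.chrom == "chr1")
        gene = next(g for g in ann.genes if g.chrom == "chr2")
        seqs, truth = simulate_sequences(
            ann, [(lnc.feature_id, gene.feature_id)], duplex_len=25, seed=0,
            truth=truth,
        )
        energy = duplex_mfe(seqs[lnc.feature_id], seqs[gene.feature_id]).energy
        assert energy < -20
        assert (lnc.feature_id, gene.feature_id) in truth.trans_pairs

    def test_same_chromosome_request_is_error(self, ann_truth):
        ann, truth = ann_truth
        lnc = next(l for l in ann.lncrnas if l.chrom == "chr1")
        gene = next(g for g in ann.genes if g.chrom == "chr1")
        with pytest.raises(ValidationError, match="same-chromosome"):
            simulate_sequences(ann, [(lnc.feature_id, gene.feature_id)], seed=0)

    def test_non_planted_random_pairs_stay_above_cutoff(self, ann_truth):
        ann, _ = ann_truth
        for seed in range(20):
            seqs, _ = simulate_sequences(ann, [], seed=seed)
            lnc = ann.lncrnas[seed % len(ann.lncrnas)]
            gene = ann.genes[seed % len(ann.genes)]
            e = duplex_mfe(seqs[lnc.feature_id], seqs[gene.feature_id]).energy
            assert e > -20

    def test_duplex_len_minimum_enforced(self, ann_truth):
        ann, _ = ann_truth
        with pytest.raises(ValidationError):
            simulate_sequences(ann, [], duplex_len=10, seed=0)

    def test_same_seed_identical(self, ann_truth):
        ann, _ = ann_truth
        s1, _ = simulate_sequences(ann, [], seed=9)
        s2, _ = simulate_sequences(ann, [], seed=9)
        assert s1 == s2


@pytest.fixture(scope="module")
def ann():
    return simulate_annotation(n_genes=30, n_lncrnas=5, seed=0)[0]


class TestSimulateExpression:
    def test_noise_free_limit_recovers_planted_fold_change(self, ann):
        truth = SimulationTruth(seed=0, de_up={"G0001"}, de_down={"G0002"})
        m = simulate_expression(ann, truth, noise_sd_log2=1e-9, seed=1)
        case = m.group_columns("case")
        control = m.group_columns("control")
        i_up = m.probe_ids.index("G0001")
        i_dn = m.probe_ids.index("G0002")
        assert case[i_up].mean() / control[i_up].mean() == pytest.approx(4.0, rel=1e-6)
        assert case[i_dn].mean() / control[i_dn].mean() == pytest.approx(0.25, rel=1e-6)

    def test_null_feature_ratio_near_one_at_large_n(self, ann):
        truth = SimulationTruth(seed=0)
        m = simulate_expression(ann, truth, n_per_group=200, seed=2)
        ratios = m.group_columns("case").mean(axis=1) / m.group_columns("control").mean(axis=1)
        assert np.allclose(ratios, 1.0, atol=0.1)

    def test_strictly_positive(self, ann):
        m = simulate_expression(ann, SimulationTruth(seed=0), seed=3)
        assert np.all(m.values > 0)

    def test_too_few_replicates_error(self, ann):
        with pytest.raises(ValidationError, match="n_per_group"):
            simulate_expression(ann, SimulationTruth(seed=0), n_per_group=1)

    def test_same_seed_identical(self, ann):
        truth = SimulationTruth(seed=0, de_up={"G0003"})
        m1 = simulate_expression(ann, truth, seed=4)
        m2 = simulate_expression(ann, truth, seed=4)
        assert np.array_equal(m1.values, m2.values)


class TestSimulateGenesets:
    def test_planted_set_contains_planted_targets(self, small_dataset):
        ds = small_dataset
        (enriched_id,) = ds.truth.enriched_set_ids
        de = ds.truth.de_up | ds.truth.de_down
        planted = {g for _, g in ds.truth.cis_pairs | ds.truth.trans_pairs
                   if g in de}
        members = ds.genesets[enriched_id]
        assert len(members & planted) >= len(members) // 2

    def test_set_size_cap_error(self):
        ann, truth = simulate_annotation(n_genes=5, n_lncrnas=2, seed=0)
        with pytest.raises(ValidationError):
            simulate_genesets(ann, truth, n_sets=3, set_size=10, seed=0)

    def test_same_seed_identical(self):
        ann, truth = simulate_annotation(n_genes=30, n_lncrnas=5, seed=0)
        g1 = simulate_genesets(ann, truth, n_sets=5, set_size=6, seed=2)
        g2 = simulate_genesets(ann, truth, n_sets=5, set_size=6, seed=2)
        assert g1.sets == g2.sets


class TestSimulateDataset:
    def test_truth_internally_consistent(self, small_dataset):
        truth = small_dataset.truth
        assert not (truth.de_up & truth.de_down)
        truth.validate(small_dataset.annotation)
        # every planted lncRNA is deregulated, so its targets are groupable
        for lnc, _ in truth.cis_pairs | truth.trans_pairs:
            assert lnc in truth.de_up | truth.de_down

    def test_deterministic_in_seed(self):
        cfg = SimulationConfig(n_genes=60, n_lncrnas=10, n_trans_pairs=2,
                               n_sets=5, set_size=8)
        d1 = simulate_dataset(cfg, seed=3)
        d2 = simulate_dataset(cfg, seed=3)
        assert d1.truth.to_json_dict() == d2.truth.to_json_dict()
        assert d1.sequences == d2.sequences
        assert np.array_equal(d1.matrix.values, d2.matrix.values)
        assert d1.genesets.sets == d2.genesets.sets

    def test_different_seeds_differ(self):
        cfg = SimulationConfig(n_genes=60, n_lncrnas=10, n_trans_pairs=2,
                               n_sets=5, set_size=8)
        d1 = simulate_dataset(cfg, seed=3)
        d2 = simulate_dataset(cfg, seed=4)
        assert not np.array_equal(d1.matrix.values, d2.matrix.values)


class TestDEBenchmark:
    def test_planted_counts_and_determinism(self):
        m1, t1, _ = simulate_de_benchmark(n_de=10, n_genes=200, n_lncrnas=20,
                                          seed=6)
        m2, t2, _ = simulate_de_benchmark(n_de=10, n_genes=200, n_lncrnas=20,
                                          seed=6)
        assert len(t1.de_up) == 5 and len(t1.de_down) == 5
        assert t1.de_up == t2.de_up and np.array_equal(m1.values, m2.values)
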