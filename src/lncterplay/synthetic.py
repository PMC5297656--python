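"""Synthetic two-group lncRNA/mRNA datasets with planted ground truth.

The generators emulate the design of a two-group (n = 4 vs 4) liver
microarray study at desk scale: log-normal intensity noise around a
common baseline, planted two-fold (in log2: +/-2) expression changes in
the case group, lncRNAs placed within or beyond a 10 kbp genomic window
of genes (planted cis pairs), engineered reverse-complement windows
between lncRNAs and mRNAs on different chromosomes (planted trans
pairs), and one gene set preferentially populated with planted target
genes (planted enrichment).  Every generator is a pure function of its
arguments including the seed.

Defaults are the package's reference study conditions: 300 genes and 50
lncRNAs on 5 chromosomes, half the lncRNAs cis-planted, 10 trans pairs
with 25-nt complementary windows, lncRNA transcripts of 200 nt and mRNA
transcripts of 150 nt, baseline intensity 2^8 with sigma = 0.25 log2
noise, and 20 gene sets of 20 genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .duplex import duplex_mfe, default_params, EnergyParams
from .types import (
    BIOTYPE_LNCRNA,
    BIOTYPE_MRNA,
    ExpressionMatrix,
    Feature,
    FeatureAnnotation,
    GeneSetCollection,
    GROUP_CASE,
    GROUP_CONTROL,
    SimulationTruth,
    ValidationError,
)

__all__ = [
    "simulate_annotation",
    "simulate_sequences",
    "simulate_expression",
    "simulate_genesets",
    "simulate_de_benchmark",
    "simulate_dataset",
    "SimulationConfig",
    "SyntheticDataset",
]

_RNA = np.array(list("ACGU"))
_RC = str.maketrans("ACGU", "UGCA")

GENE_LEN = 2000        # genomic span of a synthetic gene locus, nt
LNC_LOCUS_LEN = 500    # genomic span of a synthetic lncRNA locus, nt


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_annotation(
    n_genes: int,
    n_lncrnas: int,
    n_chroms: int = 5,
    window: int = 10_000,
    cis_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
    chrom_length: int = 50_000_000,
) -> tuple[FeatureAnnotation, SimulationTruth]:
    """Lay out genes and lncRNAs so the cis rule is decidable by construction.

    Genes are spaced more than two windows apart, cis-planted lncRNAs sit
    within ``window`` of exactly one gene, and the remaining lncRNAs sit
    beyond ``window`` of every gene.  Truth records the planted cis pairs.
    """
    if n_genes < 1 or n_lncrnas < 1:
        raise ValidationError("need at least one gene and one lncRNA")
    if window <= 0:
        raise ValidationError("window must be positive")
    if not (0 <= cis_fraction <= 1):
        raise ValidationError("cis_fraction must be in [0, 1]")
    rng = _rng(seed)
    seed_int = seed if isinstance(seed, int) else -1
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    cursors = {c: 1000 for c in chroms}
    features: list[Feature] = []
    genes: list[Feature] = []
    for g in range(n_genes):
        chrom = chroms[g % n_chroms]
        start = cursors[chrom]
        gene = Feature(
            feature_id=f"G{g + 1:04d}", biotype=BIOTYPE_MRNA, chrom=chrom,
            start=start, end=start + GENE_LEN, strand="+" if rng.random() < 0.5 else "-",
        )
        genes.append(gene)
        features.append(gene)
        gap = int(rng.integers(2 * window + 2000, 4 * window))
        cursors[chrom] = gene.end + gap
        if cursors[chrom] > chrom_length:
            raise ValidationError(
                f"{chrom} too short ({chrom_length} nt) to honor gene spacing"
            )
    n_cis = int(round(cis_fraction * n_lncrnas))
    if n_cis > n_genes:
        raise ValidationError("more cis lncRNAs requested than genes available")
    truth = SimulationTruth(seed=seed_int)
    host_idx = rng.choice(n_genes, size=n_cis, replace=False)
    for i in range(n_lncrnas):
        lnc_id = f"L{i + 1:04d}"
        if i < n_cis:
            host = genes[int(host_idx[i])]
            d = int(rng.integers(100, window - LNC_LOCUS_LEN))
            start = host.end + d
            lnc = Feature(
                feature_id=lnc_id, biotype=BIOTYPE_LNCRNA, chrom=host.chrom,
                start=start, end=start + LNC_LOCUS_LEN,
                strand="+" if rng.random() < 0.5 else "-",
            )
            truth.cis_pairs.add((lnc_id, host.feature_id))
        else:
            chrom = chroms[i % n_chroms]
            start = cursors[chrom] + window + 1 + int(rng.integers(500, 5000))
            lnc = Feature(
                feature_id=lnc_id, biotype=BIOTYPE_LNCRNA, chrom=chrom,
                start=start, end=start + LNC_LOCUS_LEN,
                strand="+" if rng.random() < 0.5 else "-",
            )
            cursors[chrom] = lnc.end + int(rng.integers(1000, 3000))
            if cursors[chrom] > chrom_length:
                raise ValidationError(
                    f"{chrom} too short ({chrom_length} nt) to honor lncRNA spacing"
                )
        features.append(lnc)
    annotation = FeatureAnnotation(features)
    truth.validate(annotation)
    return annotation, truth


def _random_seq(n: int, rng: np.random.Generator, p=None) -> str:
    return "".join(rng.choice(_RNA, size=n, p=p))


def simulate_sequences(
    annotation: FeatureAnnotation,
    trans_pairs_requested: list[tuple[str, str]],
    duplex_len: int = 25,
    seed: int | np.random.Generator = 0,
    lnc_len: int = 200,
    mrna_len: int = 150,
    decoy_pairs: list[tuple[str, str]] = (),
    params: EnergyParams | None = None,
    margin_energy: float = -25.0,
    truth: SimulationTruth | None = None,
) -> tuple[dict[str, str], SimulationTruth]:
    """i.i.d. uniform transcripts with engineered complementary windows.

    Each requested trans pair (which must be inter-chromosomal) gets a
    GC-biased ``duplex_len``-mer window in the mRNA whose reverse
    complement is embedded in the lncRNA; the construction is verified
    against the duplex scorer and resampled (bounded retries) until the
    hybrid clears ``margin_energy``, so planted pairs pass the screening
    cutoff by construction and not by luck.  ``decoy_pairs`` plant the
    same complementarity on the SAME chromosome (for exercising the
    exclusion rule) and are recorded separately in the truth.
    """
    if duplex_len < 15:
        raise ValidationError("duplex_len must be >= 15")
    rng = _rng(seed)
    if params is None:
        params = default_params()
    if truth is None:
        truth = SimulationTruth(seed=seed if isinstance(seed, int) else -1)
    seqs: dict[str, str] = {}
    for f in annotation:
        n = lnc_len if f.biotype == BIOTYPE_LNCRNA else mrna_len
        seqs[f.feature_id] = _random_seq(n, rng)

    def plant(lnc_id: str, gene_id: str, want_same_chrom: bool) -> None:
        lnc_f, gene_f = annotation[lnc_id], annotation[gene_id]
        if lnc_f.biotype != BIOTYPE_LNCRNA or gene_f.biotype != BIOTYPE_MRNA:
            raise ValidationError(f"pair ({lnc_id}, {gene_id}) has wrong biotypes")
        same = lnc_f.chrom == gene_f.chrom
        if want_same_chrom and not same:
            raise ValidationError(
                f"decoy pair ({lnc_id}, {gene_id}) must share a chromosome"
            )
        if not want_same_chrom and same:
            raise ValidationError(
                f"trans pair ({lnc_id}, {gene_id}) lies on one chromosome "
                "(would be excluded by the same-chromosome rule)"
            )
        for _ in range(20):
            win = _random_seq(duplex_len, rng, p=[0.2, 0.3, 0.3, 0.2])
            gpos = int(rng.integers(0, mrna_len - duplex_len + 1))
            lpos = int(rng.integers(0, lnc_len - duplex_len + 1))
            m = seqs[gene_id]
            l = seqs[lnc_id]
            new_m = m[:gpos] + win + m[gpos + duplex_len:]
            new_l = l[:lpos] + win[::-1].translate(_RC) + l[lpos + duplex_len:]
            if duplex_mfe(new_l, new_m, params).energy < margin_energy:
                seqs[gene_id] = new_m
                seqs[lnc_id] = new_l
                return
        raise ValidationError(
            f"could not engineer a strong duplex for ({lnc_id}, {gene_id})"
        )

    for lnc_id, gene_id in trans_pairs_requested:
        plant(lnc_id, gene_id, want_same_chrom=False)
        truth.trans_pairs.add((lnc_id, gene_id))
    for lnc_id, gene_id in decoy_pairs:
        plant(lnc_id, gene_id, want_same_chrom=True)
        truth.decoy_pairs.add((lnc_id, gene_id))
    truth.validate(annotation)
    return seqs, truth


def simulate_expression(
    annotation: FeatureAnnotation,
    truth: SimulationTruth,
    n_per_group: int = 4,
    base_log2_mean: float = 8.0,
    noise_sd_log2: float = 0.25,
    effect_log2: float = 2.0,
    seed: int | np.random.Generator = 0,
    low_base_log2: float = 1.5,
) -> ExpressionMatrix:
    """Log-normal intensity matrix with planted case-group shifts.

    intensity = 2^(base + group_effect + eps), eps ~ N(0, noise_sd_log2).
    Features in ``truth.de_up`` get +effect_log2 in case samples,
    ``truth.de_down`` get -effect_log2; controls sit at baseline.
    ``truth.low_intensity`` features use ``low_base_log2`` instead of the
    main baseline so the low-intensity filter has real work to do.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2 (t-test undefined below)")
    if effect_log2 < 0:
        raise ValidationError("effect_log2 must be >= 0")
    if noise_sd_log2 <= 0:
        raise ValidationError("noise_sd_log2 must be > 0")
    rng = _rng(seed)
    probe_ids = [f.feature_id for f in annotation]
    case_ids = [f"case_{i + 1}" for i in range(n_per_group)]
    control_ids = [f"control_{i + 1}" for i in range(n_per_group)]
    sample_ids = case_ids + control_ids
    groups = {s: GROUP_CASE for s in case_ids} | {s: GROUP_CONTROL for s in control_ids}
    base = np.full(len(probe_ids), base_log2_mean)
    shift = np.zeros(len(probe_ids))
    for i, pid in enumerate(probe_ids):
        if pid in truth.low_intensity:
            base[i] = low_base_log2
        if pid in truth.de_up:
            shift[i] = effect_log2
        elif pid in truth.de_down:
            shift[i] = -effect_log2
    log2_vals = base[:, None] + rng.normal(0, noise_sd_log2, (len(probe_ids), 2 * n_per_group))
    log2_vals[:, : n_per_group] += shift[:, None]
    return ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        groups=groups,
        values=np.power(2.0, log2_vals),
    )


def simulate_genesets(
    annotation: FeatureAnnotation,
    truth: SimulationTruth,
    n_sets: int = 20,
    set_size: int = 20,
    seed: int | np.random.Generator = 0,
    planted_fraction: float = 0.75,
) -> GeneSetCollection:
    """Gene sets over the gene universe with one planted enriched set.

    The first set is preferentially populated (``planted_fraction`` of its
    size, availability permitting) with planted DE target genes; the rest
    are uniform draws.  Truth records the enriched set id.
    """
    universe = sorted(f.feature_id for f in annotation.genes)
    if set_size > len(universe):
        raise ValidationError("set_size exceeds the number of genes")
    rng = _rng(seed)
    de = truth.de_up | truth.de_down
    planted_targets = sorted(
        {g for _, g in truth.cis_pairs | truth.trans_pairs if g in de}
    )
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    enriched_id = "GS01"
    n_plant = min(len(planted_targets), int(round(planted_fraction * set_size)))
    members = (
        {str(x) for x in rng.choice(planted_targets, size=n_plant, replace=False)}
        if n_plant else set()
    )
    rest = [g for g in universe if g not in members]
    filler = rng.choice(rest, size=set_size - len(members), replace=False)
    sets[enriched_id] = members | {str(x) for x in filler}
    names[enriched_id] = "planted enriched pathway"
    for s in range(1, n_sets):
        sid = f"GS{s + 1:02d}"
        sets[sid] = {str(x) for x in rng.choice(universe, size=set_size, replace=False)}
        names[sid] = f"background pathway {s + 1}"
    truth.enriched_set_ids.add(enriched_id)
    return GeneSetCollection(sets=sets, names=names, universe=set(universe))


def simulate_de_benchmark(
    n_de: int = 20,
    n_genes: int = 2000,
    n_lncrnas: int = 100,
    n_per_group: int = 4,
    noise_sd_log2: float = 0.25,
    effect_log2: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth, FeatureAnnotation]:
    """Sparse-DE matrix for fold-change/t-test parameter recovery.

    Plants ``n_de`` deregulated features (half up, half down) in an
    otherwise null matrix — the sparse regime of real arrays, where a few
    percent of probes change at most.  Quantile normalization mixes the
    extreme ranks of case and control columns, so at desk scale a planted
    4-fold change reads as roughly 2.3-fold after normalization; recovery
    against the two-fold rule is only meaningful when the deregulated
    features are a small minority, as they are on a real array.
    """
    root = np.random.SeedSequence(seed)
    s_ann, s_pick, s_expr = [np.random.default_rng(c) for c in root.spawn(3)]
    annotation, truth = simulate_annotation(n_genes, n_lncrnas, seed=s_ann)
    truth.seed = seed
    truth.cis_pairs.clear()
    ids = [f.feature_id for f in annotation]
    de = s_pick.choice(ids, size=n_de, replace=False)
    for i, f in enumerate(de):
        (truth.de_up if i % 2 == 0 else truth.de_down).add(str(f))
    matrix = simulate_expression(
        annotation, truth, n_per_group=n_per_group,
        noise_sd_log2=noise_sd_log2, effect_log2=effect_log2, seed=s_expr,
    )
    return matrix, truth, annotation


@dataclass
class SimulationConfig:
    """Reference study conditions for the end-to-end synthetic dataset."""

    n_genes: int = 300
    n_lncrnas: int = 50
    n_chroms: int = 5
    window: int = 10_000
    cis_fraction: float = 0.5
    n_trans_pairs: int = 10
    n_decoy_pairs: int = 0
    duplex_len: int = 25
    lnc_len: int = 200
    mrna_len: int = 150
    n_per_group: int = 4
    base_log2_mean: float = 8.0
    noise_sd_log2: float = 0.25
    effect_log2: float = 2.0
    n_sets: int = 20
    set_size: int = 20
    n_extra_de_lnc: int = 5
    n_extra_de_mrna: int = 20
    concordant_fraction: float = 0.85
    discordant_fraction: float = 0.10
    low_intensity_fraction: float = 0.05


@dataclass
class SyntheticDataset:
    annotation: FeatureAnnotation
    sequences: dict[str, str]
    genesets: GeneSetCollection
    matrix: ExpressionMatrix
    truth: SimulationTruth
    config: SimulationConfig = field(default_factory=SimulationConfig)


def simulate_dataset(
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Full dataset: annotation, sequences, gene sets, expression, truth.

    Direction assignment: every lncRNA with a planted cis or trans pair is
    deregulated (up/down with equal probability); each of its target genes
    changes in the same direction with probability ``concordant_fraction``,
    the opposite direction with ``discordant_fraction``, and stays
    unchanged otherwise.  A few extra lncRNAs and mRNAs without planted
    pairs are also deregulated, and a fraction of unplanted features is
    assigned a low baseline.
    """
    cfg = config or SimulationConfig()
    root = np.random.SeedSequence(seed)
    s_ann, s_pair, s_seq, s_dir, s_gs, s_expr, s_low = [
        np.random.default_rng(c) for c in root.spawn(7)
    ]
    annotation, truth = simulate_annotation(
        cfg.n_genes, cfg.n_lncrnas, cfg.n_chroms, cfg.window,
        cfg.cis_fraction, seed=s_ann,
    )
    truth.seed = seed
    # choose trans pairs among lncRNAs without a cis partner, targeting genes
    # on other chromosomes that are not already cis targets
    cis_lncs = {l for l, _ in truth.cis_pairs}
    cis_genes = {g for _, g in truth.cis_pairs}
    free_lncs = [f for f in annotation.lncrnas if f.feature_id not in cis_lncs]
    free_genes = [f for f in annotation.genes if f.feature_id not in cis_genes]
    if cfg.n_trans_pairs > len(free_lncs):
        raise ValidationError("not enough cis-free lncRNAs for trans pairs")
    trans_pairs: list[tuple[str, str]] = []
    lnc_choice = s_pair.choice(len(free_lncs), size=cfg.n_trans_pairs, replace=False)
    used_genes: set[str] = set()
    for li in lnc_choice:
        lnc = free_lncs[int(li)]
        candidates = [
            g for g in free_genes
            if g.chrom != lnc.chrom and g.feature_id not in used_genes
        ]
        if not candidates:
            raise ValidationError("no inter-chromosomal gene left for a trans pair")
        gene = candidates[int(s_pair.integers(0, len(candidates)))]
        used_genes.add(gene.feature_id)
        trans_pairs.append((lnc.feature_id, gene.feature_id))
    decoys: list[tuple[str, str]] = []
    if cfg.n_decoy_pairs:
        pool = [
            (l.feature_id, g.feature_id)
            for l in annotation.lncrnas for g in annotation.genes
            if l.chrom == g.chrom and l.feature_id not in cis_lncs
            and (l.feature_id, g.feature_id) not in truth.cis_pairs
        ]
        idx = s_pair.choice(len(pool), size=cfg.n_decoy_pairs, replace=False)
        decoys = [pool[int(i)] for i in idx]
    sequences, truth = simulate_sequences(
        annotation, trans_pairs, cfg.duplex_len, seed=s_seq,
        lnc_len=cfg.lnc_len, mrna_len=cfg.mrna_len,
        decoy_pairs=decoys, truth=truth,
    )
    # direction assignment
    planted_pairs = sorted(truth.cis_pairs | truth.trans_pairs)
    planted_lncs = sorted({l for l, _ in planted_pairs})
    lnc_dir = {l: ("up" if s_dir.random() < 0.5 else "down") for l in planted_lncs}
    for lnc, d in lnc_dir.items():
        (truth.de_up if d == "up" else truth.de_down).add(lnc)
    for lnc, gene in planted_pairs:
        if gene in truth.de_up or gene in truth.de_down:
            continue
        u = s_dir.random()
        if u < cfg.concordant_fraction:
            d = lnc_dir[lnc]
        elif u < cfg.concordant_fraction + cfg.discordant_fraction:
            d = "down" if lnc_dir[lnc] == "up" else "up"
        else:
            continue
        (truth.de_up if d == "up" else truth.de_down).add(gene)
    unplanted_lncs = [
        f.feature_id for f in annotation.lncrnas
        if f.feature_id not in truth.de_up | truth.de_down
    ]
    for l in s_dir.choice(unplanted_lncs, size=min(cfg.n_extra_de_lnc, len(unplanted_lncs)), replace=False):
        (truth.de_up if s_dir.random() < 0.5 else truth.de_down).add(str(l))
    planted_genes = {g for _, g in planted_pairs}
    unplanted_genes = [
        f.feature_id for f in annotation.genes
        if f.feature_id not in truth.de_up | truth.de_down | planted_genes
    ]
    for g in s_dir.choice(unplanted_genes, size=min(cfg.n_extra_de_mrna, len(unplanted_genes)), replace=False):
        (truth.de_up if s_dir.random() < 0.5 else truth.de_down).add(str(g))
    # low-intensity probes among fully unplanted features
    touched = truth.de_up | truth.de_down | {x for p in planted_pairs for x in p}
    quiet = [f.feature_id for f in annotation if f.feature_id not in touched]
    n_low = int(round(cfg.low_intensity_fraction * len(annotation)))
    truth.low_intensity = {
        str(x) for x in s_low.choice(quiet, size=min(n_low, len(quiet)), replace=False)
    }
    genesets = simulate_genesets(
        annotation, truth, cfg.n_sets, cfg.set_size, seed=s_gs,
    )
    matrix = simulate_expression(
        annotation, truth, cfg.n_per_group, cfg.base_log2_mean,
        cfg.noise_sd_log2, cfg.effect_log2, seed=s_expr,
    )
    truth.validate(annotation)
    return SyntheticDataset(
        annotation=annotation, sequences=sequences, genesets=genesets,
        matrix=matrix, truth=truth, config=cfg,
    )
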