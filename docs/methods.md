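# Methods

This note documents the models implemented in `lncterplay`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical conventions that matter for reproducing
results.

## Study design being emulated

The pipeline reproduces a common integrative design for intensity
microarrays: two groups (disease vs control, n = 4 per group), probe-level
intensities for both lncRNAs and mRNAs, a fold-change + t-test rule for
calling deregulation, positional (cis) and hybridization-based (trans)
lncRNA target prediction, gene-set over-representation of the predicted
targets, and an integration step asking which pathways are implicated by
both the lncRNA and the mRNA layers and whether targets move with or
against their lncRNAs. All thresholds that define the reference analysis
are surfaced as configuration with these defaults:

| parameter | default | units | role |
|---|---|---|---|
| `lnc_intensity` / `mrna_intensity` | 5 / 6 | raw intensity | low-intensity probe filter |
| `fc` | 2 | ratio | fold-change threshold ("two-fold") |
| `alpha` | 0.05 | — | t-test and permutation significance |
| `window` | 10 000 | nt | cis window around the lncRNA locus |
| `energy_cutoff` | −20 | kcal/mol | trans duplex screen (strict `<`) |
| `n_perm` | 1000 | draws | permutation p-value resolution |

## Preprocessing

**Low-intensity filter.** A probe is kept iff
`max(mean(case), mean(control)) ≥ threshold` for its biotype, computed on
raw intensities, before normalization; the kept set defines the matrix
that is normalized. The max-of-group-means aggregation preserves probes
expressed in only one condition — exactly the biologically interesting
case — rather than demanding every sample clear the bar. The boundary is
inclusive. Filtering before normalization reflects the filter's purpose
(removing unreliable probes from the analysis altogether); both the
order and the aggregation are package conventions, exposed as config.

**Quantile normalization.** Each column's value at rank *r* is replaced
by the mean over columns of the *r*-th order statistics. Ties within a
column receive the mean of the row-means across their tied ranks (the
same convention as limma's `normalizeQuantiles(ties=TRUE)`, against which
the implementation is cross-checked on tie-free data). Two consequences
worth knowing:

- With ties present, the strict "all columns share one multiset"
  property and exact idempotence hold only up to the tie-averaging; on
  continuous data both are exact.
- **Effect attenuation at small scale.** The row-mean at an extreme rank
  averages the planted case values with the control noise extremes, so a
  true 4-fold change reads as ≈ 2.3-fold after normalization. On a real
  array (tens of thousands of probes, ≲ 1 % deregulated) the attenuation
  is mild; on a few-hundred-probe matrix with a quarter of probes
  deregulated it is strong enough to push down-changes against the
  two-fold boundary. This is a property of quantile normalization, not of
  the caller; it is why the differential-expression recovery benchmark
  uses a ~2000-probe matrix with ~1 % planted changes (the realistic
  regime), while the end-to-end synthetic pipeline — which needs a dense
  planting to exercise every downstream stage — simply reports its
  attenuated counts.

## Differential expression

Fold change is the ratio of arithmetic group means on the linear
intensity scale; the t-test is the two-sided pooled-variance (Student's)
test computed on log2 intensities, matching the log-normal noise model.
A feature is *up* iff FC ≥ `fc` and p < `alpha`, *down* symmetrically for
FC ≤ 1/`fc`; the fold-change boundary is inclusive by default
(configurable). No multiple-testing correction enters the call;
Benjamini–Hochberg q-values are reported alongside. Degenerate inputs
follow fixed conventions: zero pooled variance gives p = 1 for equal
means and p = 0 otherwise.

## Duplex energy model (trans screen)

The trans screen scores the best intermolecular hybrid between a lncRNA
and an mRNA transcript, ignoring intramolecular structure — the design of
fast RNA–RNA interaction scanners. The energy of a hybrid is

```
E = duplex_init + Σ stacks + Σ loop penalties + terminal AU/GU penalties
```

over a chain of canonical pairs (AU, UA, CG, GC, GU, UG; `N` never
pairs) whose positions increase along strand A and decrease along strand
B. Adjacent pairs contribute a nearest-neighbor stacking term; a gap of
`la`/`lb` unpaired bases (each ≤ `max_loop` = 15) contributes an affine
penalty: bulges (one side empty) cost `bulge_open + bulge_extend·(l−1)`,
interior loops cost `interior_open + interior_extend·(la+lb−2)`. The
terminal penalty applies at both helix ends (twice for a single-pair
hybrid). If no canonical pair exists the energy is +∞ with an empty
pairing.

The dynamic program fills `E[i,j]` = best energy of a hybrid whose
3′-most pair on strand A is `(a_i, b_j)`, in O(|a|·|b|·max_loop) time via
row-wise vectorized minima with per-row loop aggregates; a batch mode
scores one lncRNA against many candidate windows simultaneously. mRNAs
longer than 300 nt are chunked into overlapping windows (300 nt, 150
overlap) and the window minimum taken — hybrids spanning a window
boundary may be missed, an accepted approximation of the screen.
The traceback reconstructs the optimal pairing by re-evaluating
predecessor candidates at tolerance 1e-9; energies are rounded to 10
decimals so the batch and single-pair paths agree exactly at the strict
cutoff comparison.

**Parameter set** (versioned JSON, `data/nn_energy_v1.json`). The
screening table uses the Xia et al. (1998) Watson–Crick nearest-neighbor
free energies scaled to 70 %, near-neutral wobble-containing stacks
(−0.3 kcal/mol, 0 for the weakest motif), `duplex_init` = 4.09,
terminal AU/GU penalty 0.45, bulge 5.5 + 0.9/nt and interior 6.5 + 0.9/nt.
The scaling and stiff loop costs make the scorer deliberately
*conservative*: at the package's transcript scale (200-nt lncRNAs,
150-nt mRNAs), chance hybrids between uniform random sequences stay well
above the −20 kcal/mol cutoff (empirically ≈ −6 mean, ≈ −17 extreme over
>10³ random pairs), while engineered full 25-mer complements score −28
to −43. With an unscaled thermodynamic table, chance complementary runs
at transcriptome scale cross −20 frequently — which is precisely why
screens on real transcriptomes return tens of thousands of candidates —
and a planted/background separation suitable for recovery testing would
not exist. The energies are therefore *screen scores under a pinned
model*, not thermodynamic predictions; the table is overridable via
`EnergyParams`. The DP is verified against exhaustive enumeration of all
pairing chains for short sequences.

## Target assignment

- **cis**: a gene is a cis target iff the gap between the gene locus and
  the lncRNA locus (0 if they overlap) is ≤ `window` on the same
  chromosome — inclusive boundary, either strand, window measured from
  both ends of the full locus rather than the TSS. With half-open
  coordinates the gap between `[s1,e1)` and `[s2,e2)` is
  `max(0, max(s1,s2) − min(e1,e2))`.
- **trans**: screen hits below the cutoff with same-chromosome genes
  removed (genomic proximity would confound a hybridization-based call);
  the candidate universe is every annotated mRNA on other chromosomes.
- Targets of each deregulated lncRNA are organized into four groups:
  {cis, trans} × {lncRNA up, lncRNA down}; pairs whose lncRNA is not
  deregulated are dropped with a logged count.

## Enrichment

Over-representation only (upper tail). For a query of size *n* drawn
from a universe of size *N*, a set with *K* members in the universe and
overlap *k*: the hypergeometric p is the exact tail `P(X ≥ k)`, and the
permutation p is `(1 + #{uniform same-size redraws with overlap ≥ k}) /
(1 + n_perm)` — the add-one convention bounds p below by 1/(1+n_perm)
and keeps the test valid. One independent RNG stream is spawned per gene
set so results do not depend on evaluation order. Significance is keyed
to the permutation p (< 0.05 strict); BH q-values over the
hypergeometric p are reported but not used for calling. Backgrounds: the
predicted-target analysis uses all annotated genes; the mRNA analysis
uses the filtered mRNA features. Both are configuration, since the
choice of universe is the classic silent degree of freedom in enrichment
analysis.

## Interplay

Common pathways are those significant in both enrichment analyses.
Within them the report counts target genes, DE mRNA genes and their
gene-level overlap, and separately counts (lncRNA, gene) *pairs*:
overlap is deduplicated at the gene level, but concordance is judged per
pair — a gene reached by two lncRNAs contributes two concordance pairs,
and a pair whose gene direction is `unchanged` is excluded (direction
undefined). A pair is concordant iff the gene's DE direction equals its
lncRNA's. Per-pathway cis/trans tallies always sum to the pathway's
overlap-pair count (asserted at construction).

## Synthetic data

The generators are pure functions of their arguments including the seed
(numpy `SeedSequence` spawning per stage).

- **Annotation**: genes laid out round-robin over 5 chromosomes with
  inter-gene gaps > 2 windows, so a cis-planted lncRNA (placed at a gap
  of 100 … window−500 nt from its host gene) is within the window of
  exactly one gene, and non-cis lncRNAs (placed > window beyond the last
  gene) are within the window of none. The cis rule is therefore
  decidable by construction, and recovery is exact rather than lucky.
- **Sequences**: i.i.d. uniform ACGU transcripts (lncRNA 200 nt — the
  definitional minimum length for the class — mRNA 150 nt, desk-scale
  stand-ins for kilobase transcripts). Each requested trans pair embeds
  a GC-biased 25-mer window in the mRNA and its reverse complement in
  the lncRNA; the construction is verified against the duplex scorer and
  resampled (≤ 20 tries) until it clears −25 kcal/mol, so planted pairs
  beat the −20 cutoff by construction. Same-chromosome "decoy" pairs can
  be planted the same way to exercise the exclusion rule.
- **Expression**: `intensity = 2^(base + effect + ε)`,
  `ε ~ N(0, 0.25)` in log2, baseline 2^8, planted features shifted
  ±2 log2 units in case samples only (controls at baseline, matching the
  case/control fold-change convention). About 5 % of unplanted features
  get a low baseline (2^1.5 ≈ 2.8, below both filter thresholds) so the
  low-intensity filter has real work end-to-end.
- **Gene sets**: 20 sets of 20 genes; the first is filled to 75 % with
  planted deregulated target genes (availability permitting), the rest
  uniform.
- **Dataset orchestration**: 300 genes + 50 lncRNAs (the reference
  scale), 25 cis pairs (cis_fraction 0.5), 10 trans pairs among cis-free
  lncRNAs targeting distinct genes on other chromosomes. Every planted
  lncRNA is deregulated (up/down equiprobable); each of its targets
  moves concordantly with probability 0.85, discordantly 0.10, else
  stays unchanged; 5 extra lncRNAs and 20 extra mRNAs are deregulated
  without planted pairs.

**What the generators do not emulate**: vendor probe-level artifacts
(spatial effects, dye bias, background), probe redundancy per gene
(probe→feature is one-to-one), transcript isoforms, correlated noise
between samples, realistic sequence composition, or GO-style nested gene
sets. Passing recovery tests therefore demonstrates the pipeline's
correctness under its own model assumptions, not performance on real
arrays.

## Problem sizes and runtime

The reference pipeline (300 genes, 50 lncRNAs, 4 vs 4, 1000
permutations) runs in well under a minute on one CPU; the recovery
benchmarks use 20 seeds each (DE: 2100 probes per seed; trans screen: 60
random background pairs; duplex-vs-enumeration: 200 pairs ≤ 8 nt;
permutation accuracy: 10⁵ draws × 5 configurations). These sizes were
chosen to make every planted/background separation decisive while
keeping any single check in seconds.

## Known limitations

- Quantile normalization attenuates large effects at small matrix scale
  (see above); headline counts from the dense end-to-end planting are
  attenuated accordingly.
- Duplex energies are pinned screen scores, not thermodynamics, and the
  windowed screen can miss boundary-spanning hybrids.
- The cis rule is purely positional; no expression correlation, no
  strand or TSS logic.
- Enrichment treats gene sets as flat (no GO DAG propagation) and the
  permutation scheme is the package's own definition of "permuted
  p-value".
- The concordance report states direction agreement, not mechanism or
  causality.
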