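"""Local gene-set over-representation analysis.

For each gene set the overlap with a query gene list is scored two ways:
an exact upper-tail hypergeometric p-value (urn model: draw the query
without replacement from the universe) and an empirical permutation
p-value from uniform same-size redraws of the query, with the add-one
convention p = (1 + #{overlap >= observed}) / (1 + n_perm).  Significance
is keyed to the permutation p-value; Benjamini-Hochberg q-values over the
hypergeometric p-values are reported but not used for calling.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import EnrichmentResult, GeneSetCollection, ValidationError

__all__ = ["hypergeom_p", "permutation_p", "enrich"]


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); exact tail sum.

    ``N`` universe size, ``K`` gene-set size, ``n`` query size, ``k``
    observed overlap.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValidationError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def permutation_p(
    query: set[str],
    gene_set: set[str],
    universe: set[str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for the overlap of ``query`` with ``gene_set``.

    Permuted queries are uniform same-size draws without replacement from
    the universe; p = (1 + #{overlap >= observed}) / (1 + n_perm), so
    p >= 1/(1+n_perm) always.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    query = set(query)
    if len(query) > len(universe):
        raise ValidationError("query larger than universe")
    query &= universe
    if not query:
        raise ValidationError("query has no genes in the universe")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uni = np.array(sorted(universe))
    in_set = np.isin(uni, sorted(gene_set & universe))
    observed = len(query & gene_set)
    n = len(query)
    # draw n_perm subsets of size n as the smallest-n entries of random keys
    count = 0
    chunk = max(1, min(n_perm, int(2e7 // max(len(uni), 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, len(uni)))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        count += int((in_set[idx].sum(axis=1) >= observed).sum())
        done += m
    return (1 + count) / (1 + n_perm)


def enrich(
    query_genes,
    genesets: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Score every gene set against a query; sorted by hypergeometric p.

    Duplicate query genes are deduplicated; query genes outside the
    universe are ignored.  One independent permutation stream per gene set
    is spawned from ``seed`` so results do not depend on set order.
    """
    query = set(query_genes) & set(universe)
    if not query:
        raise ValidationError("query and universe are disjoint")
    universe = set(universe)
    N, n = len(universe), len(query)
    results = []
    p_hyp = []
    set_ids = sorted(genesets.sets)
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.spawn(len(set_ids))
    for sid, child in zip(set_ids, child_seeds):
        members = genesets[sid] & universe
        K = len(members)
        k = len(query & members)
        ph = hypergeom_p(k, K, n, N) if K else 1.0
        pp = (
            permutation_p(query, members, universe, n_perm=n_perm,
                          seed=np.random.default_rng(child))
            if K
            else 1.0
        )
        p_hyp.append(ph)
        results.append((sid, k, K, ph, pp))
    q_values = multipletests(np.array(p_hyp), method="fdr_bh")[1] if results else []
    out = [
        EnrichmentResult(
            set_id=sid,
            overlap=k,
            set_size=K,
            query_size=n,
            universe_size=N,
            p_hypergeom=ph,
            p_permutation=pp,
            q_value=float(q),
        )
        for (sid, k, K, ph, pp), q in zip(results, q_values)
    ]
    out.sort(key=lambda r: (r.p_hypergeom, r.set_id))
    return out


def significant_sets(results: list[EnrichmentResult], alpha: float = 0.05) -> set[str]:
    """Set ids whose permutation p-value is below alpha (strict)."""
    return {r.set_id for r in results if r.p_permutation < alpha}
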