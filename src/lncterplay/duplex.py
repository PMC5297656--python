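"""Intermolecular RNA-RNA hybridization minimum-free-energy scoring.

A simplified nearest-neighbor duplex model in the spirit of fast
RNA-RNA interaction scanners (RNAplex, RNAhybrid): intramolecular
structure on either strand is ignored, and the hybrid free energy is

    E = duplex_init
        + sum of stacking terms over adjacent base pairs
        + sum of affine bulge / interior-loop penalties
        + terminal AU/GU penalties at both helix ends.

Base pairs are the six canonical RNA pairs (AU, UA, CG, GC, GU, UG);
``N`` never pairs.  Pair positions increase along strand A and decrease
along strand B (antiparallel hybrid).  The dynamic program fills
``E[i, j]`` = best energy of a hybrid whose 3'-most pair on strand A is
(a_i, b_j), extending by stacking (adjacent pair) or by a bulge/interior
loop of up to ``max_loop`` unpaired bases per side.

The energy parameter set is a versioned JSON data file shipped with the
package (``data/nn_energy_v1.json``); all values can be overridden by
constructing an :class:`EnergyParams` by hand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

from .types import RNA_ALPHABET, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["EnergyParams", "DuplexResult", "duplex_mfe", "screen_candidates",
           "default_params"]

_BASES = "ACGUN"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
_PAIRS = ("AU", "UA", "CG", "GC", "GU", "UG")
_PAIR_INDEX = {p: i for i, p in enumerate(_PAIRS)}

INF = float("inf")


@dataclass(frozen=True)
class EnergyParams:
    """Nearest-neighbor duplex energy parameters (kcal/mol)."""

    stack_energy: dict[str, float]   # "XY>ZW" -> kcal/mol
    duplex_init: float
    au_gu_end_penalty: float
    bulge_open: float
    bulge_extend: float
    interior_open: float
    interior_extend: float
    max_loop: int
    version: str = "custom"

    def __post_init__(self) -> None:
        if self.max_loop < 1:
            raise ValidationError("max_loop must be >= 1")
        for key, val in self.stack_energy.items():
            if val > 0:
                raise ValidationError(f"stack energy {key} must be <= 0, got {val}")
        for name in ("bulge_open", "bulge_extend", "interior_open",
                     "interior_extend"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    # -- derived lookup tables (cached per instance via object identity) --

    def _tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return _build_tables(self)


@lru_cache(maxsize=8)
def _build_tables_cached(key: tuple) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    stack_items, end_pen = key[0], key[1]
    stack_map = dict(stack_items)
    # pair_idx[a_code, b_code] -> pair index or -1
    pair_idx = np.full((5, 5), -1, dtype=np.int8)
    for p, i in _PAIR_INDEX.items():
        pair_idx[_BASE_CODE[p[0]], _BASE_CODE[p[1]]] = i
    stack = np.full((6, 6), INF)
    for k, v in stack_map.items():
        left, right = k.split(">")
        stack[_PAIR_INDEX[left], _PAIR_INDEX[right]] = v
    ends = np.zeros(6)
    for p in ("AU", "UA", "GU", "UG"):
        ends[_PAIR_INDEX[p]] = end_pen
    return pair_idx, stack, ends


def _build_tables(params: EnergyParams):
    key = (tuple(sorted(params.stack_energy.items())), params.au_gu_end_penalty)
    return _build_tables_cached(key)


@lru_cache(maxsize=1)
def default_params() -> EnergyParams:
    """The packaged versioned parameter set."""
    text = resources.files("lncterplay").joinpath("data/nn_energy_v1.json").read_text()
    d = json.loads(text)
    return EnergyParams(
        stack_energy=d["stack_energy"],
        duplex_init=d["duplex_init"],
        au_gu_end_penalty=d["au_gu_end_penalty"],
        bulge_open=d["bulge_open"],
        bulge_extend=d["bulge_extend"],
        interior_open=d["interior_open"],
        interior_extend=d["interior_extend"],
        max_loop=d["max_loop"],
        version=d["version"],
    )


@dataclass(frozen=True)
class DuplexResult:
    """Best intermolecular hybrid between two strands.

    ``energy`` is +inf with an empty ``pairing`` when no canonical pair
    exists.  ``pairing`` lists (position in A, position in B) with positions
    strictly increasing in A and strictly decreasing in B; ``span_a`` /
    ``span_b`` are the half-open intervals covered by the pairing.
    """

    energy: float
    pairing: tuple[tuple[int, int], ...] = ()
    span_a: tuple[int, int] = (0, 0)
    span_b: tuple[int, int] = (0, 0)

    def pairing_string(self) -> str:
        """Dot-bracket-like ``(((&)))`` rendering of the paired spans."""
        if not self.pairing:
            return "&"
        a_paired = {i for i, _ in self.pairing}
        b_paired = {j for _, j in self.pairing}
        left = "".join(
            "(" if i in a_paired else "." for i in range(self.span_a[0], self.span_a[1])
        )
        right = "".join(
            ")" if j in b_paired else "." for j in range(self.span_b[0], self.span_b[1])
        )
        return f"{left}&{right}"


def encode(seq: str) -> np.ndarray:
    """Map an RNA string to integer codes; rejects non-RNA characters."""
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValidationError(f"non-RNA character(s) in sequence: {sorted(bad)}")
    return np.array([_BASE_CODE[c] for c in seq], dtype=np.int8)


def _loop_costs(params: EnergyParams) -> tuple[np.ndarray, np.ndarray]:
    L = params.max_loop
    ls = np.arange(1, L + 1, dtype=float)
    bulge = params.bulge_open + params.bulge_extend * (ls - 1)
    interior_side = params.interior_extend * (ls - 1)  # per-side extension
    return bulge, interior_side


def _shift_left(row: np.ndarray, k: int = 1) -> np.ndarray:
    """row'[..., j] = row[..., j+k], padded with +inf on the right."""
    out = np.full_like(row, INF)
    if k < row.shape[-1]:
        out[..., : row.shape[-1] - k] = row[..., k:]
    return out


def _dp_rows(a_codes: np.ndarray, b_codes: np.ndarray, params: EnergyParams,
             keep_full: bool):
    """Shared DP core.

    ``b_codes`` may be 1-D (single sequence) or 2-D (batch, length); the
    batch dimension broadcasts through every row operation.  Returns
    (E, best) where ``best`` is the per-batch minimum of E + end penalty,
    and E is the full (…, len_a, len_b) matrix when ``keep_full``.
    """
    pair_idx, stack, ends = params._tables()
    La = a_codes.shape[0]
    batched = b_codes.ndim == 2
    B = b_codes if batched else b_codes[None, :]
    nb, Lb = B.shape
    L = params.max_loop
    bulge_cost, int_side = _loop_costs(params)

    # pair index matrix per row is computed lazily: pidx_row[i] shape (nb, Lb)
    pidx = pair_idx[a_codes[:, None, None], B[None, :, :]]  # (La, nb, Lb)
    pairable = pidx >= 0
    pidx_safe = np.where(pairable, pidx, 0)

    full = np.full((La, nb, Lb), INF) if keep_full else None
    # ring buffers of the last max_loop+1 finished rows, pre-shifted by 1 in j
    shifted_rows: list[np.ndarray | None] = [None] * La
    ib_rows: list[np.ndarray | None] = [None] * La  # interior lb-aggregate
    best = np.full(nb, INF)

    prev_row = None          # E[i-1]
    prev_pidx = None         # pidx row i-1
    for i in range(La):
        row_pairable = pairable[i]
        cand = np.full((nb, Lb), INF)
        # open a new hybrid at (i, j)
        init_term = params.duplex_init + ends[pidx_safe[i]]
        np.copyto(cand, init_term, where=row_pairable)
        if prev_row is not None:
            sh_prev = shifted_rows[i - 1]
            # stack on the adjacent pair (i-1, j+1)
            stack_term = sh_prev + stack[
                _shift_left_idx(prev_pidx), pidx_safe[i]
            ]
            np.minimum(cand, stack_term, out=cand)
            # bulge on strand B: predecessor (i-1, j+1+lb)
            for lb in range(1, L + 1):
                np.minimum(cand, _shift_left(sh_prev, lb) + bulge_cost[lb - 1],
                           out=cand)
            # bulge on strand A: predecessor (i-1-la, j+1)
            for la in range(1, L + 1):
                r = i - 1 - la
                if r < 0:
                    break
                np.minimum(cand, shifted_rows[r] + bulge_cost[la - 1], out=cand)
            # interior loop: predecessor (i-1-la, j+1+lb), la,lb >= 1
            for la in range(1, L + 1):
                r = i - 1 - la
                if r < 0:
                    break
                ib = ib_rows[r]
                if ib is not None:
                    np.minimum(
                        cand,
                        ib + params.interior_open + int_side[la - 1],
                        out=cand,
                    )
        row = np.where(row_pairable, cand, INF)
        if keep_full:
            full[i] = row
        end_term = np.where(row_pairable, row + ends[pidx_safe[i]], INF)
        np.minimum(best, end_term.min(axis=-1), out=best)

        sh = _shift_left(row)
        shifted_rows[i] = sh
        # interior aggregate over lb for this row: min_lb sh[j+lb] + ie*(lb-1)
        ib = np.full((nb, Lb), INF)
        for lb in range(1, L + 1):
            np.minimum(ib, _shift_left(sh, lb) + int_side[lb - 1], out=ib)
        ib_rows[i] = ib if np.any(np.isfinite(ib)) else None
        # free buffers beyond the lookback horizon
        if i - 1 - L >= 0:
            shifted_rows[i - 1 - L] = None
            ib_rows[i - 1 - L] = None
        prev_row = row
        prev_pidx = pidx_safe[i]

    if keep_full:
        return full, best
    return None, best


def _shift_left_idx(pidx_row: np.ndarray) -> np.ndarray:
    out = np.zeros_like(pidx_row)
    out[..., :-1] = pidx_row[..., 1:]
    return out


def duplex_mfe(seq_a: str, seq_b: str, params: EnergyParams | None = None
               ) -> DuplexResult:
    """Minimum-free-energy intermolecular hybrid of two RNA strands.

    Returns a :class:`DuplexResult` with the optimal energy, the base-pair
    list, and the spans covered on each strand.  If the two sequences admit
    no canonical pair the energy is ``+inf`` and the pairing empty.
    """
    if params is None:
        params = default_params()
    if not seq_a or not seq_b:
        raise ValidationError("sequences must be non-empty")
    a = encode(seq_a)
    b = encode(seq_b)
    full, best = _dp_rows(a, b, params, keep_full=True)
    energy = float(best[0])
    if not np.isfinite(energy):
        return DuplexResult(energy=INF)
    E = full[:, 0, :]
    pairing = _traceback(E, a, b, params)
    ia = [i for i, _ in pairing]
    jb = [j for _, j in pairing]
    return DuplexResult(
        energy=round(energy, 10),
        pairing=tuple(pairing),
        span_a=(min(ia), max(ia) + 1),
        span_b=(min(jb), max(jb) + 1),
    )


def _traceback(E: np.ndarray, a: np.ndarray, b: np.ndarray, params: EnergyParams
               ) -> list[tuple[int, int]]:
    pair_idx, stack, ends = params._tables()
    L = params.max_loop
    bulge_cost, int_side = _loop_costs(params)
    La, Lb = E.shape
    # terminal cell: argmin of E + right-end penalty
    pm = pair_idx[a[:, None], b[None, :]]
    endpen = np.where(pm >= 0, ends[np.where(pm >= 0, pm, 0)], INF)
    total = E + endpen
    i, j = np.unravel_index(np.argmin(total), total.shape)
    pairs_rev = [(int(i), int(j))]
    tol = 1e-9
    while True:
        v = E[i, j]
        p_cur = pm[i, j]
        # opened here?
        if abs(v - (params.duplex_init + ends[p_cur])) < tol:
            break
        moved = False
        # stack predecessor
        if i >= 1 and j + 1 < Lb and pm[i - 1, j + 1] >= 0:
            cost = stack[pm[i - 1, j + 1], p_cur]
            if np.isfinite(E[i - 1, j + 1]) and abs(v - (E[i - 1, j + 1] + cost)) < tol:
                i, j = i - 1, j + 1
                pairs_rev.append((i, j))
                moved = True
        if not moved:
            for la in range(0, L + 1):
                if moved:
                    break
                for lb in range(0, L + 1):
                    if la == 0 and lb == 0:
                        continue
                    ip, jp = i - 1 - la, j + 1 + lb
                    if ip < 0 or jp >= Lb or not np.isfinite(E[ip, jp]):
                        continue
                    if la == 0 or lb == 0:
                        cost = bulge_cost[max(la, lb) - 1]
                    else:
                        cost = (params.interior_open
                                + int_side[la - 1] + int_side[lb - 1])
                    if abs(v - (E[ip, jp] + cost)) < tol:
                        i, j = ip, jp
                        pairs_rev.append((i, j))
                        moved = True
                        break
        if not moved:  # pragma: no cover - would indicate a DP/traceback mismatch
            raise RuntimeError(f"traceback failed at cell ({i}, {j})")
    return pairs_rev[::-1]


def _windows(seq: str, window: int, overlap: int) -> list[tuple[int, str]]:
    if len(seq) <= window:
        return [(0, seq)]
    step = window - overlap
    starts = list(range(0, len(seq) - window + step, step))
    out = []
    for s in starts:
        s = min(s, len(seq) - window)
        out.append((s, seq[s : s + window]))
    # dedupe clamped tail windows
    seen = set()
    uniq = []
    for s, w in out:
        if s not in seen:
            uniq.append((s, w))
            seen.add(s)
    return uniq


def screen_candidates(
    lnc_seq: str,
    mrna_seq_map: dict[str, str],
    params: EnergyParams | None = None,
    cutoff: float = -20.0,
    window: int = 300,
    overlap: int = 150,
) -> list[tuple[str, DuplexResult]]:
    """Screen one lncRNA against candidate mRNAs for stable hybrids.

    Long mRNAs are chunked into overlapping windows (default 300 nt,
    150 nt overlap) and the window minimum taken.  Only candidates whose
    best hybrid satisfies the strict cutoff ``energy < cutoff`` are
    returned, sorted ascending by energy, each with a full traceback
    (spans in whole-transcript coordinates).
    """
    if params is None:
        params = default_params()
    if not mrna_seq_map:
        return []
    a = encode(lnc_seq)
    win_meta: list[tuple[str, int]] = []
    win_codes: list[np.ndarray] = []
    width = 0
    for gene_id, seq in mrna_seq_map.items():
        if not seq:
            logger.warning("skipping %s: empty sequence", gene_id)
            continue
        for start, w in _windows(seq, window, overlap):
            win_meta.append((gene_id, start))
            codes = encode(w)
            win_codes.append(codes)
            width = max(width, len(codes))
    if not win_codes:
        return []
    N_CODE = _BASE_CODE["N"]  # padding never pairs
    batch = np.full((len(win_codes), width), N_CODE, dtype=np.int8)
    for k, codes in enumerate(win_codes):
        batch[k, : len(codes)] = codes
    _, best = _dp_rows(a, batch, params, keep_full=False)

    per_gene: dict[str, tuple[float, int]] = {}
    for (gene_id, start), e in zip(win_meta, best):
        e = round(float(e), 10) if np.isfinite(e) else float(e)
        if gene_id not in per_gene or e < per_gene[gene_id][0]:
            per_gene[gene_id] = (e, start)
    hits = []
    for gene_id, (e, start) in per_gene.items():
        if e < cutoff:
            seq = mrna_seq_map[gene_id]
            wseq = seq[start : start + window]
            res = duplex_mfe(lnc_seq, wseq, params)
            res = DuplexResult(
                energy=res.energy,
                pairing=tuple((i, j + start) for i, j in res.pairing),
                span_a=res.span_a,
                span_b=(res.span_b[0] + start, res.span_b[1] + start),
            )
            hits.append((gene_id, res))
    hits.sort(key=lambda t: (t[1].energy, t[0]))
    return hits
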