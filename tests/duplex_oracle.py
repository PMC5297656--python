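"""Independent brute-force oracle for the duplex MFE dynamic program.

Enumerates every valid pairing chain (positions strictly increasing in
strand A, strictly decreasing in strand B, canonical pairs only, loop
sides bounded by max_loop) and scores it directly from the parameter set.
Feasible for sequences up to ~8 nt; shares nothing with the DP
implementation beyond the parameter definitions.
"""

from lncterplay.duplex import EnergyParams

CANONICAL = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
WEAK_ENDS = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}


def chain_energy(a: str, b: str, chain: list[tuple[int, int]],
                 params: EnergyParams) -> float | None:
    """Energy of one pairing chain, or None if a loop exceeds max_loop."""
    e = params.duplex_init
    first, last = chain[0], chain[-1]
    for i, j in (first, last):
        if (a[i], b[j]) in WEAK_ENDS:
            e += params.au_gu_end_penalty
    for (ip, jp), (i, j) in zip(chain, chain[1:]):
        la, lb = i - ip - 1, jp - j - 1
        if la == 0 and lb == 0:
            e += params.stack_energy[f"{a[ip]}{b[jp]}>{a[i]}{b[j]}"]
        elif la == 0 or lb == 0:
            l = max(la, lb)
            if l > params.max_loop:
                return None
            e += params.bulge_open + params.bulge_extend * (l - 1)
        else:
            if la > params.max_loop or lb > params.max_loop:
                return None
            e += (params.interior_open
                  + params.interior_extend * (la + lb - 2))
    return e


def brute_force_mfe(a: str, b: str, params: EnergyParams) -> float:
    """Exhaustive minimum over all pairing chains; +inf if none exists."""
    cand = [
        (i, j)
        for i in range(len(a))
        for j in range(len(b))
        if (a[i], b[j]) in CANONICAL
    ]
    best = float("inf")

    def extend(chain):
        nonlocal best
        if chain:
            e = chain_energy(a, b, chain, params)
            if e is not None and e < best:
                best = e
        last = chain[-1] if chain else None
        for i, j in cand:
            if last is None or (i > last[0] and j < last[1]):
                chain.append((i, j))
                extend(chain)
                chain.pop()

    extend([])
    return best
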