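import math

import numpy as np
import pytest

from lncterplay.duplex import (
    DuplexResult,
    default_params,
    duplex_mfe,
    screen_candidates,
)
from lncterplay.types import ValidationError

from duplex_oracle import brute_force_mfe, chain_energy

RC = str.maketrans("ACGU", "UGCA")


def random_rna(n, rng):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestDuplexMFE:
    def test_no_canonical_pair_gives_sentinel(self):
        res = duplex_mfe("AAAA", "AAAA")
        assert math.isinf(res.energy)
        assert res.pairing == ()

    def test_perfect_gc_helix_energy_sums_table_entries(self):
        p = default_params()
        res = duplex_mfe("GGGG", "CCCC")
        expected = p.duplex_init + 3 * p.stack_energy["GC>GC"]
        assert res.energy == pytest.approx(expected)
        assert res.pairing == ((0, 3), (1, 2), (2, 1), (3, 0))

    def test_terminal_au_penalty_applied_both_ends(self):
        p = default_params()
        res = duplex_mfe("AA", "UU")
        expected = (p.duplex_init + p.stack_energy["AU>AU"]
                    + 2 * p.au_gu_end_penalty)
        assert res.energy == pytest.approx(expected)

    def test_n_never_pairs(self):
        assert math.isinf(duplex_mfe("NNNN", "NNNN").energy)
        # Ns inside a helix force a loop rather than a pair
        with_n = duplex_mfe("GGNGG", "CCNCC")
        assert all("N" not in {"GGNGG"[i], "CCNCC"[j]}
                   for i, j in with_n.pairing)

    def test_rejects_non_rna(self):
        with pytest.raises(ValidationError):
            duplex_mfe("ACGT", "ACGU")

    def test_matches_brute_force_on_short_random_pairs(self):
        p = default_params()
        rng = np.random.default_rng(0)
        for _ in range(60):
            a = random_rna(int(rng.integers(1, 9)), rng)
            b = random_rna(int(rng.integers(1, 9)), rng)
            dp = duplex_mfe(a, b, p).energy
            bf = brute_force_mfe(a, b, p)
            if math.isinf(bf):
                assert math.isinf(dp)
            else:
                assert dp == pytest.approx(bf, abs=1e-9)

    def test_traceback_energy_reconstructs_reported_energy(self):
        p = default_params()
        rng = np.random.default_rng(8)
        for _ in range(20):
            a, b = random_rna(30, rng), random_rna(30, rng)
            res = duplex_mfe(a, b, p)
            if res.pairing:
                assert chain_energy(a, b, list(res.pairing), p) == pytest.approx(
                    res.energy, abs=1e-9
                )

    def test_pairing_monotone_in_a_antimonotone_in_b(self):
        rng = np.random.default_rng(2)
        res = duplex_mfe(random_rna(40, rng), random_rna(40, rng))
        ia = [i for i, _ in res.pairing]
        jb = [j for _, j in res.pairing]
        assert ia == sorted(ia) and len(set(ia)) == len(ia)
        assert jb == sorted(jb, reverse=True) and len(set(jb)) == len(jb)

    def test_unpairable_flanks_never_worsen_energy(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a, b = random_rna(20, rng), random_rna(20, rng)
            base = duplex_mfe(a, b).energy
            assert duplex_mfe("AAAA" + a + "AAAA", b).energy <= base + 1e-9
            assert duplex_mfe(a, "AAAA" + b + "AAAA").energy <= base + 1e-9

    def test_exact_complement_beats_every_point_mutant(self):
        seq = "GACUGUCAGG"
        comp = seq[::-1].translate(RC)
        best = duplex_mfe(seq, comp).energy
        for pos in range(len(comp)):
            for alt in "ACGU":
                if alt == comp[pos]:
                    continue
                mut = comp[:pos] + alt + comp[pos + 1:]
                assert best <= duplex_mfe(seq, mut).energy + 1e-9


class TestScreenCandidates:
    def test_empty_candidate_map(self):
        assert screen_candidates("ACGU", {}) == []

    def test_cutoff_is_strict(self):
        # engineer candidates right at the boundary using a fake cutoff equal
        # to a computed energy: a hit AT the cutoff must be excluded
        rng = np.random.default_rng(9)
        a = random_rna(40, rng)
        b = a[::-1].translate(RC)
        e = duplex_mfe(a, b).energy
        hits_at = screen_candidates(a, {"g": b}, cutoff=e)
        assert hits_at == []
        hits_below = screen_candidates(a, {"g": b}, cutoff=e + 1e-6)
        assert [g for g, _ in hits_below] == ["g"]

    def test_screen_energy_matches_duplex_mfe_for_short_targets(self):
        rng = np.random.default_rng(5)
        lnc = random_rna(80, rng)
        cands = {f"g{k}": random_rna(60, rng) for k in range(8)}
        # compare against per-pair calls with a permissive cutoff
        hits = dict(screen_candidates(lnc, cands, cutoff=1e9))
        for gid, seq in cands.items():
            expected = duplex_mfe(lnc, seq).energy
            if math.isinf(expected):
                assert gid not in hits
            else:
                assert hits[gid].energy == pytest.approx(expected, abs=1e-9)

    def test_hits_sorted_ascending_by_energy(self, rng):
        lnc = random_rna(60, rng)
        cands = {f"g{k}": random_rna(60, rng) for k in range(10)}
        hits = screen_candidates(lnc, cands, cutoff=1e9)
        energies = [h.energy for _, h in hits]
        assert energies == sorted(energies)

    def test_windowing_covers_long_targets(self, rng):
        lnc = random_rna(50, rng)
        window = lnc[::-1].translate(RC)
        # bury the complement deep inside a 900-nt target
        target = random_rna(700, rng) + window + random_rna(150, rng)
        hits = screen_candidates(lnc, {"g": target}, cutoff=-20)
        assert [g for g, _ in hits] == ["g"]
        (_, res), = hits
        assert 650 <= res.span_b[0] <= 760  # span reported in whole-target coords
        assert res.pairing_string().count("&") == 1
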