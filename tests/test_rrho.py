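"""Signed RRHO: exact tails, oracle-checked grids, quadrant extraction."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from crossconcord import demod, rrho, synthgen


def exact_tail_by_enumeration(N, K, n, k):
    """P(X >= k) as an exact fraction via the hypergeometric pmf."""
    total = Fraction(math.comb(N, n))
    hits = sum(
        Fraction(math.comb(K, x) * math.comb(N - K, n - x))
        for x in range(k, min(K, n) + 1)
    )
    return hits / total


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "N,K,n,k,expected",
        [
            (10, 5, 5, 5, 1 / 252),       # all draws hit: 1 / C(10,5)
            (10, 5, 5, 0, 1.0),
            (6, 3, 3, 2, 0.5),            # (9 + 1) / 20 by hand enumeration
        ],
    )
    def test_known_values(self, N, K, n, k, expected):
        assert rrho.hypergeom_tail(N, K, n, k) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_for_small_universes(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        exact = float(exact_tail_by_enumeration(N, K, n, k))
                        assert rrho.hypergeom_tail(N, K, n, k) == pytest.approx(
                            exact, rel=1e-10, abs=1e-12
                        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            rrho.hypergeom_tail(10, 5, 5, 6)
        with pytest.raises(ValueError):
            rrho.hypergeom_tail(5, 7, 3, 1)


class TestSignedScore:
    def test_examples(self):
        assert rrho.signed_score(0.01, -0.5) == pytest.approx(-2.0)
        assert rrho.signed_score(1.0, 3.0) == pytest.approx(0.0)
        assert rrho.signed_score(1e-320, 1.0) == pytest.approx(300.0)

    def test_p_zero_capped(self):
        assert rrho.signed_score(0.0, 1.0) == pytest.approx(300.0)

    def test_zero_lfc_positive_sign(self):
        assert rrho.signed_score(0.01, 0.0) == pytest.approx(2.0)


class TestMapOrthologs:
    def test_case_insensitive_match(self):
        out = rrho.map_orthologs(["ABC1", "XYZ2"], ["Abc1", "Qrs3"])
        assert list(out["key"]) == ["ABC1"]
        assert list(out["symbol_b"]) == ["Abc1"]

    def test_duplicates_dropped(self):
        out = rrho.map_orthologs(["ABC1", "abc1", "DEF2"], ["Abc1", "Def2"])
        assert list(out["key"]) == ["DEF2"]

    def test_no_shared_genes_rejected(self):
        with pytest.raises(ValueError, match="no shared genes"):
            rrho.map_orthologs(["A"], ["B"])

    def test_matches_brute_force_double_loop(self, rng):
        pool = [f"SYM{i}" for i in range(60)]
        a = list(rng.choice(pool, 40, replace=False))
        b = [s.capitalize() for s in rng.choice(pool, 40, replace=False)]
        out = rrho.map_orthologs(a, b)
        brute = {
            sa.upper()
            for sa in a
            for sb in b
            if sa.upper() == sb.upper()
        }
        assert set(out["key"]) == brute


def brute_force_overlap(order_a, order_b, i, j):
    return len(set(order_a[:i]) & set(order_b[:j]))


def random_signature(rng, genes):
    return rrho.RankedSignature.from_table(
        genes, rng.uniform(0.001, 1, len(genes)), rng.normal(size=len(genes))
    )


class TestComputeRRHOMap:
    def test_identical_signatures_concordant(self, rng):
        genes = [f"g{i:03d}" for i in range(100)]
        sig = random_signature(rng, genes)
        m = rrho.compute_rrho_map(sig, sig)
        best = max(m.summaries, key=lambda q: m.summaries[q]["max"])
        assert best in rrho.CONCORDANT_QUADRANTS
        # every diagonal concordant cell's overlap equals its threshold
        for quad in rrho.CONCORDANT_QUADRANTS:
            t = int(m.thresholds[0])
            assert m.grids[quad][0, 0] == pytest.approx(
                rrho.neglog10_hypergeom_tail(100, t, t, t)
            )

    def test_negated_signature_discordant(self, rng):
        genes = [f"g{i:03d}" for i in range(100)]
        sig = random_signature(rng, genes)
        neg = rrho.RankedSignature.from_table(
            sig.genes, 10 ** (-np.abs(sig.scores)), -sig.scores
        )
        m = rrho.compute_rrho_map(sig, neg)
        best = max(m.summaries, key=lambda q: m.summaries[q]["max"])
        assert best in rrho.DISCORDANT_QUADRANTS

    def test_grid_matches_brute_force_oracle(self, rng):
        genes = [f"g{i:02d}" for i in range(30)]
        sig_a = random_signature(rng, genes)
        sig_b = random_signature(rng, genes)
        m = rrho.compute_rrho_map(sig_a, sig_b, step=1)
        N = 30
        from crossconcord.rrho import _orderings
        ord_a, ord_b = _orderings(sig_a), _orderings(sig_b)
        for quad in rrho.QUADRANTS:
            qa, qb = quad.split("-")
            oa, ob = list(ord_a[qa]), list(ord_b[qb])
            for i in range(1, N + 1):
                for j in range(1, N + 1):
                    k = brute_force_overlap(oa, ob, i, j)
                    expected = (
                        rrho.neglog10_hypergeom_tail(N, i, j, k)
                        if k > i * j / N
                        else 0.0
                    )
                    assert m.grids[quad][i - 1, j - 1] == pytest.approx(
                        expected, abs=1e-9
                    ), (quad, i, j)

    def test_swap_transposes_grids(self, rng):
        genes = [f"g{i:02d}" for i in range(40)]
        sig_a = random_signature(rng, genes)
        sig_b = random_signature(rng, genes)
        m_ab = rrho.compute_rrho_map(sig_a, sig_b, step=1)
        m_ba = rrho.compute_rrho_map(sig_b, sig_a, step=1)
        for quad in rrho.CONCORDANT_QUADRANTS:
            np.testing.assert_allclose(m_ab.grids[quad], m_ba.grids[quad].T)
        np.testing.assert_allclose(m_ab.grids["down-up"], m_ba.grids["up-down"].T)
        np.testing.assert_allclose(m_ab.grids["up-down"], m_ba.grids["down-up"].T)

    def test_differing_universes_rejected(self, rng):
        sig_a = random_signature(rng, ["a", "b", "c"])
        sig_b = random_signature(rng, ["a", "b", "d"])
        with pytest.raises(ValueError, match="universe"):
            rrho.compute_rrho_map(sig_a, sig_b)

    def test_random_signatures_rarely_show_strong_concordance(self):
        rng = np.random.default_rng(100)
        genes = [f"g{i:04d}" for i in range(1000)]
        exceed = 0
        n_sim = 40
        for _ in range(n_sim):
            sig_a = random_signature(rng, genes)
            sig_b = random_signature(rng, genes)
            m = rrho.compute_rrho_map(sig_a, sig_b)
            if m.max_value() > 5:
                exceed += 1
        assert exceed / n_sim < 0.10

    def test_planted_concordance_dominates_discordance(self):
        design = synthgen.SyntheticDesign(
            n_genes=600, groups=("control", "case"), n_per_group=10,
            frac_concordant_up=0.35, frac_concordant_down=0.35,
            frac_discordant=0.0, frac_unique_a=0.0, frac_unique_b=0.0,
        )
        wins = 0
        n_sim = 10
        for s in range(n_sim):
            mat_a, mat_b, orth, _ = synthgen.generate_pair(design, design, seed=1000 + s)
            de_a = demod.run_de(mat_a, ("control", "case"))
            de_b = demod.run_de(mat_b, ("control", "case"))
            sig_a, sig_b = rrho.align_signatures(de_a, de_b, orth)
            m = rrho.compute_rrho_map(sig_a, sig_b)
            conc = max(m.summaries[q]["max"] for q in rrho.CONCORDANT_QUADRANTS)
            disc = max(m.summaries[q]["max"] for q in rrho.DISCORDANT_QUADRANTS)
            if conc - disc >= 10:
                wins += 1
        assert wins >= n_sim - 1


class TestQuadrantGenes:
    def test_identical_signature_down_down(self, rng):
        genes = [f"g{i:03d}" for i in range(64)]
        sig = random_signature(rng, genes)
        m = rrho.compute_rrho_map(sig, sig)
        got = rrho.quadrant_genes(m, "down-down")
        size = m.summaries["down-down"]["argmax_i"]
        # identical lists: the argmax prefix intersection is the shared down-most genes
        assert m.summaries["down-down"]["argmax_i"] == m.summaries["down-down"]["argmax_j"]
        down_order = sig.genes[np.lexsort((sig.genes, sig.scores))]
        assert set(got) == set(down_order[:size])

    def test_equals_brute_force_prefix_intersection(self, rng):
        genes = [f"g{i:02d}" for i in range(30)]
        sig_a = random_signature(rng, genes)
        sig_b = random_signature(rng, genes)
        m = rrho.compute_rrho_map(sig_a, sig_b, step=1)
        from crossconcord.rrho import _orderings
        ord_a, ord_b = _orderings(sig_a), _orderings(sig_b)
        for quad in rrho.QUADRANTS:
            qa, qb = quad.split("-")
            i = m.summaries[quad]["argmax_i"]
            j = m.summaries[quad]["argmax_j"]
            brute = set(ord_a[qa][:i]) & set(ord_b[qb][:j])
            assert set(rrho.quadrant_genes(m, quad)) == brute

    def test_unknown_quadrant_rejected(self, rng):
        sig = random_signature(rng, ["a", "b", "c", "d"])
        m = rrho.compute_rrho_map(sig, sig, step=1)
        with pytest.raises(ValueError, match="quadrant"):
            rrho.quadrant_genes(m, "left-right")
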