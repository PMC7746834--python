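"""Diversity statistics, Weir-Cockerham f, exact HWE tests, sex ratios."""

import itertools
from collections import Counter
from math import lgamma, log

import numpy as np
import pytest

from msatpop.genotypes import MultilocusGenotype, allele_frequencies
from msatpop.popstats import (
    diversity,
    fis_weir_cockerham,
    genotype_counts_at_locus,
    hwe_exact,
    null_allele_screen,
    sex_ratio_test,
)


def _gts(calls, locus="L"):
    return [MultilocusGenotype(f"i{n}", {locus: c}) for n, c in enumerate(calls)]


class TestDiversityClosedForms:
    def test_biallelic_half(self):
        # 4 individuals, p = q = 0.5
        gts = _gts([(100, 100), (100, 102), (100, 102), (102, 102)])
        d = diversity(gts, hwe=False).per_locus.loc["L"]
        assert d.he == pytest.approx(0.5)
        assert d.ne_alleles == pytest.approx(2.0)
        assert d.pic == pytest.approx(0.375)
        assert d.ho == pytest.approx(0.5)
        assert d.uhe == pytest.approx(0.5 * 8 / 7)

    def test_monomorphic(self):
        gts = _gts([(100, 100)] * 5)
        d = diversity(gts, hwe=False).per_locus.loc["L"]
        assert d.ho == d.he == d.pic == 0.0
        assert d.ne_alleles == 1.0
        assert np.isnan(d.fis_wc)
        assert d.p_hwe == 1.0

    def test_pic_strictly_below_he_when_polymorphic(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            k = rng.integers(2, 6)
            p = rng.dirichlet(np.ones(k))
            s2 = np.sum(p ** 2)
            he = 1 - s2
            pic = 1 - s2 - sum(
                2 * p[i] ** 2 * p[j] ** 2
                for i in range(k) for j in range(i + 1, k)
            )
            assert pic < he

    def test_uhe_at_least_he(self, default_sim):
        from msatpop.simdata import true_consensus_genotypes

        gts = true_consensus_genotypes(default_sim["truth"])
        per = diversity(gts, hwe=False).per_locus
        assert (per.uhe >= per.he - 1e-12).all()


def _wc_f_reference(calls):
    """Independent Weir-Cockerham variance-component coding of f.

    Written directly from the single-population ANOVA layout: for each
    allele, within-individual component c = h/2 and between-individual
    component b from the genotype mean squares — algebra kept distinct
    from the implementation (explicit MSG/MSW mean squares).
    """
    n = len(calls)
    alleles = sorted({a for c in calls for a in c})
    num = den = 0.0
    for a in alleles:
        x = np.array([int(c[0] == a) + int(c[1] == a) for c in calls], dtype=float)
        p = x.mean() / 2.0
        # mean squares for gene frequencies within/among individuals
        MSW = np.sum(x * (2 - x)) / (2.0 * n)  # within-individual MS
        MSG = (np.sum(x ** 2) / 2.0 - 2.0 * n * p ** 2) / (n - 1.0)
        b = (MSG - MSW) / 2.0
        c_comp = MSW
        num += c_comp
        den += b + c_comp
    return 1.0 - num / den if den else float("nan")


class TestWeirCockerhamF:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_independent_coding(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet([2, 2, 1, 1])
        calls = [
            tuple(sorted(rng.choice([100, 102, 104, 106], 2, p=p)))
            for _ in range(12)
        ]
        if len({a for c in calls for a in c}) < 2:
            pytest.skip("monomorphic draw")
        gts = _gts(calls)
        assert fis_weir_cockerham(gts, "L") == pytest.approx(
            _wc_f_reference(calls), abs=1e-10
        )

    def test_approaches_one_minus_ho_over_he_at_large_n(self):
        rng = np.random.default_rng(3)
        calls = [
            tuple(sorted(rng.choice([100, 102], 2, p=[0.6, 0.4])))
            for _ in range(10_000)
        ]
        gts = _gts(calls)
        ft = allele_frequencies(gts)
        p = np.array(list(ft["L"].values()))
        he = 1 - np.sum(p ** 2)
        ho = sum(1 for c in calls if c[0] != c[1]) / len(calls)
        assert fis_weir_cockerham(gts, "L") == pytest.approx(1 - ho / he, abs=0.01)

    def test_all_heterozygotes_negative(self):
        gts = _gts([(100, 102)] * 10)
        assert fis_weir_cockerham(gts, "L") < -0.9


# ---------------------------------------------------------------------------
# exact HWE oracle: independent brute-force enumeration over het counts
# ---------------------------------------------------------------------------

def _hwe_biallelic_oracle(n_aa, n_ab, n_bb):
    """Levene/Haldane conditional distribution over heterozygote counts."""
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    n = n_aa + n_ab + n_bb

    def logprob(nab):
        naa = (na - nab) // 2
        nbb = (nb - nab) // 2
        return (
            lgamma(n + 1) - lgamma(naa + 1) - lgamma(nab + 1) - lgamma(nbb + 1)
            + nab * log(2) + lgamma(na + 1) + lgamma(nb + 1) - lgamma(2 * n + 1)
        )

    support = [h for h in range(min(na, nb) + 1)
               if (na - h) % 2 == 0 and h % 2 == na % 2 and (nb - h) >= 0
               and (na - h) >= 0]
    support = [h for h in support if (nb - h) % 2 == 0]
    probs = {h: np.exp(logprob(h)) for h in support}
    tot = sum(probs.values())
    obs = probs[n_ab] / tot
    return sum(p for p in probs.values() if p / tot <= obs / tot * (1 + 1e-12)) / tot


class TestHWEExact:
    def test_perfect_hwe_tiny_sample(self):
        r = hwe_exact({(1, 1): 1, (1, 2): 2, (2, 2): 1})
        assert r.method == "enumeration"
        assert r.p == 1.0

    def test_all_heterozygotes_small_p_matches_oracle(self):
        r = hwe_exact({(1, 2): 10})
        assert r.method == "enumeration"
        assert r.p == pytest.approx(_hwe_biallelic_oracle(0, 10, 0), abs=1e-10)

    @pytest.mark.parametrize(
        "counts",
        [(3, 4, 5), (6, 0, 6), (1, 10, 1), (5, 2, 0), (2, 2, 2)],
    )
    def test_biallelic_matches_levene_oracle(self, counts):
        n_aa, n_ab, n_bb = counts
        r = hwe_exact({(1, 1): n_aa, (1, 2): n_ab, (2, 2): n_bb})
        assert r.p == pytest.approx(
            _hwe_biallelic_oracle(n_aa, n_ab, n_bb), abs=1e-10
        )

    def test_monte_carlo_agrees_with_enumeration(self):
        gc = {(1, 1): 6, (1, 2): 3, (2, 2): 6, (1, 3): 2, (2, 3): 2, (3, 3): 4}
        exact = hwe_exact(gc)
        assert exact.method == "enumeration"
        mc = hwe_exact(gc, max_enumeration=1, n_draws=200_000, seed=3)
        assert mc.method == "monte-carlo"
        assert mc.se is not None
        assert mc.p == pytest.approx(exact.p, abs=5 * mc.se)

    def test_het_deficit_one_sided(self):
        # strong homozygote excess: one-sided p small, het-excess side large
        gc = {(1, 1): 8, (2, 2): 8, (1, 2): 0}
        assert hwe_exact(gc, alternative="het_deficit").p < 0.01
        gc2 = {(1, 2): 16}
        assert hwe_exact(gc2, alternative="het_deficit").p == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        assert hwe_exact({(1, 1): 10}).p == 1.0

    def test_determinism_of_monte_carlo(self):
        gc = {(1, 1): 20, (1, 2): 30, (2, 2): 25, (1, 3): 10, (2, 3): 10,
              (3, 3): 15}
        a = hwe_exact(gc, max_enumeration=1, seed=7)
        b = hwe_exact(gc, max_enumeration=1, seed=7)
        assert a.p == b.p


class TestNullAlleleScreen:
    def test_equal_ho_he_gives_zero(self):
        # p=q=0.5 with exactly HWE genotype proportions
        gts = _gts([(100, 100), (100, 102), (100, 102), (102, 102)])
        row = null_allele_screen(gts).iloc[0]
        assert row.null_chakraborty == pytest.approx(0.0)
        assert row.null_brookfield1 == pytest.approx(0.0)

    def test_direct_formula(self):
        # engineered Ho=0.4; He computed from the same data
        calls = [(100, 102)] * 4 + [(100, 100)] * 3 + [(102, 102)] * 3
        gts = _gts(calls)
        ft = allele_frequencies(gts)
        p = np.array(list(ft["L"].values()))
        he = 1 - np.sum(p ** 2)
        ho = 0.4
        row = null_allele_screen(gts).iloc[0]
        assert row.null_chakraborty == pytest.approx((he - ho) / (he + ho))
        assert row.null_brookfield1 == pytest.approx((he - ho) / (1 + he))

    def test_true_null_allele_flagged(self):
        """A null allele at freq 0.2 produces positive estimates and flags."""
        rng = np.random.default_rng(0)
        hits = est_pos = 0
        n_seeds = 50
        for _ in range(n_seeds):
            # visible alleles 100/102 + null allele: null homozygotes drop out,
            # null heterozygotes look like visible homozygotes
            p = np.array([0.5, 0.3, 0.2])
            calls = []
            for _ in range(100):
                a, b = rng.choice(3, 2, p=p)
                if a == 2 and b == 2:
                    continue  # null homozygote: no genotype
                if a == 2:
                    a = b
                if b == 2:
                    b = a
                calls.append(tuple(sorted((100 + 2 * a, 100 + 2 * b))))
            gts = _gts(calls)
            row = null_allele_screen(gts).iloc[0]
            est_pos += row.null_chakraborty > 0
            hits += bool(row.flagged)
        assert est_pos >= 0.9 * n_seeds
        assert hits >= 0.8 * n_seeds


class TestSexRatio:
    @pytest.mark.parametrize(
        "f, m, chi2, p",
        [
            (4, 8, 1.333, 0.248),
            (1, 2, 0.333, 0.564),
            (1, 3, 1.000, 0.317),
            (1, 6, 3.571, 0.059),
        ],
    )
    def test_reported_pearson_values(self, f, m, chi2, p):
        t = sex_ratio_test(f, m)
        assert round(t.chi2_plain, 3) == chi2
        assert round(t.p_plain, 3) == p

    def test_yates_closed_form(self):
        t = sex_ratio_test(4, 8)
        assert t.chi2_yates == pytest.approx(0.75)

    def test_perfect_balance(self):
        t = sex_ratio_test(6, 6)
        assert t.chi2_plain == 0.0
        assert t.chi2_yates == 0.0
        assert t.p_plain == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sex_ratio_test(0, 0)


class TestSummaryRows:
    def test_mean_row_is_column_mean(self, default_sim):
        from msatpop.simdata import true_consensus_genotypes

        gts = true_consensus_genotypes(default_sim["truth"])
        s = diversity(gts, hwe=False)
        assert s.mean["na"] == pytest.approx(s.per_locus.na.mean())
        assert s.mean["ho"] == pytest.approx(s.per_locus.ho.mean())
        assert s.sd["he"] == pytest.approx(s.per_locus.he.std(ddof=1))
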