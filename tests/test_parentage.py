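"""Trio likelihoods (brute-force oracle), parent-pair assignment, pedigrees."""

import itertools

import numpy as np
import pytest

from msatpop.genotypes import AlleleFrequencyTable, MultilocusGenotype, allele_frequencies
from msatpop.identity import identify_individuals
from msatpop.parentage import (
    PedigreeError,
    assign_parent_pairs,
    full_sib_groups,
    trio_likelihood,
)
from msatpop.repqc import call_consensus, error_rates
from msatpop.simdata import SimConfig, simulate_population


def _ft(freqs_by_locus):
    return AlleleFrequencyTable(
        freqs_by_locus, {l: 24 for l in freqs_by_locus}
    )


def _g(iid, calls, sex=None):
    return MultilocusGenotype(iid, calls, sex=sex)


# ---------------------------------------------------------------------------
# brute-force oracle: exhaustive summation over true genotypes & transmissions
# ---------------------------------------------------------------------------

def _oracle_locus_lik(obs_o, obs_f, obs_m, freqs, e):
    alleles = sorted(freqs)
    genos = list(itertools.combinations_with_replacement(alleles, 2))

    def hwe(g):
        return freqs[g[0]] * freqs[g[1]] * (1 if g[0] == g[1] else 2)

    def p_obs(obs, g):
        return e * hwe(obs) + (1 - e) * (obs == g)

    num = 0.0
    den = 0.0
    for gf in genos:
        for gm in genos:
            w = hwe(gf) * hwe(gm)
            wf = p_obs(obs_f, gf) if obs_f is not None else 1.0
            wm = p_obs(obs_m, gm) if obs_m is not None else 1.0
            inner = 0.0
            # explicit transmission: each parent passes one allele uniformly
            for fa in gf:
                for ma in gm:
                    go = tuple(sorted((fa, ma)))
                    inner += 0.25 * p_obs(obs_o, go)
            num += w * wf * wm * inner
            den += w * wf * wm
    return num / den


class TestTrioLikelihood:
    FREQS = {"L": {100: 0.4, 102: 0.35, 104: 0.25}}

    def test_forced_transmission_probability_one(self):
        ft = _ft({"L": {100: 0.5, 102: 0.5}})
        ll = trio_likelihood(
            _g("o", {"L": (100, 102)}),
            _g("f", {"L": (100, 100)}),
            _g("m", {"L": (102, 102)}),
            ft, error_rate=0.0,
        )
        assert ll == pytest.approx(0.0)  # log 1

    def test_mendelian_exclusion_zero_likelihood(self):
        ft = _ft({"L": {100: 0.5, 102: 0.5}})
        ll = trio_likelihood(
            _g("o", {"L": (100, 100)}),
            _g("f", {"L": (102, 102)}),
            _g("m", {"L": (100, 102)}),
            ft, error_rate=0.0,
        )
        assert ll == -np.inf

    @pytest.mark.parametrize("e", [0.0, 0.01, 0.1])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle(self, e, seed):
        rng = np.random.default_rng(seed)
        alleles = [100, 102, 104]
        ft = _ft(self.FREQS)

        def rand_geno():
            return tuple(sorted(rng.choice(alleles, 2)))

        o, f, m = rand_geno(), rand_geno(), rand_geno()
        got = trio_likelihood(
            _g("o", {"L": o}), _g("f", {"L": f}), _g("m", {"L": m}),
            ft, error_rate=e,
        )
        want = _oracle_locus_lik(o, f, m, self.FREQS["L"], e)
        if want == 0.0:
            assert got == -np.inf
        else:
            assert got == pytest.approx(np.log(want), abs=1e-10)

    def test_missing_parent_integrated_over_hwe(self):
        ft = _ft(self.FREQS)
        o = (100, 102)
        got = trio_likelihood(
            _g("o", {"L": o}), _g("f", {"L": (100, 100)}), None, ft, 0.0
        )
        want = _oracle_locus_lik(o, (100, 100), None, self.FREQS["L"], 0.0)
        assert got == pytest.approx(np.log(want), abs=1e-10)

    def test_invariant_to_allele_relabeling(self):
        f1 = {"L": {100: 0.4, 102: 0.35, 104: 0.25}}
        f2 = {"L": {200: 0.4, 300: 0.35, 400: 0.25}}
        relabel = {100: 200, 102: 300, 104: 400}
        trio1 = ((100, 102), (100, 104), (102, 102))
        trio2 = tuple(tuple(relabel[a] for a in g) for g in trio1)
        ll1 = trio_likelihood(
            _g("o", {"L": trio1[0]}), _g("f", {"L": trio1[1]}),
            _g("m", {"L": trio1[2]}), _ft(f1), 0.02,
        )
        ll2 = trio_likelihood(
            _g("o", {"L": trio2[0]}), _g("f", {"L": trio2[1]}),
            _g("m", {"L": trio2[2]}), _ft(f2), 0.02,
        )
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_error_rate_domain(self):
        ft = _ft({"L": {100: 0.5, 102: 0.5}})
        with pytest.raises(ValueError):
            trio_likelihood(
                _g("o", {"L": (100, 100)}), _g("f", {"L": (100, 100)}),
                _g("m", {"L": (100, 100)}), ft, error_rate=0.6,
            )


class TestAssignment:
    def _panel(self, n_loci=9):
        rng = np.random.default_rng(42)
        freqs = {}
        for i in range(n_loci):
            p = rng.dirichlet(np.ones(4) * 2)
            freqs[f"L{i}"] = {100 + 2 * j: float(x) for j, x in enumerate(p)}
        return freqs

    def test_unique_compatible_pair_dominates(self):
        freqs = self._panel()
        rng = np.random.default_rng(0)
        father, mother, other_f, other_m = {}, {}, {}, {}
        child = {}
        for l, fr in freqs.items():
            al = sorted(fr)
            father[l] = (al[0], al[0])
            mother[l] = (al[1], al[1])
            child[l] = (al[0], al[1])
            other_f[l] = (al[2], al[2])  # excluded at every locus
            other_m[l] = (al[3], al[3])
        ft = AlleleFrequencyTable(freqs, {l: 24 for l in freqs})
        males = [_g("f", father, "male"), _g("xf", other_f, "male")]
        females = [_g("m", mother, "female"), _g("xm", other_m, "female")]
        assigns, _ = assign_parent_pairs(
            [_g("o", child)], males, females, ft, error_rate=0.0
        )
        a = assigns[0]
        assert (a.father_id, a.mother_id) == ("f", "m")
        assert a.assignment_probability == pytest.approx(1.0, abs=1e-6)
        assert a.n_excluding_loci_best_pair == 0

    def test_no_compatible_pair_goes_unsampled(self):
        freqs = self._panel()
        child, f, m = {}, {}, {}
        for l, fr in freqs.items():
            al = sorted(fr)
            child[l] = (al[0], al[0])
            f[l] = (al[1], al[1])
            m[l] = (al[2], al[2])
        ft = AlleleFrequencyTable(freqs, {l: 24 for l in freqs})
        assigns, _ = assign_parent_pairs(
            [_g("o", child)], [_g("f", f, "male")], [_g("m", m, "female")],
            ft, error_rate=0.0,
        )
        assert assigns[0].father_id is None
        assert assigns[0].posterior[("<unsampled>", "<unsampled>")] == pytest.approx(1.0)

    def test_posterior_normalizes(self):
        freqs = self._panel(5)
        rng = np.random.default_rng(1)
        ft = AlleleFrequencyTable(freqs, {l: 24 for l in freqs})

        def rand(iid, sex=None):
            calls = {
                l: tuple(sorted(rng.choice(sorted(fr), 2, p=list(fr.values()))))
                for l, fr in freqs.items()
            }
            return _g(iid, calls, sex)

        males = [rand(f"M{i}", "male") for i in range(3)]
        females = [rand(f"F{i}", "female") for i in range(3)]
        assigns, _ = assign_parent_pairs(
            [rand("o")], males, females, ft, error_rate=0.02
        )
        assert sum(assigns[0].posterior.values()) == pytest.approx(1.0, abs=1e-9)

    def test_error_free_assignment_never_excluded(self):
        """With error_rate=0 an assigned pair has zero excluding loci."""
        truth, reps, sex_calls, _ = simulate_population(SimConfig(seed=21))
        from msatpop.simdata import true_consensus_genotypes

        inds = true_consensus_genotypes(truth)
        ft = allele_frequencies(inds)
        males = [g for g in inds if g.sex == "male"]
        females = [g for g in inds if g.sex == "female"]
        offspring = [g for g in inds if g.individual_id in truth.pedigree]
        assigns, _ = assign_parent_pairs(
            offspring, males, females, ft, error_rate=0.0, resolve_cycles=True
        )
        for a in assigns:
            if a.father_id is not None:
                assert a.n_excluding_loci_best_pair == 0

    def test_cycle_detection_and_resolution(self):
        # two individuals assigned as each other's parent: strict -> error
        freqs = {"L": {100: 0.5, 102: 0.5}}
        ft = AlleleFrequencyTable(freqs, {"L": 8})
        a = _g("a", {"L": (100, 102)}, "male")
        b = _g("b", {"L": (100, 102)}, "female")
        import networkx as nx
        from msatpop.parentage import PedigreeAssignment

        # construct the degenerate situation directly via the public API:
        # each is offspring with the other as sole candidate; with one
        # uninformative locus both may exceed no threshold -> force it
        assigns, graph = assign_parent_pairs(
            [a, b], [a], [b], ft, error_rate=0.0, prob_threshold=0.0,
            resolve_cycles=True,
        )
        assert nx.is_directed_acyclic_graph(graph)

    def test_full_sib_groups(self):
        from msatpop.parentage import PedigreeAssignment

        assigns = [
            PedigreeAssignment("c1", "f", "m", 0.99, 0, 10),
            PedigreeAssignment("c2", "f", "m", 0.98, 0, 10),
            PedigreeAssignment("c3", "f2", "m", 0.97, 0, 10),
            PedigreeAssignment("c4", None, None, 0.5, 0, 10),
        ]
        assert full_sib_groups(assigns) == [["c1", "c2"]]


class TestSimulationRecovery:
    def test_true_parents_top_ranked_and_no_wrong_assignment(self):
        """>=90% top-ranked true pairs; zero wrong assignments at 0.95."""
        tot = top_correct = wrong = 0
        for seed in range(10):
            truth, reps, sex_calls, _ = simulate_population(SimConfig(seed=seed))
            cons = call_consensus(reps)
            rates = error_rates(reps, cons)
            inds, clusters, _, _ = identify_individuals(cons, sex_calls)
            owner = {
                ind.individual_id: truth.sample_map[c[0]]
                for ind, c in zip(inds, clusters)
            }
            ft = allele_frequencies(inds)
            ado = rates.ado_per_allele
            e = max(float(ado) if np.isfinite(ado) else 0.0, 0.01)
            adults = {
                iid for iid in truth.true_genotypes if iid not in truth.pedigree
            }
            males = [g for g in inds
                     if g.sex == "male" and owner[g.individual_id] in adults]
            females = [g for g in inds
                       if g.sex == "female" and owner[g.individual_id] in adults]
            offspring = [g for g in inds if owner[g.individual_id] in truth.pedigree]
            assigns, _ = assign_parent_pairs(
                offspring, males, females, ft, error_rate=e, prob_threshold=0.95
            )
            for a in assigns:
                if a.n_typed_loci < 8:
                    continue
                tf, tm = truth.pedigree[owner[a.offspring_id]]
                top = max(a.posterior.items(), key=lambda kv: kv[1])[0]
                top_pair = (owner.get(top[0], top[0]), owner.get(top[1], top[1]))
                tot += 1
                top_correct += top_pair == (tf, tm)
                if a.father_id is not None:
                    got = (owner.get(a.father_id), owner.get(a.mother_id))
                    wrong += got != (tf, tm)
        assert tot >= 40
        assert top_correct / tot >= 0.90
        assert wrong == 0
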