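"""Likelihood-based parent-pair assignment with a genotyping-error model.

For each offspring, every (candidate father, candidate mother) pair is
scored by the multilocus probability of the offspring's observed
genotype given the pair's observed genotypes under Mendelian
segregation, allowing each observed genotype to be a mistyping: with
probability ``error_rate`` an observed genotype is a random draw from
Hardy–Weinberg genotype frequencies instead of the true one. An
"unsampled parents" alternative integrates the parental genotypes over
HWE frequencies. Posteriors over the pair space (flat prior) yield an
assignment when the best pair reaches the probability threshold.

This is a trio-likelihood (pairwise/parent-pair) method in the CERVUS
tradition, sized for very small populations; full-pedigree sibship MCMC
is out of scope, but individuals sharing both assigned parents are
labelled full sibs as a follow-on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .genotypes import AlleleFrequencyTable, MultilocusGenotype

__all__ = [
    "PedigreeAssignment",
    "PedigreeError",
    "trio_likelihood",
    "assign_parent_pairs",
    "full_sib_groups",
]


class PedigreeError(ValueError):
    """Inconsistent pedigree (cycles / an individual ancestral to itself)."""


@dataclass
class PedigreeAssignment:
    offspring_id: str
    father_id: "str | None"
    mother_id: "str | None"
    assignment_probability: float
    n_excluding_loci_best_pair: int
    n_typed_loci: int
    #: posterior over every candidate pair plus ("<unsampled>", "<unsampled>")
    posterior: dict = field(repr=False, default_factory=dict)


# ---------------------------------------------------------------------------
# per-locus machinery
# ---------------------------------------------------------------------------

def _hwe_genotype_probs(freqs_locus: dict) -> dict:
    """Unordered genotype -> HWE probability at one locus."""
    out = {}
    alleles = sorted(freqs_locus)
    for a, b in combinations_with_replacement(alleles, 2):
        pa, pb = freqs_locus[a], freqs_locus[b]
        out[(a, b)] = pa * pb if a == b else 2.0 * pa * pb
    return out


def _transmission_prob(go, gf, gm) -> float:
    """P(offspring genotype | father, mother) under Mendelian segregation."""
    p = 0.0
    for fa in gf:
        for ma in gm:
            pair = (fa, ma) if fa <= ma else (ma, fa)
            if pair == go:
                p += 0.25
    return p


def _obs_given_true(obs, true_g, hwe_probs: dict, e: float) -> float:
    """P(observed genotype | true genotype) under the HWE-mistyping model."""
    p = e * hwe_probs.get(obs, 0.0)
    if obs == true_g:
        p += 1.0 - e
    return p


def _posterior_true(obs, hwe_probs: dict, e: float) -> dict:
    """P(true genotype | observed genotype), prior = HWE."""
    weights = {g: hwe_probs[g] * _obs_given_true(obs, g, hwe_probs, e)
               for g in hwe_probs}
    tot = sum(weights.values())
    return {g: w / tot for g, w in weights.items() if w > 0}


def _locus_offspring_lik(obs_o, obs_f, obs_m, freqs_locus: dict, e: float) -> float:
    """P(obs_o | obs_f, obs_m) at one locus, marginalizing true genotypes.

    A missing parent observation (None) integrates that parent's genotype
    over HWE frequencies.
    """
    hwe = _hwe_genotype_probs(freqs_locus)
    post_f = _posterior_true(obs_f, hwe, e) if obs_f is not None else hwe
    post_m = _posterior_true(obs_m, hwe, e) if obs_m is not None else hwe
    lik = 0.0
    for gf, wf in post_f.items():
        for gm, wm in post_m.items():
            inner = 0.0
            for go in hwe:
                t = _transmission_prob(go, gf, gm)
                if t > 0.0:
                    inner += t * _obs_given_true(obs_o, go, hwe, e)
            lik += wf * wm * inner
    return lik


def _locus_unrelated_lik(obs_o, freqs_locus: dict, e: float) -> float:
    """P(obs_o) when both parents are unsampled (offspring genotype ~ HWE)."""
    hwe = _hwe_genotype_probs(freqs_locus)
    return sum(hwe[g] * _obs_given_true(obs_o, g, hwe, e) for g in hwe)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def trio_likelihood(offspring: MultilocusGenotype,
                    father: "MultilocusGenotype | None",
                    mother: "MultilocusGenotype | None",
                    freqs: AlleleFrequencyTable,
                    error_rate: float = 0.01) -> float:
    """Multilocus log-likelihood log P(offspring obs | parent pair obs).

    Loci where the offspring is untyped are skipped; a parent untyped at
    a locus is integrated over HWE frequencies there. With
    ``error_rate=0`` a Mendelian-impossible trio returns -inf.
    """
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    loglik = 0.0
    n_informative = 0
    for locus in freqs.loci:
        obs_o = offspring.calls.get(locus)
        if obs_o is None:
            continue
        n_informative += 1
        obs_f = father.calls.get(locus) if father is not None else None
        obs_m = mother.calls.get(locus) if mother is not None else None
        lik = _locus_offspring_lik(obs_o, obs_f, obs_m, freqs[locus], error_rate)
        loglik += -np.inf if lik <= 0.0 else float(np.log(lik))
    if n_informative == 0:
        raise ValueError(
            f"offspring {offspring.individual_id}: no typed locus shared "
            "with the frequency table"
        )
    return loglik


def _n_excluding_loci(offspring, father, mother, loci) -> int:
    """Loci at which the trio is Mendelian-impossible (error-free)."""
    n = 0
    for locus in loci:
        go = offspring.calls.get(locus)
        gf = father.calls.get(locus) if father else None
        gm = mother.calls.get(locus) if mother else None
        if go is None or gf is None or gm is None:
            continue
        if _transmission_prob(go, gf, gm) <= 0.0:
            n += 1
    return n


def assign_parent_pairs(offspring_set, candidate_males, candidate_females,
                        freqs: AlleleFrequencyTable, error_rate: float = 0.01,
                        prob_threshold: float = 0.95,
                        resolve_cycles: bool = False):
    """Posterior parent-pair assignment for each offspring.

    The hypothesis space per offspring is every (male, female) candidate
    pair (excluding the offspring itself) plus a single "both parents
    unsampled" alternative, with a flat prior. An assignment is emitted
    when the maximum posterior probability reaches ``prob_threshold``.

    Returns ``(assignments, pedigree_graph)``; the graph has a
    parent → offspring edge per assigned parent and is checked for
    cycles (an individual ancestral to itself raises PedigreeError).
    With ``resolve_cycles`` the lowest-probability assignment on each
    cycle is retracted instead — useful when every individual is run as
    a potential offspring and candidate lists overlap the offspring set.
    """
    assignments = []
    graph = nx.DiGraph()
    unsampled = ("<unsampled>", "<unsampled>")
    for off in offspring_set:
        graph.add_node(off.individual_id)
        hyps = []
        logliks = []
        for f in candidate_males:
            if f.individual_id == off.individual_id:
                continue
            for m in candidate_females:
                if m.individual_id == off.individual_id:
                    continue
                hyps.append((f, m))
                logliks.append(trio_likelihood(off, f, m, freqs, error_rate))
        hyps.append(None)
        logliks.append(
            sum(
                float(np.log(_locus_unrelated_lik(off.calls[l], freqs[l], error_rate)))
                for l in freqs.loci if off.calls.get(l) is not None
            )
        )
        logliks = np.array(logliks)
        post = np.exp(logliks - logsumexp(logliks))
        posterior = {}
        for h, pr in zip(hyps, post):
            key = unsampled if h is None else (h[0].individual_id, h[1].individual_id)
            posterior[key] = float(pr)
        best = int(np.argmax(post))
        best_h = hyps[best]
        best_p = float(post[best])
        if best_h is not None and best_p >= prob_threshold:
            f, m = best_h
            n_excl = _n_excluding_loci(off, f, m, freqs.loci)
            assignments.append(
                PedigreeAssignment(
                    off.individual_id, f.individual_id, m.individual_id,
                    best_p, n_excl, off.n_typed(), posterior,
                )
            )
            graph.add_edge(f.individual_id, off.individual_id)
            graph.add_edge(m.individual_id, off.individual_id)
        else:
            assignments.append(
                PedigreeAssignment(
                    off.individual_id, None, None,
                    best_p if best_h is None else float(posterior[unsampled]),
                    0, off.n_typed(), posterior,
                )
            )
    by_off = {a.offspring_id: a for a in assignments}
    while not nx.is_directed_acyclic_graph(graph):
        cyc = nx.find_cycle(graph)
        if not resolve_cycles:
            raise PedigreeError(f"pedigree contains a cycle: {cyc}")
        weakest = min(
            (by_off[v] for _, v in cyc if by_off[v].father_id is not None),
            key=lambda a: a.assignment_probability,
        )
        graph.remove_edges_from(
            [(weakest.father_id, weakest.offspring_id),
             (weakest.mother_id, weakest.offspring_id)]
        )
        weakest.father_id = None
        weakest.mother_id = None
    return assignments, graph


def full_sib_groups(assignments) -> list:
    """Group assigned offspring sharing both parents (full-sib sets)."""
    by_pair: dict = {}
    for a in assignments:
        if a.father_id is not None and a.mother_id is not None:
            by_pair.setdefault((a.father_id, a.mother_id), []).append(a.offspring_id)
    return sorted(sorted(v) for v in by_pair.values() if len(v) > 1)
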