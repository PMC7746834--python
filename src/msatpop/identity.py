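"""Individual identification from multilocus genotypes.

Probability of identity (PID) for unrelated individuals and for full
sibs quantify how well the marker panel discriminates individuals; the
cumulative curve over increasingly informative loci tells how many loci
are needed. Samples are collapsed into individuals by exact multilocus
genotype matching over co-typed loci, with a conservative one-mismatch
"inconclusive" band (a single mismatch can be a residual allelic
dropout), and sex-marker band patterns supply each individual's sex
(males show 2-3 bands, females exactly 1).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencyTable, MultilocusGenotype, allele_frequencies
from .repqc import ConsensusResult, consensus_genotypes

__all__ = [
    "IdentityPanel",
    "MatchDecision",
    "SexConflictError",
    "pid_unbiased",
    "pid_sib",
    "cumulative_identity_curve",
    "match_samples",
    "call_sex",
    "identify_individuals",
]


class SexConflictError(ValueError):
    """A genotype cluster contains samples with conflicting sex calls."""


# ---------------------------------------------------------------------------
# probability of identity
# ---------------------------------------------------------------------------

def pid_unbiased(freqs: AlleleFrequencyTable, locus: str) -> float:
    """PID for two unrelated individuals: 2(Σp_i²)² − Σp_i⁴.

    A monomorphic locus returns 1 (no discrimination).
    """
    p = np.array(list(freqs[locus].values()))
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 2.0 * s2 ** 2 - s4


def pid_sib(freqs: AlleleFrequencyTable, locus: str) -> float:
    """PID for two full siblings: 0.25 + 0.5Σp² + 0.5(Σp²)² − 0.25Σp⁴."""
    p = np.array(list(freqs[locus].values()))
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    return 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4


@dataclass
class IdentityPanel:
    """Per-locus and cumulative discriminating power of a marker panel.

    Loci are ordered most → least informative (ascending per-locus PID);
    cumulative values are running products in that order.
    """

    table: pd.DataFrame  # columns: locus, pid, pid_sib, cum_pid, cum_pid_sib
    pid_max: float
    pid_sib_max: float
    #: minimal number of loci with cumulative PID < pid_max (None if never)
    n_loci_pid: "int | None"
    n_loci_pid_sib: "int | None"
    monomorphic: list = field(default_factory=list)


def cumulative_identity_curve(freqs: AlleleFrequencyTable,
                              pid_max: float = 0.001,
                              pid_sib_max: float = 0.01) -> IdentityPanel:
    """Cumulative PID / PIDsib curve over loci sorted by informativeness."""
    rows = []
    mono = []
    for locus in freqs.loci:
        pid = pid_unbiased(freqs, locus)
        psib = pid_sib(freqs, locus)
        if len(freqs[locus]) < 2:
            mono.append(locus)
        rows.append((locus, pid, psib))
    if not rows:
        raise ValueError("empty panel")
    df = pd.DataFrame(rows, columns=["locus", "pid", "pid_sib"])
    df = df.sort_values(["pid", "locus"], kind="stable").reset_index(drop=True)
    df["cum_pid"] = df["pid"].cumprod()
    df["cum_pid_sib"] = df["pid_sib"].cumprod()

    def crossing(col, thr):
        hit = df.index[df[col] < thr]
        return int(hit[0]) + 1 if len(hit) else None

    return IdentityPanel(
        table=df,
        pid_max=pid_max,
        pid_sib_max=pid_sib_max,
        n_loci_pid=crossing("cum_pid", pid_max),
        n_loci_pid_sib=crossing("cum_pid_sib", pid_sib_max),
        monomorphic=mono,
    )


# ---------------------------------------------------------------------------
# genotype matching
# ---------------------------------------------------------------------------

@dataclass
class MatchDecision:
    sample_a: str
    sample_b: str
    n_compared_loci: int
    n_mismatches: int
    verdict: str  # "same" | "different" | "inconclusive"


def _pairwise_verdict(ga: MultilocusGenotype, gb: MultilocusGenotype,
                      min_overlap: int, max_mismatch: int) -> MatchDecision:
    shared = [l for l in ga.calls if ga.calls[l] is not None
              and gb.calls.get(l) is not None]
    mism = sum(1 for l in shared if ga.calls[l] != gb.calls[l])
    if len(shared) < min_overlap:
        verdict = "inconclusive"
    elif mism <= max_mismatch:
        verdict = "same"
    elif mism == max_mismatch + 1:
        # one residual mismatch may be an uncorrected dropout: flag for review
        verdict = "inconclusive"
    else:
        verdict = "different"
    return MatchDecision(ga.individual_id, gb.individual_id, len(shared), mism, verdict)


def match_samples(consensus, min_overlap: int = 5, max_mismatch: int = 0,
                  sexes: "dict | None" = None):
    """Collapse samples into individuals by multilocus genotype matching.

    ``consensus`` may be a :class:`~msatpop.repqc.ConsensusResult` or a
    list of :class:`MultilocusGenotype`. Returns ``(decisions, clusters)``
    where clusters (a partition of the samples) are connected components
    of the verdict=same graph. If ``sexes`` maps samples to sex calls, a
    cluster mixing "male" and "female" raises :class:`SexConflictError`.
    """
    if isinstance(consensus, ConsensusResult):
        genotypes = consensus_genotypes(consensus, sexes=sexes)
    else:
        genotypes = list(consensus)
    decisions = []
    g = nx.Graph()
    g.add_nodes_from(x.individual_id for x in genotypes)

    def sex_conflict(a, b):
        if not sexes:
            return False
        sa, sb = sexes.get(a), sexes.get(b)
        return sa in ("male", "female") and sb in ("male", "female") and sa != sb

    for i in range(len(genotypes)):
        for j in range(i + 1, len(genotypes)):
            d = _pairwise_verdict(genotypes[i], genotypes[j], min_overlap, max_mismatch)
            # the sex marker is part of the multilocus identity: a known
            # sex conflict rules out "same" regardless of autosomal match
            if d.verdict != "different" and sex_conflict(d.sample_a, d.sample_b):
                d.verdict = "different"
            decisions.append(d)

    # conflict-aware transitive closure: apply "same" edges strongest
    # (most co-typed loci) first, never joining two components that
    # contain a "different" pair — a clear multi-locus mismatch is
    # stronger evidence than a match over a minimal locus overlap.
    cannot = {frozenset((d.sample_a, d.sample_b))
              for d in decisions if d.verdict == "different"}
    edges = sorted(
        (d for d in decisions if d.verdict == "same"),
        key=lambda d: (-d.n_compared_loci, d.sample_a, d.sample_b),
    )
    comp = {x.individual_id: {x.individual_id} for x in genotypes}
    for d in edges:
        ca, cb = comp[d.sample_a], comp[d.sample_b]
        if ca is cb:
            continue
        if any(frozenset((a, b)) in cannot for a in ca for b in cb):
            continue  # conflicting evidence: leave split, pairs stay listed
        ca |= cb
        for x in cb:
            comp[x] = ca
        g.add_edge(d.sample_a, d.sample_b)
    clusters = sorted((sorted(c) for c in nx.connected_components(g)),
                      key=lambda c: c[0])
    if sexes:
        for c in clusters:
            sx = {sexes.get(s) for s in c} - {None, "unknown"}
            if len(sx) > 1:
                raise SexConflictError(
                    f"cluster {c} mixes sex calls {sorted(sx)}"
                )
    return decisions, clusters


# ---------------------------------------------------------------------------
# sex markers
# ---------------------------------------------------------------------------

def call_sex(band_patterns: "dict[str, list[int]]") -> dict:
    """Sex per sample from marker band counts (>=2 male, 1 female, 0 unknown).

    Replicates that disagree give "unknown" with a warning.
    """
    def one(bands: int) -> str:
        if bands >= 2:
            return "male"
        if bands == 1:
            return "female"
        return "unknown"

    out = {}
    for sample, reps in band_patterns.items():
        calls = {one(b) for b in reps} - {"unknown"}
        if len(calls) == 1:
            out[sample] = calls.pop()
        elif len(calls) > 1:
            warnings.warn(
                f"sample {sample}: conflicting sex-marker replicates {reps}",
                stacklevel=2,
            )
            out[sample] = "unknown"
        else:
            out[sample] = "unknown"
    return out


# ---------------------------------------------------------------------------
# end-to-end identification
# ---------------------------------------------------------------------------

def _merged_genotype(members) -> dict:
    """Consensus-of-consensus across a cluster, preferring heterozygotes.

    Allelic dropout can turn a true heterozygote into an apparent
    homozygote but never the reverse (false alleles are filtered at
    consensus), so a heterozygote call seen in any member overrides
    homozygote calls sharing one of its alleles. Ties break to the most
    frequent, then lexicographically smallest, call.
    """
    loci = sorted({l for g in members for l in g.calls})
    merged = {}
    for loc in loci:
        calls = [g.calls[loc] for g in members if g.calls.get(loc) is not None]
        if not calls:
            merged[loc] = None
            continue
        hets = [c for c in calls if c[0] != c[1]]
        pool = hets if hets else calls
        cnt = Counter(pool)
        top = max(cnt.values())
        merged[loc] = min(c for c, n in cnt.items() if n == top)
    return merged


def _attach_conflicts(single_calls: dict, cluster_calls: dict):
    """(hard, soft, overlap): soft = singleton-hom vs cluster-het w/ shared allele."""
    hard = soft = overlap = 0
    for loc, cs in single_calls.items():
        cc = cluster_calls.get(loc)
        if cs is None or cc is None:
            continue
        overlap += 1
        if cs == cc:
            continue
        if cs[0] == cs[1] and cc[0] != cc[1] and cs[0] in cc:
            soft += 1  # explainable by residual dropout in the orphan sample
        else:
            hard += 1
    return hard, soft, overlap


def _reconcile_singletons(genotypes, clusters, sexes, min_overlap: int) -> list:
    """Attach an orphan sample to the unique cluster it is compatible with.

    A singleton whose genotype shows no hard conflict and at most one
    dropout-explainable (homozygote-vs-heterozygote) conflict against
    exactly one cluster's merged genotype, over at least ``min_overlap``
    co-typed loci and without sex conflict, joins that cluster. This is
    the deterministic analogue of the manual review of dropout-flagged
    sample pairs in field studies; ambiguous orphans stay separate.
    """
    by_id = {g.individual_id: g for g in genotypes}
    merged = [list(c) for c in clusters]
    for i, c in enumerate(clusters):
        if len(c) != 1 or c[0] not in by_id:
            continue
        s = c[0]
        candidates = []
        for j, other in enumerate(clusters):
            if j == i or not merged[j]:
                continue
            cluster_calls = _merged_genotype([by_id[x] for x in other if x in by_id])
            hard, soft, overlap = _attach_conflicts(by_id[s].calls, cluster_calls)
            if overlap >= min_overlap and hard == 0 and soft <= 1:
                candidates.append(j)
        if len(candidates) == 1:
            j = candidates[0]
            sx = {sexes.get(x) for x in merged[j] + [s]} - {None, "unknown"}
            if len(sx) <= 1:
                merged[j].extend(merged[i])
                merged[i] = []
    return sorted((sorted(c) for c in merged if c), key=lambda c: c[0])


def identify_individuals(consensus: ConsensusResult,
                         band_patterns: "dict | None" = None,
                         min_overlap: int = 5, max_mismatch: int = 0,
                         groups: "dict | None" = None,
                         reconcile: bool = True):
    """Samples → individuals with sexes, plus the panel's identity curve.

    One representative genotype per cluster (the sample typed at most
    loci; within a cluster, loci are merged preferring called values) is
    emitted as the individual. PID frequencies are computed from the
    deduplicated individual set — one frequency pass after clustering —
    to avoid pseudo-replication from multiply-sampled individuals. With
    ``reconcile`` (default) unambiguous one-mismatch orphan samples are
    folded into their unique matching cluster, emulating the manual
    review of dropout-flagged pairs.

    Returns ``(individuals, clusters, decisions, panel)``.
    """
    sexes = call_sex(band_patterns) if band_patterns else {}
    decisions, clusters = match_samples(
        consensus, min_overlap=min_overlap, max_mismatch=max_mismatch, sexes=sexes
    )
    if reconcile:
        clusters = _reconcile_singletons(
            list(consensus_genotypes(consensus)), clusters, sexes, min_overlap
        )
    genotypes = {g.individual_id: g for g in consensus_genotypes(consensus)}
    individuals = []
    for idx, cluster in enumerate(clusters):
        members = [genotypes[s] for s in cluster if s in genotypes]
        if not members:
            continue
        merged = _merged_genotype(members)
        for loc in genotypes[cluster[0]].calls:
            merged.setdefault(loc, None)
        sx = {sexes.get(s) for s in cluster} - {None, "unknown"}
        grp = {(groups or {}).get(s) for s in cluster} - {None}
        individuals.append(
            MultilocusGenotype(
                f"IND{idx + 1:02d}",
                merged,
                sex=sx.pop() if sx else None,
                group=grp.pop() if len(grp) == 1 else None,
            )
        )
    panel = cumulative_identity_curve(allele_frequencies(individuals)) \
        if individuals else None
    return individuals, clusters, decisions, panel
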