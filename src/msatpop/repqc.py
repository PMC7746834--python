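"""Consensus genotype calling from PCR replicates and reliability metrics.

Implements the multi-tubes consensus rule (a heterozygote needs each
allele confirmed in >= 2 replicates; a homozygote needs its single allele
as the only supported allele in >= 3 replicates), plus the standard
noninvasive-genotyping quality metrics:

* ADO rate — among successful replicates of heterozygous-consensus
  cells, the fraction appearing homozygous for one consensus allele;
* FA rate — among successful replicates of called cells, the fraction
  containing an allele absent from the consensus;
* PCR success rate — replicates exactly matching the consensus over
  replicates attempted at called cells;
* quality index QI — per cell the proportion of replicates matching the
  consensus, averaged per locus, per sample and globally.

Failed replicates count against QI and the PCR success rate (a failed
PCR is not a correct genotype) but are excluded from ADO/FA denominators,
which condition on successful amplification.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import ReplicateCallSet, MultilocusGenotype

__all__ = [
    "ConsensusResult",
    "ErrorRates",
    "QualityIndex",
    "call_consensus",
    "error_rates",
    "quality_index",
    "consensus_genotypes",
]


@dataclass
class ConsensusResult:
    """Consensus calls and per-cell replicate support."""

    #: (sample, locus) -> allele pair or None (missing / not callable)
    calls: dict
    #: (sample, locus) -> {allele: number of successful replicates containing it}
    support: dict
    #: (sample, locus) -> number of replicates attempted
    n_attempted: dict
    #: (sample, locus) -> number of successful replicates
    n_successful: dict

    def called_cells(self) -> list:
        return sorted(k for k, v in self.calls.items() if v is not None)

    @property
    def samples(self) -> list:
        return sorted({s for s, _ in self.calls})

    @property
    def loci(self) -> list:
        return sorted({l for _, l in self.calls})


def call_consensus(reps: ReplicateCallSet, min_het_obs: int = 2,
                   min_hom_reps: int = 3) -> ConsensusResult:
    """Multi-tubes consensus per sample × locus.

    A heterozygote A/B is called iff exactly two alleles are each seen in
    >= ``min_het_obs`` successful replicates. A homozygote A/A is called
    iff A is the only allele with >= ``min_het_obs`` observations and A
    appears in >= ``min_hom_reps`` successful replicates (alleles seen
    once are treated as contradicted false alleles and excluded). All
    other patterns give a missing consensus.
    """
    n_rep_max = max((r for _, _, r in reps.entries), default=0)
    if min_het_obs > n_rep_max:
        raise ValueError(
            f"min_het_obs={min_het_obs} exceeds the replicate count {n_rep_max}"
        )
    calls, support, n_att, n_succ = {}, {}, {}, {}
    for cell in reps.cells():
        sample, locus = cell
        rep_calls = reps.replicates_for(sample, locus)
        succ = [c for c in rep_calls if c is not None]
        cnt: Counter = Counter()
        for c in succ:
            for a in set(c):
                cnt[a] += 1
        supported = sorted(a for a, n in cnt.items() if n >= min_het_obs)
        if len(supported) == 2:
            consensus = (supported[0], supported[1])
        elif len(supported) == 1 and cnt[supported[0]] >= min_hom_reps:
            consensus = (supported[0], supported[0])
        else:
            consensus = None
        calls[cell] = consensus
        support[cell] = dict(cnt)
        n_att[cell] = len(rep_calls)
        n_succ[cell] = len(succ)
    return ConsensusResult(calls, support, n_att, n_succ)


@dataclass
class ErrorRates:
    """Genotyping error/reliability rates, global and per locus.

    ``ado_rate`` is the observed per-replicate dropout rate (a replicate
    of a heterozygous-consensus cell appearing homozygous for one
    consensus allele). Because each allele of a heterozygote can drop
    independently and double dropouts fail outright, the observed rate x
    relates to the per-allele dropout probability p by x = 2p/(1+p);
    ``ado_per_allele`` reports the inverted estimate p = x/(2-x).
    ``amplification_success_rate`` is successful / attempted replicates
    over all cells, the upstream PCR performance figure.
    """

    ado_rate: float
    fa_rate: float
    pcr_success_rate: float
    ado_per_allele: float
    amplification_success_rate: float
    n_het_replicates: int
    n_called_replicates: int
    per_locus: pd.DataFrame = field(repr=False, default=None)


def _is_dropout(call, consensus) -> bool:
    a, b = consensus
    return call is not None and (call == (a, a) or call == (b, b))


def error_rates(reps: ReplicateCallSet, consensus: ConsensusResult) -> ErrorRates:
    """ADO, FA and PCR-success rates relative to the consensus genotypes."""
    per_locus_rows = []
    tot = Counter()
    for locus in consensus.loci:
        c = Counter()
        for cell in consensus.called_cells():
            if cell[1] != locus:
                continue
            sample = cell[0]
            cons = consensus.calls[cell]
            het = cons[0] != cons[1]
            cons_set = set(cons)
            for call in reps.replicates_for(sample, locus):
                c["attempted"] += 1
                if call is None:
                    continue
                c["successful"] += 1
                if call == cons:
                    c["match"] += 1
                if set(call) - cons_set:
                    c["fa"] += 1
                if het:
                    c["het_successful"] += 1
                    if _is_dropout(call, cons):
                        c["ado"] += 1
        tot.update(c)
        per_locus_rows.append(
            (
                locus,
                c["ado"] / c["het_successful"] if c["het_successful"] else np.nan,
                c["fa"] / c["successful"] if c["successful"] else np.nan,
                c["match"] / c["attempted"] if c["attempted"] else np.nan,
                c["het_successful"],
                c["successful"],
                c["attempted"],
            )
        )
    # amplification success over *all* cells, called or not
    n_all = len(reps.entries)
    n_all_succ = sum(1 for v in reps.entries.values() if v is not None)

    ado = tot["ado"] / tot["het_successful"] if tot["het_successful"] else np.nan
    fa = tot["fa"] / tot["successful"] if tot["successful"] else np.nan
    succ = tot["match"] / tot["attempted"] if tot["attempted"] else np.nan
    per_locus = pd.DataFrame(
        per_locus_rows,
        columns=[
            "locus", "ado_rate", "fa_rate", "pcr_success_rate",
            "n_het_successful", "n_successful", "n_attempted",
        ],
    )
    return ErrorRates(
        ado_rate=ado,
        fa_rate=fa,
        pcr_success_rate=succ,
        ado_per_allele=(ado / (2.0 - ado)) if np.isfinite(ado) else np.nan,
        amplification_success_rate=n_all_succ / n_all if n_all else np.nan,
        n_het_replicates=int(tot["het_successful"]),
        n_called_replicates=int(tot["successful"]),
        per_locus=per_locus,
    )


@dataclass
class QualityIndex:
    """Quality index per locus, per sample and globally.

    QI of a called cell is the proportion of its attempted replicates
    whose call equals the consensus; per-locus and per-sample values are
    means of the defined cells, and the global QI is the mean over all
    defined cells.
    """

    qi_locus: dict
    qi_sample: dict
    qi_global: float
    #: (sample, locus) -> QI of the cell (defined cells only)
    qi_cell: dict


def quality_index(reps: ReplicateCallSet, consensus: ConsensusResult) -> QualityIndex:
    qi_cell = {}
    for cell in consensus.called_cells():
        sample, locus = cell
        cons = consensus.calls[cell]
        rep_calls = reps.replicates_for(sample, locus)
        n_match = sum(1 for c in rep_calls if c == cons)
        qi_cell[cell] = n_match / len(rep_calls)
    if not qi_cell:
        raise ValueError("no called cells: quality index undefined")
    by_locus: dict = {}
    by_sample: dict = {}
    for (sample, locus), v in qi_cell.items():
        by_locus.setdefault(locus, []).append(v)
        by_sample.setdefault(sample, []).append(v)
    return QualityIndex(
        qi_locus={l: float(np.mean(v)) for l, v in by_locus.items()},
        qi_sample={s: float(np.mean(v)) for s, v in by_sample.items()},
        qi_global=float(np.mean(list(qi_cell.values()))),
        qi_cell=qi_cell,
    )


def consensus_genotypes(consensus: ConsensusResult,
                        sexes: "dict | None" = None,
                        groups: "dict | None" = None) -> list:
    """Package consensus calls as one MultilocusGenotype per sample.

    Samples with no called locus are skipped (they carry no genotype
    information for downstream stages).
    """
    out = []
    loci = consensus.loci
    for sample in consensus.samples:
        calls = {loc: consensus.calls.get((sample, loc)) for loc in loci}
        if not any(c is not None for c in calls.values()):
            continue
        out.append(
            MultilocusGenotype(
                sample,
                calls,
                sex=(sexes or {}).get(sample),
                group=(groups or {}).get(sample),
            )
        )
    return out
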