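"""Current-vs-historical cohort comparison: allele loss and frequency classes.

A shrinking population loses rare alleles first. Comparing the current
allele-frequency table against a published historical one, per shared
locus, gives the allele-set difference (lost / gained alleles, allele
counts) and per-cohort histograms of alleles over ten equal-width
frequency classes on (0, 1]: class k covers ((k−1)/10, k/10], class 1
covering (0, 0.1]. Depletion of the low classes in the current cohort
is the signature of recent loss of rare variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencyTable

__all__ = ["CohortComparison", "compare_cohorts", "frequency_class_histogram"]


def frequency_class_histogram(freqs: AlleleFrequencyTable,
                              loci: "list | None" = None) -> np.ndarray:
    """Counts of alleles per frequency class 1..10 over the given loci."""
    counts = np.zeros(10, dtype=int)
    for locus in (loci if loci is not None else freqs.loci):
        for p in freqs[locus].values():
            # class k covers ((k-1)/10, k/10]
            k = int(np.ceil(p * 10.0 - 1e-12))
            counts[min(max(k, 1), 10) - 1] += 1
    return counts


@dataclass
class CohortComparison:
    #: per-locus table: na_current, na_historical, alleles_lost, alleles_gained
    per_locus: pd.DataFrame
    hist_current: np.ndarray
    hist_historical: np.ndarray
    n_loci_decreased: int
    n_loci_equal: int
    n_loci_increased: int
    shared_loci: list = field(default_factory=list)


def compare_cohorts(current: AlleleFrequencyTable,
                    historical: AlleleFrequencyTable) -> CohortComparison:
    """Per-locus allele loss/gain and frequency-class redistribution.

    Alleles are matched by binned length; only loci present in both
    tables are compared (none shared is an error). Losses and gains are
    reported symmetrically, without interpretation.
    """
    shared = sorted(set(current.loci) & set(historical.loci))
    if not shared:
        raise ValueError("no shared loci between cohorts")
    rows = []
    dec = eq = inc = 0
    for locus in shared:
        cur = set(current[locus])
        hist = set(historical[locus])
        lost = sorted(hist - cur)
        gained = sorted(cur - hist)
        na_c, na_h = len(cur), len(hist)
        if na_c < na_h:
            dec += 1
        elif na_c == na_h:
            eq += 1
        else:
            inc += 1
        rows.append((locus, na_c, na_h, lost, gained))
    per_locus = pd.DataFrame(
        rows,
        columns=["locus", "na_current", "na_historical",
                 "alleles_lost", "alleles_gained"],
    )
    return CohortComparison(
        per_locus=per_locus,
        hist_current=frequency_class_histogram(current, shared),
        hist_historical=frequency_class_histogram(historical, shared),
        n_loci_decreased=dec,
        n_loci_equal=eq,
        n_loci_increased=inc,
        shared_loci=shared,
    )
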