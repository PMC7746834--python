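"""Linkage-disequilibrium effective population size (LD-Ne).

In a closed random-mating population of effective size Ne, drift
generates association between alleles at unlinked loci in proportion to
1/(3Ne). The estimator measures the mean squared Burrows composite
correlation r̂² across allele pairs of all locus pairs (no phase
information required), subtracts the expected sampling component
E[r̂²_sample] for the observed sample size S, and inverts the
drift-expectation formula. Alleles rarer than ``p_crit`` are screened
out because rare alleles upwardly bias r̂².

The sampling-bias and inversion coefficients are the published
random-mating small-sample corrections of the NeEstimator-v2 / LDNe
lineage; they are data, stored in :data:`NE_COEFFICIENTS`, so alternate
coefficient sets can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MultilocusGenotype

__all__ = [
    "NeEstimate",
    "NeEstimationError",
    "NE_COEFFICIENTS",
    "burrows_r2",
    "estimate_ne",
]


class NeEstimationError(ValueError):
    """Estimation impossible (fewer than two usable loci after screening)."""


#: Random-mating expectation/inversion coefficients, by sample-size regime.
#: E[r²_sample] = a0 + a1/S + a2/S²;  Ne = (b0 + sqrt(b0² − b1·r²'))/(2·r²').
NE_COEFFICIENTS = {
    "random": {
        "large": {"a": (0.0, 1.0, 3.19), "b": (1.0 / 3.0, 2.76), "min_S": 30},
        "small": {"a": (0.0018, 0.907, 4.44), "b": (0.618, 5.24)},
    }
}


def expected_r2_sample(S: float, mating_model: str = "random") -> float:
    """Expected sampling component of r̂² at (harmonic mean) sample size S."""
    coef = NE_COEFFICIENTS[mating_model]
    c = coef["large"] if S >= coef["large"]["min_S"] else coef["small"]
    a0, a1, a2 = c["a"]
    return a0 + a1 / S + a2 / S ** 2


def _ne_from_r2_drift(r2_drift: float, S: float, mating_model: str = "random") -> float:
    coef = NE_COEFFICIENTS[mating_model]
    c = coef["large"] if S >= coef["large"]["min_S"] else coef["small"]
    b0, b1 = c["b"]
    if r2_drift <= 0.0:
        return float("inf")
    disc = b0 ** 2 - b1 * r2_drift
    if disc < 0.0:
        disc = 0.0
    return (b0 + sqrt(disc)) / (2.0 * r2_drift)


# ---------------------------------------------------------------------------
# Burrows composite disequilibrium
# ---------------------------------------------------------------------------

def _allele_dosage(genotypes, locus: str):
    """Individual × allele dosage matrix (0/1/2) and allele list at a locus."""
    alleles = sorted({a for g in genotypes
                      for a in (g.calls.get(locus) or ())})
    dosage = np.full((len(genotypes), len(alleles)), -1, dtype=float)
    idx = {a: i for i, a in enumerate(alleles)}
    for r, g in enumerate(genotypes):
        call = g.calls.get(locus)
        if call is None:
            continue
        dosage[r, :] = 0.0
        dosage[r, idx[call[0]]] += 1.0
        dosage[r, idx[call[1]]] += 1.0
    return alleles, dosage  # rows with -1 mark missing individuals


def _screened_alleles(freqs: np.ndarray, p_crit: float):
    """Column indices passing the frequency screen.

    A locus needs at least two passing alleles to stay informative
    (excluding one allele of a biallelic locus leaves it monomorphic).
    A truly biallelic locus contributes a single allele (the more
    frequent): its two dosage columns carry identical |r| and would
    double-count.
    """
    keep = [j for j, p in enumerate(freqs)
            if p >= p_crit and p <= 1.0 - 1e-12]
    if len(keep) < 2:
        return []
    if len(freqs) == 2:
        return [int(np.argmax(freqs))]
    return keep


def burrows_r2(genotypes, locus_pair, p_crit: float = 0.01):
    """Mean squared Burrows composite correlation for one locus pair.

    For each retained allele pair (A at locus 1, B at locus 2), with
    dosages g_A, g_B over the S individuals typed at both loci and
    sample frequencies p_A, p_B,

        Δ̂_AB = S/(S−1) · [ (1/S) Σ g_A g_B / 2 − 2 p̂_A p̂_B ]
        r̂²_AB = Δ̂²_AB / [ p̂_A(1−p̂_A) p̂_B(1−p̂_B) ]

    Returns ``(mean_r2, n_comparisons, S)``. Alleles with frequency
    below ``p_crit`` among the shared individuals are excluded; a locus
    monomorphic after screening yields ``(nan, 0, S)``.
    """
    loc1, loc2 = locus_pair
    al1, d1 = _allele_dosage(genotypes, loc1)
    al2, d2 = _allele_dosage(genotypes, loc2)
    if not al1 or not al2:
        return float("nan"), 0, 0
    typed = (d1[:, 0] >= 0) & (d2[:, 0] >= 0)
    S = int(typed.sum())
    if S < 2:
        return float("nan"), 0, S
    # frequencies restricted to the shared (co-typed) individuals
    f1 = d1[typed].sum(axis=0) / (2.0 * S)
    f2 = d2[typed].sum(axis=0) / (2.0 * S)
    k1 = _screened_alleles(f1, p_crit)
    k2 = _screened_alleles(f2, p_crit)
    if not k1 or not k2:
        return float("nan"), 0, S
    r2s = []
    g1 = d1[typed]
    g2 = d2[typed]
    for i in k1:
        for j in k2:
            pa, pb = f1[i], f2[j]
            delta = (g1[:, i] * g2[:, j]).sum() / (2.0 * S) - 2.0 * pa * pb
            delta *= S / (S - 1.0)
            r2s.append(delta ** 2 / (pa * (1.0 - pa) * pb * (1.0 - pb)))
    return float(np.mean(r2s)), len(r2s), S


# ---------------------------------------------------------------------------
# Ne estimation
# ---------------------------------------------------------------------------

@dataclass
class NeEstimate:
    ne_point: float  # may be inf
    ci_low: float
    ci_high: float
    ci_parametric: tuple
    p_crit: float
    n_comparisons: int
    harmonic_mean_S: float
    mean_r2: float
    mean_r2_sample: float
    r2_drift: float
    per_pair: pd.DataFrame = field(repr=False, default=None)


def estimate_ne(genotypes, p_crit: float = 0.01,
                mating_model: str = "random") -> NeEstimate:
    """LD effective population size from all pairs of polymorphic loci.

    The overall mean r̂² weights every allele-pair comparison equally;
    S enters as the comparison-weighted harmonic mean across locus
    pairs. The headline confidence interval is a jackknife over loci
    (pairwise r̂² values are correlated, which makes the also-reported
    parametric chi-square CI anti-conservative). ``r2_drift <= 0`` gives
    an infinite point estimate with a finite lower bound.
    """
    loci = sorted({l for g in genotypes for l in g.calls})
    rows = []
    for loc1, loc2 in combinations(loci, 2):
        r2, n, S = burrows_r2(genotypes, (loc1, loc2), p_crit)
        if n > 0 and np.isfinite(r2):
            rows.append((loc1, loc2, r2, n, S))
    if not rows:
        raise NeEstimationError(
            f"fewer than 2 usable polymorphic loci at p_crit={p_crit}"
        )
    per_pair = pd.DataFrame(rows, columns=["locus1", "locus2", "r2", "n_comp", "S"])
    used_loci = sorted(set(per_pair.locus1) | set(per_pair.locus2))
    if len(used_loci) < 2:
        raise NeEstimationError(
            f"fewer than 2 usable polymorphic loci at p_crit={p_crit}"
        )

    def pooled(df):
        w = df.n_comp.to_numpy(dtype=float)
        r2bar = float(np.average(df.r2, weights=w))
        S_h = float(w.sum() / np.sum(w / df.S))
        exp_s = expected_r2_sample(S_h, mating_model)
        drift = r2bar - exp_s
        return r2bar, S_h, exp_s, drift, _ne_from_r2_drift(drift, S_h, mating_model)

    r2bar, S_h, exp_s, drift, ne = pooled(per_pair)
    n_comp = int(per_pair.n_comp.sum())

    # parametric chi-square CI on mean r2 with df = number of comparisons
    df_ = n_comp
    lo_r2 = df_ * r2bar / stats.chi2.ppf(0.975, df_)
    hi_r2 = df_ * r2bar / stats.chi2.ppf(0.025, df_)
    ci_par = (
        _ne_from_r2_drift(hi_r2 - exp_s, S_h, mating_model),
        _ne_from_r2_drift(lo_r2 - exp_s, S_h, mating_model),
    )
    ci_par = (min(ci_par), max(ci_par))

    # jackknife over loci on mean r2, transformed through the Ne formula
    if len(used_loci) > 2:
        jk = []
        for drop in used_loci:
            sub = per_pair[(per_pair.locus1 != drop) & (per_pair.locus2 != drop)]
            if len(sub):
                jk.append(pooled(sub)[0])
        jk = np.array(jk)
        m = len(jk)
        var_jk = (m - 1.0) / m * np.sum((jk - jk.mean()) ** 2)
        se = sqrt(var_jk)
        lo_r2_j = max(r2bar - 1.96 * se, 0.0)
        hi_r2_j = r2bar + 1.96 * se
        ci_low = _ne_from_r2_drift(hi_r2_j - exp_s, S_h, mating_model)
        ci_high = _ne_from_r2_drift(lo_r2_j - exp_s, S_h, mating_model)
        ci_low, ci_high = min(ci_low, ci_high), max(ci_low, ci_high)
    else:
        ci_low, ci_high = ci_par

    return NeEstimate(
        ne_point=ne,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_parametric=ci_par,
        p_crit=p_crit,
        n_comparisons=n_comp,
        harmonic_mean_S=S_h,
        mean_r2=r2bar,
        mean_r2_sample=exp_s,
        r2_drift=drift,
        per_pair=per_pair,
    )
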