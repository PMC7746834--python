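"""Per-locus diversity, inbreeding, Hardy-Weinberg and sex-ratio tests.

Statistics per locus: number of alleles Na, effective number of alleles
1/Σp², observed heterozygosity Ho, expected heterozygosity He = 1 − Σp²
(with the small-sample unbiased variant uHe = 2n/(2n−1)·He), polymorphic
information content PIC, the Weir–Cockerham within-population inbreeding
coefficient f (FIS), an exact Hardy–Weinberg test, and two closed-form
null-allele frequency estimators with a heterozygote-deficit flag.

The HWE test is the exact conditional test: genotype arrays with the
observed allele counts are enumerated in full when the number of tables
is small enough, otherwise a seeded Monte-Carlo permutation sampler
(Guo–Thompson style) is used and the Monte-Carlo standard error is
reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import AlleleFrequencyTable, MultilocusGenotype, allele_frequencies

__all__ = [
    "DiversitySummary",
    "HWEResult",
    "SexRatioTest",
    "diversity",
    "hwe_exact",
    "genotype_counts_at_locus",
    "null_allele_screen",
    "sex_ratio_test",
    "fis_weir_cockerham",
]


# ---------------------------------------------------------------------------
# closed-form per-locus statistics
# ---------------------------------------------------------------------------

def _pic(p: np.ndarray) -> float:
    s2 = float(np.sum(p ** 2))
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] ** 2 * p[j] ** 2
    return 1.0 - s2 - cross


def fis_weir_cockerham(genotypes, locus: str) -> float:
    """Weir–Cockerham within-population inbreeding coefficient f at a locus.

    Single-population ANOVA estimator: per allele A with sample frequency
    p and observed A-heterozygote proportion h over n typed individuals,

        b = n/(n−1) · [ p(1−p) − (2n−1)/(4n) · h ],   c = h/2,

    and f = 1 − Σc / Σ(b+c) over alleles. Monomorphic loci return NaN.
    """
    calls = [g.calls[locus] for g in genotypes
             if g.calls.get(locus) is not None]
    n = len(calls)
    if n < 2:
        return float("nan")
    alleles = sorted({a for c in calls for a in c})
    if len(alleles) < 2:
        return float("nan")
    sum_b = sum_c = 0.0
    for a in alleles:
        # int() casts: numpy bools would saturate instead of adding
        p = sum(int(c[0] == a) + int(c[1] == a) for c in calls) / (2.0 * n)
        h = sum(1 for c in calls if (a in c) and c[0] != c[1]) / n
        b = n / (n - 1.0) * (p * (1.0 - p) - (2.0 * n - 1.0) / (4.0 * n) * h)
        c_ = h / 2.0
        sum_b += b
        sum_c += c_
    denom = sum_b + sum_c
    return float("nan") if denom == 0 else 1.0 - sum_c / denom


@dataclass
class DiversitySummary:
    """Per-locus diversity table plus mean/SD/SE summary rows.

    ``per_locus`` columns: na, ne_alleles, ho, he, uhe, pic, fis_wc,
    p_hwe, null_chakraborty, null_brookfield1, n_typed.
    """

    per_locus: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    se: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.per_locus.copy()
        out.loc["Mean"] = self.mean
        out.loc["SD"] = self.sd
        out.loc["SE"] = self.se
        return out


def diversity(genotypes, freqs: "AlleleFrequencyTable | None" = None,
              hwe: bool = True, seed: int = 0) -> DiversitySummary:
    """Diversity/inbreeding summary across loci for one population."""
    if freqs is None:
        freqs = allele_frequencies(genotypes)
    rows = {}
    for locus in freqs.loci:
        p = np.array(list(freqs[locus].values()))
        calls = [g.calls[locus] for g in genotypes if g.calls.get(locus) is not None]
        n = len(calls)
        if n < 2:
            continue
        na = len(p)
        s2 = float(np.sum(p ** 2))
        he = 1.0 - s2
        ho = sum(1 for c in calls if c[0] != c[1]) / n
        uhe = (2.0 * n) / (2.0 * n - 1.0) * he
        if na < 2:
            pic = 0.0
            fis = float("nan")
            p_hwe = 1.0
        else:
            pic = _pic(p)
            fis = fis_weir_cockerham(genotypes, locus)
            p_hwe = (
                hwe_exact(genotype_counts_at_locus(genotypes, locus), seed=seed).p
                if hwe else float("nan")
            )
        denom_c = he + ho
        null_c = (he - ho) / denom_c if denom_c > 0 else float("nan")
        null_b = (he - ho) / (1.0 + he)
        rows[locus] = dict(
            na=na, ne_alleles=1.0 / s2, ho=ho, he=he, uhe=uhe, pic=pic,
            fis_wc=fis, p_hwe=p_hwe, null_chakraborty=null_c,
            null_brookfield1=null_b, n_typed=n,
        )
    per_locus = pd.DataFrame.from_dict(rows, orient="index")
    stat_cols = [c for c in per_locus.columns if c != "n_typed"]
    mean = per_locus[stat_cols].mean()
    sd = per_locus[stat_cols].std(ddof=1)
    se = sd / np.sqrt(per_locus[stat_cols].notna().sum())
    return DiversitySummary(per_locus=per_locus, mean=mean, sd=sd, se=se)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def genotype_counts_at_locus(genotypes, locus: str) -> dict:
    """Genotype → count mapping at one locus (missing calls skipped)."""
    cnt: Counter = Counter()
    for g in genotypes:
        call = g.calls.get(locus)
        if call is not None:
            cnt[call] += 1
    return dict(cnt)


@dataclass
class HWEResult:
    p: float
    method: str  # "enumeration" | "monte-carlo"
    n_tables: "int | None" = None
    se: "float | None" = None

    def __float__(self) -> float:
        return self.p


def _allele_counts(genotype_counts: dict):
    alleles = sorted({a for g in genotype_counts for a in g})
    idx = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    ac = np.zeros(k, dtype=int)
    obs = np.zeros((k, k), dtype=int)
    for (a, b), c in genotype_counts.items():
        i, j = sorted((idx[a], idx[b]))
        obs[i, j] += c
        ac[i] += c
        ac[j] += c
    return alleles, ac, obs


def _log_table_prob_terms(table: np.ndarray) -> tuple:
    """(Σ log n_ij!, number of heterozygote individuals) for a genotype table."""
    lf = 0.0
    het = 0
    k = table.shape[0]
    for i in range(k):
        for j in range(i, k):
            lf += lgamma(table[i, j] + 1.0)
            if i != j:
                het += table[i, j]
    return lf, het


class _EnumerationOverflow(Exception):
    pass


def _enumerate_pvalue(ac: np.ndarray, obs: np.ndarray, alternative: str,
                      max_tables: int):
    """Exact p-value by DFS over all genotype tables with margins ``ac``.

    Raises :class:`_EnumerationOverflow` after visiting ``max_tables``
    complete tables, signalling the caller to fall back to Monte-Carlo.
    """
    k = len(ac)
    obs_lf, obs_het = _log_table_prob_terms(obs)
    # log P(table) = const - Σ log n_ij! + H log 2, const common to all tables
    obs_stat = obs_het * log(2.0) - obs_lf
    tol = 1e-9
    num = 0.0
    den = 0.0
    n_tables = 0
    rem = list(ac)

    def rec(i: int, j: int, lf: float, het: int):
        nonlocal num, den, n_tables
        if i == k:
            n_tables += 1
            if n_tables > max_tables:
                raise _EnumerationOverflow
            stat = het * log(2.0) - lf
            w = np.exp(stat)  # un-normalized table probability
            den += w
            if alternative == "two-sided":
                if stat <= obs_stat + tol:
                    num += w
            else:  # het-deficit: as few or fewer heterozygotes
                if het <= obs_het:
                    num += w
            return
        if j == k:
            if rem[i] == 0:
                rec(i + 1, i + 1, lf, het)
            return
        if j == k - 1:
            # last cell of the row absorbs the remaining copies exactly
            if j == i:
                nii, r = divmod(rem[i], 2)
                if r == 0:
                    rem[i] = 0
                    rec(i, j + 1, lf + lgamma(nii + 1.0), het)
                    rem[i] = 2 * nii
            else:
                nij = rem[i]
                if nij <= rem[j]:
                    rem[i] = 0
                    rem[j] -= nij
                    rec(i, j + 1, lf + lgamma(nij + 1.0), het + nij)
                    rem[i] = nij
                    rem[j] += nij
            return
        if j == i:
            for nii in range(rem[i] // 2 + 1):
                rem[i] -= 2 * nii
                rec(i, j + 1, lf + lgamma(nii + 1.0), het)
                rem[i] += 2 * nii
        else:
            for nij in range(min(rem[i], rem[j]) + 1):
                rem[i] -= nij
                rem[j] -= nij
                rec(i, j + 1, lf + lgamma(nij + 1.0), het + nij)
                rem[i] += nij
                rem[j] += nij

    rec(0, 0, 0.0, 0)
    return num / den, n_tables


def _mc_pvalue(ac: np.ndarray, obs: np.ndarray, n_draws: int, seed: int,
               alternative: str):
    k = len(ac)
    rng = np.random.default_rng(seed)
    obs_lf, obs_het = _log_table_prob_terms(obs)
    obs_stat = obs_het * log(2.0) - obs_lf
    copies = np.repeat(np.arange(k, dtype=np.int8), ac)
    n = len(copies) // 2
    hits = 0
    done = 0
    chunk = 20000
    from scipy.special import gammaln
    while done < n_draws:
        b = min(chunk, n_draws - done)
        mat = rng.permuted(np.tile(copies, (b, 1)), axis=1)
        pairs = mat.reshape(b, n, 2).astype(np.int32)
        lo = pairs.min(axis=2)
        hi = pairs.max(axis=2)
        het = (lo != hi).sum(axis=1)
        ids = lo * k + hi + (np.arange(b)[:, None] * k * k)
        counts = np.bincount(ids.ravel(), minlength=b * k * k).reshape(b, k * k)
        if alternative == "two-sided":
            lf = gammaln(counts + 1.0).sum(axis=1)
            stat = het * log(2.0) - lf
            hits += int(np.sum(stat <= obs_stat + 1e-9))
        else:
            hits += int(np.sum(het <= obs_het))
        done += b
    # include the observed table itself (guarantees p > 0, standard practice)
    p = (hits + 1.0) / (n_draws + 1.0)
    se = float(np.sqrt(p * (1.0 - p) / n_draws))
    return p, se


def hwe_exact(genotype_counts: dict, n_draws: int = 100_000, seed: int = 0,
              max_enumeration: int = 1_000_000,
              alternative: str = "two-sided") -> HWEResult:
    """Exact conditional Hardy–Weinberg test at one locus.

    ``genotype_counts`` maps unordered allele pairs to counts. With
    ``alternative="two-sided"`` the p-value sums the conditional
    probabilities of all genotype tables (with the observed allele
    counts) no more probable than the observed table; with
    ``alternative="het_deficit"`` it sums tables with at most the
    observed number of heterozygotes (one-sided homozygote excess).

    Full enumeration is used when the number of tables is at most
    ``max_enumeration``; otherwise a seeded Monte-Carlo permutation
    sampler with ``n_draws`` draws (>= 1e5 by default) reports the
    estimate and its standard error. Monomorphic input returns p = 1.
    """
    if alternative not in ("two-sided", "het_deficit"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if not genotype_counts:
        raise ValueError("empty genotype counts")
    alleles, ac, obs = _allele_counts(genotype_counts)
    if len(alleles) < 2:
        return HWEResult(p=1.0, method="monomorphic", n_tables=1)
    try:
        p, nt = _enumerate_pvalue(ac, obs, alternative, max_enumeration)
        return HWEResult(p=float(p), method="enumeration", n_tables=nt)
    except _EnumerationOverflow:
        p, se = _mc_pvalue(ac, obs, n_draws, seed, alternative)
        return HWEResult(p=float(p), method="monte-carlo", se=se)


# ---------------------------------------------------------------------------
# null-allele screen
# ---------------------------------------------------------------------------

def null_allele_screen(genotypes, freqs: "AlleleFrequencyTable | None" = None,
                       alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Closed-form null-allele frequency estimates with a het-deficit flag.

    Reports the Chakraborty estimator (He−Ho)/(He+Ho) and the
    Brookfield-1 estimator (He−Ho)/(1+He) per locus, and flags loci whose
    homozygote excess is significant under the one-sided exact HWE test.
    """
    if freqs is None:
        freqs = allele_frequencies(genotypes)
    rows = []
    for locus in freqs.loci:
        p = np.array(list(freqs[locus].values()))
        calls = [g.calls[locus] for g in genotypes if g.calls.get(locus) is not None]
        n = len(calls)
        he = 1.0 - float(np.sum(p ** 2))
        ho = sum(1 for c in calls if c[0] != c[1]) / n if n else float("nan")
        if he + ho > 0:
            chak = (he - ho) / (he + ho)
        else:
            chak = float("nan")
        brook = (he - ho) / (1.0 + he)
        if len(p) >= 2 and n >= 2:
            p_def = hwe_exact(
                genotype_counts_at_locus(genotypes, locus),
                seed=seed, alternative="het_deficit",
            ).p
        else:
            p_def = 1.0
        rows.append((locus, chak, brook, p_def, bool(p_def < alpha)))
    return pd.DataFrame(
        rows,
        columns=["locus", "null_chakraborty", "null_brookfield1",
                 "p_het_deficit", "flagged"],
    )


# ---------------------------------------------------------------------------
# sex ratio
# ---------------------------------------------------------------------------

@dataclass
class SexRatioTest:
    female_count: int
    male_count: int
    ratio_text: str
    chi2_plain: float
    chi2_yates: float
    p_plain: float
    p_yates: float


def sex_ratio_test(female_count: int, male_count: int) -> SexRatioTest:
    """Chi-square test of a sex-count pair against 1:1 (df = 1).

    Both the plain Pearson statistic Σ(O−E)²/E and the Yates-corrected
    Σ(|O−E|−0.5)²/E are computed; the continuity correction is clipped at
    zero so perfect balance gives 0 under both.
    """
    if female_count < 0 or male_count < 0:
        raise ValueError("counts must be non-negative")
    total = female_count + male_count
    if total == 0:
        raise ValueError("total count must be positive")
    e = total / 2.0
    obs = np.array([female_count, male_count], dtype=float)
    chi2_plain = float(np.sum((obs - e) ** 2 / e))
    adj = np.maximum(np.abs(obs - e) - 0.5, 0.0)
    chi2_yates = float(np.sum(adj ** 2 / e))
    from math import gcd
    g = gcd(female_count, male_count) or 1
    return SexRatioTest(
        female_count=female_count,
        male_count=male_count,
        ratio_text=f"{female_count // g}:{male_count // g}",
        chi2_plain=chi2_plain,
        chi2_yates=chi2_yates,
        p_plain=float(stats.chi2.sf(chi2_plain, df=1)),
        p_yates=float(stats.chi2.sf(chi2_yates, df=1)),
    )
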