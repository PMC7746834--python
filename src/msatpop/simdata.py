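"""Synthetic populations with known ground truth.

Emulates the sampling regime of a noninvasive microsatellite study of a
very small, group-living primate population: a handful of monogamous
family groups, replicate fecal samples per individual, three PCR
replicates per sample, and genotyping noise in the form of amplification
failure, allelic dropout (ADO) and false alleles (FA, stutter-dominated).

Ground truth (pedigree, true genotypes, true sexes, sample→individual
map, generating error rates) is returned alongside the noisy data so
that every downstream stage can be scored against what the simulator
actually did.

A separate Wright–Fisher simulator provides multilocus genotype samples
from a closed random-mating population of known effective size, used to
validate the linkage-disequilibrium Ne estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotypes import (
    LocusDef,
    MultilocusGenotype,
    ReplicateCallSet,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimConfigError",
    "simulate_population",
    "simulate_wright_fisher",
    "write_truth",
    "read_truth",
]


class SimConfigError(ValueError):
    """Raised for non-realizable simulation configurations."""


# Default panel mirrors the study design: 10 loci (mixed di/tri/tetra
# motifs, 2-6 founder alleles each), 3 monogamous family groups totalling
# 12 sampled individuals, 3 fecal samples per individual, 3 PCR replicates
# per sample, ~93% amplification success, male-biased offspring sex ratio.
_DEFAULT_MOTIFS = (3, 4, 2, 4, 4, 4, 4, 2, 4, 2)
_DEFAULT_ALLELE_COUNTS = (3, 3, 5, 3, 6, 3, 4, 5, 2, 4)


@dataclass
class SimConfig:
    """Parameters of the population/genotyping simulator.

    Probabilities are per event: ``p_amp_fail`` per replicate,
    ``p_ado`` per allele of a heterozygote given successful
    amplification, ``p_fa`` per successful replicate.
    """

    n_loci: int = 10
    motif_lengths: Sequence = _DEFAULT_MOTIFS
    founder_allele_counts: Sequence = _DEFAULT_ALLELE_COUNTS
    founder_freq_concentration: float = 1.0
    n_groups: int = 3
    #: per group: (number of monogamous adult pairs, number of offspring)
    group_structure: Sequence = ((1, 1), (1, 2), (1, 3))
    offspring_sex_bias: float = 0.75
    p_amp_fail: float = 0.06
    p_ado: float = 0.04
    p_fa: float = 0.01
    n_replicates: int = 3
    samples_per_individual: int = 3
    seed: int = 0

    def validate(self) -> None:
        if len(self.motif_lengths) != self.n_loci:
            raise SimConfigError("motif_lengths length must equal n_loci")
        if len(self.founder_allele_counts) != self.n_loci:
            raise SimConfigError("founder_allele_counts length must equal n_loci")
        if any(m not in (2, 3, 4) for m in self.motif_lengths):
            raise SimConfigError("motif lengths must be 2, 3 or 4")
        if any(not (2 <= k <= 9) for k in self.founder_allele_counts):
            raise SimConfigError("founder allele counts must be in 2..9")
        for p, name in [
            (self.p_amp_fail, "p_amp_fail"),
            (self.p_ado, "p_ado"),
            (self.p_fa, "p_fa"),
        ]:
            if not (0.0 <= p <= 1.0):
                raise SimConfigError(f"{name} must be in [0, 1]")
        if not (0.0 < self.offspring_sex_bias < 1.0):
            raise SimConfigError("offspring_sex_bias must be in (0, 1)")
        if self.n_replicates < 1:
            raise SimConfigError("n_replicates must be >= 1")
        if self.samples_per_individual < 1:
            raise SimConfigError("samples_per_individual must be >= 1")
        if len(self.group_structure) != self.n_groups:
            raise SimConfigError("group_structure length must equal n_groups")
        if self.founder_freq_concentration <= 0:
            raise SimConfigError("founder_freq_concentration must be positive")
        for pairs, off in self.group_structure:
            if off > 0 and pairs == 0:
                raise SimConfigError(
                    "group with offspring but no adult pair is not realizable"
                )


@dataclass
class SimTruth:
    """Hidden ground truth of a simulated population."""

    #: child id -> (father id, mother id)
    pedigree: dict
    #: individual id -> {locus -> (allele, allele)}
    true_genotypes: dict
    #: individual id -> "male" | "female"
    true_sexes: dict
    #: sample id -> individual id
    sample_map: dict
    #: generating probabilities (copy of the noise part of the config)
    error_params: dict
    #: locus -> {allele: frequency} in the founder source pool (the
    #: diverse population the founders descend from)
    founder_freqs: "dict | None" = None

    def individuals(self) -> list:
        return sorted(self.true_genotypes)


def _founder_panel(cfg: SimConfig, rng: np.random.Generator):
    """Locus definitions, allele grids and founder frequencies."""
    loci, grids, freqs = [], {}, {}
    for i in range(cfg.n_loci):
        m = int(cfg.motif_lengths[i])
        k = int(cfg.founder_allele_counts[i])
        name = f"L{i + 1:02d}"
        base = 100 + 12 * i
        # k distinct grid positions within ~20 repeats of the base size
        offsets = rng.choice(20, size=k, replace=False)
        alleles = sorted(int(base + m * o) for o in offsets)
        p = rng.dirichlet(np.full(k, cfg.founder_freq_concentration))
        # keep every founder allele representable: floor at 2%
        p = np.maximum(p, 0.02)
        p = p / p.sum()
        loci.append(LocusDef(name, m))
        grids[name] = alleles
        freqs[name] = dict(zip(alleles, p))
    return loci, grids, freqs


def _draw_genotype(freqs_locus: dict, rng: np.random.Generator):
    al = sorted(freqs_locus)
    p = np.array([freqs_locus[a] for a in al])
    a, b = rng.choice(al, size=2, p=p)
    return (int(a), int(b)) if a <= b else (int(b), int(a))


def _mendel(father_g, mother_g, rng: np.random.Generator):
    a = father_g[rng.integers(2)]
    b = mother_g[rng.integers(2)]
    return (int(a), int(b)) if a <= b else (int(b), int(a))


def _noisy_replicate(true_g, grid, cfg: SimConfig, rng: np.random.Generator):
    """One PCR replicate of one sample × locus under the error model.

    Amplification fails outright with p_amp_fail. For a heterozygote each
    allele then drops independently with p_ado (both dropping = failed
    amplification; homozygotes cannot drop out). Finally with p_fa one of
    the two reported allele copies is replaced by a different allele, with
    stutter (±1 repeat of the replaced allele) weighted 3:1 over every
    other allele of the locus grid.
    """
    if rng.random() < cfg.p_amp_fail:
        return None
    a, b = true_g
    if a != b:
        drop_a = rng.random() < cfg.p_ado
        drop_b = rng.random() < cfg.p_ado
        if drop_a and drop_b:
            return None
        if drop_a:
            a = b
        elif drop_b:
            b = a
    call = [a, b]
    if rng.random() < cfg.p_fa:
        pos = int(rng.integers(2))
        src = call[pos]
        motif = None
        # infer motif from the grid spacing (grids are built on the motif)
        if len(grid) > 1:
            motif = int(np.gcd.reduce(np.diff(sorted(grid))))
        else:
            motif = 2
        candidates = sorted(set(grid) | {src - motif, src + motif})
        candidates = [c for c in candidates if c != src and c > 0]
        w = np.array([3.0 if abs(c - src) == motif else 1.0 for c in candidates])
        call[pos] = int(rng.choice(candidates, p=w / w.sum()))
    call.sort()
    return (call[0], call[1])


def simulate_population(config: SimConfig):
    """Simulate a small group-structured population and its noisy genotyping.

    Returns ``(truth, replicate_calls, sex_marker_calls, loci)`` where
    *loci* is the list of :class:`~msatpop.genotypes.LocusDef` for the
    simulated panel. Founders draw genotypes from the founder allele
    frequencies; offspring are produced by Mendelian sampling from their
    group's adult pair. Sex markers reflect the true sex without error
    (males show 2 bands, females 1). Identical seeds give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    loci, grids, founder_freqs = _founder_panel(config, rng)

    pedigree: dict = {}
    true_genotypes: dict = {}
    true_sexes: dict = {}
    group_of: dict = {}

    for gi, (n_pairs, n_off) in enumerate(config.group_structure):
        gname = chr(ord("A") + gi)
        pairs = []
        for pi in range(n_pairs):
            fid = f"{gname}M{pi + 1}"
            mid = f"{gname}F{pi + 1}"
            for iid, sex in ((fid, "male"), (mid, "female")):
                true_sexes[iid] = sex
                group_of[iid] = gname
                true_genotypes[iid] = {
                    l.name: _draw_genotype(founder_freqs[l.name], rng) for l in loci
                }
            pairs.append((fid, mid))
        for oi in range(n_off):
            fid, mid = pairs[oi % len(pairs)]
            oid = f"{gname}O{oi + 1}"
            true_sexes[oid] = (
                "male" if rng.random() < config.offspring_sex_bias else "female"
            )
            group_of[oid] = gname
            pedigree[oid] = (fid, mid)
            true_genotypes[oid] = {
                l.name: _mendel(true_genotypes[fid][l.name],
                                true_genotypes[mid][l.name], rng)
                for l in loci
            }

    entries: dict = {}
    sex_calls: dict = {}
    sample_map: dict = {}
    for iid in sorted(true_genotypes):
        for si in range(config.samples_per_individual):
            sid = f"{iid}s{si + 1}"
            sample_map[sid] = iid
            for l in loci:
                for rep in range(1, config.n_replicates + 1):
                    entries[(sid, l.name, rep)] = _noisy_replicate(
                        true_genotypes[iid][l.name], grids[l.name], config, rng
                    )
            bands = 2 if true_sexes[iid] == "male" else 1
            sex_calls[sid] = [bands] * config.n_replicates

    truth = SimTruth(
        pedigree=pedigree,
        true_genotypes=true_genotypes,
        true_sexes=true_sexes,
        sample_map=sample_map,
        error_params={
            "p_amp_fail": config.p_amp_fail,
            "p_ado": config.p_ado,
            "p_fa": config.p_fa,
        },
        founder_freqs={
            loc: {int(a): float(p) for a, p in fr.items()}
            for loc, fr in founder_freqs.items()
        },
    )
    truth.group_of = group_of  # convenience attribute, not part of the contract
    return truth, ReplicateCallSet(entries), sex_calls, loci


def true_consensus_genotypes(truth: SimTruth, group_of: "dict | None" = None):
    """The simulator's individuals as noise-free MultilocusGenotype records."""
    out = []
    for iid in truth.individuals():
        out.append(
            MultilocusGenotype(
                iid,
                dict(truth.true_genotypes[iid]),
                sex=truth.true_sexes[iid],
                group=(group_of or getattr(truth, "group_of", {})).get(iid),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Wright-Fisher validation population
# ---------------------------------------------------------------------------

def simulate_wright_fisher(ne: int, n_loci: int, generations: int,
                           sample_size: int, seed: int,
                           n_alleles: int = 4):
    """Constant-size discrete-generation random-mating diploid population.

    Loci are unlinked and start equifrequent with ``n_alleles`` alleles.
    Each generation every one of the ``ne`` children picks a father and a
    mother uniformly at random (selfing excluded by construction is NOT
    enforced; random mating with replacement) and inherits one random
    allele per locus from each. Returns a final-generation sample of
    ``sample_size`` diploid multilocus genotypes, with loci that went to
    fixation flagged via the second return value.
    """
    if ne < 2:
        raise ValueError("ne must be >= 2")
    if sample_size > ne:
        raise ValueError("sample_size cannot exceed ne")
    rng = np.random.default_rng(seed)
    # allele codes on a bp-like grid so downstream treats them as lengths
    alleles = 100 + 2 * np.arange(n_alleles)
    pop = rng.choice(n_alleles, size=(ne, n_loci, 2))
    for _ in range(generations):
        fathers = rng.integers(ne, size=ne)
        mothers = rng.integers(ne, size=ne)
        lidx = np.broadcast_to(np.arange(n_loci), (ne, n_loci))
        pat = pop[fathers[:, None], lidx, rng.integers(2, size=(ne, n_loci))]
        mat = pop[mothers[:, None], lidx, rng.integers(2, size=(ne, n_loci))]
        pop = np.stack([pat, mat], axis=2)
    idx = rng.choice(ne, size=sample_size, replace=False)
    sample = pop[idx]
    fixed = [f"WF{j + 1:02d}" for j in range(n_loci)
             if len(np.unique(sample[:, j, :])) == 1]
    out = []
    for i in range(sample_size):
        calls = {}
        for j in range(n_loci):
            a, b = sorted(alleles[sample[i, j]])
            calls[f"WF{j + 1:02d}"] = (int(a), int(b))
        out.append(MultilocusGenotype(f"ind{i + 1:03d}", calls))
    return out, fixed


# ---------------------------------------------------------------------------
# truth sidecar I/O
# ---------------------------------------------------------------------------

def write_truth(path, truth: SimTruth) -> None:
    payload = {
        "pedigree": truth.pedigree,
        "true_genotypes": {
            iid: {loc: list(g) for loc, g in gl.items()}
            for iid, gl in truth.true_genotypes.items()
        },
        "true_sexes": truth.true_sexes,
        "sample_map": truth.sample_map,
        "error_params": truth.error_params,
        "founder_freqs": truth.founder_freqs,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path) -> SimTruth:
    d = json.loads(Path(path).read_text())
    return SimTruth(
        pedigree={k: tuple(v) for k, v in d["pedigree"].items()},
        true_genotypes={
            iid: {loc: tuple(g) for loc, g in gl.items()}
            for iid, gl in d["true_genotypes"].items()
        },
        true_sexes=d["true_sexes"],
        sample_map=d["sample_map"],
        error_params=d["error_params"],
        founder_freqs=(
            {loc: {int(a): p for a, p in fr.items()}
             for loc, fr in d["founder_freqs"].items()}
            if d.get("founder_freqs") else None
        ),
    )
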