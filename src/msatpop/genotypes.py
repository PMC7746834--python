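"""Core data model and file I/O for microsatellite data.

Alleles are identified by their binned fragment length in base pairs
(fragment-analysis data; there is no sequence-level allele concept here).
The central containers are:

* :class:`LocusDef` — a locus and its repeat-motif length,
* :class:`ReplicateCallSet` — raw per-PCR-replicate allele calls per
  sample × locus, the substrate for consensus calling and QC,
* :class:`MultilocusGenotype` — one individual's consensus diploid
  genotype across loci, the unit of all downstream statistics,
* :class:`AlleleFrequencyTable` — per-locus allele frequencies with the
  number of typed gene copies.

Interchange formats: GenePop (2/3-digit diploid codes) for consensus
genotypes, tidy CSV for replicate-level calls (GenePop has no replicate
concept), JSON for locus definitions.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Allele",
    "Call",
    "LocusDef",
    "ReplicateCallSet",
    "MultilocusGenotype",
    "AlleleFrequencyTable",
    "SexMarkerCalls",
    "BinningError",
    "GenePopParseError",
    "bin_alleles",
    "allele_frequencies",
    "read_genepop",
    "write_genepop",
    "read_locus_defs",
    "write_locus_defs",
]

Allele = int
#: A diploid call: unordered allele pair stored sorted, or ``None`` = failed/missing.
Call = "tuple[int, int] | None"

#: Per-sample sex-marker band counts, one entry per PCR replicate.
SexMarkerCalls = "dict[str, list[int]]"


class BinningError(ValueError):
    """Raised when raw fragment lengths cannot be snapped onto a locus grid."""


class GenePopParseError(ValueError):
    """Raised on malformed GenePop input; carries the offending line number."""


def _norm_pair(a: float, b: float) -> tuple:
    a, b = (a, b) if a <= b else (b, a)
    return (a, b)


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: name, repeat-motif length (bp), optional size range."""

    name: str
    motif_length: int
    known_size_range: "tuple[int, int] | None" = None

    def __post_init__(self):
        if self.motif_length not in (2, 3, 4):
            raise ValueError(
                f"locus {self.name}: motif_length must be 2, 3 or 4, "
                f"got {self.motif_length}"
            )


class ReplicateCallSet:
    """Raw per-replicate allele calls, keyed by (sample_id, locus, replicate).

    Replicate indices are 1-based and dense per sample × locus. Allele
    pairs are unordered: (a, b) and (b, a) are the same call and are
    stored sorted. A value of ``None`` records a failed amplification.
    """

    def __init__(self, entries: "Mapping[tuple[str, str, int], Call]"):
        self.entries: dict = {}
        for (s, loc, rep), call in entries.items():
            if call is not None:
                call = _norm_pair(*call)
            self.entries[(s, str(loc), int(rep))] = call
        self._check_dense()

    def _check_dense(self) -> None:
        by_cell: dict = {}
        for (s, loc, rep) in self.entries:
            by_cell.setdefault((s, loc), []).append(rep)
        for (s, loc), reps in by_cell.items():
            if sorted(reps) != list(range(1, len(reps) + 1)):
                raise ValueError(
                    f"replicate indices for sample {s!r}, locus {loc!r} "
                    f"are not dense from 1: {sorted(reps)}"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def samples(self) -> list:
        return sorted({s for s, _, _ in self.entries})

    @property
    def loci(self) -> list:
        return sorted({loc for _, loc, _ in self.entries})

    def cells(self) -> "list[tuple[str, str]]":
        return sorted({(s, loc) for s, loc, _ in self.entries})

    def replicates_for(self, sample: str, locus: str) -> list:
        reps = sorted(r for s, loc, r in self.entries if s == sample and loc == locus)
        return [self.entries[(sample, locus, r)] for r in reps]

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, ReplicateCallSet) and self.entries == other.entries

    # -- tidy CSV ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (s, loc, rep), call in sorted(self.entries.items()):
            a1, a2 = (call if call is not None else (np.nan, np.nan))
            rows.append((s, loc, rep, a1, a2))
        return pd.DataFrame(
            rows, columns=["sample_id", "locus", "replicate", "allele1_bp", "allele2_bp"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReplicateCallSet":
        entries = {}
        for row in df.itertuples(index=False):
            a1, a2 = row.allele1_bp, row.allele2_bp
            if pd.isna(a1) or pd.isna(a2):
                call = None
            else:
                call = (float(a1), float(a2))
            entries[(str(row.sample_id), str(row.locus), int(row.replicate))] = call
        return cls(entries)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ReplicateCallSet":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class MultilocusGenotype:
    """Consensus diploid genotype of one individual across loci.

    ``calls`` maps locus name to an unordered allele pair (bp lengths) or
    ``None`` for missing. At least one locus must be non-missing.
    """

    individual_id: str
    calls: dict
    sex: "str | None" = None
    group: "str | None" = None

    def __post_init__(self):
        if not any(c is not None for c in self.calls.values()):
            raise ValueError(
                f"individual {self.individual_id!r} has no typed locus"
            )
        self.calls = {
            loc: (None if c is None else _norm_pair(*c)) for loc, c in self.calls.items()
        }

    def typed_loci(self) -> list:
        return [loc for loc, c in self.calls.items() if c is not None]

    def n_typed(self) -> int:
        return len(self.typed_loci())


class AlleleFrequencyTable:
    """Per-locus allele relative frequencies and number of typed gene copies."""

    def __init__(self, freqs: "dict[str, dict[Allele, float]]",
                 n_gene_copies: "dict[str, int]"):
        self.freqs = {str(k): dict(v) for k, v in freqs.items()}
        self.n_gene_copies = {str(k): int(v) for k, v in n_gene_copies.items()}
        for loc, fr in self.freqs.items():
            tot = sum(fr.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"frequencies at locus {loc!r} sum to {tot}, not 1")
            if any(p <= 0 for p in fr.values()):
                raise ValueError(f"non-positive frequency at locus {loc!r}")

    @property
    def loci(self) -> list:
        return sorted(self.freqs)

    def alleles(self, locus: str) -> list:
        return sorted(self.freqs[locus])

    def __getitem__(self, locus: str) -> dict:
        return self.freqs[locus]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (loc, allele, p, self.n_gene_copies[loc])
            for loc in self.loci
            for allele, p in sorted(self.freqs[loc].items())
        ]
        return pd.DataFrame(rows, columns=["locus", "allele", "frequency", "n_gene_copies"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleFrequencyTable":
        freqs: dict = {}
        ncopies: dict = {}
        for row in df.itertuples(index=False):
            freqs.setdefault(str(row.locus), {})[row.allele] = float(row.frequency)
            ncopies[str(row.locus)] = int(row.n_gene_copies)
        return cls(freqs, ncopies)

    @classmethod
    def from_counts(cls, counts: "dict[str, dict[Allele, int]]") -> "AlleleFrequencyTable":
        freqs, ncopies = {}, {}
        for loc, cnt in counts.items():
            tot = sum(cnt.values())
            if tot == 0:
                continue
            freqs[loc] = {a: c / tot for a, c in cnt.items() if c > 0}
            ncopies[loc] = tot
        return cls(freqs, ncopies)


# ---------------------------------------------------------------------------
# allele binning
# ---------------------------------------------------------------------------

def bin_alleles(raw_calls: ReplicateCallSet, loci: "Sequence[LocusDef]"):
    """Snap raw fragment lengths onto each locus's motif grid.

    The grid for a locus is anchored at the modal raw length (rounded to
    the nearest integer; ties toward the smaller value) and extends in
    integer multiples of the motif length. Each raw length is snapped to
    the nearest grid point, with exact half-way ties broken downward.

    Returns ``(binned_set, report)`` where *report* is a per-locus
    DataFrame with the anchor, the maximum snap distance and call counts.

    Raises
    ------
    BinningError
        If at some locus more than 10% of calls lie further than half a
        motif length from the nearest grid point (possible only when a
        ``known_size_range`` truncates the grid).
    """
    by_name = {l.name: l for l in loci}
    missing = [loc for loc in raw_calls.loci if loc not in by_name]
    if missing:
        raise ValueError(f"no LocusDef for loci: {missing}")

    # anchor per locus = modal rounded raw length, ties toward smaller
    raw_by_locus: dict = {loc: [] for loc in raw_calls.loci}
    for (s, loc, rep), call in raw_calls.entries.items():
        if call is not None:
            raw_by_locus[loc].extend(call)

    entries: dict = {}
    report_rows = []
    snapped: dict = {}
    for loc in raw_calls.loci:
        ldef = by_name[loc]
        raws = raw_by_locus[loc]
        if not raws:
            report_rows.append((loc, np.nan, 0.0, 0, 0))
            continue
        counts = Counter(int(np.floor(x + 0.5)) for x in raws)
        top = max(counts.values())
        anchor = min(v for v, c in counts.items() if c == top)
        m = ldef.motif_length
        lo, hi = (None, None)
        if ldef.known_size_range is not None:
            lo, hi = ldef.known_size_range

        def snap(x: float) -> tuple:
            k = (x - anchor) / m
            # tie exactly half-way -> lower grid point
            kf = np.floor(k)
            down, up = anchor + kf * m, anchor + (kf + 1) * m
            g = down if (x - down) <= (up - x) else up
            if lo is not None:
                g = min(max(g, lo), hi)
            return int(round(g)), abs(x - g)

        dists = []
        for x in raws:
            snapped[(loc, x)] = snap(x)
            dists.append(snapped[(loc, x)][1])
        n_far = sum(d > m / 2 + 1e-9 for d in dists)
        if n_far > 0.10 * len(dists):
            raise BinningError(
                f"locus {loc}: {n_far}/{len(dists)} calls snap further than "
                f"motif_length/2 = {m / 2} bp from the grid"
            )
        report_rows.append((loc, anchor, max(dists), len(dists), n_far))

    for (s, loc, rep), call in raw_calls.entries.items():
        if call is None:
            entries[(s, loc, rep)] = None
        else:
            entries[(s, loc, rep)] = (snapped[(loc, call[0])][0], snapped[(loc, call[1])][0])

    report = pd.DataFrame(
        report_rows, columns=["locus", "anchor_bp", "max_snap_bp", "n_calls", "n_far"]
    )
    return ReplicateCallSet(entries), report


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(genotypes: "Sequence[MultilocusGenotype]") -> AlleleFrequencyTable:
    """Count allele frequencies over non-missing gene copies per locus.

    Loci with zero calls across all individuals are excluded (n_gene_copies
    is locus-specific, so missing data at one locus never distort another).
    """
    counts: dict = {}
    for g in genotypes:
        for loc, call in g.calls.items():
            if call is None:
                continue
            c = counts.setdefault(loc, Counter())
            c[call[0]] += 1
            c[call[1]] += 1
    return AlleleFrequencyTable.from_counts({loc: dict(c) for loc, c in counts.items()})


# ---------------------------------------------------------------------------
# GenePop I/O  (2/3-digit diploid dialect)
# ---------------------------------------------------------------------------

def _infer_motif(alleles: "Iterable[int]") -> int:
    diffs = []
    al = sorted(set(alleles))
    for a, b in zip(al, al[1:]):
        diffs.append(b - a)
    g = 0
    for d in diffs:
        g = int(np.gcd(g, d))
    return g if g in (2, 3, 4) else 2


def write_genepop(path, genotypes: "Sequence[MultilocusGenotype]",
                  loci: "Sequence[str] | None" = None,
                  title: str = "msatpop export", digits: int = 3) -> None:
    """Write consensus genotypes as a GenePop file (one Pop per group)."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if loci is None:
        loci = sorted({loc for g in genotypes for loc in g.calls})
    fmt = f"{{:0{digits}d}}"
    lines = [title]
    lines.extend(loci)
    groups: dict = {}
    for g in genotypes:
        groups.setdefault(g.group, []).append(g)
    for grp in sorted(groups, key=lambda x: (x is None, x)):
        lines.append("Pop")
        for g in groups[grp]:
            toks = []
            for loc in loci:
                call = g.calls.get(loc)
                if call is None:
                    toks.append(fmt.format(0) * 2)
                else:
                    if max(call) >= 10 ** digits:
                        raise ValueError(
                            f"allele {max(call)} does not fit in {digits} digits"
                        )
                    toks.append(fmt.format(call[0]) + fmt.format(call[1]))
            lines.append(f"{g.individual_id} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path):
    """Read a GenePop file; returns ``(locus_defs, genotypes)``.

    Motif lengths are inferred from the gcd of inter-allele spacings per
    locus (defaulting to 2 when uninformative) since GenePop carries no
    motif metadata. Missing genotypes are coded 00/000.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenePopParseError("empty file")
    loci: list = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus names: one per line, or comma-separated on one line
        for name in re.split(r"[,\s]+", lines[i].strip()):
            if name:
                loci.append(name)
        i += 1
    if i == len(lines):
        raise GenePopParseError("no 'Pop' line found")
    genotypes: list = []
    pop_idx = 0
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise GenePopParseError(f"line {lineno + 1}: no comma after individual id")
        ind_id, rest = line.split(",", 1)
        toks = rest.split()
        if len(toks) != len(loci):
            raise GenePopParseError(
                f"line {lineno + 1}: {len(toks)} genotypes for {len(loci)} loci"
            )
        calls = {}
        for loc, tok in zip(loci, toks):
            if len(tok) == 4:
                d = 2
            elif len(tok) == 6:
                d = 3
            else:
                raise GenePopParseError(
                    f"line {lineno + 1}: genotype token {tok!r} is neither "
                    "4 (2-digit) nor 6 (3-digit) characters"
                )
            a1, a2 = int(tok[:d]), int(tok[d:])
            calls[loc] = None if (a1 == 0 or a2 == 0) else (a1, a2)
        genotypes.append(
            MultilocusGenotype(ind_id.strip(), calls, group=f"pop{pop_idx}")
        )
    locus_defs = []
    for loc in loci:
        alleles = [a for g in genotypes if g.calls.get(loc) for a in g.calls[loc]]
        locus_defs.append(LocusDef(loc, _infer_motif(alleles)))
    return locus_defs, genotypes


# ---------------------------------------------------------------------------
# locus-definition JSON
# ---------------------------------------------------------------------------

def write_locus_defs(path, loci: "Sequence[LocusDef]") -> None:
    payload = [
        {
            "name": l.name,
            "motif_length": l.motif_length,
            "known_size_range": list(l.known_size_range) if l.known_size_range else None,
        }
        for l in loci
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_locus_defs(path) -> list:
    payload = json.loads(Path(path).read_text())
    return [
        LocusDef(
            d["name"],
            d["motif_length"],
            tuple(d["known_size_range"]) if d.get("known_size_range") else None,
        )
        for d in payload
    ]
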