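"""Mutation calling from pileup allele counts, and mutation-spectrum summaries.

A mutation is called in an MA line from per-site, per-line, per-strand read
counts when six filters all pass at an eligible site:

1. no read supports the mutant allele in the parental line;
2. a two-sided Fisher's exact test of strand bias gives p > 0.001;
3. no more than two alleles are observed in the mutant line;
4. the mutant allele frequency exceeds 20% in the mutant line;
5. no other line carries the mutant allele at frequency above 5%;
6. no more than two other lines have any read supporting the mutant allele.

A site is eligible when the parental line and at least 10 MA lines each show
between 15 and 250 reads, and no more than 10 alleles are observed across all
lines.  Called mutations are classified (SBS/MBS/INS/DEL/COMPLEX) and
summarized: transition/transversion counts with opportunity-normalized ratio,
mutation bias toward G/C ancestral bases, DUST-style local sequence
complexity, and per-gene mutation counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

__all__ = [
    "PileupTable",
    "MutationCall",
    "SpectrumSummary",
    "LocalContext",
    "eligible_sites",
    "fisher_exact_2x2",
    "call_mutations",
    "classify_mutation",
    "titv_summary",
    "gc_fold_bias",
    "gc_bias",
    "dust_complexity",
    "local_context",
    "mutations_per_gene",
    "summarize_spectrum",
]

CLASSES = ("SBS", "MBS", "INS", "DEL", "COMPLEX")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class PileupTable:
    """Per-site, per-line, per-strand allele read counts with a parental flag.

    Wraps a DataFrame with columns chrom, pos (1-based), line_id, allele,
    strand (+/-), count.  Exactly one line is flagged parental.
    """

    def __init__(self, data: pd.DataFrame, parental_id: str):
        required = ["chrom", "pos", "line_id", "allele", "strand", "count"]
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise ValueError(f"pileup table missing columns: {missing}")
        if (data["count"] < 0).any():
            raise ValueError("read counts must be non-negative")
        bad = set(data["strand"].unique()) - {"+", "-"}
        if bad:
            raise ValueError(f"invalid strand values: {bad}")
        self.data = data.reset_index(drop=True)
        self.parental_id = parental_id

    @property
    def line_ids(self) -> list[str]:
        return sorted(self.data["line_id"].unique())

    @property
    def ma_line_ids(self) -> list[str]:
        return [l for l in self.line_ids if l != self.parental_id]

    def sites(self) -> list[tuple[str, int]]:
        return sorted(
            self.data[["chrom", "pos"]].drop_duplicates().itertuples(index=False, name=None)
        )

    def site_table(self, chrom: str, pos: int) -> pd.DataFrame:
        mask = (self.data["chrom"] == chrom) & (self.data["pos"] == pos)
        return self.data[mask]


@dataclass(frozen=True)
class MutationCall:
    """One called mutation: line, locus, alleles, frequency and class."""

    line_id: str
    chrom: str
    pos: int  # 1-based
    ancestral: str
    mutant: str
    frequency: float
    mclass: str

    def __post_init__(self) -> None:
        if self.mutant == self.ancestral:
            raise ValueError("mutant allele equals ancestral")
        if not 0.0 < self.frequency <= 1.0:
            raise ValueError("frequency must be in (0, 1]")
        if self.mclass not in CLASSES:
            raise ValueError(f"unknown class {self.mclass}")


@dataclass
class SpectrumSummary:
    """Counts by mutation class plus Ti/Tv and ancestral-base bias summaries."""

    class_counts: dict[str, int]
    ti: int
    tv: int
    titv_normalized: float | None
    n_gc: int
    n_at: int
    gc_fold_bias: float | None

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())


def _depth_per_line(site: pd.DataFrame) -> pd.Series:
    return site.groupby("line_id")["count"].sum()


def eligible_sites(
    pileups: PileupTable,
    min_depth: int = 15,
    max_depth: int = 250,
    min_ma_lines: int = 10,
    max_alleles: int = 10,
) -> list[tuple[str, int]]:
    """Sites where the parental line and >= ``min_ma_lines`` MA lines each
    have depth in [min_depth, max_depth] and at most ``max_alleles`` alleles
    are observed across all lines."""
    if pileups.parental_id not in pileups.line_ids:
        raise ValueError("parental line absent from pileup table")
    out = []
    grouped = pileups.data.groupby(["chrom", "pos"], sort=True)
    for (chrom, pos), site in grouped:
        depth = _depth_per_line(site)
        par = depth.get(pileups.parental_id, 0)
        if not min_depth <= par <= max_depth:
            continue
        ma_depth = depth.drop(pileups.parental_id, errors="ignore")
        if (ma_depth.between(min_depth, max_depth)).sum() < min_ma_lines:
            continue
        if site["allele"].nunique() > max_alleles:
            continue
        out.append((chrom, int(pos)))
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the 2x2 table [[a, b], [c, d]]."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        return 1.0
    return float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1])


def classify_mutation(ancestral: str, mutant: str) -> str:
    """Partition an allele pair into SBS, MBS, INS, DEL or COMPLEX.

    Equal lengths: one differing base is a single base substitution, two or
    more a multiple base substitution.  A pure length gain (ancestral a
    subsequence of the mutant) is an insertion; a pure loss a deletion; any
    length change combined with substitution is complex.
    """
    if not ancestral or not mutant:
        raise ValueError("alleles must be non-empty")
    if ancestral == mutant:
        raise ValueError("alleles are identical")
    if len(ancestral) == len(mutant):
        ndiff = sum(1 for x, y in zip(ancestral, mutant) if x != y)
        return "SBS" if ndiff == 1 else "MBS"

    def _subseq(short: str, long: str) -> bool:
        it = iter(long)
        return all(ch in it for ch in short)

    if len(mutant) > len(ancestral):
        return "INS" if _subseq(ancestral, mutant) else "COMPLEX"
    return "DEL" if _subseq(mutant, ancestral) else "COMPLEX"


def call_mutations(
    pileups: PileupTable,
    freq_cutoff: float = 0.2,
    leak_freq: float = 0.05,
    max_leak_lines: int = 2,
    strand_p: float = 0.001,
    sites: Sequence[tuple[str, int]] | None = None,
    eligibility: dict | None = None,
) -> list[MutationCall]:
    """Apply the six calling filters at each (eligible) site and line.

    ``sites`` restricts calling to a precomputed site list; by default
    :func:`eligible_sites` is applied (``eligibility`` passes its thresholds).
    Each MA line is evaluated independently against all other lines; the
    ancestral allele at a site is the parental line's majority allele.
    """
    if pileups.parental_id not in pileups.line_ids:
        raise ValueError("parental line absent from pileup table")
    if sites is None:
        sites = eligible_sites(pileups, **(eligibility or {}))
    site_set = set(sites)
    calls: list[MutationCall] = []
    grouped = pileups.data.groupby(["chrom", "pos"], sort=True)
    for (chrom, pos), site in grouped:
        if (chrom, pos) not in site_set:
            continue
        by_line = site.groupby(["line_id", "allele"])["count"].sum().unstack(fill_value=0)
        if pileups.parental_id not in by_line.index:
            continue
        par_counts = by_line.loc[pileups.parental_id]
        ancestral = par_counts.idxmax()
        depth = by_line.sum(axis=1)
        for line_id in by_line.index:
            if line_id == pileups.parental_id:
                continue
            row = by_line.loc[line_id]
            line_alleles = row[row > 0]
            for mutant in line_alleles.index:
                if mutant == ancestral:
                    continue
                # (1) no parental read supports the mutant allele
                if par_counts.get(mutant, 0) > 0:
                    continue
                # (3) at most two alleles observed in the mutant line
                if len(line_alleles) > 2:
                    continue
                # (4) mutant frequency above the cutoff in the mutant line
                freq = row[mutant] / depth[line_id]
                if not freq > freq_cutoff:
                    continue
                # (2) no strand bias: Fisher p must exceed strand_p
                sub = site[site["line_id"] == line_id]
                mut_fwd = int(sub.loc[(sub["allele"] == mutant) & (sub["strand"] == "+"), "count"].sum())
                mut_rev = int(sub.loc[(sub["allele"] == mutant) & (sub["strand"] == "-"), "count"].sum())
                oth_fwd = int(sub.loc[(sub["allele"] != mutant) & (sub["strand"] == "+"), "count"].sum())
                oth_rev = int(sub.loc[(sub["allele"] != mutant) & (sub["strand"] == "-"), "count"].sum())
                if not fisher_exact_2x2(mut_fwd, mut_rev, oth_fwd, oth_rev) > strand_p:
                    continue
                # (5) no other line carries the mutant allele above leak_freq
                others = by_line.drop(index=[line_id, pileups.parental_id])
                if mutant in others.columns:
                    other_freq = others[mutant] / depth.loc[others.index].replace(0, np.nan)
                    if (other_freq.fillna(0) > leak_freq).any():
                        continue
                    # (6) at most max_leak_lines other lines with any mutant read
                    if int((others[mutant] > 0).sum()) > max_leak_lines:
                        continue
                calls.append(
                    MutationCall(
                        line_id=line_id,
                        chrom=chrom,
                        pos=int(pos),
                        ancestral=ancestral,
                        mutant=mutant,
                        frequency=float(freq),
                        mclass=classify_mutation(ancestral, mutant),
                    )
                )
    return calls


def _sbs_change(call: MutationCall) -> tuple[str, str]:
    """The (ancestral, mutant) base pair of an SBS, normalizing equal-length
    representations that differ at a single position."""
    if len(call.ancestral) == 1:
        return call.ancestral, call.mutant
    for x, y in zip(call.ancestral, call.mutant):
        if x != y:
            return x, y
    raise ValueError("no differing base")


def titv_summary(calls: Iterable[MutationCall]) -> tuple[int, int, float | None]:
    """Transition/transversion counts and the opportunity-normalized ratio.

    Transitions are A<->G and C<->T.  Each site offers one transition and two
    transversions, so the normalized ratio is ``2 * ti / tv``; with no
    transversions the ratio is undefined (None).
    """
    ti = tv = 0
    for call in calls:
        if call.mclass != "SBS":
            raise ValueError("titv_summary expects SBS calls only")
        pair = _sbs_change(call)
        if pair in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    ratio = 2.0 * ti / tv if tv else None
    return ti, tv, ratio


def gc_fold_bias(n_gc: int, n_at: int, genome_gc: float) -> float:
    """Fold increase of mutations at G/C ancestral bases over A/T, normalized
    by the genomic base composition: ``(n_GC/gc) / (n_AT/(1-gc))``."""
    if not 0 < genome_gc < 1:
        raise ValueError("genome_gc must be in (0, 1)")
    if n_at == 0:
        raise ValueError("no mutations at A/T bases; fold bias undefined")
    return (n_gc / genome_gc) / (n_at / (1.0 - genome_gc))


def gc_bias(calls: Iterable[MutationCall], genome_gc: float) -> float:
    """GC fold bias of substitution calls (SBS/MBS with single-base states)."""
    n_gc = n_at = 0
    for call in calls:
        if call.mclass not in ("SBS", "MBS"):
            continue
        anc = _sbs_change(call)[0] if call.mclass == "SBS" else call.ancestral[0]
        if anc in "GC":
            n_gc += 1
        elif anc in "AT":
            n_at += 1
    return gc_fold_bias(n_gc, n_at, genome_gc)


def dust_complexity(window: str) -> tuple[float, float]:
    """DUST-style low-complexity score of a sequence window.

    Overlapping trinucleotides are counted; with counts ``c_i`` over ``w``
    valid triplets, ``S = sum c_i (c_i - 1) / 2 / (w - 1)``.  Triplets
    containing non-ACGT characters are skipped.  Returns ``(S, -ln S)`` with
    S = 0 mapped to +inf.
    """
    if len(window) < 3:
        raise ValueError("window must be at least 3 bases")
    window = window.upper()
    counts: dict[str, int] = {}
    w = 0
    for i in range(len(window) - 2):
        tri = window[i : i + 3]
        if any(ch not in "ACGT" for ch in tri):
            continue
        w += 1
        counts[tri] = counts.get(tri, 0) + 1
    if w == 0:
        raise ValueError("no valid ACGT triplets in window")
    repeats = sum(c * (c - 1) // 2 for c in counts.values())
    s = repeats / (w - 1) if w > 1 else 0.0
    return s, (math.inf if s == 0 else -math.log(s))


@dataclass(frozen=True)
class LocalContext:
    """GC content and complexity of the window around a mutation."""

    gc_content: float
    s: float
    neg_ln_s: float
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive


def local_context(genome, call_or_pos, flank: int = 20) -> LocalContext:
    """GC fraction and DUST complexity of the +/-``flank`` bp window around a
    call (a :class:`MutationCall` or a 1-based global position); truncated at
    genome ends with the effective window recorded."""
    pos1 = call_or_pos.pos if isinstance(call_or_pos, MutationCall) else int(call_or_pos)
    if isinstance(call_or_pos, MutationCall):
        pos0 = genome.global_pos(call_or_pos.chrom, call_or_pos.pos)
    else:
        pos0 = pos1 - 1
    start = max(0, pos0 - flank)
    end = min(len(genome.sequence), pos0 + flank + 1)
    window = genome.sequence[start:end]
    gc = (window.count("G") + window.count("C")) / len(window)
    s, neg = dust_complexity(window)
    return LocalContext(gc_content=gc, s=s, neg_ln_s=neg, start=start, end=end)


def mutations_per_gene(
    calls: Iterable[MutationCall],
    genes: Iterable[tuple[str, str, int, int]],
) -> pd.DataFrame:
    """Mutation count and covered length per gene interval.

    Genes are (name, chrom, start, end) with 0-based half-open coordinates on
    the genome.  A call in overlapping genes is counted in every one of them.
    Returns a DataFrame (gene, chrom, covered_bases, n_mutations) suitable for
    a count-versus-length regression.
    """
    calls = list(calls)
    rows = []
    for name, chrom, start, end in genes:
        if end <= start:
            raise ValueError(f"empty gene interval {name}")
        n = sum(1 for c in calls if c.chrom == chrom and start <= c.pos - 1 < end)
        rows.append((name, chrom, end - start, n))
    return pd.DataFrame(rows, columns=["gene", "chrom", "covered_bases", "n_mutations"])


def summarize_spectrum(calls: Iterable[MutationCall], genome_gc: float | None = None) -> SpectrumSummary:
    """Class counts, Ti/Tv and GC-bias summary of a call set."""
    calls = list(calls)
    class_counts = {c: 0 for c in CLASSES}
    for call in calls:
        class_counts[call.mclass] += 1
    sbs = [c for c in calls if c.mclass == "SBS"]
    ti, tv, ratio = titv_summary(sbs) if sbs else (0, 0, None)
    n_gc = n_at = 0
    for call in calls:
        if call.mclass not in ("SBS", "MBS"):
            continue
        anc = _sbs_change(call)[0] if call.mclass == "SBS" else call.ancestral[0]
        if anc in "GC":
            n_gc += 1
        elif anc in "AT":
            n_at += 1
    fold = None
    if genome_gc is not None and n_at > 0:
        fold = gc_fold_bias(n_gc, n_at, genome_gc)
    return SpectrumSummary(
        class_counts=class_counts, ti=ti, tv=tv, titv_normalized=ratio,
        n_gc=n_gc, n_at=n_at, gc_fold_bias=fold,
    )
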