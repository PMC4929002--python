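"""Synthetic data generation with known ground truth.

Emulates every input the analysis consumes: a progenitor genome, per-line
mutation histories under neutral Wright-Fisher drift at effective size
``2Ne`` haploids, pileup-style allele counts with sequencing noise, and
line x replicate trait panels (MA-style, where among-line variance
accumulates from mutations, and inbred-panel-style, where it reflects
standing variation at genotyped loci).

All randomness flows from a single seed; identical seeds give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "TrueMutation",
    "TraitPanel",
    "generate_genome",
    "simulate_ma_lines",
    "render_pileups",
    "simulate_trait_panel",
    "simulate_inbred_panel",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class Genome:
    """A progenitor genome: one string of A/C/G/T with per-base chromosome tags.

    The first ``x_length`` bases are tagged "X"; the remainder "A" (autosome).
    Coordinates are 0-based internally; 1-based in written output.
    """

    sequence: str
    x_length: int

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome length must be positive")
        if not 0 <= self.x_length <= len(self.sequence):
            raise ValueError("x_length out of range")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        seq = self.sequence
        return (seq.count("G") + seq.count("C")) / len(seq)

    def chrom_of(self, pos0: int) -> str:
        """Chromosome tag ("X" or "A") of a 0-based position."""
        if not 0 <= pos0 < len(self.sequence):
            raise IndexError("position outside genome")
        return "X" if pos0 < self.x_length else "A"

    @property
    def chrom_labels(self) -> np.ndarray:
        labels = np.full(len(self.sequence), "A", dtype="<U1")
        labels[: self.x_length] = "X"
        return labels

    def chrom_pos(self, pos0: int) -> tuple[str, int]:
        """(chrom, 1-based position within chromosome) of a 0-based index."""
        chrom = self.chrom_of(pos0)
        return (chrom, pos0 + 1 if chrom == "X" else pos0 - self.x_length + 1)

    def global_pos(self, chrom: str, pos1: int) -> int:
        """0-based global index from (chrom, 1-based within-chromosome pos)."""
        return pos1 - 1 if chrom == "X" else self.x_length + pos1 - 1


@dataclass
class TrueMutation:
    """One simulated mutation and its full drift trajectory.

    ``trajectory[i]`` is the mutant copy count (in [0, 2Ne]) at generation
    ``origin_generation + i``; the count changes only by binomial resampling
    after an origin at one copy, and absorbing states (0 and 2Ne) are
    permanent.
    """

    line_id: str
    position: int  # 1-based global position
    chrom: str
    ancestral: str
    mutant: str
    origin_generation: int
    two_ne: int
    trajectory: np.ndarray

    def freq_at(self, generation: int) -> float:
        """Mutant frequency (copies / 2Ne) at an absolute generation."""
        if generation < self.origin_generation:
            return 0.0
        i = min(generation - self.origin_generation, len(self.trajectory) - 1)
        return float(self.trajectory[i]) / self.two_ne


@dataclass
class TraitPanel:
    """Line x replicate measurements of one quantitative trait.

    ``pool_n`` is the number of individuals pooled per measured sample (each
    recorded value is a pool mean), which inflates the mapping from
    within-line variance to per-individual environmental variance.
    """

    trait: str
    sex: str
    data: pd.DataFrame  # columns: line, replicate, value
    pool_n: int = 1

    def __post_init__(self) -> None:
        required = {"line", "replicate", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"panel data must have columns {sorted(required)}")
        if not np.isfinite(self.data["value"]).all():
            raise ValueError("trait values must be finite")
        counts = self.data.groupby("line").size()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError("need >=2 lines with >=2 observations each")

    @property
    def n_lines(self) -> int:
        return self.data["line"].nunique()


def generate_genome(
    length: int, gc: float = 0.4248, x_fraction: float = 0.2, seed: int | None = None
) -> Genome:
    """I.i.d. random genome with target GC content.

    ``P(G) = P(C) = gc/2`` and ``P(A) = P(T) = (1-gc)/2``; the first
    ``x_fraction`` of bases is tagged as the X chromosome.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    if not 0 <= x_fraction < 1:
        raise ValueError("x_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(_BASES, size=length, p=probs)
    return Genome(sequence="".join(seq), x_length=int(round(length * x_fraction)))


def _wf_trajectory(two_ne: int, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Copy counts from a single-copy origin through n_steps binomial updates."""
    traj = np.empty(n_steps + 1, dtype=np.int64)
    traj[0] = 1
    c = 1
    for i in range(1, n_steps + 1):
        if 0 < c < two_ne:
            c = rng.binomial(two_ne, c / two_ne)
        traj[i] = c
    return traj


def _homopolymer_positions(sequence: str, min_run: int = 4) -> np.ndarray:
    """0-based positions lying inside homopolymer runs of >= min_run bases."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [arr.size]])
    keep = (ends - starts) >= min_run
    if not keep.any():
        return np.array([], dtype=np.int64)
    return np.concatenate([np.arange(s, e) for s, e in zip(starts[keep], ends[keep])])


def simulate_ma_lines(
    genome: Genome,
    n_lines: int,
    t: int,
    mu: float,
    two_ne: int,
    seed: int | None = None,
    two_ne_x: int | None = None,
    indel_fraction: float = 0.0,
    slippage_bias: float = 0.9,
    line_prefix: str = "MA",
) -> dict[str, list[TrueMutation]]:
    """Simulate mutation histories of MA lines under neutral drift.

    Each generation, each line receives ``Poisson(2Ne * mu * B)`` new
    mutations, each starting as a single copy among ``two_ne`` haploids
    (``two_ne_x`` on the X, if given) and evolving by Wright-Fisher binomial
    resampling to generation ``t``.  Positions already mutated in a line are
    re-drawn (infinite-sites).  A fraction ``indel_fraction`` of mutations
    are single-base insertions/deletions, placed inside homopolymer runs
    with probability ``slippage_bias`` (replication slippage).

    Returns ``{line_id: [TrueMutation, ...]}`` including mutations later lost.
    """
    if two_ne < 2:
        raise ValueError("two_ne must be >= 2")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    rng = np.random.default_rng(seed)
    B = len(genome)
    homo = _homopolymer_positions(genome.sequence) if indel_fraction > 0 else None
    lines: dict[str, list[TrueMutation]] = {}
    width = max(2, len(str(n_lines)))
    for i in range(n_lines):
        line_id = f"{line_prefix}{i + 1:0{width}d}"
        taken: set[int] = set()
        muts: list[TrueMutation] = []
        for gen in range(1, t + 1):
            ne_here = two_ne  # rate uses the autosomal/global 2Ne
            n_new = rng.poisson(ne_here * mu * B)
            for _ in range(n_new):
                is_indel = indel_fraction > 0 and rng.random() < indel_fraction
                for _ in range(1000):  # infinite sites: re-draw collisions
                    if is_indel and homo is not None and homo.size and rng.random() < slippage_bias:
                        pos0 = int(rng.choice(homo))
                    else:
                        pos0 = int(rng.integers(B))
                    if pos0 not in taken:
                        break
                else:  # pragma: no cover - saturated toy genome
                    continue
                taken.add(pos0)
                anc = genome.sequence[pos0]
                if is_indel:
                    if rng.random() < 0.75 and pos0 + 1 < B:  # deletions 3x insertions
                        anc_allele = genome.sequence[pos0 : pos0 + 2]
                        mut_allele = anc
                        taken.add(pos0 + 1)
                    else:
                        anc_allele = anc
                        mut_allele = anc + anc  # slippage duplicates the base
                else:
                    anc_allele = anc
                    alternates = [b for b in "ACGT" if b != anc]
                    mut_allele = alternates[int(rng.integers(3))]
                chrom = genome.chrom_of(pos0)
                ne_m = two_ne_x if (chrom == "X" and two_ne_x is not None) else two_ne
                traj = _wf_trajectory(ne_m, t - gen, rng)
                muts.append(
                    TrueMutation(
                        line_id=line_id,
                        position=pos0 + 1,
                        chrom=chrom,
                        ancestral=anc_allele,
                        mutant=mut_allele,
                        origin_generation=gen,
                        two_ne=ne_m,
                        trajectory=traj,
                    )
                )
        lines[line_id] = muts
    return lines


def render_pileups(
    genome: Genome,
    true_mutations: dict[str, list[TrueMutation]],
    mean_depth: float = 30.0,
    depth_bounds: tuple[int, int] = (1, 250),
    error_rate: float = 0.0,
    seed: int | None = None,
    t: int | None = None,
    parental_id: str = "P0",
    n_background: int = 0,
    positions: list[int] | None = None,
):
    """Render per-site, per-line, per-strand allele counts at selected sites.

    Sites rendered are the union of all true-mutation positions, ``positions``
    (1-based global), and ``n_background`` uniformly drawn background sites.
    Per line and site the total depth is Poisson(``mean_depth``) truncated to
    ``depth_bounds``; mutant reads are Binomial(depth, line frequency at
    generation ``t``); reads split across strands Binomial(n, 0.5); each read
    is replaced by a uniformly random other base with probability
    ``error_rate``.

    Returns a :class:`madrift.calling.PileupTable`.
    """
    from .calling import PileupTable

    if depth_bounds[0] > depth_bounds[1]:
        raise ValueError("depth bounds inverted")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= error_rate < 0.01:
        raise ValueError("error_rate must be in [0, 0.01)")
    rng = np.random.default_rng(seed)

    site_set: set[int] = set()
    mut_at: dict[tuple[int, str], tuple[str, str, float]] = {}
    for line_id, muts in true_mutations.items():
        for m in muts:
            gen = t if t is not None else m.origin_generation + len(m.trajectory) - 1
            f = m.freq_at(gen)
            site_set.add(m.position)
            if f > 0:
                mut_at[(m.position, line_id)] = (m.ancestral, m.mutant, f)
    if positions:
        site_set.update(positions)
    if n_background:
        site_set.update(int(p) + 1 for p in rng.integers(len(genome), size=n_background))

    sites = sorted(site_set)
    line_ids = [parental_id] + sorted(true_mutations)
    lo, hi = depth_bounds
    rows: list[tuple[str, int, str, str, str, int]] = []

    def _emit(chrom: str, pos1: int, line_id: str, allele: str, count: int) -> None:
        if count <= 0:
            return
        fwd = int(rng.binomial(count, 0.5))
        if fwd:
            rows.append((chrom, pos1, line_id, allele, "+", fwd))
        if count - fwd:
            rows.append((chrom, pos1, line_id, allele, "-", count - fwd))

    for pos1 in sites:
        pos0 = pos1 - 1
        chrom, cpos = genome.chrom_pos(pos0)
        ref_base = genome.sequence[pos0]
        for line_id in line_ids:
            depth = int(np.clip(rng.poisson(mean_depth), lo, hi))
            anc_allele, mut_allele, f = mut_at.get((pos1, line_id), (ref_base, None, 0.0))
            n_mut = int(rng.binomial(depth, f)) if mut_allele is not None else 0
            n_anc = depth - n_mut
            counts: dict[str, int] = {}
            for allele, n in ((anc_allele, n_anc), (mut_allele, n_mut)):
                if allele is None or n == 0:
                    continue
                n_err = int(rng.binomial(n, error_rate)) if error_rate else 0
                counts[allele] = counts.get(allele, 0) + (n - n_err)
                for _ in range(n_err):
                    base = allele[0] if allele else ref_base
                    err = [b for b in "ACGT" if b != base][int(rng.integers(3))]
                    counts[err] = counts.get(err, 0) + 1
            for allele, n in sorted(counts.items()):
                _emit(chrom, cpos, line_id, allele, n)

    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "line_id", "allele", "strand", "count"]
    )
    return PileupTable(df, parental_id=parental_id)


def simulate_trait_panel(
    n_lines: int,
    reps_per_line: int,
    v_line: float,
    v_within: float,
    pool_n: int = 1,
    seed: int | None = None,
    trait: str = "trait",
    sex: str = "F",
    line_prefix: str = "L",
) -> TraitPanel:
    """Balanced line x replicate panel: value = N(0, v_line) + N(0, v_within)."""
    if v_line < 0 or v_within < 0:
        raise ValueError("variances must be non-negative")
    if n_lines < 2 or reps_per_line < 2:
        raise ValueError("need >=2 lines and >=2 replicates per line")
    rng = np.random.default_rng(seed)
    line_eff = rng.normal(0.0, np.sqrt(v_line), size=n_lines)
    values = np.repeat(line_eff, reps_per_line) + rng.normal(
        0.0, np.sqrt(v_within), size=n_lines * reps_per_line
    )
    width = max(2, len(str(n_lines)))
    df = pd.DataFrame(
        {
            "line": np.repeat([f"{line_prefix}{i + 1:0{width}d}" for i in range(n_lines)], reps_per_line),
            "replicate": np.tile(np.arange(1, reps_per_line + 1), n_lines),
            "value": values,
        }
    )
    return TraitPanel(trait=trait, sex=sex, data=df, pool_n=pool_n)


def simulate_inbred_panel(
    n_lines: int,
    n_loci: int,
    allele_freqs,
    effect_var: float,
    v_within: float,
    seed: int | None = None,
    reps_per_line: int = 2,
    trait: str = "trait",
    sex: str = "F",
    line_prefix: str = "I",
) -> tuple[TraitPanel, pd.DataFrame]:
    """Inbred (fully homozygous) panel with standing variation at known loci.

    Dosages are 0 or 2 (inbred lines carry two copies of one allele) drawn
    Bernoulli(freq) per locus; allelic effects ``a_i ~ N(0, effect_var)``; the
    line genetic value is ``sum_i a_i g_i``.  The among-line trait variance
    converges to ``effect_var * sum_i Var(g_i)`` as loci grow.
    """
    freqs = np.broadcast_to(np.asarray(allele_freqs, dtype=float), (n_loci,)).copy()
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ValueError("allele frequencies must be in (0, 1)")
    if effect_var < 0 or v_within < 0:
        raise ValueError("variances must be non-negative")
    rng = np.random.default_rng(seed)
    dosage = 2 * (rng.random((n_lines, n_loci)) < freqs).astype(np.int64)
    effects = rng.normal(0.0, np.sqrt(effect_var), size=n_loci)
    genetic = dosage @ effects
    values = np.repeat(genetic, reps_per_line) + rng.normal(
        0.0, np.sqrt(v_within), size=n_lines * reps_per_line
    )
    width = max(2, len(str(n_lines)))
    line_ids = [f"{line_prefix}{i + 1:0{width}d}" for i in range(n_lines)]
    df = pd.DataFrame(
        {
            "line": np.repeat(line_ids, reps_per_line),
            "replicate": np.tile(np.arange(1, reps_per_line + 1), n_lines),
            "value": values,
        }
    )
    dosage_df = pd.DataFrame(
        dosage, index=pd.Index(line_ids, name="line"),
        columns=[f"locus{j + 1}" for j in range(n_loci)],
    )
    return TraitPanel(trait=trait, sex=sex, data=df, pool_n=1), dosage_df
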