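"""Wright-Fisher drift simulation and simulation-based inference of effective
population size and mutation rate in mutation-accumulation (MA) lines.

MA lines are propagated at tiny population size, so a new mutation's fate is
governed almost entirely by genetic drift among ``2Ne`` haploid genomes.  This
module simulates the marginal frequency distribution at the sequencing
generation of mutations that arose once per line per generation, and uses it
for three things:

* the *detection probability* ``p`` — the marginal chance, integrated over all
  origin generations, that a mutation attains sampled frequency above the
  calling cutoff (0.2) at generation ``t``;
* a 16-bin multinomial likelihood over the mutant allele-frequency spectrum on
  (0.2, 1], maximized over an integer grid of ``2Ne`` values;
* the per-line mutation-rate estimator ``mu = m / (t * 2Ne * p * B)``.

The closed-form (diffusion) fixation probability for a mutation of additive
selection coefficient ``s`` is also provided for comparison with the neutral
``1/(2Ne)`` limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "BIN_EDGES",
    "N_BINS",
    "FrequencySpectrum",
    "NeFit",
    "RateEstimate",
    "DetectionDistribution",
    "expected_spectrum",
    "detection_distribution",
    "bin_spectrum",
    "multinomial_loglik",
    "estimate_ne",
    "fixation_probability",
    "estimate_mutation_rate",
    "ne_sensitivity",
    "expected_pairwise_difference",
]

#: Half-open bin edges (lo, hi] for mutant frequencies on (0.2, 1].
N_BINS = 16
BIN_EDGES = np.round(np.linspace(0.2, 1.0, N_BINS + 1), 10)


@dataclass(frozen=True)
class FrequencySpectrum:
    """Counts of mutant allele frequencies in 16 half-open bins on (0.2, 1]."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_BINS,):
            raise ValueError(f"spectrum must have exactly {N_BINS} bins")
        if (counts < 0).any():
            raise ValueError("bin counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DetectionDistribution:
    """Simulated marginal distribution of sampled mutant frequencies at G``t``.

    ``p_detect`` is the fraction of all simulated mutations whose sampled
    frequency exceeds the cutoff; ``bin_probs`` is that detected mass
    distributed over the 16 spectrum bins.  ``p_below`` and ``below_freqs``
    describe mutations still segregating at ``t`` but below the cutoff
    (sampled frequency in (0, cutoff]); they support the augmentation of
    sequence-variance sums with undetected mutations.
    """

    two_ne: int
    t: int
    n_mutations: int
    p_detect: float
    bin_probs: np.ndarray
    p_below: float
    below_freqs: np.ndarray
    low_confidence: bool

    def sample_below_cutoff(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` sub-cutoff segregating sampled frequencies (empirical)."""
        if self.below_freqs.size == 0:
            raise ValueError("no sub-cutoff frequencies were recorded")
        return rng.choice(self.below_freqs, size=n, replace=True)


@dataclass
class NeFit:
    """Likelihood profile of the effective size over an integer grid."""

    grid: np.ndarray
    logliks: np.ndarray
    bin_probs: np.ndarray  # shape (len(grid), 16)
    ml_two_ne: int
    p_detect: float  # detection probability at the ML grid point
    reps: int
    t: int
    seed: int
    impossible: bool = False  # every grid point had -inf likelihood

    def profile(self) -> dict[int, float]:
        return {int(g): float(l) for g, l in zip(self.grid, self.logliks)}


@dataclass(frozen=True)
class RateEstimate:
    """Per-line spontaneous mutation rate ``mu = m / (t * 2Ne * p * B)``."""

    line_id: str
    m: int
    t: int
    two_ne: int
    p: float
    callable_bases: float
    mu: float


def _simulate_sampled_frequencies(
    two_ne: int,
    t: int,
    n_lines: int,
    sample_n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sampled G``t`` frequencies of ``n_lines * t`` independent mutations.

    One new single-copy mutation is introduced per line per generation; each
    evolves by neutral Wright-Fisher binomial resampling among ``two_ne``
    haploids.  A mutation arising in generation ``g`` undergoes ``t - g``
    resampling steps before ``sample_n`` chromosomes are drawn binomially
    (with replacement) at generation ``t``.

    Returns the full vector of sampled frequencies (zeros included), length
    ``n_lines * t``.
    """
    out = np.empty(n_lines * t, dtype=np.float64)
    pos = 0
    for duration in range(t):
        counts = np.ones(n_lines, dtype=np.int64)
        n_fixed = 0
        n_lost = 0
        for _ in range(duration):
            counts = rng.binomial(two_ne, counts / two_ne)
            n_fixed += int((counts == two_ne).sum())
            n_lost += int((counts == 0).sum())
            counts = counts[(counts > 0) & (counts < two_ne)]
            if counts.size == 0:
                break
        freqs = np.concatenate(
            [counts / two_ne, np.ones(n_fixed), np.zeros(n_lost)]
        )
        sampled = rng.binomial(sample_n, freqs) / sample_n
        out[pos : pos + n_lines] = sampled
        pos += n_lines
    return out


def detection_distribution(
    two_ne: int,
    t: int = 60,
    reps: int = 100_000,
    sample_n: int = 200,
    cutoff: float = 0.2,
    seed: int | None = None,
) -> DetectionDistribution:
    """Simulate the marginal sampled-frequency distribution of new mutations.

    ``reps`` is the number of simulated MA lines; each contributes one new
    mutation per generation, so ``reps * t`` trajectories are simulated.
    """
    if two_ne < 2 or two_ne > 10_000:
        raise ValueError("two_ne must be in [2, 10000]")
    if reps * t < 10_000:
        raise ValueError("too few trajectories; increase reps")
    rng = np.random.default_rng(seed)
    sampled = _simulate_sampled_frequencies(two_ne, t, reps, sample_n, rng)
    n = sampled.size
    detected = sampled[sampled > cutoff]
    below = sampled[(sampled > 0) & (sampled <= cutoff)]
    counts, _ = np.histogram(detected, bins=BIN_EDGES)
    p_detect = detected.size / n
    if detected.size:
        bin_probs = counts / detected.size
    else:
        bin_probs = np.zeros(N_BINS)
    return DetectionDistribution(
        two_ne=two_ne,
        t=t,
        n_mutations=n,
        p_detect=p_detect,
        bin_probs=bin_probs,
        p_below=below.size / n,
        below_freqs=below,
        low_confidence=bool((counts == 0).any()),
    )


_SPECTRUM_CACHE: dict[tuple, tuple[np.ndarray, float]] = {}


def expected_spectrum(
    two_ne: int,
    t: int = 60,
    reps: int = 100_000,
    sample_n: int = 200,
    cutoff: float = 0.2,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Expected 16-bin probabilities and detection probability at ``two_ne``.

    Returns ``(bin_probs, p)`` where ``bin_probs`` sums to 1 over the bins on
    (0.2, 1] and ``p`` is the marginal probability, integrated over the ``t``
    origin generations, that a mutation's sampled frequency exceeds the
    cutoff at generation ``t``.  Seeded results are memoized (the grid search
    re-simulates the same points across calls).
    """
    key = (two_ne, t, reps, sample_n, cutoff, seed)
    if seed is not None and key in _SPECTRUM_CACHE:
        probs, p = _SPECTRUM_CACHE[key]
        return probs.copy(), p
    dist = detection_distribution(two_ne, t, reps, sample_n, cutoff, seed)
    if seed is not None:
        if len(_SPECTRUM_CACHE) > 512:
            _SPECTRUM_CACHE.clear()
        _SPECTRUM_CACHE[key] = (dist.bin_probs.copy(), dist.p_detect)
    return dist.bin_probs, dist.p_detect


def bin_spectrum(frequencies: Iterable[float]) -> FrequencySpectrum:
    """Bin mutant frequencies into the 16 half-open (lo, hi] bins on (0.2, 1]."""
    freqs = np.asarray(list(frequencies), dtype=np.float64)
    if freqs.size == 0:
        return FrequencySpectrum(np.zeros(N_BINS, dtype=np.int64))
    if (freqs <= BIN_EDGES[0]).any() or (freqs > 1.0).any():
        raise ValueError("frequencies must lie in (0.2, 1]")
    # half-open (lo, hi]: searchsorted with side='left' on the inner edges
    idx = np.searchsorted(BIN_EDGES[1:-1], freqs, side="left")
    counts = np.bincount(idx, minlength=N_BINS)
    return FrequencySpectrum(counts.astype(np.int64))


def multinomial_loglik(spectrum: FrequencySpectrum, probs: Sequence[float]) -> float:
    """Log multinomial pmf of the observed spectrum under bin probabilities.

    Includes the multinomial coefficient.  A bin with zero probability but a
    positive observed count yields ``-inf``.
    """
    p = np.asarray(probs, dtype=np.float64)
    if p.shape != (N_BINS,):
        raise ValueError(f"expected {N_BINS} bin probabilities")
    if not math.isclose(float(p.sum()), 1.0, abs_tol=1e-8):
        raise ValueError("bin probabilities must sum to 1")
    m = spectrum.counts
    total = spectrum.total
    if total == 0:
        return 0.0
    if ((p == 0) & (m > 0)).any():
        return float("-inf")
    active = m > 0
    coef = gammaln(total + 1) - gammaln(m + 1).sum()
    return float(coef + (m[active] * np.log(p[active])).sum())


def estimate_ne(
    spectrum: FrequencySpectrum,
    grid: Sequence[int] = range(10, 41),
    t: int = 60,
    reps: int = 100_000,
    sample_n: int = 200,
    cutoff: float = 0.2,
    seed: int = 0,
) -> NeFit:
    """Maximum-likelihood effective size over an integer ``2Ne`` grid.

    For each grid value the expected spectrum is simulated with a seed derived
    deterministically from ``seed`` and the grid value (common random numbers
    smooth the likelihood profile across the grid).  Ties break toward the
    smaller ``2Ne``.
    """
    if spectrum.total < 1:
        raise ValueError("observed spectrum is empty")
    grid = np.asarray(sorted(int(g) for g in grid), dtype=np.int64)
    logliks = np.empty(grid.size)
    probs = np.empty((grid.size, N_BINS))
    p_detects = np.empty(grid.size)
    for i, two_ne in enumerate(grid):
        sub_seed = int(np.random.SeedSequence([seed, int(two_ne)]).generate_state(1)[0] % (2**31))
        bin_probs, p = expected_spectrum(
            int(two_ne), t=t, reps=reps, sample_n=sample_n, cutoff=cutoff, seed=sub_seed
        )
        probs[i] = bin_probs
        p_detects[i] = p
        logliks[i] = multinomial_loglik(spectrum, bin_probs)
    impossible = bool(np.isneginf(logliks).all())
    best = int(np.argmax(logliks))  # argmax returns the first (smallest) maximizer
    return NeFit(
        grid=grid,
        logliks=logliks,
        bin_probs=probs,
        ml_two_ne=int(grid[best]),
        p_detect=float(p_detects[best]),
        reps=reps,
        t=t,
        seed=seed,
        impossible=impossible,
    )


def fixation_probability(s: float, ne: float) -> float:
    """Diffusion fixation probability of a new additive mutation.

    ``u = (1 - exp(-2s)) / (1 - exp(-4 s Ne))``; the neutral limit ``s -> 0``
    is ``1 / (2 Ne)``.
    """
    if ne <= 0:
        raise ValueError("ne must be positive")
    if abs(s) < 1e-12:
        return 1.0 / (2.0 * ne)
    return float(np.expm1(-2.0 * s) / np.expm1(-4.0 * s * ne))


def estimate_mutation_rate(
    m: int, t: int, two_ne: float, p: float, callable_bases: float, line_id: str = ""
) -> RateEstimate:
    """Per-line mutation rate ``mu = m / (t * 2Ne * p * B)``.

    ``m`` observed mutations over ``t`` generations; ``p`` the detection
    probability at the fitted ``2Ne``; ``B`` the number of bases eligible for
    calling in that line.
    """
    if t <= 0 or two_ne <= 0:
        raise ValueError("t and two_ne must be positive")
    if p <= 0 or callable_bases <= 0:
        raise ValueError("p and callable_bases must be positive")
    if m < 0:
        raise ValueError("m must be non-negative")
    mu = m / (t * two_ne * p * callable_bases)
    return RateEstimate(
        line_id=line_id, m=m, t=t, two_ne=int(two_ne), p=p,
        callable_bases=callable_bases, mu=mu,
    )


def ne_sensitivity(
    grid: Sequence[int] = range(10, 41),
    t: int = 60,
    reps: int = 20_000,
    sample_n: int = 200,
    cutoff: float = 0.2,
    seed: int = 0,
    p_func: Callable[[int], float] | None = None,
) -> tuple[float, dict[int, float]]:
    """Relative spread of ``2Ne * p(2Ne)`` across the grid, as a percentage.

    Because the rate estimator divides by ``2Ne * p``, the spread
    ``100 * (max - min) / min`` of that product bounds how much mis-specifying
    ``2Ne`` within the grid can move the rate estimate.  ``p_func`` may
    replace the simulation (used to validate the spread formula itself).
    """
    products: dict[int, float] = {}
    for two_ne in sorted(int(g) for g in grid):
        if p_func is not None:
            p = p_func(two_ne)
        else:
            sub_seed = int(np.random.SeedSequence([seed, two_ne]).generate_state(1)[0] % (2**31))
            _, p = expected_spectrum(
                two_ne, t=t, reps=reps, sample_n=sample_n, cutoff=cutoff, seed=sub_seed
            )
        products[two_ne] = two_ne * p
    vals = np.array(list(products.values()))
    spread = 100.0 * (vals.max() - vals.min()) / vals.min()
    return float(spread), products


def expected_pairwise_difference(mean_mutations_per_line: float) -> float:
    """Expected number of sites at which two MA lines differ.

    Mutations arise independently per line from a shared progenitor, so two
    lines differ at the union of their private mutations: twice the per-line
    mean.
    """
    return 2.0 * mean_mutations_per_line
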