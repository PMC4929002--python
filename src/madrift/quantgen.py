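"""Quantitative-genetic analysis of MA and inbred-panel trait data.

Partitions trait variance into among-line and within-line components by REML,
converts the accumulated among-line variance of MA lines into the per-
generation mutational variance through the drift correction factor

    k = 2 [ t - (2Ne - 5) (1 - exp(-t / 2Ne)) ],

computes the mutational heritability h2m = Vm/Ve, and compares mutational to
standing genetic variance (Vm/Vg) against the neutral expectation 1/(4N) and
the sequence-based expectation sum Var(m_i)/k over sum Var(g_i).  The
mutation-selection-balance summaries are the house-of-cards locus number
n = Vg / (4 mu Vs) and the pleiotropic selection coefficient s = Vm/Vg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .simulate import TraitPanel

__all__ = [
    "VarianceComponents",
    "MutationalParams",
    "SelectionReport",
    "MixtureFit",
    "normal_quantile_transform",
    "fit_expression_mixture",
    "partition_variance",
    "k_factor",
    "mutational_heritability",
    "neutral_population_size",
    "sequence_variance_sum",
    "ma_dosage_matrix",
    "selection_report",
    "fdr_adjust",
]

#: Ratio of the standard deviation to the median absolute deviation of a
#: normal distribution, as used for the rank-based normal transform.
MAD_SCALE = 1.4824


@dataclass
class VarianceComponents:
    """REML variance partition of one trait panel."""

    trait: str
    sex: str
    v_line: float
    v_within: float
    v_rep: float | None
    n_lines: int
    n_obs: int
    loglik: float
    loglik_null: float
    p_value: float
    q_value: float | None = None


@dataclass(frozen=True)
class MutationalParams:
    """Per-generation mutational variance and heritability."""

    vm: float
    ve: float
    h2m: float
    k: float
    t: int
    two_ne: int
    pool_n: int


@dataclass(frozen=True)
class SelectionReport:
    """Mutational vs standing variance against neutral and selection models."""

    vg: float
    vm_vg: float
    neutral_expectation: float  # 1 / (4N)
    sequence_ratio: float  # sum Var(m_i)/k over sum Var(g_i)
    effect_size_ratio: float  # E(a_m^2) / E(a_g^2)
    s_pleiotropic: float  # = Vm/Vg
    hoc_n_loci: float  # house-of-cards n = Vg / (4 mu Vs)


def normal_quantile_transform(
    values: Sequence[float], scale_factor: float = MAD_SCALE
) -> np.ndarray:
    """Rank-based transform to a normal with robust location and scale.

    Values are replaced by quantiles of Normal(median(x), (scale_factor *
    MAD(x))^2) at plotting positions rank/(n+1); tied values share averaged
    ranks, so the transform is rank-preserving and invariant to monotone
    transformations of the input.  ``scale_factor`` defaults to the normal-
    consistency constant 1.4824 relating the MAD to the standard deviation
    (set it to 1.0 for a raw-MAD scale).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 3 or not np.isfinite(x).all():
        raise ValueError("need >=3 finite values")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0:
        raise ValueError("MAD is zero; transform is degenerate")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (x.size + 1), loc=med, scale=scale_factor * mad)


@dataclass
class MixtureFit:
    """Two-component normal mixture fit of median expression values."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    cutoff: float | None
    expressed: np.ndarray  # boolean per gene
    degenerate: bool


def fit_expression_mixture(
    median_expressions: Sequence[float],
    seed: int = 0,
    max_restarts: int = 10,
    posterior_threshold: float = 2.0 / 3.0,
) -> MixtureFit:
    """Classify genes as expressed via a two-normal mixture.

    Fits a 2-component Gaussian mixture by EM; the expression cutoff is the
    smallest value whose posterior probability of the high-mean component
    reaches ``posterior_threshold``, and a gene is called expressed when its
    posterior exceeds that threshold.  If one BIC-preferred component
    suffices (or the component means coincide), the fit is flagged
    degenerate with no cutoff.  EM runs with a vanishing component are
    restarted up to ``max_restarts`` times before failing.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(median_expressions, dtype=np.float64).reshape(-1, 1)
    if x.shape[0] < 50:
        raise ValueError("need >=50 genes for a stable mixture fit")
    fit2 = None
    for attempt in range(max_restarts):
        gm = GaussianMixture(
            n_components=2, n_init=3, random_state=seed + attempt, reg_covar=1e-9
        ).fit(x)
        if gm.weights_.min() > 1e-3 and gm.covariances_.min() > 1e-12:
            fit2 = gm
            break
    if fit2 is None:
        raise RuntimeError("mixture EM degenerate after restarts")
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(x)
    means = fit2.means_.ravel()
    sds = np.sqrt(fit2.covariances_.ravel())
    order = np.argsort(means)
    means, sds = means[order], sds[order]
    weights = fit2.weights_[order]
    sep = abs(means[1] - means[0]) / math.sqrt(float(sds.mean() ** 2))
    if gm1.bic(x) <= fit2.bic(x) or sep < 1e-3:
        return MixtureFit(
            means=means, sds=sds, weights=weights, cutoff=None,
            expressed=np.zeros(x.shape[0], dtype=bool), degenerate=True,
        )

    def posterior_high(v: np.ndarray) -> np.ndarray:
        num = weights[1] * stats.norm.pdf(v, means[1], sds[1])
        den = num + weights[0] * stats.norm.pdf(v, means[0], sds[0])
        return num / den

    grid = np.linspace(x.min(), x.max(), 4001)
    post = posterior_high(grid)
    above = np.flatnonzero(post >= posterior_threshold)
    cutoff = None
    if above.size:
        i = above[0]
        if i == 0:
            cutoff = float(grid[0])
        else:
            cutoff = float(
                optimize.brentq(
                    lambda v: posterior_high(np.array([v]))[0] - posterior_threshold,
                    grid[i - 1], grid[i],
                )
            )
    expressed = posterior_high(x.ravel()) > posterior_threshold
    return MixtureFit(
        means=means, sds=sds, weights=weights, cutoff=cutoff,
        expressed=expressed, degenerate=cutoff is None,
    )


# ---------------------------------------------------------------------------
# REML variance partitioning


def _reml_stats(
    y_blocks: list[np.ndarray],
    rep_blocks: list[np.ndarray] | None,
    lam_line: float,
    lam_rep: float,
) -> tuple[float, float, float, float]:
    """(logdet, 1'V^-1 1, 1'V^-1 y, y'V^-1 y) for unit-residual covariance
    V = I + lam_rep * J_rep-blocks + lam_line * J, accumulated over lines."""
    logdet = a11 = a1y = ayy = 0.0
    for bi, y in enumerate(y_blocks):
        n = y.size
        V = np.eye(n)
        if lam_rep and rep_blocks is not None:
            reps = rep_blocks[bi]
            V += lam_rep * (reps[:, None] == reps[None, :])
        if lam_line:
            V += lam_line
        L = np.linalg.cholesky(V)
        logdet += 2.0 * np.log(np.diag(L)).sum()
        ones = np.ones(n)
        s1 = np.linalg.solve(L, ones)
        sy = np.linalg.solve(L, y)
        a11 += s1 @ s1
        a1y += s1 @ sy
        ayy += sy @ sy
    return logdet, a11, a1y, ayy


def _reml_loglik(
    y_blocks: list[np.ndarray],
    rep_blocks: list[np.ndarray] | None,
    lam_line: float,
    lam_rep: float,
) -> tuple[float, float]:
    """Profiled REML log-likelihood and the profiled residual variance."""
    n_obs = sum(y.size for y in y_blocks)
    logdet, a11, a1y, ayy = _reml_stats(y_blocks, rep_blocks, lam_line, lam_rep)
    q = ayy - a1y**2 / a11
    if q <= 0:
        return math.inf, 0.0  # degenerate: no residual variation
    sigma_e2 = q / (n_obs - 1)
    ll = -0.5 * ((n_obs - 1) * (math.log(2 * math.pi * sigma_e2) + 1.0) + logdet + math.log(a11))
    return ll, sigma_e2


def _maximize_reml(
    y_blocks, rep_blocks, fit_line: bool, fit_rep: bool
) -> tuple[float, float, float, float]:
    """Maximize REML over the requested variance ratios (others fixed at 0).

    Returns (loglik, lam_line, lam_rep, sigma_e2).
    """
    def nll_1d_line(u: float) -> float:
        return -_reml_loglik(y_blocks, rep_blocks, math.exp(u), 0.0)[0]

    def nll_1d_rep(u: float) -> float:
        return -_reml_loglik(y_blocks, rep_blocks, 0.0, math.exp(u))[0]

    best = (_reml_loglik(y_blocks, rep_blocks, 0.0, 0.0)[0], 0.0, 0.0)
    if fit_line and not fit_rep:
        res = optimize.minimize_scalar(nll_1d_line, bounds=(-18, 18), method="bounded")
        if -res.fun > best[0]:
            best = (-res.fun, math.exp(res.x), 0.0)
    elif fit_rep and not fit_line:
        res = optimize.minimize_scalar(nll_1d_rep, bounds=(-18, 18), method="bounded")
        if -res.fun > best[0]:
            best = (-res.fun, 0.0, math.exp(res.x))
    elif fit_line and fit_rep:
        for u0 in ((0.0, 0.0), (-3.0, -3.0), (2.0, -2.0)):
            res = optimize.minimize(
                lambda u: -_reml_loglik(y_blocks, rep_blocks, math.exp(u[0]), math.exp(u[1]))[0],
                x0=np.array(u0), method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10},
            )
            if -res.fun > best[0]:
                best = (-res.fun, math.exp(res.x[0]), math.exp(res.x[1]))
        # boundary: each single ratio alone
        for fit_l, fit_r in ((True, False), (False, True)):
            ll, ll_lam_line, ll_lam_rep, _ = _maximize_reml(y_blocks, rep_blocks, fit_l, fit_r)
            if ll > best[0]:
                best = (ll, ll_lam_line, ll_lam_rep)
    ll, lam_line, lam_rep = best
    # truncate vanishing ratios to exactly zero
    if lam_line < 1e-10:
        lam_line = 0.0
    if lam_rep < 1e-10:
        lam_rep = 0.0
    ll, sigma_e2 = _reml_loglik(y_blocks, rep_blocks, lam_line, lam_rep)
    return ll, lam_line, lam_rep, sigma_e2


def partition_variance(
    panel: TraitPanel | pd.DataFrame,
    with_replicate_term: bool = False,
    trait: str | None = None,
    sex: str | None = None,
) -> VarianceComponents:
    """REML partition of a trait panel into among- and within-line variance.

    Fits the random-effects model ``y = mu + line + e`` (or ``y = mu + line +
    replicate(line) + e`` when ``with_replicate_term``) by restricted maximum
    likelihood with the residual variance profiled out; negative component
    estimates are truncated at zero.  The among-line test is a likelihood-
    ratio test against ``V_line = 0`` with the boundary null distribution
    ``0.5 chi2_0 + 0.5 chi2_1``.  Unbalanced designs are allowed.
    """
    if isinstance(panel, TraitPanel):
        df = panel.data
        trait = trait or panel.trait
        sex = sex or panel.sex
    else:
        df = panel
        trait = trait or "trait"
        sex = sex or "NA"
    counts = df.groupby("line").size()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >=2 lines with >=2 observations each")
    y_blocks, rep_blocks = [], []
    for _, sub in df.groupby("line", sort=True):
        y_blocks.append(sub["value"].to_numpy(dtype=np.float64))
        rep_blocks.append(sub["replicate"].to_numpy())
    n_obs = int(sum(b.size for b in y_blocks))
    if float(np.var(np.concatenate(y_blocks))) < 1e-30:
        return VarianceComponents(
            trait=trait, sex=sex, v_line=0.0, v_within=0.0,
            v_rep=0.0 if with_replicate_term else None,
            n_lines=len(y_blocks), n_obs=n_obs,
            loglik=0.0, loglik_null=0.0, p_value=1.0,
        )
    ll, lam_line, lam_rep, sigma_e2 = _maximize_reml(
        y_blocks, rep_blocks if with_replicate_term else None, True, with_replicate_term
    )
    ll0, _, _, _ = _maximize_reml(
        y_blocks, rep_blocks if with_replicate_term else None, False, with_replicate_term
    )
    lrt = max(0.0, 2.0 * (ll - ll0))
    p = 0.5 * stats.chi2.sf(lrt, df=1) if lrt > 1e-12 else 1.0
    return VarianceComponents(
        trait=trait, sex=sex,
        v_line=lam_line * sigma_e2,
        v_within=sigma_e2,
        v_rep=(lam_rep * sigma_e2) if with_replicate_term else None,
        n_lines=len(y_blocks), n_obs=n_obs,
        loglik=ll, loglik_null=ll0, p_value=float(p),
    )


def k_factor(t: float, two_ne: float) -> float:
    """Drift correction relating accumulated among-line variance to the
    per-generation mutational variance: VMA = k Vm with
    ``k = 2 [t - (2Ne - 5)(1 - exp(-t / 2Ne))]``."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if two_ne < 2:
        raise ValueError("two_ne must be >= 2")
    return 2.0 * (t - (two_ne - 5.0) * (1.0 - math.exp(-t / two_ne)))


def mutational_heritability(
    components: VarianceComponents,
    t: int,
    two_ne: int = 21,
    pool_n: int = 1,
    mode: str = "expression",
) -> MutationalParams:
    """Mutational variance Vm = V_line / k and heritability h2m = Vm / Ve.

    ``mode`` selects the environmental-variance construction: for pooled
    expression samples Ve = pool_n * V_within (an upward-biased Ve, hence a
    conservative h2m); for sleep traits Ve = V_within; for bristle counts
    Ve = V_within + V_rep.
    """
    if mode not in ("expression", "sleep", "bristle"):
        raise ValueError("mode must be expression, sleep or bristle")
    k = k_factor(t, two_ne)
    vm = components.v_line / k
    if mode == "expression":
        ve = pool_n * components.v_within
    elif mode == "sleep":
        ve = components.v_within
    else:
        if components.v_rep is None:
            raise ValueError("bristle mode requires a replicate variance component")
        ve = components.v_within + components.v_rep
    if ve == 0:
        raise ValueError("environmental variance is zero")
    return MutationalParams(
        vm=vm, ve=ve, h2m=vm / ve, k=k, t=t, two_ne=two_ne, pool_n=pool_n
    )


def neutral_population_size(pi: float, mu: float) -> float:
    """Effective population size from nucleotide diversity: N = pi / (4 mu)."""
    if pi <= 0 or mu <= 0:
        raise ValueError("pi and mu must be positive")
    return pi / (4.0 * mu)


def ma_dosage_matrix(calls, line_ids: Sequence[str]) -> pd.DataFrame:
    """Mutant-allele dosage matrix (lines x mutations) from MA calls.

    Each call contributes one column: dosage ``2 * frequency`` in the mutant
    line (2 when fixed) and 0 elsewhere.
    """
    line_ids = list(line_ids)
    cols = {}
    for i, c in enumerate(calls):
        v = np.zeros(len(line_ids))
        v[line_ids.index(c.line_id)] = 2.0 * c.frequency
        cols[f"{c.chrom}:{c.pos}:{c.line_id}:{i}"] = v
    return pd.DataFrame(cols, index=pd.Index(line_ids, name="line"))


def sequence_variance_sum(
    dosage: pd.DataFrame | np.ndarray,
    k: float | None = None,
    below_cutoff_sampler: Callable[[int, np.random.Generator], np.ndarray] | None = None,
    n_below: int = 0,
    seed: int | None = None,
) -> float:
    """Sum over loci of the sample variance of mutant-allele dosage.

    ``dosage`` is lines x loci with entries in [0, 2].  In MA mode supply the
    drift correction ``k`` (the sum is divided by it) and, to account for
    mutations segregating below the detection cutoff, a sampler drawing
    ``n_below`` sub-cutoff frequencies from the expected drift distribution;
    each undetected mutation contributes the variance of a single-line dosage
    ``2f`` among the observed lines.
    """
    mat = np.asarray(dosage, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("dosage matrix needs >=2 lines")
    if (mat < 0).any() or (mat > 2).any():
        raise ValueError("dosages must lie in [0, 2]")
    total = float(mat.var(axis=0, ddof=1).sum()) if mat.shape[1] else 0.0
    if below_cutoff_sampler is not None and n_below > 0:
        rng = np.random.default_rng(seed)
        freqs = np.asarray(below_cutoff_sampler(n_below, rng), dtype=np.float64)
        n = mat.shape[0]
        # sample variance of one value 2f among n lines (rest 0) is (2f)^2 / n
        total += float(((2.0 * freqs) ** 2 / n).sum())
    if k is not None:
        if k <= 0:
            raise ValueError("k must be positive")
        total /= k
    return total


def selection_report(
    vm: float,
    vg: float,
    sum_var_m_over_k: float,
    sum_var_g: float,
    n_pop: float,
    mu: float,
    vs_multiplier: float,
    ve: float,
) -> SelectionReport:
    """Assemble the mutation-selection comparison for one trait.

    ``Vm/Vg`` is compared with the neutral expectation ``1/(4N)`` and with the
    sequence-based expectation ``sum Var(m_i)/k / sum Var(g_i)`` (their ratio
    is the effect-size ratio ``E(a_m^2)/E(a_g^2)``).  The pleiotropic model
    gives ``s = Vm/Vg``; the house-of-cards model gives the implied number of
    loci ``n = Vg / (4 mu Vs)`` with ``Vs = vs_multiplier * Ve``.
    """
    for name, v in (("vm", vm), ("vg", vg), ("sum_var_m_over_k", sum_var_m_over_k),
                    ("sum_var_g", sum_var_g), ("n_pop", n_pop), ("mu", mu),
                    ("vs_multiplier", vs_multiplier), ("ve", ve)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    vm_vg = vm / vg
    seq_ratio = sum_var_m_over_k / sum_var_g
    return SelectionReport(
        vg=vg,
        vm_vg=vm_vg,
        neutral_expectation=1.0 / (4.0 * n_pop),
        sequence_ratio=seq_ratio,
        effect_size_ratio=vm_vg / seq_ratio,
        s_pleiotropic=vm_vg,
        hoc_n_loci=vg / (4.0 * mu * vs_multiplier * ve),
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
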