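"""Historical demography from mismatch distributions and neutrality tests.

Implements the sudden-expansion mismatch machinery of Rogers & Harpending
(1992): the equilibrium distribution of pairwise differences
F_j(theta) = theta^j / (theta + 1)^(j+1), the transient distribution after
a stepwise change from theta0 to theta1 at tau mutational-time units ago,

    F_j(tau) = F_j(theta1)
             + exp(-tau (theta1 + 1)/theta1)
               * sum_{i=0..j} tau^(j-i)/(j-i)! * [F_i(theta0) - F_i(theta1)],

a bounded least-squares fit of (tau, theta0, theta1) minimising the sum of
squared deviations (SSD) from the observed mismatch, and the Schneider &
Excoffier parametric bootstrap for the SSD p-value. Harpending's (1994)
raggedness index and Fu's (1997) FS (via the Ewens sampling distribution of
the number of haplotypes) complete the expansion diagnostics; FS is tested
against neutral constant-size coalescent simulations conditioned on the
observed mean pairwise differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .seqio import Alignment, pairwise_differences
from . import synth

logger = logging.getLogger(__name__)


@dataclass
class MismatchDistribution:
    """Histogram of pairwise nucleotide-difference counts."""

    counts: np.ndarray  # counts per difference class 0..d_max

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("negative mismatch counts")
        if self.counts.sum() <= 0:
            raise ValueError("empty mismatch distribution")

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def mean(self) -> float:
        return float((np.arange(len(self.counts)) * self.freqs).sum())


@dataclass
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    p_ssd: float | None
    expected: np.ndarray
    converged: bool = True
    n_bootstrap: int = 0
    notes: list[str] = field(default_factory=list)


@dataclass
class NeutralityStats:
    raggedness: float
    fu_fs: float
    p_r: float | None
    p_fs: float | None
    n_sims: int
    flagged: bool = False
    notes: list[str] = field(default_factory=list)


def mismatch_observed(aln: Alignment) -> MismatchDistribution:
    """Histogram of all n(n-1)/2 pairwise difference counts."""
    if aln.n < 2:
        raise ValueError("mismatch distribution needs n >= 2")
    d = pairwise_differences(aln).values
    iu = np.triu_indices(aln.n, 1)
    diffs = d[iu].astype(int)
    counts = np.bincount(diffs)
    return MismatchDistribution(counts)


def equilibrium_mismatch(theta: float, d_max: int) -> np.ndarray:
    """Watterson/Li equilibrium F_j(theta) = theta^j/(theta+1)^(j+1)."""
    j = np.arange(d_max + 1)
    if theta == 0:
        out = np.zeros(d_max + 1)
        out[0] = 1.0
        return out
    return np.exp(j * np.log(theta) - (j + 1) * np.log(theta + 1.0))


def expected_mismatch(
    tau: float, theta0: float, theta1: float, d_max: int,
    renormalize: bool = True,
) -> np.ndarray:
    """Transient sudden-expansion mismatch distribution.

    Truncated at d_max; when ``renormalize`` the truncated mass is folded
    back proportionally (the deficit is logged at debug level).
    """
    for name, v in (("tau", tau), ("theta0", theta0), ("theta1", theta1)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0")
    f0 = equilibrium_mismatch(theta0, d_max)
    f1 = equilibrium_mismatch(theta1, d_max)
    if theta1 == 0:
        return f0
    diff = f0 - f1
    j = np.arange(d_max + 1)
    # sum_{i<=j} tau^(j-i)/(j-i)! * diff_i  == convolution with Poisson weights
    log_w = np.where(j > 0, j * np.log(tau) if tau > 0 else -np.inf, 0.0)
    with np.errstate(divide="ignore"):
        w = np.exp(log_w - [math.lgamma(k + 1) for k in j])
    if tau == 0:
        w = np.zeros(d_max + 1)
        w[0] = 1.0
    conv = np.convolve(w, diff)[: d_max + 1]
    f = f1 + math.exp(-tau * (theta1 + 1.0) / theta1) * conv
    f = np.clip(f, 0.0, None)
    total = f.sum()
    deficit = 1.0 - total
    logger.debug("expected_mismatch truncation deficit: %.3g", deficit)
    if renormalize and total > 0:
        f = f / total
    return f


def ssd(observed: np.ndarray, expected: np.ndarray) -> float:
    """Sum of squared deviations between two frequency vectors."""
    k = max(len(observed), len(expected))
    o = np.zeros(k)
    e = np.zeros(k)
    o[: len(observed)] = observed
    e[: len(expected)] = expected
    return float(((o - e) ** 2).sum())


def _fit_params(
    freqs: np.ndarray, d_max: int, n_starts: int, rng: np.random.Generator
) -> tuple[np.ndarray, float, bool]:
    mean_d = float((np.arange(len(freqs)) * freqs).sum())

    def objective(x):
        tau, th0, th1 = x
        return ssd(freqs, expected_mismatch(tau, th0, th1, d_max))

    hi_tau = max(2.0 * d_max, 5.0)
    hi_th = max(20.0 * max(mean_d, 1.0), 100.0)
    bounds = [(0.0, hi_tau), (0.0, hi_th), (1e-3, 1e5)]
    starts = [np.array([max(mean_d, 0.5), 0.5, max(10 * mean_d, 10.0)])]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(
            np.array(
                [
                    rng.uniform(0, min(hi_tau, 3 * mean_d + 5)),
                    rng.uniform(0, max(mean_d, 2.0)),
                    10 ** rng.uniform(0, 4),
                ]
            )
        )
    best_x, best_f, ok = None, np.inf, False
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds
        )
        if res.fun < best_f:
            best_x, best_f, ok = res.x, float(res.fun), bool(res.success)
    return best_x, best_f, ok


def fit_expansion(
    obs: MismatchDistribution,
    n: int | None = None,
    n_bootstrap: int = 1000,
    n_starts: int = 20,
    seed: int | None = 0,
) -> ExpansionFit:
    """Fit (tau, theta0, theta1) by bounded least squares, multi-start.

    When ``n`` (the sample size behind the mismatch) is given and
    ``n_bootstrap`` > 0, the SSD p-value is obtained by parametric
    bootstrap: simulate coalescent samples of size n under the fitted
    expansion, refit each, and compare simulated SSDs with the observed
    one (p = (#[SSD_sim >= SSD_obs] + 1)/(B + 1)).
    """
    rng = np.random.default_rng(seed)
    freqs = obs.freqs
    d_max = obs.d_max
    x, f, ok = _fit_params(freqs, d_max, n_starts, rng)
    tau, th0, th1 = (float(v) for v in x)
    notes = []
    if not ok:
        notes.append("optimizer did not report convergence; best point kept")
    if th1 < th0:
        notes.append("fitted theta1 < theta0 (contraction rather than expansion)")
    expected = expected_mismatch(tau, th0, th1, d_max)
    p_ssd = None
    b_done = 0
    if n is not None and n_bootstrap > 0:
        hits = 0
        refit_starts = min(n_starts, 6)
        for _ in range(n_bootstrap):
            counts = synth.expansion_mismatch_sample(n, tau, th0, th1, rng)
            sim = MismatchDistribution(counts)
            xs, fs_, _ = _fit_params(sim.freqs, sim.d_max, refit_starts, rng)
            if fs_ >= f:
                hits += 1
        b_done = n_bootstrap
        p_ssd = (hits + 1) / (n_bootstrap + 1)
    return ExpansionFit(
        tau=tau, theta0=th0, theta1=th1, ssd=f, p_ssd=p_ssd,
        expected=expected, converged=ok, n_bootstrap=b_done, notes=notes,
    )


def raggedness(obs: MismatchDistribution) -> float:
    """Harpending's raggedness r = sum_{i=1..d+1} (x_i - x_{i-1})^2.

    The boundary class x_{d+1} = 0, d = largest observed difference class.
    Smooth unimodal distributions give small r; multi-peaked ones large r.
    """
    x = np.append(obs.freqs, 0.0)
    return float((np.diff(x) ** 2).sum())


def ewens_k_pmf(n: int, theta: float) -> np.ndarray:
    """P(K = k), k = 1..n, haplotypes in a sample of n under the Ewens
    sampling distribution with scaled diversity theta.

    Uses the representation of K as a sum of independent Bernoulli
    variables with success probabilities theta/(theta + i), i = 0..n-1
    (a Poisson-binomial convolution), which is numerically exact.
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    pmf = np.array([1.0])  # K = 1 contribution from i = 0 (prob 1)
    for i in range(1, n):
        q = theta / (theta + i)
        new = np.zeros(len(pmf) + 1)
        new[: len(pmf)] += pmf * (1.0 - q)
        new[1:] += pmf * q
        pmf = new
    return pmf  # index k-1 -> P(K = k)


def fu_fs_statistic(n: int, k_obs: int, theta: float) -> float:
    """FS = ln(S'/(1 - S')) with S' = P(K >= k_obs | theta, n)."""
    if n < 3:
        raise ValueError("Fu's FS needs n >= 3")
    if theta <= 0:
        raise ValueError("FS undefined for monomorphic samples (theta = 0)")
    pmf = ewens_k_pmf(n, theta)
    s_ge = float(pmf[k_obs - 1 :].sum())
    s_lt = float(pmf[: k_obs - 1].sum())
    if s_lt == 0.0 or s_ge == 0.0:
        raise FloatingPointError("S' at the boundary; FS infinite")
    return float(np.log(s_ge) - np.log(s_lt))


def fu_fs(
    aln: Alignment, n_sims: int = 1000, seed: int | None = 0
) -> NeutralityStats:
    """Fu's FS with its coalescent p-value.

    theta-hat is the mean pairwise difference per sequence (Fu's original
    choice). The null distribution comes from neutral constant-size
    coalescent simulations conditioned on theta-hat; p_fs is the fraction
    of simulations with FS_sim <= FS_obs (expansion pushes FS negative).
    """
    n = aln.n
    if n < 3:
        raise ValueError("Fu's FS needs n >= 3")
    d = pairwise_differences(aln).values
    iu = np.triu_indices(n, 1)
    theta_hat = float(d[iu].mean())
    k_obs = len(set(aln.seqs))
    if theta_hat <= 0 or k_obs == 1:
        return NeutralityStats(
            raggedness=np.nan, fu_fs=np.nan, p_r=None, p_fs=None,
            n_sims=0, flagged=True,
            notes=["monomorphic sample: FS undefined"],
        )
    try:
        fs_obs = fu_fs_statistic(n, k_obs, theta_hat)
    except FloatingPointError:
        return NeutralityStats(
            raggedness=np.nan, fu_fs=np.inf, p_r=None, p_fs=None,
            n_sims=0, flagged=True,
            notes=["S' at boundary (k = 1): FS infinite, flagged"],
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        k_sim, pi_sim = synth.neutral_summary(n, theta_hat, rng)
        if pi_sim <= 0 or k_sim == 1:
            fs_sim = np.inf  # monomorphic: maximally 'non-expanded'
        else:
            try:
                fs_sim = fu_fs_statistic(n, k_sim, pi_sim)
            except FloatingPointError:
                fs_sim = -np.inf if k_sim == n else np.inf
        if fs_sim <= fs_obs:
            hits += 1
    p_fs = (hits + 1) / (n_sims + 1)
    return NeutralityStats(
        raggedness=np.nan, fu_fs=fs_obs, p_r=None, p_fs=p_fs, n_sims=n_sims
    )


def demography_analysis(
    aln: Alignment,
    n_bootstrap: int = 1000,
    n_sims: int = 1000,
    n_starts: int = 20,
    seed: int | None = 0,
) -> tuple[MismatchDistribution, ExpansionFit, NeutralityStats]:
    """Mismatch fit + raggedness + Fu's FS for one pooled sample.

    The raggedness p-value shares the expansion fit's parametric bootstrap
    (r is recomputed on each simulated sample).
    """
    obs = mismatch_observed(aln)
    rng = np.random.default_rng(seed)
    freqs = obs.freqs
    x, f, ok = _fit_params(freqs, obs.d_max, n_starts, rng)
    tau, th0, th1 = (float(v) for v in x)
    r_obs = raggedness(obs)
    hits_ssd = hits_r = 0
    refit_starts = min(n_starts, 6)
    for _ in range(n_bootstrap):
        counts = synth.expansion_mismatch_sample(aln.n, tau, th0, th1, rng)
        sim = MismatchDistribution(counts)
        _, fs_, _ = _fit_params(sim.freqs, sim.d_max, refit_starts, rng)
        if fs_ >= f:
            hits_ssd += 1
        if raggedness(sim) >= r_obs:
            hits_r += 1
    p_ssd = (hits_ssd + 1) / (n_bootstrap + 1) if n_bootstrap else None
    p_r = (hits_r + 1) / (n_bootstrap + 1) if n_bootstrap else None
    fit = ExpansionFit(
        tau=tau, theta0=th0, theta1=th1, ssd=f, p_ssd=p_ssd,
        expected=expected_mismatch(tau, th0, th1, obs.d_max),
        converged=ok, n_bootstrap=n_bootstrap,
    )
    neut = fu_fs(aln, n_sims=n_sims, seed=None if seed is None else seed + 1)
    neut.raggedness = r_obs
    neut.p_r = p_r
    return obs, fit, neut


def demography_table(
    aln: Alignment, meta, n_bootstrap: int = 1000, n_sims: int = 1000,
    n_starts: int = 20, seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-area expansion diagnostics plus observed/expected mismatch curves.

    Mismatch distributions are computed on individual sequences (not
    collapsed haplotypes) pooled by biogeographical area.
    """
    meta = meta.aligned_to(aln)
    areas = meta.areas
    area_series = meta.table["area"]
    rows, curves = [], []
    for i, area in enumerate(areas):
        idx = list(np.flatnonzero(area_series == area))
        sub = aln.subset(idx)
        s = None if seed is None else seed + 101 * i
        obs, fit, neut = demography_analysis(
            sub, n_bootstrap=n_bootstrap, n_sims=n_sims,
            n_starts=n_starts, seed=s,
        )
        rows.append(
            {
                "area": area, "n": sub.n,
                "tau": fit.tau, "theta0": fit.theta0, "theta1": fit.theta1,
                "SSD": fit.ssd, "p_SSD": fit.p_ssd,
                "r": neut.raggedness, "p_r": neut.p_r,
                "FS": neut.fu_fs, "p_FS": neut.p_fs,
            }
        )
        for j, (o, e) in enumerate(zip(obs.freqs, fit.expected)):
            curves.append(
                {"area": area, "differences": j, "observed": o, "expected": e}
            )
    return pd.DataFrame(rows), pd.DataFrame(curves)
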