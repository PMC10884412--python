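"""Copy-number-stratified selection inference.

Machinery: the Poisson-random-field expected site-frequency spectrum for
a mutation of scaled selection coefficient S (density per population
frequency q of theta * (1 - e^{-S(1-q)}) / ((1 - e^{-S}) q (1 - q)),
binomially sampled to n chromosomes and folded), a gamma distribution of
deleterious |Nes| fitted to the zero-fold folded SFS by maximum Poisson
likelihood with four-fold sites fixing the neutral theta, and the
derived quantities: |Nes| bin proportions, the adaptive proportion of
nonsynonymous divergence alpha, the adaptive rate omega_a, the fixation
index FI = (Dn/Ds)/(Pn/Ps), log-ratio constraint/selection effects, a
by-gene bootstrap, and pairwise two-tailed t contrasts between retention
classes.

Demography is deliberately constant-size: the simulator that feeds the
recovery tests makes the same assumption, so parameter recovery is
internally consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "SelectionInput",
    "DFEFit",
    "AdaptiveEstimate",
    "MKStats",
    "NES_BINS",
    "fold_sfs",
    "neutral_folded_sfs",
    "expected_folded_sfs",
    "dfe_expected_folded_sfs",
    "dfe_fixation_factor",
    "fit_gamma_dfe",
    "estimate_alpha_omega_a",
    "fixation_index",
    "snipre_like_effects",
    "bootstrap_by_gene",
    "compare_retention_classes",
]

#: |Nes| bin edges, reported on the conventional negative scale
#: (0,-1), (-1,-10), (-10,-100), (-100,-inf)
NES_BINS = ((0.0, 1.0), (1.0, 10.0), (10.0, 100.0), (100.0, math.inf))


@dataclass
class SelectionInput:
    """Per-copy-class selection data: per-gene site and count table plus
    per-gene folded SFS contributions (genes x folded classes)."""

    copy_class: int
    n_chrom: int
    genes: pd.DataFrame  # gene, L0, L4, Pn, Ps, Dn, Ds
    sfs_zero: np.ndarray
    sfs_four: np.ndarray
    true_params: dict | None = None

    def __post_init__(self):
        self.sfs_zero = np.atleast_2d(np.asarray(self.sfs_zero, float))
        self.sfs_four = np.atleast_2d(np.asarray(self.sfs_four, float))
        k = self.n_chrom // 2
        if self.sfs_zero.shape[1] != k or self.sfs_four.shape[1] != k:
            raise ValueError(f"folded SFS needs {k} classes for "
                             f"n_chrom={self.n_chrom}")
        if (self.sfs_zero < 0).any() or (self.sfs_four < 0).any():
            raise ValueError("negative SFS counts")

    @property
    def pooled_zero(self) -> np.ndarray:
        return self.sfs_zero.sum(axis=0)

    @property
    def pooled_four(self) -> np.ndarray:
        return self.sfs_four.sum(axis=0)

    def totals(self) -> dict:
        g = self.genes
        return {k: float(g[k].sum()) for k in ("L0", "L4", "Pn", "Ps",
                                               "Dn", "Ds")}

    def resample(self, rng: np.random.Generator) -> "SelectionInput":
        idx = rng.integers(0, len(self.genes), size=len(self.genes))
        return SelectionInput(
            copy_class=self.copy_class, n_chrom=self.n_chrom,
            genes=self.genes.iloc[idx].reset_index(drop=True),
            sfs_zero=self.sfs_zero[idx], sfs_four=self.sfs_four[idx],
            true_params=self.true_params)


@dataclass
class DFEFit:
    shape: float
    mean_nes: float
    theta_ns: float
    bin_props: tuple[float, ...]
    loglik: float
    converged: bool
    n_chrom: int


@dataclass
class AdaptiveEstimate:
    alpha: float
    omega_a: float
    bootstrap_alpha: np.ndarray = field(
        default_factory=lambda: np.array([]))
    bootstrap_omega_a: np.ndarray = field(
        default_factory=lambda: np.array([]))


@dataclass
class MKStats:
    fi: float | None
    corrected: bool
    constraint_effect: float
    selection_effect: float


# --------------------------------------------------------------------------
# expected SFS machinery


@lru_cache(maxsize=8)
def _q_grid(n_quad: int):
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    q = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    return q, w


@lru_cache(maxsize=32)
def _binom_matrix(n_chrom: int, n_quad: int):
    q, w = _q_grid(n_quad)
    i = np.arange(1, n_chrom)
    logb = (special.gammaln(n_chrom + 1) - special.gammaln(i + 1)
            - special.gammaln(n_chrom - i + 1))
    lp = (logb[:, None] + i[:, None] * np.log(q)[None, :]
          + (n_chrom - i)[:, None] * np.log1p(-q)[None, :])
    return np.exp(lp)  # (n-1, n_quad)


def _log_expm1(x: np.ndarray) -> np.ndarray:
    """log(e^x - 1), stable for large and small positive x."""
    x = np.asarray(x, float)
    out = np.empty_like(x)
    small = x < 30.0
    with np.errstate(divide="ignore"):
        out[small] = np.log(np.expm1(x[small]))
    out[~small] = x[~small]
    return out


def _sfs_density(q: np.ndarray, s) -> np.ndarray:
    """PRF frequency density (theta = 1) for scaled coefficients ``s``
    (array, negative = deleterious); rows index s, columns q."""
    s = np.atleast_1d(np.asarray(s, float))[:, None]
    q = q[None, :]
    out = np.empty((s.shape[0], q.shape[1]))
    tiny = np.abs(s[:, 0]) < 1e-8
    if tiny.any():
        out[tiny] = (1.0 / q) * (1.0 + s[tiny] * q / 2.0)
    big = ~tiny
    if big.any():
        sb = s[big]
        res = np.empty((sb.shape[0], q.shape[1]))
        neg = sb[:, 0] < 0
        if neg.any():
            # deleterious: (e^{t(1-q)} - 1)/((e^t - 1) q(1-q)), t = -s > 0,
            # computed in log space to survive very large t
            t = -sb[neg]
            lognum = _log_expm1(t * (1.0 - q))
            logden = _log_expm1(t)
            res[neg] = np.exp(lognum - logden) / (q * (1.0 - q))
        if (~neg).any():
            sp = sb[~neg]
            res[~neg] = (-np.expm1(-sp * (1.0 - q))) \
                / ((-np.expm1(-sp)) * q * (1.0 - q))
        out[big] = res
    return out


def expected_folded_sfs(s: float, theta: float, n_chrom: int,
                        n_quad: int = 400) -> np.ndarray:
    """Expected folded SFS counts (classes 1..n_chrom//2) for scaled
    selection s (negative = deleterious) and scaled mutation rate theta
    (per locus). Continuous in s at 0; the s = 0 limit is the neutral
    theta/i spectrum."""
    if n_chrom < 2:
        raise ValueError("n_chrom must be >= 2")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    unfolded = _expected_unfolded(np.array([s]), n_chrom, n_quad)[0]
    return theta * fold_sfs(unfolded, n_chrom)


def _expected_unfolded(s: np.ndarray, n_chrom: int,
                       n_quad: int = 400) -> np.ndarray:
    """Expected unfolded SFS (theta = 1) for an array of s values;
    rows index s, columns classes 1..n-1."""
    q, w = _q_grid(n_quad)
    b = _binom_matrix(n_chrom, n_quad)  # (n-1, M)
    f = _sfs_density(q, s)              # (len(s), M)
    return f @ (b * w[None, :]).T       # (len(s), n-1)


def fold_sfs(unfolded: np.ndarray, n_chrom: int) -> np.ndarray:
    """Fold an unfolded SFS (classes 1..n-1) into minor-allele classes
    1..n//2; the middle class at even n is counted once."""
    unfolded = np.asarray(unfolded, float)
    if unfolded.shape[-1] != n_chrom - 1:
        raise ValueError(f"unfolded SFS needs {n_chrom - 1} classes")
    k = n_chrom // 2
    out = np.empty(unfolded.shape[:-1] + (k,))
    for i in range(1, k + 1):
        j = n_chrom - i
        if j == i:
            out[..., i - 1] = unfolded[..., i - 1]
        else:
            out[..., i - 1] = unfolded[..., i - 1] + unfolded[..., j - 1]
    return out


def neutral_folded_sfs(theta: float, n_chrom: int) -> np.ndarray:
    """Watterson folded spectrum: theta * (1/i + 1/(n-i)), middle class
    once."""
    i = np.arange(1, n_chrom)
    return theta * fold_sfs(1.0 / i, n_chrom)


# --------------------------------------------------------------------------
# gamma DFE


@lru_cache(maxsize=8)
def _loggrid(n_nodes: int):
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    return nodes, weights


def _gamma_nodes(shape: float, mean: float, n_nodes: int = 200):
    """Quadrature nodes/weights for E_g[h(g)] with g ~ Gamma(shape,
    scale=mean/shape): Gauss-Legendre on log g between extreme gamma
    quantiles. Robust across the many orders of magnitude a wide |Nes|
    gamma spans (plain Gauss-Laguerre fails when scale >> 1)."""
    scale = mean / shape
    lo = stats.gamma.ppf(1e-12, shape, scale=scale)
    hi = stats.gamma.isf(1e-12, shape, scale=scale)
    lo = max(lo, 1e-300)
    a, b = math.log(lo), math.log(hi)
    x, w = _loggrid(n_nodes)
    u = 0.5 * (b - a) * x + 0.5 * (a + b)
    g = np.exp(u)
    dens = stats.gamma.pdf(g, shape, scale=scale) * g  # d(g)/d(log g)
    weights = 0.5 * (b - a) * w * dens
    return g, weights


def dfe_expected_folded_sfs(shape: float, mean_nes: float, theta: float,
                            n_chrom: int, n_nodes: int = 200,
                            n_quad: int = 400) -> np.ndarray:
    """Expected folded SFS mixing the PRF spectrum over a gamma DFE of
    deleterious |Nes| (theta per locus)."""
    g, w = _gamma_nodes(shape, mean_nes, n_nodes)
    unfolded = _expected_unfolded(-g, n_chrom, n_quad)  # (K, n-1)
    mixed = w @ unfolded
    return theta * fold_sfs(mixed, n_chrom)


def dfe_fixation_factor(shape: float, mean_nes: float,
                        n_nodes: int = 200) -> float:
    """Relative fixation rate of new mutations under the gamma DFE:
    E[S / (1 - e^{-S})] with S = -|Nes|, i.e. E[g / (e^g - 1)];
    equals 1 for a point mass at 0, -> 0 for strongly deleterious."""
    if mean_nes <= 0:
        return 1.0
    g, w = _gamma_nodes(shape, mean_nes, n_nodes)
    with np.errstate(over="ignore"):
        h = np.where(g < 1e-8, 1.0 - g / 2.0, g / np.expm1(g))
    return float(w @ h)


def gamma_bin_props(shape: float, mean_nes: float) -> tuple[float, ...]:
    """Mass of the fitted gamma in the |Nes| bins (0,1), (1,10),
    (10,100), (100,inf)."""
    scale = mean_nes / shape
    cdf = [stats.gamma.cdf(hi, shape, scale=scale) if math.isfinite(hi)
           else 1.0 for _, hi in NES_BINS]
    lo_cdf = [stats.gamma.cdf(lo, shape, scale=scale) for lo, _ in NES_BINS]
    return tuple(float(c - l) for c, l in zip(cdf, lo_cdf))


def _fit_theta_neutral(sfs_four: np.ndarray, n_chrom: int) -> float:
    """Poisson MLE of the neutral per-locus theta from the four-fold
    folded SFS."""
    coeff = fold_sfs(1.0 / np.arange(1, n_chrom), n_chrom)
    return float(sfs_four.sum() / coeff.sum())


_DEFAULT_STARTS = ((0.2, 10.0), (0.5, 100.0), (1.0, 1000.0),
                   (0.3, 2000.0), (0.8, 50.0))


def fit_gamma_dfe(sel: SelectionInput, n_starts: int = 5,
                  n_nodes: int = 200, n_quad: int = 400,
                  theta_mode: str = "tied") -> DFEFit:
    """Maximum-Poisson-likelihood gamma DFE fit to the zero-fold folded
    SFS. The four-fold SFS fixes the neutral per-site theta; in the
    default ``tied`` mode the nonsynonymous mutation rate per site is
    the same, so theta_ns = theta_syn * (L0/L4) — this is what makes the
    strongly-deleterious mass identifiable (mutations that never
    segregate leave a deficit against the tied rate). ``theta_mode='free'``
    profiles theta_ns out as the Poisson scale MLE instead. Multi-start
    Nelder-Mead on log parameters; ties resolved by best log-likelihood
    then smallest shape."""
    if theta_mode not in ("tied", "free"):
        raise ValueError("theta_mode must be 'tied' or 'free'")
    obs = sel.pooled_zero
    syn = sel.pooled_four
    if obs.size < 2:
        raise ValueError("need >= 2 folded classes")
    if syn.sum() <= 0:
        raise ValueError("empty synonymous SFS")
    n = sel.n_chrom
    t = sel.totals()
    theta_syn = _fit_theta_neutral(syn, n)
    theta_tied = theta_syn * t["L0"] / t["L4"]

    def unit_spectrum(shape, mean):
        g, w = _gamma_nodes(shape, mean, n_nodes)
        unfolded = _expected_unfolded(-g, n, n_quad)
        return fold_sfs(w @ unfolded, n)

    def negll(logp):
        shape = math.exp(logp[0])
        mean = math.exp(logp[1])
        if not (1e-2 < shape < 1e2 and 1e-4 < mean < 1e8):
            return 1e12
        unit = unit_spectrum(shape, mean)
        tot = unit.sum()
        if not np.isfinite(tot) or tot <= 0:
            return 1e12
        theta_ns = theta_tied if theta_mode == "tied" \
            else obs.sum() / tot
        lam = np.maximum(theta_ns * unit, 1e-300)
        ll = float(stats.poisson.logpmf(np.round(obs), lam).sum())
        return -ll if np.isfinite(ll) else 1e12

    starts = _DEFAULT_STARTS[:max(n_starts, 1)]
    fits = []
    for s0, m0 in starts:
        res = optimize.minimize(
            negll, np.log([s0, m0]), method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 2000})
        fits.append(res)
    best = min(fits, key=lambda r: (r.fun, math.exp(r.x[0])))
    if not any(r.success for r in fits):
        raise RuntimeError(
            f"gamma DFE fit did not converge after {len(starts)} starts; "
            f"best loglik {-best.fun:.3f} at shape="
            f"{math.exp(best.x[0]):.3g}, mean={math.exp(best.x[1]):.3g}")
    shape = math.exp(best.x[0])
    mean = math.exp(best.x[1])
    if theta_mode == "tied":
        theta_ns = float(theta_tied)
    else:
        unit = unit_spectrum(shape, mean)
        theta_ns = float(obs.sum() / unit.sum())
    return DFEFit(shape=shape, mean_nes=mean, theta_ns=theta_ns,
                  bin_props=gamma_bin_props(shape, mean),
                  loglik=-float(best.fun), converged=True, n_chrom=n)


def estimate_alpha_omega_a(fit: DFEFit, sel: SelectionInput,
                           n_boot: int = 200,
                           rng: np.random.Generator | None = None,
                           boot_starts: int = 2) -> AdaptiveEstimate:
    """Adaptive divergence under the fitted DFE.

    Expected non-adaptive nonsynonymous divergence is Ds * (L0/L4) *
    E[S/(1-e^{-S})]; alpha = (Dn - E[Dn_na]) / Dn and omega_a =
    alpha * (Dn/L0) / (Ds/L4). The bootstrap resamples genes with
    replacement, re-pools SFS and counts, and refits the DFE per
    replicate (200 by default).
    """
    tot = sel.totals()
    if tot["Ds"] <= 0 or tot["Dn"] <= 0:
        raise ValueError("alpha undefined: zero divergence counts")

    def point(f: DFEFit, t: dict) -> tuple[float, float]:
        fix = dfe_fixation_factor(f.shape, f.mean_nes)
        dn_na = t["Ds"] * (t["L0"] / t["L4"]) * fix
        alpha = (t["Dn"] - dn_na) / t["Dn"]
        omega_a = alpha * (t["Dn"] / t["L0"]) / (t["Ds"] / t["L4"])
        return alpha, omega_a

    alpha, omega_a = point(fit, tot)
    boots_a, boots_w = [], []
    if n_boot > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        for _ in range(n_boot):
            rs = sel.resample(rng)
            t = rs.totals()
            if t["Ds"] <= 0 or t["Dn"] <= 0 or rs.pooled_four.sum() <= 0:
                continue
            try:
                f = fit_gamma_dfe(rs, n_starts=boot_starts)
            except RuntimeError:
                continue
            a, w = point(f, t)
            boots_a.append(a)
            boots_w.append(w)
    return AdaptiveEstimate(alpha=float(alpha), omega_a=float(omega_a),
                            bootstrap_alpha=np.array(boots_a),
                            bootstrap_omega_a=np.array(boots_w))


# --------------------------------------------------------------------------
# MK statistics


def fixation_index(dn: float, ds: float, pn: float,
                   ps: float) -> MKStats | tuple[float, bool]:
    """FI = (Dn/Ds)/(Pn/Ps); 0.5 added to every cell when any cell is
    zero. Returns (fi, corrected); all-zero input is undefined."""
    cells = [dn, ds, pn, ps]
    if any(c < 0 for c in cells):
        raise ValueError("negative MK counts")
    if all(c == 0 for c in cells):
        return (None, True)
    corrected = any(c == 0 for c in cells)
    if corrected:
        dn, ds, pn, ps = (c + 0.5 for c in cells)
    return ((dn / ds) / (pn / ps), corrected)


def snipre_like_effects(dn: float, ds: float, pn: float, ps: float,
                        l0: float, l4: float) -> tuple[float, float]:
    """Closed-form log-ratio surrogates for constraint and selection
    effects (0.5 added unconditionally):

    constraint = ln((Pn+.5)/(Ps+.5)) - ln(L0/L4)  (< 0: purifying)
    selection  = ln((Dn+.5)/(Ds+.5)) - ln((Pn+.5)/(Ps+.5))  (> 0: excess
    nonsynonymous fixation)
    """
    if l0 <= 0 or l4 <= 0:
        raise ValueError("site counts must be positive")
    constraint = math.log((pn + 0.5) / (ps + 0.5)) - math.log(l0 / l4)
    selection = math.log((dn + 0.5) / (ds + 0.5)) \
        - math.log((pn + 0.5) / (ps + 0.5))
    return constraint, selection


def bootstrap_by_gene(sel: SelectionInput, statistic, n_reps: int = 200,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Generic by-gene bootstrap: resample genes with replacement,
    re-pool, and evaluate ``statistic(SelectionInput)`` per replicate."""
    if len(sel.genes) < 2:
        raise ValueError("need >= 2 genes to bootstrap")
    if rng is None:
        rng = np.random.default_rng(0)
    return np.array([statistic(sel.resample(rng)) for _ in range(n_reps)])


def compare_retention_classes(samples: dict) -> pd.DataFrame:
    """Pairwise two-tailed t tests between per-class statistic samples,
    with star annotations at 0.05 (*) and 0.001 (***)."""
    keys = sorted(samples)
    rows = []
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            xa = np.asarray(samples[a], float)
            xb = np.asarray(samples[b], float)
            if xa.size < 2 or xb.size < 2:
                raise ValueError("need >= 2 values per class")
            degenerate = xa.std() == 0 and xb.std() == 0
            if degenerate and np.allclose(xa.mean(), xb.mean()):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(xa, xb)
            stars = "***" if p < 0.001 else ("*" if p < 0.05 else "")
            rows.append((a, b, float(t), float(p), stars, degenerate))
    return pd.DataFrame(rows, columns=["class_a", "class_b", "t", "p",
                                       "stars", "degenerate"])
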