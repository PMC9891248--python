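"""Automatic selection of the penalty weight rho from UMI abundances.

The observed exact-match read count of a true UMI is modeled as a
Galton-Watson branching process modified for sequencing: a founder molecule
undergoes ``cycles`` rounds of PCR in which every copy duplicates
independently with per-cycle efficiency lambda, the amplified copies are
thinned binomially by the read-sampling rate, and each sequenced copy
escapes its UMI's exact-match count (through a PCR or sequencing error
anywhere in the read) with probability ``error_escape``. The two thinning
stages compose into a single effective Bernoulli keep-probability
``sample_rate * (1 - error_escape)``, so only that product is identifiable
from abundance data; ``error_escape`` is therefore held fixed during
fitting.

The model is fit to the observed candidate-UMI abundance distribution by
minimizing the Kolmogorov-Smirnov statistic after right-truncating the long
tail caused by UMI collisions, and rho is the fifth percentile of the
fitted count distribution conditional on detection (count >= 1): molecules
amplified less than that are indistinguishable from error at the chosen
operating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import binom

logger = logging.getLogger(__name__)

#: exact generating-function evaluation is used up to this many cycles
#: (the pmf support is 2^cycles); beyond it we fall back to Monte Carlo
_MAX_EXACT_CYCLES = 14
_MIN_UMIS = 20


def _check_ranges(efficiency: float, cycles: int, sample_rate: float, error_escape: float) -> None:
    if not (0.0 <= efficiency <= 1.0):
        raise ValueError("efficiency must be in [0, 1]")
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    if not (0.0 < sample_rate <= 1.0):
        raise ValueError("sample_rate must be in (0, 1]")
    if not (0.0 <= error_escape < 1.0):
        raise ValueError("error_escape must be in [0, 1)")


def _gw_copy_pmf(efficiency: float, cycles: int) -> np.ndarray:
    """Exact pmf of the copy number of one founder after ``cycles`` rounds.

    Computed by composing the per-cycle offspring pgf g(z) = z(1-lam+lam*z)
    with itself: F_c(z) = F_{c-1}(g(z)), carried as polynomial coefficients
    (F[m] = P(copies = m)).
    """
    g = np.array([0.0, 1.0 - efficiency, efficiency])
    F = np.array([0.0, 1.0])  # pgf of a single starting molecule: z
    for _ in range(cycles):
        # Horner evaluation of F at the polynomial g
        res = np.array([F[-1]])
        for coef in F[-2::-1]:
            res = np.convolve(res, g)
            res[0] += coef
        F = res
    return F


def _thin_pmf(copy_pmf: np.ndarray, keep_prob: float, max_count: int) -> np.ndarray:
    """pmf of Binomial(copies, keep_prob) marginalized over the copy pmf."""
    ms = np.flatnonzero(copy_pmf > 0)
    ks = np.arange(max_count + 1)
    mat = binom.pmf(ks[:, None], ms[None, :], keep_prob)  # (max+1, M)
    return mat @ copy_pmf[ms]


def branching_pmf(
    efficiency: float,
    cycles: int,
    sample_rate: float,
    error_escape: float = 0.0,
    max_count: int = 200,
    method: str = "auto",
    rng: np.random.Generator | None = None,
    n_mc: int = 200_000,
) -> np.ndarray:
    """Distribution of the observed exact-match read count of one founder.

    ``method`` is "exact" (generating functions), "mc" (Monte Carlo, needs
    ``rng``), or "auto" (exact when the cycle count allows it). The returned
    array covers counts 0..max_count and is renormalized; choose max_count
    large enough that the truncated tail is negligible.
    """
    _check_ranges(efficiency, cycles, sample_rate, error_escape)
    if max_count < 1:
        raise ValueError("max_count must be >= 1")
    keep = sample_rate * (1.0 - error_escape)
    if method == "auto":
        method = "exact" if cycles <= _MAX_EXACT_CYCLES else "mc"
    if method == "exact":
        if cycles > _MAX_EXACT_CYCLES:
            raise ValueError("too many cycles for exact evaluation; use method='mc'")
        pmf = _thin_pmf(_gw_copy_pmf(efficiency, cycles), keep, max_count)
    elif method == "mc":
        rng = rng if rng is not None else np.random.default_rng(0)
        m = np.ones(n_mc, dtype=np.int64)
        for _ in range(cycles):
            m += rng.binomial(m, efficiency)
        x = rng.binomial(m, keep)
        pmf = np.bincount(np.minimum(x, max_count), minlength=max_count + 1).astype(float)
        pmf /= pmf.sum()
    else:
        raise ValueError(f"unknown method {method!r}")
    total = pmf.sum()
    if total < 1.0 - 1e-6:
        logger.debug("branching pmf truncated %.3g of its mass at max_count=%d",
                     1.0 - total, max_count)
    return pmf / total


@dataclass
class BranchingFit:
    """Fitted branching model for the observed UMI abundance distribution."""

    efficiency: float
    cycles: int
    sample_rate: float
    error_escape: float
    ks_stat: float
    fitted_pmf: np.ndarray  # counts 0..max, sums to one

    def conditional_cdf(self) -> np.ndarray:
        """CDF over counts >= 1, conditional on detection."""
        p = self.fitted_pmf[1:]
        return np.cumsum(p) / p.sum()


def truncate_abundances(abundances: np.ndarray, truncate_quantile: float) -> np.ndarray:
    """Drop the ceil((1 - q) * N) largest abundances (collision-driven tail)."""
    a = np.sort(np.asarray(abundances))
    n_drop = int(np.ceil((1.0 - truncate_quantile) * len(a) - 1e-9))
    return a[: len(a) - n_drop] if n_drop > 0 else a


def _ks_statistic(pmf: np.ndarray, kept: np.ndarray, lo: int = 1) -> float:
    """Sup distance between the model CDF conditional on the truncated
    support [lo, max(kept)] and the empirical CDF of the kept abundances.

    Observed candidate-UMI abundances are at least one, so the model is
    conditioned on detection (lo=1); calibration data that include
    zero counts are compared unconditionally (lo=0), which restores the
    identifiability of the amplification efficiency.
    """
    kept = np.sort(kept)
    xmax = int(kept.max())
    p = pmf[lo : xmax + 1].copy()
    total = p.sum()
    if total <= 0:
        return 1.0
    model_cdf = np.cumsum(p) / total
    emp_cdf = np.searchsorted(kept, np.arange(lo, xmax + 1), side="right") / len(kept)
    return float(np.abs(model_cdf - emp_cdf).max())


def fit_branching(
    umi_abundances,
    truncate_quantile: float = 0.95,
    cycles: int = 10,
    error_escape: float = 0.0,
    efficiency_grid: np.ndarray | None = None,
    seed: int = 0,
) -> BranchingFit:
    """Fit (efficiency, effective keep rate) by KS minimization.

    Grid search over efficiency crossed with a multiplicative grid of keep
    rates centered on the method-of-moments value, followed by a local
    refinement of the keep rate at the best efficiency. Deterministic given
    the seed (the seed only matters for cycle counts requiring Monte Carlo).
    """
    abundances = np.asarray(umi_abundances, dtype=np.int64)
    if len(abundances) < _MIN_UMIS:
        raise ValueError(
            f"need at least {_MIN_UMIS} candidate UMIs to fit the abundance model; "
            "supply rho manually (--rho)"
        )
    kept = truncate_abundances(abundances, truncate_quantile)
    lo = 0 if (kept == 0).any() else 1
    xmax = int(kept.max())
    max_count = max(2 * xmax, 10)
    mean_kept = float(kept.mean())
    if efficiency_grid is None:
        efficiency_grid = np.arange(0.05, 1.0001, 0.05)
    rng = np.random.default_rng(seed)

    def pmf_for(lam: float, keep: float) -> np.ndarray:
        return branching_pmf(
            lam, cycles, min(keep, 1.0), 0.0, max_count=max_count, rng=rng
        )

    best = (np.inf, None, None)
    for lam in efficiency_grid:
        copy_mean = (1.0 + lam) ** cycles
        keep0 = min(mean_kept / copy_mean, 1.0)
        for factor in np.exp(np.linspace(-1.5, 1.5, 13)):
            keep = min(keep0 * factor, 1.0)
            ks = _ks_statistic(pmf_for(lam, keep), kept, lo)
            if ks < best[0]:
                best = (ks, float(lam), keep)
    ks_best, lam_best, keep_best = best
    # local refinement of the keep rate (only ever improves on the grid)
    res = minimize_scalar(
        lambda lk: _ks_statistic(pmf_for(lam_best, float(np.exp(lk))), kept, lo),
        bracket=None,
        bounds=(np.log(keep_best) - 0.7, min(np.log(keep_best) + 0.7, 0.0)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    if res.fun < ks_best:
        ks_best, keep_best = float(res.fun), float(np.exp(res.x))
    pmf = pmf_for(lam_best, keep_best)
    return BranchingFit(
        efficiency=lam_best,
        cycles=cycles,
        sample_rate=keep_best / (1.0 - error_escape),
        error_escape=error_escape,
        ks_stat=ks_best,
        fitted_pmf=pmf,
    )


def select_rho(fit: BranchingFit, percentile: float = 0.05, override: int | None = None) -> int:
    """Fifth percentile of the fitted count distribution given detection.

    The smallest count x >= 1 with CDF(x | count >= 1) >= percentile;
    always at least 1. ``override`` short-circuits the rule (manual rho).
    """
    if override is not None:
        return int(override)
    cdf = fit.conditional_cdf()
    idx = int(np.searchsorted(cdf, percentile - 1e-12, side="left"))
    return max(1, idx + 1)


def fit_cdf_table(fit: BranchingFit, abundances) -> "np.ndarray":
    """Fitted-vs-empirical CDF pairs for plotting/diagnostics (counts >= 1)."""
    import pandas as pd

    a = np.sort(np.asarray(abundances))
    xmax = int(a.max())
    pmf = fit.fitted_pmf
    p = pmf[1 : xmax + 1]
    model = np.cumsum(p) / pmf[1:].sum()
    emp = np.searchsorted(a, np.arange(1, xmax + 1), side="right") / len(a)
    return pd.DataFrame(
        {"count": np.arange(1, xmax + 1), "fitted_cdf": model[:xmax], "empirical_cdf": emp}
    )
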