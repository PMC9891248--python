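"""Penalized mixture model over (UMI, haplotype) pairs and its EM fitter.

Each read is an independent draw from a one-step hidden Markov chain: a
true UMI u_s is chosen with mixing proportion eta_s, a haplotype h_k is
attached with transition probability gamma_sk, and the observed UMI and
sample sequence are emitted with sequencing error. The observed log
likelihood

    sum_i log sum_{s,k} eta_s Pr(b_i | u_s) gamma_sk Pr(r_i | h_k)

is maximized after subtracting the sparsity penalty
rho * sum_{s,k} log(1 + gamma_sk / omega). With omega tiny (default 1e-20)
the penalty is l0-like: a transition survives only when the expected
amplified count of molecule (u_s, h_k) exceeds roughly rho, which is how
PCR-error haplotypes are eliminated and UMI collisions (two surviving
transitions in one row) are detected.

Sparsity/speed approximations: transitions are restricted to admissible
pairs (co-observed error-free at least once); per-read posteriors keep only
the top T entries and are renormalized; UMI rows whose mixing proportion
hits zero are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .candidates import CandidateSet, admissible_pairs, initialize_params, umi_emission_matrix
from .error_model import (
    DEFAULT_D_MAX,
    MAX_QUAL,
    ErrorProfile,
    align_auto,
    emission_logprob,
    indel_logprob,
)
from .io_reads import ReadSet, encode_seq

logger = logging.getLogger(__name__)

#: positivity cutoff for "gamma > 0" after clamping (guards numerics only)
GAMMA_TOL = 1e-9
#: M-step solutions below this are treated as the omega-scale boundary and
#: clamped to exact zero
_CLAMP = 1e-10


@dataclass
class PenaltyConfig:
    """Penalty weight rho (in expected-read-count units) and omega."""

    rho: float
    omega: float = 1e-20

    def __post_init__(self) -> None:
        if self.rho < 0 or self.omega <= 0:
            raise ValueError("rho must be >= 0 and omega > 0")


@dataclass
class ModelParams:
    """Mixing proportions eta, transition matrix gamma, and the fixed pools."""

    eta: np.ndarray  # (N,)
    gamma: np.ndarray  # (N, K), zeros outside the admissible mask
    umis: list[str]
    haplotypes: list[str]
    mask: np.ndarray  # (N, K) bool

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=np.float64)
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)

    def validate(self, atol: float = 1e-9) -> None:
        assert abs(self.eta.sum() - 1.0) < atol
        assert (self.eta >= 0).all()
        assert (self.gamma[~self.mask] == 0).all()
        rs = self.gamma.sum(axis=1)
        assert np.allclose(rs, 1.0, atol=atol)

    @property
    def n_umis(self) -> int:
        return len(self.umis)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


@dataclass
class PosteriorMatrix:
    """Sparse per-read posteriors over admissible pairs, truncated to top T.

    ``probs[i, p]`` is e_isk for pair p = (pair_s[p], pair_k[p]); each row
    has at most T nonzeros (ties at the T-th value are all kept, matching
    the truncation's indicator definition) and sums to one.
    """

    pair_s: np.ndarray
    pair_k: np.ndarray
    probs: np.ndarray  # (n, P)
    T: int

    def expected_counts(self, n_umis: int, n_haps: int) -> np.ndarray:
        """Dense (N, K) matrix of expected amplified counts c_sk."""
        c = np.zeros((n_umis, n_haps))
        np.add.at(c, (self.pair_s, self.pair_k), self.probs.sum(axis=0))
        return c


@dataclass
class Emissions:
    """Precomputed log emission matrices (independent of eta and gamma)."""

    umi: np.ndarray  # (n, N) — indel-free
    seq: np.ndarray  # (n, K) — indel-capable


def compute_emissions(
    reads: ReadSet,
    U: CandidateSet | list[str],
    H: CandidateSet | list[str],
    profile: ErrorProfile,
    d_max: int = DEFAULT_D_MAX,
) -> Emissions:
    umis = U.sequences if isinstance(U, CandidateSet) else list(U)
    haps = H.sequences if isinstance(H, CandidateSet) else list(H)
    LB = umi_emission_matrix(reads, umis, profile)
    LR = seq_emission_matrix(reads, haps, profile, d_max=d_max)
    return Emissions(LB, LR)


def seq_emission_matrix(
    reads: ReadSet, haps: list[str], profile: ErrorProfile, d_max: int = DEFAULT_D_MAX
) -> np.ndarray:
    """(n, K) matrix of indel-capable log emissions of sample sequences.

    Fast path: when a read and candidate have equal length and their edit
    distance equals their Hamming distance, the gap-free alignment is
    optimal and the emission is a direct table gather. Pairs where an indel
    alignment is strictly better (rare) are recomputed via the banded DP.
    """
    n = reads.n
    LR = np.empty((n, len(haps)))
    L = reads.uniform_seq_length
    if L is not None and all(len(h) == L for h in haps):
        X = reads.seq_matrix
        Q = np.clip(reads.seq_qual_matrix, 0, MAX_QUAL)
        d0 = {len(h): indel_logprob(0, len(h), profile.delta, d_max) for h in haps}
        for k, h in enumerate(haps):
            hc = encode_seq(h)
            LR[:, k] = profile.logp[hc[None, :], X, Q].sum(axis=1) + d0[len(h)]
        # patch pairs where an indel alignment beats pure substitutions
        from .error_model import INDEL_SEARCH_MAX_HAMMING

        seq_to_rows: dict[str, list[int]] = {}
        for i, s in enumerate(reads.seqs):
            seq_to_rows.setdefault(s, []).append(i)
        hap_codes = [encode_seq(h) for h in haps]
        for s, rows in seq_to_rows.items():
            sc = encode_seq(s)
            for k, h in enumerate(haps):
                ham = int((sc != hap_codes[k]).sum())
                if ham <= 1 or ham > INDEL_SEARCH_MAX_HAMMING:
                    continue
                res = edlib.align(s, h, mode="NW", task="distance", k=ham - 1)
                if res["editDistance"] < 0:
                    continue
                for i in rows:
                    LR[i, k] = emission_logprob(
                        s, reads.reads[i].quals, h, profile, allow_indels=True, d_max=d_max
                    )
        return LR
    for i, r in enumerate(reads.reads):
        for k, h in enumerate(haps):
            LR[i, k] = emission_logprob(r.seq, r.quals, h, profile, allow_indels=True, d_max=d_max)
    return LR


# ---------------------------------------------------------------------------
# Objective pieces
# ---------------------------------------------------------------------------

def _pair_scores(params: ModelParams, emissions: Emissions) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-read log scores over admissible pairs: log(eta * Pr * gamma * Pr)."""
    ps, pk = np.nonzero(params.mask)
    with np.errstate(divide="ignore"):
        w = np.log(params.eta)[ps] + np.log(params.gamma)[ps, pk]
    scores = emissions.umi[:, ps] + emissions.seq[:, pk] + w[None, :]
    return ps, pk, scores


def log_likelihood(
    params: ModelParams,
    reads: ReadSet,
    profile: ErrorProfile,
    emissions: Emissions | None = None,
) -> float:
    """Observed log likelihood, computed with log-sum-exp over admissible pairs.

    A read with zero admissible mass (all weights underflow) contributes its
    best available emission mass instead of -inf, with a warning.
    """
    if emissions is None:
        emissions = compute_emissions(reads, params.umis, params.haplotypes, profile)
    _, _, scores = _pair_scores(params, emissions)
    per_read = logsumexp(scores, axis=1)
    bad = ~np.isfinite(per_read)
    if bad.any():
        logger.warning("%d reads have zero admissible emission mass", int(bad.sum()))
        fallback = (emissions.umi[:, params.mask.any(axis=1)].max(axis=1)
                    + emissions.seq.max(axis=1))
        per_read = np.where(bad, fallback, per_read)
    return float(per_read.sum())


def penalty_value(gamma: np.ndarray, cfg: PenaltyConfig) -> float:
    """rho * sum log(1 + gamma / omega); zero entries contribute nothing."""
    return float(cfg.rho * np.log1p(np.asarray(gamma) / cfg.omega).sum())


def penalized_log_likelihood(
    params: ModelParams,
    reads: ReadSet,
    profile: ErrorProfile,
    cfg: PenaltyConfig,
    emissions: Emissions | None = None,
) -> float:
    return log_likelihood(params, reads, profile, emissions) - penalty_value(params.gamma, cfg)


# ---------------------------------------------------------------------------
# E step
# ---------------------------------------------------------------------------

def e_step(
    params: ModelParams,
    reads: ReadSet,
    profile: ErrorProfile,
    T: int = 10,
    emissions: Emissions | None = None,
) -> PosteriorMatrix:
    """Posteriors e_isk over admissible pairs, truncated to each read's top T
    entries and renormalized to sum one."""
    if emissions is None:
        emissions = compute_emissions(reads, params.umis, params.haplotypes, profile)
    ps, pk, scores = _pair_scores(params, emissions)
    P = scores.shape[1]
    if T < P:
        thresh = np.partition(scores, P - T, axis=1)[:, P - T]
        scores = np.where(scores >= thresh[:, None], scores, -np.inf)
    mx = scores.max(axis=1)
    bad = ~np.isfinite(mx)
    if bad.any():
        logger.warning("%d reads retained via best-available pair", int(bad.sum()))
        best = (emissions.umi[:, ps] + emissions.seq[:, pk]).argmax(axis=1)
        scores[bad] = -np.inf
        scores[bad, best[bad]] = 0.0
        mx = scores.max(axis=1)
    w = np.exp(scores - mx[:, None])
    w /= w.sum(axis=1, keepdims=True)
    return PosteriorMatrix(ps, pk, w, T)


# ---------------------------------------------------------------------------
# M step
# ---------------------------------------------------------------------------

def _row_gamma(lam: float, c: np.ndarray, rho: float, omega: float) -> np.ndarray:
    """Positive root of the per-component stationarity quadratic
    lam*g^2 + (lam*omega + rho - c)*g - c*omega = 0, computed stably."""
    b = lam * omega + rho - c
    disc = np.sqrt(b * b + 4.0 * lam * c * omega)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(b > 0, 2.0 * c * omega / (b + disc), (disc - b) / (2.0 * lam))
    return np.where(c > 0, g, 0.0)


def optimize_gamma_row(c: np.ndarray, cfg: PenaltyConfig) -> np.ndarray:
    """Maximize sum_k c_k log g_k - rho * sum_k log(1 + g_k/omega) on the simplex.

    Solved by root-finding the simplex Lagrangian on the per-component
    stationarity quadratic; solutions at the omega boundary are clamped to
    exact zero and the row renormalized. In the omega -> 0 limit this gives
    g_k proportional to max(c_k - rho, 0): transitions whose expected count
    falls below rho vanish. When every c_k is at or below rho the row keeps
    its argmax component (a UMI must explain its reads) — this is also the
    exact constrained maximizer in that regime.
    """
    c = np.asarray(c, dtype=np.float64)
    out = np.zeros_like(c)
    total = c.sum()
    if total <= 0:
        out[np.argmax(c)] = 1.0
        return out
    if cfg.rho == 0:
        return c / total
    if c.max() <= cfg.rho:
        out[np.argmax(c)] = 1.0
        return out

    def f(lam: float) -> float:
        return _row_gamma(lam, c, cfg.rho, cfg.omega).sum() - 1.0

    hi = total
    while f(hi) > 0:
        hi *= 2.0
    lo = max((c - cfg.rho).clip(min=0.0).sum() * 0.5, 1e-300)
    while f(lo) <= 0 and lo > 1e-290:
        lo *= 0.25
    if f(lo) <= 0:  # no interior solution: degenerate row
        out[np.argmax(c)] = 1.0
        return out
    lam = hi if f(hi) == 0.0 else brentq(f, lo, hi, xtol=1e-15, rtol=1e-14)
    g = _row_gamma(lam, c, cfg.rho, cfg.omega)
    g[g < _CLAMP] = 0.0
    if g.sum() <= 0:
        out[np.argmax(c)] = 1.0
        return out
    return g / g.sum()


def m_step(
    post: PosteriorMatrix, reads: ReadSet, params: ModelParams, cfg: PenaltyConfig
) -> ModelParams:
    """Update eta (unpenalized) and each admissible gamma row (penalized)."""
    n = reads.n
    N, K = params.mask.shape
    c = post.expected_counts(N, K)
    eta = c.sum(axis=1) / n
    gamma = np.zeros_like(c)
    for s in range(N):
        adm = params.mask[s]
        if not adm.any():
            continue
        gamma[s, adm] = optimize_gamma_row(c[s, adm], cfg)
    return ModelParams(eta, gamma, params.umis, params.haplotypes, params.mask)


# ---------------------------------------------------------------------------
# Fitter
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: ModelParams
    trace: np.ndarray  # penalized observed log likelihood per iteration
    converged: bool
    iterations: int
    expected_counts: np.ndarray  # (N, K) c_sk at the fitted params
    n_reads: int

    def summary(self) -> dict:
        collisions = [
            self.params.umis[s]
            for s in range(self.params.n_umis)
            if (self.params.gamma[s] > GAMMA_TOL).sum() >= 2
        ]
        return {
            "iterations": self.iterations,
            "converged": self.converged,
            "penalized_log_likelihood": float(self.trace[-1]) if len(self.trace) else None,
            "n_umis_retained": self.params.n_umis,
            "n_haplotypes": self.params.n_haplotypes,
            "collisions": collisions,
        }


def _drop_rows(params: ModelParams, emissions: Emissions, keep: np.ndarray):
    params = ModelParams(
        params.eta[keep] / params.eta[keep].sum(),
        params.gamma[keep],
        [params.umis[s] for s in np.flatnonzero(keep)],
        params.haplotypes,
        params.mask[keep],
    )
    emissions = Emissions(emissions.umi[:, keep], emissions.seq)
    return params, emissions


def fit_em(
    reads: ReadSet,
    U: CandidateSet,
    H: CandidateSet,
    profile: ErrorProfile,
    cfg: PenaltyConfig,
    T: int = 10,
    tol: float = 1e-6,
    max_iter: int = 1000,
    emissions: Emissions | None = None,
    params: ModelParams | None = None,
) -> FitResult:
    """Alternate E and M steps from observed-count initialization until the
    relative change in penalized observed log likelihood drops below tol.

    UMI rows reaching eta = 0 are excluded as error UMIs. The trace is
    monitored: it is nondecreasing up to truncation-induced tolerance.
    """
    if params is None:
        mask = admissible_pairs(reads, U, H)
        params = initialize_params(reads, U, H, mask)
    if emissions is None:
        emissions = compute_emissions(reads, params.umis, params.haplotypes, profile)
    elif emissions.umi.shape[1] != params.n_umis:
        # caller precomputed emissions over the full U; align to retained rows
        keep_idx = [U.sequences.index(u) for u in params.umis]
        emissions = Emissions(emissions.umi[:, keep_idx], emissions.seq)
    trace: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post = e_step(params, reads, profile, T=T, emissions=emissions)
        params = m_step(post, reads, params, cfg)
        keep = params.eta > 0
        if not keep.all():
            params, emissions = _drop_rows(params, emissions, keep)
        pll = penalized_log_likelihood(params, reads, profile, cfg, emissions)
        trace.append(pll)
        if np.isfinite(prev) and abs(pll - prev) <= tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = pll
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    final_post = e_step(params, reads, profile, T=T, emissions=emissions)
    counts = final_post.expected_counts(params.n_umis, params.n_haplotypes)
    return FitResult(params, np.asarray(trace), converged, it, counts, reads.n)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

@dataclass
class DedupResult:
    """Deduplicated abundances and per-UMI haplotype assignments.

    ``haplotypes``/``dedup_abundance`` list haplotypes with at least one
    supporting molecule; ``full_abundance`` covers every haplotype in the
    fitted pool (zeros included). ``umi_assignments`` maps each retained UMI
    to its positive-transition haplotypes with expected amplified counts
    n * eta_s * gamma_sk; ``collisions`` lists UMIs linked to two or more
    haplotypes.
    """

    haplotypes: list[str]
    dedup_abundance: np.ndarray
    full_haplotypes: list[str]
    full_abundance: np.ndarray
    umi_assignments: list[tuple[str, list[tuple[int, float, float]]]]
    collisions: list[str]

    def abundance_profile(self, min_abundance: int = 1) -> dict[str, int]:
        return {
            h: int(a)
            for h, a in zip(self.haplotypes, self.dedup_abundance)
            if a >= min_abundance
        }

    def assignment_rows(self):
        for umi, entries in self.umi_assignments:
            for k, expected, gamma in entries:
                yield umi, self.full_haplotypes[k], expected, gamma


def deduplicate(
    params: ModelParams,
    n: int,
    ncollision: bool = False,
    gamma_tol: float = GAMMA_TOL,
) -> DedupResult:
    """Deduplicated abundance of haplotype k: number of retained UMIs
    (n * eta_s >= 1) whose fitted transition to k is positive.

    With ``ncollision`` each UMI is assigned to one and only one haplotype,
    the argmax of its gamma row (ties: larger expected amplified count, then
    lower haplotype index).
    """
    K = params.n_haplotypes
    dedup = np.zeros(K, dtype=np.int64)
    assignments = []
    collisions = []
    for s in range(params.n_umis):
        expected_abund = n * params.eta[s]
        if expected_abund < 1.0 - 1e-9:
            continue
        ks = np.flatnonzero(params.gamma[s] > gamma_tol)
        if ks.size == 0:
            continue
        if ncollision and ks.size > 1:
            g = params.gamma[s, ks]
            ks = ks[[int(np.argmax(g))]]  # argmax; numpy picks the lowest index on ties
        entries = [
            (int(k), float(expected_abund * params.gamma[s, k]), float(params.gamma[s, k]))
            for k in ks
        ]
        assignments.append((params.umis[s], entries))
        dedup[ks] += 1
        if ks.size >= 2:
            collisions.append(params.umis[s])
    keep = dedup > 0
    return DedupResult(
        [h for h, kp in zip(params.haplotypes, keep) if kp],
        dedup[keep],
        list(params.haplotypes),
        dedup,
        assignments,
        collisions,
    )
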