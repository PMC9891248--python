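"""End-to-end workflow: denoise pools, estimate the error model, pick rho,
fit the penalized mixture and deduplicate."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import candidates as cand
from .candidates import CandidateSet
from .error_model import ErrorProfile, estimate_error_profile
from .io_reads import ReadSet
from .model_em import (
    DedupResult,
    Emissions,
    FitResult,
    PenaltyConfig,
    compute_emissions,
    deduplicate,
    fit_em,
)
from .penalty_select import BranchingFit, fit_branching, select_rho

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    result: DedupResult
    fit: FitResult
    U: CandidateSet
    H: CandidateSet
    profile: ErrorProfile
    rho: float
    branching: BranchingFit | None = None

    def abundance_profile(self, min_abundance: int = 1) -> dict[str, int]:
        return self.result.abundance_profile(min_abundance)


def build_candidates(
    reads: ReadSet,
    umi_min_abundance: int = 1,
    hap_min_abundance: int = 2,
    alpha: float = cand.DEFAULT_ALPHA,
    overdispersion: float = 1.0,
    candidate_umis: CandidateSet | None = None,
    candidate_haps: CandidateSet | None = None,
    profile: ErrorProfile | None = None,
) -> tuple[CandidateSet, CandidateSet, ErrorProfile]:
    """Initialization stage: UMI pool, error profile, haplotype pool.

    Either pool can be supplied externally (e.g. from another denoiser);
    whatever is missing is built by the greedy expected-misread denoiser.
    """
    U = candidate_umis or cand.denoise_umis(
        reads, min_abundance=umi_min_abundance, alpha=alpha, overdispersion=overdispersion
    )
    if profile is None:
        clusters = cand.split_umi_clusters(cand.assign_reads_to_umis(reads, U), reads)
        err_clusters = cand.build_error_clusters(clusters, reads)
        profile = estimate_error_profile(err_clusters)
    H = candidate_haps or cand.denoise_haplotypes(
        reads, profile, min_abundance=hap_min_abundance, alpha=alpha, overdispersion=overdispersion
    )
    return U, H, profile


def auto_rho(U: CandidateSet, cycles: int = 10, seed: int = 0) -> tuple[int, BranchingFit]:
    """Branching-model fit to candidate-UMI abundances, rho = 5th percentile."""
    fit = fit_branching(U.observed_abundance, cycles=cycles, seed=seed)
    return select_rho(fit), fit


def run_pipeline(
    reads: ReadSet,
    rho: float | None = None,
    omega: float = 1e-20,
    T: int = 10,
    ncollision: bool = False,
    cycles: int = 10,
    umi_min_abundance: int = 1,
    hap_min_abundance: int = 2,
    alpha: float = cand.DEFAULT_ALPHA,
    overdispersion: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
    candidate_umis: CandidateSet | None = None,
    candidate_haps: CandidateSet | None = None,
    profile: ErrorProfile | None = None,
    emissions: Emissions | None = None,
) -> PipelineResult:
    """Full run: candidate pools -> error profile -> rho -> EM -> dedup."""
    if reads.n < 1:
        raise ValueError("cannot fit an empty read set")
    U, H, profile = build_candidates(
        reads,
        umi_min_abundance=umi_min_abundance,
        hap_min_abundance=hap_min_abundance,
        alpha=alpha,
        overdispersion=overdispersion,
        candidate_umis=candidate_umis,
        candidate_haps=candidate_haps,
        profile=profile,
    )
    branching = None
    if rho is None:
        rho, branching = auto_rho(U, cycles=cycles, seed=seed)
        logger.info("auto-selected rho=%s (KS=%.4f)", rho, branching.ks_stat)
    cfg = PenaltyConfig(rho=float(rho), omega=omega)
    if emissions is None:
        emissions = compute_emissions(reads, U, H, profile)
    fit = fit_em(reads, U, H, profile, cfg, T=T, tol=tol, max_iter=max_iter, emissions=emissions)
    result = deduplicate(fit.params, reads.n, ncollision=ncollision)
    return PipelineResult(result, fit, U, H, profile, float(rho), branching)
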