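"""Candidate pool construction and model initialization.

Builds the true-UMI pool U and haplotype pool H by a greedy
expected-misread denoiser: distinct observed sequences are scanned in
decreasing abundance, and a sequence is admitted unless its observed count
is statistically attributable to misreads of already-accepted, more
abundant neighbors under the quality-based emission model. UMIs are judged
with the PHRED-default table (indel-free); haplotype candidates are judged
on full reads (UMI + sample sequence) with the estimated error profile and
indel-capable emissions, then stripped of the UMI prefix.

Users with an external denoiser can bypass either pool via sized FASTA
files (see :func:`candidate_set_from_fasta`).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy.stats import poisson

from . import error_model
from .error_model import MAX_QUAL, ErrorProfile, align_auto, indel_logprob
from .io_reads import ReadSet, encode_seq, read_sized_fasta, write_sized_fasta

logger = logging.getLogger(__name__)

#: neighbors farther than this (edit distance) contribute negligibly to the
#: expected-misread sum and are skipped
NEIGHBOR_MAX_DIST = 4
#: significance level of the misread-attribution test: a candidate is kept
#: only when its count is this unlikely under the error model
DEFAULT_ALPHA = 1e-3


@dataclass
class CandidateSet:
    """Pool of distinct candidate sequences with observed exact-match counts."""

    sequences: list[str]
    observed_abundance: np.ndarray
    role: str  # "umi" or "haplotype"

    def __post_init__(self) -> None:
        self.observed_abundance = np.asarray(self.observed_abundance, dtype=np.int64)
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("candidate sequences must be distinct")
        if len(self.sequences) != len(self.observed_abundance):
            raise ValueError("sequences and abundances differ in length")

    def __len__(self) -> int:
        return len(self.sequences)

    def to_fasta(self, path, prefix: str | None = None) -> None:
        prefix = prefix or ("U" if self.role == "umi" else "H")
        write_sized_fasta(
            path,
            [
                (f"{prefix}{i + 1}", s, int(a))
                for i, (s, a) in enumerate(zip(self.sequences, self.observed_abundance))
            ],
        )


def candidate_set_from_fasta(path, role: str) -> CandidateSet:
    entries = read_sized_fasta(path)
    return CandidateSet([s for _, s, _ in entries], [a for _, _, a in entries], role)


@dataclass
class UmiCluster:
    """Reads grouped under one accepted UMI.

    ``seq_center`` is the modal sample sequence of the members (set by
    :func:`split_umi_clusters` / the error-profile builder); after a
    collision split two clusters may share the same UMI center.
    """

    center: str
    members: list[int]
    seq_center: str | None = None


def _distinct_by_abundance(items: list[str]) -> list[tuple[str, int]]:
    """Distinct values ordered by count descending, then lexicographic."""
    counts = Counter(items)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _accept(count: int, expected: float, alpha: float) -> bool:
    """Misread-attribution test: keep iff the count is improbably large.

    One-sided Poisson tail: accept when P(Poisson(expected) >= count) < alpha.
    With expected == 0 any observation is unexplainable by error and the
    candidate is always kept.
    """
    if expected <= 0.0:
        return True
    return bool(poisson.sf(count - 1, expected) < alpha)


# ---------------------------------------------------------------------------
# UMI pool
# ---------------------------------------------------------------------------

def denoise_umis(
    reads: ReadSet,
    min_abundance: int = 1,
    alpha: float = DEFAULT_ALPHA,
    overdispersion: float = 1.0,
) -> CandidateSet:
    """Greedy abundance-descending denoising of observed UMIs.

    For each distinct UMI the expected misread count is the sum, over
    accepted UMIs within Hamming distance :data:`NEIGHBOR_MAX_DIST`, of the
    PHRED emission probability of the candidate given the neighbor,
    evaluated at each of the neighbor's exact-match reads' qualities.
    """
    if reads.n < 1:
        raise ValueError("need at least one read")
    order = _distinct_by_abundance(reads.umis)
    L = reads.umi_length
    profile = ErrorProfile.phred_default()
    # reads grouped by exact UMI
    by_umi: dict[str, list[int]] = defaultdict(list)
    for i, u in enumerate(reads.umis):
        by_umi[u].append(i)
    umi_quals = reads.umi_qual_matrix
    codes = {u: encode_seq(u) for u, _ in order}

    accepted: list[tuple[str, int]] = []
    for umi, count in order:
        if accepted and count < min_abundance:
            continue
        expected = 0.0
        x_code = codes[umi]
        for a_umi, _ in accepted:
            a_code = codes[a_umi]
            mism = np.flatnonzero(a_code != x_code)
            if len(mism) > NEIGHBOR_MAX_DIST:
                continue
            q = np.clip(umi_quals[by_umi[a_umi]], 0, MAX_QUAL)  # (m, L)
            # log Pr(x | a, q) per read of the neighbor
            lp = profile.logp[a_code[None, :], x_code[None, :], q].sum(axis=1)
            expected += float(np.exp(lp).sum())
        if not accepted or _accept(count, overdispersion * expected, alpha):
            accepted.append((umi, count))
    return CandidateSet(
        [u for u, _ in accepted], [c for _, c in accepted], role="umi"
    )


def assign_reads_to_umis(reads: ReadSet, U: CandidateSet) -> list[UmiCluster]:
    """Assign every read to the accepted UMI with maximal PHRED emission.

    Ties go to the more abundant UMI, then lexicographically smaller.
    Returns one cluster per accepted UMI (possibly empty); clusters
    partition the reads.
    """
    if len(U) == 0:
        raise ValueError("U must be nonempty")
    order = np.lexsort((U.sequences, -U.observed_abundance))
    LB = umi_emission_matrix(reads, [U.sequences[i] for i in order], ErrorProfile.phred_default())
    best = np.argmax(LB + 1e-12 >= LB.max(axis=1, keepdims=True), axis=1)  # first max in order
    clusters = [UmiCluster(u, []) for u in U.sequences]
    inv = {U.sequences[i]: i for i in range(len(U))}
    for i, b in enumerate(best):
        clusters[inv[U.sequences[order[b]]]].members.append(i)
    for cl in clusters:
        _set_seq_center(cl, reads)
    return clusters


def umi_emission_matrix(reads: ReadSet, umis: list[str], profile: ErrorProfile) -> np.ndarray:
    """(n, N) matrix of indel-free log emissions of observed UMIs."""
    B = reads.umi_matrix
    Q = np.clip(reads.umi_qual_matrix, 0, MAX_QUAL)
    LB = np.empty((reads.n, len(umis)))
    for s, u in enumerate(umis):
        uc = encode_seq(u)
        LB[:, s] = profile.logp[uc[None, :], B, Q].sum(axis=1)
    return LB


def _modal_seq(members: list[int], reads: ReadSet) -> tuple[str, int]:
    counts = Counter(reads.reads[i].seq for i in members)
    seq, cnt = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return seq, cnt


def _set_seq_center(cluster: UmiCluster, reads: ReadSet) -> None:
    if cluster.members:
        cluster.seq_center = _modal_seq(cluster.members, reads)[0]


def _seq_distance(a: str, b: str) -> int:
    if len(a) == len(b):
        return sum(x != y for x, y in zip(a, b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def split_umi_clusters(clusters: list[UmiCluster], reads: ReadSet) -> list[UmiCluster]:
    """Split clusters whose runner-up sample sequence is over half the top.

    Such a cluster is a possible UMI collision: the two sequences are
    promoted to centers and every member is reassigned to the closer center
    (Hamming distance; the more abundant center when equidistant). Applied
    once, without recursion.
    """
    out: list[UmiCluster] = []
    for cl in clusters:
        if not cl.members:
            out.append(cl)
            continue
        counts = Counter(reads.reads[i].seq for i in cl.members)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) < 2 or 2 * ranked[1][1] <= ranked[0][1]:
            _set_seq_center(cl, reads)
            out.append(cl)
            continue
        (c1, _), (c2, _) = ranked[0], ranked[1]
        m1, m2 = [], []
        for i in cl.members:
            d1 = _seq_distance(reads.reads[i].seq, c1)
            d2 = _seq_distance(reads.reads[i].seq, c2)
            # ties go to the more abundant center, which is c1 by ranking
            (m1 if d1 <= d2 else m2).append(i)
        out.append(UmiCluster(cl.center, m1, seq_center=c1))
        out.append(UmiCluster(cl.center, m2, seq_center=c2))
    return out


def build_error_clusters(
    clusters: list[UmiCluster], reads: ReadSet, min_center_abundance: int = 2
) -> list[tuple[str, list[tuple[str, np.ndarray]]]]:
    """Assemble (center, members) pairs for error-profile estimation.

    The center is the cluster's UMI followed by its modal sample sequence;
    members are full observed reads (UMI + sample sequence) with their
    qualities. Clusters whose center sequence is not replicated at least
    ``min_center_abundance`` times are dropped so centers are error-free.
    """
    out = []
    for cl in clusters:
        if not cl.members:
            continue
        seq_center, center_count = _modal_seq(cl.members, reads)
        if center_count < min_center_abundance:
            continue
        center = cl.center + seq_center
        members = [
            (
                reads.reads[i].umi + reads.reads[i].seq,
                np.concatenate([reads.reads[i].umi_quals, reads.reads[i].quals]),
            )
            for i in cl.members
        ]
        out.append((center, members))
    return out


# ---------------------------------------------------------------------------
# Haplotype pool
# ---------------------------------------------------------------------------

def denoise_haplotypes(
    reads: ReadSet,
    profile: ErrorProfile,
    min_abundance: int = 2,
    alpha: float = DEFAULT_ALPHA,
    overdispersion: float = 1.0,
) -> CandidateSet:
    """Greedy denoising over distinct full reads; accepted reads are stripped
    of the UMI prefix and deduplicated to form the haplotype pool H.

    The expected-misread sum uses indel-capable emissions under the
    estimated profile; only accepted neighbors within edit distance
    :data:`NEIGHBOR_MAX_DIST` contribute.
    """
    full = [r.umi + r.seq for r in reads.reads]
    order = _distinct_by_abundance(full)
    by_full: dict[str, list[int]] = defaultdict(list)
    for i, f in enumerate(full):
        by_full[f].append(i)

    def member_quals(f: str) -> np.ndarray:
        return np.vstack(
            [
                np.concatenate([reads.reads[i].umi_quals, reads.reads[i].quals])
                for i in by_full[f]
            ]
        )

    accepted: list[str] = []
    for seq, count in order:
        if accepted and count < min_abundance:
            continue
        expected = 0.0
        for a in accepted:
            res = edlib.align(seq, a, mode="NW", task="distance", k=NEIGHBOR_MAX_DIST)
            dist = res["editDistance"]
            if dist < 0:
                continue
            aln = align_auto(seq, a)
            xpos, xc, yc = aln.match_columns()
            Q = np.clip(member_quals(a)[:, xpos], 0, MAX_QUAL)
            lp = profile.logp[yc[None, :], xc[None, :], Q].sum(axis=1)
            lp += indel_logprob(min(aln.d, error_model.DEFAULT_D_MAX), aln.l, profile.delta)
            expected += float(np.exp(lp).sum())
        if not accepted or _accept(count, overdispersion * expected, alpha):
            accepted.append(seq)
    Lu = reads.umi_length
    hap_counts: dict[str, int] = {}
    for f in accepted:
        hap_counts.setdefault(f[Lu:], 0)
    all_seq_counts = Counter(reads.seqs)
    haps = sorted(hap_counts, key=lambda h: (-all_seq_counts[h], h))
    return CandidateSet(haps, [all_seq_counts[h] for h in haps], role="haplotype")


# ---------------------------------------------------------------------------
# Admissible pairs and initialization
# ---------------------------------------------------------------------------

def admissible_pairs(reads: ReadSet, U: CandidateSet, H: CandidateSet) -> np.ndarray:
    """Boolean (N, K) mask: pair (s, k) is admissible iff some read shows
    UMI u_s and sample sequence h_k both without error."""
    if len(U) == 0 or len(H) == 0:
        raise ValueError("U and H must be nonempty")
    u_idx = {u: s for s, u in enumerate(U.sequences)}
    h_idx = {h: k for k, h in enumerate(H.sequences)}
    mask = np.zeros((len(U), len(H)), dtype=bool)
    for r in reads.reads:
        s = u_idx.get(r.umi)
        k = h_idx.get(r.seq)
        if s is not None and k is not None:
            mask[s, k] = True
    for k in np.flatnonzero(~mask.any(axis=0)):
        logger.warning(
            "haplotype %d has no admissible UMI and can never receive abundance", k
        )
    return mask


def initialize_params(reads: ReadSet, U: CandidateSet, H: CandidateSet, mask: np.ndarray):
    """Initialize mixing proportions to relative observed UMI abundances and
    the transition matrix to row-normalized observed transition counts.

    UMI rows without any admissible pair are dropped (they can never emit a
    read under the sparsity mask). Returns a ModelParams.
    """
    from .model_em import ModelParams  # local import to avoid a cycle

    keep = np.flatnonzero(mask.any(axis=1))
    if keep.size == 0:
        raise ValueError("no admissible (UMI, haplotype) pairs")
    if keep.size < len(U):
        logger.warning("dropping %d UMIs with no admissible pair", len(U) - keep.size)
    umis = [U.sequences[s] for s in keep]
    mask = mask[keep]
    u_idx = {u: s for s, u in enumerate(umis)}
    h_idx = {h: k for k, h in enumerate(H.sequences)}
    eta = np.zeros(len(umis))
    counts = np.zeros((len(umis), len(H)))
    for r in reads.reads:
        s = u_idx.get(r.umi)
        if s is None:
            continue
        eta[s] += 1.0
        k = h_idx.get(r.seq)
        if k is not None and mask[s, k]:
            counts[s, k] += 1.0
    if eta.sum() == 0:
        raise ValueError("no read matches any candidate UMI exactly")
    eta /= eta.sum()
    gamma = np.zeros_like(counts)
    for s in range(len(umis)):
        row = counts[s]
        if row.sum() > 0:
            gamma[s] = row / row.sum()
        else:
            adm = mask[s]
            gamma[s, adm] = 1.0 / adm.sum()
    return ModelParams(eta, gamma, umis, list(H.sequences), mask)
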