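"""Evaluation metrics and the naive UMI-identity consensus baseline.

Haplotype-set agreement is scored with the Jaccard index and its
abundance-weighted form, the Ruzicka similarity; set recovery against a
gold standard with precision/recall; and read clusterings with the standard
conditional-entropy homogeneity and completeness. When ground truth is
unavailable, method self-consistency is measured across random bipartitions
of the reads.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_reads import ReadSet

logger = logging.getLogger(__name__)

#: fixed tie order of the majority-rule consensus
CONSENSUS_TIE_ORDER = "ATCG"

AbundanceProfile = Mapping[str, int]


def jaccard_index(A: Iterable, B: Iterable) -> float:
    """|A ∩ B| / |A ∪ B|; 1.0 when both sets are empty."""
    A, B = set(A), set(B)
    if not A and not B:
        return 1.0
    return len(A & B) / len(A | B)


def ruzicka_similarity(A: AbundanceProfile, B: AbundanceProfile) -> float:
    """sum min(A[h], B[h]) / sum max(A[h], B[h]) over the key union.

    The abundance-weighted form of the Jaccard index: it reduces to Jaccard
    when all abundances are one. 1.0 when both profiles are empty.
    """
    keys = set(A) | set(B)
    if not keys:
        return 1.0
    num = sum(min(A.get(h, 0), B.get(h, 0)) for h in keys)
    den = sum(max(A.get(h, 0), B.get(h, 0)) for h in keys)
    return num / den if den else 1.0


def precision_recall(est: Iterable, gold: Iterable) -> tuple[float, float]:
    """Set precision and recall of estimated haplotypes against a gold
    standard. Precision is defined as 1 for an empty estimate."""
    est, gold = set(est), set(gold)
    if not gold:
        raise ValueError("gold set must be nonempty for recall")
    tp = len(est & gold)
    precision = tp / len(est) if est else 1.0
    return precision, tp / len(gold)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def homogeneity_completeness(
    cluster_labels: Sequence, true_labels: Sequence
) -> tuple[float, float]:
    """Conditional-entropy clustering scores.

    homogeneity = 1 - H(true | cluster)/H(true);
    completeness = 1 - H(cluster | true)/H(cluster); each defined as 1 when
    the corresponding unconditional entropy is zero.
    """
    if len(cluster_labels) != len(true_labels):
        raise ValueError("label sequences must have equal length")
    table = pd.crosstab(pd.Series(true_labels), pd.Series(cluster_labels)).to_numpy(float)
    n = table.sum()
    h_true = _entropy(table.sum(axis=1))
    h_clu = _entropy(table.sum(axis=0))
    # conditional entropies from the joint
    p = table / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h_true_given = -np.nansum(p * (np.log(p) - np.log(p.sum(axis=0, keepdims=True))))
        h_clu_given = -np.nansum(p * (np.log(p) - np.log(p.sum(axis=1, keepdims=True))))
    homogeneity = 1.0 if h_true == 0 else 1.0 - h_true_given / h_true
    completeness = 1.0 if h_clu == 0 else 1.0 - h_clu_given / h_clu
    return float(homogeneity), float(completeness)


def consensus_sequence(seqs: Sequence[str]) -> str:
    """Per-position majority vote; ties resolved by the fixed base order
    A, T, C, G. Unequal lengths are truncated to the shortest with a warning."""
    if not seqs:
        raise ValueError("cannot build a consensus of zero sequences")
    L = min(len(s) for s in seqs)
    if any(len(s) != L for s in seqs):
        warnings.warn("unequal read lengths; consensus truncated to the shortest")
    out = []
    for j in range(L):
        counts = Counter(s[j] for s in seqs)
        best = max(CONSENSUS_TIE_ORDER, key=lambda b: (counts.get(b, 0), -CONSENSUS_TIE_ORDER.index(b)))
        out.append(best)
    return "".join(out)


def naive_baseline(
    reads: ReadSet, discard_singletons: bool = True
) -> tuple[dict[str, list[int]], dict[str, int]]:
    """Cluster reads by exact UMI identity and call one consensus molecule
    per surviving group.

    Singleton UMI groups (and their attached sample sequences) are discarded
    as likely errors when the flag is set. Returns the clusters and an
    abundance profile counting one molecule per group per consensus.
    """
    clusters: dict[str, list[int]] = defaultdict(list)
    for i, r in enumerate(reads.reads):
        clusters[r.umi].append(i)
    if discard_singletons:
        clusters = {u: m for u, m in clusters.items() if len(m) > 1}
    profile: dict[str, int] = defaultdict(int)
    for u in sorted(clusters):
        cons = consensus_sequence([reads.reads[i].seq for i in clusters[u]])
        profile[cons] += 1
    return dict(clusters), dict(profile)


def bipartition_consistency(
    reads: ReadSet,
    method: Callable[[ReadSet], AbundanceProfile],
    n_repeats: int = 5,
    rng: np.random.Generator | None = None,
    min_abundance: int = 1,
) -> pd.DataFrame:
    """Self-consistency of a method across random read bipartitions.

    The reads are split uniformly at random into two halves, the method runs
    independently on each, and the two estimated profiles are compared.
    Returns one row per repeat (Hap1, Hap2, Jaccard, Ruzicka); summary mean
    and SD are in ``DataFrame.attrs['summary']``.
    """
    if reads.n < 2:
        raise ValueError("need at least two reads to bipartition")
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for _ in range(n_repeats):
        perm = rng.permutation(reads.n)
        half = reads.n // 2
        p1 = _filter_profile(method(reads.subset(perm[:half])), min_abundance)
        p2 = _filter_profile(method(reads.subset(perm[half:])), min_abundance)
        rows.append(
            {
                "Hap1": len(p1),
                "Hap2": len(p2),
                "Jaccard": jaccard_index(p1.keys(), p2.keys()),
                "Ruzicka": ruzicka_similarity(p1, p2),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["summary"] = {
        col: {"mean": float(df[col].mean()), "sd": float(df[col].std(ddof=1))}
        for col in df.columns
    }
    return df


def _filter_profile(profile: AbundanceProfile, min_abundance: int) -> dict[str, int]:
    """Post-filter view of a profile (e.g. deduplicated abundance >= 2)."""
    return {h: int(a) for h, a in profile.items() if a >= min_abundance}
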