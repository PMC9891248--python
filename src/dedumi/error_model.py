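"""Sequencing-error model: emission probabilities Pr(observed | true).

A read emission factorizes into an indel term — the number of indel events
``d`` along the read/candidate alignment follows a truncated Poisson with
rate ``delta * l`` (``l`` = alignment length) — and a product of per-column
substitution probabilities Pr(X_j | Y_j; q_j) that depend on the PHRED
quality q_j of the observed base. Indel columns contribute probability 1 to
the substitution product. UMIs are assumed indel-free (``d = 0``): they are
short, early-cycle, high-quality stretches.

Two substitution tables are supported: the PHRED default, where the correct
base has probability 1 - 10^(-q/10) and the error mass is split evenly over
the three alternatives, and an empirical table estimated from UMI-defined
read clusters under the assumption that all differences between cluster
members and their (replicated, hence error-free) centers are errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from .io_reads import BASES, encode_seq

logger = logging.getLogger(__name__)

MAX_QUAL = 63
DEFAULT_D_MAX = 4  # truncation bound of the indel-count Poisson
#: error probabilities are capped so a "correct" base never has prob <= 0
_MAX_ERROR_PROB = 0.75


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

GAP = "-"


@dataclass
class Alignment:
    """Global alignment of an observed read ``x`` against a candidate ``y``.

    ``x_aligned``/``y_aligned`` are equal-length gapped strings. ``cost``
    is the unit-cost edit distance realized by the path.
    """

    x_aligned: str
    y_aligned: str
    cost: int

    @property
    def l(self) -> int:
        """Alignment length (number of columns)."""
        return len(self.x_aligned)

    @property
    def d(self) -> int:
        """Number of indel events = maximal gap runs (either row)."""
        d = 0
        in_gap = False
        for cx, cy in zip(self.x_aligned, self.y_aligned):
            gap = cx == GAP or cy == GAP
            if gap and not in_gap:
                d += 1
            in_gap = gap
        return d

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.x_aligned, self.y_aligned))

    def match_columns(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x_positions, x_codes, y_codes) over non-gap columns.

        ``x_positions`` index into the ungapped read, for quality lookup.
        """
        xpos, xc, yc = [], [], []
        i = 0
        for cx, cy in zip(self.x_aligned, self.y_aligned):
            if cx != GAP and cy != GAP:
                xpos.append(i)
                xc.append(BASES.index(cx))
                yc.append(BASES.index(cy))
            if cx != GAP:
                i += 1
        return (
            np.asarray(xpos, dtype=np.intp),
            np.asarray(xc, dtype=np.uint8),
            np.asarray(yc, dtype=np.uint8),
        )


def identity_alignment(x: str, y: str) -> Alignment:
    """Column-by-column alignment of equal-length sequences (no gaps)."""
    if len(x) != len(y):
        raise ValueError("identity alignment requires equal lengths")
    cost = sum(a != b for a, b in zip(x, y))
    return Alignment(x, y, cost)


def align_banded(read_seq: str, candidate: str, band: int) -> Alignment:
    """Optimal global alignment under unit-cost edit distance within a band.

    Only cells with ``|j - i| <= band`` are explored (i indexes the read,
    j the candidate). Ties are broken deterministically by traceback
    preference: diagonal (match, then mismatch) over deletion (gap in the
    read) over insertion (gap in the candidate).
    """
    if not read_seq or not candidate:
        raise ValueError("sequences must be non-empty")
    nx, ny = len(read_seq), len(candidate)
    if band < abs(nx - ny):
        raise ValueError(f"band {band} < length difference {abs(nx - ny)}")
    INF = nx + ny + 10
    # D[i] is a dict j -> cost for the banded window of row i
    prev = {j: j for j in range(0, min(ny, band) + 1)}
    rows = [prev]
    for i in range(1, nx + 1):
        lo, hi = max(0, i - band), min(ny, i + band)
        cur: dict[int, int] = {}
        for j in range(lo, hi + 1):
            best = INF
            if j > 0 and i > 0:
                dcost = rows[i - 1].get(j - 1, INF) + (read_seq[i - 1] != candidate[j - 1])
                best = min(best, dcost)
            if j > 0:
                best = min(best, cur.get(j - 1, INF) + 1)  # deletion: gap in read
            best = min(best, rows[i - 1].get(j, INF) + 1)  # insertion: gap in candidate
            cur[j] = best
        rows.append(cur)
    # traceback with fixed preference
    xa: list[str] = []
    ya: list[str] = []
    i, j = nx, ny
    while i > 0 or j > 0:
        cost = rows[i][j]
        if i > 0 and j > 0 and rows[i - 1].get(j - 1, INF) + (
            read_seq[i - 1] != candidate[j - 1]
        ) == cost:
            xa.append(read_seq[i - 1])
            ya.append(candidate[j - 1])
            i -= 1
            j -= 1
        elif j > 0 and rows[i].get(j - 1, INF) + 1 == cost:
            xa.append(GAP)
            ya.append(candidate[j - 1])
            j -= 1
        else:
            xa.append(read_seq[i - 1])
            ya.append(GAP)
            i -= 1
    return Alignment("".join(reversed(xa)), "".join(reversed(ya)), rows[nx][ny])


#: equal-length pairs more divergent than this are aligned gap-free: indel
#: re-alignment only matters for genuinely related sequences, and emissions
#: this far out are negligible under any alignment
INDEL_SEARCH_MAX_HAMMING = 16


def align_auto(read_seq: str, candidate: str, band: int | None = None) -> Alignment:
    """Alignment with a fast path for pure-substitution pairs.

    When the sequences have equal length and the edit distance equals the
    Hamming distance, the gap-free column alignment is optimal (and is the
    alignment the tie-breaking rules would pick, since diagonal moves are
    preferred). Equal-length pairs beyond :data:`INDEL_SEARCH_MAX_HAMMING`
    mismatches are likewise treated as pure substitutions. Everything else
    falls back to the banded DP.
    """
    if len(read_seq) == len(candidate):
        ham = sum(a != b for a, b in zip(read_seq, candidate))
        if ham <= 1 or ham > INDEL_SEARCH_MAX_HAMMING:
            return identity_alignment(read_seq, candidate)
        dist = edlib.align(
            read_seq, candidate, mode="NW", task="distance", k=ham - 1
        )["editDistance"]
        if dist < 0:  # no indel path beats the substitution-only alignment
            return identity_alignment(read_seq, candidate)
    else:
        dist = edlib.align(read_seq, candidate, mode="NW", task="distance")["editDistance"]
    if band is None:
        band = max(abs(len(read_seq) - len(candidate)), dist, 4) + 1
    return align_banded(read_seq, candidate, band)


# ---------------------------------------------------------------------------
# Indel term
# ---------------------------------------------------------------------------

def indel_logprob(d: int, l: int, delta: float, d_max: int = DEFAULT_D_MAX) -> float:
    """Log probability of ``d`` indel events under truncated Poisson(delta*l)."""
    if d < 0 or l < 1:
        raise ValueError("require d >= 0 and l >= 1")
    if d > d_max:
        raise ValueError(f"d={d} exceeds truncation bound d_max={d_max}")
    if delta == 0.0:
        return 0.0 if d == 0 else -np.inf
    mu = delta * l
    logs = np.array([j * math.log(mu) - math.lgamma(j + 1) for j in range(d_max + 1)])
    logs -= -mu + np.logaddexp.reduce(logs) + mu  # normalize the truncated pmf
    return float(logs[d])


# ---------------------------------------------------------------------------
# Error profile
# ---------------------------------------------------------------------------

@dataclass
class ErrorProfile:
    """Substitution log-probability table plus an indel rate.

    ``logp[y, x, q]`` is log Pr(observed base x | true base y, quality q);
    rows (y, q) sum to one over x. ``delta`` is the per-position per-read
    indel rate.
    """

    logp: np.ndarray  # (4, 4, MAX_QUAL + 1)
    delta: float
    source: str = "phred_default"
    qual_bin_width: int = 1

    def __post_init__(self) -> None:
        self.logp = np.asarray(self.logp, dtype=np.float64)
        if self.logp.shape != (4, 4, MAX_QUAL + 1):
            raise ValueError("logp must have shape (4, 4, MAX_QUAL+1)")

    @classmethod
    def phred_default(cls, delta: float = 0.0) -> "ErrorProfile":
        """PHRED-consistent table: Pr(correct) = 1 - 10^(-q/10), errors 1/3 each."""
        q = np.arange(MAX_QUAL + 1)
        e = np.minimum(10.0 ** (-q / 10.0), _MAX_ERROR_PROB)
        logp = np.empty((4, 4, MAX_QUAL + 1))
        logp[:] = np.log(e / 3.0)
        for y in range(4):
            logp[y, y, :] = np.log1p(-e)
        return cls(logp, delta, source="phred_default")

    # ---- serialization -------------------------------------------------

    def to_tsv(self, path) -> None:
        width = self.qual_bin_width
        with open(path, "w") as fh:
            fh.write(
                f"# delta={self.delta!r}\tqual_bin_width={width}\tsource={self.source}\n"
            )
            fh.write("true_base\tobs_base\tqual_bin\tprob\n")
            for y in range(4):
                for x in range(4):
                    for b in range(0, MAX_QUAL + 1, width):
                        fh.write(
                            f"{BASES[y]}\t{BASES[x]}\t{b // width}\t"
                            f"{math.exp(self.logp[y, x, b]):.12g}\n"
                        )

    @classmethod
    def from_tsv(cls, path) -> "ErrorProfile":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split("\t")
            meta = dict(kv.split("=", 1) for kv in header)
            fh.readline()  # column names
            width = int(meta["qual_bin_width"])
            logp = np.full((4, 4, MAX_QUAL + 1), -np.inf)
            for line in fh:
                y, x, b, p = line.split("\t")
                lo = int(b) * width
                hi = min(lo + width, MAX_QUAL + 1)
                val = float(p)
                logp[BASES.index(y), BASES.index(x), lo:hi] = (
                    math.log(val) if val > 0 else -np.inf
                )
        return cls(logp, float(meta["delta"]), source=meta["source"].strip(), qual_bin_width=width)


def emission_logprob(
    seq: str,
    quals: np.ndarray,
    candidate: str,
    profile: ErrorProfile,
    allow_indels: bool = True,
    band: int | None = None,
    d_max: int = DEFAULT_D_MAX,
) -> float:
    """Log emission probability of an observed read given a candidate source.

    With ``allow_indels`` False (the UMI case) the sequences must have equal
    length and the emission is the plain product of per-column substitution
    probabilities (d is fixed at 0, no indel factor). Otherwise the read is
    aligned to the candidate and the truncated-Poisson indel term is added;
    indel columns contribute probability one.
    """
    quals = np.asarray(quals)
    if not candidate:
        raise ValueError("candidate must be non-empty")
    if not allow_indels:
        if len(seq) != len(candidate):
            raise ValueError("length mismatch with allow_indels=False")
        aln = identity_alignment(seq, candidate)
        xpos, xc, yc = aln.match_columns()
        return float(profile.logp[yc, xc, np.clip(quals[xpos], 0, MAX_QUAL)].sum())
    aln = align_auto(seq, candidate, band=band)
    d = min(aln.d, d_max)  # alignments worse than the truncation bound saturate
    xpos, xc, yc = aln.match_columns()
    sub = float(profile.logp[yc, xc, np.clip(quals[xpos], 0, MAX_QUAL)].sum())
    return sub + indel_logprob(d, aln.l, profile.delta, d_max=d_max)


# ---------------------------------------------------------------------------
# Profile estimation from UMI-defined clusters
# ---------------------------------------------------------------------------

def estimate_error_profile(
    clusters: list[tuple[str, list[tuple[str, np.ndarray]]]],
    qual_bin_width: int = 2,
    min_real_obs: int = 1,
) -> ErrorProfile:
    """Estimate the substitution table and indel rate from read clusters.

    ``clusters`` holds ``(center_sequence, members)`` pairs where each member
    is ``(sequence, phred_quals)``; all member/center differences are treated
    as errors. Counts are tallied per (true base, observed base, quality bin)
    with add-one smoothing and renormalized over the observed base. Bins with
    no real observations for a given true base fall back to the PHRED
    default so emissions stay quality-aware outside the sampled range. The
    indel rate is total indel events over total aligned positions.
    """
    nbins = (MAX_QUAL // qual_bin_width) + 1
    counts = np.zeros((4, 4, nbins))
    indel_events = 0
    aligned_positions = 0
    if not clusters:
        logger.warning("no clusters survive filtering; falling back to PHRED default")
        return ErrorProfile.phred_default()
    for center, members in clusters:
        for seq, quals in members:
            aln = align_auto(seq, center)
            xpos, xc, yc = aln.match_columns()
            qb = np.clip(np.asarray(quals)[xpos], 0, MAX_QUAL) // qual_bin_width
            np.add.at(counts, (yc, xc, qb), 1.0)
            indel_events += aln.d
            aligned_positions += aln.l
    delta = indel_events / aligned_positions if aligned_positions else 0.0
    default = ErrorProfile.phred_default()
    logp = np.empty((4, 4, MAX_QUAL + 1))
    for y in range(4):
        for b in range(nbins):
            lo, hi = b * qual_bin_width, min((b + 1) * qual_bin_width, MAX_QUAL + 1)
            total_real = counts[y, :, b].sum()
            if total_real < min_real_obs:
                # PHRED fallback at the bin's representative quality, kept
                # constant across the bin so the table is piecewise-constant
                logp[y, :, lo:hi] = default.logp[y, :, lo][:, None]
                continue
            smoothed = counts[y, :, b] + 1.0
            probs = smoothed / smoothed.sum()
            logp[y, :, lo:hi] = np.log(probs)[:, None]
    return ErrorProfile(logp, delta, source="estimated", qual_bin_width=qual_bin_width)
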