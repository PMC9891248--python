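"""Simulator of UMI-tagged amplicon sequencing with a complete truth table.

Pipeline: (i) relative haplotype abundances are drawn from a power law
f(x) proportional to x^(-a) on (0, 1] and normalized; (ii) founder
molecules are sampled multinomially and tagged with random UMIs — with the
collision option the distinct UMI pool is resampled with replacement before
attachment, so some UMIs tag two or more molecules; (iii) molecules are PCR
amplified, every copy duplicating per cycle with the given efficiency and
each new copy mutating per base with substitution-specific per-cycle rates;
(iv) reads are drawn uniformly with replacement from the amplified pool and
sequencing noise is applied: position-dependent PHRED qualities from a
logistic decay profile, substitution errors realized at the quality-implied
rates, and indels at a fixed per-position rate.

Everything downstream of the seed is reproducible, and every read records
its source molecule and founder.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_reads import BASES, Read, ReadSet, decode_seq, write_fastq

logger = logging.getLogger(__name__)


def default_pcr_sub_rates(transition: float = 1e-4, transversion: float = 1e-5) -> np.ndarray:
    """Per-base per-cycle substitution rate matrix (rows: true base A,C,G,T).

    Transitions (A<->G, C<->T) are roughly tenfold more frequent than
    transversions in PCR; reported per-cycle rates span 1e-4 to 1e-6.
    """
    R = np.full((4, 4), transversion)
    np.fill_diagonal(R, 0.0)
    R[0, 2] = R[2, 0] = transition  # A <-> G
    R[1, 3] = R[3, 1] = transition  # C <-> T
    return R


@dataclass
class SimulationConfig:
    K: int = 25
    n_molecules: int = 400
    umi_length: int = 9
    power_exponent: float = 0.5
    collision: bool = False
    cycles: int = 10
    efficiency: float = 0.6
    pcr_sub_rates: np.ndarray = field(default_factory=default_pcr_sub_rates)
    read_length: int = 250
    seq_indel_rate: float = 2e-5
    n_reads: int = 10_000
    quality_start: float = 38.0
    quality_end: float = 30.0
    quality_sd: float = 2.0
    #: scale on the quality-implied substitution rate; 0 gives error-free
    #: reads whose qualities still follow the quality model
    seq_error_scale: float = 1.0
    pool_cap: int = 5_000_000
    seed: int = 0

    @property
    def haplotype_length(self) -> int:
        return self.read_length - self.umi_length

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["pcr_sub_rates"] = np.asarray(self.pcr_sub_rates).tolist()
        return json.dumps(d, indent=2)


#: named presets differing in collision flag and sequencing depth
PRESETS: dict[str, dict] = {
    "sim1": {"collision": False, "n_reads": 10_000},
    "sim2": {"collision": False, "n_reads": 20_000},
    "sim3": {"collision": True, "n_reads": 10_000},
    "sim4": {"collision": True, "n_reads": 20_000},
}


def preset_config(name: str, **overrides) -> SimulationConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@dataclass
class TruthTable:
    """Ground truth: one row per founder molecule plus per-haplotype counts."""

    umis: list[str]  # per founder molecule
    hap_ids: np.ndarray  # per founder molecule
    hap_counts: np.ndarray  # (K,) true sampled count per haplotype

    @property
    def n_molecules(self) -> int:
        return len(self.umis)

    @property
    def collision_pairs(self) -> dict[str, set[int]]:
        """UMIs attached to two or more distinct haplotypes."""
        by_umi: dict[str, set[int]] = {}
        for u, k in zip(self.umis, self.hap_ids):
            by_umi.setdefault(u, set()).add(int(k))
        return {u: ks for u, ks in by_umi.items() if len(ks) >= 2}

    def molecules_per_umi(self) -> Counter:
        return Counter(self.umis)

    def dedup_truth(self) -> dict[int, int]:
        """True deduplicated abundance: distinct (UMI, haplotype) links per
        haplotype."""
        links = {(u, int(k)) for u, k in zip(self.umis, self.hap_ids)}
        out: dict[int, int] = {}
        for _, k in links:
            out[k] = out.get(k, 0) + 1
        return out


def draw_abundances(K: int, power_exponent: float, rng: np.random.Generator) -> np.ndarray:
    """K relative abundances from the density proportional to x^(-a) on (0,1].

    Inverse-CDF sampling: X = V^(1/(1-a)) for uniform V, then normalize.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not (0.0 < power_exponent < 1.0):
        raise ValueError("power exponent must be in (0, 1)")
    v = rng.random(K)
    x = v ** (1.0 / (1.0 - power_exponent))
    return x / x.sum()


def _random_distinct_umis(n: int, length: int, rng: np.random.Generator) -> list[str]:
    if 4**length < n:
        raise ValueError(f"cannot draw {n} distinct UMIs of length {length}")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        codes = rng.integers(0, 4, size=(n - len(out), length), dtype=np.uint8)
        for row in codes:
            u = decode_seq(row)
            if u not in seen:
                seen.add(u)
                out.append(u)
    return out


def attach_umis(
    n_molecules: int,
    umi_length: int,
    collision: bool,
    haplotype_draws: np.ndarray,
    rng: np.random.Generator,
) -> TruthTable:
    """Tag each founder molecule with a UMI.

    ``haplotype_draws`` is the multinomial count vector per haplotype. With
    ``collision`` the n distinct UMIs are resampled with replacement before
    attachment, so distinct molecules can share a UMI.
    """
    hap_ids = np.repeat(np.arange(len(haplotype_draws)), haplotype_draws)
    if len(hap_ids) != n_molecules:
        raise ValueError("haplotype draws must sum to n_molecules")
    pool = _random_distinct_umis(n_molecules, umi_length, rng)
    if collision:
        umis = [pool[i] for i in rng.integers(0, n_molecules, size=n_molecules)]
    else:
        umis = pool
    return TruthTable(umis, hap_ids, np.asarray(haplotype_draws, dtype=np.int64))


@dataclass
class AmplifiedPool:
    """PCR product pool: encoded full molecules plus founder lineage labels."""

    seqs: np.ndarray  # (M, L) uint8
    founders: np.ndarray  # (M,) index into the truth table

    @property
    def size(self) -> int:
        return self.seqs.shape[0]


def _mutate(seqs: np.ndarray, rates: np.ndarray, rng: np.random.Generator) -> None:
    """In-place per-base substitution with base-specific rates."""
    total = rates.sum(axis=1)
    u = rng.random(seqs.shape)
    for b in range(4):
        hit = (seqs == b) & (u < total[b])
        n_hit = int(hit.sum())
        if n_hit == 0:
            continue
        targets = np.flatnonzero(rates[b] > 0)
        probs = rates[b, targets] / total[b]
        seqs[hit] = rng.choice(targets, size=n_hit, p=probs).astype(np.uint8)


def amplify_pcr(
    truth: TruthTable,
    haplotype_seqs: list[str],
    cycles: int,
    efficiency: float,
    pcr_sub_rates: np.ndarray,
    rng: np.random.Generator,
    pool_cap: int = 5_000_000,
) -> AmplifiedPool:
    """Amplify founder molecules; each copy duplicates per cycle with the
    given efficiency and new copies mutate per base at the per-cycle rates."""
    from .io_reads import encode_seq

    rates = np.asarray(pcr_sub_rates, dtype=float)
    if rates.min() < 0 or rates.max() > 1:
        raise ValueError("substitution rates must be in [0, 1]")
    founders_enc = np.vstack(
        [
            np.concatenate([encode_seq(u), encode_seq(haplotype_seqs[k])])
            for u, k in zip(truth.umis, truth.hap_ids)
        ]
    )
    seqs = founders_enc.copy()
    founders = np.arange(truth.n_molecules)
    for _ in range(cycles):
        dup = rng.random(seqs.shape[0]) < efficiency
        if dup.any():
            copies = seqs[dup].copy()
            _mutate(copies, rates, rng)
            seqs = np.vstack([seqs, copies])
            founders = np.concatenate([founders, founders[dup]])
        if seqs.shape[0] > pool_cap:
            raise RuntimeError(
                f"amplified pool exceeds cap {pool_cap}; reduce cycles or molecules"
            )
    return AmplifiedPool(seqs, founders)


def quality_profile(read_length: int, q_start: float, q_end: float) -> np.ndarray:
    """Mean PHRED quality per position: logistic decay along the read."""
    pos = np.arange(read_length)
    mid, scale = 0.6 * read_length, 0.08 * read_length
    return q_end + (q_start - q_end) / (1.0 + np.exp((pos - mid) / scale))


def sequence_reads(
    pool: AmplifiedPool,
    n_reads: int,
    read_length: int,
    quality_model: tuple[float, float, float],
    seq_indel_rate: float,
    rng: np.random.Generator,
    seq_error_scale: float = 1.0,
) -> tuple[list[tuple[str, str, np.ndarray]], pd.DataFrame]:
    """Draw reads uniformly with replacement from the pool and add noise.

    Returns FASTQ-style records ``(id, sequence, quals)`` plus a read-level
    truth frame (source molecule index and founder). Reads are truncated or
    padded (random bases at quality 2) back to ``read_length`` after indels.
    """
    if pool.size == 0:
        raise ValueError("amplified pool is empty")
    q_start, q_end, q_sd = quality_model
    idx = rng.integers(0, pool.size, size=n_reads)
    seqs = pool.seqs[idx].copy()
    n, L = seqs.shape
    qmean = quality_profile(L, q_start, q_end)
    quals = np.clip(np.rint(qmean[None, :] + rng.normal(0.0, q_sd, size=(n, L))), 2, 41).astype(np.int16)
    err = rng.random((n, L)) < seq_error_scale * 10.0 ** (-quals / 10.0)
    n_err = int(err.sum())
    if n_err:
        seqs[err] = (seqs[err] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
    records: list[tuple[str, str, np.ndarray]] = []
    n_indels = rng.binomial(L, seq_indel_rate, size=n)
    for i in range(n):
        s = seqs[i]
        q = quals[i]
        if n_indels[i]:
            s, q = _apply_indels(s, q, int(n_indels[i]), read_length, rng)
        records.append((f"sim_read_{i}", decode_seq(s), q))
    truth = pd.DataFrame(
        {
            "read_id": [r[0] for r in records],
            "molecule": idx,
            "founder": pool.founders[idx],
        }
    )
    return records, truth


def _apply_indels(
    seq: np.ndarray, quals: np.ndarray, k: int, read_length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    s, q = list(seq), list(quals)
    for _ in range(k):
        pos = int(rng.integers(0, len(s)))
        if rng.random() < 0.5 and len(s) > 1:  # deletion
            del s[pos], q[pos]
        else:  # insertion of a random base, quality borrowed from neighbor
            s.insert(pos, int(rng.integers(0, 4)))
            q.insert(pos, q[pos])
    while len(s) < read_length:  # pad with random low-quality bases
        s.append(int(rng.integers(0, 4)))
        q.append(2)
    return np.asarray(s[:read_length], dtype=np.uint8), np.asarray(q[:read_length], dtype=np.int16)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    readset: ReadSet
    truth: TruthTable
    haplotypes: list[str]
    pi: np.ndarray
    read_truth: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _random_haplotypes(K: int, length: int, rng: np.random.Generator) -> list[str]:
    haps: list[str] = []
    seen: set[str] = set()
    while len(haps) < K:
        h = decode_seq(rng.integers(0, 4, size=length, dtype=np.uint8))
        if h not in seen:
            seen.add(h)
            haps.append(h)
    return haps


def simulate_dataset(cfg: SimulationConfig, out_dir=None) -> SimulatedDataset:
    """Run the full pipeline; optionally write FASTQ + truth TSVs + config."""
    rng = np.random.default_rng(cfg.seed)
    pi = draw_abundances(cfg.K, cfg.power_exponent, rng)
    haps = _random_haplotypes(cfg.K, cfg.haplotype_length, rng)
    draws = rng.multinomial(cfg.n_molecules, pi)
    truth = attach_umis(cfg.n_molecules, cfg.umi_length, cfg.collision, draws, rng)
    pool = amplify_pcr(
        truth, haps, cfg.cycles, cfg.efficiency, cfg.pcr_sub_rates, rng, cfg.pool_cap
    )
    records, read_truth = sequence_reads(
        pool,
        cfg.n_reads,
        cfg.read_length,
        (cfg.quality_start, cfg.quality_end, cfg.quality_sd),
        cfg.seq_indel_rate,
        rng,
        seq_error_scale=cfg.seq_error_scale,
    )
    reads = [
        Read(seq[: cfg.umi_length], q[: cfg.umi_length], seq[cfg.umi_length :], q[cfg.umi_length :])
        for _, seq, q in records
    ]
    readset = ReadSet(reads, cfg.umi_length)
    paths: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths["fastq"] = out_dir / "reads.fastq"
        write_fastq(paths["fastq"], records)
        paths["molecules"] = out_dir / "truth_molecules.tsv"
        pd.DataFrame(
            {
                "molecule_id": np.arange(truth.n_molecules),
                "umi": truth.umis,
                "haplotype_id": truth.hap_ids,
            }
        ).to_csv(paths["molecules"], sep="\t", index=False)
        paths["haplotypes"] = out_dir / "truth_haplotypes.tsv"
        pd.DataFrame(
            {
                "haplotype_id": np.arange(cfg.K),
                "sequence": haps,
                "true_count": truth.hap_counts,
            }
        ).to_csv(paths["haplotypes"], sep="\t", index=False)
        paths["collisions"] = out_dir / "truth_collisions.tsv"
        pd.DataFrame(
            [
                {"umi": u, "haplotype_ids": ",".join(map(str, sorted(ks)))}
                for u, ks in sorted(truth.collision_pairs.items())
            ],
            columns=["umi", "haplotype_ids"],
        ).to_csv(paths["collisions"], sep="\t", index=False)
        paths["read_truth"] = out_dir / "truth_reads.tsv"
        read_truth.to_csv(paths["read_truth"], sep="\t", index=False)
        paths["config"] = out_dir / "config.json"
        paths["config"].write_text(cfg.to_json())
    return SimulatedDataset(cfg, readset, truth, haps, pi, read_truth, paths)
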