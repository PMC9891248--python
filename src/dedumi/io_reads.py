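"""Reading and writing the formats the tool touches.

Input reads are single-end FASTQ records laid out as a fixed-length UMI
prefix followed by the sample sequence, or a paired arrangement of one UMI
FASTQ plus one detagged-read FASTQ. Outputs are FASTA (haplotypes and
candidate pools, with usearch-style ``;size=`` abundance annotations) and
TSV (per-UMI assignments).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

BASES = "ACGT"
#: uint8 codes for A,C,G,T; 255 marks anything else (ambiguous).
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


@dataclass
class Read:
    """One sequencing read split into UMI and sample-sequence parts.

    ``umi_quals`` and ``quals`` are integer PHRED scores, one per base.
    """

    umi: str
    umi_quals: np.ndarray
    seq: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        self.umi_quals = np.asarray(self.umi_quals, dtype=np.int16)
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.umi) != len(self.umi_quals):
            raise ValueError("UMI and UMI quality lengths differ")
        if len(self.seq) != len(self.quals):
            raise ValueError("sequence and quality lengths differ")


class ReadSet:
    """Ordered collection of reads sharing one UMI length."""

    def __init__(self, reads: list[Read], umi_length: int):
        for r in reads:
            if len(r.umi) != umi_length:
                raise ValueError("all UMIs must have length umi_length")
        self.reads = reads
        self.umi_length = umi_length
        self._cache: dict[str, np.ndarray] = {}

    @property
    def n(self) -> int:
        return len(self.reads)

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, i):
        return self.reads[i]

    def subset(self, indices: Iterable[int]) -> "ReadSet":
        return ReadSet([self.reads[i] for i in indices], self.umi_length)

    # ---- cached matrix views used by the numerical modules ----

    @property
    def umis(self) -> list[str]:
        return [r.umi for r in self.reads]

    @property
    def seqs(self) -> list[str]:
        return [r.seq for r in self.reads]

    @property
    def umi_matrix(self) -> np.ndarray:
        if "umi_matrix" not in self._cache:
            self._cache["umi_matrix"] = np.vstack(
                [encode_seq(r.umi) for r in self.reads]
            ) if self.n else np.empty((0, self.umi_length), dtype=np.uint8)
        return self._cache["umi_matrix"]

    @property
    def umi_qual_matrix(self) -> np.ndarray:
        if "umi_quals" not in self._cache:
            self._cache["umi_quals"] = np.vstack(
                [r.umi_quals for r in self.reads]
            ) if self.n else np.empty((0, self.umi_length), dtype=np.int16)
        return self._cache["umi_quals"]

    @property
    def uniform_seq_length(self) -> int | None:
        """Common sample-sequence length, or None if lengths vary."""
        lens = {len(r.seq) for r in self.reads}
        return lens.pop() if len(lens) == 1 else None

    @property
    def seq_matrix(self) -> np.ndarray | None:
        if self.uniform_seq_length is None:
            return None
        if "seq_matrix" not in self._cache:
            self._cache["seq_matrix"] = np.vstack([encode_seq(r.seq) for r in self.reads])
        return self._cache["seq_matrix"]

    @property
    def seq_qual_matrix(self) -> np.ndarray | None:
        if self.uniform_seq_length is None:
            return None
        if "seq_quals" not in self._cache:
            self._cache["seq_quals"] = np.vstack([r.quals for r in self.reads])
        return self._cache["seq_quals"]


def _open_text(path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _is_unambiguous(seq: str) -> bool:
    return not (set(seq) - set(BASES))


def load_fastq(
    path,
    umi_length: int,
    drop_ambiguous: bool = True,
    phred_offset: int = 33,
    trim_to: int | None = None,
) -> ReadSet:
    """Load a FASTQ file (plain or gzip) of UMI-prefixed reads.

    Each record is split into its first ``umi_length`` bases (the UMI) and
    the remainder (the sample sequence). Records containing non-ACGT bases
    are dropped when ``drop_ambiguous`` is set; records shorter than the
    UMI (no sample sequence left) are dropped with a warning. Input order
    is preserved.
    """
    if umi_length < 1:
        raise ValueError("umi_length must be >= 1")
    fmt = "fastq" if phred_offset == 33 else "fastq-illumina"
    reads: list[Read] = []
    with _open_text(path) as handle:
        parser = SeqIO.parse(handle, fmt)
        idx = -1
        while True:
            idx += 1
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {idx}: {exc}") from exc
            seq = str(rec.seq).upper()
            quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16)
            if trim_to is not None:
                seq, quals = seq[:trim_to], quals[:trim_to]
            if len(seq) <= umi_length:
                logger.warning(
                    "record %d (%s) shorter than umi_length+1; dropped", idx, rec.id
                )
                continue
            if drop_ambiguous and not _is_unambiguous(seq):
                continue
            reads.append(
                Read(seq[:umi_length], quals[:umi_length], seq[umi_length:], quals[umi_length:])
            )
    return ReadSet(reads, umi_length)


def load_fastq_pair(
    umi_path,
    read_path,
    drop_ambiguous: bool = True,
    phred_offset: int = 33,
    trim_to: int | None = None,
) -> ReadSet:
    """Load the two-file arrangement: UMI FASTQ plus detagged-read FASTQ.

    Records are paired positionally; UMI lengths must agree across records.
    """
    fmt = "fastq" if phred_offset == 33 else "fastq-illumina"
    reads: list[Read] = []
    umi_length = None
    with _open_text(umi_path) as uh, _open_text(read_path) as rh:
        for idx, (urec, rrec) in enumerate(zip(SeqIO.parse(uh, fmt), SeqIO.parse(rh, fmt))):
            umi = str(urec.seq).upper()
            seq = str(rrec.seq).upper()
            uq = np.asarray(urec.letter_annotations["phred_quality"], dtype=np.int16)
            rq = np.asarray(rrec.letter_annotations["phred_quality"], dtype=np.int16)
            if trim_to is not None:
                seq, rq = seq[:trim_to], rq[:trim_to]
            if umi_length is None:
                umi_length = len(umi)
            elif len(umi) != umi_length:
                logger.warning("record %d UMI length differs; dropped", idx)
                continue
            if not seq:
                logger.warning("record %d has empty sample sequence; dropped", idx)
                continue
            if drop_ambiguous and not (_is_unambiguous(umi) and _is_unambiguous(seq)):
                continue
            reads.append(Read(umi, uq, seq, rq))
    if umi_length is None:
        raise ValueError("no records in UMI FASTQ")
    return ReadSet(reads, umi_length)


# ---------------------------------------------------------------------------
# FASTA with ;size= annotations (candidate pools and result haplotypes)
# ---------------------------------------------------------------------------

def write_sized_fasta(path, entries: Iterable[tuple[str, str, int]]) -> None:
    """Write ``(name, sequence, size)`` entries as ``>name;size=N`` FASTA."""
    with open(path, "w") as fh:
        for name, seq, size in entries:
            fh.write(f">{name};size={size}\n{seq}\n")


def read_sized_fasta(path) -> list[tuple[str, str, int]]:
    """Read a ``;size=`` annotated FASTA; size defaults to 1 when absent."""
    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            size = 1
            name = rec.description
            for fieldpart in rec.description.split(";"):
                if fieldpart.startswith("size="):
                    size = int(fieldpart[5:])
                    name = rec.description.split(";")[0]
            out.append((name, str(rec.seq).upper(), size))
    return out


ASSIGNMENT_COLUMNS = ["umi", "haplotype_id", "expected_amplified_count", "gamma"]


def write_results(result, haplotype_fasta, assignment_tsv) -> None:
    """Serialize a fitted :class:`~dedumi.model_em.DedupResult`.

    The FASTA carries per-haplotype deduplicated abundance in the header
    (``>H<k>;size=<dedup_abundance>``); the TSV lists per-UMI haplotype
    assignments with expected amplified counts and transition weights.
    """
    hap_ids = {h: f"H{i + 1}" for i, h in enumerate(result.haplotypes)}
    write_sized_fasta(
        haplotype_fasta,
        [
            (hap_ids[h], h, int(a))
            for h, a in zip(result.haplotypes, result.dedup_abundance)
        ],
    )
    rows = []
    for umi, hap_seq, expected, gamma in result.assignment_rows():
        rows.append(
            {
                "umi": umi,
                "haplotype_id": hap_ids.get(hap_seq, "."),
                "expected_amplified_count": expected,
                "gamma": gamma,
            }
        )
    pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS).to_csv(
        assignment_tsv, sep="\t", index=False
    )


def read_results(haplotype_fasta, assignment_tsv=None):
    """Re-read :func:`write_results` output.

    Returns ``(haplotypes, dedup_abundances, assignments)`` where
    ``assignments`` is a DataFrame (or None).
    """
    entries = read_sized_fasta(haplotype_fasta)
    haps = [seq for _, seq, _ in entries]
    sizes = [size for _, _, size in entries]
    table = pd.read_csv(assignment_tsv, sep="\t") if assignment_tsv else None
    return haps, sizes, table


def write_fastq(path, records: Iterable[tuple[str, str, np.ndarray]], phred_offset: int = 33) -> None:
    """Write ``(id, sequence, phred_quals)`` records as plain FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, quals in records:
            qstr = "".join(chr(int(q) + phred_offset) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")
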