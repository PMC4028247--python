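"""Sequence I/O, quality filtering and a self-contained toy aligner.

Readers accept the plain-text formats the rest of the pipeline consumes:
FASTA proteomes and 12-column tabular all-vs-all similarity.  The toy
Smith-Waterman aligner stands in for an external search tool so tests and
synthetic runs need no binaries on PATH.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable

from Bio import Align, SeqIO

#: Floor applied to all expectation values before log transforms.
EVALUE_FLOOR = 1e-180

TABULAR_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence tagged with its species of origin."""

    id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def stop_fraction(self) -> float:
        """Fraction of '*' characters over the full residue string."""
        return self.residues.count("*") / len(self.residues)


@dataclass(frozen=True)
class QCParams:
    """Thresholds for the sequence quality filter.

    A sequence is dropped when shorter than ``min_length`` residues or when
    its stop-codon fraction strictly exceeds ``max_stop_fraction``.
    """

    min_length: int = 10
    max_stop_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0.0 <= self.max_stop_fraction <= 1.0:
            raise ValueError("max_stop_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise similarity result (BLAST-style tabular row)."""

    query: str
    subject: str
    identity: float
    aln_length: int
    evalue: float
    bitscore: float
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    mismatch: int = 0
    gapopen: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def is_self(self) -> bool:
        return self.query == self.subject


class FastaFormatError(ValueError):
    pass


class TabularFormatError(ValueError):
    pass


def read_fasta(path: str | os.PathLike, species: str) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    The id is the first whitespace-delimited header token; wrapped sequence
    lines are concatenated.  Duplicate ids or empty sequence blocks raise
    :class:`FastaFormatError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"empty sequence block for {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, species=species, residues=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def qc_filter(
    records: Iterable[SequenceRecord],
    params: QCParams | None = None,
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Split records into (kept, dropped-with-reason).

    Reasons: ``"short"`` for length < min_length, ``"stops"`` for stop
    fraction strictly above the threshold.  Length takes precedence when
    both apply.
    """
    params = params or QCParams()
    kept: list[SequenceRecord] = []
    dropped: list[tuple[SequenceRecord, str]] = []
    for rec in records:
        if len(rec) < params.min_length:
            dropped.append((rec, "short"))
        elif rec.stop_fraction > params.max_stop_fraction:
            dropped.append((rec, "stops"))
        else:
            kept.append(rec)
    return kept, dropped


def write_dropped_report(
    dropped: Iterable[tuple[SequenceRecord, str]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("id\tspecies\treason\n")
        for rec, reason in dropped:
            fh.write(f"{rec.id}\t{rec.species}\t{reason}\n")


def read_similarity_tabular(path: str | os.PathLike) -> list[SimilarityHit]:
    """Read 12-column tab-separated similarity (BLAST outfmt-6 layout).

    Malformed lines (wrong column count, non-numeric fields) raise
    :class:`TabularFormatError` naming the 1-based line number.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise TabularFormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hit = SimilarityHit(
                    query=fields[0],
                    subject=fields[1],
                    identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise TabularFormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_similarity_tabular(
    hits: Iterable[SimilarityHit], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.identity:.2f}\t{h.aln_length}\t"
                f"{h.mismatch}\t{h.gapopen}\t{h.qstart}\t{h.qend}\t"
                f"{h.sstart}\t{h.send}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# -- toy local aligner -------------------------------------------------------

#: Scoring scheme: match +2, mismatch -1, linear gap -2.
MATCH_SCORE = 2
MISMATCH_SCORE = -1
GAP_SCORE = -2


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


_ALIGNER = _make_aligner()


def pseudo_evalue(score: float, len_a: int, len_b: int) -> float:
    """E = len(a)*len(b)*2^(-score), floored at ``EVALUE_FLOOR``."""
    log2_e = math.log2(len_a) + math.log2(len_b) - score
    if log2_e < math.log2(EVALUE_FLOOR):
        return EVALUE_FLOOR
    return max(len_a * len_b * 2.0 ** (-score), EVALUE_FLOOR)


def toy_local_similarity(a: SequenceRecord, b: SequenceRecord) -> SimilarityHit:
    """Smith-Waterman local alignment of two records.

    The bitscore is the raw alignment score; the expectation value is a
    pseudo e-value E = len(a)*len(b)*2^(-score), floored at 1e-180.  With no
    positive-scoring local alignment the score is 0 and the alignment
    statistics are empty.
    """
    score = float(_ALIGNER.score(a.residues, b.residues))
    evalue = pseudo_evalue(score, len(a), len(b))
    identity = 0.0
    aln_length = 0
    mismatches = 0
    gaps = 0
    qstart = qend = sstart = send = 0
    if score > 0:
        aln = _ALIGNER.align(a.residues, b.residues)[0]
        counts = aln.counts()
        aln_length = aln.length
        mismatches = counts.mismatches
        gaps = counts.gaps
        identity = 100.0 * counts.identities / aln_length if aln_length else 0.0
        qstart = int(aln.coordinates[0][0]) + 1
        qend = int(aln.coordinates[0][-1])
        sstart = int(aln.coordinates[1][0]) + 1
        send = int(aln.coordinates[1][-1])
    return SimilarityHit(
        query=a.id,
        subject=b.id,
        identity=identity,
        aln_length=aln_length,
        mismatch=mismatches,
        gapopen=gaps,
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        evalue=evalue,
        bitscore=score,
    )
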