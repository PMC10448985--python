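"""Sequence and annotation I/O plus per-nucleotide label tracks.

All coordinates inside the package are 0-based half-open.  GFF3's 1-based
inclusive convention is converted at the reader/writer boundary only, so there
is a single place where off-by-one errors could be introduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SequenceRecord:
    """An identified DNA string over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        extra = set(self.seq) - ALPHABET
        if extra:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside ACGTN: "
                f"{sorted(extra)}; normalize with SequenceRecord.from_raw"
            )

    @classmethod
    def from_raw(cls, rec_id: str, raw: str) -> "SequenceRecord":
        """Build a record from raw text: uppercase, map unknown symbols to N."""
        seq, n_replaced = normalize_sequence(raw)
        if n_replaced:
            logger.warning(
                "sequence %s: %d symbols outside ACGTN mapped to N",
                rec_id, n_replaced,
            )
        return cls(id=rec_id, seq=seq)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(id=self.id, seq=self.seq.translate(_COMPLEMENT)[::-1])


def normalize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase *raw* and map characters outside ACGTN to N.

    Returns the normalized string and the number of replaced characters.
    """
    seq = raw.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    allowed = np.zeros(256, dtype=bool)
    for c in "ACGTN":
        allowed[ord(c)] = True
    bad = ~allowed[arr]
    n_bad = int(bad.sum())
    if n_bad:
        arr = arr.copy()
        arr[bad] = ord("N")
        seq = arr.tobytes().decode("ascii")
    return seq, n_bad


@dataclass
class CdsAnnotation:
    """Union of CDS intervals on one sequence, sorted and merged."""

    seq_id: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_intervals(
        cls, seq_id: str, intervals: list[tuple[int, int]], seq_len: int | None = None
    ) -> "CdsAnnotation":
        merged = merge_intervals(intervals)
        if seq_len is not None:
            for s, e in merged:
                if s < 0 or e > seq_len:
                    raise ValueError(
                        f"CDS interval ({s}, {e}) outside sequence of length {seq_len}"
                    )
        return cls(seq_id=seq_id, intervals=merged)

    def total_coding(self) -> int:
        return sum(e - s for s, e in self.intervals)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and union-merge half-open intervals (adjacent intervals coalesce)."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if s >= e:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class PredictionTrack:
    """Per-nucleotide 0/1 labels with a valid (non-sequestered) range."""

    seq_id: str
    labels: np.ndarray
    valid_start: int
    valid_end: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.valid_start > self.valid_end:
            raise ValueError("valid_start > valid_end")

    def valid_labels(self) -> np.ndarray:
        return self.labels[self.valid_start:self.valid_end]

    def n_valid(self) -> int:
        return self.valid_end - self.valid_start

    def copy_with(self, labels: np.ndarray) -> "PredictionTrack":
        return PredictionTrack(self.seq_id, np.asarray(labels, dtype=np.uint8),
                               self.valid_start, self.valid_end)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into normalized SequenceRecords.

    Sequences are uppercased; symbols outside ACGTN are mapped to N with a
    logged warning count.  Duplicate ids raise.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord.from_raw(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_gff_cds(path, seq_id: str, seq_len: int) -> CdsAnnotation:
    """Collect CDS features for *seq_id* from a GFF3 file.

    Coordinates are converted from 1-based inclusive to 0-based half-open and
    unioned across all transcripts, so nucleotides coding in any alternative
    transcript are labeled coding.
    """
    intervals: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed GFF line "
                    f"({len(fields)} fields, expected 9)"
                )
            if fields[0] != seq_id or fields[2] != "CDS":
                continue
            try:
                start = int(fields[3])
                end = int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 1 or end < start:
                raise ValueError(f"{path}:{lineno}: bad coordinates {start}..{end}")
            if end > seq_len:
                raise ValueError(
                    f"{path}:{lineno}: CDS end {end} exceeds sequence length {seq_len}"
                )
            intervals.append((start - 1, end))
    return CdsAnnotation.from_intervals(seq_id, intervals, seq_len)


def write_gff_cds(annotation: CdsAnnotation, path, source: str = "cdscan") -> None:
    """Write CDS intervals back out as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (s, e) in enumerate(annotation.intervals):
            fh.write(
                f"{annotation.seq_id}\t{source}\tCDS\t{s + 1}\t{e}\t.\t+\t0\t"
                f"ID=cds{i}\n"
            )


def label_nucleotides(
    record: SequenceRecord, annotation: CdsAnnotation, window: int = 69
) -> PredictionTrack:
    """Build the truth PredictionTrack for *record*.

    labels[i] = 1 iff i lies in some CDS interval.  floor(window/2) positions
    at each end are sequestered (excluded from the valid range) because a
    centered sensor window does not fit there.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if annotation.seq_id != record.id:
        raise ValueError(
            f"annotation seq_id {annotation.seq_id!r} != record id {record.id!r}"
        )
    half = window // 2
    n = len(record)
    valid_start, valid_end = half, n - half
    if valid_end <= valid_start:
        raise ValueError(
            f"sequence {record.id!r} of length {n} has no valid positions "
            f"for window {window}"
        )
    labels = np.zeros(n, dtype=np.uint8)
    for s, e in annotation.intervals:
        labels[s:e] = 1
    return PredictionTrack(record.id, labels, valid_start, valid_end)


def write_bed(intervals, path, seq_id: str | None = None) -> None:
    """Write intervals as BED6.  *intervals* may be (start, end) pairs or
    objects with start/end/cds_type/ratio attributes (PotentialCds)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if isinstance(iv, tuple):
                s, e = iv
                name, score, sid = "region", 0, seq_id or "."
            else:
                s, e = iv.start, iv.end
                name = getattr(iv, "cds_type", "region")
                ratio = getattr(iv, "ratio", None)
                if ratio is None or not np.isfinite(ratio):
                    score = 1000
                else:
                    score = min(1000, int(round(100 * ratio)))
                sid = seq_id or getattr(iv, "seq_id", ".")
            fh.write(f"{sid}\t{s}\t{e}\t{name}\t{score}\t+\n")


def write_track_tsv(track: PredictionTrack, path) -> None:
    """Write the valid portion of a track as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write(
            f"# seq_id={track.seq_id} valid_start={track.valid_start} "
            f"valid_end={track.valid_end} length={len(track.labels)}\n"
        )
        fh.write("position\tlabel\n")
        for pos in range(track.valid_start, track.valid_end):
            fh.write(f"{pos}\t{int(track.labels[pos])}\n")


def read_track_tsv(path) -> PredictionTrack:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing track metadata header")
        meta = dict(item.split("=", 1) for item in header[1:].split())
        fh.readline()  # column names
        labels = np.zeros(int(meta["length"]), dtype=np.uint8)
        for line in fh:
            pos_s, lab_s = line.split("\t")
            labels[int(pos_s)] = int(lab_s)
    return PredictionTrack(
        meta["seq_id"], labels, int(meta["valid_start"]), int(meta["valid_end"])
    )
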