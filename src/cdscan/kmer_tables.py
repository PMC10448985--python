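"""Coding/noncoding k-mer frequency weight tables.

A table stores, for every k-mer j over {A,C,G,T}, a coding weight p1(j) and a
noncoding weight p0(j).  Weights are raw counts plus a pseudocount divided by
the total number of bases extracted (not the number of k-mer windows), so they
are frequency weights rather than a normalized probability distribution.  The
sensor score for a k-mer is -ln(p1/p0), which the pseudocount keeps finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_io import CdsAnnotation, SequenceRecord

logger = logging.getLogger(__name__)

VALID_KS = (2, 3, 4, 5, 6)

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A,C,G,T -> 0..3 and N (or other) -> 4."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_index(kmer: str) -> int:
    idx = 0
    for c in kmer:
        code = _BASE_CODE[ord(c)]
        if code > 3:
            raise ValueError(f"k-mer {kmer!r} contains a symbol outside ACGT")
        idx = idx * 4 + int(code)
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def all_kmers(k: int) -> list[str]:
    return [index_to_kmer(i, k) for i in range(4 ** k)]


def corpus_target_bases(k: int) -> int:
    """Base budget per class aimed at 1000:1 statistics: 4^k * k * 1000."""
    return (4 ** k) * k * 1000


@dataclass
class KmerFrequencyTable:
    k: int
    p1: np.ndarray  # coding weights, indexed by kmer_index
    p0: np.ndarray  # noncoding weights
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.k not in VALID_KS:
            raise ValueError(f"k must be in {VALID_KS}, got {self.k}")
        self.p1 = np.asarray(self.p1, dtype=np.float64)
        self.p0 = np.asarray(self.p0, dtype=np.float64)
        n = 4 ** self.k
        if self.p1.shape != (n,) or self.p0.shape != (n,):
            raise ValueError(f"tables must have exactly {n} entries")
        if not (np.all(self.p1 > 0) and np.all(self.p0 > 0)):
            raise ValueError("all frequency weights must be strictly positive")

    def log_ratios(self) -> np.ndarray:
        """Per-k-mer score -ln(p1/p0); finite by construction."""
        return -np.log(self.p1 / self.p0)

    def score(self, kmer: str) -> float:
        return float(self.log_ratios()[kmer_index(kmer)])


def _class_segments(
    records: list[SequenceRecord],
    annotations: list[CdsAnnotation],
) -> tuple[list[str], list[str]]:
    """Split each record into coding (CDS) and noncoding (complement) segments."""
    ann_by_id = {a.seq_id: a for a in annotations}
    coding: list[str] = []
    noncoding: list[str] = []
    for rec in records:
        ann = ann_by_id.get(rec.id)
        ivs = ann.intervals if ann is not None else []
        pos = 0
        for s, e in ivs:
            if s > pos:
                noncoding.append(rec.seq[pos:s])
            coding.append(rec.seq[s:e])
            pos = e
        if pos < len(rec.seq):
            noncoding.append(rec.seq[pos:])
    return coding, noncoding


def count_kmers(segments: list[str], k: int, max_bases: int | None = None
                ) -> tuple[np.ndarray, int]:
    """Count k-mers with a stride-1 window inside each segment separately.

    k-mers containing N are skipped.  Segments are consumed in order until
    *max_bases* bases have been taken (the last segment is truncated to fit).
    Returns (counts indexed by kmer_index, total bases consumed).
    """
    counts = np.zeros(4 ** k, dtype=np.int64)
    total = 0
    for seg in segments:
        if max_bases is not None and total >= max_bases:
            break
        if max_bases is not None and total + len(seg) > max_bases:
            seg = seg[: max_bases - total]
        total += len(seg)
        if len(seg) < k:
            continue
        codes = encode_bases(seg)
        valid = codes[: len(seg) - k + 1] < 4
        idx = np.zeros(len(seg) - k + 1, dtype=np.int64)
        for t in range(k):
            sub = codes[t: t + len(idx)]
            valid &= sub < 4
            idx = idx * 4 + np.where(sub < 4, sub, 0)
        if valid.any():
            counts += np.bincount(idx[valid], minlength=4 ** k)
    return counts, total


def estimate_tables(
    records: list[SequenceRecord],
    annotations: list[CdsAnnotation],
    k: int,
    seed: int | None = None,
    pseudocount: float = 1.0,
    max_bases: int | None = None,
    randomize_segments: bool = False,
) -> KmerFrequencyTable:
    """Estimate p1/p0 weights from labeled sequences.

    Up to 4^k*k*1000 bases (the 1000:1 sufficiency target) are extracted from
    each class; when fewer exist all available bases are used and the shortfall
    is logged.  Weights are (count + pseudocount) / total_bases_extracted.
    """
    if k not in VALID_KS:
        raise ValueError(f"k must be in {VALID_KS}, got {k}")
    if max_bases is None:
        max_bases = corpus_target_bases(k)
    coding, noncoding = _class_segments(records, annotations)
    coding = [s for s in coding if s]
    noncoding = [s for s in noncoding if s]
    if not coding:
        raise ValueError("no coding bases available for k-mer estimation")
    if not noncoding:
        raise ValueError("no noncoding bases available for k-mer estimation")
    if randomize_segments:
        rng = np.random.default_rng(seed)
        coding = [coding[i] for i in rng.permutation(len(coding))]
        noncoding = [noncoding[i] for i in rng.permutation(len(noncoding))]

    tables = []
    for name, segs in (("coding", coding), ("noncoding", noncoding)):
        counts, total = count_kmers(segs, k, max_bases=max_bases)
        if total < max_bases:
            logger.info(
                "k=%d %s corpus shortfall: %d of %d target bases",
                k, name, total, max_bases,
            )
        tables.append((counts + pseudocount) / total)
    return KmerFrequencyTable(k=k, p1=tables[0], p0=tables[1],
                              pseudocount=pseudocount)


DEFAULT_COLUMNS = {"kmer": "kmer", "coding": "coding_freq",
                   "noncoding": "noncoding_freq"}


def load_tables_csv(
    path,
    k: int,
    pseudocount: float = 1.0,
    columns: dict | None = None,
) -> KmerFrequencyTable:
    """Load a k-mer frequency table from CSV (columns kmer, coding_freq,
    noncoding_freq by default; remappable via *columns*).

    Missing k-mers and non-positive entries are filled with a pseudocount-only
    weight of pseudocount / (4^k * k * 1000) and counted in a warning.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path)
    for role in ("kmer", "coding", "noncoding"):
        if cols[role] not in df.columns:
            raise ValueError(f"{path}: missing column {cols[role]!r}")
    n = 4 ** k
    fill = pseudocount / corpus_target_bases(k)
    p1 = np.full(n, fill, dtype=np.float64)
    p0 = np.full(n, fill, dtype=np.float64)
    seen = np.zeros(n, dtype=bool)
    for _, row in df.iterrows():
        kmer = str(row[cols["kmer"]]).strip().upper()
        if len(kmer) != k:
            raise ValueError(f"{path}: k-mer {kmer!r} has length != {k}")
        idx = kmer_index(kmer)  # raises on non-ACGT symbols
        try:
            c1 = float(row[cols["coding"]])
            c0 = float(row[cols["noncoding"]])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric frequency for {kmer}") from exc
        if np.isnan(c1) or np.isnan(c0):
            raise ValueError(f"{path}: non-numeric frequency for {kmer}")
        p1[idx] = c1 if c1 > 0 else fill
        p0[idx] = c0 if c0 > 0 else fill
        seen[idx] = True
    n_missing = int((~seen).sum())
    if n_missing:
        logger.warning(
            "%s: %d of %d k-mers missing, filled with pseudocount-only weight",
            path, n_missing, n,
        )
    return KmerFrequencyTable(k=k, p1=p1, p0=p0, pseudocount=pseudocount)


def save_tables_csv(table: KmerFrequencyTable, path) -> None:
    df = pd.DataFrame({
        "kmer": all_kmers(table.k),
        "coding_freq": table.p1,
        "noncoding_freq": table.p0,
    })
    df.to_csv(path, index=False)
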