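"""The 16 per-nucleotide sensor features over a centered window of W bases.

Feature order (fixed, also the TSV column order):

    dft, kmer2, kmer3, kmer4, kmer5, kmer6, gc,
    start_right, start_left, stop_right, stop_left,
    acc_right, acc_left, don_right, don_left, entropy

Scalar functions (``sensor_*``) operate on a single window string and serve
as the reference semantics; :func:`featurize_track` computes the same values
for every valid position of a sequence with vectorized sliding-window code.

N handling: N zeroes its Voss column, skips any k-mer containing it, is
excluded from the GC numerator and denominator, breaks motif matches, but
still counts toward the fixed window length W in the entropy base
probabilities P(b) = n_b / W.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmer_tables import KmerFrequencyTable, encode_bases
from .sequence_io import SequenceRecord

FEATURE_NAMES = (
    "dft", "kmer2", "kmer3", "kmer4", "kmer5", "kmer6", "gc",
    "start_right", "start_left", "stop_right", "stop_left",
    "acc_right", "acc_left", "don_right", "don_left", "entropy",
)
N_FEATURES = len(FEATURE_NAMES)

MOTIF_FAMILIES = {
    "start": ("ATG",),
    "stop": ("TAG", "TAA", "TGA"),
    "acceptor": ("CAG", "TAG"),  # YAG with Y in {C, T}
    "donor": ("GT",),
}


@dataclass
class SensorConfig:
    window: int = 69
    kmer_ks: tuple[int, ...] = (2, 3, 4, 5, 6)
    entropy_variant: str = "as_printed"  # or "standard"
    # True: sum over all W-k+1 k-mer positions in the window; False: only the
    # first W-k-1 positions (the literal summation limit; see docs).
    full_kmer_coverage: bool = True

    def __post_init__(self) -> None:
        w = self.window
        if w % 2 == 0 or w < 3:
            raise ValueError(f"window must be odd and >= 3, got {w}")
        if w % 3 != 0:
            raise ValueError(
                f"window must be divisible by 3 for the period-3 DFT, got {w}"
            )
        if self.entropy_variant not in ("as_printed", "standard"):
            raise ValueError(f"unknown entropy variant {self.entropy_variant!r}")


@dataclass
class FeatureMatrix:
    """Per-valid-position 16-component sensor vectors for one sequence."""

    seq_id: str
    positions: np.ndarray
    values: np.ndarray  # shape (n_positions, 16)
    seq_len: int
    window: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.positions), N_FEATURES):
            raise ValueError("values must have one 16-vector per position")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# seq_id={self.seq_id} seq_len={self.seq_len} "
                f"window={self.window}\n"
            )
            fh.write("position\t" + "\t".join(FEATURE_NAMES) + "\n")
            for pos, row in zip(self.positions, self.values):
                fh.write(str(int(pos)) + "\t" +
                         "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing metadata header")
            meta = dict(item.split("=", 1) for item in header[1:].split())
            names = fh.readline().strip().split("\t")[1:]
            if tuple(names) != FEATURE_NAMES:
                raise ValueError(f"{path}: unexpected feature columns {names}")
            positions, rows = [], []
            for line in fh:
                parts = line.split("\t")
                positions.append(int(parts[0]))
                rows.append([float(v) for v in parts[1:]])
        return cls(meta["seq_id"], np.array(positions, dtype=np.int64),
                   np.array(rows, dtype=np.float64),
                   int(meta["seq_len"]), int(meta["window"]))


# ---------------------------------------------------------------------------
# scalar reference sensors
# ---------------------------------------------------------------------------

def voss_encode(window_seq: str) -> np.ndarray:
    """Binary indicator stack, rows ordered A, T, G, C; N gives a null column."""
    codes = encode_bases(window_seq)  # A,C,G,T -> 0..3, N -> 4
    out = np.zeros((4, len(window_seq)), dtype=np.int8)
    for row, code in enumerate((0, 3, 2, 1)):  # A, T, G, C
        out[row] = codes == code
    return out


def sensor_dft(window_seq: str) -> float:
    """Period-3 DFT magnitude summed over the four Voss tracks."""
    w = len(window_seq)
    if w % 3 != 0:
        raise ValueError(f"window length must be divisible by 3, got {w}")
    x = voss_encode(window_seq)
    phase = np.exp(-2j * np.pi * np.arange(w) / 3.0)
    return float(np.abs(x @ phase).sum())


def sensor_kmer(window_seq: str, table: KmerFrequencyTable,
                full_coverage: bool = True) -> float:
    """Sum of -ln(p1/p0) over the k-mers in the window, sliding one base at a
    time.  k-mers containing N contribute 0."""
    k = table.k
    w = len(window_seq)
    if w < k:
        raise ValueError(f"window shorter than k={k}")
    scores = table.log_ratios()
    n_pos = w - k + 1 if full_coverage else max(0, w - k - 1)
    total = 0.0
    for i in range(n_pos):
        kmer = window_seq[i:i + k]
        if "N" in kmer:
            continue
        idx = 0
        for c in kmer:
            idx = idx * 4 + "ACGT".index(c)
        total += scores[idx]
    return total


def sensor_gc(window_seq: str) -> float:
    """GC fraction of the window; N excluded; empty denominator -> 0."""
    n_gc = sum(1 for c in window_seq if c in "GC")
    n_acgt = sum(1 for c in window_seq if c in "ACGT")
    return n_gc / n_acgt if n_acgt else 0.0


def sensor_motif_distance(window_seq: str, motif_family: str, side: str) -> float:
    """Distance feature max(W/2 - D, 0) to the nearest motif on one side.

    D is counted from the window center to the motif's first base.  A motif
    whose first base is at the center counts to the right with D = 0; left-side
    distances start at D = 1.  Motifs must lie fully inside the window; if no
    motif is found on the requested side the feature is 0.
    """
    motifs = MOTIF_FAMILIES[motif_family]
    w = len(window_seq)
    if w % 2 == 0:
        raise ValueError("window length must be odd")
    center = w // 2
    best_d = None
    for m in motifs:
        start = 0
        while True:
            p = window_seq.find(m, start)
            if p < 0:
                break
            start = p + 1
            if side == "right" and p >= center:
                d = p - center
            elif side == "left" and p < center:
                d = center - p
            else:
                continue
            if best_d is None or d < best_d:
                best_d = d
    if best_d is None:
        return 0.0
    return max(w / 2.0 - best_d, 0.0)


def sensor_entropy(window_seq: str, variant: str = "as_printed") -> float:
    """Window base entropy with P(b) = n_b / W (N counts in W, not as a base).

    as_printed: -(1/W) * sum_b n_b * P(b) * ln P(b)
    standard:   -sum_b P(b) * ln P(b)
    """
    w = len(window_seq)
    total = 0.0
    for b in "ATGC":
        nb = window_seq.count(b)
        if nb == 0:
            continue
        p = nb / w
        if variant == "as_printed":
            total += nb * p * np.log(p)
        elif variant == "standard":
            total += p * np.log(p)
        else:
            raise ValueError(f"unknown entropy variant {variant!r}")
    if variant == "as_printed":
        total /= w
    return -total


# ---------------------------------------------------------------------------
# vectorized whole-track featurization
# ---------------------------------------------------------------------------

def _window_sums(values: np.ndarray, width: int) -> np.ndarray:
    """Sliding-window sums: out[s] = sum(values[s : s + width])."""
    return np.convolve(values, np.ones(width, dtype=values.dtype), mode="valid")


def _dft_column(codes: np.ndarray, w: int) -> np.ndarray:
    phase = np.exp(-2j * np.pi * np.arange(w) / 3.0)
    kernel = phase[::-1]
    total = None
    for code in (0, 1, 2, 3):
        track = (codes == code).astype(np.float64)
        mag = np.abs(np.convolve(track, kernel, mode="valid"))
        total = mag if total is None else total + mag
    return total


def _kmer_column(codes: np.ndarray, table: KmerFrequencyTable, w: int,
                 full_coverage: bool) -> np.ndarray:
    k = table.k
    n = len(codes)
    n_kpos = n - k + 1
    idx = np.zeros(n_kpos, dtype=np.int64)
    valid = np.ones(n_kpos, dtype=bool)
    for t in range(k):
        sub = codes[t: t + n_kpos]
        valid &= sub < 4
        idx = idx * 4 + np.where(sub < 4, sub, 0)
    scores = np.where(valid, table.log_ratios()[idx], 0.0)
    width = w - k + 1 if full_coverage else w - k - 1
    return _window_sums(scores, width)[: n - w + 1]


def motif_positions(seq: str, motif_family: str) -> np.ndarray:
    """Sorted start positions of all occurrences of a motif family."""
    codes = encode_bases(seq)
    hits = np.zeros(len(seq), dtype=bool)
    for m in MOTIF_FAMILIES[motif_family]:
        mc = encode_bases(m)
        lm = len(mc)
        if len(seq) < lm:
            continue
        match = np.ones(len(seq) - lm + 1, dtype=bool)
        for t, c in enumerate(mc):
            match &= codes[t: t + len(match)] == c
        hits[: len(match)] |= match
    return np.flatnonzero(hits)


def _distance_columns(seq: str, centers: np.ndarray, w: int
                      ) -> dict[str, np.ndarray]:
    """Vectorized motif-distance features, one (family, side) pair each."""
    half = w // 2
    out: dict[str, np.ndarray] = {}
    for family, short in (("start", "start"), ("stop", "stop"),
                          ("acceptor", "acc"), ("donor", "don")):
        motif_len = len(MOTIF_FAMILIES[family][0])
        pos = motif_positions(seq, family)
        # nearest motif start >= center
        i = np.searchsorted(pos, centers, side="left")
        d_right = np.full(len(centers), np.inf)
        has = i < len(pos)
        d_right[has] = pos[i[has]] - centers[has]
        d_right[d_right > half - motif_len + 1] = np.inf
        out[f"{short}_right"] = np.where(
            np.isfinite(d_right), np.maximum(w / 2.0 - d_right, 0.0), 0.0)
        # nearest motif start < center
        j = np.searchsorted(pos, centers, side="left") - 1
        d_left = np.full(len(centers), np.inf)
        has = j >= 0
        d_left[has] = centers[has] - pos[j[has]]
        d_left[d_left > half] = np.inf
        out[f"{short}_left"] = np.where(
            np.isfinite(d_left), np.maximum(w / 2.0 - d_left, 0.0), 0.0)
    return out


def featurize_track(
    record: SequenceRecord,
    config: SensorConfig,
    tables: dict[int, KmerFrequencyTable],
) -> FeatureMatrix:
    """Compute all 16 sensors with the window centered at each valid position."""
    w = config.window
    n = len(record)
    if n < w:
        raise ValueError(
            f"sequence {record.id!r} of length {n} shorter than window {w}"
        )
    for k in config.kmer_ks:
        if k not in tables:
            raise ValueError(f"missing k-mer table for k={k}")
    half = w // 2
    centers = np.arange(half, n - half, dtype=np.int64)
    codes = encode_bases(record.seq)

    cols: dict[str, np.ndarray] = {}
    cols["dft"] = _dft_column(codes, w)
    for k in config.kmer_ks:
        cols[f"kmer{k}"] = _kmer_column(codes, tables[k], w,
                                        config.full_kmer_coverage)

    is_gc = ((codes == 1) | (codes == 2)).astype(np.int64)
    is_acgt = (codes < 4).astype(np.int64)
    n_gc = _window_sums(is_gc.astype(np.float64), w)
    n_acgt = _window_sums(is_acgt.astype(np.float64), w)
    cols["gc"] = np.where(n_acgt > 0, n_gc / np.maximum(n_acgt, 1), 0.0)

    cols.update(_distance_columns(record.seq, centers, w))

    ent = np.zeros(len(centers))
    for code in (0, 1, 2, 3):
        nb = _window_sums((codes == code).astype(np.float64), w)
        p = nb / w
        term = np.where(nb > 0, p * np.log(np.where(nb > 0, p, 1.0)), 0.0)
        if config.entropy_variant == "as_printed":
            ent -= nb * term / w
        else:
            ent -= term
    cols["entropy"] = ent

    values = np.column_stack([cols[name] for name in FEATURE_NAMES])
    return FeatureMatrix(record.id, centers, values, seq_len=n, window=w)


def featurize_window(window_seq: str, config: SensorConfig,
                     tables: dict[int, KmerFrequencyTable]) -> np.ndarray:
    """Scalar-path 16-vector for a single window (reference implementation)."""
    if len(window_seq) != config.window:
        raise ValueError("window string has wrong length")
    vals = [sensor_dft(window_seq)]
    for k in config.kmer_ks:
        vals.append(sensor_kmer(window_seq, tables[k],
                                config.full_kmer_coverage))
    vals.append(sensor_gc(window_seq))
    for family in ("start", "stop", "acceptor", "donor"):
        for side in ("right", "left"):
            vals.append(sensor_motif_distance(window_seq, family, side))
    vals.append(sensor_entropy(window_seq, config.entropy_variant))
    return np.array(vals, dtype=np.float64)
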