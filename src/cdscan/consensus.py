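"""Motif-bounded CDS consensus post-processing of initial predictions.

A potential CDS is any interval bounded by a legal left motif (ATG start or
YAG acceptor) and right motif (GT donor or TAG/TAA/TGA stop), with interior
length strictly between lmin and lmax.  Interior conventions:

    single   : ATG ... stop   interior = [atg, stop + 3)
    start    : ATG ... GT     interior = [atg, gt)
    internal : YAG ... GT     interior = [yag + 3, gt)
    end      : YAG ... stop   interior = [yag + 3, stop + 3)

i.e. start/stop codons are inside the scored span while splice dinucleotides
lie outside, matching standard CDS conventions.

Candidates are tested longest-first.  A candidate is accepted when its
N1/N0 ratio over the initial predictions strictly exceeds the threshold and
it is not contained in an already accepted region; candidates contained in an
accepted region are never tested.  The adjusted track is 1 exactly on the
union of accepted interiors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .sequence_io import PredictionTrack

logger = logging.getLogger(__name__)

CDS_TYPES = ("single", "start", "internal", "end")
_STOP_LEN = 3
_YAG_LEN = 3


def default_threshold_grid() -> list[float]:
    """0.5 .. 1.0 by 0.1, then 1.5, then the integers 2 .. 30."""
    grid = [round(0.5 + 0.1 * i, 1) for i in range(6)]
    grid.append(1.5)
    grid.extend(float(t) for t in range(2, 31))
    return grid


@dataclass
class ConsensusConfig:
    lmin: int = 40
    lmax: int = 400
    threshold: float = 1.0
    threshold_grid: list[float] = field(default_factory=default_threshold_grid)
    target_coding_fraction: float | None = None
    fraction_margin: float = 0.1

    def __post_init__(self) -> None:
        if self.lmin >= self.lmax:
            raise ValueError("lmin must be < lmax")
        if any(b <= a for a, b in zip(self.threshold_grid,
                                      self.threshold_grid[1:])):
            raise ValueError("threshold_grid must be strictly increasing")


@dataclass
class MotifIndex:
    starts: np.ndarray     # ATG start positions
    stops: np.ndarray      # TAG/TAA/TGA start positions
    acceptors: np.ndarray  # YAG start positions
    donors: np.ndarray     # GT start positions


@dataclass
class PotentialCds:
    start: int
    end: int
    cds_type: str
    left_motif: tuple[str, int]
    right_motif: tuple[str, int]
    n1: int | None = None
    n0: int | None = None
    ratio: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_motifs(seq: str) -> MotifIndex:
    """Locate every boundary motif occurrence; motifs containing N never match."""
    from .sensors import motif_positions

    return MotifIndex(
        starts=motif_positions(seq, "start"),
        stops=motif_positions(seq, "stop"),
        acceptors=motif_positions(seq, "acceptor"),
        donors=motif_positions(seq, "donor"),
    )


_TYPE_CODE = {t: i for i, t in enumerate(CDS_TYPES)}


def _enumerate_arrays(seq: str, config: ConsensusConfig,
                      motifs: MotifIndex | None = None):
    """All candidates as parallel arrays sorted by (length desc, start asc,
    type).  Returns (start, end, type_code, left_pos, right_pos)."""
    if motifs is None:
        motifs = scan_motifs(seq)
    lmin, lmax = config.lmin, config.lmax
    starts_l: list[np.ndarray] = []
    ends_l: list[np.ndarray] = []
    types_l: list[np.ndarray] = []
    lpos_l: list[np.ndarray] = []
    rpos_l: list[np.ndarray] = []

    # (interior start array, right motif array, interior-end offset, type)
    combos = (
        (motifs.starts, motifs.starts, motifs.stops, _STOP_LEN, "single"),
        (motifs.starts, motifs.starts, motifs.donors, 0, "start"),
        (motifs.acceptors + _YAG_LEN, motifs.acceptors, motifs.donors, 0,
         "internal"),
        (motifs.acceptors + _YAG_LEN, motifs.acceptors, motifs.stops,
         _STOP_LEN, "end"),
    )
    for int_starts, left_pos, right_arr, end_off, cds_type in combos:
        if len(int_starts) == 0 or len(right_arr) == 0:
            continue
        interior_ends = right_arr + end_off
        # interior end e must satisfy lmin < e - s < lmax (strict)
        lo = np.searchsorted(interior_ends, int_starts + lmin + 1, side="left")
        hi = np.searchsorted(interior_ends, int_starts + lmax, side="left")
        counts = hi - lo
        keep = counts > 0
        if not keep.any():
            continue
        reps = counts[keep]
        s_rep = np.repeat(int_starts[keep], reps)
        l_rep = np.repeat(left_pos[keep], reps)
        idx = np.concatenate(
            [np.arange(a, b) for a, b in zip(lo[keep], hi[keep])]
        )
        e_rep = interior_ends[idx]
        starts_l.append(s_rep)
        ends_l.append(e_rep)
        types_l.append(np.full(len(s_rep), _TYPE_CODE[cds_type],
                               dtype=np.int64))
        lpos_l.append(l_rep)
        rpos_l.append(right_arr[idx])

    if not starts_l:
        empty = np.zeros(0, dtype=np.int64)
        return empty, empty, empty, empty, empty
    start = np.concatenate(starts_l)
    end = np.concatenate(ends_l)
    tcode = np.concatenate(types_l)
    lpos = np.concatenate(lpos_l)
    rpos = np.concatenate(rpos_l)
    order = np.lexsort((tcode, start, -(end - start)))
    return start[order], end[order], tcode[order], lpos[order], rpos[order]


_LEFT_NAME = {"single": "ATG", "start": "ATG", "internal": "YAG", "end": "YAG"}
_RIGHT_NAME = {"single": "stop", "start": "GT", "internal": "GT", "end": "stop"}


def _to_candidates(arrays) -> list[PotentialCds]:
    start, end, tcode, lpos, rpos = arrays
    out = []
    for s, e, t, lp, rp in zip(start, end, tcode, lpos, rpos):
        cds_type = CDS_TYPES[t]
        out.append(PotentialCds(
            start=int(s), end=int(e), cds_type=cds_type,
            left_motif=(_LEFT_NAME[cds_type], int(lp)),
            right_motif=(_RIGHT_NAME[cds_type], int(rp)),
        ))
    return out


def enumerate_potential_cds(seq: str, config: ConsensusConfig,
                            motifs: MotifIndex | None = None
                            ) -> list[PotentialCds]:
    """All motif-bounded candidates with lmin < L < lmax, sorted by length
    descending (ties: start ascending, then type)."""
    return _to_candidates(_enumerate_arrays(seq, config, motifs))


def score_region(region: PotentialCds, initial: PredictionTrack) -> PotentialCds:
    """Fill n1/n0/ratio by counting initial labels over the interior.

    Interiors reaching outside the valid range are scored on the overlap only.
    """
    s = max(region.start, initial.valid_start)
    e = min(region.end, initial.valid_end)
    if s != region.start or e != region.end:
        logger.debug("region (%d, %d) clipped to valid range (%d, %d)",
                     region.start, region.end, s, e)
    overlap = max(0, e - s)
    n1 = int(initial.labels[s:e].sum()) if overlap else 0
    n0 = overlap - n1
    ratio = np.inf if n0 == 0 and n1 > 0 else (n1 / n0 if n0 else 0.0)
    return replace(region, n1=n1, n0=n0, ratio=ratio)


class _PrefixMaxTree:
    """Fenwick tree over interval start positions supporting
    'max end among accepted intervals with start <= s'."""

    def __init__(self, n: int):
        self.n = n + 1
        self.tree = np.full(self.n + 1, -1, dtype=np.int64)

    def insert(self, start: int, end: int) -> None:
        i = start + 1
        while i <= self.n:
            if self.tree[i] < end:
                self.tree[i] = end
            i += i & (-i)

    def query(self, start: int) -> int:
        i = start + 1
        best = -1
        while i > 0:
            if self.tree[i] > best:
                best = self.tree[i]
            i -= i & (-i)
        return best


def _cum_labels(initial: PredictionTrack) -> np.ndarray:
    cum = np.zeros(len(initial.labels) + 1, dtype=np.int64)
    cum[1:] = np.cumsum(initial.labels)
    return cum


def adjust_predictions(
    seq: str,
    initial: PredictionTrack,
    config: ConsensusConfig,
    candidates=None,
) -> tuple[PredictionTrack, list[PotentialCds]]:
    """Apply the consensus rule at config.threshold.

    Returns the adjusted track (1 exactly on the union of accepted interiors)
    and the accepted candidates in acceptance order.  *candidates* may carry a
    precomputed ``_enumerate_arrays`` result to share work across thresholds.
    """
    if candidates is None:
        candidates = _enumerate_arrays(seq, config)
    start, end, tcode, lpos, rpos = candidates
    threshold = config.threshold

    cum = _cum_labels(initial)
    vs, ve = initial.valid_start, initial.valid_end
    s_c = np.clip(start, vs, ve)
    e_c = np.clip(end, vs, ve)
    overlap = np.maximum(e_c - s_c, 0)
    n1 = cum[e_c] - cum[s_c]
    n0 = overlap - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n0 > 0, n1 / np.maximum(n0, 1),
                         np.where(n1 > 0, np.inf, 0.0))
    passing = ratio > threshold

    tree = _PrefixMaxTree(len(seq))
    accepted: list[PotentialCds] = []
    for i in np.flatnonzero(passing):
        s, e = int(start[i]), int(end[i])
        if tree.query(s) >= e:  # contained in an accepted region: skip
            continue
        tree.insert(s, e)
        cds_type = CDS_TYPES[tcode[i]]
        accepted.append(PotentialCds(
            start=s, end=e, cds_type=cds_type,
            left_motif=(_LEFT_NAME[cds_type], int(lpos[i])),
            right_motif=(_RIGHT_NAME[cds_type], int(rpos[i])),
            n1=int(n1[i]), n0=int(n0[i]), ratio=float(ratio[i]),
        ))

    labels = np.zeros(len(initial.labels), dtype=np.uint8)
    for reg in accepted:
        labels[reg.start:reg.end] = 1
    return initial.copy_with(labels), accepted


def coding_fraction(track: PredictionTrack) -> float:
    """Fraction of valid positions labeled 1."""
    n = track.n_valid()
    if n == 0:
        raise ValueError("track has an empty valid range")
    return float(track.valid_labels().sum()) / n


@dataclass
class SweepResult:
    threshold: float
    adjusted: PredictionTrack
    accepted: list[PotentialCds]
    trajectory: list[tuple[float, float]]
    exhausted: bool = False


def fraction_targeted_sweep(
    seq: str,
    initial: PredictionTrack,
    config: ConsensusConfig,
) -> SweepResult:
    """Increase the threshold along the grid until the adjusted coding
    fraction drops to target + margin; exhaustion returns the grid maximum
    with a warning."""
    if config.target_coding_fraction is None:
        raise ValueError("target_coding_fraction must be set for the sweep")
    if not config.threshold_grid:
        raise ValueError("threshold_grid is empty")
    limit = config.target_coding_fraction + config.fraction_margin
    arrays = _enumerate_arrays(seq, config)
    trajectory: list[tuple[float, float]] = []
    last = None
    for th in config.threshold_grid:
        cfg = replace(config, threshold=th)
        adjusted, accepted = adjust_predictions(seq, initial, cfg, arrays)
        frac = coding_fraction(adjusted)
        trajectory.append((th, frac))
        last = SweepResult(th, adjusted, accepted, list(trajectory))
        if frac <= limit:
            return last
    logger.warning(
        "threshold sweep exhausted: fraction %.4f above target %.4f + margin "
        "%.4f at grid maximum %.3g",
        trajectory[-1][1], config.target_coding_fraction,
        config.fraction_margin, config.threshold_grid[-1],
    )
    last.exhausted = True
    return last
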