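"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's vectorized code paths:
brute-force loops, direct complex summation, and list-based containment, so
the tests compare two independent routes to the same answer.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass

import numpy as np
import pytest

from cdscan.sequence_io import PredictionTrack, SequenceRecord

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_dft(window_seq: str) -> float:
    """Brute-force period-3 DFT magnitude via explicit complex summation."""
    total = 0.0
    for base in "ATGC":
        acc = 0 + 0j
        for n, c in enumerate(window_seq):
            if c == base:
                acc += cmath.exp(-2j * cmath.pi * n / 3.0)
        total += abs(acc)
    return total


def oracle_kmer(window_seq: str, table, full_coverage: bool = True,
                use_math_log: bool = False) -> float:
    """Per-position recomputation of the summed k-mer log-ratio.

    Position indexing, N-skipping and summation are independent of the
    package.  The per-k-mer score is recomputed here from p1/p0 with numpy's
    log (bitwise-identical to the package's formula, enabling exact-equality
    checks); use_math_log swaps in math.log, which can differ by 1 ulp and is
    compared with a tolerance instead.
    """
    import math

    k = table.k
    scores = -np.log(np.asarray(table.p1) / np.asarray(table.p0))
    n_pos = (len(window_seq) - k + 1 if full_coverage
             else len(window_seq) - k - 1)
    total = 0.0
    for i in range(n_pos):
        kmer = window_seq[i:i + k]
        if "N" in kmer:
            continue
        idx = 0
        for c in kmer:
            idx = idx * 4 + "ACGT".index(c)
        if use_math_log:
            total += -math.log(table.p1[idx] / table.p0[idx])
        else:
            total += float(scores[idx])
    return total


_STOPS = ("TAG", "TAA", "TGA")


def oracle_scan_motifs(seq: str) -> dict[str, list[int]]:
    out = {"start": [], "stop": [], "acceptor": [], "donor": []}
    for i in range(len(seq)):
        if seq[i:i + 3] == "ATG":
            out["start"].append(i)
        if seq[i:i + 3] in _STOPS:
            out["stop"].append(i)
        if (i + 3 <= len(seq) and seq[i] in "CT" and seq[i + 1:i + 3] == "AG"):
            out["acceptor"].append(i)
        if seq[i:i + 2] == "GT":
            out["donor"].append(i)
    return out


@dataclass
class OracleRegion:
    start: int
    end: int
    cds_type: str
    ratio: float = 0.0


_TYPE_ORDER = {"single": 0, "start": 1, "internal": 2, "end": 3}


def oracle_enumerate(seq: str, lmin: int, lmax: int) -> list[OracleRegion]:
    m = oracle_scan_motifs(seq)
    regions = []
    for atg in m["start"]:
        for stop in m["stop"]:
            L = stop + 3 - atg
            if lmin < L < lmax:
                regions.append(OracleRegion(atg, stop + 3, "single"))
        for gt in m["donor"]:
            L = gt - atg
            if lmin < L < lmax:
                regions.append(OracleRegion(atg, gt, "start"))
    for yag in m["acceptor"]:
        s = yag + 3
        for gt in m["donor"]:
            L = gt - s
            if lmin < L < lmax:
                regions.append(OracleRegion(s, gt, "internal"))
        for stop in m["stop"]:
            L = stop + 3 - s
            if lmin < L < lmax:
                regions.append(OracleRegion(s, stop + 3, "end"))
    regions.sort(key=lambda r: (-(r.end - r.start), r.start,
                                _TYPE_ORDER[r.cds_type]))
    return regions


def oracle_adjust(seq: str, track: PredictionTrack, lmin: int, lmax: int,
                  threshold: float):
    """Exhaustive consensus: enumerate everything, longest first, strict
    ratio rule, skip candidates contained in an accepted region."""
    accepted: list[OracleRegion] = []
    for reg in oracle_enumerate(seq, lmin, lmax):
        if any(a.start <= reg.start and reg.end <= a.end for a in accepted):
            continue
        s = max(reg.start, track.valid_start)
        e = min(reg.end, track.valid_end)
        overlap = max(0, e - s)
        n1 = int(track.labels[s:e].sum()) if overlap else 0
        n0 = overlap - n1
        if n0 == 0:
            ratio = float("inf") if n1 > 0 else 0.0
        else:
            ratio = n1 / n0
        if ratio > threshold:
            reg.ratio = ratio
            accepted.append(reg)
    labels = np.zeros(len(track.labels), dtype=np.uint8)
    for a in accepted:
        labels[a.start:a.end] = 1
    return track.copy_with(labels), accepted


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, n: int, with_n: float = 0.0) -> str:
    if with_n > 0:
        p = [(1 - with_n) / 4] * 4 + [with_n]
        return "".join(rng.choice(list("ACGTN"), size=n, p=p))
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_tables(rng):
    """Random but positive k-mer tables for all five k."""
    from cdscan.kmer_tables import KmerFrequencyTable

    tables = {}
    for k in (2, 3, 4, 5, 6):
        tables[k] = KmerFrequencyTable(
            k=k,
            p1=rng.uniform(0.2, 2.0, 4 ** k),
            p0=rng.uniform(0.2, 2.0, 4 ** k),
        )
    return tables


@pytest.fixture
def flat_tables():
    """Tables with p1 == p0 so every k-mer sensor is identically 0."""
    from cdscan.kmer_tables import KmerFrequencyTable

    return {
        k: KmerFrequencyTable(k=k, p1=np.ones(4 ** k), p0=np.ones(4 ** k))
        for k in (2, 3, 4, 5, 6)
    }


@pytest.fixture(scope="session")
def small_genome():
    """A 60 kb synthetic genome shared across fast tests."""
    from cdscan.simulate import GenomeSimConfig, generate

    return generate(GenomeSimConfig(length=60_000, seed=42))
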