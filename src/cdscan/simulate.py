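"""Synthetic genome fixtures: planted multi-exon genes with legal boundary
motifs and a tunable compositional contrast between coding and noncoding DNA.

Grammar of a planted gene (forward strand):

    single-exon : ATG + sense codons + stop
    first exon  : ATG + body            | intron: GT ... YAG
    internal    : body                  | flanked by YAG on the left
    last exon   : body + stop           |          and GT on the right

Splice motifs live in the intronic flanks, so every planted exon interior is
exactly a motif-bounded candidate of the consensus module.  Coding bodies are
drawn from a codon model interpolated between the noncoding background and a
fixed skewed usage table by ``codon_bias_strength``; at strength 0 coding
composition is the background itself, so the genome carries no coding signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_io import CdsAnnotation, SequenceRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
_ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
SENSE_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]

# Fixed skewed codon-usage table: a reproducible strong bias, independent of
# the per-genome seed so that "bias strength" means the same thing everywhere.
_skew_rng = np.random.default_rng(421)
SKEWED_CODON_WEIGHTS = np.exp(1.8 * _skew_rng.standard_normal(len(SENSE_CODONS)))
SKEWED_CODON_WEIGHTS /= SKEWED_CODON_WEIGHTS.sum()


@dataclass
class GenomeSimConfig:
    length: int = 100_000
    target_coding_fraction: float = 0.2
    exon_len_range: tuple[int, int] = (40, 400)
    exons_per_gene: tuple[int, int] = (1, 6)
    intron_len_range: tuple[int, int] = (50, 200)
    codon_bias_strength: float = 0.8
    gc_noncoding: float = 0.5
    min_intergenic_gap: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.codon_bias_strength <= 1.0:
            raise ValueError("codon_bias_strength must be in [0, 1]")
        if not 0.0 < self.target_coding_fraction < 1.0:
            raise ValueError("target_coding_fraction must be in (0, 1)")
        if self.exon_len_range[0] < 9:
            raise ValueError("minimum exon length must be >= 9")
        if self.intron_len_range[0] < 6:
            raise ValueError("introns must be >= 6 nt to hold GT...YAG flanks")


def _background_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T


def codon_distribution(config: GenomeSimConfig) -> np.ndarray:
    """Sense-codon probabilities interpolated between the background-composition
    codon model and the fixed skewed usage table."""
    bg = _background_probs(config.gc_noncoding)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    bprobs = np.array([
        bg[base_idx[c[0]]] * bg[base_idx[c[1]]] * bg[base_idx[c[2]]]
        for c in SENSE_CODONS
    ])
    bprobs /= bprobs.sum()
    s = config.codon_bias_strength
    return (1 - s) * bprobs + s * SKEWED_CODON_WEIGHTS


@dataclass
class _GeneDraft:
    seq: str
    exon_spans: list[tuple[int, int]]  # relative to gene start; includes ATG/stop

    @property
    def coding(self) -> int:
        return sum(e - s for s, e in self.exon_spans)


class GenomeSimulator:
    def __init__(self, config: GenomeSimConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self._codon_p = codon_distribution(config)
        self._bg_p = _background_probs(config.gc_noncoding)

    # -- low-level emitters -------------------------------------------------

    def _background(self, n: int) -> str:
        if n <= 0:
            return ""
        return "".join(
            np.array(list(BASES))[self.rng.choice(4, size=n, p=self._bg_p)])

    def _codons(self, n: int) -> str:
        idx = self.rng.choice(len(SENSE_CODONS), size=n, p=self._codon_p)
        return "".join(SENSE_CODONS[i] for i in idx)

    def _body(self, n: int) -> str:
        """Exon body of n bases (no boundary motifs)."""
        if n <= 0:
            return ""
        if self.config.codon_bias_strength == 0.0:
            return self._background(n)
        return self._codons(-(-n // 3))[:n]

    def _stop(self) -> str:
        return STOP_CODONS[self.rng.integers(3)]

    def _intron(self) -> str:
        lo, hi = self.config.intron_len_range
        n = int(self.rng.integers(lo, hi + 1))
        y = "CT"[self.rng.integers(2)]
        return "GT" + self._background(n - 5) + y + "AG"

    # -- gene assembly ------------------------------------------------------

    def _draw_gene(self) -> _GeneDraft:
        cfg = self.config
        n_exons = int(self.rng.integers(cfg.exons_per_gene[0],
                                        cfg.exons_per_gene[1] + 1))
        lens = self.rng.integers(cfg.exon_len_range[0],
                                 cfg.exon_len_range[1] + 1, size=n_exons)
        parts: list[str] = []
        spans: list[tuple[int, int]] = []
        pos = 0
        for i, raw_len in enumerate(lens):
            ln = int(raw_len)
            if n_exons == 1:
                ln -= ln % 3  # ATG + sense codons + stop, no premature stop
                exon = "ATG" + self._codons((ln - 6) // 3) + self._stop()
            elif i == 0:
                exon = "ATG" + self._body(ln - 3)
            elif i == n_exons - 1:
                exon = self._body(ln - 3) + self._stop()
            else:
                exon = self._body(ln)
            spans.append((pos, pos + len(exon)))
            parts.append(exon)
            pos += len(exon)
            if i < n_exons - 1:
                intron = self._intron()
                parts.append(intron)
                pos += len(intron)
        return _GeneDraft(seq="".join(parts), exon_spans=spans)

    # -- genome layout ------------------------------------------------------

    def _layout(self, seq_id: str):
        cfg = self.config
        f = cfg.target_coding_fraction
        chunks: list[str] = []
        pos = 0
        coding = 0
        exons: list[tuple[int, int]] = []
        genes: list[dict] = []
        while True:
            gene = self._draw_gene()
            # gap sized so the running coding fraction tracks the target
            want = (coding + gene.coding) / f - len(gene.seq) - pos
            gap = max(cfg.min_intergenic_gap, int(round(want)))
            if pos + gap + len(gene.seq) > cfg.length:
                break
            chunks.append(self._background(gap))
            pos += gap
            gene_start = pos
            chunks.append(gene.seq)
            for s, e in gene.exon_spans:
                exons.append((gene_start + s, gene_start + e))
            genes.append({
                "gene_id": f"g{len(genes) + 1}",
                "start": gene_start,
                "end": gene_start + len(gene.seq),
                "n_exons": len(gene.exon_spans),
                "exon_starts": ",".join(str(gene_start + s)
                                        for s, _ in gene.exon_spans),
                "exon_ends": ",".join(str(gene_start + e)
                                      for _, e in gene.exon_spans),
            })
            pos += len(gene.seq)
            coding += gene.coding
        chunks.append(self._background(cfg.length - pos))
        return "".join(chunks), exons, genes, coding


def generate(config: GenomeSimConfig, seq_id: str = "synth",
             max_retries: int = 5
             ) -> tuple[SequenceRecord, CdsAnnotation, pd.DataFrame]:
    """Generate a genome; reproducible under config.seed.

    Raises if the realized coding fraction misses the target by more than 0.05
    after bounded retries (infeasible configuration).
    """
    last_frac = None
    for attempt in range(max_retries):
        cfg = config if attempt == 0 else GenomeSimConfig(
            **{**config.__dict__, "seed": config.seed + 7919 * attempt})
        sim = GenomeSimulator(cfg)
        seq, exons, genes, coding = sim._layout(seq_id)
        frac = coding / cfg.length
        last_frac = frac
        if abs(frac - config.target_coding_fraction) <= 0.05 and genes:
            record = SequenceRecord(id=seq_id, seq=seq)
            annotation = CdsAnnotation.from_intervals(seq_id, exons, len(seq))
            table = pd.DataFrame(
                genes, columns=["gene_id", "start", "end", "n_exons",
                                "exon_starts", "exon_ends"])
            if attempt:
                logger.info("genome accepted on retry %d (fraction %.3f)",
                            attempt, frac)
            return record, annotation, table
    raise ValueError(
        f"infeasible simulation config: realized coding fraction {last_frac:.3f} "
        f"vs target {config.target_coding_fraction} after {max_retries} attempts"
    )


def write_fixture(config: GenomeSimConfig, out_prefix: str,
                  seq_id: str = "synth") -> tuple[str, str, str]:
    """Write <prefix>.fasta, <prefix>.gff3 and <prefix>.genes.tsv."""
    from .sequence_io import write_fasta, write_gff_cds

    record, annotation, table = generate(config, seq_id=seq_id)
    fasta = f"{out_prefix}.fasta"
    gff = f"{out_prefix}.gff3"
    tsv = f"{out_prefix}.genes.tsv"
    write_fasta([record], fasta)
    write_gff_cds(annotation, gff, source="cdscan_sim")
    table.to_csv(tsv, sep="\t", index=False)
    return fasta, gff, tsv
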