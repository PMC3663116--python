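"""PolII activity metrics from strand-specific coverage (GRO-seq style).

Three per-gene quantities summarize nascent-transcription coverage around a
gene model:

* gene body activity  N / L: reads mapped from 1 kb downstream of the TSS to
  the gene end, divided by the length L of that region;
* promoter activity: the maximum read count in any 50-bp window fully inside
  the +/- 1 kb region around the TSS (windows step by 1 bp);
* pause index: (promoter activity / 50) / body activity — the per-bp signal
  of the busiest promoter window relative to the per-bp body signal, so a
  uniform coverage field has pause index exactly 1.

Coordinates are BED-style 0-based half-open throughout, and all metrics are
computed on the gene's own strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "CoverageTrack",
    "PauseMetrics",
    "read_bed6",
    "gene_body_activity",
    "promoter_activity",
    "pause_index",
    "compute_pause_metrics",
]

PROMOTER_FLANK = 1000
PROMOTER_WINDOW = 50
BODY_OFFSET = 1000


@dataclass(frozen=True)
class GeneModel:
    """One gene in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class CoverageTrack:
    """Per-base, per-strand read coverage; positions not covered are 0."""

    def __init__(self) -> None:
        self._data: dict[tuple[str, str], np.ndarray] = {}

    def add_interval(self, chrom: str, strand: str, start: int, end: int, value: float) -> None:
        if value < 0:
            raise ValueError("coverage values must be nonnegative")
        key = (chrom, strand)
        arr = self._data.get(key)
        if arr is None or arr.size < end:
            new = np.zeros(max(end, 2 * (arr.size if arr is not None else 0)), dtype=float)
            if arr is not None:
                new[: arr.size] = arr
            self._data[key] = arr = new
        arr[start:end] += value

    @classmethod
    def from_bedgraph(cls, plus_path: str | Path | None = None, minus_path: str | Path | None = None) -> "CoverageTrack":
        """Build a track from one bedGraph file per strand."""
        track = cls()
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            if path is None:
                continue
            df = pd.read_csv(
                path,
                sep=r"\s+",
                header=None,
                comment="#",
                names=["chrom", "start", "end", "value"],
                dtype={"chrom": str},
            )
            df = df[~df["chrom"].str.startswith("track")]
            for chrom, start, end, value in df.itertuples(index=False):
                track.add_interval(str(chrom), strand, int(start), int(end), float(value))
        return track

    def region(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Coverage values over [start, end); out-of-track positions are 0."""
        if end <= start:
            return np.zeros(0, dtype=float)
        out = np.zeros(end - start, dtype=float)
        arr = self._data.get((chrom, strand))
        if arr is None:
            return out
        lo = max(start, 0)
        hi = min(end, arr.size)
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


@dataclass(frozen=True)
class PauseMetrics:
    """Per-gene PolII activity summary; None marks undefined metrics."""

    gene_id: str
    body_activity: float | None
    promoter_activity: float
    pause_index: float | None


def _body_region(gene: GeneModel) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.start + BODY_OFFSET, gene.end
    return gene.start, gene.end - BODY_OFFSET


def gene_body_activity(track: CoverageTrack, gene: GeneModel) -> float | None:
    """Strand-matched reads from TSS+1kb to the gene end, per bp (N/L).

    Returns None for genes of 1 kb or shorter, whose body region is empty.
    """
    start, end = _body_region(gene)
    if end <= start:
        return None
    cov = track.region(gene.chrom, gene.strand, start, end)
    return float(cov.sum() / (end - start))


def promoter_activity(track: CoverageTrack, gene: GeneModel) -> float:
    """Maximum 50-bp window read count within +/- 1 kb of the TSS.

    Windows step by 1 bp and must lie fully inside the 2-kb region.  The
    flank is defined by transcription-direction offsets [-1000, +1000)
    around the TSS, so plus- and minus-strand genes are treated exactly
    symmetrically.
    """
    if gene.strand == "+":
        lo = gene.tss - PROMOTER_FLANK
        hi = gene.tss + PROMOTER_FLANK
    else:
        lo = gene.tss - PROMOTER_FLANK + 1
        hi = gene.tss + PROMOTER_FLANK + 1
    cov = track.region(gene.chrom, gene.strand, lo, hi)
    if cov.size < PROMOTER_WINDOW:
        return float(cov.sum())
    kernel = np.ones(PROMOTER_WINDOW)
    sums = np.convolve(cov, kernel, mode="valid")
    return float(sums.max())


def pause_index(track: CoverageTrack, gene: GeneModel) -> float | None:
    """(promoter activity / 50) / body activity; None when body activity is 0."""
    body = gene_body_activity(track, gene)
    if body is None or body == 0.0:
        return None
    return (promoter_activity(track, gene) / PROMOTER_WINDOW) / body


def compute_pause_metrics(track: CoverageTrack, gene: GeneModel) -> PauseMetrics:
    body = gene_body_activity(track, gene)
    prom = promoter_activity(track, gene)
    pi = None
    if body is not None and body > 0.0:
        pi = (prom / PROMOTER_WINDOW) / body
    return PauseMetrics(gene_id=gene.gene_id, body_activity=body, promoter_activity=prom, pause_index=pi)


def read_bed6(path: str | Path) -> list[GeneModel]:
    """Read gene models from a BED6 file (chrom start end name score strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        GeneModel(chrom=r.chrom, start=int(r.start), end=int(r.end), strand=r.strand, gene_id=r.name)
        for r in df.itertuples(index=False)
    ]
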