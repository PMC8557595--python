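"""Genomic interval algebra and BED-family I/O.

All coordinates are 0-based half-open (BED convention): an interval
``(chrom, start, end)`` covers bases ``start .. end-1``.  Every distance
computed here uses this arithmetic; strand is never consulted.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Depth-normalization scale: signals are reported per million units of
#: library size ("counts per million" style).
SCALE_CONSTANT = 1e6

#: A signal track: chrom -> sorted, non-overlapping (start, end, per-base value)
#: bins, bedGraph style.
SignalTrack = dict[str, list[tuple[int, int, float]]]


class IntervalError(ValueError):
    """Raised for malformed genomic records."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError(f"empty chromosome name in {self!r}")
        if self.start < 0:
            raise IntervalError(f"negative start in {self!r}")
        if self.end <= self.start:
            raise IntervalError(f"end <= start in {self!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SignalPeak:
    """An interval carrying depth-normalized H3K27ac signal."""

    interval: GenomicInterval
    signal: float

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise IntervalError(f"negative signal in {self!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus with its transcription start site and biotype."""

    gene_id: str
    interval: GenomicInterval
    tss: int
    biotype: str = "mRNA"

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.tss < self.interval.end):
            raise IntervalError(
                f"TSS {self.tss} outside gene body for {self.gene_id!r}"
            )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share >= 1 base.

    Half-open arithmetic: bookended intervals (a.end == b.start) do NOT
    overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(
    intervals: Iterable[GenomicInterval], min_gap: int = 0
) -> list[GenomicInterval]:
    """Collapse intervals whose gap on the same chromosome is <= ``min_gap``.

    Output is sorted by (chrom, start); intervals in the result are pairwise
    separated by more than ``min_gap`` bases.  With ``min_gap=0`` this is a
    plain union (``bedtools merge``); with a positive gap it is the peak
    stitching used for super-enhancer definition.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    items = sorted(intervals)
    out: list[GenomicInterval] = []
    for iv in items:
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end <= min_gap:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            out.append(iv)
    return out


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Edge-to-edge gap in bases; 0 when overlapping; None across chromosomes."""
    if a.chrom != b.chrom:
        return None
    if overlaps(a, b):
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def genes_within_window(
    region: GenomicInterval,
    annotation: Sequence[GeneAnnotation],
    window: int,
) -> list[tuple[GeneAnnotation, int]]:
    """All genes whose body lies within ``window`` bp of ``region``.

    Distance is 0 for overlapping genes, otherwise the gap between nearest
    edges; both upstream and downstream neighbors qualify (strand ignored).
    Result sorted by (distance, gene_id).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    hits: list[tuple[GeneAnnotation, int]] = []
    for gene in annotation:
        d = interval_distance(region, gene.interval)
        if d is not None and d <= window:
            hits.append((gene, d))
    hits.sort(key=lambda t: (t[1], t[0].gene_id))
    return hits


def quantify_signal(
    regions: Sequence[GenomicInterval],
    track: SignalTrack,
    library_size: float,
    scale_constant: float = SCALE_CONSTANT,
) -> list[SignalPeak]:
    """Depth-normalized signal per region.

    signal = (sum of per-base track values over the region) *
    (scale_constant / library_size).  A region on a chromosome missing from
    the track gets signal 0 with a logged warning.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    factor = scale_constant / library_size
    out: list[SignalPeak] = []
    for region in regions:
        bins = track.get(region.chrom)
        if bins is None:
            logger.warning(
                "chromosome %s absent from signal track; signal set to 0",
                region.chrom,
            )
            out.append(SignalPeak(region, 0.0))
            continue
        total = 0.0
        # bins sorted by start; skip everything ending before the region
        i = bisect_left(bins, (region.start,)) if bins else 0
        # step back one bin: it may straddle region.start
        if i > 0:
            i -= 1
        for start, end, value in bins[i:]:
            if start >= region.end:
                break
            ov = min(end, region.end) - max(start, region.start)
            if ov > 0:
                total += ov * value
        out.append(SignalPeak(region, total * factor))
    return out


# ---------------------------------------------------------------------------
# BED / bedGraph I/O


def _data_lines(path: Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track") or line.startswith("browser"):
                continue
            yield lineno, line.split("\t")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, list[str]]]:
    """Read BED3+; returns (interval, extra columns) per record.

    ``track``/``browser``/``#`` lines are skipped.  Malformed coordinates
    raise with the offending line number.
    """
    records: list[tuple[GenomicInterval, list[str]]] = []
    for lineno, fields in _data_lines(Path(path)):
        if len(fields) < 3:
            raise IntervalError(f"{path}:{lineno}: fewer than 3 BED columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise IntervalError(f"{path}:{lineno}: non-integer coordinates") from exc
        try:
            iv = GenomicInterval(fields[0], start, end)
        except IntervalError as exc:
            raise IntervalError(f"{path}:{lineno}: {exc}") from exc
        records.append((iv, fields[3:]))
    return records


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """BED3+ reader discarding any extra columns."""
    return [iv for iv, _ in read_bed(path)]


def write_bed(
    records: Iterable[GenomicInterval | tuple[GenomicInterval, Sequence[str]]],
    path: str | Path,
) -> None:
    """Write intervals (optionally with extra columns) as tab-delimited BED."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                iv, extra = rec, ()
            else:
                iv, extra = rec
            fields = [iv.chrom, str(iv.start), str(iv.end), *map(str, extra)]
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph (chrom, start, end, value) into a SignalTrack."""
    track: SignalTrack = {}
    for lineno, fields in _data_lines(Path(path)):
        if len(fields) < 4:
            raise IntervalError(f"{path}:{lineno}: fewer than 4 bedGraph columns")
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise IntervalError(f"{path}:{lineno}: malformed bedGraph fields") from exc
        if end <= start:
            raise IntervalError(f"{path}:{lineno}: end <= start")
        track.setdefault(fields[0], []).append((start, end, value))
    for bins in track.values():
        bins.sort()
    return track


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track):
            for start, end, value in sorted(track[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotation from BED6+.

    Column 4 is the gene_id; column 7 (thickStart), when present, carries the
    TSS; otherwise the TSS defaults to the start (plus strand) or end-1
    (minus strand, column 6).  Column 8, when present, is the biotype.
    """
    genes: list[GeneAnnotation] = []
    for iv, extra in read_bed(path):
        if not extra:
            raise IntervalError(f"{path}: gene BED needs a name column")
        gene_id = extra[0]
        strand = extra[2] if len(extra) > 2 else "+"
        if len(extra) > 3 and extra[3] != ".":
            tss = int(extra[3])
        else:
            tss = iv.start if strand != "-" else iv.end - 1
        biotype = extra[4] if len(extra) > 4 else "mRNA"
        genes.append(GeneAnnotation(gene_id, iv, tss, biotype))
    return genes


def write_gene_bed(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        str(g.interval.start),
                        str(g.interval.end),
                        g.gene_id,
                        "0",
                        "+",
                        str(g.tss),
                        g.biotype,
                    ]
                )
                + "\n"
            )
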