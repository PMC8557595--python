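"""Rank-order super-enhancer identification (ROSE-style).

Constituent enhancer peaks are stitched into regions, TSS-proximal peaks are
excluded, stitched regions are ranked by aggregate H3K27ac signal, and the
super/typical threshold is placed at the inflection of the rank-signal
"hockey stick": the point where, after min-max scaling both axes, the slope
of the curve first exceeds 1 scanning from the low-signal end.  Regions with
signal strictly above the cutoff are super-enhancers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    SCALE_CONSTANT,
    GeneAnnotation,
    GenomicInterval,
    SignalPeak,
    SignalTrack,
    merge_intervals,
    quantify_signal,
)

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Too few regions to place a rank-curve cutoff."""


@dataclass(frozen=True)
class StitchedRegion:
    interval: GenomicInterval
    n_constituents: int
    signal: float

    def __post_init__(self) -> None:
        if self.n_constituents < 1:
            raise ValueError("n_constituents must be >= 1")
        if self.signal < 0:
            raise ValueError("signal must be >= 0")


@dataclass(frozen=True)
class SECall:
    region: StitchedRegion
    rank: int
    is_super: bool


@dataclass(frozen=True)
class SEConfig:
    """Parameters of the stitch-rank-threshold procedure.

    stitch_distance: peaks closer than this (bp) are stitched (12.5 kb,
    the ROSE default).  tss_exclusion: peaks fully contained within
    +/- this many bp of an annotated TSS are dropped before stitching
    (0 disables the exclusion).  scale_constant: depth-normalization scale.
    """

    stitch_distance: int = 12_500
    tss_exclusion: int = 250
    scale_constant: float = SCALE_CONSTANT

    def __post_init__(self) -> None:
        if self.stitch_distance < 0 or self.tss_exclusion < 0:
            raise ValueError("distances must be >= 0")
        if self.scale_constant <= 0:
            raise ValueError("scale_constant must be > 0")


def exclude_tss_peaks(
    peaks: Sequence[SignalPeak],
    annotation: Sequence[GeneAnnotation],
    tss_exclusion: int,
) -> list[SignalPeak]:
    """Drop peaks fully contained within +/- ``tss_exclusion`` bp of a TSS.

    Promoter-proximal H3K27ac would otherwise dominate the stitched signal.
    Partial overlap with an exclusion zone retains the peak; ``0`` disables
    the filter entirely.
    """
    if tss_exclusion < 0:
        raise ValueError("tss_exclusion must be >= 0")
    if tss_exclusion == 0 or not annotation:
        return list(peaks)
    by_chrom: dict[str, list[int]] = {}
    for gene in annotation:
        by_chrom.setdefault(gene.interval.chrom, []).append(gene.tss)
    for tss_list in by_chrom.values():
        tss_list.sort()
    kept: list[SignalPeak] = []
    for peak in peaks:
        iv = peak.interval
        contained = False
        for tss in by_chrom.get(iv.chrom, ()):  # few TSSs per chrom in practice
            if tss - tss_exclusion <= iv.start and iv.end <= tss + tss_exclusion:
                contained = True
                break
        if not contained:
            kept.append(peak)
    return kept


def stitch_peaks(
    peaks: Sequence[SignalPeak], stitch_distance: int
) -> list[StitchedRegion]:
    """Transitively merge peaks within ``stitch_distance`` on a chromosome.

    The stitched region's signal is the sum of its constituents' signals and
    its interval the envelope of the chain.
    """
    ordered = sorted(peaks, key=lambda p: p.interval)
    out: list[StitchedRegion] = []
    for peak in ordered:
        iv = peak.interval
        if (
            out
            and iv.chrom == out[-1].interval.chrom
            and iv.start - out[-1].interval.end <= stitch_distance
        ):
            prev = out[-1]
            out[-1] = StitchedRegion(
                GenomicInterval(
                    prev.interval.chrom,
                    prev.interval.start,
                    max(prev.interval.end, iv.end),
                ),
                prev.n_constituents + 1,
                prev.signal + peak.signal,
            )
        else:
            out.append(StitchedRegion(iv, 1, peak.signal))
    return out


def hockey_stick_cutoff(signals: Sequence[float]) -> float:
    """Signal threshold at the rank-curve inflection.

    ``signals`` must be sorted ascending.  Both the rank index and the signal
    are min-max scaled to [0, 1]; the cutoff is the signal at the first index
    (scanning from the low end) where the two-point finite-difference slope
    exceeds 1 — the point a slope-1 tangent touches on a convex curve.
    Regions with signal strictly above the returned value are super.

    All-equal inputs return the maximum (nothing exceeds it) with a warning.
    """
    y = np.asarray(signals, dtype=float)
    if y.size < 2:
        raise DegenerateInputError("need >= 2 signals to place a cutoff")
    if np.any(np.diff(y) < 0):
        raise ValueError("signals must be sorted ascending")
    lo, hi = y[0], y[-1]
    if hi == lo:
        logger.warning("all signals equal; cutoff set to max (no super calls)")
        return float(hi)
    ys = (y - lo) / (hi - lo)
    xs = np.linspace(0.0, 1.0, y.size)
    slopes = np.gradient(ys, xs)
    above = np.nonzero(slopes > 1.0)[0]
    if above.size == 0:  # numerically flat-then-jump edge case
        return float(hi)
    return float(y[above[0]])


def call_super_enhancers(
    peaks: Sequence[SignalPeak],
    annotation: Sequence[GeneAnnotation],
    config: SEConfig | None = None,
) -> list[SECall]:
    """Full stitch-rank-threshold pipeline.

    Returns calls sorted by rank (1 = highest signal); signal ties are broken
    by (chrom, start) so the permutation is stable and order-independent.
    With fewer than 2 stitched regions the cutoff is undefined: the lone
    region is returned as typical with a warning.
    """
    cfg = config or SEConfig()
    filtered = exclude_tss_peaks(peaks, annotation, cfg.tss_exclusion)
    stitched = stitch_peaks(filtered, cfg.stitch_distance)
    if not stitched:
        return []
    ranked = sorted(
        stitched, key=lambda r: (-r.signal, r.interval.chrom, r.interval.start)
    )
    if len(ranked) < 2:
        logger.warning("only one stitched region; returned as typical")
        return [SECall(ranked[0], 1, False)]
    ascending = sorted(r.signal for r in ranked)
    cutoff = hockey_stick_cutoff(ascending)
    return [
        SECall(region, rank, region.signal > cutoff)
        for rank, region in enumerate(ranked, start=1)
    ]


def super_regions(calls: Iterable[SECall]) -> list[GenomicInterval]:
    """Intervals of the super-enhancer calls only."""
    return [c.region.interval for c in calls if c.is_super]


@dataclass(frozen=True)
class UniverseQuantification:
    """Merged SE universe quantified across stages.

    ``signal``: DataFrame, one row per merged universe region (index
    "chrom:start-end"), one column per stage, depth-normalized signal.
    ``fold_change``: DataFrame with one column per ordered stage pair
    "b_vs_a", pseudocount-stabilized ratios (not logged).
    """

    regions: tuple[GenomicInterval, ...]
    signal: pd.DataFrame
    fold_change: pd.DataFrame = field(repr=False)


def quantify_universe(
    stage_calls: Mapping[str, Sequence[SECall]],
    stage_signals: Mapping[str, SignalTrack],
    stage_library_sizes: Mapping[str, float],
    scale_constant: float = SCALE_CONSTANT,
    pseudocount: float = 1.0,
) -> UniverseQuantification:
    """Collapse all stages' super-enhancers and quantify each stage over the union.

    The universe is the min-gap-0 merge of every stage's SE intervals
    ("AllSEs"); each stage's track is then quantified over every universe
    region regardless of whether that stage called it.  Fold changes use
    ``(b + pseudocount) / (a + pseudocount)`` so zero-signal stages stay
    finite.
    """
    stages = list(stage_calls)
    if not stages:
        raise ValueError("need at least one stage")
    universe = merge_intervals(
        [iv for calls in stage_calls.values() for iv in super_regions(calls)],
        min_gap=0,
    )
    index = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in universe]
    data = {}
    for stage in stages:
        quantified = quantify_signal(
            universe,
            stage_signals[stage],
            stage_library_sizes[stage],
            scale_constant,
        )
        data[stage] = [p.signal for p in quantified]
    signal = pd.DataFrame(data, index=index)
    fc_cols = {}
    for a in stages:
        for b in stages:
            if a != b:
                fc_cols[f"{b}_vs_{a}"] = (signal[b] + pseudocount) / (
                    signal[a] + pseudocount
                )
    fold_change = pd.DataFrame(fc_cols, index=index)
    return UniverseQuantification(tuple(universe), signal, fold_change)


def calls_to_frame(calls: Sequence[SECall]) -> pd.DataFrame:
    """ROSE-style per-stage table: chrom, start, end, n_constituents, signal, rank, is_super."""
    return pd.DataFrame(
        {
            "chrom": [c.region.interval.chrom for c in calls],
            "start": [c.region.interval.start for c in calls],
            "end": [c.region.interval.end for c in calls],
            "n_constituents": [c.region.n_constituents for c in calls],
            "signal": [c.region.signal for c in calls],
            "rank": [c.rank for c in calls],
            "is_super": [c.is_super for c in calls],
        }
    )


def write_se_table(calls: Sequence[SECall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
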