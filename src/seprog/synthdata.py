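"""Seeded synthetic inputs with planted ground truth.

Every input the pipeline consumes can be generated here: stage-ordered
ChIP-seq peak/signal sets with super-enhancer clusters planted on a known
acquisition/loss schedule, stage expression tables with planted cis
lncRNA-mRNA pairs among decoys, patient expression matrices with controlled
correlations, patient SE cohorts with known representation fractions, and
qPCR Ct tables with planted fold changes and nuclear/cytoplasmic splits.

The generators emulate the statistical structure of an H3K27ac progression
study — a baseline epithelial line and three successive premalignant/
malignant stages — not read-level sequencing: peaks arrive as intervals
with depth-normalized signal, tracks as 50-bp-binned bedGraphs.  All
generators are pure functions of the config (seed included); repeated calls
are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneAnnotation,
    GenomicInterval,
    SignalPeak,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_gene_bed,
)
from .prioritize import ExpressionSeries, expression_to_frame

BIN = 50  # signal track resolution, bp


@dataclass(frozen=True)
class SynthConfig:
    """Defaults mirror the study design being emulated: a 4-stage
    progression series, ~25 true SE clusters among ~400 typical-enhancer
    decoys, 50 patients, and qPCR noise of a twentieth of a cycle."""

    seed: int = 1
    n_stages: int = 4
    stage_names: tuple[str, ...] = ("normal", "atypia", "dcis", "idc")
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 20_000_000),
        ("chr2", 20_000_000),
    )
    n_decoy_peaks: int = 400
    n_planted_se_clusters: int = 25
    # expression funnel
    n_planted_cis_pairs: int = 8
    n_extreme_fc: int = 4
    n_lnc_decoys: int = 200
    n_mrna_decoys: int = 50
    n_patients: int = 50
    cis_r_target: float = 0.9
    # qPCR
    n_qpcr_targets: int = 5
    n_replicates: int = 3
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if len(self.stage_names) != self.n_stages:
            raise ValueError("one stage name per stage required")
        if self.n_stages < 2:
            raise ValueError("need >= 2 stages")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _default_schedule(cfg: SynthConfig) -> list[tuple[int, int | None]]:
    """(acquired_stage, lost_stage or None) per cluster, cycling through
    baseline-stable, acquired-and-retained, baseline-lost and transient
    patterns so every dynamics class is represented."""
    last = cfg.n_stages - 1
    patterns: list[tuple[int, int | None]] = [
        (0, None),        # baseline, stable
        (1, None),        # acquired early, retained
        (min(2, last), None),
        (last, None),     # acquired at the final stage
        (0, 1),           # lost immediately
        (0, min(2, last)),
        (0, last),
        (1, last),        # transient: acquired then lost
    ]
    return [patterns[i % len(patterns)] for i in range(cfg.n_planted_se_clusters)]


@dataclass(frozen=True)
class ChipSeqSeries:
    """Per-stage peaks/tracks plus the planted-cluster truth table.

    ``truth`` columns: cluster_id, chrom, start, end, acquired_stage,
    lost_stage (NaN = never lost).  ``library_sizes`` are chosen equal to
    the normalization scale so quantified signal equals planted signal.
    """

    stage_names: tuple[str, ...]
    peaks: Mapping[str, tuple[SignalPeak, ...]]
    tracks: Mapping[str, SignalTrack]
    library_sizes: Mapping[str, float]
    annotation: tuple[GeneAnnotation, ...]
    truth: pd.DataFrame = field(repr=False)


def gen_chipseq_series(cfg: SynthConfig | None = None) -> ChipSeqSeries:
    """Stage-ordered peak sets with planted super-enhancer clusters.

    Planted clusters are 3-8 peaks spanning < 12.5 kb with per-peak signal
    >= 10x the decoy median, present from their acquisition stage until
    their loss stage; decoys are isolated exponential-signal peaks present
    at every stage.  Features sit in 40-kb slots so no two stitch together.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    slot = 40_000
    slots = [
        (chrom, start)
        for chrom, length in cfg.genome
        for start in range(0, length - slot, slot)
    ]
    n_features = cfg.n_planted_se_clusters + cfg.n_decoy_peaks
    if n_features > len(slots):
        raise ValueError("genome too small for requested features")
    chosen = rng.choice(len(slots), size=n_features, replace=False)
    schedule = _default_schedule(cfg)

    # geometry first (stage-independent), then per-stage signals
    cluster_geoms: list[tuple[str, list[tuple[int, int]]]] = []
    truth_rows = []
    for ci in range(cfg.n_planted_se_clusters):
        chrom, base = slots[chosen[ci]]
        pos = base + int(rng.integers(0, 2_000 // BIN)) * BIN
        n_peaks = int(rng.integers(3, 9))
        coords = []
        for _ in range(n_peaks):
            width = int(rng.integers(6, 19)) * BIN  # 300-900 bp
            coords.append((pos, pos + width))
            pos += width + int(rng.integers(2, 11)) * BIN  # 100-500 bp gap
        acquired, lost = schedule[ci]
        truth_rows.append(
            {
                "cluster_id": f"se_cluster_{ci:03d}",
                "chrom": chrom,
                "start": coords[0][0],
                "end": coords[-1][1],
                "acquired_stage": acquired,
                "lost_stage": np.nan if lost is None else lost,
            }
        )
        cluster_geoms.append((chrom, coords))
    decoy_geoms: list[tuple[str, int, int]] = []
    for di in range(cfg.n_decoy_peaks):
        chrom, base = slots[chosen[cfg.n_planted_se_clusters + di]]
        start = base + int(rng.integers(0, 5_000 // BIN)) * BIN
        width = int(rng.integers(4, 41)) * BIN  # 200-2000 bp
        decoy_geoms.append((chrom, start, start + width))

    peaks: dict[str, tuple[SignalPeak, ...]] = {}
    tracks: dict[str, SignalTrack] = {}
    for si, stage in enumerate(cfg.stage_names):
        stage_peaks: list[SignalPeak] = []
        track: SignalTrack = {chrom: [] for chrom, _ in cfg.genome}
        for ci, (chrom, coords) in enumerate(cluster_geoms):
            acquired, lost = schedule[ci]
            active = acquired <= si and (lost is None or si < lost)
            if not active:
                continue
            for start, end in coords:
                signal = 20.0 + float(rng.exponential(5.0))
                stage_peaks.append(SignalPeak(GenomicInterval(chrom, start, end), signal))
                track[chrom].append((start, end, signal / (end - start)))
        for chrom, start, end in decoy_geoms:
            signal = float(rng.exponential(1.0))
            stage_peaks.append(SignalPeak(GenomicInterval(chrom, start, end), signal))
            track[chrom].append((start, end, signal / (end - start)))
        for bins in track.values():
            bins.sort()
        stage_peaks.sort(key=lambda p: p.interval)
        peaks[stage] = tuple(stage_peaks)
        tracks[stage] = track

    # one gene near every cluster (for SE -> neighboring-gene reports) plus
    # distal genes; TSSs sit outside peaks so exclusion leaves clusters intact
    genes = []
    for ci, (chrom, coords) in enumerate(cluster_geoms):
        start = coords[-1][1] + 20_000
        genes.append(
            GeneAnnotation(f"gene_{ci:03d}", GenomicInterval(chrom, start, start + 2_000), start)
        )
    truth = pd.DataFrame(truth_rows)
    return ChipSeqSeries(
        stage_names=cfg.stage_names,
        peaks=peaks,
        tracks=tracks,
        library_sizes={s: 1e6 for s in cfg.stage_names},
        annotation=tuple(genes),
        truth=truth,
    )


def write_chipseq(series: ChipSeqSeries, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in series.stage_names:
        write_bed(
            [(p.interval, ["peak", f"{p.signal:.6g}"]) for p in series.peaks[stage]],
            outdir / f"{stage}.peaks.bed",
        )
        write_bedgraph(series.tracks[stage], outdir / f"{stage}.signal.bedgraph")
    write_gene_bed(series.annotation, outdir / "genes.bed")
    series.truth.to_csv(outdir / "truth_clusters.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression funnel fixture


@dataclass(frozen=True)
class ExpressionBundle:
    lnc_table: tuple[ExpressionSeries, ...]
    mrna_table: tuple[ExpressionSeries, ...]
    annotation: tuple[GeneAnnotation, ...]
    annotated_ids: tuple[str, ...]
    patient_matrix: pd.DataFrame
    patient_direction: dict[str, int]
    truth_pairs: tuple[tuple[str, str], ...]  # planted (lncRNA, mRNA)
    truth_extreme: tuple[str, ...]  # planted extreme responders


def _stage_values(rng, baseline: float, total_fc: float, n: int) -> tuple[float, ...]:
    """Monotone geometric ramp from baseline to baseline*total_fc with
    +/-3% multiplicative jitter."""
    ratio = total_fc ** (1.0 / (n - 1))
    vals = [baseline * ratio**i * float(rng.uniform(0.97, 1.03)) for i in range(n)]
    vals[0] = baseline
    vals[-1] = baseline * total_fc
    return tuple(max(v, 0.0) for v in vals)


def gen_expression(cfg: SynthConfig | None = None) -> ExpressionBundle:
    """Stage tables, annotation, patient matrix and id lists, with truth.

    Planted cis pairs: lncRNA and mRNA < 50 kb apart, both with
    |log2 FC| >= 1 across the series (extreme responders >= log2(10) are
    separate lncRNAs), patient rows sharing a latent factor with loading
    sqrt(cis_r_target) so their correlation is near the target.  Decoys
    rotate through the failure modes of each funnel step: co-located but
    uncorrelated and trend-discordant; co-located but unannotated;
    correlated but distal (> 50 kb); flat; changing with only a flat
    neighbor.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    stages = cfg.stage_names
    n = cfg.n_stages
    slot = 200_000
    chrom = "chrE1"

    lnc_table: list[ExpressionSeries] = []
    mrna_table: list[ExpressionSeries] = []
    annotation: list[GeneAnnotation] = []
    annotated: list[str] = []
    corr_pairs: list[tuple[str, str, float]] = []  # rows built with shared factor
    uncorr_rows: list[str] = []
    patient_direction: dict[str, int] = {}
    truth_pairs: list[tuple[str, str]] = []
    truth_extreme: list[str] = []

    def add_gene(gene_id: str, start: int, biotype: str) -> None:
        annotation.append(
            GeneAnnotation(gene_id, GenomicInterval(chrom, start, start + 2_000), start, biotype)
        )

    slot_i = 0

    def next_slot() -> int:
        nonlocal slot_i
        base = slot_i * slot + 10_000
        slot_i += 1
        return base

    def series_dir(rng) -> float:
        return 4.0 if rng.random() < 0.5 else 0.25

    # planted cis pairs
    for i in range(cfg.n_planted_cis_pairs):
        lnc_id, mrna_id = f"lnc_cis_{i:03d}", f"mrna_cis_{i:03d}"
        base = next_slot()
        add_gene(lnc_id, base, "lncRNA")
        gap = int(rng.integers(1_000, 40_000))
        add_gene(mrna_id, base + 2_000 + gap, "mRNA")
        fc = series_dir(rng)
        lnc_table.append(
            ExpressionSeries(lnc_id, "lncRNA", stages, _stage_values(rng, float(rng.uniform(50, 200)), fc, n))
        )
        mrna_table.append(
            ExpressionSeries(mrna_id, "mRNA", stages, _stage_values(rng, float(rng.uniform(100, 400)), fc, n))
        )
        annotated.append(lnc_id)
        direction = 1 if fc > 1 else -1
        patient_direction[mrna_id] = direction
        if i < cfg.n_planted_cis_pairs * 3 // 4:
            corr_pairs.append((lnc_id, mrna_id, cfg.cis_r_target))
        # remaining pairs are absent from the patient matrix and recovered
        # through the trend-concordance branch
        truth_pairs.append((lnc_id, mrna_id))

    # planted extreme responders (no qualifying neighbor; standalone branch)
    for i in range(cfg.n_extreme_fc):
        lnc_id = f"lnc_extreme_{i:03d}"
        base = next_slot()
        add_gene(lnc_id, base, "lncRNA")
        fc = 16.0 if i % 2 == 0 else 1 / 16.0
        # baselines high enough that the pseudocount-stabilized ratio still
        # clears the +/-10 extreme cutoff for the down-regulated features
        lnc_table.append(
            ExpressionSeries(lnc_id, "lncRNA", stages, _stage_values(rng, float(rng.uniform(300, 800)), fc, n))
        )
        annotated.append(lnc_id)
        truth_extreme.append(lnc_id)

    # decoy lncRNAs cycling through failure modes
    for i in range(cfg.n_lnc_decoys):
        lnc_id = f"lnc_decoy_{i:03d}"
        base = next_slot()
        add_gene(lnc_id, base, "lncRNA")
        mode = i % 5
        baseline = float(rng.uniform(50, 200))
        if mode == 3:  # flat: fails the differential filter
            lnc_table.append(
                ExpressionSeries(lnc_id, "lncRNA", stages, _stage_values(rng, baseline, 1.0, n))
            )
            continue
        fc = series_dir(rng)
        lnc_table.append(
            ExpressionSeries(lnc_id, "lncRNA", stages, _stage_values(rng, baseline, fc, n))
        )
        direction = 1 if fc > 1 else -1
        if mode == 0:
            # co-located changing neighbor, annotated, but uncorrelated in
            # patients and trend-discordant
            mrna_id = f"mrna_decoy_{i:03d}"
            add_gene(mrna_id, base + 2_000 + int(rng.integers(1_000, 40_000)), "mRNA")
            mrna_table.append(
                ExpressionSeries(mrna_id, "mRNA", stages, _stage_values(rng, float(rng.uniform(100, 400)), fc, n))
            )
            annotated.append(lnc_id)
            uncorr_rows.extend([lnc_id, mrna_id])
            patient_direction[mrna_id] = -direction
        elif mode == 1:
            # co-located changing neighbor but lncRNA not annotated
            mrna_id = f"mrna_decoy_{i:03d}"
            add_gene(mrna_id, base + 2_000 + int(rng.integers(1_000, 40_000)), "mRNA")
            mrna_table.append(
                ExpressionSeries(mrna_id, "mRNA", stages, _stage_values(rng, float(rng.uniform(100, 400)), fc, n))
            )
            patient_direction[mrna_id] = direction
        elif mode == 2:
            # correlated in patients but neighbor sits > 50 kb away
            mrna_id = f"mrna_decoy_{i:03d}"
            add_gene(mrna_id, base + 2_000 + int(rng.integers(60_000, 120_000)), "mRNA")
            mrna_table.append(
                ExpressionSeries(mrna_id, "mRNA", stages, _stage_values(rng, float(rng.uniform(100, 400)), fc, n))
            )
            annotated.append(lnc_id)
            corr_pairs.append((lnc_id, mrna_id, cfg.cis_r_target))
            patient_direction[mrna_id] = direction
        else:  # mode == 4: changing lncRNA whose only neighbor is flat
            mrna_id = f"mrna_decoy_{i:03d}"
            add_gene(mrna_id, base + 2_000 + int(rng.integers(1_000, 40_000)), "mRNA")
            mrna_table.append(
                ExpressionSeries(mrna_id, "mRNA", stages, _stage_values(rng, float(rng.uniform(100, 400)), 1.0, n))
            )
            annotated.append(lnc_id)

    # unrelated scattered flat mRNAs
    for i in range(cfg.n_mrna_decoys):
        mrna_id = f"mrna_flat_{i:03d}"
        add_gene(mrna_id, next_slot(), "mRNA")
        mrna_table.append(
            ExpressionSeries(mrna_id, "mRNA", stages, _stage_values(rng, float(rng.uniform(100, 400)), 1.0, n))
        )

    # patient matrix: latent-factor construction for correlated pairs,
    # independent noise for everything else
    patients = [f"P{i:03d}" for i in range(cfg.n_patients)]
    rows: dict[str, np.ndarray] = {}
    for lnc_id, mrna_id, r in corr_pairs:
        z = rng.standard_normal(cfg.n_patients)
        loading = np.sqrt(r)
        for fid in (lnc_id, mrna_id):
            noise = rng.standard_normal(cfg.n_patients)
            rows[fid] = loading * z + np.sqrt(1 - loading**2) * noise
    for fid in uncorr_rows:
        rows[fid] = rng.standard_normal(cfg.n_patients)
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=patients)
    matrix.index.name = "feature_id"

    return ExpressionBundle(
        lnc_table=tuple(lnc_table),
        mrna_table=tuple(mrna_table),
        annotation=tuple(annotation),
        annotated_ids=tuple(annotated),
        patient_matrix=matrix,
        patient_direction=patient_direction,
        truth_pairs=tuple(truth_pairs),
        truth_extreme=tuple(truth_extreme),
    )


def write_expression(bundle: ExpressionBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expression_to_frame(bundle.lnc_table).to_csv(outdir / "lnc.tsv", sep="\t", index=False)
    expression_to_frame(bundle.mrna_table).to_csv(outdir / "mrna.tsv", sep="\t", index=False)
    write_gene_bed(bundle.annotation, outdir / "genes.bed")
    Path(outdir / "annotated_ids.txt").write_text("\n".join(bundle.annotated_ids) + "\n")
    bundle.patient_matrix.to_csv(outdir / "patient_matrix.tsv", sep="\t")
    pd.Series(bundle.patient_direction, name="direction").rename_axis("feature_id").to_csv(
        outdir / "patient_direction.tsv", sep="\t"
    )
    pd.DataFrame(bundle.truth_pairs, columns=["lncrna_id", "mrna_id"]).to_csv(
        outdir / "truth_pairs.tsv", sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Patient cohort fixture


def gen_patient_cohort(
    regions: Sequence[GenomicInterval],
    fractions: Sequence[float],
    n_patients: int,
    seed: int,
    cohort_name: str = "synthetic_cohort",
):
    """Patient SE sets in which region i is represented in round(f_i * n)
    patients; each positive patient carries an SE overlapping the region."""
    from .se_dynamics import PatientSECohort

    if len(regions) != len(fractions):
        raise ValueError("one fraction per region required")
    rng = np.random.default_rng(seed)
    per_patient: list[list[GenomicInterval]] = [[] for _ in range(n_patients)]
    for region, frac in zip(regions, fractions):
        k = int(round(frac * n_patients))
        positive = rng.choice(n_patients, size=k, replace=False)
        for p in positive:
            jitter = int(rng.integers(-2_000, 2_000))
            start = max(0, region.start + jitter)
            per_patient[p].append(GenomicInterval(region.chrom, start, max(start + 1, region.end + jitter)))
    return PatientSECohort(
        cohort_name,
        [(f"patient_{i:03d}", regs) for i, regs in enumerate(per_patient)],
    )


# ---------------------------------------------------------------------------
# qPCR fixture


@dataclass(frozen=True)
class QpcrBundle:
    """Long-format Ct table plus planted truth.

    ``ct_table`` columns: sample_id, gene_id, fraction, condition,
    replicate, ct.  ``truth_fold_changes``: gene_id -> planted fold change
    (tumor vs control, whole-cell).  ``truth_shares``: gene_id -> planted
    nuclear share (control condition).
    """

    ct_table: pd.DataFrame
    reference_genes: tuple[str, ...]
    control_condition: str
    condition: str
    truth_fold_changes: dict[str, float]
    truth_shares: dict[str, float]


_PLANTED_FCS = (2.0, 0.5, 4.0, 1.0, 8.0)
_PLANTED_SHARES = (0.9, 0.8, 0.5, 0.2, 0.1)


def gen_qpcr(cfg: SynthConfig | None = None) -> QpcrBundle:
    """Ct table with planted fold changes and nuclear/cytoplasmic splits.

    A planted fold change f appears as a target Ct shift of -log2(f) in the
    tumor condition (references unshifted); a planted nuclear share s as a
    fraction Ct difference of -log2(s/(1-s)).  Gaussian noise of
    ``noise_sd`` cycles is added to every observation.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed + 2)
    control, tumor = "normal", "tumor"
    refs = {"RN18S": 14.0, "ACTB": 18.0, "GAPDH": 20.0}
    rows = []
    truth_fc: dict[str, float] = {}
    truth_share: dict[str, float] = {}

    def emit(gene, fraction, condition, base_ct):
        for rep in range(1, cfg.n_replicates + 1):
            ct = base_ct + float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd else base_ct
            rows.append(
                {
                    "sample_id": f"{condition}_{fraction}",
                    "gene_id": gene,
                    "fraction": fraction,
                    "condition": condition,
                    "replicate": rep,
                    "ct": round(ct, 6),
                }
            )

    for gene, ct0 in refs.items():
        for cond in (control, tumor):
            emit(gene, "whole", cond, ct0)
        for frac in ("nuclear", "cytoplasmic"):
            emit(gene, frac, control, ct0 + 1.0)

    for i in range(cfg.n_qpcr_targets):
        gene = f"target_{i:03d}"
        fc = _PLANTED_FCS[i % len(_PLANTED_FCS)]
        share = _PLANTED_SHARES[i % len(_PLANTED_SHARES)]
        base_ct = float(rng.uniform(22, 28))
        emit(gene, "whole", control, base_ct)
        emit(gene, "whole", tumor, base_ct - np.log2(fc))
        # fractions measured in the control condition
        cyto_ct = base_ct + 1.0
        nuc_ct = cyto_ct - float(np.log2(share / (1 - share)))
        emit(gene, "nuclear", control, nuc_ct)
        emit(gene, "cytoplasmic", control, cyto_ct)
        truth_fc[gene] = fc
        truth_share[gene] = share

    return QpcrBundle(
        ct_table=pd.DataFrame(rows),
        reference_genes=tuple(refs),
        control_condition=control,
        condition=tumor,
        truth_fold_changes=truth_fc,
        truth_shares=truth_share,
    )


def write_qpcr(bundle: QpcrBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.ct_table.to_csv(outdir / "ct.tsv", sep="\t", index=False)
    pd.Series(bundle.truth_fold_changes, name="fold_change").rename_axis("gene_id").to_csv(
        outdir / "truth_fold_changes.tsv", sep="\t"
    )
    pd.Series(bundle.truth_shares, name="nuclear_share").rename_axis("gene_id").to_csv(
        outdir / "truth_shares.tsv", sep="\t"
    )
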