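"""Prioritization cascade for potentially cis-acting SE-lncRNAs.

Starting from a per-stage expression table of lncRNAs transcribed from
super-enhancer regions, the funnel narrows candidates through successive
filters:

1. differential: |log2 FC| between the first and last stage >= log2(2);
2. proximity: a neighboring mRNA within 50 kb (gene body to gene body)
   whose expression passes the same fold-change cutoff;
3. annotation: the lncRNA is annotated in an external patient atlas
   (membership supplied as a plain id list, never fetched);
4. correlation: |Pearson r| >= 0.5 between lncRNA and mRNA across patients;
   pairs that cannot be or are not correlated fall through to
5. trend concordance: the mRNA's normal-to-tumor direction in patients
   matches its direction across the cell-line series.

A separate branch keeps extreme responders (|log2 FC| >= log2(10),
annotated) regardless of pairing.  The shortlist is the union of the
correlation, trend, and extreme branches.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneAnnotation, genes_within_window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionSeries:
    """One feature's linear-scale expression across ordered stages."""

    feature_id: str
    biotype: str  # lncRNA | mRNA
    stages: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.stages) != len(self.values):
            raise ValueError(f"{self.feature_id}: one value per stage required")
        if any(not math.isfinite(v) or v < 0 for v in self.values):
            raise ValueError(f"{self.feature_id}: values must be finite and >= 0")

    def value(self, stage: str) -> float:
        try:
            return self.values[self.stages.index(stage)]
        except ValueError as exc:
            raise KeyError(f"unknown stage {stage!r} for {self.feature_id}") from exc


@dataclass(frozen=True)
class CandidatePair:
    lncrna_id: str
    mrna_id: str
    distance_bp: int
    lncrna_fc: float  # log2
    mrna_fc: float  # log2
    pearson_r: float | None = None
    annotated: bool = False
    trend_concordant: bool | None = None


@dataclass(frozen=True)
class CascadeConfig:
    """Funnel thresholds.

    Fold-change cutoffs are on the linear scale and applied as
    |log2 FC| >= log2(cutoff), boundary inclusive.
    """

    fc_cutoff: float = 2.0
    top_fc_cutoff: float = 10.0
    window_bp: int = 50_000
    r_cutoff: float = 0.5
    first_stage: str = ""
    last_stage: str = ""
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 0 or self.top_fc_cutoff < self.fc_cutoff:
            raise ValueError("need 0 < fc_cutoff <= top_fc_cutoff")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if not 0 < self.r_cutoff <= 1:
            raise ValueError("r_cutoff must be in (0, 1]")

    def contrast(self, series: ExpressionSeries) -> tuple[str, str]:
        first = self.first_stage or series.stages[0]
        last = self.last_stage or series.stages[-1]
        return first, last


@dataclass(frozen=True)
class CascadeReport:
    """Per-step retained sets, in funnel order."""

    n_input: int
    differential_ids: tuple[str, ...]
    paired: tuple[CandidatePair, ...]
    annotated: tuple[CandidatePair, ...]
    correlated: tuple[CandidatePair, ...]
    trend_concordant: tuple[CandidatePair, ...]
    top_differential_ids: tuple[str, ...]
    shortlist: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        cis = {p.lncrna_id for p in self.correlated}
        cis |= {p.lncrna_id for p in self.trend_concordant}
        cis |= set(self.top_differential_ids)
        object.__setattr__(self, "shortlist", tuple(sorted(cis)))

    @property
    def cis_pairs(self) -> tuple[CandidatePair, ...]:
        """Pairs surviving either the correlation or the trend branch."""
        return tuple(self.correlated) + tuple(self.trend_concordant)

    def counts(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "differential": len(self.differential_ids),
            "paired": len({p.lncrna_id for p in self.paired}),
            "annotated": len({p.lncrna_id for p in self.annotated}),
            "correlated": len({p.lncrna_id for p in self.correlated}),
            "trend_concordant": len({p.lncrna_id for p in self.trend_concordant}),
            "top_differential": len(self.top_differential_ids),
            "shortlist": len(self.shortlist),
        }


def fold_change(
    series: ExpressionSeries,
    stage_a: str,
    stage_b: str,
    pseudocount: float = 1.0,
) -> float:
    """log2 fold change of stage_b vs stage_a, pseudocount-stabilized.

    Antisymmetric under swapping the stages.
    """
    va, vb = series.value(stage_a), series.value(stage_b)
    return math.log2((vb + pseudocount) / (va + pseudocount))


def filter_differential(
    table: Sequence[ExpressionSeries], cfg: CascadeConfig
) -> list[str]:
    """Feature ids with |log2 FC(first -> last)| >= log2(fc_cutoff)."""
    threshold = math.log2(cfg.fc_cutoff)
    out = []
    for series in table:
        first, last = cfg.contrast(series)
        if abs(fold_change(series, first, last, cfg.pseudocount)) >= threshold:
            out.append(series.feature_id)
    return out


def pair_neighbors(
    lncrna_ids: Iterable[str],
    annotation: Sequence[GeneAnnotation],
    lnc_table: Sequence[ExpressionSeries],
    mrna_table: Sequence[ExpressionSeries],
    cfg: CascadeConfig,
    neighbor_biotypes: tuple[str, ...] = ("mRNA",),
) -> list[CandidatePair]:
    """Pair each retained lncRNA with co-changing neighbors within the window.

    Distance is gene body to gene body (nearest edges).  A neighboring gene
    qualifies only if its own |log2 FC| passes ``fc_cutoff``.  lncRNAs
    missing from the annotation are logged and skipped.
    """
    loci = {g.gene_id: g for g in annotation}
    neighbors_pool = [g for g in annotation if g.biotype in neighbor_biotypes]
    lnc_by_id = {s.feature_id: s for s in lnc_table}
    mrna_by_id = {s.feature_id: s for s in mrna_table}
    threshold = math.log2(cfg.fc_cutoff)
    pairs: list[CandidatePair] = []
    for lnc_id in lncrna_ids:
        locus = loci.get(lnc_id)
        if locus is None:
            logger.warning("lncRNA %s missing from annotation; skipped", lnc_id)
            continue
        lnc_series = lnc_by_id[lnc_id]
        first, last = cfg.contrast(lnc_series)
        lnc_fc = fold_change(lnc_series, first, last, cfg.pseudocount)
        for gene, distance in genes_within_window(
            locus.interval, neighbors_pool, cfg.window_bp
        ):
            if gene.gene_id == lnc_id:
                continue
            mrna_series = mrna_by_id.get(gene.gene_id)
            if mrna_series is None:
                continue
            m_fc = fold_change(mrna_series, first, last, cfg.pseudocount)
            if abs(m_fc) >= threshold:
                pairs.append(
                    CandidatePair(lnc_id, gene.gene_id, distance, lnc_fc, m_fc)
                )
    return pairs


def crossref_annotation(
    pairs: Sequence[CandidatePair], annotated_ids: set[str] | frozenset[str]
) -> list[CandidatePair]:
    """Keep pairs whose lncRNA is in the external annotation id set."""
    return [
        replace(p, annotated=True) for p in pairs if p.lncrna_id in annotated_ids
    ]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def correlation_filter(
    pairs: Sequence[CandidatePair],
    patient_matrix: pd.DataFrame,
    cfg: CascadeConfig,
) -> tuple[list[CandidatePair], list[CandidatePair]]:
    """Split pairs into (correlated, unresolved) on patient co-expression.

    ``patient_matrix`` is feature x patient.  Pairs with both members present
    get ``pearson_r``; those with |r| >= r_cutoff (inclusive) pass.  Pairs
    with either member absent from the matrix — or failing the threshold —
    are returned as unresolved for the trend-concordance branch.
    """
    passed: list[CandidatePair] = []
    unresolved: list[CandidatePair] = []
    for pair in pairs:
        if pair.lncrna_id in patient_matrix.index and pair.mrna_id in patient_matrix.index:
            r = pearson(
                patient_matrix.loc[pair.lncrna_id].to_numpy(),
                patient_matrix.loc[pair.mrna_id].to_numpy(),
            )
            pair = replace(pair, pearson_r=r)
            if abs(r) >= cfg.r_cutoff:
                passed.append(pair)
            else:
                unresolved.append(pair)
        else:
            unresolved.append(pair)
    return passed, unresolved


def trend_concordance_filter(
    pairs: Sequence[CandidatePair],
    patient_direction: Mapping[str, int],
    series_direction: Mapping[str, int],
) -> list[CandidatePair]:
    """Keep pairs whose mRNA moves the same way in patients and in the series.

    Directions are signs in {-1, 0, +1}; 0 (no change) never matches.
    Pairs whose mRNA is absent from either mapping are dropped with a warning.
    """
    out: list[CandidatePair] = []
    for pair in pairs:
        if pair.mrna_id not in patient_direction or pair.mrna_id not in series_direction:
            logger.warning(
                "mRNA %s missing from a direction table; pair dropped", pair.mrna_id
            )
            continue
        p, s = patient_direction[pair.mrna_id], series_direction[pair.mrna_id]
        concordant = p == s and p != 0
        if concordant:
            out.append(replace(pair, trend_concordant=True))
    return out


def top_differential(
    table: Sequence[ExpressionSeries],
    cfg: CascadeConfig,
    annotated_ids: set[str] | frozenset[str],
) -> list[str]:
    """Extreme responders: |log2 FC| >= log2(top_fc_cutoff) and annotated."""
    threshold = math.log2(cfg.top_fc_cutoff)
    out = []
    for series in table:
        first, last = cfg.contrast(series)
        fc = fold_change(series, first, last, cfg.pseudocount)
        if abs(fc) >= threshold and series.feature_id in annotated_ids:
            out.append(series.feature_id)
    return out


def series_directions(
    table: Sequence[ExpressionSeries], cfg: CascadeConfig
) -> dict[str, int]:
    """Sign of first-to-last change per feature, on the stabilized log ratio."""
    out = {}
    for series in table:
        first, last = cfg.contrast(series)
        fc = fold_change(series, first, last, cfg.pseudocount)
        out[series.feature_id] = (fc > 0) - (fc < 0)
    return out


def run_cascade(
    lnc_table: Sequence[ExpressionSeries],
    mrna_table: Sequence[ExpressionSeries],
    annotation: Sequence[GeneAnnotation],
    annotated_ids: Iterable[str],
    patient_matrix: pd.DataFrame,
    patient_direction: Mapping[str, int],
    cfg: CascadeConfig | None = None,
) -> CascadeReport:
    """Execute the full funnel and record every step's retained set.

    Deterministic and invariant to the row order of every input table:
    outputs are sorted by feature id.
    """
    cfg = cfg or CascadeConfig()
    annotated_set = frozenset(annotated_ids)
    lnc_sorted = sorted(lnc_table, key=lambda s: s.feature_id)
    mrna_sorted = sorted(mrna_table, key=lambda s: s.feature_id)
    differential = filter_differential(lnc_sorted, cfg)
    paired = pair_neighbors(differential, annotation, lnc_sorted, mrna_sorted, cfg)
    annotated = crossref_annotation(paired, annotated_set)
    correlated, unresolved = correlation_filter(annotated, patient_matrix, cfg)
    trend = trend_concordance_filter(
        unresolved, patient_direction, series_directions(mrna_sorted, cfg)
    )
    top = top_differential(lnc_sorted, cfg, annotated_set)
    return CascadeReport(
        n_input=len(lnc_sorted),
        differential_ids=tuple(differential),
        paired=tuple(paired),
        annotated=tuple(annotated),
        correlated=tuple(correlated),
        trend_concordant=tuple(trend),
        top_differential_ids=tuple(top),
    )


# ---------------------------------------------------------------------------
# Tabular I/O


def read_expression_table(path: str | Path, biotype: str) -> list[ExpressionSeries]:
    """Tab-delimited table: feature_id, biotype, then one column per stage."""
    df = pd.read_csv(path, sep="\t")
    stage_cols = [c for c in df.columns if c not in ("feature_id", "biotype")]
    return [
        ExpressionSeries(
            row["feature_id"],
            row.get("biotype", biotype),
            tuple(stage_cols),
            tuple(float(row[c]) for c in stage_cols),
        )
        for _, row in df.iterrows()
    ]


def expression_to_frame(table: Sequence[ExpressionSeries]) -> pd.DataFrame:
    if not table:
        return pd.DataFrame(columns=["feature_id", "biotype"])
    stages = table[0].stages
    rows = [
        {"feature_id": s.feature_id, "biotype": s.biotype,
         **dict(zip(s.stages, s.values))}
        for s in table
    ]
    return pd.DataFrame(rows, columns=["feature_id", "biotype", *stages])


def write_report(report: CascadeReport, outdir: str | Path) -> None:
    """CascadeReport -> per-step TSVs plus a JSON count summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.Series(report.differential_ids, name="feature_id").to_csv(
        outdir / "differential.tsv", sep="\t", index=False
    )
    for name, pairs in (
        ("paired", report.paired),
        ("annotated", report.annotated),
        ("correlated", report.correlated),
        ("trend_concordant", report.trend_concordant),
    ):
        pd.DataFrame([vars(p) for p in pairs]).to_csv(
            outdir / f"{name}.tsv", sep="\t", index=False
        )
    pd.Series(report.top_differential_ids, name="feature_id").to_csv(
        outdir / "top_differential.tsv", sep="\t", index=False
    )
    pd.Series(report.shortlist, name="feature_id").to_csv(
        outdir / "shortlist.tsv", sep="\t", index=False
    )
    with open(outdir / "counts.json", "w") as fh:
        json.dump(report.counts(), fh, indent=2)
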