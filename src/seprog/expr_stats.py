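"""qPCR relative quantification, transcript localization, and group tests.

Fold changes use the comparative-Ct (delta-delta-Ct) model: for each
condition, dCt = Ct_target - mean(Ct_reference genes); ddCt contrasts a
condition against the control; fold change = 2^(-ddCt).  Multiple reference
genes are combined by the arithmetic mean of their Ct values, i.e. the
geometric mean of their relative quantities.

Nuclear/cytoplasmic localization compares relative abundance 2^(-Ct)
between fractions of the same transcript; the nuclear share
nuc / (nuc + cyto) is thresholded into a nuclear / cytoplasmic /
undetermined call.

Group comparisons mirror standard qPCR practice: one-way ANOVA with Tukey
HSD across a progression series, unpaired or paired Student t tests for
two-group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Ct at or above this is treated as near the detection floor.
DETECTION_CT = 40.0


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR observation."""

    sample_id: str
    gene_id: str
    fraction: str  # whole | nuclear | cytoplasmic | none
    ct: float
    replicate: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct):
            raise ValueError(f"non-finite Ct for {self.gene_id}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


@dataclass(frozen=True)
class FoldChangeResult:
    gene_id: str
    condition: str
    control_condition: str
    fold_change: float  # 2^(-ddCt) of the replicate-mean Cts
    replicate_fold_changes: tuple[float, ...]
    low_confidence: bool  # any constituent Ct at/above the detection floor

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")


@dataclass(frozen=True)
class LocalizationCall:
    gene_id: str
    nuclear_share: float  # in [0, 1]; NaN when undetermined by low expression
    call: str  # nuclear | cytoplasmic | undetermined


def _mean_reference_ct(reference_gene_cts: Mapping[str, Sequence[float]]) -> float:
    """Arithmetic mean over reference genes of their replicate-mean Cts."""
    if not reference_gene_cts:
        raise ValueError("at least one reference gene required")
    return float(np.mean([np.mean(list(v)) for v in reference_gene_cts.values()]))


def delta_delta_ct(
    target_cts: Mapping[str, Sequence[float]],
    reference_gene_cts: Mapping[str, Mapping[str, Sequence[float]]],
    condition: str,
    control_condition: str,
    gene_id: str = "target",
) -> FoldChangeResult:
    """Comparative-Ct fold change of ``condition`` vs ``control_condition``.

    ``target_cts``: condition -> replicate Cts of the target gene.
    ``reference_gene_cts``: reference gene -> condition -> replicate Cts.
    Per-replicate fold changes (each replicate's dCt against the control
    mean dCt) are returned for dispersion estimates.
    """
    for cond in (condition, control_condition):
        if cond not in target_cts:
            raise KeyError(f"target Cts missing for condition {cond!r}")
        for ref, conds in reference_gene_cts.items():
            if cond not in conds:
                raise KeyError(f"reference {ref!r} missing condition {cond!r}")

    ref_ct = {
        cond: _mean_reference_ct(
            {ref: conds[cond] for ref, conds in reference_gene_cts.items()}
        )
        for cond in (condition, control_condition)
    }
    dct_control = float(np.mean(list(target_cts[control_condition]))) - ref_ct[
        control_condition
    ]
    dct_cond = float(np.mean(list(target_cts[condition]))) - ref_ct[condition]
    ddct = dct_cond - dct_control
    rep_fc = tuple(
        2.0 ** -((ct - ref_ct[condition]) - dct_control)
        for ct in target_cts[condition]
    )
    all_cts = [
        ct
        for cond in (condition, control_condition)
        for ct in target_cts[cond]
    ] + [
        ct
        for conds in reference_gene_cts.values()
        for cond in (condition, control_condition)
        for ct in conds[cond]
    ]
    return FoldChangeResult(
        gene_id=gene_id,
        condition=condition,
        control_condition=control_condition,
        fold_change=2.0**-ddct,
        replicate_fold_changes=rep_fc,
        low_confidence=any(ct >= DETECTION_CT for ct in all_cts),
    )


def localization_call(
    nuclear_cts: Sequence[float],
    cytoplasmic_cts: Sequence[float],
    reference_gene_cts: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
    gene_id: str = "target",
    nuclear_threshold: float = 0.6,
    cytoplasmic_threshold: float = 0.4,
) -> LocalizationCall:
    """Nuclear vs cytoplasmic call from fraction Cts of one transcript.

    Relative abundance per fraction is 2^(-Ct) (optionally 2^(-dCt) against
    per-fraction reference genes when supplied), normalized within the
    transcript across the two fractions.  Share >= ``nuclear_threshold`` ->
    nuclear; <= ``cytoplasmic_threshold`` -> cytoplasmic; otherwise
    undetermined.  Transcripts at the detection floor in both fractions are
    undetermined outright.
    """
    if not len(nuclear_cts) or not len(cytoplasmic_cts):
        raise ValueError("both fractions must be measured")
    nuc_ct = float(np.mean(list(nuclear_cts)))
    cyto_ct = float(np.mean(list(cytoplasmic_cts)))
    if min(nuc_ct, cyto_ct) >= DETECTION_CT:
        return LocalizationCall(gene_id, float("nan"), "undetermined")
    if reference_gene_cts:
        nuc_ct -= _mean_reference_ct(
            {ref: conds["nuclear"] for ref, conds in reference_gene_cts.items()}
        )
        cyto_ct -= _mean_reference_ct(
            {ref: conds["cytoplasmic"] for ref, conds in reference_gene_cts.items()}
        )
    # share = 2^-nuc / (2^-nuc + 2^-cyto), computed via the Ct difference
    share = 1.0 / (1.0 + 2.0 ** (nuc_ct - cyto_ct))
    if share >= nuclear_threshold:
        call = "nuclear"
    elif share <= cytoplasmic_threshold:
        call = "cytoplasmic"
    else:
        call = "undetermined"
    return LocalizationCall(gene_id, share, call)


def one_way_anova_tukey(
    groups: Sequence[Sequence[float]],
    group_names: Sequence[str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """One-way ANOVA F-test plus Tukey-HSD pairwise comparisons.

    Returns (overall p-value, DataFrame with columns group_a, group_b,
    statistic, p_adjusted).  Tukey adjustment uses the studentized-range
    distribution.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 values")
    names = list(group_names) if group_names else [f"group{i}" for i in range(len(arrays))]
    overall_p = float(stats.f_oneway(*arrays).pvalue)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "statistic": float(hsd.statistic[i, j]),
                    "p_adjusted": float(hsd.pvalue[i, j]),
                }
            )
    return overall_p, pd.DataFrame(rows)


def t_test(a: Sequence[float], b: Sequence[float], paired: bool = False) -> float:
    """Two-sided Student t test p-value (classical equal-variance form)."""
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if paired:
        if aa.size != bb.size or aa.size < 2:
            raise ValueError("paired test needs equal n >= 2")
        if np.ptp(aa - bb) == 0:
            raise ValueError("paired differences have zero variance")
        res = stats.ttest_rel(aa, bb)
    else:
        if aa.size < 2 or bb.size < 2:
            raise ValueError("each sample needs n >= 2")
        if np.ptp(aa) == 0 and np.ptp(bb) == 0:
            raise ValueError("zero pooled variance")
        res = stats.ttest_ind(aa, bb, equal_var=True)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Long-format Ct table helpers


def read_ct_table(path) -> pd.DataFrame:
    """Long-format TSV: sample_id, gene_id, fraction, condition, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gene_id", "fraction", "condition", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def _cts(df: pd.DataFrame, gene: str, condition: str, fraction: str) -> list[float]:
    sel = df[
        (df.gene_id == gene)
        & (df.condition == condition)
        & (df.fraction == fraction)
    ]
    return sel.sort_values("replicate").ct.tolist()


def fold_changes_from_table(
    df: pd.DataFrame,
    reference_genes: Sequence[str],
    control_condition: str,
    fraction: str = "whole",
) -> pd.DataFrame:
    """ddCt fold change for every (target gene, non-control condition)."""
    targets = sorted(set(df.gene_id) - set(reference_genes))
    conditions = sorted(set(df.condition) - {control_condition})
    rows = []
    for gene in targets:
        for cond in conditions:
            target_cts = {
                c: _cts(df, gene, c, fraction) for c in (cond, control_condition)
            }
            if any(not v for v in target_cts.values()):
                continue
            refs = {
                ref: {c: _cts(df, ref, c, fraction) for c in (cond, control_condition)}
                for ref in reference_genes
            }
            res = delta_delta_ct(target_cts, refs, cond, control_condition, gene)
            rows.append(
                {
                    "gene_id": gene,
                    "condition": cond,
                    "control": control_condition,
                    "fold_change": res.fold_change,
                    "low_confidence": res.low_confidence,
                }
            )
    return pd.DataFrame(rows)


def localization_from_table(
    df: pd.DataFrame,
    condition: str,
    reference_genes: Sequence[str] = (),
    **thresholds,
) -> pd.DataFrame:
    """Localization call for every non-reference gene measured in both fractions."""
    targets = sorted(set(df.gene_id) - set(reference_genes))
    rows = []
    for gene in targets:
        nuc = _cts(df, gene, condition, "nuclear")
        cyto = _cts(df, gene, condition, "cytoplasmic")
        if not nuc or not cyto:
            continue
        refs = (
            {
                ref: {
                    "nuclear": _cts(df, ref, condition, "nuclear"),
                    "cytoplasmic": _cts(df, ref, condition, "cytoplasmic"),
                }
                for ref in reference_genes
            }
            if reference_genes
            else None
        )
        call = localization_call(nuc, cyto, refs, gene, **thresholds)
        rows.append(
            {
                "gene_id": gene,
                "nuclear_share": call.nuclear_share,
                "call": call.call,
            }
        )
    return pd.DataFrame(rows)
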