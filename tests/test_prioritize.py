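"""The cis-lncRNA prioritization funnel: filters, pairing, and the cascade."""

import math

import numpy as np
import pandas as pd
import pytest

from seprog.intervals import GeneAnnotation, GenomicInterval
from seprog.prioritize import (
    CandidatePair,
    CascadeConfig,
    ExpressionSeries,
    correlation_filter,
    crossref_annotation,
    filter_differential,
    fold_change,
    pair_neighbors,
    pearson,
    run_cascade,
    top_differential,
    trend_concordance_filter,
)

STAGES = ("normal", "atypia", "dcis", "idc")


def _series(fid, values, biotype="lncRNA"):
    return ExpressionSeries(fid, biotype, STAGES, tuple(map(float, values)))


def _gene(gid, start, biotype, chrom="chr1", length=2_000):
    return GeneAnnotation(gid, GenomicInterval(chrom, start, start + length), start, biotype)


# --- fold change -------------------------------------------------------------


def test_fold_change_basics():
    s = _series("x", [100, 100, 100, 100])
    assert fold_change(s, "normal", "idc") == 0.0
    s4 = _series("x", [10_000, 1, 1, 40_000])
    assert fold_change(s4, "normal", "idc") == pytest.approx(2.0, abs=1e-3)
    assert fold_change(s4, "idc", "normal") == pytest.approx(
        -fold_change(s4, "normal", "idc"), abs=1e-12
    )
    with pytest.raises(KeyError):
        fold_change(s, "normal", "nope")


def test_fold_change_matches_direct_formula(rng):
    for _ in range(50):
        vals = rng.uniform(0, 500, size=4)
        s = _series("x", vals)
        expected = math.log2((vals[3] + 1.0) / (vals[0] + 1.0))
        assert fold_change(s, "normal", "idc") == pytest.approx(expected, abs=1e-12)


# --- differential filter -----------------------------------------------------


def test_differential_boundary_inclusive():
    cfg = CascadeConfig()
    exactly2 = _series("hit", [999, 999, 999, 1_999])  # (1999+1)/(999+1) = 2
    below = _series("miss", [999, 999, 999, 1_899])
    assert filter_differential([exactly2, below], cfg) == ["hit"]


def test_differential_planted_recovery(rng):
    cfg = CascadeConfig()
    changed = [_series(f"c{i}", [100, 150, 250, 450]) for i in range(10)]
    flat = [
        _series(f"f{i}", 100 * rng.uniform(0.95, 1.05, size=4)) for i in range(90)
    ]
    got = filter_differential(changed + flat, cfg)
    assert got == [s.feature_id for s in changed]


# --- pairing -----------------------------------------------------------------


def _pair_fixture():
    lnc = _series("lncA", [50, 100, 150, 200])
    near = _series("mrnaNear", [100, 200, 300, 400], "mRNA")
    far = _series("mrnaFar", [100, 200, 300, 400], "mRNA")
    flat = _series("mrnaFlat", [100, 100, 100, 100], "mRNA")
    annotation = [
        _gene("lncA", 100_000, "lncRNA"),
        _gene("mrnaNear", 140_000, "mRNA"),  # 38 kb gap
        _gene("mrnaFar", 165_000, "mRNA"),  # 63 kb gap
        _gene("mrnaFlat", 110_000, "mRNA"),  # near but unchanging
    ]
    return lnc, [near, far, flat], annotation


def test_pair_neighbors_window_and_cochange():
    lnc, mrnas, annotation = _pair_fixture()
    cfg = CascadeConfig()
    pairs = pair_neighbors(["lncA"], annotation, [lnc], mrnas, cfg)
    assert [p.mrna_id for p in pairs] == ["mrnaNear"]
    assert pairs[0].distance_bp == 38_000


def test_pair_neighbors_overlapping_gene_distance_zero():
    lnc = _series("lncA", [50, 100, 150, 200])
    mrna = _series("mrnaB", [100, 200, 300, 400], "mRNA")
    annotation = [
        _gene("lncA", 100_000, "lncRNA"),
        _gene("mrnaB", 101_000, "mRNA"),
    ]
    pairs = pair_neighbors(["lncA"], annotation, [lnc], [mrna], CascadeConfig())
    assert pairs[0].distance_bp == 0


def test_pair_neighbors_missing_annotation_skipped(caplog):
    lnc = _series("ghost", [50, 100, 150, 200])
    with caplog.at_level("WARNING"):
        pairs = pair_neighbors(["ghost"], [], [lnc], [], CascadeConfig())
    assert pairs == []
    assert "ghost" in caplog.text


def test_pair_neighbors_planted_fixture(rng):
    """5 planted cis pairs among 50 distal/flat decoy mRNAs -> exactly 5 pairs."""
    cfg = CascadeConfig()
    lnc_table, mrna_table, annotation, planted = [], [], [], []
    pos = 100_000
    for i in range(5):
        lid, mid = f"lnc{i}", f"mrna{i}"
        lnc_table.append(_series(lid, [50, 100, 150, 250]))
        mrna_table.append(_series(mid, [100, 200, 300, 500], "mRNA"))
        annotation.append(_gene(lid, pos, "lncRNA"))
        annotation.append(_gene(mid, pos + 2_000 + int(rng.integers(1_000, 40_000)), "mRNA"))
        planted.append((lid, mid))
        pos += 200_000
    for i in range(50):
        mid = f"decoy{i}"
        mrna_table.append(_series(mid, [100, 200, 300, 500], "mRNA"))
        annotation.append(_gene(mid, pos, "mRNA"))
        pos += 200_000
    pairs = pair_neighbors(
        [s.feature_id for s in lnc_table], annotation, lnc_table, mrna_table, cfg
    )
    assert sorted((p.lncrna_id, p.mrna_id) for p in pairs) == planted


# --- annotation cross-reference ----------------------------------------------


def test_crossref_subsets():
    pairs = [
        CandidatePair("a", "m1", 0, 1.5, 1.5),
        CandidatePair("b", "m2", 0, 1.5, 1.5),
    ]
    assert crossref_annotation(pairs, set()) == []
    both = crossref_annotation(pairs, {"a", "b"})
    assert [p.lncrna_id for p in both] == ["a", "b"]
    assert all(p.annotated for p in both)
    assert [p.lncrna_id for p in crossref_annotation(pairs, {"b"})] == ["b"]


# --- pearson -----------------------------------------------------------------


def test_pearson_exact_cases():
    x = [1.0, 2.0, 3.0, 4.0]
    assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
    assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)
    # hand formula for x=(1,2,3,4), y=(1,3,2,4): cov=2.5/..., r=0.8
    assert pearson(x, [1.0, 3.0, 2.0, 4.0]) == pytest.approx(0.8)


def test_pearson_constant_vector_errors():
    with pytest.raises(ValueError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_pearson_matches_two_pass_formula(rng):
    for _ in range(30):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        mx, my = x.mean(), y.mean()
        num = float(((x - mx) * (y - my)).sum())
        den = math.sqrt(float(((x - mx) ** 2).sum()) * float(((y - my) ** 2).sum()))
        assert pearson(x, y) == pytest.approx(num / den, abs=1e-12)


# --- correlation & trend filters ---------------------------------------------


def _patient_matrix(rows):
    return pd.DataFrame(rows, columns=[f"P{i}" for i in range(len(next(iter(rows.values()))))])


def test_correlation_filter_planted_and_noise(rng):
    z = rng.standard_normal(50)
    a = math.sqrt(0.9)
    matrix = pd.DataFrame(
        {
            "lnc_hi": a * z + math.sqrt(1 - a * a) * rng.standard_normal(50),
            "mrna_hi": a * z + math.sqrt(1 - a * a) * rng.standard_normal(50),
            "lnc_lo": rng.standard_normal(50),
            "mrna_lo": rng.standard_normal(50),
        }
    ).T
    pairs = [
        CandidatePair("lnc_hi", "mrna_hi", 0, 2.0, 2.0),
        CandidatePair("lnc_lo", "mrna_lo", 0, 2.0, 2.0),
        CandidatePair("lnc_absent", "mrna_absent", 0, 2.0, 2.0),
    ]
    passed, unresolved = correlation_filter(pairs, matrix, CascadeConfig())
    assert [p.lncrna_id for p in passed] == ["lnc_hi"]
    assert passed[0].pearson_r > 0.5
    # failing and absent pairs both fall through to the trend branch
    assert [p.lncrna_id for p in unresolved] == ["lnc_lo", "lnc_absent"]
    assert unresolved[0].pearson_r is not None
    assert unresolved[1].pearson_r is None


def test_correlation_boundary_inclusive():
    # x=(1,2,3), y=(0,-2,2): r = 2/sqrt(2*8) = 0.5, exact in floating point
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([0.0, -2.0, 2.0])
    assert pearson(x, y) == 0.5
    matrix = pd.DataFrame({"l": x, "m": y}).T
    pairs = [CandidatePair("l", "m", 0, 2.0, 2.0)]
    passed, unresolved = correlation_filter(pairs, matrix, CascadeConfig())
    assert len(passed) == 1
    assert passed[0].pearson_r == pytest.approx(0.5)


def test_trend_concordance_sign_logic(caplog):
    pairs = [
        CandidatePair("a", "m_up", 0, 2.0, 2.0),
        CandidatePair("b", "m_down", 0, 2.0, 2.0),
        CandidatePair("c", "m_zero", 0, 2.0, 2.0),
        CandidatePair("d", "m_missing", 0, 2.0, 2.0),
    ]
    patient = {"m_up": 1, "m_down": -1, "m_zero": 0}
    series = {"m_up": 1, "m_down": 1, "m_zero": 0}
    with caplog.at_level("WARNING"):
        kept = trend_concordance_filter(pairs, patient, series)
    assert [p.lncrna_id for p in kept] == ["a"]
    assert kept[0].trend_concordant is True
    assert "m_missing" in caplog.text


def test_trend_random_signs_match_elementwise_oracle(rng):
    pairs = [CandidatePair(f"l{i}", f"m{i}", 0, 2.0, 2.0) for i in range(100)]
    patient = {f"m{i}": int(rng.integers(-1, 2)) for i in range(100)}
    series = {f"m{i}": int(rng.integers(-1, 2)) for i in range(100)}
    kept = {p.mrna_id for p in trend_concordance_filter(pairs, patient, series)}
    expected = {
        m for m in patient if patient[m] == series[m] and patient[m] != 0
    }
    assert kept == expected


# --- extreme responders ------------------------------------------------------


def test_top_differential_rules():
    cfg = CascadeConfig()
    exactly10 = _series("ten", [999, 0, 0, 9_999])  # ratio exactly 10
    big_unannotated = _series("big", [100, 0, 0, 5_000])
    assert top_differential([exactly10, big_unannotated], cfg, {"ten"}) == ["ten"]
    assert top_differential([big_unannotated], cfg, set()) == []


# --- cascade -----------------------------------------------------------------


def test_cascade_empty_input():
    report = run_cascade([], [], [], [], pd.DataFrame(), {})
    assert report.counts() == {
        "input": 0,
        "differential": 0,
        "paired": 0,
        "annotated": 0,
        "correlated": 0,
        "trend_concordant": 0,
        "top_differential": 0,
        "shortlist": 0,
    }


def test_cascade_planted_truth_recovery(expression):
    report = run_cascade(
        expression.lnc_table,
        expression.mrna_table,
        expression.annotation,
        expression.annotated_ids,
        expression.patient_matrix,
        expression.patient_direction,
    )
    predicted = {(p.lncrna_id, p.mrna_id) for p in report.cis_pairs}
    truth = set(expression.truth_pairs)
    assert predicted == truth  # precision = recall = 1.0
    assert set(report.top_differential_ids) == set(expression.truth_extreme)


def test_cascade_funnel_monotone(expression):
    report = run_cascade(
        expression.lnc_table,
        expression.mrna_table,
        expression.annotation,
        expression.annotated_ids,
        expression.patient_matrix,
        expression.patient_direction,
    )
    diff = set(report.differential_ids)
    paired = {p.lncrna_id for p in report.paired}
    annotated = {p.lncrna_id for p in report.annotated}
    resolved = {p.lncrna_id for p in report.correlated} | {
        p.lncrna_id for p in report.trend_concordant
    }
    assert paired <= diff
    assert annotated <= paired
    assert resolved <= annotated
    counts = report.counts()
    assert (
        counts["input"]
        >= counts["differential"]
        >= counts["paired"]
        >= counts["annotated"]
        >= counts["correlated"]
    )


def test_cascade_shortlist_is_exact_union(expression):
    report = run_cascade(
        expression.lnc_table,
        expression.mrna_table,
        expression.annotation,
        expression.annotated_ids,
        expression.patient_matrix,
        expression.patient_direction,
    )
    expected = (
        {p.lncrna_id for p in report.correlated}
        | {p.lncrna_id for p in report.trend_concordant}
        | set(report.top_differential_ids)
    )
    assert set(report.shortlist) == expected
    assert len(report.shortlist) == len(set(report.shortlist))


def test_cascade_invariant_to_row_order(rng, expression):
    base = run_cascade(
        expression.lnc_table,
        expression.mrna_table,
        expression.annotation,
        expression.annotated_ids,
        expression.patient_matrix,
        expression.patient_direction,
    )
    lnc = list(expression.lnc_table)
    mrna = list(expression.mrna_table)
    annot = list(expression.annotation)
    shuffled = run_cascade(
        [lnc[i] for i in rng.permutation(len(lnc))],
        [mrna[i] for i in rng.permutation(len(mrna))],
        [annot[i] for i in rng.permutation(len(annot))],
        list(expression.annotated_ids)[::-1],
        expression.patient_matrix.sample(frac=1, random_state=7),
        expression.patient_direction,
    )
    assert base.shortlist == shuffled.shortlist
    assert set(base.differential_ids) == set(shuffled.differential_ids)
    assert {(p.lncrna_id, p.mrna_id) for p in base.cis_pairs} == {
        (p.lncrna_id, p.mrna_id) for p in shuffled.cis_pairs
    }
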