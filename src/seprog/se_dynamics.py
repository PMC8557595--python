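"""Acquired / lost / retained super-enhancer dynamics across a progression.

A stage series is ordered from the baseline (normal) line onward, e.g.
MCF10A -> AT1 -> DCIS -> CA1.  "Present at a stage" means >= 1 bp overlap
with any SE interval of that stage: stitched boundaries shift between
samples, so identity of coordinates is never required.

- acquired at stage k: an SE of stage k overlapping nothing at any earlier
  stage (reported with the stage-k coordinates).
- lost at stage k: a baseline SE overlapping nothing at stage k.
- retained: an acquired SE that stays present at every later stage through
  the end of the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, overlaps


@dataclass(frozen=True)
class StageSECollection:
    stage_name: str
    stage_index: int
    regions: tuple[GenomicInterval, ...]

    def __init__(
        self,
        stage_name: str,
        stage_index: int,
        regions: Sequence[GenomicInterval],
    ) -> None:
        if stage_index < 0:
            raise ValueError("stage_index must be >= 0")
        object.__setattr__(self, "stage_name", stage_name)
        object.__setattr__(self, "stage_index", stage_index)
        object.__setattr__(self, "regions", tuple(regions))


@dataclass(frozen=True)
class SEDynamicsLabel:
    region: GenomicInterval
    status: str  # acquired | lost | retained
    stage_name: str


@dataclass(frozen=True)
class PatientSECohort:
    cohort_name: str
    patients: tuple[tuple[str, tuple[GenomicInterval, ...]], ...]

    def __init__(
        self,
        cohort_name: str,
        patients: Sequence[tuple[str, Sequence[GenomicInterval]]],
    ) -> None:
        ids = [pid for pid, _ in patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in cohort")
        object.__setattr__(self, "cohort_name", cohort_name)
        object.__setattr__(
            self,
            "patients",
            tuple((pid, tuple(regs)) for pid, regs in patients),
        )


def _present(region: GenomicInterval, regions: Sequence[GenomicInterval]) -> bool:
    return any(overlaps(region, other) for other in regions)


def _check_series(series: Sequence[StageSECollection]) -> None:
    indices = [s.stage_index for s in series]
    if indices != sorted(indices) or len(set(indices)) != len(indices):
        raise ValueError("stage series must have unique, ascending stage_index")


def acquired_at_stage(
    series: Sequence[StageSECollection], k: int
) -> list[GenomicInterval]:
    """SEs of stage ``k`` overlapping no SE of any stage before it."""
    _check_series(series)
    if not 1 <= k < len(series):
        raise ValueError("acquisition is defined for 1 <= k < n_stages")
    earlier = [iv for stage in series[:k] for iv in stage.regions]
    return [iv for iv in series[k].regions if not _present(iv, earlier)]


def lost_at_stage(
    baseline: StageSECollection, stage: StageSECollection
) -> list[GenomicInterval]:
    """Baseline SEs with no overlapping SE at ``stage``."""
    if baseline.stage_index != 0:
        raise ValueError("loss is measured relative to the baseline (index 0)")
    return [iv for iv in baseline.regions if not _present(iv, stage.regions)]


def retained(
    acquired: Mapping[int, Sequence[GenomicInterval]],
    series: Sequence[StageSECollection],
) -> list[SEDynamicsLabel]:
    """Label each acquired region ``retained`` if present at every later stage.

    ``acquired`` maps stage index -> regions from :func:`acquired_at_stage`.
    Regions acquired at the final stage are trivially retained.
    """
    _check_series(series)
    labels: list[SEDynamicsLabel] = []
    for k, regions in sorted(acquired.items()):
        stage_name = series[k].stage_name
        for iv in regions:
            persists = all(
                _present(iv, later.regions) for later in series[k + 1 :]
            )
            labels.append(
                SEDynamicsLabel(iv, "retained" if persists else "acquired", stage_name)
            )
    return labels


def classify_dynamics(series: Sequence[StageSECollection]) -> pd.DataFrame:
    """Full dynamics table: acquired/retained per stage plus losses vs baseline.

    Columns: chrom, start, end, status, stage.
    """
    _check_series(series)
    acquired = {k: acquired_at_stage(series, k) for k in range(1, len(series))}
    rows = [
        (l.region.chrom, l.region.start, l.region.end, l.status, l.stage_name)
        for l in retained(acquired, series)
    ]
    for stage in series[1:]:
        for iv in lost_at_stage(series[0], stage):
            rows.append((iv.chrom, iv.start, iv.end, "lost", stage.stage_name))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "status", "stage"]
    )


def cohort_representation(
    region: GenomicInterval, cohort: PatientSECohort
) -> tuple[int, int]:
    """(count, total): patients with >= 1 SE overlapping ``region``.

    Presence per patient is boolean — overlapping two of a patient's SEs
    still counts that patient once.
    """
    if not cohort.patients:
        raise ValueError(f"cohort {cohort.cohort_name!r} has no patients")
    count = sum(1 for _, regions in cohort.patients if _present(region, regions))
    return count, len(cohort.patients)
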