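"""False-positive accounting for null genome scans.

Counts genome-wide significant (GWS) markers per replicate at the classic
LOD thresholds (3.3 GWS, 1.9 suggestive), estimates the family-wise error
rate across replicates with an exact binomial interval, stratifies
significant markers by estimated MAF, and profiles which families drive
each significant score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genotypes import MarkerInfo
from .linkage import LodResult
from .allele_freq import MAF_FLOOR


@dataclass(frozen=True)
class Thresholds:
    """LOD thresholds: genome-wide significant, suggestive, family profiling."""

    gws_lod: float = 3.3
    suggestive_lod: float = 1.9
    family_minor_lod_mid: float = 1.0
    family_minor_lod_low: float = 0.5

    def __post_init__(self) -> None:
        if not (
            self.gws_lod > self.suggestive_lod
            > self.family_minor_lod_mid > self.family_minor_lod_low > 0
        ):
            raise ValueError("thresholds must satisfy gws > suggestive > mid > low > 0")


@dataclass
class SignificantMarker:
    marker_id: str
    total_lod: float
    estimated_maf: float | None
    family_lods: dict[str, float]
    position_bp: int | None = None
    chromosome: str | None = None


@dataclass
class ReplicateSummary:
    replicate: int
    n_significant_markers: int
    max_lod: float
    records: list[SignificantMarker] = field(default_factory=list)


@dataclass
class ExperimentSummary:
    n_replicates: int
    n_replicates_with_gws: int
    fwer_estimate: float
    fwer_ci95: tuple[float, float]
    mean_significant: float
    min_significant: int
    max_significant: int
    n_significant_total: int
    maf_lt_005: int
    maf_lt_001: int
    maf_at_floor: int
    n_driver_1_2_suggestive: int
    n_diffuse: int
    n_other_profile: int
    thresholds: Thresholds = field(default_factory=Thresholds)


def summarize_replicate(
    lods: Iterable[LodResult],
    thresholds: Thresholds = Thresholds(),
    replicate: int = 0,
    marker_info: dict[str, MarkerInfo] | None = None,
) -> ReplicateSummary:
    """Count markers with total LOD >= the GWS threshold (boundary inclusive).

    Non-finite totals (-inf sentinels from zero likelihood at the tested
    theta, NaN) are evidence against linkage and are excluded from both the
    count and the maximum.
    """
    n_sig = 0
    max_lod = -math.inf
    records: list[SignificantMarker] = []
    empty = True
    for r in lods:
        empty = False
        t = r.total_lod
        if not math.isfinite(t):
            continue
        max_lod = max(max_lod, t)
        if t >= thresholds.gws_lod:
            n_sig += 1
            info = (marker_info or {}).get(r.marker_id)
            records.append(
                SignificantMarker(
                    marker_id=r.marker_id,
                    total_lod=t,
                    estimated_maf=info.estimated_maf if info else None,
                    family_lods=dict(r.family_lod),
                    position_bp=info.position_bp if info else None,
                    chromosome=info.chromosome if info else None,
                )
            )
    if empty:
        raise ValueError("empty LOD stream")
    return ReplicateSummary(
        replicate=replicate,
        n_significant_markers=n_sig,
        max_lod=max_lod,
        records=records,
    )


def family_contribution_profile(
    family_lods: dict[str, float] | SignificantMarker,
    thresholds: Thresholds = Thresholds(),
) -> str:
    """Label who drives a significant marker.

    ``driver_1_2_suggestive``: one or two families alone exceed the
    suggestive threshold.  ``diffuse``: no family exceeds the mid threshold
    and two to five families sit above the low threshold.  Everything else
    is ``other``.
    """
    if isinstance(family_lods, SignificantMarker):
        family_lods = family_lods.family_lods
    vals = np.array(list(family_lods.values()), dtype=float)
    n_sugg = int((vals > thresholds.suggestive_lod).sum())
    if 1 <= n_sugg <= 2:
        return "driver_1_2_suggestive"
    n_mid = int((vals > thresholds.family_minor_lod_mid).sum())
    n_low = int((vals > thresholds.family_minor_lod_low).sum())
    if n_mid == 0 and 2 <= n_low <= 5:
        return "diffuse"
    return "other"


def summarize_experiment(
    reps: Sequence[ReplicateSummary],
    thresholds: Thresholds = Thresholds(),
) -> ExperimentSummary:
    """Experiment-level accounting across replicates.

    The FWER estimate is the fraction of replicates with at least one GWS
    marker, with a Clopper-Pearson (exact binomial) 95% interval.  MAF
    strata are nested: the floor stratum (MAF exactly 0.0001) is contained
    in < 0.01, which is contained in < 0.05.
    """
    if not reps:
        raise ValueError("need at least one replicate summary")
    n = len(reps)
    k = sum(1 for r in reps if r.n_significant_markers >= 1)
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    counts = [r.n_significant_markers for r in reps]
    all_records = [rec for r in reps for rec in r.records]
    mafs = np.array(
        [rec.estimated_maf for rec in all_records if rec.estimated_maf is not None]
    )
    profiles = [family_contribution_profile(rec, thresholds) for rec in all_records]
    return ExperimentSummary(
        n_replicates=n,
        n_replicates_with_gws=k,
        fwer_estimate=k / n,
        fwer_ci95=(float(ci.low), float(ci.high)),
        mean_significant=float(np.mean(counts)),
        min_significant=int(min(counts)),
        max_significant=int(max(counts)),
        n_significant_total=len(all_records),
        maf_lt_005=int((mafs < 0.05).sum()) if mafs.size else 0,
        maf_lt_001=int((mafs < 0.01).sum()) if mafs.size else 0,
        maf_at_floor=int((mafs == MAF_FLOOR).sum()) if mafs.size else 0,
        n_driver_1_2_suggestive=profiles.count("driver_1_2_suggestive"),
        n_diffuse=profiles.count("diffuse"),
        n_other_profile=profiles.count("other"),
        thresholds=thresholds,
    )


def cross_replicate_overlap(reps: Sequence[ReplicateSummary]) -> dict[str, int]:
    """How many replicates each ever-significant marker was significant in."""
    counts: dict[str, int] = {}
    for r in reps:
        for rec in r.records:
            counts[rec.marker_id] = counts.get(rec.marker_id, 0) + 1
    return counts
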