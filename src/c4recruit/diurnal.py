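"""Closely related duplicates within recruited lineages, and diurnal
time-course normalization.

Recent duplicates are recognized when several nonidentical genes are
assigned to one lineage in one species; pairs with identical coding
sequence cannot be distinguished by read assignment and are merged by
*averaging* their expression (lineage totals elsewhere are sums — the
two procedures are deliberately distinct).  Diurnal RT-PCR-style signals
are normalized per time point to a constitutive reference gene
(polyubiquitin UBQ10 in the original assays) and summarized by peak and
trough position, amplitude, and whether the peak falls in the light
period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DuplicateGroup",
    "DuplicateReport",
    "TimeCourse",
    "NormalizedTimeCourse",
    "TimeCourseSummary",
    "detect_duplicates",
    "compare_duplicates",
    "normalize_timecourse",
    "summarize_timecourse",
]

SEGMENTS = ("A", "B", "C", "D")


@dataclass
class DuplicateGroup:
    """>= 2 genes of one species assigned to one lineage, with their
    leaf-gradient rpkm profiles (segments A-D)."""

    family_id: str
    lineage_id: str
    species_id: str
    profiles: dict[str, dict[str, float]]  # gene_id -> {A,B,C,D: rpkm}
    merged_identical: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.profiles) < 2:
            raise ValueError("a duplicate group needs >= 2 genes")


def detect_duplicates(
    assignment: dict[str, tuple[str, str, str]],
    profiles: dict[str, dict[str, float]],
    identical_cds: Sequence[frozenset[str]] = (),
) -> list[DuplicateGroup]:
    """Group genes by (family, lineage, species) and keep groups of >= 2.

    ``assignment`` maps gene_id -> (family_id, lineage_id, species_id);
    ``identical_cds`` lists sets of genes with identical coding sequence,
    which are merged into one pseudo-gene (ids joined with '/') whose
    profile is the per-segment mean.
    """
    ident_of = {}
    for group in identical_cds:
        for g in group:
            ident_of[g] = frozenset(group)

    buckets: dict[tuple[str, str, str], dict[str, dict[str, float]]] = {}
    merged_by_bucket: dict[tuple[str, str, str], list[tuple[str, ...]]] = {}
    seen_merged: set[frozenset[str]] = set()
    for gene, key in sorted(assignment.items()):
        if gene not in profiles:
            continue
        if gene in ident_of:
            members = ident_of[gene]
            if members in seen_merged:
                continue
            seen_merged.add(members)
            ordered = tuple(sorted(members))
            merged_id = "/".join(ordered)
            prof = {
                s: float(np.mean([profiles[g][s] for g in ordered]))
                for s in SEGMENTS
            }
            buckets.setdefault(key, {})[merged_id] = prof
            merged_by_bucket.setdefault(key, []).append(ordered)
        else:
            buckets.setdefault(key, {})[gene] = dict(profiles[gene])

    groups = []
    for (family, lineage, species), profs in sorted(buckets.items()):
        if len(profs) < 2:
            continue
        groups.append(
            DuplicateGroup(
                family_id=family,
                lineage_id=lineage,
                species_id=species,
                profiles=profs,
                merged_identical=merged_by_bucket.get(
                    (family, lineage, species), []
                ),
            )
        )
    return groups


@dataclass
class DuplicateReport:
    family_id: str
    lineage_id: str
    species_id: str
    max_rpkm: dict[str, float]
    dev_increase: dict[str, bool]
    dominant_gene: str
    runner_up: Optional[str]
    dominance_ratio: float  # inf when the runner-up never exceeds 0
    tie: bool = False


def compare_duplicates(group: DuplicateGroup) -> DuplicateReport:
    """Rank duplicates by their maximum rpkm over segments A-D.

    The dominant gene is the one with the highest maximum; the dominance
    ratio divides it by the runner-up's maximum (infinite when the
    runner-up is never detected).  Equal maxima are a logged tie broken
    by gene id order.
    """
    maxima = {
        g: max(prof[s] for s in SEGMENTS) for g, prof in group.profiles.items()
    }
    dev = {
        g: (prof["C"] + prof["D"]) / 2.0 > (prof["A"] + prof["B"]) / 2.0
        for g, prof in group.profiles.items()
    }
    ranked = sorted(maxima.items(), key=lambda kv: (-kv[1], kv[0]))
    dominant, top = ranked[0]
    runner, second = ranked[1]
    ratio = math.inf if second == 0 else top / second
    return DuplicateReport(
        family_id=group.family_id,
        lineage_id=group.lineage_id,
        species_id=group.species_id,
        max_rpkm=maxima,
        dev_increase=dev,
        dominant_gene=dominant,
        runner_up=runner,
        dominance_ratio=ratio,
        tie=(top == second),
    )


@dataclass
class TimeCourse:
    """Replicated signals for one gene over a day, with matched reference-
    gene signals for normalization.

    ``signals`` and ``reference`` are (n_times, n_replicates) arrays;
    ``times`` are hours after dawn; ``lights_on_duration`` is the length
    of the light period in hours.
    """

    gene_id: str
    species_id: str
    photo_type: str
    times: np.ndarray
    signals: np.ndarray
    reference: np.ndarray
    lights_on_duration: float = 12.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.signals = np.atleast_2d(np.asarray(self.signals, float))
        self.reference = np.atleast_2d(np.asarray(self.reference, float))
        if len(self.times) < 2:
            raise ValueError("need >= 2 time points")
        if self.signals.shape != self.reference.shape:
            raise ValueError("signal and reference shapes differ")
        if self.signals.shape[0] != len(self.times):
            raise ValueError("first axis of signals must index time points")


@dataclass
class NormalizedTimeCourse:
    times: np.ndarray
    normalized: np.ndarray  # (n_times, n_replicates)
    mean: np.ndarray
    se: np.ndarray


def normalize_timecourse(tc: TimeCourse) -> NormalizedTimeCourse:
    """Divide each signal by the matched reference signal, then average
    replicates per time point (standard error uses the n-1 denominator)."""
    bad = np.argwhere(tc.reference <= 0)
    if bad.size:
        t_idx, rep = bad[0]
        raise ValueError(
            f"nonpositive reference signal at t={tc.times[t_idx]:g} h, "
            f"replicate {rep}"
        )
    norm = tc.signals / tc.reference
    mean = norm.mean(axis=1)
    n = norm.shape[1]
    if n > 1:
        se = norm.std(axis=1, ddof=1) / math.sqrt(n)
    else:
        se = np.zeros_like(mean)
    return NormalizedTimeCourse(times=tc.times, normalized=norm, mean=mean, se=se)


@dataclass
class TimeCourseSummary:
    peak_time: float
    trough_time: float
    amplitude: float
    in_phase_with_light: bool
    peak_value: float
    c4_c3_peak_ratio: Optional[float] = None


def summarize_timecourse(
    times: Sequence[float],
    means: Sequence[float],
    lights_on_duration: float = 12.0,
    c3_means: Optional[Sequence[float]] = None,
) -> TimeCourseSummary:
    """Peak/trough positions and amplitude of a replicate-mean series.

    Extrema are taken at sampled points only (no interpolation); the peak
    is in phase with the light period when it falls strictly before
    lights-off.  When a matched C3 series is supplied, the C4:C3 ratio of
    peak values is reported.
    """
    times = np.asarray(times, float)
    means = np.asarray(means, float)
    if len(times) < 2:
        raise ValueError("need >= 2 time points")
    i_max = int(np.argmax(means))
    i_min = int(np.argmin(means))
    ratio = None
    if c3_means is not None:
        c3_peak = float(np.max(np.asarray(c3_means, float)))
        ratio = math.inf if c3_peak == 0 else float(means[i_max]) / c3_peak
    return TimeCourseSummary(
        peak_time=float(times[i_max]),
        trough_time=float(times[i_min]),
        amplitude=float(means[i_max] - means[i_min]),
        in_phase_with_light=float(times[i_max]) < lights_on_duration,
        peak_value=float(means[i_max]),
        c4_c3_peak_ratio=ratio,
    )
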