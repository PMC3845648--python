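"""Call the C4-recruited lineage per enzyme family per species.

Two sampling designs are supported, matching the two kinds of evidence
used to recognize a lineage serving the C4 cycle:

* diurnal design (a C3/C4 species pair sampled in light and dark): the
  recruited lineage must exceed an rpkm threshold in the C4 day sample,
  be higher in the C4 than in the C3, and higher in the light than in
  the dark;
* gradient design (leaf developmental segments A-D, base to tip): the
  recruited lineage must exceed the threshold in each of the mature
  segments C and D, and mean(C, D) must exceed mean(A, B).

When several lineages pass in one species, the primary call is the
top-expressed one and the ambiguity is recorded.  Lineages whose
expression also rises day-over-night in the C3 relative are flagged
``c3_shared_pattern``: a high-in-C4 call with the same diurnal behaviour
in the C3 is not C4-specific evidence, and such families are excluded
from the convergence tally by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .expression import LineageExpression

__all__ = [
    "RecruitmentRuleConfig",
    "LineageEvidence",
    "RecruitmentCall",
    "ConvergenceTally",
    "classify_diurnal",
    "classify_gradient",
    "tally_convergence",
]

NONE_CALL = None


@dataclass
class RecruitmentRuleConfig:
    """Thresholds for recruitment calls.

    ``rpkm_threshold`` defaults to 300 rpkm; ``strict_inequalities``
    applies '>' everywhere (set False for '>=' sensitivity analysis).
    """

    rpkm_threshold: float = 300.0
    strict_inequalities: bool = True

    def __post_init__(self) -> None:
        if self.rpkm_threshold <= 0:
            raise ValueError("rpkm_threshold must be positive")

    def gt(self, a: float, b: float) -> bool:
        return a > b if self.strict_inequalities else a >= b


@dataclass
class LineageEvidence:
    lineage_id: str
    day_rpkm: float
    threshold_pass: bool = False
    c4_gt_c3: Optional[bool] = None
    light_gt_dark: Optional[bool] = None
    dev_increase: Optional[bool] = None
    c3_shared_pattern: bool = False

    @property
    def passes(self) -> bool:
        checks = [self.threshold_pass, self.c4_gt_c3, self.light_gt_dark,
                  self.dev_increase]
        return all(c for c in checks if c is not None) and self.threshold_pass


@dataclass
class RecruitmentCall:
    family_id: str
    species_id: str
    evidence: dict[str, LineageEvidence]
    passing_lineages: list[str]  # ordered by descending day/mature rpkm
    primary_lineage: Optional[str]
    excluded_single_lineage: bool = False
    ties: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ambiguous(self) -> bool:
        return len(self.passing_lineages) > 1

    @property
    def c3_shared(self) -> bool:
        return any(
            self.evidence[l].c3_shared_pattern for l in self.passing_lineages
        )


def _rank_passing(evidence: dict[str, LineageEvidence]) -> tuple[list[str], list]:
    passing = [ev for ev in evidence.values() if ev.passes]
    # deterministic: descending rpkm, lexicographic id on ties (logged)
    passing.sort(key=lambda ev: (-ev.day_rpkm, ev.lineage_id))
    ties = [
        (a.lineage_id, b.lineage_id)
        for a, b in zip(passing, passing[1:])
        if a.day_rpkm == b.day_rpkm
    ]
    return [ev.lineage_id for ev in passing], ties


def classify_diurnal(
    expr: LineageExpression,
    family_id: str,
    c4_species: str,
    c3_species: str,
    cfg: RecruitmentRuleConfig | None = None,
) -> RecruitmentCall:
    """Recruitment call from a C3/C4 pair sampled in light and dark."""
    cfg = cfg or RecruitmentRuleConfig()
    m = expr.means
    fam = m[(m["family_id"] == family_id)]
    lineage_ids = sorted(fam["lineage_id"].unique())
    if not lineage_ids:
        raise ValueError(f"no expression rows for family {family_id!r}")

    evidence: dict[str, LineageEvidence] = {}
    for lid in lineage_ids:
        c4_light = expr.mean_rpkm(family_id, lid, c4_species, "light")
        c4_dark = expr.mean_rpkm(family_id, lid, c4_species, "dark")
        c3_light = expr.mean_rpkm(family_id, lid, c3_species, "light")
        ev = LineageEvidence(
            lineage_id=lid,
            day_rpkm=c4_light,
            threshold_pass=cfg.gt(c4_light, cfg.rpkm_threshold),
            c4_gt_c3=cfg.gt(c4_light, c3_light),
            light_gt_dark=cfg.gt(c4_light, c4_dark),
        )
        try:
            c3_dark = expr.mean_rpkm(family_id, lid, c3_species, "dark")
        except KeyError:
            c3_dark = None
        if ev.passes and c3_dark is not None and cfg.gt(c3_light, c3_dark):
            ev.c3_shared_pattern = True
        evidence[lid] = ev

    passing, ties = _rank_passing(evidence)
    return RecruitmentCall(
        family_id=family_id,
        species_id=c4_species,
        evidence=evidence,
        passing_lineages=passing,
        primary_lineage=passing[0] if passing else NONE_CALL,
        ties=ties,
    )


def classify_gradient(
    expr: LineageExpression,
    family_id: str,
    species_id: str,
    cfg: RecruitmentRuleConfig | None = None,
) -> RecruitmentCall:
    """Recruitment call from a leaf developmental gradient (segments A-D)."""
    cfg = cfg or RecruitmentRuleConfig()
    m = expr.means
    fam = m[(m["family_id"] == family_id)]
    lineage_ids = sorted(fam["lineage_id"].unique())
    if not lineage_ids:
        raise ValueError(f"no expression rows for family {family_id!r}")

    evidence: dict[str, LineageEvidence] = {}
    for lid in lineage_ids:
        seg = {
            s: expr.mean_rpkm(family_id, lid, species_id, s)
            for s in ("A", "B", "C", "D")
        }
        mature = (seg["C"] + seg["D"]) / 2.0
        young = (seg["A"] + seg["B"]) / 2.0
        evidence[lid] = LineageEvidence(
            lineage_id=lid,
            day_rpkm=mature,
            threshold_pass=(
                cfg.gt(seg["C"], cfg.rpkm_threshold)
                and cfg.gt(seg["D"], cfg.rpkm_threshold)
            ),
            dev_increase=cfg.gt(mature, young),
        )

    passing, ties = _rank_passing(evidence)
    return RecruitmentCall(
        family_id=family_id,
        species_id=species_id,
        evidence=evidence,
        passing_lineages=passing,
        primary_lineage=passing[0] if passing else NONE_CALL,
        ties=ties,
    )


@dataclass
class ConvergenceTally:
    observed_count: int
    families_counted: list[str]
    convergent_families: list[str]
    excluded_single_lineage: list[str]
    excluded_incomplete: list[str]
    excluded_c3_shared: list[str]
    ambiguities: dict[str, list[str]] = field(default_factory=dict)

    @property
    def is_na(self) -> bool:
        return not self.families_counted


def tally_convergence(
    calls: list[RecruitmentCall],
    family_sizes: dict[str, int],
    exclude_c3_shared: bool = True,
) -> ConvergenceTally:
    """Count families in which all C4 species recruited the same lineage.

    Single-lineage families are excluded (convergence is undefined when
    there is no choice); a family enters the tally only when every
    species has a primary call.  Convergence is decided on primary calls;
    multi-pass ambiguities are reported but do not change the tally.
    """
    by_family: dict[str, dict[str, RecruitmentCall]] = {}
    for call in calls:
        by_family.setdefault(call.family_id, {})[call.species_id] = call

    species_sets = {frozenset(v) for v in by_family.values()}
    if len(species_sets) > 1:
        raise ValueError(
            "inconsistent species coverage across families: "
            f"{[sorted(s) for s in species_sets]}"
        )

    counted: list[str] = []
    convergent: list[str] = []
    single: list[str] = []
    incomplete: list[str] = []
    shared: list[str] = []
    ambiguities: dict[str, list[str]] = {}

    for family in sorted(by_family):
        fam_calls = by_family[family]
        k = family_sizes.get(family)
        if k is None:
            raise ValueError(f"no family size for {family!r}")
        if k <= 1:
            single.append(family)
            continue
        for call in fam_calls.values():
            if call.ambiguous:
                ambiguities.setdefault(family, []).extend(
                    call.passing_lineages
                )
        if any(c.primary_lineage is None for c in fam_calls.values()):
            incomplete.append(family)
            continue
        if exclude_c3_shared and any(c.c3_shared for c in fam_calls.values()):
            shared.append(family)
            continue
        counted.append(family)
        primaries = {c.primary_lineage for c in fam_calls.values()}
        if len(primaries) == 1:
            convergent.append(family)

    return ConvergenceTally(
        observed_count=len(convergent),
        families_counted=counted,
        convergent_families=convergent,
        excluded_single_lineage=single,
        excluded_incomplete=incomplete,
        excluded_c3_shared=shared,
        ambiguities=ambiguities,
    )
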