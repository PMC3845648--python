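"""Published survey of C4-enzyme gene families in grasses.

Curated from the printed comparative survey of three independently
evolved C4 grasses (*Alloteropsis semialata* subsp. *semialata*,
*Setaria italica*, *Zea mays*): the number of grass gene lineages per
enzyme family, the lineage each C4 origin recruited (where identifiable
from expression evidence), and the leaf-gradient rpkm profiles of
closely related gene duplicates inside recruited lineages.

For the four convergent families whose lineage numbering is not printed
(ALA-AT, PEPC) or is printed only for some species, the encoded id is an
arbitrary shared label: only identity *across* species enters the
convergence tally.  Setaria's ASP-AT call was ambiguous between the
Alloteropsis-matching and Zea-matching lineages; the primary here is the
Alloteropsis-matching one, which does not affect the tally because
Alloteropsis and Zea differ.
"""

from __future__ import annotations

from .classify import LineageEvidence, RecruitmentCall

C4_SPECIES = ["Alloteropsis", "Setaria", "Zea"]

#: Grass gene lineages per enzyme family (k).
FAMILY_SIZES: dict[str, int] = {
    "ALA-AT": 5,
    "ASP-AT": 4,
    "beta-CA": 3,
    "NAD(P)-MDH": 4,
    "NADP-ME": 4,
    "PCK": 1,
    "PEPC": 7,
    "PPDK": 2,
}

#: Recruited lineage per family per C4 species (None = no call); the
#: ASP-AT entry for Setaria lists both high-abundance lineages, primary
#: first.
RECRUITED: dict[str, dict[str, object]] = {
    "ALA-AT": {"Alloteropsis": "1", "Setaria": "1", "Zea": "1"},
    "ASP-AT": {"Alloteropsis": "2", "Setaria": ["2", "3"], "Zea": "3"},
    "beta-CA": {"Alloteropsis": "3", "Setaria": "3", "Zea": "3"},
    "NAD(P)-MDH": {"Alloteropsis": "4", "Setaria": "1", "Zea": "1"},
    "NADP-ME": {"Alloteropsis": "4", "Setaria": "4", "Zea": "4"},
    "PCK": {"Alloteropsis": "1", "Setaria": None, "Zea": "1"},
    "PEPC": {"Alloteropsis": "1", "Setaria": "1", "Zea": "1"},
    "PPDK": {"Alloteropsis": "2", "Setaria": "2", "Zea": "2"},
}

#: Leaf-gradient rpkm of closely related duplicates within recruited
#: lineages (segments A-D, base to mature tip).  The merged Setaria
#: entry "Si002140/Si002148" averages two duplicates with identical
#: coding sequence.
DUPLICATE_PROFILES: list[dict] = [
    {"family": "beta-CA", "lineage": "3", "species": "Setaria",
     "gene": "Si003882", "A": 80, "B": 2157, "C": 6769, "D": 8297},
    {"family": "beta-CA", "lineage": "3", "species": "Setaria",
     "gene": "Si002140/Si002148", "A": 2, "B": 2, "C": 21, "D": 56},
    {"family": "beta-CA", "lineage": "3", "species": "Zea",
     "gene": "GRMZM2G121878", "A": 3, "B": 573, "C": 2868, "D": 1782},
    {"family": "beta-CA", "lineage": "3", "species": "Zea",
     "gene": "GRMZM2G348512", "A": 6, "B": 300, "C": 1308, "D": 792},
    {"family": "beta-CA", "lineage": "3", "species": "Zea",
     "gene": "GRMZM2G094165", "A": 419, "B": 260, "C": 233, "D": 4},
    {"family": "NADP-ME", "lineage": "4", "species": "Zea",
     "gene": "GRMZM2G085019", "A": 5, "B": 501, "C": 1810, "D": 1963},
    {"family": "NADP-ME", "lineage": "4", "species": "Zea",
     "gene": "GRMZM2G122479", "A": 6, "B": 368, "C": 868, "D": 4},
    {"family": "PCK", "lineage": "1", "species": "Zea",
     "gene": "GRMZM2G001696", "A": 1, "B": 117, "C": 41, "D": 1408},
    {"family": "PCK", "lineage": "1", "species": "Zea",
     "gene": "GRMZM5G870932", "A": 4, "B": 270, "C": 14, "D": 6},
    {"family": "PPDK", "lineage": "2", "species": "Zea",
     "gene": "GRMZM2G306345", "A": 64, "B": 6106, "C": 18544, "D": 16386},
    {"family": "PPDK", "lineage": "2", "species": "Zea",
     "gene": "GRMZM2G097457", "A": 19, "B": 43, "C": 96, "D": 356},
]


def multi_lineage_sizes() -> list[int]:
    """Family sizes entering the null model (single-lineage families,
    where convergence is undefined, excluded)."""
    return [k for k in FAMILY_SIZES.values() if k >= 2]


def published_calls() -> list[RecruitmentCall]:
    """Recruitment calls reconstructed from the published survey, suitable
    for :func:`c4recruit.classify.tally_convergence`."""
    calls: list[RecruitmentCall] = []
    for family, per_species in RECRUITED.items():
        for species in C4_SPECIES:
            entry = per_species[species]
            if entry is None:
                passing: list[str] = []
            elif isinstance(entry, list):
                passing = list(entry)
            else:
                passing = [entry]
            evidence = {
                lid: LineageEvidence(
                    lineage_id=lid, day_rpkm=float("nan"), threshold_pass=True
                )
                for lid in passing
            }
            calls.append(
                RecruitmentCall(
                    family_id=family,
                    species_id=species,
                    evidence=evidence,
                    passing_lineages=passing,
                    primary_lineage=passing[0] if passing else None,
                    excluded_single_lineage=FAMILY_SIZES[family] <= 1,
                )
            )
    return calls
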