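"""Seeded synthetic fixtures with known recruitment truth.

The generator emulates the statistical structure the downstream stages
assume, without simulating sequences or reads:

* a fixed 5-taxon grass species tree,
  ((Brachypodium,Oryza),(Zea,(Setaria,Alloteropsis)));
* gene-family trees built as k species-tree copies joined by a basal
  duplication ladder (grass gene lineages arose from duplications
  predating grass diversification), with bootstrap supports drawn from a
  configurable range and known gene -> lineage truth;
* count tables for the two sampling designs: a C3/C4 accession pair of
  *Alloteropsis* with pooled light and dark libraries (one replicate
  each), and leaf developmental gradients (segments A-D, replicated) for
  *Setaria* and *Zea*.  One lineage per family can be "planted" as
  C4-recruited: it receives a high day/mature rpkm target in every C4
  sample and the baseline elsewhere, so that with noiseless counts it
  passes every classification rule by construction;
* diurnal time courses with a constant-mean reference gene.

Counts are obtained by inverting the rpkm formula from the target rpkm,
gene length and library depth (``count = rpkm * length_bp/1000 *
depth/1e6``, rounded), optionally Poisson-perturbed using that value as
the mean.  One root seed drives everything; per-family and per-stage
child streams are spawned with ``numpy.random.SeedSequence(seed).spawn``
in a fixed order, so regeneration is bit-identical and partial
regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .delimit import GeneLineage
from .expression import ExpressionTable, SampleSheet
from .diurnal import TimeCourse
from .trees import GeneRecord, Node, parse_newick, to_newick

__all__ = [
    "SimulationConfig",
    "FamilyTruth",
    "FixtureBundle",
    "default_species_tree",
    "simulate_gene_family",
    "simulate_counts",
    "simulate_time_course",
    "generate_bundle",
    "write_fixture",
]

SPECIES_TREE_NEWICK = (
    "((Brachypodium:1,Oryza:1):1,(Zea:1,(Setaria:1,Alloteropsis:1):1):1);"
)
PAIR_SPECIES = "Alloteropsis"
ALLO_C4 = "Alloteropsis_C4"
ALLO_C3 = "Alloteropsis_C3"
GRADIENT_SPECIES = ("Setaria", "Zea")
SEGMENTS = ("A", "B", "C", "D")
TIME_POINTS = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    Defaults mirror the published study: family sizes from the printed
    survey (one to seven lineages per enzyme family), a 300-rpkm
    classification threshold comfortably cleared by the planted lineage,
    pooled single-replicate light/dark libraries for the accession pair,
    and duplicated gradient replicates.
    """

    seed: int = 0
    n_families: int = 8
    lineage_counts: list[int] = field(
        default_factory=lambda: [5, 4, 3, 4, 4, 1, 7, 2]
    )
    planted_lineage: Optional[list[Optional[int]]] = None  # 1-based, None=skip
    baseline_rpkm: float = 50.0
    recruited_day_rpkm: float = 500.0
    night_to_day_ratio: float = 0.2
    gradient_profile: tuple[float, float, float, float] = (0.1, 0.2, 0.9, 1.0)
    n_replicates_gradient: int = 2
    depth_per_sample: int = 1_000_000
    mean_cds_length_bp: int = 1500
    count_noise: str = "none"  # none | poisson
    support_range: tuple[int, int] = (80, 100)
    loss_rate: float = 0.0
    day_mode: str = "pooled"  # pooled | single

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_replicates_gradient < 1:
            raise ValueError("counts must be >= 1")
        if len(self.lineage_counts) != self.n_families:
            raise ValueError("lineage_counts must have n_families entries")
        if any(k < 1 for k in self.lineage_counts):
            raise ValueError("every family needs >= 1 lineage")
        if self.recruited_day_rpkm <= 300:
            raise ValueError(
                "recruited_day_rpkm must exceed the 300-rpkm call threshold"
            )
        if not 0 < self.night_to_day_ratio < 1:
            raise ValueError("night_to_day_ratio must be in (0, 1)")
        gp = self.gradient_profile
        if len(gp) != 4 or (gp[2] + gp[3]) / 2 <= (gp[0] + gp[1]) / 2:
            raise ValueError(
                "gradient_profile must have 4 entries with mean(C,D) > mean(A,B)"
            )
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be positive")
        if self.count_noise not in ("none", "poisson"):
            raise ValueError("count_noise must be 'none' or 'poisson'")
        if self.day_mode not in ("pooled", "single"):
            raise ValueError("day_mode must be 'pooled' or 'single'")
        lo, hi = self.support_range
        if not (0 <= lo <= hi <= 100):
            raise ValueError("support_range must satisfy 0 <= lo <= hi <= 100")
        if self.planted_lineage is None:
            self.planted_lineage = [1] * self.n_families
        if len(self.planted_lineage) != self.n_families:
            raise ValueError("planted_lineage must have n_families entries")
        for k, p in zip(self.lineage_counts, self.planted_lineage):
            if p is not None and not 1 <= p <= k:
                raise ValueError(f"planted lineage {p} outside 1..{k}")

    def family_ids(self) -> list[str]:
        return [f"FAM{i + 1}" for i in range(self.n_families)]


@dataclass
class FamilyTruth:
    """Known gene -> lineage membership and the planted recruited lineage."""

    family_id: str
    lineages: dict[str, dict[str, list[str]]]  # lineage_id -> species -> genes
    planted: Optional[str]  # lineage_id, shared by all C4 origins
    gene_lengths: dict[str, int] = field(default_factory=dict)

    def gene_to_lineage(self) -> dict[str, str]:
        return {
            g: lid
            for lid, by_sp in self.lineages.items()
            for genes in by_sp.values()
            for g in genes
        }

    def as_lineages(self) -> list[GeneLineage]:
        return [
            GeneLineage(self.family_id, lid, {s: list(g) for s, g in by_sp.items()})
            for lid, by_sp in self.lineages.items()
        ]


def default_species_tree() -> Node:
    """The fixed 5-taxon grass topology with unit branch lengths:
    Panicoideae (*Zea*, (*Setaria*, *Alloteropsis*)) sister to the
    BEP clade (*Brachypodium*, *Oryza*)."""
    return parse_newick(SPECIES_TREE_NEWICK)


def simulate_gene_family(
    cfg: SimulationConfig,
    species_tree: Node,
    k: int,
    seed: int,
    family_id: str = "FAM1",
    planted: Optional[int] = None,
) -> tuple[Node, FamilyTruth]:
    """One gene-family tree: k species-tree copies on a basal ladder.

    Each copy is one lineage; supports are drawn uniformly from
    ``cfg.support_range``; with ``cfg.loss_rate > 0`` individual species
    may be lost from non-planted lineages (at least one leaf always
    remains).  Truth records every gene's lineage and its drawn CDS
    length.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = cfg.support_range

    def draw_support() -> float:
        return float(rng.integers(lo, hi + 1))

    lineages: dict[str, dict[str, list[str]]] = {}
    lengths: dict[str, int] = {}

    def make_copy(lineage_idx: int) -> Optional[Node]:
        lid = str(lineage_idx)
        copy = species_tree.copy()
        keep: dict[str, bool] = {}
        species = copy.leaf_labels()
        for sp in species:
            lose = (
                cfg.loss_rate > 0
                and lineage_idx != planted
                and rng.random() < cfg.loss_rate
            )
            keep[sp] = not lose
        if not any(keep.values()):
            keep[species[0]] = True  # a lineage never loses every species

        def build(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if not keep[node.label]:
                    return None
                gene_id = f"{family_id}_L{lid}_{node.label}"
                length = int(
                    rng.integers(
                        int(0.8 * cfg.mean_cds_length_bp),
                        int(1.2 * cfg.mean_cds_length_bp) + 1,
                    )
                )
                lengths[gene_id] = length
                lineages.setdefault(lid, {}).setdefault(node.label, []).append(
                    gene_id
                )
                return Node(
                    label=gene_id,
                    record=GeneRecord(
                        gene_id=gene_id,
                        species_id=node.label,
                        cds_length_bp=length,
                    ),
                )
            kept = [build(c) for c in node.children]
            kept = [c for c in kept if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                return kept[0]
            return Node(support=draw_support(), children=kept)

        return build(copy)

    root = make_copy(1)
    for j in range(2, k + 1):
        root = Node(support=draw_support(), children=[root, make_copy(j)])

    truth = FamilyTruth(
        family_id=family_id,
        lineages=lineages,
        planted=str(planted) if planted is not None else None,
        gene_lengths=lengths,
    )
    return root, truth


def _sample_sheet_rows(cfg: SimulationConfig) -> list[dict]:
    rows = []
    for accession, photo in ((ALLO_C4, "C4"), (ALLO_C3, "C3")):
        for condition in ("light", "dark"):
            rows.append(
                {
                    "sample_id": f"{accession}_{condition}",
                    "species_id": accession,
                    "photo_type": photo,
                    "design": "diurnal",
                    "condition": condition,
                    "replicate": 1,
                    "total_mapped_reads": cfg.depth_per_sample,
                }
            )
    for sp in GRADIENT_SPECIES:
        for seg in SEGMENTS:
            for rep in range(1, cfg.n_replicates_gradient + 1):
                rows.append(
                    {
                        "sample_id": f"{sp}_{seg}_r{rep}",
                        "species_id": sp,
                        "photo_type": "C4",
                        "design": "gradient",
                        "condition": seg,
                        "replicate": rep,
                        "total_mapped_reads": cfg.depth_per_sample,
                    }
                )
    return rows


def _lineage_target_rpkm(
    cfg: SimulationConfig, is_planted: bool, sample: dict
) -> float:
    """Target lineage-level rpkm for one sample."""
    day_factor = 1.0 if cfg.day_mode == "pooled" else 1.2
    if sample["design"] == "diurnal":
        if not is_planted or sample["species_id"] == ALLO_C3:
            return cfg.baseline_rpkm
        if sample["condition"] == "light":
            return cfg.recruited_day_rpkm * day_factor
        return cfg.recruited_day_rpkm * cfg.night_to_day_ratio
    # gradient design
    if not is_planted:
        return cfg.baseline_rpkm
    seg_idx = SEGMENTS.index(sample["condition"])
    return cfg.recruited_day_rpkm * cfg.gradient_profile[seg_idx]


def simulate_counts(
    cfg: SimulationConfig, truths: Sequence[FamilyTruth], seed: int
) -> tuple[ExpressionTable, SampleSheet]:
    """Count table + sample sheet realizing each family's planted pattern.

    A lineage's target rpkm is split evenly over that species' member
    genes, converted to a count by inverting the rpkm formula, and
    rounded (Poisson-perturbed when ``cfg.count_noise == 'poisson'``).
    Genes of a species not measured by a sample's design get zero counts
    there.
    """
    if not truths:
        raise ValueError("truth must be nonempty")
    if cfg.depth_per_sample <= 0:
        raise ValueError("depth_per_sample must be positive")
    rng = np.random.default_rng(seed)
    samples = _sample_sheet_rows(cfg)
    sheet = SampleSheet(pd.DataFrame(samples))

    gene_ids: list[str] = []
    lengths: dict[str, int] = {}
    for truth in truths:
        for gid, length in truth.gene_lengths.items():
            gene_ids.append(gid)
            lengths[gid] = length

    counts = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    row_of = {g: i for i, g in enumerate(gene_ids)}

    for truth in truths:
        for lid, by_species in sorted(truth.lineages.items()):
            is_planted = lid == truth.planted
            for j, sample in enumerate(samples):
                if sample["design"] == "diurnal":
                    members = by_species.get(PAIR_SPECIES, [])
                else:
                    members = by_species.get(sample["species_id"], [])
                if not members:
                    continue
                lineage_rpkm = _lineage_target_rpkm(cfg, is_planted, sample)
                per_gene = lineage_rpkm / len(members)
                for gid in members:
                    mean_count = (
                        per_gene
                        * (lengths[gid] / 1000.0)
                        * (sample["total_mapped_reads"] / 1e6)
                    )
                    if cfg.count_noise == "poisson":
                        counts[row_of[gid], j] = rng.poisson(mean_count)
                    else:
                        counts[row_of[gid], j] = int(round(mean_count))

    table = ExpressionTable(
        counts=pd.DataFrame(
            counts,
            index=pd.Index(gene_ids, name="feature_id"),
            columns=[s["sample_id"] for s in samples],
        ),
        lengths=pd.Series(lengths, name="length_bp"),
    )
    return table, sheet


def simulate_time_course(
    cfg: SimulationConfig,
    seed: int,
    gene_id: str = "planted_gene",
    photo_type: str = "C4",
    peak_time: float = 4.0,
    amplitude: float = 1.0,
    baseline: float = 1.0,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
) -> TimeCourse:
    """Diurnal series at 4-h spacing over 24 h (12:12 light:dark), three
    biological replicates, with a constant-mean reference gene.

    The C4 shape is a raised cosine peaking at ``peak_time`` (in the
    light period by default); C3 series are flat at ``baseline``.
    """
    rng = np.random.default_rng(seed)
    times = np.array(TIME_POINTS)
    if photo_type == "C4":
        shape = 0.5 * (1.0 + np.cos(2.0 * np.pi * (times - peak_time) / 24.0))
        mean_series = baseline + amplitude * shape
    else:
        mean_series = np.full_like(times, baseline)
    signals = np.repeat(mean_series[:, None], n_replicates, axis=1)
    reference = np.ones_like(signals)
    if noise_sd > 0:
        signals = signals + rng.normal(0.0, noise_sd, signals.shape)
        signals = np.clip(signals, 0.0, None)
        reference = np.clip(
            reference + rng.normal(0.0, noise_sd, reference.shape), 1e-6, None
        )
    return TimeCourse(
        gene_id=gene_id,
        species_id=PAIR_SPECIES,
        photo_type=photo_type,
        times=times,
        signals=signals,
        reference=reference,
        lights_on_duration=12.0,
    )


@dataclass
class FixtureBundle:
    species_tree: Node
    gene_trees: dict[str, Node]
    truth: list[FamilyTruth]
    counts: ExpressionTable
    samples: SampleSheet
    time_courses: list[TimeCourse]
    config: SimulationConfig

    def planted_convergent_count(self) -> int:
        """Families with >= 2 lineages and a planted recruited lineage
        (shared across the C4 origins by construction)."""
        sizes = dict(zip(self.config.family_ids(), self.config.lineage_counts))
        return sum(
            1
            for t in self.truth
            if t.planted is not None and sizes[t.family_id] >= 2
        )


def generate_bundle(cfg: SimulationConfig) -> FixtureBundle:
    """Generate the full fixture set from one root seed."""
    root_ss = np.random.SeedSequence(cfg.seed)
    # fixed spawn order: one child per family, then counts, then time courses
    children = root_ss.spawn(cfg.n_families + 2)
    family_ids = cfg.family_ids()

    gene_trees: dict[str, Node] = {}
    truths: list[FamilyTruth] = []
    species_tree = default_species_tree()
    for i, (fam, k) in enumerate(zip(family_ids, cfg.lineage_counts)):
        tree, truth = simulate_gene_family(
            cfg,
            species_tree,
            k,
            seed=children[i],
            family_id=fam,
            planted=cfg.planted_lineage[i],
        )
        gene_trees[fam] = tree
        truths.append(truth)

    counts, sheet = simulate_counts(cfg, truths, seed=children[cfg.n_families])
    tc_seed = children[cfg.n_families + 1]
    tc_c4 = simulate_time_course(cfg, tc_seed, gene_id="tc_C4", photo_type="C4")
    tc_c3 = simulate_time_course(cfg, tc_seed, gene_id="tc_C3", photo_type="C3")
    return FixtureBundle(
        species_tree=species_tree,
        gene_trees=gene_trees,
        truth=truths,
        counts=counts,
        samples=sheet,
        time_courses=[tc_c4, tc_c3],
        config=cfg,
    )


def write_fixture(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files under one directory.

    Trees as Newick (supports as internal labels), counts/lengths/sample
    sheet as TSV, truth as a TSV of membership and planted records.
    Returns the written paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["species_tree"] = outdir / "species_tree.nwk"
    paths["species_tree"].write_text(
        to_newick(bundle.species_tree, include_lengths=True) + "\n"
    )
    tree_dir = outdir / "gene_trees"
    tree_dir.mkdir(exist_ok=True)
    for fam, tree in bundle.gene_trees.items():
        p = tree_dir / f"{fam}.nwk"
        p.write_text(to_newick(tree) + "\n")
        paths[f"gene_tree:{fam}"] = p

    paths["counts"] = outdir / "counts.tsv"
    paths["lengths"] = outdir / "lengths.tsv"
    bundle.counts.write_tsv(paths["counts"], paths["lengths"])
    paths["samples"] = outdir / "samples.tsv"
    bundle.samples.write_tsv(paths["samples"])

    paths["truth"] = outdir / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("record\tfamily_id\tlineage_id\tspecies_id\tgene_id\n")
        for truth in bundle.truth:
            for lid, by_sp in sorted(truth.lineages.items()):
                for sp, genes in sorted(by_sp.items()):
                    for g in genes:
                        fh.write(f"member\t{truth.family_id}\t{lid}\t{sp}\t{g}\n")
            if truth.planted is not None:
                fh.write(f"planted\t{truth.family_id}\t{truth.planted}\t\t\n")

    paths["timecourse"] = outdir / "time_courses.tsv"
    with open(paths["timecourse"], "w") as fh:
        fh.write(
            "gene_id\tspecies_id\tphoto_type\ttime_h\treplicate\t"
            "signal\treference_signal\n"
        )
        for tc in bundle.time_courses:
            for ti, t in enumerate(tc.times):
                for rep in range(tc.signals.shape[1]):
                    fh.write(
                        f"{tc.gene_id}\t{tc.species_id}\t{tc.photo_type}\t"
                        f"{t:g}\t{rep + 1}\t{tc.signals[ti, rep]:.6f}\t"
                        f"{tc.reference[ti, rep]:.6f}\n"
                    )
    return paths
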