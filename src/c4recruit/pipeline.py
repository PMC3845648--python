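"""End-to-end orchestration: delimit -> assign -> quantify -> classify ->
tally -> randomness test, from a config mapping or YAML file.

Every stage writes its table under the output directory; the run report
is a single JSON document that is regenerable byte-for-byte from the
same config and seed (timestamps go to the log, not the report).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from . import __version__
from .classify import (
    RecruitmentCall,
    RecruitmentRuleConfig,
    classify_diurnal,
    classify_gradient,
    tally_convergence,
)
from .convergence import run_convergence_test
from .delimit import UNASSIGNED, delimit_lineages, assign_query
from .expression import (
    ExpressionTable,
    SampleSheet,
    aggregate_to_lineage,
    validate_inputs,
)
from .trees import annotate_gene_leaves, parse_newick

log = logging.getLogger("c4recruit")

DEFAULTS = {
    "tau": 70.0,
    "rpkm_threshold": 300.0,
    "strict_inequalities": True,
    "n_replicates": 100_000,
    "n_species": 3,
    "seed": 0,
    "exclude_c3_shared": True,
}


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    species_tree: Path
    gene_trees: dict[str, Path]  # family_id -> newick path
    counts: Path
    lengths: Path
    samples: Path
    outdir: Path
    c4_pair_species: str = "Alloteropsis_C4"
    c3_pair_species: str = "Alloteropsis_C3"
    gradient_species: list[str] = field(
        default_factory=lambda: ["Setaria", "Zea"]
    )
    tau: float = 70.0
    rpkm_threshold: float = 300.0
    strict_inequalities: bool = True
    n_replicates: int = 100_000
    n_species: int = 3
    seed: int = 0
    exclude_c3_shared: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def p(key: str) -> Path:
            if key not in raw:
                raise PipelineConfigError(f"config missing required key {key!r}")
            return (base / raw[key]).resolve()

        trees = {
            fam: (base / rel).resolve()
            for fam, rel in raw.get("gene_trees", {}).items()
        }
        if not trees:
            raise PipelineConfigError("config lists no gene trees")
        kwargs = {
            k: raw[k]
            for k in (
                "c4_pair_species",
                "c3_pair_species",
                "gradient_species",
                "tau",
                "rpkm_threshold",
                "strict_inequalities",
                "n_replicates",
                "n_species",
                "seed",
                "exclude_c3_shared",
            )
            if k in raw
        }
        return cls(
            species_tree=p("species_tree"),
            gene_trees=trees,
            counts=p("counts"),
            lengths=p("lengths"),
            samples=p("samples"),
            outdir=(base / raw.get("outdir", "out")).resolve(),
            **kwargs,
        )

    def validate_paths(self) -> None:
        missing = [
            str(p)
            for p in [
                self.species_tree,
                self.counts,
                self.lengths,
                self.samples,
                *self.gene_trees.values(),
            ]
            if not Path(p).exists()
        ]
        if missing:
            raise PipelineConfigError(f"missing input files: {missing}")


def call_to_row(call: RecruitmentCall) -> dict:
    return {
        "family_id": call.family_id,
        "species_id": call.species_id,
        "primary_lineage": call.primary_lineage or "NONE",
        "passing_lineages": ",".join(call.passing_lineages),
        "ambiguous": call.ambiguous,
        "c3_shared": call.c3_shared,
        "ties": ";".join(f"{a}={b}" for a, b in call.ties),
    }


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the JSON-serializable run report."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    species_tree = parse_newick(Path(config.species_tree).read_text())
    table = ExpressionTable.read_tsv(config.counts, config.lengths)
    sheet = SampleSheet.read_tsv(config.samples)
    report_validation = validate_inputs(table, sheet)
    if not report_validation.ok:
        raise PipelineConfigError(
            f"input validation failed: {report_validation.errors}"
        )

    rule_cfg = RecruitmentRuleConfig(
        rpkm_threshold=config.rpkm_threshold,
        strict_inequalities=config.strict_inequalities,
    )

    # delimit + assign
    lineage_rows = []
    assignment: dict[str, tuple[str, str]] = {}
    family_sizes: dict[str, int] = {}
    for family, tree_path in sorted(config.gene_trees.items()):
        gene_tree = parse_newick(Path(tree_path).read_text())
        annotate_gene_leaves(gene_tree, species_tree.leaf_labels())
        lineages = delimit_lineages(
            gene_tree, species_tree, tau=config.tau, family_id=family
        )
        family_sizes[family] = len(lineages)
        for lin in lineages:
            for sp, genes in sorted(lin.members.items()):
                for g in genes:
                    assignment[g] = (family, lin.lineage_id)
                    lineage_rows.append(
                        {
                            "family_id": family,
                            "lineage_id": lin.lineage_id,
                            "species_id": sp,
                            "gene_id": g,
                        }
                    )
        queries = assign_query(gene_tree, lineages)
        for q, lid in queries.items():
            assignment[q] = (family, lid)  # lid may be UNASSIGNED
            if lid == UNASSIGNED:
                log.info("query %s in %s left unassigned", q, family)
    pd.DataFrame(lineage_rows).to_csv(
        outdir / "lineages.tsv", sep="\t", index=False
    )

    # quantify
    expr = aggregate_to_lineage(
        table, sheet, {f: fl for f, fl in assignment.items()}
    )
    expr.write_tsv(outdir / "lineage_expression.tsv")
    if expr.unassigned_rpkm:
        log.info("total unassigned rpkm dropped: %.3f", expr.unassigned_rpkm)

    # classify per family per species
    calls: list[RecruitmentCall] = []
    measured_species = set(sheet.frame["species_id"])
    for family in sorted(config.gene_trees):
        if config.c4_pair_species in measured_species:
            calls.append(
                classify_diurnal(
                    expr,
                    family,
                    c4_species=config.c4_pair_species,
                    c3_species=config.c3_pair_species,
                    cfg=rule_cfg,
                )
            )
        for sp in config.gradient_species:
            if sp in measured_species:
                calls.append(classify_gradient(expr, family, sp, cfg=rule_cfg))
    calls_frame = pd.DataFrame([call_to_row(c) for c in calls])
    calls_frame.to_csv(outdir / "calls.tsv", sep="\t", index=False)

    # tally + randomness test
    tally = tally_convergence(
        calls, family_sizes, exclude_c3_shared=config.exclude_c3_shared
    )
    sizes_for_null = [
        family_sizes[f] for f in sorted(family_sizes) if family_sizes[f] >= 2
    ]
    result = run_convergence_test(
        sizes_for_null,
        observed=tally.observed_count,
        n_species=config.n_species,
        n_replicates=config.n_replicates,
        seed=config.seed,
    )
    hist_frame = pd.DataFrame(
        {
            "convergent_count": list(result.histogram),
            "replicates": list(result.histogram.values()),
        }
    )
    hist_frame.to_csv(outdir / "null_histogram.tsv", sep="\t", index=False)

    report = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "tau": config.tau,
            "rpkm_threshold": config.rpkm_threshold,
            "strict_inequalities": config.strict_inequalities,
            "n_replicates": config.n_replicates,
            "n_species": config.n_species,
            "exclude_c3_shared": config.exclude_c3_shared,
        },
        "family_sizes": family_sizes,
        "n_lineages_delimited": sum(family_sizes.values()),
        "unassigned_rpkm": expr.unassigned_rpkm,
        "calls": [call_to_row(c) for c in calls],
        "tally": {
            "observed_count": tally.observed_count,
            "families_counted": tally.families_counted,
            "convergent_families": tally.convergent_families,
            "excluded_single_lineage": tally.excluded_single_lineage,
            "excluded_incomplete": tally.excluded_incomplete,
            "excluded_c3_shared": tally.excluded_c3_shared,
            "ambiguities": tally.ambiguities,
            "is_na": tally.is_na,
        },
        "convergence": result.to_dict(),
        "warnings": report_validation.warnings,
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
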