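"""End-to-end orchestration of the unexploited-gene triage pipeline.

Stages run in a fixed order — paired-expression vote-count scoring, disease
DEG integration, stress/disease intersection, database-linkage
classification, candidate refinement, literature adjudication — with every
intermediate table persisted as TSV so the workflow can stop at the manual
curation step and resume.  The report records the funnel of gene counts
(universe → stress DEGs → shared DEGs → unlinked → candidates →
unexploited) that summarizes a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as uio
from .candidates import filter_candidates
from .integrate import integrate_disease_degs, intersect_os_disease
from .linker import SNAPSHOT_NAMES, classify_linkage, convert_ids, count_gene_literature
from .literature import adjudicate, make_worksheet
from .onscore import compute_on_scores, select_os_degs
from .simulate import (DISEASE_ID, SimulationConfig, generate_expression,
                       generate_pd_studies, generate_snapshots)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "make_fixture"]


@dataclass
class PipelineConfig:
    """Input paths and parameters for one pipeline run."""

    expression: str
    pairing: str
    study_lists: dict[str, str]            # study id -> path
    twas: str
    snapshots: dict[str, str]              # database name -> path
    idmap: str
    gene2pubmed: str
    literature: str | None = None          # curated evidence; None stops after worksheet
    outdir: str = "results"
    disease_ids: list[str] = field(default_factory=lambda: [DISEASE_ID])
    fold_threshold: float = 1.5
    selection_fraction: float = 0.05
    min_studies: int = 2
    min_scores: dict[str, float] = field(default_factory=dict)
    disease_term: str = "parkinson"

    def __post_init__(self) -> None:
        if not (self.fold_threshold > 1):
            raise ValueError("fold_threshold must be > 1")
        if not (0 < self.selection_fraction <= 1):
            raise ValueError("selection_fraction must be in (0, 1]")
        if self.min_studies < 1:
            raise ValueError("min_studies must be >= 1")
        missing = set(SNAPSHOT_NAMES) - set(self.snapshots)
        if missing:
            raise ValueError(f"config lacks snapshots: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def input_paths(self) -> list[str]:
        paths = [self.expression, self.pairing, self.twas, self.idmap, self.gene2pubmed]
        paths += list(self.study_lists.values()) + list(self.snapshots.values())
        if self.literature:
            paths.append(self.literature)
        return paths


@dataclass
class PipelineReport:
    """Stage-by-stage gene counts, artifact paths and run metadata."""

    counts: dict[str, int]
    outputs: dict[str, str]
    parameters: dict
    input_checksums: dict[str, str]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage from the configured inputs; see the module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums = {p: _sha256(p) for p in config.input_paths()}

    # stage 1: stress meta-analysis
    logger.info("stage os_meta: scoring paired expression")
    matrix = uio.read_expression(config.expression, config.pairing)
    onscores = compute_on_scores(matrix, config.fold_threshold)
    selection = select_os_degs(onscores, config.selection_fraction)
    uio.write_on_scores(onscores, outdir / "on_scores.tsv")
    uio.write_gene_list(selection.up_genes, outdir / "os_degs_up.txt")
    uio.write_gene_list(selection.down_genes, outdir / "os_degs_down.txt")
    logger.info("stage os_meta: %d genes -> %d stress DEGs",
                len(onscores), len(selection.genes))

    # stage 2: disease DEG integration
    lists = [uio.read_study_list(p, study_id=s) for s, p in config.study_lists.items()]
    twas = uio.read_twas(config.twas)
    integrated = integrate_disease_degs(lists, twas)
    uio.write_integrated(integrated, outdir / "disease_degs.tsv")
    logger.info("stage deg_integration: %d disease DEGs", len(integrated))

    # stage 3: intersection
    shared = intersect_os_disease(selection, integrated, onscores)
    shared.to_csv(outdir / "shared_degs.tsv", sep="\t", float_format="%.10g")
    shared_genes = list(shared.index)
    uio.write_gene_list(shared_genes, outdir / "shared_degs.txt")
    logger.info("stage intersect: %d shared DEGs", len(shared_genes))

    # stage 4: database linkage
    idmap = uio.read_idmap(config.idmap)
    keyed = convert_ids(shared_genes, idmap)
    snapshots = {name: uio.read_snapshot(path, name)
                 for name, path in config.snapshots.items()}
    report = classify_linkage(keyed, snapshots, config.disease_ids, config.min_scores)
    lit_counts = count_gene_literature(keyed, uio.read_gene2pubmed(config.gene2pubmed))
    report.table = report.table.join(lit_counts)
    uio.write_link_report(report, outdir / "link_report.tsv")
    unlinked = sorted(report.unlinked)
    uio.write_gene_list(sorted(report.linked), outdir / "linked.txt")
    uio.write_gene_list(unlinked, outdir / "unlinked.txt")
    logger.info("stage disease_linker: %d linked + %d unlinked",
                len(report.linked), len(unlinked))

    # stage 5: candidate refinement
    symbols = {k.input_id: k.symbol or k.input_id for k in keyed}
    cands = filter_candidates(unlinked, integrated, onscores,
                              min_studies=config.min_studies, symbols=symbols)
    uio.write_candidates(cands, integrated.study_ids, outdir / "candidates.tsv")
    worksheet = make_worksheet(cands, config.disease_term)
    worksheet.to_csv(outdir / "worksheet.tsv", sep="\t", index=False)
    logger.info("stage candidate_filter: %d candidates", len(cands))

    # stage 6: literature adjudication (requires curated evidence)
    counts = {
        "universe": len(onscores),
        "os_degs": len(selection.genes),
        "disease_degs": len(integrated),
        "shared_degs": len(shared_genes),
        "linked": len(report.linked),
        "unlinked": len(unlinked),
        "candidates": len(cands),
    }
    outputs = {p.stem: str(p) for p in sorted(outdir.glob("*.tsv"))}
    if config.literature:
        evidence = uio.read_literature_evidence(config.literature)
        adjudicated = adjudicate(cands, evidence)
        uio.write_literature(adjudicated, outdir / "literature_verdicts.tsv")
        unexploited = [r.gene for r in adjudicated if r.unexploited == "yes"]
        uio.write_gene_list(unexploited, outdir / "unexploited.txt")
        counts["unexploited"] = len(unexploited)
        logger.info("stage literature_screen: %d unexploited genes", len(unexploited))
    else:
        logger.info("no curated evidence table: stopping after the worksheet")

    outputs = {p.stem: str(p)
               for p in sorted(list(outdir.glob("*.tsv")) + list(outdir.glob("*.txt")))}
    parameters = {
        "fold_threshold": config.fold_threshold,
        "selection_fraction": config.selection_fraction,
        "min_studies": config.min_studies,
        "min_scores": config.min_scores,
        "disease_ids": config.disease_ids,
    }
    result = PipelineReport(counts=counts, outputs=outputs, parameters=parameters,
                            input_checksums=checksums)
    result.to_json(outdir / "report.json")
    return result


def make_fixture(config: SimulationConfig, outdir) -> dict[str, str]:
    """Generate every pipeline input into ``outdir``; returns the manifest.

    The manifest (also written as ``manifest.tsv``) maps each input role to
    its path and includes the planted ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate_expression(config)
    lists, twas = generate_pd_studies(config, truth)
    snapshots, idmap, gene2pubmed, literature = generate_snapshots(config, truth)

    manifest: dict[str, str] = {}

    def _reg(role: str, name: str) -> Path:
        path = outdir / name
        manifest[role] = str(path)
        return path

    uio.write_expression(matrix, _reg("expression", "expression.tsv"),
                         _reg("pairing", "pairing.tsv"))
    for sl in lists:
        uio.write_study_list(sl, _reg(f"study:{sl.study_id}", f"study_{sl.study_id}.tsv"))
    uio.write_twas(twas, _reg("twas", "twas.tsv"))
    for snap in snapshots:
        uio.write_snapshot(snap, _reg(f"snapshot:{snap.database_name}",
                                      f"snapshot_{snap.database_name}.tsv"))
    uio.write_idmap(idmap, _reg("idmap", "idmap.tsv"))
    uio.write_gene2pubmed(gene2pubmed, _reg("gene2pubmed", "gene2pubmed.tsv"))
    uio.write_literature_input(literature, _reg("literature", "literature.tsv"))
    uio.write_truth(truth, _reg("truth", "truth.tsv"))

    import pandas as pd
    pd.DataFrame(sorted(manifest.items()), columns=["role", "path"]
                 ).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest


def config_from_manifest(manifest: dict[str, str], outdir: str,
                         **overrides) -> PipelineConfig:
    """Build a pipeline config from a fixture manifest."""
    return PipelineConfig(
        expression=manifest["expression"],
        pairing=manifest["pairing"],
        study_lists={role.removeprefix("study:"): path
                     for role, path in manifest.items() if role.startswith("study:")},
        twas=manifest["twas"],
        snapshots={role.removeprefix("snapshot:"): path
                   for role, path in manifest.items() if role.startswith("snapshot:")},
        idmap=manifest["idmap"],
        gene2pubmed=manifest["gene2pubmed"],
        literature=manifest.get("literature"),
        outdir=outdir,
        **overrides,
    )


def read_manifest(path) -> dict[str, str]:
    import pandas as pd
    t = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(t["role"], t["path"]))
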