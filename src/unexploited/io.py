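"""Tab-separated readers and writers for every table the pipeline exchanges.

All artifacts are plain TSV with header rows (gene lists: one ID per line).
Writers and readers round-trip values at full ``repr`` precision.  The
linkage report uses the published supplementary-table column names
(``availability of associations``, ``Evidence``, ``NU_PMIDs_PD``, ...);
candidate and literature tables mirror the published table conventions,
rendering absent values as ``Not Found``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .candidates import CandidateRecord
from .integrate import IntegratedDEGTable, StudyDEGList, TwasRecord
from .linker import SNAPSHOT_NAMES, AssociationSnapshot, IDMap, LinkReport
from .literature import LiteratureEvidence
from .onscore import ExpressionMatrix, ONScoreTable, SamplePair
from .simulate import GroundTruth

NOT_FOUND = "Not Found"


# -- expression + pairing ---------------------------------------------------

def write_expression(matrix: ExpressionMatrix, expr_path, pairing_path) -> None:
    matrix.values.to_csv(expr_path, sep="\t", float_format="%.10g")
    pd.DataFrame(matrix.pairs,
                 columns=["stress_sample", "control_sample", "source_study"]
                 ).to_csv(pairing_path, sep="\t", index=False)


def read_expression(expr_path, pairing_path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    pairing = pd.read_csv(pairing_path, sep="\t", dtype=str).fillna("")
    pairs = [SamplePair(r.stress_sample, r.control_sample, r.source_study)
             for r in pairing.itertuples(index=False)]
    return ExpressionMatrix(values, pairs)


# -- gene lists -------------------------------------------------------------

def write_gene_list(genes: Sequence[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


# -- ON-score table ---------------------------------------------------------

def write_on_scores(table: ONScoreTable, path) -> None:
    out = table.table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_on_scores(path, n_pairs: int | None = None,
                   fold_threshold: float = 1.5) -> ONScoreTable:
    t = pd.read_csv(path, sep="\t", index_col=0)
    if n_pairs is None:
        n_pairs = int((t["n_up"] + t["n_down"] + t["n_unchanged"]).iloc[0])
    return ONScoreTable(t, n_pairs=n_pairs, fold_threshold=fold_threshold)


# -- study DEG lists + TWAS -------------------------------------------------

def write_study_list(sl: StudyDEGList, path) -> None:
    sl.records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_study_list(path, study_id: str | None = None) -> StudyDEGList:
    if study_id is None:  # study_<id>.tsv convention
        stem = Path(path).stem
        study_id = stem.removeprefix("study_")
    t = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return StudyDEGList(study_id, t)


def write_twas(records: Sequence[TwasRecord], path) -> None:
    pd.DataFrame(records, columns=["gene_id", "z", "source"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_twas(path) -> list[TwasRecord]:
    t = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "source": str})
    return [TwasRecord(r.gene_id, float(r.z), r.source) for r in t.itertuples(index=False)]


# -- integrated disease table ----------------------------------------------

def write_integrated(table: IntegratedDEGTable, path) -> None:
    out = table.table.copy()
    # published naming convention for provenance columns
    out = out.rename(columns={f"log2fc_{s}": f"PD_log2(fold change)_{s}"
                              for s in table.study_ids})
    out = out.drop(columns=[f"in_{s}" for s in table.study_ids])
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_integrated(path) -> IntegratedDEGTable:
    t = pd.read_csv(path, sep="\t", index_col=0)
    prefix = "PD_log2(fold change)_"
    study_ids = [c.removeprefix(prefix) for c in t.columns if c.startswith(prefix)]
    t = t.rename(columns={f"{prefix}{s}": f"log2fc_{s}" for s in study_ids})
    for s in study_ids:
        t[f"in_{s}"] = t[f"log2fc_{s}"].notna()
    t["twas_flag"] = t["twas_flag"].astype(bool)
    return IntegratedDEGTable(t, study_ids=study_ids)


# -- association snapshots, ID map, gene2pubmed -----------------------------

def write_snapshot(snapshot: AssociationSnapshot, path) -> None:
    out = snapshot.records.copy()
    out["pmids"] = out["pmids"].map(lambda v: ";".join(v) if isinstance(v, (list, tuple)) else "")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_snapshot(path, database_name: str) -> AssociationSnapshot:
    t = pd.read_csv(path, sep="\t", dtype={"gene_key": str, "disease_id": str,
                                           "pmids": str})
    t["pmids"] = t["pmids"].fillna("").map(lambda s: [p for p in s.split(";") if p])
    if "score" not in t.columns:
        t["score"] = np.nan
    t["score"] = pd.to_numeric(t["score"], errors="coerce")
    return AssociationSnapshot(database_name, t)


def write_idmap(idmap: IDMap, path) -> None:
    idmap.table.to_csv(path, sep="\t", index=False)


def read_idmap(path) -> IDMap:
    return IDMap(pd.read_csv(path, sep="\t", dtype=str))


def write_gene2pubmed(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene2pubmed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


# -- link report (supplementary-table schema) -------------------------------

_LINK_COLUMNS = {
    "availability": "availability of associations",
    "evidence_databases": "Evidence",
    "n_pmids_disease": "NU_PMIDs_PD",
    "n_pmids_gene": "NU_PMIDs_NCBI",
    "pmids_disease": "PMIDs_PD",
    "pmids_gene": "PMIDs_NCBI",
}


def write_link_report(report: LinkReport, path) -> None:
    out = report.table.copy()
    for col in ("evidence_databases", "pmids_disease", "pmids_gene"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: ";".join(v) if v else NOT_FOUND)
    out = out.rename(columns=_LINK_COLUMNS)
    out.index.name = "ENSG"
    out.to_csv(path, sep="\t")


def read_link_report(path) -> LinkReport:
    t = pd.read_csv(path, sep="\t", index_col=0)
    t = t.rename(columns={v: k for k, v in _LINK_COLUMNS.items()})
    for col in ("evidence_databases", "pmids_disease", "pmids_gene"):
        if col in t.columns:
            t[col] = t[col].map(
                lambda s: [] if pd.isna(s) or s == NOT_FOUND else str(s).split(";"))
    return LinkReport(t)


# -- candidates (published Table-3 style) -----------------------------------

def write_candidates(records: Sequence[CandidateRecord],
                     study_ids: Sequence[str], path) -> None:
    rows = []
    for r in records:
        row = {"Ensembl gene ID": r.gene, "GeneSymbol": r.symbol, "ON score": r.on_score}
        for s in study_ids:
            fc = r.log2fcs.get(s)
            row[f"PD_log2(fold change)_{s}"] = NOT_FOUND if fc is None else f"{fc:.10g}"
        row["TWAS Z score"] = NOT_FOUND if r.twas_z is None else f"{r.twas_z:.10g}"
        row["TWAS original paper"] = r.twas_source if r.twas_source else NOT_FOUND
        row["reason"] = ";".join(sorted(r.reason))
        rows.append(row)
    cols = (["Ensembl gene ID", "GeneSymbol", "ON score"]
            + [f"PD_log2(fold change)_{s}" for s in study_ids]
            + ["TWAS Z score", "TWAS original paper", "reason"])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_candidates(path) -> list[CandidateRecord]:
    t = pd.read_csv(path, sep="\t", dtype=str)
    prefix = "PD_log2(fold change)_"
    study_ids = [c.removeprefix(prefix) for c in t.columns if c.startswith(prefix)]
    out = []
    for r in t.to_dict("records"):
        log2fcs = {s: float(r[f"{prefix}{s}"]) for s in study_ids
                   if r[f"{prefix}{s}"] != NOT_FOUND}
        twas_z = None if r["TWAS Z score"] == NOT_FOUND else float(r["TWAS Z score"])
        out.append(CandidateRecord(
            gene=r["Ensembl gene ID"], symbol=r["GeneSymbol"],
            on_score=int(r["ON score"]), log2fcs=log2fcs, twas_z=twas_z,
            twas_source=None if r["TWAS original paper"] == NOT_FOUND
            else r["TWAS original paper"],
            reason=frozenset(r["reason"].split(";")),
        ))
    return out


# -- literature evidence (published Table-4 style) --------------------------

_LIT_COLUMNS = ["Ensembl gene ID", "GeneSymbol", "Unexploited genes (yes or no)",
                "Evidence (PMCID)", "Evidence statements in research paper",
                "Search query in PMC", "Search date",
                "The number of publications yielded"]


def write_literature(rows: Sequence[LiteratureEvidence], path) -> None:
    out = pd.DataFrame([{
        "Ensembl gene ID": r.gene,
        "GeneSymbol": r.symbol,
        "Unexploited genes (yes or no)": r.unexploited,
        "Evidence (PMCID)": r.evidence_pmcid or NOT_FOUND,
        "Evidence statements in research paper": r.evidence_statement or NOT_FOUND,
        "Search query in PMC": r.query,
        "Search date": r.search_date,
        "The number of publications yielded": r.n_publications,
    } for r in rows], columns=_LIT_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_literature_evidence(path) -> dict[str, LiteratureEvidence]:
    """Read a curated evidence table (generator dialect) keyed by gene ID."""
    t = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str,
                                           "evidence_pmcid": str,
                                           "evidence_statement": str})
    out = {}
    for r in t.to_dict("records"):
        pmcid = r.get("evidence_pmcid")
        statement = r.get("evidence_statement")
        out[r["gene_id"]] = LiteratureEvidence(
            gene=r["gene_id"], symbol=r["symbol"], query=r["query"],
            search_date=str(r["search_date"]),
            n_publications=int(r["n_publications"]),
            evidence_pmcid=None if pd.isna(pmcid) or pmcid == "" else pmcid,
            evidence_statement=None if pd.isna(statement) or statement == "" else statement,
            functional_statement=bool(r["functional_statement"]),
        )
    return out


def write_literature_input(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# -- ground truth -----------------------------------------------------------

def write_truth(truth: GroundTruth, path) -> None:
    rows = []
    for role, genes in (
        ("planted_up", truth.planted_up),
        ("planted_down", truth.planted_down),
        ("twas", truth.twas_genes),
        ("db_linked", truth.db_linked_genes),
        ("functional_literature", truth.functional_literature_genes),
    ):
        rows += [(role, g) for g in sorted(genes)]
    for study, genes in sorted(truth.study_membership.items()):
        rows += [(f"study:{study}", g) for g in sorted(genes)]
    pd.DataFrame(rows, columns=["role", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_truth(path) -> GroundTruth:
    t = pd.read_csv(path, sep="\t", dtype=str)
    by_role: dict[str, set[str]] = {}
    for r in t.itertuples(index=False):
        by_role.setdefault(r.role, set()).add(r.gene_id)
    truth = GroundTruth(
        planted_up=by_role.get("planted_up", set()),
        planted_down=by_role.get("planted_down", set()),
        twas_genes=by_role.get("twas", set()),
        db_linked_genes=by_role.get("db_linked", set()),
        functional_literature_genes=by_role.get("functional_literature", set()),
    )
    truth.study_membership = {
        role.removeprefix("study:"): genes
        for role, genes in by_role.items() if role.startswith("study:")
    }
    return truth
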