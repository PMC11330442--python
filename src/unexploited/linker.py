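"""Offline gene-disease linkage against frozen association-database snapshots.

Reimplements the linkage step of the triage pipeline without network access:
each input gene is converted to every available key form (Ensembl ID, symbol,
Entrez ID), searched against five local database snapshots (Open Targets,
DisGeNET, miRTex, RNADisease, PubChem), and classified *linked* if any
snapshot holds a matching record for the disease of interest, otherwise
*unlinked*.  Supporting PubMed IDs are aggregated and deduplicated across
databases, and the gene's total literature footprint is counted from a
gene2pubmed-style table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SNAPSHOT_NAMES = ("open_targets", "disgenet", "mirtex", "rnadisease", "pubchem")

__all__ = [
    "SNAPSHOT_NAMES",
    "AssociationSnapshot",
    "IDMap",
    "KeyedGene",
    "LinkReport",
    "convert_ids",
    "query_snapshot",
    "classify_linkage",
    "count_gene_literature",
]


@dataclass
class AssociationSnapshot:
    """Frozen records of one gene-disease association database.

    ``records`` columns: gene_key, disease_id, pmids (list of str), score
    (float, NaN when the source provides none).  Every record must carry at
    least one evidence PMID or a score.
    """

    database_name: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.database_name not in SNAPSHOT_NAMES:
            raise ValueError(
                f"unknown database {self.database_name!r}; expected one of {SNAPSHOT_NAMES}"
            )
        bad = []
        for i, row in enumerate(self.records.itertuples(index=False)):
            has_pmid = isinstance(row.pmids, (list, tuple)) and len(row.pmids) > 0
            has_score = row.score is not None and not (
                isinstance(row.score, float) and math.isnan(row.score)
            )
            if not row.gene_key or not row.disease_id or not (has_pmid or has_score):
                bad.append(i + 1)
        if bad:
            raise ValueError(
                f"snapshot {self.database_name}: malformed rows (need gene_key, "
                f"disease_id and >=1 PMID or a score) at lines {bad[:20]}"
            )


@dataclass
class IDMap:
    """Ensembl <-> symbol <-> Entrez mapping table; any field may be absent."""

    table: pd.DataFrame  # columns: ensembl_id, symbol, entrez_id

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table, columns=["ensembl_id", "symbol", "entrez_id"])
        present = t["ensembl_id"].dropna()
        if present.duplicated().any():
            dups = present[present.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ensembl_id rows in ID map: {dups[:5]}")
        self.table = t


@dataclass(frozen=True)
class KeyedGene:
    """One input gene with every key form available for snapshot lookup."""

    input_id: str
    ensembl: str | None = None
    symbol: str | None = None
    entrez: str | None = None
    unmapped: bool = False

    @property
    def keys(self) -> set[str]:
        return {k for k in (self.input_id, self.ensembl, self.symbol, self.entrez) if k}


@dataclass
class LinkReport:
    """Per-gene linkage verdicts with aggregated evidence.

    ``table`` is indexed by input gene ID with columns: availability (yes/no),
    evidence_databases (list), pmids_disease (list), n_pmids_disease,
    pmids_gene (list), n_pmids_gene, unmapped.
    """

    table: pd.DataFrame
    disease_ids: list[str] = field(default_factory=list)

    @property
    def linked(self) -> set[str]:
        return set(self.table.index[self.table["availability"] == "yes"])

    @property
    def unlinked(self) -> set[str]:
        return set(self.table.index[self.table["availability"] == "no"])


def convert_ids(genes: Sequence[str], idmap: IDMap) -> list[KeyedGene]:
    """Attach all known key forms to each gene; unmapped genes are kept.

    The input may be in any of the three key forms.  A symbol mapping to
    several Ensembl IDs resolves to the lowest-sorting one (logged).
    """
    t = idmap.table
    by_col: dict[str, dict[str, int]] = {}
    for col in ("ensembl_id", "symbol", "entrez_id"):
        col_map: dict[str, int] = {}
        for i, v in t[col].items():
            if pd.isna(v) or v == "":
                continue
            v = str(v)
            if v in col_map:
                prev = t.at[col_map[v], "ensembl_id"]
                cur = t.at[i, "ensembl_id"]
                keep_prev = str(prev) <= str(cur)
                logger.warning(
                    "ID map: %s %r maps to multiple rows; keeping ensembl %s",
                    col, v, prev if keep_prev else cur,
                )
                if keep_prev:
                    continue
            col_map[v] = i
        by_col[col] = col_map

    out = []
    for gene in genes:
        key = str(gene)
        row_i = None
        for col in ("ensembl_id", "symbol", "entrez_id"):
            if key in by_col[col]:
                row_i = by_col[col][key]
                break
        if row_i is None:
            out.append(KeyedGene(input_id=key, unmapped=True))
            continue
        row = t.loc[row_i]

        def _get(col: str) -> str | None:
            v = row[col]
            return None if pd.isna(v) or v == "" else str(v)

        out.append(
            KeyedGene(
                input_id=key,
                ensembl=_get("ensembl_id"),
                symbol=_get("symbol"),
                entrez=_get("entrez_id"),
            )
        )
    return out


def query_snapshot(
    genes: Sequence[KeyedGene],
    snapshot: AssociationSnapshot,
    disease_id: str,
    min_score: float = 0.0,
) -> dict[str, list]:
    """Records of one snapshot matching each gene for one disease ID.

    A record hits when its gene key equals any key form of the gene, its
    disease ID equals ``disease_id`` exactly, and its score (when present)
    is >= ``min_score``.  Returns input-gene-ID -> list of matching rows.
    """
    if not disease_id:
        raise ValueError("disease_id must be nonempty")
    recs = snapshot.records
    mask = recs["disease_id"].astype(str) == str(disease_id)
    score = recs["score"].astype(float)
    mask &= score.isna() | (score >= min_score)
    sub = recs[mask]
    by_key: dict[str, list] = {}
    for row in sub.itertuples(index=False):
        by_key.setdefault(str(row.gene_key), []).append(row)
    hits: dict[str, list] = {}
    for g in genes:
        found = []
        for k in sorted(g.keys):
            found.extend(by_key.get(k, []))
        if found:
            hits[g.input_id] = found
    return hits


def classify_linkage(
    genes: Sequence[KeyedGene],
    snapshots: Mapping[str, AssociationSnapshot] | Sequence[AssociationSnapshot],
    disease_ids: str | Sequence[str],
    thresholds: Mapping[str, float] | None = None,
) -> LinkReport:
    """Classify every gene as disease-linked or -unlinked across all snapshots.

    ``disease_ids`` may list several synonymous IDs (one per source ontology);
    a gene is linked as soon as any snapshot holds a hit for any of them.
    ``thresholds`` gives a per-database minimum association score (default 0:
    any evidence counts).  A score-only hit (no PMIDs) still links the gene
    but contributes nothing to the disease PMID list.  Unmapped genes are
    classified unlinked with a warning rather than erroring.
    """
    if isinstance(snapshots, Mapping):
        snap_map = dict(snapshots)
    else:
        snap_map = {s.database_name: s for s in snapshots}
    missing = set(SNAPSHOT_NAMES) - set(snap_map)
    if missing:
        raise ValueError(f"missing snapshots: {sorted(missing)}")
    if isinstance(disease_ids, str):
        disease_ids = [disease_ids]
    thresholds = dict(thresholds or {})

    rows = {}
    for g in genes:
        if g.unmapped:
            logger.warning("gene %r not in the ID map; classified unlinked", g.input_id)
        rows[g.input_id] = {
            "availability": "no",
            "evidence_databases": [],
            "pmids_disease": [],
            "n_pmids_disease": 0,
            "unmapped": g.unmapped,
        }
    for name in SNAPSHOT_NAMES:
        min_score = thresholds.get(name, 0.0)
        for did in disease_ids:
            hits = query_snapshot(genes, snap_map[name], did, min_score)
            for gene_id, recs in hits.items():
                row = rows[gene_id]
                row["availability"] = "yes"
                if name not in row["evidence_databases"]:
                    row["evidence_databases"].append(name)
                for r in recs:
                    row["pmids_disease"].extend(r.pmids or [])
    for row in rows.values():
        row["pmids_disease"] = sorted(set(row["pmids_disease"]))
        row["n_pmids_disease"] = len(row["pmids_disease"])
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene_id"
    return LinkReport(table=table, disease_ids=list(disease_ids))


def count_gene_literature(
    genes: Sequence[KeyedGene],
    gene2pubmed: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene deduplicated PubMed IDs from a (entrez_id, pmid) table.

    Genes without an Entrez key get count 0 and ``entrez_missing=True``.
    """
    t = pd.DataFrame(gene2pubmed, columns=["entrez_id", "pmid"]).astype(str)
    grouped = t.groupby("entrez_id")["pmid"].agg(lambda s: sorted(set(s)))
    rows = {}
    for g in genes:
        pmids = list(grouped.get(g.entrez, [])) if g.entrez else []
        rows[g.input_id] = {
            "pmids_gene": pmids,
            "n_pmids_gene": len(pmids),
            "entrez_missing": g.entrez is None,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out
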