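"""Integration of per-study disease DEG lists and TWAS evidence.

Disease DEGs reported by independent meta-analyses are combined as a
provenance-tracked union: one row per gene, one log2 fold-change column per
study, plus TWAS membership (Z score and source study).  TWAS genes count
toward the disease union but stay flagged separately so downstream candidate
filtering can distinguish the two evidence types.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .onscore import DEGSelection, ONScoreTable

__all__ = [
    "StudyDEGList",
    "TwasRecord",
    "IntegratedDEGTable",
    "integrate_disease_degs",
    "venn_region_counts",
    "intersect_os_disease",
]


@dataclass
class StudyDEGList:
    """DEGs reported by one study: (gene, log2 fold change) pairs."""

    study_id: str
    records: pd.DataFrame  # columns: gene_id, log2fc

    def __post_init__(self) -> None:
        self.records = pd.DataFrame(self.records, columns=["gene_id", "log2fc"])
        dup = self.records.duplicated(subset="gene_id", keep=False)
        if dup.any():
            conflicting = self.records[dup].groupby("gene_id")["log2fc"].nunique()
            if (conflicting > 1).any():
                bad = conflicting[conflicting > 1].index.tolist()
                raise ValueError(
                    f"study {self.study_id}: conflicting duplicate log2fc for {bad}"
                )
            self.records = self.records.drop_duplicates(subset="gene_id")

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene_id"])


class TwasRecord(NamedTuple):
    gene: str
    z_score: float
    source_study: str


@dataclass
class IntegratedDEGTable:
    """Union of study DEG lists plus TWAS genes, with per-source provenance.

    ``table`` is indexed by gene ID with one ``log2fc_<study>`` column per
    study (NaN = not reported), boolean ``in_<study>`` flags, and
    ``twas_flag`` / ``twas_z`` / ``twas_source`` columns.
    """

    table: pd.DataFrame
    study_ids: list[str]

    @property
    def genes(self) -> set[str]:
        return set(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def n_studies_for(self, gene: str) -> int:
        cols = [f"log2fc_{s}" for s in self.study_ids]
        return int(self.table.loc[gene, cols].notna().sum())


def integrate_disease_degs(
    lists: Sequence[StudyDEGList],
    twas: Iterable[TwasRecord] = (),
) -> IntegratedDEGTable:
    """Build the provenance-tracked union of study DEG lists and TWAS genes."""
    study_ids = [sl.study_id for sl in lists]
    if len(set(study_ids)) != len(study_ids):
        raise ValueError(f"duplicate study IDs: {study_ids}")
    twas = [TwasRecord(*t) for t in twas]
    genes = sorted(
        set(itertools.chain.from_iterable(sl.genes for sl in lists))
        | {t.gene for t in twas}
    )
    table = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for sl in lists:
        fc = sl.records.set_index("gene_id")["log2fc"]
        table[f"log2fc_{sl.study_id}"] = fc.reindex(table.index)
        table[f"in_{sl.study_id}"] = table[f"log2fc_{sl.study_id}"].notna()
    z = pd.Series({t.gene: t.z_score for t in twas}, dtype=float)
    src = pd.Series({t.gene: t.source_study for t in twas}, dtype=object)
    table["twas_flag"] = table.index.isin(z.index)
    table["twas_z"] = z.reindex(table.index)
    table["twas_source"] = src.reindex(table.index)
    return IntegratedDEGTable(table=table, study_ids=study_ids)


def venn_region_counts(lists: Sequence[StudyDEGList]) -> dict[frozenset, int]:
    """Counts of every non-empty membership region among up to six gene sets.

    Keys are frozensets of study IDs; all 2^k - 1 regions are present (zero
    counts included) and the counts sum to the union size.
    """
    if len(lists) > 6:
        raise ValueError(f"at most 6 sets supported, got {len(lists)}")
    ids = [sl.study_id for sl in lists]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate study IDs: {ids}")
    sets = {sl.study_id: sl.genes for sl in lists}
    counts: dict[frozenset, int] = {}
    for r in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, r):
            counts[frozenset(combo)] = 0
    for gene in set().union(*sets.values()) if sets else set():
        member = frozenset(s for s, gs in sets.items() if gene in gs)
        counts[member] += 1
    return counts


_ID_PATTERNS = {
    "ensembl": re.compile(r"^ENSG\d{6,}"),
    "numeric": re.compile(r"^\d+$"),
}


def _id_style(ids: Iterable[str]) -> str:
    sample = list(itertools.islice(iter(ids), 200))
    for name, pat in _ID_PATTERNS.items():
        if sample and all(pat.match(str(g)) for g in sample):
            return name
    return "symbol"


def intersect_os_disease(
    os_sel: DEGSelection,
    pd_table: IntegratedDEGTable,
    onscores: ONScoreTable | None = None,
) -> pd.DataFrame:
    """Genes dysregulated in both the stress selection and the disease union.

    Returns one row per shared gene carrying the stress direction, the score
    (when an :class:`ONScoreTable` is supplied), all per-study log2
    fold-changes and the TWAS columns.  A complete ID-format mismatch between
    the two inputs (e.g. Ensembl IDs vs symbols) raises instead of silently
    returning an empty intersection.
    """
    os_genes = os_sel.genes
    if not os_genes or not len(pd_table):
        raise ValueError("both the stress selection and disease table must be nonempty")
    shared = sorted(os_genes & pd_table.genes)
    if not shared:
        style_a, style_b = _id_style(os_genes), _id_style(pd_table.genes)
        if style_a != style_b:
            raise ValueError(
                f"no shared genes and ID formats differ ({style_a} vs {style_b}); "
                "run both inputs through the same ID normalization"
            )
    out = pd_table.table.loc[shared].copy()
    out.insert(0, "direction", [os_sel.direction(g) for g in shared])
    if onscores is not None:
        out.insert(1, "on_score", onscores.table["on_score"].reindex(shared))
    return out
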