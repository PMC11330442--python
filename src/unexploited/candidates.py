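"""Refinement of disease-unlinked genes into unexploited candidates.

A database-unlinked gene stays a candidate when independent evidence still
points at the disease: either a TWAS Z score (genetically regulated
expression associated with disease risk) or differential expression reported
by at least ``min_studies`` of the curated disease meta-analyses.  A gene
meeting both criteria is emitted once with both reasons recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .integrate import IntegratedDEGTable
from .onscore import ONScoreTable

__all__ = ["CandidateRecord", "filter_candidates"]


@dataclass(frozen=True)
class CandidateRecord:
    """One unexploited-candidate gene with the evidence that retained it."""

    gene: str
    symbol: str
    on_score: int
    log2fcs: Mapping[str, float]  # study id -> log2 fold change (present only)
    twas_z: float | None
    twas_source: str | None
    reason: frozenset  # nonempty subset of {"twas", "multi_study"}

    @property
    def n_meta_studies(self) -> int:
        return len(self.log2fcs)

    def __post_init__(self) -> None:
        if not self.reason:
            raise ValueError(f"candidate {self.gene} emitted without a reason")
        if not self.reason <= {"twas", "multi_study"}:
            raise ValueError(f"unknown reason in {sorted(self.reason)}")


def filter_candidates(
    unlinked: Iterable[str],
    integrated: IntegratedDEGTable,
    onscores: ONScoreTable,
    min_studies: int = 2,
    *,
    min_abs_twas_z: float = 0.0,
    symbols: Mapping[str, str] | None = None,
) -> list[CandidateRecord]:
    """Retain unlinked genes with TWAS evidence or multi-study DEG support.

    Parameters
    ----------
    unlinked : database-unlinked genes (must be known to the integrated
        disease table or the score table).
    integrated : provenance-tracked disease DEG union.
    onscores : per-gene vote-count scores from the stress meta-analysis.
    min_studies : minimum number of meta-analyses reporting the gene as a
        disease DEG for the multi-study criterion (default 2).
    min_abs_twas_z : optional absolute-Z cutoff for the TWAS criterion;
        the default 0 makes mere presence of a Z score sufficient, either sign.
    symbols : optional gene-ID -> display-symbol mapping.

    Returns records sorted by \\|score\\| descending, then gene ID.
    """
    if min_studies < 1:
        raise ValueError(f"min_studies must be >= 1, got {min_studies}")
    symbols = symbols or {}
    unlinked = sorted(set(unlinked))
    known = integrated.genes | set(onscores.gene_ids)
    unknown = [g for g in unlinked if g not in known]
    if unknown:
        raise ValueError(f"unlinked genes outside the analysis universe: {unknown[:5]}")

    fc_cols = [f"log2fc_{s}" for s in integrated.study_ids]
    out: list[CandidateRecord] = []
    for gene in unlinked:
        if gene in integrated.genes:
            row = integrated.table.loc[gene]
            log2fcs = {
                s: float(row[f"log2fc_{s}"])
                for s in integrated.study_ids
                if pd.notna(row[f"log2fc_{s}"])
            }
            twas_z = float(row["twas_z"]) if pd.notna(row["twas_z"]) else None
            twas_source = row["twas_source"] if pd.notna(row["twas_source"]) else None
        else:
            log2fcs, twas_z, twas_source = {}, None, None
        reasons = set()
        if twas_z is not None and abs(twas_z) >= min_abs_twas_z:
            reasons.add("twas")
        if len(log2fcs) >= min_studies:
            reasons.add("multi_study")
        if not reasons:
            continue
        score = int(onscores.table.at[gene, "on_score"]) if gene in onscores.gene_ids else 0
        out.append(
            CandidateRecord(
                gene=gene,
                symbol=symbols.get(gene, gene),
                on_score=score,
                log2fcs=log2fcs,
                twas_z=twas_z,
                twas_source=twas_source,
                reason=frozenset(reasons),
            )
        )
    out.sort(key=lambda r: (-abs(r.on_score), r.gene))
    return out
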