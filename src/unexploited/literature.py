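"""Literature adjudication of unexploited candidates.

The final pipeline stage is a manual full-text search: for each candidate a
PubMed Central query is generated, a curator records what the literature
contains, and this module validates and applies the decision rule — a gene
is *unexploited* only when the literature holds a mechanistic/functional
statement tying it to the disease (a DEG-list mention alone is not enough).
The module structures the human decision; it performs no text mining.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .candidates import CandidateRecord

__all__ = ["LiteratureEvidence", "build_query", "adjudicate", "make_worksheet"]


@dataclass(frozen=True)
class LiteratureEvidence:
    """Curated literature-search outcome for one candidate gene."""

    gene: str
    symbol: str
    query: str
    search_date: str
    n_publications: int
    evidence_pmcid: str | None = None
    evidence_statement: str | None = None
    functional_statement: bool = False
    unexploited: str = "no"  # yes/no

    def __post_init__(self) -> None:
        if self.n_publications < 0:
            raise ValueError(f"{self.gene}: negative publication count")
        if self.unexploited not in ("yes", "no"):
            raise ValueError(f"{self.gene}: unexploited must be yes/no")
        if self.unexploited == "yes":
            if not self.functional_statement or not self.evidence_pmcid:
                raise ValueError(
                    f"{self.gene}: unexploited=yes requires a functional statement "
                    "and an evidence PMCID"
                )
            if self.n_publications == 0:
                raise ValueError(
                    f"{self.gene}: unexploited=yes with zero search results"
                )


def build_query(symbol: str, disease_term: str = "parkinson") -> str:
    """Full-text search query for one gene symbol, PubMed Central syntax."""
    if not symbol or symbol != symbol.strip() or any(c.isspace() for c in symbol):
        raise ValueError(f"invalid gene symbol {symbol!r}")
    return f"{symbol}[All Fields] AND {disease_term}[All Fields]"


def adjudicate(
    candidates: Sequence[CandidateRecord],
    evidence: Mapping[str, LiteratureEvidence],
) -> list[LiteratureEvidence]:
    """Apply the unexploited decision rule to every candidate, in order.

    unexploited = yes iff the curated row records a functional statement
    (genes only listed among DEGs, or absent from the literature, get no).
    Every candidate must have an evidence row; a missing row is an error so
    incomplete curation cannot pass silently.
    """
    missing = [c.gene for c in candidates if c.gene not in evidence]
    if missing:
        raise KeyError(f"candidates without a literature-evidence row: {missing}")
    out = []
    for c in candidates:
        row = evidence[c.gene]
        verdict = "yes" if row.functional_statement and row.n_publications > 0 else "no"
        out.append(replace(row, unexploited=verdict))
    return out


def make_worksheet(
    candidates: Sequence[CandidateRecord],
    disease_term: str = "parkinson",
) -> pd.DataFrame:
    """Curator worksheet: one row per candidate with its query, evidence blank."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene for c in candidates],
            "symbol": [c.symbol for c in candidates],
            "query": [build_query(c.symbol, disease_term) for c in candidates],
            "search_date": "",
            "n_publications": "",
            "evidence_pmcid": "",
            "evidence_statement": "",
            "functional_statement": "",
        }
    )
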