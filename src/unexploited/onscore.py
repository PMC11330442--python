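"""Vote-counting meta-analysis of paired stress/control expression.

For every gene and every (stress, control) sample pair the pseudocounted
expression ratio

    ratio = (T_stress + 1) / (T_control + 1)

is classified as *up* (ratio >= f), *down* (ratio <= 1/f) or *unchanged*
against a fold threshold f (default 1.5).  The per-gene score is the number
of pairs voting up minus the number voting down; genes with the most extreme
scores across the cohort form the stress DEG selection (by default the top
and bottom 2.5% each, i.e. 5% of the universe).

The +1 pseudocount keeps the ratio finite for unexpressed genes: a gene at
zero in both samples of a pair has ratio 1 and votes *unchanged*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SamplePair",
    "ExpressionMatrix",
    "ONScoreTable",
    "DEGSelection",
    "compute_on_ratio",
    "classify_pair",
    "compute_on_scores",
    "select_os_degs",
]


class SamplePair(NamedTuple):
    stress_sample: str
    control_sample: str
    source_study: str = ""


@dataclass
class ExpressionMatrix:
    """TPM-scale expression values plus a stress/control pairing manifest.

    ``values`` is a genes x samples DataFrame (index = gene IDs); ``pairs``
    maps each stress sample to its matched control from the same study.
    """

    values: pd.DataFrame
    pairs: list[SamplePair]

    def __post_init__(self) -> None:
        self.pairs = [SamplePair(*p) for p in self.pairs]
        cols = set(self.values.columns)
        seen_stress: set[str] = set()
        seen_control: set[str] = set()
        for p in self.pairs:
            for sample in (p.stress_sample, p.control_sample):
                if sample not in cols:
                    raise ValueError(f"paired sample {sample!r} missing from matrix")
            if p.stress_sample in seen_stress:
                raise ValueError(f"sample {p.stress_sample!r} paired twice as stress")
            if p.control_sample in seen_control:
                raise ValueError(f"sample {p.control_sample!r} paired twice as control")
            seen_stress.add(p.stress_sample)
            seen_control.add(p.control_sample)
        if not self.values.index.is_unique:
            raise ValueError("gene IDs are not unique")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any() or (np.nan_to_num(vals) < 0).any():
            raise ValueError("expression values must be finite and >= 0 (NaN = missing)")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def swapped(self) -> "ExpressionMatrix":
        """Return a copy with the stress/control roles of every pair exchanged."""
        return ExpressionMatrix(
            self.values.copy(),
            [SamplePair(p.control_sample, p.stress_sample, p.source_study)
             for p in self.pairs],
        )


@dataclass
class ONScoreTable:
    """Per-gene vote counts and integer score over all sample pairs.

    ``table`` columns: n_up, n_down, n_unchanged, on_score, mean_log2_ratio
    (the per-gene mean of log2 pseudocounted ratios, kept for deterministic
    tie-breaking at the selection boundary).
    """

    table: pd.DataFrame
    n_pairs: int
    fold_threshold: float

    def __post_init__(self) -> None:
        t = self.table
        counts = t["n_up"] + t["n_down"] + t["n_unchanged"]
        if not (counts == self.n_pairs).all():
            raise ValueError("vote counts do not sum to the number of pairs")
        if not (t["on_score"] == t["n_up"] - t["n_down"]).all():
            raise ValueError("on_score must equal n_up - n_down")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class DEGSelection:
    """Ordered up- and down-regulated gene selections, disjoint by construction."""

    up_genes: list[str]
    down_genes: list[str]
    fraction: float
    fold_threshold: float
    min_abs_score: int = 0

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down selections overlap")

    @property
    def genes(self) -> set[str]:
        return set(self.up_genes) | set(self.down_genes)

    def direction(self, gene: str) -> str:
        if gene in set(self.up_genes):
            return "up"
        if gene in set(self.down_genes):
            return "down"
        raise KeyError(gene)


def compute_on_ratio(t_stress: float, t_control: float) -> float:
    """Pseudocounted stress/control expression ratio (T_stress+1)/(T_control+1)."""
    for name, v in (("t_stress", t_stress), ("t_control", t_control)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
    return (t_stress + 1.0) / (t_control + 1.0)


def classify_pair(on_ratio: float, fold_threshold: float = 1.5) -> str:
    """Classify a single pair's ratio as 'up', 'down' or 'unchanged'.

    The threshold is inclusive on both sides: a ratio exactly at f (or 1/f)
    counts as up (down), keeping the +-f cutoff pair symmetric.
    """
    if not (fold_threshold > 1):
        raise ValueError(f"fold_threshold must be > 1, got {fold_threshold}")
    if not (on_ratio > 0) or not math.isfinite(on_ratio):
        raise ValueError(f"on_ratio must be positive and finite, got {on_ratio!r}")
    if on_ratio >= fold_threshold:
        return "up"
    if on_ratio <= 1.0 / fold_threshold:
        return "down"
    return "unchanged"


def compute_on_scores(
    matrix: ExpressionMatrix,
    fold_threshold: float = 1.5,
    *,
    missing: str = "unchanged",
) -> ONScoreTable:
    """Vote-count every gene across all sample pairs of the cohort.

    Parameters
    ----------
    matrix : paired expression values.
    fold_threshold : ratio cutoff f; a pair votes up at ratio >= f and down
        at ratio <= 1/f.
    missing : how to treat a NaN in either sample of a pair: ``"unchanged"``
        (default; the pair abstains) or ``"error"`` (strict mode).
    """
    if not (fold_threshold > 1):
        raise ValueError(f"fold_threshold must be > 1, got {fold_threshold}")
    if missing not in ("unchanged", "error"):
        raise ValueError(f"missing must be 'unchanged' or 'error', got {missing!r}")
    if not matrix.pairs:
        raise ValueError("pairing manifest is empty")

    stress = matrix.values[[p.stress_sample for p in matrix.pairs]].to_numpy(dtype=float)
    control = matrix.values[[p.control_sample for p in matrix.pairs]].to_numpy(dtype=float)
    nan_mask = np.isnan(stress) | np.isnan(control)
    if nan_mask.any() and missing == "error":
        g, p = np.argwhere(nan_mask)[0]
        raise ValueError(
            f"missing value for gene {matrix.gene_ids[g]!r} in pair {p} (strict mode)"
        )
    with np.errstate(invalid="ignore"):
        ratio = (stress + 1.0) / (control + 1.0)
    up = (ratio >= fold_threshold) & ~nan_mask
    down = (ratio <= 1.0 / fold_threshold) & ~nan_mask
    n_up = up.sum(axis=1).astype(int)
    n_down = down.sum(axis=1).astype(int)
    log2_ratio = np.where(nan_mask, 0.0, np.log2(ratio))
    table = pd.DataFrame(
        {
            "n_up": n_up,
            "n_down": n_down,
            "n_unchanged": matrix.n_pairs - n_up - n_down,
            "on_score": n_up - n_down,
            "mean_log2_ratio": log2_ratio.mean(axis=1),
        },
        index=matrix.gene_ids,
    )
    return ONScoreTable(table, n_pairs=matrix.n_pairs, fold_threshold=fold_threshold)


def _per_direction_count(fraction: float, n_genes: int) -> int:
    # half-up rounding of fraction/2 * G (62,266 genes at 5% -> 1557 per side)
    return int(math.floor(fraction / 2.0 * n_genes + 0.5))


def select_os_degs(
    table: ONScoreTable,
    fraction: float = 0.05,
    *,
    min_abs_score: int = 0,
) -> DEGSelection:
    """Select the most extreme genes by score: top m up, bottom m down.

    m = round(fraction/2 * G), halves rounded up.  Genes are put in one total
    order — score descending, then mean log2 ratio descending, then gene ID —
    and the selection takes the first m (up) and last m (down) entries, so the
    two lists cannot overlap while 2m <= G.  Within a tied score the signed
    mean log2 ratio favors the larger effect at either end.  ``min_abs_score``
    optionally drops selected genes with \\|score\\| below the given value.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(table) == 0:
        raise ValueError("empty score table")
    n_genes = len(table)
    m = _per_direction_count(fraction, n_genes)
    if 2 * m > n_genes:
        raise ValueError(
            f"cannot select {m} genes per direction from a {n_genes}-gene universe"
        )
    t = table.table
    # lexsort: last key is primary; gene ID ascending breaks residual ties
    idx = np.lexsort(
        (
            t.index.to_numpy(),
            -t["mean_log2_ratio"].to_numpy(),
            -t["on_score"].to_numpy(),
        )
    )
    ordered = t.index.to_numpy()[idx]
    up = list(ordered[:m])
    down = list(ordered[n_genes - m:][::-1])
    if min_abs_score > 0:
        up = [g for g in up if t.at[g, "on_score"] >= min_abs_score]
        down = [g for g in down if t.at[g, "on_score"] <= -min_abs_score]
    return DEGSelection(
        up_genes=up,
        down_genes=down,
        fraction=fraction,
        fold_threshold=table.fold_threshold,
        min_abs_score=min_abs_score,
    )
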