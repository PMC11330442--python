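"""Synthetic inputs with known ground truth for the full triage pipeline.

Emulates the statistical shape of the real study design — a large gene
universe measured as TPM over paired stress/control samples, a subset of
genes planted with a multiplicative fold effect that fires in only a
fraction of pairs, several partially overlapping disease-study DEG lists,
sparse TWAS hits, and sparse database/literature annotations — so every
pipeline stage can be exercised offline against planted truth.

Expression model: each gene draws a lognormal baseline
``exp(N(baseline_log_mean, baseline_log_sd))``; each sample multiplies it by
``exp(N(0, noise_sd))`` pair-level noise.  A planted-up gene additionally
multiplies its stress sample by ``fold_effect`` (planted-down: divides) in a
Bernoulli(``response_prob``) subset of pairs.  The lognormal noise keeps
values positive and mimics the multiplicative dispersion of TPM estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .linker import SNAPSHOT_NAMES
from .literature import build_query
from .onscore import ExpressionMatrix, SamplePair

__all__ = ["SimulationConfig", "GroundTruth", "generate_expression",
           "generate_pd_studies", "generate_snapshots", "DISEASE_ID"]

DISEASE_ID = "MONDO:0005180"  # Parkinson disease; decoy records use other IDs
_DECOY_DISEASE_ID = "MONDO:0004975"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study; defaults are the standard fixture.

    The defaults describe a scaled-down cohort: a 2000-gene universe over 50
    stress/control pairs, 50 genes planted up and 50 down at a 2-fold effect
    responding in 80% of pairs, three disease studies each capturing 60% of
    the true disease genes plus 20 false positives, sparse TWAS hits (10%),
    ~30% of true disease genes already registered in a database, and 20%
    carrying a functional literature statement.
    """

    n_genes: int = 2000
    n_pairs: int = 50
    n_planted_up: int = 50
    n_planted_down: int = 50
    fold_effect: float = 2.0
    response_prob: float = 0.8
    noise_sd: float = 0.25
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    min_planted_baseline: float = 4.0
    n_studies: int = 3
    study_capture_prob: float = 0.6
    study_fp_count: int = 20
    twas_hit_prob: float = 0.1
    db_link_prob: float = 0.3
    lit_functional_prob: float = 0.2
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_pairs", "n_studies"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive int")
        for name in ("n_planted_up", "n_planted_down", "study_fp_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_planted_up + self.n_planted_down > self.n_genes:
            raise ValueError("planted genes exceed the universe")
        for name in ("response_prob", "study_capture_prob", "twas_hit_prob",
                     "db_link_prob", "lit_functional_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (self.fold_effect > 1):
            raise ValueError(f"fold_effect must be > 1, got {self.fold_effect}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.min_planted_baseline < 0:
            raise ValueError("min_planted_baseline must be >= 0")
        for name in ("fold_effect", "response_prob", "noise_sd",
                     "baseline_log_mean", "baseline_log_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted truth behind one synthetic data set."""

    planted_up: set[str]
    planted_down: set[str]
    study_membership: dict[str, set[str]] = field(default_factory=dict)
    twas_genes: set[str] = field(default_factory=set)
    db_linked_genes: set[str] = field(default_factory=set)
    functional_literature_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.planted_up & self.planted_down:
            raise ValueError("a gene cannot be planted both up and down")

    @property
    def disease_genes(self) -> set[str]:
        return self.planted_up | self.planted_down

    def expected_unexploited(self, min_studies: int = 2) -> set[str]:
        """The genes an exact pipeline run must report as unexploited.

        Valid for noise-free fixtures where the stress selection recovers the
        planted genes exactly: unexploited = functional-literature genes that
        are database-unlinked and pass the candidate criteria (TWAS evidence
        or membership in >= ``min_studies`` study lists).
        """
        multi = {
            g
            for g in self.disease_genes
            if sum(g in s for s in self.study_membership.values()) >= min_studies
        }
        candidates = (self.twas_genes | multi) - self.db_linked_genes
        return self.functional_literature_genes & candidates


def _gene_ids(n: int) -> list[str]:
    return [f"ENSG{i + 1:011d}" for i in range(n)]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # one global seed, one independent stream per generator
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Paired stress/control TPM-scale matrix with planted fold effects."""
    rng = _rng(config, 0)
    genes = _gene_ids(config.n_genes)
    planted = rng.choice(
        config.n_genes, size=config.n_planted_up + config.n_planted_down, replace=False
    )
    up_idx = planted[: config.n_planted_up]
    down_idx = planted[config.n_planted_up:]

    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes)
    )
    # planted genes must be detectably expressed: below ~f(t-1)/(f-t) TPM the
    # +1 pseudocount keeps a true fold effect f under the calling threshold t,
    # and no expression-based method could recover the gene
    baseline[planted] = np.maximum(baseline[planted], config.min_planted_baseline)
    shape = (config.n_genes, config.n_pairs)
    control = baseline[:, None] * np.exp(rng.normal(0.0, config.noise_sd, size=shape))
    effect = np.ones(shape)
    responds = rng.random(shape) < config.response_prob
    effect[up_idx] = np.where(responds[up_idx], config.fold_effect, 1.0)
    effect[down_idx] = np.where(responds[down_idx], 1.0 / config.fold_effect, 1.0)
    stress = (
        baseline[:, None] * effect * np.exp(rng.normal(0.0, config.noise_sd, size=shape))
    )

    pairs, columns, data = [], [], []
    for p in range(config.n_pairs):
        s_name, c_name = f"stress_{p:03d}", f"control_{p:03d}"
        pairs.append(SamplePair(s_name, c_name, f"SYNSTUDY{p % 5 + 1}"))
        columns += [s_name, c_name]
        data += [stress[:, p], control[:, p]]
    values = pd.DataFrame(np.column_stack(data), index=pd.Index(genes, name="gene_id"),
                          columns=columns)
    truth = GroundTruth(
        planted_up={genes[i] for i in up_idx},
        planted_down={genes[i] for i in down_idx},
    )
    return ExpressionMatrix(values, pairs), truth


def generate_pd_studies(config: SimulationConfig, truth: GroundTruth):
    """Per-study disease DEG lists plus TWAS records, written into ``truth``.

    Each study captures each true disease gene with ``study_capture_prob``
    (log2FC sign matching the planted direction) and adds
    ``study_fp_count`` random non-disease genes; TWAS hits are drawn from the
    true disease genes with ``twas_hit_prob``.
    """
    from .integrate import StudyDEGList, TwasRecord  # local import avoids a cycle

    rng = _rng(config, 1)
    genes = _gene_ids(config.n_genes)
    if not genes:
        raise ValueError("empty gene universe")
    disease = sorted(truth.disease_genes)
    others = sorted(set(genes) - truth.disease_genes)

    lists = []
    for s in range(config.n_studies):
        study_id = f"9{s + 1:07d}"  # PMID-like synthetic identifier
        rows = []
        for g in disease:
            if rng.random() < config.study_capture_prob:
                mag = max(0.1, rng.normal(0.6, 0.25))
                sign = 1.0 if g in truth.planted_up else -1.0
                rows.append((g, round(sign * mag, 3)))
        n_fp = min(config.study_fp_count, len(others))
        for i in rng.choice(len(others), size=n_fp, replace=False) if n_fp else []:
            mag = max(0.1, rng.normal(0.6, 0.25))
            rows.append((others[int(i)], round(rng.choice([-1.0, 1.0]) * mag, 3)))
        lists.append(
            StudyDEGList(study_id, pd.DataFrame(rows, columns=["gene_id", "log2fc"]))
        )
        truth.study_membership[study_id] = {g for g, _ in rows}

    twas = []
    twas_source = "80000001"
    for g in disease:
        if rng.random() < config.twas_hit_prob:
            z = float(rng.choice([-1.0, 1.0]) * rng.uniform(3.0, 6.0))
            twas.append(TwasRecord(g, round(z, 2), twas_source))
    truth.twas_genes = {t.gene for t in twas}
    return lists, twas


def generate_snapshots(config: SimulationConfig, truth: GroundTruth):
    """Five association snapshots, ID map, gene2pubmed and literature tables.

    Each database-linked gene (true disease gene with ``db_link_prob``)
    appears in one to three of the five snapshots under that database's
    natural key form, with synthetic evidence PMIDs.  Literature-evidence
    rows cover every gene occurring in any study list or TWAS record (i.e.
    every possible candidate); functional statements are planted only on
    database-UNLINKED disease genes with ``lit_functional_prob`` so the
    planted unexploited set is nonempty by construction.
    """
    from .linker import AssociationSnapshot, IDMap

    rng = _rng(config, 2)
    genes = _gene_ids(config.n_genes)
    symbols = {g: f"SYG{i + 1}" for i, g in enumerate(genes)}
    entrez = {g: str(100000 + i) for i, g in enumerate(genes)}

    idmap = IDMap(pd.DataFrame({
        "ensembl_id": genes,
        "symbol": [symbols[g] for g in genes],
        "entrez_id": [entrez[g] for g in genes],
    }))

    disease = sorted(truth.disease_genes)
    linked = {g for g in disease if rng.random() < config.db_link_prob}
    truth.db_linked_genes = linked

    key_form = {
        "open_targets": lambda g: g,
        "disgenet": lambda g: symbols[g],
        "mirtex": lambda g: symbols[g],
        "rnadisease": lambda g: symbols[g],
        "pubchem": lambda g: entrez[g],
    }
    records: dict[str, list] = {name: [] for name in SNAPSHOT_NAMES}
    for g in sorted(linked):
        n_dbs = int(rng.integers(1, 4))
        dbs = rng.choice(len(SNAPSHOT_NAMES), size=n_dbs, replace=False)
        for d in dbs:
            name = SNAPSHOT_NAMES[int(d)]
            pmids = [str(int(rng.integers(10_000_000, 40_000_000)))
                     for _ in range(int(rng.integers(1, 4)))]
            score = round(float(rng.uniform(0.1, 1.0)), 3)
            records[name].append((key_form[name](g), DISEASE_ID, pmids, score))
    # decoy rows for an unrelated disease: exact disease-ID matching is exercised
    for g in [genes[int(i)] for i in rng.choice(config.n_genes, size=20, replace=False)]:
        name = SNAPSHOT_NAMES[int(rng.integers(0, 5))]
        records[name].append(
            (key_form[name](g), _DECOY_DISEASE_ID,
             [str(int(rng.integers(10_000_000, 40_000_000)))], None)
        )
    snapshots = [
        AssociationSnapshot(
            name,
            pd.DataFrame(records[name], columns=["gene_key", "disease_id", "pmids", "score"]),
        )
        for name in SNAPSHOT_NAMES
    ]

    # gene2pubmed: every disease gene plus a background sample gets a footprint
    g2p_rows = []
    background = [genes[int(i)]
                  for i in rng.choice(config.n_genes, size=min(200, config.n_genes),
                                      replace=False)]
    for g in sorted(set(disease) | set(background)):
        for _ in range(1 + int(rng.poisson(4))):
            g2p_rows.append((entrez[g], str(int(rng.integers(10_000_000, 40_000_000)))))
    gene2pubmed = pd.DataFrame(g2p_rows, columns=["entrez_id", "pmid"])

    # every gene a study or TWAS table mentions gets a literature row, so any
    # gene that can reach the adjudication stage is covered
    mentioned = set(truth.twas_genes)
    for members in truth.study_membership.values():
        mentioned |= members
    functional = set()
    lit_rows = []
    for g in sorted(mentioned | truth.disease_genes):
        is_functional = (
            g in truth.disease_genes
            and g not in linked
            and rng.random() < config.lit_functional_prob
        )
        n_pub = int(rng.integers(1, 80)) if (is_functional or rng.random() < 0.7) else 0
        row = {
            "gene_id": g,
            "symbol": symbols[g],
            "query": build_query(symbols[g]),
            "search_date": "2025-01-15",
            "n_publications": n_pub,
            "evidence_pmcid": f"PMC{int(rng.integers(1_000_000, 12_000_000))}"
            if is_functional else "",
            "evidence_statement": f"{symbols[g]} modulates disease-relevant redox signaling."
            if is_functional else "",
            "functional_statement": is_functional,
        }
        lit_rows.append(row)
        if is_functional:
            functional.add(g)
    truth.functional_literature_genes = functional
    literature = pd.DataFrame(lit_rows)
    return snapshots, idmap, gene2pubmed, literature
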