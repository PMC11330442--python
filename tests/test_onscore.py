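"""Vote-count scoring of paired expression, checked against a two-loop oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unexploited import (ExpressionMatrix, SamplePair, classify_pair,
                         compute_on_ratio, compute_on_scores, select_os_degs)
from unexploited.onscore import ONScoreTable, _per_direction_count


def random_matrix(rng, n_genes, n_pairs, missing_frac=0.0):
    vals = rng.gamma(1.0, 20.0, size=(n_genes, 2 * n_pairs))
    if missing_frac:
        mask = rng.random(vals.shape) < missing_frac
        vals = np.where(mask, np.nan, vals)
    cols, pairs = [], []
    for p in range(n_pairs):
        cols += [f"s{p}", f"c{p}"]
        pairs.append(SamplePair(f"s{p}", f"c{p}", "st"))
    df = pd.DataFrame(vals, index=[f"g{i:03d}" for i in range(n_genes)], columns=cols)
    return ExpressionMatrix(df, pairs)


def recount_oracle(matrix, fold_threshold):
    """Independent per-gene, per-pair recount using the scalar operations."""
    rows = {}
    for gene in matrix.gene_ids:
        n_up = n_down = n_unc = 0
        for p in matrix.pairs:
            s = matrix.values.at[gene, p.stress_sample]
            c = matrix.values.at[gene, p.control_sample]
            if np.isnan(s) or np.isnan(c):
                call = "unchanged"
            else:
                call = classify_pair(compute_on_ratio(s, c), fold_threshold)
            n_up += call == "up"
            n_down += call == "down"
            n_unc += call == "unchanged"
        rows[gene] = (n_up, n_down, n_unc, n_up - n_down)
    return rows


class TestOnRatio:
    @pytest.mark.parametrize(
        "stress,control,expected",
        [(0, 0, 1.0), (2, 1, 1.5), (1, 2, 2 / 3), (0, 9, 0.1), (99, 0, 100.0)],
    )
    def test_pseudocount_ratio(self, stress, control, expected):
        assert compute_on_ratio(stress, control) == pytest.approx(expected)

    def test_swap_symmetry(self):
        assert compute_on_ratio(1, 2) == pytest.approx(1 / compute_on_ratio(2, 1))

    @pytest.mark.parametrize("bad", [(-1, 0), (0, -0.5), (float("nan"), 1),
                                     (float("inf"), 1)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            compute_on_ratio(*bad)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(1.0, "unchanged"), (1.5, "up"), (2 / 3, "down"), (1.49, "unchanged"),
         (0.67, "unchanged"), (10.0, "up"), (0.01, "down")],
    )
    def test_threshold_classification(self, ratio, expected):
        assert classify_pair(ratio, 1.5) == expected

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            classify_pair(2.0, 1.0)


class TestComputeOnScores:
    def test_counts_from_explicit_calls(self):
        # calls per pair: up, up, down, unchanged -> (2, 1, 1, score 1)
        df = pd.DataFrame(
            {
                "s0": [2.0], "c0": [1.0],   # ratio 1.5 -> up
                "s1": [5.0], "c1": [1.0],   # ratio 3 -> up
                "s2": [1.0], "c2": [2.0],   # ratio 2/3 -> down
                "s3": [1.0], "c3": [1.0],   # ratio 1 -> unchanged
            },
            index=["g"],
        )
        pairs = [SamplePair(f"s{i}", f"c{i}", "x") for i in range(4)]
        t = compute_on_scores(ExpressionMatrix(df, pairs), 1.5).table
        assert tuple(t.loc["g", ["n_up", "n_down", "n_unchanged", "on_score"]]) == (2, 1, 1, 1)

    def test_zero_in_both_samples_is_unchanged(self):
        df = pd.DataFrame({"s0": [0.0], "c0": [0.0]}, index=["g"])
        t = compute_on_scores(ExpressionMatrix(df, [SamplePair("s0", "c0", "x")])).table
        assert t.loc["g", "n_unchanged"] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_recount_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, n_genes=20, n_pairs=10, missing_frac=0.05)
        table = compute_on_scores(m, 1.5).table
        oracle = recount_oracle(m, 1.5)
        for gene, (nu, nd, nc, sc) in oracle.items():
            row = table.loc[gene]
            assert (row["n_up"], row["n_down"], row["n_unchanged"], row["on_score"]) \
                == (nu, nd, nc, sc)

    def test_swapping_pairs_negates_scores(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 30, 8)
        fwd = compute_on_scores(m, 1.5).table["on_score"]
        rev = compute_on_scores(m.swapped(), 1.5).table["on_score"]
        assert (fwd + rev == 0).all()

    def test_vote_totals_cover_every_pair(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 25, 7)
        t = compute_on_scores(m).table
        assert (t[["n_up", "n_down", "n_unchanged"]].sum(axis=1) == 7).all()
        assert t[["n_up", "n_down", "n_unchanged"]].to_numpy().sum() == 25 * 7

    def test_strict_mode_errors_on_missing(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 10, 4, missing_frac=0.2)
        with pytest.raises(ValueError, match="missing value"):
            compute_on_scores(m, missing="error")

    def test_empty_pairing_rejected(self):
        df = pd.DataFrame({"a": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            compute_on_scores(ExpressionMatrix(df, []))


def make_score_table(scores, tiebreak=None):
    genes = [f"g{i:03d}" for i in range(len(scores))]
    n_pairs = max(abs(int(s)) for s in scores) + 2
    t = pd.DataFrame(
        {
            "n_up": [max(s, 0) for s in scores],
            "n_down": [max(-s, 0) for s in scores],
            "n_unchanged": [n_pairs - abs(s) for s in scores],
            "on_score": scores,
            "mean_log2_ratio": tiebreak if tiebreak is not None
            else [s / 10 for s in scores],
        },
        index=genes,
    )
    return ONScoreTable(t, n_pairs=n_pairs, fold_threshold=1.5)


class TestSelectOsDegs:
    def test_published_universe_selection_size(self):
        # 5% of a 62,266-gene universe: 1557 per direction, 3114 total
        assert _per_direction_count(0.05, 62266) == 1557

    def test_small_universe_rounding(self):
        # round(0.5 * 0.05 * 40) = 1 per direction
        table = make_score_table(list(range(-20, 20)))
        sel = select_os_degs(table, 0.05)
        assert len(sel.up_genes) == len(sel.down_genes) == 1

    def test_selects_extremes(self):
        table = make_score_table([5, -7, 0, 3, -2, 9, 1, -1])
        sel = select_os_degs(table, 0.5)  # 2 per direction
        assert sel.up_genes == ["g005", "g000"]   # scores 9, 5
        assert sel.down_genes == ["g001", "g004"]  # scores -7, -2

    def test_deterministic_under_repetition(self):
        rng = np.random.default_rng(11)
        table = make_score_table(list(rng.integers(-5, 6, size=60)))
        a = select_os_degs(table, 0.1)
        b = select_os_degs(table, 0.1)
        assert a.up_genes == b.up_genes and a.down_genes == b.down_genes

    def test_up_down_disjoint_even_with_massive_ties(self):
        table = make_score_table([0] * 50, tiebreak=[0.0] * 50)
        sel = select_os_degs(table, 0.5)
        # m = round-half-up(0.25 * 50) = 13 per direction
        assert len(sel.up_genes) == len(sel.down_genes) == 13
        assert not set(sel.up_genes) & set(sel.down_genes)

    def test_tie_break_favors_larger_effect(self):
        # equal scores: the up end prefers the most positive mean log2 ratio
        table = make_score_table([3, 3, 3, -3, -3, -3],
                                 tiebreak=[0.1, 0.9, 0.5, -0.9, -0.1, -0.5])
        sel = select_os_degs(table, 1 / 3)  # 1 per direction
        assert sel.up_genes == ["g001"]
        assert sel.down_genes == ["g003"]

    def test_min_abs_score_filter(self):
        table = make_score_table([5, 1, 0, -1, -6, 0])
        sel = select_os_degs(table, 2 / 3, min_abs_score=3)
        assert sel.up_genes == ["g000"] and sel.down_genes == ["g004"]

    def test_oversized_fraction_rejected(self):
        table = make_score_table([1, -1, 0])
        with pytest.raises(ValueError):
            select_os_degs(table, 1.0)

    @given(st.lists(st.integers(-10, 10), min_size=10, max_size=50))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_selection_property(self, scores):
        table = make_score_table(scores)
        sel = select_os_degs(table, 0.2)
        m = _per_direction_count(0.2, len(scores))
        assert len(sel.up_genes) == len(sel.down_genes) == m
        assert not set(sel.up_genes) & set(sel.down_genes)
        # every selected up score >= every unselected score >= every down score
        t = table.table["on_score"]
        rest = set(table.gene_ids) - sel.genes
        if rest:
            assert min(t[g] for g in sel.up_genes) >= max(t[g] for g in rest) or m == 0
            assert max(t[g] for g in sel.down_genes) <= min(t[g] for g in rest)
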