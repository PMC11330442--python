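"""Offline gene-disease linkage: ID conversion, snapshot queries, classification."""

import numpy as np
import pandas as pd
import pytest

from unexploited import (AssociationSnapshot, IDMap, classify_linkage,
                         convert_ids, count_gene_literature, query_snapshot)
from unexploited.linker import SNAPSHOT_NAMES

DISEASE = "MONDO:0005180"


def idmap(rows):
    return IDMap(pd.DataFrame(rows, columns=["ensembl_id", "symbol", "entrez_id"]))


def snapshot(name, rows):
    return AssociationSnapshot(
        name, pd.DataFrame(rows, columns=["gene_key", "disease_id", "pmids", "score"])
    )


def empty_snapshots(**overrides):
    snaps = {n: snapshot(n, []) for n in SNAPSHOT_NAMES}
    snaps.update(overrides)
    return snaps


class TestConvertIds:
    def test_full_mapping_populates_all_keys(self):
        m = idmap([("ENSG1", "GENEA", "111")])
        (g,) = convert_ids(["ENSG1"], m)
        assert (g.ensembl, g.symbol, g.entrez, g.unmapped) == ("ENSG1", "GENEA", "111", False)

    def test_lookup_by_symbol_or_entrez(self):
        m = idmap([("ENSG1", "GENEA", "111")])
        assert convert_ids(["GENEA"], m)[0].ensembl == "ENSG1"
        assert convert_ids(["111"], m)[0].symbol == "GENEA"

    def test_unmapped_gene_flagged_not_dropped(self):
        m = idmap([("ENSG1", "GENEA", "111")])
        out = convert_ids(["ENSGX", "ENSG1"], m)
        assert [g.input_id for g in out] == ["ENSGX", "ENSG1"]
        assert out[0].unmapped and not out[1].unmapped

    def test_symbol_collision_resolves_to_lowest_ensembl(self, caplog):
        m = idmap([("ENSG2", "DUP", "222"), ("ENSG1", "DUP", "111")])
        with caplog.at_level("WARNING"):
            (g,) = convert_ids(["DUP"], m)
        assert g.ensembl == "ENSG1"
        assert any("multiple rows" in r.message for r in caplog.records)

    def test_duplicate_ensembl_rejected(self):
        with pytest.raises(ValueError, match="duplicate ensembl"):
            idmap([("ENSG1", "A", "1"), ("ENSG1", "B", "2")])


class TestQuerySnapshot:
    def test_score_threshold(self):
        snap = snapshot("disgenet", [("GENEA", DISEASE, ["1"], 0.9)])
        m = idmap([("ENSG1", "GENEA", "111")])
        genes = convert_ids(["ENSG1"], m)
        assert "ENSG1" in query_snapshot(genes, snap, DISEASE, min_score=0.5)
        assert query_snapshot(genes, snap, DISEASE, min_score=0.95) == {}

    def test_exact_disease_match_required(self):
        snap = snapshot("disgenet", [("GENEA", "MONDO:9999999", ["1"], 0.9)])
        genes = convert_ids(["GENEA"], idmap([("ENSG1", "GENEA", "1")]))
        assert query_snapshot(genes, snap, DISEASE) == {}

    def test_scoreless_record_always_passes_threshold(self):
        snap = snapshot("mirtex", [("GENEA", DISEASE, ["1"], np.nan)])
        genes = convert_ids(["ENSG1"], idmap([("ENSG1", "GENEA", "1")]))
        assert "ENSG1" in query_snapshot(genes, snap, DISEASE, min_score=0.99)

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(8)
        keys = [f"G{i}" for i in range(30)]
        rows = [(rng.choice(keys), rng.choice([DISEASE, "OTHER"]),
                 [str(rng.integers(1, 99))], float(rng.uniform(0, 1)))
                for _ in range(80)]
        snap = snapshot("rnadisease", rows)
        m = idmap([(f"E{i}", k, str(i)) for i, k in enumerate(keys)])
        genes = convert_ids([f"E{i}" for i in range(30)], m)
        hits = query_snapshot(genes, snap, DISEASE, min_score=0.4)
        for g in genes:
            expected = [r for r in rows
                        if r[0] in g.keys and r[1] == DISEASE and r[3] >= 0.4]
            assert len(hits.get(g.input_id, [])) == len(expected)

    def test_malformed_rows_reported_with_lines(self):
        with pytest.raises(ValueError, match="lines \\[2\\]"):
            snapshot("pubchem", [("G1", DISEASE, ["1"], 0.5),
                                 ("G2", DISEASE, [], np.nan)])


class TestClassifyLinkage:
    def test_single_database_hit(self):
        snaps = empty_snapshots(
            disgenet=snapshot("disgenet", [("GENEA", DISEASE, ["123"], np.nan)]))
        genes = convert_ids(["ENSG1"], idmap([("ENSG1", "GENEA", "1")]))
        rep = classify_linkage(genes, snaps, DISEASE)
        row = rep.table.loc["ENSG1"]
        assert row["availability"] == "yes"
        assert row["evidence_databases"] == ["disgenet"]
        assert row["n_pmids_disease"] == 1

    def test_absent_gene_is_unlinked(self):
        genes = convert_ids(["ENSG1"], idmap([("ENSG1", "GENEA", "1")]))
        rep = classify_linkage(genes, empty_snapshots(), DISEASE)
        assert rep.table.at["ENSG1", "availability"] == "no"
        assert rep.table.at["ENSG1", "evidence_databases"] == []

    def test_shared_pmid_across_databases_counted_once(self):
        snaps = empty_snapshots(
            disgenet=snapshot("disgenet", [("GENEA", DISEASE, ["77", "88"], np.nan)]),
            mirtex=snapshot("mirtex", [("GENEA", DISEASE, ["88", "99"], np.nan)]))
        genes = convert_ids(["ENSG1"], idmap([("ENSG1", "GENEA", "1")]))
        row = classify_linkage(genes, snaps, DISEASE).table.loc["ENSG1"]
        # brute-force dedup oracle: {77, 88} | {88, 99}
        assert row["pmids_disease"] == sorted({"77", "88", "99"})
        assert row["n_pmids_disease"] == 3
        assert set(row["evidence_databases"]) == {"disgenet", "mirtex"}

    def test_linked_unlinked_partition(self):
        snaps = empty_snapshots(
            open_targets=snapshot("open_targets", [("E1", DISEASE, ["1"], np.nan)]))
        m = idmap([(f"E{i}", f"S{i}", str(i)) for i in range(5)])
        genes = convert_ids([f"E{i}" for i in range(5)], m)
        rep = classify_linkage(genes, snaps, DISEASE)
        assert rep.linked | rep.unlinked == {f"E{i}" for i in range(5)}
        assert not rep.linked & rep.unlinked
        assert rep.linked == {"E1"}

    def test_raising_threshold_never_links_more(self):
        rng = np.random.default_rng(9)
        rows = [(f"S{i}", DISEASE, ["1"], float(rng.uniform(0, 1))) for i in range(20)]
        m = idmap([(f"E{i}", f"S{i}", str(i)) for i in range(20)])
        genes = convert_ids([f"E{i}" for i in range(20)], m)
        prev = None
        for thr in (0.0, 0.3, 0.6, 0.9):
            snaps = empty_snapshots(disgenet=snapshot("disgenet", rows))
            linked = classify_linkage(genes, snaps, DISEASE,
                                      thresholds={"disgenet": thr}).linked
            if prev is not None:
                assert linked <= prev
            prev = linked

    def test_order_invariance(self):
        rows = [("S1", DISEASE, ["2", "1"], np.nan), ("S3", DISEASE, ["9"], np.nan)]
        m = idmap([(f"E{i}", f"S{i}", str(i)) for i in range(5)])
        ids = [f"E{i}" for i in range(5)]
        snaps_a = empty_snapshots(mirtex=snapshot("mirtex", rows))
        snaps_b = empty_snapshots(mirtex=snapshot("mirtex", rows[::-1]))
        rep_a = classify_linkage(convert_ids(ids, m), snaps_a, DISEASE)
        rep_b = classify_linkage(convert_ids(ids[::-1], m), snaps_b, DISEASE)
        assert rep_a.linked == rep_b.linked
        for g in ids:
            assert rep_a.table.at[g, "pmids_disease"] == rep_b.table.at[g, "pmids_disease"]

    def test_unmapped_gene_classified_unlinked_with_warning(self, caplog):
        genes = convert_ids(["NOPE"], idmap([("ENSG1", "A", "1")]))
        with caplog.at_level("WARNING"):
            rep = classify_linkage(genes, empty_snapshots(), DISEASE)
        assert rep.table.at["NOPE", "availability"] == "no"
        assert rep.table.at["NOPE", "unmapped"]
        assert any("not in the ID map" in r.message for r in caplog.records)

    def test_missing_snapshot_rejected(self):
        snaps = empty_snapshots()
        del snaps["pubchem"]
        with pytest.raises(ValueError, match="missing snapshots"):
            classify_linkage([], snaps, DISEASE)

    def test_score_only_hit_links_without_pmids(self):
        snap = AssociationSnapshot("disgenet", pd.DataFrame(
            [("GENEA", DISEASE, [], 0.8)],
            columns=["gene_key", "disease_id", "pmids", "score"]))
        genes = convert_ids(["GENEA"], idmap([("ENSG1", "GENEA", "1")]))
        row = classify_linkage(genes, empty_snapshots(disgenet=snap),
                               DISEASE).table.loc["GENEA"]
        assert row["availability"] == "yes"
        assert row["n_pmids_disease"] == 0


class TestCountGeneLiterature:
    def test_counts_match_groupby_oracle(self):
        rng = np.random.default_rng(10)
        rows = [(str(rng.integers(1, 6)), str(rng.integers(100, 110)))
                for _ in range(60)]
        table = pd.DataFrame(rows, columns=["entrez_id", "pmid"])
        m = idmap([(f"E{i}", f"S{i}", str(i)) for i in range(1, 6)])
        genes = convert_ids([f"E{i}" for i in range(1, 6)], m)
        out = count_gene_literature(genes, table)
        oracle = table.drop_duplicates().groupby("entrez_id")["pmid"].nunique()
        for g in genes:
            assert out.at[g.input_id, "n_pmids_gene"] == int(oracle.get(g.entrez, 0))

    def test_duplicates_collapsed(self):
        table = pd.DataFrame({"entrez_id": ["1", "1", "1"], "pmid": ["9", "9", "8"]})
        genes = convert_ids(["E1"], idmap([("E1", "S", "1")]))
        assert count_gene_literature(genes, table).at["E1", "n_pmids_gene"] == 2

    def test_gene_without_entrez_counts_zero(self):
        m = IDMap(pd.DataFrame({"ensembl_id": ["E1"], "symbol": ["S"],
                                "entrez_id": [None]}))
        genes = convert_ids(["E1"], m)
        out = count_gene_literature(genes, pd.DataFrame({"entrez_id": ["1"],
                                                         "pmid": ["5"]}))
        assert out.at["E1", "n_pmids_gene"] == 0
        assert out.at["E1", "entrez_missing"]
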