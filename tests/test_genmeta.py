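"""Relatedness classification, phenotype-aware pruning, and PLINK/BGENIE
file I/O. Pruning is checked against brute-force minimum vertex covers on
small graphs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ukbkit import (
    FormatError,
    degree_of,
    read_fam,
    read_kinship,
    read_sample,
    read_sqc,
    rel_count,
    related_with_data,
    samples_to_remove,
    sqc_names,
    write_genetic_files,
)
from ukbkit.fixtures import generate_genetic_sidecars, generate_kinship
from ukbkit.genmeta import DEFAULT_KINSHIP_CUTOFF, KINSHIP_COLUMNS


def _pairs(edges):
    """Build a kinship frame from (id1, id2, kinship) tuples."""
    return pd.DataFrame(
        [(a, b, 0.2, 0.002, k) for a, b, k in edges],
        columns=KINSHIP_COLUMNS)


def _min_vertex_cover_size(nodes, edges):
    """Brute-force minimum vertex cover by subset enumeration (n <= 12)."""
    nodes = sorted(nodes, key=str)
    for size in range(len(nodes) + 1):
        for cover in itertools.combinations(nodes, size):
            cs = set(cover)
            if all(a in cs or b in cs for a, b in edges):
                return size
    return len(nodes)


class TestDegreeOf:
    @pytest.mark.parametrize("kinship,expected", [
        (0.5, "duplicate_mz"), (0.4, "duplicate_mz"),
        (0.3536, "first"), (0.25, "first"),
        (0.1768, "second"), (0.1, "second"),
        (0.0884, "third"), (0.05, "third"),
        (0.0442, None), (0.01, None), (-0.1, None),
    ])
    def test_king_bins(self, kinship, expected):
        assert degree_of(kinship) == expected


class TestSqc:
    def test_default_schema_applies_to_fixture(self, tmp_path):
        paths, _ = generate_genetic_sidecars(tmp_path, 6, seed=1)
        df = read_sqc(paths["sqc"])
        names = sqc_names()
        assert list(df.columns) == names
        assert len(df) == 6
        assert {"inferred_gender", "used_in_pca_calculation",
                "pc1", "pc40"} <= set(names)

    def test_user_schema(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("1 2 3\n4 5 6\n")
        s = tmp_path / "schema.txt"
        s.write_text("a\nb\nc\n")
        df = read_sqc(p, sqc_names(s))
        assert list(df.columns) == ["a", "b", "c"]

    def test_length_mismatch_reports_both_counts(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("1 2 3 4\n")
        with pytest.raises(FormatError, match="3 names.*4 columns"):
            read_sqc(p, ["a", "b", "c"])


class TestRelCount:
    def test_one_pair_per_category(self):
        pairs = _pairs([("a", "b", 0.4), ("c", "d", 0.2), ("e", "f", 0.1),
                        ("g", "h", 0.05)])
        counts, scatter = rel_count(pairs)
        assert counts.set_index("degree")["n_pairs"].tolist() == [1, 1, 1, 1]
        assert len(scatter) == 4

    def test_restriction_requires_both_members(self):
        pairs = _pairs([("a", "b", 0.4), ("c", "d", 0.2)])
        counts, _ = rel_count(pairs, restrict_to={"a", "c", "d"})
        assert counts["n_pairs"].sum() == 1

    def test_empty_pairs_all_zero(self):
        counts, scatter = rel_count(_pairs([]))
        assert counts["n_pairs"].tolist() == [0, 0, 0, 0]
        assert scatter.empty

    def test_total_equals_pairs_above_lowest_bin(self):
        rng = np.random.default_rng(3)
        pairs = _pairs([(f"i{k}", f"j{k}", float(rng.uniform(0, 0.5)))
                        for k in range(200)])
        counts, _ = rel_count(pairs)
        assert counts["n_pairs"].sum() == int(
            (pairs["Kinship"] > 0.0442).sum())


class TestRelatedWithData:
    def test_kept_and_dropped(self):
        pairs = _pairs([("a", "b", 0.2), ("a", "c", 0.2)])
        out = related_with_data(pairs, {"a", "b"})
        assert out[["ID1", "ID2"]].values.tolist() == [["a", "b"]]

    def test_matches_brute_force_on_random_input(self):
        rng = np.random.default_rng(9)
        ids = [f"s{i}" for i in range(30)]
        edges = [(ids[i], ids[j], float(rng.uniform(0, 0.5)))
                 for i, j in zip(rng.integers(0, 30, 60),
                                 rng.integers(0, 30, 60)) if i != j]
        seen = set()
        edges = [e for e in edges
                 if frozenset(e[:2]) not in seen
                 and not seen.add(frozenset(e[:2]))]
        pairs = _pairs(edges)
        pheno = set(rng.choice(ids, size=15, replace=False))
        out = related_with_data(pairs, pheno)
        expected = [e for e in edges if e[0] in pheno and e[1] in pheno]
        assert len(out) == len(expected)
        assert all(r.ID1 in pheno and r.ID2 in pheno
                   for r in out.itertuples())


class TestSamplesToRemove:
    def test_no_pairs_above_cutoff(self):
        pairs = _pairs([("a", "b", 0.01)])
        assert samples_to_remove(pairs, {"a", "b"}) == []

    def test_single_edge_removes_lexicographically_smaller(self):
        pairs = _pairs([("b", "a", 0.1)])
        assert samples_to_remove(pairs, {"a", "b"}) == ["a"]

    def test_star_removes_hub_only(self):
        pairs = _pairs([("H", "A", 0.1), ("H", "B", 0.1), ("H", "C", 0.1)])
        assert samples_to_remove(pairs, {"H", "A", "B", "C"}) == ["H"]

    def test_unphenotyped_members_ignored(self):
        pairs = _pairs([("a", "b", 0.3), ("c", "d", 0.3)])
        assert samples_to_remove(pairs, {"a", "b"}) == ["a"]

    def test_cutoff_is_strict(self):
        pairs = _pairs([("a", "b", DEFAULT_KINSHIP_CUTOFF)])
        assert samples_to_remove(pairs, {"a", "b"}) == []

    @pytest.mark.parametrize("family,expected_size", [
        # path a-b-c-d: min cover 2 (b, c)
        ([("a", "b", 0.1), ("b", "c", 0.1), ("c", "d", 0.1)], 2),
        # two disjoint pairs: min cover 2
        ([("a", "b", 0.1), ("c", "d", 0.1)], 2),
        # star: min cover 1
        ([("h", "a", 0.1), ("h", "b", 0.1), ("h", "c", 0.1),
          ("h", "d", 0.1)], 1),
    ])
    def test_structured_families_hit_minimum(self, family, expected_size):
        pairs = _pairs(family)
        ids = {x for e in family for x in e[:2]}
        removed = samples_to_remove(pairs, ids)
        assert len(removed) == expected_size
        edges = [(a, b) for a, b, _ in family]
        assert len(removed) == _min_vertex_cover_size(ids, edges)

    def test_random_graphs_cover_and_parsimony(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(3, 13))
            ids = [f"n{i:02d}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.3:
                        edges.append((ids[i], ids[j],
                                      float(rng.uniform(0, 0.5))))
            pairs = _pairs(edges)
            removed = samples_to_remove(pairs, set(ids))
            hot = [(a, b) for a, b, k in edges
                   if k > DEFAULT_KINSHIP_CUTOFF]
            removed_set = set(removed)
            # vertex cover: every above-cutoff edge touched
            assert all(a in removed_set or b in removed_set
                       for a, b in hot)
            # sanity bound vs brute-force minimum
            assert len(removed) >= _min_vertex_cover_size(ids, hot)
            # no gratuitous removals: each removed node had an uncovered
            # edge at its removal time
            live = list(hot)
            for victim in removed:
                assert any(victim in e for e in live)
                live = [e for e in live if victim not in e]
            assert not live

    def test_deterministic(self):
        rng = np.random.default_rng(23)
        edges = [(f"a{i}", f"b{int(rng.integers(0, 8))}",
                  float(rng.uniform(0.05, 0.5))) for i in range(8)]
        pairs = _pairs(edges)
        ids = {x for e in edges for x in e[:2]}
        assert samples_to_remove(pairs, ids) == samples_to_remove(pairs, ids)


class TestFamSample:
    def test_fam_roundtrip_order_preserved(self, tmp_path):
        paths, truth = generate_genetic_sidecars(tmp_path, 5, seed=4)
        fam = read_fam(paths["fam"])
        assert len(fam) == 5
        assert fam["iid"].tolist() == [str(e) for e in truth.eids]
        assert fam["sex"].isin([0, 1, 2]).all()

    def test_fam_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "bad.fam"
        p.write_text("1 1 0 0 1 -9\n2 2 0 0 1\n")
        with pytest.raises(FormatError, match=":2"):
            read_fam(p)

    def test_fam_invalid_sex_rejected(self, tmp_path):
        p = tmp_path / "bad.fam"
        p.write_text("1 1 0 0 7 -9\n")
        with pytest.raises(FormatError, match="sex"):
            read_fam(p)

    def test_sample_roundtrip(self, tmp_path):
        paths, truth = generate_genetic_sidecars(tmp_path, 7, seed=5)
        tbl, types = read_sample(paths["sample"])
        assert len(tbl) == 7
        assert list(types.values())[:3] == ["0", "0", "0"]
        assert tbl["ID_2"].tolist() == [str(e) for e in truth.eids]

    def test_sample_type_line_not_data(self, tmp_path):
        p = tmp_path / "s.sample"
        p.write_text("ID_1 ID_2 missing pheno\n0 0 0 P\n1 1 0 2.5\n")
        tbl, types = read_sample(p)
        assert len(tbl) == 1
        assert types["pheno"] == "P"
        assert tbl["pheno"].iloc[0] == pytest.approx(2.5)

    def test_sample_header_type_mismatch(self, tmp_path):
        p = tmp_path / "s.sample"
        p.write_text("ID_1 ID_2 missing pheno\n0 0 0\n")
        with pytest.raises(FormatError, match="type line"):
            read_sample(p)


class TestWriters:
    def _data(self):
        return pd.DataFrame({
            "eid": [101, 103, 102],
            "bmi": [27.1, None, 31.5],
            "age": [55.0, 61.0, 48.0],
        })

    def test_plink_pheno_matches_brute_construction(self, tmp_path):
        out = write_genetic_files("plink_pheno", self._data(),
                                  tmp_path / "p.pheno")
        lines = out.read_text().splitlines()
        assert lines[0] == "FID IID bmi age"
        assert lines[1] == "101 101 27.1 55"
        assert lines[2] == "103 103 NA 61"
        assert lines[3] == "102 102 31.5 48"

    def test_bgenie_row_order_follows_sample_order(self, tmp_path):
        rng = np.random.default_rng(8)
        for _ in range(5):
            order = [str(e) for e in rng.permutation([101, 102, 103, 104])]
            out = write_genetic_files("bgenie_pheno", self._data(),
                                      tmp_path / "b.pheno",
                                      sample_order=order)
            lines = out.read_text().splitlines()
            assert lines[0] == "bmi age"
            assert len(lines) == 1 + len(order)
            by_id = {"101": "27.1 55", "102": "31.5 48",
                     "103": "-999 61", "104": "-999 -999"}
            assert lines[1:] == [by_id[i] for i in order]

    def test_missing_tokens_per_kind(self, tmp_path):
        plink = write_genetic_files("plink_pheno", self._data(),
                                    tmp_path / "p.txt").read_text()
        bgenie = write_genetic_files("bgenie_pheno", self._data(),
                                     tmp_path / "b.txt",
                                     sample_order=["103"]).read_text()
        assert " NA " in plink and "-999" not in plink
        assert "-999" in bgenie and "NA" not in bgenie.splitlines()[1]

    def test_exclusions_two_columns(self, tmp_path):
        out = write_genetic_files("plink_exclusions", [7, 8],
                                  tmp_path / "excl.txt")
        assert out.read_text() == "7 7\n8 8\n"

    def test_bgenie_requires_sample_order(self, tmp_path):
        with pytest.raises(ValueError, match="sample_order"):
            write_genetic_files("bgenie_pheno", self._data(),
                                tmp_path / "x.txt")

    def test_unknown_column_rejected(self, tmp_path):
        with pytest.raises(KeyError, match="nope"):
            write_genetic_files("plink_pheno", self._data(),
                                tmp_path / "x.txt", columns=["nope"])

    def test_kinship_reader_roundtrip(self, tmp_path):
        path, truth = generate_kinship(tmp_path / "rel.txt",
                                       ids=list(range(6)), n_pairs=8,
                                       seed=2)
        df = read_kinship(path)
        pd.testing.assert_frame_equal(df, truth.pairs)
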