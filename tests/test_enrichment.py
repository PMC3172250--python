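"""Target intersection, hypergeometric enrichment, term subnetworks."""

import itertools
import math

import numpy as np
import pytest

from mirtime.enrichment import (
    AnnotationMap,
    TargetMap,
    category_targets,
    go_subnetwork,
    hypergeom_enrichment,
    intersect_targets,
    parse_targets,
    read_gmt,
    write_gmt,
    write_targets_tsv,
)
from mirtime.errors import ConfigurationError, InputError, ParseError
from mirtime.network import Category
from mirtime.synthetic import SynthConfig, gen_ground_truth, gen_target_predictions


def hypergeom_brute_force(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating all C(N, n) draws."""
    universe = range(N)
    term = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


class TestParseTargets:
    def test_deduplication(self, tmp_path):
        fp = tmp_path / "t.tsv"
        fp.write_text("m1\tg1\nm1\tg1\nM1\tg2\n")
        tmap = parse_targets(fp)
        assert tmap.targets == {"m1": frozenset({"g1", "g2"})}

    def test_empty_file_warns(self, tmp_path):
        fp = tmp_path / "t.tsv"
        fp.write_text("")
        with pytest.warns(UserWarning):
            tmap = parse_targets(fp)
        assert tmap.targets == {}

    def test_unknown_dialect(self, tmp_path):
        fp = tmp_path / "t.tsv"
        fp.write_text("m1\tg1\n")
        with pytest.raises(ConfigurationError):
            parse_targets(fp, "pita")

    def test_miranda_skips_comments(self, tmp_path):
        fp = tmp_path / "t.tsv"
        fp.write_text("# header\nm1\tg1\n")
        assert parse_targets(fp, "miranda").targets == {"m1": frozenset({"g1"})}

    def test_targetscan_header_columns(self, tmp_path):
        fp = tmp_path / "t.tsv"
        fp.write_text("miR Family\tGene Symbol\tSite\nmiR-1\tGENE1\tx\n")
        assert parse_targets(fp, "targetscan").targets == {
            "mir-1": frozenset({"GENE1"})
        }

    def test_writer_reader_round_trip(self, tmp_path, small_cfg):
        truth = gen_ground_truth(small_cfg)
        a, _ = gen_target_predictions(truth, small_cfg)
        fp = tmp_path / "a.tsv"
        write_targets_tsv(a, fp)
        back = parse_targets(fp)
        assert back.targets == a.targets


class TestIntersectTargets:
    def _map(self, d):
        return TargetMap(source="x", targets=d)

    def test_disjoint_gene_sets_drop_mirna(self):
        out = intersect_targets(self._map({"m": {"g1"}}), self._map({"m": {"g2"}}))
        assert "m" not in out.targets

    def test_identity(self):
        a = self._map({"m": {"g1", "g2"}})
        assert intersect_targets(a, a).targets == a.targets

    def test_commutative_associative_idempotent(self):
        a = self._map({"m": {"g1", "g2"}, "n": {"g3"}})
        b = self._map({"m": {"g2", "g4"}, "o": {"g5"}})
        c = self._map({"m": {"g2"}, "n": {"g3"}})
        ab = intersect_targets(a, b)
        ba = intersect_targets(b, a)
        assert ab.targets == ba.targets
        assert (
            intersect_targets(ab, c).targets
            == intersect_targets(a, intersect_targets(b, c)).targets
        )
        assert intersect_targets(a, a).targets == a.targets

    def test_synthetic_intersection_keeps_truth_prunes_decoys(self, small_cfg):
        truth = gen_ground_truth(small_cfg)
        a, b = gen_target_predictions(truth, small_cfg)
        inter = intersect_targets(a, b)
        assert truth.true_pairs <= inter.pairs()
        decoys_a = len(a.pairs() - truth.true_pairs)
        decoys_inter = len(inter.pairs() - truth.true_pairs)
        assert decoys_inter < decoys_a


class TestCategoryTargets:
    def test_single_member(self):
        cat = Category("D6", frozenset({"m1"}))
        tmap = TargetMap("x", {"m1": {"g1", "g2"}})
        assert category_targets(cat, tmap) == {"g1", "g2"}

    def test_empty_category(self):
        assert category_targets(Category("D6", frozenset()), TargetMap("x", {})) == set()

    def test_missing_member_reported_and_skipped(self):
        cat = Category("D6", frozenset({"m1", "ghost"}))
        tmap = TargetMap("x", {"m1": {"g1"}})
        with pytest.warns(UserWarning, match="ghost"):
            genes = category_targets(cat, tmap)
        assert genes == {"g1"}


class TestHypergeomEnrichment:
    def _ann(self, terms, universe):
        return AnnotationMap(
            terms={t: (t, frozenset(g)) for t, g in terms.items()},
            universe=frozenset(universe),
        )

    def test_term_equal_to_universe_gives_p_one(self):
        uni = {f"g{i}" for i in range(10)}
        ann = self._ann({"T": uni}, uni)
        (res,) = hypergeom_enrichment(set(list(uni)[:4]), ann)
        assert res.p == pytest.approx(1.0)

    def test_exact_worked_example(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        uni = [f"g{i}" for i in range(10)]
        ann = self._ann({"T": uni[:5]}, uni)
        (res,) = hypergeom_enrichment(set(uni[:4]), ann)
        assert res.p == pytest.approx(5 / 210, abs=1e-12)

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 4), (12, 6, 5)])
    def test_matches_exhaustive_enumeration(self, N, K, n):
        uni = [f"g{i}" for i in range(N)]
        ann = self._ann({"T": uni[:K]}, uni)
        for k in range(1, min(K, n) + 1):
            query = set(uni[:k]) | set(uni[K : K + (n - k)])
            (res,) = hypergeom_enrichment(query, ann)
            assert res.p == pytest.approx(
                hypergeom_brute_force(N, K, n, k), abs=1e-9
            )

    def test_empty_universe_rejected(self):
        ann = AnnotationMap(terms={}, universe=frozenset())
        with pytest.raises(InputError):
            hypergeom_enrichment({"g1"}, ann)

    def test_query_outside_universe_reported_and_dropped(self):
        uni = [f"g{i}" for i in range(10)]
        ann = self._ann({"T": uni[:5]}, uni)
        with pytest.warns(UserWarning, match="outside"):
            (res,) = hypergeom_enrichment(set(uni[:3]) | {"alien"}, ann)
        assert res.overlap == 3

    def test_planted_terms_rank_first(self, small_cfg):
        from mirtime.synthetic import gen_annotation

        truth = gen_ground_truth(small_cfg)
        ann = gen_annotation(small_cfg, truth)
        query = {g for _, g in truth.true_pairs}
        results = hypergeom_enrichment(query, ann)
        top = {r.term for r in results[: len(truth.enriched_terms)]}
        assert top == truth.enriched_terms


class TestGoSubnetwork:
    def test_edges(self):
        cat = Category("D6", frozenset({"m1", "m2", "m3"}))
        tmap = TargetMap("x", {"m1": {"g1"}, "m2": {"g1", "g2"}, "m3": {"g9"}})
        uni = {"g1", "g2", "g9"}
        ann = AnnotationMap(
            terms={"T": ("t", frozenset({"g1", "g2"}))}, universe=frozenset(uni)
        )
        results = hypergeom_enrichment({"g1", "g2"}, ann)
        edges = go_subnetwork("T", results, cat, tmap)
        assert edges == [("m1", "g1"), ("m2", "g1"), ("m2", "g2")]

    def test_untested_term_rejected(self):
        cat = Category("D6", frozenset())
        tmap = TargetMap("x", {})
        with pytest.raises(InputError):
            go_subnetwork("missing", [], cat, tmap)


class TestGmtIo:
    def test_round_trip(self, tmp_path, small_cfg):
        from mirtime.synthetic import gen_annotation

        truth = gen_ground_truth(small_cfg)
        ann = gen_annotation(small_cfg, truth)
        fp = tmp_path / "a.gmt"
        write_gmt(ann, fp)
        back = read_gmt(fp, universe=ann.universe)
        assert back.terms == ann.terms

    def test_malformed_line_rejected(self, tmp_path):
        fp = tmp_path / "bad.gmt"
        fp.write_text("TERM1\tdesc\n")
        with pytest.raises(ParseError):
            read_gmt(fp)
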