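"""RPKM arithmetic, operon collapse, top-K intersection and chaperone pull."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from promine.expression import (
    CandidateSet,
    ExpressionProfile,
    Operon,
    collapse_operons,
    compute_rpkm,
    expressed_genes,
    infer_operons,
    operons_from_annotation,
    read_counts_tsv,
    select_chaperones,
    select_top_n_by_mean,
    select_top_shared,
    write_counts_tsv,
)
from promine.genome_io import Gene


def _gene(gid, length, product="hypothetical protein", start=0):
    return Gene(gid, "chr", start, start + length, "+", product=product)


class TestRpkm:
    @pytest.mark.parametrize(
        "count, length, library, expected",
        [
            (10, 1000, 10**6, 10.0),
            (0, 1000, 10**6, 0.0),
            (50, 2500, 2 * 10**7, 1.0),  # 50*1e9/(2500*2e7)
        ],
    )
    def test_hand_arithmetic(self, count, length, library, expected):
        profile = ExpressionProfile("s", {"g": count}, library)
        assert compute_rpkm(profile, [_gene("g", length)]) == {"g": expected}

    def test_unannotated_gene_is_hard_error(self):
        profile = ExpressionProfile("s", {"ghost": 5}, 1000)
        with pytest.raises(ValueError, match="ghost"):
            compute_rpkm(profile, [_gene("g", 1000)])

    def test_uncounted_gene_gets_zero(self):
        profile = ExpressionProfile("s", {"g": 3}, 1000)
        rpkm = compute_rpkm(profile, [_gene("g", 500), _gene("h", 500, start=600)])
        assert rpkm["h"] == 0.0

    @given(
        count=st.integers(1, 10**6),
        length=st.integers(100, 10**4),
        library=st.integers(10**3, 10**8),
        factor=st.integers(2, 50),
    )
    @settings(max_examples=50, derandomize=True)
    def test_invariant_under_joint_scaling(self, count, length, library, factor):
        gene = [_gene("g", length)]
        a = compute_rpkm(ExpressionProfile("s", {"g": count}, library), gene)["g"]
        b = compute_rpkm(
            ExpressionProfile("s", {"g": count * factor}, library * factor), gene
        )["g"]
        assert b == pytest.approx(a, rel=1e-12)


class TestCollapse:
    def test_three_gene_enumeration(self):
        operons = [
            Operon("o1", ("g1", "g2"), "+"),
            Operon("o2", ("g4", "g5"), "+"),
        ]
        expressed = ["g1", "g2", "g3", "g4", "g5"]
        assert collapse_operons(expressed, operons) == ["g1", "g3", "g4"]

    def test_no_operons_is_identity(self):
        assert collapse_operons(["b", "a"], []) == ["a", "b"]

    def test_minus_strand_operon_keeps_transcription_first(self):
        genes = [
            Gene("left", "chr", 0, 300, "-", operon="op"),
            Gene("right", "chr", 320, 600, "-", operon="op"),
        ]
        (operon,) = operons_from_annotation(genes)
        assert operon.member_gene_ids == ("right", "left")
        assert collapse_operons(["left", "right"], [operon]) == ["right"]

    def test_double_assignment_is_hard_error(self):
        operons = [Operon("o1", ("g1", "g2"), "+"), Operon("o2", ("g2", "g3"), "+")]
        with pytest.raises(ValueError, match="g2"):
            collapse_operons(["g1", "g2", "g3"], operons)

    def test_unexpressed_member_warns(self):
        operons = [Operon("o1", ("g1", "g2"), "+")]
        with pytest.warns(UserWarning, match="not in the expressed set"):
            collapse_operons(["g1"], operons)

    def test_conservation_on_random_structures(self):
        """|collapsed| == |expressed| - |operon members| + |operons|."""
        rng = random.Random(4242)
        for _ in range(100):
            n = rng.randint(10, 400)
            ids = [f"g{i}" for i in range(n)]
            rng.shuffle(ids)
            operons, cursor, k = [], 0, 0
            while cursor + 2 <= n and rng.random() < 0.8:
                size = rng.randint(2, min(6, n - cursor))
                k += 1
                operons.append(
                    Operon(f"o{k}", tuple(ids[cursor : cursor + size]), "+")
                )
                cursor += size
            members = sum(len(o.member_gene_ids) for o in operons)
            result = collapse_operons(ids, operons)
            assert len(result) == n - members + len(operons)


class TestTopSelection:
    def test_identical_rankings(self):
        rpkm = {f"g{i}": float(100 - i) for i in range(10)}
        assert len(select_top_shared(rpkm, dict(rpkm), 5)) == 5

    def test_reversed_rankings_are_disjoint(self):
        a = {f"g{i}": float(i) for i in range(10)}
        b = {f"g{i}": float(10 - i) for i in range(10)}
        assert select_top_shared(a, b, 5) == []

    def test_matches_brute_force_on_random_permutations(self):
        rng = random.Random(7)
        genes = [f"g{i:03d}" for i in range(200)]
        for _ in range(10):
            a = {g: float(v) for g, v in zip(genes, rng.sample(range(1000), 200))}
            b = {g: float(v) for g, v in zip(genes, rng.sample(range(1000), 200))}
            top = lambda r: {g for g in r if sum(x > r[g] for x in r.values()) < 100}
            expected = sorted(top(a) & top(b))
            assert select_top_shared(a, b, 100) == expected

    def test_symmetric_and_monotone_in_k(self):
        rng = random.Random(11)
        genes = [f"g{i}" for i in range(60)]
        a = {g: rng.random() for g in genes}
        b = {g: rng.random() for g in genes}
        assert select_top_shared(a, b, 20) == select_top_shared(b, a, 20)
        prev: set = set()
        for k in (5, 10, 30, 60):
            cur = set(select_top_shared(a, b, k))
            assert prev <= cur
            prev = cur

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            select_top_shared({"g": 1.0}, {"g": 1.0}, 0)

    def test_top_n_by_mean_sort_and_ties(self):
        a = {"x": 40.0, "y": 20.0, "z": 10.0, "w": 20.0}
        b = {"x": 20.0, "y": 20.0, "z": 10.0, "w": 20.0}
        top = select_top_n_by_mean(["x", "y", "z", "w"], a, b, 3)
        assert top.gene_ids == ("x", "w", "y")  # tie 20.0 broken w < y
        assert top.mean_rpkm["x"] == 30.0
        full = select_top_n_by_mean(["x", "y", "z", "w"], a, b, 4)
        assert full.gene_ids == ("x", "w", "y", "z")
        with pytest.raises(ValueError):
            select_top_n_by_mean(["x"], a, b, 2)


class TestChaperones:
    def test_keyword_match_is_case_insensitive_substring(self):
        genes = [
            _gene("g1", 300, "Molecular chaperone DnaK"),
            _gene("g2", 300, "Ferritin", start=400),
        ]
        assert select_chaperones(genes).gene_ids == ("g1",)

    def test_six_annotated_chaperones_found(self):
        products = [
            "Molecular chaperone GroEL",
            "Molecular chaperone GroEL",
            "Molecular chaperone DnaJ",
            "Molecular chaperone DnaJ",
            "Co-chaperone GroES",
            "Molecular chaperone DnaK",
            "Elongation factor Tu",
            "50S ribosomal protein L21",
        ]
        genes = [_gene(f"g{i}", 300, p, start=400 * i) for i, p in enumerate(products)]
        assert len(select_chaperones(genes)) == 6

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning, match="no chaperone"):
            result = select_chaperones([_gene("g", 300, "Ferritin")])
        assert len(result) == 0


class TestOperonInference:
    def test_gap_heuristic_runs(self):
        genes = [
            Gene("a", "chr", 0, 300, "+"),
            Gene("b", "chr", 330, 600, "+"),    # gap 30 -> same operon
            Gene("c", "chr", 700, 900, "+"),    # gap 100 -> breaks
            Gene("d", "chr", 920, 1100, "-"),   # strand switch -> breaks
            Gene("e", "chr", 1110, 1300, "-"),  # gap 10 -> joins d
        ]
        operons = infer_operons(genes, max_gap=50)
        assert [o.member_gene_ids for o in operons] == [("a", "b"), ("e", "d")]

    def test_operon_type_invariants(self):
        with pytest.raises(ValueError):
            Operon("o", ("g1",), "+")
        with pytest.raises(ValueError):
            Operon("o", ("g1", "g1"), "+")
        with pytest.raises(ValueError):
            CandidateSet(("g1", "g1"), "top_expression")


def test_counts_tsv_round_trip(tmp_path):
    profile = ExpressionProfile("s1", {"g1": 5, "g2": 0, "g3": 123456}, 999_999)
    path = tmp_path / "counts.tsv"
    write_counts_tsv(profile, path)
    back = read_counts_tsv(path, "s1")
    assert back == profile


def test_expressed_genes_intersects_conditions():
    a = {"g1": 5.0, "g2": 0.0, "g3": 2.0}
    b = {"g1": 1.0, "g2": 3.0, "g3": 0.0}
    assert expressed_genes([a, b]) == {"g1"}
    assert expressed_genes([a, b], threshold=2.0) == set()
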