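"""Protein alignment, BBH ortholog tables, synteny-run decomposition."""

import numpy as np
import pytest

from rgpscan.errors import InputError
from rgpscan.orthology import (
    OrthologTable,
    align_protein_pair,
    backbone_run_ids,
    build_ortholog_table,
    find_synteny_runs,
    syntenic_gene_ids,
)
from rgpscan.params import ParameterSet
from rgpscan.simulate import divergent_protein_pair

from oracles import maximal_colinear_chains, sw_align
from toys import make_genome, make_table, protein


def test_identical_proteins_align_at_full_identity():
    p = protein(np.random.default_rng(0), 100)
    identity, coverage = align_protein_pair(p, p)
    assert identity == 100.0
    assert coverage == 1.0


def test_empty_protein_is_an_input_error():
    with pytest.raises(InputError):
        align_protein_pair("MAAA", "")


def test_unrelated_random_pair_rejected_at_default_thresholds():
    rng = np.random.default_rng(5)
    params = ParameterSet()
    identity, coverage = align_protein_pair(protein(rng, 100), protein(rng, 100))
    assert not (identity >= params.min_identity and coverage >= params.min_coverage)


def test_alignment_agrees_with_dynamic_programming_oracle():
    """Scores match the brute-force Gotoh oracle exactly; identity and
    coverage agree up to co-optimal traceback ambiguity."""
    rng = np.random.default_rng(42)
    for k in range(30):
        length = int(rng.integers(60, 160))
        if k % 3 == 0:
            a, b = divergent_protein_pair(rng, length, float(rng.uniform(25, 90)))
        elif k % 3 == 1:
            a, b = protein(rng, length), protein(rng, int(rng.integers(60, 160)))
        else:
            a = protein(rng, length)
            b = a
        score_oracle, id_oracle, cov_oracle = sw_align(a, b)
        from rgpscan.orthology import _aligner

        assert _aligner().score(a, b) == pytest.approx(score_oracle)
        if score_oracle > 0:
            identity, coverage = align_protein_pair(a, b)
            assert identity == pytest.approx(id_oracle, abs=2.0)
            assert coverage == pytest.approx(cov_oracle, abs=0.05)


def test_realized_identity_near_threshold_decides_admission():
    """Pairs generated just above / below 30% identity are accepted /
    rejected, consistently with their realized identity and coverage."""
    rng = np.random.default_rng(7)
    params = ParameterSet()
    for target, expected in [(31.0, True), (29.0, False)]:
        for length in (120, 200, 280):
            a, b = divergent_protein_pair(rng, length, target)
            identity, coverage = align_protein_pair(a, b)
            admitted = identity >= params.min_identity and coverage >= params.min_coverage
            assert admitted == expected, (target, length, identity, coverage)
            ga = make_genome("A", proteins=[a])
            gb = make_genome("B", proteins=[b])
            table = build_ortholog_table(ga, gb, params)
            assert bool(table.pairs) == expected


@pytest.fixture(scope="module")
def shared_proteomes():
    rng = np.random.default_rng(11)
    shared = [protein(rng, int(rng.integers(90, 200))) for _ in range(30)]
    mut = []
    for p in shared:
        body = list(p)
        for i in rng.choice(len(p) - 1, size=max(1, len(p) // 10), replace=False):
            body[i + 1] = "A" if body[i + 1] != "A" else "C"
        mut.append("".join(body))
    unique_a = [protein(rng, 120) for _ in range(10)]
    unique_b = [protein(rng, 120) for _ in range(10)]
    ga = make_genome("A", proteins=shared + unique_a)
    gb = make_genome("B", proteins=mut + unique_b)
    return ga, gb


def test_bbh_count_matches_planted_sharing(shared_proteomes):
    ga, gb = shared_proteomes
    table = build_ortholog_table(ga, gb)
    assert len(table.bbh_pairs) == 30
    assert all(p.identity > 80 for p in table.bbh_pairs)


def test_bbh_symmetry_under_role_swap(shared_proteomes):
    ga, gb = shared_proteomes
    ab = build_ortholog_table(ga, gb)
    ba = build_ortholog_table(gb, ga)
    fwd = {(p.gene_a, p.gene_b) for p in ab.bbh_pairs}
    rev = {(p.gene_b, p.gene_a) for p in ba.bbh_pairs}
    assert fwd == rev


def test_raising_thresholds_never_adds_pairs(shared_proteomes):
    ga, gb = shared_proteomes
    loose = build_ortholog_table(ga, gb, ParameterSet(min_identity=20))
    tight = build_ortholog_table(ga, gb, ParameterSet(min_identity=60))
    loose_pairs = {(p.gene_a, p.gene_b) for p in loose.pairs}
    tight_pairs = {(p.gene_a, p.gene_b) for p in tight.pairs}
    assert tight_pairs <= loose_pairs


def test_self_comparison_gives_identity_self_pairs():
    ga = make_genome("A", n_genes=8, seed=3)
    gb = make_genome("B", proteins=[g.protein for g in ga.genes], seed=3)
    table = build_ortholog_table(ga, gb)
    assert len(table.bbh_pairs) == 8
    for p in table.bbh_pairs:
        assert p.rank_a == p.rank_b
        assert p.identity == 100.0


@pytest.mark.parametrize(
    "links,max_gap,expected_chains",
    [
        # identical gene order -> one run covering all genes
        ([(i, i) for i in range(10)], 2, [10]),
        # one inserted (non-orthologous) reference gene mid-run
        ([(i, i) for i in range(5)] + [(i + 1, i) for i in range(5, 9)], 2, [9]),
        ([(i, i) for i in range(5)] + [(i + 2, i) for i in range(5, 9)], 0, [5, 4]),
        # whole-run inversion is a single run
        ([(i, 9 - i) for i in range(10)], 2, [10]),
        # fully shuffled order -> singleton runs
        ([(0, 3), (1, 7), (2, 1), (3, 5), (4, 0)], 0, [1, 1, 1, 1, 1]),
    ],
)
def test_synteny_runs_on_hand_enumerated_toys(links, max_gap, expected_chains):
    table = make_table("A", "B", links)
    runs = find_synteny_runs(table, ParameterSet(max_gap=max_gap))
    assert [r.n_pairs for r in runs] == expected_chains


def test_run_decomposition_matches_exhaustive_oracle():
    """Random <=50-gene toy tables decompose exactly as the brute-force
    maximal colinear chain search."""
    rng = np.random.default_rng(23)
    for trial in range(25):
        n = int(rng.integers(5, 50))
        ranks_b = rng.permutation(n)
        # partially shuffle: keep stretches colinear
        for _ in range(int(rng.integers(0, 6))):
            i, j = sorted(rng.integers(0, n, 2))
            ranks_b[i:j] = sorted(ranks_b[i:j])
        keep = rng.random(n) < 0.8
        links = [(i, int(ranks_b[i])) for i in range(n) if keep[i]]
        if not links:
            continue
        max_gap = int(rng.integers(0, 4))
        table = make_table("A", "B", links)
        runs = find_synteny_runs(table, ParameterSet(max_gap=max_gap))
        got = [[(p.rank_a, p.rank_b) for p in r.pairs] for r in runs]
        expected = maximal_colinear_chains(links, max_gap)
        assert got == expected, (trial, links, max_gap)


def test_backbone_excludes_displaced_run():
    # genes 10..14 of A sit at ranks 40..44 of B: off the colinear backbone
    links = [(i, i) for i in range(10)] + [(10 + k, 40 + k) for k in range(5)] + [
        (15 + i, 15 + i) for i in range(10)
    ]
    table = make_table("A", "B", links)
    runs = find_synteny_runs(table, ParameterSet(max_gap=1))
    backbone = backbone_run_ids(runs)
    displaced = [r for r in runs if r.run_id not in backbone]
    assert len(displaced) == 1
    assert [p.rank_a for p in displaced[0].pairs] == [10, 11, 12, 13, 14]
    in_place = syntenic_gene_ids(runs, backbone_only=True)
    assert "A_g010" not in in_place and "A_g000" in in_place
    anywhere = syntenic_gene_ids(runs, backbone_only=False)
    assert "A_g010" in anywhere
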