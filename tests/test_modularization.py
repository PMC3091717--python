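"""Module splitting, presence tiers, functional classes, distribution
groups, and deletion-boundary matching."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rgpscan.detection import RGP
from rgpscan.modularization import (
    Module,
    assign_distribution_group,
    assign_functional_class,
    match_deletion_to_modules,
    presence_call,
    split_into_modules,
)
from rgpscan.params import DEFAULT_GROUP_SCHEME, GroupScheme, ParameterSet

from toys import make_genome


def _rgp_over(genome, rb, re_):
    genes = genome.genes[rb : re_ + 1]
    return RGP(
        rgp_id=7,
        replicon_id=genome.replicons[0].replicon_id,
        begin=genes[0].begin,
        end=genes[-1].end,
        genes=[g.feature_id for g in genes],
        rank_begin=rb,
        rank_end=re_,
    )


def test_state_change_enumeration_sscc_ss():
    """Conservation states S S C C S S cut into modules of sizes 2, 2, 2."""
    genome = make_genome("A", n_genes=6)
    rgp = _rgp_over(genome, 0, 5)
    conserved = frozenset({("B", "B:r1")})
    states = {"A_g002": conserved, "A_g003": conserved}
    modules = split_into_modules(rgp, genome, states)
    assert [m.n_genes for m in modules] == [2, 2, 2]
    assert [m.module_id for m in modules] == ["7_a", "7_b", "7_c"]
    assert [m.conserved for m in modules] == [False, True, False]


def test_strain_specific_rgp_is_single_module():
    genome = make_genome("A", n_genes=5)
    rgp = _rgp_over(genome, 0, 4)
    assert len(split_into_modules(rgp, genome, {})) == 1


def test_adjacent_conserved_blocks_with_different_partner_runs_split():
    genome = make_genome("A", n_genes=4)
    rgp = _rgp_over(genome, 0, 3)
    states = {
        "A_g000": frozenset({("B", "B:r1")}),
        "A_g001": frozenset({("B", "B:r1")}),
        "A_g002": frozenset({("B", "B:r2")}),
        "A_g003": frozenset({("B", "B:r2")}),
    }
    modules = split_into_modules(rgp, genome, states)
    assert [m.n_genes for m in modules] == [2, 2]


def test_non_coding_genes_inherit_neighbour_state():
    genome = make_genome("A", n_genes=5, kinds=["tRNA", "CDS", "CDS", "tRNA", "CDS"])
    rgp = _rgp_over(genome, 0, 4)
    s = frozenset({("B", "B:r1")})
    states = {"A_g001": s, "A_g002": s, "A_g004": s}
    modules = split_into_modules(rgp, genome, states)
    assert len(modules) == 1  # tRNAs never cut a block on their own


def test_modules_partition_every_rgp(default_run):
    result = default_run["result"]
    for gid, rgps in result.rgps.items():
        mods_by_rgp = {}
        for m in result.modules[gid]:
            mods_by_rgp.setdefault(m.rgp_id, []).append(m)
        for rgp in rgps:
            concat = list(
                itertools.chain.from_iterable(
                    m.genes for m in mods_by_rgp.get(rgp.rgp_id, [])
                )
            )
            assert concat == rgp.genes


@pytest.mark.parametrize(
    "hits,total,expected",
    [
        (16, 16, "present"),
        (13, 16, "present"),  # f = 0.8125 > 0.80
        (4, 5, "partial"),  # f = 0.80 exactly: NOT "more than 80%"
        (5, 16, "partial"),  # f = 0.3125
        (4, 16, "absent"),  # f = 0.25 exactly: NOT "more than 25%"
        (5, 19, "partial"),  # f just above 0.25
        (0, 7, "absent"),
    ],
)
def test_presence_tiers_use_strict_inequalities(hits, total, expected):
    assert presence_call(hits, total) == expected


@given(st.integers(1, 40), st.integers(0, 40))
def test_presence_is_monotone_in_hits(total, hits):
    hits = min(hits, total)
    order = {"absent": 0, "partial": 1, "present": 2}
    if hits > 0:
        assert (
            order[presence_call(hits, total)]
            >= order[presence_call(hits - 1, total)]
        )


def _mods(products):
    genome = make_genome("A", n_genes=len(products), products=products)
    return list(genome.genes)


def test_functional_class_unanimous_phage():
    genes = _mods(["phage tail protein", "major capsid protein"])
    assert assign_functional_class(genes) == "phage"


def test_functional_class_plurality_wins():
    genes = _mods(
        [
            "sugar ABC transporter permease",
            "aldehyde dehydrogenase",
            "glycosyl transferase",
            "putative transposase",
        ]
    )
    assert assign_functional_class(genes) == "metabolism"


def test_functional_class_tie_breaks_by_priority():
    genes = _mods(["putative transposase", "aldehyde dehydrogenase"])
    # 1 recombination vote vs 1 metabolism vote: recombination has priority
    assert assign_functional_class(genes) == "recombination"


def test_functional_class_unknown_when_uninformative():
    genes = _mods(["hypothetical protein", "hypothetical protein"])
    assert assign_functional_class(genes) == "unknown"


GROUP_MAP = {
    "SELF": "same_genus",
    "B": "same_genus",
    "C": "other_genus",
    "D": "pathogen",
    "E": "commensal",
}


def _expected_group(presence):
    """Hand-written precedence oracle over the published five classes."""
    seen = {g for g, s in presence.items() if g != "SELF" and s in ("present", "partial")}
    if "E" in seen:
        return "family"
    if "D" in seen:
        return "pathogens"
    if "C" in seen:
        return "cross_genus"
    if "B" in seen:
        return "genus"
    return "strain"


def test_distribution_group_against_enumerated_oracle():
    """All 3^4 presence patterns reproduce the precedence-table oracle."""
    for pattern in itertools.product(["present", "partial", "absent"], repeat=4):
        presence = dict(zip(["B", "C", "D", "E"], pattern))
        presence["SELF"] = "present"
        got = assign_distribution_group(presence, "SELF", GROUP_MAP)
        assert got == _expected_group(presence), presence


def test_partial_presence_can_be_excluded_by_scheme():
    presence = {"SELF": "present", "B": "partial", "C": "absent", "D": "absent",
                "E": "absent"}
    strict = GroupScheme(count_partial=False)
    assert assign_distribution_group(presence, "SELF", GROUP_MAP, strict) == "strain"
    assert assign_distribution_group(presence, "SELF", GROUP_MAP) == "genus"


def _module(mid, rgp_id, begin, end):
    return Module(
        module_id=mid,
        rgp_id=rgp_id,
        replicon_id="chr",
        begin=begin,
        end=end,
        genes=[f"g{begin}"],
    )


def test_deletion_matching_whole_sub_and_none():
    modules = [
        _module("1_a", 1, 1000, 5000),
        _module("1_b", 1, 5000, 11000),
        _module("1_c", 1, 11000, 14000),
        _module("2_a", 2, 30000, 40000),
    ]
    dels = [
        ("chr", 1000, 11000),  # modules a+b exactly
        ("chr", 1050, 10950),  # within the 200 bp tolerance
        ("chr", 5000, 8000),  # ends mid-module
        ("chr", 20000, 25000),  # outside every module
        ("chr", 12000, 31000),  # spans two different RGPs
    ]
    matches = match_deletion_to_modules(dels, modules)
    assert [m.match_type for m in matches] == [
        "whole-module",
        "whole-module",
        "sub-module",
        "none",
        "sub-module",
    ]
    assert matches[0].matched_modules == ["1_a", "1_b"]
    assert (matches[1].left_offset, matches[1].right_offset) == (50, -50)


def test_deletion_tolerance_is_configurable():
    modules = [_module("1_a", 1, 1000, 6000)]
    dels = [("chr", 1300, 6000)]
    assert match_deletion_to_modules(dels, modules)[0].match_type == "sub-module"
    assert (
        match_deletion_to_modules(dels, modules, tolerance_bp=400)[0].match_type
        == "whole-module"
    )
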