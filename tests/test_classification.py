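"""Mobility-gene detection, prophage calls, and the class decision tree."""

import pytest

from rgpscan.classification import (
    EvidenceBundle,
    classify_rgp,
    detect_mobility_genes,
    detect_prophage,
)
from rgpscan.detection import RGP
from rgpscan.params import ParameterSet

from toys import make_genome


def _genes(products):
    genome = make_genome("A", n_genes=len(products), products=products)
    return list(genome.genes)


@pytest.mark.parametrize(
    "product,category",
    [
        ("putative transposase", "transposase/IS"),
        ("serine resolvase", "resolvase"),
        ("DNA invertase", "invertase"),
        ("phage excisionase", "excisionase"),
        ("site-specific recombinase", "other recombinase"),
    ],
)
def test_mobility_lexicon_categories(product, category):
    mob, integrase = detect_mobility_genes(_genes([product]))
    assert [c for _, c in mob] == [category]
    assert not integrase


def test_integrase_reported_separately_from_mob_genes():
    mob, integrase = detect_mobility_genes(_genes(["tyrosine integrase"]))
    assert mob == []
    assert integrase


def test_hypothetical_products_give_no_hits():
    mob, integrase = detect_mobility_genes(_genes(["hypothetical protein"] * 5))
    assert mob == [] and not integrase


def test_mobility_count_matches_hand_enumeration():
    products = ["hypothetical protein"] * 8 + ["serine resolvase", "DNA invertase"]
    mob, _ = detect_mobility_genes(_genes(products))
    assert len(mob) == 2


def _rgp(genome, rank_begin, rank_end):
    genes = genome.genes[rank_begin : rank_end + 1]
    return RGP(
        rgp_id=0,
        replicon_id=genome.replicons[0].replicon_id,
        begin=genes[0].begin,
        end=genes[-1].end,
        genes=[g.feature_id for g in genes],
        rank_begin=rank_begin,
        rank_end=rank_end,
    )


def test_prophage_heuristic_on_synthetic_cassette():
    products = [
        "phage terminase large subunit",
        "major capsid protein",
        "phage portal protein",
        "phage tail fiber protein",
        "phage holin",
        "hypothetical protein",
        "hypothetical protein",
        "hypothetical protein",
    ]
    genome = make_genome("A", n_genes=len(products), products=products)
    rgp = _rgp(genome, 0, len(products) - 1)
    is_phage, count, structural, external = detect_prophage(rgp, list(genome.genes))
    assert is_phage and structural and not external
    assert count == 5


def test_no_phage_keywords_means_no_prophage():
    genome = make_genome("A", n_genes=6, products=["hypothetical protein"] * 6)
    rgp = _rgp(genome, 0, 5)
    is_phage, count, *_ = detect_prophage(rgp, list(genome.genes))
    assert not is_phage and count == 0


def test_external_prophage_call_overrides_heuristic():
    genome = make_genome("A", n_genes=6, products=["hypothetical protein"] * 6)
    rgp = _rgp(genome, 0, 5)
    span = rgp.end - rgp.begin
    full = [(rgp.replicon_id, rgp.begin, rgp.end)]
    is_phage, _, _, external = detect_prophage(rgp, list(genome.genes),
                                               external_calls=full)
    assert is_phage and external
    # an external call covering under half of the RGP does not override
    small = [(rgp.replicon_id, rgp.begin, rgp.begin + span // 4)]
    is_phage, _, _, external = detect_prophage(rgp, list(genome.genes),
                                               external_calls=small)
    assert not is_phage and not external


PHAGE_EV = dict(phage_gene_count=6, phage_structural_present=True)


@pytest.mark.parametrize(
    "evidence,expected",
    [
        # prophage wins over every other hallmark (precedence)
        (dict(**PHAGE_EV, trna_adjacent=True, integrase_present=True), "prophage"),
        (dict(external_prophage_overlap=True, gc_deviant=True), "prophage"),
        # each GI hallmark alone suffices
        (dict(trna_adjacent=True), "GI"),
        (dict(integrase_present=True), "GI"),
        (dict(gc_deviant=True), "GI"),
        (dict(atypical_composition=True), "GI"),
        # GI outranks mobility genes
        (dict(trna_adjacent=True, mob_genes=[("g", "resolvase")]), "GI"),
        # mobility genes alone -> RGP_mob
        (dict(mob_genes=[("g", "transposase/IS")]), "RGP_mob"),
        # phage genes below threshold do not make a prophage
        (dict(phage_gene_count=4, phage_structural_present=True), "RGP_none"),
        (dict(phage_gene_count=6, phage_structural_present=False), "RGP_none"),
        (dict(), "RGP_none"),
    ],
)
def test_decision_tree(evidence, expected):
    assert classify_rgp(EvidenceBundle(**evidence)) == expected


def test_every_bundle_gets_exactly_one_class_deterministically():
    bundles = [
        EvidenceBundle(),
        EvidenceBundle(trna_adjacent=True),
        EvidenceBundle(mob_genes=[("g", "resolvase")]),
        EvidenceBundle(**PHAGE_EV),
    ]
    classes = {"prophage", "GI", "RGP_mob", "RGP_none"}
    for b in bundles:
        first = classify_rgp(b)
        assert first in classes
        assert classify_rgp(b) == first
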