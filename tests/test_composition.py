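"""GC profiles, deviation flags, CAI, atypical-composition z-scores."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rgpscan.composition import (
    CompositionProfile,
    atypical_composition_score,
    codon_adaptation_index,
    composition_profile,
    count_codon_usage,
    gc_deviation_flag,
    reference_weights,
    SYNONYMOUS,
)
from rgpscan.errors import InputError, ParameterError
from rgpscan.genome_io import Replicon


def test_all_g_sequence_profile():
    p = composition_profile(Replicon("t", "G" * 6000, "circular"), 1000, 500)
    assert np.allclose(p.gc_percent, 100.0)
    assert np.allclose(p.gc_skew, 1.0)


def test_alternating_gc_has_zero_skew():
    p = composition_profile(Replicon("t", "GC" * 3000, "circular"), 1000, 500)
    assert np.allclose(p.gc_percent, 100.0)
    assert np.allclose(p.gc_skew, 0.0)


def test_random_windows_match_binomial_sampling():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 100_000))
    p = composition_profile(Replicon("t", seq, "circular"), 1000, 1000)
    se = 100 * math.sqrt(0.25 / 1000)
    assert abs(p.gc_percent.mean() - 50.0) < 3 * se


def test_gc_and_at_sum_to_hundred_with_n_excluded():
    seq = "ACGTN" * 1000
    p = composition_profile(Replicon("t", seq, "circular"), 1000, 500)
    assert np.allclose(p.gc_percent, 50.0)  # N bases excluded from counts


def test_skew_flips_sign_under_reverse_complement():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), 4000, p=[0.2, 0.2, 0.35, 0.25]))
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    p = composition_profile(Replicon("t", seq, "linear"), 4000, 4000)
    q = composition_profile(Replicon("t", rc, "linear"), 4000, 4000)
    assert p.gc_skew[0] == pytest.approx(-q.gc_skew[0])
    assert p.gc_percent[0] == pytest.approx(q.gc_percent[0])


def test_window_larger_than_replicon_rejected():
    with pytest.raises(ParameterError):
        composition_profile(Replicon("t", "ACGT" * 10, "circular"), 1000, 10)


def _fixed_profile(mean: float, sd: float) -> CompositionProfile:
    return CompositionProfile(
        replicon_id="t",
        window=100,
        step=100,
        starts=np.array([0]),
        gc_percent=np.array([mean]),
        gc_skew=np.array([0.0]),
        mean_gc=mean,
        sd_gc=sd,
    )


@pytest.mark.parametrize(
    "region_gc,flagged",
    [(50, False), (60.0, False), (61.0, True), (39.0, True), (40.0, False)],
)
def test_gc_deviation_uses_strict_two_sd_inequality(region_gc, flagged):
    """Deviation exactly at 2.0 SD does not flag (strict inequality)."""
    n_gc = int(region_gc)
    seq = "G" * n_gc + "A" * (100 - n_gc)
    rep = Replicon("t", seq, "linear")
    assert gc_deviation_flag(0, 100, rep, _fixed_profile(50.0, 5.0)) is flagged


def test_cai_closed_form_three_codons():
    w = {"GCT": 1.0, "GCA": 0.5, "GCC": 0.25}
    cai, flagged = codon_adaptation_index("GCTGCAGCC", w)
    assert cai == pytest.approx((1.0 * 0.5 * 0.25) ** (1 / 3))
    assert not flagged


def test_cai_is_one_for_optimal_codon_recoding():
    usage = {c: 7 + i for i, c in enumerate(sorted(SYNONYMOUS["L"]))}
    usage.update({c: 3 for c in SYNONYMOUS["A"]})
    w = reference_weights(usage)
    best_l = max(SYNONYMOUS["L"], key=lambda c: usage[c])
    cai, _ = codon_adaptation_index(best_l * 5, w)
    assert cai == pytest.approx(1.0)


def test_cai_no_informative_codons_flagged():
    w = reference_weights({c: 1 for cods in SYNONYMOUS.values() for c in cods})
    cai, flagged = codon_adaptation_index("ATGTGG", w)  # Met + Trp only
    assert (cai, flagged) == (1.0, True)


def test_cai_requires_whole_codons():
    with pytest.raises(InputError):
        codon_adaptation_index("ATGC", {})


def test_cai_matches_brute_force_product():
    rng = np.random.default_rng(3)
    codons = [c for aa, cods in SYNONYMOUS.items() if aa != "*" for c in cods]
    gene = "".join(rng.choice(codons, 60))
    usage = {c: int(rng.integers(1, 50)) for c in codons}
    w = reference_weights(usage)
    cai, _ = codon_adaptation_index(gene, w)
    informative = [
        gene[i : i + 3]
        for i in range(0, len(gene), 3)
        if gene[i : i + 3] not in ("ATG", "TGG", "TAA", "TAG", "TGA")
    ]
    brute = math.prod(w[c] for c in informative) ** (1 / len(informative))
    assert cai == pytest.approx(brute)


@given(st.integers(0, 2**31 - 1))
def test_cai_invariant_under_identical_codon_choice(seed):
    """Repeating the same codons in any order leaves CAI unchanged."""
    rng = np.random.default_rng(seed)
    codons = [c for aa, cods in SYNONYMOUS.items() if aa != "*" for c in cods]
    picks = list(rng.choice(codons, 12))
    w = reference_weights({c: int(rng.integers(1, 9)) for c in codons})
    base, _ = codon_adaptation_index("".join(picks), w)
    rng.shuffle(picks)
    shuffled, _ = codon_adaptation_index("".join(picks), w)
    assert base == pytest.approx(shuffled)


@pytest.fixture(scope="module")
def background():
    rng = np.random.default_rng(0)
    return "".join(rng.choice(list("ACGT"), 30_000))


def test_whole_replicon_region_scores_zero(background):
    rep = Replicon("x", background, "circular")
    assert atypical_composition_score(0, len(background), rep) == 0.0


def test_foreign_dinucleotide_bias_scores_high(background):
    rng = np.random.default_rng(9)
    biased = "".join(rng.choice(["CG", "TA", "CC"], 1500))
    seq = background[:12_000] + biased + background[15_000:]
    rep = Replicon("y", seq, "circular")
    z = atypical_composition_score(12_000, 15_000, rep, rng=np.random.default_rng(1))
    assert z > 3


def test_background_regions_rarely_flagged(background):
    rep = Replicon("x", background, "circular")
    rng = np.random.default_rng(17)
    flags = 0
    for trial in range(20):
        start = int(rng.integers(0, 27_000))
        z = atypical_composition_score(
            start, start + 2000, rep, rng=np.random.default_rng(trial)
        )
        flags += abs(z) >= 3
    assert flags <= 1


def test_per_cds_cai_on_synthetic_genome():
    from rgpscan.composition import per_cds_cai
    from rgpscan.simulate import SimulationConfig, generate_genome_set

    gset, _ = generate_genome_set(
        SimulationConfig(seed=12, n_core=30, trna_positions=(9,), islands=())
    )
    genome = gset.reference
    df = per_cds_cai(genome)
    assert len(df) == sum(1 for g in genome.genes if g.kind == "CDS")
    assert ((df["cai"] > 0) & (df["cai"] <= 1)).all()
    ribo = {
        g.feature_id for g in genome.genes if "ribosomal protein" in g.product
    }
    assert df[df["feature_id"].isin(ribo)]["cai"].mean() >= df["cai"].mean()


def test_region_below_one_kb_rejected(background):
    with pytest.raises(ParameterError):
        atypical_composition_score(0, 500, Replicon("x", background, "circular"))
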