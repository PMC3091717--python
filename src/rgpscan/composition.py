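"""Compositional evidence of horizontal acquisition.

Windowed GC% and GC skew profiles with +/- k-SD deviation flags, the codon
adaptation index against a highly-expressed reference gene set, and a
simplified atypical-composition z-score based on fixed-order Markov models
of nucleotide context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError
from .genome_io import GenomeRecord, Replicon
from .params import ParameterSet, RIBOSOMAL_KEYWORDS

__all__ = [
    "CompositionProfile",
    "composition_profile",
    "gc_deviation_flag",
    "count_codon_usage",
    "reference_weights",
    "codon_adaptation_index",
    "ribosomal_reference_usage",
    "atypical_composition_score",
]

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i

STOP_CODONS = {"TAA", "TAG", "TGA"}

# Standard genetic code (table 11 shares codon->AA assignments).
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
SYNONYMOUS: dict[str, list[str]] = {}
for codon, aa in GENETIC_CODE.items():
    SYNONYMOUS.setdefault(aa, []).append(codon)
# Codons excluded from CAI: stops and single-codon amino acids (Met, Trp).
_UNINFORMATIVE = set(STOP_CODONS) | {
    c for aa, cods in SYNONYMOUS.items() if aa != "*" and len(cods) == 1 for c in cods
}


@dataclass
class CompositionProfile:
    """Windowed GC%/skew profile of one replicon."""

    replicon_id: str
    window: int
    step: int
    starts: np.ndarray
    gc_percent: np.ndarray
    gc_skew: np.ndarray
    mean_gc: float
    sd_gc: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "window_start": self.starts,
                "gc_percent": np.round(self.gc_percent, 4),
                "gc_skew": np.round(self.gc_skew, 6),
            }
        )


def _gc_counts(codes: np.ndarray) -> tuple[int, int, int]:
    """(G, C, non-N) counts of an encoded sequence slice."""
    g = int(np.count_nonzero(codes == 2))
    c = int(np.count_nonzero(codes == 1))
    valid = int(np.count_nonzero(codes >= 0))
    return g, c, valid


def composition_profile(
    replicon: Replicon, window: int = 5000, step: int = 1000
) -> CompositionProfile:
    """Circular sliding-window GC% and GC skew ((G-C)/(G+C)); N excluded."""
    if not window >= step > 0:
        raise ParameterError("require window >= step > 0")
    if window > replicon.length:
        raise ParameterError(
            f"window {window} exceeds replicon length {replicon.length}"
        )
    codes = _BASE_CODE[np.frombuffer(replicon.sequence.encode(), dtype=np.uint8)]
    n = len(codes)
    if replicon.topology == "circular":
        ext = np.concatenate([codes, codes[: window - 1]])
        starts = np.arange(0, n, step)
    else:
        ext = codes
        starts = np.arange(0, n - window + 1, step)
    isg = (ext == 2).astype(np.int64)
    isc = (ext == 1).astype(np.int64)
    valid = (ext >= 0).astype(np.int64)
    cg, cc, cv = np.cumsum(isg), np.cumsum(isc), np.cumsum(valid)

    def _win(cum: np.ndarray) -> np.ndarray:
        hi = cum[starts + window - 1]
        lo = np.where(starts > 0, cum[np.maximum(starts - 1, 0)], 0)
        return hi - lo

    g, c, v = _win(cg), _win(cc), _win(cv)
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(v > 0, 100.0 * (g + c) / v, np.nan)
        skew = np.where(g + c > 0, (g - c) / (g + c), 0.0)
    mean_gc = float(np.nanmean(gc))
    sd_gc = float(np.nanstd(gc))
    return CompositionProfile(
        replicon_id=replicon.replicon_id,
        window=window,
        step=step,
        starts=starts,
        gc_percent=gc,
        gc_skew=skew,
        mean_gc=mean_gc,
        sd_gc=sd_gc,
    )


def gc_deviation_flag(
    begin: int,
    end: int,
    replicon: Replicon,
    profile: CompositionProfile,
    params: ParameterSet | None = None,
) -> bool:
    """True iff the region's mean GC deviates from the genome mean by
    strictly more than ``gc_sd_threshold`` window-SDs.

    Regions shorter than one window are evaluated on their exact counts.
    """
    params = params or ParameterSet()
    codes = _BASE_CODE[
        np.frombuffer(replicon.sequence[begin:end].encode(), dtype=np.uint8)
    ]
    g, c, valid = _gc_counts(codes)
    if valid == 0 or profile.sd_gc == 0:
        return False
    region_gc = 100.0 * (g + c) / valid
    return abs(region_gc - profile.mean_gc) > params.gc_sd_threshold * profile.sd_gc


# ---------------------------------------------------------------------------
# Codon adaptation index
# ---------------------------------------------------------------------------


def count_codon_usage(cds_sequences: list[str]) -> dict[str, int]:
    """Codon counts over a set of in-frame CDS nucleotide sequences."""
    counts = {codon: 0 for codon in GENETIC_CODE}
    for seq in cds_sequences:
        seq = seq.upper()
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    return counts


def reference_weights(usage: dict[str, int | float]) -> dict[str, float]:
    """Relative adaptiveness w = usage / max usage within each synonymous
    family; unseen codons get a small floor so log w stays finite."""
    w: dict[str, float] = {}
    for aa, codons in SYNONYMOUS.items():
        if aa == "*":
            continue
        mx = max(float(usage.get(c, 0)) for c in codons)
        for c in codons:
            w[c] = (float(usage.get(c, 0)) / mx) if mx > 0 else 1.0
            if w[c] <= 0:
                w[c] = 0.01
    return w


def cds_dna(genome: GenomeRecord, gene) -> str:
    """Coding-strand DNA of a CDS feature (origin-wrap parts included)."""
    rep = genome.replicon(gene.replicon_id)
    dna = "".join(rep.sequence[b:e] for b, e in gene.parts)
    if gene.strand == -1:
        dna = dna.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return dna


def ribosomal_reference_usage(genome: GenomeRecord) -> dict[str, int]:
    """Codon usage of ribosomal-protein CDS (the highly-expressed set)."""
    seqs = [
        cds_dna(genome, g)
        for g in genome.genes
        if g.kind == "CDS"
        and any(k in g.product.lower() for k in RIBOSOMAL_KEYWORDS)
    ]
    return count_codon_usage(seqs)


def per_cds_cai(genome: GenomeRecord):
    """CAI of every CDS against the ribosomal-protein reference usage."""
    import pandas as pd

    weights = reference_weights(ribosomal_reference_usage(genome))
    rows = []
    for g in genome.genes:
        if g.kind != "CDS" or g.pseudo:
            continue
        dna = cds_dna(genome, g)
        dna = dna[: len(dna) - len(dna) % 3]
        if not dna:
            continue
        cai, flagged = codon_adaptation_index(dna, weights)
        rows.append(
            {
                "feature_id": g.feature_id,
                "replicon": g.replicon_id,
                "cai": round(cai, 4),
                "uninformative": int(flagged),
            }
        )
    return pd.DataFrame(rows, columns=["feature_id", "replicon", "cai", "uninformative"])


def codon_adaptation_index(
    cds_sequence: str, weights: dict[str, float]
) -> tuple[float, bool]:
    """CAI = geometric mean of w over informative codons.

    Stops and single-codon amino acids (Met, Trp) are excluded.  Returns
    ``(cai, flagged)`` where ``flagged`` marks a CDS with no informative
    codon (CAI reported as 1).
    """
    seq = cds_sequence.upper()
    if len(seq) % 3 != 0:
        raise InputError("CDS length must be divisible by 3")
    logs = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in _UNINFORMATIVE or codon not in weights:
            continue
        logs.append(math.log(weights[codon]))
    if not logs:
        return 1.0, True
    return math.exp(sum(logs) / len(logs)), False


# ---------------------------------------------------------------------------
# Atypical composition (simplified fixed-order Markov score)
# ---------------------------------------------------------------------------


def _kmer_logprobs(codes: np.ndarray, order: int, pseudo: float = 0.5) -> np.ndarray:
    """log P(next base | previous ``order`` bases), shape (4**order, 4)."""
    k = order + 1
    valid = codes >= 0
    counts = np.zeros((4**order, 4), dtype=np.float64)
    if len(codes) >= k:
        idx = np.zeros(len(codes) - k + 1, dtype=np.int64)
        ok = np.ones(len(codes) - k + 1, dtype=bool)
        for j in range(order):
            idx = idx * 4 + codes[j : j + len(idx)]
            ok &= valid[j : j + len(idx)]
        nxt = codes[order : order + len(idx)]
        ok &= valid[order : order + len(idx)]
        np.add.at(counts, (idx[ok], nxt[ok]), 1.0)
    counts += pseudo
    return np.log(counts / counts.sum(axis=1, keepdims=True))


def _score_region(
    codes: np.ndarray, lp_region: np.ndarray, lp_genome: np.ndarray, order: int
) -> float:
    """Mean per-base log-odds of the region under region vs genome model."""
    k = order + 1
    if len(codes) < k:
        return 0.0
    idx = np.zeros(len(codes) - k + 1, dtype=np.int64)
    ok = np.ones(len(codes) - k + 1, dtype=bool)
    valid = codes >= 0
    for j in range(order):
        idx = idx * 4 + codes[j : j + len(idx)]
        ok &= valid[j : j + len(idx)]
    nxt = codes[order : order + len(idx)]
    ok &= valid[order : order + len(idx)]
    if not np.any(ok):
        return 0.0
    diffs = lp_region[idx[ok], nxt[ok]] - lp_genome[idx[ok], nxt[ok]]
    return float(diffs.mean())


def atypical_composition_score(
    begin: int,
    end: int,
    replicon: Replicon,
    order: int = 2,
    n_null: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """z-score of the region's compositional atypicality.

    The statistic is the mean per-base log-odds of the region under a
    region-trained versus genome-trained order-``order`` Markov model,
    standardized against the same statistic for ``n_null`` random windows
    of identical length drawn from the replicon (circular).  Regions
    compositionally indistinguishable from the background score near zero;
    foreign-looking regions score high.
    """
    if end - begin < 1000:
        raise ParameterError("atypical composition needs a region >= 1 kb")
    rng = rng or np.random.default_rng(0)
    codes = _BASE_CODE[np.frombuffer(replicon.sequence.encode(), dtype=np.uint8)]
    n = len(codes)
    length = end - begin
    if length >= n:
        # the region is the whole replicon: indistinguishable by construction
        return 0.0
    ext = np.concatenate([codes, codes]) if replicon.topology == "circular" else codes
    lp_genome = _kmer_logprobs(codes, order)
    region = codes[begin:end]
    s_region = _score_region(region, _kmer_logprobs(region, order), lp_genome, order)
    max_start = n if replicon.topology == "circular" else n - length
    if max_start <= 0:
        return 0.0
    starts = rng.integers(0, max_start, size=n_null)
    null_scores = np.empty(n_null)
    for i, st in enumerate(starts):
        w = ext[st : st + length]
        null_scores[i] = _score_region(w, _kmer_logprobs(w, order), lp_genome, order)
    sd = float(null_scores.std())
    if sd < 1e-12:
        return 0.0
    return float((s_region - null_scores.mean()) / sd)
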