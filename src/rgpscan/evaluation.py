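"""Scoring pipeline output against a synthetic truth table."""

from __future__ import annotations

from .detection import RGP
from .simulate import TruthIsland

__all__ = ["gene_level_scores", "class_recovery", "match_island_to_rgp"]


def gene_level_scores(
    rgps: list[RGP], truth_islands: list[TruthIsland]
) -> tuple[float, float]:
    """Gene-level (precision, recall) of detected RGPs vs planted islands."""
    detected: set[str] = set()
    for r in rgps:
        detected.update(r.genes)
    truth: set[str] = set()
    for isl in truth_islands:
        truth.update(isl.gene_ids)
    if not detected:
        return (1.0 if not truth else 0.0), (1.0 if not truth else 0.0)
    tp = len(detected & truth)
    precision = tp / len(detected)
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def match_island_to_rgp(island: TruthIsland, rgps: list[RGP]) -> RGP | None:
    """The detected RGP with the largest gene overlap with an island."""
    truth = set(island.gene_ids)
    best, best_overlap = None, 0
    for r in rgps:
        ov = len(truth & set(r.genes))
        if ov > best_overlap:
            best, best_overlap = r, ov
    return best


def class_recovery(
    rgps: list[RGP], truth_islands: list[TruthIsland]
) -> dict[str, tuple[str, str]]:
    """Per island: (planted class, detected class of the matching RGP)."""
    out: dict[str, tuple[str, str]] = {}
    for isl in truth_islands:
        rgp = match_island_to_rgp(isl, rgps)
        out[isl.name] = (isl.planted_class, rgp.rgp_class if rgp else "missed")
    return out
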