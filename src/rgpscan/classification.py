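"""RGP classification: prophage, genomic island, RGP_mob, RGP_none.

Evidence is gathered per RGP (tRNA adjacency, integrase, GC deviation,
atypical composition, recombination-enzyme genes, phage gene content or an
external prophage call) and resolved by a fixed decision tree with
precedence prophage > GI > RGP_mob > RGP_none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import (
    CompositionProfile,
    atypical_composition_score,
    gc_deviation_flag,
)
from .detection import RGP
from .genome_io import GeneFeature, GenomeRecord
from .params import (
    INTEGRASE_KEYWORDS,
    MOBILITY_LEXICON,
    PHAGE_KEYWORDS,
    PHAGE_STRUCTURAL_KEYWORDS,
    ParameterSet,
)

__all__ = [
    "EvidenceBundle",
    "detect_mobility_genes",
    "detect_prophage",
    "classify_rgp",
    "gather_evidence",
    "classify_all",
]


@dataclass
class EvidenceBundle:
    """The genetic features an RGP classification is based on."""

    trna_adjacent: bool = False
    integrase_present: bool = False
    gc_deviant: bool = False
    atypical_composition: bool = False
    mob_genes: list[tuple[str, str]] = field(default_factory=list)
    phage_gene_count: int = 0
    phage_structural_present: bool = False
    external_prophage_overlap: bool = False

    def flags(self) -> dict[str, bool | int]:
        return {
            "trna_adjacent": self.trna_adjacent,
            "integrase": self.integrase_present,
            "gc_deviant": self.gc_deviant,
            "atypical": self.atypical_composition,
            "n_mob_genes": len(self.mob_genes),
            "phage_genes": self.phage_gene_count,
            "phage_structural": self.phage_structural_present,
            "external_prophage": self.external_prophage_overlap,
        }


def detect_mobility_genes(
    genes: list[GeneFeature],
    lexicon: dict[str, tuple[str, ...]] | None = None,
) -> tuple[list[tuple[str, str]], bool]:
    """Keyword scan of product strings for recombination-enzyme genes.

    Returns ``(mob_genes, integrase_present)``; integrase is reported
    separately (GI evidence) from the other recombinases (RGP_mob
    evidence).  Matching is case-insensitive substring search; the first
    matching category in lexicon order wins per gene.
    """
    lexicon = lexicon or MOBILITY_LEXICON
    mob: list[tuple[str, str]] = []
    integrase = False
    for g in genes:
        product = g.product.lower()
        if any(k in product for k in INTEGRASE_KEYWORDS):
            integrase = True
            continue
        for category, keywords in lexicon.items():
            if any(k in product for k in keywords):
                mob.append((g.feature_id, category))
                break
    return mob, integrase


def detect_prophage(
    rgp: RGP,
    genes: list[GeneFeature],
    params: ParameterSet | None = None,
    external_calls: list[tuple[str, int, int]] | None = None,
) -> tuple[bool, int, bool, bool]:
    """Prophage call for an RGP.

    An externally supplied prophage interval overlapping at least half of
    the RGP overrides the heuristic; otherwise the RGP is a prophage when
    it contains at least ``phage_min_genes`` phage-annotated genes
    including at least one structural gene (capsid/tail/terminase/portal/
    baseplate).  Returns (is_prophage, phage_gene_count,
    structural_present, external_overlap).
    """
    params = params or ParameterSet()
    count = 0
    structural = False
    for g in genes:
        product = g.product.lower()
        if any(k in product for k in PHAGE_KEYWORDS):
            count += 1
            if any(k in product for k in PHAGE_STRUCTURAL_KEYWORDS):
                structural = True
    external = False
    for rep, b, e in external_calls or []:
        if rep != rgp.replicon_id:
            continue
        overlap = min(e, rgp.end) - max(b, rgp.begin)
        if overlap >= 0.5 * rgp.size:
            external = True
            break
    is_prophage = external or (count >= params.phage_min_genes and structural)
    return is_prophage, count, structural, external


def classify_rgp(evidence: EvidenceBundle, params: ParameterSet | None = None) -> str:
    """Resolve an evidence bundle into one of the four RGP classes.

    Precedence: prophage > GI > RGP_mob > RGP_none.  Prophage requires an
    external prophage call or ``phage_min_genes`` phage-annotated genes
    with a structural gene among them; GI requires at least one
    horizontal-transfer hallmark (tRNA adjacency, integrase, GC deviation
    or atypical composition); RGP_mob requires at least one
    recombination-enzyme gene; everything else is RGP_none.
    """
    params = params or ParameterSet()
    if evidence.external_prophage_overlap or (
        evidence.phage_gene_count >= params.phage_min_genes
        and evidence.phage_structural_present
    ):
        return "prophage"
    if (
        evidence.trna_adjacent
        or evidence.integrase_present
        or evidence.gc_deviant
        or evidence.atypical_composition
    ):
        return "GI"
    if evidence.mob_genes:
        return "RGP_mob"
    return "RGP_none"


def _trna_adjacent(rgp: RGP, genome: GenomeRecord, window: int) -> bool:
    """A tRNA gene within ``window`` gene ranks of either RGP boundary
    (inside or outside; circular replicons wrap)."""
    genes = genome.genes_of(rgp.replicon_id)
    n = len(genes)
    circular = genome.replicon(rgp.replicon_id).topology == "circular"
    ranks: set[int] = set()
    for edge in (rgp.rank_begin, rgp.rank_end):
        for d in range(-window, window + 1):
            i = edge + d
            if circular:
                ranks.add(i % n)
            elif 0 <= i < n:
                ranks.add(i)
    return any(genes[i].kind == "tRNA" for i in ranks)


def gather_evidence(
    rgp: RGP,
    genome: GenomeRecord,
    profile: CompositionProfile,
    params: ParameterSet | None = None,
    external_calls: list[tuple[str, int, int]] | None = None,
    mobility_lexicon: dict[str, tuple[str, ...]] | None = None,
    rng: np.random.Generator | None = None,
) -> EvidenceBundle:
    """Fill the complete evidence bundle for one RGP."""
    params = params or ParameterSet()
    genes = [genome.gene(fid) for fid in rgp.genes]
    mob, integrase = detect_mobility_genes(genes, mobility_lexicon)
    _, phage_count, structural, external = detect_prophage(
        rgp, genes, params, external_calls
    )
    replicon = genome.replicon(rgp.replicon_id)
    gc_dev = gc_deviation_flag(rgp.begin, rgp.end, replicon, profile, params)
    atypical = False
    if rgp.size >= 1000:
        z = atypical_composition_score(
            rgp.begin, rgp.end, replicon, rng=rng or np.random.default_rng(0)
        )
        atypical = z > params.atypical_z_threshold
    return EvidenceBundle(
        trna_adjacent=_trna_adjacent(rgp, genome, params.trna_flank_window),
        integrase_present=integrase,
        gc_deviant=gc_dev,
        atypical_composition=atypical,
        mob_genes=mob,
        phage_gene_count=phage_count,
        phage_structural_present=structural,
        external_prophage_overlap=external,
    )


def classify_all(
    rgps: list[RGP],
    genome: GenomeRecord,
    profiles: dict[str, CompositionProfile],
    params: ParameterSet | None = None,
    external_calls: list[tuple[str, int, int]] | None = None,
    mobility_lexicon: dict[str, tuple[str, ...]] | None = None,
    seed: int = 0,
) -> None:
    """Attach evidence and class to every RGP in place (deterministic)."""
    params = params or ParameterSet()
    for rgp in rgps:
        rng = np.random.default_rng((seed, rgp.rgp_id))
        ev = gather_evidence(
            rgp,
            genome,
            profiles[rgp.replicon_id],
            params,
            external_calls,
            mobility_lexicon,
            rng=rng,
        )
        rgp.evidence = ev
        rgp.rgp_class = classify_rgp(ev, params)
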