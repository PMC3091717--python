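"""Hand-built miniature genomes and ortholog tables for unit tests."""

from __future__ import annotations

import numpy as np

from rgpscan.genome_io import GeneFeature, GenomeRecord, Replicon, _assign_ranks
from rgpscan.orthology import OrthologPair, OrthologTable

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def protein(rng: np.random.Generator, length: int = 80) -> str:
    return "M" + "".join(rng.choice(AA, length - 1))


def make_genome(
    genome_id: str,
    n_genes: int = 0,
    proteins: list[str | None] | None = None,
    intervals: list[tuple[int, int]] | None = None,
    kinds: list[str] | None = None,
    products: list[str] | None = None,
    names: list[str | None] | None = None,
    gene_len: int = 600,
    spacer: int = 100,
    topology: str = "circular",
    seed: int = 0,
) -> GenomeRecord:
    """A toy genome with evenly spaced genes (or explicit intervals)."""
    rng = np.random.default_rng(seed)
    if proteins is None:
        proteins = [protein(rng) for _ in range(n_genes)]
    n = len(proteins)
    if intervals is None:
        intervals = [
            (i * (gene_len + spacer) + spacer, i * (gene_len + spacer) + spacer + gene_len)
            for i in range(n)
        ]
    total = max(e for _, e in intervals) + spacer
    seq = "".join(rng.choice(list("ACGT"), total))
    feats = []
    for i, ((b, e), prot) in enumerate(zip(intervals, proteins)):
        kind = (kinds or ["CDS"] * n)[i]
        feats.append(
            GeneFeature(
                feature_id=f"{genome_id}_g{i:03d}",
                replicon_id=f"{genome_id}_chr",
                begin=b,
                end=e,
                strand=1,
                kind=kind,
                product=(products or [""] * n)[i],
                protein=prot if kind == "CDS" else None,
                name=(names or [None] * n)[i],
            )
        )
    return GenomeRecord(
        genome_id=genome_id,
        replicons=[Replicon(f"{genome_id}_chr", seq, topology)],
        genes=_assign_ranks(feats),
    )


def make_table(
    genome_a: str,
    genome_b: str,
    links: list[tuple[int, int]],
    n_a: int | None = None,
    identity: float = 90.0,
    coverage: float = 1.0,
) -> OrthologTable:
    """An ortholog table linking gene ranks of two toy genomes as BBH."""
    pairs = [
        OrthologPair(
            gene_a=f"{genome_a}_g{ra:03d}",
            gene_b=f"{genome_b}_g{rb:03d}",
            identity=identity,
            coverage=coverage,
            bidirectional_best=True,
            rank_a=ra,
            rank_b=rb,
            replicon_a=f"{genome_a}_chr",
            replicon_b=f"{genome_b}_chr",
        )
        for ra, rb in links
    ]
    return OrthologTable(genome_a, genome_b, pairs)
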