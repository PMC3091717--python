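"""Synthetic genome sets with planted RGPs, modules, hotspots, deletions.

The generator emulates the structure of a small enterobacterial comparison
set: a conserved core-gene backbone shared in order by all genomes, with
islands (>=5 kb) inserted between designated core genes.  Island evidence
features (tRNA flank, integrase gene, GC shift, transposase genes, phage
cassette) and module-sharing patterns (which genomes carry which gene
blocks, and where) are controlled per island, and everything generated is
recorded in a machine-readable truth table.

Proteins are drawn from a random amino-acid model and diverged by per-site
substitution, so realized identities are measured, never assumed.  The
same seed always reproduces byte-identical output.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .genome_io import GeneFeature, GenomeRecord, GenomeSet, Replicon, _assign_ranks

__all__ = [
    "BlockSpec",
    "IslandSpec",
    "TranslocationSpec",
    "SimulationConfig",
    "TruthModule",
    "TruthIsland",
    "TruthTable",
    "generate_genome_set",
    "plant_deletion",
    "write_genome_set",
    "divergent_protein_pair",
    "default_config",
    "worked_example_config",
    "translocation_config",
    "shared_sites_config",
]

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# codons per amino acid, translation table 11 assignments
from .composition import GENETIC_CODE, SYNONYMOUS  # noqa: E402


# ---------------------------------------------------------------------------
# Specs and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockSpec:
    """A gene block of an island: strain-specific or shared by carriers."""

    n_genes: int
    carriers: tuple[str, ...] = ()
    theme: str = "generic"


@dataclass(frozen=True)
class IslandSpec:
    """A planted variable region and its evidence features."""

    name: str
    site: int  # inserted between core genes ``site`` and ``site + 1``
    blocks: tuple[BlockSpec, ...]
    genome: str | None = None  # owner genome; defaults to the reference
    trna_flank: bool = False
    integrase: bool = False
    gc_shift: float = 0.0  # GC percentage points added to island DNA
    n_mob_genes: int = 0  # transposase products among the first block genes
    phage: bool = False  # phage-cassette products
    planted_class: str = "RGP_none"
    carrier_site: dict[str, int] = field(default_factory=dict)
    carrier_intercalate: dict[str, int] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return sum(b.n_genes for b in self.blocks)


@dataclass(frozen=True)
class TranslocationSpec:
    """Move ``n_genes`` core genes (starting at ``start``) elsewhere."""

    genome: str
    start: int
    n_genes: int
    dest: int  # re-inserted after core gene ``dest`` (in backbone order)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_ids: tuple[str, ...] = ("AA1", "AA2", "BB1", "BB2")
    groups: tuple[tuple[str, str], ...] = (
        ("AA1", "same_genus"),
        ("AA2", "same_genus"),
        ("BB1", "other_genus"),
        ("BB2", "other_genus"),
    )
    reference: str = "AA1"
    n_core: int = 110
    core_len_range: tuple[int, int] = (120, 300)
    island_len_range: tuple[int, int] = (200, 350)  # keeps 8-gene islands >5 kb
    divergence: float = 0.05
    gc_background: float = 0.5
    spacer_len_range: tuple[int, int] = (60, 140)
    trna_positions: tuple[int, ...] = (15, 35, 55, 75, 95)
    islands: tuple[IslandSpec, ...] = ()
    translocations: tuple[TranslocationSpec, ...] = ()
    core_gene_names: tuple[tuple[int, str], ...] = ()

    def group_of(self, genome_id: str) -> str:
        for gid, grp in self.groups:
            if gid == genome_id:
                return grp
        raise ConfigError(f"genome {genome_id} has no group label")


@dataclass
class TruthModule:
    letter: str
    gene_ids: list[str]
    begin: int
    end: int
    carriers: tuple[str, ...]


@dataclass
class TruthIsland:
    name: str
    genome_id: str
    replicon_id: str
    begin: int
    end: int
    gene_ids: list[str]
    planted_class: str
    modules: list[TruthModule]
    left_core: str  # flanking core gene symbol
    right_core: str
    site: int


@dataclass
class TruthTable:
    islands: list[TruthIsland]
    shared_site_genomes: dict[int, list[str]]  # core site -> occupant genomes

    def islands_of(self, genome_id: str) -> list[TruthIsland]:
        return [i for i in self.islands if i.genome_id == genome_id]

    def to_manifest(self) -> dict:
        return {
            "islands": [
                {
                    "name": i.name,
                    "genome": i.genome_id,
                    "replicon": i.replicon_id,
                    "begin": i.begin,
                    "end": i.end,
                    "class": i.planted_class,
                    "genes": i.gene_ids,
                    "left_core": i.left_core,
                    "right_core": i.right_core,
                    "modules": [
                        {
                            "letter": m.letter,
                            "genes": m.gene_ids,
                            "begin": m.begin,
                            "end": m.end,
                            "carriers": list(m.carriers),
                        }
                        for m in i.modules
                    ],
                }
                for i in self.islands
            ],
            "shared_sites": {
                str(k): v for k, v in self.shared_site_genomes.items()
            },
        }


# ---------------------------------------------------------------------------
# Sequence-level helpers
# ---------------------------------------------------------------------------


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(AA_ALPHABET, size=length - 1))
    return "M" + body


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = list(protein)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        if i == 0:
            continue  # keep the start methionine
        choices = AA_ALPHABET[AA_ALPHABET != out[i]]
        out[i] = str(rng.choice(choices))
    return "".join(out)


def divergent_protein_pair(
    rng: np.random.Generator, length: int, identity_pct: float
) -> tuple[str, str]:
    """A protein pair whose *realized* alignment identity sits at
    ``identity_pct`` (within one percentage point, full-ish coverage).

    Matching positions are spread evenly (first and last position always
    match) so a local alignment cannot raise the identity by trimming;
    because gapped re-alignment of the random substitutions can still
    shift the measured value, the realized identity is checked against
    the same local-alignment measure used for orthology and the pair is
    redrawn until it lands on target.
    """
    from .orthology import align_protein_pair  # measuring instrument

    n_match = max(2, min(length, int(round(identity_pct / 100.0 * length))))
    match_pos = set(
        int(round(i * (length - 1) / (n_match - 1))) for i in range(n_match)
    )
    last: tuple[str, str] | None = None
    for _ in range(50):
        a = _random_protein(rng, length)
        b = list(a)
        for i in range(length):
            if i in match_pos:
                continue
            choices = AA_ALPHABET[AA_ALPHABET != a[i]]
            b[i] = str(rng.choice(choices))
        last = a, "".join(b)
        identity, coverage = align_protein_pair(*last)
        if abs(identity - identity_pct) <= 1.0 and coverage >= 0.9:
            return last
    raise ConfigError(
        f"could not realize identity {identity_pct}% at length {length}"
    )


def _codon_weights(gc_target: float) -> dict[str, np.ndarray]:
    """Per-amino-acid synonymous codon weights biased toward a GC target."""
    p = min(max(gc_target, 0.05), 0.95)
    weights: dict[str, np.ndarray] = {}
    for aa, codons in SYNONYMOUS.items():
        if aa == "*":
            continue
        w = np.array(
            [
                p ** sum(c in "GC" for c in codon)
                * (1 - p) ** sum(c in "AT" for c in codon)
                for codon in codons
            ]
        )
        weights[aa] = w / w.sum()
    return weights


def _encode_protein(
    rng: np.random.Generator, protein: str, weights: dict[str, np.ndarray]
) -> str:
    parts = []
    for aa in protein:
        codons = SYNONYMOUS[aa]
        parts.append(codons[rng.choice(len(codons), p=weights[aa])])
    parts.append("TAA")
    return "".join(parts)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


_RC = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# Product annotation themes
# ---------------------------------------------------------------------------

_CORE_PRODUCTS = [
    "DNA-directed RNA polymerase subunit",
    "DNA polymerase III subunit",
    "elongation factor Tu",
    "chaperonin GroEL",
    "ATP synthase F1 subunit",
    "succinate dehydrogenase flavoprotein subunit",
    "glyceraldehyde-3-phosphate dehydrogenase",
    "citrate synthase",
    "DNA gyrase subunit",
    "preprotein translocase subunit",
    "cell division protein FtsZ",
    "phosphoglycerate kinase",
    "enolase",
    "aminopeptidase",
    "signal recognition particle protein",
    "peptide chain release factor",
]
_RIBOSOMAL_PRODUCTS = [f"50S ribosomal protein L{i}" for i in range(1, 7)] + [
    f"30S ribosomal protein S{i}" for i in range(1, 7)
]

_PHAGE_PRODUCTS = [
    "phage terminase large subunit",
    "major capsid protein",
    "phage portal protein",
    "phage tail tape measure protein",
    "baseplate assembly protein",
    "phage holin",
    "phage lysozyme",
    "terminase small subunit",
    "phage antirepressor protein",
    "phage tail fiber protein",
]

_THEME_PRODUCTS = {
    "generic": [
        "hypothetical protein",
        "putative exported protein",
        "conserved hypothetical protein",
        "putative membrane protein",
    ],
    "metabolism": [
        "sugar ABC transporter permease",
        "aldehyde dehydrogenase",
        "amino acid transporter",
        "glycosyl transferase",
        "short-chain dehydrogenase/reductase",
    ],
    "secretion": [
        "type VI secretion system contractile sheath protein",
        "type VI secretion system baseplate-independent spike protein VgrG",
        "type VI secretion system membrane core protein",
        "type VI secretion system ATPase ClpV",
        "type VI secretion system effector delivery protein",
    ],
    "hemolysin": [
        "two-partner secretion family hemolysin",
        "hemolysin activator protein",
        "hemolysin secretion/activation protein",
    ],
    "antibiotic": [
        "non-ribosomal peptide synthetase",
        "polyketide synthase module",
        "bacteriocin biosynthesis protein",
    ],
    "recombination": [
        "site-specific DNA recombinase",
        "DNA invertase",
    ],
}


def _block_products(block: BlockSpec, island: IslandSpec) -> list[str]:
    if island.phage:
        base = _PHAGE_PRODUCTS
    else:
        base = _THEME_PRODUCTS.get(block.theme, _THEME_PRODUCTS["generic"])
    return [base[i % len(base)] for i in range(block.n_genes)]


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------


@dataclass
class _PlannedGene:
    key: str  # stable cross-genome identity key (for truth bookkeeping)
    protein: str
    product: str
    kind: str = "CDS"
    name: str | None = None
    gc: float | None = None  # override GC target for this gene's DNA
    island: str | None = None  # island name, for truth collection
    block_sig: tuple[str, ...] | None = None  # carrier signature


def _ancestral_pool(config: SimulationConfig, rng: np.random.Generator):
    """Ancestral proteins for core genes and shared island blocks."""
    lo, hi = config.core_len_range
    core = [_random_protein(rng, int(rng.integers(lo, hi))) for _ in range(config.n_core)]
    ilo, ihi = config.island_len_range
    blocks: dict[tuple[str, int], list[str]] = {}
    for isl in config.islands:
        for bi, block in enumerate(isl.blocks):
            if block.carriers:
                blocks[(isl.name, bi)] = [
                    _random_protein(rng, int(rng.integers(ilo, ihi)))
                    for _ in range(block.n_genes)
                ]
    return core, blocks


def _plan_island_genes(
    isl: IslandSpec,
    genome_id: str,
    owner: str,
    block_pool: dict[tuple[str, int], list[str]],
    rng: np.random.Generator,
    config: SimulationConfig,
) -> list[_PlannedGene]:
    """Planned genes of one island as they appear in ``genome_id``."""
    ilo, ihi = config.island_len_range
    gc = (
        config.gc_background + isl.gc_shift / 100.0
        if isl.gc_shift
        else None
    )
    genes: list[_PlannedGene] = []
    is_owner = genome_id == owner
    mob_left = isl.n_mob_genes if is_owner else 0
    first_carried = True
    for bi, block in enumerate(isl.blocks):
        in_this = is_owner or genome_id in block.carriers
        if not in_this:
            continue
        if not is_owner and not first_carried:
            # intercalated carrier-specific genes between carried blocks
            for j in range(isl.carrier_intercalate.get(genome_id, 0)):
                genes.append(
                    _PlannedGene(
                        key=f"{isl.name}.x{genome_id}.{bi}.{j}",
                        protein=_random_protein(rng, int(rng.integers(ilo, ihi))),
                        product="hypothetical protein",
                        gc=gc,
                        island=isl.name,
                        block_sig=(genome_id,),
                    )
                )
        products = _block_products(block, isl)
        sig = tuple(sorted(set(block.carriers) | {owner}))
        for j in range(block.n_genes):
            if (isl.name, bi) in block_pool:
                protein = _mutate_protein(
                    rng, block_pool[(isl.name, bi)][j], config.divergence
                )
            else:
                protein = _random_protein(rng, int(rng.integers(ilo, ihi)))
            product = products[j]
            if is_owner and mob_left > 0 and not block.carriers:
                product = "IS630 family transposase"
                mob_left -= 1
            if is_owner and isl.integrase and bi == 0 and j == block.n_genes - 1:
                product = "site-specific integrase"
            genes.append(
                _PlannedGene(
                    key=f"{isl.name}.b{bi}.{j}",
                    protein=protein,
                    product=product,
                    gc=gc,
                    island=isl.name,
                    block_sig=sig if block.carriers else (owner,),
                )
            )
        if not is_owner:
            first_carried = False
    if is_owner and isl.trna_flank and genes:
        genes.insert(
            0,
            _PlannedGene(
                key=f"{isl.name}.trna",
                protein="",
                product="tRNA-Leu",
                kind="tRNA",
                gc=gc,
                island=isl.name,
                block_sig=genes[0].block_sig,
            ),
        )
    return genes


def _plan_genome(
    config: SimulationConfig,
    genome_id: str,
    core_pool: list[str],
    block_pool: dict[tuple[str, int], list[str]],
    rng: np.random.Generator,
) -> list[_PlannedGene]:
    name_overrides = dict(config.core_gene_names)
    ribo_every = max(1, config.n_core // len(_RIBOSOMAL_PRODUCTS))

    def _core_gene(idx: int) -> _PlannedGene:
        if idx % ribo_every == 0 and idx // ribo_every < len(_RIBOSOMAL_PRODUCTS):
            product = _RIBOSOMAL_PRODUCTS[idx // ribo_every]
        else:
            product = _CORE_PRODUCTS[idx % len(_CORE_PRODUCTS)]
        return _PlannedGene(
            key=f"core.{idx}",
            protein=_mutate_protein(rng, core_pool[idx], config.divergence),
            product=product,
            name=name_overrides.get(idx, f"cg{idx:03d}"),
        )

    # insertions per backbone site
    at_site: dict[int, list[_PlannedGene]] = {}
    for isl in config.islands:
        owner = isl.genome or config.reference
        site = isl.site
        if genome_id != owner:
            site = isl.carrier_site.get(genome_id, isl.site)
        genes = _plan_island_genes(isl, genome_id, owner, block_pool, rng, config)
        if genes:
            at_site.setdefault(site, []).extend(genes)
    for pos in config.trna_positions:
        at_site.setdefault(pos, []).insert(
            0,
            _PlannedGene(key=f"trna.{pos}", protein="", product="tRNA-Gly", kind="tRNA"),
        )

    order: list[_PlannedGene] = []
    for idx in range(config.n_core):
        order.append(_core_gene(idx))
        order.extend(at_site.get(idx, []))
    # translocations: move core blocks elsewhere (backbone order indices)
    for tr in config.translocations:
        if tr.genome != genome_id:
            continue
        keys = {f"core.{i}" for i in range(tr.start, tr.start + tr.n_genes)}
        moved = [g for g in order if g.key in keys]
        if len(moved) != tr.n_genes:
            raise ConfigError(f"translocation {tr} references missing core genes")
        order = [g for g in order if g.key not in keys]
        anchor = next(
            i for i, g in enumerate(order) if g.key == f"core.{tr.dest}"
        )
        order[anchor + 1 : anchor + 1] = moved
    return order


def _assemble(
    config: SimulationConfig,
    genome_id: str,
    planned: list[_PlannedGene],
    rng: np.random.Generator,
) -> tuple[GenomeRecord, dict[str, tuple[str, _PlannedGene]]]:
    """Emit DNA + features for a planned gene order."""
    rep_id = f"{genome_id}_chr"
    weights_cache: dict[float, dict[str, np.ndarray]] = {}
    slo, shi = config.spacer_len_range
    seq_parts: list[str] = []
    feats: list[GeneFeature] = []
    by_key: dict[str, tuple[str, _PlannedGene]] = {}
    pos = 0
    for i, pg in enumerate(planned):
        gc = pg.gc if pg.gc is not None else config.gc_background
        spacer = _random_dna(rng, int(rng.integers(slo, shi)), gc)
        seq_parts.append(spacer)
        pos += len(spacer)
        if pg.kind == "tRNA":
            dna = _random_dna(rng, 76, gc)
            strand = 1
            protein = None
        else:
            if gc not in weights_cache:
                weights_cache[gc] = _codon_weights(gc)
            coding = _encode_protein(rng, pg.protein, weights_cache[gc])
            strand = 1 if rng.random() < 0.7 else -1
            dna = coding if strand == 1 else coding.translate(_RC)[::-1]
            protein = pg.protein
        fid = f"{genome_id}_{i:05d}"
        feats.append(
            GeneFeature(
                feature_id=fid,
                replicon_id=rep_id,
                begin=pos,
                end=pos + len(dna),
                strand=strand,
                kind=pg.kind,
                product=pg.product,
                protein=protein,
                name=pg.name,
            )
        )
        by_key[pg.key] = (fid, pg)
        seq_parts.append(dna)
        pos += len(dna)
    tail = _random_dna(rng, int(rng.integers(slo, shi)), config.gc_background)
    seq_parts.append(tail)
    record = GenomeRecord(
        genome_id=genome_id,
        replicons=[
            Replicon(
                replicon_id=rep_id,
                sequence="".join(seq_parts),
                topology="circular",
            )
        ],
        genes=_assign_ranks(feats),
        group_label=config.group_of(genome_id),
    )
    return record, by_key


def _collect_truth(
    config: SimulationConfig,
    genomes: dict[str, GenomeRecord],
    keymaps: dict[str, dict[str, tuple[str, _PlannedGene]]],
) -> TruthTable:
    islands: list[TruthIsland] = []
    site_occupants: dict[int, set[str]] = {}
    for isl in config.islands:
        owner = isl.genome or config.reference
        for gid, genome in genomes.items():
            entries = [
                (fid, pg)
                for (fid, pg) in keymaps[gid].values()
                if pg.island == isl.name
            ]
            if not entries:
                continue
            feats = sorted(
                (genome.gene(fid) for fid, _ in entries), key=lambda f: f.begin
            )
            pg_of = {fid: pg for fid, pg in entries}
            # group contiguous genes by carrier signature -> truth modules
            modules: list[TruthModule] = []
            cur: list[GeneFeature] = []
            cur_sig: tuple[str, ...] | None = None
            for f in feats:
                sig = pg_of[f.feature_id].block_sig
                if pg_of[f.feature_id].kind == "tRNA" and cur_sig is None:
                    sig = None  # leading tRNA joins the first block
                if cur and None not in (sig, cur_sig) and sig != cur_sig:
                    modules.append(_truth_module(cur, cur_sig, len(modules)))
                    cur = []
                cur.append(f)
                if sig is not None:
                    cur_sig = sig
            if cur:
                modules.append(_truth_module(cur, cur_sig or (owner,), len(modules)))
            site = isl.site
            if gid != owner:
                site = isl.carrier_site.get(gid, isl.site)
            site_occupants.setdefault(site, set()).add(gid)
            name_overrides = dict(config.core_gene_names)
            islands.append(
                TruthIsland(
                    name=isl.name,
                    genome_id=gid,
                    replicon_id=feats[0].replicon_id,
                    begin=feats[0].begin,
                    end=max(f.end for f in feats),
                    gene_ids=[f.feature_id for f in feats],
                    planted_class=isl.planted_class if gid == owner else "RGP_none",
                    modules=modules,
                    left_core=name_overrides.get(site, f"cg{site:03d}"),
                    right_core=name_overrides.get(site + 1, f"cg{site + 1:03d}"),
                    site=site,
                )
            )
    shared = {
        site: sorted(gids)
        for site, gids in site_occupants.items()
        if len(gids) > 1
    }
    return TruthTable(islands=islands, shared_site_genomes=shared)


def _truth_module(
    feats: list[GeneFeature], sig: tuple[str, ...], index: int
) -> TruthModule:
    letters = "abcdefghijklmnopqrstuvwxyz"
    return TruthModule(
        letter=letters[index],
        gene_ids=[f.feature_id for f in feats],
        begin=feats[0].begin,
        end=max(f.end for f in feats),
        carriers=sig,
    )


def generate_genome_set(
    config: SimulationConfig | None = None,
) -> tuple[GenomeSet, TruthTable]:
    """Generate a genome set plus its truth table (deterministic by seed)."""
    config = config or default_config()
    for isl in config.islands:
        if not 0 <= isl.site < config.n_core - 1:
            raise ConfigError(f"island {isl.name} site {isl.site} outside backbone")
    ss = np.random.SeedSequence(config.seed)
    anc_seed, *genome_seeds = ss.spawn(1 + len(config.genome_ids))
    core_pool, block_pool = _ancestral_pool(
        config, np.random.default_rng(anc_seed)
    )
    genomes: dict[str, GenomeRecord] = {}
    keymaps: dict[str, dict[str, tuple[str, _PlannedGene]]] = {}
    for gid, gseed in zip(config.genome_ids, genome_seeds):
        rng = np.random.default_rng(gseed)
        planned = _plan_genome(config, gid, core_pool, block_pool, rng)
        genomes[gid], keymaps[gid] = _assemble(config, gid, planned, rng)
    ref = genomes[config.reference]
    comparisons = [genomes[g] for g in config.genome_ids if g != config.reference]
    truth = _collect_truth(config, genomes, keymaps)
    return GenomeSet(reference=ref, comparisons=comparisons), truth


# ---------------------------------------------------------------------------
# Deletions
# ---------------------------------------------------------------------------


def plant_deletion(
    genome: GenomeRecord, intervals: list[tuple[str, int, int]]
) -> GenomeRecord:
    """Excise intervals from a genome; downstream coordinates shift left.

    Features fully inside a deleted interval disappear; features cut by a
    boundary are truncated and flagged partial (their translation is
    dropped).  Overlapping intervals are a configuration error.
    """
    by_rep: dict[str, list[tuple[int, int]]] = {}
    for rep, b, e in intervals:
        if not 0 <= b < e <= genome.replicon(rep).length:
            raise ConfigError(f"deletion [{b}, {e}) outside replicon {rep}")
        by_rep.setdefault(rep, []).append((b, e))
    for cuts in by_rep.values():
        cuts.sort()
        for (b1, e1), (b2, e2) in zip(cuts, cuts[1:]):
            if b2 < e1:
                raise ConfigError("overlapping deletion intervals")
    new_reps: list[Replicon] = []
    new_feats: list[GeneFeature] = []
    for rep in genome.replicons:
        cuts = by_rep.get(rep.replicon_id, [])
        if not cuts:
            new_reps.append(rep)
            new_feats.extend(genome.genes_of(rep.replicon_id))
            continue
        keep_seq = []
        pos = 0
        shift_at: list[tuple[int, int]] = []  # (cut begin, cumulative removed)
        removed = 0
        for b, e in cuts:
            keep_seq.append(rep.sequence[pos:b])
            removed += e - b
            shift_at.append((b, removed))
            pos = e
        keep_seq.append(rep.sequence[pos:])
        new_reps.append(replace(rep, sequence="".join(keep_seq)))

        def _shift(x: int) -> int:
            s = 0
            for b, cum in shift_at:
                if x >= b:
                    s = cum
            return x - s

        for g in genome.genes_of(rep.replicon_id):
            nb, ne = g.begin, g.end
            inside = any(b <= g.begin and g.end <= e for b, e in cuts)
            if inside:
                continue
            truncated = False
            for b, e in cuts:
                if g.begin < e and g.end > b:  # partial overlap
                    truncated = True
                    if g.begin < b:
                        ne = min(g.end, b)
                        nb = g.begin
                    else:
                        nb = e
                        ne = g.end
            nb2 = _shift(nb)
            ne2 = nb2 + (ne - nb) if truncated else _shift(ne)
            if ne2 <= nb2:
                continue
            new_feats.append(
                replace(
                    g,
                    begin=nb2,
                    end=ne2,
                    parts=((nb2, ne2),),
                    partial=g.partial or truncated,
                    protein=None if truncated else g.protein,
                )
            )
    return GenomeRecord(
        genome_id=genome.genome_id + "-var",
        replicons=new_reps,
        genes=_assign_ranks(new_feats),
        group_label=genome.group_label,
    )


# ---------------------------------------------------------------------------
# GenBank output
# ---------------------------------------------------------------------------


def write_genome_set(
    genome_set: GenomeSet, truth: TruthTable | None, outdir: str
) -> list[str]:
    """Write each genome as a GenBank flat file (+ truth manifest JSON)."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    os.makedirs(outdir, exist_ok=True)
    paths: list[str] = []
    for genome in genome_set.all_genomes:
        records = []
        for rep in genome.replicons:
            rec = SeqRecord(
                Seq(rep.sequence),
                id=rep.replicon_id,
                name=rep.replicon_id[:16],
                description=f"synthetic genome {genome.genome_id}",
                annotations={
                    "molecule_type": "DNA",
                    "topology": rep.topology,
                },
            )
            for g in genome.genes_of(rep.replicon_id):
                quals = {"locus_tag": [g.feature_id]}
                if g.product:
                    quals["product"] = [g.product]
                if g.name:
                    quals["gene"] = [g.name]
                if g.protein:
                    quals["translation"] = [g.protein]
                rec.features.append(
                    SeqFeature(
                        FeatureLocation(g.begin, g.end, strand=g.strand),
                        type=g.kind,
                        qualifiers=quals,
                    )
                )
            records.append(rec)
        path = os.path.join(outdir, f"{genome.genome_id}.gbk")
        SeqIO.write(records, path, "genbank")
        paths.append(path)
    if truth is not None:
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(truth.to_manifest(), fh, indent=1)
    return paths


# ---------------------------------------------------------------------------
# Stock configurations
# ---------------------------------------------------------------------------


def default_config(seed: int = 0) -> SimulationConfig:
    """The default study conditions: four genomes (two per genus), six
    planted islands covering every evidence type, one shared-module island
    carried by three genomes at the same site."""
    islands = (
        IslandSpec(
            name="phage1",
            site=9,
            blocks=(BlockSpec(14),),
            phage=True,
            planted_class="prophage",
        ),
        IslandSpec(
            name="gi_trna",
            site=24,
            blocks=(BlockSpec(9),),
            trna_flank=True,
            integrase=True,
            planted_class="GI",
        ),
        IslandSpec(
            name="gi_gc",
            site=44,
            blocks=(BlockSpec(8, theme="metabolism"),),
            gc_shift=12.0,
            planted_class="GI",
        ),
        IslandSpec(
            name="mob1",
            site=64,
            blocks=(BlockSpec(8),),
            n_mob_genes=2,
            planted_class="RGP_mob",
        ),
        IslandSpec(
            name="none1",
            site=84,
            blocks=(BlockSpec(8, theme="generic"),),
            planted_class="RGP_none",
        ),
        IslandSpec(
            name="shared1",
            site=99,
            blocks=(
                BlockSpec(3, theme="generic"),
                BlockSpec(16, carriers=("AA2", "BB1"), theme="secretion"),
                BlockSpec(3, carriers=("AA2",), theme="hemolysin"),
                BlockSpec(2, theme="metabolism"),
            ),
            planted_class="RGP_none",
        ),
    )
    return SimulationConfig(seed=seed, islands=islands)


def worked_example_config(seed: int = 7) -> SimulationConfig:
    """Synthetic stand-in for the published worked example: an island
    between core genes named typA and treC splitting into modules a-d
    (b = 16 genes, c = 3 genes, both conserved in the three other
    genomes), plus a trmE-flanked site occupied in all four genomes."""
    genome_ids = ("XN", "XB", "PL", "PA")
    groups = (
        ("XN", "same_genus"),
        ("XB", "same_genus"),
        ("PL", "other_genus"),
        ("PA", "other_genus"),
    )
    others = ("XB", "PL", "PA")
    islands = [
        IslandSpec(
            name="rgp99",
            site=29,
            blocks=(
                BlockSpec(2, theme="generic"),
                BlockSpec(16, carriers=others, theme="secretion"),
                BlockSpec(3, carriers=others, theme="hemolysin"),
                BlockSpec(2, theme="recombination"),
            ),
            planted_class="RGP_mob",
            carrier_site={"XB": 59, "PL": 59, "PA": 59},
            carrier_intercalate={"PL": 4, "PA": 4},
        )
    ]
    for gid in genome_ids:
        islands.append(
            IslandSpec(
                name=f"hs_{gid}",
                site=69,
                blocks=(BlockSpec(8, theme="metabolism"),),
                genome=gid,
                planted_class="RGP_none",
            )
        )
    return SimulationConfig(
        seed=seed,
        genome_ids=genome_ids,
        groups=groups,
        reference="XN",
        islands=tuple(islands),
        core_gene_names=((29, "typA"), (30, "treC"), (69, "trmE")),
    )


def translocation_config(seed: int = 3) -> SimulationConfig:
    """A comparison genome with a relocated (not absent) core block."""
    return SimulationConfig(
        seed=seed,
        islands=(),
        translocations=(TranslocationSpec(genome="AA2", start=40, n_genes=8, dest=90),),
    )


def shared_sites_config(seed: int = 11, n_sites: int = 3) -> SimulationConfig:
    """Several islands whose site is occupied in multiple genomes."""
    sites = (19, 39, 49)[:n_sites]
    islands = []
    for k, site in enumerate(sites):
        for gid in ("AA1", "AA2", "BB1"):
            islands.append(
                IslandSpec(
                    name=f"s{k}_{gid}",
                    site=site,
                    blocks=(BlockSpec(8, theme="generic"),),
                    genome=gid,
                    planted_class="RGP_none",
                )
            )
    return SimulationConfig(
        seed=seed, n_core=60, trna_positions=(15, 30), islands=tuple(islands)
    )


def scaled_entero_config(seed: int = 5) -> SimulationConfig:
    """A scaled-down eight-genome comparison set spanning all taxonomic
    tiers (two genera, a pathogen outgroup, a commensal outgroup), used
    for set-size scaling and distribution-tier checks."""
    genome_ids = ("AA1", "AA2", "BB1", "BB2", "PG1", "PG2", "PG3", "CM1")
    groups = (
        ("AA1", "same_genus"),
        ("AA2", "same_genus"),
        ("BB1", "other_genus"),
        ("BB2", "other_genus"),
        ("PG1", "pathogen"),
        ("PG2", "pathogen"),
        ("PG3", "pathogen"),
        ("CM1", "commensal"),
    )
    islands = (
        IslandSpec(
            name="i_genus",
            site=8,
            blocks=(
                BlockSpec(4, theme="generic"),
                BlockSpec(5, carriers=("AA2",), theme="metabolism"),
            ),
            planted_class="RGP_none",
        ),
        IslandSpec(
            name="i_pathogen",
            site=19,
            blocks=(BlockSpec(8, carriers=("BB1", "PG1"), theme="metabolism"),),
            planted_class="RGP_none",
        ),
        IslandSpec(
            name="i_family",
            site=28,
            blocks=(BlockSpec(8, carriers=("CM1",), theme="generic"),),
            planted_class="RGP_none",
        ),
        IslandSpec(
            name="i_strain",
            site=34,
            blocks=(BlockSpec(8, theme="generic"),),
            planted_class="RGP_none",
        ),
    )
    return SimulationConfig(
        seed=seed,
        genome_ids=genome_ids,
        groups=groups,
        n_core=40,
        trna_positions=(13,),
        islands=islands,
    )
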