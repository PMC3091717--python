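"""Module decomposition of RGPs and module-level scoring.

A module is a maximal run of contiguous RGP genes with a constant
conservation state, where the state of a gene is the set of
(genome, synteny-run) memberships of its ortholog pairs.  Two adjacent
conserved blocks with different partner runs therefore split into two
modules, and strain-specific stretches (empty state) form modules of
their own.  Modules are then scored for per-genome presence (the
"more than 80% (25%)" rule), functional class (eight-class keyword vote)
and taxonomic distribution, and matched against deletion intervals of
variant genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .detection import RGP, ReferenceContext
from .genome_io import GeneFeature, GenomeRecord
from .params import (
    DEFAULT_GROUP_SCHEME,
    FUNCTION_LEXICON,
    FUNCTIONAL_CLASSES,
    GroupScheme,
    ParameterSet,
)

__all__ = [
    "Module",
    "DeletionMatch",
    "conservation_states",
    "split_into_modules",
    "presence_call",
    "module_presence",
    "assign_functional_class",
    "assign_distribution_group",
    "match_deletion_to_modules",
    "modularize_all",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _letter(i: int) -> str:
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = _LETTERS[r] + out
    return out


@dataclass
class Module:
    """A contiguous gene block within an RGP."""

    module_id: str
    rgp_id: int
    replicon_id: str
    begin: int
    end: int
    genes: list[str]
    state: frozenset = frozenset()
    functional_class: str = "unknown"
    presence: dict[str, str] = field(default_factory=dict)
    distribution_group: str = ""

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def length(self) -> int:
        return self.end - self.begin

    @property
    def conserved(self) -> bool:
        return bool(self.state)


@dataclass
class DeletionMatch:
    """How a deletion interval of a variant genome maps onto modules."""

    replicon_id: str
    begin: int
    end: int
    matched_modules: list[str]
    match_type: str  # whole-module | sub-module | none
    left_offset: int | None = None  # deletion begin - first module begin
    right_offset: int | None = None  # deletion end - last module end


def conservation_states(ctx: ReferenceContext) -> dict[str, frozenset]:
    """Conservation state per reference gene: the frozen set of
    (genome_id, run_id) memberships over runs of >=2 pairs (conservation
    anywhere, displaced runs included)."""
    memberships: dict[str, set[tuple[str, str]]] = {}
    for gid, runs in ctx.runs.items():
        for run in runs:
            if run.n_pairs < 2:
                continue
            for p in run.pairs:
                memberships.setdefault(p.gene_a, set()).add((gid, run.run_id))
    return {g: frozenset(s) for g, s in memberships.items()}


def split_into_modules(
    rgp: RGP,
    ref: GenomeRecord,
    states: dict[str, frozenset],
) -> list[Module]:
    """Cut an RGP at every conservation-state change.

    Genes that cannot carry orthology information (tRNAs, pseudo genes)
    inherit the state of the preceding gene so they do not fragment a
    block on their own; a leading such gene joins the first block.
    """
    genes = [ref.gene(fid) for fid in rgp.genes]
    gene_states: list[frozenset] = []
    for g in genes:
        if not g.orthology_eligible:
            gene_states.append(gene_states[-1] if gene_states else None)
        else:
            gene_states.append(states.get(g.feature_id, frozenset()))
    # resolve a leading None (inherit forward from the first informative gene)
    first_state = next((s for s in gene_states if s is not None), frozenset())
    gene_states = [first_state if s is None else s for s in gene_states]

    modules: list[Module] = []
    block: list[GeneFeature] = [genes[0]]
    block_state = gene_states[0]
    for g, s in zip(genes[1:], gene_states[1:]):
        if s != block_state:
            modules.append(_make_module(rgp, block, block_state, len(modules)))
            block, block_state = [g], s
        else:
            block.append(g)
    modules.append(_make_module(rgp, block, block_state, len(modules)))
    return modules


def _make_module(
    rgp: RGP, block: list[GeneFeature], state: frozenset, index: int
) -> Module:
    return Module(
        module_id=f"{rgp.rgp_id}_{_letter(index)}",
        rgp_id=rgp.rgp_id,
        replicon_id=rgp.replicon_id,
        begin=block[0].begin,
        end=max(g.end for g in block),
        genes=[g.feature_id for g in block],
        state=state,
    )


def presence_call(n_hits: int, n_genes: int, params: ParameterSet | None = None) -> str:
    """present | partial | absent from a syntenic-ortholog fraction.

    Strict inequalities, exactly the "more than 80% (25%)" rule: present
    iff f > presence_hi, partial iff presence_lo < f <= presence_hi,
    absent iff f <= presence_lo.
    """
    params = params or ParameterSet()
    if n_genes == 0:
        return "absent"
    f = n_hits / n_genes
    if f > params.presence_hi:
        return "present"
    if f > params.presence_lo:
        return "partial"
    return "absent"


def module_presence(
    module: Module,
    target_id: str,
    ctx: ReferenceContext,
    params: ParameterSet | None = None,
) -> str:
    """Presence of a module in a target genome of the comparison set."""
    if target_id == ctx.reference.genome_id:
        return "present"
    conserved = ctx.conserved_anywhere[target_id]
    eligible = [
        fid for fid in module.genes if ctx.reference.gene(fid).orthology_eligible
    ]
    hits = sum(1 for fid in eligible if fid in conserved)
    return presence_call(hits, len(eligible), params)


def assign_functional_class(
    genes: list[GeneFeature],
    lexicon: dict[str, tuple[str, ...]] | None = None,
) -> str:
    """Plurality vote of per-gene keyword classes.

    Each gene votes for the first functional class (in priority order)
    whose keyword matches its product; ties break by the fixed class
    priority; no informative gene gives "unknown".
    """
    lexicon = lexicon or FUNCTION_LEXICON
    votes: dict[str, int] = {}
    for g in genes:
        product = g.product.lower()
        for cls in FUNCTIONAL_CLASSES:
            if cls == "unknown":
                continue
            if any(k in product for k in lexicon.get(cls, ())):
                votes[cls] = votes.get(cls, 0) + 1
                break
    if not votes:
        return "unknown"
    best = max(votes.values())
    for cls in FUNCTIONAL_CLASSES:  # priority order breaks ties
        if votes.get(cls) == best:
            return cls
    return "unknown"


def assign_distribution_group(
    presence: dict[str, str],
    self_id: str,
    group_map: dict[str, str],
    scheme: GroupScheme | None = None,
) -> str:
    """Widest taxonomic tier where the module is present outside itself.

    ``presence`` maps genome id to present/partial/absent; ``group_map``
    maps genome id to a group category.  Partial presence counts toward
    membership when the scheme says so (default).  A module seen in no
    other genome is a "strain" module.
    """
    scheme = scheme or DEFAULT_GROUP_SCHEME
    counted = {"present", "partial"} if scheme.count_partial else {"present"}
    best_tier = -1
    for gid, status in presence.items():
        if gid == self_id or status not in counted:
            continue
        tier = scheme.tier(group_map[gid])
        best_tier = max(best_tier, tier)
    if best_tier < 0:
        return scheme.strain_label
    return scheme.label_for_tier(best_tier)


def match_deletion_to_modules(
    deletions: list[tuple[str, int, int]],
    modules: list[Module],
    tolerance_bp: int | None = None,
    params: ParameterSet | None = None,
) -> list[DeletionMatch]:
    """Map deletion intervals of a variant genome onto module boundaries.

    A deletion is a whole-module(s) match when both of its boundaries lie
    within ``tolerance_bp`` of module boundaries and it covers an integer
    run of consecutive modules; any other overlap is a sub-module match.
    Boundary offsets are reported signed (deletion edge minus module edge).
    """
    params = params or ParameterSet()
    tol = params.deletion_tolerance_bp if tolerance_bp is None else tolerance_bp
    by_rep: dict[str, list[Module]] = {}
    for m in modules:
        by_rep.setdefault(m.replicon_id, []).append(m)
    for mods in by_rep.values():
        mods.sort(key=lambda m: m.begin)
    out: list[DeletionMatch] = []
    for rep, b, e in deletions:
        overlapped = [
            m for m in by_rep.get(rep, []) if m.begin < e and m.end > b
        ]
        if not overlapped:
            out.append(DeletionMatch(rep, b, e, [], "none"))
            continue
        first, last = overlapped[0], overlapped[-1]
        left_off = b - first.begin
        right_off = e - last.end
        contiguous = all(
            overlapped[i].rgp_id == overlapped[i + 1].rgp_id
            and overlapped[i].end <= overlapped[i + 1].begin
            for i in range(len(overlapped) - 1)
        )
        whole = abs(left_off) <= tol and abs(right_off) <= tol and contiguous
        out.append(
            DeletionMatch(
                rep,
                b,
                e,
                [m.module_id for m in overlapped],
                "whole-module" if whole else "sub-module",
                left_off,
                right_off,
            )
        )
    return out


def modularize_all(
    rgps: list[RGP],
    ctx: ReferenceContext,
    group_map: dict[str, str],
    params: ParameterSet | None = None,
    scheme: GroupScheme | None = None,
    lexicon: dict[str, tuple[str, ...]] | None = None,
) -> list[Module]:
    """Full module pass for one reference genome: split, score presence
    in every genome of the set, assign functional class and distribution
    group."""
    params = params or ParameterSet()
    states = conservation_states(ctx)
    self_id = ctx.reference.genome_id
    all_ids = [self_id] + ctx.comparison_ids
    modules: list[Module] = []
    for rgp in rgps:
        for m in split_into_modules(rgp, ctx.reference, states):
            m.presence = {
                gid: module_presence(m, gid, ctx, params) for gid in all_ids
            }
            m.functional_class = assign_functional_class(
                [ctx.reference.gene(fid) for fid in m.genes], lexicon
            )
            m.distribution_group = assign_distribution_group(
                m.presence, self_id, group_map, scheme
            )
            modules.append(m)
    return modules
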