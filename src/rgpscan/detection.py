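"""RGP detection by synteny breaks against a comparison genome set.

A region of genomic plasticity (RGP) on the reference chromosome is the
union of overlapping runs of consecutive genes that lack an in-place
syntenic ortholog in at least one comparison genome, cleaned of point
noise, snapped outward to the nearest core genes, and kept only when at
least 5 kb long.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genome_io import GeneFeature, GenomeRecord, GenomeSet
from .orthology import (
    OrthologTable,
    SyntenyRun,
    build_ortholog_table,
    find_synteny_runs,
    syntenic_gene_ids,
)
from .params import ParameterSet

__all__ = [
    "MissingSegment",
    "RGP",
    "ReferenceContext",
    "build_reference_context",
    "find_missing_segments",
    "merge_to_rgps",
    "homogenize_and_clean",
    "locate_flanks",
    "LEFT_SENTINEL",
    "RIGHT_SENTINEL",
]

LEFT_SENTINEL = "<replicon-start>"
RIGHT_SENTINEL = "<replicon-end>"


@dataclass(frozen=True)
class MissingSegment:
    """A maximal run of reference genes non-syntenic in one genome."""

    replicon_id: str
    begin: int
    end: int
    rank_begin: int
    rank_end: int  # inclusive
    absent_in: str

    @property
    def n_genes(self) -> int:
        return self.rank_end - self.rank_begin + 1


@dataclass
class RGP:
    """A reference-genome interval of genomic plasticity."""

    rgp_id: int
    replicon_id: str
    begin: int
    end: int
    genes: list[str]
    rank_begin: int
    rank_end: int  # inclusive
    left_flank: str = LEFT_SENTINEL
    right_flank: str = RIGHT_SENTINEL
    relocated: bool = False
    rgp_class: str = "unset"
    evidence: object | None = None

    @property
    def size(self) -> int:
        return self.end - self.begin

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def label(self, genome_tag: str) -> str:
        """Report-time name in the ``<class><n>_<TAG>`` style."""
        prefix = {
            "prophage": "P",
            "GI": "GI",
            "RGP_mob": "RGP",
            "RGP_none": "RGP",
            "unset": "RGP",
        }[self.rgp_class]
        return f"{prefix}{self.rgp_id}_{genome_tag}"


@dataclass
class ReferenceContext:
    """Per-reference bundle of ortholog tables and synteny information.

    ``syntenic_in_place[g]``: reference genes with a backbone syntenic
    ortholog in genome g (the break-of-synteny notion).
    ``conserved_anywhere[g]``: genes in a run of >=2 pairs anywhere in g
    (the module-conservation notion).
    """

    reference: GenomeRecord
    tables: dict[str, OrthologTable]
    runs: dict[str, list[SyntenyRun]]
    syntenic_in_place: dict[str, set[str]]
    conserved_anywhere: dict[str, set[str]]

    @property
    def comparison_ids(self) -> list[str]:
        return list(self.tables)

    def core_gene_ids(self) -> set[str]:
        """Genes with an in-place syntenic ortholog in every genome."""
        ids: set[str] | None = None
        for s in self.syntenic_in_place.values():
            ids = set(s) if ids is None else ids & s
        return ids or set()


def build_reference_context(
    genome_set: GenomeSet,
    params: ParameterSet | None = None,
    tables: dict[str, OrthologTable] | None = None,
    include_plasmids: bool = False,
) -> ReferenceContext:
    """Compute (or reuse) ortholog tables and synteny runs for a reference.

    ``tables`` maps comparison genome id to a precomputed table with the
    reference as genome_a; missing entries are computed here.
    """
    params = params or ParameterSet()
    ref = genome_set.reference
    tables = dict(tables or {})
    runs: dict[str, list[SyntenyRun]] = {}
    in_place: dict[str, set[str]] = {}
    anywhere: dict[str, set[str]] = {}
    circ_ref = {r.replicon_id for r in ref.replicons if r.topology == "circular"}
    for other in genome_set.comparisons:
        gid = other.genome_id
        if gid not in tables:
            tables[gid] = build_ortholog_table(
                ref, other, params, include_plasmids=include_plasmids
            )
        circ_other = {
            r.replicon_id for r in other.replicons if r.topology == "circular"
        }
        runs[gid] = find_synteny_runs(
            tables[gid], params, circular_a=circ_ref, circular_b=circ_other
        )
        in_place[gid] = syntenic_gene_ids(runs[gid], backbone_only=True)
        anywhere[gid] = syntenic_gene_ids(runs[gid], backbone_only=False)
    return ReferenceContext(
        reference=ref,
        tables=tables,
        runs=runs,
        syntenic_in_place=in_place,
        conserved_anywhere=anywhere,
    )


def find_missing_segments(
    ref: GenomeRecord,
    other_id: str,
    syntenic: set[str],
    params: ParameterSet | None = None,
    include_plasmids: bool = False,
) -> list[MissingSegment]:
    """Maximal runs of consecutive reference genes non-syntenic in a genome.

    ``syntenic`` is the in-place syntenic gene-id set for the pair.  Runs
    shorter than ``min_missing_run`` genes are discarded as point noise
    (isolated absences, annotation artifacts, lone tRNAs).
    """
    params = params or ParameterSet()
    segments: list[MissingSegment] = []
    for rep in ref.replicons:
        if rep.is_plasmid and not include_plasmids:
            continue
        genes = ref.genes_of(rep.replicon_id)
        run: list[GeneFeature] = []
        for g in genes:
            if g.feature_id in syntenic:
                if len(run) >= params.min_missing_run:
                    segments.append(_segment_from(run, other_id))
                run = []
            else:
                run.append(g)
        if len(run) >= params.min_missing_run:
            segments.append(_segment_from(run, other_id))
    return segments


def _segment_from(run: list[GeneFeature], other_id: str) -> MissingSegment:
    return MissingSegment(
        replicon_id=run[0].replicon_id,
        begin=run[0].begin,
        end=max(g.end for g in run),
        rank_begin=run[0].rank,
        rank_end=run[-1].rank,
        absent_in=other_id,
    )


def merge_to_rgps(
    segments: list[MissingSegment],
    ref: GenomeRecord,
    params: ParameterSet | None = None,
) -> list[RGP]:
    """Union overlapping / rank-adjacent missing segments into RGPs.

    Segments from different comparison genomes merge whenever their gene
    spans overlap or touch; merged regions shorter than ``min_rgp_len`` bp
    are dropped; survivors are numbered left to right.
    """
    params = params or ParameterSet()
    by_rep: dict[str, list[MissingSegment]] = {}
    for s in segments:
        by_rep.setdefault(s.replicon_id, []).append(s)
    rgps: list[RGP] = []
    counter = 0
    for rep in ref.replicons:  # keep replicon input order
        segs = sorted(
            by_rep.get(rep.replicon_id, []), key=lambda s: (s.rank_begin, s.rank_end)
        )
        if not segs:
            continue
        merged: list[tuple[int, int]] = []
        cur = [segs[0].rank_begin, segs[0].rank_end]
        for s in segs[1:]:
            if s.rank_begin <= cur[1] + 1:
                cur[1] = max(cur[1], s.rank_end)
            else:
                merged.append(tuple(cur))
                cur = [s.rank_begin, s.rank_end]
        merged.append(tuple(cur))
        genes = ref.genes_of(rep.replicon_id)
        for rb, re_ in merged:
            span = genes[rb : re_ + 1]
            begin, end = span[0].begin, max(g.end for g in span)
            if end - begin < params.min_rgp_len:
                continue
            rgps.append(
                RGP(
                    rgp_id=counter,
                    replicon_id=rep.replicon_id,
                    begin=begin,
                    end=end,
                    genes=[g.feature_id for g in span],
                    rank_begin=rb,
                    rank_end=re_,
                )
            )
            counter += 1
    return rgps


def homogenize_and_clean(
    rgps: list[RGP],
    ctx: ReferenceContext,
    params: ParameterSet | None = None,
) -> list[RGP]:
    """Snap RGP boundaries outward to the nearest core genes and re-filter.

    Boundaries extend to cover every gene between the flanking core genes
    (genes syntenic in all genomes of the set), which homogenizes
    boundaries across references; regions merged by the extension collapse
    into one; post-snap regions under ``min_rgp_len`` are dropped.  RGPs
    whose gene content is more than half composed of genes that are present
    elsewhere in some genome (displaced, not absent) are flagged
    ``relocated`` rather than deleted.
    """
    params = params or ParameterSet()
    ref = ctx.reference
    core = ctx.core_gene_ids()
    out: list[RGP] = []
    counter = 0
    for rep in ref.replicons:
        genes = ref.genes_of(rep.replicon_id)
        core_ranks = [g.rank for g in genes if g.feature_id in core]
        spans: list[tuple[int, int]] = []
        for rgp in rgps:
            if rgp.replicon_id != rep.replicon_id:
                continue
            left_cores = [r for r in core_ranks if r < rgp.rank_begin]
            right_cores = [r for r in core_ranks if r > rgp.rank_end]
            rb = (max(left_cores) + 1) if left_cores else 0
            re_ = (min(right_cores) - 1) if right_cores else len(genes) - 1
            spans.append((rb, re_))
        spans.sort()
        merged: list[list[int]] = []
        for rb, re_ in spans:
            if merged and rb <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], re_)
            else:
                merged.append([rb, re_])
        for rb, re_ in merged:
            span = genes[rb : re_ + 1]
            begin, end = span[0].begin, max(g.end for g in span)
            if end - begin < params.min_rgp_len:
                continue
            gene_ids = [g.feature_id for g in span]
            eligible = [g for g in span if g.orthology_eligible]
            relocated_genes = [
                g
                for g in eligible
                if any(
                    g.feature_id not in ctx.syntenic_in_place[gid]
                    and ctx.tables[gid].has_ortholog(g.feature_id)
                    for gid in ctx.comparison_ids
                )
            ]
            relocated = bool(eligible) and len(relocated_genes) > len(eligible) / 2
            rgp = RGP(
                rgp_id=counter,
                replicon_id=rep.replicon_id,
                begin=begin,
                end=end,
                genes=gene_ids,
                rank_begin=rb,
                rank_end=re_,
                relocated=relocated,
            )
            rgp.left_flank, rgp.right_flank = locate_flanks(rgp, ref, core)
            out.append(rgp)
            counter += 1
    return out


def locate_flanks(
    rgp: RGP, ref: GenomeRecord, core_gene_ids: set[str]
) -> tuple[str, str]:
    """Nearest core gene on each side of an RGP (sentinel at replicon ends).

    On circular replicons the search wraps around the origin.
    """
    rep = ref.replicon(rgp.replicon_id)
    genes = ref.genes_of(rgp.replicon_id)
    n = len(genes)
    circular = rep.topology == "circular"

    def _scan(start: int, step: int) -> str | None:
        i = start
        for _ in range(n):
            if circular:
                i %= n
            elif not 0 <= i < n:
                return None
            if genes[i].feature_id in core_gene_ids:
                return genes[i].feature_id
            i += step
        return None

    left = _scan(rgp.rank_begin - 1, -1)
    right = _scan(rgp.rank_end + 1, 1)
    return left or LEFT_SENTINEL, right or RIGHT_SENTINEL
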