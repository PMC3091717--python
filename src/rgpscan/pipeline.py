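"""End-to-end orchestration: I/O -> orthology -> detection -> composition
-> classification -> modularization -> hotspots -> reports.

Every stage result is kept on the :class:`PipelineResult` bundle and can be
serialized as tab-delimited tables; reruns on identical inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field

import pandas as pd

from .classification import classify_all
from .composition import CompositionProfile, composition_profile
from .detection import (
    RGP,
    ReferenceContext,
    build_reference_context,
    find_missing_segments,
    homogenize_and_clean,
    merge_to_rgps,
)
from .errors import ConfigError
from .genome_io import GenomeRecord, GenomeSet, write_table
from .hotspots import IntegrationSite, collect_integration_sites, find_hotspots
from .modularization import DeletionMatch, Module, match_deletion_to_modules, modularize_all
from .orthology import OrthologTable, build_ortholog_table
from .params import DEFAULT_GROUP_SCHEME, GroupScheme, ParameterSet

__all__ = ["PipelineResult", "run_pipeline", "summarize", "all_ortholog_tables"]


@dataclass
class PipelineResult:
    genome_set: GenomeSet
    params: ParameterSet
    tables: dict[tuple[str, str], OrthologTable]
    contexts: dict[str, ReferenceContext]
    rgps: dict[str, list[RGP]]
    modules: dict[str, list[Module]]
    profiles: dict[str, dict[str, CompositionProfile]]
    sites: list[IntegrationSite]
    hotspots: list[IntegrationSite]
    deletion_matches: dict[str, list[DeletionMatch]] = field(default_factory=dict)

    def rgp_frame(self, genome_id: str) -> pd.DataFrame:
        rows = []
        for r in self.rgps[genome_id]:
            ev = r.evidence.flags() if r.evidence is not None else {}
            rows.append(
                {
                    "rgp_id": r.label(genome_id),
                    "replicon": r.replicon_id,
                    "begin": r.begin,
                    "end": r.end,
                    "size": r.size,
                    "n_genes": r.n_genes,
                    "left_flank": r.left_flank,
                    "right_flank": r.right_flank,
                    "class": r.rgp_class,
                    "relocated": int(r.relocated),
                    **{f"ev_{k}": int(v) for k, v in ev.items()},
                }
            )
        return pd.DataFrame(rows)

    def module_frame(self, genome_id: str) -> pd.DataFrame:
        rows = []
        for m in self.modules[genome_id]:
            rows.append(
                {
                    "module_id": m.module_id,
                    "rgp_id": m.rgp_id,
                    "replicon": m.replicon_id,
                    "begin": m.begin,
                    "end": m.end,
                    "n_genes": m.n_genes,
                    "functional_class": m.functional_class,
                    "distribution_group": m.distribution_group,
                    **{f"in_{gid}": st for gid, st in m.presence.items()},
                }
            )
        return pd.DataFrame(rows)

    def hotspot_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.hotspots:
            rows.append(
                {
                    "site_id": s.site_id,
                    "site_type": s.site_type,
                    "n_genomes": s.n_genomes,
                    **{f"in_{gid}": occ for gid, occ in s.occupancy.items()},
                }
            )
        return pd.DataFrame(rows)


def all_ortholog_tables(
    genome_set: GenomeSet,
    params: ParameterSet,
    include_plasmids: bool = False,
) -> dict[tuple[str, str], OrthologTable]:
    """Ortholog tables for every ordered genome pair (computed once per
    unordered pair, mirrored by symmetry)."""
    genomes = genome_set.all_genomes
    tables: dict[tuple[str, str], OrthologTable] = {}
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            t = build_ortholog_table(ga, gb, params, include_plasmids)
            tables[(ga.genome_id, gb.genome_id)] = t
            tables[(gb.genome_id, ga.genome_id)] = t.swapped()
    return tables


def detect_rgps_for_reference(
    genome_set: GenomeSet,
    params: ParameterSet,
    tables: dict[tuple[str, str], OrthologTable] | None = None,
    include_plasmids: bool = False,
) -> tuple[ReferenceContext, list[RGP]]:
    """Detection stage for one reference genome (segments -> merge ->
    homogenize/clean, flanks recorded)."""
    ref_id = genome_set.reference.genome_id
    pre = None
    if tables is not None:
        pre = {
            other.genome_id: tables[(ref_id, other.genome_id)]
            for other in genome_set.comparisons
        }
    ctx = build_reference_context(
        genome_set, params, tables=pre, include_plasmids=include_plasmids
    )
    segments = []
    for other in genome_set.comparisons:
        segments.extend(
            find_missing_segments(
                ctx.reference,
                other.genome_id,
                ctx.syntenic_in_place[other.genome_id],
                params,
                include_plasmids,
            )
        )
    rgps = merge_to_rgps(segments, ctx.reference, params)
    rgps = homogenize_and_clean(rgps, ctx, params)
    return ctx, rgps


def run_pipeline(
    genome_set: GenomeSet,
    params: ParameterSet | None = None,
    scheme: GroupScheme | None = None,
    seed: int = 0,
    references: list[str] | None = None,
    external_prophages: dict[str, list[tuple[str, int, int]]] | None = None,
    deletions: dict[str, list[tuple[str, int, int]]] | None = None,
    include_plasmids: bool = False,
    outdir: str | None = None,
    log=None,
) -> PipelineResult:
    """Run every stage for each requested reference genome.

    ``references`` defaults to all genomes of the set (needed for hotspot
    analysis across genomes).  ``deletions`` maps a genome id to variant
    deletion intervals matched against that genome's modules.
    """
    params = params or ParameterSet()
    scheme = scheme or DEFAULT_GROUP_SCHEME
    if len(genome_set.all_genomes) < 2:
        raise ConfigError("the pipeline needs a reference plus >=1 comparison")
    log = log or (lambda msg: print(msg, file=sys.stderr))
    group_map = genome_set.group_map
    log(f"[rgpscan] genomes: {', '.join(group_map)}; params: {params}")

    tables = all_ortholog_tables(genome_set, params, include_plasmids)
    n_bbh = {k: len(t.bbh_pairs) for k, t in sorted(tables.items()) if k[0] < k[1]}
    log(f"[rgpscan] orthology: BBH pairs per genome pair: {n_bbh}")

    ref_ids = references or [g.genome_id for g in genome_set.all_genomes]
    contexts: dict[str, ReferenceContext] = {}
    rgps: dict[str, list[RGP]] = {}
    modules: dict[str, list[Module]] = {}
    profiles: dict[str, dict[str, CompositionProfile]] = {}
    for rid in ref_ids:
        sub = genome_set.with_reference(rid)
        ctx, found = detect_rgps_for_reference(sub, params, tables, include_plasmids)
        contexts[rid] = ctx
        genome = sub.reference
        profiles[rid] = {}
        for rep in genome.replicons:
            window = min(5000, rep.length)
            step = min(1000, window)
            profiles[rid][rep.replicon_id] = composition_profile(rep, window, step)
        classify_all(
            found,
            genome,
            profiles[rid],
            params,
            (external_prophages or {}).get(rid),
            seed=seed,
        )
        rgps[rid] = found
        modules[rid] = modularize_all(found, ctx, group_map, params, scheme)
        log(
            f"[rgpscan] {rid}: {len(found)} RGPs, "
            f"{len(modules[rid])} modules"
        )

    sites = collect_integration_sites(
        rgps, {g.genome_id: g for g in genome_set.all_genomes},
        {k: t for k, t in tables.items() if k[0] < k[1]}, params
    )
    hot = find_hotspots(sites, params)
    log(f"[rgpscan] {len(sites)} integration sites, {len(hot)} hotspots")

    deletion_matches: dict[str, list[DeletionMatch]] = {}
    for gid, intervals in (deletions or {}).items():
        deletion_matches[gid] = match_deletion_to_modules(
            intervals, modules.get(gid, []), params=params
        )

    result = PipelineResult(
        genome_set=genome_set,
        params=params,
        tables=tables,
        contexts=contexts,
        rgps=rgps,
        modules=modules,
        profiles=profiles,
        sites=sites,
        hotspots=hot,
        deletion_matches=deletion_matches,
    )
    if outdir is not None:
        serialize(result, outdir)
    return result


def serialize(result: PipelineResult, outdir: str) -> None:
    """Write every stage table under ``outdir`` (deterministic bytes)."""
    os.makedirs(outdir, exist_ok=True)
    for (a, b), t in sorted(result.tables.items()):
        if a < b:
            write_table(t.to_frame(), os.path.join(outdir, f"orthologs_{a}_{b}.tsv"))
    for gid in result.rgps:
        write_table(result.rgp_frame(gid), os.path.join(outdir, f"rgps_{gid}.tsv"))
        write_table(
            result.module_frame(gid), os.path.join(outdir, f"modules_{gid}.tsv")
        )
    for gid, ctx in result.contexts.items():
        rows = [
            {
                "run_id": run.run_id,
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "rank_a": p.rank_a,
                "rank_b": p.rank_b,
            }
            for other in sorted(ctx.runs)
            for run in ctx.runs[other]
            for p in run.pairs
        ]
        write_table(
            pd.DataFrame(rows, columns=["run_id", "gene_a", "gene_b", "rank_a", "rank_b"]),
            os.path.join(outdir, f"synteny_runs_{gid}.tsv"),
        )
    for gid, by_rep in result.profiles.items():
        for rep_id, profile in sorted(by_rep.items()):
            write_table(
                profile.to_frame(),
                os.path.join(outdir, f"composition_{gid}_{rep_id}.tsv"),
            )
    from .composition import per_cds_cai

    for genome in result.genome_set.all_genomes:
        if genome.genome_id in result.contexts:
            write_table(
                per_cds_cai(genome), os.path.join(outdir, f"cai_{genome.genome_id}.tsv")
            )
    write_table(result.hotspot_frame(), os.path.join(outdir, "hotspots.tsv"))
    for name, df in summarize(result).items():
        write_table(df, os.path.join(outdir, f"summary_{name}.tsv"))
    if result.deletion_matches:
        rows = []
        for gid, matches in sorted(result.deletion_matches.items()):
            for m in matches:
                rows.append(
                    {
                        "genome": gid,
                        "replicon": m.replicon_id,
                        "begin": m.begin,
                        "end": m.end,
                        "match_type": m.match_type,
                        "modules": ",".join(m.matched_modules),
                        "left_offset": m.left_offset,
                        "right_offset": m.right_offset,
                    }
                )
        write_table(pd.DataFrame(rows), os.path.join(outdir, "deletion_matches.tsv"))


def summarize(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Report tables: per-genome RGP counts and flexible-genome fraction,
    class composition, module functional classes, module distribution
    groups, and an RGP size histogram in 5 kb bins."""
    genomes = {g.genome_id: g for g in result.genome_set.all_genomes}
    overview_rows = []
    class_rows = []
    func_rows = []
    dist_rows = []
    hist_rows = []
    classes = ("prophage", "GI", "RGP_mob", "RGP_none")
    for gid, rgps in result.rgps.items():
        genome = genomes[gid]
        rgp_bp = sum(r.size for r in rgps)
        overview_rows.append(
            {
                "genome": gid,
                "genome_bp": genome.length,
                "n_rgps": len(rgps),
                "rgp_bp": rgp_bp,
                "flexible_pct": round(100.0 * rgp_bp / genome.length, 2),
            }
        )
        row = {"genome": gid}
        for cls in classes:
            n = sum(1 for r in rgps if r.rgp_class == cls)
            row[cls] = n
            row[f"{cls}_pct"] = round(100.0 * n / len(rgps), 1) if rgps else 0.0
        class_rows.append(row)
        mods = result.modules.get(gid, [])
        frow = {"genome": gid}
        for cls in sorted({m.functional_class for m in mods} | {"unknown"}):
            n = sum(1 for m in mods if m.functional_class == cls)
            frow[cls] = round(100.0 * n / len(mods), 1) if mods else 0.0
        func_rows.append(frow)
        drow = {"genome": gid}
        for lab in ("strain", "genus", "cross_genus", "pathogens", "family"):
            n = sum(1 for m in mods if m.distribution_group == lab)
            drow[lab] = round(100.0 * n / len(mods), 4) if mods else 0.0
        dist_rows.append(drow)
        for r in rgps:
            hist_rows.append({"genome": gid, "size_bin_kb": 5 * (r.size // 5000)})
    hist = (
        pd.DataFrame(hist_rows)
        .groupby(["genome", "size_bin_kb"])
        .size()
        .rename("n_rgps")
        .reset_index()
        if hist_rows
        else pd.DataFrame(columns=["genome", "size_bin_kb", "n_rgps"])
    )
    return {
        "overview": pd.DataFrame(overview_rows),
        "classes": pd.DataFrame(class_rows),
        "module_functions": pd.DataFrame(func_rows),
        "module_distribution": pd.DataFrame(dist_rows),
        "size_histogram": hist,
    }
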