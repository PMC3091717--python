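"""Integration-site analysis: RGPs grouped by orthologous flanking genes.

Every RGP registers at the site of each of its flanking core genes; sites
are identified with ortholog groups of flank genes across the genome set
(connected components of bidirectional best hits).  Sites occupied in at
least ``hotspot_min_genomes`` genomes are integration hotspots, split into
tRNA-sites and CDS-sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .detection import LEFT_SENTINEL, RIGHT_SENTINEL, RGP
from .genome_io import GenomeRecord
from .orthology import OrthologTable
from .params import ParameterSet

__all__ = ["IntegrationSite", "collect_integration_sites", "find_hotspots"]


@dataclass
class IntegrationSite:
    """An orthologous flanking-gene locus and its occupancy across genomes."""

    site_id: str
    site_type: str  # tRNA-site | CDS-site
    members: dict[str, list[str]]  # genome_id -> member gene ids
    occupants: list[tuple[str, int]]  # (genome_id, rgp_id)
    occupancy: dict[str, str]  # genome_id -> RGP label | "core genome" |
    #                                        "inside <label>" | "not present"

    @property
    def n_genomes(self) -> int:
        return len({g for g, _ in self.occupants})


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root choice
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def _near_trna(genome: GenomeRecord, gene_id: str, window: int) -> bool:
    g = genome.gene(gene_id)
    genes = genome.genes_of(g.replicon_id)
    n = len(genes)
    circular = genome.replicon(g.replicon_id).topology == "circular"
    for d in range(-window, window + 1):
        i = g.rank + d
        if circular:
            i %= n
        elif not 0 <= i < n:
            continue
        if genes[i].kind == "tRNA":
            return True
    return False


def collect_integration_sites(
    rgps_by_genome: dict[str, list[RGP]],
    genomes: dict[str, GenomeRecord],
    tables: dict[tuple[str, str], OrthologTable],
    params: ParameterSet | None = None,
) -> list[IntegrationSite]:
    """One site per ortholog group of RGP-flanking genes.

    ``tables`` holds ortholog tables for genome pairs (either orientation).
    An RGP contributes through both of its flanks; genomes whose member
    gene carries no RGP there are recorded as "core genome", or as
    "inside <rgp>" when the gene lies within another RGP.
    """
    params = params or ParameterSet()
    genome_order = list(rgps_by_genome)

    flank_genes: dict[str, set[str]] = {g: set() for g in genome_order}
    flank_rgps: dict[tuple[str, str], list[RGP]] = {}
    for gid, rgps in rgps_by_genome.items():
        for rgp in rgps:
            for flank in (rgp.left_flank, rgp.right_flank):
                if flank in (LEFT_SENTINEL, RIGHT_SENTINEL):
                    continue
                flank_genes[gid].add(flank)
                flank_rgps.setdefault((gid, flank), []).append(rgp)

    uf = _UnionFind()
    for (ga, gb), table in tables.items():
        for p in table.bbh_pairs:
            uf.union((ga, p.gene_a), (gb, p.gene_b))
    # components that contain at least one flank gene
    comp_members: dict[object, list[tuple[str, str]]] = {}
    for gid in genome_order:
        for fid in sorted(flank_genes[gid]):
            comp_members.setdefault(uf.find((gid, fid)), [])
    for gid in genome_order:
        for g in genomes[gid].genes:
            key = (gid, g.feature_id)
            root = uf.find(key)
            if root in comp_members:
                comp_members[root].append(key)

    sites: list[IntegrationSite] = []
    for root in sorted(comp_members, key=str):
        members_list = comp_members[root]
        members: dict[str, list[str]] = {}
        for gid, fid in members_list:
            members.setdefault(gid, []).append(fid)
        occupants: list[tuple[str, int]] = []
        occupancy: dict[str, str] = {}
        for gid in genome_order:
            if gid not in members:
                occupancy[gid] = "not present"
                continue
            rgps_here = []
            inside: str | None = None
            for fid in members[gid]:
                for rgp in flank_rgps.get((gid, fid), []):
                    rgps_here.append(rgp)
                if inside is None:
                    gene = genomes[gid].gene(fid)
                    for rgp in rgps_by_genome[gid]:
                        if (
                            rgp.replicon_id == gene.replicon_id
                            and rgp.rank_begin <= gene.rank <= rgp.rank_end
                        ):
                            inside = rgp.label(gid)
                            break
            if rgps_here:
                seen = sorted({r.rgp_id for r in rgps_here})
                occupants.extend((gid, rid) for rid in seen)
                occupancy[gid] = ",".join(
                    next(r for r in rgps_here if r.rgp_id == rid).label(gid)
                    for rid in seen
                )
            elif inside is not None:
                occupancy[gid] = f"inside {inside}"
            else:
                occupancy[gid] = "core genome"
        if not occupants:
            continue
        names = Counter(
            genomes[gid].gene(fid).name
            for gid, fid in members_list
            if genomes[gid].gene(fid).name
        )
        if names:
            site_id = names.most_common(1)[0][0]
        else:
            first_gid = next(g for g in genome_order if g in members)
            site_id = members[first_gid][0]
        trna = any(
            _near_trna(genomes[gid], fid, params.trna_flank_window)
            for gid, fid in members_list
        )
        sites.append(
            IntegrationSite(
                site_id=site_id,
                site_type="tRNA-site" if trna else "CDS-site",
                members=members,
                occupants=occupants,
                occupancy=occupancy,
            )
        )
    sites.sort(key=lambda s: (-s.n_genomes, s.site_id))
    return sites


def find_hotspots(
    sites: list[IntegrationSite], params: ParameterSet | None = None
) -> list[IntegrationSite]:
    """Sites occupied in at least ``hotspot_min_genomes`` genomes, sorted
    by occupancy breadth then site id."""
    params = params or ParameterSet()
    kept = [s for s in sites if s.n_genomes >= params.hotspot_min_genomes]
    kept.sort(key=lambda s: (-s.n_genomes, s.site_id))
    return kept
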