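"""Annotated-genome input and interval output.

Reads annotated bacterial genomes (GenBank flat files, or GFF3 plus FASTA)
into light-weight records of ordered gene features, and writes every
interval-bearing result type as GFF3, BED or TSV.

Coordinate conventions (bit-exact contract):

* internal coordinates are 0-based half-open ``[begin, end)``;
* GFF3 output is 1-based inclusive;
* BED output is 0-based half-open;
* a feature spanning the origin of a circular replicon is stored as its two
  sub-intervals and ranked by the first one, so gene order stays linear.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import EmptyAnnotationError, FormatError, UnknownRepliconError

__all__ = [
    "Replicon",
    "GeneFeature",
    "GenomeRecord",
    "GenomeSet",
    "read_genome",
    "write_regions",
    "read_regions",
    "write_table",
]


@dataclass(frozen=True)
class Replicon:
    """One chromosome or plasmid: sequence plus recorded topology."""

    replicon_id: str
    sequence: str
    topology: str = "linear"  # circular | linear; recorded, never inferred
    is_plasmid: bool = False

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise FormatError(f"unknown topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene feature with a stable rank in its replicon's gene order.

    ``parts`` holds the (begin, end) sub-intervals; origin-spanning features
    on circular replicons have two parts and take the rank of the first.
    ``begin``/``end`` describe the first part.
    """

    feature_id: str
    replicon_id: str
    begin: int
    end: int
    strand: int
    kind: str  # CDS | tRNA | rRNA | other
    product: str = ""
    protein: str | None = None
    name: str | None = None  # gene symbol, when annotated
    pseudo: bool = False
    partial: bool = False
    rank: int = -1
    parts: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.begin < self.end:
            raise FormatError(
                f"bad interval [{self.begin}, {self.end}) for {self.feature_id}"
            )
        if not self.parts:
            object.__setattr__(self, "parts", ((self.begin, self.end),))

    @property
    def length(self) -> int:
        return sum(e - b for b, e in self.parts)

    @property
    def orthology_eligible(self) -> bool:
        """CDS with a usable translation enter protein comparison."""
        return (
            self.kind == "CDS"
            and bool(self.protein)
            and not self.pseudo
            and not self.partial
        )


@dataclass
class GenomeRecord:
    """One annotated genome: ordered replicons and rank-sorted genes."""

    genome_id: str
    replicons: list[Replicon]
    genes: list[GeneFeature]
    group_label: str = "same_genus"

    def __post_init__(self) -> None:
        if not self.replicons:
            raise FormatError(f"genome {self.genome_id} has no replicon")
        self._by_id = {g.feature_id: g for g in self.genes}
        self._by_replicon: dict[str, list[GeneFeature]] = {
            r.replicon_id: [] for r in self.replicons
        }
        for g in self.genes:
            self._by_replicon[g.replicon_id].append(g)

    @property
    def length(self) -> int:
        return sum(r.length for r in self.replicons)

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise UnknownRepliconError(
            f"replicon {replicon_id!r} not in genome {self.genome_id}"
        )

    def gene(self, feature_id: str) -> GeneFeature:
        return self._by_id[feature_id]

    def genes_of(self, replicon_id: str) -> list[GeneFeature]:
        if replicon_id not in self._by_replicon:
            raise UnknownRepliconError(
                f"replicon {replicon_id!r} not in genome {self.genome_id}"
            )
        return self._by_replicon[replicon_id]

    def proteome(self, include_plasmids: bool = True) -> list[GeneFeature]:
        plasmids = {r.replicon_id for r in self.replicons if r.is_plasmid}
        return [
            g
            for g in self.genes
            if g.orthology_eligible
            and (include_plasmids or g.replicon_id not in plasmids)
        ]


@dataclass
class GenomeSet:
    """A reference genome plus an ordered comparison set."""

    reference: GenomeRecord
    comparisons: list[GenomeRecord]

    def __post_init__(self) -> None:
        if not self.comparisons:
            raise FormatError("a genome set needs at least one comparison genome")
        ids = [g.genome_id for g in self.all_genomes]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate genome ids in set: {ids}")

    @property
    def all_genomes(self) -> list[GenomeRecord]:
        return [self.reference] + self.comparisons

    @property
    def group_map(self) -> dict[str, str]:
        return {g.genome_id: g.group_label for g in self.all_genomes}

    def genome(self, genome_id: str) -> GenomeRecord:
        for g in self.all_genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def with_reference(self, genome_id: str) -> "GenomeSet":
        """Same set re-rooted on another member genome."""
        ref = self.genome(genome_id)
        others = [g for g in self.all_genomes if g.genome_id != genome_id]
        return GenomeSet(reference=ref, comparisons=others)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _assign_ranks(genes: list[GeneFeature]) -> list[GeneFeature]:
    """Sort genes per replicon by coordinate and assign consecutive ranks."""
    out: list[GeneFeature] = []
    by_rep: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_rep.setdefault(g.replicon_id, []).append(g)
    for rep_genes in by_rep.values():
        rep_genes.sort(key=lambda g: (g.begin, g.end, g.feature_id))
        for rank, g in enumerate(rep_genes):
            out.append(replace(g, rank=rank))
    return out


def _feature_from_seqfeature(
    feat, rec_id: str, rec_seq: str, n_genes: int
) -> GeneFeature | None:
    kind = _KINDS.get(feat.type)
    if kind is None:
        return None
    q = feat.qualifiers
    fid = (
        q.get("locus_tag", [None])[0]
        or q.get("protein_id", [None])[0]
        or q.get("gene", [None])[0]
        or f"{rec_id}_f{n_genes:05d}"
    )
    parts = tuple(
        sorted((int(p.start), int(p.end)) for p in feat.location.parts)
    )
    # Origin wrap: a part ending at the replicon end followed by one starting
    # at 0 keeps its two sub-intervals; the first (by coordinate-of-use) is
    # the one touching the sequence end.
    if len(parts) == 2 and parts[1][1] == len(rec_seq) and parts[0][0] == 0:
        parts = (parts[1], parts[0])
    begin, end = parts[0]
    pseudo = "pseudo" in q or "pseudogene" in q
    partial = "<" in str(feat.location) or ">" in str(feat.location)
    protein = None
    if kind == "CDS" and not pseudo:
        protein = q.get("translation", [None])[0]
        if protein is None and not partial:
            try:
                protein = str(
                    feat.extract(Seq(rec_seq)).translate(table=11, cds=False)
                ).rstrip("*")
            except Exception:
                protein = None
        if protein is not None and ("*" in protein or not protein):
            protein = None
    return GeneFeature(
        feature_id=fid,
        replicon_id=rec_id,
        begin=begin,
        end=end,
        strand=-1 if feat.location.strand == -1 else 1,
        kind=kind,
        product=q.get("product", [""])[0],
        protein=protein,
        name=q.get("gene", [None])[0],
        pseudo=pseudo,
        partial=partial,
        parts=parts,
    )


def _read_genbank(path: str, genome_id: str | None) -> GenomeRecord:
    try:
        records = list(SeqIO.parse(path, "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subtypes
        raise FormatError(f"cannot parse {path} as GenBank: {exc}") from exc
    if not records:
        raise FormatError(f"no records in {path}")
    replicons: list[Replicon] = []
    genes: list[GeneFeature] = []
    for rec in records:
        seq = str(rec.seq).upper()
        topology = rec.annotations.get("topology", "linear")
        is_plasmid = "plasmid" in (rec.description or "").lower()
        replicons.append(
            Replicon(
                replicon_id=rec.id,
                sequence=seq,
                topology=topology if topology in ("circular", "linear") else "linear",
                is_plasmid=is_plasmid,
            )
        )
        for feat in rec.features:
            gf = _feature_from_seqfeature(feat, rec.id, seq, len(genes))
            if gf is not None:
                genes.append(gf)
    if not genes:
        raise EmptyAnnotationError(f"{path} contains no gene features")
    gid = genome_id or os.path.splitext(os.path.basename(path))[0]
    return GenomeRecord(genome_id=gid, replicons=replicons, genes=_assign_ranks(genes))


def _read_gff3_fasta(
    gff_path: str, fasta_path: str, genome_id: str | None
) -> GenomeRecord:
    import gffutils

    try:
        seqs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")
        }
    except Exception as exc:
        raise FormatError(f"cannot parse {fasta_path} as FASTA: {exc}") from exc
    if not seqs:
        raise FormatError(f"no sequences in {fasta_path}")
    with open(gff_path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            raise EmptyAnnotationError(f"{gff_path} contains no gene features")
    try:
        db = gffutils.create_db(
            gff_path,
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise FormatError(f"cannot parse {gff_path} as GFF3: {exc}") from exc
    genes: list[GeneFeature] = []
    for ftype, kind in (("CDS", "CDS"), ("tRNA", "tRNA"), ("rRNA", "rRNA")):
        for feat in db.features_of_type(ftype):
            if feat.seqid not in seqs:
                raise FormatError(
                    f"GFF3 feature on unknown sequence {feat.seqid!r}"
                )
            begin, end = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
            fid = (
                feat.attributes.get("locus_tag", [None])[0]
                or feat.attributes.get("ID", [None])[0]
                or f"{feat.seqid}_f{len(genes):05d}"
            )
            pseudo = "pseudo" in feat.attributes
            partial = "partial" in feat.attributes
            protein = None
            if kind == "CDS" and not pseudo and not partial:
                dna = seqs[feat.seqid][begin:end]
                if feat.strand == "-":
                    dna = str(Seq(dna).reverse_complement())
                try:
                    protein = str(Seq(dna).translate(table=11)).rstrip("*")
                except Exception:
                    protein = None
                if protein is not None and ("*" in protein or not protein):
                    protein = None
            genes.append(
                GeneFeature(
                    feature_id=fid,
                    replicon_id=feat.seqid,
                    begin=begin,
                    end=end,
                    strand=-1 if feat.strand == "-" else 1,
                    kind=kind,
                    product=feat.attributes.get("product", [""])[0],
                    protein=protein,
                    name=feat.attributes.get("gene", [None])[0],
                    pseudo=pseudo,
                    partial=partial,
                )
            )
    if not genes:
        raise EmptyAnnotationError(f"{gff_path} contains no gene features")
    replicons = [
        Replicon(replicon_id=rid, sequence=seq, topology="linear")
        for rid, seq in seqs.items()
    ]
    gid = genome_id or os.path.splitext(os.path.basename(fasta_path))[0]
    return GenomeRecord(genome_id=gid, replicons=replicons, genes=_assign_ranks(genes))


def read_genome(
    path: str,
    format: str = "genbank",
    fasta_path: str | None = None,
    genome_id: str | None = None,
    group_label: str = "same_genus",
) -> GenomeRecord:
    """Read an annotated genome.

    Parameters
    ----------
    path:
        GenBank flat file, or the GFF3 file when ``format="gff3+fasta"``.
    format:
        ``"genbank"`` or ``"gff3+fasta"``.
    fasta_path:
        Nucleotide FASTA, required for ``gff3+fasta``.
    genome_id:
        Short tag for the genome; defaults to the file stem.
    group_label:
        Taxonomic category used by module distribution classification
        (one of :data:`rgpscan.params.GROUP_CATEGORIES`).
    """
    if format == "genbank":
        rec = _read_genbank(path, genome_id)
    elif format == "gff3+fasta":
        if fasta_path is None:
            raise FormatError("gff3+fasta format needs fasta_path")
        rec = _read_gff3_fasta(path, fasta_path, genome_id)
    else:
        raise FormatError(f"unknown genome format {format!r}")
    rec.group_label = group_label
    return rec


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _region_fields(region) -> tuple[str, str, int, int, str]:
    """(id, replicon, begin, end, class) from any interval-bearing result."""
    rid = getattr(region, "region_id", None) or getattr(region, "rgp_id", None)
    rid = rid if rid is not None else getattr(region, "module_id", None)
    if rid is None:
        rid = region[0] if isinstance(region, (tuple, list)) else "region"
    cls = getattr(region, "rgp_class", None) or getattr(region, "kind", "") or ""
    return (
        str(rid),
        region.replicon_id,
        int(region.begin),
        int(region.end),
        str(cls),
    )


def write_regions(
    regions: Sequence,
    path: str,
    format: str = "tsv",
    genome: GenomeRecord | None = None,
) -> None:
    """Write interval-bearing results as GFF3, BED or TSV.

    GFF3 is written 1-based inclusive, BED 0-based half-open; a round-trip
    through :func:`read_regions` reproduces (id, replicon, begin, end)
    exactly.  When ``genome`` is given, replicon ids are validated.
    """
    rows = [_region_fields(r) for r in regions]
    if genome is not None:
        known = {r.replicon_id for r in genome.replicons}
        for rid, rep, *_ in rows:
            if rep not in known:
                raise UnknownRepliconError(
                    f"region {rid} references unknown replicon {rep!r}"
                )
    buf = io.StringIO()
    if format == "gff3":
        buf.write("##gff-version 3\n")
        for rid, rep, b, e, cls in rows:
            attrs = f"ID={rid}" + (f";rgp_class={cls}" if cls else "")
            buf.write(
                f"{rep}\trgpscan\tregion\t{b + 1}\t{e}\t.\t.\t.\t{attrs}\n"
            )
    elif format == "bed":
        for rid, rep, b, e, cls in rows:
            name = rid if not cls else f"{rid}|{cls}"
            buf.write(f"{rep}\t{b}\t{e}\t{name}\n")
    elif format == "tsv":
        buf.write("# region_id\treplicon\tbegin\tend\tclass\n")
        for rid, rep, b, e, cls in rows:
            buf.write(f"{rid}\t{rep}\t{b}\t{e}\t{cls}\n")
    else:
        raise FormatError(f"unknown region format {format!r}")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_regions(path: str, format: str = "tsv") -> list[tuple[str, str, int, int, str]]:
    """Read a region file written by :func:`write_regions`.

    Returns (id, replicon, begin, end, class) tuples in internal (0-based
    half-open) coordinates regardless of the on-disk convention.
    """
    out: list[tuple[str, str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if format == "gff3":
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                out.append(
                    (
                        attrs.get("ID", ""),
                        cols[0],
                        int(cols[3]) - 1,
                        int(cols[4]),
                        attrs.get("rgp_class", ""),
                    )
                )
            elif format == "bed":
                name, _, cls = cols[3].partition("|")
                out.append((name, cols[0], int(cols[1]), int(cols[2]), cls))
            elif format == "tsv":
                out.append((cols[0], cols[1], int(cols[2]), int(cols[3]), cols[4]))
            else:
                raise FormatError(f"unknown region format {format!r}")
    return out


def write_table(df, path: str) -> None:
    """Write a DataFrame as tab-delimited text with a commented header."""
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
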