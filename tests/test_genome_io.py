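"""Genome reading, interval writing, and coordinate conventions."""

import re

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from hypothesis import given
from hypothesis import strategies as st

from rgpscan.errors import EmptyAnnotationError, FormatError, UnknownRepliconError
from rgpscan.genome_io import read_genome, read_regions, write_regions
from rgpscan.simulate import default_config, generate_genome_set, write_genome_set

from toys import make_genome


@pytest.fixture(scope="module")
def genbank_path(tmp_path_factory):
    gset, _ = generate_genome_set(default_config(seed=2))
    outdir = tmp_path_factory.mktemp("gbk")
    paths = write_genome_set(gset, None, str(outdir))
    return paths[0], gset.all_genomes[0]


def test_genbank_reader_matches_independent_flat_file_scan(genbank_path):
    """Feature count/order agree with a raw text scan of the flat file."""
    path, original = genbank_path
    genome = read_genome(path)
    # independent scan: count feature headers and coordinates in raw text
    text = open(path).read()
    spans = re.findall(
        r"^     (CDS|tRNA)\s+(?:complement\()?(\d+)\.\.(\d+)\)?\s*$",
        text,
        flags=re.M,
    )
    assert len(genome.genes) == len(spans)
    scanned = sorted((int(b) - 1, int(e)) for _, b, e in spans)
    parsed = sorted((g.begin, g.end) for g in genome.genes)
    assert parsed == scanned
    assert genome.length == original.length


def test_ranks_are_consecutive_and_coordinate_sorted(genbank_path):
    path, _ = genbank_path
    genome = read_genome(path)
    for rep in genome.replicons:
        genes = genome.genes_of(rep.replicon_id)
        assert [g.rank for g in genes] == list(range(len(genes)))
        begins = [g.begin for g in genes]
        assert begins == sorted(begins)


def test_topology_and_translations_recorded(genbank_path):
    path, original = genbank_path
    genome = read_genome(path)
    assert all(r.topology == "circular" for r in genome.replicons)
    for g, o in zip(genome.genes, original.genes):
        assert g.protein == o.protein
        assert g.kind == o.kind


def test_empty_annotation_raises(tmp_path):
    gff = tmp_path / "x.gff3"
    gff.write_text("##gff-version 3\n")
    fasta = tmp_path / "x.fa"
    fasta.write_text(">chr1\nACGTACGTACGT\n")
    with pytest.raises(EmptyAnnotationError):
        read_genome(str(gff), format="gff3+fasta", fasta_path=str(fasta))


def test_unparseable_file_raises_format_error(tmp_path):
    bad = tmp_path / "bad.gbk"
    bad.write_text("this is not a genbank file\n")
    with pytest.raises((FormatError, EmptyAnnotationError)):
        read_genome(str(bad))


def test_gff3_fasta_reader_translates_cds(tmp_path):
    dna = "ATGGCTGCTGCTTAA"  # M A A A *
    fasta = tmp_path / "g.fa"
    fasta.write_text(f">chr1\n{dna}GGGGCCCC\n")
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tCDS\t1\t15\t.\t+\t0\tID=cds1;locus_tag=tag1;product=demo\n"
    )
    genome = read_genome(str(gff), format="gff3+fasta", fasta_path=str(fasta))
    (g,) = genome.genes
    assert (g.feature_id, g.begin, g.end, g.protein) == ("tag1", 0, 15, "MAAA")


def test_origin_spanning_feature_stored_as_two_parts(tmp_path):
    seq = "ATG" * 400
    rec = SeqRecord(
        Seq(seq),
        id="circ1",
        name="circ1",
        description="",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    loc = CompoundLocation(
        [FeatureLocation(1100, 1200, strand=1), FeatureLocation(0, 40, strand=1)]
    )
    rec.features.append(
        SeqFeature(loc, type="CDS", qualifiers={"locus_tag": ["wrap"],
                                                "translation": ["MW"]})
    )
    rec.features.append(
        SeqFeature(FeatureLocation(500, 620, strand=1), type="CDS",
                   qualifiers={"locus_tag": ["mid"], "translation": ["MA"]})
    )
    path = tmp_path / "circ.gbk"
    SeqIO.write([rec], str(path), "genbank")
    genome = read_genome(str(path))
    wrap = genome.gene("wrap")
    assert wrap.parts == ((1100, 1200), (0, 40))
    assert (wrap.begin, wrap.end) == (1100, 1200)  # ranked by first part
    assert wrap.rank > genome.gene("mid").rank
    assert wrap.length == 140


def test_region_write_conventions(tmp_path):
    genome = make_genome("A", n_genes=2)

    class R:
        region_id, replicon_id, begin, end = "r1", "A_chr", 999, 2000
        rgp_class = "GI"

    for fmt, expect in [
        ("gff3", ("\t1000\t2000\t")),
        ("bed", ("A_chr\t999\t2000\t")),
    ]:
        path = tmp_path / f"out.{fmt}"
        write_regions([R()], str(path), format=fmt, genome=genome)
        assert expect in path.read_text()


@given(
    st.lists(
        st.tuples(st.integers(0, 10_000), st.integers(1, 3000)),
        min_size=1,
        max_size=6,
        unique_by=lambda t: t[0],
    ),
    st.sampled_from(["gff3", "bed", "tsv"]),
)
def test_region_round_trip_is_identity(entries, fmt):
    """write_regions then read_regions reproduces intervals exactly."""
    import tempfile

    regions = []
    for i, (b, length) in enumerate(entries):

        class R:
            pass

        r = R()
        r.region_id, r.replicon_id = f"r{i}", "chr"
        r.begin, r.end = b, b + length
        r.rgp_class = "GI"
        regions.append(r)
    with tempfile.TemporaryDirectory() as d:
        path = f"{d}/regions.txt"
        write_regions(regions, path, format=fmt)
        back = read_regions(path, format=fmt)
    assert [(x[0], x[1], x[2], x[3]) for x in back] == [
        (r.region_id, r.replicon_id, r.begin, r.end) for r in regions
    ]


def test_unknown_replicon_rejected(tmp_path):
    genome = make_genome("A", n_genes=1)

    class R:
        region_id, replicon_id, begin, end, rgp_class = "r", "nope", 0, 10, ""

    with pytest.raises(UnknownRepliconError):
        write_regions([R()], str(tmp_path / "x.tsv"), genome=genome)
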