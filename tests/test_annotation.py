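"""Region-model construction, UTR extension and sequence-context queries."""

import pytest

from dartcall.annotation import (
    GenomeSequence,
    GtfParseError,
    extend_utr3,
    parse_annotation,
    reverse_complement,
    write_gtf,
)
from tests.conftest import mirror_dataset, write_fasta

GTF_PLUS = (
    'chr1\tt\texon\t1\t100\t.\t{s}\t.\tgene_id "g1"; transcript_id "g1.t1";\n'
    'chr1\tt\texon\t201\t300\t.\t{s}\t.\tgene_id "g1"; transcript_id "g1.t1";\n'
    'chr1\tt\tCDS\t51\t100\t.\t{s}\t.\tgene_id "g1"; transcript_id "g1.t1";\n'
    'chr1\tt\tCDS\t201\t250\t.\t{s}\t.\tgene_id "g1"; transcript_id "g1.t1";\n'
)


def _write(tmp_path, text, name="a.gtf"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_cds_partition_plus_strand(tmp_path):
    ann = parse_annotation(_write(tmp_path, GTF_PLUS.format(s="+")))
    m = ann.genes["g1"]
    assert m.utr5 == [(0, 50)]
    assert m.cds == [(50, 100), (200, 250)]
    assert m.utr3 == [(250, 300)]
    assert m.region_lengths == {"utr5": 50, "cds": 100, "utr3": 50}


def test_cds_partition_minus_strand_swaps_ends(tmp_path):
    ann = parse_annotation(_write(tmp_path, GTF_PLUS.format(s="-")))
    m = ann.genes["g1"]
    # transcript order is descending genomic coordinate
    assert m.utr5 == [(250, 300)]
    assert m.cds == [(200, 250), (50, 100)]
    assert m.utr3 == [(0, 50)]


def test_representative_transcript_is_longest(tmp_path):
    text = (
        'chr1\tt\texon\t1\t300\t.\t+\t.\tgene_id "g"; transcript_id "short";\n'
        'chr1\tt\texon\t1\t500\t.\t+\t.\tgene_id "g"; transcript_id "long";\n'
    )
    ann = parse_annotation(_write(tmp_path, text))
    assert ann.representative_transcript["g"] == "long"
    assert ann.genes["g"].exons == [(0, 500)]
    # independent check by enumerating both transcripts
    lengths = {"short": 300, "long": 500}
    assert max(lengths, key=lengths.get) == "long"


def test_representative_tie_breaks_lexicographically(tmp_path):
    text = (
        'chr1\tt\texon\t1\t300\t.\t+\t.\tgene_id "g"; transcript_id "tB";\n'
        'chr1\tt\texon\t1\t300\t.\t+\t.\tgene_id "g"; transcript_id "tA";\n'
    )
    ann = parse_annotation(_write(tmp_path, text))
    assert ann.representative_transcript["g"] == "tA"


def test_noncoding_gene_has_empty_regions(tmp_path):
    text = 'chr1\tt\texon\t1\t200\t.\t+\t.\tgene_id "nc"; transcript_id "nc.t";\n'
    m = parse_annotation(_write(tmp_path, text)).genes["nc"]
    assert not m.coding and m.utr5 == [] and m.utr3 == []
    with pytest.raises(ValueError):
        m.locate(10)


@pytest.mark.parametrize(
    "bad",
    [
        "chr1\tt\texon\t1\t100\t.\t+\t.\n",  # 8 fields
        'chr1\tt\texon\tx\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n',
        'chr1\tt\texon\t1\t100\t.\t+\t.\tgene_id "g";\n',  # no transcript_id
    ],
)
def test_malformed_gtf_names_line(tmp_path, bad):
    path = _write(tmp_path, 'chr1\tt\texon\t1\t50\t.\t+\t.\tgene_id "g"; '
                            'transcript_id "t";\n' + bad)
    with pytest.raises(GtfParseError, match="line 2"):
        parse_annotation(path)


def test_exon_beyond_chromosome_rejected(tmp_path):
    path = _write(tmp_path, GTF_PLUS.format(s="+"))
    with pytest.raises(GtfParseError):
        parse_annotation(path, chrom_lengths={"chr1": 250})


def test_extend_utr3_plus_and_clip(tmp_path):
    ann = parse_annotation(_write(tmp_path, GTF_PLUS.format(s="+")),
                           chrom_lengths={"chr1": 10000})
    # gene ends at 300; small genome stands in for the 1000-end example
    ext = extend_utr3(ann, 5000)
    assert ext.genes["g1"].utr3 == [(250, 300), (300, 5300)]
    clipped = extend_utr3(ann, 9900)
    assert clipped.genes["g1"].utr3[-1] == (300, 10000)
    assert extend_utr3(ann, 0).genes["g1"].utr3 == [(250, 300)]
    with pytest.raises(ValueError):
        extend_utr3(ann, -1)


def test_extend_utr3_minus_strand_goes_left(tmp_path):
    ann = parse_annotation(_write(tmp_path, GTF_PLUS.format(s="-")),
                           chrom_lengths={"chr1": 10000})
    ext = extend_utr3(ann, 5000)
    assert ext.genes["g1"].utr3[-1] == (0, 0) or ext.genes["g1"].utr3[-1][0] == 0
    # annotated utr3 is [0,50): extension clips at chromosome start
    assert ext.genes["g1"].utr3 == [(0, 50)]  # nothing to add below 0


def test_context_queries(tmp_path):
    fa = write_fasta(tmp_path / "g.fa", {"c": "TTGACTT"})
    g = GenomeSequence(fa)
    assert g.context("c", 4, "+", up=2, down=0) == "GAC"  # C at pos 4
    assert g.context("c", 4, "+", up=0, down=0) == "C"
    assert g.base("c", 2, "-") == "C"  # plus-strand G
    with pytest.raises(IndexError):
        g.context("c", 1, "+", up=2, down=0)


def test_minus_strand_context_is_reverse_complement(tmp_path):
    # plus strand reads GTC; the minus-strand transcript context is GAC
    fa = write_fasta(tmp_path / "g.fa", {"c": "TTGTCTT"})
    g = GenomeSequence(fa)
    assert g.context("c", 2, "-", up=2, down=0) == "GAC"
    assert reverse_complement("GTC") == "GAC"


def test_gtf_round_trip(sim_small, tmp_path):
    ann = parse_annotation(sim_small.gtf_path)
    out = tmp_path / "rt.gtf"
    write_gtf(ann, out)
    again = parse_annotation(out)
    assert set(again.genes) == set(ann.genes)
    for gid in ann.genes:
        a, b = ann.genes[gid], again.genes[gid]
        assert (a.exons, a.utr5, a.cds, a.utr3) == (b.exons, b.utr5, b.cds, b.utr3)


def test_regions_are_disjoint_on_simulated_genome(sim_small):
    for m in sim_small.annotation.genes.values():
        covered = set()
        for region in ("utr5", "cds", "utr3"):
            for s, e in getattr(m, region):
                block = set(range(s, e))
                assert not covered & block
                covered |= block
        assert m.region_lengths["cds"] > 0


def test_mirrored_genome_gives_mirrored_models(sim_small, tmp_path):
    mirror = mirror_dataset(sim_small.fasta_path, sim_small.gtf_path, None, tmp_path)
    ann = parse_annotation(sim_small.gtf_path)
    m_ann = parse_annotation(mirror["gtf"])
    L = mirror["lengths"]["chrSim"]
    for gid, m in ann.genes.items():
        mm = m_ann.genes[gid]
        assert mm.strand != m.strand
        assert mm.region_lengths == m.region_lengths
        assert sorted((L - e, L - s) for s, e in m.exons) == mm.exons
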