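"""Shared fixtures: tiny hand-built genomes/annotations and simulated data."""

from __future__ import annotations

from pathlib import Path

import pytest

from dartcall.annotation import GenomeSequence, parse_annotation
from dartcall.pileup import EditingTable
from dartcall.simulate import simulate_genome


def write_fasta(path, seqs: dict[str, str]):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    return path


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """Six-gene genome with short UTR extension; reused across tests."""
    out = tmp_path_factory.mktemp("sim_small")
    return simulate_genome(out, n_genes=6, seed=3, utr3_extension=500)


@pytest.fixture(scope="session")
def sim_small_genome(sim_small):
    return GenomeSequence(sim_small.fasta_path)


# ---------------------------------------------------------------------------
# Hand-constructed filter-boundary dataset: one plus-strand gene on chrT with
# twelve editable positions, each probing one threshold of the cascade.
# ---------------------------------------------------------------------------

BOUNDARY_POSITIONS = [20 * i for i in range(1, 13)]  # site i at pos 20*i

# per site: (wt1 (e,u), wt2 (e,u), ko1 (e,u), ko2 (e,u))
_D = {
    1: ((5, 44), (5, 44), (0, 50), (0, 50)),  # coverage 49 -> fail
    2: ((5, 45), (5, 45), (0, 50), (0, 50)),  # coverage 50, rate 10 -> pass
    3: ((2, 98), (2, 98), (0, 50), (0, 50)),  # edited 2 -> fail
    4: ((9, 991), (9, 991), (0, 50), (0, 50)),  # rate 0.9 -> fail
    5: ((10, 990), (10, 990), (0, 50), (0, 50)),  # rate 1.0 -> pass
    6: ((950, 50), (950, 50), (0, 50), (0, 50)),  # rate 95.0 -> pass
    7: ((951, 49), (951, 49), (0, 50), (0, 50)),  # rate 95.1 -> fail
    8: ((10, 90), (10, 90), (4, 46), (0, 50)),  # fold exactly 1.25 -> pass
    9: ((10, 90), (10, 90), (81, 919), (0, 50)),  # fold 1.235 < 1.25 -> fail
    10: ((10, 90), (4, 36), (0, 50), (0, 50)),  # called in one replicate only
    11: ((10, 90), (10, 90), (0, 50), (0, 50)),  # non-RAC context (TAC)
    12: ((6, 94), (6, 94), (81, 1919), (81, 1919)),  # WT/KO mean 6/4.05 < 1.5x
}

BOUNDARY_EXPECT = {
    "candidates_rep1": {2, 5, 6, 8, 10, 11, 12},
    "candidates_rep2": {2, 5, 6, 8, 11, 12},
    "merged": {2, 5, 6, 8, 11, 12},
    "rac": {2, 5, 6, 8, 12},
    "high_confidence": {2, 5, 6, 8},
}


def _table(sample_id, col):
    pos = [BOUNDARY_POSITIONS[i - 1] for i in sorted(_D)]
    e = [_D[i][col][0] for i in sorted(_D)]
    u = [_D[i][col][1] for i in sorted(_D)]
    return EditingTable.from_counts(
        sample_id, ["chrT"] * len(pos), pos, ["+"] * len(pos), ["gT"] * len(pos), e, u
    )


@pytest.fixture(scope="session")
def boundary_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("boundary")
    seq = ["T"] * 400
    for i, p in enumerate(BOUNDARY_POSITIONS, start=1):
        motif = "TAC" if i == 11 else "GAC"
        seq[p - 2 : p + 1] = list(motif)
    fasta = write_fasta(out / "chrT.fa", {"chrT": "".join(seq)})
    gtf = out / "chrT.gtf"
    gtf.write_text(
        'chrT\ttest\texon\t1\t400\t.\t+\t.\tgene_id "gT"; transcript_id "gT.t1";\n'
        'chrT\ttest\tCDS\t101\t300\t.\t+\t.\tgene_id "gT"; transcript_id "gT.t1";\n'
    )
    genome = GenomeSequence(fasta)
    ann = parse_annotation(gtf, chrom_lengths=genome.lengths)
    wt = {"wt1": _table("wt1", 0), "wt2": _table("wt2", 1)}
    ko = {"ko1": _table("ko1", 2), "ko2": _table("ko2", 3)}
    return {"genome": genome, "annotation": ann, "wt": wt, "ko": ko}


def sites_of(df) -> set[int]:
    return {p // 20 for p in df["pos"]}


# ---------------------------------------------------------------------------
# Mirror transform: reverse-complement the genome, mirror annotation and
# alignments.  Used for the strand-symmetry properties.
# ---------------------------------------------------------------------------


def mirror_dataset(fasta_path, gtf_path, sam_path, out_dir) -> dict:
    from dartcall.annotation import reverse_complement

    out_dir = Path(out_dir)
    out_dir.mkdir(exist_ok=True)
    seqs = {}
    name = None
    for line in Path(fasta_path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        else:
            seqs[name].append(line.strip())
    seqs = {n: "".join(parts) for n, parts in seqs.items()}
    lengths = {n: len(s) for n, s in seqs.items()}
    m_fasta = write_fasta(
        out_dir / "mirror.fa", {n: reverse_complement(s) for n, s in seqs.items()}
    )
    flip = {"+": "-", "-": "+"}
    lines = []
    for line in Path(gtf_path).read_text().splitlines():
        f = line.split("\t")
        L = lengths[f[0]]
        start, end = int(f[3]), int(f[4])  # 1-based closed
        f[3], f[4] = str(L - end + 1), str(L - start + 1)
        f[6] = flip[f[6]]
        lines.append("\t".join(f))
    m_gtf = out_dir / "mirror.gtf"
    m_gtf.write_text("\n".join(lines) + "\n")
    m_sam = None
    if sam_path is not None:
        records = []
        header = []
        for line in Path(sam_path).read_text().splitlines():
            if line.startswith("@"):
                header.append(line)
                continue
            f = line.split("\t")
            L = lengths[f[2]]
            pos0 = int(f[3]) - 1
            rlen = len(f[9])
            f[3] = str(L - (pos0 + rlen) + 1)
            f[1] = str(int(f[1]) ^ 16)
            f[9] = reverse_complement(f[9])
            f[10] = f[10][::-1]
            records.append((int(f[3]), "\t".join(f)))
        records.sort()
        m_sam = out_dir / "mirror.sam"
        m_sam.write_text("\n".join(header + [r[1] for r in records]) + "\n")
    return {"fasta": m_fasta, "gtf": m_gtf, "sam": m_sam, "lengths": lengths}
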