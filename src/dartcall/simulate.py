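"""Synthetic genomes, editing data and paired count matrices with ground truth.

The generator emulates the study design the pipeline targets: DART
(APOBEC1-YTH) samples carrying Bernoulli C-to-U conversion at planted sites
in RAC context on the transcript strand, a low uniform background
conversion everywhere, methyltransferase-KO controls editing only at
background, per-position coverage with negative-binomial overdispersion,
and NB-distributed gene counts for paired soma/neurite samples with planted
localization effects.  Every generator is a pure function of its parameters
and seed, and serializes its truth for leak-free recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    GenomeAnnotation,
    GenomeSequence,
    RegionModel,
    extend_utr3,
    reverse_complement,
)
from .localization import CountMatrix
from .pileup import EditingTable

CHROM = "chrSim"


@dataclass
class PlantedSite:
    gene_id: str
    chrom: str
    strand: str
    tx_offset: int  # transcript coordinate of the edited C
    pos: int  # plus-strand genomic coordinate of the edited C
    motif: str  # transcript-strand 3-mer ending at the C
    is_rac: bool
    rate_wt: float
    rate_ko: float


@dataclass
class TruthSet:
    planted_sites: list[PlantedSite]
    background_rate: float
    coverage_mean: float
    coverage_dispersion: float
    seed: int
    localization: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "planted_sites": [asdict(s) for s in self.planted_sites],
            "background_rate": self.background_rate,
            "coverage_mean": self.coverage_mean,
            "coverage_dispersion": self.coverage_dispersion,
            "seed": self.seed,
            "localization": (
                None
                if self.localization is None
                else self.localization.to_dict(orient="list")
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_sites=[PlantedSite(**s) for s in payload["planted_sites"]],
            background_rate=payload["background_rate"],
            coverage_mean=payload["coverage_mean"],
            coverage_dispersion=payload["coverage_dispersion"],
            seed=payload["seed"],
            localization=(
                None
                if payload["localization"] is None
                else pd.DataFrame(payload["localization"])
            ),
        )


@dataclass
class SimulatedGenome:
    fasta_path: str
    gtf_path: str
    truth: TruthSet
    annotation: GenomeAnnotation = field(repr=False)


def _nb_draw(rng, mean, dispersion, size):
    """NB(mean, dispersion) with Var = mean + dispersion*mean^2."""
    mean = np.broadcast_to(np.asarray(mean, float), size).copy()
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_genome(
    out_dir,
    n_genes: int = 50,
    seed: int = 0,
    utr5_range=(100, 250),
    cds_range=(300, 700),
    utr3_range=(200, 500),
    utr3_extension: int = 5000,
    intergenic_pad: int = 200,
    sites_per_gene: float = 3.0,
    frac_non_rac: float = 0.2,
    rate_range=(0.10, 0.50),
    background_rate: float = 0.001,
    coverage_mean: float = 200.0,
    coverage_dispersion: float = 0.05,
    two_exon_fraction: float = 0.3,
    intron_length: int = 150,
) -> SimulatedGenome:
    """Random single-chromosome genome with planted editable sites.

    Genes alternate strands and are spaced by the 3'UTR extension plus a
    pad so extended territories never overlap.  Edit sites are planted at
    recorded transcript offsets, most in RAC ([AG]AC) context; a fraction
    get a deliberately non-RAC context (TAC) to exercise the motif filter.
    Deterministic for a fixed seed; writes FASTA (+ .fai on first access),
    GTF and a truth JSON to ``out_dir``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    strands = ["+" if i % 2 == 0 else "-" for i in range(n_genes)]

    def gap_after(i):
        # room for this gene's rightward extension (if +) and the next
        # gene's leftward extension (if -), so territories stay disjoint
        need = intergenic_pad
        if i >= 0 and strands[i] == "+":
            need += utr3_extension
        if i + 1 < n_genes and strands[i + 1] == "-":
            need += utr3_extension
        return need

    chrom_seq: list[str] = []
    genes: dict[str, RegionModel] = {}
    rep: dict[str, str] = {}
    planted: list[PlantedSite] = []
    gtf_lines = []
    lead = gap_after(-1)
    chrom_seq.append(_random_seq(rng, lead))
    cursor = lead
    for i in range(n_genes):
        gid = f"g{i + 1:04d}"
        strand = strands[i]
        l5 = int(rng.integers(*utr5_range))
        lc = int(rng.integers(*cds_range))
        l3 = int(rng.integers(*utr3_range))
        tx_len = l5 + lc + l3
        tx = list(_random_seq(rng, tx_len))
        two_exon = rng.random() < two_exon_fraction and lc > 120
        # plant sites, spaced and clear of exon boundaries
        n_sites = max(1, int(rng.poisson(sites_per_gene)))
        split_tx = l5 + lc // 2  # transcript offset of the intron, if any
        offsets = _plant_offsets(rng, tx_len, n_sites, l5, split_tx if two_exon else None)
        for off in offsets:
            non_rac = rng.random() < frac_non_rac
            r_base = "T" if non_rac else ("A" if rng.random() < 0.5 else "G")
            tx[off - 2], tx[off - 1], tx[off] = r_base, "A", "C"
        # scrub accidental RAC/ C-after-A collisions adjacent to planted sites
        motifs = ["".join(tx[o - 2 : o + 1]) for o in offsets]
        rates = rng.uniform(*rate_range, size=len(offsets))

        exons_tx: list[tuple[int, int]]
        if two_exon:
            exons_tx = [(0, split_tx), (split_tx, tx_len)]
        else:
            exons_tx = [(0, tx_len)]
        gene_start = cursor
        exons_gen: list[tuple[int, int]] = []
        if strand == "+":
            pos0 = gene_start
            for a, b in exons_tx:
                exons_gen.append((pos0, pos0 + (b - a)))
                pos0 += (b - a) + (intron_length if b != tx_len else 0)
            seq_parts = []
            for k, (a, b) in enumerate(exons_tx):
                seq_parts.append("".join(tx[a:b]))
                if b != tx_len:
                    seq_parts.append(_random_seq(rng, intron_length))
            genomic = "".join(seq_parts)
        else:
            # transcript runs right-to-left on the genome
            total = tx_len + (intron_length if two_exon else 0)
            genomic_rc = []
            for k, (a, b) in enumerate(exons_tx):
                genomic_rc.append("".join(tx[a:b]))
                if b != tx_len:
                    genomic_rc.append(_random_seq(rng, intron_length))
            genomic = reverse_complement("".join(genomic_rc))
            pos0 = gene_start + total
            for a, b in exons_tx:
                exons_gen.append((pos0 - (b - a), pos0))
                pos0 -= (b - a) + (intron_length if b != tx_len else 0)
            exons_gen.sort()
        chrom_seq.append(genomic)
        cursor = gene_start + len(genomic)
        gap = gap_after(i)
        chrom_seq.append(_random_seq(rng, gap))
        cursor += gap

        tx2gen = _tx_to_genomic(exons_tx, exons_gen, strand)
        cds_tx = (l5, l5 + lc)
        cds_gen = _project_interval(cds_tx, exons_tx, exons_gen, strand)
        model = _model_from_parts(gid, strand, exons_gen, cds_gen)
        genes[gid] = model
        rep[gid] = f"{gid}.t1"
        gtf_lines.extend(_gtf_for(model, f"{gid}.t1"))
        for off, motif, rate in zip(offsets, motifs, rates):
            planted.append(
                PlantedSite(
                    gene_id=gid,
                    chrom=CHROM,
                    strand=strand,
                    tx_offset=int(off),
                    pos=int(tx2gen[off]),
                    motif=motif,
                    is_rac=motif[0] in "AG" and motif[1] == "A",
                    rate_wt=float(rate),
                    rate_ko=background_rate,
                )
            )
    seq = "".join(chrom_seq)
    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{CHROM}\n")
        for j in range(0, len(seq), 80):
            fh.write(seq[j : j + 80] + "\n")
    gtf_path = out_dir / "genes.gtf"
    with open(gtf_path, "w") as fh:
        fh.writelines(gtf_lines)
    ann = GenomeAnnotation(
        genes=genes,
        representative_transcript=rep,
        chrom_lengths={CHROM: len(seq)},
    )
    ann = extend_utr3(ann, utr3_extension)
    truth = TruthSet(
        planted_sites=planted,
        background_rate=background_rate,
        coverage_mean=coverage_mean,
        coverage_dispersion=coverage_dispersion,
        seed=seed,
    )
    truth.to_json(out_dir / "truth.json")
    return SimulatedGenome(str(fasta_path), str(gtf_path), truth, ann)


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _plant_offsets(rng, tx_len, n_sites, l5, split_tx, min_gap=6):
    """Transcript offsets biased toward the stop-proximal region, spaced and
    away from exon boundaries so the 3-mer context is intra-exonic."""
    lo, hi = max(4, l5 // 2), tx_len - 4
    offsets: list[int] = []
    tries = 0
    while len(offsets) < n_sites and tries < 200:
        tries += 1
        off = int(rng.integers(lo, hi))
        if split_tx is not None and split_tx - 3 <= off <= split_tx + 2:
            continue
        if all(abs(off - o) >= min_gap for o in offsets):
            offsets.append(off)
    return sorted(offsets)


def _tx_to_genomic(exons_tx, exons_gen, strand):
    mapping = {}
    order = exons_gen if strand == "+" else exons_gen[::-1]
    for (a, b), (gs, ge) in zip(exons_tx, order):
        for k in range(b - a):
            mapping[a + k] = gs + k if strand == "+" else ge - 1 - k
    return mapping


def _project_interval(iv_tx, exons_tx, exons_gen, strand):
    a, b = iv_tx
    out = []
    order = exons_gen if strand == "+" else exons_gen[::-1]
    for (ta, tb), (gs, ge) in zip(exons_tx, order):
        s, e = max(a, ta), min(b, tb)
        if s >= e:
            continue
        if strand == "+":
            out.append((gs + (s - ta), gs + (e - ta)))
        else:
            out.append((ge - (e - ta), ge - (s - ta)))
    return sorted(out)


def _model_from_parts(gid, strand, exons_gen, cds_gen):
    from .annotation import _build_model

    return _build_model(gid, CHROM, strand, sorted(exons_gen), cds_gen)


def _gtf_for(model: RegionModel, tx: str):
    attrs = f'gene_id "{model.gene_id}"; transcript_id "{tx}";'
    lines = []
    for s, e in model.exons:
        lines.append(
            f"{model.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t{attrs}\n"
        )
    for s, e in sorted(model.cds):
        lines.append(
            f"{model.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{model.strand}\t.\t{attrs}\n"
        )
    return lines


def _c_positions(genome: GenomeSequence, annotation: GenomeAnnotation):
    """All transcript-strand reference-C positions over gene territory."""
    rows = []
    for gid, m in sorted(annotation.genes.items()):
        want = "C" if m.strand == "+" else "G"
        for s, e in m.territory():
            seq = genome.context(m.chrom, s, "+", 0, e - s - 1)
            for k, b in enumerate(seq):
                if b == want:
                    rows.append((m.chrom, s + k, m.strand, gid))
    return rows


def simulate_editing(
    sim: SimulatedGenome,
    n_wt: int = 4,
    n_ko: int = 4,
    seed: int = 1,
    coverage_mean: float | None = None,
    coverage_dispersion: float | None = None,
) -> tuple[dict[str, EditingTable], dict[str, EditingTable]]:
    """Per-sample editing tables drawn directly from the generative model.

    Coverage at every transcript-strand C position is NB; edited reads are
    Binomial(coverage, rate) with the planted per-site WT rate in DART
    samples and the uniform background rate elsewhere and in every KO
    sample.  Returns (wt_tables, ko_tables) keyed by sample id.
    """
    truth = sim.truth
    cov_mean = coverage_mean if coverage_mean is not None else truth.coverage_mean
    cov_disp = (
        coverage_dispersion
        if coverage_dispersion is not None
        else truth.coverage_dispersion
    )
    rng = np.random.default_rng(seed)
    genome = GenomeSequence(sim.fasta_path)
    positions = _c_positions(genome, sim.annotation)
    chroms = [r[0] for r in positions]
    pos = np.array([r[1] for r in positions])
    strands = [r[2] for r in positions]
    gids = [r[3] for r in positions]
    rate_wt = np.full(len(pos), truth.background_rate)
    planted_idx = {(s.chrom, s.pos): s for s in truth.planted_sites}
    for k, (c, p) in enumerate(zip(chroms, pos)):
        site = planted_idx.get((c, int(p)))
        if site is not None:
            rate_wt[k] = site.rate_wt
    rate_ko = np.full(len(pos), truth.background_rate)

    def draw(sample_id, rates):
        cov = _nb_draw(rng, cov_mean, cov_disp, len(pos))
        edited = rng.binomial(cov, rates)
        return EditingTable.from_counts(
            sample_id, chroms, pos, strands, gids, edited, cov - edited
        )

    wt = {f"wt{i + 1}": draw(f"wt{i + 1}", rate_wt) for i in range(n_wt)}
    ko = {f"ko{i + 1}": draw(f"ko{i + 1}", rate_ko) for i in range(n_ko)}
    return wt, ko


def simulate_reads(
    sim: SimulatedGenome,
    sample_id: str,
    out_sam,
    seed: int = 1,
    coverage_mean: float = 30.0,
    read_length: int = 50,
    is_ko: bool = False,
) -> EditingTable:
    """Emit a coordinate-sorted single-end SAM realizing the editing model
    read by read, and return the editing table obtained by independently
    tallying those reads (the pileup ground truth).

    Reads are full-match (CIGAR ``<L>M``), MAPQ 60, constant base quality,
    drawn uniformly within each territory segment of each gene; the library
    is forward-stranded (reads on the transcript strand).
    """
    rng = np.random.default_rng(seed)
    genome = GenomeSequence(sim.fasta_path)
    truth = sim.truth
    planted = {(s.chrom, s.pos): s for s in truth.planted_sites}
    chrom_len = sim.annotation.chrom_lengths[CHROM]
    counts: dict[tuple, list[int]] = {}  # (chrom,pos,strand,gid) -> [edited, unedited]
    records = []
    for gid, m in sorted(sim.annotation.genes.items()):
        segments = _merged(m.territory())
        want = "C" if m.strand == "+" else "G"
        edit_to = "T" if m.strand == "+" else "A"
        for s, e in segments:
            e = min(e, chrom_len)
            if e - s < read_length:
                continue
            n_reads = rng.poisson(coverage_mean * (e - s) / read_length)
            starts = np.sort(rng.integers(s, e - read_length + 1, size=n_reads))
            for ridx, st in enumerate(starts):
                ref = genome.context(m.chrom, int(st), "+", 0, read_length - 1)
                seq = list(ref)
                for k, b in enumerate(seq):
                    if b != want:
                        continue
                    gpos = int(st) + k
                    site = planted.get((m.chrom, gpos))
                    rate = (
                        truth.background_rate
                        if (site is None or is_ko)
                        else site.rate_wt
                    )
                    key = (m.chrom, gpos, m.strand, gid)
                    tallies = counts.setdefault(key, [0, 0])
                    if rng.random() < rate:
                        seq[k] = edit_to
                        tallies[0] += 1
                    else:
                        tallies[1] += 1
                flag = 0 if m.strand == "+" else 16
                records.append(
                    (
                        int(st),
                        f"{sample_id}.{gid}.{s}.{ridx}",
                        flag,
                        "".join(seq),
                    )
                )
    records.sort(key=lambda r: r[0])
    with open(out_sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{CHROM}\tLN:{chrom_len}\n")
        for st, qname, flag, seq in records:
            fh.write(
                f"{qname}\t{flag}\t{CHROM}\t{st + 1}\t60\t{len(seq)}M\t*\t0\t0\t"
                f"{seq}\t{'I' * len(seq)}\n"
            )
    keys = sorted(counts)
    return EditingTable.from_counts(
        sample_id,
        [k[0] for k in keys],
        [k[1] for k in keys],
        [k[2] for k in keys],
        [k[3] for k in keys],
        [counts[k][0] for k in keys],
        [counts[k][1] for k in keys],
    )


def _merged(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(e, out[-1][1]))
        else:
            out.append((s, e))
    return out


def overlapping_pair_sam(path, chrom=CHROM, chrom_len=1000):
    """Two proper mates overlapping one position with a concordant T, for
    exercising the count-once rule of overlapping mate bases."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_len}\n")
        # 10-bp mates both covering position 104 (0-based) with T
        fh.write(
            f"frag1\t99\t{chrom}\t101\t60\t10M\t=\t105\t14\tAAAATAAAAA\tIIIIIIIIII\n"
        )
        fh.write(
            f"frag1\t147\t{chrom}\t105\t60\t10M\t=\t101\t-14\tTAAAAAAAAA\tIIIIIIIIII\n"
        )


def simulate_localization_counts(
    n_genes: int = 2000,
    n_pairs: int = 2,
    seed: int = 0,
    base_mean: float = 500.0,
    mean_sigma: float = 0.6,
    dispersion: float = 0.01,
    frac_enriched: float = 0.05,
    enrichment_log2: float = 2.0,
    frac_delta: float = 0.10,
    delta_log2: float = 1.0,
    size_factor_sigma: float = 0.15,
    conditions: tuple[str, str] = ("A", "B"),
) -> tuple[CountMatrix, pd.DataFrame]:
    """Paired soma/neurite NB counts for two conditions with planted truths.

    Soma means are log-normal around ``base_mean``.  A fraction of genes is
    neurite-enriched in both conditions (|log2 FC_N/S| = enrichment_log2,
    random sign); an independent fraction gets a localization change:
    condition B multiplies the neurite mean by 2^(+/-delta_log2).  Returns
    the count matrix (size factors recorded in the sample sheet) and a
    truth frame with per-gene true effects.
    """
    if n_pairs < 2:
        raise ValueError("need >=2 pairs per condition")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    soma_mean = np.exp(rng.normal(np.log(base_mean), mean_sigma, size=n_genes))
    fc = np.zeros(n_genes)
    enr = rng.random(n_genes) < frac_enriched
    fc[enr] = enrichment_log2 * rng.choice([-1.0, 1.0], size=enr.sum())
    delta = np.zeros(n_genes)
    hit = rng.random(n_genes) < frac_delta
    delta[hit] = delta_log2 * rng.choice([-1.0, 1.0], size=hit.sum())

    samples = []
    cols = {}
    for cond_i, cond in enumerate(conditions):
        for p in range(n_pairs):
            pair = f"{cond}p{p + 1}"
            for comp in ("soma", "neurite"):
                sid = f"{comp[0]}_{pair}"
                sf = float(np.exp(rng.normal(0.0, size_factor_sigma)))
                mu = soma_mean.copy()
                if comp == "neurite":
                    mu = mu * 2.0**fc
                    if cond_i == 1:
                        mu = mu * 2.0**delta
                cols[sid] = _nb_draw(rng, mu * sf, dispersion, n_genes)
                samples.append(
                    {
                        "sample_id": sid,
                        "compartment": comp,
                        "condition": cond,
                        "pair_id": pair,
                        "size_factor": sf,
                    }
                )
    counts = pd.DataFrame(cols, index=genes)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "soma_mean": soma_mean,
            "log2_fc_ns": fc,
            "delta_log2_fc_ns": delta,
        }
    )
    return CountMatrix(counts, pd.DataFrame(samples)), truth
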