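"""Alignment pileup over gene territory and per-sample C-to-U editing tables.

The pileup counts plus-strand reference bases (A/C/G/T/N) at every position
inside annotated exons and extended 3'UTRs.  The editing table then reduces
those counts to transcript-strand reference-C positions: on a plus-strand
gene the edit allele is T and the reference allele C; on a minus-strand
gene they are the plus-strand A and G.  %C2U uses edited/(edited+unedited)
as its denominator — stray non-C2U alleles contribute to coverage (which
feeds the read-depth filter) but not to the rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .annotation import GenomeAnnotation, GenomeSequence

log = logging.getLogger(__name__)

BASES = "ACGTN"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_SKIP_FLAGS = (
    pysam.FUNMAP | pysam.FSECONDARY | pysam.FSUPPLEMENTARY | pysam.FDUP | pysam.FQCFAIL
)

TABLE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "gene_id",
    "edited",
    "unedited",
    "coverage",
    "rate",
]


class PileupMatrix:
    """Per-position base counts for one sample, restricted to gene territory."""

    def __init__(self, sample_id: str):
        self.sample_id = sample_id
        # chrom -> pos -> int64[5] counts in BASES order
        self.counts: dict[str, dict[int, np.ndarray]] = {}

    def add(self, chrom: str, pos: int, base: str) -> None:
        chrom_counts = self.counts.setdefault(chrom, {})
        arr = chrom_counts.get(pos)
        if arr is None:
            arr = np.zeros(5, dtype=np.int64)
            chrom_counts[pos] = arr
        arr[BASE_INDEX.get(base, 4)] += 1

    def at(self, chrom: str, pos: int) -> np.ndarray:
        return self.counts.get(chrom, {}).get(pos, np.zeros(5, dtype=np.int64))


@dataclass
class EditingTable:
    """Per-sample %C2U at transcript-strand reference-C positions.

    ``df`` columns: chrom, pos, strand, gene_id, edited, unedited, coverage,
    rate (percent, NaN where edited+unedited is 0).  Rows with zero coverage
    are absent.
    """

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        bad = (self.df["edited"] < 0) | (self.df["edited"] > self.df["coverage"])
        if bad.any():
            raise ValueError("edited counts outside [0, coverage]")

    @classmethod
    def from_counts(cls, sample_id, chrom, pos, strand, gene_id, edited, unedited,
                    coverage=None):
        edited = np.asarray(edited, dtype=np.int64)
        unedited = np.asarray(unedited, dtype=np.int64)
        coverage = (
            edited + unedited if coverage is None else np.asarray(coverage, np.int64)
        )
        denom = edited + unedited
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(denom > 0, 100.0 * edited / denom, np.nan)
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": np.asarray(pos, dtype=np.int64),
                "strand": strand,
                "gene_id": gene_id,
                "edited": edited,
                "unedited": unedited,
                "coverage": coverage,
                "rate": rate,
            }
        )
        return cls(sample_id=sample_id, df=df[df["coverage"] > 0])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, sample_id: str) -> "EditingTable":
        return cls(sample_id=sample_id, df=pd.read_csv(path, sep="\t"))


def _fragment_strand(read: pysam.AlignedSegment, strandedness: str) -> str | None:
    """Transcript strand implied by a read under the library protocol."""
    if strandedness == "unstranded":
        return None
    first = not read.is_paired or read.is_read1
    strand = "-" if read.is_reverse else "+"
    if not first:
        strand = "-" if strand == "+" else "+"
    if strandedness == "reverse":
        strand = "-" if strand == "+" else "+"
    return strand


def _read_bases(read, min_baseq) -> dict[int, tuple[str, int]]:
    """refpos -> (base, qual) for aligned (non-indel) positions passing baseq."""
    seq = read.query_sequence
    quals = read.query_qualities
    out = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        q = quals[qpos] if quals is not None else 255
        if q >= min_baseq:
            out[rpos] = (seq[qpos].upper(), q)
    return out


def _merge_mates(a: dict, b: dict) -> dict:
    """Count overlapping mate bases once; disagreements go to the higher
    quality base, quality ties are discarded."""
    merged = dict(a)
    for rpos, (base, q) in b.items():
        if rpos not in merged:
            merged[rpos] = (base, q)
            continue
        obase, oq = merged[rpos]
        if base == obase:
            continue
        if q > oq:
            merged[rpos] = (base, q)
        elif q == oq:
            del merged[rpos]
    return merged


def build_pileup(
    alignment_path,
    annotation: GenomeAnnotation,
    min_mapq: int = 10,
    min_baseq: int = 20,
    strandedness: str = "reverse",
    sample_id: str | None = None,
    territory: dict | None = None,
) -> PileupMatrix:
    """Base counts over gene territory from a coordinate-sorted SAM/BAM.

    Unmapped/secondary/supplementary/duplicate/QC-fail reads and low-MAPQ
    alignments are excluded; bases below ``min_baseq`` are excluded;
    deletions and insertions contribute nothing.  Bases of overlapping
    proper mates are counted once.  With a stranded protocol, a read only
    contributes at positions of genes on its implied transcript strand.
    """
    if strandedness not in ("forward", "reverse", "unstranded"):
        raise ValueError(f"bad strandedness {strandedness!r}")
    if territory is None:
        territory = annotation.territory_map()
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        pm = PileupMatrix(sample_id or str(alignment_path))
        known = set(af.references or [])
        unknown = known - set(
            annotation.chrom_lengths or {c for c in territory}
            | {m.chrom for m in annotation.genes.values()}
        )
        if unknown:
            raise ValueError(f"alignment contigs absent from genome: {sorted(unknown)}")
        pending: dict[str, tuple[dict, str | None, str]] = {}
        last = {}
        for read in af.fetch(until_eof=True):
            if read.flag & _SKIP_FLAGS or read.mapping_quality < min_mapq:
                continue
            chrom = read.reference_name
            if last.get(chrom, -1) > read.reference_start:
                raise ValueError("alignment file is not coordinate-sorted")
            last[chrom] = read.reference_start
            bases = _read_bases(read, min_baseq)
            fstrand = _fragment_strand(read, strandedness)
            if read.is_paired and read.is_proper_pair:
                key = read.query_name
                if key in pending:
                    obases, ostrand, ochrom = pending.pop(key)
                    if ochrom == chrom:
                        bases = _merge_mates(obases, bases)
                    else:  # discordant contigs; count separately
                        _count(pm, territory, ochrom, obases, ostrand)
                    _count(pm, territory, chrom, bases, fstrand)
                else:
                    pending[key] = (bases, fstrand, chrom)
            else:
                _count(pm, territory, chrom, bases, fstrand)
        for bases, fstrand, chrom in pending.values():  # mates never seen
            _count(pm, territory, chrom, bases, fstrand)
    return pm


def _count(pm, territory, chrom, bases, fstrand):
    chrom_terr = territory.get(chrom)
    if not chrom_terr:
        return
    for rpos, (base, _q) in bases.items():
        hit = chrom_terr.get(rpos)
        if hit is None:
            continue
        if fstrand is not None and hit[1] != fstrand:
            continue
        pm.add(chrom, rpos, base)


def c2u_table(
    pileup: PileupMatrix,
    genome: GenomeSequence,
    annotation: GenomeAnnotation,
    territory: dict | None = None,
) -> EditingTable:
    """Reduce a pileup to the editing table at transcript-strand C positions."""
    if territory is None:
        territory = annotation.territory_map()
    rows = {k: [] for k in TABLE_COLUMNS[:4]}
    edited_l, unedited_l, coverage_l = [], [], []
    for chrom in sorted(pileup.counts):
        chrom_terr = territory.get(chrom, {})
        for pos in sorted(pileup.counts[chrom]):
            hit = chrom_terr.get(pos)
            if hit is None:
                continue
            gene_id, strand = hit
            ref = genome.base(chrom, pos, "+")
            if ref == "N":
                log.info("skipping reference N at %s:%d", chrom, pos)
                continue
            if strand == "+" and ref == "C":
                e_base, u_base = "T", "C"
            elif strand == "-" and ref == "G":
                e_base, u_base = "A", "G"
            else:
                continue
            counts = pileup.counts[chrom][pos]
            cov = int(counts.sum())
            if cov == 0:
                continue
            rows["chrom"].append(chrom)
            rows["pos"].append(pos)
            rows["strand"].append(strand)
            rows["gene_id"].append(gene_id)
            edited_l.append(int(counts[BASE_INDEX[e_base]]))
            unedited_l.append(int(counts[BASE_INDEX[u_base]]))
            coverage_l.append(cov)
    return EditingTable.from_counts(
        pileup.sample_id,
        rows["chrom"],
        rows["pos"],
        rows["strand"],
        rows["gene_id"],
        edited_l,
        unedited_l,
        coverage_l,
    )
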