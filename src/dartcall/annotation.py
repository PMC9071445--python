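"""Genome sequence access and gene/region models.

Coordinates are 0-based, half-open everywhere inside the package.  GTF input
is converted from its 1-based closed convention on parse; BED output is
0-based half-open.  Region models partition a gene's representative
transcript into 5'UTR / CDS / 3'UTR intervals held in transcript (5'->3')
order, and carry the downstream 3'UTR extension used to capture editing in
unannotated UTR territory.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REGIONS = ("utr5", "cds", "utr3")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GtfParseError(ValueError):
    pass


class GenomeSequence:
    """Random-access genome backed by a faidx-indexed FASTA.

    Base and context queries are strand-aware: minus-strand queries return
    the reverse complement of the plus-strand sequence, i.e. the base as
    read on the transcript.  Out-of-range queries raise rather than clip.
    """

    def __init__(self, fasta_path):
        self._fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    @property
    def chrom_names(self) -> list[str]:
        return list(self._fa.keys())

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(self._fa[name]) for name in self._fa.keys()}

    def _check(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self._fa:
            raise KeyError(f"unknown contig {chrom!r}")
        if start < 0 or end > len(self._fa[chrom]):
            raise IndexError(
                f"window [{start},{end}) outside {chrom} "
                f"(length {len(self._fa[chrom])})"
            )

    def base(self, chrom: str, pos: int, strand: str = "+") -> str:
        self._check(chrom, pos, pos + 1)
        b = self._fa[chrom][pos]
        return reverse_complement(b) if strand == "-" else b

    def context(self, chrom: str, pos: int, strand: str, up: int, down: int) -> str:
        """Transcript-strand sequence covering [pos-up, pos+down] around pos.

        ``up`` bases 5' and ``down`` bases 3' of ``pos`` in transcript
        orientation; the window is reverse-complemented for minus-strand
        queries.
        """
        if strand == "+":
            start, end = pos - up, pos + down + 1
        else:
            start, end = pos - down, pos + up + 1
        self._check(chrom, start, end)
        seq = self._fa[chrom][start:end]
        return reverse_complement(seq) if strand == "-" else seq


def _interval_len(iv: tuple[int, int]) -> int:
    return iv[1] - iv[0]


@dataclass
class RegionModel:
    """Per-gene exon structure partitioned into 5'UTR / CDS / 3'UTR.

    ``exons`` is genomically sorted; ``utr5``/``cds``/``utr3`` are listed in
    transcript order (descending genomic coordinate for minus-strand genes).
    ``utr3`` may end with the downstream extension interval added by
    :func:`extend_utr3`.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    utr3_extended_bp: int = 0

    @property
    def coding(self) -> bool:
        return len(self.cds) > 0

    @property
    def region_lengths(self) -> dict[str, int]:
        return {
            "utr5": sum(map(_interval_len, self.utr5)),
            "cds": sum(map(_interval_len, self.cds)),
            "utr3": sum(map(_interval_len, self.utr3)),
        }

    @property
    def annotated_region_lengths(self) -> dict[str, int]:
        """Region lengths excluding the downstream 3'UTR extension."""
        utr3 = self.utr3[:-1] if (self.utr3_extended_bp > 0 and self.utr3) else self.utr3
        return {
            "utr5": sum(map(_interval_len, self.utr5)),
            "cds": sum(map(_interval_len, self.cds)),
            "utr3": sum(map(_interval_len, utr3)),
        }

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def contains(self, pos: int) -> bool:
        """True if pos lies in the non-extended annotation (exons)."""
        return any(s <= pos < e for s, e in self.exons)

    def three_prime_end(self) -> int:
        """Genomic coordinate of the annotated 3' terminus."""
        return self.end - 1 if self.strand == "+" else self.start

    def territory(self) -> list[tuple[int, int]]:
        """Exons plus the extended 3'UTR, as genomic intervals."""
        ivs = list(self.exons)
        for iv in self.utr3:
            if not any(s <= iv[0] and iv[1] <= e for s, e in self.exons):
                ivs.append(iv)
        ivs.sort()
        return ivs

    def locate(self, pos: int) -> tuple[str, int]:
        """Map a genomic position to (region, transcript offset into region).

        Offsets run 5'->3' on the transcript.  Raises for positions outside
        the utr5/cds/utr3 partition (e.g. intronic input) and for noncoding
        genes, whose metagene regions are undefined.
        """
        if not self.coding:
            raise ValueError(f"{self.gene_id}: noncoding gene has no metagene regions")
        for region in REGIONS:
            offset = 0
            for s, e in getattr(self, region):
                if s <= pos < e:
                    within = (pos - s) if self.strand == "+" else (e - 1 - pos)
                    return region, offset + within
                offset += e - s
        raise ValueError(f"{self.gene_id}: position {pos} not in any region")


@dataclass
class GenomeAnnotation:
    """All gene models plus representative-transcript bookkeeping."""

    genes: dict[str, RegionModel]
    representative_transcript: dict[str, str]
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    mito_chroms: tuple[str, ...] = ("chrM", "MT")

    def mito_genes(self) -> set[str]:
        return {g for g, m in self.genes.items() if m.chrom in self.mito_chroms}

    def territory_map(self) -> dict[str, dict[int, tuple[str, str]]]:
        """Per-chromosome position -> (gene_id, strand) over gene territory.

        Where two genes' territories overlap the position is assigned to the
        gene whose non-extended annotation contains it, falling back to the
        gene with the nearer annotated 3' end.
        """
        out: dict[str, dict[int, tuple[str, str]]] = {}
        for gid, model in self.genes.items():
            chrom_map = out.setdefault(model.chrom, {})
            for s, e in model.territory():
                for pos in range(s, e):
                    incumbent = chrom_map.get(pos)
                    if incumbent is None:
                        chrom_map[pos] = (gid, model.strand)
                        continue
                    chrom_map[pos] = self._resolve(pos, incumbent[0], gid)
        return out

    def _resolve(self, pos: int, gid_a: str, gid_b: str) -> tuple[str, str]:
        a, b = self.genes[gid_a], self.genes[gid_b]
        in_a, in_b = a.contains(pos), b.contains(pos)
        if in_a != in_b:
            winner = a if in_a else b
        else:
            winner = min(
                (a, b), key=lambda m: (abs(pos - m.three_prime_end()), m.gene_id)
            )
        return winner.gene_id, winner.strand


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def parse_annotation(
    gtf_path,
    chrom_lengths: dict[str, int] | None = None,
    mito_chroms: tuple[str, ...] = ("chrM", "MT"),
) -> GenomeAnnotation:
    """Parse a GTF into per-gene region models.

    Only ``exon`` and ``CDS`` features are consulted; gene/transcript
    container lines are ignored.  When a gene has several transcripts the
    representative is the one with the longest summed exon length (ties by
    lexicographically smallest transcript_id).  Exonic sequence outside the
    CDS span becomes 5'UTR (upstream) or 3'UTR (downstream) in transcript
    orientation; genes without any CDS are kept as noncoding models with all
    exons and empty regions.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cdss: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)  # 1-based closed -> half-open
            except ValueError as exc:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or end <= start:
                raise GtfParseError(f"{gtf_path}: line {lineno}: bad interval")
            if chrom_lengths and chrom in chrom_lengths and end > chrom_lengths[chrom]:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: feature beyond end of {chrom}"
                )
            a = _parse_attributes(attrs)
            if "gene_id" not in a or "transcript_id" not in a:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: missing gene_id/transcript_id"
                )
            tx = a["transcript_id"]
            tx_meta.setdefault(tx, (a["gene_id"], chrom, strand))
            target = exons if feature == "exon" else cdss
            target.setdefault(tx, []).append((start, end))

    by_gene: dict[str, list[str]] = {}
    for tx, (gene, _, _) in tx_meta.items():
        by_gene.setdefault(gene, []).append(tx)

    genes: dict[str, RegionModel] = {}
    representative: dict[str, str] = {}
    for gene, txs in by_gene.items():
        rep = min(
            txs,
            key=lambda t: (-sum(e - s for s, e in exons.get(t, [])), t),
        )
        representative[gene] = rep
        _, chrom, strand = tx_meta[rep]
        genes[gene] = _build_model(
            gene, chrom, strand, sorted(exons.get(rep, [])), sorted(cdss.get(rep, []))
        )
    return GenomeAnnotation(
        genes=genes,
        representative_transcript=representative,
        chrom_lengths=dict(chrom_lengths or {}),
        mito_chroms=tuple(mito_chroms),
    )


def _build_model(gene, chrom, strand, exons, cds) -> RegionModel:
    if not exons:
        raise GtfParseError(f"gene {gene}: transcript has no exons")
    if not cds:
        return RegionModel(gene_id=gene, chrom=chrom, strand=strand, exons=exons)
    cds_start = min(s for s, _ in cds)
    cds_end = max(e for _, e in cds)
    left, middle, right = [], [], []
    for s, e in exons:
        if s < cds_start:
            left.append((s, min(e, cds_start)))
        ms, me = max(s, cds_start), min(e, cds_end)
        if ms < me:
            middle.append((ms, me))
        if e > cds_end:
            right.append((max(s, cds_end), e))
    if strand == "+":
        utr5, utr3 = left, right
    else:
        utr5, utr3 = right[::-1], left[::-1]
        middle = middle[::-1]
    return RegionModel(
        gene_id=gene,
        chrom=chrom,
        strand=strand,
        exons=exons,
        utr5=utr5,
        cds=middle,
        utr3=utr3,
    )


def extend_utr3(
    annotation: GenomeAnnotation, extension_bp: int = 5000
) -> GenomeAnnotation:
    """Append ``extension_bp`` of downstream territory to every 3'UTR.

    The extension continues past the annotated transcript end in transcript
    orientation and is clipped at the chromosome boundary; it does not stop
    at neighboring genes (overlap is resolved at territory-map time).
    Genes are returned as new models; extension 0 is the identity.
    """
    if extension_bp < 0:
        raise ValueError("extension must be non-negative")
    if extension_bp == 0:
        return annotation
    genes = {}
    for gid, m in annotation.genes.items():
        chrom_len = annotation.chrom_lengths.get(m.chrom)
        if m.strand == "+":
            start = m.end
            end = start + extension_bp
            if chrom_len is not None:
                end = min(end, chrom_len)
            ext = (start, end)
        else:
            end = m.start
            ext = (max(0, end - extension_bp), end)
        utr3 = list(m.utr3)
        if ext[1] > ext[0]:
            utr3 = utr3 + [ext]
        genes[gid] = replace(m, utr3=utr3, utr3_extended_bp=extension_bp)
    return replace(annotation, genes=genes)


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Emit exon and CDS features (1-based closed) for round-tripping."""
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            m = annotation.genes[gid]
            tx = annotation.representative_transcript.get(gid, f"{gid}.t1")
            attrs = f'gene_id "{gid}"; transcript_id "{tx}";'
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tdartcall\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            for s, e in sorted(m.cds):
                fh.write(
                    f"{m.chrom}\tdartcall\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
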