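"""Gene annotation model and GTF I/O.

GTF files are parsed with :mod:`gffutils` (in-memory database) and converted
to plain dataclasses holding 0-based half-open intervals. Annotations can
also be constructed programmatically (the synthetic generator does this and
round-trips through the GTF writer in tests).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import gffutils

from .errors import AnnotationError
from .intervals import (
    Interval,
    merge_intervals,
    overlaps,
    subtract_intervals,
    total_length,
)

REGION_PRECEDENCE = ("three_prime_utr", "five_prime_utr", "CDS", "intron")
REGION_LABELS = {
    "three_prime_utr": "3UTR",
    "five_prime_utr": "5UTR",
    "CDS": "CDS",
    "intron": "intron",
}


@dataclass
class SupportFilter:
    """Transcript confidence filter on GENCODE-style support attributes.

    ``direction='le'`` keeps transcripts with level <= max_level and
    TSL <= max_tsl (the high-confidence reading); ``'ge'`` inverts both
    comparisons. Transcripts lacking an attribute pass that comparison.
    """

    max_level: int = 2
    max_tsl: int = 3
    direction: str = "le"

    def passes(self, transcript: "Transcript") -> bool:
        for value, bound in ((transcript.level, self.max_level), (transcript.tsl, self.max_tsl)):
            if value is None:
                continue
            if self.direction == "le" and value > bound:
                return False
            if self.direction == "ge" and value < bound:
                return False
        return True


@dataclass
class Transcript:
    transcript_id: str
    start: int
    end: int
    level: Optional[int] = None
    tsl: Optional[int] = None
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    gene_type: str = "protein_coding"
    name: Optional[str] = None
    transcripts: list[Transcript] = field(default_factory=list)

    def qualifying_transcripts(self, flt: Optional[SupportFilter]) -> list[Transcript]:
        if flt is None:
            return list(self.transcripts)
        return [t for t in self.transcripts if flt.passes(t)]

    def merged_exons(self, flt: Optional[SupportFilter] = None) -> list[Interval]:
        txs = self.qualifying_transcripts(flt) or self.transcripts
        return merge_intervals(iv for t in txs for iv in t.exons)

    def merged_region(self, region: str, flt: Optional[SupportFilter] = None) -> list[Interval]:
        txs = self.qualifying_transcripts(flt) or self.transcripts
        attr = {"three_prime_utr": "utr3", "five_prime_utr": "utr5", "CDS": "cds"}[region]
        return merge_intervals(iv for t in txs for iv in getattr(t, attr))


class Annotation:
    """Gene set with per-(chrom, strand) overlap lookup."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {g.gene_id: g for g in genes}
        self._index: dict[tuple[str, str], tuple[list[int], list[Gene]]] = {}
        by_key: dict[tuple[str, str], list[Gene]] = {}
        for g in self.genes.values():
            by_key.setdefault((g.chrom, g.strand), []).append(g)
        for key, gs in by_key.items():
            gs.sort(key=lambda g: g.start)
            self._index[key] = ([g.start for g in gs], gs)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def genes_overlapping(
        self, chrom: str, strand: str, start: int, end: int, protein_coding_only: bool = False
    ) -> list[Gene]:
        starts, gs = self._index.get((chrom, strand), ([], []))
        # genes are short relative to chromosome; scan a bounded neighborhood
        hi = bisect.bisect_right(starts, end)
        out = []
        for g in gs[:hi]:
            if g.end > start and g.start < end:
                if not protein_coding_only or g.gene_type == "protein_coding":
                    out.append(g)
        return out

    def region_of_window(
        self, gene: Gene, start: int, end: int, flt: Optional[SupportFilter] = None
    ) -> str:
        """Single region label by precedence 3'UTR > 5'UTR > CDS > intron."""
        for region in ("three_prime_utr", "five_prime_utr", "CDS"):
            if overlaps((start, end), gene.merged_region(region, flt)):
                return region
        return "intron"

    def utr3_intervals(self, flt: Optional[SupportFilter] = None) -> list[tuple[str, str, int, int]]:
        out = []
        for g in self:
            for s, e in g.merged_region("three_prime_utr", flt):
                out.append((g.chrom, g.strand, s, e))
        return out

    def polya_sites(
        self, flt: Optional[SupportFilter] = None, min_utr3: int = 0
    ) -> list[tuple[str, str, int]]:
        """Unique annotated transcript 3' ends (position of the last
        transcribed nucleotide), from transcripts passing the support filter
        whose 3' UTR totals at least ``min_utr3`` nt."""
        seen = set()
        out = []
        for g in self:
            for t in g.qualifying_transcripts(flt):
                if total_length(t.utr3) < min_utr3:
                    continue
                pos = t.end - 1 if g.strand == "+" else t.start
                key = (g.chrom, g.strand, pos)
                if key not in seen:
                    seen.add(key)
                    out.append(key)
        return sorted(out)


def _classify_utr(iv: Interval, cds: list[Interval], strand: str) -> str:
    if not cds:
        return "three_prime_utr"
    cds_start = min(s for s, _ in cds)
    cds_end = max(e for _, e in cds)
    if iv[1] <= cds_start:
        return "three_prime_utr" if strand == "-" else "five_prime_utr"
    if iv[0] >= cds_end:
        return "three_prime_utr" if strand == "+" else "five_prime_utr"
    return "three_prime_utr"


def _int_attr(feature, name: str) -> Optional[int]:
    vals = feature.attributes.get(name)
    if not vals:
        return None
    try:
        return int(str(vals[0]))
    except ValueError:
        return None


def load_gtf(path: str) -> Annotation:
    """Parse a GTF into an :class:`Annotation`.

    Requires ``gene_type`` on gene features (the single-gene assignment rule
    depends on it). Generic ``UTR`` features are classified as 5'/3' by their
    position relative to the transcript CDS.
    """
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:
        raise AnnotationError(f"cannot parse GTF {path}: {exc}") from exc

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    tx_gene: dict[str, str] = {}

    for f in db.features_of_type("gene"):
        if "gene_type" not in f.attributes:
            raise AnnotationError(
                f"gene {f.id} lacks the gene_type attribute required for "
                "protein-coding gene assignment"
            )
        gid = f.attributes["gene_id"][0]
        genes[gid] = Gene(
            gene_id=gid,
            chrom=f.seqid,
            strand=f.strand,
            start=f.start - 1,
            end=f.end,
            gene_type=f.attributes["gene_type"][0],
            name=(f.attributes.get("gene_name") or [None])[0],
        )

    for f in db.features_of_type("transcript"):
        tid = f.attributes["transcript_id"][0]
        gid = f.attributes["gene_id"][0]
        if gid not in genes:
            raise AnnotationError(f"transcript {tid} references unknown gene {gid}")
        tx = Transcript(
            transcript_id=tid,
            start=f.start - 1,
            end=f.end,
            level=_int_attr(f, "level"),
            tsl=_int_attr(f, "transcript_support_level"),
        )
        transcripts[tid] = tx
        tx_gene[tid] = gid
        genes[gid].transcripts.append(tx)

    pending_utrs: list[tuple[str, Interval]] = []
    for ftype in ("exon", "CDS", "five_prime_utr", "three_prime_utr", "UTR"):
        for f in db.features_of_type(ftype):
            tid = f.attributes["transcript_id"][0]
            tx = transcripts.get(tid)
            if tx is None:
                continue
            iv = (f.start - 1, f.end)
            if ftype == "exon":
                tx.exons.append(iv)
            elif ftype == "CDS":
                tx.cds.append(iv)
            elif ftype == "five_prime_utr":
                tx.utr5.append(iv)
            elif ftype == "three_prime_utr":
                tx.utr3.append(iv)
            else:
                pending_utrs.append((tid, iv))

    for tid, iv in pending_utrs:
        tx = transcripts[tid]
        strand = genes[tx_gene[tid]].strand
        kind = _classify_utr(iv, tx.cds, strand)
        (tx.utr3 if kind == "three_prime_utr" else tx.utr5).append(iv)

    for tx in transcripts.values():
        tx.exons = merge_intervals(tx.exons)
        tx.cds = merge_intervals(tx.cds)
        tx.utr5 = merge_intervals(tx.utr5)
        tx.utr3 = merge_intervals(tx.utr3)

    return Annotation(genes.values())


def write_gtf(annotation: Annotation, path: str, source: str = "arichclip") -> None:
    """Write the annotation as GTF (1-based closed coordinates)."""

    def attrs(gene: Gene, tx: Optional[Transcript] = None) -> str:
        parts = [f'gene_id "{gene.gene_id}"', f'gene_type "{gene.gene_type}"']
        if gene.name:
            parts.append(f'gene_name "{gene.name}"')
        if tx is not None:
            parts.append(f'transcript_id "{tx.transcript_id}"')
            if tx.level is not None:
                parts.append(f'level {tx.level}')
            if tx.tsl is not None:
                parts.append(f'transcript_support_level "{tx.tsl}"')
        return "; ".join(parts) + ";"

    with open(path, "w") as fh:
        for gene in sorted(annotation, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{gene.chrom}\t{source}\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\t{attrs(gene)}\n"
            )
            for tx in gene.transcripts:
                fh.write(
                    f"{gene.chrom}\t{source}\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t"
                    f"{gene.strand}\t.\t{attrs(gene, tx)}\n"
                )
                for ftype, ivs in (
                    ("exon", tx.exons),
                    ("CDS", tx.cds),
                    ("five_prime_utr", tx.utr5),
                    ("three_prime_utr", tx.utr3),
                ):
                    for s, e in ivs:
                        fh.write(
                            f"{gene.chrom}\t{source}\t{ftype}\t{s + 1}\t{e}\t.\t"
                            f"{gene.strand}\t.\t{attrs(gene, tx)}\n"
                        )


def intronic_intervals(gene: Gene, flt: Optional[SupportFilter] = None) -> list[Interval]:
    return subtract_intervals([(gene.start, gene.end)], gene.merged_exons(flt))
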