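"""Read-level barcode quality filtering, duplicate removal and crosslink
extraction.

The crosslink nucleotide is the position one nt upstream (in transcript
5' direction) of a read's 5' mapping position: ``five_prime_pos - 1`` on the
plus strand, ``five_prime_pos + 1`` on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, InputError
from .tracks import CrosslinkTrack


@dataclass(frozen=True)
class BarcodeScheme:
    """9-nt barcode layout and Phred thresholds (1-based read positions)."""

    random_positions: frozenset[int] = frozenset({1, 2, 3, 8, 9})
    experimental_positions: frozenset[int] = frozenset({4, 5, 6, 7})
    min_qual_random: int = 17
    min_qual_experimental: int = 20
    max_low_experimental: int = 1

    def __post_init__(self) -> None:
        if self.random_positions & self.experimental_positions:
            raise ConfigurationError("random and experimental barcode positions overlap")
        if any(p < 1 for p in self.random_positions | self.experimental_positions):
            raise ConfigurationError("barcode positions are 1-based and must be >= 1")


class BarcodeRegionError(InputError):
    """Read too short to cover the barcode region (explicit, not a drop)."""


def _phred(qualities: str | Sequence[int]) -> list[int]:
    if isinstance(qualities, str):
        return [ord(c) - 33 for c in qualities]
    return list(qualities)


def filter_barcode_quality(qualities: str | Sequence[int], scheme: BarcodeScheme) -> bool:
    """Keep iff at most ``max_low_experimental`` experimental-barcode
    positions fall below ``min_qual_experimental`` and no random-barcode
    position falls below ``min_qual_random``."""
    quals = _phred(qualities)
    needed = max(scheme.random_positions | scheme.experimental_positions)
    if len(quals) < needed:
        raise BarcodeRegionError(
            f"read of length {len(quals)} does not cover barcode position {needed}"
        )
    if any(quals[p - 1] < scheme.min_qual_random for p in scheme.random_positions):
        return False
    n_low = sum(1 for p in scheme.experimental_positions if quals[p - 1] < scheme.min_qual_experimental)
    return n_low <= scheme.max_low_experimental


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    chrom: str
    strand: str
    five_prime_pos: int  # 0-based genomic coordinate of the read's 5' end
    random_barcode: str


def dedup_random_barcode(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Collapse technical duplicates: among records sharing
    (chrom, strand, 5' position, random barcode) the first survives.
    Records at the same position with different barcodes all survive."""
    seen: set[tuple[str, str, int, str]] = set()
    out = []
    for r in records:
        key = (r.chrom, r.strand, r.five_prime_pos, r.random_barcode)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def extract_crosslinks(
    records: Iterable[AlignmentRecord],
    replicate: str,
    contig_lengths: Mapping[str, int] | None = None,
) -> CrosslinkTrack:
    """One crosslink event per record at the position upstream of its 5' end.

    Records whose crosslink position falls outside the contig are counted in
    ``track.meta['skipped_out_of_bounds']`` and skipped.
    """
    track = CrosslinkTrack(replicate=replicate)
    skipped = 0
    n = 0
    for r in records:
        if r.strand == "+":
            pos = r.five_prime_pos - 1
        elif r.strand == "-":
            pos = r.five_prime_pos + 1
        else:
            raise InputError(f"unknown strand symbol {r.strand!r} in record {r.read_id}")
        if pos < 0 or (
            contig_lengths is not None
            and (r.chrom not in contig_lengths or pos >= contig_lengths[r.chrom])
        ):
            skipped += 1
            continue
        track.add(r.chrom, r.strand, pos)
        n += 1
    track.meta["n_records"] = n
    track.meta["skipped_out_of_bounds"] = skipped
    return track


def read_alignment_tsv(path: str) -> list[AlignmentRecord]:
    """5-column TSV: read id, chrom, strand, 5' position (0-based), barcode."""
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise InputError(f"{path}:{ln}: expected 5 columns")
            records.append(
                AlignmentRecord(parts[0], parts[1], parts[2], int(parts[3]), parts[4])
            )
    return records


def read_alignment_sam(path: str, barcode_from_name: bool = True) -> list[AlignmentRecord]:
    """Minimal SAM reader (mapped, primary records only).

    The random barcode is taken from the read name suffix after the last
    ``_`` when ``barcode_from_name`` (the common iCLIP convention after
    demultiplexing), otherwise empty.
    """
    import pysam

    records = []
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            five_prime = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            barcode = aln.query_name.rsplit("_", 1)[-1] if barcode_from_name else ""
            records.append(
                AlignmentRecord(aln.query_name, aln.reference_name, strand, five_prime, barcode)
            )
    return records
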