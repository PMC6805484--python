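"""Sparse stranded per-nucleotide crosslink-count tracks and bedGraph I/O.

A track stores, per (chrom, strand), a sparse mapping position -> count.
bedGraph files are written as one plus-strand and one minus-strand file per
replicate, 0-based half-open, counts positive in both files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import InputError

STRANDS = ("+", "-")


@dataclass
class CrosslinkTrack:
    """Stranded sparse crosslink-event counts for one replicate."""

    replicate: str = "merged"
    data: dict[tuple[str, str], dict[int, int]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def add(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        if strand not in STRANDS:
            raise InputError(f"unknown strand symbol {strand!r}")
        key = (chrom, strand)
        d = self.data.setdefault(key, {})
        d[pos] = d.get(pos, 0) + count
        self._arrays_cache = None

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self.data.get((chrom, strand), {}).get(pos, 0)

    def total(self) -> int:
        return sum(sum(d.values()) for d in self.data.values())

    # cached sorted-array view per (chrom, strand), for vectorized queries
    _arrays_cache: dict | None = None

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        if self._arrays_cache is None:
            self._arrays_cache = {}
        key = (chrom, strand)
        if key not in self._arrays_cache:
            d = self.data.get(key, {})
            if d:
                pos = np.array(sorted(d), dtype=np.int64)
                cnt = np.array([d[p] for p in pos], dtype=np.int64)
            else:
                pos = np.empty(0, dtype=np.int64)
                cnt = np.empty(0, dtype=np.int64)
            self._arrays_cache[key] = (pos, cnt)
        return self._arrays_cache[key]

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> int:
        pos, cnt = self.arrays(chrom, strand)
        lo, hi = np.searchsorted(pos, [start, end])
        return int(cnt[lo:hi].sum())

    def counts_at(self, chrom: str, strand: str, positions: np.ndarray) -> np.ndarray:
        """Counts at an arbitrary (sorted or not) position vector."""
        pos, cnt = self.arrays(chrom, strand)
        idx = np.searchsorted(pos, positions)
        out = np.zeros(len(positions), dtype=np.int64)
        ok = (idx < len(pos))
        ok[ok] &= pos[idx[ok]] == np.asarray(positions)[ok]
        out[ok] = cnt[idx[ok]]
        return out

    def chrom_strands(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.data))


def merge_tracks(tracks: Iterable[CrosslinkTrack], replicate: str = "merged") -> CrosslinkTrack:
    """Position-wise sum over replicates."""
    merged = CrosslinkTrack(replicate=replicate)
    for t in tracks:
        for (chrom, strand), d in t.data.items():
            md = merged.data.setdefault((chrom, strand), {})
            for p, c in d.items():
                md[p] = md.get(p, 0) + c
    merged._arrays_cache = None
    return merged


def write_bedgraph_pair(track: CrosslinkTrack, prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.plus.bedgraph`` / ``<prefix>.minus.bedgraph``.

    Runs of equal counts are collapsed into single records.
    """
    paths = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        path = f"{prefix}.{tag}.bedgraph"
        with open(path, "w") as fh:
            for (chrom, s), d in sorted(track.data.items()):
                if s != strand:
                    continue
                run_start = run_end = None
                run_val = None
                for p in sorted(d):
                    c = d[p]
                    if run_val == c and p == run_end:
                        run_end = p + 1
                    else:
                        if run_val is not None:
                            fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_val}\n")
                        run_start, run_end, run_val = p, p + 1, c
                if run_val is not None:
                    fh.write(f"{chrom}\t{run_start}\t{run_end}\t{run_val}\n")
        paths.append(path)
    return tuple(paths)


def read_bedgraph_pair(plus_path: str, minus_path: str, replicate: str = "rep") -> CrosslinkTrack:
    track = CrosslinkTrack(replicate=replicate)
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        if not os.path.exists(path):
            raise InputError(f"bedGraph file not found: {path}")
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise InputError(f"{path}:{ln}: expected 4 bedGraph columns")
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), parts[3]
                count = int(round(abs(float(value))))
                if count == 0:
                    continue
                d = track.data.setdefault((chrom, strand), {})
                for p in range(start, end):
                    d[p] = d.get(p, 0) + count
    return track


def bedgraph_contigs(paths: Iterable[str]) -> set[str]:
    contigs: set[str] = set()
    for path in paths:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                contigs.add(line.split("\t", 1)[0])
    return contigs
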