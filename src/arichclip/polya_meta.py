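"""Poly(A)-tail evidence in unmapped reads and crosslink metaprofiles around
polyadenylation sites and A-rich stretch starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import Annotation, SupportFilter
from .errors import InputError
from .seqcontext import ARichStretch
from .tracks import CrosslinkTrack


@dataclass
class ReadAStats:
    """Cumulative A-content and terminal-A curves over a read set."""

    n_reads: int
    a_content_thresholds: np.ndarray = field(default_factory=lambda: np.array([]))
    a_content_fraction: np.ndarray = field(default_factory=lambda: np.array([]))
    frac_over_half: float = 0.0  # headline: reads with A in more than half of positions
    terminal_k: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    terminal_percentage: np.ndarray = field(default_factory=lambda: np.array([]))


def _a_fraction(read: str) -> float:
    return read.upper().count("A") / len(read) if read else 0.0


def _terminal_a_run(read: str) -> int:
    n = 0
    for ch in reversed(read.upper()):
        if ch != "A":
            break
        n += 1
    return n


def read_a_content_curve(
    reads: Sequence[str], thresholds: Optional[np.ndarray] = None
) -> ReadAStats:
    """Fraction of reads whose A-content is at least each threshold."""
    if not reads:
        raise InputError("empty read set")
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 3)
    fracs = np.array([_a_fraction(r) for r in reads])
    curve = np.array([(fracs >= t).mean() for t in thresholds])
    return ReadAStats(
        n_reads=len(reads),
        a_content_thresholds=thresholds,
        a_content_fraction=curve,
        frac_over_half=float((fracs > 0.5).mean()),
    )


def terminal_a_curve(reads: Sequence[str], max_k: Optional[int] = None) -> ReadAStats:
    """Cumulative percentage of reads with at least k terminal A's.

    The terminal run is computed on the read as stored (no reverse
    complement); the k=0 entry is 100% by construction.
    """
    if not reads:
        raise InputError("empty read set")
    runs = np.array([_terminal_a_run(r) for r in reads])
    if max_k is None:
        max_k = int(runs.max()) + 1
    ks = np.arange(0, max_k + 1)
    pct = np.array([(runs >= k).mean() * 100.0 for k in ks])
    return ReadAStats(n_reads=len(reads), terminal_k=ks, terminal_percentage=pct)


def read_a_stats(reads: Sequence[str]) -> ReadAStats:
    """Both curves in one record."""
    a = read_a_content_curve(reads)
    t = terminal_a_curve(reads)
    a.terminal_k = t.terminal_k
    a.terminal_percentage = t.terminal_percentage
    return a


@dataclass
class MetaProfile:
    anchor_kind: str
    radius: int
    offsets: np.ndarray
    profile: np.ndarray  # normalized, unsmoothed
    smoothed: Optional[np.ndarray]
    n_regions: int
    smooth_width: Optional[int]
    enrichment_factor: Optional[float] = None
    total_counted: int = 0


def running_mean(values: np.ndarray, width: int) -> np.ndarray:
    """Centered running mean with truncated windows at the profile edges
    (shorter averaging near the ends, no padding)."""
    n = len(values)
    left = width // 2
    right = width - 1 - left
    cum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - left, 0)
    hi = np.minimum(np.arange(n) + right + 1, n)
    return (cum[hi] - cum[lo]) / (hi - lo)


def _window_counts(
    track: CrosslinkTrack, chrom: str, strand: str, anchor: int, radius: int
) -> np.ndarray:
    """Counts at strand-aware offsets -radius..+radius around an anchor
    (offset increases 5'->3' in transcript orientation)."""
    if strand == "+":
        positions = np.arange(anchor - radius, anchor + radius + 1)
        return track.counts_at(chrom, strand, positions).astype(float)
    positions = np.arange(anchor + radius, anchor - radius - 1, -1)
    pos_sorted = positions[::-1]
    counts = track.counts_at(chrom, strand, pos_sorted)[::-1]
    return counts.astype(float)


def polyA_site_metaprofile(
    track: CrosslinkTrack,
    annotation: Annotation,
    radius: int = 1000,
    min_events: int = 10,
    min_utr3: int = 1000,
    smooth: Optional[int] = 50,
    support_filter: Optional[SupportFilter] = None,
    enrichment_near: tuple[int, int] = (-150, -50),
    enrichment_body: tuple[int, int] = (-750, -650),
) -> MetaProfile:
    """Normalized crosslink profile around annotated polyadenylation sites.

    Transcript 3' ends with 3' UTRs of at least ``min_utr3`` nt anchor
    windows of 2*radius+1 nt; anchors with fewer than ``min_events`` events
    in the window are dropped. The summed profile is divided by the number
    of retained regions, smoothed with a running ``smooth``-nt window, and
    the enrichment factor is the smoothed mean over ``enrichment_near``
    divided by the mean over ``enrichment_body``.
    """
    anchors = annotation.polya_sites(support_filter, min_utr3=min_utr3)
    offsets = np.arange(-radius, radius + 1)
    total = np.zeros(len(offsets))
    n_regions = 0
    counted = 0
    for chrom, strand, pos in anchors:
        vec = _window_counts(track, chrom, strand, pos, radius)
        s = int(vec.sum())
        if s < min_events:
            continue
        total += vec
        counted += s
        n_regions += 1
    if n_regions == 0:
        raise InputError(
            f"no qualifying region: {len(anchors)} anchors, none with >= {min_events} events"
        )
    profile = total / n_regions
    smoothed = running_mean(profile, smooth) if smooth else None
    basis = smoothed if smoothed is not None else profile
    near = basis[(offsets >= enrichment_near[0]) & (offsets <= enrichment_near[1])]
    body = basis[(offsets >= enrichment_body[0]) & (offsets <= enrichment_body[1])]
    ef = float(near.mean() / body.mean()) if body.mean() > 0 else None
    return MetaProfile(
        anchor_kind="polyadenylation_site",
        radius=radius,
        offsets=offsets,
        profile=profile,
        smoothed=smoothed,
        n_regions=n_regions,
        smooth_width=smooth,
        enrichment_factor=ef,
        total_counted=counted,
    )


def stretch_start_metaprofile(
    track: CrosslinkTrack,
    stretches: Sequence[ARichStretch],
    radius: int = 100,
    matrix_radius: int = 50,
) -> tuple[MetaProfile, pd.DataFrame]:
    """Mean crosslink count per offset around A-rich stretch starts, plus the
    per-stretch matrix over ``2*matrix_radius+1`` nt (heatmap input)."""
    offsets = np.arange(-radius, radius + 1)
    total = np.zeros(len(offsets))
    rows = []
    index = []
    for i, st in enumerate(stretches):
        anchor = st.start if st.strand == "+" else st.end - 1
        vec = _window_counts(track, st.chrom, st.strand, anchor, radius)
        total += vec
        rows.append(vec[radius - matrix_radius : radius + matrix_radius + 1])
        index.append(f"stretch_{i + 1:05d}")
    n = max(1, len(stretches))
    profile = total / n
    matrix = pd.DataFrame(
        rows, index=index, columns=np.arange(-matrix_radius, matrix_radius + 1)
    )
    meta = MetaProfile(
        anchor_kind="stretch_start",
        radius=radius,
        offsets=offsets,
        profile=profile,
        smoothed=None,
        n_regions=len(stretches),
        smooth_width=None,
        total_counted=int(total.sum()),
    )
    return meta, matrix


def write_curves_tsv(stats: ReadAStats, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_reads={stats.n_reads}\tfrac_A_content_over_half={stats.frac_over_half:.6f}\n")
        fh.write("curve\tthreshold\tvalue\n")
        for t, v in zip(stats.a_content_thresholds, stats.a_content_fraction):
            fh.write(f"a_content\t{t:.3f}\t{v:.6f}\n")
        for k, v in zip(stats.terminal_k, stats.terminal_percentage):
            fh.write(f"terminal_a\t{k}\t{v:.6f}\n")


def write_metaprofile_tsv(meta: MetaProfile, path: str) -> None:
    with open(path, "w") as fh:
        ef = "NA" if meta.enrichment_factor is None else f"{meta.enrichment_factor:.6f}"
        fh.write(
            f"# anchor={meta.anchor_kind}\tn_regions={meta.n_regions}"
            f"\tsmooth={meta.smooth_width}\tenrichment_factor={ef}\n"
        )
        fh.write("offset\tprofile" + ("\tsmoothed" if meta.smoothed is not None else "") + "\n")
        for i, off in enumerate(meta.offsets):
            row = f"{off}\t{meta.profile[i]:.6f}"
            if meta.smoothed is not None:
                row += f"\t{meta.smoothed[i]:.6f}"
            fh.write(row + "\n")
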