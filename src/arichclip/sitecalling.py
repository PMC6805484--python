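"""Peak detection and the binding-site refinement cascade.

Candidate peaks are maximal runs of positions whose merged crosslink count is
significant under a negative binomial fitted (method of moments) to the
surrounding 500 nt of the gene's exonic territory. Peaks are then resized to
uniform 9-nt windows around their weighted centers, sparsely covered windows
removed, overlapping windows merged at the cumulative-half-maximum position,
windows assigned to single protein-coding genes and regions, and finally
filtered for reproducibility across replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .annotation import Annotation, REGION_LABELS, SupportFilter
from .errors import ConfigurationError
from .tracks import CrosslinkTrack, merge_tracks

logger = logging.getLogger(__name__)

SITE_WIDTH = 9


@dataclass
class NBParams:
    """Local negative-binomial peak model settings (and, when fitted, the
    method-of-moments estimates r = m^2/(v-m), p = m/v)."""

    window: int = 500
    alpha: float = 0.01
    r: Optional[float] = None
    p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ConfigurationError("window must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")


@dataclass
class RawPeak:
    chrom: str
    strand: str
    start: int
    end: int  # half-open
    counts: dict[int, int]  # position -> merged count (only covered positions)


@dataclass
class BindingSite:
    site_id: str
    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str
    region: str
    rep_counts: dict[str, int] = field(default_factory=dict)

    @property
    def center(self) -> int:
        return self.start + (self.end - self.start) // 2

    @property
    def merged_count(self) -> int:
        return sum(self.rep_counts.values())


def nb_tail(count: int | np.ndarray, r: float, p: float) -> float | np.ndarray:
    """P(X >= count) for X ~ NB(r, p) in the scipy parameterization."""
    return stats.nbinom.sf(np.asarray(count) - 1, r, p)


def call_raw_peaks(
    merged: CrosslinkTrack,
    annotation: Annotation,
    params: NBParams,
    support_filter: Optional[SupportFilter] = None,
) -> list[RawPeak]:
    """Significant-position runs over each gene's exonic territory.

    For every covered exonic position the NB background is fitted to all
    exonic positions of the same gene within ``params.window`` nt (zeros
    included). Windows whose variance does not exceed their mean fall back
    to a Poisson tail (logged). Positions outside annotated genes are never
    scanned, so no peak can lie outside a gene.
    """
    half = params.window // 2
    peaks: list[RawPeak] = []
    seen: set[tuple[str, str, int, int]] = set()
    n_poisson_fallback = 0

    for gene in annotation:
        exons = gene.merged_exons(support_filter)
        if not exons:
            continue
        positions = np.concatenate([np.arange(s, e) for s, e in exons])
        counts = merged.counts_at(gene.chrom, gene.strand, positions)
        covered = np.nonzero(counts > 0)[0]
        if len(covered) == 0:
            continue

        c1 = np.concatenate([[0], np.cumsum(counts)])
        c2 = np.concatenate([[0], np.cumsum(counts.astype(np.float64) ** 2)])
        lo = np.searchsorted(positions, positions[covered] - half)
        hi = np.searchsorted(positions, positions[covered] + half + 1)
        n = (hi - lo).astype(np.float64)
        s1 = c1[hi] - c1[lo]
        s2 = c2[hi] - c2[lo]
        m = s1 / n
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(n > 1, (s2 - n * m**2) / (n - 1), 0.0)
        c = counts[covered]
        pvals = np.ones(len(covered))
        nb_ok = v > m
        if nb_ok.any():
            r = m[nb_ok] ** 2 / (v[nb_ok] - m[nb_ok])
            p = m[nb_ok] / v[nb_ok]
            pvals[nb_ok] = stats.nbinom.sf(c[nb_ok] - 1, r, p)
        po = ~nb_ok
        if po.any():
            pvals[po] = stats.poisson.sf(c[po] - 1, m[po])
            n_poisson_fallback += int(po.sum())
        sig = pvals < params.alpha
        sig_pos = positions[covered][sig]
        if len(sig_pos) == 0:
            continue
        breaks = np.nonzero(np.diff(sig_pos) != 1)[0]
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [len(sig_pos) - 1]])
        for a, b in zip(run_starts, run_ends):
            start, end = int(sig_pos[a]), int(sig_pos[b]) + 1
            key = (gene.chrom, gene.strand, start, end)
            if key in seen:
                continue
            seen.add(key)
            pk_counts = {
                int(p_): int(c_)
                for p_, c_ in zip(sig_pos[a : b + 1], merged.counts_at(gene.chrom, gene.strand, sig_pos[a : b + 1]))
            }
            peaks.append(RawPeak(gene.chrom, gene.strand, start, end, pk_counts))

    if n_poisson_fallback:
        logger.info("Poisson fallback used at %d positions (local variance <= mean)", n_poisson_fallback)
    return peaks


def weighted_center(peak: RawPeak) -> int:
    """Count-weighted mean position, rounded half toward the 5' end
    (genomic left on '+', genomic right on '-')."""
    den = sum(peak.counts.values())
    if den == 0:
        raise ValueError("weighted_center of an all-zero peak is undefined")
    num = sum(p * c for p, c in peak.counts.items())
    q, rem = divmod(num, den)
    if 2 * rem < den:
        return q
    if 2 * rem > den:
        return q + 1
    return q if peak.strand == "+" else q + 1


def resize_to_uniform_window(
    center: int, contig_length: int, width: int = SITE_WIDTH
) -> Optional[tuple[int, int]]:
    """9-nt (or other odd-width) window centered on ``center``; returns None
    (caller logs/drops) when the window would leave the contig."""
    if width % 2 == 0:
        raise ConfigurationError("window width must be odd")
    half = width // 2
    start, end = center - half, center + half + 1
    if start < 0 or end > contig_length:
        return None
    return start, end


def sparse_filter(
    window: tuple[int, int],
    merged: CrosslinkTrack,
    chrom: str,
    strand: str,
    min_covered: int = 3,
) -> bool:
    """Keep iff at least ``min_covered`` positions in the window have
    crosslink events."""
    pos, cnt = merged.arrays(chrom, strand)
    lo, hi = np.searchsorted(pos, [window[0], window[1]])
    return int((cnt[lo:hi] > 0).sum()) >= min_covered


def merge_windows(
    windows: Sequence[tuple[int, int]],
    merged: CrosslinkTrack,
    chrom: str,
    strand: str,
    contig_length: Optional[int] = None,
    width: int = SITE_WIDTH,
    direction: str = "genomic",
) -> list[tuple[int, int]]:
    """Iteratively merge overlapping windows at the cumulative-half-maximum.

    For every cluster of overlapping windows: take the union span, scan the
    merged counts in 5'->3' of the chosen ``direction`` ('genomic': always
    left->right; 'transcript': right->left on the minus strand), and place
    the new center at the first position where the cumulative count reaches
    half the span total. Repeats until no two windows overlap.
    """
    current = sorted(set(windows))
    half = width // 2
    while True:
        out: list[tuple[int, int]] = []
        changed = False
        i = 0
        while i < len(current):
            j = i + 1
            span_end = current[i][1]
            while j < len(current) and current[j][0] < span_end:
                span_end = max(span_end, current[j][1])
                j += 1
            cluster = current[i:j]
            if len(cluster) == 1:
                out.append(cluster[0])
            else:
                changed = True
                span_start = cluster[0][0]
                positions = np.arange(span_start, span_end)
                counts = merged.counts_at(chrom, strand, positions)
                total = int(counts.sum())
                if total == 0:
                    center = int(positions[len(positions) // 2])
                else:
                    if direction == "transcript" and strand == "-":
                        order = np.arange(len(positions))[::-1]
                    else:
                        order = np.arange(len(positions))
                    cum = np.cumsum(counts[order])
                    k = int(np.argmax(2 * cum >= total))
                    center = int(positions[order[k]])
                start, end = center - half, center + half + 1
                if start < 0 or (contig_length is not None and end > contig_length):
                    logger.info("merged window at %s:%d dropped at contig edge", chrom, center)
                else:
                    out.append((start, end))
            i = j
        current = sorted(set(out))
        if not changed:
            return current


def assign_gene_region(
    window: tuple[int, int],
    annotation: Annotation,
    chrom: str,
    strand: str,
    support_filter: Optional[SupportFilter] = None,
) -> tuple[str, str]:
    """Returns ``(gene_id, region_label)`` or ``('', reason_code)`` for
    windows overlapping none or multiple protein-coding genes."""
    genes = annotation.genes_overlapping(chrom, strand, window[0], window[1], protein_coding_only=True)
    if len(genes) == 0:
        return "", "no_gene_overlap"
    if len(genes) > 1:
        return "", "multiple_gene_overlap"
    gene = genes[0]
    if not gene.qualifying_transcripts(support_filter):
        return "", "no_qualifying_transcript"
    region = annotation.region_of_window(gene, window[0], window[1], support_filter)
    return gene.gene_id, REGION_LABELS[region]


def reproducibility_filter(
    window: tuple[int, int],
    tracks: Sequence[CrosslinkTrack],
    chrom: str,
    strand: str,
    min_events: int = 3,
) -> bool:
    """Keep iff every replicate has at least ``min_events`` crosslink events
    within the window."""
    return all(t.window_sum(chrom, strand, window[0], window[1]) >= min_events for t in tracks)


def call_binding_sites(
    tracks: Sequence[CrosslinkTrack],
    annotation: Annotation,
    contig_lengths: Mapping[str, int],
    params: Optional[NBParams] = None,
    support_filter: Optional[SupportFilter] = None,
    min_covered: int = 3,
    min_events: int = 3,
    merge_direction: str = "genomic",
    exclude_introns: bool = True,
) -> tuple[list[BindingSite], dict]:
    """Full cascade from replicate tracks to final binding sites.

    Returns the sites plus a funnel dict tallying every exclusion reason
    (auditable counterpart of the peak -> site refinement).
    """
    params = params or NBParams()
    merged = merge_tracks(tracks)
    funnel: dict[str, int] = {}

    peaks = call_raw_peaks(merged, annotation, params, support_filter)
    funnel["raw_peaks"] = len(peaks)

    windows_by_cs: dict[tuple[str, str], list[tuple[int, int]]] = {}
    n_edge = n_sparse = 0
    for pk in peaks:
        win = resize_to_uniform_window(weighted_center(pk), contig_lengths[pk.chrom])
        if win is None:
            n_edge += 1
            continue
        if not sparse_filter(win, merged, pk.chrom, pk.strand, min_covered):
            n_sparse += 1
            continue
        windows_by_cs.setdefault((pk.chrom, pk.strand), []).append(win)
    funnel["dropped_contig_edge"] = n_edge
    funnel["dropped_sparse"] = n_sparse
    funnel["windows_after_sparse"] = sum(len(v) for v in windows_by_cs.values())

    sites: list[BindingSite] = []
    reasons: dict[str, int] = {}
    n_merged = n_intron = n_repro = 0
    for (chrom, strand), wins in sorted(windows_by_cs.items()):
        merged_wins = merge_windows(
            wins, merged, chrom, strand, contig_lengths[chrom], direction=merge_direction
        )
        n_merged += len(merged_wins)
        for win in merged_wins:
            gene_id, region = assign_gene_region(win, annotation, chrom, strand, support_filter)
            if not gene_id:
                reasons[region] = reasons.get(region, 0) + 1
                continue
            if exclude_introns and region == "intron":
                n_intron += 1
                continue
            if not reproducibility_filter(win, tracks, chrom, strand, min_events):
                n_repro += 1
                continue
            rep_counts = {
                t.replicate: t.window_sum(chrom, strand, win[0], win[1]) for t in tracks
            }
            sites.append(
                BindingSite("", chrom, strand, win[0], win[1], gene_id, region, rep_counts)
            )
    funnel["windows_after_merge"] = n_merged
    funnel["excluded_gene_assignment"] = reasons
    funnel["excluded_intron"] = n_intron
    funnel["dropped_reproducibility"] = n_repro

    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    for i, s in enumerate(sites, 1):
        s.site_id = f"site_{i:05d}"
    funnel["final_sites"] = len(sites)
    return sites, funnel


def write_sites_bed(sites: Sequence[BindingSite], path: str, sob: Optional[Mapping[str, object]] = None) -> None:
    """BED6+ site output: name=site id, score=merged count; extra columns
    gene, region, per-replicate counts, mean SOB (NA when undefined)."""
    with open(path, "w") as fh:
        fh.write("# BED6+: chrom start end name score strand gene region rep_counts mean_sob\n")
        for s in sites:
            reps = ",".join(f"{k}={v}" for k, v in sorted(s.rep_counts.items()))
            sob_val = "NA"
            if sob is not None and s.site_id in sob:
                sv = sob[s.site_id]
                if getattr(sv, "defined", False):
                    sob_val = f"{sv.mean_sob:.4f}"
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.site_id}\t{s.merged_count}\t{s.strand}"
                f"\t{s.gene_id}\t{s.region}\t{reps}\t{sob_val}\n"
            )
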