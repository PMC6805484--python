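"""Sequence context of binding sites: positional 4-mer profiles, empirical
k-mer z-scores, the A-rich stretch maximization search, and SOB
stratification by longest continuous A-run (LCA).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import Annotation, SupportFilter
from .errors import ConfigurationError, InputError
from .genome import GenomeStore
from .sitecalling import BindingSite

ALL_4MERS = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
REGION_CLASSES = ("upstream_flank", "site_window", "downstream_flank", "combined")


@dataclass(frozen=True)
class StretchSearchParams:
    """A-rich stretch search settings: window sizes scanned within the
    search space downstream of the site center, and the keep-thresholds."""

    search_space: int = 55
    min_window: int = 8
    max_window: int = 30
    min_a_content: float = 0.70
    min_weighted_a: float = 11.0
    min_lca: int = 4
    exclusion_mode: str = "any"  # 'any': drop on failing any threshold; 'all': drop only if all fail

    def __post_init__(self) -> None:
        if not 1 <= self.min_window <= self.max_window <= self.search_space:
            raise ConfigurationError("window sizes must lie within [1, search_space]")
        if self.exclusion_mode not in ("any", "all"):
            raise ConfigurationError("exclusion_mode must be 'any' or 'all'")


@dataclass
class ARichStretch:
    chrom: str
    strand: str
    start: int
    end: int
    a_content: float
    lca: int
    weighted_a: float
    site_ids: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class KmerZScore:
    kmer: str
    region: str
    observed: float
    bg_mean: float
    bg_sd: float
    z: Optional[float]


def longest_a_run(seq: str) -> int:
    best = cur = 0
    for ch in seq:
        cur = cur + 1 if ch == "A" else 0
        if cur > best:
            best = cur
    return best


def _passes(a_content: float, weighted: float, lca: int, params: StretchSearchParams) -> bool:
    ok_a = a_content >= params.min_a_content
    ok_w = weighted >= params.min_weighted_a
    ok_l = lca >= params.min_lca
    if params.exclusion_mode == "any":
        return ok_a and ok_w and ok_l
    return ok_a or ok_w or ok_l


def find_stretch_in_sequence(
    seq: str, params: StretchSearchParams
) -> Optional[tuple[int, int, float, int, float]]:
    """Maximization search over a transcript-orientation search space.

    For every window size the placement with maximal A-content is selected
    (ties -> the placement closer to the site, i.e. smaller offset), giving
    one candidate per size. Candidates failing the keep-thresholds are
    dropped; survivors are ranked by LCA, then weighted A-content, then
    smaller size, then smaller offset.

    Returns ``(offset, size, a_content, lca, weighted_a)`` or None.
    """
    n = len(seq)
    if n < params.min_window:
        return None
    is_a = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("A")
    cum = np.concatenate([[0], np.cumsum(is_a)])
    best = None
    for w in range(params.min_window, min(params.max_window, n) + 1):
        counts = cum[w:] - cum[:-w]  # A count per offset
        offset = int(np.argmax(counts))  # argmax takes the first maximum
        n_a = int(counts[offset])
        a_content = n_a / w
        window = seq[offset : offset + w]
        lca = longest_a_run(window)
        weighted = a_content * n_a
        if not _passes(a_content, weighted, lca, params):
            continue
        key = (lca, weighted, -w, -offset)
        if best is None or key > best[0]:
            best = (key, (offset, w, a_content, lca, weighted))
    return None if best is None else best[1]


def find_arich_stretch(
    site: BindingSite,
    genome: GenomeStore,
    params: Optional[StretchSearchParams] = None,
) -> Optional[ARichStretch]:
    """A-rich stretch in the search space starting at the site center and
    extending 3' (strand-aware)."""
    params = params or StretchSearchParams()
    center = site.center
    if site.strand == "+":
        seq = genome.fetch(site.chrom, center, center + params.search_space, "+")
    else:
        seq = genome.fetch(site.chrom, center - params.search_space + 1, center + 1, "-")
    hit = find_stretch_in_sequence(seq, params)
    if hit is None:
        return None
    offset, w, a_content, lca, weighted = hit
    if site.strand == "+":
        start, end = center + offset, center + offset + w
    else:
        start, end = center - offset - w + 1, center - offset + 1
    return ARichStretch(site.chrom, site.strand, start, end, a_content, lca, weighted, [site.site_id])


def merge_neighboring_stretches(stretches: Iterable[ARichStretch]) -> list[ARichStretch]:
    """Among overlapping stretches keep the highest scoring one (max LCA,
    then max weighted A-content, then 5'-most); all contributing sites are
    linked to the survivor. Output is non-overlapping."""
    out: list[ARichStretch] = []
    by_cs: dict[tuple[str, str], list[ARichStretch]] = {}
    for st in stretches:
        by_cs.setdefault((st.chrom, st.strand), []).append(st)
    for (chrom, strand), group in sorted(by_cs.items()):
        group.sort(key=lambda s: s.start)
        cluster: list[ARichStretch] = []
        cluster_end = None
        for st in group + [None]:  # type: ignore[list-item]
            if st is not None and (cluster_end is None or st.start < cluster_end):
                cluster.append(st)
                cluster_end = max(cluster_end or st.end, st.end)
                continue
            if cluster:
                five_prime = (lambda s: -s.start) if strand == "+" else (lambda s: s.start)
                winner = max(cluster, key=lambda s: (s.lca, s.weighted_a, five_prime(s)))
                linked = sorted({sid for s in cluster for sid in s.site_ids})
                out.append(
                    ARichStretch(
                        winner.chrom, winner.strand, winner.start, winner.end,
                        winner.a_content, winner.lca, winner.weighted_a, linked,
                    )
                )
            if st is not None:
                cluster = [st]
                cluster_end = st.end
    return out


def kmer_positional_profile(
    sites: Sequence[BindingSite],
    genome: GenomeStore,
    kmers: Sequence[str],
    halfwindow: int = 50,
) -> pd.DataFrame:
    """Per-offset k-mer start frequency across sites (offset relative to the
    site center, transcript orientation). Offsets where a site's sequence is
    unavailable (contig edge) are excluded from that site's denominator."""
    k = len(kmers[0])
    if any(len(km) != k for km in kmers):
        raise ConfigurationError("all query k-mers must share one length")
    offsets = np.arange(-halfwindow, halfwindow + 1)
    hits = {km: np.zeros(len(offsets)) for km in kmers}
    denom = np.zeros(len(offsets))
    for site in sites:
        c = site.center
        if site.strand == "+":
            lo = c - halfwindow
            seq = genome.fetch(site.chrom, lo, c + halfwindow + k, "+")
            lead_clip = max(0, -(c - halfwindow))
        else:
            hi = c + halfwindow + 1
            seq = genome.fetch(site.chrom, c - halfwindow - k + 1, hi, "-")
            lead_clip = max(0, hi - genome.length(site.chrom))
        for i, off in enumerate(offsets):
            j = off + halfwindow - lead_clip
            if j < 0 or j + k > len(seq):
                continue
            denom[i] += 1
            sub = seq[j : j + k]
            if sub in hits:
                hits[sub][i] += 1
    data = {"offset": offsets}
    with np.errstate(invalid="ignore", divide="ignore"):
        for km in kmers:
            data[km] = np.where(denom > 0, hits[km] / np.maximum(denom, 1), 0.0)
    return pd.DataFrame(data).set_index("offset")


def _count_kmers_layout(
    windows: Iterable[tuple[str, str, int, int]],
    genome: GenomeStore,
    flank: int,
    k: int = 4,
) -> dict[str, dict[str, int]]:
    """4-mer counts per region class over a set of 9-nt windows with flanks.

    Regions are taken in transcript orientation: ``flank`` nt upstream of the
    window, the window itself, and ``flank`` nt downstream; 'combined' counts
    k-mers over the full contiguous span (including those straddling region
    boundaries).
    """
    counts: dict[str, dict[str, int]] = {rc: {} for rc in REGION_CLASSES}
    for chrom, strand, start, end in windows:
        width = end - start
        if strand == "+":
            full = genome.fetch(chrom, start - flank, end + flank, "+")
            lead = flank - max(0, flank - start)
        else:
            full = genome.fetch(chrom, start - flank, end + flank, "-")
            lead = flank - max(0, (end + flank) - genome.length(chrom))
        regions = {
            "upstream_flank": full[:lead],
            "site_window": full[lead : lead + width],
            "downstream_flank": full[lead + width :],
            "combined": full,
        }
        for rc, seq in regions.items():
            d = counts[rc]
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                d[km] = d.get(km, 0) + 1
    return counts


def kmer_zscores(
    sites: Sequence[BindingSite],
    genome: GenomeStore,
    annotation: Annotation,
    flank: int = 40,
    bg_windows: int = 1000,
    bg_repeats: int = 100,
    seed: int = 0,
    support_filter: Optional[SupportFilter] = None,
    width: int = 9,
) -> pd.DataFrame:
    """Empirical z-scores for all 4-mers against a resampled 3' UTR background.

    Observed counts come from the site windows (+flanks); the background is
    ``bg_repeats`` independent draws of ``bg_windows`` random 9-nt windows
    in annotated 3' UTRs, counted in the identical layout. All counts are
    normalized per window so observed and background are on one scale
    regardless of the number of sites.
    """
    utrs = annotation.utr3_intervals(support_filter)
    utrs = [(c, s, a, b) for c, s, a, b in utrs if b - a >= width]
    if not utrs:
        raise InputError("no 3' UTR interval can hold a background window")
    lengths = np.array([b - a - width + 1 for _, _, a, b in utrs], dtype=float)
    probs = lengths / lengths.sum()
    rng = np.random.default_rng(seed)

    site_windows = [(s.chrom, s.strand, s.start, s.end) for s in sites]
    obs = _count_kmers_layout(site_windows, genome, flank)
    n_sites = max(1, len(site_windows))

    bg = {rc: np.zeros((bg_repeats, len(ALL_4MERS))) for rc in REGION_CLASSES}
    kmer_idx = {km: i for i, km in enumerate(ALL_4MERS)}
    for rep in range(bg_repeats):
        choice = rng.choice(len(utrs), size=bg_windows, p=probs)
        starts = rng.integers(0, 2**31, size=bg_windows)
        windows = []
        for idx, raw in zip(choice, starts):
            chrom, strand, a, b = utrs[idx]
            start = a + int(raw % (b - a - width + 1))
            windows.append((chrom, strand, start, start + width))
        cnt = _count_kmers_layout(windows, genome, flank)
        for rc in REGION_CLASSES:
            for km, c in cnt[rc].items():
                if km in kmer_idx:
                    bg[rc][rep, kmer_idx[km]] = c
    rows = []
    for rc in REGION_CLASSES:
        mat = bg[rc] / bg_windows
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1)
        for km in ALL_4MERS:
            i = kmer_idx[km]
            observed = obs[rc].get(km, 0) / n_sites
            z = (observed - mean[i]) / sd[i] if sd[i] > 0 else None
            rows.append(
                {
                    "kmer": km,
                    "region": rc,
                    "observed": observed,
                    "bg_mean": mean[i],
                    "bg_sd": sd[i],
                    "z": z,
                }
            )
    return pd.DataFrame(rows)


def stratify_sob_by_lca(
    sites: Sequence[BindingSite],
    sob: Mapping[str, object],
    stretches: Sequence[ARichStretch],
) -> pd.DataFrame:
    """Mean/s.d. of defined SOB per LCA bin, plus a 'no_stretch' bin holding
    the sites without an associated stretch."""
    site_lca: dict[str, int] = {}
    for st in stretches:
        for sid in st.site_ids:
            site_lca[sid] = max(site_lca.get(sid, 0), st.lca)
    groups: dict[object, list[float]] = {}
    for s in sites:
        v = sob.get(s.site_id)
        if v is None or not getattr(v, "defined", False):
            continue
        key = site_lca.get(s.site_id, "no_stretch")
        groups.setdefault(key, []).append(v.mean_sob)
    rows = []
    for key in sorted(groups, key=lambda k: (isinstance(k, str), k)):
        vals = np.array(groups[key])
        rows.append(
            {
                "lca_bin": key,
                "n": len(vals),
                "mean_sob": float(vals.mean()),
                "sd_sob": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def write_stretches_bed(stretches: Sequence[ARichStretch], path: str) -> None:
    """BED6+ with score=LCA; extra columns a_content, weighted_a, site ids."""
    with open(path, "w") as fh:
        fh.write("# BED6+: chrom start end name score(lca) strand a_content weighted_a site_ids\n")
        for i, st in enumerate(sorted(stretches, key=lambda s: (s.chrom, s.start)), 1):
            fh.write(
                f"{st.chrom}\t{st.start}\t{st.end}\tstretch_{i:05d}\t{st.lca}\t{st.strand}"
                f"\t{st.a_content:.4f}\t{st.weighted_a:.4f}\t{','.join(st.site_ids)}\n"
            )
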