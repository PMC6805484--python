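"""Signal-over-background (SOB) binding-strength statistic.

SOB for a site is its 9-nt window crosslink count divided by the host gene's
background crosslink density. Background density is the sum of crosslinks at
effective exonic positions outside all site windows (each expanded by 5 nt)
divided by the gene's effective exon length, where the 3' UTR contribution is
truncated 10 nt past the 3'-most site in the UTR (or at 500 nt when the UTR
holds no site). Computed per replicate, then averaged; genes with fewer than
10 background events yield an undefined (never zero) SOB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .annotation import Annotation, Gene, SupportFilter
from .errors import AnnotationError
from .intervals import (
    clip_at_3prime_boundary,
    intersect_intervals,
    merge_intervals,
    subtract_intervals,
    total_length,
    truncate_from_5prime,
)
from .sitecalling import BindingSite
from .tracks import CrosslinkTrack


@dataclass
class GeneBackground:
    gene_id: str
    replicate: str
    background_count: int
    effective_length: int

    @property
    def density(self) -> float:
        return self.background_count / self.effective_length


@dataclass
class SobValue:
    site_id: str
    ratios: dict[str, Optional[float]] = field(default_factory=dict)
    mean_sob: Optional[float] = None
    defined: bool = False
    reason: str = ""


def effective_exon_intervals(
    gene: Gene,
    sites: Sequence[BindingSite],
    support_filter: Optional[SupportFilter] = None,
    utr3_fallback: int = 500,
    past_site: int = 10,
) -> list[tuple[int, int]]:
    """Merged exon intervals with the 3' UTR truncated, strand-aware.

    With a 3'-UTR site: UTR kept up to ``past_site`` nt past the 3'-most
    site. Without: the first ``utr3_fallback`` nt of UTR (in transcript
    direction) are kept.
    """
    exons = gene.merged_exons(support_filter)
    if not exons:
        raise AnnotationError(f"gene {gene.gene_id} has no exons")
    utr3 = gene.merged_region("three_prime_utr", support_filter)
    if not utr3:
        return exons
    non_utr = subtract_intervals(exons, utr3)
    utr3_sites = [s for s in sites if s.gene_id == gene.gene_id and s.region == "3UTR"]
    if utr3_sites:
        if gene.strand == "+":
            boundary = max(s.end for s in utr3_sites) + past_site
        else:
            boundary = min(s.start for s in utr3_sites) - past_site
        kept_utr = clip_at_3prime_boundary(utr3, gene.strand, boundary)
    else:
        kept_utr = truncate_from_5prime(utr3, gene.strand, utr3_fallback)
    return merge_intervals(non_utr + kept_utr)


def effective_exon_length(
    gene: Gene,
    sites: Sequence[BindingSite],
    support_filter: Optional[SupportFilter] = None,
    utr3_fallback: int = 500,
    past_site: int = 10,
) -> int:
    return total_length(
        effective_exon_intervals(gene, sites, support_filter, utr3_fallback, past_site)
    )


def gene_background(
    gene: Gene,
    track: CrosslinkTrack,
    sites: Sequence[BindingSite],
    support_filter: Optional[SupportFilter] = None,
    buffer: int = 5,
    utr3_fallback: int = 500,
    past_site: int = 10,
) -> GeneBackground:
    """Crosslinks at effective exonic positions outside site windows +-buffer."""
    effective = effective_exon_intervals(gene, sites, support_filter, utr3_fallback, past_site)
    eff_len = total_length(effective)
    if eff_len == 0:
        raise AnnotationError(f"gene {gene.gene_id} has zero effective exon length")
    gene_sites = [s for s in sites if s.gene_id == gene.gene_id]
    excluded = [(s.start - buffer, s.end + buffer) for s in gene_sites]
    bg_intervals = subtract_intervals(effective, excluded)
    bg_count = sum(
        track.window_sum(gene.chrom, gene.strand, s, e) for s, e in bg_intervals
    )
    return GeneBackground(gene.gene_id, track.replicate, bg_count, eff_len)


def site_sob(
    site: BindingSite,
    backgrounds: Mapping[str, GeneBackground],
    min_background: int = 10,
    strict: bool = False,
) -> SobValue:
    """Per-replicate signal/background ratios averaged into the site SOB.

    A replicate whose gene background holds fewer than ``min_background``
    events (or has zero density against a nonzero window count) contributes
    no ratio. By default the mean is over the defined replicates and the SOB
    is undefined only when no replicate qualifies; ``strict=True`` requires
    every replicate to qualify.
    """
    out = SobValue(site_id=site.site_id)
    for rep, count in sorted(site.rep_counts.items()):
        bg = backgrounds.get(rep)
        if bg is None:
            out.ratios[rep] = None
            continue
        if bg.background_count < min_background:
            out.ratios[rep] = None
        elif bg.density == 0:
            out.ratios[rep] = None
            out.reason = "zero_density"
        else:
            out.ratios[rep] = count / bg.density
    defined = [r for r in out.ratios.values() if r is not None]
    if not defined or (strict and len(defined) < len(out.ratios)):
        out.defined = False
        out.reason = out.reason or "background_below_minimum"
    else:
        out.defined = True
        out.mean_sob = sum(defined) / len(defined)
    return out


def compute_sob(
    sites: Sequence[BindingSite],
    tracks: Sequence[CrosslinkTrack],
    annotation: Annotation,
    support_filter: Optional[SupportFilter] = None,
    min_background: int = 10,
    buffer: int = 5,
    strict: bool = False,
) -> dict[str, SobValue]:
    """SOB for every site, computing gene backgrounds once per (gene, rep)."""
    by_gene: dict[str, list[BindingSite]] = {}
    for s in sites:
        by_gene.setdefault(s.gene_id, []).append(s)
    out: dict[str, SobValue] = {}
    for gene_id, gene_sites in by_gene.items():
        gene = annotation.genes[gene_id]
        backgrounds = {
            t.replicate: gene_background(gene, t, sites, support_filter, buffer)
            for t in tracks
        }
        for s in gene_sites:
            out[s.site_id] = site_sob(s, backgrounds, min_background, strict)
    return out


def write_sob_tsv(
    sob: Mapping[str, SobValue], sites: Sequence[BindingSite], path: str
) -> None:
    reps = sorted({r for s in sites for r in s.rep_counts})
    with open(path, "w") as fh:
        header = ["site_id", "gene", "region"] + [f"sob_{r}" for r in reps] + [
            "mean_sob",
            "defined",
            "reason",
        ]
        fh.write("\t".join(header) + "\n")
        for s in sites:
            v = sob[s.site_id]
            row = [s.site_id, s.gene_id, s.region]
            for r in reps:
                ratio = v.ratios.get(r)
                row.append("NA" if ratio is None else f"{ratio:.4f}")
            row.append("NA" if v.mean_sob is None else f"{v.mean_sob:.4f}")
            row.append(str(int(v.defined)))
            row.append(v.reason or ".")
            fh.write("\t".join(row) + "\n")
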