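"""Synthetic genomes, annotations, crosslink tracks and reads with ground truth.

Every downstream stage of the pipeline is tested against data from this
module: genes with planted 9-nt crosslink footprints positioned a fixed
offset upstream of planted A-rich stretches in 3' UTRs, negative-binomial
background noise over exons, and unmapped-style reads carrying untemplated
terminal A runs.

Determinism contract: identical (seed, config) produce byte-identical
outputs. All randomness flows through generators derived from
``numpy.random.SeedSequence([seed, stream])`` with fixed stream ids.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .annotation import Annotation, Gene, Transcript
from .errors import ConfigurationError
from .genome import revcomp
from .tracks import CrosslinkTrack

BASES = np.array(list("ACGT"))
# background composition keeps A below 0.3 so planted stretches stand out
BACKGROUND_BASE_PROBS = np.array([0.22, 0.28, 0.28, 0.22])

_STREAM_REFERENCE = 0
_STREAM_TRACKS = 1
_STREAM_READS = 2


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (1500, 3000)
    utr5_length_range: tuple[int, int] = (50, 150)
    utr3_length_range: tuple[int, int] = (1100, 1500)
    n_replicates: int = 3
    background_rate: float = 0.05
    site_enrichment: float = 50.0
    dispersion: float = 2.0
    frac_genes_with_stretch: float = 0.8
    stretch_length_range: tuple[int, int] = (15, 25)
    stretch_purity: float = 0.9
    site_offset: int = 15
    polyA_read_fraction: float = 0.06
    n_reads: int = 2000
    read_length: int = 75
    expression_sigma: float = 1.0
    expression_min: float = 0.3
    expression_max: float = 2.0
    intergenic_gap: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        for name in ("background_rate", "site_enrichment", "dispersion"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("frac_genes_with_stretch", "stretch_purity", "polyA_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        lo, hi = self.stretch_length_range
        if not (8 <= lo <= hi <= 30):
            raise ConfigurationError("stretch_length_range must lie within [8, 30]")
        if self.stretch_purity < 0.7:
            raise ConfigurationError("stretch_purity must be >= 0.7")
        if hi + 20 > self.utr3_length_range[0]:
            raise ConfigurationError("stretch longer than its host 3' UTR")
        if self.read_length <= 9:
            raise ConfigurationError("read_length must exceed the 9-nt barcode")


@dataclass
class PlantedSite:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 9-nt footprint, half-open
    end: int
    enrichment: float | None = None  # overrides config.site_enrichment when set

    @property
    def center(self) -> int:
        return self.start + 4


@dataclass
class PlantedStretch:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    purity: float
    a_content: float
    lca: int


@dataclass
class SyntheticTruth:
    planted_sites: list[PlantedSite] = field(default_factory=list)
    planted_stretches: list[PlantedStretch] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=dict)
    config: SimulationConfig | None = None


def _rng(config: SimulationConfig, stream: int, extra: tuple[int, ...] = ()) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream) + extra))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.choice(4, size=n, p=BACKGROUND_BASE_PROBS)])


def _longest_a_run(seq: str) -> int:
    best = cur = 0
    for ch in seq:
        cur = cur + 1 if ch == "A" else 0
        best = max(best, cur)
    return best


def _stretch_seq(rng: np.random.Generator, length: int, purity: float) -> str:
    """A-rich stretch: round((1-purity)*length) non-A bases at random
    interior positions, first/last base forced to A so the realized interval
    begins and ends A-rich."""
    n_non_a = int(round((1.0 - purity) * length))
    seq = ["A"] * length
    if n_non_a > 0 and length > 2:
        pos = rng.choice(np.arange(1, length - 1), size=min(n_non_a, length - 2), replace=False)
        for p in pos:
            seq[p] = str(rng.choice(["C", "G", "T"]))
    return "".join(seq)


def generate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], Annotation, SyntheticTruth]:
    """Build a two-chromosome genome, a GTF-writable annotation and the truth.

    Genes alternate between chromosomes and strands; each gene is a
    single-exon transcript laid out 5'UTR / CDS / 3'UTR in transcript
    orientation (minus-strand genes are reverse-complemented into the
    genome). A fraction of genes carries one planted A-rich stretch in the
    3' UTR with a planted 9-nt footprint exactly ``site_offset`` nt upstream
    (footprint center to stretch start, strand-aware).
    """
    rng = _rng(config, _STREAM_REFERENCE)
    truth = SyntheticTruth(config=config)
    chrom_parts: dict[str, list[str]] = {"chr1": [], "chr2": []}
    chrom_cursor = {"chr1": 0, "chr2": 0}
    genes: list[Gene] = []

    n_with_stretch = int(round(config.frac_genes_with_stretch * config.n_genes))
    has_stretch = np.zeros(config.n_genes, dtype=bool)
    has_stretch[:n_with_stretch] = True
    rng.shuffle(has_stretch)

    for i in range(config.n_genes):
        gene_id = f"G{i + 1:04d}"
        chrom = "chr1" if i % 2 == 0 else "chr2"
        strand = "+" if (i // 2) % 2 == 0 else "-"
        glen = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        u5 = int(rng.integers(config.utr5_length_range[0], config.utr5_length_range[1] + 1))
        u3 = int(rng.integers(config.utr3_length_range[0], config.utr3_length_range[1] + 1))
        if u5 + u3 + 300 > glen:
            glen = u5 + u3 + 300
        cds_len = glen - u5 - u3

        tseq = list(_random_seq(rng, glen))  # transcript orientation
        stretch_info = None
        if has_stretch[i]:
            slen = int(
                rng.integers(config.stretch_length_range[0], config.stretch_length_range[1] + 1)
            )
            if slen + 20 > u3:
                raise ConfigurationError(
                    f"planted stretch ({slen} nt) does not fit in 3' UTR ({u3} nt)"
                )
            # transcript coord of stretch start: inside 3'UTR, leaving room
            # so the footprint (center at start - site_offset) stays exonic
            lo = u5 + cds_len + max(60, config.site_offset + 5)
            hi = u5 + glen - u5 - 10 - slen  # = glen - 10 - slen
            start_t = int(rng.integers(lo, max(lo + 1, hi)))
            sseq = _stretch_seq(rng, slen, config.stretch_purity)
            tseq[start_t : start_t + slen] = list(sseq)
            # scrub flanking A's so the planted interval is the local optimum
            for p in (start_t - 1, start_t + slen):
                if 0 <= p < glen and tseq[p] == "A":
                    tseq[p] = "C"
            stretch_info = (start_t, slen, sseq)

        tseq = "".join(tseq)
        gstart = chrom_cursor[chrom] + config.intergenic_gap
        gap = _random_seq(rng, config.intergenic_gap)
        gseq = tseq if strand == "+" else revcomp(tseq)
        chrom_parts[chrom].extend([gap, gseq])
        chrom_cursor[chrom] = gstart + glen
        gend = gstart + glen

        def g(t_pos: int) -> int:
            """Transcript coord -> genomic coord of that base."""
            return gstart + t_pos if strand == "+" else gend - 1 - t_pos

        def g_iv(t_start: int, t_end: int) -> tuple[int, int]:
            if strand == "+":
                return gstart + t_start, gstart + t_end
            return gend - t_end, gend - t_start

        tx = Transcript(
            transcript_id=f"{gene_id}.t1",
            start=gstart,
            end=gend,
            level=1,
            tsl=1,
            exons=[(gstart, gend)],
            cds=[g_iv(u5, u5 + cds_len)],
            utr5=[g_iv(0, u5)],
            utr3=[g_iv(u5 + cds_len, glen)],
        )
        genes.append(
            Gene(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                start=gstart,
                end=gend,
                gene_type="protein_coding",
                name=gene_id,
                transcripts=[tx],
            )
        )

        if stretch_info is not None:
            start_t, slen, sseq = stretch_info
            s_start, s_end = g_iv(start_t, start_t + slen)
            center_t = start_t - config.site_offset
            f_start, f_end = g_iv(center_t - 4, center_t + 5)
            truth.planted_sites.append(PlantedSite(gene_id, chrom, strand, f_start, f_end))
            truth.planted_stretches.append(
                PlantedStretch(
                    gene_id,
                    chrom,
                    strand,
                    s_start,
                    s_end,
                    purity=config.stretch_purity,
                    a_content=sseq.count("A") / slen,
                    lca=_longest_a_run(sseq),
                )
            )

    # trailing intergenic tail on each chromosome
    for chrom in chrom_parts:
        chrom_parts[chrom].append(_random_seq(rng, config.intergenic_gap))
    genome = {chrom: "".join(parts) for chrom, parts in chrom_parts.items()}

    # log-normal abundance, clipped so planted footprints stay detectable at
    # the default depth and background noise cannot mimic reproducible sites
    expr = np.exp(rng.normal(0.0, config.expression_sigma, size=config.n_genes))
    expr = np.clip(expr, config.expression_min, config.expression_max)
    truth.expression = {g.gene_id: float(e) for g, e in zip(genes, expr)}

    return genome, Annotation(genes), truth


def simulate_crosslink_tracks(
    annotation: Annotation, truth: SyntheticTruth, config: SimulationConfig
) -> list[CrosslinkTrack]:
    """Per-replicate negative-binomial crosslink counts over exonic positions.

    Mean per exonic nucleotide is ``background_rate * expression``; inside
    planted footprints the mean is multiplied by ``site_enrichment``.
    Positions outside exons get no counts.
    """
    sites_by_gene: dict[str, list[PlantedSite]] = {}
    for s in truth.planted_sites:
        sites_by_gene.setdefault(s.gene_id, []).append(s)

    tracks = []
    for rep in range(config.n_replicates):
        rng = _rng(config, _STREAM_TRACKS, (rep,))
        track = CrosslinkTrack(replicate=f"rep{rep + 1}")
        for gene in annotation:
            expr = truth.expression.get(gene.gene_id, 1.0)
            for ex_start, ex_end in gene.merged_exons():
                positions = np.arange(ex_start, ex_end)
                mean = np.full(len(positions), config.background_rate * expr)
                # footprint signal is a fold-increase over background; with a
                # zero background rate the fold is anchored to the default
                # reference rate so planted footprints still emit signal
                base = config.background_rate if config.background_rate > 0 else 0.05
                for site in sites_by_gene.get(gene.gene_id, []):
                    inside = (positions >= site.start) & (positions < site.end)
                    mult = site.enrichment if site.enrichment is not None else config.site_enrichment
                    mean[inside] = base * expr * mult
                counts = _nbinom_draw(rng, mean, config.dispersion)
                nz = counts > 0
                d = track.data.setdefault((gene.chrom, gene.strand), {})
                for p, c in zip(positions[nz], counts[nz]):
                    d[int(p)] = d.get(int(p), 0) + int(c)
        tracks.append(track)
    return tracks


def _nbinom_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    out = np.zeros(len(mean), dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = size_param / (size_param + mean[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    quality: str


def simulate_reads(truth: SyntheticTruth, config: SimulationConfig) -> list[SimulatedRead]:
    """FASTQ-writable reads with the 9-nt barcode layout at positions 1-9.

    Positions 1-3 and 8-9 hold a random barcode, 4-7 a fixed experimental
    barcode. A fraction ``polyA_read_fraction`` of reads ends in >= 10
    untemplated terminal A's (run length uniform in [10, 20], preceded by a
    non-A base so the run length is exact).
    """
    rng = _rng(config, _STREAM_READS)
    reads = []
    insert_len = config.read_length - 9
    is_polya = rng.random(config.n_reads) < config.polyA_read_fraction
    qual = chr(33 + 35) * config.read_length
    for i in range(config.n_reads):
        rb = "".join(BASES[rng.integers(0, 4, size=5)])
        barcode = rb[:3] + "TAGC" + rb[3:]
        if is_polya[i]:
            tail = int(rng.integers(10, min(21, insert_len)))
            body = _random_seq(rng, insert_len - tail - 1)
            anchor = str(rng.choice(["C", "G", "T"]))
            insert = body + anchor + "A" * tail
        else:
            insert = list(_random_seq(rng, insert_len))
            # suppress accidental terminal A-runs >= 10 (p ~ 4e-7 anyway)
            if "".join(insert[-10:]) == "A" * 10:
                insert[-1] = "C"
            insert = "".join(insert)
        reads.append(SimulatedRead(f"read{i + 1:06d}", barcode + insert, qual))
    return reads


def write_fastq(reads: list[SimulatedRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_truth_tables(truth: SyntheticTruth, sites_path: str, stretches_path: str) -> None:
    """Truth as BED6+ TSV (documented extra columns)."""
    with open(sites_path, "w") as fh:
        fh.write("# BED6+: chrom start end gene score strand\n")
        for s in truth.planted_sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.gene_id}\t0\t{s.strand}\n")
    with open(stretches_path, "w") as fh:
        fh.write("# BED6+: chrom start end gene lca strand a_content purity\n")
        for st in truth.planted_stretches:
            fh.write(
                f"{st.chrom}\t{st.start}\t{st.end}\t{st.gene_id}\t{st.lca}\t{st.strand}"
                f"\t{st.a_content:.4f}\t{st.purity:.4f}\n"
            )


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
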