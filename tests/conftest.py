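import numpy as np
import pytest

from arichclip.annotation import Annotation, Gene, Transcript
from arichclip.synthetic import (
    SimulationConfig,
    generate_reference,
    simulate_crosslink_tracks,
)
from arichclip.tracks import CrosslinkTrack


def make_gene(
    gene_id="G1",
    chrom="chr1",
    strand="+",
    start=0,
    end=1000,
    exons=None,
    cds=None,
    utr5=None,
    utr3=None,
    gene_type="protein_coding",
    level=1,
    tsl=1,
):
    exons = exons if exons is not None else [(start, end)]
    tx = Transcript(
        transcript_id=f"{gene_id}.t1",
        start=start,
        end=end,
        level=level,
        tsl=tsl,
        exons=exons,
        cds=cds or [],
        utr5=utr5 or [],
        utr3=utr3 or [],
    )
    return Gene(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        gene_type=gene_type,
        transcripts=[tx],
    )


def make_track(counts, chrom="chr1", strand="+", replicate="rep1"):
    """Track from a {position: count} dict on one chrom/strand."""
    t = CrosslinkTrack(replicate=replicate)
    for p, c in counts.items():
        t.add(chrom, strand, p, c)
    return t


@pytest.fixture(scope="session")
def sim_bundle():
    """Small default simulation shared by read-only tests."""
    cfg = SimulationConfig(n_genes=30, seed=11)
    genome, annotation, truth = generate_reference(cfg)
    tracks = simulate_crosslink_tracks(annotation, truth, cfg)
    contig_lengths = {c: len(genome[c]) for c in genome}
    return {
        "config": cfg,
        "genome": genome,
        "annotation": annotation,
        "truth": truth,
        "tracks": tracks,
        "contig_lengths": contig_lengths,
    }
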