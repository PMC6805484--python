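"""Stage orchestration: simulate -> (preprocess) -> callsites -> sob ->
seqcontext -> polya/metaprofiles, with a run manifest and input validation."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .annotation import Annotation, SupportFilter, load_gtf, write_gtf
from .config import PipelineConfig
from .errors import AnnotationError, InputError, StageError
from .genome import GenomeStore, write_fasta
from .polya_meta import (
    polyA_site_metaprofile,
    read_a_stats,
    stretch_start_metaprofile,
    write_curves_tsv,
    write_metaprofile_tsv,
)
from .seqcontext import (
    StretchSearchParams,
    find_arich_stretch,
    kmer_positional_profile,
    kmer_zscores,
    merge_neighboring_stretches,
    stratify_sob_by_lca,
    write_stretches_bed,
)
from .sitecalling import NBParams, call_binding_sites, write_sites_bed
from .sob import compute_sob, write_sob_tsv
from .synthetic import (
    generate_reference,
    simulate_crosslink_tracks,
    simulate_reads,
    write_fastq,
    write_truth_tables,
)
from .tracks import bedgraph_contigs, read_bedgraph_pair, write_bedgraph_pair

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    genome_path: Optional[str] = None,
    annotation_path: Optional[str] = None,
    bedgraph_paths: Optional[list[str]] = None,
    fastq_path: Optional[str] = None,
) -> ValidationReport:
    """Syntactic and cross-file consistency checks, fatal vs warning."""
    report = ValidationReport()
    contigs: set[str] = set()
    if genome_path:
        if not os.path.exists(genome_path):
            report.errors.append(f"genome FASTA not found: {genome_path}")
        else:
            try:
                contigs = set(GenomeStore(genome_path).contigs)
                if not contigs:
                    report.errors.append(f"genome FASTA has no sequences: {genome_path}")
            except Exception as exc:
                report.errors.append(f"cannot read FASTA {genome_path}: {exc}")
    if annotation_path:
        if not os.path.exists(annotation_path):
            report.errors.append(f"annotation GTF not found: {annotation_path}")
        else:
            try:
                ann = load_gtf(annotation_path)
                ann_contigs = {g.chrom for g in ann}
                if contigs and not ann_contigs <= contigs:
                    report.errors.append(
                        f"GTF contigs absent from FASTA: {sorted(ann_contigs - contigs)}"
                    )
            except AnnotationError as exc:
                report.errors.append(
                    f"{exc} (the single-protein-coding-gene assignment rule requires gene_type)"
                )
            except Exception as exc:
                report.errors.append(f"cannot parse GTF {annotation_path}: {exc}")
    for path in bedgraph_paths or []:
        if not os.path.exists(path):
            report.errors.append(f"bedGraph not found: {path}")
            continue
        try:
            bg_contigs = bedgraph_contigs([path])
        except Exception as exc:
            report.errors.append(f"cannot parse bedGraph {path}: {exc}")
            continue
        if contigs and not bg_contigs <= contigs:
            report.errors.append(
                f"bedGraph {path} contigs absent from FASTA: {sorted(bg_contigs - contigs)}"
            )
    if fastq_path:
        if not os.path.exists(fastq_path):
            report.errors.append(f"FASTQ not found: {fastq_path}")
        else:
            try:
                from Bio import SeqIO

                n = 0
                for _ in SeqIO.parse(fastq_path, "fastq"):
                    n += 1
                    if n >= 100:
                        break
                if n == 0:
                    report.warnings.append(f"FASTQ {fastq_path} holds no records")
            except Exception as exc:
                report.errors.append(f"cannot parse FASTQ {fastq_path}: {exc}")
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    # --- inputs: simulate or load -------------------------------------------------
    if config.simulate:
        sim = config.simulation
        genome_dict, annotation, truth = generate_reference(sim)
        tracks = simulate_crosslink_tracks(annotation, truth, sim)
        reads = simulate_reads(truth, sim)
        genome_path = os.path.join(outdir, "genome.fa")
        gtf_path = os.path.join(outdir, "annotation.gtf")
        fastq_path = os.path.join(outdir, "reads.fastq")
        write_fasta(genome_dict, genome_path)
        write_gtf(annotation, gtf_path)
        write_fastq(reads, fastq_path)
        write_truth_tables(
            truth,
            os.path.join(outdir, "truth_sites.tsv"),
            os.path.join(outdir, "truth_stretches.tsv"),
        )
        for t in tracks:
            write_bedgraph_pair(t, os.path.join(outdir, f"crosslinks.{t.replicate}"))
        genome = GenomeStore(genome_dict)
        read_seqs = [r.sequence[9:] for r in reads]  # barcode removed
        manifest["stages"]["simulate"] = {
            "n_genes": len(annotation),
            "planted_sites": len(truth.planted_sites),
            "planted_stretches": len(truth.planted_stretches),
            "n_reads": len(reads),
        }
    else:
        if not config.genome or not config.annotation or not config.tracks:
            raise InputError("genome, annotation and tracks are required unless simulating")
        report = validate_inputs(
            config.genome,
            config.annotation,
            [p for t in config.tracks for p in (t["plus"], t["minus"])],
            config.reads,
        )
        if not report.ok:
            raise InputError("; ".join(report.errors))
        genome = GenomeStore(config.genome)
        annotation = load_gtf(config.annotation)
        tracks = [
            read_bedgraph_pair(t["plus"], t["minus"], t.get("replicate", f"rep{i + 1}"))
            for i, t in enumerate(config.tracks)
        ]
        read_seqs = None
        if config.reads:
            from Bio import SeqIO

            read_seqs = [str(r.seq)[9:] for r in SeqIO.parse(config.reads, "fastq")]

    contig_lengths = {c: genome.length(c) for c in genome.contigs}
    sc = config.sitecalling
    support = SupportFilter(sc.support_max_level, sc.support_max_tsl, sc.support_direction)

    # --- sitecalling --------------------------------------------------------------
    try:
        sites, funnel = call_binding_sites(
            tracks,
            annotation,
            contig_lengths,
            NBParams(window=sc.nb_window, alpha=sc.alpha),
            support,
            min_covered=sc.min_covered,
            min_events=sc.min_events,
            merge_direction=sc.merge_direction,
            exclude_introns=sc.exclude_introns,
        )
    except Exception as exc:
        raise StageError("callsites", str(exc)) from exc
    manifest["stages"]["callsites"] = funnel
    with open(os.path.join(outdir, "exclusions.tsv"), "w") as fh:
        fh.write("reason\tcount\n")
        for k, v in sorted(funnel.get("excluded_gene_assignment", {}).items()):
            fh.write(f"{k}\t{v}\n")
        fh.write(f"intron\t{funnel['excluded_intron']}\n")
        fh.write(f"reproducibility\t{funnel['dropped_reproducibility']}\n")
        fh.write(f"sparse\t{funnel['dropped_sparse']}\n")

    # --- sob ----------------------------------------------------------------------
    try:
        sob = compute_sob(
            sites, tracks, annotation, support,
            min_background=config.sob.min_background,
            buffer=config.sob.buffer,
            strict=config.sob.strict,
        )
    except Exception as exc:
        raise StageError("sob", str(exc)) from exc
    write_sob_tsv(sob, sites, os.path.join(outdir, "sob.tsv"))
    write_sites_bed(sites, os.path.join(outdir, "sites.bed"), sob)
    n_defined = sum(1 for v in sob.values() if v.defined)
    manifest["stages"]["sob"] = {
        "sites": len(sites),
        "defined": n_defined,
        "undefined": len(sites) - n_defined,
    }

    # --- seqcontext ---------------------------------------------------------------
    st = config.stretch
    params = StretchSearchParams(
        search_space=st.search_space, min_window=st.min_window, max_window=st.max_window,
        min_a_content=st.min_a_content, min_weighted_a=st.min_weighted_a,
        min_lca=st.min_lca, exclusion_mode=st.exclusion_mode,
    )
    try:
        utr3_sites = [s for s in sites if s.region == "3UTR"]
        per_site = [find_arich_stretch(s, genome, params) for s in utr3_sites]
        stretches = merge_neighboring_stretches([x for x in per_site if x is not None])
        write_stretches_bed(stretches, os.path.join(outdir, "stretches.bed"))
        strat = stratify_sob_by_lca(sites, sob, stretches)
        strat.to_csv(os.path.join(outdir, "sob_by_lca.tsv"), sep="\t", index=False)
        if sites:
            profile = kmer_positional_profile(
                sites, genome, list(config.kmer.profile_kmers), config.kmer.profile_halfwindow
            )
            profile.to_csv(os.path.join(outdir, "kmer_profile.tsv"), sep="\t")
            zs = kmer_zscores(
                sites, genome, annotation,
                flank=config.kmer.flank, bg_windows=config.kmer.bg_windows,
                bg_repeats=config.kmer.bg_repeats, seed=config.seed,
                support_filter=support,
            )
            zs.to_csv(os.path.join(outdir, "kmer_zscores.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise StageError("seqcontext", str(exc)) from exc
    manifest["stages"]["seqcontext"] = {
        "utr3_sites": len(utr3_sites),
        "sites_with_stretch": sum(1 for x in per_site if x is not None),
        "merged_stretches": len(stretches),
    }

    # --- polya / metaprofiles -----------------------------------------------------
    from .tracks import merge_tracks

    merged = merge_tracks(tracks)
    mp = config.metaprofile
    stage: dict = {}
    try:
        if read_seqs:
            stats = read_a_stats(read_seqs)
            write_curves_tsv(stats, os.path.join(outdir, "polya_read_curves.tsv"))
            k10 = (
                float(stats.terminal_percentage[10]) if len(stats.terminal_percentage) > 10 else 0.0
            )
            stage["reads"] = stats.n_reads
            stage["pct_ge10_terminal_a"] = k10
        try:
            meta = polyA_site_metaprofile(
                merged, annotation,
                radius=mp.polya_radius, min_events=mp.min_events, min_utr3=mp.min_utr3,
                smooth=mp.smooth, support_filter=support,
                enrichment_near=mp.enrichment_near, enrichment_body=mp.enrichment_body,
            )
            write_metaprofile_tsv(meta, os.path.join(outdir, "polya_metaprofile.tsv"))
            stage["polya_regions"] = meta.n_regions
            stage["enrichment_factor"] = meta.enrichment_factor
        except InputError as exc:
            logger.warning("polyA metaprofile skipped: %s", exc)
            stage["polya_regions"] = 0
        if stretches:
            smeta, matrix = stretch_start_metaprofile(
                merged, stretches, radius=mp.stretch_radius, matrix_radius=mp.matrix_radius
            )
            write_metaprofile_tsv(smeta, os.path.join(outdir, "stretch_metaprofile.tsv"))
            matrix.to_csv(os.path.join(outdir, "stretch_heatmap.tsv"), sep="\t")
            stage["stretch_regions"] = smeta.n_regions
    except StageError:
        raise
    except Exception as exc:
        raise StageError("polya_meta", str(exc)) from exc
    manifest["stages"]["polya_meta"] = stage

    from .config import save_config

    save_config(config, os.path.join(outdir, "run_config.yaml"))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
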