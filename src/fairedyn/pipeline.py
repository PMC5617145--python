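"""End-to-end orchestration: simulate -> call peaks -> classify ->
profiles/correlation -> differential motifs -> LD report.

One global seed deterministically derives every stage's substream, so a
rerun with the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as gio
from .dynamics import classify_peaks, annotate_peaks, fig3_rules, fig5_rules
from .ld import format_ld_report, ld_expand, snps_in_peaks
from .motifs import build_background, extract_peak_sequences, motif_enrichment, \
    pairwise_motif_table
from .peakcall import PeakCallParams, call_peaks, coverage_track, filter_to_assembly, \
    merge_fragment_sets
from .profiles import correlation_matrix, tss_profile
from .simulate import (
    CONDITIONS,
    DECOY_CONDITIONS,
    SimulationConfig,
    ap1_like_motif,
    make_gene_models,
    make_motif_library,
    plant_motif_instances,
    plant_truth_peaks,
    simulate_fragments,
    simulate_genome,
    simulate_haplotypes,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "fairedyn_run"
    replicates: int = 2
    # peak calling (FAIRE fixed-width defaults)
    peak_size: int = 200
    tbp: int = 1
    fdr: float = 0.05
    # summaries
    bin_size: int = 10_000
    flank: int = 2500
    profile_bin: int = 50
    # classification
    f_present: float = 0.25
    f_absent: float = 0.10
    # regulatory domains
    basal_up: int = 5000
    basal_down: int = 1000
    max_ext: int = 1_000_000
    # motifs
    threshold_frac: float = 0.8
    n_decoy_motifs: int = 50
    # LD
    r2_min: float = 0.8
    # simulation overrides (keys of SimulationConfig other than seed)
    simulation: dict = field(default_factory=dict)
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate", "callpeaks", "classify", "profiles", "motifdiff", "ld",
    )

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if not 0 < self.f_present <= 1 or not 0 < self.f_absent <= 1:
            raise ValueError("overlap fractions must be in (0, 1]")
        if not 0 < self.threshold_frac <= 1:
            raise ValueError("threshold_frac must be in (0, 1]")
        if not 0 < self.r2_min <= 1:
            raise ValueError("r2_min must be in (0, 1]")
        known = {f.name for f in dataclasses.fields(SimulationConfig)} - {"seed"}
        unknown = set(self.simulation) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages in dependency order.

    Returns the run directory, which contains per-stage outputs plus
    ``manifest.json`` (seed, resolved parameters, stage counts, input
    checksums) and ``config.yaml`` (the resolved configuration).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = dataclasses.asdict(config)
    resolved["stages"] = list(config.stages)
    (outdir / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    manifest: dict = {"seed": config.seed, "stages": {}, "checksums": {}}
    sim = config.sim_config()

    # ---- simulate -------------------------------------------------------
    genome = simulate_genome(sim)
    truth = plant_truth_peaks(genome, sim)
    planted_motif = ap1_like_motif()
    genome, plant_log = plant_motif_instances(genome, truth, planted_motif, sim)
    panel, disease_catalog, _pairs = simulate_haplotypes(sim, truth)
    genes_open, genes_closed = make_gene_models(genome, truth, sim)
    if "simulate" in config.stages:
        simdir = outdir / "simulate"
        simdir.mkdir(exist_ok=True)
        gio.write_fasta(genome, simdir / "genome.fa")
        gio.write_chrom_sizes(genome.chrom_sizes, simdir / "genome.chrom.sizes")
        gio.write_bed(
            [dataclasses.replace(t.interval, name=t.class_label) for t in truth],
            simdir / "truth_peaks.bed",
        )
        gio.write_vcf_haplotypes(panel, simdir / "panel.vcf")
        gio.write_snp_catalog(disease_catalog, simdir / "disease_snps.tsv")
        library = [planted_motif] + make_motif_library(config.n_decoy_motifs,
                                                       seed=config.seed + 1)
        gio.write_pfm_library(library, simdir / "motifs.pfm")
        manifest["stages"]["simulate"] = {
            "truth_peaks": len(truth),
            "motif_instances_planted": len(plant_log),
            "panel_snps": len(panel.snps),
            "disease_snps": len(disease_catalog),
        }

    # ---- fragments + peak calling --------------------------------------
    peak_params = PeakCallParams(peak_size=config.peak_size, tbp_cap=config.tbp,
                                 fdr=config.fdr)
    all_samples = CONDITIONS + DECOY_CONDITIONS
    replicate_sets: dict[str, list] = {}
    merged_sets = {}
    peak_sets = {}
    for sample in all_samples:
        reps = [simulate_fragments(genome, truth, sample, sim, replicate=r)
                for r in range(config.replicates)]
        replicate_sets[sample] = reps
        merged = merge_fragment_sets(reps)
        if merged.source_tags is not None:
            merged = filter_to_assembly(merged, "human")
        merged_sets[sample] = merged
        peak_sets[sample] = call_peaks(merged, genome.chrom_sizes, peak_params,
                                       assembly=genome)
    if "callpeaks" in config.stages:
        peakdir = outdir / "peaks"
        peakdir.mkdir(exist_ok=True)
        for sample, ps in peak_sets.items():
            gio.write_bed(ps.peaks, peakdir / f"{sample}.peaks.bed")
        manifest["stages"]["callpeaks"] = {
            s: {"fragments": len(merged_sets[s]), "peaks": len(peak_sets[s])}
            for s in all_samples
        }

    # ---- classification -------------------------------------------------
    condition_sets = {c: peak_sets[c] for c in CONDITIONS}
    decoy_sets = [peak_sets[d] for d in DECOY_CONDITIONS]
    fig3 = classify_peaks(condition_sets, decoy_sets, fig3_rules())
    fig5 = classify_peaks(condition_sets, decoy_sets, fig5_rules())
    if "classify" in config.stages:
        classdir = outdir / "classes"
        classdir.mkdir(exist_ok=True)
        for result, tag in ((fig3, "dynamics"), (fig5, "tad")):
            for class_name in result.counts:
                peaks = result.by_class(class_name)
                if peaks:
                    gio.write_bed(sorted(peaks, key=lambda p: (p.chrom, p.start)),
                                  classdir / f"{tag}.{class_name}.bed")
        annotate_peaks(
            [cp.peak for cp in fig3.peaks], genes_open + genes_closed
        ).to_csv(classdir / "dynamics.nearest_gene.tsv", sep="\t", index=False)
        manifest["stages"]["classify"] = {
            "dynamics_counts": fig3.counts, "tad_counts": fig5.counts,
        }

    # ---- correlation + TSS profiles -------------------------------------
    if "profiles" in config.stages:
        profdir = outdir / "profiles"
        profdir.mkdir(exist_ok=True)
        tracks = []
        for sample in all_samples:
            for r, rep in enumerate(replicate_sets[sample]):
                track = coverage_track(rep, genome.chrom_sizes, normalize=True)
                track.sample = f"{sample}_rep{r + 1}"
                tracks.append(track)
        corr = correlation_matrix(tracks, genome.chrom_sizes, bin_size=config.bin_size)
        corr.to_csv(profdir / "correlation.tsv", sep="\t")
        merged_track = coverage_track(merged_sets["ESS"], genome.chrom_sizes, normalize=True)
        for label, gene_list in (("accessible", genes_open), ("inaccessible", genes_closed)):
            prof = tss_profile(merged_track, gene_list, flank=config.flank,
                               bin_size=config.profile_bin, label=label)
            with open(profdir / f"tss_profile.{label}.tsv", "w") as handle:
                handle.write("offset\tmean_signal\n")
                for off, v in zip(prof.offsets, prof.values):
                    handle.write(f"{off:g}\t{v:.6g}\n")
        manifest["stages"]["profiles"] = {"tracks": len(tracks)}

    # ---- differential motifs --------------------------------------------
    if "motifdiff" in config.stages:
        motifdir = outdir / "motifs"
        motifdir.mkdir(exist_ok=True)
        library = [planted_motif] + make_motif_library(config.n_decoy_motifs,
                                                       seed=config.seed + 1)
        fg_a = fig3.by_class("BarrierDeficient")
        fg_b = peak_sets["Graft"].peaks
        bg = build_background(fg_a, fg_b, genome, seed=config.seed + 2)
        enr_a = motif_enrichment(extract_peak_sequences(fg_a, genome), bg, library,
                                 threshold_frac=config.threshold_frac)
        enr_b = motif_enrichment(extract_peak_sequences(fg_b, genome), bg, library,
                                 threshold_frac=config.threshold_frac)
        table = pairwise_motif_table(enr_a, enr_b)
        table.to_csv(motifdir / "barrierdeficient_vs_graft.tsv", sep="\t", index=False)
        manifest["stages"]["motifdiff"] = {
            "motifs_tested": len(library),
            "top_delta_motif": table.iloc[0]["motif"],
        }

    # ---- LD --------------------------------------------------------------
    if "ld" in config.stages:
        lddir = outdir / "ld"
        lddir.mkdir(exist_ok=True)
        dynamic = [
            (cp.peak, cp.class_name)
            for cp in fig3.peaks
            if cp.class_name not in ("Unclassified",)
        ]
        in_peak = snps_in_peaks(panel.snps, dynamic)
        report = ld_expand(in_peak, disease_catalog, panel, r2_min=config.r2_min)
        format_ld_report(report).to_csv(lddir / "snp_peak_associations.tsv",
                                        sep="\t", index=False)
        manifest["stages"]["ld"] = {
            "snps_in_dynamic_peaks": len(in_peak),
            "association_rows": len(report),
        }

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["checksums"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
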