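"""End-to-end orchestration: simulate → filter → signatures → rates →
covariates → clonality, under one config and one seed.

Each stage writes its outputs under the run directory with fixed relative
names; with reuse_existing=True a stage whose outputs already exist is
loaded instead of recomputed, so deleting downstream outputs and re-running
reproduces them from cached upstream files. The report contains only
numbers reproducible from config + seed (no timestamps), so identical runs
produce byte-identical reports.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, covariates, filtering, io, rates, signatures
from . import synthetic as syn

log = logging.getLogger("somamosaic")


@dataclass
class RunConfig:
    """Configuration for a full synthetic run."""

    outdir: str = "somamosaic_run"
    seed: int = 0
    # simulation
    genome_length: int = 300_000
    gc_fraction: float = 0.41
    n_mutations: int = 3000
    process_weights: dict = field(default_factory=lambda: dict(
        syn.ProcessMix.default().weights))
    tcr_factor: float = 0.5
    depth_mean: float = 50.0
    fp_rate: float = 0.05
    fn_rate: float = 0.05
    n_genes: int = 8
    gene_length_range: tuple = (5_000, 20_000)
    gradient_strength: float = 1.0
    window_size: int = 20_000
    germline_density: float = 0.001
    # filtering
    min_depth: int = 10
    min_alt: int = 3
    het_window: tuple = filtering.HET_WINDOW
    hom_threshold: float = filtering.HOM_THRESHOLD
    # signatures / tests
    alpha: float = 0.05
    bins: int = 5
    bin_mode: str = "population"
    # sample metadata
    donor: str = "D1"
    site: str = "forearm"
    clone_id: str = "D1-L-F1"
    age: float = 62.0
    measured_telomere: float = 1_000.0
    attrition: float = 100.0
    reuse_existing: bool = False


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty iff the config is valid)."""
    v = []
    if config.genome_length < 10_000:
        v.append("genome_length: must be >= 10000")
    if not 0 < config.gc_fraction < 1:
        v.append("gc_fraction: must be in (0, 1)")
    if config.n_mutations < 0:
        v.append("n_mutations: must be >= 0")
    w = config.process_weights
    if any(x < 0 for x in w.values()) or abs(sum(w.values()) - 1) > 1e-9:
        v.append("process_weights: must be non-negative and sum to 1")
    if not 0 < config.tcr_factor <= 1:
        v.append("tcr_factor: must be in (0, 1]")
    if config.depth_mean < 10:
        v.append("depth_mean: must be >= 10")
    if config.min_depth < 1:
        v.append("min_depth: must be >= 1")
    if config.min_alt < 0:
        v.append("min_alt: must be >= 0")
    lo, hi = config.het_window
    if not 0 <= lo < hi <= 1:
        v.append("het_window: must satisfy 0 <= low < high <= 1")
    if not 0 < config.hom_threshold < 1:
        v.append("hom_threshold: must be in (0, 1)")
    if not 0 < config.alpha < 1:
        v.append("alpha: must be in (0, 1)")
    if config.bins < 2:
        v.append("bins: must be >= 2")
    if config.bin_mode not in ("population", "width"):
        v.append("bin_mode: must be 'population' or 'width'")
    if config.age <= 0:
        v.append("age: must be positive")
    if config.attrition <= 0:
        v.append("attrition: must be positive")
    if config.window_size <= 0:
        v.append("window_size: must be positive")
    return v


@dataclass
class RunReport:
    """Aggregated outputs of one pipeline run."""

    version: str
    config: dict
    stage_counts: dict
    catalog_size: int
    het_count: int
    hom_count: int
    enrichment: list
    uv_min_load_total: float
    cc_tt_pairs: int
    rate_table: list
    density_bins: dict
    strand_tests: list
    clonality: list

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True,
                          default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage in dependency order; deterministic for a fixed
    config + seed. Any stage failure is re-raised naming the stage."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(config.seed).spawn(8)]

    stage = "simulate"
    try:
        genome_path = out / "genome.fa"
        truth_path = out / "truth.vcf"
        if config.reuse_existing and genome_path.exists() and truth_path.exists():
            genome = io.read_fasta(genome_path)
            truth = io.read_vcf(truth_path)
            genes = io.read_bed(out / "genes.bed")
            tracks = pd.read_csv(out / "covariates.tsv", sep="\t")
            tracks.attrs["window_size"] = config.window_size
            tables = {c: io.read_vcf(out / f"caller_{c}.vcf")
                      for c in ("A", "B", "C")}
            blood = io.read_vcf(out / "blood.vcf")
        else:
            genome = syn.generate_reference(
                config.genome_length, config.gc_fraction, seeds[0])
            genes = syn.emit_genes(genome, config.n_genes, seeds[1],
                                   tuple(config.gene_length_range))
            tracks = syn.emit_covariate_tracks(
                genome, config.gradient_strength, seeds[2],
                config.window_size)
            mix = syn.ProcessMix(config.process_weights, config.n_mutations,
                                 config.tcr_factor)
            truth = syn.plant_somatic_mutations(
                genome, mix, genes, seeds[3], density=tracks)
            germline = syn.plant_germline(genome, config.germline_density,
                                          seeds[4])
            tables, blood = syn.emit_caller_tables(
                truth, germline, genome, config.depth_mean,
                config.fp_rate, config.fn_rate, seeds[5])
            io.write_fasta(genome, genome_path)
            io.write_vcf(truth, truth_path, genome.lengths)
            io.write_bed(genes, out / "genes.bed")
            tracks.to_csv(out / "covariates.tsv", sep="\t", index=False)
            io.write_bedgraph(tracks, out / "rep_timing.bedGraph",
                              "rep_timing")
            io.write_bedgraph(tracks, out / "dnase_peaks.bedGraph",
                              "dnase_peaks")
            for c, tab in tables.items():
                io.write_vcf(tab, out / f"caller_{c}.vcf", genome.lengths)
            io.write_vcf(blood, out / "blood.vcf", genome.lengths)
        log.info("simulate: %d truth records, %d blood records",
                 len(truth), len(blood))

        stage = "filter"
        catalog, stage_counts = filtering.consensus_catalog(
            tables, blood, min_depth=config.min_depth,
            min_alt=config.min_alt, het_window=tuple(config.het_window),
            hom_threshold=config.hom_threshold, donor=config.donor,
            site=config.site, clone_id=config.clone_id, age=config.age)
        io.write_vcf(catalog.calls, out / "catalog.vcf", genome.lengths)
        log.info("filter: %s", stage_counts)

        stage = "signatures"
        table = signatures.enrichment_table(
            genome, {config.clone_id: catalog.calls}, alpha=config.alpha)
        table.to_csv(out / "signatures.tsv", sep="\t", index=False)
        cc_pairs = signatures.count_cc_tt(catalog.calls)
        by_motif = table.set_index("motif")
        uv_total = signatures.uv_min_load_total(
            by_motif.loc["yCn", "min_load"], by_motif.loc["nTt", "min_load"],
            cc_pairs)
        uv_total = min(uv_total, float(len(catalog.calls)))
        log.info("signatures: UV min load %.1f, %d CC->TT pairs",
                 uv_total, cc_pairs)

        stage = "rates"
        model = rates.TelomereModel(
            attrition_per_division=config.attrition)
        divisions = rates.estimate_divisions(config.measured_telomere, model)
        est = rates.RateEstimate(
            sample=config.clone_id, donor=config.donor, site=config.site,
            load=len(catalog.calls), age=config.age,
            uv_min_load=uv_total, divisions=divisions)
        rate_rows = rates.rates_frame([est])
        rate_rows["divisions"] = divisions
        rate_rows["rate_per_nt_per_division"] = est.rate_per_nt_per_division
        rate_rows.to_csv(out / "rates.tsv", sep="\t", index=False)

        stage = "covariates"
        windows = tracks[["contig", "start", "end"]]
        dens = covariates.mutation_density(catalog.calls, windows)
        bins = covariates.quantile_bins(
            tracks["rep_timing"].to_numpy(), config.bins, config.bin_mode)
        means, slope = covariates.density_by_bin(dens, bins, config.bins)
        pd.DataFrame({"bin": np.arange(1, config.bins + 1),
                      "mean_density": means}).to_csv(
            out / "density_bins.tsv", sep="\t", index=False)
        uv_counts = covariates.uv_strand_counts(
            genome, catalog.calls, genes, config.clone_id)
        ctl_counts = covariates.non_uv_control(
            genome, catalog.calls, genes, config.clone_id)
        strand = covariates.strand_bias_table([uv_counts, ctl_counts])
        strand_rows = [{
            "sample": c.sample, "class": c.signature_class,
            "non_transcribed": c.non_transcribed,
            "transcribed": c.transcribed, "p": c.p, "q": c.q,
        } for c in strand]
        pd.DataFrame(strand_rows).to_csv(out / "strand_tests.tsv",
                                         sep="\t", index=False)

        stage = "clonality"
        # demonstration calls exercising the clonality rules
        from .clonality import InsertionCall, SVCall, clonality_table
        sv_demo = [
            SVCall("deletion", genome.names[0], 1000, 5000, 40, 100, 0),
            SVCall("inversion", genome.names[0], 9000, 12000, 20, 100, 0),
        ]
        ins_demo = [InsertionCall("L1", genome.names[0], 15000, 5, 45,
                                  config.depth_mean, config.depth_mean)]
        clon = clonality_table(sv_demo, ins_demo)
        clon.to_csv(out / "clonality.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        version=__version__,
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()},
        stage_counts=stage_counts,
        catalog_size=len(catalog.calls),
        het_count=int((catalog.calls["zygosity"] == "het").sum()),
        hom_count=int((catalog.calls["zygosity"] == "hom").sum()),
        enrichment=table.round(6).to_dict("records"),
        uv_min_load_total=float(uv_total),
        cc_tt_pairs=int(cc_pairs),
        rate_table=rate_rows.round(12).to_dict("records"),
        density_bins={"mean_density": means.tolist(),
                      "slope": float(slope)},
        strand_tests=strand_rows,
        clonality=clon.round(6).to_dict("records"),
    )
    (out / "report.json").write_text(report.to_json())
    return report
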