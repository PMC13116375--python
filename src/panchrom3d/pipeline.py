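"""Pipeline configuration, input validation and orchestration.

A single YAML/JSON config drives an end-to-end run on synthetic data:
simulate -> chromatin -> pan-classify -> sv -> select/enrich -> capture-diff.
Runs are deterministic under a fixed seed; a JSON manifest records the seed,
a parameter hash and every emitted file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import capture as capture_mod
from . import chromatin, io, pan, popgen, sv as sv_mod, synth
from .core import GenomeCoordinates, Interval

STAGES = ("simulate", "chromatin", "pan_classify", "sv", "select_enrich",
          "capture_diff")
#: every stage consumes the synthetic dataset produced by ``simulate``
STAGE_DEPS = {s: ("simulate",) for s in STAGES if s != "simulate"}

_KNOWN_KEYS = {"seed", "outdir", "stages", "simulate", "chromatin",
               "select_enrich", "capture_diff", "log_level", "inputs"}


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    params: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config requires an explicit seed")
        stages = list(raw.get("stages", STAGES))
        for s in stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
            for dep in STAGE_DEPS.get(s, ()):
                if dep not in stages:
                    raise ValueError(f"stage {s!r} requires {dep!r}")
        return cls(seed=int(raw["seed"]),
                   outdir=str(raw.get("outdir", "panchrom3d_out")),
                   stages=stages,
                   params={k: raw[k] for k in
                           ("simulate", "chromatin", "select_enrich",
                            "capture_diff") if k in raw})


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def sniff_format(path) -> str:
    """Best-effort format detection from the first data line."""
    text = Path(path).read_text().splitlines()
    for line in text:
        if line.startswith("##fileformat=VCF"):
            return "vcf"
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 9 and parts[2] == "gene":
            return "gff"
        if len(parts) >= 6:
            try:
                int(parts[1]), int(parts[2]), int(parts[4]), int(parts[5])
                return "bedpe"
            except ValueError:
                pass
        if len(parts) >= 3:
            try:
                int(parts[1]), int(parts[2])
                return "bed"
            except ValueError:
                pass
        return "unknown"
    return "empty"


def validate_inputs(paths, chrom_sizes: Mapping[str, int] | None = None) -> list[str]:
    """Fail-fast validation of declared input files.

    Returns a list of per-file diagnostics (empty when everything is valid):
    missing files, malformed records (with line numbers from the readers),
    and intervals beyond the declared chromosome sizes.
    """
    report: list[str] = []
    genome = GenomeCoordinates(chrom_sizes) if chrom_sizes else None
    for path in paths:
        p = Path(path)
        if not p.exists():
            report.append(f"{path}: file not found")
            continue
        fmt = sniff_format(p)
        try:
            if fmt == "bed":
                ivs = io.read_bed(p)
            elif fmt == "bedpe":
                pairs = io.read_bedpe(p)
                ivs = [a for pr in pairs for a in (pr.anchor1, pr.anchor2)]
            elif fmt == "gff":
                ivs = io.read_gff_genes(p)
            elif fmt == "vcf":
                ivs = [r.as_interval() for r in io.read_sv_vcf(p)[0]]
            else:
                report.append(f"{path}: unrecognized format")
                continue
        except ValueError as err:
            report.append(str(err))
            continue
        if genome is not None:
            for iv in ivs:
                if iv.chrom not in genome:
                    report.append(f"{path}: unknown chromosome {iv.chrom}")
                    break
                if iv.end > genome[iv.chrom]:
                    report.append(
                        f"{path}: interval {iv.chrom}:{iv.start}-{iv.end} "
                        f"beyond chromosome end {genome[iv.chrom]}")
                    break
    return report


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the declared stages in dependency order.

    Returns the provenance manifest (also written to ``manifest.json``).
    Identical config + seed yields byte-identical non-log outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    param_hash = hashlib.sha256(
        json.dumps({"seed": config.seed, "stages": config.stages,
                    "params": config.params}, sort_keys=True,
                   default=str).encode()).hexdigest()
    manifest = {"version": __version__, "seed": config.seed,
                "param_hash": param_hash, "stages": [], "outputs": []}

    def emit(name):
        manifest["outputs"].append(str(name.relative_to(outdir)))

    dataset = None
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            if stage == "simulate":
                sim_params = dict(config.params.get("simulate", {}))
                if "chrom_sizes" in sim_params:
                    sim_params["chrom_sizes"] = {
                        str(k): int(v)
                        for k, v in sim_params["chrom_sizes"].items()}
                if "class_probs" in sim_params:
                    sim_params["class_probs"] = {
                        str(k): float(v)
                        for k, v in sim_params["class_probs"].items()}
                cfg = synth.SimConfig(seed=config.seed, **sim_params)
                dataset = synth.simulate_pan_dataset(cfg)
                _write_dataset(dataset, outdir, emit)
            elif stage == "chromatin":
                _stage_chromatin(config, dataset, outdir, emit)
            elif stage == "pan_classify":
                _stage_pan(dataset, outdir, emit)
            elif stage == "sv":
                _stage_sv(dataset, outdir, emit)
            elif stage == "select_enrich":
                _stage_select(config, dataset, outdir, emit)
            elif stage == "capture_diff":
                _stage_capture(config, outdir, emit)
            manifest["stages"].append(stage)
    except Exception as err:
        manifest["error"] = f"stage failed: {err}"
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write_dataset(ds: synth.SimDataset, outdir: Path, emit) -> None:
    for gid in ds.genome_ids:
        io.write_bed(ds.boundaries[gid], outdir / f"{gid}.boundaries.bed")
        emit(outdir / f"{gid}.boundaries.bed")
        io.write_bed(ds.ltcres[gid], outdir / f"{gid}.ltcres.bed")
        emit(outdir / f"{gid}.ltcres.bed")
        io.write_bedpe(ds.loops[gid], outdir / f"{gid}.loops.bedpe")
        emit(outdir / f"{gid}.loops.bedpe")
        io.write_liftover_map(ds.maps[gid], outdir / f"{gid}.liftover.tsv")
        emit(outdir / f"{gid}.liftover.tsv")
    io.write_sv_vcf(ds.svs, outdir / "svs.vcf")
    emit(outdir / "svs.vcf")
    fam = pd.DataFrame(ds.families.presence.astype(int),
                       index=ds.families.cluster_ids,
                       columns=ds.families.genome_ids)
    fam.to_csv(outdir / "gene_families.tsv", sep="\t")
    emit(outdir / "gene_families.tsv")


def _stage_chromatin(config, ds, outdir: Path, emit) -> None:
    p = dict(config.params.get("chromatin", {}))
    bin_size = int(p.get("bin_size", 40_000))
    w = int(p.get("window", 2))
    n_tads = int(p.get("n_tads", 20))
    tads = synth.plant_tads("chr1", n_tads, bin_size, seed=config.seed)
    cm = synth.simulate_contact_matrix(
        tads, bin_size, within=float(p.get("within", 5.0)),
        between=float(p.get("between", 1.0)), seed=config.seed)
    io.write_contact_matrix(cm, outdir / "contacts.tsv")
    emit(outdir / "contacts.tsv")
    track = chromatin.insulation_score(cm, w)
    calls = chromatin.passing_boundaries(chromatin.call_boundaries(track))
    bed = [c.interval for c in calls]
    for c, iv in zip(calls, bed):
        iv.meta["score"] = c.strength
        iv.meta["name"] = "boundary"
    io.write_bed(bed, outdir / "boundaries.bed")
    emit(outdir / "boundaries.bed")
    tad_ivs = chromatin.call_tads(calls, cm.chrom, cm.n_bins * bin_size)
    io.write_bed(tad_ivs, outdir / "tads.bed")
    emit(outdir / "tads.bed")


def _stage_pan(ds: synth.SimDataset, outdir: Path, emit) -> None:
    lifted_b, _ = pan.lift_features(ds.boundaries, ds.maps)
    lifted_c, _ = pan.lift_features(ds.ltcres, ds.maps)
    lifted_l, _ = pan.lift_loops(ds.loops, ds.maps)
    tables = [
        pan.clusters_to_table(pan.cluster_lifted_intervals(
            lifted_b, pan.DEFAULT_MAX_GAP["boundary"], "boundary")),
        pan.clusters_to_table(pan.cluster_lifted_intervals(
            lifted_c, pan.DEFAULT_MAX_GAP["ltcre"], "ltcre")),
        pan.clusters_to_table(pan.cluster_loops(lifted_l)),
        pan.clusters_to_table(pan.classify_pan_svs(
            sv_mod.merge_svs(ds.svs), ds.config.n_genomes)),
    ]
    io.write_table(pd.concat(tables, ignore_index=True),
                   outdir / "pan_clusters.tsv")
    emit(outdir / "pan_clusters.tsv")
    curves = pan.accumulation_curves(ds.families, n_orders=100, seed=ds.config.seed)
    io.write_table(pd.DataFrame({
        "k": np.arange(1, ds.config.n_genomes + 1),
        "pan_mean": curves["pan_mean"], "pan_sd": curves["pan_sd"],
        "core_mean": curves["core_mean"], "core_sd": curves["core_sd"]}),
        outdir / "accumulation.tsv")
    emit(outdir / "accumulation.tsv")


def _stage_sv(ds: synth.SimDataset, outdir: Path, emit) -> None:
    merged = sv_mod.merge_svs(ds.svs)
    mech = [sv_mod.classify_sv_mechanism(m.representative) for m in merged]
    io.write_table(pd.DataFrame({
        "chrom": [m.representative.chrom for m in merged],
        "start": [m.representative.start for m in merged],
        "end": [m.representative.end for m in merged],
        "sv_type": [m.representative.sv_type for m in merged],
        "support": [m.presence_count for m in merged],
        "mechanism": [c.mechanism for c in mech]}),
        outdir / "sv_merged.tsv")
    emit(outdir / "sv_merged.tsv")
    _, table = sv_mod.sv_hotspots(ds.svs, ds.backbone)
    io.write_table(table, outdir / "sv_hotspots.tsv")
    emit(outdir / "sv_hotspots.tsv")


def _stage_select(config, ds: synth.SimDataset, outdir: Path, emit) -> None:
    p = dict(config.params.get("select_enrich", {}))
    n_sites = len(ds.truth.cluster_positions.get("sv", [])) or 100
    freqs = synth.divergent_allele_freqs(
        n_sites, ds.config.fst_target, seed=config.seed)
    table = synth.simulate_genotypes(ds.config.pop_sizes, freqs,
                                     seed=config.seed)
    g1, g2 = table.pop_slices()
    theta, _ = popgen.wc_fst(g1, g2)
    pi1, _ = popgen.nucleotide_diversity(g1)
    pi2, _ = popgen.nucleotide_diversity(g2)
    sel = popgen.build_selection_table(theta, pi1, pi2)
    try:
        sel = popgen.screen_candidate_svs(sel)
    except ValueError:
        pass     # too few finite markers to screen
    io.write_table(sel, outdir / "selection.tsv")
    emit(outdir / "selection.tsv")
    regions = ds.truth.boundary_positions
    result = popgen.bootstrap_coverage_test(
        [s.as_interval() for s in ds.svs], regions, ds.backbone,
        n_draws=int(p.get("n_draws", 1000)), seed=config.seed)
    (outdir / "bootstrap.json").write_text(json.dumps({
        "observed": result.observed,
        "null_mean": float(result.null_draws.mean()),
        "null_sd": float(result.null_draws.std()),
        "p_depletion": result.p_depletion,
        "p_enrichment": result.p_enrichment,
        "z": result.z_score, "n_draws": result.n_draws,
        "seed": config.seed}, indent=2, sort_keys=True) + "\n")
    emit(outdir / "bootstrap.json")


def _stage_capture(config, outdir: Path, emit) -> None:
    p = dict(config.params.get("capture_diff", {}))
    df, _ = synth.simulate_capture_table(
        int(p.get("n_interactions", 200)),
        float(p.get("frac_mt_specific", 0.2)), seed=config.seed)
    labelled = capture_mod.differential_interactions(df)
    io.write_table(labelled, outdir / "capture_diff.tsv")
    emit(outdir / "capture_diff.tsv")
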