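"""End-to-end orchestration: simulate -> discover -> annotate -> genotype ->
selection scan -> windowed popgen, driven by one YAML config with a run
manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import annotation, discovery, genotyping, popgen, selection
from . import io as svio
from .models import GenotypeMatrix
from .simulate import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the study design."""

    out_dir: str = "svscan_out"
    seed: int = 0
    log_level: str = "INFO"
    # stage gating: when inputs exist the simulate stage may be skipped
    skip_simulate: bool = False
    paf: Optional[str] = None
    genome_a: Optional[str] = None
    genome_b: Optional[str] = None
    gff3: Optional[str] = None
    groups: Optional[str] = None
    sam_a_dir: Optional[str] = None
    sam_b_dir: Optional[str] = None
    snp_vcf: Optional[str] = None
    # module parameters
    sim: dict = field(default_factory=dict)
    min_sv_size: int = 10
    max_sv_size: int = 50_000
    min_anchor: int = 1_000
    flank_bp: int = 2_000
    mismatch_frac: float = 0.03
    geno_w: int = 20
    geno_min_depth: int = 4
    geno_hom_frac: float = 0.8
    min_call_rate: float = 0.70
    min_maf: float = 0.03
    alpha: float = 0.05
    window_bp: int = 15_000
    top_fraction: float = 0.05
    ld_max_dist: int = 50_000
    ld_bin_bp: int = 1_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to out_dir/manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {
        "svscan_version": __version__,
        "parameters": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "inputs": {},
        "headline": {},
    }
    t0 = time.time()

    # ---- simulate -------------------------------------------------
    stage = "simulate"
    try:
        if config.skip_simulate:
            paths = {
                "paf": config.paf, "genome_a": config.genome_a,
                "genome_b": config.genome_b, "gff3": config.gff3,
                "groups": config.groups,
            }
            for key, p in paths.items():
                if p is None:
                    raise ConfigError(f"skip_simulate requires input {key!r}")
            sam_a = {p.stem: str(p) for p in sorted(Path(config.sam_a_dir).glob("*.sam"))}
            sam_b = {p.stem: str(p) for p in sorted(Path(config.sam_b_dir).glob("*.sam"))}
            paths.update({"sam_a": sam_a, "sam_b": sam_b, "snp_vcf": config.snp_vcf})
        else:
            sim_cfg = SimConfig(seed=config.seed, **config.sim)
            sim_dir = out / "sim"
            sim_manifest = simulate_dataset(sim_cfg, sim_dir)
            paths = {
                "paf": sim_manifest["paf"], "genome_a": sim_manifest["genome_a"],
                "genome_b": sim_manifest["genome_b"], "gff3": sim_manifest["gff3"],
                "groups": str(sim_dir / "groups.tsv"),
                "sam_a": sim_manifest["sam_a"], "sam_b": sim_manifest["sam_b"],
                "snp_vcf": sim_manifest.get("snp_vcf"),
            }
        manifest["stages"][stage] = "ok"
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    for key in ("paf", "genome_a", "genome_b", "gff3", "groups"):
        manifest["inputs"][key] = {"path": paths[key], "sha256": _sha256(Path(paths[key]))}

    groups = svio.read_groups_tsv(paths["groups"])
    genome_a = svio.read_fasta(paths["genome_a"])
    genome_b = svio.read_fasta(paths["genome_b"])
    lens_a = {c: len(v) for c, v in genome_a.items()}

    # ---- discover -------------------------------------------------
    stage = "discover"
    try:
        svs, disc_report = discovery.discover_svs(
            paths["paf"], min_size=config.min_sv_size, max_size=config.max_sv_size,
            min_anchor=config.min_anchor, genome_b=genome_b)
        svio.write_sv_vcf(svs, lens_a, out / "sv.vcf")
        svio.write_sv_truth_tsv(svs, out / "sv.tsv")
        manifest["stages"][stage] = "ok"
        manifest["headline"]["n_svs"] = len(svs)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- annotate -------------------------------------------------
    stage = "annotate"
    try:
        genes = svio.read_gff3(paths["gff3"])
        context = annotation.classify_all(svs, genes, config.flank_bp, config.flank_bp)
        context.to_csv(out / "sv_context.tsv", sep="\t", index=False)
        pairs = annotation.map_svs_to_genes(svs, genes, config.flank_bp)
        pairs.to_csv(out / "sv_gene_pairs.tsv", sep="\t", index=False)
        manifest["headline"]["n_genes_affected"] = int(pairs["gene_id"].nunique())
        manifest["headline"]["category_counts"] = annotation.category_counts(context)
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- genotype -------------------------------------------------
    stage = "genotype"
    try:
        params = genotyping.GenotypingParams(
            w=config.geno_w, min_depth=config.geno_min_depth,
            hom_frac=config.geno_hom_frac, max_mismatch_frac=config.mismatch_frac)
        matrix, summary, supports = genotyping.genotype_population(
            paths["sam_a"], paths["sam_b"], svs, groups, params)
        # "filtering by Illumina read mapping": keep discovery SVs genotypable
        # in at least one accession
        genotyped_any = matrix.loci[matrix.dosages.notna().any(axis=1)]
        matrix = matrix.subset_loci(genotyped_any)
        svs_kept = [sv for sv in svs if sv.id in set(genotyped_any)]
        filtered = genotyping.filter_matrix(matrix, config.min_call_rate, config.min_maf)
        svio.write_sv_vcf(svs_kept, lens_a, out / "geno.vcf",
                          genotypes=matrix.dosages, supports=supports)
        matrix.dosages.rename_axis("sv_id").to_csv(out / "geno_matrix.tsv", sep="\t")
        summary.to_csv(out / "accession_summary.tsv", sep="\t", index=False)
        manifest["headline"]["n_svs_genotyped"] = int(len(matrix.loci))
        manifest["headline"]["n_svs_pass_filters"] = int(len(filtered.loci))
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- selection scan -------------------------------------------
    stage = "scan"
    try:
        scan = selection.run_selection_scan(filtered, alpha=config.alpha)
        scan.to_csv(out / "selection.tsv", sep="\t", index=False)
        sel_ids = set(scan.loc[scan["selected"], "sv_id"])
        sel_svs = [sv for sv in svs if sv.id in sel_ids]
        sel_pairs = annotation.map_svs_to_genes(sel_svs, genes, config.flank_bp)
        sel_pairs.to_csv(out / "selected_sv_genes.tsv", sep="\t", index=False)
        manifest["headline"]["n_selected_svs"] = int(len(sel_ids))
        manifest["headline"]["n_selected_genes"] = int(sel_pairs["gene_id"].nunique())
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- popgen ---------------------------------------------------
    stage = "popgen"
    try:
        if paths.get("snp_vcf"):
            panel = popgen.SnpPanel.from_vcf(paths["snp_vcf"], groups)
            stats = popgen.window_stats(panel, config.window_bp, lens_a)
            stats = popgen.top_fraction_outliers(stats, config.top_fraction)
            stats.to_csv(out / "window_stats.tsv", sep="\t", index=False)
            ld = popgen.ld_decay(panel, "cultivated", config.ld_max_dist, config.ld_bin_bp)
            ld.to_csv(out / "ld_decay_cultivated.tsv", sep="\t", index=False)
            pca_coords, evr = popgen.genotype_pca(panel.dosages, k=10)
            pca_coords.rename_axis("accession").to_csv(out / "pca.tsv", sep="\t")
            manifest["headline"]["n_outlier_windows_fst"] = int(stats["outlier_fst"].sum())
            manifest["headline"]["genome_fst"] = float(popgen.genome_fst(panel))
        else:
            logger.info("no SNP VCF provided; popgen stage skipped")
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(manifest["headline"], fh, indent=2, sort_keys=True)
    return manifest
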