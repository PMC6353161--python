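"""End-to-end orchestration: QC -> F_ST -> d_i scan -> regions -> LD -> structure.

A run is driven by a :class:`RunConfig` (loadable from YAML); every stage
writes plain-text TSV/Newick/JSON artifacts into the output directory, and
``manifest.json`` records the config hash and the stage log so reruns can be
verified bitwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fst, ld, plink, popstruct, qc, scan
from .model import GenotypeMatrix

log = logging.getLogger("divscan")


@dataclass
class RunConfig:
    plink_prefix: str
    breeds_tsv: str | None = None
    annotation: str | None = None           # BED or GFF3 gene intervals
    annotation_format: str | None = None    # "bed" | "gff3" | None = by suffix
    out_dir: str = "divscan_out"
    sample_call_rate_min: float = 0.97
    maf_min: float = 0.05
    snp_missing_max: float = 0.20
    hwe_p_min: float = 1.0e-6
    sex_chroms: tuple[str, ...] = ("X", "Y", "32", "33")
    window_size: int = 10
    quantile: float = 0.999
    extension_bp: int = 25_000
    ld_max_span_bp: int = 500_000
    breed_types: dict = field(default_factory=dict)  # type label -> [breeds]
    ld_top_regions: int = 1                 # per breed, for block analysis
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def thresholds(self) -> qc.QcThresholds:
        return qc.QcThresholds(
            sample_call_rate_min=self.sample_call_rate_min,
            maf_min=self.maf_min,
            snp_missing_max=self.snp_missing_max,
            hwe_p_min=self.hwe_p_min,
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: (sorted(v.items()) if isinstance(v, dict) else v)
             for k, v in self.__dict__.items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate_types(self, breeds: list[str]) -> None:
        seen: set[str] = set()
        for label, members in self.breed_types.items():
            ms = set(members)
            unknown = ms - set(breeds)
            if unknown:
                raise ValueError(f"type {label!r} names unknown breeds {sorted(unknown)}")
            if ms & seen:
                raise ValueError(f"breed assigned to two types: {sorted(ms & seen)}")
            seen |= ms


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name, fn, stage_log, *args, **kw):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        out = fn(*args, **kw)
    except Exception as exc:  # halt with stage named; partial outputs remain
        stage_log.append({"stage": name, "status": "failed", "error": str(exc)})
        raise StageError(f"stage {name!r} failed: {exc}") from exc
    stage_log.append(
        {"stage": name, "status": "ok",
         "seconds": round(time.perf_counter() - t0, 3)}
    )
    return out


def load_inputs(cfg: RunConfig):
    breeds = plink.read_breeds_tsv(cfg.breeds_tsv) if cfg.breeds_tsv else None
    return plink.read_plink(
        cfg.plink_prefix + ".map", cfg.plink_prefix + ".ped", breeds=breeds
    )


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns a dict of the
    in-memory results keyed by stage."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    stage_log: list[dict] = []
    results: dict = {}
    t = cfg.thresholds()
    try:
        markers, samples, g = _stage("load", load_inputs, stage_log, cfg)

        def qc_stage():
            g1 = qc.filter_samples_by_call_rate(g, t)
            _, g2 = qc.filter_autosomes(g1.markers, g1, cfg.sex_chroms)
            g3, report = qc.filter_markers(g2, g2.samples, t, return_report=True)
            summary = qc.panel_summary(g3, g3.samples, g3.markers, t)
            report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
            summary.table.assign(
                mean_intermarker_kb=summary.mean_intermarker_kb
            ).to_csv(out / "panel_summary.tsv", sep="\t", index=False)
            return g3, report, summary

        gq, qc_report, summary = _stage("qc", qc_stage, stage_log)
        results["panel"] = gq
        results["panel_summary"] = summary
        cfg.validate_types(gq.samples.breeds)

        def fst_stage():
            matrix, tracks = fst.fst_matrix(gq, gq.samples)
            matrix.to_frame().to_csv(out / "fst_matrix.tsv", sep="\t")
            for key, tr in tracks.items():
                pair = "_".join(sorted(key))
                pd.DataFrame({
                    "snp_id": gq.markers.snp_id, "chrom": gq.markers.chrom,
                    "pos_bp": gq.markers.pos_bp, "theta": tr.theta,
                }).to_csv(out / f"fst_{pair}.tsv", sep="\t", index=False,
                          float_format="%.6g")
            return matrix, tracks

        matrix, tracks = _stage("fst", fst_stage, stage_log)
        results["fst_matrix"] = matrix

        def scan_stage():
            genes = None
            if cfg.annotation:
                fmt = cfg.annotation_format or (
                    "gff3" if str(cfg.annotation).endswith((".gff", ".gff3"))
                    else "bed"
                )
                genes = (scan.read_gff3_genes(cfg.annotation) if fmt == "gff3"
                         else scan.read_bed_genes(cfg.annotation))
            tspec = scan.ThresholdSpec(cfg.quantile)
            profiles, all_regions, gene_hits = {}, [], []
            comparisons = [(b, None) for b in gq.samples.breeds]
            type_labels = sorted(cfg.breed_types)
            for ia in range(len(type_labels)):
                for ib in range(ia + 1, len(type_labels)):
                    comparisons.append((type_labels[ia], type_labels[ib]))
            for a, b in comparisons:
                if b is None:
                    prof = scan.di_per_snp(a, tracks, gq.markers.chrom,
                                           gq.markers.pos_bp)
                else:
                    prof = scan.type_comparison(
                        set(cfg.breed_types[a]), set(cfg.breed_types[b]),
                        tracks, gq.markers.chrom, gq.markers.pos_bp,
                    )
                scan.window_smooth(prof, cfg.window_size)
                regions = scan.call_regions(prof, tspec)
                profiles[prof.focal] = (prof, regions)
                all_regions.extend(regions)
                prof.windows.to_csv(
                    out / f"windows_{prof.focal}.tsv", sep="\t", index=False,
                    float_format="%.6g",
                )
                if genes is not None:
                    gene_hits.append(scan.annotate_regions(
                        regions, genes, pad=cfg.extension_bp))
            scan.regions_frame(all_regions).to_csv(
                out / "regions.tsv", sep="\t", index=False, float_format="%.6g")
            if gene_hits:
                pd.concat(gene_hits, ignore_index=True).to_csv(
                    out / "region_genes.tsv", sep="\t", index=False)
            return profiles, all_regions

        profiles, regions = _stage("scan", scan_stage, stage_log)
        results["profiles"] = profiles
        results["regions"] = regions

        def ld_stage():
            blocks_out = []
            for breed in gq.samples.breeds:
                prof_regions = profiles[breed][1]
                top = sorted(prof_regions, key=lambda r: -r.peak_di)[: cfg.ld_top_regions]
                rows = gq.samples.indices_of(breed)
                for region in top:
                    in_region = np.flatnonzero(
                        (gq.markers.chrom == region.chrom)
                        & (gq.markers.pos_bp >= region.start)
                        & (gq.markers.pos_bp <= region.stop)
                    )
                    sub = gq.subset(sample_idx=rows, snp_idx=in_region)
                    blocks = ld.gabriel_blocks(
                        sub.markers, sub, max_span_bp=cfg.ld_max_span_bp)
                    bf = ld.blocks_frame(blocks)
                    bf.insert(0, "region_start", region.start)
                    bf.insert(0, "breed", breed)
                    blocks_out.append(bf)
            frame = (pd.concat(blocks_out, ignore_index=True)
                     if blocks_out else pd.DataFrame())
            frame.to_csv(out / "haploblocks.tsv", sep="\t", index=False,
                         float_format="%.6g")
            return frame

        results["haploblocks"] = _stage("ld", ld_stage, stage_log)

        def structure_stage():
            pca = popstruct.pca_genotypes(gq, K=2)
            pca.coords.to_csv(out / "pca_coords.tsv", sep="\t", index=False,
                              float_format="%.6g")
            tree = popstruct.nj_tree(matrix, use="weighted")
            popstruct.write_newick(tree, out / "nj_weighted.nwk")
            return pca, tree

        pca, tree = _stage("structure", structure_stage, stage_log)
        results["pca"] = pca
        results["nj_tree"] = tree
    finally:
        manifest = {
            "config_hash": cfg.config_hash(),
            "config": {k: (v if not isinstance(v, tuple) else list(v))
                       for k, v in cfg.__dict__.items()},
            "stages": stage_log,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str) + "\n")
        log.removeHandler(fh)
        fh.close()
    return results
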