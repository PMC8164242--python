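"""End-to-end orchestration of the triplex/TAD analysis.

``run_pipeline`` sequences the full study on one input bundle (synthetic or
loaded from files): expressed-lncRNA selection → dominant isoforms → TFS/TFD
prediction → enrichment in TADs/boundaries/anchors → positional preference →
size–coverage correlation → CTCF distance comparison → functional annotation
densities → TAD/background classification with lncRNA importance → and the
cross-cell-line shared-site classification.  Every random draw flows from the
config seed; a config digest is embedded in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .annotation import build_gene_model_set, feature_density
from .enrichment import (
    bp_coverage,
    ctcf_distance_test,
    enrichment_test,
    positional_preference_test,
    shuffle_intervals,
    shuffled_coverages,
    size_coverage_correlation,
    tad_enrichment,
)
from .expression import filter_expressed
from .shared import classify_shared_sites, dedupe_sites, nearest_gene
from .synthetic import SyntheticBundle, SyntheticConfig, simulate
from .tad_ml import (
    build_feature_matrix,
    check_tad_fraction,
    generate_background,
    importance_table,
    lncrna_importance,
    train_and_tune,
)
from .triplex import TriplexParams, merge_tfds, search_triplexes, select_dominant_isoform

ALL_STAGES = ("triplex", "enrichment", "positional", "size_correlation",
              "ctcf", "annotation", "ml", "shared")


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    triplex: TriplexParams = field(default_factory=TriplexParams)
    n_shuffles: int = 1000
    seed: int = 0
    tpm_threshold: float = 5.0
    enrichment_alpha: float = 1e-3
    ml_models: tuple[str, ...] = ("random_forest",)
    importance_repeats: int = 25
    stages: tuple[str, ...] = ALL_STAGES
    cell_lines: tuple[str, ...] | None = None    # default: all in the TPM table
    outdir: str | None = None

    def digest(self) -> str:
        blob = yaml.safe_dump({
            "synthetic": dataclasses.asdict(self.synthetic),
            "triplex": dataclasses.asdict(self.triplex),
            "n_shuffles": self.n_shuffles, "seed": self.seed,
            "tpm_threshold": self.tpm_threshold,
            "enrichment_alpha": self.enrichment_alpha,
            "ml_models": list(self.ml_models),
            "importance_repeats": self.importance_repeats,
            "stages": list(self.stages),
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def prepare_regions(points: pd.DataFrame, chrom_sizes: Mapping[str, int],
                    flank: int = 10_000) -> pd.DataFrame:
    """Expand 1-bp calls (chrom, pos) to ±flank intervals, clipped at ends.

    Accepts a frame with columns (chrom, pos) or (chrom, start, end) where
    start == end marks the point.  Clipping at a chromosome end warns.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if "pos" in points.columns:
        pos = points["pos"].to_numpy(np.int64)
    else:
        pos = points["start"].to_numpy(np.int64)
    chroms = points["chrom"].to_numpy()
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if (pos < 0).any() or (pos > sizes).any():
        raise ValueError("boundary point outside genome")
    start = pos - flank
    end = pos + flank
    clipped = (start < 0) | (end > sizes)
    if clipped.any():
        warnings.warn(f"{int(clipped.sum())} boundary interval(s) clipped at chromosome ends",
                      stacklevel=2)
    return pd.DataFrame({"chrom": chroms, "start": np.maximum(start, 0),
                         "end": np.minimum(end, sizes)})


def _result_dict(res) -> dict:
    return {
        "observed_coverage": res.observed_coverage,
        "expected_mean": res.expected_mean, "expected_sd": res.expected_sd,
        "n_shuffles": res.n_shuffles, "ad_statistic": res.ad_statistic,
        "ad_pvalue": res.ad_pvalue, "z": res.z, "p_value": res.p_value,
        "p_display": res.p_display, "region_class": res.region_class,
    }


def dominant_isoform_sites(sites: pd.DataFrame, gene_of: Mapping[str, str]) -> pd.DataFrame:
    """Keep, per lncRNA gene, only the isoform with the most TFSs."""
    if len(sites) == 0:
        return sites
    keep = []
    for gene, sub in sites.groupby("lncrna_id"):
        counts = {iso: 0 for iso, g in gene_of.items() if g == gene}
        counts.update(sub.groupby("isoform_id").size().to_dict())
        keep.append((gene, select_dominant_isoform(counts)))
    keep_set = set(keep)
    mask = [(g, i) in keep_set for g, i in zip(sites["lncrna_id"], sites["isoform_id"])]
    return sites[mask].reset_index(drop=True)


def run_pipeline(cfg: PipelineConfig, bundle: SyntheticBundle | None = None) -> dict:
    """Run the full study; returns the (JSON-serialisable) report."""
    if bundle is None:
        bundle = simulate(cfg.synthetic)
    chrom_sizes = bundle.chrom_sizes
    rng_root = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ("shuffle", "positional", "ctcf", "ml", "importance", "background"),
        rng_root.spawn(6))}

    report: dict = {"config_digest": cfg.digest(), "seed": cfg.seed, "cell_lines": {}}

    sites_all = search_triplexes(bundle.lncrnas, bundle.genome, cfg.triplex, bundle.gene_of)
    sites_all = dominant_isoform_sites(sites_all, bundle.gene_of)
    per_line_expressed, union_expressed = filter_expressed(bundle.tpm, cfg.tpm_threshold)
    report["n_expressed_union"] = len(union_expressed)
    report["n_tfs_total"] = int(len(sites_all))

    lines = list(cfg.cell_lines) if cfg.cell_lines else list(bundle.tpm.columns)
    gms = build_gene_model_set(bundle.gene_models, chrom_sizes)
    pooled_in_domain = []

    for line in lines:
        expressed = per_line_expressed[line]
        sites = sites_all[sites_all["lncrna_id"].isin(expressed)].reset_index(drop=True)
        tads = bundle.tad_sets[line]
        boundaries = bundle.boundary_sets[line]
        anchors = bundle.anchor_sets[line]
        entry: dict = {"n_expressed": len(expressed), "n_tfs": int(len(sites))}

        tfd_lengths = []
        n_tfds = 0
        for _, sub in sites.groupby(["lncrna_id", "isoform_id"]):
            doms = merge_tfds(sub)
            n_tfds += len(doms)
            tfd_lengths += [d.length for d in doms]
        entry["n_tfds"] = n_tfds
        entry["tfd_median_length"] = float(np.median(tfd_lengths)) if tfd_lengths else None

        if "enrichment" in cfg.stages and len(sites):
            entry["enrichment"] = {}
            for cls, regions in [("TAD", tads), ("boundary", boundaries), ("anchor", anchors)]:
                if len(regions) == 0:
                    continue
                res = tad_enrichment(sites, regions, chrom_sizes, cfg.n_shuffles,
                                     region_class=cls, rng=streams["shuffle"])
                d = _result_dict(res)
                d["enriched"] = bool(res.p_sentinel or res.p_value < cfg.enrichment_alpha)
                entry["enrichment"][cls] = d

        # position/distance statistics sample the distinct genomic footprints
        # (sites of many lncRNAs stack on one tract and are not independent)
        units = dedupe_sites(sites) if len(sites) else sites

        if "positional" in cfg.stages and len(sites):
            control = next(shuffle_intervals(units, chrom_sizes, 1, rng=streams["positional"]))
            try:
                pt = positional_preference_test(units, tads, control)
                entry["positional"] = {
                    "bin_counts": pt.observed.bin_counts.tolist(),
                    "control_bin_counts": pt.control.bin_counts.tolist(),
                    "ks_statistic": pt.ks_statistic, "ks_pvalue": pt.ks_pvalue,
                }
            except ValueError as exc:
                entry["positional"] = {"error": str(exc)}

        if "size_correlation" in cfg.stages and len(sites) and len(tads) >= 3:
            r, _table = size_coverage_correlation(sites, tads)
            entry["size_coverage_pearson_r"] = r

        if "ctcf" in cfg.stages and len(sites) and len(bundle.ctcf_sites):
            rand_ctcf = next(shuffle_intervals(bundle.ctcf_sites, chrom_sizes, 1,
                                               rng=streams["ctcf"]))
            ct = ctcf_distance_test(units, bundle.ctcf_sites, rand_ctcf)
            entry["ctcf"] = {"chi2": ct["chi2"], "p_value": ct["p_value"],
                             "hist_real": ct["hist_real"].tolist(),
                             "hist_random": ct["hist_random"].tolist()}

        if "annotation" in cfg.stages and len(sites):
            entry["annotation_density_per_10kb"] = feature_density(sites, gms)

        if "ml" in cfg.stages and len(sites) and len(tads) >= 25:
            try:
                check_tad_fraction(tads, chrom_sizes)
                bg = generate_background(tads, chrom_sizes, rng=streams["background"])
                X, y = build_feature_matrix(tads, bg, sites)
                entry["ml"] = {}
                best = None
                for model in cfg.ml_models:
                    rep = train_and_tune(X, y, model=model, seed=cfg.seed)
                    entry["ml"][model] = {"metrics": rep.metrics, "best_params": rep.best_params}
                    if best is None or rep.metrics["accuracy"] > best.metrics["accuracy"]:
                        best = rep
                imp = lncrna_importance(best, repeats=cfg.importance_repeats,
                                        rng=streams["importance"])
                entry["importance_top10"] = importance_table(imp, 10).to_dict("records")
                entry["ml"]["best_model"] = best.model_name
            except ValueError as exc:
                entry["ml"] = {"error": str(exc)}

        if "shared" in cfg.stages and len(sites):
            pooled_in_domain.append(sites[["chrom", "start", "end"]])

        report["cell_lines"][line] = entry

    if "shared" in cfg.stages and pooled_in_domain and len(lines) >= 2:
        pooled = pd.concat(pooled_in_domain, ignore_index=True)
        table = classify_shared_sites(pooled, {c: bundle.tad_sets[c] for c in lines})
        shared_all = table[table["category"] == "shared_all"]
        ng, genes = nearest_gene(shared_all, gms) if len(shared_all) else (None, [])
        report["shared_sites"] = {
            "n_pooled_unique": int(len(table)),
            "category_counts": table["category"].value_counts().to_dict(),
            "n_shared_all": int(len(shared_all)),
            "n_nearest_genes": len(genes),
        }

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        sites_all.to_csv(out / "tfs_all.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
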