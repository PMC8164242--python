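"""Canned simulation experiments: calibration, power, and recovery studies.

Each experiment generates synthetic study systems from scratch, runs the
relevant pipeline stages, and summarises the outcome.  The configurations are
the package's reference study conditions:

* **calibration** — small systems (2 × 150 kb, 8 TADs) with enrichment factor
  1, where the shuffle-test p-values must be uniform;
* **power** — 2 × 400 kb systems with 20 TADs and a dense tract background
  (250/Mb), where factor ≥ 2 must be detected;
* **ml** — 4 × 500 kb systems with 60 TADs (2n = 120 regions) and a dense
  tract background (400/Mb), 20 informative + 80 noise lncRNAs;
* **importance** — like ml but with 2 informative lncRNAs reading two
  disjoint tract families, so that each planted feature is individually
  necessary and its target-shuffling importance must be positive.

Problem sizes are chosen so each experiment completes in minutes on one CPU.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import (positional_preference_test, shuffle_intervals,
                         tad_enrichment)
from .synthetic import SyntheticConfig, gen_regions, simulate
from .tad_ml import (build_feature_matrix, generate_background,
                     lncrna_importance, train_and_tune)
from .triplex import TriplexParams, search_triplexes

RF_GRID = {"clf__n_estimators": [300], "clf__max_features": ["sqrt", 0.5]}
RF_GRID_FAST = {"clf__n_estimators": [200], "clf__max_features": ["sqrt"]}
# with few informative columns among many all-zero ones, per-split feature
# subsampling would often hide every informative feature from a split; the
# importance study therefore lets each split see all features
RF_GRID_IMPORTANCE = {"clf__n_estimators": [300], "clf__max_features": [1.0]}


def calibration_config(seed: int, factor: float = 1.0) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, n_chroms=2, chrom_length=150_000, n_tads=8,
                           tad_length_range=(8_000, 14_000), n_lncrnas=30,
                           n_genes=10, tts_enrichment_factor=factor)


def power_config(seed: int, factor: float) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, n_chroms=2, chrom_length=400_000, n_tads=20,
                           tad_length_range=(10_000, 16_000), n_lncrnas=40,
                           n_genes=12, tts_rate_background=250.0,
                           tts_enrichment_factor=factor)


def ml_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, n_chroms=4, chrom_length=500_000, n_tads=60,
                           tad_length_range=(8_000, 12_000), n_lncrnas=100,
                           n_informative=20, n_tract_families=6, n_genes=20,
                           tts_rate_background=600.0, tts_enrichment_factor=3.0)


def importance_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, n_chroms=4, chrom_length=500_000, n_tads=90,
                           tad_length_range=(6_000, 10_000), n_lncrnas=40,
                           n_informative=2, n_tract_families=2, n_genes=20,
                           tts_rate_background=400.0, tts_enrichment_factor=3.0)


def _bundle_enrichment(cfg: SyntheticConfig, n_shuffles: int, rng_seed: int):
    bundle = simulate(cfg)
    sites = search_triplexes(bundle.lncrnas, bundle.genome, TriplexParams(),
                             bundle.gene_of)
    if len(sites) == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tad_enrichment(sites, bundle.tads, bundle.chrom_sizes,
                              n_shuffles, rng=rng_seed)


def enrichment_null_calibration(n_bundles: int = 100, n_shuffles: int = 200,
                                seed: int = 0) -> dict:
    """Fraction of null (factor 1) bundles with enrichment p < 0.05."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_bundles) % (2**31)
    ps, zs = [], []
    for i in range(n_bundles):
        res = _bundle_enrichment(calibration_config(int(seeds[i])), n_shuffles,
                                 int(seeds[n_bundles + i]))
        if res is None:
            continue
        ps.append(0.0 if res.p_sentinel else res.p_value)
        zs.append(res.z)
    ps = np.asarray(ps)
    return {"n": len(ps), "fraction_p_lt_05": float((ps < 0.05).mean()),
            "mean_z": float(np.mean(zs)), "p_values": ps}


def enrichment_power(n_bundles: int = 50, n_shuffles: int = 200, seed: int = 0,
                     factors: Sequence[float] = (1.0, 2.0, 4.0),
                     n_side: int = 10) -> dict:
    """Detection rate at factor 2 plus mean z across enrichment factors."""
    ss = np.random.SeedSequence(seed + 1)
    seeds = ss.generate_state(4 * n_bundles + 200) % (2**31)
    k = 0
    mean_z = {}
    frac_sig = None
    for factor in factors:
        n = n_bundles if factor == 2.0 else n_side
        zs, sig = [], 0
        for _ in range(n):
            res = _bundle_enrichment(power_config(int(seeds[k]), factor),
                                     n_shuffles, int(seeds[k + 1]))
            k += 2
            if res is None:
                continue
            zs.append(res.z)
            sig += (res.p_sentinel is not None) or (res.p_value < 1e-3)
        mean_z[factor] = float(np.mean(zs))
        if factor == 2.0:
            frac_sig = sig / n
    return {"fraction_p_lt_001_at_factor2": frac_sig, "mean_z_by_factor": mean_z}


def positional_uniformity(n_runs: int = 50, seed: int = 0,
                          n_sites: int = 150) -> dict:
    """KS calibration: uniform in-TAD sites vs uniform control."""
    ss = np.random.SeedSequence(seed + 2)
    seeds = ss.generate_state(n_runs) % (2**31)
    ok = 0
    n_eval = 0
    for s in seeds:
        cfg = calibration_config(int(s))
        tads, _, _ = gen_regions(cfg)
        sizes = cfg.chrom_sizes()
        rng = np.random.default_rng(int(s) + 17)
        proto = pd.DataFrame({"chrom": "chr1", "start": 0, "end": 20},
                             index=range(n_sites))
        obs = next(shuffle_intervals(proto, sizes, 1, allowed_regions=tads, rng=rng))
        ctl = next(shuffle_intervals(proto, sizes, 1, rng=rng))
        try:
            res = positional_preference_test(obs, tads, ctl)
        except ValueError:
            continue
        n_eval += 1
        ok += res.ks_pvalue > 0.05
    return {"n": n_eval, "fraction_p_gt_05": ok / n_eval}


def ml_recovery(seed: int = 0, n_label_permutations: int = 10) -> dict:
    """Random-forest recovery of the planted TAD signal (20 informative
    lncRNAs) plus the label-permuted chance control."""
    cfg = ml_config(seed)
    bundle = simulate(cfg)
    sites = search_triplexes(bundle.lncrnas, bundle.genome, TriplexParams(),
                             bundle.gene_of)
    bg = generate_background(bundle.tads, bundle.chrom_sizes, rng=seed + 1)
    X, y = build_feature_matrix(bundle.tads, bg, sites)
    rep = train_and_tune(X, y, "random_forest", seed=seed, grid=RF_GRID)
    rng = np.random.default_rng(seed + 77)
    perm_accs = []
    for _ in range(n_label_permutations):
        yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        rp = train_and_tune(X, yp, "random_forest", seed=seed, grid=RF_GRID_FAST)
        perm_accs.append(rp.metrics["accuracy"])
    return {"metrics": rep.metrics, "auc": rep.metrics["auc"],
            "accuracy": rep.metrics["accuracy"],
            "n_regions": len(X), "n_features": X.shape[1],
            "permuted_label_accuracy": float(np.mean(perm_accs)),
            "report": rep}


def importance_recovery(n_runs: int = 50, seed: int = 0) -> dict:
    """Fraction of runs in which every planted informative lncRNA scores
    above the 95th percentile of the noise-lncRNA importance scores."""
    ss = np.random.SeedSequence(seed + 3)
    seeds = ss.generate_state(n_runs) % (2**31)
    ok = 0
    n_eval = 0
    constant_zero_ok = True
    for s in seeds:
        s = int(s)
        cfg = importance_config(s)
        bundle = simulate(cfg)
        sites = search_triplexes(bundle.lncrnas, bundle.genome, TriplexParams(),
                                 bundle.gene_of)
        bg = generate_background(bundle.tads, bundle.chrom_sizes, rng=s + 1)
        lnc_ids = sorted(set(bundle.gene_of.values()))
        X, y = build_feature_matrix(bundle.tads, bg, sites, lncrna_ids=lnc_ids)
        rep = train_and_tune(X, y, "random_forest", seed=s, grid=RF_GRID_IMPORTANCE)
        imp = lncrna_importance(rep, repeats=50, rng=s + 2)
        scores = {i.lncrna_id: i.score for i in imp}
        informative = set(bundle.truth.informative_ids)
        noise = np.array([v for k, v in scores.items() if k not in informative])
        if noise.size == 0 or not informative:
            continue
        # all-zero (constant) noise columns must score exactly 0
        const_cols = [c for c in rep.X_test.columns
                      if c not in informative
                      and rep.X_test[c].nunique() == 1]
        if any(scores[c] != 0.0 for c in const_cols):
            constant_zero_ok = False
        p95 = np.percentile(noise, 95)
        n_eval += 1
        ok += all(scores[k] > p95 for k in informative)
    return {"n": n_eval, "fraction_all_above_p95": ok / n_eval,
            "constant_columns_score_zero": constant_zero_ok}
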