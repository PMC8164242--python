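"""Cross-cell-line shared TFS classification and nearest-gene assignment.

A pooled, deduplicated site is "in-domain" for a cell line when it is fully
contained in at least one TAD of that line's set; sites in-domain in every
line are ``shared_all``, in exactly one are ``specific:<line>``, otherwise
``partial`` (the per-line flag vector and the in-domain count are kept).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import GeneModelSet
from .intervals import contained_in_any, overlaps_any


def dedupe_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Unique sites by (chrom, start, end); idempotent."""
    return (sites[["chrom", "start", "end"]]
            .drop_duplicates()
            .sort_values(["chrom", "start", "end"])
            .reset_index(drop=True))


def classify_shared_sites(sites: pd.DataFrame, tad_sets: dict[str, pd.DataFrame],
                          containment: bool = True) -> pd.DataFrame:
    """Per-site in-domain flags across cell lines and a shared/specific category.

    ``containment=True`` (default) requires full containment in a domain;
    ``False`` relaxes to any overlap.
    """
    if len(tad_sets) < 2:
        raise ValueError("need ≥ 2 TAD sets")
    table = dedupe_sites(sites)
    lines = list(tad_sets)
    test = contained_in_any if containment else overlaps_any
    for line in lines:
        table[f"in_{line}"] = test(table, tad_sets[line])
    flags = table[[f"in_{line}" for line in lines]].to_numpy()
    k = flags.sum(axis=1)
    cats = np.where(k == len(lines), "shared_all",
                    np.where(k == 1, "specific", "partial")).astype(object)
    for i in np.flatnonzero(k == 1):
        line = lines[int(np.flatnonzero(flags[i])[0])]
        cats[i] = f"specific:{line}"
    table["n_in_domain"] = k
    table["category"] = cats
    return table


def nearest_gene(sites: pd.DataFrame, models: GeneModelSet
                 ) -> tuple[pd.DataFrame, list[str]]:
    """Nearest gene (by gene-body distance, 0 on overlap) for each site.

    Ties break to the lexicographically smaller gene id.  Also returns the
    unique list of assigned genes.
    """
    genes = models.genes
    if len(genes) == 0:
        raise ValueError("empty gene set")
    g_by = {c: sub.sort_values(["tx_start", "gene_id"]).reset_index(drop=True)
            for c, sub in genes.groupby("chrom", sort=False)}
    out_gene = np.full(len(sites), "", dtype=object)
    out_dist = np.full(len(sites), np.inf)
    for i, (_, s) in enumerate(sites.iterrows()):
        sub = g_by.get(s["chrom"])
        if sub is None:
            continue
        gs = sub["tx_start"].to_numpy(np.int64)
        ge = sub["tx_end"].to_numpy(np.int64)
        ss, se = int(s["start"]), int(s["end"])
        d = np.where((gs < se) & (ge > ss), 0, np.maximum(gs - se, ss - ge))
        d = np.maximum(d, 0)
        best = d.min()
        cand = sub.loc[d == best, "gene_id"].sort_values()
        out_gene[i] = cand.iloc[0]
        out_dist[i] = best
    result = sites[["chrom", "start", "end"]].copy()
    result["nearest_gene"] = out_gene
    result["distance"] = out_dist
    unique_genes = sorted(set(out_gene) - {""})
    return result, unique_genes
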