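"""Functional-element annotation of TFSs and per-10 kb density.

Gene models (TSS, exon structure, CDS span) are expanded into element
tracks — promoter, 5'UTR, 3'UTR, CDS exon, intron — and every site is
labelled by the class covering its midpoint, resolved through a fixed
priority (promoter first, intergenic as fallback).  The promoter is the
strand-aware window from 1 kb upstream to 100 bp downstream of the TSS.
Densities are sites per 10 kb of the merged (same-class) element track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import empty_intervals, merge_intervals, subtract_intervals, total_length

DEFAULT_PRIORITY = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")


@dataclass
class GeneModelSet:
    """Gene models plus derived, merged element tracks."""

    genes: pd.DataFrame
    chrom_sizes: dict[str, int]
    tracks: dict[str, pd.DataFrame]
    priority: tuple[str, ...] = DEFAULT_PRIORITY

    def merged_length(self, element: str) -> int:
        if element == "intergenic":
            genic = pd.concat([self.tracks[c] for c in self.tracks], ignore_index=True)
            return sum(self.chrom_sizes.values()) - total_length(genic)
        return total_length(self.tracks[element])


def _parse_exons(g: pd.Series) -> list[tuple[int, int]]:
    ss = [int(x) for x in str(g["exon_starts"]).split(",") if x != ""]
    ee = [int(x) for x in str(g["exon_ends"]).split(",") if x != ""]
    return list(zip(ss, ee))


def build_gene_model_set(genes: pd.DataFrame, chrom_sizes: Mapping[str, int],
                         promoter_upstream: int = 1000, promoter_downstream: int = 100,
                         priority: tuple[str, ...] = DEFAULT_PRIORITY) -> GeneModelSet:
    """Derive promoter/UTR/exon/intron tracks from gene models.

    Expects columns gene_id, chrom, strand, tx_start, tx_end, cds_start,
    cds_end, exon_starts, exon_ends (comma-separated absolute coordinates);
    ``tss`` is taken from the frame when present, else from the strand.
    """
    rows: dict[str, list[tuple]] = {c: [] for c in ("promoter", "utr5", "utr3", "exon", "intron")}
    for _, g in genes.iterrows():
        chrom = g["chrom"]
        size = chrom_sizes[chrom]
        strand = g["strand"]
        tss = int(g["tss"]) if "tss" in g and not pd.isna(g.get("tss")) else (
            int(g["tx_start"]) if strand == "+" else int(g["tx_end"]))
        if strand == "+":
            p0, p1 = tss - promoter_upstream, tss + promoter_downstream
        else:
            p0, p1 = tss - promoter_downstream, tss + promoter_upstream
        rows["promoter"].append((chrom, max(0, p0), min(size, p1)))
        exons = _parse_exons(g)
        cds0, cds1 = int(g["cds_start"]), int(g["cds_end"])
        for s, e in exons:
            # split each exon into 5'UTR / CDS / 3'UTR parts
            left = (s, min(e, cds0))
            mid = (max(s, cds0), min(e, cds1))
            right = (max(s, cds1), e)
            left_cls = "utr5" if strand == "+" else "utr3"
            right_cls = "utr3" if strand == "+" else "utr5"
            if left[1] > left[0]:
                rows[left_cls].append((chrom, left[0], left[1]))
            if mid[1] > mid[0]:
                rows["exon"].append((chrom, mid[0], mid[1]))
            if right[1] > right[0]:
                rows[right_cls].append((chrom, right[0], right[1]))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1:
                rows["intron"].append((chrom, e1, s2))
    tracks = {}
    for cls, rr in rows.items():
        df = pd.DataFrame(rr, columns=["chrom", "start", "end"]) if rr else empty_intervals()
        tracks[cls] = merge_intervals(df) if len(df) else df
    return GeneModelSet(genes=genes, chrom_sizes=dict(chrom_sizes), tracks=tracks,
                        priority=priority)


def annotate_sites(sites: pd.DataFrame, models: GeneModelSet
                   ) -> tuple[pd.Series, dict[str, int]]:
    """Label each site by the element class of its midpoint.

    Labels are exhaustive and exclusive: the first class in the priority
    order whose merged track covers the midpoint wins; ``intergenic`` is the
    fallback.  A site outside the genome raises.
    """
    labels = np.full(len(sites), "intergenic", dtype=object)
    mids = (sites["start"].to_numpy(np.int64) + sites["end"].to_numpy(np.int64)) // 2
    chroms = sites["chrom"].to_numpy()
    for i, (c, m) in enumerate(zip(chroms, mids)):
        if c not in models.chrom_sizes or not (0 <= m < models.chrom_sizes[c]):
            raise ValueError(f"site midpoint {c}:{m} outside the genome")
    for cls in models.priority:
        if cls == "intergenic":
            continue
        track = models.tracks[cls]
        by_chrom = {c: sub for c, sub in track.groupby("chrom", sort=False)}
        for c, sub in by_chrom.items():
            sel = (chroms == c) & (labels == "intergenic")
            if not sel.any():
                continue
            ts = sub["start"].to_numpy(np.int64)
            te = sub["end"].to_numpy(np.int64)
            m = mids[sel]
            j = np.searchsorted(ts, m, side="right") - 1
            jc = np.maximum(j, 0)
            inside = (j >= 0) & (m < te[jc])
            tmp = labels[sel]
            tmp[inside] = cls
            labels[sel] = tmp
    # priority among the non-fallback classes: handled by first-hit order above
    out = pd.Series(labels, index=sites.index, name="element")
    counts = {cls: int((out == cls).sum()) for cls in models.priority}
    return out, counts


def feature_density(sites: pd.DataFrame, models: GeneModelSet) -> dict[str, float]:
    """TFS density per class, in sites per 10 kb of merged element track."""
    _, counts = annotate_sites(sites, models)
    out = {}
    for cls in models.priority:
        length = models.merged_length(cls)
        if length <= 0:
            warnings.warn(f"element class {cls!r} has zero merged length; omitted",
                          stacklevel=2)
            continue
        out[cls] = counts[cls] / length * 1e4
    return out
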