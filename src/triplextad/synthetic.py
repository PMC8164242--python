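"""Seeded synthetic genomes with planted triplex structure.

The generator emulates the statistical shape of the real analysis inputs so
that every downstream stage is testable offline:

* a multi-chromosome random genome carrying **polypurine tracts** (triplex
  target sites, TTSs) planted inside TADs at ``tts_enrichment_factor`` times
  the outside density.  Tracts are noisy copies of a small pool of *tract
  families* so that one lncRNA domain can bind many genomic sites, as real
  triplex-forming lncRNAs do;
* **TADs** packed without overlap to a configurable genome coverage, with
  1-bp edge calls expanded to ``2 × boundary_flank`` boundary intervals and a
  subset of boundaries marked as loop anchors;
* **lncRNAs** carrying 0–3 planted triplex-forming domains (TFDs): each TFD
  is the Hoogsteen third-strand read-out of one tract family under one motif
  code, embedded in otherwise random transcript sequence; optional second
  isoforms drop one TFD;
* a **TPM matrix** with cell-line-specific block structure;
* boundary-enriched **CTCF sites** and non-overlapping **gene models** with
  promoter/UTR/exon/intron structure.

Every generator is a pure function of the configuration; all randomness
flows from ``SyntheticConfig.seed`` through named child streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as tio
from .intervals import empty_intervals, merge_intervals, subtract_intervals, total_length
from .triplex import MOTIF_CODES

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: fraction of lncRNAs with 0/1/2/3 TFDs; proportions follow the observed
#: split 1110 : 541 : 221 : 82 (domain counts above 3 folded out).
DEFAULT_TFD_COUNT_DIST = (0.568, 0.277, 0.113, 0.042)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study system (rates in events per Mb)."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 500_000
    n_tads: int = 30
    tad_length_range: tuple[int, int] = (10_000, 16_000)
    tad_coverage: float | None = None      # overrides n_tads when set
    boundary_flank: int = 10_000
    anchor_fraction: float = 0.5
    tts_rate_background: float = 150.0     # planted tracts per Mb outside TADs
    tts_enrichment_factor: float = 3.0     # in-TAD / out-of-TAD tract density
    n_tract_families: int = 6
    tract_mutation_rate: float = 0.02
    n_lncrnas: int = 100
    lncrna_length_range: tuple[int, int] = (500, 1500)
    tfd_count_dist: tuple[float, ...] = DEFAULT_TFD_COUNT_DIST
    tfd_length_range: tuple[int, int] = (20, 30)
    n_informative: int | None = None       # force exactly this many lncRNAs to have ≥1 TFD
    isoform_prob: float = 0.3
    n_cell_lines: int = 7
    tpm_threshold: float = 5.0
    n_nonspecific_clusters: int = 0
    tpm_noise_sd: float = 0.25             # sd on the natural-log scale
    ctcf_boundary_density: float = 60.0
    ctcf_background_density: float = 15.0
    ctcf_site_length: int = 10
    n_genes: int = 40
    gc_content: float = 0.5
    tad_jitter: int = 3000                 # per-cell-line TAD edge jitter

    def __post_init__(self):
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValueError("n_chroms and chrom_length must be positive")
        lo, hi = self.tad_length_range
        if not (0 < lo <= hi):
            raise ValueError("tad_length_range must be positive and ordered")
        if hi + 2 * self.boundary_flank > self.chrom_length:
            raise ValueError("tad_length_range does not fit within chrom_length")
        if abs(sum(self.tfd_count_dist) - 1.0) > 1e-6:
            raise ValueError("tfd_count_dist must sum to 1")
        if self.tts_enrichment_factor < 0:
            raise ValueError("tts_enrichment_factor must be ≥ 0")
        lo, hi = self.tfd_length_range
        if not (0 < lo <= hi):
            raise ValueError("tfd_length_range must be positive and ordered")
        if not (0 <= self.gc_content <= 1):
            raise ValueError("gc_content must be in [0, 1]")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}

    def rng(self, stream: str) -> np.random.Generator:
        """Named child RNG stream, a pure function of (seed, stream)."""
        h = int.from_bytes(stream.encode(), "big") % (2**32)
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(h,)))


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    tts: pd.DataFrame                      # chrom,start,end,strand,family,in_tad
    tfds: pd.DataFrame                     # lncrna_id,isoform_id,rna_start,rna_end,family,motif
    informative_ids: list[str]
    cluster_labels: pd.Series              # lncRNA gene id → planted cluster
    ctcf_classes: pd.Series                # site index → "boundary"/"background"
    realized_enrichment: float
    tract_families: list[str]


@dataclass
class SyntheticBundle:
    """One synthetic study system (genome shared across cell lines)."""

    config: SyntheticConfig
    genome: dict[str, str]
    tads: pd.DataFrame
    boundaries: pd.DataFrame
    anchors: pd.DataFrame
    tad_sets: dict[str, pd.DataFrame]      # per cell line
    boundary_sets: dict[str, pd.DataFrame]
    anchor_sets: dict[str, pd.DataFrame]
    ctcf_sites: pd.DataFrame
    gene_models: pd.DataFrame
    lncrnas: dict[str, str]                # isoform id → sequence
    gene_of: dict[str, str]                # isoform id → lncRNA gene id
    tpm: pd.DataFrame
    truth: SyntheticTruth

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


# ---------------------------------------------------------------------------
# regions


def _pack_tads(rng: np.random.Generator, chrom: str, k: int, cfg: SyntheticConfig) -> list[tuple]:
    lo, hi = cfg.tad_length_range
    lengths = rng.integers(lo, hi + 1, size=k)
    margin = cfg.boundary_flank          # keep boundary intervals clippable-free
    min_gap = 200
    avail = cfg.chrom_length - 2 * margin
    free = avail - int(lengths.sum()) - min_gap * (k + 1)
    if free < 0:
        raise ValueError(
            f"cannot pack {k} TADs of {lo}-{hi} bp into chromosome of "
            f"{cfg.chrom_length} bp (n_tads/tad_length_range too large)")
    gaps = min_gap + np.floor(free * rng.dirichlet(np.ones(k + 1))).astype(int)
    out = []
    pos = margin
    for i in range(k):
        pos += int(gaps[i])
        out.append((chrom, pos, pos + int(lengths[i])))
        pos += int(lengths[i])
    return out


def gen_regions(cfg: SyntheticConfig, rng: np.random.Generator | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Non-overlapping TADs, expanded boundaries, and loop anchors.

    Boundary points are each TAD edge, expanded ±``boundary_flank`` into
    intervals of exactly ``2 × boundary_flank`` bp.
    """
    rng = rng if rng is not None else cfg.rng("regions")
    n = cfg.n_tads
    if cfg.tad_coverage is not None:
        mean_len = sum(cfg.tad_length_range) / 2
        n = int(round(cfg.tad_coverage * cfg.n_chroms * cfg.chrom_length / mean_len))
    per_chrom = np.full(cfg.n_chroms, n // cfg.n_chroms)
    per_chrom[: n % cfg.n_chroms] += 1
    rows = []
    for chrom, k in zip(cfg.chrom_names(), per_chrom):
        if k:
            rows.extend(_pack_tads(rng, chrom, int(k), cfg))
    tads = (pd.DataFrame(rows, columns=["chrom", "start", "end"])
            if rows else empty_intervals())
    boundaries, anchors = expand_boundaries(tads, cfg.boundary_flank, cfg.anchor_fraction, rng)
    return tads, boundaries, anchors


def expand_boundaries(tads: pd.DataFrame, flank: int, anchor_fraction: float,
                      rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    points = []
    for _, t in tads.iterrows():
        points.append((t["chrom"], int(t["start"])))
        points.append((t["chrom"], int(t["end"])))
    points = sorted(set(points))
    rows = [(c, p - flank, p + flank) for c, p in points]
    boundaries = (pd.DataFrame(rows, columns=["chrom", "start", "end"])
                  if rows else empty_intervals())
    if points:
        take = rng.random(len(points)) < anchor_fraction
        arows = [r for r, t in zip(rows, take) if t]
    else:
        arows = []
    anchors = (pd.DataFrame(arows, columns=["chrom", "start", "end"])
               if arows else empty_intervals())
    return boundaries, anchors


# ---------------------------------------------------------------------------
# genome with planted tracts


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _complement_bytes(arr: np.ndarray) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        table[a] = b
    return table[arr][::-1]


def _gen_tract_families(cfg: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    lo, hi = cfg.tfd_length_range
    fams = []
    for _ in range(cfg.n_tract_families):
        n = int(rng.integers(lo, hi + 1))
        fams.append("".join("AG"[b] for b in rng.integers(0, 2, size=n)))
    return fams


def _place_tracts(rng, allowed: pd.DataFrame, n: int, families: list[str],
                  cfg: SyntheticConfig, occupied: dict[str, list[tuple[int, int]]],
                  limiting: str) -> list[tuple]:
    """Place n non-overlapping family copies uniformly within allowed intervals."""
    if n == 0:
        return []
    iv = allowed.reset_index(drop=True)
    rows = []
    max_len = max(len(f) for f in families)
    weights = np.maximum(0, iv["end"] - iv["start"] - max_len + 1).to_numpy(float)
    if weights.sum() <= 0:
        raise ValueError(f"no placeable space for planted tracts ({limiting} too large)")
    cw = np.cumsum(weights / weights.sum())
    for _ in range(n):
        fam_i = int(rng.integers(len(families)))
        fam = families[fam_i]
        placed = False
        for _try in range(2000):
            j = int(np.searchsorted(cw, rng.random()))
            lo, hi = int(iv.loc[j, "start"]), int(iv.loc[j, "end"]) - len(fam)
            if hi < lo:
                continue
            s = int(rng.integers(lo, hi + 1))
            e = s + len(fam)
            chrom = iv.loc[j, "chrom"]
            occ = occupied.setdefault(chrom, [])
            if any(s < oe and e > os_ for os_, oe in occ):
                continue
            occ.append((s, e))
            rows.append((chrom, s, e, "+-"[int(rng.integers(2))], fam_i))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"planted tract count exceeds placeable capacity ({limiting} too large)")
    return rows


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        arr[hit] = _BASES[rng.integers(0, 4, size=int(hit.sum()))]
    return arr.tobytes().decode()


def gen_genome(cfg: SyntheticConfig, tads: pd.DataFrame,
               rng: np.random.Generator | None = None
               ) -> tuple[dict[str, str], pd.DataFrame, list[str]]:
    """Random genome with polypurine tracts planted in/out of TADs.

    Tract counts are Poisson with densities ``tts_rate_background`` outside
    TADs and ``tts_rate_background × tts_enrichment_factor`` inside; each
    tract is a lightly mutated copy of one tract family, written on a
    uniformly chosen strand (coordinates always forward-strand).
    """
    rng = rng if rng is not None else cfg.rng("genome")
    sizes = cfg.chrom_sizes()
    arrays = {c: _random_seq(rng, n, cfg.gc_content) for c, n in sizes.items()}
    families = _gen_tract_families(cfg, rng)

    genome_df = pd.DataFrame(
        {"chrom": list(sizes), "start": 0, "end": [sizes[c] for c in sizes]})
    inside = merge_intervals(tads) if len(tads) else empty_intervals()
    outside = subtract_intervals(genome_df, inside)
    in_bp, out_bp = total_length(inside), total_length(outside)

    n_in = int(rng.poisson(cfg.tts_rate_background * cfg.tts_enrichment_factor * in_bp / 1e6))
    n_out = int(rng.poisson(cfg.tts_rate_background * out_bp / 1e6))

    occupied: dict[str, list[tuple[int, int]]] = {}
    rows = []
    if n_in:
        if in_bp == 0:
            raise ValueError("in-TAD tracts requested but no TAD space (n_tads=0)")
        rows += [r + (True,) for r in _place_tracts(
            rng, inside, n_in, families, cfg, occupied,
            "tts_rate_background × tts_enrichment_factor")]
    if n_out:
        rows += [r + (False,) for r in _place_tracts(
            rng, outside, n_out, families, cfg, occupied, "tts_rate_background")]

    for chrom, s, e, strand, fam_i, _in in rows:
        copy = _mutate(families[fam_i], rng, cfg.tract_mutation_rate)
        b = np.frombuffer(copy.encode(), dtype=np.uint8)
        if strand == "-":
            b = _complement_bytes(b)
        arrays[chrom][s:e] = b

    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "family", "in_tad"])
    truth = truth.sort_values(["chrom", "start"]).reset_index(drop=True)
    genome = {c: a.tobytes().decode() for c, a in arrays.items()}
    return genome, truth, families


def realized_enrichment_factor(truth: pd.DataFrame, tads: pd.DataFrame,
                               chrom_sizes: Mapping[str, int]) -> float:
    """In-TAD over out-of-TAD planted tract density (per-bp counts)."""
    in_bp = total_length(tads)
    out_bp = sum(chrom_sizes.values()) - in_bp
    n_in = int(truth["in_tad"].sum())
    n_out = int((~truth["in_tad"]).sum())
    if n_out == 0 or out_bp == 0 or in_bp == 0:
        return np.inf if n_in else np.nan
    return (n_in / in_bp) / (n_out / out_bp)


# ---------------------------------------------------------------------------
# lncRNAs with planted TFDs

#: purine-strand base → third-strand RNA base, per motif code
_INVERSE_CODE = {
    "pyrimidine": {"A": "T", "G": "C"},
    "purine": {"A": "A", "G": "G"},
    "mixed": {"A": "T", "G": "G"},
}


def tfo_for_tract(tract_purine_seq: str, motif: str) -> str:
    """The RNA third strand that reads *tract_purine_seq* perfectly under *motif*."""
    parallel, _ = MOTIF_CODES[motif]
    rna = "".join(_INVERSE_CODE[motif][b] for b in tract_purine_seq)
    return rna if parallel else rna[::-1]


def gen_lncrnas(cfg: SyntheticConfig, families: list[str], tts_truth: pd.DataFrame,
                rng: np.random.Generator | None = None
                ) -> tuple[dict[str, str], dict[str, str], pd.DataFrame, list[str]]:
    """Transcript sequences with 0–3 planted TFDs.

    Returns (isoform sequences, isoform → gene map, TFD truth, informative gene ids).
    """
    rng = rng if rng is not None else cfg.rng("lncrnas")
    dist = np.asarray(cfg.tfd_count_dist, dtype=float)
    if cfg.n_informative is None:
        ks = rng.choice(len(dist), size=cfg.n_lncrnas, p=dist)
    else:
        if cfg.n_informative > cfg.n_lncrnas:
            raise ValueError("n_informative exceeds n_lncrnas")
        pos = dist[1:] / dist[1:].sum()
        ks = np.zeros(cfg.n_lncrnas, dtype=int)
        ks[: cfg.n_informative] = rng.choice(np.arange(1, len(dist)), size=cfg.n_informative, p=pos)
    if ks.sum() > 0 and len(tts_truth) == 0:
        raise ValueError("lncRNAs request TFDs but no tracts were planted")
    lo, hi = cfg.lncrna_length_range
    if hi < cfg.tfd_length_range[1] + 20:
        raise ValueError("lncrna_length_range too short to host a TFD")
    planted_fams = sorted(tts_truth["family"].unique()) if len(tts_truth) else []

    seqs: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    truth_rows = []
    informative = []
    motifs = list(MOTIF_CODES)
    for i in range(cfg.n_lncrnas):
        gene = f"LNC{i:04d}"
        k = int(ks[i])
        length = int(rng.integers(lo, hi + 1))
        backbone = _random_seq(rng, length, cfg.gc_content).tobytes().decode()
        placements = []
        arr = list(backbone)
        for _ in range(k):
            if cfg.n_informative is not None and planted_fams:
                # controlled design: informative lncRNA i reads family i mod F,
                # so features are minimally redundant for recovery experiments
                fam_i = int(planted_fams[i % len(planted_fams)])
            else:
                fam_i = int(planted_fams[int(rng.integers(len(planted_fams)))])
            motif = motifs[int(rng.integers(len(motifs)))]
            tfo = tfo_for_tract(families[fam_i], motif)
            for _try in range(200):
                s = int(rng.integers(0, length - len(tfo) + 1))
                e = s + len(tfo)
                if all(e + 5 <= ps or s >= pe + 5 for ps, pe in [(p[0], p[1]) for p in placements]):
                    placements.append((s, e, fam_i, motif))
                    arr[s:e] = tfo
                    break
        iso1 = f"{gene}.1"
        seqs[iso1] = "".join(arr)
        gene_of[iso1] = gene
        for s, e, fam_i, motif in placements:
            truth_rows.append((gene, iso1, s, e, fam_i, motif))
        if placements:
            informative.append(gene)
            if rng.random() < cfg.isoform_prob:
                # second isoform lacking the last planted TFD
                arr2 = list("".join(arr))
                s, e, *_ = placements[-1]
                arr2[s:e] = _random_seq(rng, e - s, cfg.gc_content).tobytes().decode()
                iso2 = f"{gene}.2"
                seqs[iso2] = "".join(arr2)
                gene_of[iso2] = gene
                for s, e, fam_i, motif in placements[:-1]:
                    truth_rows.append((gene, iso2, s, e, fam_i, motif))
        elif rng.random() < cfg.isoform_prob:
            iso2 = f"{gene}.2"
            seqs[iso2] = _random_seq(rng, length, cfg.gc_content).tobytes().decode()
            gene_of[iso2] = gene

    tfds = pd.DataFrame(
        truth_rows,
        columns=["lncrna_id", "isoform_id", "rna_start", "rna_end", "family", "motif"])
    return seqs, gene_of, tfds, informative


# ---------------------------------------------------------------------------
# expression


def gen_expression(cfg: SyntheticConfig, lnc_ids: list[str],
                   rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Block-structured TPM matrix: each cluster is high in one cell line.

    Optional nonspecific clusters are uniformly high / uniformly moderate in
    every line.  Noise is lognormal with sd ``tpm_noise_sd`` on the log scale;
    sd 0 reproduces the exact block matrix.
    """
    if cfg.n_cell_lines < 2:
        raise ValueError("n_cell_lines must be ≥ 2")
    rng = rng if rng is not None else cfg.rng("expression")
    lines = [f"CL{i + 1}" for i in range(cfg.n_cell_lines)]
    n_clusters = cfg.n_cell_lines + cfg.n_nonspecific_clusters
    labels = pd.Series([i % n_clusters for i in range(len(lnc_ids))], index=lnc_ids, name="cluster")
    log_hi, log_lo = np.log(50.0), np.log(0.5)
    mu = np.full((len(lnc_ids), cfg.n_cell_lines), log_lo)
    for i, g in enumerate(lnc_ids):
        c = labels.iloc[i]
        if c < cfg.n_cell_lines:
            mu[i, c] = log_hi
        elif (c - cfg.n_cell_lines) % 2 == 0:
            mu[i, :] = np.log(30.0)       # nonspecific high
        else:
            mu[i, :] = np.log(2.0)        # nonspecific moderate
    noise = rng.normal(0.0, cfg.tpm_noise_sd, size=mu.shape) if cfg.tpm_noise_sd > 0 else 0.0
    tpm = pd.DataFrame(np.exp(mu + noise), index=lnc_ids, columns=lines)
    tpm.index.name = "lncrna_id"
    return tpm, labels


# ---------------------------------------------------------------------------
# annotation tracks


def _place_nonoverlapping(rng, allowed: pd.DataFrame, n: int, length: int,
                          occupied: dict[str, list[tuple[int, int]]], what: str) -> list[tuple]:
    iv = allowed.reset_index(drop=True)
    weights = np.maximum(0, iv["end"] - iv["start"] - length + 1).to_numpy(float)
    if n and weights.sum() <= 0:
        raise ValueError(f"no space to place {what}")
    cw = np.cumsum(weights / weights.sum()) if weights.sum() > 0 else None
    rows = []
    for _ in range(n):
        for _try in range(2000):
            j = int(np.searchsorted(cw, rng.random()))
            lo, hi = int(iv.loc[j, "start"]), int(iv.loc[j, "end"]) - length
            if hi < lo:
                continue
            s = int(rng.integers(lo, hi + 1))
            chrom = iv.loc[j, "chrom"]
            occ = occupied.setdefault(chrom, [])
            if any(s < oe and s + length > os_ for os_, oe in occ):
                continue
            occ.append((s, s + length))
            rows.append((chrom, s, s + length))
            break
        else:
            raise ValueError(f"{what} density exceeds placeable capacity")
    return rows


def gen_annotation_tracks(cfg: SyntheticConfig, boundaries: pd.DataFrame,
                          rng: np.random.Generator | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Boundary-enriched CTCF sites and non-overlapping gene models."""
    rng = rng if rng is not None else cfg.rng("annotation")
    sizes = cfg.chrom_sizes()
    genome_df = pd.DataFrame({"chrom": list(sizes), "start": 0, "end": [sizes[c] for c in sizes]})
    bnd = merge_intervals(boundaries) if len(boundaries) else empty_intervals()
    bg = subtract_intervals(genome_df, bnd) if len(bnd) else genome_df

    occupied: dict[str, list[tuple[int, int]]] = {}
    n_b = int(rng.poisson(cfg.ctcf_boundary_density * total_length(bnd) / 1e6)) if len(bnd) else 0
    n_g = int(rng.poisson(cfg.ctcf_background_density * total_length(bg) / 1e6))
    rows = _place_nonoverlapping(rng, bnd, n_b, cfg.ctcf_site_length, occupied, "boundary CTCF")
    classes = ["boundary"] * len(rows)
    rows += _place_nonoverlapping(rng, bg, n_g, cfg.ctcf_site_length, occupied, "background CTCF")
    classes += ["background"] * (len(rows) - len(classes))
    ctcf = (pd.DataFrame(rows, columns=["chrom", "start", "end"])
            if rows else empty_intervals())
    order = ctcf.sort_values(["chrom", "start"]).index if len(ctcf) else []
    ctcf_classes = pd.Series([classes[i] for i in order], name="ctcf_class").reset_index(drop=True)
    ctcf = ctcf.loc[order].reset_index(drop=True) if len(ctcf) else ctcf

    genes = _gen_gene_models(cfg, rng)
    return ctcf, genes, ctcf_classes


def _gen_gene_models(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    sizes = cfg.chrom_sizes()
    occupied: dict[str, list[tuple[int, int]]] = {}
    rows = []
    chroms = cfg.chrom_names()
    for gi in range(cfg.n_genes):
        for _try in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(3000, 8001))
            margin = 1500                   # promoter head-room
            s = int(rng.integers(margin, sizes[chrom] - length - margin + 1))
            e = s + length
            occ = occupied.setdefault(chrom, [])
            if any(s - margin < oe and e + margin > os_ for os_, oe in occ):
                continue
            occ.append((s, e))
            break
        else:
            raise ValueError("n_genes exceeds placeable capacity")
        strand = "+-"[int(rng.integers(2))]
        n_ex = int(rng.integers(2, 6))
        ex_lens = rng.integers(150, 401, size=n_ex)
        while ex_lens.sum() > length - 100 * (n_ex - 1):
            n_ex -= 1
            ex_lens = ex_lens[:n_ex]
        free = length - int(ex_lens.sum())
        cuts = np.sort(rng.random(n_ex - 1)) if n_ex > 1 else np.array([])
        gap_frac = np.diff(np.concatenate([[0.0], cuts, [1.0]])) if n_ex > 1 else np.array([1.0])
        # n_ex exons separated by n_ex-1 introns spanning [s, e)
        intron_total = free
        introns = np.floor(intron_total * gap_frac[:-1]).astype(int) if n_ex > 1 else np.array([], int)
        ex_s, pos = [], s
        for j in range(n_ex):
            ex_s.append(pos)
            pos += int(ex_lens[j])
            if j < n_ex - 1:
                pos += max(50, int(introns[j]))
        ex_e = [a + int(l) for a, l in zip(ex_s, ex_lens)]
        tx_end = ex_e[-1]
        cds_start = ex_s[0] + min(80, int(ex_lens[0]) // 2)
        cds_end = ex_e[-1] - min(80, int(ex_lens[-1]) // 2)
        tss = s if strand == "+" else tx_end
        rows.append({
            "gene_id": f"GENE{gi:03d}", "chrom": chrom, "strand": strand,
            "tx_start": s, "tx_end": tx_end, "tss": tss,
            "cds_start": cds_start, "cds_end": cds_end,
            "exon_starts": ",".join(map(str, ex_s)),
            "exon_ends": ",".join(map(str, ex_e)),
        })
    return pd.DataFrame(rows).sort_values(["chrom", "tx_start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# full bundle


def _jitter_tads(tads: pd.DataFrame, cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """A cell-line variant of the canonical TAD set: edges jittered, a few dropped."""
    rows = []
    for chrom, sub in tads.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        prev_end = cfg.boundary_flank
        for _, t in sub.iterrows():
            if rng.random() < 0.1:        # cell-line-specific domain loss
                continue
            j1 = int(rng.integers(-cfg.tad_jitter, cfg.tad_jitter + 1))
            j2 = int(rng.integers(-cfg.tad_jitter, cfg.tad_jitter + 1))
            s = max(prev_end + 1, int(t["start"]) + j1)
            e = min(cfg.chrom_length - cfg.boundary_flank, int(t["end"]) + j2)
            if e - s >= cfg.tad_length_range[0] // 2:
                rows.append((chrom, s, e))
                prev_end = e
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]) if rows else empty_intervals()


def simulate(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate one complete synthetic study system from a config."""
    tads, boundaries, anchors = gen_regions(cfg)
    genome, tts_truth, families = gen_genome(cfg, tads)
    seqs, gene_of, tfd_truth, informative = gen_lncrnas(cfg, families, tts_truth)
    lnc_ids = sorted({g for g in gene_of.values()})
    tpm, cluster_labels = gen_expression(cfg, lnc_ids)
    ctcf, genes, ctcf_classes = gen_annotation_tracks(cfg, boundaries)

    tad_sets, boundary_sets, anchor_sets = {}, {}, {}
    lines = list(tpm.columns)
    for li, line in enumerate(lines):
        if li == 0:
            t = tads
        else:
            t = _jitter_tads(tads, cfg, cfg.rng(f"tads-{line}"))
        b, a = expand_boundaries(t, cfg.boundary_flank, cfg.anchor_fraction,
                                 cfg.rng(f"anchors-{line}"))
        tad_sets[line], boundary_sets[line], anchor_sets[line] = t, b, a

    truth = SyntheticTruth(
        tts=tts_truth, tfds=tfd_truth, informative_ids=informative,
        cluster_labels=cluster_labels, ctcf_classes=ctcf_classes,
        realized_enrichment=realized_enrichment_factor(tts_truth, tads, cfg.chrom_sizes()),
        tract_families=families,
    )
    return SyntheticBundle(
        config=cfg, genome=genome, tads=tads, boundaries=boundaries, anchors=anchors,
        tad_sets=tad_sets, boundary_sets=boundary_sets, anchor_sets=anchor_sets,
        ctcf_sites=ctcf, gene_models=genes, lncrnas=seqs, gene_of=gene_of,
        tpm=tpm, truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write a bundle as FASTA + BED + TSV files (plus truth tables)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_fasta(bundle.genome, out / "genome.fa")
    tio.write_fasta(bundle.lncrnas, out / "lncrnas.fa")
    for name, df in [("tads", bundle.tads), ("boundaries", bundle.boundaries),
                     ("anchors", bundle.anchors), ("ctcf", bundle.ctcf_sites)]:
        tio.write_bed(df, out / f"{name}.bed")
    for line, df in bundle.tad_sets.items():
        tio.write_bed(df, out / f"tads_{line}.bed")
    tio.write_tsv(bundle.tpm.reset_index(), out / "tpm.tsv")
    tio.write_gene_models_bed12(bundle.gene_models, out / "genes.bed12")
    tio.write_tsv(bundle.truth.tts, out / "truth_tts.tsv")
    tio.write_tsv(bundle.truth.tfds, out / "truth_tfds.tsv")
    tio.write_tsv(pd.DataFrame({"isoform_id": list(bundle.gene_of),
                                "lncrna_id": list(bundle.gene_of.values())}),
                  out / "isoforms.tsv")
    cfg_dict = dataclasses.asdict(bundle.config)
    import yaml
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh)
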