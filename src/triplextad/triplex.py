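"""Prediction of lncRNA:DNA triplex-forming sites (TFSs).

The predictor is a deterministic, documented motif-code model of third-strand
(Hoogsteen) binding:

1. **Triplex target sites (TTSs).**  Duplex DNA accommodates a third strand
   on polypurine tracts.  ``find_tts`` scans both strands for maximal runs of
   windows (window width = ``min_length``) whose purine fraction reaches
   ``min_purine_fraction``; each merged run is one candidate tract, reported
   on forward coordinates with the strand carrying the purines.

2. **Motif codes.**  The RNA third strand reads the purine strand of the
   duplex through one of three canonical binding codes:

   ========== ============ =======================================
   motif      orientation  RNA base → purine-strand base it reads
   ========== ============ =======================================
   pyrimidine parallel     U/T → A,  C → G
   purine     antiparallel A → A,  G → G
   mixed      antiparallel G → G,  U/T → A
   ========== ============ =======================================

3. **Site calling.**  For every (transcript, tract, motif) pair, every
   ungapped alignment window of length ≥ ``min_length`` whose mismatch count
   is within ``floor(max_error_rate × length)`` is a candidate site; on each
   alignment diagonal only containment-maximal windows are reported (no
   sub-site enumeration).  RNA bases outside the motif alphabet and DNA ``N``
   bases always count as mismatches.

RNA-side footprints of the sites of one lncRNA, merged into maximal disjoint
intervals, are its triplex-forming domains (TFDs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

# base encoding: A=0 C=1 G=2 T/U=3, anything else (incl. N) = 4
_ENC = np.full(256, 4, dtype=np.int8)
for b, v in zip(b"ACGTU", [0, 1, 2, 3, 3]):
    _ENC[b] = v
    _ENC[b + 32] = v

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N

SITE_COLUMNS = ["lncrna_id", "isoform_id", "chrom", "start", "end", "tts_strand",
                "rna_start", "rna_end", "motif", "mismatches"]

#: motif → (is_parallel, {rna_code: purine_strand_code})
MOTIF_CODES: dict[str, tuple[bool, dict[int, int]]] = {
    "pyrimidine": (True, {3: 0, 1: 2}),   # U/T reads A, C reads G
    "purine": (False, {0: 0, 2: 2}),      # A reads A, G reads G
    "mixed": (False, {2: 2, 3: 0}),       # G reads G, U/T reads A
}


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    table = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(table)[::-1]


def mismatch_budget(length: int, rate: float) -> int:
    """floor(rate × length), guarded against binary-float underestimation."""
    return int(np.floor(rate * length + 1e-9))


@dataclass(frozen=True)
class TriplexParams:
    """Tunable knobs of the triplex site predictor."""

    min_length: int = 20
    max_error_rate: float = 0.05
    motifs: tuple[str, ...] = ("pyrimidine", "purine", "mixed")
    min_purine_fraction: float = 0.9
    max_sites_per_lncrna: int | None = None

    def __post_init__(self):
        if self.min_length < 10:
            raise ValueError("min_length must be ≥ 10")
        if not (0 <= self.max_error_rate < 0.5):
            raise ValueError("max_error_rate must be in [0, 0.5)")
        unknown = set(self.motifs) - set(MOTIF_CODES)
        if unknown:
            raise ValueError(f"unknown motifs {sorted(unknown)}")


@dataclass(frozen=True)
class TriplexDomain:
    lncrna_id: str
    rna_start: int
    rna_end: int
    n_supporting_sites: int

    @property
    def length(self) -> int:
        return self.rna_end - self.rna_start


# ---------------------------------------------------------------------------
# TTS detection


def _qualifying_window_runs(count_ok: np.ndarray, window: int, min_ok: float) -> list[tuple[int, int]]:
    """Merge sliding windows with ≥ min_ok qualifying bases into maximal runs."""
    n = count_ok.size
    if n < window:
        return []
    csum = np.concatenate([[0], np.cumsum(count_ok)])
    wsum = csum[window:] - csum[:-window]          # count in window starting at i
    good = wsum >= min_ok - 1e-9
    if not good.any():
        return []
    idx = np.flatnonzero(good)
    runs = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i > prev + window:                      # windows no longer overlap/abut
            runs.append((run_start, prev + window))
            run_start = i
        prev = i
    runs.append((run_start, prev + window))
    return runs


def find_tts(dna_sequence: str, params: TriplexParams | None = None) -> list[tuple[int, int, str]]:
    """Candidate triplex target tracts of one sequence.

    Returns ``(start, end, strand)`` tuples in forward 0-based half-open
    coordinates; ``strand`` is the strand carrying the purine tract.
    """
    params = params or TriplexParams()
    if not dna_sequence:
        return []
    enc = encode(dna_sequence)
    purine = ((enc == 0) | (enc == 2)).astype(np.int64)
    pyrimidine = ((enc == 1) | (enc == 3)).astype(np.int64)
    need = params.min_purine_fraction * params.min_length
    tracts = [(s, e, "+") for s, e in _qualifying_window_runs(purine, params.min_length, need)]
    tracts += [(s, e, "-") for s, e in _qualifying_window_runs(pyrimidine, params.min_length, need)]
    tracts.sort()
    return tracts


# ---------------------------------------------------------------------------
# site search


def _mapped_rna(enc_rna: np.ndarray, motif: str) -> np.ndarray:
    """RNA encoded as the purine-strand base each position reads; -2 = unmappable."""
    _, code = MOTIF_CODES[motif]
    out = np.full(enc_rna.size, -2, dtype=np.int8)
    for rna_code, target in code.items():
        out[enc_rna == rna_code] = target
    return out


def _candidate_segments(mapped: np.ndarray, params: TriplexParams, max_budget: int) -> list[tuple[int, int]]:
    """Maximal RNA stretches that could host a qualifying alignment window.

    A qualifying window of any admissible length carries ≤ ``max_budget``
    mismatches in total, hence every ``min_length`` sub-window has at most
    ``max_budget`` unmappable bases; the union of such sub-windows therefore
    covers every possible site, so matching can be restricted to these runs.
    """
    mappable = (mapped >= 0).astype(np.int64)
    need = params.min_length - max_budget
    return _qualifying_window_runs(mappable, params.min_length, need)


def _maximal_windows_on_diagonal(mism: np.ndarray, params: TriplexParams) -> list[tuple[int, int, int]]:
    """Containment-maximal qualifying windows ``(s, e, n_mismatch)`` on one diagonal."""
    d = mism.size
    W = params.min_length
    if d < W:
        return []
    c = np.concatenate([[0], np.cumsum(mism)])
    s_idx = np.arange(d + 1)
    length = s_idx[None, :] - s_idx[:, None]                 # e - s
    nm = c[None, :] - c[:, None]
    budget = np.floor(params.max_error_rate * length + 1e-9)
    Q = (length >= W) & (nm <= budget)
    any_q = Q.any(axis=1)
    if not any_q.any():
        return []
    emax = np.where(any_q, np.argmax(Q[:, ::-1], axis=1), d + 1)
    emax = np.where(any_q, d - emax, -1)                      # max e with Q[s, e]
    out = []
    running = -1
    for s in range(d + 1):
        e = int(emax[s])
        if e > running:
            out.append((s, e, int(c[e] - c[s])))
            running = e
    return out


def search_triplexes(
    lncrna_sequences: Mapping[str, str],
    genome: Mapping[str, str],
    params: TriplexParams | None = None,
    gene_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Predict all TFSs between a set of transcripts and a genome.

    Parameters
    ----------
    lncrna_sequences
        isoform id → transcript sequence.
    genome
        chromosome name → sequence.
    gene_of
        optional isoform id → lncRNA gene id (defaults to the isoform id).
    """
    params = params or TriplexParams()
    collisions = set(lncrna_sequences) & set(genome)
    if collisions:
        raise ValueError(f"transcript/chromosome id collision: {sorted(collisions)}")
    gene_of = gene_of or {}

    # tract database: (chrom, fwd_start, fwd_end, strand, purine-strand codes)
    tracts = []
    for chrom, seq in genome.items():
        for s, e, strand in find_tts(seq, params):
            sub = seq[s:e] if strand == "+" else revcomp(seq[s:e])
            p = encode(sub).astype(np.int8)
            p[p == 4] = -1                       # N never matches
            p_ind = [(p == v).astype(np.float64) for v in (0, 2)]
            tracts.append((chrom, s, e, strand, p, p_ind))
    max_tract_len = max((t[4].size for t in tracts), default=0)

    rows: list[tuple] = []
    for iso_id, rna in lncrna_sequences.items():
        enc_rna = encode(rna)
        lnc_id = gene_of.get(iso_id, iso_id)
        iso_rows: list[tuple] = []
        for motif in params.motifs:
            parallel, _ = MOTIF_CODES[motif]
            mapped = _mapped_rna(enc_rna, motif)
            oriented = mapped if parallel else mapped[::-1]
            cap = min(max_tract_len, oriented.size)
            if cap < params.min_length:
                continue
            max_budget = mismatch_budget(cap, params.max_error_rate)
            segments = _candidate_segments(oriented, params, max_budget)
            if not segments:
                continue
            seg_pre = []
            for a, b in segments:
                S = oriented[a:b]
                seg_pre.append((a, S, [(S[::-1] == v).astype(np.float64) for v in (0, 2)]))
            for chrom, ts, te, strand, P, p_ind in tracts:
                matches: list[tuple] = []
                for a, S, s_ind in seg_pre:
                    matches += _align_segment(
                        S, P, params,
                        seg_offset=a, rna_len=enc_rna.size, parallel=parallel,
                        s_ind=s_ind, p_ind=p_ind,
                    )
                for rs, re, ps, pe, nm in merge_overlapping_matches(matches):
                    if strand == "+":
                        g0, g1 = ts + ps, ts + pe
                    else:
                        g0, g1 = te - pe, te - ps
                    iso_rows.append((lnc_id, iso_id, chrom, g0, g1, strand,
                                     rs, re, motif, nm))
        if params.max_sites_per_lncrna is not None and len(iso_rows) > params.max_sites_per_lncrna:
            # keep the longest, then fewest-mismatch sites
            iso_rows.sort(key=lambda r: (-(r[4] - r[3]), r[9], r[2], r[3]))
            iso_rows = iso_rows[: params.max_sites_per_lncrna]
        rows += iso_rows

    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if len(df):
        df = df.sort_values(["lncrna_id", "isoform_id", "chrom", "start", "end", "motif"],
                            kind="stable").reset_index(drop=True)
    return df


def merge_overlapping_matches(matches: list[tuple]) -> list[tuple]:
    """Merge tract-overlapping matches of one (lncRNA, tract, motif) group.

    Diagonal-maximal windows that overlap on the tract (e.g. shifted
    alignments of near-homopolymeric sequence) collapse to one site spanning
    the union of their tract and RNA extents; the reported mismatch count is
    the minimum over the merged members.  After merging, the genomic and
    RNA extents of a site may differ in length by the diagonal spread.
    """
    if not matches:
        return []
    matches = sorted(matches, key=lambda m: (m[2], m[3]))       # by tract start/end
    merged: list[list] = []
    for rs, re, ps, pe, nm in matches:
        if merged and ps < merged[-1][3]:
            m = merged[-1]
            m[0], m[1] = min(m[0], rs), max(m[1], re)
            m[3] = max(m[3], pe)
            m[4] = min(m[4], nm)
        else:
            merged.append([rs, re, ps, pe, nm])
    return [tuple(m) for m in merged]


def _align_segment(S: np.ndarray, P: np.ndarray, params: TriplexParams,
                   seg_offset: int, rna_len: int, parallel: bool,
                   s_ind: list[np.ndarray] | None = None,
                   p_ind: list[np.ndarray] | None = None) -> list[tuple]:
    """Maximal qualifying windows of one RNA segment against one tract.

    Returns ``(rna_start, rna_end, p_start, p_end, mismatches)`` with RNA
    coordinates in original transcript orientation and P coordinates on the
    tract's purine strand (5'→3').
    """
    Ls, Lp = S.size, P.size
    if min(Ls, Lp) < params.min_length:
        return []
    # a qualifying window needs ≥ min_length − budget matching positions on
    # its diagonal; per-diagonal match totals come from two cheap convolutions
    need = params.min_length - mismatch_budget(min(Ls, Lp), params.max_error_rate)
    if s_ind is None:
        s_ind = [(S[::-1] == v).astype(np.float64) for v in (0, 2)]
    if p_ind is None:
        p_ind = [(P == v).astype(np.float64) for v in (0, 2)]
    diag_matches = np.convolve(s_ind[0], p_ind[0]) + np.convolve(s_ind[1], p_ind[1])
    candidate_d = np.flatnonzero(diag_matches >= need) - (Ls - 1)
    if candidate_d.size == 0:
        return []
    eq = (S[:, None] == P[None, :]) & (S[:, None] >= 0)
    out = []
    # diagonal d: S[i] aligns with P[i + d]
    for d in candidate_d:
        i0 = max(0, -d)
        i1 = min(Ls, Lp - d)
        if i1 - i0 < params.min_length:
            continue
        diag = eq[np.arange(i0, i1), np.arange(i0 + d, i1 + d)]
        if diag.sum() < params.min_length - mismatch_budget(i1 - i0, params.max_error_rate):
            continue
        for s, e, nm in _maximal_windows_on_diagonal(~diag, params):
            si, ei = i0 + s, i0 + e                  # window in S-local coords
            ps, pe = si + d, ei + d
            if parallel:
                rs, re = seg_offset + si, seg_offset + ei
            else:
                rs = rna_len - (seg_offset + ei)
                re = rna_len - (seg_offset + si)
            out.append((rs, re, ps, pe, nm))
    return out


# ---------------------------------------------------------------------------
# TFDs and isoform selection


def merge_tfds(sites: pd.DataFrame) -> list[TriplexDomain]:
    """Merge the RNA-side footprints of one lncRNA's sites into TFDs."""
    if len(sites) == 0:
        return []
    ids = sites["lncrna_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"sites span multiple lncRNAs: {sorted(ids)}")
    iv = sites[["rna_start", "rna_end"]].sort_values("rna_start").to_numpy(np.int64)
    domains: list[list[int]] = []
    for s, e in iv:
        if domains and s <= domains[-1][1]:
            domains[-1][1] = max(domains[-1][1], e)
        else:
            domains.append([s, e])
    out = []
    for s, e in domains:
        n = int(((sites["rna_start"] < e) & (sites["rna_end"] > s)).sum())
        out.append(TriplexDomain(str(ids[0]), int(s), int(e), n))
    return out


def select_dominant_isoform(tfs_counts: Mapping[str, int]) -> str:
    """Isoform with the most TFSs; ties go to the lexicographically smallest id."""
    if not tfs_counts:
        raise ValueError("no isoforms supplied")
    return min(tfs_counts, key=lambda k: (-tfs_counts[k], k))
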