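"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: full enumeration, per-base membership,
no shortcuts shared with the library implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from triplextad.triplex import MOTIF_CODES, TriplexParams, mismatch_budget

PURINES = set("AG")
PYRIMIDINES = set("CT")

_CODE_CHARS = {
    "pyrimidine": {"T": "A", "U": "A", "C": "G"},
    "purine": {"A": "A", "G": "G"},
    "mixed": {"G": "G", "T": "A", "U": "A"},
}


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_force_tts(seq: str, params: TriplexParams) -> list[tuple[int, int, str]]:
    """All min_length windows meeting the purine criterion, merged per strand."""
    W = params.min_length
    out = []
    for strand, alphabet in (("+", PURINES), ("-", PYRIMIDINES)):
        covered = np.zeros(len(seq), dtype=bool)
        for i in range(0, len(seq) - W + 1):
            window = seq[i:i + W]
            frac = sum(1 for b in window if b in alphabet) / W
            if frac >= params.min_purine_fraction - 1e-9:
                covered[i:i + W] = True
        # merged maximal runs
        i = 0
        while i < len(seq):
            if covered[i]:
                j = i
                while j < len(seq) and covered[j]:
                    j += 1
                out.append((i, j, strand))
                i = j
            else:
                i += 1
    return sorted(out)


def _all_qualifying_windows(rna_oriented: str, tract_purine: str, params: TriplexParams):
    """Every (s_rna, e_rna, s_p, e_p, nm) qualifying window on every diagonal."""
    Ls, Lp = len(rna_oriented), len(tract_purine)
    W = params.min_length
    windows = []
    for d in range(-(Ls - 1), Lp):
        i0, i1 = max(0, -d), min(Ls, Lp - d)
        span = i1 - i0
        if span < W:
            continue
        mism = [rna_oriented[i] != tract_purine[i + d] or rna_oriented[i] == "?"
                or tract_purine[i + d] == "N"
                for i in range(i0, i1)]
        for a in range(span):
            for b in range(a + W, span + 1):
                nm = sum(mism[a:b])
                if nm <= mismatch_budget(b - a, params.max_error_rate):
                    windows.append((d, i0 + a, i0 + b, nm))
    # containment-maximal per diagonal
    maximal = []
    for d, a, b, nm in windows:
        contained = any(
            dd == d and aa <= a and bb >= b and (aa, bb) != (a, b)
            for dd, aa, bb, _ in windows)
        if not contained:
            maximal.append((d, a, b, nm))
    return maximal


def brute_force_triplexes(rna_seqs: dict[str, str], genome: dict[str, str],
                          params: TriplexParams) -> pd.DataFrame:
    """Full enumeration equivalent of search_triplexes (tiny inputs only)."""
    rows = []
    for chrom, seq in genome.items():
        for ts, te, strand in brute_force_tts(seq, params):
            tract = seq[ts:te] if strand == "+" else revcomp(seq[ts:te])
            for iso, rna in rna_seqs.items():
                for motif in params.motifs:
                    parallel = MOTIF_CODES[motif][0]
                    code = _CODE_CHARS[motif]
                    mapped = "".join(code.get(b, "?") for b in rna.upper())
                    oriented = mapped if parallel else mapped[::-1]
                    wins = _all_qualifying_windows(oriented, tract, params)
                    # merge tract-overlapping windows; mismatches = min over
                    # the merged containment-maximal members
                    wins.sort(key=lambda w: (w[1] + w[0], w[2] + w[0]))
                    merged = []
                    for d, a, b, nm in wins:
                        ps, pe = a + d, b + d
                        if merged and ps < merged[-1][1]:
                            m = merged[-1]
                            m[1] = max(m[1], pe)
                            m[2] = min(m[2], a)
                            m[3] = max(m[3], b)
                            m[4] = min(m[4], nm)
                        else:
                            merged.append([ps, pe, a, b, nm])
                    for ps, pe, a, b, nm in merged:
                        if strand == "+":
                            g0, g1 = ts + ps, ts + pe
                        else:
                            g0, g1 = te - pe, te - ps
                        if parallel:
                            rs, re = a, b
                        else:
                            rs, re = len(rna) - b, len(rna) - a
                        rows.append((iso, iso, chrom, g0, g1, strand, rs, re, motif, nm))
    df = pd.DataFrame(rows, columns=["lncrna_id", "isoform_id", "chrom", "start", "end",
                                     "tts_strand", "rna_start", "rna_end", "motif",
                                     "mismatches"])
    if len(df):
        df = df.sort_values(["lncrna_id", "isoform_id", "chrom", "start", "end", "motif"],
                            kind="stable").reset_index(drop=True)
    return df


def per_base_coverage(sites: pd.DataFrame, regions: pd.DataFrame,
                      chrom_sizes: dict[str, int]) -> int:
    """|union(sites) ∩ union(regions)| by explicit per-base membership."""
    total = 0
    for chrom, n in chrom_sizes.items():
        a = np.zeros(n, dtype=bool)
        b = np.zeros(n, dtype=bool)
        for _, r in sites[sites["chrom"] == chrom].iterrows():
            a[r["start"]:r["end"]] = True
        for _, r in regions[regions["chrom"] == chrom].iterrows():
            b[r["start"]:r["end"]] = True
        total += int((a & b).sum())
    return total
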