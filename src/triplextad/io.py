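"""Standard-format I/O: FASTA, BED6/BED12, TSV.

BED coordinates are 0-based half-open on disk and in memory, so reading and
writing are identity transforms on the coordinate values.  FASTA goes through
Biopython; record ids are the first whitespace-separated token of the header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import empty_intervals


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered id → uppercase sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 into an interval frame (extra columns: name, score, strand)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has {len(parts)} fields, need ≥3")
            try:
                rec = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if len(parts) > 3:
                rec["name"] = parts[3]
            if len(parts) > 4:
                rec["score"] = parts[4]
            if len(parts) > 5:
                rec["strand"] = parts[5]
            for i, extra in enumerate(parts[6:], 7):
                rec[f"col{i}"] = extra
            rows.append(rec)
    if not rows:
        return empty_intervals(["name", "score", "strand"])
    return pd.DataFrame(rows)


def write_bed(df: pd.DataFrame, path: str | Path, extra_columns: list[str] | None = None) -> None:
    """Write BED6 (+ optional extra columns appended after column 6)."""
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            name = str(row["name"]) if "name" in df.columns else "."
            score = str(row["score"]) if "score" in df.columns else "0"
            strand = str(row["strand"]) if "strand" in df.columns else "."
            fields = [str(row["chrom"]), str(int(row["start"])), str(int(row["end"])),
                      name, score, strand]
            for col in extra_columns or []:
                fields.append(str(row[col]))
            fh.write("\t".join(fields) + "\n")


def read_tsv(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# gene models (BED12)

def write_gene_models_bed12(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as BED12 (thickStart/thickEnd carry the CDS span).

    Expects columns: gene_id, chrom, strand, tx_start, tx_end, cds_start,
    cds_end, exon_starts (comma list, absolute), exon_ends.
    """
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            ex_s = [int(x) for x in str(g["exon_starts"]).split(",") if x != ""]
            ex_e = [int(x) for x in str(g["exon_ends"]).split(",") if x != ""]
            sizes = ",".join(str(e - s) for s, e in zip(ex_s, ex_e)) + ","
            rel = ",".join(str(s - int(g["tx_start"])) for s in ex_s) + ","
            fh.write("\t".join([
                str(g["chrom"]), str(int(g["tx_start"])), str(int(g["tx_end"])),
                str(g["gene_id"]), "0", str(g["strand"]),
                str(int(g["cds_start"])), str(int(g["cds_end"])), "0",
                str(len(ex_s)), sizes, rel,
            ]) + "\n")


def read_gene_models_bed12(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields, got {len(p)}")
            tx_start = int(p[1])
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            rels = [int(x) for x in p[11].rstrip(",").split(",")]
            ex_s = [tx_start + r for r in rels]
            ex_e = [s + z for s, z in zip(ex_s, sizes)]
            rows.append({
                "gene_id": p[3], "chrom": p[0], "strand": p[5],
                "tx_start": tx_start, "tx_end": int(p[2]),
                "cds_start": int(p[6]), "cds_end": int(p[7]),
                "exon_starts": ",".join(map(str, ex_s)),
                "exon_ends": ",".join(map(str, ex_e)),
            })
    return pd.DataFrame(rows)
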