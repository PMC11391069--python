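"""Readers and writers for the plain-text formats the pipeline consumes.

TSV tables (pandas), BED 0-based half-open peak files, MTX sparse count
matrices with row/column index files (scipy.io), FASTA region sequences
(Bio.SeqIO), and JASPAR-style position frequency matrices (Bio.motifs).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, header_lines: list[str] | None = None,
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_bed(path) -> pd.DataFrame:
    """BED3+name -> DataFrame(chrom, start, end, region_id)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "region_id"]
    return df


def write_bed(regions: pd.DataFrame, path) -> None:
    regions[["chrom", "start", "end", "region_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_counts(path, index_col: int = 0) -> pd.DataFrame:
    """Dense region-by-sample (or cell-by-gene) integer TSV."""
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """MTX + .rows / .cols index files under the given path prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", sp.csr_matrix(counts.to_numpy()))
    Path(str(prefix) + ".rows").write_text("\n".join(map(str, counts.index)) + "\n")
    Path(str(prefix) + ".cols").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = str(prefix)
    mat = scipy.io.mmread(prefix + ".mtx").toarray()
    rows = Path(prefix + ".rows").read_text().splitlines()
    cols = Path(prefix + ".cols").read_text().splitlines()
    return pd.DataFrame(mat, index=rows, columns=cols)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_jaspar_pfms(path) -> dict[str, np.ndarray]:
    """JASPAR-format PFM file -> {motif_id: 4 x L count matrix (A,C,G,T)}."""
    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = {}
    for m in parsed:
        key = m.matrix_id or m.name
        out[key] = np.array([m.counts[b] for b in "ACGT"], dtype=float)
    return out


def write_jaspar_pfms(pfms: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for name, pfm in pfms.items():
            fh.write(f">{name}\t{name}\n")
            for base, row in zip("ACGT", pfm):
                vals = " ".join(f"{v:.2f}" for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


def read_gene_set(path) -> list[str]:
    """One gene per line; GMT lines (name, description, genes...) accepted."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) > 2:  # GMT record
            genes.extend(fields[2:])
        else:
            genes.append(fields[0])
    return genes
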