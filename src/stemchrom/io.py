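"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic intervals handled here follow the conventions of their format:
GFF3 is 1-based inclusive, BED is 0-based half-open. In-memory tables are
always 0-based half-open pandas DataFrames.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_COLUMNS = ["gene_id", "contig", "start", "end", "strand"]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 gene models (gene features only; exons optional)

def write_gff3(genes: pd.DataFrame, path, source: str = "stemchrom") -> None:
    """Write gene spans as GFF3 (1-based, inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.contig}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["contig", "source", "type", "start1", "end1", "score", "strand", "frame", "attr"],
    )
    df = df[df["type"] == "gene"].copy()
    df["gene_id"] = df["attr"].str.extract(r"ID=([^;]+)")
    df["start"] = df["start1"] - 1
    df["end"] = df["end1"]
    return df[GENE_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# BED

def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bed3(path, extra_names=()) -> pd.DataFrame:
    names = ["contig", "start", "end", *extra_names]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names
    return df


def write_fragments(frags: pd.DataFrame, path) -> None:
    write_bed(frags, path, columns=["contig", "start", "end", "sample"])


def read_fragments(path) -> pd.DataFrame:
    return read_bed3(path, extra_names=("sample",))


PEAK_COLUMNS = ["contig", "start", "end", "name", "score", "strand", "neg_log10_p", "summit"]


def write_peaks(peaks: pd.DataFrame, path) -> None:
    """narrowPeak-compatible: -log10 p in column 7, summit offset in column 8."""
    write_bed(peaks, path, columns=PEAK_COLUMNS)


def read_peaks(path) -> pd.DataFrame:
    return read_bed3(path, extra_names=("name", "score", "strand", "neg_log10_p", "summit"))


# ---------------------------------------------------------------------------
# Count matrix + sample sheet

def write_counts(counts: pd.DataFrame, lengths: pd.Series, path) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    lengths = df.pop("length")
    return df, lengths


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False, columns=["sample", "isolation", "replicate"])


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Hi-C: COO contact text (bin_i TAB bin_j TAB count) + bin table + chrom sizes

def write_contacts_coo(matrix: np.ndarray, path) -> None:
    i, j = np.nonzero(np.triu(matrix))
    with open(path, "w") as fh:
        for a, b in zip(i, j):
            fh.write(f"{a}\t{b}\t{matrix[a, b]:g}\n")


def read_contacts_coo(path, n_bins: int) -> np.ndarray:
    m = np.zeros((n_bins, n_bins))
    coo = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "count"])
    m[coo["i"], coo["j"]] = coo["count"]
    m[coo["j"], coo["i"]] = coo["count"]
    return m


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def write_bedgraph(track: pd.DataFrame, path) -> None:
    write_bed(track, path, columns=["contig", "start", "end", "value"])


# ---------------------------------------------------------------------------
# PWMs: minimal MEME text dialect (parsed with Bio.motifs)

def read_meme(path) -> dict[str, "motifs.Motif"]:
    with open(path) as fh:
        parsed = motifs.parse(fh, "minimal")
    return {m.name: m for m in parsed}


def write_meme(named_matrices: dict[str, np.ndarray], background: dict[str, float], path) -> None:
    """named_matrices: name -> (w, 4) probability matrix, columns A C G T."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {background[b]:.5f}" for b in "ACGT") + "\n\n")
        for name, mat in named_matrices.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {mat.shape[0]} nsites= 20 E= 0\n")
            for row in mat:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Plan / config files (plain-text key: value, nestable)

def write_keyvalue(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_keyvalue(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def sha256_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
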