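"""Readers and writers for the external formats the pipeline touches.

Formats: expression matrices as TSV or GCT with a sample-metadata TSV, gene
sets as GMT, motifs as minimal MEME text, sequences as FASTA (via Biopython),
mask intervals as BED (0-based half-open), and per-base conservation as
bedGraph.  Readers never silently drop records; rejects are logged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from psormod.datatypes import (
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    MotifModel,
)

logger = logging.getLogger(__name__)

_META_COLUMNS = ["study_id", "patient_id", "condition"]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path: str | Path,
    meta_path: str | Path,
    flags_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a TSV or GCT expression matrix and join sample metadata.

    The matrix format is inferred from the first line: a ``#1.2`` header
    marks GCT, anything else is plain TSV with gene ids in the first column.
    ``flags_path`` optionally supplies an above-background boolean matrix of
    identical shape (TSV, 0/1 or True/False).
    """
    matrix_path = Path(matrix_path)
    with open(matrix_path) as fh:
        first = fh.readline().strip()
    if first.startswith("#1.2"):
        values = _read_gct(matrix_path)
    else:
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if values.index.has_duplicates:
        dup = values.index[values.index.duplicated()].unique()
        raise FormatError(f"{matrix_path}: duplicate gene ids {list(dup[:5])}")
    values.index.name = None
    values.columns.name = None

    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    missing_cols = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"{meta_path}: missing metadata columns {missing_cols}")
    absent = [s for s in values.columns if s not in meta.index]
    if absent:
        raise FormatError(f"{meta_path}: no metadata for samples {absent}")

    flags = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0).astype(bool)
        flags.index.name = None
        flags.columns.name = None
        if flags.shape != values.shape:
            raise FormatError(
                f"{flags_path}: flag shape {flags.shape} != matrix {values.shape}"
            )
    return ExpressionMatrix(values=values, samples=meta, above_background=flags)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise FormatError(f"{path}: not a GCT 1.2 file (header {version!r})")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed GCT dimension line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t", index_col=0)
    body = body.drop(columns=["Description"], errors="ignore")
    if body.shape != (n_genes, n_samples):
        raise FormatError(
            f"{path}: GCT declares {n_genes}×{n_samples}, body is {body.shape}"
        )
    return body


def write_expression(
    expr: ExpressionMatrix,
    matrix_path: str | Path,
    meta_path: str | Path,
    flags_path: str | Path | None = None,
) -> None:
    expr.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    expr.samples[_META_COLUMNS].to_csv(meta_path, sep="\t", index_label="sample_id")
    if flags_path is not None:
        expr.above_background.astype(int).to_csv(
            flags_path, sep="\t", index_label="gene_id"
        )


def write_gct(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(expr.sample_ids) + "\n")
        for gene, row in expr.values.iterrows():
            fh.write(gene + "\tna\t" + "\t".join(f"{v:g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: per line set_id, description, then members."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields (<3)"
                )
            set_id, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning(
                    "%s:%d: set %s has %d duplicate members (collapsed)",
                    path, lineno, set_id, len(members) - len(unique),
                )
            sets[set_id] = unique
            descriptions[set_id] = desc
    return GeneSetCollection(name=name or path.stem, sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, members in collection:
            desc = collection.descriptions.get(set_id, "na") or "na"
            fh.write("\t".join([set_id, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# MEME-style motif files
# ---------------------------------------------------------------------------

def read_motifs(path: str | Path) -> list[MotifModel]:
    """Read a minimal MEME-format motif file.

    Recognized records: ``MOTIF <id> [<alt>]`` followed by a
    ``letter-probability matrix`` block (one row per position, columns
    A C G T).  An optional ``CONSENSUS <iupac>`` line inside a record
    overrides the derived consensus.
    """
    path = Path(path)
    motifs: list[MotifModel] = []
    motif_id: str | None = None
    consensus: str | None = None
    rows: list[list[float]] = []
    in_matrix = False

    def flush() -> None:
        nonlocal motif_id, consensus, rows, in_matrix
        if motif_id is not None:
            if not rows:
                raise FormatError(f"{path}: motif {motif_id!r} has no matrix")
            ppm = np.array(rows, dtype=float).T  # rows are positions in file
            motifs.append(MotifModel(motif_id=motif_id, ppm=ppm, consensus=consensus))
        motif_id, consensus, rows, in_matrix = None, None, [], False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: MOTIF line without id")
                motif_id = parts[1]
            elif line.startswith("CONSENSUS"):
                consensus = line.split()[1]
            elif line.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix and line and line[0] in "0123456789.":
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}:{lineno}: matrix row has {len(vals)} columns (need 4)"
                    )
                if abs(sum(vals) - 1.0) > 1e-3:
                    raise FormatError(
                        f"{path}:{lineno}: matrix row sums to {sum(vals):.4f}"
                    )
                rows.append(vals)
            elif in_matrix and (not line or not line[0].isdigit()):
                in_matrix = False
    flush()
    return motifs


def write_motifs(motifs: Iterable[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        for motif in motifs:
            fh.write(f"MOTIF {motif.motif_id}\n")
            fh.write(f"CONSENSUS {motif.consensus}\n")
            fh.write(
                "letter-probability matrix: alength= 4 "
                f"w= {motif.length} nsites= 20 E= 0\n"
            )
            for col in motif.ppm.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA / BED / bedGraph
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {record id: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="") for gene, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read BED3 intervals (0-based half-open) grouped by sequence name."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            intervals.setdefault(chrom, []).append((start, end))
    return intervals


def write_bed(intervals: dict[str, list[tuple[int, int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in intervals.items():
            for start, end in ivs:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """Read bedGraph per-base scores into dense arrays per sequence.

    The score of each interval applies to every covered base; array length is
    the maximum end coordinate seen per sequence, uncovered bases are 0.
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: bedGraph line has <4 fields")
            chrom = fields[0]
            start, end, score = int(fields[1]), int(fields[2]), float(fields[3])
            spans.setdefault(chrom, []).append((start, end, score))
    out: dict[str, np.ndarray] = {}
    for chrom, ivs in spans.items():
        length = max(end for _, end, _ in ivs)
        arr = np.zeros(length, dtype=float)
        for start, end, score in ivs:
            arr[start:end] = score
        out[chrom] = arr
    return out


def write_bedgraph(scores: dict[str, np.ndarray], path: str | Path) -> None:
    """Write per-base scores, run-length-collapsing equal adjacent values."""
    with open(path, "w") as fh:
        for chrom, arr in scores.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [arr.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")
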