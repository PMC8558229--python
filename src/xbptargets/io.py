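"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA via Biopython; BED3/BED6 as whitespace-delimited text; annotation, Ct,
DE and profile-matrix tables as tab-delimited files with a header line. The
profile matrix marks a significant cell with a trailing ``*`` on the fold
change (mirroring the grey cells of the validated panel).
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import PROFILE_COLUMNS
from .errors import XbpTargetsError
from .intervals import GenomicInterval, TSSAnnotation
from .motifs import GeneMotifReport, MotifHit
from .qpcr import CT_COLUMNS


# --- FASTA ---------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-sequence FASTA into ``{name: uppercase sequence}``."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# --- BED -----------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6 (0-based half-open). Track/browser lines are skipped."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise XbpTargetsError(f"{path}:{ln}: fewer than 3 BED fields")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_hits_bed(hits: Mapping[str, list[MotifHit]], path: str | Path) -> None:
    """Motif hits as BED6: name = gene_id:index, score = 0."""
    with open(path, "w") as fh:
        for gene_id in sorted(hits):
            for i, h in enumerate(hits[gene_id]):
                fh.write(
                    f"{h.chrom}\t{h.start}\t{h.end}\t{gene_id}:{i}\t0\t{h.strand}\n"
                )


# --- TSS annotation ------------------------------------------------------

def read_tss_table(path: str | Path) -> list[TSSAnnotation]:
    """Tab-delimited ``gene_id  chrom  tss  strand`` with one header line."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise XbpTargetsError(f"TSS table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise XbpTargetsError(f"duplicate gene_id {dup!r} in TSS table")
    return [
        TSSAnnotation(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def write_tss_table(annotations: Iterable[TSSAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.chrom}\t{a.tss}\t{a.strand}\n")


# --- motif reports -------------------------------------------------------

def write_motif_report(reports: Iterable[GeneMotifReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tn_hits\tn_clusters\tsearched_bases\n")
        for r in reports:
            fh.write(f"{r.gene_id}\t{r.n_hits}\t{r.n_clusters}\t{r.searched_bases}\n")


def read_motif_report(path: str | Path) -> list[GeneMotifReport]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneMotifReport(
            str(r.gene_id), int(r.n_hits), int(r.n_clusters), int(r.searched_bases)
        )
        for r in df.itertuples()
    ]


# --- Ct and DE tables ----------------------------------------------------

def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise XbpTargetsError(f"Ct table lacks columns {missing}")
    if not df["ct"].map(math.isfinite).all():
        raise XbpTargetsError("Ct table contains non-finite Ct values")
    return df


def read_de_table(
    path: str | Path,
    gene_col: str = "gene_id",
    lfc_col: str = "log2_fold_change",
    p_col: str = "p_value",
    q_col: str | None = "q_value",
) -> pd.DataFrame:
    """Generic DE table; column names are configurable so upstream tool
    output (e.g. Cuffdiff) maps in without editing."""
    df = pd.read_csv(path, sep="\t")
    rename = {gene_col: "gene_id", lfc_col: "log2_fold_change", p_col: "p_value"}
    if q_col is not None and q_col in df.columns:
        rename[q_col] = "q_value"
    missing = [c for c in (gene_col, lfc_col, p_col) if c not in df.columns]
    if missing:
        raise XbpTargetsError(f"DE table lacks columns {missing}")
    return df.rename(columns=rename)


# --- profile matrix (validated-panel shape) ------------------------------

def read_profile_matrix(
    path_or_buffer,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Read a panel-shaped matrix with ``*``-marked significant cells.

    Columns: ``gene``, ``n_motifs`` and the seven fold-change columns of
    :data:`~xbptargets.classify.PROFILE_COLUMNS`; a trailing ``*`` on a fold
    change marks the cell significant. Returns ``(fold_changes,
    significance, motif_counts)`` indexed by gene.
    """
    raw = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
    missing = [c for c in ["gene", "n_motifs", *PROFILE_COLUMNS] if c not in raw.columns]
    if missing:
        raise XbpTargetsError(f"profile matrix lacks columns {missing}")
    raw = raw.set_index("gene")
    fc = pd.DataFrame(index=raw.index, columns=PROFILE_COLUMNS, dtype=float)
    sig = pd.DataFrame(False, index=raw.index, columns=PROFILE_COLUMNS)
    for col in PROFILE_COLUMNS:
        cells = raw[col].astype(str).str.strip()
        starred = cells.str.endswith("*")
        fc[col] = cells.str.rstrip("*").astype(float)
        sig[col] = starred
    motifs = pd.to_numeric(raw["n_motifs"], errors="coerce")
    return fc, sig, motifs


def write_profile_matrix(
    fc: pd.DataFrame,
    sig: pd.DataFrame,
    motifs: pd.Series,
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tn_motifs\t" + "\t".join(PROFILE_COLUMNS) + "\n")
        for gene in fc.index:
            m = motifs.get(gene)
            m_str = "" if m is None or (isinstance(m, float) and math.isnan(m)) else str(int(m))
            cells = [
                f"{fc.loc[gene, c]:.2f}" + ("*" if bool(sig.loc[gene, c]) else "")
                for c in PROFILE_COLUMNS
            ]
            fh.write(gene + "\t" + m_str + "\t" + "\t".join(cells) + "\n")


# --- packaged fixtures ---------------------------------------------------

def load_validated_panel() -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """The packaged 40-gene validated panel (plus the XBP1s reference row)."""
    ref = resources.files("xbptargets.data").joinpath("table1.tsv")
    with resources.as_file(ref) as path:
        return read_profile_matrix(path)


def load_consensus() -> str:
    """The packaged XBP1-binding consensus pattern."""
    return (
        resources.files("xbptargets.data")
        .joinpath("consensus_xbp1.txt")
        .read_text()
        .strip()
    )
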