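"""Readers and writers for the pipeline's standard text formats.

All tabular files are tab-separated, UTF-8, '.' decimal, no quoting.
Missing expression values are written as ``NA`` and read back as NaN so
that "filtered out" stays distinguishable from zero intensity.
Promoters travel as plain FASTA (via Biopython).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import ExpressionMatrix, PromoterRecord, SampleMeta

_NA = "NA"

SAMPLE_SHEET_COLUMNS = ["sample_id", "variety", "seed_class", "stage", "replicate"]


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {sorted(missing)}")
    metas = [
        SampleMeta(
            sample_id=row.sample_id,
            variety=row.variety,
            seed_class=row.seed_class,
            stage=row.stage,
            replicate=int(row.replicate),
        )
        for row in df.itertuples(index=False)
    ]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError(f"sample sheet {path}: duplicate sample IDs")
    return metas


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        w.writerow(SAMPLE_SHEET_COLUMNS)
        for s in samples:
            w.writerow([s.sample_id, s.variety, s.seed_class, s.stage, s.replicate])


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    sample_sheet: str | Path,
    log2: bool = False,
) -> ExpressionMatrix:
    """Read a gene x sample TSV plus its sample sheet into a validated matrix.

    The first column holds gene IDs, the header row sample IDs.  Every
    sample in the matrix must appear in the sheet; row and column order
    are preserved from the files.
    """
    metas = {m.sample_id: m for m in read_sample_sheet(sample_sheet)}
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene IDs: {dups[:5]}")
    for sid in df.columns:
        if sid not in metas:
            raise ValueError(
                f"{path}: sample {sid!r} is missing from the sample sheet"
            )
    values = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            # astype(float) uses the correctly-rounded parser, so written
            # values survive the round trip bit for bit
            values[col] = df[col].astype(float)
        except (ValueError, TypeError):
            for i, cell in enumerate(df[col]):
                if pd.isna(cell):
                    continue
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at gene "
                        f"{df.index[i]!r}, sample {col!r}"
                    ) from None
            raise
    ordered = [metas[sid] for sid in df.columns]
    return ExpressionMatrix(values, ordered, log2=log2)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep=_NA, float_format="%.17g")


# ---------------------------------------------------------------------------
# promoters (FASTA)
# ---------------------------------------------------------------------------

def read_promoters(path: str | Path) -> list[PromoterRecord]:
    """Read promoter FASTA; sequences are uppercased and U -> T.

    Record order follows the file.  Duplicate IDs, empty sequences and
    non-IUPAC-DNA characters raise.
    """
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate promoter ID {rec.id!r}")
        seen.add(rec.id)
        records.append(PromoterRecord(gene_id=rec.id, sequence=str(rec.seq)))
    return records


def write_promoters(promoters: Sequence[PromoterRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(p.sequence), id=p.gene_id, description="")
        for p in promoters
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# candidate rankings
# ---------------------------------------------------------------------------

def write_ranking(ranking, path: str | Path) -> None:
    """Write a candidate ranking sorted by descending final score.

    Columns: gene_id, the per-dataset association columns, a, b, c,
    score, rank, in_top_k.
    """
    df = ranking.table.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep=_NA, float_format="%.17g")


def read_ranking_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False
    )
    if "in_top_k" in df.columns:
        df["in_top_k"] = df["in_top_k"].astype(bool)
    return df
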