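"""Core containers: sample metadata, expression matrices, promoter records.

An :class:`ExpressionMatrix` is a thin wrapper around a pandas DataFrame
(genes x samples) carrying per-sample design metadata (variety, seededness
class, developmental stage S1-S4, replicate) and a flag saying whether the
values are linear fluorescence intensities or log2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SEED_CLASSES = ("SD", "SL")
STAGES = ("S1", "S2", "S3", "S4")


@dataclass(frozen=True)
class SampleMeta:
    """Design metadata for one array/sample."""

    sample_id: str
    variety: str
    seed_class: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.seed_class not in SEED_CLASSES:
            raise ValueError(
                f"sample {self.sample_id!r}: seed_class must be one of "
                f"{SEED_CLASSES}, got {self.seed_class!r}"
            )
        if self.stage not in STAGES:
            raise ValueError(
                f"sample {self.sample_id!r}: stage must be one of {STAGES}, "
                f"got {self.stage!r}"
            )
        if self.replicate < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate must be >= 1"
            )


# A sample filter: a callable on SampleMeta, a mapping of field -> value
# (e.g. {"seed_class": "SD"}), or an explicit collection of sample IDs.
SampleFilter = Callable[[SampleMeta], bool] | Mapping[str, object] | Iterable[str]


class ExpressionMatrix:
    """Gene x sample expression values plus sample design metadata.

    Values live in a DataFrame whose index is the gene IDs and whose
    columns are the sample IDs, in file order.  Missing values are NaN.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: Sequence[SampleMeta],
        log2: bool = False,
    ) -> None:
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample IDs in metadata")
        if list(values.columns) != sample_ids:
            raise ValueError(
                "matrix columns do not match sample sheet order: "
                f"{list(values.columns)[:5]} vs {sample_ids[:5]}"
            )
        self.values = values.astype(float)
        self.samples = list(samples)
        self.log2 = bool(log2)

    # -- basic introspection -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    # -- selection -----------------------------------------------------------

    def select_samples(self, flt: SampleFilter) -> list[str]:
        """Resolve a sample filter to an ordered list of sample IDs."""
        if callable(flt):
            return [s.sample_id for s in self.samples if flt(s)]
        if isinstance(flt, Mapping):
            def match(s: SampleMeta) -> bool:
                return all(getattr(s, k) == v for k, v in flt.items())
            return [s.sample_id for s in self.samples if match(s)]
        wanted = set(flt)
        unknown = wanted - set(self.sample_ids)
        if unknown:
            raise KeyError(f"unknown sample IDs: {sorted(unknown)}")
        return [sid for sid in self.sample_ids if sid in wanted]

    def subset(self, flt: SampleFilter) -> "ExpressionMatrix":
        ids = self.select_samples(flt)
        id_set = set(ids)
        metas = [s for s in self.samples if s.sample_id in id_set]
        return ExpressionMatrix(self.values[ids], metas, log2=self.log2)

    # -- scale handling ------------------------------------------------------

    def log2_values(self) -> pd.DataFrame:
        """Values on the log2 scale; non-positive linear values become NaN."""
        if self.log2:
            return self.values
        vals = self.values.where(self.values > 0)
        return np.log2(vals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.log2 == other.log2
            and self.samples == other.samples
            and self.values.equals(other.values)
        )

    def __repr__(self) -> str:
        scale = "log2" if self.log2 else "linear"
        return (
            f"<ExpressionMatrix {self.n_genes} genes x {self.n_samples} "
            f"samples, {scale}>"
        )


_DNA_ALPHABET = set("ACGTN")
MIN_PROMOTER_LENGTH = 10  # shortest CArG box


@dataclass(frozen=True)
class PromoterRecord:
    """Upstream regulatory sequence for one gene.

    Coordinates used by the motif scanner are 1-based inclusive on the
    given strand; position 1 is the 5'-most base of the stored sequence
    (declared upstream-of-ATG, 5'->3').
    """

    gene_id: str
    sequence: str
    coordinate_note: str = "upstream-of-ATG, 1-based, 5'->3'"

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"promoter {self.gene_id!r}: empty sequence")
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"promoter {self.gene_id!r}: non-IUPAC-DNA characters "
                f"{sorted(bad)}"
            )
        if len(seq) < MIN_PROMOTER_LENGTH:
            raise ValueError(
                f"promoter {self.gene_id!r}: length {len(seq)} below the "
                f"minimum motif width {MIN_PROMOTER_LENGTH}"
            )

    def __len__(self) -> int:
        return len(self.sequence)
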