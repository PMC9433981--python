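"""Bait-centered multi-dataset co-expression and composite candidate ranking.

Candidate targets of a bait transcription factor are prioritized by a
product of three components computed across one primary expression
experiment and any number of auxiliary datasets:

* **a — concordance**: the fraction of datasets in which the gene passes
  that dataset's co-expression membership test (Pearson r >= r_min, or
  highest-reciprocal-rank HRR <= hrr_max).  Genes passing nowhere
  (a = 0) are excluded from the listed set.
* **b — intensity**: the product of per-dataset association strengths,
  |r| for Pearson datasets and 1/HRR for HRR datasets (both in (0, 1],
  lower HRR = stronger).
* **c — expression level**: the rank fraction of the gene's mean
  normalized intensity in the primary tissue, 1 for the most expressed
  gene.

The final score s = a*b*c sorts genes from highest to lowest; the top-K
prefix is the candidate list.  Negative co-expression (the bait acting
as a repressor) is handled as a separate ranking with sign_mode
"negative" rather than by mixing signs into one product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .types import STAGES, ExpressionMatrix

logger = logging.getLogger(__name__)

Measure = Literal["pearson", "hrr"]


@dataclass
class DatasetSpec:
    name: str
    measure: Measure = "pearson"

    def __post_init__(self) -> None:
        if self.measure not in ("pearson", "hrr"):
            raise ValueError(f"unknown measure {self.measure!r}")


@dataclass
class ScoringConfig:
    bait_id: str = "bait"
    datasets: Sequence[DatasetSpec] = ()
    r_min: float = 0.6
    hrr_max: int = 100
    top_k: int = 100
    sign_mode: Literal["positive", "negative"] = "positive"
    require_down_in_sl: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.r_min < 1:
            raise ValueError("r_min must be in (0, 1)")
        if self.hrr_max < 1:
            raise ValueError("hrr_max must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class CandidateRanking:
    """Ranked candidate table plus exclusion bookkeeping."""

    table: pd.DataFrame  # indexed by gene_id, sorted by rank
    config: ScoringConfig = field(repr=False, default=None)
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def top_k_ids(self) -> set[str]:
        return set(self.table.index[self.table["in_top_k"]])


# ---------------------------------------------------------------------------
# per-dataset association measures
# ---------------------------------------------------------------------------

def bait_pearson(matrix: ExpressionMatrix, bait_id: str) -> pd.Series:
    """Pearson correlation of every gene with the bait on log2 values.

    Computed over all samples of the dataset.  Genes with zero variance
    get NaN (undefined, excluded downstream); a flat or absent bait is
    an error.
    """
    log2 = matrix.log2_values()
    if bait_id not in log2.index:
        raise KeyError(f"bait {bait_id!r} absent from matrix")
    bait = log2.loc[bait_id]
    if bait.std(skipna=True) == 0 or bait.dropna().size < 3:
        raise ValueError(f"bait {bait_id!r} has no usable variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = log2.T.corrwith(bait)
    n_flat = int(r.isna().sum())
    if n_flat:
        logger.debug("%d gene(s) with undefined correlation", n_flat)
    return r


def _corr_matrix(log2: pd.DataFrame) -> np.ndarray:
    X = log2.to_numpy(float)
    sd = X.std(axis=1)
    Z = np.zeros_like(X)
    ok = sd > 0
    Z[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    C = Z @ Z.T / X.shape[1]
    C[~ok, :] = np.nan
    C[:, ~ok] = np.nan
    return C


def bait_hrr(matrix: ExpressionMatrix, bait_id: str) -> pd.Series:
    """Highest reciprocal rank of every gene with respect to the bait.

    rank_b(g) is g's position in the bait's neighbor list sorted by
    descending correlation (best = 1, self excluded); rank_g(b) is the
    bait's position in g's list.  HRR(g) = max of the two; lower is
    stronger.  Correlation ties break by gene-ID lexicographic order.
    """
    log2 = matrix.log2_values()
    if bait_id not in log2.index:
        raise KeyError(f"bait {bait_id!r} absent from matrix")
    if log2.shape[0] < 3:
        raise ValueError("HRR needs at least 3 genes")
    genes = list(log2.index)
    C = _corr_matrix(log2)
    bi = genes.index(bait_id)
    if np.isnan(C[bi, bi]):
        raise ValueError(f"bait {bait_id!r} has no usable variance")

    def neighbor_ranks(i: int) -> np.ndarray:
        """1-based rank of every other gene in gene i's neighbor list."""
        r = C[i].copy()
        r[i] = np.nan
        order = sorted(
            (j for j in range(len(genes)) if j != i and not np.isnan(r[j])),
            key=lambda j: (-r[j], genes[j]),
        )
        ranks = np.full(len(genes), np.nan)
        for pos, j in enumerate(order, start=1):
            ranks[j] = pos
        return ranks

    rank_from_bait = neighbor_ranks(bi)
    # rank of the bait in each gene's own neighbor list, vectorized:
    # 1 + (# neighbors more correlated than the bait) + (ties that sort
    # before the bait lexicographically)
    M = C.copy()
    np.fill_diagonal(M, np.nan)
    r_with_bait = M[:, bi].copy()
    M[:, bi] = np.nan
    id_before_bait = np.array([g < genes[bi] for g in genes])
    stronger = np.nansum(M > r_with_bait[:, None], axis=1)
    ties = np.nansum(
        (M == r_with_bait[:, None]) & id_before_bait[None, :], axis=1
    )
    rank_of_bait = stronger + ties + 1.0
    hrr = np.maximum(rank_from_bait, rank_of_bait)
    hrr[np.isnan(r_with_bait)] = np.nan
    hrr[bi] = np.nan
    return pd.Series(hrr, index=log2.index, name="hrr")


# ---------------------------------------------------------------------------
# score components
# ---------------------------------------------------------------------------

def concordance_a(memberships: pd.DataFrame) -> pd.Series:
    """Fraction of datasets whose membership test the gene passes."""
    if memberships.shape[1] < 1:
        raise ValueError("need at least one dataset")
    return memberships.fillna(False).astype(bool).sum(axis=1) / memberships.shape[1]


def intensity_b(similarities: pd.DataFrame) -> pd.Series:
    """Product of per-dataset similarities over datasets measuring the gene.

    Similarities are expected in [0, 1] (|r| or 1/HRR); absent datasets
    (NaN) contribute no factor.  Genes measured nowhere get NaN.
    """
    measured = similarities.notna()
    b = similarities.where(measured, 1.0).prod(axis=1)
    b[~measured.any(axis=1)] = np.nan
    return b


def expression_c(matrix: ExpressionMatrix) -> pd.Series:
    """Rank fraction of each gene's mean intensity over the primary samples.

    The highest-expressed gene gets c = 1; ties receive average ranks.
    Rank fractions are invariant to rescaling all intensities, so c is
    dimensionless.
    """
    means = matrix.values.mean(axis=1, skipna=True)
    return means.rank(method="average") / len(means)


def down_in_sl_flags(
    matrix: ExpressionMatrix, min_stages: int = 2
) -> pd.Series:
    """Seedless down-regulation flag from the primary experiment.

    True when the SD-minus-SL mean log2 difference is positive in at
    least ``min_stages`` of stages S2-S4.
    """
    log2 = matrix.log2_values()
    wins = pd.Series(0, index=log2.index)
    for stage in STAGES[1:]:
        sd = matrix.select_samples({"seed_class": "SD", "stage": stage})
        sl = matrix.select_samples({"seed_class": "SL", "stage": stage})
        diff = log2[sd].mean(axis=1) - log2[sl].mean(axis=1)
        wins = wins + (diff > 0).astype(int)
    return wins >= min_stages


# ---------------------------------------------------------------------------
# composite ranking
# ---------------------------------------------------------------------------

def score_candidates(
    primary: ExpressionMatrix,
    datasets: dict[str, ExpressionMatrix],
    config: ScoringConfig,
) -> CandidateRanking:
    """Full a*b*c scoring across all configured datasets.

    ``datasets`` maps each configured dataset name to its matrix; the
    primary matrix additionally supplies the expression-level component
    and the optional seedless down-regulation filter.
    """
    if not config.datasets:
        raise ValueError("scoring needs at least one dataset")
    assoc: dict[str, pd.Series] = {}
    member: dict[str, pd.Series] = {}
    sim: dict[str, pd.Series] = {}
    for spec in config.datasets:
        mat = datasets[spec.name]
        if spec.measure == "pearson":
            r = bait_pearson(mat, config.bait_id)
            if config.sign_mode == "positive":
                member[spec.name] = r >= config.r_min
            else:
                member[spec.name] = r <= -config.r_min
            sim[spec.name] = r.abs()
            assoc[f"r_{spec.name}"] = r
        else:
            hrr = bait_hrr(mat, config.bait_id)
            member[spec.name] = hrr <= config.hrr_max
            sim[spec.name] = 1.0 / hrr
            assoc[f"hrr_{spec.name}"] = hrr

    genes = pd.Index(primary.gene_ids)
    memberships = pd.DataFrame(member).reindex(genes)
    similarities = pd.DataFrame(sim).reindex(genes)

    a = concordance_a(memberships)
    b = intensity_b(similarities)
    c = expression_c(primary)
    down = down_in_sl_flags(primary)

    table = pd.DataFrame(
        {**{k: v.reindex(genes) for k, v in assoc.items()},
         "a": a, "b": b, "c": c, "down_in_sl": down}
    )
    excluded = {"bait": int(config.bait_id in table.index)}
    table = table.drop(index=config.bait_id, errors="ignore")
    excluded["no_membership"] = int((table["a"] == 0).sum())
    excluded["unmeasured"] = int(table["b"].isna().sum())
    table = table[(table["a"] > 0) & table["b"].notna()]
    return composite_rank(table, config, excluded)


def composite_rank(
    components: pd.DataFrame,
    config: ScoringConfig,
    excluded: dict[str, int] | None = None,
) -> CandidateRanking:
    """Sort by s = a*b*c descending and flag the top-K prefix.

    Ties break on higher b then gene ID.  With ``require_down_in_sl``
    genes lacking the seedless down-regulation flag are demoted below
    every flagged gene before ranking.
    """
    t = components.copy()
    t["score"] = t["a"] * t["b"] * t["c"]
    demote = (
        ~t["down_in_sl"].fillna(False).astype(bool)
        if config.require_down_in_sl and "down_in_sl" in t
        else pd.Series(False, index=t.index)
    )
    order = sorted(
        t.index,
        key=lambda g: (demote[g], -t.at[g, "score"], -t.at[g, "b"], g),
    )
    t = t.loc[order]
    t["rank"] = np.arange(1, len(t) + 1)
    t["in_top_k"] = t["rank"] <= config.top_k
    return CandidateRanking(table=t, config=config, excluded=excluded or {})
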