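"""Normalization and differential expression between sample groups.

The normalization mirrors standard single-channel microarray practice:
negative (background-subtracted) signals are filtered out on the linear
scale, then each sample is rescaled so its 75th percentile equals a
common target.  Differential expression is a per-gene two-sample t-test
on log2 values (Welch by default, pooled optional), with genes called
up/down under joint p-value and linear fold-change thresholds
(p < 0.05, |FC| > 2 by default).  Venn-style set algebra between
contrasts is provided for the usual "common DEGs" bookkeeping.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, SampleFilter

logger = logging.getLogger(__name__)


@dataclass
class DEGConfig:
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    percentile: float = 0.75
    percentile_target: float = 100.0
    welch: bool = True
    fdr: bool = False  # optional BH correction; the default reports raw p

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.fc_threshold < 1:
            raise ValueError("thresholds must be positive, fc_threshold >= 1")
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must be in (0, 1)")
        if self.percentile_target <= 0:
            raise ValueError("percentile_target must be > 0")


def filter_negative_signals(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes that are non-positive/missing everywhere; mask the rest.

    Individual non-positive values in retained genes become missing, so
    every retained value is > 0 on the linear scale afterwards.  Gene
    order is preserved.
    """
    if matrix.log2:
        raise ValueError("negative-signal filtering applies to linear-scale "
                         "matrices only")
    positive = matrix.values > 0
    keep = positive.any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("negative-signal filter removed %d gene(s)", dropped)
    vals = matrix.values.loc[keep].where(positive.loc[keep])
    return ExpressionMatrix(vals, matrix.samples, log2=False)


def percentile_normalize(
    matrix: ExpressionMatrix, config: DEGConfig | None = None
) -> ExpressionMatrix:
    """Scale each sample so its chosen percentile hits the common target.

    The quantile is the linear-interpolation quantile over non-missing
    values.  Per-sample scale factors are logged at DEBUG level.
    """
    config = config or DEGConfig()
    if matrix.log2:
        raise ValueError("percentile normalization applies to the linear scale")
    factors = {}
    cols = {}
    for sid in matrix.sample_ids:
        col = matrix.values[sid]
        obs = col.dropna()
        if obs.empty:
            raise ValueError(f"sample {sid!r}: all values missing")
        q = float(np.quantile(obs.to_numpy(), config.percentile))
        if q <= 0:
            raise ValueError(
                f"sample {sid!r}: {config.percentile:.0%} percentile is "
                f"{q}, cannot normalize"
            )
        f = config.percentile_target / q
        factors[sid] = f
        cols[sid] = col * f
    logger.debug("percentile scale factors: %s", factors)
    vals = pd.DataFrame(cols, index=matrix.values.index)
    return ExpressionMatrix(vals[matrix.sample_ids], matrix.samples, log2=False)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

DEG_COLUMNS = [
    "mean_log2_a", "mean_log2_b", "log2fc", "fold_change",
    "p_value", "direction", "stage", "testable",
]


def _signed_fc(log2fc: np.ndarray) -> np.ndarray:
    """Linear fold change with the sign of log2fc (FC = +-2^|log2fc|)."""
    fc = np.exp2(np.abs(log2fc))
    return np.where(log2fc < 0, -fc, fc)


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: SampleFilter,
    group_b: SampleFilter,
    stage: str | None = None,
    config: DEGConfig | None = None,
) -> pd.DataFrame:
    """Per-gene t-test of group A vs group B on log2 values.

    ``log2fc`` is mean(A) - mean(B); ``direction`` is 'up' when
    p <= p_threshold and log2fc >= log2(fc_threshold), 'down'
    symmetrically, 'ns' otherwise.  Genes with fewer than two observed
    values in either group are reported with ``testable = False`` rather
    than dropped.  Restricting to one stage intersects both groups with
    that stage's samples.
    """
    config = config or DEGConfig()
    ids_a = matrix.select_samples(group_a)
    ids_b = matrix.select_samples(group_b)
    if stage is not None:
        stage_ids = set(matrix.select_samples({"stage": stage}))
        ids_a = [s for s in ids_a if s in stage_ids]
        ids_b = [s for s in ids_b if s in stage_ids]
    if not ids_a:
        raise ValueError(f"group A filter {group_a!r} selects no samples")
    if not ids_b:
        raise ValueError(f"group B filter {group_b!r} selects no samples")
    overlap = set(ids_a) & set(ids_b)
    if overlap:
        raise ValueError(f"groups overlap on samples {sorted(overlap)[:5]}")

    log2 = matrix.log2_values()
    a = log2[ids_a].to_numpy()
    b = log2[ids_b].to_numpy()
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    testable = (n_a >= 2) & (n_b >= 2)

    # untestable genes produce empty/degenerate slices below; their NaNs
    # are masked out at the end, so the slice warnings are expected noise
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        log2fc = mean_a - mean_b
        res = stats.ttest_ind(
            a, b, axis=1, equal_var=not config.welch, nan_policy="omit"
        )
        p = np.asarray(res.pvalue, dtype=float)
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_b = np.nanvar(b, axis=1, ddof=1)
    both_flat = (var_a == 0) & (var_b == 0)
    # degenerate zero-variance genes: identical means are defined as p = 1
    # (no evidence), different means as p = 0 (infinite t)
    p = np.where(both_flat & np.isclose(mean_a, mean_b), 1.0, p)
    p = np.where(both_flat & ~np.isclose(mean_a, mean_b), 0.0, p)
    p = np.where(testable, p, np.nan)

    p_eff = p
    q = None
    if config.fdr:
        q = np.full_like(p, np.nan)
        mask = ~np.isnan(p)
        if mask.any():
            q[mask] = stats.false_discovery_control(p[mask], method="bh")
        p_eff = q

    lfc_cut = np.log2(config.fc_threshold)
    up = testable & (p_eff <= config.p_threshold) & (log2fc >= lfc_cut)
    down = testable & (p_eff <= config.p_threshold) & (log2fc <= -lfc_cut)
    direction = np.where(up, "up", np.where(down, "down", "ns"))

    out = pd.DataFrame(
        {
            "mean_log2_a": mean_a,
            "mean_log2_b": mean_b,
            "log2fc": log2fc,
            "fold_change": _signed_fc(log2fc),
            "p_value": p,
            "direction": direction,
            "stage": stage if stage is not None else "all",
            "testable": testable,
        },
        index=log2.index,
    )
    if q is not None:
        out["q_value"] = q
    return out


def deg_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Up/down/all DEG ID sets from a differential-expression table."""
    up = set(table.index[table["direction"] == "up"])
    down = set(table.index[table["direction"] == "down"])
    return {"up": up, "down": down, "all": up | down}


# ---------------------------------------------------------------------------
# Venn partitions
# ---------------------------------------------------------------------------

def venn_partition(
    sets: dict[str, set[str]]
) -> dict[tuple[str, ...], tuple[int, set[str]]]:
    """Exclusive Venn regions of 2-4 named sets.

    Each region is keyed by the tuple of set names whose intersection it
    represents (members of exactly those sets and no others); all
    2^n - 1 regions are reported and their counts sum to |union|.
    """
    names = list(sets)
    if len(names) != len(set(names)):
        raise ValueError("duplicate set names")
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_partition supports 2-4 sets")
    regions: dict[tuple[str, ...], tuple[int, set[str]]] = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            members = set.intersection(*(sets[n] for n in inside))
            for n in names:
                if n not in inside:
                    members = members - sets[n]
            regions[inside] = (len(members), members)
    return regions
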