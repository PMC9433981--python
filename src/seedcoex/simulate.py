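"""Synthetic expression experiments with planted, recoverable structure.

The generator emulates the statistical design of a seed-development
transcriptomic study: two seeded (SD) and two seedless (SL) varieties
sampled at four stages (S1 pre-bloom .. S4 veraison) with replicates, a
bait transcription factor that peaks sharply at S3 in seeded varieties
and stays flat and low in seedless ones, a set of target genes that track
the bait across the primary experiment and across auxiliary co-expression
datasets, extra genes differentially expressed at S3 only, and promoters
with (targets) or without (everything else) planted CArG boxes.

All sampling is Gaussian on the log2 scale (log-normal intensities), the
standard approximation for fluorescence microarray data and the model the
downstream t-test assumes.  Matrices are returned on the linear scale.

Every planted feature is recorded in a :class:`SyntheticTruth` so that
downstream stages can be scored against exact ground truth.  A fixed seed
gives bitwise-identical output; the expression streams and the promoter
stream are drawn from separate child seeds, so skipping promoter
generation does not perturb the matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .motifs import CARG_WIDTHS, _CARG_RE
from .types import STAGES, ExpressionMatrix, PromoterRecord, SampleMeta

DEFAULT_VARIETIES = (
    ("SD1", "SD"),
    ("SD2", "SD"),
    ("SL1", "SL"),
    ("SL2", "SL"),
)


@dataclass
class SimulationParams:
    """Knobs of the synthetic experiment (log2-scale unless noted)."""

    n_genes: int = 5000
    n_targets: int = 50
    n_deg_extra: int = 200
    varieties: Sequence[tuple[str, str]] = DEFAULT_VARIETIES
    replicates: int = 3
    bait_profile_sd: Sequence[float] = (6.0, 6.0, 12.0, 9.0)
    bait_profile_sl: Sequence[float] = (5.0, 5.0, 6.0, 5.0)
    target_correlation: float = 0.9
    noise_sd: float = 0.5
    deg_log2fc: float = 2.0
    n_aux_datasets: int = 2
    aux_n_samples: int = 30
    motif_per_target: int = 1
    promoter_length: int = 2000
    baseline_range: tuple[float, float] = (6.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_targets + self.n_deg_extra > self.n_genes - 1:
            raise ValueError(
                "n_targets + n_deg_extra must leave room for the bait: "
                f"{self.n_targets} + {self.n_deg_extra} > {self.n_genes} - 1"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 < self.target_correlation <= 1:
            raise ValueError("target_correlation must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.bait_profile_sd) != 4 or len(self.bait_profile_sl) != 4:
            raise ValueError("bait profiles must have one mean per stage")
        if self.promoter_length < 12:
            raise ValueError("promoter_length must fit the widest CArG box")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated experiment."""

    bait_id: str
    target_ids: set[str]
    deg_ids_by_stage: dict[str, set[str]]
    motif_positions: dict[str, list[tuple[int, int, str]]]
    params: SimulationParams = field(repr=False, default=None)


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _design(params: SimulationParams) -> list[SampleMeta]:
    metas = []
    for vname, vclass in params.varieties:
        for stage in STAGES:
            for rep in range(1, params.replicates + 1):
                metas.append(
                    SampleMeta(f"{vname}_{stage}_r{rep}", vname, vclass,
                               stage, rep)
                )
    return metas


def _correlated_block(
    rng: np.random.Generator,
    bait_vals: np.ndarray,
    n_targets: int,
    rho: float,
    means: np.ndarray,
) -> np.ndarray:
    """Target rows t = mu + s * (rho * z_bait + sqrt(1-rho^2) * eps).

    z_bait is the observed bait vector standardized over the given
    samples and s its standard deviation, so each target tracks the bait
    trajectory with expected Pearson correlation rho against the bait's
    observed values.
    """
    s = bait_vals.std()
    z = (bait_vals - bait_vals.mean()) / s
    eps = rng.standard_normal((n_targets, bait_vals.size))
    signal = rho * z[None, :] + np.sqrt(1.0 - rho * rho) * eps
    return means[:, None] + s * signal


def _primary_log2(
    params: SimulationParams,
    rng: np.random.Generator,
    genes: list[str],
    metas: list[SampleMeta],
    bait_idx: int,
    target_idx: np.ndarray,
    deg_idx: np.ndarray,
    null: bool,
) -> pd.DataFrame:
    n_genes, n_samples = params.n_genes, len(metas)
    lo, hi = params.baseline_range
    baselines = rng.uniform(lo, hi, n_genes)
    vals = baselines[:, None] + rng.normal(0.0, params.noise_sd,
                                           (n_genes, n_samples))
    if not null:
        sd_mean = dict(zip(STAGES, params.bait_profile_sd))
        sl_mean = dict(zip(STAGES, params.bait_profile_sl))
        stage_idx = {s: i for i, s in enumerate(STAGES)}
        is_sd = np.array([m.seed_class == "SD" for m in metas])
        bait_means = np.array(
            [sd_mean[m.stage] if m.seed_class == "SD" else sl_mean[m.stage]
             for m in metas]
        )
        vals[bait_idx] = bait_means + rng.normal(0.0, params.noise_sd,
                                                 n_samples)
        # targets: track the bait over the SD samples, sit at baseline in
        # SL with an extra down-shift at S2-S4 (seedless down-regulation)
        sd_cols = np.flatnonzero(is_sd)
        sl_cols = np.flatnonzero(~is_sd)
        t_means = baselines[target_idx]
        vals[np.ix_(target_idx, sd_cols)] = _correlated_block(
            rng, vals[bait_idx, sd_cols], target_idx.size,
            params.target_correlation, t_means,
        )
        late = np.array(
            [stage_idx[metas[c].stage] >= 1 for c in sl_cols]
        )
        shift = np.where(late, params.deg_log2fc / 2.0, 0.0)
        vals[np.ix_(target_idx, sl_cols)] -= shift[None, :]
        # extra DEGs: up in SD at S3 only
        s3_sd = np.flatnonzero(
            [m.stage == "S3" and m.seed_class == "SD" for m in metas]
        )
        vals[np.ix_(deg_idx, s3_sd)] += params.deg_log2fc
    return pd.DataFrame(vals, index=genes,
                        columns=[m.sample_id for m in metas])


def _aux_matrix(
    params: SimulationParams,
    rng: np.random.Generator,
    genes: list[str],
    bait_idx: int,
    target_idx: np.ndarray,
    d: int,
    null: bool,
) -> ExpressionMatrix:
    n_genes, n_samples = params.n_genes, params.aux_n_samples
    lo, hi = params.baseline_range
    baselines = rng.uniform(lo, hi, n_genes)
    vals = baselines[:, None] + rng.normal(0.0, params.noise_sd,
                                           (n_genes, n_samples))
    if not null:
        # bait varies strongly across the atlas-like samples
        vals[bait_idx] = 8.0 + rng.normal(0.0, 2.0, n_samples)
        vals[target_idx] = _correlated_block(
            rng, vals[bait_idx], target_idx.size,
            params.target_correlation, baselines[target_idx],
        )
    # nominal design metadata: auxiliary datasets are tissue atlases, the
    # seed-experiment factors do not apply and are filled cyclically
    metas = [
        SampleMeta(
            f"aux{d}_s{i:02d}", f"atlas{d}",
            "SD" if i % 2 == 0 else "SL",
            STAGES[i % 4], i // 4 + 1,
        )
        for i in range(n_samples)
    ]
    df = pd.DataFrame(
        np.exp2(vals), index=genes, columns=[m.sample_id for m in metas]
    )
    return ExpressionMatrix(df, metas, log2=False)


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _carg_sites(seq: str) -> list[tuple[int, int]]:
    """All (0-based start, width) CArG matches on the plus strand."""
    return sorted(
        (m.start(), w)
        for w, pat in _CARG_RE.items()
        for m in pat.finditer(seq)
    )


def _clean_background(rng: np.random.Generator, length: int) -> str:
    """Uniform A/C/G/T sequence rejection-sampled to be CArG-free.

    Matches are removed by re-randomizing their windows rather than
    regenerating the whole sequence; each pass can only create new
    matches near re-drawn windows, and the loop converges quickly.
    """
    arr = rng.choice(_BASES, size=length)
    for _ in range(200):
        seq = arr.tobytes().decode()
        sites = _carg_sites(seq)
        if not sites:
            return seq
        for start, w in sites:
            arr[start:start + w] = rng.choice(_BASES, size=w)
    raise RuntimeError("rejection sampling failed to converge")


def _promoter_with_motifs(
    rng: np.random.Generator, length: int, n_motifs: int
) -> tuple[str, list[tuple[int, int, str]]]:
    """CArG-free background with exactly n_motifs planted boxes.

    Accepts only when the scan of the finished sequence finds exactly
    the planted sites, so junction artifacts cannot slip through.
    """
    for _ in range(100):
        seq = list(_clean_background(rng, length))
        planted: list[tuple[int, int]] = []  # (start0, width)
        taken: list[tuple[int, int]] = []
        ok = True
        for _ in range(n_motifs):
            w = int(rng.choice(CARG_WIDTHS))
            for _ in range(100):
                start = int(rng.integers(0, length - w + 1))
                if all(start + w <= s or start >= s + tw
                       for s, tw in taken):
                    break
            else:
                ok = False
                break
            core = "".join("AT"[b] for b in rng.integers(0, 2, w - 4))
            seq[start:start + w] = f"CC{core}GG"
            planted.append((start, w))
            taken.append((start, w))
        if not ok:
            continue
        final = "".join(seq)
        if _carg_sites(final) == sorted(planted):
            positions = [
                (s + 1, s + w, "+") for s, w in sorted(planted)
            ]
            return final, positions
    raise RuntimeError("motif planting failed to converge")


def _make_promoters(
    params: SimulationParams,
    rng: np.random.Generator,
    genes: list[str],
    target_ids: set[str],
) -> tuple[list[PromoterRecord], dict[str, list[tuple[int, int, str]]]]:
    records = []
    positions: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        if g in target_ids and params.motif_per_target > 0:
            seq, pos = _promoter_with_motifs(
                rng, params.promoter_length, params.motif_per_target
            )
            positions[g] = pos
        else:
            seq = _clean_background(rng, params.promoter_length)
        records.append(PromoterRecord(gene_id=g, sequence=seq))
    return records, positions


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _generate(
    params: SimulationParams, null: bool, with_promoters: bool
) -> tuple[ExpressionMatrix, list[ExpressionMatrix], list[PromoterRecord],
           SyntheticTruth]:
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    prim_seed, aux_seed, prom_seed = ss.spawn(3)

    genes = _gene_ids(params.n_genes)
    bait_idx = 0
    target_idx = np.arange(1, 1 + params.n_targets)
    deg_idx = np.arange(1 + params.n_targets,
                        1 + params.n_targets + params.n_deg_extra)
    metas = _design(params)

    rng = np.random.default_rng(prim_seed)
    log2_primary = _primary_log2(
        params, rng, genes, metas, bait_idx, target_idx, deg_idx, null
    )
    primary = ExpressionMatrix(np.exp2(log2_primary), metas, log2=False)

    aux_rng = np.random.default_rng(aux_seed)
    aux = [
        _aux_matrix(params, aux_rng, genes, bait_idx, target_idx, d, null)
        for d in range(params.n_aux_datasets)
    ]

    target_ids = set() if null else {genes[i] for i in target_idx}
    deg_by_stage = (
        {} if null else {"S3": {genes[i] for i in deg_idx}}
    )

    if with_promoters:
        prom_rng = np.random.default_rng(prom_seed)
        promoters, motif_pos = _make_promoters(
            params, prom_rng, genes, set() if null else target_ids
        )
    else:
        promoters, motif_pos = [], {}

    truth = SyntheticTruth(
        bait_id=genes[bait_idx],
        target_ids=target_ids,
        deg_ids_by_stage=deg_by_stage,
        motif_positions=motif_pos,
        params=params,
    )
    return primary, aux, promoters, truth


def generate_experiment(
    params: SimulationParams, with_promoters: bool = True
) -> tuple[ExpressionMatrix, list[ExpressionMatrix], list[PromoterRecord],
           SyntheticTruth]:
    """Simulate the full seeded-vs-seedless experiment with planted truth."""
    return _generate(params, null=False, with_promoters=with_promoters)


def synthetic_regulatory_region(
    length: int = 2147,
    n_boxes: int = 4,
    seed: int = 0,
    gene_id: str = "bait_promoter_synthetic",
) -> tuple[PromoterRecord, list[tuple[int, int, str]]]:
    """Synthetic stand-in for the bait's own upstream regulatory region.

    A uniform-composition sequence of the given length carrying exactly
    ``n_boxes`` planted CArG boxes at recorded positions, emulating a
    MADS-box gene promoter that is bound by its own product.  This is a
    synthetic construct, not a cloned sequence; it exists so the scanner
    can be exercised on a realistic promoter-sized worked example with
    known truth.
    """
    rng = np.random.default_rng(seed)
    seq, positions = _promoter_with_motifs(rng, length, n_boxes)
    return PromoterRecord(gene_id=gene_id, sequence=seq), positions


def generate_null(
    params: SimulationParams, with_promoters: bool = True
) -> tuple[ExpressionMatrix, list[ExpressionMatrix], list[PromoterRecord],
           SyntheticTruth]:
    """Simulate pure noise: no bait structure, no DEGs, no motifs.

    The designated bait is an ordinary noise gene; truth sets are empty.
    Used to calibrate type-I error of the differential-expression and
    profile-significance stages.
    """
    return _generate(params, null=True, with_promoters=with_promoters)
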