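"""Short time-series profile clustering with permutation significance.

Genes are summarized per variety as log2 fold-change trajectories
anchored at the first stage (v1 = 0).  Candidate model profiles are all
integer trajectories starting at 0 whose successive steps change by at
most c units; m representatives are chosen by greedy max-min distance,
each gene is assigned to its best-correlated profile, and profile
enrichment is judged against the exact permutation null over all T!
stage orderings with a binomial tail and Bonferroni correction — the
scheme of the Short Time-series Expression Miner, made exact for the
small T used here (T! = 24 orderings at four stages).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import STAGES, ExpressionMatrix


@dataclass
class StemConfig:
    unit_change_c: int = 1
    n_model_profiles_m: int = 15
    alpha: float = 0.05
    max_permutations: int = 40320  # 8! — exact enumeration cap

    def __post_init__(self) -> None:
        if self.unit_change_c < 0:
            raise ValueError("unit_change_c must be >= 0")
        if self.n_model_profiles_m < 1:
            raise ValueError("n_model_profiles_m must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ModelProfile:
    profile_id: int
    trajectory: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.trajectory[0] != 0:
            raise ValueError("profile trajectories are anchored at 0")


@dataclass
class ProfileClustering:
    """Result of one variety's clustering run."""

    variety: str
    profiles: list[ModelProfile]
    assignment: pd.Series  # gene -> profile_id (NaN = unassigned)
    table: pd.DataFrame  # profile_id, trajectory, observed, expected, p, sig
    n_assigned: int
    config: StemConfig = field(repr=False, default=None)

    def genes_in_profile(self, profile_id: int) -> set[str]:
        known = {p.profile_id for p in self.profiles}
        if profile_id not in known:
            raise KeyError(f"unknown profile_id {profile_id}")
        return set(self.assignment.index[self.assignment == profile_id])


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def to_foldchange_trajectory(
    matrix: ExpressionMatrix, variety: str, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene stage trajectories: mean log2 per stage minus stage 1.

    Genes with any missing stage mean are dropped (unassignable).
    """
    log2 = matrix.log2_values()
    stage_means = {}
    for stage in STAGES:
        ids = matrix.select_samples({"variety": variety, "stage": stage})
        if not ids:
            raise ValueError(f"variety {variety!r} has no samples at {stage}")
        stage_means[stage] = log2[ids].mean(axis=1)
    traj = pd.DataFrame(stage_means)
    if genes is not None:
        traj = traj.loc[[g for g in genes if g in traj.index]]
    traj = traj.dropna()
    return traj.sub(traj[STAGES[0]], axis=0)


# ---------------------------------------------------------------------------
# model profiles
# ---------------------------------------------------------------------------

def enumerate_candidate_profiles(T: int, c: int) -> list[ModelProfile]:
    """All (2c+1)^(T-1) integer trajectories anchored at 0.

    Successive differences lie in {-c..c}; order is lexicographic in the
    step sequence, so the enumeration is deterministic.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if c < 0:
        raise ValueError("c must be >= 0")
    profiles = []
    for i, steps in enumerate(
        itertools.product(range(-c, c + 1), repeat=T - 1)
    ):
        traj = (0, *itertools.accumulate(steps))
        profiles.append(ModelProfile(i, tuple(traj)))
    return profiles


def _profile_distance(p: tuple[int, ...], q: tuple[int, ...]) -> float:
    """1 - Pearson; Euclidean fallback when either trajectory is flat."""
    pa, qa = np.asarray(p, float), np.asarray(q, float)
    if pa.std() == 0 or qa.std() == 0:
        return float(np.linalg.norm(pa - qa))
    return float(1.0 - np.corrcoef(pa, qa)[0, 1])


def select_model_profiles(
    candidates: list[ModelProfile], m: int
) -> list[ModelProfile]:
    """Greedy max-min representative selection, seeded at the flat profile.

    Repeatedly adds the candidate whose minimum distance to the selected
    set is largest; ties break on lexicographic trajectory order.
    """
    if m > len(candidates):
        raise ValueError(f"m = {m} exceeds {len(candidates)} candidates")
    T = len(candidates[0].trajectory)
    flat = (0,) * T
    by_traj = {p.trajectory: p for p in candidates}
    if flat not in by_traj:
        raise ValueError("candidate set lacks the flat anchor profile")
    selected = [by_traj[flat]]
    remaining = [p for p in candidates if p.trajectory != flat]
    while len(selected) < m:
        best = max(
            remaining,
            key=lambda p: (
                min(_profile_distance(p.trajectory, s.trajectory)
                    for s in selected),
                tuple(-x for x in p.trajectory),
            ),
        )
        selected.append(best)
        remaining.remove(best)
    return selected


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def _correlation_table(
    traj: np.ndarray, profiles: list[ModelProfile]
) -> tuple[np.ndarray, np.ndarray]:
    """Genes x profiles Pearson matrix; flat profiles get -inf columns."""
    P = np.array([p.trajectory for p in profiles], dtype=float)
    p_sd = P.std(axis=1)
    g_sd = traj.std(axis=1)
    Pz = np.zeros_like(P)
    ok = p_sd > 0
    Pz[ok] = (P[ok] - P[ok].mean(axis=1, keepdims=True)) / p_sd[ok, None]
    gz = np.zeros_like(traj)
    gok = g_sd > 0
    gz[gok] = (traj[gok] - traj[gok].mean(axis=1, keepdims=True)) / g_sd[gok, None]
    corr = gz @ Pz.T / traj.shape[1]
    corr[:, ~ok] = -np.inf
    corr[~gok, :] = -np.inf
    return corr, gok


def assign_genes(
    trajectories: pd.DataFrame, profiles: list[ModelProfile]
) -> pd.Series:
    """Best-correlated model profile per gene.

    Flat (zero-variance) gene trajectories stay unassigned, flat model
    profiles are never assignment targets, and correlation ties resolve
    to the lowest profile_id.
    """
    ids = np.array([p.profile_id for p in profiles])
    order = np.argsort(ids, kind="stable")
    profs = [profiles[i] for i in order]
    corr, gok = _correlation_table(trajectories.to_numpy(float), profs)
    # argmax scans in ascending profile_id order, so ties pick the lowest
    best = np.argmax(corr, axis=1)
    assigned = np.where(gok, ids[order][best].astype(float), np.nan)
    return pd.Series(assigned, index=trajectories.index, name="profile_id")


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def profile_significance(
    assignment: pd.Series,
    trajectories: pd.DataFrame,
    profiles: list[ModelProfile],
    config: StemConfig | None = None,
    variety: str = "",
) -> ProfileClustering:
    """Exact permutation test of per-profile gene counts.

    For every ordering of the T stages the trajectories are re-ordered,
    re-anchored at the first element and re-assigned; the expected count
    E_p is the mean count over all T! orderings (the identity ordering
    included).  The p-value is the binomial tail
    P(X >= observed | n assigned genes, E_p / n), and a profile is
    significant when p <= alpha / m (Bonferroni over the m profiles).
    """
    config = config or StemConfig()
    T = trajectories.shape[1]
    if math.factorial(T) > config.max_permutations:
        raise ValueError(
            f"T = {T} gives {math.factorial(T)} orderings, above the exact "
            "enumeration cap; a sampled permutation mode is not implemented"
        )
    traj = trajectories.to_numpy(float)
    observed = assignment.dropna().astype(int)
    n = len(observed)
    ids = [p.profile_id for p in profiles]
    obs_counts = observed.value_counts().reindex(ids, fill_value=0)

    perm_counts = np.zeros((math.factorial(T), len(ids)))
    for k, perm in enumerate(itertools.permutations(range(T))):
        v = traj[:, perm]
        v = v - v[:, [0]]
        assigned = assign_genes(
            pd.DataFrame(v, index=trajectories.index), profiles
        ).dropna().astype(int)
        counts = assigned.value_counts().reindex(ids, fill_value=0)
        perm_counts[k] = counts.to_numpy()
    expected = perm_counts.mean(axis=0)

    m = len(ids)
    if n > 0:
        prob = np.clip(expected / n, 0.0, 1.0)
        pvals = stats.binom.sf(obs_counts.to_numpy() - 1, n, prob)
    else:
        pvals = np.ones(m)
    significant = pvals <= config.alpha / m

    table = pd.DataFrame(
        {
            "profile_id": ids,
            "trajectory": [
                ",".join(map(str, p.trajectory)) for p in profiles
            ],
            "observed": obs_counts.to_numpy(),
            "expected": expected,
            "p_value": pvals,
            "significant": significant,
        }
    ).set_index("profile_id")
    return ProfileClustering(
        variety=variety,
        profiles=list(profiles),
        assignment=assignment,
        table=table,
        n_assigned=n,
        config=config,
    )


def cluster_deg_overlap(
    clustering: ProfileClustering, deg_ids: set[str], profile_id: int
) -> tuple[int, set[str]]:
    """Genes shared between one profile's cluster and a DEG set."""
    members = clustering.genes_in_profile(profile_id)
    shared = members & deg_ids
    return len(shared), shared
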