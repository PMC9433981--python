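"""End-to-end orchestration: simulate or load, normalize, DEG, profiles,
co-expression ranking, motif scan, reports.

A single :class:`RunConfig` (loadable from YAML) drives the whole run.
Every stage writes its tables under the output directory and the run
report records per-stage counts, thresholds and the seed, so that a rerun
with the same config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import io as sio
from .deg import (DEGConfig, deg_sets, differential_expression,
                  filter_negative_signals, percentile_normalize,
                  venn_partition)
from .motifs import motif_summary, scan_carg, write_hits
from .profiles import (StemConfig, assign_genes, enumerate_candidate_profiles,
                       profile_significance, select_model_profiles,
                       to_foldchange_trajectory)
from .ranking import CandidateRanking, DatasetSpec, ScoringConfig, score_candidates
from .simulate import (SimulationParams, SyntheticTruth, generate_experiment)
from .types import STAGES, ExpressionMatrix, PromoterRecord

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    sim: SimulationParams = field(default_factory=SimulationParams)
    primary_matrix: str | None = None
    sample_sheet: str | None = None
    aux_matrices: list[str] = field(default_factory=list)
    aux_sheets: list[str] = field(default_factory=list)
    promoters: str | None = None
    bait_id: str | None = None  # required in files mode
    deg: DEGConfig = field(default_factory=DEGConfig)
    stem: StemConfig = field(default_factory=StemConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    out_dir: str = "run_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("mode", "primary_matrix", "sample_sheet", "promoters",
                    "bait_id", "out_dir", "seed", "log_level",
                    "aux_matrices", "aux_sheets"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "sim" in raw:
            cfg.sim = SimulationParams(**raw["sim"])
        if "deg" in raw:
            cfg.deg = DEGConfig(**raw["deg"])
        if "stem" in raw:
            cfg.stem = StemConfig(**raw["stem"])
        if "scoring" in raw:
            sc = dict(raw["scoring"])
            if "datasets" in sc:
                sc["datasets"] = [DatasetSpec(**d) for d in sc["datasets"]]
            cfg.scoring = ScoringConfig(**sc)
        if cfg.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {cfg.mode!r}")
        return cfg


def _default_datasets(n_aux: int) -> list[DatasetSpec]:
    """Primary + auxiliary datasets; the last auxiliary uses HRR.

    Mirrors the common setup of one in-house experiment, one expression
    atlas queried by Pearson correlation, and one co-expression database
    queried by the HRR network measure.
    """
    specs = [DatasetSpec("primary", "pearson")]
    for d in range(n_aux):
        measure = "hrr" if (n_aux > 1 and d == n_aux - 1) else "pearson"
        specs.append(DatasetSpec(f"aux{d}", measure))
    return specs


def _load_inputs(config: RunConfig):
    if config.mode == "synthetic":
        sim = dataclasses.replace(config.sim, seed=config.seed)
        primary, aux, promoters, truth = generate_experiment(sim)
        bait = truth.bait_id
    else:
        for pth, what in ((config.primary_matrix, "primary matrix"),
                          (config.sample_sheet, "sample sheet")):
            if pth is None or not Path(pth).exists():
                raise FileNotFoundError(f"missing {what}: {pth}")
        primary = sio.read_expression_matrix(
            config.primary_matrix, config.sample_sheet
        )
        aux = [
            sio.read_expression_matrix(m, s)
            for m, s in zip(config.aux_matrices, config.aux_sheets)
        ]
        promoters = (
            sio.read_promoters(config.promoters) if config.promoters else []
        )
        truth = None
        if config.bait_id is None:
            raise ValueError("files mode requires bait_id")
        bait = config.bait_id
    return primary, aux, promoters, truth, bait


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage in order and return the run report."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed,
        "mode": config.mode,
        "thresholds": {
            "p_threshold": config.deg.p_threshold,
            "fc_threshold": config.deg.fc_threshold,
            "percentile": config.deg.percentile,
            "n_model_profiles": config.stem.n_model_profiles_m,
            "alpha": config.stem.alpha,
            "r_min": config.scoring.r_min,
            "hrr_max": config.scoring.hrr_max,
            "top_k": config.scoring.top_k,
        },
        "stages": {},
    }
    stage = "load"
    try:
        primary, aux, promoters, truth, bait = _load_inputs(config)
        sio.write_expression_matrix(primary, out / "primary_matrix.tsv")
        sio.write_sample_sheet(primary.samples, out / "primary_samples.tsv")
        for d, mat in enumerate(aux):
            sio.write_expression_matrix(mat, out / f"aux{d}_matrix.tsv")
            sio.write_sample_sheet(mat.samples, out / f"aux{d}_samples.tsv")
        if promoters:
            sio.write_promoters(promoters, out / "promoters.fasta")
        report["stages"]["load"] = {
            "n_genes": primary.n_genes,
            "n_samples": primary.n_samples,
            "n_aux": len(aux),
            "bait_id": bait,
        }

        stage = "normalize"
        filtered = filter_negative_signals(primary)
        normalized = percentile_normalize(filtered, config.deg)
        sio.write_expression_matrix(normalized, out / "normalized_matrix.tsv")
        report["stages"]["normalize"] = {
            "genes_after_filter": filtered.n_genes,
            "genes_removed": primary.n_genes - filtered.n_genes,
        }

        stage = "deg"
        deg_tables = {}
        for st in STAGES:
            table = differential_expression(
                normalized, {"seed_class": "SD"}, {"seed_class": "SL"},
                stage=st, config=config.deg,
            )
            table.to_csv(out / f"deg_{st}.tsv", sep="\t", na_rep="NA")
            deg_tables[st] = table
        per_stage = {st: deg_sets(t) for st, t in deg_tables.items()}
        report["stages"]["deg"] = {
            st: {"up": len(s["up"]), "down": len(s["down"])}
            for st, s in per_stage.items()
        }
        venn = venn_partition(
            {st: per_stage[st]["all"] for st in ("S2", "S3", "S4")}
        )
        with open(out / "venn_regions.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"&".join(k): v[0] for k, v in sorted(venn.items())},
                fh, indent=2, sort_keys=True,
            )

        stage = "profiles"
        s3_degs = sorted(per_stage["S3"]["all"])
        candidates = enumerate_candidate_profiles(len(STAGES),
                                                  config.stem.unit_change_c)
        model = select_model_profiles(candidates,
                                      config.stem.n_model_profiles_m)
        clusterings = {}
        for vname, _ in (config.sim.varieties if config.mode == "synthetic"
                         else [(v, None) for v in
                               sorted({s.variety for s in primary.samples})]):
            traj = to_foldchange_trajectory(normalized, vname, genes=s3_degs)
            assignment = assign_genes(traj, model)
            clustering = profile_significance(
                assignment, traj, model, config.stem, variety=vname
            )
            clustering.table.to_csv(
                out / f"profiles_{vname}.tsv", sep="\t", na_rep="NA"
            )
            clusterings[vname] = clustering
        report["stages"]["profiles"] = {
            v: {
                "n_assigned": c.n_assigned,
                "significant_profiles":
                    [int(i) for i in c.table.index[c.table["significant"]]],
            }
            for v, c in clusterings.items()
        }

        stage = "rank"
        scoring = dataclasses.replace(
            config.scoring,
            bait_id=bait,
            datasets=(config.scoring.datasets
                      or _default_datasets(len(aux))),
        )
        matrices = {"primary": normalized}
        for d, mat in enumerate(aux):
            matrices[f"aux{d}"] = mat
        ranking = score_candidates(normalized, matrices, scoring)
        sio.write_ranking(ranking, out / "ranking.tsv")
        report["stages"]["rank"] = {
            "n_scored": int(len(ranking.table)),
            "n_excluded": ranking.excluded,
            "top_k": scoring.top_k,
        }
        if truth is not None and truth.target_ids:
            top = ranking.top_k_ids
            hits = len(top & truth.target_ids)
            report["stages"]["rank"]["target_recall"] = (
                hits / len(truth.target_ids)
            )
            report["stages"]["rank"]["target_precision"] = (
                hits / min(scoring.top_k, max(len(top), 1))
            )

        stage = "scan"
        if promoters:
            hits = [h for p in promoters for h in scan_carg(p)]
            write_hits(hits, out / "motif_hits.tsv")
            summary = motif_summary(promoters)
            summary.to_csv(out / "motif_summary.tsv", sep="\t", index=False)
            report["stages"]["scan"] = {
                "n_promoters": len(promoters),
                "n_hits": len(hits),
                "genes_with_hits": int((summary["n_hits"] > 0).sum()),
            }
    except Exception as exc:
        report["error"] = {"stage": stage, "message": str(exc)}
        report["incomplete"] = True
        with open(out / "run_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report["wall_time_s"] = round(time.time() - t0, 3)
    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
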