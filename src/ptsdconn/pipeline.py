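"""End-to-end pipeline driver.

Runs the stages in study order — connectome assembly, clinical outcome
scores, NBS on baseline patients against the residual change score,
composite and network-pair metrics, baseline group tests, group-by-time
ANOVA, and LOOCV outcome prediction — writing every intermediate
artifact plus a run log carrying the config hash and seeds, so a rerun
with the same config reproduces all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .atlas import ParcelAtlas
from .clinical import derive_outcomes, response_groups, summarize_cohort
from .composite import (
    baseline_group_tests,
    composite_metric,
    fdr_adjust_table,
    group_by_time_anova,
    network_pair_means,
)
from .connectivity import (
    DEFAULT_BAND,
    DEFAULT_DVARS_THRESHOLD,
    DEFAULT_FD_THRESHOLD,
    compute_connectome,
    preprocess_run,
)
from .errors import ConfigurationError, InputError
from .nbs import DEFAULT_ALPHA, DEFAULT_N_PERM, DEFAULT_THRESHOLD_P, nbs
from .predict import compare_models, feature_table, loocv_predict

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run (YAML-serialisable)."""

    atlas_path: str
    clinical_path: str
    output_dir: str
    connectome_dir: str | None = None  # precomputed connectome TSVs
    timeseries_dir: str | None = None  # else raw runs to preprocess
    fd_threshold: float = DEFAULT_FD_THRESHOLD
    dvars_threshold: float = DEFAULT_DVARS_THRESHOLD
    band: tuple[float, float] = DEFAULT_BAND
    threshold_p: float = DEFAULT_THRESHOLD_P
    n_perm: int = DEFAULT_N_PERM
    alpha: float = DEFAULT_ALPHA
    tail: str = "two_sided"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        if cfg.band is not None:
            cfg.band = tuple(cfg.band)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_connectomes(config: PipelineConfig, atlas: ParcelAtlas):
    if config.connectome_dir:
        paths = sorted(Path(config.connectome_dir).glob("*.tsv"))
        if not paths:
            raise InputError(f"no connectome TSVs in {config.connectome_dir}")
        return [pio.read_connectome(p, atlas) for p in paths]
    if config.timeseries_dir:
        d = Path(config.timeseries_dir)
        metas = sorted(d.glob("*_meta.json"))
        if not metas:
            raise InputError(f"no runs in {config.timeseries_dir}")
        by_subject: dict[tuple[str, str], list] = {}
        for m in metas:
            stem = m.name[: -len("_meta.json")]
            run = pio.read_run(d, stem)
            by_subject.setdefault((run.subject_id, run.session), []).append(run)
        conns = []
        for (sid, session), runs in sorted(by_subject.items()):
            prepped = [
                preprocess_run(r, config.fd_threshold, config.dvars_threshold,
                               config.band)
                for r in runs
            ]
            conns.append(
                compute_connectome(prepped, atlas, subject_id=sid, session=session)
            )
        return conns
    raise ConfigurationError("config needs connectome_dir or timeseries_dir")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report bundle (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "python": platform.python_version(),
    }
    stage = "setup"
    try:
        stage = "atlas"
        atlas = pio.read_atlas(config.atlas_path)

        stage = "connectomes"
        connectomes = _load_connectomes(config, atlas)
        baseline = {c.subject_id: c for c in connectomes if c.session == "baseline"}
        post = {c.subject_id: c for c in connectomes if c.session == "post"}

        stage = "clinical_scores"
        cohort = derive_outcomes(pio.read_clinical(config.clinical_path))
        pio.write_clinical(cohort, out / "clinical_scored.csv")
        summarize_cohort(cohort).to_csv(out / "cohort_summary.tsv", sep="\t",
                                        index=False)

        stage = "nbs"
        pats = cohort[
            cohort["group"].eq("patient")
            & cohort["residual_change"].notna()
            & cohort["subject_id"].isin(baseline)
        ]
        edge_matrix = np.vstack(
            [baseline[s].edge_vector() for s in pats["subject_id"]]
        )
        result = nbs(
            edge_matrix,
            pats["residual_change"].to_numpy(dtype=float),
            kind="correlation",
            threshold_p=config.threshold_p,
            n_perm=config.n_perm,
            alpha=config.alpha,
            tail=config.tail,
            seed=config.seed,
        )
        pio.write_nbs_result(result, atlas, out)
        report: dict = {
            "atlas_id": atlas.atlas_id,
            "n_subjects": len(connectomes),
            "nbs_component_sizes": list(map(int, result.component_sizes)),
            "nbs_corrected_p": [float(p) for p in result.corrected_p],
            "n_significant_edges": len(result.significant_edges),
        }

        if result.any_significant:
            stage = "composite"
            edge_set = result.significant_edges
            order = cohort["subject_id"].tolist()
            have_base = [s for s in order if s in baseline]
            conns_base = [baseline[s] for s in have_base]
            comp = composite_metric(conns_base, edge_set)
            comp_series = pd.Series(comp, index=have_base, name="composite_z")
            pairs = network_pair_means(conns_base, atlas, edge_set)
            pair_df = pd.DataFrame(
                {f"{a}|{b}": s.mean_z for (a, b), s in
                 ((p.pair, p) for p in pairs)},
                index=have_base,
            )
            pair_df.insert(0, "composite_z", comp)
            pair_df.to_csv(out / "composite_metrics.tsv", sep="\t",
                           index_label="subject_id")

            stage = "baseline_group_tests"
            rg = response_groups(cohort.set_index("subject_id").loc[have_base]
                                 .reset_index())
            ok = rg.notna().to_numpy()
            tables = [baseline_group_tests(comp[ok], rg[ok].to_numpy(),
                                           measure="composite")]
            for p in pairs:
                tables.append(
                    baseline_group_tests(
                        p.mean_z[ok], rg[ok].to_numpy(),
                        measure=f"{p.pair[0]}|{p.pair[1]}",
                    )
                )
            baseline_table = fdr_adjust_table(pd.concat(tables, ignore_index=True))
            baseline_table.to_csv(out / "baseline_group_tests.tsv", sep="\t",
                                  index=False)
            report["baseline_tests"] = len(baseline_table)

            stage = "group_by_time"
            have_both = [s for s in have_base if s in post]
            if have_both:
                pre_vals = composite_metric([baseline[s] for s in have_both],
                                            edge_set)
                post_vals = composite_metric([post[s] for s in have_both],
                                             edge_set)
                rg2 = response_groups(
                    cohort.set_index("subject_id").loc[have_both].reset_index()
                )
                ok2 = rg2.notna().to_numpy()
                gxt = group_by_time_anova(pre_vals[ok2], post_vals[ok2],
                                          rg2[ok2].to_numpy(),
                                          alpha=config.alpha)
                gxt["anova"].to_csv(out / "group_by_time_anova.tsv", sep="\t",
                                    index=False)
                gxt["posthoc"].to_csv(out / "group_by_time_posthoc.tsv", sep="\t",
                                      index=False)
                report["interaction_p"] = gxt["interaction_p"]

            stage = "prediction"
            pred_cohort = cohort[cohort["subject_id"].isin(have_base)
                                 & cohort["responder"].notna()]
            labels = pred_cohort["responder"].astype(bool).to_numpy()
            if len(pred_cohort) >= 6 and labels.any() and not labels.all():
                base_x = feature_table(pred_cohort)
                aug_x = feature_table(
                    pred_cohort,
                    composite=comp_series.loc[pred_cohort["subject_id"]],
                )
                base_res = loocv_predict(base_x, labels, seed=config.seed)
                aug_res = loocv_predict(aug_x, labels, seed=config.seed)
                p_cmp = compare_models(base_res, aug_res, seed=config.seed)
                metrics = {
                    "base": {"accuracy": base_res.accuracy,
                             "sensitivity": base_res.sensitivity,
                             "specificity": base_res.specificity,
                             "features": base_res.feature_names},
                    "augmented": {"accuracy": aug_res.accuracy,
                                  "sensitivity": aug_res.sensitivity,
                                  "specificity": aug_res.specificity,
                                  "features": aug_res.feature_names},
                    "comparison_p": p_cmp,
                }
                (out / "prediction_metrics.json").write_text(
                    json.dumps(metrics, indent=2)
                )
                pd.DataFrame(
                    {
                        "subject_id": pred_cohort["subject_id"].to_numpy(),
                        "true": labels,
                        "pred_base": base_res.predicted,
                        "proba_base": base_res.probability,
                        "pred_augmented": aug_res.predicted,
                        "proba_augmented": aug_res.probability,
                    }
                ).to_csv(out / "prediction_folds.tsv", sep="\t", index=False)
                report["prediction"] = metrics
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    provenance["report"] = _jsonable(report)
    (out / "run_log.json").write_text(json.dumps(provenance, indent=2))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
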