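"""End-to-end orchestration: synthesize/load -> preprocess ->
microstates -> connectivity -> statistics -> report.

Statistics are always computed from per-participant values (one value
per participant x condition x microstate class); grand-average
quantities are only ever used for the shared template set, mirroring
standard microstate practice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from msconn import connectivity as conn
from msconn import io as msio
from msconn import microstate as ms
from msconn import stats as msstats
from msconn import synthetic
from msconn.config import CONDITIONS, RunConfig
from msconn.preprocess import EpochedData, ERP, preprocess_participant

logger = logging.getLogger("msconn")

#: default rating cell means for synthetic runs: valence is lower for
#: negative material, reappraisal sits between Neg and Neu, and the
#: music group rates slightly more positively.
DEFAULT_VALENCE_MEANS = {
    ("music", "Neg"): 2.6, ("music", "Rea"): 4.3, ("music", "Neu"): 6.6,
    ("control", "Neg"): 2.4, ("control", "Rea"): 4.0, ("control", "Neu"): 6.4,
}
DEFAULT_RATING_SD = 0.8


@dataclass
class RunReport:
    config: dict
    selected_k: int = 0
    n_participants: int = 0
    stage_counts: list = field(default_factory=list)
    durations_table: pd.DataFrame | None = None
    metrics_table: pd.DataFrame | None = None
    anova_table: pd.DataFrame | None = None
    ratings_table: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        return {
            "config": self.config,
            "selected_k": self.selected_k,
            "n_participants": self.n_participants,
            "stage_counts": self.stage_counts,
            "n_duration_rows": 0 if self.durations_table is None else len(self.durations_table),
            "n_metric_rows": 0 if self.metrics_table is None else len(self.metrics_table),
        }


def _anova_rows(metric: str, cls_label: str, results: dict[str, msstats.AnovaResult]) -> list[dict]:
    rows = []
    for effect, res in results.items():
        posthoc = ""
        if res.posthoc is not None:
            sig = res.posthoc[res.posthoc["p_adj"] < 0.05]
            posthoc = "; ".join(
                f"{r.comparison} (p={r.p_adj:.3g})" for r in sig.itertuples()
            )
        rows.append(
            {
                "metric": metric,
                "MS": cls_label,
                "effect": effect,
                "F": res.F,
                "df1": res.df1,
                "df2": res.df2,
                "p": res.p,
                "gg_applied": res.gg_applied,
                "epsilon": res.epsilon,
                "posthoc_significant": posthoc,
            }
        )
    return rows


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> RunReport:
    """Execute the full analysis described by ``config``."""
    logging.basicConfig(level=config.log_level)
    report = RunReport(config=json.loads(config.model_dump_json()))
    out_dir = Path(config.out_dir)

    # ------------------------------------------------------------------ input
    if config.input_dir is not None:
        cohort = msio.read_cohort(config.input_dir)
        ratings = None
        logger.info("loaded %d participants from %s", len(cohort), config.input_dir)
    else:
        gen = config.synthetic.model_copy(update={"seed": config.seed})
        cohort, _truths, _templates = synthetic.simulate_cohort(gen)
        ratings = synthetic.simulate_ratings(
            DEFAULT_VALENCE_MEANS,
            DEFAULT_RATING_SD,
            {
                "music": gen.n_participants_music,
                "control": gen.n_participants_control,
            },
            seed=config.seed + 101,
        )
        logger.info("synthesized %d participants", len(cohort))
    report.n_participants = len(cohort)
    report.ratings_table = ratings

    # ------------------------------------------------------------- preprocess
    erps_by_part: dict[str, dict[str, ERP]] = {}
    cleaned_by_part: dict[str, EpochedData] = {}
    for epochs in cohort:
        erps, cleaned, stage = preprocess_participant(epochs, config.preprocess)
        erps_by_part[epochs.participant_id] = erps
        cleaned_by_part[epochs.participant_id] = cleaned
        report.stage_counts.append(stage)
    logger.info("preprocessed %d participants", len(erps_by_part))

    # ------------------------------------------------------------ microstates
    erp_lists = {pid: list(erps.values()) for pid, erps in erps_by_part.items()}
    mcfg = config.microstate
    if mcfg.fixed_k is not None:
        k = mcfg.fixed_k
        cv_table = None
    else:
        k, cv_table = ms.cross_validate_k(
            erp_lists,
            k_range=mcfg.k_range,
            n_repeats=mcfg.n_repeats,
            split=mcfg.split,
            n_restarts=mcfg.cv_n_restarts,
            seed=config.seed + 1,
            gfp_peaks_only=mcfg.gfp_peaks_only,
            criterion=mcfg.selection_criterion,
        )
    report.selected_k = k
    logger.info("selected k = %d microstate classes", k)

    individual_sets = []
    for pid, erps in erp_lists.items():
        maps = np.vstack([ms._erp_maps(e, mcfg.gfp_peaks_only) for e in erps])
        individual_sets.append(
            ms.kmeans_microstates(
                maps, k, n_restarts=mcfg.n_restarts, seed=config.seed + 2,
                max_iter=mcfg.max_iter, tol=mcfg.tol,
            )
        )
    global_set, _perms = ms.align_templates(individual_sets)

    # back-fit everyone, then name classes A.. by descending total labelled time
    segmentations: dict[tuple[str, str], ms.Segmentation] = {}
    total_time = np.zeros(k)
    for pid, erps in erps_by_part.items():
        for cond, erp in erps.items():
            seg = ms.backfit(global_set, erp, min_duration_ms=mcfg.min_duration_ms)
            segmentations[(pid, cond)] = seg
            for cls, dur in seg.durations_ms().items():
                total_time[cls] += dur
    order = np.argsort(-total_time)
    global_set = ms.MicrostateTemplateSet(
        maps=global_set.maps[:, order],
        labels=[chr(ord("A") + i) for i in range(k)],
        scope="global",
    )
    segmentations = {
        key: ms.backfit(global_set, erps_by_part[key[0]][key[1]], min_duration_ms=mcfg.min_duration_ms)
        for key in segmentations
    }

    dur_rows = []
    for (pid, cond), seg in segmentations.items():
        group = erps_by_part[pid][cond].group
        for cls, dur in seg.durations_ms().items():
            dur_rows.append(
                {
                    "participant": pid, "group": group, "condition": cond,
                    "MS": global_set.labels[cls], "duration_ms": dur,
                }
            )
    report.durations_table = pd.DataFrame(dur_rows)

    # ----------------------------------------------------------- connectivity
    ccfg = config.connectivity
    metric_rows = []
    for pid, cleaned in cleaned_by_part.items():
        for cond in erps_by_part[pid]:
            trials = cleaned.data[cleaned.conditions == cond]
            phase = conn.instantaneous_phase(trials, edge_trim=ccfg.edge_trim,
                                             sampling_rate=cleaned.sampling_rate)
            plv = conn.plv_matrix_timecourse(phase)
            seg = segmentations[(pid, cond)]
            nets = conn.microstate_gated_plv(
                plv, seg, n_trials=trials.shape[0], valid=phase.valid, n_classes=k
            )
            for cls, net in nets.items():
                if net.empty:
                    continue
                gm = conn.graph_metrics(net.adjacency, mode=ccfg.mode, sparsity=ccfg.sparsity)
                metric_rows.append(
                    {
                        "participant": pid, "group": cleaned.group, "condition": cond,
                        "MS": global_set.labels[cls], "cp": gm.cp, "lp": gm.lp,
                        "n_gated_samples": net.n_samples,
                    }
                )
    report.metrics_table = pd.DataFrame(metric_rows)
    logger.info("computed PLV networks for %d participant-condition cells",
                len(metric_rows) // max(k, 1))

    # ------------------------------------------------------------------ stats
    anova_rows: list[dict] = []
    if ratings is not None:
        res = msstats.analyze_metric(ratings, gg_policy=config.stats.gg_policy,
                                     alpha=config.stats.alpha)
        anova_rows += _anova_rows("valence", "-", res)
    for cls_label in global_set.labels:
        sub = report.durations_table[report.durations_table["MS"] == cls_label]
        table = sub.rename(columns={"duration_ms": "value"})[
            ["participant", "group", "condition", "value"]
        ]
        res = msstats.analyze_metric(table, gg_policy=config.stats.gg_policy,
                                     alpha=config.stats.alpha)
        anova_rows += _anova_rows("duration", cls_label, res)
        for metric in ("cp", "lp"):
            msub = report.metrics_table[report.metrics_table["MS"] == cls_label]
            if msub.empty:
                continue
            complete = msub.groupby("participant")["condition"].nunique()
            keep = complete[complete == len(CONDITIONS)].index
            mtable = msub[msub["participant"].isin(keep)].rename(columns={metric: "value"})[
                ["participant", "group", "condition", "value"]
            ]
            if mtable["participant"].nunique() < 4 or mtable["group"].nunique() < 2:
                continue
            res = msstats.analyze_metric(mtable, gg_policy=config.stats.gg_policy,
                                         alpha=config.stats.alpha)
            anova_rows += _anova_rows(metric, cls_label, res)
    report.anova_table = pd.DataFrame(anova_rows)

    # ----------------------------------------------------------------- output
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
        report.durations_table.to_csv(out_dir / "durations.csv", index=False)
        report.metrics_table.to_csv(out_dir / "graph_metrics.csv", index=False)
        report.anova_table.to_csv(out_dir / "anova_results.csv", index=False)
        if ratings is not None:
            ratings.to_csv(out_dir / "ratings.csv", index=False)
        if mcfg.fixed_k is None and cv_table is not None:
            cv_table.to_csv(out_dir / "cv_scores.csv", index=False)
        np.savetxt(out_dir / "global_templates.tsv", global_set.maps, delimiter="\t")
        (out_dir / "report.json").write_text(json.dumps(report.to_json_dict(), indent=2))
        logger.info("wrote results to %s", out_dir)
    return report
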