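"""End-to-end analysis pipeline: simulate -> fit -> cluster -> score -> stats.

Stages mirror the standard analysis of a masked-face recognition eye-tracking
study.  Per participant, one HMM is fitted per design cell (two learning-phase
models: unmasked/masked; four recognition-phase models: the 2x2 mask
conditions).  All models of a phase are clustered together into two
representative patterns; each participant-cell is then scored on the A-B
scale and its entropy profile, recognition responses are summarized as
d'/criterion/correct-trial RT, and the statistical layer runs the 2x2
within-subject ANOVAs, the three planned contrasts against the
unmasked-unmasked baseline, and the strategy-change vs performance-change
correlations with and without covariate partialling.

Every stage is an importable function; :func:`run_pipeline` wires them
together behind a :class:`PipelineConfig`.  All randomness derives from the
single config seed, so a rerun with an identical config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    ClusterConfig,
    ClusterResult,
    PatternPair,
    SeparationResult,
    as_pattern_pair,
    cluster_vhem,
    median_roi_count,
    pattern_separation,
)
from .exceptions import DegenerateVarianceError
from .data import (
    FixationSequence,
    MASK_MASKED,
    MASK_NA,
    MASK_UNMASKED,
    PHASE_LEARNING,
    PHASE_RECOGNITION,
    read_fixations,
)
from .exceptions import InputError
from .hmm import DEFAULT_FACE_BOX, FitResult, GaussianHMM, decode_rois, select_n_rois
from .metrics import ab_scale, fixation_entropies
from .stats import (
    CONDITION_ORDER,
    ResponseCounts,
    StatResult,
    correlation,
    dprime,
    paired_contrast,
    rm_anova_2x2,
)
from .synth import ExperimentDesign, _COND_KEY, make_default_dataset

log = logging.getLogger("gazehmm")

#: the three planned mask-use scenarios, each contrasted against baseline "uu"
PLANNED_SCENARIOS = {
    "mask_during_learning": "mu",
    "mask_during_recognition": "um",
    "mask_during_both": "mm",
}

EYE_DVS = ["ab_scale", "h1", "h2_given_1", "h3_given_2"]
BEHAVIOR_DVS = ["dprime", "mean_correct_rt"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, in one serializable object."""

    seed: int = 0
    out_dir: str | None = None
    # input files; when None, a synthetic dataset is generated
    fixations_path: str | None = None
    responses_path: str | None = None
    covariates_path: str | None = None
    # synthetic design
    n_participants: int = 88
    n_blocks: int = 8
    mix: float = 0.5
    perturb: float = 1.0
    # VBEM settings
    roi_range: list[int] = field(default_factory=lambda: list(range(1, 11)))
    vbem_restarts: int = 5
    vbem_tol: float = 1e-6
    vbem_max_iter: int = 300
    # VHEM settings
    n_virtual_samples: int = 1000
    virtual_length: int = 10
    vhem_restarts: int = 5
    # metrics / behavior
    entropy_base: str = "bits"
    dprime_correction: str = "half_count"
    min_sequences_per_cell: int = 10
    covariates: list[str] = field(
        default_factory=lambda: ["rspm", "working_memory", "planning", "attention"]
    )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InputError("config file must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_data(config: PipelineConfig):
    """Load fixations/responses/covariates, simulating when no paths are set."""
    if config.fixations_path:
        if not (config.responses_path and config.covariates_path):
            raise InputError("responses_path and covariates_path are required "
                             "alongside fixations_path")
        fixations = read_fixations(config.fixations_path)
        responses = pd.read_csv(config.responses_path)
        covariates = pd.read_csv(config.covariates_path)
        truth = None
    else:
        design = ExperimentDesign(n_participants=config.n_participants,
                                  n_blocks=config.n_blocks)
        ds, _, _ = make_default_dataset(seed=config.seed, design=design,
                                        mix=config.mix, perturb=config.perturb)
        fixations, responses, covariates = ds.fixations, ds.responses, ds.covariates
        truth = ds.ground_truth
    return fixations, responses, covariates, truth


def group_cells(
    fixations: list[FixationSequence],
) -> dict[tuple[str, str], list[FixationSequence]]:
    """Group sequences by (participant, cell key)."""
    cells: dict[tuple[str, str], list[FixationSequence]] = {}
    for s in fixations:
        if s.phase == PHASE_LEARNING:
            key = f"learn_{s.learn_mask}"
        else:
            key = f"recog_{_COND_KEY[(s.learn_mask, s.recog_mask)]}"
        cells.setdefault((s.participant_id, key), []).append(s)
    return cells


def stage_fit(
    fixations: list[FixationSequence], config: PipelineConfig
) -> tuple[dict[tuple[str, str], FitResult], pd.DataFrame]:
    """Fit one HMM per participant-cell; returns fits and an exclusion log.

    Cells with fewer than ``min_sequences_per_cell`` sequences are excluded
    from eye-movement analyses (never from behavioral ones) and logged.
    """
    cells = group_cells(fixations)
    rng = np.random.default_rng(config.seed + 1)
    fits: dict[tuple[str, str], FitResult] = {}
    excluded = []
    for (pid, cell), seqs in sorted(cells.items()):
        if len(seqs) < config.min_sequences_per_cell:
            excluded.append((pid, cell, len(seqs), "too_few_sequences"))
            log.warning("excluding %s/%s: %d sequences", pid, cell, len(seqs))
            continue
        fit_seed = int(rng.integers(0, 2**31 - 1))
        fits[(pid, cell)] = select_n_rois(
            seqs,
            roi_range=config.roi_range,
            n_restarts=config.vbem_restarts,
            seed=fit_seed,
            tol=config.vbem_tol,
            max_iter=config.vbem_max_iter,
        )
    exclusions = pd.DataFrame(
        excluded, columns=["participant_id", "cell", "n_sequences", "reason"])
    return fits, exclusions


def stage_cluster(
    fits: dict[tuple[str, str], FitResult], config: PipelineConfig
) -> dict[str, tuple[PatternPair, ClusterResult, list[str]]]:
    """Cluster each phase's individual models into two representative patterns.

    Learning-phase and recognition-phase models are clustered separately;
    within a phase, all participant-cell models enter one clustering, with
    the group ROI count set to the median of the individual ROI counts.
    """
    out = {}
    for phase, prefix in ((PHASE_LEARNING, "learn_"), (PHASE_RECOGNITION, "recog_")):
        ids = [f"{pid}|{cell}" for (pid, cell) in sorted(fits)
               if cell.startswith(prefix)]
        models = [fits[tuple(i.split("|"))].model for i in ids]
        if len(models) < 2:
            raise InputError(f"not enough fitted models to cluster phase {phase}")
        k_group = median_roi_count(models)
        cfg = ClusterConfig(
            n_virtual_samples=config.n_virtual_samples,
            virtual_length=config.virtual_length,
            n_restarts=config.vhem_restarts,
        )
        res = cluster_vhem(models, 2, k_group, cfg,
                           seed=config.seed + (2 if phase == PHASE_LEARNING else 3))
        out[phase] = (as_pattern_pair(res, ids), res, ids)
    return out


def stage_separation(
    fixations: list[FixationSequence],
    patterns: dict[str, tuple[PatternPair, ClusterResult, list[str]]],
) -> dict[str, SeparationResult | None]:
    """Own-vs-other pattern likelihood test per phase's clustering.

    Returns None for a phase whose assignment groups are too small to test.
    """
    cells = group_cells(fixations)
    out: dict[str, SeparationResult | None] = {}
    for phase, (pair, _res, ids) in patterns.items():
        seqs_by_id = {i: cells[tuple(i.split("|"))] for i in ids}
        try:
            out[phase] = pattern_separation(seqs_by_id, pair)
        except DegenerateVarianceError:
            log.warning("pattern separation untestable for phase %s", phase)
            out[phase] = None
    return out


def stage_metrics(
    fixations: list[FixationSequence],
    fits: dict[tuple[str, str], FitResult],
    patterns: dict[str, tuple[PatternPair, ClusterResult, list[str]]],
    config: PipelineConfig,
) -> pd.DataFrame:
    """A-B scale and entropy profile per fitted participant-cell."""
    cells = group_cells(fixations)
    rows = []
    for (pid, cell), fit in sorted(fits.items()):
        phase = PHASE_LEARNING if cell.startswith("learn_") else PHASE_RECOGNITION
        pair = patterns[phase][0]
        seqs = cells[(pid, cell)]
        score = ab_scale(seqs, pair.pattern_a, pair.pattern_b)
        ent = fixation_entropies(fit.model, base=config.entropy_base)
        if phase == PHASE_LEARNING:
            learn_mask, recog_mask = cell.removeprefix("learn_"), MASK_NA
        else:
            cond = cell.removeprefix("recog_")
            learn_mask = MASK_UNMASKED if cond[0] == "u" else MASK_MASKED
            recog_mask = MASK_UNMASKED if cond[1] == "u" else MASK_MASKED
        rows.append((pid, phase, learn_mask, recog_mask, cell, score.value,
                     score.ll_a, score.ll_b, ent.h1, ent.h2_given_1,
                     ent.h3_given_2, fit.n_rois_selected))
    return pd.DataFrame(rows, columns=[
        "participant_id", "phase", "learn_mask", "recog_mask", "cell",
        "ab_scale", "ll_a", "ll_b", "h1", "h2_given_1", "h3_given_2", "n_rois"])


def stage_behavior(responses: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Per participant-condition d', criterion and mean correct-trial RT."""
    rows = []
    for (pid, lm, rm), g in responses.groupby(
            ["participant_id", "learn_mask", "recog_mask"], sort=True):
        old = g[g["is_old"]]
        new = g[~g["is_old"]]
        counts = ResponseCounts(
            n_old=len(old), hits=int((old["response"] == "old").sum()),
            n_new=len(new), false_alarms=int((new["response"] == "old").sum()))
        perf = dprime(counts, correction=config.dprime_correction)
        correct = g[g["correct"]]
        rt = float(correct["rt_ms"].mean()) if len(correct) else np.nan
        rows.append((pid, lm, rm, f"recog_{_COND_KEY[(lm, rm)]}",
                     perf.dprime, perf.criterion, rt))
    return pd.DataFrame(rows, columns=[
        "participant_id", "learn_mask", "recog_mask", "cell",
        "dprime", "criterion", "mean_correct_rt"])


def _cell_table(df: pd.DataFrame, value: str) -> pd.DataFrame:
    """participants x 4 recognition cells (uu, um, mu, mm), complete cases only."""
    sub = df[df["cell"].str.startswith("recog_")]
    wide = sub.pivot(index="participant_id", columns="cell", values=value)
    order = [f"recog_{_COND_KEY[c]}" for c in CONDITION_ORDER]
    wide = wide.reindex(columns=order)
    return wide.dropna()


def stage_stats(
    metrics: pd.DataFrame,
    behavior: pd.DataFrame,
    covariates: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """ANOVAs, planned contrasts, and change-change correlations."""
    merged_values = {
        "dprime": behavior, "mean_correct_rt": behavior,
        **{dv: metrics for dv in EYE_DVS},
    }
    anovas: dict[str, dict[str, StatResult]] = {}
    contrasts: dict[str, dict[str, StatResult | None]] = {}
    analyzed_n: dict[str, int] = {}
    wides = {}
    for dv, source in merged_values.items():
        wide = _cell_table(source, dv)
        wides[dv] = wide
        analyzed_n[dv] = len(wide)
        if len(wide) >= 3:
            anovas[dv] = rm_anova_2x2(wide.to_numpy())
            contrasts[dv] = {
                name: paired_contrast(wide[f"recog_{cond}"], wide["recog_uu"])
                for name, cond in PLANNED_SCENARIOS.items()
            }
    # learning-phase masked-vs-unmasked contrasts on the eye DVs
    learning_contrasts = {}
    learn = metrics[metrics["phase"] == PHASE_LEARNING]
    lw = learn.pivot(index="participant_id", columns="cell", values="ab_scale")
    for dv in EYE_DVS:
        lwide = learn.pivot(index="participant_id", columns="cell",
                            values=dv).dropna()
        if {"learn_masked", "learn_unmasked"} <= set(lwide.columns) and len(lwide) >= 3:
            learning_contrasts[dv] = paired_contrast(
                lwide["learn_masked"], lwide["learn_unmasked"])
    del lw

    # strategy-change vs performance-change correlations
    correlations = {}
    cov = covariates.set_index("participant_id")[config.covariates] \
        if len(covariates) else None
    dp = wides.get("dprime")
    specs = {
        # change toward Pattern B when the mask was used during learning
        # vs the matching d' impairment
        "ab_change_vs_dprime_impairment_mu": ("ab_scale", "recog_mu"),
        # change toward consistent transitions when the mask was used during
        # recognition vs the matching d' impairment
        "h3_change_vs_dprime_impairment_um": ("h3_given_2", "recog_um"),
    }
    for name, (dv, cell) in specs.items():
        wide = wides.get(dv)
        if wide is None or dp is None:
            continue
        common = wide.index.intersection(dp.index)
        if cov is not None:
            common = common.intersection(cov.index)
        if len(common) < 8:
            continue
        change = (wide.loc[common, "recog_uu"] - wide.loc[common, cell]).to_numpy()
        impair = (dp.loc[common, "recog_uu"] - dp.loc[common, cell]).to_numpy()
        entry = {"n": len(common),
                 "simple": correlation(change, impair)}
        if cov is not None:
            entry["partial_intelligence"] = correlation(
                change, impair, cov.loc[common, config.covariates[:1]])
            entry["partial_all_covariates"] = correlation(
                change, impair, cov.loc[common, config.covariates])
        correlations[name] = entry
    return {
        "anovas": anovas,
        "planned_contrasts": contrasts,
        "learning_contrasts": learning_contrasts,
        "correlations": correlations,
        "analyzed_n": analyzed_n,
    }


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _stat_to_dict(s: StatResult) -> dict:
    return {
        "statistic": round(float(s.statistic), 6),
        "df": list(s.df),
        "p_value": float(s.p_value),
        "effect_name": s.effect_name,
        "effect_size": round(float(s.effect_size), 6),
        "effect_ci": [round(float(v), 6) for v in s.effect_ci],
    }


@dataclass
class PipelineResult:
    config: PipelineConfig
    metrics: pd.DataFrame
    behavior: pd.DataFrame
    stats: dict
    patterns: dict
    exclusions: pd.DataFrame
    fits: dict
    ground_truth: dict | None

    def report(self) -> dict:
        """JSON-serializable analysis report (deterministic for a fixed config)."""
        stats = self.stats
        rep = {
            "provenance": {
                "package": "gazehmm",
                "version": __version__,
                "seed": self.config.seed,
                "settings": self.config.to_dict(),
            },
            "exclusions": {
                "n_excluded_cells": int(len(self.exclusions)),
                "rows": self.exclusions.to_dict("records"),
            },
            "anovas": {dv: {eff: _stat_to_dict(s) for eff, s in effs.items()}
                       for dv, effs in stats["anovas"].items()},
            "planned_contrasts": {
                dv: {name: _stat_to_dict(s) for name, s in cs.items()}
                for dv, cs in stats["planned_contrasts"].items()},
            "learning_contrasts": {
                dv: _stat_to_dict(s)
                for dv, s in stats["learning_contrasts"].items()},
            "correlations": {
                name: {
                    "n": entry["n"],
                    **{k: {"r": round(float(v.r), 6), "df": v.df,
                           "p_value": float(v.p_value)}
                       for k, v in entry.items() if k != "n"},
                }
                for name, entry in stats["correlations"].items()},
            "analyzed_n": stats["analyzed_n"],
        }
        for phase, (pair, res, ids) in self.patterns.items():
            entry = {
                "n_group_rois": pair.n_group_rois,
                "degenerate": pair.degenerate,
                "n_models": len(ids),
                "n_pattern_a": sum(1 for v in pair.assignments.values() if v == "A"),
                "n_pattern_b": sum(1 for v in pair.assignments.values() if v == "B"),
            }
            sep = stats.get("separation", {}).get(phase)
            if sep is not None:
                entry["separation"] = {
                    "f_stat": round(float(sep.f_stat), 6),
                    "df": list(sep.df),
                    "p_value": float(sep.p_value),
                    "partial_eta_sq": round(float(sep.effect_size), 6),
                    "eta_ci_90": [round(float(v), 6) for v in sep.effect_ci],
                    "mean_margin": round(float(np.mean(
                        list(sep.per_participant_margin.values()))), 6),
                }
            rep.setdefault("patterns", {})[phase] = entry
        return rep

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.behavior.to_csv(out / "behavior.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)
        for phase, (pair, res, ids) in self.patterns.items():
            pair.pattern_a.save(out / f"pattern_A_{phase}.json")
            pair.pattern_b.save(out / f"pattern_B_{phase}.json")
            pd.DataFrame(
                {"model_id": ids,
                 "assignment": [pair.assignments[i] for i in ids]}
            ).to_csv(out / f"assignments_{phase}.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.report(), fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described in the module docstring."""
    log.info("loading data (seed=%d)", config.seed)
    fixations, responses, covariates, truth = stage_data(config)
    log.info("fitting per-cell HMMs over ROI range %s", config.roi_range)
    fits, exclusions = stage_fit(fixations, config)
    log.info("clustering %d fitted models", len(fits))
    patterns = stage_cluster(fits, config)
    metrics = stage_metrics(fixations, fits, patterns, config)
    behavior = stage_behavior(responses, config)
    stats = stage_stats(metrics, behavior, covariates, config)
    stats["separation"] = stage_separation(fixations, patterns)
    result = PipelineResult(config, metrics, behavior, stats, patterns,
                            exclusions, fits, truth)
    if config.out_dir:
        result.write(config.out_dir)
    return result


# ---------------------------------------------------------------------------
# replicate studies of the planted couplings
# ---------------------------------------------------------------------------

def coupling_replicates(
    n_reps: int,
    seed: int,
    design: ExperimentDesign | None = None,
    n_proxy_trials: int | None = None,
) -> pd.DataFrame:
    """Replicate the strategy-change vs performance-change correlations.

    Each replicate draws a fresh population, simulates recognition responses
    (aggregate SDT counts), and correlates d' impairment with the
    eye-movement change scores: the A-B scale change between the baseline
    and mismatched-learning conditions (scored by sampling scanpaths from
    the generating models against the archetype patterns, with the design's
    own per-cell trial count) and the exact h3|2 entropy change between the
    baseline and masked-recognition conditions.  Returns one row per
    replicate with ``r_strategy`` and ``r_consistency``; both planted
    couplings predict negative values.
    """
    from .metrics import ab_scale, fixation_entropies
    from .stats import dprime as dprime_fn
    from .stats import ResponseCounts
    from .synth import (make_prototypes, sample_population,
                        simulate_condition_counts)
    from .hmm import sample_sequences

    des = design or ExperimentDesign()
    if n_proxy_trials is None:
        n_proxy_trials = des.n_blocks * des.targets_per_condition_per_block * 2
    protos = make_prototypes()
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        pop = sample_population(protos, des.n_participants,
                                seed=int(rng.integers(0, 2**31 - 1)))
        counts = simulate_condition_counts(
            des, pop, seed=int(rng.integers(0, 2**31 - 1)))
        counts["dprime"] = [
            dprime_fn(ResponseCounts(r.n_old, r.hits, r.n_new,
                                     r.false_alarms)).dprime
            for r in counts.itertuples()]
        dp = counts.pivot(index="participant_id",
                          columns=["learn_mask", "recog_mask"],
                          values="dprime")
        imp_mu = dp[("unmasked", "unmasked")] - dp[("masked", "unmasked")]
        imp_um = dp[("unmasked", "unmasked")] - dp[("unmasked", "masked")]
        ab_change, h3_change = [], []
        for member in pop:
            s_uu = sample_sequences(member.models["recog_uu"], n_proxy_trials,
                                    6, seed=int(rng.integers(0, 2**31 - 1)))
            s_mu = sample_sequences(member.models["recog_mu"], n_proxy_trials,
                                    6, seed=int(rng.integers(0, 2**31 - 1)))
            ab_change.append(
                ab_scale(s_uu, protos.pattern_a, protos.pattern_b).value
                - ab_scale(s_mu, protos.pattern_a, protos.pattern_b).value)
            h3_change.append(
                fixation_entropies(member.models["recog_uu"]).h3_given_2
                - fixation_entropies(member.models["recog_um"]).h3_given_2)
        ids = [m.participant_id for m in pop]
        rows.append((
            float(np.corrcoef(ab_change, imp_mu.loc[ids])[0, 1]),
            float(np.corrcoef(h3_change, imp_um.loc[ids])[0, 1]),
        ))
    return pd.DataFrame(rows, columns=["r_strategy", "r_consistency"])


# ---------------------------------------------------------------------------
# heatmap summary
# ---------------------------------------------------------------------------

@dataclass
class HeatmapSummary:
    """Gridded fixation density plus decoded ROI labels, for report figures."""

    histogram: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    roi_labels: list[np.ndarray]


def make_heatmap_summary(
    model: GaussianHMM,
    seqs: list[FixationSequence],
    bins: int = 20,
    face_box: tuple[float, float] = DEFAULT_FACE_BOX,
) -> HeatmapSummary:
    """2-D fixation histogram over the face box with per-fixation ROI labels."""
    if not seqs:
        raise InputError("need at least one sequence")
    pts = np.concatenate([s.positions for s in seqs], axis=0)
    w, h = face_box
    hist, xe, ye = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=bins,
        range=[[-w / 2, w / 2], [-h / 2, h / 2]])
    # fixations outside the box still count: clip them onto the border bins
    if hist.sum() < pts.shape[0]:
        xi = np.clip(np.searchsorted(xe, pts[:, 0], side="right") - 1, 0, bins - 1)
        yi = np.clip(np.searchsorted(ye, pts[:, 1], side="right") - 1, 0, bins - 1)
        hist = np.zeros_like(hist)
        np.add.at(hist, (xi, yi), 1.0)
    labels = [decode_rois(model, s) for s in seqs]
    return HeatmapSummary(histogram=hist, x_edges=xe, y_edges=ye, roi_labels=labels)
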