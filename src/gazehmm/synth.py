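"""Synthetic face-recognition experiments with planted ground truth.

Emulates a 2x2 within-subject masked-face recognition design: every
participant learns 16 faces per block and then discriminates them from 16
matched foils, across 8 blocks, with four target faces per block in each of
the four mask conditions (unmasked/masked at learning x unmasked/masked at
recognition).  Faces rotate through conditions across participants by a Latin
square; lighting and mask-color labels are carried as metadata only.  The
default design therefore consumes 8 x 32 = 256 unique face identities.

Ground truth is planted at two levels:

* **Eye movements** — two archetypal scanpath generators (an eyes-focused and
  a broader nose/center-focused pattern).  Each participant gets perturbed
  copies per condition: recognizing masked faces pulls the generator toward
  the eyes-focused pattern and sharpens its transition rows (lower
  conditional entropy) in proportion to the participant's consistency trait;
  recognizing unmasked faces that were learned masked pulls toward the
  eyes-focused pattern in proportion to the strategy-shift trait.

* **Behavior** — old/new responses follow an equal-variance signal-detection
  model whose per-condition d' couples to the same traits, so that larger
  strategy adjustment predicts smaller performance impairment in the
  mismatched conditions, mirroring the individual-differences effects the
  pipeline is meant to detect.  Cognitive covariates share a latent factor
  with the consistency trait, giving partial-correlation analyses a testable
  ground truth.

All sampling is driven by one integer seed; identical seeds give
byte-identical dataset files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import PatternPair
from .data import (
    FixationSequence,
    MASK_MASKED,
    MASK_NA,
    MASK_UNMASKED,
    PHASE_LEARNING,
    PHASE_RECOGNITION,
    write_fixations,
)
from .exceptions import InputError
from .hmm import DEFAULT_FACE_BOX, GaussianHMM
from .stats import CONDITION_ORDER

RESPONSE_COLUMNS = [
    "participant_id", "trial_id", "block", "face_id", "learn_mask",
    "recog_mask", "is_old", "response", "correct", "rt_ms",
]

#: short keys of the six generating models each participant carries
MODEL_KEYS = ("learn_unmasked", "learn_masked",
              "recog_uu", "recog_um", "recog_mu", "recog_mm")

_COND_KEY = {
    (MASK_UNMASKED, MASK_UNMASKED): "uu",
    (MASK_UNMASKED, MASK_MASKED): "um",
    (MASK_MASKED, MASK_UNMASKED): "mu",
    (MASK_MASKED, MASK_MASKED): "mm",
}


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class ExperimentDesign:
    """Block/trial arithmetic of the recognition experiment."""

    n_participants: int = 88
    n_blocks: int = 8
    targets_per_block: int = 16
    foils_per_block: int = 16
    targets_per_condition_per_block: int = 4
    learning_exposure_ms: float = 5000.0

    def validate(self) -> None:
        if self.targets_per_condition_per_block * 4 != self.targets_per_block:
            raise InputError(
                "targets_per_block must equal 4 x targets_per_condition_per_block"
            )
        if self.foils_per_block != self.targets_per_block:
            raise InputError("foil conditions must match target conditions")
        if min(self.n_participants, self.n_blocks) < 1:
            raise InputError("design must have at least one participant and block")

    @property
    def unique_faces(self) -> int:
        """Total distinct face identities the design consumes."""
        return self.n_blocks * (self.targets_per_block + self.foils_per_block)

    def trial_table(self, participant_index: int) -> pd.DataFrame:
        """Per-trial face/condition assignment for one participant.

        Faces rotate through the four mask conditions across participants by
        a Latin square, so each face serves each condition equally often.
        Lighting/mask-color labels alternate across half the blocks and are
        metadata only.
        """
        self.validate()
        rows = []
        faces_per_block = self.targets_per_block + self.foils_per_block
        for b in range(self.n_blocks):
            base = b * faces_per_block
            lighting = (
                "learn_white_blue-recog_yellow_white"
                if b < self.n_blocks // 2
                else "learn_yellow_white-recog_white_blue"
            )
            for j in range(faces_per_block):
                role = "target" if j < self.targets_per_block else "foil"
                cond = CONDITION_ORDER[(j + participant_index) % 4]
                rows.append((b, base + j, role, cond[0], cond[1], lighting))
        return pd.DataFrame(
            rows,
            columns=["block", "face_id", "role", "learn_mask", "recog_mask",
                     "nuisance"],
        )


# ---------------------------------------------------------------------------
# archetype prototypes
# ---------------------------------------------------------------------------

@dataclass
class ROILayout:
    """Centers and covariances of the three canonical face ROIs (pixels).

    Separate entries for the two archetypes reflect that the eyes-focused
    pattern keeps a tighter, higher eye ROI and a larger forehead ROI than
    the broad/center-focused pattern.
    """

    broad_center: tuple[float, float] = (0.0, 45.0)
    eye_center: tuple[float, float] = (0.0, -5.0)
    forehead_center: tuple[float, float] = (0.0, -80.0)
    broad_cov: tuple[float, float] = (2000.0, 1400.0)
    eye_cov: tuple[float, float] = (2200.0, 450.0)
    forehead_cov: tuple[float, float] = (1200.0, 500.0)
    # eyes-focused archetype variants
    eyes_focused_eye_center: tuple[float, float] = (0.0, -12.0)
    eyes_focused_eye_cov: tuple[float, float] = (1500.0, 280.0)
    eyes_focused_forehead_center: tuple[float, float] = (0.0, -92.0)
    eyes_focused_forehead_cov: tuple[float, float] = (1800.0, 800.0)


def make_prototypes(
    face_box: tuple[float, float] = DEFAULT_FACE_BOX,
    layout: ROILayout | None = None,
) -> PatternPair:
    """Construct the two archetypal scanpath generators.

    Pattern A is the broad/center-focused archetype: scanpaths start in a
    large central ROI covering the eyes and nose, then wander between it, the
    eye region and the forehead.  Pattern B is the eyes-focused archetype:
    scanpaths start broad, switch to the eye region with high probability and
    stay there (eye self-transition above 0.9), so its gaze transitions are
    markedly more consistent.  Both share three ROIs.
    """
    lay = layout or ROILayout()
    centers_a = np.array([lay.broad_center, lay.eye_center, lay.forehead_center])
    centers_b = np.array([lay.broad_center, lay.eyes_focused_eye_center,
                          lay.eyes_focused_forehead_center])
    w, h = face_box
    for centers in (centers_a, centers_b):
        if np.any(np.abs(centers[:, 0]) > w / 2) or np.any(np.abs(centers[:, 1]) > h / 2):
            raise InputError("ROI centers fall outside the face box")
        d01 = np.linalg.norm(centers[0] - centers[1])
        d02 = np.linalg.norm(centers[0] - centers[2])
        d12 = np.linalg.norm(centers[1] - centers[2])
        if min(d01, d02, d12) < 10.0:
            raise InputError("degenerate ROI layout: centers overlap")
    # state order: broad, eyes, forehead
    pattern_a = GaussianHMM(
        prior=np.array([1.0, 0.0, 0.0]),
        transitions=np.array([
            [0.38, 0.40, 0.22],
            [0.06, 0.88, 0.06],
            [0.06, 0.06, 0.88],
        ]),
        means=centers_a,
        covariances=np.stack([np.diag(lay.broad_cov), np.diag(lay.eye_cov),
                              np.diag(lay.forehead_cov)]),
    )
    pattern_b = GaussianHMM(
        prior=np.array([0.96, 0.01, 0.03]),
        transitions=np.array([
            [0.01, 0.97, 0.02],
            [0.02, 0.96, 0.02],
            [0.10, 0.20, 0.70],
        ]),
        means=centers_b,
        covariances=np.stack([np.diag(lay.broad_cov),
                              np.diag(lay.eyes_focused_eye_cov),
                              np.diag(lay.eyes_focused_forehead_cov)]),
    )
    pattern_a.validate()
    pattern_b.validate()
    return PatternPair(pattern_a=pattern_a, pattern_b=pattern_b,
                       assignments={}, n_group_rois=3)


def shift_toward(model: GaussianHMM, target: GaussianHMM, t: float) -> GaussianHMM:
    """Linear interpolation of all parameters toward ``target`` by ``t`` in [0, 1]."""
    if not 0.0 <= t <= 1.0:
        raise InputError("interpolation weight must lie in [0, 1]")
    if model.n_rois != target.n_rois:
        raise InputError("models must share the number of ROIs")
    return GaussianHMM(
        prior=(1 - t) * model.prior + t * target.prior,
        transitions=(1 - t) * model.transitions + t * target.transitions,
        means=(1 - t) * model.means + t * target.means,
        covariances=(1 - t) * model.covariances + t * target.covariances,
    )


def sharpen_transitions(model: GaussianHMM, gamma: float) -> GaussianHMM:
    """Reduce transition-row entropy by tempering rows with exponent 1 + gamma.

    The prior is left untouched, so the marginal entropy of the first
    fixation is unaffected — only gaze-transition consistency changes.
    """
    if gamma < 0:
        raise InputError("gamma must be non-negative")
    rows = model.transitions ** (1.0 + gamma)
    return GaussianHMM(
        prior=model.prior.copy(),
        transitions=rows / rows.sum(axis=1, keepdims=True),
        means=model.means.copy(),
        covariances=model.covariances.copy(),
    )


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

COVARIATE_NAMES = ["rspm", "working_memory", "planning", "attention"]


@dataclass
class TraitModel:
    """Distribution of the latent participant traits.

    ``consistency_loading`` and ``strategy_loading`` tie the respective
    traits to the latent cognitive factor shared by the covariates, so
    covariate partialling has a planted effect to find.
    """

    strategy_shift_mean: float = 0.6
    strategy_shift_sd: float = 0.3
    consistency_gain_mean: float = 0.6
    consistency_gain_sd: float = 0.3
    base_dprime_mean: float = 2.2
    base_dprime_sd: float = 0.45
    criterion_mean: float = 0.1
    criterion_sd: float = 0.25
    covariate_loading: float = 0.5
    consistency_loading: float = 0.35
    strategy_loading: float = 0.15


@dataclass
class ParticipantTraits:
    archetype: str                      # "eyes_focused" | "nose_focused"
    strategy_shift: float
    consistency_gain: float
    base_dprime: float
    criterion: float
    covariates: np.ndarray


@dataclass
class PopulationMember:
    participant_id: str
    traits: ParticipantTraits
    models: dict[str, GaussianHMM]


@dataclass
class ShiftScales:
    """How strongly condition-specific generators deviate from the base model."""

    masked_recognition_shift: float = 0.35
    mismatch_learning_shift: float = 0.8
    sharpen_scale: float = 2.5


def _perturb_model(
    proto: GaussianHMM, perturb: float, rng: np.random.Generator
) -> GaussianHMM:
    if perturb == 0.0:
        return GaussianHMM(proto.prior.copy(), proto.transitions.copy(),
                           proto.means.copy(), proto.covariances.copy())
    for _ in range(100):
        conc = 120.0 / perturb
        prior = rng.dirichlet(proto.prior * conc + 0.5)
        rows = np.stack([rng.dirichlet(row * conc + 0.5)
                         for row in proto.transitions])
        means = proto.means + rng.normal(0.0, 8.0 * perturb, proto.means.shape)
        scale = np.exp(rng.normal(0.0, 0.1 * perturb, proto.n_rois))
        covs = proto.covariances * scale[:, None, None]
        cand = GaussianHMM(prior, rows, means, covs)
        try:
            cand.validate()
            return cand
        except Exception:
            continue
    raise InputError("could not generate a valid perturbed model in 100 attempts")


def sample_population(
    prototypes: PatternPair,
    n: int,
    mix: float = 0.5,
    perturb: float = 1.0,
    trait_model: TraitModel | None = None,
    seed: int = 0,
    shift_scales: ShiftScales | None = None,
) -> list[PopulationMember]:
    """Draw a participant population with condition-specific generators.

    ``mix`` is the proportion of eyes-focused archetypes; ``perturb`` scales
    individual deviation from the archetype prototypes (0 reproduces them
    exactly).  Each member carries six generating HMMs: two learning-phase
    models (identical by construction — mask condition at learning does not
    alter planted gaze behavior) and four recognition-phase models, with the
    condition-specific shifts described in the module docstring.
    """
    if not 0.0 <= mix <= 1.0:
        raise InputError("mix must lie in [0, 1]")
    if perturb < 0:
        raise InputError("perturb must be non-negative")
    tm = trait_model or TraitModel()
    ss = shift_scales or ShiftScales()
    rng = np.random.default_rng(seed)
    members = []
    n_eyes = int(round(mix * n))
    archetypes = ["eyes_focused"] * n_eyes + ["nose_focused"] * (n - n_eyes)
    for i in range(n):
        arch = archetypes[i]
        g = rng.standard_normal()  # latent cognitive factor
        def loaded(mean, sd, loading):
            eps = rng.standard_normal()
            return mean + sd * (loading * g + np.sqrt(1 - loading**2) * eps)
        strategy = float(np.clip(loaded(tm.strategy_shift_mean,
                                        tm.strategy_shift_sd,
                                        tm.strategy_loading), 0.0, 1.0))
        consistency = float(np.clip(loaded(tm.consistency_gain_mean,
                                           tm.consistency_gain_sd,
                                           tm.consistency_loading), 0.0, 1.0))
        base_dp = float(max(tm.base_dprime_mean
                            + tm.base_dprime_sd * rng.standard_normal(), 0.2))
        crit = float(tm.criterion_mean + tm.criterion_sd * rng.standard_normal())
        lam = tm.covariate_loading
        covs = lam * g + np.sqrt(1 - lam**2) * rng.standard_normal(len(COVARIATE_NAMES))
        traits = ParticipantTraits(arch, strategy, consistency, base_dp, crit, covs)

        proto = (prototypes.pattern_b if arch == "eyes_focused"
                 else prototypes.pattern_a)
        base = _perturb_model(proto, perturb, rng)
        masked = shift_toward(base, prototypes.pattern_b,
                              ss.masked_recognition_shift)
        masked = sharpen_transitions(masked, ss.sharpen_scale * consistency)
        mismatch = shift_toward(base, prototypes.pattern_b,
                                ss.mismatch_learning_shift * strategy)
        models = {
            "learn_unmasked": base,
            "learn_masked": base,
            "recog_uu": base,
            "recog_mu": mismatch,
            "recog_um": masked,
            "recog_mm": masked,
        }
        members.append(PopulationMember(f"P{i:03d}", traits, models))
    return members


# ---------------------------------------------------------------------------
# experiment simulation
# ---------------------------------------------------------------------------

@dataclass
class BehaviorCoupling:
    """Planted links between traits and condition-specific d'.

    Offsets encode the group-level impairment pattern (largest in the
    mismatched conditions); the coupling slopes let the trait that drives a
    condition's strategy adjustment also attenuate that condition's
    impairment, producing the planted negative correlation between strategy
    adjustment and d' impairment.
    """

    offset_uu: float = 0.0
    offset_um: float = -0.38
    offset_mu: float = -0.42
    offset_mm: float = -0.32
    strategy_to_mu: float = 2.0
    consistency_to_um: float = 2.0

    def dprime_for(self, traits: ParticipantTraits, cond: tuple[str, str],
                   trait_model: TraitModel | None = None) -> float:
        tm = trait_model or TraitModel()
        key = _COND_KEY[cond]
        d = traits.base_dprime + getattr(self, f"offset_{key}")
        if key == "mu":
            d += self.strategy_to_mu * (traits.strategy_shift - tm.strategy_shift_mean)
        if key == "um":
            d += self.consistency_to_um * (traits.consistency_gain
                                           - tm.consistency_gain_mean)
        return d


@dataclass
class SyntheticDataset:
    """Complete generated study: fixations, responses, covariates, truth."""

    fixations: list[FixationSequence]
    responses: pd.DataFrame
    covariates: pd.DataFrame
    ground_truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fixations(self.fixations, out / "fixations.csv")
        self.responses.to_csv(out / "responses.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)


def _draw_length(rng, mean, lo, hi):
    return int(np.clip(rng.poisson(mean), lo, hi))


def simulate_experiment(
    design: ExperimentDesign,
    population: list[PopulationMember],
    behavior_coupling: BehaviorCoupling | None = None,
    seed: int = 0,
    *,
    trait_model: TraitModel | None = None,
    learning_fix_mean: float = 15.0,
    recognition_fix_mean: float = 6.0,
    include_fixations: bool = True,
) -> SyntheticDataset:
    """Run the full design through every participant's generators.

    Learning trials draw fixation-sequence lengths around
    ``learning_fix_mean`` (calibrated to a 5 s exposure); self-terminating
    recognition trials are shorter.  Responses come from the equal-variance
    signal-detection model parameterized by :class:`BehaviorCoupling`; RTs
    are log-normal with a small shift for masked-recognition and error
    trials.  Everything planted is recorded under ``ground_truth``.

    ``include_fixations=False`` skips scanpath sampling and produces
    responses only — useful for large replicate studies of the behavioral
    layer, where eye-movement measures come from the ground-truth models.
    """
    design.validate()
    if len(population) != design.n_participants:
        raise InputError("population size must match the design")
    bc = behavior_coupling or BehaviorCoupling()
    rng = np.random.default_rng(seed)
    fixations: list[FixationSequence] = []
    resp_rows = []
    cov_rows = []
    truth_participants = {}
    for member in population:
        pid = member.participant_id
        table = design.trial_table(int(pid[1:]) if pid[1:].isdigit() else 0)
        chols = {k: np.linalg.cholesky(m.covariances)
                 for k, m in member.models.items()} if include_fixations else {}

        def sample_seq(model_key, T, trial_id, phase, learn_mask, recog_mask):
            m = member.models[model_key]
            states = np.empty(T, dtype=int)
            states[0] = rng.choice(m.n_rois, p=m.prior)
            for t in range(1, T):
                states[t] = rng.choice(m.n_rois, p=m.transitions[states[t - 1]])
            noise = rng.standard_normal((T, 2))
            pos = m.means[states] + np.einsum(
                "tij,tj->ti", chols[model_key][states], noise)
            durs = np.maximum(rng.gamma(4.0, 62.5, T), 1.0)
            fixations.append(FixationSequence(
                pid, trial_id, phase, learn_mask, recog_mask,
                np.column_stack([pos, durs])))

        d_cond = {c: bc.dprime_for(member.traits, c, trait_model)
                  for c in CONDITION_ORDER}
        for b in range(design.n_blocks):
            block = table[table["block"] == b]
            targets = block[block["role"] == "target"]
            if include_fixations:
                for _, tr in targets.iterrows():
                    T = _draw_length(rng, learning_fix_mean, 3, 25)
                    sample_seq(f"learn_{tr.learn_mask}", T,
                               f"{pid}_b{b}_learn_f{tr.face_id}",
                               PHASE_LEARNING, tr.learn_mask, MASK_NA)
            order = block.sample(frac=1.0,
                                 random_state=int(rng.integers(0, 2**31 - 1)))
            for _, tr in order.iterrows():
                cond = (tr.learn_mask, tr.recog_mask)
                key = f"recog_{_COND_KEY[cond]}"
                trial_id = f"{pid}_b{b}_recog_f{tr.face_id}"
                if include_fixations:
                    T = _draw_length(rng, recognition_fix_mean, 2, 15)
                    sample_seq(key, T, trial_id, PHASE_RECOGNITION,
                               tr.learn_mask, tr.recog_mask)
                is_old = tr.role == "target"
                strength = d_cond[cond] if is_old else 0.0
                said_old = bool(rng.normal(strength, 1.0)
                                > member.traits.criterion)
                correct = said_old == is_old
                log_rt = (np.log(900.0)
                          + 0.12 * (tr.recog_mask == MASK_MASKED)
                          + 0.08 * (not correct)
                          + rng.normal(0.0, 0.25))
                resp_rows.append((pid, trial_id, b, int(tr.face_id),
                                  tr.learn_mask, tr.recog_mask, is_old,
                                  "old" if said_old else "new", correct,
                                  round(float(np.exp(log_rt)), 1)))
        cov_rows.append([pid] + list(np.round(member.traits.covariates, 6)))
        truth_participants[pid] = {
            "archetype": member.traits.archetype,
            "strategy_shift": member.traits.strategy_shift,
            "consistency_gain": member.traits.consistency_gain,
            "base_dprime": member.traits.base_dprime,
            "criterion": member.traits.criterion,
            "dprime_by_condition": {_COND_KEY[c]: d_cond[c]
                                    for c in CONDITION_ORDER},
            "models": {k: m.to_dict() for k, m in member.models.items()},
        }
    responses = pd.DataFrame(resp_rows, columns=RESPONSE_COLUMNS)
    covariates = pd.DataFrame(cov_rows, columns=["participant_id"] + COVARIATE_NAMES)
    ground_truth = {
        "design": asdict(design),
        "behavior_coupling": asdict(bc),
        "seed": seed,
        "participants": truth_participants,
    }
    return SyntheticDataset(fixations, responses, covariates, ground_truth)


def simulate_condition_counts(
    design: ExperimentDesign,
    population: list[PopulationMember],
    behavior_coupling: BehaviorCoupling | None = None,
    seed: int = 0,
    trait_model: TraitModel | None = None,
) -> pd.DataFrame:
    """Aggregate old/new response counts per participant-condition.

    Distributionally equivalent to tallying :func:`simulate_experiment`
    responses (each trial is an independent equal-variance SDT draw), but
    drawn as binomial counts directly — used by large replicate studies of
    the behavioral layer.  Returns one row per participant x condition with
    n_old, hits, n_new and false_alarms.
    """
    design.validate()
    bc = behavior_coupling or BehaviorCoupling()
    rng = np.random.default_rng(seed)
    n_per = design.n_blocks * design.targets_per_condition_per_block
    from scipy.stats import norm

    rows = []
    for member in population:
        c = member.traits.criterion
        for cond in CONDITION_ORDER:
            d = bc.dprime_for(member.traits, cond, trait_model)
            p_hit = float(norm.sf(c - d))
            p_fa = float(norm.sf(c))
            rows.append((member.participant_id, cond[0], cond[1],
                         n_per, int(rng.binomial(n_per, p_hit)),
                         n_per, int(rng.binomial(n_per, p_fa))))
    return pd.DataFrame(rows, columns=[
        "participant_id", "learn_mask", "recog_mask",
        "n_old", "hits", "n_new", "false_alarms"])


def make_default_dataset(
    seed: int = 0,
    design: ExperimentDesign | None = None,
    mix: float = 0.5,
    perturb: float = 1.0,
    behavior_coupling: BehaviorCoupling | None = None,
) -> tuple[SyntheticDataset, list[PopulationMember], PatternPair]:
    """Convenience wrapper: prototypes -> population -> simulated study."""
    des = design or ExperimentDesign()
    protos = make_prototypes()
    rng = np.random.default_rng(seed)
    pop_seed, exp_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    pop = sample_population(protos, des.n_participants, mix=mix,
                            perturb=perturb, seed=pop_seed)
    ds = simulate_experiment(des, pop, behavior_coupling, seed=exp_seed)
    return ds, pop, protos
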