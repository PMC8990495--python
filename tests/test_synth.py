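"""Tests of the synthetic-study generator: design arithmetic, archetype
prototypes, population sampling, and the planted behavioral couplings."""

import json

import numpy as np
import pandas as pd
import pytest

from gazehmm.data import read_fixations
from gazehmm.exceptions import InputError
from gazehmm.hmm import GaussianHMM
from gazehmm.metrics import fixation_entropies
from gazehmm.synth import (
    BehaviorCoupling,
    ExperimentDesign,
    ROILayout,
    TraitModel,
    make_prototypes,
    sample_population,
    sharpen_transitions,
    shift_toward,
    simulate_experiment,
)


class TestDesign:
    def test_default_design_consumes_256_faces(self):
        assert ExperimentDesign().unique_faces == 256

    def test_four_targets_per_condition_per_block(self):
        design = ExperimentDesign()
        for p in (0, 1, 5):
            table = design.trial_table(p)
            for b in range(design.n_blocks):
                block = table[table["block"] == b]
                targets = block[block["role"] == "target"]
                foils = block[block["role"] == "foil"]
                t_counts = targets.groupby(["learn_mask", "recog_mask"]).size()
                f_counts = foils.groupby(["learn_mask", "recog_mask"]).size()
                assert set(t_counts) == {4} and len(t_counts) == 4
                assert set(f_counts) == {4} and len(f_counts) == 4

    def test_latin_square_rotates_faces_through_conditions(self):
        design = ExperimentDesign()
        seen = {}
        for p in range(4):
            table = design.trial_table(p)
            cond = table.set_index("face_id")[["learn_mask", "recog_mask"]]
            seen[p] = cond.apply(tuple, axis=1)
        # every face serves each condition exactly once across four rotations
        stacked = pd.concat(seen, axis=1)
        assert (stacked.nunique(axis=1) == 4).all()

    def test_each_face_in_one_block_and_role(self):
        table = ExperimentDesign().trial_table(0)
        assert table["face_id"].is_unique
        assert len(table) == 256

    def test_invalid_arithmetic_rejected(self):
        with pytest.raises(InputError):
            ExperimentDesign(targets_per_block=15).validate()


class TestPrototypes:
    def test_eyes_focused_self_transition_high(self):
        protos = make_prototypes()
        # state order broad, eyes, forehead: eye-region self-stay >= 0.9
        assert protos.pattern_b.transitions[1, 1] >= 0.9
        assert protos.pattern_b.transitions[0, 1] >= 0.9  # broad -> eyes

    def test_pattern_b_more_consistent(self):
        protos = make_prototypes()
        ha = fixation_entropies(protos.pattern_a).h2_given_1
        hb = fixation_entropies(protos.pattern_b).h2_given_1
        assert hb < ha

    def test_round_trip_serialization(self, tmp_path):
        protos = make_prototypes()
        path = tmp_path / "a.json"
        protos.pattern_a.save(path)
        loaded = GaussianHMM.load(path)
        np.testing.assert_array_equal(loaded.transitions,
                                      protos.pattern_a.transitions)

    def test_degenerate_layout_rejected(self):
        lay = ROILayout(broad_center=(0.0, -5.0))  # coincides with eye center
        with pytest.raises(InputError):
            make_prototypes(layout=lay)


class TestPopulation:
    def test_zero_perturbation_reproduces_prototypes(self):
        protos = make_prototypes()
        neutral = TraitModel(strategy_shift_sd=0.0, consistency_gain_sd=0.0,
                             strategy_shift_mean=0.0, consistency_gain_mean=0.0)
        pop = sample_population(protos, 4, mix=0.0, perturb=0.0,
                                trait_model=neutral, seed=1)
        for member in pop:
            np.testing.assert_array_equal(
                member.models["recog_uu"].means, protos.pattern_a.means)
            np.testing.assert_array_equal(
                member.models["recog_uu"].transitions,
                protos.pattern_a.transitions)

    def test_mix_one_all_eyes_focused(self):
        pop = sample_population(make_prototypes(), 10, mix=1.0, seed=2)
        assert all(m.traits.archetype == "eyes_focused" for m in pop)

    def test_masked_models_shift_toward_b_and_lower_entropy(self):
        protos = make_prototypes()
        pop = sample_population(protos, 30, seed=3)
        h_uu = [fixation_entropies(m.models["recog_uu"]).h2_given_1 for m in pop]
        h_um = [fixation_entropies(m.models["recog_um"]).h2_given_1 for m in pop]
        assert np.mean(h_um) < np.mean(h_uu)
        # learning-phase models are identical across mask conditions
        for m in pop:
            np.testing.assert_array_equal(
                m.models["learn_unmasked"].means, m.models["learn_masked"].means)

    def test_shift_scales_with_parameter(self):
        protos = make_prototypes()
        base = protos.pattern_a
        near = shift_toward(base, protos.pattern_b, 0.2)
        far = shift_toward(base, protos.pattern_b, 0.8)
        d_near = np.abs(near.transitions - base.transitions).sum()
        d_far = np.abs(far.transitions - base.transitions).sum()
        assert d_far > d_near

    def test_sharpen_reduces_row_entropy_only(self):
        m = make_prototypes().pattern_a
        s = sharpen_transitions(m, 1.0)
        assert fixation_entropies(s).h2_given_1 < fixation_entropies(m).h2_given_1
        np.testing.assert_array_equal(s.prior, m.prior)


class TestSimulation:
    @pytest.fixture(scope="class")
    def small_study(self):
        design = ExperimentDesign(n_participants=10, n_blocks=2)
        protos = make_prototypes()
        pop = sample_population(protos, 10, seed=4)
        return design, pop

    def test_trial_counts_match_design(self, small_study):
        design, pop = small_study
        ds = simulate_experiment(design, pop, seed=5)
        per = ds.responses.groupby("participant_id").size()
        assert (per == design.n_blocks * 32).all()
        learn = [s for s in ds.fixations if s.phase == "learning"]
        assert len(learn) == 10 * design.n_blocks * 16

    def test_same_seed_byte_identical_files(self, small_study, tmp_path):
        design, pop = small_study
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        simulate_experiment(design, pop, seed=6).write(a_dir)
        simulate_experiment(design, pop, seed=6).write(b_dir)
        for name in ("fixations.csv", "responses.csv", "covariates.csv",
                     "ground_truth.json"):
            assert (a_dir / name).read_bytes() == (b_dir / name).read_bytes()

    def test_fixation_csv_round_trip(self, small_study, tmp_path):
        design, pop = small_study
        ds = simulate_experiment(design, pop, seed=7)
        ds.write(tmp_path)
        seqs = read_fixations(tmp_path / "fixations.csv")
        assert len(seqs) == len(ds.fixations)
        np.testing.assert_allclose(seqs[0].fixations, ds.fixations[0].fixations)

    def test_null_coupling_equal_dprime(self):
        """With zero offsets and couplings the four conditions share d'."""
        design = ExperimentDesign(n_participants=30, n_blocks=8)
        pop = sample_population(make_prototypes(), 30, seed=8)
        bc = BehaviorCoupling(offset_uu=0, offset_um=0, offset_mu=0,
                              offset_mm=0, strategy_to_mu=0,
                              consistency_to_um=0)
        ds = simulate_experiment(design, pop, bc, seed=9,
                                 include_fixations=False)
        gt = ds.ground_truth["participants"]
        for rec in gt.values():
            vals = list(rec["dprime_by_condition"].values())
            assert max(vals) - min(vals) < 1e-12

    def test_planted_coupling_sign_recovered(self):
        """Across replicates, higher strategy-shift participants show less
        mismatch impairment: the planted correlation is negative."""
        design = ExperimentDesign(n_participants=88, n_blocks=8)
        protos = make_prototypes()
        neg = 0
        reps = 12
        for rep in range(reps):
            pop = sample_population(protos, 88, seed=100 + rep)
            ds = simulate_experiment(design, pop, seed=200 + rep,
                                     include_fixations=False)
            wide = (ds.responses
                    .assign(said_old=lambda d: d["response"] == "old")
                    .groupby(["participant_id", "learn_mask", "recog_mask"])
                    .apply(lambda g: (
                        (g[g.is_old].said_old.mean() if g.is_old.any() else 0.5)
                        - (g[~g.is_old].said_old.mean() if (~g.is_old).any() else 0.5)),
                        include_groups=False)
                    .unstack([1, 2]))
            imp = (wide[("unmasked", "unmasked")]
                   - wide[("masked", "unmasked")]).to_numpy()
            strat = np.array([m.traits.strategy_shift for m in pop])
            neg += np.corrcoef(strat, imp)[0, 1] < 0
        assert neg >= int(0.9 * reps)

    def test_ground_truth_records_planted_quantities(self, small_study):
        design, pop = small_study
        ds = simulate_experiment(design, pop, seed=10)
        gt = ds.ground_truth
        assert set(gt["participants"]) == {m.participant_id for m in pop}
        rec = gt["participants"]["P000"]
        assert set(rec["dprime_by_condition"]) == {"uu", "um", "mu", "mm"}
        assert set(rec["models"]) >= {"recog_uu", "recog_mm"}
        json.dumps(gt)  # must be JSON-serializable
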