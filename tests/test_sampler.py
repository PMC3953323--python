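"""Sampler behaviour: block moves, sweeps, deferred clashes, side chains,
free endpoints and reproducibility."""
import math
import random

import numpy as np
import pytest

from loopmc.closure import Block
from loopmc.diagnostics import energy_distance_test
from loopmc.fixtures import make_planar_chain, spatial_seven_loop
from loopmc.kinematics import ExpandedState, forward_kinematics
from loopmc.planar import PlanarLoopSampler, WholeChainMH
from loopmc.rigid import frame_error
from loopmc.rotamers import ChiMixture, RotamerLibrary
from loopmc.sampler import (
    ProteinLoopSampler,
    SamplerConfig,
    run,
    sample_free_endpoint_block,
    spatial_block_mh,
)


class TestRun:
    def test_zero_samples_returns_only_initial_state(self, helix_system, toy_priors):
        cfg = SamplerConfig(n_samples=0, seed=3)
        states, report = run(cfg, helix_system["system"], helix_system["state"],
                             rama_grid=toy_priors["grid"])
        assert len(states) == 1
        np.testing.assert_array_equal(states[0].angles, helix_system["state"].angles)

    def test_same_seed_gives_bitwise_identical_ensembles(self, helix_system, toy_priors):
        cfg = SamplerConfig(n_samples=4, seed=11, proposal_mode="local",
                            local_sigma_deg=8.0, n_ik_seeds=150)
        a, _ = run(cfg, helix_system["system"], helix_system["state"],
                   rama_grid=toy_priors["grid"])
        b, _ = run(cfg, helix_system["system"], helix_system["state"],
                   rama_grid=toy_priors["grid"])
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.angles, sb.angles)
            assert np.array_equal(sa.frames, sb.frames)

    def test_emitted_states_close_and_satisfy_kinematics(self, helix_system, toy_priors):
        """Every emitted conformation closes to 1e-8 and its stored frames
        agree with recomputed forward kinematics (the expanded state stays
        kinematically consistent)."""
        system = helix_system["system"]
        cfg = SamplerConfig(n_samples=6, seed=5, proposal_mode="local",
                            local_sigma_deg=8.0, n_ik_seeds=150)
        states, _ = run(cfg, system, helix_system["state"], rama_grid=toy_priors["grid"])
        target = np.asarray(system.chain.end_frame_constraint)
        for st in states:
            dp, dR = frame_error(st.frames[-1], target)
            assert dp < 1e-8 and dR < 1e-8
            recomputed = forward_kinematics(system.chain, st.angles)
            assert np.max(np.abs(recomputed[:-1] - st.frames[:-1])) < 1e-8


class TestBlocks:
    def test_seven_residue_loop_has_four_blocks(self, tmp_path, toy_priors):
        from loopmc.backbone import load_state_from_pdb
        from loopmc.fixtures import make_mini_protein

        p = tmp_path / "seven.pdb"
        _, _, spec = make_mini_protein(p, n_residues=11, loop_start=3, loop_end=9,
                                       kind="helix", seed=2)
        system, state = load_state_from_pdb(p, spec)
        sampler = ProteinLoopSampler(system, state, SamplerConfig(n_samples=0))
        assert system.model.n_residues == 7
        assert len(sampler.block_starts) == 4  # starts at residues 1..4

    def test_four_residue_loop_has_one_block(self, tmp_path):
        from loopmc.backbone import load_state_from_pdb
        from loopmc.fixtures import make_mini_protein

        p = tmp_path / "four.pdb"
        _, _, spec = make_mini_protein(p, n_residues=8, loop_start=3, loop_end=6,
                                       kind="helix", seed=3)
        system, state = load_state_from_pdb(p, spec)
        sampler = ProteinLoopSampler(system, state, SamplerConfig(n_samples=0))
        assert len(sampler.block_starts) == 1

    def test_no_mixing_for_small_blocks(self):
        """Blocks of five or fewer spatial angles are overdetermined by the
        closure constraints: the state is bitwise unchanged over any number
        of sweeps."""
        chain, state = spatial_seven_loop()
        rng = np.random.default_rng(0)
        before_angles = state.angles.copy()
        before_frames = state.frames.copy()
        for _ in range(1000):
            for start in range(0, 3):
                step = spatial_block_mh(chain, state, Block(start, 5, n_dependent=6), rng)
                assert step.accepted  # the identity move
        assert np.array_equal(state.angles, before_angles)
        assert np.array_equal(state.frames, before_frames)


class TestDeferredClash:
    def test_deferred_and_eager_clash_orders_agree(self, helix_system, toy_priors):
        """Checking collisions after the acceptance draw gives identical
        accept/reject outcomes to checking them before, on the same random
        stream (the clash factor is binary, so it commutes with the
        Metropolis test); only the cost differs."""
        system = helix_system["system"]
        common = dict(n_samples=0, seed=7, proposal_mode="local",
                      local_sigma_deg=10.0, n_ik_seeds=150)
        deferred = ProteinLoopSampler(system, helix_system["state"],
                                      SamplerConfig(**common),
                                      rama_grid=toy_priors["grid"])
        eager = ProteinLoopSampler(system, helix_system["state"],
                                   SamplerConfig(eager_clash=True, **common),
                                   rama_grid=toy_priors["grid"])
        rng_a = np.random.default_rng(42)
        rng_b = np.random.default_rng(42)
        for sweep in range(4):
            for k in deferred.block_starts:
                step_a = deferred.sample_block_mh(k, rng_a)
                step_b = eager.sample_block_mh(k, rng_b)
                assert step_a.accepted == step_b.accepted
        assert np.array_equal(deferred.state.angles, eager.state.angles)


class TestSidechains:
    @staticmethod
    def _arg_system(tmp_path, arg=(5, 6)):
        from loopmc.backbone import load_state_from_pdb
        from loopmc.fixtures import make_mini_protein

        p = tmp_path / "arg.pdb"
        _, _, spec = make_mini_protein(p, n_residues=12, loop_start=4, loop_end=9,
                                       kind="helix", seed=4, arg_positions=arg)
        return load_state_from_pdb(p, spec)

    def test_clash_free_acceptance_equals_backbone_alpha(self, tmp_path, toy_priors):
        """In a clash-free environment the combined backbone+side-chain
        acceptance equals the backbone-only acceptance exactly (paired random
        streams)."""
        system, state = self._arg_system(tmp_path)
        system.env_positions = np.empty((0, 3))  # clash-free environment
        system.env_radii = np.empty(0)
        cfg_bb = SamplerConfig(n_samples=0, seed=1, use_clash=False,
                               proposal_mode="local", local_sigma_deg=8.0,
                               n_ik_seeds=150)
        cfg_sc = SamplerConfig(n_samples=0, seed=1, use_clash=False, use_rotamer=True,
                               proposal_mode="local", local_sigma_deg=8.0,
                               n_ik_seeds=150)
        lib = toy_priors["rotamers"]
        for seed in range(8):
            bb = ProteinLoopSampler(system, state, cfg_bb, rama_grid=toy_priors["grid"])
            sc = ProteinLoopSampler(system, state, cfg_sc, rama_grid=toy_priors["grid"],
                                    rotamer_library=lib)
            sc.env_radii = np.empty(0)
            step_a = bb.sample_block_mh(2, np.random.default_rng(seed))
            step_b = sc.sample_block_mh(2, np.random.default_rng(seed))
            assert step_a.alpha == step_b.alpha
            assert step_a.accepted == step_b.accepted

    def test_sidechain_clash_vetoes_block(self, tmp_path, toy_priors):
        """Any side-chain clash makes the block acceptance zero: the backbone
        update is rolled back."""
        system, state = self._arg_system(tmp_path)
        # a rotamer library whose chis slam the side chain into the backbone
        lib = RotamerLibrary(bin_width_deg=360.0)
        lib.add("ARG", 0, 0, ChiMixture(
            weights=np.array([1.0]),
            means=np.zeros((1, 4)),
            sigmas=np.full((1, 4), 1e-4),
        ))
        cfg = SamplerConfig(n_samples=0, seed=1, use_rotamer=True, use_clash=True,
                            clash_overlap=2.5,  # inflated radii: clash guaranteed
                            proposal_mode="local", local_sigma_deg=5.0, n_ik_seeds=150)
        sampler = ProteinLoopSampler(system, state, cfg, rama_grid=toy_priors["grid"],
                                     rotamer_library=lib)
        before = sampler.state.angles.copy()
        accepted = 0
        for seed in range(12):
            step = sampler.sample_block_mh(2, np.random.default_rng(seed))
            accepted += step.accepted
        assert accepted == 0
        np.testing.assert_array_equal(sampler.state.angles, before)


class TestFreeEndpoint:
    def test_uniform_score_always_accepts(self):
        from loopmc.fixtures import random_spatial_chain

        ch = random_spatial_chain(6, 1)
        rng = np.random.default_rng(0)
        q = rng.uniform(-np.pi, np.pi, 6)
        state = ExpandedState(angles=q, frames=forward_kinematics(ch, q))
        for _ in range(20):
            step = sample_free_endpoint_block(ch, state, 3, rng)
            assert step.accepted and step.alpha == 1.0

    def test_zero_perturbation_width_never_moves(self):
        from loopmc.fixtures import random_spatial_chain

        ch = random_spatial_chain(6, 2)
        rng = np.random.default_rng(0)
        q = rng.uniform(-np.pi, np.pi, 6)
        state = ExpandedState(angles=q, frames=forward_kinematics(ch, q))
        for _ in range(10):
            sample_free_endpoint_block(ch, state, 2, rng, sigma=0.0)
        np.testing.assert_array_equal(state.angles, q)

    def test_closed_chain_rejects_free_endpoint_moves(self):
        chain, state = spatial_seven_loop()
        with pytest.raises(ValueError):
            sample_free_endpoint_block(chain, state, 3, np.random.default_rng(0))

    def test_free_planar_chain_matches_whole_chain_mh_oracle(self):
        """The blocked free-endpoint sampler and a long-run whole-chain M-H
        oracle agree on a free 6-link chain with position priors."""
        fx = make_planar_chain(n_links=6, prior="position_gaussian", closed=False,
                               seed=5, position_sigma=0.6)
        s1 = PlanarLoopSampler(lengths=fx.lengths, base=fx.base, end=None,
                               init_angles=fx.init_angles, frame_logp=fx.frame_logp,
                               block_size=4, tail_sigma=math.radians(25.0))
        r1 = random.Random(1)
        samples1 = np.array(s1.run(60000, rng=r1, record_every=1))
        oracle = WholeChainMH(fx.lengths, fx.base, fx.init_angles,
                              frame_logp=fx.frame_logp, sigma=math.radians(20.0))
        r2 = random.Random(2)
        samples2 = np.array(oracle.run(120000, rng=r2, record_every=1))

        def emb(X):
            return np.concatenate([np.sin(X), np.cos(X)], axis=1)

        a = emb(samples1[::75][-700:])
        b = emb(samples2[::150][-700:])
        stat, p = energy_distance_test(a, b, n_permutations=200,
                                       rng=np.random.default_rng(0))
        assert p > 0.01, f"free-endpoint sampler disagrees with M-H oracle (p={p})"


class TestSweepOrdering:
    def test_forward_and_random_orderings_agree_in_distribution(self):
        """Block ordering has no effect on the stationary distribution."""
        fx = make_planar_chain(n_links=8, anchor_distance=4.0, prior="vonmises", seed=6)

        def run_order(order, seed):
            s = PlanarLoopSampler(lengths=fx.lengths, base=fx.base, end=fx.end,
                                  init_angles=fx.init_angles,
                                  angle_logp=fx.angle_logp, sweep_order=order)
            return np.array(s.run(40000, rng=random.Random(seed), record_every=1))

        a = run_order("forward", 1)[::45][-700:]
        b = run_order("random", 2)[::45][-700:]

        def emb(X):
            return np.concatenate([np.sin(X), np.cos(X)], axis=1)

        stat, p = energy_distance_test(emb(a), emb(b), n_permutations=200,
                                       rng=np.random.default_rng(0))
        assert p > 0.01, f"sweep orderings disagree (p={p})"
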