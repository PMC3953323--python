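"""Blocked Gibbs / Metropolis-Hastings samplers over kinematic chains.

The core update is Sample-Block-MH: draw a candidate for a block of
consecutive dihedrals with the sub-loop IK sampler, evaluate the forward and
reverse proposal densities Q = P(y) / (s sqrt(det G)) on the closure
manifold, and accept with the Metropolis-Hastings probability

    alpha = min(1, Phi_B(x') Q(x | .) / (Phi_B(x) Q(x' | .))).

A sweep updates overlapping blocks at one-residue stride down the loop.
Steric clashes are checked only after a move is provisionally accepted
(clash factors are binary, so deferring them changes cost, never the
accept/reject outcome).  Side chains are drawn from backbone-dependent
rotamer mixtures after a backbone block is accepted and can veto the whole
block on clash, which reproduces the exact joint acceptance probability.
"""
from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from .backbone import ProteinLoopSystem, backbone_to_atoms, sidechain_atoms
from .closure import Block, sample_block, solve_spatial_6
from .factors import VDW_RADII, RamachandranGrid, log_bfactor_factor
from .kinematics import ExpandedState, forward_kinematics
from .manifold import SingularChartError, block_chart_geometry, log_proposal_density
from .rotamers import RotamerLibrary

__all__ = [
    "MHStep",
    "SamplerConfig",
    "SidechainState",
    "ProteinLoopSampler",
    "spatial_block_mh",
    "sample_free_endpoint_block",
    "run",
]

LOG_TWO_PI = math.log(2.0 * math.pi)


@dataclass
class MHStep:
    """Record of one Sample-Block-MH move."""

    alpha: float
    accepted: bool
    log_phi_fwd: float = -math.inf
    log_phi_rev: float = -math.inf
    log_q_fwd: float = math.nan
    log_q_rev: float = math.nan
    failure_reason: str | None = None  # None | ik_failure | clash | singular


@dataclass
class SamplerConfig:
    """Run-time configuration; the seed fully determines the output."""

    block_residues: int = 4
    b: int = 8
    sweep_order: str = "forward"  # forward | backward | random
    n_samples: int = 100
    skip: int = 1
    seed: int = 0
    temperature: float = 1.0
    use_rama: bool = True
    use_bfactor: bool = True
    use_clash: bool = True
    use_rotamer: bool = False
    bfactor_scale: float = 1.0
    clash_overlap: float = 0.75
    n_ik_seeds: int = 300
    time_cutoff: float | None = None
    allow_finite_blocks: bool = False  # permit b == 6 (non-mixing) blocks
    #: independent-angle proposal: 'prior' samples the Ramachandran marginal
    #: (uniform without a grid), 'uniform' is always uniform, 'local' is a
    #: symmetric Gaussian random walk around the current angles (width
    #: local_sigma_deg) whose densities cancel in the acceptance ratio --
    #: useful where closure admits only a small neighbourhood of the current
    #: independent angles.  Any choice leaves the stationary law unchanged
    #: because the proposal density enters Q explicitly.
    proposal_mode: str = "prior"
    local_sigma_deg: float = 15.0
    #: record one entry per block move (alpha, accepted, failure reason) in
    #: the run report under "steps" -- a JSON-lines-ready trace
    log_steps: bool = False
    #: evaluate clash factors before the acceptance draw instead of after it
    #: (slower; identical outcomes -- the clash factor is binary).  Exists to
    #: verify that deferring the check changes cost, never the decision.
    eager_clash: bool = False

    def __post_init__(self) -> None:
        if self.b != 2 * self.block_residues:
            raise ValueError("b must equal two angles per residue in the block")
        if self.b < 7 and not self.allow_finite_blocks:
            raise ValueError(
                "spatial blocks need b >= 7 for a continuous solution manifold"
            )


@dataclass
class SidechainState:
    """Chi angles per residue index (radians, wrapped to [-pi, pi))."""

    chis: dict = field(default_factory=dict)

    def copy(self) -> "SidechainState":
        return SidechainState({k: v.copy() for k, v in self.chis.items()})


_SELECTION_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


class ProteinLoopSampler:
    """Blocked Gibbs sampler for one protein loop with closure anchors."""

    def __init__(
        self,
        system: ProteinLoopSystem,
        state: ExpandedState,
        config: SamplerConfig,
        rama_grid: RamachandranGrid | dict | None = None,
        rotamer_library: RotamerLibrary | None = None,
    ):
        self.system = system
        self.config = config
        self.rama_grid = rama_grid
        self.rotamer_library = rotamer_library
        self.chain = system.chain
        self.model = system.model
        self.L = system.model.n_residues
        if self.L < config.block_residues:
            raise ValueError("loop shorter than one block")
        self.state = state.copy()
        if self.chain.end_frame_constraint is not None:
            self.state.frames[-1] = np.asarray(self.chain.end_frame_constraint)
        self.atoms = backbone_to_atoms(self.model, self.state.frames)
        self.sidechains = SidechainState()
        self.block_starts = list(range(0, self.L - config.block_residues + 1))
        k = len(system.atom_selection)
        elements = [_SELECTION_ELEMENTS.get(a, "X") for a in system.atom_selection]
        self.loop_radii = np.array([VDW_RADII[e] for e in elements] * self.L)
        self.env_radii = np.array([VDW_RADII.get(e, VDW_RADII["X"]) for e in system.env_elements])
        self._exclusions = _backbone_exclusion_mask(self.L, system.atom_selection)
        self._env_exclusions = _anchor_exclusions(system)
        self.stats = {"proposed": 0, "accepted": 0, "ik_failure": 0, "clash": 0, "singular": 0}

    # -- priors ---------------------------------------------------------
    def _grid_for(self, residue_index: int) -> RamachandranGrid | None:
        if self.rama_grid is None:
            return None
        if isinstance(self.rama_grid, dict):
            return self.rama_grid.get(self.model.residue_names[residue_index])
        return self.rama_grid

    def prior_sampler(self, rng: np.random.Generator, angle_index: int) -> float:
        """Independent-angle proposal draw, per config.proposal_mode."""
        mode = self.config.proposal_mode
        if mode == "local":
            sigma = math.radians(self.config.local_sigma_deg)
            a = float(self.state.angles[angle_index]) + float(rng.normal(0.0, sigma))
            return math.atan2(math.sin(a), math.cos(a))
        grid = self._grid_for(angle_index // 2)
        if mode == "uniform" or grid is None or not self.config.use_rama:
            return float(rng.uniform(-math.pi, math.pi))
        which = "phi" if angle_index % 2 == 0 else "psi"
        return grid.sample_marginal(which, rng)

    def _log_prior_y(self, angle_indices, values) -> float:
        """Log proposal density of the independent angles.  The local
        random-walk proposal is symmetric between the forward and reverse
        moves, so its contribution cancels and is reported as 0."""
        if self.config.proposal_mode == "local":
            return 0.0
        total = 0.0
        for idx, v in zip(angle_indices, values):
            grid = self._grid_for(idx // 2)
            if self.config.proposal_mode == "uniform" or grid is None or not self.config.use_rama:
                total += -LOG_TWO_PI
            else:
                which = "phi" if idx % 2 == 0 else "psi"
                total += grid.log_marginal_density(which, float(v))
        return total

    # -- scoring --------------------------------------------------------
    def _log_phi_block(self, kres: int, angles: np.ndarray, frames: np.ndarray) -> float:
        """Product of non-clash factors touching the block of residues
        kres..kres+3 (Ramachandran per residue, B-factor per atom)."""
        nb = self.config.block_residues
        total = 0.0
        if self.config.use_rama and self.rama_grid is not None:
            for r in range(kres, kres + nb):
                grid = self._grid_for(r)
                if grid is None:
                    continue
                v = grid.lookup(float(angles[2 * r]), float(angles[2 * r + 1]))
                if v <= 0.0:
                    return -math.inf
                total += math.log(v)
        if self.config.use_bfactor:
            atoms = backbone_to_atoms(self.model, frames)
            c = self.config.bfactor_scale
            sel = self.system.atom_selection
            for r in range(kres, kres + nb):
                for j in range(len(sel)):
                    total += log_bfactor_factor(
                        atoms[r, j], self.system.mu_positions[r, j],
                        float(self.system.bfactors[r, j]), c,
                    )
        return total

    def _clash_free(self, kres: int, frames: np.ndarray) -> bool:
        """Deferred steric check of the block's moved atoms."""
        nb = self.config.block_residues
        atoms = backbone_to_atoms(self.model, frames)
        flat = atoms.reshape(-1, 3)
        nsel = atoms.shape[1]
        moved = np.arange(kres * nsel, (kres + nb) * nsel)
        static_loop = np.setdiff1d(np.arange(flat.shape[0]), moved)
        overlap = self.config.clash_overlap
        # moved vs static loop atoms
        if static_loop.size:
            d = np.linalg.norm(flat[moved][:, None] - flat[static_loop][None], axis=2)
            cut = overlap * (self.loop_radii[moved][:, None] + self.loop_radii[static_loop][None])
            bad = d < cut
            for a, b_ in zip(*np.nonzero(bad)):
                if (int(moved[a]), int(static_loop[b_])) not in self._exclusions:
                    return False
        # moved vs environment (anchor-bonded pairs are excluded)
        if self.system.env_positions.size:
            d = np.linalg.norm(flat[moved][:, None] - self.system.env_positions[None], axis=2)
            cut = overlap * (self.loop_radii[moved][:, None] + self.env_radii[None])
            for a, b_ in zip(*np.nonzero(d < cut)):
                if (int(moved[a]), int(b_)) not in self._env_exclusions:
                    return False
        # moved vs moved
        d = np.linalg.norm(flat[moved][:, None] - flat[moved][None], axis=2)
        cut = overlap * (self.loop_radii[moved][:, None] + self.loop_radii[moved][None])
        ii, jj = np.nonzero(d < cut)
        for a, b_ in zip(ii, jj):
            if a >= b_:
                continue
            if (int(moved[a]), int(moved[b_])) not in self._exclusions:
                return False
        return True

    # -- the core move --------------------------------------------------
    def sample_block_mh(self, kres: int, rng: np.random.Generator) -> MHStep:
        cfg = self.config
        i = 2 * kres
        b = cfg.b
        block = Block(i, b, n_dependent=6)
        self.stats["proposed"] += 1
        prop = sample_block(self.chain, self.state, block, self.prior_sampler, rng,
                            n_seeds=cfg.n_ik_seeds)
        u = float(rng.random())  # drawn unconditionally: keeps the stream
        if prop is None:  # identical whether clash checks are deferred or not
            self.stats["ik_failure"] += 1
            return MHStep(alpha=0.0, accepted=False, failure_reason="ik_failure")
        q_block, frames_block, s_fwd = prop
        cand_frames = self.state.frames.copy()
        cand_frames[i : i + b] = frames_block
        cand_angles = self.state.angles.copy()
        cand_angles[i : i + b] = q_block
        try:
            geom_f = block_chart_geometry(self.chain, cand_frames, block, s_fwd)
            # reverse move: IK solution count and chart metric at the current
            # state (s enters Q at both ends of the move)
            A_rev = self.state.frames[i + 1]
            dep = self.chain.subchain(i + 2, i + b, base_frame=A_rev)
            target = self.state.frames[i + b - 1]
            s_rev = solve_spatial_6(
                dep, A_rev, target, n_seeds=cfg.n_ik_seeds,
                extra_seeds=self.state.angles[None, i + 2 : i + b],
            ).count
            s_rev = max(s_rev, 1)
            geom_r = block_chart_geometry(self.chain, self.state.frames, block, s_rev)
        except SingularChartError:
            self.stats["singular"] += 1
            return MHStep(alpha=0.0, accepted=False, failure_reason="singular")
        idx_y = [i, i + 1]
        log_q_f = log_proposal_density(
            self._log_prior_y(idx_y, q_block[:2]), s_fwd, geom_f.log_det
        )
        log_q_r = log_proposal_density(
            self._log_prior_y(idx_y, self.state.angles[i : i + 2]), s_rev, geom_r.log_det
        )
        lp_f = self._log_phi_block(kres, cand_angles, cand_frames)
        lp_r = self._log_phi_block(kres, self.state.angles, self.state.frames)
        eager_clashing = False
        if cfg.use_clash and cfg.eager_clash:
            eager_clashing = not self._clash_free(kres, cand_frames)
            if eager_clashing:
                lp_f = -math.inf  # clash factor folded into the score
        log_alpha = (lp_f - lp_r) / cfg.temperature + log_q_r - log_q_f
        alpha = min(1.0, math.exp(min(log_alpha, 0.0)))
        step = MHStep(alpha=alpha, accepted=False, log_phi_fwd=lp_f, log_phi_rev=lp_r,
                      log_q_fwd=log_q_f, log_q_rev=log_q_r)
        if not (log_alpha >= 0.0 or u < math.exp(log_alpha)):
            if eager_clashing:
                self.stats["clash"] += 1
                step.failure_reason = "clash"
            return step
        # provisional acceptance; deferred clash factors
        if cfg.use_clash and not cfg.eager_clash and not self._clash_free(kres, cand_frames):
            self.stats["clash"] += 1
            step.failure_reason = "clash"
            return step
        if cfg.use_rotamer and self.rotamer_library is not None:
            sc = self.sample_sidechains(kres, cand_angles, cand_frames, rng)
            if sc is None:
                self.stats["clash"] += 1
                step.failure_reason = "clash"
                return step
            self.sidechains.chis.update(sc.chis)
        self.state.angles = cand_angles
        self.state.frames = cand_frames
        self.stats["accepted"] += 1
        step.accepted = True
        return step

    # -- side chains ----------------------------------------------------
    def sample_sidechains(
        self, kres: int, angles: np.ndarray, frames: np.ndarray, rng: np.random.Generator
    ) -> SidechainState | None:
        """Draw chi angles for the block's residues from their
        backbone-dependent mixtures; returns None when any side-chain atom
        clashes (rejecting the whole block).  B-factor priors are not applied
        to side chains."""
        nb = self.config.block_residues
        lib = self.rotamer_library
        out = SidechainState()
        backbone = backbone_to_atoms(self.model, frames).reshape(-1, 3)
        placed: list[np.ndarray] = []
        placed_radii: list[float] = []
        for r in range(kres, kres + nb):
            name = self.model.residue_names[r]
            if lib is None or not lib.has(name):
                continue
            mix = lib.mixture_for(name, float(angles[2 * r]), float(angles[2 * r + 1]))
            chis = mix.sample(rng)
            names, coords = sidechain_atoms(self.model, frames, r, chis)
            radii = np.array([VDW_RADII.get(e, VDW_RADII["X"]) for _, e in names])
            if not self._sidechain_clash_free(r, coords, radii, backbone, placed, placed_radii):
                return None
            placed.extend(coords)
            placed_radii.extend(radii)
            out.chis[r] = chis
        return out

    def _sidechain_clash_free(self, r, coords, radii, backbone, placed, placed_radii) -> bool:
        overlap = self.config.clash_overlap
        nsel = len(self.system.atom_selection)
        own = set(range(r * nsel, (r + 1) * nsel))
        for i3, (p, rad) in enumerate(zip(coords, radii)):
            for j, (bp, brad) in enumerate(zip(backbone, self.loop_radii)):
                if j in own:
                    continue
                if np.sum((p - bp) ** 2) < (overlap * (rad + brad)) ** 2:
                    return False
            if self.system.env_positions.size:
                d2 = np.sum((self.system.env_positions - p) ** 2, axis=1)
                if np.any(d2 < (overlap * (rad + self.env_radii)) ** 2):
                    return False
            for q, (pp, prad) in enumerate(zip(placed, placed_radii)):
                if np.sum((p - pp) ** 2) < (overlap * (rad + prad)) ** 2:
                    return False
            # intra-side-chain: atoms bonded within two steps are exempt
            for q in range(i3 - 2):
                if np.sum((p - coords[q]) ** 2) < (overlap * (rad + radii[q])) ** 2:
                    return False
        return True

    # -- sweeps ---------------------------------------------------------
    def gibbs_sweep(self, rng: np.random.Generator) -> list[MHStep]:
        """One pass of overlapping blocks at one-residue stride; ordering per
        config (no effect on the asymptotic distribution)."""
        order = list(self.block_starts)
        if self.config.sweep_order == "backward":
            order.reverse()
        elif self.config.sweep_order == "random":
            order = [order[k] for k in rng.permutation(len(order))]
        return [self.sample_block_mh(k, rng) for k in order]

    @property
    def acceptance_rate(self) -> float:
        return self.stats["accepted"] / max(1, self.stats["proposed"])


def _backbone_exclusion_mask(L: int, selection: tuple) -> set:
    """Bonded (1-2) and angle (1-3) pairs over the flat loop-atom layout."""
    idx = {name: j for j, name in enumerate(selection)}
    nsel = len(selection)

    def flat(i, name):
        return i * nsel + idx[name]

    pairs: set[tuple[int, int]] = set()

    def add(a, b):
        pairs.add((a, b))
        pairs.add((b, a))

    for i in range(L):
        if "N" in idx and "CA" in idx:
            add(flat(i, "N"), flat(i, "CA"))
        if "CA" in idx and "C" in idx:
            add(flat(i, "CA"), flat(i, "C"))
        if "C" in idx and "O" in idx:
            add(flat(i, "C"), flat(i, "O"))
        if "N" in idx and "C" in idx:
            add(flat(i, "N"), flat(i, "C"))  # 1-3 via CA
        if "CA" in idx and "O" in idx:
            add(flat(i, "CA"), flat(i, "O"))  # 1-3 via C
        if "N" in idx and "O" in idx:
            add(flat(i, "N"), flat(i, "O"))  # 1-4, tight in trans peptides
        if i + 1 < L:
            if "C" in idx and "N" in idx:
                add(flat(i, "C"), flat(i + 1, "N"))  # peptide bond
            if "CA" in idx and "N" in idx:
                add(flat(i, "CA"), flat(i + 1, "N"))  # 1-3
            if "O" in idx and "N" in idx:
                add(flat(i, "O"), flat(i + 1, "N"))  # 1-3
            if "C" in idx and "CA" in idx:
                add(flat(i, "C"), flat(i + 1, "CA"))  # 1-3
            if "C" in idx:
                add(flat(i, "C"), flat(i + 1, "C"))  # 1-4 across omega
            if "O" in idx and "CA" in idx:
                add(flat(i, "O"), flat(i + 1, "CA"))  # 1-4, planar peptide
    return pairs


def _anchor_exclusions(system: ProteinLoopSystem) -> set:
    """Bonded (1-2), angle (1-3) and planar-peptide 1-4 pairs between loop
    atoms and the covalently attached anchor residues, as (loop flat index,
    environment index) pairs."""
    sel = system.atom_selection
    idx = {name: j for j, name in enumerate(sel)}
    nsel = len(sel)
    L = system.model.n_residues
    prev_num = system.spec.start - 1
    next_num = system.spec.end + 1
    out: set[tuple[int, int]] = set()
    # (loop residue index, loop atom, anchor residue number, anchor atom)
    rules = [
        (0, "N", prev_num, "C"),   # peptide bond
        (0, "N", prev_num, "CA"),  # 1-3
        (0, "N", prev_num, "O"),   # 1-3
        (0, "CA", prev_num, "C"),  # 1-3
        (0, "CA", prev_num, "O"),  # 1-4, planar peptide
        (L - 1, "C", next_num, "N"),
        (L - 1, "C", next_num, "CA"),
        (L - 1, "C", next_num, "C"),  # 1-4 across omega
        (L - 1, "O", next_num, "N"),
        (L - 1, "O", next_num, "CA"),  # 1-4, planar peptide
        (L - 1, "CA", next_num, "N"),
    ]
    for res_i, aname, env_num, env_name in rules:
        if aname not in idx:
            continue
        for env_idx, (num, name) in enumerate(system.env_meta):
            if num == env_num and name == env_name:
                out.add((res_i * nsel + idx[aname], env_idx))
    return out


def spatial_block_mh(
    chain,
    state: ExpandedState,
    block: Block,
    rng: np.random.Generator,
    prior_sampler=None,
    log_prior_y=None,
    log_phi=None,
    n_seeds: int = 600,
) -> MHStep:
    """Generic Sample-Block-MH on a spatial chain with closure anchors.

    ``log_phi(angles, frames)`` scores the block factors (uniform when
    omitted).  Mutates ``state`` in place when the move is accepted.

    Blocks of b <= 5 angles are overdetermined by the six closure
    constraints: away from singular conformations the conditional is a Dirac
    at the current state, so the move is the identity and the chain never
    mixes.  Blocks of b == 6 propose from the finite IK solution set (also
    non-mixing: the walk is restricted to finitely many conformations).
    """
    b = block.size
    i = block.start
    if prior_sampler is None:
        prior_sampler = lambda rng_, idx: float(rng_.uniform(-math.pi, math.pi))
        log_prior_y = lambda vals: -LOG_TWO_PI * len(vals)
    if b <= 5:
        # overdetermined closure: Dirac conditional, identity move
        return MHStep(alpha=1.0, accepted=True)
    prop = sample_block(chain, state, block, prior_sampler, rng, n_seeds=n_seeds)
    u = float(rng.random())
    if prop is None:
        return MHStep(alpha=0.0, accepted=False, failure_reason="ik_failure")
    q_block, frames_block, s_fwd = prop
    cand_frames = state.frames.copy()
    cand_frames[i : i + b] = frames_block
    cand_angles = state.angles.copy()
    cand_angles[i : i + b] = q_block
    ni = block.n_independent
    try:
        geom_f = block_chart_geometry(chain, cand_frames, block, s_fwd)
        A_rev = chain.base_frame if ni == 0 and i == 0 else (
            state.frames[i + ni - 1] if ni > 0 else state.frames[i - 1]
        )
        dep = chain.subchain(i + ni, i + b, base_frame=A_rev)
        target = state.frames[i + b - 1]
        s_rev = solve_spatial_6(
            dep, A_rev, target, n_seeds=n_seeds,
            extra_seeds=state.angles[None, i + ni : i + b],
        ).count
        s_rev = max(s_rev, 1)
        geom_r = block_chart_geometry(chain, state.frames, block, s_rev)
    except SingularChartError:
        return MHStep(alpha=0.0, accepted=False, failure_reason="singular")
    log_q_f = log_proposal_density(log_prior_y(q_block[:ni]), s_fwd, geom_f.log_det)
    log_q_r = log_proposal_density(
        log_prior_y(state.angles[i : i + ni]), s_rev, geom_r.log_det
    )
    lp_f = log_phi(cand_angles, cand_frames) if log_phi else 0.0
    lp_r = log_phi(state.angles, state.frames) if log_phi else 0.0
    log_alpha = lp_f - lp_r + log_q_r - log_q_f
    alpha = min(1.0, math.exp(min(log_alpha, 0.0)))
    step = MHStep(alpha=alpha, accepted=False, log_phi_fwd=lp_f, log_phi_rev=lp_r,
                  log_q_fwd=log_q_f, log_q_rev=log_q_r)
    if log_alpha >= 0.0 or u < math.exp(log_alpha):
        state.angles = cand_angles
        state.frames = cand_frames
        step.accepted = True
    return step


def sample_free_endpoint_block(
    chain,
    state: ExpandedState,
    start: int,
    rng: np.random.Generator,
    sigma: float = math.radians(1.0),
    log_phi=None,
) -> MHStep:
    """Standard Metropolis-Hastings update of a terminal (free-endpoint)
    block: Gaussian perturbation of the angles from ``start`` to the chain
    end, no closure and no metric correction.  The proposal is symmetric, so
    alpha = min(1, Phi ratio).  Zero perturbation width leaves the chain
    unchanged."""
    if chain.end_frame_constraint is not None:
        raise ValueError("terminal block sampling requires a free endpoint")
    n = chain.n_joints
    cand_angles = state.angles.copy()
    cand_angles[start:] += rng.normal(0.0, sigma, n - start)
    u = float(rng.random())
    base = chain.base_frame if start == 0 else state.frames[start - 1]
    tail = chain.subchain(start, n, base_frame=base)
    cand_frames = state.frames.copy()
    cand_frames[start:] = forward_kinematics(tail, cand_angles[start:], base=base)
    lp_f = log_phi(cand_angles, cand_frames) if log_phi else 0.0
    lp_r = log_phi(state.angles, state.frames) if log_phi else 0.0
    log_alpha = lp_f - lp_r
    alpha = min(1.0, math.exp(min(log_alpha, 0.0)))
    step = MHStep(alpha=alpha, accepted=False, log_phi_fwd=lp_f, log_phi_rev=lp_r)
    if log_alpha >= 0.0 or u < math.exp(log_alpha):
        state.angles = cand_angles
        state.frames = cand_frames
        step.accepted = True
    return step


def run(
    config: SamplerConfig,
    system: ProteinLoopSystem,
    initial_state: ExpandedState,
    rama_grid: RamachandranGrid | dict | None = None,
    rotamer_library: RotamerLibrary | None = None,
) -> tuple[list[ExpandedState], dict]:
    """Run the loop sampler: ``n_samples`` sweeps (or until the time cutoff),
    recording one conformation per sweep plus a thinned ensemble.

    Deterministic given ``config.seed``.  Returns (all states including the
    initial one, report).  The report carries the config echo, acceptance
    statistics per failure reason and the thinned-sample indices.
    """
    rng = np.random.default_rng(config.seed)
    sampler = ProteinLoopSampler(system, initial_state, config, rama_grid, rotamer_library)
    states = [sampler.state.copy()]
    step_log: list[dict] = []
    t0 = time.monotonic()
    for sweep in range(config.n_samples):
        steps = sampler.gibbs_sweep(rng)
        if config.log_steps:
            step_log.extend(
                {"sweep": sweep, "alpha": s.alpha, "accepted": s.accepted,
                 "reason": s.failure_reason}
                for s in steps
            )
        states.append(sampler.state.copy())
        if config.time_cutoff is not None and time.monotonic() - t0 > config.time_cutoff:
            break
    thinned = list(range(0, len(states), max(1, config.skip)))
    report: dict = {
        "seed": config.seed,
        "n_sweeps_run": len(states) - 1,
        "acceptance_rate": sampler.acceptance_rate,
        "stats": dict(sampler.stats),
        "thinned_indices": thinned,
        "config": {k: getattr(config, k) for k in (
            "block_residues", "b", "sweep_order", "n_samples", "skip", "seed",
            "temperature", "use_rama", "use_bfactor", "use_clash", "use_rotamer",
            "bfactor_scale")},
    }
    if config.log_steps:
        report["steps"] = step_log
    return states, report
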