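"""Planar branched blocks: trees of revolute joints with multiple closures.

A planar tree is a set of joints with parent pointers; each joint's frame is
its parent's frame (or the base) advanced by a link translation and a
rotation.  Anchors pin the frames of selected joints to fixed poses.  A
branched block treats, for each anchor, the last three joints on the path to
it as a dependent subchain closed by planar IK in topological order; all
remaining joints are independent.  The proposal density over the multi-loop
solution manifold is Q = P(y) / (s sqrt(det G)) with s the product of
per-anchor solution counts and G assembled from the sparse multi-constraint
implicit Jacobian.  A tree with no anchored branches degenerates exactly to
the linear planar block.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .planar import solve_planar_3r, wrap_angle

__all__ = ["PlanarTree", "BranchedBlockSampler", "fk_tree"]


@dataclass
class PlanarTree:
    """parents[j] is the parent joint of j (-1 for the base); lengths[j] is
    the link translation preceding rotation j; anchors maps a joint index to
    the fixed pose its frame must hold."""

    parents: list
    lengths: list
    base: tuple = (0.0, 0.0, 0.0)
    anchors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.parents)
        if len(self.lengths) != n:
            raise ValueError("parents and lengths must have equal length")
        for j, p in enumerate(self.parents):
            if p >= j:
                raise ValueError("parents must precede children (topological order)")
        for a in self.anchors:
            if not 0 <= a < n:
                raise ValueError(f"anchor joint {a} out of range")

    @property
    def n_joints(self) -> int:
        return len(self.parents)

    def path_to(self, j: int) -> list:
        out = []
        while j >= 0:
            out.append(j)
            j = self.parents[j]
        return out[::-1]

    def closure_plan(self) -> list:
        """Per anchor (in topological order): (anchor joint, the dependent
        triple = last 3 joints on its path).  Each anchored path needs at
        least 3 joints, and the dependent triples must be disjoint."""
        plan = []
        used: set[int] = set()
        for a in sorted(self.anchors):
            path = self.path_to(a)
            if len(path) < 3:
                raise ValueError(f"anchored path to joint {a} has fewer than 3 joints")
            triple = path[-3:]
            if any(t in used for t in triple):
                raise ValueError("dependent subchains of two anchors overlap")
            used.update(triple)
            plan.append((a, triple))
        return plan


def fk_tree(tree: PlanarTree, q) -> list:
    """Poses of all joint frames given the angle vector."""
    poses = [None] * tree.n_joints
    for j in range(tree.n_joints):
        px, py, pth = tree.base if tree.parents[j] < 0 else poses[tree.parents[j]]
        x = px + tree.lengths[j] * math.cos(pth)
        y = py + tree.lengths[j] * math.sin(pth)
        poses[j] = (x, y, pth + q[j])
    return poses


class BranchedBlockSampler:
    """Metropolis-Hastings sampling of a whole planar tree as one branched
    block (toy scale: the block covers all state variables)."""

    def __init__(self, tree: PlanarTree, init_angles, angle_logp=None, frame_logp=None,
                 drop_det_g: bool = False, drop_solution_count: bool = False,
                 proposal_sigma: float | None = None):
        #: proposal_sigma: width of a symmetric Gaussian random walk on the
        #: independent angles (None = uniform independence proposal).  The
        #: symmetric densities cancel in the acceptance ratio, so either
        #: choice leaves the stationary law unchanged; local proposals help
        #: when most of independent-angle space admits no closure.
        self.tree = tree
        self.plan = tree.closure_plan()
        dep = [t for _, triple in self.plan for t in triple]
        self.dep = dep
        self.indep = [j for j in range(tree.n_joints) if j not in set(dep)]
        self.q = [wrap_angle(a) for a in init_angles]
        self.poses = fk_tree(tree, self.q)
        for a, _ in self.plan:
            ax, ay, ath = tree.anchors[a]
            px, py, pth = self.poses[a]
            if math.hypot(px - ax, py - ay) > 1e-6 or abs(wrap_angle(pth - ath)) > 1e-6:
                raise ValueError("initial conformation violates an anchor")
            self.poses[a] = tree.anchors[a]
        self.angle_logp = angle_logp or [None] * tree.n_joints
        self.frame_logp = frame_logp or [None] * tree.n_joints
        self.drop_det_g = drop_det_g
        self.drop_solution_count = drop_solution_count
        self.proposal_sigma = proposal_sigma
        self.n_proposed = 0
        self.n_accepted = 0
        self.n_ik_failures = 0

    # -- closure --------------------------------------------------------
    def close(self, y_values, rng=None, branch_choice=None):
        """Assemble a full angle vector from independent values by closing
        each anchored branch in topological order.

        Returns (q, poses, s, choices) or None when any branch has no IK
        solution.  ``branch_choice`` forces the branch picks (used by the
        reverse-move evaluation and by oracles)."""
        q = [0.0] * self.tree.n_joints
        for j, v in zip(self.indep, y_values):
            q[j] = v
        poses = [None] * self.tree.n_joints
        s_total = 1
        choices = []
        solved: set[int] = set()

        def pose_of(j):
            if j < 0:
                return self.tree.base
            return poses[j]

        # process joints in topological order, pausing at dependent triples
        done = [False] * self.tree.n_joints
        triples = {triple[0]: (a, triple) for a, triple in self.plan}
        j = 0
        for j in range(self.tree.n_joints):
            if done[j]:
                continue
            if j in triples:
                a, triple = triples[j]
                start_pose = pose_of(self.tree.parents[triple[0]])
                if start_pose is None:
                    raise RuntimeError("topological order violated in closure plan")
                sols = solve_planar_3r(
                    start_pose,
                    self.tree.lengths[triple[0]],
                    self.tree.lengths[triple[1]],
                    self.tree.lengths[triple[2]],
                    self.tree.anchors[a],
                )
                if not sols:
                    return None
                if branch_choice is not None:
                    pick = branch_choice[len(choices)] % len(sols)
                else:
                    pick = rng.randrange(len(sols)) if len(sols) > 1 else 0
                s_total *= len(sols)
                choices.append(pick)
                z = sols[pick]
                prev = start_pose
                for t, ang in zip(triple, z):
                    q[t] = ang
                    px, py, pth = prev
                    x = px + self.tree.lengths[t] * math.cos(pth)
                    yv = py + self.tree.lengths[t] * math.sin(pth)
                    prev = (x, yv, pth + ang)
                    poses[t] = prev
                    done[t] = True
                poses[triple[2]] = self.tree.anchors[a]  # snap
            else:
                px, py, pth = pose_of(self.tree.parents[j])
                x = px + self.tree.lengths[j] * math.cos(pth)
                yv = py + self.tree.lengths[j] * math.sin(pth)
                poses[j] = (x, yv, pth + q[j])
                done[j] = True
        return q, poses, s_total, choices

    # -- geometry -------------------------------------------------------
    def _origins(self, poses):
        """Rotation centre of each joint: its own frame origin."""
        return [(p[0], p[1]) for p in poses]

    def log_det_g(self, q, poses):
        """log det of the branched-block metric via the multi-constraint
        implicit Jacobian; None at singular conformations."""
        tree = self.tree
        n = tree.n_joints
        origins = self._origins(poses)
        on_path = [set(tree.path_to(a)) for a, _ in self.plan]
        nC = 3 * len(self.plan)
        C = np.zeros((nC, n))
        for c, ((a, _), members) in enumerate(zip(self.plan, on_path)):
            ax, ay, _ = tree.anchors[a]
            for j in members:
                ox, oy = origins[j]
                C[3 * c + 0, j] = -(ay - oy)
                C[3 * c + 1, j] = ax - ox
                C[3 * c + 2, j] = 1.0
        Cy = C[:, self.indep]
        Cz = C[:, self.dep]
        sv = np.linalg.svd(Cz, compute_uv=False)
        if sv[-1] <= 1e-10 * sv[0]:
            return None
        dzdy = -np.linalg.solve(Cz, Cy)
        ni = len(self.indep)
        dq_dy = np.zeros((n, ni))
        for r, j in enumerate(self.indep):
            dq_dy[j, r] = 1.0
        for r, j in enumerate(self.dep):
            dq_dy[j, :] = dzdy[r]
        rows = [dq_dy]
        # frame-origin rows for every joint frame (angular rows weight 0)
        ancestors = [set(tree.path_to(k)) for k in range(n)]
        for k in range(n):
            fx, fy = origins[k]
            Jp = np.zeros((2, n))
            for j in ancestors[k]:
                ox, oy = origins[j]
                Jp[0, j] = -(fy - oy)
                Jp[1, j] = fx - ox
            rows.append(Jp @ dq_dy)
        J = np.vstack(rows)
        G = J.T @ J
        sign, ld = np.linalg.slogdet(G)
        if sign <= 0:
            return None
        return float(ld)

    def _log_phi(self, q, poses):
        total = 0.0
        for j in range(self.tree.n_joints):
            f = self.angle_logp[j]
            if f is not None:
                total += f(q[j])
            g = self.frame_logp[j]
            if g is not None:
                total += g(poses[j][0], poses[j][1])
        return total

    def _log_q(self, q, poses, s):
        logq = -len(self.indep) * math.log(2.0 * math.pi)
        if not self.drop_solution_count:
            logq -= math.log(s)
        if not self.drop_det_g:
            ld = self.log_det_g(q, poses)
            if ld is None:
                return None
            logq -= 0.5 * ld
        return logq

    # -- the move -------------------------------------------------------
    def step(self, rng):
        """One branched-block M-H move."""
        self.n_proposed += 1
        if self.proposal_sigma is None:
            y = [rng.uniform(-math.pi, math.pi) for _ in self.indep]
        else:
            y = [wrap_angle(self.q[j] + rng.gauss(0.0, self.proposal_sigma))
                 for j in self.indep]
        closed = self.close(y, rng=rng)
        u = rng.random()
        if closed is None:
            self.n_ik_failures += 1
            return False
        q_new, poses_new, s_fwd, _ = closed
        logq_f = self._log_q(q_new, poses_new, s_fwd)
        if logq_f is None:
            return False
        # reverse: solution count at the current independent values
        cur_y = [self.q[j] for j in self.indep]
        closed_rev = self.close(cur_y, branch_choice=[0] * len(self.plan))
        s_rev = closed_rev[2] if closed_rev is not None else 1
        logq_r = self._log_q(self.q, self.poses, s_rev)
        if logq_r is None:
            return False
        d = self._log_phi(q_new, poses_new) - self._log_phi(self.q, self.poses)
        log_alpha = d + logq_r - logq_f
        if log_alpha >= 0.0 or u < math.exp(log_alpha):
            self.q = q_new
            self.poses = poses_new
            self.n_accepted += 1
            return True
        return False

    def run(self, n_steps, rng, record_every=1):
        out = []
        for k in range(n_steps):
            self.step(rng)
            if (k + 1) % record_every == 0:
                out.append(tuple(self.q))
        return out

    @property
    def acceptance_rate(self):
        return self.n_accepted / max(1, self.n_proposed)
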