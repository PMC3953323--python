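"""Fast planar-chain engine for long Monte Carlo runs.

The generic 3D machinery (kinematics / closure / manifold modules) handles
planar chains as a special case; this module re-implements the planar block
update with plain Python floats so that runs with hundreds of thousands of
block moves complete in seconds.  A dedicated test asserts that the two code
paths agree on the same inputs.

Conventions: a planar pose is a tuple (x, y, theta); joint j first translates
by L_j along the local x axis and then rotates by q_j about +z, so the origin
of frame j is fixed under its own rotation.
"""
from __future__ import annotations

import math
import random
from dataclasses import dataclass

TWO_PI = 2.0 * math.pi


def wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = math.fmod(a, TWO_PI)
    if a <= -math.pi:
        a += TWO_PI
    elif a > math.pi:
        a -= TWO_PI
    return a


def fk_poses(lengths, base, q):
    """Poses of frames 1..N (list of (x, y, theta)) from the base pose."""
    x, y, th = base
    out = []
    for L, qq in zip(lengths, q):
        x += L * math.cos(th)
        y += L * math.sin(th)
        th = th + qq
        out.append((x, y, th))
    return out


def solve_planar_3r(anchor, L1, L2, L3, target, tol=1e-12):
    """All angle triples (q1, q2, q3) closing a planar 3-link chain.

    ``anchor`` is the pose preceding the first dependent joint; the first
    dependent joint origin is anchor + L1 along the anchor heading.  ``target``
    is the required pose of the frame after the third rotation.  Generic
    reachable targets give exactly two solutions (elbow up/down); tangency
    gives one; unreachable targets give an empty list.
    """
    ax, ay, ath = anchor
    tx, ty, tth = target
    c1x = ax + L1 * math.cos(ath)
    c1y = ay + L1 * math.sin(ath)
    vx = tx - c1x
    vy = ty - c1y
    d2 = vx * vx + vy * vy
    d = math.sqrt(d2)
    if d < 1e-12:
        # coincident circle centers: either no solution or a continuum
        # (singular); treat as unsolvable -- measure zero in practice.
        return []
    a = (L2 * L2 - L3 * L3 + d2) / (2.0 * d)
    h2 = L2 * L2 - a * a
    if h2 < -tol * max(1.0, L2 * L2):
        return []
    h = math.sqrt(h2) if h2 > 0.0 else 0.0
    ux, uy = vx / d, vy / d
    bx = c1x + a * ux
    by = c1y + a * uy
    sols = []
    offsets = (h, -h) if h > 1e-9 * max(1.0, L2) else (0.0,)
    for off in offsets:
        c2x = bx - off * uy
        c2y = by + off * ux
        th1 = math.atan2(c2y - c1y, c2x - c1x)
        th2 = math.atan2(ty - c2y, tx - c2x)
        q1 = wrap_angle(th1 - ath)
        q2 = wrap_angle(th2 - th1)
        q3 = wrap_angle(tth - th2)
        sols.append((q1, q2, q3))
    return sols


def block_log_det_g(origins, target_xy, n_indep, weight_frames=True):
    """log det G for a planar block.

    origins : joint origins o_j of the block's angles, in chain order
        (independent then dependent); frame origins of the intervening frames
        coincide with the dependent-joint origins plus the independent ones
        past the first, which is exactly the o_j list minus nothing -- the
        block's intervening frames are the frames of its first b-1 joints.
    target_xy : (x, y) of the fixed terminal frame.
    n_indep : number of independent angles (b - 3).

    The chart stacks [I; dz/dy; frame-origin rows]; angular frame rows carry
    zero weight by default (heterogeneous units).
    """
    b = len(origins)
    tx, ty = target_xy
    # constraint Jacobian columns: d(terminal pose)/dq_j = (-(ty-ojy), tx-ojx, 1)
    cols = [(-(ty - oy), tx - ox, 1.0) for (ox, oy) in origins]
    Cy = cols[:n_indep]
    Cz = cols[n_indep:]
    # dz/dy = -Cz^{-1} Cy   (3x3 solve, closed form)
    a11, a21, a31 = Cz[0]
    a12, a22, a32 = Cz[1]
    a13, a23, a33 = Cz[2]
    det = (
        a11 * (a22 * a33 - a23 * a32)
        - a12 * (a21 * a33 - a23 * a31)
        + a13 * (a21 * a32 - a22 * a31)
    )
    if abs(det) < 1e-12:
        return None  # singular dependent subchain
    i11 = (a22 * a33 - a23 * a32) / det
    i12 = (a13 * a32 - a12 * a33) / det
    i13 = (a12 * a23 - a13 * a22) / det
    i21 = (a23 * a31 - a21 * a33) / det
    i22 = (a11 * a33 - a13 * a31) / det
    i23 = (a13 * a21 - a11 * a23) / det
    i31 = (a21 * a32 - a22 * a31) / det
    i32 = (a12 * a31 - a11 * a32) / det
    i33 = (a11 * a22 - a12 * a21) / det
    dzdy = []  # 3 x n_indep
    for r, (r1, r2, r3) in enumerate(((i11, i12, i13), (i21, i22, i23), (i31, i32, i33))):
        row = []
        for m in range(n_indep):
            cy1, cy2, cy3 = Cy[m]
            row.append(-(r1 * cy1 + r2 * cy2 + r3 * cy3))
        dzdy.append(row)
    # dq/dy: identity over independent rows, dzdy over dependent rows
    dq = [[1.0 if r == m else 0.0 for m in range(n_indep)] for r in range(n_indep)]
    dq.extend(dzdy)
    # G = dq^T dq  (angle rows of the chart)
    G = [[0.0] * n_indep for _ in range(n_indep)]
    for row in dq:
        for r in range(n_indep):
            vr = row[r]
            if vr == 0.0:
                continue
            for c in range(r, n_indep):
                G[r][c] += vr * row[c]
    if weight_frames:
        # frame-origin rows: intervening frames are frames of joints 1..b-1 of
        # the block; frame k origin is the origin of joint k+1 (translation
        # precedes rotation), and is moved by block joints j <= k.
        for k in range(b - 1):
            fx, fy = origins[k + 1]
            # velocity of this origin wrt block angle j (j <= k): z x (p - o_j)
            vxs = []
            vys = []
            for j in range(k + 1):
                ox, oy = origins[j]
                vxs.append(-(fy - oy))
                vys.append(fx - ox)
            # rows = [vx; vy] . dq  (columns over y)
            rowx = [0.0] * n_indep
            rowy = [0.0] * n_indep
            for j in range(k + 1):
                dqj = dq[j]
                vx = vxs[j]
                vy = vys[j]
                for m in range(n_indep):
                    rowx[m] += vx * dqj[m]
                    rowy[m] += vy * dqj[m]
            for r in range(n_indep):
                for c in range(r, n_indep):
                    G[r][c] += rowx[r] * rowx[c] + rowy[r] * rowy[c]
    for r in range(n_indep):
        for c in range(r):
            G[r][c] = G[c][r]
    # determinant of small SPD matrix
    if n_indep == 1:
        det_g = G[0][0]
    elif n_indep == 2:
        det_g = G[0][0] * G[1][1] - G[0][1] * G[1][0]
    else:
        det_g = _det(G)
    if det_g <= 1e-14:
        return None
    return math.log(det_g)


def _det(M):
    n = len(M)
    A = [row[:] for row in M]
    det = 1.0
    for i in range(n):
        p = max(range(i, n), key=lambda r: abs(A[r][i]))
        if abs(A[p][i]) < 1e-300:
            return 0.0
        if p != i:
            A[i], A[p] = A[p], A[i]
            det = -det
        det *= A[i][i]
        inv = 1.0 / A[i][i]
        for r in range(i + 1, n):
            f = A[r][i] * inv
            for c in range(i, n):
                A[r][c] -= f * A[i][c]
    return det


LOG_TWO_PI = math.log(TWO_PI)


@dataclass
class PlanarLoopSampler:
    """Blocked Gibbs / Metropolis-Hastings sampler for a planar closed chain.

    Parameters
    ----------
    lengths : link lengths L_1..L_N
    base : base pose (x, y, theta)
    end : fixed terminal pose of frame N (loop closure anchor)
    init_angles : a closed initial conformation
    angle_logp : optional per-joint log prior density over the joint angle
        (list of callables or None entries; None means uniform)
    frame_logp : optional per-frame log prior over the frame origin
        (list of callables f(x, y) or None)
    block_size : b, number of consecutive angles per block (>= 4)
    proposal_sampler / proposal_logp : independent-angle proposal; default is
        uniform on (-pi, pi].  Any choice leaves the stationary law unchanged
        because the proposal density enters the acceptance ratio explicitly.
    drop_det_g, drop_solution_count : debug switches that deliberately omit
        the sqrt(det G) or 1/s correction from the proposal density (negative
        controls for bias tests; never used in production runs).
    """

    lengths: list
    base: tuple
    end: tuple | None
    init_angles: list
    angle_logp: list | None = None
    frame_logp: list | None = None
    block_size: int = 4
    proposal_sampler: object = None
    proposal_logp: object = None
    drop_det_g: bool = False
    drop_solution_count: bool = False
    sweep_order: str = "forward"
    tail_sigma: float = math.radians(5.0)  # free-endpoint tail perturbation

    n_proposed: int = 0
    n_accepted: int = 0
    n_ik_failures: int = 0

    def __post_init__(self):
        self.n = len(self.lengths)
        b = self.block_size
        if b < 4:
            raise ValueError("planar mixing blocks need at least 4 angles")
        if b > self.n:
            raise ValueError("block size exceeds chain length")
        self.q = [wrap_angle(a) for a in self.init_angles]
        self.poses = fk_poses(self.lengths, self.base, self.q)
        if self.end is not None:
            ex, ey, eth = self.end
            px, py, pth = self.poses[-1]
            if math.hypot(px - ex, py - ey) > 1e-6 or abs(wrap_angle(pth - eth)) > 1e-6:
                raise ValueError("initial conformation does not satisfy loop closure")
            # snap the stored terminal frame to the exact anchor
            self.poses[-1] = (ex, ey, eth)
        if self.angle_logp is None:
            self.angle_logp = [None] * self.n
        if self.frame_logp is None:
            self.frame_logp = [None] * self.n
        if self.proposal_sampler is None:
            self.proposal_sampler = lambda rng: rng.uniform(-math.pi, math.pi)
            self.proposal_logp = lambda q: -LOG_TWO_PI
        self.block_starts = list(range(0, self.n - b + 1))

    # -- scoring ---------------------------------------------------------
    def _block_logphi(self, i, qblock, poses_block):
        """Log product of prior factors touching block angles i..i+b-1 and
        frames i..i+b-2 (the terminal block frame is fixed)."""
        b = self.block_size
        total = 0.0
        for j in range(b):
            f = self.angle_logp[i + j]
            if f is not None:
                total += f(qblock[j])
        for k in range(b - 1):
            f = self.frame_logp[i + k]
            if f is not None:
                x, y, _ = poses_block[k]
                total += f(x, y)
        return total

    def _origins(self, i, anchor_pose, poses_block):
        """Joint origins o_{i..i+b-1}: origin of frame j (rotation center)."""
        b = self.block_size
        origins = []
        prev = anchor_pose
        for j in range(b):
            x, y, th = prev
            L = self.lengths[i + j]
            origins.append((x + L * math.cos(th), y + L * math.sin(th)))
            prev = poses_block[j]
        return origins

    def _log_q(self, i, anchor_pose, qblock, poses_block, s, target):
        b = self.block_size
        n_indep = b - 3
        logq = 0.0
        for m in range(n_indep):
            logq += self.proposal_logp(qblock[m])
        if not self.drop_solution_count:
            logq -= math.log(s)
        if not self.drop_det_g:
            origins = self._origins(i, anchor_pose, poses_block)
            ld = block_log_det_g(origins, (target[0], target[1]), n_indep)
            if ld is None:
                return None
            logq -= 0.5 * ld
        return logq

    # -- sampling --------------------------------------------------------
    def propose_block(self, i, rng):
        """One Sample-Block draw for the block starting at angle i.

        Returns (qblock, poses_block, s, anchor_pose, target) or None on IK
        failure.  Does not touch the chain state.
        """
        b = self.block_size
        n_indep = b - 3
        anchor_pose = self.base if i == 0 else self.poses[i - 1]
        target = self.poses[i + b - 1]
        y = [self.proposal_sampler(rng) for _ in range(n_indep)]
        poses_block = []
        prev = anchor_pose
        for m in range(n_indep):
            x, yy, th = prev
            L = self.lengths[i + m]
            nx = x + L * math.cos(th)
            ny = yy + L * math.sin(th)
            nth = th + y[m]
            prev = (nx, ny, nth)
            poses_block.append(prev)
        sols = solve_planar_3r(
            prev,
            self.lengths[i + n_indep],
            self.lengths[i + n_indep + 1],
            self.lengths[i + n_indep + 2],
            target,
        )
        s = len(sols)
        if s == 0:
            return None
        z = sols[rng.randrange(s)] if s > 1 else sols[0]
        qblock = y + list(z)
        # dependent frames
        x, yy, th = prev
        for m in range(3):
            L = self.lengths[i + n_indep + m]
            x += L * math.cos(th)
            yy += L * math.sin(th)
            th = th + z[m]
            poses_block.append((x, yy, th))
        # snap terminal to the fixed target frame
        poses_block[-1] = target
        return qblock, poses_block, s, anchor_pose, target

    def step(self, i, rng):
        """One Metropolis-Hastings block move; returns True if accepted."""
        b = self.block_size
        n_indep = b - 3
        self.n_proposed += 1
        prop = self.propose_block(i, rng)
        u = rng.random()
        if prop is None:
            self.n_ik_failures += 1
            return False
        qnew, poses_new, s_fwd, anchor_pose, target = prop
        logq_fwd = self._log_q(i, anchor_pose, qnew, poses_new, s_fwd, target)
        if logq_fwd is None:
            return False
        # reverse move evaluated at the current state
        q_cur = self.q[i : i + b]
        poses_cur = self.poses[i : i + b]
        prev = anchor_pose if n_indep == 0 else poses_cur[n_indep - 1]
        s_rev = len(
            solve_planar_3r(
                prev,
                self.lengths[i + n_indep],
                self.lengths[i + n_indep + 1],
                self.lengths[i + n_indep + 2],
                target,
            )
        )
        if s_rev == 0:
            s_rev = 1  # current state closes; numerical tangency guard
        logq_rev = self._log_q(i, anchor_pose, q_cur, poses_cur, s_rev, target)
        if logq_rev is None:
            return False
        dlogphi = self._block_logphi(i, qnew, poses_new) - self._block_logphi(
            i, q_cur, poses_cur
        )
        log_alpha = dlogphi + logq_rev - logq_fwd
        if log_alpha >= 0.0 or u < math.exp(log_alpha):
            self.q[i : i + b] = qnew
            self.poses[i : i + b] = poses_new
            self.n_accepted += 1
            return True
        return False

    def free_tail_step(self, rng, n_tail=3):
        """Standard M-H update of the last ``n_tail`` angles of a free-endpoint
        chain: symmetric Gaussian perturbation, so alpha = min(1, Phi ratio).
        Interior blocks keep their terminal frame fixed (Gibbs conditional);
        this move is what lets the free terminus explore."""
        if self.end is not None:
            raise ValueError("free-tail moves require a free endpoint")
        i0 = self.n - n_tail
        self.n_proposed += 1
        q_new = [
            wrap_angle(self.q[i0 + m] + rng.gauss(0.0, self.tail_sigma))
            for m in range(n_tail)
        ]
        u = rng.random()
        prev = self.base if i0 == 0 else self.poses[i0 - 1]
        poses_new = []
        x, y, th = prev
        for m in range(n_tail):
            L = self.lengths[i0 + m]
            x += L * math.cos(th)
            y += L * math.sin(th)
            th = th + q_new[m]
            poses_new.append((x, y, th))
        lp_new = lp_old = 0.0
        for m in range(n_tail):
            f = self.angle_logp[i0 + m]
            if f is not None:
                lp_new += f(q_new[m])
                lp_old += f(self.q[i0 + m])
            g = self.frame_logp[i0 + m]
            if g is not None:
                lp_new += g(poses_new[m][0], poses_new[m][1])
                lp_old += g(self.poses[i0 + m][0], self.poses[i0 + m][1])
        if lp_new - lp_old >= 0.0 or u < math.exp(lp_new - lp_old):
            self.q[i0:] = q_new
            self.poses[i0:] = poses_new
            self.n_accepted += 1
            return True
        return False

    def sweep(self, rng):
        """One pass of overlapping blocks (stride one angle); free-endpoint
        chains additionally get a terminal tail move."""
        order = self.block_starts
        if self.sweep_order == "backward":
            order = order[::-1]
        elif self.sweep_order == "random":
            order = order[:]
            rng.shuffle(order)
        for i in order:
            self.step(i, rng)
        if self.end is None:
            self.free_tail_step(rng)

    def run(self, n_sweeps, rng=None, seed=0, record_every=1):
        """Run sweeps, recording the angle vector every ``record_every``
        sweeps.  Returns the list of recorded angle tuples."""
        if rng is None:
            rng = random.Random(seed)
        out = []
        for k in range(n_sweeps):
            self.sweep(rng)
            if (k + 1) % record_every == 0:
                out.append(tuple(self.q))
        return out

    @property
    def acceptance_rate(self):
        return self.n_accepted / max(1, self.n_proposed)


class WholeChainMH:
    """Baseline: whole-chain Metropolis-Hastings on a free planar chain.

    Every angle is perturbed at once by a Gaussian of standard deviation
    ``sigma`` (default 1 degree); the proposal is symmetric so alpha is the
    plain score ratio.  Acceptance collapses as the chain grows because a
    single bad angle rejects the entire move -- the behaviour the blocked
    sampler avoids.
    """

    def __init__(self, lengths, base, init_angles, angle_logp=None, frame_logp=None,
                 sigma=math.radians(1.0)):
        self.lengths = list(lengths)
        self.base = tuple(base)
        self.n = len(self.lengths)
        self.q = [wrap_angle(a) for a in init_angles]
        self.poses = fk_poses(self.lengths, self.base, self.q)
        self.angle_logp = angle_logp or [None] * self.n
        self.frame_logp = frame_logp or [None] * self.n
        self.sigma = sigma
        self.n_proposed = 0
        self.n_accepted = 0

    def _logphi(self, q, poses):
        total = 0.0
        for j in range(self.n):
            f = self.angle_logp[j]
            if f is not None:
                total += f(q[j])
            g = self.frame_logp[j]
            if g is not None:
                total += g(poses[j][0], poses[j][1])
        return total

    def step(self, rng):
        self.n_proposed += 1
        q_new = [wrap_angle(a + rng.gauss(0.0, self.sigma)) for a in self.q]
        poses_new = fk_poses(self.lengths, self.base, q_new)
        u = rng.random()
        d = self._logphi(q_new, poses_new) - self._logphi(self.q, self.poses)
        if d >= 0.0 or u < math.exp(d):
            self.q = q_new
            self.poses = poses_new
            self.n_accepted += 1
            return True
        return False

    def run(self, n_steps, rng=None, seed=0, record_every=1):
        if rng is None:
            rng = random.Random(seed)
        out = []
        for k in range(n_steps):
            self.step(rng)
            if (k + 1) % record_every == 0:
                out.append(tuple(self.q))
        return out

    @property
    def acceptance_rate(self):
        return self.n_accepted / max(1, self.n_proposed)


def closed_arc_angles(n, distance, lengths=None):
    """Angles of a circular-arc conformation of an n-link unit chain whose
    endpoint lies at the given distance from the base (chord of the arc).
    Used to construct valid initial closed conformations.  Raises ValueError
    when the distance exceeds the total chain length."""
    if lengths is None:
        total = float(n)
    else:
        total = float(sum(lengths))
    if distance > total:
        raise ValueError(
            f"anchor distance {distance} exceeds total chain length {total}"
        )
    if distance == total:
        return [0.0] * n
    # endpoint distance of a unit chain with constant turning tau:
    # |sin(n tau / 2) / sin(tau / 2)|
    lo, hi = 1e-9, 2.0 * math.pi / n * 1.999
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        d = abs(math.sin(n * mid / 2.0) / math.sin(mid / 2.0))
        if d > distance:
            lo = mid
        else:
            hi = mid
    tau = 0.5 * (lo + hi)
    return [tau] * n
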