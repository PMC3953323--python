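"""Synthetic test systems: planar chains, ideal-geometry mini-proteins and
toy prior tables.

Everything here is generated programmatically and deterministically from a
seed, so the full test suite runs with no downloads.  The planar fixtures
emulate anchored 20-link chains with uniform or smooth nonuniform priors;
the mini-protein is an ideal-geometry polyalanine scaffold with a helix or
coil loop and synthetic B-factors; the toy Ramachandran table is a two-basin
(phi, psi) mixture and the toy rotamer table a small Gaussian mixture over
chi angles.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .backbone import BackboneGeometry, BackboneModel, LoopSpec, backbone_to_atoms, build_backbone_chain
from .factors import Factor, FactorGraph, RamachandranGrid
from .kinematics import Chain, ExpandedState, forward_kinematics, planar_chain
from .planar import closed_arc_angles, fk_poses
from .rotamers import ChiMixture, RotamerLibrary

__all__ = [
    "spatial_seven_loop",
    "PlanarFixture",
    "make_planar_chain",
    "make_mini_protein",
    "make_toy_priors",
    "random_spatial_chain",
]


@dataclass
class PlanarFixture:
    """A planar chain with priors, in both representations: the generic
    `Chain`/`ExpandedState`/`FactorGraph` triple and the plain-float fields
    consumed by the fast planar sampler."""

    chain: Chain
    state: ExpandedState
    factor_graph: FactorGraph
    lengths: list
    base: tuple
    end: tuple | None
    init_angles: list
    angle_logp: list
    frame_logp: list


def make_planar_chain(
    n_links: int = 20,
    anchor_distance: float = 10.0,
    prior: str = "uniform",
    closed: bool = True,
    seed: int = 0,
    vonmises_kappa: float = 1.0,
    position_sigma: float = 0.5,
) -> PlanarFixture:
    """Planar chain fixture with unit links.

    ``prior`` is one of:
      * ``uniform`` -- no factors;
      * ``vonmises`` -- smooth nonuniform per-angle factor exp(kappa cos q)
        (favors straight joints);
      * ``position_gaussian`` -- per-frame Gaussian position factors centred
        on the initial conformation with standard deviation
        ``position_sigma``.

    Closed chains are initialized on a circular arc whose chord equals the
    anchor distance; an anchor distance beyond the total chain length raises
    a ValueError.
    """
    rng = np.random.default_rng(seed)
    lengths = [1.0] * n_links
    base = (0.0, 0.0, 0.0)
    if closed:
        q0 = closed_arc_angles(n_links, anchor_distance)
    else:
        q0 = list(rng.uniform(-0.3, 0.3, n_links))
    poses0 = fk_poses(lengths, base, q0)
    end = poses0[-1] if closed else None

    angle_logp: list = [None] * n_links
    frame_logp: list = [None] * n_links
    if prior == "vonmises":
        k = float(vonmises_kappa)
        angle_logp = [(lambda q, k=k: k * math.cos(q)) for _ in range(n_links)]
    elif prior == "position_gaussian":
        inv2s2 = 1.0 / (2.0 * position_sigma**2)
        frame_logp = [
            (lambda x, y, mx=p[0], my=p[1], c=inv2s2: -((x - mx) ** 2 + (y - my) ** 2) * c)
            for p in poses0
        ]
    elif prior != "uniform":
        raise ValueError(f"unknown prior kind {prior!r}")

    chain = planar_chain(lengths, base_pose=base, end_pose=end)
    frames = forward_kinematics(chain, np.asarray(q0))
    state = ExpandedState(angles=np.asarray(q0, dtype=float), frames=frames)

    graph = FactorGraph()
    for j, f in enumerate(angle_logp):
        if f is not None:
            graph.add(Factor(frozenset({("q", j)}),
                             lambda a, j=j, f=f: f(a[("q", j)]), name=f"angle_{j}"))
    for j, g in enumerate(frame_logp):
        if g is not None:
            graph.add(Factor(frozenset({("T", j)}),
                             lambda a, j=j, g=g: g(*a[("T", j)][:2]), name=f"frame_{j}"))
    return PlanarFixture(
        chain=chain, state=state, factor_graph=graph, lengths=lengths,
        base=base, end=end, init_angles=list(q0),
        angle_logp=angle_logp, frame_logp=frame_logp,
    )


# ---------------------------------------------------------------------------
# Mini proteins
# ---------------------------------------------------------------------------

HELIX_PHI_PSI = (math.radians(-57.0), math.radians(-47.0))


def make_mini_protein(
    path,
    n_residues: int = 12,
    loop_start: int = 4,
    loop_end: int = 9,
    kind: str = "helix",
    seed: int = 0,
    arg_positions: tuple = (),
    geometry: BackboneGeometry | None = None,
) -> tuple[BackboneModel, ExpandedState, LoopSpec]:
    """Write an ideal-geometry mini-protein PDB and return its model, state
    and loop specification.

    ``kind='helix'`` builds every residue at (phi, psi) = (-57, -47)
    degrees; ``kind='coil'`` draws dihedrals from a broad beta-basin.
    Synthetic B-factors in [10, 25) A^2 are attached per atom.  Residues are
    ALA except the (1-based) indices in ``arg_positions``, which become ARG
    for side-chain tests.
    """
    if not (1 < loop_start <= loop_end < n_residues):
        raise ValueError("loop must leave at least one anchor residue on each side")
    rng = np.random.default_rng(seed)
    names = ["ALA"] * n_residues
    for i in arg_positions:
        names[i - 1] = "ARG"
    model = build_backbone_chain(n_residues, geometry=geometry, residue_names=names)
    if kind == "helix":
        angles = np.tile(HELIX_PHI_PSI, n_residues)
    elif kind == "coil":
        phis = rng.normal(math.radians(-120.0), math.radians(25.0), n_residues)
        psis = rng.normal(math.radians(130.0), math.radians(25.0), n_residues)
        angles = np.empty(2 * n_residues)
        angles[0::2] = phis
        angles[1::2] = psis
    else:
        raise ValueError(f"unknown kind {kind!r}")
    frames = forward_kinematics(model.chain, angles)
    state = ExpandedState(angles=angles, frames=frames)
    atoms = backbone_to_atoms(model, frames)
    bfac = rng.uniform(10.0, 25.0, size=atoms.shape[:2])
    _write_pdb(path, model, atoms, bfac)
    return model, state, LoopSpec(chain_id="A", start=loop_start, end=loop_end)


def _write_pdb(path, model: BackboneModel, atoms: np.ndarray, bfactors: np.ndarray) -> None:
    st = gemmi.Structure()
    st.name = "loopmc-fixture"
    mdl = gemmi.Model(1)
    ch = gemmi.Chain("A")
    atom_spec = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))
    for i in range(model.n_residues):
        res = gemmi.Residue()
        res.name = model.residue_names[i]
        res.seqid = gemmi.SeqId(i + 1, " ")
        for j, (aname, elem) in enumerate(atom_spec[: atoms.shape[1]]):
            at = gemmi.Atom()
            at.name = aname
            at.element = gemmi.Element(elem)
            at.pos = gemmi.Position(*atoms[i, j])
            at.occ = 1.0
            at.b_iso = float(bfactors[i, j])
            res.add_atom(at)
        ch.add_residue(res)
    mdl.add_chain(ch)
    st.add_model(mdl)
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())


# ---------------------------------------------------------------------------
# Toy priors
# ---------------------------------------------------------------------------


def make_toy_priors(
    seed: int = 0, bin_width_deg: float = 10.0
) -> tuple[RamachandranGrid, RotamerLibrary]:
    """Two-basin (phi, psi) probability grid (alpha and beta basins) and a
    small chi Gaussian-mixture rotamer table for an arginine-like side chain.

    The grid integrates to 1 (sum times cell area); rotamer weights sum to 1
    per bin.
    """
    n = int(round(360.0 / bin_width_deg))
    centers = -180.0 + (np.arange(n) + 0.5) * bin_width_deg
    phi, psi = np.meshgrid(centers, centers, indexing="ij")

    def basin(mu_phi, mu_psi, s_phi, s_psi):
        dphi = _wrap_deg(phi - mu_phi)
        dpsi = _wrap_deg(psi - mu_psi)
        return np.exp(-0.5 * ((dphi / s_phi) ** 2 + (dpsi / s_psi) ** 2))

    values = 0.55 * basin(-60.0, -45.0, 25.0, 20.0) + 0.45 * basin(-110.0, 130.0, 30.0, 25.0)
    values /= values.sum() * bin_width_deg**2
    grid = RamachandranGrid(values, bin_width_deg)

    lib = RotamerLibrary(bin_width_deg=360.0)  # one backbone bin: toy table
    mix = ChiMixture(
        weights=np.array([0.5, 0.3, 0.2]),
        means=np.radians([[-60.0, 180.0, 65.0, 85.0],
                          [60.0, -170.0, -65.0, -85.0],
                          [180.0, 65.0, 180.0, -175.0]]),
        sigmas=np.radians(np.full((3, 4), 9.0)),
    )
    lib.add("ARG", 0, 0, mix)
    return grid, lib


def _wrap_deg(d: np.ndarray) -> np.ndarray:
    return (d + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# Random spatial chains
# ---------------------------------------------------------------------------


def spatial_seven_loop(seed: int = 4) -> tuple[Chain, ExpandedState]:
    """A 7-joint spatial chain with fixed end frames, closed at a generic
    conformation: the canonical fixture for one-dimensional-manifold tests.

    The geometry (seed 4) is chosen so that the dependent 6-angle closure
    problem has a solution count that varies (2 to 8) along the manifold and
    every independent-angle value is reachable -- the conditions under which
    the 1/s factor in the proposal density actually matters.
    """
    rng = np.random.default_rng(seed)
    free = random_spatial_chain(7, rng)
    q0 = rng.uniform(-math.pi, math.pi, 7)
    frames = forward_kinematics(free, q0)
    chain = Chain(
        axes=free.axes,
        rel_transforms=free.rel_transforms,
        base_frame=free.base_frame,
        end_frame_constraint=frames[-1].copy(),
        topology="linear",
    )
    return chain, ExpandedState(angles=q0, frames=frames)


def random_spatial_chain(
    n_joints: int,
    rng: np.random.Generator | int = 0,
    translation_scale: float = 1.5,
) -> Chain:
    """Generic random 3D revolute chain: random unit axes, random rigid
    relative transforms with translations up to ``translation_scale``."""
    from .rigid import make_transform, rotation_about_axis

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    axes = rng.normal(size=(n_joints, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    rel = np.empty((n_joints, 4, 4))
    for j in range(n_joints):
        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        rel[j] = make_transform(
            R=rotation_about_axis(ax, rng.uniform(-math.pi, math.pi)),
            t=rng.uniform(-translation_scale, translation_scale, 3),
        )
    return Chain(axes=axes, rel_transforms=rel, topology="free")
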