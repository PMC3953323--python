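"""Protein backbone kinematics and PDB I/O.

A loop of L residues is modelled as a revolute chain of N = 2L joints, the
backbone dihedrals phi_1, psi_1, ..., phi_L, psi_L.  Bond lengths, bond
angles and the omega dihedral are held at ideal values (config-overridable);
the relative transforms between consecutive dihedral frames are calibrated
numerically from an ideal-geometry fragment so that the joint angle q equals
the IUPAC dihedral exactly.  Frame conventions:

  * the phi_i frame sits at CA_i with z along the N_i -> CA_i bond;
  * the psi_i frame sits at C_i with z along the CA_i -> C_i bond;

each frame origin lies on its joint axis, so backbone atoms are fixed
offsets in these frames and there is a one-to-one correspondence between
frames and backbone atom positions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .kinematics import Chain, ExpandedState, forward_kinematics, measure_dihedral
from .rigid import (
    apply_transform,
    frame_from_zx,
    inverse_transform,
    make_transform,
    rotation_about_axis,
)

__all__ = [
    "BackboneGeometry",
    "LoopSpec",
    "BackboneModel",
    "ProteinLoopSystem",
    "place_atom",
    "build_backbone_chain",
    "backbone_to_atoms",
    "load_state_from_pdb",
    "write_ensemble_pdb",
    "SIDECHAIN_TEMPLATES",
]


def place_atom(a, b, c, length: float, angle_deg: float, dihedral_rad: float) -> np.ndarray:
    """Place atom d with |c-d| = length, angle(b, c, d) = angle_deg and
    dihedral(a, b, c, d) = dihedral_rad (standard internal-coordinate chain
    extension)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    d_local = np.array(
        [
            -length * math.cos(ang),
            length * math.sin(ang) * math.cos(dihedral_rad),
            length * math.sin(ang) * math.sin(dihedral_rad),
        ]
    )
    M = np.column_stack([bc, m, n])
    return c + M @ d_local


@dataclass(frozen=True)
class BackboneGeometry:
    """Ideal backbone covalent geometry (lengths in Angstrom, angles in
    degrees); omega is fixed."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ca_cb: float = 1.521
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    ang_n_ca_cb: float = 110.4
    omega_deg: float = 180.0

    def __post_init__(self) -> None:
        for name in ("n_ca", "ca_c", "c_n", "c_o", "ca_cb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"bond length {name} must be positive")
        for name in ("ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca", "ang_ca_c_o"):
            a = getattr(self, name)
            if not 0.0 < a < 180.0:
                raise ValueError(f"bond angle {name} must lie in (0, 180) degrees")


_TEMPLATE_CACHE: dict[BackboneGeometry, dict] = {}


def _calibrate(geo: BackboneGeometry) -> dict:
    """Relative transforms and in-frame atom offsets from an ideal-geometry
    dipeptide fragment built at phi = psi = 0, omega at its fixed value."""
    if geo in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[geo]
    omega = math.radians(geo.omega_deg)
    C0 = np.zeros(3)
    N1 = np.array([geo.c_n, 0.0, 0.0])
    th = math.pi - math.radians(geo.ang_c_n_ca)
    CA1 = N1 + geo.n_ca * np.array([math.cos(th), math.sin(th), 0.0])
    C1 = place_atom(C0, N1, CA1, geo.ca_c, geo.ang_n_ca_c, 0.0)
    N2 = place_atom(N1, CA1, C1, geo.c_n, geo.ang_ca_c_n, 0.0)
    O1 = place_atom(N1, CA1, C1, geo.c_o, geo.ang_ca_c_o, math.pi)
    CB1 = place_atom(C1, N1, CA1, geo.ca_cb, geo.ang_n_ca_cb, math.radians(-122.6))
    CA2 = place_atom(CA1, C1, N2, geo.n_ca, geo.ang_c_n_ca, omega)
    C2 = place_atom(C1, N2, CA2, geo.ca_c, geo.ang_n_ca_c, 0.0)
    F_phi1 = frame_from_zx(CA1, CA1 - N1, C0)
    F_psi1 = frame_from_zx(C1, C1 - CA1, N1)
    F_phi2 = frame_from_zx(CA2, CA2 - N2, C1)
    inv_phi1 = inverse_transform(F_phi1)
    inv_psi1 = inverse_transform(F_psi1)
    tpl = {
        "rel_intra": inv_phi1 @ F_psi1,  # phi frame -> psi frame (same residue)
        "rel_inter": inv_psi1 @ F_phi2,  # psi frame -> next phi frame (omega folded in)
        "o_N": inv_phi1 @ np.append(N1, 1.0),
        "o_CB": inv_phi1 @ np.append(CB1, 1.0),
        "o_O": inv_psi1 @ np.append(O1, 1.0),
        "o_N_next": inv_psi1 @ np.append(N2, 1.0),
        "o_CA_next": inv_psi1 @ np.append(CA2, 1.0),
        "base": F_phi1,
    }
    _TEMPLATE_CACHE[geo] = tpl
    return tpl


@dataclass(frozen=True)
class LoopSpec:
    """Loop selection: chain ID and inclusive author-numbered residue range."""

    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("loop end precedes loop start")

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1


@dataclass
class BackboneModel:
    """Kinematic model of an L-residue backbone loop (chain of 2L dihedrals)."""

    chain: Chain
    geometry: BackboneGeometry
    n_residues: int
    residue_names: list = field(default_factory=list)

    @property
    def templates(self) -> dict:
        return _calibrate(self.geometry)

    def atoms_from_frames(self, frames: np.ndarray, include_o: bool = True) -> np.ndarray:
        """Backbone atom coordinates from the dihedral frames.

        Returns (L, k, 3) with atom order (N, CA, C[, O]) per residue;
        consecutive bond lengths equal the configured ideal values by
        construction.
        """
        return backbone_to_atoms(self, frames, include_o=include_o)

    def dihedrals_from_atoms(self, atoms: np.ndarray) -> np.ndarray:
        """(phi_i, psi_i) measured from (L, >=3, 3) backbone coordinates;
        terminal phi_1 needs the base frame and terminal psi_L the closure
        frame, so they are measured against the model's anchors."""
        L = self.n_residues
        tpl = self.templates
        out = np.empty(2 * L)
        # phi_1 reference: the atom before N_1 is the anchor carbonyl carbon,
        # recoverable from the base frame of the chain
        C_prev = _anchor_prev_c(self)
        for i in range(L):
            N, CA, C = atoms[i, 0], atoms[i, 1], atoms[i, 2]
            a_prev = C_prev if i == 0 else atoms[i - 1, 2]
            out[2 * i] = measure_dihedral(a_prev, N, CA, C)
            if i + 1 < L:
                out[2 * i + 1] = measure_dihedral(N, CA, C, atoms[i + 1, 0])
            else:
                if self.chain.end_frame_constraint is not None:
                    n_next = apply_transform(
                        np.asarray(self.chain.end_frame_constraint), tpl["o_N_next"][:3]
                    )
                    out[2 * i + 1] = measure_dihedral(N, CA, C, n_next)
                else:
                    out[2 * i + 1] = np.nan
        return out


def _anchor_prev_c(model: BackboneModel) -> np.ndarray:
    """Position of the anchor carbonyl carbon preceding the loop, implied by
    the base frame (x axis points toward its projection by construction)."""
    tpl = model.templates
    base_can = tpl["base"]
    C0_local = inverse_transform(base_can) @ np.array([0.0, 0.0, 0.0, 1.0])
    return (model.chain.base_frame @ C0_local)[:3]


def build_backbone_chain(
    n_residues: int,
    geometry: BackboneGeometry | None = None,
    base_frame: np.ndarray | None = None,
    residue_names: list | None = None,
) -> BackboneModel:
    """Ideal-geometry backbone chain of 2L dihedral joints, free endpoint."""
    geo = geometry or BackboneGeometry()
    tpl = _calibrate(geo)
    N = 2 * n_residues
    axes = np.tile(np.array([0.0, 0.0, 1.0]), (N, 1))
    rel = np.empty((N, 4, 4))
    rel[0] = np.eye(4)
    for j in range(1, N):
        rel[j] = tpl["rel_intra"] if j % 2 == 1 else tpl["rel_inter"]
    base = tpl["base"] if base_frame is None else np.asarray(base_frame, dtype=float)
    chain = Chain(axes=axes, rel_transforms=rel, base_frame=base, topology="free")
    names = residue_names or ["ALA"] * n_residues
    return BackboneModel(chain=chain, geometry=geo, n_residues=n_residues, residue_names=names)


def backbone_to_atoms(model: BackboneModel, frames: np.ndarray, include_o: bool = True) -> np.ndarray:
    """Per-residue backbone coordinates (N, CA, C[, O]) from dihedral frames."""
    L = model.n_residues
    tpl = model.templates
    k = 4 if include_o else 3
    out = np.empty((L, k, 3))
    for i in range(L):
        F_phi = frames[2 * i]
        F_psi = frames[2 * i + 1]
        out[i, 0] = (F_phi @ tpl["o_N"])[:3]
        out[i, 1] = F_phi[:3, 3]
        out[i, 2] = F_psi[:3, 3]
        if include_o:
            out[i, 3] = (F_psi @ tpl["o_O"])[:3]
    return out


# ---------------------------------------------------------------------------
# Side chains
# ---------------------------------------------------------------------------

#: generic side-chain templates: (atom name, element, bond length, bond angle)
#: per chi-extension atom beyond CB; chi_k is the dihedral placing atom k+1.
SIDECHAIN_TEMPLATES = {
    "ALA": [],
    "ARG": [
        ("CG", "C", 1.52, 114.0),
        ("CD", "C", 1.52, 111.0),
        ("NE", "N", 1.46, 112.0),
        ("CZ", "C", 1.33, 124.0),
    ],
}


def sidechain_atoms(
    model: BackboneModel, frames: np.ndarray, residue_index: int, chis: np.ndarray
) -> tuple[list, np.ndarray]:
    """Side-chain atom names/elements and coordinates for one residue given
    its chi angles; CB is placed from the backbone, subsequent atoms by chain
    extension with the template geometry."""
    tpl = model.templates
    name = model.residue_names[residue_index]
    template = SIDECHAIN_TEMPLATES.get(name, [])
    if len(chis) != len(template):
        raise ValueError(f"{name} expects {len(template)} chi angles, got {len(chis)}")
    F_phi = frames[2 * residue_index]
    atoms = backbone_to_atoms(model, frames, include_o=False)
    N, CA = atoms[residue_index, 0], atoms[residue_index, 1]
    CB = (F_phi @ tpl["o_CB"])[:3]
    names = [("CB", "C")]
    coords = [CB]
    prev3 = (N, CA, CB)
    for (aname, elem, length, angle), chi in zip(template, chis):
        new = place_atom(*prev3, length, angle, chi)
        names.append((aname, elem))
        coords.append(new)
        prev3 = (prev3[1], prev3[2], new)
    return names, np.asarray(coords).reshape(len(coords), 3)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


@dataclass
class ProteinLoopSystem:
    """Everything the sampler needs for one PDB loop: the kinematic model,
    anchors, native reference positions, B-factors and the fixed environment."""

    model: BackboneModel
    spec: LoopSpec
    mu_positions: np.ndarray  # (L, k, 3) native reference for the B-factor prior
    bfactors: np.ndarray  # (L, k) per selected atom
    env_positions: np.ndarray  # fixed surrounding atoms
    env_elements: list
    env_meta: list = field(default_factory=list)  # (residue number, atom name)
    atom_selection: tuple = ("N", "CA", "C", "O")

    @property
    def chain(self) -> Chain:
        return self.model.chain


def _pick_conformer(residue: "gemmi.Residue") -> dict:
    """Highest-occupancy atom per name (altLoc resolution)."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        cur = best.get(atom.name)
        if cur is None or atom.occ > cur.occ:
            best[atom.name] = atom
    return best


def _get_atom(best: dict, name: str, label: str) -> np.ndarray:
    if name not in best:
        raise ValueError(f"missing backbone atom {name} in residue {label}")
    p = best[name].pos
    return np.array([p.x, p.y, p.z])


def load_state_from_pdb(
    pdb_path,
    loop_spec: LoopSpec,
    geometry: BackboneGeometry | None = None,
    atom_selection: tuple = ("N", "CA", "C", "O"),
    reclose: bool = True,
) -> tuple[ProteinLoopSystem, ExpandedState]:
    """Build the loop kinematic chain and its native expanded state from a
    PDB file.

    The frames flanking the loop act as closure constraints: the base frame
    is derived from the anchor residue preceding the loop and the end-frame
    constraint from the residue following it.  Native dihedrals initialize
    the state; with ``reclose`` the last six angles are adjusted by inverse
    kinematics so the idealized-geometry chain closes exactly onto the native
    anchor (deviations of real covalent geometry from ideal values otherwise
    leave a small terminal gap).
    """
    geo = geometry or BackboneGeometry()
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    chain = None
    for model_ in st:
        for ch in model_:
            if ch.name == loop_spec.chain_id:
                chain = ch
                break
        break
    if chain is None:
        raise ValueError(f"chain {loop_spec.chain_id!r} not found in {pdb_path}")
    by_seqid: dict[int, gemmi.Residue] = {}
    for res in chain:
        if res.seqid.icode not in (" ", "", "\x00"):
            raise ValueError(
                f"insertion code {res.seqid.icode!r} at residue {res.seqid.num}: "
                "insertion codes are not supported; renumber the chain first"
            )
        by_seqid[res.seqid.num] = res
    needed = range(loop_spec.start - 1, loop_spec.end + 2)
    for num in needed:
        if num not in by_seqid:
            raise ValueError(
                f"residue {num} (chain {loop_spec.chain_id}) required for the loop "
                f"[{loop_spec.start}, {loop_spec.end}] is missing"
            )
    L = loop_spec.n_residues
    res_prev = _pick_conformer(by_seqid[loop_spec.start - 1])
    res_next = _pick_conformer(by_seqid[loop_spec.end + 1])
    loop_res = [_pick_conformer(by_seqid[loop_spec.start + i]) for i in range(L)]
    names = [by_seqid[loop_spec.start + i].name for i in range(L)]

    C_prev = _get_atom(res_prev, "C", f"{loop_spec.start - 1}")
    coords = np.empty((L, 3, 3))
    for i, res in enumerate(loop_res):
        lbl = f"{loop_spec.start + i}"
        coords[i, 0] = _get_atom(res, "N", lbl)
        coords[i, 1] = _get_atom(res, "CA", lbl)
        coords[i, 2] = _get_atom(res, "C", lbl)
    N_next = _get_atom(res_next, "N", f"{loop_spec.end + 1}")

    model = build_backbone_chain(L, geometry=geo, residue_names=names)
    tpl = model.templates
    base = frame_from_zx(coords[0, 1], coords[0, 1] - coords[0, 0], C_prev)
    # end constraint: frame at the last carbonyl carbon whose fixed N-offset
    # reproduces the native position of the next residue's nitrogen
    F_t = frame_from_zx(coords[L - 1, 2], coords[L - 1, 2] - coords[L - 1, 1], N_next)
    local = inverse_transform(F_t) @ np.append(N_next, 1.0)
    a_have = math.atan2(local[1], local[0])
    o_nn = tpl["o_N_next"]
    a_want = math.atan2(o_nn[1], o_nn[0])
    F_target = F_t @ make_transform(R=rotation_about_axis([0, 0, 1], a_have - a_want))

    chain_k = Chain(
        axes=model.chain.axes,
        rel_transforms=model.chain.rel_transforms,
        base_frame=base,
        end_frame_constraint=F_target,
        topology="linear",
    )
    model = BackboneModel(chain=chain_k, geometry=geo, n_residues=L, residue_names=names)

    # native dihedrals
    angles = np.empty(2 * L)
    for i in range(L):
        a_prev = C_prev if i == 0 else coords[i - 1, 2]
        angles[2 * i] = measure_dihedral(a_prev, coords[i, 0], coords[i, 1], coords[i, 2])
        n_next_i = coords[i + 1, 0] if i + 1 < L else N_next
        angles[2 * i + 1] = measure_dihedral(coords[i, 0], coords[i, 1], coords[i, 2], n_next_i)

    frames = forward_kinematics(chain_k, angles)
    if reclose and L >= 3:
        from .closure import solve_spatial_6

        A = frames[2 * L - 7]
        dep = chain_k.subchain(2 * L - 6, 2 * L, base_frame=A)
        sols = solve_spatial_6(dep, A, F_target, extra_seeds=angles[None, 2 * L - 6 :])
        if sols.count > 0:
            d = np.abs(
                np.arctan2(
                    np.sin(sols.solutions - angles[None, 2 * L - 6 :]),
                    np.cos(sols.solutions - angles[None, 2 * L - 6 :]),
                )
            ).max(axis=1)
            angles[2 * L - 6 :] = sols.solutions[int(np.argmin(d))]
            frames = forward_kinematics(chain_k, angles)
            frames[-1] = F_target
    state = ExpandedState(angles=angles, frames=frames)
    state.atom_positions = backbone_to_atoms(model, frames).reshape(-1, 3)

    # B-factor prior references and environment
    k = len(atom_selection)
    mu = np.zeros((L, k, 3))
    bf = np.full((L, k), 20.0)
    for i, res in enumerate(loop_res):
        for j, aname in enumerate(atom_selection):
            if aname in res:
                p = res[aname].pos
                mu[i, j] = (p.x, p.y, p.z)
                bf[i, j] = max(res[aname].b_iso, 1e-3)
            elif aname == "O":
                mu[i, j] = coords[i, 2]  # fall back to the carbonyl carbon
    env_pos = []
    env_elem = []
    env_meta = []
    for num, res in by_seqid.items():
        if loop_spec.start <= num <= loop_spec.end:
            continue
        for aname, atom in _pick_conformer(res).items():
            if aname not in atom_selection:
                continue
            env_pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
            env_elem.append(atom.element.name if atom.element else "C")
            env_meta.append((num, aname))
    system = ProteinLoopSystem(
        model=model,
        spec=loop_spec,
        mu_positions=mu,
        bfactors=bf,
        env_positions=np.asarray(env_pos, dtype=float).reshape(-1, 3),
        env_elements=env_elem,
        env_meta=env_meta,
        atom_selection=tuple(atom_selection),
    )
    return system, state


def write_ensemble_pdb(
    path,
    model: BackboneModel,
    states: list,
    loop_spec: LoopSpec | None = None,
    bfactors: np.ndarray | None = None,
) -> None:
    """Write conformations as a multi-MODEL PDB of the loop backbone."""
    st = gemmi.Structure()
    st.name = "loopmc-ensemble"
    start = loop_spec.start if loop_spec is not None else 1
    chain_id = loop_spec.chain_id if loop_spec is not None else "A"
    for m_idx, state in enumerate(states, start=1):
        mdl = gemmi.Model(m_idx)
        ch = gemmi.Chain(chain_id)
        atoms = backbone_to_atoms(model, state.frames)
        for i in range(model.n_residues):
            res = gemmi.Residue()
            res.name = model.residue_names[i]
            res.seqid = gemmi.SeqId(start + i, " ")
            for j, (aname, elem) in enumerate((("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))):
                at = gemmi.Atom()
                at.name = aname
                at.element = gemmi.Element(elem)
                at.pos = gemmi.Position(*atoms[i, j])
                at.occ = 1.0
                at.b_iso = float(bfactors[i, j]) if bfactors is not None else 20.0
                res.add_atom(at)
            ch.add_residue(res)
        mdl.add_chain(ch)
        st.add_model(mdl)
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)
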