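"""Sparse factored scores Phi(x) = prod_i phi_i(S_i).

Each factor is a non-negative local term over a small subset of variables
(angles ("q", j), frames ("T", j) or atom positions ("p", a)).  The global
score is their product; block-restricted evaluation multiplies exactly the
factors whose domain intersects a block, which is all the Metropolis ratio
needs because factors outside the block cancel.  Factors are evaluated in
log space to avoid underflow on long chains; hard constraints (clashes,
zero-probability prior cells) map to -inf.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Hashable, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "FactorGraph",
    "RamachandranGrid",
    "ramachandran_factor",
    "bfactor_factor",
    "log_bfactor_factor",
    "energy_to_score",
    "ClashGrid",
    "clash_factor",
    "block_score",
    "VDW_RADII",
]

#: van der Waals radii (Angstrom) for the backbone/side-chain elements we place
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "X": 1.70}


@dataclass(frozen=True)
class Factor:
    """Non-negative local score over a small variable subset."""

    domain: frozenset
    log_evaluate: Callable[[dict], float]
    name: str = ""

    def evaluate(self, assignment: dict) -> float:
        return math.exp(self.log_evaluate(assignment))


class FactorGraph:
    """A set of factors with an index from variable to the factors citing it."""

    def __init__(self, factors: Iterable[Factor] = ()):
        self.factors: list[Factor] = []
        self.index: dict[Hashable, list[Factor]] = {}
        for f in factors:
            self.add(f)

    def add(self, factor: Factor) -> None:
        self.factors.append(factor)
        for v in factor.domain:
            self.index.setdefault(v, []).append(factor)

    def factors_touching(self, variables: Iterable[Hashable]) -> list[Factor]:
        seen: set[int] = set()
        out: list[Factor] = []
        for v in variables:
            for f in self.index.get(v, ()):
                if id(f) not in seen:
                    seen.add(id(f))
                    out.append(f)
        return out

    def log_score(self, assignment: dict) -> float:
        return sum(f.log_evaluate(assignment) for f in self.factors)

    def log_block_score(self, assignment: dict, block_variables: Iterable[Hashable]) -> float:
        return sum(
            f.log_evaluate(assignment) for f in self.factors_touching(block_variables)
        )


def block_score(graph: FactorGraph, assignment: dict, block_variables) -> float:
    """Product over exactly the factors whose domain intersects the block's
    variables; equals the full score Phi for a whole-chain block."""
    return math.exp(graph.log_block_score(assignment, block_variables))


# ---------------------------------------------------------------------------
# Ramachandran prior
# ---------------------------------------------------------------------------


class RamachandranGrid:
    """Discretized (phi, psi) probability table on [-180, 180)^2 degrees.

    Lookup is piecewise constant per cell (bilinear interpolation behind the
    ``interpolate`` flag).  Values are a probability density per square
    degree; angles passed in radians are wrapped into range.
    """

    def __init__(self, values: np.ndarray, bin_width_deg: float):
        values = np.asarray(values, dtype=float)
        n = int(round(360.0 / bin_width_deg))
        if values.shape != (n, n):
            raise ValueError(f"grid must be {n}x{n} for bin width {bin_width_deg}")
        if np.any(values < 0):
            raise ValueError("grid entries must be non-negative")
        self.values = values
        self.bin_width_deg = float(bin_width_deg)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def _cell(self, angle_rad: float) -> int:
        deg = math.degrees(angle_rad)
        deg = (deg + 180.0) % 360.0  # wrap into [0, 360)
        return min(int(deg / self.bin_width_deg), self.n_bins - 1)

    def lookup(self, phi: float, psi: float, interpolate: bool = False) -> float:
        if not interpolate:
            return float(self.values[self._cell(phi), self._cell(psi)])
        return self._bilinear(phi, psi)

    def _bilinear(self, phi: float, psi: float) -> float:
        w = self.bin_width_deg
        n = self.n_bins
        fi = ((math.degrees(phi) + 180.0) % 360.0) / w - 0.5
        fj = ((math.degrees(psi) + 180.0) % 360.0) / w - 0.5
        i0, j0 = math.floor(fi), math.floor(fj)
        di, dj = fi - i0, fj - j0
        out = 0.0
        for a, wa in ((i0, 1 - di), (i0 + 1, di)):
            for b, wb in ((j0, 1 - dj), (j0 + 1, dj)):
                out += wa * wb * self.values[a % n, b % n]
        return float(out)

    # marginals, for the independent-angle proposal ---------------------
    def marginal(self, which: str) -> np.ndarray:
        if which == "phi":
            m = self.values.sum(axis=1)
        elif which == "psi":
            m = self.values.sum(axis=0)
        else:
            raise ValueError("which must be 'phi' or 'psi'")
        total = m.sum()
        if total <= 0:
            raise ValueError("grid has zero total mass")
        return m / total

    def sample_marginal(self, which: str, rng: np.random.Generator) -> float:
        """Draw one angle (radians) from the phi or psi marginal: pick a bin
        by weight, then uniform within the bin."""
        m = self.marginal(which)
        k = int(rng.choice(m.shape[0], p=m))
        w = self.bin_width_deg
        deg = -180.0 + (k + rng.uniform()) * w
        return math.radians(deg)

    def log_marginal_density(self, which: str, angle_rad: float) -> float:
        """Log density per radian of the marginal at the given angle."""
        m = self.marginal(which)
        p = m[self._cell(angle_rad)]
        if p <= 0:
            return -math.inf
        bin_rad = math.radians(self.bin_width_deg)
        return math.log(p / bin_rad)

    # tab-separated serialization ---------------------------------------
    def to_tsv(self, path) -> None:
        w = self.bin_width_deg
        rows = []
        for i in range(self.n_bins):
            for j in range(self.n_bins):
                rows.append((-180.0 + i * w, -180.0 + j * w, self.values[i, j]))
        df = pd.DataFrame(rows, columns=["phi_low", "psi_low", "value"])
        with open(path, "w") as fh:
            fh.write(f"# bin_width_deg\t{w}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RamachandranGrid":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# bin_width_deg"):
                raise ValueError("missing bin-width header")
            w = float(header.split("\t")[1])
            df = pd.read_csv(fh, sep="\t")
        n = int(round(360.0 / w))
        values = np.zeros((n, n))
        i = ((df["phi_low"].to_numpy() + 180.0) / w).round().astype(int)
        j = ((df["psi_low"].to_numpy() + 180.0) / w).round().astype(int)
        values[i, j] = df["value"].to_numpy()
        return cls(values, w)


def ramachandran_factor(grid: RamachandranGrid, phi: float, psi: float) -> float:
    """Grid value at the cell containing (phi, psi); angles outside range are
    wrapped.  A zero-probability cell returns 0, forcing rejection."""
    return grid.lookup(phi, psi)


# ---------------------------------------------------------------------------
# B-factor positional prior
# ---------------------------------------------------------------------------


def log_bfactor_factor(p, mu, B: float, c: float = 1.0) -> float:
    if B <= 0:
        raise ValueError("B-factor must be positive")
    if c <= 0:
        raise ValueError("scale c must be positive")
    d2 = float(np.sum((np.asarray(p, float) - np.asarray(mu, float)) ** 2))
    return -math.log(c * math.sqrt(2.0 * math.pi * B)) - d2 / (2.0 * B * c * c)


def bfactor_factor(p, mu, B: float, c: float = 1.0) -> float:
    """Gaussian positional prior centred on the reference position mu with
    variance B c^2: (1 / (c sqrt(2 pi B))) exp(-||p - mu||^2 / (2 B c^2)).

    The normalizer is one-dimensional while the squared distance is
    three-dimensional; as a density this is a convention, and the constant
    cancels in every acceptance ratio, so the sampler is unaffected.
    """
    return math.exp(log_bfactor_factor(p, mu, B, c))


def energy_to_score(E: float, T: float) -> float:
    """Gibbs measure: Phi = exp(-E / T)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(-E / T)


# ---------------------------------------------------------------------------
# Steric clashes
# ---------------------------------------------------------------------------


class ClashGrid:
    """Spatial hash for neighbor queries; the neighbor set returned for a
    query sphere is a superset of all atoms within it."""

    def __init__(self, positions: np.ndarray, radii: np.ndarray, cell_size: float | None = None):
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(radii, dtype=float).reshape(-1)
        if self.radii.shape[0] != self.positions.shape[0]:
            raise ValueError("one radius per atom required")
        # cell size: the largest pair radius sum, so one shell of neighboring
        # cells suffices for any contact query
        self.cell_size = float(cell_size) if cell_size else 2.0 * float(np.max(self.radii, initial=1.0))
        self.cells: dict[tuple, list[int]] = {}
        for idx, p in enumerate(self.positions):
            self.cells.setdefault(self._key(p), []).append(idx)

    def _key(self, p) -> tuple:
        return tuple(np.floor(np.asarray(p) / self.cell_size).astype(int))

    def neighbors(self, p, radius: float) -> list[int]:
        reach = int(math.ceil(radius / self.cell_size))
        kx, ky, kz = self._key(p)
        out: list[int] = []
        for dx in range(-reach, reach + 1):
            for dy in range(-reach, reach + 1):
                for dz in range(-reach, reach + 1):
                    out.extend(self.cells.get((kx + dx, ky + dy, kz + dz), ()))
        return out


def clash_factor(
    grid: ClashGrid,
    positions: np.ndarray | None = None,
    pair_exclusions: set | None = None,
    overlap: float = 0.75,
    query_indices: Iterable[int] | None = None,
    query_positions: np.ndarray | None = None,
    query_radii: np.ndarray | None = None,
) -> int:
    """0 if any non-excluded pair overlaps, 1 otherwise.

    Two atoms clash when their distance is below ``overlap`` times the sum of
    their van der Waals radii.  Bonded (1-2) and angle (1-3) pairs are passed
    in ``pair_exclusions`` as frozensets of atom indices.  With no query
    arguments every pair held by the grid is checked (identical to the
    exhaustive all-pairs test); ``query_positions`` checks candidate atoms
    against the grid contents instead.
    """
    exclusions = pair_exclusions or set()
    if query_positions is not None:
        qpos = np.asarray(query_positions, dtype=float).reshape(-1, 3)
        qrad = np.asarray(query_radii, dtype=float).reshape(-1)
        qidx = list(query_indices) if query_indices is not None else [None] * len(qpos)
        for qi, (p, r) in zip(qidx, zip(qpos, qrad)):
            for j in grid.neighbors(p, r + float(np.max(grid.radii))):
                if qi is not None and (j == qi or frozenset((qi, j)) in exclusions):
                    continue
                cutoff = overlap * (r + grid.radii[j])
                if np.sum((p - grid.positions[j]) ** 2) < cutoff * cutoff:
                    return 0
        return 1
    pos = grid.positions if positions is None else np.asarray(positions, float)
    for i in range(pos.shape[0]):
        r_i = grid.radii[i]
        for j in grid.neighbors(pos[i], r_i + float(np.max(grid.radii))):
            if j <= i or frozenset((i, j)) in exclusions:
                continue
            cutoff = overlap * (r_i + grid.radii[j])
            if np.sum((pos[i] - pos[j]) ** 2) < cutoff * cutoff:
                return 0
    return 1
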