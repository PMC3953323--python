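"""Backbone-dependent side-chain rotamer priors.

The (phi, psi) plane of each rotameric residue type is discretized into
square bins; each bin holds a Gaussian mixture over the chi angles.  Tables
are tab-separated with one mixture component per row:

    residue  phi_low  psi_low  weight  chi1_mean ... chi4_mean  chi1_sigma ... chi4_sigma

Angles in the table are degrees; the API works in radians.  Mixture weights
must sum to one within each bin.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ChiMixture", "RotamerLibrary"]


@dataclass
class ChiMixture:
    """Gaussian mixture over an n_chi-dimensional chi vector (radians)."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, n_chi)
    sigmas: np.ndarray  # (K, n_chi)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.means = np.atleast_2d(np.asarray(self.means, float))
        self.sigmas = np.atleast_2d(np.asarray(self.sigmas, float))
        if not math.isclose(float(self.weights.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.sigmas <= 0):
            raise ValueError("mixture sigmas must be positive")

    @property
    def n_chi(self) -> int:
        return self.means.shape[1]

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Pick a component by weight, then draw each chi from its Gaussian,
        wrapped into [-pi, pi)."""
        k = int(rng.choice(self.weights.shape[0], p=self.weights))
        chis = rng.normal(self.means[k], self.sigmas[k])
        return np.arctan2(np.sin(chis), np.cos(chis))

    def log_density(self, chis: np.ndarray) -> float:
        """Mixture log density (unwrapped Gaussians; toy tables keep their
        mass away from the +-pi seam)."""
        chis = np.asarray(chis, float)
        comp = -0.5 * np.sum(((chis[None] - self.means) / self.sigmas) ** 2, axis=1)
        comp -= np.sum(np.log(self.sigmas * math.sqrt(2 * math.pi)), axis=1)
        m = np.max(comp)
        return float(m + np.log(np.sum(self.weights * np.exp(comp - m))))


class RotamerLibrary:
    def __init__(self, bin_width_deg: float = 360.0):
        self.bin_width_deg = float(bin_width_deg)
        self.entries: dict[tuple, ChiMixture] = {}

    def _bin(self, angle_rad: float) -> int:
        deg = (math.degrees(angle_rad) + 180.0) % 360.0
        n = int(round(360.0 / self.bin_width_deg))
        return min(int(deg / self.bin_width_deg), n - 1)

    def add(self, residue: str, phi_bin: int, psi_bin: int, mixture: ChiMixture) -> None:
        self.entries[(residue, phi_bin, psi_bin)] = mixture

    def mixture_for(self, residue: str, phi: float, psi: float) -> ChiMixture:
        key = (residue, self._bin(phi), self._bin(psi))
        if key not in self.entries:
            raise KeyError(f"no rotamer entry for {key}")
        return self.entries[key]

    def has(self, residue: str) -> bool:
        return any(k[0] == residue for k in self.entries)

    # ------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        rows = []
        for (res, ib, jb), mix in sorted(self.entries.items()):
            w = self.bin_width_deg
            for k in range(mix.weights.shape[0]):
                row = {
                    "residue": res,
                    "phi_low": -180.0 + ib * w,
                    "psi_low": -180.0 + jb * w,
                    "weight": mix.weights[k],
                }
                for c in range(4):
                    row[f"chi{c + 1}_mean"] = (
                        math.degrees(mix.means[k, c]) if c < mix.n_chi else np.nan
                    )
                    row[f"chi{c + 1}_sigma"] = (
                        math.degrees(mix.sigmas[k, c]) if c < mix.n_chi else np.nan
                    )
                rows.append(row)
        df = pd.DataFrame(rows)
        with open(path, "w") as fh:
            fh.write(f"# bin_width_deg\t{self.bin_width_deg}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_published_library(cls, path):  # pragma: no cover - converter stub
        """Converter stub for the published backbone-dependent rotamer
        library format.

        The published tables are whitespace-separated with columns::

            residue  phi  psi  count  r1 r2 r3 r4  probability
            chi1_mean chi2_mean chi3_mean chi4_mean
            chi1_sigma chi2_sigma chi3_sigma chi4_sigma

        at a 10-degree (phi, psi) grid.  Mapping to this package's format:
        one mixture component per rotamer row, ``weight`` from
        ``probability`` (renormalized per bin), means/sigmas copied through
        in degrees, and the bin lower edges ``phi_low = phi - 5``,
        ``psi_low = psi - 5``.  The conversion is not bundled because the
        published tables are license-restricted; this stub documents the
        mapping for users who have them.
        """
        raise NotImplementedError(
            "convert the published library per the documented column mapping "
            "and load the result with RotamerLibrary.from_tsv"
        )

    @classmethod
    def from_tsv(cls, path) -> "RotamerLibrary":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# bin_width_deg"):
                raise ValueError("missing bin-width header")
            w = float(header.split("\t")[1])
            df = pd.read_csv(fh, sep="\t")
        lib = cls(bin_width_deg=w)
        for (res, plo, slo), grp in df.groupby(["residue", "phi_low", "psi_low"]):
            ib = int(round((plo + 180.0) / w))
            jb = int(round((slo + 180.0) / w))
            means, sigmas = [], []
            for _, row in grp.iterrows():
                m = [row[f"chi{c}_mean"] for c in range(1, 5)]
                s = [row[f"chi{c}_sigma"] for c in range(1, 5)]
                m = [math.radians(v) for v in m if not pd.isna(v)]
                s = [math.radians(v) for v in s if not pd.isna(v)]
                means.append(m)
                sigmas.append(s)
            lib.add(
                res,
                ib,
                jb,
                ChiMixture(grp["weight"].to_numpy(), np.array(means), np.array(sigmas)),
            )
        return lib
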