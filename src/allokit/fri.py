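"""Flexibility–rigidity index (FRI) profiles.

A matrix-decomposition-free flexibility estimate: each residue's rigidity
is the kernel-weighted count of its neighbors, and flexibility is its
reciprocal.  The default is the fast exponential kernel
Phi(r) = exp(-(r/eta)^kappa) with eta = 3 A, kappa = 2; a Lorentz kernel
Phi(r) = 1 / (1 + (r/eta)^nu) is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import TrajectoryEnsemble

RIGIDITY_FLOOR = 1e-12


@dataclass(frozen=True)
class FRIKernel:
    kind: str = "exponential"      # exponential | lorentz
    eta: float = 3.0               # Angstrom
    power: float = 2.0             # kappa (exponential) or nu (lorentz)

    def __post_init__(self):
        if self.kind not in ("exponential", "lorentz"):
            raise ValueError(f"unknown FRI kernel {self.kind!r}")
        if self.eta <= 0 or self.power <= 0:
            raise ValueError("kernel scale and power must be positive")

    def __call__(self, r: np.ndarray) -> np.ndarray:
        x = (np.asarray(r, float) / self.eta) ** self.power
        if self.kind == "exponential":
            return np.exp(-x)
        return 1.0 / (1.0 + x)


@dataclass
class FlexibilityProfile:
    mu: np.ndarray                 # rigidity, per residue
    flexibility: np.ndarray        # 1 / mu, ensemble-averaged when frames given
    normalized: Optional[np.ndarray] = None


def rigidity_index(coords: np.ndarray,
                   kernel: FRIKernel = FRIKernel()) -> np.ndarray:
    """mu_i = sum_{j != i} Phi(r_ij), floored at 1e-12."""
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need an (N, 3) array with N >= 2")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    phi = kernel(d)
    np.fill_diagonal(phi, 0.0)
    mu = phi.sum(axis=1)
    return np.maximum(mu, RIGIDITY_FLOOR)


def flexibility_profile(coords: np.ndarray,
                        kernel: FRIKernel = FRIKernel(),
                        ensemble: Optional[TrajectoryEnsemble] = None,
                        normalize: bool = False) -> FlexibilityProfile:
    """Per-residue flexibility f_i = 1/mu_i; with an ensemble, f is
    computed per frame and averaged (mu reported for the mean structure
    alongside)."""
    mu = rigidity_index(coords, kernel)
    if ensemble is None:
        flex = 1.0 / mu
    else:
        per_frame = np.stack([1.0 / rigidity_index(f, kernel)
                              for f in ensemble.frames])
        flex = per_frame.mean(axis=0)
    norm = None
    if normalize:
        lo, hi = flex.min(), flex.max()
        norm = (flex - lo) / (hi - lo) if hi > lo else np.zeros_like(flex)
    return FlexibilityProfile(mu=mu, flexibility=flex, normalized=norm)
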