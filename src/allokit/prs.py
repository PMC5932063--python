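"""Perturbation response scanning (PRS).

Linear response: a force F applied at residue i displaces the whole chain
by dR = C F, with C the covariance matrix standing in for the inverse
Hessian (the thermal prefactor is absorbed — only relative profile shapes
matter downstream).  Scanning applies a sphere of random unit forces to
one residue at a time; entry (i, j) of the N x N response map is the mean
squared displacement of residue j.  Averaging |C_ji f|^2 over uniformly
random unit directions f has the closed form ||C_ji||_F^2 / 3 in the 3x3
blocks of C, which serves as the deterministic reference for the Monte
Carlo scan.

Row means (perturbed residue fixed) give the effector profile — the
ability of a residue to move the rest of the protein; column means give
the sensor profile — how strongly a residue responds to perturbation
elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import CovarianceMatrix

DEFAULT_N_FORCES = 250
DEFAULT_PEAK_Z = 1.5
PEAK_MIN_SEPARATION = 3


class DegenerateResidueError(ValueError):
    pass


@dataclass
class ResponseMatrix:
    values: np.ndarray           # (N, N); (i, j) = response of j to forces at i
    normalization: str           # raw | diagonal-normalized
    n_forces: int
    seed: Optional[int]

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


@dataclass
class PRSProfile:
    values: np.ndarray
    kind: str                    # effector | sensor
    peaks: np.ndarray            # indices, z-score above threshold
    zscores: np.ndarray


def random_unit_forces(n_forces: int, seed: int,
                       stratified: bool = True) -> np.ndarray:
    """Random directions on the unit sphere.

    ``stratified`` (default) draws random orthonormal triads (QR of
    Gaussian matrices): each direction is marginally uniform on the
    sphere, but every complete triad averages any quadratic form exactly,
    so the scan's quadrature error shrinks from O(1/sqrt(K)) to O(1/K).
    ``stratified=False`` gives plain iid normalized Gaussian triples.
    """
    if n_forces < 1:
        raise ValueError("need at least one force")
    rng = np.random.default_rng(seed)
    if not stratified:
        v = rng.standard_normal((n_forces, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    n_triads = (n_forces + 2) // 3
    out = np.empty((3 * n_triads, 3))
    for t in range(n_triads):
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q = q * np.sign(np.diag(r))  # unique, uniformly distributed frame
        out[3 * t:3 * t + 3] = q.T
    return out[:n_forces]


def prs_scan(cov: CovarianceMatrix, n_forces: int = DEFAULT_N_FORCES,
             seed: int = 0) -> ResponseMatrix:
    """Monte Carlo PRS map: for each residue i, apply ``n_forces`` random
    unit forces to its 3-block and average the squared displacement of
    every residue j."""
    C = cov.matrix
    n = cov.n_residues
    _check_psd(C)
    forces = random_unit_forces(n_forces, seed)  # (K, 3)
    out = np.empty((n, n))
    for i in range(n):
        block = C[:, 3 * i:3 * i + 3]            # (3N, 3)
        disp = block @ forces.T                  # (3N, K)
        sq = disp.reshape(n, 3, n_forces) ** 2
        out[i] = sq.sum(axis=1).mean(axis=1)
    return ResponseMatrix(values=out, normalization="raw",
                          n_forces=n_forces, seed=seed)


def prs_expected(cov: CovarianceMatrix) -> ResponseMatrix:
    """Closed-form direction average of the scan:
    E_f |C_ji f|^2 = ||C_ji||_F^2 / 3 for unit forces f uniform on the
    sphere (E[f f^T] = I/3)."""
    C = cov.matrix
    n = cov.n_residues
    blocks = C.reshape(n, 3, n, 3)
    # entry (i, j): response at j to force at i uses block C[j, i]
    out = np.einsum("jaib,jaib->ij", blocks, blocks) / 3.0
    return ResponseMatrix(values=out, normalization="raw", n_forces=0,
                          seed=None)


def normalize_prs(m: ResponseMatrix) -> ResponseMatrix:
    """Divide each row by its diagonal entry so self-response is 1."""
    d = np.diag(m.values)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        raise DegenerateResidueError(
            f"zero self-response at residue index {bad[0]}")
    return ResponseMatrix(values=m.values / d[:, None],
                          normalization="diagonal-normalized",
                          n_forces=m.n_forces, seed=m.seed)


def _profile(m: ResponseMatrix, axis: int, kind: str,
             include_diagonal: bool, peak_z: float) -> PRSProfile:
    n = m.n_residues
    if n < 3:
        raise ValueError("profiles need at least 3 residues")
    vals = m.values.copy()
    if include_diagonal:
        prof = vals.mean(axis=axis)
    else:
        np.fill_diagonal(vals, np.nan)
        prof = np.nanmean(vals, axis=axis)
    sd = prof.std()
    z = (prof - prof.mean()) / sd if sd > 0 else np.zeros(n)
    peaks = _pick_peaks(z, peak_z)
    return PRSProfile(values=prof, kind=kind, peaks=peaks, zscores=z)


def _pick_peaks(z: np.ndarray, threshold: float,
                min_separation: int = PEAK_MIN_SEPARATION) -> np.ndarray:
    """Above-threshold entries, greedily thinned so peaks are at least
    ``min_separation`` residues apart (strongest first)."""
    cand = np.flatnonzero(z > threshold)
    cand = cand[np.argsort(z[cand])[::-1]]
    chosen: list[int] = []
    for c in cand:
        if all(abs(c - p) >= min_separation for p in chosen):
            chosen.append(int(c))
    return np.asarray(sorted(chosen), dtype=int)


def effector_profile(m: ResponseMatrix, include_diagonal: bool = False,
                     peak_z: float = DEFAULT_PEAK_Z) -> PRSProfile:
    """Row means: how strongly perturbing residue i moves everything
    else.  The diagonal (self-response) is excluded by default."""
    return _profile(m, axis=1, kind="effector",
                    include_diagonal=include_diagonal, peak_z=peak_z)


def sensor_profile(m: ResponseMatrix, include_diagonal: bool = False,
                   peak_z: float = DEFAULT_PEAK_Z) -> PRSProfile:
    """Column means: how strongly residue j responds to perturbations
    applied elsewhere."""
    return _profile(m, axis=0, kind="sensor",
                    include_diagonal=include_diagonal, peak_z=peak_z)


def _check_psd(C: np.ndarray, tol: float = 1e-6) -> None:
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("covariance matrix is not symmetric")
    w = np.linalg.eigvalsh(C)
    if w.min() < -tol * max(abs(w.max()), 1.0):
        raise ValueError("covariance matrix is not positive semidefinite")
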