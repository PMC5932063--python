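"""Coarse-grained conformational ensembles and their second moments.

Two generators are provided.  The event-driven discrete molecular dynamics
(DMD) engine simulates C-alpha beads bound by infinite square wells: bonded
neighbors (|i-j| = 1) with fractional well half-width sigma = 0.05 around
the native 3.8 A spacing, and nonbonded native pairs closer than r_c = 8 A
with sigma = 0.1.  Between collisions beads move ballistically; at a well
wall the normal component of the pair's relative velocity is reflected
elastically, conserving energy and momentum exactly.

The elastic-network (ENM) surrogate draws frames from the multivariate
Gaussian whose covariance is the pseudo-inverse of the anisotropic network
Hessian with the six rigid-body modes removed — a desk-scale stand-in for
long all-atom trajectories that feeds the same downstream stages.

Downstream reductions: 3N x 3N covariance (with optional least-squares
superposition), per-residue mean-square fluctuations / B-factors, and
normalized slow-mode displacement profiles whose local minima mark hinges.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structure import CaTrace

BOND_SIGMA = 0.05
NONBOND_SIGMA = 0.1
DMD_CUTOFF = 8.0
CA_SPACING = 3.8


class ConnectivityError(ValueError):
    pass


@dataclass
class SquareWellPair:
    i: int
    j: int
    bonded: bool
    r0: float
    d_min: float
    d_max: float


@dataclass
class SquareWellModel:
    n_beads: int
    pairs: list[SquareWellPair]
    native: np.ndarray  # (N, 3)

    def pair_arrays(self):
        idx_i = np.array([p.i for p in self.pairs])
        idx_j = np.array([p.j for p in self.pairs])
        dmin = np.array([p.d_min for p in self.pairs])
        dmax = np.array([p.d_max for p in self.pairs])
        return idx_i, idx_j, dmin, dmax


@dataclass
class TrajectoryEnsemble:
    frames: np.ndarray          # (F, N, 3) Angstrom
    source: str                 # dmd | enm-surrogate | external | synthetic
    frame_interval: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (F, N, 3)")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return self.frames.shape[1]


@dataclass
class CovarianceMatrix:
    matrix: np.ndarray          # (3N, 3N), Angstrom^2
    mean: np.ndarray            # (N, 3)

    @property
    def n_residues(self) -> int:
        return self.mean.shape[0]


@dataclass
class MobilityProfile:
    msf: np.ndarray             # (N,) Angstrom^2
    bfactor: np.ndarray         # (N,) Angstrom^2, B = (8 pi^2 / 3) msf


@dataclass
class SlowModeProfile:
    profile: np.ndarray         # (N,), sums to 1
    smoothed: np.ndarray
    minima: np.ndarray          # hinge candidates (indices)
    maxima: np.ndarray          # mobile-region candidates (indices)
    n_modes: int
    eigenvalues: np.ndarray


def build_square_well_model(trace: CaTrace, r_c: float = DMD_CUTOFF,
                            sigma_bond: float = BOND_SIGMA,
                            sigma_nonbond: float = NONBOND_SIGMA,
                            chain_breaks: Optional[Sequence[int]] = None
                            ) -> SquareWellModel:
    """Square-well pair list from a native C-alpha trace.

    Consecutive beads are bonded unless a chain break separates them
    (``chain_breaks`` lists the first bead index of each new chain).
    Nonconsecutive pairs interact when their native distance is below
    ``r_c``; all wells are [(1-sigma) r0, (1+sigma) r0].
    """
    pos = np.asarray(trace.positions, dtype=float)
    n = pos.shape[0]
    if n < 2:
        raise ValueError("need at least 2 beads")
    breaks = set(chain_breaks or ())
    pairs: list[SquareWellPair] = []
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            bonded = (j == i + 1) and (j not in breaks)
            if bonded:
                sigma = sigma_bond
                if not 2.5 <= d[i, j] <= 4.5:
                    import logging
                    logging.getLogger(__name__).warning(
                        "bonded distance %.2f A between beads %d-%d outside "
                        "[2.5, 4.5]", d[i, j], i, j)
            elif d[i, j] < r_c:
                sigma = sigma_nonbond
            else:
                continue
            r0 = d[i, j]
            pairs.append(SquareWellPair(i=i, j=j, bonded=bonded, r0=r0,
                                        d_min=(1 - sigma) * r0,
                                        d_max=(1 + sigma) * r0))
    return SquareWellModel(n_beads=n, pairs=pairs, native=pos.copy())


def pair_event_time(r: np.ndarray, v: np.ndarray, d_min: float,
                    d_max: float) -> float:
    """Time to the next wall crossing for one pair in relative coordinates.

    The pair is assumed inside (or numerically at) its well.  Returns
    +inf when the relative velocity vanishes.
    """
    a = float(v @ v)
    if a == 0.0:
        return math.inf
    b = float(r @ v)
    c2 = float(r @ r)
    if b < 0.0:  # approaching: inner wall may be hit first
        disc_in = b * b - a * (c2 - d_min * d_min)
        if disc_in >= 0.0:
            t_in = (-b - math.sqrt(disc_in)) / a
            if t_in >= 0.0:
                return t_in
    disc_out = b * b + a * (d_max * d_max - c2)
    if disc_out < 0.0:
        disc_out = 0.0  # numerically at/over the wall while moving outward
    return (-b + math.sqrt(disc_out)) / a


def _reflect(pos: np.ndarray, vel: np.ndarray, i: int, j: int) -> None:
    """Elastic reflection of the pair's relative velocity along the pair
    axis (equal masses): exchanges the normal components."""
    rhat = pos[i] - pos[j]
    rhat = rhat / np.linalg.norm(rhat)
    s = float((vel[i] - vel[j]) @ rhat)
    vel[i] -= s * rhat
    vel[j] += s * rhat


def run_dmd(model: SquareWellModel, start: Optional[CaTrace] = None,
            temperature: float = 1.0, n_events: int = 100_000,
            sample_every: int = 100, seed: int = 0,
            burn_in_events: Optional[int] = None,
            andersen_interval: Optional[float] = None,
            record_events: bool = False,
            pre_event_hook=None) -> TrajectoryEnsemble:
    """Event-driven square-well dynamics in reduced units (mass 1,
    k_B T = ``temperature``).

    Velocities are initialized from the Maxwell–Boltzmann distribution with
    the center-of-mass drift removed.  Pair events are kept in a binary
    heap and invalidated lazily via per-bead collision counters.  Frames
    are sampled on a uniform time grid whose spacing corresponds to
    ``sample_every`` events at the observed collision rate, after a burn-in
    of ``burn_in_events`` (default: one fifth of ``n_events``); sampling on
    a time grid rather than at collision instants gives time-weighted
    (equilibrium) configuration statistics.

    ``andersen_interval``, if set, resamples all velocities from the
    Maxwell–Boltzmann distribution at that interval of simulation time
    (Andersen-style thermostat; default off, so kinetic energy is conserved
    exactly between resamplings).
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    rng = np.random.default_rng(seed)
    n = model.n_beads
    pos = (np.asarray(start.positions, float).copy() if start is not None
           else model.native.copy())
    if pos.shape != (n, 3):
        raise ValueError("start geometry does not match the model")
    pos = _project_into_wells(model, pos)

    vel = rng.normal(0.0, math.sqrt(temperature), size=(n, 3))
    vel -= vel.mean(axis=0)

    pairs = model.pairs
    n_pairs = len(pairs)
    # adjacency: bead -> pair indices
    bead_pairs: list[list[int]] = [[] for _ in range(n)]
    for k, p in enumerate(pairs):
        bead_pairs[p.i].append(k)
        bead_pairs[p.j].append(k)

    epoch = [0] * n_pairs
    heap: list[tuple] = []
    t_now = 0.0

    def schedule(k: int) -> None:
        p = pairs[k]
        dt = pair_event_time(pos[p.i] - pos[p.j], vel[p.i] - vel[p.j],
                             p.d_min, p.d_max)
        if math.isfinite(dt):
            heapq.heappush(heap, (t_now + dt, k, epoch[k]))

    for k in range(n_pairs):
        schedule(k)

    if burn_in_events is None:
        burn_in_events = n_events // 5
    frames: list[np.ndarray] = []
    events: list[tuple] = []
    kinetic0 = 0.5 * float(np.sum(vel * vel))
    momentum0 = vel.sum(axis=0).copy()

    sample_dt: Optional[float] = None
    next_sample: Optional[float] = None
    burn_in_end_time: Optional[float] = None
    next_thermostat = (andersen_interval if andersen_interval is not None
                       else math.inf)

    n_done = 0
    while n_done < n_events:
        if not heap:
            break
        t_ev, k, ep = heapq.heappop(heap)
        if ep != epoch[k]:
            continue
        # emit frames on the time grid crossed by this ballistic segment
        if next_sample is not None:
            while next_sample <= t_ev:
                frames.append(pos + vel * (next_sample - t_now))
                next_sample += sample_dt
        # thermostat acts between events
        if next_thermostat <= t_ev:
            pos = pos + vel * (next_thermostat - t_now)
            t_now = next_thermostat
            vel = rng.normal(0.0, math.sqrt(temperature), size=(n, 3))
            vel -= vel.mean(axis=0)
            next_thermostat += andersen_interval
            for kk in range(n_pairs):
                epoch[kk] += 1
                schedule(kk)
            continue
        p = pairs[k]
        if pre_event_hook is not None:
            # validation hook: state at t_now, scheduled event (t_ev, pair)
            pre_event_hook(t_now, t_ev, (p.i, p.j), pos, vel)
        pos += vel * (t_ev - t_now)
        t_now = t_ev
        _reflect(pos, vel, p.i, p.j)
        if record_events:
            events.append((t_now, p.i, p.j))
        for b in (p.i, p.j):
            for kk in bead_pairs[b]:
                epoch[kk] += 1
        for b in (p.i, p.j):
            for kk in bead_pairs[b]:
                schedule(kk)
        n_done += 1
        if n_done == burn_in_events:
            burn_in_end_time = t_now
            mean_dt = t_now / max(n_done, 1)
            sample_dt = max(mean_dt * sample_every, 1e-12)
            next_sample = t_now + sample_dt

    kinetic1 = 0.5 * float(np.sum(vel * vel))
    momentum1 = vel.sum(axis=0)
    if len(frames) < 2:
        frames.append(pos.copy())
        frames.append(pos + vel * 1e-9)
    meta = {
        "kinetic_energy_initial": kinetic0,
        "kinetic_energy_final": kinetic1,
        "momentum_drift": float(np.max(np.abs(momentum1 - momentum0))),
        "n_events": n_done,
        "final_time": t_now,
        "seed": seed,
        "temperature": temperature,
    }
    if record_events:
        meta["events"] = events
    return TrajectoryEnsemble(frames=np.asarray(frames), source="dmd",
                              frame_interval=sample_dt or 1.0, meta=meta)


def _project_into_wells(model: SquareWellModel, pos: np.ndarray,
                        max_iter: int = 200) -> np.ndarray:
    """Iteratively nudge pair distances into their wells (used when the
    start geometry violates a constraint; logged)."""
    idx_i, idx_j, dmin, dmax = model.pair_arrays()
    pos = pos.copy()
    for _ in range(max_iter):
        delta = pos[idx_i] - pos[idx_j]
        d = np.linalg.norm(delta, axis=1)
        lo = d < dmin
        hi = d > dmax
        if not (lo.any() or hi.any()):
            return pos
        for mask, target in ((lo, dmin * 1.001), (hi, dmax * 0.999)):
            for k in np.flatnonzero(mask):
                i, j = idx_i[k], idx_j[k]
                u = (pos[i] - pos[j]) / max(d[k], 1e-12)
                corr = (target[k] - d[k]) / 2.0
                pos[i] += corr * u
                pos[j] -= corr * u
        import logging
        logging.getLogger(__name__).info(
            "projected start geometry toward well constraints")
    raise RuntimeError("could not project start geometry into the wells")


def well_violation(model: SquareWellModel, frames: np.ndarray) -> float:
    """Maximum relative well-bound violation over frames and pairs
    (0 when every sampled distance respects its well)."""
    idx_i, idx_j, dmin, dmax = model.pair_arrays()
    worst = 0.0
    for f in frames:
        d = np.linalg.norm(f[idx_i] - f[idx_j], axis=1)
        over = np.max((d - dmax) / dmax)
        under = np.max((dmin - d) / dmin)
        worst = max(worst, float(over), float(under))
    return max(worst, 0.0)


# ---------------------------------------------------------------------------
# Elastic-network surrogate

def build_anm_hessian(coords: np.ndarray, cutoff: float, gamma: float = 1.0,
                      extra_springs: Optional[Sequence[tuple]] = None
                      ) -> np.ndarray:
    """Anisotropic network Hessian: for each contact (distance < cutoff)
    the 3x3 block -gamma * u u^T with u the unit inter-bead vector.
    ``extra_springs`` adds (i, j, k) springs regardless of distance."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    H = np.zeros((3 * n, 3 * n))
    pairs: list[tuple] = []
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < cutoff:
                pairs.append((i, j, gamma))
    for (i, j, k) in (extra_springs or ()):
        pairs.append((int(i), int(j), float(k)))
    for i, j, k in pairs:
        u = coords[i] - coords[j]
        nrm = np.linalg.norm(u)
        if nrm < 1e-9:
            continue
        u = u / nrm
        block = k * np.outer(u, u)
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[sl_i, sl_j] -= block
        H[sl_j, sl_i] -= block
        H[sl_i, sl_i] += block
        H[sl_j, sl_j] += block
    return H


def enm_covariance(coords: np.ndarray, spring_cutoff: float = 10.0,
                   gamma: float = 1.0, temperature_scale: float = 1.0,
                   extra_springs: Optional[Sequence[tuple]] = None,
                   springs: Optional[Sequence[tuple]] = None
                   ) -> CovarianceMatrix:
    """Covariance proportional to the Hessian pseudo-inverse with the six
    rigid-body modes excluded.  Raises when the spring network is
    disconnected (more than six near-zero modes).

    ``springs`` replaces the distance-cutoff pair list entirely with an
    explicit (i, j, k) list — used by generators that plant per-pair
    stiffness patterns."""
    coords = np.asarray(coords, float)
    if springs is not None:
        H = build_anm_hessian(coords, 0.0, gamma, springs)
    else:
        H = build_anm_hessian(coords, spring_cutoff, gamma, extra_springs)
    w, V = np.linalg.eigh(H)
    tol = max(1e-8, 1e-10 * w[-1])
    n_zero = int(np.sum(w < tol))
    if n_zero > 6:
        raise ConnectivityError(
            f"elastic network is disconnected at cutoff {spring_cutoff} A "
            f"({n_zero} zero modes); increase the cutoff")
    inv = np.zeros_like(w)
    inv[6:] = temperature_scale / w[6:]
    C = (V * inv) @ V.T
    return CovarianceMatrix(matrix=C, mean=coords.copy())


def sample_enm_ensemble(trace: CaTrace, spring_cutoff: float = 10.0,
                        n_frames: int = 1000, temperature_scale: float = 1.0,
                        seed: int = 0, gamma: float = 1.0,
                        extra_springs: Optional[Sequence[tuple]] = None
                        ) -> TrajectoryEnsemble:
    """Draw frames from the ENM Gaussian around the input coordinates."""
    cov = enm_covariance(trace.positions, spring_cutoff, gamma,
                         temperature_scale, extra_springs)
    return sample_gaussian_ensemble(cov, n_frames, seed,
                                    source="enm-surrogate")


def sample_gaussian_ensemble(cov: CovarianceMatrix, n_frames: int, seed: int,
                             source: str = "synthetic") -> TrajectoryEnsemble:
    """Frames = mean + L z with L an eigen-factor of the covariance."""
    w, V = np.linalg.eigh(cov.matrix)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("covariance is not positive semidefinite")
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, w.size))
    flat = cov.mean.reshape(-1) + z @ L.T
    frames = flat.reshape(n_frames, cov.n_residues, 3)
    return TrajectoryEnsemble(frames=frames, source=source)


# ---------------------------------------------------------------------------
# Covariance and mode analysis

def superpose_frames(frames: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Least-squares (Kabsch) superposition of every frame onto the running
    mean structure; removes rigid-body motion before covariance analysis."""
    frames = np.asarray(frames, float).copy()
    ref = frames[0].copy()
    for _ in range(n_iter):
        ref_c = ref - ref.mean(axis=0)
        for f in range(frames.shape[0]):
            x = frames[f] - frames[f].mean(axis=0)
            U, _, Vt = np.linalg.svd(x.T @ ref_c)
            if np.linalg.det(U @ Vt) < 0:
                U[:, -1] *= -1
            frames[f] = x @ (U @ Vt)
        ref = frames.mean(axis=0)
    return frames


def compute_covariance(traj: TrajectoryEnsemble,
                       superpose: bool = True) -> CovarianceMatrix:
    """3N x 3N second-moment matrix of residue deviations from the mean,
    C = (1/F) sum_t dR(t) dR(t)^T, optionally after superposition."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    frames = superpose_frames(traj.frames) if superpose else traj.frames
    F = frames.shape[0]
    flat = frames.reshape(F, -1)
    mean = flat.mean(axis=0)
    dR = flat - mean
    C = dR.T @ dR / F
    return CovarianceMatrix(matrix=C, mean=mean.reshape(-1, 3))


def compute_bfactors(cov: CovarianceMatrix) -> MobilityProfile:
    """Mean-square fluctuation per residue (trace of the diagonal 3x3
    block) and the crystallographic convention B = (8 pi^2 / 3) msf."""
    n = cov.n_residues
    diag = np.diag(cov.matrix)
    msf = diag.reshape(n, 3).sum(axis=1)
    return MobilityProfile(msf=msf, bfactor=(8.0 * np.pi ** 2 / 3.0) * msf)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + x.size]
    return out


def _local_extrema(y: np.ndarray, kind: str) -> np.ndarray:
    """Interior strict local extrema plus qualifying endpoints."""
    n = y.size
    hits = []
    for i in range(n):
        left = y[i - 1] if i > 0 else None
        right = y[i + 1] if i < n - 1 else None
        if kind == "min":
            ok = all(v is None or y[i] < v for v in (left, right))
        else:
            ok = all(v is None or y[i] > v for v in (left, right))
        if ok:
            hits.append(i)
    return np.asarray(hits, dtype=int)


def pca_slow_modes(cov: CovarianceMatrix, n_modes: int = 3,
                   smooth_window: int = 5,
                   extremum_percentile: float = 25.0,
                   segments: Optional[Sequence[tuple]] = None
                   ) -> SlowModeProfile:
    """Per-residue normalized square displacement averaged (eigenvalue-
    weighted) over the ``n_modes`` largest covariance modes.

    Hinges are local minima of the smoothed profile lying below its
    ``extremum_percentile``-th percentile; mobile maxima are local maxima
    above the mirrored (100 - p) percentile.  ``segments`` lists
    (start, stop) residue ranges — e.g. the protomers of a dimer — within
    which smoothing and extremum detection are confined so profiles never
    blur across a chain boundary.
    """
    n = cov.n_residues
    if n_modes > 3 * n:
        raise ValueError("n_modes exceeds the number of coordinates")
    w, V = np.linalg.eigh(cov.matrix)
    order = np.argsort(w)[::-1][:n_modes]
    lams = np.clip(w[order], 0.0, None)
    disp = np.zeros(n)
    for lam, m in zip(lams, order):
        sq = V[:, m].reshape(n, 3)
        disp += lam * np.sum(sq * sq, axis=1)
    total = disp.sum()
    profile = disp / total if total > 0 else np.full(n, 1.0 / n)

    return slow_mode_profile_from_values(profile, smooth_window,
                                         extremum_percentile, segments,
                                         n_modes=n_modes,
                                         eigenvalues=lams)


def slow_mode_profile_from_values(profile: np.ndarray,
                                  smooth_window: int = 5,
                                  extremum_percentile: float = 25.0,
                                  segments: Optional[Sequence[tuple]] = None,
                                  n_modes: int = 0,
                                  eigenvalues: Optional[np.ndarray] = None
                                  ) -> SlowModeProfile:
    """Extremum detection on an already-computed displacement profile
    (used e.g. after averaging the two protomers of a homodimer)."""
    profile = np.asarray(profile, float)
    total = profile.sum()
    if total > 0:
        profile = profile / total
    n = profile.size
    if segments is None:
        segments = [(0, n)]
    smoothed = np.empty(n)
    minima: list[int] = []
    maxima: list[int] = []
    for (a, b) in segments:
        seg = _smooth(profile[a:b], smooth_window)
        smoothed[a:b] = seg
        lo = np.percentile(seg, extremum_percentile)
        hi = np.percentile(seg, 100.0 - extremum_percentile)
        minima.extend(a + i for i in _local_extrema(seg, "min")
                      if seg[i] <= lo)
        maxima.extend(a + i for i in _local_extrema(seg, "max")
                      if seg[i] >= hi)
    return SlowModeProfile(
        profile=profile, smoothed=smoothed,
        minima=np.asarray(sorted(minima), dtype=int),
        maxima=np.asarray(sorted(maxima), dtype=int),
        n_modes=n_modes,
        eigenvalues=(eigenvalues if eigenvalues is not None
                     else np.empty(0)))


# ---------------------------------------------------------------------------
# Trajectory I/O (multi-model PDB)

def write_trajectory_pdb(traj: TrajectoryEnsemble,
                         residue_keys: Sequence[tuple], path) -> None:
    """Write frames as a multi-model C-alpha PDB."""
    with open(path, "w") as fh:
        for m, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {m:>4d}\n")
            for k, (key, xyz) in enumerate(zip(residue_keys, frame), start=1):
                chain, resnum = key[0], key[1]
                fh.write(
                    f"ATOM  {k:>5d}  CA  ALA {chain:1s}{resnum:>4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"           C\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory_pdb(path) -> TrajectoryEnsemble:
    """Read a multi-model C-alpha PDB back into an ensemble."""
    frames: list[list[list[float]]] = []
    current: Optional[list] = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                current = []
            elif line.startswith("ENDMDL"):
                if current:
                    frames.append(current)
                current = None
            elif line.startswith("ATOM") and current is not None:
                current.append([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])])
    return TrajectoryEnsemble(frames=np.asarray(frames, float),
                              source="external")
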