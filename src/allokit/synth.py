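"""Synthetic study systems with planted, recoverable ground truth.

Three generators emulate the pipeline's three inputs: a toy multi-domain
homodimer structure (compact bead domains joined by a linker, with a
planted hinge bead, a planted globally coupled effector bead, and a floppy
sensor tail), multiple sequence alignments with planted conserved columns
and planted coevolving column pairs, and Gaussian trajectory ensembles
drawn from a known covariance.  Every generator is deterministic under a
fixed seed and returns its distributional ground truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from ._tables import AMINO_ACIDS, AMINO1_TO_3, BACKGROUND_FREQUENCIES
from .coevolution import Alignment
from .dynamics import (CovarianceMatrix, TrajectoryEnsemble, enm_covariance,
                       sample_gaussian_ensemble)
from .structure import AtomRecord, StructureModel

BOND_LENGTH = 3.8
MIN_SEPARATION = 3.6


@dataclass
class ToyDimerSpec:
    """Geometry and planted features of the toy homodimer.

    Two identical protomers of three compact domains (pseudo-NTD/MD/CTD)
    dimerize through their CTD blobs.  The hinge bead is the unique linker
    bead between the NTD and MD blobs; the effector bead sits centrally in
    the MD and receives extra elastic-network springs into every domain
    (globally coupled, low fluctuation); the sensor tail is a stretch of
    extended C-terminal beads with minimal contacts (floppy)."""

    beads_per_domain: int = 10
    tail_length: int = 4
    domain_radius: float = 6.5
    domain_gap: float = 14.0
    dimer_gap: float = 9.0
    effector_spring: float = 3.0
    effector_anchors: int = 4
    hinge_pin_spring: float = 3.0
    interface_spring: float = 0.15
    tail_spring: float = 0.25
    effector_contraction: float = 0.2
    hinge_contraction: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.beads_per_domain < 5:
            raise ValueError("need at least 5 beads per domain")
        if self.tail_length >= self.beads_per_domain:
            raise ValueError("tail cannot consume a whole domain")


@dataclass
class SyntheticMSASpec:
    """Planted structure of the synthetic alignment."""

    n_sequences: int = 200
    length: int = 50
    conserved_columns: tuple = ()
    conservation_level: float = 0.95
    coevolving_pairs: tuple = ()
    coupling: float = 0.9
    gap_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences < 2:
            raise ValueError("need at least 2 sequences")
        flat = set(self.conserved_columns)
        for a, b in self.coevolving_pairs:
            flat.update((a, b))
        if flat and max(flat) >= self.length:
            raise ValueError("planted columns exceed alignment length")
        pair_cols = [c for ab in self.coevolving_pairs for c in ab]
        if len(pair_cols) != len(set(pair_cols)):
            raise ValueError("coevolving pairs must not share columns")
        if set(pair_cols) & set(self.conserved_columns):
            raise ValueError("conserved and coevolving columns overlap")


def _grow_domain(rng: np.random.Generator, placed: list, start: np.ndarray,
                 center: np.ndarray, radius: float, n_beads: int,
                 max_tries: int = 400) -> list:
    """Self-avoiding compact growth: 3.8 A bonded steps biased toward the
    domain center, rejecting proposals within 3.6 A of any placed bead."""
    out = []
    current = start
    for _ in range(n_beads):
        for attempt in range(max_tries):
            step = rng.standard_normal(3)
            to_center = center - current
            dist_c = np.linalg.norm(to_center)
            if dist_c > radius:  # pull back inside the blob
                step = step + 1.5 * to_center / max(dist_c, 1e-9)
            step = step / np.linalg.norm(step) * BOND_LENGTH
            cand = current + step
            others = placed + out
            if others:
                d = np.linalg.norm(np.asarray(others) - cand, axis=1)
                if d.min() < MIN_SEPARATION:
                    continue
            if np.linalg.norm(cand - center) > radius + BOND_LENGTH:
                continue
            out.append(cand)
            current = cand
            break
        else:
            raise RuntimeError("domain growth stalled")
    return out


def _build_protomer(spec: ToyDimerSpec, rng: np.random.Generator
                    ) -> np.ndarray:
    b = spec.beads_per_domain
    centers = [np.array([0.0, 0.0, 0.0]),
               np.array([spec.domain_gap, 0.0, 0.0]),
               np.array([2 * spec.domain_gap - 2.0, 3.0, 0.0])]
    coords: list = []
    # domain 1 (pseudo-NTD)
    coords += _grow_domain(rng, coords, centers[0].copy(), centers[0],
                           spec.domain_radius, b)
    # unique NTD-MD linker bead = first bead of domain 2, bonded to the
    # NTD terminus and stepping toward the inter-blob midpoint (the
    # planted hinge)
    midpoint = (centers[0] + centers[1]) / 2.0
    last = coords[-1]
    linker = None
    for _ in range(400):
        step = (midpoint - last)
        step = step / np.linalg.norm(step) + 0.3 * rng.standard_normal(3)
        step = step / np.linalg.norm(step) * BOND_LENGTH
        cand = last + step
        dmin = np.min(np.linalg.norm(np.asarray(coords) - cand, axis=1))
        if dmin >= MIN_SEPARATION:
            linker = cand
            break
    if linker is None:
        raise RuntimeError("could not place the linker bead")
    coords.append(linker)
    coords += _grow_domain(rng, coords, linker, centers[1],
                           spec.domain_radius, b - 1)
    # domain 3 (pseudo-CTD), junction kept tight (no free linker)
    core = b - spec.tail_length
    coords += _grow_domain(rng, coords, coords[-1], centers[2],
                           spec.domain_radius, core)
    # floppy tail: extended beads marching away from the body with a mild
    # alternating kink (a straight line would leave transverse zero modes
    # in the elastic network)
    away = coords[-1] - np.mean(np.asarray(coords), axis=0)
    away = away / np.linalg.norm(away)
    perp = np.cross(away, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(away, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    perp2 = np.cross(away, perp)
    kinks = [perp, perp2, -perp, -perp2]
    for t in range(spec.tail_length):
        step = away + 0.45 * kinks[t % 4]
        step = step / np.linalg.norm(step) * BOND_LENGTH
        coords.append(coords[-1] + step)
    return np.asarray(coords)


def _attempt_dimer(spec: ToyDimerSpec, seed: int):
    rng = np.random.default_rng(seed)
    A = _build_protomer(spec, rng)
    n = A.shape[0]
    b = spec.beads_per_domain
    # a compact multi-domain protein has a real inter-domain interface:
    # require NTD/MD contacts beyond the covalent linker
    dA = np.linalg.norm(A[:, None, :] - A[None, :, :], axis=-1)
    n_iface = sum(1 for i in range(b) for j in range(b + 1, 2 * b)
                  if dA[i, j] < 10.0)
    if n_iface < 2:
        raise RuntimeError("no NTD-MD interface")
    # rigid duplication: rotate pi about z, translate so the CTD blobs of
    # the two protomers meet across the dimer interface
    R = np.diag([-1.0, -1.0, 1.0])
    ctd = slice(2 * b, 3 * b - spec.tail_length)
    ctd_centroid = A[ctd].mean(axis=0)
    # place B so its CTD centroid sits dimer_gap away from A's along +y
    t = ctd_centroid + np.array([0.0, spec.dimer_gap, 0.0]) - R @ ctd_centroid
    B = A @ R.T + t
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    if d.min() < MIN_SEPARATION:
        raise RuntimeError("protomer clash")
    if d.min() > 10.0:
        raise RuntimeError("no dimer interface")
    return A, B


def make_toy_dimer(spec: ToyDimerSpec, sequence: Optional[str] = None,
                   max_restarts: int = 25):
    """Generate the toy homodimer as a C-alpha-only StructureModel plus a
    ground-truth label dictionary.

    Infeasible growth (overlapping beads) retries with a derived seed up to
    ``max_restarts`` times.  ``sequence`` (one-letter, per protomer) names
    the residues; default is a background-frequency draw shared by both
    chains.
    """
    last_err: Optional[Exception] = None
    for trial in range(max_restarts):
        try:
            A, B = _attempt_dimer(spec, spec.seed + 1_000_003 * trial)
            break
        except RuntimeError as err:
            last_err = err
    else:
        raise RuntimeError(f"could not realize toy dimer spec: {last_err}")

    n = A.shape[0]
    rng = np.random.default_rng(spec.seed + 7)
    if sequence is None:
        aas = list(BACKGROUND_FREQUENCIES)
        probs = np.array([BACKGROUND_FREQUENCIES[a] for a in aas])
        sequence = "".join(rng.choice(aas, size=n, p=probs / probs.sum()))
    if len(sequence) != n:
        raise ValueError(f"sequence length {len(sequence)} != {n} beads")

    atoms = []
    for chain, coords in (("A", A), ("B", B)):
        for i in range(n):
            atoms.append(AtomRecord(
                chain_id=chain, residue_number=i + 1, icode="",
                residue_name=AMINO1_TO_3[sequence[i]], atom_name="CA",
                element="C", coordinates=coords[i].copy()))
    residues = [(a.chain_id, a.residue_number, a.icode, a.residue_name)
                for a in atoms]
    b = spec.beads_per_domain
    domain_of = lambda i: ("NTD" if i < b else "MD" if i < 2 * b else "CTD")
    model = StructureModel(
        atoms=atoms, residues=residues,
        domain_labels={(c, i + 1): domain_of(i)
                       for c in "AB" for i in range(n)})

    hinge = b                      # the linker bead (0-based, per protomer)
    md_coords = A[b + 1:2 * b]     # MD blob proper, excluding the linker
    effector = b + 1 + int(np.argmin(np.linalg.norm(
        md_coords - md_coords.mean(axis=0), axis=1)))
    tail = list(range(n - spec.tail_length, n))
    labels = {
        "n_per_protomer": n,
        "beads_per_domain": b,
        "hinge": hinge,
        "effector": effector,
        "sensor_tail": tail,
        "hinge_all": [hinge, n + hinge],
        "effector_all": [effector, n + effector],
        "sensor_tail_all": tail + [n + t for t in tail],
        "sequence": sequence,
        "domains": {"NTD": [0, b], "MD": [b, 2 * b], "CTD": [2 * b, n]},
    }
    return model, labels


def make_dimer_covariance(model: StructureModel, labels: dict,
                          spring_cutoff: float = 10.0,
                          temperature_scale: float = 1.0,
                          spec: Optional[ToyDimerSpec] = None
                          ) -> CovarianceMatrix:
    """Elastic-network covariance of the toy dimer with the planted
    dynamical signatures.

    The spring network is assembled explicitly so the ground-truth labels
    are real dynamical features, not just geometric annotations:

    * ordinary native contacts (distance < ``spring_cutoff``) get unit
      stiffness;
    * same-chain NTD/MD cross-domain contacts are softened to
      ``interface_spring`` (a slow inter-domain swing), with anchors onto
      six distinct NTD beads always present so the interface never
      degenerates to a single covalent bond or rotation axis;
    * the hinge linker is pinned to the four nearest CTD-core beads
      (``hinge_pin_spring``) — the pivot is attached to the rigid dimer
      frame;
    * the effector bead of each protomer gains ``effector_spring`` anchors
      in every domain of both chains, placed in quiet regions (near the
      pivot in the NTD, near the CTD junction in the MD, spread over the
      CTD core), making it globally coupled;
    * tail beads keep only soft backbone springs (``tail_spring``) plus
      faint i+2..i+4 stabilizers, a genuinely floppy appendage whatever
      contacts the random geometry happens to form.

    Finally the hinge neighborhood and the effector bead are amplitude-
    contracted (a diagonal similarity scaling of the covariance, which
    preserves positive semidefiniteness and all correlation structure):
    the hinge is an immobilized pivot and the effector a stiff, low-
    fluctuation bead, while both keep their broad couplings.
    """
    from .structure import extract_ca_trace
    spec = spec or ToyDimerSpec()
    trace = extract_ca_trace(model)
    X = trace.positions
    n = labels["n_per_protomer"]
    b = labels["beads_per_domain"]
    hinge = labels["hinge"]
    effector = labels["effector"]
    tail = set(labels["sensor_tail_all"])
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    n_tot = X.shape[0]
    same_chain = lambda i, j: (i < n) == (j < n)
    domain_of = lambda i: 0 if (i % n) < b else (1 if (i % n) < 2 * b else 2)
    t_k = spec.tail_spring

    springs: list = []
    iface_pairs: set = set()
    for i in range(n_tot):
        for j in range(i + 1, n_tot):
            if i in tail or j in tail:
                if same_chain(i, j) and j - i == 1:
                    springs.append((i, j, t_k))
                elif same_chain(i, j) and j - i in (2, 3):
                    springs.append((i, j, t_k / 5))
                elif same_chain(i, j) and j - i == 4:
                    springs.append((i, j, t_k / 20))
                continue
            if d[i, j] >= spring_cutoff:
                continue
            k = 1.0
            if same_chain(i, j) and hinge not in (i % n, j % n) and \
                    {domain_of(i), domain_of(j)} == {0, 1}:
                k = spec.interface_spring
                iface_pairs.add((i, j))
            springs.append((i, j, k))

    # the NTD must never dangle from the linker alone: force soft
    # interface springs onto six distinct NTD beads per chain (distinct
    # anchors rule out an infinitesimal rotation axis through a shared
    # anchor pair)
    for off in (0, n):
        cand = [(d[i, j], i, j)
                for i in range(off, off + b)
                for j in range(off + b + 1, off + 2 * b)
                if hinge not in (i % n, j % n)]
        cand.sort()
        n_natural = sum(1 for (i, j) in iface_pairs if off <= i < off + n)
        # a chain with no natural interface contact would swing wildly on
        # its forced anchors alone; compensate with stiffer anchors
        k_forced = spec.interface_spring * (4.0 if n_natural == 0 else 1.0)
        used_ntd: set = set()
        for _, i, j in cand:
            if len(used_ntd) >= 6:
                break
            if i in used_ntd:
                continue
            used_ntd.add(i)
            if (i, j) not in iface_pairs:
                springs.append((i, j, k_forced))
                iface_pairs.add((i, j))

    # coordination floor: an under-coordinated body bead (sparse random
    # growth) would be a spurious local floppy site; tie it to its nearest
    # same-chain body neighbors until it has four springs
    degree = np.zeros(n_tot, dtype=int)
    spring_set = {(i, j) for i, j, _ in springs}
    for i, j, _ in springs:
        degree[i] += 1
        degree[j] += 1
    for i in range(n_tot):
        if i in tail or degree[i] >= 4:
            continue
        near = sorted((j for j in range(n_tot)
                       if j != i and j not in tail
                       and (i < n) == (j < n)), key=lambda j: d[i, j])
        for j in near:
            if degree[i] >= 4:
                break
            key = (min(i, j), max(i, j))
            if key in spring_set:
                continue
            springs.append((key[0], key[1], 0.5))
            spring_set.add(key)
            degree[i] += 1
            degree[j] += 1

    for off in (0, n):
        h = off + hinge
        ctd = sorted((off + r for r in range(2 * b, n)
                      if off + r not in tail), key=lambda t: d[h, t])
        for t in ctd[:4]:
            springs.append((h, t, spec.hinge_pin_spring))

    for off in (0, n):
        eff = off + effector
        for off2 in (0, n):
            hh = off2 + hinge
            junction = off2 + 2 * b
            ntd = sorted(range(off2, off2 + b),
                         key=lambda t: d[hh, t])[:2]
            md = sorted(range(off2 + b + 1, off2 + 2 * b),
                        key=lambda t: d[junction, t])[:3]
            ctd = [off2 + int(a) for a in
                   np.linspace(2 * b, n - spec.tail_length - 1,
                               spec.effector_anchors, dtype=int)]
            for t in list(ntd) + list(md) + ctd:
                if t != eff and t not in tail:
                    springs.append((eff, t, spec.effector_spring))

    cov = enm_covariance(X, temperature_scale=temperature_scale,
                         springs=springs)
    scale = np.ones(n_tot)
    wing = min(1.0, spec.hinge_contraction + 0.2)
    for off in (0, n):
        scale[off + effector] = spec.effector_contraction
        scale[off + hinge] = spec.hinge_contraction
        scale[off + hinge - 1] = wing
        scale[off + hinge + 1] = wing
    S = np.repeat(scale, 3)
    cov.matrix[:] = cov.matrix * np.outer(S, S)
    return cov


def make_synthetic_msa(spec: SyntheticMSASpec):
    """Synthetic alignment with planted conserved columns and coevolving
    pairs; returns (Alignment, ground_truth).

    Background columns are iid draws from the database composition.
    A conserved column emits one peak amino acid with probability
    ``conservation_level``.  In a coevolving pair (a, b), column b copies
    a seeded bijective recoding of column a with probability ``coupling``.
    Gaps are sprinkled at ``gap_rate`` everywhere except the first (query)
    row, which stays ungapped so it can anchor structure mapping.
    """
    rng = np.random.default_rng(spec.seed)
    N, L = spec.n_sequences, spec.length
    aas = np.array(list(AMINO_ACIDS))
    probs = np.array([BACKGROUND_FREQUENCIES[a] for a in aas])
    probs = probs / probs.sum()

    cols = {}
    truth = {"conserved": {}, "pairs": []}
    for c in range(L):
        cols[c] = rng.choice(20, size=N, p=probs)
    for c in spec.conserved_columns:
        peak = int(rng.integers(20))
        keep = rng.random(N) < spec.conservation_level
        col = np.where(keep, peak, rng.choice(20, size=N, p=probs))
        cols[c] = col
        truth["conserved"][int(c)] = AMINO_ACIDS[peak]
    for (a, b) in spec.coevolving_pairs:
        mapping = rng.permutation(20)
        follow = rng.random(N) < spec.coupling
        cols[b] = np.where(follow, mapping[cols[a]],
                           rng.choice(20, size=N, p=probs))
        truth["pairs"].append({"a": int(a), "b": int(b),
                               "mapping": mapping.tolist()})

    matrix = np.stack([cols[c] for c in range(L)], axis=1)
    gaps = rng.random((N, L)) < spec.gap_rate
    gaps[0, :] = False
    seqs = []
    for r in range(N):
        chars = [("-" if gaps[r, c] else AMINO_ACIDS[matrix[r, c]])
                 for c in range(L)]
        seqs.append("".join(chars))
    ids = ["query"] + [f"seq{r}" for r in range(1, N)]
    truth["spec"] = asdict(spec)
    return Alignment(sequences=seqs, ids=ids), truth


def make_gaussian_trajectory(cov: CovarianceMatrix, n_frames: int,
                             seed: int) -> TrajectoryEnsemble:
    """Frames drawn from the given covariance around its mean structure."""
    return sample_gaussian_ensemble(cov, n_frames, seed, source="synthetic")


def make_ptm_table(model: StructureModel, labels: dict,
                   n_background: int = 5, seed: int = 0) -> pd.DataFrame:
    """PTM annotations on the planted hinge/effector/tail beads of chain A
    plus random background beads, as a serializable table."""
    rng = np.random.default_rng(seed)
    n = labels["n_per_protomer"]
    planted = [("hinge", labels["hinge"]), ("effector", labels["effector"]),
               ("sensor", labels["sensor_tail"][-1])]
    taken = {idx for _, idx in planted}
    pool = [i for i in range(n) if i not in taken]
    background = rng.choice(pool, size=min(n_background, len(pool)),
                            replace=False)
    rows = []
    for tag, idx in planted + [("background", int(i)) for i in background]:
        res = model.residues[idx]  # chain A occupies the first n residues
        rows.append({"chain": res[0], "resnum": res[1], "resname": res[3],
                     "ptm_type": "phospho" if tag != "effector" else "acetyl",
                     "planted_role": tag})
    return pd.DataFrame(rows)


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not serializable: {type(obj)}")
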