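"""Solvent accessibility and residue depth.

SASA uses a dot-sphere (Shrake–Rupley-style) construction: each heavy atom
is covered with a near-uniform spherical lattice at radius r_vdw + probe;
dots occluded by any neighboring atom's solvent-expanded sphere are
removed, and each surviving dot carries an equal share of the expanded
sphere's area.  The surviving dots double as a discrete model of the
solvent-accessible surface, from which residue depth (RD) is measured as
the distance to the nearest accessible dot beyond an atom's own expanded
radius — a deterministic surface-dot proxy for solvated-box depth methods,
monotone-equivalent on compact structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._tables import MAX_ACCESSIBILITY, VDW_RADII
from .structure import StructureModel

DEFAULT_PROBE = 1.4
DEFAULT_N_DOTS = 960
CA_COARSE_RADIUS = 3.0  # enlarged bead radius for C-alpha-only inputs

EXPOSED_RSA = 50.0
BURIED_RSA = 20.0
DEEPLY_BURIED_RSA = 10.0
RSA_CAP = 150.0


class UnknownElementError(KeyError):
    pass


class UndefinedDepthError(ValueError):
    pass


@dataclass
class SASAProfile:
    atom_area: np.ndarray          # per heavy atom, A^2
    atom_residue: np.ndarray       # heavy atom -> residue index
    residue_area: np.ndarray       # per residue, A^2
    probe: float
    surface_dots: np.ndarray       # (M, 3) surviving dot coordinates
    dot_atom: np.ndarray           # dot -> heavy atom index
    coarse: bool = False


@dataclass
class RSAProfile:
    rsa: np.ndarray                # percent
    exposure_class: list           # buried | intermediate | exposed
    deeply_buried: np.ndarray      # RSA < 10 %


@dataclass
class RDProfile:
    depth_mean: np.ndarray         # A
    depth_min: np.ndarray          # A


def _sphere_dots(n: int) -> np.ndarray:
    """Near-uniform unit-sphere lattice (golden-spiral construction)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def compute_sasa(model: StructureModel, probe: float = DEFAULT_PROBE,
                 n_dots: int = DEFAULT_N_DOTS,
                 radii: Optional[dict] = None) -> SASAProfile:
    """Dot-sphere accessible surface area per heavy atom and per residue.

    Hydrogens are ignored.  A structure whose residues carry only C-alpha
    atoms is scored in a coarse mode with an enlarged bead radius; the
    result is tagged so downstream consumers can suppress RSA classes.
    """
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})

    coords, owners, rads = [], [], []
    names = []
    for ridx in range(model.n_residues):
        for a in model.residue_atoms(ridx):
            if a.element == "H":
                continue
            coords.append(a.coordinates)
            owners.append(ridx)
            names.append(a.atom_name)
            if a.element not in table:
                raise UnknownElementError(
                    f"no van der Waals radius for element {a.element!r} "
                    f"(atom {a.atom_name} in {a.residue_name} "
                    f"{a.chain_id}{a.residue_number})")
            rads.append(table[a.element])
    coords = np.asarray(coords, float)
    owners = np.asarray(owners)
    rads = np.asarray(rads, float)

    coarse = all(n == "CA" for n in names) and len(names) == model.n_residues
    if coarse:
        rads = np.full_like(rads, CA_COARSE_RADIUS)

    expanded = rads + probe
    unit = _sphere_dots(n_dots)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()

    atom_area = np.zeros(coords.shape[0])
    kept_dots: list[np.ndarray] = []
    kept_owner: list[np.ndarray] = []
    for i in range(coords.shape[0]):
        dots = coords[i] + expanded[i] * unit
        nbr = [j for j in tree.query_ball_point(coords[i], max_reach)
               if j != i]
        alive = np.ones(n_dots, dtype=bool)
        for j in nbr:
            d2 = np.sum((dots - coords[j]) ** 2, axis=1)
            alive &= d2 > expanded[j] ** 2
        n_alive = int(alive.sum())
        atom_area[i] = 4.0 * np.pi * expanded[i] ** 2 * n_alive / n_dots
        if n_alive:
            kept_dots.append(dots[alive])
            kept_owner.append(np.full(n_alive, i))

    residue_area = np.zeros(model.n_residues)
    np.add.at(residue_area, owners, atom_area)
    surface_dots = (np.concatenate(kept_dots) if kept_dots
                    else np.empty((0, 3)))
    dot_atom = (np.concatenate(kept_owner) if kept_owner
                else np.empty(0, dtype=int))
    return SASAProfile(atom_area=atom_area, atom_residue=owners,
                       residue_area=residue_area, probe=probe,
                       surface_dots=surface_dots, dot_atom=dot_atom,
                       coarse=coarse)


def load_reference_accessibility(source=None) -> dict:
    """Unfolded-state (Gly-X-Gly) maximal accessibilities, A^2; the built-in
    theoretical table is overridable by a two-column TSV."""
    if source is None:
        return dict(MAX_ACCESSIBILITY)
    df = pd.read_csv(source, sep="\t", header=None,
                     names=["resname", "area"], comment="#")
    return {str(r.resname).upper(): float(r.area) for r in df.itertuples()}


def relative_accessibility(model: StructureModel, sasa: SASAProfile,
                           reference: Optional[dict] = None) -> RSAProfile:
    """RSA% = 100 x observed residue SASA / unfolded-state reference.

    Exposure classes: exposed above 50%, buried below 20%, intermediate
    between; RSA below 10% is additionally flagged deeply buried.  Values
    above 150% (distorted geometry) are capped with a warning.
    """
    ref = reference if reference is not None else dict(MAX_ACCESSIBILITY)
    n = model.n_residues
    rsa = np.zeros(n)
    classes = []
    for i, res in enumerate(model.residues):
        resname = res[3]
        if resname == "MSE":
            resname = "MET"
        if resname not in ref:
            raise KeyError(f"no reference accessibility for residue type "
                           f"{resname!r}")
        rsa[i] = 100.0 * sasa.residue_area[i] / ref[resname]
        if rsa[i] > RSA_CAP:
            import logging
            logging.getLogger(__name__).warning(
                "RSA %.0f%% capped at %.0f%% for %s%d", rsa[i], RSA_CAP,
                res[0], res[1])
            rsa[i] = RSA_CAP
        if rsa[i] > EXPOSED_RSA:
            classes.append("exposed")
        elif rsa[i] < BURIED_RSA:
            classes.append("buried")
        else:
            classes.append("intermediate")
    return RSAProfile(rsa=rsa, exposure_class=classes,
                      deeply_buried=rsa < DEEPLY_BURIED_RSA)


def residue_depth(model: StructureModel, sasa: SASAProfile) -> RDProfile:
    """Distance of each residue to bulk solvent, measured against the
    retained accessible-surface dot set.

    Per atom: depth = max(0, distance to the nearest surface dot minus the
    atom's own solvent-expanded radius), so an atom owning a surviving dot
    has depth 0.  Per residue both the mean and the minimum over its heavy
    atoms are reported.
    """
    if sasa.surface_dots.shape[0] == 0:
        raise UndefinedDepthError("structure exposes no surface dots")
    coords = []
    for ridx in range(model.n_residues):
        for a in model.residue_atoms(ridx):
            if a.element != "H":
                coords.append(a.coordinates)
    coords = np.asarray(coords, float)
    tree = cKDTree(sasa.surface_dots)
    nearest, _ = tree.query(coords)

    table = dict(VDW_RADII)
    expanded = []
    for ridx in range(model.n_residues):
        for a in model.residue_atoms(ridx):
            if a.element != "H":
                r = CA_COARSE_RADIUS if sasa.coarse else table[a.element]
                expanded.append(r + sasa.probe)
    depth = np.maximum(nearest - np.asarray(expanded), 0.0)

    n = model.n_residues
    depth_mean = np.zeros(n)
    depth_min = np.zeros(n)
    for r in range(n):
        mask = sasa.atom_residue == r
        depth_mean[r] = depth[mask].mean()
        depth_min[r] = depth[mask].min()
    return RDProfile(depth_mean=depth_mean, depth_min=depth_min)


def ensemble_residue_sasa(model: StructureModel, frames: np.ndarray,
                          probe: float = DEFAULT_PROBE,
                          n_dots: int = DEFAULT_N_DOTS):
    """Per-residue SASA averaged over trajectory frames of a C-alpha model.

    Returns (mean profile, per-frame matrix).  The mean is accumulated in
    a single pass, so streaming and batch averaging agree exactly up to
    floating-point summation order.
    """
    frames = np.asarray(frames, float)
    per_frame = []
    running = np.zeros(model.n_residues)
    for f, coords in enumerate(frames):
        shifted = _with_coordinates(model, coords)
        prof = compute_sasa(shifted, probe=probe, n_dots=n_dots)
        per_frame.append(prof.residue_area)
        running += (prof.residue_area - running) / (f + 1)
    return running, np.stack(per_frame)


def _with_coordinates(model: StructureModel, coords: np.ndarray
                      ) -> StructureModel:
    """Copy of a one-atom-per-residue model with replaced coordinates."""
    from dataclasses import replace
    atoms = []
    k = 0
    for ridx in range(model.n_residues):
        for a in model.residue_atoms(ridx):
            atoms.append(replace(a, coordinates=np.asarray(coords[k],
                                                           float)))
            k += 1
    return StructureModel(atoms=atoms, residues=list(model.residues),
                          domain_labels=model.domain_labels)


def surface_table(model: StructureModel, sasa: SASAProfile,
                  rsa: Optional[RSAProfile],
                  rd: Optional[RDProfile]) -> pd.DataFrame:
    rows = []
    for i, res in enumerate(model.residues):
        rows.append({
            "chain": res[0], "resnum": res[1],
            "sasa": sasa.residue_area[i],
            "rsa": rsa.rsa[i] if rsa is not None else np.nan,
            "class": rsa.exposure_class[i] if rsa is not None else "",
            "rd_mean": rd.depth_mean[i] if rd is not None else np.nan,
            "rd_min": rd.depth_min[i] if rd is not None else np.nan,
        })
    return pd.DataFrame(rows)
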