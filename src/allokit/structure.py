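"""Residue-level structure models, contact maps, and PTM-site mapping.

Structures are read from PDB-format text.  Author residue numbering (the
numbers printed in the file) is the public coordinate system throughout the
package; internal indices are 0-based and contiguous over the ordered
residue list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._tables import AMINO3_TO_1

log = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Raised when a coordinate record cannot be parsed; names the line."""


class EmptyStructureError(ValueError):
    """Raised when a PDB text contains no protein atoms."""


class InsufficientTraceError(ValueError):
    """Raised when fewer than two residues carry a C-alpha atom."""


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_number: int
    icode: str
    residue_name: str
    atom_name: str
    element: str
    coordinates: np.ndarray  # (3,) in Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    is_protein: bool = True

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.icode)


@dataclass
class StructureModel:
    """Atoms grouped into an ordered residue list.

    ``residues`` is ordered chain-then-number(-then-insertion-code)
    ascending; every protein atom's residue key appears exactly once.
    Waters and ligands are retained in ``atoms`` flagged non-protein but do
    not appear in ``residues``.
    """

    atoms: list[AtomRecord]
    residues: list[tuple]  # (chain_id, residue_number, icode, residue_name)
    domain_labels: Optional[dict] = None
    _atom_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._atom_index:
            for a in self.atoms:
                if a.is_protein:
                    self._atom_index.setdefault(a.residue_key, []).append(a)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_index(self, chain_id: str, residue_number: int,
                      icode: str = "") -> Optional[int]:
        """0-based index of an author-numbered residue, or None."""
        key = (chain_id, residue_number, icode)
        for i, r in enumerate(self.residues):
            if (r[0], r[1], r[2]) == key:
                return i
        return None

    def residue_atoms(self, index: int) -> list[AtomRecord]:
        r = self.residues[index]
        return self._atom_index.get((r[0], r[1], r[2]), [])

    def sequence(self, chain_id: Optional[str] = None) -> str:
        """One-letter sequence over the ordered residues ('X' for unknowns)."""
        out = []
        for r in self.residues:
            if chain_id is not None and r[0] != chain_id:
                continue
            out.append(AMINO3_TO_1.get(r[3], "X"))
        return "".join(out)

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r[0] not in seen:
                seen.append(r[0])
        return seen


@dataclass
class CaTrace:
    """One bead per residue that has a C-alpha atom."""

    positions: np.ndarray  # (N, 3) Angstrom
    residue_index_map: list[tuple]  # row -> (chain_id, residue_number, icode)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


@dataclass
class ContactMap:
    n_residues: int
    contacts: np.ndarray  # (N, N) bool, symmetric, False diagonal
    cutoff: float
    metric: str

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.contacts[i])

    def to_edge_list(self) -> pd.DataFrame:
        ii, jj = np.nonzero(np.triu(self.contacts, k=1))
        return pd.DataFrame({"i": ii, "j": jj})


def _parse_float(text: str, what: str, lineno: int, line: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(
            f"malformed {what} field {text!r} on line {lineno}: {line.rstrip()}"
        ) from None


def load_structure(pdb_text: str,
                   domain_labels: Optional[dict] = None) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    ATOM and HETATM records are read with fixed-column slicing; altloc and
    insertion-code columns are honored.  Among alternate locations the
    highest-occupancy conformer is kept (ties go to the first encountered).
    Hydrogens are retained in the atom list; downstream metrics that must
    ignore them do so explicitly.
    """
    raw: list[AtomRecord] = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"truncated coordinate record on line {lineno}")
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        try:
            resseq = int(line[22:26])
        except ValueError:
            raise PDBParseError(
                f"malformed residue number on line {lineno}: {line.rstrip()}"
            ) from None
        icode = line[26].strip()
        x = _parse_float(line[30:38], "x coordinate", lineno, line)
        y = _parse_float(line[38:46], "y coordinate", lineno, line)
        z = _parse_float(line[46:54], "z coordinate", lineno, line)
        occ_text = line[54:60].strip()
        occupancy = float(occ_text) if occ_text else 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _element_from_name(name)
        is_protein = resname in AMINO3_TO_1 and resname not in WATER_NAMES
        raw.append(AtomRecord(
            chain_id=chain, residue_number=resseq, icode=icode,
            residue_name=resname, atom_name=name, element=element,
            coordinates=np.array([x, y, z], dtype=float),
            occupancy=occupancy, altloc=altloc, is_protein=is_protein,
        ))

    if not any(a.is_protein for a in raw):
        raise EmptyStructureError("no protein ATOM records found")

    atoms = _resolve_altlocs(raw)

    seen: dict[tuple, str] = {}
    for a in atoms:
        if a.is_protein and a.residue_key not in seen:
            seen[a.residue_key] = a.residue_name
    residues = sorted(
        [(c, n, i, seen[(c, n, i)]) for (c, n, i) in seen],
        key=lambda r: (r[0], r[1], r[2]),
    )
    return StructureModel(atoms=atoms, residues=residues,
                          domain_labels=domain_labels)


def _element_from_name(name: str) -> str:
    """Heuristic element assignment for files without element columns."""
    s = name.strip()
    if not s:
        return ""
    if s[0].isdigit():
        s = s.lstrip("0123456789")
    if s[:1].upper() == "H":
        return "H"
    two = s[:2].upper()
    if two in ("SE", "FE", "ZN", "MG", "MN", "NA", "CL", "BR"):
        return two
    return s[:1].upper()


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.icode, a.atom_name)
        if key not in best:
            best[key] = a
            order.append(key)
        elif a.occupancy > best[key].occupancy:
            best[key] = a
    return [best[k] for k in order]


def to_pdb_text(model: StructureModel) -> str:
    """Serialize protein atoms back to PDB-format text."""
    lines = []
    serial = 1
    for ridx, res in enumerate(model.residues):
        for a in model.residue_atoms(ridx):
            name = a.atom_name
            # standard alignment: 1-3 char names start in column 14
            fmt_name = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = a.coordinates
            lines.append(
                f"ATOM  {serial:>5d} {fmt_name}{'':1s}{a.residue_name:>3s} "
                f"{a.chain_id:1s}{a.residue_number:>4d}{a.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def extract_ca_trace(model: StructureModel) -> CaTrace:
    """One bead per residue with a C-alpha; residues lacking one are skipped
    and logged."""
    positions = []
    index_map = []
    for ridx, res in enumerate(model.residues):
        ca = next((a for a in model.residue_atoms(ridx)
                   if a.atom_name == "CA"), None)
        if ca is None:
            log.warning("residue %s%d%s lacks a CA atom; skipped from trace",
                        res[0], res[1], res[2])
            continue
        positions.append(ca.coordinates)
        index_map.append((res[0], res[1], res[2]))
    if len(positions) < 2:
        raise InsufficientTraceError(
            f"only {len(positions)} C-alpha atoms found; need at least 2")
    return CaTrace(positions=np.asarray(positions, dtype=float),
                   residue_index_map=index_map)


def compute_contact_map(model: StructureModel, cutoff: float,
                        metric: str = "heavy-atom-min") -> ContactMap:
    """Boolean residue contact map under a strict ``distance < cutoff`` rule.

    ``heavy-atom-min`` uses the shortest distance between any two non-
    hydrogen atoms of the residue pair; ``ca-ca`` uses C-alpha positions
    only (residues without a C-alpha have no contacts in that mode).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if metric not in ("heavy-atom-min", "ca-ca"):
        raise ValueError(f"unknown contact metric {metric!r}")
    n = model.n_residues
    contacts = np.zeros((n, n), dtype=bool)

    if metric == "ca-ca":
        pos = np.full((n, 3), np.nan)
        for i in range(n):
            ca = next((a for a in model.residue_atoms(i)
                       if a.atom_name == "CA"), None)
            if ca is not None:
                pos[i] = ca.coordinates
        valid = ~np.isnan(pos[:, 0])
        idx = np.flatnonzero(valid)
        if idx.size:
            d = np.linalg.norm(pos[idx, None, :] - pos[None, idx, :], axis=-1)
            hit = d < cutoff
            np.fill_diagonal(hit, False)
            contacts[np.ix_(idx, idx)] = hit
    else:
        coords, owner = [], []
        for i in range(n):
            for a in model.residue_atoms(i):
                if a.element != "H":
                    coords.append(a.coordinates)
                    owner.append(i)
        coords = np.asarray(coords)
        owner = np.asarray(owner)
        from scipy.spatial import cKDTree
        tree = cKDTree(coords)
        for ai, aj in tree.query_pairs(cutoff * (1 - 1e-12)):
            ri, rj = owner[ai], owner[aj]
            if ri != rj:
                contacts[ri, rj] = contacts[rj, ri] = True
    np.fill_diagonal(contacts, False)
    return ContactMap(n_residues=n, contacts=contacts, cutoff=cutoff,
                      metric=metric)


# ---------------------------------------------------------------------------
# PTM annotation tables

PTM_TYPES = ("phospho", "acetyl", "other")

PTM_TABLE_COLUMNS = ["chain", "resnum", "resname", "ptm_type"]


def read_ptm_table(tsv_text_or_path) -> pd.DataFrame:
    """Read a PTM-site table (TSV with header chain/resnum/resname/ptm_type)."""
    if isinstance(tsv_text_or_path, str) and "\t" in tsv_text_or_path:
        handle = StringIO(tsv_text_or_path)
    else:
        handle = tsv_text_or_path
    df = pd.read_csv(handle, sep="\t", dtype={"chain": str, "resname": str,
                                              "ptm_type": str})
    missing = [c for c in PTM_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PTM table missing columns: {missing}")
    df["resnum"] = df["resnum"].astype(int)
    dup = df.duplicated(subset=["chain", "resnum", "ptm_type"])
    if dup.any():
        raise ValueError("duplicate (chain, resnum) rows for the same ptm_type")
    return df


def write_ptm_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class PTMMapping:
    """Result of projecting an annotation table onto a structure."""

    mapped: pd.DataFrame    # adds residue_index and name_mismatch columns
    unmapped: pd.DataFrame

    @property
    def residue_indices(self) -> np.ndarray:
        return self.mapped["residue_index"].to_numpy()


def map_ptm_sites(table: pd.DataFrame, model: StructureModel) -> PTMMapping:
    """Map annotation rows onto structure residues by (chain, resnum).

    Rows whose residue exists are mapped; a residue-name disagreement is
    flagged, not dropped.  Off-structure rows are returned as unmapped —
    annotation tables are typically compiled on full-length sequences while
    structures have unresolved segments.
    """
    if len(table) == 0:
        raise ValueError("PTM table is empty")
    lookup = {(r[0], r[1]): (i, r[3]) for i, r in enumerate(model.residues)}
    mapped_rows, unmapped_rows = [], []
    for _, row in table.iterrows():
        hit = lookup.get((row["chain"], int(row["resnum"])))
        if hit is None:
            unmapped_rows.append(row)
            continue
        ridx, resname = hit
        out = row.copy()
        out["residue_index"] = ridx
        out["name_mismatch"] = (str(row["resname"]).upper() != resname.upper())
        mapped_rows.append(out)
    mapped = pd.DataFrame(mapped_rows).reset_index(drop=True) if mapped_rows \
        else pd.DataFrame(columns=PTM_TABLE_COLUMNS + ["residue_index",
                                                       "name_mismatch"])
    if mapped_rows:
        mapped["residue_index"] = mapped["residue_index"].astype(int)
    unmapped = pd.DataFrame(unmapped_rows).reset_index(drop=True) if \
        unmapped_rows else pd.DataFrame(columns=PTM_TABLE_COLUMNS)
    return PTMMapping(mapped=mapped, unmapped=unmapped)
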