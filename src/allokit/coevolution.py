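"""Conservation and coevolution scoring of alignment columns.

Per-column Kullback–Leibler (KL) conservation against database background
frequencies, pairwise mutual information (MI) between columns with optional
average-product correction (APC) and column-shuffle z-scoring, the
cumulative per-column score cMI (sum of above-threshold MI), and the
structure-aware proximity score pMI (neighborhood mean of cMI within a
heavy-atom distance cutoff).

All information quantities use natural logarithms (nats).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Optional

import numpy as np
import pandas as pd

from ._tables import AMINO_ACIDS, BACKGROUND_FREQUENCIES, GAP_CHARS
from .structure import ContactMap, StructureModel

# Symbol encoding: 0..19 amino acids, 20 = gap/unknown
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_GAP_CODE = 20

DEFAULT_MI_THRESHOLD = 6.5      # applied to z-scored, APC-corrected MI
DEFAULT_PROXIMITY_CUTOFF = 5.0  # Angstrom, heavy-atom minimum distance


class AllGapColumnError(ValueError):
    pass


class MappingQualityError(ValueError):
    pass


@dataclass
class Alignment:
    """A multiple sequence alignment over the 20 amino acids plus gaps."""

    sequences: list[str]
    ids: list[str]

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def encoded(self) -> np.ndarray:
        """(N, L) integer matrix; 20 encodes gap or non-standard symbol."""
        enc = np.full((self.n_sequences, self.length), _GAP_CODE,
                      dtype=np.int8)
        for r, seq in enumerate(self.sequences):
            for c, ch in enumerate(seq):
                enc[r, c] = _AA_INDEX.get(ch, _GAP_CODE)
        return enc

    @classmethod
    def from_fasta(cls, source) -> "Alignment":
        from Bio import AlignIO
        handle = StringIO(source) if isinstance(source, str) and \
            source.lstrip().startswith(">") else source
        aln = AlignIO.read(handle, "fasta")
        return cls([str(r.seq) for r in aln], [r.id for r in aln])

    @classmethod
    def from_stockholm(cls, source) -> "Alignment":
        from Bio import AlignIO
        handle = StringIO(source) if isinstance(source, str) and \
            "\n" in source else source
        aln = AlignIO.read(handle, "stockholm")
        return cls([str(r.seq) for r in aln], [r.id for r in aln])


def load_background_frequencies(source=None) -> dict:
    """Background amino-acid frequencies; default is the built-in
    database-wide table, overridable by a two-column TSV (aa, frequency)."""
    if source is None:
        return dict(BACKGROUND_FREQUENCIES)
    df = pd.read_csv(source, sep="\t", header=None, names=["aa", "freq"],
                     comment="#")
    q = {str(r.aa).upper(): float(r.freq) for r in df.itertuples()}
    total = sum(q.values())
    if total <= 0:
        raise ValueError("background frequencies must be positive")
    return {aa: v / total for aa, v in q.items()}


def column_frequencies(aln: Alignment, col: int):
    """Amino-acid frequencies over non-gap symbols of one column, plus the
    gap fraction.  Raises on an all-gap column."""
    if not 0 <= col < aln.length:
        raise IndexError(f"column {col} out of range 0..{aln.length - 1}")
    codes = aln.encoded()[:, col]
    non_gap = codes[codes != _GAP_CODE]
    gap_fraction = 1.0 - non_gap.size / codes.size
    if non_gap.size == 0:
        raise AllGapColumnError(f"column {col} contains only gaps")
    counts = np.bincount(non_gap, minlength=20)
    freqs = {AMINO_ACIDS[i]: counts[i] / non_gap.size
             for i in range(20) if counts[i] > 0}
    return freqs, gap_fraction


@dataclass
class ConservationProfile:
    kl_score: np.ndarray            # (L,)
    gap_fraction: np.ndarray        # (L,)
    unreliable: np.ndarray          # (L,) bool: gap fraction above max

    @property
    def length(self) -> int:
        return self.kl_score.size


def kl_conservation(aln: Alignment, background: Optional[dict] = None,
                    max_gap_fraction: float = 0.5) -> ConservationProfile:
    """Per-column KL divergence of observed amino-acid frequencies from
    background: score_c = sum_a P(a) ln(P(a)/Q(a)), non-negative by the
    Gibbs inequality.  Columns gappier than ``max_gap_fraction`` are scored
    but flagged unreliable; all-gap columns score NaN.
    """
    bg = background if background is not None else dict(BACKGROUND_FREQUENCIES)
    enc = aln.encoded()
    L = aln.length
    scores = np.full(L, np.nan)
    gaps = np.zeros(L)
    for c in range(L):
        codes = enc[:, c]
        non_gap = codes[codes != _GAP_CODE]
        gaps[c] = 1.0 - non_gap.size / codes.size
        if non_gap.size == 0:
            continue
        counts = np.bincount(non_gap, minlength=20).astype(float)
        p = counts / counts.sum()
        s = 0.0
        for i in np.flatnonzero(p):
            aa = AMINO_ACIDS[i]
            if aa not in bg:
                raise ValueError(f"background table lacks amino acid {aa!r}")
            s += p[i] * np.log(p[i] / bg[aa])
        scores[c] = s
    unreliable = gaps > max_gap_fraction
    return ConservationProfile(kl_score=scores, gap_fraction=gaps,
                               unreliable=unreliable)


@dataclass
class MIMatrix:
    """L x L symmetric mutual-information matrix in nats.

    The diagonal and pairs with too few joint observations are NaN-masked.
    ``values`` holds the requested variant (raw / apc / zscore); ``raw`` is
    always retained.
    """

    values: np.ndarray
    raw: np.ndarray
    correction: str
    min_joint_observations: int

    @property
    def length(self) -> int:
        return self.values.shape[0]


def _pair_mi_and_count(enc: np.ndarray, i: int, j: int):
    """Raw MI of columns i, j over pairwise-complete (both non-gap) rows."""
    ci, cj = enc[:, i], enc[:, j]
    ok = (ci != _GAP_CODE) & (cj != _GAP_CODE)
    n = int(ok.sum())
    if n == 0:
        return np.nan, 0
    joint = np.bincount(ci[ok].astype(np.int64) * 21 + cj[ok],
                        minlength=21 * 21).reshape(21, 21)[:20, :20]
    p = joint / n
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(pi, pj)
    mi = float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))
    return max(mi, 0.0), n


def mutual_information_matrix(aln: Alignment, correction: str = "zscore",
                              min_joint_observations: int = 10,
                              n_shuffles: int = 50,
                              seed: int = 0) -> MIMatrix:
    """Pairwise column MI with optional APC correction and z-scoring.

    Raw MI uses pairwise-complete observations (rows non-gapped at both
    columns).  APC subtracts MI_i.*MI_.j/MI_.. computed over unmasked
    off-diagonal entries.  ``zscore`` standardizes the APC-corrected matrix
    against a null obtained by independently permuting every column
    (``n_shuffles`` times, seeded), which preserves column compositions but
    destroys covariation.
    """
    if correction not in ("raw", "apc", "zscore"):
        raise ValueError(f"unknown correction {correction!r}")
    enc = aln.encoded()
    L = aln.length
    raw = _mi_matrix_from_encoding(enc, min_joint_observations)

    if correction == "raw":
        values = raw.copy()
    elif correction == "apc":
        values = _apply_apc(raw)
    else:
        rng = np.random.default_rng(seed)
        observed = _apply_apc(raw)
        null = np.empty((n_shuffles, L, L))
        for s in range(n_shuffles):
            shuffled = np.empty_like(enc)
            for c in range(L):
                shuffled[:, c] = enc[rng.permutation(enc.shape[0]), c]
            null[s] = _apply_apc(
                _mi_matrix_from_encoding(shuffled, min_joint_observations))
        import warnings as _warnings
        with _warnings.catch_warnings():
            # masked pairs are all-NaN across the null stack by design
            _warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(null, axis=0)
            sd = np.nanstd(null, axis=0, ddof=1)
        sd[sd < 1e-12] = 1e-12
        values = (observed - mu) / sd
    return MIMatrix(values=values, raw=raw, correction=correction,
                    min_joint_observations=min_joint_observations)


def _mi_matrix_from_encoding(enc: np.ndarray, min_obs: int) -> np.ndarray:
    L = enc.shape[1]
    out = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(i + 1, L):
            mi, n = _pair_mi_and_count(enc, i, j)
            if n < min_obs:
                continue
            out[i, j] = out[j, i] = mi
    return out


def _apply_apc(mi: np.ndarray) -> np.ndarray:
    """Average-product correction over unmasked off-diagonal entries."""
    valid = ~np.isnan(mi)
    if not valid.any():
        return mi.copy()
    col_mean = np.nanmean(np.where(valid, mi, np.nan), axis=0)
    overall = np.nanmean(mi[valid])
    if overall == 0:
        return mi.copy()
    apc = np.outer(col_mean, col_mean) / overall
    out = mi - apc
    out[~valid] = np.nan
    return out


def cumulative_mi(mi: MIMatrix, threshold: float = DEFAULT_MI_THRESHOLD
                  ) -> np.ndarray:
    """Per-column cMI: sum of MI values strictly above ``threshold`` over
    the pairs the column participates in; masked entries excluded."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = mi.values.copy()
    vals[np.isnan(vals)] = -np.inf
    keep = vals > threshold
    contrib = np.where(keep, vals, 0.0)
    return contrib.sum(axis=1)


@dataclass
class ColumnStructureMap:
    """Injective map from alignment columns to structure residue indices."""

    column_to_residue: dict     # col -> residue index (0-based, model order)
    residue_to_column: dict
    identity: float

    def mapped_columns(self) -> list[int]:
        return sorted(self.column_to_residue)


def map_columns_to_residues(aln: Alignment, model: StructureModel,
                            query_id: str, chain_id: Optional[str] = None,
                            min_identity: float = 0.9) -> ColumnStructureMap:
    """Align the query sequence's ungapped positions to the structure's
    residue sequence by global alignment; unmatched columns are masked.

    When ``chain_id`` is given, columns map into that chain's residues;
    otherwise the full ordered residue list is used.
    """
    try:
        qrow = aln.ids.index(query_id)
    except ValueError:
        raise KeyError(f"query id {query_id!r} not in alignment") from None
    qseq = aln.sequences[qrow]
    q_cols = [c for c, ch in enumerate(qseq) if ch not in GAP_CHARS
              and ch != "."]
    q_ungapped = "".join(qseq[c] for c in q_cols)

    if chain_id is None:
        target_idx = list(range(model.n_residues))
    else:
        target_idx = [i for i, r in enumerate(model.residues)
                      if r[0] == chain_id]
    sseq = "".join(model.sequence()[i] for i in target_idx)

    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(q_ungapped, sseq)[0]

    col_to_res: dict[int, int] = {}
    matches = 0
    aligned_pairs = 0
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        for off in range(qe - qs):
            qpos, tpos = qs + off, ts + off
            col_to_res[q_cols[qpos]] = target_idx[tpos]
            aligned_pairs += 1
            if q_ungapped[qpos] == sseq[tpos]:
                matches += 1
    identity = matches / aligned_pairs if aligned_pairs else 0.0
    if identity < min_identity:
        raise MappingQualityError(
            f"query/structure identity {identity:.2f} below the "
            f"{min_identity:.2f} floor")
    res_to_col = {r: c for c, r in col_to_res.items()}
    return ColumnStructureMap(column_to_residue=col_to_res,
                              residue_to_column=res_to_col,
                              identity=identity)


def residue_cmi(cmi: np.ndarray, colmaps, n_residues: int) -> np.ndarray:
    """Project per-column cMI into residue index space through one or more
    column->residue maps (a homodimer maps each protomer independently)."""
    if isinstance(colmaps, ColumnStructureMap):
        colmaps = [colmaps]
    out = np.full(n_residues, np.nan)
    for cm in colmaps:
        for col, res in cm.column_to_residue.items():
            if col < cmi.size:
                out[res] = cmi[col]
    return out


def proximity_mi_from_residue_cmi(per_res_cmi: np.ndarray,
                                  contacts: ContactMap) -> np.ndarray:
    """pMI in residue space: mean cMI over {residue} + structural
    neighbors; unmapped neighbors drop out of the mean."""
    n = contacts.n_residues
    out = np.full(n, np.nan)
    for r in range(n):
        if np.isnan(per_res_cmi[r]):
            continue
        hood = [r] + list(contacts.neighbors(r))
        vals = per_res_cmi[hood]
        vals = vals[~np.isnan(vals)]
        out[r] = vals.mean() if vals.size else np.nan
    return out


def proximity_mi(cmi: np.ndarray, contacts: ContactMap,
                 colmap) -> np.ndarray:
    """Per-residue pMI: mean cMI over the residue itself plus its structural
    neighbors (heavy-atom contacts), in structure residue index space.

    Residues without a mapped alignment column are NaN; unmapped neighbors
    drop out of the mean.  Self-inclusion keeps isolated residues defined.
    ``colmap`` may be a single map or a list (one per protomer).
    """
    per_res = residue_cmi(cmi, colmap, contacts.n_residues)
    return proximity_mi_from_residue_cmi(per_res, contacts)


def profile_table(model: StructureModel, colmap: ColumnStructureMap,
                  kl: ConservationProfile, cmi: np.ndarray,
                  pmi: np.ndarray) -> pd.DataFrame:
    """Per-residue profile table (chain, resnum, kl, cmi, pmi) for export."""
    rows = []
    for ridx, res in enumerate(model.residues):
        col = colmap.residue_to_column.get(ridx)
        rows.append({
            "chain": res[0], "resnum": res[1],
            "kl": kl.kl_score[col] if col is not None else np.nan,
            "cmi": cmi[col] if col is not None else np.nan,
            "pmi": pmi[ridx],
        })
    return pd.DataFrame(rows)
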