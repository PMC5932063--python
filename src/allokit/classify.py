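"""Functional-role assignment for annotated PTM sites.

Integrates the per-residue profiles computed upstream: a site is flagged
*conserved* when its column's KL conservation score is markedly above the
alignment average (mean + k.SD, k = 1 by default); roles are assigned
from the dynamics profiles — *effector* (high PRS effector z-score),
*sensor* (high PRS sensor z-score), *hinge* (near a slow-mode local
minimum), *carrier* (in a slow-mode local-maximum region or the top
sensor quartile).  Roles are non-exclusive sets: a hinge can also be an
effector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coevolution import ConservationProfile, ColumnStructureMap
from .dynamics import SlowModeProfile
from .prs import PRSProfile

DEFAULT_CONSERVATION_K = 1.0
DEFAULT_EFFECTOR_Z = 1.5
DEFAULT_SENSOR_Z = 1.5
DEFAULT_HINGE_WINDOW = 2


@dataclass
class ConservedPTMSet:
    conserved_indices: np.ndarray     # residue indices flagged conserved
    unknown_indices: np.ndarray       # sites without a mapped column
    kl_threshold: float
    site_kl: dict                     # residue index -> KL score


def conserved_ptms(cons: ConservationProfile, colmap: ColumnStructureMap,
                   site_indices: Sequence[int],
                   k_sd: float = DEFAULT_CONSERVATION_K) -> ConservedPTMSet:
    """Flag PTM sites whose column KL score exceeds mean + k_sd * SD of
    all scored columns.  Sites without a mapped alignment column are
    reported unknown and excluded from the conserved set."""
    scores = cons.kl_score[~np.isnan(cons.kl_score)]
    if scores.size == 0:
        raise ValueError("conservation profile has no scored columns")
    threshold = float(scores.mean() + k_sd * scores.std())
    conserved, unknown = [], []
    site_kl = {}
    for r in site_indices:
        col = colmap.residue_to_column.get(int(r))
        if col is None or np.isnan(cons.kl_score[col]):
            unknown.append(int(r))
            continue
        site_kl[int(r)] = float(cons.kl_score[col])
        if cons.kl_score[col] > threshold:
            conserved.append(int(r))
    return ConservedPTMSet(
        conserved_indices=np.asarray(sorted(conserved), dtype=int),
        unknown_indices=np.asarray(sorted(unknown), dtype=int),
        kl_threshold=threshold, site_kl=site_kl)


def classify_roles(sites: Sequence[int],
                   effector: PRSProfile, sensor: PRSProfile,
                   slow_modes: SlowModeProfile,
                   conserved: Optional[ConservedPTMSet] = None,
                   z_eff: float = DEFAULT_EFFECTOR_Z,
                   z_sen: float = DEFAULT_SENSOR_Z,
                   hinge_window: int = DEFAULT_HINGE_WINDOW) -> pd.DataFrame:
    """Assign role sets to PTM sites from the PRS and slow-mode profiles.

    effector: PRS effector z-score > z_eff; sensor: PRS sensor z-score >
    z_sen; hinge: within ``hinge_window`` residues of a slow-mode local
    minimum; carrier: within the window of a slow-mode local maximum or in
    the top sensor quartile.  Returns one row per site with every
    supporting score, so assignments are reproducible from the table.
    """
    n = effector.values.size
    if sensor.values.size != n or slow_modes.profile.size != n:
        raise ValueError("profiles disagree on residue count")
    sensor_q75 = float(np.percentile(sensor.values, 75.0))
    rows = []
    for r in sites:
        r = int(r)
        roles = set()
        if effector.zscores[r] > z_eff:
            roles.add("effector")
        if sensor.zscores[r] > z_sen:
            roles.add("sensor")
        near_min = bool(slow_modes.minima.size and
                        np.min(np.abs(slow_modes.minima - r))
                        <= hinge_window)
        near_max = bool(slow_modes.maxima.size and
                        np.min(np.abs(slow_modes.maxima - r))
                        <= hinge_window)
        if near_min:
            roles.add("hinge")
        if near_max or sensor.values[r] >= sensor_q75:
            roles.add("carrier")
        rows.append({
            "residue_index": r,
            "conserved": bool(conserved is not None and
                              r in conserved.conserved_indices),
            "roles": ",".join(sorted(roles)) if roles else "none",
            "effector_z": float(effector.zscores[r]),
            "sensor_z": float(sensor.zscores[r]),
            "slow_mode": float(slow_modes.profile[r]),
            "near_slow_minimum": near_min,
            "near_slow_maximum": near_max,
            "kl": (conserved.site_kl.get(r, np.nan)
                   if conserved is not None else np.nan),
        })
    columns = ["residue_index", "conserved", "roles", "effector_z",
               "sensor_z", "slow_mode", "near_slow_minimum",
               "near_slow_maximum", "kl"]
    return pd.DataFrame(rows, columns=columns)


def summarize(assignments: pd.DataFrame, metadata: dict,
              extra_scores: Optional[dict] = None) -> dict:
    """Machine-readable report: one record per PTM site with every score,
    plus run metadata (seeds, thresholds, versions)."""
    table = assignments.copy()
    if extra_scores:
        for name, values in extra_scores.items():
            table[name] = [values[int(r)] if int(r) < len(values) else None
                           for r in table["residue_index"]]
    return {
        "sites": table.to_dict(orient="records"),
        "n_sites": int(len(table)),
        "metadata": dict(metadata),
    }
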