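"""End-to-end orchestration: structure -> (coevolution | dynamics) ->
profiles -> network -> PTM role classification, with reproducibility
metadata.

Two input modes share the same stage code: *synthetic* mode generates the
toy homodimer study (structure, alignment, PTM table, planted covariance)
from one master seed, and *file* mode consumes a PDB structure, an
alignment, and a PTM TSV, generating the conformational ensemble from the
elastic-network surrogate.  All stage randomness derives from the master
seed; every threshold defaults to its standard value (MI z > 6.5,
proximity 5 A, R_MI > 0.5, 250 PRS forces).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classify as _classify
from . import coevolution as _coevo
from . import dynamics as _dyn
from . import fri as _fri
from . import network as _net
from . import prs as _prs
from . import surface as _surf
from . import synth as _synth
from . import structure as _struct

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every stage parameter with its standard default."""

    # inputs (file mode); synthetic mode ignores them
    structure_path: Optional[str] = None
    alignment_path: Optional[str] = None
    ptm_table_path: Optional[str] = None
    query_id: str = "query"
    synthetic: bool = True

    # synthetic study conditions
    beads_per_domain: int = 10
    msa_sequences: int = 200
    msa_coupling: float = 0.9
    msa_conservation_level: float = 0.95
    n_frames: int = 400
    n_ensembles: int = 2

    # stage thresholds (printed defaults)
    mi_threshold: float = 6.5          # on z-scored, APC-corrected MI
    mi_correction: str = "zscore"
    mi_shuffles: int = 30
    proximity_cutoff: float = 5.0      # A, heavy-atom minimum distance
    rmi_threshold: float = 0.5
    n_forces: int = 250
    enm_cutoff: float = 10.0
    conservation_k: float = 1.0
    effector_z: float = 1.5
    sensor_z: float = 1.5
    hinge_window: int = 2
    k_paths: int = 3
    smooth_window: int = 3

    seed: int = 0
    out_dir: Optional[str] = None

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        directory does not affect results and is excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    model: _struct.StructureModel
    labels: Optional[dict]
    assignments: pd.DataFrame
    report: dict
    profiles: dict = field(default_factory=dict)

    def role_of(self, residue_index: int) -> set:
        row = self.assignments[
            self.assignments["residue_index"] == residue_index]
        if row.empty:
            return set()
        roles = row.iloc[0]["roles"]
        return set() if roles == "none" else set(roles.split(","))


def _stage_seed(master: int, stage: int) -> int:
    return (master * 1_000_003 + stage * 7919) % (2 ** 31 - 1)


def fold_protomers(values: np.ndarray, n: int,
                   warn_threshold: float = 0.2) -> np.ndarray:
    """Average a length-2n dimer profile over its two protomers; warn when
    the protomers deviate by more than ``warn_threshold`` relative."""
    a, b = values[:n], values[n:2 * n]
    scale = max(np.nanmean(np.abs(a)), np.nanmean(np.abs(b)), 1e-12)
    rel = np.nanmean(np.abs(a - b)) / scale
    if rel > warn_threshold:
        log.warning("protomer profiles deviate by %.0f%% — dimer symmetry "
                    "is degraded", 100 * rel)
    return 0.5 * (a + b)


def _zscore_profile(values: np.ndarray, kind: str,
                    peak_z: float) -> _prs.PRSProfile:
    sd = values.std()
    z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    peaks = _prs._pick_peaks(z, peak_z)
    return _prs.PRSProfile(values=values, kind=kind, peaks=peaks, zscores=z)


def run_full_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute every stage in dependency order and assemble the report.

    Missing alignment input degrades gracefully: coevolution-dependent
    outputs are skipped and the residue network is built in pure-dynamics
    mode.
    """
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: structure + annotations -------------------------------
    labels = None
    truth_msa = None
    aln = None
    if cfg.synthetic:
        spec = _synth.ToyDimerSpec(beads_per_domain=cfg.beads_per_domain,
                                   seed=_stage_seed(cfg.seed, 1))
        model, labels = _synth.make_toy_dimer(spec)
        n_chain = labels["n_per_protomer"]
        conserved_cols = (labels["hinge"], labels["effector"])
        avoid = set(conserved_cols)
        free = [c for c in range(n_chain) if c not in avoid]
        pairs = tuple((free[k], free[len(free) // 2 + k]) for k in range(3))
        aln, truth_msa = _synth.make_synthetic_msa(_synth.SyntheticMSASpec(
            n_sequences=cfg.msa_sequences, length=n_chain,
            conserved_columns=conserved_cols,
            conservation_level=cfg.msa_conservation_level,
            coevolving_pairs=pairs, coupling=cfg.msa_coupling,
            seed=_stage_seed(cfg.seed, 2)))
        # the structure's chain-A sequence must equal the query row
        model, labels = _synth.make_toy_dimer(spec, sequence=aln.sequences[0])
        ptm_table = _synth.make_ptm_table(model, labels, seed=_stage_seed(
            cfg.seed, 3))
    else:
        if cfg.structure_path is None:
            raise ValueError("file mode needs a structure path")
        model = _struct.load_structure(Path(cfg.structure_path).read_text())
        if cfg.alignment_path:
            text = Path(cfg.alignment_path).read_text()
            reader = (_coevo.Alignment.from_stockholm
                      if text.startswith("# STOCKHOLM")
                      else _coevo.Alignment.from_fasta)
            aln = reader(text)
        ptm_table = (_struct.read_ptm_table(cfg.ptm_table_path)
                     if cfg.ptm_table_path else None)

    trace = _struct.extract_ca_trace(model)
    n_res = model.n_residues
    coarse = all(len(model.residue_atoms(i)) == 1 for i in range(n_res))
    contact_metric = "ca-ca" if coarse else "heavy-atom-min"
    contact_cutoff = (_dyn.DMD_CUTOFF if coarse else cfg.proximity_cutoff)
    contacts = _struct.compute_contact_map(model, contact_cutoff,
                                           contact_metric)
    if out:
        (out / "structure").mkdir(exist_ok=True)
        (out / "structure" / "model.pdb").write_text(
            _struct.to_pdb_text(model))

    # ---- stage 2: coevolution -------------------------------------------
    kl = cmi = pmi = None
    colmaps = []
    if aln is not None:
        kl = _coevo.kl_conservation(aln)
        mi = _coevo.mutual_information_matrix(
            aln, correction=cfg.mi_correction, n_shuffles=cfg.mi_shuffles,
            seed=_stage_seed(cfg.seed, 4))
        cmi = _coevo.cumulative_mi(mi, cfg.mi_threshold)
        for chain in model.chains():
            colmaps.append(_coevo.map_columns_to_residues(
                aln, model, cfg.query_id, chain_id=chain))
        per_res_cmi = _coevo.residue_cmi(cmi, colmaps, n_res)
        pmi = _coevo.proximity_mi_from_residue_cmi(per_res_cmi, contacts)
        if out:
            (out / "coevolution").mkdir(exist_ok=True)
            _coevo.profile_table(model, colmaps[0], kl, cmi, pmi).to_csv(
                out / "coevolution" / "profiles.tsv", sep="\t", index=False)
    else:
        log.warning("no alignment supplied: conservation and coevolution "
                    "outputs skipped; network runs in pure-dynamics mode")

    # ---- stage 3: conformational ensembles ------------------------------
    ensembles = []
    if cfg.synthetic:
        cov_true = _synth.make_dimer_covariance(model, labels,
                                                spring_cutoff=cfg.enm_cutoff)
        for e in range(cfg.n_ensembles):
            ensembles.append(_synth.make_gaussian_trajectory(
                cov_true, cfg.n_frames, _stage_seed(cfg.seed, 10 + e)))
    else:
        for e in range(cfg.n_ensembles):
            ensembles.append(_dyn.sample_enm_ensemble(
                trace, spring_cutoff=cfg.enm_cutoff, n_frames=cfg.n_frames,
                seed=_stage_seed(cfg.seed, 10 + e)))
    cov = _dyn.compute_covariance(ensembles[0], superpose=not cfg.synthetic)

    # ---- stage 4: per-residue profiles ----------------------------------
    mobility = _dyn.compute_bfactors(cov)
    chain_sizes = [sum(1 for r in model.residues if r[0] == c)
                   for c in model.chains()]
    bounds = np.cumsum([0] + chain_sizes)
    segments = [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
    slow = _dyn.pca_slow_modes(cov, smooth_window=cfg.smooth_window,
                               segments=segments)
    response = _prs.prs_scan(cov, n_forces=cfg.n_forces,
                             seed=_stage_seed(cfg.seed, 20))
    # effector/sensor asymmetry only exists on the self-response-normalized
    # map (the raw linear-response matrix is symmetric)
    response_n = _prs.normalize_prs(response)
    effector = _prs.effector_profile(response_n, peak_z=cfg.effector_z)
    sensor = _prs.sensor_profile(response_n, peak_z=cfg.sensor_z)
    flex = _fri.flexibility_profile(trace.positions,
                                    ensemble=ensembles[0])
    sasa = _surf.compute_sasa(model)
    rsa = None if sasa.coarse else _surf.relative_accessibility(model, sasa)
    rd = _surf.residue_depth(model, sasa)
    if out:
        (out / "profiles").mkdir(exist_ok=True)
        pd.DataFrame({
            "bfactor": mobility.bfactor, "msf": mobility.msf,
            "slow_mode": slow.profile, "effector": effector.values,
            "sensor": sensor.values, "flexibility": flex.flexibility,
            "sasa": sasa.residue_area, "rd_mean": rd.depth_mean,
        }).to_csv(out / "profiles" / "profiles.tsv", sep="\t",
                  index_label="residue_index")

    # ---- stage 5: residue network ---------------------------------------
    rmi = _net.generalized_correlation(ensembles, pmi=pmi,
                                       superpose=not cfg.synthetic)
    graph = _net.build_network(rmi, contacts=contacts,
                               threshold=cfg.rmi_threshold)
    pathset = None
    if effector.peaks.size and sensor.peaks.size:
        pathset = _net.communication_pathways(
            graph, [int(p) for p in effector.peaks],
            [int(p) for p in sensor.peaks], k_paths=cfg.k_paths)
    if out:
        (out / "network").mkdir(exist_ok=True)
        _net.export_edge_list(graph).to_csv(
            out / "network" / "edges.tsv", sep="\t", index=False)
        if pathset is not None:
            pathset.to_table().to_csv(out / "network" / "paths.tsv",
                                      sep="\t", index=False)

    # ---- stage 6: PTM classification ------------------------------------
    assignments = pd.DataFrame()
    conserved_set = None
    mapping = None
    if ptm_table is not None:
        mapping = _struct.map_ptm_sites(ptm_table, model)
        sites = [int(r) for r in mapping.residue_indices]
        if kl is not None and colmaps:
            conserved_set = _classify.conserved_ptms(
                kl, colmaps[0], sites, k_sd=cfg.conservation_k)
        # homodimer: average profiles across protomers before classifying
        if len(segments) == 2 and chain_sizes[0] == chain_sizes[1]:
            n = chain_sizes[0]
            eff_f = _zscore_profile(fold_protomers(effector.values, n),
                                    "effector", cfg.effector_z)
            sen_f = _zscore_profile(fold_protomers(sensor.values, n),
                                    "sensor", cfg.sensor_z)
            slow_f = _dyn.slow_mode_profile_from_values(
                fold_protomers(slow.profile, n),
                smooth_window=cfg.smooth_window)
            sites_f = sorted({s % n for s in sites})
            assignments = _classify.classify_roles(
                sites_f, eff_f, sen_f, slow_f, conserved_set,
                z_eff=cfg.effector_z, z_sen=cfg.sensor_z,
                hinge_window=cfg.hinge_window)
        else:
            assignments = _classify.classify_roles(
                sites, effector, sensor, slow, conserved_set,
                z_eff=cfg.effector_z, z_sen=cfg.sensor_z,
                hinge_window=cfg.hinge_window)

    metadata = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "thresholds": {
            "mi": cfg.mi_threshold, "proximity": cfg.proximity_cutoff,
            "rmi": cfg.rmi_threshold, "forces": cfg.n_forces,
            "conservation_k": cfg.conservation_k,
            "effector_z": cfg.effector_z, "sensor_z": cfg.sensor_z,
        },
        "n_residues": n_res,
        "network_mode": "composite" if pmi is not None else "pure-dynamics",
        "ensemble_source": ensembles[0].source,
    }
    report = _classify.summarize(assignments, metadata)
    if labels is not None:
        report["ground_truth"] = {
            k: labels[k] for k in ("hinge", "effector", "sensor_tail")}
    if out:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True,
                       default=_synth._json_default) + "\n")
        if not assignments.empty:
            assignments.to_csv(out / "report.tsv", sep="\t", index=False)
        _write_resolved_config(cfg, out / "config.toml")

    profiles = {
        "bfactor": mobility.bfactor, "msf": mobility.msf,
        "slow": slow, "effector": effector, "sensor": sensor,
        "flexibility": flex.flexibility, "pmi": pmi, "kl": kl,
        "covariance": cov, "graph": graph, "pathset": pathset,
        "contacts": contacts, "rmi": rmi, "rsa": rsa, "rd": rd,
        "mapping": mapping,
    }
    return PipelineResult(config=cfg, model=model, labels=labels,
                          assignments=assignments, report=report,
                          profiles=profiles)


def _write_resolved_config(cfg: RunConfig, path: Path) -> None:
    lines = ["[run]"]
    for key, value in sorted(asdict(cfg).items()):
        if value is None:
            continue
        if isinstance(value, bool):
            rendered = "true" if value else "false"
        elif isinstance(value, (int, float)):
            rendered = repr(value)
        else:
            rendered = json.dumps(str(value))
        lines.append(f"{key} = {rendered}")
    path.write_text("\n".join(lines) + "\n")


def load_config(path, **overrides) -> RunConfig:
    """Read a TOML config ([run] table) and apply keyword overrides."""
    import tomllib
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    table = data.get("run", data)
    known = {f for f in RunConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in table.items() if k in known}
    unknown = set(table) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**kwargs)
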