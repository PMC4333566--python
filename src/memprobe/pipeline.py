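"""End-to-end orchestration: conservation → topology → trajectory metrics →
pocket statistics → assay fitting, from a single config.

Every stage can run on user-supplied input files or, by default, on the
synthetic study bundle whose generator parameters are fixed in
``DEFAULT_CONFIG`` (758-row alignment, 12-helix topology, 3-replica helical
trajectories, 21% / 35% contact and salt-bridge constructions, 65.58 Å²
membrane boxes, wildtype/mutant competition curves). The run is fully
deterministic given the seed: the summary JSON contains no timestamps and is
byte-identical across reruns.
"""
from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .alignment import (
    ConservationConfig,
    conservation_profile,
    read_alignment,
    write_alignment_fasta,
    write_profile_tsv,
)
from .assay import fit_experiments, read_dose_response_csv, write_summary_csv
from .pocket import CavityConfig, area_per_lipid, cavity_volume, contact_occupancy, salt_bridge_trace
from .pdbio import read_trajectory, write_trajectory
from .secondary import helicity_profile
from .superpose import plateau_stats, rmsd_series
from .synthetic import (
    HelixSpec,
    MsaSpec,
    derive_seed,
    gen_contact_trace,
    gen_dose_response,
    gen_helix_trajectory,
    gen_lipid_boxes,
    gen_msa,
    gen_salt_bridge_trace,
    gen_spherical_pocket,
    gen_topology_tracks,
)
from .topology import consensus, read_tracks, write_segments_tsv, write_tracks

__all__ = ["DEFAULT_CONFIG", "PipelineStageError", "load_config", "run_pipeline"]

logger = logging.getLogger("memprobe.pipeline")

# Hydrophobic-conservation targets used to parameterise the synthetic MSA:
# labelled binding-site residues with their class frequencies (fractions).
_LABELLED_RESIDUES = {
    "C297": 0.355,
    "W300": 0.939,
    "Y462": 0.861,
    "W666": 0.825,
    "W454": 0.798,
    "F688": 0.881,
    "V296": 0.960,
    "F280": 0.802,
    "L284": 0.963,
    "L296": 0.763,
}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": {
        "conservation": True,
        "topology": True,
        "trajectory": True,
        "pocket": True,
        "assay": True,
    },
    "conservation": {
        "alignment_path": None,  # None -> synthesise from msa spec below
        "format": None,
        "reference_id": "reference",
        "residue_class": "MAVILCYFW",
        "gap_policy": "all_rows",
        "msa": {"n_rows": 758, "length": 40, "class_freq": 0.8, "gap_prob": 0.0},
        # labelled positions (1-based) -> generator class frequency
        "labelled_residues": _LABELLED_RESIDUES,
    },
    "topology": {
        "tracks_path": None,
        "threshold": 0.5,
        "min_len": 15,
        "max_gap": 3,
        "expected_count": 12,
        "synthetic": {
            "n_residues": 313,
            "segment_len": 21,
            "loop_len": 5,
            "n_segments": 12,
            "n_predictors": 4,
            "flip_prob": 0.03,
        },
    },
    "trajectory": {
        "paths": None,  # list of multi-model PDB files, one per replica
        "helix": {
            "n_residues": 30,
            "n_frames": 120,
            "n_replicas": 3,
            "unwind": {8: 0.5, 20: 0.2},
        },
        "selection": None,  # residue numbers for the RMSD; None -> all but termini
        "helical_codes": ["H"],
        "helicity_criterion": 0.60,
        "plateau_window_fraction": 0.5,
    },
    "pocket": {
        "cavity": {
            "grid_spacing": 1.0,
            "probe_radius": 1.4,
            "radius": 8.0,
            "n_shell_atoms": 300,
        },
        "contact": {"cutoff": 6.0, "target_fraction": 0.21, "n_frames": 100},
        "salt_bridge": {"threshold": 3.5, "occupancy": 0.35, "n_frames": 100},
        "lipids": {
            "area_per_lipid": 65.58,
            "n_lipids_total": 200,
            "jitter_sd": 0.82,
            "n_frames": 100,
        },
    },
    "assay": {
        "csv_path": None,
        "n_experiments": 3,
        "noise_sd": 0.01,
        "compounds": {
            # generator truths for the competition curves (pIC50, hill);
            # null pIC50 -> flat curve (binding abolished)
            "wildtype": {"pIC50": 7.1, "hill": -1.0},
            "W454A": {"pIC50": 6.7, "hill": -1.0},
            "D670A": {"pIC50": None, "hill": -1.0},
            "F688A": {"pIC50": 7.1, "hill": -1.0},
        },
    },
}


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML/JSON config file and explicit overrides onto defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if not 0 < cfg["topology"]["threshold"] <= 1:
        raise ValueError("topology.threshold must be in (0, 1]")
    if not 0 <= cfg["trajectory"]["helicity_criterion"] <= 1:
        raise ValueError("trajectory.helicity_criterion must be in [0, 1]")
    if cfg["pocket"]["contact"]["cutoff"] <= 0:
        raise ValueError("pocket.contact.cutoff must be > 0")
    if cfg["pocket"]["salt_bridge"]["threshold"] <= 0:
        raise ValueError("pocket.salt_bridge.threshold must be > 0")
    for key, sub, name in (
        ("conservation", "alignment_path", "alignment"),
        ("topology", "tracks_path", "tracks"),
        ("assay", "csv_path", "assay CSV"),
    ):
        p = cfg[key][sub]
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{name} file not found: {p}")
    paths = cfg["trajectory"]["paths"]
    if paths is not None:
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"trajectory file not found: {p}")


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def _stage_conservation(cfg: dict, outdir: Path, seed: int) -> dict:
    c = cfg["conservation"]
    labelled = {str(k): float(v) for k, v in c["labelled_residues"].items()}
    if c["alignment_path"] is not None:
        aln = read_alignment(c["alignment_path"], c["reference_id"], c["format"])
        label_positions = None
    else:
        msa = c["msa"]
        freq = np.full(int(msa["length"]), float(msa["class_freq"]))
        # labelled residues occupy the first columns, in sorted-label order
        labels = sorted(labelled)
        if len(labels) > int(msa["length"]):
            raise ValueError("more labelled residues than alignment columns")
        for i, lab in enumerate(labels):
            freq[i] = labelled[lab]
        spec = MsaSpec(
            n_rows=int(msa["n_rows"]),
            length=int(msa["length"]),
            class_freq=freq,
            gap_prob=float(msa["gap_prob"]),
            seed=derive_seed(seed, "pipeline-msa"),
            reference_id=c["reference_id"],
        )
        aln, _ = gen_msa(spec)
        write_alignment_fasta(aln, outdir / "alignment.fasta")
        label_positions = {lab: i + 1 for i, lab in enumerate(labels)}

    prof = conservation_profile(
        aln,
        ConservationConfig(
            residue_class=frozenset(c["residue_class"]), gap_policy=c["gap_policy"]
        ),
    )
    write_profile_tsv(prof, outdir / "conservation_profile.tsv")
    report = {}
    if label_positions:
        for lab, pos in label_positions.items():
            k = int(np.nonzero(prof.positions == pos)[0][0])
            report[lab] = {
                "position": pos,
                "class_pct": round(float(prof.class_pct[k]), 6),
                "identity_pct": round(float(prof.identity_pct[k]), 6),
                "generator_class_pct": 100.0 * labelled[lab],
            }
    return {
        "n_rows": aln.n_rows,
        "n_positions": len(prof),
        "mean_class_pct": round(float(prof.class_pct.mean()), 6),
        "labelled_residues": report,
    }


def _stage_topology(cfg: dict, outdir: Path, seed: int) -> dict:
    t = cfg["topology"]
    if t["tracks_path"] is not None:
        tracks = read_tracks(t["tracks_path"])
        truth_segments = None
    else:
        s = t["synthetic"]
        seg_len, loop, nseg = int(s["segment_len"]), int(s["loop_len"]), int(s["n_segments"])
        segments, start = [], loop + 1
        for _ in range(nseg):
            segments.append((start, start + seg_len - 1))
            start += seg_len + loop
        tracks, truth = gen_topology_tracks(
            segments,
            int(s["n_residues"]),
            n_predictors=int(s["n_predictors"]),
            flip_prob=float(s["flip_prob"]),
            seed=derive_seed(seed, "pipeline-topology"),
        )
        write_tracks(tracks, outdir / "topology_tracks.tsv")
        truth_segments = truth["segments"]
    topo = consensus(
        tracks,
        threshold=float(t["threshold"]),
        min_len=int(t["min_len"]),
        max_gap=int(t["max_gap"]),
        expected_count=t["expected_count"],
    )
    write_segments_tsv(topo, outdir / "topology_segments.tsv")
    out = {
        "n_segments": topo.n_segments,
        "segments": [[s, e] for s, e in topo.segments],
        "expected_count": t["expected_count"],
    }
    if truth_segments is not None:
        out["true_segments"] = [[s, e] for s, e in truth_segments]
    return out


def _stage_trajectory(cfg: dict, outdir: Path, seed: int) -> dict:
    t = cfg["trajectory"]
    if t["paths"] is not None:
        trajs = [read_trajectory(p) for p in t["paths"]]
        truth = None
    else:
        h = t["helix"]
        spec = HelixSpec(
            n_residues=int(h["n_residues"]),
            n_frames=int(h["n_frames"]),
            n_replicas=int(h["n_replicas"]),
            unwind={int(k): float(v) for k, v in h["unwind"].items()},
            seed=derive_seed(seed, "pipeline-helix"),
        )
        trajs, truth = gen_helix_trajectory(spec)
        write_trajectory(trajs[0], outdir / "trajectory_rep0.pdb")

    n_res = int(trajs[0].frames[0].residue_numbers.max())
    selection = t["selection"] or list(range(2, n_res))
    series = [rmsd_series(tr, selection) for tr in trajs]
    for s in series:
        s.write_csv(outdir / f"rmsd_{s.replica_id}.csv")
    plateau = plateau_stats(series, float(t["plateau_window_fraction"]))

    prof = helicity_profile(trajs, tuple(t["helical_codes"]))
    prof.write_csv(outdir / "helicity_profile.csv")
    criterion = float(t["helicity_criterion"])
    conserved = prof.conserved(criterion)
    out = {
        "n_replicas": len(trajs),
        "rmsd_plateau": {
            "mean_A": round(plateau["mean_A"], 6),
            "sd_A": round(plateau["sd_A"], 6),
            "window_fraction": plateau["window_fraction"],
        },
        "helicity": {
            "criterion": criterion,
            "n_conserved": int(conserved.sum()),
            "n_residues": int(conserved.size),
            "below_criterion_residues": prof.residue_numbers[~conserved].tolist(),
        },
    }
    if truth is not None:
        err = np.abs(prof.mean - truth["mean_fraction"])
        out["helicity"]["max_abs_error_vs_truth"] = round(float(err.max()), 6)
    return out


def _stage_pocket(cfg: dict, outdir: Path, seed: int) -> dict:
    p = cfg["pocket"]
    cav = p["cavity"]
    shell = gen_spherical_pocket(float(cav["radius"]), int(cav["n_shell_atoms"]))
    half = float(cav["radius"]) * 0.75
    volume = cavity_volume(
        shell,
        CavityConfig(
            region=((-half, half), (-half, half), (-half, half)),
            seed_point=(0.0, 0.0, 0.0),
            grid_spacing=float(cav["grid_spacing"]),
            probe_radius=float(cav["probe_radius"]),
        ),
    )

    con = p["contact"]
    ctraj, ctruth = gen_contact_trace(
        n_frames=int(con["n_frames"]),
        target_fraction=float(con["target_fraction"]),
        cutoff=float(con["cutoff"]),
        seed=derive_seed(seed, "pipeline-contact"),
    )
    occ = contact_occupancy(
        ctraj,
        ligand_selection={"resnames": "LIG"},
        residue_set=[ctruth["contact_residue"]],
        cutoff=float(con["cutoff"]),
    )
    occ.write_csv(outdir / "contacts.csv")

    sb = p["salt_bridge"]
    straj, struth = gen_salt_bridge_trace(
        n_frames=int(sb["n_frames"]),
        occupancy=float(sb["occupancy"]),
        threshold=float(sb["threshold"]),
        seed=derive_seed(seed, "pipeline-saltbridge"),
    )
    trace = salt_bridge_trace(
        straj,
        donor_atoms={"resids": 694, "names": ["HZ1", "HZ2", "HZ3"]},
        acceptor_atoms={"resids": 670, "names": ["OD1", "OD2"]},
        threshold=float(sb["threshold"]),
    )
    trace.write_csv(outdir / "salt_bridge.csv")

    lp = p["lipids"]
    ltraj, ltruth = gen_lipid_boxes(
        n_frames=int(lp["n_frames"]),
        area_per_lipid=float(lp["area_per_lipid"]),
        n_lipids_total=int(lp["n_lipids_total"]),
        jitter_sd=float(lp["jitter_sd"]),
        seed=derive_seed(seed, "pipeline-lipids"),
    )
    areas = area_per_lipid(ltraj, int(lp["n_lipids_total"]))
    areas.write_csv(outdir / "lipid_areas.csv")

    return {
        "cavity_volume_A3": round(volume, 6),
        "contact": {
            "residue": int(ctruth["contact_residue"]),
            "fraction": round(float(occ.fractions[0]), 6),
            "target_fraction": ctruth["fraction"],
            "cutoff_A": float(con["cutoff"]),
        },
        "salt_bridge": {
            "occupancy": round(trace.occupancy, 6),
            "mean_A": round(trace.mean, 6),
            "sd_A": round(trace.sd, 6),
            "threshold_A": trace.threshold,
            "target_occupancy": struth["occupancy"],
        },
        "area_per_lipid": {
            "mean_A2": round(areas.mean, 6),
            "sd_A2": round(areas.sd, 6),
            "target_A2": float(lp["area_per_lipid"]),
        },
    }


def _stage_assay(cfg: dict, outdir: Path, seed: int) -> dict:
    a = cfg["assay"]
    if a["csv_path"] is not None:
        by_compound = {"input": read_dose_response_csv(a["csv_path"])}
        truths = {}
    else:
        by_compound, truths = {}, {}
        for compound, pars in a["compounds"].items():
            exps = []
            for k in range(int(a["n_experiments"])):
                if pars["pIC50"] is None:  # binding abolished: flat curve
                    data, _ = gen_dose_response(
                        7.0,
                        hill=pars["hill"],
                        top=100.0,
                        bottom=100.0,
                        noise_sd=float(a["noise_sd"]),
                        seed=derive_seed(seed, f"assay-{compound}-{k}"),
                        experiment_id=f"{compound}-{k}",
                    )
                else:
                    data, _ = gen_dose_response(
                        float(pars["pIC50"]),
                        hill=float(pars["hill"]),
                        noise_sd=float(a["noise_sd"]),
                        seed=derive_seed(seed, f"assay-{compound}-{k}"),
                        experiment_id=f"{compound}-{k}",
                    )
                exps.append(data)
            by_compound[compound] = exps
            truths[compound] = pars["pIC50"]

    fits_json, summaries = {}, {}
    for compound in sorted(by_compound):
        fits, summary = fit_experiments(by_compound[compound])
        if compound in truths:
            summary["generator_pIC50"] = truths[compound]
        summaries[compound] = summary
        fits_json[compound] = [f.to_dict() for f in fits]
    with open(outdir / "assay_fits.json", "w") as fh:
        json.dump(fits_json, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_summary_csv(summaries, outdir / "assay_summary.csv")
    return {
        compound: {
            "mean_pIC50": None
            if s["mean_pIC50"] is None
            else round(s["mean_pIC50"], 6),
            "sd_pIC50": None if s["sd_pIC50"] is None else round(s["sd_pIC50"], 6),
            "n": s["n"],
            "no_inhibition": s["no_inhibition"],
            "generator_pIC50": s.get("generator_pIC50"),
        }
        for compound, s in summaries.items()
    }


_STAGES = {
    "conservation": _stage_conservation,
    "topology": _stage_topology,
    "trajectory": _stage_trajectory,
    "pocket": _stage_pocket,
    "assay": _stage_assay,
}


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Run the enabled stages and write per-stage outputs plus summary.json.

    Stage failures are collected (partial outputs preserved) and re-raised
    as :class:`PipelineStageError` for the first failing stage after all
    stages have been attempted.
    """
    _validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    logger.info(
        "memprobe %s run: seed=%d config_hash=%s", __version__, seed, config_hash(cfg)
    )

    summary: dict[str, Any] = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "stages": {},
    }
    errors: list[PipelineStageError] = []
    for name, fn in _STAGES.items():
        if not cfg["stages"].get(name, True):
            logger.info("stage %s disabled", name)
            continue
        try:
            summary["stages"][name] = fn(cfg, outdir, seed)
            logger.info("stage %s ok", name)
        except Exception as exc:  # noqa: BLE001 — reported per stage
            logger.error("stage %s failed: %s", name, exc)
            errors.append(PipelineStageError(name, exc))
            summary["stages"][name] = {"error": str(exc)}

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if errors:
        raise errors[0]
    return summary
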