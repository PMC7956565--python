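"""Orchestration: run the per-protein characterization stages from one
config document and assemble a reproducible report."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import refdata
from .assays import ldh_activity, residual_activity, viability_ratio
from .cdspec import TwoStateTitration
from .hydro import (
    SECCalibrator, profile_protein, read_proteins_csv, read_standards_csv,
    rs_calibrant, rs_idp, rs_u,
)
from .seqmetrics import phase_region, summarize, summary_row, REPORT_COLUMNS
from .sequences import pairwise_identity, read_cds_fasta, read_fasta
from .synthgen import gen_titration

KNOWN_STAGES = ("sequence", "hydro", "cd", "assays")
KNOWN_TOP_KEYS = set(KNOWN_STAGES) | {"seed"}


class ConfigError(ValueError):
    """Invalid or incomplete characterization config."""


@dataclass
class CharacterizationReport:
    """Per-stage result blocks plus provenance (input hashes, config,
    package version, seed)."""

    blocks: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"blocks": self.blocks, "provenance": self.provenance}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        if "sequence" in self.blocks:
            pd.DataFrame(self.blocks["sequence"]["table"]).to_csv(
                out / "sequence_metrics.csv", index=False
            )
        if "hydro" in self.blocks:
            pd.DataFrame(self.blocks["hydro"]["table"]).to_csv(
                out / "hydrodynamics.csv", index=False
            )
        return out / "report.json"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - KNOWN_TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if not any(k in config for k in KNOWN_STAGES):
        raise ConfigError(f"config must request at least one stage of {KNOWN_STAGES}")
    return config


def _stage_sequence(cfg: dict, hashes: dict) -> dict:
    fasta = Path(cfg["fasta"])
    if not fasta.exists():
        raise ConfigError(f"missing FASTA {fasta}")
    hashes[str(fasta)] = _sha256(fasta)
    seqs = read_cds_fasta(fasta) if cfg.get("cds") else read_fasta(fasta)
    blobs = tuple(cfg.get("kappa_blobs", (5, 6)))
    rows = [summary_row(summarize(s)) for s in seqs]
    block = {"table": rows, "columns": REPORT_COLUMNS, "kappa_blobs": list(blobs)}
    if len(seqs) == 2 and len(seqs[0]) == len(seqs[1]):
        ident, subs = pairwise_identity(seqs[0], seqs[1])
        block["pairwise_identity_percent"] = round(ident, 1)
        block["substitutions"] = [list(s) for s in subs]
    return block


def _stage_hydro(cfg: dict, hashes: dict) -> dict:
    calibrator = None
    block: dict = {}
    if cfg.get("standards"):
        spath = Path(cfg["standards"])
        if not spath.exists():
            raise ConfigError(f"missing standards CSV {spath}")
        hashes[str(spath)] = _sha256(spath)
        calibrator = SECCalibrator().fit(read_standards_csv(spath))
        block["calibration"] = {
            "slope": calibrator.slope_, "intercept": calibrator.intercept_,
            "r2": calibrator.r2_, "ve_range_ml": list(calibrator.ve_range_),
        }
    ppath = Path(cfg["proteins"])
    if not ppath.exists():
        raise ConfigError(f"missing proteins CSV {ppath}")
    hashes[str(ppath)] = _sha256(ppath)
    profiles = read_proteins_csv(ppath, calibrator=calibrator)
    block["table"] = [p.row() for p in profiles]
    block["notes"] = {p.id: list(p.notes) for p in profiles if p.notes}
    return block


def _stage_cd(cfg: dict, hashes: dict, seed) -> dict:
    tpath = Path(cfg["titration"])
    if not tpath.exists():
        raise ConfigError(f"missing titration CSV {tpath}")
    hashes[str(tpath)] = _sha256(tpath)
    df = pd.read_csv(tpath)
    for col in ("concentration", "helix_fraction"):
        if col not in df.columns:
            raise ConfigError("titration CSV needs concentration and helix_fraction columns")
    t_k = float(cfg.get("temperature_c", 20.0)) + 273.15
    est = TwoStateTitration(temperature_k=t_k).fit(
        df["concentration"].to_numpy(), df["helix_fraction"].to_numpy()
    )
    r = est.result_
    return {
        "two_state_fit": {
            "midpoint": r.cm, "m_value": r.m_value, "f_min": r.f_min,
            "f_max": r.f_max, "dg0_kcal_mol": r.dg0, "r2": r.r2,
            "extrapolated": r.extrapolated, "notes": list(r.notes),
        }
    }


def _stage_assays(cfg: dict, hashes: dict) -> dict:
    block: dict = {}
    if cfg.get("ldh"):
        path = Path(cfg["ldh"])
        if not path.exists():
            raise ConfigError(f"missing LDH CSV {path}")
        hashes[str(path)] = _sha256(path)
        df = pd.read_csv(path)
        df["activity"] = ldh_activity(df["dA340_per_min"].to_numpy())
        out = []
        for cond, grp in df.groupby("condition"):
            t0 = grp["time_min"].min()
            base = grp.loc[grp["time_min"] == t0, "activity"].mean()
            mean = grp.groupby("time_min")["activity"].mean()
            out.append({
                "condition": cond,
                "residual_percent": {
                    str(t): round(float(residual_activity(v, base)), 1)
                    for t, v in mean.items()
                },
            })
        block["ldh"] = out
    if cfg.get("viability"):
        path = Path(cfg["viability"])
        if not path.exists():
            raise ConfigError(f"missing viability CSV {path}")
        hashes[str(path)] = _sha256(path)
        df = pd.read_csv(path)
        ref_name = cfg.get("reference")
        ratios = {}
        for strain, grp in df.groupby("strain"):
            stressed = grp.loc[grp["plate_type"] == "stressed", "colonies"]
            control = grp.loc[grp["plate_type"] == "control", "colonies"]
            ratios[strain] = viability_ratio(stressed, control, strain=strain)
        ref = ratios.get(ref_name)
        block["viability"] = [
            {
                "strain": s.strain,
                "viability_percent": round(s.viability_ratio, 1),
                "fold_vs_reference": (
                    None if ref is None else round(s.viability_ratio / ref.viability_ratio, 2)
                ),
            }
            for s in ratios.values()
        ]
    if not block:
        raise ConfigError("assays stage requests neither ldh nor viability input")
    return block


def run_characterize(config) -> CharacterizationReport:
    """Execute the requested stages and return the assembled report.

    Stages are independent; any stage error is raised with its stage name
    attached.
    """
    cfg = _load_config(config)
    hashes: dict[str, str] = {}
    report = CharacterizationReport()
    errors = []
    for stage in KNOWN_STAGES:
        if stage not in cfg:
            continue
        try:
            if stage == "sequence":
                report.blocks[stage] = _stage_sequence(cfg[stage], hashes)
            elif stage == "hydro":
                report.blocks[stage] = _stage_hydro(cfg[stage], hashes)
            elif stage == "cd":
                report.blocks[stage] = _stage_cd(cfg[stage], hashes, cfg.get("seed"))
            elif stage == "assays":
                report.blocks[stage] = _stage_assays(cfg[stage], hashes)
        except Exception as err:  # aggregated with stage context
            errors.append(f"{stage}: {err}")
    if errors:
        raise ConfigError("; ".join(errors))
    report.provenance = {
        "package_version": _version,
        "config": {k: v for k, v in cfg.items()},
        "input_sha256": hashes,
        "seed": cfg.get("seed"),
    }
    return report


# ---------------------------------------------------------------------------
# self-test / regression suite
# ---------------------------------------------------------------------------

def run_regression_suite(seed: int = 1, titration_replicates: int = 25) -> dict:
    """Recompute the analytic reference quantities and a reduced
    Monte-Carlo titration recovery; returns a machine-readable pass/fail
    summary (failures are results, not exceptions)."""
    checks: dict[str, dict] = {}

    def add(name, value, expected, tol):
        checks[name] = {
            "value": float(value), "expected": float(expected), "tol": float(tol),
            "pass": bool(abs(value - expected) <= tol),
        }

    for ref in (refdata.TT_ABA_WDS, refdata.HV_ABA_WDS):
        prof = profile_protein(ref.mm_recombinant, ref.n_recombinant, ref.rs_obs, id=ref.id)
        add(f"{ref.id}.rs_unfolded", round(prof.rs_u, 1), round(rs_u(ref.mm_recombinant), 1), 0.05)
        add(f"{ref.id}.ci", round(prof.ci, 2), ref.ci, 0.005)
        add(f"{ref.id}.ratio_idp", round(prof.ratio_idp, 2), ref.ratio_idp, 0.005)
        add(
            f"{ref.id}.pdr",
            phase_region(ref.count_plus / ref.n_domain, ref.count_minus / ref.n_domain),
            ref.pdr, 0,
        )
    add("rs_idp_83", round(float(rs_idp(83)), 1), 23.6, 0.05)
    add("rs_nf_calibrant_9200", round(float(rs_calibrant(9200)), 1), 16.2, 0.05)

    ref = refdata.TT_ABA_WDS
    grid, curves, _ = gen_titration(
        ref.tfe_midpoint, ref.tfe_m_value, refdata.TITRATION_F_MIN, refdata.TITRATION_F_MAX,
        refdata.TFE_GRID_PERCENT, refdata.TITRATION_NOISE_SD,
        replicates=titration_replicates, seed=seed,
    )
    cms, ms = [], []
    for k, y in enumerate(curves):
        est = TwoStateTitration(
            bias_correction="bootstrap", sigma=refdata.TITRATION_NOISE_SD,
            n_boot=60, random_state=(seed * 10007 + k) % (2**31),
        ).fit(grid, y)
        cms.append(est.cm_)
        ms.append(est.m_value_)
    # a reduced Monte-Carlo run carries its own sampling error, so the pass
    # band is the 5% relative target widened by twice the standard error
    se_cm = float(np.std(cms) / np.sqrt(len(cms)))
    se_m = float(np.std(ms) / np.sqrt(len(ms)))
    checks["titration.midpoint_recovery"] = {
        "value": float(np.mean(cms)), "expected": ref.tfe_midpoint,
        "ci95": [float(np.mean(cms) - 2 * se_cm), float(np.mean(cms) + 2 * se_cm)],
        "pass": bool(
            abs(np.mean(cms) - ref.tfe_midpoint) < 0.05 * ref.tfe_midpoint + 2 * se_cm
        ),
    }
    checks["titration.m_value_recovery"] = {
        "value": float(np.mean(ms)), "expected": ref.tfe_m_value,
        "ci95": [float(np.mean(ms) - 2 * se_m), float(np.mean(ms) + 2 * se_m)],
        "pass": bool(
            abs(np.mean(ms) - ref.tfe_m_value) < 0.05 * ref.tfe_m_value + 2 * se_m
        ),
    }
    checks["_summary"] = {
        "n_checks": len(checks),
        "all_pass": all(v.get("pass", True) for k, v in checks.items() if k != "_summary"),
    }
    return checks
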