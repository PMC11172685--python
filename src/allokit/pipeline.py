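"""Tier I -> II -> III pipeline orchestration with a machine-readable report.

``run_pipeline`` wires the screening stages together from a plain key-value
config (YAML).  Stages are individually skippable: any stage whose config
block is absent is skipped; inputs for every enabled stage are validated
before anything runs.  Every threshold of the screen appears in the config
with its published default (700 Da, |q| <= 1, top 2000, depth schedule
20..100, 3 A ligand-RMSD criterion, 0.90/0.50 class boundaries, 2.0 A
pocket deviation, 3.5 A salt bridge).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .screen import (
    DEFAULT_CONSENSUS_SCHEDULE,
    SHP099_REFERENCE_AFFINITY,
    crosscheck_site1,
    merge_hit_sets,
    plan_tier3,
    prefilter,
    progressive_consensus,
    rank,
)
from .stability import (
    LigandRmsdSeries,
    STABILITY_RMSD_THRESHOLD,
    classify_stability,
    consensus_stability,
)
from .structio import read_compounds, read_score_table

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "mw_max": 700.0,
    "abs_charge_max": 1,
    "tier1_top_n": 2000,
    "consensus_depths": list(DEFAULT_CONSENSUS_SCHEDULE),
    "stability_threshold": STABILITY_RMSD_THRESHOLD,
    "stability_f_hi": 0.90,
    "stability_f_lo": 0.50,
    "pocket_deviation_threshold": 2.0,
    "salt_bridge_cutoff": 3.5,
    "site1_reference_affinity": SHP099_REFERENCE_AFFINITY,
    "site1_margin": 2.0,
}


@dataclass
class RunReport:
    """Per-stage parameters, input hashes and headline outputs."""

    seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, params: dict, outputs: dict,
                  input_hashes: dict | None = None) -> None:
        self.stages.append(
            {
                "stage": name,
                "params": params,
                "input_hashes": input_hashes or {},
                "outputs": outputs,
            }
        )

    def stage(self, name: str) -> dict:
        for s in self.stages:
            if s["stage"] == name:
                return s
        raise KeyError(f"stage {name!r} not in report")

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "stages": self.stages,
                "warnings": self.warnings,
            },
            indent=indent,
        )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


_STAGE_INPUTS = {
    "prefilter": ("library",),
    "tier1": ("score_table",),
    "tier2": ("score_table_a", "score_table_b"),
    "crosscheck": ("score_table",),
    "stability": ("traces",),
}


def _validate_inputs(config: dict) -> None:
    """Fail before any stage runs if an enabled stage misses an input file."""
    for stage, keys in _STAGE_INPUTS.items():
        block = config.get(stage)
        if block is None:
            continue
        for key in keys:
            value = block.get(key)
            if value is None:
                raise ValueError(f"stage {stage!r}: missing required input {key!r}")
            if not Path(value).exists():
                raise FileNotFoundError(f"stage {stage!r}: input not found: {value}")


def run_pipeline(config: dict[str, Any]) -> RunReport:
    """Execute the enabled stages of the multi-tier screen.

    Flow: prefilter -> tier1 rank/top-N -> tier2 progressive consensus ->
    merge with curated list -> site-1 crosscheck -> tier3 planning ->
    stability triage.  Later stages consume earlier outputs where their own
    inputs are not given explicitly (e.g. tier3 plans for the merged hits).
    """
    stage_names = set(_STAGE_INPUTS) | {"merge", "tier3"}
    if not any(k in config for k in stage_names):
        raise ValueError(
            "empty config: enable at least one stage "
            f"(one of {sorted(stage_names)})"
        )
    cfg = {**DEFAULT_CONFIG, **config}
    _validate_inputs(cfg)
    report = RunReport(seed=int(cfg["seed"]))

    hit_ids: list[str] | None = None

    if "prefilter" in cfg:
        block = cfg["prefilter"]
        lib = read_compounds(block["library"], fmt=block.get("format", "sdf"))
        rep = prefilter(
            lib, mw_max=cfg["mw_max"], abs_charge_max=cfg["abs_charge_max"]
        )
        report.add_stage(
            "prefilter",
            {"mw_max": cfg["mw_max"], "abs_charge_max": cfg["abs_charge_max"],
             "format": block.get("format", "sdf")},
            {
                "n_input": rep.n_input,
                "n_kept": len(rep.kept),
                "n_rejected": len(rep.rejected),
                "rejected_by_reason": {
                    r: sum(1 for v in rep.rejected.values() if v == r)
                    for r in ("metal", "mol_weight", "net_charge")
                },
            },
            {"library": _sha256(block["library"])},
        )

    if "tier1" in cfg:
        block = cfg["tier1"]
        st = read_score_table(block["score_table"])
        ranked = rank(st, block["receptor"])
        top_n = int(block.get("top_n", cfg["tier1_top_n"]))
        survivors = ranked.top(top_n)
        report.add_stage(
            "tier1",
            {"receptor": block["receptor"], "top_n": top_n},
            {
                "n_ranked": len(ranked),
                "n_survivors": len(survivors),
                "best": {
                    "compound_id": ranked.compound_ids[0],
                    "affinity": ranked.affinities[ranked.compound_ids[0]],
                },
            },
            {"score_table": _sha256(block["score_table"])},
        )

    if "tier2" in cfg:
        block = cfg["tier2"]
        st_a = read_score_table(block["score_table_a"])
        st_b = read_score_table(block["score_table_b"])
        rec_a = block.get("receptor_a") or st_a.receptors[0]
        rec_b = block.get("receptor_b") or st_b.receptors[0]
        depths = tuple(block.get("depths", cfg["consensus_depths"]))
        consensus = progressive_consensus(rank(st_a, rec_a), rank(st_b, rec_b), depths)
        hit_ids = consensus.ids
        report.add_stage(
            "tier2",
            {"receptor_a": rec_a, "receptor_b": rec_b, "depths": list(depths)},
            {
                "n_hits": len(consensus.ids),
                "hits_per_depth": {
                    str(d): len(consensus.at_depth(d)) for d in depths
                },
                "hits": consensus.ids,
            },
            {
                "score_table_a": _sha256(block["score_table_a"]),
                "score_table_b": _sha256(block["score_table_b"]),
            },
        )

    if "merge" in cfg:
        block = cfg["merge"]
        tba_ids = block.get("tba_ids")
        if tba_ids is None:
            if hit_ids is None:
                raise ValueError(
                    "merge stage needs 'tba_ids' or an enabled tier2 stage"
                )
            tba_ids = hit_ids
        hvi_ids = block.get("hvi_ids")
        if hvi_ids is None and block.get("hvi_file"):
            hvi_ids = pd.read_csv(block["hvi_file"])["compound_id"].unique().tolist()
        if hvi_ids is None:
            raise ValueError("merge stage needs 'hvi_ids' or 'hvi_file'")
        merged = merge_hit_sets(tba_ids, hvi_ids)
        hit_ids = merged.ids
        report.add_stage(
            "merge",
            {"n_tba": len(set(tba_ids)), "n_hvi": len(set(hvi_ids))},
            {"n_merged": len(merged), "overlap": merged.overlap,
             "ids": merged.ids},
        )

    if "crosscheck" in cfg:
        block = cfg["crosscheck"]
        st = read_score_table(block["score_table"])
        ids = block.get("hits", hit_ids)
        if ids is None:
            raise ValueError("crosscheck stage needs 'hits' or an earlier hit set")
        result = crosscheck_site1(
            ids, st,
            receptor_id=block.get("receptor"),
            reference_affinity=float(
                block.get("reference_affinity", cfg["site1_reference_affinity"])
            ),
            margin=float(block.get("margin", cfg["site1_margin"])),
        )
        report.add_stage(
            "crosscheck",
            {"reference_affinity": result.reference_affinity,
             "margin": result.margin},
            {"n_hits": len(result.flags), "n_competitive": result.n_competitive},
            {"score_table": _sha256(block["score_table"])},
        )

    if "tier3" in cfg:
        block = cfg["tier3"]
        ids = block.get("hits", hit_ids)
        if ids is None:
            raise ValueError("tier3 stage needs 'hits' or an earlier hit set")
        jobs = plan_tier3(
            ids,
            block.get("receptors", ["wtSHP2", "mtSHP2"]),
            duration_ns=float(block.get("duration_ns", 100.0)),
        )
        report.add_stage(
            "tier3",
            {"receptors": block.get("receptors", ["wtSHP2", "mtSHP2"]),
             "duration_ns": float(block.get("duration_ns", 100.0))},
            {"n_jobs": len(jobs),
             "jobs": [[j.receptor_id, j.compound_id] for j in jobs]},
        )

    if "stability" in cfg:
        block = cfg["stability"]
        df = pd.read_csv(block["traces"])
        for col in ("compound_id", "receptor_id", "frame", "rmsd"):
            if col not in df.columns:
                raise ValueError(f"stability traces missing column {col!r}")
        calls_by_receptor: dict[str, dict] = {}
        for (cid, rid), grp in df.groupby(["compound_id", "receptor_id"]):
            series = LigandRmsdSeries(
                compound_id=str(cid), receptor_id=str(rid),
                values=grp.sort_values("frame")["rmsd"].to_numpy(),
            )
            call = classify_stability(
                series,
                threshold=float(block.get("threshold", cfg["stability_threshold"])),
                f_hi=float(block.get("f_hi", cfg["stability_f_hi"])),
                f_lo=float(block.get("f_lo", cfg["stability_f_lo"])),
            )
            calls_by_receptor.setdefault(str(rid), {})[str(cid)] = call
        outputs: dict[str, Any] = {
            "class_counts": {
                rid: {
                    k: sum(1 for c in calls.values() if c.klass == k)
                    for k in ("highly_stable", "partially_stable", "unstable")
                }
                for rid, calls in calls_by_receptor.items()
            }
        }
        if len(calls_by_receptor) == 2:
            a, b = sorted(calls_by_receptor)
            final = consensus_stability(calls_by_receptor[a], calls_by_receptor[b])
            outputs["final_hits"] = final
            outputs["n_final_hits"] = len(final)
        report.add_stage(
            "stability",
            {"threshold": float(block.get("threshold", cfg["stability_threshold"])),
             "f_hi": float(block.get("f_hi", cfg["stability_f_hi"])),
             "f_lo": float(block.get("f_lo", cfg["stability_f_lo"]))},
            outputs,
            {"traces": _sha256(block["traces"])},
        )

    return report
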