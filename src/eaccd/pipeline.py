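"""Configuration-driven pipeline: cases in, prognostic-system artifacts out.

A run builds one prognostic system per requested factor set / age cutoff,
exports its group table, C-index curve, per-group KM curves and Newick
dendrogram, compares systems pairwise with the jackknife C-difference
test, stamps AJCC 8th-edition stages where the factor set permits, and
writes a deterministic machine-readable manifest (config hash + seed, no
timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import io as eio
from .cohort import CaseRecord, FactorSet, case_level
from .prognosis import PrognosticGrouper
from .staging import ajcc8_stage, association, contingency
from .survstats import compare_c, harrell_c

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "cases": None,
    "seed": 0,
    "min_count": 25,
    "runs": 1000,
    "k_min": 2,
    "k_max": None,
    "overlap_tol": 0.0,
    "knee_threshold": 0.25,
    "tied_events": True,
    "systems": [{"name": "TNMA", "factors": ["T", "N", "M", "A"], "age_cutoff": 55}],
    "compare": "all",   # "all", list of [name, name] pairs, or []
    "ajcc": True,
    "out_dir": "eaccd_run",
}


def _normalise_config(config: dict) -> dict:
    cfg = {**DEFAULT_CONFIG, **config}
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if cfg["cases"] is None:
        raise ValueError("config['cases'] must name a case CSV")
    for i, sysc in enumerate(cfg["systems"]):
        bad = set(sysc) - {"name", "factors", "age_cutoff"}
        if bad:
            raise ValueError(f"systems[{i}]: unknown keys {sorted(bad)}")
        if "factors" not in sysc:
            raise ValueError(f"systems[{i}]: 'factors' is required")
        sysc.setdefault("age_cutoff", 55)
        sysc.setdefault("name", "".join(sysc["factors"]))
    names = [s["name"] for s in cfg["systems"]]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate system names: {names}")
    return cfg


def _config_hash(cfg: dict) -> str:
    # out_dir does not influence any computed result
    hashed = {k: v for k, v in cfg.items() if k != "out_dir"}
    blob = json.dumps(hashed, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _export_system(model: PrognosticGrouper, out: Path, name: str) -> dict:
    sysdir = out / name
    sysdir.mkdir(parents=True, exist_ok=True)
    system = model.system_

    gframe = system.groups_frame()
    sizes = {c.label: c.size for c in model.combinations_}
    gframe["size"] = gframe["label"].map(sizes)
    gframe.to_csv(sysdir / "groups.csv", index=False)

    system.cindex_curve.to_frame().to_csv(sysdir / "cindex_curve.csv", index=False)

    rows = []
    for grp in sorted(system.curves):
        curve = system.curves[grp]
        for t, s, r in zip(curve.times, curve.surv, curve.n_at_risk):
            rows.append({"group": grp, "time": t, "surv": s, "at_risk": r})
    pd.DataFrame(rows).to_csv(sysdir / "km_curves.csv", index=False)

    (sysdir / "dendrogram.nwk").write_text(system.dendrogram.to_newick() + "\n")
    system.dendrogram.merge_table().to_csv(sysdir / "merges.csv", index=False)

    report = {
        "name": name,
        "factors": list(model.factor_set_.factors),
        "age_cutoff": model.factor_set_.age_cutoff,
        "n_combinations": len(model.combinations_),
        "n_discarded": len(model.discarded_),
        "n_cases": int(sum(sizes.values())),
        "n_groups": system.n_groups,
        "g_valid": system.g_valid,
        "c_index": system.c_index,
        "five_year": {str(g): system.five_year[g] for g in sorted(system.five_year)},
    }
    (sysdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _case_risks(model: PrognosticGrouper, cases: List[CaseRecord]) -> np.ndarray:
    return model.predict(cases)


def _ajcc_report(model: PrognosticGrouper, out: Path, name: str,
                 tied_events: bool) -> Optional[dict]:
    fs = model.factor_set_
    if not {"T", "N", "M", "A"} <= set(fs.factors):
        return None
    system = model.system_
    stage_of = {}
    for combo in model.combinations_:
        stage_of[combo.label] = ajcc8_stage(
            combo.levels["T"], combo.levels["N"], combo.levels["M"], combo.levels["A"]
        )
    sizes = {c.label: c.size for c in model.combinations_}
    table = contingency(system.group_of, stage_of, sizes)
    corr = association(system.group_of, stage_of)

    times = np.concatenate([c.times for c in model.combinations_])
    events = np.concatenate([c.events for c in model.combinations_])
    grp_pred = np.concatenate(
        [np.full(c.size, system.group_of[c.label]) for c in model.combinations_]
    ).astype(float)
    stage_pred = np.concatenate(
        [np.full(c.size, int(stage_of[c.label])) for c in model.combinations_]
    ).astype(float)
    c_ajcc = harrell_c(stage_pred, times, events, tied_events=tied_events).c
    delta, z, p = compare_c(grp_pred, stage_pred, times, events, tied_events=tied_events)

    sysdir = out / name
    table.with_margins().to_csv(sysdir / "ajcc_contingency.csv")
    report = {
        "system": name,
        "c_index_system": system.c_index,
        "c_index_ajcc": c_ajcc,
        "delta": delta,
        "z": z,
        "p": p,
        "spearman_rho": corr.rho,
        "spearman_p": corr.p,
        "n_combinations": len(model.combinations_),
    }
    (sysdir / "ajcc_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _compare_systems(models: dict, pair, tied_events: bool) -> dict:
    """Jackknife C-difference between two systems on their shared cases."""
    a, b = pair
    ma, mb = models[a], models[b]
    kept_a = {}
    for combo in ma.combinations_:
        grp = ma.system_.group_of[combo.label]
        for case in combo.members:
            kept_a[case.id] = (case, grp)
    kept_b = {}
    for combo in mb.combinations_:
        grp = mb.system_.group_of[combo.label]
        for case in combo.members:
            kept_b[case.id] = grp
    shared = sorted(set(kept_a) & set(kept_b))
    if not shared:
        raise ValueError(f"systems {a!r} and {b!r} share no cases")
    times = np.array([kept_a[i][0].surv_months for i in shared], dtype=float)
    events = np.array([kept_a[i][0].event for i in shared], dtype=int)
    pred_a = np.array([kept_a[i][1] for i in shared], dtype=float)
    pred_b = np.array([kept_b[i] for i in shared], dtype=float)
    c_a = harrell_c(pred_a, times, events, tied_events=tied_events).c
    c_b = harrell_c(pred_b, times, events, tied_events=tied_events).c
    delta, z, p = compare_c(pred_a, pred_b, times, events, tied_events=tied_events)
    return {"pair": [a, b], "n_shared": len(shared), "c_a": c_a, "c_b": c_b,
            "delta": delta, "z": z, "p": p}


def run_pipeline(config: dict, out_dir: Optional[str] = None) -> dict:
    """Execute the configured analysis; returns the manifest (also written
    to ``<out_dir>/manifest.json``)."""
    cfg = _normalise_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)

    cases, read_report = eio.read_cases(cfg["cases"])
    manifest = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "n_rows": read_report.n_rows,
        "n_cases": read_report.n_kept,
        "exclusions": read_report.exclusions,
        "systems": [],
        "ajcc": [],
        "comparisons": [],
    }

    models = {}
    for sysc in cfg["systems"]:
        model = PrognosticGrouper(
            factors=tuple(sysc["factors"]), age_cutoff=sysc["age_cutoff"],
            min_count=cfg["min_count"], runs=cfg["runs"], k_min=cfg["k_min"],
            k_max=cfg["k_max"], overlap_tol=cfg["overlap_tol"],
            knee_threshold=cfg["knee_threshold"], tied_events=cfg["tied_events"],
            random_state=cfg["seed"],
        ).fit(cases)
        models[sysc["name"]] = model
        manifest["systems"].append(_export_system(model, out, sysc["name"]))
        if cfg["ajcc"]:
            rep = _ajcc_report(model, out, sysc["name"], cfg["tied_events"])
            if rep is not None:
                manifest["ajcc"].append(rep)

    pairs = cfg["compare"]
    if pairs == "all":
        names = list(models)
        pairs = [[names[i], names[j]] for i in range(len(names))
                 for j in range(i + 1, len(names))]
    for pair in pairs:
        manifest["comparisons"].append(_compare_systems(models, pair, cfg["tied_events"]))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                                  default=str) + "\n")
    return manifest
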