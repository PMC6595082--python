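"""End-to-end measurement and reporting over files.

Ties volumetry, deformation fields and statistics into the two file-level
entry points the command line exposes: :func:`measure` (one segmentation +
one deformation field → one PVC record by both routes) and :func:`report`
(a PVC table → group summary, ANOVA/Tukey block, reproducibility and
method-agreement distances, and the effect-size/sample-size table).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nifti_io
from .fields import pvc_both_routes
from .stats import (
    CohortTable,
    apply_exclusion,
    d_ave_scans,
    distance_matrix,
    group_anova,
    plot_distance_matrix,
    power_analysis,
    scan_pairs,
    subject_pvc,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "measure", "report", "power_table"]


@dataclass
class RunConfig:
    """Validated run parameters for the reporting pipeline."""

    threshold: float = 25.0
    alpha: float = 0.05
    power: float = 0.80
    anova_mode: str = "pooled"
    seed: int = 0
    contrasts: tuple[tuple[str, str], ...] = (("CTRL", "MCI"), ("CTRL", "AD"))

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.anova_mode not in ("pooled", "mixed"):
            raise ValueError("anova_mode must be 'pooled' or 'mixed'")


def measure(seg_path, field_path, out_path, *, mesh_out=None,
            iso_level: float = 0.5) -> dict:
    """Measure one structure's volume change by both routes and write it out.

    Reads a baseline binary segmentation and a baseline→follow-up
    displacement field (NIfTI), measures V_BL and V_FU by the mesh route and
    V_FU by Jacobian integration, and writes the record as JSON. The warped
    follow-up mesh is written as PLY when ``mesh_out`` is given.
    """
    seg = nifti_io.load_label_volume(seg_path)
    fld = nifti_io.load_displacement_field(field_path)
    rec = pvc_both_routes(seg, fld, iso_level=iso_level)
    out_path = Path(out_path)
    try:
        if mesh_out is not None:
            from .meshes import extract_mesh
            from .fields import warp_mesh
            warped = warp_mesh(extract_mesh(seg, iso_level=iso_level), fld)
            nifti_io.save_mesh(warped, mesh_out)
        out_path.write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")
    except Exception:
        # do not leave partial outputs behind
        out_path.unlink(missing_ok=True)
        if mesh_out is not None:
            Path(mesh_out).unlink(missing_ok=True)
        raise
    return rec


def _group_summary(subj: pd.DataFrame) -> dict:
    out = {}
    for group, g in subj.groupby("group", observed=True):
        out[str(group)] = {
            "mean": float(g["pvc"].mean()),
            "sd": float(g["pvc"].std(ddof=1)),
            "n_observations": int(len(g)),
        }
    return out


def power_table(group_summary: dict, config: RunConfig) -> dict:
    """Effect sizes and per-group sample sizes for the configured contrasts.

    ``group_summary`` maps group → {mean, sd}; entries missing a contrast's
    group are skipped.
    """
    out = {}
    for g1, g2 in config.contrasts:
        if g1 not in group_summary or g2 not in group_summary:
            continue
        s1, s2 = group_summary[g1], group_summary[g2]
        try:
            res = power_analysis(s1["mean"], s1["sd"], s2["mean"], s2["sd"],
                                 alpha=config.alpha, power=config.power)
        except ValueError as err:
            out[f"{g1}-{g2}"] = {"error": str(err)}
            continue
        out[f"{g1}-{g2}"] = {"cohen_d": res.cohen_d,
                             "n_per_group": res.n_per_group,
                             "sigma_pooled": res.sigma_pooled}
    return out


def report(pvc_csv, out_dir, config: RunConfig | None = None) -> dict:
    """Full statistics report for a PVC table (one or more methods).

    Writes ``report.json`` plus, when at least two methods are present, the
    between-method distance matrix as CSV and a heatmap PNG. The JSON is
    byte-stable for fixed inputs (keys sorted, no timestamps).
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = CohortTable.from_csv(pvc_csv, threshold=config.threshold)
    table = apply_exclusion(table, threshold=config.threshold)
    subj_all = subject_pvc(table)
    if subj_all.empty:
        raise ValueError("no usable subject-level records after exclusion")

    methods = sorted(subj_all["method"].unique())
    blocks: dict = {"config": {
        "threshold": config.threshold, "alpha": config.alpha,
        "power": config.power, "anova_mode": config.anova_mode,
    }, "methods": {}}
    per_method_subj = {}
    for m in methods:
        subj = subj_all[subj_all["method"] == m]
        per_method_subj[m] = subj
        summary = _group_summary(subj)
        entry: dict = {"group_summary": summary}
        n_excl = int(table.df[(table.df["method"] == m)]["excluded"].sum())
        entry["n_excluded_records"] = n_excl
        try:
            entry["anova"] = group_anova(subj, mode=config.anova_mode).as_dict()
        except ValueError as err:
            entry["anova"] = {"error": str(err)}
        a, b = scan_pairs(subj)
        entry["d_ave_scans"] = d_ave_scans(a, b) if len(a) else None
        entry["power"] = power_table(summary, config)
        blocks["methods"][m] = entry

    if len(methods) >= 2:
        dm = distance_matrix(per_method_subj)
        dm.to_csv(out_dir / "distance_matrix.csv")
        plot_distance_matrix(dm, out_dir / "distance_matrix.png")
        blocks["distance_matrix"] = {
            "methods": list(dm.columns),
            "values": [[float(x) for x in row] for row in dm.to_numpy()],
        }

    text = json.dumps(_round_floats(blocks), indent=2, sort_keys=True)
    (out_dir / "report.json").write_text(text + "\n")
    return blocks


def _round_floats(obj, ndigits: int = 10):
    """Round floats for byte-stable JSON across BLAS/platform variation."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
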