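"""Scenario orchestration: the virtual-surgery experiment matrix.

A :class:`PhantomStudy` builds one phantom mesh, one synthetic diffusion
tensor field and one electrode layout, then runs any number of scenarios
(intact skull, craniectomies of parametric shape, resection) as pure
relabelings of that shared mesh.  Because geometry and tensors never
change, paired statistics (field differences, r^2) are element-by-element
with no interpolation, and every result is reproducible from (config,
seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conductivity import (ConductivityField, TissueTable,
                           build_conductivity_field, optimize_slope)
from .constants import DEFAULT_PEAK_CURRENT, Tissue
from .mesh import VolumeMesh
from .metrics import (TERModel, paired_difference, r_squared, region_stats,
                      sar, sar_stats)
from .phantom import (HeadPhantomSpec, SkullDefectSpec, TensorParams,
                      apply_resection, apply_skull_defect,
                      build_head_phantom, generate_diffusion_tensors,
                      place_electrode_pairs)
from .solver import FieldSolution, assemble, solve_pair

__all__ = ["ScenarioConfig", "ScenarioResult", "PhantomStudy",
           "run_scenario", "diameter_sweep", "burr_hole_comparison",
           "scenario_regions"]


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario: phantom + optional surgery + optional resection."""

    phantom: HeadPhantomSpec = field(default_factory=HeadPhantomSpec)
    surgery: SkullDefectSpec | None = None
    resection: bool = False
    pairs: tuple = ("LR", "AP")
    current: float = DEFAULT_PEAK_CURRENT
    seed: int = 0
    name: str = "scenario"


@dataclass
class ScenarioResult:
    name: str
    mesh: VolumeMesh
    sigma: ConductivityField
    solutions: dict                     # pair name -> FieldSolution
    report: pd.DataFrame                # tidy: scenario, pair, region, statistic, value

    def stat(self, pair: str, region: str, statistic: str) -> float:
        df = self.report
        row = df[(df["pair"] == pair) & (df["region"] == region)
                 & (df["statistic"] == statistic)]
        if len(row) != 1:
            raise KeyError(f"no unique stat ({pair}, {region}, {statistic})")
        return float(row["value"].iloc[0])


def scenario_regions(mesh: VolumeMesh, axis=None) -> dict:
    """Named element masks used in the reports.

    ``tumor`` covers the tumor (or, after resection, the cavity at the same
    elements); healthy GM/WM exclude the peritumoral shell; contralateral
    regions lie on the hemisphere opposite the tumor/defect axis.
    """
    labels = mesh.labels
    peri = mesh.get_flag("peritumoral")
    tumor = (labels == Tissue.TUMOR) | mesh.get_flag("resected")
    if axis is None:
        c = np.asarray(mesh.metadata.get("tumor_center", (1.0, 0.0, 0.0)))
        axis = c if np.linalg.norm(c) > 1.0 else np.array([1.0, 0.0, 0.0])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    side = mesh.centroids @ axis
    gm_h = (labels == Tissue.GM) & ~peri & ~tumor
    wm_h = (labels == Tissue.WM) & ~peri & ~tumor
    regions = {
        "tumor": tumor,
        "peritumor": peri,
        "gm_healthy": gm_h,
        "wm_healthy": wm_h,
        "gm_contralateral": gm_h & (side < 0),
        "wm_contralateral": wm_h & (side < 0),
    }
    for name in ("under_electrode_skin", "over_defect_skin"):
        m = mesh.get_flag(name)
        if np.any(m):
            regions["skin_under_electrodes" if "electrode" in name
                    else "skin_over_defect"] = m
    return {k: v for k, v in regions.items() if np.any(v)}


class PhantomStudy:
    """Shared mesh + tensors + electrodes for a family of paired scenarios."""

    def __init__(self, spec: HeadPhantomSpec | None = None,
                 tensor_params: TensorParams | None = None,
                 layout: dict | None = None,
                 current: float = DEFAULT_PEAK_CURRENT,
                 table: TissueTable | None = None,
                 ter_model: TERModel | None = None,
                 seed: int = 0):
        self.spec = spec or HeadPhantomSpec()
        self.seed = seed
        self.current = current
        self.table = table or TissueTable()
        self.ter_model = ter_model or TERModel()
        self.base_mesh = build_head_phantom(self.spec)
        self.tensors = generate_diffusion_tensors(
            self.base_mesh, tensor_params, seed=seed)
        self.slope = optimize_slope(self.tensors, self.base_mesh, self.table)
        self.pairs = place_electrode_pairs(self.base_mesh, layout,
                                           current=current)
        self._pair_by_name = {p.name: p for p in self.pairs}

    def run(self, surgery: SkullDefectSpec | None = None,
            resection: bool = False, pairs=("LR", "AP"),
            name: str | None = None) -> ScenarioResult:
        """Apply surgery/resection to a copy of the base mesh, map
        conductivities, solve the requested pairs and report all metrics."""
        mesh = self.base_mesh.copy()
        # electrode flags were set on base_mesh; carry them over
        mesh.flags.setdefault(
            "under_electrode_skin",
            self.base_mesh.get_flag("under_electrode_skin"))
        if name is None:
            name = _scenario_name(surgery, resection)
        try:
            if surgery is not None:
                mesh = apply_skull_defect(mesh, surgery)
            if resection:
                mesh = apply_resection(mesh)
        except Exception as exc:
            raise RuntimeError(f"scenario {name!r}: surgery stage failed: {exc}") from exc

        sigma = build_conductivity_field(mesh, self.table, self.tensors,
                                         self.slope)
        system = assemble(mesh, sigma)
        solutions = {}
        for pname in pairs:
            pair = self._pair_by_name[pname]
            solutions[pname] = solve_pair(system, pair)

        report = self._report(name, mesh, sigma, solutions)
        return ScenarioResult(name=name, mesh=mesh, sigma=sigma,
                              solutions=solutions, report=report)

    def _report(self, name, mesh, sigma, solutions) -> pd.DataFrame:
        regions = scenario_regions(mesh)
        rows = []
        for pname, sol in solutions.items():
            sar_vals = sar(sol, sigma, mesh, self.table)
            for rname, mask in regions.items():
                stats = region_stats(sol, mesh, mask, self.ter_model, rname)
                stats.update(sar_stats(sar_vals, mesh, mask, rname))
                for k, v in stats.items():
                    rows.append((name, pname, rname, k, v))
        return pd.DataFrame(rows, columns=["scenario", "pair", "region",
                                           "statistic", "value"])

    def compare(self, result: ScenarioResult, baseline: ScenarioResult) -> pd.DataFrame:
        """Paired element-by-element statistics of a scenario against a
        baseline sharing the same mesh geometry."""
        regions = scenario_regions(result.mesh)
        rows = []
        for pname, sol in result.solutions.items():
            base = baseline.solutions[pname]
            for rname, mask in regions.items():
                d = paired_difference(sol, base, result.mesh, mask)
                rows.append((result.name, pname, rname,
                             "median_delta", d["median_delta"]))
                rows.append((result.name, pname, rname,
                             "fraction_increased", d["fraction_increased"]))
                try:
                    r2 = r_squared(sol, base, result.mesh, mask)
                except ValueError:
                    r2 = np.nan
                rows.append((result.name, pname, rname, "r2", r2))
        return pd.DataFrame(rows, columns=["scenario", "pair", "region",
                                           "statistic", "value"])


def _scenario_name(surgery, resection) -> str:
    if surgery is None:
        base = "intact"
    elif surgery.kind == "circle":
        base = f"circle{surgery.diameter:g}"
    elif surgery.kind == "oval_flap":
        a, b = surgery.principal_diameters
        base = f"oval{a:g}x{b:g}"
    else:
        base = f"burr{len(surgery.hole_centers)}x{surgery.hole_diameter:g}"
    return base + ("_resected" if resection else "")


def run_scenario(cfg: ScenarioConfig, study: PhantomStudy | None = None,
                 out_dir=None) -> ScenarioResult:
    """Run one scenario from its config (building a study if none given);
    optionally write the CSV/JSON report artifacts."""
    if study is None:
        study = PhantomStudy(cfg.phantom, current=cfg.current, seed=cfg.seed)
    result = study.run(cfg.surgery, cfg.resection, cfg.pairs, cfg.name)
    if out_dir is not None:
        write_report(result, out_dir, seed=cfg.seed)
    return result


def write_report(result: ScenarioResult, out_dir, seed: int | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / f"{result.name}_report.csv", index=False)
    summary = {
        "scenario": result.name,
        "seed": seed,
        "mesh_hash": result.mesh.geometry_hash(),
        "stats": {
            f"{r.pair}/{r.region}/{r.statistic}": r.value
            for r in result.report.itertuples()
        },
    }
    (out / f"{result.name}_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))


def diameter_sweep(study: PhantomStudy, diameters=None,
                   pairs=("LR", "AP"), resection: bool = False,
                   direction=(1.0, 0.0, 0.0)) -> pd.DataFrame:
    """Tumor/peritumor median and 99th-percentile |E| for circular
    craniectomies of each diameter (mm); diameter 0 is the intact baseline.

    Each diameter re-solves from scratch — no state is carried between
    solves, so rows are independently reproducible.
    """
    if diameters is None:
        diameters = list(range(10, 101, 5))
    rows = []
    for d in [0] + [d for d in diameters if d > 0]:
        surgery = None if d == 0 else SkullDefectSpec(
            kind="circle", diameter=float(d), center_direction=direction)
        res = study.run(surgery, resection=resection, pairs=pairs)
        for pname in pairs:
            for region in ("tumor", "peritumor"):
                rows.append({
                    "diameter_mm": d,
                    "pair": pname,
                    "region": region,
                    "Q2": res.stat(pname, region, "Q2"),
                    "p99": res.stat(pname, region, "p99"),
                })
    return pd.DataFrame(rows)


def burr_hole_comparison(study: PhantomStudy, pairs=("LR", "AP"),
                         direction=(1.0, 0.0, 0.0)) -> pd.DataFrame:
    """Compare four distributed 15-mm burr holes against single circular
    craniectomies of 30 mm (equal total area) and 50 mm.

    The returned table carries tumor/peritumor medians per pair plus a
    ``burr_beats_circle30`` flag on the burr-hole rows.
    """
    burr = SkullDefectSpec.four_burr_holes(
        tumor_semiaxes=study.spec.tumor_semiaxes, center_direction=direction)
    scenarios = {
        "burr_4x15": burr,
        "circle30": SkullDefectSpec(kind="circle", diameter=30.0,
                                    center_direction=direction),
        "circle50": SkullDefectSpec(kind="circle", diameter=50.0,
                                    center_direction=direction),
    }
    results = {nm: study.run(sg, pairs=pairs, name=nm)
               for nm, sg in scenarios.items()}
    rows = []
    for nm, res in results.items():
        for pname in pairs:
            for region in ("tumor", "peritumor"):
                row = {
                    "scenario": nm,
                    "pair": pname,
                    "region": region,
                    "Q2": res.stat(pname, region, "Q2"),
                    "p99": res.stat(pname, region, "p99"),
                }
                if nm == "burr_4x15" and region == "tumor":
                    row["burr_beats_circle30"] = bool(
                        row["Q2"] >= results["circle30"].stat(
                            pname, "tumor", "Q2"))
                rows.append(row)
    return pd.DataFrame(rows)
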