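"""End-to-end study pipeline: cohort -> FEM -> stress summaries -> statistics.

``run_study`` reproduces the shape of a radiograph-based stress comparison
study: a factorial cohort of phantoms (fracture types x fixation systems,
n replicates per cell) is generated, each phantom is mapped to materials,
meshed one element per pixel, solved under the standard gravity load, and
summarised into one bone-region and one fixation-region von Mises scalar
per model.  Group statistics are then computed exactly as in
:mod:`xray2fem.stats`: Kruskal-Wallis with eta-squared and Bonferroni
pairwise tests across fracture types within each system, and Mann-Whitney
U between systems within each fracture type.

Everything is deterministic given the base seed; per-model results are
written as CSV so every reported statistic can be recomputed from the
per-model table alone (see :func:`compute_report`).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .materials import MaterialTable, Radiograph, build_material_table, assign_materials
from .mesh import build_mesh
from .phantom import FractureType, Implant, generate_phantom, make_cohort, save_phantom
from .solver import DEFAULT_TRACTION_MPA, make_standard_bc, solve_static
from .stats import kruskal_wallis, mann_whitney_u, pairwise_bonferroni
from .stress import Region, recover_stresses, summarize_region
from .vtkio import write_heatmap_png, write_vtk

__all__ = ["StudyConfig", "StudyReport", "run_study", "compute_report", "solve_radiograph"]

log = logging.getLogger("xray2fem")

_CSV_FLOAT = "%.10g"  # fixed formatting so reruns are byte-identical


@dataclass
class StudyConfig:
    n_per_cell: int = 5
    types: tuple = (FractureType.A1, FractureType.A2, FractureType.A3)
    implants: tuple = (Implant.GNF, Implant.DHS)
    base_seed: int = 0
    order: str = "q4"
    plane: str = "stress"
    statistic: str = "p95"
    load_region: str = "tissue"
    traction_mpa: float = DEFAULT_TRACTION_MPA
    material_mode: str = "discrete"
    image_height_px: int = 220
    image_width_px: int = 120
    pixel_spacing_mm: float = 1.0
    alpha: float = 0.05
    min_n_stats: int = 3
    out_dir: str | None = None
    write_vtk: bool = False
    write_png: bool = False

    def __post_init__(self) -> None:
        self.types = tuple(FractureType(t) for t in self.types)
        self.implants = tuple(Implant(m) for m in self.implants)
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


@dataclass
class StudyReport:
    per_model: pd.DataFrame
    table_bone: pd.DataFrame
    table_fixation: pd.DataFrame
    between_systems: pd.DataFrame
    warnings: list = field(default_factory=list)
    config: StudyConfig | None = None


def solve_radiograph(
    radiograph: Radiograph,
    table: MaterialTable | None = None,
    order: str = "q4",
    plane: str = "stress",
    load_region: str = "tissue",
    traction_mpa: float = DEFAULT_TRACTION_MPA,
):
    """Material-map, mesh and solve a single radiograph.

    Returns ``(mesh, result, stress)`` -- the building block behind both
    the study pipeline and the single-image CLI mode.
    """
    table = table or build_material_table()
    mm = assign_materials(radiograph, table)
    mesh = build_mesh(mm, order=order)
    bc = make_standard_bc(mesh, traction_mpa=traction_mpa, base="clamped", load_region=load_region)
    result = solve_static(mesh, bc, plane=plane)
    stress = recover_stresses(result, mesh)
    return mesh, result, stress


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full phantom study; see the module docstring."""
    t0 = time.time()
    table = build_material_table(mode=config.material_mode)
    specs = make_cohort(
        config.n_per_cell,
        types=list(config.types),
        implants=list(config.implants),
        base_seed=config.base_seed,
        image_height_px=config.image_height_px,
        image_width_px=config.image_width_px,
        pixel_spacing_mm=config.pixel_spacing_mm,
    )
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        (out / "models").mkdir(parents=True, exist_ok=True)

    n_cells = len(config.types) * len(config.implants)
    rows = []
    for idx, spec in enumerate(specs):
        replicate = idx // n_cells
        model_id = f"{spec.fracture_type.value}_{spec.implant.value}_r{replicate:02d}"
        stage = "generate"
        try:
            rad, mask = generate_phantom(spec)
            stage = "solve"
            mesh, result, stress = solve_radiograph(
                rad,
                table,
                order=config.order,
                plane=config.plane,
                load_region=config.load_region,
                traction_mpa=config.traction_mpa,
            )
            stage = "summarize"
            bone = summarize_region(stress, mesh.material, Region.BONE, config.statistic)
            fixation = (
                summarize_region(stress, mesh.material, Region.FIXATION, config.statistic)
                if spec.implant is not Implant.NONE
                else None
            )
        except Exception as exc:  # noqa: BLE001 - reported with model context
            raise RuntimeError(f"model {model_id} failed at stage {stage!r}: {exc}") from exc

        rows.append(
            {
                "model_id": model_id,
                "fracture_type": spec.fracture_type.value,
                "implant": spec.implant.value,
                "replicate": replicate,
                "seed": spec.seed,
                "statistic": config.statistic,
                "bone_MPa": bone.value_MPa,
                "fixation_MPa": np.nan if fixation is None else fixation.value_MPa,
                "max_von_mises_MPa": float(stress.von_mises.max()),
                "n_elements": mesh.n_elements,
                "equilibrium_error": result.equilibrium_error,
            }
        )
        log.info("model %s solved (%d elements)", model_id, mesh.n_elements)
        if out and config.write_vtk:
            write_vtk(
                out / "models" / f"{model_id}.vtk",
                mesh,
                {"von_mises_MPa": stress.von_mises, "material": mesh.material},
            )
        if out and config.write_png:
            save_phantom(rad, mask, out / "models", model_id)
            write_heatmap_png(
                out / "models" / f"{model_id}_vm.png",
                mesh,
                stress.von_mises,
                title=f"{model_id} von Mises",
            )

    per_model = pd.DataFrame(rows)
    table_bone, table_fix, between, warnings = compute_report(
        per_model, alpha=config.alpha, min_n=config.min_n_stats
    )
    report = StudyReport(
        per_model=per_model,
        table_bone=table_bone,
        table_fixation=table_fix,
        between_systems=between,
        warnings=warnings,
        config=config,
    )
    if out:
        per_model.to_csv(out / "per_model.csv", index=False, float_format=_CSV_FLOAT)
        table_bone.to_csv(out / "report_bone.csv", index=False, float_format=_CSV_FLOAT)
        table_fix.to_csv(out / "report_fixation.csv", index=False, float_format=_CSV_FLOAT)
        between.to_csv(out / "stats.csv", index=False, float_format=_CSV_FLOAT)
        with open(out / "study.log", "w") as fh:
            fh.write(f"models: {len(specs)}\n")
            fh.write(f"elapsed_s: {time.time() - t0:.1f}\n")
            for w in warnings:
                fh.write(f"warning: {w}\n")
    return report


def _median_range(values: np.ndarray) -> str:
    return f"{np.median(values):.1f} ({values.min():.1f}-{values.max():.1f})"


def compute_report(per_model: pd.DataFrame, alpha: float = 0.05, min_n: int = 3):
    """Group statistics from the per-model table alone.

    Returns ``(table_bone, table_fixation, between_systems, warnings)``.
    The tables hold, per fixation system, the median (min-max) summary per
    fracture type, the Kruskal-Wallis p and eta-squared across types, and
    the Bonferroni-significant pairs.  ``between_systems`` holds the
    Mann-Whitney U/Z/p between the two systems within each type.
    """
    warnings: list[str] = []
    types = sorted(per_model["fracture_type"].unique())
    implants = [m for m in per_model["implant"].unique()]

    def cell(implant, ftype, col):
        sel = (per_model["implant"] == implant) & (per_model["fracture_type"] == ftype)
        return per_model.loc[sel, col].dropna().to_numpy()

    tables = {}
    for col, region in (("bone_MPa", "bone"), ("fixation_MPa", "fixation")):
        recs = []
        for implant in implants:
            groups = [cell(implant, t, col) for t in types]
            if any(g.size == 0 for g in groups):
                warnings.append(f"{region}/{implant}: empty group, statistics skipped")
                continue
            rec = {"implant": implant}
            for t, g in zip(types, groups):
                rec[f"{t}_median_range"] = _median_range(g)
                rec[f"{t}_median_MPa"] = float(np.median(g))
            if min(g.size for g in groups) >= min_n:
                kw = kruskal_wallis(groups)
                pw = pairwise_bonferroni(groups, labels=types, alpha=alpha)
                rec["kw_H"] = kw.H
                rec["kw_p"] = kw.p
                rec["eta_squared"] = kw.eta_squared
                rec["significant_pairs"] = ";".join(
                    f"{p.pair[0]}-{p.pair[1]}" for p in pw if p.significant
                )
            else:
                warnings.append(
                    f"{region}/{implant}: fewer than {min_n} models per type, "
                    "Kruskal-Wallis skipped"
                )
            recs.append(rec)
        tables[region] = pd.DataFrame(recs)

    between_recs = []
    if len(implants) >= 2:
        for col, region in (("bone_MPa", "bone"), ("fixation_MPa", "fixation")):
            for t in types:
                a = cell(implants[0], t, col)
                b = cell(implants[1], t, col)
                if a.size == 0 or b.size == 0:
                    continue
                res = mann_whitney_u(a, b)
                between_recs.append(
                    {
                        "region": region,
                        "fracture_type": t,
                        "implant_a": implants[0],
                        "implant_b": implants[1],
                        "U": res.U,
                        "Z": res.z,
                        "p": res.p,
                        "method": res.method,
                    }
                )
    between = pd.DataFrame(between_recs)
    return tables["bone"], tables["fixation"], between, warnings
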