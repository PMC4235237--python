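"""End-to-end comparison pipeline: geometry -> fields -> frames -> FE -> report.

Drives the three-way material comparison (isotropic, per-element orthotropic,
zoned orthotropic) on a given mesh with a single declarative configuration,
so runs are reproducible from one YAML file and a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import elasticity as el
from . import frames as fr
from . import harmonic as hm
from . import report as rp
from . import solver as sv
from .geometry import ProxyParams, centerline_tangent, generate_proxy
from .io import write_mesh
from .mesh import BONE_TAGS, REGION_TAGS, TetMesh

log = logging.getLogger("orthobone")


@dataclass
class RunConfig:
    """Declarative description of a comparison run.

    ``variants`` entries are ``"isotropic"``, ``"orthotropic"`` or
    ``"zoned:<n>"``.  ``materials`` maps region names to material-database
    names used by the isotropic variant (bone regions switch to their
    orthotropic row in the orthotropic/zoned variants).  Loads are given in N
    on named node sets; restraints pin axes of named node sets.
    """

    geometry: Dict = field(default_factory=dict)        # ProxyParams fields
    mesh_path: Optional[str] = None                     # load instead of generate
    use_virtual: bool = True
    variants: List[str] = field(default_factory=lambda: ["isotropic", "orthotropic", "zoned:4"])
    materials: Dict[str, str] = field(default_factory=lambda: {
        "cortical": "bone_cortical_iso",
        "cancellous": "bone_cancellous_iso",
        "implant": "titanium",
    })
    fixed: List = field(default_factory=lambda: [["end_cap_A", "xyz"], ["end_cap_B", "xyz"]])
    loads: List = field(default_factory=lambda: [["implant_top", [0.0, 0.0, -150.0]]])
    roi_distance: float = 2.0
    nu_eff: float = 0.3
    seed: int = 0
    out_dir: str = "runs"

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def proxy_params(self) -> ProxyParams:
        return ProxyParams(seed=self.seed, **self.geometry)


@dataclass
class VariantResult:
    name: str
    u: np.ndarray
    stress: np.ndarray                 # (m, 3, 3) MPa
    strain: np.ndarray
    measures: Dict[str, np.ndarray]
    summaries: List[rp.RegionSummary]
    frame_deviation_mean: Optional[float] = None


@dataclass
class RunResult:
    mesh: TetMesh
    phi_long: np.ndarray
    phi_rad: np.ndarray
    variants: Dict[str, VariantResult]
    comparison: pd.DataFrame


def _load_or_generate(config: RunConfig) -> TetMesh:
    if config.mesh_path:
        from .io import read_mesh
        return read_mesh(config.mesh_path)
    return generate_proxy(config.proxy_params())


def element_stiffness_isotropic(mesh: TetMesh, materials: Dict[str, str]) -> np.ndarray:
    """Per-element 6x6 stiffness (GPa) from region-wise isotropic constants."""
    C = np.full((mesh.n_elements, 6, 6), np.nan)
    for region, mat_name in materials.items():
        mat = el.lookup_material(mat_name)
        if isinstance(mat, el.OrthotropicConstants):
            raise ValueError(f"isotropic variant requires isotropic constants for {region!r}")
        Ce = mat.stiffness()
        C[mesh.elements_of(region)] = Ce
    return C


def element_stiffness_orthotropic(
    mesh: TetMesh,
    frames: fr.FrameField,
    materials: Dict[str, str],
    bone_ortho: Dict[str, str] | None = None,
) -> np.ndarray:
    """Per-element stiffness with rotated orthotropic bone, isotropic elsewhere."""
    bone_ortho = bone_ortho or {
        "cortical": "bone_cortical_ortho",
        "cancellous": "bone_cancellous_ortho",
    }
    C = np.full((mesh.n_elements, 6, 6), np.nan)
    for region, mat_name in materials.items():
        if region in bone_ortho:
            continue
        mat = el.lookup_material(mat_name)
        C[mesh.elements_of(region)] = mat.stiffness()
    for region, mat_name in bone_ortho.items():
        ortho = el.lookup_material(mat_name)
        C_local = el.stiffness_from_compliance(el.compliance_from_constants(ortho))
        elems = mesh.elements_of(region)
        if not frames.defined[elems].all():
            raise ValueError(f"frames undefined on some {region!r} elements")
        C[elems] = el.rotate_stiffness_batch(C_local, frames.R[elems])
    return C


def run_comparison(config: RunConfig, write_outputs: bool = False) -> RunResult:
    """Execute every requested variant and build the comparison table."""
    t0 = time.time()
    mesh = _load_or_generate(config)
    log.info("mesh: %d nodes, %d elements, regions %s",
             mesh.n_nodes, mesh.n_elements, mesh.region_names())

    use_virtual = config.use_virtual and len(mesh.elements_of("virtual")) > 0
    phi_long, phi_rad = hm.solve_field_pair(mesh, use_virtual=use_virtual)
    g_long = hm.element_gradients(mesh, phi_long,
                                  ["cortical", "cancellous"] + (["virtual"] if use_virtual else []))
    g_rad = hm.element_gradients(mesh, phi_rad, ["cortical", "cancellous"])
    log.info("harmonic fields solved (use_virtual=%s) in %.1fs", use_virtual, time.time() - t0)

    params = config.proxy_params() if not config.mesh_path else None
    reference = (lambda pts: centerline_tangent(params, pts)) if params else None
    per_elem_frames = fr.build_frames(g_long, g_rad, mesh, reference=reference)

    solve_elems = np.flatnonzero(mesh.region != REGION_TAGS["virtual"])
    bcs = sv.BCSpec(fixed=[tuple(x) for x in config.fixed],
                    node_loads=[(n, v) for n, v in config.loads])

    rois = {
        "cortical": rp.select_roi(mesh, "implant_surface", config.roi_distance, "cortical"),
        "cancellous": rp.select_roi(mesh, "implant_surface", config.roi_distance, "cancellous"),
    }

    variants: Dict[str, VariantResult] = {}
    for name in config.variants:
        tv = time.time()
        if name == "isotropic":
            C = element_stiffness_isotropic(mesh, config.materials)
            dev = None
        elif name == "orthotropic":
            C = element_stiffness_orthotropic(mesh, per_elem_frames, config.materials)
            if reference:
                _, s = fr.frame_quality(per_elem_frames, mesh, reference)
                dev = s["mean"]
            else:
                dev = None
        elif name.startswith("zoned"):
            n_zones = int(name.split(":")[1]) if ":" in name else 4
            zf = fr.zoned_frames(mesh, phi_long, n_zones, frames=per_elem_frames)
            C = element_stiffness_orthotropic(mesh, zf, config.materials)
            if reference:
                _, s = fr.frame_quality(zf, mesh, reference)
                dev = s["mean"]
            else:
                dev = None
        else:
            raise ValueError(f"unknown variant {name!r}")

        u = sv.solve_elasticity(mesh, C, bcs, elems=solve_elems)
        strain, stress = sv.recover_fields(mesh, u, C, elems=solve_elems)
        ms = sv.scalar_measures(stress, "stress")
        me = sv.scalar_measures(strain, "strain", nu_eff=config.nu_eff)
        measures = {
            "equivalent_stress": ms["equivalent"],
            "tensile_stress": ms["first_principal"],
            "compressive_stress": ms["third_principal"],
            "equivalent_strain": me["equivalent"],
            "tensile_strain": me["first_principal"],
            "compressive_strain": me["third_principal"],
        }
        summaries = [
            rp.summarize(measures, mesh, rois[r], model=name, region=r,
                         roi_distance=config.roi_distance)
            for r in rois
        ]
        variants[name] = VariantResult(name=name, u=u, stress=stress, strain=strain,
                                       measures=measures, summaries=summaries,
                                       frame_deviation_mean=dev)
        log.info("variant %s solved in %.1fs", name, time.time() - tv)

    all_summaries = [s for v in variants.values() for s in v.summaries]
    baseline = "isotropic" if "isotropic" in variants else config.variants[0]
    comparison = rp.compare_models(all_summaries, baseline=baseline) \
        if len(variants) > 1 else pd.DataFrame(
            [dict(region=s.region, quantity=q, statistic=st,
                  **{baseline: s.get(q, st)})
             for s in all_summaries for q in rp.QUANTITIES for st in ("max", "avg")])

    result = RunResult(mesh=mesh, phi_long=phi_long, phi_rad=phi_rad,
                       variants=variants, comparison=comparison)
    if write_outputs:
        _write_outputs(config, result)
    log.info("run complete in %.1fs", time.time() - t0)
    return result


def _write_outputs(config: RunConfig, result: RunResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_sha256": config.digest(), "seed": str(config.seed),
            "roi_distance_mm": str(config.roi_distance)}
    rp.write_comparison_csv(result.comparison, out / "comparison.csv", meta)
    node_fields = {"phi_long": np.nan_to_num(result.phi_long, nan=-1.0),
                   "phi_rad": np.nan_to_num(result.phi_rad, nan=-1.0)}
    elem_fields = {}
    for name, v in result.variants.items():
        elem_fields[f"eq_stress_{name}"] = np.nan_to_num(
            v.measures["equivalent_stress"], nan=0.0)
        elem_fields[f"eq_strain_{name}"] = np.nan_to_num(
            v.measures["equivalent_strain"], nan=0.0)
    write_mesh(result.mesh, out / "result.vtk",
               node_fields=node_fields, elem_fields=elem_fields)
    config.to_yaml(out / "config.yaml")
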