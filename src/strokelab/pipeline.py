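"""End-to-end orchestration: simulate -> analyze -> report.

A RunConfig (YAML-serializable, schema-validated, every random stage
explicitly seeded) selects stages and parameters; run_pipeline executes
them in dependency order into an output directory and writes a RunManifest
(config echo, package version, per-output SHA-256 checksums) so that any
output is traceable and re-runs with identical configs are bit-identical
for the deterministic stages. make_report renders the manifest's outputs
into a plain-markdown summary with embedded figures.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError
import yaml

import strokelab
from strokelab import behavior as behavior_mod
from strokelab import beam_optics, lsci, mbll, oct_angio
from strokelab import io as slio
from strokelab.experiments import measure_occlusion_drops
from strokelab.synthetic import (AngioPhantomSpec, BehaviorSpec,
                                 HemoForwardSpec, canonical_response,
                                 gaussian_kernel, gen_angiogram_phantom,
                                 gen_multispectral_movie, gen_paw_events)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "make_report",
           "load_config"]

log = logging.getLogger("strokelab")

_STAGE_ORDER = ["optics", "speckle", "ios", "oct", "behavior", "report"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpeckleConfig(_Block):
    shape: tuple[int, int] = (128, 128)
    n_frames: int = 50
    tau_c_vessel_s: float = 20e-6
    vessel_factor: float = 5.0
    core_factor: float = 2.5
    exposure_s: float = 0.005
    window: int = 7
    seed: int = 1


class IosConfig(_Block):
    shape: tuple[int, int] = (48, 48)
    n_trials: int = 5
    noise_sd: float = 0.01
    seed: int = 2


class OctConfig(_Block):
    volume_shape: tuple[int, int, int] = (80, 120, 120)
    voxel_size_um: float = 3.0
    capillary_fraction: float = 0.05
    ablation_radius_um: float = 120.0
    ablation_survival: float = 0.1
    n_acquisitions: int = 5
    slab_um: tuple[float, float] = (60.0, 210.0)
    rings: tuple[float, float, float] = (100.0, 300.0, 50.0)
    seed: int = 3


class BehaviorConfig(_Block):
    n_subjects: int = 3
    n_rears_per_session: int = 40
    seed: int = 4


class OpticsConfig(_Block):
    wavelength_nm: float = 520.0
    na_values: tuple[float, ...] = (0.1, 0.02)


class RunConfig(_Block):
    """Full pipeline configuration; unknown keys are rejected by name."""

    stages: tuple[str, ...] = ("optics", "speckle", "ios", "oct",
                               "behavior", "report")
    log_level: str = "INFO"
    optics: OpticsConfig = OpticsConfig()
    speckle: SpeckleConfig = SpeckleConfig()
    ios: IosConfig = IosConfig()
    oct: OctConfig = OctConfig()
    behavior: BehaviorConfig = BehaviorConfig()


class RunManifest(BaseModel):
    config: RunConfig
    version: str
    outputs: dict[str, str]  # relative path -> sha256
    stage_timestamps: dict[str, float]


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; unknown keys raise with the
    offending key named."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        raise ValueError(f"invalid config: {err}") from err


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_optics(cfg: RunConfig, out: Path) -> list[Path]:
    rows = []
    for na in cfg.optics.na_values:
        rows.append({
            "na": na,
            "axial_psf_um": beam_optics.axial_psf(cfg.optics.wavelength_nm, na),
            "rayleigh_range_um": beam_optics.rayleigh_range(
                cfg.optics.wavelength_nm, na=na),
            "waist_um": 0.61 * cfg.optics.wavelength_nm * 1e-3 / na,
        })
    table = pd.DataFrame(rows)
    table["fov_mm"] = lsci.field_of_view_mm()
    table["oct_pixel_um"] = oct_angio.oct_pixel_size_um()
    p = out / "optics_table.csv"
    table.to_csv(p, index=False)
    return [p]


def _stage_speckle(cfg: RunConfig, out: Path) -> list[Path]:
    c = cfg.speckle
    drops = measure_occlusion_drops(
        shape=c.shape, n_frames=c.n_frames, tau_c_vessel_s=c.tau_c_vessel_s,
        vessel_factor=c.vessel_factor, core_factor=c.core_factor,
        exposure_s=c.exposure_s, window=c.window, seed=c.seed)
    p_drops = out / "lsci_roi_drops.csv"
    pd.DataFrame(drops).T.rename_axis("roi").to_csv(p_drops)

    # drive the guidance controller with a trace shaped like the measured
    # occlusion: baseline, then a held drop at the measured level
    t = np.arange(0.0, 600.0, 1.0)
    vessel = np.where(t < 60, 100.0, 100.0 - drops["vessel"]["drop_pct"])
    region = np.where(t < 60, 100.0, 100.0 - drops["core"]["drop_pct"])
    trace = lsci.occlusion_guidance(vessel, region, t)
    p_proto = out / "protocol_optimized.csv"
    slio.write_protocol_trace(p_proto, trace)
    p_nonopt = out / "protocol_nonoptimized.csv"
    slio.write_protocol_trace(p_nonopt, lsci.nonoptimized_protocol())
    (out / "occlusion_confirmed.json").write_text(json.dumps(
        {"occlusion_confirmed": trace.occlusion_confirmed}))
    return [p_drops, p_proto, p_nonopt, out / "occlusion_confirmed.json"]


def _stage_ios(cfg: RunConfig, out: Path) -> list[Path]:
    c = cfg.ios
    design = mbll.TrialDesign(n_trials=c.n_trials)
    dHbO, dHbR = canonical_response(design)
    spec = HemoForwardSpec(
        dHbO_t=dHbO, dHbR_t=dHbR, spatial_kernel=gaussian_kernel(c.shape),
        trial_design=design, noise_sd=c.noise_sd)
    stack = gen_multispectral_movie(spec, mbll.DEFAULT_EXTINCTION,
                                    mbll.DEFAULT_PATHLENGTH, seed=c.seed)
    dod = mbll.delta_od(stack, design=design)
    dmua = mbll.invert_mua(dod, mbll.DEFAULT_PATHLENGTH)
    series = mbll.solve_hemoglobin(dmua, mbll.DEFAULT_EXTINCTION)
    _, response = mbll.block_average(series, design)
    mask, flags = mbll.response_roi(response, 0.5)
    p_map = out / "hbt_response_map.npy"
    slio.write_volume(p_map, response, {"units": "molar", "flags": flags})
    p_sum = out / "ios_summary.csv"
    pd.DataFrame([{
        "peak_dHbT_molar": float(np.nanmax(response)),
        "roi_pixels": int(mask.sum()),
        "n_trials": c.n_trials,
    }]).to_csv(p_sum, index=False)
    return [p_map, p_sum]


def _stage_oct(cfg: RunConfig, out: Path) -> list[Path]:
    c = cfg.oct
    center = (c.volume_shape[2] * c.voxel_size_um / 2,
              c.volume_shape[1] * c.voxel_size_um / 2)
    common = dict(volume_shape=c.volume_shape, voxel_size_um=c.voxel_size_um,
                  capillary_fraction=c.capillary_fraction,
                  ablation_center_um=center)
    pre_spec = AngioPhantomSpec(**common)
    post_spec = AngioPhantomSpec(**common,
                                 ablation_radius_um=c.ablation_radius_um,
                                 ablation_survival=c.ablation_survival)
    profiles = {}
    densities = {}
    for name, spec, seed in (("pre", pre_spec, c.seed),
                             ("post", post_spec, c.seed)):
        repeats, _ = gen_angiogram_phantom(
            spec, seed=seed, n_acquisitions=c.n_acquisitions)
        vol = oct_angio.build_angiogram(repeats,
                                        voxel_size_um=c.voxel_size_um)
        fp = oct_angio.surface_vessel_footprint(
            vol, spec.surface_vessel_depth_um)
        mask = oct_angio.segment_capillaries(vol, slab_um=c.slab_um,
                                             exclusion=fp)
        densities[name] = mask.density
        baseline = profiles.get("pre")
        profiles[name] = oct_angio.ring_density(mask, center,
                                                radii_spec=c.rings,
                                                baseline=baseline)
    rows = []
    for name, prof in profiles.items():
        for i, r in enumerate(prof.radii_um):
            rows.append({"condition": name, "ring_inner_um": r,
                         "density": prof.density[i],
                         "normalized": (prof.normalized[i]
                                        if prof.normalized is not None
                                        else np.nan)})
    p_rings = out / "ring_densities.csv"
    pd.DataFrame(rows).to_csv(p_rings, index=False)
    p_dens = out / "capillary_density.csv"
    pd.DataFrame([densities]).to_csv(p_dens, index=False)
    return [p_rings, p_dens]


def _stage_behavior(cfg: RunConfig, out: Path) -> list[Path]:
    c = cfg.behavior
    logs = [gen_paw_events(BehaviorSpec(
        n_rears_per_session=c.n_rears_per_session,
        subject_id=f"m{i + 1}", seed=c.seed + i))
        for i in range(c.n_subjects)]
    events = pd.concat(logs, ignore_index=True)
    p_events = out / "paw_events.csv"
    events.to_csv(p_events, index=False)
    table = behavior_mod.score_session(events)
    p_table = out / "asymmetry_table.csv"
    table.to_csv(p_table, index=False)
    tests = behavior_mod.longitudinal_tests(table)
    p_tests = out / "behavior_tests.csv"
    tests.to_csv(p_tests, index=False)
    return [p_events, p_table, p_tests]


_STAGE_FUNCS = {
    "optics": _stage_optics,
    "speckle": _stage_speckle,
    "ios": _stage_ios,
    "oct": _stage_oct,
    "behavior": _stage_behavior,
}


def run_pipeline(config: RunConfig, out_dir) -> RunManifest:
    """Execute the requested stages in dependency order.

    Each stage writes its outputs into ``out_dir`` before the next starts,
    so partial failures leave completed outputs intact. Returns the
    manifest (also written to ``manifest.json``).
    """
    unknown = set(config.stages) - set(_STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    outputs: dict[str, str] = {}
    timestamps: dict[str, float] = {}
    for stage in _STAGE_ORDER:
        if stage not in config.stages or stage == "report":
            continue
        log.info("stage %s: start (%s)", stage,
                 getattr(config, stage, None))
        t0 = time.time()
        paths = _STAGE_FUNCS[stage](config, out)
        for p in paths:
            outputs[p.name] = _sha256(p)
            # JSON sidecars written by io helpers belong to the manifest too
            side = p.with_suffix(".json")
            if side != p and side.exists():
                outputs[side.name] = _sha256(side)
        timestamps[stage] = time.time() - t0
        log.info("stage %s: done in %.2f s", stage, timestamps[stage])

    manifest = RunManifest(config=config, version=strokelab.__version__,
                           outputs=outputs, stage_timestamps=timestamps)
    (out / "manifest.json").write_text(manifest.model_dump_json(indent=2))
    if "report" in config.stages:
        make_report(manifest, out)
    return manifest


def make_report(manifest: RunManifest, out_dir) -> Path:
    """Render a human-readable markdown summary of a run.

    Missing referenced outputs are listed but do not abort the report.
    Text sections are deterministic (no timestamps), so regeneration from
    the same manifest is byte-identical.
    """
    out = Path(out_dir)
    lines = ["# strokelab run report", ""]
    missing = [name for name in manifest.outputs
               if not (out / name).exists()]
    if not manifest.outputs:
        lines += ["**Warning: empty manifest — no stage outputs.**", ""]
    if missing:
        lines += ["**Missing outputs:** " + ", ".join(sorted(missing)), ""]

    def table_section(fname: str, title: str, float_fmt=None,
                      formatters=None):
        p = out / fname
        if p.exists():
            df = pd.read_csv(p)
            text = df.to_string(index=False, float_format=float_fmt,
                                formatters=formatters)
            lines.extend([f"## {title}", "", "```", text, "```", ""])

    table_section("optics_table.csv", "Beam optics (closed forms)",
                  float_fmt=lambda x: f"{x:.1f}",
                  formatters={"na": lambda x: f"{x:g}"})
    table_section("lsci_roi_drops.csv", "LSCI occlusion drops (% of baseline BFI)")
    table_section("protocol_optimized.csv", "Guided illumination protocol")
    table_section("ring_densities.csv", "OCT capillary ring densities")
    table_section("capillary_density.csv", "OCT mean capillary density")
    table_section("behavior_tests.csv", "Cylinder-test statistics")

    fig_path = out / "ring_density_profile.png"
    rings = out / "ring_densities.csv"
    if rings.exists():
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        df = pd.read_csv(rings)
        fig, ax = plt.subplots(figsize=(4, 3))
        for cond, sub in df.groupby("condition"):
            ax.plot(sub.ring_inner_um, sub.density, marker="o", label=cond)
        ax.set_xlabel("ring inner radius (um)")
        ax.set_ylabel("flowing-voxel density")
        ax.legend()
        fig.tight_layout()
        fig.savefig(fig_path, dpi=100)
        plt.close(fig)
        lines += [f"![ring density]({fig_path.name})", ""]

    p = out / "report.md"
    p.write_text("\n".join(lines))
    return p
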