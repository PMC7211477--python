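"""End-to-end workflow: generate/read -> condition -> shrink-wrap ->
interconnectivity -> percolation -> segmented percolation -> report.

Configured by a TOML file (schema below, unknown keys rejected).  All
randomness flows from one seed; re-running a config reproduces the summary
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import __version__
from .accessibility import ClusterRange, local_thickness, porosity, shrink_wrap_series
from .connectivity import interconnectivity_curve
from .lattice import MeshSpec, NoiseSpec, apply_noise, generate_lattice
from .percolation import (NU_3D, FitError, fit_percolation,
                          percolation_depths, segmented_percolation)
from .stack_io import otsu_threshold, read_stack, save_masks, seal_lateral_faces
from .volume import FACES, VoxelVolume

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir", "input_dir", "pixel_size_um", "seal", "save_masks",
         "mesh", "noise", "clusters", "percolation"},
    "mesh": {"pixel_size_um", "repeat_distance_um", "lattice_kind",
             "n_slices", "slice_width_px", "strut_thickness_px"},
    "noise": {"passes", "invert_fraction", "blur_radius_px"},
    "clusters": {"c_min", "c_max", "g_c"},
    "percolation": {"g_sub", "methods", "nu", "n_data_min", "mode",
                    "entry_faces"},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    out_dir: Path = Path("poreperc_out")
    input_dir: Optional[Path] = None
    pixel_size_um: Optional[float] = None
    seal: bool = False
    save_masks: bool = False
    mesh: Optional[MeshSpec] = None
    noise: Optional[NoiseSpec] = None
    clusters: ClusterRange = field(default_factory=ClusterRange)
    g_sub: int = 20
    methods: tuple[str, ...] = ("centre", "left")
    nu: float = NU_3D
    n_data_min: int = 6
    mode: str = "sealed"
    entry_faces: Optional[tuple[str, ...]] = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        for section, allowed in _SCHEMA.items():
            block = raw if section == "" else raw.get(section, {})
            if not isinstance(block, dict):
                raise ValueError(f"config section [{section}] must be a table")
            unknown = set(block) - allowed
            if section == "":
                unknown -= set()  # top-level keys checked against _SCHEMA[""]
            if unknown:
                where = f"[{section}]" if section else "top level"
                raise ValueError(f"unknown config keys at {where}: {sorted(unknown)}")
        mesh = None
        if "mesh" in raw:
            mesh = MeshSpec(**raw["mesh"])
        noise = None
        if "noise" in raw:
            seed = int(raw.get("seed", 0))
            noise = NoiseSpec(rng_seed=seed, **raw["noise"])
        clusters = ClusterRange(**raw.get("clusters", {}))
        perc = raw.get("percolation", {})
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "poreperc_out")),
            input_dir=Path(raw["input_dir"]) if "input_dir" in raw else None,
            pixel_size_um=raw.get("pixel_size_um"),
            seal=bool(raw.get("seal", False)),
            save_masks=bool(raw.get("save_masks", False)),
            mesh=mesh, noise=noise, clusters=clusters,
            g_sub=int(perc.get("g_sub", 20)),
            methods=tuple(perc.get("methods", ("centre", "left"))),
            nu=float(perc.get("nu", NU_3D)),
            n_data_min=int(perc.get("n_data_min", 6)),
            mode=perc.get("mode", "sealed"),
            entry_faces=tuple(perc["entry_faces"]) if "entry_faces" in perc else None,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mesh is None and self.input_dir is None:
            raise ValueError("config needs either a [mesh] block or input_dir")
        if self.input_dir is not None and not self.pixel_size_um:
            raise ValueError("input_dir requires pixel_size_um")
        if self.g_sub < 2:
            raise ValueError("percolation.g_sub must be >= 2")
        for m in self.methods:
            if m not in ("centre", "left"):
                raise ValueError(f"unknown subdivision method {m!r}")
        if self.mode not in ("sealed", "open"):
            raise ValueError("percolation.mode must be 'sealed' or 'open'")
        if self.entry_faces is not None:
            bad = set(self.entry_faces) - set(FACES)
            if bad:
                raise ValueError(f"unknown entry faces {sorted(bad)}")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the configured workflow; writes reports and returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mesh is not None:
        volume = generate_lattice(config.mesh)
    else:
        volume = read_stack(config.input_dir, config.pixel_size_um)
    if config.noise is not None and config.noise.passes > 0:
        volume = apply_noise(volume, config.noise)
    if volume.encoding != "binary":
        volume = otsu_threshold(volume)
    entry_faces = config.entry_faces
    if config.seal:
        volume = seal_lateral_faces(volume)
        if entry_faces is None:
            entry_faces = ("top", "bottom")

    results = shrink_wrap_series(volume, config.clusters, entry_faces)
    if config.save_masks:
        save_masks(results, out / "masks")

    curve = interconnectivity_curve(results)
    df = curve.to_frame(volume.pixel_size_um)
    profile = percolation_depths(results, mode=config.mode)
    df["L_top_um"] = profile.L_top_um
    df["L_bot_um"] = profile.L_bot_um
    df.to_csv(out / "interconnectivity.csv", index=False)

    fits: dict[str, Any] = {}
    for direction in ("top", "bottom"):
        try:
            f = fit_percolation(profile, direction=direction, nu=config.nu,
                                n_data_min=config.n_data_min)
            fits[direction] = {
                "d_perc_um": f.d_perc_um, "r_squared": f.r_squared,
                "L0_um": f.L0_um, "n_points_used": f.n_points_used,
                "physical": f.physical,
            }
        except FitError as exc:
            fits[direction] = {"error": str(exc)}

    segmented: dict[str, Any] = {}
    try:
        stable, traces = segmented_percolation(
            volume, config.clusters, g_sub=config.g_sub,
            methods=config.methods, nu=config.nu, mode=config.mode,
            entry_faces=entry_faces, n_data_min=config.n_data_min,
            results=results,
        )
        segmented = {
            "d_perc_stable_um": stable.d_perc_stable_um,
            "plateau_length": stable.plateau_length,
            "plateau_R_range_px": list(stable.plateau_R_range_px),
            "per_method_mean_um": stable.per_method_mean_um,
            "per_method_sd_um": stable.per_method_sd_um,
            "per_trace": {
                f"{m}/{d}": {"value_um": c.value_um, "length": c.length,
                             "R_range_px": list(c.R_range_px)}
                for (m, d), c in stable.per_trace.items()
            },
        }
    except ValueError as exc:
        segmented = {"error": str(exc)}

    pores = local_thickness(volume, "pore")
    summary = {
        "poreperc_version": __version__,
        "seed": config.seed,
        "pixel_size_um": volume.pixel_size_um,
        "shape_vox": list(volume.shape),
        "porosity": porosity(volume),
        "pore_size": {
            "mean_um": pores.mean_um, "sd_um": pores.sd_um,
            "mode_um": pores.mode_um,
        },
        "interconnectivity": {
            "d_median_um": curve.d_median_um,
            "I_percent": curve.I_percent.tolist(),
            "d_um": curve.d_um.tolist(),
        },
        "percolation": fits,
        "segmented_percolation": segmented,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    provenance = {
        "poreperc": __version__,
        "numpy": np.__version__,
        "config": _config_echo(config),
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str) + "\n"
    )
    return summary


def _config_echo(config: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    return {k: v for k, v in d.items() if v is not None}
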