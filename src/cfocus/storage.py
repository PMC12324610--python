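"""File formats, run configuration, and on-disk fixtures.

Conventions: rasters (phase screens, phantoms, grayscale masks, label maps,
image stacks) are TIFF; binary masks are 1-bit PNG; vectors and tables are
CSV; all metadata is JSON.  Every artifact directory carries a ``manifest
.json`` with the seeds and a hash of the generating configuration, enough to
regenerate it bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .config import OpticalConfig
from .media import PhaseScreen, ScatteringMedium, make_phase_screen
from .patterns import BinaryMask, GrayscaleMask, PatternSet, blank_mask
from .phantoms import Phantom, make_phantom
from .recon import ReconConfig, SolveDiagnostics
from .segmentation import SubregionMap

__all__ = ["RunConfig", "save_binary_mask", "load_binary_mask",
           "save_grayscale_mask", "load_grayscale_mask", "save_pattern_set",
           "load_pattern_set", "save_measurements", "load_measurements",
           "save_measurement_bundle", "load_measurement_bundle",
           "save_medium", "load_medium", "save_phantom", "load_phantom",
           "save_subregions", "load_subregions", "save_diagnostics",
           "make_fixture", "FIXTURE_NAMES"]


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def _config_hash(obj: dict) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# masks

def save_binary_mask(path, mask: BinaryMask, extra: dict | None = None) -> None:
    """1-bit PNG on the superpixel grid plus a JSON sidecar."""
    path = Path(path)
    Image.fromarray(mask.values).convert("1").save(path)
    meta = {"grid": list(mask.grid_shape),
            "superpixel_size": mask.superpixel_size,
            "on_count": mask.on_count,
            "power_ratio": mask.on_fraction}
    meta.update(extra or {})
    _write_json(path.with_suffix(".json"), meta)


def load_binary_mask(path) -> BinaryMask:
    path = Path(path)
    values = np.asarray(Image.open(path).convert("1"), dtype=bool)
    meta = json.loads(path.with_suffix(".json").read_text())
    return BinaryMask(values, int(meta.get("superpixel_size", 8)))


def save_grayscale_mask(path, mask: GrayscaleMask) -> None:
    tifffile.imwrite(path, mask.values.astype(np.float32))


def load_grayscale_mask(path, provenance: str = "manual") -> GrayscaleMask:
    return GrayscaleMask(tifffile.imread(path).astype(float), provenance)


# ---------------------------------------------------------------------------
# pattern sets and measurements

def save_pattern_set(path, patterns: PatternSet) -> None:
    """Multi-page TIFF (one 0/1 page per pattern) plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, patterns.patterns.astype(np.uint8))
    _write_json(path.with_suffix(".json"),
                {"n": len(patterns), "grid": list(patterns.grid_shape),
                 "sparsity": patterns.sparsity, "seed": patterns.seed,
                 "superpixel_size": patterns.superpixel_size})


def load_pattern_set(path) -> PatternSet:
    path = Path(path)
    raw = tifffile.imread(path)
    if raw.ndim == 2:
        raw = raw[None]
    if not np.isin(raw, (0, 1)).all():
        raise ValueError("pattern file contains non-binary values")
    meta = json.loads(path.with_suffix(".json").read_text())
    return PatternSet(raw.astype(bool), float(meta["sparsity"]),
                      int(meta["seed"]), int(meta.get("superpixel_size", 8)))


def save_measurements(path, measurements) -> None:
    from .workflow import MeasurementSet

    if isinstance(measurements, MeasurementSet):
        vec, dwell = measurements.intensities, measurements.dwell_time
    else:
        vec, dwell = np.asarray(measurements, dtype=float), float("nan")
    pd.DataFrame({"intensity": vec}).to_csv(path, index=False)
    _write_json(Path(path).with_suffix(".json"),
                {"n": len(vec), "dwell_time_s": dwell})


def load_measurements(path):
    from .workflow import MeasurementSet

    df = pd.read_csv(path)
    vec = df["intensity"].to_numpy(dtype=float)
    if (vec < 0).any():
        raise ValueError("negative intensities in measurement file")
    meta_path = Path(path).with_suffix(".json")
    dwell = 0.5e-3
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if np.isfinite(meta.get("dwell_time_s", float("nan"))):
            dwell = float(meta["dwell_time_s"])
    return MeasurementSet(vec, dwell)


def save_measurement_bundle(outdir, patterns: PatternSet, measurements,
                            manifest: dict | None = None) -> Path:
    """Aligned (patterns, measurements) pair with a regeneration manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_pattern_set(outdir / "patterns.tif", patterns)
    save_measurements(outdir / "measurements.csv", measurements)
    man = dict(manifest or {})
    man.setdefault("kind", "measurement_bundle")
    man["n_patterns"] = len(patterns)
    man["config_hash"] = _config_hash(
        {k: v for k, v in man.items() if k != "config_hash"})
    _write_json(outdir / "manifest.json", man)
    return outdir


def load_measurement_bundle(path):
    """Validated, aligned (PatternSet, MeasurementSet) in acquisition order."""
    path = Path(path)
    patterns = load_pattern_set(path / "patterns.tif")
    measurements = load_measurements(path / "measurements.csv")
    if len(patterns) != len(measurements):
        raise ValueError(
            f"bundle mismatch: {len(patterns)} patterns but "
            f"{len(measurements)} measurements")
    return patterns, measurements


# ---------------------------------------------------------------------------
# media, phantoms, subregions

def save_medium(outdir, medium: ScatteringMedium) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    screens = []
    for i, s in enumerate(medium.screens):
        fname = f"screen_{i}.tif"
        tifffile.imwrite(outdir / fname, s.phase.astype(np.float32))
        screens.append({"file": fname, "z_position": s.z_position,
                        "correlation_length": s.correlation_length,
                        "phase_std": s.phase_std, "seed": s.seed})
    _write_json(outdir / "medium.json",
                {"screens": screens, "attenuation_eal": medium.attenuation_eal})
    return outdir


def load_medium(path) -> ScatteringMedium:
    path = Path(path)
    meta = json.loads((path / "medium.json").read_text())
    screens = []
    for s in meta["screens"]:
        phase = tifffile.imread(path / s["file"]).astype(float)
        screens.append(PhaseScreen(phase, s["z_position"],
                                   s["correlation_length"], s["phase_std"],
                                   s["seed"]))
    return ScatteringMedium(tuple(screens), meta.get("attenuation_eal"))


def save_phantom(path, phantom: Phantom) -> None:
    path = Path(path)
    tifffile.imwrite(path, phantom.values.astype(np.float32))
    _write_json(path.with_suffix(".json"),
                {"xy_pitch": phantom.xy_pitch,
                 "z_positions": list(phantom.z_positions),
                 "kind": phantom.kind, "origin": list(phantom.origin)})


def load_phantom(path) -> Phantom:
    path = Path(path)
    vals = tifffile.imread(path).astype(float)
    if vals.ndim == 2:
        vals = vals[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    return Phantom(vals, float(meta["xy_pitch"]),
                   np.asarray(meta["z_positions"], dtype=float),
                   meta.get("kind", "manual"),
                   tuple(meta.get("origin", (0.0, 0.0))))


def save_subregions(path, sm: SubregionMap) -> None:
    path = Path(path)
    tifffile.imwrite(path, sm.labels.astype(np.int32))
    _write_json(path.with_suffix(".json"),
                {"targets": [list(t) for t in sm.targets],
                 "grid_shape": list(sm.grid_shape),
                 "patch_labels": sm.patch_labels.tolist(),
                 "min_separation": sm.min_separation,
                 "dim_threshold": sm.dim_threshold,
                 "pixel_pitch": sm.pixel_pitch})


def load_subregions(path) -> SubregionMap:
    path = Path(path)
    labels = tifffile.imread(path).astype(int)
    meta = json.loads(path.with_suffix(".json").read_text())
    return SubregionMap(labels,
                        [(int(r), int(c), float(p))
                         for r, c, p in meta["targets"]],
                        tuple(meta["grid_shape"]),
                        np.asarray(meta["patch_labels"], dtype=int),
                        float(meta["min_separation"]),
                        float(meta["dim_threshold"]),
                        float(meta["pixel_pitch"]))


def save_diagnostics(path, diag: SolveDiagnostics) -> None:
    path = Path(path)
    pd.DataFrame({"objective": diag.objective, "fidelity": diag.fidelity,
                  "tv": diag.tv}).to_csv(path, index=False)
    _write_json(path.with_suffix(".json"),
                {"iterations": diag.iterations, "converged": diag.converged,
                 "step_size": diag.step_size,
                 "measurement_scale": diag.measurement_scale})


# ---------------------------------------------------------------------------
# run configuration

_RUNCONFIG_SECTIONS = {"schema_version", "optical", "recon", "medium",
                       "phantom", "patterns", "segmentation", "noise",
                       "seeds", "scan"}


@dataclass
class RunConfig:
    """Nested configuration for CLI runs; every seed is explicit."""

    optical: dict = field(default_factory=dict)
    recon: dict = field(default_factory=dict)
    medium: dict = field(default_factory=dict)
    phantom: dict = field(default_factory=dict)
    patterns: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    noise: dict | None = None
    seeds: dict = field(default_factory=lambda: {"medium": 0, "patterns": 0,
                                                 "noise": 0, "phantom": 0})
    scan: dict = field(default_factory=dict)
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _RUNCONFIG_SECTIONS
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        if int(raw.get("schema_version", 1)) != 1:
            raise ValueError("unsupported schema_version")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    # builders ------------------------------------------------------------

    def optical_config(self) -> OpticalConfig:
        return OpticalConfig(**self.optical)

    def recon_config(self) -> ReconConfig:
        return ReconConfig(**self.recon)

    def build_medium(self, cfg: OpticalConfig) -> ScatteringMedium:
        p = dict(self.medium)
        if not p:
            return ScatteringMedium(())
        p.setdefault("seed", self.seeds.get("medium", 0))
        eal = p.pop("attenuation_eal", None)
        med = make_phase_screen(cfg, **p)
        return ScatteringMedium(med.screens, eal)

    def build_phantom(self) -> Phantom:
        p = dict(self.phantom)
        kind = p.pop("kind", "bead")
        seed = p.pop("seed", self.seeds.get("phantom", 0))
        return make_phantom(kind, p, seed)

    def config_hash(self) -> str:
        return _config_hash(dataclasses.asdict(self))


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_NAMES = ("bead_weak", "bead_strong", "two_beads_memory_effect",
                 "filament_field", "attenuation_stack")


def make_fixture(name: str, seed: int, outdir,
                 cfg: OpticalConfig | None = None) -> Path:
    """Write a named, deterministic on-disk fixture bundle.

    Fixtures emulate the characterisation experiments at desk scale: single
    beads behind weak/strong screens (with pattern acquisitions), a two-bead
    scene separated beyond the memory-effect range, a filament field, and a
    depth stack with a configured attenuation length.
    """
    from .optics import transfer_vector, pattern_signals
    from .patterns import generate_random_patterns
    from .workflow import MeasurementSet, memory_effect_correlation

    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from "
                         f"{FIXTURE_NAMES}")
    cfg = cfg or OpticalConfig.desk()
    outdir = Path(outdir) / name
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"name": name, "seed": seed,
                      "optical": dataclasses.asdict(cfg)}
    corr = 4 * cfg.superpixel_size * cfg.focal_pixel_pitch

    if name in ("bead_weak", "bead_strong"):
        std = 1.0 if name == "bead_weak" else 2.5
        medium = make_phase_screen(cfg, corr, std, 20.0, seed=seed)
        save_medium(outdir / "medium", medium)
        phantom = make_phantom("bead", {"diameter": 0.71}, seed=seed)
        save_phantom(outdir / "phantom.tif", phantom)
        patterns = generate_random_patterns(500, cfg.superpixel_grid, 0.4,
                                            seed, cfg.superpixel_size)
        u = transfer_vector(medium, cfg, (0.0, 0.0, 0.0))
        ms = MeasurementSet(pattern_signals(patterns, u))
        save_measurement_bundle(outdir, patterns, ms,
                                {"phase_std": std, "z_position": 20.0,
                                 "correlation_length": corr, "seed": seed})
        manifest.update(phase_std=std, n_patterns=500)

    elif name == "two_beads_memory_effect":
        medium = make_phase_screen(cfg, corr, 2.5, 20.0, seed=seed)
        save_medium(outdir / "medium", medium)
        half = cfg.fov / 2.0
        shifts = np.linspace(0.0, 0.6 * half, 8)
        c = memory_effect_correlation(medium, cfg, shifts)
        below = np.nonzero(c < 0.5)[0]
        me_range = float(shifts[below[0]]) if len(below) else float(shifts[-1])
        sep = min(max(2.0 * me_range, me_range + 6.0), 1.5 * half)
        assert sep > me_range, "bead separation must exceed the memory range"
        ph = make_phantom("bead", {"diameter": 0.71,
                                   "position": (-sep / 2, 0.0, 0.0)}, seed)
        ph2 = make_phantom("bead", {"diameter": 0.71,
                                    "position": (sep / 2, 0.0, 0.0)}, seed)
        save_phantom(outdir / "bead_a.tif", ph)
        save_phantom(outdir / "bead_b.tif", ph2)
        manifest.update(memory_range_um=me_range, separation_um=sep,
                        correlation_curve=[float(x) for x in c])

    elif name == "filament_field":
        medium = make_phase_screen(cfg, corr, 2.0, 20.0, seed=seed)
        save_medium(outdir / "medium", medium)
        phantom = make_phantom("filament", {"diameter": 1.5, "length": 20.0},
                               seed=seed)
        save_phantom(outdir / "phantom.tif", phantom)
        manifest.update(filament_diameter_um=1.5)

    elif name == "attenuation_stack":
        eal = 150.0
        depths = np.arange(0.0, 401.0, 50.0)
        medium = ScatteringMedium((), attenuation_eal=eal)
        base = 1e4
        signals = base * np.array([medium.amplitude_factor(d) for d in depths]) ** 4
        # generator self-check: the written stack must encode the configured EAL
        slope = np.polyfit(depths, np.log(signals), 1)[0]
        assert abs(-2.0 / slope - eal) < 1e-6 * eal
        pd.DataFrame({"depth_um": depths, "peak_signal": signals}).to_csv(
            outdir / "stack.csv", index=False)
        manifest.update(eal_um=eal, depths=[float(d) for d in depths])

    manifest["config_hash"] = _config_hash(
        {k: v for k, v in manifest.items() if k != "config_hash"})
    _write_json(outdir / "manifest.json", manifest)
    return outdir
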