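"""End-to-end pipeline driven by a single serializable configuration.

A :class:`RunConfig` describes one full run: simulate an example set,
build the patch database, reconstruct an input (with translation
averaging), and evaluate the result.  Every stochastic choice flows from
``seed``, so a persisted config reproduces a run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .database import build_database
from .ensemble import EnsembleConfig, ensemble_reconstruct
from .evaluate import ssim, two_filament_specs
from .grid import CanvasGeometry, ImageGrid, LR_PIXEL_NM, SR_PIXEL_NM
from .io import read_image, write_example_set, write_image
from .mrf import InferenceConfig
from .simulate import (
    LR_WIDTH_NM,
    SR_WIDTH_NM,
    add_noise,
    make_crossing_set,
    make_random_set,
    make_single_set,
    render_filaments,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class SimulateConfig:
    lr_width_px: int = 20
    sr_width_px: int = 100
    angle_step_deg: float = 30.0
    n_random_images: int = 0
    filaments_per_image: int = 5
    snr: float | None = None
    lr_pixel_size_nm: float = LR_PIXEL_NM
    sr_pixel_size_nm: float = SR_PIXEL_NM
    lr_width_nm: float = LR_WIDTH_NM
    sr_width_nm: float = SR_WIDTH_NM


@dataclass
class InputConfig:
    """Either a TIFF path or a synthetic two-filament probe."""

    path: str | None = None
    separation_nm: float = 640.0
    snr: float | None = None


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "exsr_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    input: InputConfig = field(default_factory=InputConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    shifts_x: int = 2
    shifts_y: int = 2

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sections = {
            "simulate": SimulateConfig,
            "input": InputConfig,
            "inference": InferenceConfig,
        }
        kwargs = {}
        for name, typ in sections.items():
            sub = d.pop(name, {})
            unknown = set(sub) - {f for f in typ.__dataclass_fields__}
            if unknown:
                raise ValueError(f"unknown keys in '{name}': {sorted(unknown)}")
            kwargs[name] = typ(**sub)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _canvases(sim: SimulateConfig) -> tuple[CanvasGeometry, CanvasGeometry]:
    lr = CanvasGeometry(sim.lr_width_px, sim.lr_width_px, sim.lr_pixel_size_nm)
    sr = CanvasGeometry(sim.sr_width_px, sim.sr_width_px, sim.sr_pixel_size_nm)
    return lr, sr


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute simulate -> build-db -> reconstruct -> evaluate.

    Returns the run report (also written to ``report.json``); every
    artifact directory carries the config digest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_digest": config.digest(), "stages": {}}

    def stage(name):
        t0 = time.perf_counter()

        def done(**extra):
            report["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **extra,
            }
            log(f"[{name}] done in {report['stages'][name]['seconds']} s")

        return done

    # --- simulate -----------------------------------------------------
    done = stage("simulate")
    sim = config.simulate
    lr_canvas, sr_canvas = _canvases(sim)
    examples = make_single_set(
        angle_stop_deg=None, angle_step_deg=sim.angle_step_deg, lr_canvas=lr_canvas, sr_canvas=sr_canvas,
        lr_width_nm=sim.lr_width_nm, sr_width_nm=sim.sr_width_nm,
    )
    examples += make_crossing_set(
        angle_stop_deg=None, angle_step_deg=sim.angle_step_deg, lr_canvas=lr_canvas, sr_canvas=sr_canvas,
        lr_width_nm=sim.lr_width_nm, sr_width_nm=sim.sr_width_nm,
    )
    if sim.n_random_images:
        examples += make_random_set(
            sim.n_random_images,
            filaments_per_image=sim.filaments_per_image,
            lr_canvas=lr_canvas,
            sr_canvas=sr_canvas,
            lr_width_nm=sim.lr_width_nm,
            sr_width_nm=sim.sr_width_nm,
            seed=config.seed,
        )
    if sim.snr is not None:
        for i, ex in enumerate(examples):
            ex.lr = add_noise(ex.lr, sim.snr, seed=config.seed + i)
    write_example_set(out / "examples", examples)
    done(n_examples=len(examples))

    # --- build database ----------------------------------------------
    done = stage("build_db")
    db = build_database(examples)
    db_path = out / "database.h5"
    db.save(db_path)
    done(n_pairs=len(db), path=str(db_path))

    # --- input --------------------------------------------------------
    done = stage("input")
    if config.input.path:
        lr_input = read_image(config.input.path, pixel_size_nm=sim.lr_pixel_size_nm)
        truth = None
    else:
        specs = two_filament_specs(lr_canvas, config.input.separation_nm)
        lr_input = render_filaments(specs, lr_canvas, sim.lr_width_nm)
        truth = render_filaments(specs, sr_canvas, sim.sr_width_nm)
    if config.input.snr is not None:
        lr_input = add_noise(lr_input, config.input.snr, seed=config.seed + 10_007)
    write_image(out / "input_lr.tif", lr_input, {"config_digest": config.digest()})
    done()

    # --- reconstruct --------------------------------------------------
    done = stage("reconstruct")
    ens = EnsembleConfig(
        shifts_x=config.shifts_x, shifts_y=config.shifts_y, inference=config.inference
    )
    result = ensemble_reconstruct(lr_input, db, ens)
    write_image(out / "output_sr.tif", result.mean_sr, {"config_digest": config.digest()})
    write_image(out / "sd_map.tif", result.sd_map, {"config_digest": config.digest()})
    done(n_shifts=result.n_shifts)

    # --- evaluate -----------------------------------------------------
    done = stage("evaluate")
    if truth is not None:
        write_image(out / "truth_sr.tif", truth, {"config_digest": config.digest()})
        report["ssim_vs_truth"] = ssim(result.mean_sr, truth)
        done(ssim=report["ssim_vs_truth"])
    else:
        done(skipped="no ground truth for external input")

    (out / "report.json").write_text(json.dumps(report, indent=1))
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    return report
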