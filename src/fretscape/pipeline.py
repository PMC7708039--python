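"""Pipeline configuration and the end-to-end run.

A single flat configuration (YAML, overridable from the command line)
drives simulate -> MEM inversion -> Gaussian decomposition -> FRET, plus
the geometry stage when a structure is configured.  All randomness flows
from the single configured seed, and every output file embeds the tool
version and a hash of the configuration, so a rerun with the same config
is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import descriptors as geo
from .landscape import average_fret, build_landscape, count_peaks
from .mem import LifetimeGrid, mem_fit
from .structure import read_structure
from .synthetic import simulate_decay
from .trace import AcquisitionConfig, read_decay

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "load_config"]

log = logging.getLogger("fretscape")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[fretscape:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage_log(stage: str, message: str) -> None:
    log.info(message, extra={"stage": stage})


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run (flat sections, YAML-backed)."""

    seed: int = 1
    # decay source: either simulated components or a trace file
    components: list[tuple[float, float]] | None = None
    trace_path: str | None = None
    # acquisition (simulation only)
    window: float = 100.0
    n_channels: int = 4096
    peak_counts: float = 10_000.0
    irf_fwhm: float = 0.0
    background_rate: float = 0.0
    # MEM
    grid_min: float = 0.02
    grid_max: float = 20.0
    grid_points: int = 120
    chi2_target: float = 1.0
    # landscape
    max_components: int = 4
    threshold_fraction: float = 0.02
    tau_d: float = 4.9
    # geometry (optional)
    pdb_path: str | None = None
    span: tuple[int, int] | None = None
    hinge: int | None = None
    arms: int = 5
    site: tuple[int, ...] = ()
    blocks: int = 5
    twist_initial: float | None = None
    outdir: str = "fretscape_out"

    def __post_init__(self) -> None:
        # validate against the owning stages' preconditions up front
        AcquisitionConfig(self.window, self.n_channels, self.peak_counts,
                          self.irf_fwhm, self.background_rate, self.seed)
        LifetimeGrid(self.grid_min, self.grid_max, self.grid_points)
        if self.components is None and self.trace_path is None:
            raise ValueError("config needs either components or trace_path")
        if self.components is not None:
            total = sum(a for _, a in self.components)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"component amplitudes must sum to 1, got {total!r}"
                )
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        if not self.tau_d > 0:
            raise ValueError("tau_d must be > 0")
        if self.chi2_target <= 0:
            raise ValueError("chi2_target must be > 0")
        if self.pdb_path is not None:
            if self.span is None or self.hinge is None:
                raise ValueError("geometry stage needs span and hinge")
            if self.blocks < 2:
                raise ValueError("blocks must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d

    def config_hash(self) -> str:
        """Hash of the scientific settings (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        payload = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config file, applying keyword overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if "components" in raw and raw["components"] is not None:
        raw["components"] = [tuple(map(float, c)) for c in raw["components"]]
    for key in ("span", "site"):
        if raw.get(key) is not None:
            raw[key] = tuple(int(v) for v in raw[key])
    return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write the reports.

    Returns the JSON-ready summary dict (also written to
    ``summary.json``); ``dist.tsv`` and ``landscape.tsv`` hold the
    lifetime distribution and the Gaussian landscape, ``descriptors.tsv``
    the geometry series when a structure is configured.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = {"version": __version__, "config_hash": chash,
             "seed": config.seed}
    summary: dict = {"config": config.to_dict(), "config_hash": chash}

    # --- decay stage -----------------------------------------------------
    try:
        if config.trace_path is not None:
            _stage_log("decay", f"reading trace {config.trace_path}")
            trace = read_decay(config.trace_path)
        else:
            acq = AcquisitionConfig(
                config.window, config.n_channels, config.peak_counts,
                config.irf_fwhm, config.background_rate, config.seed,
            )
            _stage_log(
                "decay",
                f"simulating {len(config.components)} components, "
                f"seed {config.seed}",
            )
            trace = simulate_decay(config.components, acq)
    except Exception as exc:
        raise PipelineStageError("decay", exc) from exc

    # --- MEM stage -------------------------------------------------------
    try:
        grid = LifetimeGrid(config.grid_min, config.grid_max,
                            config.grid_points)
        _stage_log("mem", f"inverting on {grid.n}-point grid, "
                          f"chi2 target {config.chi2_target}")
        dist = mem_fit(trace, grid, chi2_target=config.chi2_target)
    except Exception as exc:
        raise PipelineStageError("mem", exc) from exc
    dist.write(outdir / "dist.tsv", header_extra=stamp)
    d = dist.diagnostics
    summary["mem"] = {
        "chi2_red": round(d.chi2_red, 6),
        "reg_weight": float(f"{d.reg_weight:.6g}"),
        "converged": d.converged,
        "background": round(d.background, 6),
        "n_channels": d.n_channels,
    }

    # --- landscape stage -------------------------------------------------
    try:
        n_peaks = count_peaks(dist, config.threshold_fraction)
        _stage_log("peaks", f"{n_peaks} resolved peaks")
        landscape = build_landscape(dist, config.tau_d,
                                    max_components=config.max_components)
    except Exception as exc:
        raise PipelineStageError("peaks", exc) from exc
    landscape.write(outdir / "landscape.tsv", header_extra=stamp)
    summary["landscape"] = {
        "n_peaks": n_peaks,
        "tau_d": config.tau_d,
        "mean_E_peaks": round(landscape.mean_e, 6),
        "mean_E_grid": round(average_fret(dist, config.tau_d), 6),
        "peaks": [
            {
                "center_ns": round(p.center, 6),
                "width_log10": round(p.width, 6),
                "fraction": round(p.fraction, 6),
                "E": round(p.e_peak, 6),
                "E_raw": round(p.e_raw, 6),
            }
            for p in landscape.peaks
        ],
    }

    # --- geometry stage --------------------------------------------------
    if config.pdb_path is not None:
        try:
            summary["geometry"] = _geometry_stage(config, outdir, stamp)
        except Exception as exc:
            raise PipelineStageError("geometry", exc) from exc

    out_json = json.dumps(summary, indent=2, sort_keys=True)
    (outdir / "summary.json").write_text(out_json + "\n")
    _stage_log("done", f"reports in {outdir}")
    return summary


def _geometry_stage(config: PipelineConfig, outdir: Path, stamp: dict) -> dict:
    _stage_log("geometry", f"reading {config.pdb_path}")
    model = read_structure(config.pdb_path)
    lo, hi = config.span
    twists = geo.twist_series(model, lo, hi)
    if config.twist_initial is not None:
        ref = config.twist_initial
    else:  # reference ensemble: first quarter of the models
        n_ref = max(model.n_models // 4, 1)
        ref = twists[:n_ref]
    untwist = geo.untwist_angle(twists, ref)
    if model.n_models >= config.blocks:
        untwist = untwist.with_blocks(config.blocks)
    result = {
        "n_models": model.n_models,
        "span": [lo, hi],
        "untwist_mean": round(float(np.mean(untwist.values)), 4),
        "untwist_block_sd": (
            None if untwist.block_sd is None else round(untwist.block_sd, 4)
        ),
    }
    bend = [
        geo.bend_angle(model, config.hinge, config.arms, m)
        for m in range(model.n_models)
    ]
    direction = [
        geo.bend_direction_dihedral(model, config.hinge, config.arms, m)
        for m in range(model.n_models)
    ]
    result["bend_mean"] = round(float(np.mean(bend)), 4)
    defined = [v for v in direction if v is not None]
    result["bend_direction_mean"] = (
        round(float(np.mean(defined)), 4) if defined else None
    )
    extrusion = {
        str(site): [
            round(geo.base_extrusion_dihedral(model, site, m), 4)
            for m in range(model.n_models)
        ]
        for site in config.site
    }
    result["extrusion"] = {
        k: round(float(np.mean(v)), 4) for k, v in extrusion.items()
    }
    hb = geo.hydrogen_bonds(model)
    result["n_hydrogen_bonds"] = len(hb)

    lines = ["# fretscape geometry descriptors"]
    for key, val in sorted(stamp.items()):
        lines.append(f"# {key} = {val}")
    lines.append("# columns = model\tuntwist_deg\tbend_deg\tbend_direction_deg")
    for m in range(model.n_models):
        dirv = direction[m]
        lines.append(
            f"{m}\t{untwist.values[m]:.4f}\t{bend[m]:.4f}\t"
            + (f"{dirv:.4f}" if dirv is not None else "undefined")
        )
    (outdir / "descriptors.tsv").write_text("\n".join(lines) + "\n")
    return result
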