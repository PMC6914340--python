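"""End-to-end pipeline configuration, execution and reporting.

Ties the stages together in the order the dual-color experiment
dictates: channel registration -> single-channel tracking -> immobile
exclusion -> mobility statistics -> co-localization/co-tracking ->
double-labeling correction. Every run records its full parameter set, a
config hash and the seed, so results are reproducible bit-for-bit for
the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .cotracking import CoTrackingParams, DimerizationResult, \
    quantify_dimerization
from .io import LocalizationTable, read_localizations
from .mobility import DiffusionEstimate, StepLengthMixtureFit, \
    collect_step_lengths, compute_msd, exclude_immobile, \
    fit_diffusion_constant, fit_step_length_mixture
from .registration import AffineTransform2D, apply_transform, fit_affine
from .tracking import LinkingParams, filter_min_steps, link_localizations

logger = logging.getLogger("smcotrack")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run.

    Defaults reproduce the standard acquisition/analysis constants:
    100 nm co-localization radius, 10-step minimum trajectory length,
    32 ms frame time, 150-frame movies.
    """

    table_a_path: str | None = None
    table_b_path: str | None = None
    beads_path: str | None = None
    transform_path: str | None = None
    pixel_size_nm: float | None = None

    max_step_nm: float | None = None
    max_gap: int = 1
    assignment: str = "greedy"

    radius_nm: float = 100.0
    min_steps: int = 10
    exclude_immobile: bool = True
    immobile_eps_nm: float = 50.0
    immobile_min_pts: int = 5

    frame_time_s: float = 0.032
    n_frames: int = 150
    msd_max_lag: int = 10
    msd_lag_range: tuple[int, int] = (2, 10)
    mixture_components: int = 2

    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be > 0")
        if self.min_steps < 0:
            raise ValueError("min_steps must be >= 0")
        if self.frame_time_s <= 0:
            raise ValueError("frame_time_s must be > 0")

    def linking_params(self) -> LinkingParams:
        kw = {"max_gap": self.max_gap, "assignment": self.assignment}
        if self.max_step_nm is not None:
            kw["max_step_nm"] = self.max_step_nm
        return LinkingParams(**kw)

    def cotracking_params(self) -> CoTrackingParams:
        return CoTrackingParams(
            linking=self.linking_params(), radius_nm=self.radius_nm,
            min_steps=self.min_steps,
            exclude_immobile=self.exclude_immobile,
            immobile_eps_nm=self.immobile_eps_nm,
            immobile_min_pts=self.immobile_min_pts,
            frame_time_s=self.frame_time_s)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["msd_lag_range"] = list(d["msd_lag_range"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Load a key-value config file; keyword overrides win on conflict."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "msd_lag_range" in data:
            data["msd_lag_range"] = tuple(data["msd_lag_range"])
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    """Bundle of per-run results: dimerization, mobility, provenance."""

    dimerization: DimerizationResult
    diffusion: dict[str, DiffusionEstimate]
    mixture: StepLengthMixtureFit | None
    config: PipelineConfig
    label: str = ""

    def to_dict(self) -> dict:
        dim = self.dimerization
        out = {
            "label": self.label,
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "dimerization": {
                "A": dim.a, "B": dim.b, "AB": dim.ab,
                "AB_star": dim.ab_star,
                "rel_colocomotion": dim.rel_colocomotion,
                "radius_nm": dim.radius_nm, "min_steps": dim.min_steps,
                "intermediates": dim.intermediates,
            },
            "diffusion": {
                ch: {"D_um2_s": d.d_um2_s, "intercept_nm2": d.intercept_nm2,
                     "stderr_um2_s": d.stderr_um2_s,
                     "lag_range": list(d.lag_range)}
                for ch, d in self.diffusion.items()
            },
            "params": self.config.to_dict(),
        }
        if self.mixture is not None:
            m = self.mixture
            out["mixture"] = {"alpha": m.alpha, "D1_um2_s": m.d1_um2_s,
                              "D2_um2_s": m.d2_um2_s, "loglik": m.loglik,
                              "converged": m.converged}
        return out

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         default=float))


def _register_b(table_b: LocalizationTable,
                config: PipelineConfig) -> LocalizationTable:
    transform = None
    if config.transform_path:
        transform = AffineTransform2D.load(config.transform_path)
    elif config.beads_path:
        beads = np.loadtxt(config.beads_path, delimiter=",", skiprows=1)
        transform = fit_affine(beads[:, :2], beads[:, 2:4])
        logger.info("registration: fitted affine from %d beads, RMS %.2f nm",
                    len(beads), transform.residual_rms_nm)
    if transform is not None:
        return apply_transform(table_b, transform)
    return table_b


def analyze_tables(table_a: LocalizationTable, table_b: LocalizationTable,
                   config: PipelineConfig, label: str = "") -> PipelineResult:
    """Run tracking, mobility and co-tracking on two registered tables."""
    t0 = time.perf_counter()
    params = config.cotracking_params()
    dim = quantify_dimerization(table_a, table_b, params)

    diffusion: dict[str, DiffusionEstimate] = {}
    all_steps = []
    for tag, table in (("A", table_a), ("B", table_b)):
        tracks = link_localizations(table, params.linking)
        if config.exclude_immobile:
            tracks, _ = exclude_immobile(tracks, config.immobile_eps_nm,
                                         config.immobile_min_pts)
        tracks = filter_min_steps(tracks, config.min_steps)
        if len(tracks):
            msd = compute_msd(tracks, config.msd_max_lag, config.frame_time_s)
            try:
                diffusion[tag] = fit_diffusion_constant(msd,
                                                        config.msd_lag_range)
            except ValueError:
                pass
            all_steps.append(collect_step_lengths(tracks))
    steps = np.concatenate(all_steps) if all_steps else np.empty(0)
    mixture = None
    if steps.size >= 50:
        mixture = fit_step_length_mixture(steps, config.frame_time_s,
                                          config.mixture_components,
                                          seed=config.seed)
    logger.info("pipeline %s: %.2f s, %s", label or "-",
                time.perf_counter() - t0, dim.summary())
    return PipelineResult(dim, diffusion, mixture, config, label)


def run_pipeline(config: PipelineConfig, out_dir=None,
                 label: str = "") -> PipelineResult:
    """Execute the full pipeline from localization files.

    Reads both channels, registers channel B into channel A's frame
    (from a saved transform or a bead file, when provided), then runs
    tracking, mobility and co-tracking. When ``out_dir`` is given,
    writes ``result.json`` there.
    """
    if not config.table_a_path or not config.table_b_path:
        raise FileNotFoundError("table_a_path and table_b_path are required")
    for p in (config.table_a_path, config.table_b_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    table_a = read_localizations(config.table_a_path,
                                 pixel_size_nm=config.pixel_size_nm)
    table_b = read_localizations(config.table_b_path,
                                 pixel_size_nm=config.pixel_size_nm)
    table_b = _register_b(table_b, config)
    table_a.registered = True
    table_b.registered = True
    result = analyze_tables(table_a, table_b, config, label)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.save_json(out_dir / "result.json")
    return result


def report(results: list[PipelineResult]) -> str:
    """Human-readable summary table of one or more pipeline results.

    Batch results are sorted by scenario label; an empty list renders
    the header only.
    """
    header = (f"{'label':<14} {'A':>6} {'B':>6} {'AB':>5} {'AB*':>8} "
              f"{'rel':>7} {'D_A':>8} {'D_B':>8}")
    lines = [header]
    for r in sorted(results, key=lambda r: r.label):
        dim = r.dimerization
        da = r.diffusion.get("A")
        db = r.diffusion.get("B")
        lines.append(
            f"{r.label or '-':<14} {dim.a:>6} {dim.b:>6} {dim.ab:>5} "
            f"{dim.ab_star:>8.2f} {dim.rel_colocomotion:>7.4f} "
            f"{(da.d_um2_s if da else float('nan')):>8.4f} "
            f"{(db.d_um2_s if db else float('nan')):>8.4f}")
    return "\n".join(lines)
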