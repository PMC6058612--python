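"""End-to-end pipeline: input → normalize → extract → segment → stats → targeting.

Stage outputs are files, so each stage is independently re-runnable and
partial results survive a failing stage.  A run manifest records the seed,
the config hash and package versions; two runs with the same config and seed
produce byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analytes import by_role, default_analyte_table, load_analyte_table
from .msi_core import (
    MSIDataset,
    compute_tissue_mask,
    extract_ion_image,
    read_imzml,
    tic_normalize,
)
from .segmentation import segment_dataset, segments_to_rois
from .spatial_stats import correlation_table, pixel_rsd
from .synthetic_lung import SyntheticScenario, default_scenario, simulate_replicates
from .targeting import PlasmaSample, compute_targeting_report

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Input is either a scenario (YAML path or ``"default"``) that is simulated
    with ``n_replicates`` sections, or a list of imzML paths (one per
    replicate section).
    """

    out_dir: str
    scenario: str | None = "default"
    imzml_paths: list[str] = field(default_factory=list)
    n_replicates: int = 3
    analyte_table: str | None = None
    mask_method: str = "tic_threshold"
    mask_quantile: float = 0.40
    sigma_px: float = 1.0
    bin_width: float = 0.5
    k: int = 6
    n_restarts: int = 4
    seed: int = 0
    plasma: dict | None = None  # {"inhaled": conc, "iv": conc, "unit": str}
    run_targeting: bool = True
    write_imzml_outputs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str, t0: float, **info) -> None:
    logger.info("stage %-12s %6.2fs %s", name, time.perf_counter() - t0, info or "")


def analyze_section(
    raw: MSIDataset,
    analytes,
    k: int = 6,
    seed: int = 0,
    sigma_px: float = 1.0,
    bin_width: float = 0.5,
    n_restarts: int = 4,
    mask_quantile: float = 0.40,
):
    """Single-section analysis chain: normalize → mask → segment → name ROIs.

    Returns ``(normalized_dataset, roiset, tissue_mask)`` — the triple that
    :func:`lungtarget.targeting.compute_targeting_report` consumes per
    replicate.
    """
    norm = tic_normalize(raw)
    mask = compute_tissue_mask(dataset=raw, threshold_quantile=mask_quantile)
    seg = segment_dataset(
        norm, k=k, seed=seed, sigma_px=sigma_px, bin_width=bin_width, n_restarts=n_restarts
    )
    marker_images = {
        role: extract_ion_image(norm, by_role(analytes, role))
        for role in ("marker_alveolar", "marker_bronchiolar", "marker_vessel")
    }
    rois = segments_to_rois(seg, marker_images, raw.to_grid(raw.tic()))
    return norm, rois, mask


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured run; returns a dict of artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {}

    # -- stage: input --------------------------------------------------------
    t0 = time.perf_counter()
    scenario: SyntheticScenario | None = None
    try:
        if config.imzml_paths:
            sections_raw = [read_imzml(p) for p in config.imzml_paths]
        else:
            if config.scenario in (None, "default"):
                scenario = default_scenario()
            else:
                scenario = SyntheticScenario.from_yaml(config.scenario)
            sims = simulate_replicates(scenario, config.n_replicates, seed=config.seed)
            sections_raw = [ds for ds, _truth in sims]
            if config.write_imzml_outputs:
                from .msi_core import write_imzml

                for i, ds in enumerate(sections_raw):
                    write_imzml(ds, out / f"section_{i}.imzML")
    except Exception as exc:
        raise PipelineStageError("input", str(exc)) from exc
    _stage("input", t0, sections=len(sections_raw))

    # -- stage: analytes -----------------------------------------------------
    if config.analyte_table:
        analytes = load_analyte_table(config.analyte_table)
    elif scenario is not None:
        analytes = scenario.analyte_definitions()
    else:
        analytes = default_analyte_table()
    roles = ("drug_inhaled", "drug_iv", "marker_alveolar", "marker_bronchiolar", "marker_vessel")
    try:
        by_role_map = {r: by_role(analytes, r) for r in roles}
    except Exception as exc:
        raise PipelineStageError("analytes", str(exc)) from exc

    per_section = []
    for i, raw in enumerate(sections_raw):
        # -- stage: normalize ------------------------------------------------
        t0 = time.perf_counter()
        try:
            norm = tic_normalize(raw)
            mask = compute_tissue_mask(
                dataset=raw,
                method=config.mask_method,
                threshold_quantile=config.mask_quantile,
            )
        except Exception as exc:
            raise PipelineStageError("normalize", f"section {i}: {exc}") from exc
        _stage("normalize", t0, section=i, on_tissue=mask.n_pixels)

        # -- stage: ion images ----------------------------------------------
        t0 = time.perf_counter()
        try:
            images = {a.name: extract_ion_image(norm, a) for a in analytes}
            for name, img in images.items():
                img.to_csv(out / f"ion_image_s{i}_{name}.csv")
        except Exception as exc:
            raise PipelineStageError("ion_images", f"section {i}: {exc}") from exc
        _stage("ion_images", t0, section=i, n_images=len(images))

        # -- stage: segment --------------------------------------------------
        t0 = time.perf_counter()
        try:
            seg = segment_dataset(
                norm,
                k=config.k,
                seed=config.seed,
                sigma_px=config.sigma_px,
                bin_width=config.bin_width,
                n_restarts=config.n_restarts,
            )
            marker_images = {
                r: images[by_role_map[r].name]
                for r in ("marker_alveolar", "marker_bronchiolar", "marker_vessel")
            }
            rois = segments_to_rois(seg, marker_images, raw.to_grid(raw.tic()))
            seg.to_csv(out / f"segmentation_s{i}.csv")
            rois.to_yaml(out / f"roi_map_s{i}.yaml")
        except Exception as exc:
            raise PipelineStageError("segment", f"section {i}: {exc}") from exc
        _stage("segment", t0, section=i, k_actual=seg.k_actual)
        per_section.append((raw, norm, mask, images, rois))

    # -- stage: stats (first section, whole-image) ---------------------------
    t0 = time.perf_counter()
    try:
        raw, norm, mask, images, rois = per_section[0]
        stat_images = {by_role_map[r].name: images[by_role_map[r].name] for r in roles}
        corr = correlation_table(stat_images, mask.grid)
        corr.round(1).to_csv(out / "correlation_table.csv")
        het_rows = []
        for route, role in (("inhaled", "drug_inhaled"), ("iv", "drug_iv")):
            for j, (_raw, _norm, m, imgs, _rois) in enumerate(per_section):
                h = pixel_rsd(imgs[by_role_map[role].name], m.grid, route=route)
                het_rows.append(
                    {"section": j, "route": route, "analyte": h.analyte,
                     "rsd_percent": round(h.rsd_percent, 2), "n_pixels": h.n_pixels}
                )
        pd.DataFrame(het_rows).to_csv(out / "heterogeneity.csv", index=False)
    except Exception as exc:
        raise PipelineStageError("stats", str(exc)) from exc
    _stage("stats", t0)

    # -- stage: targeting ----------------------------------------------------
    if config.run_targeting:
        t0 = time.perf_counter()
        try:
            plasma = config.plasma
            if plasma is None and scenario is not None:
                plasma = dict(scenario.plasma, unit=scenario.plasma_unit)
            if plasma is None or "inhaled" not in plasma or "iv" not in plasma:
                raise ValueError("plasma concentrations for both routes are required")
            unit = plasma.get("unit", "nmol/L")
            plasma_samples = {
                route: PlasmaSample(
                    route=route,
                    analyte=by_role_map[f"drug_{'inhaled' if route == 'inhaled' else 'iv'}"].name,
                    concentration=float(plasma[route]),
                    unit=unit,
                )
                for route in ("inhaled", "iv")
            }
            report = compute_targeting_report(
                [(norm, rois, mask) for _raw, norm, mask, _imgs, rois in per_section],
                by_role_map["drug_inhaled"],
                by_role_map["drug_iv"],
                plasma=plasma_samples,
            )
            report.per_replicate.round(6).to_csv(out / "targeting_per_replicate.csv", index=False)
            report.to_frame().round(6).to_csv(out / "targeting_summary.csv", index=False)
            with open(out / "targeting.json", "w") as fh:
                json.dump(
                    {
                        "factors": report.factors,
                        "factors_sd": {
                            k: (None if np.isnan(v) else v)
                            for k, v in report.factors_sd.items()
                        },
                        "section_level_factor": report.section_level_factor,
                        "n_replicates": report.n_replicates,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
            artifacts["targeting_factors"] = report.factors
        except Exception as exc:
            raise PipelineStageError("targeting", str(exc)) from exc
        _stage("targeting", t0)

    # -- stage: manifest -----------------------------------------------------
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "n_sections": len(per_section),
        "on_tissue_pixels": [int(m.n_pixels) for _r, _n, m, _i, _ro in per_section],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    artifacts["out_dir"] = str(out)
    artifacts["files"] = sorted(p.name for p in out.iterdir())
    return artifacts
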