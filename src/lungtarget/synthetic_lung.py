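"""Synthetic rat-lung MSI generator with known ground truth.

The phantom is a 2-D pseudo-section on a rectangular pixel grid: an elliptical
tissue area containing an alveolar bed perforated by small porosity holes,
a handful of circular airways (lumen surrounded by an epithelium ring and a
sub-epithelium ring) and circular blood vessels, framed by off-tissue
background.  Each compartment carries a characteristic spectrum over ~14 m/z
channels: the two drug channels of a dual-isotope design (inhaled drug and IV
isotopologue), the three endogenous histology markers (Heme b — vessels,
PC(32:0) — alveolar, PC(36:4) — bronchiolar), a set of structural lipids that
differentiate the compartments spectrally, and nuisance matrix ions present
everywhere.

The generator derives the inhaled-drug compartment means *from* the requested
ground-truth targeting factors (never both independently), so the true TF of
every scenario is exact by construction:

    inhaled_mean(c) = TF(c) * iv_mean(c) * plasma_inhaled / plasma_iv.

Noise model, applied in this order so that TIC normalization removes exactly
and only the drift term:

1. per-pixel biological variability — mean-one log-normal per channel,
2. per-airway deposition multipliers on the inhaled drug (patchy deposition),
3. Poisson counting noise on the resulting intensities,
4. a multiplicative per-pixel TIC drift factor on the whole spectrum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .analytes import AnalyteDefinition, D3_MASS_SHIFT
from .msi_core import MSIDataset, write_imzml
from .segmentation import ROISet

LABEL_CODES = {
    "background": 0,
    "alveolar": 1,
    "sub_epithelium": 2,
    "epithelium": 3,
    "lumen": 4,
    "vessel": 5,
}
LABEL_NAMES = {v: k for k, v in LABEL_CODES.items()}

#: ground-truth label -> ROI compartment name
TRUTH_ROI_MAPPING = {
    0: "lumen_or_background",
    1: "alveolar",
    2: "sub_epithelium",
    3: "epithelium",
    4: "lumen_or_background",
    5: "vessel",
}

COMPARTMENT_ORDER = ("background", "lumen", "alveolar", "sub_epithelium", "epithelium", "vessel")

_SALMETEROL_MH = 416.2795


def _default_channels() -> list[dict]:
    return [
        {"name": "salmeterol", "mz": _SALMETEROL_MH, "kind": "drug_inhaled"},
        {"name": "d3_salmeterol", "mz": _SALMETEROL_MH + D3_MASS_SHIFT, "kind": "drug_iv"},
        {"name": "heme_b", "mz": 616.1773, "kind": "marker_vessel"},
        {"name": "pc_32_0", "mz": 734.5694, "kind": "marker_alveolar"},
        {"name": "pc_36_4", "mz": 782.5694, "kind": "marker_bronchiolar"},
        {"name": "lpc_16_0", "mz": 496.3398, "kind": "endogenous"},
        {"name": "sm_34_1", "mz": 703.5748, "kind": "endogenous"},
        {"name": "pc_34_2", "mz": 758.5694, "kind": "endogenous"},
        {"name": "pc_34_1", "mz": 760.5851, "kind": "endogenous"},
        {"name": "pe_38_4", "mz": 768.5538, "kind": "endogenous"},
        {"name": "pc_38_6", "mz": 806.5694, "kind": "endogenous"},
        {"name": "matrix_331", "mz": 331.0450, "kind": "matrix"},
        {"name": "matrix_551", "mz": 551.1608, "kind": "matrix"},
        {"name": "matrix_573", "mz": 573.1427, "kind": "matrix"},
    ]


def _default_channel_means() -> dict[str, dict[str, float]]:
    # order: background, lumen, alveolar, sub_epithelium, epithelium, vessel
    raw = {
        "d3_salmeterol": (0, 0, 120, 60, 35, 100),
        "heme_b": (0, 0, 40, 25, 8, 600),
        "pc_32_0": (0, 60, 700, 120, 60, 80),
        "pc_36_4": (0, 8, 70, 320, 620, 60),
        "lpc_16_0": (0, 80, 180, 60, 40, 50),
        "sm_34_1": (0, 5, 60, 120, 450, 90),
        "pc_34_2": (0, 0, 160, 320, 120, 100),
        "pc_34_1": (0, 10, 300, 120, 260, 120),
        "pe_38_4": (0, 0, 90, 260, 60, 70),
        "pc_38_6": (0, 0, 140, 60, 160, 40),
        "matrix_331": (25, 20, 30, 30, 30, 30),
        "matrix_551": (12, 10, 15, 15, 15, 15),
        "matrix_573": (6, 8, 8, 8, 8, 8),
    }
    return {
        name: dict(zip(COMPARTMENT_ORDER, map(float, values)))
        for name, values in raw.items()
    }


@dataclass
class SyntheticScenario:
    """Full parameterization of the virtual lung section.

    Geometry is in pixels on a ``grid_size`` grid at ``pixel_size`` µm; the
    tissue ellipse has semi-axes ``section_axes_frac`` × grid dimensions.
    Intensity tables are arbitrary MSI units; the inhaled-drug means in the
    three quantified compartments are derived from ``ground_truth_tf`` (see
    module docstring), with direct values only for lumen/vessel/background
    where no TF is defined.
    """

    grid_size: tuple[int, int] = (200, 200)
    pixel_size: float = 10.0
    mz_range: tuple[float, float] = (300.0, 1000.0)
    section_axes_frac: tuple[float, float] = (0.45, 0.45)
    n_airways: int = 5
    lumen_radius: tuple[float, float] = (6.0, 8.0)
    epithelium_thickness: float = 3.0
    subepithelium_thickness: float = 4.0
    n_vessels: int = 6
    vessel_radius: tuple[float, float] = (2.0, 4.0)
    alveolar_porosity: float = 0.015
    hole_radius: tuple[float, float] = (1.5, 2.5)

    channels: list[dict] = field(default_factory=_default_channels)
    channel_means: dict[str, dict[str, float]] = field(default_factory=_default_channel_means)
    inhaled_other_means: dict[str, float] = field(
        default_factory=lambda: {"background": 0.0, "lumen": 60.0, "vessel": 25.0}
    )
    ground_truth_tf: dict[str, float] = field(
        default_factory=lambda: {"alveolar": 5.0, "sub_epithelium": 31.0, "epithelium": 45.0}
    )
    plasma: dict[str, float] = field(default_factory=lambda: {"inhaled": 2.0, "iv": 8.0})
    plasma_unit: str = "nmol/L"

    bio_sigma: dict[str, float] = field(
        default_factory=lambda: {
            "drug_inhaled": 0.7,
            "drug_iv": 0.25,
            "marker": 0.2,
            "endogenous": 0.2,
            "matrix": 0.15,
        }
    )
    airway_deposition_sigma: float = 0.15
    tic_drift_sigma: float = 0.3
    counting_noise: bool = True

    def __post_init__(self) -> None:
        ny, nx = self.grid_size
        r_out = self.lumen_radius[1] + self.epithelium_thickness + self.subepithelium_thickness
        if 2 * r_out >= min(ny, nx) * min(self.section_axes_frac):
            raise ValueError("airway outer radius does not fit the tissue ellipse")
        for name, table in self.channel_means.items():
            for compartment, mean in table.items():
                if mean < 0:
                    raise ValueError(f"negative mean for {name} in {compartment}")
        for route in ("inhaled", "iv"):
            if self.plasma[route] <= 0:
                raise ValueError("plasma concentrations must be > 0")

    # -- channel helpers -----------------------------------------------------

    @property
    def channel_names(self) -> list[str]:
        return [c["name"] for c in self.channels]

    def channel_kind(self, name: str) -> str:
        for c in self.channels:
            if c["name"] == name:
                return c["kind"]
        raise KeyError(name)

    @property
    def inhaled_channel(self) -> str:
        return next(c["name"] for c in self.channels if c["kind"] == "drug_inhaled")

    @property
    def iv_channel(self) -> str:
        return next(c["name"] for c in self.channels if c["kind"] == "drug_iv")

    def analyte_definitions(self, tolerance: float = 0.1) -> list[AnalyteDefinition]:
        role_map = {
            "drug_inhaled": "drug_inhaled",
            "drug_iv": "drug_iv",
            "marker_vessel": "marker_vessel",
            "marker_alveolar": "marker_alveolar",
            "marker_bronchiolar": "marker_bronchiolar",
        }
        return [
            AnalyteDefinition(
                c["name"], c["mz"], tolerance=tolerance,
                role=role_map.get(c["kind"], "other"),
            )
            for c in self.channels
        ]

    # -- derived intensities -------------------------------------------------

    def inhaled_means(self) -> dict[str, float]:
        """Inhaled-drug mean per compartment, derived from the requested TFs."""
        ratio = self.plasma["inhaled"] / self.plasma["iv"]
        iv = self.channel_means[self.iv_channel]
        means = dict(self.inhaled_other_means)
        for compartment, tf in self.ground_truth_tf.items():
            means[compartment] = tf * iv[compartment] * ratio
        return means

    def mean_table(self) -> dict[str, dict[str, float]]:
        """Complete channel × compartment mean table, inhaled drug included."""
        table = {name: dict(vals) for name, vals in self.channel_means.items()}
        table[self.inhaled_channel] = self.inhaled_means()
        return table

    def sigma_for(self, channel: str) -> float:
        kind = self.channel_kind(channel)
        if kind.startswith("marker"):
            kind = "marker"
        return float(self.bio_sigma.get(kind, 0.0))

    def without_noise(self) -> "SyntheticScenario":
        """Copy with every stochastic intensity term switched off."""
        return dataclasses.replace(
            self,
            channels=[dict(c) for c in self.channels],
            channel_means={k: dict(v) for k, v in self.channel_means.items()},
            inhaled_other_means=dict(self.inhaled_other_means),
            ground_truth_tf=dict(self.ground_truth_tf),
            plasma=dict(self.plasma),
            bio_sigma={k: 0.0 for k in self.bio_sigma},
            airway_deposition_sigma=0.0,
            tic_drift_sigma=0.0,
            counting_noise=False,
        )

    # -- serialization -------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        for key in ("grid_size", "mz_range", "section_axes_frac", "lumen_radius",
                    "vessel_radius", "hole_radius"):
            payload[key] = list(payload[key])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        payload = yaml.safe_load(Path(path).read_text())
        for key in ("grid_size", "mz_range", "section_axes_frac", "lumen_radius",
                    "vessel_radius", "hole_radius"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def default_scenario() -> SyntheticScenario:
    """The documented default virtual lung.

    Ground-truth targeting factors 5 (alveolar), 31 (sub-epithelium) and 45
    (epithelium); patchy inhaled deposition versus smooth IV distribution;
    each histology marker enriched in its own compartment.  All intensity and
    plasma values are scenario design, not measured data.
    """
    return SyntheticScenario()


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass
class LungGeometry:
    """Ground-truth compartment labels plus airway bookkeeping."""

    labels: np.ndarray
    airway_id: np.ndarray  # -1 outside airways; airway index on lumen+rings
    n_airways: int
    n_vessels: int
    seed: int

    def pixel_counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == code).sum())
            for name, code in LABEL_CODES.items()
        }

    @property
    def tissue_mask(self) -> np.ndarray:
        return np.isin(self.labels, [1, 2, 3, 5])


def generate_geometry(scenario: SyntheticScenario, seed: int = 0) -> LungGeometry:
    """Place airways, vessels and porosity holes in the elliptical section.

    Airways and vessels are non-overlapping circles placed by rejection
    sampling (bounded retries); deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    ny, nx = scenario.grid_size
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    b, a = scenario.section_axes_frac[0] * ny, scenario.section_axes_frac[1] * nx
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)

    inside = ((yy - cy) / b) ** 2 + ((xx - cx) / a) ** 2 <= 1.0
    labels = np.where(inside, LABEL_CODES["alveolar"], LABEL_CODES["background"]).astype(np.int32)
    airway_id = np.full((ny, nx), -1, dtype=np.int32)

    def sample_center(margin: float, occupied: list[tuple[float, float, float]], retries: int = 500):
        for _ in range(retries):
            y = rng.uniform(cy - b, cy + b)
            x = rng.uniform(cx - a, cx + a)
            if ((y - cy) / (b - margin)) ** 2 + ((x - cx) / (a - margin)) ** 2 > 1.0:
                continue
            if all(np.hypot(y - oy, x - ox) > margin + orad + 2.0 for oy, ox, orad in occupied):
                return y, x
        raise RuntimeError(
            "could not place requested structures without overlap; "
            "reduce counts or radii"
        )

    occupied: list[tuple[float, float, float]] = []
    for i in range(scenario.n_airways):
        r_lumen = rng.uniform(*scenario.lumen_radius)
        r_epi = r_lumen + scenario.epithelium_thickness
        r_out = r_epi + scenario.subepithelium_thickness
        y, x = sample_center(r_out + 1.0, occupied)
        occupied.append((y, x, r_out))
        dist = np.hypot(yy - y, xx - x)
        labels[(dist <= r_out) & inside] = LABEL_CODES["sub_epithelium"]
        labels[(dist <= r_epi) & inside] = LABEL_CODES["epithelium"]
        labels[(dist <= r_lumen) & inside] = LABEL_CODES["lumen"]
        airway_id[(dist <= r_out) & inside] = i

    for _ in range(scenario.n_vessels):
        r = rng.uniform(*scenario.vessel_radius)
        y, x = sample_center(r + 1.0, occupied)
        occupied.append((y, x, r))
        dist = np.hypot(yy - y, xx - x)
        labels[(dist <= r) & inside] = LABEL_CODES["vessel"]

    if scenario.alveolar_porosity > 0:
        alveolar_area = int((labels == LABEL_CODES["alveolar"]).sum())
        mean_hole = np.pi * np.mean(np.square(scenario.hole_radius))
        n_holes = int(round(scenario.alveolar_porosity * alveolar_area / mean_hole))
        for _ in range(n_holes):
            r = rng.uniform(*scenario.hole_radius)
            y = rng.uniform(cy - b, cy + b)
            x = rng.uniform(cx - a, cx + a)
            dist = np.hypot(yy - y, xx - x)
            hole = (dist <= r) & (labels == LABEL_CODES["alveolar"])
            labels[hole] = LABEL_CODES["background"]

    return LungGeometry(
        labels=labels,
        airway_id=airway_id,
        n_airways=scenario.n_airways,
        n_vessels=scenario.n_vessels,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Spectrum simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the pipeline is asked to recover."""

    labels: np.ndarray
    noiseless_channels: dict[str, np.ndarray]
    tf: dict[str, float]
    plasma: dict[str, float]
    plasma_unit: str
    geometry: LungGeometry

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.geometry.tissue_mask

    def roiset(self) -> ROISet:
        """ROISet built from the true labels (bypassing segmentation)."""
        return ROISet.from_label_grid(self.labels, TRUTH_ROI_MAPPING)


def simulate_msi(
    scenario: SyntheticScenario,
    geometry: LungGeometry | None = None,
    seed: int = 0,
    channel_scale: Mapping[str, float] | None = None,
    write_path: str | Path | None = None,
) -> tuple[MSIDataset, GroundTruth]:
    """Simulate one dual-dosed section as a continuous-mode MSI dataset.

    ``channel_scale`` multiplies selected channels' means (used by the kinetic
    series to follow a concentration-time curve).  With every noise term off
    the extracted channel images equal the noiseless truth exactly.
    """
    if geometry is None:
        geometry = generate_geometry(scenario, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7151]))
    ny, nx = scenario.grid_size
    labels = geometry.labels
    n_pixels = ny * nx

    mean_table = scenario.mean_table()
    if channel_scale:
        mean_table = {
            name: {c: m * float(channel_scale.get(name, 1.0)) for c, m in vals.items()}
            for name, vals in mean_table.items()
        }

    order = np.argsort([c["mz"] for c in scenario.channels])
    names = [scenario.channels[i]["name"] for i in order]
    mz_axis = np.array([scenario.channels[i]["mz"] for i in order])

    noiseless = {}
    matrix = np.zeros((ny, nx, len(names)), dtype=np.float64)
    for j, name in enumerate(names):
        mean_map = np.zeros((ny, nx))
        for compartment, code in LABEL_CODES.items():
            mean_map[labels == code] = mean_table[name][compartment]
        noiseless[name] = mean_map
        field_ = mean_map.copy()

        if name == scenario.inhaled_channel and scenario.airway_deposition_sigma > 0:
            s = scenario.airway_deposition_sigma
            factors = np.exp(rng.normal(-s * s / 2, s, size=geometry.n_airways))
            in_airway = geometry.airway_id >= 0
            field_[in_airway] *= factors[geometry.airway_id[in_airway]]

        s = scenario.sigma_for(name)
        if s > 0:
            field_ *= np.exp(rng.normal(-s * s / 2, s, size=(ny, nx)))
        matrix[:, :, j] = field_

    flat = matrix.reshape(n_pixels, len(names))
    if scenario.counting_noise:
        flat = rng.poisson(flat).astype(np.float64)
    if scenario.tic_drift_sigma > 0:
        s = scenario.tic_drift_sigma
        drift = np.exp(rng.normal(-s * s / 2, s, size=n_pixels))  # mean-one drift
        flat = flat * drift[:, None]

    xg, yg = np.meshgrid(np.arange(1, nx + 1), np.arange(1, ny + 1))
    coords = np.column_stack([xg.ravel(), yg.ravel()])
    dataset = MSIDataset(
        coords,
        mode="continuous",
        pixel_size=scenario.pixel_size,
        polarity="positive",
        mz_range=scenario.mz_range,
        metadata={"scenario_seed": seed},
        mz_axis=mz_axis,
        intensity_matrix=flat,
    )
    truth = GroundTruth(
        labels=labels,
        noiseless_channels=noiseless,
        tf=dict(scenario.ground_truth_tf),
        plasma=dict(scenario.plasma),
        plasma_unit=scenario.plasma_unit,
        geometry=geometry,
    )
    if write_path is not None:
        write_imzml(dataset, write_path)
    return dataset, truth


def simulate_replicates(
    scenario: SyntheticScenario, n: int, seed: int = 0
) -> list[tuple[MSIDataset, GroundTruth]]:
    """Simulate n replicate sections with independent geometry and noise."""
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)
    return [simulate_msi(scenario, seed=int(s)) for s in child_seeds]


def biphasic_concentration(
    times_min: Sequence[float],
    fast_amplitude: float = 0.8,
    fast_rate: float = 0.12,
    slow_amplitude: float = 0.2,
    slow_rate: float = 0.01,
) -> np.ndarray:
    """Biphasic lung concentration-time curve (fast + slow exponential)."""
    t = np.asarray(times_min, dtype=np.float64)
    return fast_amplitude * np.exp(-fast_rate * t) + slow_amplitude * np.exp(-slow_rate * t)


def simulate_kinetic_series(
    scenario: SyntheticScenario,
    times_min: Sequence[float],
    seed: int = 0,
    **curve_params,
) -> tuple[list[tuple[float, MSIDataset, GroundTruth]], np.ndarray]:
    """Sections at several post-dose times with the inhaled channel following
    a biphasic concentration curve; returns the sections and the true curve."""
    conc = biphasic_concentration(times_min, **curve_params)
    geometry = generate_geometry(scenario, seed=seed)
    out = []
    for i, (t, c) in enumerate(zip(times_min, conc)):
        dataset, truth = simulate_msi(
            scenario,
            geometry=geometry,
            seed=seed + 1000 * (i + 1),
            channel_scale={scenario.inhaled_channel: float(c)},
        )
        out.append((float(t), dataset, truth))
    return out, conc
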