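"""Plasma-normalized regional exposure and the lung targeting factor.

The dual-isotope design images the inhaled drug and its deuterated
isotopologue (given IV) in the same section, so both routes share tissue,
section processing and detection.  For a compartment c and route r, the
plasma-normalized exposure is

    E_r(c) = mean MSI intensity of the route-r drug channel in c
             / plasma concentration of the route-r drug,

and the lung targeting factor is the fold gain of inhaled delivery over IV at
matched systemic exposure:

    TF(c) = E_inhaled(c) / E_iv(c).

TF is dimensionless and invariant to any common rescaling of both channels'
intensity units.  A section-level factor is computed the same way over the
whole tissue mask, with no regional breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .analytes import AnalyteDefinition
from .msi_core import IonImage, MSIDataset, TissueMask, extract_ion_image
from .segmentation import QUANTIFIED_COMPARTMENTS, ROISet
from .spatial_stats import roi_mean_intensity

ROUTES = ("inhaled", "iv")


@dataclass(frozen=True)
class PlasmaSample:
    """Plasma concentration of one drug species for one administration route."""

    route: str
    analyte: str
    concentration: float
    unit: str = "nmol/L"
    time_post_dose: float | None = None

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.concentration <= 0:
            raise ValueError("plasma concentration must be > 0")


def normalized_exposure(mean_intensity: float, plasma_concentration: float) -> float:
    """MSI mean intensity divided by plasma concentration (intensity·volume/amount)."""
    if plasma_concentration <= 0:
        raise ValueError("plasma concentration must be > 0")
    if mean_intensity < 0:
        raise ValueError("mean intensity must be >= 0")
    return mean_intensity / plasma_concentration


def targeting_factor(exposure_inhaled: float, exposure_iv: float) -> float:
    """Fold gain of inhaled over IV exposure at matched plasma levels."""
    if exposure_iv <= 0:
        raise ValueError("IV exposure must be > 0 to form a targeting factor")
    return exposure_inhaled / exposure_iv


@dataclass
class TargetingResult:
    """Per-compartment targeting report aggregated over replicate sections.

    ``per_replicate`` holds one row per (replicate, compartment) with raw mean
    intensities, normalized exposures and the replicate's targeting factor;
    the ``factors``/``factors_sd`` dicts aggregate across replicates
    (per-replicate TF averaged, preserving biological-replicate variance).
    """

    per_replicate: pd.DataFrame
    factors: dict[str, float]
    factors_sd: dict[str, float]
    section_level_factor: float
    section_level_sd: float
    n_replicates: int
    response_factor: float = 1.0
    plasma: dict[str, PlasmaSample] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compartment": c,
                "targeting_factor": self.factors[c],
                "targeting_factor_sd": self.factors_sd[c],
                "n_replicates": self.n_replicates,
            }
            for c in self.factors
        ]
        rows.append(
            {
                "compartment": "whole_section",
                "targeting_factor": self.section_level_factor,
                "targeting_factor_sd": self.section_level_sd,
                "n_replicates": self.n_replicates,
            }
        )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        self.to_frame().to_json(path, orient="records", indent=2)


def compute_targeting_report(
    sections: Sequence[tuple[MSIDataset, ROISet, TissueMask]],
    inhaled: AnalyteDefinition,
    iv: AnalyteDefinition,
    plasma: Mapping[str, PlasmaSample | float],
    response_factor: float = 1.0,
    aggregate: str = "per_replicate",
) -> TargetingResult:
    """Full targeting analysis over replicate dual-dosed sections.

    Each section must be TIC-normalized and carry an ROISet containing all
    three quantified compartments plus a tissue mask for the section-level
    factor.  ``plasma`` maps route → concentration (or
    :class:`PlasmaSample`); units must match between routes.
    ``response_factor`` multiplies the IV channel to correct a differential
    ionization efficiency between isotopologues (default 1: no correction).

    ``aggregate="per_replicate"`` computes a TF per section then averages;
    ``aggregate="pooled"`` averages intensities across sections first.
    """
    if not sections:
        raise ValueError("no sections provided")
    if aggregate not in ("per_replicate", "pooled"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")

    plasma_samples: dict[str, PlasmaSample] = {}
    for route in ROUTES:
        if route not in plasma:
            raise ValueError(f"missing plasma concentration for route {route!r}")
        p = plasma[route]
        if not isinstance(p, PlasmaSample):
            p = PlasmaSample(route=route, analyte="", concentration=float(p))
        plasma_samples[route] = p
    if plasma_samples["inhaled"].unit != plasma_samples["iv"].unit:
        raise ValueError(
            "plasma units differ between routes: "
            f"{plasma_samples['inhaled'].unit!r} vs {plasma_samples['iv'].unit!r}"
        )

    rows = []
    for rep, (dataset, roiset, tissue_mask) in enumerate(sections):
        if not dataset.metadata.get("tic_normalized", False):
            raise ValueError(f"replicate {rep}: dataset is not TIC-normalized")
        if not roiset.has_quantified_compartments():
            missing = [
                c for c in QUANTIFIED_COMPARTMENTS if not roiset.mask_for(c).any()
            ]
            raise ValueError(f"replicate {rep}: missing compartments {missing}")
        img_inh = extract_ion_image(dataset, inhaled)
        img_iv = extract_ion_image(dataset, iv)
        for compartment in QUANTIFIED_COMPARTMENTS:
            roi = roiset.mask_for(compartment)
            mean_inh, n = roi_mean_intensity(img_inh, roi)
            mean_iv, _ = roi_mean_intensity(img_iv, roi)
            rows.append(_row(rep, compartment, mean_inh, mean_iv, n, plasma_samples, response_factor))
        mean_inh, n = roi_mean_intensity(img_inh, tissue_mask.grid)
        mean_iv, _ = roi_mean_intensity(img_iv, tissue_mask.grid)
        rows.append(_row(rep, "whole_section", mean_inh, mean_iv, n, plasma_samples, response_factor))

    table = pd.DataFrame(rows)
    n_reps = len(sections)

    factors: dict[str, float] = {}
    factors_sd: dict[str, float] = {}
    for compartment in (*QUANTIFIED_COMPARTMENTS, "whole_section"):
        sub = table[table["compartment"] == compartment]
        if aggregate == "per_replicate":
            tfs = sub["targeting_factor"].to_numpy()
            factors[compartment] = float(tfs.mean())
            factors_sd[compartment] = float(tfs.std(ddof=1)) if n_reps > 1 else np.nan
        else:
            exp_inh = sub["exposure_inhaled"].mean()
            exp_iv = sub["exposure_iv"].mean()
            factors[compartment] = targeting_factor(exp_inh, exp_iv)
            factors_sd[compartment] = np.nan

    section_tf = factors.pop("whole_section")
    section_sd = factors_sd.pop("whole_section")
    return TargetingResult(
        per_replicate=table,
        factors=factors,
        factors_sd=factors_sd,
        section_level_factor=section_tf,
        section_level_sd=section_sd,
        n_replicates=n_reps,
        response_factor=response_factor,
        plasma=plasma_samples,
    )


def _row(rep, compartment, mean_inh, mean_iv, n, plasma_samples, response_factor):
    exp_inh = normalized_exposure(mean_inh, plasma_samples["inhaled"].concentration)
    exp_iv = normalized_exposure(
        mean_iv * response_factor, plasma_samples["iv"].concentration
    )
    return {
        "replicate": rep,
        "compartment": compartment,
        "mean_intensity_inhaled": mean_inh,
        "mean_intensity_iv": mean_iv,
        "n_pixels": n,
        "exposure_inhaled": exp_inh,
        "exposure_iv": exp_iv,
        "targeting_factor": targeting_factor(exp_inh, exp_iv),
    }


def plot_targeting_report(result: TargetingResult, path) -> None:
    """Three-panel bar chart: raw regional means, plasma-normalized exposures,
    and targeting factors per compartment (mean ± sd over replicates)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result.per_replicate
    compartments = list(QUANTIFIED_COMPARTMENTS)
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    width = 0.38
    x = np.arange(len(compartments))
    for ax, column, title in zip(
        axes[:2],
        ("mean_intensity", "exposure"),
        ("mean MSI intensity", "plasma-normalized exposure"),
    ):
        for offset, route in ((0.0, "inhaled"), (width, "iv")):
            col = f"{column}_{route}"
            means = [
                table.loc[table["compartment"] == c, col].mean() for c in compartments
            ]
            sds = [
                table.loc[table["compartment"] == c, col].std(ddof=1)
                if result.n_replicates > 1 else 0.0
                for c in compartments
            ]
            ax.bar(x + offset, means, width, yerr=sds, capsize=3, label=route)
        ax.set_xticks(x + width / 2, compartments, rotation=20)
        ax.set_title(title)
        ax.legend(fontsize=8)
    tf = [result.factors[c] for c in compartments]
    tf_sd = [
        0.0 if np.isnan(result.factors_sd[c]) else result.factors_sd[c]
        for c in compartments
    ]
    axes[2].bar(x, tf, width * 1.6, yerr=tf_sd, capsize=3, color="tab:green")
    axes[2].set_xticks(x, compartments, rotation=20)
    axes[2].set_title("lung targeting factor (inhaled / IV)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def kinetic_profile(
    datasets_by_time: Sequence[tuple[float, MSIDataset]],
    masks: Sequence[TissueMask],
    analyte: AnalyteDefinition,
    reference_series: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Whole-section mean intensity of one analyte across time points.

    Each dataset should be TIC-normalized.  When a companion concentration
    series (e.g. from homogenate bioanalysis) is supplied it is attached after
    least-squares rescaling to the MSI profile, and the Pearson r between the
    two series is stored in ``DataFrame.attrs["pearson_r"]``.
    """
    if len(datasets_by_time) < 2:
        raise ValueError("kinetic_profile needs at least 2 time points")
    if len(masks) != len(datasets_by_time):
        raise ValueError("one mask per dataset required")
    times, means = [], []
    for (t, dataset), mask in zip(datasets_by_time, masks):
        img = extract_ion_image(dataset, analyte)
        mean, _n = roi_mean_intensity(img, mask.grid)
        times.append(float(t))
        means.append(mean)
    frame = pd.DataFrame({"time_min": times, "mean_intensity": means})
    if reference_series is not None:
        ref = np.asarray(reference_series, dtype=np.float64)
        if ref.size != len(times):
            raise ValueError("reference series length does not match time points")
        msi = np.asarray(means)
        scale = float(msi @ ref / (ref @ ref)) if (ref @ ref) > 0 else 1.0
        frame["reference_scaled"] = ref * scale
        if np.ptp(ref) > 0 and np.ptp(msi) > 0:
            frame.attrs["pearson_r"] = float(stats.pearsonr(msi, ref)[0])
    return frame
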