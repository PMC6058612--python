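"""Core MSI data model and I/O.

An :class:`MSIDataset` is a set of pixels on an integer grid, each carrying a
mass spectrum (m/z values in Da, intensities in arbitrary counts).  Continuous
mode shares one m/z axis across all pixels and is stored as a dense
``(n_pixels, n_mz)`` intensity matrix; processed mode keeps per-pixel arrays.

Coordinates follow the imzML convention: 1-based pixel indices, x increasing
rightward and y downward.  Internal 2-D grids are 0-based ``(row, col)`` =
``(y - y_min, x - x_min)``; the conversion lives only in this module.

The operations here are the pre-statistics stages of the pipeline:

* :func:`read_imzml` / :func:`write_imzml` — imzML 1.1 + ibd interchange with
  UUID and SHA-1 integrity checks,
* :func:`tic_normalize` — total-ion-count normalization compensating per-pixel
  signal instability,
* :func:`extract_ion_image` — summed intensity within an analyte m/z window,
* :func:`compute_tissue_mask` — restriction of whole-section statistics to
  on-tissue pixels.
"""

from __future__ import annotations

import hashlib
import logging
import uuid as uuid_mod
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .analytes import AnalyteDefinition

logger = logging.getLogger(__name__)

MZML_NS = "http://psi.hupo.org/ms/mzml"


class ImzMLIntegrityError(RuntimeError):
    """Raised when an imzML/ibd pair fails an integrity check."""


class EmptyDatasetError(ValueError):
    """Raised for datasets or masks with no usable pixels."""


class MSIDataset:
    """Pixel grid with per-pixel mass spectra and acquisition metadata.

    Parameters
    ----------
    coordinates:
        ``(n_pixels, 2)`` integer array of 1-based imzML ``(x, y)`` positions.
    mode:
        ``"continuous"`` (shared m/z axis, ``intensity_matrix`` required) or
        ``"processed"`` (per-pixel ``mz_arrays`` / ``intensity_arrays``).
    pixel_size:
        Micrometres per pixel (isotropic).
    mz_range:
        Acquired mass range ``(lo, hi)`` in Da.
    """

    def __init__(
        self,
        coordinates: np.ndarray,
        *,
        mode: str = "continuous",
        pixel_size: float = 1.0,
        polarity: str = "positive",
        mz_range: tuple[float, float] | None = None,
        metadata: dict | None = None,
        mz_axis: np.ndarray | None = None,
        intensity_matrix: np.ndarray | None = None,
        mz_arrays: Sequence[np.ndarray] | None = None,
        intensity_arrays: Sequence[np.ndarray] | None = None,
    ) -> None:
        self.coordinates = np.asarray(coordinates, dtype=np.int64).reshape(-1, 2)
        self.mode = mode
        self.pixel_size = float(pixel_size)
        self.polarity = polarity
        self.metadata: dict = dict(metadata or {})
        if mode == "continuous":
            if mz_axis is None or intensity_matrix is None:
                raise ValueError("continuous mode requires mz_axis and intensity_matrix")
            self.mz_axis = np.asarray(mz_axis, dtype=np.float64)
            self.intensity_matrix = np.asarray(intensity_matrix, dtype=np.float64)
            self.mz_arrays = None
            self.intensity_arrays = None
        elif mode == "processed":
            if mz_arrays is None or intensity_arrays is None:
                raise ValueError("processed mode requires mz_arrays and intensity_arrays")
            self.mz_axis = None
            self.intensity_matrix = None
            self.mz_arrays = [np.asarray(m, dtype=np.float64) for m in mz_arrays]
            self.intensity_arrays = [np.asarray(i, dtype=np.float64) for i in intensity_arrays]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if mz_range is None:
            mz_range = self._data_mz_range()
        self.mz_range = (float(mz_range[0]), float(mz_range[1]))
        self.validate()

    # -- construction / validation -------------------------------------------------

    def _data_mz_range(self) -> tuple[float, float]:
        if self.mode == "continuous":
            if self.mz_axis.size == 0:
                return (0.0, 0.0)
            return (float(self.mz_axis.min()), float(self.mz_axis.max()))
        mins = [m.min() for m in self.mz_arrays if m.size]
        maxs = [m.max() for m in self.mz_arrays if m.size]
        if not mins:
            return (0.0, 0.0)
        return (float(min(mins)), float(max(maxs)))

    def validate(self) -> None:
        n = self.n_pixels
        if n == 0:
            raise EmptyDatasetError("empty dataset: no pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        uniq = {tuple(c) for c in self.coordinates.tolist()}
        if len(uniq) != n:
            raise ValueError("pixel coordinates are not unique")
        lo, hi = self.mz_range
        if self.mode == "continuous":
            if self.intensity_matrix.shape != (n, self.mz_axis.size):
                raise ValueError("intensity_matrix shape does not match pixels x mz axis")
            if self.intensity_matrix.size and self.intensity_matrix.min() < 0:
                raise ValueError("negative intensities present")
            if self.mz_axis.size and (self.mz_axis.min() < lo or self.mz_axis.max() > hi):
                raise ValueError("m/z axis extends outside mz_range")
        else:
            if len(self.mz_arrays) != n or len(self.intensity_arrays) != n:
                raise ValueError("per-pixel arrays do not match pixel count")
            for i, (m, y) in enumerate(zip(self.mz_arrays, self.intensity_arrays)):
                if m.shape != y.shape:
                    raise ValueError(f"pixel {i}: m/z and intensity lengths differ")
                if y.size and y.min() < 0:
                    raise ValueError(f"pixel {i}: negative intensities present")
                if m.size and (m.min() < lo or m.max() > hi):
                    raise ValueError(f"pixel {i}: m/z outside mz_range")

    # -- basic accessors -----------------------------------------------------------

    @property
    def n_pixels(self) -> int:
        return self.coordinates.shape[0]

    def spectrum(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        if self.mode == "continuous":
            return self.mz_axis, self.intensity_matrix[i]
        return self.mz_arrays[i], self.intensity_arrays[i]

    def tic(self) -> np.ndarray:
        """Total ion count per pixel, in acquisition order."""
        if self.mode == "continuous":
            return self.intensity_matrix.sum(axis=1)
        return np.array([y.sum() for y in self.intensity_arrays])

    # -- grid mapping --------------------------------------------------------------

    @property
    def grid_origin(self) -> tuple[int, int]:
        """(x_min, y_min) of the pixel bounding box, 1-based imzML units."""
        return (int(self.coordinates[:, 0].min()), int(self.coordinates[:, 1].min()))

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the bounding-box grid."""
        x, y = self.coordinates[:, 0], self.coordinates[:, 1]
        return (int(y.max() - y.min() + 1), int(x.max() - x.min() + 1))

    def pixel_rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based (row, col) grid position of every pixel."""
        x0, y0 = self.grid_origin
        return (self.coordinates[:, 1] - y0, self.coordinates[:, 0] - x0)

    def to_grid(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a per-pixel vector onto the 2-D grid; absent cells get ``fill``."""
        values = np.asarray(values, dtype=np.float64)
        grid = np.full(self.grid_shape, fill, dtype=np.float64)
        rows, cols = self.pixel_rows_cols()
        grid[rows, cols] = values
        return grid

    def acquired_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid_shape, dtype=bool)
        rows, cols = self.pixel_rows_cols()
        mask[rows, cols] = True
        return mask


@dataclass
class IonImage:
    """2-D intensity map for one analyte window on the dataset grid.

    ``grid`` holds summed window intensity per pixel; cells never acquired are
    NaN (missing), which is distinct from an acquired pixel with zero signal.
    """

    grid: np.ndarray
    analyte: AnalyteDefinition
    normalized: bool
    pixel_size: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.grid)

    def values(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Finite pixel values, optionally restricted to a boolean mask."""
        sel = self.finite_mask if mask is None else (self.finite_mask & mask)
        return self.grid[sel]

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.grid, delimiter=",", fmt="%.8g")

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.grid.astype(np.float32))


@dataclass
class TissueMask:
    """Boolean on-tissue mask aligned with the dataset grid."""

    grid: np.ndarray
    provenance: str = "threshold"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if not self.grid.any():
            raise EmptyDatasetError("tissue mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.grid.sum())

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.grid.astype(np.uint8), delimiter=",", fmt="%d")

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.grid.astype(np.uint8) * np.uint8(255))


# ---------------------------------------------------------------------------
# imzML I/O
# ---------------------------------------------------------------------------

def _ibd_path(imzml_path: Path) -> Path:
    for suffix in (".ibd", ".IBD"):
        cand = imzml_path.with_suffix(suffix)
        if cand.exists():
            return cand
    return imzml_path.with_suffix(".ibd")


def write_imzml(dataset: MSIDataset, path: str | Path) -> None:
    """Write a dataset as imzML 1.1 + ibd (float64 m/z and intensities).

    Pixel size and acquired m/z range are stored as parameters in the scan
    settings so that :func:`read_imzml` restores them.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    with ImzMLWriter(
        str(path),
        mode=dataset.mode,
        mz_dtype=np.float64,
        intensity_dtype=np.float64,
        polarity=dataset.polarity,
    ) as writer:
        for i, (x, y) in enumerate(dataset.coordinates):
            mzs, ints = dataset.spectrum(i)
            writer.addSpectrum(mzs, ints, (int(x), int(y), 1))
    _inject_scan_settings(path, dataset.pixel_size, dataset.mz_range)


def _inject_scan_settings(
    path: Path, pixel_size: float, mz_range: tuple[float, float]
) -> None:
    """Add pixel size (IMS cvParams) and m/z range (userParams) to the XML."""
    ET.register_namespace("", MZML_NS)
    tree = ET.parse(path)
    scan = tree.getroot().find(f".//{{{MZML_NS}}}scanSettings")
    if scan is None:  # pragma: no cover - writer always emits scanSettings
        return
    for accession, name in (("IMS:1000046", "pixel size (x)"), ("IMS:1000047", "pixel size y")):
        ET.SubElement(
            scan,
            f"{{{MZML_NS}}}cvParam",
            cvRef="IMS",
            accession=accession,
            name=name,
            value=repr(float(pixel_size)),
        )
    for name, value in (("mz range lo", mz_range[0]), ("mz range hi", mz_range[1])):
        ET.SubElement(
            scan, f"{{{MZML_NS}}}userParam", name=name, value=repr(float(value))
        )
    tree.write(path, xml_declaration=True, encoding="ISO-8859-1")


def _read_scan_settings(path: Path) -> dict:
    tree = ET.parse(path)
    out: dict = {}
    scan = tree.getroot().find(f".//{{{MZML_NS}}}scanSettings")
    if scan is None:
        return out
    for el in scan.iter():
        name = el.get("name")
        if name in ("pixel size (x)", "mz range lo", "mz range hi"):
            out["pixel size x" if name == "pixel size (x)" else name] = float(el.get("value"))
    return out


def _verify_ibd(parser, ibd: Path) -> None:
    params = parser.metadata.file_description.param_by_name
    declared = params.get("universally unique identifier")
    if declared is not None:
        with open(ibd, "rb") as fh:
            actual = uuid_mod.UUID(bytes=fh.read(16))
        if uuid_mod.UUID(str(declared).strip("{}")) != actual:
            raise ImzMLIntegrityError(
                f"ibd UUID {actual} does not match imzML declaration {declared}"
            )
    declared_sha = params.get("ibd SHA-1")
    if declared_sha is not None:
        sha = hashlib.sha1()
        with open(ibd, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                sha.update(chunk)
        if sha.hexdigest().lower() != str(declared_sha).lower():
            raise ImzMLIntegrityError(
                f"ibd SHA-1 mismatch: file {sha.hexdigest()} vs declared {declared_sha}"
            )


def read_imzml(path: str | Path, verify: bool = True) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Verifies that the ibd companion exists, that its UUID matches the imzML
    declaration and (when declared) that its SHA-1 checksum is intact.
    Negative intensities and empty files are rejected.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"imzML file not found: {path}")
    ibd = _ibd_path(path)
    if not ibd.exists():
        raise ImzMLIntegrityError(f"missing ibd companion for {path}")

    parser = ImzMLParser(str(path))
    try:
        if verify:
            _verify_ibd(parser, ibd)
        params = parser.metadata.file_description.param_by_name
        mode = "processed" if "processed" in params else "continuous"
        n = len(parser.coordinates)
        if n == 0:
            raise EmptyDatasetError(f"empty dataset: {path} contains no pixels")
        coords = np.array([(x, y) for x, y, _z in parser.coordinates], dtype=np.int64)
        scan = _read_scan_settings(path)
        pixel_size = scan.get("pixel size x", 1.0)
        mz_range = None
        if "mz range lo" in scan and "mz range hi" in scan:
            mz_range = (scan["mz range lo"], scan["mz range hi"])
        polarity = parser.polarity or "positive"

        if mode == "continuous":
            mz_axis, first = parser.getspectrum(0)
            matrix = np.empty((n, mz_axis.size), dtype=np.float64)
            matrix[0] = first
            for i in range(1, n):
                _mz, ints = parser.getspectrum(i)
                matrix[i] = ints
            return MSIDataset(
                coords,
                mode="continuous",
                pixel_size=pixel_size,
                polarity=polarity,
                mz_range=mz_range,
                mz_axis=mz_axis,
                intensity_matrix=matrix,
            )
        mzs, ints = [], []
        for i in range(n):
            m, y = parser.getspectrum(i)
            mzs.append(np.asarray(m, dtype=np.float64))
            ints.append(np.asarray(y, dtype=np.float64))
        return MSIDataset(
            coords,
            mode="processed",
            pixel_size=pixel_size,
            polarity=polarity,
            mz_range=mz_range,
            mz_arrays=mzs,
            intensity_arrays=ints,
        )
    finally:
        if hasattr(parser, "m") and parser.m is not None:
            parser.m.close()


# ---------------------------------------------------------------------------
# TIC normalization
# ---------------------------------------------------------------------------

def tic_normalize(dataset: MSIDataset, target: float | None = None) -> MSIDataset:
    """Rescale every pixel spectrum so its total ion count equals ``target``.

    ``target`` defaults to the mean raw TIC over pixels with signal, which
    preserves the global intensity scale.  Pixels with zero TIC carry no
    spectral information; they are dropped from the output and their count is
    logged and recorded under ``metadata["dropped_zero_tic"]``.
    """
    tics = dataset.tic()
    keep = tics > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise EmptyDatasetError("tic_normalize: all pixels have zero TIC")
    if n_dropped:
        logger.info("tic_normalize: dropped %d zero-TIC pixels", n_dropped)
    if target is None:
        target = float(tics[keep].mean())
    if target <= 0:
        raise ValueError("tic_normalize: target must be positive")

    factors = target / tics[keep]
    metadata = dict(dataset.metadata)
    metadata.update(
        tic_normalized=True, tic_target=target, dropped_zero_tic=n_dropped
    )
    coords = dataset.coordinates[keep]
    if dataset.mode == "continuous":
        matrix = dataset.intensity_matrix[keep] * factors[:, None]
        return MSIDataset(
            coords,
            mode="continuous",
            pixel_size=dataset.pixel_size,
            polarity=dataset.polarity,
            mz_range=dataset.mz_range,
            metadata=metadata,
            mz_axis=dataset.mz_axis,
            intensity_matrix=matrix,
        )
    idx = np.flatnonzero(keep)
    mzs = [dataset.mz_arrays[i] for i in idx]
    ints = [dataset.intensity_arrays[i] * f for i, f in zip(idx, factors)]
    return MSIDataset(
        coords,
        mode="processed",
        pixel_size=dataset.pixel_size,
        polarity=dataset.polarity,
        mz_range=dataset.mz_range,
        metadata=metadata,
        mz_arrays=mzs,
        intensity_arrays=ints,
    )


# ---------------------------------------------------------------------------
# Ion images
# ---------------------------------------------------------------------------

_REDUCERS: dict[str, Callable[[np.ndarray], float]] = {
    "sum": np.sum,
    "mean": np.mean,
    "max": np.max,
}


def extract_ion_image(
    dataset: MSIDataset,
    analyte: AnalyteDefinition,
    reducer: str = "sum",
) -> IonImage:
    """Reduce intensities inside the analyte's closed m/z window per pixel.

    A pixel whose spectrum has no peaks inside the window contributes 0 (an
    acquired empty window is a measurement of absence); grid cells that were
    never acquired stay NaN.
    """
    lo, hi = analyte.window()
    if hi < dataset.mz_range[0] or lo > dataset.mz_range[1]:
        raise ValueError(
            f"analyte window [{lo:.4f}, {hi:.4f}] lies outside dataset "
            f"mz_range {dataset.mz_range}"
        )
    if reducer not in _REDUCERS:
        raise ValueError(f"unknown reducer {reducer!r}")
    red = _REDUCERS[reducer]

    if dataset.mode == "continuous":
        cols = (dataset.mz_axis >= lo) & (dataset.mz_axis <= hi)
        if cols.any():
            sub = dataset.intensity_matrix[:, cols]
            if reducer == "sum":
                values = sub.sum(axis=1)
            elif reducer == "mean":
                values = sub.mean(axis=1)
            else:
                values = sub.max(axis=1)
        else:
            values = np.zeros(dataset.n_pixels)
    else:
        values = np.empty(dataset.n_pixels)
        for i in range(dataset.n_pixels):
            m, y = dataset.spectrum(i)
            sel = (m >= lo) & (m <= hi)
            values[i] = red(y[sel]) if sel.any() else 0.0

    grid = dataset.to_grid(values)
    return IonImage(
        grid=grid,
        analyte=analyte,
        normalized=bool(dataset.metadata.get("tic_normalized", False)),
        pixel_size=dataset.pixel_size,
    )


# ---------------------------------------------------------------------------
# Tissue masking
# ---------------------------------------------------------------------------

def compute_tissue_mask(
    dataset: MSIDataset | None = None,
    marker_images: Sequence[IonImage] | None = None,
    method: str = "tic_threshold",
    threshold_quantile: float = 0.40,
) -> TissueMask:
    """Boolean on-tissue mask.

    ``tic_threshold`` marks acquired pixels whose raw TIC lies strictly above
    the given quantile of the TIC distribution.  The default quantile of 0.40
    suits framed sections where tissue occupies roughly 60% of the acquired
    field; for a section with no off-tissue frame use a low quantile or a
    ground-truth mask.  ``marker_union`` marks pixels where any marker ion
    image exceeds its own quantile threshold.
    """
    if not 0.0 <= threshold_quantile < 1.0:
        raise ValueError("threshold_quantile must be in [0, 1)")
    if method == "tic_threshold":
        if dataset is None:
            raise ValueError("tic_threshold requires the dataset")
        tics = dataset.tic()
        thr = float(np.quantile(tics, threshold_quantile))
        grid = dataset.to_grid(tics, fill=-np.inf) > thr
    elif method == "marker_union":
        if not marker_images:
            raise ValueError("marker_union requires at least one marker image")
        grid = np.zeros(marker_images[0].shape, dtype=bool)
        for img in marker_images:
            vals = img.values()
            thr = float(np.quantile(vals, threshold_quantile))
            grid |= np.where(img.finite_mask, img.grid, -np.inf) > thr
    else:
        raise ValueError(f"unknown mask method {method!r}")
    if not grid.any():
        raise EmptyDatasetError(f"tissue mask ({method}) is empty")
    return TissueMask(grid=grid, provenance="threshold")
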