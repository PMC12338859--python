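"""Synthetic dual-excitation ratiometric microscopy with known ground truth.

Emulates cells expressing a ratiometric pH probe imaged with alternating
405/488 nm excitation: a calibration series in defined-pH buffers (where a
surface-anchored probe senses the buffer pH directly) and treatment
experiments where the cytosolic pH per condition is set by the caller.

The stated world
----------------
* Calibration buffers at pH 3.5, 4.77, 5.5, 6.0, 6.5 (MES) and 7.0, 7.5,
  8.0 (HEPES) — the standard defined-pH series for this probe class.
* 15 cells per field by default, matching typical per-condition counts in
  published ratiometric calibrations.
* Cells are non-overlapping ellipses of uniform interior intensity; the
  per-cell expression level is heterogeneous (uniform over a 4x range) but
  the 405/488 ratio is expression-independent, as for a true ratiometric
  probe.
* Sensor response is a four-parameter monotone logistic in pH with midpoint
  near the probe's apparent pKa (default 6.5) — configurable in sign and
  steepness because real calibration directions vary by probe.
* Noise: Poisson shot noise on photon counts plus Gaussian read noise
  (sd 5 counts) over a uniform background (100 counts), quantized to 16-bit
  TIFF.  A float debug mode skips quantization for exactness tests.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from phquant.io import FieldImagePair, MANIFEST_COLUMNS, write_manifest

__all__ = [
    "SensorModel",
    "SimConfig",
    "Treatment",
    "GroundTruthRecord",
    "render_field",
    "generate_calibration_series",
    "generate_experiment",
    "DEFAULT_BUFFER_PH",
]

#: defined-pH calibration buffer series (MES for <=6.5, HEPES above)
DEFAULT_BUFFER_PH = (3.5, 4.77, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0)


@dataclass(frozen=True)
class SensorModel:
    """Ground-truth ratio-vs-pH response of the simulated probe.

    ``response(pH) = R_min + (R_max - R_min) / (1 + 10**(s*(pH_half - pH)))``
    with ``s = slope`` if the ratio increases with pH (default) and
    ``s = -slope`` otherwise.  Strictly monotone for slope > 0.
    """

    R_min: float = 0.3
    R_max: float = 2.5
    pH_half: float = 6.5
    slope: float = 1.0
    increasing: bool = True

    def __post_init__(self) -> None:
        if not (self.R_max > self.R_min > 0):
            raise ValueError(f"need R_max > R_min > 0, got {self.R_min}, {self.R_max}")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0 < self.pH_half < 14:
            raise ValueError("pH_half must lie in (0, 14)")

    def response(self, pH):
        s = self.slope if self.increasing else -self.slope
        pH = np.asarray(pH, dtype=float)
        r = self.R_min + (self.R_max - self.R_min) / (1.0 + 10.0 ** (s * (self.pH_half - pH)))
        return r if r.ndim else float(r)


@dataclass(frozen=True)
class Treatment:
    """One experimental arm: buffer pH, optional weak-acid dose, true cytosolic pH."""

    label: str
    pH_E: float
    true_pH_I: Optional[float]
    species: str = ""
    conc_E_mM: float = 0.0


@dataclass
class SimConfig:
    """All knobs of the simulated acquisition; ``seed`` makes outputs bit-identical."""

    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 15
    cell_axis_range: tuple[float, float] = (8.0, 14.0)
    expression_range: tuple[float, float] = (2000.0, 8000.0)
    background_level: float = 100.0
    read_noise_sd: float = 5.0
    shot_noise: bool = True
    bit_depth: int = 16
    float_mode: bool = False
    seed: int = 0
    buffer_pH_list: tuple[float, ...] = DEFAULT_BUFFER_PH
    treatments: tuple[Treatment, ...] = ()

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cell_axis_range[1] * 2 >= min(self.image_shape):
            raise ValueError("cell semi-axes do not fit in the image")


@dataclass(frozen=True)
class GroundTruthRecord:
    field_id: str
    cell_id: int
    centroid_row: float
    centroid_col: float
    area: int
    true_pH: float
    expression: float
    true_ratio: float


def _field_rng(config: SimConfig, field_id: str) -> np.random.Generator:
    # stable per-field stream: master seed + CRC32 of the field id
    return np.random.default_rng([config.seed, zlib.crc32(field_id.encode())])


def _place_ellipses(config: SimConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse parameters (bounding-circle test)."""
    nrow, ncol = config.image_shape
    amin, amax = config.cell_axis_range
    placed: list[tuple[float, float, float, float, float]] = []
    attempts = 0
    max_attempts = 500 * config.n_cells
    while len(placed) < config.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {config.n_cells} non-overlapping cells in a "
                f"{nrow}x{ncol} image after {max_attempts} attempts; reduce "
                "n_cells or cell_axis_range"
            )
        attempts += 1
        a = rng.uniform(amin, amax)
        b = rng.uniform(amin, amax)
        theta = rng.uniform(0, math.pi)
        rmax = max(a, b)
        r = rng.uniform(rmax + 1, nrow - rmax - 1)
        c = rng.uniform(rmax + 1, ncol - rmax - 1)
        # transiently transfected cells are sparse: keep a clear gap between them
        if all(
            math.hypot(r - r0, c - c0) > rmax + max(a0, b0) + 3
            for (r0, c0, a0, b0, _) in placed
        ):
            placed.append((r, c, a, b, theta))
    return placed


def _ellipse_mask(shape, r0, c0, a, b, theta) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr, dc = rr - r0, cc - c0
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_field(
    config: SimConfig,
    sensor: SensorModel,
    true_pH: float,
    field_id: str,
) -> tuple[FieldImagePair, list[GroundTruthRecord], np.ndarray]:
    """Render one field of view at a single ground-truth pH.

    Channel model before noise: per-cell expression E (arbitrary counts) is
    drawn uniformly; the 488 nm channel carries E and the 405 nm channel
    E * R(true_pH), so the pixelwise 405/488 ratio inside a cell equals the
    sensor response exactly.  Background, optional Poisson shot noise and
    Gaussian read noise are then added and the result quantized to the
    configured bit depth (skipped in ``float_mode``).
    """
    if not 0 < true_pH < 14:
        raise ValueError(f"true_pH must lie in (0, 14), got {true_pH}")
    rng = _field_rng(config, field_id)
    ellipses = _place_ellipses(config, rng)
    ratio = sensor.response(true_pH)

    labels = np.zeros(config.image_shape, dtype=np.int32)
    img488 = np.full(config.image_shape, config.background_level, dtype=np.float64)
    img405 = np.full(config.image_shape, config.background_level, dtype=np.float64)
    records: list[GroundTruthRecord] = []
    for cell_id, (r0, c0, a, b, theta) in enumerate(ellipses, start=1):
        mask = _ellipse_mask(config.image_shape, r0, c0, a, b, theta)
        expression = rng.uniform(*config.expression_range)
        labels[mask] = cell_id
        img488[mask] += expression
        img405[mask] += expression * ratio
        rows, cols = np.nonzero(mask)
        records.append(
            GroundTruthRecord(
                field_id=field_id,
                cell_id=cell_id,
                centroid_row=float(rows.mean()),
                centroid_col=float(cols.mean()),
                area=int(mask.sum()),
                true_pH=float(true_pH),
                expression=float(expression),
                true_ratio=float(ratio),
            )
        )

    if config.shot_noise:
        img488 = rng.poisson(img488).astype(np.float64)
        img405 = rng.poisson(img405).astype(np.float64)
    if config.read_noise_sd > 0:
        img488 = img488 + rng.normal(0, config.read_noise_sd, size=img488.shape)
        img405 = img405 + rng.normal(0, config.read_noise_sd, size=img405.shape)

    if not config.float_mode:
        top = 2**config.bit_depth - 1
        img488 = np.clip(np.rint(img488), 0, top).astype(np.uint16)
        img405 = np.clip(np.rint(img405), 0, top).astype(np.uint16)
    else:
        img488 = np.clip(img488, 0, None)
        img405 = np.clip(img405, 0, None)

    pair = FieldImagePair(
        img405=np.asarray(img405, dtype=np.float64),
        img488=np.asarray(img488, dtype=np.float64),
        field_id=field_id,
        metadata={"true_pH": float(true_pH)},
    )
    return pair, records, labels


def _save_field(
    outdir: Path, cond: str, fidx: int, pair: FieldImagePair, labels: np.ndarray, config: SimConfig
) -> dict:
    stem = f"{cond}_f{fidx:03d}"
    if config.float_mode:
        im405 = pair.img405.astype(np.float32)
        im488 = pair.img488.astype(np.float32)
    else:
        im405 = pair.img405.astype(np.uint16)
        im488 = pair.img488.astype(np.uint16)
    tifffile.imwrite(outdir / f"{stem}_ex405.tif", im405)
    tifffile.imwrite(outdir / f"{stem}_ex488.tif", im488)
    tifffile.imwrite(outdir / f"{stem}_labels.tif", labels.astype(np.uint16))
    return {
        "path_ex405": f"{stem}_ex405.tif",
        "path_ex488": f"{stem}_ex488.tif",
        "path_labels": f"{stem}_labels.tif",
    }


def _prepare_outdir(outdir: str | Path, overwrite: bool) -> Path:
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {outdir} is non-empty; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def _truth_frame(records: list[GroundTruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def generate_calibration_series(
    config: SimConfig,
    sensor: SensorModel,
    outdir: str | Path,
    n_fields_per_pH: int = 1,
    overwrite: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render the defined-pH buffer series and write TIFFs + manifest + truth.

    For a surface-anchored probe the sensed pH equals the buffer pH, so every
    cell's ground-truth pH is the buffer value.  Returns (manifest, truth).
    """
    if len(config.buffer_pH_list) == 0:
        raise ValueError("buffer_pH_list must be non-empty")
    outdir = _prepare_outdir(outdir, overwrite)
    manifest_rows: list = []
    truth: list = []
    for pH in config.buffer_pH_list:
        cond = f"pH{pH:.2f}"
        for fidx in range(n_fields_per_pH):
            field_id = f"{cond}_f{fidx:03d}"
            pair, records, labels = render_field(config, sensor, pH, field_id)
            paths = _save_field(outdir, cond, fidx, pair, labels, config)
            manifest_rows.append(
                {
                    "field_id": field_id,
                    "condition": cond,
                    "treatment": "calibration",
                    "species": "",
                    "conc_E_mM": 0.0,
                    "pH_E": pH,
                    "true_pH_I": pH,
                    **paths,
                }
            )
            truth.extend(records)
    manifest = write_manifest(manifest_rows, outdir / "manifest.csv")
    truth_df = _truth_frame(truth)
    truth_df.to_csv(outdir / "ground_truth.csv", index=False)
    return manifest, truth_df


def generate_experiment(
    config: SimConfig,
    sensor: SensorModel,
    outdir: str | Path,
    n_fields_per_treatment: int = 1,
    overwrite: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render treatment arms at their assigned true cytosolic pH.

    Each treatment names the buffer pH (pH_E) and the ground-truth cytosolic
    pH (true_pH_I); a butyrate arm encoding acidification simply sets
    true_pH_I below the matching control's.  Returns (manifest, truth).
    """
    if len(config.treatments) == 0:
        raise ValueError("config.treatments must be non-empty")
    for t in config.treatments:
        if t.true_pH_I is None:
            raise ValueError(f"treatment {t.label!r} lacks true_pH_I")
    outdir = _prepare_outdir(outdir, overwrite)
    manifest_rows, truth = [], []
    for t in config.treatments:
        for fidx in range(n_fields_per_treatment):
            field_id = f"{t.label}_f{fidx:03d}"
            pair, records, labels = render_field(config, sensor, t.true_pH_I, field_id)
            paths = _save_field(outdir, t.label, fidx, pair, labels, config)
            manifest_rows.append(
                {
                    "field_id": field_id,
                    "condition": t.label,
                    "treatment": t.species if t.conc_E_mM > 0 else "control",
                    "species": t.species,
                    "conc_E_mM": t.conc_E_mM,
                    "pH_E": t.pH_E,
                    "true_pH_I": t.true_pH_I,
                    **paths,
                }
            )
            truth.extend(records)
    manifest = write_manifest(manifest_rows, outdir / "manifest.csv")
    truth_df = _truth_frame(truth)
    truth_df.to_csv(outdir / "ground_truth.csv", index=False)
    return manifest, truth_df
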