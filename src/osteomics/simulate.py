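"""Synthetic-data generators with known ground truth for every pipeline input.

Generates (a) protein-group intensity matrices in the study's replicate
design (three biological replicates per class except two for day-8 gravity
control) with spiked differential abundance and left-censored (MNAR)
missingness, (b) single-cell fluorescence images with a radially decaying
intensity profile around a known centrosome, (c) qPCR Ct tables with known
fold changes, and (d) plate-reader absorbance tables from a known
calibration line. Every generator is a deterministic function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import belts as _belts
from .assays import DEFAULT_REFERENCE_GENE
from .proteomics import CLASS_ORDER, IntensityMatrix

#: Replicate design of the study: 14 samples over five classes.
DEFAULT_CLASS_SIZES = {"T0": 3, "T8_GC": 2, "T8_RPM": 3, "T28_GC": 3, "T28_RPM": 3}

#: Spike patterns as (sign at T8, sign at T28) applied to the RPM classes,
#: matching the trend-category vocabulary used downstream.
TREND_PATTERNS = {
    "down_T8_only": (-1, 0),
    "up_T8_only": (1, 0),
    "down_T28_only": (0, -1),
    "up_T28_only": (0, 1),
    "down_both": (-1, -1),
    "up_both": (1, 1),
}


@dataclass
class ProteomicsSimSpec:
    """Parameters of the synthetic label-free quantification experiment.

    ``effect_log2`` is either a scalar magnitude — each spiked protein gets a
    trend pattern drawn uniformly from :data:`TREND_PATTERNS`, with shifts of
    that magnitude on the RPM classes — or an explicit class -> log2 shift
    mapping applied identically to every spiked protein. Baseline log2
    intensities default to mean 20, sd 2 with replicate noise sd 0.25,
    typical of median-normalized LFQ data; ``mnar_quantile`` is the
    per-sample detection-limit quantile below which values go missing.
    """

    n_proteins: int = 1000
    class_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    frac_dapg: float = 0.0
    effect_log2: float | Mapping[str, float] = 2.0
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    noise_sd: float = 0.25
    mnar_quantile: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if "T0" not in self.class_sizes:
            raise ValueError("class_sizes must include the T0 reference class")
        unknown = set(self.class_sizes) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        if any(n < 2 for n in self.class_sizes.values()):
            raise ValueError("every class needs at least 2 replicates")
        if not 0.0 <= self.frac_dapg <= 1.0:
            raise ValueError("frac_dapg must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.mnar_quantile < 1.0:
            raise ValueError("mnar_quantile must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated intensity matrix."""

    dapg_flags: pd.Series  # per-gene boolean
    true_category: pd.Series  # trend label for spiked genes, None otherwise
    true_effects: pd.DataFrame  # gene x class log2 shift


def _effect_table(spec: ProteomicsSimSpec, rng: np.random.Generator) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    genes = [f"G{i:05d}" for i in range(spec.n_proteins)]
    classes = [c for c in CLASS_ORDER if c in spec.class_sizes]
    n_dapg = int(round(spec.frac_dapg * spec.n_proteins))
    flagged = np.zeros(spec.n_proteins, dtype=bool)
    if n_dapg:
        flagged[rng.choice(spec.n_proteins, size=n_dapg, replace=False)] = True
    effects = pd.DataFrame(0.0, index=genes, columns=classes)
    category = pd.Series([None] * spec.n_proteins, index=genes, dtype=object)
    if isinstance(spec.effect_log2, Mapping):
        for cls, shift in spec.effect_log2.items():
            if cls not in classes:
                raise ValueError(f"effect class {cls!r} not in design")
            effects.loc[flagged, cls] = float(shift)
        sign8 = np.sign(effects.get("T8_RPM", pd.Series(0.0, index=genes)))
        sign28 = np.sign(effects.get("T28_RPM", pd.Series(0.0, index=genes)))
        inverse = {v: k for k, v in TREND_PATTERNS.items()}
        for g in np.array(genes)[flagged]:
            category[g] = inverse.get((int(sign8[g]), int(sign28[g])))
    else:
        mag = float(spec.effect_log2)
        names = list(TREND_PATTERNS)
        picks = rng.integers(0, len(names), size=spec.n_proteins)
        for i, g in enumerate(genes):
            if not flagged[i]:
                continue
            cat = names[picks[i]]
            s8, s28 = TREND_PATTERNS[cat]
            if "T8_RPM" in effects.columns:
                effects.loc[g, "T8_RPM"] = s8 * mag
            if "T28_RPM" in effects.columns:
                effects.loc[g, "T28_RPM"] = s28 * mag
            category[g] = cat
    return pd.Series(flagged, index=genes), category, effects


def gen_proteomics(spec: ProteomicsSimSpec) -> tuple[IntensityMatrix, SimTruth]:
    """Simulate a linear-scale intensity matrix with MNAR missingness.

    Linear intensities are ``2^(baseline + class effect + noise)``; within
    each sample column, values below that column's empirical
    ``mnar_quantile`` are censored to missing, reproducing the left-censoring
    that the downshifted-Gaussian imputation assumes.
    """
    rng = np.random.default_rng(spec.seed)
    flags, category, effects = _effect_table(spec, rng)
    genes = effects.index
    columns, col_class = [], []
    for cls in (c for c in CLASS_ORDER if c in spec.class_sizes):
        for rep in range(1, spec.class_sizes[cls] + 1):
            columns.append(f"{cls}_{rep}")
            col_class.append(cls)
    base = rng.normal(spec.base_log2_mean, spec.base_log2_sd, len(genes))
    log2_vals = (
        base[:, None]
        + effects[col_class].to_numpy()
        + rng.normal(0.0, spec.noise_sd, (len(genes), len(columns)))
    )
    values = np.power(2.0, log2_vals)
    if spec.mnar_quantile > 0:
        limits = np.quantile(values, spec.mnar_quantile, axis=0)
        values = np.where(values < limits[None, :], np.nan, values)
    data = pd.DataFrame(values, index=genes, columns=columns)
    data.index.name = "gene"
    truth = SimTruth(dapg_flags=flags, true_category=category, true_effects=effects)
    return IntensityMatrix(data, log2=False), truth


# ---------------------------------------------------------------------------
# single-cell image
# ---------------------------------------------------------------------------

@dataclass
class ImageSimSpec:
    """Synthetic single-channel cell image with a radial intensity profile.

    Intensity inside the cell polygon decays exponentially with the
    normalized radius from the centrosome:
    ``peak_intensity * exp(-decay_rate * rho) + noise``; outside the polygon
    only background noise remains. The centrosome is the brightest pixel by
    construction.
    """

    image_size: tuple[int, int] = (64, 64)
    polygon: Sequence[tuple[float, float]] = ()
    centrosome: tuple[int, int] = (0, 0)
    decay_rate: float = 2.0
    peak_intensity: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_intensity <= 0:
            raise ValueError("peak_intensity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or len(poly) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        if not _belts.point_in_polygon(np.asarray(self.centrosome, float), poly):
            raise ValueError("centrosome must lie strictly inside the polygon")


def gen_cell_image(spec: ImageSimSpec) -> _belts.CellImage:
    """Render the radial-decay cell image described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    poly = np.asarray(spec.polygon, dtype=float)
    pixels = np.zeros(spec.image_size)
    mask = _belts.polygon_mask(spec.image_size, poly)
    pts = np.argwhere(mask).astype(float)
    rho = _belts.normalized_radius(pts, spec.centrosome, poly)
    signal = spec.peak_intensity * np.exp(-spec.decay_rate * rho)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, len(signal))
        pixels[~mask] = rng.normal(0.0, spec.noise_sd, int((~mask).sum()))
    pixels[mask] = signal
    pixels = np.clip(pixels, 0.0, None)
    r, c = spec.centrosome
    # the specified centrosome is the brightest in-cell point by construction
    interior_max = pixels[mask].max()
    target = spec.peak_intensity if spec.noise_sd == 0 else interior_max + 3 * spec.noise_sd
    pixels[r, c] = max(pixels[r, c], target)
    return _belts.CellImage(pixels=pixels, polygon=poly, centrosome=(r, c))


def circle_polygon(
    center: tuple[float, float], radius: float, n_vertices: int = 128
) -> np.ndarray:
    """Regular polygon approximating a circle, in (row, col) coordinates."""
    ang = 2 * np.pi * np.arange(n_vertices) / n_vertices
    return np.column_stack(
        [center[0] + radius * np.sin(ang), center[1] + radius * np.cos(ang)]
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def gen_ct_table(
    fold_changes: Mapping[str, float],
    ct_ref: float = 15.0,
    baseline: float = 5.0,
    noise_sd: float = 0.0,
    timepoint: str = "T8",
    n_replicates: int = 3,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a triplicate-well Ct table with known RPM fold changes.

    For each target gene, the gravity-control dCt equals ``baseline`` and the
    RPM target Ct is ``ct_ref + baseline - log2(fold_change) + noise`` so the
    2^-ddCt calculator recovers ``fold_change`` exactly at zero noise.
    """
    for gene, fc in fold_changes.items():
        if fc <= 0:
            raise ValueError(f"fold change for {gene!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for condition in ("GC", "RPM"):
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "gene": reference_gene,
                    "condition": condition,
                    "timepoint": timepoint,
                    "replicate": rep,
                    "ct": ct_ref + rng.normal(0.0, noise_sd),
                }
            )
            for gene, fc in fold_changes.items():
                shift = 0.0 if condition == "GC" else -np.log2(fc)
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "timepoint": timepoint,
                        "replicate": rep,
                        "ct": ct_ref + baseline + shift + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate-reader tables
# ---------------------------------------------------------------------------

def gen_plate(
    slope: float,
    intercept: float,
    standards: Sequence[float],
    unknowns: Sequence[float],
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate triplicate absorbance reads from a linear calibration.

    ``standards`` are known (strictly increasing) concentrations;
    ``unknowns`` are the true concentrations of the unknown wells, retained
    in the ``true_concentration`` column as ground truth.
    """
    standards = list(standards)
    if len(standards) < 2:
        raise ValueError("need at least 2 standards")
    if any(b <= a for a, b in zip(standards, standards[1:])):
        raise ValueError("standards must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for kind, concs in (("standard", standards), ("unknown", list(unknowns))):
        for i, conc in enumerate(concs):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "well": f"{kind[0].upper()}{i + 1}",
                        "sample_type": kind,
                        "true_concentration": conc,
                        "replicate": rep,
                        "absorbance": slope * conc + intercept + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
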