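"""Assay calculators: 2^-ddCt expression, standard-curve calibration,
crystal-size statistics and the shared two-sample Student's t-test.

The qPCR calculator follows the comparative-Ct (2^-ddCt) method with a
reference gene (18S rRNA by default) and the gravity-control condition as
calibrator. Plate-reader calibrations are ordinary least-squares lines
(both assays operate in their linear range). Hydroxyapatite crystal areas
are compared between gravity control and simulated microgravity with a
pooled-variance Student's t-test and a shared-bin frequency distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REFERENCE_GENE = "18S"


# ---------------------------------------------------------------------------
# Student's t
# ---------------------------------------------------------------------------

def student_t(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance by default).

    Degenerate inputs: zero pooled variance with equal means gives
    ``(0, 1)``; zero pooled variance with unequal means gives ``p = 0``
    (the groups are perfectly separated).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def student_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance t-test reconstructed from summary statistics."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# 2^-ddCt relative quantification
# ---------------------------------------------------------------------------

CT_COLUMNS = ("gene", "condition", "timepoint", "replicate", "ct")


@dataclass
class FoldChange:
    """2^-ddCt fold change with the replicate-sd range."""

    gene: str
    condition: str
    calibrator: str
    fold: float
    ddct: float
    sd: float  # sd of the replicate dCt values in the sample condition
    low: float  # 2^-(ddct + sd)
    high: float  # 2^-(ddct - sd)


def _delta_ct(sub: pd.DataFrame, gene: str, reference_gene: str) -> tuple[float, np.ndarray]:
    tgt = sub[sub["gene"] == gene].sort_values("replicate")
    ref = sub[sub["gene"] == reference_gene].sort_values("replicate")
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} missing")
    if tgt.empty:
        raise ValueError(f"target gene {gene!r} missing")
    dct = float(tgt["ct"].mean() - ref["ct"].mean())
    if len(tgt) == len(ref):
        reps = tgt["ct"].to_numpy() - ref["ct"].to_numpy()
    else:  # unpaired wells: centre target Cts on the mean reference Ct
        reps = tgt["ct"].to_numpy() - float(ref["ct"].mean())
    return dct, reps


def ddct_fold_change(
    table: pd.DataFrame,
    gene: str,
    condition: str = "RPM",
    calibrator: str = "GC",
    timepoint: str | None = None,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
) -> FoldChange:
    """Relative expression of ``gene`` by the 2^-ddCt method.

    dCt = mean Ct(target) - mean Ct(reference) within each condition;
    ddCt = dCt(condition) - dCt(calibrator); fold = 2^-ddCt. The replicate
    spread is propagated as the sd of per-replicate dCt values, giving the
    asymmetric range 2^-(ddCt +- sd).
    """
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    sub = table if timepoint is None else table[table["timepoint"] == timepoint]
    sample = sub[sub["condition"] == condition]
    calib = sub[sub["condition"] == calibrator]
    dct_s, reps = _delta_ct(sample, gene, reference_gene)
    dct_c, _ = _delta_ct(calib, gene, reference_gene)
    ddct = dct_s - dct_c
    sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
    return FoldChange(
        gene=gene,
        condition=condition,
        calibrator=calibrator,
        fold=float(2.0 ** (-ddct)),
        ddct=float(ddct),
        sd=sd,
        low=float(2.0 ** (-(ddct + sd))),
        high=float(2.0 ** (-(ddct - sd))),
    )


# ---------------------------------------------------------------------------
# standard curves (ALPL activity, indirect ELISA)
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve:
    """Linear calibration: absorbance = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass
class Calibrated:
    concentration: float
    extrapolated: bool


def fit_standard_curve(
    concentrations, absorbances
) -> StandardCurve:
    """Ordinary least-squares calibration line from >= 2 standards."""
    conc = np.asarray(concentrations, dtype=float)
    absorb = np.asarray(absorbances, dtype=float)
    if len(conc) != len(absorb):
        raise ValueError("concentration and absorbance lengths differ")
    if len(np.unique(conc)) < 2:
        raise ValueError("need at least 2 distinct standard concentrations")
    fit = stats.linregress(conc, absorb)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        conc_range=(float(conc.min()), float(conc.max())),
    )


def calibrate(curve: StandardCurve, absorbance: float) -> Calibrated:
    """Back-calculate a concentration from an absorbance reading.

    Readings mapping outside the standards' concentration range are flagged
    as extrapolated rather than rejected.
    """
    if curve.slope == 0:
        raise ValueError("cannot invert a flat standard curve (slope = 0)")
    conc = (absorbance - curve.intercept) / curve.slope
    lo, hi = curve.conc_range
    return Calibrated(concentration=float(conc), extrapolated=not (lo <= conc <= hi))


# ---------------------------------------------------------------------------
# crystal-size statistics
# ---------------------------------------------------------------------------

@dataclass
class CrystalSet:
    """Areas of manually segmented mineral crystals from one condition."""

    areas: np.ndarray
    group: str
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.size == 0:
            raise ValueError("a crystal set cannot be empty")
        if (self.areas <= 0).any():
            raise ValueError("crystal areas must be positive")

    def summary(self) -> dict[str, float]:
        return {
            "n": int(self.areas.size),
            "min": float(self.areas.min()),
            "max": float(self.areas.max()),
            "mean": float(self.areas.mean()),
        }


@dataclass
class CrystalComparison:
    summaries: dict[str, dict[str, float]]
    bin_edges: np.ndarray
    fractions: dict[str, np.ndarray]  # per group, sums to 1
    counts: dict[str, np.ndarray]
    t: float
    p: float


def crystal_stats(g1: CrystalSet, g2: CrystalSet, bins: int = 10) -> CrystalComparison:
    """Summary statistics, shared-bin frequency distribution and Student's t
    comparing crystal areas between two growth conditions."""
    combined = np.concatenate([g1.areas, g2.areas])
    edges = np.histogram_bin_edges(combined, bins=bins)
    counts, fractions = {}, {}
    for g in (g1, g2):
        c, _ = np.histogram(g.areas, bins=edges)
        counts[g.group] = c
        fractions[g.group] = c / c.sum()
    t, p = student_t(g1.areas, g2.areas)
    return CrystalComparison(
        summaries={g1.group: g1.summary(), g2.group: g2.summary()},
        bin_edges=edges,
        fractions=fractions,
        counts=counts,
        t=t,
        p=p,
    )
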