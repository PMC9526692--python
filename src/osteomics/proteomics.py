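"""Perseus-style differential-abundance statistics for label-free DIA proteomics.

The pipeline mirrors the standard workflow for a four-class (time ×
gravity-condition) label-free quantification experiment on differentiating
bone marrow stromal cells:

1.  average the T0 (day-zero) replicates into a per-protein reference,
2.  express every later sample as a ratio to that reference and drop T0,
3.  keep protein groups with >= 70 % valid values in at least one class,
4.  log2-transform,
5.  impute missing (left-censored) values from a downshifted Gaussian,
6.  one-way ANOVA across the four classes,
7.  permutation-based FDR (class labels shuffled, ANOVA recomputed),
8.  Tukey HSD post hoc on significant protein groups,
9.  collapse redundant isoform gene names,
10. classify each significant protein group by its trend in simulated
    microgravity (RPM) relative to gravity control (GC) at day 8 and 28.

All functions are pure: they take an :class:`IntensityMatrix` and return a
new one (or plain results), so the chain is trivially re-runnable and, with a
fixed seed, bit-reproducible.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

logger = logging.getLogger(__name__)

#: All recognised sample classes, in canonical order.
CLASS_ORDER = ("T0", "T8_GC", "T8_RPM", "T28_GC", "T28_RPM")

#: Classes entering the four-group comparison (after T0 referencing).
ANALYSIS_CLASSES = ("T8_GC", "T8_RPM", "T28_GC", "T28_RPM")

#: The six unordered class pairs tested post hoc, in canonical order.
CLASS_PAIRS = tuple(
    (ANALYSIS_CLASSES[i], ANALYSIS_CLASSES[j])
    for i in range(len(ANALYSIS_CLASSES))
    for j in range(i + 1, len(ANALYSIS_CLASSES))
)

#: Trend categories for significant protein groups (RPM relative to GC).
TREND_CATEGORIES = (
    "down_T8_only",
    "up_T8_only",
    "down_T28_only",
    "up_T28_only",
    "down_both",
    "up_both",
    "time_only",
    "mixed",
)


def parse_sample_label(label: str) -> tuple[str, int]:
    """Split a ``CLASS_rep`` column label into ``(class, replicate)``.

    >>> parse_sample_label("T8_GC_1")
    ('T8_GC', 1)
    """
    cls, _, rep = str(label).rpartition("_")
    if cls not in CLASS_ORDER:
        raise ValueError(
            f"cannot parse sample label {label!r}: class {cls!r} not one of {CLASS_ORDER}"
        )
    try:
        return cls, int(rep)
    except ValueError as exc:
        raise ValueError(f"cannot parse replicate index in {label!r}") from exc


@dataclass
class IntensityMatrix:
    """Protein-group x sample abundance matrix.

    Parameters
    ----------
    data
        DataFrame indexed by gene symbol with ``CLASS_rep`` column labels
        (e.g. ``T8_RPM_2``). Missing values are ``NaN``.
    log2
        Whether ``data`` is on the log2 scale.
    imputed
        Optional boolean DataFrame (same shape) marking imputed entries.
    """

    data: pd.DataFrame
    log2: bool = False
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        samples = [parse_sample_label(c) for c in self.data.columns]
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate (class, replicate) sample labels")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene rows: {dups}")
        if self.imputed is not None and self.imputed.shape != self.data.shape:
            raise ValueError("imputed mask shape does not match data")
        self._samples = samples

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> list[tuple[str, int]]:
        return list(self._samples)

    def class_labels(self) -> np.ndarray:
        """Per-column class label array."""
        return np.array([cls for cls, _ in self._samples])

    def class_columns(self) -> dict[str, list[str]]:
        """Map class -> list of column labels, in canonical class order."""
        out: dict[str, list[str]] = {}
        for cls in CLASS_ORDER:
            cols = [c for c, (k, _) in zip(self.data.columns, self._samples) if k == cls]
            if cols:
                out[cls] = cols
        return out

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True where the value is missing)."""
        return self.data.isna()


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def average_reference(m: IntensityMatrix) -> pd.Series:
    """Per-gene arithmetic mean of the non-missing T0 replicate intensities."""
    cols = m.class_columns().get("T0")
    if not cols:
        raise ValueError("matrix has no T0 samples; a reference class is required")
    return m.data[cols].mean(axis=1, skipna=True)


def ratio_to_reference(m: IntensityMatrix, ref: pd.Series) -> IntensityMatrix:
    """Divide every non-T0 sample by the T0 reference; drop the T0 columns.

    Genes whose reference is missing or non-positive get all-missing ratios
    (with a logged warning for the non-positive case).
    """
    if len(ref) != len(m.data) or not ref.index.equals(m.data.index):
        raise ValueError("reference vector does not match the matrix gene set")
    keep = [c for c, (cls, _) in zip(m.data.columns, m.samples) if cls != "T0"]
    bad = ref.notna() & (ref <= 0)
    if bad.any():
        logger.warning(
            "reference is zero/negative for %d gene(s); their ratios are set missing",
            int(bad.sum()),
        )
    safe_ref = ref.where(~bad)
    out = m.data[keep].div(safe_ref, axis=0)
    return IntensityMatrix(out, log2=m.log2)


def filter_valid(m: IntensityMatrix, min_fraction: float = 0.7) -> IntensityMatrix:
    """Keep genes with a valid-value fraction >= ``min_fraction`` in >= 1 class.

    The fraction is computed against the exact class size, with no rounding:
    2/3 (0.667) fails the default 0.7 threshold while 2/2 passes.
    """
    by_class = m.class_columns()
    if not by_class:
        raise ValueError("matrix has no classes")
    keep = pd.Series(False, index=m.data.index)
    for cols in by_class.values():
        frac = m.data[cols].notna().sum(axis=1) / len(cols)
        keep |= frac >= min_fraction
    return IntensityMatrix(m.data.loc[keep], log2=m.log2)


def log2_transform(m: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log2; non-positive non-missing values are an error."""
    if m.log2:
        raise ValueError("matrix is already on the log2 scale")
    vals = m.data.to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        raise ValueError("non-positive intensities cannot be log2 transformed")
    return IntensityMatrix(np.log2(m.data), log2=True)


def impute_gaussian(
    m: IntensityMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> IntensityMatrix:
    """Impute missing log2 values from a per-column downshifted Gaussian.

    Each missing entry in sample column *s* is drawn from
    ``Normal(mu_s - downshift * sigma_s, (width * sigma_s)^2)`` where ``mu_s``
    and ``sigma_s`` are the column's observed mean and standard deviation —
    the de-facto Perseus defaults for left-censored (MNAR) LFQ data.
    """
    if not m.log2:
        raise ValueError("imputation expects a log2-scale matrix")
    if rng is None:
        rng = np.random.default_rng(seed)
    data = m.data.copy()
    imputed = pd.DataFrame(False, index=data.index, columns=data.columns)
    for col in data.columns:
        observed = data[col].dropna()
        missing = data[col].isna()
        if not missing.any():
            continue
        if len(observed) < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        mu, sigma = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - downshift * sigma, width * sigma, int(missing.sum()))
        data.loc[missing, col] = draws
        imputed.loc[missing, col] = True
    return IntensityMatrix(data, log2=True, imputed=imputed)


# ---------------------------------------------------------------------------
# ANOVA and permutation FDR
# ---------------------------------------------------------------------------

_ZERO_TOL = 1e-12


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    Returns the between/within mean-square F statistic and the p-value from
    the F(k-1, N-k) distribution. A fully constant input (zero between *and*
    within sums of squares) is defined as F = 0, p = 1; zero within-variance
    with distinct means gives p = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 classes")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every class needs at least 2 values")
    n = np.array([len(g) for g in groups])
    N, k = int(n.sum()), len(groups)
    means = np.array([g.mean() for g in groups])
    grand = sum(g.sum() for g in groups) / N
    ssb = float(np.sum(n * (means - grand) ** 2))
    ssw = float(sum(((g - mu) ** 2).sum() for g, mu in zip(groups, means)))
    scale = ssb + ssw
    if ssw <= _ZERO_TOL * max(scale, 1.0):
        if ssb <= _ZERO_TOL * max(scale, 1.0):
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = (ssb / (k - 1)) / (ssw / (N - k))
    return f_stat, float(stats.f.sf(f_stat, k - 1, N - k))


def _anova_pvalues(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorised per-row one-way ANOVA p-values for a complete matrix.

    ``x`` is genes x samples with no NaN; ``labels`` assigns each column to a
    class. Degenerate rows follow the same convention as :func:`anova_oneway`.
    """
    classes = np.unique(labels)
    k = len(classes)
    n_tot = x.shape[1]
    onehot = (labels[None, :] == classes[:, None]).T.astype(float)  # samples x k
    n = onehot.sum(axis=0)
    sums = x @ onehot
    sqsums = (x**2) @ onehot
    means = sums / n
    grand = x.sum(axis=1) / n_tot
    ssb = ((means - grand[:, None]) ** 2 * n).sum(axis=1)
    ssw = (sqsums - n * means**2).sum(axis=1)
    ssw = np.maximum(ssw, 0.0)  # guard tiny negative round-off
    scale = np.maximum(ssb + ssw, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ssb / (k - 1)) / (ssw / (n_tot - k))
        p = stats.f.sf(f_stat, k - 1, n_tot - k)
    const = ssw <= _ZERO_TOL * scale
    p[const & (ssb <= _ZERO_TOL * scale)] = 1.0
    p[const & (ssb > _ZERO_TOL * scale)] = 0.0
    return p


@dataclass
class PermutationFdrResult:
    """Outcome of the permutation-based FDR procedure."""

    p_values: pd.Series
    significant: pd.Series
    cutoff: float
    n_perm: int

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def permutation_fdr(
    m: IntensityMatrix,
    n_perm: int = 250,
    fdr: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationFdrResult:
    """Permutation-based FDR control for the per-gene one-way ANOVA.

    For each of ``n_perm`` permutations the class labels are shuffled across
    all samples (class sizes preserved) and all ANOVA p-values recomputed.
    The estimated FDR at a cutoff *c* is the mean over permutations of
    ``#{perm p <= c}`` divided by ``max(1, #{observed p <= c})``; the
    significance cutoff is the largest observed p-value whose estimated FDR
    is <= ``fdr`` (no genes are called if none qualifies).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if m.data.isna().any().any():
        raise ValueError("permutation FDR expects a complete (imputed) matrix")
    x = m.data.to_numpy(dtype=float)
    labels = m.class_labels()
    obs_p = _anova_pvalues(x, labels)
    order = np.argsort(obs_p, kind="stable")
    obs_sorted = obs_p[order]
    # number of observed p-values <= each candidate cutoff (ties included)
    obs_counts = np.searchsorted(obs_sorted, obs_sorted, side="right")
    perm_counts = np.zeros(len(obs_sorted))
    for _ in range(n_perm):
        perm_p = np.sort(_anova_pvalues(x, rng.permutation(labels)))
        perm_counts += np.searchsorted(perm_p, obs_sorted, side="right")
    est_fdr = (perm_counts / n_perm) / np.maximum(1, obs_counts)
    qualifying = obs_sorted[est_fdr <= fdr]
    cutoff = float(qualifying.max()) if qualifying.size else float("-inf")
    significant = obs_p <= cutoff
    return PermutationFdrResult(
        p_values=pd.Series(obs_p, index=m.genes, name="anova_p"),
        significant=pd.Series(significant, index=m.genes, name="significant"),
        cutoff=cutoff,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# post hoc, de-duplication, trend classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairCall:
    """One Tukey HSD pairwise comparison: which class mean is higher and
    whether the difference is significant at the chosen alpha."""

    higher: str
    significant: bool
    p_value: float


def tukey_hsd(
    groups: Mapping[str, np.ndarray], alpha: float = 0.05
) -> dict[tuple[str, str], PairCall]:
    """Tukey–Kramer studentized-range test for all class pairs.

    Handles unequal group sizes (the day-8 gravity control has only two
    replicates in the study design). Returns one :class:`PairCall` per
    unordered pair, keyed in canonical class order.
    """
    names = list(groups)
    arrays = [np.asarray(groups[c], dtype=float) for c in names]
    if len(arrays) < 2:
        raise ValueError("Tukey HSD needs at least 2 classes")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every class needs at least 2 values")
    res = stats.tukey_hsd(*arrays)
    means = {c: a.mean() for c, a in zip(names, arrays)}
    ordered = [c for c in ANALYSIS_CLASSES if c in names]
    ordered += [c for c in names if c not in ordered]
    calls: dict[tuple[str, str], PairCall] = {}
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            p = float(res.pvalue[names.index(a), names.index(b)])
            higher = a if means[a] >= means[b] else b
            calls[(a, b)] = PairCall(higher=higher, significant=p < alpha, p_value=p)
    return calls


@dataclass
class DapgRecord:
    """Per-protein result: ANOVA p, FDR call, the six pair calls, trend."""

    gene: str
    anova_p: float
    significant: bool
    pair_calls: dict[tuple[str, str], PairCall] = field(default_factory=dict)
    category: str | None = None

    @property
    def neg_log_p(self) -> float:
        """-log10 of the ANOVA p-value, as reported in results tables."""
        return float(-np.log10(max(self.anova_p, np.finfo(float).tiny)))


_ISOFORM_SUFFIX = re.compile(r"-\d+$")


def base_gene_name(gene: str) -> str:
    """Strip a trailing isoform suffix like ``-2`` from a gene symbol."""
    return _ISOFORM_SUFFIX.sub("", gene)


def dedupe_isoforms(records: Sequence[DapgRecord]) -> list[DapgRecord]:
    """Collapse records sharing a base gene name to the smallest-p one.

    Emulates the manual removal of redundant gene names referring to
    uncharacterised isoforms; ties broken by gene name.
    """
    best: dict[str, DapgRecord] = {}
    for rec in records:
        key = base_gene_name(rec.gene)
        cur = best.get(key)
        if cur is None or (rec.anova_p, rec.gene) < (cur.anova_p, cur.gene):
            best[key] = rec
    kept = [best[base_gene_name(r.gene)] for r in records]
    out, seen = [], set()
    for rec in kept:
        if id(rec) not in seen:
            seen.add(id(rec))
            out.append(rec)
    removed = len(records) - len(out)
    if removed:
        logger.info("dedupe_isoforms removed %d redundant record(s)", removed)
    return out


def classify_trend(record: DapgRecord) -> str:
    """Assign the RPM-vs-GC trend category from the six pair calls.

    Direction at each time point is read off the same-time SMG pair
    (T8_GC vs T8_RPM, T28_GC vs T28_RPM). Genes significant in neither SMG
    pair fall into ``time_only`` (driven by the within-condition time pairs);
    opposite directions at the two times are ``mixed``.
    """
    try:
        smg8 = record.pair_calls[("T8_GC", "T8_RPM")]
        smg28 = record.pair_calls[("T28_GC", "T28_RPM")]
    except KeyError as exc:
        raise KeyError(f"missing pair call for gene {record.gene}: {exc}") from exc
    down8 = smg8.significant and smg8.higher == "T8_GC"
    up8 = smg8.significant and smg8.higher == "T8_RPM"
    down28 = smg28.significant and smg28.higher == "T28_GC"
    up28 = smg28.significant and smg28.higher == "T28_RPM"
    if down8 and down28:
        return "down_both"
    if up8 and up28:
        return "up_both"
    if (down8 and up28) or (up8 and down28):
        return "mixed"
    if down8:
        return "down_T8_only"
    if up8:
        return "up_T8_only"
    if down28:
        return "down_T28_only"
    if up28:
        return "up_T28_only"
    # no SMG pair significant: attributed to maturation over time
    return "time_only"


def trend_summary(categories: Iterable[str] | Mapping[str, int]) -> pd.DataFrame:
    """Count and percentage (1 decimal) of each trend category.

    Accepts either an iterable of category labels or a precomputed
    ``category -> count`` mapping (e.g. printed pie-chart counts).
    """
    if isinstance(categories, Mapping):
        counts = {c: int(categories.get(c, 0)) for c in TREND_CATEGORIES}
        unknown = set(categories) - set(TREND_CATEGORIES)
    else:
        cats = list(categories)
        counts = {c: cats.count(c) for c in TREND_CATEGORIES}
        unknown = set(cats) - set(TREND_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown trend categories: {sorted(unknown)}")
    total = sum(counts.values())
    rows = [
        {
            "category": c,
            "count": counts[c],
            "percent": round(100.0 * counts[c] / total, 1) if total else 0.0,
        }
        for c in TREND_CATEGORIES
    ]
    return pd.DataFrame(rows).set_index("category")


# ---------------------------------------------------------------------------
# Fig.-4-style summaries: top regulated genes, clustering, PCA
# ---------------------------------------------------------------------------

def rpm_vs_gc_score(m: IntensityMatrix) -> pd.Series:
    """Mean RPM-minus-GC log2 difference across both time points, per gene."""
    if not m.log2:
        raise ValueError("scores are defined on the log2 ratio matrix")
    cols = m.class_columns()
    diffs = []
    for t in ("T8", "T28"):
        rpm, gc = cols.get(f"{t}_RPM"), cols.get(f"{t}_GC")
        if rpm and gc:
            diffs.append(m.data[rpm].mean(axis=1) - m.data[gc].mean(axis=1))
    if not diffs:
        raise ValueError("matrix lacks RPM/GC class pairs")
    return sum(diffs) / len(diffs)


def top_regulated(
    m: IntensityMatrix, genes: Sequence[str] | None = None, k: int = 10
) -> tuple[list[str], list[str]]:
    """The ``k`` most down- and most upregulated genes in RPM vs GC.

    Ranked by :func:`rpm_vs_gc_score`; ties broken by gene name. Returns all
    available genes (with a warning) when fewer than ``k`` exist.
    """
    score = rpm_vs_gc_score(m)
    if genes is not None:
        score = score.loc[[g for g in genes if g in score.index]]
    ranked = score.sort_index().sort_values(kind="stable")
    if len(ranked) < 2 * k:
        warnings.warn(
            f"only {len(ranked)} genes available for top-{k} selection", stacklevel=2
        )
    down = ranked.index[: min(k, len(ranked))].tolist()
    up = ranked.index[::-1][: min(k, len(ranked))].tolist()
    return down, up


def zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score (mean 0, sd 1, sample sd); zero-variance rows error."""
    sd = df.std(axis=1, ddof=1)
    flat = sd[~(sd > 0)]
    if len(flat):
        raise ValueError(f"zero-variance row(s): {flat.index.tolist()}")
    return df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)


@dataclass
class ClusterResult:
    zscores: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]


def zscore_and_cluster(
    df: pd.DataFrame, method: str = "average", metric: str = "euclidean"
) -> ClusterResult:
    """Z-score rows then agglomeratively cluster rows and columns.

    Leaf order is the deterministic scipy dendrogram order.
    """
    z = zscore_rows(df)
    row_link = linkage(z.to_numpy(), method=method, metric=metric)
    col_link = linkage(z.to_numpy().T, method=method, metric=metric)
    return ClusterResult(
        zscores=z,
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=[z.index[i] for i in leaves_list(row_link)],
        col_order=[z.columns[i] for i in leaves_list(col_link)],
    )


@dataclass
class PcaResult:
    variance_fractions: np.ndarray  # sums to 1
    scores: pd.DataFrame  # samples x components

    @property
    def variance_percent(self) -> np.ndarray:
        return self.variance_fractions * 100.0


def pca_variance(m: IntensityMatrix) -> PcaResult:
    """PCA with samples as observations on the mean-centered matrix."""
    from sklearn.decomposition import PCA

    if m.data.isna().any().any():
        raise ValueError("PCA expects a complete (imputed) matrix")
    x = m.data.to_numpy(dtype=float).T  # samples x genes
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 genes")
    if np.allclose(x, x.mean(axis=0), atol=1e-12):
        raise ValueError("constant matrix has no principal components")
    pca = PCA(n_components=min(x.shape[0] - 1, x.shape[1]), svd_solver="full")
    scores = pca.fit_transform(x - x.mean(axis=0))
    frac = pca.explained_variance_ratio_
    frac = frac / frac.sum()
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        variance_fractions=frac,
        scores=pd.DataFrame(scores, index=m.data.columns, columns=cols),
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    matrix: IntensityMatrix  # processed (ratioed, filtered, log2, imputed)
    fdr: PermutationFdrResult
    records: list[DapgRecord]  # significant, de-duplicated, classified
    summary: pd.DataFrame
    pca: PcaResult

    @property
    def significant_genes(self) -> list[str]:
        return [r.gene for r in self.records]


def run_pipeline(
    m: IntensityMatrix,
    min_fraction: float = 0.7,
    n_perm: int = 250,
    fdr: float = 0.05,
    alpha: float = 0.05,
    impute_width: float = 0.3,
    impute_downshift: float = 1.8,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full differential-abundance chain on a raw intensity matrix.

    The fixed order is: T0 reference averaging -> ratio -> valid-value filter
    -> log2 -> downshifted-Gaussian imputation -> ANOVA + permutation FDR ->
    Tukey HSD on significant genes -> isoform de-duplication -> trend
    classification. All randomness flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    ref = average_reference(m)
    ratioed = ratio_to_reference(m, ref)
    filtered = filter_valid(ratioed, min_fraction=min_fraction)
    logged = log2_transform(filtered)
    imputed = impute_gaussian(
        logged, width=impute_width, downshift=impute_downshift, rng=rng
    )
    fdr_res = permutation_fdr(imputed, n_perm=n_perm, fdr=fdr, rng=rng)

    cols = imputed.class_columns()
    records: list[DapgRecord] = []
    for gene in imputed.genes[fdr_res.significant.to_numpy()]:
        groups = {c: imputed.data.loc[gene, cs].to_numpy(float) for c, cs in cols.items()}
        rec = DapgRecord(
            gene=str(gene),
            anova_p=float(fdr_res.p_values[gene]),
            significant=True,
            pair_calls=tukey_hsd(groups, alpha=alpha),
        )
        records.append(rec)
    records = dedupe_isoforms(records)
    for rec in records:
        rec.category = classify_trend(rec)
    return PipelineResult(
        matrix=imputed,
        fdr=fdr_res,
        records=records,
        summary=trend_summary([r.category for r in records]),
        pca=pca_variance(imputed),
    )
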