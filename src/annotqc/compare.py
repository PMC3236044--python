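"""Cross-genome comparison statistics.

Given a genomes x measures matrix, this module provides the statistics used
to compare annotation quality across a cohort: column scaling to zero mean
and unit sample standard deviation, per-measure ordinary least-squares
regression (slope, intercept, R^2, two-sided p-value for zero slope),
principal component analysis of the scaled matrix, agglomerative
hierarchical clustering (Euclidean distance, average linkage) for heatmap
ordering, and z-score outlier flagging of individual (genome, measure)
cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .lint import Finding
from .metrics import MetricsRow


@dataclass
class MeasureMatrix:
    """A dense genomes x measures grid with NaN as the missing mask."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)

    @property
    def genomes(self) -> list[str]:
        return list(self.data.index)

    @property
    def measures(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def missing(self) -> np.ndarray:
        return self.data.isna().to_numpy()

    @classmethod
    def from_metrics_rows(cls, rows: Sequence[MetricsRow],
                          measures: Optional[Sequence[str]] = None) -> "MeasureMatrix":
        """Build from per-genome measure rows; default measure set is every
        numeric field of the row."""
        default = ["total_length_bp", "gc_percent", "protein_count", "rna_count",
                   "trna_aa_count", "hypothetical_count", "coding_density",
                   "avg_protein_len_aa", "min_protein_len_aa",
                   "short_protein_percent", "standard_start_percent"]
        measures = list(measures) if measures else default
        recs = {}
        for i, row in enumerate(rows):
            label = row.organism or f"genome{i + 1}"
            base = label
            k = 2
            while label in recs:
                label = f"{base}#{k}"
                k += 1
            values = {}
            for m in measures:
                v = getattr(row, m) if hasattr(row, m) else None
                if m == "hypothetical_ratio":
                    v = row.hypothetical_ratio
                values[m] = np.nan if v is None else float(v)
            recs[label] = values
        df = pd.DataFrame.from_dict(recs, orient="index", columns=measures)
        return cls(df)

    def to_tsv(self) -> str:
        return self.data.to_csv(sep="\t", index_label="genome", na_rep="NA")

    @classmethod
    def from_tsv(cls, text_or_path) -> "MeasureMatrix":
        import io, os
        src = text_or_path
        if isinstance(text_or_path, str) and "\n" in text_or_path:
            src = io.StringIO(text_or_path)
        elif isinstance(text_or_path, (str, os.PathLike)):
            src = str(text_or_path)
        df = pd.read_csv(src, sep="\t", index_col=0, na_values=["NA"])
        return cls(df)


def scale_columns(m: MeasureMatrix) -> MeasureMatrix:
    """Center each measure to mean 0 and scale to sample (n-1) sd 1.

    Missing entries are ignored in the moments and stay missing.  A column
    with fewer than two distinct observed values cannot be scaled and is an
    error naming the measure.
    """
    df = m.data.copy()
    for col in df.columns:
        observed = df[col].dropna()
        if observed.nunique() < 2:
            raise ValueError(f"measure {col!r} is constant; cannot scale")
        sd = observed.std(ddof=1)
        df[col] = (df[col] - observed.mean()) / sd
    return MeasureMatrix(df)


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares line fit of y on x."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    stderr: float = float("nan")

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


def fit_line(x, y) -> RegressionFit:
    """OLS fit with R^2 and the two-sided t-test p-value for zero slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("regression needs at least 3 complete observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 0.0
    else:
        yhat = res.intercept + res.slope * x
        r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=max(0.0, min(1.0, r2)),
                         p_value=float(res.pvalue), n=int(x.size),
                         stderr=float(res.stderr))


def regression_table(m: MeasureMatrix, x_measure: str) -> pd.DataFrame:
    """Fit every other measure against ``x_measure``; one row per measure."""
    rows = {}
    x = m.data[x_measure]
    for col in m.measures:
        if col == x_measure:
            continue
        try:
            fit = fit_line(x, m.data[col])
        except ValueError:
            continue
        rows[col] = {"slope": fit.slope, "intercept": fit.intercept,
                     "r_squared": fit.r_squared, "p_value": fit.p_value, "n": fit.n}
    return pd.DataFrame.from_dict(rows, orient="index")


def pca(m: MeasureMatrix, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a scaled matrix via SVD.

    Returns ``(loadings, scores, variance_fractions)`` with orthonormal
    loadings (measures x k), scores = data @ loadings, and the fraction of
    total variance per retained component.  Missing entries are imputed at
    the column mean, which is 0 on scaled input.  Sign convention: the
    largest-magnitude element of each loading vector is non-negative.
    """
    if k > len(m.measures):
        raise ValueError(f"k={k} exceeds the number of measures {len(m.measures)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    X = m.values.copy()
    X[np.isnan(X)] = 0.0
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s ** 2))
    fractions = (s ** 2 / total) if total > 0 else np.zeros_like(s)
    loadings = vt[:k].T.copy()
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    scores = Xc @ loadings
    return loadings, scores, fractions[:k].copy()


@dataclass
class Dendrogram:
    """Agglomerative clustering result: linkage matrix plus leaf order."""

    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[int]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def hier_cluster(m: MeasureMatrix, axis: str = "genomes") -> Dendrogram:
    """Average-linkage Euclidean clustering of genomes or measures.

    Ties are broken deterministically by input order (scipy's linkage is
    deterministic for a fixed input).  Missing entries are imputed at 0,
    the column mean of scaled input.
    """
    if axis not in ("genomes", "measures"):
        raise ValueError("axis must be 'genomes' or 'measures'")
    X = m.values.copy()
    X[np.isnan(X)] = 0.0
    labels = m.genomes
    if axis == "measures":
        X = X.T
        labels = m.measures
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least 2 items")
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    order = list(hierarchy.leaves_list(Z))
    return Dendrogram(labels=list(labels), linkage=Z, leaf_order=order)


def flag_outliers(m: MeasureMatrix, z_threshold: float = 3.0) -> list[Finding]:
    """One WARN finding per (genome, measure) cell with |z| above threshold.

    Expects scaled input (each column already in z-units)."""
    findings = []
    values = m.values
    for i, genome in enumerate(m.genomes):
        for j, measure in enumerate(m.measures):
            z = values[i, j]
            if np.isnan(z):
                continue
            if abs(z) > z_threshold:
                findings.append(Finding(
                    rule_id="OUT001", severity="WARN", replicon="",
                    feature_handle=genome,
                    message=f"{measure}: z={z:+.2f} beyond |z|>{z_threshold:g} "
                            "relative to the cohort",
                ))
    return findings
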