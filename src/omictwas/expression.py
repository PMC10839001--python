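"""Expression post-processing: expressed-feature filtering, TMM
normalization, counts-per-million and per-feature standardization.

This module is the bridge between raw feature quantification (a
``CountMatrix`` of read counts per gene or transcript per individual) and
the standardized expression matrix ``Z`` that the relationship-matrix and
mixed-model stages consume.  The processing order is

    filter_expressed -> tmm_factors -> cpm -> standardize

Lowly expressed features are removed on *raw* counts (a feature is kept
only when it has >= ``min_count`` reads in strictly more than ``min_frac``
of individuals), library composition is corrected with trimmed-mean-of-
M-values (TMM) factors, expression is expressed as counts per million of
the effective library size, and finally each feature is centred and scaled
to unit (population) variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "filter_expressed",
    "tmm_factors",
    "cpm",
    "standardize",
    "log_cpm",
]

# canonical TMM trim fractions
DEFAULT_TRIM_M = 0.30
DEFAULT_TRIM_A = 0.05

FEATURE_META_COLUMNS = ("chromosome", "start", "end", "biotype", "novel", "level")


@dataclass
class CountMatrix:
    """Raw read counts, features x individuals, plus feature annotation.

    Parameters
    ----------
    counts : integer ndarray, shape (n_features, n_individuals)
    feature_meta : DataFrame indexed by feature id with columns
        ``chromosome, start, end, biotype, novel, level``.
    individual_ids : ordered individual identifiers (unique).
    """

    counts: np.ndarray
    feature_meta: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (features x individuals)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.counts.shape[0] != len(self.feature_meta):
            raise ValueError("feature_meta length must match number of rows")
        if self.counts.shape[1] != len(self.individual_ids):
            raise ValueError("individual_ids length must match number of columns")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual_ids must be unique")
        if self.feature_meta.index.has_duplicates:
            raise ValueError("feature ids must be unique")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[1]

    @property
    def feature_ids(self) -> np.ndarray:
        return self.feature_meta.index.to_numpy()

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-individual library size: the column sum of counts."""
        return self.counts.sum(axis=0)

    def subset_features(self, mask_or_index) -> "CountMatrix":
        mask = np.asarray(mask_or_index)
        return CountMatrix(
            counts=self.counts[mask],
            feature_meta=self.feature_meta.iloc[mask]
            if mask.dtype.kind in "iu"
            else self.feature_meta.loc[mask],
            individual_ids=list(self.individual_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_meta.index, columns=self.individual_ids
        )


@dataclass
class ExpressionMatrix:
    """Real-valued expression, CPM scale or standardized scale.

    ``mu`` and ``sigma2`` hold the per-feature mean and population variance
    of the CPM values, recorded when :func:`standardize` runs so that the
    relationship matrix and its interpretation stay tied to the original
    scale.
    """

    values: np.ndarray
    feature_meta: pd.DataFrame
    individual_ids: list[str]
    scale_tag: str = "cpm"  # {"cpm", "standardized"}
    tmm_factors: np.ndarray | None = None
    mu: np.ndarray | None = None
    sigma2: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> np.ndarray:
        return self.feature_meta.index.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_meta.index, columns=self.individual_ids
        )


def filter_expressed(
    counts: CountMatrix, min_count: int = 2, min_frac: float = 0.30
) -> CountMatrix:
    """Keep features effectively expressed in more than ``min_frac`` of individuals.

    A feature is retained iff the number of individuals with raw count
    >= ``min_count`` is *strictly* greater than ``min_frac * n``.  With the
    defaults a feature seen at >=2 reads in exactly 30% of individuals is
    dropped; 40% is kept.
    """
    n = counts.n_individuals
    n_expressed = (counts.counts >= min_count).sum(axis=1)
    keep = n_expressed > min_frac * n
    if not keep.any():
        raise ValueError(
            "no feature passes the expressed filter "
            f"(min_count={min_count}, min_frac={min_frac}); "
            "lower the thresholds or check the input counts"
        )
    return counts.subset_features(np.flatnonzero(keep))


def _uq_reference_column(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Reference = column whose upper-quartile/library-size ratio is closest
    to the mean of those ratios."""
    with np.errstate(divide="ignore", invalid="ignore"):
        uq = np.quantile(counts, 0.75, axis=0) / lib_sizes
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = DEFAULT_TRIM_M,
    trim_a: float = DEFAULT_TRIM_A,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, one per individual.

    For each column k against the reference column r, over features with
    positive counts in both: M = log2((y_k/N_k)/(y_r/N_r)) and
    A = 0.5*log2((y_k/N_k)*(y_r/N_r)).  The upper and lower ``trim_m``
    fraction by M and ``trim_a`` fraction by A are discarded, and the
    factor is the precision-weighted mean of the surviving M values, with
    weights the inverse of the delta-method variance
    (N_k - y_k)/(N_k y_k) + (N_r - y_r)/(N_r y_r).  Factors are rescaled to
    geometric mean 1, so the reference drifts off exactly 1 only by that
    global rescaling.
    """
    y = counts.counts.astype(float)
    m_feat, n = y.shape
    if n < 2:
        raise ValueError("TMM needs at least 2 individuals")
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every column must contain at least one positive count")
    ref = _uq_reference_column(y, lib)
    log_factors = np.zeros(n)
    yr = y[:, ref]
    for k in range(n):
        if k == ref:
            continue
        yk = y[:, k]
        shared = (yk > 0) & (yr > 0)
        if not shared.any():
            warnings.warn(
                f"column {counts.individual_ids[k]!r} shares no expressed feature "
                "with the TMM reference; factor set to 1",
                RuntimeWarning,
            )
            continue
        pk = yk[shared] / lib[k]
        pr = yr[shared] / lib[ref]
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        v = (lib[k] - yk[shared]) / (lib[k] * yk[shared]) + (lib[ref] - yr[shared]) / (
            lib[ref] * yr[shared]
        )
        if np.max(np.abs(m)) < 1e-6:  # columns proportional: no correction
            continue
        ng = m.size
        lo_m = np.floor(ng * trim_m) + 1
        hi_m = ng + 1 - lo_m
        lo_a = np.floor(ng * trim_a) + 1
        hi_a = ng + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            warnings.warn(
                f"TMM trimming removed every feature for column "
                f"{counts.individual_ids[k]!r}; factor set to 1",
                RuntimeWarning,
            )
            continue
        log_factors[k] = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return factors


def cpm(counts: CountMatrix, factors: np.ndarray | None = None) -> ExpressionMatrix:
    """Counts per million of the effective library size N_j * f_j."""
    lib = counts.library_sizes.astype(float)
    if np.any(lib <= 0):
        raise ValueError("zero library size: cannot compute CPM")
    if factors is None:
        factors = np.ones(counts.n_individuals)
    factors = np.asarray(factors, dtype=float)
    values = counts.counts / (lib * factors) * 1e6
    return ExpressionMatrix(
        values=values,
        feature_meta=counts.feature_meta.copy(),
        individual_ids=list(counts.individual_ids),
        scale_tag="cpm",
        tmm_factors=factors,
    )


def log_cpm(counts: CountMatrix, factors: np.ndarray | None = None) -> ExpressionMatrix:
    """log2(CPM + 1) variant of :func:`cpm` (configurable alternative scale)."""
    expr = cpm(counts, factors)
    expr.values = np.log2(expr.values + 1.0)
    return expr


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Centre and scale each feature to mean 0 and population variance 1.

    The population (1/n) variance convention makes the mean diagonal of the
    downstream relationship matrix exactly 1, so the REML variance fraction
    reads directly as a proportion of phenotypic variance.  Zero-variance
    features carry no information and are dropped with a warning.
    Standardizing a standardized matrix is a no-op up to the recorded
    mu/sigma2 bookkeeping.
    """
    if expr.n_individuals < 2:
        raise ValueError("standardization needs at least 2 individuals")
    x = np.asarray(expr.values, dtype=float)
    mu = x.mean(axis=1)
    sigma2 = x.var(axis=1)  # population (1/n) variance
    keep = sigma2 > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance feature(s) before "
            "standardization",
            RuntimeWarning,
        )
    x = x[keep]
    mu_k = mu[keep]
    s_k = np.sqrt(sigma2[keep])
    z = (x - mu_k[:, None]) / s_k[:, None]
    return ExpressionMatrix(
        values=z,
        feature_meta=expr.feature_meta.iloc[np.flatnonzero(keep)].copy(),
        individual_ids=list(expr.individual_ids),
        scale_tag="standardized",
        tmm_factors=expr.tmm_factors,
        mu=mu_k,
        sigma2=s_k**2,
    )
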