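"""Cross-sample entropy (CSE) between pairs of ROI time series.

Cross-sample entropy quantifies the asynchrony of two signals: it is the
negative logarithm of the conditional probability that two sub-vector
("template") sequences that match for ``m`` consecutive points also match
for ``m + 1`` points,

    CSE(x, y; m, r) = -ln( A / B ),

where ``B`` counts ordered template pairs whose Chebyshev distance at
length ``m`` is below the tolerance ``r`` and ``A`` counts the same at
length ``m + 1``.  Synchronous signals produce many long matches and hence
low CSE; independent signals produce few and hence high CSE.

Template counting follows the standard sample-entropy convention: for
series of length ``N`` the same ``N - m`` template start positions are used
for both lengths, which guarantees ``A <= B`` and therefore ``CSE >= 0``.
Series are standardized to zero mean and unit variance before matching, so
the tolerance ``r`` is expressed in SD units; a raw-units mode is available
for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .preprocess import ROITimeSeries

__all__ = [
    "EntropyParams",
    "MatchCounts",
    "RawCSEMatrix",
    "standardize",
    "chebyshev_distance",
    "count_matches",
    "match_counts",
    "cross_sample_entropy",
    "compute_cse_matrix",
    "CrossSampleEntropy",
]


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of the CSE computation.

    m : template (embedding) length; matches are sought at lengths m and m+1.
    r : Chebyshev tolerance, in SD units of the standardized series by
        default (``raw_units=False``).
    undefined_policy : what to do when no template pair matches — "cap"
        replaces the undefined logarithm with the largest value resolvable
        at the given series length, ``-ln(1 / n_templates**2)``; "missing"
        records NaN and flags the entry in the undefined mask.
    include_self_pairs : whether diagonal matrix entries are computed with
        the formula applied verbatim to the pair (x, x).
    """

    m: int = 2
    r: float = 0.6
    undefined_policy: Literal["cap", "missing"] = "cap"
    raw_units: bool = False
    include_self_pairs: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"template length m must be >= 1, got {self.m}")
        if not self.r > 0:
            raise ValueError(f"tolerance r must be > 0, got {self.r}")
        if self.undefined_policy not in ("cap", "missing"):
            raise ValueError(f"unknown undefined_policy {self.undefined_policy!r}")


@dataclass(frozen=True)
class MatchCounts:
    """Template match counts underlying one CSE value."""

    n_templates: int
    b_total: int  # ordered pairs matching at length m
    a_total: int  # ordered pairs matching at length m + 1

    def __post_init__(self) -> None:
        if not (0 <= self.a_total <= self.b_total <= self.n_templates**2):
            raise ValueError(
                f"inconsistent counts a={self.a_total}, b={self.b_total}, "
                f"n_templates={self.n_templates}"
            )


@dataclass
class RawCSEMatrix:
    """R x R matrix of pairwise cross-sample entropies for one subject."""

    subject_id: str
    values: np.ndarray
    params: EntropyParams
    undefined_mask: np.ndarray
    roi_labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.undefined_mask = np.asarray(self.undefined_mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"values must be square, got shape {self.values.shape}")
        if self.undefined_mask.shape != self.values.shape:
            raise ValueError("undefined_mask shape must match values")
        if not self.roi_labels:
            self.roi_labels = list(range(1, self.values.shape[0] + 1))

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def standardize(series: Sequence[float] | np.ndarray) -> np.ndarray:
    """Shift and scale a series to mean 0 and (population) SD 1.

    A constant series has no scale and maps to all zeros.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be 1-D with length >= 2")
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def chebyshev_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Maximum absolute componentwise difference between two vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.max(np.abs(u - v)))


def _shifted_max(d0: np.ndarray, length: int, n_templates: int) -> np.ndarray:
    """Chebyshev template distances from the pointwise distance grid.

    ``d0[i, j] = |x_i - y_j|``; the distance between templates starting at
    (i, j) is the maximum of d0 along the diagonal offsets 0..length-1.
    """
    d = d0[:n_templates, :n_templates].copy()
    for k in range(1, length):
        np.maximum(d, d0[k : k + n_templates, k : k + n_templates], out=d)
    return d


def count_matches(
    x: np.ndarray,
    y: np.ndarray,
    l: int,
    r: float,
    n_templates: int | None = None,
) -> int:
    """Count ordered template pairs (i, j) with Chebyshev distance < r.

    Templates are the length-``l`` sub-vectors ``x[i:i+l]`` and ``y[j:j+l]``.
    By default ``N - l`` start positions are compared; the CSE computation
    overrides this with the shared ``N - m`` range for both lengths.
    Matching is strict (``d < r``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("series must be 1-D")
    n = min(x.size, y.size)
    if n_templates is None:
        n_templates = n - l
    if n_templates < 1:
        raise ValueError(f"series too short (length {n}) for template length {l}")
    if n_templates + l - 1 > n:
        raise ValueError(
            f"{n_templates} templates of length {l} do not fit in series of length {n}"
        )
    d0 = np.abs(x[:, None] - y[None, :])
    d = _shifted_max(d0, l, n_templates)
    return int(np.count_nonzero(d < r))


def match_counts(x: np.ndarray, y: np.ndarray, params: EntropyParams) -> MatchCounts:
    """B and A counts over the shared N - m template range."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = min(x.size, y.size)
    if n < params.m + 2:
        raise ValueError(f"series length {n} < m + 2 = {params.m + 2}")
    nt = n - params.m
    # one pointwise grid serves both template lengths
    d0 = np.abs(x[:, None] - y[None, :])
    dm = _shifted_max(d0, params.m, nt)
    b = int(np.count_nonzero(dm < params.r))
    np.maximum(dm, d0[params.m : params.m + nt, params.m : params.m + nt], out=dm)
    a = int(np.count_nonzero(dm < params.r))
    return MatchCounts(n_templates=nt, b_total=b, a_total=a)


def cross_sample_entropy(
    x: np.ndarray,
    y: np.ndarray,
    params: EntropyParams | None = None,
) -> float:
    """CSE of a series pair; NaN marks an undefined value under "missing".

    Series are standardized first unless ``params.raw_units`` is set.  When
    no (m+1)-length or even no m-length match exists the ratio A/B is
    undefined; policy "cap" substitutes the largest resolvable entropy
    ``-ln(1 / n_templates**2)``, policy "missing" returns NaN.
    """
    params = params or EntropyParams()
    if not params.raw_units:
        x = standardize(x)
        y = standardize(y)
    counts = match_counts(x, y, params)
    return _entropy_from_counts(counts, params)


def _entropy_from_counts(counts: MatchCounts, params: EntropyParams) -> float:
    if counts.a_total > 0:  # b_total >= a_total > 0
        return -math.log(counts.a_total / counts.b_total)
    if params.undefined_policy == "cap":
        return -math.log(1.0 / counts.n_templates**2)
    return math.nan


def compute_cse_matrix(ts: ROITimeSeries, params: EntropyParams | None = None) -> RawCSEMatrix:
    """Pairwise CSE between every pair of ROI rows of one subject.

    The matrix is symmetric by construction (each unordered pair is computed
    once); the diagonal applies the formula to the pair (x, x) unless
    ``params.include_self_pairs`` is off, in which case it is NaN-masked.
    """
    params = params or EntropyParams()
    rows = ts.values
    n_rois, n_t = rows.shape
    if n_t < params.m + 2:
        raise ValueError(f"need at least m + 2 = {params.m + 2} timepoints, got {n_t}")
    if params.raw_units:
        std_rows = rows.astype(float)
    else:
        std_rows = np.stack([standardize(row) for row in rows])
    values = np.full((n_rois, n_rois), np.nan)
    mask = np.zeros((n_rois, n_rois), dtype=bool)
    for i in range(n_rois):
        start = i if params.include_self_pairs else i + 1
        for k in range(start, n_rois):
            v = _entropy_from_counts(match_counts(std_rows[i], std_rows[k], params), params)
            values[i, k] = values[k, i] = v
            if math.isnan(v):
                mask[i, k] = mask[k, i] = True
    if not params.include_self_pairs:
        mask[np.diag_indices(n_rois)] = True
    return RawCSEMatrix(
        subject_id=ts.subject_id,
        values=values,
        params=params,
        undefined_mask=mask,
        roi_labels=list(ts.roi_labels),
    )


class CrossSampleEntropy:
    """Transformer mapping ROI time series to pairwise CSE matrices.

    scikit-learn style: stateless apart from parameters; ``transform``
    accepts a single :class:`ROITimeSeries` or an iterable of them and
    returns :class:`RawCSEMatrix` objects.
    """

    def __init__(
        self,
        m: int = 2,
        r: float = 0.6,
        undefined_policy: str = "cap",
        raw_units: bool = False,
        include_self_pairs: bool = True,
    ):
        self.m = m
        self.r = r
        self.undefined_policy = undefined_policy
        self.raw_units = raw_units
        self.include_self_pairs = include_self_pairs

    def _params(self) -> EntropyParams:
        return EntropyParams(
            m=self.m,
            r=self.r,
            undefined_policy=self.undefined_policy,  # type: ignore[arg-type]
            raw_units=self.raw_units,
            include_self_pairs=self.include_self_pairs,
        )

    def fit(self, X=None, y=None) -> "CrossSampleEntropy":
        self.params_ = self._params()
        return self

    def transform(self, X):
        params = self._params()
        if isinstance(X, ROITimeSeries):
            return compute_cse_matrix(X, params)
        return [compute_cse_matrix(ts, params) for ts in X]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {
            "m": self.m,
            "r": self.r,
            "undefined_policy": self.undefined_policy,
            "raw_units": self.raw_units,
            "include_self_pairs": self.include_self_pairs,
        }

    def set_params(self, **kwargs) -> "CrossSampleEntropy":
        for key, value in kwargs.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self
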