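"""Per-chromosome segment model and Mahalanobis distances.

A chromosome is summarized by the mean vector mu and sample covariance S of
the rho vectors of its 5-kb segments. The squared Mahalanobis distance of a
query composition x (typically a whole plasmid) is

    D^2 = (x - mu)^T S^{-1} (x - mu).

The model is *unavailable* when the number of segments n does not exceed the
number of k-mer variables p = 4^k (S is then singular by construction); an
unavailable model yields NA distances, never an exception. Because D^2 has
no upper bound, it is converted to an empirical P value: the fraction of the
chromosome's own segments whose D^2 from mu strictly exceeds the query's.
P near 1 means the plasmid is compositionally indistinguishable from the
chromosome's own segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional

import numpy as np

from .composition import CompositionMatrix, KmerVector

__all__ = [
    "ChromosomeModel",
    "DistanceResult",
    "SegmentMahalanobis",
    "fit_model",
    "mahalanobis_d2",
    "segment_distances",
    "empirical_p",
]

#: reciprocal-condition threshold below which S is treated as singular
RCOND_SINGULAR = 1e-12


@dataclass
class ChromosomeModel:
    """Fitted segment-population summary (the Results object of the fit).

    Attributes
    ----------
    mu : (p,) mean of segment rho vectors
    S : (p, p) sample covariance (denominator n - 1)
    available : False when n <= p; no distance may then be computed
    used_pseudoinverse : True when S was numerically singular despite n > p
        and a Moore-Penrose pseudo-inverse was used
    condition_estimate : ratio of largest to smallest singular value of S
    """

    source_id: str
    k: int
    mu: np.ndarray
    S: np.ndarray
    n: int
    p: int
    available: bool
    used_pseudoinverse: bool = False
    condition_estimate: float = np.inf
    _S_inv: Optional[np.ndarray] = field(default=None, repr=False)
    _matrix: Optional[CompositionMatrix] = field(default=None, repr=False)

    def mahalanobis_d2(self, x) -> float:
        return mahalanobis_d2(x, self)

    @cached_property
    def segment_d2(self) -> np.ndarray:
        if self._matrix is None:
            raise ValueError("model was not fitted from a retained matrix")
        return segment_distances(self, self._matrix)

    def score(self, x) -> "DistanceResult":
        """Distance and empirical P value of a query composition."""
        if not self.available:
            return DistanceResult(
                source_id=self.source_id, k=self.k, d2_plasmid=np.nan,
                segment_d2=np.full(self.n, np.nan), empirical_p=np.nan,
                na=True, n_segments=self.n, n_exceed=0,
            )
        d2 = self.mahalanobis_d2(x)
        seg = self.segment_d2
        n_exceed = int(np.count_nonzero(seg > d2))
        return DistanceResult(
            source_id=self.source_id, k=self.k, d2_plasmid=d2,
            segment_d2=seg, empirical_p=n_exceed / len(seg), na=False,
            n_segments=len(seg), n_exceed=n_exceed,
        )

    def summary(self) -> str:
        lines = [
            f"Segment Mahalanobis model: {self.source_id} (k={self.k})",
            f"  segments (n): {self.n}    variables (p = 4^k): {self.p}",
            f"  available: {self.available}"
            + ("" if self.available else "  [n <= p: distances are NA]"),
            f"  condition estimate of S: {self.condition_estimate:.3g}",
            f"  pseudo-inverse used: {self.used_pseudoinverse}",
        ]
        return "\n".join(lines)

    def to_tsv(self, prefix) -> None:
        """Write mu and S as a TSV pair with a small metadata header."""
        header = (
            f"# source_id={self.source_id} k={self.k} n={self.n} p={self.p} "
            f"available={self.available} used_pseudoinverse={self.used_pseudoinverse}\n"
        )
        for name, arr in (("mu", self.mu[None, :]), ("cov", self.S)):
            path = f"{prefix}.{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                np.savetxt(fh, arr, delimiter="\t", fmt="%.10g")


@dataclass
class DistanceResult:
    """D^2 of one query against one chromosome model, with empirical P."""

    source_id: str
    k: int
    d2_plasmid: float
    segment_d2: np.ndarray
    empirical_p: float
    na: bool
    n_segments: int = 0
    n_exceed: int = 0

    @property
    def p_fraction(self) -> str:
        """Empirical P as an exact fraction string, e.g. ``'12/116'``."""
        return "NA" if self.na else f"{self.n_exceed}/{self.n_segments}"


class SegmentMahalanobis:
    """Model object: segment composition matrix -> (mu, S) summary.

    ``fit()`` returns a :class:`ChromosomeModel`. The covariance uses the
    unbiased denominator n - 1; when S is numerically singular despite
    n > p, a Moore-Penrose pseudo-inverse is substituted and flagged.
    """

    def __init__(self, matrix: CompositionMatrix):
        if matrix.n == 0:
            raise ValueError("empty composition matrix")
        self.matrix = matrix

    def fit(self, rcond_threshold: float = RCOND_SINGULAR) -> ChromosomeModel:
        X = self.matrix.rows
        n, p = X.shape
        mu = X.mean(axis=0)
        available = n > p
        if n > 1:
            S = np.cov(X, rowvar=False, ddof=1)
            S = np.atleast_2d(S)
        else:
            S = np.zeros((p, p))
        S_inv = None
        used_pinv = False
        cond = np.inf
        if available:
            # SVD once: condition estimate, inverse or pseudo-inverse
            U, s, Vt = np.linalg.svd(S, hermitian=True)
            smax = s[0] if len(s) else 0.0
            smin = s[-1] if len(s) else 0.0
            cond = np.inf if smin == 0 else smax / smin
            eps = np.finfo(float).eps
            # cancellation noise floor: degenerate data leave O((eps|X|)^2)
            # residuals in S that must not be inverted
            noise_floor = n * p * (eps * max(1.0, float(np.abs(X).max()))) ** 2
            if smax <= noise_floor or smin / smax < rcond_threshold:
                used_pinv = True
                tol = max(p * eps * smax, noise_floor)
                inv_s = np.where(s > tol, 1.0 / np.where(s > tol, s, 1.0), 0.0)
            else:
                inv_s = 1.0 / s
            S_inv = (Vt.T * inv_s) @ U.T
        return ChromosomeModel(
            source_id=self.matrix.source_id,
            k=self.matrix.k,
            mu=mu,
            S=S,
            n=n,
            p=p,
            available=available,
            used_pseudoinverse=used_pinv,
            condition_estimate=cond,
            _S_inv=S_inv,
            _matrix=self.matrix,
        )


def fit_model(matrix: CompositionMatrix) -> ChromosomeModel:
    """Fit the (mu, S) segment model; unavailability (n <= p) is a state."""
    return SegmentMahalanobis(matrix).fit()


def _as_vector(x, model: ChromosomeModel) -> np.ndarray:
    if isinstance(x, KmerVector):
        if x.k != model.k:
            raise ValueError(f"k mismatch: query k={x.k}, model k={model.k}")
        if not x.valid:
            raise ValueError("query KmerVector is invalid (degenerate composition)")
        x = x.values
    x = np.asarray(x, dtype=float)
    if x.shape != (model.p,):
        raise ValueError(f"dimension mismatch: query {x.shape}, model p={model.p}")
    return x


def mahalanobis_d2(x, model: ChromosomeModel) -> float:
    """Squared Mahalanobis distance of x from the segment population.

    Returns NaN (NA) when the model is unavailable.
    """
    if not model.available:
        return np.nan
    xv = _as_vector(x, model)
    diff = xv - model.mu
    # clamp tiny negative round-off from the symmetric quadratic form
    return float(max(diff @ model._S_inv @ diff, 0.0))


def segment_distances(model: ChromosomeModel, matrix: CompositionMatrix) -> np.ndarray:
    """D^2 of each retained segment from mu, in row order; NA if unavailable."""
    if matrix.k != model.k:
        raise ValueError("k mismatch between model and matrix")
    if not model.available:
        return np.full(matrix.n, np.nan)
    diff = matrix.rows - model.mu
    return np.maximum(np.einsum("ij,jk,ik->i", diff, model._S_inv, diff), 0.0)


def empirical_p(d2_query: float, segment_d2) -> float:
    """Fraction of segment distances strictly exceeding the query distance.

    Ties count against the query (strict '>'), so P ranges over
    {0, 1/n, ..., 1}; P near 1 means the query is more central than nearly
    all of the chromosome's own segments.
    """
    seg = np.asarray(segment_d2, dtype=float)
    if seg.size == 0:
        raise ValueError("segment_d2 must be non-empty")
    return float(np.count_nonzero(seg > d2_query) / seg.size)
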