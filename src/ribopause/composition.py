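"""Compositional metagene analysis: 10-bin density compositions, ilr
coordinates, and the paired Hotelling T^2 comparison between conditions.

Per-bin density percentages are compositions (parts of a whole), so
standard multivariate statistics are applied only after the isometric
log-ratio (ilr) transform maps the 10-part simplex to R^9.  Geometric
means summarize condition profiles, the standard central-tendency measure
for compositional data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import helmert


@dataclass
class HotellingResult:
    """Paired Hotelling T^2 on ilr coordinates.

    F = T^2 * (n - p) / (p * (n - 1)); the p-value is the upper tail of
    F(df1 = p, df2 = n - p).
    """

    T2: float
    F: float
    df1: int
    df2: int
    p_value: float
    n_pairs: int


@dataclass
class MardiaResult:
    """Mardia's multivariate skewness and kurtosis tests (advisory)."""

    skew_stat: float
    skew_p: float
    kurt_stat: float
    kurt_p: float

    @property
    def p_value(self) -> float:
        # Bonferroni combination of the two sub-tests
        return min(1.0, 2.0 * min(self.skew_p, self.kurt_p))


def close(parts, total: float = 100.0) -> np.ndarray:
    """Rescale a positive vector to the given constant sum (closure)."""
    parts = np.asarray(parts, dtype=float)
    s = parts.sum()
    if not s > 0:
        raise ValueError("cannot close a vector with non-positive sum")
    return parts * (total / s)


def bin_edges(window_length: int, n_bins: int = 10) -> np.ndarray:
    """Split a window into n_bins contiguous segments of near-equal nt
    length; the remainder nucleotides go one each to the 3'-most bins."""
    if window_length < n_bins:
        raise ValueError(f"window of {window_length} nt cannot fill {n_bins} bins")
    base, extra = divmod(window_length, n_bins)
    sizes = np.full(n_bins, base)
    if extra:
        sizes[-extra:] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


def bin_composition(track, window: tuple[int, int], n_bins: int = 10) -> np.ndarray:
    """Percent of window density per bin: a composition summing to 100."""
    lo, hi = window
    v = np.asarray(track.values if hasattr(track, "values") else track, dtype=float)[lo:hi]
    if not v.sum() > 0:
        raise ValueError("zero density in window: composition undefined")
    edges = bin_edges(len(v), n_bins)
    sums = np.add.reduceat(v, edges[:-1])
    return close(sums, 100.0)


def replace_zeros(parts, fraction: float = 0.65, floor: float = 1e-6) -> np.ndarray:
    """Multiplicative simple zero replacement.

    Zero parts are set to ``fraction`` of the smallest nonzero part of the
    same composition (never below ``floor``), then the composition is
    re-closed to its original total.  No-op for strictly positive input.
    """
    parts = np.asarray(parts, dtype=float)
    if (parts < 0).any():
        raise ValueError("negative part in composition")
    zero = parts == 0
    if not zero.any():
        return parts.copy()
    if zero.all():
        raise ValueError("all-zero composition cannot be repaired")
    delta = max(fraction * parts[~zero].min(), floor)
    out = parts.copy()
    out[zero] = delta
    return close(out, parts.sum())


def geometric_mean_profile(compositions) -> np.ndarray:
    """Part-wise geometric mean across compositions, re-closed to 100."""
    X = np.atleast_2d(np.asarray(compositions, dtype=float))
    if (X <= 0).any():
        raise ValueError("geometric mean requires strictly positive parts; "
                         "apply zero replacement first")
    return close(np.exp(np.log(X).mean(axis=0)), 100.0)


def ilr_basis(n_parts: int, kind: str = "pivot-1") -> np.ndarray:
    """Orthonormal contrast matrix V of shape (n_parts - 1, n_parts).

    "pivot-1": pivot balances in part order — row i contrasts part i
    against the geometric mean of parts i+1..D.  "helmert": the
    normalized Helmert sub-matrix.  Rows are unit-norm and orthogonal to
    the all-ones vector, so coords = V @ clr(x).
    """
    D = n_parts
    if D < 2:
        raise ValueError("need at least 2 parts")
    if kind == "pivot-1":
        V = np.zeros((D - 1, D))
        for i in range(D - 1):
            r = D - i - 1  # parts to the right of the pivot
            norm = np.sqrt(r / (r + 1))
            V[i, i] = norm
            V[i, i + 1 :] = -norm / r
        return V
    if kind == "helmert":
        H = helmert(D)
        return H / np.linalg.norm(H, axis=1, keepdims=True)
    raise ValueError(f"unknown ilr basis {kind!r}")


def ilr_transform(parts, basis: np.ndarray) -> np.ndarray:
    """Isometric log-ratio coordinates: V @ (ln x - mean ln x).

    Closure-invariant: ilr(c*x) == ilr(x) for any positive scalar c.
    """
    parts = np.asarray(parts, dtype=float)
    if (parts <= 0).any():
        raise ValueError("ilr requires strictly positive parts")
    logp = np.log(parts)
    clr = logp - logp.mean(axis=-1, keepdims=True)
    return clr @ basis.T


def paired_hotelling(ilr_a, ilr_b) -> HotellingResult:
    """Paired Hotelling T^2 test on two matched samples of ilr coordinates.

    Rows are paired observations (same ORFs, two conditions).  T^2 =
    n * dbar' S^-1 dbar on the differences d = a - b, with S their sample
    covariance.  Identical samples give T^2 = 0, p = 1 exactly.
    """
    a = np.atleast_2d(np.asarray(ilr_a, dtype=float))
    b = np.atleast_2d(np.asarray(ilr_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}: pairs must align")
    n, p = a.shape
    if n <= p:
        raise ValueError(
            f"insufficient paired ORFs for a {p}-dimensional test: need n > {p}, got {n}"
        )
    d = a - b
    if np.allclose(d, 0.0):
        return HotellingResult(0.0, 0.0, p, n - p, 1.0, n)
    dbar = d.mean(axis=0)
    S = np.cov(d, rowvar=False, ddof=1)
    try:
        sol = np.linalg.solve(S, dbar)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular difference covariance; consider fewer bins"
        ) from exc
    T2 = float(n * dbar @ sol)
    F = T2 * (n - p) / (p * (n - 1))
    pval = float(stats.f.sf(F, p, n - p))
    return HotellingResult(T2, F, p, n - p, pval, n)


def normality_check(ilr_sample) -> MardiaResult:
    """Mardia's multivariate skewness/kurtosis tests on ilr coordinates.

    Advisory only: reported alongside the Hotelling test, never used to
    gate the pipeline.  Skewness statistic n*b1p/6 is chi-squared with
    p(p+1)(p+2)/6 df; kurtosis is a two-sided normal z-test of b2p
    against p(p+2).
    """
    X = np.atleast_2d(np.asarray(ilr_sample, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p for the normality check, got n={n}, p={p}")
    d = X - X.mean(axis=0)
    S = d.T @ d / n  # ML covariance, as in Mardia's statistics
    Sinv = np.linalg.inv(S)
    G = d @ Sinv @ d.T
    b1p = float((G**3).sum()) / n**2
    skew_stat = n * b1p / 6.0
    skew_df = p * (p + 1) * (p + 2) / 6.0
    skew_p = float(stats.chi2.sf(skew_stat, skew_df))
    b2p = float((np.diag(G) ** 2).sum()) / n
    kurt_stat = (b2p - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    kurt_p = float(2.0 * stats.norm.sf(abs(kurt_stat)))
    return MardiaResult(skew_stat, skew_p, float(kurt_stat), kurt_p)
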