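"""Mutual-information distances between component maps.

The dissimilarity between two spatial components s_i, s_j is the variation of
information

    D(s_i, s_j) = H(s_i, s_j) - I(s_i, s_j),

with H the joint entropy and I the mutual information (natural logarithm, so
D is in nats).  Unlike I itself, D is a true metric on random variables,
which is what makes it usable as input to hierarchical clustering.

Two estimators are provided:

* ``histogram`` -- each map is rank-ordered (an adaptive partitioning that
  renders the marginals uniform and the result insensitive to monotone
  transforms of the maps), then binned into M = round(1 + log2 N)
  equal-population bins per axis; H and I are plug-in sums over the M x M
  joint frequency table.
* ``kde`` -- each map is standardised and its densities estimated with
  Gaussian kernels at the Silverman bandwidths h = 1.06 sigma N^(-1/5) (1D)
  and h = sigma (4/(d+2))^(1/(d+4)) N^(-1/(d+4)), d = 2 (2D, which reduces to
  sigma N^(-1/6)); H and I are computed by adaptive Simpson quadrature of the
  kernel densities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "HistogramEstimatorConfig",
    "KDEEstimatorConfig",
    "DistanceMatrix",
    "QuadratureError",
    "rank_transform",
    "n_bins_rule",
    "joint_histogram",
    "hist_entropy_mi",
    "silverman_1d",
    "silverman_2d",
    "kde_pdf_1d",
    "kde_pdf_2d",
    "adaptive_simpson",
    "kde_entropy_mi",
    "entropy_mi",
    "mi_distance",
    "pairwise_distances",
]


class QuadratureError(RuntimeError):
    """Adaptive Simpson quadrature failed to reach the requested tolerance."""


@dataclass(frozen=True)
class HistogramEstimatorConfig:
    """``n_bins`` defaults to the sample-size rule M = round(1 + log2 N)."""

    n_bins: int | None = None
    rank_order: bool = True

    def bins_for(self, n_samples: int) -> int:
        m = self.n_bins if self.n_bins is not None else n_bins_rule(n_samples)
        if m < 2:
            raise ValueError("need at least 2 bins")
        return m


@dataclass(frozen=True)
class KDEEstimatorConfig:
    """Bandwidths default to the Silverman rules on standardised data.

    ``bounds_pad`` is the integration-box margin beyond the data range, in
    units of the 2D bandwidth.
    """

    bandwidth_1d: float | None = None
    bandwidth_2d: float | None = None
    integration_tolerance: float = 1e-6
    bounds_pad: float = 5.0
    density_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.bandwidth_1d is not None and self.bandwidth_1d <= 0:
            raise ValueError("bandwidth_1d must be positive")
        if self.bandwidth_2d is not None and self.bandwidth_2d <= 0:
            raise ValueError("bandwidth_2d must be positive")
        if self.bounds_pad < 5.0:
            raise ValueError("integration bounds must extend at least 5 bandwidths")


@dataclass
class DistanceMatrix:
    values: np.ndarray  # (n, n) symmetric, zero diagonal
    estimator: str  # "histogram" | "kde"
    component_ids: list[int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if (v < -1e-9).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        labels = [f"IC{i}" for i in self.component_ids]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.to_dataframe().to_csv(csv_path)
        sidecar = csv_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"estimator": self.estimator, **self.provenance}, indent=2)
        )


# ---------------------------------------------------------------------------
# histogram path


def rank_transform(values: np.ndarray) -> np.ndarray:
    """Replace values by their ranks (1..N, ties averaged)."""
    v = np.asarray(values)
    if v.size < 2:
        raise ValueError("need at least two observations")
    return rankdata(v, method="average")


def n_bins_rule(n_samples: int) -> int:
    """Sturges-style bin count M = round(1 + log2 N)."""
    if n_samples < 2:
        raise ValueError("need at least two observations")
    return int(round(1 + np.log2(n_samples)))


def _quantile_edges(values: np.ndarray, m: int) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0.0, 1.0, m + 1))
    span = edges[-1] - edges[0]
    eps = 1e-9 * max(span, 1.0)
    edges[0] -= eps
    edges[-1] += eps
    return edges


def joint_histogram(x: np.ndarray, y: np.ndarray, m: int | None = None) -> np.ndarray:
    """M x M joint probability table over equal-population (quantile) bins.

    On rank-transformed inputs quantile bins coincide with equal-width bins up
    to ties, realising adaptive partitioning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if m is None:
        m = n_bins_rule(len(x))
    counts, _, _ = np.histogram2d(x, y, bins=[_quantile_edges(x, m), _quantile_edges(y, m)])
    return counts / len(x)


def hist_entropy_mi(table: np.ndarray) -> tuple[float, float]:
    """(joint entropy H, mutual information I) of a joint probability table,
    in nats, with the 0 log 0 = 0 convention."""
    p = np.asarray(table, dtype=float)
    if p.min() < -1e-12 or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("not a probability table")
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    prow = p.sum(axis=1)
    pcol = p.sum(axis=0)
    outer = np.outer(prow, pcol)
    i = float((p[nz] * np.log(p[nz] / outer[nz])).sum())
    return h, i


# ---------------------------------------------------------------------------
# KDE path


def silverman_1d(sigma: float, n_samples: int) -> float:
    """Rule-of-thumb 1D bandwidth h = 1.06 sigma N^(-1/5)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_samples < 2:
        raise ValueError("need at least two observations")
    return 1.06 * sigma * n_samples ** (-1.0 / 5.0)


def silverman_2d(sigma: float, n_samples: int) -> float:
    """Rule-of-thumb isotropic 2D bandwidth; at d = 2 the prefactor
    (4/(d+2))^(1/(d+4)) equals 1, so h = sigma N^(-1/6)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_samples < 2:
        raise ValueError("need at least two observations")
    d = 2
    return sigma * (4.0 / (d + 2)) ** (1.0 / (d + 4)) * n_samples ** (-1.0 / (d + 4))


def kde_pdf_1d(data: np.ndarray, h: float):
    """Gaussian-mixture density estimate; returns a vectorised evaluator."""
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    data = np.asarray(data, dtype=float)
    norm = 1.0 / (len(data) * h * np.sqrt(2.0 * np.pi))

    def pdf(x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return norm * np.exp(-0.5 * ((x[None, :] - data[:, None]) / h) ** 2).sum(axis=0)

    return pdf


def kde_pdf_2d(x: np.ndarray, y: np.ndarray, h: float):
    """Isotropic bivariate Gaussian-mixture density; evaluator takes point
    arrays (xq, yq) of equal length."""
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    norm = 1.0 / (2.0 * np.pi * len(x) * h * h)

    def pdf(xq: np.ndarray, yq: np.ndarray) -> np.ndarray:
        xq = np.atleast_1d(np.asarray(xq, dtype=float))
        yq = np.atleast_1d(np.asarray(yq, dtype=float))
        d2 = ((xq[None, :] - x[:, None]) ** 2 + (yq[None, :] - y[:, None]) ** 2) / (h * h)
        return norm * np.exp(-0.5 * d2).sum(axis=0)

    return pdf


def adaptive_simpson(
    f,
    a: float,
    b: float,
    tol: float = 1e-6,
    max_depth: int = 30,
    max_evals: int = 2_000_000,
    initial_intervals: int = 8,
) -> np.ndarray:
    """Adaptive Simpson quadrature of a vector-valued integrand on [a, b].

    ``f`` maps an array of P points to a (P, k) array; all k components are
    integrated on a shared adaptive grid, bisecting intervals until the local
    Richardson error estimate meets the length-proportional share of ``tol``
    (absolute, per component).  Pending midpoints of one refinement level are
    evaluated in a single batched call.  Raises :class:`QuadratureError` when
    the depth or evaluation budget is exhausted.
    """
    if b <= a:
        raise ValueError("invalid integration interval")
    def _eval(points: np.ndarray) -> np.ndarray:
        out = np.asarray(f(points), dtype=float)
        if out.ndim == 1:
            out = out[:, None]
        if out.shape[0] != len(points):
            raise ValueError("integrand must return one row per evaluation point")
        return out

    edges = np.linspace(a, b, initial_intervals + 1)
    xl = edges[:-1].copy()
    xr = edges[1:].copy()
    xm = 0.5 * (xl + xr)
    fvals = _eval(np.concatenate([edges, xm]))
    f_edges, f_mid = fvals[: initial_intervals + 1], fvals[initial_intervals + 1 :]
    fl, fr, fm = f_edges[:-1], f_edges[1:], f_mid
    widths = xr - xl
    S = (widths[:, None] / 6.0) * (fl + 4.0 * fm + fr)
    depth = np.zeros(initial_intervals, dtype=int)

    total = np.zeros(fvals.shape[1])
    n_evals = len(fvals)
    span = b - a

    while len(xl):
        lm = 0.5 * (xl + xm)
        rm = 0.5 * (xm + xr)
        new = _eval(np.concatenate([lm, rm]))
        n_evals += len(new)
        flm, frm = new[: len(lm)], new[len(lm) :]
        half = 0.5 * (xr - xl)
        Sl = (half[:, None] / 6.0) * (fl + 4.0 * flm + fm)
        Sr = (half[:, None] / 6.0) * (fm + 4.0 * frm + fr)
        err = (Sl + Sr - S) / 15.0
        done = np.abs(err).max(axis=1) <= tol * (xr - xl) / span
        if (~done & (depth + 1 >= max_depth)).any():
            raise QuadratureError(
                f"max depth {max_depth} reached on [{a}, {b}] at tol {tol}"
            )
        if n_evals > max_evals:
            raise QuadratureError(
                f"evaluation budget {max_evals} exhausted on [{a}, {b}] at tol {tol}"
            )
        total += ((Sl + Sr + err)[done]).sum(axis=0)
        keep = ~done
        xl = np.concatenate([xl[keep], xm[keep]])
        xr = np.concatenate([xm[keep], xr[keep]])
        fl = np.concatenate([fl[keep], fm[keep]])
        fr = np.concatenate([fm[keep], fr[keep]])
        S = np.concatenate([Sl[keep], Sr[keep]])
        depth = np.concatenate([depth[keep] + 1, depth[keep] + 1])
        xm = 0.5 * (xl + xr)
        fm = np.concatenate([flm[keep], frm[keep]])
    return total


def kde_entropy_mi(
    x: np.ndarray, y: np.ndarray, config: KDEEstimatorConfig | None = None
) -> tuple[float, float]:
    """(H joint, I) of two samples by Gaussian KDE + adaptive Simpson.

    Inputs are standardised to zero mean / unit variance, so sigma = 1 in the
    bandwidth rules.  The joint density uses the 2D bandwidth, the marginals
    the 1D one; both integrals run over the data range padded by
    ``bounds_pad`` bandwidths, with a density floor inside the logarithms.
    """
    cfg = config or KDEEstimatorConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has no density estimate")
    n = len(x)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    h1 = cfg.bandwidth_1d if cfg.bandwidth_1d is not None else silverman_1d(1.0, n)
    h2 = cfg.bandwidth_2d if cfg.bandwidth_2d is not None else silverman_2d(1.0, n)
    pad = cfg.bounds_pad * h2
    ax, bx = xs.min() - pad, xs.max() + pad
    ay, by = ys.min() - pad, ys.max() + pad
    floor = cfg.density_floor
    tol = cfg.integration_tolerance

    px_eval = kde_pdf_1d(xs, h1)
    py_eval = kde_pdf_1d(ys, h1)
    joint_norm = 1.0 / (2.0 * np.pi * n * h2 * h2)

    def outer_integrand(xq: np.ndarray) -> np.ndarray:
        # inner integral over y, batched across the outer points xq
        A = np.exp(-0.5 * ((xq[None, :] - xs[:, None]) / h2) ** 2)  # (n, Px)
        log_px = np.log(np.maximum(px_eval(xq), floor))  # (Px,)

        def inner_integrand(yq: np.ndarray) -> np.ndarray:
            B = np.exp(-0.5 * ((yq[None, :] - ys[:, None]) / h2) ** 2)  # (n, Py)
            pxy = joint_norm * (B.T @ A)  # (Py, Px)
            log_py = np.log(np.maximum(py_eval(yq), floor))  # (Py,)
            lp = np.log(np.maximum(pxy, floor))
            lp = np.where(pxy > floor, lp, 0.0)  # 0 log 0 = 0
            g_h = pxy * lp
            g_i = pxy * (lp - log_px[None, :] - log_py[:, None])
            return np.stack([g_h, g_i], axis=-1).reshape(len(yq), -1)

        inner_tol = 0.5 * tol / (bx - ax)
        res = adaptive_simpson(inner_integrand, ay, by, tol=inner_tol)
        return res.reshape(len(xq), 2)

    h_raw, i_val = adaptive_simpson(outer_integrand, ax, bx, tol=0.5 * tol)
    return -float(h_raw), float(i_val)


# ---------------------------------------------------------------------------
# unified front ends


def entropy_mi(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "histogram",
    config: HistogramEstimatorConfig | KDEEstimatorConfig | None = None,
) -> tuple[float, float]:
    """(H joint, I) of two samples by the chosen estimator."""
    if method == "histogram":
        cfg = config or HistogramEstimatorConfig()
        if cfg.rank_order:
            x, y = rank_transform(x), rank_transform(y)
        table = joint_histogram(x, y, cfg.bins_for(len(np.asarray(x))))
        return hist_entropy_mi(table)
    if method == "kde":
        return kde_entropy_mi(x, y, config)
    raise ValueError(f"unknown estimator {method!r}")


def mi_distance(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "histogram",
    config: HistogramEstimatorConfig | KDEEstimatorConfig | None = None,
) -> float:
    """Variation of information D = H(x, y) - I(x, y), in nats."""
    h, i = entropy_mi(x, y, method, config)
    d = h - i
    if d < 0:
        if d < -1e-6:
            warnings.warn(f"negative distance {d:.3e} clamped to 0", RuntimeWarning)
        d = 0.0
    return d


def pairwise_distances(
    decomposition,
    method: str = "histogram",
    config: HistogramEstimatorConfig | KDEEstimatorConfig | None = None,
) -> DistanceMatrix:
    """All n(n-1)/2 distances between component maps over in-mask voxels.

    Accepts an :class:`~icdep.ica.ICADecomposition` or a raw (n, N) array of
    maps.  A failure in any pair is re-raised naming the pair.
    """
    maps = getattr(decomposition, "maps", decomposition)
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need at least two components")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = mi_distance(maps[i], maps[j], method, config)
            except Exception as exc:  # noqa: BLE001 - annotate with pair identity
                raise RuntimeError(f"distance computation failed for pair ({i}, {j})") from exc
            values[i, j] = values[j, i] = d
    prov = {"method": method}
    if method == "histogram":
        cfg = config or HistogramEstimatorConfig()
        prov["n_bins"] = cfg.bins_for(maps.shape[1])
        prov["rank_order"] = cfg.rank_order
    else:
        cfg = config or KDEEstimatorConfig()
        nvox = maps.shape[1]
        prov["bandwidth_1d"] = cfg.bandwidth_1d or silverman_1d(1.0, nvox)
        prov["bandwidth_2d"] = cfg.bandwidth_2d or silverman_2d(1.0, nvox)
        prov["integration_tolerance"] = cfg.integration_tolerance
    return DistanceMatrix(
        values=values,
        estimator=method,
        component_ids=list(range(n)),
        provenance=prov,
    )
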