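"""Spatial ICA of an image sequence by fixed-point negentropy maximisation.

The observed data x(v) = [x_1(v), ..., x_T(v)]^T (one random variable per
scan, voxels as observations) are centered, reduced to ``model_order``
principal components and whitened; the symmetric FastICA fixed point with the
tanh nonlinearity then estimates spatial components s_i (maps over in-mask
voxels) whose time courses are the columns of the back-projected mixing
matrix.  Model-order overestimation at this stage is what the downstream
residual-dependency analysis probes.

Centering removes the spatial mean of each image (each variable's mean over
its voxel observations).  The static baseline pattern and the task-driven
fluctuation of the spatial mean therefore remain in the data, and typically
surface as a flat, sub-Gaussian component whose map mirrors the overall
intensity distribution -- a known by-product of this centering convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .synthdata import ImageSequence


class ICAConvergenceError(RuntimeError):
    """FastICA failed to converge within the restart budget."""

    def __init__(self, message: str, iterations: list[int]):
        super().__init__(message)
        self.iterations = iterations


@dataclass
class WhitenedData:
    """PCA-reduced, whitened data plus the operators needed to map back."""

    z: np.ndarray  # (n, N) whitened rows over voxels
    basis: np.ndarray  # (T, n) eigenvectors E
    scales: np.ndarray  # (n,) sqrt of eigenvalues
    spatial_mean: np.ndarray  # (T,) removed per-image spatial mean

    @property
    def model_order(self) -> int:
        return self.z.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Rank-n approximation of the centered (T, N) data matrix."""
        return (self.basis * self.scales) @ self.z


@dataclass
class ICADecomposition:
    """Spatial components, unmixing matrix and back-projected time courses."""

    maps: np.ndarray  # (n, N) component maps, zero mean / unit variance over mask
    unmixing: np.ndarray  # (n, n) W in whitened space
    mixing_timecourses: np.ndarray  # (T, n) columns = component time courses
    model_order: int
    convergence_info: dict
    whitened: WhitenedData

    @property
    def n_components(self) -> int:
        return self.model_order


@dataclass
class ZMap:
    values: np.ndarray  # z per masked voxel
    threshold: float
    component_index: int


def center_reduce_whiten(
    seq: ImageSequence | np.ndarray, model_order: int, rank_tol: float = 1e-10
) -> WhitenedData:
    """Center the data matrix, reduce to ``model_order`` PCs and whiten.

    Accepts an :class:`ImageSequence` or a raw (T, N) matrix.  Rows of the
    output are uncorrelated with unit variance over voxels; the PCA basis and
    eigenvalue scales are retained so component time courses can be mapped
    back to scan space.
    """
    x = seq.to_matrix() if isinstance(seq, ImageSequence) else np.asarray(seq, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (T, N) data matrix")
    T, N = x.shape
    if model_order > T:
        raise ValueError(f"model order {model_order} exceeds the {T} time points")

    spatial_mean = x.mean(axis=1)
    xc = x - spatial_mean[:, None]

    cov = xc @ xc.T / N
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[model_order - 1] <= rank_tol * max(evals[0], 1.0):
        raise ValueError(
            f"data rank is below the requested model order {model_order}"
        )
    basis = evecs[:, :model_order]
    scales = np.sqrt(evals[:model_order])
    z = (basis / scales).T @ xc
    return WhitenedData(z=z, basis=basis, scales=scales, spatial_mean=spatial_mean)


def fastica_tanh(
    white: WhitenedData,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 1000,
    n_restarts: int = 5,
    on_failure: str = "warn",
) -> ICADecomposition:
    """Symmetric (parallel) FastICA with the tanh contrast on whitened data.

    Deterministic under ``seed``; a run that does not converge within
    ``max_iter`` iterations is restarted from a fresh random orthogonal
    initialisation up to ``n_restarts`` times.  When every attempt exhausts
    the iteration budget the last solution is still returned (the symmetric
    update re-orthonormalises every step, so it is a valid rotation, merely
    not a fixed point -- the typical situation when two sources are nearly
    identical, e.g. at short inter-ROI delays) and a warning is emitted;
    pass ``on_failure="raise"`` to get an :class:`ICAConvergenceError`
    carrying the per-attempt iteration counts instead.
    """
    if on_failure not in ("warn", "raise"):
        raise ValueError("on_failure must be 'warn' or 'raise'")
    n = white.model_order
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    iterations: list[int] = []
    converged = False
    for attempt in range(n_restarts):
        w_init = rng.standard_normal((n, n))
        ica = FastICA(
            n_components=n,
            algorithm="parallel",
            whiten=False,
            fun="logcosh",
            max_iter=max_iter,
            tol=tol,
            w_init=w_init,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica.fit(white.z.T)
        iterations.append(int(ica.n_iter_))
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        if converged:
            break
    if not converged:
        msg = (
            f"FastICA did not converge in {n_restarts} restarts "
            f"(tol={tol}, max_iter={max_iter}); iterations per attempt: {iterations}"
        )
        if on_failure == "raise":
            raise ICAConvergenceError(msg, iterations)
        warnings.warn(msg, RuntimeWarning)

    W = np.asarray(ica.components_)  # (n, n), orthonormal rows in whitened space
    maps = W @ white.z
    # fix sign so each map has non-negative skewness (stable display; all
    # quantitative steps downstream are sign-invariant)
    skew = ((maps - maps.mean(axis=1, keepdims=True)) ** 3).mean(axis=1)
    signs = np.where(skew < 0, -1.0, 1.0)
    maps = maps * signs[:, None]
    # re-standardise defensively (whitening already guarantees this)
    maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    # x_c = E diag(scales) z = E diag(scales) W^T s  ->  mixing A = E diag(scales) W^T
    mixing = (white.basis * white.scales) @ W.T * signs[None, :]
    return ICADecomposition(
        maps=maps,
        unmixing=W * signs[:, None],
        mixing_timecourses=mixing,
        model_order=n,
        convergence_info={
            "attempts": len(iterations),
            "iterations": iterations,
            "converged": converged,
        },
        whitened=white,
    )


def decompose(
    seq: ImageSequence | np.ndarray,
    model_order: int,
    seed: int = 0,
    **fastica_kwargs,
) -> ICADecomposition:
    """Whiten and run FastICA in one call."""
    white = center_reduce_whiten(seq, model_order)
    return fastica_tanh(white, seed=seed, **fastica_kwargs)


def component_zmap(values: np.ndarray, component_index: int = 0, threshold: float = 2.0) -> ZMap:
    """Standardise a component map to a z map: z = (s - mean) / std.

    Voxels with |z| at or above ``threshold`` (default 2) are the ones
    conventionally displayed as active.
    """
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("constant map has no z transform")
    return ZMap(values=(v - v.mean()) / sd, threshold=threshold, component_index=component_index)
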