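"""Native niche volume via Gaussian kernel density estimation in PCA space.

The climatic niche of a species' native range is measured as the geometric
volume of the region of climate space holding a fixed fraction q of the
probability mass of a Gaussian KDE fit to the species' native occurrence
scores. Scores live in a PCA of *all* valid climate cells of the raster
stack, shared across species so volumes are comparable; the kernel
bandwidth is likewise fixed across species at the maximum per-axis
rule-of-thumb bandwidth observed in a preliminary pass.

The superlevel-set volume is estimated by importance sampling: draw points
from the KDE mixture itself, find the density threshold whose superlevel
set carries mass q, and average 1/f over the retained samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .grids import ClimateStack


@dataclass
class GlobalClimatePCA:
    """Shared climate ordination fit on every valid raster cell."""

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (k, n_dims)
    explained_variance_ratio: np.ndarray
    n_dims: int

    def project(self, env: np.ndarray) -> np.ndarray:
        X = np.asarray(env, dtype=float)
        if X.shape[1] != len(self.columns):
            raise ValueError("environment columns do not match the PCA")
        return ((X - self.means) / self.sds) @ self.loadings


@dataclass
class HypervolumeResult:
    species_id: str
    n_dims: int
    bandwidth: float
    quantile: float
    volume: float
    n_samples: int
    seed: int | None


def fit_global_pca(stack: ClimateStack, n_dims: int = 3) -> GlobalClimatePCA:
    """PCA of the standardised environment over all valid raster cells."""
    env, _, _ = stack.env_table()
    sds = env.std(axis=0)
    keep = sds > 0
    dropped = [c for c, ok in zip(stack.layer_names, keep) if not ok]
    if dropped:
        warnings.warn(f"dropping zero-variance layers: {dropped}")
    cols = [c for c, ok in zip(stack.layer_names, keep) if ok]
    if len(cols) < n_dims:
        raise ValueError(f"only {len(cols)} non-degenerate layers for n_dims={n_dims}")
    X = env[:, keep]
    means, sds = X.mean(axis=0), X.std(axis=0)
    pca = PCA(n_components=n_dims, svd_solver="full")
    pca.fit((X - means) / sds)
    return GlobalClimatePCA(
        columns=cols,
        means=means,
        sds=sds,
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_dims=n_dims,
    )


def silverman_bandwidth(scores: np.ndarray) -> np.ndarray:
    """Per-axis rule-of-thumb bandwidths b_j = 1.06 * SD_j * n^(-1/5)."""
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 points")
    sd = X.std(axis=0)
    b = 1.06 * sd * n ** (-0.2)
    if (sd == 0).any():
        warnings.warn("zero spread on some axis; bandwidth set to machine epsilon")
        b = np.where(sd == 0, np.finfo(float).eps, b)
    return b


def fixed_bandwidth(all_species_scores: list[np.ndarray]) -> float:
    """Single scalar bandwidth: max over species of max per-axis bandwidth."""
    if not all_species_scores:
        raise ValueError("need at least one species")
    return float(max(silverman_bandwidth(s).max() for s in all_species_scores))


def _kde_log_density(x: np.ndarray, points: np.ndarray, b: float,
                     chunk: int = 500) -> np.ndarray:
    """Log density of the equal-weight isotropic Gaussian mixture at x."""
    n, d = points.shape
    log_norm = -np.log(n) - 0.5 * d * np.log(2 * np.pi * b * b)
    out = np.empty(len(x))
    for i in range(0, len(x), chunk):
        xs = x[i : i + chunk]
        d2 = ((xs[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
        m = (-0.5 * d2 / (b * b))
        mx = m.max(axis=1, keepdims=True)
        out[i : i + chunk] = (mx[:, 0] + np.log(np.exp(m - mx).sum(axis=1))) + log_norm
    return out


def gaussian_hypervolume(
    scores: np.ndarray,
    b: float,
    q: float = 0.95,
    n_samples: int | None = None,
    seed: int | None = None,
    species_id: str = "",
    chunk: int = 500,
) -> HypervolumeResult:
    """Volume of the mass-q superlevel set of a Gaussian KDE.

    The KDE is an equal-weight mixture of isotropic Gaussians (SD ``b``)
    centred at the data points. ``n_samples`` draws are taken from the
    mixture itself; the threshold f* is the empirical (1-q) quantile of the
    density at the samples (so the superlevel set {f >= f*} carries an
    estimated mass q), and the volume is the importance-sampling sum
    ``(1/N) * sum_{f(x_i) >= f*} 1/f(x_i)``. Deterministic given ``seed``.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 points")
    if not 0.0 < q < 1.0:
        raise ValueError("mass quantile q must lie in (0, 1)")
    if n_samples is None:
        n_samples = 10_000 * d
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    rng = np.random.default_rng(seed)
    comp = rng.integers(0, n, size=n_samples)
    draws = X[comp] + b * rng.standard_normal((n_samples, d))
    logf = _kde_log_density(draws, X, b, chunk=chunk)
    log_fstar = np.quantile(logf, 1.0 - q)
    keep = logf >= log_fstar
    volume = float(np.exp(-logf[keep]).sum() / n_samples)
    return HypervolumeResult(
        species_id=species_id,
        n_dims=d,
        bandwidth=float(b),
        quantile=q,
        volume=volume,
        n_samples=n_samples,
        seed=seed,
    )
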