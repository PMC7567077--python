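"""Niche-shift metrics: Schoener's D, expansion, equivalency, BH correction.

Schoener's D = 1 - 0.5 * sum |z1 - z2| compares two occupancy densities on
a common grid (0 = no overlap, 1 = identical niches). Expansion is the
percentage of non-native occupancy mass on climates absent from the native
niche; below 10% it is conventionally treated as non-significant. The
equivalency test pools all occurrences, re-splits them at the observed
native:non-native ratio, and compares the observed D with the simulated
distribution; niche equivalency is rejected when the observed D falls below
95% of the simulated values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .niche_space import GridDensity, bca_direction, grid_density
from .preprocess import EnvMatrix


@dataclass
class NicheShiftResult:
    """Per-species niche-shift metrics."""

    species_id: str
    D: float
    expansion_pct: float
    expansion_class: str
    p_equiv: float
    n_native: int
    n_nonnative: int
    p_equiv_adj: float | None = None


def _occupancy(z) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(z, GridDensity):
        return z.z, z.edges
    return np.asarray(z, dtype=float), None


def _check_common_grid(z1, z2) -> tuple[np.ndarray, np.ndarray]:
    a, ea = _occupancy(z1)
    b, eb = _occupancy(z2)
    if len(a) != len(b):
        raise ValueError("occupancy vectors live on different grids")
    if ea is not None and eb is not None and not np.array_equal(ea, eb):
        raise ValueError("grid bin edges differ between the two densities")
    for v in (a, b):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError("occupancy must sum to 1")
    return a, b


def schoener_d(z1, z2) -> float:
    """Niche overlap D = 1 - 0.5 * L1 distance of the occupancy densities."""
    a, b = _check_common_grid(z1, z2)
    return float(1.0 - 0.5 * np.abs(a - b).sum())


def expansion_pct(z_native, z_nonnative, presence_quantile: float = 0.0) -> float:
    """Percentage of non-native occupancy on climates outside the native niche.

    Native presence defaults to bins with z_native > 0. A positive
    ``presence_quantile`` q instead discards the lowest-density native bins
    holding at most a fraction q of native mass before defining presence,
    which guards against smoothing leaking tiny mass into marginal bins.
    """
    zn, znn = _check_common_grid(z_native, z_nonnative)
    if presence_quantile > 0:
        order = np.argsort(zn)
        cum = np.cumsum(zn[order])
        cut = zn[order][np.searchsorted(cum, presence_quantile, side="right")] \
            if cum[0] <= presence_quantile else 0.0
        present = zn > cut
    else:
        present = zn > 0
    return float(100.0 * znn[~present].sum())


def classify_expansion(E: float, threshold: float = 10.0) -> str:
    """'low' below the threshold, 'high' at or above it."""
    if not 0.0 <= E <= 100.0:
        raise ValueError("expansion percentage must lie in [0, 100]")
    return "low" if E < threshold else "high"


@dataclass
class EquivalencyResult:
    D_obs: float
    p: float
    d_sim: np.ndarray


def equivalency_test(
    env_native: EnvMatrix | np.ndarray,
    env_nonnative: EnvMatrix | np.ndarray,
    *,
    n_reps: int = 1000,
    seed: int | None = None,
    n_axes: int = 10,
    n_bins: int = 100,
    refit_axis: bool = True,
    bg_native: np.ndarray | None = None,
    bg_nonnative: np.ndarray | None = None,
    builder=None,
) -> EquivalencyResult:
    """Permutation test of niche equivalency.

    All occurrences are pooled and randomly re-split at the observed
    native:non-native ratio ``n_reps`` times; each split is scored with
    exactly the same procedure as the observed data (standardise, PCA,
    between-class axis, common-grid corrected densities, Schoener's D).
    One-sided p = (1 + #{D_sim <= D_obs}) / (1 + n_reps); ties count toward
    the null, and the add-one convention keeps p > 0.

    By default the between-class axis is re-derived for every split, so the
    statistic is computed identically for observed and permuted labellings
    and the test is exact under exchangeability. ``refit_axis=False`` keeps
    the observed axis and grid fixed across splits (cheaper, but the
    supervised axis then biases the observed D low relative to the null).
    The pooled standardisation and PCA are label-free and computed once.

    ``bg_native``/``bg_nonnative`` are optional background environment
    matrices (raster cells available to each range); without them the
    pooled occurrences serve as the availability background for both sides.
    A custom ``builder(values_a, values_b) -> (z_a, z_b)`` overrides the
    internal density construction entirely.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    Xn = env_native.values if isinstance(env_native, EnvMatrix) else np.asarray(env_native, float)
    Xa = env_nonnative.values if isinstance(env_nonnative, EnvMatrix) else np.asarray(env_nonnative, float)
    n1, n2 = len(Xn), len(Xa)
    n = n1 + n2
    rng = np.random.default_rng(seed)
    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[:n1] = True

    if builder is not None:
        X = np.vstack([Xn, Xa])

        def d_for(mask: np.ndarray) -> float:
            za, zb = builder(X[mask], X[~mask])
            return schoener_d(za, zb)

    else:
        X = np.vstack([Xn, Xa])
        sd = X.std(axis=0)
        keep = sd > 0
        Xk = X[:, keep]
        mu, sd = Xk.mean(axis=0), Xk.std(axis=0)
        Z = (Xk - mu) / sd
        m = min(n_axes, Z.shape[1], n - 1)
        pca = PCA(n_components=m, svd_solver="full")
        S = pca.fit_transform(Z)

        def bg_scores(bg: np.ndarray | None) -> np.ndarray:
            if bg is None:
                return S
            B = (np.asarray(bg, float)[:, keep] - mu) / sd
            return B @ pca.components_.T

        B1, B2 = bg_scores(bg_native), bg_scores(bg_nonnative)
        u_fixed = bca_direction(S, obs_mask) if not refit_axis else None

        def d_for(mask: np.ndarray) -> float:
            u = u_fixed if u_fixed is not None else bca_direction(S, mask)
            s = S @ u
            b1, b2 = B1 @ u, B2 @ u
            bounds = (min(b1.min(), b2.min()), max(b1.max(), b2.max()))
            g1 = grid_density(s[mask], b1, n_bins=n_bins, bounds=bounds)
            g2 = grid_density(s[~mask], b2, n_bins=n_bins, bounds=bounds)
            return schoener_d(g1.z, g2.z)

    d_obs = d_for(obs_mask)
    d_sim = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n1]] = True
        d_sim[r] = d_for(mask)
    p = (1.0 + np.sum(d_sim <= d_obs + 1e-12)) / (1.0 + n_reps)
    return EquivalencyResult(D_obs=float(d_obs), p=float(p), d_sim=d_sim)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
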