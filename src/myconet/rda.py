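"""Partial redundancy analysis (RDA) of mycelial trait tables.

The model is ``traits ~ species + Condition(phylum)``: trait variation
is first adjusted for phylum membership (the covariate is "conditioned
out" by least squares), then the remainder is regressed on species
identity.  Inertia — variance summed over standardized traits —
partitions exactly into conditional + constrained + unconstrained
components; the constrained part is eigen-decomposed into RDA axes.
Significance of the species effect comes from a permutation pseudo-F
test with reduced-model permutations (rows of the phylum-adjusted
residuals are shuffled).

Implemented directly on QR/SVD projections so the arithmetic is fully
inspectable; inertia accounting follows the standard constrained-
ordination conventions (variances use the n-1 denominator throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: the 15 canonical trait columns used by the single-scale models.
#: global efficiency enters as its MST-normalized variant, the form used
#: for ordination; raw G_eff stays available in the trait table.
MODEL_FULL_TRAITS = [
    "mean_edge_length", "mean_tip_width", "mean_main_width",
    "mean_branch_angle", "length_density",
    "meshedness", "R_eff", "RT_eff", "G_eff_MST", "volume_MST",
    "rob_random_single", "rob_random_chunk", "rob_asc_width",
    "rob_desc_width", "rob_desc_length",
]

#: size-independent / size-normalized network traits for the cross-scale model
MODEL3_TRAITS = [
    "meshedness", "G_eff_MST", "volume_MST", "R_eff_area", "RT_eff_area",
    "rob_random_single", "rob_random_chunk", "rob_asc_width",
    "rob_desc_width", "rob_desc_length",
]

MODEL_TRAITS = {
    "model1_micro": MODEL_FULL_TRAITS,
    "model2_macro": MODEL_FULL_TRAITS,
    "model3_all": MODEL3_TRAITS,
}


@dataclass
class OrdinationResult:
    total_inertia: float
    conditional_inertia: float
    constrained_inertia: float
    unconstrained_inertia: float
    proportions: dict[str, float]
    eigenvalues: np.ndarray            # constrained axis eigenvalues
    axis_proportion: np.ndarray        # eigenvalue / total inertia
    site_scores: pd.DataFrame          # colonies on RDA axes
    loadings: pd.DataFrame             # unit-norm trait loadings per axis
    df_model: int
    df_residual: int
    pseudo_F: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def partition_table(self) -> pd.DataFrame:
        """Variance partition in the conventional inertia-table layout."""
        rows = [("Total", self.total_inertia, 1.0)]
        if self.conditional_inertia > 0:
            rows.append(("Conditional", self.conditional_inertia,
                         self.conditional_inertia / self.total_inertia))
        rows.append(("Constrained", self.constrained_inertia,
                     self.constrained_inertia / self.total_inertia))
        rows.append(("Unconstrained", self.unconstrained_inertia,
                     self.unconstrained_inertia / self.total_inertia))
        return pd.DataFrame(rows, columns=["component", "inertia", "proportion"])


def standardize(Y: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Column-wise z-scores (mean 0, variance 1 with the n-1 denominator).

    Standardizing puts traits with different magnitudes and units on a
    common scale so total inertia equals the number of traits.
    """
    arr = np.asarray(Y, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D trait matrix")
    sd = arr.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = (list(np.asarray(Y.columns)[zero]) if isinstance(Y, pd.DataFrame)
                 else list(zero))
        raise ValueError(f"zero-variance trait column(s): {names}")
    z = (arr - arr.mean(axis=0)) / sd
    if isinstance(Y, pd.DataFrame):
        return pd.DataFrame(z, index=Y.index, columns=Y.columns)
    return z


def design_matrix(factor) -> np.ndarray:
    """Treatment-coded (drop-first) dummy matrix for a categorical factor."""
    codes, levels = pd.factorize(np.asarray(factor), sort=True)
    if len(levels) < 2:
        return np.zeros((len(codes), 0))
    out = np.zeros((len(codes), len(levels) - 1))
    for j in range(1, len(levels)):
        out[codes == j, j - 1] = 1.0
    return out


def _as_design(X, n: int) -> np.ndarray:
    """Accept a factor vector or an explicit design matrix."""
    arr = np.asarray(X)
    if arr.ndim == 1 or arr.dtype.kind in "OUS":
        return design_matrix(arr)
    if arr.shape[0] != n:
        raise ValueError("design matrix row count mismatch")
    return arr.astype(float)


def _orthonormal_basis(M: np.ndarray) -> np.ndarray:
    """Orthonormal column basis (rank-revealing, intercept included upstream)."""
    if M.shape[1] == 0:
        return np.zeros((M.shape[0], 0))
    q, r = np.linalg.qr(M)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Per-axis sign convention: the largest-magnitude loading is positive."""
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return flip


def rda_fit(Y_std, X, Z=None, trait_names=None, sample_ids=None) -> OrdinationResult:
    """Fit the (partial) RDA ``Y_std ~ X + Condition(Z)``.

    ``Y_std`` must already be standardized/centered.  ``X`` and ``Z``
    may be factor vectors (dummy-coded internally) or design matrices.
    """
    if isinstance(Y_std, pd.DataFrame):
        trait_names = trait_names or list(Y_std.columns)
        sample_ids = sample_ids if sample_ids is not None else list(Y_std.index)
    Y = np.asarray(Y_std, dtype=float)
    n, p = Y.shape
    if trait_names is None:
        trait_names = [f"trait_{j}" for j in range(p)]
    if sample_ids is None:
        sample_ids = list(range(n))
    denom = n - 1

    Xd = _as_design(X, n)
    Zd = _as_design(Z, n) if Z is not None else np.zeros((n, 0))

    # conditioning step: project out intercept + covariate
    ones = np.ones((n, 1))
    Qz = _orthonormal_basis(np.hstack([ones, Zd]))
    Y_fit_z = Qz @ (Qz.T @ Y)
    Yr = Y - Y_fit_z
    Xr = Xd - Qz @ (Qz.T @ Xd)
    Qx = _orthonormal_basis(Xr)
    rank_x = Qx.shape[1]
    rank_z = Qz.shape[1] - 1  # covariate rank net of the intercept

    total = float(np.sum((Y - Y.mean(axis=0)) ** 2)) / denom
    conditional = float(np.sum((Y_fit_z - Y.mean(axis=0)) ** 2)) / denom
    Y_hat = Qx @ (Qx.T @ Yr)
    constrained = float(np.sum(Y_hat ** 2)) / denom
    unconstrained = float(np.sum((Yr - Y_hat) ** 2)) / denom

    # RDA axes: eigen-decomposition of the fitted covariance via SVD
    u, s, vt = np.linalg.svd(Y_hat / math.sqrt(denom), full_matrices=False)
    n_axes = min(rank_x, p)
    eig = (s ** 2)[:n_axes]
    V = vt[:n_axes].T                      # unit-norm trait loadings
    flip = _fix_signs(V)
    V = V * flip
    scores = (Yr @ V)                      # colony scores on the RDA axes

    axis_names = [f"RDA{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        total_inertia=total,
        conditional_inertia=conditional,
        constrained_inertia=constrained,
        unconstrained_inertia=unconstrained,
        proportions={
            "conditional": conditional / total,
            "constrained": constrained / total,
            "unconstrained": unconstrained / total,
        },
        eigenvalues=eig,
        axis_proportion=eig / total,
        site_scores=pd.DataFrame(scores, index=sample_ids, columns=axis_names),
        loadings=pd.DataFrame(V, index=trait_names, columns=axis_names),
        df_model=rank_x,
        df_residual=n - 1 - rank_z - rank_x,
    )


def permutation_test(fit: OrdinationResult | None, Y_std, X, Z=None,
                     n_perm: int = 9999, seed: int = 0,
                     strategy: str = "reduced") -> tuple[float, float]:
    """Permutation pseudo-F test of the constrained (species) effect.

    pseudo-F = (constrained/df_model) / (unconstrained/df_residual).
    The null distribution permutes rows of the covariate-adjusted
    residuals (``strategy='reduced'``, the correct exchangeable unit for
    partial RDA) or of the raw trait rows (``strategy='full'``).
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so 9999 permutations
    bound p below at 1e-4.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if strategy not in ("reduced", "full"):
        raise ValueError(f"unknown permutation strategy {strategy!r}")
    Y = np.asarray(Y_std, dtype=float)
    n = Y.shape[0]
    Xd = _as_design(X, n)
    Zd = _as_design(Z, n) if Z is not None else np.zeros((n, 0))
    ones = np.ones((n, 1))
    Qz = _orthonormal_basis(np.hstack([ones, Zd]))
    Yr = Y - Qz @ (Qz.T @ Y)
    Xr = Xd - Qz @ (Qz.T @ Xd)
    Qx = _orthonormal_basis(Xr)
    dfx = Qx.shape[1]
    dfres = n - Qz.shape[1] - dfx
    if dfx == 0 or dfres <= 0:
        raise ValueError("degenerate design: no constrained or residual degrees of freedom")

    def f_stat(R: np.ndarray) -> float:
        num = float(np.sum((Qx.T @ R) ** 2))
        den = float(np.sum(R ** 2)) - num
        return (num / dfx) / (den / dfres)

    f_obs = f_stat(Yr)
    rng = np.random.default_rng(seed)
    base = Yr if strategy == "reduced" else Y
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Rp = base[perm]
        Rp = Rp - Qz @ (Qz.T @ Rp)   # re-residualize the permuted rows
        if f_stat(Rp) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    if fit is not None:
        fit.pseudo_F = f_obs
        fit.p_value = p
        fit.n_permutations = n_perm
        fit.seed = seed
    return f_obs, p


def select_traits(table: pd.DataFrame, model: str) -> pd.DataFrame:
    """Trait columns for one of the three RDA models (factors carried along).

    model1_micro / model2_macro use the full 15-trait set; model3_all
    keeps only the 10 size-independent or size-normalized network traits
    so micro- and macro-scale colonies are comparable.
    """
    if model not in MODEL_TRAITS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODEL_TRAITS)}")
    wanted = MODEL_TRAITS[model]
    missing = [c for c in wanted if c not in table.columns]
    if missing:
        raise ValueError(f"trait table lacks required columns: {missing}")
    factors = [c for c in ("species", "phylum") if c in table.columns]
    return table[wanted + factors].copy()


def anova_table(fit: OrdinationResult) -> pd.DataFrame:
    """Permutation-test summary in the conventional RDA anova-table layout."""
    return pd.DataFrame([
        {"source": "Model", "Df": fit.df_model,
         "Variance": fit.constrained_inertia, "F": fit.pseudo_F, "p": fit.p_value},
        {"source": "Residual", "Df": fit.df_residual,
         "Variance": fit.unconstrained_inertia, "F": np.nan, "p": np.nan},
    ])
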