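"""PCA of the spectral population and global-H (GH) outlier screening.

The spectral population is decomposed by principal components; a sample's
global H is its squared Mahalanobis distance in the retained score space
divided by the number of retained components,

    GH_i = (1/k) * sum_j (t_ij - tbar_j)^2 / s_j^2,

with score variances s_j^2 computed with an (n-1) denominator over the
fitting population.  Division by k makes the statistic scale-free, so the
conventional GH > 3.0 cutoff applies regardless of how many components the
variance target retains.  For the fitting population itself the mean GH is
exactly (n-1)/n.

NH (neighbourhood H) — the smallest standardized score-space distance (per
component count) from a sample to any other sample — is reported as a
redundancy diagnostic only; no elimination rule is attached to it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from nirscal.datasets import InputError, SpectraDataset
from nirscal.preprocess import ModelRecipe, PreprocessState, apply_recipe

#: screening recipe used by the pipeline before any model-specific grid search
DEFAULT_SCREEN_RECIPE = ModelRecipe(
    derivative=(1, 4, 4, 1), scatter="SNV", wl_range=(408.0, 2492.0)
)


@dataclasses.dataclass
class PCAModel:
    """Centred PCA of a spectral population.

    ``loadings`` has shape (k, p) with orthonormal rows; ``score_var`` the
    per-component score variances (ddof=1) of the fitting population;
    ``explained`` the fraction of total variance per retained component.
    """

    center: np.ndarray
    loadings: np.ndarray
    score_var: np.ndarray
    explained: np.ndarray
    n_fit: int

    @property
    def k(self) -> int:
        return self.loadings.shape[0]

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.center.size:
            raise InputError(
                f"spectra have {X.shape[1]} wavelengths, model expects {self.center.size}"
            )
        return (X - self.center) @ self.loadings.T


@dataclasses.dataclass
class OutlierReport:
    """Per-sample GH/NH values and elimination flags."""

    table: pd.DataFrame  # columns: gh, nh, eliminated; index: sample_id
    cutoff: float
    n_components: int
    explained_cum: float

    @property
    def eliminated_ids(self) -> list[str]:
        return list(self.table.index[self.table["eliminated"]])


def fit_pca(
    X: np.ndarray,
    variance_target: float = 0.9981,
    max_components: int | None = None,
) -> PCAModel:
    """Fit a centred PCA retaining the fewest components reaching ``variance_target``.

    The retained count is the smallest k whose cumulative explained-variance
    fraction reaches the target, capped at ``max_components`` (default
    ``min(n - 1, 63)``).  The sign convention — largest-magnitude loading
    element positive — makes the decomposition reproducible.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise InputError("spectra contain non-finite values")
    n = X.shape[0]
    if n < 3:
        raise InputError("PCA needs at least 3 samples")
    if not 0 < variance_target <= 1:
        raise InputError("variance_target must lie in (0, 1]")
    cap = min(n - 1, 63) if max_components is None else int(max_components)

    center = X.mean(axis=0)
    Xc = X - center
    # SVD of the centred matrix: singular values give component variances
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    if total == 0:
        raise InputError("spectral population has zero variance")
    frac = var / total
    cum = np.cumsum(frac)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, cap, s.size)
    k = max(k, 1)

    loadings = Vt[:k]
    # deterministic sign: largest |element| of each loading vector positive
    for j in range(k):
        idx = np.argmax(np.abs(loadings[j]))
        if loadings[j, idx] < 0:
            loadings[j] = -loadings[j]
    scores = Xc @ loadings.T
    score_var = scores.var(axis=0, ddof=1)
    return PCAModel(
        center=center,
        loadings=loadings,
        score_var=score_var,
        explained=frac[:k],
        n_fit=n,
    )


def global_h(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """GH of each spectrum: mean squared standardized score over retained components."""
    if np.any(model.score_var <= 0):
        raise InputError("degenerate principal component (zero score variance)")
    t = model.scores(X)
    z2 = t**2 / model.score_var  # fitting scores are centred, so tbar = 0
    return z2.mean(axis=1)


def neighborhood_h(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """NH: per-component-mean squared standardized distance to the nearest other sample."""
    if np.any(model.score_var <= 0):
        raise InputError("degenerate principal component (zero score variance)")
    z = model.scores(X) / np.sqrt(model.score_var)
    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2) / model.k
    np.fill_diagonal(d2, np.inf)
    return d2.min(axis=1)


def screen(
    ds: SpectraDataset,
    recipe: ModelRecipe = DEFAULT_SCREEN_RECIPE,
    gh_cutoff: float = 3.0,
    variance_target: float = 0.9981,
    max_components: int | None = None,
    state: PreprocessState | None = None,
) -> tuple[SpectraDataset, OutlierReport]:
    """Single-pass GH screening of a spectral population.

    Pretreats ``ds`` with ``recipe``, fits a PCA to the whole population,
    computes GH, and eliminates every sample with GH > ``gh_cutoff``.  The
    kept dataset preserves the input sample order and carries the *raw*
    spectra (screening decides membership; downstream models choose their
    own pretreatment).
    """
    if ds.n_samples < 10:
        raise InputError("screening needs at least 10 samples")
    pre, _ = apply_recipe(ds, recipe, state=state)
    model = fit_pca(pre.X, variance_target=variance_target, max_components=max_components)
    gh = global_h(model, pre.X)
    nh = neighborhood_h(model, pre.X)
    eliminated = gh > gh_cutoff
    if eliminated.all():
        raise InputError("all samples exceeded the GH cutoff; screening aborted")
    table = pd.DataFrame(
        {"gh": gh, "nh": nh, "eliminated": eliminated},
        index=pd.Index(ds.ids, name="sample_id"),
    )
    report = OutlierReport(
        table=table,
        cutoff=gh_cutoff,
        n_components=model.k,
        explained_cum=float(model.explained.sum()),
    )
    kept = ds.subset(~eliminated)
    return kept, report


def scree_table(model: PCAModel) -> pd.DataFrame:
    """Per-component explained-variance table (for CSV export)."""
    return pd.DataFrame(
        {
            "component": np.arange(1, model.k + 1),
            "explained_fraction": model.explained,
            "cumulative_fraction": np.cumsum(model.explained),
            "score_variance": model.score_var,
        }
    )
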