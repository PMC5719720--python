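"""Calibration, cross-validation and external-validation statistics.

Conventions (all standard errors in the trait's units):

* ``SEC  = sqrt(SSE / (n - Terms - 1))`` — calibration degrees of freedom;
* ``SECV = sqrt(SSE_cv / n)`` and ``SEP = sqrt(SSE_val / n_val)`` — plain
  root-mean-square errors of pooled out-of-fold / external predictions;
* ``R² = 1 - SSE/SST`` in every flavour (not a squared correlation; the two
  coincide for calibration fits with intercept);
* ``RPD = SD / SECV`` (or ``SD_val / SEP`` externally), the ratio of the
  reference SD to the prediction error — RPD >= 2 is conventionally usable,
  >= 3 strong;
* all SDs use the sample (n-1) denominator.

Cross validation follows the random-group scheme: the calibration set is
split at random into ``n_groups`` folds (default 4), each fold predicted by
a model fitted to the others, and the out-of-fold predictions pooled.  The
optimal number of factors ("Terms") is the smallest count whose SECV is
within 2% of the minimum — a parsimony rule.

:func:`grid_search` evaluates a full pretreatment grid (derivative codes x
scatter methods x wavelength ranges), cross-validating each combination,
and returns rows in the conventional calibration-table column order.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from nirscal.datasets import InputError, SpectraDataset
from nirscal.mpls import MPLSModel, fit_mpls
from nirscal.preprocess import (
    DEFAULT_DERIVATIVE_CODES,
    DEFAULT_RANGES,
    ModelRecipe,
    PreprocessState,
    apply_recipe,
)

#: scatter methods conventionally compared (the five corrections plus none)
DEFAULT_SCATTER_METHODS = ("NONE", "SNV", "DET", "MSC", "SNVD", "WMSC")

TABLE_COLUMNS = [
    "N", "Terms", "DT", "SCM", "Spectrum range (nm)",
    "Mean", "SD", "SEC", "R2", "SECV", "R2cv", "RPD",
]


@dataclasses.dataclass
class ValidationStats:
    """One calibration-table row: a recipe and its fit/validation statistics."""

    trait: str
    recipe: ModelRecipe
    n: int
    terms: int
    mean: float
    sd: float
    sec: float
    r2: float
    secv: float
    r2cv: float
    rpd: float
    sep: float | None = None
    r2ev: float | None = None
    rpd_ev: float | None = None

    def as_row(self) -> dict:
        d, g, s1, s2 = self.recipe.derivative
        lo, hi = self.recipe.wl_range
        row = {
            "N": self.n,
            "Terms": self.terms,
            "DT": f"{d},{g},{s1},{s2}",
            "SCM": self.recipe.scatter,
            "Spectrum range (nm)": f"{lo:g}-{hi:g}",
            "Mean": self.mean,
            "SD": self.sd,
            "SEC": self.sec,
            "R2": self.r2,
            "SECV": self.secv,
            "R2cv": self.r2cv,
            "RPD": self.rpd,
        }
        if self.r2ev is not None:
            row.update({"SEP": self.sep, "R2ev": self.r2ev, "RPD_ev": self.rpd_ev})
        return row


# ----------------------------------------------------------------- primitives


def calibration_stats(y: np.ndarray, yhat: np.ndarray, n_factors: int) -> tuple[float, float]:
    """SEC and R² of a calibration fit.

    ``SEC = sqrt(SSE / (n - n_factors - 1))``; ``R² = 1 - SSE/SST``.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    n = y.size
    if yhat.size != n:
        raise InputError("y and yhat lengths differ")
    if n < n_factors + 2:
        raise InputError(f"need at least n_factors + 2 = {n_factors + 2} samples")
    sse = float(((y - yhat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise InputError("reference values are constant (zero SST)")
    sec = float(np.sqrt(sse / (n - n_factors - 1)))
    return sec, 1.0 - sse / sst


def rpd(sd: float, secv: float) -> float:
    """Ratio performance deviation, SD / SECV."""
    if secv <= 0:
        raise InputError("SECV must be positive to form an RPD")
    return sd / secv


def _trait_values(ds: SpectraDataset, trait: str) -> np.ndarray:
    if ds.traits is None:
        raise InputError("dataset carries no trait table")
    if trait not in ds.traits.columns:
        raise InputError(f"trait {trait!r} not in trait table")
    y = ds.traits[trait].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise InputError(f"trait {trait!r} contains non-finite values")
    return y


# ------------------------------------------------------------ cross-validation


@dataclasses.dataclass
class CVResult:
    secv: float
    r2cv: float
    terms: int
    secv_by_factor: np.ndarray  # SECV at 1..max_factors
    folds: np.ndarray           # fold label per sample


def cross_validate(
    ds: SpectraDataset,
    recipe: ModelRecipe,
    trait: str,
    max_factors: int = 15,
    n_groups: int = 4,
    seed: int = 0,
    standardize_residuals: bool = True,
) -> CVResult:
    """Random-group cross validation of one recipe for one trait.

    Pretreats the calibration population once, partitions samples into
    ``n_groups`` seeded random folds, pools out-of-fold predictions for
    every candidate factor count, and applies the 2% parsimony rule to pick
    the optimal Terms.
    """
    if n_groups < 2:
        raise InputError("n_groups must be >= 2")
    n = ds.n_samples
    if n < n_groups:
        raise InputError(f"need at least n_groups = {n_groups} samples")
    y = _trait_values(ds, trait)
    pre, _ = apply_recipe(ds, recipe)

    rng = np.random.default_rng(seed)
    folds = np.repeat(np.arange(n_groups), -(-n // n_groups))[:n]
    folds = folds[rng.permutation(n)]

    min_train = min(int((folds != f).sum()) for f in range(n_groups))
    kmax = min(max_factors, min_train - 2, pre.n_wavelengths)
    if kmax < 1:
        raise InputError("too few samples or wavelengths for cross validation")

    pooled = np.empty((n, kmax))
    for f in range(n_groups):
        test = folds == f
        model = fit_mpls(
            pre.X[~test], y[~test], n_factors=kmax,
            standardize_residuals=standardize_residuals,
        )
        pooled[test] = model.predict_per_factor(pre.X[test])[:, :kmax]

    sse = ((pooled - y[:, None]) ** 2).sum(axis=0)
    secv_by_factor = np.sqrt(sse / n)
    best = secv_by_factor.min()
    terms = int(np.argmax(secv_by_factor <= 1.02 * best) + 1)
    sst = float(((y - y.mean()) ** 2).sum())
    secv = float(secv_by_factor[terms - 1])
    r2cv = 1.0 - float(sse[terms - 1]) / sst
    return CVResult(secv=secv, r2cv=r2cv, terms=terms,
                    secv_by_factor=secv_by_factor, folds=folds)


# ------------------------------------------------------------- split/external


def split_calibration_validation(
    ds: SpectraDataset, n_validation: int, seed: int = 0
) -> tuple[SpectraDataset, SpectraDataset, pd.DataFrame]:
    """Seeded random split into calibration and external-validation sets.

    Returns (calibration, validation, summary) where the summary compares
    the two sets trait-by-trait (mean/min/max/SD), the conventional check
    that a random split produced comparable populations.
    """
    n = ds.n_samples
    if not 0 < n_validation < n:
        raise InputError("n_validation must satisfy 0 < n_validation < n")
    rng = np.random.default_rng(seed)
    val_idx = np.sort(rng.choice(n, size=n_validation, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[val_idx] = True
    cal, val = ds.subset(~mask), ds.subset(mask)

    summary = pd.DataFrame()
    if ds.traits is not None:
        num = ds.traits.select_dtypes("number")
        rows = []
        for name, part in (("calibration", cal.traits), ("validation", val.traits)):
            for col in num.columns:
                v = part[col].to_numpy(float)
                rows.append({
                    "set": name, "trait": col, "n": v.size, "mean": v.mean(),
                    "min": v.min(), "max": v.max(), "sd": v.std(ddof=1),
                })
        summary = pd.DataFrame(rows)
    return cal, val, summary


def external_validate(
    model: MPLSModel,
    validation: SpectraDataset,
    trait: str,
    recipe: ModelRecipe,
    state: PreprocessState | None = None,
    calibration_ids: set[str] | None = None,
    allow_overlap: bool = False,
) -> tuple[float, float, float]:
    """External validation of a fitted model on held-out samples.

    Returns ``(R²ev, SEP, RPD_ev)`` with ``SEP = sqrt(SSE/n)``,
    ``R²ev = 1 - SSE/SST`` and ``RPD_ev = SD/SEP`` on the validation set.
    ``state`` should be the preprocessing state of the calibration run so
    MSC/WMSC corrections use the calibration reference spectrum.
    """
    if calibration_ids is not None and not allow_overlap:
        overlap = set(validation.ids) & set(calibration_ids)
        if overlap:
            raise InputError(
                f"validation set overlaps calibration set ({len(overlap)} shared IDs)"
            )
    y = _trait_values(validation, trait)
    pre, _ = apply_recipe(validation, recipe, state=state)
    yhat = model.predict(pre.X)
    sse = float(((y - yhat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise InputError("validation reference values are constant")
    sep = float(np.sqrt(sse / y.size))
    r2ev = 1.0 - sse / sst
    rpd_ev = float(y.std(ddof=1) / sep)
    return r2ev, sep, rpd_ev


# ------------------------------------------------------------------ top level


def evaluate_recipe(
    ds: SpectraDataset,
    recipe: ModelRecipe,
    trait: str,
    max_factors: int = 15,
    n_groups: int = 4,
    seed: int = 0,
) -> tuple[ValidationStats, MPLSModel, PreprocessState]:
    """Cross-validate one recipe, then refit on the full set at the optimal Terms."""
    y = _trait_values(ds, trait)
    cv = cross_validate(ds, recipe, trait, max_factors=max_factors,
                        n_groups=n_groups, seed=seed)
    pre, state = apply_recipe(ds, recipe)
    model = fit_mpls(pre.X, y, n_factors=cv.terms,
                     provenance=pre.provenance, trait=trait)
    yhat = model.predict(pre.X)
    sec, r2 = calibration_stats(y, yhat, cv.terms)
    sd = float(y.std(ddof=1))
    stats = ValidationStats(
        trait=trait, recipe=recipe, n=ds.n_samples, terms=cv.terms,
        mean=float(y.mean()), sd=sd, sec=sec, r2=r2,
        secv=cv.secv, r2cv=cv.r2cv, rpd=rpd(sd, cv.secv),
    )
    return stats, model, state


def grid_search(
    ds: SpectraDataset,
    trait: str,
    derivative_codes=DEFAULT_DERIVATIVE_CODES,
    scatter_methods=DEFAULT_SCATTER_METHODS,
    ranges=DEFAULT_RANGES,
    max_factors: int = 15,
    n_groups: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate every recipe in the grid and rank rows by SECV.

    Returns a DataFrame in the conventional calibration-table column order
    plus ``trait``, ``recipe`` (token) and ``status`` columns; recipes that
    fail (e.g. a derivative trimming the range below 2 points) are kept with
    ``status`` recording the error.  The same CV fold seed is used for every
    recipe so rankings compare like with like.
    """
    if not (len(derivative_codes) and len(scatter_methods) and len(ranges)):
        raise InputError("empty pretreatment grid")
    rows = []
    for code in derivative_codes:
        for scm in scatter_methods:
            for rng_ in ranges:
                recipe = ModelRecipe(derivative=tuple(code), scatter=scm,
                                     wl_range=tuple(rng_))
                try:
                    stats, _, _ = evaluate_recipe(
                        ds, recipe, trait, max_factors=max_factors,
                        n_groups=n_groups, seed=seed,
                    )
                    row = {"trait": trait, "recipe": recipe.token(),
                           "status": "ok", **stats.as_row()}
                except (InputError, np.linalg.LinAlgError) as exc:
                    row = {"trait": trait, "recipe": recipe.token(),
                           "status": f"failed: {exc}"}
                rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["status"] == "ok"
    ranked = pd.concat(
        [table[ok].sort_values("SECV", kind="stable"), table[~ok]],
        ignore_index=True,
    )
    cols = ["trait", "recipe", "status"] + [c for c in TABLE_COLUMNS if c in ranked.columns]
    return ranked[cols]
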