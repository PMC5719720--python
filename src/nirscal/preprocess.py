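"""Spectral pretreatments: scatter correction, detrending, gap-segment derivatives.

A pretreatment configuration (:class:`ModelRecipe`) combines three choices:

* a derivative code ``d,g,s1,s2`` in the ISI convention — derivative order,
  gap over which each difference is taken, and two running-mean smoothing
  segment widths (``0,0,1,1`` is the identity);
* a scatter-correction method: ``NONE``, ``SNV`` (standard normal variate),
  ``DET`` (polynomial detrend), ``MSC`` (multiplicative scatter correction),
  ``SNVD`` (SNV followed by detrend), or ``WMSC`` (weighted MSC);
* a wavelength range restriction, conventionally 408-2492, 780-2492 or
  1108-2492 nm.

:func:`apply_recipe` applies them in the order range -> scatter -> derivative.
Scatter models are defined on raw absorbance, which is why the range cut and
scatter correction precede differentiation; the order is recorded in the
dataset provenance.  MSC/WMSC need a population reference spectrum: fitting
state is captured in a :class:`PreprocessState` so spectra of new samples
(e.g. an external validation set) can be corrected against the calibration
population's reference.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np

from nirscal.datasets import InputError, SpectraDataset

SCATTER_METHODS = ("NONE", "SNV", "DET", "MSC", "SNVD", "WMSC")

#: derivative codes conventionally explored when building a calibration
DEFAULT_DERIVATIVE_CODES = (
    (0, 0, 1, 1),
    (1, 4, 4, 1),
    (2, 4, 4, 1),
    (2, 4, 4, 2),
    (2, 5, 5, 2),
    (2, 8, 8, 1),
    (2, 8, 8, 2),
    (2, 10, 10, 2),
)

#: wavelength windows (nm) conventionally compared
DEFAULT_RANGES = ((408.0, 2492.0), (780.0, 2492.0), (1108.0, 2492.0))


@dataclasses.dataclass(frozen=True)
class ModelRecipe:
    """One pretreatment configuration: derivative code, scatter method, range."""

    derivative: tuple[int, int, int, int] = (0, 0, 1, 1)
    scatter: str = "NONE"
    wl_range: tuple[float, float] = (408.0, 2492.0)

    def __post_init__(self) -> None:
        d, g, s1, s2 = self.derivative
        if d not in (0, 1, 2):
            raise InputError(f"derivative order must be 0, 1 or 2, got {d}")
        if d > 0 and g < 1:
            raise InputError("gap must be >= 1 when the derivative order is > 0")
        if d == 0 and g != 0:
            raise InputError("gap must be 0 when the derivative order is 0")
        if s1 < 1 or s2 < 1:
            raise InputError("smoothing segments must be >= 1")
        if self.scatter not in SCATTER_METHODS:
            raise InputError(
                f"unknown scatter method {self.scatter!r}; expected one of {SCATTER_METHODS}"
            )
        if not self.wl_range[0] < self.wl_range[1]:
            raise InputError("wavelength range must satisfy lo < hi")

    def token(self) -> str:
        """Printed form, e.g. ``'2,5,5,2 | SNVD | 1108-2492'``."""
        d = ",".join(str(v) for v in self.derivative)
        lo, hi = self.wl_range
        return f"{d} | {self.scatter} | {lo:g}-{hi:g}"

    @classmethod
    def from_token(cls, token: str) -> "ModelRecipe":
        m = re.fullmatch(
            r"\s*(\d+),(\d+),(\d+),(\d+)\s*\|\s*(\w+)\s*\|\s*([\d.]+)-([\d.]+)\s*",
            token,
        )
        if m is None:
            raise InputError(f"unparseable recipe token: {token!r}")
        return cls(
            derivative=tuple(int(m.group(i)) for i in range(1, 5)),
            scatter=m.group(5).upper(),
            wl_range=(float(m.group(6)), float(m.group(7))),
        )


@dataclasses.dataclass
class PreprocessState:
    """Population statistics captured while pretreating a calibration set.

    ``msc_reference`` is the column-mean raw spectrum on the restricted range;
    ``wmsc_weights`` the default inverse-variance weights.  Reusing the state
    corrects new spectra against the same reference population.
    """

    recipe: ModelRecipe
    msc_reference: np.ndarray | None = None
    wmsc_weights: np.ndarray | None = None


# ----------------------------------------------------------------- operations


def snv(X: np.ndarray, ids: list[str] | None = None) -> np.ndarray:
    """Standard normal variate: centre each spectrum and scale to sample SD 1."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise InputError("SNV needs at least 2 wavelengths per spectrum")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        label = ids[bad[0]] if ids is not None else f"row {bad[0]}"
        raise InputError(f"zero-variance spectrum for sample {label}; SNV undefined")
    return (X - mu) / sd


def _poly_design(grid: np.ndarray, order: int) -> np.ndarray:
    # centred/scaled abscissa keeps the Vandermonde well conditioned
    g = np.asarray(grid, dtype=float)
    span = np.ptp(g)
    t = (g - g.mean()) / (span / 2 if span else 1.0)
    return np.vander(t, order + 1, increasing=True)


def detrend(X: np.ndarray, grid: np.ndarray | None = None, order: int = 2) -> np.ndarray:
    """Remove a least-squares polynomial (default quadratic) in wavelength per row."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if order >= p:
        raise InputError(f"detrend order {order} needs more than {order} wavelengths")
    if grid is None:
        grid = np.arange(p, dtype=float)
    D = _poly_design(grid, order)
    coef, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    return X - (D @ coef).T


def msc(X: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is regressed on the reference, ``x = a + b*ref``, and
    returned as ``(x - a) / b``.  With ``reference=None`` the column-mean
    spectrum of ``X`` is used.
    """
    X = np.asarray(X, dtype=float)
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.size != X.shape[1]:
        raise InputError("MSC reference length must equal the wavelength count")
    return _msc_core(X, ref, weights=None)


def wmsc(
    X: np.ndarray,
    reference: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted MSC: weighted least-squares fit of each spectrum on the reference.

    Default weights are the reciprocal of the across-sample variance at each
    wavelength, down-weighting unstable spectral regions.
    """
    X = np.asarray(X, dtype=float)
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.size != X.shape[1]:
        raise InputError("WMSC reference length must equal the wavelength count")
    if weights is None:
        var = X.var(axis=0, ddof=1)
        # floor avoids infinite weight at an accidentally constant wavelength
        floor = max(var[var > 0].min() if np.any(var > 0) else 1.0, 1e-30) * 1e-6
        weights = 1.0 / np.maximum(var, floor)
    w = np.asarray(weights, dtype=float)
    if w.size != X.shape[1]:
        raise InputError("WMSC weights length must equal the wavelength count")
    if np.any(w < 0) or not np.any(w > 0):
        raise InputError("WMSC weights must be non-negative and not all zero")
    return _msc_core(X, ref, weights=w)


def _msc_core(X: np.ndarray, ref: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    w = np.ones_like(ref) if weights is None else weights
    sw = w.sum()
    mw_ref = (w * ref).sum() / sw
    mw_x = (X * w).sum(axis=1) / sw
    sxx = (w * (ref - mw_ref) ** 2).sum()
    if sxx == 0:
        raise InputError("MSC reference has zero (weighted) variance")
    b = ((X - mw_x[:, None]) * (w * (ref - mw_ref))).sum(axis=1) / sxx
    a = mw_x - b * mw_ref
    if np.any(np.abs(b) < 1e-12):
        bad = int(np.flatnonzero(np.abs(b) < 1e-12)[0])
        raise InputError(
            f"spectrum at row {bad} is uncorrelated with the MSC reference (|b| < 1e-12)"
        )
    return (X - a[:, None]) / b[:, None]


def _running_mean(X: np.ndarray, grid: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Valid-mode running mean over wavelengths; grid is averaged identically."""
    if window == 1:
        return X, grid
    if X.shape[1] < window:
        raise InputError("spectrum narrower than smoothing window")
    kernel = np.ones(window) / window
    Xs = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, X)
    gs = np.convolve(grid, kernel, mode="valid")
    return Xs, gs


def _gap_difference(X: np.ndarray, grid: np.ndarray, gap: int) -> tuple[np.ndarray, np.ndarray]:
    """One gap difference: x(i + ceil(g/2)) - x(i - floor(g/2)), edges dropped."""
    hi = -(-gap // 2)  # ceil
    lo = gap // 2
    p = X.shape[1]
    if p <= lo + hi:
        raise InputError("spectrum too narrow for the requested gap")
    Xd = X[:, lo + hi :] - X[:, : p - lo - hi]
    gd = 0.5 * (grid[lo + hi :] + grid[: p - lo - hi])
    return Xd, gd


def gap_segment_derivative(
    X: np.ndarray, grid: np.ndarray, code: tuple[int, int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Gap-segment derivative in the ISI ``d,g,s1,s2`` convention.

    Pipeline: running-mean smooth with segment ``s1`` -> ``d`` successive
    gap differences over gap ``g`` -> running-mean smooth with segment
    ``s2``.  Edge points without full support are dropped and the returned
    grid is trimmed to the surviving (effective) wavelength positions; the
    grid positions are propagated through each step so that, for odd gaps
    or even segments, half-step shifts stay explicit.  Code ``0,0,1,1``
    returns the input unchanged.
    """
    d, g, s1, s2 = code
    ModelRecipe(derivative=(d, g, s1, s2))  # validates the code
    X = np.asarray(X, dtype=float)
    grid = np.asarray(grid, dtype=float)
    X, grid = _running_mean(X, grid, s1)
    for _ in range(d):
        X, grid = _gap_difference(X, grid, g)
    X, grid = _running_mean(X, grid, s2)
    if X.shape[1] < 2:
        raise InputError("derivative code leaves fewer than 2 wavelengths")
    return X, grid


def restrict_range(
    X: np.ndarray, grid: np.ndarray, wl_range: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = wl_range
    mask = (grid >= lo) & (grid <= hi)
    if mask.sum() < 2:
        raise InputError(f"wavelength range {lo}-{hi} covers fewer than 2 grid points")
    return X[:, mask], grid[mask]


def apply_recipe(
    ds: SpectraDataset,
    recipe: ModelRecipe,
    state: PreprocessState | None = None,
) -> tuple[SpectraDataset, PreprocessState]:
    """Apply a pretreatment recipe: range cut, scatter correction, derivative.

    Returns the pretreated dataset (with the recipe token appended to its
    provenance) and the fitted :class:`PreprocessState`.  Pass the state of a
    calibration run to pretreat new samples against the same MSC reference
    and WMSC weights.
    """
    X, grid = restrict_range(ds.X, ds.wavelengths, recipe.wl_range)

    if state is not None and state.recipe != recipe:
        raise InputError(
            f"preprocess state was fitted with {state.recipe.token()!r}, "
            f"recipe is {recipe.token()!r}"
        )
    new_state = PreprocessState(recipe=recipe)

    method = recipe.scatter
    if method == "SNV":
        X = snv(X, ids=ds.ids)
    elif method == "DET":
        X = detrend(X, grid)
    elif method == "SNVD":
        X = detrend(snv(X, ids=ds.ids), grid)
    elif method == "MSC":
        ref = state.msc_reference if state is not None else X.mean(axis=0)
        X = msc(X, reference=ref)
        new_state.msc_reference = ref
    elif method == "WMSC":
        if state is not None:
            ref, w = state.msc_reference, state.wmsc_weights
        else:
            ref = X.mean(axis=0)
            var = X.var(axis=0, ddof=1)
            floor = max(var[var > 0].min() if np.any(var > 0) else 1.0, 1e-30) * 1e-6
            w = 1.0 / np.maximum(var, floor)
        X = wmsc(X, reference=ref, weights=w)
        new_state.msc_reference = ref
        new_state.wmsc_weights = w
    elif method != "NONE":  # pragma: no cover - guarded by ModelRecipe
        raise InputError(f"unknown scatter method {method!r}")

    X, grid = gap_segment_derivative(X, grid, recipe.derivative)
    return ds.with_spectra(grid, X, provenance_token=recipe.token()), new_state
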