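"""Seeded synthetic rice-straw populations: trait tables, spectra, outliers.

The generator emulates the statistical structure a straw NIRS calibration
assumes, so every pipeline stage is testable without instrument data:

* wall-polymer features are drawn from a correlated multivariate normal
  matched to target means/SDs, with out-of-bounds rows redrawn (rejection,
  not clipping, to avoid boundary spikes);
* saccharification yields are linear combinations of the standardized
  polymer features plus independent noise, with signed coefficients that
  force the known correlation structure (cellulose and lignin depress, Ara
  raises, X/A depresses hexose yields) by construction;
* spectra follow a Beer-Lambert surrogate: absorbance(sample, λ) =
  m·Σ_k c_k·e_k(λ) + b + s·(λ - λ_min) + ε(λ), with per-sample
  multiplicative factor m, baseline offset b, wavelength slope s and i.i.d.
  noise ε emulating scatter artifacts;
* :func:`inject_outliers` perturbs chosen samples with structured spectral
  deviations (random Gaussian bumps) and records their IDs as ground truth.

All defaults live in a versioned YAML config bundled with the package
(``data/default_generator.yaml``); every output is deterministic given its
seed.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from nirscal.datasets import ConfigurationError, InputError, SpectraDataset

_MAX_REJECTIONS = 1000


@dataclasses.dataclass(frozen=True)
class TraitSpec:
    """Target marginal for one trait (trait units)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigurationError(f"SD must be positive, got {self.sd}")
        if not self.lo < self.mean < self.hi:
            raise ConfigurationError(
                f"bounds must satisfy min < mean < max, got {self.lo}/{self.mean}/{self.hi}"
            )


@dataclasses.dataclass(frozen=True)
class SacchSpec:
    """Target marginal plus generating linear model for a saccharification yield."""

    mean: float
    sd: float
    lo: float
    hi: float
    weights: dict[str, float]     # loadings on standardized polymer features
    explained: float              # fraction of variance carried by the polymers

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigurationError(f"SD must be positive, got {self.sd}")
        if not self.lo < self.mean < self.hi:
            raise ConfigurationError("bounds must satisfy min < mean < max")
        if not 0 < self.explained < 1:
            raise ConfigurationError("explained variance fraction must lie in (0, 1)")


@dataclasses.dataclass
class TraitConfig:
    """Trait marginals, polymer correlation matrix, and yield generating models."""

    polymer: dict[str, TraitSpec]
    correlation: np.ndarray
    sacch: dict[str, SacchSpec]

    def __post_init__(self) -> None:
        k = len(self.polymer)
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (k, k):
            raise ConfigurationError(
                f"correlation matrix is {R.shape}, expected ({k}, {k})"
            )
        if not np.allclose(R, R.T, atol=1e-12):
            raise ConfigurationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ConfigurationError("correlation matrix must have unit diagonal")
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10:
            raise ConfigurationError(
                f"correlation matrix is not positive semidefinite (min eig {eig.min():.3g})"
            )
        self.correlation = R
        for name, spec in self.sacch.items():
            unknown = set(spec.weights) - set(self.polymer)
            if unknown:
                raise ConfigurationError(
                    f"yield {name!r} references unknown polymer traits {sorted(unknown)}"
                )

    @property
    def polymer_names(self) -> list[str]:
        return list(self.polymer)

    @property
    def trait_names(self) -> list[str]:
        return list(self.polymer) + list(self.sacch)


@dataclasses.dataclass
class ComponentLibrary:
    """Pure-component absorptivity curves on a regular wavelength grid."""

    wavelengths: np.ndarray
    curves: dict[str, np.ndarray]  # trait -> absorptivity per unit concentration

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        step = np.diff(w)
        if w.size < 2 or np.any(step <= 0) or not np.allclose(step, step[0]):
            raise ConfigurationError("grid must be strictly increasing with constant step")
        self.wavelengths = w
        for name, c in self.curves.items():
            c = np.asarray(c, dtype=float)
            if c.shape != w.shape:
                raise ConfigurationError(f"curve {name!r} does not match the grid")
            if np.any(c < 0):
                raise ConfigurationError(f"curve {name!r} has negative absorptivity")
            self.curves[name] = c

    @classmethod
    def from_bands(cls, wavelengths, bands: dict[str, list[dict]]) -> "ComponentLibrary":
        """Build curves as sums of Gaussian bands {center, sigma, height}."""
        w = np.asarray(wavelengths, dtype=float)
        curves = {}
        for name, blist in bands.items():
            c = np.zeros_like(w)
            for b in blist:
                c += b["height"] * np.exp(-0.5 * ((w - b["center"]) / b["sigma"]) ** 2)
            curves[name] = c
        return cls(wavelengths=w, curves=curves)


@dataclasses.dataclass(frozen=True)
class ScatterConfig:
    """Per-sample scatter-artifact scales (all SDs >= 0)."""

    multiplicative_sd: float = 0.05
    offset_sd: float = 0.02
    slope_sd: float = 1e-5
    noise_sd: float = 5e-4

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigurationError(f"{f.name} must be >= 0")


# ------------------------------------------------------------- default config


def load_default_config() -> dict:
    """Parsed contents of the bundled ``default_generator.yaml``."""
    text = resources.files("nirscal.data").joinpath("default_generator.yaml").read_text()
    return yaml.safe_load(text)


def default_trait_config(raw: dict | None = None) -> TraitConfig:
    raw = load_default_config() if raw is None else raw
    polymer = {}
    for name, d in raw["polymer_traits"].items():
        lo = d.get("min", d["mean"] - 4 * d["sd"])
        hi = d.get("max", d["mean"] + 4 * d["sd"])
        polymer[name] = TraitSpec(mean=d["mean"], sd=d["sd"], lo=lo, hi=hi)
    sacch = {}
    for name, d in raw["sacch_traits"].items():
        lo = d.get("min", d["mean"] - 4 * d["sd"])
        hi = d.get("max", d["mean"] + 4 * d["sd"])
        sacch[name] = SacchSpec(
            mean=d["mean"], sd=d["sd"], lo=lo, hi=hi,
            weights=dict(d["weights"]), explained=d["explained"],
        )
    return TraitConfig(
        polymer=polymer,
        correlation=np.array(raw["polymer_correlation"], dtype=float),
        sacch=sacch,
    )


def default_component_library(raw: dict | None = None) -> ComponentLibrary:
    raw = load_default_config() if raw is None else raw
    g = raw["wavelength_grid"]
    grid = np.arange(g["start"], g["stop"] + g["step"] / 2, g["step"])
    return ComponentLibrary.from_bands(grid, raw["component_library"])


def default_scatter_config(raw: dict | None = None) -> ScatterConfig:
    raw = load_default_config() if raw is None else raw
    return ScatterConfig(**raw["scatter"])


# ----------------------------------------------------------------- generators


def generate_trait_table(n: int, cfg: TraitConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw a correlated trait table with the configured marginal structure.

    Polymer features come from a multivariate normal matched to the target
    means/SDs/correlations; saccharification yields are computed from the
    standardized polymer features through their configured linear model,
    with noise scaled so the marginal SD hits its target.  Out-of-bounds
    draws are rejected, never clipped, so bounded traits show no boundary
    spikes.  Rejection is staged to keep the polymer marginals and
    correlations undistorted by yield bounds: a polymer vector violating its
    own bounds is redrawn; a yield violating its bounds has its noise
    redrawn; only if a yield's noise redraws are exhausted (the polymer
    signal itself is far outside the yield bounds — rare) is the entire row
    redrawn.  The overall cap is 1000 attempts per row.
    """
    if n < 2:
        raise InputError("need n >= 2 samples")
    cfg = default_trait_config() if cfg is None else cfg
    rng = np.random.default_rng(seed)
    names = cfg.polymer_names
    k = len(names)
    mu = np.array([cfg.polymer[t].mean for t in names])
    sd = np.array([cfg.polymer[t].sd for t in names])
    lo = np.array([cfg.polymer[t].lo for t in names])
    hi = np.array([cfg.polymer[t].hi for t in names])
    L = np.linalg.cholesky(cfg.correlation + 1e-12 * np.eye(k))

    R = cfg.correlation
    ynames = list(cfg.sacch)
    W = np.empty((len(ynames), k))       # scaled loadings, trait units
    ymu = np.empty(len(ynames))
    ylo = np.empty(len(ynames))
    yhi = np.empty(len(ynames))
    noise_sd = np.empty(len(ynames))
    for j, yname in enumerate(ynames):
        spec = cfg.sacch[yname]
        w = np.array([spec.weights.get(t, 0.0) for t in names])
        wRw = float(w @ R @ w)
        if wRw <= 0:
            raise ConfigurationError(f"yield {yname!r} has degenerate weights")
        W[j] = w * spec.sd * np.sqrt(spec.explained / wRw)
        ymu[j] = spec.mean
        ylo[j], yhi[j] = spec.lo, spec.hi
        noise_sd[j] = spec.sd * np.sqrt(1 - spec.explained)

    noise_redraws = 50  # per yield, before the whole row is abandoned
    rows = np.empty((n, k + len(ynames)))
    for i in range(n):
        for attempt in range(_MAX_REJECTIONS):
            z = L @ rng.standard_normal(k)
            x = mu + sd * z
            if not np.all((x >= lo) & (x <= hi)):
                continue
            signal = ymu + W @ z
            y = signal + rng.normal(0, noise_sd)
            ok = True
            for j in np.flatnonzero((y < ylo) | (y > yhi)):
                for _ in range(noise_redraws):
                    y[j] = signal[j] + rng.normal(0, noise_sd[j])
                    if ylo[j] <= y[j] <= yhi[j]:
                        break
                else:
                    ok = False
                    break
            if ok:
                rows[i, :k] = x
                rows[i, k:] = y
                break
        else:
            raise ConfigurationError(
                f"row {i}: {_MAX_REJECTIONS} rejections; bounds too tight for the marginals"
            )
    table = pd.DataFrame(rows, columns=names + ynames)
    table.index = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id")
    return table


def generate_spectra(
    traits: pd.DataFrame,
    lib: ComponentLibrary | None = None,
    scatter: ScatterConfig | None = None,
    seed: int = 0,
) -> SpectraDataset:
    """Beer-Lambert surrogate spectra for a trait table, with scatter artifacts."""
    lib = default_component_library() if lib is None else lib
    scatter = default_scatter_config() if scatter is None else scatter
    missing = [t for t in lib.curves if t not in traits.columns]
    if missing:
        raise InputError(f"trait table lacks columns used by the library: {missing}")
    comp_names = list(lib.curves)
    C = traits[comp_names].to_numpy(float)          # (n, k) concentrations
    E = np.stack([lib.curves[t] for t in comp_names])  # (k, p)
    mix = C @ E

    n, p = mix.shape
    rng = np.random.default_rng(seed)
    m = 1.0 + rng.normal(0, scatter.multiplicative_sd, size=n)
    b = rng.normal(0, scatter.offset_sd, size=n)
    s = rng.normal(0, scatter.slope_sd, size=n)
    eps = rng.normal(0, scatter.noise_sd, size=(n, p))
    lam = lib.wavelengths - lib.wavelengths[0]
    X = m[:, None] * mix + b[:, None] + s[:, None] * lam[None, :] + eps
    return SpectraDataset(
        wavelengths=lib.wavelengths.copy(),
        X=X,
        ids=[str(i) for i in traits.index],
        traits=traits.copy(),
    )


def inject_outliers(
    ds: SpectraDataset, k: int, magnitude: float = 6.0, seed: int = 0
) -> SpectraDataset:
    """Perturb ``k`` random samples with structured spectral deviations.

    Each chosen spectrum gains a sum of three random-sign Gaussian bumps,
    normalized to unit RMS over the grid and scaled by ``magnitude`` times
    the population's mean per-wavelength SD.  Perturbed IDs are recorded in
    ``outlier_truth``; every other spectrum is bit-identical to the input.
    """
    if not 0 <= k <= ds.n_samples:
        raise InputError(f"k must lie in [0, {ds.n_samples}]")
    if k == 0:
        return ds
    rng = np.random.default_rng(seed)
    idx = rng.choice(ds.n_samples, size=k, replace=False)
    pooled_sd = float(ds.X.std(axis=0, ddof=1).mean())
    grid = ds.wavelengths
    X = ds.X.copy()
    for i in idx:
        shape = np.zeros_like(grid)
        for _ in range(3):
            center = rng.uniform(grid[0], grid[-1])
            sigma = rng.uniform(30.0, 120.0)
            sign = rng.choice([-1.0, 1.0])
            shape += sign * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        shape /= np.sqrt(np.mean(shape**2))
        X[i] = X[i] + magnitude * pooled_sd * shape
    flagged = frozenset(ds.ids[i] for i in idx)
    return SpectraDataset(
        wavelengths=ds.wavelengths.copy(),
        X=X,
        ids=list(ds.ids),
        traits=None if ds.traits is None else ds.traits.copy(),
        outlier_truth=ds.outlier_truth | flagged,
        provenance=ds.provenance,
    )


def simulate_population(
    n: int = 247,
    n_outliers: int = 7,
    outlier_magnitude: float = 6.0,
    seed: int = 0,
    cfg: TraitConfig | None = None,
    lib: ComponentLibrary | None = None,
    scatter: ScatterConfig | None = None,
) -> SpectraDataset:
    """Convenience wrapper: traits -> spectra -> injected outliers, one seed.

    Sub-seeds for the three stages are spawned deterministically from
    ``seed`` so the stages stay independently reproducible.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    traits = generate_trait_table(n, cfg=cfg, seed=sub[0])
    ds = generate_spectra(traits, lib=lib, scatter=scatter, seed=sub[1])
    return inject_outliers(ds, n_outliers, magnitude=outlier_magnitude, seed=sub[2])
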