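"""In-memory containers for spectra and reference chemistry.

A :class:`SpectraDataset` couples an absorbance matrix (samples x
wavelengths on a regular grid) with sample IDs, an optional per-sample
trait table (reference chemistry and saccharification yields), optional
ground-truth outlier flags (synthetic data only), and a provenance record
of the pretreatment applied.  Trait tables are plain :class:`pandas.DataFrame`
objects indexed by sample ID.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Invalid user input (shapes, names, counts)."""


class ConfigurationError(ValueError):
    """Invalid configuration (non-PSD correlation matrix, bad bounds, ...)."""


@dataclasses.dataclass
class SpectraDataset:
    """Absorbance spectra with aligned sample metadata.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelength grid in nm.
    X
        Absorbance matrix, shape ``(n_samples, n_wavelengths)``.
    ids
        Sample identifiers, unique, length ``n_samples``.
    traits
        Optional reference trait table indexed by sample ID.
    outlier_truth
        IDs of samples carrying injected spectral perturbations
        (synthetic data only; used to score screening).
    provenance
        Pretreatment provenance tokens, e.g. ``["1,4,4,1 | SNV | 408-2492"]``.
    """

    wavelengths: np.ndarray
    X: np.ndarray
    ids: list[str]
    traits: pd.DataFrame | None = None
    outlier_truth: frozenset[str] = frozenset()
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.ids = [str(i) for i in self.ids]
        if self.X.ndim != 2:
            raise InputError("spectra matrix must be 2-D (samples x wavelengths)")
        if self.X.shape != (len(self.ids), self.wavelengths.size):
            raise InputError(
                f"shape mismatch: X {self.X.shape}, "
                f"{len(self.ids)} ids, {self.wavelengths.size} wavelengths"
            )
        if len(set(self.ids)) != len(self.ids):
            raise InputError("sample IDs must be unique")
        if self.wavelengths.size >= 2 and np.any(np.diff(self.wavelengths) <= 0):
            raise InputError("wavelength grid must be strictly increasing")
        if self.traits is not None and list(self.traits.index) != self.ids:
            # tolerate same set in different order by reindexing
            if set(self.traits.index) >= set(self.ids):
                self.traits = self.traits.loc[self.ids]
            else:
                raise InputError("trait table does not cover all sample IDs")
        self.outlier_truth = frozenset(self.outlier_truth)
        self.provenance = tuple(self.provenance)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.X.shape[1]

    def subset(self, keep: np.ndarray | list) -> "SpectraDataset":
        """Row-subset by boolean mask or list of IDs, preserving order."""
        if isinstance(keep, (list, tuple, set, frozenset)):
            keep_set = {str(k) for k in keep}
            mask = np.array([i in keep_set for i in self.ids])
        else:
            mask = np.asarray(keep, dtype=bool)
            if mask.size != self.n_samples:
                raise InputError("boolean mask length must equal sample count")
        ids = [i for i, m in zip(self.ids, mask) if m]
        return SpectraDataset(
            wavelengths=self.wavelengths.copy(),
            X=self.X[mask].copy(),
            ids=ids,
            traits=None if self.traits is None else self.traits.loc[ids].copy(),
            outlier_truth=self.outlier_truth & set(ids),
            provenance=self.provenance,
        )

    def with_spectra(
        self,
        wavelengths: np.ndarray,
        X: np.ndarray,
        provenance_token: str | None = None,
    ) -> "SpectraDataset":
        """Return a copy carrying new spectra (same samples, new grid allowed)."""
        prov = self.provenance
        if provenance_token is not None:
            prov = prov + (provenance_token,)
        return SpectraDataset(
            wavelengths=wavelengths,
            X=X,
            ids=list(self.ids),
            traits=None if self.traits is None else self.traits.copy(),
            outlier_truth=self.outlier_truth,
            provenance=prov,
        )

    # ------------------------------------------------------------------ I/O

    def to_csv(self, spectra_path, traits_path=None, sidecar_path=None,
               meta: dict | None = None) -> None:
        """Write spectra (and optionally traits) as CSV.

        Spectra CSV layout: header ``sample_id,<wl0>,<wl1>,...`` with the
        wavelength grid in nm as column names; one sample per row.
        """
        df = pd.DataFrame(self.X, index=pd.Index(self.ids, name="sample_id"),
                          columns=[f"{w:g}" for w in self.wavelengths])
        df.to_csv(spectra_path)
        if traits_path is not None and self.traits is not None:
            self.traits.rename_axis("sample_id").to_csv(traits_path)
        if sidecar_path is not None:
            payload = dict(meta or {})
            payload.setdefault("provenance", list(self.provenance))
            payload["n_samples"] = self.n_samples
            payload["n_wavelengths"] = self.n_wavelengths
            Path(sidecar_path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, spectra_path, traits_path=None) -> "SpectraDataset":
        df = pd.read_csv(spectra_path, index_col=0)
        wavelengths = np.array([float(c) for c in df.columns])
        traits = None
        if traits_path is not None:
            traits = pd.read_csv(traits_path, index_col=0)
            traits.index = traits.index.astype(str)
        return cls(wavelengths=wavelengths, X=df.to_numpy(float),
                   ids=[str(i) for i in df.index], traits=traits)
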