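"""Modified partial least squares (MPLS) calibration.

MPLS is single-response (PLS1) NIPALS regression with one modification: the
spectral residuals at each wavelength, obtained after extracting each
factor, are standardized — divided by the standard deviation of the
residuals at that wavelength — before the next factor is computed.  The
per-factor scaling vectors are stored in the model so that prediction can
replay them in order.  With ``standardize_residuals=False`` the algorithm
reduces to ordinary NIPALS PLS1 and reproduces a reference PLS1
implementation's predictions.

Factor extraction (residuals X_a, y_a start as centred X, y):

    w_a = X_a' y_a / ||X_a' y_a||        covariance weight (unit norm)
    t_a = X_a w_a                        score
    p_a = X_a' t_a / (t_a' t_a)          X loading
    q_a = y_a' t_a / (t_a' t_a)          response loading
    X_{a+1} = X_a - t_a p_a'             deflation
    y_{a+1} = y_a - q_a t_a
    (MPLS) X_{a+1} <- X_{a+1} / sd_a     column-wise, sd_a stored

Only the wavelength residuals are rescaled; the response residuals are not.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from nirscal.datasets import InputError


@dataclasses.dataclass
class MPLSModel:
    """A fitted MPLS (or plain PLS1) calibration."""

    x_center: np.ndarray          # (p,)
    y_center: float
    weights: np.ndarray           # (k, p) unit-norm covariance weights
    loadings: np.ndarray          # (k, p) X loadings
    y_loadings: np.ndarray        # (k,)
    residual_scale: np.ndarray    # (k, p) per-factor wavelength SDs (ones if off)
    n_factors: int
    standardize_residuals: bool
    provenance: tuple[str, ...] = ()
    trait: str | None = None

    def predict(self, X: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        """Predict the response for pretreated spectra ``X``.

        Centring, factor-wise score computation, deflation and the stored
        residual scalings are replayed in fit order.  ``n_factors`` may
        truncate the model to its first factors.
        """
        preds = self.predict_per_factor(X)
        k = self.n_factors if n_factors is None else int(n_factors)
        if not 1 <= k <= self.n_factors:
            raise InputError(f"n_factors must be in [1, {self.n_factors}]")
        return preds[:, k - 1]

    def predict_per_factor(self, X: np.ndarray) -> np.ndarray:
        """Cumulative predictions after 1..n_factors factors, shape (n, k)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.x_center.size:
            raise InputError(
                f"spectra have {X.shape[1] if X.ndim == 2 else '?'} wavelengths, "
                f"model expects {self.x_center.size}"
            )
        R = X - self.x_center
        out = np.empty((X.shape[0], self.n_factors))
        yhat = np.full(X.shape[0], self.y_center)
        for a in range(self.n_factors):
            t = R @ self.weights[a]
            yhat = yhat + self.y_loadings[a] * t
            out[:, a] = yhat
            R = (R - np.outer(t, self.loadings[a])) / self.residual_scale[a]
        return out

    def regression_vector(self) -> tuple[np.ndarray, float]:
        """Collapsed (slope, intercept) of the fitted linear map, for inspection.

        The factor-wise replay is the canonical prediction path; this
        collapses it by propagating the deflation/rescaling recursion, which
        is exact because the whole map is affine in the input spectrum.
        """
        p = self.x_center.size
        # M maps the raw (uncentred) residual row-space through the replay
        M = np.eye(p)
        beta = np.zeros(p)
        for a in range(self.n_factors):
            w_eff = M @ self.weights[a]
            beta = beta + self.y_loadings[a] * w_eff
            M = (M - np.outer(w_eff, self.loadings[a])) / self.residual_scale[a]
        intercept = self.y_center - float(self.x_center @ beta)
        return beta, intercept

    # ------------------------------------------------------------------ I/O

    def to_json(self, path) -> None:
        payload = {
            "format": "nirscal-mpls-model",
            "version": 1,
            "trait": self.trait,
            "provenance": list(self.provenance),
            "n_factors": self.n_factors,
            "standardize_residuals": self.standardize_residuals,
            "x_center": self.x_center.tolist(),
            "y_center": self.y_center,
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "residual_scale": self.residual_scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "MPLSModel":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "nirscal-mpls-model":
            raise InputError(f"{path} is not a serialized MPLS model")
        return cls(
            x_center=np.array(d["x_center"]),
            y_center=float(d["y_center"]),
            weights=np.array(d["weights"]),
            loadings=np.array(d["loadings"]),
            y_loadings=np.array(d["y_loadings"]),
            residual_scale=np.array(d["residual_scale"]),
            n_factors=int(d["n_factors"]),
            standardize_residuals=bool(d["standardize_residuals"]),
            provenance=tuple(d.get("provenance", ())),
            trait=d.get("trait"),
        )


def fit_mpls(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    standardize_residuals: bool = True,
    provenance: tuple[str, ...] = (),
    trait: str | None = None,
) -> MPLSModel:
    """Fit an MPLS calibration of ``y`` on pretreated spectra ``X``.

    Parameters
    ----------
    X, y
        Pretreated spectra (n x p) and reference values (n,).
    n_factors
        Number of latent factors ("Terms") to extract.
    standardize_residuals
        If True (default), divide each wavelength's residual column by its
        sample SD after each factor — the MPLS modification.  If False the
        fit is ordinary NIPALS PLS1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise InputError("X and y disagree on sample count")
    if n_factors < 1:
        raise InputError("n_factors must be >= 1")
    if n <= n_factors + 1:
        raise InputError(f"need more than n_factors + 1 = {n_factors + 1} samples, got {n}")
    if np.ptp(y) == 0:
        raise InputError("response is constant; calibration undefined")

    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    R = X - x_center
    r = y - y_center

    W = np.empty((n_factors, p))
    P = np.empty((n_factors, p))
    q = np.empty(n_factors)
    S = np.ones((n_factors, p))

    for a in range(n_factors):
        w = R.T @ r
        wn = np.linalg.norm(w)
        if wn == 0:
            raise InputError(
                f"residual covariance vanished at factor {a + 1}; reduce n_factors"
            )
        w /= wn
        t = R @ w
        tt = float(t @ t)
        if tt <= 0:
            raise InputError(f"degenerate score at factor {a + 1}; reduce n_factors")
        pa = R.T @ t / tt
        qa = float(r @ t) / tt
        R = R - np.outer(t, pa)
        r = r - qa * t
        if standardize_residuals:
            sd = R.std(axis=0, ddof=1)
            zero = sd == 0
            if zero.any():
                warnings.warn(
                    f"{int(zero.sum())} wavelength(s) with zero residual SD at factor "
                    f"{a + 1}; scaling replaced by 1",
                    RuntimeWarning,
                    stacklevel=2,
                )
                sd = np.where(zero, 1.0, sd)
            R = R / sd
            S[a] = sd
        W[a], P[a], q[a] = w, pa, qa

    return MPLSModel(
        x_center=x_center,
        y_center=y_center,
        weights=W,
        loadings=P,
        y_loadings=q,
        residual_scale=S,
        n_factors=n_factors,
        standardize_residuals=standardize_residuals,
        provenance=tuple(provenance),
        trait=trait,
    )
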