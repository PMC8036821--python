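"""OLS residual diagnostics: Moran's I and variance-inflation factors.

The model-selection path of a tract-level ecological regression runs OLS
first, tests its residuals for spatial autocorrelation with Moran's I, and
screens the predictors for multicollinearity with VIF before committing to
the spatial lag / spatial error specifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import fit_ols, ModelFit  # noqa: F401  (fit_ols re-exported here)
from .weights import SpatialWeights


@dataclass
class MoranResult:
    """Global Moran's I with inference.

    ``expected`` is -1/(n-1); ``z = (I - expected)/sqrt(variance)``.  The
    ``normal`` scheme uses the variance under the normality assumption; the
    ``permutation`` scheme reports an empirical pseudo p-value from random
    relabelings and the permutation variance.
    """

    I: float
    expected: float
    variance: float
    z: float
    p: float
    scheme: str
    n_perm: int | None = None

    def to_dict(self) -> dict:
        return {"I": self.I, "expected": self.expected,
                "variance": self.variance, "z": self.z, "p": self.p,
                "scheme": self.scheme, "n_perm": self.n_perm}


def morans_i(residuals: np.ndarray, W: SpatialWeights,
             scheme: str = "normal", n_perm: int = 999,
             seed: int = 0) -> MoranResult:
    """Moran's I of a residual vector under a spatial weight matrix.

    ``I = (n / S0) * (e' W e) / (e' e)`` on the residuals exactly as given
    (no studentizing, no centering beyond what the regression already did).
    Two-sided p-values.
    """
    e = np.asarray(residuals, dtype=float).ravel()
    n = len(e)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 observations")
    if n != W.n:
        raise ValueError("residual length does not match W")
    if np.allclose(e, e[0]):
        raise ValueError("constant residuals: Moran's I undefined")
    Wm = W.matrix
    S0 = Wm.sum()
    I = (n / S0) * float(e @ (Wm @ e)) / float(e @ e)
    EI = -1.0 / (n - 1)
    if scheme == "normal":
        S1 = 0.5 * ((Wm + Wm.T) ** 2).sum()
        S2 = ((Wm.sum(axis=1) + Wm.sum(axis=0)) ** 2).sum()
        var = (n**2 * S1 - n * S2 + 3.0 * S0**2) / (S0**2 * (n**2 - 1)) - EI**2
        z = (I - EI) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        return MoranResult(I, EI, float(var), float(z), float(p), "normal")
    if scheme == "permutation":
        rng = np.random.default_rng(seed)
        sims = np.empty(n_perm)
        denom = float(e @ e)
        for b in range(n_perm):
            ep = rng.permutation(e)
            sims[b] = (n / S0) * float(ep @ (Wm @ ep)) / denom
        var = float(sims.var(ddof=1))
        z = (I - sims.mean()) / np.sqrt(var)
        # two-sided pseudo p-value with the +1 correction
        more_extreme = np.sum(np.abs(sims - sims.mean()) >= abs(I - sims.mean()))
        p = (more_extreme + 1.0) / (n_perm + 1.0)
        return MoranResult(I, EI, var, float(z), float(p), "permutation", n_perm)
    raise ValueError(f"unknown inference scheme {scheme!r}")


def vif(X: np.ndarray, feature_names: list[str] | None = None) -> pd.Series:
    """Variance inflation factors, ``VIF_j = 1 / (1 - R^2_j)``.

    Each auxiliary regression of predictor j on the remaining predictors
    includes an intercept.  X must not itself contain a constant column.
    Exactly collinear predictors get ``inf``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictor columns")
    n, k = X.shape
    if n <= k:
        raise ValueError("need more observations than predictors")
    names = feature_names if feature_names is not None else [
        f"x{j}" for j in range(k)]
    out = np.empty(k)
    for j in range(k):
        yj = X[:, j]
        Zj = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        bj, *_ = np.linalg.lstsq(Zj, yj, rcond=None)
        resid = yj - Zj @ bj
        tss = float(((yj - yj.mean()) ** 2).sum())
        if tss == 0:
            raise ValueError(f"predictor {names[j]!r} has zero variance")
        r2 = 1.0 - float(resid @ resid) / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=names, name="VIF")
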