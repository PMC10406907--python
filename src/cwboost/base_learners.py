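"""Ridge-penalized least-squares base-learners with df-calibrated penalties.

A base-learner is a subset of design columns fit to the current
pseudo-residuals by ridge regression.  Its effective degrees of freedom are

    df(lambda) = tr(2S - S'S),    S = X (X'X + lambda I)^{-1} X',

which in terms of the eigenvalues d_i of X'X equals

    df(lambda) = sum_i [ 2 d_i/(d_i+lambda) - (d_i/(d_i+lambda))^2 ].

Equalizing df across base-learners of different complexity is what makes
component-wise selection fair: a wider block gets a larger penalty so that
no learner wins merely by having more columns.  The penalty for a target df
is found by a bracketed root search on the strictly decreasing df(lambda);
the rank-1 case has the closed form s = 1 - sqrt(1 - df), lambda =
d (1 - s)/s, which doubles as an independent check on the root-finder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "RidgeBaseLearner",
    "BaseLearnerFit",
    "df_from_lambda",
    "lambda_from_df",
    "fit_base_learner",
]

DF_TOL = 1e-6
_RANK_RTOL = 1e-10


def _spectrum(block: np.ndarray) -> np.ndarray:
    """Eigenvalues of the block's cross-product matrix, ascending."""
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.shape[1] < 1:
        raise ValueError("block must be an n x k matrix with k >= 1")
    gram = block.T @ block
    return np.linalg.eigvalsh(gram)


def _rank(spectrum: np.ndarray) -> int:
    top = float(np.max(spectrum, initial=0.0))
    if top <= 0.0:
        return 0
    return int(np.sum(spectrum > top * _RANK_RTOL))


def _df_spectral(spectrum: np.ndarray, lam: float) -> float:
    if np.isinf(lam):
        return 0.0
    d = np.asarray(spectrum, dtype=float)
    if lam == 0.0:
        return float(_rank(d))
    s = d / (d + lam)
    return float(np.sum(2.0 * s - s * s))


def df_from_lambda(block: np.ndarray, lam: float) -> float:
    """Effective degrees of freedom tr(2S - S'S) of the ridge hat matrix."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return _df_spectral(_spectrum(block), lam)


def _lambda_from_spectrum(spectrum: np.ndarray, target_df: float) -> float:
    d = np.asarray(spectrum, dtype=float)
    rank = _rank(d)
    if rank == 0:
        raise ValueError("block has rank 0; df calibration undefined")
    if target_df <= 0.0:
        return np.inf
    if target_df > rank + 1e-9:
        raise ValueError(
            f"target df {target_df} exceeds block rank {rank}"
        )
    if abs(target_df - rank) <= 1e-12:
        return 0.0
    nz = d[d > d.max() * _RANK_RTOL]
    if nz.size == 1:
        # rank-1 closed form: df = 2s - s^2  =>  s = 1 - sqrt(1 - df)
        s = 1.0 - np.sqrt(1.0 - target_df)
        return float(nz[0] * (1.0 - s) / s)

    def g(lam: float) -> float:
        return _df_spectral(d, lam) - target_df

    hi = float(nz.max())
    while g(hi) > 0.0:
        hi *= 10.0
        if hi > 1e300:  # pragma: no cover - pathological scaling
            raise RuntimeError("df root bracket expansion failed")
    lam = brentq(g, 0.0, hi, xtol=1e-12 * max(1.0, hi), rtol=1e-15, maxiter=200)
    if abs(_df_spectral(d, lam) - target_df) > DF_TOL:  # pragma: no cover
        raise RuntimeError("df calibration did not reach tolerance")
    return float(lam)


def lambda_from_df(block: np.ndarray, target_df: float) -> float:
    """Penalty whose effective df matches ``target_df`` to within 1e-6."""
    return _lambda_from_spectrum(_spectrum(block), target_df)


@dataclass
class RidgeBaseLearner:
    """A calibrated ridge base-learner over one block of design columns.

    ``spectrum``/``basis`` hold the eigendecomposition of the block's
    cross-product matrix computed at calibration time; ``lam`` is +inf for
    an excluded learner (target_df = 0), which is never selectable.
    """

    term_id: str
    cols: tuple
    target_df: float
    lam: float
    spectrum: np.ndarray
    basis: np.ndarray
    kind: str = "individual"

    @property
    def excluded(self) -> bool:
        return np.isinf(self.lam)

    @property
    def width(self) -> int:
        return len(self.cols)

    @classmethod
    def from_block(cls, design, block, target_df: float, kind: str = None):
        """Calibrate a learner for one block of a design matrix."""
        X = design.values[:, list(block.cols)]
        gram = X.T @ X
        d, V = np.linalg.eigh(gram)
        lam = _lambda_from_spectrum(d, target_df) if target_df > 0 else np.inf
        if kind is None:
            kind = "interaction" if block.kind == "interaction" else "individual"
        return cls(
            term_id=block.term_id,
            cols=tuple(block.cols),
            target_df=float(target_df),
            lam=lam,
            spectrum=d,
            basis=V,
            kind=kind,
        )

    @classmethod
    def from_columns(cls, design, term_id, cols, target_df, kind):
        """Calibrate a learner over an arbitrary column set (e.g. a group)."""
        X = design.values[:, list(cols)]
        gram = X.T @ X
        d, V = np.linalg.eigh(gram)
        lam = _lambda_from_spectrum(d, target_df) if target_df > 0 else np.inf
        return cls(
            term_id=term_id,
            cols=tuple(cols),
            target_df=float(target_df),
            lam=lam,
            spectrum=d,
            basis=V,
            kind=kind,
        )


@dataclass
class BaseLearnerFit:
    """Result of fitting one base-learner to a pseudo-residual vector."""

    coef: np.ndarray
    fitted: np.ndarray
    sse: float


def ridge_solve(X: np.ndarray, u: np.ndarray, lam: float) -> np.ndarray:
    """(X'X + lambda I)^{-1} X'u, via the eigendecomposition of X'X.

    With lam = 0 on a rank-deficient block this is the minimum-norm
    (pseudoinverse) solution.
    """
    gram = X.T @ X
    d, V = np.linalg.eigh(gram)
    z = V.T @ (X.T @ u)
    denom = d + lam
    inv = np.zeros_like(d)
    ok = denom > max(d.max(), 1.0) * _RANK_RTOL
    inv[ok] = 1.0 / denom[ok]
    return V @ (z * inv)


def fit_base_learner(learner: RidgeBaseLearner, block: np.ndarray, u: np.ndarray) -> BaseLearnerFit:
    """Ridge fit of a calibrated learner to the pseudo-residuals ``u``."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("pseudo-residuals must be finite")
    if learner.excluded:
        zero = np.zeros(block.shape[1])
        return BaseLearnerFit(coef=zero, fitted=np.zeros_like(u), sse=float(u @ u))
    coef = ridge_solve(block, u, learner.lam)
    fitted = block @ coef
    resid = u - fitted
    return BaseLearnerFit(coef=coef, fitted=fitted, sse=float(resid @ resid))
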