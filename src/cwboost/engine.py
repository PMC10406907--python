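"""Functional gradient descent with component-wise base-learner selection.

The generic algorithm: initialize the fit at a constant offset; at each
iteration compute the negative gradient of the loss at the current fit (the
pseudo-residuals), fit every base-learner to the pseudo-residuals by
penalized least squares, update the fit by a fraction ``eta`` of the best
learner's fitted values, and repeat for ``m_stop`` iterations.  Selecting a
single learner per step yields variable selection; early stopping by
cross-validation controls overfitting.

Losses
------
The shipped loss is the binomial negative log-likelihood with a logit link
(pseudo-residuals u_i = y_i - 1/(1+exp(-f_i))).  A Gaussian (L2) mode
exists as a test hook so that single steps have closed-form least-squares
oracles; it is not exposed on the command line.

Selection rule
--------------
The winner of each iteration is the learner whose ridge fit has the
smallest sum of squared errors to the pseudo-residuals, the standard
model-based boosting convention; ties go to the learner listed first.

K-step boosting
---------------
``kstep_boost`` runs the algorithm K times in sequence, each stage with its
own base-learner set, initializing stage k at stage k-1's fitted function
(equivalently, continuing from its final pseudo-residual state).  With
main-effect learners in stage 1 and interaction learners in stage 2 this
prioritizes main effects over interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .base_learners import _RANK_RTOL

__all__ = [
    "BinomialLogitLoss",
    "GaussianLoss",
    "BoostConfig",
    "BoostFit",
    "KStep",
    "KStepConfig",
    "CVResult",
    "negative_gradient",
    "init_offset",
    "risk",
    "boost",
    "cv_mstop",
    "kstep_boost",
    "predict",
]


class BinomialLogitLoss:
    """Binomial negative log-likelihood under a logit link (stateless)."""

    name = "binomial"

    @staticmethod
    def probability(f: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-f))

    @staticmethod
    def negative_gradient(y: np.ndarray, f: np.ndarray) -> np.ndarray:
        return y - BinomialLogitLoss.probability(f)

    @staticmethod
    def risk(y: np.ndarray, f: np.ndarray) -> float:
        # sum_i log(1 + exp(f_i)) - y_i f_i, numerically stable
        return float(np.sum(np.logaddexp(0.0, f) - y * f))

    @staticmethod
    def offset(y: np.ndarray, mode: str = "logit-mean") -> float:
        if mode == "zero":
            return 0.0
        ybar = float(np.mean(y))
        if ybar <= 0.0 or ybar >= 1.0:
            raise ValueError("outcome has a single class; offset undefined")
        return float(np.log(ybar / (1.0 - ybar)))


class GaussianLoss:
    """Squared-error loss; test hook with closed-form one-step oracles."""

    name = "gaussian"

    @staticmethod
    def negative_gradient(y: np.ndarray, f: np.ndarray) -> np.ndarray:
        return y - f

    @staticmethod
    def risk(y: np.ndarray, f: np.ndarray) -> float:
        r = y - f
        return float(0.5 * (r @ r))

    @staticmethod
    def offset(y: np.ndarray, mode: str = "logit-mean") -> float:
        return 0.0 if mode == "zero" else float(np.mean(y))


_FAMILIES = {"binomial": BinomialLogitLoss, "gaussian": GaussianLoss}


def _loss(family: str):
    try:
        return _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown family {family!r}") from None


def negative_gradient(y: np.ndarray, f: np.ndarray, family: str = "binomial") -> np.ndarray:
    """Pseudo-residuals: the loss's negative gradient evaluated at f."""
    return _loss(family).negative_gradient(np.asarray(y, float), np.asarray(f, float))


def init_offset(y: np.ndarray, family: str = "binomial", mode: str = "logit-mean") -> float:
    """Loss-minimizing constant fit (log-odds of the prevalence for binomial)."""
    return _loss(family).offset(np.asarray(y, float), mode)


def risk(y: np.ndarray, f: np.ndarray, family: str = "binomial") -> float:
    """In-sample risk (summed negative log-likelihood) at linear predictor f."""
    return _loss(family).risk(np.asarray(y, float), np.asarray(f, float))


@dataclass
class BoostConfig:
    """Everything a boosting run needs besides the data."""

    learners: list
    eta: float = 0.1
    m_stop: int = 100
    cv_folds: int = 10
    cv_max: int = 1000
    seed: int = 0
    family: str = "binomial"
    offset_init: str = "logit-mean"
    design: object = None  # the DesignMatrix the learner columns refer to
    name: str = ""

    def __post_init__(self):
        if not (0.0 < self.eta < 1.0):
            raise ValueError("eta must lie in (0, 1)")
        if self.m_stop < 0:
            raise ValueError("m_stop must be >= 0")


@dataclass
class BoostFit:
    """The state of a completed boosting run."""

    offset: float
    f_init: np.ndarray  # prior stages' linear predictor, or None
    selection_path: list
    increments: list  # (term_id, raw coefficient vector) per step
    aggregated: np.ndarray  # per-column totals, eta included
    risk_path: np.ndarray  # length m_stop + 1; entry 0 is the offset risk
    fitted: np.ndarray
    eta: float
    family: str
    kinds: dict  # term_id -> learner kind
    cols: dict  # term_id -> column tuple

    @property
    def m_stop(self) -> int:
        return len(self.selection_path)

    @property
    def selected_terms(self) -> set:
        return set(self.selection_path)


@dataclass(frozen=True)
class KStep:
    """One stage of a K-step run: its learner set and iteration count.

    ``m_stop=None`` requests cross-validated early stopping for the stage.
    """

    learners: tuple
    m_stop: int = None

    def __post_init__(self):
        ids = [l.term_id for l in self.learners]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate learner ids within a step")


@dataclass
class KStepConfig:
    """Configuration of a K-step boosting run."""

    steps: list
    eta: float = 0.1
    cv_folds: int = 10
    cv_max: int = 1000
    seed: int = 0
    family: str = "binomial"
    offset_init: str = "logit-mean"
    design: object = None
    name: str = ""

    def __post_init__(self):
        if len(self.steps) < 1:
            raise ValueError("K-step config needs at least one step")


class _LearnerBank:
    """Per-row-subset fitting machinery for a fixed learner list.

    Single-column learners are fit in one vectorized pass; wider blocks get
    an eigendecomposition each.  Penalties come from the learners (they are
    calibrated once on the full design and held fixed); the grams are
    recomputed on the given rows.
    """

    def __init__(self, X: np.ndarray, learners):
        self.learners = list(learners)
        self.sel = [i for i, l in enumerate(self.learners) if not l.excluded]
        sel_learners = [self.learners[i] for i in self.sel]
        self.n_sel = len(sel_learners)
        single_pos = [j for j, l in enumerate(sel_learners) if l.width == 1]
        multi_pos = [j for j, l in enumerate(sel_learners) if l.width > 1]
        self.single_pos = np.asarray(single_pos, dtype=int)
        self.multi_pos = multi_pos
        if single_pos:
            cols = [sel_learners[j].cols[0] for j in single_pos]
            self.Xs = np.ascontiguousarray(X[:, cols])
            self.ds = np.einsum("ij,ij->j", self.Xs, self.Xs)
            self.lams = np.asarray([sel_learners[j].lam for j in single_pos])
            self.inv = 1.0 / (self.ds + self.lams)
        self.multis = []
        for j in multi_pos:
            l = sel_learners[j]
            Xb = np.ascontiguousarray(X[:, list(l.cols)])
            gram = Xb.T @ Xb
            d, V = np.linalg.eigh(gram)
            denom = d + l.lam
            inv = np.zeros_like(d)
            ok = denom > max(d.max(), 1.0) * _RANK_RTOL
            inv[ok] = 1.0 / denom[ok]
            self.multis.append((j, l, Xb, d, V, inv))
        self._sel_learners = sel_learners

    def best(self, u: np.ndarray):
        """Fit all selectable learners to u; return (learner, coef, fitted).

        The winner minimizes the SSE of its ridge fit to u.  Exact ties
        (e.g. two binary variables with identical crosstabs against the
        outcome) break toward the learner listed first; the comparison uses
        a 1e-9 relative tolerance so the tie-break does not depend on
        floating-point summation order.
        """
        uu = float(u @ u)
        sse = np.full(self.n_sel, np.inf)
        if self.single_pos.size:
            c = self.Xs.T @ u
            beta = c * self.inv
            sse[self.single_pos] = uu - 2.0 * beta * c + beta * beta * self.ds
        multi_cache = {}
        for j, l, Xb, d, V, inv in self.multis:
            z = V.T @ (Xb.T @ u)
            w = z * inv
            # SSE via the gram: ||u||^2 - 2 b'X'u + b'X'Xb with b = V w
            sse[j] = uu - 2.0 * float(z @ w) + float((w * w) @ d)
            multi_cache[j] = (Xb, V, w)
        tol = 1e-9 * max(uu, 1e-300)
        jbest = int(np.flatnonzero(sse <= sse.min() + tol)[0])
        learner = self._sel_learners[jbest]
        if learner.width == 1:
            k = int(np.searchsorted(self.single_pos, jbest))
            c_j = float(self.Xs[:, k] @ u)
            b = c_j * self.inv[k]
            coef = np.array([b])
            fitted = self.Xs[:, k] * b
        else:
            Xb, V, w = multi_cache[jbest]
            coef = V @ w
            fitted = Xb @ coef
        return learner, coef, fitted


def _run_path(
    X: np.ndarray,
    y: np.ndarray,
    learners,
    eta: float,
    m_stop: int,
    family: str,
    f0: np.ndarray,
    X_eval: np.ndarray = None,
    f0_eval: np.ndarray = None,
    y_eval: np.ndarray = None,
):
    """Core boosting loop on given rows; optionally tracks held-out risk."""
    loss = _loss(family)
    bank = _LearnerBank(X, learners)
    f = f0.copy()
    track_eval = X_eval is not None
    if track_eval:
        f_eval = f0_eval.copy()
        n_eval = len(y_eval)
        eval_risk = np.empty(m_stop + 1)
        eval_risk[0] = loss.risk(y_eval, f_eval) / n_eval
    path, increments = [], []
    aggregated = np.zeros(X.shape[1])
    risk_path = np.empty(m_stop + 1)
    risk_path[0] = loss.risk(y, f)
    if bank.n_sel == 0:
        if m_stop > 0:
            warnings.warn("all base-learners excluded; returning offset-only fit")
        m_stop = 0
        risk_path = risk_path[:1]
        if track_eval:
            eval_risk = eval_risk[:1]
    for m in range(1, m_stop + 1):
        u = loss.negative_gradient(y, f)
        learner, coef, fitted = bank.best(u)
        f += eta * fitted
        idx = np.asarray(learner.cols)
        aggregated[idx] += eta * coef
        path.append(learner.term_id)
        increments.append((learner.term_id, coef))
        risk_path[m] = loss.risk(y, f)
        if track_eval:
            f_eval += eta * (X_eval[:, idx] @ coef)
            eval_risk[m] = loss.risk(y_eval, f_eval) / n_eval
    out = (path, increments, aggregated, risk_path, f)
    if track_eval:
        return out + (eval_risk, f_eval)
    return out + (None,)


def boost(design, y, config: BoostConfig, f_init: np.ndarray = None, m_stop: int = None) -> BoostFit:
    """Run component-wise boosting on a design matrix.

    ``f_init`` continues from an existing linear predictor (used by K-step
    boosting); in that case the offset is carried by the prior stage and
    this fit's own offset is zero.
    """
    y = np.asarray(y, dtype=float)
    X = design.values
    if m_stop is None:
        m_stop = config.m_stop
    if f_init is None:
        offset = init_offset(y, config.family, config.offset_init)
        f0 = np.full(len(y), offset)
        f_init_stored = None
    else:
        offset = 0.0
        f0 = np.asarray(f_init, dtype=float)
        f_init_stored = f0.copy()
    path, increments, aggregated, risk_path, fitted, _ = _run_path(
        X, y, config.learners, config.eta, m_stop, config.family, f0
    )
    return BoostFit(
        offset=offset,
        f_init=f_init_stored,
        selection_path=path,
        increments=increments,
        aggregated=aggregated,
        risk_path=risk_path,
        fitted=fitted,
        eta=config.eta,
        family=config.family,
        kinds={l.term_id: l.kind for l in config.learners},
        cols={l.term_id: l.cols for l in config.learners},
    )


@dataclass
class CVResult:
    """Cross-validated stopping iteration and the mean out-of-fold risk curve."""

    mstop: int
    risk: np.ndarray  # mean out-of-fold risk per observation, length cv_max+1
    folds: int

    def __int__(self) -> int:
        return self.mstop


def _stratified_folds(y: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def cv_mstop(design, y, config: BoostConfig, folds: int = None, f_init: np.ndarray = None) -> CVResult:
    """Cross-validated early stopping.

    Fits on each training partition, evaluates the out-of-fold risk (mean
    negative log-likelihood per observation) after every iteration up to
    ``config.cv_max``, and returns the iteration minimizing the fold-mean
    risk, ties broken toward the smallest m.  Folds are stratified by the
    outcome and drawn from ``config.seed``.
    """
    y = np.asarray(y, dtype=float)
    folds = folds if folds is not None else config.cv_folds
    if folds < 2:
        raise ValueError("need at least 2 folds")
    X = design.values
    M = config.cv_max
    if config.family == "binomial":
        splits = _stratified_folds(y, folds, config.seed)
        for tr, _ in splits:
            if len(np.unique(y[tr])) < 2:
                raise ValueError("a training fold contains a single class")
    else:
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(len(y))
        splits = [
            (np.delete(perm, s), perm[s])
            for s in np.array_split(np.arange(len(y)), folds)
        ]
    curves = np.empty((len(splits), M + 1))
    for i, (tr, te) in enumerate(splits):
        if f_init is None:
            offset = init_offset(y[tr], config.family, config.offset_init)
            f0_tr = np.full(len(tr), offset)
            f0_te = np.full(len(te), offset)
        else:
            f0_tr = np.asarray(f_init, float)[tr]
            f0_te = np.asarray(f_init, float)[te]
        *_, eval_risk, _f_eval = _run_path(
            X[tr], y[tr], config.learners, config.eta, M, config.family,
            f0_tr, X_eval=X[te], f0_eval=f0_te, y_eval=y[te],
        )
        if len(eval_risk) < M + 1:  # all learners excluded
            eval_risk = np.concatenate([eval_risk, np.full(M + 1 - len(eval_risk), eval_risk[-1])])
        curves[i] = eval_risk
    mean_risk = curves.mean(axis=0)
    mstop = int(np.argmin(mean_risk))  # argmin takes the first (smallest m)
    return CVResult(mstop=mstop, risk=mean_risk, folds=len(splits))


def kstep_boost(design, y, ksteps: KStepConfig) -> list:
    """Sequential K-step boosting; returns one BoostFit per stage.

    Stage 1 runs the plain algorithm; stage k > 1 starts at stage (k-1)'s
    fitted function and may only select from its own learner set.  A stage
    with ``m_stop=None`` picks its iteration count by cross-validation.

    The final model fits each stage once on the full data, each continuing
    from the previous stage's fit.  Inside the cross-validation, however,
    every fold re-runs the *earlier* stages on its own training rows before
    evaluating the current stage's out-of-fold risk; without this the
    earlier stages would have seen the held-out rows and the fold baseline
    would be optimistic, biasing later stages' stopping toward zero.
    """
    y = np.asarray(y, dtype=float)
    X = design.values
    loss = _loss(ksteps.family)
    needs_cv = any(s.m_stop is None for s in ksteps.steps)
    fold_state = None
    if needs_cv:
        if ksteps.family == "binomial":
            splits = _stratified_folds(y, ksteps.cv_folds, ksteps.seed)
        else:
            rng = np.random.default_rng(ksteps.seed)
            perm = rng.permutation(len(y))
            splits = [
                (np.delete(perm, s), perm[s])
                for s in np.array_split(np.arange(len(y)), ksteps.cv_folds)
            ]
        fold_state = []
        for tr, te in splits:
            offset = loss.offset(y[tr], ksteps.offset_init)
            fold_state.append(
                [tr, te, np.full(len(tr), offset), np.full(len(te), offset)]
            )

    fits = []
    f_cur = None
    n_steps = len(ksteps.steps)
    for k, step in enumerate(ksteps.steps):
        cfg = BoostConfig(
            learners=list(step.learners),
            eta=ksteps.eta,
            m_stop=step.m_stop if step.m_stop is not None else 0,
            cv_folds=ksteps.cv_folds,
            cv_max=ksteps.cv_max,
            seed=ksteps.seed,
            family=ksteps.family,
            offset_init=ksteps.offset_init,
            design=ksteps.design if ksteps.design is not None else design,
        )
        m = step.m_stop
        if m is None:
            M = ksteps.cv_max
            curves = np.empty((len(fold_state), M + 1))
            for i, (tr, te, f_tr, f_te) in enumerate(fold_state):
                *_, eval_risk, _ = _run_path(
                    X[tr], y[tr], cfg.learners, cfg.eta, M, cfg.family,
                    f_tr, X_eval=X[te], f0_eval=f_te, y_eval=y[te],
                )
                if len(eval_risk) < M + 1:
                    eval_risk = np.concatenate(
                        [eval_risk, np.full(M + 1 - len(eval_risk), eval_risk[-1])]
                    )
                curves[i] = eval_risk
            m = int(np.argmin(curves.mean(axis=0)))
        # advance the fold states through this stage for later stages' CV
        if fold_state is not None and k < n_steps - 1:
            for state in fold_state:
                tr, te, f_tr, f_te = state
                *_, f_tr_new, _, f_te_new = _run_path(
                    X[tr], y[tr], cfg.learners, cfg.eta, m, cfg.family,
                    f_tr, X_eval=X[te], f0_eval=f_te, y_eval=y[te],
                )
                state[2], state[3] = f_tr_new, f_te_new
        fit = boost(design, y, cfg, f_init=f_cur, m_stop=m)
        fits.append(fit)
        f_cur = fit.fitted
    return fits


def predict(fit_or_fits, X_new: np.ndarray, scale: str = "response") -> np.ndarray:
    """Predictions for new design rows on the link or response scale.

    Accepts a single fit or the list returned by :func:`kstep_boost`; stage
    contributions are summed.  ``X_new`` must come from the same design
    (use ``DesignMatrix.transform`` on raw data).
    """
    fits = fit_or_fits if isinstance(fit_or_fits, (list, tuple)) else [fit_or_fits]
    if fits[0].f_init is not None:
        raise ValueError(
            "the first fit is a continuation; predict from the full stage list"
        )
    X_new = np.asarray(X_new, dtype=float)
    p = len(fits[0].aggregated)
    if X_new.ndim != 2 or X_new.shape[1] != p:
        raise ValueError(f"expected {p} design columns, got {X_new.shape}")
    f = np.full(X_new.shape[0], fits[0].offset)
    for fit in fits:
        if len(fit.aggregated) != p:
            raise ValueError("stage fits refer to different designs")
        f = f + X_new @ fit.aggregated
    if scale == "link":
        return f
    if scale == "response":
        family = fits[-1].family
        if family == "gaussian":
            return f
        return BinomialLogitLoss.probability(f)
    raise ValueError("scale must be 'link' or 'response'")
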