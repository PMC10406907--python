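"""Interpretation tools for boosted fits.

Variable importance
    Each boosting iteration reduces the in-sample negative log-likelihood;
    the reduction is credited to the base-learner selected in that step.
    Summed per learner and expressed as a percentage of the total
    reduction, this compares the relative importance of terms of any kind
    (individual, group, interaction) on one scale.  For K-step fits the
    stages are concatenated into one table, with the percentage taken
    relative to the combined reduction and a per-stage breakdown retained.

Aggregated effects
    A term's total coefficient is the learning rate times the sum of its
    per-step coefficient increments; exponentiating gives an odds ratio per
    design column (contrast against the reference category).

Partial effects
    Predicted probabilities for the categories of one term with every other
    term's contribution held at its training mean (on the link scale).

Interaction profiles
    A standalone logistic regression with both main effects and their
    interaction — one interaction term at a time, optionally per stratum —
    giving the fitted outcome probability for each joint category.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import DesignError, _encode, _product_block
from .engine import BinomialLogitLoss

__all__ = [
    "variable_importance",
    "aggregated_effects",
    "partial_effect",
    "interaction_profile",
]


def _as_fit_list(fit_or_fits) -> list:
    return list(fit_or_fits) if isinstance(fit_or_fits, (list, tuple)) else [fit_or_fits]


def variable_importance(fit_or_fits) -> pd.DataFrame:
    """Per-term risk reduction and its percentage of the total.

    Columns: ``term``, ``kind``, ``step`` (stage index, 1-based),
    ``reduction`` (absolute negative log-likelihood reduction) and
    ``percent``.  The reductions sum to the difference between the first
    and last entries of the (concatenated) risk path by construction.
    """
    fits = _as_fit_list(fit_or_fits)
    rows: dict = {}
    total = 0.0
    for stage, fit in enumerate(fits, start=1):
        drops = -np.diff(fit.risk_path)
        total += float(fit.risk_path[0] - fit.risk_path[-1])
        for term, drop in zip(fit.selection_path, drops):
            key = (term, stage)
            if key not in rows:
                rows[key] = {
                    "term": term,
                    "kind": fit.kinds.get(term, "individual"),
                    "step": stage,
                    "reduction": 0.0,
                }
            rows[key]["reduction"] += float(drop)
    table = pd.DataFrame(list(rows.values()),
                         columns=["term", "kind", "step", "reduction"])
    if len(table) and total > 0:
        table["percent"] = 100.0 * table["reduction"] / total
    else:
        if len(table):
            warnings.warn("total risk reduction is zero; percentages set to 0")
        table["percent"] = 0.0
    return table.sort_values("reduction", ascending=False, kind="stable").reset_index(drop=True)


def aggregated_effects(fit_or_fits, design) -> pd.DataFrame:
    """Total coefficient and odds ratio per term and design column.

    The total coefficient of a column is eta times the sum of that column's
    increments over the steps in which its term was selected; a term never
    selected has coefficient 0 and odds ratio 1.
    """
    fits = _as_fit_list(fit_or_fits)
    totals: dict = {}
    kinds: dict = {}
    for fit in fits:
        for term, cols in fit.cols.items():
            totals.setdefault(term, np.zeros(len(cols)))
            kinds.setdefault(term, fit.kinds.get(term, "individual"))
        for term, coef in fit.increments:
            totals[term] = totals[term] + fit.eta * coef
    rows = []
    for term, coef in totals.items():
        cols = None
        for fit in fits:
            if term in fit.cols:
                cols = fit.cols[term]
                break
        for c, beta in zip(cols, coef):
            rows.append(
                {
                    "term": term,
                    "column": design.column_names[c],
                    "kind": kinds[term],
                    "coefficient": float(beta),
                    "odds_ratio": float(np.exp(beta)),
                }
            )
    return pd.DataFrame(rows, columns=["term", "column", "kind", "coefficient", "odds_ratio"])


def _term_categories(design, term_id):
    """Category labels and uncentered code rows for one term's columns."""
    block = design.block(term_id)
    if block.kind == "main":
        spec = design.variable(block.sources[0])
        if spec.var_type == "continuous":
            raise DesignError(
                f"partial effects need categorical terms; {term_id!r} is continuous"
            )
        labels = list(spec.categories)
        codes = np.vstack([np.zeros(spec.width)] + list(np.eye(spec.width)))
        return labels, codes
    mod, partner = block.sources
    sm_, sp_ = design.variable(mod), design.variable(partner)
    labels, codes = [], []
    eye_m = np.vstack([np.zeros(sm_.width)] + list(np.eye(sm_.width)))
    eye_p = np.vstack([np.zeros(sp_.width)] + list(np.eye(sp_.width)))
    for i, cm in enumerate(sm_.categories):
        for j, cp in enumerate(sp_.categories):
            labels.append(f"{cm} x {cp}")
            codes.append(_product_block(eye_m[i][None, :], eye_p[j][None, :])[0])
    return labels, np.vstack(codes)


def partial_effect(fit_or_fits, design, term_id: str) -> pd.DataFrame:
    """Predicted probability per category of one term, others at average.

    "Average" means each other term's mean training contribution on the
    link scale (zero for centered columns), so an offset-only model yields
    a flat profile at the training prevalence.
    """
    fits = _as_fit_list(fit_or_fits)
    if fits[0].f_init is not None:
        raise ValueError("pass the full stage list for a K-step fit")
    block = design.block(term_id)
    idx = np.asarray(block.cols)
    agg = np.sum([f.aggregated for f in fits], axis=0)
    # mean contribution of every term; centered columns make these ~0,
    # computed explicitly so the identity is robust to design changes
    others = [b for b in design.blocks if b.term_id != term_id]
    base = fits[0].offset
    for b in others:
        j = np.asarray(b.cols)
        base += float(np.mean(design.values[:, j] @ agg[j]))
    labels, codes = _term_categories(design, term_id)
    link = base + (codes - design.column_means[idx]) @ agg[idx]
    return pd.DataFrame(
        {
            "term": term_id,
            "category": labels,
            "link": link,
            "probability": BinomialLogitLoss.probability(link),
        }
    )


def interaction_profile(
    data: pd.DataFrame,
    y,
    moderator: str,
    partner: str,
    dictionary,
    stratify_by: str = None,
) -> pd.DataFrame:
    """Fitted probability per joint category from a one-interaction logistic fit.

    For each stratum (the whole data, plus each level of ``stratify_by``
    when given), fits a standalone logistic regression with both variables'
    main effects and their interaction — saturated for two categorical
    variables — and returns the fitted probability of y = 1 for every joint
    category.  Joint cells with no observations in a stratum are flagged
    (``n = 0``) and their probability left missing.
    """
    y = np.asarray(y, dtype=float)
    specs = {s.name: s for s in dictionary}
    for name in (moderator, partner):
        if name not in specs:
            raise DesignError(f"unknown variable {name!r}")
        if specs[name].var_type == "continuous":
            raise DesignError(f"{name!r} is continuous; profiles need categories")
    sm_spec, sp_spec = specs[moderator], specs[partner]

    strata = [("all", np.ones(len(data), dtype=bool))]
    if stratify_by is not None:
        col = data[stratify_by].astype(str)
        for level in pd.unique(col):
            strata.append((level, (col == level).to_numpy()))

    rows = []
    for label, mask in strata:
        sub = data.loc[mask]
        ysub = y[mask]
        mc = _encode(sm_spec, sub)
        pc = _encode(sp_spec, sub)
        X = np.column_stack(
            [np.ones(len(sub)), mc, pc, _product_block(mc, pc)]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(ysub, X, family=sm.families.Binomial()).fit(
                maxiter=200, tol=1e-10
            )
        eye_m = np.vstack([np.zeros(sm_spec.width)] + list(np.eye(sm_spec.width)))
        eye_p = np.vstack([np.zeros(sp_spec.width)] + list(np.eye(sp_spec.width)))
        marr = sub[moderator].astype(str).to_numpy()
        parr = sub[partner].astype(str).to_numpy()
        for i, cm in enumerate(sm_spec.categories):
            for j, cp in enumerate(sp_spec.categories):
                n_cell = int(np.sum((marr == cm) & (parr == cp)))
                if n_cell == 0:
                    prob = np.nan
                else:
                    x = np.concatenate(
                        [[1.0], eye_m[i], eye_p[j],
                         _product_block(eye_m[i][None, :], eye_p[j][None, :])[0]]
                    )
                    prob = float(res.predict(x[None, :])[0])
                rows.append(
                    {
                        "stratum": label,
                        moderator: cm,
                        partner: cp,
                        "n": n_cell,
                        "probability": prob,
                    }
                )
    return pd.DataFrame(rows)


def plot_importance(table: pd.DataFrame, ax=None, max_terms: int = 15,
                    min_percent: float = 1.0):
    """Horizontal importance bars (display rule: top terms above a cutoff)."""
    import matplotlib.pyplot as plt  # optional dependency

    shown = table[table["percent"] >= min_percent].head(max_terms)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * max(len(shown), 1) + 1))
    ax.barh(shown["term"][::-1], shown["percent"][::-1])
    ax.set_xlabel("share of risk reduction (%)")
    return ax
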