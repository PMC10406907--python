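"""Synthetic survey-like data with planted main and interaction effects.

Emulates the statistical structure the analysis pipeline assumes: a few
hundred observations of mostly binary variables organized into named
groups, a handful of multi-category variables (a four-region geography, a
three-level norms item), a subset of variables flagged as moderators, and a
binary outcome generated from a logistic model with known (planted) main
and interaction coefficients.  The planted truth is returned alongside the
data so recovery can be tested end to end.

Covariates are drawn independently of each other by default; an optional
within-group correlation knob (latent Gaussian thresholding) emulates
group-level latent variables.  Effects are defined on the same uncentered
reference coding the design-matrix builder uses, so a coefficient here is
directly comparable to a fitted aggregated coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import VariableSpec

__all__ = [
    "SyntheticVariable",
    "SyntheticSpec",
    "generate",
    "paper_like_spec",
    "mains_recovery_spec",
    "interaction_recovery_spec",
]


@dataclass(frozen=True)
class SyntheticVariable:
    """A variable declaration plus its category sampling probabilities."""

    spec: VariableSpec
    probs: tuple

    def __post_init__(self):
        probs = tuple(float(p) for p in self.probs)
        object.__setattr__(self, "probs", probs)
        if self.spec.var_type == "continuous":
            raise ValueError("the generator draws categorical variables only")
        if len(probs) != len(self.spec.categories):
            raise ValueError(
                f"{self.spec.name!r}: {len(probs)} probabilities for "
                f"{len(self.spec.categories)} categories"
            )
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"{self.spec.name!r}: probabilities must sum to 1")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of one synthetic dataset.

    ``main_effects`` maps a variable name to its coefficient(s) on the
    non-reference categories; ``interaction_effects`` maps a (moderator,
    partner) pair to a w_mod x w_partner coefficient matrix (scalars are
    accepted for binary x binary).  ``group_correlation`` in [0, 1) induces
    within-group dependence through a shared latent Gaussian factor.
    """

    n: int
    variables: tuple
    intercept: float = 0.0
    main_effects: dict = field(default_factory=dict)
    interaction_effects: dict = field(default_factory=dict)
    seed: int = 0
    outcome_name: str = "y"
    group_correlation: float = 0.0

    def __post_init__(self):
        names = {v.spec.name for v in self.variables}
        for name in self.main_effects:
            if name not in names:
                raise ValueError(f"main effect on undeclared variable {name!r}")
        for m, v in self.interaction_effects:
            if m not in names or v not in names:
                raise ValueError(f"interaction effect on undeclared pair ({m!r}, {v!r})")
        if not (0.0 <= self.group_correlation < 1.0):
            raise ValueError("group_correlation must lie in [0, 1)")

    @property
    def dictionary(self) -> list:
        return [v.spec for v in self.variables]

    def with_effects(self, intercept: float, main_effects: dict,
                     interaction_effects: dict) -> "SyntheticSpec":
        """Same variables and sampling, different planted effects."""
        return replace(
            self,
            intercept=intercept,
            main_effects=dict(main_effects),
            interaction_effects=dict(interaction_effects),
        )


def _codes(var: SyntheticVariable, drawn: np.ndarray) -> np.ndarray:
    """Uncentered reference codes (n x width) for drawn category labels."""
    cats = var.spec.categories
    return np.column_stack([(drawn == c).astype(float) for c in cats[1:]])


def _draw_correlated(rng, var_list, rho: float, n: int) -> dict:
    """Within-group dependent draws via a shared latent Gaussian factor."""
    out = {}
    by_group: dict = {}
    for v in var_list:
        by_group.setdefault(v.spec.group, []).append(v)
    for group, members in by_group.items():
        factor = rng.standard_normal(n)
        for v in members:
            z = np.sqrt(rho) * factor + np.sqrt(1 - rho) * rng.standard_normal(n)
            # threshold the latent normal at the category quantiles
            cum = np.cumsum(v.probs)[:-1]
            edges = norm.ppf(cum)
            idx = np.searchsorted(edges, z)
            out[v.spec.name] = np.asarray(v.spec.categories)[idx]
    return out


def generate(spec: SyntheticSpec):
    """Draw one dataset: (data frame incl. outcome, dictionary, truth record).

    Covariates are sampled per declared category probabilities; the outcome
    is Bernoulli with logit equal to the planted linear predictor.  The
    truth record stores the exact per-row linear predictor.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if spec.group_correlation > 0.0:
        drawn = _draw_correlated(rng, spec.variables, spec.group_correlation, n)
    else:
        drawn = {
            v.spec.name: rng.choice(v.spec.categories, size=n, p=v.probs)
            for v in spec.variables
        }
    eta = np.full(n, float(spec.intercept))
    codes = {name: _codes(v, drawn[name])
             for name, v in ((v.spec.name, v) for v in spec.variables)}
    for name, coef in spec.main_effects.items():
        coef = np.atleast_1d(np.asarray(coef, dtype=float))
        eta += codes[name] @ coef
    for (m, v), coef in spec.interaction_effects.items():
        cm, cv = codes[m], codes[v]
        coef = np.asarray(coef, dtype=float).reshape(cm.shape[1], cv.shape[1])
        eta += np.einsum("ni,ij,nj->n", cm, coef, cv)
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = rng.binomial(1, prob)
    data = pd.DataFrame({v.spec.name: drawn[v.spec.name] for v in spec.variables})
    data[spec.outcome_name] = y
    truth = {
        "linear_predictor": eta,
        "probability": prob,
        "intercept": spec.intercept,
        "main_effects": {k: np.atleast_1d(v).tolist()
                         for k, v in spec.main_effects.items()},
        "interaction_effects": {f"{m}:{v}": np.asarray(c, dtype=float).tolist()
                                for (m, v), c in spec.interaction_effects.items()},
        "seed": spec.seed,
        "n": n,
    }
    return data, spec.dictionary, truth


# ---------------------------------------------------------------------------
# Survey-like default specification
# ---------------------------------------------------------------------------

# observed category shares of the kind seen in farmer surveys (count / 801)
_PREVALENCE_POOL = [
    647, 464, 138, 231, 283, 318, 508, 571, 721, 629, 659, 671, 542, 137,
    358, 346, 148, 96, 528, 203, 490, 635, 460, 466, 320, 258, 446, 470,
    648, 676, 685, 755, 438, 121, 459, 577, 399, 437, 95, 161, 415, 219,
    319, 166, 313, 192, 97, 174, 291, 329, 241, 433, 268, 215, 184, 312,
    351, 317, 360, 643, 673, 592,
]

# group -> (number of binary variables at full scale, moderators at full scale)
_GROUPS = {
    "climate_experience": (4, 4),
    "biophysical": (9, 4),
    "economic": (6, 2),
    "goals": (4, 1),
    "harm": (5, 1),
    "human": (12, 3),
    "social": (30, 6),
    "spatial": (3, 0),
}

_REGIONS = ("CentralChile", "CentralTunisia", "NorthernTunisia", "SouthernChile")
_REGION_PROBS = (200 / 801, 200 / 801, 201 / 801, 200 / 801)
_NORMS_PROBS = (424 / 801, 151 / 801, 226 / 801)


def _binary(name, group, prev, moderator=False) -> SyntheticVariable:
    return SyntheticVariable(
        spec=VariableSpec(name=name, var_type="binary",
                          categories=("no", "yes"), group=group,
                          is_moderator=moderator),
        probs=(1.0 - prev, prev),
    )


def paper_like_spec(scale: float = 1.0, seed: int = 0) -> SyntheticSpec:
    """Survey-scale synthetic specification.

    At scale 1: n = 801 observations, 75 variables in 10 named groups
    (one four-region geography variable, one three-level norms item, the
    rest binary with realistic survey prevalences), 22 moderators, and
    planted effects comprising region main effects, one economic main
    effect and two region x goal interactions.  Smaller scales shrink the
    observation count, the per-group variable counts and the moderator
    count proportionally.
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must lie in (0, 1]")
    n = max(40, round(801 * scale))
    variables = [
        SyntheticVariable(
            spec=VariableSpec("natural_assets", "categorical", _REGIONS,
                              group="natural", is_moderator=True),
            probs=_REGION_PROBS,
        )
    ]
    pool = iter(_PREVALENCE_POOL * 10)
    for group, (count, n_mod) in _GROUPS.items():
        k = max(1, round(count * scale))
        k_mod = min(k, round(n_mod * scale))
        for i in range(k):
            prev = next(pool) / 801
            variables.append(
                _binary(f"{group}_{i + 1}", group, prev, moderator=i < k_mod)
            )
    variables.append(
        SyntheticVariable(
            spec=VariableSpec("norms_1", "categorical", ("1", "2", "3"),
                              group="norms", is_moderator=False),
            probs=_NORMS_PROBS,
        )
    )
    declared = {v.spec.name for v in variables}
    # planted effects, restricted to the variables present at this scale
    main_effects = {
        name: coef
        for name, coef in {
            "natural_assets": [1.9, -1.6, 1.15],
            "economic_1": [1.4],
            "biophysical_3": [-1.2],
            "spatial_1": [1.0],
        }.items()
        if name in declared
    }
    interaction_effects = {
        pair: coef
        for pair, coef in {
            ("natural_assets", "goals_1"): [[1.4], [-1.2], [1.0]],
            ("natural_assets", "goals_2"): [[-1.3], [1.1], [-0.9]],
        }.items()
        if pair[0] in declared and pair[1] in declared
    }
    return SyntheticSpec(
        n=n,
        variables=tuple(variables),
        intercept=float(np.log(358 / 443)),  # prevalence anchor 358/801
        main_effects=main_effects,
        interaction_effects=interaction_effects,
        seed=seed,
    )


def mains_recovery_spec(seed: int = 0, scale: float = 1.0) -> SyntheticSpec:
    """Survey-scale variables with three strong main effects and no interactions."""
    base = paper_like_spec(scale=scale, seed=seed)
    return base.with_effects(
        intercept=float(np.log(358 / 443)),
        main_effects={
            "economic_1": [1.2],
            "biophysical_1": [-1.1],
            "goals_1": [1.0],
        },
        interaction_effects={},
    )


def interaction_recovery_spec(seed: int = 0, scale: float = 1.0) -> SyntheticSpec:
    """Survey-scale variables with one strong planted interaction plus two mains.

    The planted pair (a moderator x partner product of two binaries) is the
    target a two-step interaction search should find; the two main effects
    give the first stage something real to select.
    """
    base = paper_like_spec(scale=scale, seed=seed)
    return base.with_effects(
        intercept=float(np.log(358 / 443)),
        main_effects={
            "economic_1": [1.0],
            "goals_1": [-1.0],
        },
        interaction_effects={("climate_experience_1", "spatial_1"): [[1.8]]},
    )
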