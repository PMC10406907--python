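"""Preset model builders over the boosting engine.

Four named configurations:

``mb``
    Component-wise boosting with one ridge base-learner per variable, every
    learner calibrated to one effective degree of freedom.
``mb int``
    Main-effect and interaction base-learners offered in parallel in every
    iteration (all df 1); the selection step decides between them.
``sgb``
    Sparse group boosting: each variable gets an individual learner with
    df = alpha / p_g and each group of p_g variables gets one learner over
    the union of its columns with df = (1 - alpha) / p_g.  alpha = 1
    recovers component-wise boosting, alpha = 0 pure group boosting.
``2-boost``
    Two-step boosting: stage 1 is the mb learner set, stage 2 offers only
    interaction learners and continues from the stage-1 fit, so main
    effects are prioritized over interactions.
"""

from __future__ import annotations

from .base_learners import RidgeBaseLearner
from .data_model import DesignMatrix, extend_design
from .engine import BoostConfig, KStep, KStepConfig

__all__ = [
    "SGBSpec",
    "make_mb",
    "make_mb_int",
    "make_sgb",
    "make_2boost",
    "MODEL_NAMES",
]

MODEL_NAMES = ("mb", "mb-int", "sgb", "2boost")


def _main_blocks(design: DesignMatrix):
    return [b for b in design.blocks if b.kind == "main"]


def _interaction_blocks(design: DesignMatrix):
    return [b for b in design.blocks if b.kind == "interaction"]


def make_mb(design: DesignMatrix, *, eta: float = 0.1, **kw) -> BoostConfig:
    """Component-wise boosting: one df-1 learner per main-effect block."""
    learners = [
        RidgeBaseLearner.from_block(design, b, target_df=1.0, kind="individual")
        for b in _main_blocks(design)
    ]
    return BoostConfig(learners=learners, eta=eta, design=design, name="mb", **kw)


def make_mb_int(design: DesignMatrix, interactions=None, *, eta: float = 0.1, **kw) -> BoostConfig:
    """Parallel main + interaction boosting, all learners at df 1.

    ``interactions`` is the list built by
    :func:`cwboost.data_model.build_interactions`; alternatively pass a
    design already extended with interaction blocks.  The design actually
    used is carried on the returned config.
    """
    if interactions is not None:
        design = extend_design(design, interactions)
    learners = [
        RidgeBaseLearner.from_block(
            design, b, target_df=1.0,
            kind="individual" if b.kind == "main" else "interaction",
        )
        for b in design.blocks
    ]
    return BoostConfig(learners=learners, eta=eta, design=design, name="mb-int", **kw)


class SGBSpec:
    """Grouping and mixing parameter for sparse group boosting.

    ``groups`` maps a group label to its member variable names; variables
    outside any declared group form singleton groups.  ``p_g`` counts
    member variables, not expanded columns.
    """

    def __init__(self, alpha: float = 0.5, groups: dict = None):
        if not (0.0 <= alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        self.alpha = float(alpha)
        self.groups = dict(groups) if groups else None

    @classmethod
    def from_dictionary(cls, dictionary, alpha: float = 0.5) -> "SGBSpec":
        groups: dict = {}
        for spec in dictionary:
            groups.setdefault(spec.group, []).append(spec.name)
        return cls(alpha=alpha, groups=groups)


def make_sgb(
    design: DesignMatrix,
    spec: SGBSpec = None,
    *,
    alpha: float = 0.5,
    eta: float = 0.1,
    df_variant: str = "pg-scaled",
    **kw,
) -> BoostConfig:
    """Sparse group boosting learners over a main-effects design.

    Per group g with p_g member variables: one learner per member with
    target df alpha / p_g, plus one group learner over the union of the
    members' columns with target df (1 - alpha) / p_g.  Learners with
    target df 0 are excluded (never selectable), so alpha = 1 drops all
    group learners and alpha = 0 drops all individual learners.

    ``df_variant="unscaled-group"`` uses (individual alpha / p_g, group
    1 - alpha) instead, for comparison with the unnormalized convention.
    """
    if spec is None:
        spec = SGBSpec.from_dictionary(design.dictionary, alpha=alpha)
    if df_variant not in ("pg-scaled", "unscaled-group"):
        raise ValueError(f"unknown df variant {df_variant!r}")
    a = spec.alpha
    declared = {v for members in spec.groups.values() for v in members}
    groups = dict(spec.groups)
    for b in _main_blocks(design):
        if b.term_id not in declared:
            groups[b.term_id] = [b.term_id]
    p_g = {g: len(members) for g, members in groups.items()}
    group_of = {v: g for g, members in groups.items() for v in members}
    # individual learners in dictionary (block) order, then group learners
    learners = []
    for b in _main_blocks(design):
        g = group_of[b.term_id]
        learners.append(
            RidgeBaseLearner.from_block(
                design, b, target_df=a / p_g[g], kind="individual"
            )
        )
    for g, members in groups.items():
        cols = tuple(
            c for v in members for c in design.block(v).cols
        )
        df_group = (1.0 - a) / p_g[g] if df_variant == "pg-scaled" else (1.0 - a)
        learners.append(
            RidgeBaseLearner.from_columns(
                design, term_id=f"group:{g}", cols=cols,
                target_df=df_group, kind="group",
            )
        )
    return BoostConfig(learners=learners, eta=eta, design=design, name="sgb", **kw)


def make_2boost(
    design: DesignMatrix,
    interactions=None,
    *,
    eta: float = 0.1,
    m1: int = None,
    m2: int = None,
    cv_folds: int = 10,
    cv_max: int = 1000,
    seed: int = 0,
    **kw,
) -> KStepConfig:
    """Two-step boosting: main effects first, interactions second.

    Stage 1 uses the mb learner set; stage 2 offers only interaction
    learners (df 1) and continues from the stage-1 fit.  ``m1``/``m2`` of
    ``None`` request cross-validated early stopping for that stage; the
    stage-1 model is fitted once and reused.
    """
    if interactions is not None:
        design = extend_design(design, interactions)
    mains = [
        RidgeBaseLearner.from_block(design, b, target_df=1.0, kind="individual")
        for b in _main_blocks(design)
    ]
    inters = [
        RidgeBaseLearner.from_block(design, b, target_df=1.0, kind="interaction")
        for b in _interaction_blocks(design)
    ]
    if not inters:
        raise ValueError("2-boost needs interaction blocks in the design")
    return KStepConfig(
        steps=[KStep(tuple(mains), m1), KStep(tuple(inters), m2)],
        eta=eta,
        cv_folds=cv_folds,
        cv_max=cv_max,
        seed=seed,
        design=design,
        name="2boost",
        **kw,
    )
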