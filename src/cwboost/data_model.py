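"""Dictionary-driven design matrices for grouped tabular survey data.

Variables are declared in a data dictionary: each entry names the variable,
its type (binary, categorical or continuous), its ordered category labels,
the group it belongs to, and whether it may act as a moderator (i.e. form
interaction terms with other variables).

Coding conventions
------------------
* Binary / categorical variables are reference-coded: the first listed
  category is the reference and a variable with ``c`` categories becomes a
  block of ``c - 1`` indicator columns.  Continuous variables enter as a
  single column.
* Every design column is centered on the training rows; the centering
  constants are stored so that new data can be mapped into the identical
  column space (no re-centering on test rows).
* An interaction block is the elementwise product of the two parents'
  *uncentered* indicator columns, centered after the product.  Its width is
  the product of the parents' block widths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "VariableSpec",
    "Block",
    "DesignMatrix",
    "InteractionTerm",
    "read_dictionary",
    "write_dictionary",
    "build_design",
    "build_interactions",
    "extend_design",
    "apply_design",
]

VAR_TYPES = ("binary", "categorical", "continuous")


class DesignError(ValueError):
    """Raised when data and dictionary disagree or a design is degenerate."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single variable in the data dictionary."""

    name: str
    var_type: str
    categories: tuple = ()
    group: str = "ungrouped"
    is_moderator: bool = False

    def __post_init__(self):
        if self.var_type not in VAR_TYPES:
            raise DesignError(
                f"variable {self.name!r}: unknown type {self.var_type!r}"
            )
        cats = tuple(str(c) for c in self.categories)
        object.__setattr__(self, "categories", cats)
        if self.var_type == "binary" and len(cats) != 2:
            raise DesignError(
                f"binary variable {self.name!r} needs exactly 2 categories, "
                f"got {len(cats)}"
            )
        if self.var_type == "categorical" and len(cats) < 2:
            raise DesignError(
                f"categorical variable {self.name!r} needs >= 2 categories"
            )
        if self.var_type == "continuous" and cats:
            raise DesignError(
                f"continuous variable {self.name!r} must not list categories"
            )
        if len(set(cats)) != len(cats):
            raise DesignError(f"variable {self.name!r}: duplicate categories")
        if not self.group:
            raise DesignError(f"variable {self.name!r}: empty group label")

    @property
    def width(self) -> int:
        """Number of design columns this variable contributes."""
        if self.var_type == "continuous":
            return 1
        return len(self.categories) - 1


@dataclass(frozen=True)
class Block:
    """A contiguous set of design columns belonging to one model term."""

    term_id: str
    cols: tuple
    kind: str  # "main" | "interaction"
    sources: tuple  # variable name(s) the block is built from

    @property
    def width(self) -> int:
        return len(self.cols)


@dataclass
class DesignMatrix:
    """Centered, block-structured design matrix with its bookkeeping.

    ``values`` holds the centered columns; ``values + column_means``
    recovers the raw (reference-coded) columns, which is what interaction
    products are formed from.
    """

    values: np.ndarray
    blocks: list
    column_means: np.ndarray
    column_names: list
    dictionary: tuple
    _block_map: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._block_map = {b.term_id: b for b in self.blocks}

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def block(self, term_id: str) -> Block:
        try:
            return self._block_map[term_id]
        except KeyError:
            raise DesignError(f"unknown term {term_id!r}") from None

    def variable(self, name: str) -> VariableSpec:
        for spec in self.dictionary:
            if spec.name == name:
                return spec
        raise DesignError(f"unknown variable {name!r}")

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        """Map new observations into this design's column space.

        Uses the stored training centering constants; interaction columns
        are recomputed as products of the parents' uncentered codes.
        """
        raw = {s.name: _encode(s, data) for s in self.dictionary}
        out = np.empty((len(data), self.p))
        for b in self.blocks:
            idx = np.asarray(b.cols)
            if b.kind == "main":
                out[:, idx] = raw[b.sources[0]]
            else:
                mod, partner = b.sources
                out[:, idx] = _product_block(raw[mod], raw[partner])
            out[:, idx] -= self.column_means[idx]
        return out


@dataclass(frozen=True)
class InteractionTerm:
    """A moderator x partner interaction block (centered values)."""

    moderator: str
    partner: str
    term_id: str
    values: np.ndarray
    column_means: np.ndarray
    column_names: tuple


def read_dictionary(path) -> list:
    """Read a data dictionary CSV.

    Expected columns: ``variable,type,categories,group,is_moderator`` with
    categories pipe-separated and is_moderator in {0, 1}.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"variable", "type", "categories", "group", "is_moderator"}
    missing = required - set(df.columns)
    if missing:
        raise DesignError(f"dictionary is missing columns {sorted(missing)}")
    specs = []
    for row in df.itertuples(index=False):
        cats = tuple(c for c in str(row.categories).split("|") if c != "")
        specs.append(
            VariableSpec(
                name=row.variable,
                var_type=row.type,
                categories=cats,
                group=row.group,
                is_moderator=str(row.is_moderator).strip() in ("1", "True", "true"),
            )
        )
    _check_unique_names(specs)
    return specs


def write_dictionary(specs, path) -> None:
    """Write a data dictionary CSV (inverse of :func:`read_dictionary`)."""
    df = pd.DataFrame(
        {
            "variable": [s.name for s in specs],
            "type": [s.var_type for s in specs],
            "categories": ["|".join(s.categories) for s in specs],
            "group": [s.group for s in specs],
            "is_moderator": [int(s.is_moderator) for s in specs],
        }
    )
    df.to_csv(path, index=False)


def _check_unique_names(specs) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise DesignError(f"duplicate variable names in dictionary: {dupes}")


def _encode(spec: VariableSpec, data: pd.DataFrame) -> np.ndarray:
    """Uncentered codes for one variable: n x width reference coding."""
    if spec.name not in data.columns:
        raise DesignError(f"variable {spec.name!r} missing from the data")
    col = data[spec.name]
    if col.isna().any():
        raise DesignError(f"variable {spec.name!r} has missing values")
    if spec.var_type == "continuous":
        vals = pd.to_numeric(col, errors="coerce")
        if vals.isna().any():
            raise DesignError(f"variable {spec.name!r} has non-numeric values")
        return vals.to_numpy(dtype=float).reshape(-1, 1)
    obs = col.astype(str)
    known = set(spec.categories)
    bad = sorted(set(obs) - known)
    if bad:
        raise DesignError(
            f"variable {spec.name!r}: unknown category value {bad[0]!r}"
        )
    arr = obs.to_numpy()
    return np.column_stack(
        [(arr == c).astype(float) for c in spec.categories[1:]]
    )


def _product_block(mcodes: np.ndarray, pcodes: np.ndarray) -> np.ndarray:
    """Columnwise products: column i*wp + j = mcodes[:, i] * pcodes[:, j]."""
    n, wm = mcodes.shape
    wp = pcodes.shape[1]
    return (mcodes[:, :, None] * pcodes[:, None, :]).reshape(n, wm * wp)


def _main_col_names(spec: VariableSpec) -> list:
    if spec.var_type == "continuous":
        return [spec.name]
    return [f"{spec.name}[{c}]" for c in spec.categories[1:]]


def build_design(data: pd.DataFrame, dictionary) -> DesignMatrix:
    """Build the centered main-effects design matrix from data + dictionary.

    One block per variable; reference coding (first category = reference);
    all columns centered on the provided rows.  Constant columns are
    rejected because the degrees-of-freedom calibration of a ridge
    base-learner is undefined for them.
    """
    dictionary = tuple(dictionary)
    _check_unique_names(dictionary)
    if not dictionary:
        raise DesignError("empty dictionary")
    cols, names, blocks = [], [], []
    start = 0
    for spec in dictionary:
        raw = _encode(spec, data)
        for j in range(raw.shape[1]):
            if np.ptp(raw[:, j]) == 0.0:
                raise DesignError(
                    f"variable {spec.name!r} yields a constant design column"
                )
        width = raw.shape[1]
        blocks.append(
            Block(
                term_id=spec.name,
                cols=tuple(range(start, start + width)),
                kind="main",
                sources=(spec.name,),
            )
        )
        names.extend(_main_col_names(spec))
        cols.append(raw)
        start += width
    raw_matrix = np.hstack(cols)
    means = raw_matrix.mean(axis=0)
    return DesignMatrix(
        values=raw_matrix - means,
        blocks=blocks,
        column_means=means,
        column_names=names,
        dictionary=dictionary,
    )


def interaction_pairs(dictionary, include_moderator_pairs: bool = True) -> list:
    """Deterministic list of (moderator, partner) variable pairs.

    Every flagged moderator is paired with every other variable; an
    unordered pair appears once, listed under the earlier moderator.
    """
    dictionary = tuple(dictionary)
    moderators = [s.name for s in dictionary if s.is_moderator]
    mod_rank = {m: i for i, m in enumerate(moderators)}
    pairs = []
    for m in moderators:
        for s in dictionary:
            v = s.name
            if v == m:
                continue
            if v in mod_rank:
                if not include_moderator_pairs:
                    continue
                if mod_rank[v] < mod_rank[m]:
                    continue  # already listed under the earlier moderator
            pairs.append((m, v))
    return pairs


def build_interactions(
    design: DesignMatrix,
    dictionary=None,
    include_moderator_pairs: bool = True,
) -> list:
    """All moderator x variable interaction terms for a design.

    Term columns are products of the parents' uncentered codes, centered
    afterwards.  Returns an empty list (with a warning) when no variable is
    flagged as a moderator.
    """
    dictionary = tuple(dictionary) if dictionary is not None else design.dictionary
    pairs = interaction_pairs(dictionary, include_moderator_pairs)
    if not pairs:
        warnings.warn("no moderators flagged; no interaction terms built")
        return []
    raw = design.values + design.column_means
    terms = []
    for m, v in pairs:
        bm, bv = design.block(m), design.block(v)
        prod = _product_block(raw[:, list(bm.cols)], raw[:, list(bv.cols)])
        means = prod.mean(axis=0)
        names = tuple(
            f"{design.column_names[i]}:{design.column_names[j]}"
            for i in bm.cols
            for j in bv.cols
        )
        terms.append(
            InteractionTerm(
                moderator=m,
                partner=v,
                term_id=f"{m}:{v}",
                values=prod - means,
                column_means=means,
                column_names=names,
            )
        )
    return terms


def extend_design(design: DesignMatrix, terms) -> DesignMatrix:
    """Append interaction blocks to a main-effects design."""
    if not terms:
        return design
    blocks = list(design.blocks)
    start = design.p
    values = [design.values]
    means = [design.column_means]
    names = list(design.column_names)
    for t in terms:
        width = t.values.shape[1]
        blocks.append(
            Block(
                term_id=t.term_id,
                cols=tuple(range(start, start + width)),
                kind="interaction",
                sources=(t.moderator, t.partner),
            )
        )
        values.append(t.values)
        means.append(t.column_means)
        names.extend(t.column_names)
        start += width
    return DesignMatrix(
        values=np.hstack(values),
        blocks=blocks,
        column_means=np.concatenate(means),
        column_names=names,
        dictionary=design.dictionary,
    )


def apply_design(design: DesignMatrix, data: pd.DataFrame) -> np.ndarray:
    """Map new observations into an existing design's column space."""
    return design.transform(data)
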