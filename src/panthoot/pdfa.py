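"""Permuted discriminant function analysis (pDFA) for two-factor designs.

A plain DFA inflates group differences when multiple calls come from each
individual.  The pDFA corrects this with a design-respecting permutation
test on classification accuracy:

* **crossed** design (e.g. context tested within individuals): test-factor
  labels are permuted *within* each control level, and balancing draws an
  equal number of calls per test level from every control level (that
  level's minimum cell count).
* **nested** design (e.g. individuals nested in communities): whole control
  units — all of an individual's calls together — are reassigned to test
  levels, preserving the observed number of units per level; balancing draws
  the global minimum per-unit call count from every unit.
* **nested with a restriction factor** (e.g. testing individual identity with
  community as restriction): label permutation is confined to each
  restriction level.

Each of the ``n_perm`` datasets (the original plus ``n_perm - 1``
randomized ones) gets a fresh balanced subsample; the left-out calls provide
cross-validated accuracy.  The p-value is the fraction of the ``n_perm``
datasets whose accuracy is at least the observed one (so ``p >= 1/n_perm``),
and "expected" accuracy is the mean over the randomized datasets.
Significance is declared on the cross-validated accuracy at ``alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureTable
from .errors import DesignError
from .lda import accuracy, classify, fit_lda

CROSSED = "crossed"
NESTED = "nested"


@dataclass
class PDFADesign:
    """Two-factor test specification.

    ``test_factor`` is the grouping under test; ``control_factor`` the
    repeated-measures unit (may be ``None`` in nested designs that use a
    restriction factor only); ``restriction_factor`` confines nested label
    permutation to an outer grouping.
    """

    test_factor: str
    control_factor: str | None = None
    restriction_factor: str | None = None
    design: str = CROSSED

    def __post_init__(self) -> None:
        if self.design not in (CROSSED, NESTED):
            raise DesignError(f"unknown design {self.design!r}")
        if self.design == CROSSED and self.control_factor is None:
            raise DesignError("crossed design requires a control factor")
        if self.restriction_factor is not None and self.design != NESTED:
            raise DesignError("restriction factor only applies to nested designs")

    def validate(self, df: pd.DataFrame) -> None:
        for col in (self.test_factor, self.control_factor, self.restriction_factor):
            if col is not None and col not in df.columns:
                raise DesignError(f"factor column {col!r} not in table")
        test_levels = df[self.test_factor].unique()
        if len(test_levels) < 2:
            raise DesignError("test factor needs at least 2 levels")
        if self.design == CROSSED:
            counts = df.groupby(
                [self.control_factor, self.test_factor], sort=True
            ).size().unstack(fill_value=0)
            empty = counts[counts == 0].stack()
            if len(empty):
                cell = empty.index[0]
                raise DesignError(
                    f"crossed design cell empty: control={cell[0]!r} test={cell[1]!r}"
                )
        elif self.control_factor is not None:
            n_test_per_control = df.groupby(self.control_factor)[self.test_factor].nunique()
            bad = n_test_per_control[n_test_per_control > 1]
            if len(bad):
                raise DesignError(
                    f"control level(s) span multiple test levels: {list(bad.index)}"
                )


@dataclass
class PDFAConfig:
    """Permutation-test settings: 1000 randomized datasets including the
    original, alpha 0.05 on cross-validated accuracy, by default."""

    n_perm: int = 1000
    alpha: float = 0.05
    n_select_per_cell: int | None = None
    seed: int = 0
    rebalance_each_perm: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PDFAResult:
    observed_accuracy_selected: float
    observed_accuracy_cv: float
    expected_accuracy_selected: float
    expected_accuracy_cv: float
    p_selected: float
    p_cv: float
    n_calls_used: int
    n_levels: int
    cv_available: bool
    perm_accuracy_selected: np.ndarray = field(repr=False, default=None)
    perm_accuracy_cv: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> bool:
        """Significance on cross-validated accuracy at alpha = 0.05."""
        return self.p_cv < 0.05

    def to_dict(self) -> dict:
        return {
            "observed_accuracy_selected": self.observed_accuracy_selected,
            "observed_accuracy_cv": self.observed_accuracy_cv,
            "expected_accuracy_selected": self.expected_accuracy_selected,
            "expected_accuracy_cv": self.expected_accuracy_cv,
            "p_selected": self.p_selected,
            "p_cv": self.p_cv,
            "n_calls_used": self.n_calls_used,
            "n_levels": self.n_levels,
            "cv_available": self.cv_available,
        }


# ---------------------------------------------------------------------------
# internal array-level machinery
# ---------------------------------------------------------------------------


class _DesignArrays:
    """Integer-coded factor columns plus precomputed group indices."""

    def __init__(self, df: pd.DataFrame, design: PDFADesign):
        self.design = design
        self.test = pd.Categorical(df[design.test_factor])
        self.test_codes = np.asarray(self.test.codes)
        self.n_test_levels = len(self.test.categories)
        self.n = len(df)

        if design.control_factor is not None:
            ctrl = pd.Categorical(df[design.control_factor])
            self.control_codes = np.asarray(ctrl.codes)
            self.n_control_levels = len(ctrl.categories)
        else:
            self.control_codes = None
            self.n_control_levels = 0

        if design.restriction_factor is not None:
            restr = pd.Categorical(df[design.restriction_factor])
            self.restr_codes = np.asarray(restr.codes)
        else:
            self.restr_codes = None

        if design.design == NESTED and self.control_codes is not None:
            # unit (control level) -> its rows and its test level
            self.unit_rows = [
                np.flatnonzero(self.control_codes == u)
                for u in range(self.n_control_levels)
            ]
            self.unit_test = np.array(
                [self.test_codes[rows[0]] for rows in self.unit_rows]
            )
            if self.restr_codes is not None:
                self.unit_restr = np.array(
                    [self.restr_codes[rows[0]] for rows in self.unit_rows]
                )
            else:
                self.unit_restr = np.zeros(self.n_control_levels, dtype=int)


def _permuted_labels(arr: _DesignArrays, rng: np.random.Generator) -> np.ndarray:
    """One design-respecting random relabeling of the test factor (row-level)."""
    d = arr.design
    labels = arr.test_codes.copy()
    if d.design == CROSSED:
        for c in range(arr.n_control_levels):
            rows = np.flatnonzero(arr.control_codes == c)
            labels[rows] = rng.permutation(labels[rows])
        return labels
    if arr.control_codes is not None:
        # reassign whole units to test levels, within restriction strata
        unit_test = arr.unit_test.copy()
        for r in np.unique(arr.unit_restr):
            units = np.flatnonzero(arr.unit_restr == r)
            unit_test[units] = rng.permutation(unit_test[units])
        for u, rows in enumerate(arr.unit_rows):
            labels[rows] = unit_test[u]
        return labels
    # nested, call-level units: permute row labels within restriction strata
    strata = arr.restr_codes if arr.restr_codes is not None else np.zeros(arr.n, dtype=int)
    for r in np.unique(strata):
        rows = np.flatnonzero(strata == r)
        labels[rows] = rng.permutation(labels[rows])
    return labels


def _balance_indices(
    arr: _DesignArrays,
    labels: np.ndarray,
    rng: np.random.Generator,
    n_select_per_cell: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced selected/left-out row indices given (possibly permuted) labels."""
    d = arr.design
    selected: list[np.ndarray] = []
    if d.design == CROSSED:
        for c in range(arr.n_control_levels):
            rows = np.flatnonzero(arr.control_codes == c)
            cells = [rows[labels[rows] == t] for t in range(arr.n_test_levels)]
            sizes = [len(cell) for cell in cells]
            if min(sizes) == 0:
                t = int(np.argmin(sizes))
                raise DesignError(f"empty cell: control level {c}, test level {t}")
            m = min(sizes) if n_select_per_cell is None else n_select_per_cell
            if m > min(sizes):
                raise DesignError(
                    f"n_select_per_cell={m} exceeds the smallest cell ({min(sizes)})"
                )
            for cell in cells:
                selected.append(rng.choice(cell, size=m, replace=False))
    else:
        if arr.control_codes is not None:
            groups = arr.unit_rows
        else:
            groups = [
                np.flatnonzero(labels == t) for t in range(arr.n_test_levels)
            ]
        sizes = [len(g) for g in groups]
        if min(sizes) == 0:
            raise DesignError("a balancing group has no observations")
        m = min(sizes) if n_select_per_cell is None else n_select_per_cell
        if m > min(sizes):
            raise DesignError(
                f"n_select_per_cell={m} exceeds the smallest group ({min(sizes)})"
            )
        for g in groups:
            selected.append(rng.choice(g, size=m, replace=False))
    sel = np.sort(np.concatenate(selected))
    mask = np.ones(arr.n, dtype=bool)
    mask[sel] = False
    return sel, np.flatnonzero(mask)


def _as_df(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    return table.df if isinstance(table, FeatureTable) else table


def balance_split(
    table: FeatureTable | pd.DataFrame,
    design: PDFADesign,
    rng: np.random.Generator,
    n_select_per_cell: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one balanced subsample; returns (selected, left-out) row indices.

    Crossed: an equal number of calls per test level from each control level
    (that level's minimum cell count unless overridden).  Nested: the global
    minimum per-unit count from each control unit (or per test level when no
    control factor is set).  The left-out complement is used for
    cross-validation.
    """
    df = _as_df(table).reset_index(drop=True)
    design.validate(df)
    arr = _DesignArrays(df, design)
    return _balance_indices(arr, arr.test_codes, rng, n_select_per_cell)


def permute_labels(
    table: FeatureTable | pd.DataFrame,
    design: PDFADesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Return a copy of the table with one design-respecting label randomization."""
    df = _as_df(table).reset_index(drop=True).copy()
    design.validate(df)
    arr = _DesignArrays(df, design)
    codes = _permuted_labels(arr, rng)
    df[design.test_factor] = np.asarray(arr.test.categories)[codes]
    return df


def run_pdfa(
    table: FeatureTable | pd.DataFrame,
    design: PDFADesign,
    config: PDFAConfig,
    feature_columns: list[str] | None = None,
    X: np.ndarray | None = None,
) -> PDFAResult:
    """Run the full permutation test.

    ``X`` may be passed directly (e.g. PCA scores); otherwise
    ``feature_columns`` (default: the table's feature columns) are used.
    Reproducible given ``config.seed``: permutation ``i`` uses the
    independent substream ``default_rng([seed, i])``.
    """
    df = _as_df(table).reset_index(drop=True)
    design.validate(df)
    if X is None:
        if feature_columns is None:
            if not isinstance(table, FeatureTable):
                raise ValueError("feature_columns required for a bare DataFrame")
            feature_columns = table.feature_names
        X = df[feature_columns].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains missing/non-finite values")
    if X.shape[0] != len(df):
        raise ValueError("feature matrix and table row counts differ")

    arr = _DesignArrays(df, design)
    smallest_cat = np.bincount(arr.test_codes, minlength=arr.n_test_levels).min()
    if X.shape[1] > smallest_cat:
        warnings.warn(
            f"{X.shape[1]} features exceed the smallest test-category size "
            f"({smallest_cat}); the discriminant fit may overfit"
        )

    n_perm = config.n_perm
    acc_sel = np.full(n_perm, np.nan)
    acc_cv = np.full(n_perm, np.nan)
    cv_available = True
    fixed_split = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ridge warnings inside the loop
        for i in range(n_perm):
            rng = np.random.default_rng([config.seed, i])
            labels = arr.test_codes if i == 0 else _permuted_labels(arr, rng)
            if config.rebalance_each_perm or fixed_split is None:
                sel, out = _balance_indices(arr, labels, rng, config.n_select_per_cell)
                if not config.rebalance_each_perm:
                    fixed_split = (sel, out)
            else:
                sel, out = fixed_split
            model = fit_lda(X[sel], labels[sel])
            acc_sel[i] = accuracy(classify(model, X[sel]), labels[sel])
            if len(out):
                acc_cv[i] = accuracy(classify(model, X[out]), labels[out])
            else:
                cv_available = False

    def _p(acc: np.ndarray) -> float:
        if np.isnan(acc[0]):
            return float("nan")
        return float(np.mean(acc >= acc[0] - 1e-9))

    return PDFAResult(
        observed_accuracy_selected=float(acc_sel[0]),
        observed_accuracy_cv=float(acc_cv[0]),
        expected_accuracy_selected=float(np.nanmean(acc_sel[1:])),
        expected_accuracy_cv=float(np.nanmean(acc_cv[1:])) if cv_available else float("nan"),
        p_selected=_p(acc_sel),
        p_cv=_p(acc_cv) if cv_available else float("nan"),
        n_calls_used=int(len(df)),
        n_levels=int(arr.n_test_levels),
        cv_available=cv_available,
        perm_accuracy_selected=acc_sel,
        perm_accuracy_cv=acc_cv,
    )


def run_pairwise_pdfa(
    table: FeatureTable | pd.DataFrame,
    test_factor: str,
    pairs: list[tuple[str, str]],
    design: PDFADesign,
    config: PDFAConfig,
    feature_columns: list[str] | None = None,
) -> dict[tuple[str, str], PDFAResult]:
    """Two-level pDFAs for each listed pair of test-factor levels.

    No multiplicity correction is applied to the pairwise p-values (they are
    reported as-is, as descriptive follow-ups to the omnibus test).
    """
    df = _as_df(table).reset_index(drop=True)
    levels = set(df[test_factor].unique())
    results: dict[tuple[str, str], PDFAResult] = {}
    for a, b in pairs:
        unknown = {a, b} - levels
        if unknown:
            raise ValueError(f"unknown test-factor level(s): {sorted(unknown)}")
        mask = df[test_factor].isin([a, b]).to_numpy()
        sub = df.loc[mask].reset_index(drop=True)
        if isinstance(table, FeatureTable):
            sub_table: FeatureTable | pd.DataFrame = FeatureTable(
                sub, list(table.feature_names), dict(table.feature_family)
            )
        else:
            sub_table = sub
        results[(a, b)] = run_pdfa(sub_table, design, config, feature_columns)
    return results
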