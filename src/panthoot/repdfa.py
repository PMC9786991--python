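"""Variable-importance resampling over repeated balanced DFAs (repDFA).

A significant omnibus pDFA says the test factor is discriminable but not by
which variables.  repDFA refits a plain DFA on many balanced datasets drawn
with the *true* labels (no permutation) and counts which variable carries
the highest-magnitude standardized coefficient on the first and second
discriminant functions in each refit.  Variables that top the count in many
refits are the stable discriminators.

Two balancing schemes:

* crossed — the same balanced subsampling as the pDFA (equal calls per test
  level within each control level, without replacement);
* nested — each run resamples the same number of recordings per individual
  *with* replacement, then fits the DFA on the test factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .data import FeatureTable
from .errors import DesignError
from .lda import fit_lda, raw_coefficients, standardized_coefficients
from .pdfa import (
    CROSSED,
    NESTED,
    PDFADesign,
    _as_df,
    _balance_indices,
    _DesignArrays,
)


@dataclass
class RepDFAResult:
    """Counts of how often each variable topped DF1/DF2 across ``n_runs`` DFAs.

    With two test-factor levels there is no second discriminant function;
    ``top_df2_counts`` is then ``None`` (absent, as opposed to "never top").
    """

    n_runs: int
    variable_names: list[str]
    top_df1_counts: dict[str, int] = field(default_factory=dict)
    top_df2_counts: dict[str, int] | None = None

    def ranking(self, df: int = 1) -> list[tuple[str, int]]:
        counts = self.top_df1_counts if df == 1 else (self.top_df2_counts or {})
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "top_df1_counts": dict(self.top_df1_counts),
            "top_df2_counts": None if self.top_df2_counts is None else dict(self.top_df2_counts),
        }


def _count_runs(
    X: np.ndarray,
    variable_names: list[str],
    draw_indices,
    labels_for,
    n_runs: int,
    use_standardized: bool,
) -> RepDFAResult:
    d1 = np.zeros(len(variable_names), dtype=int)
    d2 = np.zeros(len(variable_names), dtype=int)
    has_df2 = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_runs):
            idx = draw_indices(i)
            model = fit_lda(X[idx], labels_for(idx))
            coefs = (
                standardized_coefficients(model)
                if use_standardized
                else raw_coefficients(model)
            )
            d1[np.argmax(np.abs(coefs[:, 0]))] += 1
            if model.n_discriminants >= 2:
                has_df2 = True
                d2[np.argmax(np.abs(coefs[:, 1]))] += 1
    return RepDFAResult(
        n_runs=n_runs,
        variable_names=list(variable_names),
        top_df1_counts={v: int(c) for v, c in zip(variable_names, d1)},
        top_df2_counts=(
            {v: int(c) for v, c in zip(variable_names, d2)} if has_df2 else None
        ),
    )


def run_repdfa(
    table: FeatureTable | pd.DataFrame,
    design: PDFADesign,
    n_runs: int = 1000,
    rng: np.random.Generator | None = None,
    feature_columns: list[str] | None = None,
    X: np.ndarray | None = None,
    use_standardized: bool = True,
) -> RepDFAResult:
    """Crossed-design repDFA: balanced refits with true labels, no permutation."""
    if design.design != CROSSED:
        raise DesignError("run_repdfa requires a crossed design; see run_repdfa_nested")
    df = _as_df(table).reset_index(drop=True)
    design.validate(df)
    if X is None:
        if feature_columns is None:
            if not isinstance(table, FeatureTable):
                raise ValueError("feature_columns required for a bare DataFrame")
            feature_columns = table.feature_names
        X = df[feature_columns].to_numpy(dtype=float)
        names = list(feature_columns)
    else:
        names = [f"var{i + 1}" for i in range(X.shape[1])]
    rng = rng or np.random.default_rng()
    arr = _DesignArrays(df, design)

    def draw(_i: int) -> np.ndarray:
        sel, _ = _balance_indices(arr, arr.test_codes, rng)
        return sel

    return _count_runs(X, names, draw, lambda idx: arr.test_codes[idx], n_runs, use_standardized)


def run_repdfa_nested(
    table: FeatureTable | pd.DataFrame,
    design: PDFADesign,
    n_runs: int = 1000,
    n_per_individual: int | None = None,
    rng: np.random.Generator | None = None,
    feature_columns: list[str] | None = None,
    X: np.ndarray | None = None,
    use_standardized: bool = True,
    individual_column: str = "individual",
) -> RepDFAResult:
    """Nested-design repDFA: resample ``n_per_individual`` calls per individual
    with replacement in each run, then fit the DFA on the test factor.

    Default ``n_per_individual`` is the global per-individual minimum, so
    every run uses ``n_individuals * n_per_individual`` rows.
    """
    if design.design != NESTED:
        raise DesignError("run_repdfa_nested requires a nested design")
    df = _as_df(table).reset_index(drop=True)
    design.validate(df)
    if X is None:
        if feature_columns is None:
            if not isinstance(table, FeatureTable):
                raise ValueError("feature_columns required for a bare DataFrame")
            feature_columns = table.feature_names
        X = df[feature_columns].to_numpy(dtype=float)
        names = list(feature_columns)
    else:
        names = [f"var{i + 1}" for i in range(X.shape[1])]
    rng = rng or np.random.default_rng()

    ind = pd.Categorical(df[individual_column])
    groups = [np.flatnonzero(ind.codes == u) for u in range(len(ind.categories))]
    sizes = [len(g) for g in groups]
    if min(sizes) < 1:
        raise DesignError("an individual has no calls")
    m = min(sizes) if n_per_individual is None else n_per_individual
    if m < 1:
        raise ValueError("n_per_individual must be >= 1")
    test_codes = np.asarray(pd.Categorical(df[design.test_factor]).codes)

    def draw(_i: int) -> np.ndarray:
        return np.concatenate([rng.choice(g, size=m, replace=True) for g in groups])

    return _count_runs(X, names, draw, lambda idx: test_codes[idx], n_runs, use_standardized)
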