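"""Call-level feature tables and the study's inclusion/exclusion filters.

The universal currency of the pipeline is a :class:`FeatureTable`: one row per
recorded call, identifier columns (``call_id``, ``site``, ``community``,
``individual``, ``context``), boolean phase flags (``has_introduction`` ...),
and named numeric acoustic feature columns.  Missing feature values are a
first-class state (``NaN``), distinct from a count of zero: a count of 0 with
the phase flag set means "phase present but empty", while phase absence is
encoded as count 0 *and* flag ``False``.  Phase-requirement filters treat the
flag as authoritative.

Filters only ever remove rows or columns, never edit values, and are
idempotent; every filter returns a :class:`FilterReport` whose counts are
additive (input = retained + dropped).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import IntegrityError, SchemaError

#: Identifier columns every table must carry, in canonical order.
FACTOR_COLUMNS = ("call_id", "site", "community", "individual", "context")

#: Pant-hoot phases, in temporal order (drumming is an optional accompaniment).
PHASES = ("introduction", "buildup", "climax", "letdown", "drumming")

#: Phase-flag column names derived from :data:`PHASES`.
PHASE_FLAG_COLUMNS = tuple(f"has_{p}" for p in PHASES)

#: Behavioural contexts, from highest to lowest priority.  When several
#: contexts co-occur during a recording, the highest-priority one is kept.
CONTEXT_PRIORITY = ("travel", "feed", "display", "rest")

CONTEXTS = CONTEXT_PRIORITY + ("unknown",)

FEATURE_FAMILIES = ("continuous", "count", "binary")


def resolve_context(raw_flags: Iterable[str]) -> str:
    """Collapse co-occurring context tags to the single highest-priority one.

    The priority hierarchy is travel > feed > display > rest.  An empty set of
    tags resolves to ``"unknown"``.
    """
    flags = {str(f).strip().lower() for f in raw_flags}
    unknown = flags - set(CONTEXT_PRIORITY)
    if unknown:
        raise SchemaError(f"unknown context tags: {sorted(unknown)}")
    for ctx in CONTEXT_PRIORITY:
        if ctx in flags:
            return ctx
    return "unknown"


@dataclass
class FeatureTable:
    """Call-level rows with factor labels and named numeric features.

    Parameters
    ----------
    df:
        One row per call.  Must contain :data:`FACTOR_COLUMNS`; phase-flag
        columns and feature columns are optional but declared feature columns
        must exist.
    feature_names:
        Ordered list of feature column names.
    feature_family:
        Mapping feature name -> ``"continuous" | "count" | "binary"``.
    """

    df: pd.DataFrame
    feature_names: list[str]
    feature_family: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in FACTOR_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing factor column(s): {missing}")
        absent = [f for f in self.feature_names if f not in self.df.columns]
        if absent:
            raise SchemaError(f"declared features absent from table: {absent}")
        if self.df["call_id"].duplicated().any():
            dups = self.df.loc[self.df["call_id"].duplicated(), "call_id"].tolist()
            raise IntegrityError(f"duplicate call_id values: {dups[:5]}")
        bad_fam = {f: v for f, v in self.feature_family.items() if v not in FEATURE_FAMILIES}
        if bad_fam:
            raise SchemaError(f"unknown feature families: {bad_fam}")
        self.df = self.df.reset_index(drop=True)
        self.df["context"] = self.df["context"].astype(str).str.lower()

    # -- convenience ------------------------------------------------------
    @property
    def n_calls(self) -> int:
        return len(self.df)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.df["individual"].unique())

    @property
    def communities(self) -> list[str]:
        return sorted(self.df["community"].unique())

    def features(self) -> pd.DataFrame:
        """The numeric feature block, ordered as ``feature_names``."""
        return self.df[self.feature_names]

    def matrix(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=float)

    def subset_rows(self, mask: pd.Series | np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.df.loc[mask].reset_index(drop=True).copy(),
            list(self.feature_names),
            dict(self.feature_family),
        )

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        absent = [f for f in names if f not in self.feature_names]
        if absent:
            raise SchemaError(f"unknown feature(s): {absent}")
        keep_cols = [c for c in self.df.columns if c not in self.feature_names or c in names]
        return FeatureTable(
            self.df[keep_cols].copy(),
            [f for f in self.feature_names if f in names],
            {f: self.feature_family[f] for f in self.feature_names if f in names},
        )


@dataclass
class FilterReport:
    """Bookkeeping for a single filtering stage."""

    n_input_calls: int
    n_output_calls: int
    excluded_individuals: list[tuple[str, str]] = field(default_factory=list)
    dropped_features: list[str] = field(default_factory=list)
    dropped_rows_missing: int = 0

    def __post_init__(self) -> None:
        if self.n_output_calls > self.n_input_calls:
            raise IntegrityError("filter produced more rows than it received")

    @property
    def n_dropped_calls(self) -> int:
        return self.n_input_calls - self.n_output_calls

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FeatureSetSpec:
    """Which feature columns enter an analysis and which phases each call needs.

    ``structural`` excludes drumming-related features and the categorical
    presence/absence flags; ``buildup``/``climax`` require the corresponding
    phase; ``entire_call`` requires both.
    """

    name: str
    features: list[str]
    required_phases: frozenset[str] = frozenset()
    excluded_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.required_phases) - set(PHASES)
        if bad:
            raise SchemaError(f"unknown phases in spec: {sorted(bad)}")


def read_feature_table(
    path: str | Path,
    families: Mapping[str, str] | str | Path | None = None,
) -> FeatureTable:
    """Read a call-feature CSV into a :class:`FeatureTable`.

    CSV dialect: comma-separated, UTF-8, header row required, "." decimal,
    empty cell = missing (never coerced to zero).  Columns other than the
    factor columns and phase flags are treated as features.  Families may be
    declared via a sidecar YAML/JSON mapping (path or dict); otherwise they
    are inferred (integer-valued columns -> count, 0/1 -> binary, else
    continuous).
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=[""], keep_default_na=True)
    missing = [c for c in FACTOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing factor column(s) {missing}")

    feature_names = [
        c for c in df.columns if c not in FACTOR_COLUMNS and c not in PHASE_FLAG_COLUMNS
    ]
    declared: dict[str, str] = {}
    if families is not None:
        if isinstance(families, (str, Path)):
            text = Path(families).read_text()
            declared = dict(
                json.loads(text) if str(families).endswith(".json") else yaml.safe_load(text)
            )
        else:
            declared = dict(families)

    family: dict[str, str] = {}
    for f in feature_names:
        if f in declared:
            family[f] = declared[f]
            continue
        col = pd.to_numeric(df[f], errors="coerce")
        vals = col.dropna()
        if len(vals) and np.allclose(vals, np.round(vals)):
            family[f] = "binary" if set(np.unique(vals)) <= {0.0, 1.0} else "count"
        else:
            family[f] = "continuous"
    for f in feature_names:
        df[f] = pd.to_numeric(df[f], errors="coerce")
    for c in PHASE_FLAG_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype(float).fillna(0).astype(bool)
    return FeatureTable(df, feature_names, family)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table back to the CSV dialect :func:`read_feature_table` reads."""
    df = table.df.copy()
    for c in PHASE_FLAG_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype(int)
    df.to_csv(path, index=False)


def apply_inclusion_filters(
    table: FeatureTable, min_calls: int = 8
) -> tuple[FeatureTable, FilterReport]:
    """Drop individuals with fewer than ``min_calls`` recorded calls.

    The study threshold of 8 calls per male balances the number of calls per
    individual against the number of individuals retained.
    """
    if min_calls < 1:
        raise ValueError("min_calls must be >= 1")
    counts = table.df.groupby("individual", sort=True).size()
    keep = set(counts.index[counts >= min_calls])
    excluded = [
        (ind, f"only {int(counts[ind])} call(s), need >= {min_calls}")
        for ind in counts.index
        if ind not in keep
    ]
    out = table.subset_rows(table.df["individual"].isin(keep).to_numpy())
    report = FilterReport(
        n_input_calls=table.n_calls,
        n_output_calls=out.n_calls,
        excluded_individuals=excluded,
    )
    return out, report


def apply_context_filters(
    table: FeatureTable,
    contexts: Sequence[str] = ("feed", "travel"),
    min_per_context: int = 3,
) -> tuple[FeatureTable, FilterReport]:
    """Restrict to the listed contexts and to individuals sampled in all of them.

    Rows from other contexts are dropped first; then individuals with fewer
    than ``min_per_context`` calls in *each* listed context are excluded
    (study default: at least three calls in both feed and travel).
    """
    contexts = [c.lower() for c in contexts]
    in_ctx = table.df["context"].isin(contexts)
    sub = table.df.loc[in_ctx]
    pivot = sub.groupby(["individual", "context"], sort=True).size().unstack(fill_value=0)
    for c in contexts:
        if c not in pivot.columns:
            pivot[c] = 0
    ok = pivot.index[(pivot[contexts] >= min_per_context).all(axis=1)]
    keep_mask = (in_ctx & table.df["individual"].isin(ok)).to_numpy()
    excluded = [
        (str(ind), "fewer than %d calls in context(s) %s"
         % (min_per_context, [c for c in contexts if pivot.loc[ind, c] < min_per_context]))
        for ind in pivot.index
        if ind not in set(ok)
    ]
    out = table.subset_rows(keep_mask)
    report = FilterReport(
        n_input_calls=table.n_calls,
        n_output_calls=out.n_calls,
        excluded_individuals=excluded,
    )
    return out, report


def select_feature_set(
    table: FeatureTable, spec: FeatureSetSpec
) -> tuple[FeatureTable, FilterReport]:
    """Apply a feature-set spec: column selection, phase requirements, complete cases.

    Drops the spec's excluded features, keeps only ``spec.features``, removes
    rows whose phase flags do not satisfy ``spec.required_phases`` (flags are
    authoritative), then removes rows with any missing value among the
    retained features (complete-case analysis).
    """
    wanted = [f for f in spec.features if f not in spec.excluded_features]
    absent = [f for f in wanted if f not in table.feature_names]
    if absent:
        raise SchemaError(f"feature set {spec.name!r} names unknown feature(s): {absent}")
    dropped_features = [f for f in table.feature_names if f not in wanted]
    out = table.subset_features(wanted)

    n_input = out.n_calls
    mask = np.ones(n_input, dtype=bool)
    for phase in spec.required_phases:
        col = f"has_{phase}"
        if col not in out.df.columns:
            raise SchemaError(f"phase flag column {col!r} required by spec but absent")
        mask &= out.df[col].to_numpy(dtype=bool)
    n_phase_dropped = int(n_input - mask.sum())

    complete = ~out.features().isna().any(axis=1).to_numpy()
    n_missing_dropped = int((mask & ~complete).sum())
    out = out.subset_rows(mask & complete)

    report = FilterReport(
        n_input_calls=n_input,
        n_output_calls=out.n_calls,
        dropped_features=dropped_features,
        dropped_rows_missing=n_missing_dropped,
        excluded_individuals=[],
    )
    # phase-based drops are the remainder: n_input - n_output - missing
    assert report.n_dropped_calls == n_phase_dropped + n_missing_dropped
    return out, report


def spectrogram_resolution(
    fs_hz: float, nfft: int, overlap_frac: float
) -> tuple[float, float, float]:
    """Spectrogram parameter arithmetic: (freq res Hz, time res ms, freq range Hz).

    ``freq_res = fs/nfft``; ``time_res = nfft*(1-overlap)/fs`` (returned in
    milliseconds); ``freq_range = fs/2``.  Rounding is left to the caller:
    the study's settings (24 kHz, 1024-point FFT, 93.75 % overlap) give
    23.4 Hz -> "23 Hz" and 2.67 ms -> "2.7 ms" at the printed precision.
    """
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if nfft < 2:
        raise ValueError("nfft must be >= 2")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    freq_res = fs_hz / nfft
    time_res_ms = 1000.0 * nfft * (1.0 - overlap_frac) / fs_hz
    return freq_res, time_res_ms, fs_hz / 2.0


# ---------------------------------------------------------------------------
# Published per-individual call counts (printed study table), usable as input
# for filter bookkeeping and for shaping simulations.
# ---------------------------------------------------------------------------

#: (site, community, individual code) -> total pant-hoots recorded.
PUBLISHED_CALL_COUNTS: dict[tuple[str, str, str], int] = {
    ("gombe", "kasekela", "FND"): 11,
    ("gombe", "kasekela", "FO"): 20,
    ("gombe", "kasekela", "FU"): 33,
    ("gombe", "kasekela", "SL"): 15,
    ("gombe", "kasekela", "SN"): 38,
    ("gombe", "kasekela", "ZS"): 11,
    ("gombe", "mitumba", "EDG"): 45,
    ("gombe", "mitumba", "FAN"): 8,
    ("gombe", "mitumba", "KOC"): 16,
    ("gombe", "mitumba", "LAM"): 9,
    ("gombe", "mitumba", "LON"): 8,
    ("kibale", "kanyawara", "BB"): 8,
    ("kibale", "kanyawara", "ES"): 18,
    ("kibale", "kanyawara", "KK"): 21,
    ("kibale", "kanyawara", "LK"): 14,
    ("kibale", "kanyawara", "PG"): 10,
    ("kibale", "kanyawara", "ST"): 14,
    ("kibale", "kanyawara", "TJ"): 26,
}


def published_counts_table(extra_individuals: Mapping[tuple[str, str, str], int] | None = None) -> FeatureTable:
    """Expand the published per-individual totals into a one-row-per-call table.

    ``extra_individuals`` lets tests add below-threshold individuals to
    exercise the inclusion filter.  The table carries a single placeholder
    feature so it is a valid :class:`FeatureTable`.
    """
    counts = dict(PUBLISHED_CALL_COUNTS)
    if extra_individuals:
        counts.update(extra_individuals)
    rows = []
    for (site, community, ind), n in counts.items():
        for k in range(n):
            rows.append(
                {
                    "call_id": f"{ind}_{k:03d}",
                    "site": site,
                    "community": community,
                    "individual": ind,
                    "context": "unknown",
                    "placeholder": 0.0,
                }
            )
    df = pd.DataFrame(rows)
    return FeatureTable(df, ["placeholder"], {"placeholder": "continuous"})
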