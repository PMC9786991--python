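"""End-to-end analysis orchestration and report rendering.

Reproduces the study's decision logic per acoustic feature set:

1. a crossed context pDFA (control = individual) decides whether context is
   a covariate that must be controlled;
2. community pDFAs (nested, control = individual) run for each configured
   community subset — stratified by context for the feature sets where the
   context test was significant, on the pooled data otherwise;
3. pairwise community pDFAs follow a significant omnibus (or always/never,
   by plan toggle);
4. an individual-identity pDFA runs nested with community as the
   restriction factor;
5. significant omnibus tests trigger repDFA variable-importance resampling;
6. a significant context test additionally triggers per-feature Poisson
   mixed models on the count features that load highest on the winning
   principal component, with Benjamini-Hochberg adjustment.

Analyses that a dataset cannot support (e.g. too few individuals recorded
in both contexts) are skipped with the reason recorded, never failed.  One
master seed deterministically spawns per-analysis seeds by hashing the
analysis name, so adding an analysis never changes the results of others.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .data import (
    FeatureSetSpec,
    FeatureTable,
    apply_context_filters,
    apply_inclusion_filters,
    select_feature_set,
)
from .errors import DesignError, PanthootError
from .pca import fit_pca, select_components_cap, select_components_scree, transform
from .pdfa import CROSSED, NESTED, PDFAConfig, PDFADesign, run_pdfa
from .posthoc import adjust_batch, fit_mixed_count, fit_mixed_gaussian
from .repdfa import run_repdfa, run_repdfa_nested


@dataclass
class AnalysisPlan:
    """What to test, on which feature sets and community subsets."""

    feature_sets: list[FeatureSetSpec]
    community_subsets: dict[str, list[str] | None] = field(
        default_factory=lambda: {"all": None}
    )
    contexts: tuple[str, str] = ("feed", "travel")
    min_calls: int = 8
    min_per_context: int = 3
    alpha: float = 0.05
    pairwise: str = "if_significant"  # never | if_significant | always
    component_heuristics: tuple[str, ...] = ("cap",)
    run_importance: bool = True
    run_posthoc: bool = True
    n_repdfa_runs: int = 1000

    def __post_init__(self) -> None:
        if self.pairwise not in ("never", "if_significant", "always"):
            raise ValueError("pairwise must be never | if_significant | always")
        bad = set(self.component_heuristics) - {"cap", "scree"}
        if bad:
            raise ValueError(f"unknown heuristic(s): {sorted(bad)}")


@dataclass
class AnalysisReport:
    """Printed-table-shaped rows plus importance/post-hoc follow-ups."""

    rows: list[dict] = field(default_factory=list)
    importance: list[dict] = field(default_factory=list)
    posthoc: list[dict] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)
    master_seed: int = 0
    software: str = f"panthoot {_pkg_version}"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(**d)


ROW_COLUMNS = [
    "analysis",
    "feature_set",
    "test_factor",
    "design",
    "control_factor",
    "restriction_factor",
    "heuristic",
    "n_components",
    "n_individuals",
    "median_calls_per_individual",
    "calls_range",
    "total_calls",
    "observed_accuracy_cv",
    "expected_accuracy_cv",
    "p_cv",
    "significant",
    "skipped",
    "reason",
]


def analysis_seed(master_seed: int, name: str) -> int:
    """Deterministic per-analysis seed from the master seed and analysis name."""
    return int(zlib.crc32(f"{master_seed}:{name}".encode()) & 0x7FFFFFFF)


def _call_stats(df: pd.DataFrame) -> tuple[int, float, str, int]:
    per_ind = df.groupby("individual").size()
    return (
        int(per_ind.size),
        float(per_ind.median()),
        f"{int(per_ind.min())}-{int(per_ind.max())}",
        int(len(df)),
    )


def _skipped_row(name: str, fs: str, design: PDFADesign, reason: str) -> dict:
    row = {c: None for c in ROW_COLUMNS}
    row.update(
        analysis=name,
        feature_set=fs,
        test_factor=design.test_factor,
        design=design.design,
        control_factor=design.control_factor,
        restriction_factor=design.restriction_factor,
        skipped=True,
        reason=reason,
        significant=False,
    )
    return row


def _pca_scores(table: FeatureTable, design: PDFADesign, heuristic: str):
    """Fit PCA on the analysis table and select components per heuristic."""
    model = fit_pca(table.matrix(), table.feature_names, standardize=True)
    smallest = int(table.df[design.test_factor].value_counts().min())
    if heuristic == "cap":
        k = select_components_cap(model, smallest)
    else:
        k = min(select_components_scree(model), smallest)
    k = max(k, 1)
    return model, k, transform(model, table.matrix(), n_components=k)


def _run_one(
    name: str,
    table: FeatureTable,
    design: PDFADesign,
    pdfa_config: PDFAConfig,
    heuristic: str,
    alpha: float,
    report: AnalysisReport,
) -> tuple[dict, object | None, object | None]:
    """Run one pDFA with PCA reduction; returns (row, pca_model, result)."""
    try:
        design.validate(table.df)
        model, k, scores = _pca_scores(table, design, heuristic)
        res = run_pdfa(table.df, design, pdfa_config, X=scores)
    except (PanthootError, ValueError) as exc:
        return _skipped_row(name, "", design, str(exc)), None, None
    n_ind, med, rng_str, total = _call_stats(table.df)
    row = {
        "analysis": name,
        "feature_set": "",
        "test_factor": design.test_factor,
        "design": design.design,
        "control_factor": design.control_factor,
        "restriction_factor": design.restriction_factor,
        "heuristic": heuristic,
        "n_components": k,
        "n_individuals": n_ind,
        "median_calls_per_individual": med,
        "calls_range": rng_str,
        "total_calls": total,
        "observed_accuracy_cv": res.observed_accuracy_cv,
        "expected_accuracy_cv": res.expected_accuracy_cv,
        "p_cv": res.p_cv,
        "significant": bool(res.p_cv < alpha) if np.isfinite(res.p_cv) else False,
        "skipped": False,
        "reason": "",
    }
    report.seeds[name] = pdfa_config.seed
    return row, model, res


def run_full_analysis(
    data: FeatureTable,
    plan: AnalysisPlan,
    config: PDFAConfig,
) -> AnalysisReport:
    """Execute the full decision logic; see the module docstring."""
    report = AnalysisReport(master_seed=config.seed)
    base, _ = apply_inclusion_filters(data, plan.min_calls)

    for fs in plan.feature_sets:
        fs_table, _ = select_feature_set(base, fs)
        primary_heuristic = plan.component_heuristics[0]

        # ---- 1. context test (crossed, control = individual) -------------
        ctx_design = PDFADesign(
            test_factor="context", control_factor="individual", design=CROSSED
        )
        ctx_table, _ = apply_context_filters(
            fs_table, plan.contexts, plan.min_per_context
        )
        context_significant = False
        ctx_model = None
        for heuristic in plan.component_heuristics:
            name = f"{fs.name}:context:{heuristic}"
            seed = analysis_seed(config.seed, name)
            cfg = dataclasses.replace(config, seed=seed)
            if ctx_table.n_calls == 0 or ctx_table.df["individual"].nunique() < 2:
                row = _skipped_row(
                    name, fs.name, ctx_design,
                    "too few individuals recorded in both contexts",
                )
            else:
                row, model, res = _run_one(
                    name, ctx_table, ctx_design, cfg, heuristic, plan.alpha, report
                )
                row["feature_set"] = fs.name
                if heuristic == primary_heuristic and not row["skipped"]:
                    context_significant = row["significant"]
                    ctx_model = model
            report.rows.append(row)

        # context repDFA + post-hoc on a significant context difference
        if context_significant and plan.run_importance:
            _context_followups(
                fs, ctx_table, ctx_design, ctx_model, plan, config, report
            )

        # ---- 2. community tests ------------------------------------------
        comm_design = PDFADesign(
            test_factor="community", control_factor="individual", design=NESTED
        )
        strata = (
            [(f"context={c}", ctx_table.subset_rows(ctx_table.df["context"] == c))
             for c in plan.contexts]
            if context_significant
            else [("", fs_table)]
        )
        for subset_name, levels in plan.community_subsets.items():
            for stratum_name, stratum_table in strata:
                sub = (
                    stratum_table
                    if levels is None
                    else stratum_table.subset_rows(
                        stratum_table.df["community"].isin(levels)
                    )
                )
                for heuristic in plan.component_heuristics:
                    suffix = f":{stratum_name}" if stratum_name else ""
                    name = f"{fs.name}:community:{subset_name}{suffix}:{heuristic}"
                    seed = analysis_seed(config.seed, name)
                    cfg = dataclasses.replace(config, seed=seed)
                    row, model, res = _run_one(
                        name, sub, comm_design, cfg, heuristic, plan.alpha, report
                    )
                    row["feature_set"] = fs.name
                    report.rows.append(row)
                    if heuristic != primary_heuristic or row["skipped"]:
                        continue
                    communities = sorted(sub.df["community"].unique())
                    want_pairs = plan.pairwise == "always" or (
                        plan.pairwise == "if_significant" and row["significant"]
                    )
                    if want_pairs and len(communities) > 2:
                        _pairwise_runs(
                            fs, name, sub, comm_design, cfg, plan, report, communities
                        )
                    if row["significant"] and plan.run_importance:
                        _nested_importance(fs, name, sub, comm_design, plan, cfg, report)

        # ---- 3. individual test (nested, restriction = community) --------
        ind_design = PDFADesign(
            test_factor="individual",
            restriction_factor="community",
            design=NESTED,
        )
        for heuristic in plan.component_heuristics:
            name = f"{fs.name}:individual:{heuristic}"
            seed = analysis_seed(config.seed, name)
            cfg = dataclasses.replace(config, seed=seed)
            row, model, res = _run_one(
                name, fs_table, ind_design, cfg, heuristic, plan.alpha, report
            )
            row["feature_set"] = fs.name
            report.rows.append(row)
            if (
                heuristic == primary_heuristic
                and not row["skipped"]
                and row["significant"]
                and plan.run_importance
            ):
                _nested_importance(fs, name, fs_table, ind_design, plan, cfg, report)

    return report


def _pairwise_runs(fs, parent_name, table, design, cfg, plan, report, communities):
    """Two-community follow-up pDFAs; each pair gets its own PCA reduction.

    Pairwise p-values are reported without multiplicity correction, as
    descriptive follow-ups to the omnibus result.
    """
    pairs = [(a, b) for i, a in enumerate(communities) for b in communities[i + 1:]]
    for a, b in pairs:
        name = f"{parent_name}:pair:{a}-{b}"
        sub = table.subset_rows(table.df["community"].isin([a, b]).to_numpy())
        pair_cfg = dataclasses.replace(cfg, seed=analysis_seed(cfg.seed, name))
        row, _, _ = _run_one(
            name, sub, design, pair_cfg, plan.component_heuristics[0], plan.alpha, report
        )
        row["feature_set"] = fs.name
        if not row["skipped"]:
            row["reason"] = "no multiplicity correction applied to pairwise tests"
        report.rows.append(row)


def _context_followups(fs, ctx_table, ctx_design, ctx_model, plan, config, report):
    """repDFA on PC scores + Poisson mixed models on implicated count features."""
    heuristic = plan.component_heuristics[0]
    try:
        model, k, scores = _pca_scores(ctx_table, ctx_design, heuristic)
        seed = analysis_seed(config.seed, f"{fs.name}:context:repdfa")
        imp = run_repdfa(
            ctx_table.df,
            ctx_design,
            n_runs=plan.n_repdfa_runs,
            rng=np.random.default_rng(seed),
            X=scores,
        )
    except (PanthootError, ValueError) as exc:
        report.importance.append(
            {"analysis": f"{fs.name}:context", "skipped": True, "reason": str(exc)}
        )
        return
    pc_names = [f"PC{i + 1}" for i in range(k)]
    df1 = {pc_names[int(v[3:]) - 1]: c for v, c in imp.top_df1_counts.items()}
    report.importance.append(
        {
            "analysis": f"{fs.name}:context",
            "mode": "crossed",
            "n_runs": imp.n_runs,
            "top_df1_counts": df1,
            "top_df2_counts": (
                None
                if imp.top_df2_counts is None
                else {pc_names[int(v[3:]) - 1]: c for v, c in imp.top_df2_counts.items()}
            ),
        }
    )
    if not plan.run_posthoc:
        return
    # highest-loading original features on the winning PC, count family first
    winner = max(df1.items(), key=lambda kv: kv[1])[0]
    pc_idx = int(winner[2:]) - 1
    loadings = np.abs(model.loadings[:, pc_idx])
    order = np.argsort(loadings)[::-1]
    candidates = [model.feature_names[i] for i in order[:3]]
    results = []
    for feat in candidates:
        fam = ctx_table.feature_family.get(feat, "continuous")
        vals = ctx_table.df[feat].to_numpy()
        fixed = ctx_table.df["context"].to_numpy()
        random = ctx_table.df["individual"].to_numpy()
        try:
            if fam == "count":
                results.append(fit_mixed_count(vals, fixed, random, feature=feat))
            else:
                results.append(fit_mixed_gaussian(vals, fixed, random, feature=feat))
        except (ValueError, PanthootError) as exc:
            report.posthoc.append(
                {"analysis": f"{fs.name}:context", "feature": feat,
                 "skipped": True, "reason": str(exc)}
            )
    if results:
        adjust_batch(results)
        for r in results:
            d = r.to_dict()
            d["analysis"] = f"{fs.name}:context"
            d["skipped"] = False
            report.posthoc.append(d)


def _nested_importance(fs, parent_name, table, design, plan, cfg, report):
    try:
        model, k, scores = _pca_scores(table, design, plan.component_heuristics[0])
        seed = analysis_seed(cfg.seed, f"{parent_name}:repdfa")
        imp = run_repdfa_nested(
            table.df,
            design,
            n_runs=plan.n_repdfa_runs,
            rng=np.random.default_rng(seed),
            X=scores,
        )
    except (PanthootError, ValueError) as exc:
        report.importance.append(
            {"analysis": parent_name, "skipped": True, "reason": str(exc)}
        )
        return
    pc_names = [f"PC{i + 1}" for i in range(k)]
    report.importance.append(
        {
            "analysis": parent_name,
            "mode": "nested",
            "n_runs": imp.n_runs,
            "top_df1_counts": {
                pc_names[int(v[3:]) - 1]: c for v, c in imp.top_df1_counts.items()
            },
            "top_df2_counts": (
                None
                if imp.top_df2_counts is None
                else {pc_names[int(v[3:]) - 1]: c for v, c in imp.top_df2_counts.items()}
            ),
        }
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_report(
    report: AnalysisReport, fmt: str, out_dir: str | Path
) -> Path:
    """Write the report as ``json`` (lossless), ``csv`` or ``markdown``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = out_dir / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, allow_nan=True))
        return path
    if fmt == "csv":
        path = out_dir / "report.csv"
        pd.DataFrame(report.rows, columns=ROW_COLUMNS).to_csv(path, index=False)
        return path
    if fmt == "markdown":
        path = out_dir / "report.md"
        lines = ["| " + " | ".join(ROW_COLUMNS) + " |",
                 "|" + "---|" * len(ROW_COLUMNS)]
        for row in report.rows:
            lines.append(
                "| " + " | ".join(str(row.get(c, "")) for c in ROW_COLUMNS) + " |"
            )
        path.write_text("\n".join(lines) + "\n")
        return path
    raise ValueError(f"unknown format {fmt!r}")


def load_report(path: str | Path) -> AnalysisReport:
    return AnalysisReport.from_dict(json.loads(Path(path).read_text()))
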