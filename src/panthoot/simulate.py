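"""Hierarchical synthetic call-feature generator.

Emulates the structure the analysis assumes: communities, individuals nested
within communities, behavioural contexts, and within-individual noise.  A
feature's value for call *j* of individual *i* in community *k* is

* gaussian:  ``x = mu + c_k + a_i + g_context + eps``,
  ``c_k ~ N(0, sigma_community)``, ``a_i ~ N(0, sigma_individual)``,
  ``eps ~ N(0, sigma_residual)``;
* poisson:   ``count ~ Poisson(exp(eta))`` with the same linear predictor on
  the log scale (residual variation is the Poisson noise itself);
* bernoulli: analogous on the logit scale.

Count features may be tied to a pant-hoot phase: a zero count sets the
matching phase flag to ``False`` (phase absent), mirroring how real tables
encode phase structure.  Setting ``sigma_community = 0`` for every feature
gives the exchangeability null for the community test — the calibration
harness uses exactly that.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import FeatureTable, PHASES
from .errors import ConfigError
from .pca import fit_pca, select_components_cap, transform
from .pdfa import NESTED, PDFAConfig, PDFADesign, run_pdfa

FAMILIES = ("gaussian", "poisson", "bernoulli")


@dataclass
class FeatureSpec:
    """Variance-component specification for one simulated feature.

    ``mean`` is the grand mean (gaussian) or the intercept on the log/logit
    scale (poisson/bernoulli).  ``context_effects`` maps context label ->
    additive shift on the same scale.  ``phase``: pant-hoot phase whose
    presence flag this count encodes (count 0 => flag False).
    """

    name: str
    family: str = "gaussian"
    mean: float = 0.0
    sigma_community: float = 0.0
    sigma_individual: float = 0.0
    sigma_residual: float = 1.0
    context_effects: dict[str, float] = field(default_factory=dict)
    phase: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}")
        for s in (self.sigma_community, self.sigma_individual, self.sigma_residual):
            if s < 0:
                raise ConfigError("sigmas must be non-negative")
        if self.phase is not None and self.phase not in PHASES:
            raise ConfigError(f"unknown phase {self.phase!r}")


@dataclass
class SimConfig:
    """Design and variance components for one simulated study."""

    n_communities: int = 3
    individuals_per_community: list[int] = field(default_factory=lambda: [6, 5, 7])
    calls_per_individual: tuple[int, int] | list[int] = (8, 45)
    context_proportions: dict[str, float] = field(
        default_factory=lambda: {"feed": 0.55, "travel": 0.45}
    )
    feature_specs: list[FeatureSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0
    community_names: list[str] | None = None
    site_of_community: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.individuals_per_community) != self.n_communities:
            raise ConfigError("individuals_per_community length must match n_communities")
        total = sum(self.context_proportions.values())
        if not np.isclose(total, 1.0):
            raise ConfigError("context proportions must sum to 1")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if not self.feature_specs:
            raise ConfigError("at least one feature spec is required")


@dataclass
class SimTruth:
    """Realized random effects per feature, plus the generating config."""

    config: SimConfig
    community_effects: dict[str, np.ndarray]
    individual_effects: dict[str, np.ndarray]


def _community_names(config: SimConfig) -> list[str]:
    if config.community_names is not None:
        if len(config.community_names) != config.n_communities:
            raise ConfigError("community_names length mismatch")
        return list(config.community_names)
    return [f"community_{chr(ord('A') + k)}" for k in range(config.n_communities)]


def simulate_dataset(config: SimConfig) -> tuple[FeatureTable, SimTruth]:
    """Draw one complete call-feature table from the hierarchical model."""
    rng = np.random.default_rng(config.seed)
    comms = _community_names(config)
    site_of = config.site_of_community or {c: f"site_{c}" for c in comms}

    individuals: list[tuple[str, str]] = []  # (community, individual id)
    for k, n_ind in enumerate(config.individuals_per_community):
        for i in range(n_ind):
            individuals.append((comms[k], f"{comms[k]}_m{i + 1:02d}"))
    n_ind_total = len(individuals)

    if isinstance(config.calls_per_individual, (tuple, list)) and len(
        config.calls_per_individual
    ) == 2 and not isinstance(config.calls_per_individual, list):
        lo, hi = config.calls_per_individual
        calls_per_ind = rng.integers(lo, hi + 1, size=n_ind_total)
    else:
        calls_per_ind = np.asarray(list(config.calls_per_individual))
        if len(calls_per_ind) != n_ind_total:
            raise ConfigError("calls_per_individual list length must equal total individuals")

    ctx_labels = list(config.context_proportions)
    ctx_probs = np.array([config.context_proportions[c] for c in ctx_labels])

    rows = []
    for (comm, ind), n_calls in zip(individuals, calls_per_ind):
        contexts = rng.choice(ctx_labels, size=n_calls, p=ctx_probs)
        for j, ctx in enumerate(contexts):
            rows.append(
                {
                    "call_id": f"{ind}_c{j + 1:03d}",
                    "site": site_of[comm],
                    "community": comm,
                    "individual": ind,
                    "context": ctx,
                }
            )
    df = pd.DataFrame(rows)
    comm_idx = df["community"].map({c: k for k, c in enumerate(comms)}).to_numpy()
    ind_idx = df["individual"].map(
        {ind: i for i, (_, ind) in enumerate(individuals)}
    ).to_numpy()
    n_rows = len(df)

    community_effects: dict[str, np.ndarray] = {}
    individual_effects: dict[str, np.ndarray] = {}
    feature_names: list[str] = []
    family_map: dict[str, str] = {}
    phase_flags = {p: np.ones(n_rows, dtype=bool) for p in PHASES}
    phase_flags["drumming"] = np.zeros(n_rows, dtype=bool)

    for spec in config.feature_specs:
        c_eff = rng.normal(0.0, spec.sigma_community, size=config.n_communities)
        a_eff = rng.normal(0.0, spec.sigma_individual, size=n_ind_total)
        g_eff = df["context"].map(lambda c: spec.context_effects.get(c, 0.0)).to_numpy()
        eta = spec.mean + c_eff[comm_idx] + a_eff[ind_idx] + g_eff
        if spec.family == "gaussian":
            x = eta + rng.normal(0.0, spec.sigma_residual, size=n_rows)
            family_map[spec.name] = "continuous"
        elif spec.family == "poisson":
            x = rng.poisson(np.exp(eta)).astype(float)
            family_map[spec.name] = "count"
        else:
            p = 1.0 / (1.0 + np.exp(-eta))
            x = rng.binomial(1, p).astype(float)
            family_map[spec.name] = "binary"
        if config.missing_rate > 0:
            miss = rng.random(n_rows) < config.missing_rate
            x = np.where(miss, np.nan, x)
        df[spec.name] = x
        feature_names.append(spec.name)
        community_effects[spec.name] = c_eff
        individual_effects[spec.name] = a_eff
        if spec.phase is not None and spec.family == "poisson":
            phase_flags[spec.phase] &= ~(df[spec.name].fillna(1.0).to_numpy() == 0)

    for p in PHASES:
        df[f"has_{p}"] = phase_flags[p]

    table = FeatureTable(df, feature_names, family_map)
    return table, SimTruth(config, community_effects, individual_effects)


def simulate_null(config: SimConfig) -> tuple[FeatureTable, SimTruth]:
    """Same generator with every feature's community variance forced to zero.

    Individual and context effects are retained — this is the
    exchangeability null for the community test, not an i.i.d. null.
    """
    null_specs = [replace(s, sigma_community=0.0) for s in config.feature_specs]
    return simulate_dataset(replace(config, feature_specs=null_specs))


# ---------------------------------------------------------------------------
# ready-made configurations
# ---------------------------------------------------------------------------


def study_shaped_config(
    seed: int = 0,
    sigma_community: float = 0.0,
    sigma_individual: float = 1.0,
    sigma_residual: float = 1.0,
    calls_per_individual: tuple[int, int] = (8, 45),
    n_features: int = 5,
) -> SimConfig:
    """Three communities (6/5/7 males, 8-45 calls each), two contexts, and a
    compact continuous feature block sharing one set of variance components.

    Count features for the post-hoc path carry the context shifts the
    study's post-hoc table reports (more let-down and build-up elements when
    travelling, fewer climax elements).
    """
    specs = [
        FeatureSpec(
            name=f"acoustic_{i + 1}",
            family="gaussian",
            mean=0.0,
            sigma_community=sigma_community,
            sigma_individual=sigma_individual,
            sigma_residual=sigma_residual,
        )
        for i in range(n_features)
    ]
    specs += [
        FeatureSpec(
            name="n_letdown_elements", family="poisson", mean=0.3,
            sigma_individual=0.3, context_effects={"travel": 0.57}, phase="letdown",
        ),
        FeatureSpec(
            name="n_buildup_elements", family="poisson", mean=1.2,
            sigma_individual=0.3, context_effects={"travel": 0.34}, phase="buildup",
        ),
        FeatureSpec(
            name="n_climax_elements", family="poisson", mean=1.1,
            sigma_individual=0.3, context_effects={"travel": -0.27}, phase="climax",
        ),
    ]
    return SimConfig(
        n_communities=3,
        individuals_per_community=[6, 5, 7],
        calls_per_individual=calls_per_individual,
        feature_specs=specs,
        seed=seed,
    )


def calibration_config(
    seed: int = 0,
    sigma_community: float = 0.0,
    calls_per_individual: tuple[int, int] = (8, 30),
    n_features: int = 4,
) -> SimConfig:
    """Study-shaped design trimmed for repeated calibration runs."""
    specs = [
        FeatureSpec(
            name=f"acoustic_{i + 1}",
            family="gaussian",
            sigma_community=sigma_community,
            sigma_individual=1.0,
            sigma_residual=1.0,
        )
        for i in range(n_features)
    ]
    return SimConfig(
        n_communities=3,
        individuals_per_community=[6, 5, 7],
        calls_per_individual=calls_per_individual,
        feature_specs=specs,
        seed=seed,
    )


def run_calibration(
    config: SimConfig,
    n_datasets: int,
    pdfa_config: PDFAConfig,
    design: PDFADesign | None = None,
    alpha: float = 0.05,
    use_pca: bool = True,
) -> dict:
    """Type-I error / power harness: simulate -> pDFA, ``n_datasets`` times.

    Returns the rejection fraction at ``alpha`` on cross-validated accuracy
    and the empirical p-value distribution.  Dataset and permutation seeds
    are all derived from ``config.seed``.
    """
    if design is None:
        design = PDFADesign(
            test_factor="community", control_factor="individual", design=NESTED
        )
    master = np.random.default_rng(config.seed)
    data_seeds = master.integers(0, 2**31 - 1, size=n_datasets)
    perm_seeds = master.integers(0, 2**31 - 1, size=n_datasets)

    p_values = np.empty(n_datasets)
    for d in range(n_datasets):
        cfg = replace(config, seed=int(data_seeds[d]))
        table, _ = simulate_dataset(cfg)
        X = table.matrix()
        if use_pca:
            model = fit_pca(X, table.feature_names, standardize=True)
            smallest = table.df[design.test_factor].value_counts().min()
            k = select_components_cap(model, int(smallest))
            X = transform(model, table.matrix(), n_components=k)
        cfg_p = replace(pdfa_config, seed=int(perm_seeds[d]))
        res = run_pdfa(table, design, cfg_p, X=X)
        p_values[d] = res.p_cv
    return {
        "n_datasets": n_datasets,
        "alpha": alpha,
        "rejection_rate": float(np.mean(p_values < alpha)),
        "p_values": p_values,
    }
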