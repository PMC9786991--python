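import numpy as np
import pandas as pd
import pytest

from panthoot.data import FeatureTable, PHASES


def make_table(rows: list[dict], feature_names: list[str],
               families: dict[str, str] | None = None) -> FeatureTable:
    """Build a FeatureTable from row dicts, filling factor defaults."""
    df = pd.DataFrame(rows)
    for col, default in [("site", "s1"), ("community", "c1"), ("context", "unknown")]:
        if col not in df.columns:
            df[col] = default
    if "call_id" not in df.columns:
        df["call_id"] = [f"call_{i}" for i in range(len(df))]
    if families is None:
        families = {f: "continuous" for f in feature_names}
    return FeatureTable(df, feature_names, families)


def crossed_table(n_ind=6, calls_per_cell=(5, 5), effect=0.0, n_features=3,
                  seed=0, cell_jitter=0) -> FeatureTable:
    """Two-context table, every individual recorded in both contexts.

    ``effect`` shifts feature 1 in the travel context; ``cell_jitter`` makes
    cell sizes unequal so balanced subsampling actually subsamples.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ind):
        for ctx, base in zip(("feed", "travel"), calls_per_cell):
            n = base + (rng.integers(0, cell_jitter + 1) if cell_jitter else 0)
            for j in range(n):
                feats = rng.normal(0, 1, n_features)
                if ctx == "travel":
                    feats[0] += effect
                rows.append(
                    dict(
                        individual=f"m{i:02d}",
                        context=ctx,
                        **{f"f{k + 1}": feats[k] for k in range(n_features)},
                    )
                )
    return make_table(rows, [f"f{k + 1}" for k in range(n_features)])


def nested_table(ind_per_comm=(3, 3), calls=(6, 10), comm_effect=0.0,
                 ind_effect=1.0, n_features=3, seed=0) -> FeatureTable:
    """Individuals nested in communities, gaussian features."""
    rng = np.random.default_rng(seed)
    rows = []
    for c, n_ind in enumerate(ind_per_comm):
        comm = f"comm{c}"
        c_eff = rng.normal(0, comm_effect, n_features)
        for i in range(n_ind):
            a_eff = rng.normal(0, ind_effect, n_features)
            n = int(rng.integers(calls[0], calls[1] + 1))
            for j in range(n):
                feats = c_eff + a_eff + rng.normal(0, 1, n_features)
                rows.append(
                    dict(
                        community=comm,
                        individual=f"{comm}_m{i}",
                        context=rng.choice(["feed", "travel"]),
                        **{f"f{k + 1}": feats[k] for k in range(n_features)},
                    )
                )
    return make_table(rows, [f"f{k + 1}" for k in range(n_features)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
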