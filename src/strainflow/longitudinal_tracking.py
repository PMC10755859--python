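"""Per-infant strain trajectories and colonization statistics.

Turns per-sample strain categories into infant × visit trajectories and
computes the headline longitudinal quantities: detection rates by visit
and group, probiotic colonization during supplementation (V2 and/or V3),
persistence after cessation (V4), strain replacement events between
consecutive typed visits, and chi-square association tests between
category distributions and grouping factors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

PROBIOTIC_CAT = "LMG11588"
OTHER_CAT = "OtherInfantis"
TYPED = (PROBIOTIC_CAT, OTHER_CAT)
DETECTED = (PROBIOTIC_CAT, OTHER_CAT, "UntypedLow", "UntypedHet")


def build_trajectories(
    classifications: pd.DataFrame,
    metadata: pd.DataFrame,
    visits: tuple[str, ...] = ("V1", "V2", "V3", "V4"),
) -> pd.DataFrame:
    """One row per infant with ordered per-visit categories (NaN = missing).

    ``classifications`` needs sample_id + category; ``metadata`` maps
    sample_id to infant_id/visit and carries arm and feeding mode.
    """
    merged = classifications.merge(
        metadata[["sample_id", "infant_id", "visit", "arm", "feeding"]], on="sample_id"
    )
    dup = merged.duplicated(subset=["infant_id", "visit"])
    if dup.any():
        raise ValueError("more than one sample per infant and visit")
    wide = merged.pivot(index="infant_id", columns="visit", values="category")
    wide = wide.reindex(columns=list(visits))
    meta = merged.drop_duplicates("infant_id").set_index("infant_id")[["arm", "feeding"]]
    out = meta.join(wide).reset_index()
    out.columns.name = None
    return out


def detection_rate(
    trajectories: pd.DataFrame,
    visit: str,
    categories: tuple[str, ...] = DETECTED,
    group_by: str | None = None,
    exclude_missing: bool = True,
) -> pd.DataFrame:
    """Fraction of infants whose category at `visit` lies in `categories`.

    Denominators exclude infants with a missing sample at the visit when
    ``exclude_missing`` (the default); both numerator and denominator are
    reported.
    """
    if visit not in trajectories.columns:
        raise KeyError(f"visit {visit!r} not present")
    df = trajectories if group_by is None else trajectories
    keys = [group_by] if group_by else []

    def _one(g: pd.DataFrame) -> pd.Series:
        col = g[visit]
        denom = col.notna().sum() if exclude_missing else len(col)
        num = col.isin(categories).sum()
        if denom == 0:
            warnings.warn("empty group in detection_rate")
            return pd.Series({"n_positive": 0, "n_total": 0, "rate": np.nan})
        return pd.Series({"n_positive": int(num), "n_total": int(denom), "rate": num / denom})

    if keys:
        res = df.groupby(keys[0], observed=True).apply(_one, include_groups=False).reset_index()
    else:
        res = _one(df).to_frame().T
    res[["n_positive", "n_total"]] = res[["n_positive", "n_total"]].astype(int)
    return res


def colonized_during_intervention(row: pd.Series) -> bool | None:
    """Probiotic detected at V2 and/or V3; None when both visits are missing."""
    v2, v3 = row.get("V2"), row.get("V3")
    if pd.isna(v2) and pd.isna(v3):
        return None
    return (v2 == PROBIOTIC_CAT) or (v3 == PROBIOTIC_CAT)


def intervention_colonization_rate(trajectories: pd.DataFrame) -> dict:
    """Fraction of infants with the probiotic at V2 and/or V3 (undefined excluded)."""
    flags = trajectories.apply(colonized_during_intervention, axis=1)
    valid = flags.dropna()
    return {
        "n_colonized": int(valid.sum()),
        "n_total": int(len(valid)),
        "rate": float(valid.mean()) if len(valid) else np.nan,
    }


def persistence_rate(trajectories: pd.DataFrame) -> dict:
    """Among infants colonized during supplementation with a usable V4
    sample, the fraction still carrying the probiotic at V4.  A V4 sample
    typed as another strain counts as non-persistent."""
    flags = trajectories.apply(colonized_during_intervention, axis=1)
    eligible = trajectories[(flags == True) & trajectories["V4"].notna()]  # noqa: E712
    if eligible.empty:
        warnings.warn("no eligible infants for persistence")
        return {"n_persisting": 0, "n_total": 0, "rate": np.nan}
    persisting = (eligible["V4"] == PROBIOTIC_CAT).sum()
    return {
        "n_persisting": int(persisting),
        "n_total": int(len(eligible)),
        "rate": float(persisting / len(eligible)),
    }


def replacement_events(
    trajectories: pd.DataFrame, visits: tuple[str, ...] = ("V1", "V2", "V3", "V4")
) -> dict:
    """Counts of infants with ≥1 strain replacement between consecutive visits.

    Only transitions between *consecutively typed* visits count: an
    untyped or missing visit breaks adjacency, so no event is inferred
    across it.
    """
    n_prob_to_other = 0
    n_other_to_prob = 0
    for _, row in trajectories.iterrows():
        p2o = o2p = False
        for a, b in zip(visits[:-1], visits[1:]):
            ca, cb = row.get(a), row.get(b)
            if ca in TYPED and cb in TYPED and ca != cb:
                if ca == PROBIOTIC_CAT:
                    p2o = True
                else:
                    o2p = True
        n_prob_to_other += p2o
        n_other_to_prob += o2p
    return {"probiotic_to_other": n_prob_to_other, "other_to_probiotic": n_other_to_prob}


def flat_table_rates(
    classifications: pd.DataFrame, metadata: pd.DataFrame,
    visits: tuple[str, ...] = ("V1", "V2", "V3", "V4"),
) -> dict:
    """Detection/colonization/persistence computed by flat-table aggregation.

    An independent route to the trajectory-scan results, used to check the
    two agree exactly.
    """
    merged = classifications.merge(
        metadata[["sample_id", "infant_id", "visit"]], on="sample_id"
    )
    per_visit = {}
    for v in visits:
        sub = merged[merged["visit"] == v]
        per_visit[v] = {
            "n_positive": int(sub["category"].isin(DETECTED).sum()),
            "n_total": int(len(sub)),
        }
    col = merged[merged["visit"].isin(("V2", "V3"))]
    colonized = set(col.loc[col["category"] == PROBIOTIC_CAT, "infant_id"])
    has_intervention_sample = set(col["infant_id"])
    v4 = merged[merged["visit"] == "V4"]
    eligible = v4[v4["infant_id"].isin(colonized)]
    return {
        "detection": per_visit,
        "colonized_infants": len(colonized),
        "intervention_denominator": len(has_intervention_sample),
        "persistence": {
            "n_persisting": int((eligible["category"] == PROBIOTIC_CAT).sum()),
            "n_total": int(len(eligible)),
        },
    }


def category_group_test(
    contingency: pd.DataFrame | np.ndarray,
    monte_carlo: int = 0,
    seed: int | None = None,
) -> dict:
    """Pearson chi-square test of a category × group contingency table.

    Zero-margin rows/columns are dropped with a warning.  With
    ``monte_carlo`` > 0 the p-value is estimated by simulating tables
    with fixed margins (add-one rule), which is preferable for sparse
    tables; a warning is raised when any expected count is below 5.
    """
    table = np.asarray(contingency, dtype=float)
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping zero-margin rows/columns")
        table = table[keep_r][:, keep_c]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return {"statistic": 0.0, "p": 1.0, "df": 0}
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("expected counts below 5; consider monte_carlo p")
    out = {"statistic": float(res.statistic), "p": float(res.pvalue), "df": int(res.dof)}
    if monte_carlo > 0:
        rng = np.random.default_rng(seed)
        obs = res.statistic
        row_m = table.sum(axis=1).astype(int)
        col_m = table.sum(axis=0).astype(int)
        labels = np.repeat(np.arange(len(col_m)), col_m)
        row_of = np.repeat(np.arange(len(row_m)), row_m)
        exceed = 0
        for _ in range(monte_carlo):
            perm = rng.permutation(labels)
            sim = np.zeros_like(table)
            np.add.at(sim, (row_of, perm), 1.0)
            e = np.outer(row_m, col_m) / table.sum()
            stat = ((sim - e) ** 2 / e).sum()
            exceed += stat >= obs - 1e-12
        out["p_mc"] = (1 + exceed) / (1 + monte_carlo)
    return out


def feeding_association(
    trajectories: pd.DataFrame,
    visit: str = "V4",
    categories: tuple[str, ...] = TYPED,
    monte_carlo: int = 0,
    seed: int | None = None,
) -> dict:
    """Chi-square association between feeding mode and colonization at a visit."""
    df = trajectories[trajectories[visit].notna()]
    colonized = df[visit].isin(categories)
    tab = pd.crosstab(df["feeding"], colonized)
    return category_group_test(tab, monte_carlo=monte_carlo, seed=seed)


def summarize(trajectories: pd.DataFrame) -> dict:
    """All headline longitudinal rates in one JSON-ready dict."""
    out = {
        "baseline_detection": detection_rate(trajectories, "V1").iloc[0].to_dict(),
        "intervention_colonization": intervention_colonization_rate(
            trajectories[trajectories["arm"] != "CG"]
        ),
        "persistence": persistence_rate(trajectories[trajectories["arm"] != "CG"]),
        "replacement": replacement_events(trajectories[trajectories["arm"] != "CG"]),
        "other_infantis_v4": detection_rate(trajectories, "V4", (OTHER_CAT,)).iloc[0].to_dict(),
    }
    return out
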