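"""Microbiome ecology statistics: diversity, ordination, PERMANOVA with
marginal terms, Procrustes association, taxon-biomarker correlation, and
pathogen prevalence.

Beta diversity uses Bray-Curtis dissimilarity with principal-coordinates
ordination; group effects are tested by distance-based PERMANOVA with
marginal (type-III-like) sums of squares — each term's SS is the drop
from the full model when that term is removed — and permutation p-values
with the add-one rule.  Taxon-biomarker association uses Kendall's tau-b
with Benjamini-Hochberg adjustment across the whole matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .trial_stats import bh_adjust

INFANT_TYPE_BIFIDO = ["B. longum", "B. breve", "B. bifidum", "B. scardovii"]


# ---------------------------------------------------------------------------
# taxon aggregation and diversity
# ---------------------------------------------------------------------------


def aggregate_infant_type_bifido(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    species: list[str] | None = None,
) -> pd.Series:
    """Per-sample summed abundance of the infant-type bifidobacteria
    (*B. longum* incl. both subspecies, *B. breve*, *B. bifidum*,
    *B. scardovii*).

    ``taxonomy`` (optional) maps table columns to species names via
    columns ``taxon``/``species``; otherwise table columns are matched by
    species-name prefix so subspecies-level columns roll up.  Absent
    species contribute zero (warned once).
    """
    species = species or INFANT_TYPE_BIFIDO
    if taxonomy is not None:
        tx = taxonomy.set_index("taxon")["species"]
        cols = [c for c in table.columns if tx.get(c) in species]
    else:
        cols = [
            c for c in table.columns if any(c == s or c.startswith(s + " ") for s in species)
        ]
    found_species = set()
    for c in cols:
        for s in species:
            if (taxonomy is not None and taxonomy.set_index("taxon")["species"].get(c) == s) or (
                taxonomy is None and (c == s or c.startswith(s + " "))
            ):
                found_species.add(s)
    missing = set(species) - found_species
    if missing:
        warnings.warn(f"species absent from table, contributing 0: {sorted(missing)}")
    if not cols:
        return pd.Series(0.0, index=table.index)
    return table[cols].sum(axis=1)


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Observed richness and Shannon index (natural log) per sample."""
    arr = table.to_numpy(dtype=float)
    richness = (arr > 0).sum(axis=1)
    tot = arr.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, arr / np.where(tot > 0, tot, 1), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    out = pd.DataFrame(
        {"richness": richness, "shannon": shannon}, index=table.index
    )
    out["all_zero"] = tot.ravel() == 0
    return out


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix; zero-sum samples are flagged."""
    arr = table.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).any():
        warnings.warn("zero-sum samples present; their dissimilarities are undefined")
    d = squareform(pdist(arr, metric="braycurtis"))
    d = np.nan_to_num(d, nan=1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, [str(i) for i in table.index])


# ---------------------------------------------------------------------------
# PERMANOVA with marginal terms
# ---------------------------------------------------------------------------


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _design(meta: pd.DataFrame, terms: list[str]) -> dict[str, np.ndarray]:
    """Per-term design-matrix columns (dummy coding, no intercept column)."""
    mats = {}
    for t in terms:
        col = meta[t]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dm = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
        else:
            dm = col.to_numpy(dtype=float)[:, None]
        mats[t] = dm
    return mats


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def _permanova_stats(g: np.ndarray, mats: dict[str, np.ndarray]) -> dict:
    n = g.shape[0]
    ones = np.ones((n, 1))
    full_x = np.hstack([ones] + list(mats.values()))
    h_full = _hat(full_x)
    ss_total = float(np.trace(g))
    ss_model = float(np.trace(h_full @ g))
    resid = np.eye(n) - h_full
    ss_resid = float(np.trace(resid @ g @ resid))
    df_resid = n - np.linalg.matrix_rank(full_x)
    out = {"ss_total": ss_total, "ss_resid": ss_resid, "df_resid": df_resid, "terms": {}}
    for t in mats:
        reduced = np.hstack([ones] + [m for u, m in mats.items() if u != t])
        h_red = _hat(reduced)
        ss_t = ss_model - float(np.trace(h_red @ g))
        df_t = np.linalg.matrix_rank(full_x) - np.linalg.matrix_rank(reduced)
        f = (ss_t / df_t) / (ss_resid / df_resid) if df_t > 0 and ss_resid > 0 else np.nan
        out["terms"][t] = {"ss": ss_t, "df": df_t, "F": f, "R2": ss_t / ss_total}
    return out


def permanova(
    dist: DistanceMatrix | np.ndarray,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Distance-based PERMANOVA with marginal sums of squares.

    Each term's SS is SS(full) − SS(full minus term); the permutation
    p-value permutes raw sample labels (rows of the metadata) with the
    add-one rule, so p is never exactly zero.  Collinear terms raise an
    error naming them.
    """
    if isinstance(dist, DistanceMatrix):
        ids = list(dist.ids)
        d = dist.data
        meta = metadata.loc[ids]
    else:
        d = np.asarray(dist, dtype=float)
        meta = metadata
    if meta.isna().any().any():
        raise ValueError("metadata must be complete for all samples in the distance matrix")
    mats = _design(meta, terms)
    full = np.hstack([np.ones((d.shape[0], 1))] + list(mats.values()))
    if np.linalg.matrix_rank(full) < full.shape[1]:
        for t in terms:
            others = np.hstack(
                [np.ones((d.shape[0], 1))] + [m for u, m in mats.items() if u != t]
            )
            if np.linalg.matrix_rank(np.hstack([others, mats[t]])) < np.linalg.matrix_rank(
                others
            ) + mats[t].shape[1]:
                raise ValueError(f"collinear term: {t}")
    g = _gower_center(d)
    obs = _permanova_stats(g, mats)
    rng = np.random.default_rng(seed)
    exceed = {t: 0 for t in terms}
    n = d.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pm = {t: m[perm] for t, m in mats.items()}
        sim = _permanova_stats(g, pm)
        for t in terms:
            if sim["terms"][t]["F"] >= obs["terms"][t]["F"] - 1e-12:
                exceed[t] += 1
    rows = []
    for t in terms:
        o = obs["terms"][t]
        rows.append(
            {
                "term": t,
                "df": o["df"],
                "ss": o["ss"],
                "R2": o["R2"],
                "F": o["F"],
                "p": (1 + exceed[t]) / (1 + n_perm),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PCoAResult:
    samples: pd.DataFrame  # coordinates, axes sorted by descending eigenvalue
    eigvals: pd.Series     # all eigenvalues, negatives reported as-is

    @property
    def proportion_explained(self) -> pd.Series:
        pos = self.eigvals.clip(lower=0)
        return pos / pos.sum()


def pcoa(dist: DistanceMatrix | np.ndarray) -> PCoAResult:
    """Principal-coordinates analysis of a dissimilarity matrix.

    Eigendecomposition of the Gower-centered matrix; axes are scaled by
    sqrt(eigenvalue) and sorted descending.  Negative eigenvalues (from
    non-Euclidean dissimilarities) are reported as-is; their axes carry
    zero coordinates.
    """
    if isinstance(dist, DistanceMatrix):
        ids = list(dist.ids)
        d = dist.data
    else:
        d = np.asarray(dist, dtype=float)
        ids = [str(i) for i in range(d.shape[0])]
    g = _gower_center(d)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = evecs * np.sqrt(np.clip(evals, 0, None))
    axes = [f"PC{i + 1}" for i in range(len(evals))]
    return PCoAResult(
        samples=pd.DataFrame(coords, index=ids, columns=axes),
        eigvals=pd.Series(evals, index=axes),
    )


# ---------------------------------------------------------------------------
# Procrustes association
# ---------------------------------------------------------------------------


def procrustes_correlation(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Symmetric Procrustes correlation PrC = sqrt(1 − m²) with a
    row-permutation p-value (permuting samples of the second ordination).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("both coordinate sets must cover the same samples")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    k = min(a.shape[1], b.shape[1])
    a, b = a[:, :k], b[:, :k]
    _, _, m2 = _scipy_procrustes(a, b)
    prc = float(np.sqrt(max(0.0, 1.0 - m2)))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, _, m2p = _scipy_procrustes(a, b[rng.permutation(b.shape[0])])
        if np.sqrt(max(0.0, 1.0 - m2p)) >= prc - 1e-12:
            hits += 1
    return {"prc": prc, "m2": float(m2), "p": (1 + hits) / (1 + n_perm)}


def biomarker_pca_coords(biomarkers: pd.DataFrame, n_components: int = 2) -> np.ndarray:
    """Standardized Euclidean PCA coordinates of a biomarker matrix."""
    x = biomarkers.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    u, s, _ = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    return u[:, :n_components] * s[:n_components]


# ---------------------------------------------------------------------------
# taxon-biomarker association
# ---------------------------------------------------------------------------


def kendall_associations(
    taxa: pd.DataFrame,
    biomarkers: pd.DataFrame,
    min_mean_abundance: float = 0.01,
    always_include: list[str] | None = None,
) -> pd.DataFrame:
    """Kendall tau-b between taxa and biomarkers, BH-adjusted.

    Taxa are filtered to mean abundance ≥ ``min_mean_abundance`` plus any
    nominated taxa of interest (e.g. *Bifidobacterium* members).
    Constant vectors give an undefined tau (flagged NaN, excluded from
    BH).  Significance convention: adjusted p < 0.1.
    """
    always = always_include or []
    keep = [
        c for c in taxa.columns if taxa[c].mean() >= min_mean_abundance or c in always
    ]
    common = taxa.index.intersection(biomarkers.index)
    taxa = taxa.loc[common, keep]
    biomarkers = biomarkers.loc[common]
    rows = []
    for tx in keep:
        for bm in biomarkers.columns:
            x, y = taxa[tx].to_numpy(), biomarkers[bm].to_numpy()
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
                tau, p = np.nan, np.nan
            else:
                tau, p = stats.kendalltau(x[ok], y[ok])
            rows.append({"taxon": tx, "biomarker": bm, "tau": tau, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < 0.1
    return out


# ---------------------------------------------------------------------------
# pathogen prevalence
# ---------------------------------------------------------------------------


def pathogen_prevalence(
    detections: pd.DataFrame, infant_of_sample: pd.Series
) -> pd.DataFrame:
    """Percent of positive samples and of positive infants per pathogen.

    ``detections`` is boolean samples × pathogens; an infant is positive
    if any of its samples is.  Infants without samples do not enter the
    infant denominator.
    """
    infant = pd.Series(infant_of_sample).reindex(detections.index)
    if infant.isna().any():
        raise KeyError("every sample needs an infant id")
    n_samples = len(detections)
    n_infants = infant.nunique()
    rows = []
    for col in detections.columns:
        pos = detections[col].astype(bool)
        pos_infants = infant[pos].nunique()
        rows.append(
            {
                "pathogen": col,
                "n_samples_positive": int(pos.sum()),
                "pct_samples": 100.0 * pos.sum() / n_samples,
                "n_infants_positive": int(pos_infants),
                "pct_infants": 100.0 * pos_infants / n_infants,
            }
        )
    return pd.DataFrame(rows)
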