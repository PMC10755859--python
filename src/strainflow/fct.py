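"""Fecal community typing via Dirichlet-multinomial mixtures.

Genus-level count vectors x_i are modeled as a K-component mixture where
component k draws taxon proportions p ~ Dirichlet(α_k) and counts
x | p ~ Multinomial(N_i, p).  Marginalizing p gives the
Dirichlet-multinomial with log pmf

    log DM(x | α) = log N! − Σ_j log x_j!
                  + log Γ(A) − log Γ(N + A)
                  + Σ_j [log Γ(x_j + α_j) − log Γ(α_j)],    A = Σ_j α_j.

Fitting is EM with responsibilities ∝ π_k DM(x | α_k) and Minka
fixed-point updates for α (monotone in the weighted likelihood).  Model
selection over K uses the Laplace approximation to the negative log model
evidence (primary criterion), with AIC and BIC always reported; the
number of free parameters is p = K·G + (K − 1).

Components are relabeled by chronological prevalence (ascending mean
visit index of their member samples) before any reporting, so community
types are numbered from early to late, and transition tables between
consecutive visits plus group-trajectory comparisons follow the same
labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, psi

from .longitudinal_tracking import category_group_test
from .trial_stats import bh_adjust

ALPHA_FLOOR = 1e-6


def dm_logpmf(counts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet-multinomial log pmf for (n, G) counts × (K, G) alphas → (n, K)."""
    x = np.asarray(counts, dtype=float)
    a = np.atleast_2d(np.asarray(alpha, dtype=float))
    N = x.sum(axis=1)
    A = a.sum(axis=1)
    coef = gammaln(N + 1) - gammaln(x + 1).sum(axis=1)
    core = (
        gammaln(A)[None, :]
        - gammaln(N[:, None] + A[None, :])
        + (gammaln(x[:, None, :] + a[None, :, :]) - gammaln(a)[None, :, :]).sum(axis=2)
    )
    return coef[:, None] + core


@dataclass
class DMMModel:
    """A fitted Dirichlet-multinomial mixture."""

    K: int
    pi: np.ndarray
    alpha: np.ndarray  # (K, G)
    responsibilities: np.ndarray  # (n, K)
    log_likelihood: float
    laplace: float
    aic: float
    bic: float
    converged: bool
    n_iter: int
    taxa: list[str] = field(default_factory=list)
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_parameters(self) -> int:
        return self.K * self.alpha.shape[1] + (self.K - 1)

    def assign(self) -> np.ndarray:
        """Max-posterior component labels, 1-based."""
        return self.responsibilities.argmax(axis=1) + 1


def _moment_match_alpha(props: np.ndarray) -> np.ndarray:
    """Method-of-moments Dirichlet fit to a set of proportion vectors."""
    mean = props.mean(axis=0)
    mean = np.clip(mean, 1e-8, None)
    mean /= mean.sum()
    var = props.var(axis=0)
    ok = (var > 1e-12) & (mean > 1e-6) & (mean < 1 - 1e-6)
    if ok.sum() == 0:
        s = 10.0
    else:
        s = np.clip(np.median(mean[ok] * (1 - mean[ok]) / var[ok] - 1), 1.0, 1e4)
    return np.clip(s * mean, ALPHA_FLOOR, None)


def _kmeanspp_partition(props: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding plus a few Lloyd iterations on proportion vectors.

    A handful of Lloyd refinements after seeding matters: one-shot
    seed assignment occasionally under-seeds a cluster, which leaves EM in
    a local optimum that distorts model selection across K.
    """
    n = props.shape[0]
    centers = [props[rng.integers(n)]]
    for _ in range(1, K):
        d2 = np.min(
            [((props - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        tot = d2.sum()
        p = d2 / tot if tot > 0 else np.full(n, 1.0 / n)
        centers.append(props[rng.choice(n, p=p)])
    centers = np.stack(centers)
    labels = np.zeros(n, dtype=int)
    for _ in range(10):
        d = ((props[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d.argmin(axis=1)
        if (new_labels == labels).all():
            break
        labels = new_labels
        for k in range(K):
            if (labels == k).any():
                centers[k] = props[labels == k].mean(axis=0)
    return labels


def _update_alpha(
    x: np.ndarray, r_k: np.ndarray, alpha: np.ndarray, inner_iters: int = 3
) -> np.ndarray:
    """Minka fixed-point ascent on the responsibility-weighted DM likelihood."""
    N = x.sum(axis=1)
    a = alpha.copy()
    for _ in range(inner_iters):
        A = a.sum()
        num = (r_k[:, None] * (psi(x + a[None, :]) - psi(a)[None, :])).sum(axis=0)
        den = (r_k * (psi(N + A) - psi(A))).sum()
        if den <= 0:
            break
        a = np.clip(a * num / den, ALPHA_FLOOR, 1e8)
    return a


def _laplace_score(
    x: np.ndarray, pi: np.ndarray, alpha: np.ndarray, r: np.ndarray, loglik: float
) -> float:
    """Laplace approximation to the negative log model evidence.

    −log evidence ≈ −logL − (p/2)·log 2π + ½·Σ log h_ii, with a diagonal
    observed-information approximation in λ = log α space computed from
    the responsibility-weighted per-component Dirichlet-multinomial
    curvature (complete-data information).  This deliberately ignores
    cross-component coupling: near-duplicate components at overlarge K
    produce flat coupled directions whose vanishing curvature would make
    the raw Laplace integral diverge rather than penalize complexity.
    Mixture-weight curvature uses the multinomial information n·π_k for
    the K−1 free weights.
    """
    from scipy.special import polygamma

    K, G = alpha.shape
    n = x.shape[0]
    p = K * G + (K - 1)
    N = x.sum(axis=1)
    logdet = 0.0
    for k in range(K):
        a = alpha[k]
        A = a.sum()
        w = r[:, k]
        common = (w * (polygamma(1, A) - polygamma(1, N + A))).sum()
        for g in range(G):
            d2 = -(common + (w * (polygamma(1, x[:, g] + a[g]) - polygamma(1, a[g]))).sum())
            h = a[g] ** 2 * d2
            logdet += np.log(max(h, 1e-10))
    for k in range(K - 1):
        logdet += np.log(max(n * pi[k], 1e-10))
    return -loglik - 0.5 * p * np.log(2 * np.pi) + 0.5 * logdet


def fit_dmm(
    counts: pd.DataFrame | np.ndarray,
    K: int,
    n_restarts: int = 10,
    seed: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 400,
) -> DMMModel:
    """Fit a K-component Dirichlet-multinomial mixture by EM.

    Best of ``n_restarts`` random initializations (k-means++-style
    partitions of the proportion vectors, moment-matched to Dirichlet
    parameters) by final log-likelihood.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    taxa = list(counts.columns) if isinstance(counts, pd.DataFrame) else []
    x = np.asarray(counts, dtype=float)
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("every sample must have positive total count")
    n, G = x.shape
    props = x / x.sum(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(n_restarts, 1)):
        if K == 1:
            labels = np.zeros(n, dtype=int)
        else:
            labels = _kmeanspp_partition(props, K, rng)
        alpha = np.stack(
            [
                _moment_match_alpha(props[labels == k])
                if (labels == k).sum() >= 2
                else _moment_match_alpha(props) * np.exp(rng.normal(0, 0.3, size=G))
                for k in range(K)
            ]
        )
        pi = np.clip(np.bincount(labels, minlength=K) / n, 1e-3, None)
        pi /= pi.sum()

        prev_ll = -np.inf
        trace = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            lp = dm_logpmf(x, alpha) + np.log(pi)[None, :]
            ll_i = logsumexp(lp, axis=1)
            ll = float(ll_i.sum())
            trace.append(ll)
            r = np.exp(lp - ll_i[:, None])
            if ll - prev_ll < tol and it > 1:
                converged = True
                break
            prev_ll = ll
            pi = np.clip(r.mean(axis=0), 1e-10, None)
            pi /= pi.sum()
            for k in range(K):
                alpha[k] = _update_alpha(x, r[:, k], alpha[k])
        if best is None or ll > best[0]:
            best = (ll, pi.copy(), alpha.copy(), r.copy(), converged, it, np.array(trace))

    ll, pi, alpha, r, converged, n_iter, trace = best
    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations for K={K}")
    p = K * G + (K - 1)
    model = DMMModel(
        K=K,
        pi=pi,
        alpha=alpha,
        responsibilities=r,
        log_likelihood=ll,
        laplace=_laplace_score(x, pi, alpha, r, ll),
        aic=-2 * ll + 2 * p,
        bic=-2 * ll + p * np.log(n),
        converged=converged,
        n_iter=n_iter,
        taxa=taxa,
        loglik_trace=trace,
    )
    return model


def fit_dmm_range(
    counts: pd.DataFrame | np.ndarray,
    k_max: int = 15,
    n_restarts: int = 10,
    seed: int | None = None,
    **kwargs,
) -> list[DMMModel]:
    """Fit K = 1..k_max; seeds derived per K for reproducibility."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=k_max)
    return [
        fit_dmm(counts, K, n_restarts=n_restarts, seed=int(seeds[K - 1]), **kwargs)
        for K in range(1, k_max + 1)
    ]


def select_k(models: list[DMMModel]) -> dict:
    """Argmin of each criterion over the fitted models (Laplace is primary)."""
    out = {}
    for crit in ("laplace", "aic", "bic"):
        vals = [getattr(m, crit) for m in models]
        out[crit] = models[int(np.argmin(vals))].K
    out["primary"] = out["laplace"]
    return out


def relative_to_counts(
    rel: pd.DataFrame, library_size: int = 10000
) -> pd.DataFrame:
    """Convert relative genus abundances to integer counts (rounded)."""
    counts = (rel * library_size).round().astype(int)
    counts[counts.sum(axis=1) == 0] = 1  # guard all-zero rows
    return counts


def order_chronologically(
    model: DMMModel, sample_ids: list[str], visit_index: pd.Series
) -> pd.DataFrame:
    """Relabel components 1..K by ascending mean visit index of members.

    Ties break by descending overall prevalence; empty components sort
    last with a warning.  Returns an assignment frame with both raw and
    chronological labels (the relabeling is a bijection; membership is
    unchanged).
    """
    raw = model.assign()
    vi = pd.Series(visit_index).reindex(sample_ids)
    if vi.isna().any():
        raise KeyError("every sample needs a visit index")
    stats = []
    for k in range(1, model.K + 1):
        members = raw == k
        n_k = int(members.sum())
        if n_k == 0:
            warnings.warn(f"component {k} has no members; placed last")
            stats.append((k, np.inf, 0))
        else:
            stats.append((k, float(vi.to_numpy()[members].mean()), n_k))
    order = sorted(stats, key=lambda t: (t[1], -t[2]))
    mapping = {old: new + 1 for new, (old, _, _) in enumerate(order)}
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "component_raw": raw,
            "fct": [mapping[k] for k in raw],
        }
    )


def transition_summary(
    assignments: pd.DataFrame,
    metadata: pd.DataFrame,
    visits: tuple[str, ...] = ("V1", "V2", "V3", "V4"),
    label_col: str = "fct",
) -> pd.DataFrame:
    """Per-visit-pair transition counts and row-normalized fractions.

    Counts infants assigned at both visits of each consecutive pair;
    fractions are conditional on the source community type.
    """
    merged = assignments.merge(
        metadata[["sample_id", "infant_id", "visit"]], on="sample_id"
    )
    wide = merged.pivot(index="infant_id", columns="visit", values=label_col)
    K = int(merged[label_col].max())
    rows = []
    for a, b in zip(visits[:-1], visits[1:]):
        if a not in wide.columns or b not in wide.columns:
            continue
        sub = wide[[a, b]].dropna().astype(int)
        counts = np.zeros((K, K), dtype=int)
        np.add.at(counts, (sub[a].to_numpy() - 1, sub[b].to_numpy() - 1), 1)
        row_tot = counts.sum(axis=1)
        for i in range(K):
            for j in range(K):
                rows.append(
                    {
                        "from_visit": a,
                        "to_visit": b,
                        "from_fct": i + 1,
                        "to_fct": j + 1,
                        "n": int(counts[i, j]),
                        "fraction": counts[i, j] / row_tot[i] if row_tot[i] else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def compare_trajectories(
    assignments: pd.DataFrame,
    metadata: pd.DataFrame,
    groups: pd.Series,
    visits: tuple[str, ...] = ("V1", "V2", "V3", "V4"),
    monte_carlo: int = 2000,
    seed: int | None = None,
    label_col: str = "fct",
) -> pd.DataFrame:
    """Per-visit community-type × colonization-group tests, BH-adjusted.

    ``groups`` maps infant_id to a colonization group (e.g. no
    *B. infantis* / probiotic / other strains).  Sparse tables get a
    Monte-Carlo chi-square p; BH adjustment runs across visits.
    """
    merged = assignments.merge(
        metadata[["sample_id", "infant_id", "visit"]], on="sample_id"
    )
    merged["group"] = merged["infant_id"].map(groups)
    rows = []
    rng = np.random.default_rng(seed)
    for v in visits:
        sub = merged[(merged["visit"] == v) & merged["group"].notna()]
        if sub.empty or sub["group"].nunique() < 2:
            warnings.warn(f"skipping visit {v}: insufficient groups")
            continue
        tab = pd.crosstab(sub[label_col], sub["group"])
        res = category_group_test(
            tab, monte_carlo=monte_carlo, seed=int(rng.integers(2**31 - 1))
        )
        rows.append(
            {
                "visit": v,
                "statistic": res["statistic"],
                "p": res.get("p_mc", res["p"]),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
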