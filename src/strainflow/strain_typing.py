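"""SNV-based strain typing of *B. infantis* over signature genes.

The procedure: per-position consensus calling (a base is called when its
allele frequency reaches the threshold, default ≥90%, at sufficient
depth), sample-level read/gene filters (≥250 reads over ≥10 genes),
per-sample exclusion of noisy genes (more than 20% of covered positions
with major-allele frequency below the threshold), concatenation into a
catalog-aligned profile, pairwise SNV distances over shared called
positions, a neighbor-joining tree rooted on a *B. longum* subsp.
*longum* outgroup, and a rule-based categorization of each sample as
LMG11588 (probiotic clade), OtherInfantis, UntypedLow (*B. infantis*
below 0.16% abundance), UntypedHet (heterogeneous or unplaceable
profile), or NotDetected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .synthetic_cohort import AlleleCountTable, GeneCatalog, OUTGROUP_ID, PROBIOTIC_ID

CATEGORIES = ["LMG11588", "OtherInfantis", "UntypedLow", "UntypedHet", "NotDetected"]


@dataclass
class TypingParams:
    """All thresholds of the strain-typing procedure."""

    af_threshold: float = 0.90
    min_depth: int = 4
    min_reads: int = 250
    min_genes: int = 10
    gene_low_af_max: float = 0.20
    low_abund_threshold: float = 0.0016
    het_max: float = 0.002
    probiotic_radius: float = 0.001
    min_shared: int = 1000
    read_length: int = 100

    def __post_init__(self) -> None:
        if not 0.5 < self.af_threshold <= 1.0:
            raise ValueError("af_threshold must be in (0.5, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class StrainProfile:
    """A sample's consensus profile on the concatenated catalog.

    ``calls`` holds base codes 0–3 and -1 for uncalled positions; QC
    metrics cover the pre-filter pileup.
    """

    sample_id: str
    calls: np.ndarray
    total_signature_reads: int
    genes_with_reads: int
    genes_retained: int
    heterogeneity_fraction: float
    covered_positions: int
    excluded_genes: list[str] = field(default_factory=list)
    passed_filter: bool = True

    @property
    def called_positions(self) -> int:
        return int((self.calls >= 0).sum())


def call_consensus(
    counts: np.ndarray, af_threshold: float = 0.90, min_depth: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Consensus-call every position of an (L, 4) count array.

    A position is called to base b iff depth ≥ min_depth and
    count_b / depth ≥ af_threshold (inclusive).  Returns
    ``(calls, depth, major_af)`` with calls -1 where uncalled and
    major_af NaN where depth is zero.  An empty pileup yields an
    all-uncalled profile, not an error.
    """
    if not 0.5 < af_threshold <= 1.0:
        raise ValueError("af_threshold must be in (0.5, 1]")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    counts = np.asarray(counts)
    depth = counts.sum(axis=1).astype(np.int64)
    major = counts.argmax(axis=1).astype(np.int8)
    with np.errstate(invalid="ignore", divide="ignore"):
        major_af = np.where(depth > 0, counts.max(axis=1) / np.maximum(depth, 1), np.nan)
    calls = np.where((depth >= min_depth) & (major_af >= af_threshold), major, -1).astype(np.int8)
    return calls, depth, major_af


def sample_passes_typing_filter(
    total_reads: int, genes_with_reads: int, min_reads: int = 250, min_genes: int = 10
) -> bool:
    """At least `min_reads` reads mapping to at least `min_genes` genes (inclusive)."""
    return total_reads >= min_reads and genes_with_reads >= min_genes


def exclude_noisy_genes(
    depth: np.ndarray,
    major_af: np.ndarray,
    catalog: GeneCatalog,
    af_threshold: float = 0.90,
    min_depth: int = 4,
    max_low_af_fraction: float = 0.20,
) -> tuple[list[str], list[str]]:
    """Per-sample gene exclusion: retain a gene iff the fraction of its
    covered positions with major-allele frequency < af_threshold is
    ≤ max_low_af_fraction (strictly greater excludes).  Genes with zero
    covered positions are excluded and flagged "no-coverage".

    Returns (retained_gene_ids, excluded_gene_ids).
    """
    retained, excluded = [], []
    covered = depth >= min_depth
    low = covered & (major_af < af_threshold)
    for g, gid in enumerate(catalog.gene_ids):
        sl = slice(catalog.offsets[g], catalog.offsets[g + 1])
        n_cov = int(covered[sl].sum())
        if n_cov == 0:
            excluded.append(gid)
            continue
        frac = low[sl].sum() / n_cov
        (retained if frac <= max_low_af_fraction else excluded).append(gid)
    return retained, excluded


def build_profile(
    sample_id: str,
    counts: np.ndarray,
    catalog: GeneCatalog,
    params: TypingParams | None = None,
) -> StrainProfile:
    """Full per-sample profile: consensus calls over retained genes only.

    Positions of excluded genes are recorded as uncalled but retained in
    coordinates, so profiles stay alignable by catalog position.
    """
    params = params or TypingParams()
    calls, depth, major_af = call_consensus(counts, params.af_threshold, params.min_depth)
    covered = depth >= params.min_depth
    n_cov = int(covered.sum())
    het = float((covered & (major_af < params.af_threshold)).sum() / n_cov) if n_cov else 0.0
    gene_depth = np.add.reduceat(depth, catalog.offsets[:-1])
    genes_with_reads = int((gene_depth > 0).sum())
    total_reads = int(round(depth.sum() / params.read_length))
    passed = sample_passes_typing_filter(
        total_reads, genes_with_reads, params.min_reads, params.min_genes
    )
    retained, excluded_ids = exclude_noisy_genes(
        depth, major_af, catalog, params.af_threshold, params.min_depth, params.gene_low_af_max
    )
    if excluded_ids:
        gidx = catalog.gene_index()
        for gid in excluded_ids:
            g = gidx[gid]
            calls[catalog.offsets[g]: catalog.offsets[g + 1]] = -1
    return StrainProfile(
        sample_id=sample_id,
        calls=calls,
        total_signature_reads=total_reads,
        genes_with_reads=genes_with_reads,
        genes_retained=len(retained),
        heterogeneity_fraction=het,
        covered_positions=n_cov,
        excluded_genes=excluded_ids,
        passed_filter=passed,
    )


def reference_profile(sample_id: str, sequence: np.ndarray) -> StrainProfile:
    """An error-free, fully-called profile for a reference genome."""
    calls = np.asarray(sequence, dtype=np.int8)
    return StrainProfile(
        sample_id=sample_id,
        calls=calls,
        total_signature_reads=10**9,
        genes_with_reads=10**9,
        genes_retained=10**9,
        heterogeneity_fraction=0.0,
        covered_positions=calls.shape[0],
    )


def pairwise_snv_distance(
    profile_a: StrainProfile | np.ndarray,
    profile_b: StrainProfile | np.ndarray,
    min_shared: int = 1000,
) -> tuple[int, int, float]:
    """(raw SNV count, shared called positions, normalized distance).

    The normalized distance is NaN (flagged undefined) when fewer than
    ``min_shared`` positions are called in both profiles; disjoint called
    sets are undefined, not zero.
    """
    a = profile_a.calls if isinstance(profile_a, StrainProfile) else profile_a
    b = profile_b.calls if isinstance(profile_b, StrainProfile) else profile_b
    both = (a >= 0) & (b >= 0)
    shared = int(both.sum())
    raw = int((a[both] != b[both]).sum())
    norm = raw / shared if shared >= max(min_shared, 1) else float("nan")
    return raw, shared, norm


def distance_matrix(
    profiles: list[StrainProfile], min_shared: int = 1000
) -> tuple[np.ndarray, list[str]]:
    """Symmetric normalized SNV distance matrix over profiles (NaN where undefined)."""
    calls = np.stack([p.calls for p in profiles])
    called = calls >= 0
    n = len(profiles)
    dist = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1:]
        shared = both.sum(axis=1)
        raw = ((calls[i] != calls[i + 1:]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(shared >= max(min_shared, 1), raw / np.maximum(shared, 1), np.nan)
        dist[i, i + 1:] = norm
        dist[i + 1:, i] = norm
    return dist, [p.sample_id for p in profiles]


def build_strain_tree(
    dist: np.ndarray, labels: list[str], outgroup: str = OUTGROUP_ID
) -> TreeNode:
    """Neighbor-joining tree rooted on the outgroup.

    Negative NJ branch lengths are clamped to zero (the length is shifted
    to the adjacent branch by the standard correction inside scikit-bio's
    implementation; any residual negatives are clamped here).
    """
    if len(labels) < 3:
        warnings.warn("fewer than 3 tips: returning trivial tree")
        tree = TreeNode(name="root")
        for lab, d in zip(labels, dist[0] if len(labels) else []):
            tree.append(TreeNode(name=lab, length=float(d)))
        return tree
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains undefined entries; drop unplaced samples first")
    dm = DistanceMatrix(dist, labels)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            if node.parent is not None and node.parent.length is not None:
                node.parent.length += node.length
            node.length = 0.0
    if outgroup in labels:
        og = tree.find(outgroup)
        tree = tree.root_at(og.parent if og.parent is not None else og)
    return tree


def classify_strain(
    abundance: float,
    profile: StrainProfile | None,
    distance_to_probiotic: float,
    shared_with_probiotic: int,
    params: TypingParams | None = None,
) -> str:
    """Rule-based strain category for one sample.

    Rule order: NotDetected (no *B. infantis* in the taxonomic profile)
    → UntypedLow (detected but abundance < low threshold, strict)
    → UntypedHet (typing filter failed, heterogeneous profile, or too few
    shared called positions with the probiotic reference)
    → LMG11588 iff normalized distance to the probiotic reference is
    within the probiotic radius, else OtherInfantis.
    """
    params = params or TypingParams()
    if not 0.0 <= abundance <= 1.0:
        raise ValueError("abundance must be in [0, 1]")
    if abundance == 0.0:
        return "NotDetected"
    if abundance < params.low_abund_threshold:
        return "UntypedLow"
    if (
        profile is None
        or not profile.passed_filter
        or profile.heterogeneity_fraction > params.het_max
        or shared_with_probiotic < params.min_shared
        or np.isnan(distance_to_probiotic)
    ):
        return "UntypedHet"
    if distance_to_probiotic <= params.probiotic_radius:
        return "LMG11588"
    return "OtherInfantis"


def type_samples(
    pileups: AlleleCountTable,
    abundances: pd.Series | dict,
    references: dict[str, np.ndarray],
    params: TypingParams | None = None,
) -> tuple[pd.DataFrame, dict[str, StrainProfile]]:
    """Run the full typing procedure over a cohort of pileups.

    ``references`` maps reference ids (must include the probiotic
    reference) to full-length sequences.  Returns a classification frame
    (sample_id, category, abundance, distance/shared evidence, QC
    metrics) plus the per-sample profiles.
    """
    params = params or TypingParams()
    if PROBIOTIC_ID not in references:
        raise KeyError(f"references must include the probiotic reference {PROBIOTIC_ID!r}")
    abund = pd.Series(abundances, dtype=float)
    catalog = pileups.catalog
    ref_calls = np.asarray(references[PROBIOTIC_ID], dtype=np.int8)
    rows = []
    profiles: dict[str, StrainProfile] = {}
    for sid in pileups.sample_ids:
        ab = float(abund.get(sid, 0.0))
        counts = pileups.counts[sid]
        if counts.sum() == 0:
            profile = None
            raw, shared, norm = 0, 0, float("nan")
        else:
            profile = build_profile(sid, counts, catalog, params)
            profiles[sid] = profile
            raw, shared, norm = pairwise_snv_distance(profile.calls, ref_calls, params.min_shared)
        cat = classify_strain(ab, profile, norm, shared, params)
        rows.append(
            {
                "sample_id": sid,
                "category": cat,
                "abundance": ab,
                "snv_to_probiotic": raw,
                "shared_with_probiotic": shared,
                "dist_to_probiotic": norm,
                "total_signature_reads": profile.total_signature_reads if profile else 0,
                "genes_with_reads": profile.genes_with_reads if profile else 0,
                "genes_retained": profile.genes_retained if profile else 0,
                "heterogeneity_fraction": profile.heterogeneity_fraction if profile else np.nan,
                "passed_filter": bool(profile.passed_filter) if profile else False,
            }
        )
    return pd.DataFrame(rows), profiles


def placeable_profiles(
    profiles: dict[str, StrainProfile],
    classifications: pd.DataFrame,
    references: dict[str, np.ndarray],
    params: TypingParams | None = None,
) -> list[StrainProfile]:
    """Profiles eligible for tree placement (typed clades) plus reference tips."""
    params = params or TypingParams()
    typed = set(
        classifications.loc[
            classifications["category"].isin(["LMG11588", "OtherInfantis"]), "sample_id"
        ]
    )
    tips = [profiles[s] for s in profiles if s in typed]
    tips += [reference_profile(rid, seq) for rid, seq in references.items()]
    return tips
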