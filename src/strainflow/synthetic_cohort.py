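"""Synthetic trial-cohort generator with machine-readable ground truth.

Emulates a three-arm (placebo CG, low-dose Lo-EG, high-dose Hi-EG),
four-visit (V1 baseline .. V4 post-cessation) probiotic supplementation
trial at the level the analysis pipeline consumes: per-sample allele-count
pileups over a signature-gene catalog, genus-level count tables drawn from
a known Dirichlet-multinomial mixture, infant/visit metadata with
anthropometrics, and fecal biomarkers with configurable monotone coupling
to *B. infantis* abundance.  Every planted truth (colonizing strain,
SNV positions, community-type label, effect size) is recorded so that
downstream recovery can be scored without peeking.

Base encoding is A=0, C=1, G=2, T=3 throughout; -1 marks an uncalled
position in consensus profiles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.array(["A", "C", "G", "T"])

PROBIOTIC_ID = "LMG11588"
OUTGROUP_ID = "B_longum_longum_JCM1217"

#: analyte -> sign of its monotone dependence on B. infantis abundance
BIOMARKER_SIGNS = {
    "acetate": +1,
    "AAT": +1,
    "calprotectin": +1,
    "sIgA": +1,
    "butyrate": -1,
    "IL-1b": -1,
    "IL-8": -1,
    "IFN-g": -1,
}

#: genera used for the community-type truth (dominance patterns echo the
#: early/late infant gut: bifidobacteria-rich vs facultative-anaerobe-rich)
DEFAULT_GENERA = [
    "Bifidobacterium",
    "Escherichia",
    "Streptococcus",
    "Klebsiella",
    "Staphylococcus",
    "Veillonella",
    "Enterobacter",
    "Bacteroides",
    "Clostridium",
    "Lactobacillus",
]


# ---------------------------------------------------------------------------
# gene catalog and strain genomes
# ---------------------------------------------------------------------------


@dataclass
class GeneCatalog:
    """A signature-gene catalog: gene ids, lengths, and one reference sequence.

    The reference sequence is stored concatenated (int8 codes); ``offsets``
    has ``n_genes + 1`` entries so gene *g* occupies
    ``sequence[offsets[g]:offsets[g+1]]`` (0-based, half-open).
    """

    gene_ids: list[str]
    lengths: np.ndarray
    sequence: np.ndarray
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        if self.sequence.shape[0] != self.offsets[-1]:
            raise ValueError("sequence length does not match sum of gene lengths")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def total_length(self) -> int:
        return int(self.offsets[-1])

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def position_gene_ids(self) -> np.ndarray:
        """Gene index for every concatenated position."""
        return np.repeat(np.arange(self.n_genes), self.lengths)


def simulate_catalog(
    n_genes: int = 100,
    length_range: tuple[int, int] = (300, 1500),
    seed: int | None = None,
) -> GeneCatalog:
    """Simulate a signature-gene catalog with uniform random bases."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise ValueError("length_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    seq = rng.integers(0, 4, size=int(lengths.sum()), dtype=np.int8)
    ids = [f"gene_{i:04d}" for i in range(n_genes)]
    return GeneCatalog(ids, lengths, seq)


@dataclass
class StrainSet:
    """Reference and simulated strain genomes over a catalog.

    ``sequences`` maps strain id to a concatenated int8 sequence.  The
    probiotic reference equals the catalog reference; autochthonous
    subclades and probiotic-clade variants carry planted SNVs recorded in
    ``snv_positions`` (positions differing from the probiotic reference).
    """

    catalog: GeneCatalog
    sequences: dict[str, np.ndarray]
    snv_positions: dict[str, np.ndarray]
    probiotic_id: str = PROBIOTIC_ID
    outgroup_id: str = OUTGROUP_ID

    @property
    def autochthonous_ids(self) -> list[str]:
        return [s for s in self.sequences if s.startswith("auto_")]

    @property
    def probiotic_clade_ids(self) -> list[str]:
        return [s for s in self.sequences if s.startswith(self.probiotic_id)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Mutate each site independently with probability `rate`; return (seq, positions)."""
    n_mut = rng.binomial(seq.shape[0], rate)
    pos = rng.choice(seq.shape[0], size=n_mut, replace=False)
    out = seq.copy()
    out[pos] = (out[pos] + rng.integers(1, 4, size=n_mut)) % 4
    return out, np.sort(pos)


def simulate_strain_genomes(
    catalog: GeneCatalog,
    n_autoch_subclades: int = 8,
    snv_rate_between: float = 0.005,
    snv_rate_within_probiotic: float = 0.0001,
    n_probiotic_variants: int = 2,
    outgroup_rate: float = 0.02,
    seed: int | None = None,
) -> StrainSet:
    """Simulate one probiotic clade plus diverse autochthonous subclades.

    ``snv_rate_between`` is the expected *pairwise* per-site divergence
    between autochthonous subclades: each subclade receives
    Binomial(L, rate/2) substitutions from the shared ancestral reference,
    so two subclades differ at ≈ rate × L sites.  The probiotic clade has
    negligible internal variability (``snv_rate_within_probiotic``, same
    pairwise convention), and a distant outgroup genome is included for
    tree rooting.
    """
    for name, r in [("snv_rate_between", snv_rate_between),
                    ("snv_rate_within_probiotic", snv_rate_within_probiotic)]:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if snv_rate_between > 0.05 or snv_rate_within_probiotic > 0.05:
        raise ValueError("per-site SNV rates above 0.05 are not biologically plausible here")
    rng = np.random.default_rng(seed)
    ref = catalog.sequence
    seqs: dict[str, np.ndarray] = {PROBIOTIC_ID: ref.copy()}
    snvs: dict[str, np.ndarray] = {PROBIOTIC_ID: np.array([], dtype=np.int64)}
    for v in range(n_probiotic_variants):
        s, p = _mutate(ref, snv_rate_within_probiotic / 2.0, rng)
        seqs[f"{PROBIOTIC_ID}_v{v + 1}"] = s
        snvs[f"{PROBIOTIC_ID}_v{v + 1}"] = p
    for k in range(n_autoch_subclades):
        s, p = _mutate(ref, snv_rate_between / 2.0, rng)
        seqs[f"auto_{k + 1:02d}"] = s
        snvs[f"auto_{k + 1:02d}"] = p
    og, ogp = _mutate(ref, outgroup_rate, rng)
    seqs[OUTGROUP_ID] = og
    snvs[OUTGROUP_ID] = ogp
    return StrainSet(catalog, seqs, snvs)


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Design of the synthetic trial and all planted rates.

    Defaults emulate the trial design and the colonization patterns the
    analysis is meant to recover: 76 infants per arm, four visits,
    feeding-mode mix 58/26/16 (EBF/mixed/formula), 16% baseline
    autochthonous carriage, 78.7% probiotic colonization during
    supplementation in the experimental arms, feeding-dependent
    persistence after cessation (coin probabilities 0.88 EBF vs 0.54
    otherwise, which pool to an observed persistence of ≈0.70 — and ≈0.84
    in EBF — after low-abundance sampling, mixtures, and replacement by
    resident strains shave ≈5%), a slow autochthonous acquisition reaching ≈18% carriage by
    V4, a small control-arm probiotic leakage, and rare two-strain
    mixture samples.
    """

    n_per_arm: int = 76
    arm_sizes: tuple[int, ...] | None = None
    arms: tuple[str, ...] = ("CG", "Lo-EG", "Hi-EG")
    visits: tuple[str, ...] = ("V1", "V2", "V3", "V4")
    feeding_probs: dict[str, float] = field(
        default_factory=lambda: {"EBF": 0.58, "mixed": 0.26, "formula": 0.16}
    )
    seed: int = 0
    dropout_prob: float = 0.008  # per-visit missing-sample probability
    # strain colonization truth
    baseline_colonization_prob: float = 0.16
    probiotic_col_prob: float = 0.787
    persistence_prob_ebf: float = 0.88
    persistence_prob_other: float = 0.54
    autoch_acquisition_prob: float = 0.01
    leakage_prob: float = 0.02
    probiotic_displaces_prob: float = 0.005
    mixture_prob: float = 0.007
    mixture_proportion: float = 0.5
    # abundance model (log10 scale for colonized samples)
    log10_abund_mean: float = -1.7
    log10_abund_sd: float = 0.55
    trace_detection_prob: float = 0.10
    low_abund_threshold: float = 0.0016
    # growth / biomarkers
    group_effects: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.0, "Lo-EG": 0.0, "Hi-EG": 0.0}
    )
    gain_mean: float = 35.0  # g/day
    gain_sd: float = 7.7
    baseline_weight_mean: float = 3.5  # kg
    baseline_weight_sd: float = 0.4
    sex_effect: float = 1.0  # g/day added for male infants
    baseline_slope: float = 0.0  # g/day per kg of baseline weight
    study_days: int = 56  # enrollment (V1) to end of supplementation (V3)
    biomarker_noise_sd: float = 1.0
    biomarker_slope: float = 1.0
    # community-type truth
    n_fct: int = 6
    fct_concentration: float = 30.0
    fct_colonization_effect: float = 3.0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if abs(sum(self.feeding_probs.values()) - 1.0) > 1e-9:
            raise ValueError("feeding_probs must sum to 1")
        if len(set(self.visits)) != len(self.visits):
            raise ValueError("visits must be strictly ordered (unique)")
        if self.arm_sizes is not None and len(self.arm_sizes) != len(self.arms):
            raise ValueError("arm_sizes must match arms")

    def sizes(self) -> tuple[int, ...]:
        return self.arm_sizes if self.arm_sizes is not None else (self.n_per_arm,) * len(self.arms)


@dataclass
class CohortTruth:
    """All planted ground truth for one simulated cohort."""

    config: CohortConfig
    infants: pd.DataFrame  # infant_id, arm, feeding, sex, delivery
    samples: pd.DataFrame  # sample_id, infant_id, visit, strain, second_strain,
    #                        mixture, abundance, true_category, fct_label
    strains: StrainSet

    def to_json(self, path) -> None:
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.config).items()
            },
            "infants": self.infants.to_dict(orient="records"),
            "samples": self.samples.where(pd.notna(self.samples), None).to_dict(orient="records"),
            "snv_positions": {k: v.tolist() for k, v in self.strains.snv_positions.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _true_category(strain, abundance, mixture, low_thr) -> str:
    if abundance <= 0 or strain is None:
        return "NotDetected"
    if abundance < low_thr:
        return "UntypedLow"
    if mixture:
        return "UntypedHet"
    if str(strain).startswith(PROBIOTIC_ID):
        return "LMG11588"
    return "OtherInfantis"


def simulate_cohort(config: CohortConfig, strains: StrainSet | None = None) -> CohortTruth:
    """Draw infants, per-visit colonization truth, and abundances.

    Colonization model: autochthonous carriage is an absorbing state (one
    subclade per infant, stable across visits); the probiotic colonizes
    experimental-arm infants during supplementation (V2/V3) unless an
    autochthonous strain already holds the niche, persists at V4 with a
    feeding-dependent probability, and appears sporadically in the control
    arm (horizontal-transmission leakage).  Non-colonized samples carry a
    trace-level detection (below the low-abundance threshold) with small
    probability, else no *B. infantis* at all.
    """
    rng = np.random.default_rng(config.seed)
    if strains is None:
        strains = simulate_strain_genomes(simulate_catalog(seed=config.seed), seed=config.seed)
    autos = strains.autochthonous_ids
    prob_clade = strains.probiotic_clade_ids
    # probiotic_col_prob is the *marginal* detection rate during
    # supplementation; resident autochthonous strains block the probiotic,
    # so the per-infant win probability is inflated accordingly
    blocked = min(config.baseline_colonization_prob + config.autoch_acquisition_prob, 0.99)
    win_prob = min(config.probiotic_col_prob / (1.0 - blocked), 1.0)
    feeding_labels = list(config.feeding_probs)
    feeding_p = np.array([config.feeding_probs[k] for k in feeding_labels])

    infants = []
    for arm, n_arm in zip(config.arms, config.sizes()):
        for i in range(n_arm):
            infants.append(
                {
                    "infant_id": f"{arm}_{i + 1:03d}",
                    "arm": arm,
                    "feeding": feeding_labels[rng.choice(len(feeding_labels), p=feeding_p)],
                    "sex": "male" if rng.random() < 0.53 else "female",
                    "delivery": "vaginal" if rng.random() < 0.85 else "c-section",
                }
            )
    infants = pd.DataFrame(infants)

    sample_rows = []
    for rec in infants.itertuples(index=False):
        subclade = autos[rng.integers(len(autos))]
        auto_carrier = rng.random() < config.baseline_colonization_prob
        is_eg = rec.arm != config.arms[0]
        probiotic_wins = rng.random() < win_prob
        persist_p = (
            config.persistence_prob_ebf
            if rec.feeding == "EBF"
            else config.persistence_prob_other
        )
        persists = rng.random() < persist_p
        pvariant = prob_clade[rng.integers(len(prob_clade))]
        probiotic_present = False
        for vi, visit in enumerate(config.visits):
            if rng.random() < config.dropout_prob:
                continue  # missing sample
            if vi > 0 and not auto_carrier and rng.random() < config.autoch_acquisition_prob:
                auto_carrier = True
            supplementation = visit in ("V2", "V3")
            if is_eg:
                if supplementation:
                    probiotic_present = probiotic_wins
                elif visit == "V4":
                    probiotic_present = probiotic_present and persists
            else:
                probiotic_present = supplementation and rng.random() < config.leakage_prob
            strain = None
            second = None
            mixture = False
            if auto_carrier and probiotic_present:
                # autochthonous strains usually out-compete the probiotic
                if rng.random() < config.probiotic_displaces_prob:
                    strain = pvariant
                    auto_carrier = False
                else:
                    strain = subclade
            elif auto_carrier:
                strain = subclade
            elif probiotic_present:
                strain = pvariant
            if strain is not None and rng.random() < config.mixture_prob and len(autos) > 1:
                others = [a for a in autos if a != strain]
                second = others[rng.integers(len(others))]
                mixture = True
            if strain is not None:
                ab = 10 ** rng.normal(config.log10_abund_mean, config.log10_abund_sd)
                ab = min(ab, 0.5)
            elif rng.random() < config.trace_detection_prob:
                # trace-level detection without an established strain
                strain = autos[rng.integers(len(autos))]
                ab = 10 ** rng.uniform(-5, np.log10(config.low_abund_threshold))
            else:
                ab = 0.0
            sample_rows.append(
                {
                    "sample_id": f"{rec.infant_id}_{visit}",
                    "infant_id": rec.infant_id,
                    "arm": rec.arm,
                    "visit": visit,
                    "feeding": rec.feeding,
                    "strain": strain,
                    "second_strain": second,
                    "mixture": mixture,
                    "abundance": ab,
                }
            )
    samples = pd.DataFrame(sample_rows)
    samples["true_category"] = [
        _true_category(s, a, m, config.low_abund_threshold)
        for s, a, m in zip(samples["strain"], samples["abundance"], samples["mixture"])
    ]
    samples["fct_label"] = _assign_fct_labels(samples, config, rng)
    return CohortTruth(config, infants, samples, strains)


def _assign_fct_labels(samples: pd.DataFrame, config: CohortConfig, rng) -> np.ndarray:
    """Markov community-type truth drifting from early to late types.

    Infants colonized by any *B. infantis* strain are biased toward the
    bifidobacteria-dominated type (component 2); non-colonized infants
    toward the mixed early type (component 3), mirroring the trajectory
    split the community-type comparison is meant to detect.
    """
    K = config.n_fct
    visits = list(config.visits)
    labels = np.zeros(len(samples), dtype=int)
    order = np.arange(K)
    for idx_group, (_, grp) in enumerate(samples.groupby("infant_id", sort=False)):
        colonized = (grp["abundance"] >= config.low_abund_threshold).any()
        state = None
        for ridx, row in zip(grp.index, grp.itertuples(index=False)):
            vi = visits.index(row.visit)
            # prevalence weights drift with visit so chronology is recoverable
            w = np.exp(-0.5 * ((order - (vi * (K - 1) / max(len(visits) - 1, 1))) / 1.2) ** 2)
            if colonized and K >= 2:
                w[1] *= config.fct_colonization_effect
            elif not colonized and K >= 3:
                w[2] *= config.fct_colonization_effect
            if state is not None:
                w[state] *= 3.0  # sticky: infants tend to stay in their type
            w = w / w.sum()
            state = rng.choice(K, p=w)
            labels[samples.index.get_loc(ridx)] = state + 1
    return labels


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------


class AlleleCountTable:
    """Per-sample, per-position nucleotide counts over a catalog.

    Stored densely: ``counts[sample_id]`` is an (L, 4) uint32 array over
    the concatenated catalog coordinates (columns A, C, G, T).
    """

    def __init__(self, catalog: GeneCatalog, counts: dict[str, np.ndarray] | None = None):
        self.catalog = catalog
        self.counts: dict[str, np.ndarray] = counts or {}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts)

    def add(self, sample_id: str, counts: np.ndarray) -> None:
        if counts.shape != (self.catalog.total_length, 4):
            raise ValueError("counts shape does not match catalog")
        self.counts[sample_id] = counts.astype(np.uint32)

    def to_long_frame(self) -> pd.DataFrame:
        """Sparse long format: one row per covered position."""
        gene_of_pos = self.catalog.position_gene_ids()
        offsets = self.catalog.offsets
        frames = []
        for sid, c in self.counts.items():
            cov = c.sum(axis=1) > 0
            pos = np.nonzero(cov)[0]
            gi = gene_of_pos[pos]
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sid,
                        "gene_id": np.asarray(self.catalog.gene_ids)[gi],
                        "pos": pos - offsets[gi],
                        "nA": c[pos, 0],
                        "nC": c[pos, 1],
                        "nG": c[pos, 2],
                        "nT": c[pos, 3],
                    }
                )
            )
        if not frames:
            return pd.DataFrame(
                columns=["sample_id", "gene_id", "pos", "nA", "nC", "nG", "nT"]
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame, catalog: GeneCatalog) -> "AlleleCountTable":
        table = cls(catalog)
        gidx = catalog.gene_index()
        offsets = catalog.offsets
        lengths = catalog.lengths
        for sid, grp in frame.groupby("sample_id", sort=False):
            c = np.zeros((catalog.total_length, 4), dtype=np.uint32)
            gi = grp["gene_id"].map(gidx)
            if gi.isna().any():
                bad = sorted(set(grp.loc[gi.isna(), "gene_id"]))
                raise KeyError(f"unknown gene ids in pileup: {bad}")
            gi = gi.to_numpy(dtype=np.int64)
            pos = grp["pos"].to_numpy(dtype=np.int64)
            if (pos < 0).any() or (pos >= lengths[gi]).any():
                raise ValueError("pileup position outside gene length")
            flat = offsets[gi] + pos
            for j, col in enumerate(["nA", "nC", "nG", "nT"]):
                np.add.at(c[:, j], flat, grp[col].to_numpy(dtype=np.uint32))
            table.counts[str(sid)] = c
        return table


def _spread_errors(n_err: np.ndarray, rng) -> np.ndarray:
    """Distribute error reads uniformly over the 3 non-true bases; (L,3)."""
    e1 = rng.binomial(n_err, 1.0 / 3.0)
    e2 = rng.binomial(n_err - e1, 0.5)
    return np.stack([e1, e2, n_err - e1 - e2], axis=1)


def _haplotype_counts(seq: np.ndarray, depth: np.ndarray, error_rate: float, rng) -> np.ndarray:
    """Multinomial base counts around a single haplotype."""
    L = seq.shape[0]
    counts = np.zeros((L, 4), dtype=np.int64)
    n_err = rng.binomial(depth, error_rate) if error_rate > 0 else np.zeros(L, dtype=np.int64)
    counts[np.arange(L), seq] = depth - n_err
    if error_rate > 0:
        err = _spread_errors(n_err, rng)
        others = (seq[:, None] + np.arange(1, 4)[None, :]) % 4
        np.add.at(counts, (np.repeat(np.arange(L), 3), others.ravel()), err.ravel())
    return counts


def simulate_pileups(
    truth: CohortTruth,
    depth_per_unit_abundance: float = 5000.0,
    error_rate: float = 0.002,
    library_factor_sd: float = 0.25,
    seed: int | None = None,
) -> AlleleCountTable:
    """Simulate per-position allele counts for every sample in the cohort.

    Mean per-position depth is ``depth_per_unit_abundance × abundance``
    (so 1% abundance gives 50× at the default 5000), scaled by a
    per-sample log-normal library-size factor and Poisson-dispersed per
    position.  Reads carry uniform substitution errors at ``error_rate``;
    mixture samples draw per-position depth binomially between the two
    haplotypes at the configured proportion.  Samples without *B. infantis*
    receive no counts.
    """
    if depth_per_unit_abundance <= 0:
        raise ValueError("depth_per_unit_abundance must be positive")
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    strains = truth.strains
    table = AlleleCountTable(strains.catalog)
    L = strains.catalog.total_length
    for row in truth.samples.itertuples(index=False):
        if row.abundance <= 0 or row.strain is None:
            table.counts[row.sample_id] = np.zeros((L, 4), dtype=np.uint32)
            continue
        if row.strain not in strains.sequences:
            raise KeyError(f"unknown strain id in truth: {row.strain}")
        lib = float(np.exp(rng.normal(0.0, library_factor_sd))) if library_factor_sd > 0 else 1.0
        mean_depth = depth_per_unit_abundance * row.abundance * lib
        depth = rng.poisson(mean_depth, size=L)
        if row.mixture and row.second_strain is not None:
            w = truth.config.mixture_proportion
            d1 = rng.binomial(depth, w)
            c = _haplotype_counts(strains.sequences[row.strain], d1, error_rate, rng)
            c += _haplotype_counts(
                strains.sequences[row.second_strain], depth - d1, error_rate, rng
            )
        else:
            c = _haplotype_counts(strains.sequences[row.strain], depth, error_rate, rng)
        table.counts[row.sample_id] = c.astype(np.uint32)
    return table


# ---------------------------------------------------------------------------
# genus tables (community-type generator)
# ---------------------------------------------------------------------------


def default_dmm_params(
    n_components: int = 6,
    genera: list[str] | None = None,
    concentration: float = 30.0,
    seed: int = 12345,
) -> np.ndarray:
    """Well-separated per-component Dirichlet parameter vectors (K, G).

    Each component is dominated by one or two genera (echoing
    bifidobacteria-dominated vs *Escherichia*/*Streptococcus*-dominated
    community types) with the remaining mass spread evenly.
    """
    genera = genera if genera is not None else DEFAULT_GENERA
    G = len(genera)
    rng = np.random.default_rng(seed)
    alphas = np.empty((n_components, G))
    for k in range(n_components):
        mean = np.full(G, 0.25 / max(G - 2, 1))
        dom = [k % G, (k + 3) % G]
        mean[dom[0]] = 0.55
        mean[dom[1]] = 0.20
        mean = mean / mean.sum()
        # small jitter so no two components are exactly permutations
        mean = mean * np.exp(rng.normal(0, 0.05, size=G))
        mean /= mean.sum()
        alphas[k] = concentration * mean
    return alphas


def simulate_genus_tables(
    fct_labels: np.ndarray | pd.Series,
    dmm_params: np.ndarray,
    library_size: int = 10000,
    seed: int | None = None,
    sample_ids: list[str] | None = None,
    genera: list[str] | None = None,
) -> pd.DataFrame:
    """Draw genus counts ~ Multinomial(library, p), p ~ Dirichlet(α of the label)."""
    dmm_params = np.asarray(dmm_params, dtype=float)
    if dmm_params.ndim != 2 or dmm_params.shape[1] == 0:
        raise ValueError("dmm_params must be a (K, G) array with G >= 1")
    if (dmm_params <= 0).any():
        raise ValueError("Dirichlet parameters must be strictly positive")
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    labels = np.asarray(fct_labels, dtype=int)
    if labels.min() < 1 or labels.max() > dmm_params.shape[0]:
        raise ValueError("fct labels must be in 1..K")
    rng = np.random.default_rng(seed)
    G = dmm_params.shape[1]
    counts = np.empty((labels.shape[0], G), dtype=np.int64)
    for i, lab in enumerate(labels):
        p = rng.dirichlet(dmm_params[lab - 1])
        counts[i] = rng.multinomial(library_size, p)
    cols = genera if genera is not None else (
        DEFAULT_GENERA[:G] if G <= len(DEFAULT_GENERA) else [f"genus_{j}" for j in range(G)]
    )
    idx = sample_ids if sample_ids is not None else [f"S{i:04d}" for i in range(len(labels))]
    return pd.DataFrame(counts, index=pd.Index(idx, name="sample_id"), columns=cols)


# ---------------------------------------------------------------------------
# biomarkers and growth
# ---------------------------------------------------------------------------


def simulate_biomarkers_and_growth(
    truth: CohortTruth,
    noise_sd: float | None = None,
    slope: float | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biomarkers with signed monotone abundance coupling, plus growth data.

    Biomarkers (V1–V3 samples): value = 5 + sign·slope·log10(abundance+1e-5)
    + N(0, noise²), with the sign pattern of ``BIOMARKER_SIGNS``
    (acetate/AAT/calprotectin/sIgA rise with *B. infantis*; inflammatory
    cytokines fall).  Each analyte is given an LLD at its empirical 5th
    percentile and an LOD slightly below, so censoring rules have material
    to act on.

    Growth (one row per infant): baseline weight ~ N(3.5, 0.4²) kg; daily
    weight gain ~ N(35 + group_effect + sex_effect·male +
    baseline_slope·(baseline − mean), 7.7²) g/day over the supplementation
    period.
    """
    cfg = truth.config
    noise_sd = cfg.biomarker_noise_sd if noise_sd is None else noise_sd
    slope = cfg.biomarker_slope if slope is None else slope
    rng = np.random.default_rng(seed)

    rows = truth.samples[truth.samples["visit"].isin(cfg.visits[:3])]
    logab = np.log10(rows["abundance"].to_numpy() + 1e-5)
    bio = pd.DataFrame({"sample_id": rows["sample_id"].to_numpy()})
    for analyte, sign in BIOMARKER_SIGNS.items():
        vals = 5.0 + sign * slope * logab + rng.normal(0.0, noise_sd, size=len(rows))
        bio[analyte] = vals
    limits = {}
    for analyte in BIOMARKER_SIGNS:
        lld = float(np.quantile(bio[analyte], 0.05))
        limits[analyte] = {"LLD": lld, "LOD": lld - 0.5}
    bio.attrs["limits"] = limits

    growth_rows = []
    for rec in truth.infants.itertuples(index=False):
        baseline = rng.normal(cfg.baseline_weight_mean, cfg.baseline_weight_sd)
        gain = (
            cfg.gain_mean
            + cfg.group_effects.get(rec.arm, 0.0)
            + (cfg.sex_effect if rec.sex == "male" else 0.0)
            + cfg.baseline_slope * (baseline - cfg.baseline_weight_mean)
            + rng.normal(0.0, cfg.gain_sd)
        )
        growth_rows.append(
            {
                "infant_id": rec.infant_id,
                "arm": rec.arm,
                "sex": rec.sex,
                "baseline_weight_kg": baseline,
                "weight_gain_g_day": gain,
                "end_weight_kg": baseline + gain * cfg.study_days / 1000.0,
            }
        )
    growth = pd.DataFrame(growth_rows)
    return bio, growth
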