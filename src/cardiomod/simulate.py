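"""Synthetic cohort, genotype, annotation, SV and expression generators.

Everything the discovery pipeline consumes can be generated here with the
statistical structure the analysis assumes: a 48-person sequencing cohort
containing 6 families (40 unrelated individuals), demographic and morphology
marginals matching the study population, rare variants (MAF below 1%) with
planted modifier genes that shift cardiac traits, annotation tables whose
allele frequencies straddle the 1% rarity boundary, caller-attributed SV
intervals with controlled reciprocal overlap, and qPCR / RNA-seq expression
experiments with known fold changes.

All generators are deterministic functions of their seed; substreams are
derived with ``numpy.random.SeedSequence`` so the global seed propagates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import GenotypeCall, VariantRecord, VariantTable
from .intervals import RegionSet
from .sv import SVCall

__all__ = [
    "CohortConfig",
    "Cohort",
    "TruthSet",
    "ModifierSpec",
    "SimParams",
    "GenotypeSimResult",
    "SVEventSpec",
    "ExpressionSimConfig",
    "generate_cohort",
    "generate_genotypes",
    "generate_annotations",
    "generate_external_controls",
    "generate_sv_callsets",
    "generate_expression_experiment",
    "generate_gene_evidence_tables",
    "make_gene_models",
    "make_exome_intervals",
    "make_blacklist",
]

# Demographic marginals of the sequenced cohort (48 individuals).
DEFAULT_MORPHOLOGY = {
    "Apical hypertrophy": 2,
    "Asymmetric septal hypertrophy": 30,
    "Burnt-out hypertrophic": 1,
    "Concentric hypertrophy": 6,
    "Dilated": 1,
    "ECG+/LVH-": 3,
    "Inferior hypertrophy": 2,
    "Isolated noncompaction": 3,
}
DEFAULT_DIAGNOSIS = {"hypertrophic": 42, "dilated": 1, "noncompaction": 3,
                     "other": 2}
DEFAULT_SEX = {"F": 24, "M": 24}
DEFAULT_ANCESTRY = {
    "Caucasian": 34,
    "Hispanic": 2,
    "Asian": 3,
    "Middle Eastern": 2,
    "African American": 7,
}
# Continuous trait distributions: age/weight/height follow the cohort's
# summary statistics; the cardiac traits use typical HCM clinic values since
# only their analysis is specified, not their marginals.
DEFAULT_TRAITS = {
    "age": (47.2, 16.1),
    "weight_lbs": (177.8, 47.7),
    "height_in": (66.7, 5.4),
    "lvwt": (19.0, 5.0),  # mm
    "ef": (62.0, 8.0),  # percent
    "lvotg": (25.0, 20.0),  # mmHg
}
DEFAULT_TRAIT_BOUNDS = {
    "age": (7.0, 85.0),
    "weight_lbs": (40.0, 350.0),
    "height_in": (40.0, 82.0),
    "lvwt": (6.0, 40.0),
    "ef": (5.0, 90.0),
    "lvotg": (0.0, 150.0),
}

HYPERTROPHIC_MORPHS = (
    "Apical hypertrophy",
    "Asymmetric septal hypertrophy",
    "Burnt-out hypertrophic",
    "Concentric hypertrophy",
    "Inferior hypertrophy",
)


def _largest_remainder(counts: Mapping[str, int], total: int) -> dict[str, int]:
    """Rescale an integer marginal to a new total, preserving order."""
    src_total = sum(counts.values())
    raw = {k: v * total / src_total for k, v in counts.items()}
    out = {k: int(math.floor(v)) for k, v in raw.items()}
    short = total - sum(out.values())
    order = sorted(counts, key=lambda k: (-(raw[k] - out[k]), k))
    for k in order[:short]:
        out[k] += 1
    return out


@dataclass
class CohortConfig:
    """Structure and marginals of the simulated sequencing cohort."""

    n_individuals: int = 48
    n_families: int = 6
    n_unrelated: int = 40
    morphology_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOLOGY))
    diagnosis_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS))
    sex_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SEX))
    ancestry_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ANCESTRY))
    trait_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAITS))
    trait_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_BOUNDS))
    # Planted size of the analysis subset (unrelated individuals of the
    # reference ancestry with a hypertrophic diagnosis); the study analyzed 28.
    analysis_subset_target: int = 28
    reference_ancestry: str = "Caucasian"
    reference_diagnosis: str = "hypertrophic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        if self.n_individuals == 0:
            return
        for name in ("morphology_counts", "diagnosis_counts", "sex_counts",
                     "ancestry_counts"):
            counts = getattr(self, name)
            if any(v < 0 for v in counts.values()):
                raise ValueError(f"negative count in {name}")
            if sum(counts.values()) != self.n_individuals:
                raise ValueError(
                    f"{name} sums to {sum(counts.values())}, "
                    f"expected {self.n_individuals}"
                )
        for trait, (_, sd) in self.trait_means_sds.items():
            if sd <= 0:
                raise ValueError(f"sd for {trait} must be > 0")
        if not 0 < self.n_unrelated <= self.n_individuals:
            raise ValueError("n_unrelated must be in (0, n_individuals]")
        if not 0 < self.n_families <= self.n_unrelated:
            raise ValueError("n_families must be in (0, n_unrelated]")
        n_extras = self.n_individuals - self.n_unrelated
        if n_extras > 3 * self.n_families:
            raise ValueError("more than 3 extra relatives per family on average")

    @classmethod
    def scaled(cls, n_individuals: int, seed: int = 0) -> "CohortConfig":
        """Default marginals rescaled to a different cohort size."""
        base = cls()
        factor = n_individuals / base.n_individuals
        return cls(
            n_individuals=n_individuals,
            n_families=max(1, round(base.n_families * factor)),
            n_unrelated=max(1, round(base.n_unrelated * factor)),
            morphology_counts=_largest_remainder(DEFAULT_MORPHOLOGY, n_individuals),
            diagnosis_counts=_largest_remainder(DEFAULT_DIAGNOSIS, n_individuals),
            sex_counts=_largest_remainder(DEFAULT_SEX, n_individuals),
            ancestry_counts=_largest_remainder(DEFAULT_ANCESTRY, n_individuals),
            analysis_subset_target=round(base.analysis_subset_target * factor),
            seed=seed,
        )


@dataclass
class Cohort:
    """Generated individuals with pedigree, demographics and cardiac traits."""

    table: pd.DataFrame
    config: CohortConfig
    analysis_eligible_probands: int = 0

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])

    def __len__(self) -> int:
        return len(self.table)

    def copy(self) -> "Cohort":
        return Cohort(self.table.copy(), self.config,
                      self.analysis_eligible_probands)

    def to_tsv(self, path=None) -> str | None:
        text = self.table.to_csv(sep="\t", index=False, float_format="%.6g")
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def _family_sizes(config: CohortConfig) -> list[int]:
    """Extra first-degree relatives per family (1-3 each), round-robin."""
    extras = [0] * config.n_families
    remaining = config.n_individuals - config.n_unrelated
    i = 0
    while remaining > 0:
        if extras[i % config.n_families] < 3:
            extras[i % config.n_families] += 1
            remaining -= 1
        i += 1
    return extras


def _choose_noncaucasian_families(extras: list[int], needed_extras: int
                                  ) -> list[int] | None:
    """Smallest set of family indices whose extras sum to ``needed_extras``."""
    if needed_extras == 0:
        return []
    # DP over subset sums, tracking the fewest families (deterministic).
    best: dict[int, tuple[int, tuple[int, ...]]] = {0: (0, ())}
    for idx, x in enumerate(extras):
        for total, (cnt, who) in sorted(best.items()):
            new = total + x
            if new > needed_extras:
                continue
            cand = (cnt + 1, who + (idx,))
            if new not in best or cand < best[new]:
                best[new] = cand
    if needed_extras in best:
        return list(best[needed_extras][1])
    return None


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the cohort table.

    Categorical marginals match the configured counts exactly.  Family
    membership, ancestry and diagnosis are cross-classified so that the number
    of unrelated reference-ancestry individuals with the reference diagnosis
    equals ``analysis_subset_target`` whenever the marginals allow it; the
    achieved count is recorded on the returned cohort as the fixture truth.
    """
    config = config or CohortConfig()
    if config.n_individuals == 0:
        cols = ["sample_id", "family_id", "is_proband", "related_to", "sex",
                "ancestry", "diagnosis", "morphology", "age", "weight_lbs",
                "height_in", "bmi", "lvwt", "ef", "lvotg"]
        return Cohort(pd.DataFrame(columns=cols), config, 0)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))

    n = config.n_individuals
    extras = _family_sizes(config)
    n_extras = sum(extras)
    n_singles = config.n_unrelated - config.n_families
    ref_anc = config.reference_ancestry
    ref_dx = config.reference_diagnosis
    n_ref_anc = config.ancestry_counts.get(ref_anc, 0)
    n_ref_dx = config.diagnosis_counts.get(ref_dx, 0)

    # --- plant the analysis-subset size -------------------------------------
    # Families carry the reference diagnosis (sarcomere families).  Extras
    # share their family's ancestry, so the count of unrelated eligible
    # individuals is  (#reference-ancestry families) + (#eligible singles).
    # Making E_NC extras non-reference leaves  n_ref_anc - k - E_C  reference-
    # ancestry singles; the planted subset size is met by solving for E_NC.
    target = config.analysis_subset_target
    nc_families: list[int] = []
    feasible = n_ref_dx >= config.n_families + n_extras
    if feasible:
        needed_nc_extras = n_extras - n_ref_anc + target
        if 0 <= needed_nc_extras <= n_extras:
            chosen = _choose_noncaucasian_families(extras, needed_nc_extras)
            if chosen is not None:
                k = config.n_families - len(chosen)
                e_c = n_extras - needed_nc_extras
                singles_c = n_ref_anc - k - e_c
                h_singles = n_ref_dx - config.n_families - n_extras
                if 0 <= singles_c <= n_singles and singles_c <= h_singles:
                    nc_families = chosen

    rows: list[dict] = []
    fam_counter = 0
    for f in range(config.n_families):
        fam_counter += 1
        fam = f"FAM{fam_counter:03d}"
        proband = {"family_id": fam, "is_proband": True, "related_to": ""}
        rows.append(proband)
        for _ in range(extras[f]):
            rows.append({"family_id": fam, "is_proband": False,
                         "related_to": ""})
    for _ in range(n_singles):
        fam_counter += 1
        rows.append({"family_id": f"FAM{fam_counter:03d}", "is_proband": True,
                     "related_to": ""})
    df = pd.DataFrame(rows)
    df["sample_id"] = [f"S{i + 1:04d}" for i in range(n)]
    proband_of = df[df.is_proband].set_index("family_id")["sample_id"]
    df.loc[~df.is_proband, "related_to"] = df.loc[
        ~df.is_proband, "family_id"].map(proband_of)

    # --- ancestry -----------------------------------------------------------
    family_ids = [f"FAM{f + 1:03d}" for f in range(config.n_families)]
    nc_fam_ids = {family_ids[i] for i in nc_families}
    ancestry = pd.Series(index=df.index, dtype=object)
    pool = []
    for name, cnt in sorted(config.ancestry_counts.items()):
        if name != ref_anc:
            pool.extend([name] * cnt)
    is_family = df["family_id"].isin(family_ids)
    in_nc_family = df["family_id"].isin(nc_fam_ids)
    n_ref_left = n_ref_anc
    # reference-ancestry families first, then singles, then the remainder
    for idx in df.index[is_family & ~in_nc_family]:
        ancestry[idx] = ref_anc
        n_ref_left -= 1
    nonref_iter = iter(pool)
    for idx in df.index[in_nc_family]:
        ancestry[idx] = next(nonref_iter)
    for idx in df.index[~is_family]:
        if n_ref_left > 0:
            ancestry[idx] = ref_anc
            n_ref_left -= 1
        else:
            ancestry[idx] = next(nonref_iter)
    df["ancestry"] = ancestry

    # --- diagnosis ----------------------------------------------------------
    dx = pd.Series(index=df.index, dtype=object)
    other_dx = []
    for name, cnt in sorted(config.diagnosis_counts.items()):
        if name != ref_dx:
            other_dx.extend([name] * cnt)
    n_dx_left = n_ref_dx
    # family members first, then reference-ancestry singles (this is what
    # plants the analysis subset), then everyone else
    order = list(df.index[is_family])
    singles_idx = list(df.index[~is_family])
    order += [i for i in singles_idx if ancestry[i] == ref_anc]
    order += [i for i in singles_idx if ancestry[i] != ref_anc]
    other_iter = iter(other_dx)
    for idx in order:
        if n_dx_left > 0:
            dx[idx] = ref_dx
            n_dx_left -= 1
        else:
            dx[idx] = next(other_iter)
    df["diagnosis"] = dx

    eligible = (
        (df["ancestry"] == ref_anc)
        & (df["diagnosis"] == ref_dx)
        & df["is_proband"]
    )
    planted = int(eligible.sum())

    # --- morphology, consistent with diagnosis ------------------------------
    morph = pd.Series(index=df.index, dtype=object)
    remaining = dict(config.morphology_counts)

    def take(idx, choices) -> None:
        for c in choices:
            if remaining.get(c, 0) > 0:
                remaining[c] -= 1
                morph[idx] = c
                return
        # fall back to any morphology left
        for c in sorted(remaining):
            if remaining[c] > 0:
                remaining[c] -= 1
                morph[idx] = c
                return

    dx_pref = {
        "dilated": ("Dilated",),
        "noncompaction": ("Isolated noncompaction",),
        "other": ("ECG+/LVH-",),
        ref_dx: HYPERTROPHIC_MORPHS + ("ECG+/LVH-",),
    }
    for idx in df.index:
        prefs = dx_pref.get(dx[idx], ())
        if dx[idx] == ref_dx:
            shuffled = list(HYPERTROPHIC_MORPHS)
            rng.shuffle(shuffled)
            prefs = tuple(shuffled) + ("ECG+/LVH-",)
        take(idx, prefs)
    df["morphology"] = morph

    # --- sex ----------------------------------------------------------------
    sex_pool = []
    for name, cnt in sorted(config.sex_counts.items()):
        sex_pool.extend([name] * cnt)
    df["sex"] = rng.permutation(sex_pool)

    # --- continuous traits (truncated normal by rejection) -------------------
    for trait, (mean, sd) in config.trait_means_sds.items():
        lo, hi = config.trait_bounds.get(trait, (-np.inf, np.inf))
        vals = rng.normal(mean, sd, size=n)
        bad = (vals < lo) | (vals > hi)
        while bad.any():
            vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = (vals < lo) | (vals > hi)
        df[trait] = np.round(vals, 4)
    df["bmi"] = np.round(703.0 * df["weight_lbs"] / df["height_in"] ** 2, 4)

    cols = ["sample_id", "family_id", "is_proband", "related_to", "sex",
            "ancestry", "diagnosis", "morphology", "age", "weight_lbs",
            "height_in", "bmi", "lvwt", "ef", "lvotg"]
    return Cohort(df[cols].reset_index(drop=True), config, planted)


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

TRAIT_COLUMNS = {"LVWT": "lvwt", "EF": "ef", "LVOTG": "lvotg"}
VALID_TRUTH_TRAITS = ("LVWT", "EF", "LVOTG", "CASE_CONTROL")


@dataclass(frozen=True)
class ModifierSpec:
    """A planted modifier gene: carriers shift the linked trait."""

    gene: str
    trait: str  # LVWT | EF | LVOTG | CASE_CONTROL
    effect_sd: float  # per carried variant, in trait SD units
    carrier_fraction: float

    def __post_init__(self) -> None:
        if self.trait not in VALID_TRUTH_TRAITS:
            raise ValueError(f"trait must be one of {VALID_TRUTH_TRAITS}")
        if not np.isfinite(self.effect_sd):
            raise ValueError("effect size must be finite")
        if not 0 <= self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must lie in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth of the simulation: modifier genes and null genes."""

    modifiers: list[ModifierSpec] = field(default_factory=list)
    null_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = {m.gene for m in self.modifiers} & set(self.null_genes)
        if overlap:
            raise ValueError(f"genes both modifier and null: {sorted(overlap)}")

    @property
    def modifier_genes(self) -> list[str]:
        return [m.gene for m in self.modifiers]


@dataclass
class SimParams:
    """Rare-variant architecture and platform-noise parameters."""

    maf_range: tuple[float, float] = (1e-4, 0.01)
    variants_per_gene_mean: float = 8.0
    missingness_rate: float = 0.02
    depth_mean: float = 30.0
    cadd_mean: float = 14.0
    cadd_sd: float = 8.0
    impact_class_probs: dict[str, float] = field(
        default_factory=lambda: {"HIGH": 0.05, "MODERATE": 0.25,
                                 "LOW": 0.40, "MODIFIER": 0.30})
    fraction_novel: float = 0.30
    fraction_common: float = 0.08
    whitelist_fraction: float = 0.02
    low_avr_fraction: float = 0.05
    intergenic_variant_count: int = 40
    relative_sharing: float = 0.5  # transmission probability to relatives

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0 <= lo < hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 <= lo < hi <= 0.5")
        total = sum(self.impact_class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("impact class probabilities must sum to 1")
        for name in ("missingness_rate", "fraction_novel", "fraction_common",
                     "whitelist_fraction", "low_avr_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def make_gene_models(
    genes: Sequence[str],
    chrom: str = "chr1",
    gene_length: int = 20_000,
    spacing: int = 100_000,
    first_start: int = 100_000,
) -> pd.DataFrame:
    """Synthetic single-chromosome gene models (0-based half-open spans)."""
    rows = []
    for i, gene in enumerate(genes):
        start = first_start + i * spacing
        rows.append({"gene": str(gene).upper(), "chrom": chrom,
                     "start": start, "end": start + gene_length})
    return pd.DataFrame(rows)


def make_exome_intervals(
    gene_models: pd.DataFrame, exon_length: int = 12_000, name: str = "exome"
) -> RegionSet:
    """A capture footprint: the central ``exon_length`` bp of every gene.

    At this level of abstraction each gene's coding exons are a single
    central block, so the capture covers most but not all of the gene body
    and none of the intergenic space.
    """
    intervals = []
    for row in gene_models.itertuples():
        mid = (row.start + row.end) // 2
        half = min(exon_length, row.end - row.start) // 2
        intervals.append((row.chrom, mid - half, mid + half))
    return RegionSet(name, intervals)


def make_blacklist(gene_models: pd.DataFrame, width: int = 2000,
                   name: str = "blacklist") -> RegionSet:
    """False-positive-prone intervals placed between gene spans."""
    intervals = []
    gm = gene_models.sort_values(["chrom", "start"])
    for (_, a), (_, b) in zip(gm.iterrows(), gm.iloc[1:].iterrows()):
        if a.chrom != b.chrom or b.start - a.end < 3 * width:
            continue
        mid = (a.end + b.start) // 2
        intervals.append((a.chrom, mid - width // 2, mid + width // 2))
    return RegionSet(name, intervals)


@dataclass
class GenotypeSimResult:
    """Genotypes plus the trait-adjusted cohort and per-variant truth."""

    variants: VariantTable
    cohort: Cohort
    gene_of_variant: list[str]  # "" for intergenic background variants
    true_maf: np.ndarray
    carrier_status: pd.DataFrame  # genes x samples, planted carrier alleles

    @property
    def modifier_keys(self) -> list[tuple]:
        truth_genes = set(self.carrier_status.index)
        return [rec.key for rec, g in zip(self.variants.records,
                                          self.gene_of_variant)
                if g in truth_genes]


def generate_genotypes(
    cohort: Cohort,
    truth: TruthSet,
    params: SimParams | None = None,
    gene_models: pd.DataFrame | None = None,
    seed: int = 0,
) -> GenotypeSimResult:
    """Simulate rare-variant genotypes over the cohort.

    Null genes and intergenic background sites receive independent
    binomial(2, MAF) genotypes with MAF log-uniform in the configured rare
    range.  For each planted modifier gene, carriers are drawn at the
    configured carrier fraction and receive one heterozygous variant of the
    gene; each carried allele shifts the linked trait by ``effect_sd`` trait
    standard deviations.  First-degree relatives inherit each of their
    proband's alternate alleles with probability ``relative_sharing``.
    Missing genotypes are injected at ``missingness_rate`` together with
    simulated supporting read depths.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    params = params or SimParams()
    if gene_models is None:
        gene_models = make_gene_models(
            list(truth.modifier_genes) + list(truth.null_genes))
    models = {str(r.gene).upper(): r for r in gene_models.itertuples()}
    for gene in truth.modifier_genes + list(truth.null_genes):
        if str(gene).upper() not in models:
            raise KeyError(f"truth gene {gene!r} absent from gene models")

    ss = np.random.SeedSequence([seed, 23])
    rng_pos, rng_geno, rng_miss, rng_depth, rng_avr = (
        np.random.default_rng(s) for s in ss.spawn(5))

    df = cohort.table
    samples = list(df["sample_id"])
    n = len(samples)
    sample_idx = {s: i for i, s in enumerate(samples)}
    founder = df["is_proband"].to_numpy(dtype=bool)
    proband_row = np.full(n, -1)
    for i, rel in enumerate(df["related_to"]):
        if rel:
            proband_row[i] = sample_idx[rel]

    positions: list[tuple[str, int, str]] = []  # (chrom, pos0, gene)
    lo, hi = params.maf_range
    gene_list = sorted(models)
    for gene in gene_list:
        row = models[gene]
        m = 1 + rng_pos.poisson(max(params.variants_per_gene_mean - 1, 0.0))
        pos0 = np.sort(rng_pos.choice(
            np.arange(row.start, row.end), size=m, replace=False))
        positions.extend((row.chrom, int(p), gene) for p in pos0)
    # intergenic background on the same chromosome, upstream of all genes
    if params.intergenic_variant_count > 0:
        chrom0 = gene_models.iloc[0].chrom
        lo_pos = max(0, int(gene_models.start.min()) - 80_000)
        inter = np.sort(rng_pos.choice(
            np.arange(lo_pos, int(gene_models.start.min()) - 10_000),
            size=params.intergenic_variant_count, replace=False))
        positions.extend((chrom0, int(p), "") for p in inter)

    m_total = len(positions)
    mafs = np.exp(rng_geno.uniform(np.log(lo), np.log(hi), size=m_total))
    dosage = np.zeros((n, m_total), dtype=float)
    var_gene = [g for _, _, g in positions]
    gene_cols: dict[str, list[int]] = {}
    for j, g in enumerate(var_gene):
        if g:
            gene_cols.setdefault(g, []).append(j)

    # background genotypes for founders
    modifier_genes = set(truth.modifier_genes)
    background_cols = [j for j, g in enumerate(var_gene)
                       if g not in modifier_genes]
    for j in background_cols:
        dosage[founder, j] = rng_geno.binomial(2, mafs[j], size=founder.sum())

    # planted modifiers: carriers receive one het variant of the gene
    carrier = pd.DataFrame(False, index=sorted(modifier_genes), columns=samples)
    sd_map = {t: cohort.config.trait_means_sds[c][1]
              for t, c in TRAIT_COLUMNS.items()}
    adjusted = df.copy()
    for spec in truth.modifiers:
        gene = str(spec.gene).upper()
        cols = gene_cols[gene]
        implied = spec.carrier_fraction / (2 * len(cols))
        if spec.trait == "CASE_CONTROL":
            # effect_sd is the log2 fold-enrichment of carriers in cases
            # relative to the background population the controls sample
            implied /= 2.0 ** max(spec.effect_sd, 0.0)
        mafs[cols] = np.minimum(implied, hi * 0.99)
        is_carrier = rng_geno.random(n) < spec.carrier_fraction
        is_carrier &= founder
        which = rng_geno.integers(0, len(cols), size=n)
        for i in np.flatnonzero(is_carrier):
            dosage[i, cols[which[i]]] = 1.0
            carrier.loc[gene, samples[i]] = True

    # relatives inherit from their proband
    share = params.relative_sharing
    for i in np.flatnonzero(~founder):
        p = proband_row[i]
        transmitted = rng_geno.binomial(
            dosage[p].astype(int), share).astype(float)
        other = rng_geno.binomial(1, mafs)
        # modifier-gene columns get no background alleles from the other parent
        for g in modifier_genes:
            other[gene_cols[str(g).upper()]] = 0
        dosage[i] = np.minimum(transmitted + other, 2)
        for g in sorted(modifier_genes):
            if dosage[i, gene_cols[str(g).upper()]].sum() > 0:
                carrier.loc[str(g).upper(), samples[i]] = True

    # trait effects
    for spec in truth.modifiers:
        if spec.trait == "CASE_CONTROL":
            continue  # enrichment arises against background-MAF controls
        col = TRAIT_COLUMNS[spec.trait]
        burden = dosage[:, gene_cols[str(spec.gene).upper()]].sum(axis=1)
        adjusted[col] = adjusted[col] + spec.effect_sd * sd_map[spec.trait] * burden

    # missingness with simulated read support
    missing = rng_miss.random((n, m_total)) < params.missingness_rate
    records: list[VariantRecord] = []
    alphabet = ("A", "C", "G", "T")
    depth = rng_depth.poisson(params.depth_mean, size=(n, m_total))
    avr = np.where(
        rng_avr.random(m_total) < params.low_avr_fraction,
        rng_avr.uniform(0.001, 0.0199, size=m_total),
        rng_avr.uniform(0.02, 1.0, size=m_total),
    )
    for j, (chrom, pos0, _) in enumerate(positions):
        ref = alphabet[pos0 % 4]
        alt = alphabet[(pos0 + 1 + (j % 3)) % 4]
        per_sample = []
        for i in range(n):
            d = max(int(depth[i, j]), 1)
            g = dosage[i, j]
            if g == 0:
                ref_reads, alt_reads = d, 0
            elif g == 1:
                alt_reads = int(rng_depth.binomial(d, 0.5))
                ref_reads = d - alt_reads
            else:
                alt_reads, ref_reads = d, 0
            if missing[i, j]:
                per_sample.append(GenotypeCall("missing", ref_reads, alt_reads))
            else:
                name = {0: "hom_ref", 1: "het", 2: "hom_alt"}[int(g)]
                per_sample.append(GenotypeCall(name, ref_reads, alt_reads))
        records.append(VariantRecord(chrom, pos0 + 1, ref, alt, per_sample,
                                     avr_score=float(round(avr[j], 6))))
    table = VariantTable(samples, records)
    return GenotypeSimResult(
        variants=table,
        cohort=Cohort(adjusted, cohort.config, cohort.analysis_eligible_probands),
        gene_of_variant=var_gene,
        true_maf=mafs,
        carrier_status=carrier,
    )


def generate_annotations(
    variants: VariantTable | Sequence[VariantRecord],
    params: SimParams | None = None,
    seed: int = 0,
    true_maf: np.ndarray | None = None,
    favored_keys: Iterable[tuple] = (),
) -> pd.DataFrame:
    """Annotation table (population AF, CADD, impact, whitelist) per variant.

    Population AFs mix novel entries (absent), rare values scattered around
    the generating MAF, and a common fraction above the 1% boundary, so the
    rarity filter boundary is exercised from both sides.  ``favored_keys``
    (typically planted modifier variants) are guaranteed rare-or-novel and
    moderate/high impact: planted modifiers are functional rare variants by
    construction.
    """
    params = params or SimParams()
    records = variants.records if isinstance(variants, VariantTable) else list(variants)
    if not records:
        raise ValueError("variant list is empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    favored = set(favored_keys)
    m = len(records)
    if true_maf is None:
        true_maf = np.full(m, np.sqrt(params.maf_range[0] * params.maf_range[1]))
    u = rng.random(m)
    af = np.empty(m)
    novel = u < params.fraction_novel
    common = (u >= params.fraction_novel) & (
        u < params.fraction_novel + params.fraction_common)
    af[:] = np.clip(true_maf * np.exp(rng.normal(0, 0.5, size=m)),
                    1e-5, 0.0099)
    af[common] = rng.uniform(0.01, 0.05, size=int(common.sum()))
    af[novel] = np.nan
    cadd = np.clip(rng.normal(params.cadd_mean, params.cadd_sd, size=m), 0, 60)
    classes = sorted(params.impact_class_probs)
    probs = np.array([params.impact_class_probs[c] for c in classes])
    impact = rng.choice(classes, size=m, p=probs / probs.sum())
    whitelist = rng.random(m) < params.whitelist_fraction
    rows = []
    for j, rec in enumerate(records):
        is_fav = rec.key in favored
        rows.append({
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref,
            "alt": rec.alt,
            "population_af": np.nan if is_fav else af[j],
            "cadd": round(float(cadd[j]), 3),
            "impact": "MODERATE" if is_fav and impact[j] not in ("HIGH", "MODERATE")
                      else str(impact[j]),
            "whitelist_member": bool(whitelist[j]),
        })
    return pd.DataFrame(rows)


def generate_external_controls(
    case_table: VariantTable,
    exome_intervals: RegionSet,
    n_controls: int = 100,
    true_maf: np.ndarray | None = None,
    seed: int = 0,
    prefix: str = "CTRL",
) -> VariantTable:
    """Exome-sequenced external controls (platform-restricted footprint).

    Controls are genotyped only at the case variants that fall inside the
    exome capture intervals, at the background population MAF; this emulates
    the genome-vs-exome platform difference the digital-exome restriction is
    designed to mitigate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 53]))
    keep = [i for i, rec in enumerate(case_table.records)
            if exome_intervals.contains(rec.chrom, rec.pos0)]
    samples = [f"{prefix}{i + 1:04d}" for i in range(n_controls)]
    records = []
    for i in keep:
        rec = case_table.records[i]
        if true_maf is not None:
            maf = float(true_maf[i])
        else:
            G = np.array([c.dosage for c in rec.per_sample])
            maf = float(np.nanmean(G) / 2) if np.isfinite(G).any() else 0.0
        g = rng.binomial(2, min(maf, 0.5), size=n_controls)
        per_sample = [
            GenotypeCall({0: "hom_ref", 1: "het", 2: "hom_alt"}[int(x)],
                         ref_reads=30 - 15 * int(x), alt_reads=15 * int(x))
            for x in g
        ]
        records.append(replace(rec, per_sample=per_sample))
    return VariantTable(samples, records)


# --------------------------------------------------------------------------
# structural variants
# --------------------------------------------------------------------------

DEFAULT_CALLERS = ("breakdancer", "breakseqlite", "cnvnator", "delly", "freec")


@dataclass(frozen=True)
class SVEventSpec:
    """One requested SV event with a controlled reciprocal overlap."""

    sample: str
    callers: tuple[str, ...]
    ro: float = 1.0
    sv_type: str = "DEL"
    chrom: str = "chr1"
    start: int | None = None
    length: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.ro <= 1.0:
            raise ValueError(f"reciprocal overlap {self.ro} outside [0, 1]")
        if not self.callers:
            raise ValueError("event needs at least one caller")
        if self.length <= 0:
            raise ValueError("length must be > 0")


def generate_sv_callsets(
    cohort: Cohort | Sequence[str],
    overlap_spec: Sequence[SVEventSpec] | None = None,
    n_callers: int = 2,
    caller_names: Sequence[str] = DEFAULT_CALLERS,
    seed: int = 0,
) -> dict[str, list[SVCall]]:
    """Per-caller SV call lists with controlled pairwise reciprocal overlap.

    For each event the first listed caller receives the base interval; every
    additional caller receives the same-length interval shifted so that its
    reciprocal overlap with the base call equals the requested fraction to
    within 1/length.  When no spec is given, a default mixture of
    trusted-only, concordant (RO 0.7) and discordant (RO 0.3) events is
    produced for the first few samples.
    """
    samples = cohort.samples if isinstance(cohort, Cohort) else list(cohort)
    if overlap_spec is None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 67]))
        overlap_spec = []
        for s in samples[: min(8, len(samples))]:
            overlap_spec.extend([
                SVEventSpec(s, ("breakseqlite",), 1.0, "DEL"),
                SVEventSpec(s, tuple(caller_names[:n_callers]), 0.7, "DUP"),
                SVEventSpec(s, tuple(caller_names[:n_callers]), 0.3, "DEL"),
            ])
        del rng  # reserved for future jitter
    callsets: dict[str, list[SVCall]] = {c: [] for c in caller_names}
    cursor = 10_000
    for event in overlap_spec:
        start = event.start if event.start is not None else cursor
        cursor = max(cursor, start + event.length + 9 * event.length + 1000)
        shift = round(event.length * (1.0 - event.ro))
        for k, caller in enumerate(event.callers):
            s = start if k == 0 else start + shift
            call = SVCall(event.chrom, s, s + event.length, event.sv_type,
                          caller, event.sample)
            callsets.setdefault(caller, []).append(call)
    return callsets


# --------------------------------------------------------------------------
# expression experiments
# --------------------------------------------------------------------------

DEFAULT_EXPR_GENES = ("NPPB", "FHOD3", "MSRB2", "MYH7B", "PACSIN3", "SORBS2")


@dataclass
class ExpressionSimConfig:
    """Known fold changes and noise for the qPCR and RNA-seq experiments."""

    genes: tuple[str, ...] = DEFAULT_EXPR_GENES
    fold_change_case: dict[str, float] = field(
        default_factory=lambda: {"NPPB": 4.0, "SORBS2": 2.0, "FHOD3": 1.5})
    n_case: int = 39
    n_control: int = 13
    ct_noise_sd: float = 0.5
    housekeeping_ct: float = 18.0
    log2fd_treated_vs_sham: dict[str, float] = field(
        default_factory=lambda: {"NPPB": 2.0, "FHOD3": 1.0, "SORBS2": 1.0})
    n_per_arm: int = 3
    fpkm_log2_noise_sd: float = 0.25
    unexpressed_genes: tuple[str, ...] = ()


def generate_expression_experiment(
    seed: int = 0, config: ExpressionSimConfig | None = None
) -> tuple[pd.DataFrame, "object"]:
    """Simulate the qPCR Ct table and the treatment FPKM matrix.

    Returns ``(ct_table, expression_matrix)``.  Ct values: for each gene a
    baseline dCt is drawn once; case samples shift by -log2(fold change).
    FPKM: arms pre, treated and sham share a per-gene baseline and a common
    culture drift; the treated arm additionally changes by the configured
    log2 fold difference, so the treated-vs-sham ratio analysis recovers it.
    """
    from .expression import ExpressionMatrix

    config = config or ExpressionSimConfig()
    ss = np.random.SeedSequence([seed, 71])
    rng_ct, rng_fpkm = (np.random.default_rng(s) for s in ss.spawn(2))

    rows = []
    base_dct = {g: rng_ct.uniform(2.0, 8.0) for g in config.genes}
    for gene in config.genes:
        fold = config.fold_change_case.get(gene, 1.0)
        for grp, n_grp, shift in (("control", config.n_control, 0.0),
                                  ("case", config.n_case, -np.log2(fold))):
            for i in range(n_grp):
                hk = config.housekeeping_ct + rng_ct.normal(0, 0.2)
                dct = base_dct[gene] + shift + rng_ct.normal(
                    0, config.ct_noise_sd)
                rows.append({
                    "sample": f"{grp[:4].upper()}{i + 1:03d}",
                    "group": grp,
                    "gene": gene,
                    "ct_target": round(hk + dct, 4),
                    "ct_housekeeping": round(hk, 4),
                })
    ct_table = pd.DataFrame(rows)

    arms = {}
    cols = {}
    base = {g: float(np.exp(rng_fpkm.uniform(np.log(2.0), np.log(200.0))))
            for g in config.genes}
    for g in config.unexpressed_genes:
        base[g] = 0.2
    drift = 1.3  # shared culture drift between pre and the later arms
    for arm in ("pre", "sham", "treated"):
        for i in range(config.n_per_arm):
            name = f"{arm}_{i + 1}"
            arms[name] = arm
            vals = []
            for gene in base:
                mean = base[gene]
                if arm in ("sham", "treated"):
                    mean *= drift
                if arm == "treated":
                    mean *= 2.0 ** config.log2fd_treated_vs_sham.get(gene, 0.0)
                vals.append(mean * 2.0 ** rng_fpkm.normal(
                    0, config.fpkm_log2_noise_sd))
            cols[name] = vals
    values = pd.DataFrame(cols, index=list(base))
    return ct_table, ExpressionMatrix(values, arms)


# --------------------------------------------------------------------------
# external gene evidence (priors consumed by the scoring algorithm)
# --------------------------------------------------------------------------


def generate_gene_evidence_tables(
    truth: TruthSet, seed: int = 0
) -> dict[str, object]:
    """Favorable external priors for planted modifiers, unremarkable for nulls.

    Emulates the annotation context of a true modifier: high left-ventricle
    expression, loss-of-function constraint and curated candidate status
    (4 points).  Deliberately NOT sufficient for a notable modifier score on
    their own: reaching the reporting thresholds additionally requires the
    association evidence, so parameter-recovery runs test the whole pipeline,
    not the priors.  Null genes receive values drawn below every scoring
    threshold.  Returns expression/constraint/network tables, the candidate
    list and an empty flag list.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 83]))
    mods = [str(g).upper() for g in truth.modifier_genes]
    nulls = [str(g).upper() for g in truth.null_genes]
    genes = mods + nulls
    is_mod = np.array([g in set(mods) for g in genes])
    rpkm = np.where(is_mod, rng.uniform(20, 120, len(genes)),
                    rng.uniform(0, 8, len(genes)))
    lof = np.where(is_mod, rng.uniform(3.2, 6, len(genes)),
                   rng.normal(0, 1, len(genes)))
    mis = rng.normal(0, 1, len(genes))
    qh = rng.uniform(0.05, 1.0, len(genes))
    qf = rng.uniform(0.05, 1.0, len(genes))
    return {
        "expression": pd.DataFrame({"gene": genes, "rpkm_lv": rpkm.round(3)}),
        "constraint": pd.DataFrame({"gene": genes, "lof_z": lof.round(3),
                                    "mis_z": mis.round(3)}),
        "network": pd.DataFrame({"gene": genes,
                                 "q_hypertrophy": qh.round(6),
                                 "q_heart_failure": qf.round(6)}),
        "candidates": list(mods),
        "flags": [],
    }
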