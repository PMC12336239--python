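"""Post-calling variant filter cascade.

Reduces raw multi-sample calls to rare, high-confidence, putatively functional
variants and partitions them into the three analysis footprints:

* SET1 - all retained variants, genic and intergenic;
* SET2 - variants within gene bodies padded by 5 kb on each side;
* SET3 - a "digital exome": variants within exome-capture intervals padded by
  10 bp, used when comparing genome-sequenced cases against exome-sequenced
  controls.

The cascade order is: caller quality (AVR) -> cross-sample merge with
missing-genotype imputation -> population rarity -> false-positive region
blacklist -> functional consequence -> set construction.  Variants present in
clinically curated catalogues (ClinVar, GWAS catalog, PharmGKB, COSMIC) carry a
whitelist flag that rescues them from every knowledge-based filter, but never
from the caller-quality filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import RegionSet

__all__ = [
    "GenotypeCall",
    "VariantRecord",
    "VariantTable",
    "FilterConfig",
    "filter_by_avr",
    "merge_and_impute",
    "impute_missing",
    "apply_rarity_filter",
    "apply_region_blacklist",
    "apply_functional_filter",
    "build_variant_sets",
    "attach_annotations",
    "run_filter_cascade",
]

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")

VariantKey = tuple[str, int, str, str]  # chrom, 1-based pos, ref, alt


@dataclass
class GenotypeCall:
    """One sample's genotype at one site with supporting read counts."""

    genotype: str  # hom_ref | het | hom_alt | missing
    ref_reads: int = 0
    alt_reads: int = 0

    def __post_init__(self) -> None:
        if self.genotype not in ("hom_ref", "het", "hom_alt", "missing"):
            raise ValueError(f"bad genotype {self.genotype!r}")
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be >= 0")

    @property
    def dosage(self) -> float:
        return {"hom_ref": 0.0, "het": 1.0, "hom_alt": 2.0, "missing": np.nan}[
            self.genotype
        ]


@dataclass
class VariantRecord:
    """A biallelic called variant with per-sample genotypes and annotations.

    ``population_af`` of ``None`` encodes a novel variant (absent from the
    population reference panel); it is distinct from an observed frequency of
    zero.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    per_sample: list[GenotypeCall] = field(default_factory=list)
    avr_score: float | None = None
    population_af: float | None = None
    cadd: float | None = None
    impact: str | None = None
    whitelist_member: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.population_af is not None and not 0 <= self.population_af <= 1:
            raise ValueError(f"population_af outside [0,1]: {self.population_af}")
        if self.impact is not None and self.impact not in IMPACT_LEVELS:
            raise ValueError(f"impact must be one of {IMPACT_LEVELS}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def pos0(self) -> int:
        """0-based position (BED convention)."""
        return self.pos - 1


@dataclass
class VariantTable:
    """An ordered collection of variants over a fixed sample panel."""

    samples: list[str]
    records: list[VariantRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.per_sample and len(rec.per_sample) != len(self.samples):
                raise ValueError(
                    f"variant {rec.key} has {len(rec.per_sample)} genotype calls "
                    f"for {len(self.samples)} samples"
                )

    def __len__(self) -> int:
        return len(self.records)

    def dosage_matrix(self) -> np.ndarray:
        """n_samples x n_variants dosage matrix; missing genotypes are NaN."""
        n, m = len(self.samples), len(self.records)
        G = np.full((n, m), np.nan)
        for j, rec in enumerate(self.records):
            for i, call in enumerate(rec.per_sample):
                G[i, j] = call.dosage
        return G

    def subset(self, keep: Sequence[int]) -> "VariantTable":
        return VariantTable(self.samples, [self.records[i] for i in keep])

    def subset_samples(self, sample_ids: Sequence[str]) -> "VariantTable":
        idx = [self.samples.index(s) for s in sample_ids]
        recs = [
            replace(rec, per_sample=[rec.per_sample[i] for i in idx])
            if rec.per_sample
            else rec
            for rec in self.records
        ]
        return VariantTable(list(sample_ids), recs)

    def restrict_to_regions(self, regions: RegionSet) -> "VariantTable":
        keep = [
            i
            for i, rec in enumerate(self.records)
            if regions.contains(rec.chrom, rec.pos0)
        ]
        return self.subset(keep)


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade (defaults are the pipeline's)."""

    avr_min: float = 0.02
    af_max: float = 0.01
    cadd_min: float = 20.0
    impact_pass: frozenset[str] = frozenset({"MODERATE", "HIGH"})
    impute_min_reads: int = 10
    genic_pad_bp: int = 5000
    exome_pad_bp: int = 10

    def __post_init__(self) -> None:
        for name in ("avr_min", "af_max", "cadd_min", "impute_min_reads",
                     "genic_pad_bp", "exome_pad_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def filter_by_avr(
    variants: Iterable[VariantRecord], config: FilterConfig | None = None
) -> list[VariantRecord]:
    """Retain variants with caller quality (AVR) score >= the floor.

    The quality filter is never bypassed by whitelist membership.
    """
    config = config or FilterConfig()
    out = []
    for rec in variants:
        if rec.avr_score is None:
            raise ValueError(f"variant {rec.key} has no AVR score")
        if rec.avr_score >= config.avr_min:
            out.append(rec)
    return out


def merge_and_impute(
    calls_by_sample: Mapping[str, Mapping[VariantKey, GenotypeCall]],
    depths: Mapping[str, Mapping[VariantKey, tuple[int, int]]]
    | Callable[[str, VariantKey], tuple[int, int]]
    | None = None,
    config: FilterConfig | None = None,
) -> VariantTable:
    """Merge per-sample call sets over the union of variant keys.

    A sample without a call at a union site has its genotype imputed to
    homozygous reference when the site shows strictly more than
    ``impute_min_reads`` reference-supporting reads and zero reads supporting
    an alternate allele in that sample; otherwise the genotype stays missing.
    Read support for uncalled sites comes from ``depths`` (mapping or callable);
    absent evidence means zero reads, hence a missing genotype.
    """
    config = config or FilterConfig()
    samples = sorted(calls_by_sample)
    union: set[VariantKey] = set()
    for calls in calls_by_sample.values():
        union.update(calls)
    by_pos: dict[tuple[str, int], set[str]] = {}
    for chrom, pos, ref, _ in union:
        by_pos.setdefault((chrom, pos), set()).add(ref)
    for (chrom, pos), refs in by_pos.items():
        if len(refs) > 1:
            raise ValueError(
                f"conflicting reference alleles {sorted(refs)} at {chrom}:{pos}"
            )

    def lookup(sample: str, key: VariantKey) -> tuple[int, int]:
        if depths is None:
            return (0, 0)
        if callable(depths):
            return depths(sample, key)
        return depths.get(sample, {}).get(key, (0, 0))

    records = []
    for key in sorted(union):
        chrom, pos, ref, alt = key
        per_sample = []
        for sample in samples:
            call = calls_by_sample[sample].get(key)
            if call is None or call.genotype == "missing":
                ref_reads, alt_reads = (
                    (call.ref_reads, call.alt_reads) if call else lookup(sample, key)
                )
                if ref_reads > config.impute_min_reads and alt_reads == 0:
                    call = GenotypeCall("hom_ref", ref_reads, alt_reads)
                else:
                    call = GenotypeCall("missing", ref_reads, alt_reads)
            per_sample.append(call)
        records.append(VariantRecord(chrom, pos, ref, alt, per_sample))
    return VariantTable(samples, records)


def impute_missing(
    table: VariantTable, config: FilterConfig | None = None
) -> tuple[VariantTable, int]:
    """Apply the missing-genotype imputation rule to a merged table.

    Same rule as :func:`merge_and_impute`, for tables that already carry read
    support on their missing calls: a missing genotype becomes homozygous
    reference when strictly more than ``impute_min_reads`` reference reads
    support the site and no read supports an alternate allele.  Returns the
    imputed table and the number of imputed genotypes.
    """
    config = config or FilterConfig()
    n_imputed = 0
    records = []
    for rec in table.records:
        per_sample = []
        for call in rec.per_sample:
            if (call.genotype == "missing"
                    and call.ref_reads > config.impute_min_reads
                    and call.alt_reads == 0):
                call = GenotypeCall("hom_ref", call.ref_reads, call.alt_reads)
                n_imputed += 1
            per_sample.append(call)
        records.append(replace(rec, per_sample=per_sample))
    return VariantTable(table.samples, records), n_imputed


def apply_rarity_filter(
    variants: Iterable[VariantRecord], config: FilterConfig | None = None
) -> list[VariantRecord]:
    """Retain novel variants and those with population AF strictly below 1%.

    Whitelisted variants are retained regardless of frequency.
    """
    config = config or FilterConfig()
    return [
        rec
        for rec in variants
        if rec.whitelist_member
        or rec.population_af is None
        or rec.population_af < config.af_max
    ]


def apply_region_blacklist(
    variants: Iterable[VariantRecord], blacklist: RegionSet
) -> list[VariantRecord]:
    """Drop variants inside false-positive-enriched regions (whitelist wins)."""
    return [
        rec
        for rec in variants
        if rec.whitelist_member or not blacklist.contains(rec.chrom, rec.pos0)
    ]


def apply_functional_filter(
    variants: Iterable[VariantRecord], config: FilterConfig | None = None
) -> list[VariantRecord]:
    """Retain variants with moderate/high predicted impact or CADD > 20.

    The CADD comparison is strict.  Whitelisted variants are retained.
    """
    config = config or FilterConfig()
    out = []
    for rec in variants:
        if rec.whitelist_member:
            out.append(rec)
            continue
        ok_impact = rec.impact is not None and rec.impact in config.impact_pass
        ok_cadd = rec.cadd is not None and rec.cadd > config.cadd_min
        if ok_impact or ok_cadd:
            out.append(rec)
    return out


def build_variant_sets(
    variants: Sequence[VariantRecord],
    gene_models: pd.DataFrame,
    exome_intervals: RegionSet,
    config: FilterConfig | None = None,
) -> dict[str, list[VariantRecord]]:
    """Partition retained variants into the three analysis footprints.

    ``gene_models`` needs columns ``gene, chrom, start, end`` in 0-based
    half-open coordinates.  SET2 pads the full gene span by ``genic_pad_bp`` on
    both sides; SET3 pads each exome-capture interval by ``exome_pad_bp``.
    Variants on chromosomes absent from the models are excluded from SET2/SET3
    with a warning.
    """
    config = config or FilterConfig()
    genic = RegionSet(
        "genic",
        [(r.chrom, r.start, r.end) for r in gene_models.itertuples()],
    ).padded(config.genic_pad_bp)
    exome = exome_intervals.padded(config.exome_pad_bp)
    known_chroms = genic.chromosomes() | exome.chromosomes()
    unknown = sorted({rec.chrom for rec in variants} - known_chroms)
    if unknown:
        warnings.warn(
            f"chromosomes {unknown} absent from gene models/exome intervals; "
            "their variants appear only in SET1",
            stacklevel=2,
        )
    return {
        "SET1": list(variants),
        "SET2": [r for r in variants if genic.contains(r.chrom, r.pos0)],
        "SET3": [r for r in variants if exome.contains(r.chrom, r.pos0)],
    }


def attach_annotations(
    variants: Iterable[VariantRecord], annotations: pd.DataFrame
) -> list[VariantRecord]:
    """Join an annotation table onto variant records by (chrom, pos, ref, alt).

    Expected columns: ``chrom, pos, ref, alt, population_af, cadd, impact,
    whitelist_member``; a NaN ``population_af`` encodes a novel variant.
    """
    idx = {}
    for row in annotations.itertuples():
        idx[(str(row.chrom), int(row.pos), row.ref, row.alt)] = row
    out = []
    for rec in variants:
        row = idx.get(rec.key)
        if row is None:
            out.append(rec)
            continue
        af = None if pd.isna(row.population_af) else float(row.population_af)
        out.append(
            replace(
                rec,
                population_af=af,
                cadd=float(row.cadd),
                impact=str(row.impact),
                whitelist_member=bool(row.whitelist_member),
            )
        )
    return out


def run_filter_cascade(
    table: VariantTable,
    annotations: pd.DataFrame,
    blacklist: RegionSet,
    gene_models: pd.DataFrame,
    exome_intervals: RegionSet,
    config: FilterConfig | None = None,
) -> tuple[dict[str, VariantTable], pd.DataFrame]:
    """Run AVR -> rarity -> blacklist -> functional -> set construction.

    The input ``table`` is assumed to be the merged, imputed cohort table.
    Returns the three variant sets (as tables over the same samples) and a
    per-stage counts report (stage, variants_in, variants_out).
    """
    config = config or FilterConfig()
    stages = []
    recs = attach_annotations(table.records, annotations)

    def log(stage: str, before: int, after: int) -> None:
        stages.append({"stage": stage, "variants_in": before, "variants_out": after})

    n0 = len(recs)
    recs = filter_by_avr(recs, config)
    log("avr", n0, len(recs))
    imputed, n_imputed = impute_missing(
        VariantTable(table.samples, recs), config)
    recs = imputed.records
    log(f"impute({n_imputed} genotypes)", len(recs), len(recs))
    n0 = len(recs)
    recs = apply_rarity_filter(recs, config)
    log("rarity", n0, len(recs))
    n0 = len(recs)
    recs = apply_region_blacklist(recs, blacklist)
    log("blacklist", n0, len(recs))
    n0 = len(recs)
    recs = apply_functional_filter(recs, config)
    log("functional", n0, len(recs))
    sets = build_variant_sets(recs, gene_models, exome_intervals, config)
    for name in ("SET1", "SET2", "SET3"):
        log(name, len(recs), len(sets[name]))
    tables = {
        name: VariantTable(table.samples, list(members))
        for name, members in sets.items()
    }
    return tables, pd.DataFrame(stages)
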