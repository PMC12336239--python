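"""Readers and writers for the pipeline's on-disk formats.

Multi-sample VCF 4.2 (GT, DP, AD per sample) via cyvcf2 on read, plain text on
write; phenotype/annotation/SV/results tables as TSV; region sets as BED
(0-based half-open).  Multi-allelic VCF records are split into biallelic
records on read.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .filtering import GenotypeCall, VariantRecord, VariantTable
from .intervals import RegionSet
from .sv import SVCall

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_bed",
    "read_bed",
    "write_sv_calls",
    "read_sv_calls",
    "write_annotations",
    "read_annotations",
]

_GT_STR = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}
_STR_GT = {(0, 0): "hom_ref", (0, 1): "het", (1, 0): "het", (1, 1): "hom_alt"}


def write_vcf(table: VariantTable, path: str) -> None:
    """Write a VariantTable as a plain-text multi-sample VCF 4.2."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AVR,Number=1,Type=Float,Description="Adaptive variant '
        'rescoring score">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples),
    ]
    for rec in sorted(table.records, key=lambda r: (r.chrom, r.pos, r.ref,
                                                    r.alt)):
        info = f"AVR={rec.avr_score:.6g}" if rec.avr_score is not None else "."
        fields = [rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".",
                  "PASS", info, "GT:DP:AD"]
        for call in rec.per_sample:
            dp = call.ref_reads + call.alt_reads
            fields.append(
                f"{_GT_STR[call.genotype]}:{dp}:{call.ref_reads},{call.alt_reads}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> VariantTable:
    """Read a multi-sample VCF with cyvcf2, splitting multi-allelic records."""
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        alts = v.ALT or []
        gt_types = v.genotypes  # [[a, b, phased], ...]
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        avr = v.INFO.get("AVR")
        for alt_i, alt in enumerate(alts, start=1):
            per_sample = []
            for si in range(len(samples)):
                a, b = gt_types[si][0], gt_types[si][1]
                if a < 0 or b < 0:
                    name = "missing"
                else:
                    name = _STR_GT[(int(a == alt_i), int(b == alt_i))]
                if ad is not None and ad.shape[1] > alt_i:
                    ref_reads = max(int(ad[si][0]), 0)
                    alt_reads = max(int(ad[si][alt_i]), 0)
                else:
                    ref_reads = alt_reads = 0
                per_sample.append(GenotypeCall(name, ref_reads, alt_reads))
            records.append(
                VariantRecord(str(v.CHROM), int(v.POS), str(v.REF), str(alt),
                              per_sample,
                              avr_score=float(avr) if avr is not None else None))
    return VariantTable(samples, records)


def write_bed(regions: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\t{regions.name}\n")


def read_bed(path: str, name: str | None = None) -> RegionSet:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "label"],
                     usecols=[0, 1, 2, 3], comment="#",
                     dtype={0: str})
    label = name or (str(df["label"].iloc[0]) if len(df) else "regions")
    return RegionSet(label, [(r.chrom, int(r.start), int(r.end))
                             for r in df.itertuples()])


def write_sv_calls(calls: Iterable[SVCall], path: str) -> None:
    rows = [{"chrom": c.chrom, "start": c.start, "end": c.end,
             "type": c.sv_type, "caller": c.caller, "sample": c.sample}
            for c in calls]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sv_calls(path: str) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [SVCall(r.chrom, int(r.start), int(r.end), str(r.type),
                   str(r.caller), str(r.sample)) for r in df.itertuples()]


def write_annotations(annotations: pd.DataFrame, path: str) -> None:
    annotations.to_csv(path, sep="\t", index=False, float_format="%.6g",
                       na_rep="NA")


def read_annotations(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    df["whitelist_member"] = df["whitelist_member"].astype(bool)
    return df
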