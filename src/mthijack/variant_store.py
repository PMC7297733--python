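"""Per-sample mtDNA variant calls: containers, I/O, filtering, normalisation.

Coordinates are 1-based and circular (canine mtDNA, length 16,727 by
default).  Insertions are anchored at the base preceding the inserted
sequence, i.e. REF is the anchor base and ALT is anchor + inserted bases,
following VCF convention.  The VCF dialect is v4.2, single sample, with
AD/DP carrying supporting/total read counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

TSV_COLUMNS = ["sample", "chrom", "pos", "ref", "alt",
               "supporting_reads", "total_reads", "vaf"]


class VariantValidationError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Variant:
    """A single mtDNA variant (substitution, insertion or deletion)."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise VariantValidationError("alleles must be non-empty")
        if self.position < 1:
            raise VariantValidationError(f"position {self.position} < 1")

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "substitution"
        if len(self.alt) > len(self.ref):
            return "insertion"
        return "deletion"

    def __str__(self) -> str:
        if self.kind == "substitution":
            return f"{self.position}{self.ref}>{self.alt}"
        if self.kind == "insertion":
            return f"{self.position}ins{self.alt[len(self.ref):]}"
        return f"{self.position}del{self.ref[len(self.alt):]}"


def validate_position(pos: int, genome_length: int) -> None:
    if not 1 <= pos <= genome_length:
        raise VariantValidationError(
            f"position {pos} outside 1..{genome_length}")


class VariantTable:
    """Table of per-sample variant calls with read support and VAF.

    Backed by a pandas DataFrame with columns ``sample, chrom, pos, ref,
    alt, supporting_reads, total_reads, vaf``.  Read counts may be NaN for
    profile-derived calls without pileup evidence; when counts are present,
    ``vaf = supporting_reads / total_reads``.
    """

    def __init__(self, df: pd.DataFrame, genome_length: int = 16727):
        missing = [c for c in TSV_COLUMNS if c not in df.columns]
        if missing:
            raise VariantValidationError(f"missing columns: {missing}")
        df = df[TSV_COLUMNS].copy()
        for col in ("supporting_reads", "total_reads", "vaf"):
            df[col] = df[col].astype(float)
        df["pos"] = df["pos"].astype(int)
        for pos in df["pos"]:
            validate_position(int(pos), genome_length)
        has_reads = df["total_reads"].notna() & (df["total_reads"] > 0)
        if (df.loc[has_reads, "supporting_reads"]
                > df.loc[has_reads, "total_reads"]).any():
            raise VariantValidationError("supporting_reads > total_reads")
        expected = (df.loc[has_reads, "supporting_reads"]
                    / df.loc[has_reads, "total_reads"])
        if not np.allclose(df.loc[has_reads, "vaf"], expected, atol=1e-6):
            raise VariantValidationError(
                "vaf inconsistent with supporting/total reads")
        if ((df["vaf"] < 0) | (df["vaf"] > 1)).any():
            raise VariantValidationError("vaf outside [0, 1]")
        self.df = df.reset_index(drop=True)
        self.genome_length = genome_length

    @classmethod
    def from_calls(cls, calls: Iterable[tuple[str, Variant, float]],
                   genome_length: int = 16727) -> "VariantTable":
        """Build from (sample, variant, vaf) triples without read counts."""
        rows = [
            {"sample": s, "chrom": "MT", "pos": v.position, "ref": v.ref,
             "alt": v.alt, "supporting_reads": np.nan,
             "total_reads": np.nan, "vaf": f}
            for s, v, f in calls
        ]
        df = pd.DataFrame(rows, columns=TSV_COLUMNS)
        return cls(df, genome_length)

    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def variants_of(self, sample: str, min_vaf: float = 0.0) -> set[Variant]:
        sub = self.df[(self.df["sample"] == sample)
                      & (self.df["vaf"] >= min_vaf)]
        return {Variant(int(r.pos), r.ref, r.alt)
                for r in sub.itertuples(index=False)}

    def vafs_of(self, sample: str) -> dict[Variant, float]:
        sub = self.df[self.df["sample"] == sample]
        return {Variant(int(r.pos), r.ref, r.alt): float(r.vaf)
                for r in sub.itertuples(index=False)}

    def carriers(self, variant: Variant, min_vaf: float = 0.0) -> set[str]:
        sub = self.df[(self.df["pos"] == variant.position)
                      & (self.df["ref"] == variant.ref)
                      & (self.df["alt"] == variant.alt)
                      & (self.df["vaf"] >= min_vaf)]
        return set(sub["sample"])

    def _canonical(self) -> pd.DataFrame:
        return (self.df.sort_values(["sample", "pos", "ref", "alt"])
                .reset_index(drop=True))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantTable):
            return NotImplemented
        a, b = self._canonical(), other._canonical()
        if len(a) != len(b):
            return False
        obj_eq = (a[["sample", "chrom", "ref", "alt"]]
                  .equals(b[["sample", "chrom", "ref", "alt"]]))
        num_a = a[["pos", "supporting_reads", "total_reads", "vaf"]].to_numpy(float)
        num_b = b[["pos", "supporting_reads", "total_reads", "vaf"]].to_numpy(float)
        num_eq = np.allclose(num_a, num_b, atol=1e-9, equal_nan=True)
        return bool(obj_eq and num_eq)

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path, format: str = "tsv",
                       genome_length: int = 16727) -> VariantTable:
    """Read a variant table from TSV or single-sample VCF."""
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise VariantValidationError(f"cannot parse {path}: {exc}") from exc
        if df.empty and not set(TSV_COLUMNS) <= set(df.columns):
            df = pd.DataFrame(columns=TSV_COLUMNS)
        return VariantTable(df, genome_length)
    if format == "vcf":
        return _read_vcf(path, genome_length)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: Path, genome_length: int) -> VariantTable:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if len(sample_names) != 1:
            raise VariantValidationError(
                f"expected single-sample VCF, found {len(sample_names)} samples")
        sample = sample_names[0]
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                sup = tot = np.nan
                fmt = rec.samples[sample]
                if "AD" in fmt and fmt["AD"] is not None and fmt["AD"][0] is not None:
                    ad = fmt["AD"]
                    sup = float(ad[1])
                    tot = float(fmt.get("DP") or sum(a for a in ad if a is not None))
                if not math.isnan(tot) and tot > 0:
                    vaf = sup / tot
                elif "AF" in rec.info:
                    af = rec.info["AF"]
                    vaf = float(af[0] if isinstance(af, tuple) else af)
                else:
                    vaf = 1.0
                rows.append({"sample": sample, "chrom": rec.chrom,
                             "pos": rec.pos, "ref": rec.ref, "alt": alt,
                             "supporting_reads": sup, "total_reads": tot,
                             "vaf": vaf})
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    return VariantTable(df, genome_length)


def write_variant_table(table: VariantTable, path: str | Path,
                        format: str = "tsv") -> Path:
    """Write a variant table; VCF output requires a single-sample table."""
    path = Path(path)
    if format == "tsv":
        table.df.to_csv(path, sep="\t", index=False)
        return path
    if format == "vcf":
        samples = table.samples()
        if len(samples) > 1:
            raise VariantValidationError(
                "VCF output is single-sample; write one file per sample")
        sample = samples[0] if samples else "SAMPLE"
        _write_vcf(table, sample, path)
        return path
    raise ValueError(f"unknown format {format!r}")


def _write_vcf(table: VariantTable, sample: str, path: Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=MT,length={table.genome_length}>",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele fraction">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt supporting reads">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    sub = table._canonical()
    for r in sub.itertuples(index=False):
        info = f"AF={r.vaf:.6g}"
        if not (isinstance(r.total_reads, float) and math.isnan(r.total_reads)):
            tot, sup = int(r.total_reads), int(r.supporting_reads)
            fmt, val = "GT:AD:DP", f"1:{tot - sup},{sup}:{tot}"
        else:
            fmt, val = "GT", "1"
        lines.append(f"MT\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                     f"{info}\t{fmt}\t{val}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pileup filtering
# ---------------------------------------------------------------------------

def filter_substitutions(pileup: pd.DataFrame, min_reads: int = 3,
                         min_mq: int = 20, min_bq: int = 20) -> pd.DataFrame:
    """Apply the supporting-read quality filter to a pileup summary.

    ``pileup`` holds one row per supporting read with columns ``sample,
    pos, ref, alt, mq, bq``.  A variant passes iff the number of its reads
    with mapping quality >= ``min_mq`` and base quality >= ``min_bq`` is at
    least ``min_reads``.  Returns one row per variant with ``n_qualifying``
    and ``passed``.
    """
    required = {"sample", "pos", "ref", "alt", "mq", "bq"}
    if not required <= set(pileup.columns):
        raise VariantValidationError(
            f"pileup missing columns: {sorted(required - set(pileup.columns))}")
    if ((pileup["mq"] < 0) | (pileup["bq"] < 0)).any():
        raise VariantValidationError("qualities must be >= 0")
    keys = ["sample", "pos", "ref", "alt"]
    qual = (pileup["mq"] >= min_mq) & (pileup["bq"] >= min_bq)
    counts = (pileup.assign(q=qual.astype(int)).groupby(keys, sort=True)["q"]
              .sum().reset_index(name="n_qualifying"))
    counts["passed"] = counts["n_qualifying"] >= min_reads
    return counts


# ---------------------------------------------------------------------------
# Indel normalisation
# ---------------------------------------------------------------------------

def _circ(pos: int, genome_length: int) -> int:
    return (pos - 1) % genome_length + 1


def _ref_base(reference: str, pos: int) -> str:
    return reference[(pos - 1) % len(reference)]


def normalise_indel(variant: Variant, reference: str) -> Variant:
    """Left-align an indel on the circular reference (idempotent).

    Insertions/deletions inside a homopolymer or repeat run are shifted to
    the leftmost equivalent anchor, wrapping through the origin if needed.
    Substitutions are returned unchanged after allele validation.
    """
    n = len(reference)
    validate_position(variant.position, n)
    if variant.kind == "substitution":
        if _ref_base(reference, variant.position) != variant.ref:
            raise VariantValidationError(
                f"ref allele {variant.ref} does not match reference at "
                f"{variant.position}")
        return variant

    anchor = variant.position
    if _ref_base(reference, anchor) != variant.ref[0]:
        raise VariantValidationError(
            f"anchor base {variant.ref[0]} does not match reference at {anchor}")

    if variant.kind == "insertion":
        ins = variant.alt[len(variant.ref):]
        if len(variant.ref) != 1:
            raise VariantValidationError("insertion REF must be the anchor base")
        # shift left while the last inserted base equals the base at the
        # current anchor (rotation equivalence); bounded walk on the circle
        for _ in range(n):
            if ins[-1] == _ref_base(reference, anchor):
                ins = _ref_base(reference, anchor) + ins[:-1]
                anchor = _circ(anchor - 1, n)
            else:
                break
        base = _ref_base(reference, anchor)
        return Variant(anchor, base, base + ins)

    # deletion: REF = anchor + deleted bases, ALT = anchor
    deleted = variant.ref[len(variant.alt):]
    if len(variant.alt) != 1:
        raise VariantValidationError("deletion ALT must be the anchor base")
    for i, b in enumerate(deleted):
        if _ref_base(reference, _circ(anchor + 1 + i, n)) != b:
            raise VariantValidationError(
                f"deleted bases do not match reference after {anchor}")
    k = len(deleted)
    for _ in range(n):
        if _ref_base(reference, anchor) == _ref_base(reference, _circ(anchor + k, n)):
            anchor = _circ(anchor - 1, n)
        else:
            break
    base = _ref_base(reference, anchor)
    deleted = "".join(_ref_base(reference, _circ(anchor + 1 + i, n))
                      for i in range(k))
    return Variant(anchor, base + deleted, base)
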