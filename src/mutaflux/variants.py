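"""Somatic SNV filtering and early-passage baseline subtraction.

The pipeline consumes VCF calls from a tumor/matched-normal caller and
applies the post-calling filters used for hypermutator cell-line data:
minimum depth in both samples (20x normal / 30x tumor for exomes, 10x/10x
for whole genomes), exclusion of sites present in common variant databases
(dbSNP138, 1000 Genomes, CG69, ESP6500 — carried as INFO flags), and a 5%
variant-allele-frequency floor.  Subtracting an early-passage (P0) call
set then isolates mutations that arose during a defined number of
population doublings.

VCF reading and writing go through :mod:`pysam`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam

__all__ = [
    "DB_FLAGS",
    "VariantRecord",
    "FilterConfig",
    "FilterResult",
    "filter_variants",
    "subtract_baseline",
    "read_vcf",
    "write_vcf",
]

#: INFO flag keys marking membership in common variant databases.
DB_FLAGS = ("DBSNP", "KG", "CG69", "ESP")

_DEPTH_DEFAULTS = {"exome": (20, 30), "wgs": (10, 10)}


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV call with depths, VAF and database flags."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref_base: str
    alt_base: str
    tumor_depth: int
    normal_depth: int
    vaf: float
    db_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT" or len(b) != 1:
                raise ValueError(f"SNV records need single ACGT alleles, got {b!r}")
        if not (0 <= self.vaf <= 1):
            raise ValueError("vaf must be in [0, 1]")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref_base, self.alt_base)


@dataclass
class FilterConfig:
    """Depth / database / VAF retention thresholds for one assay type."""

    assay: str = "exome"
    min_normal_depth: Optional[int] = None
    min_tumor_depth: Optional[int] = None
    min_vaf: float = 0.05
    exclude_db: frozenset = frozenset(DB_FLAGS)

    def __post_init__(self) -> None:
        if self.assay not in _DEPTH_DEFAULTS:
            raise ValueError(f"unknown assay {self.assay!r}; use 'exome' or 'wgs'")
        normal_default, tumor_default = _DEPTH_DEFAULTS[self.assay]
        if self.min_normal_depth is None:
            self.min_normal_depth = normal_default
        if self.min_tumor_depth is None:
            self.min_tumor_depth = tumor_default
        if not (0 <= self.min_vaf <= 1):
            raise ValueError("min_vaf must be in [0, 1]")
        self.exclude_db = frozenset(self.exclude_db)


@dataclass
class FilterResult:
    """Retained records plus a per-criterion rejection tally.

    Each rejected record is attributed to its *first* failing criterion in
    the fixed order depth -> database -> vaf, so the tally is reproducible
    and sums (with the retained count) to the input count.  Iterating the
    result yields the retained records.
    """

    records: list[VariantRecord]
    tally: dict[str, int]
    n_input: int

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


def filter_variants(
    records: Sequence[VariantRecord], config: FilterConfig
) -> FilterResult:
    """Apply depth, database-membership and VAF filters, preserving order."""
    kept: list[VariantRecord] = []
    tally = {"depth": 0, "database": 0, "vaf": 0}
    for rec in records:
        if (
            rec.normal_depth < config.min_normal_depth
            or rec.tumor_depth < config.min_tumor_depth
        ):
            tally["depth"] += 1
        elif rec.db_flags & config.exclude_db:
            tally["database"] += 1
        elif rec.vaf < config.min_vaf:
            tally["vaf"] += 1
        else:
            kept.append(rec)
    return FilterResult(records=kept, tally=tally, n_input=len(records))


def subtract_baseline(
    late: Iterable[VariantRecord], baseline: Iterable[VariantRecord]
) -> list[VariantRecord]:
    """Keep late-sample calls absent from the baseline (by chrom,pos,ref,alt)."""
    baseline_keys = {rec.key for rec in baseline}
    return [rec for rec in late if rec.key not in baseline_keys]


# --- VCF I/O -------------------------------------------------------------------


def read_vcf(
    path: str | Path,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Read SNVs from a VCF into :class:`VariantRecord` objects.

    Multiallelic rows are split into one record per alt allele.  Non-SNV
    alleles (indels, symbolic) are rejected at parse and counted.  Depths
    come from the per-sample FORMAT ``DP``; VAF from the tumor sample's
    ``AF`` (falling back to ``AD``).  Database membership is read from the
    INFO flags DBSNP/KG/CG69/ESP.

    Returns ``(records, skipped_tally)``.
    """
    records: list[VariantRecord] = []
    skipped = {"non_snv": 0, "missing_fields": 0}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if tumor_sample not in samples or normal_sample not in samples:
            if len(samples) == 2:
                normal_sample, tumor_sample = samples
            else:
                raise ValueError(
                    f"samples {tumor_sample!r}/{normal_sample!r} not in VCF "
                    f"(found {samples})"
                )
        declared_flags = [k for k in DB_FLAGS if k in vcf.header.info]
        for row in vcf:
            flags = frozenset(k for k in declared_flags if row.info.get(k, False))
            tumor = row.samples[tumor_sample]
            normal = row.samples[normal_sample]
            for i, alt in enumerate(row.alts or ()):
                if len(row.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                    skipped["non_snv"] += 1
                    continue
                try:
                    t_dp = int(tumor["DP"])
                    n_dp = int(normal["DP"])
                except (KeyError, TypeError):
                    skipped["missing_fields"] += 1
                    continue
                vaf = _tumor_vaf(tumor, i, t_dp)
                if vaf is None:
                    skipped["missing_fields"] += 1
                    continue
                records.append(
                    VariantRecord(
                        chrom=row.chrom,
                        pos=row.pos,
                        ref_base=row.ref,
                        alt_base=alt,
                        tumor_depth=t_dp,
                        normal_depth=n_dp,
                        vaf=vaf,
                        db_flags=flags,
                    )
                )
    return records, skipped


def _tumor_vaf(sample, alt_index: int, depth: int) -> Optional[float]:
    af = sample.get("AF")
    if af is not None:
        value = af[alt_index] if isinstance(af, tuple) else af
        if value is not None:
            return float(value)
    ad = sample.get("AD")
    if ad is not None and depth > 0:
        alt_reads = ad[alt_index + 1]
        if alt_reads is not None:
            return float(alt_reads) / depth
    return None


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    contig_lengths: Optional[dict[str, int]] = None,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> None:
    """Write records as an uncompressed two-sample VCF (NORMAL, TUMOR)."""
    header = pysam.VariantHeader()
    for flag in DB_FLAGS:
        header.add_meta(
            "INFO",
            items=[("ID", flag), ("Number", 0), ("Type", "Flag"),
                   ("Description", f"Present in {flag} database")],
        )
    header.add_meta(
        "FORMAT",
        items=[("ID", "DP"), ("Number", 1), ("Type", "Integer"),
               ("Description", "Read depth")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "AF"), ("Number", "A"), ("Type", "Float"),
               ("Description", "Allele fraction")],
    )
    if contig_lengths is None:
        contig_lengths = {}
        for rec in records:
            contig_lengths[rec.chrom] = max(
                contig_lengths.get(rec.chrom, 0), rec.pos + 1
            )
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.add_sample(normal_sample)
    header.add_sample(tumor_sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt_base)):
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos,
                alleles=(rec.ref_base, rec.alt_base),
            )
            for flag in rec.db_flags:
                row.info[flag] = True
            row.samples[normal_sample]["DP"] = rec.normal_depth
            row.samples[tumor_sample]["DP"] = rec.tumor_depth
            row.samples[tumor_sample]["AF"] = (rec.vaf,)
            out.write(row)


def write_rejection_report(result: FilterResult, path: str | Path) -> None:
    """TSV report of per-criterion rejection counts for one filter run."""
    lines = ["criterion\trejected"]
    for crit, n in result.tally.items():
        lines.append(f"{crit}\t{n}")
    lines.append(f"retained\t{len(result)}")
    lines.append(f"input\t{result.n_input}")
    Path(path).write_text("\n".join(lines) + "\n")
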