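"""Reporter-gene mutation arithmetic and genome-wide extrapolation.

Covers the quantities derived from selectable reporter assays (HPRT1 /
6-thioguanine and lacZ reversion): mutant frequency, population doubling
level (PDL), error-rate decomposition by mutation class, and the
Drake/Lynch extrapolation from a per-locus rate to a genome-wide
per-base-pair substitution rate

    mu_BS = (mu_L * f_T * f_BS) / (L * f_L * [x * (n_m + n_n) / n_n])

where the bracketed term corrects for the fraction of base substitutions
that are phenotypically detectable via chain-terminating (nonsense)
changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "GrowthRecord",
    "ReporterMutation",
    "MutantCatalog",
    "ExtrapolationParams",
    "LacZReversionAssay",
    "MUTATION_CLASSES",
    "pdl",
    "mutant_frequency",
    "unique_mutations",
    "class_error_rates",
    "lacz_error_rate",
    "mu_bs",
    "predicted_mutations",
    "observed_vs_predicted",
    "rate_per_doubling",
    "fold_change",
    "parse_fraction",
    "read_catalog_tsv",
]

MUTATION_CLASSES = (
    "BPS_missense",
    "BPS_nonsense",
    "BPS_silent",
    "FS_insertion",
    "FS_deletion",
    "splice_exon_loss",
)


@dataclass
class GrowthRecord:
    """One passage: cells seeded, cells harvested, plating efficiency."""

    n_seeded: float
    n_harvested: float
    plating_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.n_seeded <= 0 or self.n_harvested <= 0:
            raise ValueError("cell counts must be positive")
        if not (0 < self.plating_efficiency <= 1):
            raise ValueError("plating efficiency must be in (0, 1]")


@dataclass(frozen=True)
class ReporterMutation:
    """One sequenced mutation in a reporter ORF from a resistant clone."""

    clone_id: str
    pdl: float
    position: int
    ref_base: str
    alt_base: str
    mut_class: str

    def __post_init__(self) -> None:
        if self.mut_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mut_class!r}")
        if self.mut_class.startswith("BPS") and (
            len(self.ref_base) != 1 or len(self.alt_base) != 1
        ):
            raise ValueError("base substitutions need single-base ref/alt")
        if self.mut_class.startswith("FS") and len(self.ref_base) == len(
            self.alt_base
        ):
            raise ValueError("frameshift records need a length change")


@dataclass
class MutantCatalog:
    """Sequenced mutations plus how many clones were sequenced overall."""

    mutations: list[ReporterMutation]
    n_clones_sequenced: int

    def __post_init__(self) -> None:
        distinct = len({m.clone_id for m in self.mutations})
        if self.n_clones_sequenced < distinct:
            raise ValueError(
                "n_clones_sequenced smaller than the number of distinct clones"
            )


@dataclass
class ExtrapolationParams:
    """Inputs to the Drake/Lynch genome-wide extrapolation.

    mu_L : per-locus mutation rate at the reporter.
    f_T : fraction of mutants in which a mutation was found on sequencing.
    f_BS : fraction of reporter mutations that are base substitutions.
    L : reporter ORF length (nt).
    f_L : fraction of the reporter in which mutations are detectable.
    x : fraction of random base substitutions creating chain terminators.
    n_m, n_n : observed missense and nonsense counts.
    """

    mu_L: float
    f_T: float
    f_BS: float
    L: float
    f_L: float
    x: float
    n_m: int
    n_n: int

    def __post_init__(self) -> None:
        for name in ("f_T", "f_BS", "f_L", "x"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.L <= 0:
            raise ValueError("reporter length must be positive")
        if self.mu_L < 0:
            raise ValueError("mu_L must be non-negative")


@dataclass
class LacZReversionAssay:
    """Counts from an in vitro lacZ reversion fidelity assay."""

    n_class_mutants: int
    mutant_frequency: float
    n_sequenced: int
    n_detectable_sites: int
    expression_factor: float = 0.6
    background_frequency: Optional[float] = None


def pdl(growth: GrowthRecord) -> float:
    """Population doublings for one passage: [ln N_t - ln(N_0 * PE)] / ln 2."""
    n0_effective = growth.n_seeded * growth.plating_efficiency
    if n0_effective <= 0 or growth.n_harvested <= 0:
        raise ValueError("cell counts must be positive")
    return (math.log(growth.n_harvested) - math.log(n0_effective)) / math.log(2)


def mutant_frequency(
    n_resistant: int,
    pe_colonies: int,
    pe_seeded: int,
    n_seeded_selective: float,
) -> float:
    """Mutant frequency corrected for plating efficiency.

    frequency = resistant colonies / (PE * cells seeded under selection),
    PE = colonies scored on the non-selective plates / cells seeded there.
    """
    if pe_seeded <= 0 or n_seeded_selective <= 0:
        raise ValueError("seeded cell counts must be positive")
    if pe_colonies > pe_seeded:
        raise ValueError("plating efficiency cannot exceed 1")
    pe = pe_colonies / pe_seeded
    if pe == 0:
        raise ValueError("zero plating efficiency")
    return n_resistant / (pe * n_seeded_selective)


def unique_mutations(catalog: MutantCatalog) -> MutantCatalog:
    """Collapse repeat (position, ref, alt) records within each PDL.

    Repeat isolates of the same mutation at one population doubling level
    reflect clonal expansion of a single event; the same change seen at a
    different PDL is kept as an independent event.
    """
    seen: set[tuple] = set()
    kept: list[ReporterMutation] = []
    for mut in catalog.mutations:
        key = (mut.pdl, mut.position, mut.ref_base, mut.alt_base)
        if key not in seen:
            seen.add(key)
            kept.append(mut)
    return MutantCatalog(mutations=kept, n_clones_sequenced=catalog.n_clones_sequenced)


def class_error_rates(
    total_rate: float, catalog: MutantCatalog
) -> dict[str, float]:
    """Partition a total mutation rate by mutation-class proportions.

    Groups: BPS (all base-substitution classes), FS (insertion/deletion
    frameshifts) and splice_exon_loss reported separately.  Each group's
    rate is total_rate * (group count / total mutations).
    """
    if total_rate < 0:
        raise ValueError("total_rate must be non-negative")
    n_total = len(catalog.mutations)
    if n_total == 0:
        if total_rate > 0:
            raise ValueError("cannot decompose a nonzero rate over an empty catalog")
        return {"BPS": 0.0, "FS": 0.0, "splice_exon_loss": 0.0}
    groups = {"BPS": 0, "FS": 0, "splice_exon_loss": 0}
    for mut in catalog.mutations:
        if mut.mut_class.startswith("BPS"):
            groups["BPS"] += 1
        elif mut.mut_class.startswith("FS"):
            groups["FS"] += 1
        else:
            groups["splice_exon_loss"] += 1
    return {g: total_rate * n / n_total for g, n in groups.items()}


def lacz_error_rate(assay: LacZReversionAssay) -> tuple[float, bool]:
    """Per-nucleotide error rate from a lacZ reversion assay.

    rate = (class mutants * mutant frequency)
           / (mutations sequenced * 0.6 * detectable sites)

    where 0.6 is the expressed fraction of newly synthesized strands.
    Returns ``(rate, is_upper_bound)``; the flag is set when a supplied
    background frequency is at or above the observed frequency, making the
    value a maximal estimate.
    """
    if assay.n_sequenced <= 0 or assay.n_detectable_sites <= 0:
        raise ValueError("sequenced count and detectable sites must be positive")
    rate = (assay.n_class_mutants * assay.mutant_frequency) / (
        assay.n_sequenced * assay.expression_factor * assay.n_detectable_sites
    )
    at_background = (
        assay.background_frequency is not None
        and assay.background_frequency >= assay.mutant_frequency
    )
    return rate, at_background


def mu_bs(params: ExtrapolationParams) -> float:
    """Genome-wide per-bp substitution rate by the Drake/Lynch extrapolation.

    The nonsense-detectability bracket x*(n_m+n_n)/n_n is applied as a
    single multiplicative factor in the denominator.
    """
    if params.n_n == 0:
        raise ValueError("nonsense count n_n must be positive for the correction")
    bracket = params.x * (params.n_m + params.n_n) / params.n_n
    denom = params.L * params.f_L * bracket
    if denom <= 0:
        raise ValueError("extrapolation denominator must be positive")
    return (params.mu_L * params.f_T * params.f_BS) / denom


def predicted_mutations(
    mu_bs: float, genome_bp: float, doublings: float
) -> float:
    """Expected genome-wide mutations: mu_BS * genome size * doublings."""
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    if doublings < 0:
        raise ValueError("doublings must be non-negative")
    return mu_bs * genome_bp * doublings


def observed_vs_predicted(n_observed: float, n_predicted: float) -> float:
    """Fold excess of observed over predicted mutations, to 1 decimal."""
    if n_predicted <= 0:
        raise ValueError("predicted count must be positive")
    return round(n_observed / n_predicted, 1)


def rate_per_doubling(n_observed: float, doublings: float) -> float:
    """Mutations per population doubling, rounded to the nearest integer."""
    if doublings <= 0:
        raise ValueError("doublings must be positive")
    return round(n_observed / doublings)


def fold_change(rate_a: float, rate_b: float) -> float:
    """Ratio of two rates, to 1 decimal."""
    if rate_b <= 0:
        raise ValueError("divisor rate must be positive")
    return round(rate_a / rate_b, 1)


def parse_fraction(text: str | float) -> float:
    """Parse '79/126'-style exact fractions (plain floats pass through)."""
    if isinstance(text, (int, float)):
        return float(text)
    return float(Fraction(text))


def read_catalog_tsv(path: str | Path, n_clones_sequenced: Optional[int] = None) -> MutantCatalog:
    """Read a reporter mutant catalog.

    Columns: clone_id, pdl, position (1-based ORF), ref, alt, class.
    ``n_clones_sequenced`` defaults to the number of distinct clone ids.
    """
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str})
    muts = [
        ReporterMutation(
            clone_id=str(row["clone_id"]),
            pdl=float(row["pdl"]),
            position=int(row["position"]),
            ref_base=str(row["ref"]),
            alt_base=str(row["alt"]),
            mut_class=str(row["class"]),
        )
        for _, row in df.iterrows()
    ]
    if n_clones_sequenced is None:
        n_clones_sequenced = len({m.clone_id for m in muts})
    return MutantCatalog(mutations=muts, n_clones_sequenced=max(n_clones_sequenced, 1))
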