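"""Synthetic inputs for the whole analysis chain.

Generates, with explicit seeding and no hidden state:

* fluctuation-assay colony counts with Luria–Delbrück structure
  (Poisson number of mutational events per culture; each event's clone
  size drawn from the continuous-growth lineage law P(size >= j) = 1/j,
  which reproduces the MSS pmf exactly);
* i.i.d. synthetic genomes at a chosen GC content, with their exact
  pyrimidine-centered trinucleotide census;
* SNV catalogs drawn from a mixture of signature probability vectors and
  placed at genome positions whose trinucleotide context matches the
  drawn bin, with depths and VAFs from simple clonal models — optionally
  as a baseline/late pair whose difference is a known novel set;
* reporter-gene mutant catalogs with chosen class proportions and
  optional duplicate injection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .contexts import (
    BASES,
    COMPLEMENT,
    CONTEXT_LABELS_96,
    PYRIMIDINES,
    TRINUC_LABELS_32,
    revcomp,
    trinuc_of_bin,
    trinucleotide_census,
)
from .fluctuation import FluctuationExperiment
from .reporter import MUTATION_CLASSES, MutantCatalog, ReporterMutation
from .spectrum import SignatureCatalog
from .variants import VariantRecord

__all__ = [
    "SimulationConfig",
    "simulate_fluctuation",
    "simulate_genome",
    "simulate_catalog",
    "simulate_reporter_catalog",
    "write_fasta",
]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic generators.

    Defaults mirror the cell-line study conditions the pipeline analyzes:
    12 parallel cultures grown to 1e7 cells with 5e5 plated under
    selection; a diploid-like 40% GC genome; clonal heterozygous variants
    (VAF ~ Beta(20, 20) around 0.5) sequenced to ~36x (whole-genome-like
    depth).
    """

    seed: int = 0
    # fluctuation assay
    n_cultures: int = 12
    m: Optional[float] = 2.0  # expected mutational events per culture
    mu: Optional[float] = None  # per-cell rate; with final_population derives m
    final_population: float = 1e7
    cells_plated_selective: Optional[float] = None
    censor_cap: Optional[int] = None
    # genome
    genome_length: int = 100_000
    gc_fraction: float = 0.4
    # SNV catalog
    n_mutations: int = 1000
    signature_mix: Optional[dict[str, float]] = None
    depth_mean: float = 36.0
    vaf_beta: tuple[float, float] = (20.0, 20.0)
    # reporter catalog
    n_clones: int = 25
    orf_length: int = 627
    class_proportions: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.signature_mix is not None:
            total = sum(self.signature_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("signature_mix weights must sum to 1")
        if self.class_proportions is not None:
            total = sum(self.class_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("class_proportions must sum to 1")
        if not (0 <= self.gc_fraction <= 1):
            raise ValueError("gc_fraction must be in [0, 1]")

    def effective_m(self) -> float:
        if self.m is not None:
            return self.m
        if self.mu is not None:
            return self.mu * self.final_population
        raise ValueError("either m or mu must be given")


def _rng(config_or_seed) -> np.random.Generator:
    seed = (
        config_or_seed.seed
        if isinstance(config_or_seed, SimulationConfig)
        else config_or_seed
    )
    return np.random.default_rng(seed)


def simulate_fluctuation(config: SimulationConfig) -> FluctuationExperiment:
    """Draw Luria–Delbrück-distributed resistant-colony counts.

    Per culture the number of mutational events is Poisson(m); each event
    founds a clone of size floor(1/U), U ~ Uniform(0,1) — the size law of
    a mutation arising uniformly in time during exponential growth —
    capped at the final population.  With partial plating each mutant cell
    is observed independently with probability ``plating_fraction``.
    """
    rng = _rng(config)
    m = config.effective_m()
    if m < 0:
        raise ValueError("m must be non-negative")
    n_events = rng.poisson(m, size=config.n_cultures)
    counts = np.zeros(config.n_cultures, dtype=np.int64)
    total_events = int(n_events.sum())
    if total_events:
        u = rng.uniform(size=total_events)
        clone_sizes = np.minimum(
            np.floor(1.0 / u).astype(np.int64), int(config.final_population)
        )
        owner = np.repeat(np.arange(config.n_cultures), n_events)
        counts = np.bincount(owner, weights=clone_sizes, minlength=config.n_cultures)
        counts = counts.astype(np.int64)
    plating_fraction = 1.0
    if config.cells_plated_selective is not None:
        plating_fraction = config.cells_plated_selective / config.final_population
    if plating_fraction < 1.0:
        counts = rng.binomial(counts, plating_fraction)
    return FluctuationExperiment(
        culture_counts=counts.tolist(),
        final_population=config.final_population,
        cells_plated_selective=config.cells_plated_selective,
        censor_cap=config.censor_cap,
    )


def simulate_genome(config: SimulationConfig) -> tuple[str, np.ndarray]:
    """I.i.d. random genome at the configured GC fraction.

    Returns ``(sequence, census)`` where ``census`` is the exact 32-bin
    pyrimidine-centered trinucleotide count of the sequence.
    """
    if config.genome_length < 3:
        raise ValueError("genome_length must be at least 3")
    rng = _rng(config)
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=config.genome_length, p=probs)
    seq = "".join(BASES[i] for i in idx)
    return seq, trinucleotide_census(seq)


def _position_index(seq: str) -> dict[str, list[int]]:
    """0-based center positions of each canonical trinucleotide context.

    Positions whose forward trinucleotide is purine-centered are indexed
    under the reverse complement (their canonical bin)."""
    index: dict[str, list[int]] = {lab: [] for lab in TRINUC_LABELS_32}
    for i in range(1, len(seq) - 1):
        tri = seq[i - 1 : i + 2]
        if any(b not in COMPLEMENT for b in tri):
            continue
        canon = tri if tri[1] in PYRIMIDINES else revcomp(tri)
        index[canon].append(i)
    return index


def _bin_to_record(
    bin_index: int, center_pos: int, seq: str, depth: int, n_depth: int, vaf: float,
    chrom: str,
) -> VariantRecord:
    """Materialize a drawn 96-bin at a genome position with matching context."""
    label = CONTEXT_LABELS_96[bin_index]
    ref_pyr, alt_pyr = label[2], label[4]
    center = seq[center_pos]
    if center == ref_pyr:  # forward strand carries the pyrimidine
        ref, alt = ref_pyr, alt_pyr
    else:  # purine-centered site; emit the complementary change
        ref, alt = COMPLEMENT[ref_pyr], COMPLEMENT[alt_pyr]
    return VariantRecord(
        chrom=chrom,
        pos=center_pos + 1,
        ref_base=ref,
        alt_base=alt,
        tumor_depth=depth,
        normal_depth=n_depth,
        vaf=vaf,
        db_flags=frozenset(),
    )


def simulate_catalog(
    config: SimulationConfig,
    genome: str,
    catalog: SignatureCatalog,
    chrom: str = "chrS",
    n_baseline: int = 0,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Draw an SNV catalog from a signature mixture on a synthetic genome.

    Each SNV's 96-bin is drawn from the mixture distribution implied by
    ``config.signature_mix`` over ``catalog``; its position is chosen
    uniformly among genome sites whose trinucleotide context matches the
    bin (distinct positions; a bin with no matching site raises).  Depths
    are Poisson around ``depth_mean`` and VAFs Beta around 0.5.

    Returns ``(novel, baseline)``: ``baseline`` holds ``n_baseline``
    additional independent records, and a late sample is their union, so
    baseline subtraction recovers exactly the novel set.
    """
    if config.signature_mix is None:
        raise ValueError("signature_mix required")
    missing = set(config.signature_mix) - set(catalog.names)
    if missing:
        raise ValueError(f"signatures not in catalog: {sorted(missing)}")
    rng = _rng(config)
    mix = np.zeros(96)
    for name, w in config.signature_mix.items():
        mix += w * catalog.vector(name)
    mix = mix / mix.sum()

    index = _position_index(genome)
    available = {lab: list(pos) for lab, pos in index.items()}

    def draw(n: int) -> list[VariantRecord]:
        bins = rng.choice(96, size=n, p=mix)
        records = []
        for b in bins:
            tri = TRINUC_LABELS_32[trinuc_of_bin(int(b))]
            pool = available[tri]
            if not pool:
                raise RuntimeError(
                    f"no genome position left with context {tri} "
                    f"for bin {CONTEXT_LABELS_96[int(b)]}"
                )
            j = int(rng.integers(len(pool)))
            pos = pool.pop(j)
            depth = max(1, int(rng.poisson(config.depth_mean)))
            n_depth = max(1, int(rng.poisson(config.depth_mean)))
            vaf = float(np.clip(rng.beta(*config.vaf_beta), 0.0, 1.0))
            records.append(
                _bin_to_record(int(b), pos, genome, depth, n_depth, vaf, chrom)
            )
        return records

    novel = draw(config.n_mutations)
    baseline = draw(n_baseline) if n_baseline else []
    return novel, baseline


def simulate_reporter_catalog(config: SimulationConfig, n_duplicates: int = 0) -> MutantCatalog:
    """Reporter mutant catalog with chosen class proportions.

    One mutation per clone at a random ORF position; ``n_duplicates``
    extra clones repeat an existing mutation at the same PDL (to exercise
    unique-mutation collapsing).
    """
    props = config.class_proportions or {
        "BPS_missense": 0.55,
        "BPS_nonsense": 0.05,
        "BPS_silent": 0.03,
        "FS_insertion": 0.12,
        "FS_deletion": 0.21,
        "splice_exon_loss": 0.04,
    }
    unknown = set(props) - set(MUTATION_CLASSES)
    if unknown:
        raise ValueError(f"unknown classes: {sorted(unknown)}")
    rng = _rng(config)
    classes = list(props.keys())
    weights = np.array([props[c] for c in classes])
    weights = weights / weights.sum()
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    muts: list[ReporterMutation] = []
    pdl_levels = [6.6, 47.9, 71.0]
    for i in range(config.n_clones):
        cls = classes[int(rng.choice(len(classes), p=weights))]
        pos = int(rng.integers(1, config.orf_length + 1))
        ref = BASES[int(rng.integers(4))]
        if cls.startswith("BPS"):
            alts = [b for b in BASES if b != ref]
            alt = alts[int(rng.integers(3))]
        elif cls == "FS_insertion":
            alt = ref + BASES[int(rng.integers(4))]
        elif cls == "FS_deletion":
            ref, alt = ref + BASES[int(rng.integers(4))], ref[0]
        else:  # splice_exon_loss: exon-scale deletion descriptor
            ref, alt = ref + "EXON", ref[0]
        pdl_value = float(pdl_levels[int(rng.integers(len(pdl_levels)))])
        muts.append(
            ReporterMutation(
                clone_id=f"clone{i + 1}",
                pdl=pdl_value,
                position=pos,
                ref_base=ref,
                alt_base=alt,
                mut_class=cls,
            )
        )
    for d in range(n_duplicates):
        src = muts[int(rng.integers(len(muts)))]
        muts.append(
            ReporterMutation(
                clone_id=f"dup{d + 1}",
                pdl=src.pdl,
                position=src.position,
                ref_base=src.ref_base,
                alt_base=src.alt_base,
                mut_class=src.mut_class,
            )
        )
    return MutantCatalog(mutations=muts, n_clones_sequenced=len(muts))


def write_fasta(seq: str, path: str | Path, name: str = "chrS", width: int = 70) -> None:
    """Write a single-record FASTA file."""
    lines = [f">{name}"]
    for i in range(0, len(seq), width):
        lines.append(seq[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n")
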