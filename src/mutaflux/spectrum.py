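"""Substitution spectra, context normalization, spectrum comparison and
signature refitting.

SNVs are classified into the 6 pyrimidine-strand substitution classes and
96 trinucleotide-context bins; counts can be normalized by how often each
trinucleotide occurs in the callable territory (opportunity); spectra are
compared with Yates-corrected chi-square tests; and an observed spectrum
is scored against a catalog of signature probability vectors by cosine
similarity and decomposed by non-negative least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .contexts import (
    CONTEXT_INDEX_96,
    CONTEXT_LABELS_96,
    SUBSTITUTION_CLASSES,
    TRINUC_INDEX_32,
    TRINUC_LABELS_32,
    AmbiguousBaseError,
    canonical_substitution,
    trinuc_of_bin,
    trinucleotide_census,
)
from .variants import VariantRecord

__all__ = [
    "SpectrumProfile",
    "SignatureCatalog",
    "RefitResult",
    "classify_substitution",
    "build_spectrum",
    "normalize_by_opportunity",
    "chisq_yates",
    "cosine_similarity",
    "refit_signatures",
    "bundled_signature_catalog",
]


class ReferenceMismatchError(ValueError):
    """A record's ref allele disagrees with the reference sequence."""


@dataclass
class SpectrumProfile:
    """Counts of classified SNVs in 96 context bins for one sample.

    ``counts96`` follows :data:`~mutaflux.contexts.CONTEXT_LABELS_96`
    order; ``opportunity`` (optional) is the 32-bin pyrimidine-centered
    trinucleotide census of the territory the calls came from.
    ``n_skipped`` counts records dropped for ambiguous bases or missing
    flanks.
    """

    sample: str
    counts96: np.ndarray
    opportunity: Optional[np.ndarray] = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts96 = np.asarray(self.counts96, dtype=float)
        if self.counts96.shape != (96,):
            raise ValueError("counts96 must have length 96")
        if (self.counts96 < 0).any():
            raise ValueError("counts must be non-negative")
        if self.opportunity is not None:
            self.opportunity = np.asarray(self.opportunity, dtype=float)
            if self.opportunity.shape != (32,):
                raise ValueError("opportunity census must have length 32")

    @property
    def counts6(self) -> np.ndarray:
        """Marginal counts of the 6 substitution classes."""
        return self.counts96.reshape(6, 16).sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.counts96.sum())

    def proportions(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros(96)
        return self.counts96 / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "context": CONTEXT_LABELS_96,
                "class": [CONTEXT_LABELS_96[i][2:5] for i in range(96)],
                "count": self.counts96,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sample: str = "") -> "SpectrumProfile":
        df = pd.read_csv(path, sep="\t")
        counts = np.zeros(96)
        for _, row in df.iterrows():
            counts[CONTEXT_INDEX_96[row["context"]]] = row["count"]
        return cls(sample=sample or str(path), counts96=counts)


@dataclass
class SignatureCatalog:
    """Named 96-bin probability vectors (COSMIC-style signature catalog)."""

    names: list[str]
    vectors: np.ndarray  # shape (n_signatures, 96), rows sum to 1

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 96:
            raise ValueError("vectors must have shape (n, 96)")
        if len(self.names) != self.vectors.shape[0]:
            raise ValueError("one name per vector required")
        if (self.vectors < 0).any():
            raise ValueError("signature entries must be non-negative")
        sums = self.vectors.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each signature must sum to 1 within 1e-6")

    def __len__(self) -> int:
        return len(self.names)

    def vector(self, name: str) -> np.ndarray:
        return self.vectors[self.names.index(name)]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureCatalog":
        """Read a tab-delimited catalog: first column the 96 context labels
        in "A[C>A]A" style, one column per signature."""
        df = pd.read_csv(path, sep="\t")
        label_col = df.columns[0]
        order = [CONTEXT_INDEX_96[lab] for lab in df[label_col]]
        if sorted(order) != list(range(96)):
            raise ValueError("catalog must contain all 96 context labels exactly once")
        names = list(df.columns[1:])
        mat = np.zeros((len(names), 96))
        for j, name in enumerate(names):
            mat[j, order] = df[name].to_numpy(dtype=float)
        return cls(names=names, vectors=mat)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"context": CONTEXT_LABELS_96})
        for name, vec in zip(self.names, self.vectors):
            df[name] = vec
        df.to_csv(path, sep="\t", index=False)


def classify_substitution(
    ref_base: str, alt_base: str, context5: str, context3: str
) -> tuple[str, str]:
    """Pyrimidine-strand (class, 96-context) of one substitution.

    Thin wrapper over :func:`mutaflux.contexts.canonical_substitution`.
    """
    return canonical_substitution(ref_base, alt_base, context5, context3)


def build_spectrum(
    records: Sequence[VariantRecord],
    reference: Mapping[str, str],
    sample: str = "sample",
    opportunity_from: Optional[Mapping[str, str] | str] = None,
) -> SpectrumProfile:
    """Classify SNVs against a reference into a 96-bin spectrum.

    ``reference`` maps chromosome name to sequence (a dict of strings or a
    ``pyfaidx.Fasta`` both work).  A record whose ref allele disagrees with
    the reference raises :class:`ReferenceMismatchError`; records at
    sequence ends (no flank) or with ambiguous context bases are skipped
    and tallied.  When ``opportunity_from`` is given (sequences, or the
    string "reference"), the 32-bin trinucleotide census of that territory
    is attached.
    """
    counts = np.zeros(96)
    skipped = 0
    seq_cache: dict[str, str] = {}

    def chrom_seq(chrom: str) -> str:
        if chrom not in seq_cache:
            seq_cache[chrom] = str(reference[chrom]).upper()
        return seq_cache[chrom]

    for rec in records:
        seq = chrom_seq(rec.chrom)
        idx = rec.pos - 1
        if not (0 <= idx < len(seq)):
            raise ReferenceMismatchError(
                f"{rec.chrom}:{rec.pos} outside reference ({len(seq)} bp)"
            )
        if seq[idx] != rec.ref_base:
            raise ReferenceMismatchError(
                f"{rec.chrom}:{rec.pos} ref {rec.ref_base} != reference {seq[idx]}"
            )
        if idx == 0 or idx == len(seq) - 1:
            skipped += 1
            continue
        try:
            _, label = canonical_substitution(
                rec.ref_base, rec.alt_base, seq[idx - 1], seq[idx + 1]
            )
        except AmbiguousBaseError:
            skipped += 1
            continue
        counts[CONTEXT_INDEX_96[label]] += 1

    opportunity = None
    if opportunity_from is not None:
        territory = reference if opportunity_from == "reference" else opportunity_from
        opportunity = np.zeros(32, dtype=float)
        for chrom in territory.keys():
            opportunity += trinucleotide_census(str(territory[chrom]).upper())
    return SpectrumProfile(
        sample=sample, counts96=counts, opportunity=opportunity, n_skipped=skipped
    )


def normalize_by_opportunity(profile: SpectrumProfile) -> SpectrumProfile:
    """Convert counts to opportunity-relative rates, preserving the total.

    Each bin's count is divided by the census of its trinucleotide, then
    the whole vector is rescaled so its sum equals the original total
    count, keeping raw and normalized spectra on one axis.
    """
    if profile.opportunity is None:
        raise ValueError("profile has no opportunity census")
    opp_per_bin = profile.opportunity[[trinuc_of_bin(i) for i in range(96)]]
    nonzero = profile.counts96 > 0
    if (opp_per_bin[nonzero] <= 0).any():
        bad = np.where(nonzero & (opp_per_bin <= 0))[0][0]
        raise ValueError(
            f"zero opportunity for context with nonzero count: {CONTEXT_LABELS_96[bad]}"
        )
    rates = np.divide(
        profile.counts96,
        opp_per_bin,
        out=np.zeros(96),
        where=opp_per_bin > 0,
    )
    total = profile.total
    if rates.sum() > 0 and total > 0:
        rates = rates * (total / rates.sum())
    return SpectrumProfile(
        sample=profile.sample,
        counts96=rates,
        opportunity=profile.opportunity,
        n_skipped=profile.n_skipped,
    )


def chisq_yates(
    observed_a: Sequence[float], observed_b: Sequence[float]
) -> tuple[float, int, float]:
    """Yates-corrected chi-square comparison of two count vectors.

    The two vectors form a 2xN contingency table (samples x categories).
    For 2x2 tables this is the classical Yates continuity correction; for
    wider tables the correction is applied per cell as max(|O-E|-0.5, 0)
    (a documented generalization).  Categories with zero total are dropped
    and the degrees of freedom adjusted.

    Returns ``(statistic, df, p)``.
    """
    a = np.asarray(observed_a, dtype=float)
    b = np.asarray(observed_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length count vectors of length >= 2")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size < 2 or a.sum() == 0 or b.sum() == 0:
        raise ValueError("a margin of the table is all zero")
    table = np.vstack([a, b])
    if table.shape == (2, 2):
        stat, p, df, _ = stats.chi2_contingency(table, correction=True)
        return float(stat), int(df), float(p)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    adj = np.maximum(np.abs(table - expected) - 0.5, 0.0)
    stat = float((adj**2 / expected).sum())
    df = int((table.shape[0] - 1) * (table.shape[1] - 1))
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def cosine_similarity(v: Sequence[float], w: Sequence[float]) -> float:
    """Cosine of the angle between two non-negative spectra (in [0, 1])."""
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0 or nw == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(v, w) / (nv * nw))


@dataclass
class RefitResult:
    """Non-negative decomposition of a spectrum over a signature catalog.

    ``weights`` minimize || p - V^T w ||_2 with w >= 0, where p is the
    spectrum as proportions; ``contributions`` are weights normalized to
    sum to 1; ``cosine_table`` scores each catalog signature against the
    raw spectrum.
    """

    names: list[str]
    weights: np.ndarray
    residual_norm: float
    cosine_table: dict[str, float]

    @property
    def contributions(self) -> dict[str, float]:
        total = self.weights.sum()
        if total == 0:
            return {name: 0.0 for name in self.names}
        return {n: float(w / total) for n, w in zip(self.names, self.weights)}

    def top_cosine(self) -> tuple[str, float]:
        name = max(self.cosine_table, key=self.cosine_table.get)
        return name, self.cosine_table[name]

    def summary(self) -> str:
        lines = [
            "Signature refit (non-negative least squares)",
            "=" * 46,
            f"residual norm: {self.residual_norm:.4g}",
            f"{'signature':<24}{'weight':>10}{'contrib':>10}{'cosine':>10}",
        ]
        contribs = self.contributions
        for name, w in zip(self.names, self.weights):
            lines.append(
                f"{name:<24}{w:>10.4f}{contribs[name]:>10.4f}"
                f"{self.cosine_table[name]:>10.4f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        contribs = self.contributions
        return pd.DataFrame(
            {
                "signature": self.names,
                "weight": self.weights,
                "contribution": [contribs[n] for n in self.names],
                "cosine": [self.cosine_table[n] for n in self.names],
            }
        )


def refit_signatures(
    profile: SpectrumProfile, catalog: SignatureCatalog
) -> RefitResult:
    """Decompose a spectrum as a non-negative mixture of catalog signatures.

    Weights solve the non-negative least-squares problem against the
    spectrum's proportion vector (active-set NNLS, exact KKT at
    convergence).  Also reports per-signature cosine similarity.
    """
    if len(catalog) == 0:
        raise ValueError("empty signature catalog")
    if profile.total <= 0:
        raise ValueError("cannot refit an empty spectrum")
    p = profile.proportions()
    A = catalog.vectors.T  # 96 x n
    weights, residual = nnls(A, p)
    cosines = {}
    for name, vec in zip(catalog.names, catalog.vectors):
        cosines[name] = (
            cosine_similarity(p, vec) if np.linalg.norm(vec) > 0 else 0.0
        )
    return RefitResult(
        names=list(catalog.names),
        weights=weights,
        residual_norm=float(residual),
        cosine_table=cosines,
    )


def bundled_signature_catalog() -> SignatureCatalog:
    """The small synthetic 4-signature catalog shipped with the package."""
    path = Path(__file__).parent / "data" / "synthetic_signatures.tsv"
    return SignatureCatalog.from_tsv(path)
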