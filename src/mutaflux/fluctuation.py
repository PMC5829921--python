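"""Luria–Delbrück fluctuation analysis.

Mutation rates are estimated from the distribution of resistant-colony
counts across parallel cultures.  The number of mutational events per
culture is Poisson with mean ``m``; each event founds a clone whose final
size, for a mutation arising uniformly in time during exponential growth,
has the heavy-tailed distribution P(size >= j) = 1/j.  The resulting count
distribution satisfies the classic recursion

    p_0 = exp(-m)
    p_k = (m / k) * sum_{i=0}^{k-1} p_i / (k - i + 1)

and the Ma–Sandri–Sarkar maximum-likelihood estimator (MSS-MLE) maximizes
the product of these probabilities over cultures.  Confidence intervals
come from the profile likelihood (chi-square(1) cutoff).

Modeled after the statsmodels pattern: build a
:class:`LuriaDelbrueckModel` from a :class:`FluctuationExperiment`, call
``fit()``, and read estimates off the returned :class:`FluctuationResults`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "FluctuationExperiment",
    "LDModel",
    "MutationRateEstimate",
    "LuriaDelbrueckModel",
    "FluctuationResults",
    "ld_pmf",
    "mss_mle",
    "rate_from_m",
    "read_counts_tsv",
]

#: log-likelihood drop defining the 95% profile-likelihood interval
#: (half the chi-square(1) 95% quantile, 3.841/2).
_PROFILE_DROP = 1.92


@dataclass
class FluctuationExperiment:
    """Colony counts from one set of parallel cultures plus plating metadata.

    Parameters
    ----------
    culture_counts
        Resistant colonies per parallel culture.  Counts at or above
        ``censor_cap`` are right-censored jackpots recorded at the cap.
    final_population
        Cells per culture at the time of plating (N_t, assumed equal
        across cultures).
    cells_plated_selective
        Cells actually plated under selection per culture; with
        ``final_population`` it determines ``plating_fraction``.
    plating_fraction
        Fraction of each culture examined under selection (epsilon in
        (0, 1]).  Derived from the two counts above when both are given.
    censor_cap
        Optional countable-plate ceiling; ``None`` means no censoring.
    """

    culture_counts: Sequence[int]
    final_population: float
    cells_plated_selective: Optional[float] = None
    plating_fraction: Optional[float] = None
    censor_cap: Optional[int] = None

    def __post_init__(self) -> None:
        self.culture_counts = [int(c) for c in self.culture_counts]
        if any(c < 0 for c in self.culture_counts):
            raise ValueError("colony counts must be non-negative")
        if self.final_population <= 0:
            raise ValueError("final_population must be positive")
        if self.plating_fraction is None:
            if self.cells_plated_selective is not None:
                self.plating_fraction = (
                    self.cells_plated_selective / self.final_population
                )
            else:
                self.plating_fraction = 1.0
        if not (0 < self.plating_fraction <= 1):
            raise ValueError("plating_fraction must be in (0, 1]")
        if self.censor_cap is not None:
            if self.censor_cap <= 0:
                raise ValueError("censor_cap must be positive")
            self.culture_counts = [
                min(c, self.censor_cap) for c in self.culture_counts
            ]

    @property
    def n_cultures(self) -> int:
        return len(self.culture_counts)

    def censored_mask(self) -> np.ndarray:
        """Boolean mask of counts recorded at the censoring cap."""
        counts = np.asarray(self.culture_counts)
        if self.censor_cap is None:
            return np.zeros(counts.shape, dtype=bool)
        return counts >= self.censor_cap


@dataclass
class LDModel:
    """A truncated Luria–Delbrück pmf: p_0..p_{k_max} plus the tail mass."""

    m: float
    k_max: int
    pmf: np.ndarray
    tail_mass: float


@dataclass
class MutationRateEstimate:
    """MSS-MLE output: events/culture, per-cell rate and 95% CI."""

    m_hat: float
    rate: float
    ci95: tuple[float, float]
    method: str
    log_likelihood: float
    n_cultures: int

    def to_dict(self) -> dict:
        return {
            "m_hat": self.m_hat,
            "rate": self.rate,
            "ci95": list(self.ci95),
            "method": self.method,
            "n_cultures": self.n_cultures,
            "log_likelihood": self.log_likelihood,
        }


def ld_pmf(m: float, k_max: int) -> LDModel:
    """Luria–Delbrück pmf up to ``k_max`` by the MSS recursion.

    Returns an :class:`LDModel` with ``pmf[k] = P(count = k)`` for
    k = 0..k_max and ``tail_mass = P(count > k_max)``.
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    p = np.zeros(k_max + 1)
    p[0] = math.exp(-m)
    if m > 0 and k_max > 0:
        # inv[j] = 1/j ; coefficient for term i at step k is 1/(k-i+1)
        inv = 1.0 / np.arange(1, k_max + 2)
        for k in range(1, k_max + 1):
            p[k] = (m / k) * np.dot(p[:k], inv[k:0:-1])
    tail = max(0.0, 1.0 - p.sum())
    return LDModel(m=m, k_max=k_max, pmf=p, tail_mass=tail)


def rate_from_m(m: float, final_population: float) -> float:
    """Convert events/culture to a per-cell, per-division rate: m / N_t."""
    if final_population <= 0:
        raise ValueError("final_population must be positive")
    if m < 0:
        raise ValueError("m must be non-negative")
    return m / final_population


class LuriaDelbrueckModel:
    """MSS maximum-likelihood model for one fluctuation experiment.

    ``fit()`` maximizes the MSS likelihood over ln(m) and converts the
    events-per-culture estimate to a per-cell rate using
    rate = m / (plating_fraction * N_t): with partial plating the counts
    inform m_obs ~= m * epsilon, so the observed-scale estimate is divided
    back by epsilon before the population-size conversion.  This first-order
    correction slightly overestimates the variance relative to the exact
    partial-plating likelihood.
    """

    def __init__(self, experiment: FluctuationExperiment):
        if experiment.n_cultures < 2:
            raise ValueError("need at least 2 parallel cultures")
        self.experiment = experiment
        counts = np.asarray(experiment.culture_counts)
        censored = experiment.censored_mask()
        if censored.all() and counts.size:
            raise ValueError("all cultures censored; m is unidentifiable")
        self._counts = counts
        self._censored = censored
        self._k_max = int(counts.max(initial=0))

    def loglike(self, m: float) -> float:
        """MSS log-likelihood of m given the observed (possibly censored) counts."""
        if m < 0:
            raise ValueError("m must be non-negative")
        model = ld_pmf(m, self._k_max)
        p = np.clip(model.pmf, 1e-300, None)
        ll = float(np.sum(np.log(p[self._counts[~self._censored]])))
        if self._censored.any():
            cap = self.experiment.censor_cap
            tail_at_cap = max(1.0 - float(model.pmf[:cap].sum()), 1e-300)
            ll += float(self._censored.sum()) * math.log(tail_at_cap)
        return ll

    def fit(self) -> "FluctuationResults":
        expt = self.experiment
        n = expt.n_cultures
        if self._counts.max(initial=0) == 0:
            # boundary MLE: one-sided upper CI where loglike(m) = -n*m drops by 1.92
            m_up = _PROFILE_DROP / n
            return FluctuationResults(
                model=self,
                m_hat=0.0,
                m_ci=(0.0, m_up),
                log_likelihood=0.0,
                method="mle",
            )
        lo, hi = math.log(1e-6), math.log(max(self._counts.max(), 2.0))
        res = minimize_scalar(
            lambda t: -self.loglike(math.exp(t)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        m_hat = math.exp(res.x)
        ll_max = -res.fun
        m_ci = self._profile_ci(m_hat, ll_max)
        return FluctuationResults(
            model=self, m_hat=m_hat, m_ci=m_ci, log_likelihood=ll_max,
            method="mle",
        )

    def _profile_ci(self, m_hat: float, ll_max: float) -> tuple[float, float]:
        target = ll_max - _PROFILE_DROP

        def g(m: float) -> float:
            return self.loglike(m) - target

        # lower bound
        m_lo_bracket = m_hat
        lo = 0.0
        while m_lo_bracket > 1e-12:
            m_lo_bracket /= 4.0
            if g(m_lo_bracket) < 0:
                lo = brentq(g, m_lo_bracket, m_hat, xtol=1e-12)
                break
        # upper bound
        m_hi_bracket = m_hat
        for _ in range(200):
            m_hi_bracket *= 2.0
            if g(m_hi_bracket) < 0:
                hi = brentq(g, m_hat, m_hi_bracket, xtol=1e-12)
                break
        else:  # pragma: no cover - pathological flat likelihood
            hi = math.inf
        return (lo, hi)


@dataclass
class FluctuationResults:
    """Fitted MSS-MLE results with profile-likelihood 95% CI.

    ``m_hat`` and ``m_ci`` are on the observed (plated) scale; ``rate`` and
    ``rate_ci95`` are per cell per division, corrected for partial plating.
    """

    model: LuriaDelbrueckModel
    m_hat: float
    m_ci: tuple[float, float]
    log_likelihood: float
    method: str = "mle"

    @property
    def experiment(self) -> FluctuationExperiment:
        return self.model.experiment

    @property
    def m_true(self) -> float:
        """Events per culture corrected for partial plating."""
        return self.m_hat / self.experiment.plating_fraction

    @property
    def rate(self) -> float:
        return rate_from_m(self.m_true, self.experiment.final_population)

    @property
    def rate_ci95(self) -> tuple[float, float]:
        eps = self.experiment.plating_fraction
        nt = self.experiment.final_population
        return (self.m_ci[0] / eps / nt, self.m_ci[1] / eps / nt)

    def estimate(self) -> MutationRateEstimate:
        return MutationRateEstimate(
            m_hat=self.m_hat,
            rate=self.rate,
            ci95=self.rate_ci95,
            method=self.method,
            log_likelihood=self.log_likelihood,
            n_cultures=self.experiment.n_cultures,
        )

    def summary(self) -> str:
        e = self.experiment
        lines = [
            "Luria-Delbrueck MSS-MLE fluctuation analysis",
            "=" * 46,
            f"cultures:            {e.n_cultures}",
            f"final population:    {e.final_population:.3g}",
            f"plating fraction:    {e.plating_fraction:.3g}",
            f"m_hat (per culture): {self.m_hat:.4g}",
            f"m 95% CI:            [{self.m_ci[0]:.4g}, {self.m_ci[1]:.4g}]",
            f"rate (per cell/div): {self.rate:.4g}",
            "rate 95% CI:         "
            f"[{self.rate_ci95[0]:.4g}, {self.rate_ci95[1]:.4g}]",
            f"log-likelihood:      {self.log_likelihood:.4f}",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.estimate().to_dict(), indent=2))


def mss_mle(expt: FluctuationExperiment) -> MutationRateEstimate:
    """Ma–Sandri–Sarkar MLE of the mutation rate for one experiment."""
    return LuriaDelbrueckModel(expt).fit().estimate()


def read_counts_tsv(
    path: str | Path,
    final_population: float,
    cells_plated_selective: Optional[float] = None,
    censor_cap: Optional[int] = None,
) -> FluctuationExperiment:
    """Read a per-culture colony-count table.

    Expected columns: ``culture_id``, ``colony_count`` and optionally
    ``censored`` (0/1).  Rows flagged censored are recorded at
    ``censor_cap`` (which must then be given).
    """
    df = pd.read_csv(path, sep="\t")
    counts = df["colony_count"].astype(int).tolist()
    if "censored" in df.columns and df["censored"].astype(int).any():
        if censor_cap is None:
            raise ValueError("censored rows present but no censor_cap given")
        counts = [
            max(c, censor_cap) if flag else c
            for c, flag in zip(counts, df["censored"].astype(int))
        ]
    return FluctuationExperiment(
        culture_counts=counts,
        final_population=final_population,
        cells_plated_selective=cells_plated_selective,
        censor_cap=censor_cap,
    )
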