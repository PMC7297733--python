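"""Enrichment simulation test, mutation-rate calibration and event dating.

The enrichment test asks whether one haplotype was captured by the tumour
lineage more often than expected if every host haplotype had an equal
horizontal-transfer opportunity proportional to its population frequency.
Each replicate draws the observed number of events i.i.d. from the
haplotype frequency distribution; the empirical p value is the proportion
of replicates in which the target haplotype was drawn at least as often as
observed.  The exact binomial upper tail of the target's marginal is
computed alongside as an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np


@dataclass(frozen=True)
class RateEstimate:
    """Somatic mutation rate (mutations/year) with a calibration interval."""

    point: float
    low: float
    high: float
    mean_mutations: float | None = None
    divergence_years: float | None = None
    divergence_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.low <= self.point <= self.high):
            raise ValueError("require 0 < low <= point <= high")


@dataclass(frozen=True)
class EnrichmentResult:
    n_events: int
    observed_count: int
    target_haplotype: str
    replicates: int
    seed: int
    empirical_p: float
    empirical_p_add_one: float  # (k+1)/(n+1) estimator, never exactly 0
    exact_tail_p: float
    restricted_to_pairs: bool = False


def enrichment_test(haplotype_freqs: Mapping[str, float], n_events: int,
                    observed_count: int, target_haplotype: str,
                    replicates: int = 10000, seed: int = 76,
                    restricted_to_pairs: bool = False) -> EnrichmentResult:
    """Monte-Carlo enrichment test for repeated capture of one haplotype."""
    if target_haplotype not in haplotype_freqs:
        raise ValueError(f"target {target_haplotype!r} absent from frequencies")
    total = float(sum(haplotype_freqs.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"haplotype frequencies sum to {total}, expected 1")
    if not 0 <= observed_count <= n_events:
        raise ValueError("require 0 <= observed_count <= n_events")
    if replicates <= 0:
        raise ValueError("replicates must be positive")

    names = list(haplotype_freqs)
    probs = np.array([haplotype_freqs[n] for n in names], dtype=float)
    target_idx = names.index(target_haplotype)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_events, probs, size=replicates)
    target_counts = draws[:, target_idx]
    hits = int((target_counts >= observed_count).sum())
    return EnrichmentResult(
        n_events=n_events,
        observed_count=observed_count,
        target_haplotype=target_haplotype,
        replicates=replicates,
        seed=seed,
        empirical_p=hits / replicates,
        empirical_p_add_one=(hits + 1) / (replicates + 1),
        exact_tail_p=exact_tail_probability(haplotype_freqs[target_haplotype],
                                            n_events, observed_count),
        restricted_to_pairs=restricted_to_pairs,
    )


def exact_tail_probability(freq: float, n: int, k: int) -> float:
    """Exact binomial upper tail P(X >= k), X ~ Binomial(n, freq).

    Computed by direct summation of binomial probabilities with exact
    integer coefficients.
    """
    if not 0 <= freq <= 1:
        raise ValueError("freq must be in [0, 1]")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if k == 0:
        return 1.0
    return float(sum(math.comb(n, i) * freq ** i * (1 - freq) ** (n - i)
                     for i in range(k, n + 1)))


def calibrate_rate(mean_mutations: float, divergence_years: float,
                   divergence_interval: tuple[float, float]) -> RateEstimate:
    """Mutation rate from a mean somatic burden and a divergence-time anchor.

    ``point = mean_mutations / divergence_years``; the rate interval inverts
    the divergence-time interval (older divergence -> slower rate).
    """
    lo_years, hi_years = divergence_interval
    if min(mean_mutations, divergence_years, lo_years, hi_years) <= 0:
        raise ValueError("all calibration inputs must be positive")
    if lo_years > hi_years:
        raise ValueError("divergence interval must be (low, high)")
    return RateEstimate(
        point=mean_mutations / divergence_years,
        low=mean_mutations / hi_years,
        high=mean_mutations / lo_years,
        mean_mutations=mean_mutations,
        divergence_years=divergence_years,
        divergence_interval=(lo_years, hi_years),
    )


def date_ht_event(somatic_count: float, rate: RateEstimate
                  ) -> tuple[float, tuple[float, float]]:
    """Years since transfer from a somatic mutation count and a rate.

    The count should include only confident (polymorphic) somatic variants,
    excluding variants whose germline or somatic status is unknown.
    """
    if somatic_count < 0:
        raise ValueError("somatic_count must be >= 0")
    point = somatic_count / rate.point
    return point, (somatic_count / rate.high, somatic_count / rate.low)
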