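"""mtDNA copy-number estimation from coverage and VAF-derived tumour purity.

Copy number per cell is ``(mtCOV-T / nuclCOV-T) x P`` where ``mtCOV-T`` is
mean mitochondrial coverage scaled by the mitochondrial tumour fraction,
``nuclCOV-T`` is mean nuclear coverage scaled by the nuclear tumour
fraction, and ``P`` is ploidy (2 for tumours and dogs alike).  Nuclear
tumour fraction is estimated as twice the mode of the somatic variant
allele fraction (diploid heterozygous somatic variants sit at VAF =
purity/2); the mitochondrial tumour fraction is the median VAF of
tumour-specific homoplasmic mtDNA variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CoverageSummary:
    sample_id: str
    mt_coverage: float
    nuclear_coverage: float
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.mt_coverage <= 0 or self.nuclear_coverage <= 0:
            raise ValueError("coverages must be > 0")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")


#: Histogram used for the VAF mode: bins of width 0.02 over (0.05, 0.95].
VAF_BIN_EDGES = np.round(np.arange(0.05, 0.95 + 1e-9, 0.02), 10)


def estimate_nuclear_tumour_fraction(somatic_vafs: Sequence[float],
                                     min_observations: int = 20) -> float:
    """Twice the histogram mode of nuclear somatic VAFs, capped at 1.

    The mode is the midpoint of the maximal-count bin (width 0.02 over
    (0.05, 0.95]); ties resolve to the lower bin.
    """
    vafs = np.asarray(somatic_vafs, dtype=float)
    vafs = vafs[(vafs > 0) & (vafs < 1)]
    if len(vafs) < min_observations:
        raise ValueError(
            f"need >= {min_observations} somatic VAFs in (0, 1), got {len(vafs)}")
    counts, _ = np.histogram(vafs, bins=VAF_BIN_EDGES)
    mode_bin = int(np.argmax(counts))  # argmax takes the lower bin on ties
    mode = (VAF_BIN_EDGES[mode_bin] + VAF_BIN_EDGES[mode_bin + 1]) / 2
    return min(2.0 * mode, 1.0)


def estimate_mt_tumour_fraction(mt_somatic_vafs: Sequence[float]) -> float:
    """Median VAF of tumour-specific homoplasmic mtDNA variants."""
    vafs = np.asarray(mt_somatic_vafs, dtype=float)
    if len(vafs) == 0:
        raise ValueError("no tumour-specific mtDNA variants supplied")
    return float(np.median(vafs))


def mtdna_copy_number(coverage: CoverageSummary, mt_fraction: float,
                      nuclear_fraction: float) -> float:
    """Copies of mtDNA per cell via (mtCOV-T / nuclCOV-T) x P."""
    if not 0 < mt_fraction <= 1 or not 0 < nuclear_fraction <= 1:
        raise ValueError("tumour fractions must be in (0, 1]")
    mt_cov_t = coverage.mt_coverage * mt_fraction
    nucl_cov_t = coverage.nuclear_coverage * nuclear_fraction
    if nucl_cov_t == 0:
        raise ZeroDivisionError("nuclear tumour coverage is zero")
    return (mt_cov_t / nucl_cov_t) * coverage.ploidy


def compare_groups_ttest(values_a: Sequence[float],
                         values_b: Sequence[float]) -> tuple[float, float]:
    """Unpaired two-tailed Student's t test (pooled variance)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance groups")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
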