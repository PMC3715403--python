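"""Per-site summary statistics stored alongside each variant.

All statistics are computed per biallelic record (multi-allelic sites are
split upstream) from the genotype-type codes of the cohort: genotype-type
counts, call rate, alternate allele frequency, a 1-d.f. Pearson chi-square
test for Hardy-Weinberg equilibrium, the per-site inbreeding coefficient
F = 1 - H_obs / H_exp, and the unbiased per-site nucleotide diversity
pi = 2 j (m - j) / (m (m - 1)) where j counts alternate alleles among the
m called alleles. Statistics that are undefined (no called genotypes, or a
monomorphic site for F) are returned as ``None`` and stored as SQL NULLs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .gtstore import HET, HOM_ALT, HOM_REF, UNKNOWN

__all__ = [
    "SiteStats",
    "genotype_counts",
    "hwe_test",
    "inbreeding_coefficient",
    "nucleotide_diversity",
    "site_stats",
]


@dataclass
class SiteStats:
    num_hom_ref: int
    num_het: int
    num_hom_alt: int
    num_unknown: int
    call_rate: Optional[float]
    aaf: Optional[float]
    hwe_chi2: Optional[float]
    hwe_p: Optional[float]
    inbreeding_F: Optional[float]
    pi: Optional[float]


def genotype_counts(gt_types: Sequence[int]) -> tuple[int, int, int, int]:
    """Tally (hom_ref, het, hom_alt, unknown); an exhaustive partition."""
    arr = np.asarray(gt_types, dtype=np.int64)
    if arr.size and (arr.min() < 0 or arr.max() > 3):
        raise ValueError("gt_types codes must be in {0,1,2,3}")
    return (
        int(np.count_nonzero(arr == HOM_REF)),
        int(np.count_nonzero(arr == HET)),
        int(np.count_nonzero(arr == HOM_ALT)),
        int(np.count_nonzero(arr == UNKNOWN)),
    )


def hwe_test(
    num_hom_ref: int, num_het: int, num_hom_alt: int
) -> tuple[Optional[float], Optional[float]]:
    """Pearson chi-square goodness of fit to Hardy-Weinberg proportions.

    Expected counts are n*(p^2, 2pq, q^2) with the reference-allele
    frequency p estimated from the allele counts; 1 degree of freedom
    (3 classes - 1 - 1 estimated parameter), no continuity correction.
    A monomorphic site fits its expectation exactly: chi2=0, p=1.
    Returns (None, None) when no genotypes are called.
    """
    n = num_hom_ref + num_het + num_hom_alt
    if n == 0:
        return None, None
    p = (2 * num_hom_ref + num_het) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([num_hom_ref, num_het, num_hom_alt], dtype=float)
    mask = expected > 0
    chi2 = float(((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum())
    pval = float(min(1.0, max(0.0, sps.chi2.sf(chi2, df=1))))
    return chi2, pval


def inbreeding_coefficient(
    num_hom_ref: int, num_het: int, num_hom_alt: int
) -> Optional[float]:
    """F = 1 - observed het fraction / expected het fraction (2pq).

    Undefined (None) at monomorphic sites where 2pq = 0.
    """
    n = num_hom_ref + num_het + num_hom_alt
    if n == 0:
        return None
    p = (2 * num_hom_ref + num_het) / (2 * n)
    he = 2 * p * (1 - p)
    if he == 0:
        return None
    return 1.0 - (num_het / n) / he


def nucleotide_diversity(
    num_hom_ref: int, num_het: int, num_hom_alt: int
) -> Optional[float]:
    """Probability two alleles drawn without replacement differ.

    pi = 2 j (m - j) / (m (m - 1)) with j alternate alleles among m
    called alleles; the m/(m-1) factor makes it the unbiased per-site
    heterozygosity. Undefined for m < 2.
    """
    n = num_hom_ref + num_het + num_hom_alt
    m = 2 * n
    if m < 2:
        return None
    j = num_het + 2 * num_hom_alt
    return 2.0 * j * (m - j) / (m * (m - 1))


def site_stats(gt_types: Sequence[int]) -> SiteStats:
    """All per-site statistics for one variant's genotype-type array."""
    hom_ref, het, hom_alt, unknown = genotype_counts(gt_types)
    total = hom_ref + het + hom_alt + unknown
    called = total - unknown
    call_rate = called / total if total else None
    aaf = (het + 2 * hom_alt) / (2 * called) if called else None
    chi2, pval = hwe_test(hom_ref, het, hom_alt)
    return SiteStats(
        num_hom_ref=hom_ref,
        num_het=het,
        num_hom_alt=hom_alt,
        num_unknown=unknown,
        call_rate=call_rate,
        aaf=aaf,
        hwe_chi2=chi2,
        hwe_p=pval,
        inbreeding_F=inbreeding_coefficient(hom_ref, het, hom_alt),
        pi=nucleotide_diversity(hom_ref, het, hom_alt),
    )
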