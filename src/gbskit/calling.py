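"""Depth-dependent genotype calling and the binomial miscall model.

At a truly heterozygous locus every sequencing read independently shows one
of the two alleles.  With allele fraction ``f`` (1/2 in a diploid; 1/4, 2/4
or 3/4 in an autotetraploid) the probability that *all* ``n`` reads show
the same allele — so the site is miscalled homozygous — is ``f^n +
(1-f)^n``.  Solving for the smallest ``n`` keeping this below a type-I
error rate gives the familiar minimum-depth thresholds: 6 reads for an
outbred diploid and 11 for homozygous calls in an outbred autotetraploid
at alpha = 0.05 (worst case over heterozygote dose classes).  Reads are
modelled as error-free draws of the true alleles.

Genotype calls distinguish three classes only (two homozygotes and one
pooled heterozygote class); allele-dosage resolution is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
from scipy import stats


class Call(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


@dataclass(frozen=True)
class PloidyModel:
    """Heterozygote allele-dose classes for a given ploidy.

    Diploid heterozygotes carry allele fraction 1/2; autotetraploid
    heterozygotes (simplex/duplex/triplex, pooled into one call class)
    carry 1/4, 2/4 or 3/4.
    """

    ploidy: int
    het_dose_fractions: tuple[float, ...] = field(init=False)
    pooled_het_call: bool = True

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValueError("ploidy must be 2 or 4")
        fracs = tuple(d / self.ploidy for d in range(1, self.ploidy))
        object.__setattr__(self, "het_dose_fractions", fracs)

    @property
    def worst_case_fraction(self) -> float:
        """The majority-allele fraction hardest to distinguish from homozygous."""
        return max(max(f, 1.0 - f) for f in self.het_dose_fractions)


DIPLOID = PloidyModel(2)
TETRAPLOID = PloidyModel(4)


@dataclass(frozen=True)
class CallFilterRule:
    """Minimum read depths for accepting heterozygous / homozygous calls."""

    min_depth_het: int = 4
    min_depth_hom: int = 11

    def __post_init__(self) -> None:
        if self.min_depth_het < 1 or self.min_depth_hom < 1:
            raise ValueError("minimum depths must be >= 1")


#: Outbred-tetraploid filtering rule: het < 4 reads and hom < 11 reads removed.
TETRAPLOID_RULE = CallFilterRule(min_depth_het=4, min_depth_hom=11)
#: Inbred rule (residual heterozygosity allowed): minimum depth 3 for either class.
INBRED_RULE = CallFilterRule(min_depth_het=3, min_depth_hom=3)


def miscall_probability(n: int, majority_fraction: float) -> float:
    """P(all ``n`` reads show one allele) at a heterozygous site.

    ``f**n + (1-f)**n`` with ``f`` the majority-allele fraction; strictly
    decreasing in ``n``.
    """
    if n < 1:
        raise ValueError("read depth must be >= 1")
    f = majority_fraction
    if not 0.0 < f < 1.0:
        raise ValueError("majority fraction must lie strictly in (0, 1)")
    return f**n + (1.0 - f) ** n


def min_depth_for_error(ploidy_model: PloidyModel, alpha: float) -> int:
    """Smallest depth keeping the worst-case het-as-hom miscall below ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    f = ploidy_model.worst_case_fraction
    n = 1
    while miscall_probability(n, f) >= alpha:
        n += 1
    return n


def call_genotype(a: int, b: int, rule: CallFilterRule) -> Call:
    """Three-class genotype call from reference/alternative read counts.

    Both alleles seen with total depth >= ``min_depth_het`` -> HET; a single
    allele seen with depth >= ``min_depth_hom`` -> that homozygote;
    otherwise MISSING.
    """
    if a < 0 or b < 0:
        raise ValueError("read counts must be non-negative")
    if a > 0 and b > 0:
        return Call.HET if a + b >= rule.min_depth_het else Call.MISSING
    depth = a + b
    if depth >= rule.min_depth_hom:
        return Call.HOM_REF if a > 0 else Call.HOM_ALT
    return Call.MISSING


def expected_missing_rate(
    depth_distribution: Mapping[int, float] | stats.rv_discrete,
    het_fraction: float,
    rule: CallFilterRule,
    allele_fraction: float = 0.5,
    max_depth: int = 200,
) -> float:
    """Analytic probability of a MISSING call under a depth distribution.

    Total probability over read depth and allele-sampling outcomes.  A
    truly homozygous locus (probability ``1 - het_fraction``) is missing
    iff its depth falls below ``min_depth_hom``.  A truly heterozygous
    locus with majority-allele fraction ``allele_fraction`` is missing when
    both alleles are seen but depth < ``min_depth_het``, or when a single
    allele is seen (binomial tail) and depth < ``min_depth_hom``.
    """
    if not 0.0 <= het_fraction <= 1.0:
        raise ValueError("het_fraction must lie in [0, 1]")
    if isinstance(depth_distribution, Mapping):
        items = list(depth_distribution.items())
    else:
        ns = np.arange(0, max_depth + 1)
        pmf = depth_distribution.pmf(ns)
        items = list(zip(ns.tolist(), pmf.tolist()))
    f = allele_fraction
    p_missing = 0.0
    for n, p_n in items:
        if p_n == 0.0:
            continue
        n = int(n)
        if n == 0:
            p_missing += p_n  # no reads: missing whatever the genotype
            continue
        p_hom_missing = 1.0 if n < rule.min_depth_hom else 0.0
        one_allele = f**n + (1.0 - f) ** n
        both = 1.0 - one_allele
        p_het_missing = (
            (both if n < rule.min_depth_het else 0.0)
            + (one_allele if n < rule.min_depth_hom else 0.0)
        )
        p_missing += p_n * (
            (1.0 - het_fraction) * p_hom_missing + het_fraction * p_het_missing
        )
    return p_missing


def threshold_table(alphas=(0.05, 0.01), ploidies=(DIPLOID, TETRAPLOID)):
    """Minimum-depth thresholds for each (ploidy, alpha) pair, as a table."""
    import pandas as pd

    rows = [
        {
            "ploidy": pm.ploidy,
            "alpha": alpha,
            "worst_case_fraction": pm.worst_case_fraction,
            "min_depth": min_depth_for_error(pm, alpha),
        }
        for pm in ploidies
        for alpha in alphas
    ]
    return pd.DataFrame(rows)
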