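"""Phenotypic vs genomic selection: gain per year under equal evaluation cost.

The framework compares one cycle of phenotypic selection with one cycle of
genomic selection on the breeder's-equation scale.  Predicted gain per
year is

    dG_P = i_P * h   * s_A * r_gP / t_P      (phenotypic; h -> H for inbreds)
    dG_G = i_G * r_A * s_A * r_gG / t_G      (genomic)

where ``i`` is the standardized selection differential (selection
intensity), ``h``/``H`` the square root of narrow-/broad-sense
heritability, ``r_A`` the genomic prediction accuracy, ``s_A`` the
standard deviation of breeding values, ``r_g`` the genetic correlation
between selection and target conditions, and ``t`` the cycle length in
years.  Because genotyping is cheaper per candidate than phenotyping, an
equal budget lets the genomic scheme screen ``cost_P / cost_G`` times more
candidates, raising ``i_G``; intensities follow the infinite-population
truncated-normal mean ``phi(z)/p`` unless supplied directly.

Broad-sense line-mean heritability from a multi-environment trial is

    H2 = s_g2 / (s_g2 + s_ge2 / e + s_e2 / (e * r))

with genotypic, genotype-by-environment and error variance components and
``e`` environments x ``r`` replications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd
from scipy import integrate, stats


def selection_intensity(p: float) -> float:
    """Standardized selection differential for a selected fraction ``p``.

    The mean of the upper ``p`` tail of a standard normal: ``phi(z)/p``
    with ``z`` the ``1-p`` quantile.  Strictly decreasing in ``p``;
    ``p = 1`` gives 0 (no truncation).
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("selected fraction must lie in (0, 1]")
    if p == 1.0:
        return 0.0
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def selection_intensity_finite(k: int, N: int) -> float:
    """Finite-sample intensity: expected mean of the top ``k`` of ``N``
    standard-normal order statistics (numerical integration).

    Provided as an optional refinement of :func:`selection_intensity`;
    never applied silently.
    """
    if not 1 <= k <= N:
        raise ValueError("need 1 <= k <= N")
    total = 0.0
    for r in range(N - k + 1, N + 1):  # the k largest order statistics
        logc = (
            math.lgamma(N + 1) - math.lgamma(r) - math.lgamma(N - r + 1)
        )

        def integrand(x, r=r, logc=logc):
            logf = (
                logc
                + (r - 1) * stats.norm.logcdf(x)
                + (N - r) * stats.norm.logsf(x)
                + stats.norm.logpdf(x)
            )
            return x * math.exp(logf)

        val, _ = integrate.quad(integrand, -12, 12, limit=200)
        total += val
    return total / k


@dataclass(frozen=True)
class VarianceComponents:
    """Genotype, GE-interaction and error variances from a trial series."""

    s_g2: float
    s_ge2: float
    s_e2: float
    e: int = 1
    r: int = 1

    def __post_init__(self) -> None:
        if min(self.s_g2, self.s_ge2, self.s_e2) < 0:
            raise ValueError("variance components must be non-negative")
        if self.e < 1 or self.r < 1:
            raise ValueError("e and r must be >= 1")


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """Line-mean broad-sense heritability H2."""
    denom = vc.s_g2 + vc.s_ge2 / vc.e + vc.s_e2 / (vc.e * vc.r)
    if denom <= 0:
        raise ValueError("all variance components are zero")
    return vc.s_g2 / denom


@dataclass(frozen=True)
class SelectionScheme:
    """One arm of a selection-scheme comparison.

    ``accuracy`` is ``h`` (or ``H``) for phenotypic schemes and ``r_A`` for
    genomic schemes.  The selection intensity comes from ``intensity`` when
    given, otherwise from the truncated-normal mean at ``k / n_candidates``.
    """

    mode: Literal["phenotypic", "genomic"]
    accuracy: float
    cycle_years: float
    selected: int | None = None
    n_candidates: int | None = None
    intensity: float | None = None
    genetic_correlation: float = 1.0
    cost_per_genotype: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if self.cycle_years <= 0:
            raise ValueError("cycle length must be positive")
        if not -1.0 <= self.genetic_correlation <= 1.0:
            raise ValueError("genetic correlation must lie in [-1, 1]")
        if self.intensity is None and (
            self.selected is None
            or (self.n_candidates is None and self.cost_per_genotype is None)
        ):
            # candidates may instead be derived from cost data at comparison
            # time (equal-cost scaling)
            raise ValueError("give an intensity, selected/candidate counts, "
                             "or selected + cost data")
        if self.selected is not None and self.n_candidates is not None:
            if not 1 <= self.selected <= self.n_candidates:
                raise ValueError("need 1 <= selected <= candidates")

    def effective_intensity(self) -> float:
        if self.intensity is not None:
            return self.intensity
        return selection_intensity(self.selected / self.n_candidates)


def gain_per_year(scheme: SelectionScheme, s_A: float = 1.0) -> float:
    """Predicted gain per year: ``i * accuracy * s_A * r_g / t``."""
    if s_A <= 0:
        raise ValueError("s_A must be positive")
    i = scheme.effective_intensity()
    return i * scheme.accuracy * s_A * scheme.genetic_correlation / scheme.cycle_years


@dataclass(frozen=True)
class GainScenario:
    """A phenotypic/genomic scheme pair under a common breeding-value scale."""

    phenotypic: SelectionScheme
    genomic: SelectionScheme
    s_A: float = 1.0

    def __post_init__(self) -> None:
        if self.s_A <= 0:
            raise ValueError("s_A must be positive")
        if self.phenotypic.mode != "phenotypic" or self.genomic.mode != "genomic":
            raise ValueError("scenario needs one phenotypic and one genomic scheme")


@dataclass
class ComparisonResult:
    """Gain per year of both schemes, their ratio, and the intensities used."""

    gain_phenotypic: float
    gain_genomic: float
    ratio: float
    intensity_phenotypic: float
    intensity_genomic: float
    n_candidates_genomic: int | None = None
    break_even_accuracy: float | None = None

    def summary(self) -> str:
        lines = [
            "Genomic vs phenotypic selection (per-year gain, s_A units)",
            "=" * 58,
            f"phenotypic gain/year:  {self.gain_phenotypic:.3f}"
            f"   (i = {self.intensity_phenotypic:.2f})",
            f"genomic gain/year:     {self.gain_genomic:.3f}"
            f"   (i = {self.intensity_genomic:.2f})",
            f"ratio genomic/phen.:   {self.ratio:.2f}",
        ]
        if self.n_candidates_genomic is not None:
            lines.append(
                f"genomic candidates (equal cost): {self.n_candidates_genomic}"
            )
        if self.break_even_accuracy is not None:
            lines.append(
                f"break-even genomic accuracy:     {self.break_even_accuracy:.3f}"
            )
        return "\n".join(lines)


def compare_schemes_equal_cost(scenario: GainScenario) -> ComparisonResult:
    """Gain-per-year comparison at equal total evaluation cost.

    When the genomic scheme has costs but no candidate count, the equal
    budget buys ``N_G = N_P * cost_P / cost_G`` genomic candidates; the
    genomic intensity then follows from selecting ``k`` of ``N_G``.
    """
    phen, gen = scenario.phenotypic, scenario.genomic
    n_g = gen.n_candidates
    i_g = gen.intensity
    if i_g is None and n_g is None:
        if (
            phen.cost_per_genotype is None
            or gen.cost_per_genotype is None
            or phen.n_candidates is None
            or gen.selected is None
        ):
            raise ValueError(
                "genomic scheme needs candidates, an intensity, or cost data"
            )
        if gen.cost_per_genotype <= 0:
            raise ValueError("genomic cost per genotype must be positive")
        n_g = int(round(phen.n_candidates * phen.cost_per_genotype / gen.cost_per_genotype))
        if n_g < gen.selected:
            raise ValueError(
                f"equal-cost genomic candidates ({n_g}) fewer than selected "
                f"({gen.selected})"
            )
        gen = SelectionScheme(
            mode="genomic",
            accuracy=gen.accuracy,
            cycle_years=gen.cycle_years,
            selected=gen.selected,
            n_candidates=n_g,
            genetic_correlation=gen.genetic_correlation,
            cost_per_genotype=gen.cost_per_genotype,
        )
    dg_p = gain_per_year(phen, scenario.s_A)
    dg_g = gain_per_year(gen, scenario.s_A)
    ratio = dg_g / dg_p if dg_p > 0 else math.inf
    scenario_eff = GainScenario(phenotypic=phen, genomic=gen, s_A=scenario.s_A)
    return ComparisonResult(
        gain_phenotypic=dg_p,
        gain_genomic=dg_g,
        ratio=ratio,
        intensity_phenotypic=phen.effective_intensity(),
        intensity_genomic=gen.effective_intensity(),
        n_candidates_genomic=gen.n_candidates,
        break_even_accuracy=break_even_accuracy(scenario_eff, advantage_factor=1.0),
    )


def break_even_accuracy(scenario: GainScenario, advantage_factor: float = 1.0) -> float:
    """Genomic accuracy at which ``dG_G = advantage_factor * dG_P``.

    Closed form: ``r_A = factor * acc_P * i_P * r_gP * t_G /
    (i_G * r_gG * t_P)``.
    """
    if advantage_factor < 0:
        raise ValueError("advantage factor must be non-negative")
    phen, gen = scenario.phenotypic, scenario.genomic
    i_p, i_g = phen.effective_intensity(), gen.effective_intensity()
    if i_g == 0 or gen.genetic_correlation == 0:
        raise ValueError("genomic intensity and genetic correlation must be non-zero")
    return (
        advantage_factor
        * phen.accuracy
        * i_p
        * phen.genetic_correlation
        * gen.cycle_years
        / (i_g * gen.genetic_correlation * phen.cycle_years)
    )


def multi_trait_population_size(k: int, n_traits: int, per_trait_rate: float) -> int:
    """Candidates needed to select ``k`` finalists under independent
    per-trait culling at rate ``per_trait_rate``: ``k * (1/rate)^n_traits``."""
    if not 0.0 < per_trait_rate <= 1.0:
        raise ValueError("per-trait selection rate must lie in (0, 1]")
    if n_traits < 0:
        raise ValueError("n_traits must be >= 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    return math.ceil(k * (1.0 / per_trait_rate) ** n_traits)


def cost_ratio_summary(costs: pd.DataFrame) -> pd.DataFrame:
    """Phenotypic:genomic evaluation-cost ratios per crop.

    Expects columns ``crop, phenotypic_low, phenotypic_high, genomic_low,
    genomic_high``; returns min (low/high), max (high/low) and midpoint
    (mean/mean) ratios.
    """
    required = {
        "crop", "phenotypic_low", "phenotypic_high", "genomic_low", "genomic_high",
    }
    missing = required - set(costs.columns)
    if missing:
        raise ValueError(f"cost table missing columns {sorted(missing)}")
    if (costs[["genomic_low", "genomic_high"]] <= 0).any().any():
        raise ValueError("genomic costs must be positive")
    out = pd.DataFrame({"crop": costs["crop"]})
    out["ratio_min"] = costs["phenotypic_low"] / costs["genomic_high"]
    out["ratio_max"] = costs["phenotypic_high"] / costs["genomic_low"]
    out["ratio_mid"] = (
        (costs["phenotypic_low"] + costs["phenotypic_high"])
        / (costs["genomic_low"] + costs["genomic_high"])
    )
    return out
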