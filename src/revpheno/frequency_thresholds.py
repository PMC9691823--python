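"""Disease-specific maximum credible population allele frequency.

For a recessive (biallelic) disease the highest allele frequency a truly
causative allele can plausibly reach in a reference population is

    af_max = sqrt(prevalence * genetic_heterogeneity / penetrance)
             * allelic_heterogeneity

and for a dominant (monoallelic) disease

    af_max = prevalence * genetic_heterogeneity * allelic_heterogeneity
             / (2 * penetrance)

where *genetic_heterogeneity* is the fraction of cases attributable to the
gene and *allelic_heterogeneity* the fraction of the gene's disease alleles
contributed by the single most common allele.  With the packaged ciliopathy
disease model (biallelic, prevalence 1/500, allelic heterogeneity 0.1,
genetic heterogeneity 0.2, full penetrance) this gives the pipeline's
default rarity cut-off of 0.002.

A confidence-adjusted maximum tolerated allele count is also provided: the
largest number of observations of an allele in a reference cohort that is
still statistically consistent (at the given confidence) with the maximum
credible frequency, under a Poisson sampling model.  The pipeline default
applies the allele-frequency cut-off directly; the allele count is exposed
for users who filter on counts rather than frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["DiseaseModel", "max_credible_af", "max_tolerated_ac", "CILIOPATHY_MODEL"]


@dataclass(frozen=True)
class DiseaseModel:
    """Epidemiological parameters of one disease/gene model.

    All proportions are in (0, 1]; ``prevalence`` and ``confidence`` must be
    strictly below 1.  ``reference_population_size`` is a count of diploid
    individuals in the reference database.
    """

    prevalence: float
    allelic_heterogeneity: float
    genetic_heterogeneity: float
    penetrance: float = 1.0
    mode: str = "biallelic"
    confidence: float = 0.95
    reference_population_size: int = 121_412

    def __post_init__(self) -> None:
        checks = {
            "prevalence": (self.prevalence, 0.0, 1.0, "()"),
            "allelic_heterogeneity": (self.allelic_heterogeneity, 0.0, 1.0, "(]"),
            "genetic_heterogeneity": (self.genetic_heterogeneity, 0.0, 1.0, "(]"),
            "penetrance": (self.penetrance, 0.0, 1.0, "(]"),
            "confidence": (self.confidence, 0.0, 1.0, "()"),
        }
        for name, (v, lo, hi, kind) in checks.items():
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            hi_ok = v <= hi if kind == "(]" else v < hi
            if not (lo < v and hi_ok):
                raise ValueError(f"{name}={v} outside {kind[0]}{lo}, {hi}{kind[1]}")
        if self.mode not in ("biallelic", "monoallelic"):
            raise ValueError(f"unknown inheritance mode {self.mode!r}")
        if self.reference_population_size <= 0:
            raise ValueError("reference_population_size must be positive")


#: Parameters used for the nine-gene ciliopathy screen.
CILIOPATHY_MODEL = DiseaseModel(
    prevalence=1 / 500,
    allelic_heterogeneity=0.1,
    genetic_heterogeneity=0.2,
    penetrance=1.0,
    mode="biallelic",
    confidence=0.95,
    reference_population_size=121_412,
)


def max_credible_af(model: DiseaseModel) -> float:
    """Maximum credible population allele frequency for ``model``.

    Deterministic closed form; see the module docstring for the two
    inheritance-mode formulas.
    """
    if model.mode == "biallelic":
        return (
            math.sqrt(model.prevalence * model.genetic_heterogeneity / model.penetrance)
            * model.allelic_heterogeneity
        )
    return (
        model.prevalence
        * model.genetic_heterogeneity
        * model.allelic_heterogeneity
        / (2.0 * model.penetrance)
    )


def max_tolerated_ac(
    af_max: float, n_individuals: int, confidence: float = 0.95
) -> int:
    """Largest allele count consistent with ``af_max`` at ``confidence``.

    Under a Poisson model with rate ``2 * n_individuals * af_max`` (two
    chromosomes per diploid individual), returns the largest integer ``c``
    such that ``P(X >= c) > 1 - confidence``; an allele seen more often than
    this is implausibly common for a causative allele.  Returns 0 when
    ``af_max`` is 0.
    """
    if af_max < 0:
        raise ValueError("af_max must be non-negative")
    if af_max == 0:
        return 0
    rate = 2.0 * n_individuals * af_max
    alpha = 1.0 - confidence
    # P(X >= c) = sf(c - 1); decreasing in c, so the set {c : sf(c-1) > alpha}
    # is an integer interval [0, c_max] found by inverting the survival
    # function.
    c = int(stats.poisson.isf(alpha, rate))
    while stats.poisson.sf(c - 1, rate) > alpha:
        c += 1
    while c > 0 and stats.poisson.sf(c - 1, rate) <= alpha:
        c -= 1
    return c
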