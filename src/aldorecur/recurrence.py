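"""Significance statistics for recurrent mutations in a sequenced cohort.

Observing the *same* protein-altering mutation independently in several
unrelated probands is strong evidence for causality, provided the chance
probability of such recurrence is small.  Two complementary binomial
calculations quantify it:

* the probability that two or more *de novo* mutations hit the same base in a
  set of sequenced cases, corrected for the protein-altering target size of
  the exome; and
* the probability that a variant of a given (conservatively chosen)
  population allele frequency is carried by ``k`` further unrelated cases.

Their product bounds the chance probability of the full observation.  A
Hardy-Weinberg helper converts a cumulative loss-of-function allele
frequency into the expected frequency of biallelic (homozygous or compound
heterozygous) carriers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "RecurrenceParams",
    "RecurrenceResult",
    "p_recurrent_de_novo",
    "p_additional_carriers",
    "combined_recurrence",
    "biallelic_lof_frequency",
    "recurrence_report",
]

#: Default per-base per-proband de novo mutation probability.
DEFAULT_MU_DN = 1.4e-8
#: Default protein-altering target size of the human exome, in base pairs.
DEFAULT_TARGET_BP = 24.75e6


@dataclass(frozen=True)
class RecurrenceParams:
    """Parameters of the recurrence model.

    Attributes
    ----------
    mu_dn:
        Per-base per-proband de novo mutation probability (dimensionless).
    target_bp:
        Protein-altering target size in base pairs.
    allele_freq:
        Assumed population allele frequency of the variant under test.
    """

    mu_dn: float = DEFAULT_MU_DN
    target_bp: float = DEFAULT_TARGET_BP
    allele_freq: float = 1e-5

    def __post_init__(self) -> None:
        if not 0.0 < self.mu_dn < 1.0:
            raise ValueError("mu_dn must lie in (0, 1)")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must lie in (0, 1)")
        if self.target_bp < 1:
            raise ValueError("target_bp must be >= 1")
        if self.mu_dn * self.target_bp >= 1.0:
            warnings.warn(
                "mu_dn * target_bp >= 1: the linear genome-wide correction "
                "is not a probability in this regime",
                stacklevel=2,
            )


@dataclass(frozen=True)
class RecurrenceResult:
    """Bundle of the three recurrence probabilities for one variant."""

    p_de_novo_recurrent: float
    p_additional_carriers: float
    p_combined: float
    n_cases_de_novo: int
    n_cases_inherited: int
    k_carriers: int

    def __post_init__(self) -> None:
        for p in (self.p_de_novo_recurrent, self.p_additional_carriers, self.p_combined):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def p_recurrent_de_novo(
    n_cases: int,
    mu_dn: float = DEFAULT_MU_DN,
    target_bp: float = DEFAULT_TARGET_BP,
    *,
    genomewide: str = "linear",
    strict: bool = False,
) -> float:
    """Probability of >=2 de novo hits at any single protein-altering base.

    The per-site probability of observing two or more de novo mutations at a
    specified position among ``n_cases`` probands is the upper binomial tail
    ``P(X >= 2)`` with ``X ~ Binomial(n_cases, mu_dn)``.  It is corrected for
    the number of sites at which such a coincidence could have occurred.

    Parameters
    ----------
    n_cases:
        Number of probands in which a de novo event could be ascertained.
    mu_dn:
        Per-base per-proband de novo mutation probability.
    target_bp:
        Protein-altering target size (number of candidate sites).
    genomewide:
        ``"linear"`` multiplies the per-site tail by ``target_bp`` (a
        Bonferroni-style union bound, clamped to 1); ``"exact"`` returns
        ``1 - (1 - P_site)**target_bp``, the probability of at least one such
        site genome-wide under independence.  The two are indistinguishable
        whenever the result is small.
    strict:
        If True, ``n_cases < 2`` raises instead of returning 0.

    Returns
    -------
    float
        Genome-wide probability, clamped to ``[0, 1]``.
    """
    if not 0.0 < mu_dn < 1.0:
        raise ValueError("recurrence undefined: mu_dn must lie in (0, 1)")
    if target_bp < 1:
        raise ValueError("target_bp must be >= 1")
    if n_cases < 0:
        raise ValueError("n_cases must be >= 0")
    if n_cases < 2:
        if strict:
            raise ValueError("recurrence undefined for fewer than 2 cases")
        return 0.0
    p_site = float(stats.binom.sf(1, n_cases, mu_dn))
    if genomewide == "linear":
        return min(1.0, p_site * target_bp)
    if genomewide == "exact":
        # log1p route keeps precision for tiny p_site and huge target_bp
        return -math.expm1(target_bp * math.log1p(-p_site))
    raise ValueError(f"unknown genomewide mode {genomewide!r}")


def p_recurrent_de_novo_approx(
    n_cases: int,
    mu_dn: float = DEFAULT_MU_DN,
    target_bp: float = DEFAULT_TARGET_BP,
) -> float:
    """C(n,2)*mu^2 small-probability approximation of :func:`p_recurrent_de_novo`."""
    if n_cases < 2:
        return 0.0
    return min(1.0, math.comb(n_cases, 2) * mu_dn**2 * target_bp)


def p_additional_carriers(
    n_subjects: int,
    k: int,
    allele_freq: float,
    *,
    tail: bool = False,
) -> float:
    """Binomial probability of ``k`` carriers among ``n_subjects``.

    The per-subject carrier probability is set equal to the allele frequency
    itself.  This understates the heterozygote frequency (which is ``~2q``
    under Hardy-Weinberg) and therefore *understates* the chance probability
    — a deliberately conservative convention, since the statistic is used as
    evidence against the chance hypothesis.

    Parameters
    ----------
    n_subjects:
        Number of additional unrelated subjects screened.
    k:
        Observed carrier count.
    allele_freq:
        Assumed population allele frequency, used directly as the per-subject
        carrier probability.
    tail:
        If True return ``P(X >= k)`` instead of ``P(X = k)``.
    """
    if not 0.0 < allele_freq < 1.0:
        raise ValueError("allele_freq must lie in (0, 1)")
    if not 0 <= k <= n_subjects:
        raise ValueError("require 0 <= k <= n_subjects")
    if tail:
        return float(stats.binom.sf(k - 1, n_subjects, allele_freq))
    return float(stats.binom.pmf(k, n_subjects, allele_freq))


def combined_recurrence(p1: float, p2: float) -> float:
    """Product of two independent recurrence probabilities."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    return p1 * p2


def biallelic_lof_frequency(cum_lof_freq: float) -> tuple[float, float]:
    """Expected biallelic loss-of-function subject frequency under Hardy-Weinberg.

    With cumulative loss-of-function allele frequency ``q`` (summing all
    splice, frameshift and nonsense alleles, so that both homozygosity and
    compound heterozygosity are covered), the expected frequency of subjects
    carrying two such alleles is ``q**2``.

    Returns
    -------
    (q_squared, one_in_n):
        The biallelic frequency and its reciprocal ("1 in N subjects").
    """
    if not 0.0 < cum_lof_freq < 1.0:
        raise ValueError("cum_lof_freq must lie in (0, 1)")
    q2 = cum_lof_freq**2
    return q2, 1.0 / q2


def recurrence_report(
    n_cases_de_novo: int,
    n_cases_inherited: int,
    k_carriers: int,
    params: RecurrenceParams | None = None,
) -> RecurrenceResult:
    """Full recurrence analysis for one variant.

    Combines the genome-wide de novo recurrence probability over
    ``n_cases_de_novo`` probands with the probability of ``k_carriers``
    further carriers among ``n_cases_inherited`` unrelated subjects.
    """
    params = params or RecurrenceParams()
    p1 = p_recurrent_de_novo(n_cases_de_novo, params.mu_dn, params.target_bp)
    p2 = p_additional_carriers(n_cases_inherited, k_carriers, params.allele_freq)
    return RecurrenceResult(
        p_de_novo_recurrent=p1,
        p_additional_carriers=p2,
        p_combined=combined_recurrence(p1, p2),
        n_cases_de_novo=n_cases_de_novo,
        n_cases_inherited=n_cases_inherited,
        k_carriers=k_carriers,
    )
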