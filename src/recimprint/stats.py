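"""Per-observation allele-specific expression (ASE) statistics.

The elementary test throughout the package is a Pearson chi-square
goodness-of-fit of the two allelic read counts at a heterozygous SNP (or a
gene aggregate) against the balanced 50:50 expectation, with one degree of
freedom and no continuity correction:

    chi2 = (b - n/2)^2 / (n/2) + (c - n/2)^2 / (n/2) = (b - c)^2 / n

where ``b`` and ``c`` are the reads supporting the C57BL/6J ("B") and
CAST/EiJ ("C") alleles and ``n = b + c``.  Direction of bias is simply the
allele carrying more than half of the reads.

Imprinting evidence combines the two reciprocal crosses: a unit is
*reciprocally* biased when the maternal allele carries the majority of reads
in both crosses (or the paternal allele does), and the signed imprinting
score is ``-log10`` of the *less* significant of the two per-cross p-values,
positive for maternal bias and negative for paternal bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats as sps

from .errors import UndefinedTestError

Cross = Literal["BxC", "CxB"]

#: Crosses are written maternal-strain-first: BxC = B mother x C father.
CROSSES = ("BxC", "CxB")


@dataclass(frozen=True)
class AseTest:
    """Chi-square ASE test result at one SNP/gene in one sample."""

    count_B: int
    count_C: int
    chi2: float
    p: float
    direction: Literal["B", "C", "none"]

    @property
    def n(self) -> int:
        return self.count_B + self.count_C


@dataclass(frozen=True)
class ImprintScore:
    """Signed log10 significance of reciprocal parental bias.

    ``score`` is defined only when ``reciprocal`` is True; its magnitude is
    ``-log10(p_used)`` where ``p_used`` is the less significant (larger) of
    the two per-cross p-values, and its sign is +1 for maternal bias and -1
    for paternal bias.
    """

    reciprocal: bool
    score: float | None
    p_used: float
    direction: Literal["maternal", "paternal", "none"]


def chi2_components(count_B, count_C):
    """Vectorised Pearson statistic and two-sided tail p for balanced counts.

    Returns ``(chi2, p)`` as float arrays; entries with zero total depth get
    ``chi2 = nan, p = nan`` (callers treat them as untestable).
    """
    b = np.asarray(count_B, dtype=float)
    c = np.asarray(count_C, dtype=float)
    n = b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(n > 0, (b - c) ** 2 / np.where(n > 0, n, 1.0), np.nan)
    p = sps.chi2.sf(chi2, df=1)
    return chi2, p


def direction_codes(count_B, count_C):
    """Vectorised direction of bias: +1 = B majority, -1 = C, 0 = tie."""
    b = np.asarray(count_B)
    c = np.asarray(count_C)
    return np.sign(b - c).astype(np.int8)


def chi_square_ase(count_B: int, count_C: int) -> AseTest:
    """Test one pair of allelic counts against the 50:50 expectation.

    Examples
    --------
    >>> t = chi_square_ase(30, 70)
    >>> round(t.chi2, 6), t.direction
    (16.0, 'C')
    """
    if count_B < 0 or count_C < 0:
        raise ValueError("allelic counts must be non-negative")
    n = count_B + count_C
    if n == 0:
        raise UndefinedTestError("chi-square ASE test undefined at zero depth")
    chi2 = (count_B - count_C) ** 2 / n
    p = float(sps.chi2.sf(chi2, df=1))
    if count_B > count_C:
        direction = "B"
    elif count_C > count_B:
        direction = "C"
    else:
        direction = "none"
    return AseTest(count_B=count_B, count_C=count_C, chi2=float(chi2), p=p, direction=direction)


def maternal_fraction(count_B: int, count_C: int, cross: Cross) -> float:
    """Fraction of reads from the maternal-strain allele.

    Under BxC the mother is strain B, so the maternal allele is B; under CxB
    it is C.
    """
    n = count_B + count_C
    if n == 0:
        raise UndefinedTestError("maternal fraction undefined at zero depth")
    if cross == "BxC":
        return count_B / n
    if cross == "CxB":
        return count_C / n
    raise ValueError(f"unknown cross {cross!r}; expected one of {CROSSES}")


def imprinting_score(
    test_bxc: AseTest,
    test_cxb: AseTest,
    crosses: tuple[Cross, Cross] = ("BxC", "CxB"),
) -> ImprintScore:
    """Combine the two reciprocal-cross tests into a signed score.

    The score exists only when both samples are biased toward the same
    parental sex (maternal fraction on the same side of 0.5 in both). A tie
    (direction ``none``) in either sample voids reciprocity.
    """
    mf1 = maternal_fraction(test_bxc.count_B, test_bxc.count_C, crosses[0])
    mf2 = maternal_fraction(test_cxb.count_B, test_cxb.count_C, crosses[1])
    p_used = max(test_bxc.p, test_cxb.p)
    if mf1 > 0.5 and mf2 > 0.5:
        direction = "maternal"
    elif mf1 < 0.5 and mf2 < 0.5:
        direction = "paternal"
    else:
        return ImprintScore(reciprocal=False, score=None, p_used=p_used, direction="none")
    sign = 1.0 if direction == "maternal" else -1.0
    # p_used > 0 always for finite counts (chi2 tail), but guard the log.
    magnitude = -np.log10(p_used) if p_used > 0 else np.inf
    return ImprintScore(reciprocal=True, score=sign * float(magnitude), p_used=p_used, direction=direction)


def maternal_fraction_arrays(count_B, count_C, cross: Cross):
    """Vectorised :func:`maternal_fraction`; zero-depth entries get nan."""
    b = np.asarray(count_B, dtype=float)
    c = np.asarray(count_C, dtype=float)
    n = b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_b = np.where(n > 0, b / np.where(n > 0, n, 1.0), np.nan)
    if cross == "BxC":
        return frac_b
    if cross == "CxB":
        return 1.0 - frac_b
    raise ValueError(f"unknown cross {cross!r}; expected one of {CROSSES}")
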