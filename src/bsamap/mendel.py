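"""Mendelian cross models: segregation ratios, goodness of fit, bulk allele frequencies.

A bulked-segregant design derives its power from the expected allele-frequency
contrast between phenotype-class bulks. For an F2 from selfed F1 heterozygotes
segregating a monogenic recessive trait, the recessive-phenotype bulk is fixed
for the recessive allele (frequency 1) while the dominant-phenotype bulk mixes
AA and Aa genotypes 1:2, giving recessive-allele frequency 1/3. The difference,
2/3 ~ 0.667, is the theoretical peak height of the delta-SNP-index scan.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "CrossModel",
    "expected_ratio",
    "chi_square_gof",
    "expected_bulk_freq",
]

_SUPPORTED_DESIGNS = {"F2_self", "backcross"}
_SUPPORTED_DOMINANCE = {"recessive", "dominant"}


@dataclass(frozen=True)
class CrossModel:
    """A two-class Mendelian mapping design.

    Parameters
    ----------
    design:
        ``"F2_self"`` (selfed F1 heterozygote, genotypes 1:2:1) or
        ``"backcross"`` (F1 x recessive parent, genotypes 1:1).
    dominance:
        Which homozygote class expresses the mapped phenotype; only
        ``"recessive"`` traits are fully supported (the dominant case
        raises where expectations are not defined).
    penetrance:
        Probability in (0, 1] that a recessive genotype expresses the
        phenotype; non-penetrant recessives are scored in the dominant class.
    """

    design: str = "F2_self"
    dominance: str = "recessive"
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if self.design not in _SUPPORTED_DESIGNS:
            raise NotImplementedError(f"unsupported cross design: {self.design!r}")
        if self.dominance not in _SUPPORTED_DOMINANCE:
            raise ValueError(f"unknown dominance: {self.dominance!r}")
        if not (0.0 < self.penetrance <= 1.0):
            raise ValueError(f"penetrance must be in (0, 1], got {self.penetrance}")


def expected_ratio(cross: CrossModel) -> tuple[float, float]:
    """Expected (dominant-class, recessive-class) phenotype weights.

    For a fully penetrant recessive trait in an F2 this is the classical 3:1;
    a backcross to the recessive parent gives 1:1. Penetrance ``p`` < 1 moves
    the non-penetrant fraction of recessive genotypes into the dominant class:
    F2 weights become ``(3 + (1 - p), p)`` per four plants, e.g. p = 0.5
    yields 7:1.
    """
    if cross.dominance != "recessive":
        raise NotImplementedError("only recessive traits are modelled")
    p = cross.penetrance
    if cross.design == "F2_self":
        return (3.0 + (1.0 - p), p)
    # backcross to recessive parent: Aa : aa = 1 : 1
    return (1.0 + (1.0 - p), p)


def chi_square_gof(
    observed: tuple[int, int],
    ratio: tuple[float, float],
    yates: bool = False,
) -> tuple[float, int, float]:
    """Pearson chi-square goodness of fit of two observed class counts to a ratio.

    Returns ``(chi2, df, p)`` with df = 1. ``observed`` is
    (dominant-class count, recessive-class count); ``ratio`` the expected
    weights, e.g. ``(3, 1)``. The Yates continuity correction is off by
    default.
    """
    n1, n2 = observed
    total = n1 + n2
    if total <= 0:
        raise ValueError("total observed count must be positive")
    w1, w2 = ratio
    if w1 <= 0 or w2 <= 0:
        raise ValueError("expected ratio weights must be positive")
    wsum = w1 + w2
    e1 = total * w1 / wsum
    e2 = total * w2 / wsum
    if yates:
        chi2 = (abs(n1 - e1) - 0.5) ** 2 / e1 + (abs(n2 - e2) - 0.5) ** 2 / e2
    else:
        chi2 = (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    df = 1
    p = float(stats.chi2.sf(chi2, df))
    return (float(chi2), df, p)


def expected_bulk_freq(cross: CrossModel, bulk_class: str) -> float:
    """Expected recessive-allele frequency among plants of a phenotype class.

    ``bulk_class`` is ``"recessive"`` or ``"dominant"``. For a fully penetrant
    recessive F2 trait: the recessive-phenotype class is all aa, frequency 1;
    the dominant-phenotype class is AA:Aa = 1:2, frequency 1/3. With
    penetrance ``p`` < 1 the dominant class additionally contains non-penetrant
    aa plants with weight (1 - p), giving (2 - p) / (4 - p).
    """
    if cross.dominance != "recessive":
        raise NotImplementedError("only recessive traits are modelled")
    if bulk_class not in ("recessive", "dominant"):
        raise ValueError(f"unknown bulk class: {bulk_class!r}")
    p = cross.penetrance
    if cross.design == "F2_self":
        if bulk_class == "recessive":
            return 1.0  # every penetrant sterile plant is aa
        # dominant class: AA (w=1, 0 copies), Aa (w=2, 1 copy), aa (w=1-p, 2 copies)
        return (2.0 + 2.0 * (1.0 - p)) / (2.0 * (3.0 + (1.0 - p)))
    # backcross to recessive parent: classes Aa (dominant) and aa (recessive)
    if bulk_class == "recessive":
        return 1.0
    # dominant class: Aa (w=1) plus non-penetrant aa (w=1-p)
    return (1.0 + 2.0 * (1.0 - p)) / (2.0 * (1.0 + (1.0 - p)))
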