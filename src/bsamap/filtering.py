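"""The four SNP-filtering rules applied before association scanning.

In order, a site is removed if it
  R1 "multiallelic":      carries more than one alternate allele;
  R2 "low_support":       has too few supporting reads (default: either
                          pool's total depth below 4);
  R3 "same_genotype":     both bulks show the same inferred pool genotype,
                          so the site cannot separate the phenotype classes;
  R4 "not_from_parent":   the allele fixed in the recessive (sterile) bulk
                          is not carried by the recessive parent, i.e. the
                          call contradicts the cross.

A record failing several rules is charged to the first in this fixed order,
so the per-rule counts in the report are reproducible. Pool genotypes are
called from the allele-frequency band: alt-fraction below 0.2 is ref-fixed,
above 0.8 alt-fixed, between is het-like; zero depth gives no-call (such a
site is removed by R2 first anyway).

The read-support rule exists in two modes because "fewer than four
supporting reads" can be read per-pool or per-allele: mode ``"pool"``
(default) removes sites where either bulk's total depth < min_support;
mode ``"allele"`` removes sites where the alternate allele's combined
support across bulks is positive but < min_support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RULES",
    "FilterReport",
    "infer_pool_genotype",
    "infer_pool_genotypes",
    "filter_variants",
]

RULES = ("multiallelic", "low_support", "same_genotype", "not_from_parent")

REF_FIXED, HET_LIKE, ALT_FIXED, NO_CALL = "ref-fixed", "het-like", "alt-fixed", "no-call"


@dataclass
class FilterReport:
    input_count: int
    removed_per_rule: dict[str, int] = field(default_factory=dict)
    output_count: int = 0

    def summary(self) -> str:
        lines = [f"input sites: {self.input_count}"]
        lines += [f"  removed by {r}: {self.removed_per_rule.get(r, 0)}" for r in RULES]
        lines.append(f"surviving sites: {self.output_count}")
        return "\n".join(lines)


def infer_pool_genotype(
    ref_depth: int, alt_depth: int, het_band: tuple[float, float] = (0.2, 0.8)
) -> str:
    """Call a pool's genotype class from its allele depths (see module docs)."""
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("depths must be non-negative")
    total = ref_depth + alt_depth
    if total == 0:
        return NO_CALL
    f = alt_depth / total
    low, high = het_band
    if f < low:
        return REF_FIXED
    if f > high:
        return ALT_FIXED
    return HET_LIKE


def infer_pool_genotypes(
    ref_depth: np.ndarray, alt_depth: np.ndarray, het_band: tuple[float, float] = (0.2, 0.8)
) -> np.ndarray:
    """Vectorised :func:`infer_pool_genotype` over site arrays."""
    ref_depth = np.asarray(ref_depth)
    alt_depth = np.asarray(alt_depth)
    total = ref_depth + alt_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, alt_depth / np.maximum(total, 1), np.nan)
    low, high = het_band
    out = np.full(ref_depth.shape, HET_LIKE, dtype=object)
    out[f < low] = REF_FIXED
    out[f > high] = ALT_FIXED
    out[total == 0] = NO_CALL
    return out


def _parent_alleles(gt: pd.Series) -> list[set[int]]:
    out = []
    for g in gt:
        if g in (None, "", "./."):
            out.append(set())
        else:
            out.append({int(a) for a in str(g).split("/")})
    return out


def filter_variants(
    sites: pd.DataFrame,
    min_support: int = 4,
    het_band: tuple[float, float] = (0.2, 0.8),
    support_mode: str = "pool",
    apply_parent_rule: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply rules R1-R4 in order; returns surviving sites and a report.

    Input order is preserved. ``apply_parent_rule=False`` disables R4 (for
    datasets without parent genotype calls); with R4 enabled, missing parent
    genotype columns raise.
    """
    if support_mode not in ("pool", "allele"):
        raise ValueError(f"support_mode must be 'pool' or 'allele', got {support_mode!r}")
    report = FilterReport(input_count=len(sites), removed_per_rule={r: 0 for r in RULES})
    if sites.empty:
        report.output_count = 0
        return sites.copy(), report
    if apply_parent_rule and "gt_parent_sterile" not in sites.columns:
        raise ValueError("parent genotype column required for the parent-origin rule")

    n = len(sites)
    removed_by = np.full(n, "", dtype=object)

    # R1: more than one alternate allele
    r1 = sites["n_alt_alleles"].to_numpy() > 1
    removed_by[r1 & (removed_by == "")] = "multiallelic"

    # R2: read support
    s_tot = (sites["ad_ref_bulk_sterile"] + sites["ad_alt_bulk_sterile"]).to_numpy()
    f_tot = (sites["ad_ref_bulk_fertile"] + sites["ad_alt_bulk_fertile"]).to_numpy()
    if support_mode == "pool":
        r2 = (s_tot < min_support) | (f_tot < min_support)
    else:
        alt_support = (sites["ad_alt_bulk_sterile"] + sites["ad_alt_bulk_fertile"]).to_numpy()
        r2 = (alt_support > 0) & (alt_support < min_support)
    removed_by[r2 & (removed_by == "")] = "low_support"

    # R3: identical inferred pool genotypes
    g_s = infer_pool_genotypes(
        sites["ad_ref_bulk_sterile"], sites["ad_alt_bulk_sterile"], het_band
    )
    g_f = infer_pool_genotypes(
        sites["ad_ref_bulk_fertile"], sites["ad_alt_bulk_fertile"], het_band
    )
    r3 = g_s == g_f
    removed_by[r3 & (removed_by == "")] = "same_genotype"

    # R4: sterile-bulk fixed allele must come from the sterile parent
    if apply_parent_rule:
        parent = _parent_alleles(sites["gt_parent_sterile"])
        fixed_allele = np.where(g_s == ALT_FIXED, 1, np.where(g_s == REF_FIXED, 0, -1))
        r4 = np.array(
            [
                fa >= 0 and len(al) > 0 and fa not in al
                for fa, al in zip(fixed_allele, parent)
            ]
        )
        removed_by[r4 & (removed_by == "")] = "not_from_parent"

    keep = removed_by == ""
    for rule in RULES:
        report.removed_per_rule[rule] = int(np.sum(removed_by == rule))
    out = sites.loc[keep].copy()
    report.output_count = len(out)
    return out, report
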