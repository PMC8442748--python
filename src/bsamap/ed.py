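"""Euclidean-distance (ED) association statistic for pooled sequencing.

At a biallelic site the two bulks are summarised by their allele-frequency
vectors (p, 1-p) and (q, 1-q); the ED statistic is the Euclidean distance
between them, sqrt((p-q)^2 + ((1-p)-(1-q))^2) = sqrt(2)*|p-q|, ranging from
0 (identical pools) to sqrt(2) (fixed for opposite alleles). Raising the
distance to a power (default 5) suppresses background noise before window
fitting; the fitted track is thresholded at median + 3*SD of all fitted
values, the rule the study applied.
"""

from __future__ import annotations


import numpy as np
import pandas as pd

from .snp_index import snp_index_table

__all__ = ["ed_statistic", "ed_power", "ed_table", "median_3sd_threshold"]


def ed_statistic(p: float | np.ndarray, q: float | np.ndarray):
    """Euclidean distance between the two pools' allele-frequency vectors.

    ``p`` and ``q`` are the sterile-parent-allele frequencies in the sterile
    and fertile bulks; the two-component form is evaluated literally (its
    sqrt(2)*|p-q| closed form is checked against it in the tests). NaN inputs
    (zero-depth pools) propagate to NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = np.sqrt((p - q) ** 2 + ((1.0 - p) - (1.0 - q)) ** 2)
    return float(d) if d.ndim == 0 else d


def ed_power(ed, k: int = 5):
    """ed**k; k >= 1 (k = 1 disables the noise-suppression transform)."""
    if k < 1:
        raise ValueError(f"ED power must be >= 1, got {k}")
    out = np.asarray(ed, dtype=float) ** k
    return float(out) if out.ndim == 0 else out


def ed_table(sites: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Per-site ED and powered ED columns for a four-role site table."""
    out = snp_index_table(sites)
    out["ed"] = ed_statistic(out["index_sterile"].to_numpy(), out["index_fertile"].to_numpy())
    out["ed_pow"] = ed_power(out["ed"].to_numpy(), k)
    return out


def median_3sd_threshold(fitted_values) -> float:
    """median + 3 * sample SD (n-1 denominator) of all non-missing fitted values."""
    values = np.asarray(fitted_values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("need at least 2 non-missing fitted values")
    return float(np.median(values) + 3.0 * np.std(values, ddof=1))
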