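"""SNP-index / delta-SNP-index association scan.

The SNP index of a pool at a biallelic site is the fraction of its reads
carrying the sterile-parent allele; the delta-SNP index is the sterile-bulk
index minus the fertile-bulk index. Near a recessive causal locus the sterile
bulk is fixed for the sterile-parent allele (index 1) while the fertile bulk
mixes AA:Aa = 1:2 (index 1/3), so the expected delta peaks at 2/3 ~ 0.667 —
the theoretical significance threshold for this design.

Raw per-site values are smoothed with a physical sliding-window mean
(default 1 Mb window advanced by 10 kb; windows holding fewer than
``min_sites`` sites are flagged missing). Candidate regions are maximal runs
of consecutive non-missing windows whose fitted value strictly exceeds the
chosen threshold; the threshold is either the theoretical delta, a
genome-wide percentile of the fitted values (the study used the 99th, later
relaxing the cutoff to a fixed 0.56), or a user-fixed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mendel import CrossModel, expected_bulk_freq

__all__ = [
    "ScanTrack",
    "CandidateRegion",
    "snp_index",
    "snp_index_table",
    "theoretical_delta",
    "fit_track",
    "fit_tracks",
    "percentile_threshold",
    "extract_regions",
    "top_peak_region",
]


class OrientationError(ValueError):
    """Parental genotypes do not define a sterile-parent allele at a site."""


@dataclass
class ScanTrack:
    """Fitted statistic along one chromosome plus the raw sites beneath it."""

    chrom: str
    centers: np.ndarray  # window centers, bp, strictly increasing
    fitted: np.ndarray  # NaN where the window holds < min_sites sites
    n_sites: np.ndarray  # sites per window
    positions: np.ndarray  # raw site positions (sorted)
    raw: np.ndarray  # raw per-site statistic values
    window_bp: int
    step_bp: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "center": self.centers,
                "fitted": self.fitted,
                "n_sites": self.n_sites,
            }
        )


@dataclass
class CandidateRegion:
    """Maximal above-threshold interval; 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    peak_value: float
    peak_pos: int
    n_sites: int


def _orientation(gt_sterile: str, gt_fertile: str) -> int:
    """+1 if ALT is the sterile-parent allele, -1 if REF is; else error.

    Requires both parents homozygous and different — the inbred-line
    assumption under which "the sterile-parent allele" is well defined.
    """
    try:
        s = {int(a) for a in gt_sterile.split("/")}
        f = {int(a) for a in gt_fertile.split("/")}
    except ValueError as exc:
        raise OrientationError(f"uncalled parent genotype: {gt_sterile}/{gt_fertile}") from exc
    if len(s) != 1 or len(f) != 1 or s == f:
        raise OrientationError(
            f"parents must be homozygous and different, got {gt_sterile} vs {gt_fertile}"
        )
    return 1 if s == {1} else -1


def snp_index(ref_depth: int, alt_depth: int, alt_is_sterile_allele: bool = True) -> float:
    """Fraction of the pool's reads carrying the sterile-parent allele.

    Returns NaN at zero total depth (the site is excluded from fitting).
    """
    total = ref_depth + alt_depth
    if total == 0:
        return math.nan
    f = alt_depth / total
    return f if alt_is_sterile_allele else 1.0 - f


def snp_index_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site SNP indices and delta for the whole dataset.

    Adds ``index_sterile``, ``index_fertile`` and ``delta`` columns; sites
    where the parents fail the homozygous-and-different requirement raise an
    :class:`OrientationError` (filter rule R3/R4 input data should already
    satisfy it for simulated parents).
    """
    orient = np.array(
        [
            _orientation(s, f)
            for s, f in zip(sites["gt_parent_sterile"], sites["gt_parent_fertile"])
        ]
    )
    out = sites.copy()
    for bulk in ("sterile", "fertile"):
        ref = sites[f"ad_ref_bulk_{bulk}"].to_numpy(dtype=float)
        alt = sites[f"ad_alt_bulk_{bulk}"].to_numpy(dtype=float)
        total = ref + alt
        with np.errstate(invalid="ignore", divide="ignore"):
            f_alt = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
        out[f"index_{bulk}"] = np.where(orient == 1, f_alt, 1.0 - f_alt)
    out["delta"] = out["index_sterile"] - out["index_fertile"]
    return out


def theoretical_delta(cross: CrossModel | None = None) -> float:
    """Expected delta-SNP index at the causal locus at infinite depth.

    For the default F2 recessive design: 1 - 1/3 = 2/3 (0.667 to three
    decimals), the theoretical correlation threshold of the scan.
    """
    cross = cross or CrossModel()
    return expected_bulk_freq(cross, "recessive") - expected_bulk_freq(cross, "dominant")


def fit_track(
    positions: Sequence[int] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    chrom: str = "",
    window_bp: int = 1_000_000,
    step_bp: int = 10_000,
    min_sites: int = 3,
) -> ScanTrack:
    """Sliding-window mean of per-site values along one chromosome.

    Window centers run from the first to the last covered position in steps
    of ``step_bp``; each window is the half-open interval
    [center - window/2, center + window/2). NaN-valued sites (e.g. zero
    depth) are ignored; windows with fewer than ``min_sites`` usable sites
    are set to NaN.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if positions.size == 0:
        return ScanTrack(chrom, np.array([]), np.array([]), np.array([], dtype=int),
                         positions, values, window_bp, step_bp)
    order = np.argsort(positions, kind="stable")
    positions, values = positions[order], values[order]
    ok = ~np.isnan(values)
    pos_ok, val_ok = positions[ok], values[ok]

    centers = np.arange(positions[0], positions[-1] + 1, step_bp, dtype=np.int64)
    half = window_bp / 2.0
    lo = np.searchsorted(pos_ok, np.ceil(centers - half), side="left")
    hi = np.searchsorted(pos_ok, np.ceil(centers + half), side="left")
    csum = np.concatenate(([0.0], np.cumsum(val_ok)))
    counts = hi - lo
    with np.errstate(invalid="ignore"):
        fitted = np.where(counts > 0, (csum[hi] - csum[lo]) / np.maximum(counts, 1), np.nan)
    fitted[counts < min_sites] = np.nan
    return ScanTrack(chrom, centers, fitted, counts, positions, values, window_bp, step_bp)


def fit_tracks(
    sites: pd.DataFrame,
    value_col: str,
    chrom_order: Sequence[str] | None = None,
    window_bp: int = 1_000_000,
    step_bp: int = 10_000,
    min_sites: int = 3,
) -> dict[str, ScanTrack]:
    """One fitted track per chromosome from a per-site value column."""
    if chrom_order is None:
        chrom_order = list(dict.fromkeys(sites["chrom"]))
    tracks = {}
    for chrom in chrom_order:
        sub = sites[sites["chrom"] == chrom]
        if sub.empty:
            continue
        tracks[chrom] = fit_track(
            sub["pos"].to_numpy(), sub[value_col].to_numpy(), chrom,
            window_bp, step_bp, min_sites,
        )
    return tracks


def percentile_threshold(tracks: dict[str, ScanTrack] | np.ndarray, q: float = 99.0) -> float:
    """q-th percentile (linear interpolation) of all non-missing fitted values."""
    if isinstance(tracks, dict):
        values = np.concatenate([t.fitted for t in tracks.values()]) if tracks else np.array([])
    else:
        values = np.asarray(tracks, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no non-missing fitted values to take a percentile of")
    return float(np.percentile(values, q, method="linear"))


def extract_regions(track: ScanTrack, threshold: float) -> list[CandidateRegion]:
    """Maximal runs of consecutive non-missing windows strictly above threshold.

    Missing (NaN) windows break runs. Region bounds are the outermost window
    boundaries of the run clipped to the positions of covered sites; the peak
    is the highest fitted window, its position the window center.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    above = np.zeros(track.fitted.shape, dtype=bool)
    ok = ~np.isnan(track.fitted)
    above[ok] = track.fitted[ok] > threshold
    regions: list[CandidateRegion] = []
    i, n = 0, above.size
    half = track.window_bp / 2.0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        left = track.centers[i] - half
        right = track.centers[j] + half  # run spans [left, right)
        in_span = (track.positions >= left) & (track.positions < right)
        span_pos = track.positions[in_span]
        if span_pos.size:
            run = track.fitted[i : j + 1]
            k = int(np.nanargmax(run))
            regions.append(
                CandidateRegion(
                    chrom=track.chrom,
                    start=int(span_pos[0]),
                    end=int(span_pos[-1]),
                    peak_value=float(run[k]),
                    peak_pos=int(track.centers[i + k]),
                    n_sites=int(span_pos.size),
                )
            )
        i = j + 1
    return regions


def top_peak_region(regions: Sequence[CandidateRegion]) -> CandidateRegion | None:
    """The region with the highest fitted peak, or None."""
    return max(regions, key=lambda r: r.peak_value, default=None)


def top_peak_chrom(tracks: dict[str, ScanTrack]) -> str | None:
    """Chromosome carrying the genome-wide maximum fitted value (None if
    every window is missing); threshold-independent notion of the top peak."""
    best_chrom, best = None, -np.inf
    for chrom, t in tracks.items():
        if np.any(~np.isnan(t.fitted)):
            m = np.nanmax(t.fitted)
            if m > best:
                best_chrom, best = chrom, m
    return best_chrom
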