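"""End-to-end scan driver: filter -> per-site statistic -> fit -> threshold -> regions.

This is the composition layer the command line, the analysis drivers and the
acceptance checks all share, so a "scan" means the same thing everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ed as ed_mod
from . import filtering, snp_index
from .mendel import CrossModel

__all__ = ["ScanResult", "run_scan", "fitted_at", "resolve_threshold"]


@dataclass
class ScanResult:
    stat: str
    sites: pd.DataFrame  # per-site values after filtering
    tracks: dict[str, snp_index.ScanTrack]
    threshold: float
    threshold_rule: str
    regions: list[snp_index.CandidateRegion]
    filter_report: filtering.FilterReport | None

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "peak_value": r.peak_value,
                    "peak_pos": r.peak_pos,
                    "n_sites": r.n_sites,
                }
                for r in self.regions
            ]
        )


def resolve_threshold(
    rule: str,
    tracks: dict[str, snp_index.ScanTrack],
    cross: CrossModel | None = None,
) -> float:
    """Threshold rules: 'theoretical', 'percentile:<q>', 'median3sd', 'fixed:<x>'."""
    if rule == "theoretical":
        return snp_index.theoretical_delta(cross)
    if rule == "median3sd":
        fitted = np.concatenate([t.fitted for t in tracks.values()])
        return ed_mod.median_3sd_threshold(fitted)
    if rule.startswith("percentile:"):
        return snp_index.percentile_threshold(tracks, float(rule.split(":", 1)[1]))
    if rule.startswith("fixed:"):
        return float(rule.split(":", 1)[1])
    raise ValueError(f"unknown threshold rule: {rule!r}")


def run_scan(
    sites: pd.DataFrame,
    stat: str = "snpindex",
    threshold: str | None = None,
    window_bp: int = 1_000_000,
    step_bp: int = 10_000,
    min_sites: int = 3,
    ed_k: int = 5,
    apply_filter: bool = True,
    min_support: int = 4,
    chrom_order=None,
    cross: CrossModel | None = None,
) -> ScanResult:
    """Run one association scan over a four-role site table.

    ``stat`` is ``"snpindex"`` (fits the delta-SNP index; default threshold
    rule "theoretical") or ``"ed"`` (fits powered ED; default rule
    "median3sd").
    """
    report = None
    if apply_filter:
        sites, report = filtering.filter_variants(sites, min_support=min_support)
    if stat == "snpindex":
        table = snp_index.snp_index_table(sites)
        value_col = "delta"
        rule = threshold or "theoretical"
    elif stat == "ed":
        table = ed_mod.ed_table(sites, k=ed_k)
        value_col = "ed_pow"
        rule = threshold or "median3sd"
    else:
        raise ValueError(f"unknown statistic: {stat!r}")
    tracks = snp_index.fit_tracks(
        table, value_col, chrom_order=chrom_order,
        window_bp=window_bp, step_bp=step_bp, min_sites=min_sites,
    )
    thr = resolve_threshold(rule, tracks, cross)
    regions = [r for t in tracks.values() for r in snp_index.extract_regions(t, thr)]
    return ScanResult(stat, table, tracks, thr, rule, regions, report)


def fitted_at(tracks: dict[str, snp_index.ScanTrack], chrom: str, pos: int) -> float:
    """Fitted value at the locus: the nearest non-missing window center
    among windows containing the position; NaN if none covers it."""
    track = tracks.get(chrom)
    if track is None or track.centers.size == 0:
        return float("nan")
    half = track.window_bp / 2.0
    contains = (track.centers - half <= pos) & (pos < track.centers + half)
    usable = contains & ~np.isnan(track.fitted)
    if not usable.any():
        return float("nan")
    idx = np.flatnonzero(usable)
    best = idx[np.argmin(np.abs(track.centers[idx] - pos))]
    return float(track.fitted[best])
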