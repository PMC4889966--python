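"""Bin-count normalization: pseudocount + autosome mean, GC LOESS,
and reference-sample division.

The normalized quantity throughout is the per-bin ratio: bin count plus one
pseudocount, scaled so the mean over non-bad autosome bins is exactly 1.
GC bias is removed by dividing by a LOESS fit of ratio against bin GC
(fit on autosome bins, evaluated everywhere), and shared systematic noise
is cancelled by dividing by an independent reference sample processed the
same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .binning import BinCounts, BinScheme
from .genome import Genome

STAGES = ("mean_normalized", "gc_corrected", "reference_normalized")


@dataclass
class RatioTrack:
    """Per-bin ratio values with missing (NaN) markers on bad bins."""

    values: np.ndarray  # float, NaN = missing
    stage: str
    sample: str = ""
    reference: Optional[str] = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self, scheme: BinScheme) -> pd.DataFrame:
        df = scheme.table[["chrom", "start", "end"]].copy()
        df["value"] = self.values
        df["stage"] = self.stage
        return df


def _autosome_good(scheme: BinScheme, genome: Genome) -> np.ndarray:
    return scheme.autosome_bins(genome) & scheme.good()


def normalize_mean(counts: BinCounts, scheme: BinScheme, genome: Genome) -> RatioTrack:
    """(count + 1) scaled so the mean over non-bad autosome bins is 1.

    Bad bins are set missing (NaN).
    """
    if len(counts.counts) != len(scheme):
        raise ValueError("counts not aligned to bin scheme")
    auto = _autosome_good(scheme, genome)
    if not auto.any():
        raise ValueError("no usable autosome bins")
    v = counts.counts.astype(float) + 1.0
    m = v[auto].mean()
    values = v / m
    values[~scheme.good()] = np.nan
    return RatioTrack(values=values, stage="mean_normalized", sample=counts.sample)


def gc_correct(
    track: RatioTrack,
    scheme: BinScheme,
    genome: Genome,
    span: float = 0.3,
    min_autosome_bins: int = 50,
) -> RatioTrack:
    """Divide out a LOESS fit of ratio vs GC (locally linear, robust).

    The curve is fit on non-missing autosome bins and evaluated on every
    bin by interpolation on GC; the corrected autosome mean is re-scaled
    to 1.
    """
    gc = scheme.table["gc"].to_numpy(dtype=float)
    auto = _autosome_good(scheme, genome) & ~track.missing & ~np.isnan(gc)
    if auto.sum() < min_autosome_bins:
        raise ValueError(
            f"only {int(auto.sum())} autosome bins available; "
            f"need >= {min_autosome_bins} for a stable GC fit"
        )
    fit = lowess(track.values[auto], gc[auto], frac=span, it=2, return_sorted=True)
    fx, fy = fit[:, 0], fit[:, 1]
    # collapse duplicate GC knots for interpolation
    fx_u, idx = np.unique(fx, return_index=True)
    fy_u = fy[idx]
    pred = np.interp(gc, fx_u, fy_u)
    pred = np.where(pred <= 0, np.nan, pred)
    values = track.values / pred
    good = auto & ~np.isnan(values)
    values = values / np.nanmean(values[good])
    return RatioTrack(values=values, stage="gc_corrected", sample=track.sample)


def reference_normalize(
    sample: RatioTrack,
    reference: RatioTrack,
    scheme: BinScheme,
    genome: Genome,
    max_zero_fraction: float = 0.05,
) -> RatioTrack:
    """Divide the sample track by an independent reference sample's track.

    Bins where the reference is missing or <= 0 become missing; the
    autosome mean is re-set to 1.  Cancels bin-level systematic noise
    shared between samples run through the same pipeline.
    """
    if sample.values.shape != reference.values.shape:
        raise ValueError("sample and reference tracks have different lengths")
    ref = reference.values
    invalid = np.isnan(ref) | (ref <= 0)
    n_zero = int((~np.isnan(ref) & (ref <= 0)).sum())
    if n_zero > max_zero_fraction * ref.size:
        raise ValueError(
            f"{n_zero}/{ref.size} reference bins are zero; sequence the "
            "reference sample deeper"
        )
    values = np.where(invalid, np.nan, sample.values / np.where(invalid, 1.0, ref))
    auto = _autosome_good(scheme, genome) & ~np.isnan(values)
    if not auto.any():
        raise ValueError("no usable autosome bins after reference division")
    values = values / values[auto].mean()
    return RatioTrack(
        values=values,
        stage="reference_normalized",
        sample=sample.sample,
        reference=reference.sample,
    )


def subsample_counts(counts: BinCounts, target_total: int, seed: int) -> BinCounts:
    """Subsample a count vector to a target total (without replacement),
    used to match reference depth to the sample's."""
    total = counts.total
    if target_total >= total:
        return counts
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=target_total, replace=False)
    bin_of_map = np.repeat(np.arange(counts.counts.size), counts.counts)
    sub = np.bincount(bin_of_map[chosen], minlength=counts.counts.size)
    return BinCounts(counts=sub, sample=counts.sample, dropped=counts.dropped)
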