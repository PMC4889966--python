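"""Pipeline evaluation statistics: MAD, lag-1 autocorrelation, and the
X-vs-autosome signal-to-noise ratio used to compare mapping rules and
normalization choices on male samples."""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, Optional

import numpy as np

from .binning import BinScheme
from .genome import Genome
from .normalization import RatioTrack


@dataclass
class QCSummary:
    mad_autosome: float
    mad_X: float
    autocorrelation: float
    signal_to_noise: float
    maps_per_bin: float
    maps_per_read_pair: float
    sn_capped: bool = False

    def to_dict(self) -> Dict[str, float]:
        return asdict(self)


def mad(values: np.ndarray) -> float:
    """Median absolute deviation, unscaled: median(|x - median(x)|)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least two finite values for MAD")
    return float(np.median(np.abs(v - np.median(v))))


def autocorrelation(track: RatioTrack, scheme: BinScheme) -> float:
    """Lag-1 Pearson autocorrelation, computed within chromosomes and
    pooled by a length-weighted mean (weight = number of lag pairs)."""
    chrom_arr = scheme.table["chrom"].to_numpy()
    num = 0.0
    wsum = 0.0
    n_used = 0
    for chrom in scheme.chroms:
        v = track.values[chrom_arr == chrom]
        v = v[~np.isnan(v)]
        if v.size < 3:
            continue
        sd = v.std()
        if sd == 0:
            continue
        r = float(np.corrcoef(v[:-1], v[1:])[0, 1])
        w = v.size - 1
        num += w * r
        wsum += w
        n_used += v.size
    if n_used < 10:
        raise ValueError("need >= 10 non-missing bins for autocorrelation")
    if wsum == 0:
        raise ValueError("zero variance on every chromosome")
    return num / wsum


def signal_to_noise(
    track: RatioTrack,
    scheme: BinScheme,
    genome: Genome,
    cap: Optional[float] = None,
) -> float:
    """(median_autosome - median_X) / sqrt(MAD_auto^2 + MAD_X^2) on
    unsegmented ratios of a male sample.

    A noiseless track has zero MADs; the result is then +inf (or ``cap``
    when given) — callers should treat that as a flag, not a measurement.
    """
    sex = scheme.table["chrom"].map(genome.sex_class).to_numpy()
    vals = track.values
    auto = vals[(sex == "autosome") & ~np.isnan(vals)]
    x = vals[(sex == "X") & ~np.isnan(vals)]
    if x.size == 0:
        raise ValueError("no X-chromosome bins in scheme")
    if auto.size < 2 or x.size < 2:
        raise ValueError("too few bins for signal-to-noise")
    noise = math.sqrt(mad(auto) ** 2 + mad(x) ** 2)
    diff = float(np.median(auto) - np.median(x))
    if noise == 0:
        return cap if cap is not None else math.inf
    sn = diff / noise
    if cap is not None and sn > cap:
        return cap
    return sn


def qc_summary(
    track: RatioTrack,
    scheme: BinScheme,
    genome: Genome,
    total_maps: int = 0,
    total_pairs: int = 0,
) -> QCSummary:
    sex = scheme.table["chrom"].map(genome.sex_class).to_numpy()
    vals = track.values
    auto = vals[(sex == "autosome") & ~np.isnan(vals)]
    xv = vals[(sex == "X") & ~np.isnan(vals)]
    sn = signal_to_noise(track, scheme, genome) if xv.size >= 2 else math.nan
    return QCSummary(
        mad_autosome=mad(auto),
        mad_X=mad(xv) if xv.size >= 2 else math.nan,
        autocorrelation=autocorrelation(track, scheme),
        signal_to_noise=sn if math.isfinite(sn) else math.nan,
        maps_per_bin=total_maps / len(scheme) if len(scheme) else math.nan,
        maps_per_read_pair=total_maps / total_pairs if total_pairs else math.nan,
        sn_capped=not math.isfinite(sn),
    )
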