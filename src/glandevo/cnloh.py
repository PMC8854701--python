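"""Allelic-imbalance signal processing and a simplified CN-LOH caller.

The degree of allelic imbalance at a germline heterozygous site is the
absolute log odds ratio of variant-allele read counts between a gland and
its matched blood. After excluding known copy-number-altered regions, the
genome-wide mean is subtracted so the signal is centred at zero, and a
centred moving average over 100 heterozygous sites smooths it.

Segment calling here is deliberately simple tooling for synthetic signals:
maximal runs of consecutive sites whose moving average exceeds a threshold
become segments. The cellular fraction rho of an event is an input carried
through to timing, not estimated (full allele-specific copy-number fitting
is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 100
DEFAULT_THRESHOLD = 0.2
DEFAULT_MIN_SITES = 100


@dataclass
class HetSiteSignal:
    """Ordered heterozygous sites with |log odds ratio| imbalance values."""

    sites: pd.DataFrame  # columns: chrom, pos, abs_log_or; sorted within chrom

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "abs_log_or"}
        if not required.issubset(self.sites.columns):
            raise ValueError(f"signal table needs columns {sorted(required)}")
        if (self.sites["abs_log_or"] < 0).any():
            raise ValueError("|log OR| values must be >= 0")
        for _, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("sites must be position-sorted within chromosome")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class CnlohSegment:
    """A called copy-neutral LOH segment (major:minor = 2:0)."""

    chrom: str
    start: int
    end: int
    rho: float = 1.0
    copy_state: str = "2:0"
    n_sites: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("cellular fraction rho must be in (0, 1]")


def normalize_imbalance(
    signal: HetSiteSignal,
    excluded_regions: Sequence[tuple[str, int, int]] = (),
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Mean-centre the imbalance signal and smooth it.

    The mean is computed over sites *outside* ``excluded_regions``
    (half-open (chrom, start, end) intervals holding known copy-number
    alterations) and subtracted from every site. A centred moving average
    over ``window`` sites, truncated at chromosome ends, is added as the
    ``smoothed`` column.
    """
    df = signal.sites.copy()
    excluded = np.zeros(len(df), dtype=bool)
    for chrom, start, end in excluded_regions:
        excluded |= (
            (df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)
        ).to_numpy()
    if excluded.all():
        raise ValueError("all sites fall in excluded regions")
    mean = df.loc[~excluded, "abs_log_or"].mean()
    df["normalized"] = df["abs_log_or"] - mean
    df["excluded"] = excluded
    df["smoothed"] = (
        df.groupby("chrom", sort=False)["normalized"]
        .transform(lambda s: s.rolling(window, center=True, min_periods=1).mean())
    )
    return df


def call_segments(
    normalized: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    min_sites: int = DEFAULT_MIN_SITES,
    rho: float | dict[str, float] = 1.0,
) -> list[CnlohSegment]:
    """Call CN-LOH segments from the smoothed imbalance signal.

    A segment is a maximal run of >= ``min_sites`` consecutive sites on one
    chromosome whose smoothed value exceeds ``threshold``. ``rho`` is the
    cellular fraction to annotate (a scalar, or a mapping per chromosome);
    it comes from configuration or simulation truth.
    """
    segments: list[CnlohSegment] = []
    for chrom, grp in normalized.groupby("chrom", sort=False):
        above = (grp["smoothed"] > threshold).to_numpy()
        pos = grp["pos"].to_numpy()
        start_i = None
        for i, flag in enumerate(np.append(above, False)):
            if flag and start_i is None:
                start_i = i
            elif not flag and start_i is not None:
                if i - start_i >= min_sites:
                    seg_rho = rho.get(str(chrom), 1.0) if isinstance(rho, dict) else rho
                    segments.append(
                        CnlohSegment(
                            chrom=str(chrom),
                            start=int(pos[start_i]),
                            end=int(pos[i - 1]) + 1,
                            rho=seg_rho,
                            n_sites=i - start_i,
                        )
                    )
                start_i = None
    return segments
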