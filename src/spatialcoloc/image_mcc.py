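"""Manders colocalization coefficients for two-channel images.

M1 is the fraction of channel-A intensity lying where channel B is present;
M2 the symmetric quantity for channel B. Sums are intensity-weighted over
binary masks; a zero denominator yields a not-computable coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from spatialcoloc.errors import DegenerateHistogramError, ValidationError
from spatialcoloc.synthgen import ChannelImagePair


@dataclass(frozen=True)
class MccResult:
    m1: Optional[float]  # None when sum_a_total == 0
    m2: Optional[float]
    threshold_a: Optional[float]
    threshold_b: Optional[float]
    method: str
    sums: tuple[float, float, float, float]
    # (sum_a_total, sum_a_in_b, sum_b_total, sum_b_in_a)

    def __post_init__(self):
        for m in (self.m1, self.m2):
            if m is not None and not (0.0 <= m <= 1.0):
                raise ValidationError(f"coefficient {m} outside [0, 1]")


@dataclass(frozen=True)
class MccGroupSummary:
    """Per-group n / mean / sd of M1 and M2, groups in first-seen order."""

    groups: tuple[str, ...]
    n: tuple[int, ...]
    mean_m1: tuple[float, ...]
    sd_m1: tuple[Optional[float], ...]
    mean_m2: tuple[float, ...]
    sd_m2: tuple[Optional[float], ...]
    records: tuple[tuple[str, MccResult], ...]


def threshold_channel(
    channel: np.ndarray,
    method: str = "otsu",
    fixed_value: Optional[float] = None,
) -> tuple[np.ndarray, float]:
    """Binarize one channel; returns (mask, threshold), mask = channel > t.

    Otsu runs on a 256-bin histogram; a constant image has no foreground /
    background split and raises DegenerateHistogramError.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValidationError("empty image")
    if method == "fixed":
        if fixed_value is None:
            raise ValidationError("fixed threshold requires fixed_value")
        t = float(fixed_value)
    elif method == "otsu":
        if float(channel.max()) == float(channel.min()):
            raise DegenerateHistogramError(
                "degenerate histogram: constant image"
            )
        t = float(threshold_otsu(channel, nbins=256))
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    return channel > t, t


def manders(
    pair: ChannelImagePair,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    method: str = "fixed",
    threshold_a: Optional[float] = None,
    threshold_b: Optional[float] = None,
) -> MccResult:
    """Intensity-weighted Manders coefficients over the given masks.

    m1 = sum(A over mask_a & mask_b) / sum(A over mask_a); m2 symmetric.
    """
    a, b = pair.channel_a, pair.channel_b
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != a.shape or mask_b.shape != b.shape:
        raise ValidationError("masks must match channel shape")

    both = mask_a & mask_b
    sum_a_total = float(a[mask_a].sum())
    sum_a_in_b = float(a[both].sum())
    sum_b_total = float(b[mask_b].sum())
    sum_b_in_a = float(b[both].sum())

    m1 = sum_a_in_b / sum_a_total if sum_a_total > 0 else None
    m2 = sum_b_in_a / sum_b_total if sum_b_total > 0 else None
    return MccResult(
        m1=m1,
        m2=m2,
        threshold_a=threshold_a,
        threshold_b=threshold_b,
        method=method,
        sums=(sum_a_total, sum_a_in_b, sum_b_total, sum_b_in_a),
    )


def manders_auto(
    pair: ChannelImagePair,
    method: str = "otsu",
    fixed_a: Optional[float] = None,
    fixed_b: Optional[float] = None,
) -> MccResult:
    """Threshold both channels then compute the coefficients."""
    mask_a, ta = threshold_channel(pair.channel_a, method, fixed_a)
    mask_b, tb = threshold_channel(pair.channel_b, method, fixed_b)
    return manders(
        pair, mask_a, mask_b, method=method, threshold_a=ta, threshold_b=tb
    )


def coefficient_to_percent(m: float) -> float:
    """Render a coefficient in [0, 1] as a percentage with one decimal."""
    if not 0.0 <= m <= 1.0:
        raise ValidationError(f"coefficient {m} outside [0, 1]")
    return round(100.0 * m, 1)


def _group_stats(values: list[float]) -> tuple[float, Optional[float]]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return mean, sd


def mcc_timecourse(
    records: Sequence[tuple[str, MccResult]]
) -> MccGroupSummary:
    """Summarize coefficients per group (e.g. timepoint); no testing done.

    Not-computable coefficients are excluded from the mean/sd but still
    counted in the per-group n.
    """
    if len(records) == 0:
        raise ValidationError("no records to summarize")

    groups: list[str] = []
    members: dict[str, list[MccResult]] = {}
    for label, res in records:
        if label not in members:
            groups.append(label)
            members[label] = []
        members[label].append(res)

    n, mean1, sd1, mean2, sd2 = [], [], [], [], []
    for g in groups:
        rs = members[g]
        n.append(len(rs))
        v1 = [r.m1 for r in rs if r.m1 is not None]
        v2 = [r.m2 for r in rs if r.m2 is not None]
        if not v1 or not v2:
            raise ValidationError(
                f"group {g!r} has no computable coefficients"
            )
        m, s = _group_stats(v1)
        mean1.append(m)
        sd1.append(s)
        m, s = _group_stats(v2)
        mean2.append(m)
        sd2.append(s)

    return MccGroupSummary(
        groups=tuple(groups),
        n=tuple(n),
        mean_m1=tuple(mean1),
        sd_m1=tuple(sd1),
        mean_m2=tuple(mean2),
        sd_m2=tuple(sd2),
        records=tuple((g, r) for g, r in records),
    )
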