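"""Windowed protection score (WPS).

WPS at base ``p`` is the number of fragments fully spanning the ``k``-bp
window centred on ``p`` minus the number of fragments with at least one
endpoint inside that window. Nucleosome-protected positions collect spanning
fragments (positive WPS); linker and accessible DNA collects endpoints
(negative WPS). The even window is placed asymmetrically as
``W(p) = [p - k/2, p + k/2 - 1]``; a fragment ``[s, e)`` has endpoints ``s``
and ``e - 1`` (its last covered base).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError, ValidationError
from .io import FragmentSet, TargetRegion


@dataclass(frozen=True)
class WpsProfile:
    """Per-bp signed WPS over ``[region.start, region.end)``."""

    region: TargetRegion
    window_k: int
    values: np.ndarray

    def __post_init__(self):
        if len(self.values) != self.region.length:
            raise ValidationError("profile length must equal region length")


def compute_wps(frags: FragmentSet, region: TargetRegion,
                window_k: int = 120) -> WpsProfile:
    """WPS profile over ``region`` using all fragments from the sample.

    Fragments are deliberately *not* clipped to the region, so values near
    the region edges are identical to what a genome-wide computation would
    give. ``window_k`` must be even (default 120 bp, the long-fragment
    protection window).
    """
    if window_k % 2 != 0 or window_k <= 0:
        raise UsageError(f"window_k must be a positive even integer, got {window_k}")
    h = window_k // 2
    L = region.length
    diff = np.zeros(L + 1, dtype=np.int64)
    starts, ends = frags.overlapping(region.chrom, region.start, region.end,
                                     pad=window_k)

    def add_interval(lo: np.ndarray, hi: np.ndarray, weight: int):
        # inclusive genomic interval [lo, hi] -> region-clipped diff update
        lo = np.clip(lo - region.start, 0, L)
        hi = np.clip(hi - region.start + 1, 0, L)
        keep = hi > lo
        np.add.at(diff, lo[keep], weight)
        np.add.at(diff, hi[keep], -weight)

    if len(starts):
        lengths = ends - starts
        # spanning: s <= p - h and e - 1 >= p + h - 1  <=>  p in [s + h, e - h]
        span = lengths >= window_k
        add_interval(starts[span] + h, ends[span] - h, +1)
        # endpoint: s in W(p) -> p in [s - h + 1, s + h]; e - 1 in W(p) ->
        # p in [e - h, e - 1 + h]; count each fragment once on the union
        a1, b1 = starts - h + 1, starts + h
        a2, b2 = ends - h, ends - 1 + h
        merged = a2 <= b1 + 1  # short fragments: the two windows touch
        add_interval(a1[merged], b2[merged], -1)
        add_interval(a1[~merged], b1[~merged], -1)
        add_interval(a2[~merged], b2[~merged], -1)

    values = np.cumsum(diff[:-1])
    return WpsProfile(region, window_k, values)


def write_wps_bedgraph(profiles: list[WpsProfile], path) -> None:
    """bedGraph export of per-bp WPS, run-length collapsed."""
    with open(path, "w") as fh:
        for prof in profiles:
            r = prof.region
            values = prof.values
            run_start = 0
            for b in range(1, len(values) + 1):
                if b == len(values) or values[b] != values[run_start]:
                    fh.write(f"{r.chrom}\t{r.start + run_start}\t{r.start + b}"
                             f"\t{int(values[run_start])}\n")
                    run_start = b


def region_wps_feature(profile: WpsProfile,
                       window: TargetRegion | None = None) -> float:
    """Arithmetic mean WPS over ``window`` (default: the whole region)."""
    if window is None:
        return float(profile.values.mean())
    r = profile.region
    if window.start < r.start or window.end > r.end:
        raise UsageError(f"window [{window.start}, {window.end}) outside "
                         f"profile region [{r.start}, {r.end})")
    return float(profile.values[window.start - r.start:window.end - r.start].mean())
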