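"""Nucleosome occupancy, peak calling, fuzziness, and fragmentomics diagnostics.

Occupancy is the per-bp pileup of nucleosome-length cfDNA fragments: the raw
value at base ``b`` is the number of kept fragments covering ``b``. Because
cfDNA is protected from endonuclease digestion where nucleosomes sit, the
pileup of 80–200 bp fragments reads out population-average nucleosome
occupancy; per-sample depth differences are removed by scaling each sample so
its panel-wide mean occupancy is 1.

Nucleosome *fuzziness* measures positional heterogeneity: after calling a
nucleosome peak, it is the population standard deviation (bp) of the
midpoints of the fragments supporting that peak. Identically positioned
nucleosomes across the contributing cells give fuzziness 0; loosely
positioned ones give large values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import UsageError, ValidationError
from .io import FragmentSet, TargetRegion

NUCLEOSOME_BP = 147
HALF_NUC = NUCLEOSOME_BP // 2  # 73


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-bp occupancy over ``[region.start, region.end)``."""

    region: TargetRegion
    values: np.ndarray
    norm_factor: float = 1.0

    def __post_init__(self):
        if len(self.values) != self.region.length:
            raise ValidationError("profile length must equal region length")

    def slice(self, start: int, end: int) -> np.ndarray:
        """Values over ``[start, end)`` (must lie within the profile region)."""
        r = self.region
        if start < r.start or end > r.end or end <= start:
            raise UsageError(f"[{start}, {end}) not inside profile region "
                             f"[{r.start}, {r.end})")
        return self.values[start - r.start:end - r.start]


@dataclass(frozen=True)
class NucleosomePeak:
    """A called nucleosome: summit, height, 147-bp span and fuzziness."""

    chrom: str
    summit: int
    summit_occ: float
    fuzziness: float = float("nan")

    @property
    def span(self) -> tuple[int, int]:
        return self.summit - HALF_NUC, self.summit + HALF_NUC + 1


def compute_occupancy(frags: FragmentSet, region: TargetRegion,
                      norm_factor: float = 1.0) -> OccupancyProfile:
    """Per-bp fragment pileup over ``region``, scaled by ``norm_factor``.

    Fragments overlapping the region by >= 1 bp contribute; coverage is
    clipped to the region bounds. Pass the factor from
    :func:`panel_norm_factor` to put samples on a common depth scale.
    """
    if region.length <= 0:
        raise UsageError(f"region {region.name} has zero length")
    starts, ends = frags.overlapping(region.chrom, region.start, region.end)
    L = region.length
    diff = np.zeros(L + 1, dtype=np.float64)
    s = np.clip(starts - region.start, 0, L)
    e = np.clip(ends - region.start, 0, L)
    np.add.at(diff, s, 1.0)
    np.add.at(diff, e, -1.0)
    values = np.cumsum(diff[:-1]) * norm_factor
    return OccupancyProfile(region, values, norm_factor)


def panel_norm_factor(frags: FragmentSet, regions: list[TargetRegion]) -> float:
    """Factor scaling a sample's panel-wide mean occupancy to 1.

    The panel mean is total fragment-overlap mass divided by total panel bp;
    1.0 is returned for a sample with no panel coverage.
    """
    total_bp = 0
    mass = 0.0
    for region in regions:
        starts, ends = frags.overlapping(region.chrom, region.start, region.end)
        ov = (np.minimum(ends, region.end) - np.maximum(starts, region.start))
        mass += float(ov[ov > 0].sum())
        total_bp += region.length
    if total_bp == 0 or mass == 0.0:
        return 1.0
    return total_bp / mass


def smooth_profile(values: np.ndarray, window: int = HALF_NUC) -> np.ndarray:
    """Centred moving average; nearest-edge padding keeps summits in place."""
    if window <= 1:
        return values.astype(float)
    return uniform_filter1d(values.astype(float), size=window, mode="nearest")


def _plateau_maxima(x: np.ndarray) -> list[int]:
    """Leftmost indices of strict local maxima, treating plateaus as one."""
    n = len(x)
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        left_ok = i == 0 or x[i - 1] < x[i]
        right_ok = j == n - 1 or x[j + 1] < x[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            maxima.append(i)
        i = j + 1
    return maxima


def call_peaks(profile: OccupancyProfile, min_summit_occ: float = 0.5,
               min_spacing: int = NUCLEOSOME_BP,
               smooth_window: int = HALF_NUC) -> list[NucleosomePeak]:
    """Call nucleosome peaks as local maxima of the smoothed profile.

    Maxima below ``min_summit_occ`` are discarded; maxima closer than
    ``min_spacing`` bp are merged keeping the higher summit (ties keep the
    leftmost). Deterministic and invariant to fragment input order.
    """
    sm = smooth_profile(profile.values, smooth_window)
    cands = [i for i in _plateau_maxima(sm) if sm[i] >= min_summit_occ]
    # greedy merge, tallest first (leftmost on ties)
    accepted: list[int] = []
    for i in sorted(cands, key=lambda i: (-sm[i], i)):
        if all(abs(i - a) >= min_spacing for a in accepted):
            accepted.append(i)
    accepted.sort()
    return [NucleosomePeak(profile.region.chrom, profile.region.start + i,
                           float(sm[i])) for i in accepted]


def peak_fuzziness(frags: FragmentSet, peak: NucleosomePeak) -> float:
    """Population SD (bp) of supporting fragment midpoints.

    Supporting fragments are those whose midpoint ``floor((start+end-1)/2)``
    lies within the peak's 147-bp span; NaN with fewer than 2 supporters.
    """
    lo, hi = peak.span
    starts, ends = frags.overlapping(peak.chrom, lo, hi, pad=200)
    mids = (starts + ends - 1) // 2
    mids = mids[(mids >= lo) & (mids < hi)]
    if len(mids) < 2:
        return float("nan")
    return float(np.std(mids.astype(float), ddof=0))


def call_nucleosomes(frags: FragmentSet, profile: OccupancyProfile,
                     min_summit_occ: float = 0.5,
                     min_spacing: int = NUCLEOSOME_BP,
                     smooth_window: int = HALF_NUC) -> list[NucleosomePeak]:
    """Call peaks on ``profile`` and attach per-peak fuzziness."""
    peaks = call_peaks(profile, min_summit_occ, min_spacing, smooth_window)
    return [dataclasses.replace(p, fuzziness=peak_fuzziness(frags, p))
            for p in peaks]


def region_occupancy_feature(profile: OccupancyProfile,
                             window: TargetRegion | None = None) -> float:
    """Mean per-bp occupancy over ``window`` (default: the whole region)."""
    if window is None:
        return float(profile.values.mean())
    return float(profile.slice(window.start, window.end).mean())


def region_fuzziness_feature(peaks: list[NucleosomePeak],
                             window: TargetRegion) -> float:
    """Mean fuzziness of nucleosomes whose summit lies inside ``window``.

    NaN when no peak falls inside or every qualifying fuzziness is missing.
    """
    vals = [p.fuzziness for p in peaks
            if window.start <= p.summit < window.end
            and p.chrom == window.chrom and not np.isnan(p.fuzziness)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def write_occupancy_bedgraph(profiles: list[OccupancyProfile], path) -> None:
    """bedGraph export: one line per run of constant per-bp occupancy."""
    with open(path, "w") as fh:
        for prof in profiles:
            r = prof.region
            values = prof.values
            run_start = 0
            for b in range(1, len(values) + 1):
                if b == len(values) or values[b] != values[run_start]:
                    fh.write(f"{r.chrom}\t{r.start + run_start}\t{r.start + b}"
                             f"\t{values[run_start]:.6g}\n")
                    run_start = b


def write_peaks_bed(peaks: list[NucleosomePeak], path) -> None:
    """Peaks as BED6+2: span, name, height, strand '.', summit, fuzziness."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            lo, hi = p.span
            fuzz = "." if np.isnan(p.fuzziness) else f"{p.fuzziness:.4g}"
            fh.write(f"{p.chrom}\t{lo}\t{hi}\tnuc{i}\t{p.summit_occ:.4g}\t."
                     f"\t{p.summit}\t{fuzz}\n")


# ---------------------------------------------------------------------------
# fragmentomics diagnostics
# ---------------------------------------------------------------------------

def fragment_length_histogram(frags: FragmentSet) -> pd.Series:
    """Exact integer counts per fragment length, indexed by length (bp).

    Run on *unfiltered* fragments so the mono-nucleosome mode (~167 bp,
    nucleosome core + linker) is visible in context.
    """
    lengths = frags.lengths
    if len(lengths) == 0:
        return pd.Series(dtype=np.int64, name="count")
    counts = pd.Series(lengths).value_counts().sort_index()
    counts.name = "count"
    counts.index.name = "length"
    return counts


def modal_length(hist: pd.Series) -> int | None:
    """Length with the highest count (smallest length on ties)."""
    if len(hist) == 0:
        return None
    return int(hist.index[np.argmax(hist.to_numpy())])


def dinucleotide_profile(frags: FragmentSet, fasta_path, frag_len: int = 147,
                         flank: int = 50,
                         dinucs: tuple[str, ...] = ("AA", "AT", "TA", "TT"),
                         ) -> pd.DataFrame:
    """Per-offset fraction of a dinucleotide class across aligned fragments.

    Fragments of exactly ``frag_len`` bp are stacked, aligned at their start,
    extended by ``flank`` bp of genomic context on both sides, and the
    fraction of fragments whose dinucleotide at each offset belongs to
    ``dinucs`` (default: the A/T class) is reported. Nucleosome-wrapped DNA
    shows an ~10-bp periodicity in this profile, the rotational positioning
    signature of the helical repeat.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(fasta_path))
    width = frag_len + 2 * flank
    counts = np.zeros(width - 1, dtype=np.int64)
    n_used = 0
    dinuc_set = {d.upper() for d in dinucs}
    for frag in frags:
        if frag.length != frag_len:
            continue
        if frag.chrom not in genome:
            raise UsageError(f"contig {frag.chrom!r} missing from FASTA")
        contig = genome[frag.chrom]
        lo = frag.start - flank
        hi = frag.end + flank
        if lo < 0 or hi > len(contig):
            continue
        seq = str(contig[lo:hi]).upper()
        n_used += 1
        for j in range(width - 1):
            if seq[j:j + 2] in dinuc_set:
                counts[j] += 1
    if n_used == 0:
        raise UsageError(f"no fragments of length {frag_len} with full flanks")
    return pd.DataFrame({
        "offset": np.arange(-flank, frag_len + flank - 1),
        "fraction": counts / n_used,
    })


def dominant_period(profile: pd.DataFrame, min_period: float = 5.0,
                    max_period: float = 20.0,
                    detrend_window: int = 21) -> tuple[float, float]:
    """Dominant period (bp) of the detrended dinucleotide profile.

    The profile is detrended with a centred moving average, then the discrete
    spectrum is scanned over periods in ``[min_period, max_period]``. Returns
    ``(period, prominence)`` where prominence is the peak power divided by
    the median power in the band — near 1 means no periodicity above the
    noise floor.
    """
    y = profile["fraction"].to_numpy(dtype=float)
    y = y - uniform_filter1d(y, size=detrend_window, mode="nearest")
    power = np.abs(np.fft.rfft(y)) ** 2
    freqs = np.fft.rfftfreq(len(y), d=1.0)
    band = (freqs > 0) & (1.0 / np.maximum(freqs, 1e-12) >= min_period) \
        & (1.0 / np.maximum(freqs, 1e-12) <= max_period)
    if not band.any():
        raise UsageError("profile too short for the requested period band")
    p_band = power[band]
    f_band = freqs[band]
    k = int(np.argmax(p_band))
    med = float(np.median(p_band))
    prominence = float(p_band[k] / med) if med > 0 else float("inf")
    return float(1.0 / f_band[k]), prominence
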