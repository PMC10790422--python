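"""Fragment- and region-level input handling.

Everything downstream of this module works in BED conventions: 0-based,
half-open intervals ``[start, end)``. One :class:`Fragment` is one sequenced
cfDNA molecule; paired-end inputs (BEDPE, BAM) are collapsed to the outer
span of the pair at read time. Strand is ignored throughout — none of the
derived signals (occupancy, fuzziness, WPS, methylation ratios) are
strand-aware.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParseError, UsageError, ValidationError

REGION_TYPES = ("cpg_marker", "tss", "pas")


class Fragment(NamedTuple):
    """One cfDNA molecule as a genomic interval with sample attribution."""

    chrom: str
    start: int
    end: int
    sample_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint of the covered bases: ``floor((start + end - 1) / 2)``."""
        return (self.start + self.end - 1) // 2


@dataclass(frozen=True)
class TargetRegion:
    """A panel region: a CpG-marker window or a TSS/PAS ± flank interval."""

    chrom: str
    start: int
    end: int
    name: str
    region_type: str = "cpg_marker"
    anchor: int | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"region {self.name}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.region_type not in REGION_TYPES:
            raise ValidationError(
                f"region {self.name}: unknown region_type {self.region_type!r}"
            )
        if self.anchor is not None and not (self.start <= self.anchor < self.end):
            raise ValidationError(
                f"region {self.name}: anchor {self.anchor} outside [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class FragmentSet:
    """A sorted collection of fragments from one sample.

    Backed by per-chromosome numpy arrays sorted by (start, end) so per-region
    queries are cheap; iteration yields :class:`Fragment` records.
    """

    def __init__(self, chroms: Sequence[str], starts: Sequence[int],
                 ends: Sequence[int], sample_id: str | None = None):
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if not (len(chroms) == len(starts) == len(ends)):
            raise ValidationError("chroms/starts/ends must have equal length")
        if np.any(ends <= starts):
            bad = int(np.argmax(ends <= starts))
            raise ValidationError(
                f"fragment {chroms[bad]}:{starts[bad]}-{ends[bad]}: end must exceed start"
            )
        order = np.lexsort((ends, starts, chroms.astype(str)))
        self._chroms = chroms[order]
        self._starts = starts[order]
        self._ends = ends[order]
        self.sample_id = sample_id
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in pd.unique(self._chroms):
            mask = self._chroms == chrom
            self._by_chrom[str(chrom)] = (self._starts[mask], self._ends[mask])
        self._max_len = int((self._ends - self._starts).max()) if len(starts) else 0

    @classmethod
    def from_fragments(cls, frags: Iterable[Fragment],
                       sample_id: str | None = None) -> "FragmentSet":
        frags = list(frags)
        sid = sample_id
        if sid is None and frags:
            sid = frags[0].sample_id
        return cls([f.chrom for f in frags], [f.start for f in frags],
                   [f.end for f in frags], sample_id=sid)

    def __len__(self) -> int:
        return len(self._starts)

    def __iter__(self) -> Iterator[Fragment]:
        for c, s, e in zip(self._chroms, self._starts, self._ends):
            yield Fragment(str(c), int(s), int(e), self.sample_id)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FragmentSet):
            return NotImplemented
        return (len(self) == len(other)
                and bool(np.all(self._chroms == other._chroms))
                and bool(np.all(self._starts == other._starts))
                and bool(np.all(self._ends == other._ends)))

    @property
    def lengths(self) -> np.ndarray:
        return self._ends - self._starts

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of all fragments on ``chrom``, sorted by start."""
        return self._by_chrom.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))

    def overlapping(self, chrom: str, start: int, end: int,
                    pad: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of fragments overlapping ``[start - pad, end + pad)``."""
        starts, ends = self.chrom_arrays(chrom)
        if len(starts) == 0:
            return starts, ends
        lo, hi = start - pad, end + pad
        i0 = np.searchsorted(starts, lo - self._max_len, side="left")
        i1 = np.searchsorted(starts, hi, side="left")
        s, e = starts[i0:i1], ends[i0:i1]
        keep = e > lo
        return s[keep], e[keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self._chroms.astype(str),
            "start": self._starts,
            "end": self._ends,
        })


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_int(token: str, what: str, path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"non-integer {what}: {token!r}", path, lineno) from None


def read_fragments(path, format: str = "bed",
                   sample_id: str | None = None) -> FragmentSet:
    """Read fragments from BED3, BEDPE (cols 1–6) or coordinate-sorted BAM.

    BEDPE and BAM records are collapsed to one fragment per read pair spanning
    the outermost coordinates. Output is sorted by (chrom, start, end).
    """
    if format == "bam":
        return _read_fragments_bam(path, sample_id)
    if format not in ("bed", "bedpe"):
        raise UsageError(f"unknown fragment format {format!r}")
    if not os.path.exists(path):
        raise DataError(f"fragment file not found: {path}")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if format == "bed":
                if len(cols) < 3:
                    raise ParseError("BED line needs >= 3 columns", path, lineno)
                chrom = cols[0]
                s = _parse_int(cols[1], "start", path, lineno)
                e = _parse_int(cols[2], "end", path, lineno)
            else:
                if len(cols) < 6:
                    raise ParseError("BEDPE line needs >= 6 columns", path, lineno)
                chrom = cols[0]
                if cols[3] != chrom:
                    raise ParseError(
                        f"read pair on different chromosomes ({chrom} vs {cols[3]})",
                        path, lineno)
                s1 = _parse_int(cols[1], "start1", path, lineno)
                e1 = _parse_int(cols[2], "end1", path, lineno)
                s2 = _parse_int(cols[4], "start2", path, lineno)
                e2 = _parse_int(cols[5], "end2", path, lineno)
                s, e = min(s1, s2), max(e1, e2)
            if e <= s:
                raise ParseError(f"end ({e}) <= start ({s})", path, lineno)
            chroms.append(chrom)
            starts.append(s)
            ends.append(e)
    return FragmentSet(chroms, starts, ends, sample_id=sample_id)


def _read_fragments_bam(path, sample_id: str | None) -> FragmentSet:
    import pysam  # deferred: BAM support is optional at runtime

    if not os.path.exists(path):
        raise DataError(f"fragment file not found: {path}")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with pysam.AlignmentFile(path, "rb") as bam:
        for read in bam:
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate or not read.is_proper_pair):
                continue
            # one fragment per pair: take the leftmost mate (positive tlen)
            if read.template_length <= 0:
                continue
            chroms.append(read.reference_name)
            starts.append(read.reference_start)
            ends.append(read.reference_start + read.template_length)
    return FragmentSet(chroms, starts, ends, sample_id=sample_id)


def write_fragments(frags: FragmentSet | Iterable[Fragment], path,
                    format: str = "bed") -> None:
    """Write fragments as BED3 or BEDPE (pair split at the fragment midpoint)."""
    if format not in ("bed", "bedpe"):
        raise UsageError(f"unknown fragment format {format!r}")
    with open(path, "w") as fh:
        for f in frags:
            if format == "bed":
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")
            else:
                mid = (f.start + f.end) // 2
                r1e = max(f.start + 1, mid)
                r2s = min(f.end - 1, mid)
                fh.write(f"{f.chrom}\t{f.start}\t{r1e}\t{f.chrom}\t{r2s}\t{f.end}\n")


def filter_fragments(frags: FragmentSet | Iterable[Fragment],
                     min_len: int = 80, max_len: int = 200):
    """Keep fragments with ``min_len <= length <= max_len`` (inclusive bounds).

    The inclusive [80, 200] bp default removes sub-nucleosomal debris and
    di-nucleosomal / genomic contamination while retaining the ~167 bp
    mono-nucleosome mode. Order is preserved; returns the same container kind
    it was given.
    """
    if min_len < 1:
        raise UsageError(f"min_len must be >= 1, got {min_len}")
    if max_len < min_len:
        raise UsageError(f"max_len ({max_len}) < min_len ({min_len})")
    if isinstance(frags, FragmentSet):
        keep = (frags.lengths >= min_len) & (frags.lengths <= max_len)
        return FragmentSet(frags._chroms[keep], frags._starts[keep],
                           frags._ends[keep], sample_id=frags.sample_id)
    return [f for f in frags if min_len <= f.length <= max_len]


def read_regions(path, default_type: str | None = None) -> list[TargetRegion]:
    """Read a target-region panel from BED4+ (name in col 4).

    Optional column 5 is the region type (``cpg_marker``/``tss``/``pas``) and
    column 6 the anchor coordinate for tss/pas regions. When the type column
    is absent, ``default_type`` applies to every row.
    """
    if not os.path.exists(path):
        raise DataError(f"region file not found: {path}")
    regions: list[TargetRegion] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError("region BED needs >= 4 columns", path, lineno)
            name = cols[3]
            if name in names:
                raise ValidationError(f"duplicate region name {name!r} at line {lineno}")
            names.add(name)
            rtype = cols[4] if len(cols) > 4 and cols[4] else default_type
            if rtype is None:
                rtype = "cpg_marker"
            anchor = None
            if len(cols) > 5 and cols[5] not in ("", "."):
                anchor = _parse_int(cols[5], "anchor", path, lineno)
            elif rtype in ("tss", "pas"):
                # anchor-centred panel convention: default to the midpoint
                anchor = (_parse_int(cols[1], "start", path, lineno)
                          + _parse_int(cols[2], "end", path, lineno)) // 2
            regions.append(TargetRegion(
                chrom=cols[0],
                start=_parse_int(cols[1], "start", path, lineno),
                end=_parse_int(cols[2], "end", path, lineno),
                name=name, region_type=rtype, anchor=anchor))
    return regions


def write_regions(regions: Iterable[TargetRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            anchor = "." if r.anchor is None else str(r.anchor)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.region_type}\t{anchor}\n")


def make_windows(region: TargetRegion, window: int = 1000,
                 step: int = 10) -> list[TargetRegion]:
    """Tile a region with sliding windows of ``window`` bp every ``step`` bp.

    Windows start at ``region.start`` and advance by ``step`` while they still
    fit inside the region; window ``k`` is named ``"<name>:win<k>"``.
    """
    if step < 1:
        raise UsageError(f"step must be >= 1, got {step}")
    if window > region.length:
        raise UsageError(
            f"window ({window}) exceeds region {region.name} length ({region.length})")
    out = []
    for k, s in enumerate(range(region.start, region.end - window + 1, step)):
        anchor = region.anchor if (region.anchor is not None
                                   and s <= region.anchor < s + window) else None
        out.append(TargetRegion(region.chrom, s, s + window,
                                f"{region.name}:win{k}", region.region_type, anchor))
    return out


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SHEET_REQUIRED = ("sample_id", "label", "cohort")
SHEET_PATHS = ("fragments", "methylation", "lambda")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the cohort sample sheet (TSV with header).

    Required columns: sample_id, label, cohort. Optional path columns:
    fragments, methylation, lambda. Relative paths are resolved against the
    sheet's directory.
    """
    if not os.path.exists(path):
        raise DataError(f"sample sheet not found: {path}")
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_REQUIRED if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sorted(sheet.loc[sheet["sample_id"].duplicated(), "sample_id"])
        raise ValidationError(f"duplicate sample_ids in sheet: {dups}")
    if sheet["label"].nunique() < 2:
        raise ValidationError("sample sheet must contain >= 2 distinct labels")
    base = os.path.dirname(os.path.abspath(path))
    for col in SHEET_PATHS:
        if col in sheet.columns:
            sheet[col] = sheet[col].map(
                lambda p: p if (pd.isna(p) or os.path.isabs(p))
                else os.path.join(base, p))
    return sheet.set_index("sample_id", drop=False)
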