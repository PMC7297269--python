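"""Per-base score tracks and interval annotation tracks.

Score tracks (conservation in the PhastCons / fitCons role) are read from
bedGraph text; interval tracks (m6A-biology overlaps, miRNA targets) from
BED6.  bedGraph and BED are 0-based half-open on disk; queries here take
genomic 1-based positions to match the annotation convention used
throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .fold import nussinov_fold

log = logging.getLogger(__name__)


class ScoreTrack:
    """Piecewise-constant per-base score track backed by bedGraph intervals."""

    def __init__(self, name: str = "score"):
        self.name = name
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_bedgraph(cls, path, name: str | None = None) -> "ScoreTrack":
        track = cls(name or str(path))
        raw: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"{path}:{ln}: expected 4 bedGraph columns")
                chrom, start, end, value = parts[:4]
                raw.setdefault(chrom, []).append(
                    (int(start), int(end), float(value))
                )
        for chrom, ivs in raw.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs])
            ends = np.array([e for _, e, _ in ivs])
            vals = np.array([v for _, _, v in ivs])
            track._chrom[chrom] = (starts, ends, vals)
        return track

    @classmethod
    def from_intervals(cls, intervals, name: str = "score") -> "ScoreTrack":
        """Build from an iterable of (chrom, start0, end0, value)."""
        track = cls(name)
        raw: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in intervals:
            raw.setdefault(chrom, []).append((int(s), int(e), float(v)))
        for chrom, ivs in raw.items():
            ivs.sort()
            track._chrom[chrom] = (
                np.array([s for s, _, _ in ivs]),
                np.array([e for _, e, _ in ivs]),
                np.array([v for _, _, v in ivs]),
            )
        return track

    def values(self, chrom: str, positions) -> np.ndarray:
        """Scores at genomic 1-based positions; NaN where undefined."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, np.nan)
        if chrom not in self._chrom:
            return out
        starts, ends, vals = self._chrom[chrom]
        zero = positions - 1  # 0-based
        idx = np.searchsorted(starts, zero, side="right") - 1
        ok = (idx >= 0) & (zero < ends[np.clip(idx, 0, len(ends) - 1)])
        out[ok] = vals[idx[ok]]
        return out

    def value(self, chrom: str, position: int) -> float:
        return float(self.values(chrom, [position])[0])


@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    name: str = "."
    score: float = 0.0
    strand: str = "."


class IntervalTrack:
    """Strand-aware BED6 interval set with point-overlap queries."""

    def __init__(self, name: str = "intervals"):
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        self.n_intervals = 0

    @classmethod
    def from_bed(cls, path, name: str | None = None) -> "IntervalTrack":
        track = cls(name or str(path))
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: expected >=3 BED columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name_ = parts[3] if len(parts) > 3 else "."
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
                strand = parts[5] if len(parts) > 5 else "."
                track.add(BedInterval(chrom, start, end, name_, score, strand))
        return track

    @classmethod
    def from_intervals(cls, intervals, name: str = "intervals") -> "IntervalTrack":
        track = cls(name)
        for iv in intervals:
            track.add(iv if isinstance(iv, BedInterval) else BedInterval(*iv))
        return track

    def add(self, interval: BedInterval) -> None:
        if interval.end <= interval.start:
            raise ValueError(f"empty interval {interval}")
        self._trees.setdefault(interval.chrom, IntervalTree()).addi(
            interval.start, interval.end, interval
        )
        self.n_intervals += 1

    def overlaps(self, chrom: str, position: int, strand: str | None = None) -> bool:
        """Whether the genomic 1-based position lies in any interval."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        for hit in tree.at(position - 1):
            iv: BedInterval = hit.data
            if strand is None or iv.strand == "." or iv.strand == strand:
                return True
        return False

    def overlaps_range(self, chrom: str, start1: int, end1: int,
                       strand: str | None = None) -> bool:
        """Overlap with genomic 1-based inclusive range [start1, end1]."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        for hit in tree.overlap(start1 - 1, end1):
            iv: BedInterval = hit.data
            if strand is None or iv.strand == "." or iv.strand == strand:
                return True
        return False

    def intervals(self) -> list[BedInterval]:
        return [hit.data for tree in self._trees.values() for hit in tree]


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                f"{iv.score:g}\t{iv.strand}\n"
            )


def write_bedgraph(intervals, path) -> None:
    """intervals: iterable of (chrom, start0, end0, value)."""
    with open(path, "w") as fh:
        for chrom, s, e, v in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


class StructureProvider:
    """Dot-bracket structure source for site windows.

    Either precomputed structures keyed by ``"transcript_id:window_start"``
    (1-based transcript coordinate of the window's 5' end) or the built-in
    maximum-pairing folder applied to the window sequence.
    """

    def __init__(self, precomputed: dict[str, str] | None = None,
                 use_fold: bool = True):
        self.precomputed = dict(precomputed or {})
        self.use_fold = use_fold

    @classmethod
    def from_file(cls, path) -> "StructureProvider":
        """Read ``key<TAB>dot-bracket`` lines."""
        pre = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    key, db = line.split("\t")
                except ValueError:
                    raise ValueError(f"{path}:{ln}: expected 'key<TAB>structure'")
                pre[key] = db
        return cls(pre, use_fold=False)

    def dot_bracket(self, key: str, window_sequence: str) -> str | None:
        if key in self.precomputed:
            return self.precomputed[key]
        if self.use_fold:
            # pads at transcript ends cannot fold; strip and re-pad unpaired
            seq = window_sequence
            left = len(seq) - len(seq.lstrip("N"))
            right = len(seq) - len(seq.rstrip("N"))
            core = seq[left: len(seq) - right] if len(seq) - right > left else ""
            folded = nussinov_fold(core) if core else ""
            return "." * left + folded + "." * right
        return None


@dataclass
class TrackBundle:
    """All non-sequence evidence backing the genomic features.

    ``score_tracks``: the four conservation-role tracks; ``interval_tracks``:
    the 13 m6A-biology overlap tracks in frozen registry order;
    ``mirna_targets``: gene-level miRNA-target intervals; ``structure``:
    dot-bracket source.
    """

    score_tracks: list[ScoreTrack] = field(default_factory=list)
    interval_tracks: list[IntervalTrack] = field(default_factory=list)
    mirna_targets: IntervalTrack | None = None
    structure: StructureProvider = field(default_factory=StructureProvider)

    N_SCORE = 4
    N_INTERVAL = 13

    def __post_init__(self):
        while len(self.score_tracks) < self.N_SCORE:
            self.score_tracks.append(ScoreTrack(f"score_{len(self.score_tracks)}"))
        while len(self.interval_tracks) < self.N_INTERVAL:
            self.interval_tracks.append(
                IntervalTrack(f"slot_{43 + len(self.interval_tracks)}")
            )
        if len(self.score_tracks) != self.N_SCORE:
            raise ValueError(f"expected {self.N_SCORE} score tracks")
        if len(self.interval_tracks) != self.N_INTERVAL:
            raise ValueError(f"expected {self.N_INTERVAL} interval tracks")
        if self.mirna_targets is None:
            self.mirna_targets = IntervalTrack("mirna_targets")

    @classmethod
    def empty(cls) -> "TrackBundle":
        return cls()
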