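"""Windowed-identity dot plots and tandem-duplication signatures.

A dot marks every pair of window start positions at which two sequences are
100% identical over a fixed-length window (step 1 bp, case-insensitive).
Bases masked as repetitive (lowercase, following RepeatMasker soft-masking
convention) or ambiguous (N) never participate in a match, so inputs should
be repeat-masked beforehand.  Direct repeats appear as diagonals parallel to
the main diagonal; a tandem gene duplication shows up as off-center partial
diagonals connecting one locus on one axis to the other locus on the other
axis.  Only the forward strand is scanned: the duplication signatures of
interest are direct repeats, not inverted ones.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class DotMatch:
    """An identical window pair: 1-based starts in sequences A and B."""

    pos_a: int
    pos_b: int
    window: int

    @property
    def offset(self) -> int:
        return self.pos_b - self.pos_a


@dataclass(frozen=True)
class DiagonalSegment:
    """A collinear run of matches at one offset."""

    offset: int
    start_a: int
    length: int  # bp covered on the A axis, window included
    n_windows: int

    @property
    def end_a(self) -> int:
        return self.start_a + self.length - 1

    @property
    def start_b(self) -> int:
        return self.start_a + self.offset

    @property
    def end_b(self) -> int:
        return self.end_a + self.offset


@dataclass
class DuplicationCall:
    verdict: str  # duplication_present / duplication_absent / indeterminate
    evidence: list[DiagonalSegment]


def _window_ok(chunk: str) -> bool:
    # lowercase = masked repeat, N = ambiguous; both void the window
    return all(c in "ACGT" for c in chunk)


def windowed_matches(seq_a: str, seq_b: str, window: int) -> list[DotMatch]:
    """All pairs of identical windows between two sequences.

    Windows advance in 1-bp steps; comparison is case-insensitive but any
    window containing a masked (lowercase) or N base produces no match.
    """
    for seq in (seq_a, seq_b):
        bad = set(seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    if window < 1 or window > min(len(seq_a), len(seq_b)):
        raise ValueError("window must be in [1, min sequence length]")

    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(seq_b) - window + 1):
        chunk = seq_b[j:j + window]
        if _window_ok(chunk):
            index[chunk.upper()].append(j + 1)
    matches = []
    for i in range(len(seq_a) - window + 1):
        chunk = seq_a[i:i + window]
        if _window_ok(chunk):
            for j in index.get(chunk.upper(), ()):
                matches.append(DotMatch(i + 1, j, window))
    matches.sort(key=lambda m: (m.pos_a, m.pos_b))
    return matches


def longest_identical_stretch(matches: Iterable[DotMatch], window: int) -> int:
    """Length in bp of the longest run of 100% identity, from match runs.

    A run of k consecutive same-offset matches covers k + window - 1
    identical bases.  Returns 0 for no matches.
    """
    by_offset: dict[int, list[int]] = defaultdict(list)
    for m in matches:
        by_offset[m.offset].append(m.pos_a)
    best = 0
    for starts in by_offset.values():
        starts.sort()
        run = 1
        for prev, cur in zip(starts, starts[1:]):
            run = run + 1 if cur == prev + 1 else 1
            best = max(best, run)
        best = max(best, run if starts else 0, 1 if starts else 0)
    return best + window - 1 if best else 0


def diagonal_segments(matches: Sequence[DotMatch], min_windows: int = 3,
                      max_gap: int = 0) -> list[DiagonalSegment]:
    """Group matches into collinear segments.

    Matches sharing an offset are split into segments wherever consecutive
    start positions differ by more than ``max_gap`` + 1 (``max_gap`` = 0
    keeps only strictly contiguous runs); segments with fewer than
    ``min_windows`` matches are discarded.
    """
    by_offset: dict[int, list[DotMatch]] = defaultdict(list)
    for m in matches:
        by_offset[m.offset].append(m)
    segments = []
    for offset in sorted(by_offset):
        group = sorted(by_offset[offset], key=lambda m: m.pos_a)
        run: list[DotMatch] = [group[0]]
        for m in group[1:]:
            if m.pos_a - run[-1].pos_a > max_gap + 1:
                segments.extend(_close_run(run, offset, min_windows))
                run = []
            run.append(m)
        segments.extend(_close_run(run, offset, min_windows))
    return segments


def _close_run(run: list[DotMatch], offset: int,
               min_windows: int) -> list[DiagonalSegment]:
    if len(run) < min_windows:
        return []
    length = run[-1].pos_a + run[-1].window - run[0].pos_a
    return [DiagonalSegment(offset, run[0].pos_a, length, len(run))]


def _overlaps(lo1: int, hi1: int, lo2: int, hi2: int) -> bool:
    return lo1 <= hi2 and lo2 <= hi1


def classify_duplication(segments: Sequence[DiagonalSegment],
                         region_a: tuple[int, int], region_b: tuple[int, int],
                         min_offset_fraction: float = 0.5,
                         min_length: int = 0) -> DuplicationCall:
    """Decide whether two loci show a tandem-duplication signature.

    ``region_a`` and ``region_b`` are the spans of the two gene loci along
    the plot axes.  A duplication is called present when some segment's
    offset magnitude is at least ``min_offset_fraction`` of the inter-region
    distance AND the segment connects one region on the A axis to the
    *other* region on the B axis (cross-pairing): that is the off-center
    partial diagonal produced by paralogous sequence between the two loci.
    If segments exist but all substantial ones are near-diagonal, the
    duplication is absent; with no segments the call is indeterminate.
    """
    if _overlaps(*region_a, *region_b):
        raise ValueError("gene regions must not overlap")
    inter_region = abs(((region_b[0] + region_b[1])
                        - (region_a[0] + region_a[1])) // 2)
    threshold = min_offset_fraction * inter_region

    cross_evidence = []
    for seg in segments:
        if seg.length < min_length or abs(seg.offset) < threshold:
            continue
        a_in_first = _overlaps(seg.start_a, seg.end_a, *region_a)
        a_in_second = _overlaps(seg.start_a, seg.end_a, *region_b)
        b_in_first = _overlaps(seg.start_b, seg.end_b, *region_a)
        b_in_second = _overlaps(seg.start_b, seg.end_b, *region_b)
        if (a_in_first and b_in_second) or (a_in_second and b_in_first):
            cross_evidence.append(seg)
    if cross_evidence:
        return DuplicationCall("duplication_present", cross_evidence)
    if segments:
        return DuplicationCall("duplication_absent", list(segments))
    return DuplicationCall("indeterminate", [])


def render_ascii(matches: Sequence[DotMatch], len_a: int, len_b: int, *,
                 layout: str = "square", is_self: bool = False,
                 width: int = 60, dot: str = "#", blank: str = ".") -> str:
    """Deterministic text raster of a dot plot (A along rows, B along columns).

    The triangular layout, which plots only the upper half (pos_b >= pos_a),
    is meaningful only for self-comparisons and is refused otherwise.
    """
    if layout not in ("square", "triangular"):
        raise ValueError(f"unknown layout {layout!r}")
    if layout == "triangular" and not is_self:
        raise ValueError("triangular layout requires a self-comparison")
    if not matches:
        return ""
    n_rows = max(1, min(width, len_a))
    n_cols = max(1, min(width, len_b))
    grid = [[blank] * n_cols for _ in range(n_rows)]
    for m in matches:
        if layout == "triangular" and m.pos_b < m.pos_a:
            continue
        row = (m.pos_a - 1) * n_rows // len_a
        col = (m.pos_b - 1) * n_cols // len_b
        grid[row][col] = dot
    return "\n".join("".join(row) for row in grid)
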