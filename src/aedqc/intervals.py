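"""Genomic interval arithmetic and single-linkage locus clustering.

Coordinates follow the GFF3 convention throughout: 1-based, fully closed
intervals, so an interval ``[start, end]`` covers ``end - start + 1`` bases.
All higher-level computations (AED, comparison metrics, locus building) are
expressed in terms of the primitives here: normalization of interval
collections into sorted non-overlapping sets, union/intersection base
counts, and transitive-overlap clustering of stranded features.

Book-ended intervals (``[1,10]`` and ``[11,20]``) are deliberately *not*
merged by :func:`normalize`: they cover adjacent but distinct positions, so
the covered-base count is unaffected, while keeping them separate preserves
exon boundaries needed for exon-level comparison metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "LocusCluster",
    "normalize",
    "intersection_size",
    "union_size",
    "cluster_single_linkage",
    "strands_compatible",
    "MixedSeqidError",
]

#: Strand symbol for features whose orientation is unknown or irrelevant.
UNSTRANDED = "."

_VALID_STRANDS = {"+", "-", UNSTRANDED}


class MixedSeqidError(ValueError):
    """Raised when intervals from different sequences are combined."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully closed interval on one sequence.

    Parameters
    ----------
    seqid : str
        Identifier of the landmark sequence (chromosome, scaffold, contig).
    start, end : int
        1-based inclusive coordinates, ``1 <= start <= end``.
    strand : str
        ``"+"``, ``"-"``, or ``"."`` (unstranded).
    """

    seqid: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] on {self.seqid!r}: "
                "require 1 <= start <= end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class IntervalSet:
    """A normalized (sorted, overlap-merged) set of intervals on one seqid.

    Construct via :func:`normalize`; direct construction assumes the tuples
    are already sorted and pairwise non-overlapping.
    """

    seqid: str
    intervals: tuple[tuple[int, int], ...] = ()

    @property
    def covered_bases(self) -> int:
        """Number of distinct genomic positions covered (size of the union)."""
        return sum(e - s + 1 for s, e in self.intervals)

    @property
    def span(self) -> tuple[int, int] | None:
        """(min start, max end) over members, or None when empty."""
        if not self.intervals:
            return None
        return self.intervals[0][0], self.intervals[-1][1]

    def __len__(self) -> int:
        return len(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)


def _merge_pairs(pairs: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort and merge overlapping (but not book-ended) closed intervals."""
    if not pairs:
        return ()
    pairs.sort()
    merged: list[tuple[int, int]] = [pairs[0]]
    for s, e in pairs[1:]:
        ls, le = merged[-1]
        if s <= le:  # genuine overlap; book-ended (s == le + 1) stays split
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return tuple(merged)


def normalize(intervals: Iterable[GenomicInterval] | Iterable[tuple[int, int]],
              seqid: str | None = None) -> IntervalSet:
    """Normalize a collection of intervals into a sorted, overlap-merged set.

    Accepts either :class:`GenomicInterval` objects (which must all share one
    seqid) or bare ``(start, end)`` tuples together with an explicit
    ``seqid``. Overlapping intervals are merged; book-ended intervals are
    kept separate (the covered-base count is identical either way).

    Raises
    ------
    MixedSeqidError
        If the input mixes intervals from different sequences.
    """
    pairs: list[tuple[int, int]] = []
    seen_seqid = seqid
    for iv in intervals:
        if isinstance(iv, GenomicInterval):
            if seen_seqid is None:
                seen_seqid = iv.seqid
            elif iv.seqid != seen_seqid:
                raise MixedSeqidError(
                    f"cannot normalize intervals from multiple sequences: "
                    f"{seen_seqid!r} and {iv.seqid!r}"
                )
            pairs.append((iv.start, iv.end))
        else:
            s, e = iv
            if s < 1 or e < s:
                raise ValueError(f"invalid interval ({s}, {e})")
            pairs.append((int(s), int(e)))
    if seen_seqid is None:
        seen_seqid = ""
    return IntervalSet(seqid=seen_seqid, intervals=_merge_pairs(pairs))


def intersection_size(a: IntervalSet, b: IntervalSet, *,
                      on_seqid_mismatch: str = "warn") -> int:
    """Number of genomic positions covered by both sets (``|a ∩ b|``).

    Symmetric in its arguments. Sets on different seqids share no positions;
    by default this returns 0 with a warning, or raises when
    ``on_seqid_mismatch="error"``.
    """
    if a.seqid != b.seqid:
        msg = f"intersecting interval sets on different seqids: {a.seqid!r} vs {b.seqid!r}"
        if on_seqid_mismatch == "error":
            raise MixedSeqidError(msg)
        warnings.warn(msg, stacklevel=2)
        return 0
    # two-pointer sweep over sorted non-overlapping runs
    total = 0
    i = j = 0
    ai, bi = a.intervals, b.intervals
    while i < len(ai) and j < len(bi):
        s = max(ai[i][0], bi[j][0])
        e = min(ai[i][1], bi[j][1])
        if s <= e:
            total += e - s + 1
        if ai[i][1] < bi[j][1]:
            i += 1
        else:
            j += 1
    return total


def union_size(a: IntervalSet, b: IntervalSet) -> int:
    """Number of positions covered by either set (inclusion–exclusion)."""
    if a.seqid != b.seqid:
        return a.covered_bases + b.covered_bases
    return a.covered_bases + b.covered_bases - intersection_size(a, b)


def strands_compatible(s1: str, s2: str, mode: str = "aware") -> bool:
    """Decide whether two features may be linked into one locus.

    Modes
    -----
    ``aware`` (default)
        Identical strands match; an unstranded feature matches either strand.
        Suits protein alignments, which are often reported unstranded.
    ``strict``
        Strands must be identical (``.`` only matches ``.``).
    ``ignore``
        Everything matches.
    """
    if mode == "ignore":
        return True
    if mode == "strict":
        return s1 == s2
    if mode == "aware":
        return s1 == s2 or s1 == UNSTRANDED or s2 == UNSTRANDED
    raise ValueError(f"unknown strand mode {mode!r}")


@dataclass
class LocusCluster:
    """A maximal single-linkage group of overlapping features on one seqid."""

    seqid: str
    members: list = field(default_factory=list)

    @property
    def member_ids(self) -> list:
        return [getattr(m, "id", m) for m in self.members]

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(m.intervals.span for m in self.members))
        return min(starts), max(ends)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def cluster_single_linkage(features: Sequence, *,
                           strand_mode: str = "aware",
                           min_overlap: int = 1) -> list[LocusCluster]:
    """Partition features into loci by transitive genomic overlap.

    Each feature must expose ``seqid``, ``strand`` and ``intervals`` (an
    :class:`IntervalSet`). Two features are linked when their interval sets
    share at least ``min_overlap`` bases and their strands are compatible
    under ``strand_mode``; clusters are the connected components of that
    link graph (single linkage). Features on different seqids never merge.

    Returns clusters ordered by (seqid, span start); members keep input order.
    """
    feats = list(features)
    if not feats:
        return []
    uf = _UnionFind(len(feats))

    by_seqid: dict[str, list[int]] = {}
    for idx, f in enumerate(feats):
        if not f.intervals:
            raise ValueError(f"feature {getattr(f, 'id', idx)!r} has an empty interval set")
        by_seqid.setdefault(f.seqid, []).append(idx)

    for indices in by_seqid.values():
        order = sorted(indices, key=lambda i: feats[i].intervals.span[0])
        active: list[int] = []  # indices whose span may still overlap newcomers
        for idx in order:
            start, end = feats[idx].intervals.span
            active = [a for a in active if feats[a].intervals.span[1] >= start]
            for a in active:
                if not strands_compatible(feats[a].strand, feats[idx].strand, strand_mode):
                    continue
                if intersection_size(feats[a].intervals, feats[idx].intervals) >= min_overlap:
                    uf.union(a, idx)
            active.append(idx)

    groups: dict[int, list[int]] = {}
    for idx in range(len(feats)):
        groups.setdefault(uf.find(idx), []).append(idx)
    clusters = [
        LocusCluster(seqid=feats[members[0]].seqid,
                     members=[feats[i] for i in members])
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: (c.seqid, c.span[0]))
    return clusters
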