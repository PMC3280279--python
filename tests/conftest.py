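"""Shared fixtures and brute-force oracles.

The oracles here deliberately work on explicit Python position sets and
adjacency graphs — the slowest possible implementations — so they stay
independent of the interval-arithmetic code they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from aedqc.gff import EvidenceAlignment, Transcript
from aedqc.intervals import normalize


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def positions(pairs) -> set[int]:
    """Explicit set of covered positions for (start, end) closed intervals."""
    out: set[int] = set()
    for s, e in pairs:
        out.update(range(s, e + 1))
    return out


def aed_oracle(exon_pairs, evidence_pairs) -> tuple[float, float, float]:
    """(sn, sp, aed) by direct position-set enumeration."""
    i = positions(exon_pairs)
    j = positions(evidence_pairs)
    overlap = len(i & j)
    sn = overlap / len(j) if j else 0.0
    sp = overlap / len(i)
    return sn, sp, 1.0 - (sn + sp) / 2.0


def components_oracle(features) -> list[frozenset]:
    """Connected components of the pairwise-overlap graph, by BFS.

    ``features`` are (id, seqid, strand, pairs) tuples; two nodes are linked
    when they share a seqid, a compatible strand (same, or either
    unstranded), and at least one position.
    """
    def linked(a, b):
        if a[1] != b[1]:
            return False
        sa, sb = a[2], b[2]
        if not (sa == sb or sa == "." or sb == "."):
            return False
        return bool(positions(a[3]) & positions(b[3]))

    nodes = list(features)
    unseen = set(range(len(nodes)))
    comps = []
    while unseen:
        stack = [unseen.pop()]
        comp = set(stack)
        while stack:
            u = stack.pop()
            for v in list(unseen):
                if linked(nodes[u], nodes[v]):
                    unseen.discard(v)
                    comp.add(v)
                    stack.append(v)
        comps.append(frozenset(nodes[k][0] for k in comp))
    return comps


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def make_transcript(exon_pairs, tid="t1", gene_id="g1", seqid="chr1",
                    strand="+", **kw) -> Transcript:
    return Transcript(id=tid, gene_id=gene_id, seqid=seqid, strand=strand,
                      exons=normalize(exon_pairs, seqid=seqid), **kw)


def make_evidence(part_pairs, eid="e1", seqid="chr1", strand="+",
                  evidence_class="EST") -> EvidenceAlignment:
    return EvidenceAlignment(id=eid, evidence_class=evidence_class,
                             seqid=seqid, strand=strand,
                             parts=normalize(part_pairs, seqid=seqid))


def random_interval_pairs(rng: np.random.Generator, max_pos=10_000,
                          max_n=6) -> list[tuple[int, int]]:
    n = int(rng.integers(1, max_n + 1))
    pairs = []
    for _ in range(n):
        s = int(rng.integers(1, max_pos))
        length = int(rng.integers(1, 400))
        pairs.append((s, min(s + length - 1, max_pos)))
    return pairs


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
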