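"""Downstream summaries: AED distributions, quartile enrichment, RBH orthology.

Cumulative AED distributions let two annotation builds of the same genome be
compared at a glance: the curve of a better-supported build sits higher/left.
Quartile enrichment asks whether an external gene attribute (a Pfam domain
call, presence in a later release, ...) tracks evidence support by binning
genes into the four AED quartiles [0,0.25), [0.25,0.5), [0.5,0.75),
[0.75,1.0] and reporting the attribute-positive fraction per bin.
Reciprocal-best-hit (RBH) orthology — two genes, one per dataset, that are
each other's best BLAST hit under an e-value ceiling — provides a pragmatic
orthology proxy for the same kind of quartile breakdown.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["CumulativeDistribution", "QuartileEnrichment", "RBHPair",
           "cumulative_aed", "quartile_enrichment", "read_hits",
           "reciprocal_best_hits", "orthology_by_quartile",
           "collapse_domain_table", "QUARTILE_BINS"]

#: AED quartile bins; all half-open except the last, which includes 1.0.
QUARTILE_BINS = ((0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0))

BLAST_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                 "gapopen", "qstart", "qend", "sstart", "send",
                 "evalue", "bitscore"]

DEFAULT_MAX_EVALUE = 1e-6


@dataclass(frozen=True)
class CumulativeDistribution:
    """Ordered (aed, fraction of genes with AED <= aed) pairs."""

    points: tuple[tuple[float, float], ...]

    def fraction_at(self, x: float) -> float:
        frac = 0.0
        for v, f in self.points:
            if v <= x:
                frac = f
            else:
                break
        return frac


@dataclass(frozen=True)
class QuartileEnrichment:
    bins: tuple[tuple[float, float], ...]
    n_genes: tuple[int, ...]
    n_with_attribute: tuple[int, ...]

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(w / n if n else 0.0
                     for w, n in zip(self.n_with_attribute, self.n_genes))


@dataclass(frozen=True)
class RBHPair:
    id_a: str
    id_b: str
    evalue_ab: float
    evalue_ba: float


def _as_values(aeds) -> list[float]:
    if isinstance(aeds, Mapping):
        return [float(v) for v in aeds.values()]
    return [float(getattr(v, "aed", v)) for v in aeds]


def cumulative_aed(aeds) -> CumulativeDistribution:
    """Empirical cumulative distribution of AED values.

    Accepts a mapping id → AED, a sequence of AED records, or bare floats.
    Evaluated at each distinct value and at 1.0; the final fraction is 1
    whenever any genes exist. Empty input yields an empty distribution.
    """
    values = sorted(_as_values(aeds))
    if not values:
        return CumulativeDistribution(points=())
    if any(v < 0 or v > 1 for v in values):
        raise ValueError("AED values must lie in [0, 1]")
    n = len(values)
    points: list[tuple[float, float]] = []
    count = 0
    for v in values:
        count += 1
        if points and points[-1][0] == v:
            points[-1] = (v, count / n)
        else:
            points.append((v, count / n))
    if points[-1][0] != 1.0:
        points.append((1.0, 1.0))
    return CumulativeDistribution(points=tuple(points))


def _bin_index(aed: float) -> int:
    if not 0.0 <= aed <= 1.0:
        raise ValueError(f"AED {aed} outside [0, 1]")
    for k, (lo, hi) in enumerate(QUARTILE_BINS):
        if lo <= aed < hi:
            return k
    return 3  # aed == 1.0 → last bin (right-closed)


def quartile_enrichment(gene_aeds: Mapping[str, float],
                        attribute: Mapping[str, bool]) -> QuartileEnrichment:
    """Fraction of attribute-positive genes per AED quartile.

    Genes absent from ``attribute`` count as negative. Bins are half-open
    except the last; an AED of exactly 0.25 falls in the second bin, 1.0 in
    the fourth.
    """
    n = [0, 0, 0, 0]
    w = [0, 0, 0, 0]
    for gid, aed in gene_aeds.items():
        k = _bin_index(float(aed))
        n[k] += 1
        if attribute.get(gid, False):
            w[k] += 1
    return QuartileEnrichment(bins=QUARTILE_BINS, n_genes=tuple(n),
                              n_with_attribute=tuple(w))


def read_hits(source: str | os.PathLike | IO[str]) -> pd.DataFrame:
    """Read a 12-column tabular hit file (BLAST outfmt 6 dialect)."""
    try:
        df = pd.read_csv(source, sep="\t", header=None, names=BLAST_COLUMNS,
                         comment="#",
                         dtype={"qseqid": str, "sseqid": str})
        df["evalue"] = pd.to_numeric(df["evalue"])
        df["bitscore"] = pd.to_numeric(df["bitscore"])
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed hit table {source!r}: {exc}") from exc
    if df.isna()[["qseqid", "sseqid", "evalue", "bitscore"]].any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"malformed hit table {source!r}: bad row at line {bad}")
    return df


def _best_hits(hits: pd.DataFrame) -> dict[str, tuple[str, float]]:
    """Best subject per query: min e-value, then max bitscore, then id."""
    df = hits[hits["qseqid"] != hits["sseqid"]]
    best: dict[str, tuple[float, float, str]] = {}
    for q, s, e, b in zip(df["qseqid"], df["sseqid"], df["evalue"], df["bitscore"]):
        key = (e, -b, s)
        if q not in best or key < best[q]:
            best[q] = key
    return {q: (s, e) for q, (e, _nb, s) in best.items()}


def reciprocal_best_hits(hits_ab: pd.DataFrame | str | os.PathLike,
                         hits_ba: pd.DataFrame | str | os.PathLike,
                         max_evalue: float = DEFAULT_MAX_EVALUE) -> list[RBHPair]:
    """Mutual-best-hit pairs between two datasets.

    A pair (a, b) is reported iff b is a's best hit in ``hits_ab``, a is b's
    best hit in ``hits_ba``, and both best-hit e-values are at or below
    ``max_evalue`` (the threshold is inclusive). Self-hits are ignored; ties
    break toward larger bit score, then lexicographically smaller subject id.
    """
    if not isinstance(hits_ab, pd.DataFrame):
        hits_ab = read_hits(hits_ab)
    if not isinstance(hits_ba, pd.DataFrame):
        hits_ba = read_hits(hits_ba)
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    for a, (b, e_ab) in sorted(best_ab.items()):
        back = best_ba.get(b)
        if back is None:
            continue
        a_back, e_ba = back
        if a_back == a and e_ab <= max_evalue and e_ba <= max_evalue:
            pairs.append(RBHPair(id_a=a, id_b=b, evalue_ab=e_ab, evalue_ba=e_ba))
    return pairs


def orthology_by_quartile(gene_aeds: Mapping[str, float],
                          rbh_by_species: Mapping[str, Sequence[RBHPair]],
                          ) -> tuple[tuple[float, ...], float, bool]:
    """Per-quartile orthology fractions plus mean orthologs per orthologous gene.

    For each AED quartile, the fraction of genes with at least one RBH
    partner in *any* partner species; over the orthologous subset, the mean
    number of partners (pairs summed across species). Returns
    ``(fractions, mean_orthologs, any_orthologs)``; the mean is reported as
    0.0 with ``any_orthologs=False`` when no gene has a partner.
    """
    partner_counts: dict[str, int] = {g: 0 for g in gene_aeds}
    for pairs in rbh_by_species.values():
        for p in pairs:
            if p.id_a in partner_counts:
                partner_counts[p.id_a] += 1
    n = [0, 0, 0, 0]
    w = [0, 0, 0, 0]
    for gid, aed in gene_aeds.items():
        k = _bin_index(float(aed))
        n[k] += 1
        if partner_counts[gid] > 0:
            w[k] += 1
    fractions = tuple(wk / nk if nk else 0.0 for wk, nk in zip(w, n))
    counts = [c for c in partner_counts.values() if c > 0]
    if counts:
        return fractions, sum(counts) / len(counts), True
    return fractions, 0.0, False


def collapse_domain_table(domains: pd.DataFrame,
                          exclude_keywords: Sequence[str] = (),
                          ) -> dict[str, bool]:
    """Collapse a (gene, domain) table to gene → has-any-retained-domain.

    ``exclude_keywords`` removes rows whose domain name contains any keyword
    (case-insensitive) before the boolean collapse — used e.g. to drop
    reverse transcriptase / integrase / virus-related domains that mark
    transposons rather than genes.
    """
    df = domains.iloc[:, :2].copy()
    df.columns = ["gene", "domain"]
    if exclude_keywords:
        pat = "|".join(k.lower() for k in exclude_keywords)
        df = df[~df["domain"].str.lower().str.contains(pat, regex=True)]
    return {g: True for g in df["gene"].unique()}
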