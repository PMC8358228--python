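"""The ScrollSaw protocol: reduce a paralog-rich alignment to its slowly
evolving representatives.

For every unordered pair of taxonomic groups, pairwise ML distances are
computed on the two-group subset of the master alignment and the
*minimal-distance pairs* are extracted: sequence pairs (a, b) from the two
groups that are mutually closest — d(a,b) is minimal both over all partners
of a in the other group and over all partners of b. Pairs from all group
comparisons are pooled; in the pan-eukaryotic mode, sequences that occur in
only one minimal-distance pair overall are then dropped, while the
taxon-specific mode keeps them.

Because a fast-evolving sequence is rarely anyone's nearest cross-group
neighbour, the retained set is strongly enriched for short-branch (slowly
evolving) representatives of each ancestral paralog.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .evomodel import (DEFAULT_D_MAX, DEFAULT_MIN_OVERLAP, SubstitutionModel,
                       cross_distance_matrix)
from .io import ProteinAlignment, TaxonMap

__all__ = [
    "MinimalDistancePair",
    "PairLedger",
    "ScrollSawResult",
    "enumerate_group_pairs",
    "minimal_pairs",
    "minimal_pairs_rect",
    "aggregate_pairs",
    "filter_by_pair_count",
    "run_scrollsaw",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MinimalDistancePair:
    """A mutually-minimal cross-group sequence pair, canonicalised by id sort."""

    id_a: str
    id_b: str
    group_a: str
    group_b: str
    distance: float

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise ValueError("minimal-distance pair must span two distinct groups")
        if not np.isfinite(self.distance) or self.distance < 0:
            raise ValueError(f"invalid pair distance {self.distance}")
        if self.id_b < self.id_a:
            a, b = self.id_a, self.id_b
            ga, gb = self.group_a, self.group_b
            object.__setattr__(self, "id_a", b)
            object.__setattr__(self, "id_b", a)
            object.__setattr__(self, "group_a", gb)
            object.__setattr__(self, "group_b", ga)

    @property
    def ids(self) -> frozenset:
        return frozenset((self.id_a, self.id_b))


@dataclass
class PairLedger:
    """Counts, per sequence id, of minimal-distance pairs it participates in,
    accumulated over all group-pair comparisons."""

    counts: Counter = field(default_factory=Counter)
    pairs: list[MinimalDistancePair] = field(default_factory=list)

    def add(self, pair: MinimalDistancePair) -> None:
        self.pairs.append(pair)
        self.counts[pair.id_a] += 1
        self.counts[pair.id_b] += 1


@dataclass
class ScrollSawResult:
    pairs: list[MinimalDistancePair]
    union_set: set[str]
    retained_set: set[str]
    ledger: PairLedger
    mode: str
    provenance: dict = field(default_factory=dict)


def enumerate_group_pairs(groups) -> list[tuple[str, str]]:
    """All C(n, 2) unordered group pairs, in deterministic input order."""
    groups = list(groups)
    if len(set(groups)) != len(groups):
        raise ValueError("duplicate group names")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    return list(combinations(groups, 2))


def minimal_pairs_rect(ids_a, ids_b, d, group_a, group_b) -> list[MinimalDistancePair]:
    """Minimal-distance pairs from a rectangular cross-group distance matrix.

    Undefined distances (NaN) are treated as +inf and can never form a pair.
    All tied co-minimal pairs are emitted.
    """
    d = np.where(np.isnan(d), np.inf, np.asarray(d, dtype=float))
    if d.size == 0:
        raise ValueError("empty distance matrix")
    row_min = d.min(axis=1)
    col_min = d.min(axis=0)
    out = []
    for i, a in enumerate(ids_a):
        for j, b in enumerate(ids_b):
            v = d[i, j]
            if np.isfinite(v) and v == row_min[i] and v == col_min[j]:
                out.append(MinimalDistancePair(a, b, group_a, group_b, float(v)))
    return out


def minimal_pairs(dm, members_a, members_b, group_a="A", group_b="B"):
    """Minimal-distance pairs between two disjoint id sets of a square
    :class:`~scrollsaw.evomodel.DistanceMatrix`."""
    members_a, members_b = sorted(members_a), sorted(members_b)
    if not members_a or not members_b:
        raise ValueError("member sets must be non-empty")
    if set(members_a) & set(members_b):
        raise ValueError("member sets must be disjoint")
    idx = {x: i for i, x in enumerate(dm.ids)}
    sub = dm.d[np.ix_([idx[a] for a in members_a], [idx[b] for b in members_b])]
    return minimal_pairs_rect(members_a, members_b, sub, group_a, group_b)


def aggregate_pairs(per_comparison_pairs) -> tuple[set[str], PairLedger]:
    """Pool pairs from all group comparisons, de-duplicating sequence ids."""
    ledger = PairLedger()
    for pairs in per_comparison_pairs:
        for p in pairs:
            ledger.add(p)
    union = {i for p in ledger.pairs for i in (p.id_a, p.id_b)}
    return union, ledger


def filter_by_pair_count(ledger: PairLedger, min_pairs: int) -> set[str]:
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    return {i for i, c in ledger.counts.items() if c >= min_pairs}


def run_scrollsaw(
    aln: ProteinAlignment,
    taxon_map: TaxonMap,
    model: SubstitutionModel,
    mode: str = "pan_eukaryotic",
    *,
    min_pairs: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    d_max: float = DEFAULT_D_MAX,
) -> ScrollSawResult:
    """Run the full protocol on a master alignment.

    Distances are recomputed on each two-group subset of the alignment (with
    pairwise deletion this equals slicing a global matrix, but mirrors the
    subsampling workflow). ``min_pairs`` defaults to 2 in ``pan_eukaryotic``
    mode and 1 in ``taxon_specific`` mode.
    """
    if mode not in {"pan_eukaryotic", "taxon_specific"}:
        raise ValueError(f"unknown mode {mode!r}")
    taxon_map.check_covers(aln.ids)
    if min_pairs is None:
        min_pairs = 2 if mode == "pan_eukaryotic" else 1

    by_group: dict[str, list] = {g: [] for g in taxon_map.groups}
    for r in aln.rows:
        by_group[taxon_map.group_of(r.id)].append(r)
    for g, members in by_group.items():
        if not members:
            logger.warning("group %r has no sequences; its comparisons are skipped", g)

    per_comparison = []
    for ga, gb in enumerate_group_pairs(taxon_map.groups):
        rows_a, rows_b = by_group[ga], by_group[gb]
        if not rows_a or not rows_b:
            continue
        ids_a, ids_b, d = cross_distance_matrix(
            model, rows_a, rows_b, min_overlap=min_overlap, d_max=d_max
        )
        per_comparison.append(minimal_pairs_rect(ids_a, ids_b, d, ga, gb))

    union, ledger = aggregate_pairs(per_comparison)
    retained = filter_by_pair_count(ledger, min_pairs)
    logger.info("scrollsaw: %d sequences in, %d in minimal pairs, %d retained",
                len(aln), len(union), len(retained))
    return ScrollSawResult(
        pairs=list(ledger.pairs),
        union_set=union,
        retained_set=retained,
        ledger=ledger,
        mode=mode,
        provenance={
            "mode": mode, "min_pairs": min_pairs, "min_overlap": min_overlap,
            "d_max": d_max, "model": model.name, "alpha": model.alpha,
            "p_inv": model.p_inv, "n_groups": len(taxon_map.groups),
            "n_sequences_in": len(aln),
        },
    )


def write_pair_table(result: ScrollSawResult, dest) -> None:
    """Pair list TSV: id_a, id_b, group_a, group_b, distance."""
    from pathlib import Path

    handle, close = (open(dest, "w"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        handle.write("id_a\tid_b\tgroup_a\tgroup_b\tdistance\n")
        for p in sorted(result.pairs, key=lambda p: (p.id_a, p.id_b)):
            handle.write(f"{p.id_a}\t{p.id_b}\t{p.group_a}\t{p.group_b}\t{p.distance:.6f}\n")
    finally:
        if close:
            handle.close()
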