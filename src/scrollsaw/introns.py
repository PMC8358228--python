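"""Intron positions and phases mapped onto protein alignment columns.

An intron is located by the number of coding nucleotides preceding it
(1-based, stop codon excluded). Phase 0 introns fall cleanly between codons;
phase 1/2 introns interrupt a codon after its first/second base and are
attributed to the interrupted codon's residue. Mapping a residue through its
(gapped) alignment row yields an alignment column, so intron sites from
different genes become comparable: genes sharing a site at the same
(column, phase) are candidates for a conserved ancestral intron, and
paralog-specific site sets serve as structural fingerprints for annotating
highly derived sequences.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

__all__ = [
    "GeneStructure",
    "IntronSite",
    "cds_offset_to_site",
    "site_to_cds_offset",
    "map_gene_to_alignment",
    "shared_intron_clusters",
    "fingerprint_match",
]


@dataclass(frozen=True)
class GeneStructure:
    """Exon–intron structure of one gene: strictly increasing coding-nucleotide
    offsets of its introns, tied to the encoded protein ``seq_id``."""

    gene_id: str
    seq_id: str
    intron_offsets: tuple

    def __post_init__(self):
        offs = tuple(int(x) for x in self.intron_offsets)
        object.__setattr__(self, "intron_offsets", offs)
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError(f"gene {self.gene_id!r}: offsets not strictly increasing")
        if offs and offs[0] < 1:
            raise ValueError(f"gene {self.gene_id!r}: offsets must be >= 1")


@dataclass(frozen=True)
class IntronSite:
    """An intron's image on the protein: 1-based residue, phase, and 1-based
    alignment column."""

    residue_index: int
    phase: int
    column: int


def cds_offset_to_site(n: int, l_aa: int | None = None, gene: str = "?") -> tuple[int, int]:
    """Coding-nucleotide offset → (1-based residue index, phase).

    Phase ``n mod 3``; a phase-0 intron sits after residue ``n/3``, a
    phase-1/2 intron interrupts residue ``floor(n/3) + 1``.
    """
    if n < 1:
        raise ValueError(f"gene {gene!r}: intron offset {n} out of range")
    if l_aa is not None and n > 3 * l_aa - 1:
        raise ValueError(
            f"gene {gene!r}: intron offset {n} exceeds coding length {3 * l_aa}"
        )
    phase = n % 3
    residue = n // 3 if phase == 0 else n // 3 + 1
    return residue, phase


def site_to_cds_offset(residue_index: int, phase: int) -> int:
    """Inverse of :func:`cds_offset_to_site`."""
    if phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {phase}")
    if residue_index < 1:
        raise ValueError("residue index must be >= 1")
    return 3 * residue_index if phase == 0 else 3 * (residue_index - 1) + phase


def map_gene_to_alignment(gene: GeneStructure, aln) -> list[IntronSite]:
    """Map a gene's introns to alignment columns of its protein row.

    The residue index counts non-gap characters of the row; the column is the
    1-based alignment position of that residue.
    """
    row = aln.row(gene.seq_id)
    residue_to_column = [j for j, c in enumerate(row.residues, start=1) if c != "-"]
    l_aa = len(residue_to_column)
    sites = []
    for n in gene.intron_offsets:
        residue, phase = cds_offset_to_site(n, l_aa=l_aa, gene=gene.gene_id)
        sites.append(IntronSite(residue_index=residue, phase=phase,
                                column=residue_to_column[residue - 1]))
    return sites


def shared_intron_clusters(genes, aln, labels: dict[str, str] | None = None):
    """Group intron sites by exact (column, phase) identity.

    Returns ``{(column, phase): {"genes": [gene_id...], "labels": {label:
    count}}}``; the label composition (from an optional seq_id → paralog map)
    supports statements like "this position is exclusive to group X".
    Matching is exact; no fuzz window is applied.
    """
    labels = labels or {}
    clusters = defaultdict(lambda: {"genes": [], "labels": defaultdict(int)})
    for gene in sorted(genes, key=lambda g: g.gene_id):
        for site in map_gene_to_alignment(gene, aln):
            key = (site.column, site.phase)
            clusters[key]["genes"].append(gene.gene_id)
            label = labels.get(gene.seq_id)
            if label is not None:
                clusters[key]["labels"][label] += 1
    return {k: {"genes": v["genes"], "labels": dict(v["labels"])}
            for k, v in sorted(clusters.items())}


def fingerprint_match(query: GeneStructure, reference_sites, aln):
    """Does the query gene share any intron (column, phase) with a reference
    site set (e.g. the sites diagnostic for one paralog)?

    Returns ``(matched, shared_sites)``.
    """
    reference_sites = set(reference_sites)
    if not reference_sites:
        raise ValueError("reference site set is empty")
    query_sites = {(s.column, s.phase) for s in map_gene_to_alignment(query, aln)}
    shared = sorted(query_sites & reference_sites)
    return bool(shared), shared
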