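"""Readers and writers for the external formats the pipeline touches.

FASTA sequence sets and alignments, Newick trees whose internal labels carry
dual branch supports ("SH-aLRT/UFboot"), the tabular inputs (taxon map, gene
structures, presence–absence grids, predictor call tables), and PHYLIP square
distance matrices. All parsers validate strictly and raise ``ValueError``
naming the offending record or row.

Conventions used package-wide: alignment columns and residue positions are
1-based; FASTA ids are the first whitespace-delimited header token; ``.`` gap
characters are normalised to ``-`` and residues are uppercased.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "AnnotatedSequence",
    "ProteinAlignment",
    "TaxonMap",
    "parse_fasta_alignment",
    "write_fasta",
    "dedup_alignment",
    "parse_newick_dual_support",
    "write_newick_dual_support",
    "parse_table",
    "write_phylip_distances",
    "read_phylip_distances",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALLOWED_RESIDUES = set(AMINO_ACIDS) | {"X"}
_ALLOWED_ALIGNED = _ALLOWED_RESIDUES | {"-"}


@dataclass
class AnnotatedSequence:
    """A protein sequence with its provenance and annotation metadata."""

    id: str
    residues: str
    species: str | None = None
    group: str | None = None
    label: str | None = None
    conclusive: bool = False
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues.upper()) - _ALLOWED_ALIGNED
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains disallowed characters {sorted(bad)}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class ProteinAlignment:
    """Equal-length aligned rows of :class:`AnnotatedSequence`."""

    rows: list[AnnotatedSequence]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment has no rows")
        n = len(self.rows[0].residues)
        for i, r in enumerate(self.rows, start=1):
            if len(r.residues) != n:
                raise ValueError(
                    f"ragged alignment: record {i} ({r.id!r}) has length "
                    f"{len(r.residues)}, expected {n}"
                )
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate sequence ids in alignment: {dup}")
        self._index = {r.id: r for r in self.rows}

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, seq_id: str) -> AnnotatedSequence:
        return self._index[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, ids) -> "ProteinAlignment":
        wanted = set(ids)
        return ProteinAlignment([r for r in self.rows if r.id in wanted])


@dataclass
class TaxonMap:
    """Mapping sequence id → (species, taxonomic group)."""

    entries: dict[str, tuple[str, str]]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.groups:
            seen = []
            for _, g in self.entries.values():
                if g not in seen:
                    seen.append(g)
            self.groups = seen
        bad = {g for _, g in self.entries.values() if g not in self.groups}
        if bad:
            raise ValueError(f"taxon map uses undeclared groups: {sorted(bad)}")

    def species_of(self, seq_id: str) -> str:
        return self.entries[seq_id][0]

    def group_of(self, seq_id: str) -> str:
        return self.entries[seq_id][1]

    def check_covers(self, ids) -> None:
        orphans = sorted(i for i in ids if i not in self.entries)
        if orphans:
            raise KeyError(f"taxon map is missing entries for: {orphans}")


def _open_text(source):
    if isinstance(source, (str, Path)):
        return open(source), True
    return source, False


def parse_fasta_alignment(source, aligned: bool = True):
    """Parse FASTA into a :class:`ProteinAlignment` (``aligned=True``) or a
    plain list of :class:`AnnotatedSequence` (``aligned=False``).

    The id is the first whitespace token of the header; the remainder is kept
    as the description. ``.`` is normalised to ``-`` and letters uppercased.
    """
    handle, close = _open_text(source)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if not records:
        raise ValueError("empty FASTA input")
    rows = []
    for rec in records:
        residues = str(rec.seq).upper().replace(".", "-")
        desc = rec.description.split(None, 1)
        rows.append(AnnotatedSequence(
            id=rec.id, residues=residues,
            description=desc[1] if len(desc) > 1 else "",
        ))
    if aligned:
        return ProteinAlignment(rows)
    return rows


def write_fasta(seqs, dest, width: int = 60) -> None:
    rows = seqs.rows if isinstance(seqs, ProteinAlignment) else seqs
    handle, close = (open(dest, "w"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        for r in rows:
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            handle.write(header + "\n")
            for i in range(0, len(r.residues), width):
                handle.write(r.residues[i:i + width] + "\n")
    finally:
        if close:
            handle.close()


def dedup_alignment(aln: ProteinAlignment) -> ProteinAlignment:
    """Collapse rows with byte-identical aligned residue strings, keeping the
    first occurrence in input order."""
    seen = set()
    kept = []
    for r in aln.rows:
        if r.residues not in seen:
            seen.add(r.residues)
            kept.append(r)
    return ProteinAlignment(kept)


_SUPPORT_RE = re.compile(r"^\s*(-?\d+(?:\.\d+)?)\s*$")


def _parse_support_label(label: str | None, convention: str):
    """Internal-node label → (sh_alrt, ufboot); either may be None."""
    if label is None or label == "":
        return None, None
    parts = label.split("/")
    values = []
    for tok in parts:
        m = _SUPPORT_RE.match(tok)
        if not m:
            raise ValueError(f"non-numeric support token {tok!r} in label {label!r}")
        values.append(float(m.group(1)))
    if len(values) == 2:
        return values[0], values[1]
    if len(values) == 1:
        if convention == "ufboot":
            return None, values[0]
        if convention == "sh_alrt":
            return values[0], None
        raise ValueError(f"unknown single-support convention {convention!r}")
    raise ValueError(f"cannot parse support label {label!r}")


def parse_newick_dual_support(source, label_convention: str = "ufboot") -> dendropy.Tree:
    """Parse Newick whose internal labels carry dual supports "SH-aLRT/UFboot".

    Each internal node of the returned :class:`dendropy.Tree` gains
    ``sh_alrt`` and ``ufboot`` attributes (floats or None). A single numeric
    label is assigned according to ``label_convention``.
    """
    handle, close = _open_text(source)
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in Newick input")
    tree = dendropy.Tree.get(
        data=text, schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.sh_alrt = node.ufboot = None
            continue
        sh, uf = _parse_support_label(node.label, label_convention)
        for v, what in ((sh, "SH-aLRT"), (uf, "UFboot")):
            if v is not None and not (0 <= v <= 100):
                raise ValueError(f"{what} support {v} outside [0, 100]")
        node.sh_alrt, node.ufboot = sh, uf
    return tree


def _format_support(node) -> str | None:
    sh = getattr(node, "sh_alrt", None)
    uf = getattr(node, "ufboot", None)

    def fmt(v):
        return f"{v:g}"

    if sh is not None and uf is not None:
        return f"{fmt(sh)}/{fmt(uf)}"
    if uf is not None:
        return fmt(uf)
    if sh is not None:
        return fmt(sh)
    return None


def write_newick_dual_support(tree: dendropy.Tree, dest=None) -> str:
    """Serialise a tree, re-emitting dual supports as internal labels."""
    clone = tree.clone(depth=1)
    for node in clone.preorder_node_iter():
        if not node.is_leaf():
            node.label = _format_support(node)
    text = clone.as_string(schema="newick", suppress_rooting=True,
                           unquoted_underscores=True).strip() + "\n"
    if dest is not None:
        handle, close = (open(dest, "w"), True) if isinstance(dest, (str, Path)) else (dest, False)
        try:
            handle.write(text)
        finally:
            if close:
                handle.close()
    return text


_TABLE_SCHEMAS = {
    "taxon_map": ["id", "species", "group"],
    "gene_structure": ["gene_id", "seq_id", "intron_offsets"],
    "predictor_calls": ["seq_id", "site", "tool", "modification", "call"],
}


def parse_table(source, kind: str, groups: list[str] | None = None):
    """Parse one of the pipeline's TSV table kinds into a typed object.

    kinds: ``taxon_map`` → :class:`TaxonMap`; ``gene_structure`` → list of
    ``(gene_id, seq_id, offsets)`` tuples; ``presence_absence`` → pandas
    DataFrame (species × paralog, nullable Int64, NA = no transcriptome
    evidence); ``predictor_calls`` → pandas DataFrame with boolean ``call``.
    """
    handle, close = _open_text(source)
    try:
        df = pd.read_csv(handle, sep="\t", dtype=str, comment="#")
    finally:
        if close:
            handle.close()

    if kind == "presence_absence":
        first = df.columns[0]
        if df[first].duplicated().any():
            dup = df[first][df[first].duplicated()].iloc[0]
            raise ValueError(f"duplicate species {dup!r} in presence_absence table")
        out = df.set_index(first)
        for col in out.columns:
            for rownum, v in enumerate(out[col], start=2):
                if not (pd.isna(v) or v in {"0", "1", "NA"}):
                    raise ValueError(
                        f"bad presence_absence cell {v!r} at row {rownum}, column {col!r}"
                    )
        out = out.replace("NA", pd.NA)
        return out.astype("Int64")

    if kind not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    expected = _TABLE_SCHEMAS[kind]
    if list(df.columns) != expected:
        raise ValueError(f"{kind} table must have columns {expected}, got {list(df.columns)}")

    if kind == "taxon_map":
        entries = {}
        for rownum, rec in enumerate(df.itertuples(index=False), start=2):
            if rec.id in entries:
                raise ValueError(f"duplicate id {rec.id!r} at row {rownum}")
            if groups is not None and rec.group not in groups:
                raise ValueError(
                    f"row {rownum}: group {rec.group!r} not in configured group list"
                )
            entries[rec.id] = (rec.species, rec.group)
        return TaxonMap(entries=entries, groups=list(groups) if groups else [])

    if kind == "gene_structure":
        out = []
        seen = set()
        for rownum, rec in enumerate(df.itertuples(index=False), start=2):
            if rec.gene_id in seen:
                raise ValueError(f"duplicate gene_id {rec.gene_id!r} at row {rownum}")
            seen.add(rec.gene_id)
            raw = "" if pd.isna(rec.intron_offsets) else str(rec.intron_offsets).strip()
            try:
                offsets = [int(x) for x in raw.split(";") if x != ""]
            except ValueError:
                raise ValueError(
                    f"row {rownum}: bad intron_offsets {rec.intron_offsets!r}"
                ) from None
            out.append((rec.gene_id, rec.seq_id, offsets))
        return out

    # predictor_calls
    for rownum, v in enumerate(df["call"], start=2):
        if v not in {"0", "1"}:
            raise ValueError(f"row {rownum}: bad call value {v!r} (expected 0/1)")
    df["call"] = df["call"] == "1"
    df["site"] = df["site"].astype(str)
    key = df[["seq_id", "site", "tool", "modification"]].apply(tuple, axis=1)
    if key.duplicated().any():
        rownum = int(np.where(key.duplicated())[0][0]) + 2
        raise ValueError(f"duplicate predictor call key at row {rownum}")
    return df


def write_phylip_distances(dm, dest) -> None:
    """Write a :class:`~scrollsaw.evomodel.DistanceMatrix` as a PHYLIP square
    matrix (relaxed names, NaN for undefined entries)."""
    handle, close = (open(dest, "w"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        handle.write(f"{len(dm.ids)}\n")
        for name, row in zip(dm.ids, dm.d):
            cells = " ".join("NaN" if np.isnan(x) else f"{x:.6f}" for x in row)
            handle.write(f"{name}  {cells}\n")
    finally:
        if close:
            handle.close()


def read_phylip_distances(source):
    from .evomodel import DistanceMatrix

    handle, close = _open_text(source)
    try:
        lines = [ln for ln in handle.read().splitlines() if ln.strip()]
    finally:
        if close:
            handle.close()
    n = int(lines[0].split()[0])
    ids, rows = [], []
    for ln in lines[1:n + 1]:
        parts = ln.split()
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(ids=ids, d=np.array(rows))
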