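"""Readers, writers and validated domain containers for the pipeline's file formats.

The pipeline touches five plain-text formats: FASTA and Stockholm protein
alignments, Newick trees, a two-column TSV clade table, and fixed-width PDB
coordinates.  Each reader validates its input into a small domain type
(:class:`Alignment`, :class:`PhyloTree`, :class:`CladeTable`,
:class:`StructureModel`) so that downstream stages can assume well-formed data.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import AlignIO

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
#: residues accepted in alignment sequences: the 20 amino acids, unknown 'X', gap '-'
ALIGNMENT_ALPHABET = frozenset(AMINO_ACIDS) | {"X", "-"}

#: branch length substituted for edges the Newick source leaves unlabelled
DEFAULT_BRANCH_LENGTH = 0.1


class AlignmentError(ValueError):
    """Raised for ragged or otherwise structurally invalid alignments."""


class ValidationError(ValueError):
    """Raised when a parsed file violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """An equal-length, gapped protein multiple sequence alignment.

    Gap characters are normalised to ``-`` ('.' is accepted on input, as used
    by Stockholm).  ``X`` marks an unknown residue and is treated as missing
    data downstream, but preserved on output.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        if next(iter(lengths)) == 0:
            raise AlignmentError("alignment has zero columns")
        seen: set[str] = set()
        for sid, seq in self.records:
            if sid in seen:
                raise ValidationError(f"duplicate sequence id {sid!r}")
            seen.add(sid)
            for pos, ch in enumerate(seq):
                if ch not in ALIGNMENT_ALPHABET:
                    raise ValidationError(
                        f"unknown character {ch!r} in sequence {sid!r} at column {pos + 1}"
                    )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        """Build an alignment, uppercasing and normalising '.' gaps to '-'."""
        cleaned = tuple(
            (sid, seq.upper().replace(".", "-")) for sid, seq in pairs
        )
        return cls(cleaned)

    @property
    def n_cols(self) -> int:
        return len(self.records[0][1])

    @property
    def n_seqs(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.records)

    def sequence(self, sid: str) -> str:
        for rid, seq in self.records:
            if rid == sid:
                return seq
        raise KeyError(f"sequence id {sid!r} not in alignment")

    def column(self, i: int) -> str:
        """Column ``i`` (0-based) as a string over sequences in record order."""
        return "".join(seq[i] for _, seq in self.records)

    def subset(self, ids: Sequence[str]) -> "Alignment":
        """Row subset preserving the original record order."""
        keep = set(ids)
        return Alignment(tuple(r for r in self.records if r[0] in keep))


def read_alignment(path: str, format: str = "fasta") -> Alignment:
    """Read a FASTA or Stockholm alignment into a validated :class:`Alignment`.

    Record order is preserved.  Ragged lengths raise :class:`AlignmentError`;
    duplicate ids or characters outside the protein alphabet raise
    :class:`ValidationError` naming the offending record.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    if format == "fasta":
        # Bio.AlignIO rejects ragged FASTA with an opaque message; read records
        # ourselves so the error names the problem, then validate.
        pairs = _read_fasta_pairs(path)
    else:
        msa = AlignIO.read(path, "stockholm")
        pairs = [(rec.id, str(rec.seq)) for rec in msa]
    return Alignment.from_pairs(pairs)


def _read_fasta_pairs(path: str) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    sid: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if sid is not None:
                    pairs.append((sid, "".join(chunks)))
                sid = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif line:
                if sid is None:
                    raise AlignmentError("FASTA data before first header")
                chunks.append(line.strip())
    if sid is not None:
        pairs.append((sid, "".join(chunks)))
    if not pairs:
        raise AlignmentError(f"no FASTA records in {path}")
    return pairs


def write_alignment(alignment: Alignment, path: str, format: str = "fasta") -> None:
    if format != "fasta":
        raise ValueError("only FASTA output is supported")
    with open(path, "w") as fh:
        for sid, seq in alignment.records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Clade table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeTable:
    """Mapping from sequence id to clade label (mammal, fish, ...)."""

    mapping: Mapping[str, str]

    @property
    def labels(self) -> tuple[str, ...]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.mapping.values():
            seen.setdefault(lab)
        return tuple(seen)

    def members(self, label: str) -> tuple[str, ...]:
        return tuple(sid for sid, lab in self.mapping.items() if lab == label)

    def validate_against(self, alignment: Alignment) -> list[str]:
        """Check completeness w.r.t. an alignment.

        Returns the list of table ids absent from the alignment (warned about);
        raises :class:`ValidationError` if any alignment id lacks a label.
        """
        aln_ids = set(alignment.ids)
        missing = [sid for sid in alignment.ids if sid not in self.mapping]
        if missing:
            raise ValidationError(
                f"clade table is missing alignment ids: {', '.join(missing[:5])}"
                + ("..." if len(missing) > 5 else "")
            )
        extra = [sid for sid in self.mapping if sid not in aln_ids]
        for sid in extra:
            warnings.warn(f"clade table id {sid!r} not in alignment", stacklevel=2)
        return extra


def read_clade_table(path: str) -> CladeTable:
    """Read a two-column id<TAB>label table; conflicting duplicates are fatal."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sid, label = parts[0].strip(), parts[1].strip()
            if sid in mapping and mapping[sid] != label:
                raise ValidationError(
                    f"{path}:{lineno}: id {sid!r} has conflicting labels "
                    f"{mapping[sid]!r} and {label!r}"
                )
            mapping[sid] = label
    return CladeTable(mapping)


def write_clade_table(table: CladeTable, path: str) -> None:
    with open(path, "w") as fh:
        for sid, label in table.mapping.items():
            fh.write(f"{sid}\t{label}\n")


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Leaf-labelled tree with branch lengths in expected substitutions/site.

    Thin wrapper over a :class:`dendropy.Tree`; edges without a length are
    filled with :data:`DEFAULT_BRANCH_LENGTH` at construction.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                edge.length = None  # root has no branch
                continue
            if edge.length is None:
                edge.length = DEFAULT_BRANCH_LENGTH
            if not (edge.length >= 0.0) or edge.length != edge.length:
                raise ValidationError(f"negative or non-finite branch length {edge.length}")

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(lf.taxon.label for lf in self.tree.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def branch_lengths(self) -> list[float]:
        return [
            e.length
            for e in self.tree.preorder_edge_iter()
            if e.head_node is not self.tree.seed_node
        ]

    def validate_against(self, alignment: Alignment) -> None:
        if set(self.leaf_labels) != set(alignment.ids):
            raise ValidationError("tree leaf labels do not match alignment ids")

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_tree(path: str) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(
            path=path, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"Newick parse error in {path}: {exc}") from exc
    return PhyloTree(tree)


def tree_from_newick(text: str) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValidationError(f"Newick parse error: {exc}") from exc
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path: str) -> None:
    tree.tree.write(path=path, schema="newick", suppress_rooting=True,
                    unquoted_underscores=True)


# ---------------------------------------------------------------------------
# PDB structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One ATOM/HETATM record; ``hetatm`` flags heteroatoms (e.g. heme)."""

    serial: int
    name: str
    res_name: str
    chain: str
    res_seq: int
    x: float
    y: float
    z: float
    occupancy: float
    b_factor: float
    element: str
    hetatm: bool = False


@dataclass(frozen=True)
class StructureModel:
    """A parsed structure: the atom list of the ATOM/HETATM records, in order."""

    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str, bool]] = set()
        for a in self.atoms:
            key = (a.chain, a.res_seq, a.name, a.hetatm)
            if key in seen:
                raise ValidationError(
                    f"duplicate atom (chain {a.chain!r}, residue {a.res_seq}, atom {a.name!r})"
                )
            seen.add(key)
            for v in (a.x, a.y, a.z):
                if v != v or abs(v) == float("inf"):
                    raise ValidationError(f"non-finite coordinate in atom {a.serial}")

    @property
    def chains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain)
        return tuple(seen)

    def residues(self, chain: str, include_hetatm: bool = False) -> list[int]:
        """Distinct residue numbers of a chain, in order of appearance."""
        out: dict[int, None] = {}
        for a in self.atoms:
            if a.chain == chain and (include_hetatm or not a.hetatm):
                out.setdefault(a.res_seq)
        return list(out)


def read_structure(path: str) -> StructureModel:
    """Parse PDB ATOM/HETATM records (fixed-width columns).

    Only ATOM, HETATM, TER and END records are interpreted; all other record
    types are ignored.  Insertion codes are rejected.  A malformed fixed-width
    line raises :class:`ValidationError` with its line number.
    """
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 66:
                raise ValidationError(f"{path}:{lineno}: truncated {rec} record")
            if line[26] != " ":
                raise ValidationError(
                    f"{path}:{lineno}: insertion code {line[26]!r} not supported"
                )
            try:
                atoms.append(
                    Atom(
                        serial=int(line[6:11]),
                        name=line[12:16].strip(),
                        res_name=line[17:20].strip(),
                        chain=line[21].strip(),
                        res_seq=int(line[22:26]),
                        x=float(line[30:38]),
                        y=float(line[38:46]),
                        z=float(line[46:54]),
                        occupancy=float(line[54:60]),
                        b_factor=float(line[60:66]),
                        element=line[76:78].strip() if len(line) >= 78 else "",
                        hetatm=(rec == "HETATM"),
                    )
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed {rec} record: {exc}") from exc
    if not atoms:
        raise ValidationError(f"no ATOM/HETATM records in {path}")
    return StructureModel(tuple(atoms))


def _format_atom_name(name: str) -> str:
    # PDB convention: names of <=3 chars start in column 14
    return f" {name:<3s}" if len(name) < 4 else name


def write_structure(model: StructureModel, path: str) -> None:
    """Emit fixed-width PDB records (B-factor columns 61-66, %6.2f)."""
    with open(path, "w") as fh:
        for a in model.atoms:
            rec = "HETATM" if a.hetatm else "ATOM"
            fh.write(
                f"{rec:<6s}{a.serial:>5d} {_format_atom_name(a.name)} "
                f"{a.res_name:>3s} {a.chain:1s}{a.res_seq:>4d}    "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
                f"          {a.element:>2s}\n"
            )
        fh.write("END\n")


def structure_to_string(model: StructureModel) -> str:
    buf = io.StringIO()
    for a in model.atoms:
        rec = "HETATM" if a.hetatm else "ATOM"
        buf.write(
            f"{rec:<6s}{a.serial:>5d} {_format_atom_name(a.name)} "
            f"{a.res_name:>3s} {a.chain:1s}{a.res_seq:>4d}    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"          {a.element:>2s}\n"
        )
    buf.write("END\n")
    return buf.getvalue()
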