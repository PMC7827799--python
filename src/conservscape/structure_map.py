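"""Paint conservation scores or grades into a structure's B-factor column.

Produces the structure-coloring input for molecular-graphics tools: every
atom of a residue with a conservation value gets that value as its B-factor
(scores to 2 decimals, or integer grades 1..9), residues without a value get
a distinguishable sentinel, and heteroatom records (e.g. the heme) are left
untouched.  Painting changes nothing but B-factors, so it is idempotent and
round-trips through the fixed-width PDB writer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .conservation_core import SiteScoreTable
from .io_formats import Atom, StructureModel
from .refmap import RefMap

#: sentinel B-factors for residues without a conservation value
SENTINEL_SCORE = -9.99  # score mode (format minimum)
SENTINEL_GRADE = -1.00  # grade mode (grades are 1..9)


@dataclass(frozen=True)
class PaintReport:
    painted: StructureModel
    mapped_residues: tuple[int, ...]
    unmapped_residues: tuple[int, ...]


def paint_bfactor(
    structure: StructureModel,
    score_table: SiteScoreTable,
    refmap: RefMap,
    chain: str,
    mode: str = "score",
) -> PaintReport:
    """Assign per-residue conservation values to B-factors of one chain.

    Residue numbers in the structure must already be on the reference
    numbering that ``score_table``/``refmap`` report.  ``mode`` selects the
    normalized score (2 decimals) or the 1..9 grade.  Atom count, order,
    coordinates and every non-B field are unchanged.
    """
    if mode not in ("score", "grade"):
        raise ValueError(f"mode must be 'score' or 'grade', got {mode!r}")
    if chain not in structure.chains:
        raise ValueError(f"chain {chain!r} not in structure (has {structure.chains})")
    if mode == "score":
        values: Mapping[int, float] = score_table.score_by_residue()
        sentinel = SENTINEL_SCORE
    else:
        values = {r: float(g) for r, g in score_table.grade_by_residue().items()}
        sentinel = SENTINEL_GRADE
    mapped: dict[int, None] = {}
    unmapped: dict[int, None] = {}
    atoms: list[Atom] = []
    for atom in structure.atoms:
        if atom.hetatm or atom.chain != chain:
            atoms.append(atom)
            continue
        if atom.res_seq in values:
            b = round(values[atom.res_seq], 2)
            mapped.setdefault(atom.res_seq)
        else:
            b = sentinel
            unmapped.setdefault(atom.res_seq)
        atoms.append(replace(atom, b_factor=b))
    if not mapped:
        raise ValueError(f"no residues of chain {chain!r} are mapped by the score table")
    return PaintReport(
        painted=StructureModel(tuple(atoms)),
        mapped_residues=tuple(mapped),
        unmapped_residues=tuple(unmapped),
    )
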