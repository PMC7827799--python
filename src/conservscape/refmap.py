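"""Mapping between alignment columns and reference residue numbering.

All reported positions use the numbering of a chosen reference sequence
(for the aromatase study, human CYP19A1 / UniProt P11511), 1-based and
inclusive.  The ``offset`` is the residue number of the first reference
residue, absorbing e.g. the difference between a crystal construct and the
full-length UniProt sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .io_formats import Alignment


@dataclass(frozen=True)
class RefMap:
    ref_id: str
    offset: int
    col_to_res: Mapping[int, int]  # 1-based column -> residue number
    res_to_col: Mapping[int, int]

    def __post_init__(self) -> None:
        for c, r in self.col_to_res.items():
            if self.res_to_col.get(r) != c:
                raise ValueError("col_to_res and res_to_col are not mutual inverses")
        cols = sorted(self.col_to_res)
        residues = [self.col_to_res[c] for c in cols]
        if any(b <= a for a, b in zip(residues, residues[1:])):
            raise ValueError("residue numbers must strictly increase with column")

    @property
    def residues(self) -> tuple[int, ...]:
        return tuple(sorted(self.res_to_col))


def build_refmap(alignment: Alignment, ref_id: str, offset: int = 1) -> RefMap:
    """Map the k-th non-gap reference position to residue ``offset + k - 1``.

    Columns where the reference row has a gap are absent from the map and
    reported with an empty reference residue downstream.  Unknown residues
    (X) in the reference still occupy a numbered position.
    """
    if offset < 1:
        raise ValueError("offset must be >= 1")
    try:
        ref_seq = alignment.sequence(ref_id)
    except KeyError as exc:
        raise ValueError(f"reference id {ref_id!r} not in alignment") from exc
    col_to_res: dict[int, int] = {}
    res_to_col: dict[int, int] = {}
    k = 0
    for col0, ch in enumerate(ref_seq):
        if ch == "-":
            continue
        res = offset + k
        col_to_res[col0 + 1] = res
        res_to_col[res] = col0 + 1
        k += 1
    return RefMap(ref_id=ref_id, offset=offset, col_to_res=col_to_res, res_to_col=res_to_col)


def annotate_score_table(score_table, refmap: RefMap) -> None:
    """Fill the ``ref_residue`` column of a SiteScoreTable in place."""
    frame = score_table.frame
    frame["ref_residue"] = [
        float(refmap.col_to_res[c]) if c in refmap.col_to_res else float("nan")
        for c in frame["column"]
    ]
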