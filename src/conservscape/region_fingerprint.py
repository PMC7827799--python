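"""Region-level conservation statistics and dual-alignment fingerprints.

Covers the reporting layer of the analysis: percent-conserved summaries for
named regions (the P450 substrate recognition sites SRS-1..6 and conserved
structural elements), residue-by-residue reports with per-clade substitution
notes, pairwise identity/similarity percentages, the >=40%-identity curation
filter, and the classification of reference positions into shared-conserved
vs family-unique vs variable by comparing a within-family score table with a
cross-family (superfamily) one.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .conservation_core import SiteScoreTable
from .io_formats import Alignment, CladeTable
from .refmap import RefMap

#: grades counted as "conserved" in region percentages (top two of nine)
DEFAULT_CONSERVED_GRADES = frozenset({8, 9})

#: score thresholds for the fingerprint classification (normalized scale)
DEFAULT_TAU_CONSERVED = -0.5
DEFAULT_TAU_VARIABLE = 0.0

#: structural elements reported as most conserved in aromatase, bundled as
#: default regions (reference residue intervals, human CYP19A1 numbering)
DEFAULT_STRUCTURAL_REGIONS = (
    ("helix-A", ((65, 78),)),
    ("beta-1", ((83, 88),)),
    ("beta-2", ((93, 97),)),
    ("helix-E", ((187, 205),)),
    ("helix-F-part", ((221, 224),)),
    ("helix-I-central", ((302, 318),)),
    ("helix-K", ((354, 366),)),
    ("K-beta3-loop", ((368, 376),)),
    ("beta-6", ((393, 396),)),
    ("helix-L", ((427, 448),)),
)


def round1(value: float) -> float:
    """Round to 1 decimal, half away from zero (69.65 -> 69.7)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Region:
    """A named set of non-overlapping reference-residue intervals."""

    name: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if start > end:
                raise ValueError(f"region {self.name}: interval {start}-{end} inverted")
        spans = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"region {self.name}: overlapping intervals")

    @property
    def residues(self) -> tuple[int, ...]:
        out: list[int] = []
        for start, end in self.intervals:
            out.extend(range(start, end + 1))
        return tuple(out)


def default_regions() -> tuple[Region, ...]:
    return tuple(Region(name, ivs) for name, ivs in DEFAULT_STRUCTURAL_REGIONS)


# ---------------------------------------------------------------------------
# Pairwise identity / similarity and the curation filter
# ---------------------------------------------------------------------------

_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def pairwise_identity_similarity(
    alignment: Alignment,
    id_a: str,
    id_b: str,
    similarity_matrix=None,
) -> tuple[float, float]:
    """Percent identity and percent similarity between two aligned rows.

    Both are over mutually non-gap columns (X treated as missing, like a
    gap).  Similarity counts pairs with a positive score in the similarity
    matrix (BLOSUM62 by default) — the usual reading of "% homology".
    """
    matrix = similarity_matrix if similarity_matrix is not None else _blosum62()
    seq_a = alignment.sequence(id_a)
    seq_b = alignment.sequence(id_b)
    n = ident = simil = 0
    for ca, cb in zip(seq_a, seq_b):
        if ca in ("-", "X") or cb in ("-", "X"):
            continue
        n += 1
        if ca == cb:
            ident += 1
        if matrix[ca, cb] > 0:
            simil += 1
    if n == 0:
        raise ValueError(f"{id_a!r} and {id_b!r} share no non-gap columns")
    return 100.0 * ident / n, 100.0 * simil / n


def filter_by_identity(
    alignment: Alignment, ref_id: str, threshold: float
) -> Alignment:
    """Keep sequences with >= ``threshold`` % identity to the reference.

    The reference itself is always retained; record order is preserved.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    alignment.sequence(ref_id)  # raises KeyError if absent
    keep = []
    for sid in alignment.ids:
        if sid == ref_id:
            keep.append(sid)
            continue
        identity, _ = pairwise_identity_similarity(alignment, ref_id, sid)
        if identity >= threshold:
            keep.append(sid)
    return alignment.subset(keep)


# ---------------------------------------------------------------------------
# Region conservation percentages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionReport:
    name: str
    percent_conserved: float  # 1-decimal
    n_conserved: int
    n_mapped: int
    unmapped_residues: tuple[int, ...]


def region_conservation_percent(
    score_table: SiteScoreTable,
    refmap: RefMap,
    region: Region,
    conserved_grades: frozenset[int] = DEFAULT_CONSERVED_GRADES,
) -> RegionReport:
    """Percent of a region's mapped residues whose grade counts as conserved.

    Residues absent from the alignment's reference row are excluded from the
    denominator and listed in the report.
    """
    grade_by_res = score_table.grade_by_residue()
    mapped: list[int] = []
    unmapped: list[int] = []
    for res in region.residues:
        if res in refmap.res_to_col and res in grade_by_res:
            mapped.append(res)
        else:
            unmapped.append(res)
    if not mapped:
        raise ValueError(f"region {region.name!r} is entirely unmapped")
    n_cons = sum(1 for res in mapped if grade_by_res[res] in conserved_grades)
    pct = round1(100.0 * n_cons / len(mapped))
    return RegionReport(
        name=region.name,
        percent_conserved=pct,
        n_conserved=n_cons,
        n_mapped=len(mapped),
        unmapped_residues=tuple(unmapped),
    )


# ---------------------------------------------------------------------------
# Residue reports with per-clade substitution notes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueReportRow:
    ref_residue: int
    consensus: str
    score: float
    #: clade -> {residue state != consensus: within-clade frequency (2-decimal)}
    clade_notes: Mapping[str, Mapping[str, float]]


def consensus_residue(alignment: Alignment, col0: int) -> str:
    """Modal residue of a column over all sequences, ties broken alphabetically.

    Gaps and X do not vote; an all-gap column has consensus '-'.
    """
    counts: dict[str, int] = {}
    for ch in alignment.column(col0):
        if ch in ("-", "X"):
            continue
        counts[ch] = counts.get(ch, 0) + 1
    if not counts:
        return "-"
    best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
    return best[0]


def residue_report(
    alignment: Alignment,
    clade_table: CladeTable,
    score_table: SiteScoreTable,
    refmap: RefMap,
    residues: Sequence[int],
) -> tuple[list[ResidueReportRow], list[int]]:
    """Score and per-clade non-consensus states for chosen reference residues.

    Returns ``(rows, skipped)`` where ``skipped`` lists residues absent from
    the reference mapping (reported, not fatal).
    """
    score_by_res = score_table.score_by_residue()
    rows: list[ResidueReportRow] = []
    skipped: list[int] = []
    for res in residues:
        col = refmap.res_to_col.get(res)
        if col is None or res not in score_by_res:
            skipped.append(res)
            continue
        col0 = col - 1
        consensus = consensus_residue(alignment, col0)
        notes: dict[str, dict[str, float]] = {}
        for clade in clade_table.labels:
            members = clade_table.members(clade)
            if not members:
                continue
            counts: dict[str, int] = {}
            for sid in members:
                ch = alignment.sequence(sid)[col0]
                if ch in ("-", "X") or ch == consensus:
                    continue
                counts[ch] = counts.get(ch, 0) + 1
            if counts:
                notes[clade] = {
                    ch: round(c / len(members), 2) for ch, c in sorted(counts.items())
                }
        rows.append(
            ResidueReportRow(
                ref_residue=res,
                consensus=consensus,
                score=score_by_res[res],
                clade_notes=notes,
            )
        )
    return rows, skipped


# ---------------------------------------------------------------------------
# Dual-alignment fingerprint classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintCall:
    ref_residue: int
    s_within: float
    s_cross: float
    label: str  # shared-conserved | family-unique | variable | ambiguous


def fingerprint_classify(
    within_scores: Mapping[int, float],
    cross_scores: Mapping[int, float],
    tau_c: float = DEFAULT_TAU_CONSERVED,
    tau_v: float = DEFAULT_TAU_VARIABLE,
) -> tuple[list[FingerprintCall], list[int]]:
    """Label each comparable reference position by where it is conserved.

    shared-conserved: conserved (score <= tau_c) in both the family and the
    cross-family alignment; family-unique: conserved in the family but
    clearly variable (score > tau_v) across the superfamily; variable: not
    conserved within the family; ambiguous: family-conserved with a
    cross-family score in (tau_c, tau_v].  Positions present in only one
    table are returned separately as uncomparable.
    """
    if tau_v < tau_c:
        raise ValueError("tau_v must be >= tau_c")
    calls: list[FingerprintCall] = []
    uncomparable = sorted(set(within_scores) ^ set(cross_scores))
    for res in sorted(set(within_scores) & set(cross_scores)):
        s_w, s_c = within_scores[res], cross_scores[res]
        if s_w > tau_c:
            label = "variable"
        elif s_c <= tau_c:
            label = "shared-conserved"
        elif s_c > tau_v:
            label = "family-unique"
        else:
            label = "ambiguous"
        calls.append(FingerprintCall(res, s_w, s_c, label))
    return calls, uncomparable
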