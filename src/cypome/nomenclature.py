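"""Family and subfamily assignment by percent identity to named P450s.

The International P450 Nomenclature convention groups sequences with their
best-matching named homolog: >55% amino-acid identity places a protein in the
same subfamily, >=40% in the same family, and below 40% it founds a new
family.  Identity is computed from an optimal global alignment (BLOSUM62,
affine gaps 10/1) with terminal-overhang gap columns excluded from the
denominator, which approximates the identity a local aligner would report
while keeping the alignment global and deterministic.

Calls within two percentage points of the subfamily threshold are flagged
``borderline``; when a phylogenetic tree over the query and the named
references is available, the subfamily of a borderline call is taken from the
nearest named leaf instead of the raw identity ranking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .config import DEFAULT_RULES, AlignScoring, RulesConfig
from .io import ProteinRecord

GAP = "-"

_CYP_NAME = re.compile(r"^(CYP\d+)([A-Z])?(\d+)?$")

NEW_SUBFAMILY = "NEW"


@dataclass(frozen=True)
class NamedReference:
    """A named P450 used as the nomenclature anchor, e.g. CYP52A3."""

    cyp_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.cyp_name}: empty reference sequence")
        if _CYP_NAME.match(self.cyp_name) is None:
            raise ValueError(f"invalid CYP name: {self.cyp_name!r}")

    @property
    def family(self) -> str:
        return _CYP_NAME.match(self.cyp_name).group(1)

    @property
    def subfamily_letter(self) -> Optional[str]:
        return _CYP_NAME.match(self.cyp_name).group(2)


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float


@dataclass
class Assignment:
    query_id: str
    family_label: str
    subfamily_label: str
    best_reference: str
    best_identity: float
    is_new_family: bool = False
    borderline: bool = False


@lru_cache(maxsize=8)
def _aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(
        scoring.matrix_name)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _identity_from_alignment(aligned_a: str, aligned_b: str) -> float:
    """Identity over alignment columns, excluding terminal-overhang gaps."""
    n = len(aligned_a)
    lead = 0
    while lead < n and (aligned_a[lead] == GAP or aligned_b[lead] == GAP):
        lead += 1
    trail = n
    while trail > lead and (aligned_a[trail - 1] == GAP
                            or aligned_b[trail - 1] == GAP):
        trail -= 1
    core = trail - lead
    if core == 0:
        return 0.0
    matches = sum(
        1 for i in range(lead, trail) if aligned_a[i] == aligned_b[i]
    )
    return 100.0 * matches / core


def global_align(a: str, b: str,
                 scoring: AlignScoring = AlignScoring()) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Affine gap cost: a gap of length L costs ``gap_open + (L-1)*gap_extend``.
    The first optimal traceback reported by the aligner is used; it is
    deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    alignments = _aligner(scoring).align(a, b)
    best = alignments[0]
    aligned_a, aligned_b = best[0], best[1]
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=best.score,
        identity_pct=_identity_from_alignment(aligned_a, aligned_b),
    )


def percent_identity(a: str, b: str,
                     scoring: AlignScoring = AlignScoring()) -> float:
    """Percent identity between two sequences under the global aligner."""
    return global_align(a, b, scoring).identity_pct


def read_reference_fasta(path) -> list[NamedReference]:
    """Read named references from FASTA; headers must start with the CYP name."""
    from .io import read_fasta
    return [
        NamedReference(cyp_name=rec.id.split("|")[0], sequence=rec.sequence)
        for rec in read_fasta(path)
    ]


def _best_reference(query: str,
                    references: Sequence[NamedReference],
                    scoring: AlignScoring) -> tuple[NamedReference, float]:
    best_ref, best_identity = None, -1.0
    for ref in sorted(references, key=lambda r: r.cyp_name):
        ident = percent_identity(query, ref.sequence, scoring)
        if ident > best_identity:
            best_ref, best_identity = ref, ident
    return best_ref, best_identity


def assign(query: ProteinRecord,
           references: Sequence[NamedReference],
           rules: RulesConfig = DEFAULT_RULES,
           tree=None,
           new_family_index: int = 1) -> Assignment:
    """Assign a family/subfamily to one triaged P450.

    ``tree`` (optional) is a phylogeny whose leaves include the query id and
    reference CYP names; it is consulted only for borderline calls.
    ``new_family_index`` numbers the placeholder label used if the query
    founds a new family (NEWFAM1, NEWFAM2, ... in query order).
    """
    if not references:
        raise ValueError("reference set is empty")
    best_ref, identity = _best_reference(query.sequence, references,
                                         rules.scoring)
    borderline = (abs(identity - rules.subfamily_identity_threshold)
                  <= rules.borderline_band_halfwidth)
    if identity < rules.family_identity_threshold:
        result = Assignment(
            query_id=query.id,
            family_label=f"NEWFAM{new_family_index}",
            subfamily_label=NEW_SUBFAMILY,
            best_reference=best_ref.cyp_name,
            best_identity=identity,
            is_new_family=True,
            borderline=borderline,
        )
        return result
    if identity > rules.subfamily_identity_threshold:
        subfamily = best_ref.subfamily_letter or NEW_SUBFAMILY
    else:
        subfamily = NEW_SUBFAMILY
    if borderline and tree is not None:
        from .phylo import nearest_named_leaf
        named = [r.cyp_name for r in references]
        neighbor = nearest_named_leaf(tree, query.id, named)
        neighbor_ref = next(r for r in references if r.cyp_name == neighbor)
        subfamily = neighbor_ref.subfamily_letter or NEW_SUBFAMILY
    return Assignment(
        query_id=query.id,
        family_label=best_ref.family,
        subfamily_label=subfamily,
        best_reference=best_ref.cyp_name,
        best_identity=identity,
        is_new_family=False,
        borderline=borderline,
    )


def assign_p450s(queries: Sequence[ProteinRecord],
                 references: Sequence[NamedReference],
                 rules: RulesConfig = DEFAULT_RULES,
                 tree=None) -> list[Assignment]:
    """Assign all queries, numbering new-family placeholders in query order."""
    assignments = []
    next_new = 1
    for q in queries:
        a = assign(q, references, rules, tree=tree, new_family_index=next_new)
        if a.is_new_family:
            next_new += 1
        assignments.append(a)
    return assignments


def assignment_report(assignments: Sequence[Assignment]) -> pd.DataFrame:
    """Tabulate assignments for TSV export."""
    return pd.DataFrame([
        {
            "query_id": a.query_id,
            "family": a.family_label,
            "subfamily": a.subfamily_label,
            "best_ref": a.best_reference,
            "identity": round(a.best_identity, 1),
            "is_new_family": a.is_new_family,
            "borderline": a.borderline,
        }
        for a in assignments
    ], columns=["query_id", "family", "subfamily", "best_ref",
                "identity", "is_new_family", "borderline"])
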