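"""Signature-motif scanning and curation triage of P450 candidates.

Candidate proteins (e.g. from an InterPro P450-domain search) are scanned for
the two diagnostic motifs of the P450 fold: the K-helix ExxR salt bridge,
which may occur anywhere in the sequence, and the heme-binding CxG whose axial
cysteine sits near the C-terminus, so matches are only accepted in the
C-terminal third.  Each candidate is then triaged:

* both motifs and length >= 350 residues  -> ``P450``
* exactly one motif, or both but < 350 aa -> ``FRAGMENT``
* no motif, but still P450-like (>= 20% best identity to a named reference)
                                          -> ``FALSE_POSITIVE``
* no motif and no meaningful similarity   -> ``NO_HIT``

The false-positive/no-hit split is a curation heuristic: the published counts
distinguish degenerate P450-like proteins from unrelated ones without stating
a rule, so the 20% reference-identity cut-off is exposed in
:class:`~cypome.config.RulesConfig` and recorded in every report.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import DEFAULT_RULES, RulesConfig
from .io import ProteinRecord

# '.' in a motif pattern means "any allowed residue"; an X in the sequence can
# occupy a wildcard position but never satisfies a fixed letter (fixed letters
# are literal, and X is not one of them).
_WILDCARD = "[A-Z]"


class Category(str, Enum):
    P450 = "P450"
    FRAGMENT = "FRAGMENT"
    FALSE_POSITIVE = "FALSE_POSITIVE"
    NO_HIT = "NO_HIT"


@dataclass(frozen=True)
class MotifHit:
    motif_name: str           # "EXXR" or "CXG"
    start: int                # 0-based index into the sequence
    matched_text: str


@dataclass
class TriageResult:
    protein_id: str
    species_id: str
    category: Category
    motif_hits: list[MotifHit] = field(default_factory=list)
    length: int = 0
    best_reference_identity: Optional[float] = None

    @property
    def motif_names(self) -> set[str]:
        return {h.motif_name for h in self.motif_hits}


def _compile(pattern: str) -> re.Pattern:
    return re.compile(pattern.replace(".", _WILDCARD))


def scan_motifs(sequence: str,
                rules: RulesConfig = DEFAULT_RULES) -> list[MotifHit]:
    """Find all ExxR and CxG motif occurrences in an amino-acid sequence.

    Every distinct start position is reported (overlapping matches included).
    CxG hits are restricted to the C-terminal third of the sequence.  Returns
    hits sorted by (start, motif_name).
    """
    if not sequence:
        raise ValueError("cannot scan an empty sequence")
    hits: list[MotifHit] = []
    exxr = _compile(rules.exxr_pattern)
    for m in re.finditer(f"(?=({exxr.pattern}))", sequence):
        hits.append(MotifHit("EXXR", m.start(), m.group(1)))
    cxg = _compile(rules.cxg_pattern)
    window_start = (2 * len(sequence)) // 3
    for m in re.finditer(f"(?=({cxg.pattern}))", sequence):
        if m.start() >= window_start:
            hits.append(MotifHit("CXG", m.start(), m.group(1)))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


def triage(record: ProteinRecord,
           rules: RulesConfig = DEFAULT_RULES,
           best_reference_identity: Optional[float] = None) -> TriageResult:
    """Classify one candidate protein by the motif/length curation rule."""
    hits = scan_motifs(record.sequence, rules)
    names = {h.motif_name for h in hits}
    long_enough = record.length >= rules.fragment_length_cutoff
    if len(names) == 2 and long_enough:
        category = Category.P450
    elif len(names) >= 1:
        category = Category.FRAGMENT
    elif (best_reference_identity is not None
          and best_reference_identity >= rules.false_positive_identity_threshold):
        category = Category.FALSE_POSITIVE
    else:
        category = Category.NO_HIT
    return TriageResult(
        protein_id=record.id,
        species_id=record.species_id,
        category=category,
        motif_hits=hits,
        length=record.length,
        best_reference_identity=best_reference_identity,
    )


def triage_proteome(records: Sequence[ProteinRecord],
                    rules: RulesConfig = DEFAULT_RULES,
                    references: Optional[Sequence] = None,
                    ) -> tuple[dict[str, int], list[TriageResult]]:
    """Triage a whole proteome; returns (counts, per-protein results).

    All records must share one species id.  When a named reference set is
    supplied, motif-free candidates are aligned against it to split false
    positives from no-hits; without references every motif-free candidate is a
    no-hit.  The counts partition the input exactly:
    ``total_hits = p450s + fragments + false_positives + no_hits``.
    """
    species = {r.species_id for r in records}
    if len(species) > 1:
        raise ValueError(f"mixed species ids in proteome: {sorted(species)}")
    results = []
    for rec in records:
        best = None
        if references and not scan_motifs(rec.sequence, rules):
            from .nomenclature import percent_identity
            best = max(
                percent_identity(rec.sequence, ref.sequence, rules.scoring)
                for ref in references
            )
        results.append(triage(rec, rules, best_reference_identity=best))
    tally = Counter(r.category for r in results)
    counts = {
        "total_hits": len(results),
        "p450s": tally[Category.P450],
        "fragments": tally[Category.FRAGMENT],
        "false_positives": tally[Category.FALSE_POSITIVE],
        "no_hits": tally[Category.NO_HIT],
    }
    return counts, results


def triage_report(results: Iterable[TriageResult]) -> pd.DataFrame:
    """Tabulate triage results (one row per protein) for TSV export."""
    rows = []
    for r in results:
        exxr = ",".join(str(h.start) for h in r.motif_hits
                        if h.motif_name == "EXXR")
        cxg = ",".join(str(h.start) for h in r.motif_hits
                       if h.motif_name == "CXG")
        rows.append({
            "protein_id": r.protein_id,
            "species_id": r.species_id,
            "length": r.length,
            "category": r.category.value,
            "exxr_positions": exxr,
            "cxg_positions": cxg,
            "best_identity": ("" if r.best_reference_identity is None
                              else round(r.best_reference_identity, 1)),
        })
    return pd.DataFrame(rows, columns=[
        "protein_id", "species_id", "length", "category",
        "exxr_positions", "cxg_positions", "best_identity",
    ])
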