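"""Shared configuration for the CYPome curation rules.

All thresholds used across the pipeline live in :class:`RulesConfig` so that a
single object documents the curation conventions: the International P450
Nomenclature identity cut-offs (>40% family, >55% subfamily), the 350-residue
fragment rule, the borderline band around the subfamily threshold that triggers
phylogeny-assisted resolution, and the presence/absence codes used by the
conservation heatmap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    This is the convention used for every reported per-species average
    (e.g. 580/19 = 30.53 -> 31, 142/12 = 11.83 -> 12), as opposed to Python's
    banker's rounding.
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class AlignScoring:
    """Pairwise global-alignment scoring used for percent identity.

    BLOSUM62 with affine gaps: the first residue of a gap costs ``gap_open``,
    every further residue ``gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes and must be >= 0")


@dataclass(frozen=True)
class RulesConfig:
    """Curation rule set; defaults reproduce the published analysis."""

    family_identity_threshold: float = 40.0
    subfamily_identity_threshold: float = 55.0
    fragment_length_cutoff: int = 350
    borderline_band_halfwidth: float = 2.0
    bloom_member_threshold: int = 30
    false_positive_identity_threshold: float = 20.0
    presence_code: int = 3
    absence_code: int = -3
    # Motif patterns: the K-helix salt bridge (ExxR) may occur anywhere; the
    # heme-ligand CxG is restricted to the C-terminal third, where the axial
    # cysteine sits.  Fixed letters are literal; '.' spans the canonical
    # alphabet plus X.
    exxr_pattern: str = "E..R"
    cxg_pattern: str = "C.G"
    linkage_method: str = "average"
    scoring: AlignScoring = field(default_factory=AlignScoring)

    def __post_init__(self) -> None:
        if not (0 < self.family_identity_threshold
                < self.subfamily_identity_threshold < 100):
            raise ValueError(
                "need 0 < family threshold < subfamily threshold < 100")
        if self.fragment_length_cutoff <= 0:
            raise ValueError("fragment_length_cutoff must be positive")
        if self.borderline_band_halfwidth < 0:
            raise ValueError("borderline_band_halfwidth must be >= 0")
        if self.presence_code == self.absence_code:
            raise ValueError("presence and absence codes must differ")


DEFAULT_RULES = RulesConfig()
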