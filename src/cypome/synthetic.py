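"""Synthetic proteome cohorts with planted ground truth.

Real CYPome curation starts from downloaded fungal proteomes; this module
generates stand-ins whose truth is known by construction so every pipeline
stage can be exercised end to end:

* a named reference set of founder P450s (placeholder 9000-series CYP names,
  pairwise identity < 35%) with the ExxR and heme CxG motifs implanted;
* per-species proteomes whose members are founders mutated into controlled
  identity bands: (60, 75]% for same-subfamily calls, [42, 54]% for
  family-only calls, and a low band that founds new families — bands sit
  clear of the 40%/55% nomenclature thresholds so the expected call is
  unambiguous;
* fragments (truncations below 350 residues, or single-motif ablations),
  false-positive decoys (motif-ablated but still P450-like in identity) and
  no-hit decoys (random motif-free sequences, verified to stay below the
  false-positive identity heuristic);
* cluster tables with planted P450 membership mirroring anti-SMASH output.

Mutation is substitution-only, which keeps identity monotone in the number of
edits and makes band targeting a short guarded search.  A single
``numpy.random.default_rng(seed)`` drives all randomness, so equal seeds give
byte-identical cohorts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bgc import BgcCluster, BgcXrefEntry, GeneSpan
from .config import DEFAULT_RULES, RulesConfig
from .io import ProteinRecord, SpeciesMeta
from .nomenclature import NamedReference, percent_identity

AA20 = "ACDEFGHIKLMNPQRSTVWY"

CLUSTER_TYPES = ("terpene", "NRPS", "NRPS-like", "T1PKS", "fungal-RiPP")

DEFAULT_BANDS = {
    "same_subfamily": (60.0, 75.0),
    "same_family": (42.0, 54.0),
    "new_family": (20.0, 34.0),
}

DEFAULT_BAND_FRACTIONS = {
    "same_subfamily": 0.7,
    "same_family": 0.2,
    "new_family": 0.1,
}


class BandUnreachableError(RuntimeError):
    """Raised when substitution-only mutation cannot land in the band."""


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    Defaults describe a small but structurally faithful cohort: a handful of
    species split between saprotrophic and ectomycorrhizal lifestyles, member
    counts per species in the tens, fragment and decoy rates matching the
    proportions observed in the published curation (about 11% fragments and
    3% decoys of all hits).
    """

    seed: int = 0
    n_species: int = 4
    n_founder_families: int = 5
    members_per_species: int | dict[str, int] = 10
    lifestyle_assignment: Optional[dict[str, str]] = None
    identity_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    band_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_FRACTIONS))
    fragment_rate: float = 0.11
    decoy_rate: float = 0.03
    sequence_length: tuple[int, int] = (450, 550)
    # family -> species ids carrying it; None plants every family everywhere
    conserved_family_plan: Optional[dict[str, list[str]]] = None
    clusters_per_species: int = 3
    p450_clusters_per_species: int = 1
    # explicit per-species overrides (used for table-sized cohorts)
    fragments_per_species: Optional[dict[str, int]] = None
    false_positives_per_species: Optional[dict[str, int]] = None
    no_hits_per_species: Optional[dict[str, int]] = None
    rules: RulesConfig = field(default_factory=lambda: DEFAULT_RULES)

    def __post_init__(self) -> None:
        if not (0 <= self.fragment_rate <= 1 and 0 <= self.decoy_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.sequence_length
        if lo < self.rules.fragment_length_cutoff:
            raise ValueError("sequence_length must start at or above the "
                             "fragment cutoff")
        for name, (blo, bhi) in self.identity_bands.items():
            if not (0 <= blo <= bhi <= 100):
                raise ValueError(f"band {name}: bad range ({blo}, {bhi})")

    @property
    def species_ids(self) -> list[str]:
        if self.lifestyle_assignment:
            return list(self.lifestyle_assignment)
        return [f"SYN{i + 1:02d}" for i in range(self.n_species)]

    def lifestyles(self) -> dict[str, str]:
        if self.lifestyle_assignment:
            return dict(self.lifestyle_assignment)
        ids = self.species_ids
        n_sap = max(1, round(len(ids) * 5 / 19))  # observed 5 SAP of 19
        return {
            sid: ("SAP" if i < n_sap else "ECM") for i, sid in enumerate(ids)
        }

    def members_for(self, species_id: str) -> int:
        if isinstance(self.members_per_species, dict):
            return self.members_per_species[species_id]
        return int(self.members_per_species)

    @classmethod
    def table4_sized(cls, seed: int = 0,
                     n_founder_families: int = 8) -> "SyntheticSpec":
        """A 19-species cohort sized to the published per-species counts.

        Member, fragment, false-positive and no-hit counts per species are
        taken from the packaged table4 fixture, so the generated cohort has
        668 planted P450s, 88 fragments, 7 false positives and 16 no-hits.
        """
        from .fixtures import load_fixture
        t4 = load_fixture("table4")
        return cls(
            seed=seed,
            n_species=len(t4),
            n_founder_families=n_founder_families,
            members_per_species=dict(zip(t4.species_id, t4.p450s)),
            lifestyle_assignment=dict(zip(t4.species_id, t4.lifestyle)),
            fragments_per_species=dict(zip(t4.species_id, t4.fragments)),
            false_positives_per_species=dict(
                zip(t4.species_id, t4.false_positives)),
            no_hits_per_species=dict(zip(t4.species_id, t4.no_hits)),
        )


@dataclass
class Cohort:
    spec: SyntheticSpec
    references: list[NamedReference]
    proteomes: dict[str, list[ProteinRecord]]
    truth: pd.DataFrame
    species_meta: list[SpeciesMeta]
    clusters: list[BgcCluster]
    truth_xrefs: list[BgcXrefEntry]
    p450_gene_map: dict[str, str]


# ---------------------------------------------------------------------------
# sequence construction helpers

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _implant_motifs(seq: str, rng: np.random.Generator,
                    ) -> tuple[str, list[int]]:
    """Place an ExxR mid-sequence and a CxG in the C-terminal third.

    Returns the sequence and the protected (motif) positions.
    """
    chars = list(seq)
    L = len(chars)
    exxr_at = int(0.35 * L)
    chars[exxr_at] = "E"
    chars[exxr_at + 3] = "R"
    cxg_at = int(0.88 * L)
    chars[cxg_at] = "C"
    chars[cxg_at + 2] = "G"
    protected = [exxr_at, exxr_at + 1, exxr_at + 2, exxr_at + 3,
                 cxg_at, cxg_at + 1, cxg_at + 2]
    return "".join(chars), protected


def _strip_motifs(seq: str, rules: RulesConfig) -> str:
    """Remove every ExxR occurrence and every final-third CxG occurrence."""
    from .identify import scan_motifs
    chars = list(seq)
    for _ in range(50):
        hits = scan_motifs("".join(chars), rules)
        if not hits:
            return "".join(chars)
        for h in hits:
            # break the motif at its first fixed letter
            chars[h.start] = "A" if chars[h.start] != "A" else "G"
    raise RuntimeError("could not strip motifs after bounded attempts")


def mutate_to_band(sequence: str, band: tuple[float, float],
                   rng: np.random.Generator,
                   protected: Sequence[int] = (),
                   max_iter: int = 80) -> str:
    """Substitute residues until percent identity to the source lies in
    ``band``.

    Motif (``protected``) positions are never touched.  Raises
    :class:`BandUnreachableError` when the band cannot be reached with
    substitutions only (e.g. a zero-identity target while motifs are
    protected).
    """
    lo, hi = band
    if not (0 <= lo <= hi <= 100):
        raise ValueError(f"invalid band ({lo}, {hi})")
    L = len(sequence)
    protected_set = set(protected)
    free = [i for i in range(L) if i not in protected_set]
    # identity cannot fall below the protected fraction (plus chance matches)
    floor = 100.0 * (L - len(free)) / L
    if hi < floor + 3.0:
        raise BandUnreachableError(
            f"band ({lo}, {hi}) unreachable: identity floor ~{floor + 3:.1f}%"
            " with motif positions protected")
    target = float(rng.uniform(max(lo, floor + 5.0), hi))
    chars = list(sequence)
    original = list(sequence)
    n_subs = int(round(L * (1.0 - target / 100.0)))
    n_subs = min(n_subs, len(free))
    mutated = list(rng.choice(free, size=n_subs, replace=False))
    for pos in mutated:
        choices = [a for a in AA20 if a != original[pos]]
        chars[pos] = choices[int(rng.integers(len(choices)))]

    for _ in range(max_iter):
        ident = percent_identity("".join(chars), sequence)
        if lo <= ident <= hi:
            return "".join(chars)
        if ident > hi:  # not diverged enough: add substitutions
            remaining = [i for i in free if i not in mutated]
            if not remaining:
                raise BandUnreachableError(
                    f"band ({lo}, {hi}) unreachable: all free positions used")
            step = max(1, int(L * (ident - hi) / 100.0 / 2))
            step = min(step, len(remaining))
            extra = list(rng.choice(remaining, size=step, replace=False))
            for pos in extra:
                choices = [a for a in AA20 if a != original[pos]]
                chars[pos] = choices[int(rng.integers(len(choices)))]
            mutated.extend(extra)
        else:  # overshot: revert some substitutions
            if not mutated:
                raise BandUnreachableError(
                    f"band ({lo}, {hi}) unreachable from this sequence")
            step = max(1, int(L * (lo - ident) / 100.0 / 2))
            step = min(step, len(mutated))
            for _ in range(step):
                pos = mutated.pop()
                chars[pos] = original[pos]
    raise BandUnreachableError(
        f"did not converge into band ({lo}, {hi}) after {max_iter} rounds")


# ---------------------------------------------------------------------------
# reference set

def make_reference_set(spec: SyntheticSpec,
                       rng: Optional[np.random.Generator] = None,
                       max_resample: int = 50,
                       ) -> tuple[list[NamedReference], dict[str, list[int]]]:
    """Founder references CYP9001A1, CYP9002A1, ... with implanted motifs.

    All founders are pairwise < 35% identical (offending founders are
    resampled).  Returns the references and each founder's protected motif
    positions (needed to mutate members without destroying motifs).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    lo, hi = spec.sequence_length
    refs: list[NamedReference] = []
    protected: dict[str, list[int]] = {}
    for k in range(spec.n_founder_families):
        name = f"CYP{9001 + k}A1"
        for attempt in range(max_resample):
            length = int(rng.integers(lo, hi + 1))
            seq, prot = _implant_motifs(_random_sequence(rng, length), rng)
            if all(percent_identity(seq, r.sequence) < 35.0 for r in refs):
                refs.append(NamedReference(cyp_name=name, sequence=seq))
                protected[name] = prot
                break
        else:
            raise RuntimeError(
                f"could not generate founder {name} with pairwise identity "
                f"< 35% after {max_resample} attempts")
    return refs, protected


# ---------------------------------------------------------------------------
# cohort generation

_EXPECTED_SUBFAMILY = {
    "same_subfamily": "A",       # founders are all subfamily A members
    "same_family": "NEW",
    "new_family": "NEW",
}


def _plan_or_default(spec: SyntheticSpec,
                     families: Sequence[str]) -> dict[str, list[str]]:
    if spec.conserved_family_plan is None:
        return {fam: list(spec.species_ids) for fam in families}
    unknown_species = {
        s for members in spec.conserved_family_plan.values() for s in members
    } - set(spec.species_ids)
    if unknown_species:
        raise ValueError(
            f"conserved_family_plan references unknown species: "
            f"{sorted(unknown_species)}")
    unknown_fams = set(spec.conserved_family_plan) - set(families)
    if unknown_fams:
        raise ValueError(
            f"conserved_family_plan references unknown families: "
            f"{sorted(unknown_fams)}")
    return {f: list(s) for f, s in spec.conserved_family_plan.items()}


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Generate proteomes, truth labels and cluster tables for one cohort."""
    rng = np.random.default_rng(spec.seed)
    refs, protected = make_reference_set(spec, rng)
    by_name = {r.cyp_name: r for r in refs}
    families = [r.family for r in refs]
    fam_to_ref = {r.family: r for r in refs}
    plan = _plan_or_default(spec, families)
    lifestyles = spec.lifestyles()
    rules = spec.rules

    band_names = list(spec.band_fractions)
    band_probs = np.array([spec.band_fractions[b] for b in band_names])
    band_probs = band_probs / band_probs.sum()

    proteomes: dict[str, list[ProteinRecord]] = {}
    truth_rows: list[dict] = []
    serial = 0

    def next_id(species: str) -> str:
        nonlocal serial
        serial += 1
        return f"{species}_p{serial:04d}"

    for species in spec.species_ids:
        records: list[ProteinRecord] = []
        local_families = [f for f in families if species in plan.get(f, [])]
        if not local_families:
            raise ValueError(f"no families planted in species {species!r}")
        n_members = spec.members_for(species)

        # --- true P450 members, founders mutated into identity bands
        for m in range(n_members):
            fam = local_families[m % len(local_families)]
            ref = fam_to_ref[fam]
            band_name = band_names[int(rng.choice(len(band_names),
                                                  p=band_probs))]
            seq = mutate_to_band(ref.sequence, spec.identity_bands[band_name],
                                 rng, protected[ref.cyp_name])
            pid = next_id(species)
            records.append(ProteinRecord(pid, species, seq))
            truth_rows.append({
                "protein_id": pid, "species_id": species,
                "category": "P450", "band": band_name,
                "family": fam if band_name != "new_family" else "NEW",
                "subfamily": _EXPECTED_SUBFAMILY[band_name],
            })

        # --- fragments: truncations or single-motif ablations
        if spec.fragments_per_species is not None:
            n_frag = spec.fragments_per_species.get(species, 0)
        else:
            n_frag = int(round(spec.fragment_rate * n_members))
        for _ in range(n_frag):
            ref = fam_to_ref[local_families[int(rng.integers(
                len(local_families)))]]
            seq = mutate_to_band(ref.sequence,
                                 spec.identity_bands["same_subfamily"],
                                 rng, protected[ref.cyp_name])
            if rng.random() < 0.5:
                # truncate below the length cutoff but keep the ExxR motif
                exxr_end = protected[ref.cyp_name][3] + 1
                cut = int(rng.integers(max(exxr_end + 5, 250),
                                       rules.fragment_length_cutoff))
                seq = seq[:cut]
            else:
                # ablate the ExxR motif, leaving the heme CxG only
                chars = list(seq)
                for _ in range(30):
                    ms = [m.start() for m in re.finditer(
                        r"(?=(E[A-Z]{2}R))", "".join(chars))]
                    if not ms:
                        break
                    for s in ms:
                        chars[s] = "A"
                seq = "".join(chars)
            pid = next_id(species)
            records.append(ProteinRecord(pid, species, seq))
            truth_rows.append({
                "protein_id": pid, "species_id": species,
                "category": "FRAGMENT", "band": "",
                "family": "", "subfamily": "",
            })

        # --- false positives: P450-like identity, both motifs ablated
        n_fp = (spec.false_positives_per_species or {}).get(species, 0)
        for _ in range(n_fp):
            ref = fam_to_ref[local_families[int(rng.integers(
                len(local_families)))]]
            for _ in range(30):
                seq = mutate_to_band(ref.sequence, (27.0, 34.0), rng,
                                     protected[ref.cyp_name])
                seq = _strip_motifs(seq, rules)
                ident = max(percent_identity(seq, r.sequence) for r in refs)
                if ident >= rules.false_positive_identity_threshold + 2.0:
                    break
            else:
                raise RuntimeError("could not build a false-positive decoy")
            pid = next_id(species)
            records.append(ProteinRecord(pid, species, seq))
            truth_rows.append({
                "protein_id": pid, "species_id": species,
                "category": "FALSE_POSITIVE", "band": "",
                "family": "", "subfamily": "",
            })

        # --- no-hit decoys: random motif-free sequences, dissimilar to refs
        if spec.no_hits_per_species is not None:
            n_nohit = spec.no_hits_per_species.get(species, 0)
        else:
            n_nohit = int(round(spec.decoy_rate * n_members))
        for _ in range(n_nohit):
            for _ in range(30):
                length = int(rng.integers(*spec.sequence_length))
                seq = _strip_motifs(_random_sequence(rng, length), rules)
                ident = max(percent_identity(seq, r.sequence) for r in refs)
                if ident < rules.false_positive_identity_threshold - 2.0:
                    break
            else:
                raise RuntimeError("could not build a no-hit decoy")
            pid = next_id(species)
            records.append(ProteinRecord(pid, species, seq))
            truth_rows.append({
                "protein_id": pid, "species_id": species,
                "category": "NO_HIT", "band": "",
                "family": "", "subfamily": "",
            })

        proteomes[species] = records

    # --- cluster tables with planted P450 membership
    clusters: list[BgcCluster] = []
    truth_xrefs: list[BgcXrefEntry] = []
    gene_map: dict[str, str] = {}
    truth_df = pd.DataFrame(truth_rows)
    for species in spec.species_ids:
        members = truth_df[(truth_df.species_id == species)
                           & (truth_df.category == "P450")]
        p450_slots = sorted(rng.choice(
            spec.clusters_per_species,
            size=min(spec.p450_clusters_per_species,
                     spec.clusters_per_species),
            replace=False))
        for c in range(spec.clusters_per_species):
            ctype = CLUSTER_TYPES[int(rng.integers(len(CLUSTER_TYPES)))]
            base = 1 + c * 50_000
            genes = [
                GeneSpan(f"{species}_c{c + 1:02d}_g{g}", base + g * 3_000,
                         base + g * 3_000 + 1_500,
                         "+" if rng.random() < 0.5 else "-")
                for g in range(1, 4)
            ]
            cluster = BgcCluster(species, c + 1, ctype, genes)
            if c in p450_slots and len(members):
                row = members.iloc[int(rng.integers(len(members)))]
                span = GeneSpan(row.protein_id, base + 20_000,
                                base + 21_500, "+")
                cluster.member_genes.append(span)
                label = (row.family if row.family != "NEW" else "CYPNEW")
                gene_map[row.protein_id] = label
                truth_xrefs.append(BgcXrefEntry(
                    species_id=species, cluster_index=c + 1,
                    cluster_type=ctype, p450_name=label,
                    gene_id=row.protein_id))
            clusters.append(cluster)
    truth_xrefs.sort(
        key=lambda e: (e.species_id, e.cluster_index, e.gene_id))

    meta = [
        SpeciesMeta(sid, sid, lifestyles[sid]) for sid in spec.species_ids
    ]
    return Cohort(
        spec=spec,
        references=refs,
        proteomes=proteomes,
        truth=truth_df,
        species_meta=meta,
        clusters=clusters,
        truth_xrefs=truth_xrefs,
        p450_gene_map=gene_map,
    )


def evaluate_triage(truth: pd.DataFrame, results) -> float:
    """Fraction of proteins whose triage category matches the planted truth."""
    called = {r.protein_id: r.category.value for r in results}
    ok = sum(
        1 for row in truth.itertuples()
        if called.get(row.protein_id) == row.category
    )
    return ok / len(truth)


def evaluate_assignments(truth: pd.DataFrame, assignments) -> dict[str, float]:
    """Family/subfamily recovery of planted labels among true P450s.

    A family call is correct when it matches the planted founder family, or —
    for members planted below the family threshold — when the assignment
    founds a new family.  A subfamily call is correct when the label matches
    the planted expectation ('A' for same-subfamily members, NEW otherwise).
    """
    t = truth[truth.category == "P450"].set_index("protein_id")
    by_id = {a.query_id: a for a in assignments}
    fam_ok = sub_ok = 0
    for pid, row in t.iterrows():
        a = by_id[pid]
        if row.family == "NEW":
            good_fam = a.is_new_family
        else:
            good_fam = (not a.is_new_family) and a.family_label == row.family
        good_sub = a.subfamily_label == row.subfamily or (
            row.subfamily == "NEW" and a.is_new_family)
        fam_ok += good_fam
        sub_ok += good_fam and good_sub
    n = len(t)
    return {
        "family_recovery": fam_ok / n if n else 1.0,
        "subfamily_recovery": sub_ok / n if n else 1.0,
        "n_p450s": n,
    }


def cluster_table(clusters: Sequence[BgcCluster]) -> pd.DataFrame:
    """Flatten clusters into the TSV contract consumed by the bgc module."""
    rows = [
        {
            "species_id": c.species_id,
            "cluster_index": c.cluster_index,
            "cluster_type": c.cluster_type,
            "gene_id": g.gene_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
        }
        for c in clusters for g in c.member_genes
    ]
    return pd.DataFrame(rows, columns=[
        "species_id", "cluster_index", "cluster_type", "gene_id",
        "start", "end", "strand",
    ])
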