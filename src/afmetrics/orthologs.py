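"""Curation of homology-search hit tables into presence/absence calls.

The screen turns raw BLAST-style hit tables for the six ORC subunits and
MCM2 into a species x subunit presence matrix, applying the rules used in
large phylogenetic-profiling studies of the replication-licensing
machinery: identity floors to reject false positives (misassigned
subunits, CDC6-like homologs), highest-query-coverage representative
selection, taxon-level inclusion rules, subunit-loss calls, sequence QC
(undetermined residues, partial sequences), and diversity-aware
representative subsetting.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from afmetrics.types import HitRecord, PresenceMatrix, ORC_SUBUNITS

__all__ = [
    "IdentityFloors",
    "QCAnnotation",
    "call_orthologs",
    "taxon_inclusion",
    "classify_orc6_status",
    "sequence_qc",
    "select_representatives",
]

ORC6_POSITIVE = "ORC6-positive"
ORC6_NEGATIVE = "ORC6-negative"
ORC6_UNDETERMINED = "undetermined"


@dataclass
class IdentityFloors:
    """Per-subunit percent-identity floors, overridable per taxon group.

    Floors below which a hit is discarded as a false positive. They vary
    by subunit and taxonomic group in practice; the defaults are 50% for
    MCM2 and 30% for the ORC subunits (CDC6-like false positives sit
    below 30% identity), and ``per_taxon[(taxon_group, subunit)]``
    overrides take precedence.
    """

    default: float = 30.0
    per_subunit: dict[str, float] = field(
        default_factory=lambda: {"MCM2": 50.0}
    )
    per_taxon: dict[tuple[str, str], float] = field(default_factory=dict)

    def floor(self, subunit: str, taxon_group: str = "") -> float:
        if (taxon_group, subunit) in self.per_taxon:
            return self.per_taxon[(taxon_group, subunit)]
        return self.per_subunit.get(subunit, self.default)


def _representative_key(hit: HitRecord) -> tuple:
    """Sort key for representative selection: highest query coverage wins;
    ties break on higher percent identity, then smallest accession."""
    return (-hit.query_coverage, -hit.percent_identity, hit.accession)


def call_orthologs(
    hits: list[HitRecord], floors: IdentityFloors | None = None
) -> PresenceMatrix:
    """Presence/absence matrix from a hit table.

    Hits below the identity floor for their subunit (and taxon group) are
    discarded; a (species, subunit) is called present if at least one hit
    survives, and the surviving hit with the highest query coverage is
    retained as the representative sequence.
    """
    floors = floors or IdentityFloors()
    matrix = PresenceMatrix()
    surviving: dict[tuple[str, str], list[HitRecord]] = defaultdict(list)
    for hit in hits:
        matrix.taxon_of.setdefault(hit.species, hit.taxon_group)
        if hit.percent_identity >= floors.floor(hit.query_subunit, hit.taxon_group):
            surviving[(hit.species, hit.query_subunit)].append(hit)
    for key, group in surviving.items():
        matrix.entries[key] = True
        matrix.representative[key] = min(group, key=_representative_key).accession
    return matrix


def taxon_inclusion(matrix: PresenceMatrix) -> set[str]:
    """Taxon groups to exclude from the study.

    A group is excluded iff two or more of the six ORC subunits have no
    present call in any species of the group — one absent subunit (the
    ORC6-loss signal itself) never disqualifies a group.
    """
    excluded = set()
    for group in matrix.groups:
        species = matrix.species_in_group(group)
        n_missing = sum(
            1
            for sub in ORC_SUBUNITS
            if not any(matrix.present(sp, sub) for sp in species)
        )
        if n_missing >= 2:
            excluded.add(group)
    return excluded


def classify_orc6_status(matrix: PresenceMatrix) -> dict[str, str]:
    """Group-level ORC6 loss call.

    A group is ORC6-negative when no species in it has an ORC6 ortholog
    while each of ORC1-5 is reliably present in at least one species of
    the group; it is ORC6-positive when any species has ORC6. Groups with
    neither condition met (additional core subunits missing) are flagged
    undetermined — they would normally be excluded upstream.
    """
    status: dict[str, str] = {}
    for group in matrix.groups:
        species = matrix.species_in_group(group)
        if any(matrix.present(sp, "ORC6") for sp in species):
            status[group] = ORC6_POSITIVE
        elif all(
            any(matrix.present(sp, sub) for sp in species)
            for sub in ("ORC1", "ORC2", "ORC3", "ORC4", "ORC5")
        ):
            status[group] = ORC6_NEGATIVE
        else:
            status[group] = ORC6_UNDETERMINED
    return status


@dataclass
class QCAnnotation:
    """Domain-level facts needed by the sequence-QC rules.

    For a partial ORC3 sequence, whether the truncation falls within the
    insertion domain (where both the binding domain and the tether live);
    for a partial MCM2, whether the N-terminal tether-interaction region
    is missing.
    """

    truncation_in_insertion_domain: bool = False
    missing_nterm_domain: bool = False


def sequence_qc(
    candidates: list[HitRecord],
    annotations: dict[str, QCAnnotation] | None = None,
    group_sizes: dict[str, int] | None = None,
    small_group_max: int = 10,
) -> tuple[list[HitRecord], dict[str, str]]:
    """Quality-control filter for sequences entering structure prediction.

    Rules, with the reason logged per rejected accession:

    * any sequence with undetermined ``X`` residues is rejected;
    * a partial ORC3 is rejected if its truncation lies within the
      insertion domain, and otherwise accepted only for data-poor groups
      (fewer than ``small_group_max`` species);
    * a partial MCM2 is rejected only if the N-terminal domain that
      interacts with the ORC3 tether is missing.

    ``group_sizes`` defaults to the number of distinct species per taxon
    group among the candidates.
    """
    annotations = annotations or {}
    if group_sizes is None:
        by_group: dict[str, set[str]] = defaultdict(set)
        for hit in candidates:
            by_group[hit.taxon_group].add(hit.species)
        group_sizes = {g: len(sp) for g, sp in by_group.items()}

    accepted: list[HitRecord] = []
    reasons: dict[str, str] = {}
    for hit in candidates:
        ann = annotations.get(hit.accession, QCAnnotation())
        if hit.has_x_residues:
            reasons[hit.accession] = "X-residues"
            continue
        if hit.is_partial and hit.query_subunit == "ORC3":
            if ann.truncation_in_insertion_domain:
                reasons[hit.accession] = "partial: truncated within insertion domain"
                continue
            if group_sizes.get(hit.taxon_group, 0) >= small_group_max:
                reasons[hit.accession] = (
                    "partial: group has sufficient full-length data"
                )
                continue
        if hit.is_partial and hit.query_subunit == "MCM2":
            if ann.missing_nterm_domain:
                reasons[hit.accession] = "partial: missing N-terminal domain"
                continue
        reasons[hit.accession] = "accepted"
        accepted.append(hit)
    return accepted, reasons


def select_representatives(
    accepted: list[HitRecord],
    group_caps: dict[str, int],
    diversity_key: dict[str, str],
) -> list[HitRecord]:
    """Cap each taxon group at ``group_caps[group]`` sequences, maximizing
    taxonomic diversity.

    Greedy round-robin: within a group, one species per distinct
    ``diversity_key`` value (order/class label) is taken before any key
    contributes a second member. Groups without a cap pass through whole.
    Deterministic: species are visited in sorted order within sorted keys.
    """
    by_group: dict[str, list[HitRecord]] = defaultdict(list)
    for hit in accepted:
        by_group[hit.taxon_group].append(hit)

    chosen: list[HitRecord] = []
    for group in sorted(by_group):
        members = by_group[group]
        cap = group_caps.get(group)
        if cap is None or cap >= len(members):
            chosen.extend(sorted(members, key=lambda h: (h.species, h.accession)))
            continue
        by_key: dict[str, list[HitRecord]] = defaultdict(list)
        for hit in members:
            by_key[diversity_key.get(hit.species, hit.species)].append(hit)
        for key in by_key:
            by_key[key].sort(key=lambda h: (h.species, h.accession))
        picked: list[HitRecord] = []
        round_no = 0
        while len(picked) < cap:
            took_any = False
            for key in sorted(by_key):
                if len(picked) >= cap:
                    break
                if round_no < len(by_key[key]):
                    picked.append(by_key[key][round_no])
                    took_any = True
            if not took_any:
                break
            round_no += 1
        chosen.extend(picked)
    return chosen
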