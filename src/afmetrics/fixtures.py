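"""Synthetic AlphaFold-style inputs with exactly known ground truth.

Real multimer screens of this kind rest on thousands of GPU-generated
predictions that cannot be regenerated at desk scale, so every downstream
stage here is exercised on constructed mock inputs instead: five-model
two-chain "predictions" whose inter-chain contacts are *placed*, not
sampled, together with matching pLDDT vectors, pAE matrices and ipTM
values, plus toy alignments and homology hit tables.

Geometry is by construction. Chains are laid out on widely separated
rails (20 Å between neighbouring residues, 1000 Å between chains);
a designated contact pair is realised by moving the partner residue to
4-6 Å from its counterpart, which guarantees the pair — and nothing
else — falls under the 8 Å contact cutoff. Ground truth is therefore
exact, and files regenerate byte-identically from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from afmetrics import af_io
from afmetrics._geom import place_atom
from afmetrics.types import (
    Alignment,
    Atom,
    ChainRecord,
    ConfidenceBundle,
    DomainRange,
    HitRecord,
    MultimerPrediction,
    PredictedModel,
    Residue,
)

# rail layout: residue centres 20 Å apart along x, chains 1000 Å apart in y;
# contact distance 5 Å +- jitter keeps every placed pair under the 8 Å
# cutoff and every unplaced pair beyond 10 Å
_RAIL_SPACING = 20.0
_CHAIN_OFFSET = 1000.0
_CONTACT_DIST = 5.0
_CONTACT_JITTER = 0.5

#: offsets of the residue's atoms from its centre (name, element, dx, dy, dz)
_RESIDUE_ATOMS = (
    ("N", "N", -0.7, -0.7, 0.0),
    ("CA", "C", 0.0, 0.0, 0.0),
    ("C", "C", 0.7, 0.7, 0.0),
    ("O", "O", 0.9, -0.5, 0.4),
    ("HA", "H", 0.3, 0.3, 0.8),
)

DECOY_PLDDT = 45.0


@dataclass
class FixtureSpec:
    """Recipe for one five-model two-chain mock prediction."""

    interface_pairs: list[tuple[int, int]]
    chain_lengths: tuple[int, int] = (30, 30)
    n_models: int = 5
    shared_fraction: float = 1.0
    plddt_background: float = 90.0
    plddt_decoy_pairs: list[tuple[int, int]] = field(default_factory=list)
    pae_interface: float = 4.0
    pae_background: float = 10.0
    iptm: float = 0.8
    seed: int = 0
    target_id: str = "fixture"
    chain_roles: dict[str, str] = field(
        default_factory=lambda: {"A": "ORC3", "B": "ORC6"}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        la, lb = self.chain_lengths
        all_pairs = list(self.interface_pairs) + list(self.plddt_decoy_pairs)
        for i, j in all_pairs:
            if not (1 <= i <= la and 1 <= j <= lb):
                raise ValueError(
                    f"pair ({i}, {j}) outside chains of lengths {la}, {lb}"
                )
        # each residue may take part in at most one designated pair: a
        # residue cannot be placed at two contact sites at once, and a
        # sub-50 decoy residue would silently erase a true contact
        a_res = [i for i, _ in all_pairs]
        b_res = [j for _, j in all_pairs]
        if len(set(a_res)) != len(a_res) or len(set(b_res)) != len(b_res):
            raise ValueError(
                "infeasible geometry: designated pairs reuse a residue"
            )


def _pairs_per_model(spec: FixtureSpec) -> list[set[tuple[int, int]]]:
    """Ground-truth interface pairs placed in each model.

    The first ``round(shared_fraction * k)`` pairs appear in every model;
    each remaining pair appears in exactly one model, assigned round-robin.
    """
    k = len(spec.interface_pairs)
    n_shared = int(round(spec.shared_fraction * k))
    shared = spec.interface_pairs[:n_shared]
    singles = spec.interface_pairs[n_shared:]
    per_model: list[set[tuple[int, int]]] = [
        set(shared) for _ in range(spec.n_models)
    ]
    for ordinal, pair in enumerate(singles):
        per_model[ordinal % spec.n_models].add(pair)
    return per_model


def expected_average_models(spec: FixtureSpec) -> float:
    """Analytic *average models* score implied by the construction.

    With ``s`` pairs shared by all ``n`` models and ``u`` singletons the
    filtered union has ``s + u`` members and the score is
    ``(n*s + u) / (n * (s + u))``; an empty union scores 0. Decoy pairs
    never contribute (they are filtered out by the pLDDT rule).
    """
    k = len(spec.interface_pairs)
    if k == 0:
        return 0.0
    s = int(round(spec.shared_fraction * k))
    u = k - s
    return (spec.n_models * s + u) / (spec.n_models * (s + u))


def _residue(center: np.ndarray, index: int, plddt: float) -> Residue:
    atoms = [
        Atom(name, elem, center[0] + dx, center[1] + dy, center[2] + dz)
        for name, elem, dx, dy, dz in _RESIDUE_ATOMS
    ]
    return Residue(index=index, name="ALA", atoms=atoms, plddt=plddt)


def build_multimer(spec: FixtureSpec) -> MultimerPrediction:
    """Construct the five-model prediction in memory.

    Every designated pair (interface and decoy) placed in a model is
    guaranteed to be the *only* residue pair of that model with any
    non-hydrogen atoms closer than 8 Å across chains.
    """
    la, lb = spec.chain_lengths
    per_model = _pairs_per_model(spec)
    decoys = set(spec.plddt_decoy_pairs)
    decoy_res_a = {i for i, _ in decoys}
    decoy_res_b = {j for _, j in decoys}
    chain_a_id, chain_b_id = list(spec.chain_roles)[:2]

    models = []
    for m in range(spec.n_models):
        rng = np.random.default_rng(spec.seed + m)
        placed = per_model[m] | decoys  # decoys are in contact in every model
        b_site = {j: i for i, j in placed}

        res_a = [
            _residue(
                np.array([(i - 1) * _RAIL_SPACING, 0.0, 0.0]),
                i,
                DECOY_PLDDT if i in decoy_res_a else spec.plddt_background,
            )
            for i in range(1, la + 1)
        ]
        res_b = []
        for j in range(1, lb + 1):
            if j in b_site:
                i = b_site[j]
                d = _CONTACT_DIST + rng.uniform(-_CONTACT_JITTER, _CONTACT_JITTER)
                center = np.array([(i - 1) * _RAIL_SPACING, d, 0.0])
            else:
                center = np.array(
                    [(j - 1) * _RAIL_SPACING, _CHAIN_OFFSET, 0.0]
                )
            res_b.append(
                _residue(
                    center,
                    j,
                    DECOY_PLDDT if j in decoy_res_b else spec.plddt_background,
                )
            )

        model = PredictedModel(
            model_id=f"{spec.target_id}_model_{m}",
            chains=[
                ChainRecord(chain_id=chain_a_id, residues=res_a),
                ChainRecord(chain_id=chain_b_id, residues=res_b),
            ],
        )
        pae = np.full((la + lb, la + lb), spec.pae_background, dtype=float)
        for i, j in placed:
            pae[i - 1, la + j - 1] = spec.pae_interface
            pae[la + j - 1, i - 1] = spec.pae_interface
        conf = ConfidenceBundle(pae=pae, iptm=spec.iptm, ptm=spec.iptm)
        models.append((model, conf))

    return MultimerPrediction(
        target_id=spec.target_id, models=models, chain_roles=dict(spec.chain_roles)
    )


def gen_multimer(spec: FixtureSpec, out_dir: Path | str) -> list[tuple[Path, Path]]:
    """Write the five structure files (PDB) and five confidence files (JSON).

    Returns the ``(structure_path, confidence_path)`` pair per model.
    Deterministic: the same spec and seed regenerate byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prediction = build_multimer(spec)
    paths = []
    for model, conf in prediction.models:
        spath = out_dir / f"{model.model_id}.pdb"
        cpath = out_dir / f"{model.model_id}_scores.json"
        af_io.write_structure(model, spath)
        af_io.write_confidence(conf, cpath)
        paths.append((spath, cpath))
    return paths


# --- monomer domain fixtures -------------------------------------------------

_HELIX_PHI, _HELIX_PSI = -57.0, -47.0  # ideal alpha helix
_COIL_PHI, _COIL_PSI = -140.0, 145.0  # extended, outside any helix window
_OMEGA = 180.0

# backbone internal coordinates (Engh-Huber-like)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.6, 121.7

DOMAIN_KINDS = ("three_helix", "degenerate_missing_helix", "no_domain")


def _build_backbone(
    phis: list[float], psis: list[float]
) -> list[list[np.ndarray]]:
    """N/CA/C coordinates for a chain with the given per-residue dihedrals.

    Measured phi/psi of the built chain equal the requested values exactly
    (phi of residue 0 is undefined; its entry is ignored).
    """
    n = len(phis)
    coords: list[list[np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    theta = np.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    coords.append([n0, ca0, c0])
    for i in range(1, n):
        n_prev, ca_prev, c_prev = coords[-1]
        ni = place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psis[i - 1])
        cai = place_atom(ca_prev, c_prev, ni, _B_N_CA, _A_C_N_CA, _OMEGA)
        ci = place_atom(c_prev, ni, cai, _B_CA_C, _A_N_CA_C, phis[i])
        coords.append([ni, cai, ci])
    return coords


def _dihedral_schedule(kind: str, helix_len: int, loop_len: int) -> list[str]:
    n_helices = {"three_helix": 3, "degenerate_missing_helix": 2, "no_domain": 0}[
        kind
    ]
    states = ["L"] * loop_len
    for _ in range(n_helices):
        states += ["H"] * helix_len + ["L"] * loop_len
    if n_helices == 0:
        states = ["L"] * (3 * helix_len + 2 * loop_len)
    return states


def gen_domain_structure(
    kind: str,
    seed: int = 0,
    helix_len: int = 10,
    loop_len: int = 4,
    plddt: float = 85.0,
    chain_id: str = "A",
    model_id: str | None = None,
) -> PredictedModel:
    """Single-chain monomer with an ideal-geometry domain of known topology.

    ``three_helix`` builds three alpha-helical segments (phi = -57 deg,
    psi = -47 deg) of ``helix_len`` residues joined by extended loops —
    the canonical fold of a conserved three-helix binding motif.
    ``degenerate_missing_helix`` builds only two; ``no_domain`` is coil
    throughout. Construction is deterministic; the seed is folded into
    the default model identifier so cohorts of fixtures get distinct
    names.
    """
    if kind not in DOMAIN_KINDS:
        raise ValueError(f"unknown domain kind {kind!r}; one of {DOMAIN_KINDS}")
    states = _dihedral_schedule(kind, helix_len, loop_len)
    phis = [_HELIX_PHI if s == "H" else _COIL_PHI for s in states]
    psis = [_HELIX_PSI if s == "H" else _COIL_PSI for s in states]
    coords = _build_backbone(phis, psis)
    residues = []
    for i, (ni, cai, ci) in enumerate(coords, start=1):
        atoms = [
            Atom("N", "N", *ni),
            Atom("CA", "C", *cai),
            Atom("C", "C", *ci),
        ]
        residues.append(Residue(index=i, name="ALA", atoms=atoms, plddt=plddt))
    return PredictedModel(
        model_id=model_id or f"{kind}_{seed}",
        chains=[ChainRecord(chain_id=chain_id, residues=residues)],
    )


def domain_window(
    kind: str, helix_len: int = 10, loop_len: int = 4, seq_id: str = "fixture"
) -> DomainRange:
    """The residue window spanning the constructed domain (all three helix
    slots including their joining loops), matching gen_domain_structure."""
    start = loop_len + 1
    end = loop_len + 3 * helix_len + 2 * loop_len
    return DomainRange(seq_id=seq_id, domain_name="ORC6_BD", start=start, end=end)


# --- alignment fixtures ------------------------------------------------------

_AMINO = "ACDEFGHIKLMNPQRSTVWY"


def gen_alignment(
    n_rows: int,
    ref_domain_range: tuple[int, int],
    degenerate_rows: set[int] | frozenset[int] = frozenset(),
    seq_len: int = 120,
    seed: int = 0,
    conserved_mismatch_rate: float = 0.2,
    degenerate_gap_fraction: float = 0.6,
) -> Alignment:
    """Toy MSA: a reference plus conserved and degenerate rows.

    Row 0 is the ungapped reference ``REF``. Conserved rows match the
    reference at >= 70% of the domain columns; rows whose ordinal is in
    ``degenerate_rows`` instead carry a contiguous gap block across >= 50%
    of the domain columns starting at the domain start, emulating the
    gap-riddled alignments of orthologs that lost the domain.
    """
    rng = np.random.default_rng(seed)
    start, end = ref_domain_range
    if not 1 <= start <= end <= seq_len:
        raise ValueError("ref_domain_range outside sequence")
    ref = "".join(rng.choice(list(_AMINO), size=seq_len))
    rows: list[tuple[str, str]] = [("REF", ref)]
    n_gap = max(int(np.ceil(degenerate_gap_fraction * (end - start + 1))), 1)
    for r in range(1, n_rows):
        chars = list(ref)
        for c in range(seq_len):
            if rng.random() < conserved_mismatch_rate:
                choices = [a for a in _AMINO if a != ref[c]]
                chars[c] = choices[rng.integers(len(choices))]
        if r in degenerate_rows:
            for c in range(start - 1, start - 1 + n_gap):
                chars[c] = "-"
        rows.append((f"seq{r:03d}", "".join(chars)))
    return Alignment(rows=rows)


# --- hit-table fixtures ------------------------------------------------------


def gen_hit_table(
    subunits_present: dict[str, set[str]],
    taxon_of: dict[str, str] | None = None,
    false_positive_rate: float = 0.2,
    seed: int = 0,
) -> list[HitRecord]:
    """Mock homology hit table with known presence/absence ground truth.

    True orthologs get percent identity in [50, 90]; false positives
    (misassigned subunits, CDC6-like homologs) get identity below 30 and
    may appear for any (species, subunit), including subunits the species
    genuinely lacks. A species lacking a subunit never receives a
    true-ortholog row for it, so any surviving call for it downstream is a
    screening error by construction.
    """
    from afmetrics.types import ALL_SUBUNITS

    rng = np.random.default_rng(seed)
    taxon_of = taxon_of or {}
    hits: list[HitRecord] = []
    for species in sorted(subunits_present):
        group = taxon_of.get(species, "GroupA")
        for subunit in ALL_SUBUNITS:
            if subunit in subunits_present[species]:
                hits.append(
                    HitRecord(
                        query_subunit=subunit,
                        species=species,
                        taxon_group=group,
                        accession=f"{species}_{subunit}_T1",
                        percent_identity=float(rng.uniform(50, 90)),
                        query_coverage=float(rng.uniform(70, 99)),
                        sequence_length=int(rng.integers(300, 800)),
                        search_method="blastp",
                    )
                )
            if rng.random() < false_positive_rate:
                hits.append(
                    HitRecord(
                        query_subunit=subunit,
                        species=species,
                        taxon_group=group,
                        accession=f"{species}_{subunit}_FP",
                        percent_identity=float(rng.uniform(10, 29)),
                        query_coverage=float(rng.uniform(30, 90)),
                        sequence_length=int(rng.integers(300, 800)),
                        search_method="delta-blast",
                    )
                )
    return hits
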