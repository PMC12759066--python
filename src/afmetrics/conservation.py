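"""Structural conservation calls on predicted monomer models.

Given a predicted structure and an MSA-mapped domain window, this module
superposes models, detects alpha-helical segments from backbone
dihedrals, aggregates per-residue pLDDT, and issues the two conservation
calls used throughout the analysis:

* a three-helix binding-domain window is *conserved* when all three
  helices are present and the window has not been inflated by insertions;
* a flexible tether element is *present* whenever the window retains
  enough residues to form its loop-helix, regardless of whether a helix
  is actually predicted — the region is intrinsically flexible and its
  pLDDT is typically low, so demanding a predicted helix would miss real
  tethers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from afmetrics._geom import dihedral, kabsch
from afmetrics.types import (
    ChainRecord,
    ConservationCall,
    DomainRange,
    HelixSegment,
    PredictedModel,
)

__all__ = [
    "ConservationConfig",
    "superpose",
    "detect_helices",
    "classify_orc6bd",
    "classify_tether",
    "plddt_summary",
]

# phi/psi windows for the helical region of the Ramachandran plot
_PHI_RANGE = (-100.0, -30.0)
_PSI_RANGE = (-80.0, -5.0)


@dataclass
class ConservationConfig:
    min_helix_len: int = 6
    insertion_tolerance: float = 0.30  # fraction of reference window length
    tether_min_len: int = 12  # residues needed to form a loop-helix
    plddt_reliable: float = 70.0  # inclusive backbone-reliability threshold


def _ca_coords(chain: ChainRecord, residue_indices: list[int]) -> np.ndarray:
    coords = []
    for idx in residue_indices:
        res = next((r for r in chain.residues if r.index == idx), None)
        if res is None:
            raise KeyError(f"residue {idx} not in chain {chain.chain_id}")
        ca = next((a for a in res.atoms if a.name == "CA"), None)
        if ca is None:
            raise ValueError(f"residue {idx} has no CA atom")
        coords.append([ca.x, ca.y, ca.z])
    return np.array(coords, dtype=float)


def superpose(
    model_a: PredictedModel,
    model_b: PredictedModel,
    pairs: list[tuple[tuple[str, int], tuple[str, int]]],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired C-alpha atoms.

    ``pairs`` maps residues of ``model_a`` onto residues of ``model_b`` as
    ``((chain_id_a, residue_a), (chain_id_b, residue_b))`` tuples; at
    least three pairs are required. Returns the rotation matrix,
    translation vector and RMSD (Å) of the optimal fit moving ``model_a``
    onto ``model_b``.
    """
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 residue pairs, got {len(pairs)}")
    coords_a = []
    coords_b = []
    for (ca_id, ra), (cb_id, rb) in pairs:
        coords_a.append(_ca_coords(model_a.chain(ca_id), [ra])[0])
        coords_b.append(_ca_coords(model_b.chain(cb_id), [rb])[0])
    return kabsch(np.array(coords_a), np.array(coords_b))


def backbone_dihedrals(chain: ChainRecord) -> dict[int, tuple[float, float]]:
    """Measured (phi, psi) per residue index; NaN where undefined.

    phi of residue i needs C of residue i-1; psi needs N of residue i+1.
    Residues missing a backbone atom yield NaN for the affected angle.
    """

    def atom(res, name):
        a = next((x for x in res.atoms if x.name == name), None)
        return None if a is None else a.coords

    out: dict[int, tuple[float, float]] = {}
    residues = chain.residues
    for k, res in enumerate(residues):
        n, ca, c = atom(res, "N"), atom(res, "CA"), atom(res, "C")
        phi = psi = float("nan")
        if n is not None and ca is not None and c is not None:
            if k > 0 and residues[k - 1].index == res.index - 1:
                c_prev = atom(residues[k - 1], "C")
                if c_prev is not None:
                    phi = dihedral(c_prev, n, ca, c)
            if k + 1 < len(residues) and residues[k + 1].index == res.index + 1:
                n_next = atom(residues[k + 1], "N")
                if n_next is not None:
                    psi = dihedral(n, ca, c, n_next)
        out[res.index] = (phi, psi)
    return out


def detect_helices(
    model: PredictedModel,
    window: DomainRange,
    chain_id: str | None = None,
    config: ConservationConfig | None = None,
) -> list[HelixSegment]:
    """Alpha-helical segments within a residue window.

    A residue is helical when both backbone dihedrals fall in the helical
    region (phi in [-100, -30] deg, psi in [-80, -5] deg); maximal runs of
    at least ``min_helix_len`` helical residues become segments. An absent
    window yields no segments.
    """
    config = config or ConservationConfig()
    if window.absent:
        return []
    chain = model.chain(chain_id) if chain_id else model.chains[0]
    angles = backbone_dihedrals(chain)

    def is_helical(idx: int) -> bool:
        phi, psi = angles.get(idx, (float("nan"), float("nan")))
        return (
            _PHI_RANGE[0] <= phi <= _PHI_RANGE[1]
            and _PSI_RANGE[0] <= psi <= _PSI_RANGE[1]
        )

    segments: list[HelixSegment] = []
    run_start = None
    for idx in range(window.start, window.end + 2):
        if idx <= window.end and is_helical(idx):
            if run_start is None:
                run_start = idx
        else:
            if run_start is not None and idx - run_start >= config.min_helix_len:
                segments.append(
                    HelixSegment(chain_id=chain.chain_id, start=run_start, end=idx - 1)
                )
            run_start = None
    return segments


def plddt_summary(
    model: PredictedModel,
    window: DomainRange | None = None,
    chain_id: str | None = None,
    reliable_threshold: float = 70.0,
) -> tuple[float | None, bool]:
    """Mean pLDDT over a window (or the whole chain) and the backbone call.

    ``reliable`` uses the conventional inclusive threshold: a mean pLDDT
    of exactly 70 still counts as a reliable backbone. An empty selection
    returns ``(None, False)``.
    """
    chain = model.chain(chain_id) if chain_id else model.chains[0]
    if window is None:
        values = [r.plddt for r in chain.residues]
    elif window.absent:
        values = []
    else:
        values = [
            r.plddt
            for r in chain.residues
            if window.start <= r.index <= window.end
        ]
    if not values:
        return None, False
    mean = float(np.mean(values))
    return mean, mean >= reliable_threshold


def classify_orc6bd(
    model: PredictedModel,
    window: DomainRange,
    reference_length: int,
    chain_id: str | None = None,
    config: ConservationConfig | None = None,
) -> ConservationCall:
    """Conservation call for a three-helix binding-domain window.

    Conserved iff the window contains all three alpha helices and its
    length does not exceed the reference window length by more than the
    insertion tolerance (large insertions disrupt the motif even when
    three helices remain). Missing helices, or an inflated window, give
    non_conserved; a window with no residues is absent.
    """
    config = config or ConservationConfig()
    mean_chain, _ = plddt_summary(model, None, chain_id, config.plddt_reliable)
    if window.absent:
        return ConservationCall(
            seq_id=window.seq_id,
            domain_name=window.domain_name,
            status="absent",
            n_helices=0,
            mean_plddt_domain=None,
            mean_plddt_chain=mean_chain,
            evidence="window absent in mapped range",
        )
    helices = detect_helices(model, window, chain_id, config)
    mean_domain, _ = plddt_summary(model, window, chain_id, config.plddt_reliable)
    max_len = reference_length * (1.0 + config.insertion_tolerance)
    if len(helices) == 3 and window.n_residues <= max_len:
        status, why = "conserved", "three helices, no large insertion"
    elif len(helices) == 3:
        status = "non_conserved"
        why = f"insertion: window {window.n_residues} > {max_len:.0f} residues"
    else:
        status, why = "non_conserved", f"{len(helices)} of 3 helices found"
    return ConservationCall(
        seq_id=window.seq_id,
        domain_name=window.domain_name,
        status=status,
        n_helices=len(helices),
        mean_plddt_domain=mean_domain,
        mean_plddt_chain=mean_chain,
        evidence=why,
    )


def classify_tether(
    model: PredictedModel,
    window: DomainRange,
    chain_id: str | None = None,
    config: ConservationConfig | None = None,
) -> ConservationCall:
    """Presence call for the flexible tether element.

    Present iff the mapped window retains at least ``tether_min_len``
    residues — enough to form the loop-helix — independent of predicted
    secondary structure.
    """
    config = config or ConservationConfig()
    mean_chain, _ = plddt_summary(model, None, chain_id, config.plddt_reliable)
    helices = detect_helices(model, window, chain_id, config)
    mean_domain, _ = plddt_summary(model, window, chain_id, config.plddt_reliable)
    if window.n_residues >= config.tether_min_len:
        status = "present"
        why = f"{window.n_residues} residues >= {config.tether_min_len}"
    else:
        status = "absent"
        why = f"{window.n_residues} residues < {config.tether_min_len}"
    return ConservationCall(
        seq_id=window.seq_id,
        domain_name=window.domain_name,
        status=status,
        n_helices=len(helices),
        mean_plddt_domain=mean_domain,
        mean_plddt_chain=mean_chain,
        evidence=why,
    )
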