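"""Confidence-filtered inter-chain contact scoring of multimer predictions.

The central metric is the *average models* score: over the union of
confidence-filtered, domain-restricted inter-chain residue contacts found
in the five models AlphaFold2 Multimer emits per target, the mean number
of models supporting each contact, normalized by the model count. A score
of 1 means all five models agree on every contact; 0 means no contact
survived in any model. A score above 0.5 calls a confident interaction.

The chain of operations per target:

1. ``detect_contacts`` — residue pairs with any non-hydrogen atom pair
   strictly closer than 8 Å across the two chains;
2. ``filter_contacts`` — drop contacts at residues with pLDDT below 50
   and residue pairs with pAE above 15 Å;
3. ``restrict_canonical`` — keep only contacts touching the canonical
   binding window (e.g. the ORC6-binding domain on ORC3), discarding
   non-canonical interfaces;
4. ``average_models`` / ``interface_pae`` — the consistency score and the
   mean pAE over retained contact pairs.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from afmetrics.types import (
    ConfidenceBundle,
    DomainRange,
    InterfaceScore,
    MultimerPrediction,
    PredictedModel,
    ResidueContact,
    ScoreConfig,
)

__all__ = [
    "detect_contacts",
    "filter_contacts",
    "restrict_canonical",
    "average_models",
    "interface_pae",
    "score_target",
]

PairId = tuple[tuple[str, int], tuple[str, int]]


def _heavy_atoms(model: PredictedModel, chain_id: str):
    """(coords, residue_index) arrays over non-hydrogen atoms of a chain."""
    chain = model.chain(chain_id)
    coords = []
    res_idx = []
    for res in chain.residues:
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            coords.append((atom.x, atom.y, atom.z))
            res_idx.append(res.index)
    return np.asarray(coords, dtype=float), np.asarray(res_idx, dtype=int)


def detect_contacts(
    model: PredictedModel,
    chain_pair: tuple[str, str],
    cfg: ScoreConfig | None = None,
) -> set[ResidueContact]:
    """Inter-chain residue contacts of one model.

    A residue pair is a contact iff *any* pair of non-hydrogen atoms
    across the two chains is strictly closer than ``cfg.contact_cutoff``
    (8 Å by default); hydrogens are excluded by element, and atom-level
    hits collapse to one contact per residue pair carrying the minimum
    atom distance.
    """
    cfg = cfg or ScoreConfig()
    chain_a, chain_b = chain_pair
    coords_a, idx_a = _heavy_atoms(model, chain_a)
    coords_b, idx_b = _heavy_atoms(model, chain_b)
    if coords_a.size == 0 or coords_b.size == 0:
        return set()
    dist = cdist(coords_a, coords_b)
    hit_a, hit_b = np.nonzero(dist < cfg.contact_cutoff)
    best: dict[tuple[int, int], float] = {}
    for a, b in zip(hit_a, hit_b):
        key = (int(idx_a[a]), int(idx_b[b]))
        d = float(dist[a, b])
        if d < best.get(key, np.inf):
            best[key] = d
    plddt_a = {r.index: r.plddt for r in model.chain(chain_a).residues}
    plddt_b = {r.index: r.plddt for r in model.chain(chain_b).residues}
    return {
        ResidueContact(
            chain_a_res=(chain_a, ra),
            chain_b_res=(chain_b, rb),
            min_distance=d,
            min_plddt=min(plddt_a[ra], plddt_b[rb]),
        )
        for (ra, rb), d in best.items()
    }


def filter_contacts(
    contacts: Iterable[ResidueContact],
    model: PredictedModel,
    confidence: ConfidenceBundle,
    cfg: ScoreConfig | None = None,
) -> set[ResidueContact]:
    """Confidence filter: drop low-pLDDT residues and high-pAE pairs.

    A contact is removed when either residue's pLDDT is below
    ``cfg.plddt_min`` (< 50 by default — keeping exactly 50), or when the
    pair's combined pAE exceeds ``cfg.pae_max`` (> 15 Å removed, exactly
    15 kept). pAE is directional; the two directions are combined per
    ``cfg.pae_combine`` (mean by default). Retained contacts carry their
    pAE values for downstream interface-pAE averaging.
    """
    cfg = cfg or ScoreConfig()
    confidence.validate_against(model)
    kept: set[ResidueContact] = set()
    for contact in contacts:
        if contact.min_plddt < cfg.plddt_min:
            continue
        ia = model.concat_index(*contact.chain_a_res)
        ib = model.concat_index(*contact.chain_b_res)
        pae_ab = float(confidence.pae[ia, ib])
        pae_ba = float(confidence.pae[ib, ia])
        if cfg.combine_pae(pae_ab, pae_ba) > cfg.pae_max:
            continue
        kept.add(
            ResidueContact(
                chain_a_res=contact.chain_a_res,
                chain_b_res=contact.chain_b_res,
                min_distance=contact.min_distance,
                pae_ab=pae_ab,
                pae_ba=pae_ba,
                min_plddt=contact.min_plddt,
            )
        )
    return kept


def restrict_canonical(
    contacts: Iterable[ResidueContact],
    domain: DomainRange,
    domain_chain_id: str,
) -> set[ResidueContact]:
    """Keep only contacts that touch the canonical binding window.

    A contact survives iff its residue on ``domain_chain_id`` lies within
    the domain window; with an absent domain no contact can be canonical
    and the empty set is returned (downstream the score is then 0).
    """
    if domain.absent:
        return set()
    kept = set()
    for contact in contacts:
        for chain_id, res_idx in (contact.chain_a_res, contact.chain_b_res):
            if chain_id == domain_chain_id and domain.start <= res_idx <= domain.end:
                kept.add(contact)
                break
    return kept


def average_models(
    model_contact_sets: Sequence[set[ResidueContact]],
    cfg: ScoreConfig | None = None,
) -> float:
    """The *average models* contact-consistency score, normalized to 1.

    Over the union U of contacts across the n models (contacts are
    identified by their residue pair), the score is

        ( sum_{c in U} m(c) / |U| ) / n

    where m(c) counts the models containing contact c. An empty union
    scores 0; otherwise the score lies in [1/n, 1], with 1 meaning all
    models agree on every contact.
    """
    cfg = cfg or ScoreConfig()
    if len(model_contact_sets) != cfg.n_models:
        raise ValueError(
            f"expected {cfg.n_models} contact sets, got {len(model_contact_sets)}"
        )
    counts: dict[PairId, int] = {}
    for contact_set in model_contact_sets:
        for contact in contact_set:
            counts[contact.pair_id] = counts.get(contact.pair_id, 0) + 1
    if not counts:
        return 0.0
    return float(np.mean(list(counts.values())) / cfg.n_models)


def interface_pae(
    model_contact_sets: Sequence[set[ResidueContact]],
    cfg: ScoreConfig | None = None,
) -> Optional[float]:
    """Mean combined pAE over retained canonical contact pairs, in Å.

    By default every contact instance pools into the average (a pair
    contributes once per model containing it); ``cfg.pae_pool = "union"``
    instead averages one per-pair value (itself the mean over supporting
    models). With no contacts the interface pAE cannot be calculated and
    None is returned.
    """
    cfg = cfg or ScoreConfig()
    if cfg.pae_pool == "instances":
        values = [
            cfg.combine_pae(c.pae_ab, c.pae_ba)
            for contact_set in model_contact_sets
            for c in contact_set
        ]
    else:
        per_pair: dict[PairId, list[float]] = {}
        for contact_set in model_contact_sets:
            for c in contact_set:
                per_pair.setdefault(c.pair_id, []).append(
                    cfg.combine_pae(c.pae_ab, c.pae_ba)
                )
        values = [float(np.mean(v)) for v in per_pair.values()]
    if not values:
        return None
    return float(np.mean(values))


def score_target(
    prediction: MultimerPrediction,
    domain: DomainRange,
    cfg: ScoreConfig | None = None,
    domain_role: str = "ORC3",
) -> InterfaceScore:
    """Full per-target scoring chain: detect, filter, restrict, score.

    ``domain`` is the canonical binding window on the chain playing
    ``domain_role``. The confident call is strict (*average models* >
    ``cfg.confidence_threshold``); ``canonical`` records whether any
    filtered contact touched the window at all; ``iptm_best`` is the ipTM
    of the top-ranked model.
    """
    cfg = cfg or ScoreConfig()
    domain_chain = prediction.chain_for_role(domain_role)
    other_chain = next(
        cid for cid in prediction.chain_roles if cid != domain_chain
    )
    chain_pair = (domain_chain, other_chain)

    restricted_sets: list[set[ResidueContact]] = []
    for model, confidence in prediction.models:
        raw = detect_contacts(model, chain_pair, cfg)
        filtered = filter_contacts(raw, model, confidence, cfg)
        restricted_sets.append(restrict_canonical(filtered, domain, domain_chain))

    score = average_models(restricted_sets, cfg)
    pae = interface_pae(restricted_sets, cfg)
    union: set[PairId] = {
        c.pair_id for contact_set in restricted_sets for c in contact_set
    }
    return InterfaceScore(
        target_id=prediction.target_id,
        average_models=score,
        n_contacts_per_model=[len(s) for s in restricted_sets],
        n_union_contacts=len(union),
        interface_pae=pae,
        iptm_best=prediction.models[0][1].iptm,
        confident=score > cfg.confidence_threshold,
        canonical=len(union) > 0,
    )
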