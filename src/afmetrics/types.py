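"""Shared domain types for predicted structures, confidences and calls.

Conventions used throughout the package:

* residue indices are 1-based within their chain, as AlphaFold writes them;
* the concatenated (model-order) residue index used to address pAE matrices
  is always computed on the fly from chain order, never stored;
* pLDDT is a per-residue real in [0, 100]; pAE is a directional residue-pair
  error in Å and is never symmetrized by this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Subunits handled by the ortholog screen.
ORC_SUBUNITS = ("ORC1", "ORC2", "ORC3", "ORC4", "ORC5", "ORC6")
ALL_SUBUNITS = ORC_SUBUNITS + ("MCM2",)


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    index: int  # 1-based within chain
    name: str  # 3-letter code
    atoms: list[Atom]
    plddt: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError(
                f"pLDDT {self.plddt} out of [0, 100] for residue {self.index}"
            )


@dataclass
class ChainRecord:
    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"residue indices not strictly increasing in chain {self.chain_id}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PredictedModel:
    """One chain-resolved predicted structure with per-residue confidence."""

    model_id: str
    chains: list[ChainRecord]
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("model must contain at least one chain")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain identifiers in model: {ids}")

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in model {self.model_id!r}")

    def concat_index(self, chain_id: str, residue_index: int) -> int:
        """0-based position of a residue in the model-order concatenation.

        This is the index used to address pAE matrices; it is derived from
        chain order each time it is needed.
        """
        offset = 0
        for c in self.chains:
            if c.chain_id == chain_id:
                for i, r in enumerate(c.residues):
                    if r.index == residue_index:
                        return offset + i
                raise KeyError(
                    f"residue {residue_index} not in chain {chain_id!r}"
                )
            offset += len(c)
        raise KeyError(f"chain {chain_id!r} not in model {self.model_id!r}")


@dataclass
class ConfidenceBundle:
    """Per-model pAE matrix with optional global pTM/ipTM scores.

    The pAE matrix is directional (``pae[i, j] != pae[j, i]`` in general)
    and is indexed over the concatenated residues of all chains in model
    order.
    """

    pae: np.ndarray
    iptm: Optional[float] = None
    ptm: Optional[float] = None

    def __post_init__(self) -> None:
        self.pae = np.asarray(self.pae, dtype=float)
        if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
            raise ValueError(f"pAE matrix must be square, got {self.pae.shape}")
        if (self.pae < 0).any():
            raise ValueError("pAE values must be >= 0")
        for attr in ("iptm", "ptm"):
            v = getattr(self, attr)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} {v} out of [0, 1]")

    @property
    def n_residues(self) -> int:
        return self.pae.shape[0]

    def validate_against(self, model: PredictedModel) -> None:
        if self.n_residues != model.n_residues:
            raise ValueError(
                f"pAE dimension {self.n_residues} does not match model "
                f"residue count {model.n_residues}"
            )


@dataclass
class MultimerPrediction:
    """Bundle of the five models AlphaFold2 Multimer emits per target."""

    target_id: str
    models: list[tuple[PredictedModel, ConfidenceBundle]]
    chain_roles: dict[str, str]  # chain_id -> role label, e.g. "ORC3"

    N_MODELS = 5

    def __post_init__(self) -> None:
        if len(self.models) != self.N_MODELS:
            raise ValueError(
                f"expected {self.N_MODELS} models, got {len(self.models)}"
            )
        if len(set(self.chain_roles.values())) != 2:
            raise ValueError("exactly two chain roles are required")
        ref = self._composition(self.models[0][0])
        for model, conf in self.models:
            if self._composition(model) != ref:
                raise ValueError(
                    f"model {model.model_id} chain composition differs"
                )
            conf.validate_against(model)

    @staticmethod
    def _composition(model: PredictedModel) -> tuple:
        return tuple((c.chain_id, len(c)) for c in model.chains)

    def chain_for_role(self, role: str) -> str:
        for cid, r in self.chain_roles.items():
            if r == role:
                return cid
        raise KeyError(f"no chain with role {role!r}")


@dataclass(frozen=True)
class ResidueContact:
    """An inter-chain residue pair within the contact cutoff.

    Identity for cross-model matching is the (chain_id, residue_index)
    pair on each side; distances and confidences are per-model evidence.
    """

    chain_a_res: tuple[str, int]
    chain_b_res: tuple[str, int]
    min_distance: float
    pae_ab: float = float("nan")
    pae_ba: float = float("nan")
    min_plddt: float = float("nan")

    def __post_init__(self) -> None:
        if self.chain_a_res[0] == self.chain_b_res[0]:
            raise ValueError("contact residues must be on different chains")

    @property
    def pair_id(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.chain_a_res, self.chain_b_res)


@dataclass
class ScoreConfig:
    """Thresholds for contact detection and confidence filtering.

    Defaults follow common AlphaFold2 Multimer screen practice: contacts are
    non-hydrogen atom pairs strictly closer than 8 Å, contacts at residues
    with pLDDT < 50 or residue pairs with pAE > 15 Å are excluded, and an
    *average models* score above 0.5 calls a confident interaction.
    """

    contact_cutoff: float = 8.0
    plddt_min: float = 50.0
    pae_max: float = 15.0
    confidence_threshold: float = 0.5
    n_models: int = 5
    pae_combine: str = "mean"  # one of: mean, max, min
    pae_pool: str = "instances"  # interface pAE over: instances | union

    def __post_init__(self) -> None:
        for attr in ("contact_cutoff", "plddt_min", "pae_max"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if self.pae_combine not in ("mean", "max", "min"):
            raise ValueError(f"unknown pae_combine {self.pae_combine!r}")
        if self.pae_pool not in ("instances", "union"):
            raise ValueError(f"unknown pae_pool {self.pae_pool!r}")

    def combine_pae(self, pae_ab: float, pae_ba: float) -> float:
        if self.pae_combine == "mean":
            return 0.5 * (pae_ab + pae_ba)
        if self.pae_combine == "max":
            return max(pae_ab, pae_ba)
        return min(pae_ab, pae_ba)


@dataclass
class InterfaceScore:
    """Per-target interface summary: the *average models* score and friends."""

    target_id: str
    average_models: float
    n_contacts_per_model: list[int]
    n_union_contacts: int
    interface_pae: Optional[float]
    iptm_best: Optional[float]
    confident: bool
    canonical: bool

    def __post_init__(self) -> None:
        if self.n_union_contacts == 0 and self.average_models != 0.0:
            raise ValueError("score must be 0 when the contact union is empty")
        if self.n_union_contacts == 0 and self.interface_pae is not None:
            raise ValueError("interface pAE is undefined without contacts")


@dataclass(frozen=True)
class DomainRange:
    """A named domain interval on one (ungapped) sequence.

    ``start``/``end`` are 1-based inclusive residue indices; a missing
    domain is represented with ``start = end = 0`` and ``n_residues == 0``.
    """

    seq_id: str
    domain_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start == 0 and self.end == 0:
            return
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid range {self.start}-{self.end} for {self.seq_id}"
            )

    @property
    def n_residues(self) -> int:
        return 0 if self.start == 0 else self.end - self.start + 1

    @property
    def absent(self) -> bool:
        return self.n_residues == 0

    @classmethod
    def make_absent(cls, seq_id: str, domain_name: str) -> "DomainRange":
        return cls(seq_id=seq_id, domain_name=domain_name, start=0, end=0)


@dataclass
class Alignment:
    """A gapped multiple sequence alignment with unique row identifiers."""

    rows: list[tuple[str, str]]  # (seq_id, aligned sequence with "-")

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        width = len(self.rows[0][1])
        for seq_id, seq in self.rows:
            if len(seq) != width:
                raise ValueError(
                    f"ragged alignment: row {seq_id!r} has length "
                    f"{len(seq)}, expected {width}"
                )
        ids = [sid for sid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence identifiers: {dup}")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    def row(self, seq_id: str) -> str:
        for sid, seq in self.rows:
            if sid == seq_id:
                return seq
        raise KeyError(f"sequence {seq_id!r} not in alignment")

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")


@dataclass(frozen=True)
class HelixSegment:
    chain_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ConservationCall:
    seq_id: str
    domain_name: str
    status: str  # conserved | non_conserved | absent | present
    n_helices: int
    mean_plddt_domain: Optional[float]
    mean_plddt_chain: Optional[float]
    evidence: str = ""


@dataclass
class HitRecord:
    """One row of a homology-search hit table."""

    query_subunit: str
    species: str
    taxon_group: str
    accession: str
    percent_identity: float
    query_coverage: float
    sequence_length: int
    is_partial: bool = False
    has_x_residues: bool = False
    search_method: str = ""  # blastp / delta-blast provenance; never affects calls

    def __post_init__(self) -> None:
        for attr in ("percent_identity", "query_coverage"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{attr} {v} out of [0, 100]")


@dataclass
class PresenceMatrix:
    """Species x subunit ortholog presence/absence with representatives."""

    entries: dict[tuple[str, str], bool] = field(default_factory=dict)
    representative: dict[tuple[str, str], str] = field(default_factory=dict)
    taxon_of: dict[str, str] = field(default_factory=dict)

    def present(self, species: str, subunit: str) -> bool:
        return self.entries.get((species, subunit), False)

    @property
    def species(self) -> list[str]:
        return sorted(self.taxon_of)

    def species_in_group(self, taxon_group: str) -> list[str]:
        return sorted(s for s, g in self.taxon_of.items() if g == taxon_group)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.taxon_of.values()))
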