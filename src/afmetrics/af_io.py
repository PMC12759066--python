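"""Readers and writers for every external format the pipeline touches.

Structures come in as PDB or mmCIF as emitted by AlphaFold (per-residue
pLDDT in the B-factor column for PDB), confidences as JSON files carrying
the pAE matrix and optional pTM/ipTM, alignments as aligned FASTA, and
ortholog hit tables as TSV. Parsing of the structure dialects is delegated
to gemmi; FASTA handling to Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Union

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

from afmetrics.types import (
    Alignment,
    Atom,
    ChainRecord,
    ConfidenceBundle,
    HitRecord,
    PredictedModel,
    PresenceMatrix,
    Residue,
    ALL_SUBUNITS,
)

PathLike = Union[str, Path]

_HIT_TABLE_COLUMNS = (
    "query_subunit",
    "species",
    "taxon_group",
    "accession",
    "percent_identity",
    "query_coverage",
    "sequence_length",
    "is_partial",
    "has_X_residues",
)

#: tolerance for the all-atoms-agree check on per-residue B-factors
_PLDDT_ATOL = 0.01


def read_structure(path: PathLike, dialect: str = "pdb") -> PredictedModel:
    """Read a predicted structure into a :class:`PredictedModel`.

    Per-residue pLDDT is taken from the B-factor column (the value on the
    first atom of each residue); all atoms of a residue must agree within
    0.01, as AlphaFold writes identical values — disagreement indicates a
    corrupted file and raises. Hydrogen atoms are retained in the record
    and identified by their element.

    Parameters
    ----------
    path
        Structure file in the named dialect.
    dialect
        ``"pdb"`` or ``"mmcif"``.
    """
    path = Path(path)
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}.get(
        dialect.lower()
    )
    if fmt is None:
        raise ValueError(f"unknown structure dialect {dialect!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path} as {dialect}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")

    chains = []
    for ch in st[0]:
        residues = []
        for res in ch:
            atoms = [
                Atom(
                    name=at.name,
                    element=at.element.name,
                    x=at.pos.x,
                    y=at.pos.y,
                    z=at.pos.z,
                )
                for at in res
            ]
            if not atoms:
                continue
            b_values = [at.b_iso for at in res]
            if all(b == 0.0 for b in b_values):
                raise ValueError(
                    f"{path}: residue {ch.name}/{res.seqid.num} has no "
                    "confidence available (B-factor column empty)"
                )
            if max(b_values) - min(b_values) > _PLDDT_ATOL:
                raise ValueError(
                    f"{path}: atoms of residue {ch.name}/{res.seqid.num} "
                    f"carry inconsistent B-factors "
                    f"({min(b_values):.3f}..{max(b_values):.3f}); "
                    "corrupted per-residue confidence"
                )
            residues.append(
                Residue(
                    index=res.seqid.num,
                    name=res.name,
                    atoms=atoms,
                    plddt=b_values[0],
                )
            )
        if residues:
            chains.append(ChainRecord(chain_id=ch.name, residues=residues))
    return PredictedModel(model_id=path.stem, chains=chains, source_path=str(path))


def write_structure(model: PredictedModel, path: PathLike, dialect: str = "pdb") -> None:
    """Write a :class:`PredictedModel` to PDB or mmCIF, pLDDT as B-factor."""
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for chain in model.chains:
        gc = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.index, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
                ga.b_iso = res.plddt
                ga.occ = 1.0
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    if dialect.lower() == "pdb":
        st.write_pdb(str(path))
    elif dialect.lower() == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown structure dialect {dialect!r}")


def read_confidence(
    path: PathLike, model: Optional[PredictedModel] = None
) -> ConfidenceBundle:
    """Read a JSON confidence file (pAE matrix, optional pTM/ipTM).

    Accepts either a ``"pae"`` key or AlphaFold's
    ``"predicted_aligned_error"``. The matrix is kept exactly as stored —
    pAE is directional and is never symmetrized. If ``model`` is given the
    matrix dimension is validated against its residue count.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list):  # AlphaFold DB wraps the record in a list
        data = data[0]
    pae = data.get("pae", data.get("predicted_aligned_error"))
    if pae is None:
        raise ValueError(f"{path}: no pAE matrix found")
    bundle = ConfidenceBundle(
        pae=np.asarray(pae, dtype=float),
        iptm=data.get("iptm"),
        ptm=data.get("ptm"),
    )
    if model is not None:
        try:
            bundle.validate_against(model)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return bundle


def write_confidence(bundle: ConfidenceBundle, path: PathLike) -> None:
    data: dict = {"pae": bundle.pae.tolist()}
    if bundle.ptm is not None:
        data["ptm"] = bundle.ptm
    if bundle.iptm is not None:
        data["iptm"] = bundle.iptm
    with open(path, "w") as fh:
        json.dump(data, fh, separators=(",", ":"))
        fh.write("\n")


def read_alignment(path: PathLike) -> Alignment:
    """Read an aligned FASTA file; all rows must share one width."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty alignment")
    rows = [(rec.id, str(rec.seq).upper()) for rec in records]
    widths = {len(seq) for _, seq in rows}
    if len(widths) > 1:
        ragged = [sid for sid, seq in rows if len(seq) != len(rows[0][1])]
        raise ValueError(f"{path}: ragged alignment rows: {ragged}")
    return Alignment(rows=rows)


def write_alignment(aln: Alignment, path: PathLike) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in aln.rows:
            fh.write(f">{seq_id}\n{seq}\n")


def read_fasta(path: PathLike) -> dict[str, str]:
    """Plain (ungapped) FASTA as an id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


_TRUTHY = {"1", "true", "yes", "y", "t"}


def _parse_flag(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float)):
        return bool(value)
    return str(value).strip().lower() in _TRUTHY


def read_hit_table(path: PathLike) -> list[HitRecord]:
    """Read a TSV homology hit table into :class:`HitRecord` rows.

    Mandatory columns: query_subunit, species, taxon_group, accession,
    percent_identity, query_coverage, sequence_length, is_partial,
    has_X_residues. Unknown columns are ignored; an optional
    ``search_method`` column is carried through as provenance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _HIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            HitRecord(
                query_subunit=row["query_subunit"],
                species=row["species"],
                taxon_group=row["taxon_group"],
                accession=row["accession"],
                percent_identity=float(row["percent_identity"]),
                query_coverage=float(row["query_coverage"]),
                sequence_length=int(row["sequence_length"]),
                is_partial=_parse_flag(row["is_partial"]),
                has_x_residues=_parse_flag(row["has_X_residues"]),
                search_method=str(row.get("search_method", "") or ""),
            )
        )
    return records


def write_hit_table(hits: Iterable[HitRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "query_subunit": h.query_subunit,
                "species": h.species,
                "taxon_group": h.taxon_group,
                "accession": h.accession,
                "percent_identity": h.percent_identity,
                "query_coverage": h.query_coverage,
                "sequence_length": h.sequence_length,
                "is_partial": h.is_partial,
                "has_X_residues": h.has_x_residues,
                "search_method": h.search_method,
            }
            for h in hits
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_presence_matrix(matrix: PresenceMatrix, path: PathLike) -> None:
    """Presence matrix TSV: species, taxon_group, one column per subunit,
    plus the representative accession per present call."""
    rows = []
    for species in matrix.species:
        row: dict = {
            "species": species,
            "taxon_group": matrix.taxon_of[species],
        }
        for sub in ALL_SUBUNITS:
            present = matrix.present(species, sub)
            row[sub] = "present" if present else "absent"
            row[f"{sub}_representative"] = matrix.representative.get(
                (species, sub), ""
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_presence_matrix(path: PathLike) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    matrix = PresenceMatrix()
    for _, row in df.iterrows():
        species = row["species"]
        matrix.taxon_of[species] = row["taxon_group"]
        for sub in ALL_SUBUNITS:
            if sub not in df.columns:
                continue
            present = row[sub] == "present"
            matrix.entries[(species, sub)] = present
            rep = row.get(f"{sub}_representative", "")
            if present and rep:
                matrix.representative[(species, sub)] = rep
    return matrix
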