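"""Map reference-defined domain windows onto aligned sequences.

Domain boundaries (e.g. the ORC6-binding domain or the tether element
inside the ORC3 insertion domain) are known on a reference sequence —
typically human — and are transferred to every other sequence through the
columns of a multiple sequence alignment. Percent identity over a domain
window is computed against the reference, with the reference's non-gap
positions as the denominator.
"""

from __future__ import annotations

import math

from afmetrics.types import Alignment, DomainRange

__all__ = ["map_range", "percent_identity", "residue_to_column", "window_columns"]


def residue_to_column(aln: Alignment, seq_id: str) -> list[int]:
    """0-based alignment column of each (1-based) residue of a sequence."""
    return [c for c, ch in enumerate(aln.row(seq_id)) if ch != "-"]


def window_columns(
    aln: Alignment, ref_id: str, ref_range: DomainRange
) -> range:
    """Inclusive alignment-column span covered by a reference window."""
    cols = residue_to_column(aln, ref_id)
    if ref_range.end > len(cols):
        raise ValueError(
            f"reference range {ref_range.start}-{ref_range.end} exceeds "
            f"ungapped length {len(cols)} of {ref_id!r}"
        )
    return range(cols[ref_range.start - 1], cols[ref_range.end - 1] + 1)


def map_range(
    aln: Alignment, ref_id: str, ref_range: DomainRange, target_id: str
) -> DomainRange:
    """Transfer a reference residue window to a target sequence.

    The reference residues define a span of alignment columns; the mapped
    range runs from the first to the last target residue falling in that
    span, so insertions the target carries inside the window count toward
    its length. A target that is all-gap across the span has no domain and
    an explicit absent range is returned.
    """
    if ref_range.absent:
        return DomainRange.make_absent(target_id, ref_range.domain_name)
    span = window_columns(aln, ref_id, ref_range)
    target_row = aln.row(target_id)
    residue_no = 0
    first = last = None
    for c, ch in enumerate(target_row):
        if ch == "-":
            continue
        residue_no += 1
        if span.start <= c <= span[-1]:
            if first is None:
                first = residue_no
            last = residue_no
    if first is None:
        return DomainRange.make_absent(target_id, ref_range.domain_name)
    return DomainRange(
        seq_id=target_id, domain_name=ref_range.domain_name, start=first, end=last
    )


def percent_identity(
    aln: Alignment, ref_id: str, target_id: str, window: DomainRange
) -> float:
    """Percent identity of a target to the reference over a domain window.

    Computed as the number of matching positions divided by the number of
    reference (non-gap) positions in the window's columns, times 100 —
    gaps in the reference are excluded from the denominator, and a gap or
    mismatch in the target simply fails to match. Comparison is
    case-insensitive; an undetermined residue ``X`` never matches.
    Returns NaN when the window contains no reference residues.
    """
    span = window_columns(aln, ref_id, window)
    ref_row = aln.row(ref_id).upper()
    target_row = aln.row(target_id).upper()
    denom = 0
    matches = 0
    for c in span:
        r = ref_row[c]
        if r == "-":
            continue
        denom += 1
        t = target_row[c]
        if t == "-" or r == "X" or t == "X":
            continue
        if r == t:
            matches += 1
    if denom == 0:
        return math.nan
    return 100.0 * matches / denom
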