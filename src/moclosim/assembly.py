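"""Overhang-directed joining of sticky fragments into a circular product.

Ligation compatibility is a string-equality test on fusion sites: fragment
A can precede fragment B iff ``A.right_fusion == B.left_fusion``. A one-pot
reaction succeeds when this directed relation admits exactly one circular
chaining that uses every fragment once. Failure modes mirror the bench
outcomes: *incomplete* (an overhang with no partner), *ambiguous* (an
overhang offered by two fragments — multiple products), *multiple_circles*
(the pot closes several smaller circles instead of one).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from moclosim.digestion import StickyFragment, TypeIISEnzyme, digest, select_insert_fragment
from moclosim.errors import DigestionError, ReactionError
from moclosim.sequence_io import DnaMolecule

SUCCESS = "success"
INCOMPLETE = "incomplete"
AMBIGUOUS = "ambiguous"
MULTIPLE_CIRCLES = "multiple_circles"


@dataclass
class AssemblyResult:
    status: str
    product: DnaMolecule | None = None
    diagnostics: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status == SUCCESS


def _orient(fragments: list[StickyFragment], diagnostics: list[str]) -> list[StickyFragment]:
    """Reverse-complement rescue: flip a fragment only if its forward
    orientation has no chaining partner but the flipped one does."""
    oriented = list(fragments)
    for i, frag in enumerate(oriented):
        others_left = Counter(f.left_fusion for j, f in enumerate(oriented) if j != i)
        others_right = Counter(f.right_fusion for j, f in enumerate(oriented) if j != i)
        fwd_ok = frag.right_fusion in others_left and frag.left_fusion in others_right
        if fwd_ok:
            continue
        rc = frag.reverse_complement()
        rc_ok = rc.right_fusion in others_left and rc.left_fusion in others_right
        if rc_ok:
            oriented[i] = rc
            diagnostics.append(
                f"fragment from {frag.source_id!r} ({frag.left_fusion}/{frag.right_fusion}) "
                "used in reverse-complement orientation"
            )
    return oriented


def assemble(
    fragments: list[StickyFragment],
    *,
    product_id: str = "assembly",
    try_reverse_complement: bool = True,
) -> AssemblyResult:
    """Chain fragments by matching fusion sites into one circular molecule.

    The product's coordinate origin is the start of the left fusion site of
    the first-listed fragment, making output deterministic for file
    comparison. With ``try_reverse_complement`` (default), a fragment whose
    forward orientation cannot chain is retried flipped, with a diagnostic.
    """
    if len(fragments) < 2:
        return AssemblyResult(INCOMPLETE, diagnostics=["fewer than two fragments"])
    diagnostics: list[str] = []
    frags = _orient(fragments, diagnostics) if try_reverse_complement else list(fragments)

    lefts = Counter(f.left_fusion for f in frags)
    rights = Counter(f.right_fusion for f in frags)

    dup = sorted({s for s, c in lefts.items() if c > 1} | {s for s, c in rights.items() if c > 1})
    if dup:
        for s in dup:
            diagnostics.append(
                f"fusion site {s} offered by {max(lefts[s], rights[s])} fragments "
                "— multiple products possible"
            )
        return AssemblyResult(AMBIGUOUS, diagnostics=diagnostics)

    unmatched = sorted((set(rights) - set(lefts)) | (set(lefts) - set(rights)))
    if unmatched:
        for s in unmatched:
            diagnostics.append(f"fusion site {s} has no ligation partner")
        return AssemblyResult(INCOMPLETE, diagnostics=diagnostics)

    # lefts == rights as sets, all unique: each fragment has exactly one successor
    by_left = {f.left_fusion: f for f in frags}
    order = [frags[0]]
    while True:
        nxt = by_left[order[-1].right_fusion]
        if nxt is order[0]:
            break
        if nxt in order:  # pragma: no cover - impossible with unique sites
            break
        order.append(nxt)
    if len(order) < len(frags):
        leftover = sorted({f.source_id or f.left_fusion for f in frags if f not in order})
        diagnostics.append(
            "fragments close two or more separate circles; "
            f"not chained with the first: {', '.join(leftover)}"
        )
        return AssemblyResult(MULTIPLE_CIRCLES, diagnostics=diagnostics)

    sequence_parts: list[str] = []
    features = []
    offset = 0
    for frag in order:
        sequence_parts.append(frag.top_strand)
        for f in frag.features:
            features.append(f.shifted(offset))
        offset += len(frag.top_strand)
    sequence = "".join(sequence_parts)
    total = offset
    # features reaching into the right overhang of the last fragment wrap
    kept = []
    for f in features:
        if f.end <= total:
            kept.append(f)
        elif f.start < total:
            kept.append(
                type(f)(label=f.label, kind=f.kind, start=f.start, end=f.end % total, strand=f.strand)
            )
    product = DnaMolecule(
        id=product_id,
        sequence=sequence,
        topology="circular",
        features=kept,
        description=f"assembled from {len(order)} fragments",
    )
    return AssemblyResult(SUCCESS, product=product, diagnostics=diagnostics)


def simulate_reaction(
    inputs: list[DnaMolecule],
    enzyme: TypeIISEnzyme,
    *,
    product_id: str = "assembly",
    try_reverse_complement: bool = True,
    expected_fusions: list[tuple[str | None, str | None]] | None = None,
) -> AssemblyResult:
    """One one-pot Golden Gate reaction: digest every input, keep each
    input's unique recognition-free fragment, and assemble.

    The same rule covers entry plasmids (sites point into the part) and
    acceptors (sites point into the drop-out, so the usable backbone piece
    is itself recognition-free after excision). Digestion and selection
    errors are re-raised as :class:`ReactionError` tagged with the
    offending plasmid id. When *expected_fusions* (per-input (left, right)
    pairs from a typed grammar) is given, mismatching fragments add a
    warning diagnostic but do not fail the reaction.
    """
    fragments: list[StickyFragment] = []
    warnings_: list[str] = []
    for idx, molecule in enumerate(inputs):
        try:
            frags = digest(molecule, enzyme)
            insert = select_insert_fragment(frags, enzyme)
        except DigestionError as exc:
            raise ReactionError(str(exc), plasmid_id=molecule.id) from exc
        if expected_fusions is not None and idx < len(expected_fusions):
            exp_left, exp_right = expected_fusions[idx]
            if exp_left and insert.left_fusion != exp_left:
                warnings_.append(
                    f"{molecule.id!r}: left fusion {insert.left_fusion} differs from "
                    f"the grammar's expected {exp_left}"
                )
            if exp_right and insert.right_fusion != exp_right:
                warnings_.append(
                    f"{molecule.id!r}: right fusion {insert.right_fusion} differs from "
                    f"the grammar's expected {exp_right}"
                )
        fragments.append(insert)
    result = assemble(
        fragments, product_id=product_id, try_reverse_complement=try_reverse_complement
    )
    result.diagnostics = warnings_ + result.diagnostics
    return result
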