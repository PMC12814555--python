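"""Type IIS digestion: site finding, cut geometry, sticky fragments.

A Type IIS enzyme recognizes a non-palindromic sequence and cuts at a
fixed offset downstream of it, leaving a short 5' overhang (the *fusion
site*) that directs ligation. Cut geometry is expressed in gap indices on
the top strand: for a recognition match starting at ``p`` on the + strand,

    top_cut    = p + len(recognition) + spacer_top
    bottom_cut = p + len(recognition) + spacer_bottom

and for a match of the reverse-complemented recognition starting at ``q``
(a − strand site) the cuts fall upstream:

    top_cut    = q - spacer_bottom
    bottom_cut = q - spacer_top

With ``spacer_bottom > spacer_top`` the top cut always sits left of the
bottom cut, so the overhang is the top-strand 4-mer (3-mer for SapI)
``seq[top_cut:bottom_cut]`` — the convention fusion sites are named by.

Fragments between consecutive cuts are represented as
``left_fusion + payload``; the right fusion belongs to the next fragment
around the circle, which makes length conservation exact:
Σ(|payload| + overhang) = molecule length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from moclosim.errors import (
    AmbiguousInsertError,
    CutCollisionError,
    NoReleasablePartError,
    NoSitesError,
    SingleCutError,
)
from moclosim.sequence_io import AnnotationFeature, DnaMolecule, revcomp


@dataclass(frozen=True)
class TypeIISEnzyme:
    """A Type IIS enzyme defined by recognition sequence and cut spacers.

    ``spacer_top`` / ``spacer_bottom`` count nucleotides between the 3' end
    of the recognition sequence and the top / bottom strand cut, the usual
    N(a/b) notation: BsaI is GGTCTC(1/5).
    """

    name: str
    recognition: str
    spacer_top: int
    spacer_bottom: int

    def __post_init__(self):
        object.__setattr__(self, "recognition", self.recognition.upper())
        if set(self.recognition) - set("ACGT"):
            raise ValueError(f"{self.name}: recognition must be over A/C/G/T")
        if self.recognition == revcomp(self.recognition):
            raise ValueError(
                f"{self.name}: recognition {self.recognition} is palindromic; "
                "Type IIS recognition sites are non-palindromic"
            )
        if self.spacer_top < 0 or self.spacer_bottom <= self.spacer_top:
            raise ValueError(f"{self.name}: need 0 <= spacer_top < spacer_bottom")

    @property
    def overhang_length(self) -> int:
        return self.spacer_bottom - self.spacer_top

    def __str__(self) -> str:
        return f"{self.name} {self.recognition}({self.spacer_top}/{self.spacer_bottom})"


#: Enzymes used by the common MoClo kits (YTK, Cidar, EcoFlex, ...).
BUILTIN_TYPE_IIS: dict[str, TypeIISEnzyme] = {
    e.name: e
    for e in (
        TypeIISEnzyme("BsaI", "GGTCTC", 1, 5),
        TypeIISEnzyme("BsmBI", "CGTCTC", 1, 5),
        TypeIISEnzyme("BbsI", "GAAGAC", 2, 6),
        TypeIISEnzyme("SapI", "GCTCTTC", 1, 4),
        TypeIISEnzyme("AarI", "CACCTGC", 4, 8),
    )
}


def get_type_iis(name: str, extra: dict[str, TypeIISEnzyme] | None = None) -> TypeIISEnzyme:
    """Look up an enzyme by name in the built-in table plus user additions."""
    table = dict(BUILTIN_TYPE_IIS)
    if extra:
        table.update(extra)
    try:
        return table[name]
    except KeyError:
        known = ", ".join(sorted(table))
        raise KeyError(f"unknown Type IIS enzyme {name!r}; known: {known}") from None


def load_enzyme_config(path: str | Path) -> dict[str, TypeIISEnzyme]:
    """Read user enzyme definitions from a YAML file.

    Schema: a mapping of name -> {recognition, spacer_top, spacer_bottom}.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for name, spec in raw.items():
        out[name] = TypeIISEnzyme(
            name=name,
            recognition=spec["recognition"],
            spacer_top=int(spec["spacer_top"]),
            spacer_bottom=int(spec["spacer_bottom"]),
        )
    return out


@dataclass(frozen=True)
class SiteHit:
    """One recognition-site occurrence with its computed cut positions."""

    enzyme: TypeIISEnzyme
    strand: str  # '+' or '-'
    recognition_start: int
    top_cut: int
    bottom_cut: int


@dataclass(frozen=True)
class StickyFragment:
    """A double-stranded segment with a fusion site at each end.

    The canonical top-strand representation is ``left_fusion + payload``;
    ``right_fusion`` is the overhang that the *next* fragment contributes
    in an assembly (it is physically present on this fragment's bottom
    strand). Feature coordinates are relative to the start of
    ``left_fusion``.
    """

    left_fusion: str
    payload: str
    right_fusion: str
    source_id: str = ""
    features: tuple[AnnotationFeature, ...] = ()

    def __post_init__(self):
        for fusion in (self.left_fusion, self.right_fusion):
            if set(fusion) - set("ACGT"):
                raise ValueError(f"fusion site {fusion!r} must be over A/C/G/T")

    @property
    def top_strand(self) -> str:
        return self.left_fusion + self.payload

    @property
    def full_duplex(self) -> str:
        """Entire double-stranded extent (including the right overhang)."""
        return self.left_fusion + self.payload + self.right_fusion

    def __len__(self) -> int:
        return len(self.top_strand)

    def contains_recognition(self, enzyme: TypeIISEnzyme) -> bool:
        s = self.full_duplex
        return enzyme.recognition in s or revcomp(enzyme.recognition) in s

    def reverse_complement(self) -> "StickyFragment":
        """The same physical fragment flipped over."""
        n_full = len(self.full_duplex)
        feats = tuple(
            AnnotationFeature(
                label=f.label,
                kind=f.kind,
                start=n_full - f.end,
                end=n_full - f.start,
                strand="-" if f.strand == "+" else "+",
            )
            for f in self.features
            if f.start < f.end
        )
        return StickyFragment(
            left_fusion=revcomp(self.right_fusion),
            payload=revcomp(self.payload),
            right_fusion=revcomp(self.left_fusion),
            source_id=self.source_id,
            features=feats,
        )

    def key(self) -> tuple[str, str, str]:
        """(left, payload, right) — the identity used in multiset comparisons."""
        return (self.left_fusion, self.payload, self.right_fusion)


def _occurrences(haystack: str, needle: str, length: int, circular: bool) -> list[int]:
    """Start positions of *needle* on the top strand, wrapping on circles."""
    if not needle:
        return []
    search = haystack + haystack[: len(needle) - 1] if circular else haystack
    hits, start = [], 0
    while True:
        i = search.find(needle, start)
        if i == -1 or i >= length:
            break
        hits.append(i)
        start = i + 1
    return hits


def find_sites(molecule: DnaMolecule, enzyme: TypeIISEnzyme) -> list[SiteHit]:
    """All recognition-site occurrences on both strands, with cut positions.

    Matching wraps the origin on circular molecules; cut coordinates wrap
    modulo the length. On linear molecules, sites whose cuts fall outside
    the sequence are dropped (the enzyme cannot cut beyond the end).
    """
    seq, n = molecule.sequence, len(molecule)
    circular = molecule.is_circular
    m = len(enzyme.recognition)
    hits: list[SiteHit] = []
    for p in _occurrences(seq, enzyme.recognition, n, circular):
        top = p + m + enzyme.spacer_top
        bottom = p + m + enzyme.spacer_bottom
        if circular:
            hits.append(SiteHit(enzyme, "+", p, top % n, bottom % n))
        elif bottom <= n:
            hits.append(SiteHit(enzyme, "+", p, top, bottom))
    for q in _occurrences(seq, revcomp(enzyme.recognition), n, circular):
        top = q - enzyme.spacer_bottom
        bottom = q - enzyme.spacer_top
        if circular:
            hits.append(SiteHit(enzyme, "-", q, top % n, bottom % n))
        elif top >= 0:
            hits.append(SiteHit(enzyme, "-", q, top, bottom))
    hits.sort(key=lambda h: (h.recognition_start, h.strand))
    return hits


def _mod_slice(seq: str, start: int, end: int) -> str:
    """seq[start:end] with circular wrapping; start==end gives ''."""
    n = len(seq)
    start %= n
    end %= n
    if start < end:
        return seq[start:end]
    if start == end:
        return ""
    return seq[start:] + seq[:end]


def _span_len(start: int, end: int, n: int) -> int:
    return (end - start) % n


def digest(molecule: DnaMolecule, enzyme: TypeIISEnzyme) -> list[StickyFragment]:
    """Cut at every site and return the sticky fragments.

    Circular molecules with k distinct cuts yield k fragments whose
    (payload + overhang) lengths sum to the molecule length. Cuts with
    identical coordinates (two sites directing the same cut, as in
    re-digestible acceptor products) collapse into one; cuts whose overhang
    regions *partially* overlap are a collision error — biologically a
    malformed part plasmid.
    """
    hits = find_sites(molecule, enzyme)
    if not hits:
        raise NoSitesError(
            f"{enzyme.name} has no recognition site on {molecule.id!r}; molecule left uncut"
        )
    n = len(molecule)
    oh = enzyme.overhang_length
    cuts = sorted({(h.top_cut, h.bottom_cut) for h in hits})
    # overhang regions [top, top+oh) must be disjoint between distinct cuts
    for (t1, _), (t2, _) in zip(cuts, cuts[1:] + cuts[:1]):
        if len(cuts) > 1 and _span_len(t1, t2, n) < oh:
            raise CutCollisionError(
                f"{molecule.id!r}: cuts at {t1} and {t2} overlap within one "
                f"{oh}-nt overhang region"
            )
    if molecule.is_circular and len(cuts) == 1:
        raise SingleCutError(
            f"{molecule.id!r}: exactly one {enzyme.name} cut on a circular molecule "
            "(nicked circle, nothing is released)"
        )

    seq = molecule.sequence
    fragments: list[StickyFragment] = []
    if molecule.is_circular:
        for (t1, _), (t2, _) in zip(cuts, cuts[1:] + cuts[:1]):
            left = _mod_slice(seq, t1, t1 + oh)
            # payload runs from the end of the left overhang to the next cut
            payload = _mod_slice(seq, t1 + oh, t2) if (t1 + oh) % n != t2 % n else ""
            right = _mod_slice(seq, t2, t2 + oh)
            feats = _features_in_span(molecule, t1, _span_len(t1, t2, n) + oh)
            fragments.append(
                StickyFragment(left, payload, right, source_id=molecule.id, features=feats)
            )
    else:
        bounds = [0] + [t for t, _ in cuts] + [n]
        for i in range(len(bounds) - 1):
            a, b = bounds[i], bounds[i + 1]
            left = seq[a : a + oh] if i > 0 else ""
            right = seq[b : b + oh] if i < len(bounds) - 2 else ""
            start_payload = a + (oh if i > 0 else 0)
            payload = seq[start_payload:b]
            feats = tuple(
                f.shifted(-a) for f in molecule.features if a <= f.start and f.end <= b + oh
            )
            fragments.append(
                StickyFragment(left, payload, right, source_id=molecule.id, features=feats)
            )
    return fragments


def _features_in_span(
    molecule: DnaMolecule, start: int, span: int
) -> tuple[AnnotationFeature, ...]:
    """Features fully contained in the (possibly wrapping) span, rebased to it."""
    n = len(molecule)
    out = []
    for f in molecule.features:
        if f.start >= f.end:
            continue  # wrapping features not carried onto fragments
        rel = (f.start - start) % n
        if rel + (f.end - f.start) <= span:
            out.append(replace(f, start=rel, end=rel + (f.end - f.start)))
    return tuple(out)


def select_insert_fragment(
    fragments: list[StickyFragment], enzyme: TypeIISEnzyme
) -> StickyFragment:
    """The unique fragment free of recognition sites on either strand.

    This is the piece released *inside* the enzyme sites — the part (or,
    for an acceptor plasmid built with outward-facing sites around the
    drop-out, the backbone). Zero or multiple recognition-free fragments
    are errors naming the source plasmid.
    """
    free = [f for f in fragments if not f.contains_recognition(enzyme)]
    source = fragments[0].source_id if fragments else "?"
    if not free:
        raise NoReleasablePartError(
            f"{source!r}: no releasable part — every fragment retains a "
            f"{enzyme.name} recognition site"
        )
    if len(free) > 1:
        pairs = ", ".join(f"({f.left_fusion}/{f.right_fusion})" for f in free)
        raise AmbiguousInsertError(
            f"{source!r}: {len(free)} recognition-free fragments with fusion pairs {pairs}"
        )
    return free[0]
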