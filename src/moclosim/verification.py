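"""In-silico construct verification: PCR, restriction digests, gel rendering.

Verification answers "does the plasmid I picked look like the one I
designed?" by predicting the band pattern a PCR or an analytical digest
would give. Primer binding is exact full-length matching (no mismatch
model), which keeps predicted amplicon sizes deterministic. Amplicon
length is measured 5' start of the forward primer to 5' start of the
reverse primer, inclusive of both primers. The gel image is presentational
(band migration = a − b·log10(size)); the size tables are the contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from moclosim.digestion import BUILTIN_TYPE_IIS, TypeIISEnzyme, find_sites
from moclosim.errors import NoAmpliconError, UnknownEnzymeError, VerificationError
from moclosim.sequence_io import DnaMolecule, revcomp


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not 15 <= len(self.sequence) <= 40:
            raise VerificationError(
                f"primer {self.name!r}: length {len(self.sequence)} outside 15-40 nt"
            )
        if set(self.sequence) - set("ACGT"):
            raise VerificationError(f"primer {self.name!r}: alphabet must be A/C/G/T")


@dataclass(frozen=True)
class PalindromicEnzyme:
    """A conventional restriction enzyme cutting within its palindromic site.

    ``cut_offset`` is the top-strand gap index relative to the recognition
    start: EcoRI G^AATTC has cut_offset 1.
    """

    name: str
    recognition: str
    cut_offset: int


#: Common analytical cutters for verification digests.
BUILTIN_VERIFICATION: dict[str, PalindromicEnzyme] = {
    e.name: e
    for e in (
        PalindromicEnzyme("EcoRI", "GAATTC", 1),
        PalindromicEnzyme("BamHI", "GGATCC", 1),
        PalindromicEnzyme("HindIII", "AAGCTT", 1),
        PalindromicEnzyme("XhoI", "CTCGAG", 1),
        PalindromicEnzyme("NotI", "GCGGCCGC", 2),
    )
}


def _primer_sites(template: str, primer: str, circular: bool) -> list[int]:
    """Start positions of *primer* as written, on the given strand string."""
    n = len(template)
    search = template + template[: len(primer) - 1] if circular else template
    out, start = [], 0
    while True:
        i = search.find(primer, start)
        if i == -1 or i >= n:
            break
        out.append(i)
        start = i + 1
    return out


def simulate_pcr(template: DnaMolecule, fwd: Primer, rev: Primer) -> list[int]:
    """All productive amplicon lengths for one primer pair.

    The forward primer anneals where its sequence occurs on the top
    strand; the reverse primer where its reverse complement occurs
    (downstream of the forward site; wrapping around the origin on
    circular templates). Every productive (fwd site, rev site) pairing is
    reported, with a warning when a primer binds more than once.
    """
    seq, n = template.sequence, len(template)
    circular = template.is_circular
    f_sites = _primer_sites(seq, fwd.sequence, circular)
    r_sites = _primer_sites(seq, revcomp(rev.sequence), circular)
    if not f_sites:
        raise NoAmpliconError(
            f"forward primer {fwd.name!r} has no binding site on {template.id!r}",
            primer_name=fwd.name,
        )
    if not r_sites:
        raise NoAmpliconError(
            f"reverse primer {rev.name!r} has no binding site on {template.id!r}",
            primer_name=rev.name,
        )
    if len(f_sites) > 1 or len(r_sites) > 1:
        warnings.warn(
            f"multiple binding sites on {template.id!r} "
            f"({fwd.name}: {len(f_sites)}, {rev.name}: {len(r_sites)}); "
            "all products reported",
            stacklevel=2,
        )
    lengths = []
    for f in f_sites:
        for r in r_sites:
            end = r + len(rev.sequence)  # 5' end of the reverse primer, +1
            if circular:
                lengths.append(((end - f - 1) % n) + 1)
            elif end > f and r >= f:
                lengths.append(end - f)
    if not lengths:
        raise NoAmpliconError(
            f"{fwd.name}/{rev.name} bind {template.id!r} but in a non-productive "
            "arrangement (reverse site upstream of forward site)",
            primer_name=rev.name,
        )
    return sorted(lengths)


def _cut_positions(
    template: DnaMolecule, enzyme_name: str, extra: dict | None
) -> set[int]:
    table_iis = dict(BUILTIN_TYPE_IIS)
    table_pal = dict(BUILTIN_VERIFICATION)
    if extra:
        for name, enz in extra.items():
            if isinstance(enz, TypeIISEnzyme):
                table_iis[name] = enz
            else:
                table_pal[name] = enz
    if enzyme_name in table_pal:
        enz = table_pal[enzyme_name]
        seq, n = template.sequence, len(template)
        positions = set()
        search = seq + seq[: len(enz.recognition) - 1] if template.is_circular else seq
        start = 0
        while True:
            i = search.find(enz.recognition, start)
            if i == -1 or i >= n:
                break
            cut = i + enz.cut_offset
            if template.is_circular:
                positions.add(cut % n)
            elif 0 < cut < n:
                positions.add(cut)
            start = i + 1
        return positions
    if enzyme_name in table_iis:
        return {h.top_cut for h in find_sites(template, table_iis[enzyme_name])}
    known = ", ".join(sorted(set(table_pal) | set(table_iis)))
    raise UnknownEnzymeError(f"unknown enzyme {enzyme_name!r}; known: {known}")


def simulate_restriction_digest(
    template: DnaMolecule,
    enzymes: list[str],
    extra_enzymes: dict | None = None,
) -> list[int]:
    """Fragment lengths of a (multi-enzyme) analytical digest, descending.

    Cut positions are pooled across enzymes; a circular template with n
    cuts yields n fragments, a linear one n+1; lengths always sum to the
    template length. Zero cuts on a circular template return the uncut
    length with a warning.
    """
    positions: set[int] = set()
    for name in enzymes:
        positions |= _cut_positions(template, name, extra_enzymes)
    n = len(template)
    if not positions:
        if template.is_circular:
            warnings.warn(
                f"{template.id!r} is uncut by {', '.join(enzymes)}; "
                "reporting the full-length circle",
                stacklevel=2,
            )
        return [n]
    cuts = sorted(positions)
    if template.is_circular:
        sizes = [b - a for a, b in zip(cuts, cuts[1:] + [cuts[0] + n])]
    else:
        bounds = [0] + cuts + [n]
        sizes = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return sorted(sizes, reverse=True)


@dataclass(frozen=True)
class GelLane:
    label: str
    fragment_sizes: tuple[int, ...]

    def __post_init__(self):
        if any(s < 1 for s in self.fragment_sizes):
            raise VerificationError(f"lane {self.label!r}: band sizes must be >= 1 bp")
        object.__setattr__(
            self, "fragment_sizes", tuple(sorted(self.fragment_sizes, reverse=True))
        )


#: 1-kb-plus style ladder used when none is supplied.
DEFAULT_LADDER = (10000, 8000, 6000, 5000, 4000, 3000, 2000, 1500, 1000, 750, 500, 250)


def render_gel(
    lanes: list[GelLane],
    ladder: tuple[int, ...] = DEFAULT_LADDER,
    image_path: str | Path | None = None,
) -> pd.DataFrame:
    """Band table (and optionally a rendered gel image).

    Returns a DataFrame with one row per band (lane, label, size_bp,
    migration) where migration is monotone increasing in −log10(size).
    When *image_path* is given a PNG/SVG gel sketch is written, ladder in
    lane 1.
    """
    if not lanes:
        raise VerificationError("render_gel needs at least one lane")
    all_lanes = [GelLane("ladder", tuple(ladder))] + list(lanes)
    import math

    a, b = 10.0, 9.0  # migration = a - b*log10(size); presentational only
    records = []
    for idx, lane in enumerate(all_lanes):
        for size in lane.fragment_sizes:
            records.append(
                {
                    "lane": idx + 1,
                    "label": lane.label,
                    "size_bp": int(size),
                    "migration": round(a - b * math.log10(size) / 4.0, 6),
                }
            )
    table = pd.DataFrame(records, columns=["lane", "label", "size_bp", "migration"])
    if image_path is not None:
        _draw_gel(all_lanes, table, Path(image_path))
    return table


def _draw_gel(lanes: list[GelLane], table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * len(lanes), 4.0))
    ax.set_facecolor("#101018")
    for idx, lane in enumerate(lanes):
        sub = table[table["lane"] == idx + 1]
        for _, row in sub.iterrows():
            y = row["migration"]
            ax.plot(
                [idx + 0.7, idx + 1.3],
                [y, y],
                color="white" if idx else "#bbbbbb",
                linewidth=3 if idx else 2,
                solid_capstyle="butt",
            )
        ax.text(idx + 1, 10.6, lane.label, ha="center", fontsize=7, rotation=30)
    ax.set_xlim(0.3, len(lanes) + 0.7)
    ax.set_ylim(11.2, 6.0)  # wells at the top, small fragments run far
    ax.set_xticks([])
    ax.set_ylabel("migration (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
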