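"""DNA molecule data model and GenBank input/output.

The unit of work is :class:`DnaMolecule`: a named, annotated sequence with
explicit circular/linear topology. Input plasmids live in a directory of
GenBank files (the plasmid database); assembled products are written back
as GenBank plasmid maps. Coordinates are 0-based, end-exclusive throughout
the package and converted to GenBank's 1-based inclusive convention only
at serialization (biopython does this for us).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from moclosim.errors import DatabaseError, GenBankParseError, SequenceError

GENBANK_EXTENSIONS = (".gb", ".gbk", ".genbank")

_ALLOWED = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class AnnotationFeature:
    """One annotated interval: 0-based start, end-exclusive, stranded."""

    label: str
    kind: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise SequenceError(f"feature strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end < 0:
            raise SequenceError(f"negative feature coordinates: {self.start}..{self.end}")

    def shifted(self, offset: int) -> "AnnotationFeature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class DnaMolecule:
    """A named DNA sequence with topology and annotations.

    ``id`` equals the source file basename (without extension) for database
    inputs. The sequence is normalized to uppercase; only A, C, G, T and N
    are accepted — other IUPAC ambiguity codes are rejected because Type IIS
    site matching over degenerate sequence is not defined here.
    """

    id: str
    sequence: str
    topology: str = "circular"
    features: list[AnnotationFeature] = field(default_factory=list)
    description: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise SequenceError(f"molecule {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise SequenceError(
                f"molecule {self.id!r} contains unsupported letters {sorted(bad)}; "
                "only A, C, G, T, N are accepted"
            )
        if self.topology not in ("circular", "linear"):
            raise SequenceError(
                f"molecule {self.id!r}: topology must be 'circular' or 'linear', "
                f"got {self.topology!r}"
            )
        n = len(self.sequence)
        for f in self.features:
            if not (0 <= f.start < n):
                raise SequenceError(
                    f"molecule {self.id!r}: feature {f.label!r} start {f.start} outside [0, {n})"
                )
            if f.start < f.end and f.end > n:
                raise SequenceError(
                    f"molecule {self.id!r}: feature {f.label!r} end {f.end} beyond length {n}"
                )
            if f.start >= f.end and self.topology != "circular":
                raise SequenceError(
                    f"molecule {self.id!r}: wrapping feature {f.label!r} on a linear molecule"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a plain sequence string."""
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement(molecule: DnaMolecule) -> DnaMolecule:
    """Watson–Crick reverse complement with features mirrored and strand-flipped."""
    n = len(molecule)
    feats = [
        AnnotationFeature(
            label=f.label,
            kind=f.kind,
            start=n - f.end,
            end=n - f.start,
            strand="-" if f.strand == "+" else "+",
        )
        for f in molecule.features
        if f.start < f.end  # wrapping features are dropped on mirroring
    ]
    return DnaMolecule(
        id=molecule.id,
        sequence=revcomp(molecule.sequence),
        topology=molecule.topology,
        features=feats,
        description=molecule.description,
    )


def _feature_label(sf: SeqFeature) -> str:
    for key in ("label", "gene", "product", "note"):
        if key in sf.qualifiers and sf.qualifiers[key]:
            return str(sf.qualifiers[key][0])
    return sf.type


def read_genbank(path: str | Path) -> DnaMolecule:
    """Read one GenBank record into a :class:`DnaMolecule`.

    The molecule id is the file basename without extension. Topology comes
    from the LOCUS line; records that do not declare one default to circular
    (plasmid databases) with a warning.
    """
    path = Path(path)
    try:
        record: SeqRecord = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # biopython raises ValueError subclasses
        raise GenBankParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq:
        raise GenBankParseError(f"GenBank file {path} has an empty sequence")
    topology = record.annotations.get("topology")
    if topology not in ("circular", "linear"):
        warnings.warn(
            f"{path.name}: no topology on the LOCUS line; assuming circular (plasmid)",
            stacklevel=2,
        )
        topology = "circular"
    features = []
    for sf in record.features:
        if sf.type == "source":
            continue
        loc = sf.location
        if loc is None:
            continue
        for part in getattr(loc, "parts", [loc]):
            features.append(
                AnnotationFeature(
                    label=_feature_label(sf),
                    kind=sf.type,
                    start=int(part.start),
                    end=int(part.end),
                    strand="-" if part.strand == -1 else "+",
                )
            )
    return DnaMolecule(
        id=path.stem,
        sequence=seq,
        topology=topology,
        features=features,
        description=(record.description or "").strip(". "),
    )


def write_genbank(molecule: DnaMolecule, path: str | Path) -> Path:
    """Write a molecule as a GenBank flat file re-readable by :func:`read_genbank`."""
    path = Path(path)
    record = SeqRecord(
        Seq(molecule.sequence),
        id=molecule.id,
        name=molecule.id[:38],  # LOCUS name length limit
        description=molecule.description or molecule.id,
        annotations={"molecule_type": "ds-DNA", "topology": molecule.topology},
    )
    for f in molecule.features:
        if f.start < f.end:
            loc = SimpleLocation(f.start, f.end, strand=1 if f.strand == "+" else -1)
        else:  # wrapping feature on a circular molecule: split at the origin
            loc = SimpleLocation(f.start, len(molecule), strand=1 if f.strand == "+" else -1)
        record.features.append(
            SeqFeature(loc, type=f.kind or "misc_feature", qualifiers={"label": [f.label]})
        )
    with open(path, "w") as handle:
        SeqIO.write(record, handle, "genbank")
    return path


def load_database(directory: str | Path) -> dict[str, DnaMolecule]:
    """Load every GenBank file in *directory* keyed by unique basename.

    Two files sharing a basename (e.g. ``a.gb`` and ``a.gbk``) are a
    duplicate-id error. A malformed file raises :class:`DatabaseError`
    whose ``loaded`` attribute still carries the parseable molecules.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise DatabaseError(f"database directory {directory} does not exist")
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in GENBANK_EXTENSIONS)
    if not paths:
        warnings.warn(f"database directory {directory} contains no GenBank files", stacklevel=2)
        return {}
    seen: dict[str, Path] = {}
    for p in paths:
        if p.stem in seen:
            raise DatabaseError(
                f"duplicate plasmid id {p.stem!r}: {seen[p.stem].name} and {p.name}"
            )
        seen[p.stem] = p
    molecules: dict[str, DnaMolecule] = {}
    failures: list[str] = []
    for p in paths:
        try:
            molecules[p.stem] = read_genbank(p)
        except (GenBankParseError, SequenceError) as exc:
            failures.append(str(exc))
    if failures:
        raise DatabaseError(
            f"{len(failures)} file(s) failed to load "
            f"({len(molecules)} loaded successfully): " + "; ".join(failures),
            loaded=molecules,
        )
    return molecules
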