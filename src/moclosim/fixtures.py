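"""Synthetic miniature MoClo kits and campaigns for self-contained testing.

Real part kits (YTK and friends) live in external repositories; this
module generates an internally coherent stand-in: a grammar with one
fusion site per junction forming a closed circular chain, and entry
plasmids that each release exactly one recognition-free insert matching
their declared position. Everything is a pure function of the seed, so
generated files are byte-identical across runs.

Entry-plasmid layout (top strand, circularized)::

    [recognition][spacer] L payload R [spacer][revcomp(recognition)] stuffer

with the enzyme sites pointing inward at the part, so digestion releases
``(L, payload, R)`` and the backbone keeps both recognition sites.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from moclosim.campaign import IpMappingTable
from moclosim.digestion import StickyFragment, TypeIISEnzyme
from moclosim.errors import MocloSimError
from moclosim.grammar import MoCloGrammar, NamingConvention, PositionSpec, save_grammar
from moclosim.sequence_io import AnnotationFeature, DnaMolecule, revcomp, write_genbank

_GENERIC_NAMES = ("promoter", "cds", "terminator", "marker", "origin", "tag", "linker", "spacer")


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def pick_fusion_sites(n: int, length: int, rng: random.Random) -> list[str]:
    """n distinct non-palindromic fusion sites, none the reverse complement
    of another — mirroring real kit design rules against self-ligation."""
    candidates = ["".join(p) for p in itertools.product("ACGT", repeat=length)]
    rng.shuffle(candidates)
    chosen: list[str] = []
    taken: set[str] = set()
    for site in candidates:
        if site == revcomp(site):
            continue
        if site in taken or revcomp(site) in taken:
            continue
        chosen.append(site)
        taken.add(site)
        if len(chosen) == n:
            return chosen
    raise MocloSimError(
        f"cannot pick {n} mutually compatible fusion sites of length {length}"
    )


def _site_count(circle: str, motif: str) -> int:
    doubled = circle + circle[: len(motif) - 1]
    return doubled.count(motif)


def _clean_circle(seq: str, enzyme: TypeIISEnzyme) -> bool:
    """Exactly one recognition occurrence per strand on the circle."""
    return (
        _site_count(seq, enzyme.recognition) == 1
        and _site_count(seq, revcomp(enzyme.recognition)) == 1
    )


@dataclass
class EntryPart:
    """Bookkeeping for one generated entry plasmid."""

    part_name: str
    part_type: str
    plasmid_id: str
    position_index: int
    left_fusion: str
    payload: str
    right_fusion: str


@dataclass
class FixtureKit:
    grammar: MoCloGrammar
    enzyme: TypeIISEnzyme
    entry_plasmids: list[DnaMolecule]
    parts: list[EntryPart]
    mapping: IpMappingTable
    seed: int
    fusion_sites: list[str] = field(default_factory=list)

    @property
    def database(self) -> dict[str, DnaMolecule]:
        return {m.id: m for m in self.entry_plasmids}

    def parts_at(self, position_index: int) -> list[EntryPart]:
        return [p for p in self.parts if p.position_index == position_index]

    def expected_insert(self, part: EntryPart) -> StickyFragment:
        return StickyFragment(
            part.left_fusion, part.payload, part.right_fusion, source_id=part.plasmid_id
        )

    def expected_product_sequence(self, part_indices: list[int]) -> str:
        """Product top strand for one part choice per position, by construction."""
        chunks = []
        for pos, j in enumerate(part_indices):
            part = self.parts_at(pos)[j]
            chunks.append(part.left_fusion + part.payload)
        return "".join(chunks)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the kit as the file set the simulator consumes:
        a GenBank database directory, an iP_mapping CSV, a grammar YAML."""
        directory = Path(directory)
        db_dir = directory / "db"
        db_dir.mkdir(parents=True, exist_ok=True)
        for molecule in self.entry_plasmids:
            write_genbank(molecule, db_dir / f"{molecule.id}.gb")
        mapping_path = directory / "ip_mapping.csv"
        lines = ["part_name,part_type,plasmid_id"]
        for p in self.parts:
            lines.append(f"{p.part_name},{p.part_type},{p.plasmid_id}")
        mapping_path.write_text("\n".join(lines) + "\n")
        grammar_path = directory / "grammar.yaml"
        save_grammar(self.grammar, grammar_path)
        return {"db": db_dir, "mapping": mapping_path, "grammar": grammar_path}


def _make_entry_sequence(
    enzyme: TypeIISEnzyme,
    left: str,
    right: str,
    rng: random.Random,
    payload_range: tuple[int, int],
) -> tuple[str, str]:
    """(circular plasmid sequence, payload); resampled until exactly one
    recognition site per strand remains on the circle."""
    rec = enzyme.recognition
    for _ in range(200):
        payload = _random_dna(rng, rng.randint(*payload_range))
        stuffer = _random_dna(rng, rng.randint(250, 500))
        seq = (
            rec
            + _random_dna(rng, enzyme.spacer_top)
            + left
            + payload
            + right
            + _random_dna(rng, enzyme.spacer_top)
            + revcomp(rec)
            + stuffer
        )
        if _clean_circle(seq, enzyme):
            return seq, payload
    raise MocloSimError("could not scrub stray recognition sites from a fixture plasmid")


def make_kit(
    n_positions: int,
    parts_per_position: int,
    enzyme: TypeIISEnzyme,
    seed: int,
    out_dir: str | Path | None = None,
    payload_range: tuple[int, int] = (20, 200),
) -> FixtureKit:
    """Generate a miniature coherent kit: grammar + entry plasmids + mapping.

    Fusion sites form one circular chain across positions; each entry
    plasmid digests to exactly one recognition-free insert whose fusion
    pair matches its position. Fully determined by *seed*. With *out_dir*
    the kit files are written to disk as well.
    """
    if not 2 <= n_positions <= 8:
        raise MocloSimError("n_positions must be between 2 and 8")
    if parts_per_position < 1:
        raise MocloSimError("parts_per_position must be >= 1")
    rng = random.Random(seed)
    sites = pick_fusion_sites(n_positions, enzyme.overhang_length, rng)
    positions = [
        PositionSpec(
            type_name=str(i + 1),
            generic_name=_GENERIC_NAMES[i % len(_GENERIC_NAMES)],
            expected_left_fusion=sites[i],
            expected_right_fusion=sites[(i + 1) % n_positions],
        )
        for i in range(n_positions)
    ]
    grammar = MoCloGrammar(
        name=f"fixture-kit-{n_positions}x{parts_per_position}",
        enzyme=enzyme.name,
        positions=positions,
        naming=NamingConvention(joiner="-", prefix="oP", pad_width=3),
    )

    molecules: list[DnaMolecule] = []
    parts: list[EntryPart] = []
    mapping_rows: list[tuple[str, str | None, str]] = []
    counter = 1
    for i, pos in enumerate(positions):
        left, right = sites[i], sites[(i + 1) % n_positions]
        for j in range(parts_per_position):
            part_name = f"{pos.generic_name}{chr(ord('A') + j)}"
            plasmid_id = f"pFIX{counter:03d}"
            counter += 1
            seq, payload = _make_entry_sequence(enzyme, left, right, rng, payload_range)
            part_start = len(enzyme.recognition) + enzyme.spacer_top
            features = [
                AnnotationFeature(
                    label=part_name,
                    kind="misc_feature",
                    start=part_start,
                    end=part_start + len(left) + len(payload) + len(right),
                    strand="+",
                )
            ]
            molecules.append(
                DnaMolecule(
                    id=plasmid_id,
                    sequence=seq,
                    topology="circular",
                    features=features,
                    description=f"entry plasmid {part_name} (type {pos.type_name})",
                )
            )
            parts.append(
                EntryPart(
                    part_name=part_name,
                    part_type=pos.type_name,
                    plasmid_id=plasmid_id,
                    position_index=i,
                    left_fusion=left,
                    payload=payload,
                    right_fusion=right,
                )
            )
            mapping_rows.append((part_name, pos.type_name, plasmid_id))

    kit = FixtureKit(
        grammar=grammar,
        enzyme=enzyme,
        entry_plasmids=molecules,
        parts=parts,
        mapping=IpMappingTable(mapping_rows),
        seed=seed,
        fusion_sites=sites,
    )
    if out_dir is not None:
        kit.write(out_dir)
    return kit


DEFECT_KINDS = ("typo", "wrong_type")


def make_campaign(
    kit: FixtureKit,
    n_rows: int,
    error_rows: list[int] | None = None,
    seed: int = 0,
    path: str | Path | None = None,
) -> tuple[str, dict]:
    """A typed-mode campaign drawing random parts per position.

    Rows listed in *error_rows* (1-based) get an injected defect — a
    typo'd part name or a part under the wrong type — cycling through
    :data:`DEFECT_KINDS`. Returns the campaign CSV text and a manifest
    recording each injected defect; with *path* both are written to disk
    (manifest as ``<path>.manifest.json``).
    """
    error_rows = list(error_rows or [])
    rng = random.Random(seed)
    n_positions = len(kit.grammar.positions)
    header = ["output_name"] + [
        f"{p.generic_name} ({p.type_name})" for p in kit.grammar.positions
    ]
    lines = [",".join(header)]
    manifest: dict = {"seed": seed, "defects": {}}
    for row in range(1, n_rows + 1):
        choices = [rng.randrange(len(kit.parts_at(i))) for i in range(n_positions)]
        names = [kit.parts_at(i)[j].part_name for i, j in enumerate(choices)]
        if row in error_rows:
            kind = DEFECT_KINDS[error_rows.index(row) % len(DEFECT_KINDS)]
            col = rng.randrange(n_positions)
            if kind == "typo":
                bad = names[col] + "XX"
            else:  # a real part name, but from another position → wrong type
                other = (col + 1) % n_positions
                bad = kit.parts_at(other)[0].part_name
            manifest["defects"][str(row)] = {"kind": kind, "column": col + 1, "token": bad}
            names[col] = bad
        lines.append(",".join([f"construct{row:02d}"] + names))
    text = "\n".join(lines) + "\n"
    if path is not None:
        path = Path(path)
        path.write_text(text)
        Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=2))
    return text, manifest


def make_random_circle(
    enzyme: TypeIISEnzyme,
    n_cut_pairs: int,
    rng: random.Random,
    max_segment: int = 400,
) -> DnaMolecule:
    """A random circular molecule with *n_cut_pairs* inward-facing site pairs.

    Used for conservation and rotation-invariance property testing: the
    molecule digests into 2·n_cut_pairs fragments (each part piece and
    each backbone piece), with no stray sites.
    """
    sites = pick_fusion_sites(2 * n_cut_pairs, enzyme.overhang_length, rng)
    rec = enzyme.recognition
    for _ in range(200):
        chunks = []
        for i in range(n_cut_pairs):
            left, right = sites[2 * i], sites[2 * i + 1]
            chunks.append(
                rec
                + _random_dna(rng, enzyme.spacer_top)
                + left
                + _random_dna(rng, rng.randint(10, max_segment))
                + right
                + _random_dna(rng, enzyme.spacer_top)
                + revcomp(rec)
                + _random_dna(rng, rng.randint(20, max_segment))
            )
        seq = "".join(chunks)
        if (
            _site_count(seq, rec) == n_cut_pairs
            and _site_count(seq, revcomp(rec)) == n_cut_pairs
        ):
            return DnaMolecule(id="random_circle", sequence=seq, topology="circular")
    raise MocloSimError("could not build a clean random circle")
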