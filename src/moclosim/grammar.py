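"""MoClo typed systems: grammar definition, validation, campaign templates.

A MoClo grammar fixes an ordered list of typed positions (e.g. type "2" =
promoter), the Type IIS enzyme, and — optionally — the fusion-site pair
each type exposes. When consecutive positions' fusion sites are declared
they must chain circularly (right of position i = left of position i+1,
last right = first left): the coherence property that makes a part kit a
closed assembly system. Grammars are stored as YAML; templates are emitted
as CSV with one column per position.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from moclosim.errors import GrammarError


@dataclass
class PositionSpec:
    """One typed slot of the assembly: e.g. type '2', generic name 'promoter'."""

    type_name: str
    generic_name: str
    allows_subparts: bool = False
    optional: bool = False
    expected_left_fusion: str | None = None
    expected_right_fusion: str | None = None


@dataclass
class NamingConvention:
    """How composed output names and generated plasmid ids are built."""

    joiner: str = "-"
    prefix: str = "oP"
    pad_width: int = 3

    def __post_init__(self):
        if not self.prefix:
            raise GrammarError("naming prefix must be non-empty")
        if self.pad_width < 1:
            raise GrammarError("pad_width must be >= 1")

    def plasmid_id(self, counter: int) -> str:
        return f"{self.prefix}{counter:0{self.pad_width}d}"


@dataclass
class MoCloGrammar:
    name: str
    enzyme: str
    positions: list[PositionSpec]
    subpart_separator: str = "."
    naming: NamingConvention = field(default_factory=NamingConvention)

    def __post_init__(self):
        if not self.positions:
            raise GrammarError(f"grammar {self.name!r} has no positions")
        if len(self.subpart_separator) != 1:
            raise GrammarError("subpart separator must be a single character")

    @property
    def expected_fusions(self) -> list[tuple[str | None, str | None]]:
        return [(p.expected_left_fusion, p.expected_right_fusion) for p in self.positions]


def validate_grammar(grammar: MoCloGrammar) -> list[str]:
    """Coherence findings; an empty list means the grammar is a closed system.

    Checks: unique position type names, separator not colliding with type
    names, circular fusion-site chaining, and no fusion site reused by two
    positions.
    """
    findings: list[str] = []
    names = [p.type_name for p in grammar.positions]
    for name in sorted({n for n in names if names.count(n) > 1}):
        findings.append(f"duplicate position type name {name!r}")
    for p in grammar.positions:
        if grammar.subpart_separator in p.type_name:
            findings.append(
                f"type name {p.type_name!r} contains the subpart separator "
                f"{grammar.subpart_separator!r}"
            )
    n = len(grammar.positions)
    for i, p in enumerate(grammar.positions):
        q = grammar.positions[(i + 1) % n]
        if p.expected_right_fusion and q.expected_left_fusion:
            if p.expected_right_fusion != q.expected_left_fusion:
                findings.append(
                    f"junction mismatch between positions {p.type_name} and {q.type_name}: "
                    f"{p.expected_right_fusion} vs {q.expected_left_fusion}"
                )
    lefts = [p.expected_left_fusion for p in grammar.positions if p.expected_left_fusion]
    for site in sorted({s for s in lefts if lefts.count(s) > 1}):
        positions = [p.type_name for p in grammar.positions if p.expected_left_fusion == site]
        findings.append(
            f"fusion site {site} used as left fusion by positions {', '.join(positions)}"
        )
    return findings


def generate_template(grammar: MoCloGrammar) -> str:
    """Campaign-template CSV text tailored to the grammar.

    The header carries the output-name column followed by one column per
    position labeled ``generic_name (type_name)``; leading comment lines
    document the enzyme and the subpart separator. Deterministic: the same
    grammar always yields byte-identical text.
    """
    findings = validate_grammar(grammar)
    if findings:
        raise GrammarError(
            f"grammar {grammar.name!r} is not coherent: " + "; ".join(findings)
        )
    buf = io.StringIO()
    buf.write(f"# campaign template for grammar '{grammar.name}' (enzyme {grammar.enzyme})\n")
    buf.write("# one row per one-pot reaction; leave output_name blank to auto-compose\n")
    sub_positions = [p.generic_name for p in grammar.positions if p.allows_subparts]
    if sub_positions:
        buf.write(
            f"# positions allowing subparts ({', '.join(sub_positions)}): join subpart "
            f"names with the separator '{grammar.subpart_separator}'\n"
        )
    header = ["output_name"] + [f"{p.generic_name} ({p.type_name})" for p in grammar.positions]
    buf.write(",".join(header) + "\n")
    return buf.getvalue()


def write_template(grammar: MoCloGrammar, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(generate_template(grammar))
    return path


def compose_output_name(parts: list[str], convention: NamingConvention) -> str:
    """Join part names with the convention's joiner into an output name."""
    if not parts:
        raise GrammarError("cannot compose an output name from an empty part list")
    for p in parts:
        if convention.joiner in p:
            raise GrammarError(
                f"part name {p!r} contains the name joiner {convention.joiner!r}; "
                "rename the part or change the joiner"
            )
    return convention.joiner.join(parts)


def load_grammar(path: str | Path) -> MoCloGrammar:
    """Read a grammar from its YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise GrammarError(f"grammar file {path} is not a YAML mapping")
    try:
        positions = [
            PositionSpec(
                type_name=str(p["type_name"]),
                generic_name=str(p["generic_name"]),
                allows_subparts=bool(p.get("allows_subparts", False)),
                optional=bool(p.get("optional", False)),
                expected_left_fusion=p.get("expected_left_fusion"),
                expected_right_fusion=p.get("expected_right_fusion"),
            )
            for p in raw["positions"]
        ]
        naming_raw = raw.get("naming", {})
        naming = NamingConvention(
            joiner=naming_raw.get("joiner", "-"),
            prefix=naming_raw.get("prefix", "oP"),
            pad_width=int(naming_raw.get("pad_width", 3)),
        )
        return MoCloGrammar(
            name=str(raw["name"]),
            enzyme=str(raw["enzyme"]),
            positions=positions,
            subpart_separator=str(raw.get("subpart_separator", ".")),
            naming=naming,
        )
    except KeyError as exc:
        raise GrammarError(f"grammar file {path} is missing key {exc}") from exc


def save_grammar(grammar: MoCloGrammar, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "name": grammar.name,
        "enzyme": grammar.enzyme,
        "subpart_separator": grammar.subpart_separator,
        "naming": {
            "joiner": grammar.naming.joiner,
            "prefix": grammar.naming.prefix,
            "pad_width": grammar.naming.pad_width,
        },
        "positions": [
            {
                "type_name": p.type_name,
                "generic_name": p.generic_name,
                "allows_subparts": p.allows_subparts,
                "optional": p.optional,
                "expected_left_fusion": p.expected_left_fusion,
                "expected_right_fusion": p.expected_right_fusion,
            }
            for p in grammar.positions
        ],
    }
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path
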