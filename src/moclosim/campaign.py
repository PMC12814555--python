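"""Campaign parsing, part-name resolution, and batch simulation.

A campaign file holds one one-pot reaction per row. In *raw* mode each
cell is a part or plasmid name and rows may have any arity; in *typed*
mode (a grammar is supplied) the columns follow the grammar's positions
and each cell may hold several subparts joined by the grammar's separator.
Part names are resolved through one or more iP_mapping tables
(part_name, part_type, plasmid_id) against the GenBank database; names
that already equal a plasmid id resolve directly. Every row is simulated
independently — a failing row never aborts the campaign — and successes
are registered in a DB_produced table that later campaigns can load as a
mapping, closing the design-build loop.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from moclosim.__about__ import __version__ as _software_version
from moclosim.assembly import AssemblyResult, simulate_reaction
from moclosim.digestion import TypeIISEnzyme
from moclosim.errors import CampaignError, ReactionError, ResolutionError
from moclosim.grammar import MoCloGrammar, NamingConvention, compose_output_name
from moclosim.sequence_io import DnaMolecule


@dataclass(frozen=True)
class PartReference:
    """One cell of a campaign row: a part name, optional type, and subparts."""

    name: str
    part_type: str | None = None
    subparts: tuple[str, ...] = ()

    def tokens(self) -> list[str]:
        """The individually resolvable names (subparts, or the name itself)."""
        return list(self.subparts) if self.subparts else [self.name]


@dataclass
class IpMappingTable:
    """Rows of (part_name, part_type, plasmid_id); lookups by name and type."""

    rows: list[tuple[str, str | None, str]] = field(default_factory=list)

    def __post_init__(self):
        seen: dict[tuple[str, str | None], str] = {}
        for name, ptype, pid in self.rows:
            key = (name, ptype)
            if key in seen and seen[key] != pid:
                raise CampaignError(
                    f"mapping collision: part {name!r} (type {ptype!r}) maps to both "
                    f"{seen[key]!r} and {pid!r}"
                )
            seen[key] = pid
        self._index = seen

    def lookup(self, name: str, part_type: str | None) -> str | None:
        """Typed lookup: (name, type), falling back to an untyped row.
        Untyped lookup: unique by name across all types, else an error."""
        if part_type is not None:
            hit = self._index.get((name, part_type))
            if hit is not None:
                return hit
            return self._index.get((name, None))
        hits = sorted({pid for (n, _), pid in self._index.items() if n == name})
        if len(hits) > 1:
            types = sorted(str(t) for (n, t), _ in self._index.items() if n == name)
            raise ResolutionError(
                f"part name {name!r} is ambiguous without a type "
                f"(present as types {', '.join(types)})",
                token=name,
            )
        return hits[0] if hits else None

    def __len__(self) -> int:
        return len(self._index)


def load_mapping(paths: list[str | Path] | str | Path) -> IpMappingTable:
    """Load one or several iP_mapping CSVs into a single table.

    Expected header: part_name, part_type, plasmid_id (comma or semicolon
    delimited). (name, type) pairs must be unique across all files.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    rows: list[tuple[str, str | None, str]] = []
    for path in paths:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
        df.columns = [c.strip().lower() for c in df.columns]
        required = {"part_name", "plasmid_id"}
        if not required.issubset(df.columns):
            raise CampaignError(
                f"mapping file {path}: header must contain part_name and plasmid_id "
                f"(got {', '.join(df.columns)})"
            )
        for _, r in df.iterrows():
            ptype = r.get("part_type")
            ptype = None if pd.isna(ptype) or str(ptype).strip() == "" else str(ptype).strip()
            rows.append((str(r["part_name"]).strip(), ptype, str(r["plasmid_id"]).strip()))
    return IpMappingTable(rows)


@dataclass
class AssemblyRequest:
    """One campaign row resolved to concrete molecules plus its output name."""

    row_number: int
    output_name: str
    part_refs: list[PartReference]
    resolved_inputs: list[DnaMolecule] = field(default_factory=list)


@dataclass
class RowOutcome:
    row_number: int
    output_name: str
    status: str  # success | resolution_failed | reaction_failed | assembly statuses
    product: DnaMolecule | None = None
    plasmid_id: str | None = None
    message: str = ""
    diagnostics: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status == "success"


@dataclass
class CampaignReport:
    requests: list[AssemblyRequest]
    outcomes: list[RowOutcome]
    produced: list[dict]  # rows of the DB_produced table
    provenance: list[dict]
    enzyme: str

    @property
    def n_success(self) -> int:
        return sum(1 for o in self.outcomes if o.ok)

    @property
    def n_failed(self) -> int:
        return len(self.outcomes) - self.n_success

    def products(self) -> list[DnaMolecule]:
        return [o.product for o in self.outcomes if o.ok]

    def to_json(self) -> str:
        """Deterministic serialization of the campaign outcome."""
        payload = {
            "enzyme": self.enzyme,
            "rows": [
                {
                    "row": o.row_number,
                    "output_name": o.output_name,
                    "status": o.status,
                    "plasmid_id": o.plasmid_id,
                    "length": len(o.product) if o.product else None,
                    "sequence": o.product.sequence if o.product else None,
                    "message": o.message,
                }
                for o in self.outcomes
            ],
            "produced": self.produced,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _split_row(line_cells: list[str]) -> list[str]:
    return [c.strip() for c in line_cells]


def _detect_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


@dataclass
class CampaignRow:
    row_number: int
    output_name: str
    part_refs: list[PartReference]


def parse_campaign(path: str | Path, grammar: MoCloGrammar | None = None) -> list[CampaignRow]:
    """Parse a campaign file into rows of part references.

    Column 1 is the output name (may be blank → auto-composed). With a
    grammar (typed mode) the remaining columns must match the grammar's
    positions and cells may carry subparts joined by the separator; without
    one (raw mode) rows may have any number of part cells, with blanks
    skipped. Comment lines start with '#'; a header row whose first cell is
    'output_name' is ignored.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, header=None, dtype=str)
        raw_rows = [[("" if pd.isna(c) else str(c)) for c in row] for row in df.values]
    else:
        text = path.read_text()
        delim = _detect_delimiter(text.splitlines()[0] if text.splitlines() else ",")
        raw_rows = list(csv.reader(text.splitlines(), delimiter=delim))

    rows: list[CampaignRow] = []
    row_number = 0
    for cells in raw_rows:
        cells = _split_row(cells)
        if not cells or all(c == "" for c in cells):
            continue
        if cells[0].startswith("#"):
            continue
        if cells[0].lower() == "output_name":
            continue  # template header
        row_number += 1
        output_name = cells[0]
        part_cells = cells[1:]
        if grammar is not None:
            rows.append(_typed_row(row_number, output_name, part_cells, grammar))
        else:
            refs = [PartReference(name=c) for c in part_cells if c != ""]
            rows.append(CampaignRow(row_number, output_name, refs))
    return rows


def _typed_row(
    row_number: int, output_name: str, cells: list[str], grammar: MoCloGrammar
) -> CampaignRow:
    positions = grammar.positions
    # trailing blanks beyond the grammar's arity are tolerated
    while len(cells) > len(positions) and cells[-1] == "":
        cells = cells[:-1]
    if len(cells) != len(positions):
        expected = ["output_name"] + [f"{p.generic_name} ({p.type_name})" for p in positions]
        raise CampaignError(
            f"row {row_number}: expected {len(positions)} part columns for grammar "
            f"{grammar.name!r} but found {len(cells)}; header should be "
            + ", ".join(expected)
        )
    refs: list[PartReference] = []
    for pos, cell in zip(positions, cells):
        if cell == "":
            if pos.optional:
                continue
            raise CampaignError(
                f"row {row_number}: position {pos.generic_name!r} ({pos.type_name}) "
                "is required but the cell is blank"
            )
        if grammar.subpart_separator in cell:
            if not pos.allows_subparts:
                raise CampaignError(
                    f"row {row_number}: position {pos.generic_name!r} does not allow "
                    f"subparts but got {cell!r}"
                )
            subs = tuple(s.strip() for s in cell.split(grammar.subpart_separator))
            if len(subs) < 2 or any(s == "" for s in subs):
                raise CampaignError(f"row {row_number}: malformed subpart cell {cell!r}")
            refs.append(PartReference(name=cell, part_type=pos.type_name, subparts=subs))
        else:
            refs.append(PartReference(name=cell, part_type=pos.type_name))
    return CampaignRow(row_number, output_name, refs)


def resolve(
    part_refs: list[PartReference],
    mapping: IpMappingTable,
    db: dict[str, DnaMolecule],
) -> list[DnaMolecule]:
    """Resolve every reference (subparts individually, in order) to molecules.

    Resolution order per token: direct plasmid-id hit in the database, then
    the mapping by (name, type) — falling back to an untyped mapping row —
    then error. A mapped plasmid_id absent from the database names the
    missing file.
    """
    molecules: list[DnaMolecule] = []
    for col, ref in enumerate(part_refs, start=1):
        for token in ref.tokens():
            molecules.append(_resolve_token(token, ref.part_type, mapping, db, col))
    return molecules


def _resolve_token(
    token: str,
    part_type: str | None,
    mapping: IpMappingTable,
    db: dict[str, DnaMolecule],
    column: int,
) -> DnaMolecule:
    if token in db:
        return db[token]
    try:
        pid = mapping.lookup(token, part_type)
    except ResolutionError as exc:
        raise ResolutionError(f"column {column}: {exc}", token=token, column=column) from exc
    if pid is None:
        raise ResolutionError(
            f"column {column}: cannot resolve part name {token!r}"
            + (f" (type {part_type})" if part_type else "")
            + " — not a plasmid id and not in any mapping",
            token=token,
            column=column,
        )
    if pid not in db:
        raise ResolutionError(
            f"column {column}: part {token!r} maps to plasmid {pid!r} "
            "but no such GenBank file is in the database",
            token=token,
            column=column,
        )
    return db[pid]


_COUNTER_RE_CACHE: dict[str, re.Pattern] = {}


def next_counter(existing_ids, naming: NamingConvention) -> int:
    """First free counter: one past the largest prefix+digits id in use."""
    pat = _COUNTER_RE_CACHE.setdefault(
        naming.prefix, re.compile(re.escape(naming.prefix) + r"(\d+)$")
    )
    best = 0
    for pid in existing_ids:
        m = pat.fullmatch(pid)
        if m:
            best = max(best, int(m.group(1)))
    return best + 1


def _expected_fusions_for(
    refs: list[PartReference], grammar: MoCloGrammar | None
) -> list[tuple[str | None, str | None]] | None:
    if grammar is None:
        return None
    by_type = {p.type_name: p for p in grammar.positions}
    expected: list[tuple[str | None, str | None]] = []
    for ref in refs:
        pos = by_type.get(ref.part_type or "")
        if pos is None:
            expected.extend([(None, None)] * len(ref.tokens()))
            continue
        tokens = ref.tokens()
        if len(tokens) == 1:
            expected.append((pos.expected_left_fusion, pos.expected_right_fusion))
        else:  # internal subpart junctions are not constrained by the grammar
            expected.append((pos.expected_left_fusion, None))
            expected.extend([(None, None)] * (len(tokens) - 2))
            expected.append((None, pos.expected_right_fusion))
    return expected


def run_campaign(
    rows: list[CampaignRow],
    mapping: IpMappingTable,
    db: dict[str, DnaMolecule],
    enzyme: TypeIISEnzyme,
    grammar: MoCloGrammar | None = None,
    naming: NamingConvention | None = None,
    timestamp: str | None = None,
) -> CampaignReport:
    """Simulate every row independently and collect the campaign report.

    Output plasmid ids are prefix + zero-padded counter, continuing past
    the largest counter already present in the database so chained
    campaigns never collide. All per-row errors are captured as outcomes.
    """
    if naming is None:
        naming = grammar.naming if grammar is not None else NamingConvention()
    counter = next_counter(db.keys(), naming)
    requests: list[AssemblyRequest] = []
    outcomes: list[RowOutcome] = []
    produced: list[dict] = []
    provenance: list[dict] = []

    for row in rows:
        name = row.output_name or _auto_name(row, naming)
        request = AssemblyRequest(row.row_number, name, row.part_refs)
        requests.append(request)
        try:
            inputs = resolve(row.part_refs, mapping, db)
        except ResolutionError as exc:
            outcomes.append(
                RowOutcome(
                    row.row_number,
                    name,
                    "resolution_failed",
                    message=f"row {row.row_number}: {exc}",
                )
            )
            continue
        request.resolved_inputs = inputs
        try:
            result = simulate_reaction(
                inputs,
                enzyme,
                product_id=name,
                expected_fusions=_expected_fusions_for(row.part_refs, grammar),
            )
        except ReactionError as exc:
            outcomes.append(
                RowOutcome(
                    row.row_number,
                    name,
                    "reaction_failed",
                    message=f"row {row.row_number} (plasmid {exc.plasmid_id}): {exc}",
                )
            )
            continue
        if not result.ok:
            outcomes.append(
                RowOutcome(
                    row.row_number,
                    name,
                    result.status,
                    message=f"row {row.row_number}: assembly {result.status}",
                    diagnostics=result.diagnostics,
                )
            )
            continue
        pid = naming.plasmid_id(counter)
        counter += 1
        product = result.product
        product.id = pid
        product.description = name
        outcomes.append(
            RowOutcome(
                row.row_number,
                name,
                "success",
                product=product,
                plasmid_id=pid,
                diagnostics=result.diagnostics,
            )
        )
        produced.append({"part_name": name, "part_type": "", "plasmid_id": pid})
        record = {
            "row": row.row_number,
            "output_name": name,
            "inputs": [m.id for m in inputs],
            "enzyme": enzyme.name,
            "product_id": pid,
            "product_length": len(product),
            "software_version": _software_version,
        }
        if timestamp is not None:
            record["timestamp"] = timestamp
        provenance.append(record)

    return CampaignReport(requests, outcomes, produced, provenance, enzyme.name)


def _auto_name(row: CampaignRow, naming: NamingConvention) -> str:
    return compose_output_name([r.name for r in row.part_refs], naming)


def write_db_produced(report: CampaignReport, path: str | Path) -> Path:
    """DB_produced CSV: (part_name, part_type, plasmid_id), successes only.

    Directly loadable with :func:`load_mapping`, so produced plasmids can
    serve as inputs of a later campaign without manual editing.
    """
    path = Path(path)
    pd.DataFrame(report.produced, columns=["part_name", "part_type", "plasmid_id"]).to_csv(
        path, index=False
    )
    return path


def write_provenance(report: CampaignReport, path: str | Path) -> Path:
    """JSON provenance: one record per successful row."""
    path = Path(path)
    path.write_text(json.dumps(report.provenance, indent=2))
    return path
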