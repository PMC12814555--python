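"""Equimolar dilution arithmetic and picklist export for a campaign.

Golden Gate reactions want each part present at the same molar amount
(typically tens of fmol). Given stock concentrations in ng/µL and part
lengths, the required volume per reaction is

    v [µL] = target_amount [fmol] × length [bp] × 650e-6 [ng/fmol/bp] / c [ng/µL]

using the standard 650 g·mol⁻¹·bp⁻¹ average molar mass of double-stranded
DNA. Volumes below the pipettable minimum get a power-of-ten pre-dilution.
Master-mix totals multiply per-reaction volume by usage count and a dead
volume factor. Internal arithmetic is exact; files round to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from moclosim.campaign import CampaignReport
from moclosim.errors import QuantitationError

#: Average molar mass of one double-stranded base pair, g/mol.
BP_MOLAR_MASS = 650.0


def fmol_to_ng(amount_fmol: float, length_bp: int) -> float:
    """Mass in ng of *amount_fmol* of a dsDNA molecule of *length_bp*."""
    if amount_fmol <= 0 or length_bp <= 0:
        raise QuantitationError(
            f"fmol_to_ng needs positive inputs (got {amount_fmol} fmol, {length_bp} bp)"
        )
    return amount_fmol * length_bp * BP_MOLAR_MASS * 1e-6


@dataclass(frozen=True)
class StockInfo:
    plasmid_id: str
    concentration: float  # ng/µL
    length: int  # bp

    def __post_init__(self):
        if self.concentration <= 0:
            raise QuantitationError(f"{self.plasmid_id}: concentration must be > 0 ng/µL")
        if self.length < 1:
            raise QuantitationError(f"{self.plasmid_id}: length must be >= 1 bp")


@dataclass(frozen=True)
class ReactionParams:
    target_amount: float  # fmol of each part per reaction
    reaction_volume: float  # µL
    min_pipettable_volume: float  # µL
    dead_volume_factor: float = 1.0

    def __post_init__(self):
        if min(self.target_amount, self.reaction_volume, self.min_pipettable_volume) <= 0:
            raise QuantitationError("reaction parameters must all be positive")
        if self.dead_volume_factor < 1:
            raise QuantitationError("dead_volume_factor must be >= 1")


@dataclass
class DilutionEntry:
    plasmid_id: str
    stock_volume_per_reaction: float  # µL of undiluted stock equivalent
    dilution_factor: int  # 1 = use stock directly
    working_volume_per_reaction: float  # µL pipetted per reaction
    n_reactions: int
    total_working_volume: float  # µL of (diluted) stock to prepare


@dataclass
class DilutionPlan:
    entries: list[DilutionEntry]
    params: ReactionParams
    # reaction key (row number) -> water top-up volume in µL
    water_per_reaction: dict[int, float] = field(default_factory=dict)

    def entry(self, plasmid_id: str) -> DilutionEntry:
        for e in self.entries:
            if e.plasmid_id == plasmid_id:
                return e
        raise KeyError(plasmid_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "plasmid_id": e.plasmid_id,
                    "dilution_factor": e.dilution_factor,
                    "volume_per_reaction_ul": round(e.working_volume_per_reaction, 2),
                    "n_reactions": e.n_reactions,
                    "total_volume_ul": round(e.total_working_volume, 2),
                }
                for e in self.entries
            ]
        )


def _predilution_factor(volume: float, min_volume: float) -> int:
    factor = 1
    while volume * factor < min_volume:
        factor *= 10
    return factor


def compute_dilutions(
    stocks: list[StockInfo],
    params: ReactionParams,
    report: CampaignReport,
) -> DilutionPlan:
    """Per-plasmid volumes, pre-dilutions, and per-reaction water top-ups.

    Every input plasmid used by a successful row needs a stock entry. The
    equimolarity contract: each part delivers exactly ``target_amount``
    fmol per reaction (via the pre-diluted working solution when the neat
    volume falls below the pipettable minimum).
    """
    by_id = {s.plasmid_id: s for s in stocks}
    usage: dict[str, int] = {}
    row_inputs: dict[int, list[str]] = {}
    for request, outcome in zip(report.requests, report.outcomes):
        if not outcome.ok:
            continue
        ids = [m.id for m in request.resolved_inputs]
        row_inputs[request.row_number] = ids
        for pid in ids:
            usage[pid] = usage.get(pid, 0) + 1

    entries: list[DilutionEntry] = []
    working: dict[str, float] = {}
    for pid in sorted(usage):
        if pid not in by_id:
            raise QuantitationError(f"no stock concentration provided for plasmid {pid!r}")
        stock = by_id[pid]
        v = fmol_to_ng(params.target_amount, stock.length) / stock.concentration
        factor = _predilution_factor(v, params.min_pipettable_volume)
        wv = v * factor
        working[pid] = wv
        entries.append(
            DilutionEntry(
                plasmid_id=pid,
                stock_volume_per_reaction=v,
                dilution_factor=factor,
                working_volume_per_reaction=wv,
                n_reactions=usage[pid],
                total_working_volume=wv * usage[pid] * params.dead_volume_factor,
            )
        )

    water: dict[int, float] = {}
    for row, ids in sorted(row_inputs.items()):
        parts_volume = sum(working[pid] for pid in ids)
        top_up = params.reaction_volume - parts_volume
        if top_up < 0:
            raise QuantitationError(
                f"row {row}: part volumes ({parts_volume:.2f} µL) exceed the "
                f"reaction volume ({params.reaction_volume} µL)"
            )
        water[row] = top_up
    return DilutionPlan(entries=entries, params=params, water_per_reaction=water)


def _well_name(index: int) -> tuple[int, str]:
    """Row-major 96-well position (plate, 'A1'..'H12') for a 0-based index."""
    plate, pos = divmod(index, 96)
    row, col = divmod(pos, 12)
    return plate + 1, f"{chr(ord('A') + row)}{col + 1}"


def export_picklist(
    plan: DilutionPlan,
    report: CampaignReport,
    path: str | Path,
) -> Path:
    """Generic liquid-handler picklist CSV.

    Dilution steps come first (one per pre-diluted stock), then the
    assembly transfers, reactions assigned row-major to A1..H12 with a
    plate column once a campaign exceeds 96 reactions. Volumes are written
    with 2 decimals; re-export is byte-identical.
    """
    path = Path(path)
    rows = []
    for e in plan.entries:
        if e.dilution_factor > 1:
            rows.append(
                {
                    "step": "dilution",
                    "source_id": e.plasmid_id,
                    "plate": 0,
                    "destination_well": f"dil_{e.plasmid_id}",
                    "volume_ul": f"{e.total_working_volume / e.dilution_factor:.2f}",
                    "comment": f"dilute {e.dilution_factor}x",
                }
            )
    reaction_index = 0
    for request, outcome in zip(report.requests, report.outcomes):
        if not outcome.ok:
            continue
        plate, well = _well_name(reaction_index)
        for molecule in request.resolved_inputs:
            entry = plan.entry(molecule.id)
            source = (
                f"dil_{entry.plasmid_id}" if entry.dilution_factor > 1 else entry.plasmid_id
            )
            rows.append(
                {
                    "step": "assembly",
                    "source_id": source,
                    "plate": plate,
                    "destination_well": well,
                    "volume_ul": f"{entry.working_volume_per_reaction:.2f}",
                    "comment": outcome.output_name,
                }
            )
        water = plan.water_per_reaction.get(request.row_number, 0.0)
        if water > 0:
            rows.append(
                {
                    "step": "assembly",
                    "source_id": "water",
                    "plate": plate,
                    "destination_well": well,
                    "volume_ul": f"{water:.2f}",
                    "comment": outcome.output_name,
                }
            )
        reaction_index += 1
    pd.DataFrame(
        rows, columns=["step", "source_id", "plate", "destination_well", "volume_ul", "comment"]
    ).to_csv(path, index=False)
    return path


def write_dilution_plan(plan: DilutionPlan, path: str | Path) -> Path:
    """Dilution plan CSV (one row per plasmid)."""
    path = Path(path)
    plan.to_frame().to_csv(path, index=False)
    return path


def load_stocks(path: str | Path, db=None) -> list[StockInfo]:
    """Read stock concentrations from a CSV (plasmid_id, ng_per_ul[, length_bp]).

    When lengths are omitted they are taken from the database molecules.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    stocks = []
    for _, r in df.iterrows():
        pid = str(r["plasmid_id"]).strip()
        if "length_bp" in df.columns and not pd.isna(r.get("length_bp")):
            length = int(r["length_bp"])
        elif db is not None and pid in db:
            length = len(db[pid])
        else:
            raise QuantitationError(
                f"stock file {path}: no length for {pid!r} and plasmid not in database"
            )
        stocks.append(StockInfo(pid, float(r["ng_per_ul"]), length))
    return stocks
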