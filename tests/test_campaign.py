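import pytest

from moclosim.campaign import (
    IpMappingTable,
    PartReference,
    load_mapping,
    next_counter,
    parse_campaign,
    resolve,
    run_campaign,
    write_db_produced,
    write_provenance,
)
from moclosim.digestion import StickyFragment
from moclosim.errors import CampaignError, ResolutionError
from moclosim.fixtures import make_campaign, make_kit
from moclosim.grammar import NamingConvention
from moclosim.sequence_io import DnaMolecule, load_database, revcomp


@pytest.fixture
def kit_on_disk(tmp_path, kit32):
    paths = kit32.write(tmp_path)
    return kit32, paths


def test_parse_typed_row_with_subparts(tmp_path, kit32):
    kit32.grammar.positions[2].allows_subparts = True
    path = tmp_path / "c.csv"
    path.write_text("myLib1, promoterA, cdsA, promoterB.terminatorA\n")
    try:
        (row,) = parse_campaign(path, kit32.grammar)
    finally:
        kit32.grammar.positions[2].allows_subparts = False
    assert row.output_name == "myLib1"
    assert len(row.part_refs) == 3
    assert row.part_refs[2].subparts == ("promoterB", "terminatorA")


def test_parse_raw_mode_variable_arity(tmp_path):
    path = tmp_path / "c.csv"
    path.write_text("out1,a,b,c,d,e\nout2,a,,b,\n")
    rows = parse_campaign(path)
    assert len(rows[0].part_refs) == 5
    assert [r.name for r in rows[1].part_refs] == ["a", "b"]
    assert all(r.part_type is None for r in rows[0].part_refs)


def test_parse_counts_and_skips_comments_and_header(tmp_path, kit32):
    lines = ["# a comment", "output_name,promoter (1),cds (2),terminator (3)"]
    for i in range(4):
        lines.append(f"o{i},promoterA,cdsA,terminatorA")
    path = tmp_path / "c.csv"
    path.write_text("\n".join(lines) + "\n")
    assert len(parse_campaign(path, kit32.grammar)) == 4


def test_parse_semicolon_dialect(tmp_path):
    path = tmp_path / "c.csv"
    path.write_text("out1;a;b\n")
    (row,) = parse_campaign(path)
    assert [r.name for r in row.part_refs] == ["a", "b"]


def test_typed_column_mismatch_cites_row_and_header(tmp_path, kit32):
    path = tmp_path / "c.csv"
    path.write_text("o1,promoterA,cdsA,terminatorA\no2,promoterA,cdsA,terminatorA,extra\n")
    with pytest.raises(CampaignError, match=r"row 2.*promoter \(1\)"):
        parse_campaign(path, kit32.grammar)


def test_typed_blank_cell_requires_optional(tmp_path, kit32):
    path = tmp_path / "c.csv"
    path.write_text("o1,promoterA,,terminatorA\n")
    with pytest.raises(CampaignError, match="row 1.*cds"):
        parse_campaign(path, kit32.grammar)
    kit32.grammar.positions[1].optional = True
    try:
        (row,) = parse_campaign(path, kit32.grammar)
        assert len(row.part_refs) == 2
    finally:
        kit32.grammar.positions[1].optional = False


def test_mapping_collision_is_load_error(tmp_path):
    a = tmp_path / "a.csv"
    b = tmp_path / "b.csv"
    a.write_text("part_name,part_type,plasmid_id\npTET,2,pMYT015\n")
    b.write_text("part_name,part_type,plasmid_id\npTET,2,pOTHER\n")
    with pytest.raises(CampaignError, match="pTET"):
        load_mapping([a, b])
    # identical duplicate rows are tolerated
    assert len(load_mapping([a, a])) == 1


def test_resolution_by_name_type_and_direct_id(kit32):
    db = kit32.database
    part = kit32.parts[0]
    by_name = resolve([PartReference(part.part_name, part.part_type)], kit32.mapping, db)
    assert by_name[0].id == part.plasmid_id
    direct = resolve([PartReference(part.plasmid_id)], kit32.mapping, db)
    assert direct[0].id == part.plasmid_id


def test_same_name_under_two_types_resolves_by_type():
    mapping = IpMappingTable(
        [("Venus", "3", "pV3"), ("Venus", "4", "pV4")]
    )
    db = {
        "pV3": DnaMolecule("pV3", "ACGT" * 10),
        "pV4": DnaMolecule("pV4", "TGCA" * 10),
    }
    assert resolve([PartReference("Venus", "3")], mapping, db)[0].id == "pV3"
    assert resolve([PartReference("Venus", "4")], mapping, db)[0].id == "pV4"
    with pytest.raises(ResolutionError, match="ambiguous"):
        resolve([PartReference("Venus")], mapping, db)


def test_resolution_errors_name_token_and_missing_file(kit32):
    with pytest.raises(ResolutionError, match="nosuchpart"):
        resolve([PartReference("nosuchpart")], kit32.mapping, kit32.database)
    mapping = IpMappingTable([("ghost", None, "pGONE")])
    with pytest.raises(ResolutionError, match="pGONE"):
        resolve([PartReference("ghost")], mapping, kit32.database)


def test_run_campaign_with_injected_error(tmp_path, kit32, bsai):
    text, manifest = make_campaign(kit32, 6, error_rows=[4], seed=3, path=tmp_path / "c.csv")
    rows = parse_campaign(tmp_path / "c.csv", kit32.grammar)
    report = run_campaign(rows, kit32.mapping, kit32.database, bsai, grammar=kit32.grammar)
    assert report.n_success == 5 and report.n_failed == 1
    failed = next(o for o in report.outcomes if not o.ok)
    assert failed.row_number == 4
    assert manifest["defects"]["4"]["token"] in failed.message
    assert "row 4" in failed.message


def test_run_campaign_determinism(kit32, bsai, tmp_path):
    text, _ = make_campaign(kit32, 5, seed=9, path=tmp_path / "c.csv")
    rows = parse_campaign(tmp_path / "c.csv", kit32.grammar)
    r1 = run_campaign(rows, kit32.mapping, kit32.database, bsai, grammar=kit32.grammar)
    r2 = run_campaign(rows, kit32.mapping, kit32.database, bsai, grammar=kit32.grammar)
    assert r1.to_json() == r2.to_json()


def test_empty_campaign(kit32, bsai):
    report = run_campaign([], kit32.mapping, kit32.database, bsai)
    assert report.outcomes == [] and report.produced == []


def test_generated_ids_continue_past_existing_counters(kit32, bsai, tmp_path):
    naming = NamingConvention(prefix="oP", pad_width=3)
    assert next_counter(["oP007", "oP002", "pFIX001"], naming) == 8
    assert next_counter([], naming) == 1
    text, _ = make_campaign(kit32, 2, seed=5, path=tmp_path / "c.csv")
    rows = parse_campaign(tmp_path / "c.csv", kit32.grammar)
    db = dict(kit32.database)
    db["oP041"] = kit32.entry_plasmids[0]  # pre-existing product id in the database
    report = run_campaign(rows, kit32.mapping, db, bsai, grammar=kit32.grammar)
    assert [o.plasmid_id for o in report.outcomes] == ["oP042", "oP043"]


def test_auto_composed_output_names(kit32, bsai, tmp_path):
    path = tmp_path / "c.csv"
    path.write_text(",promoterA,cdsA,terminatorA\n")
    rows = parse_campaign(path, kit32.grammar)
    report = run_campaign(rows, kit32.mapping, kit32.database, bsai, grammar=kit32.grammar)
    assert report.outcomes[0].output_name == "promoterA-cdsA-terminatorA"


def test_db_produced_round_trip_and_chaining(tmp_path, kit32, bsai):
    text, _ = make_campaign(kit32, 3, seed=11, path=tmp_path / "c.csv")
    rows = parse_campaign(tmp_path / "c.csv", kit32.grammar)
    report = run_campaign(rows, kit32.mapping, kit32.database, bsai, grammar=kit32.grammar)
    out = write_db_produced(report, tmp_path / "db_produced.csv")
    produced_mapping = load_mapping(out)
    assert len(produced_mapping) == report.n_success
    # chained campaign: produced names resolve with no manual editing
    db2 = dict(kit32.database)
    for o in report.outcomes:
        db2[o.plasmid_id] = o.product
    for o in report.outcomes:
        (mol,) = resolve([PartReference(o.output_name)], produced_mapping, db2)
        assert mol.id == o.plasmid_id
    # failed rows never appear in DB_produced
    assert all(row["plasmid_id"] for row in report.produced)


def test_provenance_records(tmp_path, kit32, bsai):
    text, _ = make_campaign(kit32, 2, seed=13, path=tmp_path / "c.csv")
    rows = parse_campaign(tmp_path / "c.csv", kit32.grammar)
    report = run_campaign(
        rows, kit32.mapping, kit32.database, bsai, grammar=kit32.grammar, timestamp="T0"
    )
    path = write_provenance(report, tmp_path / "prov.json")
    import json

    records = json.loads(path.read_text())
    assert len(records) == 2
    assert all(r["enzyme"] == "BsaI" and r["timestamp"] == "T0" for r in records)
    assert all(len(r["inputs"]) == 3 for r in records)


def test_typed_and_raw_modes_give_identical_products(tmp_path, kit32, bsai):
    text, _ = make_campaign(kit32, 4, seed=21, path=tmp_path / "typed.csv")
    typed_rows = parse_campaign(tmp_path / "typed.csv", kit32.grammar)
    raw_lines = []
    for row in typed_rows:
        raw_lines.append(",".join([row.output_name] + [r.name for r in row.part_refs]))
    (tmp_path / "raw.csv").write_text("\n".join(raw_lines) + "\n")
    raw_rows = parse_campaign(tmp_path / "raw.csv")
    typed = run_campaign(typed_rows, kit32.mapping, kit32.database, bsai, grammar=kit32.grammar)
    raw = run_campaign(raw_rows, kit32.mapping, kit32.database, bsai)
    assert typed.n_success == raw.n_success == 4
    for a, b in zip(typed.outcomes, raw.outcomes):
        assert a.product.sequence == b.product.sequence


def test_grammar_fusion_cross_check_warns_on_mismatch(kit32, bsai):
    import copy

    grammar = copy.deepcopy(kit32.grammar)
    grammar.positions[0].expected_left_fusion = "CCCC"  # wrong on purpose
    rows = parse_campaign_text(kit32, "x,promoterA,cdsA,terminatorA\n")
    report = run_campaign(rows, kit32.mapping, kit32.database, bsai, grammar=grammar)
    assert report.outcomes[0].ok
    assert any("CCCC" in d for d in report.outcomes[0].diagnostics)


def parse_campaign_text(kit, text):
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as td:
        p = Path(td) / "c.csv"
        p.write_text(text)
        return parse_campaign(p, kit.grammar)
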