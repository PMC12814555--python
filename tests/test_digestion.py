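import random

import pytest

from oracles import brute_site_scan
from moclosim.digestion import (
    BUILTIN_TYPE_IIS,
    StickyFragment,
    TypeIISEnzyme,
    digest,
    find_sites,
    get_type_iis,
    load_enzyme_config,
    select_insert_fragment,
)
from moclosim.errors import (
    AmbiguousInsertError,
    CutCollisionError,
    NoReleasablePartError,
    NoSitesError,
    SingleCutError,
)
from moclosim.fixtures import make_random_circle
from moclosim.sequence_io import DnaMolecule, reverse_complement, revcomp


def test_enzyme_definition_invariants():
    assert BUILTIN_TYPE_IIS["BsaI"].overhang_length == 4
    assert BUILTIN_TYPE_IIS["SapI"].overhang_length == 3
    with pytest.raises(ValueError, match="palindromic"):
        TypeIISEnzyme("fake", "GAATTC", 1, 5)
    with pytest.raises(ValueError):
        TypeIISEnzyme("fake", "GGTCTC", 5, 5)


def test_enzyme_config_extends_builtins(tmp_path):
    cfg = tmp_path / "enzymes.yaml"
    cfg.write_text("PaqCI:\n  recognition: CACCTGC\n  spacer_top: 4\n  spacer_bottom: 8\n")
    extra = load_enzyme_config(cfg)
    assert get_type_iis("PaqCI", extra).overhang_length == 4
    with pytest.raises(KeyError, match="BsaI"):
        get_type_iis("NoSuchEnzyme")


def test_worked_circle_site_geometry(worked_circle, bsai):
    """The 29-nt example: a + site cutting 7/11 (AATG) and a − site 14/18 (GCTT)."""
    hits = find_sites(worked_circle, bsai)
    assert len(hits) == 2
    plus = next(h for h in hits if h.strand == "+")
    minus = next(h for h in hits if h.strand == "-")
    assert (plus.recognition_start, plus.top_cut, plus.bottom_cut) == (0, 7, 11)
    assert (minus.recognition_start, minus.top_cut, minus.bottom_cut) == (19, 14, 18)
    seq = worked_circle.sequence
    assert seq[plus.top_cut : plus.bottom_cut] == "AATG"
    assert seq[minus.top_cut : minus.bottom_cut] == "GCTT"


def test_no_sites_yields_empty_hit_list(bsai):
    assert find_sites(DnaMolecule("x", "ACGT" * 30), bsai) == []


@pytest.mark.parametrize("seed", range(5))
def test_find_sites_agrees_with_brute_force_scan(bsai, seed):
    rng = random.Random(seed)
    seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(500, 10000)))
    for topology in ("circular", "linear"):
        m = DnaMolecule("r", seq, topology=topology)
        got = sorted((h.strand, h.recognition_start) for h in find_sites(m, bsai))
        expected = brute_site_scan(seq, bsai.recognition, topology == "circular")
        if topology == "linear":  # the engine drops sites whose cuts run off the end
            n = len(seq)
            expected = [
                (s, p)
                for s, p in expected
                if (s == "+" and p + len(bsai.recognition) + bsai.spacer_bottom <= n)
                or (s == "-" and p - bsai.spacer_bottom >= 0)
            ]
        assert got == sorted(expected)


@pytest.mark.parametrize("seed", range(4))
def test_find_sites_strand_symmetry(bsai, seed):
    rng = random.Random(100 + seed)
    m = make_random_circle(bsai, rng.randint(1, 3), rng)
    fwd = find_sites(m, bsai)
    rev = find_sites(reverse_complement(m), bsai)
    assert len(fwd) == len(rev)
    assert sorted(h.strand for h in fwd) == sorted(
        {"+": "-", "-": "+"}[h.strand] for h in rev
    )


def test_worked_circle_digest(worked_circle, bsai):
    frags = digest(worked_circle, bsai)
    assert len(frags) == 2
    insert = select_insert_fragment(frags, bsai)
    assert (insert.left_fusion, insert.payload, insert.right_fusion) == ("AATG", "CCC", "GCTT")
    backbone = next(f for f in frags if f is not insert)
    assert backbone.contains_recognition(bsai)
    # conservation: Σ(payload + overhang) = molecule length
    assert sum(len(f.payload) + bsai.overhang_length for f in frags) == 29


@pytest.mark.parametrize("seed", range(8))
def test_digest_conservation_on_random_circles(bsai, seed):
    rng = random.Random(1000 + seed)
    m = make_random_circle(bsai, rng.randint(1, 4), rng)
    frags = digest(m, bsai)
    assert sum(len(f.payload) + bsai.overhang_length for f in frags) == len(m)


@pytest.mark.parametrize("k", [1, 5, 13, 28])
def test_digest_rotation_invariance(worked_circle, bsai, k):
    seq = worked_circle.sequence
    rotated = DnaMolecule("rot", seq[k:] + seq[:k], topology="circular")
    original = {f.key() for f in digest(worked_circle, bsai)}
    assert {f.key() for f in digest(rotated, bsai)} == original


def test_digest_of_reverse_complement_mirrors_fragments(bsai):
    rng = random.Random(7)
    m = make_random_circle(bsai, 2, rng)
    fwd = sorted(f.key() for f in digest(m, bsai))
    rc = sorted(f.reverse_complement().key() for f in digest(reverse_complement(m), bsai))
    assert fwd == rc


def test_digest_error_outcomes(bsai):
    with pytest.raises(NoSitesError, match="uncut"):
        digest(DnaMolecule("plain", "ACGT" * 30), bsai)
    # a single recognition site on a circle only nicks it
    single = DnaMolecule("nicked", "GGTCTCA" + "ACGT" * 20, topology="circular")
    with pytest.raises(SingleCutError):
        digest(single, bsai)
    # a + cut at 7/11 and a − cut at 9/13: overhang regions overlap
    clash = DnaMolecule("clash", "GGTCTCAAATGCCCGAGACC" + "TTCA" * 10, topology="circular")
    with pytest.raises(CutCollisionError):
        digest(clash, bsai)


def test_coincident_cuts_from_two_sites_collapse(bsai):
    # + site and − site directing the *same* cut: one cut, not a collision
    seq = "GGTCTCA" + "AATG" + "T" + "GAGACC" + "GCAT" * 10 + "CCTA" * 3
    # second cut elsewhere so the circle is properly digested
    seq += "GGTCTCA" + "TTAC" + "T" + "GAGACC" + "ATCC" * 8
    m = DnaMolecule("coincident", seq, topology="circular")
    frags = digest(m, bsai)
    assert sum(len(f.payload) + 4 for f in frags) == len(m)
    assert {f.left_fusion for f in frags} == {"AATG", "TTAC"}


def test_select_insert_errors(bsai):
    never_free = [
        StickyFragment("AATG", "GGTCTC", "GCTT", source_id="pX"),
        StickyFragment("GCTT", "GAGACC", "AATG", source_id="pX"),
    ]
    with pytest.raises(NoReleasablePartError, match="pX"):
        select_insert_fragment(never_free, bsai)
    two_free = [
        StickyFragment("AATG", "CCC", "GCTT", source_id="pY"),
        StickyFragment("GCTT", "AAA", "TACA", source_id="pY"),
        StickyFragment("TACA", "GGTCTCTTTGAGACC", "AATG", source_id="pY"),
    ]
    with pytest.raises(AmbiguousInsertError, match="AATG/GCTT"):
        select_insert_fragment(two_free, bsai)


def test_linear_digest_end_fragments(bsai):
    # one + site on a linear molecule: two pieces, outer ends blunt
    m = DnaMolecule("lin", "TTTTGGTCTCAAATGCCCCCCCC", topology="linear")
    frags = digest(m, bsai)
    assert len(frags) == 2
    assert frags[0].left_fusion == "" and frags[1].right_fusion == ""
    assert frags[1].left_fusion == "AATG"
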