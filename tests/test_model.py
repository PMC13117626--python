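"""Domain types, table parsing, and the dataset error scan."""

from __future__ import annotations

import textwrap

import pytest

from mti import (
    Compatibility,
    CompatibilityMatrix,
    Dataset,
    LociConsistencyTable,
    LociRelation,
    MTIError,
    ParentTable,
    ParseError,
    build_dataset,
    derive_observations,
    generate_population,
    pair_key,
    read_compatibility,
    read_loci_table,
    read_parent_table,
    validate_dataset,
    write_compatibility,
    write_loci_table,
    write_parent_table,
)
from mti.simulation import PopulationConfig

from conftest import make_truth


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text), encoding="utf-8")
    return p


# ---------------------------------------------------------------- pair keys

def test_pair_key_is_order_independent_and_rejects_self_pairs():
    assert pair_key("m2", "m1") == ("m1", "m2") == pair_key("m1", "m2")
    with pytest.raises(MTIError):
        pair_key("m1", "m1")


def test_matrix_lookup_is_symmetric():
    m = CompatibilityMatrix(("a", "b"), {("a", "b"): Compatibility.COMPATIBLE})
    assert m.lookup("a", "b") is m.lookup("b", "a") is Compatibility.COMPATIBLE


# ---------------------------------------------------------------- parent table

def test_parent_table_parses_and_defines_sibling_pairs(tmp_path):
    p = write(tmp_path, "p.csv", """\
        strain_id,dikaryon_id
        m1,D1
        m2,D1
        m3,D2
        """)
    pt = read_parent_table(p)
    assert pt.strains == ("m1", "m2", "m3")
    assert pt.sibling_pairs == {("m1", "m2")}
    assert pt.dikaryons == {"D1": ("m1", "m2"), "D2": ("m3",)}


@pytest.mark.parametrize(
    "body",
    [
        "m1,D1\nm1,D2\n",          # duplicate strain
        "m1,D1\n,D2\n",            # empty strain field
        "m1,\nm2,D1\n",            # empty dikaryon field
        "m1,D1\nm2,D1\nm3,D1\n",   # three monokaryons from one dikaryon
    ],
)
def test_parent_table_rejects_malformed_rows(tmp_path, body):
    p = write(tmp_path, "p.csv", "strain_id,dikaryon_id\n" + body)
    with pytest.raises(ParseError):
        read_parent_table(p)


def test_parent_table_requires_expected_header(tmp_path):
    p = write(tmp_path, "p.csv", "strain,parent\nm1,D1\n")
    with pytest.raises(ParseError):
        read_parent_table(p)


# ---------------------------------------------------------------- matrix

@pytest.fixture
def three_parents(tmp_path):
    return read_parent_table(
        write(tmp_path, "parents.csv", "strain_id,dikaryon_id\nm1,D1\nm2,D1\nm3,D2\n")
    )


def test_long_matrix_parses_to_canonical_pairs(tmp_path, three_parents):
    p = write(tmp_path, "m.csv", """\
        strain_a,strain_b,result
        m2,m1,compatible
        m1,m3,incompatible
        """)
    m = read_compatibility(p, three_parents)
    assert m.lookup("m1", "m2") is Compatibility.COMPATIBLE
    assert m.lookup("m3", "m1") is Compatibility.INCOMPATIBLE
    assert m.missing_pairs() == [("m2", "m3")]


def test_long_matrix_collapses_consistent_and_rejects_conflicting_duplicates(tmp_path, three_parents):
    ok = write(tmp_path, "ok.csv", "strain_a,strain_b,result\nm1,m2,compatible\nm2,m1,compatible\n")
    assert len(read_compatibility(ok, three_parents).observations) == 1
    bad = write(tmp_path, "bad.csv", "strain_a,strain_b,result\nm1,m2,compatible\nm2,m1,incompatible\n")
    with pytest.raises(ParseError):
        read_compatibility(bad, three_parents)


@pytest.mark.parametrize(
    "row",
    ["m1,m1,compatible", "m1,mX,compatible", "m1,m2,maybe"],
)
def test_long_matrix_rejects_bad_rows(tmp_path, three_parents, row):
    p = write(tmp_path, "m.csv", f"strain_a,strain_b,result\n{row}\n")
    with pytest.raises(ParseError):
        read_compatibility(p, three_parents)


def test_wide_matrix_dialect_is_autodetected(tmp_path, three_parents):
    p = write(tmp_path, "m.csv", """\
        ,m1,m2,m3
        m1,-,1,1
        m2,1,-,1
        m3,1,1,-
        """)
    m = read_compatibility(p, three_parents)
    assert all(v is Compatibility.COMPATIBLE for v in m.observations.values())
    assert len(m.observations) == 3
    assert m.missing_pairs() == []


def test_wide_matrix_handles_na_and_rejects_conflicts(tmp_path, three_parents):
    p = write(tmp_path, "m.csv", ",m1,m2,m3\nm1,-,1,NA\nm2,1,-,0\nm3,NA,0,-\n")
    m = read_compatibility(p, three_parents)
    assert m.lookup("m2", "m3") is Compatibility.INCOMPATIBLE
    assert m.missing_pairs() == [("m1", "m3")]
    bad = write(tmp_path, "bad.csv", ",m1,m2\nm1,-,1\nm2,0,-\n")
    with pytest.raises(ParseError):
        read_compatibility(bad, three_parents)


# ---------------------------------------------------------------- loci table

@pytest.mark.parametrize(
    ("token", "a_rel", "b_rel"),
    [
        ("AeqBne", LociRelation.SAME, LociRelation.DIFFERENT),
        ("AneBeq", LociRelation.DIFFERENT, LociRelation.SAME),
        ("AeqBeq", LociRelation.SAME, LociRelation.SAME),
        ("A=B≠", LociRelation.SAME, LociRelation.DIFFERENT),
        ("A≠B=", LociRelation.DIFFERENT, LociRelation.SAME),
    ],
)
def test_loci_tokens_map_to_relations(tmp_path, three_parents, token, a_rel, b_rel):
    mat = write(tmp_path, "m.csv", "strain_a,strain_b,result\nm1,m2,incompatible\n")
    matrix = read_compatibility(mat, three_parents)
    loci = read_loci_table(
        write(tmp_path, "l.csv", f"strain_a,strain_b,owe_soj\nm1,m2,{token}\n"), matrix
    )
    assert loci.records[("m1", "m2")] == (a_rel, b_rel)


def test_loci_record_for_compatible_or_untested_pair_is_an_error(tmp_path, three_parents):
    mat = write(tmp_path, "m.csv", "strain_a,strain_b,result\nm1,m2,compatible\n")
    matrix = read_compatibility(mat, three_parents)
    for pair in ("m1,m2", "m1,m3"):
        bad = write(tmp_path, "l.csv", f"strain_a,strain_b,owe_soj\n{pair},AeqBne\n")
        with pytest.raises(ParseError):
            read_loci_table(bad, matrix)


def test_loci_unknown_token_is_an_error(tmp_path, three_parents):
    mat = write(tmp_path, "m.csv", "strain_a,strain_b,result\nm1,m2,incompatible\n")
    matrix = read_compatibility(mat, three_parents)
    bad = write(tmp_path, "l.csv", "strain_a,strain_b,owe_soj\nm1,m2,AneBne\n")
    with pytest.raises(ParseError):
        read_loci_table(bad, matrix)


# ---------------------------------------------------------------- round trip

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_tables_round_trip_through_files(tmp_path, seed):
    truth = generate_population(PopulationConfig(n_dikaryons=4, a_pool=4, b_pool=4, seed=seed))
    ds = derive_observations(truth)
    write_parent_table(ds.parents, tmp_path / "p.csv")
    write_compatibility(ds.matrix, tmp_path / "m.csv")
    write_loci_table(ds.loci, tmp_path / "l.csv")
    parents = read_parent_table(tmp_path / "p.csv")
    matrix = read_compatibility(tmp_path / "m.csv", parents)
    loci = read_loci_table(tmp_path / "l.csv", matrix)
    assert parents == ds.parents
    assert matrix.observations == ds.matrix.observations
    assert matrix.strains == ds.matrix.strains
    assert loci.records == ds.loci.records


# ---------------------------------------------------------------- validation

def test_sibling_incompatible_is_a_validation_error(four_strain_dataset):
    ds = four_strain_dataset
    obs = dict(ds.matrix.observations)
    obs[("s1", "s3")] = Compatibility.INCOMPATIBLE  # (s1, s3) share dikaryon D1
    bad = Dataset(ds.parents, CompatibilityMatrix(ds.matrix.strains, obs), ds.loci)
    rep = validate_dataset(bad)
    assert any(code == "sibling_incompatible" for code, _, _ in rep.errors)


def test_complete_consistent_dataset_validates_cleanly(four_strain_dataset):
    rep = validate_dataset(four_strain_dataset)
    assert rep.ok
    assert rep.errors == [] and rep.warnings == [] and rep.missing_pairs == []


def test_missing_pairs_are_counted_not_errored():
    pt = ParentTable((("m1", "D1"), ("m2", "D1"), ("m3", "D2")))
    m = CompatibilityMatrix(
        ("m1", "m2", "m3"),
        {("m1", "m2"): Compatibility.COMPATIBLE, ("m1", "m3"): Compatibility.COMPATIBLE},
    )
    rep = validate_dataset(Dataset(pt, m))
    assert rep.ok
    assert rep.missing_pairs == [("m2", "m3")]


def test_validation_flags_both_different_records_and_unknown_strains():
    pt = ParentTable((("m1", "D1"), ("m2", "D1")))
    m = CompatibilityMatrix(
        ("m1", "m2", "m3"), {("m2", "m3"): Compatibility.INCOMPATIBLE}
    )
    loci = LociConsistencyTable(
        {("m2", "m3"): (LociRelation.DIFFERENT, LociRelation.DIFFERENT)}
    )
    rep = validate_dataset(Dataset(pt, m, loci))
    codes = {code for code, _, _ in rep.errors}
    assert "unknown_strain" in codes
    assert "loci_both_different" in codes


def test_incompatible_pair_without_record_is_only_a_warning(four_strain_dataset):
    ds = four_strain_dataset
    stripped = Dataset(ds.parents, ds.matrix, LociConsistencyTable({}))
    rep = validate_dataset(stripped)
    assert rep.ok
    assert [code for code, _, _ in rep.warnings] == ["missing_loci_record"]


def test_build_dataset_autofills_missing_sibling_pairs():
    truth = make_truth(
        {"m1": (1, 1), "m2": (2, 2), "m3": (3, 3), "m4": (4, 4)},
        [("m1", "D1"), ("m2", "D1"), ("m3", "D2"), ("m4", "D2")],
    )
    full = derive_observations(truth)
    obs = {pk: v for pk, v in full.matrix.observations.items()
           if pk not in truth.parents.sibling_pairs}
    ds = build_dataset(full.parents, CompatibilityMatrix(full.matrix.strains, obs))
    assert ds.matrix.lookup("m1", "m2") is Compatibility.COMPATIBLE
    assert ds.matrix.lookup("m3", "m4") is Compatibility.COMPATIBLE
    assert validate_dataset(ds).missing_pairs == []
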