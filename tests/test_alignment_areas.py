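"""Sequence/alignment IO, Area mapping, column filtering, query addition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppap.alignment_areas import (
    Alignment,
    AreaMap,
    AreaSegment,
    ColumnIndexSet,
    MissingExternalToolError,
    ProteinSequence,
    ReactionTypeLabel,
    add_query_to_alignment,
    aligned_query_row,
    cluster_representatives,
    extract_area_segments,
    filter_columns,
    map_reference_positions,
    read_sequences,
)


# ---------------------------------------------------------------------------
# Reading and normalization
# ---------------------------------------------------------------------------

def test_read_fasta_two_records(tmp_path):
    p = tmp_path / "in.fa"
    p.write_text(">a desc one\nMKV\n>b\nacd\n")
    seqs = read_sequences(p)
    assert [s.id for s in seqs] == ["a", "b"]
    assert seqs[1].residues == "ACD"  # lowercase is uppercased


def test_read_maps_ambiguous_codes_to_x(tmp_path, caplog):
    p = tmp_path / "in.fa"
    p.write_text(">a\nMBZU\n")
    with caplog.at_level("WARNING"):
        (seq,) = read_sequences(p)
    assert seq.residues == "MXXX"
    assert "mapped to 'X'" in caplog.text


def test_read_empty_file_errors(tmp_path):
    p = tmp_path / "empty.fa"
    p.write_text("")
    with pytest.raises(ValueError, match="no FASTA records"):
        read_sequences(p)


def test_ragged_aligned_fasta_names_offender(tmp_path):
    p = tmp_path / "aln.fa"
    p.write_text(">ok\nAC-D\n>bad\nACD\n")
    with pytest.raises(ValueError, match="bad"):
        read_sequences(p, format="aligned-fasta")


def test_protein_sequence_rejects_invalid_symbols():
    with pytest.raises(ValueError):
        ProteinSequence("q", "AC1D")
    with pytest.raises(ValueError):
        ProteinSequence("q", "")


# ---------------------------------------------------------------------------
# Reaction-type labels
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text", ["R-4-C", "R-4-A", "R-2-X", "R-2d-X",
                                  "Rn-4-Cn", "Sb-4-C", "Lh-4-L", "S-6-AL",
                                  "R-3m-L", "L-5-A"])
def test_label_grammar_accepts_observed_labels(text):
    assert str(ReactionTypeLabel.parse(text)) == text


@pytest.mark.parametrize("text", ["R-4", "Q-4-C", "R-x-C", "R-4-Z", "R4C"])
def test_label_grammar_rejects_malformed(text):
    with pytest.raises(ValueError):
        ReactionTypeLabel.parse(text, allow_wildcard=True)


def test_label_wildcards_only_in_grouping_contexts():
    with pytest.raises(ValueError):
        ReactionTypeLabel.parse("S-*-*")
    grp = ReactionTypeLabel.parse("S-*-*", allow_wildcard=True)
    assert grp.matches("S-3-L")
    assert not grp.matches("R-4-C")


# ---------------------------------------------------------------------------
# Area mapping
# ---------------------------------------------------------------------------

def test_map_reference_skips_reference_gap_columns():
    aln = Alignment(ids=("ref", "x"), rows=("A-CD", "AACD"))
    amap = AreaMap("ref", (AreaSegment("Area1", 1, 2),))
    cols = map_reference_positions(aln, amap)
    assert cols.columns["Area1"] == (0, 2)


def test_map_reference_gapless_is_identity_minus_one():
    aln = Alignment(ids=("ref",), rows=("ACDEF",))
    amap = AreaMap("ref", (AreaSegment("A", 3, 5),))
    cols = map_reference_positions(aln, amap)
    assert cols.columns["A"] == (2, 3, 4)


def test_map_reference_errors():
    aln = Alignment(ids=("ref",), rows=("AC-D",))
    with pytest.raises(KeyError):
        map_reference_positions(aln, AreaMap("nope", (AreaSegment("A", 1, 1),)))
    with pytest.raises(ValueError, match="only 3 residues"):
        map_reference_positions(aln, AreaMap("ref", (AreaSegment("A", 2, 9),)))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_map_reference_matches_bruteforce_scan(seed):
    """Column mapping equals a walk along the reference counting residues."""
    rng = np.random.default_rng(seed)
    n_cols = int(rng.integers(5, 25))
    rows = []
    for _ in range(6):
        rows.append("".join(
            "-" if rng.random() < 0.25 else str(rng.choice(list("ACDEF")))
            for _ in range(n_cols)
        ))
    ref = rows[0]
    n_res = sum(ch != "-" for ch in ref)
    if n_res < 2:
        return
    start = int(rng.integers(1, n_res))
    end = int(rng.integers(start, n_res))
    aln = Alignment(ids=tuple(f"s{i}" for i in range(6)), rows=tuple(rows))
    cols = map_reference_positions(
        aln, AreaMap("s0", (AreaSegment("A", start, end),))
    ).columns["A"]
    # brute force: enumerate (residue index, column) pairs of the reference
    expected = [c for r, c in enumerate(
        [c for c, ch in enumerate(ref) if ch != "-"], start=1
    ) if start <= r <= end]
    assert list(cols) == expected


# ---------------------------------------------------------------------------
# Area extraction
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_columns():
    aln = Alignment(
        ids=("a", "b"),
        rows=("ACDEFGHIKL", "LKIHGFEDCA"),
    )
    cols = ColumnIndexSet({"Area1": (0, 1), "Area2": (3, 4), "Area4": (9,)})
    return aln, cols


def test_extract_single_area_preserves_rows(toy_columns):
    aln, cols = toy_columns
    out = extract_area_segments(aln, cols, ["Area2"])
    assert out.rows == ("EF", "HG")
    assert out.ids == aln.ids


def test_extract_concatenates_in_area_order(toy_columns):
    aln, cols = toy_columns
    out = extract_area_segments(aln, cols, ["Area1", "Area4"])
    assert out.rows == ("ACL", "LKA")


def test_extract_is_compositional(toy_columns):
    aln, cols = toy_columns
    names = ["Area1", "Area2", "Area4"]
    combined = extract_area_segments(aln, cols, names)
    parts = [extract_area_segments(aln, cols, [n]) for n in names]
    glued = tuple("".join(p.rows[i] for p in parts) for i in range(aln.n_rows))
    assert combined.rows == glued


def test_extract_unknown_area_errors(toy_columns):
    aln, cols = toy_columns
    with pytest.raises(ValueError, match="unknown area"):
        extract_area_segments(aln, cols, ["Area9"])


def test_map_then_extract_reproduces_reference_segment():
    ref = "AC-DE-FG"
    aln = Alignment(ids=("ref", "o"), rows=(ref, "ACCDEEFG"))
    amap = AreaMap("ref", (AreaSegment("A", 2, 4),))
    cols = map_reference_positions(aln, amap)
    out = extract_area_segments(aln, cols, ["A"])
    assert out.row("ref") == "CDE"  # residues 2..4 of the ungapped reference


# ---------------------------------------------------------------------------
# Column filtering
# ---------------------------------------------------------------------------

def test_filter_gap_free_alignment_is_identity():
    aln = Alignment(ids=("a", "b"), rows=("ACDEF", "ACDEF"))
    f = filter_columns(aln)
    assert f.kept_columns == (0, 1, 2, 3, 4)
    assert f.alignment.rows == aln.rows


def test_filter_removes_internal_column_above_80_percent_gaps():
    # middle column is 100% gaps (> 0.8); terminal columns are gap-free
    rows = tuple("A-C" for _ in range(5))
    aln = Alignment(ids=tuple(f"s{i}" for i in range(5)), rows=rows)
    f = filter_columns(aln, max_gap_fraction=0.8)
    assert f.kept_columns == (0, 2)


def test_filter_keeps_internal_column_at_or_below_threshold():
    rows = ("A-C", "AAC", "AAC", "AAC", "AAC")  # middle col 20% gaps
    aln = Alignment(ids=tuple(f"s{i}" for i in range(5)), rows=rows)
    f = filter_columns(aln, max_gap_fraction=0.8)
    assert f.kept_columns == (0, 1, 2)


def test_filter_trims_terminal_gapped_columns():
    rows = ("-ACD-", "AACDA", "AACDA", "AACDA")
    aln = Alignment(ids=tuple(f"s{i}" for i in range(4)), rows=rows)
    f = filter_columns(aln)
    assert f.kept_columns == (1, 2, 3)


def test_filter_matches_bruteforce_and_is_idempotent():
    rng = np.random.default_rng(5)
    rows = []
    for _ in range(8):
        rows.append("".join(
            "-" if rng.random() < 0.3 else str(rng.choice(list("ACDEFGHIKL")))
            for _ in range(40)
        ))
    aln = Alignment(ids=tuple(f"s{i}" for i in range(8)), rows=tuple(rows))
    f = filter_columns(aln, max_gap_fraction=0.8)
    # brute force: trim any-gap terminal columns, then per-column gap filter
    fracs = [sum(r[j] == "-" for r in rows) / 8 for j in range(40)]
    lo = next(j for j in range(40) if fracs[j] == 0)
    hi = next(j for j in reversed(range(40)) if fracs[j] == 0)
    expected = [j for j in range(lo, hi + 1) if fracs[j] <= 0.8]
    assert list(f.kept_columns) == expected
    # idempotent
    f2 = filter_columns(f.alignment, max_gap_fraction=0.8)
    assert f2.alignment.rows == f.alignment.rows
    assert f2.kept_columns == tuple(range(f.n_cols))


def test_filter_all_columns_removed_errors():
    aln = Alignment(ids=("a", "b"), rows=("---", "---"))
    with pytest.raises(ValueError, match="all columns removed"):
        filter_columns(aln)


def test_filter_invalid_threshold():
    aln = Alignment(ids=("a",), rows=("ACD",))
    with pytest.raises(ValueError):
        filter_columns(aln, max_gap_fraction=0.0)


# ---------------------------------------------------------------------------
# Query addition
# ---------------------------------------------------------------------------

@pytest.fixture
def family_alignment():
    rows = (
        "MKVLITAGSEYA",
        "MKVLITAGSEYA",
        "MKVLMTAGSDYA",
        "MKVLITAGTEYA",
    )
    return Alignment(ids=("a", "b", "c", "d"), rows=rows)


@pytest.mark.parametrize("method", ["builtin", "mafft"])
def test_add_identical_query_reproduces_row(family_alignment, method):
    q = ProteinSequence("q", family_alignment.rows[0])
    merged = add_query_to_alignment(q, family_alignment, method=method)
    assert merged.n_rows == 5
    row = aligned_query_row(q, family_alignment, method=method)
    assert row == family_alignment.rows[0]


@pytest.mark.parametrize("method", ["builtin", "mafft"])
def test_add_query_with_internal_deletion(family_alignment, method):
    full = family_alignment.rows[0]
    q = ProteinSequence("q", full[:5] + full[7:])  # drop two residues
    row = aligned_query_row(q, family_alignment, method=method)
    assert len(row) == family_alignment.n_cols
    assert row.count("-") == 2


def test_add_query_preserves_original_correspondences(family_alignment):
    # a query longer than the alignment forces insertion columns
    q = ProteinSequence("q", "MKVLITAWWWGSEYA")
    merged = add_query_to_alignment(q, family_alignment, method="builtin")
    degapped = [r.replace("-", "") for r in merged.rows[:-1]]
    assert degapped == [r.replace("-", "") for r in family_alignment.rows]
    # inserted columns are all-gap across the original rows
    n_inserted = merged.n_cols - family_alignment.n_cols
    assert n_inserted == 3


def test_aligned_query_row_roundtrips_training_row(small_benchmark):
    dataset = small_benchmark.dataset
    aln = dataset.type_alignment("R-4-A")
    sid = dataset.type_ids("R-4-A")[1]
    q = dataset.sequence(sid)
    row = aligned_query_row(q, aln.drop(sid), method="builtin")
    assert row == dataset.master.row(sid)


def test_unknown_method_errors(family_alignment):
    with pytest.raises(ValueError, match="unknown alignment method"):
        add_query_to_alignment(ProteinSequence("q", "MKV"), family_alignment,
                               method="nope")


def test_cluster_wrapper_reports_missing_tool():
    with pytest.raises(MissingExternalToolError, match="cd-hit"):
        cluster_representatives([ProteinSequence("a", "MKV")],
                                binary="cd-hit-definitely-absent")
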