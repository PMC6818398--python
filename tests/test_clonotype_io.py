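"""Clonotype table parsing, validation, aggregation and metadata I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from repseq_compare.clonotype_io import (
    AggregationError,
    ClonotypeFormatError,
    EmptyRepertoireError,
    MetadataError,
    Repertoire,
    aggregate,
    metadata_records,
    read_clonotype_table,
    read_metadata,
    write_repertoire,
)

VALID_ROWS = [
    # nt (in frame, 12 nt), aa (4 aa), V, J, count
    ("TGTGCCAGCTTT", "CASF", "TRBV9", "TRBJ2-1", 5),
    ("TGTGCCTCCTTC", "CASF", "TRBV6-5", "TRBJ2-7", 3),
    ("TGTTTTAGCTTT", "CFSF", "TRBV18", "TRBJ1-1", 2),
]


def write_table(path, rows, header=("cdr3_nt", "cdr3_aa", "v_segment", "j_segment", "count")):
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def test_reads_valid_table_with_totals(tmp_path):
    path = write_table(tmp_path / "s.tsv", VALID_ROWS)
    rep = read_clonotype_table(path)
    assert rep.n_unique == 3
    assert rep.total_reads == 10
    assert rep.rejections == {"accepted": 3}


def test_stop_codon_row_rejected_with_tally(tmp_path):
    rows = VALID_ROWS + [("TGTGCCAGCTAAGAGGCCTTTTTC", "CAS*EAFF", "TRBV9", "TRBJ2-1", 4)]
    rep = read_clonotype_table(write_table(tmp_path / "s.tsv", rows))
    assert rep.rejections["unproductive"] == 1
    assert rep.n_unique == 3


def test_duplicate_keys_merged_by_summing(tmp_path):
    rows = [
        ("TGTGCCAGCTTT", "CASF", "TRBV9", "TRBJ2-1", 2),
        ("TGTGCCAGCTTT", "CASF", "TRBV9", "TRBJ2-1", 3),
    ]
    rep = read_clonotype_table(write_table(tmp_path / "s.tsv", rows))
    assert rep.n_unique == 1
    assert rep.total_reads == 5


@pytest.mark.parametrize(
    "dialect,header",
    [
        ("vdjtools", ("cdr3nt", "cdr3aa", "v", "j", "count")),
        ("airr", ("junction", "junction_aa", "v_call", "j_call", "duplicate_count")),
    ],
)
def test_alternate_dialects_and_allele_stripping(tmp_path, dialect, header):
    rows = [("TGTGCCAGCTTT", "CASF", "TRBV11-2*01", "TRBJ2-1*01", 7)]
    rep = read_clonotype_table(write_table(tmp_path / "s.tsv", rows, header), dialect=dialect)
    assert rep.table.loc[0, "v_segment"] == "TRBV11-2"
    assert rep.table.loc[0, "j_segment"] == "TRBJ2-1"
    assert rep.total_reads == 7


def test_missing_column_names_the_column(tmp_path):
    path = write_table(tmp_path / "s.tsv", [r[:4] for r in VALID_ROWS],
                       header=("cdr3_nt", "cdr3_aa", "v_segment", "j_segment"))
    with pytest.raises(ClonotypeFormatError, match="count"):
        read_clonotype_table(path)


def test_all_rows_invalid_raises_empty(tmp_path):
    rows = [("TGTNNNAGC", "C*S", "TRBV9", "TRBJ2-1", 0)]
    with pytest.raises(EmptyRepertoireError):
        read_clonotype_table(write_table(tmp_path / "s.tsv", rows))


def test_rejection_tally_partitions_input_rows(tmp_path):
    rows = VALID_ROWS + [
        ("TGTGCCAGC", "CAS*", "TRBV9", "TRBJ2-1", 1),      # stop codon
        ("TGTGCXAGCTTT", "CASF", "TRBV9", "TRBJ2-1", 1),   # bad nucleotide
        ("TGTGCCAGCTTT", "CASF", "TRBV9", "TRBJ2-1", 0),   # bad count
        ("TGTGCCAGCTTTAAA", "CASF", "TRBV9", "TRBJ2-1", 2),  # nt/aa length mismatch
    ]
    rep = read_clonotype_table(write_table(tmp_path / "s.tsv", rows))
    assert sum(rep.rejections.values()) == len(rows)
    assert rep.rejections["accepted"] == 3


def test_aggregate_nt_to_aa_merges_synonymous(rep_factory):
    table = pd.DataFrame(
        {
            "cdr3_nt": ["TGTGCCAGCTTT", "TGCGCCAGCTTT"],
            "cdr3_aa": ["CASF", "CASF"],
            "v_segment": ["TRBV9", "TRBV9"],
            "j_segment": ["TRBJ2-1", "TRBJ2-1"],
            "count": [4, 6],
        }
    )
    rep = Repertoire("s", "p", "tumor", table, key_level="nt+VJ")
    agg = aggregate(rep, "aa")
    assert agg.n_unique == 1
    assert agg.total_reads == 10
    assert agg.key_level == "aa"


def test_aggregate_identity_and_refinement_error(rep_factory):
    rep = rep_factory([5, 3, 2])
    assert aggregate(rep, "nt+VJ") is rep
    aa = aggregate(aggregate(rep, "nt"), "aa")
    with pytest.raises(AggregationError):
        aggregate(aa, "nt")


def test_singleton_survives_every_level(tmp_path):
    rep = read_clonotype_table(write_table(tmp_path / "s.tsv", VALID_ROWS[:1]))
    for level in ("nt", "aa"):
        assert aggregate(rep, level).n_unique == 1


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    counts=st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=30),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_aggregation_preserves_totals_and_shrinks_uniques(counts, seed):
    """Group-and-sum to any coarser key keeps reads, never grows uniques."""
    rng = np.random.default_rng(seed)
    n = len(counts)
    nts = [f"NT{rng.integers(0, max(2, n)):04d}_{i % 3}" for i in range(n)]
    table = pd.DataFrame(
        {
            "cdr3_nt": nts,
            "cdr3_aa": [f"AA{s[2:6]}" for s in nts],
            "v_segment": rng.choice(["TRBV9", "TRBV18"], size=n),
            "j_segment": rng.choice(["TRBJ1-1", "TRBJ2-1"], size=n),
            "count": counts,
        }
    )
    table = table.groupby(["cdr3_nt", "v_segment", "j_segment"], as_index=False).agg(
        {"cdr3_aa": "first", "count": "sum"}
    )
    rep = Repertoire("s", "p", "tumor", table, key_level="nt+VJ")
    previous = rep
    for level in ("nt", "aa"):
        agg = aggregate(rep, level)
        assert agg.total_reads == rep.total_reads
        assert agg.n_unique <= previous.n_unique
        # idempotent
        assert aggregate(agg, level).table.equals(agg.table)
        previous = agg


def test_write_read_round_trip(tmp_path):
    rep = read_clonotype_table(write_table(tmp_path / "s.tsv", VALID_ROWS))
    out = tmp_path / "round.tsv"
    write_repertoire(rep, out)
    back = read_clonotype_table(out, sample_id=rep.sample_id)
    left = rep.table.sort_values("cdr3_nt").reset_index(drop=True)
    right = back.table.sort_values("cdr3_nt").reset_index(drop=True)
    pd.testing.assert_frame_equal(left[right.columns], right)


def test_clinical_metadata_parses_printed_table(clinical_table):
    meta = read_metadata(clinical_table)
    assert len(meta) == 15
    assert int((meta["age"] <= 60).sum()) == 6
    assert meta.loc[meta["patient_id"] == "P6", "differentiation"].item() == "unknown"
    assert set(meta["tnm_stage"]) == {"I", "II", "III"}
    records = metadata_records(meta)
    assert len(records) == 15 and records[5].differentiation == "unknown"


@pytest.mark.parametrize(
    "mutate,match",
    [
        (lambda s: s.replace("62", "sixty-two"), "age"),
        (lambda s: s.replace("T3N2M0 (III)", "stage9"), "stage"),
        (lambda s: s.splitlines()[0] + "\n", "no rows"),
    ],
)
def test_metadata_validation_errors(clinical_table, tmp_path, mutate, match):
    bad = tmp_path / "bad.tsv"
    bad.write_text(mutate(clinical_table.read_text()))
    with pytest.raises(MetadataError, match=match):
        read_metadata(bad)
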