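"""FASTA/label I/O, canonicalization and stratified splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psgkmer import (
    Dataset,
    SequenceRecord,
    ValidationError,
    canonicalize,
    read_fasta,
    stratified_holdout,
    write_fasta,
    write_labels_tsv,
)
from psgkmer.sequences import read_labels_tsv


@pytest.mark.parametrize(
    "raw,canonical",
    [("acgt", "ACGU"), ("ACGU", "ACGU"), ("AcGuT", "ACGUU"), ("ttt", "UUU")],
)
def test_canonicalize(raw, canonical):
    assert canonicalize(raw) == canonical


@pytest.mark.parametrize("raw", ["ACGN", "AC GU", "", "ACG-"])
def test_canonicalize_rejects_invalid(raw):
    with pytest.raises(ValidationError):
        canonicalize(raw)


def test_dataset_rejects_mixed_lengths_and_duplicate_ids():
    with pytest.raises(ValidationError):
        Dataset([SequenceRecord("a", "ACGU"), SequenceRecord("b", "ACG")])
    with pytest.raises(ValidationError):
        Dataset([SequenceRecord("a", "ACGU"), SequenceRecord("a", "ACGU")])


def test_read_fasta_single_record(tmp_path):
    path = tmp_path / "one.fasta"
    path.write_text(">s1\nACGGCGGUG\n")
    ds = read_fasta(path)
    assert len(ds) == 1
    assert ds[0].residues == "ACGGCGGUG"
    assert ds.L == 9


def test_read_fasta_empty_file(tmp_path, caplog):
    path = tmp_path / "empty.fasta"
    path.write_text("")
    with caplog.at_level("WARNING"):
        ds = read_fasta(path)
    assert len(ds) == 0
    assert "no records" in caplog.text


def test_read_fasta_maps_thymine_to_uracil(tmp_path):
    path = tmp_path / "dna.fasta"
    path.write_text(">s1\nACGT\n")
    assert read_fasta(path, central_c="ignore")[0].residues == "ACGU"


def test_read_fasta_duplicate_id_rejected(tmp_path):
    path = tmp_path / "dup.fasta"
    path.write_text(">s1\nACGU\n>s1\nACGU\n")
    with pytest.raises(ValidationError, match="s1"):
        read_fasta(path)


def test_read_fasta_strict_rejects_bad_residue_with_position(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">s1\nACGNU\n")
    with pytest.raises(ValidationError, match="position 4"):
        read_fasta(path)


def test_read_fasta_lenient_drops_bad_records(tmp_path, caplog):
    path = tmp_path / "mixed.fasta"
    path.write_text(">ok\nACGCU\n>bad\nACGNU\n>short\nACG\n")
    with caplog.at_level("WARNING"):
        ds = read_fasta(path, strict=False, central_c="ignore")
    assert ds.ids == ["ok"]


def test_read_fasta_wrong_length_strict(tmp_path):
    path = tmp_path / "len.fasta"
    path.write_text(">a\nACGCA\n>b\nACG\n")
    with pytest.raises(ValidationError, match="length 3"):
        read_fasta(path, central_c="ignore")


def test_central_c_policy(tmp_path, caplog):
    path = tmp_path / "central.fasta"
    path.write_text(">a\nAAGAA\n")  # central position 3 is G
    with caplog.at_level("WARNING"):
        read_fasta(path)
    assert "central" in caplog.text
    with pytest.raises(ValidationError, match="central"):
        read_fasta(path, central_c="error")


def test_labels_from_header_and_tsv(tmp_path):
    fasta = tmp_path / "l.fasta"
    fasta.write_text(">a|label=1\nAACAA\n>b\nAACAA\n")
    tsv = tmp_path / "labels.tsv"
    tsv.write_text("b\t0\n")
    ds = read_fasta(fasta, tsv)
    assert [r.label for r in ds] == [1, 0]


def test_label_conflict_is_an_error(tmp_path):
    fasta = tmp_path / "c.fasta"
    fasta.write_text(">a|label=1\nAACAA\n")
    with pytest.raises(ValidationError, match="conflicts"):
        read_fasta(fasta, {"a": 0})


def test_require_labels(tmp_path):
    fasta = tmp_path / "r.fasta"
    fasta.write_text(">a\nAACAA\n")
    with pytest.raises(ValidationError, match="no label"):
        read_fasta(fasta, {"other": 1}, require_labels=True)


def test_malformed_label_tsv(tmp_path):
    tsv = tmp_path / "bad.tsv"
    tsv.write_text("a\t2\n")
    with pytest.raises(ValidationError, match="0/1"):
        read_labels_tsv(tsv)


def test_fasta_round_trip_is_byte_identical(tmp_path, balanced_toy):
    p1 = tmp_path / "a.fasta"
    p2 = tmp_path / "b.fasta"
    write_fasta(balanced_toy, p1, label_in_header=True)
    ds = read_fasta(p1, central_c="ignore")
    assert [r.label for r in ds] == [r.label for r in balanced_toy]
    write_fasta(ds, p2, label_in_header=True)
    assert p1.read_bytes() == p2.read_bytes()


def test_label_tsv_round_trip(tmp_path, balanced_toy):
    tsv = tmp_path / "labels.tsv"
    write_labels_tsv(balanced_toy, tsv)
    assert read_labels_tsv(tsv) == {
        r.id: r.label for r in balanced_toy
    }


def _balanced(n_pos, n_neg):
    return Dataset(
        [SequenceRecord(f"p{i}", "AACAA", 1) for i in range(n_pos)]
        + [SequenceRecord(f"n{i}", "AACAA", 0) for i in range(n_neg)]
    )


def test_holdout_benchmark_sizes():
    """1324 balanced records at 10% give a 1192/132 split, 66 per class."""
    ds = _balanced(662, 662)
    train, test = stratified_holdout(ds, 0.10, seed=1)
    assert (len(train), len(test)) == (1192, 132)
    assert test.label_counts() == (66, 66)
    assert train.label_counts() == (596, 596)


def test_holdout_small_stratification():
    train, test = stratified_holdout(_balanced(5, 5), 0.2, seed=0)
    assert test.label_counts() == (1, 1)


def test_holdout_deterministic():
    ds = _balanced(20, 20)
    a = stratified_holdout(ds, 0.25, seed=9)
    b = stratified_holdout(ds, 0.25, seed=9)
    assert a[0].ids == b[0].ids and a[1].ids == b[1].ids
    c = stratified_holdout(ds, 0.25, seed=10)
    assert a[1].ids != c[1].ids


@pytest.mark.parametrize("n_pos,n_neg,fraction", [
    (10, 10, 0.1), (15, 5, 0.2), (7, 13, 0.3), (50, 30, 0.11), (9, 9, 0.5),
])
def test_holdout_partition_properties(n_pos, n_neg, fraction):
    """Partitions are disjoint, exhaustive and stratified to one sample."""
    ds = _balanced(n_pos, n_neg)
    train, test = stratified_holdout(ds, fraction, seed=4)
    n = n_pos + n_neg
    assert len(test) == round(fraction * n)
    assert set(train.ids) | set(test.ids) == set(ds.ids)
    assert set(train.ids) & set(test.ids) == set()
    tp, tn = test.label_counts()
    assert abs(tp - fraction * n_pos) <= 1
    assert abs(tn - fraction * n_neg) <= 1


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    n_pos=st.integers(2, 40),
    n_neg=st.integers(2, 40),
    fraction=st.floats(0.05, 0.5),
    seed=st.integers(0, 2**16),
)
def test_holdout_property_sweep(n_pos, n_neg, fraction, seed):
    """Disjointness, exhaustiveness and stratification hold for arbitrary
    class sizes and fractions."""
    ds = _balanced(n_pos, n_neg)
    train, test = stratified_holdout(ds, fraction, seed)
    n = n_pos + n_neg
    assert len(test) == round(fraction * n)
    assert set(train.ids) | set(test.ids) == set(ds.ids)
    assert not set(train.ids) & set(test.ids)
    tp, tn = test.label_counts()
    assert abs(tp - fraction * n_pos) <= 1
    assert abs(tn - fraction * n_neg) <= 1


def test_holdout_errors():
    with pytest.raises(ValidationError):
        stratified_holdout(_balanced(5, 0), 0.2, seed=0)
    with pytest.raises(ValueError):
        stratified_holdout(_balanced(5, 5), 1.2, seed=0)
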