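"""Data types, file round-trips, labelling rules and split construction."""

import numpy as np
import pytest

from mircotrain import (
    HairpinCandidate,
    ReadStack,
    SequenceRecord,
    SplitSpec,
    ViewDataset,
    build_labelled_sets,
    gen_two_view,
    read_fasta,
    read_stacks_table,
    read_structures,
    read_view_dataset,
    split_and_seed,
    write_fasta,
    write_stacks_table,
    write_structures,
    write_view_dataset,
)
from mircotrain.datatypes import NEGATIVE, POSITIVE, UNLABELLED
from mircotrain.simulate import TwoViewSimConfig


def _candidate(cid, residues, structure=None):
    return HairpinCandidate(
        record=SequenceRecord(id=cid, residues=residues),
        structure=structure or "." * len(residues),
    )


class TestSequenceRecord:
    def test_t_normalized_to_u_and_uppercased(self):
        assert SequenceRecord("x", "acgt").residues == "ACGU"

    @pytest.mark.parametrize("bad", ["", "ACX", "AC GU"])
    def test_invalid_residues_rejected(self, bad):
        with pytest.raises(ValueError):
            SequenceRecord("x", bad)

    def test_invalid_residue_error_names_position(self):
        with pytest.raises(ValueError, match="'X' at position 3"):
            SequenceRecord("a", "ACX")


class TestFasta:
    def test_roundtrip(self, tmp_path):
        records = [SequenceRecord("a", "AC"), SequenceRecord("b", "GU")]
        path = tmp_path / "r.fasta"
        write_fasta(records, path)
        back = read_fasta(path)
        assert back == records

    def test_t_to_u_on_read(self, tmp_path):
        path = tmp_path / "t.fasta"
        path.write_text(">x\nACGT\n")
        (rec,) = read_fasta(path)
        assert rec.residues == "ACGU"

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "d.fasta"
        path.write_text(">a\nAC\n>a\nGU\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(path)


class TestStacksTable:
    def test_roundtrip_and_grouping(self, tmp_path):
        stacks = {"h1": [ReadStack(0, 22, 90), ReadStack(3, 25, 10)],
                  "h2": [ReadStack(5, 20, 7)]}
        path = tmp_path / "stacks.tsv"
        write_stacks_table(stacks, 1_000_000, path)
        back, library = read_stacks_table(path)
        assert back == stacks and library == 1_000_000

    def test_empty_body_gives_empty_mapping(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("#library_size=10\ncandidate_id\tstart\tend\tcount\n")
        back, library = read_stacks_table(path)
        assert back == {} and library == 10

    @pytest.mark.parametrize("row", ["h1\t22\t10\t5", "h1\t0\t22\t-1"])
    def test_invalid_rows_name_the_line(self, tmp_path, row):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#library_size=10\ncandidate_id\tstart\tend\tcount\n" + row + "\n"
        )
        with pytest.raises(ValueError, match=":3"):
            read_stacks_table(path)


def test_structures_roundtrip(tmp_path):
    structs = {"a": "(((...)))", "b": "....."}
    path = tmp_path / "s.txt"
    write_structures(structs, path)
    assert read_structures(path) == structs


def test_view_dataset_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    ds = ViewDataset(
        instance_ids=[f"i{k}" for k in range(5)],
        feature_names=["f1", "f2"],
        values=rng.normal(size=(5, 2)),
        labels=np.array([1, 0, 1, 0, -1]),
    )
    path = tmp_path / "v.tsv"
    write_view_dataset(ds, path)
    back = read_view_dataset(path)
    assert back.instance_ids == ds.instance_ids
    assert back.feature_names == ds.feature_names
    np.testing.assert_array_equal(back.labels, ds.labels)
    np.testing.assert_allclose(back.values, ds.values, rtol=0, atol=0)


class TestBuildLabelledSets:
    @pytest.fixture
    def known(self):
        return [SequenceRecord("mir1", "ACGUACGUACGU")]

    def test_mirna_match_is_positive(self, known):
        cand = _candidate("c1", "ACGUACGUACGU")
        pos, neg = build_labelled_sets([cand], known, {})
        assert pos == [cand] and neg == []

    def test_substring_match_either_direction(self, known):
        inside = _candidate("c1", "ACGUACGU")  # contained in the known miRNA
        around = _candidate("c2", "GGACGUACGUACGUGG")  # contains it
        pos, _ = build_labelled_sets([inside, around], known, {})
        assert [c.id for c in pos] == ["c1", "c2"]

    @pytest.mark.parametrize("mismatches,expected", [(2, True), (3, False)])
    def test_coding_hit_boundary(self, known, mismatches, expected):
        cand = _candidate("c1", "GGGGCCCCGGGG")
        pos, neg = build_labelled_sets([cand], known, {"c1": mismatches})
        assert pos == []
        assert (cand in neg) is expected

    def test_ncrna_appended_to_negatives(self, known):
        ncrna = [SequenceRecord("trna1", "GGGCCC")]
        _, neg = build_labelled_sets([], known, {}, ncrna)
        assert neg == ncrna

    def test_id_collision_with_ncrna_rejected(self, known):
        cand = _candidate("x", "GGGGCCCC")
        with pytest.raises(ValueError, match="collision"):
            build_labelled_sets([cand], known, {}, [SequenceRecord("x", "AAA")])

    def test_positive_never_also_negative(self, known):
        # a miRNA match with a perfect coding hit stays positive only
        cand = _candidate("c1", "ACGUACGUACGU")
        pos, neg = build_labelled_sets([cand], known, {"c1": 0})
        assert pos == [cand] and neg == []

    def test_order_independent(self, known):
        cands = [
            _candidate("a", "ACGUACGUACGU"),
            _candidate("b", "GGGGCCCCGGGG"),
            _candidate("c", "AAAACCCCAAAA"),
        ]
        hits = {"b": 1}
        pos1, neg1 = build_labelled_sets(cands, known, hits)
        pos2, neg2 = build_labelled_sets(cands[::-1], known, hits)
        assert {c.id for c in pos1} == {c.id for c in pos2}
        assert {c.id for c in neg1} == {c.id for c in neg2}


class TestSplitAndSeed:
    @pytest.fixture
    def dataset(self):
        view, _, _ = gen_two_view(
            TwoViewSimConfig(n_pos=50, n_neg=50, dims_a=2, dims_b=2,
                             noise_dims_a=0, noise_dims_b=0, rng_seed=7)
        )
        return view

    def test_default_sizes(self, dataset):
        seed, pool, hold = split_and_seed(dataset, SplitSpec(rng_seed=1))
        assert (len(hold), len(seed), len(pool)) == (20, 10, 70)
        assert (seed.labels == POSITIVE).sum() == 5
        assert (seed.labels == NEGATIVE).sum() == 5

    def test_partition_property(self, dataset):
        seed, pool, hold = split_and_seed(dataset, SplitSpec(rng_seed=3))
        parts = [set(seed.instance_ids), set(pool.instance_ids), set(hold.instance_ids)]
        assert parts[0] | parts[1] | parts[2] == set(dataset.instance_ids)
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_holdout_stratified_within_one_instance(self, dataset):
        _, _, hold = split_and_seed(dataset, SplitSpec(rng_seed=3))
        full_frac = (dataset.labels == POSITIVE).mean()
        n_pos = (hold.labels == POSITIVE).sum()
        assert abs(n_pos - full_frac * len(hold)) <= 1

    def test_deterministic(self, dataset):
        a = split_and_seed(dataset, SplitSpec(rng_seed=11))
        b = split_and_seed(dataset, SplitSpec(rng_seed=11))
        for x, y in zip(a, b):
            assert x.instance_ids == y.instance_ids

    def test_pool_labels_hidden_truth_retained(self, dataset):
        _, pool, _ = split_and_seed(dataset, SplitSpec(rng_seed=5))
        assert (pool.labels == UNLABELLED).all()
        assert pool.true_labels is not None
        assert set(pool.true_labels.tolist()) == {POSITIVE, NEGATIVE}

    def test_class_scarcity_error_names_class(self, dataset):
        small = dataset.subset(
            [i for i, l in zip(dataset.instance_ids, dataset.labels) if l == NEGATIVE]
            + [i for i, l in zip(dataset.instance_ids, dataset.labels) if l == POSITIVE][:4]
        )
        with pytest.raises(ValueError, match="positive"):
            split_and_seed(small, SplitSpec(rng_seed=1))
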