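"""Status determination, unions, multi-sample combination, chunking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gvpipe.formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    STATUSES,
    UNKNOWN,
    VariantKey,
    write_status_table,
)
from gvpipe.status_matrix import (
    StatusPolicy,
    build_sample_status,
    combine_samples,
    determine_status,
    filter_potential_snps,
    matrix_from_statuses,
    process_chunked,
    sort_matrix_rows,
    split_status_file,
    union_across_datatypes,
    unique_variants,
)


def keys_at(positions, chrom="chr1"):
    return [VariantKey.make(chrom, p, "A", "C") for p in positions]


class TestDetermineStatus:
    def test_low_coverage_overrides_any_call(self):
        assert determine_status(HET, 9) == UNKNOWN
        assert determine_status(HOM_ALT, 0) == UNKNOWN
        assert determine_status(None, 9) == UNKNOWN

    def test_sufficient_coverage_without_call_is_hom_ref(self):
        assert determine_status(None, 25) == HOM_REF
        assert determine_status(None, 10) == HOM_REF  # boundary: 10 is enough

    def test_call_passes_through_when_covered(self):
        assert determine_status(HOM_ALT, 30) == HOM_ALT
        assert determine_status(HET, 10) == HET

    def test_exhaustive_grid_matches_rule_table(self):
        policy = StatusPolicy()
        for depth in range(0, 31):
            for call in (None, HET, HOM_ALT):
                got = determine_status(call, depth, policy)
                if depth < 10:
                    assert got == UNKNOWN
                elif call is None:
                    assert got == HOM_REF
                else:
                    assert got == call

    def test_no_call_below_min_depth_fuzz(self, rng):
        policy = StatusPolicy(min_depth=int(rng.integers(1, 30)))
        for _ in range(500):
            depth = int(rng.integers(0, 60))
            call = [None, HET, HOM_ALT][int(rng.integers(0, 3))]
            got = determine_status(call, depth, policy)
            if depth < policy.min_depth:
                assert got == UNKNOWN
            else:
                assert got != UNKNOWN

    @given(
        depth=st.integers(0, 500),
        call=st.sampled_from([None, HET, HOM_ALT]),
        min_depth=st.integers(1, 100),
    )
    @settings(deadline=None, derandomize=True)
    def test_unknown_exactly_below_threshold(self, depth, call, min_depth):
        got = determine_status(call, depth, StatusPolicy(min_depth=min_depth))
        assert (got == UNKNOWN) == (depth < min_depth)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            determine_status(HET, -1)
        with pytest.raises(ValueError):
            determine_status("het?", 20)
        with pytest.raises(ValueError):
            StatusPolicy(min_depth=0)


class TestUnions:
    def test_unique_variants_set_union_and_total(self):
        v1, v2, v3 = keys_at([1, 2, 3])
        unique, total = unique_variants({"A": [v1, v2], "B": [v2, v3]})
        assert unique == [v1, v2, v3]
        assert total == 4

    def test_single_sample_is_its_own_keys(self):
        ks = keys_at([5, 9])
        unique, total = unique_variants({"A": ks})
        assert unique == ks and total == 2

    def test_matches_brute_force_over_random_samples(self, rng):
        samples = {
            f"S{i}": keys_at(rng.integers(1, 200, size=rng.integers(0, 40)))
            for i in range(100)
        }
        unique, total = unique_variants(samples)
        brute = set()
        for ks in samples.values():
            brute |= set(ks)
        assert set(unique) == brute
        assert total == sum(len(ks) for ks in samples.values())
        assert unique == sorted(unique, key=lambda k: k.pos)

    def test_union_across_datatypes(self, rng):
        a, b, c = keys_at([1, 2]), keys_at([3, 4, 5]), keys_at([6, 7, 8, 9])
        assert len(union_across_datatypes(a, b, c)) == 9
        assert union_across_datatypes(a, a, a) == a
        x = keys_at(rng.integers(1, 100, size=30))
        y = keys_at(rng.integers(1, 100, size=30))
        assert set(union_across_datatypes(x, y)) == set(x) | set(y)


class TestCombine:
    def test_shape_and_column_order(self):
        ks = keys_at([1, 2, 3, 4, 5])
        cols = {
            s: build_sample_status({}, {}, ks, sample_id=s) for s in ["S3", "S1", "S2"]
        }
        matrix = combine_samples(cols, ks)
        assert matrix.shape == (5, 3)
        assert list(matrix.columns) == ["S3", "S1", "S2"]

    def test_single_sample_column_identical(self):
        ks = keys_at([1, 2])
        col = build_sample_status({ks[0]: HET}, {("chr1", 1): 30, ("chr1", 2): 30}, ks)
        matrix = combine_samples({"sample": col}, ks)
        assert matrix["sample"].tolist() == col.tolist()

    def test_missing_union_key_error_names_key(self):
        ks = keys_at([1, 2])
        col = build_sample_status({}, {}, ks[:1], sample_id="S1")
        with pytest.raises(KeyError, match="chr1:2"):
            combine_samples({"S1": col}, ks)


class TestPotentialSnpFilter:
    def test_rule_rows(self):
        ks = keys_at([1, 2, 3])
        matrix = matrix_from_statuses(
            {
                "A": {ks[0]: UNKNOWN, ks[1]: HOM_REF, ks[2]: HET},
                "B": {ks[0]: HOM_REF, ks[1]: HET, ks[2]: HET},
                "C": {ks[0]: UNKNOWN, ks[1]: UNKNOWN, ks[2]: HET},
            },
            ks,
        )
        kept = filter_potential_snps(matrix)
        assert [k[1] for k in kept.index] == [2, 3]

    def test_all_het_identity_and_idempotence(self, rng):
        ks = keys_at(range(1, 20))
        matrix = matrix_from_statuses(
            {"A": {k: HET for k in ks}, "B": {k: HET for k in ks}}, ks
        )
        assert filter_potential_snps(matrix).equals(matrix)
        rand = matrix_from_statuses(
            {s: {k: str(rng.choice(STATUSES)) for k in ks} for s in "ABC"}, ks
        )
        once = filter_potential_snps(rand)
        assert filter_potential_snps(once).equals(once)
        assert len(once) <= len(rand)


def random_matrix(rng, n_rows, samples=("S1", "S2", "S3")):
    ks = keys_at(range(1, n_rows + 1))
    data = {s: rng.choice(STATUSES, size=n_rows) for s in samples}
    return pd.DataFrame(data, index=pd.MultiIndex.from_tuples(ks, names=["CHROM", "POS", "REF", "ALT"]))


class TestChunking:
    def test_split_sizes_and_merge_conservation(self, tmp_path, rng):
        matrix = random_matrix(rng, 10)
        path = tmp_path / "m.txt"
        write_status_table(matrix, str(path))
        header, chunks = split_status_file(str(path), str(tmp_path / "chunks"), chunk_rows=4)
        assert [c.rsplit("/", 1)[1] for c in chunks] == [
            "segment_0000.txt",
            "segment_0001.txt",
            "segment_0002.txt",
        ]
        sizes = [sum(1 for _ in open(c)) for c in chunks]
        assert sizes == [4, 4, 2]
        merged = "".join(open(c).read() for c in chunks)
        assert open(header).read() + merged == open(path).read()

    def test_rows_within_one_chunk(self, tmp_path, rng):
        matrix = random_matrix(rng, 3)
        path = tmp_path / "m.txt"
        write_status_table(matrix, str(path))
        _, chunks = split_status_file(str(path), str(tmp_path / "c"), chunk_rows=10)
        assert len(chunks) == 1

    def test_chunked_equals_unchunked(self, tmp_path, rng):
        matrix = random_matrix(rng, 57)
        path = tmp_path / "m.txt"
        write_status_table(matrix, str(path))
        whole = filter_potential_snps(matrix)
        for chunk_rows in (2, 10, 57, 1000):
            result = process_chunked(str(path), filter_potential_snps, chunk_rows)
            assert result.equals(whole)


class TestSorting:
    def test_sort_matrix_rows_natural_order(self):
        ks = [
            VariantKey.make("chr10", 5, "A", "C"),
            VariantKey.make("chr2", 9, "A", "C"),
            VariantKey.make("chr2", 3, "A", "C"),
        ]
        matrix = matrix_from_statuses({"S": {k: HET for k in ks}}, ks)
        ordered = sort_matrix_rows(matrix)
        assert [(c, p) for c, p, _, _ in ordered.index] == [
            ("chr2", 3),
            ("chr2", 9),
            ("chr10", 5),
        ]
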