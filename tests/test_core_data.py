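import numpy as np
import pandas as pd
import pytest

from woodwebs.core_data import (
    InteractionMatrix,
    RearingRecord,
    TraitTable,
    ValidationError,
    build_networks,
    read_matrix,
    read_records,
    read_traits,
    write_matrix,
    write_records,
)


def rec(t, h, b, n, interval=None):
    return RearingRecord(treatment=t, host=h, beetle=b, count=n, interval=interval)


class TestRearingRecord:
    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            rec("Rc", "hostA", "bugX", -1)

    def test_fractional_count_rejected(self):
        with pytest.raises(ValidationError):
            RearingRecord("Rc", "hostA", "bugX", 2.5)

    def test_empty_label_rejected(self):
        with pytest.raises(ValidationError):
            rec("Rc", "", "bugX", 1)


class TestBuildNetworks:
    def test_repeated_keys_sum(self):
        nets = build_networks([rec("Rc", "hostA", "bugX", 2), rec("Rc", "hostA", "bugX", 3)])
        mat = nets["Rc"]
        assert mat.shape == (1, 1)
        assert mat.A[0, 0] == 5

    def test_network_size_is_hosts_plus_beetles(self):
        # 22 hosts x 21 beetles, every species realized once
        records = []
        for i in range(22):
            records.append(rec("Rc", f"h{i:02d}", f"b{i % 21:02d}", 1))
        nets = build_networks(records)
        assert len(nets["Rc"].hosts) == 22
        assert len(nets["Rc"].beetles) == 21
        assert nets.network_size("Rc") == 43

    def test_zero_count_record_trimmed(self):
        nets = build_networks(
            [rec("Rc", "hostA", "bugX", 1), rec("Rc", "hostB", "bugY", 0)]
        )
        assert nets["Rc"].hosts == ["hostA"]
        assert nets["Rc"].beetles == ["bugX"]

    def test_grand_total_matches_record_sum(self, rng):
        records = [
            rec("Dg", f"h{rng.integers(5)}", f"b{rng.integers(5)}", int(rng.integers(0, 4)))
            for _ in range(60)
        ]
        records.append(rec("Dg", "h9", "b9", 1))  # keep the treatment non-empty
        nets = build_networks(records)
        assert nets["Dg"].m == sum(r.count for r in records)

    def test_empty_treatment_named_in_error(self):
        with pytest.raises(ValidationError, match="Rg"):
            build_networks([rec("Rg", "hostA", "bugX", 0)])

    def test_labels_sorted_lexicographically(self):
        nets = build_networks(
            [rec("Rc", "zeta", "mu", 1), rec("Rc", "alpha", "nu", 2)]
        )
        assert nets["Rc"].hosts == ["alpha", "zeta"]
        assert nets["Rc"].beetles == ["mu", "nu"]


class TestInteractionMatrix:
    def test_trimming_preserves_grand_total(self):
        A = np.array([[2, 0, 1], [0, 0, 0], [3, 0, 4]])
        mat = InteractionMatrix(["a", "b", "c"], ["x", "y", "z"], A)
        assert mat.shape == (2, 2)
        assert mat.m == A.sum()
        assert mat.m == mat.row_totals.sum() == mat.col_totals.sum()

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            InteractionMatrix(["a", "a"], ["x", "y"], np.ones((2, 2), int))

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValidationError):
            InteractionMatrix(["a"], ["x", "y"], np.array([[0.5, 1.0]]))


class TestRoundTrips:
    def test_matrix_round_trip(self, tmp_path):
        mat = InteractionMatrix(["acacia", "bursera"], ["x1", "x2"], [[3, 0], [1, 5]])
        path = tmp_path / "m.csv"
        write_matrix(mat, path)
        assert read_matrix(path) == mat

    def test_records_round_trip(self, tmp_path):
        records = [rec("Rc", "hostA", "bugX", 2, "4"), rec("Dg", "hostB", "bugY", 7)]
        path = tmp_path / "r.csv"
        write_records(records, path)
        assert read_records(path) == records

    def test_three_line_csv_gives_two_records(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("treatment,host,beetle,count\nRc,h,b,1\nRg,h,b,2\n")
        assert len(read_records(path)) == 2

    def test_missing_column_lists_expected_header(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("treatment,host,count\nRc,h,1\n")
        with pytest.raises(ValidationError, match="beetle"):
            read_records(path)


class TestTraitTable:
    def test_role_inappropriate_trait_rejected(self):
        df = pd.DataFrame(
            [
                {"species": "bug", "role": "beetle", "wood_density": 0.5,
                 "pdd": np.nan, "bsi": 30.0}
            ]
        )
        with pytest.raises(ValidationError, match="wood_density"):
            TraitTable(df)

    def test_read_traits_round_trip(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "species,role,wood_density,pdd,bsi\n"
            "acacia,host,0.61,0.12,\n"
            "bugX,beetle,,,42.5\n"
        )
        tt = read_traits(path)
        assert len(tt) == 2
        assert tt.for_role("beetle").loc["bugX", "bsi"] == 42.5

    def test_negative_trait_rejected(self):
        df = pd.DataFrame(
            [{"species": "a", "role": "host", "wood_density": -0.2,
              "pdd": np.nan, "bsi": np.nan}]
        )
        with pytest.raises(ValidationError):
            TraitTable(df)
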