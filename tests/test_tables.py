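import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import hostislands as hi
from hostislands.errors import ValidationError
from hostislands.tables import build_matrix


def write_family_csv(tmp_path, rows):
    path = tmp_path / "families.csv"
    with open(path, "w") as fh:
        fh.write("family,n_species,n_genera,area_km2\n")
        fh.writelines(r + "\n" for r in rows)
    return str(path)


class TestFamilyTable:
    def test_missing_values_filled_and_counted(self, tmp_path):
        path = write_family_csv(tmp_path, ["Xfam,,,"])
        load = hi.read_family_table(path)
        rec = load.records[0]
        assert (rec.n_species, rec.n_genera, rec.area_km2) == (0.5, 0.5, 1000.0)
        assert load.report["filled_species"] == 1
        assert load.report["filled_area"] == 1

    def test_complete_row_unchanged(self, tmp_path):
        path = write_family_csv(tmp_path, ["Asteraceae,25000,1600,1.2e8"])
        rec = hi.read_family_table(path).records[0]
        assert (rec.n_species, rec.n_genera, rec.area_km2) == (
            25000.0, 1600.0, 1.2e8)

    def test_zero_counts_become_half(self, tmp_path):
        path = write_family_csv(tmp_path, ["Smallfam,0,0,5e4"])
        rec = hi.read_family_table(path).records[0]
        assert rec.n_species == 0.5 and rec.n_genera == 0.5

    def test_duplicate_family_errors(self, tmp_path):
        path = write_family_csv(tmp_path, ["Afam,10,2,1e5", "Afam,9,1,1e5"])
        with pytest.raises(ValidationError, match="duplicate: Afam"):
            hi.read_family_table(path)

    def test_negative_count_errors(self, tmp_path):
        path = write_family_csv(tmp_path, ["Afam,-3,2,1e5"])
        with pytest.raises(ValidationError, match="negative"):
            hi.read_family_table(path)

    def test_names_are_nfc_normalized_and_stripped(self, tmp_path):
        path = write_family_csv(tmp_path, ["  Poaceae ,11000,700,1.3e8"])
        assert hi.read_family_table(path).records[0].family == "Poaceae"


def write_matrix_csv(tmp_path, n_families=30, columns=None):
    fams = [f"F{i:03d}" for i in range(1, n_families + 1)]
    df = pd.DataFrame(columns, index=fams)
    df.index.name = "family"
    path = tmp_path / "matrix.csv"
    df.to_csv(path)
    return str(path)


class TestUtilizationMatrix:
    def test_group_below_host_threshold_dropped(self, tmp_path):
        nine = [1] * 9 + [0] * 21
        ten = [1] * 10 + [0] * 20
        path = write_matrix_csv(tmp_path, 30, {"g9": nine, "g10": ten})
        mat = hi.read_utilization_matrix(path)
        assert mat.groups == ["g10"]
        assert mat.dropped_groups == ["g9"]

    def test_boundary_group_with_exactly_ten_retained(self, tmp_path):
        ten = [1] * 10 + [0] * 20
        path = write_matrix_csv(tmp_path, 30, {"g": ten})
        assert hi.read_utilization_matrix(path).groups == ["g"]

    def test_non_binary_cell_reports_coordinates(self, tmp_path):
        col = [1] * 12 + [0] * 17 + [2]
        path = write_matrix_csv(tmp_path, 30, {"g": col})
        with pytest.raises(ValidationError, match="F030.*'g'"):
            hi.read_utilization_matrix(path)

    def test_host_breadth_is_column_sum(self, tmp_path):
        col = [1] * 13 + [0] * 17
        path = write_matrix_csv(tmp_path, 30, {"g": col})
        assert hi.read_utilization_matrix(path).host_breadth()["g"] == 13


class TestUtilizerRatio:
    def test_simple_ratios(self):
        # checkerboard: every family used by 22 of 44 groups, and every
        # group uses 22 families (all groups survive the host filter)
        fams = [f"F{i}" for i in range(44)]
        cols = {f"g{j}": [(i + j) % 2 for i in range(44)]
                for j in range(44)}
        mat = build_matrix(fams, cols, min_host_families=10)
        ur = hi.utilizer_ratio(mat)
        assert np.allclose(ur.to_numpy(), 0.5)

    def test_denominator_is_retained_group_count(self):
        fams = [f"F{i}" for i in range(20)]
        kept = {f"g{j}": [1] * 20 for j in range(3)}
        dropped = {"tiny": [1] * 5 + [0] * 15}
        mat = build_matrix(fams, {**kept, **dropped}, min_host_families=10)
        assert mat.n_groups == 3
        assert hi.utilizer_ratio(mat).iloc[0] == pytest.approx(1.0)

    @given(st.integers(0, 2 ** 18 - 1))
    def test_total_ones_identity(self, bits):
        # sum_f UR(f) * n_groups == total number of 1s in the matrix
        cells = np.array([(bits >> i) & 1 for i in range(18)]).reshape(6, 3)
        cols = {f"g{j}": cells[:, j].tolist() for j in range(3)}
        mat = build_matrix([f"F{i}" for i in range(6)], cols,
                           min_host_families=0)
        total = hi.utilizer_ratio(mat).sum() * mat.n_groups
        assert total == pytest.approx(cells.sum())


class TestMainlandSelection:
    def make_records(self, values):
        return [hi.FamilyRecord(f"F{i:03d}", v, max(0.5, v / 10), 1e6)
                for i, v in enumerate(values)]

    def test_distinct_values_take_ceil_fraction(self):
        recs = self.make_records(np.arange(1, 421, dtype=float))
        assert len(hi.select_mainland(recs, "species", 0.10)) == 42

    def test_ten_families_take_top_one(self):
        recs = self.make_records(np.arange(1, 11, dtype=float))
        assert hi.select_mainland(recs, "species", 0.10) == {"F009"}

    def test_boundary_ties_included(self):
        # 42nd-ranked value is tied with the 43rd: both come along
        values = np.arange(420, 0, -1, dtype=float)
        values[42] = values[41]
        recs = self.make_records(values)
        chosen = hi.select_mainland(recs, "species", 0.10)
        assert len(chosen) == 43
        boundary = min(r.n_species for r in recs if r.family in chosen)
        for r in recs:
            if r.family not in chosen:
                assert r.n_species < boundary


class TestPdMin:
    def test_mainland_member_is_zero(self, tree3):
        dm = hi.cophenetic_distances(tree3)
        pdm = hi.pd_min(dm, {"C"})
        assert pdm["C"] == 0.0

    def test_hand_path_sums(self, tree3):
        dm = hi.cophenetic_distances(tree3)
        pdm = hi.pd_min(dm, {"C"})
        assert pdm["A"] == pytest.approx(4.0)
        assert pdm["B"] == pytest.approx(4.0)

    def test_exclude_self_uses_nearest_other(self, tree3):
        dm = hi.cophenetic_distances(tree3)
        pdm = hi.pd_min(dm, {"A", "C"}, exclude_self=True)
        assert pdm["A"] == pytest.approx(4.0)

    def test_is_lower_bound_over_mainland(self, yule200):
        dm = hi.cophenetic_distances(yule200)
        mainland = set(dm.labels[:20])
        pdm = hi.pd_min(dm, mainland)
        rng = np.random.default_rng(3)
        for fam in rng.choice(dm.labels, size=25, replace=False):
            for m in list(mainland)[:5]:
                assert pdm[fam] <= dm.get(fam, m) + 1e-12

    def test_empty_mainland_errors(self, tree3):
        with pytest.raises(ValidationError):
            hi.pd_min(hi.cophenetic_distances(tree3), set())
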