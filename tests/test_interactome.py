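import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_force_interactome, norm_from_values
from lrcomm.interactome import (
    Interaction,
    call_highly_expressed,
    compare_conditions,
    count_interactions,
    infer_interactions,
)
from lrcomm.lr_database import from_pairs


def _mg_matrix(values_col):
    """10 MG cells, one gene with the given per-cell values."""
    vals = np.zeros((10, 2))
    vals[:, 0] = values_col
    return norm_from_values(vals, ["MG"] * 10, gene_ids=["LGALS9", "other"])


class TestHighlyExpressed:
    def test_three_of_ten_above_threshold_is_high(self):
        norm = _mg_matrix([0.6, 0.7, 0.8] + [0.0] * 7)
        calls = call_highly_expressed(norm)
        row = calls[(calls.gene == "LGALS9") & (calls.cell_type == "MG")].iloc[0]
        assert row.expressing_fraction == pytest.approx(0.30)
        assert bool(row.is_high)

    def test_exactly_twenty_percent_is_not_high(self):
        norm = _mg_matrix([0.6, 0.7] + [0.0] * 8)
        calls = call_highly_expressed(norm)
        row = calls[calls.gene == "LGALS9"].iloc[0]
        assert row.expressing_fraction == pytest.approx(0.20)
        assert not bool(row.is_high)

    def test_value_exactly_tau_does_not_count(self):
        norm = _mg_matrix([0.5] * 10)
        calls = call_highly_expressed(norm)
        assert calls[calls.gene == "LGALS9"].iloc[0].expressing_fraction == 0.0

    def test_all_zero_gene_not_high(self):
        norm = _mg_matrix([0.0] * 10)
        row = call_highly_expressed(norm)[lambda d: d.gene == "LGALS9"].iloc[0]
        assert row.expressing_fraction == 0.0 and not bool(row.is_high)

    def test_unknown_cell_type_errors(self):
        norm = _mg_matrix([1.0] * 10)
        with pytest.raises(ValueError, match="NK"):
            call_highly_expressed(norm, cell_types=["NK"])

    def test_empty_condition_slice_errors(self):
        norm = _mg_matrix([1.0] * 10)
        with pytest.raises(ValueError, match="MG"):
            call_highly_expressed(norm, condition="IDH-mut")


class TestInfer:
    def test_named_axis_example(self, tiny_db):
        # LGALS9 high in MG, HAVCR2 high in CD8T -> MG -> CD8T edge
        vals = np.zeros((8, 2))
        vals[:4, 0] = 1.0  # LGALS9 in MG
        vals[4:, 1] = 1.0  # HAVCR2 in CD8T
        norm = norm_from_values(
            vals, ["MG"] * 4 + ["CD8T"] * 4, gene_ids=["LGALS9", "HAVCR2"]
        )
        calls = call_highly_expressed(norm)
        out = infer_interactions(calls, tiny_db, ["MG"], ["CD8T"])
        assert out == {Interaction("MG", "CD8T", "LGALS9", "HAVCR2")}

    def test_receptor_not_high_blocks_edge(self, tiny_db):
        vals = np.zeros((8, 2))
        vals[:4, 0] = 1.0
        norm = norm_from_values(
            vals, ["MG"] * 4 + ["CD8T"] * 4, gene_ids=["LGALS9", "HAVCR2"]
        )
        calls = call_highly_expressed(norm)
        assert infer_interactions(calls, tiny_db, ["MG"], ["CD8T"]) == set()

    def test_autocrine_excluded_by_default(self, tiny_db):
        vals = np.ones((6, 2))
        norm = norm_from_values(vals, ["MG"] * 6, gene_ids=["LGALS9", "HAVCR2"])
        calls = call_highly_expressed(norm)
        assert infer_interactions(calls, tiny_db, ["MG"], ["MG"]) == set()
        auto = infer_interactions(calls, tiny_db, ["MG"], ["MG"],
                                  include_autocrine=True)
        assert {i.key for i in auto} == {("MG", "MG", "LGALS9", "HAVCR2")}

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n_types = rng.integers(2, 6)
            types = [f"T{k}" for k in range(n_types)]
            cells = rng.integers(5, 30)
            genes = rng.integers(6, 20)
            labels = [types[rng.integers(n_types)] for _ in range(cells)]
            # ensure every type has a cell
            labels[:n_types] = types
            vals = rng.random((cells, genes)) * 1.2
            pairs_idx = {
                (int(rng.integers(genes)), int(rng.integers(genes)))
                for _ in range(rng.integers(3, 30))
            }
            senders = list(rng.choice(types, size=rng.integers(1, n_types),
                                      replace=False))
            receivers = list(rng.choice(types, size=rng.integers(1, n_types),
                                        replace=False))
            expected = brute_force_interactome(vals, labels, sorted(pairs_idx),
                                               senders, receivers)
            norm = norm_from_values(vals, labels)
            db = from_pairs([(f"g{a}", f"g{b}") for a, b in sorted(pairs_idx)])
            calls = call_highly_expressed(norm)
            got = {
                (i.sender, i.receiver, int(i.ligand[1:]), int(i.receptor[1:]))
                for i in infer_interactions(calls, db, senders, receivers)
            }
            assert got == expected

    def test_monotone_in_min_frac(self, rng, tiny_db):
        vals = rng.random((30, 2)) * 1.5
        norm = norm_from_values(vals, ["MG"] * 15 + ["CD8T"] * 15,
                                gene_ids=["LGALS9", "HAVCR2"])
        previous = None
        for mf in (0.6, 0.4, 0.2, 0.0):
            calls = call_highly_expressed(norm, min_frac=mf)
            got = infer_interactions(calls, tiny_db, ["MG"], ["CD8T"])
            if previous is not None:
                assert previous <= got
            previous = got


class TestCount:
    def test_empty_set_all_zero(self):
        mat = count_interactions([], senders=["MG"], receivers=["NK"])
        assert mat.loc["MG", "NK"] == 0

    def test_counts_and_conservation(self):
        ints = [
            Interaction("MG", "CD8T", f"L{i}", f"R{i}", "IDH-wt") for i in range(3)
        ] + [Interaction("MG", "NK", "L9", "R9", "IDH-wt")]
        mat = count_interactions(ints)
        assert mat.loc["MG", "CD8T"] == 3 and mat.loc["MG", "NK"] == 1
        assert mat.to_numpy().sum() == len(ints)

    def test_mixed_conditions_rejected(self):
        ints = [
            Interaction("MG", "NK", "L", "R", "IDH-wt"),
            Interaction("MG", "NK", "L2", "R2", "IDH-mut"),
        ]
        with pytest.raises(ValueError, match="mixed conditions"):
            count_interactions(ints)


_key = st.tuples(
    st.sampled_from(["MG", "DC"]),
    st.sampled_from(["NK", "CD8T", "Treg"]),
    st.integers(0, 15),
    st.integers(0, 15),
)


class TestVenn:
    def test_identical_sets(self):
        a = {Interaction("MG", "NK", "L", "R", "IDH-wt")}
        b = {Interaction("MG", "NK", "L", "R", "IDH-mut")}
        v = compare_conditions(a, b)
        assert v.unique_a == frozenset() and v.unique_b == frozenset()
        assert (v.gained.to_numpy() == 0).all()

    def test_three_way_split(self):
        x = Interaction("MG", "NK", "Lx", "Rx")
        y = Interaction("MG", "NK", "Ly", "Ry")
        z = Interaction("DC", "NK", "Lz", "Rz")
        v = compare_conditions({x, y}, {y, z})
        assert v.shared == {y.key}
        assert v.unique_a == {x.key} and v.unique_b == {z.key}
        assert v.gained.loc["MG", "NK"] == 1

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(keys_a=st.sets(_key, max_size=40), keys_b=st.sets(_key, max_size=40))
    def test_partition_is_disjoint_cover(self, keys_a, keys_b):
        a = {Interaction(s, r, f"L{l}", f"R{q}", "A") for s, r, l, q in keys_a}
        b = {Interaction(s, r, f"L{l}", f"R{q}", "B") for s, r, l, q in keys_b}
        v = compare_conditions(a, b)
        parts = [v.shared, v.unique_a, v.unique_b]
        assert sum(len(p) for p in parts) == len({i.key for i in a | b})
        assert len(v.shared) + len(v.unique_a) == len(a)
        assert len(v.shared) + len(v.unique_b) == len(b)
        assert v.gained.to_numpy().sum() == len(v.unique_a)
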