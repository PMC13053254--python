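import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from helpers import norm_from_values
from lrcomm.expression import normalize
from lrcomm.stratification import (
    DegenerateStratificationError,
    differential_enrichment,
    gene_set_dot_table,
    stratify_by_quantile,
)
from lrcomm.synthetic import MarkerModule, SimulationSpec, generate_dataset


def _marker_norm(values, cell_type="MG"):
    vals = np.column_stack([values, np.zeros(len(values))])
    return norm_from_values(vals, [cell_type] * len(values),
                            gene_ids=["LGALS9", "pad"])


class TestQuantileStrata:
    def test_distinct_1_to_100_interpolated_thresholds(self):
        norm = _marker_norm(np.arange(1.0, 101.0))
        s = stratify_by_quantile(norm, "LGALS9", "MG")
        assert s.threshold_lo == pytest.approx(25.75)
        assert s.threshold_hi == pytest.approx(75.25)
        assert len(s.negative_cells) == 25 and len(s.positive_cells) == 25
        assert set(s.negative_cells).isdisjoint(s.positive_cells)

    def test_all_equal_marker_degenerate(self):
        norm = _marker_norm(np.full(40, 2.0))
        with pytest.raises(DegenerateStratificationError, match="LGALS9"):
            stratify_by_quantile(norm, "LGALS9", "MG")

    def test_mostly_zero_marker_degenerate_with_zero_fraction(self):
        values = np.concatenate([np.zeros(32), np.linspace(1, 2, 8)])
        norm = _marker_norm(values)
        with pytest.raises(DegenerateStratificationError, match="80%"):
            stratify_by_quantile(norm, "LGALS9", "MG")

    def test_extreme_quantiles_select_min_and_max(self):
        norm = _marker_norm(np.array([5.0, 1.0, 3.0, 1.0, 9.0, 9.0, 2.0, 4.0]))
        s = stratify_by_quantile(norm, "LGALS9", "MG", q_lo=0.0, q_hi=1.0)
        vals = dict(zip([f"c{i:04d}" for i in range(8)],
                        [5.0, 1.0, 3.0, 1.0, 9.0, 9.0, 2.0, 4.0]))
        assert all(vals[c] == 1.0 for c in s.negative_cells)
        assert all(vals[c] == 9.0 for c in s.positive_cells)

    def test_too_few_cells_errors(self):
        norm = _marker_norm(np.arange(5.0))
        with pytest.raises(ValueError, match="need >= 8"):
            stratify_by_quantile(norm, "LGALS9", "MG")

    @pytest.mark.parametrize("n", [13, 40, 97, 200])
    def test_strata_sizes_within_one_of_quarter(self, n, rng):
        values = rng.permutation(np.linspace(0.5, 10, n))
        s = stratify_by_quantile(_marker_norm(values), "LGALS9", "MG")
        target = math.ceil(0.25 * n)
        assert abs(len(s.negative_cells) - target) <= 1
        assert abs(len(s.positive_cells) - target) <= 1

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        values=st.lists(
            st.floats(0.01, 50, allow_nan=False), min_size=8, max_size=60
        )
    )
    def test_invariant_under_strictly_monotone_transforms(self, values):
        values = np.array(values)
        try:
            base = stratify_by_quantile(_marker_norm(values), "LGALS9", "MG")
        except DegenerateStratificationError:
            assume(False)
        for transform in (lambda v: 3 * v + 1, np.sqrt, lambda v: v ** 3,
                          np.expm1):
            s = stratify_by_quantile(_marker_norm(transform(values)),
                                     "LGALS9", "MG")
            assert set(s.negative_cells) == set(base.negative_cells)
            assert set(s.positive_cells) == set(base.positive_cells)


class TestEnrichment:
    def test_identical_gene_not_significant(self, rng):
        marker = rng.random(40) * 3
        flat = np.ones(40)
        vals = np.column_stack([marker, flat])
        norm = norm_from_values(vals, ["MG"] * 40, gene_ids=["LGALS9", "flat"])
        s = stratify_by_quantile(norm, "LGALS9", "MG")
        table = differential_enrichment(norm, s)
        row = table[table.gene == "flat"].iloc[0]
        assert row.log2FC == pytest.approx(0.0)
        assert not bool(row.significant)

    def test_marker_itself_positive_by_construction(self, rng):
        marker = rng.permutation(np.linspace(0.1, 4, 60))
        vals = np.column_stack([marker, rng.random(60)])
        norm = norm_from_values(vals, ["MG"] * 60, gene_ids=["LGALS9", "other"])
        s = stratify_by_quantile(norm, "LGALS9", "MG")
        table = differential_enrichment(norm, s)
        assert table[table.gene == "LGALS9"].iloc[0].log2FC > 0

    def test_planted_module_recovered(self):
        """Marker-correlated module genes flagged significant, null genes not."""
        n_recovered = n_module = n_null_sig = 0
        for seed in (7, 8, 9):
            spec = SimulationSpec(
                cell_types=("MG",),
                cells_per_type=200,  # 400 MG cells pooled over both conditions
                n_genes=2000,
                marker_module=MarkerModule(
                    module_genes=tuple(f"MOD{i:03d}" for i in range(25))
                ),
                seed=seed,
            )
            ds, truth = generate_dataset(spec)
            norm = normalize(ds)
            s = stratify_by_quantile(norm, "LGALS9", "MG")
            table = differential_enrichment(norm, s)
            module = table[table.gene.isin(truth.module_genes)]
            n_recovered += int((module.significant & (module.log2FC > 0)).sum())
            n_module += len(module)
            null = table[~table.gene.isin(set(truth.module_genes) | {"LGALS9"})]
            n_null_sig += int(null.significant.sum())
        assert n_recovered / n_module >= 0.8
        # false-discovery proportion over the flagged set; BH admits ~5% of
        # the ~25 true discoveries per draw as false flags by construction
        assert n_null_sig / (n_null_sig + n_recovered) <= 0.1

    def test_null_false_positive_control_across_seeds(self):
        """Marker independent of all genes: BH keeps significant calls near zero.

        2,000 null genes per draw so the marker is a negligible fraction of
        each cell's library (no compositional shift from normalization).
        """
        total_sig = 0
        for seed in range(10):
            spec = SimulationSpec(
                cell_types=("MG",),
                cells_per_type=200,
                n_genes=2000,
                marker_module=MarkerModule(module_genes=()),
                seed=1000 + seed,
            )
            ds, _ = generate_dataset(spec)
            norm = normalize(ds)
            s = stratify_by_quantile(norm, "LGALS9", "MG")
            table = differential_enrichment(norm, s)
            null = table[table.gene != "LGALS9"]
            total_sig += int((null.p_adj < 0.05).sum())
        assert total_sig <= 2


class TestDotTable:
    def _setup(self, rng):
        n = 60
        marker = rng.permutation(np.linspace(0.1, 4, n))
        hit = marker + rng.normal(0, 0.2, n)  # co-varies with marker
        miss = rng.random(n)
        zero = np.zeros(n)
        vals = np.column_stack([marker, hit, miss, zero])
        vals[vals < 0] = 0
        norm = norm_from_values(
            vals, ["MG"] * n, gene_ids=["LGALS9", "hit", "miss", "zero"]
        )
        s = stratify_by_quantile(norm, "LGALS9", "MG")
        table = differential_enrichment(norm, s)
        return norm, {"MG": s}, {"MG": table}

    def test_union_semantics_and_scaling(self, rng):
        norm, strata, tables = self._setup(rng)
        out = gene_set_dot_table(norm, strata, tables, ["hit", "zero"])
        assert set(out.gene) == {"hit"}
        assert set(out.stratum) == {"negative", "positive"}
        # per-gene standardization across displayed groups: mean ~ 0
        assert out.mean_scaled.mean() == pytest.approx(0.0, abs=1e-9)
        assert ((out.pct_expressing >= 0) & (out.pct_expressing <= 1)).all()

    def test_no_significant_members_empty_with_warning(self, rng):
        norm, strata, tables = self._setup(rng)
        with pytest.warns(UserWarning):
            out = gene_set_dot_table(norm, strata, tables, ["zero"])
        assert len(out) == 0

    def test_empty_gene_set_rejected(self, rng):
        norm, strata, tables = self._setup(rng)
        with pytest.raises(ValueError):
            gene_set_dot_table(norm, strata, tables, [])
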