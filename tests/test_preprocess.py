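"""Binarisation, prevalence filtering, scaling, environment encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from calfscape import (assemble_components, binarize_abundance,
                       collapse_to_genus, correlation_matrix,
                       encode_environment, filter_prevalence,
                       genus_from_taxonomy, scale_chemicals)


def frame(values, columns=None, index=None):
    arr = np.asarray(values, dtype=float)
    return pd.DataFrame(
        arr,
        columns=columns or [f"t{i}" for i in range(arr.shape[1])],
        index=index or [f"s{i}" for i in range(arr.shape[0])])


class TestBinarize:
    @pytest.mark.parametrize("value,expected", [
        (0.002, 1.0),     # clearly detected
        (0.0005, 0.0),    # below the detection limit
        (0.001, 0.0),     # exactly at the threshold reads absent
        (0.0, 0.0),
    ])
    def test_threshold_is_strict(self, value, expected):
        out = binarize_abundance(frame([[value]]))
        assert out.iloc[0, 0] == expected

    def test_all_zero_column_stays_zero(self):
        out = binarize_abundance(frame([[0.0], [0.0], [0.0]]))
        assert (out == 0).all().all()

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            binarize_abundance(frame([[-0.1]]))

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=12))
    @settings(max_examples=30, deadline=None)
    def test_idempotent(self, values):
        table = frame([[v] for v in values])
        once = binarize_abundance(table)
        twice = binarize_abundance(once)
        assert once.equals(twice)


class TestPrevalenceFilter:
    def make_binary(self, counts, n_samples=36):
        data = {}
        for i, c in enumerate(counts):
            col = np.zeros(n_samples)
            col[:c] = 1.0
            data[f"t{i}"] = col
        return pd.DataFrame(data, index=[f"s{i}" for i in range(n_samples)])

    def test_window_boundaries(self):
        binary = self.make_binary([2, 3, 34, 35, 36])
        kept = filter_prevalence(binary)
        assert kept == ["t1", "t2"]

    def test_everywhere_present_taxon_excluded(self):
        binary = self.make_binary([36, 10])
        assert filter_prevalence(binary) == ["t1"]

    def test_empty_result_is_an_error(self):
        binary = self.make_binary([1, 36])
        with pytest.raises(ValueError, match="presence counts"):
            filter_prevalence(binary)

    def test_invariant_to_sample_order(self):
        binary = self.make_binary([5, 20, 35])
        shuffled = binary.sample(frac=1.0, random_state=1)
        assert filter_prevalence(binary) == filter_prevalence(shuffled)


class TestScaleChemicals:
    def test_min_max_definition(self):
        out = scale_chemicals(frame([[2.0], [4.0], [6.0]]))
        assert np.allclose(out.iloc[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = scale_chemicals(frame([[3.0], [3.0], [3.0]]))
        assert (out == 0).all().all()

    def test_endpoints_exact(self):
        out = scale_chemicals(frame([[1.7], [9.3], [4.0]]))
        assert out.iloc[:, 0].min() == 0.0
        assert out.iloc[:, 0].max() == 1.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            scale_chemicals(frame([[np.nan], [1.0]]))


class TestEncodeEnvironment:
    def meta(self, rows):
        return pd.DataFrame(rows, columns=["animal_id", "group", "day"],
                            index=[f"s{i}" for i in range(len(rows))])

    @pytest.mark.parametrize("group,day,expected", [
        ("CON", 30, (1.0, 0.53)),
        ("EXP", 3, (0.0, 0.0)),
        ("CON", 60, (1.0, 1.0)),
        ("EXP", 60, (0.0, 1.0)),
    ])
    def test_encoding_values(self, group, day, expected):
        env = encode_environment(self.meta([("A01", group, day)]))
        assert tuple(env.values_array[0]) == expected

    def test_unknown_day_rejected(self):
        with pytest.raises(ValueError, match="day"):
            encode_environment(self.meta([("A01", "CON", 45)]))

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            encode_environment(self.meta([("A01", "TRT", 30)]))

    def test_bijection_on_design(self):
        rows = [("A", g, d) for g in ("CON", "EXP") for d in (3, 30, 60)]
        env = encode_environment(self.meta(rows))
        pairs = {tuple(r) for r in env.values_array}
        assert len(pairs) == 6


class TestAssemble:
    def test_component_counts(self):
        taxa = frame(np.eye(3), columns=["a", "b", "c"])
        chems = frame([[0.1, 0.9]] * 3, columns=["x", "y"])
        cm = assemble_components(binarize_abundance(taxa, 0.5), chems)
        assert cm.n_components == 5
        assert cm.n_m == 3 and cm.n_c == 2
        assert cm.component_names[:3] == ["a", "b", "c"]

    def test_no_chemicals(self):
        taxa = binarize_abundance(frame(np.eye(2)), 0.5)
        cm = assemble_components(taxa)
        assert cm.n_components == cm.n_m == 2

    def test_misaligned_samples_rejected(self):
        taxa = binarize_abundance(frame(np.eye(2)), 0.5)
        chems = frame([[0.2]] * 2, index=["x1", "x2"])
        with pytest.raises(ValueError, match="misaligned"):
            assemble_components(taxa, chems)


class TestCorrelation:
    def meta(self, n_per_group):
        rows, idx = [], []
        for g in ("CON", "EXP"):
            for i in range(n_per_group):
                rows.append((f"{g}{i}", g, 30))
                idx.append(f"{g}_s{i}")
        return pd.DataFrame(rows, columns=["animal_id", "group", "day"],
                            index=idx)

    def test_perfect_correlations(self):
        meta = self.meta(4)
        x = np.arange(8, dtype=float)
        acids = frame(np.column_stack([x]), columns=["acid"],
                      index=list(meta.index))
        genera = frame(np.column_stack([2 * x, -x + 3.0]),
                       columns=["up", "down"], index=list(meta.index))
        out = correlation_matrix(acids, genera, meta)
        for group in ("CON", "EXP"):
            assert out[group].loc["acid", "up"] == pytest.approx(1.0)
            assert out[group].loc["acid", "down"] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        n = 5000
        meta = pd.DataFrame(
            {"animal_id": [f"a{i}" for i in range(n)],
             "group": ["CON"] * (n // 2) + ["EXP"] * (n // 2),
             "day": [30] * n},
            index=[f"s{i}" for i in range(n)])
        acids = frame(rng.normal(size=(n, 1)), columns=["acid"],
                      index=list(meta.index))
        genera = frame(rng.normal(size=(n, 1)), columns=["taxon"],
                       index=list(meta.index))
        out = correlation_matrix(acids, genera, meta)
        assert abs(out["CON"].iloc[0, 0]) < 0.05
        assert abs(out["EXP"].iloc[0, 0]) < 0.05

    def test_zero_variance_gives_nan(self):
        meta = self.meta(3)
        acids = frame([[1.0]] * 6, columns=["flat"], index=list(meta.index))
        genera = frame(np.arange(6, dtype=float)[:, None],
                       columns=["taxon"], index=list(meta.index))
        out = correlation_matrix(acids, genera, meta)
        assert np.isnan(out["CON"].loc["flat", "taxon"])

    def test_day3_excluded_by_default(self):
        rows = [("a1", "CON", 3), ("a1", "CON", 30), ("a2", "CON", 30),
                ("a3", "CON", 60), ("b1", "EXP", 30), ("b2", "EXP", 30),
                ("b3", "EXP", 60)]
        meta = pd.DataFrame(rows, columns=["animal_id", "group", "day"],
                            index=[f"s{i}" for i in range(7)])
        acids = frame(np.arange(7, dtype=float)[:, None], columns=["a"],
                      index=list(meta.index))
        # day-3 sample carries an extreme value; default days=(30, 60)
        # must ignore it entirely
        genera = acids.copy()
        genera.columns = ["t"]
        genera.iloc[0, 0] = 1e6
        out = correlation_matrix(acids, genera, meta)
        assert out["CON"].loc["a", "t"] == pytest.approx(1.0)


class TestTaxonomyParsing:
    def test_genus_extraction(self):
        s = "k__Bacteria;p__Firmicutes;c__;o__;f__Lachnospiraceae;g__Dorea"
        assert genus_from_taxonomy(s) == "Dorea"

    def test_unassigned_genus_dropped(self):
        table = frame([[0.5, 0.5]],
                      columns=["k__Bacteria;p__X;c__;o__;f__Y;g__",
                               "k__Bacteria;p__X;c__;o__;f__Y;g__Blautia"])
        out = collapse_to_genus(table)
        assert list(out.columns) == ["Blautia"]

    def test_same_genus_columns_summed(self):
        cols = ["k__Bacteria;p__A;c__;o__;f__F1;g__Dorea",
                "k__Bacteria;p__A;c__;o__;f__F2;g__Dorea"]
        out = collapse_to_genus(frame([[0.2, 0.3]], columns=cols))
        assert out.loc[:, "Dorea"].iloc[0] == pytest.approx(0.5)
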