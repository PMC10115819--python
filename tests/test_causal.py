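"""Baseline-difference transform, DirectLiNGAM, DAG export."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from calfscape import (delta_transform, estimate, export_dag, generate_sem,
                       internal_standard_check, read_dag_graphml)
from calfscape.causal import CausalModel


def make_tables(values_by_animal):
    rows, meta, idx = [], [], []
    for animal, vals in values_by_animal.items():
        for day, v in zip((3, 30, 60), vals):
            idx.append(f"{animal}_d{day}")
            rows.append([float(v)])
            meta.append((animal, "CON", day))
    values = pd.DataFrame(rows, index=idx, columns=["x"])
    metadata = pd.DataFrame(meta, index=idx,
                            columns=["animal_id", "group", "day"])
    return values, metadata


class TestDeltaTransform:
    def test_definition(self):
        values, meta = make_tables({"A": (5, 8, 2)})
        out = delta_transform(values, meta)
        assert out["x"].tolist() == [0.0, 3.0, -3.0]

    def test_constant_trajectory_all_zero(self):
        values, meta = make_tables({"A": (4, 4, 4)})
        out = delta_transform(values, meta)
        assert (out == 0).all().all()

    def test_baseline_rows_exactly_zero(self):
        values, meta = make_tables({"A": (5, 8, 2), "B": (1, 9, 7)})
        out = delta_transform(values, meta)
        d3 = meta["day"] == 3
        assert (out.loc[d3] == 0).all().all()

    def test_missing_baseline_names_animal(self):
        values, meta = make_tables({"A": (5, 8, 2)})
        keep = meta["day"] != 3
        with pytest.raises(ValueError, match="'A'"):
            delta_transform(values.loc[keep], meta.loc[keep])

    def test_drop_baseline_rows_option(self):
        values, meta = make_tables({"A": (5, 8, 2)})
        out = delta_transform(values, meta, keep_baseline_rows=False)
        assert len(out) == 2

    @given(shift=st.floats(-100, 100, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_translation_invariance(self, shift):
        values, meta = make_tables({"A": (5, 8, 2), "B": (0, 1, 2)})
        out1 = delta_transform(values, meta)
        out2 = delta_transform(values + shift, meta)
        assert np.allclose(out1.to_numpy(), out2.to_numpy())


class TestEstimate:
    def test_two_variable_recovery(self):
        B = np.zeros((2, 2))
        B[1, 0] = 1.5
        sem = generate_sem(B, [("uniform", 1.0)] * 2, n=10_000, seed=0,
                           shuffle=False)
        model = estimate(sem.data)
        assert model.ordered_variables == ["v0", "v1"]
        assert model.strength("v0", "v1") == pytest.approx(1.5, abs=0.05)

    def test_independent_columns_near_zero_strengths(self):
        B = np.zeros((3, 3))
        sem = generate_sem(B, [("uniform", 1.0)] * 3, n=10_000, seed=1)
        model = estimate(sem.data)
        assert np.max(np.abs(model.B)) < 0.05

    def test_deterministic(self):
        B = np.zeros((3, 3))
        B[1, 0] = 1.0
        sem = generate_sem(B, [("laplace", 1.0)] * 3, n=500, seed=2)
        m1 = estimate(sem.data)
        m2 = estimate(sem.data)
        assert m1.causal_order == m2.causal_order
        assert np.array_equal(m1.B, m2.B)

    def test_scale_equivariance(self):
        """Rescaling a column rescales its incident strengths: b_child<-parent
        maps to c_child/c_parent * b."""
        B = np.zeros((2, 2))
        B[1, 0] = 1.2
        sem = generate_sem(B, [("uniform", 1.0)] * 2, n=5000, seed=3,
                           shuffle=False)
        data = sem.data.copy()
        m1 = estimate(data)
        data2 = data.copy()
        data2["v0"] = data2["v0"] * 4.0
        m2 = estimate(data2)
        assert m2.strength("v0", "v1") == pytest.approx(
            m1.strength("v0", "v1") / 4.0, rel=1e-6)

    def test_column_permutation_consistent(self):
        B = np.zeros((3, 3))
        B[1, 0] = 1.5
        B[2, 1] = -1.0
        sem = generate_sem(B, [("uniform", 1.0)] * 3, n=8000, seed=4,
                           shuffle=False)
        m1 = estimate(sem.data)
        shuffled = sem.data[["v2", "v0", "v1"]]
        m2 = estimate(shuffled)
        assert m1.ordered_variables == m2.ordered_variables

    def test_more_variables_than_rows_rejected(self):
        data = pd.DataFrame(np.random.default_rng(0).random((3, 4)))
        with pytest.raises(ValueError, match="rows"):
            estimate(data)

    def test_gaussian_noise_degrades_recovery(self):
        """With Gaussian disturbances the direction is unidentifiable, so
        order recovery falls towards chance while uniform noise stays
        reliable."""
        B = np.zeros((2, 2))
        B[1, 0] = 1.0
        hits = {"uniform": 0, "gaussian": 0}
        for kind in hits:
            for seed in range(30):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sem = generate_sem(B, [(kind, 1.0)] * 2, n=800,
                                       seed=seed, shuffle=False,
                                       allow_gaussian=True)
                    model = estimate(sem.data)
                if model.ordered_variables == ["v0", "v1"]:
                    hits[kind] += 1
        assert hits["uniform"] - hits["gaussian"] >= 6


class TestInternalStandard:
    def test_constructed_aggregate_passes(self):
        rng = np.random.default_rng(0)
        genus = rng.lognormal(0, 0.8, 200)
        family = genus + 0.05 * rng.lognormal(0, 0.8, 200)
        extra = rng.laplace(0, 1, 200)
        data = pd.DataFrame({"genus": genus, "family": family,
                             "extra": extra})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = estimate(data)
        report = internal_standard_check(model, [("genus", "family")])
        assert report["verdict"].iloc[0] == "pass"
        assert 0.9 <= report["coefficient"].iloc[0] <= 1.1

    def test_disconnected_pair_fails_with_zero(self):
        model = CausalModel(variables=["a", "b"], causal_order=[0, 1],
                            B=np.zeros((2, 2)))
        report = internal_standard_check(model, [("a", "b")])
        assert report["coefficient"].iloc[0] == 0.0
        assert report["verdict"].iloc[0] == "fail"

    def test_unknown_variable_raises(self):
        model = CausalModel(variables=["a"], causal_order=[0],
                            B=np.zeros((1, 1)))
        with pytest.raises(KeyError):
            internal_standard_check(model, [("a", "zz")])


class TestExport:
    def make_model(self):
        B = np.zeros((3, 3))
        B[1, 0] = 1.5
        B[2, 1] = -0.3
        return CausalModel(variables=["x", "y", "z"],
                           causal_order=[0, 1, 2], B=B)

    def test_graphml_round_trip(self, tmp_path):
        model = self.make_model()
        path = tmp_path / "dag.graphml"
        export_dag(model, path)
        g = read_dag_graphml(path)
        assert set(g.nodes) == {"x", "y", "z"}
        assert g["x"]["y"]["weight"] == pytest.approx(1.5)
        assert g["y"]["z"]["weight"] == pytest.approx(-0.3)

    def test_dot_output(self, tmp_path):
        model = self.make_model()
        path = tmp_path / "dag.dot"
        export_dag(model, path)
        text = path.read_text()
        assert '"x" -> "y"' in text
        assert "digraph" in text

    def test_threshold_monotone(self, tmp_path):
        model = self.make_model()
        counts = []
        for thr in (0.0, 0.5, 2.0):
            p = tmp_path / f"dag_{thr}.graphml"
            export_dag(model, p, threshold=thr)
            counts.append(read_dag_graphml(p).number_of_edges())
        assert counts == sorted(counts, reverse=True)

    def test_empty_b_gives_node_only_graph(self, tmp_path):
        model = CausalModel(variables=["a", "b"], causal_order=[0, 1],
                            B=np.zeros((2, 2)))
        p = tmp_path / "empty.graphml"
        export_dag(model, p)
        g = read_dag_graphml(p)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"a", "b"}
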