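import itertools
import math

import numpy as np
import pandas as pd
import pytest

from panelbn.bn import (
    DAGStructure,
    GaussianLocal,
    CLGParameters,
    HybridBN,
    ScoreCache,
    TierConstraint,
    bic_score,
    check_arc_legal,
    fit_parameters,
    loglik,
    loglik_frame,
)
from panelbn.dataset import VariableSpec

from conftest import random_clg_frame


def _specs_3tier():
    return {
        "intervention": VariableSpec(
            "intervention", "discrete", "intervention", "static",
            ("control", "intervention"),
        ),
        "age": VariableSpec("age", "continuous", "demographic", "static"),
        "gender": VariableSpec("gender", "discrete", "demographic", "static", ("f", "m")),
        "habit@T1": VariableSpec("habit@T1", "continuous", "determinant", "T1"),
        "habit@T2": VariableSpec("habit@T2", "continuous", "determinant", "T2"),
        "mvpa@T1": VariableSpec("mvpa@T1", "continuous", "outcome", "T1"),
    }


class TestArcLegality:
    def setup_method(self):
        self.specs = _specs_3tier()
        self.constraint = TierConstraint.from_specs(self.specs)
        self.structure = DAGStructure(nodes=tuple(sorted(self.specs)))

    def test_arc_against_time_is_rejected_with_tier_reason(self):
        ok, reason = check_arc_legal(
            self.structure, self.constraint, ("habit@T2", "mvpa@T1"), self.specs
        )
        assert (ok, reason) == (False, "tier")

    def test_continuous_parent_of_discrete_node_is_rejected(self):
        ok, reason = check_arc_legal(
            self.structure, self.constraint, ("age", "gender"), self.specs
        )
        assert (ok, reason) == (False, "class")

    def test_intervention_to_later_wave_is_legal_on_empty_graph(self):
        ok, reason = check_arc_legal(
            self.structure, self.constraint, ("intervention", "habit@T1"), self.specs
        )
        assert (ok, reason) == (True, "ok")

    def test_exogenous_roots_cannot_receive_parents(self):
        ok, reason = check_arc_legal(
            self.structure, self.constraint, ("intervention", "gender"), self.specs
        )
        assert (ok, reason) == (False, "root")

    def test_cycle_detection(self):
        s = self.structure.with_arc(("habit@T1", "mvpa@T1"))
        ok, reason = check_arc_legal(
            s, self.constraint, ("mvpa@T1", "habit@T1"), self.specs
        )
        assert (ok, reason) == (False, "cycle")

    def test_unknown_node_raises(self):
        with pytest.raises(KeyError):
            check_arc_legal(self.structure, self.constraint, ("nope", "age"), self.specs)


class TestFitParameters:
    def test_root_cpt_is_empirical_frequency(self):
        specs = {"g": VariableSpec("g", "discrete", "demographic", "static", ("a", "b"))}
        frame = pd.DataFrame({"g": ["a", "b", "b", "b"]})
        params = fit_parameters(DAGStructure(("g",)), frame, specs)
        assert params.discrete["g"].probs(()) == pytest.approx([0.25, 0.75])

    def test_noiseless_linear_child_recovers_exact_coefficients(self):
        specs = {
            "x": VariableSpec("x", "continuous", "determinant", "T1"),
            "y": VariableSpec("y", "continuous", "determinant", "T1"),
        }
        x = np.linspace(-2, 2, 50)
        frame = pd.DataFrame({"x": x, "y": 3 + 2 * x})
        structure = DAGStructure(("x", "y"), frozenset({("x", "y")}))
        params = fit_parameters(structure, frame, specs)
        b0, coef, s2 = params.continuous["y"].coefs(())
        assert b0 == pytest.approx(3.0, abs=1e-9)
        assert coef[0] == pytest.approx(2.0, abs=1e-9)
        assert s2 == pytest.approx(1e-9)  # variance floor guards exact fits

    def test_sparse_configuration_falls_back_to_pooled_fit(self):
        rng = np.random.default_rng(0)
        n = 60
        g = np.array(["a"] * (n - 2) + ["b"] * 2)
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(scale=0.1, size=n)
        specs = {
            "g": VariableSpec("g", "discrete", "demographic", "static", ("a", "b")),
            "x": VariableSpec("x", "continuous", "determinant", "T1"),
            "y": VariableSpec("y", "continuous", "determinant", "T1"),
        }
        frame = pd.DataFrame({"g": g, "x": x, "y": y})
        structure = DAGStructure(
            ("g", "x", "y"), frozenset({("x", "y"), ("g", "y")})
        )
        params = fit_parameters(structure, frame, specs)
        local = params.continuous["y"]
        assert ("b",) in local.pooled_configs  # 2 rows < cont parents + 2
        # independent pooled least-squares oracle
        Z = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        got = local.coefs(("b",))
        assert got[0] == pytest.approx(beta[0])
        assert got[1][0] == pytest.approx(beta[1])


class TestBICScore:
    def test_empty_graph_matches_closed_form_per_column_bic(self):
        rng = np.random.default_rng(42)
        n, d = 1000, 5
        frame = pd.DataFrame(
            {f"x{i}": rng.normal(size=n) for i in range(d)}
        )
        specs = {
            c: VariableSpec(c, "continuous", "determinant", "T1") for c in frame
        }
        structure = DAGStructure(tuple(sorted(frame.columns)))
        got = bic_score(structure, frame, specs)
        # independent closed form: per column -(n/2)(1+ln(2*pi*s2_ml)) - (2/2) ln n
        expected = 0.0
        for c in frame:
            s2 = float(np.var(frame[c].to_numpy()))  # ML variance
            expected += -(n / 2) * (1 + math.log(2 * math.pi * s2)) - math.log(n)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_arc_between_independent_columns_lowers_bic_at_large_n(self):
        rng = np.random.default_rng(1)
        n = 5000
        frame = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        specs = {c: VariableSpec(c, "continuous", "determinant", "T1") for c in frame}
        empty = DAGStructure(("a", "b"))
        with_arc = empty.with_arc(("a", "b"))
        assert bic_score(with_arc, frame, specs) < bic_score(empty, frame, specs)

    def test_score_difference_of_one_arc_touches_only_the_child_family(self):
        frame, specs, _ = random_clg_frame(3, 4)
        cache = ScoreCache(frame, specs)
        base = {v: cache.family_bic(v, set()) for v in frame.columns}
        s_empty = sum(base.values())
        s_arc = s_empty - base["x1"] + cache.family_bic("x1", {"x0"})
        structure = DAGStructure(tuple(sorted(frame.columns)), frozenset({("x0", "x1")}))
        assert cache.total_bic(structure) == pytest.approx(s_arc)

    @pytest.mark.parametrize("seed", range(5))
    def test_total_bic_is_sum_of_family_scores_on_random_graphs(self, seed):
        frame, specs, truth = random_clg_frame(seed, 4)
        cache = ScoreCache(frame, specs)
        structure = DAGStructure(tuple(sorted(frame.columns)), frozenset(truth))
        total = cache.total_bic(structure)
        parts = sum(
            cache.family_bic(v, structure.parents(v)) for v in structure.nodes
        )
        assert total == pytest.approx(parts)

    def test_incomplete_data_is_rejected(self):
        frame = pd.DataFrame({"a": [1.0, np.nan]})
        specs = {"a": VariableSpec("a", "continuous", "determinant", "T1")}
        with pytest.raises(ValueError):
            bic_score(DAGStructure(("a",)), frame, specs)


class TestLoglik:
    def test_standard_normal_node_closed_form(self):
        specs = {"x": VariableSpec("x", "continuous", "determinant", "T1")}
        local = GaussianLocal(
            disc_parents=(), cont_parents=(), parent_levels=(),
            table={(): (0.0, np.array([]), 1.0)}, pooled=(0.0, np.array([]), 1.0),
        )
        bn = HybridBN(
            structure=DAGStructure(("x",)),
            parameters=CLGParameters(discrete={}, continuous={"x": local}),
            specs=specs,
        )
        assert loglik(bn, {"x": 0.0}) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_empty_graph_density_is_product_of_univariate_densities(self):
        frame, specs, _ = random_clg_frame(11, 3, n=200)
        structure = DAGStructure(tuple(sorted(frame.columns)))
        bn = HybridBN(structure, fit_parameters(structure, frame, specs), specs)
        got = loglik_frame(bn, frame)
        expected = np.zeros(len(frame))
        for c in frame:
            x = frame[c].to_numpy()
            mu, s2 = x.mean(), x.var()
            expected += -0.5 * (np.log(2 * np.pi * s2) + (x - mu) ** 2 / s2)
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_fitted_loglik_equals_family_loglik_used_by_bic(self, seed):
        """fit_parameters → loglik on the training data must reproduce the
        maximized likelihood inside the BIC family scores."""
        frame, specs, truth = random_clg_frame(100 + seed, 4)
        structure = DAGStructure(tuple(sorted(frame.columns)), frozenset(truth))
        cache = ScoreCache(frame, specs)
        fam_ll = sum(
            cache.family_ll(v, structure.parents(v))[0] for v in structure.nodes
        )
        bn = HybridBN(structure, fit_parameters(structure, frame, specs), specs)
        assert float(loglik_frame(bn, frame).sum()) == pytest.approx(fam_ll, rel=1e-9)

    def test_nested_structures_have_monotone_loglik(self):
        frame, specs, _ = random_clg_frame(7, 4)
        cache = ScoreCache(frame, specs)
        nodes = tuple(sorted(frame.columns))
        arcs = [("x0", "x1"), ("x0", "x2"), ("x1", "x3"), ("x2", "x3")]
        prev = -math.inf
        for k in range(len(arcs) + 1):
            s = DAGStructure(nodes, frozenset(arcs[:k]))
            ll = sum(cache.family_ll(v, s.parents(v))[0] for v in nodes)
            assert ll >= prev - 1e-9
            prev = ll

    def test_value_outside_declared_levels_raises(self):
        specs = {"g": VariableSpec("g", "discrete", "demographic", "static", ("a", "b"))}
        frame = pd.DataFrame({"g": ["a", "b"]})
        structure = DAGStructure(("g",))
        bn = HybridBN(structure, fit_parameters(structure, frame, specs), specs)
        with pytest.raises(ValueError):
            loglik(bn, {"g": "zzz"})
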