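import itertools

import numpy as np
import pandas as pd
import pytest

from panelbn.bn import DAGStructure, ScoreCache, TierConstraint, check_arc_legal
from panelbn.dataset import PanelDataset, VariableSpec
from panelbn.learning import (
    SearchSettings,
    enumerate_legal_dags,
    exhaustive_search,
    hill_climb,
    structural_em,
)
from panelbn.synthetic import mcar

from conftest import random_clg_frame

SMALL_SEARCH = SearchSettings(random_restarts=6, seed=5)


def _cont_specs(names):
    return {n: VariableSpec(n, "continuous", "determinant", "T1") for n in names}


def _chain_frame(n=5000, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 1.5 * x + rng.normal(size=n)
    z = 1.5 * y + rng.normal(size=n)
    return pd.DataFrame({"x": x, "y": y, "z": z})


class TestHillClimb:
    def test_independent_noise_yields_empty_graph(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame({f"x{i}": rng.normal(size=3000) for i in range(4)})
        specs = _cont_specs(frame.columns)
        constraint = TierConstraint(tiers=(frozenset(frame.columns),))
        res = hill_climb(frame, constraint, SMALL_SEARCH, specs=specs)
        assert res.structure.arcs == frozenset()
        # exhaustive search oracle agrees the empty graph is optimal
        ex = exhaustive_search(frame, constraint, specs=specs)
        assert ex.structure.arcs == frozenset()

    def test_three_node_chain_reaches_exhaustive_optimum(self):
        frame = _chain_frame()
        specs = _cont_specs(frame.columns)
        constraint = TierConstraint(tiers=(frozenset(frame.columns),))
        cache = ScoreCache(frame, specs)
        hc = hill_climb(frame, constraint, SMALL_SEARCH, specs=specs, cache=cache)
        ex = exhaustive_search(frame, constraint, specs=specs, cache=cache)
        assert hc.score == pytest.approx(ex.score)
        # score-equivalent to the true chain: same skeleton
        skel = {tuple(sorted(a)) for a in hc.structure.arcs}
        assert skel == {("x", "y"), ("y", "z")}

    def test_whitelisted_arc_survives_search(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        specs = _cont_specs(frame.columns)
        constraint = TierConstraint(
            tiers=(frozenset(frame.columns),),
            extra_required=frozenset({("a", "b")}),
        )
        res = hill_climb(frame, constraint, SMALL_SEARCH, specs=specs)
        assert ("a", "b") in res.structure.arcs

    @pytest.mark.parametrize("case", range(50))
    def test_matches_exhaustive_optimum_on_random_small_instances(self, case):
        d = 3 + case % 2
        frame, specs, _ = random_clg_frame(2024 + case, d)
        constraint = TierConstraint(tiers=(frozenset(frame.columns),))
        cache = ScoreCache(frame, specs)
        hc = hill_climb(frame, constraint, SMALL_SEARCH, specs=specs, cache=cache)
        ex = exhaustive_search(frame, constraint, specs=specs, cache=cache)
        assert hc.score == pytest.approx(ex.score, abs=1e-6)


class TestExhaustive:
    def test_single_node_gives_empty_graph(self):
        frame = pd.DataFrame({"a": np.random.default_rng(0).normal(size=50)})
        specs = _cont_specs(frame.columns)
        res = exhaustive_search(frame, TierConstraint(tiers=(frozenset("a"),)), specs=specs)
        assert res.structure.arcs == frozenset()

    def test_refuses_more_than_five_variables(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({f"x{i}": rng.normal(size=20) for i in range(6)})
        specs = _cont_specs(frame.columns)
        with pytest.raises(ValueError):
            exhaustive_search(frame, TierConstraint(tiers=(frozenset(frame.columns),)), specs=specs)

    def test_tiered_three_nodes_admit_exactly_eight_dags(self):
        """One node per tier: only the 3 forward arcs are free, so the legal
        DAG count is 2^3 = 8."""
        specs = {
            "a": VariableSpec("a", "continuous", "determinant", "T1"),
            "b": VariableSpec("b", "continuous", "determinant", "T2"),
            "c": VariableSpec("c", "continuous", "determinant", "T3"),
        }
        constraint = TierConstraint(
            tiers=(frozenset("a"), frozenset("b"), frozenset("c"))
        )
        dags = list(enumerate_legal_dags(["a", "b", "c"], constraint, specs))
        assert len(dags) == 8

    def test_exhaustive_score_by_enumeration_agrees_with_order_search(self):
        frame, specs, _ = random_clg_frame(77, 3)
        constraint = TierConstraint(tiers=(frozenset(frame.columns),))
        cache = ScoreCache(frame, specs)
        ex = exhaustive_search(frame, constraint, specs=specs, cache=cache)
        best = max(
            cache.total_bic(DAGStructure(tuple(sorted(frame.columns)), arcs))
            for arcs in enumerate_legal_dags(frame.columns, constraint, specs)
        )
        assert ex.score == pytest.approx(best)


class TestStructuralEM:
    def test_complete_data_reduces_to_hill_climb(
        self, compact_dataset, compact_constraint
    ):
        settings = SearchSettings(seed=2)
        sem = structural_em(compact_dataset, compact_constraint, settings)
        hc = hill_climb(compact_dataset, compact_constraint, settings)
        assert sem.bn.structure.arcs == hc.structure.arcs
        assert sem.score_log == [pytest.approx(hc.score)]
        assert sem.converged

    def test_score_log_is_non_decreasing_and_outputs_are_tier_legal(
        self, compact_missing, compact_constraint
    ):
        for seed in (0, 1, 2):
            sem = structural_em(
                compact_missing, compact_constraint, SearchSettings(seed=seed)
            )
            assert all(
                b >= a - 1e-7 for a, b in zip(sem.score_log, sem.score_log[1:])
            )
            structure = sem.bn.structure
            empty = DAGStructure(structure.nodes)
            for arc in structure.arcs:
                ok, reason = check_arc_legal(
                    empty, compact_constraint, arc, sem.bn.specs
                )
                assert ok, f"illegal arc {arc}: {reason}"

    def test_mcar_chain_recovers_true_skeleton(self):
        frame = _chain_frame(n=2000, seed=5)
        specs = _cont_specs(frame.columns)
        ds = PanelDataset(frame, specs)
        dsm = mcar(ds, 0.2, 9)
        constraint = TierConstraint(tiers=(frozenset(frame.columns),))
        sem = structural_em(dsm, constraint, SearchSettings(seed=4, random_restarts=4))
        skel = {tuple(sorted(a)) for a in sem.bn.structure.arcs}
        assert skel == {("x", "y"), ("y", "z")}

    def test_variable_with_no_observations_is_rejected(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        specs = _cont_specs(frame.columns)
        ds = PanelDataset(frame, specs)
        constraint = TierConstraint(tiers=(frozenset(frame.columns),))
        with pytest.raises(ValueError):
            structural_em(ds, constraint, SearchSettings())

    def test_single_draw_completion_is_deterministic_given_seed(self):
        frame = _chain_frame(n=400, seed=6)
        specs = _cont_specs(frame.columns)
        dsm = mcar(PanelDataset(frame, specs), 0.2, 10)
        constraint = TierConstraint(tiers=(frozenset(frame.columns),))
        settings = SearchSettings(seed=3, completion_mode="single_draw")
        a = structural_em(dsm, constraint, settings)
        b = structural_em(dsm, constraint, settings)
        assert a.bn.structure.arcs == b.bn.structure.arcs
        assert a.score_log == b.score_log


class TestParameterRecovery:
    def test_fitted_coefficients_cover_truth_within_three_standard_errors(
        self, compact_truth, compact_dataset
    ):
        """On complete CLG data (n=2000), at least 95% of the fitted
        continuous-parent coefficients lie within 3 SEs of the generating
        values (SEs from an independent per-configuration OLS)."""
        from panelbn.bn import fit_parameters

        structure = compact_truth.structure
        frame = compact_dataset.frame
        params = fit_parameters(structure, frame, compact_dataset.specs)
        checked, inside = 0, 0
        for node, local in params.continuous.items():
            if not local.cont_parents:
                continue
            truth_local = compact_truth.parameters.continuous[node]
            for cfg in local.table:
                # per-configuration OLS with covariance-based standard errors
                if local.disc_parents:
                    sel = np.ones(len(frame), dtype=bool)
                    for p, lvl in zip(local.disc_parents, cfg):
                        sel &= frame[p].to_numpy() == lvl
                else:
                    sel = np.ones(len(frame), dtype=bool)
                sub = frame.loc[sel]
                if len(sub) < len(local.cont_parents) + 2:
                    continue
                Z = np.column_stack(
                    [np.ones(len(sub))] + [sub[p].to_numpy() for p in local.cont_parents]
                )
                y = sub[node].to_numpy()
                beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
                resid = y - Z @ beta
                s2 = resid @ resid / (len(sub) - Z.shape[1])
                cov = s2 * np.linalg.inv(Z.T @ Z)
                se = np.sqrt(np.diag(cov))
                true_b0, true_coef, _ = truth_local.coefs(cfg)
                fit_b0, fit_coef, _ = local.coefs(cfg)
                for j, (tv, fv) in enumerate(
                    zip([true_b0, *true_coef], [fit_b0, *fit_coef])
                ):
                    checked += 1
                    if abs(fv - tv) <= 3 * se[j]:
                        inside += 1
        assert checked > 30
        assert inside / checked >= 0.95
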