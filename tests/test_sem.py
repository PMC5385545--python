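"""Basis sets, Fisher's C, AICc, and full piecewise-SEM fits."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dendrosem import synthetic
from dendrosem.sem import (
    SEMSpec,
    aicc_sem,
    basis_set,
    dsep_pvalues,
    fishers_c,
    fit_sem,
)


class TestSpec:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            SEMSpec(
                exogenous=["w"], endogenous=["a", "b"],
                edges=[("w", "a"), ("a", "b"), ("b", "a")],
            )

    def test_orphan_endogenous_rejected(self):
        with pytest.raises(ValueError, match="no parents"):
            SEMSpec(exogenous=["w"], endogenous=["a", "b"], edges=[("w", "a")])

    def test_correlated_error_duplicating_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicates"):
            SEMSpec(
                exogenous=["w"], endogenous=["a", "b"],
                edges=[("w", "a"), ("w", "b"), ("a", "b")],
                correlated_errors=[("a", "b")],
            )


class TestBasisSet:
    def test_saturated_model_empty(self):
        spec = SEMSpec(
            exogenous=["w", "c"], endogenous=["a", "b"],
            edges=[("w", "a"), ("c", "a"), ("w", "b"), ("c", "b"), ("a", "b")],
        )
        assert basis_set(spec) == []

    def test_textbook_chain(self):
        spec = SEMSpec(exogenous=["x"], endogenous=["m", "y"],
                       edges=[("x", "m"), ("m", "y")])
        (claim,) = basis_set(spec)
        assert claim.dependent == "y"
        assert claim.independent == "x"
        assert claim.conditioning == ("m",)

    def test_claim_count_matches_enumeration_on_random_dags(self, rng):
        for _ in range(20):
            n_exo, n_endo = int(rng.integers(1, 4)), int(rng.integers(1, 5))
            exo = [f"x{i}" for i in range(n_exo)]
            endo = [f"y{i}" for i in range(n_endo)]
            nodes = exo + endo
            edges = []
            for d_i, dst in enumerate(endo):
                # parents only from earlier nodes keeps the graph acyclic
                pool = exo + endo[:d_i]
                k = int(rng.integers(1, len(pool) + 1))
                for src in rng.choice(pool, size=k, replace=False):
                    edges.append((str(src), dst))
            spec = SEMSpec(exogenous=exo, endogenous=endo, edges=edges)
            adj = {frozenset(e) for e in edges}
            expected = sum(
                1
                for a, b in itertools.combinations(nodes, 2)
                if frozenset((a, b)) not in adj and not (a in exo and b in exo)
            )
            assert len(basis_set(spec)) == expected

    def test_correlated_errors_excluded(self):
        spec = SEMSpec(
            exogenous=["w"], endogenous=["a", "b"],
            edges=[("w", "a"), ("w", "b")],
            correlated_errors=[("a", "b")],
        )
        assert basis_set(spec) == []


class TestFishersC:
    def test_all_ones(self):
        c, df, p = fishers_c([1.0, 1.0])
        assert c == 0.0 and df == 4 and p == 1.0

    def test_hand_value(self):
        c, df, p = fishers_c([0.5, 0.5])
        assert c == pytest.approx(2.7726, abs=1e-4)
        assert df == 4

    def test_empty_saturated_convention(self):
        assert fishers_c([]) == (0.0, 0, 1.0)

    def test_additive_and_order_invariant(self, rng):
        p = rng.uniform(0.01, 1, 6)
        c_all, _, _ = fishers_c(p)
        c_a, _, _ = fishers_c(p[:3])
        c_b, _, _ = fishers_c(p[3:])
        c_perm, _, _ = fishers_c(rng.permutation(p))
        assert c_all == pytest.approx(c_a + c_b)
        assert c_all == pytest.approx(c_perm)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fishers_c([0.0, 0.5])


class TestAICc:
    def test_hand_value(self):
        assert aicc_sem(10.0, 5, 100) == pytest.approx(20.6383, abs=1e-4)

    def test_limits(self):
        assert aicc_sem(7.0, 0, 50) == 7.0
        assert aicc_sem(10.0, 5, 10**7) == pytest.approx(20.0, abs=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc_sem(10.0, 5, 6)


class TestFitSEM:
    def test_true_dag_is_not_rejected_and_paths_recovered(self):
        data, truth = synthetic.simulate_sem_dataset(seed=7)
        spec = synthetic.default_sem_spec("delta13c")
        fit = fit_sem(spec, data)
        assert fit.df == 2 * len(fit.claims)
        assert fit.global_p > 0.01
        est = fit.paths.set_index(["source", "target"])
        b = truth["coefs"][("wbal", "delta13c")]
        implied = b * data["wbal"].std(ddof=1) / data["delta13c"].std(ddof=1)
        assert est.loc[("wbal", "delta13c"), "std_coef"] == pytest.approx(implied, abs=0.15)

    def test_removing_true_edge_is_detected(self):
        data, _ = synthetic.simulate_sem_dataset(seed=7)
        spec = synthetic.default_sem_spec("delta13c")
        mis = SEMSpec(
            exogenous=spec.exogenous,
            endogenous=spec.endogenous,
            edges=[e for e in spec.edges if e != ("wbal", "delta13c")],
            correlated_errors=spec.correlated_errors,
        )
        fit = fit_sem(mis, data)
        assert fit.global_p < 0.05
        worst = fit.claims.loc[fit.claims["p"].idxmin()]
        assert {worst["dependent"], worst["independent"]} == {"wbal", "delta13c"}

    def test_affine_rescaling_leaves_standardized_paths(self):
        data, _ = synthetic.simulate_sem_dataset(seed=3)
        spec = synthetic.default_sem_spec("delta13c")
        a = fit_sem(spec, data).paths.set_index(["source", "target"])["std_coef"]
        scaled = data.assign(wbal=1000.0 * data["wbal"] + 5.0, bai=0.01 * data["bai"])
        b = fit_sem(spec, scaled).paths.set_index(["source", "target"])["std_coef"]
        assert np.allclose(a.sort_index(), b.sort_index(), atol=1e-6)

    def test_failed_component_names_node(self):
        data, _ = synthetic.simulate_sem_dataset(seed=1)
        data = data.assign(d18o=1.0)  # constant response breaks its component
        spec = synthetic.default_sem_spec("delta13c")
        with pytest.raises(RuntimeError, match="d18o"):
            fit_sem(spec, data)

    def test_empty_basis_yields_saturated_p(self):
        data, _ = synthetic.simulate_sem_dataset(seed=2)
        spec = synthetic.default_sem_spec("delta13c")
        saturated = SEMSpec(
            exogenous=spec.exogenous,
            endogenous=spec.endogenous,
            edges=spec.edges + [("co2", "d18o"), ("so4", "bai")],
            correlated_errors=spec.correlated_errors,
        )
        fit = fit_sem(saturated, data)
        assert fit.fishers_c == 0.0 and fit.global_p == 1.0


class TestDsepNull:
    def test_null_pvalues_roughly_uniform(self):
        from scipy import stats as sps

        ps = []
        for seed in range(40):
            data, _ = synthetic.simulate_sem_dataset(seed=1000 + seed)
            ps.extend(dsep_pvalues(synthetic.default_sem_spec("delta13c"), data)["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01
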