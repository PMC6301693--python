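"""Worst-case systems, characteristic maps, fixed points, certification."""

import math

import numpy as np
import pytest
import sympy as sp

from stablemodules.feedback import (
    CycleUnion, conjecture_candidates, cycle_unions, positive_cycles)
from stablemodules.mios import (
    certify_module, characteristic_map, find_fixed_points, module_report,
    scan_stable_modules, select_mios_input, thresholds_from_fixed_point,
    worst_case_system)
from stablemodules.model import SignedDigraph, parse_model, regulatory_graph


@pytest.fixture(scope="module")
def toy_wc(toy_model, toy_high_candidate):
    return worst_case_system(toy_model, toy_high_candidate)


class TestWorstCaseSystem:
    def test_toy_x_rhs_is_printed_limit_system(self, toy_wc):
        w, x = sp.symbols("w x", real=True)
        assert sp.simplify(toy_wc.rhs["x"] - (2 * w / (1 + 2 * w) - x)) == 0
        assert toy_wc.substitutions == {("x", "z"): sp.oo}

    def test_toy_w_and_y_rhs_untouched(self, toy_wc, toy_model):
        for v in ("w", "y"):
            assert sp.simplify(toy_wc.rhs[v] - toy_model.rhs[v]) == 0

    def test_inhibitory_hill_replaced_at_upper_bound(self, pag_model):
        # high candidate on the Fyn<->PAG loop: the external inhibition of PAG
        # by TCRb is pinned at TCRb = 1, i.e. H1(TCRb) -> H1(1)
        g = regulatory_graph(pag_model)
        union = cycle_unions(g, positive_cycles(g))[0]
        assert union.nodes == frozenset({"Fyn", "PAG"})
        high = conjecture_candidates(union)[0]
        wc = worst_case_system(pag_model, high)
        assert wc.substitutions == {("PAG", "TCRb"): 1}
        Fyn, PAG = sp.symbols("Fyn PAG", real=True)
        H1_at_1 = sp.Rational(2, 3)  # 1/(1 + 1/2)
        H2 = Fyn**2 / (Fyn**2 + sp.Rational(1, 4))
        expected = (1 - H1_at_1) * (1 - H2) + H2 - PAG
        assert sp.simplify(wc.rhs["PAG"] - expected) == 0

    def test_no_external_regulators_means_no_substitutions(self):
        m = parse_model("var a in [0, 1]\nvar b in [0, 1]\n"
                        "ode a = hill(b, 1/2, 2) - a\n"
                        "ode b = hill(a, 1/2, 2) - b\n")
        g = regulatory_graph(m)
        cand = conjecture_candidates(cycle_unions(g, positive_cycles(g))[0])[0]
        wc = worst_case_system(m, cand)
        assert wc.substitutions == {}
        for v in "ab":
            assert sp.simplify(wc.rhs[v] - m.rhs[v]) == 0


class TestSelectInput:
    def test_toy_opens_loop_at_substituted_variable(self, toy_wc):
        assert select_mios_input(toy_wc) == "x"

    def test_single_cycle_without_substitutions_lexicographic(self):
        m = parse_model("var a in [0, 1]\nvar b in [0, 1]\n"
                        "ode a = hill(b, 1/2, 2) - a\n"
                        "ode b = hill(a, 1/2, 2) - b\n")
        g = regulatory_graph(m)
        cand = conjecture_candidates(cycle_unions(g, positive_cycles(g))[0])[0]
        assert select_mios_input(worst_case_system(m, cand)) == "a"

    def test_vertex_disjoint_cycles_unsupported(self):
        m = parse_model(
            "var a in [0, 1]\nvar b in [0, 1]\nvar c in [0, 1]\nvar d in [0, 1]\n"
            "ode a = hill(b, 1/2, 2) - a\node b = hill(a, 1/2, 2) - b\n"
            "ode c = hill(d, 1/2, 2) - c\node d = hill(c, 1/2, 2) - d\n")
        g = regulatory_graph(m)
        sign = {(s, t): sg for s, t, sg in g.edges}
        cycles = positive_cycles(g)
        edges = frozenset(
            (x, c[(i + 1) % len(c)], sign[(x, c[(i + 1) % len(c)])])
            for c in cycles for i, x in enumerate(c))
        union = CycleUnion(nodes=frozenset("abcd"), edges=edges,
                           generating_cycles=tuple(cycles))
        cand = conjecture_candidates(union)[0]
        assert select_mios_input(worst_case_system(m, cand)) is None


class TestCharacteristicMap:
    @pytest.mark.parametrize("u, expected", [
        (0.7, 0.7),            # the printed solution x = 7/10
        (0.0, 0.0),            # hand cascade: y = 0, w = 0, balance 0
        (1.0, 8 / 11),         # closed form h(u) = 4u/(5u + 1/2)
        (0.25, 4 * 0.25 / (5 * 0.25 + 0.5)),
    ])
    def test_toy_values(self, toy_wc, u, expected):
        assert characteristic_map(toy_wc, "x", u) == pytest.approx(
            expected, abs=1e-9)

    def test_root_out_of_validity_reported(self):
        from stablemodules.mios import RootOutOfBoundsError
        m = parse_model("var a in [0, 1]\nvar b in [0, 1]\n"
                        "ode a = 5*b - a\node b = a - b\n")
        g = regulatory_graph(m)
        cand = conjecture_candidates(cycle_unions(g, positive_cycles(g))[0])[0]
        wc = worst_case_system(m, cand)
        with pytest.raises(RootOutOfBoundsError, match="a"):
            characteristic_map(wc, "b", 1.0)  # a = 5 > validity


class TestFixedPoints:
    def test_toy_fixed_points(self, toy_wc):
        fps = find_fixed_points(toy_wc, "x")
        values = [fp.value for fp in fps]
        assert len(values) == 2
        assert values[0] == pytest.approx(0.0, abs=1e-6)
        assert values[1] == pytest.approx(0.7, abs=1e-6)
        assert fps[0].crossing == "endpoint"

    def test_contractive_map_has_origin_only(self):
        # h(u) = u/2 via a two-variable chain
        m = parse_model("var a in [0, 1]\nvar b in [0, 1]\n"
                        "ode a = b/2 - a\node b = a - b\n")
        g = regulatory_graph(m)
        cand = conjecture_candidates(cycle_unions(g, positive_cycles(g))[0])[0]
        wc = worst_case_system(m, cand)
        iv = select_mios_input(wc)
        assert characteristic_map(wc, iv, 0.8) == pytest.approx(0.4)
        fps = find_fixed_points(wc, iv)
        assert [fp.value for fp in fps] == pytest.approx([0.0])

    def test_tangential_fixed_point_below_grid_resolution(self):
        # h(u) = u + (u - 1/2)^2: tangent to the diagonal at 1/2; a grid that
        # misses u = 1/2 exactly cannot see it (documented behavior), a grid
        # containing 1/2 reports it as a tangent point
        m = parse_model(
            "var a in [0, 1]\nvar b in [0, 1]\n"
            "ode a = 2*b - a\node b = (a + (a - 1/2)^2)/2 - b\n")
        g = regulatory_graph(m)
        cand = conjecture_candidates(cycle_unions(g, positive_cycles(g))[0])[0]
        wc = worst_case_system(m, cand)
        missing = find_fixed_points(wc, "a", grid_n=256)
        assert all(abs(fp.value - 0.5) > 1e-6 for fp in missing)
        catching = find_fixed_points(wc, "a", grid_n=257)
        assert any(abs(fp.value - 0.5) < 1e-9 for fp in catching)

    def test_monotone_map_assertion_holds_on_scan(self, toy_wc):
        # the scan itself asserts h is nondecreasing; reaching here means the
        # property held on the grid
        find_fixed_points(toy_wc, "x", grid_n=64)


class TestThresholds:
    def test_toy_thresholds_at_upper_fixed_point(self, toy_wc):
        th = thresholds_from_fixed_point(toy_wc, "x", 0.7)
        assert th["x"] == pytest.approx(7 / 10, abs=1e-9)
        assert th["w"] == pytest.approx(7 / 6, abs=1e-9)
        assert th["y"] == pytest.approx(7 / 12, abs=1e-9)

    def test_toy_thresholds_at_origin(self, toy_wc):
        th = thresholds_from_fixed_point(toy_wc, "x", 0.0)
        assert th == {"w": 0.0, "x": 0.0, "y": 0.0}

    def test_self_loop_candidate_returns_input_value(self):
        m = parse_model("var a in [0, 1]\node a = hill(a, 2, 1) - a\n")
        union = CycleUnion(nodes=frozenset("a"),
                           edges=frozenset({("a", "a", 1)}),
                           generating_cycles=(("a",),))
        cand = conjecture_candidates(union)[0]
        wc = worst_case_system(m, cand)
        assert select_mios_input(wc) == "a"
        fps = find_fixed_points(wc, "a")
        assert [fp.value for fp in fps] == pytest.approx([0.0])
        assert thresholds_from_fixed_point(wc, "a", 0.0) == {"a": 0.0}


class TestCertification:
    def test_toy_module_certifies(self, toy_model, toy_high_candidate):
        th = {"x": 0.7, "w": 7 / 6, "y": 7 / 12}
        mod = certify_module(toy_model, toy_high_candidate, th)
        assert mod.certified
        assert all(abs(r) <= 1e-9 for r in mod.residuals.values())
        assert set(mod.statements) == {
            ("w", ">", 7 / 6), ("x", ">", 0.7), ("y", ">", 7 / 12)}

    def test_zero_thresholds_certify(self, toy_model, toy_high_candidate):
        mod = certify_module(
            toy_model, toy_high_candidate, {"x": 0.0, "w": 0.0, "y": 0.0})
        assert mod.certified

    def test_perturbed_thresholds_fail_a_face(self, toy_model, toy_high_candidate):
        th = {"x": 0.7 * 1.1, "w": 7 / 6 * 1.1, "y": 7 / 12 * 1.1}
        mod = certify_module(toy_model, toy_high_candidate, th)
        assert not mod.certified
        bad = [v for v, b in mod.faces.items()
               if isinstance(b, float) and b < -1e-9]
        assert bad  # at least one face with outward-pointing worst case

    def test_report_prints_small_fractions(self, toy_model, toy_high_candidate):
        mod = certify_module(
            toy_model, toy_high_candidate, {"x": 0.7, "w": 7 / 6, "y": 7 / 12})
        rep = module_report(mod)
        pretty = {s["variable"]: s["pretty"] for s in rep["statements"]}
        assert "7/10" in pretty["x"] and "7/6" in pretty["w"]
        assert "7/12" in pretty["y"]


class TestScan:
    def test_toy_scan_finds_worked_module_family(self, toy_model):
        mods = scan_stable_modules(toy_model)
        stmt_sets = [dict((v, (d, t)) for v, d, t in m.statements) for m in mods]
        upper = next(s for s in stmt_sets if s["x"][1] == pytest.approx(0.7, abs=1e-6))
        assert upper["w"] == (">", pytest.approx(7 / 6, abs=1e-6))
        assert upper["y"] == (">", pytest.approx(7 / 12, abs=1e-6))
        assert any(all(t == 0.0 and d == ">" for d, t in s.values())
                   for s in stmt_sets)

    def test_certified_faces_hold_on_random_face_samples(self, toy_model):
        # condition (b) re-verified pointwise: on each face of the certified
        # module the true vector field points inward for random external
        # configurations
        mods = scan_stable_modules(toy_model)
        mod = next(m for m in mods
                   if any(abs(t - 0.7) < 1e-6 for _, _, t in m.statements))
        th = {v: t for v, _, t in mod.statements}
        rng = np.random.default_rng(0)
        syms = {s: sp.Symbol(s, real=True) for s in "uwxyz"}
        f_sym = toy_model.term_sym("f")
        fns = {v: sp.lambdify(
            (syms["u"], syms["w"], syms["x"], syms["y"], syms["z"], f_sym),
            toy_model.rhs_flat(v), "numpy") for v in th}
        for face_var in th:
            for _ in range(300):
                pt = {
                    "u": rng.uniform(0, 10), "z": rng.uniform(0, 50),
                    "w": rng.uniform(th["w"], th["w"] + 10),
                    "x": rng.uniform(th["x"], th["x"] + 10),
                    "y": rng.uniform(th["y"], th["y"] + 10),
                }
                pt[face_var] = th[face_var]
                f_val = rng.uniform(0.1, 10.0)
                val = fns[face_var](pt["u"], pt["w"], pt["x"], pt["y"],
                                    pt["z"], f_val)
                assert val >= -1e-9

    def test_worst_case_dominates_other_external_values(self, toy_model, toy_wc):
        # pinning z anywhere in its validity gives a larger x-face derivative
        # than the worst case (the domination argument behind certification)
        w, x, z = sp.symbols("w x z", real=True)
        true_fn = sp.lambdify((w, x, z), toy_model.rhs["x"], "numpy")
        wc_fn = sp.lambdify((w, x), toy_wc.rhs["x"], "numpy")
        rng = np.random.default_rng(1)
        for _ in range(200):
            wv = rng.uniform(0, 5)
            xv = rng.uniform(0, 2)
            zv = rng.uniform(0, 100)
            assert true_fn(wv, xv, zv) >= wc_fn(wv, xv) - 1e-12

    def test_scan_runs_on_random_inclass_models(self):
        from stablemodules.boolhill import random_inclass_model
        m = random_inclass_model(6, density=0.3, seed=7)
        mods = scan_stable_modules(m)
        for mod in mods:
            assert mod.certified
            for v, d, t in mod.statements:
                assert 0.0 <= t <= 1.0
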