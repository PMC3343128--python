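"""Tension, accessibility, module-strength and resilience metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nettension.io import synth_archive
from nettension.metrics import (_sym_kl, accessibility, accessibility_from_counts,
                                adjacency, module_strength, notch_interval,
                                notches_overlap, perturb_and_score,
                                select_representatives, substitute_module,
                                tension_kl, tension_median)
from nettension.model import ContractError, ModuleMap
from nettension.objectives import ObjectiveResult, default_task_spec


def _archive(medians, sigma=0.0, n=5, seed=0, task="synthetic"):
    return synth_archive({k: (v, sigma) for k, v in medians.items()}, n,
                         rng=seed, task=task)


NAMES20 = {f"p{i:02d}": 1.0 for i in range(20)}


class TestTensionMedian:
    def test_identity(self):
        a = _archive(NAMES20, sigma=0.1, seed=1)
        assert tension_median(a, a).value == 0.0

    def test_single_decade_shift_contributes_one_over_n(self):
        a = _archive(NAMES20)
        shifted = dict(NAMES20, p00=10.0)
        b = _archive(shifted)
        rep = tension_median(a, b)
        assert rep.value == pytest.approx(1.0 / 20)
        assert rep.contributions["p00"] == pytest.approx(1.0)

    def test_symmetry(self):
        a = _archive(NAMES20, sigma=0.3, seed=1)
        b = _archive(dict(NAMES20, p03=4.0), sigma=0.3, seed=2)
        assert tension_median(a, b).value == pytest.approx(
            tension_median(b, a).value)

    @given(c=st.floats(0.01, 100))
    @settings(max_examples=20, deadline=None)
    def test_analytic_shift_law(self, c):
        a = _archive(NAMES20)
        b = _archive(dict(NAMES20, p07=c))
        assert tension_median(a, b).value == pytest.approx(
            abs(math.log10(c)) / 20, abs=1e-12)

    def test_weights_must_normalise(self):
        a = _archive(NAMES20)
        with pytest.raises(ContractError):
            tension_median(a, a, weights={k: 1.0 for k in NAMES20})

    def test_empty_archive_rejected(self):
        a = _archive(NAMES20)
        empty = _archive(NAMES20, n=1)
        empty.records = []
        with pytest.raises(ContractError):
            tension_median(a, empty)

    def test_mismatched_parameters_rejected(self):
        a = _archive(NAMES20)
        b = _archive({"q": 1.0})
        with pytest.raises(ContractError):
            tension_median(a, b)

    def test_recovers_lognormal_ground_truth_within_bootstrap_error(self):
        """Synthetic archives with known medians: the estimate matches the
        analytic mean |log10 median ratio| within twice its bootstrap SE."""
        rng = np.random.default_rng(99)
        shifts = rng.uniform(-1, 1, 20)
        med_a = {f"p{i:02d}": 1.0 for i in range(20)}
        med_b = {f"p{i:02d}": float(10 ** shifts[i]) for i in range(20)}
        truth = np.mean(np.abs(shifts))
        a = synth_archive({k: (v, 0.3) for k, v in med_a.items()}, 500, rng=11)
        b = synth_archive({k: (v, 0.3) for k, v in med_b.items()}, 500, rng=12)
        est = tension_median(a, b).value
        # bootstrap over solutions
        da, db = a.params_df().to_numpy(), b.params_df().to_numpy()
        boot_rng = np.random.default_rng(13)
        boots = []
        for _ in range(200):
            ia = boot_rng.integers(0, 500, 500)
            ib = boot_rng.integers(0, 500, 500)
            med_ra = np.median(da[ia], axis=0)
            med_rb = np.median(db[ib], axis=0)
            boots.append(np.mean(np.abs(np.log10(med_ra / med_rb))))
        se = np.std(boots)
        assert abs(est - truth) < 2 * se + 1e-9


class TestTensionKL:
    def test_identical_archives_have_zero_divergence(self):
        a = _archive(NAMES20, sigma=0.2, seed=5)
        assert tension_kl(a, a).value == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p, q", [
        ([0.5, 0.5], [0.25, 0.75]),
        ([0.1, 0.2, 0.7], [0.3, 0.3, 0.4]),
        ([0.25, 0.25, 0.25, 0.25], [0.4, 0.3, 0.2, 0.1]),
        ([0.05, 0.15, 0.3, 0.3, 0.2], [0.2, 0.2, 0.2, 0.2, 0.2]),
    ])
    def test_agrees_with_direct_summation_oracle(self, p, q):
        p, q = np.asarray(p), np.asarray(q)
        oracle = 0.5 * (
            sum(pi * math.log(pi / qi) for pi, qi in zip(p, q))
            + sum(qi * math.log(qi / pi) for pi, qi in zip(p, q)))
        assert _sym_kl(p, q) == pytest.approx(oracle, abs=1e-12)

    def test_two_bin_hand_value(self):
        """KL(p||q) for p=(.5,.5), q=(.25,.75) is .5 ln2 + .5 ln(2/3);
        the symmetrised divergence averages it with KL(q||p)."""
        p, q = np.array([0.5, 0.5]), np.array([0.25, 0.75])
        kl_pq = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
        kl_qp = 0.25 * math.log(0.5) + 0.75 * math.log(1.5)
        assert kl_pq == pytest.approx(0.1438, abs=5e-5)
        assert _sym_kl(p, q) == pytest.approx(0.5 * (kl_pq + kl_qp), abs=1e-12)

    def test_invariant_under_parameter_reordering(self):
        from nettension.search import SolutionArchive

        def reordered(arch):
            out = SolutionArchive(task=arch.task, variant=arch.variant,
                                  param_names=tuple(reversed(arch.param_names)),
                                  n_iterations=arch.n_iterations)
            out.records = arch.records
            return out

        a = _archive({"a": 1.0, "b": 5.0}, sigma=0.2, seed=3, n=50)
        b = _archive({"a": 2.0, "b": 1.0}, sigma=0.2, seed=4, n=50)
        assert tension_kl(a, b).value == pytest.approx(
            tension_kl(reordered(a), reordered(b)).value)

    def test_nonnegative_and_positive_for_shifted_distributions(self):
        a = _archive(NAMES20, sigma=0.2, seed=6, n=100)
        b = _archive(dict(NAMES20, p00=30.0), sigma=0.2, seed=7, n=100)
        v = tension_kl(a, b).value
        assert v > 0


class TestAccessibility:
    def test_pooled_denominator_arithmetic(self):
        assert accessibility_from_counts(4541, 4878, 146, 14) == pytest.approx(
            (146 + 14) / (4541 + 4878))

    def test_bounds_and_extremes(self):
        assert accessibility_from_counts(10, 10, 10, 10) == 1.0
        assert accessibility_from_counts(10, 10, 0, 0) == 0.0

    def test_swap_invariance(self):
        assert accessibility_from_counts(100, 50, 7, 3) == pytest.approx(
            accessibility_from_counts(50, 100, 3, 7))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ContractError):
            accessibility_from_counts(5, 5, 6, 0)
        with pytest.raises(ContractError):
            accessibility_from_counts(0, 0, 0, 0)

    def test_cross_evaluation_on_reference_fixtures(self, base_model, nominal,
                                                    biphasic_fixture):
        from nettension.search import IterationRecord, SolutionArchive
        res = ObjectiveResult(task="x", score=1.0, components={},
                              is_solution=True, threshold=1.0)
        a = SolutionArchive(task="hysteresis", variant="base",
                            param_names=tuple(base_model.param_names))
        a.records = [IterationRecord(0, 0, "solution", nominal, res, 0, 0)]
        b = SolutionArchive(task="biphasic", variant="base",
                            param_names=tuple(base_model.param_names))
        b.records = [IterationRecord(0, 0, "solution", biphasic_fixture, res, 0, 0)]
        frac, counts = accessibility(a, b, base_model,
                                     default_task_spec("hysteresis"),
                                     default_task_spec("biphasic"))
        assert 0.0 <= frac <= 1.0
        assert counts["n_a"] == counts["n_b"] == 1
        assert frac == (counts["dual_in_a"] + counts["dual_in_b"]) / 2


class TestModuleStrength:
    MAP = ModuleMap(modules={"mod": (("k", "proportional"), ("d", "inverse"))},
                    unassigned=())

    def test_proportional_times_inverse(self):
        s = module_strength({"k": 2.0, "d": 0.5}, self.MAP)
        assert s["mod"] == pytest.approx(math.log10(4.0))

    def test_unit_parameters_give_zero_log_strength(self):
        assert module_strength({"k": 1.0, "d": 1.0}, self.MAP)["mod"] == 0.0

    def test_doubling_inverse_member_halves_strength(self):
        s1 = module_strength({"k": 3.0, "d": 1.0}, self.MAP)["mod"]
        s2 = module_strength({"k": 3.0, "d": 2.0}, self.MAP)["mod"]
        assert s1 - s2 == pytest.approx(math.log10(2.0))

    def test_reference_module_map_orientations(self, base_model):
        mm = base_model.module_map
        orient = {n: o for members in mm.modules.values() for n, o in members}
        assert orient["ke_MYC"] == "proportional"
        assert orient["d_E2Fp"] == "inverse"
        assert orient["K_X"] == "inverse"
        # every free parameter appears exactly once across modules+unassigned
        seen = list(mm.unassigned) + list(orient)
        assert sorted(seen) == sorted(base_model.param_names)


class TestRepresentatives:
    MAP = ModuleMap(modules={"sensor": (("a", "proportional"),),
                             "R": (("b", "proportional"),)}, unassigned=())

    def _gaussian_archive(self, n=200, seed=8):
        rng = np.random.default_rng(seed)
        vals = 10 ** rng.normal(0, 0.5, size=(n, 2))
        spec = {"a": (1.0, 0.0), "b": (1.0, 0.0)}
        arch = synth_archive(spec, n, rng=0)
        for rec, (va, vb) in zip(arch.records, vals):
            rec.params["a"], rec.params["b"] = float(va), float(vb)
        return arch

    def test_whole_archive_when_k_equals_size(self):
        arch = self._gaussian_archive(60)
        sub = select_representatives(arch, ("sensor", "R"), self.MAP, k=60)
        assert len(sub) == 60

    def test_selected_lie_within_60th_percentile_chebyshev_radius(self):
        arch = self._gaussian_archive(200)
        sub = select_representatives(arch, ("sensor", "R"), self.MAP, k=50)
        coords = np.log10(np.array([[r.params["a"], r.params["b"]]
                                    for r in arch.records]))
        center = np.median(coords, axis=0)
        q75, q25 = np.percentile(coords, [75, 25], axis=0)
        dist = np.max(np.abs(coords - center) / (q75 - q25), axis=1)
        cutoff = np.percentile(dist, 60)
        sel = np.log10(np.array([[r.params["a"], r.params["b"]]
                                 for r in sub.records]))
        dsel = np.max(np.abs(sel - center) / (q75 - q25), axis=1)
        assert np.all(dsel <= cutoff)

    def test_matches_brute_force_distance_sort(self):
        arch = self._gaussian_archive(100)
        sub = select_representatives(arch, ("sensor", "R"), self.MAP, k=20)
        coords = np.log10(np.array([[r.params["a"], r.params["b"]]
                                    for r in arch.records]))
        center = np.median(coords, axis=0)
        q75, q25 = np.percentile(coords, [75, 25], axis=0)
        dist = np.max(np.abs(coords - center) / (q75 - q25), axis=1)
        expected = set(np.argsort(dist, kind="stable")[:20])
        got = {arch.records.index(r) for r in sub.records}
        assert got == expected

    def test_too_small_archive_rejected(self):
        arch = self._gaussian_archive(10)
        with pytest.raises(ContractError):
            select_representatives(arch, ("sensor", "R"), self.MAP, k=50)


class TestSubstitution:
    def test_self_donor_is_identity(self, base_model, nominal):
        from nettension.search import IterationRecord, SolutionArchive
        res = ObjectiveResult(task="x", score=1.0, components={},
                              is_solution=True, threshold=1.0)
        donor = SolutionArchive(task="x", variant="base",
                                param_names=tuple(base_model.param_names))
        donor.records = [IterationRecord(0, 0, "solution", nominal, res, 0, 0)]
        out = substitute_module(nominal, donor, "R", base_model.module_map)
        assert out == pytest.approx(nominal)

    def test_disjoint_modules_commute(self, base_model, nominal):
        donor = synth_archive(
            {k: (v * 3.0, 0.1) for k, v in nominal.items()}, 20, rng=2)
        mm = base_model.module_map
        ab = substitute_module(
            substitute_module(nominal, donor, "R", mm), donor, "NFB", mm)
        ba = substitute_module(
            substitute_module(nominal, donor, "NFB", mm), donor, "R", mm)
        assert ab == pytest.approx(ba)

    def test_unknown_module_rejected(self, base_model, nominal):
        donor = synth_archive({k: (v, 0.0) for k, v in nominal.items()}, 2, rng=0)
        with pytest.raises(ContractError):
            substitute_module(nominal, donor, "oscillator", base_model.module_map)

    def test_empty_donor_rejected(self, base_model, nominal):
        donor = synth_archive({k: (v, 0.0) for k, v in nominal.items()}, 2, rng=0)
        donor.records = []
        with pytest.raises(ContractError):
            substitute_module(nominal, donor, "R", base_model.module_map)


class TestResilience:
    def _const_scorer(self, score=1.0):
        def scorer(params):
            return ObjectiveResult(task="toy", score=score, components={},
                                   is_solution=True, threshold=1.0)
        return scorer

    def test_null_perturbation_fraction_is_one(self, base_model, nominal):
        rep = perturb_and_score(base_model, nominal, default_task_spec("hysteresis"),
                                n=20, sigma=0.0, rng=0,
                                scorer=self._const_scorer())
        assert rep.fraction == 1.0
        assert np.all(rep.records["K"] == 0.0)

    def test_constant_objective_fraction_is_one(self, base_model, nominal):
        rep = perturb_and_score(base_model, nominal, default_task_spec("hysteresis"),
                                n=50, sigma=0.5, rng=1,
                                scorer=self._const_scorer())
        assert rep.fraction == 1.0

    def test_seed_determinism(self, base_model, nominal):
        kw = dict(n=30, sigma=0.3, scorer=self._const_scorer())
        r1 = perturb_and_score(base_model, nominal,
                               default_task_spec("hysteresis"), rng=7, **kw)
        r2 = perturb_and_score(base_model, nominal,
                               default_task_spec("hysteresis"), rng=7, **kw)
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_zero_original_score_rejected(self, base_model, nominal):
        with pytest.raises(ContractError):
            perturb_and_score(base_model, nominal, default_task_spec("hysteresis"),
                              n=5, rng=0, scorer=self._const_scorer(0.0))

    def test_K_is_total_log10_variation(self, base_model, nominal):
        rep = perturb_and_score(base_model, nominal, default_task_spec("hysteresis"),
                                n=5, sigma=0.1, rng=3,
                                scorer=self._const_scorer())
        assert np.all(rep.records["K"] > 0)


class TestNotchInterval:
    def test_zero_iqr_collapses_interval(self):
        assert notch_interval([5, 5, 5, 5]) == (5.0, 5.0, 5.0)

    def test_hand_computation_one_to_nine(self):
        lo, med, hi = notch_interval(range(1, 10))
        assert med == 5.0
        assert lo == pytest.approx(5 - 1.57 * 4 / 3)
        assert hi == pytest.approx(5 + 1.57 * 4 / 3)

    @given(c=st.floats(-100, 100))
    @settings(max_examples=20, deadline=None)
    def test_translation_equivariance(self, c):
        vals = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        lo, med, hi = notch_interval(vals)
        lo2, med2, hi2 = notch_interval(vals + c)
        assert (lo2, med2, hi2) == pytest.approx((lo + c, med + c, hi + c))

    def test_overlap_helper(self):
        assert notches_overlap([1, 2, 3, 4, 5], [3, 4, 5, 6, 7])
        assert not notches_overlap([1, 1.1, 1.2, 1.3], [9, 9.1, 9.2, 9.3])

    def test_too_few_values_rejected(self):
        with pytest.raises(ContractError):
            notch_interval([1.0])


class TestAdjacency:
    def test_diagonal_convention(self, base_model, nominal):
        from nettension.search import IterationRecord, SolutionArchive
        res = ObjectiveResult(task="x", score=1.0, components={},
                              is_solution=True, threshold=1.0)
        arch = SolutionArchive(task="hysteresis", variant="base",
                               param_names=tuple(base_model.param_names))
        arch.records = [IterationRecord(0, 0, "solution", nominal, res, 0, 0)]
        table = adjacency([("hysteresis", "hysteresis")],
                          {"hysteresis": arch}, base_model)
        assert len(table) == 1
        assert table.loc[0, "tension_median"] == 0.0
        assert table.loc[0, "accessibility"] == 1.0

    def test_missing_archive_rejected(self, base_model):
        with pytest.raises(ContractError):
            adjacency([("hysteresis", "biphasic")], {}, base_model)

    def test_row_count_and_csv_round_trip(self, base_model, nominal, tmp_path):
        from nettension.search import IterationRecord, SolutionArchive
        res = ObjectiveResult(task="x", score=1.0, components={},
                              is_solution=True, threshold=1.0)
        archives = {}
        for t in ("hysteresis", "adaptation", "biphasic"):
            arch = SolutionArchive(task=t, variant="base",
                                   param_names=tuple(base_model.param_names))
            arch.records = [IterationRecord(0, 0, "solution", nominal, res, 0, 0)]
            archives[t] = arch
        pairs = [(a, a) for a in archives]      # diagonal only: cheap, 3 rows
        table = adjacency(pairs, archives, base_model)
        assert len(table) == 3
        path = tmp_path / "adj.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(
            back, table, check_dtype=False, check_exact=False, atol=1e-12)
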