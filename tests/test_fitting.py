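import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from zonpbpk.fitting import (
    FitParameter,
    FitProblem,
    PKDataset,
    concordance,
    fit,
    objective_log_sse,
    predict_cells,
    scan_functional_damage,
)
from zonpbpk.synthetic import PKGeneratorSpec, generate_pk_dataset


def _dataset_from_cells(cells: dict, replicates=1) -> PKDataset:
    rows = [
        {
            "compound": c,
            "site": s,
            "time_min": t,
            "replicate": r,
            "conc_umol_per_L": v,
        }
        for (c, s, t), v in cells.items()
        for r in range(replicates)
    ]
    return PKDataset(records=pd.DataFrame(rows))


class TestObjectiveLogSse:
    def test_perfect_fit_gives_zero(self):
        cells = {("a", "right_heart", 2.0): 1.3, ("a", "portal_vein", 15.0): 0.7}
        ds = _dataset_from_cells(cells)
        sim = pd.Series(cells)
        assert float(objective_log_sse(sim, ds)) == pytest.approx(0.0, abs=1e-15)

    def test_e_factor_cells_give_unit_contributions(self):
        cells = {("a", "right_heart", t): 1.0 for t in (2.0, 15.0, 30.0)}
        ds = _dataset_from_cells(cells)
        sim = pd.Series({k: math.e * v for k, v in cells.items()})
        assert float(objective_log_sse(sim, ds)) == pytest.approx(3.0, rel=1e-12)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(42)
        cells = {
            ("a", site, t): float(rng.uniform(0.1, 10))
            for site in ("right_heart", "portal_vein", "hepatic_vein")
            for t in (2.0, 15.0, 30.0, 60.0, 120.0)
        }
        ds = _dataset_from_cells(cells, replicates=3)
        sim = pd.Series({k: float(rng.uniform(0.1, 10)) for k in cells})
        expected = 0.0
        for key, xbar in cells.items():
            expected += math.log(sim[key] / xbar) ** 2
        assert float(objective_log_sse(sim, ds)) == pytest.approx(expected, rel=1e-12)

    def test_uses_replicate_means(self):
        rows = []
        for r, v in enumerate([1.0, 2.0, 3.0]):
            rows.append(
                {"compound": "a", "site": "right_heart", "time_min": 2.0,
                 "replicate": r, "conc_umol_per_L": v}
            )
        ds = PKDataset(records=pd.DataFrame(rows))
        sim = pd.Series({("a", "right_heart", 2.0): 2.0})  # mean of 1,2,3
        assert float(objective_log_sse(sim, ds)) == pytest.approx(0.0, abs=1e-15)

    def test_lloq_exclusion_reported(self):
        cells = {("a", "right_heart", 2.0): 0.01, ("a", "right_heart", 15.0): 5.0}
        ds = _dataset_from_cells(cells)
        ds.lloq = {"a": 0.1}
        sim = pd.Series({k: v for k, v in cells.items()})
        res = objective_log_sse(sim, ds)
        assert res.excluded == (("a", "right_heart", 2.0),)
        assert res.n_cells == 1

    def test_all_cells_excluded_raises(self):
        cells = {("a", "right_heart", 2.0): 0.01}
        ds = _dataset_from_cells(cells)
        ds.lloq = {"a": 1.0}
        with pytest.raises(ValueError, match="no usable data"):
            objective_log_sse(pd.Series(cells), ds)

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_unit_rescaling(self, factor):
        rng = np.random.default_rng(3)
        cells = {("a", "right_heart", t): float(rng.uniform(0.5, 5)) for t in range(1, 6)}
        sim = pd.Series({k: float(rng.uniform(0.5, 5)) for k in cells})
        ds1 = _dataset_from_cells(cells)
        ds2 = _dataset_from_cells({k: v * factor for k, v in cells.items()})
        e1 = float(objective_log_sse(sim, ds1))
        e2 = float(objective_log_sse(sim * factor, ds2))
        assert e1 == pytest.approx(e2, rel=1e-9)


class TestConcordance:
    def test_perfect_agreement(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert concordance(x, x) == pytest.approx(1.0)

    def test_location_shift_penalized_below_pearson(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(1, 5, size=20)
        sim = obs + 2.0
        r = float(np.corrcoef(sim, obs)[0, 1])
        assert concordance(sim, obs) < r

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=10)
        n = len(x)
        sxy = sum((a - x.mean()) * (b - y.mean()) for a, b in zip(x, y)) / n
        sx2 = sum((a - x.mean()) ** 2 for a in x) / n
        sy2 = sum((b - y.mean()) ** 2 for b in y) / n
        expected = 2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
        assert concordance(x, y) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            concordance([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestFit:
    def _problem(self, phys, caffeine_family, dataset, initial=0.2):
        return FitProblem(
            parameters=[
                FitParameter(
                    name="CL_cyp1a",
                    lower=0.01,
                    upper=5.0,
                    initial=initial,
                    target=("caffeine", "CYP1A", "rate"),
                )
            ],
            dataset=dataset,
            models=list(caffeine_family),
        )

    def test_zero_noise_recovery(self, phys, caffeine_family, cocktail):
        true_rate = cocktail["caffeine"].clearance("CYP1A").rate
        ds = generate_pk_dataset(
            PKGeneratorSpec(models=caffeine_family, physiology=phys, cv=0.0, seed=0)
        )
        res = fit(self._problem(phys, caffeine_family, ds), phys, n_starts=1)
        assert abs(res.estimates["CL_cyp1a"] - true_rate) / true_rate < 1e-3

    def test_descent_contract_and_diagnostics(self, phys, caffeine_family):
        ds = generate_pk_dataset(
            PKGeneratorSpec(models=caffeine_family, physiology=phys, cv=0.2, seed=5)
        )
        problem = self._problem(phys, caffeine_family, ds, initial=0.1)
        means = ds.cell_means()
        sim0 = predict_cells(phys, problem.apply([0.1]), list(means.index))
        e0 = float(objective_log_sse(sim0, ds))
        res = fit(problem, phys, n_starts=2, seed=11)
        assert res.objective <= e0 + 1e-12
        assert set(res.diagnostics.columns) >= {"pearson", "concordance"}
        assert ((res.diagnostics[["pearson", "concordance"]].abs() <= 1.0).all()).all()

    def test_seeded_reproducibility(self, phys, caffeine_family):
        ds = generate_pk_dataset(
            PKGeneratorSpec(models=caffeine_family, physiology=phys, cv=0.2, seed=5)
        )
        r1 = fit(self._problem(phys, caffeine_family, ds), phys, n_starts=3, seed=7)
        r2 = fit(self._problem(phys, caffeine_family, ds), phys, n_starts=3, seed=7)
        assert r1.estimates == r2.estimates
        assert r1.start_objectives == r2.start_objectives

    def test_noisy_recovery_median_within_15_percent(self, phys, caffeine_family, cocktail):
        """Monte-Carlo parameter recovery at the study's noise level."""
        true_rate = cocktail["caffeine"].clearance("CYP1A").rate
        errors = []
        for seed in range(20):
            ds = generate_pk_dataset(
                PKGeneratorSpec(models=caffeine_family, physiology=phys, cv=0.2, seed=seed)
            )
            res = fit(self._problem(phys, caffeine_family, ds), phys, n_starts=1, rtol=1e-6)
            errors.append(abs(res.estimates["CL_cyp1a"] - true_rate) / true_rate)
        assert float(np.median(errors)) <= 0.15


class TestScanFunctionalDamage:
    def test_healthy_data_recovers_zero(self, phys, caffeine_family):
        ds = generate_pk_dataset(
            PKGeneratorSpec(models=caffeine_family, physiology=phys, cv=0.0, seed=0)
        )
        scan = scan_functional_damage(
            phys, caffeine_family, ds, grid=np.arange(0, 1.0001, 0.05)
        )
        assert scan.fd_star == pytest.approx(0.0, abs=1e-3)

    def test_noiseless_closed_loop_recovers_090(self, phys, caffeine_family):
        ds = generate_pk_dataset(
            PKGeneratorSpec(models=caffeine_family, physiology=phys, cv=0.0, seed=0),
            damage=0.9,
        )
        scan = scan_functional_damage(
            phys, caffeine_family, ds, grid=np.arange(0, 1.0001, 0.01)
        )
        assert scan.fd_star == pytest.approx(0.90, abs=1e-3)
        # profile is minimal at the optimum by construction
        assert scan.objective_at_optimum <= scan.error_profile.min() + 1e-12

    def test_recovery_is_monotone_in_true_damage(self, phys, caffeine_family):
        recovered = []
        for f in (0.0, 0.3, 0.6, 0.9):
            ds = generate_pk_dataset(
                PKGeneratorSpec(models=caffeine_family, physiology=phys, cv=0.0, seed=2),
                damage=f,
            )
            scan = scan_functional_damage(
                phys, caffeine_family, ds, grid=np.arange(0, 1.0001, 0.05)
            )
            recovered.append(scan.fd_star)
        assert recovered == sorted(recovered)

    def test_empty_grid_rejected(self, phys, caffeine_family):
        ds = generate_pk_dataset(
            PKGeneratorSpec(models=caffeine_family, physiology=phys, cv=0.0, seed=0)
        )
        with pytest.raises(ValueError, match="empty"):
            scan_functional_damage(phys, caffeine_family, ds, grid=[])
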