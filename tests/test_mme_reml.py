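import numpy as np
import pandas as pd
import pytest
from scipy import optimize, sparse

from ssblup.mme_reml import (
    DesignError,
    MixedModelSystem,
    ModelSpec,
    ai_reml,
    build_design,
    heritability,
    reml_loglik,
    solve_blup,
)
from ssblup.pedigree import a_inverse, a_logdet, a_matrix
from ssblup.simpop import SimConfig, simulate_population
from ssblup import crosscov


def make_system(pop, model="M1", **spec_kw):
    ped = pop["pedigree"]
    k_inv = a_inverse(ped)
    return build_design(
        pop["phenotypes"],
        ModelSpec(model_id=model, **spec_kw),
        pop["covariates"],
        pop["composition"],
        ped,
        k_inv,
        a_logdet(ped),
    )


@pytest.fixture(scope="module")
def tiny_pop():
    cfg = SimConfig(
        n_founders_per_type=(6, 6, 6, 6),
        n_generations=2,
        n_matings_per_gen=28,
        n_snps=10,
        n_cg=2,
        cg_effect_sd=1.0,
        true_sigma_u2=1.0,
        true_sigma_e2=1.0,
        seed=31,
    )
    return simulate_population(cfg)


def dense_reml(theta, sys, A):
    su2, se2 = theta
    Zd = sys.Z.toarray()
    V = su2 * Zd @ A @ Zd.T + se2 * np.eye(sys.n)
    Vi = np.linalg.inv(V)
    XVX = sys.X.T @ Vi @ sys.X
    P = Vi - Vi @ sys.X @ np.linalg.solve(XVX, sys.X.T @ Vi)
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XVX)
    return -0.5 * (ldV + ldX + sys.y @ P @ sys.y)


class TestBuildDesign:
    def _phen(self, pop, cg_sizes):
        ped = pop["pedigree"]
        n = sum(cg_sizes)
        phen = pop["phenotypes"].iloc[:n].copy()
        labels = np.repeat([f"g{i}" for i in range(len(cg_sizes))], cg_sizes)
        phen["cg"] = labels
        return phen

    def test_cg_filter_counts(self, tiny_pop):
        phen = self._phen(tiny_pop, [12, 10, 9])
        ped = tiny_pop["pedigree"]
        sys = build_design(
            phen, ModelSpec("M1"), tiny_pop["covariates"],
            tiny_pop["composition"], ped, a_inverse(ped), a_logdet(ped),
        )
        assert sys.n == 22
        assert not any("g2" in str(c) for c in sys.records["cg"].unique())

    def test_m1_has_no_cross_columns(self, tiny_pop):
        sys = make_system(tiny_pop)
        assert not any(
            lab.startswith(("frac_", "het", "rec")) for lab in sys.x_labels
        )

    def test_m5_has_specific_columns(self, small_pop):
        sys = make_system(small_pop, model="M5")
        assert sum(lab.startswith("het_") for lab in sys.x_labels) >= 4
        assert sum(lab.startswith("rec_") for lab in sys.x_labels) >= 4
        assert "het" not in sys.x_labels  # combined terms absent from M5
        assert "rec" not in sys.x_labels
        assert "frac_A" not in sys.x_labels  # dropped for identifiability

    def test_empty_after_filter(self, tiny_pop):
        phen = self._phen(tiny_pop, [4, 5])
        ped = tiny_pop["pedigree"]
        with pytest.raises(DesignError, match="contemporary-group"):
            build_design(
                phen, ModelSpec("M1"), tiny_pop["covariates"],
                tiny_pop["composition"], ped, a_inverse(ped), a_logdet(ped),
            )

    def test_rank_deficiency_reported(self, tiny_pop):
        ped = tiny_pop["pedigree"]
        cov = tiny_pop["covariates"].copy()
        cov["rec"] = cov["het"]  # duplicate covariate -> aliased column
        with pytest.raises(DesignError, match="rec|het"):
            build_design(
                tiny_pop["phenotypes"], ModelSpec("M3", cg_min_records=5), cov,
                tiny_pop["composition"], ped, a_inverse(ped), a_logdet(ped),
            )

    def test_constant_covariate_dropped(self, tiny_pop):
        ped = tiny_pop["pedigree"]
        phen = tiny_pop["phenotypes"].copy()
        phen["cow_age"] = 5.0  # constant -> centred column of zeros -> dropped
        sys = build_design(
            phen, ModelSpec("M1", cg_min_records=5), tiny_pop["covariates"],
            tiny_pop["composition"], ped, a_inverse(ped), a_logdet(ped),
        )
        assert "cow_age" not in sys.x_labels


class TestRemlLoglik:
    def test_matches_dense_formula(self, tiny_pop):
        sys = make_system(tiny_pop, cg_min_records=5)
        A = a_matrix(tiny_pop["pedigree"])
        for theta in [(0.5, 1.5), (1.0, 1.0), (2.0, 0.4)]:
            assert reml_loglik(theta, sys) == pytest.approx(
                dense_reml(theta, sys, A), abs=1e-8
            )

    def test_invariant_to_x_reparameterisation(self, tiny_pop):
        sys = make_system(tiny_pop, cg_min_records=5)
        rng = np.random.default_rng(0)
        T = rng.normal(size=(sys.p, sys.p)) + 3 * np.eye(sys.p)
        sys2 = MixedModelSystem(
            y=sys.y, X=sys.X @ T, Z=sys.Z, k_inv=sys.k_inv,
            logdet_k=sys.logdet_k, x_labels=sys.x_labels,
            animal_index=sys.animal_index,
        )
        # invariant up to a theta-independent constant (log|det T|): likelihood
        # differences, and hence the REML maximiser, are unchanged
        shift = reml_loglik((0.7, 1.3), sys) - reml_loglik((0.7, 1.3), sys2)
        for theta in [(0.3, 2.0), (1.5, 0.9)]:
            assert reml_loglik(theta, sys) - reml_loglik(theta, sys2) == pytest.approx(
                shift, abs=1e-7
            )
        _, ldt = np.linalg.slogdet(T)
        assert shift == pytest.approx(ldt, abs=1e-7)

    def test_scaling_law(self, tiny_pop):
        sys = make_system(tiny_pop, cg_min_records=5)
        c = 3.0
        sys_scaled = MixedModelSystem(
            y=c * sys.y, X=sys.X, Z=sys.Z, k_inv=sys.k_inv,
            logdet_k=sys.logdet_k, x_labels=sys.x_labels,
            animal_index=sys.animal_index,
        )
        lnl = reml_loglik((0.6, 1.1), sys)
        lnl_scaled = reml_loglik((0.6 * c**2, 1.1 * c**2), sys_scaled)
        assert lnl_scaled - lnl == pytest.approx(-(sys.n - sys.p) * np.log(c), abs=1e-7)

    def test_rejects_nonpositive(self, tiny_pop):
        sys = make_system(tiny_pop, cg_min_records=5)
        with pytest.raises(ValueError):
            reml_loglik((0.0, 1.0), sys)


class TestAiReml:
    def test_matches_derivative_free_oracle(self, tiny_pop):
        sys = make_system(tiny_pop, cg_min_records=5)
        vf = ai_reml(sys)
        assert vf.converged
        # coarse grid start + Nelder-Mead refinement, independent of AI path
        grid = [
            (su, se)
            for su in np.linspace(0.05, 3.0, 12)
            for se in np.linspace(0.05, 3.0, 12)
        ]
        start = max(grid, key=lambda t: reml_loglik(t, sys))
        res = optimize.minimize(
            lambda t: -reml_loglik(np.exp(t), sys),
            np.log(start),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        oracle = np.exp(res.x)
        assert vf.sigma_u2 == pytest.approx(oracle[0], abs=1e-4)
        assert vf.sigma_e2 == pytest.approx(oracle[1], abs=1e-4)

    def test_local_grid_optimality(self, tiny_pop):
        sys = make_system(tiny_pop, cg_min_records=5)
        vf = ai_reml(sys)
        best = reml_loglik((vf.sigma_u2, vf.sigma_e2), sys)
        for fu in (0.8, 1.0, 1.2):
            for fe in (0.8, 1.0, 1.2):
                if fu == fe == 1.0:
                    continue
                assert reml_loglik((vf.sigma_u2 * fu, vf.sigma_e2 * fe), sys) <= best + 1e-9

    def test_zero_genetic_variance_flagged(self):
        cfg = SimConfig(
            n_founders_per_type=(8, 8, 8, 8),
            n_generations=2,
            n_matings_per_gen=250,
            true_sigma_u2=0.0,
            true_sigma_e2=1.0,
            n_cg=1,
            cg_effect_sd=0.0,
            n_snps=5,
            seed=55,
        )
        pop = simulate_population(cfg)
        sys = make_system(pop)
        vf = ai_reml(sys)
        assert vf.boundary
        assert vf.sigma_u2 < 1e-4

    def test_h_without_genotypes_equals_a_fit(self, tiny_pop):
        from ssblup.genomic import HStructure, h_inverse

        sys_a = make_system(tiny_pop, cg_min_records=5)
        hs = HStructure(
            sys_a.k_inv, np.empty((0, 0)), np.empty((0, 0)),
            np.array([], dtype=np.int64),
        )
        sys_h = MixedModelSystem(
            y=sys_a.y, X=sys_a.X, Z=sys_a.Z, k_inv=h_inverse(hs),
            logdet_k=sys_a.logdet_k, x_labels=sys_a.x_labels,
            animal_index=sys_a.animal_index,
        )
        va = ai_reml(sys_a)
        vh = ai_reml(sys_h)
        assert vh.sigma_u2 == pytest.approx(va.sigma_u2, abs=1e-10)
        assert vh.sigma_e2 == pytest.approx(va.sigma_e2, abs=1e-10)

    def test_recovers_fixed_cross_effects(self):
        cfg = SimConfig(
            n_founders_per_type=(22, 50, 24, 9),
            n_generations=4,
            n_matings_per_gen=200,
            het_effect=2.0,
            recomb_effect=-1.5,
            breed_type_effects=(1.0, 0.0, -0.5, 0.5),
            n_cg=2,
            cg_effect_sd=0.5,
            true_sigma_u2=0.5,
            true_sigma_e2=1.0,
            n_snps=5,
            seed=101,
        )
        pop = simulate_population(cfg)
        sys = make_system(pop, model="M3")
        vf = ai_reml(sys)
        sol = solve_blup(sys, vf)
        # fixed-effect covariance = sigma_e2 * X-block of the MME inverse
        M = sys.mme_matrix(vf.sigma_e2 / vf.sigma_u2).toarray()
        Cxx = np.linalg.inv(M)[: sys.p, : sys.p] * vf.sigma_e2
        fe = sol.fixed_effects()
        for name, truth in [("het", 2.0), ("rec", -1.5)]:
            se = np.sqrt(Cxx[sys.x_labels.index(name), sys.x_labels.index(name)])
            assert abs(fe[name] - truth) < 3 * se


class TestSolveBlup:
    def test_shrinkage_limit(self, tiny_pop):
        sys = make_system(tiny_pop, cg_min_records=5)
        sol = solve_blup(sys, (1e-8, 1.0))
        assert np.max(np.abs(sol.u)) < 1e-4

    def test_dense_gls_oracle(self, tiny_pop):
        sys = make_system(tiny_pop, cg_min_records=5)
        A = a_matrix(tiny_pop["pedigree"])
        su2, se2 = 0.8, 1.4
        sol = solve_blup(sys, (su2, se2))
        Zd = sys.Z.toarray()
        V = su2 * Zd @ A @ Zd.T + se2 * np.eye(sys.n)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(sys.X.T @ Vi @ sys.X, sys.X.T @ Vi @ sys.y)
        u = su2 * A @ Zd.T @ Vi @ (sys.y - sys.X @ beta)
        assert np.max(np.abs(sol.beta - beta)) < 1e-8
        assert np.max(np.abs(sol.u - u)) < 1e-8

    def test_parent_average_identity(self, tiny_pop):
        # an animal with no record and no progeny gets the parent average
        ped = tiny_pop["pedigree"]
        phen = tiny_pop["phenotypes"]
        off = [i for i in range(ped.n) if not ped.is_founder[i]]
        leaves = set(off) - set(ped.sire) - set(ped.dam)
        drop = ped.ids[max(leaves)]
        phen2 = phen[phen["animal"] != drop].reset_index(drop=True)
        sys = build_design(
            phen2, ModelSpec("M1", cg_min_records=0), tiny_pop["covariates"],
            tiny_pop["composition"], ped, a_inverse(ped), a_logdet(ped),
        )
        sol = solve_blup(sys, (0.9, 1.1))
        i = ped.index_of(drop)
        pa = 0.5 * (sol.u[ped.sire[i]] + sol.u[ped.dam[i]])
        assert sol.u[i] == pytest.approx(pa, abs=1e-10)

    def test_rejects_bad_variances(self, tiny_pop):
        sys = make_system(tiny_pop, cg_min_records=5)
        with pytest.raises(ValueError):
            solve_blup(sys, (0.0, 1.0))


class TestHeritability:
    @pytest.mark.parametrize(
        "su2,se2,expected",
        [(13.151, 48.142, 0.215), (1.0, 1.0, 0.5), (0.237, 0.329, 0.419)],
    )
    def test_values(self, su2, se2, expected):
        h2, _ = heritability(su2, se2)
        assert round(h2, 3) == expected

    def test_zero_total(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0)

    def test_delta_method_se(self):
        h2, se = heritability(1.0, 1.0, np.eye(2) * 0.01)
        # grad = (0.25, -0.25); var = 0.01 * 2 * 0.0625
        assert se == pytest.approx(np.sqrt(0.01 * 2 * 0.0625))
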