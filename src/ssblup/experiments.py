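"""Canned replicate studies used by the acceptance checks.

Each study simulates fresh populations from seeded configs and recomputes
its statistic from scratch through the package's own pipeline: simulation,
covariates, relationship inverses, (optionally) AI-REML, BLUP solutions and
LR-method validation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import lr_validation as lrv
from .mme_reml import ModelSpec, ai_reml, build_design
from .model_compare import aic
from .pedigree import a_inverse, a_logdet
from .simpop import SimConfig, simulate_population

__all__ = [
    "lr_null_study",
    "recovery_study",
    "directional_study",
    "NULL_SIGMA_U2",
    "NULL_SIGMA_E2",
    "RECOVERY_SIGMA_U2",
    "RECOVERY_SIGMA_E2",
]

# null-calibration truth: h2 = 0.2
NULL_SIGMA_U2 = 0.4
NULL_SIGMA_E2 = 1.6

# recovery truth: h2 ~ 0.18 (emulated variance components of a fat trait)
RECOVERY_SIGMA_U2 = 0.425
RECOVERY_SIGMA_E2 = 1.937


def _null_config(seed: int, sigma_u2: float, sigma_e2: float) -> SimConfig:
    """~2,900-animal, 5-generation population with a ~300-animal last cohort."""
    return SimConfig(
        n_founders_per_type=(44, 100, 48, 18),
        n_generations=5,
        n_matings_per_gen=(600, 600, 600, 600, 300),
        n_snps=5,  # genotypes unused in pedigree-only studies
        n_cg=3,
        cg_effect_sd=0.5,
        true_sigma_u2=sigma_u2,
        true_sigma_e2=sigma_e2,
        seed=seed,
    )


def lr_null_study(
    n_reps: int = 30,
    base_seed: int = 0,
    sigma_u2: float = NULL_SIGMA_U2,
    sigma_e2: float = NULL_SIGMA_E2,
) -> pd.DataFrame:
    """Dispersion/bias/accuracy of a correctly specified model at true VCs.

    Each replicate simulates a population, splits off the youngest cohort,
    solves partial and whole M1 systems at the true variance components and
    computes the LR statistics.  Expected values: b = 1, mu = 0.
    """
    rows = []
    for r in range(n_reps):
        cfg = _null_config(base_seed + 1000 * r + 1, sigma_u2, sigma_e2)
        pop = simulate_population(cfg)
        ped = pop["pedigree"]
        k_inv, ld = a_inverse(ped), a_logdet(ped)
        split = lrv.forward_split(pop["phenotypes"], ped, last_k_years=1)
        stats = lrv.run_validation(
            split, ModelSpec("M1"), ped, pop["composition"],
            pop["covariates"], k_inv, ld, sigma_u2, sigma_e2,
        )
        rows.append(
            {"seed": cfg.seed, "b": stats.b, "mu": stats.mu,
             "rho": stats.rho, "n_validation": stats.n_validation}
        )
    return pd.DataFrame(rows)


def recovery_study(
    n_reps: int = 30,
    base_seed: int = 0,
    sigma_u2: float = RECOVERY_SIGMA_U2,
    sigma_e2: float = RECOVERY_SIGMA_E2,
) -> pd.DataFrame:
    """AI-REML parameter recovery at n ~ 3,000 records per replicate."""
    rows = []
    for r in range(n_reps):
        cfg = _null_config(base_seed + 1000 * r + 7, sigma_u2, sigma_e2)
        pop = simulate_population(cfg)
        ped = pop["pedigree"]
        sys = build_design(
            pop["phenotypes"], ModelSpec("M1"), pop["covariates"],
            pop["composition"], ped, a_inverse(ped), a_logdet(ped),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vf = ai_reml(sys)
        rows.append(
            {"seed": cfg.seed, "sigma_u2": vf.sigma_u2, "sigma_e2": vf.sigma_e2,
             "h2": vf.h2, "converged": vf.converged, "n": vf.n_records}
        )
    return pd.DataFrame(rows)


def directional_study(n_reps: int = 30, base_seed: int = 0) -> pd.DataFrame:
    """Model fit vs predictive ability on heterosis-laden simulations.

    Fits M1, M3 and M5 by AI-REML on data generated with nonzero breed-type,
    heterosis and recombination effects; compares AIC (M3 vs M1) and the LR
    accuracy of M1 vs M5 fits, each validated at its own estimates.
    """
    rows = []
    for r in range(n_reps):
        cfg = SimConfig(
            seed=base_seed + 1000 * r + 13,
            n_generations=5,
            het_effect=1.5,
            recomb_effect=-1.0,
            breed_type_effects=(0.8, 0.0, -0.4, 0.4),
            n_cg=3,
            cg_effect_sd=1.0,
            true_sigma_u2=0.425,
            true_sigma_e2=1.937,
            n_snps=5,
        )
        pop = simulate_population(cfg)
        ped = pop["pedigree"]
        k_inv, ld = a_inverse(ped), a_logdet(ped)
        fits = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for m in ("M1", "M3", "M5"):
                sys = build_design(
                    pop["phenotypes"], ModelSpec(m), pop["covariates"],
                    pop["composition"], ped, k_inv, ld,
                )
                fits[m] = ai_reml(sys)
            split = lrv.forward_split(pop["phenotypes"], ped, last_k_years=1)
            rho = {}
            for m in ("M1", "M5"):
                stats = lrv.run_validation(
                    split, ModelSpec(m), ped, pop["composition"],
                    pop["covariates"], k_inv, ld,
                    fits[m].sigma_u2, fits[m].sigma_e2,
                )
                rho[m] = stats.rho
        rows.append(
            {
                "seed": cfg.seed,
                "aic_m1": aic(fits["M1"].loglik, 2),
                "aic_m3": aic(fits["M3"].loglik, 2),
                "rho_m1": rho["M1"],
                "rho_m5": rho["M5"],
            }
        )
    return pd.DataFrame(rows)
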