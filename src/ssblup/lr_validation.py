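"""Forward-validation split and LR-method statistics (accuracy, dispersion, bias).

The LR method compares breeding values predicted from a partial dataset
(the phenotypes of a young validation cohort removed) with those from the
whole dataset.  Accuracy is the square root of cov(u_w, u_p) scaled by the
available genetic variance (1 - mean F) sigma_u2; dispersion is the
regression of whole on partial predictions (expected 1); bias is the mean
difference standardised by the genetic standard deviation (expected 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .mme_reml import ModelSpec, build_design, solve_blup
from .pedigree import BreedComposition, Pedigree

__all__ = [
    "ValidationSplit",
    "LRStats",
    "forward_split",
    "lr_accuracy",
    "lr_dispersion",
    "lr_bias",
    "run_validation",
]


@dataclass
class ValidationSplit:
    whole: pd.DataFrame
    partial: pd.DataFrame
    validation_ids: list
    f_bar: float  # mean inbreeding of the validation animals


@dataclass
class LRStats:
    rho: float
    b: float
    mu: float
    n_validation: int


def forward_split(
    phen: pd.DataFrame,
    ped: Pedigree,
    last_k_years: int = 2,
    require_genotype: bool = False,
    genotyped_ids=None,
) -> ValidationSplit:
    """Split phenotypes into whole / partial sets for forward validation.

    Validation animals are phenotyped, born in the last ``last_k_years``
    birth years, without progeny in the pedigree, and genotyped when
    ``require_genotype`` is set.  Their phenotype rows are removed from the
    partial set.
    """
    years = phen["birth_year"].to_numpy()
    cutoff = years.max() - (last_k_years - 1)
    has_progeny = np.zeros(ped.n, dtype=bool)
    has_progeny[ped.sire[ped.sire >= 0]] = True
    has_progeny[ped.dam[ped.dam >= 0]] = True

    idx = ped.indices_of(phen["animal"])
    is_val = (years >= cutoff) & ~has_progeny[idx]
    if require_genotype:
        if genotyped_ids is None:
            raise ValueError("require_genotype needs the genotyped id list")
        gset = set(genotyped_ids)
        is_val &= phen["animal"].isin(gset).to_numpy()
    val_ids = list(phen.loc[is_val, "animal"])
    if not val_ids:
        raise ValueError("empty validation set")
    partial = phen.loc[~is_val].reset_index(drop=True)
    if partial.empty:
        raise ValueError("partial set has no phenotypes left")
    f_bar = float(ped.F[ped.indices_of(val_ids)].mean())
    return ValidationSplit(
        whole=phen.reset_index(drop=True),
        partial=partial,
        validation_ids=val_ids,
        f_bar=f_bar,
    )


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.cov(a, b, ddof=1)[0, 1])


def lr_accuracy(u_p, u_w, f_bar: float, sigma_u2: float) -> float:
    """Accuracy: sqrt( cov(u_w, u_p) / ((1 - F_bar) sigma_u2) ).

    A negative covariance makes the ratio undefined and is mapped to 0 with
    a warning.
    """
    u_p = np.asarray(u_p, dtype=float)
    u_w = np.asarray(u_w, dtype=float)
    if u_p.size == 0 or u_p.size != u_w.size:
        raise ValueError("prediction vectors must be aligned and non-empty")
    if sigma_u2 <= 0:
        raise ValueError("sigma_u2 must be positive")
    if not 0.0 <= f_bar < 1.0:
        raise ValueError("F_bar must be in [0, 1)")
    c = _cov(u_w, u_p)
    if c < 0:
        warnings.warn("negative cov(u_w, u_p); accuracy set to 0", RuntimeWarning)
        return 0.0
    return float(np.sqrt(c / ((1.0 - f_bar) * sigma_u2)))


def lr_dispersion(u_p, u_w) -> float:
    """Dispersion: regression of whole on partial, cov(u_w, u_p) / var(u_p)."""
    u_p = np.asarray(u_p, dtype=float)
    u_w = np.asarray(u_w, dtype=float)
    v = float(np.var(u_p, ddof=1))
    if v <= 0:
        raise ValueError("var(u_p) must be positive")
    return _cov(u_w, u_p) / v


def lr_bias(u_p, u_w, sigma_u2: float, standardise: str = "sd") -> float:
    """Bias: (mean(u_p) - mean(u_w)) / sqrt(sigma_u2).

    ``standardise='var'`` divides by sigma_u2 itself (the literal printed
    form) instead of the standard deviation.
    """
    if sigma_u2 <= 0:
        raise ValueError("sigma_u2 must be positive")
    diff = float(np.mean(u_p) - np.mean(u_w))
    if standardise == "sd":
        return diff / float(np.sqrt(sigma_u2))
    if standardise == "var":
        return diff / float(sigma_u2)
    raise ValueError(f"unknown standardisation {standardise!r}")


def run_validation(
    split: ValidationSplit,
    spec: ModelSpec,
    ped: Pedigree,
    comp: BreedComposition,
    cov: pd.DataFrame,
    k_inv: sparse.spmatrix,
    logdet_k: float,
    sigma_u2: float,
    sigma_e2: float,
) -> LRStats:
    """Fit whole and partial systems at fixed variance components.

    The contemporary-group filter is applied once, on the whole data; the
    partial system is the whole system with the validation records removed
    (no re-filtering), so both fits see the same fixed-effect structure.
    """
    sys_w = build_design(split.whole, spec, cov, comp, ped, k_inv, logdet_k)
    kept = sys_w.records
    partial_animals = set(split.partial["animal"])
    partial_df = kept[kept["animal"].isin(partial_animals)].reset_index(drop=True)
    spec_p = ModelSpec(
        model_id=spec.model_id,
        relationship=spec.relationship,
        age_us_as_class=spec.age_us_as_class,
        age_us_bin_days=spec.age_us_bin_days,
        cg_min_records=0,
    )
    sys_p = build_design(partial_df, spec_p, cov, comp, ped, k_inv, logdet_k)

    sol_w = solve_blup(sys_w, (sigma_u2, sigma_e2))
    sol_p = solve_blup(sys_p, (sigma_u2, sigma_e2))

    vidx = ped.indices_of([a for a in split.validation_ids
                           if a in set(kept["animal"])])
    u_w = sol_w.u[vidx]
    u_p = sol_p.u[vidx]
    return LRStats(
        rho=lr_accuracy(u_p, u_w, split.f_bar, sigma_u2),
        b=lr_dispersion(u_p, u_w),
        mu=lr_bias(u_p, u_w, sigma_u2),
        n_validation=int(vidx.size),
    )
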