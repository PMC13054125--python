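"""Synthetic composite-cattle population generator.

Produces a multi-generation four-type composite pedigree with breed
fractions, gene-dropped unlinked SNP genotypes, and phenotypes generated
under the full fixed + additive-genetic + residual model, together with the
true underlying values needed for parameter-recovery and validation tests.

Everything is deterministic given ``SimConfig.seed``: each operation draws
from its own stream spawned from the seed, so re-running any stage with the
same config reproduces its output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import crosscov
from .genomic import GenotypeMatrix, MISSING
from .pedigree import (
    BREED_TYPES,
    BreedComposition,
    Pedigree,
    mendelian_variances,
    write_pedigree_csv,
)

__all__ = [
    "SimConfig",
    "TrueValues",
    "simulate_pedigree",
    "drop_genotypes",
    "simulate_phenotypes",
    "selective_genotyping",
    "simulate_population",
    "write_phenotypes_csv",
    "write_truth_csv",
]

# stream labels for per-operation deterministic RNGs
_STREAMS = {"pedigree": 1, "genotypes": 2, "phenotypes": 3, "genotyping": 4}


@dataclass
class SimConfig:
    """Configuration for the synthetic composite population.

    ``n_founders_per_type`` may be a single count (all four types) or a
    4-sequence; the default weights mimic mean composite fractions of
    roughly (0.22, 0.50, 0.24, 0.09) over (N, A, B, C).
    """

    n_founders_per_type: tuple = (44, 100, 48, 18)
    n_generations: int = 5
    offspring_per_mating: int = 1
    n_matings_per_gen: object = None  # int, per-generation sequence, or None (= founder total)
    n_sires_per_gen: int = 25
    mating_scheme: str = "random"  # or "cross_types"
    base_birth_year: int = 2017

    n_snps: int = 1000
    founder_allele_freq_spec: dict | None = None  # type -> (low, high)
    missing_rate: float = 0.0

    mean: float = 0.0
    true_sigma_u2: float = 0.425
    true_sigma_e2: float = 1.937
    breed_type_effects: tuple = (0.0, 0.0, 0.0, 0.0)
    het_effect: float = 0.0
    recomb_effect: float = 0.0
    n_cg: int = 4  # contemporary groups per generation
    cg_effect_sd: float = 0.5
    et_rate: float = 0.05
    et_effect: float = 0.0
    age_us_range: tuple = (480, 660)  # days
    age_us_slope: float = 0.0
    cow_age_range: tuple = (2.0, 12.0)  # years
    beta1: float = 0.0
    beta2: float = 0.0

    genotyping_fraction: float = 0.1
    selective_genotyping: bool = True
    genotyping_recent_years: int = 3

    seed: int = 0

    def __post_init__(self):
        if isinstance(self.n_founders_per_type, (int, np.integer)):
            self.n_founders_per_type = (int(self.n_founders_per_type),) * 4
        self.n_founders_per_type = tuple(int(c) for c in self.n_founders_per_type)
        self.breed_type_effects = tuple(float(b) for b in self.breed_type_effects)
        self.validate()

    def validate(self) -> None:
        if len(self.n_founders_per_type) != 4 or any(c < 0 for c in self.n_founders_per_type):
            raise ValueError("n_founders_per_type must be 4 non-negative counts")
        if sum(self.n_founders_per_type) < 2:
            raise ValueError("need at least 2 founders")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.offspring_per_mating < 1:
            raise ValueError("offspring_per_mating must be >= 1")
        if self.true_sigma_u2 < 0 or self.true_sigma_e2 < 0:
            raise ValueError("variances must be non-negative")
        if not 0.0 < self.genotyping_fraction <= 1.0:
            raise ValueError("genotyping_fraction must be in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mating_scheme not in ("random", "cross_types"):
            raise ValueError(f"unknown mating scheme {self.mating_scheme!r}")
        if self.founder_allele_freq_spec is not None:
            for t, (lo, hi) in self.founder_allele_freq_spec.items():
                if t not in BREED_TYPES:
                    raise ValueError(f"unknown breed type {t!r}")
                if not (0.0 < lo <= hi <= 1.0):
                    raise ValueError("allele frequency bounds must lie in (0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TrueValues:
    """True generative components, aligned with the pedigree index."""

    u: np.ndarray           # true breeding values
    e: np.ndarray           # residuals
    fixed_part: np.ndarray  # everything except u and e

    def as_frame(self, ped: Pedigree) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": ped.ids, "u": self.u, "e": self.e, "fixed_part": self.fixed_part}
        )


def _gen_sizes(config: SimConfig) -> list:
    base = sum(config.n_founders_per_type)
    m = config.n_matings_per_gen
    if m is None:
        m = base
    if isinstance(m, (int, np.integer)):
        sizes = [int(m)] * config.n_generations
    else:
        sizes = [int(x) for x in m]
        if len(sizes) != config.n_generations:
            raise ValueError("n_matings_per_gen sequence must match n_generations")
    return sizes


def simulate_pedigree(config: SimConfig):
    """Simulate the pedigree and breed composition.

    Founders are purebred per type.  Each later generation draws a limited
    sire team and dams from the two preceding generations; under the
    ``cross_types`` scheme each dam is mated to the available sire whose
    composition maximises expected offspring heterozygosity, which forces
    crossing (all F1s from a two-pure-type base are exactly half and half).

    Returns (Pedigree, BreedComposition).
    """
    rng = config.rng("pedigree")
    counts = config.n_founders_per_type
    n_founders = sum(counts)

    ids, sire, dam, year, sex, gen = [], [], [], [], [], []
    frac = []
    for t, c in zip(BREED_TYPES, counts):
        v = np.zeros(4)
        v[BREED_TYPES.index(t)] = 1.0
        for k in range(c):
            ids.append(f"{t}{k + 1:04d}")
            sire.append(-1)
            dam.append(-1)
            year.append(config.base_birth_year)
            sex.append(k % 2)  # 0 = male, 1 = female
            gen.append(0)
            frac.append(v)
    if not any(s == 0 for s in sex) or not any(s == 1 for s in sex):
        raise ValueError("degenerate config: need both male and female founders")

    sizes = _gen_sizes(config)
    serial = 0
    for g in range(1, config.n_generations + 1):
        pool = [i for i in range(len(ids)) if gen[i] >= g - 2 and gen[i] < g]
        males = [i for i in pool if sex[i] == 0]
        females = [i for i in pool if sex[i] == 1]
        if not males or not females:
            raise ValueError(f"degenerate config: no available parents at generation {g}")
        team = rng.choice(males, size=min(config.n_sires_per_gen, len(males)),
                          replace=False)
        team_frac = np.array([frac[i] for i in team])
        n_mat = sizes[g - 1]
        dams = rng.choice(females, size=n_mat, replace=len(females) < n_mat)
        for d in dams:
            if config.mating_scheme == "cross_types":
                het = 1.0 - team_frac @ frac[d]
                best = np.flatnonzero(het >= het.max() - 1e-12)
                s = int(team[best[rng.integers(len(best))]])
            else:
                s = int(team[rng.integers(len(team))])
            for _ in range(config.offspring_per_mating):
                serial += 1
                ids.append(f"X{serial:06d}")
                sire.append(s)
                dam.append(int(d))
                year.append(config.base_birth_year + g)
                sex.append(int(rng.integers(2)))
                gen.append(g)
                frac.append(0.5 * (frac[s] + frac[d]))

    ped = Pedigree(ids, np.array(sire), np.array(dam), np.array(year))
    n = ped.n
    fr = np.array(frac)
    sf = np.zeros((n, 4))
    df_ = np.zeros((n, 4))
    both = ped.sire >= 0
    sf[both] = fr[ped.sire[both]]
    df_[both] = fr[ped.dam[both]]
    comp = BreedComposition(fr, sf, df_, both)
    return ped, comp


def _founder_freqs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(4, n_snps) per-type allele frequencies."""
    spec = config.founder_allele_freq_spec or {}
    out = np.empty((4, config.n_snps))
    for k, t in enumerate(BREED_TYPES):
        lo, hi = spec.get(t, (0.05, 0.95))
        out[k] = lo if lo == hi else rng.uniform(lo, hi, size=config.n_snps)
    return out


def drop_genotypes(
    ped: Pedigree, comp: BreedComposition, config: SimConfig
) -> GenotypeMatrix:
    """Gene-drop unlinked SNPs through the pedigree.

    Founder genotypes are binomial draws at type-specific frequencies (a
    mixed-composition founder uses its composition-weighted frequency);
    each descendant receives one Mendelian-sampled allele per parent per
    locus.  Missing codes (5) are injected at ``missing_rate``.
    """
    rng = config.rng("genotypes")
    freqs = _founder_freqs(config, rng)
    n, m = ped.n, config.n_snps
    codes = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            p = comp.fractions[i] @ freqs
            codes[i] = rng.binomial(2, p).astype(np.int8)
        else:
            # transmitting Bernoulli(g/2) per locus is exact for unlinked loci
            gs = codes[s] if s >= 0 else rng.binomial(2, comp.fractions[i] @ freqs)
            gd = codes[d] if d >= 0 else rng.binomial(2, comp.fractions[i] @ freqs)
            codes[i] = (
                rng.random(m) < gs / 2.0
            ).astype(np.int8) + (rng.random(m) < gd / 2.0).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes[mask] = MISSING
    return GenotypeMatrix(list(ped.ids), codes)


def simulate_phenotypes(
    ped: Pedigree,
    comp: BreedComposition,
    cov: pd.DataFrame,
    config: SimConfig,
):
    """Simulate phenotypes for every animal under the full generative model.

    Breeding values follow the pedigree exactly: founders are N(0, sigma_u2)
    and each non-founder is the parent average plus a Mendelian deviation
    with variance (1/2)(1 - (F_s + F_d)/2) sigma_u2, so simulated u has
    covariance A sigma_u2.

    Returns (phenotype DataFrame, TrueValues).
    """
    rng = config.rng("phenotypes")
    n = ped.n
    missing = [t for t in ped.ids if t not in cov.index]
    if missing:
        raise ValueError(f"covariate row missing for animal {missing[0]!r}")
    cov = cov.loc[list(ped.ids)]

    su2 = config.true_sigma_u2
    u = np.zeros(n)
    msv = mendelian_variances(ped) * su2
    z = rng.standard_normal(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        pa = 0.0
        if s >= 0:
            pa += 0.5 * u[s]
        if d >= 0:
            pa += 0.5 * u[d]
        u[i] = pa + z[i] * np.sqrt(msv[i])

    # contemporary groups: random partition within each birth-year cohort
    cg = np.empty(n, dtype=object)
    cg_effects = {}
    for yr in np.unique(ped.birth_year):
        members = np.flatnonzero(ped.birth_year == yr)
        labels = rng.integers(config.n_cg, size=members.size)
        for j in range(config.n_cg):
            name = f"{yr}_{j + 1}"
            cg_effects[name] = rng.normal(0.0, config.cg_effect_sd)
        for m_, l_ in zip(members, labels):
            cg[m_] = f"{yr}_{l_ + 1}"
    cg_eff = np.array([cg_effects[c] for c in cg])

    et = (rng.random(n) < config.et_rate).astype(int)
    lo, hi = config.age_us_range
    age_us = rng.integers(lo, hi + 1, size=n)
    mid = 0.5 * (lo + hi)
    cow_age = rng.uniform(*config.cow_age_range, size=n)

    fixed = (
        config.mean
        + cg_eff
        + config.et_effect * et
        + config.age_us_slope * (age_us - mid)
        + config.beta1 * cow_age
        + config.beta2 * cow_age**2
        + comp.fractions @ np.asarray(config.breed_type_effects)
        + config.het_effect * cov["het"].to_numpy()
        + config.recomb_effect * cov["rec"].to_numpy()
    )
    e = rng.normal(0.0, np.sqrt(config.true_sigma_e2), size=n)
    y = fixed + u + e

    phen = pd.DataFrame(
        {
            "animal": ped.ids,
            "value": y,
            "cg": cg,
            "et": et,
            "age_us": age_us,
            "cow_age": cow_age,
            "birth_year": ped.birth_year,
        }
    )
    return phen, TrueValues(u=u, e=e, fixed_part=fixed)


def selective_genotyping(ped: Pedigree, truth: TrueValues, config: SimConfig) -> list:
    """Pick the genotyped animals.

    Under selective genotyping the top ``genotyping_fraction * n`` animals
    by true breeding value within the most recent birth years are taken
    (older animals fill any shortfall); otherwise a uniform random sample.
    """
    rng = config.rng("genotyping")
    n = ped.n
    m = int(round(config.genotyping_fraction * n))
    if m == 0:
        raise ValueError("genotyping_fraction selects zero animals")
    if not config.selective_genotyping:
        idx = rng.choice(n, size=m, replace=False)
        return [ped.ids[i] for i in sorted(idx)]
    cutoff = ped.birth_year.max() - (config.genotyping_recent_years - 1)
    recent = np.flatnonzero(ped.birth_year >= cutoff)
    older = np.flatnonzero(ped.birth_year < cutoff)
    ranked = recent[np.argsort(-truth.u[recent])]
    if ranked.size < m:
        extra = older[np.argsort(-truth.u[older])][: m - ranked.size]
        ranked = np.concatenate([ranked, extra])
    chosen = sorted(ranked[:m])
    return [ped.ids[i] for i in chosen]


def simulate_population(config: SimConfig) -> dict:
    """Run all simulation stages; returns a dict of every artefact."""
    ped, comp = simulate_pedigree(config)
    cov = crosscov.covariate_table(ped, comp)
    phen, truth = simulate_phenotypes(ped, comp, cov, config)
    gmat = drop_genotypes(ped, comp, config)
    genotyped = selective_genotyping(ped, truth, config)
    return {
        "config": config,
        "pedigree": ped,
        "composition": comp,
        "covariates": cov,
        "phenotypes": phen,
        "truth": truth,
        "genotypes": gmat.subset(genotyped),
        "genotyped_ids": genotyped,
    }


def write_phenotypes_csv(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, index=False)


def write_truth_csv(truth: TrueValues, ped: Pedigree, path) -> None:
    truth.as_frame(ped).to_csv(path, index=False)
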