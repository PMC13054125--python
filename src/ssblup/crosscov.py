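"""Heterosis and recombination covariates from parental breed compositions.

Combined heterosis is the expected fraction of loci carrying alleles from
two different breed types (1 - sum_i s_i d_i); combined recombination
measures the expected breakup of within-breed allele combinations in the
gametes of crossbred parents (1 - sum_i (s_i^2 + d_i^2) / 2).  Specific
(pairwise) versions split those totals by unordered type pair.

The pairwise recombination coefficient is offered in two forms.  The
``standard`` form ``s_i s_j + d_i d_j`` sums exactly to the combined
coefficient over all pairs and is zero for purebred parents; it is the
default.  The ``as_printed`` form ``(s_i + d_j)(s_j + d_i) - Het_ij`` is a
published variant that violates both properties (an F1 from two purebreds
gets a nonzero value) and is retained only for auditability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pedigree import BREED_TYPES, BreedComposition, Pedigree

__all__ = [
    "PAIRS",
    "pair_names",
    "specific_heterosis",
    "combined_heterosis",
    "combined_recombination",
    "specific_recombination",
    "covariate_table",
    "COVARIATE_COLUMNS",
]

#: unordered type pairs in canonical order
PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def pair_names() -> list:
    return [BREED_TYPES[i] + BREED_TYPES[j] for i, j in PAIRS]


COVARIATE_COLUMNS = (
    ["het", "rec"]
    + [f"het_{p}" for p in pair_names()]
    + [f"rec_{p}" for p in pair_names()]
)


def _check(vec, name):
    v = np.asarray(vec, dtype=float)
    if v.shape[-1] != 4:
        raise ValueError(f"{name} must have 4 breed-type entries")
    if np.any(np.abs(v.sum(axis=-1) - 1.0) > 1e-8):
        raise ValueError(f"{name} fractions must sum to 1")
    return v


def _pair_index(pair):
    if isinstance(pair, tuple) and all(isinstance(x, str) for x in pair):
        pair = (BREED_TYPES.index(pair[0]), BREED_TYPES.index(pair[1]))
    i, j = pair
    if i == j:
        raise ValueError("heterosis/recombination pairs require two distinct types")
    return min(i, j), max(i, j)


def specific_heterosis(sire_comp, dam_comp, pair) -> float:
    """Expected heterozygosity due to types i and j: s_i d_j + s_j d_i."""
    s = _check(sire_comp, "sire_comp")
    d = _check(dam_comp, "dam_comp")
    i, j = _pair_index(pair)
    return float(s[i] * d[j] + s[j] * d[i])


def combined_heterosis(sire_comp, dam_comp) -> float:
    """Total expected cross-type heterozygosity: 1 - sum_i s_i d_i."""
    s = _check(sire_comp, "sire_comp")
    d = _check(dam_comp, "dam_comp")
    return float(1.0 - np.dot(s, d))


def combined_recombination(sire_comp, dam_comp) -> float:
    """Total recombination-loss coefficient: 1 - sum_i (s_i^2 + d_i^2) / 2."""
    s = _check(sire_comp, "sire_comp")
    d = _check(dam_comp, "dam_comp")
    return float(1.0 - 0.5 * (np.dot(s, s) + np.dot(d, d)))


def specific_recombination(sire_comp, dam_comp, pair, form: str = "standard") -> float:
    """Pairwise recombination coefficient; ``form`` selects the definition."""
    s = _check(sire_comp, "sire_comp")
    d = _check(dam_comp, "dam_comp")
    i, j = _pair_index(pair)
    if form == "standard":
        return float(s[i] * s[j] + d[i] * d[j])
    if form == "as_printed":
        het_ij = s[i] * d[j] + s[j] * d[i]
        return float((s[i] + d[j]) * (s[j] + d[i]) - het_ij)
    raise ValueError(f"unknown specific-recombination form {form!r}")


def covariate_table(
    ped: Pedigree,
    comp: BreedComposition,
    rec_form: str = "standard",
    founders_as_selfed: bool = False,
) -> pd.DataFrame:
    """All 14 crossbreeding covariates for every animal in the pedigree.

    Animals with an unknown parent get zeros by default (their parental
    compositions are undefined); with ``founders_as_selfed`` their own
    declared composition is used for both parents instead.
    """
    if rec_form not in ("standard", "as_printed"):
        raise ValueError(f"unknown specific-recombination form {rec_form!r}")
    s = comp.sire_fractions.copy()
    d = comp.dam_fractions.copy()
    mask = comp.has_parents
    if founders_as_selfed:
        s[~mask] = comp.fractions[~mask]
        d[~mask] = comp.fractions[~mask]
        mask = np.ones(ped.n, dtype=bool)

    out = np.zeros((ped.n, len(COVARIATE_COLUMNS)))
    sm, dm = s[mask], d[mask]
    out[mask, 0] = 1.0 - np.einsum("ij,ij->i", sm, dm)
    out[mask, 1] = 1.0 - 0.5 * (
        np.einsum("ij,ij->i", sm, sm) + np.einsum("ij,ij->i", dm, dm)
    )
    for k, (i, j) in enumerate(PAIRS):
        out[mask, 2 + k] = sm[:, i] * dm[:, j] + sm[:, j] * dm[:, i]
        if rec_form == "standard":
            out[mask, 8 + k] = sm[:, i] * sm[:, j] + dm[:, i] * dm[:, j]
        else:
            het_ij = sm[:, i] * dm[:, j] + sm[:, j] * dm[:, i]
            out[mask, 8 + k] = (sm[:, i] + dm[:, j]) * (sm[:, j] + dm[:, i]) - het_ij
    return pd.DataFrame(out, index=pd.Index(ped.ids, name="animal"),
                        columns=COVARIATE_COLUMNS)
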