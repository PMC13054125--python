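import numpy as np
import pytest

from ssblup.pedigree import build_pedigree, propagate_breed_composition
from ssblup.simpop import SimConfig, simulate_population


@pytest.fixture(scope="session")
def trio():
    """sire s, dam d, child c; all non-inbred."""
    ped = build_pedigree([("s", None, None), ("d", None, None), ("c", "s", "d")])
    return ped


@pytest.fixture(scope="session")
def two_breed_f2():
    """N x A -> F1 pair -> F2 child (inbred: F1s are full sibs)."""
    ped = build_pedigree(
        [
            ("n1", None, None),
            ("a1", None, None),
            ("f1a", "n1", "a1"),
            ("f1b", "n1", "a1"),
            ("f2", "f1a", "f1b"),
        ]
    )
    comp = propagate_breed_composition(
        ped, {"n1": [1, 0, 0, 0], "a1": [0, 1, 0, 0]}
    )
    return ped, comp


def random_pedigree(n, seed, p_founder=0.25):
    """Random valid pedigree with tokens r1..rn, parents drawn from earlier animals."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        if i < 2 or rng.random() < p_founder:
            recs.append((f"r{i}", None, None))
        else:
            s, d = rng.choice(i, size=2, replace=True)
            recs.append((f"r{i}", f"r{s}", f"r{d}"))
    return build_pedigree(recs)


@pytest.fixture(scope="session")
def small_pop():
    """~620-animal simulated population with contemporary-group effects."""
    cfg = SimConfig(
        n_founders_per_type=(22, 50, 24, 9),
        n_generations=5,
        n_matings_per_gen=103,
        n_snps=300,
        n_cg=3,
        cg_effect_sd=1.0,
        et_effect=0.8,
        beta1=0.05,
        beta2=-0.004,
        true_sigma_u2=0.425,
        true_sigma_e2=1.937,
        genotyping_fraction=0.15,
        seed=42,
    )
    return simulate_population(cfg)
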