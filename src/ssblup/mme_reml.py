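"""Design matrices, REML likelihood, AI-REML and mixed-model solutions.

The restricted log-likelihood is evaluated through the mixed-model
equations.  With M(alpha) the MME coefficient matrix scaled by the residual
variance (alpha = sigma_e2 / sigma_u2),

    -2 lnL = (n - p - q) log sigma_e2 + q log sigma_u2
             + log|K| + log|M| + y'Py,

which equals -(log|V| + log|X'V^-1 X| + y'Py) up to sign, with no dropped
terms other than the n/2 log(2 pi) constant.  AI-REML uses exact score
identities; the single trace tr(K^-1 C_uu) they need is obtained as the
derivative of log|M(alpha)| in alpha, evaluated by a central difference of
the sparse log-determinant (two extra factorisations, no dense inverse).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .crosscov import pair_names
from .pedigree import BREED_TYPES, BreedComposition, Pedigree

__all__ = [
    "ModelSpec",
    "MixedModelSystem",
    "VarianceFit",
    "Solutions",
    "MODEL_IDS",
    "build_design",
    "reml_loglik",
    "ai_reml",
    "solve_blup",
    "heritability",
]

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5")

# extra effect roster per model beyond the common CG/ET/age/cow-age block
_MODEL_EFFECTS = {
    "M1": [],
    "M2": ["nabc", "het"],
    "M3": ["nabc", "het", "rec"],
    "M4": ["nabc", "rec", "specific_het"],
    "M5": ["nabc", "specific_het", "specific_rec"],
}


@dataclass
class ModelSpec:
    """One of the five fixed-effect rosters plus the relationship source."""

    model_id: str = "M1"
    relationship: str = "A"  # "A" or "H"
    age_us_as_class: bool = True
    age_us_bin_days: int = 30
    cg_min_records: int = 10

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if self.relationship not in ("A", "H"):
            raise ValueError("relationship must be 'A' or 'H'")

    @property
    def effects(self) -> list:
        return list(_MODEL_EFFECTS[self.model_id])


@dataclass
class MixedModelSystem:
    """Data, design matrices and relationship inverse for one analysis."""

    y: np.ndarray
    X: np.ndarray                    # (n, p) full column rank
    Z: sparse.csr_matrix             # (n, q) record -> animal incidence
    k_inv: sparse.csr_matrix         # (q, q) relationship inverse
    logdet_k: float                  # log|K|
    x_labels: list
    animal_index: np.ndarray         # record -> pedigree index
    records: pd.DataFrame | None = None

    # cached cross-products
    _blocks: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def blocks(self) -> dict:
        if not self._blocks:
            X, Z, y = self.X, self.Z, self.y
            self._blocks = {
                "XtX": sparse.csr_matrix(X.T @ X),
                "XtZ": sparse.csr_matrix(X.T @ Z),
                "ZtZ": (Z.T @ Z).tocsr(),
                "Xty": X.T @ y,
                "Zty": Z.T @ y,
                "yty": float(y @ y),
            }
        return self._blocks

    def mme_matrix(self, alpha: float) -> sparse.csc_matrix:
        b = self.blocks()
        return sparse.bmat(
            [[b["XtX"], b["XtZ"]], [b["XtZ"].T, b["ZtZ"] + alpha * self.k_inv]],
            format="csc",
        )


class DesignError(ValueError):
    pass


def _dummy(series: pd.Series, prefix: str, drop_first: bool):
    levels = sorted(series.unique())
    if drop_first:
        levels = levels[1:]
    cols = [(f"{prefix}:{lv}", (series == lv).to_numpy(float)) for lv in levels]
    return cols


def build_design(
    phen: pd.DataFrame,
    spec: ModelSpec,
    cov: pd.DataFrame,
    comp: BreedComposition,
    ped: Pedigree,
    k_inv: sparse.spmatrix,
    logdet_k: float,
    value_col: str = "value",
) -> MixedModelSystem:
    """Assemble y, X and Z for one model.

    Records in contemporary groups with fewer than ``cg_min_records``
    phenotypes are excluded.  The CG dummies carry the intercept (full
    coding, no separate intercept); other categorical effects drop one
    level; cow age enters centred as linear + quadratic covariates; breed
    fractions enter as 3 of the 4 types (type A, the largest, is dropped).
    """
    df = phen.copy()
    counts = df["cg"].value_counts()
    keep_cg = counts[counts >= spec.cg_min_records].index
    df = df[df["cg"].isin(keep_cg)].reset_index(drop=True)
    if df.empty:
        raise DesignError("no records remain after the contemporary-group filter")

    missing = [a for a in df["animal"] if a not in cov.index]
    if missing:
        raise DesignError(f"covariates missing for animal {missing[0]!r}")
    cv = cov.loc[df["animal"]].reset_index(drop=True)

    cols = []
    cols += _dummy(df["cg"].astype(str), "cg", drop_first=False)
    if df["et"].nunique() > 1:
        cols += _dummy(df["et"].astype(int), "et", drop_first=True)
    if spec.age_us_as_class:
        bins = (df["age_us"].to_numpy(float) // spec.age_us_bin_days).astype(int)
        if len(np.unique(bins)) > 1:
            cols += _dummy(pd.Series(bins), "age_us", drop_first=True)
    else:
        age = df["age_us"].to_numpy(float)
        cols.append(("age_us", age - age.mean()))
    ca = df["cow_age"].to_numpy(float)
    ca = ca - ca.mean()
    cols.append(("cow_age", ca))
    cols.append(("cow_age2", ca**2))

    effects = spec.effects
    if "nabc" in effects:
        idx = ped.indices_of(df["animal"])
        for k, t in enumerate(BREED_TYPES):
            if t == "A":  # dropped: fractions sum to 1 (collinear with CG block)
                continue
            cols.append((f"frac_{t}", comp.fractions[idx, k]))
    if "het" in effects:
        cols.append(("het", cv["het"].to_numpy()))
    if "rec" in effects:
        cols.append(("rec", cv["rec"].to_numpy()))
    if "specific_het" in effects:
        for p_ in pair_names():
            cols.append((f"het_{p_}", cv[f"het_{p_}"].to_numpy()))
    if "specific_rec" in effects:
        for p_ in pair_names():
            cols.append((f"rec_{p_}", cv[f"rec_{p_}"].to_numpy()))

    # an all-zero column means the effect does not occur in the data
    # (e.g. no crossbred parents of a given type pair); drop it like an
    # empty factor level rather than failing the rank check
    cols = [c for c in cols if np.any(c[1] != 0.0)]
    labels = [c[0] for c in cols]
    X = np.column_stack([c[1] for c in cols])

    # rank check via QR; report aliased columns if deficient
    _, Rm = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(Rm))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    if np.any(diag < tol):
        from scipy.linalg import qr as _qr

        _, R, piv = _qr(X, mode="economic", pivoting=True)
        rank = int(np.sum(np.abs(np.diag(R)) > np.abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps))
        aliased = [labels[j] for j in piv[rank:]]
        raise DesignError(f"design matrix is rank deficient; aliased columns: {aliased}")

    idx = ped.indices_of(df["animal"])
    n = len(df)
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), idx)), shape=(n, ped.n)
    )
    return MixedModelSystem(
        y=df[value_col].to_numpy(float),
        X=X,
        Z=Z,
        k_inv=k_inv.tocsr(),
        logdet_k=float(logdet_k),
        x_labels=labels,
        animal_index=idx,
        records=df,
    )


# ---------------------------------------------------------------------------
# REML likelihood


def _splu(M: sparse.csc_matrix):
    # symmetric minimum-degree ordering: order-of-magnitude less fill than
    # the default COLAMD on these symmetric MME matrices
    return splu(M, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})


def _logdet_from_lu(lu) -> float:
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def _solve_mme(sys: MixedModelSystem, lu):
    b = sys.blocks()
    rhs = np.concatenate([b["Xty"], b["Zty"]])
    sol = lu.solve(rhs)
    return sol[: sys.p], sol[sys.p:]


def reml_loglik(theta, sys: MixedModelSystem) -> float:
    """Restricted log-likelihood at theta = (sigma_u2, sigma_e2).

    Equals -1/2 (log|V| + log|X'V^-1 X| + y'Py); the n/2 log(2 pi) constant
    is omitted.
    """
    su2, se2 = float(theta[0]), float(theta[1])
    if su2 <= 0 or se2 <= 0:
        raise ValueError("variance components must be strictly positive")
    alpha = se2 / su2
    lu = _splu(sys.mme_matrix(alpha))
    beta, u = _solve_mme(sys, lu)
    b = sys.blocks()
    ypy = (b["yty"] - beta @ b["Xty"] - u @ b["Zty"]) / se2
    n, p, q = sys.n, sys.p, sys.q
    logdet_m = _logdet_from_lu(lu)
    return -0.5 * (
        (n - p - q) * np.log(se2) + q * np.log(su2) + sys.logdet_k + logdet_m + ypy
    )


@dataclass
class VarianceFit:
    sigma_u2: float
    sigma_e2: float
    se_u2: float
    se_e2: float
    h2: float
    h2_se: float
    loglik: float
    iterations: int
    converged: bool
    boundary: bool
    n_records: int
    p_var: int = 2
    trace: list = field(default_factory=list)
    ai_inv: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "sigma_u2": self.sigma_u2,
            "sigma_e2": self.sigma_e2,
            "se_u2": self.se_u2,
            "se_e2": self.se_e2,
            "h2": self.h2,
            "h2_se": self.h2_se,
            "loglik": self.loglik,
            "iterations": self.iterations,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_records": self.n_records,
            "p_var": self.p_var,
        }


def _iteration_state(sys: MixedModelSystem, su2: float, se2: float):
    """Factorise the MME and return everything one AI/EM step needs."""
    alpha = se2 / su2
    lu = _splu(sys.mme_matrix(alpha))
    beta, u = _solve_mme(sys, lu)
    b = sys.blocks()
    ypy = (b["yty"] - beta @ b["Xty"] - u @ b["Zty"]) / se2
    n, p, q = sys.n, sys.p, sys.q
    logdet_m = _logdet_from_lu(lu)
    lnl = -0.5 * (
        (n - p - q) * np.log(se2) + q * np.log(su2) + sys.logdet_k + logdet_m + ypy
    )
    # tr(K^-1 C_uu) = d log|M(alpha)| / d alpha, central difference
    h = max(1e-6 * alpha, 1e-12)
    ld_hi = _logdet_from_lu(_splu(sys.mme_matrix(alpha + h)))
    ld_lo = _logdet_from_lu(_splu(sys.mme_matrix(alpha - h)))
    t = (ld_hi - ld_lo) / (2.0 * h)
    return lu, beta, u, ypy, lnl, t, alpha


def ai_reml(
    sys: MixedModelSystem,
    init=None,
    max_iter: int = 200,
    tol_theta: float = 1e-8,
    tol_loglik: float = 1e-9,
    floor: float = 1e-10,
) -> VarianceFit:
    """Estimate (sigma_u2, sigma_e2) by average-information REML.

    AI updates with step-halving; an EM step is substituted whenever the AI
    update leaves the parameter space or decreases the likelihood.
    Standard errors come from the inverse AI matrix at the optimum and the
    heritability SE from the delta method.  Non-convergence and boundary
    estimates are flagged, not raised.
    """
    vary = float(np.var(sys.y))
    if init is None:
        init = (0.3 * vary, 0.7 * vary)
    su2, se2 = float(init[0]), float(init[1])
    if su2 <= 0 or se2 <= 0:
        raise ValueError("initial variances must be positive")
    n, p, q = sys.n, sys.p, sys.q
    kinv = sys.k_inv
    b = sys.blocks()

    trace_rows = []
    lnl_prev = None
    converged = False
    it = 0
    AI = None
    # below this (h2 ~ 1e-4), sigma_u2 is considered at the boundary and pinned
    bound_thresh = max(floor, 1e-4 * vary)
    was_pinned = False
    for it in range(1, max_iter + 1):
        lu, beta, u, ypy, lnl, t, alpha = _iteration_state(sys, su2, se2)
        uku = float(u @ (kinv @ u))
        resid = sys.y - sys.X @ beta - sys.Z @ u
        ee = float(resid @ resid)

        score_u = -0.5 * ((q - alpha * t) / su2 - uku / su2**2)
        score_e = -0.5 * ((n - p - q + alpha * t) / se2 - ee / se2**2)

        # average-information matrix via working vectors
        w_u = (sys.Z @ u) / su2
        w_e = resid / se2
        Pw = {}
        for name, w in (("u", w_u), ("e", w_e)):
            rhs = np.concatenate([sys.X.T @ w, sys.Z.T @ w])
            sol = lu.solve(rhs)
            Pw[name] = (w - sys.X @ sol[:p] - sys.Z @ sol[p:]) / se2
        AI = 0.5 * np.array(
            [
                [w_u @ Pw["u"], w_u @ Pw["e"]],
                [w_e @ Pw["u"], w_e @ Pw["e"]],
            ]
        )
        AI = 0.5 * (AI + AI.T)

        trace_rows.append((it, su2, se2, lnl))
        if lnl_prev is not None and abs(lnl - lnl_prev) < tol_loglik:
            converged = True
            break
        lnl_prev = lnl

        theta = np.array([su2, se2])
        try:
            delta = np.linalg.solve(AI, np.array([score_u, score_e]))
        except np.linalg.LinAlgError:
            delta = None

        new = None
        if delta is not None:
            step = delta.copy()
            for _ in range(12):
                cand = theta + step
                if cand[0] > floor and cand[1] > floor:
                    cand_lnl = reml_loglik(cand, sys)
                    if cand_lnl >= lnl - 1e-12:
                        new = cand
                        break
                step *= 0.5
        if new is None:
            # EM fallback (guaranteed ascent, always in the parameter space)
            em_u = (uku + t * se2) / q
            em_e = (b["yty"] - beta @ b["Xty"] - u @ b["Zty"]) / (n - p)
            new = np.array([max(em_u, floor), max(em_e, floor)])

        pinned = new[0] <= bound_thresh
        if pinned:
            new[0] = max(bound_thresh, floor)
        rel = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), 1e-30))
        su2, se2 = float(new[0]), float(new[1])
        if pinned and was_pinned:
            converged = True  # stuck at the lower bound
            break
        was_pinned = pinned
        if rel < tol_theta:
            converged = True
            lu, beta, u, ypy, lnl, t, alpha = _iteration_state(sys, su2, se2)
            trace_rows.append((it + 1, su2, se2, lnl))
            break

    boundary = su2 <= bound_thresh
    if not converged:
        warnings.warn("AI-REML did not converge within max_iter", RuntimeWarning)

    ai_inv = None
    se_u = se_e = np.nan
    if AI is not None:
        try:
            ai_inv = np.linalg.inv(AI)
            se_u = float(np.sqrt(max(ai_inv[0, 0], 0.0)))
            se_e = float(np.sqrt(max(ai_inv[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            pass

    h2, h2_se = heritability(su2, se2, ai_inv)
    return VarianceFit(
        sigma_u2=su2,
        sigma_e2=se2,
        se_u2=se_u,
        se_e2=se_e,
        h2=h2,
        h2_se=h2_se,
        loglik=float(trace_rows[-1][3]),
        iterations=it,
        converged=converged,
        boundary=boundary,
        n_records=sys.n,
        trace=trace_rows,
        ai_inv=ai_inv,
    )


@dataclass
class Solutions:
    beta: np.ndarray
    x_labels: list
    u: np.ndarray  # one entry per pedigree animal

    def fixed_effects(self) -> pd.Series:
        return pd.Series(self.beta, index=self.x_labels)


def solve_blup(sys: MixedModelSystem, vf) -> Solutions:
    """Solve the MME at the supplied variance components.

    ``vf`` may be a VarianceFit or a (sigma_u2, sigma_e2) pair.  Returns
    fixed-effect solutions and breeding values for every pedigree animal.
    """
    if isinstance(vf, VarianceFit):
        su2, se2 = vf.sigma_u2, vf.sigma_e2
    else:
        su2, se2 = float(vf[0]), float(vf[1])
    if su2 <= 0 or se2 <= 0:
        raise ValueError("variance components must be strictly positive")
    lu = _splu(sys.mme_matrix(se2 / su2))
    beta, u = _solve_mme(sys, lu)
    return Solutions(beta=beta, x_labels=list(sys.x_labels), u=u)


def heritability(sigma_u2, sigma_e2=None, cov: np.ndarray | None = None):
    """h2 = sigma_u2 / (sigma_u2 + sigma_e2), with a delta-method SE.

    Accepts a VarianceFit or two variances.  Returns (h2, se); the SE is
    NaN when no covariance matrix of the estimates is available.
    """
    if isinstance(sigma_u2, VarianceFit):
        vf = sigma_u2
        return heritability(vf.sigma_u2, vf.sigma_e2, vf.ai_inv)
    su2, se2 = float(sigma_u2), float(sigma_e2)
    tot = su2 + se2
    if tot <= 0:
        raise ValueError("total variance must be positive")
    h2 = su2 / tot
    if cov is None:
        return h2, float("nan")
    g = np.array([se2, -su2]) / tot**2
    var = float(g @ cov @ g)
    return h2, float(np.sqrt(max(var, 0.0)))
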