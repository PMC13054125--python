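"""Pedigree ingestion, inbreeding, and numerator relationship-matrix algebra.

Animals are recoded to consecutive 0-based internal indices with parents
always preceding offspring; the external convention is 1-based codes with
``0`` meaning "unknown parent".  All relationship matrices produced here
share that index.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "BreedComposition",
    "PedigreeError",
    "CycleError",
    "read_pedigree",
    "build_pedigree",
    "inbreeding",
    "mendelian_variances",
    "a_matrix",
    "a_inverse",
    "a_logdet",
    "a22",
    "propagate_breed_composition",
    "pedigree_summary",
    "write_pedigree_csv",
]

BREED_TYPES = ("N", "A", "B", "C")


class PedigreeError(ValueError):
    """Malformed pedigree input."""


class CycleError(PedigreeError):
    """An animal appears among its own ancestors."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    Attributes
    ----------
    ids : list of str
        Original animal tokens; position ``i`` is the animal with internal
        index ``i`` (external code ``i + 1``).
    sire, dam : ndarray of int
        0-based parent indices, ``-1`` for unknown.  Always ``< i`` for
        animal ``i``.
    birth_year : ndarray of int
        Birth year per animal, ``-1`` if unknown.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)
    _f: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {t: i for i, t in enumerate(self.ids)}
        n = len(self.ids)
        for name in ("sire", "dam", "birth_year"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise PedigreeError(f"{name} has wrong length")
        bad = (self.sire >= np.arange(n)) | (self.dam >= np.arange(n))
        if np.any(bad):
            raise PedigreeError("parents must precede offspring in the recoded order")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def index_of(self, token) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise KeyError(f"unknown animal id {token!r}") from None

    def indices_of(self, tokens) -> np.ndarray:
        return np.array([self.index_of(t) for t in tokens], dtype=np.int64)

    @property
    def F(self) -> np.ndarray:
        """Inbreeding coefficients (cached)."""
        if self._f is None:
            self._f = inbreeding(self)
        return self._f


def build_pedigree(records, birth_years=None) -> Pedigree:
    """Build a sorted :class:`Pedigree` from (animal, sire, dam) token triples.

    ``None``, empty string, ``"0"`` and ``0`` denote an unknown parent.
    Parents referenced but never listed as animals are auto-created as
    unknown-parent founders.
    """
    def norm(tok):
        if tok is None:
            return None
        if isinstance(tok, float) and np.isnan(tok):
            return None
        s = str(tok).strip()
        return None if s in ("", "0", "0.0", "nan", "NA") else s

    animals = []
    parents = {}
    seen = set()
    for rec in records:
        a, s, d = (norm(rec[0]), norm(rec[1]), norm(rec[2]))
        if a is None:
            raise PedigreeError("animal id missing")
        if a in seen:
            raise PedigreeError(f"duplicate animal id {a!r}")
        seen.add(a)
        animals.append(a)
        parents[a] = (s, d)
    years = dict(birth_years or {})
    # auto-create referenced-but-unlisted parents as founders
    for a in list(animals):
        for p in parents[a]:
            if p is not None and p not in parents:
                parents[p] = (None, None)
                animals.append(p)

    # Kahn topological sort, founders first, stable by insertion order
    children = {a: [] for a in parents}
    indeg = {}
    for a, (s, d) in parents.items():
        known = [p for p in (s, d) if p is not None]
        indeg[a] = len(known)
        for p in known:
            children[p].append(a)
    ready = [a for a in animals if indeg[a] == 0]
    order = []
    head = 0
    while head < len(ready):
        a = ready[head]
        head += 1
        order.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(order) != len(parents):
        cyc = _find_cycle(parents, set(order))
        raise CycleError("pedigree contains a cycle: " + " -> ".join(cyc))

    index = {a: i for i, a in enumerate(order)}
    sire = np.array([index[parents[a][0]] if parents[a][0] else -1 for a in order])
    dam = np.array([index[parents[a][1]] if parents[a][1] else -1 for a in order])
    by = np.array([int(years.get(a, -1)) for a in order])
    return Pedigree(order, sire, dam, by, _index=index)


def _find_cycle(parents, resolved):
    """Locate one cycle among unresolved animals, for the error message."""
    stuck = [a for a in parents if a not in resolved]
    node = stuck[0]
    seen = {}
    path = []
    while node not in seen:
        seen[node] = len(path)
        path.append(node)
        s, d = parents[node]
        node = next(p for p in (s, d) if p is not None and p not in resolved)
    return path[seen[node]:] + [node]


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with columns animal, sire, dam [, birth_year]."""
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for req in ("animal", "sire", "dam"):
        if req not in cols:
            raise PedigreeError(f"pedigree file lacks required column {req!r}")
    recs = df[[cols["animal"], cols["sire"], cols["dam"]]].itertuples(index=False)
    years = {}
    if "birth_year" in cols:
        for a, y in zip(df[cols["animal"]], df[cols["birth_year"]]):
            try:
                years[str(a).strip()] = int(float(y))
            except (TypeError, ValueError):
                pass
    return build_pedigree(list(recs), years)


def write_pedigree_csv(ped: Pedigree, comp: "BreedComposition | None", path) -> None:
    """Write pedigree (and optional breed fractions) as CSV; 0 = unknown parent."""
    out = pd.DataFrame(
        {
            "animal": ped.ids,
            "sire": [ped.ids[s] if s >= 0 else 0 for s in ped.sire],
            "dam": [ped.ids[d] if d >= 0 else 0 for d in ped.dam],
            "birth_year": ped.birth_year,
        }
    )
    if comp is not None:
        for k, t in enumerate(BREED_TYPES):
            out[f"type{t}"] = comp.fractions[:, k]
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# inbreeding and relationship matrices


def mendelian_variances(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Within-family (Mendelian-sampling) variance d_i for each animal.

    Unknown parents contribute as unrelated non-inbred base animals.
    """
    if F is None:
        F = ped.F
    n = ped.n
    d = np.ones(n)
    s, m = ped.sire, ped.dam
    both = (s >= 0) & (m >= 0)
    d[both] = 0.5 - 0.25 * (F[s[both]] + F[m[both]])
    sonly = (s >= 0) & (m < 0)
    d[sonly] = 0.75 - 0.25 * F[s[sonly]]
    monly = (s < 0) & (m >= 0)
    d[monly] = 0.75 - 0.25 * F[m[monly]]
    return d


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen–Luo recursive method.

    For each animal the diagonal of A is accumulated as
    ``1 + F_i = sum_j L_ij^2 d_j`` over the animal's ancestors, tracing
    contributions youngest-first; exact and O(n * ancestors).
    """
    n = ped.n
    F = np.zeros(n)
    d = np.ones(n)  # filled progressively; d_i only needs F of parents (< i)
    s, m = ped.sire, ped.dam
    for i in range(n):
        if s[i] >= 0 and m[i] >= 0:
            d[i] = 0.5 - 0.25 * (F[s[i]] + F[m[i]])
        elif s[i] >= 0:
            d[i] = 0.75 - 0.25 * F[s[i]]
        elif m[i] >= 0:
            d[i] = 0.75 - 0.25 * F[m[i]]
        if s[i] < 0 or m[i] < 0:
            continue  # F = 0 with any unknown parent
        # a_ii = sum over ancestors of L^2 d, via max-heap on index
        coeff = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = coeff.pop(j, 0.0)
            if lj == 0.0:
                continue
            aii += lj * lj * d[j]
            for p in (s[j], m[j]):
                if p >= 0:
                    if p not in coeff:
                        heapq.heappush(heap, -p)
                        coeff[p] = 0.0
                    coeff[p] += 0.5 * lj
        F[i] = aii - 1.0
    return F


def _ancestor_closure(ped: Pedigree, idx: np.ndarray) -> np.ndarray:
    need = np.zeros(ped.n, dtype=bool)
    need[idx] = True
    for i in range(ped.n - 1, -1, -1):
        if need[i]:
            if ped.sire[i] >= 0:
                need[ped.sire[i]] = True
            if ped.dam[i] >= 0:
                need[ped.dam[i]] = True
    return np.flatnonzero(need)


def a_matrix(ped: Pedigree, ids=None) -> np.ndarray:
    """Numerator relationship matrix A restricted to ``ids`` (tabular method).

    Computed over the ancestor closure of the requested animals and then
    subsetted, so the result is identical to the corresponding block of the
    full-pedigree A.  Rows/columns follow the order of ``ids``.
    """
    if ids is None:
        idx = np.arange(ped.n)
    else:
        idx = ped.indices_of(ids)
        if idx.size == 0:
            raise PedigreeError("empty id list")
    closure = _ancestor_closure(ped, idx)
    pos = -np.ones(ped.n, dtype=np.int64)
    pos[closure] = np.arange(closure.size)
    m = closure.size
    A = np.zeros((m, m))
    for k, i in enumerate(closure):
        si = pos[ped.sire[i]] if ped.sire[i] >= 0 else -1
        di = pos[ped.dam[i]] if ped.dam[i] >= 0 else -1
        row = np.zeros(k)
        if si >= 0:
            row += 0.5 * A[si, :k]
        if di >= 0:
            row += 0.5 * A[di, :k]
        A[k, :k] = row
        A[:k, k] = row
        aii = 1.0
        if si >= 0 and di >= 0:
            aii += 0.5 * A[si, di]
        A[k, k] = aii
    sel = pos[idx]
    return A[np.ix_(sel, sel)]


def a22(ped: Pedigree, genotyped_ids) -> np.ndarray:
    """Pedigree relationships among the genotyped animals (A restricted)."""
    genotyped_ids = list(genotyped_ids)
    if not genotyped_ids:
        raise PedigreeError("empty genotyped id list")
    return a_matrix(ped, genotyped_ids)


def a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding adjustment."""
    F = ped.F
    d = mendelian_variances(ped, F)
    alpha = 1.0 / d
    n = ped.n
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, m = ped.sire[i], ped.dam[i]
        a = alpha[i]
        add(i, i, a)
        for p in (s, m):
            if p >= 0:
                add(p, i, -0.5 * a)
                add(i, p, -0.5 * a)
                add(p, p, 0.25 * a)
        if s >= 0 and m >= 0:
            add(s, m, 0.25 * a)
            add(m, s, 0.25 * a)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def a_logdet(ped: Pedigree) -> float:
    """log |A| = sum of log Mendelian-sampling variances."""
    return float(np.sum(np.log(mendelian_variances(ped))))


# ---------------------------------------------------------------------------
# breed composition


@dataclass
class BreedComposition:
    """Per-animal breed fractions over (N, A, B, C) plus parental fractions.

    ``sire_fractions``/``dam_fractions`` hold each parent's own total
    fractions (zero rows where the parent is unknown); ``has_parents`` marks
    animals with both parents known, for which crossbreeding covariates are
    defined.
    """

    fractions: np.ndarray       # (n, 4)
    sire_fractions: np.ndarray  # (n, 4)
    dam_fractions: np.ndarray   # (n, 4)
    has_parents: np.ndarray     # (n,) bool
    types: tuple = BREED_TYPES

    def of(self, ped: Pedigree, token) -> np.ndarray:
        return self.fractions[ped.index_of(token)]


def propagate_breed_composition(ped: Pedigree, founder_fractions) -> BreedComposition:
    """Propagate declared founder fractions down the pedigree.

    ``founder_fractions`` maps founder token -> length-4 sequence over
    (N, A, B, C); each must sum to 1.  A non-founder's fractions are the
    mean of its parents'.
    """
    if isinstance(founder_fractions, pd.DataFrame):
        founder_fractions = {
            str(a): np.asarray(row, dtype=float)
            for a, row in zip(founder_fractions.index, founder_fractions.values)
        }
    n = ped.n
    frac = np.zeros((n, 4))
    sf = np.zeros((n, 4))
    df_ = np.zeros((n, 4))
    both = np.zeros(n, dtype=bool)
    for i in range(n):
        s, m = ped.sire[i], ped.dam[i]
        if s < 0 and m < 0:
            tok = ped.ids[i]
            if tok not in founder_fractions:
                raise PedigreeError(f"founder {tok!r} has no declared breed fractions")
            v = np.asarray(founder_fractions[tok], dtype=float)
            if v.shape != (4,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
                raise PedigreeError(
                    f"founder {tok!r} fractions must be 4 non-negative values summing to 1"
                )
            frac[i] = v
        elif s >= 0 and m >= 0:
            sf[i] = frac[s]
            df_[i] = frac[m]
            frac[i] = 0.5 * (sf[i] + df_[i])
            both[i] = True
        else:
            raise PedigreeError(
                f"animal {ped.ids[i]!r} has exactly one known parent; "
                "breed composition is undefined"
            )
    return BreedComposition(frac, sf, df_, both)


# ---------------------------------------------------------------------------
# summary statistics


def equivalent_generations(ped: Pedigree) -> np.ndarray:
    """Equivalent complete generations: sum over known ancestors of (1/2)^gen."""
    t = np.zeros(ped.n)
    for i in range(ped.n):
        s, m = ped.sire[i], ped.dam[i]
        if s >= 0:
            t[i] += 0.5 * (1.0 + t[s])
        if m >= 0:
            t[i] += 0.5 * (1.0 + t[m])
    return t


def pedigree_summary(ped: Pedigree) -> dict:
    """Counts, equivalent-generation statistics and inbreeding summary."""
    F = ped.F
    t = equivalent_generations(ped)
    return {
        "n_animals": int(ped.n),
        "n_founders": int(ped.is_founder.sum()),
        "mean_equivalent_generations": float(t.mean()),
        "max_equivalent_generations": float(t.max()),
        "mean_inbreeding": float(F.mean()),
        "n_inbred": int((F > 0).sum()),
    }
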