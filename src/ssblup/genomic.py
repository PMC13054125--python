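"""SNP QC, genomic relationship matrix, blending, and single-step H inverse."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, sparse
from scipy.sparse.linalg import splu

from .pedigree import Pedigree, a22 as _a22, a_inverse, a_logdet

__all__ = [
    "GenotypeMatrix",
    "QCThresholds",
    "QCReport",
    "HStructure",
    "read_snp_file",
    "write_snp_file",
    "snp_qc",
    "g_matrix",
    "blend_g",
    "h_inverse",
    "build_h_structure",
    "sparse_spd_logdet",
]

MISSING = 5


@dataclass
class GenotypeMatrix:
    """Coded genotypes: 0/1/2 allele counts, 5 = missing."""

    animal_ids: list
    codes: np.ndarray  # (n_animals, n_markers) int8
    marker_ids: list | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        if len(self.animal_ids) != self.codes.shape[0]:
            raise ValueError("animal_ids length does not match code rows")
        if self.marker_ids is None:
            self.marker_ids = [f"snp{j + 1}" for j in range(self.codes.shape[1])]
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if np.any(bad):
            raise ValueError("genotype codes must be in {0, 1, 2, 5}")

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of the counted allele, from non-missing codes."""
        obs = self.codes != MISSING
        cnt = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(obs, self.codes, 0).sum(axis=0) / (2.0 * np.maximum(cnt, 1))
        return np.where(cnt > 0, p, np.nan)

    def subset(self, animal_ids) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = [pos[a] for a in animal_ids]
        return GenotypeMatrix(list(animal_ids), self.codes[idx], list(self.marker_ids))


def read_snp_file(path) -> GenotypeMatrix:
    """Read an id + contiguous 0/1/2/5 code-string file (BLUPF90 dialect)."""
    ids, rows = [], []
    width = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {ln}: expected 'id codes'")
            aid, codes = parts
            if width is None:
                width = len(codes)
            elif len(codes) != width:
                raise ValueError(
                    f"line {ln}: code string length {len(codes)} != {width}"
                )
            try:
                row = np.frombuffer(codes.encode(), dtype=np.uint8) - ord("0")
            except Exception as exc:  # pragma: no cover
                raise ValueError(f"line {ln}: unparsable codes") from exc
            if np.any(~np.isin(row, (0, 1, 2, MISSING))):
                bad = codes[int(np.flatnonzero(~np.isin(row, (0, 1, 2, MISSING)))[0])]
                raise ValueError(f"line {ln}: invalid genotype code {bad!r}")
            ids.append(aid)
            rows.append(row.astype(np.int8))
    if not rows:
        raise ValueError("empty SNP file")
    return GenotypeMatrix(ids, np.vstack(rows))


def write_snp_file(gmat: GenotypeMatrix, path) -> None:
    width = max(len(str(a)) for a in gmat.animal_ids) + 1
    with open(path, "w") as fh:
        for aid, row in zip(gmat.animal_ids, gmat.codes):
            fh.write(f"{aid:<{width}}" + "".join(chr(ord("0") + c) for c in row) + "\n")


# ---------------------------------------------------------------------------
# quality control


@dataclass
class QCThresholds:
    min_call_rate: float = 0.90
    min_maf: float = 0.05
    remove_monomorphic: bool = True
    max_het_deviation: float = 0.15  # |obs het freq - 2p(1-p)|


@dataclass
class QCReport:
    n_input: int
    removed_call_rate: int = 0
    removed_maf: int = 0
    removed_monomorphic: int = 0
    removed_het_deviation: int = 0
    retained: int = 0
    removed_markers: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_call_rate": self.removed_call_rate,
            "removed_maf": self.removed_maf,
            "removed_monomorphic": self.removed_monomorphic,
            "removed_het_deviation": self.removed_het_deviation,
            "retained": self.retained,
        }


def snp_qc(gmat: GenotypeMatrix, thresholds: QCThresholds | None = None):
    """Remove markers failing call-rate, MAF, monomorphism or HWE-het rules.

    Rules are applied in that order; each removed marker is attributed to the
    first rule it fails.  Returns (filtered matrix, report).
    """
    th = thresholds or QCThresholds()
    if gmat.n_markers == 0:
        raise ValueError("empty genotype matrix")
    codes = gmat.codes
    obs = codes != MISSING
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / gmat.n_animals
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, codes, 0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1))
        het = ((codes == 1) & obs).sum(axis=0) / np.maximum(n_obs, 1)
    maf = np.minimum(p, 1.0 - p)

    report = QCReport(n_input=gmat.n_markers)
    fail_cr = call_rate < th.min_call_rate
    fail_maf = ~fail_cr & (maf < th.min_maf)
    fail_mono = np.zeros_like(fail_cr)
    if th.remove_monomorphic:
        fail_mono = ~fail_cr & ~fail_maf & ((p <= 0.0) | (p >= 1.0))
    dev = np.abs(het - 2.0 * p * (1.0 - p))
    fail_het = ~fail_cr & ~fail_maf & ~fail_mono & (dev > th.max_het_deviation)
    keep = ~(fail_cr | fail_maf | fail_mono | fail_het)

    report.removed_call_rate = int(fail_cr.sum())
    report.removed_maf = int(fail_maf.sum())
    report.removed_monomorphic = int(fail_mono.sum())
    report.removed_het_deviation = int(fail_het.sum())
    report.retained = int(keep.sum())
    for j in np.flatnonzero(~keep):
        rule = (
            "call_rate" if fail_cr[j]
            else "maf" if fail_maf[j]
            else "monomorphic" if fail_mono[j]
            else "het_deviation"
        )
        report.removed_markers[gmat.marker_ids[j]] = rule
    if report.retained == 0:
        raise ValueError("all markers removed by QC")
    filtered = GenotypeMatrix(
        list(gmat.animal_ids),
        codes[:, keep],
        [m for m, k in zip(gmat.marker_ids, keep) if k],
    )
    return filtered, report


# ---------------------------------------------------------------------------
# relationship matrices


def g_matrix(gmat: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix G = ZZ' / (2 sum p(1-p)).

    Z centers the codes at twice the observed (pooled) allele frequencies;
    missing codes are mean-imputed to 2p before centering.
    """
    p = gmat.allele_frequencies()
    if np.any(np.isnan(p)):
        raise ValueError("markers with no observed genotypes; run QC first")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("zero G denominator: all markers monomorphic")
    M = gmat.codes.astype(float)
    M[gmat.codes == MISSING] = np.nan
    M = np.where(np.isnan(M), 2.0 * p, M)
    Z = M - 2.0 * p
    return (Z @ Z.T) / denom


def blend_g(G: np.ndarray, A22: np.ndarray, beta: float = 0.05) -> np.ndarray:
    """Blend (1 - beta) G + beta A22 to guarantee invertibility."""
    if not 0.0 <= beta < 1.0:
        raise ValueError("blending weight must be in [0, 1)")
    G = np.asarray(G, dtype=float)
    A22 = np.asarray(A22, dtype=float)
    if G.shape != A22.shape:
        raise ValueError("G and A22 are not conformable")
    return (1.0 - beta) * G + beta * A22


@dataclass
class HStructure:
    """Pieces of the single-step relationship structure with a shared index."""

    a_inv: sparse.csr_matrix        # all animals
    G: np.ndarray                   # genotyped block (blended)
    A22: np.ndarray                 # genotyped block
    genotyped_index: np.ndarray     # positions of genotyped animals in ped order
    tau: float = 1.0
    omega: float = 1.0

    h_inv: sparse.csr_matrix | None = None


def _spd_inverse(M: np.ndarray, name: str) -> np.ndarray:
    try:
        c, low = linalg.cho_factor(M)
        return linalg.cho_solve((c, low), np.eye(M.shape[0]))
    except linalg.LinAlgError as exc:
        raise ValueError(
            f"{name} is singular or not positive definite; blend with A22 first"
        ) from exc


def h_inverse(hs: HStructure) -> sparse.csr_matrix:
    """H^-1 = A^-1 + [tau G^-1 - omega A22^-1] on the genotyped block."""
    n = hs.a_inv.shape[0]
    idx = np.asarray(hs.genotyped_index, dtype=np.int64)
    if idx.size == 0:
        hs.h_inv = hs.a_inv.tocsr()
        return hs.h_inv
    Ginv = _spd_inverse(hs.G, "G")
    A22inv = _spd_inverse(hs.A22, "A22")
    block = hs.tau * Ginv - hs.omega * A22inv
    rows = np.repeat(idx, idx.size)
    cols = np.tile(idx, idx.size)
    add = sparse.coo_matrix((block.ravel(), (rows, cols)), shape=(n, n))
    hs.h_inv = (hs.a_inv + add).tocsr()
    return hs.h_inv


def build_h_structure(
    ped: Pedigree,
    gmat: GenotypeMatrix,
    tau: float = 1.0,
    omega: float = 1.0,
    blend_beta: float = 0.05,
) -> HStructure:
    """Assemble H^-1 from a pedigree and a genotyped subset (blended G)."""
    idx = ped.indices_of(gmat.animal_ids)
    G = g_matrix(gmat)
    A22 = _a22(ped, gmat.animal_ids)
    Gb = blend_g(G, A22, blend_beta)
    hs = HStructure(a_inverse(ped), Gb, A22, idx, tau=tau, omega=omega)
    h_inverse(hs)
    return hs


def write_matrix_triplets(M, ids, path, lower_only: bool = True) -> None:
    """Write a relationship matrix as 'id_i id_j value' triplet text."""
    M = sparse.coo_matrix(M)
    with open(path, "w") as fh:
        for i, j, v in zip(M.row, M.col, M.data):
            if lower_only and j > i:
                continue
            fh.write(f"{ids[i]} {ids[j]} {v:.12g}\n")


def read_matrix_triplets(path, ids) -> np.ndarray:
    """Read a triplet file back into a dense symmetric matrix."""
    pos = {str(a): k for k, a in enumerate(ids)}
    M = np.zeros((len(ids), len(ids)))
    with open(path) as fh:
        for line in fh:
            a, b, v = line.split()
            i, j = pos[a], pos[b]
            M[i, j] = M[j, i] = float(v)
    return M


def sparse_spd_logdet(Kinv: sparse.spmatrix) -> float:
    """log|K| from its sparse SPD inverse, via LU of K^-1."""
    lu = splu(Kinv.tocsc())
    return -float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def h_logdet(ped: Pedigree, hs: HStructure) -> float:
    """log|H| (falls back to the closed-form log|A| when nothing is genotyped)."""
    if hs.genotyped_index.size == 0:
        return a_logdet(ped)
    return sparse_spd_logdet(hs.h_inv if hs.h_inv is not None else h_inverse(hs))
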