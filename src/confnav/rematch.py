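"""REMatch structure kernel and the induced kernel distance.

Two structures A and B are compared through the matrix C of pairwise
environment similarities, C_ij = k(x_i^A, x_j^B).  The REMatch kernel is the
entropy-regularized optimal matching of environments,

    K^γ(A, B) = Σ_ij P^γ_ij C_ij ,
    P^γ = argmin_P  Σ_ij P_ij (1 − C_ij + γ ln P_ij) ,

where P ranges over matrices with row sums 1/N_A and column sums 1/N_B (the
doubly stochastic set, extended to unequal environment counts).  P^γ is
computed by Sinkhorn scaling in the log domain.  γ interpolates between the
best-match kernel (γ → 0) and the average-environment kernel (γ → ∞); K^γ is
a weighted mean of C entries and lies in [0, 1].

The kernel distance  D(A,B) = sqrt(K(A,A) + K(B,B) − 2 K(A,B))  is the metric
used downstream for embedding and clustering.  Kernels are normalized to unit
self-similarity by default so distances reflect shape, not molecule size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .descriptors import SoapDescriptor, SoapParams
from .structures import Dataset, Structure

__all__ = [
    "EnvSimilarityMatrix",
    "MatchPlan",
    "KernelMatrix",
    "DistanceMatrix",
    "env_similarity",
    "sinkhorn",
    "rematch_kernel",
    "kernel_matrix",
    "kernel_to_distance",
    "REMatchKernel",
    "save_kernel",
    "load_kernel",
    "save_distance",
    "load_distance",
]

logger = logging.getLogger(__name__)

DEFAULT_GAMMA = 0.1
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 5000


@dataclass
class EnvSimilarityMatrix:
    """Environment-pair similarities C_ij(A, B) in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("C must be 2-D")
        if self.values.min() < -1e-10 or self.values.max() > 1 + 1e-10:
            raise ValueError("C entries must lie in [0, 1]")


@dataclass
class MatchPlan:
    """Converged transport plan P^γ with row sums 1/N_A, column sums 1/N_B."""

    values: np.ndarray
    gamma: float
    n_iter: int = 0
    marginal_error: float = 0.0


@dataclass
class KernelMatrix:
    """Symmetric structure-kernel matrix, with structure ids when known."""

    values: np.ndarray
    normalized: bool = True
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel matrix must be square")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("kernel matrix must be symmetric")


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with zero diagonal."""

    values: np.ndarray
    ids: list[str] | None = None
    n_clamped: int = 0  # negative Eq.-3 radicands clamped to zero

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max() > 0:
            raise ValueError("distance matrix must have zero diagonal")
        if v.min() < 0:
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """Plain-numpy logsumexp (scipy's has heavy per-call overhead here)."""
    m = a.max(axis=axis, keepdims=True)
    out = np.log(np.sum(np.exp(a - m), axis=axis)) + np.squeeze(m, axis=axis)
    return out


def _sinkhorn_log_batch(
    C: np.ndarray, gamma: float, tol: float, max_iter: int
) -> tuple[np.ndarray, int, float]:
    """Log-domain Sinkhorn on a (P, N_A, N_B) batch of similarity matrices.

    Returns (plans, n_iter, worst marginal violation).  Column marginals are
    exact after every sweep; convergence is judged on the row marginals.
    Converged members of the batch are frozen so stragglers do not make the
    whole batch iterate.
    """
    P_, NA, NB = C.shape
    logM = C / gamma
    g = np.zeros((P_, NB))
    f = np.zeros((P_, NA))
    target_row = 1.0 / NA
    active = np.arange(P_)
    lM = logM
    it_done = 0
    for it in range(1, max_iter + 1):
        fa = -np.log(NA) - _lse(lM + g[active][:, None, :], axis=2)
        ga = -np.log(NB) - _lse(lM + fa[:, :, None], axis=1)
        f[active] = fa
        g[active] = ga
        rows = np.exp(lM + fa[:, :, None] + ga[:, None, :]).sum(axis=2)
        errs = np.abs(rows - target_row).max(axis=(1,))
        it_done = it
        still = errs >= tol
        if not still.any():
            active = active[:0]
            break
        if not still.all():
            active = active[still]
            lM = lM[still]
    plans = np.exp(logM + f[:, :, None] + g[:, None, :])
    err = float(np.abs(plans.sum(axis=2) - target_row).max())
    return plans, it_done, err


def _sinkhorn_log_batch_sym(
    C: np.ndarray, gamma: float, tol: float, max_iter: int
) -> tuple[np.ndarray, int, float]:
    """Damped log-domain Sinkhorn for batches of *symmetric* matrices.

    For symmetric C the optimal plan is symmetric (f = g); enforcing that and
    damping the fixed-point update by 1/2 removes the antisymmetric slow mode
    that makes the alternating scheme stall on matrices with near-tied rows.
    """
    P_, N, _ = C.shape
    logM = C / gamma
    f = np.zeros((P_, N))
    target = 1.0 / N
    active = np.arange(P_)
    lM = logM
    fa = f[active]
    it_done = 0
    for it in range(1, max_iter + 1):
        fn = -np.log(N) - _lse(lM + fa[:, None, :], axis=2)
        fa = 0.5 * (fa + fn)
        f[active] = fa
        rows = np.exp(lM + fa[:, :, None] + fa[:, None, :]).sum(axis=2)
        errs = np.abs(rows - target).max(axis=1)
        it_done = it
        still = errs >= tol
        if not still.any():
            break
        if not still.all():
            active = active[still]
            lM = lM[still]
            fa = fa[still]
    plans = np.exp(logM + f[:, :, None] + f[:, None, :])
    err = float(np.abs(plans.sum(axis=2) - target).max())
    return plans, it_done, err


def _is_symmetric(C: np.ndarray) -> bool:
    return C.shape[0] == C.shape[1] and np.abs(C - C.T).max() < 1e-13


def sinkhorn(
    C: EnvSimilarityMatrix | np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> MatchPlan:
    """Entropy-regularized optimal matching of the similarity matrix C.

    Alternating row/column rescaling of exp(C/γ), carried out entirely in the
    log domain so small γ never overflows (a damped symmetric variant is used
    for symmetric C).  Raises on non-convergence.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    values = C.values if isinstance(C, EnvSimilarityMatrix) else np.asarray(C, float)
    solver = _sinkhorn_log_batch_sym if _is_symmetric(values) else _sinkhorn_log_batch
    plans, n_iter, err = solver(values[None], gamma, tol, max_iter)
    if err >= tol:
        raise RuntimeError(
            f"Sinkhorn did not converge in {max_iter} iterations "
            f"(marginal residual {err:.3e} >= tol {tol:.1e}); "
            "increase max_iter or gamma"
        )
    return MatchPlan(plans[0], gamma=gamma, n_iter=n_iter, marginal_error=err)


def sinkhorn_objective(P: np.ndarray, C: np.ndarray, gamma: float) -> float:
    """Σ_ij P_ij (1 − C_ij + γ ln P_ij), with 0 ln 0 = 0."""
    P = np.asarray(P, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(P > 0, P * np.log(P), 0.0)
    return float(np.sum(P * (1.0 - C)) + gamma * np.sum(ent))


class REMatchKernel(TransformerMixin, BaseEstimator):
    """REMatch structure kernel as a scikit-learn style transformer.

    ``fit`` computes environment descriptors for the reference structures and
    their self-kernels; ``transform`` returns the (optionally normalized)
    kernel of new structures against the fitted references, one row per new
    structure.  ``fit_transform`` yields the full symmetric kernel matrix of
    the fitted set.
    """

    def __init__(
        self,
        gamma: float = DEFAULT_GAMMA,
        normalize: bool = True,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        cutoff: float = 4.0,
        atom_sigma: float = 0.3,
        n_max: int = 8,
        l_max: int = 6,
        zeta: float = 2.0,
        species_mask: Sequence[str] = (),
        species_alphabet: Sequence[str] | None = None,
    ):
        self.gamma = gamma
        self.normalize = normalize
        self.tol = tol
        self.max_iter = max_iter
        self.cutoff = cutoff
        self.atom_sigma = atom_sigma
        self.n_max = n_max
        self.l_max = l_max
        self.zeta = zeta
        self.species_mask = species_mask
        self.species_alphabet = species_alphabet

    def _make_descriptor(self) -> SoapDescriptor:
        return SoapDescriptor(
            cutoff=self.cutoff,
            atom_sigma=self.atom_sigma,
            n_max=self.n_max,
            l_max=self.l_max,
            zeta=self.zeta,
            species_mask=self.species_mask,
            species_alphabet=self.species_alphabet,
        )

    def fit(self, X: Dataset | Iterable[Structure], y=None) -> "REMatchKernel":
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        X = list(X)
        if not X:
            raise ValueError("empty dataset")
        self.descriptor_ = self._make_descriptor().fit(X)
        self.ids_ = [s.id for s in X]
        self.descriptors_ = self.descriptor_.transform(X)
        self.self_kernels_ = self._self_kernels(self.descriptors_)
        return self

    def _self_kernels(self, desc: list[np.ndarray]) -> np.ndarray:
        """Batched K(A, A) for a list of descriptor arrays."""
        out = np.empty(len(desc))
        groups: dict[int, list[int]] = {}
        for i, d in enumerate(desc):
            groups.setdefault(len(d), []).append(i)
        for n, idx in groups.items():
            Cs = np.stack([self._env_sim(desc[i], desc[i]) for i in idx])
            Cs = 0.5 * (Cs + np.swapaxes(Cs, 1, 2))  # exact symmetry
            plans, _, err = _sinkhorn_log_batch_sym(
                Cs, self.gamma, self.tol, self.max_iter
            )
            if err >= self.tol:
                raise RuntimeError(
                    f"Sinkhorn did not converge for {len(idx)} self pairs "
                    f"(residual {err:.3e})"
                )
            out[idx] = np.einsum("pij,pij->p", plans, Cs)
        return out

    def _env_sim(self, da: np.ndarray, db: np.ndarray) -> np.ndarray:
        return np.clip(da @ db.T, 0.0, 1.0) ** self.zeta

    def _pair_kernel(self, da: np.ndarray, db: np.ndarray) -> float:
        C = self._env_sim(da, db)
        plan = sinkhorn(C, self.gamma, self.tol, self.max_iter)
        return float(np.sum(plan.values * C))

    def _cross_kernel(
        self,
        descA: list[np.ndarray],
        descB: list[np.ndarray],
        symmetric: bool,
        diag: np.ndarray | None = None,
    ) -> np.ndarray:
        """Kernel block; pairs with equal env counts are Sinkhorn-batched.

        With ``symmetric=True`` only the strict upper triangle is solved and
        mirrored; the diagonal is taken from ``diag`` (the self kernels).
        """
        nA, nB = len(descA), len(descB)
        K = np.full((nA, nB), np.nan)
        if symmetric and diag is not None:
            K[np.arange(nA), np.arange(nA)] = diag
        # group by environment-count shape and by symmetry of C (symmetric
        # matrices, e.g. duplicated structures, go to the damped solver)
        pairs: dict[tuple[int, int, bool], list[tuple[int, int, np.ndarray]]] = {}
        for i in range(nA):
            jstart = i + 1 if symmetric else 0
            for j in range(jstart, nB):
                C = self._env_sim(descA[i], descB[j])
                key = (C.shape[0], C.shape[1], _is_symmetric(C))
                pairs.setdefault(key, []).append((i, j, C))
        for (na, nb, sym), group in pairs.items():
            Cs = np.stack([C for _, _, C in group])
            if sym:
                Cs = 0.5 * (Cs + np.swapaxes(Cs, 1, 2))
                plans, _, err = _sinkhorn_log_batch_sym(
                    Cs, self.gamma, self.tol, self.max_iter
                )
            else:
                plans, _, err = _sinkhorn_log_batch(
                    Cs, self.gamma, self.tol, self.max_iter
                )
            if err >= self.tol:
                raise RuntimeError(
                    f"Sinkhorn did not converge for {len(group)} pairs of shape "
                    f"({na}, {nb}) (residual {err:.3e})"
                )
            vals = np.einsum("pij,pij->p", plans, Cs)
            for (i, j, _), v in zip(group, vals):
                K[i, j] = v
                if symmetric:
                    K[j, i] = v
        if not np.all(np.isfinite(K)):
            bad = np.argwhere(~np.isfinite(K))[0]
            raise RuntimeError(f"non-finite kernel entry at pair {tuple(bad)}")
        return K

    def fit_transform(self, X: Dataset | Iterable[Structure], y=None) -> np.ndarray:
        self.fit(X)
        K = self._cross_kernel(
            self.descriptors_, self.descriptors_, symmetric=True,
            diag=self.self_kernels_,
        )
        if self.normalize:
            d = np.sqrt(np.diag(K))
            K = K / np.outer(d, d)
            np.fill_diagonal(K, 1.0)
        K = 0.5 * (K + K.T)  # kill last-bit asymmetry from batching order
        return K

    def transform(self, X: Dataset | Iterable[Structure]) -> np.ndarray:
        if not hasattr(self, "descriptor_"):
            raise RuntimeError("REMatchKernel must be fitted before transform")
        X = list(X)
        descX = self.descriptor_.transform(X)
        K = self._cross_kernel(descX, self.descriptors_, symmetric=False)
        if self.normalize:
            selfX = self._self_kernels(descX)
            K = K / np.sqrt(np.outer(selfX, self.self_kernels_))
        return K


def env_similarity(
    A: Structure,
    B: Structure,
    p: SoapParams,
    species_alphabet: Sequence[str] | None = None,
) -> EnvSimilarityMatrix:
    """Matrix of environment-kernel similarities between atoms of A and B."""
    est = REMatchKernel(
        cutoff=p.cutoff,
        atom_sigma=p.atom_sigma,
        n_max=p.n_max,
        l_max=p.l_max,
        zeta=p.zeta,
        species_mask=p.species_mask,
    )
    ref: list[Structure] = [A, B]
    if species_alphabet is not None:
        ref = ref + [
            Structure(
                "_alphabet", list(species_alphabet),
                np.zeros((len(species_alphabet), 3)),
            )
        ]
    desc = est._make_descriptor().fit(ref)
    da, db = desc.transform_structure(A), desc.transform_structure(B)
    return EnvSimilarityMatrix(np.clip(da @ db.T, 0.0, 1.0) ** p.zeta)


def rematch_kernel(
    A: Structure,
    B: Structure,
    p: SoapParams,
    gamma: float = DEFAULT_GAMMA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    species_alphabet: Sequence[str] | None = None,
) -> float:
    """Unnormalized REMatch kernel K^γ(A, B) between two structures."""
    C = env_similarity(A, B, p, species_alphabet)
    plan = sinkhorn(C, gamma, tol, max_iter)
    return float(np.sum(plan.values * C.values))


def kernel_matrix(
    dataset: Dataset,
    p: SoapParams,
    gamma: float = DEFAULT_GAMMA,
    normalize: bool = True,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> KernelMatrix:
    """Full pairwise REMatch kernel matrix of a dataset."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    est = REMatchKernel(
        gamma=gamma,
        normalize=normalize,
        tol=tol,
        max_iter=max_iter,
        cutoff=p.cutoff,
        atom_sigma=p.atom_sigma,
        n_max=p.n_max,
        l_max=p.l_max,
        zeta=p.zeta,
        species_mask=p.species_mask,
    )
    K = est.fit_transform(dataset)
    return KernelMatrix(K, normalized=normalize, ids=dataset.ids)


def kernel_to_distance(K: KernelMatrix | np.ndarray) -> DistanceMatrix:
    """Kernel distance D(A,B) = sqrt(K(A,A) + K(B,B) − 2 K(A,B)).

    The REMatch kernel is not guaranteed positive semidefinite, so negative
    radicands are clamped to zero; their count is logged and recorded on the
    returned matrix so users can consider raising γ.
    """
    if isinstance(K, KernelMatrix):
        vals, ids = K.values, K.ids
    else:
        vals = np.asarray(K, dtype=float)
        ids = None
        if np.abs(vals - vals.T).max() > 1e-10:
            raise ValueError("kernel matrix must be symmetric")
    diag = np.diag(vals)
    sq = diag[:, None] + diag[None, :] - 2.0 * vals
    n_clamped = int(np.count_nonzero(sq < 0) // 2)
    if n_clamped:
        logger.warning(
            "kernel distance: clamped %d negative radicands to zero "
            "(min %.3e); consider raising gamma",
            n_clamped,
            float(sq.min()),
        )
    D = np.sqrt(np.clip(sq, 0.0, None))
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, ids=ids, n_clamped=n_clamped)


def _h5_meta(f, params: SoapParams | None, gamma: float | None, normalized) -> None:
    if params is not None:
        pg = f.create_group("soap_params")
        pg.attrs["cutoff"] = params.cutoff
        pg.attrs["atom_sigma"] = params.atom_sigma
        pg.attrs["n_max"] = params.n_max
        pg.attrs["l_max"] = params.l_max
        pg.attrs["zeta"] = params.zeta
        pg.attrs["species_mask"] = sorted(params.species_mask)
    if gamma is not None:
        f.attrs["gamma"] = gamma
    if normalized is not None:
        f.attrs["normalized"] = bool(normalized)


def save_kernel(
    path: str | Path,
    K: KernelMatrix,
    params: SoapParams | None = None,
    gamma: float | None = None,
) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("kernel", data=K.values)
        if K.ids is not None:
            f.attrs["structure_ids"] = K.ids
        _h5_meta(f, params, gamma, K.normalized)


def load_kernel(path: str | Path) -> KernelMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        vals = np.asarray(f["kernel"])
        ids = (
            [str(x) for x in f.attrs["structure_ids"]]
            if "structure_ids" in f.attrs
            else None
        )
        normalized = bool(f.attrs.get("normalized", True))
    return KernelMatrix(vals, normalized=normalized, ids=ids)


def save_distance(
    path: str | Path,
    D: DistanceMatrix,
    params: SoapParams | None = None,
    gamma: float | None = None,
) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("distance", data=D.values)
        if D.ids is not None:
            f.attrs["structure_ids"] = D.ids
        f.attrs["n_clamped"] = D.n_clamped
        _h5_meta(f, params, gamma, None)


def load_distance(path: str | Path) -> DistanceMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        vals = np.asarray(f["distance"])
        ids = (
            [str(x) for x in f.attrs["structure_ids"]]
            if "structure_ids" in f.attrs
            else None
        )
        n_clamped = int(f.attrs.get("n_clamped", 0))
    return DistanceMatrix(vals, ids=ids, n_clamped=n_clamped)


def distance_to_tsv(D: DistanceMatrix, path: str | Path) -> None:
    """Plain-TSV export for small matrices (ids as header and first column)."""
    import pandas as pd

    ids = D.ids if D.ids is not None else [str(i) for i in range(len(D))]
    pd.DataFrame(D.values, index=ids, columns=ids).to_csv(path, sep="\t")
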