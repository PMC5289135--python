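"""Sketch-map: nonlinear 2-D embedding of a dissimilarity matrix.

Sketch-map minimizes the stress

    S^2 = Σ_{i<j} w_ij [ F(D_ij) − f(d_ij) ]^2 ,

where D is the high-dimensional dissimilarity, d the Euclidean distance of
the 2-D projections, and F, f sigmoid transforms

    F(r) = 1 − (1 + (2^{a/b} − 1) (r/σ)^a)^{−b/a} ,

with exponents (A, B) in high dimension and (a, b) in 2-D.  The sigmoids
focus the optimization on distances of order σ, discarding both local
distortions and the precise layout of disconnected regions.  Maps are
labeled "σ–A_B–a_b"; the defaults A = a = 1 and B = b = 4 suit databases of
minimum-energy conformers, where there is no thermal noise to filter out.

σ can be set automatically from the histogram of all pairwise distances:
σ = 0.8 × D_max, with D_max the center of the most populated histogram bin.

Large datasets are embedded by selecting landmarks with farthest point
sampling, fitting the landmarks, and placing the remaining structures by
out-of-sample projection (minimizing each point's own stress against the
fixed landmarks).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .rematch import DistanceMatrix

__all__ = [
    "SigmoidParams",
    "SketchMapModel",
    "SketchMap",
    "sigmoid",
    "auto_sigma",
    "stress",
    "fit",
    "farthest_point_sample",
    "project",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SigmoidParams:
    """Switching threshold σ and the high-/low-dimensional exponents."""

    sigma: float
    A_hd: float = 1.0
    B_hd: float = 4.0
    a_ld: float = 1.0
    b_ld: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for name in ("A_hd", "B_hd", "a_ld", "b_ld"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def label(self) -> str:
        """Conventional 'σ–A_B–a_b' map label."""

        def fmt(x: float) -> str:
            return f"{x:g}"

        return (
            f"{fmt(self.sigma)}-{fmt(self.A_hd)}_{fmt(self.B_hd)}"
            f"-{fmt(self.a_ld)}_{fmt(self.b_ld)}"
        )


def _sigmoid(r: np.ndarray, sigma: float, a: float, b: float) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    c = 2.0 ** (a / b) - 1.0
    return 1.0 - (1.0 + c * (r / sigma) ** a) ** (-b / a)


def _sigmoid_deriv(r: np.ndarray, sigma: float, a: float, b: float) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    c = 2.0 ** (a / b) - 1.0
    t = r / sigma
    u = 1.0 + c * t**a
    with np.errstate(divide="ignore", invalid="ignore"):
        tp = np.where(t > 0, t ** (a - 1.0), 1.0 if a == 1.0 else 0.0)
    return b * c * tp * u ** (-b / a - 1.0) / sigma


def sigmoid(r, p: SigmoidParams, which: str = "high"):
    """Evaluate F (``which='high'``) or f (``which='low'``) at distance r ≥ 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    if which == "high":
        out = _sigmoid(r, p.sigma, p.A_hd, p.B_hd)
    elif which == "low":
        out = _sigmoid(r, p.sigma, p.a_ld, p.b_ld)
    else:
        raise ValueError("which must be 'high' or 'low'")
    return float(out) if out.ndim == 0 else out


def auto_sigma(D: DistanceMatrix | np.ndarray, n_bins: int = 100) -> float:
    """σ = 0.8 × D_max, D_max the center of the most populated histogram bin.

    The histogram covers the N(N−1)/2 off-diagonal distances with
    ``n_bins`` equal-width bins; ties go to the leftmost bin.
    """
    vals = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    n = vals.shape[0]
    if n < 3:
        raise ValueError("auto_sigma needs at least 3 structures")
    iu = np.triu_indices(n, k=1)
    d = vals[iu]
    if d.max() <= 0:
        raise ValueError("all pairwise distances are zero")
    counts, edges = np.histogram(d, bins=n_bins)
    mode = int(np.argmax(counts))  # argmax returns the leftmost maximum
    d_max = 0.5 * (edges[mode] + edges[mode + 1])
    return 0.8 * d_max


def stress(
    D: DistanceMatrix | np.ndarray,
    xy: np.ndarray,
    p: SigmoidParams,
    weights: np.ndarray | None = None,
) -> float:
    """Sketch-map stress S² of a 2-D configuration against D."""
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    xy = np.asarray(xy, dtype=float)
    if xy.shape != (Dv.shape[0], 2):
        raise ValueError(f"xy must be ({Dv.shape[0]}, 2), got {xy.shape}")
    iu = np.triu_indices(Dv.shape[0], k=1)
    d = np.linalg.norm(xy[iu[0]] - xy[iu[1]], axis=1)
    resid = _sigmoid(Dv[iu], p.sigma, p.A_hd, p.B_hd) - _sigmoid(
        d, p.sigma, p.a_ld, p.b_ld
    )
    if weights is None:
        return float(np.sum(resid**2))
    w = np.asarray(weights, dtype=float)
    if w.shape == Dv.shape:
        w = w[iu]
    elif w.shape != resid.shape:
        raise ValueError("weights must be per-pair (condensed or square)")
    return float(np.sum(w * resid**2))


def _stress_and_grad(
    flat_xy: np.ndarray,
    FD: np.ndarray,
    p: SigmoidParams,
    weights: np.ndarray | None,
) -> tuple[float, np.ndarray]:
    """Stress and its gradient; FD is the precomputed F(D) square matrix."""
    n = FD.shape[0]
    xy = flat_xy.reshape(n, 2)
    diff = xy[:, None, :] - xy[None, :, :]
    d = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(d, 1.0)  # dummy, masked below
    fd = _sigmoid(d, p.sigma, p.a_ld, p.b_ld)
    fp = _sigmoid_deriv(d, p.sigma, p.a_ld, p.b_ld)
    resid = fd - FD
    np.fill_diagonal(resid, 0.0)
    w = np.ones_like(resid) if weights is None else weights
    s2 = 0.5 * float(np.sum(w * resid**2))  # each pair counted twice
    coef = 2.0 * w * resid * fp / d
    np.fill_diagonal(coef, 0.0)
    grad = np.einsum("ij,ijk->ik", coef, diff)
    return s2, grad.ravel()


def _classical_mds(Dv: np.ndarray) -> np.ndarray:
    """Deterministic Torgerson scaling of D into 2-D."""
    n = Dv.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dv**2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:2]
    lam = np.clip(evals[idx], 0.0, None)
    xy = evecs[:, idx] * np.sqrt(lam)[None, :]
    # fix sign convention so the initialization is reproducible
    for k in range(2):
        col = xy[:, k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            xy[:, k] = -col
    return xy


@dataclass
class SketchMapModel:
    """Fitted landmark map: transform parameters, distances and coordinates."""

    params: SigmoidParams
    landmark_ids: list[str]
    landmark_D: np.ndarray
    landmark_xy: np.ndarray
    final_stress: float

    def __post_init__(self) -> None:
        if len(self.landmark_xy) != len(self.landmark_D):
            raise ValueError("landmark_xy and landmark_D sizes disagree")
        if self.final_stress < 0:
            raise ValueError("final_stress must be >= 0")


class SketchMap(BaseEstimator):
    """Sketch-map embedding of a precomputed dissimilarity matrix.

    ``fit(D)`` embeds all rows of D (use :func:`farthest_point_sample` to
    reduce a large set to landmarks first); ``transform(rows)`` places new
    structures out of sample from their distances to the fitted points.

    Parameters
    ----------
    sigma:
        Switching threshold; ``"auto"`` applies the 0.8 × histogram-mode rule.
    A_hd, B_hd, a_ld, b_ld:
        Sigmoid exponents; defaults 1, 4, 1, 4.
    n_starts:
        Local optimizations: one from the classical-scaling initialization
        plus ``n_starts − 1`` seeded perturbed restarts; best stress wins.
    """

    def __init__(
        self,
        sigma: float | str = "auto",
        A_hd: float = 1.0,
        B_hd: float = 4.0,
        a_ld: float = 1.0,
        b_ld: float = 4.0,
        n_bins: int = 100,
        n_starts: int = 5,
        max_iter: int = 1000,
        random_state: int = 0,
    ):
        self.sigma = sigma
        self.A_hd = A_hd
        self.B_hd = B_hd
        self.a_ld = a_ld
        self.b_ld = b_ld
        self.n_bins = n_bins
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.random_state = random_state

    def _resolve_params(self, Dv: np.ndarray) -> SigmoidParams:
        sig = auto_sigma(Dv, self.n_bins) if self.sigma == "auto" else float(self.sigma)
        return SigmoidParams(sig, self.A_hd, self.B_hd, self.a_ld, self.b_ld)

    def fit(self, D: DistanceMatrix | np.ndarray, y=None) -> "SketchMap":
        Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
        ids = D.ids if isinstance(D, DistanceMatrix) and D.ids else [
            str(i) for i in range(len(Dv))
        ]
        n = Dv.shape[0]
        if n < 3:
            raise ValueError("need at least 3 points to fit a map")
        p = self._resolve_params(Dv)
        FD = _sigmoid(Dv, p.sigma, p.A_hd, p.B_hd)
        np.fill_diagonal(FD, 0.0)
        init0 = _classical_mds(Dv)
        scale = max(np.ptp(init0), 1e-6)
        rng = np.random.default_rng(self.random_state)
        best_xy, best_s2 = None, np.inf
        for start in range(max(1, self.n_starts)):
            xy0 = init0 if start == 0 else init0 + rng.normal(
                scale=0.1 * scale, size=init0.shape
            )
            res = minimize(
                _stress_and_grad,
                xy0.ravel(),
                args=(FD, p, None),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.max_iter},
            )
            if not np.isfinite(res.fun):
                continue
            if res.fun < best_s2:
                best_s2, best_xy = res.fun, res.x.reshape(n, 2)
        if best_xy is None:
            raise RuntimeError("all sketch-map restarts diverged")
        self.params_ = p
        self.embedding_ = best_xy
        self.stress_ = stress(Dv, best_xy, p)
        self.model_ = SketchMapModel(p, list(ids), Dv.copy(), best_xy, self.stress_)
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        return self.fit(D).embedding_

    def transform(self, d_to_landmarks: np.ndarray) -> np.ndarray:
        """Out-of-sample projection of rows of landmark distances."""
        if not hasattr(self, "model_"):
            raise RuntimeError("SketchMap must be fitted before transform")
        d = np.atleast_2d(np.asarray(d_to_landmarks, dtype=float))
        return np.array([project(self.model_, row) for row in d])


def fit(
    D: DistanceMatrix | np.ndarray,
    p: SigmoidParams,
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 1000,
) -> SketchMapModel:
    """Functional wrapper: minimize the stress of D under sigmoid params p."""
    est = SketchMap(
        sigma=p.sigma,
        A_hd=p.A_hd,
        B_hd=p.B_hd,
        a_ld=p.a_ld,
        b_ld=p.b_ld,
        n_starts=n_starts,
        max_iter=max_iter,
        random_state=seed,
    )
    return est.fit(D).model_


def farthest_point_sample(
    D: DistanceMatrix | np.ndarray, m: int, seed_index: int = 0
) -> np.ndarray:
    """Greedy max-min landmark selection; ties broken by lowest index."""
    Dv = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    n = Dv.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    if not 0 <= seed_index < n:
        raise ValueError("seed_index out of range")
    chosen = [seed_index]
    mind = Dv[seed_index].copy()
    for _ in range(m - 1):
        nxt = int(np.argmax(mind))  # leftmost max = lowest index on ties
        chosen.append(nxt)
        mind = np.minimum(mind, Dv[nxt])
    return np.array(chosen)


def _project_objective(
    xy: np.ndarray, Fd: np.ndarray, lxy: np.ndarray, p: SigmoidParams
) -> tuple[float, np.ndarray]:
    diff = xy[None, :] - lxy
    r = np.linalg.norm(diff, axis=1)
    r_safe = np.maximum(r, 1e-12)
    fr = _sigmoid(r, p.sigma, p.a_ld, p.b_ld)
    resid = fr - Fd
    obj = float(np.sum(resid**2))
    fp = _sigmoid_deriv(r, p.sigma, p.a_ld, p.b_ld)
    grad = np.sum((2.0 * resid * fp / r_safe)[:, None] * diff, axis=0)
    return obj, grad


def project(
    model: SketchMapModel,
    d_to_landmarks: np.ndarray,
    grid: int = 64,
    pad: float = 0.25,
) -> np.ndarray:
    """Place one new point on a fitted map from its landmark distances.

    Coarse search on a ``grid`` × ``grid`` lattice over the landmark bounding
    box (padded by ``pad`` per side), then gradient refinement from the best
    cell.
    """
    if len(model.landmark_xy) == 0:
        raise ValueError("empty model")
    d = np.asarray(d_to_landmarks, dtype=float)
    if d.shape != (len(model.landmark_xy),):
        raise ValueError(
            f"expected {len(model.landmark_xy)} landmark distances, got {d.shape}"
        )
    p = model.params
    Fd = _sigmoid(d, p.sigma, p.A_hd, p.B_hd)
    lxy = model.landmark_xy
    lo = lxy.min(axis=0)
    hi = lxy.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    lo = lo - pad * span
    hi = hi + pad * span
    gx = np.linspace(lo[0], hi[0], grid)
    gy = np.linspace(lo[1], hi[1], grid)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    pts = np.stack([GX.ravel(), GY.ravel()], axis=1)  # (grid^2, 2)
    r = np.linalg.norm(pts[:, None, :] - lxy[None, :, :], axis=2)
    obj = np.sum((_sigmoid(r, p.sigma, p.a_ld, p.b_ld) - Fd[None, :]) ** 2, axis=1)
    x0 = pts[int(np.argmin(obj))]
    res = minimize(
        _project_objective,
        x0,
        args=(Fd, lxy, p),
        jac=True,
        method="L-BFGS-B",
        options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 500},
    )
    return res.x if res.fun <= obj.min() else x0


def save_model(path: str | Path, model: SketchMapModel) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["label"] = model.params.label
        pg = f.create_group("params")
        for k in ("sigma", "A_hd", "B_hd", "a_ld", "b_ld"):
            pg.attrs[k] = getattr(model.params, k)
        f.attrs["landmark_ids"] = model.landmark_ids
        f.create_dataset("landmark_D", data=model.landmark_D)
        f.create_dataset("landmark_xy", data=model.landmark_xy)
        f.attrs["final_stress"] = model.final_stress


def load_model(path: str | Path) -> SketchMapModel:
    import h5py

    with h5py.File(path, "r") as f:
        pg = f["params"]
        params = SigmoidParams(
            sigma=float(pg.attrs["sigma"]),
            A_hd=float(pg.attrs["A_hd"]),
            B_hd=float(pg.attrs["B_hd"]),
            a_ld=float(pg.attrs["a_ld"]),
            b_ld=float(pg.attrs["b_ld"]),
        )
        return SketchMapModel(
            params=params,
            landmark_ids=[str(x) for x in f.attrs["landmark_ids"]],
            landmark_D=np.asarray(f["landmark_D"]),
            landmark_xy=np.asarray(f["landmark_xy"]),
            final_stress=float(f.attrs["final_stress"]),
        )
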