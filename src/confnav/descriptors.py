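"""Rotation-invariant atom-centered environment descriptors.

Each atomic environment is represented by a smooth neighbor density: a sum of
Gaussians (width ``atom_sigma``) placed at the displacement vectors of all
atoms within ``cutoff`` of the center, partitioned by chemical species and
taken smoothly to zero at the cutoff.  The density is expanded in an
orthonormal polynomial radial basis on [0, r_c] times real spherical
harmonics, and the rotation-invariant power spectrum

    p_{n n' l}^{a b}  =  sum_m  c_{n l m}^{a}  c_{n' l m}^{b}

over species pairs (a, b) is flattened in a fixed, documented order and
normalized to unit Euclidean length.  The similarity of two environments is
the kernel  k(x, x') = (x · x')^zeta.

Concrete realization
--------------------
* radial basis: phi_n(r) = (r_c - r)^(n+2), n = 0..n_max-1, Löwdin
  orthonormalized against the metric  ∫ phi_n phi_m r^2 dr ;
* the expansion coefficients reduce to 1-D radial integrals involving
  exponentially scaled modified spherical Bessel functions, evaluated by
  Gauss–Legendre quadrature on [0, r_c];
* flattening order: species pairs (a <= b) in alphabet order; within a pair,
  radial pairs (n <= n' for a == b, all (n, n') for a < b) in C order, times
  l = 0..l_max.  Off-diagonal blocks carry a sqrt(2) weight so that the dot
  product of two flattened vectors equals that of the full tensors;
* the central atom contributes to its own density, so an isolated atom has a
  well-defined descriptor.

Species listed in ``species_mask`` are excluded both as centers and from the
density, which is how perturbation analyses (e.g. ignoring an adsorbed
cation) are expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import sqrtm
from scipy.special import ive, roots_legendre, sph_harm_y
from sklearn.base import BaseEstimator, TransformerMixin

from .structures import Dataset, Structure

__all__ = [
    "SoapParams",
    "EnvironmentDescriptor",
    "SoapDescriptor",
    "compute_descriptors",
    "environment_kernel",
    "save_descriptors",
    "load_descriptors",
]

_N_QUAD = 80  # Gauss-Legendre nodes on [0, r_c]; converged well below 1e-8


@dataclass(frozen=True)
class SoapParams:
    """Hyperparameters of the environment descriptor and kernel.

    Defaults are conventional magnitudes for small organic molecules:
    cutoff 4.0 Å, atom_sigma 0.3 Å, n_max 8, l_max 6, zeta 2.
    """

    cutoff: float = 4.0
    atom_sigma: float = 0.3
    n_max: int = 8
    l_max: int = 6
    zeta: float = 2.0
    species_mask: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.atom_sigma <= 0:
            raise ValueError("atom_sigma must be > 0")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.l_max < 0:
            raise ValueError("l_max must be >= 0")
        if self.zeta < 1:
            raise ValueError("zeta must be >= 1")
        object.__setattr__(self, "species_mask", frozenset(self.species_mask))


@dataclass
class EnvironmentDescriptor:
    """Unit-normalized power-spectrum vector of one atomic environment."""

    vector: np.ndarray
    center_species: str


def _radial_basis(n_max: int, cutoff: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal radial basis evaluated at Gauss-Legendre nodes.

    Returns (nodes, weights, G) where G[n, q] = g_n(r_q) and the g_n satisfy
    ∫ g_n g_m r^2 dr = δ_nm exactly (analytic overlap, Löwdin).
    """
    x, w = roots_legendre(_N_QUAD)
    r = 0.5 * cutoff * (x + 1.0)
    wq = 0.5 * cutoff * w
    # overlap of phi_n = (rc - r)^(n+2):  ∫_0^rc (rc-r)^(n+m+4) r^2 dr
    n = np.arange(n_max)
    s = n[:, None] + n[None, :] + 4
    overlap = cutoff ** (s + 3) * 2.0 / ((s + 1) * (s + 2) * (s + 3))
    inv_sqrt = np.linalg.inv(np.real(sqrtm(overlap)))
    phi = (cutoff - r)[None, :] ** (n[:, None] + 2)  # (n_max, Q)
    return r, wq, inv_sqrt @ phi


def _real_sph_harm(l_max: int, unit: np.ndarray) -> np.ndarray:
    """Real spherical harmonics Y_lm for unit vectors, shape (K, (l_max+1)^2).

    Storage order: l = 0..l_max, m = -l..l within each l.
    """
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
    phi = np.arctan2(unit[:, 1], unit[:, 0])
    out = np.empty((len(unit), (l_max + 1) ** 2))
    for l in range(l_max + 1):
        base = l * l + l  # index of m = 0
        for m in range(l + 1):
            y = sph_harm_y(l, m, theta, phi)
            if m == 0:
                out[:, base] = y.real
            else:
                fac = np.sqrt(2.0) * (-1.0) ** m
                out[:, base + m] = fac * y.real
                out[:, base - m] = fac * y.imag
    return out


def _scaled_bessel_il(l_max: int, z: np.ndarray) -> np.ndarray:
    """e^-z i_l(z) for l = 0..l_max; z >= 0, shape broadcast to (..., l_max+1)."""
    z = np.asarray(z, dtype=float)
    zs = np.maximum(z, 1e-30)
    orders = np.arange(l_max + 1) + 0.5
    vals = np.sqrt(np.pi / (2.0 * zs))[..., None] * ive(orders, zs[..., None])
    # limit z -> 0: i_0 -> 1, i_l -> 0
    small = z < 1e-12
    if np.any(small):
        vals[small] = 0.0
        vals[small, 0] = 1.0
    return vals


class SoapDescriptor(TransformerMixin, BaseEstimator):
    """Transformer mapping structures to per-atom environment descriptors.

    ``fit`` fixes the species alphabet (the union over the fitted dataset) so
    that every transformed descriptor lives in a common vector space, as a
    cross-structure environment kernel requires.  ``transform`` returns one
    ``(n_centers, n_features_)`` array per structure, rows unit-normalized,
    one row per non-masked atom in atom order.
    """

    def __init__(
        self,
        cutoff: float = 4.0,
        atom_sigma: float = 0.3,
        n_max: int = 8,
        l_max: int = 6,
        zeta: float = 2.0,
        species_mask: Sequence[str] = (),
        species_alphabet: Sequence[str] | None = None,
    ):
        self.cutoff = cutoff
        self.atom_sigma = atom_sigma
        self.n_max = n_max
        self.l_max = l_max
        self.zeta = zeta
        self.species_mask = species_mask
        self.species_alphabet = species_alphabet

    @property
    def params(self) -> SoapParams:
        return SoapParams(
            cutoff=self.cutoff,
            atom_sigma=self.atom_sigma,
            n_max=self.n_max,
            l_max=self.l_max,
            zeta=self.zeta,
            species_mask=frozenset(self.species_mask),
        )

    def fit(self, X: Dataset | Iterable[Structure], y=None) -> "SoapDescriptor":
        self.params  # validates hyperparameters
        alphabet: set[str] = set()
        if self.species_alphabet is not None:
            alphabet.update(self.species_alphabet)
        else:
            for s in X:
                alphabet.update(s.species)
        alphabet -= set(self.species_mask)
        if not alphabet:
            raise ValueError("all species masked: empty alphabet")
        self.species_alphabet_ = sorted(alphabet)
        n_sp = len(self.species_alphabet_)
        n_nn = self.n_max * (self.n_max + 1) // 2
        per_l = self.l_max + 1
        self.n_features_ = per_l * (
            n_sp * n_nn + (n_sp * (n_sp - 1) // 2) * self.n_max**2
        )
        self._r, self._wq, self._gq = _radial_basis(self.n_max, self.cutoff)
        # A[n, q] = g_n(r_q) w_q r_q^2  -- the fixed part of every radial integral
        self._A = self._gq * (self._wq * self._r**2)[None, :]
        return self

    def _coefficients(self, s: Structure) -> tuple[np.ndarray, list[str]]:
        """Density coefficients c[center, species, n, l, m] and center species."""
        mask = set(self.species_mask)
        keep = [i for i, sp in enumerate(s.species) if sp not in mask]
        if not keep:
            raise ValueError(f"structure {s.id!r}: all atoms masked")
        unknown = {sp for i, sp in enumerate(s.species) if sp not in mask} - set(
            self.species_alphabet_
        )
        if unknown:
            raise ValueError(
                f"structure {s.id!r} has species outside the fitted alphabet: "
                f"{sorted(unknown)}"
            )
        coords = s.coords[keep]
        species = [s.species[i] for i in keep]
        sp_idx = np.array([self.species_alphabet_.index(sp) for sp in species])
        n_sp = len(self.species_alphabet_)
        lmax, nmax = self.l_max, self.n_max
        n_lm = (lmax + 1) ** 2
        sig2 = self.atom_sigma**2
        c = np.zeros((len(keep), n_sp, nmax, n_lm))
        l_of_lm = np.concatenate(
            [np.full(2 * l + 1, l) for l in range(lmax + 1)]
        )
        for ci in range(len(keep)):
            disp = coords - coords[ci]
            dist = np.linalg.norm(disp, axis=1)
            nb = np.where(dist <= self.cutoff)[0]
            rj = dist[nb]
            fc = 0.5 * (np.cos(np.pi * rj / self.cutoff) + 1.0)
            unit = np.zeros((len(nb), 3))
            far = rj > 1e-12
            unit[far] = disp[nb[far]] / rj[far, None]
            unit[~far, 2] = 1.0  # direction immaterial: only l=0 survives at r=0
            ylm = _real_sph_harm(lmax, unit)  # (K, n_lm)
            # radial integrals R[k, n, l]
            gauss = np.exp(-((self._r[None, :] - rj[:, None]) ** 2) / (2 * sig2))
            il = _scaled_bessel_il(lmax, rj[:, None] * self._r[None, :] / sig2)
            R = np.einsum("nq,kq,kql->knl", self._A, gauss, il)
            contrib = (
                4.0
                * np.pi
                * fc[:, None, None]
                * R[:, :, l_of_lm]
                * ylm[:, None, :]
            )  # (K, n, n_lm)
            np.add.at(c[ci], sp_idx[nb], contrib)
        return c, species

    def _power_spectrum(self, c: np.ndarray) -> np.ndarray:
        """Flatten c[center, a, n, lm] into unit-normalized power spectra."""
        lmax, nmax = self.l_max, self.n_max
        n_sp = c.shape[1]
        lm_slices = [slice(l * l, (l + 1) * (l + 1)) for l in range(lmax + 1)]
        blocks: list[np.ndarray] = []
        iu = np.triu_indices(nmax)
        diag_scale = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
        for a in range(n_sp):
            for b in range(a, n_sp):
                # p[center, n, n', l]
                p = np.stack(
                    [
                        np.einsum("knm,kpm->knp", c[:, a, :, sl], c[:, b, :, sl])
                        for sl in lm_slices
                    ],
                    axis=-1,
                )
                if a == b:
                    p = p[:, iu[0], iu[1], :] * diag_scale[None, :, None]
                    blocks.append(p.reshape(len(c), -1))
                else:
                    blocks.append(np.sqrt(2.0) * p.reshape(len(c), -1))
        vec = np.concatenate(blocks, axis=1)
        norms = np.linalg.norm(vec, axis=1)
        if np.any(norms <= 0) or not np.all(np.isfinite(norms)):
            raise ValueError("degenerate environment descriptor (zero or non-finite)")
        return vec / norms[:, None]

    def transform_structure(self, s: Structure) -> np.ndarray:
        """Descriptor array (n_centers, n_features_) for one structure."""
        if not hasattr(self, "species_alphabet_"):
            raise RuntimeError("SoapDescriptor must be fitted before transform")
        c, _ = self._coefficients(s)
        return self._power_spectrum(c)

    def transform(self, X: Dataset | Iterable[Structure]) -> list[np.ndarray]:
        return [self.transform_structure(s) for s in X]


def compute_descriptors(
    s: Structure,
    p: SoapParams,
    species_alphabet: Sequence[str] | None = None,
) -> list[EnvironmentDescriptor]:
    """Per-atom environment descriptors of one structure.

    ``species_alphabet`` fixes the common vector space; by default it is the
    structure's own species set, which is only appropriate for single
    structures or datasets sharing one composition.
    """
    est = SoapDescriptor(
        cutoff=p.cutoff,
        atom_sigma=p.atom_sigma,
        n_max=p.n_max,
        l_max=p.l_max,
        zeta=p.zeta,
        species_mask=p.species_mask,
    )
    if species_alphabet is None:
        est.fit([s])
    else:
        alphabet = [sp for sp in species_alphabet if sp not in p.species_mask]
        dummy = Structure("alphabet", list(alphabet), np.zeros((len(alphabet), 3)))
        # fit only fixes the alphabet; geometry of the dummy is irrelevant
        est.fit([dummy])
    vecs = est.transform_structure(s)
    centers = [sp for sp in s.species if sp not in p.species_mask]
    return [EnvironmentDescriptor(v, sp) for v, sp in zip(vecs, centers)]


def environment_kernel(
    a: EnvironmentDescriptor | np.ndarray,
    b: EnvironmentDescriptor | np.ndarray,
    zeta: float = 2.0,
) -> float:
    """SOAP environment kernel k(a, b) = (a · b)^zeta, clamped to [0, 1]."""
    va = a.vector if isinstance(a, EnvironmentDescriptor) else np.asarray(a)
    vb = b.vector if isinstance(b, EnvironmentDescriptor) else np.asarray(b)
    if va.shape != vb.shape:
        raise ValueError(f"descriptor length mismatch: {va.shape} vs {vb.shape}")
    dot = float(np.clip(np.dot(va, vb), 0.0, 1.0))
    return dot**zeta


def save_descriptors(
    path: str | Path,
    dataset: Dataset,
    descriptors: Sequence[np.ndarray],
    params: SoapParams,
    species_alphabet: Sequence[str],
) -> None:
    """Persist per-structure descriptor arrays to HDF5 with their parameters."""
    import h5py

    with h5py.File(path, "w") as f:
        grp = f.create_group("descriptors")
        for s, d in zip(dataset, descriptors):
            grp.create_dataset(s.id, data=d)
        f.attrs["structure_ids"] = dataset.ids
        pg = f.create_group("params")
        pg.attrs["cutoff"] = params.cutoff
        pg.attrs["atom_sigma"] = params.atom_sigma
        pg.attrs["n_max"] = params.n_max
        pg.attrs["l_max"] = params.l_max
        pg.attrs["zeta"] = params.zeta
        pg.attrs["species_mask"] = sorted(params.species_mask)
        pg.attrs["species_alphabet"] = list(species_alphabet)


def load_descriptors(
    path: str | Path,
) -> tuple[list[str], list[np.ndarray], SoapParams, list[str]]:
    import h5py

    with h5py.File(path, "r") as f:
        ids = [str(x) for x in f.attrs["structure_ids"]]
        desc = [np.asarray(f["descriptors"][i]) for i in ids]
        pg = f["params"]
        params = SoapParams(
            cutoff=float(pg.attrs["cutoff"]),
            atom_sigma=float(pg.attrs["atom_sigma"]),
            n_max=int(pg.attrs["n_max"]),
            l_max=int(pg.attrs["l_max"]),
            zeta=float(pg.attrs["zeta"]),
            species_mask=frozenset(str(x) for x in pg.attrs["species_mask"]),
        )
        alphabet = [str(x) for x in pg.attrs["species_alphabet"]]
    return ids, desc, params, alphabet
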