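"""Labeled synthetic conformer sets with a controlled torsional landscape.

The generator emulates the statistical structure that conformer-database
analyses rely on: a small chain molecule whose two rotatable torsions sit in
well-separated basins (the analogue of bimodal cis/trans peptide-bond
isomers), Gaussian torsional noise within each basin, a smooth
structure–energy relation, a few planted outliers with torsions far from
every basin, and optionally a subset whose energies carry a constant offset
(emulating entries computed at an inconsistent level of theory).

Each conformer is built by placing a fixed chain template (bond lengths and
angles held rigid) and setting its two torsions to basin centers plus noise.
Energies follow

    E = basin_offset + Σ_t k (1 − cos(θ_t − θ_t,center)) + N(0, σ_noise)   [eV]

so that, absent injected inconsistencies, property spread shrinks together
with structural spread.  Everything is reproducible from the seed, and the
ground-truth basin labels and flags are returned (and written) alongside the
structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structures import Dataset, Structure, write_xyz

__all__ = ["ZAtom", "GeneratorSpec", "generate", "add_cation", "write_truth"]


@dataclass(frozen=True)
class ZAtom:
    """One template atom in internal coordinates.

    ``refs`` are (bonded, angle, dihedral) indices of previously placed
    atoms; ``phi`` is a fixed dihedral in degrees or ``"t<i>"`` naming the
    i-th rotatable torsion.
    """

    species: str
    refs: tuple[int, int, int] | None
    r: float = 0.0
    theta: float = 0.0
    phi: float | str = 0.0


# Butane-like heavy-atom chain with two rotatable torsions (atoms 0-1-2-3 and
# 2-3-4-5) standing in for the two peptide-bond angles; pendant hydrogens
# break the head/tail symmetry.
DEFAULT_TEMPLATE: tuple[ZAtom, ...] = (
    ZAtom("O", None),
    ZAtom("C", (0, -1, -1), 1.43),
    ZAtom("N", (1, 0, -1), 1.47, 112.0),
    ZAtom("C", (2, 1, 0), 1.47, 112.0, "t0"),
    ZAtom("C", (3, 2, 1), 1.52, 112.0, 180.0),
    ZAtom("O", (4, 3, 2), 1.43, 112.0, "t1"),
    ZAtom("H", (1, 0, 2), 1.01, 109.5, 120.0),
    ZAtom("H", (4, 3, 2), 1.01, 109.5, 60.0),
)

TORSION_QUADS: tuple[tuple[int, int, int, int], ...] = ((0, 1, 2, 3), (2, 3, 4, 5))


def _place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, phi: float
) -> np.ndarray:
    """NeRF placement of atom D with |CD| = r, angle(B,C,D) = theta and
    dihedral(A,B,C,D) = phi (degrees, IUPAC sign convention)."""
    th = np.radians(theta)
    ph = np.radians(phi)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * np.cos(th), r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_conformer(
    torsions: Sequence[float], template: Sequence[ZAtom] = DEFAULT_TEMPLATE
) -> tuple[list[str], np.ndarray]:
    """Cartesian coordinates of the template at the given torsion angles."""
    coords = np.zeros((len(template), 3))
    species: list[str] = []
    for i, atom in enumerate(template):
        species.append(atom.species)
        if atom.refs is None:
            coords[i] = 0.0
        elif atom.refs[1] < 0:  # second atom: along +x
            coords[i] = coords[atom.refs[0]] + np.array([atom.r, 0.0, 0.0])
        elif atom.refs[2] < 0:  # third atom: in the xy-plane
            b, aref = atom.refs[0], atom.refs[1]
            fake_a = coords[aref] + np.array([0.0, 0.0, 1.0])
            coords[i] = _place(
                fake_a, coords[aref], coords[b], atom.r, atom.theta, 90.0
            )
        else:
            b, aref, dref = atom.refs
            phi = atom.phi
            if isinstance(phi, str):
                phi = float(torsions[int(phi[1:])])
            coords[i] = _place(
                coords[dref], coords[aref], coords[b], atom.r, atom.theta, float(phi)
            )
    return species, coords


def _default_centers(n_basins: int) -> list[tuple[float, ...]]:
    base = [(180.0, 180.0), (0.0, 180.0), (180.0, 0.0), (0.0, 0.0)]
    if n_basins <= len(base):
        return base[:n_basins]
    raise ValueError(
        "no default torsion centers beyond 4 basins; supply torsion_centers"
    )


@dataclass
class GeneratorSpec:
    """Study conditions of a synthetic conformer set.

    Defaults: 200 structures in 2 torsional basins (trans–trans and
    cis–trans), 5° torsional noise, basin offsets 0 / 0.3 eV, torsional
    stiffness 1 eV, 10 meV energy noise, 1% planted outliers and no
    inconsistent subset unless requested (0.5 eV offset when present).
    """

    n_structures: int = 200
    n_basins: int = 2
    torsion_centers: list[tuple[float, ...]] | None = None
    torsion_noise: float = 5.0  # degrees
    basin_offsets: list[float] | None = None  # eV
    k_torsion: float = 1.0  # eV
    energy_noise: float = 0.01  # eV
    outlier_fraction: float = 0.01
    inconsistent_fraction: float = 0.0
    inconsistent_offset: float = 0.5  # eV
    seed: int = 0
    template: tuple[ZAtom, ...] = DEFAULT_TEMPLATE

    def __post_init__(self) -> None:
        if self.n_basins < 1:
            raise ValueError("n_basins must be >= 1")
        if self.torsion_noise <= 0:
            raise ValueError("torsion_noise must be > 0")
        for frac in (self.outlier_fraction, self.inconsistent_fraction):
            if not 0 <= frac < 1:
                raise ValueError("fractions must lie in [0, 1)")
        if self.torsion_centers is None:
            self.torsion_centers = _default_centers(self.n_basins)
        if len(self.torsion_centers) != self.n_basins:
            raise ValueError("need one torsion-center tuple per basin")
        if self.basin_offsets is None:
            self.basin_offsets = [0.3 * b for b in range(self.n_basins)]
        if len(self.basin_offsets) != self.n_basins:
            raise ValueError("need one basin offset per basin")


def _circ_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b) % 360.0
    return np.minimum(d, 360.0 - d)


def _min_clash(coords: np.ndarray) -> float:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    iu = np.triu_indices(len(coords), k=1)
    return float(d[iu].min())


def generate(
    spec: GeneratorSpec,
) -> tuple[Dataset, dict[str, int], dict[str, dict[str, bool]]]:
    """Build the dataset plus ground truth.

    Returns ``(dataset, labels, truth)`` where ``labels`` maps structure id
    to basin index (−1 for planted outliers) and ``truth`` maps id to
    ``{"outlier": bool, "inconsistent": bool}``.  Deterministic in the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_structures
    n_torsions = len(spec.torsion_centers[0])
    centers = np.asarray(spec.torsion_centers, dtype=float)

    n_out = int(round(spec.outlier_fraction * n))
    order = rng.permutation(n)
    outlier_idx = set(order[:n_out].tolist())
    n_inc = int(round(spec.inconsistent_fraction * (n - n_out)))
    inc_idx = set(order[n_out : n_out + n_inc].tolist())

    structures: list[Structure] = []
    labels: dict[str, int] = {}
    truth: dict[str, dict[str, bool]] = {}
    width = len(str(max(n - 1, 1)))
    for i in range(n):
        sid = f"conf-{i:0{width}d}"
        is_out = i in outlier_idx
        if is_out:
            # torsion tuple maximizing its minimum circular distance to all
            # basin centers, searched over seeded random candidates
            cand = rng.uniform(-180.0, 180.0, size=(200, n_torsions))
            score = np.array(
                [
                    min(_circ_dist(c, ctr).min() for ctr in centers)
                    for c in cand
                ]
            )
            base = cand[int(np.argmax(score))]
            basin = -1
        else:
            basin = int(rng.integers(spec.n_basins))
            base = centers[basin]
        for attempt in range(100):
            tors = base + rng.normal(scale=spec.torsion_noise, size=n_torsions)
            species, coords = build_conformer(tors, spec.template)
            if _min_clash(coords) >= 0.5:
                break
        else:
            raise RuntimeError(f"could not build clash-free geometry for {sid}")
        ref = centers[basin] if basin >= 0 else base
        nearest = centers[np.argmin([_circ_dist(tors, c).max() for c in centers])]
        tref = ref if basin >= 0 else nearest
        e = (
            (spec.basin_offsets[basin] if basin >= 0 else 0.0)
            + spec.k_torsion
            * float(np.sum(1.0 - np.cos(np.radians(tors - tref))))
            + rng.normal(scale=spec.energy_noise)
        )
        is_inc = i in inc_idx
        if is_inc:
            e += spec.inconsistent_offset
        structures.append(Structure(sid, species, coords, {"energy": e}))
        labels[sid] = basin
        truth[sid] = {"outlier": is_out, "inconsistent": is_inc}
    return Dataset(structures, name="synthetic"), labels, truth


def add_cation(
    dataset: Dataset,
    species: str = "Ca",
    distance: float = 2.4,
    seed: int = 0,
) -> Dataset:
    """Decorate each conformer with one cation near a random O or N atom.

    Emulates a perturbed (cation-bound) copy of a database for the
    species-masked projection workflow; geometries are otherwise unchanged.
    """
    rng = np.random.default_rng(seed)
    out: list[Structure] = []
    for s in dataset:
        anchors = [i for i, sp in enumerate(s.species) if sp in ("O", "N")]
        if not anchors:
            anchors = list(range(s.n_atoms))
        for attempt in range(200):
            anchor = s.coords[anchors[int(rng.integers(len(anchors)))]]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = anchor + distance * u
            if np.linalg.norm(s.coords - pos, axis=1).min() >= 1.8:
                break
        else:
            raise RuntimeError(f"could not place cation for {s.id}")
        out.append(
            Structure(
                s.id,
                list(s.species) + [species],
                np.vstack([s.coords, pos]),
                dict(s.properties),
            )
        )
    return Dataset(out, name=dataset.name + f"+{species}")


def write_truth(
    path: str | Path,
    dataset: Dataset,
    labels: dict[str, int],
    truth: dict[str, dict[str, bool]],
) -> None:
    """Ground-truth sidecar TSV: id, basin, outlier, inconsistent, energy."""
    import pandas as pd

    rows = [
        (
            s.id,
            labels[s.id],
            truth[s.id]["outlier"],
            truth[s.id]["inconsistent"],
            s.properties.get("energy", np.nan),
        )
        for s in dataset
    ]
    pd.DataFrame(
        rows, columns=["id", "basin", "outlier", "inconsistent", "energy"]
    ).to_csv(path, sep="\t", index=False)
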