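"""Conformer containers, extended-XYZ I/O and geometric order parameters.

A :class:`Structure` is the unit of database membership: an ordered list of
element symbols and Cartesian coordinates (Å), plus optional scalar
properties (e.g. ``energy`` in eV) carried on the extended-XYZ comment line
as ``key=value`` pairs.  A :class:`Dataset` is an ordered list of structures;
its order defines row/column indices of every kernel and distance matrix
downstream.

Order parameters used to interpret maps and dendrograms — signed torsion
angles (the φ/ψ/ω dihedrals of peptide backbones) and minimum cross-group
distances (H-bond indicators such as D_ON or D_H) — are computed here from
user-supplied 0-based atom indices; the package performs no bond perception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Structure",
    "Dataset",
    "read_xyz",
    "write_xyz",
    "dihedral",
    "min_group_distance",
]


@dataclass
class Structure:
    """One conformer: element symbols, coordinates (Å), scalar properties."""

    id: str
    species: list[str]
    coords: np.ndarray  # (n_atoms, 3), Å
    properties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n_atoms, 3), got {self.coords.shape}")
        if len(self.species) != len(self.coords):
            raise ValueError(
                f"species ({len(self.species)}) and coords ({len(self.coords)}) "
                "lengths differ"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"structure {self.id!r} has non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def copy(self) -> "Structure":
        return Structure(
            self.id, list(self.species), self.coords.copy(), dict(self.properties)
        )


@dataclass
class Dataset:
    """Ordered collection of structures; order fixes matrix indices."""

    structures: list[Structure]
    name: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.structures]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate structure ids in dataset: {dupes}")

    def __len__(self) -> int:
        return len(self.structures)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.structures)

    def __getitem__(self, i: int) -> Structure:
        return self.structures[i]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.structures]

    def index_of(self, sid: str) -> int:
        for i, s in enumerate(self.structures):
            if s.id == sid:
                return i
        raise KeyError(sid)

    def species_alphabet(self) -> list[str]:
        """Sorted union of element symbols over the whole dataset."""
        seen: set[str] = set()
        for s in self.structures:
            seen.update(s.species)
        return sorted(seen)


def _parse_comment(comment: str) -> dict[str, float]:
    """Extract scalar float key=value pairs from an extended-XYZ comment."""
    props: dict[str, float] = {}
    for token in comment.split():
        if "=" not in token:
            continue
        key, _, raw = token.partition("=")
        if not key:
            continue
        try:
            props[key] = float(raw)
        except ValueError:
            continue  # non-scalar values are preserved as opaque text only
    return props


def read_xyz(
    path: str | Path,
    property_keys: Sequence[str] | None = None,
    name: str | None = None,
) -> Dataset:
    """Read concatenated extended-XYZ frames into a :class:`Dataset`.

    Each frame is: an atom-count line, a comment line optionally holding
    whitespace-separated ``key=value`` pairs, then one ``symbol x y z`` line
    per atom.  Frame ids default to ``frame-<index>`` unless the comment
    carries an ``id=...`` token (kept verbatim).

    Parameters
    ----------
    path:
        File of concatenated frames.
    property_keys:
        Scalar properties to pull from the comment line; keys absent from a
        frame are simply absent from that structure.  ``None`` keeps every
        parseable scalar.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    structures: list[Structure] = []
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(
                f"frame {frame}: expected atom count, got {lines[pos]!r}"
            ) from exc
        if pos + 1 >= len(lines):
            raise ValueError(f"frame {frame}: missing comment line")
        comment = lines[pos + 1]
        species: list[str] = []
        coords = np.empty((natoms, 3), dtype=float)
        for a in range(natoms):
            lineno = pos + 2 + a
            if lineno >= len(lines):
                raise ValueError(f"frame {frame}: truncated at atom {a}")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ValueError(
                    f"frame {frame}: malformed atom line {a}: {lines[lineno]!r}"
                )
            species.append(parts[0])
            try:
                coords[a] = [float(x) for x in parts[1:4]]
            except ValueError as exc:
                raise ValueError(
                    f"frame {frame}: unparsable coordinate on atom line {a}: "
                    f"{lines[lineno]!r}"
                ) from exc
        all_props = _parse_comment(comment)
        if property_keys is None:
            props = all_props
        else:
            props = {k: all_props[k] for k in property_keys if k in all_props}
        sid = f"frame-{frame}"
        for token in comment.split():
            if token.startswith("id="):
                sid = token[3:]
                break
        structures.append(Structure(sid, species, coords, props))
        pos += 2 + natoms
        frame += 1
    return Dataset(structures, name=name if name is not None else path.stem)


def write_xyz(dataset: Dataset | Iterable[Structure], path: str | Path) -> None:
    """Write structures as concatenated extended-XYZ frames.

    The comment line carries ``id=<id>`` followed by every scalar property as
    ``key=value`` with full float precision, so a write/read round trip
    reproduces the dataset.
    """
    structures = list(dataset)
    out: list[str] = []
    for s in structures:
        out.append(str(s.n_atoms))
        tokens = [f"id={s.id}"]
        tokens += [f"{k}={v!r}" for k, v in s.properties.items()]
        out.append(" ".join(tokens))
        for sym, (x, y, z) in zip(s.species, s.coords):
            out.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(out) + "\n")


def dihedral(s: Structure, i: int, j: int, k: int, l: int) -> float:
    """Signed torsion angle (degrees, in (−180, 180]) about the j–k axis.

    IUPAC convention: looking from j towards k, a clockwise rotation of the
    i-side onto the l-side is positive.  A planar cis arrangement gives 0°,
    trans gives 180°.
    """
    idx = (i, j, k, l)
    if len(set(idx)) != 4:
        raise ValueError(f"dihedral needs four distinct atom indices, got {idx}")
    p = s.coords
    b1 = p[j] - p[i]
    b2 = p[k] - p[j]
    b3 = p[l] - p[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * max(1.0, nb2) or np.linalg.norm(n2) < 1e-10 * max(
        1.0, nb2
    ):
        raise ValueError(
            f"torsion undefined: atoms {idx} contain a collinear triple"
        )
    # atan2 form is numerically stable near 0 and 180 degrees
    ang = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def min_group_distance(
    s: Structure, group_a: Sequence[int], group_b: Sequence[int]
) -> float:
    """Minimum Euclidean distance (Å) over all cross pairs of two atom groups.

    The usual H-bond indicator for flexible molecules, e.g.
    D_ON = min over backbone O atoms of their distance to a side-chain N.
    """
    a = list(group_a)
    b = list(group_b)
    if not a or not b:
        raise ValueError("groups must be non-empty")
    if set(a) & set(b):
        raise ValueError(f"groups overlap: {sorted(set(a) & set(b))}")
    pa = s.coords[a]  # (na, 3)
    pb = s.coords[b]  # (nb, 3)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())
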