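"""Ring-lattice geometry: ideal microtubule reference rings, rigid
superposition, and radial/axial displacement profiles.

A nucleation template is microtubule-like when its ring of subunit
centres of mass matches the helical lattice of a 13-protofilament
microtubule.  This module builds an ideal lattice ring (per-subunit
angular spacing 2π/13, constant radius, constant axial rise), rigidly
superposes an observed ring onto the reference (Kabsch least squares,
proper rotations only, with an anchor subunit fixing the index
registration), and reports per-subunit radial and axial displacements
from the reference lattice — values near zero indicate microtubule-like
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "RingModel",
    "DisplacementProfile",
    "RigidTransform",
    "centre_of_mass",
    "build_reference_ring",
    "align_rings",
    "displacement_profile",
    "read_ca_centres",
]

N_PROTOFILAMENTS = 13  # canonical microtubule lattice
DEFAULT_RADIUS_A = 112.0  # ring radius, Å (13-pf B-lattice convention)
DEFAULT_RISE_A = 9.4  # axial rise per subunit, Å (monomer rise)


@dataclass
class RingModel:
    """Ordered subunit centres of mass with a helical-axis frame.

    ``subunits`` maps a 1-based, consecutive subunit index to its 3D
    centre of mass (Å); ``axis_origin``/``axis_direction`` define the
    helical axis (direction normalized).
    """

    subunits: dict[int, np.ndarray]
    axis_origin: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    label: str = ""

    def __post_init__(self) -> None:
        self.subunits = {int(k): np.asarray(v, dtype=float)
                         for k, v in self.subunits.items()}
        if len(self.subunits) < 3:
            raise ValueError("a ring needs at least 3 subunits")
        idx = sorted(self.subunits)
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("subunit indices must be consecutive from 1")
        self.axis_origin = np.asarray(self.axis_origin, dtype=float)
        d = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("axis direction must be nonzero")
        self.axis_direction = d / norm

    @property
    def indices(self) -> list[int]:
        return sorted(self.subunits)

    def coords(self, indices: Sequence[int] | None = None) -> np.ndarray:
        idx = self.indices if indices is None else list(indices)
        return np.array([self.subunits[i] for i in idx])

    def radial_distance(self, point: np.ndarray) -> float:
        """Distance of a point from this ring's axis."""
        rel = np.asarray(point, dtype=float) - self.axis_origin
        along = rel @ self.axis_direction
        return float(np.linalg.norm(rel - along * self.axis_direction))

    def axial_coordinate(self, point: np.ndarray) -> float:
        rel = np.asarray(point, dtype=float) - self.axis_origin
        return float(rel @ self.axis_direction)

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "RingModel":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return RingModel(
            {i: R @ p + t for i, p in self.subunits.items()},
            axis_origin=R @ self.axis_origin + t,
            axis_direction=R @ self.axis_direction,
            label=self.label)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [{"index": i, "x": p[0], "y": p[1], "z": p[2]}
             for i, p in sorted(self.subunits.items())]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "RingModel":
        df = pd.read_csv(path)
        return cls({int(r["index"]): np.array([r["x"], r["y"], r["z"]])
                    for _, r in df.iterrows()}, label=label)


@dataclass
class RigidTransform:
    """Proper rotation + translation, applied as x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class DisplacementProfile:
    """Per-subunit signed radial/axial displacement from a reference.

    Radial: (test distance from the reference axis) minus (reference
    subunit distance from the axis); positive = outside the reference
    radius.  Axial: (test - reference) projected on the axis direction.
    """

    indices: list[int]
    radial: np.ndarray
    axial: np.ndarray
    skipped: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.radial = np.asarray(self.radial, dtype=float)
        self.axial = np.asarray(self.axial, dtype=float)
        if not (len(self.indices) == self.radial.size == self.axial.size):
            raise ValueError("profile arrays must match index count")
        if not (np.isfinite(self.radial).all()
                and np.isfinite(self.axial).all()):
            raise ValueError("displacements must be finite")

    def summary(self) -> dict[str, float]:
        return {"mean_abs_radial": float(np.mean(np.abs(self.radial))),
                "mean_abs_axial": float(np.mean(np.abs(self.axial))),
                "mean_radial": float(np.mean(self.radial)),
                "mean_axial": float(np.mean(self.axial))}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": self.indices, "radial": self.radial,
                             "axial": self.axial,
                             "abs_axial": np.abs(self.axial)})


def centre_of_mass(coords: Sequence[Sequence[float]]) -> np.ndarray:
    """Unweighted mean of 3D coordinates."""
    arr = np.asarray(coords, dtype=float)
    if arr.size == 0:
        raise ValueError("no coordinates")
    arr = arr.reshape(-1, 3)
    return arr.mean(axis=0)


def build_reference_ring(n_subunits: int = 13,
                         radius: float = DEFAULT_RADIUS_A,
                         rise_per_subunit: float = DEFAULT_RISE_A,
                         phase0: float = 0.0) -> RingModel:
    """Construct an ideal 13-protofilament-lattice ring on the z axis.

    Subunit i sits at angle ``phase0 + 2π (i-1)/13`` (the angular spacing
    is fixed by the 13-pf lattice even for partial rings), radius
    ``radius`` and height ``(i-1) rise_per_subunit``.  At most one turn
    (13 subunits) is allowed.
    """
    if n_subunits < 3:
        raise ValueError("need at least 3 subunits")
    if n_subunits > N_PROTOFILAMENTS:
        raise ValueError("at most 13 subunits (one turn) with 13-pf "
                         "spacing")
    if radius <= 0:
        raise ValueError("radius must be positive")
    step = 2.0 * np.pi / N_PROTOFILAMENTS
    subunits = {}
    for i in range(1, n_subunits + 1):
        ang = phase0 + step * (i - 1)
        subunits[i] = np.array([radius * np.cos(ang),
                                radius * np.sin(ang),
                                (i - 1) * rise_per_subunit])
    return RingModel(subunits, label="ideal-13pf")


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t with
    R P_i + t ≈ Q_i."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(Q - qc, P - pc)
    R = rot.as_matrix()
    t = qc - R @ pc
    return R, t


def align_rings(test: RingModel, reference: RingModel, anchor: int = 6
                ) -> tuple[RingModel, RigidTransform, float]:
    """Rigidly superpose a test ring onto a reference ring.

    Subunit correspondence is by index, registered at the ``anchor``
    subunit (the anchor must be present in both rings; it fixes the
    registration but the least-squares superposition uses all shared
    subunits).  Reflections are forbidden (proper rotation only).
    Returns the transformed test ring, the transform, and the RMSD over
    shared subunit centres.
    """
    shared = sorted(set(test.subunits) & set(reference.subunits))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared subunit indices")
    if anchor not in shared:
        raise ValueError(f"anchor subunit {anchor} not shared")
    P = test.coords(shared)
    Q = reference.coords(shared)
    for X, name in ((P, "test"), (Q, "reference")):
        if np.linalg.matrix_rank(X - X.mean(axis=0), tol=1e-9) < 2:
            raise ValueError(f"degenerate (collinear) {name} ring")
    R, t = _kabsch(P, Q)
    moved = test.transformed(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum(
        (moved.coords(shared) - Q) ** 2, axis=1))))
    return moved, RigidTransform(R, t), rmsd


def displacement_profile(test_aligned: RingModel, reference: RingModel
                         ) -> DisplacementProfile:
    """Per-subunit radial/axial displacement of an aligned test ring
    relative to the reference ring's helical axis.

    Subunit indices present in only one ring are skipped and listed in
    ``skipped``.
    """
    shared = sorted(set(test_aligned.subunits) & set(reference.subunits))
    skipped = sorted((set(test_aligned.subunits)
                      ^ set(reference.subunits)))
    if not shared:
        raise ValueError("no shared subunit indices")
    radial, axial = [], []
    for i in shared:
        p_t, p_r = test_aligned.subunits[i], reference.subunits[i]
        radial.append(reference.radial_distance(p_t)
                      - reference.radial_distance(p_r))
        axial.append(float((p_t - p_r) @ reference.axis_direction))
    return DisplacementProfile(shared, np.array(radial), np.array(axial),
                               skipped=skipped)


def read_ca_centres(structure_text: str,
                    chains: Sequence[str] | None = None
                    ) -> dict[str, np.ndarray]:
    """Per-chain Cα centres of mass from PDB-format ATOM records.

    ``structure_text`` is the content of a PDB file; fixed-column ATOM
    records are parsed and the unweighted mean of Cα coordinates is
    returned per requested chain (all chains when None).  Malformed ATOM
    records raise a parse error naming the line; requested chains
    without Cα atoms raise an error listing them.
    """
    per_chain: dict[str, list[np.ndarray]] = {}
    for lineno, line in enumerate(structure_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        try:
            name = line[12:16].strip()
            chain = line[21].strip() or "_"
            xyz = np.array([float(line[30:38]), float(line[38:46]),
                            float(line[46:54])])
        except (ValueError, IndexError) as err:
            raise ValueError(
                f"malformed ATOM record at line {lineno}: {err}") from err
        if name == "CA":
            per_chain.setdefault(chain, []).append(xyz)
    wanted = list(chains) if chains is not None else sorted(per_chain)
    missing = [c for c in wanted if c not in per_chain]
    if missing:
        raise ValueError(f"chains without Cα atoms: {missing}")
    return {c: centre_of_mass(per_chain[c]) for c in wanted}
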