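"""Geometric primitives: Kabsch superposition, RMSD, gyration and rotation
tensors, center-of-mass displacements.

These back the ensemble-shape analysis of a two-domain protein: the gyration
tensor and its sorted components quantify the overall (prolate) shape, and
domain rotation/COM displacement relative to a reference conformation
quantify interdomain rearrangement after anchoring on one domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Selection, Structure


class DegenerateFitError(ValueError):
    """Raised when a superposition problem is under-determined."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference.

    ``transform(x) = x @ rotation.T + translation`` minimises the RMSD over
    the fitted atoms; ``rotation`` is a proper rotation (det = +1).
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class GyrationSummary:
    """Radius of gyration and its principal components, ascending (Å)."""

    rg: float
    components: tuple[float, float, float]  # rgx <= rgy <= rgz
    principal_axes: np.ndarray  # rows are axes, matching components
    unit: str = "angstrom"

    def to_nm(self) -> "GyrationSummary":
        return GyrationSummary(
            self.rg * 0.1, tuple(c * 0.1 for c in self.components), self.principal_axes, "nm"
        )


def _check_points(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name} must be an (N, 3) array")
    return x


def superpose(
    mobile: np.ndarray | Structure,
    reference: np.ndarray | Structure,
    fit_selection: Selection | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch, reflection-corrected).

    ``mobile`` / ``reference`` may be coordinate arrays or Structures; with a
    ``fit_selection`` the fit uses only the selected atoms of each Structure.
    Requires >= 3 non-collinear point pairs.
    """
    if isinstance(mobile, Structure):
        mobile = (mobile.select(fit_selection) if fit_selection else mobile).coords
    if isinstance(reference, Structure):
        reference = (reference.select(fit_selection) if fit_selection else reference).coords
    x = _check_points(mobile, "mobile")
    y = _check_points(reference, "reference")
    if x.shape != y.shape:
        raise ValueError(f"point counts differ: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 3:
        raise DegenerateFitError("need at least 3 point pairs")
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    # collinearity: rank of the centered cloud
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2 or np.linalg.matrix_rank(y0, tol=1e-8) < 2:
        raise DegenerateFitError("points are collinear; rotation under-determined")
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc
    moved = x @ rot.T + trans
    val = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=val)


def rmsd(
    a: np.ndarray | Structure,
    b: np.ndarray | Structure,
    fit: bool = True,
    selection: Selection | None = None,
) -> float:
    """RMSD between paired coordinate sets, optionally after superposition."""
    if isinstance(a, Structure):
        a = (a.select(selection) if selection else a).coords
    if isinstance(b, Structure):
        b = (b.select(selection) if selection else b).coords
    a = _check_points(a, "a")
    b = _check_points(b, "b")
    if a.shape != b.shape:
        raise ValueError("coordinate sets differ in size")
    if fit:
        return superpose(a, b).rmsd
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def center_of_mass(structure: Structure, mass_weighted: bool = True) -> np.ndarray:
    w = structure.masses() if mass_weighted else np.ones(structure.n_atoms)
    return np.average(structure.coords, axis=0, weights=w)


def gyration(structure: Structure, mass_weighted: bool = True) -> GyrationSummary:
    """Gyration tensor eigen-analysis about the center of mass.

    The components are the square roots of the sorted eigenvalues of the
    (optionally mass-weighted) gyration tensor, so rg^2 = rgx^2 + rgy^2 +
    rgz^2.  For a prolate particle rgx << rgy ~ rgz.
    """
    w = structure.masses() if mass_weighted else np.ones(structure.n_atoms)
    com = np.average(structure.coords, axis=0, weights=w)
    d = structure.coords - com
    t = (w[:, None] * d).T @ d / w.sum()
    evals, evecs = np.linalg.eigh(t)  # ascending
    evals = np.clip(evals, 0.0, None)
    comps = tuple(float(np.sqrt(v)) for v in evals)
    return GyrationSummary(
        rg=float(np.sqrt(evals.sum())), components=comps, principal_axes=evecs.T.copy()
    )


def rotation_axis_angle(rot: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (unit vector) and angle in degrees of a proper rotation matrix."""
    cos = (np.trace(rot) - 1.0) / 2.0
    angle = float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
    w, v = np.linalg.eig(rot)
    i = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, i])
    axis = axis / np.linalg.norm(axis)
    # orient the axis so that the rotation about it is by +angle
    if angle not in (0.0, 180.0):
        test = np.array([
            rot[2, 1] - rot[1, 2],
            rot[0, 2] - rot[2, 0],
            rot[1, 0] - rot[0, 1],
        ])
        if np.dot(axis, test) < 0:
            axis = -axis
    return axis, angle


def domain_rotation(
    conformer: Structure,
    reference: Structure,
    anchor: Selection,
    probe: Selection,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Rotation of the probe domain relative to the reference, after anchoring.

    Superposes ``conformer`` onto ``reference`` over the anchor selection
    (e.g. C-SH2 Cα), then fits the probe domain (e.g. N-SH2 Cα) onto the
    reference probe; returns (rotation matrix, axis, angle in degrees) of
    that residual fit — the "rotation tensor" of the probe domain.
    """
    anchor_fit = superpose(conformer.select(anchor).coords, reference.select(anchor).coords)
    probe_moved = anchor_fit.apply(conformer.select(probe).coords)
    probe_fit = superpose(probe_moved, reference.select(probe).coords)
    axis, angle = rotation_axis_angle(probe_fit.rotation)
    return probe_fit.rotation, axis, angle


def com_distance(
    conformer: Structure,
    reference: Structure,
    anchor: Selection,
    probe: Selection,
    mass_weighted: bool = True,
) -> float:
    """Probe-domain center-of-mass displacement after anchor superposition (Å)."""
    anchor_fit = superpose(conformer.select(anchor).coords, reference.select(anchor).coords)
    probe_c = conformer.select(probe)
    probe_r = reference.select(probe)
    w = probe_c.masses() if mass_weighted else np.ones(probe_c.n_atoms)
    com_c = np.average(anchor_fit.apply(probe_c.coords), axis=0, weights=w)
    wr = probe_r.masses() if mass_weighted else np.ones(probe_r.n_atoms)
    com_r = np.average(probe_r.coords, axis=0, weights=wr)
    return float(np.linalg.norm(com_c - com_r))
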