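"""Synthetic two-domain ensembles with known ground truth.

The generator emulates the statistical structure of a tandem-SH2-like
protein in solution: two internally rigid ~100-residue domains joined by a
short flexible linker, so that interdomain orientation is heterogeneous
(one, several, or a continuum of pose basins) while the overall particle
shape stays prolate.  Residue numbering mirrors the tandem SH2 construct by
default — domain A on residues 3-104, linker 105-111 (Cα trace only),
domain B on 112-216 — so the package's named selections apply unchanged.

Ground truth (pose labels, per-conformer surrogate alignment tensors, noise
levels, seeds) is recorded so that every downstream analysis stage can be
tested as a parameter-recovery problem.  Surrogate tensors take their
principal axes from each conformer's gyration tensor — a stand-in with the
right covariance properties for steric alignment of a rigid shape, not a
physical alignment prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import constants
from .geometry import gyration
from .rdc_analysis import AlignmentTensor, RDCRecord, back_calculate, internuclear_vectors
from .saxs_debye import SaxsCurve, ensemble_curve
from .structure_io import Ensemble, Structure

_CA_SPACING = 3.8  # Å

_AA3 = sorted(constants.RESIDUE_ELECTRONS)


class InfeasibleDistributionError(RuntimeError):
    """Raised when pose sampling rejects essentially every attempt."""


class DegenerateShapeError(ValueError):
    """Raised when a conformer's shape has no unique long axis."""


@dataclass(frozen=True)
class DomainTemplate:
    """One rigid pseudo-domain: backbone structure + linker attachment."""

    structure: Structure
    anchor_residues: tuple[int, int]  # (first, last) residue numbers


@dataclass(frozen=True)
class PoseBasin:
    """One basin of the interdomain pose distribution.

    Rotation is axis-angle (degrees) applied to domain B about its centroid;
    translation is the domain-B centroid position relative to domain A's
    centroid (Å).  Spreads are Gaussian (degrees / Å).
    """

    axis: tuple[float, float, float]
    angle_deg: float
    translation: tuple[float, float, float]
    angular_spread_deg: float = 0.0
    translational_spread: float = 0.0
    weight: float = 1.0


@dataclass(frozen=True)
class PoseDistribution:
    mode: str  # homogeneous | multibasin | continuum
    basins: tuple[PoseBasin, ...]

    def __post_init__(self):
        if self.mode not in ("homogeneous", "multibasin", "continuum"):
            raise ValueError(f"unknown mode {self.mode!r}")
        w = np.array([b.weight for b in self.basins])
        if len(w) == 0 or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("basin weights must be non-negative and sum > 0")
        for b in self.basins:
            if self.mode != "homogeneous" and (
                b.angular_spread_deg < 0 or b.translational_spread < 0
            ):
                raise ValueError("spreads must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([b.weight for b in self.basins], dtype=float)
        return w / w.sum()


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    pose_labels: np.ndarray                       # basin index per conformer
    tensors: list[AlignmentTensor] = field(default_factory=list)
    rdc_noise_sd: float | None = None
    saxs_noise: tuple[float, float] | None = None
    seed: int | None = None


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def _random_rotation(rng: np.random.Generator, max_angle_rad: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return _rotation_about(axis, rng.uniform(0.0, max_angle_rad))


def _gaussian_rotation(rng: np.random.Generator, spread_rad: float) -> np.ndarray:
    if spread_rad == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return _rotation_about(axis, rng.normal(0.0, spread_rad))


# ----------------------------------------------------------------------
# pseudo-domain construction
# ----------------------------------------------------------------------

def _compact_ca_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding Cα walk with 3.8 Å steps biased towards compactness."""
    target_radius = 2.4 * n ** (1.0 / 3.0)
    pos = [np.zeros(3)]
    attempts = 0
    while len(pos) < n:
        cur = pos[-1]
        d = np.linalg.norm(cur)
        bias = -cur / d * min(1.0, d / target_radius) if d > 1e-9 else np.zeros(3)
        step = rng.normal(size=3) + 0.8 * bias
        step = step / np.linalg.norm(step) * _CA_SPACING
        cand = cur + step
        others = np.asarray(pos[:-1])
        if len(others) == 0 or np.min(np.linalg.norm(others - cand, axis=1)) >= 3.0:
            pos.append(cand)
            attempts = 0
        else:
            attempts += 1
            if attempts > 500:  # back up one residue and retry
                pos.pop()
                attempts = 0
    arr = np.asarray(pos)
    return arr - arr.mean(axis=0)


def _backbone_from_ca(ca: np.ndarray) -> dict[str, np.ndarray]:
    """Idealized N, C', O placement from a Cα trace.

    Geometry is schematic (not Ramachandran-derived) but deterministic and
    locally planar, giving well-spread internuclear vector orientations.
    """
    n = len(ca)
    nxt = np.empty((n, 3))
    prv = np.empty((n, 3))
    nxt[:-1] = ca[1:] - ca[:-1]
    nxt[-1] = ca[-1] - ca[-2]
    prv[1:] = ca[:-1] - ca[1:]
    prv[0] = -(ca[1] - ca[0])
    nxt /= np.linalg.norm(nxt, axis=1, keepdims=True)
    prv /= np.linalg.norm(prv, axis=1, keepdims=True)
    normal = np.cross(nxt, prv)
    norms = np.linalg.norm(normal, axis=1, keepdims=True)
    fallback = np.cross(nxt, np.array([0.0, 0.0, 1.0]))
    fb_norms = np.linalg.norm(fallback, axis=1, keepdims=True)
    normal = np.where(norms > 1e-6, normal / np.where(norms > 1e-6, norms, 1.0),
                      fallback / np.where(fb_norms > 1e-6, fb_norms, 1.0))
    ndir = prv + 0.5 * normal
    ndir /= np.linalg.norm(ndir, axis=1, keepdims=True)
    cdir = nxt - 0.5 * normal
    cdir /= np.linalg.norm(cdir, axis=1, keepdims=True)
    n_pos = ca + 1.46 * ndir
    c_pos = ca + 1.52 * cdir
    o_dir = np.cross(cdir, normal)
    o_dir /= np.linalg.norm(o_dir, axis=1, keepdims=True)
    o_pos = c_pos + 1.23 * o_dir
    return {"N": n_pos, "C": c_pos, "O": o_pos}


def _amide_h(n_pos: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    u = c_prev - n_pos
    v = ca - n_pos
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    b = u + v
    return n_pos - b / np.linalg.norm(b) * 1.02


def make_pseudo_domain(
    n_residues: int,
    seed: int,
    first_residue: int = 1,
    chain_id: str = "A",
) -> DomainTemplate:
    """Procedurally build one compact rigid pseudo-domain.

    Backbone atoms N, Cα, C', O per residue plus amide H (absent on the
    first residue); consecutive Cα spacing 3.8 Å; non-adjacent Cα pairs
    >= 3.0 Å apart.  Deterministic for a given (n_residues, seed).
    """
    if n_residues < 10:
        raise ValueError("n_residues must be >= 10")
    rng = np.random.default_rng(seed)
    ca = _compact_ca_walk(n_residues, rng)
    bb = _backbone_from_ca(ca)
    resnames = [_AA3[i] for i in rng.integers(0, len(_AA3), size=n_residues)]

    names, resnums, rnames, chains, elements, coords = [], [], [], [], [], []
    for i in range(n_residues):
        resnum = first_residue + i
        entries = [("N", "N", bb["N"][i]), ("CA", "C", ca[i]), ("C", "C", bb["C"][i]),
                   ("O", "O", bb["O"][i])]
        if i > 0:
            entries.append(("H", "H", _amide_h(bb["N"][i], ca[i], bb["C"][i - 1])))
        for name, el, xyz in entries:
            names.append(name)
            resnums.append(resnum)
            rnames.append(resnames[i])
            chains.append(chain_id)
            elements.append(el)
            coords.append(xyz)
    structure = Structure(
        names, resnums, rnames, chains, elements, np.asarray(coords),
        label=f"pseudo-domain n={n_residues} seed={seed}",
    )
    return DomainTemplate(
        structure=structure,
        anchor_residues=(first_residue, first_residue + n_residues - 1),
    )


def make_tandem_domains(seed: int = 2023) -> tuple[DomainTemplate, DomainTemplate]:
    """The default pseudo-domain pair on tandem-SH2 numbering (3-104, 112-216)."""
    dom_a = make_pseudo_domain(102, seed=seed, first_residue=3)
    dom_b = make_pseudo_domain(105, seed=seed + 1, first_residue=112)
    return dom_a, dom_b


# ----------------------------------------------------------------------
# pose distributions
# ----------------------------------------------------------------------

def default_pose_distribution(
    dom_a: DomainTemplate,
    dom_b: DomainTemplate,
    mode: str = "multibasin",
    n_basins: int = 3,
    angular_spread_deg: float = 10.0,
    translational_spread: float = 1.5,
    anchor_gap: float = 14.0,
    seed: int = 0,
) -> PoseDistribution:
    """Construct a feasible pose distribution for a given domain pair.

    Basin rotations are spread around a common axis; each basin's mean
    translation is solved so that the linker anchors sit ``anchor_gap`` Å
    apart, guaranteeing linker closure at the basin centre.  Defaults (3
    basins, 10 deg angular and 1.5 Å translational spread) emulate a
    free-energy landscape with a few broad interdomain-orientation minima
    of a linker-tethered two-domain protein.
    """
    rng = np.random.default_rng(seed)
    a_struct = dom_a.structure
    b_struct = dom_b.structure
    a_anchor_ca = a_struct.coords[
        (a_struct.residue_numbers == dom_a.anchor_residues[1]) & (a_struct.atom_names == "CA")
    ][0]
    b_anchor_ca = b_struct.coords[
        (b_struct.residue_numbers == dom_b.anchor_residues[0]) & (b_struct.atom_names == "CA")
    ][0]
    com_a = a_struct.coords.mean(axis=0)
    com_b = b_struct.coords.mean(axis=0)
    if mode == "homogeneous":
        n_basins = 1
        angular_spread_deg = 0.0
        translational_spread = 0.0
    if mode == "continuum":
        n_basins = 1
        angular_spread_deg = max(angular_spread_deg, 45.0)
        translational_spread = max(translational_spread, 4.0)
    a_ca = a_struct.coords[a_struct.atom_names == "CA"]
    b_ca_local = b_struct.coords[b_struct.atom_names == "CA"] - com_b
    out_dir = a_anchor_ca - com_a
    out_dir = out_dir / np.linalg.norm(out_dir)
    basins = []
    for k in range(n_basins):
        found = False
        for _ in range(500):  # resample until the basin mean pose is feasible
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = 360.0 * k / max(n_basins, 1) + rng.uniform(-15.0, 15.0)
            rot = _rotation_about(axis, np.radians(angle))
            u = _gaussian_rotation(rng, np.radians(25.0)) @ out_dir
            # march domain B's centroid outward from A's anchor until
            # clash-free while the linker can still close
            for d_out in np.arange(6.0, 30.0, 2.0):
                com_b_pos = a_anchor_ca + d_out * u
                b_anchor = rot @ (b_anchor_ca - com_b) + com_b_pos
                span = np.linalg.norm(b_anchor - a_anchor_ca)
                if not (4.0 <= span <= max(anchor_gap, 24.0)):
                    continue
                b_ca = b_ca_local @ rot.T + com_b_pos
                dmin = np.min(np.linalg.norm(a_ca[:, None, :] - b_ca[None, :, :], axis=-1))
                if dmin >= 5.0:  # margin above the generator's 4.0 Å clash cutoff
                    found = True
                    translation = com_b_pos - com_a
                    break
            if found:
                break
        if not found:
            raise InfeasibleDistributionError(
                f"could not construct a clash-free mean pose for basin {k}"
            )
        basins.append(
            PoseBasin(
                axis=tuple(axis),
                angle_deg=float(angle),
                translation=tuple(translation),
                angular_spread_deg=angular_spread_deg,
                translational_spread=translational_spread,
                weight=1.0,
            )
        )
    return PoseDistribution(mode=mode, basins=tuple(basins))


# ----------------------------------------------------------------------
# ensemble generation
# ----------------------------------------------------------------------

def _bridge_walk(
    a: np.ndarray, b: np.ndarray, n_points: int, rng: np.random.Generator
) -> np.ndarray:
    """Cα trace of n_points between (exclusive) anchors a and b.

    A jittered chord, relaxed toward uniform ~3.8 Å spacing.
    """
    t = np.linspace(0.0, 1.0, n_points + 2)[1:-1, None]
    pts = a + t * (b - a)
    chord = b - a
    chord_len = np.linalg.norm(chord)
    slack = max(0.0, (n_points + 1) * _CA_SPACING - chord_len)
    pts = pts + rng.normal(scale=0.25 * slack / max(n_points, 1) + 0.2, size=(n_points, 3))
    full = np.vstack([a, pts, b])
    for _ in range(60):
        seg = np.diff(full, axis=0)
        lens = np.linalg.norm(seg, axis=1, keepdims=True)
        err = lens - _CA_SPACING
        adjust = 0.5 * err * seg / lens
        full[1:-1] += adjust[1:] - adjust[:-1]
    return full[1:-1]


def _assemble(
    dom_a: DomainTemplate,
    dom_b: DomainTemplate,
    b_coords: np.ndarray,
    linker_ca: np.ndarray,
    label: str,
) -> Structure:
    a = dom_a.structure
    b = dom_b.structure
    n_link = len(linker_ca)
    first_link = dom_a.anchor_residues[1] + 1
    names = np.concatenate([a.atom_names, np.full(n_link, "CA"), b.atom_names])
    resnums = np.concatenate([
        a.residue_numbers,
        np.arange(first_link, first_link + n_link),
        b.residue_numbers,
    ])
    rnames = np.concatenate([a.residue_names, np.full(n_link, "GLY"), b.residue_names])
    chains = np.concatenate([a.chain_ids, np.full(n_link, str(a.chain_ids[0])), b.chain_ids])
    elements = np.concatenate([a.elements, np.full(n_link, "C"), b.elements])
    coords = np.vstack([a.coords, linker_ca, b_coords])
    return Structure(names, resnums, rnames, chains, elements, coords, label=label)


def generate_ensemble(
    dom_a: DomainTemplate,
    dom_b: DomainTemplate,
    dist: PoseDistribution,
    n: int,
    linker_length: int = 7,
    seed: int = 0,
    clash_cutoff: float = 4.0,
    max_attempts_factor: int = 200,
) -> tuple[Ensemble, GroundTruth]:
    """Sample ``n`` conformers of the two-domain protein from ``dist``.

    A pose is accepted only if the linker can close (anchor separation
    within [3.8, linker_length x 3.8] Å) and the domains do not clash
    (interdomain Cα distances >= ``clash_cutoff``); the linker Cα trace is
    then built as a constrained random walk between the anchors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    a_struct = dom_a.structure
    b_struct = dom_b.structure
    com_a = a_struct.coords.mean(axis=0)
    com_b = b_struct.coords.mean(axis=0)
    a_ca = a_struct.coords[a_struct.atom_names == "CA"]
    b_ca_local = b_struct.coords[b_struct.atom_names == "CA"] - com_b
    a_anchor = a_struct.coords[
        (a_struct.residue_numbers == dom_a.anchor_residues[1]) & (a_struct.atom_names == "CA")
    ][0]
    b_anchor_local = b_struct.coords[
        (b_struct.residue_numbers == dom_b.anchor_residues[0]) & (b_struct.atom_names == "CA")
    ][0] - com_b
    basin_w = dist.weights
    max_span = linker_length * _CA_SPACING

    conformers, labels = [], []
    max_attempts = max(100, max_attempts_factor)
    # the basin is drawn once per conformer, then the pose is
    # rejection-sampled within that basin, so the planted basin weights are
    # preserved exactly regardless of per-basin acceptance rates
    for i in range(n):
        k = int(rng.choice(len(basin_w), p=basin_w))
        basin = dist.basins[k]
        for attempt in range(max_attempts):
            rot = _gaussian_rotation(
                rng, np.radians(basin.angular_spread_deg)
            ) @ _rotation_about(np.asarray(basin.axis), np.radians(basin.angle_deg))
            trans = com_a + np.asarray(basin.translation) + rng.normal(
                0.0, basin.translational_spread or 1e-12, size=3
            )
            b_anchor = rot @ b_anchor_local + trans
            span = np.linalg.norm(b_anchor - a_anchor)
            if not (_CA_SPACING <= span <= max_span):
                continue
            b_ca = b_ca_local @ rot.T + trans
            dmin = np.min(
                np.linalg.norm(a_ca[:, None, :] - b_ca[None, :, :], axis=-1)
            )
            if dmin < clash_cutoff:
                continue
            break
        else:
            raise InfeasibleDistributionError(
                f"basin {k}: rejection rate > {100 * (1 - 1 / max_attempts):.0f}% "
                f"over {max_attempts} attempts"
            )
        linker_ca = _bridge_walk(a_anchor, b_anchor, linker_length, rng)
        b_coords = (b_struct.coords - com_b) @ rot.T + trans
        conformers.append(
            _assemble(dom_a, dom_b, b_coords, linker_ca, label=f"synthetic[{i}]")
        )
        labels.append(k)
    ensemble = Ensemble(conformers)
    truth = GroundTruth(pose_labels=np.asarray(labels, dtype=int), seed=seed)
    return ensemble, truth


def perturb_interdomain_poses(
    ensemble: Ensemble,
    min_angle_deg: float = 60.0,
    max_angle_deg: float = 90.0,
    translation_sd: float = 1.5,
    seed: int = 0,
    probe_range: tuple[int, int] = constants.C_SH2_RANGE,
    anchor_range: tuple[int, int] = constants.N_SH2_RANGE,
    linker_range: tuple[int, int] = constants.LINKER_RANGE,
    linker_max_span: float = 30.4,
    clash_cutoff: float = 4.0,
) -> Ensemble:
    """Rotate each conformer's mobile domain by a large random angle.

    Produces a feasibility-respecting (linker closable, clash-free) but
    badly wrong starting ensemble for refinement parameter-recovery runs.
    """
    from .structure_io import Selection

    probe = Selection(residue_ranges=(probe_range,))
    rng = np.random.default_rng(seed)
    out = []
    for c in ensemble:
        m = probe.mask(c)
        coords = c.coords.copy()
        for _ in range(500):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            rot = _rotation_about(axis, np.radians(rng.uniform(min_angle_deg, max_angle_deg)))
            trial = c.coords.copy()
            cen = trial[m].mean(axis=0)
            trial[m] = (trial[m] - cen) @ rot.T + cen + rng.normal(0.0, translation_sd, 3)
            pa = trial[
                (c.residue_numbers == linker_range[0] - 1) & (c.atom_names == "CA")
            ][0]
            pb = trial[
                (c.residue_numbers == linker_range[1] + 1) & (c.atom_names == "CA")
            ][0]
            if not (_CA_SPACING <= np.linalg.norm(pb - pa) <= linker_max_span):
                continue
            aca = trial[
                (c.residue_numbers >= anchor_range[0])
                & (c.residue_numbers <= anchor_range[1])
                & (c.atom_names == "CA")
            ]
            bca = trial[
                (c.residue_numbers >= probe_range[0])
                & (c.residue_numbers <= probe_range[1])
                & (c.atom_names == "CA")
            ]
            if np.min(np.linalg.norm(aca[:, None] - bca[None], axis=-1)) >= clash_cutoff:
                coords = trial
                break
        out.append(c.with_coords(coords))
    return Ensemble(out)


# ----------------------------------------------------------------------
# surrogate tensors, simulated observables
# ----------------------------------------------------------------------

def surrogate_tensor(
    conformer: Structure,
    magnitude: float = 5e-4,
    rhombicity: float = 0.2,
    degeneracy_tol: float = 0.05,
    scale_by_anisotropy: bool = True,
) -> AlignmentTensor:
    """Shape-anchored surrogate alignment tensor for one conformer.

    Principal axes are the conformer's gyration principal axes (axial axis =
    long molecular axis); eigenvalues follow from (magnitude, rhombicity).
    With ``scale_by_anisotropy`` (default) the axial magnitude is scaled by
    the conformer's relative shape anisotropy (rgz - rgx)/rgz, normalised to
    ``magnitude`` at anisotropy 0.5 — steric alignment is stronger for more
    elongated shapes, so per-conformer tensors differ in both axes and
    magnitude.  Deterministic given the conformer; covariant with rigid
    rotations.
    """
    if magnitude == 0.0:
        return AlignmentTensor(np.zeros((3, 3)))
    gyr = gyration(conformer, mass_weighted=True)
    comps = np.asarray(gyr.components)
    aniso = (comps[2] - comps[0]) / max(comps[2], 1e-12)
    if aniso < degeneracy_tol:
        raise DegenerateShapeError(
            "gyration components nearly equal; alignment axes undefined"
        )
    mag = magnitude * (aniso / 0.5) if scale_by_anisotropy else magnitude
    return AlignmentTensor.from_axial_rhombic(mag, rhombicity, gyr.principal_axes)


def candidate_records(structure: Structure, types: Sequence[str]) -> list[RDCRecord]:
    """Zero-valued record stubs for every residue x coupling type."""
    residues = sorted(set(int(r) for r in structure.residue_numbers))
    return [RDCRecord(r, t, 0.0) for r in residues for t in types]


def simulate_rdcs(
    ensemble: Ensemble,
    tensors: Sequence[AlignmentTensor],
    types: Sequence[str] = constants.COUPLING_TYPES,
    noise_sd: float = 0.0,
    seed: int = 0,
    weights: Sequence[float] | None = None,
) -> list[RDCRecord]:
    """Ensemble-averaged RDCs from per-conformer tensors, plus Gaussian noise.

    D_obs(j) = sum_i w_i D_calc(conformer i, tensor i, record j) + N(0, sd).
    Records unresolvable on the shared topology are dropped (counted once,
    since all conformers share topology).
    """
    if len(tensors) != len(ensemble):
        raise ValueError("need one tensor per conformer")
    w = ensemble.weights if weights is None else np.asarray(weights, float) / np.sum(weights)
    stubs = candidate_records(ensemble[0], types)
    kept_ref = None
    avg = None
    for wi, conf, tensor in zip(w, ensemble, tensors):
        vs = internuclear_vectors(conf, stubs)
        if kept_ref is None:
            kept_ref = vs.kept
        elif not np.array_equal(vs.kept, kept_ref):
            raise ValueError("conformers resolve different record subsets")
        d = back_calculate(vs, tensor)
        avg = wi * d if avg is None else avg + wi * d
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        avg = avg + rng.normal(0.0, noise_sd, size=avg.shape)
    return [
        RDCRecord(
            stubs[j].residue_number,
            stubs[j].coupling_type,
            float(avg[i]),
            sigma=noise_sd if noise_sd > 0 else None,
        )
        for i, j in enumerate(kept_ref)
    ]


def simulate_saxs(
    ensemble: Ensemble,
    q_grid: np.ndarray,
    noise_a: float = 0.0,
    noise_b: float = 0.0,
    seed: int = 0,
    weights: Sequence[float] | None = None,
    sigma_bead: float = 3.0,
) -> SaxsCurve:
    """Noisy ensemble-averaged SAXS curve.

    Multiplicative Gaussian noise with relative sd (noise_a + noise_b * q);
    the per-point sigma is stored on the returned curve.
    """
    clean = ensemble_curve(ensemble, q_grid, weights=weights, sigma_bead=sigma_bead)
    if noise_a == 0.0 and noise_b == 0.0:
        return clean
    rng = np.random.default_rng(seed)
    rel = noise_a + noise_b * clean.q
    sigma = np.maximum(rel * clean.intensity, 1e-12)
    noisy = clean.intensity + rng.normal(0.0, 1.0, size=clean.q.shape) * sigma
    return SaxsCurve(q=clean.q, intensity=noisy, sigma=sigma)
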