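"""Essential dynamics of conformer ensembles: Cα PCA, essential-plane
projections, free-energy landscapes and RMSD-cutoff (GROMOS) clustering.

PCA is performed on Cα coordinates after iterative least-squares fitting to
the running mean; the two leading eigenvectors span the "essential plane"
onto which conformers (and external crystal structures) can be projected.
Free-energy landscapes are -kT ln of the binned projection density,
referenced so the most populated bin sits at zero.  Projections and
eigenvalues are reported in nm (coordinates are handled in Å internally
elsewhere in the package).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .geometry import superpose
from .structure_io import Ensemble, Selection, Structure
from . import constants

_A_TO_NM = 0.1


@dataclass
class EssentialSubspace:
    """PCA basis over fitted Cα coordinates (units: nm, nm^2)."""

    mean_coords: np.ndarray          # (3N,) nm, fitting reference and centre
    eigenvectors: np.ndarray         # (3N, K), orthonormal columns
    eigenvalues: np.ndarray          # (K,) nm^2, descending
    fit_selection: Selection
    n_conformers: int = 0

    @property
    def fractions(self) -> np.ndarray:
        """Per-mode fraction of the total positional fluctuation."""
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else np.zeros_like(self.eigenvalues)

    @property
    def cumulative_fractions(self) -> np.ndarray:
        return np.cumsum(self.fractions)


@dataclass
class FreeEnergyLandscape:
    """-kT ln P over the essential plane, minimum at 0, empty bins masked."""

    pc1_edges: np.ndarray  # nm
    pc2_edges: np.ndarray  # nm
    counts: np.ndarray     # (n1, n2) int
    g: np.ma.MaskedArray   # kJ/mol
    kT: float              # kJ/mol


@dataclass
class ClusterResult:
    """GROMOS-style clustering outcome, clusters ordered by population."""

    assignments: np.ndarray       # conformer index -> cluster id (0 = largest)
    centers: list[int]            # conformer index of each cluster centre
    populations: np.ndarray       # fractions, descending
    cutoff: float                 # nm

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def _fitted_coords(
    ensemble: Ensemble, fit_selection: Selection, tol_nm: float = 1e-6, max_iter: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose all conformers to the running mean (nm).

    Returns (aligned coordinates (C, N, 3), mean (N, 3)), both in nm.
    """
    coords = np.stack([c.select(fit_selection).coords for c in ensemble]) * _A_TO_NM
    ref = coords[0].copy()
    for _ in range(max_iter):
        aligned = np.stack([superpose(x, ref).apply(x) for x in coords])
        new_ref = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_ref - ref) ** 2, axis=1))))
        ref = new_ref
        if shift < tol_nm:
            break
    aligned = np.stack([superpose(x, ref).apply(x) for x in coords])
    return aligned, aligned.mean(axis=0)


def pca_fit(
    ensemble: Ensemble,
    fit_selection: Selection,
    reference: str = "mean",
    tol_nm: float = 1e-6,
    max_iter: int = 10,
) -> EssentialSubspace:
    """PCA of Cα fluctuations after least-squares fitting.

    ``reference='mean'`` iterates superposition onto the running mean until
    the mean shifts by less than ``tol_nm``; ``reference='first'`` fits all
    conformers onto the first one (single pass, then mean-centred).
    """
    if len(ensemble) < 2:
        raise ValueError("PCA requires at least 2 conformers")
    if reference == "mean":
        aligned, mean = _fitted_coords(ensemble, fit_selection, tol_nm, max_iter)
    elif reference == "first":
        coords = np.stack([c.select(fit_selection).coords for c in ensemble]) * _A_TO_NM
        ref = coords[0]
        aligned = np.stack([superpose(x, ref).apply(x) for x in coords])
        mean = aligned.mean(axis=0)
    else:
        raise ValueError("reference must be 'mean' or 'first'")
    c = aligned.shape[0]
    x = aligned.reshape(c, -1) - mean.reshape(-1)
    # population covariance via SVD; eigenvalues in nm^2
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / c
    eigenvectors = vt.T
    return EssentialSubspace(
        mean_coords=mean.reshape(-1),
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        fit_selection=fit_selection,
        n_conformers=c,
    )


def project(
    subspace: EssentialSubspace,
    target: Ensemble | Structure,
    n_components: int = 2,
) -> np.ndarray:
    """Project conformers onto the essential eigenvectors (nm).

    Each conformer is superposed onto the subspace mean over the fit
    selection before taking inner products, so the projection is invariant
    under rigid motion of the input.
    """
    structures = list(target) if isinstance(target, Ensemble) else [target]
    mean = subspace.mean_coords.reshape(-1, 3)
    vecs = subspace.eigenvectors[:, :n_components]
    out = np.empty((len(structures), n_components))
    for i, s in enumerate(structures):
        x = s.select(subspace.fit_selection).coords * _A_TO_NM
        if x.shape != mean.shape:
            raise ValueError(
                f"conformer has {x.shape[0]} fitted atoms, subspace expects {mean.shape[0]}"
            )
        aligned = superpose(x, mean).apply(x)
        out[i] = (aligned - mean).reshape(-1) @ vecs
    return out if isinstance(target, Ensemble) else out[0]


def fel(
    projections: np.ndarray,
    bins: tuple[int, int] = (32, 32),
    kT: float = constants.KT_KJ_MOL_300K,
) -> FreeEnergyLandscape:
    """Free-energy landscape g = -kT ln(n / n_max) over PC1/PC2 bins."""
    p = np.asarray(projections, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2 or p.shape[0] < 1:
        raise ValueError("projections must be (n_points, >=2)")
    counts, e1, e2 = np.histogram2d(p[:, 0], p[:, 1], bins=bins)
    counts = counts.astype(int)
    nmax = counts.max()
    with np.errstate(divide="ignore"):
        g = -kT * np.log(np.where(counts > 0, counts / nmax, np.nan))
    return FreeEnergyLandscape(
        pc1_edges=e1,
        pc2_edges=e2,
        counts=counts,
        g=np.ma.masked_invalid(g),
        kT=kT,
    )


def pairwise_fit_rmsd(coords: np.ndarray) -> np.ndarray:
    """All-pairs least-squares-fit RMSD matrix via batched Kabsch.

    ``coords`` is (C, N, 3); the result is symmetric (C, C) in the input
    length unit.  Uses rmsd^2 = (G_i + G_j - 2 sum_k d_k s_k) / N with s the
    singular values of the cross-covariance and d the reflection correction.
    """
    c, n, _ = coords.shape
    centred = coords - coords.mean(axis=1, keepdims=True)
    g = np.einsum("cnk,cnk->c", centred, centred)
    h = np.einsum("ink,jnm->ijkm", centred, centred)  # (C, C, 3, 3)
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(np.einsum("ijkl,ijlm->ijkm", u, vt)))
    d = s[..., 0] + s[..., 1] + sign * s[..., 2]
    sq = (g[:, None] + g[None, :] - 2.0 * d) / n
    np.fill_diagonal(sq, 0.0)
    return np.sqrt(np.clip(sq, 0.0, None))


def cluster(
    ensemble: Ensemble,
    selection: Selection,
    cutoff: float = 0.3,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """Neighbour-counting (GROMOS/Daura) clustering under a fit-RMSD cutoff.

    Repeatedly takes the conformer with the most neighbours within
    ``cutoff`` (nm) as a cluster centre, removes it and its neighbours, and
    iterates.  Ties break to the lowest conformer index; clusters are
    relabelled in order of decreasing population (then lowest centre index).
    """
    n = len(ensemble)
    if rmsd_matrix is None:
        coords = np.stack([c.select(selection).coords for c in ensemble]) * _A_TO_NM
        rmsd_matrix = pairwise_fit_rmsd(coords)
    within = rmsd_matrix <= cutoff
    remaining = np.ones(n, dtype=bool)
    raw: list[tuple[int, np.ndarray]] = []
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the first (lowest index) on ties
        members = np.where(within[center] & remaining)[0]
        raw.append((center, members))
        remaining[members] = False
    order = sorted(range(len(raw)), key=lambda k: (-len(raw[k][1]), raw[k][0]))
    assignments = np.full(n, -1, dtype=int)
    centers, pops = [], []
    for new_id, k in enumerate(order):
        center, members = raw[k]
        assignments[members] = new_id
        centers.append(center)
        pops.append(len(members) / n)
    return ClusterResult(
        assignments=assignments,
        centers=centers,
        populations=np.array(pops),
        cutoff=cutoff,
    )


# ----------------------------------------------------------------------
# plain-text serialization
# ----------------------------------------------------------------------

def save_subspace(subspace: EssentialSubspace, path: str | Path) -> None:
    """Serialize an EssentialSubspace as a commented plain-text file."""
    sel = subspace.fit_selection
    ranges = ";".join(f"{lo}-{hi}" for lo, hi in sel.residue_ranges)
    names = ",".join(sorted(sel.atom_names)) if sel.atom_names else "*"
    with open(path, "w") as fh:
        fh.write("# essential subspace (units nm, nm^2)\n")
        fh.write(f"# residue_ranges {ranges}\n")
        fh.write(f"# atom_names {names}\n")
        fh.write(f"# n_conformers {subspace.n_conformers}\n")
        fh.write(f"# n_coords {subspace.mean_coords.size} n_modes {subspace.eigenvalues.size}\n")
        np.savetxt(fh, subspace.mean_coords[None], header="mean", comments="# ")
        np.savetxt(fh, subspace.eigenvalues[None], header="eigenvalues", comments="# ")
        np.savetxt(fh, subspace.eigenvectors, header="eigenvectors (rows: coords)", comments="# ")


def load_subspace(path: str | Path) -> EssentialSubspace:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# residue_ranges"):
                meta["ranges"] = line.split()[2] if len(line.split()) > 2 else ""
            elif line.startswith("# atom_names"):
                meta["names"] = line.split()[2]
            elif line.startswith("# n_conformers"):
                meta["n_conf"] = int(line.split()[2])
            elif line.startswith("# n_coords"):
                parts = line.split()
                meta["n_coords"], meta["n_modes"] = int(parts[2]), int(parts[4])
    rows = [
        np.fromstring(line, sep=" ")
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    n_coords = meta["n_coords"]
    mean = rows[0]
    eigenvalues = rows[1][: meta["n_modes"]]
    eigenvectors = np.vstack(rows[2:]).reshape(n_coords, -1)
    ranges = tuple(
        tuple(int(v) for v in r.split("-")) for r in meta.get("ranges", "").split(";") if r
    )
    names = None if meta.get("names", "*") == "*" else frozenset(meta["names"].split(","))
    sel = Selection(residue_ranges=ranges, atom_names=names)
    return EssentialSubspace(
        mean_coords=mean,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        fit_selection=sel,
        n_conformers=meta.get("n_conf", 0),
    )


def save_fel(landscape: FreeEnergyLandscape, path: str | Path) -> None:
    """Gridded-text FEL export: pc1_centre pc2_centre count g."""
    c1 = 0.5 * (landscape.pc1_edges[:-1] + landscape.pc1_edges[1:])
    c2 = 0.5 * (landscape.pc2_edges[:-1] + landscape.pc2_edges[1:])
    with open(path, "w") as fh:
        fh.write(f"# free-energy landscape, kT = {landscape.kT} kJ/mol\n")
        fh.write("# pc1_nm\tpc2_nm\tcount\tg_kj_mol\n")
        for i, a in enumerate(c1):
            for j, b in enumerate(c2):
                g = landscape.g[i, j]
                gtxt = "nan" if np.ma.is_masked(g) else f"{float(g):.4f}"
                fh.write(f"{a:.4f}\t{b:.4f}\t{landscape.counts[i, j]}\t{gtxt}\n")
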