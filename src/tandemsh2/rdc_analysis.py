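"""Residual dipolar coupling back-calculation and Saupe-tensor SVD fitting.

An RDC measured between two nuclei is proportional to <3 cos^2 theta - 1>,
where theta is the angle between the internuclear vector and the magnetic
field, averaged over the anisotropic orientation distribution induced by the
alignment medium.  That average is captured by the traceless symmetric Saupe
order matrix S (5 independent elements), giving

    D = D_max * e^T S e

for a unit internuclear vector e, with D_max the static dipolar constant of
the nucleus pair.  For >= 5 couplings S follows from linear least squares
(SVD) on the design matrix of direction cosines.

Three fitting schemes are provided for conformer ensembles:

* ``svd_fit_single``            — one template structure, one tensor;
* ``fit_ensemble_single_tensor`` — many templates constrained to share one
  tensor (valid only if all conformers align identically);
* ``fit_ensemble_multi_tensor``  — one tensor per template, fitted jointly
  to the ensemble-averaged couplings.

Backbone coupling types use the standard convention that ``N-C`` and ``H-C``
connect the amide of residue i to the carbonyl carbon of residue i-1;
``C-CA`` is the intra-residue C'(i)-Calpha(i) coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import constants
from .structure_io import Ensemble, Structure

COUPLING_TYPES = constants.COUPLING_TYPES  # ("H-N", "N-C", "H-C", "C-CA")


class UnderdeterminedFitError(ValueError):
    """Raised when the RDC design matrix has rank < 5 per tensor."""


@dataclass(frozen=True)
class RDCRecord:
    """One measured (or simulated) residual dipolar coupling."""

    residue_number: int
    coupling_type: str
    value: float  # Hz
    sigma: float | None = None  # Hz

    def __post_init__(self):
        if self.coupling_type not in COUPLING_TYPES:
            raise ValueError(f"unknown coupling type {self.coupling_type!r}")
        if not np.isfinite(self.value):
            raise ValueError("coupling value must be finite")


class AlignmentTensor:
    """Traceless symmetric 3x3 Saupe order matrix (dimensionless)."""

    def __init__(self, saupe: np.ndarray):
        s = np.asarray(saupe, dtype=float)
        if s.shape != (3, 3):
            raise ValueError("Saupe matrix must be 3x3")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("Saupe matrix must be symmetric")
        s = 0.5 * (s + s.T)
        s = s - np.eye(3) * (np.trace(s) / 3.0)  # enforce tracelessness exactly
        self.saupe = s

    # -- 5-parameter representation (Sxx, Syy, Sxy, Sxz, Syz) --------------
    @classmethod
    def from_params(cls, p: np.ndarray) -> "AlignmentTensor":
        sxx, syy, sxy, sxz, syz = np.asarray(p, dtype=float)
        return cls(np.array([
            [sxx, sxy, sxz],
            [sxy, syy, syz],
            [sxz, syz, -sxx - syy],
        ]))

    def to_params(self) -> np.ndarray:
        s = self.saupe
        return np.array([s[0, 0], s[1, 1], s[0, 1], s[0, 2], s[1, 2]])

    @classmethod
    def from_axial_rhombic(
        cls, magnitude: float, rhombicity: float, axes: np.ndarray
    ) -> "AlignmentTensor":
        """Tensor with principal eigenvalues (2A, -A(1-1.5R), -A(1+1.5R)).

        ``axes`` rows are the principal directions; row 2 carries the unique
        (axial) eigenvalue 2A.  R must lie in [0, 2/3].
        """
        if not 0.0 <= rhombicity <= 2.0 / 3.0 + 1e-12:
            raise ValueError("rhombicity must be within [0, 2/3]")
        a = float(magnitude)
        evals = np.array([
            -a * (1.0 - 1.5 * rhombicity),
            -a * (1.0 + 1.5 * rhombicity),
            2.0 * a,
        ])
        v = np.asarray(axes, dtype=float).T  # columns = axes
        return cls(v @ np.diag(evals) @ v.T)

    # -- derived quantities -------------------------------------------------
    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues ordered |Szz| >= |Syy| >= |Sxx| with matching axes rows."""
        evals, evecs = np.linalg.eigh(self.saupe)
        order = np.argsort(np.abs(evals))  # ascending |.| -> (Sxx, Syy, Szz)
        return evals[order], evecs[:, order].T

    @property
    def axial_component(self) -> float:
        """Da = Szz / 2 (dimensionless order units)."""
        evals, _ = self.eigensystem()
        return float(evals[2] / 2.0)

    @property
    def rhombicity(self) -> float:
        evals, _ = self.eigensystem()
        if evals[2] == 0.0:
            return 0.0
        return float((2.0 / 3.0) * (evals[0] - evals[1]) / evals[2])

    def rotate(self, rot: np.ndarray) -> "AlignmentTensor":
        return AlignmentTensor(rot @ self.saupe @ rot.T)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<AlignmentTensor Da={self.axial_component:.3e} R={self.rhombicity:.3f}>"


@dataclass
class VectorSet:
    """Unit internuclear vectors and dipolar constants for a record list."""

    vectors: np.ndarray          # (M, 3) unit vectors
    dmax: np.ndarray             # (M,) Hz
    kept: np.ndarray             # indices into the input record list
    skipped: list[tuple[int, str]] = field(default_factory=list)


def _atom_index(structure: Structure) -> dict[tuple[int, str], int]:
    idx: dict[tuple[int, str], int] = {}
    for i, (r, n) in enumerate(zip(structure.residue_numbers, structure.atom_names)):
        idx.setdefault((int(r), str(n)), i)
    return idx


def _build_amide_h(structure: Structure, idx, res: int) -> np.ndarray | None:
    """Geometric amide-proton placement in the peptide plane.

    H lies in the C'(i-1)-N(i)-CA(i) plane, opposite the bisector of the
    N->C' and N->CA directions, at the configured N-H bond length.
    """
    try:
        n = structure.coords[idx[(res, "N")]]
        ca = structure.coords[idx[(res, "CA")]]
        cp = structure.coords[idx[(res - 1, "C")]]
    except KeyError:
        return None
    u = cp - n
    v = ca - n
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    b = u + v
    norm = np.linalg.norm(b)
    if norm < 1e-8:
        return None
    return n - (b / norm) * constants.BOND_LENGTHS["H-N"]


def internuclear_vectors(
    structure: Structure,
    records: Sequence[RDCRecord],
    fixed_hc_distance: bool = False,
) -> VectorSet:
    """Unit internuclear vectors (and D_max) for each coupling record.

    H-N: H(i)->N(i); N-C: N(i)->C'(i-1); H-C: H(i)->C'(i-1);
    C-CA: C'(i)->CA(i).  A missing amide proton is constructed geometrically
    (never for proline).  Unresolvable records are skipped and reported in
    ``VectorSet.skipped``.
    """
    idx = _atom_index(structure)
    resnames = {}
    for r, rn in zip(structure.residue_numbers, structure.residue_names):
        resnames.setdefault(int(r), str(rn))

    vectors, dmaxs, kept, skipped = [], [], [], []
    for k, rec in enumerate(records):
        res = rec.residue_number
        t = rec.coupling_type
        needs_h = t in ("H-N", "H-C")
        h = None
        if needs_h:
            if resnames.get(res) == "PRO":
                skipped.append((k, "proline has no amide proton"))
                continue
            for name in ("H", "HN"):
                if (res, name) in idx:
                    h = structure.coords[idx[(res, name)]]
                    break
            if h is None:
                h = _build_amide_h(structure, idx, res)
            if h is None:
                skipped.append((k, "amide proton unresolvable"))
                continue
        try:
            if t == "H-N":
                a, b = h, structure.coords[idx[(res, "N")]]
                r_eff = constants.BOND_LENGTHS["H-N"]
            elif t == "N-C":
                a = structure.coords[idx[(res, "N")]]
                b = structure.coords[idx[(res - 1, "C")]]
                r_eff = constants.BOND_LENGTHS["N-C"]
            elif t == "H-C":
                a, b = h, structure.coords[idx[(res - 1, "C")]]
                r_eff = (
                    constants.BOND_LENGTHS["H-C"]
                    if fixed_hc_distance
                    else float(np.linalg.norm(b - a))
                )
            else:  # C-CA
                a = structure.coords[idx[(res, "C")]]
                b = structure.coords[idx[(res, "CA")]]
                r_eff = constants.BOND_LENGTHS["C-CA"]
        except KeyError as exc:
            skipped.append((k, f"missing atom {exc.args[0]}"))
            continue
        vec = b - a
        norm = np.linalg.norm(vec)
        if norm < 1e-8:
            skipped.append((k, "zero-length vector"))
            continue
        vectors.append(vec / norm)
        dmaxs.append(constants.dmax(t, r_eff))
        kept.append(k)
    return VectorSet(
        vectors=np.asarray(vectors, dtype=float).reshape(-1, 3),
        dmax=np.asarray(dmaxs, dtype=float),
        kept=np.asarray(kept, dtype=int),
        skipped=skipped,
    )


def back_calculate(vectors: VectorSet, tensor: AlignmentTensor) -> np.ndarray:
    """D = D_max * e^T S e for each record vector (Hz)."""
    e = vectors.vectors
    return vectors.dmax * np.einsum("ij,jk,ik->i", e, tensor.saupe, e)


def _design_rows(vectors: VectorSet) -> np.ndarray:
    """(M, 5) design matrix rows: D = row . (Sxx, Syy, Sxy, Sxz, Syz)."""
    x, y, z = vectors.vectors.T
    rows = np.stack([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z], axis=1)
    return vectors.dmax[:, None] * rows


@dataclass
class FitStatistics:
    pearson_r: float
    pearson_r_by_type: dict[str, float]
    q_factor: float
    rms: float  # Hz


@dataclass
class FitResult:
    """Outcome of an alignment-tensor fit.

    ``tensors`` holds one tensor (single-tensor schemes) or one per
    conformer; ``d_calc`` is the (ensemble-averaged, where applicable)
    back-calculated coupling for each kept record.
    """

    tensors: list[AlignmentTensor]
    records: list[RDCRecord]
    d_obs: np.ndarray
    d_calc: np.ndarray
    stats: FitStatistics
    effective_rank: int
    condition_number: float
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"RDC fit: {len(self.records)} couplings, {len(self.tensors)} tensor(s)",
            f"  Pearson r (global): {self.stats.pearson_r:.4f}",
        ]
        for t, r in sorted(self.stats.pearson_r_by_type.items()):
            lines.append(f"  Pearson r ({t}):  {r:.4f}")
        lines.append(f"  Q factor: {self.stats.q_factor:.4f}")
        lines.append(f"  rms deviation: {self.stats.rms:.3f} Hz")
        lines.append(
            f"  effective rank {self.effective_rank}, condition number {self.condition_number:.3g}"
        )
        for i, t in enumerate(self.tensors[:5]):
            lines.append(f"  tensor {i}: Da = {t.axial_component:.3e}, R = {t.rhombicity:.3f}")
        if len(self.tensors) > 5:
            lines.append(f"  ... and {len(self.tensors) - 5} more tensors")
        return "\n".join(lines)


def fit_statistics(
    obs: np.ndarray,
    calc: np.ndarray,
    records: Sequence[RDCRecord] | None = None,
    sigmas: np.ndarray | None = None,
) -> FitStatistics:
    """Pearson r (global and per coupling type), Q factor and rms (Hz)."""
    obs = np.asarray(obs, dtype=float)
    calc = np.asarray(calc, dtype=float)
    if obs.shape != calc.shape or obs.size < 2:
        raise ValueError("observed and calculated arrays must match, length >= 2")
    r_global = float(sps.pearsonr(obs, calc).statistic)
    per_type: dict[str, float] = {}
    if records is not None:
        types = np.array([rec.coupling_type for rec in records])
        for t in COUPLING_TYPES:
            m = types == t
            if m.sum() >= 2 and np.std(obs[m]) > 0 and np.std(calc[m]) > 0:
                per_type[t] = float(sps.pearsonr(obs[m], calc[m]).statistic)
    denom = float(np.sum(obs**2))
    q = float(np.sqrt(np.sum((calc - obs) ** 2) / denom)) if denom > 0 else np.inf
    rms = float(np.sqrt(np.mean((calc - obs) ** 2)))
    return FitStatistics(pearson_r=r_global, pearson_r_by_type=per_type, q_factor=q, rms=rms)


def _solve_lstsq(
    a: np.ndarray, b: np.ndarray, rcond: float
) -> tuple[np.ndarray, int, float]:
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    cutoff = s[0] * rcond if s.size else 0.0
    keep = s > cutoff
    rank = int(keep.sum())
    inv = np.zeros_like(s)
    inv[keep] = 1.0 / s[keep]
    x = vt.T @ (inv * (u.T @ b))
    cond = float(s[0] / s[keep][-1]) if rank else np.inf
    return x, rank, cond


def _weighted(a: np.ndarray, b: np.ndarray, sigmas: np.ndarray | None):
    if sigmas is None:
        return a, b
    w = 1.0 / np.asarray(sigmas, dtype=float)
    return a * w[:, None], b * w


def _finalize(
    tensors, records, kept, d_obs, d_calc, rank, cond, skipped
) -> FitResult:
    recs = [records[i] for i in kept]
    stats = fit_statistics(d_obs, d_calc, recs)
    return FitResult(
        tensors=tensors,
        records=recs,
        d_obs=d_obs,
        d_calc=d_calc,
        stats=stats,
        effective_rank=rank,
        condition_number=cond,
        skipped=skipped,
    )


def svd_fit_single(
    structure: Structure,
    records: Sequence[RDCRecord],
    sigma_weighting: bool = False,
    fixed_hc_distance: bool = False,
) -> FitResult:
    """Fit one Saupe tensor to one template structure via SVD least squares."""
    vs = internuclear_vectors(structure, records, fixed_hc_distance)
    if len(vs.kept) < 5:
        raise UnderdeterminedFitError(f"only {len(vs.kept)} usable couplings; need >= 5")
    a = _design_rows(vs)
    b = np.array([records[i].value for i in vs.kept])
    sig = _record_sigmas(records, vs.kept) if sigma_weighting else None
    aw, bw = _weighted(a, b, sig)
    p, rank, cond = _solve_lstsq(aw, bw, rcond=1e-10)
    if rank < 5:
        _, _, vt = np.linalg.svd(aw, full_matrices=False)
        raise UnderdeterminedFitError(
            f"design matrix rank {rank} < 5; null-space directions:\n{vt[rank:]}"
        )
    tensor = AlignmentTensor.from_params(p)
    d_calc = a @ p
    return _finalize([tensor], records, vs.kept, b, d_calc, rank, cond, vs.skipped)


def _record_sigmas(records, kept) -> np.ndarray | None:
    sig = np.array([records[i].sigma if records[i].sigma else np.nan for i in kept])
    if np.isnan(sig).any():
        return None
    return sig


def _ensemble_designs(
    ensemble: Ensemble,
    records: Sequence[RDCRecord],
    weights: np.ndarray | None,
    fixed_hc_distance: bool,
):
    w = ensemble.weights if weights is None else np.asarray(weights, float) / np.sum(weights)
    designs, kept_ref, skipped = [], None, []
    for conf in ensemble:
        vs = internuclear_vectors(conf, records, fixed_hc_distance)
        if kept_ref is None:
            kept_ref, skipped = vs.kept, vs.skipped
        elif not np.array_equal(vs.kept, kept_ref):
            raise ValueError("conformers resolve different record subsets")
        designs.append(_design_rows(vs))
    return w, designs, kept_ref, skipped


def fit_ensemble_single_tensor(
    ensemble: Ensemble,
    records: Sequence[RDCRecord],
    weights: Sequence[float] | None = None,
    sigma_weighting: bool = False,
    fixed_hc_distance: bool = False,
) -> FitResult:
    """All conformers share one tensor; couplings are ensemble-averaged.

    The design rows are weight-averaged over conformers before solving, so
    the back-calculated couplings are the ensemble averages by construction.
    Only valid when every member of the physical ensemble aligns identically.
    """
    w, designs, kept, skipped = _ensemble_designs(ensemble, records, weights, fixed_hc_distance)
    if len(kept) < 5:
        raise UnderdeterminedFitError(f"only {len(kept)} usable couplings; need >= 5")
    a = np.einsum("c,cmk->mk", w, np.stack(designs))
    b = np.array([records[i].value for i in kept])
    sig = _record_sigmas(records, kept) if sigma_weighting else None
    aw, bw = _weighted(a, b, sig)
    p, rank, cond = _solve_lstsq(aw, bw, rcond=1e-10)
    if rank < 5:
        raise UnderdeterminedFitError(f"averaged design matrix rank {rank} < 5")
    tensor = AlignmentTensor.from_params(p)
    d_calc = a @ p
    return _finalize([tensor], records, kept, b, d_calc, rank, cond, skipped)


def fit_ensemble_multi_tensor(
    ensemble: Ensemble,
    records: Sequence[RDCRecord],
    weights: Sequence[float] | None = None,
    svalue_cutoff: float = 1e-6,
    sigma_weighting: bool = False,
    fixed_hc_distance: bool = False,
) -> FitResult:
    """One tensor per conformer, fitted jointly to ensemble-averaged couplings.

    The block design matrix is M x 5N (conformer i contributes its
    weight-scaled 5-column block); solved by truncated-SVD least squares
    with a relative singular-value cutoff.  With M < 5N the solution is the
    minimum-norm one and a conditioning warning is emitted.
    """
    w, designs, kept, skipped = _ensemble_designs(ensemble, records, weights, fixed_hc_distance)
    n = len(ensemble)
    m = len(kept)
    if m < 5:
        raise UnderdeterminedFitError(f"only {m} usable couplings; need >= 5")
    if m < 5 * n:
        warnings.warn(
            f"{m} couplings for {5 * n} tensor parameters; "
            "solution is truncated-SVD minimum-norm",
            stacklevel=2,
        )
    a = np.concatenate([w[i] * designs[i] for i in range(n)], axis=1)
    if not np.any(a):
        raise ValueError("all-zero design matrix")
    b = np.array([records[i].value for i in kept])
    sig = _record_sigmas(records, kept) if sigma_weighting else None
    aw, bw = _weighted(a, b, sig)
    p, rank, cond = _solve_lstsq(aw, bw, rcond=svalue_cutoff)
    tensors = [AlignmentTensor.from_params(p[5 * i : 5 * i + 5]) for i in range(n)]
    d_calc = a @ p
    return _finalize(tensors, records, kept, b, d_calc, rank, cond, skipped)


# ----------------------------------------------------------------------
# TSV dialect: header line, tab-separated; '#' comments
# ----------------------------------------------------------------------

def read_rdc_tsv(path: str | Path) -> list[RDCRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue", "type", "value_hz"}
    if not required.issubset(df.columns):
        raise ValueError(f"RDC table must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        sigma = row.get("sigma_hz")
        out.append(
            RDCRecord(
                residue_number=int(row["residue"]),
                coupling_type=str(row["type"]),
                value=float(row["value_hz"]),
                sigma=float(sigma) if sigma is not None and np.isfinite(sigma) else None,
            )
        )
    return out


def write_rdc_tsv(records: Sequence[RDCRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "residue": [r.residue_number for r in records],
            "type": [r.coupling_type for r in records],
            "value_hz": [r.value for r in records],
            "sigma_hz": [r.sigma if r.sigma is not None else np.nan for r in records],
        }
    )
    with open(path, "w") as fh:
        fh.write("# residual dipolar couplings (Hz)\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
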