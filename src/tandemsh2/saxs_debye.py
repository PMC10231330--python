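"""SAXS curve prediction with a residue-bead Debye model, ensemble
averaging, Guinier analysis and chi^2 comparison with experiment.

Each residue is represented by one bead at its Cα position carrying the
residue's electron count, with a shared Gaussian form-factor decay
exp(-(q sigma_bead)^2 / 2).  The scattering intensity follows the Debye
formula

    I(q) = sum_ij f_i(q) f_j(q) sin(q r_ij) / (q r_ij),

which is exact for an isotropically averaged collection of point-like
scatterers.  This is a deliberately coarse single-bead-per-residue model:
solvent-excluded volume and the hydration layer are not represented, so
absolute comparison with measured curves is approximate; internal
consistency (Guinier Rg vs. bead gyration radius, ensemble linearity) is
exact and is what the test-suite checks.

q is in nm^-1 throughout; bead coordinates are taken in Å and converted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from . import constants
from .structure_io import Ensemble, Structure

_A_TO_NM = 0.1


@dataclass
class SaxsCurve:
    """Scattering curve on an ascending q grid (q in nm^-1, I arbitrary)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or np.any(np.diff(self.q) <= 0) or np.any(self.q < 0):
            raise ValueError("q must be a strictly increasing non-negative grid")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")


@dataclass
class BeadModel:
    """One bead per residue: Cα centre (Å) and electron-count weight."""

    centers: np.ndarray          # (n, 3) Å
    weights: np.ndarray          # (n,) electrons
    sigma_bead: float = 3.0      # Å, Gaussian form-factor width

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.centers):
            raise ValueError("one weight per bead required")
        if np.any(self.weights <= 0):
            raise ValueError("bead weights must be positive")

    @classmethod
    def from_structure(cls, structure: Structure, sigma_bead: float = 3.0) -> "BeadModel":
        m = structure.atom_names == "CA"
        if not m.any():
            raise ValueError("structure has no Cα atoms")
        centers = structure.coords[m]
        weights = np.array(
            [
                constants.RESIDUE_ELECTRONS.get(rn, constants.DEFAULT_RESIDUE_ELECTRONS)
                for rn in structure.residue_names[m]
            ],
            dtype=float,
        )
        return cls(centers=centers, weights=weights, sigma_bead=sigma_bead)

    def gyration_radius(self) -> float:
        """Weight-weighted radius of gyration of the bead centres, nm."""
        com = np.average(self.centers, axis=0, weights=self.weights)
        d2 = np.sum((self.centers - com) ** 2, axis=1)
        return float(np.sqrt(np.average(d2, weights=self.weights))) * _A_TO_NM


def default_q_grid(qmax: float = 5.0, n: int = 201) -> np.ndarray:
    """Default momentum-transfer grid, 0..qmax nm^-1."""
    return np.linspace(0.0, qmax, n)


def debye_curve(model: BeadModel, q_grid: np.ndarray) -> SaxsCurve:
    """Debye-formula intensity of a bead model (vectorized over pairs)."""
    q = np.asarray(q_grid, dtype=float)
    w = model.weights
    r_nm = pdist(model.centers) * _A_TO_NM
    wpair = (w[:, None] * w[None, :])[np.triu_indices(len(w), k=1)]
    # sinc(x/pi) = sin(x)/x with the x->0 limit handled; pair chunks keep
    # the q x pairs workspace bounded
    cross = np.zeros_like(q)
    chunk = max(1, int(2**22 / max(len(q), 1)))
    for lo in range(0, len(r_nm), chunk):
        qr = q[:, None] * r_nm[None, lo : lo + chunk]
        cross += 2.0 * (wpair[None, lo : lo + chunk] * np.sinc(qr / np.pi)).sum(axis=1)
    self_term = float(np.sum(w**2))
    form = np.exp(-((q * model.sigma_bead * _A_TO_NM) ** 2) / 2.0)
    return SaxsCurve(q=q, intensity=form**2 * (self_term + cross))


def debye_curve_bruteforce(model: BeadModel, q_grid: np.ndarray) -> SaxsCurve:
    """Naive double-loop Debye sum (independent reference implementation)."""
    q = np.asarray(q_grid, dtype=float)
    n = len(model.weights)
    form = np.exp(-((q * model.sigma_bead * _A_TO_NM) ** 2) / 2.0)
    out = np.zeros_like(q)
    for i in range(n):
        for j in range(n):
            r = np.linalg.norm(model.centers[i] - model.centers[j]) * _A_TO_NM
            fi = model.weights[i]
            fj = model.weights[j]
            if r == 0.0:
                out += fi * fj
            else:
                qr = q * r
                term = np.where(qr == 0.0, 1.0, np.sin(qr) / np.where(qr == 0.0, 1.0, qr))
                out += fi * fj * term
    return SaxsCurve(q=q, intensity=form**2 * out)


def ensemble_curve(
    ensemble: Ensemble,
    q_grid: np.ndarray,
    weights: Sequence[float] | None = None,
    sigma_bead: float = 3.0,
) -> SaxsCurve:
    """Weighted mean of per-conformer Debye curves."""
    w = ensemble.weights if weights is None else np.asarray(weights, float) / np.sum(weights)
    total = None
    for wi, conf in zip(w, ensemble):
        c = debye_curve(BeadModel.from_structure(conf, sigma_bead), q_grid)
        total = wi * c.intensity if total is None else total + wi * c.intensity
    return SaxsCurve(q=np.asarray(q_grid, dtype=float), intensity=total)


@dataclass
class GuinierResult:
    rg: float          # nm
    i0: float
    q_window: tuple[float, float]
    n_points: int
    iterations: int
    r_value: float     # Pearson r of the ln I vs q^2 fit


def guinier_rg(
    curve: SaxsCurve, qmax_rg: float = 1.3, max_iter: int = 20
) -> GuinierResult:
    """Guinier fit with self-consistent window determination.

    Fits ln I = ln I0 - (Rg^2 / 3) q^2 over q.Rg <= ``qmax_rg``, iterating
    the window bound from the fitted Rg until it stabilizes.
    """
    q = curve.q
    i = curve.intensity
    pos = i > 0
    if pos.sum() < 3:
        raise ValueError("need at least 3 positive intensities")
    qbound = q[pos][min(10, pos.sum() - 1)]  # initial low-q window
    rg_prev = None
    for it in range(1, max_iter + 1):
        m = pos & (q <= qbound) & (q > 0)
        if m.sum() < 3:
            raise ValueError("fewer than 3 points in the Guinier window")
        x = q[m] ** 2
        y = np.log(i[m])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            raise ValueError("non-decaying curve: positive Guinier slope")
        rg = float(np.sqrt(-3.0 * slope))
        if rg_prev is not None and abs(rg - rg_prev) < 1e-9:
            break
        rg_prev = rg
        qbound = qmax_rg / rg
    else:
        raise ValueError("Guinier window did not converge")
    m = pos & (q <= qbound) & (q > 0)
    x = q[m] ** 2
    y = np.log(i[m])
    r = float(np.corrcoef(x, y)[0, 1])
    return GuinierResult(
        rg=rg,
        i0=float(np.exp(intercept)),
        q_window=(float(q[m].min()), float(q[m].max())),
        n_points=int(m.sum()),
        iterations=it,
        r_value=r,
    )


@dataclass
class Chi2Result:
    chi2: float
    scale: float
    offset: float
    n_points: int
    n_params: int


def chi2(
    calc: SaxsCurve,
    exp: SaxsCurve,
    fit_scale: bool = True,
    fit_offset: bool = False,
) -> Chi2Result:
    """Reduced chi^2 of a calculated against an experimental curve.

    The calculated curve is linearly interpolated onto the experimental q
    grid (no extrapolation); scale (and optionally offset) minimise the
    weighted residual.  chi^2 = sum[((c I_calc + b - I_exp)/sigma)^2]/(M-p).
    """
    qlo = max(calc.q[0], exp.q[0])
    qhi = min(calc.q[-1], exp.q[-1])
    if qlo >= qhi:
        raise ValueError("calculated and experimental q ranges do not overlap")
    m = (exp.q >= qlo) & (exp.q <= qhi)
    qe = exp.q[m]
    ie = exp.intensity[m]
    sig = exp.sigma[m] if exp.sigma is not None else np.ones_like(ie)
    ic = np.interp(qe, calc.q, calc.intensity)
    cols = []
    if fit_scale:
        cols.append(ic)
    if fit_offset:
        cols.append(np.ones_like(ic))
    p = len(cols)
    if p:
        a = np.stack(cols, axis=1) / sig[:, None]
        b = ie / sig
        coef, *_ = np.linalg.lstsq(a, b, rcond=None)
        fitted = np.stack(cols, axis=1) @ coef
        scale = float(coef[0]) if fit_scale else 1.0
        offset = float(coef[-1]) if fit_offset else 0.0
    else:
        fitted = ic
        scale, offset = 1.0, 0.0
    dof = max(len(qe) - p, 1)
    val = float(np.sum(((fitted - ie) / sig) ** 2) / dof)
    return Chi2Result(chi2=val, scale=scale, offset=offset, n_points=len(qe), n_params=p)


# ----------------------------------------------------------------------
# .dat dialect: 2-3 column whitespace-separated text, '#' headers
# ----------------------------------------------------------------------

def read_saxs_dat(path: str | Path) -> SaxsCurve:
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected 2-3 column scattering data")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SaxsCurve(q=data[:, 0], intensity=data[:, 1], sigma=sigma)


def write_saxs_dat(curve: SaxsCurve, path: str | Path) -> None:
    cols = [curve.q, curve.intensity]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    np.savetxt(
        path,
        np.stack(cols, axis=1),
        header="q_nm^-1 I(q) [sigma]",
        fmt="%.8e",
    )
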