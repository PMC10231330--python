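"""Bivalent-phosphopeptide (BTAM) linkage-compatibility screening.

A BTAM bridges the two SH2 domains with a linker of roughly 40 Å; whether a
tandem-SH2 conformation can be bridged is decided by superposing
peptide-bound single-domain templates (N-SH2 + ITIM-like peptide, C-SH2 +
ITSM-like peptide) onto the conformation and measuring the anchor-to-anchor
distance in the two topologically distinct directions:

* head-to-tail (h2t): backbone C of the N-SH2-bound peptide's +6 residue to
  backbone N of the C-SH2-bound peptide's -4 residue;
* tail-to-head (t2h): backbone C of the C-SH2-bound peptide's +6 residue to
  backbone N of the N-SH2-bound peptide's -4 residue

(peptide residues numbered relative to the phosphotyrosine, pY = 0).
Distances <= ~40 Å mark conformations compatible with that linkage
direction.  A straight-segment heuristic flags arrangements whose connecting
linker would have to pass through the protein.  Displacement metrics
(d_N-SH2, rmsd after C-SH2 anchoring) locate each conformation relative to
an autoinhibited reference.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import binned_statistic_2d

from .geometry import com_distance, rmsd, superpose
from .structure_io import Ensemble, Selection, Structure, ca_selection
from . import constants


class SuperpositionSupportError(ValueError):
    """Raised when template and conformer share too few fit residues."""


@dataclass(frozen=True)
class AtomSpec:
    """Unique atom address: residue number + atom name (+ optional chain)."""

    residue_number: int
    atom_name: str
    chain_id: str | None = None

    def locate(self, structure: Structure) -> int:
        m = (structure.residue_numbers == self.residue_number) & (
            structure.atom_names == self.atom_name
        )
        if self.chain_id is not None:
            m &= structure.chain_ids == self.chain_id
        idx = np.where(m)[0]
        if len(idx) != 1:
            raise ValueError(
                f"atom spec {self} resolved to {len(idx)} atoms (need exactly 1)"
            )
        return int(idx[0])


@dataclass
class PeptideTemplate:
    """A peptide-bound SH2 template used for anchor placement.

    ``head_anchor`` is the backbone C of the bound peptide's +6 residue,
    ``tail_anchor`` the backbone N of its -4 residue (pY-relative
    numbering mapped onto the template's own residue numbers).
    """

    structure: Structure
    domain_fit_selection: Selection
    head_anchor: AtomSpec
    tail_anchor: AtomSpec

    def __post_init__(self):
        if self.structure.select(self.domain_fit_selection).n_atoms < 20:
            raise SuperpositionSupportError("template fit selection has < 20 atoms")
        self.head_anchor.locate(self.structure)
        self.tail_anchor.locate(self.structure)


def _shared_ca_fit(
    template: PeptideTemplate, conformer: Structure, min_support: int = 20
):
    """Superpose the template domain onto the conformer over shared Cα residues."""
    t_dom = template.structure.select(template.domain_fit_selection)
    t_ca = t_dom.atom_names == "CA"
    t_res = t_dom.residue_numbers[t_ca]
    sel_ranges = template.domain_fit_selection.residue_ranges
    c_sel = Selection(residue_ranges=sel_ranges, atom_names=frozenset({"CA"}))
    c_dom = conformer.select(c_sel)
    shared = np.intersect1d(t_res, c_dom.residue_numbers)
    if len(shared) < min_support:
        raise SuperpositionSupportError(
            f"only {len(shared)} shared fit residues (< {min_support})"
        )
    t_coords = t_dom.coords[t_ca][np.isin(t_res, shared)]
    c_coords = c_dom.coords[np.isin(c_dom.residue_numbers, shared)]
    return superpose(t_coords, c_coords)


@dataclass
class LinkageResult:
    d_h2t: float
    d_t2h: float
    transformed_n_anchor_head: np.ndarray  # C of +6, N-template
    transformed_n_anchor_tail: np.ndarray  # N of -4, N-template
    transformed_c_anchor_head: np.ndarray  # C of +6, C-template
    transformed_c_anchor_tail: np.ndarray  # N of -4, C-template


def linkage_distances(
    conformer: Structure,
    n_template: PeptideTemplate,
    c_template: PeptideTemplate,
    min_support: int = 20,
) -> LinkageResult:
    """Head-to-tail and tail-to-head anchor distances for one conformation.

    Superposes the templates onto the conformer's two domains (shared-residue
    Cα fit) and measures d_h2t = |C(+6, N-peptide) - N(-4, C-peptide)| and
    d_t2h = |C(+6, C-peptide) - N(-4, N-peptide)| in Å.
    """
    fit_n = _shared_ca_fit(n_template, conformer, min_support)
    fit_c = _shared_ca_fit(c_template, conformer, min_support)
    nh = fit_n.apply(
        n_template.structure.coords[n_template.head_anchor.locate(n_template.structure)]
    )
    nt = fit_n.apply(
        n_template.structure.coords[n_template.tail_anchor.locate(n_template.structure)]
    )
    ch = fit_c.apply(
        c_template.structure.coords[c_template.head_anchor.locate(c_template.structure)]
    )
    ct = fit_c.apply(
        c_template.structure.coords[c_template.tail_anchor.locate(c_template.structure)]
    )
    return LinkageResult(
        d_h2t=float(np.linalg.norm(nh - ct)),
        d_t2h=float(np.linalg.norm(ch - nt)),
        transformed_n_anchor_head=nh,
        transformed_n_anchor_tail=nt,
        transformed_c_anchor_head=ch,
        transformed_c_anchor_tail=ct,
    )


def linker_clash(
    conformer: Structure,
    anchor_a: np.ndarray,
    anchor_b: np.ndarray,
    probe_radius: float = 2.0,
    step: float = 0.5,
    exclude_radius: float = 1.0,
) -> bool:
    """Straight-segment clash heuristic for the connecting peptide linker.

    Samples the segment between the transformed anchors every ``step`` Å and
    reports a clash if any sample lies within ``probe_radius`` of a heavy
    atom of the conformer (samples within ``exclude_radius`` of either
    anchor are ignored so the anchors themselves never trigger).
    """
    a = np.asarray(anchor_a, float)
    b = np.asarray(anchor_b, float)
    length = np.linalg.norm(b - a)
    n_samples = max(int(np.ceil(length / step)) + 1, 2)
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    pts = a + t * (b - a)
    keep = (np.linalg.norm(pts - a, axis=1) > exclude_radius) & (
        np.linalg.norm(pts - b, axis=1) > exclude_radius
    )
    pts = pts[keep]
    if len(pts) == 0:
        return False
    heavy = conformer.coords[conformer.elements != "H"]
    return bool(np.any(cdist(pts, heavy) < probe_radius))


@dataclass
class LinkageDistances:
    """Per-conformer linkage screen results (a tidy DataFrame wrapper)."""

    table: pd.DataFrame  # columns: conformer, d_h2t, d_t2h, clash_h2t, clash_t2h, d_n_sh2, rmsd_n_sh2

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# BTAM linkage-compatibility screen (distances in Å)\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.3f")


def screen_ensemble(
    ensemble: Ensemble,
    n_template: PeptideTemplate,
    c_template: PeptideTemplate,
    autoinhibited_reference: Structure | None = None,
    n_sh2: Selection | None = None,
    c_sh2: Selection | None = None,
    min_support: int = 20,
    probe_radius: float = 2.0,
) -> LinkageDistances:
    """Run the full linkage screen over an ensemble."""
    n_sh2 = n_sh2 or ca_selection(*constants.N_SH2_RANGE)
    c_sh2 = c_sh2 or ca_selection(*constants.C_SH2_RANGE)
    rows = []
    for i, conf in enumerate(ensemble):
        res = linkage_distances(conf, n_template, c_template, min_support)
        clash_h = linker_clash(
            conf, res.transformed_n_anchor_head, res.transformed_c_anchor_tail, probe_radius
        )
        clash_t = linker_clash(
            conf, res.transformed_c_anchor_head, res.transformed_n_anchor_tail, probe_radius
        )
        row = {
            "conformer": i,
            "d_h2t": res.d_h2t,
            "d_t2h": res.d_t2h,
            "clash_h2t": clash_h,
            "clash_t2h": clash_t,
        }
        if autoinhibited_reference is not None:
            d, r = displacement_metrics(
                conf, autoinhibited_reference, n_sh2=n_sh2, c_sh2=c_sh2
            )
            row["d_n_sh2"] = d
            row["rmsd_n_sh2"] = r
        rows.append(row)
    return LinkageDistances(table=pd.DataFrame(rows))


def fraction_below(
    distances: LinkageDistances | pd.DataFrame,
    threshold: float = 40.0,
) -> dict[str, tuple[float, tuple[float, float]]]:
    """Fraction of conformers with d < threshold, with Wilson 95% intervals."""
    from statsmodels.stats.proportion import proportion_confint

    df = distances.table if isinstance(distances, LinkageDistances) else distances
    out = {}
    n = len(df)
    if n < 1:
        raise ValueError("need at least one conformer")
    for col in ("d_h2t", "d_t2h"):
        k = int((df[col] < threshold).sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        out[col] = (k / n, (float(lo), float(hi)))
    return out


def displacement_metrics(
    conformer: Structure,
    autoinhibited_reference: Structure,
    n_sh2: Selection | None = None,
    c_sh2: Selection | None = None,
) -> tuple[float, float]:
    """(d_N-SH2, rmsd_N-SH2) relative to an autoinhibited reference.

    Superposes the conformer onto the reference at the C-SH2 Cα atoms, then
    measures the N-SH2 centre-of-mass displacement and the N-SH2 Cα RMSD
    (without re-fitting).
    """
    n_sh2 = n_sh2 or ca_selection(*constants.N_SH2_RANGE)
    c_sh2 = c_sh2 or ca_selection(*constants.C_SH2_RANGE)
    d = com_distance(conformer, autoinhibited_reference, anchor=c_sh2, probe=n_sh2)
    fit = superpose(conformer.select(c_sh2).coords, autoinhibited_reference.select(c_sh2).coords)
    moved = fit.apply(conformer.select(n_sh2).coords)
    r = rmsd(moved, autoinhibited_reference.select(n_sh2).coords, fit=False)
    return d, r


def essential_plane_map(
    projections: np.ndarray,
    values: np.ndarray,
    bins: tuple[int, int] = (32, 32),
    statistic: str = "mean",
):
    """Per-bin statistic of a scalar property over the PC1/PC2 plane.

    Returns (masked statistic grid, pc1 edges, pc2 edges); empty bins are
    masked.  ``statistic`` is one of min/mean/max.
    """
    if statistic not in ("min", "mean", "max"):
        raise ValueError("statistic must be min, mean or max")
    p = np.asarray(projections, float)
    v = np.asarray(values, float)
    if len(p) != len(v):
        raise ValueError("projections and values must align")
    res = binned_statistic_2d(p[:, 0], p[:, 1], v, statistic=statistic, bins=bins)
    grid = np.ma.masked_invalid(res.statistic)
    return grid, res.x_edge, res.y_edge


def steric_openness(
    tandem_conformer: Structure,
    full_length_reference: Structure,
    c_sh2: Selection | None = None,
    n_sh2: Selection | None = None,
    ptp_selection: Selection | None = None,
    clash_cutoff: float = 2.5,
    max_overlaps: int = 0,
) -> tuple[bool, int]:
    """Would this tandem arrangement leave the catalytic domain unobstructed?

    Superposes the conformer at C-SH2 onto a full-length reference and
    counts N-SH2 heavy atoms within ``clash_cutoff`` Å of catalytic-domain
    (PTP) heavy atoms.  Returns (count <= max_overlaps, count).
    """
    n_sh2 = n_sh2 or ca_selection(*constants.N_SH2_RANGE)
    c_sh2 = c_sh2 or ca_selection(*constants.C_SH2_RANGE)
    ptp_selection = ptp_selection or Selection(residue_ranges=((221, 524),))
    fit = superpose(
        tandem_conformer.select(c_sh2).coords, full_length_reference.select(c_sh2).coords
    )
    n_dom = tandem_conformer.select(
        Selection(residue_ranges=n_sh2.residue_ranges)
    )
    n_heavy = fit.apply(n_dom.coords[n_dom.elements != "H"])
    ptp = full_length_reference.select(ptp_selection)
    ptp_heavy = ptp.coords[ptp.elements != "H"]
    count = int(np.sum(np.any(cdist(n_heavy, ptp_heavy) < clash_cutoff, axis=1)))
    return count <= max_overlaps, count
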