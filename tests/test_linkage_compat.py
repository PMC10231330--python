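"""Bivalent-peptide linkage screening: anchor distances, clash heuristic,
displacement metrics and essential-plane property maps."""

import numpy as np
import pytest

from tandemsh2 import constants
from tandemsh2.linkage_compat import (
    AtomSpec,
    PeptideTemplate,
    displacement_metrics,
    essential_plane_map,
    fraction_below,
    linkage_distances,
    linker_clash,
    screen_ensemble,
    steric_openness,
)
from tandemsh2.structure_io import Selection, Structure, ca_selection


def _rot(axis, angle_deg):
    a = np.asarray(axis, float)
    a /= np.linalg.norm(a)
    t = np.radians(angle_deg)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def _make_template(conformer, domain_range, pep_first_res, tail_point, head_point):
    """Synthetic peptide-bound template built from the conformer's own domain.

    An 11-residue peptide trace runs from ``tail_point`` (backbone N of the
    -4 residue) to ``head_point`` (backbone C of the +6 residue).
    """
    dom = conformer.select(Selection(residue_ranges=(domain_range,)))
    t = np.linspace(0.0, 1.0, 22)
    line = np.asarray(tail_point) + t[:, None] * (
        np.asarray(head_point) - np.asarray(tail_point)
    )
    names, resn, rnames, coords = [], [], [], []
    for i in range(11):
        res = pep_first_res + i
        names += ["N", "C"]
        resn += [res, res]
        rnames += ["GLY", "GLY"]
        coords += [line[2 * i], line[2 * i + 1]]
    merged = Structure(
        np.concatenate([dom.atom_names, names]),
        np.concatenate([dom.residue_numbers, resn]),
        np.concatenate([dom.residue_names, rnames]),
        np.concatenate([dom.chain_ids, ["P"] * 22]),
        np.concatenate([dom.elements, [n[0] for n in names]]),
        np.vstack([dom.coords, coords]),
        label="synthetic peptide-bound template",
    )
    return PeptideTemplate(
        structure=merged,
        domain_fit_selection=ca_selection(*domain_range),
        head_anchor=AtomSpec(pep_first_res + 10, "C"),
        tail_anchor=AtomSpec(pep_first_res, "N"),
    )


@pytest.fixture(scope="module")
def templates(multibasin_ensemble):
    conf = multibasin_ensemble[0][0]
    n_com = conf.select(ca_selection(*constants.N_SH2_RANGE)).coords.mean(axis=0)
    c_com = conf.select(ca_selection(*constants.C_SH2_RANGE)).coords.mean(axis=0)
    out = n_com - c_com
    out /= np.linalg.norm(out)
    n_tpl = _make_template(
        conf, constants.N_SH2_RANGE, 301,
        tail_point=n_com + out * 18.0 + [3.0, 0, 0],
        head_point=n_com + out * 18.0 + [20.0, 0, 0],
    )
    c_tpl = _make_template(
        conf, constants.C_SH2_RANGE, 401,
        tail_point=c_com - out * 18.0 + [3.0, 0, 0],
        head_point=c_com - out * 18.0 + [20.0, 0, 0],
    )
    return conf, n_tpl, c_tpl


class TestLinkageDistances:
    def test_direct_geometry_on_own_conformer(self, templates):
        # templates built from the conformer's own domains superpose with
        # the identity, so the distances follow directly from the anchors
        conf, n_tpl, c_tpl = templates
        res = linkage_distances(conf, n_tpl, c_tpl)
        nh = n_tpl.structure.coords[n_tpl.head_anchor.locate(n_tpl.structure)]
        nt = n_tpl.structure.coords[n_tpl.tail_anchor.locate(n_tpl.structure)]
        ch = c_tpl.structure.coords[c_tpl.head_anchor.locate(c_tpl.structure)]
        ct = c_tpl.structure.coords[c_tpl.tail_anchor.locate(c_tpl.structure)]
        assert res.d_h2t == pytest.approx(np.linalg.norm(nh - ct), abs=1e-8)
        assert res.d_t2h == pytest.approx(np.linalg.norm(ch - nt), abs=1e-8)

    def test_coincident_anchors_give_zero(self, templates):
        conf, n_tpl, c_tpl = templates
        # move the C-template peptide so its -4 N sits exactly on the
        # N-template's +6 C
        nh = n_tpl.structure.coords[n_tpl.head_anchor.locate(n_tpl.structure)]
        ct_idx = c_tpl.tail_anchor.locate(c_tpl.structure)
        shift = nh - c_tpl.structure.coords[ct_idx]
        pep = c_tpl.structure.chain_ids == "P"
        coords = c_tpl.structure.coords.copy()
        coords[pep] += shift
        moved = PeptideTemplate(
            structure=c_tpl.structure.with_coords(coords),
            domain_fit_selection=c_tpl.domain_fit_selection,
            head_anchor=c_tpl.head_anchor,
            tail_anchor=c_tpl.tail_anchor,
        )
        res = linkage_distances(conf, n_tpl, moved)
        assert res.d_h2t == pytest.approx(0.0, abs=1e-8)

    def test_translation_along_anchor_axis_adds_exactly(self, templates):
        conf, n_tpl, c_tpl = templates
        base = linkage_distances(conf, n_tpl, c_tpl)
        u = base.transformed_c_anchor_tail - base.transformed_n_anchor_head
        u /= np.linalg.norm(u)
        m = Selection(residue_ranges=(constants.C_SH2_RANGE,)).mask(conf)
        coords = conf.coords.copy()
        coords[m] += 10.0 * u
        res = linkage_distances(conf.with_coords(coords), n_tpl, c_tpl)
        assert res.d_h2t == pytest.approx(base.d_h2t + 10.0, abs=1e-6)

    def test_rigid_motion_invariance(self, templates):
        conf, n_tpl, c_tpl = templates
        base = linkage_distances(conf, n_tpl, c_tpl)
        g = _rot([0.3, -1, 2], 84.0)
        moved = conf.with_coords(conf.coords @ g.T + np.array([12.0, 5.0, -8.0]))
        res = linkage_distances(moved, n_tpl, c_tpl)
        assert res.d_h2t == pytest.approx(base.d_h2t, abs=1e-8)
        assert res.d_t2h == pytest.approx(base.d_t2h, abs=1e-8)

    def test_anchor_role_swap_swaps_distances(self, templates):
        conf, n_tpl, c_tpl = templates
        base = linkage_distances(conf, n_tpl, c_tpl)

        def _swapped(tpl):
            return PeptideTemplate(
                structure=tpl.structure,
                domain_fit_selection=tpl.domain_fit_selection,
                head_anchor=AtomSpec(tpl.tail_anchor.residue_number, "N"),
                tail_anchor=AtomSpec(tpl.head_anchor.residue_number, "C"),
            )

        res = linkage_distances(conf, _swapped(n_tpl), _swapped(c_tpl))
        assert res.d_h2t == pytest.approx(base.d_t2h, abs=1e-8)
        assert res.d_t2h == pytest.approx(base.d_h2t, abs=1e-8)

    def test_insufficient_support_raises(self, templates):
        from tandemsh2.linkage_compat import SuperpositionSupportError

        conf, n_tpl, c_tpl = templates
        small = conf.select(Selection(residue_ranges=((3, 20), (105, 216))))
        with pytest.raises(SuperpositionSupportError):
            linkage_distances(small, n_tpl, c_tpl)


class TestScreenAndFractions:
    def test_screen_table_and_trivial_fractions(self, multibasin_ensemble, templates):
        _, n_tpl, c_tpl = templates
        ens = multibasin_ensemble[0].subset([0, 1, 2, 3])
        screen = screen_ensemble(ens, n_tpl, c_tpl, autoinhibited_reference=ens[0])
        assert len(screen.table) == 4
        assert (screen.table["d_h2t"] >= 0).all()
        fr = fraction_below(screen, threshold=1e9)
        assert fr["d_h2t"][0] == 1.0
        fr0 = fraction_below(screen, threshold=0.0)
        assert fr0["d_h2t"][0] == 0.0

    def test_planted_fraction_within_wilson_interval(self):
        import pandas as pd

        n = 400
        local = np.random.default_rng(2024)
        dists = local.uniform(20, 60, size=n)  # true mass below 40: 0.5
        df = pd.DataFrame({"d_h2t": dists, "d_t2h": dists})
        frac, (lo, hi) = fraction_below(df, threshold=40.0)["d_h2t"]
        assert frac == pytest.approx((dists < 40).mean())
        assert lo <= frac <= hi
        # binomial 3-sigma band around the planted mass
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_tsv_export(self, multibasin_ensemble, templates, tmp_path):
        _, n_tpl, c_tpl = templates
        ens = multibasin_ensemble[0].subset([0, 1])
        screen = screen_ensemble(ens, n_tpl, c_tpl)
        screen.to_tsv(tmp_path / "screen.tsv")
        import pandas as pd

        back = pd.read_csv(tmp_path / "screen.tsv", sep="\t", comment="#")
        assert list(back["conformer"]) == [0, 1]


class TestLinkerClash:
    def test_far_segment_no_clash(self, tandem_conformer):
        com = tandem_conformer.coords.mean(axis=0)
        a = com + np.array([200.0, 0, 0])
        b = com + np.array([200.0, 50.0, 0])
        assert linker_clash(tandem_conformer, a, b) is False

    def test_segment_through_core_clashes(self, tandem_conformer):
        n_com = tandem_conformer.select(
            ca_selection(*constants.N_SH2_RANGE)
        ).coords.mean(axis=0)
        direction = np.array([1.0, 0.3, -0.2])
        direction /= np.linalg.norm(direction)
        a = n_com - 30.0 * direction
        b = n_com + 30.0 * direction
        assert linker_clash(tandem_conformer, a, b) is True


class TestDisplacementMetrics:
    def test_reference_against_itself(self, tandem_conformer):
        d, r = displacement_metrics(tandem_conformer, tandem_conformer)
        assert d == pytest.approx(0.0, abs=1e-8)
        assert r == pytest.approx(0.0, abs=1e-8)

    def test_planted_translation(self, tandem_conformer):
        s = tandem_conformer
        m = Selection(residue_ranges=(constants.N_SH2_RANGE,)).mask(s)
        coords = s.coords.copy()
        coords[m] += np.array([15.0, 0.0, 0.0])
        d, r = displacement_metrics(s.with_coords(coords), s)
        assert d == pytest.approx(15.0, abs=1e-8)
        assert r == pytest.approx(15.0, abs=1e-8)  # pure translation, no re-fit

    def test_consistency_with_geometry_primitives(self, multibasin_ensemble):
        from tandemsh2.geometry import com_distance

        ens = multibasin_ensemble[0]
        n_sel = ca_selection(*constants.N_SH2_RANGE)
        c_sel = ca_selection(*constants.C_SH2_RANGE)
        d, _ = displacement_metrics(ens[1], ens[0])
        d_direct = com_distance(ens[1], ens[0], anchor=c_sel, probe=n_sel)
        assert d == pytest.approx(d_direct, abs=1e-8)


class TestEssentialPlaneMap:
    def test_constant_values_constant_map(self, rng):
        proj = rng.normal(size=(100, 2))
        grid, _, _ = essential_plane_map(proj, np.full(100, 7.5), bins=(6, 6))
        assert np.allclose(grid.compressed(), 7.5)

    def test_single_point_single_bin(self):
        grid, _, _ = essential_plane_map(
            np.array([[0.5, 0.5]]), np.array([3.0]), bins=(4, 4)
        )
        assert grid.count() == 1

    def test_min_le_mean_le_max(self, rng):
        proj = rng.normal(size=(500, 2))
        vals = rng.uniform(0, 100, size=500)
        gmin, _, _ = essential_plane_map(proj, vals, bins=(5, 5), statistic="min")
        gmean, _, _ = essential_plane_map(proj, vals, bins=(5, 5), statistic="mean")
        gmax, _, _ = essential_plane_map(proj, vals, bins=(5, 5), statistic="max")
        assert np.all(gmin.filled(0) <= gmean.filled(0) + 1e-12)
        assert np.all(gmean.filled(0) <= gmax.filled(0) + 1e-12)


class TestStericOpenness:
    @pytest.fixture(scope="class")
    def full_length_reference(self, tandem_conformer):
        from tandemsh2.synthetic_ensemble import make_pseudo_domain

        ptp = make_pseudo_domain(120, seed=99, first_residue=221).structure
        tandem = tandem_conformer
        offset = tandem.coords.mean(axis=0) + np.array([60.0, 0.0, 0.0])
        ptp_coords = ptp.coords - ptp.coords.mean(axis=0) + offset
        merged = Structure(
            np.concatenate([tandem.atom_names, ptp.atom_names]),
            np.concatenate([tandem.residue_numbers, ptp.residue_numbers]),
            np.concatenate([tandem.residue_names, ptp.residue_names]),
            np.concatenate([tandem.chain_ids, ptp.chain_ids]),
            np.concatenate([tandem.elements, ptp.elements]),
            np.vstack([tandem.coords, ptp_coords]),
        )
        return merged

    def test_own_tandem_is_open(self, tandem_conformer, full_length_reference):
        ok, count = steric_openness(tandem_conformer, full_length_reference)
        assert ok is True
        assert count == 0

    def test_probe_domain_moved_into_ptp_clashes(
        self, tandem_conformer, full_length_reference
    ):
        ref = full_length_reference
        ptp_com = ref.select(Selection(residue_ranges=((221, 340),))).coords.mean(axis=0)
        s = tandem_conformer
        m = Selection(residue_ranges=(constants.N_SH2_RANGE,)).mask(s)
        coords = s.coords.copy()
        coords[m] += ptp_com - coords[m].mean(axis=0)
        ok, count = steric_openness(s.with_coords(coords), ref)
        assert ok is False
        assert count > 0

    def test_count_monotone_in_cutoff(self, tandem_conformer, full_length_reference):
        ref = full_length_reference
        ptp_com = ref.select(Selection(residue_ranges=((221, 340),))).coords.mean(axis=0)
        s = tandem_conformer
        m = Selection(residue_ranges=(constants.N_SH2_RANGE,)).mask(s)
        coords = s.coords.copy()
        coords[m] += ptp_com - coords[m].mean(axis=0)
        moved = s.with_coords(coords)
        counts = [
            steric_openness(moved, ref, clash_cutoff=c)[1] for c in (1.5, 2.5, 4.0)
        ]
        assert counts[0] <= counts[1] <= counts[2]
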