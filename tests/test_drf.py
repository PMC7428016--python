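"""The directional-reactivity score: selection, summation, symmetry, ranking."""

import numpy as np
import pytest

from conftest import random_rotation
from dirreact import fixtures as fx
from dirreact.drf import (
    DEFAULT_TAU,
    DRFParameters,
    classify_orientation,
    compute_drf,
    rank_by_drf,
    score_molecule,
    select_fukui_mode,
    site_contributions,
)
from dirreact.fukui import DipoleVector, FukuiVector, dipole_from_point_charges
from dirreact.molecule import Atom, Molecule, TerminalSite


def _site(direction, heavy=0, sub=1):
    d = np.asarray(direction, float)
    return TerminalSite(heavy, sub, d / np.linalg.norm(d))


class TestFukuiModeSelection:
    def test_positive_receptor_uses_nucleophilic_sites(self):
        # ion screening flips the sign the ligand sees: +Q receptor -> F+
        assert select_fukui_mode(4.1) == "f_plus"

    def test_negative_receptor_uses_electrophilic_sites(self):
        assert select_fukui_mode(-4.1) == "f_minus"

    def test_override_wins(self):
        assert select_fukui_mode(4.1, override="f_minus") == "f_minus"

    def test_zero_charge_without_override_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            select_fukui_mode(0.0)


class TestSiteContributions:
    def test_zero_dipole_zeroes_every_term(self):
        sites = [_site((1, 0, 0)), _site((0, 1, 0), heavy=1)]
        fv = FukuiVector("f_plus", np.array([0.5, 0.5]))
        out = site_contributions(sites, fv, DipoleVector(np.zeros(3)))
        assert all(c.term == 0.0 and c.cos_phi == 0.0 for c in out)

    def test_parallel_site_analytic_value(self):
        out = site_contributions(
            [_site((1, 0, 0))],
            FukuiVector("f_plus", np.array([0.05])),
            DipoleVector(np.array([10.0, 0, 0])),
        )
        assert out[0].term == pytest.approx(0.5, abs=1e-12)

    def test_terms_match_bruteforce_dot_products(self, planted_fixture):
        spec, mol, (neutral, anion, cation) = planted_fixture
        from dirreact.molecule import find_terminal_sites, perceive_bonds

        bonds = perceive_bonds(mol)
        sites = find_terminal_sites(mol, bonds)
        d = dipole_from_point_charges(mol, neutral)
        fv = FukuiVector("f_plus", neutral.charges - anion.charges)
        out = site_contributions(sites, fv, d)
        dmag = float(np.linalg.norm(d.vector))
        for c, s in zip(out, sites):
            cos = sum(s.direction[k] * d.vector[k] for k in range(3)) / dmag
            assert c.cos_phi == pytest.approx(cos, abs=1e-12)
            assert c.term == pytest.approx(fv.values[s.heavy_index] * dmag * cos, abs=1e-12)

    def test_missing_fukui_entry_rejected(self):
        with pytest.raises(KeyError):
            site_contributions(
                [_site((1, 0, 0), heavy=5)],
                FukuiVector("f_plus", np.array([0.1]), condensed=True),
                DipoleVector(np.array([1.0, 0, 0])),
                heavy_index_map={0: 0},
            )


class TestComputeDrf:
    def test_arithmetic_example(self):
        out = site_contributions(
            [_site((1, 0, 0))],
            FukuiVector("f_plus", np.array([0.05])),
            DipoleVector(np.array([10.0, 0, 0])),
        )
        res = compute_drf(out, q_net=4.1)
        assert res.drf == pytest.approx(2.05, abs=1e-12)

    def test_linearity_in_clr_qnet_and_dipole(self, planted_fixture):
        spec, mol, (n, a, c) = planted_fixture
        d = dipole_from_point_charges(mol, n)
        base = score_molecule(mol, n, a, c, d, 4.1).drf
        assert score_molecule(mol, n, a, c, d, 8.2).drf == pytest.approx(2 * base, rel=1e-12)
        doubled = DipoleVector(2 * d.vector)
        assert score_molecule(mol, n, a, c, doubled, 4.1).drf == pytest.approx(2 * base, rel=1e-12)
        p2 = DRFParameters(c_lr=2.0)
        assert score_molecule(mol, n, a, c, d, 4.1, p2).drf == pytest.approx(2 * base, rel=1e-12)

    def test_dipole_negation_negates_score_exactly(self, planted_fixture):
        spec, mol, (n, a, c) = planted_fixture
        d = dipole_from_point_charges(mol, n)
        plus = score_molecule(mol, n, a, c, d, 4.1).drf
        minus = score_molecule(mol, n, a, c, DipoleVector(-d.vector), 4.1).drf
        assert minus == -plus

    def test_qnet_negation_negates_score(self, planted_fixture):
        spec, mol, (n, a, c) = planted_fixture
        d = dipole_from_point_charges(mol, n)
        plus = score_molecule(mol, n, a, c, d, 4.1, DRFParameters(fukui_mode_override="f_plus")).drf
        minus = score_molecule(mol, n, a, c, d, -4.1, DRFParameters(fukui_mode_override="f_plus")).drf
        assert minus == -plus

    def test_rotational_invariance(self, planted_fixture):
        """Rigidly rotating geometry and dipole together leaves DRF unchanged."""
        spec, mol, (n, a, c) = planted_fixture
        d = dipole_from_point_charges(mol, n)
        base = score_molecule(mol, n, a, c, d, 4.1).drf
        rot = random_rotation(123)
        mol_r = Molecule(mol.name, [Atom(at.element, rot @ at.position) for at in mol.atoms])
        d_r = DipoleVector(rot @ d.vector)
        assert score_molecule(mol_r, n, a, c, d_r, 4.1).drf == pytest.approx(base, abs=1e-10)

    def test_nonfinite_input_rejected(self):
        out = site_contributions(
            [_site((1, 0, 0))],
            FukuiVector("f_plus", np.array([0.05])),
            DipoleVector(np.array([10.0, 0, 0])),
        )
        with pytest.raises(ValueError, match="finite"):
            compute_drf(out, q_net=float("nan"))


class TestOrientationClassification:
    @pytest.mark.parametrize(
        "cos_phi,expect",
        [(1.0, "F"), (0.5, "F"), (0.0, "P"), (-0.5, "B"), (-1.0, "B")],
    )
    def test_planted_cosines(self, cos_phi, expect):
        # build a site whose bond direction has the requested cosine with D
        sin_phi = float(np.sqrt(1 - cos_phi**2))
        sites = [_site((cos_phi, sin_phi, 0))]
        fv = FukuiVector("f_plus", np.array([1.0]))
        contribs = site_contributions(sites, fv, DipoleVector(np.array([5.0, 0, 0])))
        assert classify_orientation([0], contribs, DEFAULT_TAU) == expect

    def test_zero_dipole_classifies_perpendicular(self):
        contribs = site_contributions(
            [_site((1, 0, 0))],
            FukuiVector("f_plus", np.array([1.0])),
            DipoleVector(np.zeros(3)),
        )
        assert classify_orientation([0], contribs) == "P"

    def test_out_of_plane_dipole_on_planar_sites_is_perpendicular(self, chrysene, chrysene_bonds):
        """In-plane C-H bonds vs a plane-normal dipole: perpendicular class."""
        from dirreact.molecule import find_terminal_sites

        sites = find_terminal_sites(chrysene, chrysene_bonds)
        fv = FukuiVector("f_plus", np.full(chrysene.n_atoms, 1.0 / chrysene.n_atoms))
        d = DipoleVector(np.array([0.0, 0.0, 0.03]))
        contribs = site_contributions(sites, fv, d)
        cls = classify_orientation([s.heavy_index for s in sites], contribs)
        assert cls == "P"

    def test_tied_maxima_use_mean_cosine(self):
        sites = [_site((1, 0, 0), heavy=0), _site((-1, 0, 0), heavy=1)]
        fv = FukuiVector("f_plus", np.array([0.5, 0.5]))
        contribs = site_contributions(sites, fv, DipoleVector(np.array([5.0, 0, 0])))
        # cos = +1 and -1 average to 0 -> perpendicular
        assert classify_orientation([0, 1], contribs) == "P"


class TestRanking:
    def test_reference_table_order(self):
        """Highest score first; the methylated congener tops the table."""
        from dirreact.bioassay import load_reference_tables

        tab = load_reference_tables()
        results = [
            compute_drf(
                site_contributions(
                    [_site((1, 0, 0))],
                    FukuiVector("f_plus", np.array([row.drf / 4.1])),
                    DipoleVector(np.array([1.0, 0, 0])),
                ),
                q_net=4.1,
                compound=name,
            )
            for name, row in tab.iterrows()
        ]
        ranked = rank_by_drf(results)
        assert ranked[0].compound == "2-methylchrysene"
        assert ranked[0].drf == pytest.approx(27.97)
        scores = [r.drf for r in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_ties_break_by_name(self):
        contribs = site_contributions(
            [_site((1, 0, 0))],
            FukuiVector("f_plus", np.array([0.1])),
            DipoleVector(np.array([1.0, 0, 0])),
        )
        res = [compute_drf(contribs, 1.0, compound=nm) for nm in ("b", "a", "c")]
        assert [r.compound for r in rank_by_drf(res)] == ["a", "b", "c"]

    def test_random_scores_match_sort_oracle(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(size=25)
        contribs_for = lambda s: site_contributions(
            [_site((1, 0, 0))],
            FukuiVector("f_plus", np.array([s])),
            DipoleVector(np.array([1.0, 0, 0])),
        )
        res = [
            compute_drf(contribs_for(s), 1.0, compound=f"c{i:02d}")
            for i, s in enumerate(scores)
        ]
        ranked = rank_by_drf(res)
        expect = sorted(zip(scores, [f"c{i:02d}" for i in range(25)]),
                        key=lambda t: (-t[0], t[1]))
        assert [r.compound for r in ranked] == [nm for _, nm in expect]

    def test_duplicate_names_rejected(self):
        contribs = site_contributions(
            [_site((1, 0, 0))],
            FukuiVector("f_plus", np.array([0.1])),
            DipoleVector(np.array([1.0, 0, 0])),
        )
        res = [compute_drf(contribs, 1.0, compound="x")] * 2
        with pytest.raises(ValueError, match="duplicate"):
            rank_by_drf(res)
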