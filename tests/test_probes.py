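"""Flexibility normalization, contact maps, coevolution overlays, probes."""

import numpy as np
import pytest

from foldswitch.probes import (
    compare_contact_maps,
    contact_map,
    load_coevolution_pairs,
    mean_plddt_window,
    normalize_bfactors,
    region_flexibility,
    residue_distance,
)
from foldswitch.synthetic import make_ideal_backbone

from conftest import apply_rigid, random_rigid_transform


def _with_bfactors(model, values):
    for res, v in zip(model.residues, values):
        for a in res.atoms.values():
            a.bfactor = float(v)
    return model


class TestNormalizeBfactors:
    def test_hand_computed_sample_sd(self):
        m = _with_bfactors(make_ideal_backbone("HHH", seed=0), [10, 20, 30])
        prof = normalize_bfactors(m)
        np.testing.assert_allclose(prof.bf_norm, [-1.0, 0.0, 1.0])
        assert prof.sigma == pytest.approx(10.0)  # (n-1) convention

    def test_mean_zero_unit_sd(self):
        rng = np.random.default_rng(0)
        m = _with_bfactors(make_ideal_backbone("H" * 30, seed=1),
                           rng.uniform(5, 60, 30))
        prof = normalize_bfactors(m)
        assert prof.bf_norm.mean() == pytest.approx(0.0, abs=1e-9)
        assert prof.bf_norm.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_skewed_profile_below_cutoff(self):
        # [0,0,0,40]: mean 10, sample sd 20 -> max normalized value 1.5
        m = _with_bfactors(make_ideal_backbone("HHHH", seed=0), [0, 0, 0, 40])
        prof = normalize_bfactors(m)
        assert prof.bf_norm.max() == pytest.approx(1.5)
        assert not prof.flexible.any()

    def test_constant_bfactors_degenerate(self):
        m = _with_bfactors(make_ideal_backbone("HHH", seed=0), [7, 7, 7])
        with pytest.raises(ValueError, match="constant"):
            normalize_bfactors(m)

    def test_flexible_flag_inclusive_at_2(self):
        # values engineered so one residue sits exactly at BF_norm = 2.0:
        # sample sd of [0,...,0,x] over n=10 gives 2.0 at the max for x
        vals = np.zeros(10)
        vals[-1] = 1.0
        m = _with_bfactors(make_ideal_backbone("H" * 10, seed=0), vals)
        prof = normalize_bfactors(m)
        top = prof.bf_norm.max()
        assert prof.flexible.sum() == int(top >= 2.0)


class TestRegionFlexibility:
    def test_region_summaries(self):
        m = _with_bfactors(make_ideal_backbone("H" * 10, seed=0),
                           [10, 10, 10, 10, 10, 10, 10, 10, 10, 60])
        prof = normalize_bfactors(m)
        calm = region_flexibility(prof, m, [(1, 8)])
        assert not calm["any_flexible"]
        hot = region_flexibility(prof, m, [(9, 10)])
        assert hot["any_flexible"]
        assert hot["fraction_flexible"] == pytest.approx(0.5)

    def test_empty_region_errors(self):
        m = _with_bfactors(make_ideal_backbone("HHH", seed=0), [1, 2, 3])
        prof = normalize_bfactors(m)
        with pytest.raises(ValueError):
            region_flexibility(prof, m, [(50, 60)])


class TestContactMap:
    def test_cutoff_and_seq_separation(self):
        m = make_ideal_backbone("H" * 30, seed=0)
        cm = contact_map(m, cutoff=8.0, atom_mode="CA", min_seq_sep=5)
        for c in cm.contacts:
            assert c.j - c.i >= 5
            assert c.kind == "intramolecular"
        # helix i,i+7 CA pairs sit near 10 Å; i,i+2 near 5.5 Å is excluded
        cm2 = contact_map(m, cutoff=6.0, atom_mode="CA", min_seq_sep=5)
        assert not any(c.j - c.i == 2 for c in cm2.contacts)

    def test_rigid_motion_invariance(self):
        m = make_ideal_backbone("H" * 14 + "C" * 4 + "H" * 14, seed=2)
        R, t = random_rigid_transform(4)
        moved = apply_rigid(m, R, t)
        a = contact_map(m, cutoff=10.0, atom_mode="CA")
        b = contact_map(moved, cutoff=10.0, atom_mode="CA")
        assert {(c.i, c.j) for c in a.contacts} == {(c.i, c.j) for c in b.contacts}

    def test_dimer_intermolecular_contacts(self):
        a = make_ideal_backbone("H" * 10, seed=0, model_id="A")
        b = apply_rigid(a, np.eye(3), np.array([6.0, 0.0, 0.0]))
        b.chain_id = "B"
        cm = contact_map([a, b], cutoff=8.0, atom_mode="CA")
        inter = [c for c in cm.contacts if c.kind == "intermolecular"]
        assert inter
        assert all({c.chain_i, c.chain_j} == {"A", "B"} for c in inter)


class TestCompareContactMaps:
    def test_partition_properties(self):
        m1 = make_ideal_backbone("H" * 14 + "C" * 4 + "H" * 14, seed=2)
        m2 = make_ideal_backbone("H" * 14 + "C" * 4 + "E" * 14, seed=3,
                                 sequence=m1.sequence)
        a = contact_map(m1, cutoff=10.0, atom_mode="CA")
        b = contact_map(m2, cutoff=10.0, atom_mode="CA")
        ua, ub, common = compare_contact_maps(a, b)
        assert ua | ub | common == a.contacts | b.contacts
        assert not (ua & ub) and not (ua & common) and not (ub & common)
        assert len(ua) + len(common) == len(a.contacts)
        # symmetry under argument swap
        ub2, ua2, common2 = compare_contact_maps(b, a)
        assert ua2 == ua and ub2 == ub and common2 == common

    def test_identical_and_disjoint(self):
        m = make_ideal_backbone("H" * 20, seed=0)
        a = contact_map(m, cutoff=8.0, atom_mode="CA")
        ua, ub, common = compare_contact_maps(a, a)
        assert not ua and not ub and common == a.contacts


class TestCoevolutionPairs:
    def test_load_dedupe_canonicalize(self, tmp_path):
        p = tmp_path / "coev.tsv"
        p.write_text("5 20 0.9\n20 5 1.3\n7 9 0.2\n")
        pairs = load_coevolution_pairs(p)
        assert pairs == [(5, 20, 1.3), (7, 9, 0.2)]

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("5 20 0.9\noops\n")
        with pytest.raises(ValueError, match=":2"):
            load_coevolution_pairs(p)


class TestResidueDistance:
    def test_euclidean(self):
        m = make_ideal_backbone("HHH", seed=0)
        m.residues[0].atoms["CA"].xyz = np.array([0.0, 0.0, 0.0])
        m.residues[2].atoms["CA"].xyz = np.array([3.0, 4.0, 0.0])
        assert residue_distance(m, 1, 3) == pytest.approx(5.0)
        assert residue_distance(m, 1, 1) == 0.0

    def test_triangle_inequality(self):
        m = make_ideal_backbone("H" * 10, seed=1)
        d12 = residue_distance(m, 1, 5)
        d23 = residue_distance(m, 5, 9)
        d13 = residue_distance(m, 1, 9)
        assert d13 <= d12 + d23 + 1e-9

    def test_missing_residue_named(self):
        m = make_ideal_backbone("HHH", seed=0)
        with pytest.raises(KeyError, match="99"):
            residue_distance(m, 1, 99)


class TestMeanPlddtWindow:
    def test_window_mean(self):
        m = make_ideal_backbone("HHHH", seed=0)
        for res, v in zip(m.residues, [10.0, 60.0, 80.0, 20.0]):
            res.atoms["CA"].bfactor = v
        assert mean_plddt_window(m, [(2, 3)]) == pytest.approx(70.0)
        assert mean_plddt_window(m, [(3, 3)]) == pytest.approx(80.0)
        # excluding the low-confidence tails raises the mean
        assert mean_plddt_window(m, [(2, 3)]) > mean_plddt_window(m, [(1, 4)])
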