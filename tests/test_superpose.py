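"""Superposition metrics: Kabsch vs a grid-search oracle, TM-score
construction, d0 formula, rigid-motion invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldswitch.structure_io import AtomRecord
from foldswitch.superpose import (
    Correspondence,
    build_correspondence,
    d0,
    kabsch,
    parse_region,
    region_restrict,
    rmsd,
    tm_score,
)
from foldswitch.synthetic import make_ideal_backbone

from conftest import apply_rigid, grid_search_rmsd, random_rigid_transform


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(6, 3))
        T, r = kabsch(P, P)
        assert r == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)

    def test_translation_invariance(self):
        P = np.random.default_rng(1).normal(size=(5, 3))
        _, r = kabsch(P, P + np.array([5.0, 0.0, 0.0]))
        assert r == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(scale=3.0, size=(5, 3))
        Q = rng.normal(scale=3.0, size=(5, 3))
        _, r_kabsch = kabsch(P, Q)
        r_grid = grid_search_rmsd(P, Q)
        # the optimizer can only beat the 1-degree grid
        assert r_kabsch <= r_grid + 1e-9
        assert abs(r_kabsch - r_grid) < 1e-2

    def test_rotation_always_proper(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            P = rng.normal(size=(4, 3))
            Q = rng.normal(size=(4, 3))
            T, _ = kabsch(P, Q)
            assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(T.rotation @ T.rotation.T, np.eye(3),
                                       atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_input_returns_transform(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        R, t = random_rigid_transform(5)
        Q = P @ R.T + t
        T, r = kabsch(P, Q)
        assert r == pytest.approx(0.0, abs=1e-9)


class TestD0:
    def test_formula_values(self):
        assert d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8, abs=1e-9)
        assert d0(100) == pytest.approx(3.652, abs=1e-3)

    def test_clamp(self):
        assert d0(21) == 0.5  # formula gives 0.453
        assert d0(15) == 0.5

    @given(st.integers(min_value=1, max_value=3000))
    def test_floor_everywhere(self, L):
        assert d0(L) >= 0.5


class TestTMScore:
    def test_self_is_one(self, helix20):
        corr = Correspondence([(i, i) for i in range(20)])
        res = tm_score(helix20, helix20, corr)
        assert res.tm == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, helix20):
        R, t = random_rigid_transform(11)
        moved = apply_rigid(helix20, R, t)
        corr = Correspondence([(i, i) for i in range(20)])
        assert tm_score(helix20, moved, corr).tm == pytest.approx(1.0, abs=1e-9)

    def test_single_displaced_residue_formula(self, helix20):
        """19 residues exact + 1 displaced to 2*d0 -> (19 + 1/5)/20."""
        d0_20 = d0(20)
        moved = apply_rigid(helix20, np.eye(3), np.zeros(3))
        ca = moved.residues[10].atoms["CA"]
        moved.residues[10].atoms["CA"] = AtomRecord(
            "CA", "C", ca.xyz + np.array([2 * d0_20, 0, 0]), ca.bfactor
        )
        corr = Correspondence([(i, i) for i in range(20)])
        res = tm_score(helix20, moved, corr, L_norm=20)
        assert res.tm == pytest.approx((19 + 0.2) / 20, abs=1e-6)

    def test_monotone_under_increasing_noise(self, helix20):
        """Expected TM decreases as Gaussian noise grows."""
        corr = Correspondence([(i, i) for i in range(20)])
        rng = np.random.default_rng(0)
        tms = []
        for sigma in (0.2, 0.8, 2.0):
            vals = []
            for _ in range(5):
                noisy = apply_rigid(helix20, np.eye(3), np.zeros(3))
                for r in noisy.residues:
                    for a in r.atoms.values():
                        a.xyz = a.xyz + rng.normal(scale=sigma, size=3)
                vals.append(tm_score(helix20, noisy, corr).tm)
            tms.append(np.mean(vals))
        assert tms[0] > tms[1] > tms[2]

    def test_empty_correspondence_rejected(self, helix20):
        with pytest.raises(ValueError):
            tm_score(helix20, helix20, Correspondence([]))


class TestRMSD:
    def test_identical_structures_zero(self, helix20):
        corr = Correspondence([(i, i) for i in range(20)])
        assert rmsd(helix20, helix20, corr) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed(self, helix20):
        R, t = random_rigid_transform(3)
        moved = apply_rigid(helix20, R, t)
        corr = Correspondence([(i, i) for i in range(20)])
        assert rmsd(helix20, moved, corr) == pytest.approx(0.0, abs=1e-6)

    def test_matches_grid_oracle_on_toy(self):
        """4-residue backbone RMSD equals the rotation-grid search value."""
        a = make_ideal_backbone("HHEE", seed=4)
        b = make_ideal_backbone("HEHE", seed=5, sequence=a.sequence)
        corr = Correspondence([(i, i) for i in range(4)])
        val = rmsd(a, b, corr)
        PA = np.vstack([a.residues[i].atoms[x].xyz
                        for i in range(4) for x in ("N", "CA", "C", "O")])
        PB = np.vstack([b.residues[i].atoms[x].xyz
                        for i in range(4) for x in ("N", "CA", "C", "O")])
        assert abs(val - grid_search_rmsd(PA, PB)) < 1e-2


class TestRegionRestrict:
    def test_interval_count(self):
        m = make_ideal_backbone("H" * 95, seed=0)
        corr = build_correspondence(m, m)
        sub = region_restrict(corr, parse_region("11-66"), "A", m)
        assert len(sub) == 56

    def test_region_outside_chain_errors(self, helix20):
        corr = build_correspondence(helix20, helix20)
        with pytest.raises(ValueError, match="no aligned residues"):
            region_restrict(corr, [(500, 600)], "A", helix20)

    def test_whole_chain_region_is_identity(self, helix20):
        corr = build_correspondence(helix20, helix20)
        sub = region_restrict(corr, [(1, 20)], "A", helix20)
        assert sub.pairs == corr.pairs


class TestCorrespondence:
    def test_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            Correspondence([(0, 0), (1, 1), (1, 2)])

    def test_parse_region_multi_interval(self):
        assert parse_region("11-40,45-66") == [(11, 40), (45, 66)]
        assert parse_region("52") == [(52, 52)]
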