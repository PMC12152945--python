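import itertools
import math

import numpy as np
import pytest

from lyscov.covalent_dock import SelectionCriteria
from lyscov.lysine_rotamers import (DEFAULT_CHI_LIBRARY, RotamerAssignment,
                                    RotamerConformation, RotamerScorer,
                                    build_coordinates, build_coordinates_batch,
                                    build_template, enumerate_rotamers,
                                    measure_internal, place_and_score,
                                    preminimize_pocket, scan_rotamers,
                                    scan_rotamers_fast, select_vectors)

BB = {"N": np.array([0.0, 0.0, 0.0]),
      "CA": np.array([1.458, 0.0, 0.0]),
      "C": np.array([2.009, 1.42, 0.11])}


class TestBuildTemplate:
    def test_imine_bond_length(self):
        t = build_template("salicylaldehyde")
        co = build_coordinates(t, BB, (-60, 180, 180, 180), (0.0, 0.0))
        assert 1.25 <= np.linalg.norm(co["C4A"] - co["NZ"]) <= 1.30

    def test_internal_cartesian_round_trip(self):
        for warhead in ("salicylaldehyde", "aryl-sulfonyl-fluoride"):
            t = build_template(warhead)
            chis = (-60.0, 180.0, 60.0, 180.0)
            pchis = tuple(g[1] for g in t.proton_chis)
            co = build_coordinates(t, BB, chis, pchis)
            rows = measure_internal(t, BB, co)
            rebuilt = {}
            coords = dict(BB)
            from lyscov.geometry import place_atom
            for (name, (a, b, c), *_), (d, ang, dih) in zip(t.zmat, rows):
                coords[name] = place_atom(coords[a], coords[b], coords[c], d, ang, dih)
                rebuilt[name] = coords[name]
            for name in co:
                assert np.allclose(co[name], rebuilt[name], atol=1e-6)

    def test_ring_closes(self):
        t = build_template("aryl-sulfonyl-fluoride")
        co = build_coordinates(t, BB, (180, 180, 180, 180), (60.0, 60.0, 30.0))
        assert np.linalg.norm(co["C6"] - co["C1"]) == pytest.approx(1.40, abs=0.01)

    def test_unknown_warhead_rejected(self):
        with pytest.raises(ValueError, match="unknown warhead"):
            build_template("acrylamide")

    def test_batch_build_matches_scalar(self):
        t = build_template("salicylaldehyde")
        chis = (-60.0, 180.0, -60.0, 60.0)
        grid = np.array([[0.0, 30.0], [90.0, -120.0], [150.0, 180.0]])
        batch = build_coordinates_batch(t, BB, chis, grid)
        names = t.atom_names()
        for k, pch in enumerate(grid):
            scalar = build_coordinates(t, BB, chis, tuple(pch))
            for i, name in enumerate(names):
                assert np.allclose(batch[k, i], scalar[name], atol=1e-9)


class TestEnumerateRotamers:
    def test_product_count(self):
        t = build_template("salicylaldehyde")
        lib = [[(-60, 0.5), (180, 0.3), (60, 0.2)]] * 4
        grids = [[0, 60, 120, 180, 240, 300]] * 2
        rots = enumerate_rotamers(t, lib, grids)
        assert len(rots) == 81 * 36

    def test_zero_probability_excluded(self):
        t = build_template("salicylaldehyde")
        lib = [[(-60, 0.5), (180, 0.5), (60, 0.0)]] + \
              [[(-60, 0.5), (180, 0.5)]] * 3
        rots = enumerate_rotamers(t, lib, [[0.0, 180.0]])
        assert len(rots) == 2 * 8 * 2
        assert all(r.probability > 0 for r in rots)

    def test_empty_proton_grid_gives_library_size(self):
        t = build_template("salicylaldehyde")
        lib = [[(-60, 0.6), (180, 0.4)]] * 4
        rots = enumerate_rotamers(t, lib, [])
        assert len(rots) == 16

    def test_descending_probability_order(self):
        t = build_template("salicylaldehyde")
        rots = enumerate_rotamers(t, proton_grids=[[0.0]])
        probs = [r.probability for r in rots]
        assert probs == sorted(probs, reverse=True)

    def test_empty_library_rejected(self):
        t = build_template("salicylaldehyde")
        with pytest.raises(ValueError, match="empty"):
            enumerate_rotamers(t, [], [[0.0]])


class TestPlaceAndScore:
    def test_wrong_site_rejected(self, ground_truth):
        pocket, _ = preminimize_pocket(ground_truth.complex)
        t = ground_truth.mod_template
        rot = RotamerAssignment((180.0,) * 4, (0.0,) * len(t.proton_chis), 1.0)
        with pytest.raises(Exception, match="target lysine"):
            place_and_score(pocket, ("A", 1), rot, t)

    def test_solvent_facing_rotamer_low_energy(self, ground_truth):
        pocket, _ = preminimize_pocket(ground_truth.complex)
        t = ground_truth.mod_template
        scorer = RotamerScorer(pocket, t)
        rots = enumerate_rotamers(t)
        best = min(scorer.score(r.chis, r.proton_chis)[1] for r in rots[:200])
        assert best < 25.0

    def test_backbone_clash_scores_above_threshold(self, ground_truth):
        from lyscov.energy import CLASH_ENERGY
        pocket, _ = preminimize_pocket(ground_truth.complex)
        t = ground_truth.mod_template
        scorer = RotamerScorer(pocket, t)
        rots = enumerate_rotamers(t)
        worst = max(scorer.score(r.chis, r.proton_chis)[1] for r in rots[:400])
        assert worst > CLASH_ENERGY

    def test_score_equals_double_loop_oracle(self, ground_truth):
        from lyscov.energy import AtomGroup, pair_energy
        pocket, _ = preminimize_pocket(ground_truth.complex)
        t = ground_truth.mod_template
        scorer = RotamerScorer(pocket, t)
        rot = RotamerAssignment(ground_truth.planted_chis,
                                ground_truth.planted_proton_chis, 1.0)
        xyz, e = scorer.score(rot.chis, rot.proton_chis)
        # oracle: explicit pair loop over the 10 A neighborhood
        acc = 0.0
        dirs = scorer._dirs(xyz)
        near = np.min(np.linalg.norm(
            scorer.static.xyz[None] - xyz[:, None], axis=2), axis=0) <= 10.0
        for i in range(len(xyz)):
            for j in np.nonzero(near)[0]:
                if scorer.exclude[i, j]:
                    continue
                a = AtomGroup(xyz[i:i + 1], [scorer.elements[i]], dirs[i:i + 1])
                b = AtomGroup(scorer.static.xyz[j:j + 1],
                              [scorer.static.elements[j]],
                              scorer.static.polar_dir[j:j + 1])
                acc += pair_energy(a, b)
        assert e == pytest.approx(acc, abs=1e-6)

    def test_fast_scan_matches_scalar_scan(self, ground_truth):
        pocket, _ = preminimize_pocket(ground_truth.complex)
        t = ground_truth.mod_template
        rots = enumerate_rotamers(t)[:150]
        slow = scan_rotamers(pocket, t, rots)
        fast = scan_rotamers_fast(pocket, t, rots)
        a = sorted((r.chi_values, round(r.neighborhood_score, 9)) for r in slow)
        b = sorted((r.chi_values, round(r.neighborhood_score, 9)) for r in fast)
        for (ka, va), (kb, vb) in zip(a, b):
            assert ka == kb
            assert va == pytest.approx(vb, abs=1e-6)


class TestSelectVectors:
    def _fake_rotamers(self, rng, template_ring_xyz, n=100):
        rots = []
        for k in range(n):
            shift = rng.normal(size=3)
            shift *= rng.uniform(0.0, 2.0) / np.linalg.norm(shift)
            rots.append(RotamerConformation(
                chi_values=(float(k),), probability=rng.uniform(0.01, 1.0),
                coordinates=np.zeros((1, 3)),
                ring_xyz=template_ring_xyz + shift,
                neighborhood_score=float(rng.normal()),
            ))
        return rots

    def test_matches_brute_force_rule(self, phenol3d):
        from lyscov.rmsd_metrics import heavy_coords, ring_rmsd
        rng = np.random.default_rng(123)
        txyz = heavy_coords(phenol3d)
        ring = list(phenol3d.GetRingInfo().AtomRings()[0])
        crit = SelectionCriteria()
        for _ in range(60):
            rots = self._fake_rotamers(rng, txyz[ring], n=rng.integers(10, 80))
            got = select_vectors(rots, phenol3d, txyz, crit)
            # brute-force rule application
            order = sorted(rots, key=lambda r: (r.neighborhood_score, -r.probability))
            n_top = max(1, int(np.floor(0.10 * len(order))))
            best = {}
            for r in order[:n_top]:
                m = ring_rmsd(r.ring_xyz, ["C"] * 6, phenol3d, txyz)
                if m.rmsd < 1.0:
                    key = (m.template_ring, m.mapping[0])
                    if key not in best or m.rmsd < best[key]:
                        best[key] = m.rmsd
            assert len(got) == len(best)
            for s in got:
                assert s.ring_rmsd == pytest.approx(
                    best[(s.template_ring, s.position)], abs=1e-9)

    def test_too_few_rotamers_rejected(self, phenol3d):
        with pytest.raises(ValueError, match="at least 10"):
            select_vectors([], phenol3d)

    def test_ringless_template_rejected(self):
        from conftest import embed3d
        hexane = embed3d("CCCCCC")
        rots = [RotamerConformation((0.0,), 1.0, np.zeros((1, 3)),
                                    ring_xyz=np.zeros((6, 3)),
                                    neighborhood_score=0.0) for _ in range(12)]
        with pytest.raises(ValueError, match="no rings|no ring"):
            select_vectors(rots, hexane)
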