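"""Geometric H-bond detection, partner classification, rank correlation."""

import math

import numpy as np
import pytest

from tunnelwater.hbonds import (
    AtomRecord, HBondCriteria, PartnerClass, classify_partner,
    correlate_radius_hbonds, default_table, detect_hbonds, hbond_angle,
    hbonds_at_minimal_sphere,
)

RNG = np.random.default_rng(42)


def water_at(origin, h_dirs=None):
    origin = np.asarray(origin, dtype=float)
    if h_dirs is None:
        half = math.radians(104.52 / 2)
        h_dirs = [(math.cos(half), math.sin(half), 0),
                  (math.cos(half), -math.sin(half), 0)]
    atoms = [AtomRecord("O", "O", "WAT", 1, "W", origin)]
    for i, d in enumerate(h_dirs, start=1):
        atoms.append(AtomRecord(f"H{i}", "H", "WAT", 1, "W",
                                origin + 0.9572 * np.asarray(d)))
    return atoms


def linear_acceptor(water, distance):
    """A GLY carbonyl O placed on the O-H1 line => 180 degree bond."""
    o = water[0].position
    h_dir = (water[1].position - o) / np.linalg.norm(water[1].position - o)
    acc = o + distance * h_dir
    return [AtomRecord("O", "O", "GLY", 5, "A", acc),
            AtomRecord("C", "C", "GLY", 5, "A", acc + 1.23 * h_dir)]


class TestDetectBoundaries:
    def test_cutoff_distance_is_inclusive(self):
        """A 3.5 A donor-acceptor pair at 180 degrees is a bond."""
        w = water_at([0, 0, 0])
        bonds = detect_hbonds(w, linear_acceptor(w, 3.5))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(3.5)
        assert bonds[0].angle == pytest.approx(180.0)

    def test_beyond_cutoff_rejected(self):
        w = water_at([0, 0, 0])
        assert detect_hbonds(w, linear_acceptor(w, 3.6)) == []

    def test_angle_just_below_window_rejected(self):
        """134.9 degrees at 3.0 A fails the 135-180 window."""
        w = water_at([0, 0, 0])
        o = w[0].position
        h = w[1].position
        h_dir = (h - o) / np.linalg.norm(h - o)
        perp = np.array([-h_dir[1], h_dir[0], 0.0])
        theta = math.radians(134.9)
        direction = math.cos(theta) * (-h_dir) + math.sin(theta) * perp
        # choose acceptor on the ray from H so the D-A distance is 3.0
        lo, hi = 0.0, 5.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if np.linalg.norm(h + mid * direction - o) < 3.0:
                lo = mid
            else:
                hi = mid
        acc = h + lo * direction
        assert hbond_angle(o, h, acc) == pytest.approx(134.9, abs=1e-3)
        atoms = [AtomRecord("O", "O", "GLY", 5, "A", acc)]
        assert detect_hbonds(w, atoms) == []
        # the same geometry opened to 135.0 is accepted
        theta = math.radians(135.0)
        direction = math.cos(theta) * (-h_dir) + math.sin(theta) * perp
        lo, hi = 0.0, 5.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if np.linalg.norm(h + mid * direction - o) < 3.0:
                lo = mid
            else:
                hi = mid
        atoms = [AtomRecord("O", "O", "GLY", 5, "A", h + lo * direction)]
        assert len(detect_hbonds(w, atoms)) == 1

    def test_water_missing_hydrogens_rejected(self):
        w = [AtomRecord("O", "O", "WAT", 1, "W", np.zeros(3))]
        with pytest.raises(ValueError, match="hydrogens"):
            detect_hbonds(w, [])

    def test_unknown_residue_warns_and_skips(self):
        w = water_at([0, 0, 0])
        atoms = [AtomRecord("X1", "O", "LIG", 9, "A", [2.8, 0.5, 0])]
        with pytest.warns(UserWarning, match="LIG"):
            assert detect_hbonds(w, atoms) == []


def brute_force_bonds(water_atoms, protein_atoms, criteria=None):
    """Independent triple enumeration against the residue templates."""
    criteria = criteria or HBondCriteria()
    table = default_table()
    water_o = next(a for a in water_atoms if a.element == "O")
    water_h = [a for a in water_atoms if a.element == "H"]
    residues = {}
    for a in protein_atoms:
        residues.setdefault((a.chain_id, a.residue_id), []).append(a)
    found = set()
    for atoms in residues.values():
        template = table.get(atoms[0].residue_name)
        if template is None:
            continue
        named = {a.atom_name: a for a in atoms}
        for a in atoms:
            d = np.linalg.norm(a.position - water_o.position)
            if a.atom_name in template.acceptors and d <= criteria.d_max:
                for h in water_h:
                    ang = hbond_angle(water_o.position, h.position,
                                      a.position)
                    if criteria.angle_min <= ang <= criteria.angle_max:
                        found.add((water_o.key(), h.key(), a.key()))
            if a.atom_name in template.donors and d <= criteria.d_max:
                for h_name in template.donors[a.atom_name]:
                    if h_name not in named:
                        continue
                    h = named[h_name]
                    ang = hbond_angle(a.position, h.position,
                                      water_o.position)
                    if criteria.angle_min <= ang <= criteria.angle_max:
                        found.add((a.key(), h.key(), water_o.key()))
    return found


class TestDetectOracle:
    def test_random_micro_configurations_match_enumeration(self):
        """500 random dense micro-scenes agree with brute-force triples."""
        residue_pool = [
            ("GLY", [("N", "N"), ("H", "H"), ("O", "O"), ("C", "C")]),
            ("SER", [("OG", "O"), ("HG", "H"), ("CB", "C")]),
            ("ASP", [("OD1", "O"), ("OD2", "O"), ("CG", "C")]),
            ("LYS", [("NZ", "N"), ("HZ1", "H"), ("HZ2", "H")]),
            ("HIE", [("NE2", "N"), ("HE2", "H"), ("ND1", "N")]),
        ]
        for trial in range(500):
            rng = np.random.default_rng(trial)
            w = water_at(rng.normal(0, 1, 3))
            protein = []
            for r in range(rng.integers(1, 5)):
                res, atoms = residue_pool[rng.integers(len(residue_pool))]
                base = rng.normal(0, 2.2, 3)
                for name, element in atoms:
                    protein.append(AtomRecord(
                        name, element, res, 10 + r, "A",
                        base + rng.normal(0, 0.8, 3)))
            got = {(b.donor.key(), b.hydrogen.key(), b.acceptor.key())
                   for b in detect_hbonds(w, protein)}
            assert got == brute_force_bonds(w, protein), f"trial {trial}"

    def test_invariance_under_rigid_motion_and_relabeling(self):
        rng = np.random.default_rng(3)
        w = water_at([0, 0, 0])
        protein = list(linear_acceptor(w, 3.0))  # one guaranteed bond
        for r in range(1, 7):
            base = rng.normal(0, 2.0, 3)
            protein.append(AtomRecord("O", "O", "GLY", 10 + r, "A", base))
            protein.append(AtomRecord("C", "C", "GLY", 10 + r, "A",
                                      base + [0, 0, 1.23]))
        ref = {(b.donor.key(), b.acceptor.key(), round(b.distance, 4),
                round(b.angle, 2)) for b in detect_hbonds(w, protein)}
        assert ref  # scene is dense enough to contain bonds

        theta = 1.1
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        shift = np.array([5.0, -3.0, 2.0])

        def move(a):
            return AtomRecord(a.atom_name, a.element, a.residue_name,
                              a.residue_id, a.chain_id,
                              rot @ a.position + shift)

        shuffled = [move(a) for a in protein]
        rng.shuffle(shuffled)
        moved = {(b.donor.key(), b.acceptor.key(), round(b.distance, 4),
                  round(b.angle, 2))
                 for b in detect_hbonds([move(a) for a in w], shuffled)}
        assert moved == ref

    def test_reported_geometry_rechecks_against_criteria(self):
        rng = np.random.default_rng(11)
        w = water_at([0, 0, 0])
        protein = []
        for r in range(10):
            base = rng.normal(0, 2.5, 3)
            protein.append(AtomRecord("O", "O", "GLY", r, "A", base))
        for b in detect_hbonds(w, protein):
            assert b.distance <= 3.5
            assert 135.0 <= b.angle <= 180.0
            assert b.distance == pytest.approx(
                np.linalg.norm(b.donor.position - b.acceptor.position))
            assert b.angle == pytest.approx(hbond_angle(
                b.donor.position, b.hydrogen.position, b.acceptor.position))


class TestMinimalSphereBonds:
    def test_planted_counts_per_minimal_frame(self):
        """Three minimal frames with 2/2/3 planted bonds -> [2, 2, 3]."""
        from tunnelwater.geometry import MinimalEventSphere, TransportEvent
        from tunnelwater.synthetic import plant_hbond_partners

        frames = [10, 11, 12]
        planted = [2, 2, 3]
        frame_atoms = {}
        oxy, hyd = [], []
        for f, k in zip(frames, planted):
            origin = np.array([0.0, 0.0, float(f)])
            partners, water_h = plant_hbond_partners(origin, [0, 0, 1], k)
            oxy.append(origin)
            hyd.append(water_h)
            water = [AtomRecord("O", "O", "WAT", 1, "W", origin),
                     AtomRecord("H1", "H", "WAT", 1, "W", water_h[0]),
                     AtomRecord("H2", "H", "WAT", 1, "W", water_h[1])]
            frame_atoms[f] = (water, partners)
        event = TransportEvent("E1", "W1", frames, np.array(oxy),
                               np.array(hyd))
        mes = MinimalEventSphere("E1", 1.0, 3, np.array(frames),
                                 np.array(oxy))
        counts, per_frame = hbonds_at_minimal_sphere(event, mes, frame_atoms)
        assert counts == planted
        assert sorted(per_frame) == frames

    def test_missing_frame_coordinates_named_in_error(self):
        from tunnelwater.geometry import MinimalEventSphere
        mes = MinimalEventSphere("E9", 1.0, 0, np.array([3]),
                                 np.zeros((1, 3)))
        with pytest.raises(ValueError, match="frame 3"):
            hbonds_at_minimal_sphere(None, mes, {})

    def test_no_partners_in_range_gives_zero(self):
        from tunnelwater.geometry import MinimalEventSphere, TransportEvent
        w_o = np.zeros((1, 3))
        hyd = np.array([[[0.96, 0, 0], [-0.24, 0.93, 0]]])
        event = TransportEvent("E1", "W1", [0], w_o, hyd)
        far = [AtomRecord("O", "O", "GLY", 1, "A", [50.0, 0, 0])]
        water = [AtomRecord("O", "O", "WAT", 1, "W", w_o[0]),
                 AtomRecord("H1", "H", "WAT", 1, "W", hyd[0, 0]),
                 AtomRecord("H2", "H", "WAT", 1, "W", hyd[0, 1])]
        mes = MinimalEventSphere("E1", 1.0, 0, np.array([0]), w_o)
        counts, _ = hbonds_at_minimal_sphere(event, mes, {0: (water, far)})
        assert counts == [0]


class TestClassifyPartner:
    @pytest.mark.parametrize("name,res,expected", [
        ("OD1", "ASP", PartnerClass.SIDECHAIN_NEGATIVE),
        ("OG", "SER", PartnerClass.SIDECHAIN_POLAR),
        ("O", "GLY", PartnerClass.BACKBONE),
        ("N", "ARG", PartnerClass.BACKBONE),
        ("NZ", "LYS", PartnerClass.SIDECHAIN_POSITIVE),
        ("NE2", "HIE", PartnerClass.SIDECHAIN_POSITIVE),
        ("CB", "ALA", PartnerClass.SIDECHAIN_NONPOLAR),
        ("OE1", "GLU", PartnerClass.SIDECHAIN_NEGATIVE),
        ("OH", "TYR", PartnerClass.SIDECHAIN_POLAR),
    ])
    def test_examples(self, name, res, expected):
        atom = AtomRecord(name, name[0], res, 1, "A", np.zeros(3))
        assert classify_partner(atom) == expected

    def test_residue_sets_partition_standard_amino_acids(self):
        from tunnelwater.hbonds import (_NEGATIVE, _NONPOLAR, _POLAR,
                                        _POSITIVE)
        all_residues = _NONPOLAR | _POLAR | _POSITIVE | _NEGATIVE
        assert len(all_residues) == 20
        assert sum(map(len, [_NONPOLAR, _POLAR, _POSITIVE, _NEGATIVE])) == 20

    def test_nonstandard_residue_rejected(self):
        atom = AtomRecord("C1", "C", "LIG", 1, "A", np.zeros(3))
        with pytest.raises(ValueError, match="LIG"):
            classify_partner(atom)


class TestCorrelation:
    def test_perfectly_antimonotone(self):
        pairs = [(r, 10 - r) for r in range(1, 8)]
        rho, p = correlate_radius_hbonds(pairs)
        assert rho == pytest.approx(-1.0)
        assert p < 0.01

    def test_perfectly_monotone(self):
        pairs = [(r, r * 2.0) for r in range(1, 8)]
        rho, _ = correlate_radius_hbonds(pairs)
        assert rho == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            correlate_radius_hbonds([(1.0, 2), (1.0, 3), (1.0, 4)])

    def test_matches_scipy_on_noisy_data(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(5)
        pairs = [(r, 5 - 2 * r + rng.normal(0, 0.5))
                 for r in rng.uniform(1, 2, size=50)]
        rho, p = correlate_radius_hbonds(pairs)
        ref = spearmanr([a for a, _ in pairs], [b for _, b in pairs])
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
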