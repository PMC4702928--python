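import numpy as np
import pytest

from dnabind.dna import detect_base_pairs, detect_duplexes
from dnabind.fixtures import build_ideal_bdna
from dnabind.params import Params
from dnabind.shape import (GrooveShape, aggregate_shape, ax_bend,
                           base_pair_frames, contact_zone, groove_geometry,
                           local_helix_axes, shape_table)

from conftest import random_rotation


@pytest.fixture(scope="module")
def duplex_12(ideal_12mer):
    pairs = detect_base_pairs(ideal_12mer)
    (dup,) = detect_duplexes(ideal_12mer, pairs)
    return ideal_12mer, dup


class TestContactZone:
    def test_mid_duplex_expansion(self, duplex_12):
        st, dup = duplex_12
        zone = contact_zone("i", [], dup, st,
                            contacted_residues={("D", 6, "")})
        assert {k[1] for k in zone.nucleotides if k[0] == "D"} == \
            {4, 5, 6, 7, 8}

    def test_terminal_clipping(self, duplex_12):
        st, dup = duplex_12
        zone = contact_zone("i", [], dup, st,
                            contacted_residues={("D", 1, "")})
        assert {k[1] for k in zone.nucleotides if k[0] == "D"} == {1, 2, 3}

    def test_no_contacts_empty_zone(self, duplex_12):
        st, dup = duplex_12
        zone = contact_zone("i", [], dup, st, contacted_residues=set())
        assert zone.nucleotides == set()
        assert zone.n_bp == 0


class TestFrames:
    def test_origins_on_straight_line(self, duplex_12):
        st, dup = duplex_12
        frames = base_pair_frames(st, dup.pairs)
        origins = np.array([o for _, o in frames])
        d = origins[1:] - origins[:-1]
        d = d / np.linalg.norm(d, axis=1)[:, None]
        assert np.abs(d - d[0]).max() < 1e-6

    def test_frames_co_rotate(self, duplex_12):
        st, dup = duplex_12
        rng = np.random.default_rng(8)
        rot = random_rotation(rng)
        t = np.array([4.0, -7.0, 2.0])
        moved = st.transformed(rot, t)
        f0 = base_pair_frames(st, dup.pairs)
        f1 = base_pair_frames(moved, dup.pairs)
        for (r0, o0), (r1, o1) in zip(f0, f1):
            assert np.abs(rot @ r0 - r1).max() < 1e-9
            assert np.abs(rot @ o0 + t - o1).max() < 1e-9

    def test_reversed_pair_order_keeps_angles(self, duplex_12):
        st, dup = duplex_12
        fwd = base_pair_frames(st, dup.pairs)
        rev = base_pair_frames(st, dup.pairs[::-1])
        assert ax_bend(fwd) == pytest.approx(ax_bend(rev), abs=1e-9)


class TestAxBend:
    def test_straight_duplex_zero(self, duplex_12):
        st, dup = duplex_12
        frames = base_pair_frames(st, dup.pairs)
        assert ax_bend(frames) == pytest.approx(0.0, abs=1e-6)

    def test_straight_for_any_twist_rise(self):
        for twist, rise in ((30.0, 3.0), (34.3, 3.32), (38.0, 3.6)):
            st = build_ideal_bdna("ATGCATGCATGC", twist=twist, rise=rise)
            pairs = detect_base_pairs(st)
            (dup,) = detect_duplexes(st, pairs)
            frames = base_pair_frames(st, dup.pairs)
            assert ax_bend(frames) == pytest.approx(0.0, abs=1e-6)

    def test_single_bend_mean(self):
        # 12 bp -> 11 local axes -> 10 consecutive-axis angles; a single
        # 10-degree kink contributes 10 degrees to the angle sum
        st = build_ideal_bdna("ATGCATGCATGC", bend_step=(5, 10.0))
        pairs = detect_base_pairs(st)
        (dup,) = detect_duplexes(st, pairs)
        frames = base_pair_frames(st, dup.pairs)
        angles_sum = ax_bend(frames) * 10
        assert angles_sum == pytest.approx(10.0, abs=0.2)
        assert ax_bend(frames) == pytest.approx(1.0, abs=0.02)

    def test_three_bp_zone_single_angle(self):
        st = build_ideal_bdna("ATGCATGCATGC", bend_step=(5, 8.0))
        pairs = detect_base_pairs(st)
        (dup,) = detect_duplexes(st, pairs)
        frames = base_pair_frames(st, dup.pairs[4:7])   # spans the kink
        axes = local_helix_axes(frames)
        assert len(axes) == 2
        # 3 bp -> 2 step axes -> exactly one angle; the mean is that angle
        single = np.degrees(np.arccos(np.clip(axes[0] @ axes[1], -1, 1)))
        assert ax_bend(frames) == pytest.approx(single, abs=1e-9)
        assert single > 1.0


class TestGrooves:
    def test_fiber_reference_widths(self, duplex_12):
        st, dup = duplex_12
        frames = base_pair_frames(st, dup.pairs)
        g = groove_geometry(st, dup.pairs, frames)
        assert g.minor_width == pytest.approx(5.9, abs=0.3)
        assert g.major_width == pytest.approx(11.4, abs=0.3)
        # depths by sign only (calibration-dependent)
        assert g.minor_depth > 0
        assert g.major_depth > 0

    def test_two_bp_zone_undefined(self, duplex_12):
        st, dup = duplex_12
        frames = base_pair_frames(st, dup.pairs[:2])
        g = groove_geometry(st, dup.pairs[:2], frames)
        assert g.minor_width is None and g.major_width is None
        assert g.ax_bend is None

    def test_width_tracks_radial_phosphate_displacement(self, duplex_12):
        st, dup = duplex_12
        from dnabind.structure import Structure

        def widened(delta):
            coords = st.coords.copy()
            for a in st.atoms:
                if a.atom_name == "P":
                    r = coords[a.index].copy()
                    r[2] = 0.0
                    coords[a.index] += delta * r / np.linalg.norm(r)
            s = Structure(st.id, st.assembly_id, st.atoms, coords)
            return groove_geometry(s, dup.pairs,
                                   base_pair_frames(s, dup.pairs))
        widths = [widened(d).minor_width for d in (0.0, 0.6, 1.2, 1.8)]
        assert all(w1 > w0 for w0, w1 in zip(widths, widths[1:]))
        majors = [widened(d).major_width for d in (0.0, 1.2)]
        assert majors[1] > majors[0]

    def test_rigid_invariance(self, duplex_12):
        st, dup = duplex_12
        frames = base_pair_frames(st, dup.pairs)
        g0 = groove_geometry(st, dup.pairs, frames)
        rng = np.random.default_rng(21)
        moved = st.transformed(random_rotation(rng),
                               np.array([11.0, -3.0, 6.0]))
        g1 = groove_geometry(moved, dup.pairs,
                             base_pair_frames(moved, dup.pairs))
        for k, v0 in g0.as_dict().items():
            assert g1.as_dict()[k] == pytest.approx(v0, abs=1e-6)


class TestAggregate:
    def test_single_domain_single_structure(self):
        g = GrooveShape(1.0, 5.9, 4.7, 11.4, 3.8)
        stats = aggregate_shape({"d1": [g]}, {"d1": "fam"})
        s = stats["fam"]
        for k in ("average", "minimum", "maximum"):
            assert getattr(s, k)["minor_width"] == pytest.approx(5.9)

    def test_family_avg_min_max(self):
        stats = aggregate_shape(
            {"d1": [GrooveShape(ax_bend=1.0)], "d2": [GrooveShape(ax_bend=3.0)]},
            {"d1": "fam", "d2": "fam"})
        s = stats["fam"]
        assert s.average["ax_bend"] == pytest.approx(2.0)
        assert s.minimum["ax_bend"] == pytest.approx(1.0)
        assert s.maximum["ax_bend"] == pytest.approx(3.0)
        assert s.minimum["ax_bend"] <= s.average["ax_bend"] <= \
            s.maximum["ax_bend"]

    def test_undefined_everywhere_gives_dash(self):
        stats = aggregate_shape({"d1": [GrooveShape()],
                                 "d2": [GrooveShape()]},
                                {"d1": "fam", "d2": "fam"})
        assert stats["fam"].average["minor_width"] is None
        text = shape_table(stats)
        assert "\t-\t" in text

    def test_undefined_values_skipped_in_mean(self):
        stats = aggregate_shape(
            {"d1": [GrooveShape(minor_width=4.0), GrooveShape()]},
            {"d1": "fam"})
        assert stats["fam"].average["minor_width"] == pytest.approx(4.0)
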