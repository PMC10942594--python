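"""Placement and wiring: geometry containment, blue noise/Lloyd, kernels."""

import numpy as np
import pytest
import shapely
from scipy import stats

from thetanest import topology as tp


@pytest.fixture(scope="module")
def small_layout():
    geom = tp.default_slice_geometry()
    counts = {"EC": (60, 12), "DG": (60, 6), "CA3": (30, 6), "CA1": (60, 12)}
    return tp.place_neurons(geom, counts, seed=4, lloyd_iters=15,
                            samples_per_point=30)


class TestGeometry:
    def test_annular_sector_validation(self):
        with pytest.raises(ValueError):
            tp.annular_sector((0, 0), 500, 400, 0, 90)

    def test_default_geometry_has_all_areas_and_strata(self):
        geom = tp.default_slice_geometry()
        assert set(geom) == set(tp.AREAS)
        for strata in geom.values():
            assert {"principal", "oriens"} <= set(strata)
            assert strata["principal"].area > 0


class TestPlacement:
    def test_points_inside_their_stratum(self, small_layout):
        geom = tp.default_slice_geometry()
        for (area, cls), s in small_layout.slices.items():
            stratum = "principal" if cls == "E" else "oriens"
            poly = geom[area][stratum].buffer(1.0)  # 1 um numeric margin
            xy = small_layout.positions_um[s, :2]
            assert shapely.contains_xy(poly, xy[:, 0], xy[:, 1]).all()

    def test_z_uniform_on_slice_thickness(self, small_layout):
        z = small_layout.positions_um[:, 2]
        assert z.min() >= 0 and z.max() <= tp.Z_EXTENT_UM
        p = stats.kstest(z / tp.Z_EXTENT_UM, "uniform").pvalue
        assert p > 1e-3

    def test_lloyd_energy_non_increasing(self):
        poly = tp.annular_sector((0, 0), 800, 1200, 0, 120)
        pts = tp.blue_noise_sample(poly, 40, seed=2)
        _, energies = tp.lloyd_relax(pts, poly, n_iter=25, seed=2,
                                     samples_per_point=50)
        assert np.all(np.diff(energies) <= 1e-9 * energies[0])

    def test_blue_noise_respects_radius(self):
        poly = tp.annular_sector((0, 0), 800, 1200, 0, 120)
        pts = tp.blue_noise_sample(poly, 30, seed=0, r_um=40.0)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 40.0

    def test_impossible_density_raises(self):
        poly = tp.annular_sector((0, 0), 100, 102, 0, 2)
        with pytest.raises(RuntimeError):
            tp.blue_noise_sample(poly, 5000, seed=0, max_tries=5, r_um=5.0)

    def test_same_seed_same_layout(self):
        geom = tp.default_slice_geometry()
        counts = {"CA3": (20, 5)}
        a = tp.place_neurons(geom, counts, seed=9, lloyd_iters=5)
        b = tp.place_neurons(geom, counts, seed=9, lloyd_iters=5)
        assert np.array_equal(a.positions_um, b.positions_um)

    def test_default_counts_scaling(self):
        full = tp.default_counts()
        assert full["EC"] == (10_000, 1_000)
        assert full["DG"] == (10_000, 100)
        assert full["CA3"] == (1_000, 100)
        assert full["CA1"] == (10_000, 1_000)
        desk = tp.default_counts(0.1)
        assert desk["EC"] == (1_000, 100) and desk["DG"] == (1_000, 10)


class TestIntraAreaWiring:
    def test_zero_amplitude_produces_no_edges(self, small_layout):
        g = tp.connect_intra(small_layout, seed=0,
                             a_intra={a: {k: 0.0 for k in v}
                                      for a, v in tp.A_INTRA.items()})
        assert g.n_edges == 0

    def test_no_self_connections(self, small_layout):
        g = tp.connect_intra(small_layout, seed=0)
        assert np.all(g.pre != g.post)

    def test_zero_distance_probability_is_amax(self):
        """Co-located neurons connect with probability A_intra (CA1 I->I
        0.7): statistical check against a binomial bound."""
        rng = np.random.default_rng(0)
        n = 60
        pos = np.tile(rng.uniform(0, 10, size=3), (n, 1))
        layout = tp.PopulationLayout(
            positions_um=pos, region_id=np.full(n, "CA1"),
            class_id=np.full(n, "I"), slices={("CA1", "I"): slice(0, n)})
        g = tp.connect_intra(layout, seed=1)
        n_pairs = n * (n - 1)
        p_hat = g.n_edges / n_pairs
        se = np.sqrt(0.7 * 0.3 / n_pairs)
        assert abs(p_hat - 0.7) < 4 * se

    def test_expected_edge_count_matches_analytic_oracle(self, small_layout):
        """Realized CA1 E->I edges vs the sum of pairwise probabilities."""
        g = tp.connect_intra(small_layout, seed=123)
        sel = g.provenance == "intra:CA1:E->I"
        s_pre = small_layout.block("CA1", "E")
        s_post = small_layout.block("CA1", "I")
        d2 = ((small_layout.positions_um[s_pre][:, None]
               - small_layout.positions_um[s_post][None]) ** 2).sum(-1)
        p = 0.28 * np.exp(-d2 / (2 * tp.SIGMA_INTRA_EXC_UM ** 2))
        mean, sd = p.sum(), np.sqrt((p * (1 - p)).sum())
        assert abs(sel.sum() - mean) < 4 * sd

    def test_edge_counts_scale_linearly_with_amplitude(self, small_layout):
        counts = []
        for f in (0.5, 1.0):
            a = {ar: {k: v * f for k, v in d.items()}
                 for ar, d in tp.A_INTRA.items()}
            g = tp.connect_intra(small_layout, seed=7, a_intra=a)
            counts.append(g.n_edges)
        ratio = counts[1] / counts[0]
        assert 1.7 < ratio < 2.3

    def test_increments_match_published_values(self, small_layout):
        from thetanest.synapses import INTRA_INCREMENTS_PS
        g = tp.connect_intra(small_layout, seed=0)
        seen = set()
        for name in np.unique(g.provenance):
            _, area, pair = name.split(":")
            expected = INTRA_INCREMENTS_PS[area][pair]
            assert np.all(g.weight_ps[g.provenance == name] == expected)
            seen.add(name)
        assert "intra:EC:E->I" in seen and "intra:CA1:E->I" in seen
        assert "intra:CA1:E->E" not in seen  # empty table cell -> no edges


class TestInterAreaWiring:
    def test_probability_non_increasing_in_z_distance(self):
        dz = np.linspace(0, 5000, 50)
        p = np.minimum(1.0, 1.1 * np.exp(-dz ** 2 / (2 * tp.SIGMA_INTER_UM ** 2)))
        assert np.all(np.diff(p) <= 0)

    def test_inhibitory_source_rejected(self, small_layout):
        with pytest.raises(ValueError, match="excitatory"):
            tp.connect_inter(small_layout, source_class="I")

    def test_recurrent_projection_rejected(self, small_layout):
        with pytest.raises(ValueError, match="[Rr]ecurrent"):
            tp.connect_inter_class(small_layout, "EC", "EC", "E", 1.0)

    def test_high_gain_connects_all_near_pairs(self, small_layout):
        """EC->DG at gain 13 connects every pair with small z-distance."""
        g = tp.connect_inter_class(small_layout, "EC", "DG", "E", 13.0, seed=0)
        s_pre = small_layout.block("EC", "E")
        s_post = small_layout.block("DG", "E")
        z_pre = small_layout.positions_um[s_pre, 2]
        z_post = small_layout.positions_um[s_post, 2]
        connected = set(zip(g.pre.tolist(), g.post.tolist()))
        close = 0
        for i in range(s_pre.start, s_pre.stop):
            for j in range(s_post.start, s_post.stop):
                if abs(z_pre[i - s_pre.start] - z_post[j - s_post.start]) < 500:
                    close += 1
                    assert (i, j) in connected
        assert close > 0

    def test_low_gain_probability_statistics(self, small_layout):
        """CA1->EC at gain 0.2: realized edges vs summed probabilities."""
        g = tp.connect_inter_class(small_layout, "CA1", "EC", "E", 0.2,
                                   seed=5)
        z_pre = small_layout.positions_um[small_layout.block("CA1", "E"), 2]
        z_post = small_layout.positions_um[small_layout.block("EC", "E"), 2]
        dz2 = (z_pre[:, None] - z_post[None]) ** 2
        p = np.minimum(1.0, 0.2 * np.exp(-dz2 / (2 * tp.SIGMA_INTER_UM ** 2)))
        mean, sd = p.sum(), np.sqrt((p * (1 - p)).sum())
        assert abs(g.n_edges - mean) < 4 * sd

    def test_clipped_excess_becomes_weight(self, small_layout):
        g = tp.connect_inter_class(small_layout, "EC", "DG", "E", 13.0, seed=0)
        assert g.weight_ps.max() > 20.0          # boosted near-z pairs
        assert g.weight_ps.min() >= 20.0         # never below the increment

    def test_gain_change_resamples_only_that_class(self, small_layout):
        a = tp.connect_inter(small_layout, seed=3)
        gains = dict(tp.A_INTER_DEFAULT)
        gains[("EC", "DG")] = 5.0
        b = tp.connect_inter(small_layout, seed=3, a_inter=gains)
        for cls in ("inter:CA3->CA1:E->E", "inter:CA1->EC:E->I"):
            ea = a.pre[a.provenance == cls], a.post[a.provenance == cls]
            eb = b.pre[b.provenance == cls], b.post[b.provenance == cls]
            assert np.array_equal(ea[0], eb[0]) and np.array_equal(ea[1], eb[1])


class TestWiringDiagram:
    def test_block_diagram_edge_set(self, small_layout):
        """Tri-synaptic EC->DG->CA3->CA1, monosynaptic EC->CA3/CA1, feedback
        CA1->EC only; all inter-area sources excitatory."""
        g = tp.build_graph(small_layout, seed=0)
        inter = {p.split(":")[1] for p in np.unique(g.provenance)
                 if p.startswith("inter")}
        assert inter == {"EC->DG", "EC->CA3", "EC->CA1", "DG->CA3",
                         "CA3->CA1", "CA1->EC"}
        for p in np.unique(g.provenance):
            if p.startswith("inter"):
                assert p.split(":")[2].startswith("E->")

    def test_same_seed_identical_graph(self, small_layout):
        a = tp.build_graph(small_layout, seed=42)
        b = tp.build_graph(small_layout, seed=42)
        assert np.array_equal(a.pre, b.pre)
        assert np.array_equal(a.post, b.post)
        assert np.array_equal(a.weight_ps, b.weight_ps)

    def test_layout_frame_round_trip(self, small_layout):
        df = small_layout.to_frame()
        assert len(df) == small_layout.n
        assert set(df.columns) == {"neuron_id", "region", "class",
                                   "x_um", "y_um", "z_um"}
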