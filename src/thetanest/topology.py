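"""Slice geometry, neuron placement and probabilistic wiring.

The hippocampal formation is modeled as a 15-mm-thick slice whose coronal
cross-section is a parametric arrangement of curved strata: for each area
(EC, DG, CA3, CA1) a principal-cell band (stratum pyramidale, or granulosum
in DG) that hosts the excitatory cells and an adjacent stratum-oriens band
for the basket cells.  The bands are annular sectors with millimeter
dimensions arranged along the hippocampal curl; all connectivity rules depend
only on inter-neuron distances, so any geometry of comparable spatial extent
preserves the model class.

Within the cross-section, neurons are placed by blue-noise (Poisson-disk)
sampling refined by Lloyd relaxation toward a centroidal Voronoi layout; the
third coordinate is uniform on [0, 15] mm.

Wiring:

* within an area, each ordered pair connects with probability
  ``p = A_intra · exp(−D²/2σ²)`` (D the full 3D distance; σ = 2500 µm for
  excitatory, 350 µm for inhibitory synapses);
* between areas, only excitatory projections exist and the probability
  ``p = min(1, A_inter · exp(−Δz²/2σ²))`` depends on the z-distance alone
  (σ = 1000 µm), so A_inter acts as a tunable connection strength that may
  exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .synapses import INTER_INCREMENTS_PS, INTRA_INCREMENTS_PS

__all__ = [
    "AREAS",
    "A_INTRA",
    "A_INTER_DEFAULT",
    "SIGMA_INTRA_EXC_UM",
    "SIGMA_INTRA_INH_UM",
    "SIGMA_INTER_UM",
    "Z_EXTENT_UM",
    "PopulationLayout",
    "ConnectivityGraph",
    "annular_sector",
    "default_slice_geometry",
    "default_counts",
    "blue_noise_sample",
    "lloyd_relax",
    "lloyd_energy",
    "place_neurons",
    "connect_intra",
    "connect_inter",
    "connect_inter_class",
    "build_graph",
]

AREAS = ("EC", "DG", "CA3", "CA1")
Z_EXTENT_UM = 15_000.0
SIGMA_INTRA_EXC_UM = 2500.0
SIGMA_INTRA_INH_UM = 350.0
SIGMA_INTER_UM = 1000.0

# Maximum intra-area connection probability at zero distance, by area and
# ordered population pair.  Zero entries produce no edges.
A_INTRA = {
    "EC":  {"E->E": 0.0, "E->I": 0.37, "I->E": 0.54, "I->I": 0.0},
    "DG":  {"E->E": 0.0, "E->I": 0.06, "I->E": 0.14, "I->I": 0.0},
    "CA3": {"E->E": 0.56, "E->I": 0.75, "I->E": 0.75, "I->I": 0.0},
    "CA1": {"E->E": 0.0, "E->I": 0.28, "I->E": 0.3, "I->I": 0.7},
}

# Tuned inter-area connection strengths of the reference parameterization.
# Sources are always the excitatory population.
A_INTER_DEFAULT = {
    ("EC", "DG"): 13.0,
    ("EC", "CA3"): 0.14,
    ("EC", "CA1"): 1.1,
    ("DG", "CA3"): 0.14,
    ("CA3", "CA1"): 1.1,
    ("CA1", "EC"): 0.2,
}


def default_counts(scale: float = 1.0) -> dict:
    """Neurons per (area, class); scale < 1 gives the desk-scale network."""
    full = {"EC": (10_000, 1_000), "DG": (10_000, 100),
            "CA3": (1_000, 100), "CA1": (10_000, 1_000)}
    if scale == 1.0:
        return full
    return {a: (max(1, int(round(ne * scale))), max(1, int(round(ni * scale))))
            for a, (ne, ni) in full.items()}


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def annular_sector(center, r_in_um: float, r_out_um: float,
                   a0_deg: float, a1_deg: float, n_arc: int = 72) -> Polygon:
    """Polygon approximating the annular sector between two radii/angles."""
    if not (r_out_um > r_in_um >= 0):
        raise ValueError("need r_out > r_in >= 0")
    cx, cy = center
    ang = np.deg2rad(np.linspace(a0_deg, a1_deg, n_arc))
    outer = np.column_stack([cx + r_out_um * np.cos(ang), cy + r_out_um * np.sin(ang)])
    inner = np.column_stack([cx + r_in_um * np.cos(ang[::-1]), cy + r_in_um * np.sin(ang[::-1])])
    return Polygon(np.vstack([outer, inner]))


def default_slice_geometry(scale_xy: float = 1.0) -> dict:
    """Parametric coronal-slice geometry: per area, the principal-cell band
    and the oriens band as shapely polygons (µm coordinates)."""
    # Band dimensions are chosen so that, combined with the 15-mm slice
    # thickness and the σ = 350 µm inhibitory kernel, within-area inhibition
    # is dense enough to sustain pyramidal-interneuron gamma; the wiring
    # rules depend only on distances, so the cross-section is deliberately
    # more compact than the anatomical formation.
    s = scale_xy
    spec = {
        # area: (r_in, r_out principal), (r_in, r_out oriens), angle range
        "DG":  ((480, 640), (320, 480), (150, 330)),
        "CA3": ((880, 1040), (1040, 1200), (185, 260)),
        "CA1": ((1200, 1360), (1360, 1520), (95, 180)),
        "EC":  ((1680, 1840), (1840, 2000), (200, 280)),
    }
    geom = {}
    for area, (princ, oriens, (a0, a1)) in spec.items():
        geom[area] = {
            "principal": annular_sector((0, 0), princ[0] * s, princ[1] * s, a0, a1),
            "oriens": annular_sector((0, 0), oriens[0] * s, oriens[1] * s, a0, a1),
        }
    return geom


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _uniform_in_polygon(poly: Polygon, n: int, rng) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(max(64, 2 * (n - got)), 2))
        inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        take = cand[inside][: n - got]
        out[got: got + take.shape[0]] = take
        got += take.shape[0]
    return out


def blue_noise_sample(poly: Polygon, n: int, seed: int = 0,
                      r_um: float | None = None, max_tries: int = 40) -> np.ndarray:
    """Poisson-disk dart throwing inside a polygon.

    The disk radius defaults to ~0.7 of the mean inter-point spacing for the
    target density and shrinks geometrically whenever the polygon cannot
    accommodate all points at the current radius.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if poly.area <= 0:
        raise ValueError("placement region has zero area")
    rng = np.random.default_rng(seed)
    r = r_um if r_um is not None else 0.7 * np.sqrt(poly.area / (np.pi * n))
    # an explicitly requested spacing may only be relaxed moderately; the
    # density-derived default shrinks freely
    r_floor = r * (0.2 if r_um is not None else 1e-3)
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        placed_this_round = False
        cand_batch = _uniform_in_polygon(poly, max_tries, rng)
        for cand in cand_batch:
            if got == 0 or np.min(((pts[:got] - cand) ** 2).sum(1)) >= r * r:
                pts[got] = cand
                got += 1
                placed_this_round = True
                if got == n:
                    break
        if not placed_this_round:
            r *= 0.8
            if r < r_floor:
                raise RuntimeError("geometry too small for requested density")
    return pts


def lloyd_energy(points: np.ndarray, samples: np.ndarray) -> float:
    """Quantization energy: mean squared distance of a dense uniform sample
    cloud to its nearest seed (the objective Lloyd's algorithm descends)."""
    d, _ = cKDTree(points).query(samples, k=1)
    return float(np.mean(d ** 2))


def lloyd_relax(points: np.ndarray, poly: Polygon, n_iter: int = 1000,
                tol: float = 1e-6, seed: int = 0,
                samples_per_point: int = 60):
    """Centroidal-Voronoi (Lloyd) relaxation restricted to a polygon.

    The polygon's area measure is represented by a dense uniform sample
    cloud; each iteration assigns samples to their nearest seed and moves
    every seed to the centroid of its assigned samples (k-means on the
    cloud, which is Lloyd's algorithm under the sampled measure — the
    quantization energy is non-increasing).  Stops early when the relative
    energy change drops below ``tol``.  Returns (points, energy history).
    """
    rng = np.random.default_rng(seed)
    pts = np.array(points, dtype=float)
    cloud = _uniform_in_polygon(poly, samples_per_point * len(pts), rng)
    energies = []
    for _ in range(n_iter):
        d, owner = cKDTree(pts).query(cloud, k=1)
        energies.append(float(np.mean(d ** 2)))   # pre-update energy
        counts = np.bincount(owner, minlength=len(pts))
        sx = np.bincount(owner, weights=cloud[:, 0], minlength=len(pts))
        sy = np.bincount(owner, weights=cloud[:, 1], minlength=len(pts))
        nz = counts > 0
        pts[nz, 0] = sx[nz] / counts[nz]
        pts[nz, 1] = sy[nz] / counts[nz]
        if len(energies) > 1 and abs(energies[-2] - energies[-1]) \
                <= tol * max(energies[-1], 1e-30):
            break
    # guard: centroids of clusters in a curved band may rarely fall outside
    outside = np.flatnonzero(~shapely.contains_xy(poly, pts[:, 0], pts[:, 1]))
    if outside.size:
        inside_cloud = cloud
        tree = cKDTree(inside_cloud)
        for i in outside:
            pts[i] = inside_cloud[tree.query(pts[i], k=1)[1]]
    return pts, np.asarray(energies)


@dataclass
class PopulationLayout:
    """3D positions (µm) plus area and class labels, one row per neuron.

    Neurons are ordered area-by-area (EC, DG, CA3, CA1), excitatory block
    first within each area; ``slices`` maps (area, class) to the index range.
    """

    positions_um: np.ndarray
    region_id: np.ndarray      # str array, e.g. "CA1"
    class_id: np.ndarray       # "E" or "I"
    slices: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.positions_um.shape[0]

    def block(self, area: str, cls: str) -> slice:
        return self.slices[(area, cls)]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "neuron_id": np.arange(self.n),
            "region": self.region_id,
            "class": self.class_id,
            "x_um": self.positions_um[:, 0],
            "y_um": self.positions_um[:, 1],
            "z_um": self.positions_um[:, 2],
        })


def place_neurons(geometry: dict, counts: dict, seed: int = 0,
                  lloyd_iters: int = 1000, z_extent_um: float = Z_EXTENT_UM,
                  samples_per_point: int = 60) -> PopulationLayout:
    """Place every population of every area on the slice.

    Excitatory cells go in the principal band, interneurons in the oriens
    band; z is uniform on [0, z_extent].  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    pos, regions, classes, slices = [], [], [], {}
    offset = 0
    for area in (a for a in AREAS if a in counts):
        ne, ni = counts[area]
        for cls, n_cls, stratum in (("E", ne, "principal"), ("I", ni, "oriens")):
            poly = geometry[area][stratum]
            sub = int(rng.integers(0, 2**31 - 1))
            xy = blue_noise_sample(poly, n_cls, seed=sub)
            if n_cls > 1:
                xy, _ = lloyd_relax(xy, poly, n_iter=lloyd_iters, seed=sub,
                                    samples_per_point=samples_per_point)
            z = rng.uniform(0.0, z_extent_um, size=n_cls)
            pos.append(np.column_stack([xy, z]))
            regions.append(np.full(n_cls, area, dtype=object))
            classes.append(np.full(n_cls, cls, dtype=object))
            slices[(area, cls)] = slice(offset, offset + n_cls)
            offset += n_cls
    return PopulationLayout(
        positions_um=np.vstack(pos),
        region_id=np.concatenate(regions).astype(str),
        class_id=np.concatenate(classes).astype(str),
        slices=slices,
    )


# ---------------------------------------------------------------------------
# wiring
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityGraph:
    """Directed synaptic edges with per-edge conductance increments (pS)."""

    pre: np.ndarray
    post: np.ndarray
    weight_ps: np.ndarray
    kind: np.ndarray         # "E" or "I": which conductance the edge drives
    provenance: np.ndarray   # e.g. "intra:CA1:I->E" / "inter:EC->DG"

    @property
    def n_edges(self) -> int:
        return self.pre.size

    @classmethod
    def empty(cls):
        z = np.empty(0, dtype=np.int64)
        return cls(z, z.copy(), np.empty(0), np.empty(0, dtype=object),
                   np.empty(0, dtype=object))

    @classmethod
    def concatenate(cls, graphs):
        graphs = [g for g in graphs if g.n_edges]
        if not graphs:
            return cls.empty()
        return cls(*(np.concatenate([getattr(g, f) for g in graphs])
                     for f in ("pre", "post", "weight_ps", "kind", "provenance")))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"pre": self.pre, "post": self.post,
                             "weight_ps": self.weight_ps, "kind": self.kind,
                             "provenance": self.provenance})


def _bernoulli_edges(pos_pre, pos_post, prob_fn, rng, same_block: bool,
                     chunk: int = 512):
    """Sample ordered Bernoulli edges with a distance-dependent probability."""
    pres, posts = [], []
    n_pre = pos_pre.shape[0]
    for lo in range(0, n_pre, chunk):
        hi = min(lo + chunk, n_pre)
        p = prob_fn(pos_pre[lo:hi], pos_post)
        if same_block:
            idx = np.arange(lo, hi)
            p[np.arange(hi - lo), idx] = 0.0   # no self-connections
        mask = rng.random(p.shape) < p
        i, j = np.nonzero(mask)
        pres.append(i + lo)
        posts.append(j)
    return np.concatenate(pres), np.concatenate(posts)


def connect_intra(layout: PopulationLayout, seed: int = 0,
                  a_intra: dict | None = None,
                  sigma_exc_um: float = SIGMA_INTRA_EXC_UM,
                  sigma_inh_um: float = SIGMA_INTRA_INH_UM,
                  increments_ps: dict | None = None) -> ConnectivityGraph:
    """Within-area wiring: Bernoulli per ordered pair with Gaussian
    distance decay of the full 3D distance."""
    a_intra = A_INTRA if a_intra is None else a_intra
    increments_ps = INTRA_INCREMENTS_PS if increments_ps is None else increments_ps
    graphs = []
    present = {k[0] for k in layout.slices}
    for ai, area in enumerate(a for a in AREAS if a in present):
        for pi, (pair, amax) in enumerate(sorted(a_intra.get(area, {}).items())):
            w = increments_ps.get(area, {}).get(pair, 0.0)
            if amax <= 0 or w <= 0:
                continue
            rng = np.random.default_rng([seed, 1, ai, pi])
            pre_cls, post_cls = pair.split("->")
            if (area, pre_cls) not in layout.slices \
                    or (area, post_cls) not in layout.slices:
                continue
            sigma = sigma_exc_um if pre_cls == "E" else sigma_inh_um
            s_pre = layout.block(area, pre_cls)
            s_post = layout.block(area, post_cls)
            p_pre, p_post = layout.positions_um[s_pre], layout.positions_um[s_post]

            def prob(a, b, amax=amax, sigma=sigma):
                d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
                return amax * np.exp(-d2 / (2.0 * sigma ** 2))

            pre, post = _bernoulli_edges(p_pre, p_post, prob, rng,
                                         same_block=(pre_cls == post_cls))
            graphs.append(ConnectivityGraph(
                pre=pre + s_pre.start, post=post + s_post.start,
                weight_ps=np.full(pre.size, w),
                kind=np.full(pre.size, pre_cls, dtype=object),
                provenance=np.full(pre.size, f"intra:{area}:{pair}", dtype=object)))
    return ConnectivityGraph.concatenate(graphs)


def connect_inter(layout: PopulationLayout, seed: int = 0,
                  a_inter: dict | None = None,
                  sigma_um: float = SIGMA_INTER_UM,
                  increments_ps: dict | None = None,
                  source_class: str = "E") -> ConnectivityGraph:
    """Between-area wiring: excitatory sources only, probability depending
    on the z-distance alone, clipped at 1."""
    if source_class != "E":
        raise ValueError("inter-area projections must originate from an "
                         "excitatory population")
    a_inter = A_INTER_DEFAULT if a_inter is None else a_inter
    graphs = []
    present = {k[0] for k in layout.slices}
    for (src, dst), gain in sorted(a_inter.items()):
        if src not in present or dst not in present:
            continue
        for post_cls in ("E", "I"):
            graphs.append(connect_inter_class(
                layout, src, dst, post_cls, gain, seed=seed,
                sigma_um=sigma_um, increments_ps=increments_ps))
    return ConnectivityGraph.concatenate(graphs)


def connect_inter_class(layout: PopulationLayout, src: str, dst: str,
                        post_cls: str, gain: float, seed: int = 0,
                        sigma_um: float = SIGMA_INTER_UM,
                        increments_ps: dict | None = None) -> ConnectivityGraph:
    """One inter-area projection class (source excitatory → one target
    population), with a seed derived from (seed, src, dst, target class) so
    that changing one gain leaves every other class's edge sample intact and
    increasing a gain only adds edges."""
    if src == dst:
        raise ValueError(f"recurrent inter-area projection {src}->{dst} "
                         "not allowed")
    increments_ps = INTER_INCREMENTS_PS if increments_ps is None else increments_ps
    w = increments_ps.get((src, dst), 0.0)
    if gain <= 0 or w <= 0 or (src, "E") not in layout.slices \
            or (dst, post_cls) not in layout.slices:
        return ConnectivityGraph.empty()
    rng = np.random.default_rng(
        [seed, 2, AREAS.index(src), AREAS.index(dst), int(post_cls == "I")])
    s_pre = layout.block(src, "E")
    s_post = layout.block(dst, post_cls)

    def prob(a, b, gain=gain, sigma=sigma_um):
        dz2 = (a[:, 2:3] - b[None, :, 2]) ** 2
        return np.minimum(1.0, gain * np.exp(-dz2 / (2.0 * sigma ** 2)))

    pre, post = _bernoulli_edges(layout.positions_um[s_pre],
                                 layout.positions_um[s_post], prob, rng,
                                 same_block=False)
    # where the kernel exceeds 1 the excess becomes synaptic weight
    # (multiple contacts), keeping the expected input linear in the gain
    z_pre = layout.positions_um[s_pre, 2][pre]
    z_post = layout.positions_um[s_post, 2][post]
    a_pair = gain * np.exp(-(z_pre - z_post) ** 2 / (2.0 * sigma_um ** 2))
    return ConnectivityGraph(
        pre=pre + s_pre.start, post=post + s_post.start,
        weight_ps=w * np.maximum(1.0, a_pair),
        kind=np.full(pre.size, "E", dtype=object),
        provenance=np.full(pre.size, f"inter:{src}->{dst}:E->{post_cls}",
                           dtype=object))


def build_graph(layout: PopulationLayout, seed: int = 0,
                a_inter: dict | None = None,
                a_intra: dict | None = None) -> ConnectivityGraph:
    """Full wiring diagram: intra-area loops plus the tri-synaptic
    (EC→DG→CA3→CA1), monosynaptic (EC→CA3, EC→CA1) and feedback (CA1→EC)
    pathways."""
    return ConnectivityGraph.concatenate([
        connect_intra(layout, seed=seed, a_intra=a_intra),
        connect_inter(layout, seed=seed + 1, a_inter=a_inter),
    ])
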