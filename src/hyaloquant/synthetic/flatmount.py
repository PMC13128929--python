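"""Synthetic flatmount renderer with full ground truth.

Emulates an en-face stained vessel network: a random planar tree of tubes
(CD31 footprint), endothelial nuclei on the tube centerlines, elongated
pericyte nuclei and rounder other nuclei outside the footprint (DAPI),
and TUNEL puncta — linear clusters on designated regressing segments whose
CD31 is locally attenuated, isolated puncta on intact segments, and
extravascular puncta.  Optional nuclear-marker channels add a known
per-pixel signal on endothelial nuclei over a flat background; membrane
markers add signal over the whole footprint.

The network is the minimum spanning tree of Delaunay edges over random
seed points: connected, realistic branch topology, no enclosed faces (so
hole-filling the rendered mask never swallows background), and a known
segment list once degree-2 seed points are contracted away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import Delaunay
from skimage import draw

from ..types import ENDOTHELIAL, OTHER_NON_ENDOTHELIAL, PERICYTE, FlatmountImage

__all__ = ["ChannelModel", "ImageSimSpec", "FlatmountGroundTruth", "generate_flatmount"]


@dataclass
class ChannelModel:
    """Intensity model of one channel: flat background, additive signal,
    Gaussian noise with σ expressed as a fraction of the signal level."""

    background: float
    signal: float
    noise_sigma_frac: float = 0.0

    @property
    def noise_sigma(self) -> float:
        return self.noise_sigma_frac * self.signal


def _default_channels() -> dict[str, ChannelModel]:
    return {
        "DAPI": ChannelModel(5.0, 200.0),
        "CD31": ChannelModel(10.0, 200.0),
        "TUNEL": ChannelModel(5.0, 150.0),
    }


@dataclass
class ImageSimSpec:
    """Study conditions of the synthetic flatmount.

    Sizes are in pixels (image) and micrometres (physical quantities);
    nucleus axes are semi-axes.  Pericyte axes give circularity well below
    the 0.6 classification cutoff (4:1 elongation ≈ 0.54); endothelial and
    other nuclei stay well above it.  ``seed`` fixes the entire draw.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.0
    n_seed_points: int = 14
    min_seed_separation_um: float = 55.0
    tube_radius_um: float = 6.0
    n_ec_nuclei: int = 30
    n_pericyte_nuclei: int = 12
    n_other_nuclei: int = 8
    ec_axes_um: tuple[float, float] = (4.5, 3.0)
    pericyte_axes_um: tuple[float, float] = (12.0, 2.0)
    other_radius_um: float = 3.5
    min_nucleus_separation_um: float = 27.0
    n_regressing_segments: int = 3
    puncta_per_cluster: int = 4
    cluster_span_um: float = 36.0
    cd31_gap_fraction: float = 0.5
    cd31_gap_intensity_frac: float = 0.5
    n_isolated_puncta: int = 5
    n_extravascular_puncta: int = 4
    punctum_sigma_px: float = 1.5
    channels: dict[str, ChannelModel] = field(default_factory=_default_channels)
    nuclear_markers: dict[str, ChannelModel] = field(default_factory=dict)
    membrane_markers: dict[str, ChannelModel] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tube_radius_um / self.pixel_size < 2:
            raise ValueError("tube radius must be at least 2 pixels")
        for name in (
            "n_ec_nuclei",
            "n_pericyte_nuclei",
            "n_other_nuclei",
            "n_regressing_segments",
            "n_isolated_puncta",
            "n_extravascular_puncta",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_noise(self, sigma_frac: float) -> "ImageSimSpec":
        """Copy of the spec with the given noise fraction on every channel."""
        import copy

        out = copy.deepcopy(self)
        for model in (
            list(out.channels.values())
            + list(out.nuclear_markers.values())
            + list(out.membrane_markers.values())
        ):
            model.noise_sigma_frac = sigma_frac
        return out


@dataclass
class FlatmountGroundTruth:
    """Generator-side truth for recovery tests."""

    nuclei: pd.DataFrame  # columns: row, col, cell_class
    puncta: pd.DataFrame  # columns: row, col, kind, edge_index
    footprint: np.ndarray  # boolean tube footprint
    n_edges: int
    n_branch_nodes: int
    n_endpoints: int
    edge_polylines: list[np.ndarray]  # (k, 2) vertices in pixel coords
    regressing_edges: list[int]  # indices into edge_polylines

    @property
    def footprint_px(self) -> int:
        return int(self.footprint.sum())


# ---------------------------------------------------------------------------
# geometry helpers


def _sample_seed_points(rng, shape, n, min_sep_px, margin_px, max_tries=20000):
    pts = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place the requested vessel seed points; "
                "use a larger image or fewer/closer points"
            )
        p = np.array(
            [
                rng.uniform(margin_px, shape[0] - margin_px),
                rng.uniform(margin_px, shape[1] - margin_px),
            ]
        )
        if all(np.hypot(*(p - q)) >= min_sep_px for q in pts):
            pts.append(p)
    return np.array(pts)


def _network_tree(points: np.ndarray) -> nx.Graph:
    tri = Delaunay(points)
    g = nx.Graph()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            g.add_edge(a, b, weight=float(np.hypot(*(points[a] - points[b]))))
    return nx.minimum_spanning_tree(g)


def _contract_degree2(tree: nx.Graph, points: np.ndarray):
    """Merge degree-2 seed nodes into polyline segments.

    Returns polylines (vertex coordinate arrays) between branch points
    (degree >= 3) and endpoints (degree 1), matching what skeleton analysis
    of the rendered tubes should recover.
    """
    terminals = {n for n in tree.nodes if tree.degree(n) != 2}
    polylines = []
    visited_edges = set()
    for t in sorted(terminals):
        for nb in sorted(tree.neighbors(t)):
            if (t, nb) in visited_edges:
                continue
            path = [t, nb]
            visited_edges.add((t, nb))
            visited_edges.add((nb, t))
            prev, cur = t, nb
            while cur not in terminals:
                nxt = next(n for n in tree.neighbors(cur) if n != prev)
                visited_edges.add((cur, nxt))
                visited_edges.add((nxt, cur))
                path.append(nxt)
                prev, cur = cur, nxt
            polylines.append(points[path])
    n_branch = sum(1 for n in terminals if tree.degree(n) >= 3)
    n_end = sum(1 for n in terminals if tree.degree(n) == 1)
    return polylines, n_branch, n_end


def _polyline_arclen(poly: np.ndarray) -> np.ndarray:
    steps = np.sqrt((np.diff(poly, axis=0) ** 2).sum(axis=1))
    return np.concatenate([[0.0], np.cumsum(steps)])


def _point_at_arc(poly: np.ndarray, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Point and unit tangent at arc length s along a polyline."""
    arcs = _polyline_arclen(poly)
    s = float(np.clip(s, 0, arcs[-1]))
    i = int(np.searchsorted(arcs, s, side="right") - 1)
    i = min(i, len(poly) - 2)
    seg = poly[i + 1] - poly[i]
    seg_len = np.hypot(*seg)
    t = 0.0 if seg_len == 0 else (s - arcs[i]) / seg_len
    tangent = seg / seg_len if seg_len else np.array([1.0, 0.0])
    return poly[i] + t * seg, tangent


def _draw_polyline(canvas: np.ndarray, poly: np.ndarray) -> None:
    for a, b in zip(poly[:-1], poly[1:]):
        rr, cc = draw.line(*np.round(a).astype(int), *np.round(b).astype(int))
        canvas[rr, cc] = True


def _tube_mask(shape, polylines, radius_px):
    center = np.zeros(shape, bool)
    for poly in polylines:
        _draw_polyline(center, poly)
    dist = ndi.distance_transform_edt(~center)
    return dist <= radius_px, center


def _ellipse_pixels(shape, center, semi_axes, angle):
    rr, cc = draw.ellipse(
        center[0], center[1], semi_axes[0], semi_axes[1], shape=shape, rotation=angle
    )
    return rr, cc


# ---------------------------------------------------------------------------


def generate_flatmount(spec: ImageSimSpec) -> tuple[FlatmountImage, FlatmountGroundTruth]:
    """Render a synthetic flatmount and its ground truth, deterministically
    for a given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size
    shape = spec.shape
    radius_px = spec.tube_radius_um / px

    margin = 2 * radius_px + 12
    need = spec.cluster_span_um + 4 * spec.tube_radius_um
    # resample until the contracted network can host the requested
    # regressing segments and isolated puncta (at most 2 per intact segment)
    for _attempt in range(10):
        points = _sample_seed_points(
            rng, shape, spec.n_seed_points, spec.min_seed_separation_um / px, margin
        )
        tree = _network_tree(points)
        polylines, n_branch, n_end = _contract_degree2(tree, points)
        lengths = np.array([_polyline_arclen(p)[-1] for p in polylines]) * px
        eligible = [i for i in np.argsort(-lengths) if lengths[i] >= need]
        capacity = 2 * (len(polylines) - spec.n_regressing_segments)
        if len(eligible) >= spec.n_regressing_segments and capacity >= spec.n_isolated_puncta:
            break
    else:
        raise RuntimeError(
            "could not draw a vessel network able to host the requested "
            "regressing segments and puncta; use a larger image or more seed points"
        )
    footprint, _ = _tube_mask(shape, polylines, radius_px)
    regressing = (
        sorted(
            rng.choice(eligible, size=spec.n_regressing_segments, replace=False).tolist()
        )
        if spec.n_regressing_segments
        else []
    )

    # --- CD31 channel with attenuated stretches on regressing segments ---
    cd31_model = spec.channels["CD31"]
    cd31 = np.full(shape, cd31_model.background, float)
    cd31[footprint] += cd31_model.signal
    gap_regions = np.zeros(shape, bool)
    for i in regressing:
        poly = polylines[i]
        total = _polyline_arclen(poly)[-1]
        gap_len = spec.cd31_gap_fraction * total
        s0 = (total - gap_len) / 2.0
        gap_center = np.zeros(shape, bool)
        n_steps = max(2, int(gap_len))
        pts = [
            _point_at_arc(poly, s0 + gap_len * t)[0] for t in np.linspace(0, 1, n_steps)
        ]
        _draw_polyline(gap_center, np.array(pts))
        gdist = ndi.distance_transform_edt(~gap_center)
        gap_regions |= (gdist <= radius_px + 1) & footprint
    cd31[gap_regions] = (
        cd31_model.background + cd31_model.signal * spec.cd31_gap_intensity_frac
    )

    # --- nuclei ----------------------------------------------------------
    nuclei_rows = []
    placed_centers: list[np.ndarray] = []
    min_sep = spec.min_nucleus_separation_um / px

    def _try_place(center) -> bool:
        # keep whole nuclei inside the frame so clipping never distorts shape
        if not (
            12 <= center[0] < shape[0] - 12 and 12 <= center[1] < shape[1] - 12
        ):
            return False
        if any(np.hypot(*(center - q)) < min_sep for q in placed_centers):
            return False
        placed_centers.append(center)
        return True

    total_len = lengths.sum() / px
    cum = np.cumsum(lengths / px)
    for _ in range(spec.n_ec_nuclei):
        for _try in range(4000):
            s = rng.uniform(0, total_len)
            edge_i = int(np.searchsorted(cum, s))
            local_s = s - (cum[edge_i - 1] if edge_i else 0.0)
            pos, tangent = _point_at_arc(polylines[edge_i], local_s)
            normal = np.array([-tangent[1], tangent[0]])
            center = pos + normal * rng.uniform(-radius_px / 3, radius_px / 3)
            if _try_place(center):
                angle = np.arctan2(tangent[1], tangent[0])
                nuclei_rows.append((center, spec.ec_axes_um, angle, ENDOTHELIAL))
                break
        else:
            raise RuntimeError(
                "vessel network too dense to place the requested endothelial "
                "nuclei; use a larger image"
            )
    outside_ok = ndi.distance_transform_edt(~footprint) > radius_px / 2 + 4
    ok_coords = np.argwhere(
        outside_ok
        & (ndi.distance_transform_edt(~footprint) < 6 * radius_px)
    )
    for n, axes, cls in (
        (spec.n_pericyte_nuclei, spec.pericyte_axes_um, PERICYTE),
        (spec.n_other_nuclei, (spec.other_radius_um, spec.other_radius_um), OTHER_NON_ENDOTHELIAL),
    ):
        for _ in range(n):
            for _try in range(4000):
                center = ok_coords[rng.integers(len(ok_coords))].astype(float)
                if _try_place(center):
                    nuclei_rows.append((center, axes, rng.uniform(0, np.pi), cls))
                    break
            else:
                raise RuntimeError(
                    "image too crowded to place the requested perivascular "
                    "nuclei; use a larger image"
                )

    dapi_model = spec.channels["DAPI"]
    dapi = np.full(shape, dapi_model.background, float)
    nucleus_pixel_sets = []
    for center, axes_um, angle, cls in nuclei_rows:
        rr, cc = _ellipse_pixels(shape, center, (axes_um[0] / px, axes_um[1] / px), angle)
        dapi[rr, cc] = dapi_model.background + dapi_model.signal
        nucleus_pixel_sets.append((rr, cc, cls))

    # --- TUNEL puncta -----------------------------------------------------
    tunel_model = spec.channels["TUNEL"]
    tunel = np.full(shape, tunel_model.background, float)
    puncta_rows = []
    puncta_centers: list[np.ndarray] = []
    min_punctum_sep = 7.0

    def _place_punctum(center, kind, edge_index):
        if any(np.hypot(*(center - q)) < min_punctum_sep for q in puncta_centers):
            return False
        puncta_centers.append(center)
        puncta_rows.append((center[0], center[1], kind, edge_index))
        return True

    for i in regressing:
        poly = polylines[i]
        total = _polyline_arclen(poly)[-1]
        span = min(spec.cluster_span_um / px, 0.8 * total)
        s0 = (total - span) / 2.0
        offsets = np.linspace(0, span, spec.puncta_per_cluster)
        for off in offsets:
            for _try in range(50):
                pos, tangent = _point_at_arc(poly, s0 + off + rng.uniform(-0.5, 0.5))
                normal = np.array([-tangent[1], tangent[0]])
                center = pos + normal * rng.uniform(-2, 2)
                if _place_punctum(center, "regressing", int(i)):
                    break
            else:
                raise RuntimeError(
                    "could not place a cluster punctum; reduce puncta per "
                    "cluster or enlarge the cluster span"
                )
    intact_edges = [i for i in range(len(polylines)) if i not in regressing]
    per_edge_isolated: dict[int, int] = {}
    for k in range(spec.n_isolated_puncta):
        for _try in range(2000):
            i = int(rng.choice(intact_edges))
            # cap 2 per segment: isolated events must never form a cluster
            if per_edge_isolated.get(i, 0) >= 2:
                continue
            poly = polylines[i]
            total = _polyline_arclen(poly)[-1]
            pos, _ = _point_at_arc(poly, rng.uniform(0.15, 0.85) * total)
            if _place_punctum(pos, "isolated", int(i)):
                per_edge_isolated[i] = per_edge_isolated.get(i, 0) + 1
                break
        else:
            raise RuntimeError("could not place isolated puncta; network too small")
    far_outside = np.argwhere(ndi.distance_transform_edt(~footprint) > radius_px + 6)
    for k in range(spec.n_extravascular_puncta):
        for _try in range(2000):
            center = far_outside[rng.integers(len(far_outside))].astype(float)
            if (
                8 <= center[0] < shape[0] - 8
                and 8 <= center[1] < shape[1] - 8
                and _place_punctum(center, "extravascular", None)
            ):
                break
        else:
            raise RuntimeError("could not place extravascular puncta")

    if puncta_centers:
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        for r0, c0, _, _ in puncta_rows:
            d2 = (rows - r0) ** 2 + (cols - c0) ** 2
            tunel += tunel_model.signal * np.exp(-d2 / (2 * spec.punctum_sigma_px**2))

    # --- marker channels --------------------------------------------------
    channels = {"DAPI": dapi, "CD31": cd31, "TUNEL": tunel}
    for name, model in spec.nuclear_markers.items():
        raster = np.full(shape, model.background, float)
        for rr, cc, cls in nucleus_pixel_sets:
            if cls == ENDOTHELIAL:
                raster[rr, cc] += model.signal
        channels[name] = raster
    for name, model in spec.membrane_markers.items():
        raster = np.full(shape, model.background, float)
        raster[footprint] += model.signal
        channels[name] = raster

    # --- noise ------------------------------------------------------------
    all_models = dict(spec.channels)
    all_models.update(spec.nuclear_markers)
    all_models.update(spec.membrane_markers)
    for name, raster in channels.items():
        sigma = all_models[name].noise_sigma
        if sigma > 0:
            raster += rng.normal(0.0, sigma, size=shape)
            np.clip(raster, 0.0, None, out=raster)

    image = FlatmountImage(channels=channels, pixel_size=px, metadata={"seed": spec.seed})
    gt = FlatmountGroundTruth(
        nuclei=pd.DataFrame(
            [
                {"row": c[0], "col": c[1], "cell_class": cls}
                for c, _, _, cls in nuclei_rows
            ],
            columns=["row", "col", "cell_class"],
        ),
        puncta=pd.DataFrame(
            puncta_rows, columns=["row", "col", "kind", "edge_index"]
        ),
        footprint=footprint,
        n_edges=len(polylines),
        n_branch_nodes=n_branch,
        n_endpoints=n_end,
        edge_polylines=polylines,
        regressing_edges=list(regressing),
    )
    return image, gt
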