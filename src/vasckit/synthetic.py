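"""Synthetic microscopy data with exact ground truth.

Stand-ins for the raw acquisitions of a vascularized hydrogel-construct
study: FRAP photobleach recovery stacks, dextran-leak time series, SEM-like
pore textures, bioprinted grid images, LIVE/DEAD nuclei fields and
endothelial network masks.  Each generator returns an
:class:`~vasckit.io.ImageStack` together with a :class:`GroundTruth` record
carrying the exact generating parameters, so every downstream analysis
stage can be benchmarked in closed form.

Design notes
------------
* All randomness flows from ``SynthSpec.seed`` via ``numpy``'s PCG64;
  identical specs produce bit-identical stacks.
* Frames are 16-bit grayscale with signal scaled to 80% of the dynamic
  range, leaving headroom for additive noise.
* FRAP ground truth comes from explicit finite-difference time stepping of
  the 2-D diffusion equation — an independent numerical route from the
  recovery-curve fitting that analyses it.  The stability bound
  ``dt <= dx^2/(4D)`` is enforced, never silently patched.
* Object placement (pores, nuclei) uses rejection sampling capped at 10^4
  attempts per object; an unplaceable object raises :class:`PackingError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.morphology import dilation, disk as disk_footprint

from .io import ImageStack

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "PackingError",
    "StabilityError",
    "generate",
    "generate_frap_stack",
    "generate_leak_series",
    "generate_pore_texture",
    "generate_grid_print",
    "generate_nuclei_field",
    "generate_network_mask",
    "make_random_tree",
    "make_star_vertices",
]

KINDS = ("frap", "leak", "pores", "grid", "nuclei", "network")

#: 16-bit output with signal at 80% of full scale.
FULL_SCALE = 65535
SIGNAL_SCALE = 0.8 * FULL_SCALE

MAX_PACKING_ATTEMPTS = 10_000


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place an object without overlap."""


class StabilityError(ValueError):
    """Raised when a requested diffusion time step violates the FTCS bound."""


@dataclass
class SynthSpec:
    """Recipe for one synthetic dataset.

    Parameters
    ----------
    kind
        One of ``frap, leak, pores, grid, nuclei, network``.
    seed
        Seed for all randomness; fixing it makes output byte-identical.
    pixel_size
        µm per pixel (> 0).
    shape
        Image shape (rows, cols), at least 32 x 32.
    frame_interval
        Seconds between frames, for time-series kinds.
    params
        Kind-specific parameters; see the individual generators.
    """

    kind: str
    seed: int
    pixel_size: float = 1.0
    shape: tuple[int, int] = (128, 128)
    frame_interval: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if tuple(self.shape) < (32, 32) or len(self.shape) != 2:
            raise ValueError(f"shape must be >= (32, 32), got {self.shape}")
        self.shape = (int(self.shape[0]), int(self.shape[1]))


@dataclass
class GroundTruth:
    """Exact generating parameters of a synthetic dataset."""

    kind: str
    data: dict

    def to_dict(self) -> dict:
        return {"kind": self.kind, "data": self.data}


def _rng(spec: SynthSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def _to_uint16(img: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """Quantize a float image (absolute counts) to uint16 with optional noise."""
    out = np.asarray(img, dtype=float)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(np.round(out), 0, FULL_SCALE).astype(np.uint16)


def generate(spec: SynthSpec) -> tuple[ImageStack, GroundTruth]:
    """Dispatch to the generator matching ``spec.kind``."""
    fn = {
        "frap": generate_frap_stack,
        "leak": generate_leak_series,
        "pores": generate_pore_texture,
        "grid": generate_grid_print,
        "nuclei": generate_nuclei_field,
        "network": generate_network_mask,
    }[spec.kind]
    return fn(spec)


# ---------------------------------------------------------------------------
# FRAP: photobleached disk recovering by 2-D diffusion
# ---------------------------------------------------------------------------

def generate_frap_stack(spec: SynthSpec) -> tuple[ImageStack, GroundTruth]:
    """Simulate recovery of a uniformly bleached disk in a uniform field.

    ``spec.params``:

    - ``D_true`` — diffusion coefficient, µm²/s (>= 0)
    - ``roi_radius`` — bleached-disk radius, µm
    - ``bleach_depth`` — fractional intensity drop in the disk, in (0, 1]
    - ``n_prebleach`` — number of pre-bleach frames (>= 1, default 2)
    - ``n_frames`` — total frames (default: covers ~10 characteristic times)
    - ``noise_sd`` — additive Gaussian noise, as a fraction of the signal
      amplitude (default 0)
    - ``dt`` — FTCS time step, s.  Optional; when omitted a stable step
      (0.4 x the bound, recorded in the ground truth) is used.  An explicit
      ``dt`` above the stability bound ``dx²/(4D)`` raises
      :class:`StabilityError` — it is never silently substepped.

    The field is simulated in normalized concentration (1 = pre-bleach), on
    the pixel grid, with Dirichlet value 1 at the image border (far field).
    """
    p = spec.params
    D = float(p["D_true"])
    r_um = float(p["roi_radius"])
    depth = float(p.get("bleach_depth", 0.9))
    n_pre = int(p.get("n_prebleach", 2))
    noise_sd = float(p.get("noise_sd", 0.0))
    if D < 0:
        raise ValueError("D_true must be >= 0")
    if not 0 < depth <= 1:
        raise ValueError("bleach_depth must be in (0, 1]")
    if n_pre < 1:
        raise ValueError("need at least one pre-bleach frame")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    dx = spec.pixel_size
    dt_frame = spec.frame_interval if spec.frame_interval else 0.5

    if D > 0:
        dt_bound = dx * dx / (4.0 * D)
        dt = float(p.get("dt", 0.4 * dt_bound))
        if dt > dt_bound * (1 + 1e-12):
            raise StabilityError(
                f"FTCS time step dt={dt:g} s exceeds the stability bound "
                f"dx^2/(4 D) = {dt_bound:g} s; choose a smaller dt "
                "(the generator does not substep on your behalf)"
            )
        substeps = max(1, int(math.ceil(dt_frame / dt)))
        dt = dt_frame / substeps
    else:
        substeps, dt = 0, 0.0

    if "n_frames" not in p:
        t_total = 10.0 * r_um**2 / (4.0 * D) if D > 0 else 10 * dt_frame
        n_post = int(math.ceil(t_total / dt_frame)) + 1
    else:
        n_post = int(p["n_frames"]) - n_pre
    if n_post < 2:
        raise ValueError("need at least two post-bleach frames")

    rows, cols = spec.shape
    yy, xx = np.indices((rows, cols))
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    disk_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r_um / dx) ** 2

    c = np.ones((rows, cols))
    c[disk_mask] = 1.0 - depth
    alpha = D * dt / dx**2 if D > 0 else 0.0

    frames = [np.ones((rows, cols)) for _ in range(n_pre)]
    frames.append(c.copy())
    for _ in range(n_post - 1):
        for _ in range(substeps):
            lap = (
                np.roll(c, 1, 0) + np.roll(c, -1, 0)
                + np.roll(c, 1, 1) + np.roll(c, -1, 1) - 4 * c
            )
            c = c + alpha * lap
            c[0, :] = c[-1, :] = c[:, 0] = c[:, -1] = 1.0
        frames.append(c.copy())

    rng = _rng(spec)
    raw = np.stack(frames) * SIGNAL_SCALE
    stack = ImageStack(
        frames=_to_uint16(raw, rng, noise_sd * SIGNAL_SCALE),
        pixel_size=dx,
        frame_interval=dt_frame,
    )
    truth = GroundTruth(
        "frap",
        {
            "D_true": D,
            "roi_radius_um": r_um,
            "roi_center_px": (cy, cx),
            "bleach_depth": depth,
            "bleach_frame": n_pre,
            "dt_used_s": dt,
            "noise_sd": noise_sd,
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Dextran leak series: bright channel band, flanking intensity ramp
# ---------------------------------------------------------------------------

def generate_leak_series(spec: SynthSpec) -> tuple[ImageStack, GroundTruth]:
    """Simulate a tracer-leak acquisition around a perfused channel.

    ``spec.params``:

    - ``channel_diameter`` — d, µm
    - ``I0`` — flanking-ROI intensity at the first post-perfusion frame (counts)
    - ``Ib`` — background intensity before perfusion (counts); must be < I0
    - ``slope`` — k, counts/s, linear accrual of the flanking mean
    - ``duration`` — acquisition length after perfusion starts, s
    - ``noise_sd`` — additive Gaussian noise, counts (default 0)

    Frame 0 is the pre-perfusion background frame (everything at ``Ib``);
    frames 1..N show a vertical bright channel band of diameter d with
    flanking regions ramping as I(t) = I0 + k t, t = 0 at frame 1.

    The ground-truth permeability follows the tracer-leak relation
    P = (It - I0) / (t (I0 - Ib)) * d/4 with d in cm, i.e. for a linear
    ramp P_true = k / (I0 - Ib) * d_cm / 4.
    """
    p = spec.params
    d_um = float(p["channel_diameter"])
    I0 = float(p["I0"])
    Ib = float(p["Ib"])
    k = float(p["slope"])
    duration = float(p.get("duration", 30 * 60.0))
    noise_sd = float(p.get("noise_sd", 0.0))
    dt_frame = spec.frame_interval if spec.frame_interval else 30.0
    if I0 <= Ib:
        raise ValueError(
            f"I0 ({I0}) must exceed background Ib ({Ib}): permeability is "
            "undefined for a non-positive normalizer I0 - Ib"
        )
    rows, cols = spec.shape
    half_w_px = d_um / spec.pixel_size / 2.0
    c0 = (cols - 1) / 2.0
    xx = np.arange(cols)
    channel = np.abs(xx - c0) <= half_w_px
    if not channel.any() or channel.all():
        raise ValueError("channel band must be inside the image")
    channel_intensity = float(p.get("channel_intensity", min(2.5 * I0, SIGNAL_SCALE)))

    n_post = int(math.floor(duration / dt_frame)) + 1
    frames = np.empty((1 + n_post, rows, cols))
    frames[0] = Ib
    for i in range(n_post):
        t = i * dt_frame
        frame = np.full((rows, cols), I0 + k * t)
        frame[:, channel] = channel_intensity
        frames[1 + i] = frame

    d_cm = d_um * 1e-4
    P_true = k / (I0 - Ib) * d_cm / 4.0
    rng = _rng(spec)
    stack = ImageStack(
        frames=_to_uint16(frames, rng, noise_sd),
        pixel_size=spec.pixel_size,
        frame_interval=dt_frame,
    )
    truth = GroundTruth(
        "leak",
        {
            "P_true_cm_per_s": P_true,
            "channel_diameter_um": d_um,
            "I0": I0,
            "Ib": Ib,
            "slope_per_s": k,
            "channel_center_col": c0,
            "channel_halfwidth_px": half_w_px,
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Pore texture: dark disks on a bright background
# ---------------------------------------------------------------------------

def generate_pore_texture(spec: SynthSpec) -> tuple[ImageStack, GroundTruth]:
    """SEM-like binary pore texture: non-overlapping dark disks.

    ``spec.params``: either an explicit ``radii`` list (µm) with optional
    ``centers`` (px), or ``n_disks`` with ``r_min``/``r_max`` (µm, uniform).
    ``noise_sd`` (counts) makes the histogram bimodal rather than binary.

    Ground truth carries the exact radii and the analytic areal porosity
    (sum of disk areas / image area).
    """
    p = spec.params
    rng = _rng(spec)
    rows, cols = spec.shape
    px = spec.pixel_size
    noise_sd = float(p.get("noise_sd", 0.0))

    if "radii" in p:
        radii_um = [float(r) for r in p["radii"]]
    else:
        n = int(p["n_disks"])
        radii_um = list(rng.uniform(float(p["r_min"]), float(p["r_max"]), size=n))
    radii_px = [r / px for r in radii_um]
    # place large disks first: improves packing determinism and success
    order = np.argsort(radii_px)[::-1]

    centers = p.get("centers")
    placed: list[tuple[float, float, float]] = []  # (cy, cx, r_px)
    if centers is not None:
        for (cy, cx), r in zip(centers, radii_px):
            placed.append((float(cy), float(cx), r))
    else:
        for idx in order:
            r = radii_px[idx]
            ok = False
            for _ in range(MAX_PACKING_ATTEMPTS):
                cy = rng.uniform(r + 1, rows - r - 1)
                cx = rng.uniform(r + 1, cols - r - 1)
                if all(
                    (cy - oy) ** 2 + (cx - ox) ** 2 > (r + orr) ** 2
                    for oy, ox, orr in placed
                ):
                    placed.append((cy, cx, r))
                    ok = True
                    break
            if not ok:
                raise PackingError(
                    f"could not place disk of radius {r:.1f} px without overlap "
                    f"after {MAX_PACKING_ATTEMPTS} attempts "
                    f"({len(placed)}/{len(radii_px)} placed)"
                )
        # restore original radius order in the truth record
        placed = [placed[list(order).index(i)] for i in range(len(radii_px))]

    img = np.full((rows, cols), 0.8 * SIGNAL_SCALE)
    for cy, cx, r in placed:
        rr, cc = draw_disk((cy, cx), r, shape=(rows, cols))
        img[rr, cc] = 0.2 * SIGNAL_SCALE

    porosity = sum(math.pi * r * r for r in radii_um) / (rows * px * cols * px)
    stack = ImageStack(
        frames=_to_uint16(img[None], rng, noise_sd), pixel_size=px
    )
    truth = GroundTruth(
        "pores",
        {
            "radii_um": radii_um,
            "centers_px": [(cy, cx) for cy, cx, _ in placed],
            "porosity": porosity,
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Printed grid: 3x3 enclosed pores in a bright ink block
# ---------------------------------------------------------------------------

def make_star_vertices(
    center: tuple[float, float], r_outer: float, r_inner: float, n_points: int = 6
) -> np.ndarray:
    """Vertices (row, col) of an ``n_points``-pointed star polygon."""
    angles = np.arange(2 * n_points) * math.pi / n_points
    radii = np.where(np.arange(2 * n_points) % 2 == 0, r_outer, r_inner)
    rr = center[0] + radii * np.sin(angles)
    cc = center[1] + radii * np.cos(angles)
    return np.column_stack([rr, cc])


def _polygon_perimeter_area(verts: np.ndarray) -> tuple[float, float]:
    closed = np.vstack([verts, verts[:1]])
    d = np.diff(closed, axis=0)
    perim = float(np.sum(np.hypot(d[:, 0], d[:, 1])))
    x, y = closed[:, 1], closed[:, 0]
    area = 0.5 * abs(float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])))
    return perim, area


def generate_grid_print(spec: SynthSpec) -> tuple[ImageStack, GroundTruth]:
    """Binary image of a printed 3x3 grid with enclosed pores.

    ``spec.params``:

    - ``pore_shape`` — ``square``, ``circle`` or ``star``
    - ``pore_size`` — pore extent, µm (square side / circle diameter /
      star outer diameter); must be >= 4 px
    - ``wall_thickness`` — printed wall width, µm
    - ``noise_sd`` — counts (default 0)

    Ground truth lists each pore's analytic perimeter and area in pixel
    units and the implied printability Pr = p²/(16 A): 1 for squares,
    π/4 for circles, > 1 for stars.
    """
    p = spec.params
    shape_name = p.get("pore_shape", "square")
    if shape_name not in ("square", "circle", "star"):
        raise ValueError(f"pore_shape must be square|circle|star, got {shape_name!r}")
    px = spec.pixel_size
    size_px = float(p["pore_size"]) / px
    wall_px = float(p.get("wall_thickness", 4 * px)) / px
    noise_sd = float(p.get("noise_sd", 0.0))
    if size_px < 4:
        raise ValueError(
            f"pore size of {size_px:.1f} px is below 4 px; perimeter "
            "estimation is meaningless at that scale"
        )
    n_grid = 3
    cell = size_px + wall_px
    block = n_grid * cell + wall_px
    rows, cols = spec.shape
    if block + 2 > min(rows, cols):
        raise ValueError(
            f"3x3 grid needs {block:.0f} px plus margin; image is {spec.shape}"
        )
    r0 = (rows - block) / 2.0
    c0 = (cols - block) / 2.0

    img = np.zeros((rows, cols))
    rr0, rr1 = int(round(r0)), int(round(r0 + block))
    cc0, cc1 = int(round(c0)), int(round(c0 + block))
    img[rr0:rr1, cc0:cc1] = 0.8 * SIGNAL_SCALE

    pores = []
    for i in range(n_grid):
        for j in range(n_grid):
            top = int(round(r0 + wall_px + i * cell))
            left = int(round(c0 + wall_px + j * cell))
            s = int(round(size_px))
            cy, cx = top + (s - 1) / 2.0, left + (s - 1) / 2.0
            if shape_name == "square":
                img[top : top + s, left : left + s] = 0.0
                perim, area = 4.0 * s, float(s * s)
            elif shape_name == "circle":
                r = s / 2.0
                rr, cc = draw_disk((cy, cx), r, shape=(rows, cols))
                img[rr, cc] = 0.0
                perim, area = 2 * math.pi * r, math.pi * r * r
            else:  # star
                verts = make_star_vertices((cy, cx), s / 2.0, s / 4.8)
                rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=(rows, cols))
                img[rr, cc] = 0.0
                perim, area = _polygon_perimeter_area(verts)
            pores.append(
                {
                    "perimeter_px": perim,
                    "area_px2": area,
                    "Pr": perim * perim / (16.0 * area),
                }
            )

    rng = _rng(spec)
    stack = ImageStack(frames=_to_uint16(img[None], rng, noise_sd), pixel_size=px)
    truth = GroundTruth(
        "grid",
        {
            "pore_shape": shape_name,
            "pores": pores,
            "mean_Pr": float(np.mean([q["Pr"] for q in pores])),
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Nuclei field: live / dead / all-nuclei Gaussian blobs
# ---------------------------------------------------------------------------

def generate_nuclei_field(spec: SynthSpec) -> tuple[ImageStack, GroundTruth]:
    """Three-channel (live, dead, nuclei) field of Gaussian blobs.

    ``spec.params``: ``n_live``, ``n_dead``, ``blob_radius`` (µm, default 4),
    ``min_separation`` (µm, default 4 x blob radius), ``noise_sd`` (counts).

    The all-nuclei channel contains every blob.  Ground truth carries the
    counts and the viability fraction n_live / (n_live + n_dead); an empty
    field is flagged and viability set to ``None``.
    """
    p = spec.params
    n_live = int(p["n_live"])
    n_dead = int(p["n_dead"])
    if n_live < 0 or n_dead < 0:
        raise ValueError("counts must be >= 0")
    px = spec.pixel_size
    blob_r = float(p.get("blob_radius", 4.0)) / px
    min_sep = float(p.get("min_separation", 4 * blob_r * px)) / px
    noise_sd = float(p.get("noise_sd", 0.0))
    rows, cols = spec.shape
    rng = _rng(spec)

    margin = 3 * blob_r + 1
    positions: list[tuple[float, float]] = []
    for _ in range(n_live + n_dead):
        ok = False
        for _ in range(MAX_PACKING_ATTEMPTS):
            cy = rng.uniform(margin, rows - margin)
            cx = rng.uniform(margin, cols - margin)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 >= min_sep**2 for oy, ox in positions
            ):
                positions.append((cy, cx))
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place nucleus {len(positions) + 1}/"
                f"{n_live + n_dead} with separation {min_sep:.1f} px"
            )
    live_pos = positions[:n_live]
    dead_pos = positions[n_live:]

    yy, xx = np.indices((rows, cols))

    def render(pos: list[tuple[float, float]]) -> np.ndarray:
        img = np.zeros((rows, cols))
        sigma = blob_r / 2.0
        for cy, cx in pos:
            img += np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
        return np.clip(img, 0, 1) * SIGNAL_SCALE

    frames = np.stack([render(live_pos), render(dead_pos), render(positions)])
    stack = ImageStack(
        frames=_to_uint16(frames, rng, noise_sd),
        pixel_size=px,
        channel_names=("live", "dead", "nuclei"),
    )
    empty = (n_live + n_dead) == 0
    truth = GroundTruth(
        "nuclei",
        {
            "n_live": n_live,
            "n_dead": n_dead,
            "viability": None if empty else n_live / (n_live + n_dead),
            "empty_field": empty,
            "blob_radius_px": blob_r,
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Network mask: rasterized planar graph
# ---------------------------------------------------------------------------

def make_random_tree(
    seed: int,
    n_edges: int = 20,
    extent_um: float = 500.0,
    min_edge_um: float = 40.0,
    clearance_um: float = 12.0,
    min_sibling_angle_deg: float = 35.0,
) -> dict:
    """Random planar tree (vertices in µm) for :func:`generate_network_mask`.

    Grown by attaching each new vertex to a uniformly chosen existing
    vertex at a random angle.  Candidate edges are rejected when they come
    within ``clearance_um`` of any non-adjacent existing edge or leave less
    than ``min_sibling_angle_deg`` to a sibling edge at the shared vertex —
    this keeps the drawn embedding planar and overlap-free, so the
    rasterized mask has exactly the tree's topology (zero meshes).
    """
    from shapely.geometry import LineString, Point

    rng = np.random.default_rng(seed)
    verts = [(extent_um / 2, extent_um / 2)]
    edges: list[tuple[int, int]] = []
    segments: list[LineString] = []
    attempts = 0
    while len(edges) < n_edges:
        attempts += 1
        if attempts > MAX_PACKING_ATTEMPTS:
            raise PackingError(
                f"could not grow a non-crossing tree with {n_edges} edges "
                f"in a {extent_um} µm field"
            )
        parent = int(rng.integers(len(verts)))
        ang = rng.uniform(0, 2 * math.pi)
        length = rng.uniform(min_edge_um, 2.5 * min_edge_um)
        py, pxc = verts[parent]
        ny, nx = py + length * math.sin(ang), pxc + length * math.cos(ang)
        if not (0 < ny < extent_um and 0 < nx < extent_um):
            continue
        # angular separation from sibling edges at the shared vertex
        ok = True
        for a, b in edges:
            if parent in (a, b):
                other = verts[b] if a == parent else verts[a]
                sib_ang = math.atan2(other[0] - py, other[1] - pxc)
                diff = abs((ang - sib_ang + math.pi) % (2 * math.pi) - math.pi)
                if diff < math.radians(min_sibling_angle_deg):
                    ok = False
                    break
        if not ok:
            continue
        cand = LineString([(pxc, py), (nx, ny)])
        pshape = Point(pxc, py)
        for (a, b), seg in zip(edges, segments):
            if parent in (a, b):
                # adjacent edge: measure clearance away from the shared vertex
                if cand.distance(seg) == 0 and not seg.touches(cand):
                    ok = False
                    break
                continue
            if cand.distance(seg) < clearance_um:
                ok = False
                break
        if not ok:
            continue
        # also keep the new endpoint clear of every existing vertex
        if any(
            math.hypot(vy - ny, vx - nx) < clearance_um
            for vy, vx in verts
        ):
            continue
        verts.append((ny, nx))
        edges.append((parent, len(verts) - 1))
        segments.append(cand)
    return {"vertices": verts, "edges": edges}


def generate_network_mask(spec: SynthSpec) -> tuple[ImageStack, GroundTruth]:
    """Rasterize a planar graph into a binary endothelial-network mask.

    ``spec.params``:

    - ``graph`` — ``{"vertices": [(y_um, x_um), ...], "edges": [(i, j), ...]}``
    - ``stroke_width`` — drawn line width, px (default 3)

    Ground truth carries the summed Euclidean edge length (µm) and the
    circuit rank (edges - vertices + connected components) of the graph,
    i.e. the number of independent closed meshes.
    """
    import networkx as nx

    p = spec.params
    graph = p["graph"]
    stroke = int(p.get("stroke_width", 3))
    noise_sd = float(p.get("noise_sd", 0.0))
    px = spec.pixel_size
    verts = [(float(y), float(x)) for y, x in graph["vertices"]]
    edges = [(int(a), int(b)) for a, b in graph["edges"]]

    total_len = 0.0
    for a, b in edges:
        ya, xa = verts[a]
        yb, xb = verts[b]
        length = math.hypot(yb - ya, xb - xa)
        if length < 2 * stroke * px:
            raise ValueError(
                f"edge ({a},{b}) of length {length:.1f} µm is shorter than "
                f"2 x stroke width ({2 * stroke * px:.1f} µm); its skeleton "
                "would be unrecoverable"
            )
        total_len += length

    g = nx.Graph()
    g.add_nodes_from(range(len(verts)))
    g.add_edges_from(edges)
    cycles = g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)

    rows, cols = spec.shape
    mask = np.zeros((rows, cols), dtype=bool)
    for a, b in edges:
        ya, xa = (int(round(v / px)) for v in verts[a])
        yb, xb = (int(round(v / px)) for v in verts[b])
        for v in (ya, xa, yb, xb):
            if not (0 <= v < max(rows, cols)):
                raise ValueError("graph vertices must lie inside the image")
        rr, cc = draw_line(ya, xa, yb, xb)
        keep = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        mask[rr[keep], cc[keep]] = True
    if stroke > 1:
        mask = dilation(mask, disk_footprint(stroke // 2))

    rng = _rng(spec)
    img = mask.astype(float) * SIGNAL_SCALE
    stack = ImageStack(frames=_to_uint16(img[None], rng, noise_sd), pixel_size=px)
    truth = GroundTruth(
        "network",
        {
            "total_length_um": total_len,
            "cycle_count": int(cycles),
            "n_vertices": len(verts),
            "n_edges": len(edges),
            "stroke_width_px": stroke,
        },
    )
    return stack, truth
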