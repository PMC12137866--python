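"""Synthetic specimen maps for charge-artefact simulation.

A phantom emulates the surface of a vitrified, inhomogeneous biological sample
as seen by a low-kV SEM probe: a per-pixel secondary-electron yield (the
contrast source), a per-pixel charge-leak time constant (how quickly deposited
charge drains to ground — lipid-rich organelles drain poorly and act as local
charging centres), and an integer ground-truth label map for segmentation
benchmarks.

Material constants here are calibration values, not measured properties: the
literature establishes *which* structures charge (lipid droplets, membrane
stacks, degradative compartments), not their resistivities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.draw import disk as draw_disk, line_aa

__all__ = ["Phantom", "make_phantom", "phantom_ground_truth", "save_phantom", "load_phantom"]

PRESETS = ("homogeneous", "cell", "myelin", "flyback_test")

# calibration defaults shared by the presets
DEFAULTS = {
    "yield_background": 0.5,
    "grain_std": 0.05,
    "grain_sigma_px": 2.0,
    "tau_background_ns": 1.5e3,
    "disc_yield": 0.85,
    "tau_disc_factor": 100.0,
    "membrane_yield": 0.7,
    "tau_membrane_factor": 20.0,
    # poorly grounded background patches (vitreous ice islands with bad
    # contact to the support): smooth blobs of strongly retarded leak
    "tau_patch_factor": 333.0,
    "patch_threshold": 0.8,     # standard-normal threshold -> ~20% area
    "patch_corr_px": 12.0,
    "dark_yield": 0.15,
    "n_dark": None,           # None -> scaled with grid, >= 2
    "n_discs": None,          # None -> scaled with grid, >= 3
    "n_membranes": None,      # None -> scaled with grid, >= 5
    "flyback_width": 64,
    "pixel_nm": 6.34,
}


@dataclass
class Phantom:
    """Per-pixel specimen description on an ``ny`` x ``nx`` grid."""

    nx: int
    ny: int
    yield_map: np.ndarray
    tau_map: np.ndarray
    label_map: np.ndarray
    pixel_nm: float
    seed: int
    preset: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (self.ny, self.nx)
        for name in ("yield_map", "tau_map", "label_map"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")
        if self.yield_map.min() < 0 or self.yield_map.max() > 1:
            raise ValueError("yield_map must lie in [0, 1]")
        if not (self.tau_map > 0).all():
            raise ValueError("tau_map must be positive")
        if (self.label_map < 0).any():
            raise ValueError("label_map must be non-negative")


def phantom_ground_truth(phantom: Phantom) -> np.ndarray:
    """Copy of the ground-truth label mask (0 = background) for segmentation scoring."""
    return phantom.label_map.copy()


def _textured_background(rng: np.random.Generator, ny: int, nx: int,
                         base: float, std: float, sigma: float) -> np.ndarray:
    grain = gaussian_filter(rng.standard_normal((ny, nx)), sigma)
    s = grain.std()
    if s > 0:
        grain *= std / s
    return np.clip(base + grain, 0.0, 1.0)


def _place_discs(rng: np.random.Generator, ny: int, nx: int, n: int,
                 rmin: float, rmax: float, margin: float = 2.0,
                 max_tries: int = 5000) -> list[tuple[int, int, int]]:
    """Rejection-sample n non-overlapping discs; (cy, cx, r) list."""
    placed: list[tuple[int, int, int]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(f"grid {nx}x{ny} too small to place {n} discs of radius "
                             f"{rmin:.0f}-{rmax:.0f}")
        r = int(rng.uniform(rmin, rmax))
        cy = int(rng.uniform(r + margin, ny - r - margin))
        cx = int(rng.uniform(r + margin, nx - r - margin))
        if all((cy - py) ** 2 + (cx - px) ** 2 > (r + pr + margin) ** 2
               for py, px, pr in placed):
            placed.append((cy, cx, r))
    return placed


def _draw_membrane(rng: np.random.Generator, ny: int, nx: int) -> np.ndarray:
    """Anti-aliased 1-2 px curvilinear feature as a [0,1] weight image."""
    w = np.zeros((ny, nx), dtype=np.float64)
    # quadratic Bezier between two random border-ish points with a wild control point
    p0 = np.array([rng.uniform(0, ny - 1), rng.uniform(0, nx - 1)])
    p2 = np.array([rng.uniform(0, ny - 1), rng.uniform(0, nx - 1)])
    p1 = np.array([rng.uniform(-0.3 * ny, 1.3 * ny), rng.uniform(-0.3 * nx, 1.3 * nx)])
    t = np.linspace(0, 1, 4 * max(nx, ny))
    pts = ((1 - t)[:, None] ** 2 * p0 + 2 * (t * (1 - t))[:, None] * p1 + (t[:, None] ** 2) * p2)
    pts = np.clip(pts, 0, [ny - 1, nx - 1]).astype(int)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        if (r0, c0) == (r1, c1):
            continue
        rr, cc, val = line_aa(r0, c0, r1, c1)
        np.maximum.at(w, (rr, cc), val)
    return w


def _cell_phantom(rng: np.random.Generator, nx: int, ny: int, p: dict):
    ymap = _textured_background(rng, ny, nx, p["yield_background"], p["grain_std"],
                                p["grain_sigma_px"])
    tau = np.full((ny, nx), p["tau_background_ns"], dtype=np.float64)
    labels = np.zeros((ny, nx), dtype=np.int32)

    # heterogeneous grounding: smooth patches where charge drains poorly
    if p["tau_patch_factor"] > 1:
        z = gaussian_filter(rng.standard_normal((ny, nx)), p["patch_corr_px"])
        z /= max(z.std(), 1e-12)
        # smoothstep: exactly the background value outside patches
        w = np.clip((z - p["patch_threshold"]) / 0.5, 0.0, 1.0)
        w = w * w * (3.0 - 2.0 * w)
        tau *= 1.0 + (p["tau_patch_factor"] - 1.0) * w

    n_discs = p["n_discs"] or max(3, nx // 85)
    n_dark = p["n_dark"] or max(2, nx // 85)
    n_mem = p["n_membranes"] or max(5, nx // 50)
    rmin, rmax = max(4, nx / 24), max(6, nx / 12)
    next_label = 1
    placed = _place_discs(rng, ny, nx, n_discs + n_dark, rmin, rmax)
    for cy, cx, r in placed[:n_discs]:
        rr, cc = draw_disk((cy, cx), r, shape=(ny, nx))
        ymap[rr, cc] = p["disc_yield"]
        tau[rr, cc] = p["tau_background_ns"] * p["tau_disc_factor"]
        labels[rr, cc] = next_label
        next_label += 1
    # electron-dense compartments: the dark end of the clean intensity range
    for cy, cx, r in placed[n_discs:]:
        rr, cc = draw_disk((cy, cx), r, shape=(ny, nx))
        ymap[rr, cc] = p["dark_yield"]
        labels[rr, cc] = next_label
        next_label += 1
    # a couple of near-black fissures and a few bright contamination specks:
    # negligible area, but they pin both ends of the intensity range
    # symmetrically about the 0.5 background, so the 8-bit conversion scale
    # is the same whatever an acquisition's charging or noise statistics
    for _ in range(1):
        w = _draw_membrane(rng, ny, nx)
        on = (w > 0.5) & (labels == 0)
        ymap[on] = 0.02
        labels[on] = next_label
        next_label += 1
    for _ in range(36):
        sy = rng.integers(3, ny - 6)
        sx = rng.integers(3, nx - 6)
        if (labels[sy:sy + 3, sx:sx + 3] == 0).all():
            ymap[sy:sy + 3, sx:sx + 3] = 0.98
            labels[sy:sy + 3, sx:sx + 3] = next_label
            next_label += 1
    for k in range(n_mem):
        w = _draw_membrane(rng, ny, nx)
        on = w > 0
        free = on & (labels == 0)
        # membranes image bright or dark depending on composition and local
        # orientation; alternating keeps the clean histogram centred
        y_mem = p["membrane_yield"] if k % 2 == 0 else 1.0 - p["membrane_yield"]
        ymap[free] = (1 - w[free]) * ymap[free] + w[free] * y_mem
        tau[free & (w > 0.3)] = p["tau_background_ns"] * p["tau_membrane_factor"]
        labels[free & (w > 0.3)] = next_label
        next_label += 1
    return np.clip(ymap, 0, 1), tau, labels


def _myelin_phantom(rng: np.random.Generator, nx: int, ny: int, p: dict):
    ymap = _textured_background(rng, ny, nx, p["yield_background"], p["grain_std"],
                                p["grain_sigma_px"])
    tau = np.full((ny, nx), p["tau_background_ns"], dtype=np.float64)
    labels = np.zeros((ny, nx), dtype=np.int32)

    n_stacks = max(2, nx // 100)
    rmax = max(10, nx / 6)
    next_label = 1
    yy, xx = np.mgrid[0:ny, 0:nx]
    for cy, cx, r in _place_discs(rng, ny, nx, n_stacks, rmax * 0.7, rmax, margin=4):
        dist = np.hypot(yy - cy, xx - cx)
        sheath = (dist <= r) & (dist >= 0.45 * r)
        period = max(3.0, r / 8)
        rings = ((dist - 0.45 * r) // period).astype(int) % 2
        ymap[sheath] = np.where(rings[sheath] == 0, 0.4, 0.8)
        tau[sheath] = p["tau_background_ns"] * p["tau_disc_factor"]
        labels[sheath] = next_label
        next_label += 1
        # interior organelle disc (axoplasm + mitochondrion-like blob)
        rr, cc = draw_disk((cy, cx), max(2, int(0.2 * r)), shape=(ny, nx))
        ymap[rr, cc] = 0.6
        labels[rr, cc] = next_label
        next_label += 1
    return np.clip(ymap, 0, 1), tau, labels


def _flyback_phantom(rng: np.random.Generator, nx: int, ny: int, p: dict):
    """Frame-like map whose left band of width w carries a decaying settling warp.

    The reference is a weak, smooth texture.  In the band the probe is still
    settling: columns are displaced by a damped horizontal oscillation, and the
    accompanying probe-velocity error modulates the effective dwell, imprinting
    high-contrast vertical ripples that decay smoothly to zero at ``w``.
    Columns ``>= w`` equal the unwarped reference exactly.
    """
    w = int(p["flyback_width"])
    if w < 0 or w >= nx:
        raise ValueError("flyback width must satisfy 0 <= w < nx")
    ref = _textured_background(rng, ny, nx, p["yield_background"],
                               0.02, 6.0)
    ymap = ref.copy()
    if w > 0:
        x = np.arange(w, dtype=np.float64)
        # settling oscillation: amplitude decays smoothly across the band and
        # its phase advances from line to line (the line start settles a
        # little differently each row), giving oblique ripples that carry
        # gradients in both axes right up to column w
        env = 1.0 - 0.1 * (x / w)
        lam = 40.0                                     # ripple wavelength, survives sigma=7 blur
        lam_y = 64.0
        arg = 2 * np.pi * ((x[None, :] - w) / lam
                           + np.arange(ny, dtype=np.float64)[:, None] / lam_y)
        s = 4.0 * np.sin(arg) * env[None, :]           # per-line column displacement (px)
        ds = np.gradient(s, axis=1)
        vel = np.clip(1.0 - 2.5 * ds, 0.25, 1.75)      # dwell/velocity error factor
        yy = np.repeat(np.arange(ny, dtype=np.float64)[:, None], w, axis=1)
        xsrc = np.clip(x[None, :] - s, 0, nx - 1)
        warped = map_coordinates(ref, [yy, xsrc], order=1, mode="nearest")
        # the estimator's Gaussian blur erodes a one-sided texture edge by
        # about half its sigma, so the intensity imprint gains contrast toward
        # the band edge (the displacement itself still decays): the apparent
        # extent under the reference sigma=7 then matches the planted width
        cenv = 0.22 * (1.0 + 0.8 * (x / w) ** 2)
        band = p["yield_background"] + (warped - p["yield_background"]) \
            - (vel - 1.0) * cenv[None, :]
        ymap[:, :w] = np.clip(band, 0, 1)
    tau = np.full((ny, nx), p["tau_background_ns"], dtype=np.float64)
    labels = np.zeros((ny, nx), dtype=np.int32)
    labels[:, :w] = 1
    return ymap, tau, labels


def make_phantom(preset: str, nx: int = 256, ny: int = 256, seed: int = 0,
                 overrides: dict | None = None) -> Phantom:
    """Build a synthetic specimen map.

    Presets
    -------
    homogeneous
        Constant yield 0.5 and constant leak time; no structures.
    cell
        Textured cytoplasm-like background (yield 0.5 +/- 0.05 grain) with at
        least 3 non-overlapping lipid-droplet discs (yield 0.85, leak time
        100x background) and at least 5 thin membranes (yield 0.7).
    myelin
        Concentric annulus stacks of alternating yield 0.4/0.8 (myelin
        sheaths, poorly draining) with interior organelle discs.
    flyback_test
        Fixture for the flyback-extent estimator: left band of configurable
        width (override ``flyback_width``) distorted by a smooth decaying
        horizontal warp; the rest equals the unwarped reference.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if nx < 32 or ny < 32:
        raise ValueError("grid must be at least 32x32")
    p = dict(DEFAULTS)
    p.update(overrides or {})
    rng = np.random.default_rng(seed)

    if preset == "homogeneous":
        ymap = np.full((ny, nx), p["yield_background"], dtype=np.float64)
        tau = np.full((ny, nx), p["tau_background_ns"], dtype=np.float64)
        labels = np.zeros((ny, nx), dtype=np.int32)
    elif preset == "cell":
        ymap, tau, labels = _cell_phantom(rng, nx, ny, p)
    elif preset == "myelin":
        ymap, tau, labels = _myelin_phantom(rng, nx, ny, p)
    else:
        ymap, tau, labels = _flyback_phantom(rng, nx, ny, p)

    return Phantom(nx=nx, ny=ny, yield_map=ymap, tau_map=tau, label_map=labels,
                   pixel_nm=float(p["pixel_nm"]), seed=seed, preset=preset,
                   meta={"overrides": dict(overrides or {})})


def save_phantom(phantom: Phantom, path: str | Path) -> Path:
    """Write yield/tau/label as a 3-page float32 TIFF plus a JSON side-car."""
    import tifffile

    path = Path(path)
    pages = np.stack([phantom.yield_map.astype(np.float32),
                      phantom.tau_map.astype(np.float32),
                      phantom.label_map.astype(np.float32)])
    tifffile.imwrite(path, pages, photometric="minisblack")
    side = {"nx": phantom.nx, "ny": phantom.ny, "pixel_nm": phantom.pixel_nm,
            "seed": phantom.seed, "preset": phantom.preset, "meta": phantom.meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=1))
    return path


def load_phantom(path: str | Path) -> Phantom:
    import tifffile

    path = Path(path)
    pages = tifffile.imread(path)
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Phantom(nx=side["nx"], ny=side["ny"],
                   yield_map=pages[0].astype(np.float64),
                   tau_map=pages[1].astype(np.float64),
                   label_map=pages[2].astype(np.int32),
                   pixel_nm=side["pixel_nm"], seed=side["seed"],
                   preset=side["preset"], meta=side.get("meta", {}))
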