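"""Timed scan-pattern generation for raster and interleaved (leapfrog) SEM imaging.

A scan pattern is an ordered, time-stamped sequence of probe visits over an
``nx`` x ``ny`` pixel grid.  Raster scanning visits pixels row by row, x fastest;
the probe returns to neighbouring pixels after only one dwell time (in x) or one
line time (in y), so charge deposited at a pixel has little time to dissipate
before its neighbours are irradiated.  Interleaved scanning visits a sub-lattice
of stride ``skip + 1`` per pass and then the remaining offsets, which lengthens
the revisit interval between spatial neighbours by orders of magnitude.

Times are integer nanoseconds from the start of the acquisition.  Coordinates
are 0-based, origin top-left, x = column (fast axis), y = row (slow axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.constants import elementary_charge

__all__ = [
    "ScanPattern",
    "FluenceSpec",
    "VisitBlock",
    "PatternValidation",
    "make_raster_pattern",
    "make_interleaved_pattern",
    "validate_pattern",
    "min_neighbour_interval",
    "export_pattern_text",
    "import_pattern_text",
    "compute_fluence",
]

MODES = ("raster", "interleaved")
INTEGRATIONS = ("line", "frame")


@dataclass(frozen=True)
class VisitBlock:
    """A run of consecutive visits sharing one row and a uniform x stride.

    Visit ``k`` of the block is at column ``x0 + k*dx``, row ``y``, starting at
    time ``t0_ns + k*dwell_ns``.  Blocks are the unit at which the charge
    simulator batches dissipation updates.
    """

    x0: int
    dx: int
    m: int
    y: int
    t0_ns: int
    frame: int

    @property
    def xs(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.m)


@dataclass
class ScanPattern:
    """Ordered, timed sequence of probe visits plus integration metadata.

    ``reps`` is the repetition count R: for frame integration the full frame is
    scanned R times; for line integration each line is repeated R times
    consecutively before the slow axis advances.
    """

    nx: int
    ny: int
    dwell_ns: int
    reps: int
    mode: str
    integration: str
    skip_x: int = 0
    skip_y: int = 0
    flyback_delay_ns: int = 0
    interframe_pause_ns: int = 0
    blocks: list[VisitBlock] = field(default_factory=list, repr=False)

    @property
    def n_visits(self) -> int:
        return sum(b.m for b in self.blocks)

    @property
    def visits(self) -> np.ndarray:
        """Materialize the full visit list as an (N, 3) int64 array (x, y, t_ns)."""
        out = np.empty((self.n_visits, 3), dtype=np.int64)
        i = 0
        for b in self.blocks:
            k = np.arange(b.m, dtype=np.int64)
            out[i : i + b.m, 0] = b.x0 + b.dx * k
            out[i : i + b.m, 1] = b.y
            out[i : i + b.m, 2] = b.t0_ns + self.dwell_ns * k
            i += b.m
        return out

    def iter_blocks(self) -> Iterator[VisitBlock]:
        return iter(self.blocks)

    @property
    def n_frames(self) -> int:
        """Number of output frames (repetitions for frame integration, 1 for line)."""
        return self.reps if self.integration == "frame" else 1

    def frame_time_ns(self) -> int:
        """Duration of one repetition cycle excluding interframe pauses."""
        total = self.blocks[-1].t0_ns + self.blocks[-1].m * self.dwell_ns
        pauses = (self.reps - 1) * self.interframe_pause_ns if self.integration == "frame" else 0
        return (total - pauses) // self.n_frames if self.integration == "frame" else total

    def frame_visit_order(self) -> np.ndarray:
        """First-occurrence visit order: one (x, y) row per pixel, N = nx*ny.

        For frame integration this is the first frame; for line integration it
        is the first pass over each line (identical to the raster frame order).
        """
        v = self.visits
        flat = v[:, 1] * self.nx + v[:, 0]
        seen = np.zeros(self.nx * self.ny, dtype=bool)
        keep = np.empty(len(flat), dtype=bool)
        for i, f in enumerate(flat):
            keep[i] = not seen[f]
            seen[f] = True
        return v[keep][:, :2]

    def digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(repr((self.nx, self.ny, self.dwell_ns, self.reps, self.mode,
                       self.integration, self.skip_x, self.skip_y,
                       self.flyback_delay_ns, self.interframe_pause_ns)).encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class FluenceSpec:
    """Beam and sampling parameters that set the electron fluence per pixel."""

    current_pA: float
    dwell_ns: float
    reps: int
    pixel_nm: float

    def __post_init__(self) -> None:
        for name in ("current_pA", "dwell_ns", "reps", "pixel_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dwell_ns <= 0 or self.pixel_nm <= 0 or self.reps < 1:
            raise ValueError("dwell_ns, pixel_nm must be > 0 and reps >= 1")


def _check_common(nx: int, ny: int, dwell_ns: int, reps: int) -> None:
    if nx < 1 or ny < 1 or reps < 1:
        raise ValueError("nx, ny and reps must all be >= 1")
    if dwell_ns <= 0:
        raise ValueError("dwell_ns must be positive")


def make_raster_pattern(
    nx: int,
    ny: int,
    dwell_ns: int,
    reps: int = 1,
    integration: str = "frame",
    flyback_delay_ns: int = 0,
    interframe_pause_ns: int = 0,
) -> ScanPattern:
    """Conventional raster scan: rows left to right, x the fast axis.

    Line integration repeats each line ``reps`` times consecutively, with a
    flyback settling delay inserted before every line pass.  Frame integration
    scans the whole frame and repeats it ``reps`` times with no flyback delay
    (so all strategies deposit the same fluence); supplying a flyback delay with
    frame integration is an error.
    """
    _check_common(nx, ny, dwell_ns, reps)
    if integration not in INTEGRATIONS:
        raise ValueError(f"integration must be one of {INTEGRATIONS}, got {integration!r}")
    if flyback_delay_ns < 0:
        raise ValueError("flyback_delay_ns must be >= 0")
    if integration == "frame" and flyback_delay_ns > 0:
        raise ValueError("flyback delay applies to line integration only")

    blocks: list[VisitBlock] = []
    t = 0
    line_ns = nx * dwell_ns
    if integration == "line":
        for y in range(ny):
            for _ in range(reps):
                t += flyback_delay_ns
                blocks.append(VisitBlock(0, 1, nx, y, t, 0))
                t += line_ns
    else:
        for frame in range(reps):
            for y in range(ny):
                blocks.append(VisitBlock(0, 1, nx, y, t, frame))
                t += line_ns
            t += interframe_pause_ns
    return ScanPattern(nx, ny, dwell_ns, reps, "raster", integration,
                       flyback_delay_ns=flyback_delay_ns,
                       interframe_pause_ns=interframe_pause_ns, blocks=blocks)


def make_interleaved_pattern(
    nx: int,
    ny: int,
    skip_x: int = 2,
    skip_y: int = 2,
    dwell_ns: int = 100,
    reps: int = 1,
    interframe_pause_ns: int = 0,
) -> ScanPattern:
    """Interleaved (leapfrog) scan with frame integration.

    Each pass visits the sub-lattice of stride ``(skip_x + 1, skip_y + 1)`` at
    one offset, in raster order; passes run over offsets enumerated x-major
    ((0,0), (1,0), ..., (skip_x,0), (0,1), ...) until every pixel has been
    visited once.  Consecutive visits are always one dwell time apart, so the
    frame time equals that of a raster frame at the same dwell.  ``skip_x =
    skip_y = 0`` degenerates to the raster frame-integration order.
    """
    _check_common(nx, ny, dwell_ns, reps)
    if skip_x < 0 or skip_y < 0:
        raise ValueError("skip counts must be >= 0")
    if skip_x >= nx or skip_y >= ny:
        raise ValueError("skip count must be smaller than the grid dimension")

    sx, sy = skip_x + 1, skip_y + 1
    blocks: list[VisitBlock] = []
    t = 0
    for frame in range(reps):
        for oy in range(sy):
            for ox in range(sx):
                if ox >= nx or oy >= ny:
                    continue
                for y in range(oy, ny, sy):
                    m = len(range(ox, nx, sx))
                    blocks.append(VisitBlock(ox, sx, m, y, t, frame))
                    t += m * dwell_ns
        t += interframe_pause_ns
    return ScanPattern(nx, ny, dwell_ns, reps, "interleaved", "frame",
                       skip_x=skip_x, skip_y=skip_y,
                       interframe_pause_ns=interframe_pause_ns, blocks=blocks)


@dataclass
class PatternValidation:
    """Findings from checking a pattern against its declared geometry."""

    bounds_violations: list[tuple[int, int, int]] = field(default_factory=list)
    missing_pixels: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    duplicate_pixels: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    timestamp_violations: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.bounds_violations or self.missing_pixels
                    or self.duplicate_pixels or self.timestamp_violations)

    @property
    def n_findings(self) -> int:
        return (len(self.bounds_violations) + len(self.missing_pixels)
                + len(self.duplicate_pixels) + len(self.timestamp_violations))


def _frame_chunks(pattern: ScanPattern, visits: np.ndarray) -> list[np.ndarray]:
    """Split visits into per-repetition chunks (whole sequence for line integration)."""
    if pattern.integration == "frame" and pattern.reps > 1:
        n = pattern.nx * pattern.ny
        if len(visits) == n * pattern.reps:
            return [visits[i * n : (i + 1) * n] for i in range(pattern.reps)]
    return [visits]


def validate_pattern(pattern: ScanPattern, visits: np.ndarray | None = None) -> PatternValidation:
    """Report bounds violations, per-repetition coverage defects and time-order defects.

    ``visits`` may override the pattern's own visit list (to audit an imported
    or hand-edited sequence).  A valid pattern yields an empty report.
    """
    v = pattern.visits if visits is None else np.asarray(visits)
    report = PatternValidation()
    inb = (v[:, 0] >= 0) & (v[:, 0] < pattern.nx) & (v[:, 1] >= 0) & (v[:, 1] < pattern.ny)
    for i in np.nonzero(~inb)[0]:
        report.bounds_violations.append((int(i), int(v[i, 0]), int(v[i, 1])))
    bad_t = np.nonzero(np.diff(v[:, 2]) <= 0)[0] + 1
    report.timestamp_violations.extend(int(i) for i in bad_t)

    for fidx, chunk in enumerate(_frame_chunks(pattern, v)):
        reps_here = 1 if pattern.integration == "frame" and pattern.reps > 1 else (
            pattern.reps if pattern.integration == "line" else pattern.reps)
        ok = chunk[(chunk[:, 0] >= 0) & (chunk[:, 0] < pattern.nx)
                   & (chunk[:, 1] >= 0) & (chunk[:, 1] < pattern.ny)]
        counts = np.bincount(ok[:, 1] * pattern.nx + ok[:, 0],
                             minlength=pattern.nx * pattern.ny)
        expected = reps_here
        for flat in np.nonzero(counts < expected)[0]:
            report.missing_pixels.append((fidx, (int(flat % pattern.nx), int(flat // pattern.nx))))
        for flat in np.nonzero(counts > expected)[0]:
            report.duplicate_pixels.append((fidx, (int(flat % pattern.nx), int(flat // pattern.nx))))
    return report


def min_neighbour_interval(pattern: ScanPattern, chebyshev_radius: int = 1) -> int:
    """Shortest time between visits of two distinct pixels within a Chebyshev radius.

    This is the dissipation window the scan affords: for a raster scan at
    radius 1 it equals the dwell time (x neighbours are hit back to back),
    while interleaving stretches it by the sub-lattice pass length.  For
    multi-repetition frame integration the minimum is taken within each frame.
    """
    if chebyshev_radius < 1:
        raise ValueError("radius must be >= 1")
    if chebyshev_radius >= max(pattern.nx, pattern.ny):
        raise ValueError("radius exceeds the grid extent")
    if pattern.nx * pattern.ny < 2:
        raise ValueError("a single-pixel grid has no neighbour pairs")

    best = np.inf
    for chunk in _frame_chunks(pattern, pattern.visits):
        # time lists per pixel (line integration revisits pixels within a chunk)
        tgrid: dict[tuple[int, int], list[int]] = {}
        for x, y, t in chunk:
            tgrid.setdefault((int(x), int(y)), []).append(int(t))
        offsets = [(dx, dy)
                   for dy in range(-chebyshev_radius, chebyshev_radius + 1)
                   for dx in range(-chebyshev_radius, chebyshev_radius + 1)
                   if not (dx == 0 and dy == 0)]
        single = all(len(ts) == 1 for ts in tgrid.values())
        if single:
            T = np.full((pattern.ny, pattern.nx), np.iinfo(np.int64).max, dtype=np.int64)
            present = np.zeros((pattern.ny, pattern.nx), dtype=bool)
            for (x, y), ts in tgrid.items():
                T[y, x] = ts[0]
                present[y, x] = True
            for dx, dy in offsets:
                if dx <= 0 and (dx < 0 or dy < 0):
                    continue  # each unordered pair once
                a = T[max(0, -dy):pattern.ny - max(0, dy), max(0, -dx):pattern.nx - max(0, dx)]
                b = T[max(0, dy):pattern.ny - max(0, -dy), max(0, dx):pattern.nx - max(0, -dx)]
                pa = present[max(0, -dy):pattern.ny - max(0, dy), max(0, -dx):pattern.nx - max(0, dx)]
                pb = present[max(0, dy):pattern.ny - max(0, -dy), max(0, dx):pattern.nx - max(0, -dx)]
                both = pa & pb
                if both.any():
                    best = min(best, np.abs(a[both] - b[both]).min())
        else:
            for (x, y), ts in tgrid.items():
                for dx, dy in offsets:
                    other = tgrid.get((x + dx, y + dy))
                    if other:
                        d = np.abs(np.subtract.outer(np.array(ts), np.array(other))).min()
                        best = min(best, d)
    return int(best)


def export_pattern_text(pattern: ScanPattern, destination: str | Path,
                        header: bool = True) -> Path:
    """Write the per-frame visit order as an ASCII coordinate file.

    One visit per line, ``"x y"`` with 0-based integers, in visit order, one
    frame only — repetitions and timing are metadata, carried in a ``#`` header
    line that scan engines rejecting comments can suppress with ``header=False``.
    """
    dest = Path(destination)
    order = pattern.frame_visit_order()
    with dest.open("w") as fh:
        if header:
            fh.write(f"# nx={pattern.nx} ny={pattern.ny} dwell_ns={pattern.dwell_ns} "
                     f"reps={pattern.reps} mode={pattern.mode} "
                     f"integration={pattern.integration} "
                     f"skip_x={pattern.skip_x} skip_y={pattern.skip_y}\n")
        for x, y in order:
            fh.write(f"{x} {y}\n")
    return dest


def import_pattern_text(source: str | Path, metadata: dict | None = None) -> ScanPattern:
    """Read a coordinate text file back into a single-frame ScanPattern.

    Metadata absent from the file header (dwell, reps, mode, ...) may be
    supplied via ``metadata``; header fields take precedence.  Visit times are
    reconstructed as consecutive dwell steps in file order.
    """
    src = Path(source)
    meta = dict(metadata or {})
    coords: list[tuple[int, int]] = []
    with src.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, _, val = tok.partition("=")
                        meta.setdefault(k, val)
                continue
            parts = line.split()
            try:
                if len(parts) != 2:
                    raise ValueError
                coords.append((int(parts[0]), int(parts[1])))
            except ValueError:
                raise ValueError(f"{src}:{lineno}: malformed coordinate line {line!r}") from None
    if not coords:
        raise ValueError(f"{src}: no coordinates found")
    arr = np.array(coords, dtype=np.int64)
    nx = int(meta.get("nx", arr[:, 0].max() + 1))
    ny = int(meta.get("ny", arr[:, 1].max() + 1))
    if (arr[:, 0] < 0).any() or (arr[:, 0] >= nx).any() or (arr[:, 1] < 0).any() or (arr[:, 1] >= ny).any():
        bad = np.nonzero((arr[:, 0] < 0) | (arr[:, 0] >= nx) | (arr[:, 1] < 0) | (arr[:, 1] >= ny))[0][0]
        raise ValueError(f"{src}: coordinate out of bounds on data line {bad + 1}")
    dwell = int(meta.get("dwell_ns", 100))
    blocks = [VisitBlock(int(x), 1, 1, int(y), i * dwell, 0) for i, (x, y) in enumerate(arr)]
    return ScanPattern(nx, ny, dwell, int(meta.get("reps", 1)),
                       str(meta.get("mode", "raster")), "frame",
                       skip_x=int(meta.get("skip_x", 0)), skip_y=int(meta.get("skip_y", 0)),
                       blocks=blocks)


def compute_fluence(spec: FluenceSpec) -> float:
    """Electron fluence per pixel in e-/Å².

    fluence = I * dwell * R / (e * a²) with a the pixel edge in Å.  The three
    schedules 100 ns x100, 500 ns x20 and 1000 ns x10 share the product
    dwell*R and therefore deposit identical fluence.
    """
    # dwell*reps first: fluence-matched schedules share this product exactly,
    # so they map to bit-identical fluence values
    electrons = spec.current_pA * 1e-12 * (spec.dwell_ns * spec.reps) * 1e-9 / elementary_charge
    area_A2 = (10.0 * spec.pixel_nm) ** 2
    return electrons / area_A2
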