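"""Charge deposition, dissipation and detection under arbitrary scan patterns.

The model formalizes the standard qualitative picture of specimen charging in
secondary-electron imaging of insulators:

* every probe visit deposits a fixed charge ``q0`` at the visited pixel
  (the probe FWHM, ~2 nm, is below the pixel size, so sub-pixel spread is
  ignored);
* between visits the accumulated charge field ``C`` relaxes by isotropic
  lateral diffusion (explicit 5-point stencil, zero-flux boundaries) and by
  exponential leak to ground with a per-pixel time constant ``tau``;
* the detected signal at a pixel is the secondary-electron yield attenuated
  exponentially by the locally smoothed charge,
  ``gain * yield * exp(-alpha * C~) + offset + noise``, where ``C~`` is the
  charge field smoothed with a Gaussian of width ``sigma_local_px``
  (charging darkens the image; bright flashes are available through an
  optional discharge model, off by default).

Dissipation updates are batched: the field is evolved once per run of
``batch_visits`` visits (never across a line or frame boundary) with exact
elapsed-time accounting.  Within a batch, detection still sees the charge laid
down by the batch's earlier visits through an exact causal kernel sum, so
batching changes only when *dissipation* is applied, not when charge exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from numba import njit
from scipy.ndimage import correlate1d, gaussian_filter, gaussian_filter1d

from .phantom import Phantom
from .scan_patterns import ScanPattern, VisitBlock

__all__ = [
    "SimParams",
    "ChargeState",
    "SubframeStack",
    "evolve_charge",
    "detect_signal",
    "simulate_acquisition",
    "peak_charge_trace",
    "save_stack",
    "load_stack",
]

# sub-step bound for the explicit stencil; strictly inside the 0.25 px^2
# stability limit so the checkerboard mode is damped, not merely neutral
_MAX_DIFFUSION_NUMBER = 0.2


@dataclass(frozen=True)
class SimParams:
    """Calibration constants of the charge model.

    ``q0_electrons`` defaults to the charge of one 100 ns visit at 6.3 pA
    (current * dwell / e).  ``alpha`` and ``D_px2_per_ns`` are free parameters
    of the qualitative model, calibrated so the simulator reproduces the
    observed ordering of scan strategies, not measured constants.
    """

    q0_electrons: float = 3.932
    probe_fwhm_nm: float = 2.0
    D_px2_per_ns: float = 1e-5
    alpha: float = 0.5
    sigma_local_px: float = 3.0
    noise_std: float = 1200.0
    detector_gain: float = 20000.0
    detector_offset: float = 2000.0
    batch_visits: int | None = None   # None: one batch per line/sub-lattice pass
    discharge_enabled: bool = False
    discharge_threshold: float = 50.0
    discharge_gain: float = 15000.0
    drift_step_px: float = 0.0
    burnspot_enabled: bool = False

    def __post_init__(self) -> None:
        if self.q0_electrons < 0 or self.D_px2_per_ns < 0 or self.alpha < 0:
            raise ValueError("q0, D and alpha must be >= 0")
        if self.detector_gain <= 0:
            raise ValueError("detector_gain must be positive")
        if self.batch_visits is not None and self.batch_visits < 1:
            raise ValueError("batch_visits must be >= 1")

    @classmethod
    def from_beam(cls, current_pA: float, dwell_ns: float, **kw) -> "SimParams":
        from scipy.constants import elementary_charge

        q0 = current_pA * 1e-12 * dwell_ns * 1e-9 / elementary_charge
        return cls(q0_electrons=q0, **kw)


@dataclass
class ChargeState:
    """Accumulated charge per pixel (electrons) and the simulation clock."""

    C: np.ndarray
    clock_ns: float = 0.0

    @classmethod
    def zeros(cls, ny: int, nx: int) -> "ChargeState":
        return cls(C=np.zeros((ny, nx), dtype=np.float64), clock_ns=0.0)

    @property
    def total(self) -> float:
        return float(self.C.sum())


@dataclass
class SubframeStack:
    """Raw frames from repeated scans plus acquisition/simulation metadata."""

    frames: np.ndarray          # (R, ny, nx), int16 raw or uint8 converted
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _conservative_laplacian(C: np.ndarray) -> np.ndarray:
    """Flux-form 5-point Laplacian with zero-flux (Neumann) boundaries.

    Interior fluxes cancel pairwise, so the stencil conserves total charge to
    floating-point rounding.
    """
    L = np.zeros_like(C)
    d = C[1:, :] - C[:-1, :]
    L[:-1, :] += d
    L[1:, :] -= d
    d = C[:, 1:] - C[:, :-1]
    L[:, :-1] += d
    L[:, 1:] -= d
    return L


def evolve_charge(state: ChargeState, dt_ns: float, phantom: Phantom,
                  params: SimParams) -> ChargeState:
    """Relax the charge field over ``dt_ns``: exponential leak + lateral diffusion.

    The leak is exact per pixel (``C *= exp(-dt/tau)``); diffusion uses the
    explicit stencil sub-stepped so that ``D*dt_sub <= 0.25 px^2``, with the
    leak factor split evenly across the sub-steps so the two processes stay
    interleaved.
    """
    if dt_ns < 0:
        raise ValueError("dt_ns must be >= 0")
    if dt_ns == 0:
        return state
    D = params.D_px2_per_ns
    n_sub = max(1, int(np.ceil(D * dt_ns / _MAX_DIFFUSION_NUMBER))) if D > 0 else 1
    dt_sub = dt_ns / n_sub
    with np.errstate(divide="ignore"):
        decay = np.exp(-dt_sub / phantom.tau_map)
    C = state.C
    for _ in range(n_sub):
        C *= decay
        if D > 0:
            C += (D * dt_sub) * _conservative_laplacian(C)
    state.clock_ns += dt_ns
    return state


@njit(cache=False)
def _evolve_kernel(C: np.ndarray, decay: np.ndarray, ddt: float, n_sub: int,
                   buf: np.ndarray) -> None:
    """Fused leak + 5-point zero-flux diffusion sub-steps (in place).

    Identical scheme to evolve_charge: per sub-step the exact pointwise leak
    factor is applied, then the conservative explicit stencil (zero-flux
    boundaries realised by mirroring the edge value).
    """
    ny, nx = C.shape
    for _ in range(n_sub):
        for i in range(ny):
            for j in range(nx):
                v = C[i, j] * decay[i, j]
                # flush leaked-away charge to zero (denormals cripple the FPU)
                buf[i, j] = v if v > 1e-280 else 0.0
        if ddt > 0.0:
            for i in range(ny):
                iu = i - 1 if i > 0 else i
                idn = i + 1 if i < ny - 1 else i
                a = buf[i]
                up = buf[iu]
                dn = buf[idn]
                C[i, 0] = a[0] + ddt * (up[0] + dn[0] + a[0] + a[1] - 4.0 * a[0])
                for j in range(1, nx - 1):
                    C[i, j] = a[j] + ddt * (up[j] + dn[j] + a[j - 1] + a[j + 1]
                                            - 4.0 * a[j])
                C[i, nx - 1] = a[nx - 1] + ddt * (up[nx - 1] + dn[nx - 1]
                                                  + a[nx - 2] + a[nx - 1]
                                                  - 4.0 * a[nx - 1])
        else:
            for i in range(ny):
                for j in range(nx):
                    C[i, j] = buf[i, j]


def _smooth_kernel_1d(sigma: float) -> np.ndarray:
    """The exact truncated, normalized Gaussian kernel scipy uses (truncate=4)."""
    r = int(4.0 * sigma + 0.5)
    imp = np.zeros(2 * r + 1)
    imp[r] = 1.0
    return gaussian_filter1d(imp, sigma)


def smoothed_charge(state: ChargeState, sigma: float) -> np.ndarray:
    """Gaussian-smoothed charge field C~ as used by the detector model."""
    return gaussian_filter(state.C, sigma, mode="nearest")


def _smoothed_rows(C: np.ndarray, y: int, sigma: float, kern: np.ndarray) -> np.ndarray:
    """Row ``y`` of the separably smoothed field, identical to smoothed_charge."""
    r = len(kern) // 2
    idx = np.clip(np.arange(y - r, y + r + 1), 0, C.shape[0] - 1)
    win = correlate1d(C[idx], kern, axis=1, mode="nearest")
    return kern @ win


@njit(cache=False)
def _smooth_row_kernel(C: np.ndarray, y: int, kern: np.ndarray,
                       wrow: np.ndarray, out: np.ndarray) -> None:
    """Separable clamped-edge Gaussian smoothing of one row (same math as
    _smoothed_rows / smoothed_charge, without the scipy call overhead)."""
    ny, nx = C.shape
    m = kern.shape[0]
    r = m // 2
    for j in range(nx):
        wrow[j] = 0.0
    for k in range(m):
        yy = y + k - r
        if yy < 0:
            yy = 0
        elif yy > ny - 1:
            yy = ny - 1
        w = kern[k]
        row = C[yy]
        for j in range(nx):
            wrow[j] += w * row[j]
    for j in range(nx):
        acc = 0.0
        for k in range(m):
            jj = j + k - r
            if jj < 0:
                jj = 0
            elif jj > nx - 1:
                jj = nx - 1
            acc += kern[k] * wrow[jj]
        out[j] = acc


@njit(cache=False)
def _smooth_row_prod_kernel(C: np.ndarray, D: np.ndarray, y: int,
                            kern: np.ndarray, wrow: np.ndarray,
                            out: np.ndarray) -> None:
    """Like _smooth_row_kernel but smoothing the elementwise product C*D."""
    ny, nx = C.shape
    m = kern.shape[0]
    r = m // 2
    for j in range(nx):
        wrow[j] = 0.0
    for k in range(m):
        yy = y + k - r
        if yy < 0:
            yy = 0
        elif yy > ny - 1:
            yy = ny - 1
        w = kern[k]
        rowc = C[yy]
        rowd = D[yy]
        for j in range(nx):
            wrow[j] += w * rowc[j] * rowd[j]
    for j in range(nx):
        acc = 0.0
        for k in range(m):
            jj = j + k - r
            if jj < 0:
                jj = 0
            elif jj > nx - 1:
                jj = nx - 1
            acc += kern[k] * wrow[jj]
        out[j] = acc


def detect_signal(phantom: Phantom, state: ChargeState, position: tuple[int, int],
                  params: SimParams, rng: np.random.Generator | None = None) -> float:
    """Detected intensity (detector counts) at ``position`` = (x, y).

    With the optional discharge model enabled, a locally smoothed charge above
    the threshold emits a bright spike and resets the charge within
    ``sigma_local_px`` of the position.
    """
    x, y = position
    if not (0 <= x < phantom.nx and 0 <= y < phantom.ny):
        raise IndexError(f"position {position} outside {phantom.nx}x{phantom.ny} grid")
    ct = smoothed_charge(state, params.sigma_local_px)[y, x]
    val = (params.detector_gain * phantom.yield_map[y, x] * np.exp(-params.alpha * ct)
           + params.detector_offset)
    if params.discharge_enabled and ct > params.discharge_threshold:
        val += params.discharge_gain
        yy, xx = np.ogrid[0:phantom.ny, 0:phantom.nx]
        state.C[(yy - y) ** 2 + (xx - x) ** 2 <= params.sigma_local_px ** 2] = 0.0
    if rng is not None and params.noise_std > 0:
        val += rng.normal(0.0, params.noise_std)
    return float(val)


def _causal_kernel(dx: int, kern: np.ndarray) -> np.ndarray:
    """Smoothing-kernel weight of an in-row deposit at lag L (distance L*dx).

    Uses the same discrete truncated Gaussian as the detector smoothing, so a
    visit sees the batch's earlier deposits exactly as ``smoothed_charge``
    would weight them; batching then changes only *when* dissipation is
    applied, never when charge exists.
    """
    r = len(kern) // 2
    lags = np.arange(1, r // max(1, dx) + 1)
    return kern[r] * kern[r + lags * dx], lags


class _Engine:
    """Shared block-iterating core for simulate_acquisition / peak_charge_trace."""

    def __init__(self, phantom: Phantom, pattern: ScanPattern, params: SimParams,
                 seed: int | None):
        if (pattern.nx, pattern.ny) != (phantom.nx, phantom.ny):
            raise ValueError("pattern grid does not match phantom grid")
        self.phantom = phantom
        self.pattern = pattern
        self.params = params
        self.rng = np.random.default_rng(seed)
        self.C = np.zeros((phantom.ny, phantom.nx), dtype=np.float64)
        self.kern = _smooth_kernel_1d(params.sigma_local_px)
        self.yield_map = phantom.yield_map.copy()
        self.tau_map = phantom.tau_map.copy()
        self.drift: list[tuple[int, int]] = [(0, 0)]
        self._drift_cont = [0.0, 0.0]
        self._decay_cache: dict[float, np.ndarray] = {}
        self._causal_cache: dict = {}
        self._lap_buf = np.zeros_like(self.C)
        self._wrow = np.zeros(phantom.nx)
        self._crow = np.zeros(phantom.nx)
        self._crow2 = np.zeros(phantom.nx)
        with np.errstate(divide="ignore"):
            # per-dwell leak factor, used for within-block field aging
            self._dmap = np.exp(-float(pattern.dwell_ns) / self.tau_map)
        self.clipped = 0

    def _evolve(self, dt: float) -> None:
        """Same model as evolve_charge, with the per-substep leak factors cached."""
        if dt <= 0:
            return
        D = self.params.D_px2_per_ns
        n_sub = max(1, int(np.ceil(D * dt / _MAX_DIFFUSION_NUMBER))) if D > 0 else 1
        dt_sub = dt / n_sub
        if dt_sub not in self._decay_cache:
            with np.errstate(divide="ignore"):
                self._decay_cache[dt_sub] = np.exp(-dt_sub / self.tau_map)
        decay = self._decay_cache[dt_sub]
        _evolve_kernel(self.C, decay, D * dt_sub, n_sub, self._lap_buf)

    def _deposit_comp(self, b: VisitBlock, xs: np.ndarray) -> np.ndarray:
        """Leak pre-compensation for within-block deposit ages.

        The batch update decays every deposit over the whole block, although
        visit ``j`` arrives ``j`` dwell times late.  The leak being linear and
        pointwise, crediting each deposit with ``exp(+j*dwell/tau)`` makes the
        batched leak exact per deposit (the exponent is clamped for leak
        times far below one dwell).  Returns ``(comp, age)``: the deposit
        credit and its reciprocal, the within-block leak aging that the
        detector applies to the block-start charge field.
        """
        ckey = ("comp", b.y, b.x0, b.dx, b.m)
        cached = self._causal_cache.get(ckey)
        if cached is not None:
            return cached
        j = np.arange(b.m, dtype=np.float64) * self.pattern.dwell_ns
        with np.errstate(divide="ignore"):
            ratio = np.minimum(j / self.tau_map[b.y, xs], 45.0)
        self._causal_cache[ckey] = (np.exp(ratio), np.exp(-ratio))
        return self._causal_cache[ckey]

    def _causal(self, b: VisitBlock, xs: np.ndarray) -> np.ndarray:
        """Smoothed charge a visit sees from the batch's own earlier deposits.

        Each earlier deposit (uniformly ``q0``, hence the caller scales by it)
        contributes its smoothing-kernel weight decayed by the per-pixel leak
        over the intervening dwell intervals; diffusion over a single batch is
        below the smoothing width and is deferred to the batch boundary.
        Vectors are cached per block geometry; the cache is dropped on drift
        (the leak map moves with the specimen).
        """
        ckey = (b.y, b.x0, b.dx, b.m)
        cached = self._causal_cache.get(ckey)
        if cached is not None:
            return cached
        kern = self.kern
        r = len(kern) // 2
        # clamped-edge smoothing replicates boundary pixels, so a deposit in
        # the first/last row, or at column 0, weighs more near that edge
        wy = kern[r] + (kern[:r].sum() if b.y in (0, self.pattern.ny - 1) else 0.0)
        kkey = ("kern", b.dx)
        if kkey not in self._causal_cache:
            self._causal_cache[kkey] = _causal_kernel(b.dx, kern)
        g, lags = self._causal_cache[kkey]
        ct = np.zeros(b.m)
        tau_row = self.tau_map[b.y, xs]
        dwell = self.pattern.dwell_ns
        with np.errstate(divide="ignore"):
            for gL, L in zip(g * (wy / kern[r]), lags):
                if L >= b.m:
                    break
                ct[L:] += gL * np.exp(-L * dwell / tau_row[:-L])
            if b.x0 == 0:
                # extra weight of the column-0 deposit on detections x < r
                for i in range(1, min(b.m, (r - 1) // b.dx + 1)):
                    xi = i * b.dx
                    if xi >= r:
                        break
                    ct[i] += wy * kern[:r - xi].sum() * np.exp(-i * dwell / tau_row[0])
        self._causal_cache[ckey] = ct
        return ct

    def _apply_drift(self, scale: float = 1.0) -> None:
        """Advance the specimen's random-walk drift and apply any integer shift.

        ``drift_step_px`` is the walk's standard deviation per frame-scan
        time; ``scale`` rescales it for shorter intervals (line integration
        accrues drift per line group).  The walk is continuous; the specimen
        moves by whole pixels whenever the walk crosses an integer.
        """
        p = self.params
        if p.drift_step_px <= 0:
            self.drift.append(self.drift[-1])
            return
        self._drift_cont[0] += self.rng.normal(0, p.drift_step_px * scale)
        self._drift_cont[1] += self.rng.normal(0, p.drift_step_px * scale)
        oy, ox = self.drift[-1]
        sy = int(np.rint(self._drift_cont[0])) - oy
        sx = int(np.rint(self._drift_cont[1])) - ox
        self.drift.append((oy + sy, ox + sx))
        if sy or sx:
            # specimen and its accumulated charge move together
            self.yield_map = np.roll(self.yield_map, (sy, sx), axis=(0, 1))
            self.tau_map = np.roll(self.tau_map, (sy, sx), axis=(0, 1))
            self.C = np.roll(self.C, (sy, sx), axis=(0, 1))
            self._dmap = np.roll(self._dmap, (sy, sx), axis=(0, 1))
            for k in self._decay_cache:
                self._decay_cache[k] = np.roll(self._decay_cache[k], (sy, sx), axis=(0, 1))
            self._causal_cache = {k: v for k, v in self._causal_cache.items()
                                  if isinstance(k, tuple) and k and k[0] == "kern"}

    def run(self, render: bool = True, trace: bool = False):
        p = self.params
        pat = self.pattern
        q0 = p.q0_electrons
        line_int = pat.integration == "line"
        if render:
            if line_int:
                accum = np.zeros((pat.ny, pat.nx), dtype=np.float64)
            else:
                frames = np.zeros((pat.n_frames, pat.ny, pat.nx), dtype=np.float64)
        trace_vals: list[float] = []
        t_last = 0.0
        cur_frame = 0
        last_pixel = None

        blocks = list(pat.iter_blocks())
        if p.batch_visits is not None:
            split = []
            for b in blocks:
                for k0 in range(0, b.m, p.batch_visits):
                    m = min(p.batch_visits, b.m - k0)
                    split.append(VisitBlock(b.x0 + b.dx * k0, b.dx, m, b.y,
                                            b.t0_ns + k0 * pat.dwell_ns, b.frame))
            blocks = split

        frame_time = pat.nx * pat.ny * pat.dwell_ns
        cur_y = blocks[0].y if blocks else 0
        group_t0 = 0.0
        for b in blocks:
            if b.frame != cur_frame:
                if p.burnspot_enabled and pat.interframe_pause_ns > 0 and last_pixel is not None:
                    lx, ly = last_pixel
                    self.C[ly, lx] += q0 * pat.interframe_pause_ns / pat.dwell_ns
                self._apply_drift()
                cur_frame = b.frame
            elif line_int and b.y != cur_y:
                # drift accrues in time: the uncorrectable intra-frame drift
                # of line integration advances once per line group
                self._apply_drift(scale=np.sqrt(max(b.t0_ns - group_t0, 0.0)
                                                / frame_time))
                group_t0 = b.t0_ns
                cur_y = b.y
            # one batch update per block: dissipation over the previous
            # block's scan time plus any idle gap (flyback delay, pause)
            self._evolve(b.t0_ns - t_last)
            t_last = b.t0_ns
            xs = b.x0 + b.dx * np.arange(b.m)
            if render:
                # within-block aging of the pre-existing field: the smoothed
                # charge decays per visit with the charge-weighted mean leak
                # factor of its contributors (exact when the leak time is
                # locally uniform)
                _smooth_row_kernel(self.C, b.y, self.kern, self._wrow, self._crow)
                _smooth_row_prod_kernel(self.C, self._dmap, b.y, self.kern,
                                        self._wrow, self._crow2)
                s0 = self._crow[xs]
                s1 = self._crow2[xs]
                with np.errstate(divide="ignore", invalid="ignore"):
                    logd = np.where(s0 > 0, np.log(np.maximum(s1 / np.maximum(s0, 1e-300),
                                                              1e-300)), 0.0)
                j_idx = np.arange(b.m, dtype=np.float64)
                ct = s0 * np.exp(np.maximum(j_idx * logd, -700.0)) \
                    + q0 * self._causal(b, xs)
                sig = (p.detector_gain * self.yield_map[b.y, xs] * np.exp(-p.alpha * ct)
                       + p.detector_offset)
                if p.discharge_enabled:
                    hot = ct > p.discharge_threshold
                    if hot.any():
                        sig = sig + hot * p.discharge_gain
                        r = int(np.ceil(p.sigma_local_px))
                        for x in xs[hot]:
                            y0, y1 = max(0, b.y - r), min(pat.ny, b.y + r + 1)
                            x0, x1 = max(0, x - r), min(pat.nx, x + r + 1)
                            self.C[y0:y1, x0:x1] = 0.0
                if p.noise_std > 0:
                    sig = sig + self.rng.normal(0.0, p.noise_std, size=b.m)
                if line_int:
                    accum[b.y, xs] += sig
                else:
                    frames[b.frame, b.y, xs] = sig
            if trace:
                # peak of the smoothed field right after this batch's deposits
                self.C[b.y, xs] += q0
                trace_vals.append(float(gaussian_filter(self.C, p.sigma_local_px,
                                                        mode="nearest").max()))
                self.C[b.y, xs] -= q0
            self.C[b.y, xs] += q0 * self._deposit_comp(b, xs)[0]
            last_pixel = (int(xs[-1]), b.y)
        # relax over the final block's scan time
        self._evolve(blocks[-1].m * pat.dwell_ns if blocks else 0)

        if not render:
            return np.asarray(trace_vals), None
        if line_int:
            out = accum / pat.reps
            stack = out[None, :, :]
        else:
            stack = frames
        info = np.iinfo(np.int16)
        self.clipped = int(((stack < info.min) | (stack > info.max)).sum())
        stack16 = np.clip(np.rint(stack), info.min, info.max).astype(np.int16)
        return np.asarray(trace_vals), stack16


def simulate_acquisition(phantom: Phantom, pattern: ScanPattern, params: SimParams,
                         seed: int | None = 0) -> SubframeStack:
    """Synthesize the raw subframe stack an SEM would record for this pattern.

    Frame integration yields one int16 frame per repetition; line integration
    averages each line's repeated passes into a single output frame.  Values
    outside the int16 range are clipped and counted in
    ``metadata['clipped_px']``.
    """
    eng = _Engine(phantom, pattern, params, seed)
    _, stack = eng.run(render=True, trace=False)
    meta = {
        "seed": seed,
        "params": asdict(params),
        "drift_trajectory": eng.drift,
        "pattern_digest": pattern.digest(),
        "pattern": {"mode": pattern.mode, "integration": pattern.integration,
                    "dwell_ns": pattern.dwell_ns, "reps": pattern.reps,
                    "skip_x": pattern.skip_x, "skip_y": pattern.skip_y},
        "clipped_px": eng.clipped,
        "final_total_charge": float(eng.C.sum()),
    }
    return SubframeStack(frames=stack, metadata=meta)


def peak_charge_trace(phantom: Phantom, pattern: ScanPattern, params: SimParams,
                      seed: int | None = 0) -> np.ndarray:
    """Maximum of the smoothed charge field sampled after every batch update."""
    eng = _Engine(phantom, pattern, params, seed)
    trace, _ = eng.run(render=False, trace=True)
    return trace


def save_stack(stack: SubframeStack, path: str | Path) -> Path:
    import json
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.frames)
    meta = dict(stack.metadata)
    meta["drift_trajectory"] = [list(d) for d in meta.get("drift_trajectory", [])]
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1, default=str))
    return path


def load_stack(path: str | Path) -> SubframeStack:
    import json
    import tifffile

    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    side = path.with_suffix(path.suffix + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return SubframeStack(frames=frames, metadata=meta)
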