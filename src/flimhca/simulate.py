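"""Synthetic gated-microscope: scenes, reference decays and whole plates.

The generator emulates what the real acquisition sees per field of view
(FOV): budding-yeast cells as ellipses of diffuse autofluorescence, one or
two diffraction-limited kinetochore foci per cell with low photon budgets,
an occasional large, very bright dead cell, a fixed camera offset, and
photon (Poisson) noise on a pseudo-photon scale.  Every frame of the gated
sequence scales each emitter by its closed-form gate signal, so a noiseless
rendering is *exactly* the analytic forward model of
:mod:`flimhca.decay_model` — which is what makes the downstream pipeline
testable without real data.

Signal bookkeeping: an emitter "amplitude" is its emitted signal per
excitation period in camera digital numbers (DN); the per-frame
contribution is amplitude x gate fraction.  Photobleaching multiplies the
fluorescent signal of frame ``k`` (acquisition order) by
``(1 - bleach_rate)**k``, which is why the five pre-bleach frames are
excluded from lifetime fitting downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from .decay_model import DeltaIRF, GaussianIRF, gate_signal
from .plate_io import (
    AcquisitionTemplate,
    GatedStack,
    PlateLayout,
    ReferenceDecay,
    write_fov_stack,
)

log = logging.getLogger(__name__)

__all__ = [
    "Cell",
    "Focus",
    "DeadCell",
    "SceneSpec",
    "render_gated_stack",
    "generate_reference_decay",
    "random_scene",
    "simulate_plate",
    "generate_plate",
    "DEFAULT_IRF",
]

#: Default instrument response: Gaussian, centre 0.5 ns, sigma 0.2 ns.
DEFAULT_IRF = GaussianIRF(center_ns=0.5, sigma_ns=0.2)

#: Default emitted signal per period of one kinetochore focus (DN).  Chosen
#: so a single 9-pixel focus integrates to ~1.2e5 DN over the seven FLIM
#: gates, the regime the per-image QC threshold operates in.
DEFAULT_FOCUS_AMPLITUDE_DN = 5.0e4

#: Cells per pixel^2; ~40 cells on a full 336 x 256 frame.
DEFAULT_CELL_DENSITY = 40 / (336 * 256)


@dataclass(frozen=True)
class Cell:
    row: float
    col: float
    semi_major_px: float = 5.0
    semi_minor_px: float = 4.0
    angle_rad: float = 0.0


@dataclass(frozen=True)
class Focus:
    row: float
    col: float
    amplitude_dn: float = DEFAULT_FOCUS_AMPLITUDE_DN
    tau_ns: float = 4.0


@dataclass(frozen=True)
class DeadCell:
    row: float
    col: float
    radius_px: float = 9.0
    amplitude_dn: float = 1.0e5


@dataclass
class SceneSpec:
    """Full description of one synthetic FOV."""

    cells: list[Cell] = field(default_factory=list)
    foci: list[Focus] = field(default_factory=list)
    dead_cells: list[DeadCell] = field(default_factory=list)
    autofluor_rate_dn: float = 30.0
    autofluor_tau_ns: float = 2.0
    dead_cell_tau_ns: float = 1.5
    psf_sigma_px: float = 0.35
    camera_offset_dn: float = 100.0
    gain: float = 1.0
    poisson_noise: bool = True
    bleach_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        for f in self.foci:
            if f.amplitude_dn < 0:
                raise ValueError("focus amplitudes must be non-negative")


def _gauss_pixel_weights(row: float, col: float, sigma: float, shape):
    """Analytic integral of a unit 2-D Gaussian over pixel areas.

    Returns (row_slice, col_slice, patch) for the patch of pixels within
    ~4 sigma of the subpixel centre; pixel (i, j) spans [i-.5, i+.5) x
    [j-.5, j+.5).
    """
    h, w = shape
    r = int(np.ceil(4 * sigma)) + 1
    i0, i1 = max(0, int(row) - r), min(h, int(row) + r + 1)
    j0, j1 = max(0, int(col) - r), min(w, int(col) + r + 1)
    ii = np.arange(i0, i1)
    jj = np.arange(j0, j1)
    wr = ndtr((ii + 0.5 - row) / sigma) - ndtr((ii - 0.5 - row) / sigma)
    wc = ndtr((jj + 0.5 - col) / sigma) - ndtr((jj - 0.5 - col) / sigma)
    return slice(i0, i1), slice(j0, j1), np.outer(wr, wc)


def _ellipse_mask(cell: Cell, shape) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr, dc = rr - cell.row, cc - cell.col
    ca, sa = np.cos(cell.angle_rad), np.sin(cell.angle_rad)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / cell.semi_major_px) ** 2 + (v / cell.semi_minor_px) ** 2 <= 1.0


def _disk_mask(row: float, col: float, radius: float, shape) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def render_gated_stack(
    scene: SceneSpec,
    template: AcquisitionTemplate,
    irf=DEFAULT_IRF,
    fov_id: str = "",
    well_id: str = "",
    strain_id: str = "",
) -> tuple[GatedStack, dict]:
    """Render one FOV and return the stack plus its ground-truth record."""
    shape = template.frame_shape
    h, w = shape
    for k, f in enumerate(scene.foci):
        if not (0 <= f.row < h and 0 <= f.col < w):
            raise ValueError(f"focus {k} at ({f.row}, {f.col}) outside frame {shape}")

    delays = np.asarray(template.delays_ns)
    W, T = template.gate_width_ns, template.period_ns
    nf = template.n_frames

    signal = np.zeros((nf, h, w))

    # kinetochore foci, grouped by lifetime so gate curves are shared
    by_tau: dict[float, np.ndarray] = {}
    for f in scene.foci:
        amp_map = by_tau.setdefault(f.tau_ns, np.zeros(shape))
        rs, cs, patch = _gauss_pixel_weights(f.row, f.col, scene.psf_sigma_px, shape)
        amp_map[rs, cs] += f.amplitude_dn * patch
    for tau, amp_map in by_tau.items():
        g = gate_signal(tau, 1.0, delays, W, T, irf)
        signal += g[:, None, None] * amp_map[None]

    # diffuse cellular autofluorescence (not PSF-blurred: structure is
    # much larger than the PSF)
    if scene.cells and scene.autofluor_rate_dn > 0:
        af_map = np.zeros(shape)
        for cell in scene.cells:
            af_map[_ellipse_mask(cell, shape)] = scene.autofluor_rate_dn
        # real cells do not have hard intensity edges; soften the profile
        af_map = ndimage.gaussian_filter(af_map, 1.5, mode="constant")
        g = gate_signal(scene.autofluor_tau_ns, 1.0, delays, W, T, irf)
        signal += g[:, None, None] * af_map[None]

    if scene.dead_cells:
        dc_map = np.zeros(shape)
        for dc in scene.dead_cells:
            dc_map[_disk_mask(dc.row, dc.col, dc.radius_px, shape)] = dc.amplitude_dn
        g = gate_signal(scene.dead_cell_tau_ns, 1.0, delays, W, T, irf)
        signal += g[:, None, None] * dc_map[None]

    if scene.bleach_rate > 0:
        signal *= (1.0 - scene.bleach_rate) ** np.arange(nf)[:, None, None]

    if scene.poisson_noise:
        rng = np.random.default_rng(scene.seed)
        signal = rng.poisson(signal / scene.gain).astype(float) * scene.gain

    frames = signal + scene.camera_offset_dn

    stack = GatedStack(
        frames=frames,
        template=template,
        fov_id=fov_id,
        well_id=well_id,
        strain_id=strain_id,
        fixed_background_dn=scene.camera_offset_dn,
    )
    truth = {
        "fov_id": fov_id,
        "well_id": well_id,
        "strain_id": strain_id,
        "foci": [(f.row, f.col, f.amplitude_dn, f.tau_ns) for f in scene.foci],
        "dead_cells": [(d.row, d.col, d.radius_px) for d in scene.dead_cells],
    }
    return stack, truth


def focus_amplitude_for_peak_snr(
    snr: float,
    template: AcquisitionTemplate,
    irf=DEFAULT_IRF,
    tau_ns: float = 4.0,
    autofluor_rate_dn: float = 30.0,
    autofluor_tau_ns: float = 2.0,
    psf_sigma_px: float = 0.35,
    bleach_rate: float = 0.01,
    gain: float = 1.0,
) -> float:
    """Focus amplitude giving a peak-pixel SNR of ``snr`` in the intensity
    image, for the *least favourable* subpixel placement.

    Peak SNR is defined on the frame-summed intensity image as the focus's
    brightest-pixel signal divided by the photon noise at that pixel
    (sqrt(gain x (signal + in-cell autofluorescence))).  The PSF weight of
    the worst case — a focus centred on a pixel corner — is used, so every
    focus of a scene rendered at the returned amplitude has peak SNR of at
    least ``snr``.
    """
    delays = np.asarray(template.delays_ns)
    W, T = template.gate_width_ns, template.period_ns
    bleach = (1.0 - bleach_rate) ** np.arange(template.n_frames)
    s_foc = float(gate_signal(tau_ns, 1.0, delays, W, T, irf) @ bleach)
    s_af = float(gate_signal(autofluor_tau_ns, 1.0, delays, W, T, irf) @ bleach)
    w_corner = float(ndtr(1.0 / psf_sigma_px) - ndtr(0.0)) ** 2
    b = autofluor_rate_dn * s_af
    peak = 0.5 * (snr**2 * gain + snr * np.sqrt(snr**2 * gain**2 + 4 * gain * b))
    return peak / (w_corner * s_foc)


# ---------------------------------------------------------------------------
# Reference decays

_FINE_N = 10000


def _irf_fine_samples(irf, period_ns: float, n: int) -> np.ndarray:
    if hasattr(irf, "sample"):
        return irf.sample(period_ns, n)
    vals = np.asarray(irf, dtype=float)
    src_t = np.arange(vals.size) * (period_ns / vals.size)
    t = np.arange(n) * (period_ns / n)
    ext_t = np.concatenate([src_t, [period_ns]])
    ext_v = np.concatenate([vals, [vals[0]]])  # periodic closure
    out = np.interp(t, ext_t, ext_v)
    return out / (out.sum() * period_ns / n)


def generate_reference_decay(
    tau_ref_ns: float,
    irf=DEFAULT_IRF,
    template: AcquisitionTemplate | None = None,
    noise_scale: float = 0.0,
    seed: int | None = None,
    amplitude_dn: float = 1.0e4,
    n_samples: int = 500,
) -> ReferenceDecay:
    """Simulate the finely sampled decay of a reference dye.

    Returns the period-wrapped, IRF-convolved monoexponential on a uniform
    grid (default 500 samples = 25 ps spacing over 12.5 ns).  With
    ``tau_ref_ns=0.1`` this emulates the heavily quenched short-lifetime
    sample used for time-origin QC.  ``noise_scale`` adds photon-like
    Gaussian noise with sigma = noise_scale * sqrt(value).
    """
    period = template.period_ns if template is not None else 12.5
    if not 0 < tau_ref_ns < period:
        raise ValueError("tau_ref_ns must lie in (0, period)")
    dt = period / n_samples
    t = np.arange(n_samples) * dt
    norm = tau_ref_ns * -np.expm1(-period / tau_ref_ns)
    if isinstance(irf, DeltaIRF):
        values = amplitude_dn * np.exp(-((t - irf.t0_ns) % period) / tau_ref_ns) / norm
    else:
        if _FINE_N % n_samples:
            raise ValueError("n_samples must divide the fine grid size")
        dtf = period / _FINE_N
        tf = np.arange(_FINE_N) * dtf
        irf_f = _irf_fine_samples(irf, period, _FINE_N)
        f = np.exp(-tf / tau_ref_ns) / norm
        f[0] = 0.5 * (f[0] + np.exp(-period / tau_ref_ns) / norm)
        conv = np.fft.irfft(np.fft.rfft(irf_f) * np.fft.rfft(f)) * dtf
        values = amplitude_dn * conv[:: _FINE_N // n_samples]
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_scale * np.sqrt(np.maximum(values, 0)))
        values = np.maximum(values, 0.0)
    return ReferenceDecay(
        times_ns=t, values=values, tau_ref_ns=tau_ref_ns, period_ns=period
    )


# ---------------------------------------------------------------------------
# Random scenes and whole plates


def random_scene(
    template: AcquisitionTemplate,
    tau_ns: float,
    rng: np.random.Generator,
    focus_amplitude_dn: float = DEFAULT_FOCUS_AMPLITUDE_DN,
    amplitude_cv: float = 0.2,
    cell_density: float = DEFAULT_CELL_DENSITY,
    n_cells: int | None = None,
    dead_cell_prob: float = 0.25,
    **scene_overrides,
) -> SceneSpec:
    """Draw a random FOV: cells, 1-2 kinetochore foci each, maybe a dead cell.

    Kinetochore clusters sit within their cell; metaphase cells carry two
    foci a few pixels apart, interphase cells one.
    """
    h, w = template.frame_shape
    margin = 8.0
    min_spacing = 22.0  # cells are rigid bodies; keeps foci of different
    # cells farther apart than the detector's suppression ring
    if n_cells is None:
        n_cells = max(1, int(round(cell_density * h * w)))
    centers: list[tuple[float, float]] = []
    for _ in range(60 * n_cells):
        if len(centers) >= n_cells:
            break
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_spacing**2 for r0, c0 in centers):
            centers.append((r, c))
    cells, foci = [], []
    sig = np.sqrt(np.log1p(amplitude_cv**2))
    for r, c in centers:
        # anaphase cells carry two kinetochore clusters separated along the
        # elongated cell's long axis (~5-7 um); metaphase sister clusters
        # <1 um apart are unresolved and appear as a single focus
        anaphase = rng.random() < 0.4
        ang = rng.uniform(0, np.pi)
        sep = rng.uniform(8.0, 12.0) if anaphase else 0.0
        cell = Cell(
            row=r,
            col=c,
            semi_major_px=max(rng.uniform(4.0, 6.0), sep / 2 + 4.0),
            semi_minor_px=rng.uniform(3.0, 4.5),
            angle_rad=ang,
        )
        cells.append(cell)
        offsets = [-sep / 2, sep / 2] if anaphase else [0.0]
        for off in offsets:
            amp = focus_amplitude_dn * rng.lognormal(-0.5 * sig**2, sig)
            # the ellipse's major axis points along (cos ang, sin ang)
            jr = off * np.cos(ang) + rng.normal(0, 0.8)
            jc = off * np.sin(ang) + rng.normal(0, 0.8)
            foci.append(
                Focus(
                    row=float(np.clip(r + jr, 3.0, h - 4.0)),
                    col=float(np.clip(c + jc, 3.0, w - 4.0)),
                    amplitude_dn=float(amp),
                    tau_ns=tau_ns,
                )
            )
    dead = []
    if rng.random() < dead_cell_prob:
        dead.append(
            DeadCell(
                row=rng.uniform(15, h - 15),
                col=rng.uniform(15, w - 15),
                radius_px=rng.uniform(7.0, 11.0),
            )
        )
    return SceneSpec(
        cells=cells,
        foci=foci,
        dead_cells=dead,
        seed=int(rng.integers(0, 2**31 - 1)),
        **scene_overrides,
    )


def simulate_plate(
    layout: PlateLayout,
    strain_truth: dict[str, tuple[float, float]],
    template: AcquisitionTemplate,
    irf=DEFAULT_IRF,
    seed: int = 0,
    **scene_kwargs,
):
    """Yield (GatedStack, truth record) for every FOV of a plate.

    ``strain_truth`` maps strain_id -> (tau_ns, amplitude_scale); the
    amplitude scale multiplies the default focus photon budget.  Each FOV
    uses an independent substream of the master seed, so plates are
    bit-reproducible and FOVs are statistically independent.
    """
    for strain in layout.strain_ids:
        if strain not in strain_truth:
            raise KeyError(f"no ground-truth entry for strain {strain!r}")
    ss = np.random.SeedSequence(seed)
    fovs = list(layout.iter_fovs())
    children = ss.spawn(len(fovs))
    base_amp = scene_kwargs.pop("focus_amplitude_dn", DEFAULT_FOCUS_AMPLITUDE_DN)
    for (well_id, fov_id, strain_id), child in zip(fovs, children):
        tau, amp_scale = strain_truth[strain_id]
        rng = np.random.default_rng(child)
        scene = random_scene(
            template,
            tau_ns=tau,
            rng=rng,
            focus_amplitude_dn=base_amp * amp_scale,
            **scene_kwargs,
        )
        stack, truth = render_gated_stack(
            scene, template, irf, fov_id=fov_id, well_id=well_id, strain_id=strain_id
        )
        truth["tau_ns"] = tau
        truth["amplitude_scale"] = amp_scale
        yield stack, truth


def generate_plate(
    layout: PlateLayout,
    strain_truth: dict[str, tuple[float, float]],
    template: AcquisitionTemplate,
    irf=DEFAULT_IRF,
    seed: int = 0,
    out_dir: str | Path = ".",
    **scene_kwargs,
) -> pd.DataFrame:
    """Write one TIFF per FOV plus a ground-truth table; returns the table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for stack, truth in simulate_plate(
        layout, strain_truth, template, irf, seed, **scene_kwargs
    ):
        path = out_dir / f"{stack.fov_id}.ome.tif"
        write_fov_stack(stack, path)
        rows.append(
            {
                "fov_id": stack.fov_id,
                "well_id": stack.well_id,
                "strain_id": stack.strain_id,
                "tau_ns": truth["tau_ns"],
                "amplitude_scale": truth["amplitude_scale"],
                "n_foci": len(truth["foci"]),
                "n_dead_cells": len(truth["dead_cells"]),
                "path": str(path),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ground_truth.csv", index=False)
    return table
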