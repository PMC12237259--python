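"""Ground-truth synthetic data for every stage of the NMJ pipeline.

Each generator is a pure function of its parameter set including the seed
(identical seed, bit-identical output) and returns the simulated object plus
a :class:`GroundTruth` record of everything the simulator knows: punctum
positions and areas, event times and amplitudes, release-model parameters.

What is emulated
----------------
* confocal two-channel z-stacks: a bouton-chain neuronal envelope ("HRP")
  and diffraction-limited Gaussian puncta inside it, plus "muscle" puncta
  outside the envelope that the cleaning workflow must remove;
* STED frames: annular AZ scaffolds ("BRP") with point-cluster partners at
  known nanometre offsets;
* channel pairs with a controlled population correlation;
* miniature, paired-pulse and 100-Hz / 61-stimulation train recordings from
  a depressing release model with stimulus artifacts;
* reciprocal T-maze fly counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .ephys import Trace, biexp_kernel
from .images import ImageStack

__all__ = [
    "NMJSimParams",
    "ReleaseModelParams",
    "GroundTruth",
    "make_nmj_stack",
    "make_sted_frame",
    "make_coloc_pair",
    "make_mini_trace",
    "make_train_trace",
    "make_paired_pulse",
    "make_tmaze_counts",
    "interval_length_aa",
]


@dataclass
class GroundTruth:
    """Simulator-emitted truth against which recovery is tested."""

    spot_centroids: list[tuple[float, float, float]] = field(default_factory=list)
    spot_areas_um2: list[float] = field(default_factory=list)
    spot_total_intensity: list[float] = field(default_factory=list)
    envelope_mask: np.ndarray | None = None
    event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_amps: np.ndarray = field(default_factory=lambda: np.empty(0))
    model_params: dict = field(default_factory=dict)
    # Extras used by specific generators:
    muscle_centroids: list[tuple[float, float, float]] = field(default_factory=list)
    az_centers: list[tuple[float, float]] = field(default_factory=list)
    dot_offsets_nm: list[np.ndarray] = field(default_factory=list)
    dot_distances_nm: list[np.ndarray] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def spots_frame(self) -> pd.DataFrame:
        """Truth spot table as a DataFrame (CSV-ready)."""
        return pd.DataFrame(
            {
                "z": [c[0] for c in self.spot_centroids],
                "y": [c[1] for c in self.spot_centroids],
                "x": [c[2] for c in self.spot_centroids],
                "area_um2": self.spot_areas_um2,
                "total_intensity": self.spot_total_intensity,
            }
        )


# ---------------------------------------------------------------------------
# Confocal NMJ stack
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NMJSimParams:
    """Parameters of the confocal NMJ simulation.

    Defaults describe a typical type-1b terminal imaged at 100-nm pitch with
    0.25-um optical sectioning: an 8-bouton chain about 25 um long carrying
    ~150 diffraction-limited puncta (PSF sigma 0.1 um), with sparse puncta of
    the same kind in the surrounding muscle.
    """

    n_boutons: int = 8
    bouton_radius_um: float = 1.5
    skeleton_length_um: float = 25.0
    n_spots: int = 150
    spot_sigma_um: float = 0.1
    spot_peak: float = 150.0
    muscle_spot_density: float = 0.05      # puncta per um^2 outside the envelope
    noise_gaussian_sd: float = 2.0
    noise_poisson: bool = True
    pixel_pitch_um: float = 0.1
    z_slices: int = 8
    z_step_um: float = 0.25
    min_separation_um: float | None = None
    frame_shape: tuple[int, int] | None = None   # (ny, nx); auto-sized if None
    hrp_peak: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.bouton_radius_um, self.skeleton_length_um,
               self.spot_sigma_um, self.pixel_pitch_um, self.z_step_um) <= 0:
            raise ValueError("all lengths must be positive")
        if self.n_spots < 0 or self.n_boutons < 1 or self.z_slices < 1:
            raise ValueError("counts must be non-negative (>=1 bouton/slice)")


def make_nmj_stack(params: NMJSimParams) -> tuple[ImageStack, GroundTruth]:
    """Two-channel NMJ z-stack ("HRP" envelope + "spots") with truth.

    The envelope is a chain of ``n_boutons`` discs along a gently curved
    skeleton; puncta are isotropic Gaussians (sigma ``spot_sigma_um`` in
    plane, one-slice sigma in z) placed fully inside the envelope, and
    muscle puncta of the same kind are placed outside it at
    ``muscle_spot_density``.  Truth lists only the in-envelope puncta, with
    the FWHM-disc area and the total (integrated) intensity per punctum.
    """
    rng = np.random.default_rng(params.seed)
    pitch = params.pixel_pitch_um
    r_px = params.bouton_radius_um / pitch
    sigma_px = params.spot_sigma_um / pitch

    margin_um = 3.0 * params.bouton_radius_um
    span_x_um = params.skeleton_length_um
    amp_um = min(1.5, params.bouton_radius_um)
    need_nx = int(np.ceil((span_x_um + 2 * margin_um) / pitch))
    need_ny = int(np.ceil((2 * amp_um + 2 * params.bouton_radius_um + 2 * margin_um) / pitch))
    if params.frame_shape is None:
        ny, nx = need_ny, need_nx
    else:
        ny, nx = params.frame_shape
        if ny < need_ny or nx < need_nx:
            raise ValueError(
                f"geometry needs at least ({need_ny}, {need_nx}) px, "
                f"got {params.frame_shape}"
            )

    # Bouton chain along a shallow sine.
    xs = np.linspace(margin_um, margin_um + span_x_um, params.n_boutons) / pitch
    ys = (ny / 2) + (amp_um / pitch) * np.sin(
        np.linspace(0.0, 2.0 * np.pi, params.n_boutons)
    )
    yy, xx = np.mgrid[0:ny, 0:nx]
    envelope = np.zeros((ny, nx), dtype=bool)
    for cy, cx in zip(ys, xs):
        envelope |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    # Inter-bouton tube of a third of the bouton radius.
    for (y0, x0), (y1, x1) in zip(zip(ys, xs), zip(ys[1:], xs[1:])):
        npts = int(np.hypot(y1 - y0, x1 - x0)) * 2 + 2
        for f in np.linspace(0.0, 1.0, npts):
            cy, cx = y0 + f * (y1 - y0), x0 + f * (x1 - x0)
            envelope |= (yy - cy) ** 2 + (xx - cx) ** 2 <= (r_px / 3.0) ** 2

    hrp2d = ndimage.gaussian_filter(envelope.astype(float) * params.hrp_peak, 2.0)

    inner = ndimage.binary_erosion(
        envelope, iterations=max(int(np.ceil(3 * sigma_px)) + 1, 1)
    )
    outer_excl = ndimage.binary_dilation(
        envelope, iterations=max(int(np.ceil(3 * sigma_px)) + 1, 1)
    )

    def _sample_positions(region: np.ndarray, n: int, min_sep_px: float | None):
        ys_r, xs_r = np.nonzero(region)
        if ys_r.size == 0 and n > 0:
            raise ValueError("no room for requested puncta in the frame")
        pts: list[tuple[float, float]] = []
        attempts = 0
        while len(pts) < n:
            attempts += 1
            if attempts > 200 * max(n, 1):
                raise ValueError("cannot place puncta at the requested separation")
            k = rng.integers(ys_r.size)
            py = ys_r[k] + rng.uniform(-0.5, 0.5)
            px = xs_r[k] + rng.uniform(-0.5, 0.5)
            if min_sep_px is not None and any(
                np.hypot(py - qy, px - qx) < min_sep_px for qy, qx in pts
            ):
                continue
            pts.append((py, px))
        return pts

    min_sep_px = (
        params.min_separation_um / pitch if params.min_separation_um else None
    )
    in_pts = _sample_positions(inner, params.n_spots, min_sep_px)

    area_outside_um2 = float(np.count_nonzero(~outer_excl)) * pitch**2
    n_muscle = int(rng.poisson(params.muscle_spot_density * area_outside_um2))
    out_pts = _sample_positions(~outer_excl, n_muscle, None)

    spots3d = np.zeros((params.z_slices, ny, nx))
    sigma_z = 1.0  # slices
    zz = np.arange(params.z_slices)

    def _add_spot(py: float, px: float, pz: float) -> None:
        w = int(np.ceil(4 * sigma_px)) + 1
        y0, y1 = max(int(py) - w, 0), min(int(py) + w + 1, ny)
        x0, x1 = max(int(px) - w, 0), min(int(px) + w + 1, nx)
        gy, gx = np.mgrid[y0:y1, x0:x1]
        plane = params.spot_peak * np.exp(
            -((gy - py) ** 2 + (gx - px) ** 2) / (2.0 * sigma_px**2)
        )
        zw = np.exp(-((zz - pz) ** 2) / (2.0 * sigma_z**2))
        spots3d[:, y0:y1, x0:x1] += zw[:, None, None] * plane[None]

    truth = GroundTruth(envelope_mask=np.broadcast_to(
        envelope, (params.z_slices, ny, nx)).copy())
    fwhm_area_um2 = 2.0 * np.pi * np.log(2.0) * params.spot_sigma_um**2
    total_int = params.spot_peak * 2.0 * np.pi * sigma_px**2
    for py, px in in_pts:
        pz = rng.uniform(1.0, params.z_slices - 2.0) if params.z_slices > 3 else (
            (params.z_slices - 1) / 2.0
        )
        _add_spot(py, px, pz)
        truth.spot_centroids.append((pz, py, px))
        truth.spot_areas_um2.append(fwhm_area_um2)
        truth.spot_total_intensity.append(total_int)
    for py, px in out_pts:
        pz = rng.uniform(0.0, params.z_slices - 1.0)
        _add_spot(py, px, pz)
        truth.muscle_centroids.append((pz, py, px))

    hrp3d = np.broadcast_to(hrp2d, (params.z_slices, ny, nx)).copy()
    data = np.stack([hrp3d, spots3d])
    if params.noise_poisson:
        data = rng.poisson(data).astype(float)
    if params.noise_gaussian_sd > 0:
        data = data + rng.normal(0.0, params.noise_gaussian_sd, data.shape)
    data = np.clip(data, 0.0, None)

    stack = ImageStack(
        data,
        ("HRP", "spots"),
        pixel_pitch_um=pitch,
        z_step_um=params.z_step_um,
    )
    truth.model_params = {"n_spots": params.n_spots, "n_muscle": n_muscle,
                          "seed": params.seed}
    return stack, truth


# ---------------------------------------------------------------------------
# STED frame
# ---------------------------------------------------------------------------

def make_sted_frame(
    ring_radius_nm: float = 150.0,
    n_azs: int = 9,
    dots_per_az: int = 5,
    dot_offsets_nm: list[tuple[float, float]] | None = None,
    pixel_pitch_nm: float = 20.0,
    seed: int = 0,
    roi_px: int = 53,
    ring_sigma_nm: float = 40.0,
    dot_sigma_nm: float = 30.0,
    peak: float = 200.0,
    noise_sd: float = 1.0,
    max_offset_nm: float = 400.0,
) -> tuple[ImageStack, GroundTruth]:
    """Two-channel STED frame: "BRP" annuli and "partner" point clusters.

    AZs sit on a grid of ``roi_px`` x ``roi_px`` tiles (1.06 x 1.06 um at
    20-nm pitch), each holding one annular scaffold of radius
    ``ring_radius_nm`` around a slightly jittered center.  Partner dots are
    placed at the center plus ``dot_offsets_nm`` (``(dy, dx)``, the same set
    for every AZ) or, if ``None``, at random offsets within
    ``max_offset_nm``.  Truth stores exact centers, offsets and distances.
    """
    rng = np.random.default_rng(seed)
    half_extent_nm = (roi_px // 2) * pixel_pitch_nm
    if ring_radius_nm + 3 * ring_sigma_nm >= half_extent_nm:
        raise ValueError("ring does not fit inside the ROI at this pitch")

    g = int(np.ceil(np.sqrt(n_azs)))
    ny = nx = g * roi_px
    brp = np.zeros((ny, nx))
    partner = np.zeros((ny, nx))
    yy, xx = np.mgrid[0:ny, 0:nx]
    truth = GroundTruth()
    r_px = ring_radius_nm / pixel_pitch_nm
    rs_px = ring_sigma_nm / pixel_pitch_nm
    ds_px = dot_sigma_nm / pixel_pitch_nm

    for k in range(n_azs):
        gy, gx = divmod(k, g)
        # Centers jitter on the pixel grid so that offsets stated in whole
        # multiples of the pitch land on pixel centers (truth well-defined
        # at pixel resolution).
        cy = float(gy * roi_px + roi_px // 2 + rng.integers(-1, 2))
        cx = float(gx * roi_px + roi_px // 2 + rng.integers(-1, 2))
        d = np.hypot(yy - cy, xx - cx)
        brp += peak * np.exp(-((d - r_px) ** 2) / (2.0 * rs_px**2))
        if dot_offsets_nm is None:
            ang = rng.uniform(0.0, 2.0 * np.pi, dots_per_az)
            rad = max_offset_nm * np.sqrt(rng.uniform(0.0, 1.0, dots_per_az))
            offs = np.column_stack([rad * np.sin(ang), rad * np.cos(ang)])
        else:
            offs = np.asarray(dot_offsets_nm, dtype=float)
        for dy_nm, dx_nm in offs:
            py = cy + dy_nm / pixel_pitch_nm
            px = cx + dx_nm / pixel_pitch_nm
            partner += peak * np.exp(
                -((yy - py) ** 2 + (xx - px) ** 2) / (2.0 * ds_px**2)
            )
        truth.az_centers.append((cy, cx))
        truth.dot_offsets_nm.append(offs)
        truth.dot_distances_nm.append(np.sort(np.hypot(offs[:, 0], offs[:, 1])))

    if noise_sd > 0:
        brp = brp + rng.normal(0.0, noise_sd, brp.shape)
        partner = partner + rng.normal(0.0, noise_sd, partner.shape)
    data = np.clip(np.stack([brp, partner])[:, None], 0.0, None)
    stack = ImageStack(
        data, ("BRP", "partner"),
        pixel_pitch_um=pixel_pitch_nm / 1000.0,
        z_step_um=1.0,
    )
    truth.model_params = {
        "ring_radius_nm": ring_radius_nm,
        "pixel_pitch_nm": pixel_pitch_nm,
        "seed": seed,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# Correlated channel pair
# ---------------------------------------------------------------------------

def make_coloc_pair(
    rho_target: float,
    n_px: int,
    seed: int = 0,
    mean: float = 120.0,
    sd: float = 25.0,
) -> tuple[ImageStack, GroundTruth]:
    """Two channels from a bivariate normal with population correlation rho.

    Values are clipped at zero; with the default mean/sd the clipped mass is
    negligible, so the realized sample correlation tracks ``rho_target``.
    ``n_px`` is rounded to the nearest full rectangle.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    h = max(int(round(np.sqrt(n_px))), 1)
    w = max(int(round(n_px / h)), 1)
    z1 = rng.standard_normal((h, w))
    if abs(rho_target) == 1.0:
        z2 = np.sign(rho_target) * z1
    else:
        z2 = rho_target * z1 + np.sqrt(1.0 - rho_target**2) * rng.standard_normal((h, w))
    a = np.clip(mean + sd * z1, 0.0, None)
    b = np.clip(mean + sd * z2, 0.0, None)
    realized = float(np.corrcoef(a.ravel(), b.ravel())[0, 1])
    stack = ImageStack(
        np.stack([a, b])[:, None], ("ch1", "ch2"), pixel_pitch_um=0.1, z_step_um=1.0
    )
    truth = GroundTruth(
        model_params={"rho_target": rho_target, "realized_r": realized,
                      "n_px": h * w, "seed": seed}
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Miniature traces
# ---------------------------------------------------------------------------

def make_mini_trace(
    rate_hz: float = 1.0,
    amp_mean: float = 0.7,
    amp_cv: float = 0.25,
    kernel_rise_ms: float = 1.0,
    kernel_tau_ms: float = 5.0,
    noise_sd: float = 0.05,
    duration_s: float = 90.0,
    sampling_hz: float = 10000.0,
    seed: int = 0,
    modality: str = "current",
) -> tuple[Trace, GroundTruth]:
    """Poisson-timed miniature events on Gaussian noise.

    Events use the unit-peak difference-of-exponentials waveform (negative
    for currents); amplitudes are gamma-distributed with the stated mean and
    coefficient of variation.  Defaults emulate 90-s mEJC records: ~1 Hz,
    0.7-nA events on 10-kHz sampling.
    """
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    bandwidth_hz = 1000.0 / (2.0 * np.pi * kernel_rise_ms)
    if sampling_hz < 2.0 * bandwidth_hz:
        raise ValueError("sampling below twice the kernel bandwidth")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_hz))
    sig = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    n_ev = int(rng.poisson(rate_hz * duration_s))
    times = np.sort(rng.uniform(0.0, duration_s, n_ev))
    if amp_cv > 0:
        shape = 1.0 / amp_cv**2
        amps = rng.gamma(shape, amp_mean / shape, n_ev)
    else:
        amps = np.full(n_ev, amp_mean)
    sgn = -1.0 if modality == "current" else 1.0
    kernel = biexp_kernel(kernel_rise_ms, kernel_tau_ms, sampling_hz)
    for t, a in zip(times, amps):
        i = int(round(t * sampling_hz))
        k = kernel[: max(n - i, 0)]
        sig[i:i + k.size] += sgn * a * k
    trace = Trace(sig, sampling_hz, (), modality)
    truth = GroundTruth(
        event_times_s=times,
        event_amps=sgn * amps,
        model_params={"rate_hz": rate_hz, "amp_mean": amp_mean,
                      "amp_cv": amp_cv, "seed": seed},
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Depressing-release trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReleaseModelParams:
    """Depressing release model driving train and paired-pulse traces.

    Per stimulus a fraction ``p_release`` of the current pool is released
    (or a binomial draw when ``stochastic``), the pool refills by
    ``refill_per_stim`` vesicles, and the response amplitude is the released
    count times the quantal amplitude ``q``.  Defaults follow the RRP
    protocol: 61 stimulations at 100 Hz (10-ms inter-stimulus interval).
    """

    N0: float = 500.0
    p_release: float = 0.3
    refill_per_stim: float = 0.0
    q: float = 0.7                  # quantal amplitude magnitude (nA or mV)
    n_stims: int = 61
    isi_s: float = 0.01
    mini_rate_hz: float = 0.0
    sampling_hz: float = 10000.0
    artifact_width_s: float = 0.0002
    seed: int = 0
    stochastic: bool = False
    noise_sd: float = 0.0
    kernel_rise_ms: float = 0.3
    kernel_tau_ms: float = 4.0
    artifact_amp: float = 80.0
    pre_s: float = 0.05
    post_s: float = 0.1
    modality: str = "current"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_release <= 1.0:
            raise ValueError("p_release must be in [0, 1]")
        if self.N0 < 0:
            raise ValueError("N0 must be non-negative")
        if self.n_stims < 1 or self.isi_s <= 0:
            raise ValueError("need >= 1 stimulus with positive ISI")


def make_train_trace(params: ReleaseModelParams) -> tuple[Trace, GroundTruth]:
    """Depressing stimulus train with artifacts, from the release recurrence.

    released_i = p * pool_i (deterministic) or Binomial(pool_i, p)
    (stochastic, integer pool); pool_{i+1} = pool_i - released_i + refill,
    clamped at zero (clamps recorded in the truth).  Each response is the
    released count times ``q`` convolved with the event kernel; a brief
    rectangular artifact transient of ``artifact_amp`` marks every stimulus
    onset so that artifact-exclusion logic is exercised.
    """
    rng = np.random.default_rng(params.seed)
    released = np.zeros(params.n_stims)
    clamped = False
    if params.stochastic:
        pool = int(round(params.N0))
        for i in range(params.n_stims):
            r = int(rng.binomial(pool, params.p_release)) if pool > 0 else 0
            released[i] = r
            pool = pool - r + int(round(params.refill_per_stim))
            if pool < 0:
                pool = 0
                clamped = True
    else:
        pool = float(params.N0)
        for i in range(params.n_stims):
            r = params.p_release * pool
            released[i] = r
            pool = pool - r + params.refill_per_stim
            if pool < 0:
                pool = 0.0
                clamped = True

    fs = params.sampling_hz
    duration = params.pre_s + (params.n_stims - 1) * params.isi_s + params.post_s
    n = int(round(duration * fs))
    sig = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else np.zeros(n)
    sgn = -1.0 if params.modality == "current" else 1.0
    kernel = biexp_kernel(params.kernel_rise_ms, params.kernel_tau_ms, fs)
    stim_times = tuple(params.pre_s + i * params.isi_s for i in range(params.n_stims))
    n_art = max(int(round(params.artifact_width_s * fs)), 1)
    for i, t in enumerate(stim_times):
        j = int(round(t * fs))
        sig[j:j + n_art] += params.artifact_amp
        k = kernel[: max(n - j, 0)]
        sig[j:j + k.size] += sgn * released[i] * params.q * k
    if params.mini_rate_hz > 0:
        n_ev = int(rng.poisson(params.mini_rate_hz * duration))
        for t in rng.uniform(0.0, duration, n_ev):
            j = int(round(t * fs))
            k = kernel[: max(n - j, 0)]
            sig[j:j + k.size] += sgn * params.q * k

    trace = Trace(sig, fs, stim_times, params.modality)
    truth = GroundTruth(
        event_times_s=np.asarray(stim_times),
        event_amps=sgn * released * params.q,
        model_params={
            "N0": params.N0,
            "p_release": params.p_release,
            "refill_per_stim": params.refill_per_stim,
            "q": params.q,
            "released": released,
            "pool_clamped": clamped,
            "seed": params.seed,
        },
    )
    return trace, truth


def make_paired_pulse(
    params: ReleaseModelParams, isi_s: float = 0.01
) -> tuple[Trace, GroundTruth]:
    """Two-stimulus variant of the train at the requested ISI (10 or 30 ms)."""
    from dataclasses import replace as _replace

    return make_train_trace(_replace(params, n_stims=2, isi_s=isi_s))


# ---------------------------------------------------------------------------
# T-maze counts and coordinate arithmetic
# ---------------------------------------------------------------------------

def make_tmaze_counts(
    n_flies: int = 45,
    p_avoid_cs_plus: float = 0.5,
    seed: int = 0,
    n_experiments: int = 1,
) -> pd.DataFrame:
    """Binomial arm splits for reciprocal T-maze runs.

    Defaults emulate groups of 40-50 flies per run.  Columns: experiment,
    run (1 or 2, the reciprocal pair), n_arm_cs_plus, n_arm_cs_minus.
    """
    if not 0.0 <= p_avoid_cs_plus <= 1.0:
        raise ValueError("p_avoid_cs_plus must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for e in range(n_experiments):
        for run in (1, 2):
            n_minus = int(rng.binomial(n_flies, p_avoid_cs_plus))
            rows.append(
                {"experiment": e, "run": run,
                 "n_arm_cs_plus": n_flies - n_minus,
                 "n_arm_cs_minus": n_minus}
            )
    return pd.DataFrame(rows)


def interval_length_aa(start_aa: int, end_aa: int) -> int:
    """Inclusive length of a 1-based residue interval (end - start + 1).

    Used to annotate simulated domain-deletion metadata, e.g. the printed
    MyTH4/FERM deletion spans.
    """
    if start_aa < 1 or end_aa < 1:
        raise ValueError("residue coordinates are 1-based (>= 1)")
    if start_aa > end_aa:
        raise ValueError("interval start exceeds end")
    return end_aa - start_aa + 1
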