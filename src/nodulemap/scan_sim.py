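"""Synthetic scan generator: camera scene, indentation traces, ultrasound A-scans.

Stands in for the motorized scanning platform: for every point of an
indentation grid it produces (a) a force/position trace from a
constant-speed (0.5 mm/s) indentation stopped at a 0.2 N force trigger and
(b) a 16 MHz pulse-echo A-scan of the echo reflected at the phantom-bottom /
steel-plate interface, sampled at 1.6 GHz.  It also renders a pair of camera
images (background, and background plus the phantom at an arbitrary pose)
for the vision stage.

Model choices
-------------
* The indentation force is linear-elastic with a sharp contact point:
  Fz = k_true * (Z - Z_contact) for Z past contact, plus additive Gaussian
  load-cell noise.  The stiffness feature is a secant slope, so any
  monotone law would do; the linear one makes recovery exact and testable.
* The A-scan is a Gaussian-envelope tone burst centred at the two-way
  time of flight through the layered column (matrix at its speed of sound,
  inclusion chord at its own).  The peak amplitude is attenuated by the
  two-way path (10^(-2 alpha T / 20), alpha in dB/cm) and dropped further
  over inclusions by ``inclusion_echo_drop`` scaled with the fraction of
  the inclusion's diameter intersected under the probe footprint, so the
  echo drop peaks at the centre of every inclusion regardless of its size —
  the reflectometric contrast that lets ultrasound find even 3 mm nodules.
* Air-bubble inclusions have their echo restored toward the inclusion-free
  amplitude in proportion to ``bubble_fraction`` (bubbles make nodules look
  acoustically healthy).
* Randomness: one master seed; per-point substreams are derived from
  (seed, x, y) so a re-ordered grid keeps identical per-point noise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon

from .phantom import (
    GeometryError,
    Phantom,
    local_stiffness,
    max_footprint_chord,
)

__all__ = [
    "AcquisitionConfig",
    "IndentationRecord",
    "AScan",
    "ScanDataset",
    "SceneImage",
    "render_scene_image",
    "simulate_indentation",
    "simulate_ascan",
    "simulate_scan",
    "echo_model",
    "reference_echo_amplitude",
    "point_rngs",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition parameters of the scanning platform.

    Defaults mirror the physical platform: 0.5 mm/s indentation speed,
    0.2 N trigger, 2 mm grid step, 16 MHz probe with 0.25 fractional
    bandwidth at -6 dB, 1.6 GHz ultrasound sampling, and a 0.004 N
    load-cell resolution taken as the force-noise standard deviation.
    """

    indentation_speed_mm_s: float = 0.5
    force_trigger_n: float = 0.2
    force_sample_rate_hz: float = 500.0
    us_sample_rate_hz: float = 1.6e9
    pulse_center_frequency_mhz: float = 16.0
    fractional_bandwidth: float = 0.25
    grid_step_mm: float = 2.0
    force_noise_sd_n: float = 0.004
    us_noise_sd: float = 0.02
    inclusion_echo_drop: float = 0.5
    seed: int = 0
    contact_depth_mm: float = 1.0
    record_duration_us: float = 30.0
    probe_diameter_mm: float = 3.0
    pulse_amplitude: float = 1.0

    def __post_init__(self) -> None:
        positive = (
            "indentation_speed_mm_s",
            "force_trigger_n",
            "force_sample_rate_hz",
            "us_sample_rate_hz",
            "pulse_center_frequency_mhz",
            "fractional_bandwidth",
            "grid_step_mm",
            "contact_depth_mm",
            "record_duration_us",
            "probe_diameter_mm",
            "pulse_amplitude",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"AcquisitionConfig.{name} must be positive")
        if self.force_noise_sd_n < 0 or self.us_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not (0.0 <= self.inclusion_echo_drop < 1.0):
            raise ValueError("inclusion_echo_drop must lie in [0, 1)")

    def without_noise(self) -> "AcquisitionConfig":
        return replace(self, force_noise_sd_n=0.0, us_noise_sd=0.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AcquisitionConfig":
        return cls(**data)


@dataclass
class IndentationRecord:
    """One force-controlled indentation at one grid point.

    ``z_trace`` is the probe position along Z (mm, increasing downward);
    ``force_trace`` the normal force (N); ``trigger_index`` the first sample
    where the force reached the trigger threshold.
    """

    grid_point: tuple[float, float]
    force_trace: np.ndarray
    z_trace: np.ndarray
    trigger_index: int

    def __post_init__(self) -> None:
        self.force_trace = np.asarray(self.force_trace, dtype=float)
        self.z_trace = np.asarray(self.z_trace, dtype=float)
        if self.force_trace.shape != self.z_trace.shape or self.force_trace.size < 2:
            raise ValueError("force and z traces must share a length of at least 2")
        if np.any(np.diff(self.z_trace) < 0):
            raise ValueError("z_trace must be monotone non-decreasing")
        if not (0 <= self.trigger_index < self.force_trace.size):
            raise ValueError("trigger_index out of range")


@dataclass
class AScan:
    """One pulse-echo ultrasound waveform (amplitude vs time) at one grid point."""

    grid_point: tuple[float, float]
    waveform: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.size == 0 or not np.all(np.isfinite(self.waveform)):
            raise ValueError("waveform must be non-empty and finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.waveform.size) / self.sample_rate_hz

    @property
    def energy(self) -> float:
        return float(np.sum(self.waveform**2))


@dataclass
class ScanDataset:
    """All per-point records of one automatic scan, in grid order."""

    config: AcquisitionConfig
    grid: np.ndarray  # (n, 2) surface points, mm
    records: list[IndentationRecord]
    ascans: list[AScan]
    phantom_truth: Phantom | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float).reshape(-1, 2)
        if not (len(self.records) == len(self.ascans) == len(self.grid)):
            raise ValueError("grid, records and ascans must align")


# --- scene rendering ----------------------------------------------------------


@dataclass
class SceneImage:
    """A rendered camera view: sample image, matching background, and scale."""

    sample: np.ndarray
    background: np.ndarray
    mm_per_pixel: float


def _texture(shape: tuple[int, int], rng: np.random.Generator, lo: float, hi: float) -> np.ndarray:
    noise = ndimage.gaussian_filter(rng.random(shape), sigma=3.0)
    span = noise.max() - noise.min()
    if span == 0:  # pragma: no cover - constant field cannot occur for real sizes
        return np.full(shape, (lo + hi) / 2.0)
    return lo + (hi - lo) * (noise - noise.min()) / span


def render_scene_image(
    phantom: Phantom,
    pose: tuple[float, float, float] = (0.0, 0.0, 0.0),
    image_shape: tuple[int, int] = (240, 320),
    mm_per_pixel: float = 0.5,
    seed: int = 0,
    supersample: int = 4,
) -> SceneImage:
    """Render the camera scene: textured background vs background + phantom.

    ``pose`` is (offset_x_mm, offset_y_mm, rotation_deg) of the phantom
    center relative to the image center; rotation is measured in the image
    plane toward increasing row index.  Edges are anti-aliased by
    ``supersample``-fold oversampling so the vision stage can recover the
    outline with sub-pixel fidelity.  Deterministic given ``seed``.
    """
    rows, cols = image_shape
    ox, oy, rot = pose
    rng = np.random.default_rng(seed)

    background = _texture((rows, cols), rng, 0.20, 0.35)
    fg_tex = _texture((rows, cols), rng, 0.70, 0.80)

    # Rectangle corners in mm, rotated about the phantom center, placed
    # relative to the image center.
    L, W = phantom.length_mm, phantom.width_mm
    cx_mm = cols * mm_per_pixel / 2.0 + ox
    cy_mm = rows * mm_per_pixel / 2.0 + oy
    theta = math.radians(rot)
    c, s = math.cos(theta), math.sin(theta)
    corners = []
    for dx, dy in ((-L / 2, -W / 2), (L / 2, -W / 2), (L / 2, W / 2), (-L / 2, W / 2)):
        corners.append((cx_mm + c * dx - s * dy, cy_mm + s * dx + c * dy))
    xs = [p[0] for p in corners]
    ys = [p[1] for p in corners]
    if min(xs) < 0 or min(ys) < 0 or max(xs) > cols * mm_per_pixel or max(ys) > rows * mm_per_pixel:
        raise GeometryError("phantom pose places the sample outside the camera frame")

    # Coverage mask rendered at supersample resolution, then box-averaged.
    ss = int(supersample)
    col_px = np.array(xs) / mm_per_pixel * ss - 0.5
    row_px = np.array(ys) / mm_per_pixel * ss - 0.5
    hi = np.zeros((rows * ss, cols * ss), dtype=float)
    rr, cc = _sk_polygon(row_px, col_px, shape=hi.shape)
    hi[rr, cc] = 1.0
    coverage = hi.reshape(rows, ss, cols, ss).mean(axis=(1, 3))

    sample = background * (1.0 - coverage) + fg_tex * coverage
    return SceneImage(sample=sample, background=background, mm_per_pixel=mm_per_pixel)


# --- per-point simulators -----------------------------------------------------


def simulate_indentation(
    k_true: float,
    config: AcquisitionConfig,
    rng: np.random.Generator | None = None,
    grid_point: tuple[float, float] = (0.0, 0.0),
) -> IndentationRecord:
    """Simulate one constant-speed indentation stopped at the force trigger.

    The probe advances at ``indentation_speed_mm_s``; the force is zero
    (noise only) until contact at ``contact_depth_mm``, then rises linearly
    with slope ``k_true``.  The record ends at the first sample whose force
    reaches ``force_trigger_n``.
    """
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    rng = rng or np.random.default_rng(config.seed)
    dz = config.indentation_speed_mm_s / config.force_sample_rate_hz
    zc = config.contact_depth_mm
    travel_needed = zc + config.force_trigger_n / k_true

    n = int(math.ceil(travel_needed / dz)) + 2
    for _ in range(32):
        z = np.arange(n) * dz
        clean = k_true * np.clip(z - zc, 0.0, None)
        force = clean.copy()
        if config.force_noise_sd_n > 0:
            force += rng.normal(0.0, config.force_noise_sd_n, size=n)
        hits = np.flatnonzero(force >= config.force_trigger_n)
        if hits.size:
            idx = int(hits[0])
            return IndentationRecord(
                grid_point=grid_point,
                force_trace=force[: idx + 1],
                z_trace=z[: idx + 1],
                trigger_index=idx,
            )
        n *= 2  # noise pulled the trace below trigger; extend deterministically
    raise RuntimeError("indentation never reached the force trigger")  # pragma: no cover


def _envelope_sigma_s(config: AcquisitionConfig) -> float:
    """Gaussian envelope sigma from the -6 dB fractional bandwidth.

    A Gaussian envelope exp(-t^2 / (2 s^2)) has an amplitude spectrum with
    -6 dB (half-amplitude) full width df = sqrt(2 ln 2) / (pi s); invert for
    s given df = fractional_bandwidth * f0.
    """
    df_hz = config.fractional_bandwidth * config.pulse_center_frequency_mhz * 1e6
    return math.sqrt(2.0 * math.log(2.0)) / (math.pi * df_hz)


def echo_model(
    phantom: Phantom, x: float, y: float, config: AcquisitionConfig
) -> tuple[float, float]:
    """Noise-free echo parameters at (x, y): (two-way time of flight s, peak amplitude).

    Time of flight crosses the layered column twice: (T - t) mm of matrix at
    its speed of sound and the inclusion chord t at the inclusion's.  The
    peak amplitude is the pulse amplitude attenuated over the two-way path
    (matrix attenuation, dB/cm, scaled linearly with frequency from its
    reference), then reduced by ``inclusion_echo_drop * t / d`` for an
    intersected inclusion of diameter d, and partially restored for
    air-bubble inclusions.
    """
    chord, inc = max_footprint_chord(
        phantom, x, y, footprint_diameter_mm=config.probe_diameter_mm
    )
    c_matrix = phantom.matrix_material.speed_of_sound_m_s
    T = phantom.thickness_mm
    if inc is not None and chord > 0:
        tof = 2.0 * ((T - chord) / 1000.0 / c_matrix + chord / 1000.0 / inc.material.speed_of_sound_m_s)
    else:
        tof = 2.0 * T / 1000.0 / c_matrix

    alpha = phantom.matrix_material.attenuation_db_cm * (
        config.pulse_center_frequency_mhz / phantom.matrix_material.attenuation_ref_mhz
    )
    a_ref = config.pulse_amplitude * 10.0 ** (-2.0 * alpha * (T / 10.0) / 20.0)
    amplitude = a_ref
    if inc is not None and chord > 0:
        amplitude = a_ref * (1.0 - config.inclusion_echo_drop * chord / inc.diameter_mm)
        if inc.has_air_bubble:
            amplitude += inc.bubble_fraction * (a_ref - amplitude)
    return tof, amplitude


def reference_echo_amplitude(phantom: Phantom, config: AcquisitionConfig) -> float:
    """Peak amplitude of the inclusion-free echo (used to scale the noise floor)."""
    alpha = phantom.matrix_material.attenuation_db_cm * (
        config.pulse_center_frequency_mhz / phantom.matrix_material.attenuation_ref_mhz
    )
    return config.pulse_amplitude * 10.0 ** (-2.0 * alpha * (phantom.thickness_mm / 10.0) / 20.0)


def simulate_ascan(
    phantom: Phantom,
    x: float,
    y: float,
    config: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> AScan:
    """Simulate the pulse-echo A-scan at surface point (x, y).

    The waveform is a cosine tone burst at the probe's center frequency
    under a Gaussian envelope whose -6 dB width matches the fractional
    bandwidth, centred at the two-way time of flight, plus white noise of
    standard deviation ``us_noise_sd`` relative to the inclusion-free echo
    peak.  Deterministic given ``rng``.
    """
    rng = rng or np.random.default_rng(config.seed)
    tof, amplitude = echo_model(phantom, x, y, config)

    fs = config.us_sample_rate_hz
    n = int(round(config.record_duration_us * 1e-6 * fs)) + 1
    waveform = np.zeros(n)

    sigma = _envelope_sigma_s(config)
    f0 = config.pulse_center_frequency_mhz * 1e6
    i0 = max(0, int(math.floor((tof - 6 * sigma) * fs)))
    i1 = min(n, int(math.ceil((tof + 6 * sigma) * fs)) + 1)
    t = np.arange(i0, i1) / fs - tof
    waveform[i0:i1] = amplitude * np.exp(-(t**2) / (2 * sigma**2)) * np.cos(2 * math.pi * f0 * t)

    if config.us_noise_sd > 0:
        sd = config.us_noise_sd * reference_echo_amplitude(phantom, config)
        waveform += rng.normal(0.0, sd, size=n)
    return AScan(grid_point=(x, y), waveform=waveform, sample_rate_hz=fs)


def point_rngs(
    config: AcquisitionConfig, x: float, y: float
) -> tuple[np.random.Generator, np.random.Generator]:
    """Per-point (force, ultrasound) noise substreams.

    Derived from (seed, x, y) via a seed sequence over micrometre-quantized
    coordinates, so the per-point noise is independent of grid ordering.
    """
    ss = np.random.SeedSequence(
        (int(config.seed) & 0x7FFFFFFF, int(round(x * 1000)), int(round(y * 1000)))
    )
    children = ss.spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def simulate_scan(
    phantom: Phantom,
    grid,
    config: AcquisitionConfig | None = None,
) -> ScanDataset:
    """Run the full automatic scan: one indentation and one A-scan per grid point."""
    config = config or AcquisitionConfig()
    grid = np.asarray(grid, dtype=float).reshape(-1, 2)
    records: list[IndentationRecord] = []
    ascans: list[AScan] = []
    for i, (x, y) in enumerate(grid):
        try:
            force_rng, us_rng = point_rngs(config, x, y)
            k_true = local_stiffness(
                phantom, x, y, footprint_diameter_mm=config.probe_diameter_mm
            )
            records.append(
                simulate_indentation(k_true, config, force_rng, grid_point=(x, y))
            )
            ascans.append(simulate_ascan(phantom, x, y, config, us_rng))
        except Exception as exc:
            raise type(exc)(
                f"scan failed at grid point {i} ({x:.2f}, {y:.2f}) mm: {exc}"
            ) from exc
    return ScanDataset(
        config=config, grid=grid, records=records, ascans=ascans, phantom_truth=phantom
    )


# --- dataset I/O --------------------------------------------------------------


def save_dataset(dataset: ScanDataset, directory, waveform_format: str = "npy") -> None:
    """Write a scan dataset: YAML manifest, grid TSV, trace/waveform arrays.

    ``waveform_format`` is ``"npy"`` (compact ``numpy.savez``; documented
    binary sidecar) or ``"tsv"`` (plain delimited text, one file per kind).
    Round-trips losslessly to float precision via :func:`load_dataset`.
    """
    import pathlib

    import yaml

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    manifest = {
        "format_version": 1,
        "waveform_format": waveform_format,
        "config": dataset.config.to_dict(),
        "n_points": int(len(dataset.grid)),
        "trigger_indices": [int(r.trigger_index) for r in dataset.records],
        "us_sample_rate_hz": float(dataset.config.us_sample_rate_hz),
    }
    if dataset.phantom_truth is not None:
        from .phantom import phantom_to_dict

        manifest["phantom_truth"] = phantom_to_dict(dataset.phantom_truth)
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    np.savetxt(
        directory / "grid.tsv",
        dataset.grid,
        delimiter="\t",
        header="x_mm\ty_mm",
        comments="",
    )

    if waveform_format == "npy":
        arrays = {}
        for i, (rec, scan) in enumerate(zip(dataset.records, dataset.ascans)):
            arrays[f"force_{i}"] = rec.force_trace
            arrays[f"z_{i}"] = rec.z_trace
            arrays[f"ascan_{i}"] = scan.waveform
        np.savez(directory / "signals.npz", **arrays)
    elif waveform_format == "tsv":
        with open(directory / "indentations.tsv", "w") as fh:
            fh.write("point\tz_mm\tforce_n\n")
            for i, rec in enumerate(dataset.records):
                for z, f in zip(rec.z_trace, rec.force_trace):
                    fh.write(f"{i}\t{float(z)!r}\t{float(f)!r}\n")
        with open(directory / "ascans.tsv", "w") as fh:
            fh.write("point\tamplitude\n")
            for i, scan in enumerate(dataset.ascans):
                for a in scan.waveform:
                    fh.write(f"{i}\t{float(a)!r}\n")
    else:
        raise ValueError("waveform_format must be 'npy' or 'tsv'")


def load_dataset(directory) -> ScanDataset:
    import pathlib

    import yaml

    directory = pathlib.Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    config = AcquisitionConfig.from_dict(manifest["config"])
    grid = np.loadtxt(directory / "grid.tsv", delimiter="\t", skiprows=1).reshape(-1, 2)
    triggers = manifest["trigger_indices"]
    n = manifest["n_points"]

    records: list[IndentationRecord] = []
    ascans: list[AScan] = []
    if manifest["waveform_format"] == "npy":
        with np.load(directory / "signals.npz") as data:
            for i in range(n):
                records.append(
                    IndentationRecord(
                        grid_point=tuple(grid[i]),
                        force_trace=data[f"force_{i}"],
                        z_trace=data[f"z_{i}"],
                        trigger_index=triggers[i],
                    )
                )
                ascans.append(
                    AScan(
                        grid_point=tuple(grid[i]),
                        waveform=data[f"ascan_{i}"],
                        sample_rate_hz=config.us_sample_rate_hz,
                    )
                )
    else:
        import pandas as pd

        ind = pd.read_csv(directory / "indentations.tsv", sep="\t", float_precision="round_trip")
        asc = pd.read_csv(directory / "ascans.tsv", sep="\t", float_precision="round_trip")
        for i in range(n):
            sel = ind[ind["point"] == i]
            records.append(
                IndentationRecord(
                    grid_point=tuple(grid[i]),
                    force_trace=sel["force_n"].to_numpy(),
                    z_trace=sel["z_mm"].to_numpy(),
                    trigger_index=triggers[i],
                )
            )
            ascans.append(
                AScan(
                    grid_point=tuple(grid[i]),
                    waveform=asc[asc["point"] == i]["amplitude"].to_numpy(),
                    sample_rate_hz=config.us_sample_rate_hz,
                )
            )

    phantom = None
    if "phantom_truth" in manifest:
        from .phantom import phantom_from_dict

        phantom = phantom_from_dict(manifest["phantom_truth"])
    return ScanDataset(
        config=config, grid=grid, records=records, ascans=ascans, phantom_truth=phantom
    )
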