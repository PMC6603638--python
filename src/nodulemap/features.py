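"""Per-point detection features: stiffness k and Correlation Index Amplitude.

Stiffness is the secant slope of the indentation force-position curve
between first contact and the force trigger,

    k = dFz / dZ = (Fz_max - Fz_0) / (Z_at_Fz_max - Z_at_Fz_0)   [N/mm],

where Fz_max is the force at the 0.2 N trigger and Fz_0 the first force
sample past a small contact threshold.

The ultrasound feature is the Correlation Index Amplitude (CIA), an
energy-ratio dissimilarity between the A-scan S_i at a point and a
reference A-scan S_ref acquired where no inclusion is present:

    CIA = 1 - min(sum S_ref^2, sum S_i^2) / max(sum S_ref^2, sum S_i^2).

CIA is 0 for equal-energy signals and approaches 1 when the echo energy
collapses, as it does over inclusions under the reflectometric model.
Energies are summed over the full recorded window (no gating).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scan_sim import AScan, IndentationRecord, ScanDataset

__all__ = [
    "StiffnessEstimate",
    "CiaEstimate",
    "FeatureMaps",
    "UnusableRecordError",
    "estimate_stiffness",
    "compute_cia",
    "select_reference",
    "build_feature_maps",
    "save_feature_maps",
    "load_feature_maps",
]

#: Default contact threshold (N): well above load-cell noise, well below the trigger.
DEFAULT_CONTACT_THRESHOLD_N = 0.02


class UnusableRecordError(ValueError):
    """Raised when a record cannot yield a stiffness or CIA estimate."""


@dataclass(frozen=True)
class StiffnessEstimate:
    """Secant stiffness with the four samples it was computed from."""

    k_n_mm: float
    fz0_n: float
    fzmax_n: float
    z_at_fz0_mm: float
    z_at_fzmax_mm: float

    def __post_init__(self) -> None:
        if not (self.z_at_fzmax_mm > self.z_at_fz0_mm):
            raise UnusableRecordError("no displacement between contact and trigger")
        if not (self.fzmax_n > self.fz0_n >= 0):
            raise UnusableRecordError("force did not increase between contact and trigger")
        if not (self.k_n_mm > 0):
            raise UnusableRecordError("non-positive stiffness")


@dataclass(frozen=True)
class CiaEstimate:
    cia: float
    energy_signal: float
    energy_reference: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cia <= 1.0):
            raise ValueError("CIA must lie in [0, 1]")


@dataclass
class FeatureMaps:
    """Grid-aligned stiffness and CIA values plus the reference-scan index."""

    points: np.ndarray  # (n, 2) mm
    k_values: np.ndarray
    cia_values: np.ndarray
    reference_index: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.k_values = np.asarray(self.k_values, dtype=float)
        self.cia_values = np.asarray(self.cia_values, dtype=float)
        if not (len(self.points) == len(self.k_values) == len(self.cia_values)):
            raise ValueError("feature arrays must align with the grid")
        if not (0 <= self.reference_index < len(self.points)):
            raise ValueError("reference_index out of range")


def estimate_stiffness(
    record: IndentationRecord,
    contact_threshold_n: float = DEFAULT_CONTACT_THRESHOLD_N,
) -> StiffnessEstimate:
    """Estimate the secant stiffness from one indentation record.

    Contact (Fz_0) is the first sample whose force reaches
    ``contact_threshold_n`` and whose successor stays above 80 % of it —
    the two-sample confirmation rejects isolated load-cell noise spikes.
    Fz_max is the force at the trigger index.
    """
    f = record.force_trace
    z = record.z_trace
    trig = record.trigger_index
    if contact_threshold_n >= f[trig]:
        raise UnusableRecordError(
            "contact threshold must lie below the trigger force"
        )
    above = f >= contact_threshold_n
    confirmed = above.copy()
    confirmed[:-1] &= f[1:] >= 0.8 * contact_threshold_n
    candidates = np.flatnonzero(confirmed[:trig])
    if candidates.size == 0:
        raise UnusableRecordError("contact never detected before the trigger")
    i0 = int(candidates[0])
    if z[trig] <= z[i0]:
        raise UnusableRecordError("zero displacement between contact and trigger")
    k = (f[trig] - f[i0]) / (z[trig] - z[i0])
    return StiffnessEstimate(
        k_n_mm=float(k),
        fz0_n=float(f[i0]),
        fzmax_n=float(f[trig]),
        z_at_fz0_mm=float(z[i0]),
        z_at_fzmax_mm=float(z[trig]),
    )


def compute_cia(signal: AScan, reference: AScan) -> CiaEstimate:
    """Correlation Index Amplitude between a test A-scan and the reference."""
    e_sig = signal.energy
    e_ref = reference.energy
    if e_sig == 0.0 and e_ref == 0.0:
        raise UnusableRecordError("CIA undefined: both signals have zero energy")
    lo, hi = min(e_sig, e_ref), max(e_sig, e_ref)
    return CiaEstimate(cia=1.0 - lo / hi, energy_signal=e_sig, energy_reference=e_ref)


def select_reference(ascans: list[AScan]) -> int:
    """Index of the maximum-energy A-scan, the inclusion-free proxy.

    Under the reflectometric model inclusions only remove echo energy, so
    the strongest echo is the best available stand-in for a position known
    to be free of inclusions.  Ties break toward the lowest index.
    """
    if not ascans:
        raise ValueError("need at least one A-scan")
    energies = np.array([a.energy for a in ascans])
    if np.all(energies == 0.0):
        raise UnusableRecordError("no usable reference: all A-scans have zero energy")
    return int(np.argmax(energies))


def build_feature_maps(
    dataset: ScanDataset,
    contact_threshold_n: float | None = None,
    reference_index: int | None = None,
) -> FeatureMaps:
    """Compute the stiffness map and the CIA map for a whole scan.

    The contact threshold defaults to max(0.02 N, 5 x force-noise sd).  The
    CIA reference defaults to the maximum-energy A-scan but can be pinned
    to an explicit index (e.g. a position known to be inclusion-free).
    """
    if contact_threshold_n is None:
        contact_threshold_n = max(
            DEFAULT_CONTACT_THRESHOLD_N, 5.0 * dataset.config.force_noise_sd_n
        )
    if reference_index is None:
        reference_index = select_reference(dataset.ascans)
    reference = dataset.ascans[reference_index]

    n = len(dataset.grid)
    k_values = np.empty(n)
    cia_values = np.empty(n)
    for i in range(n):
        try:
            k_values[i] = estimate_stiffness(
                dataset.records[i], contact_threshold_n
            ).k_n_mm
            cia_values[i] = compute_cia(dataset.ascans[i], reference).cia
        except UnusableRecordError as exc:
            x, y = dataset.grid[i]
            raise UnusableRecordError(
                f"feature extraction failed at grid point {i} ({x:.2f}, {y:.2f}) mm: {exc}"
            ) from exc
    return FeatureMaps(
        points=dataset.grid,
        k_values=k_values,
        cia_values=cia_values,
        reference_index=reference_index,
    )


def save_feature_maps(maps: FeatureMaps, path) -> None:
    """Write both feature maps as one delimited text table with a header."""
    with open(path, "w") as fh:
        fh.write("# units: x_mm y_mm k_n_mm cia\n")
        fh.write(f"# reference_index: {maps.reference_index}\n")
        fh.write("x_mm\ty_mm\tk_n_mm\tcia\n")
        for (x, y), k, cia in zip(maps.points, maps.k_values, maps.cia_values):
            fh.write(f"{float(x)!r}\t{float(y)!r}\t{float(k)!r}\t{float(cia)!r}\n")


def load_feature_maps(path) -> FeatureMaps:
    reference_index = None
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "reference_index:" in line:
                    reference_index = int(line.split(":", 1)[1])
                continue
            if line.strip() and not line.startswith("x_mm"):
                rows.append([float(v) for v in line.split("\t")])
    if reference_index is None:
        raise ValueError("feature map file missing reference_index header")
    arr = np.array(rows)
    return FeatureMaps(
        points=arr[:, :2],
        k_values=arr[:, 2],
        cia_values=arr[:, 3],
        reference_index=reference_index,
    )
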