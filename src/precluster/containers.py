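"""Shared data containers for correlation curves, size distributions,
intensity traces, melting curves and particle-coordinate frame sets.

These are thin, validated wrappers around numpy arrays with CSV / plain-text
round-trip support, shared by the light-scattering (DLS), fluorescence
correlation (FCS), burst, microfluidic-counting and trajectory stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationCurve",
    "SizeDistribution",
    "ClusterSizeHistogram",
    "IntensityTrace",
    "MeltingCurve",
    "Frame",
    "TrajectoryFrameSet",
]

_CURVE_KINDS = ("field", "intensity", "fluorescence")


@dataclass
class CorrelationCurve:
    """A lag-time/correlation curve with optional per-point uncertainties.

    Parameters
    ----------
    lags : array
        Lag times, strictly increasing and positive. Milliseconds for
        fluorescence correlation; microseconds-to-milliseconds for light
        scattering (the unit is carried by convention, not enforced).
    values : array
        Correlation amplitudes.
    errors : array, optional
        Per-point standard errors (>= 0). Zero errors mean "unweighted".
    kind : {"field", "intensity", "fluorescence"}
        "field" is the first-order (g1) correlation, "intensity" the
        Siegert-form intensity correlation G = 1 + b*g1**2, and
        "fluorescence" the FCS autocorrelation G(t_c).
    """

    lags: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None
    kind: str = "fluorescence"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
        if self.kind not in _CURVE_KINDS:
            raise ValueError(f"kind must be one of {_CURVE_KINDS}, got {self.kind!r}")
        if self.lags.ndim != 1 or self.lags.shape != self.values.shape:
            raise ValueError("lags and values must be 1-D arrays of equal length")
        if self.errors is not None and self.errors.shape != self.lags.shape:
            raise ValueError("errors must match lags in length")
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if self.errors is not None and np.any(self.errors < 0):
            raise ValueError("errors must be non-negative")

    def __len__(self) -> int:
        return self.lags.size

    def weights(self) -> np.ndarray:
        """Least-squares weights 1/err**2; unit weights where errors are
        absent or zero."""
        if self.errors is None or np.all(self.errors == 0):
            return np.ones_like(self.values)
        # points with a zero error in an otherwise weighted curve get zero
        # weight rather than infinite leverage
        err = np.where(self.errors > 0, self.errors, np.inf)
        return 1.0 / err**2

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "lag_ms": self.lags,
                "g": self.values,
                "err": self.errors if self.errors is not None else np.zeros_like(self.lags),
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "fluorescence") -> "CorrelationCurve":
        df = pd.read_csv(path)
        err = df["err"].to_numpy() if "err" in df.columns else None
        return cls(df["lag_ms"].to_numpy(), df["g"].to_numpy(), err, kind=kind)


@dataclass
class SizeDistribution:
    """Hydrodynamic-diameter distribution on a fixed grid.

    ``weighting`` records whether ``weights`` are proportional to scattered
    intensity or to particle number; the DLS inversion flips this flag.
    The default bin width is 0.1 nm.
    """

    d_h: np.ndarray  # nm, increasing
    weights: np.ndarray
    weighting: str = "intensity"  # or "number"
    bin_width: float = 0.1  # nm

    def __post_init__(self) -> None:
        self.d_h = np.asarray(self.d_h, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weighting not in ("intensity", "number"):
            raise ValueError("weighting must be 'intensity' or 'number'")
        if self.d_h.size == 0:
            raise ValueError("empty size distribution")
        if self.d_h.shape != self.weights.shape:
            raise ValueError("d_h and weights must have equal length")
        if np.any(np.diff(self.d_h) <= 0):
            raise ValueError("d_h grid must be strictly increasing")
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    def normalized(self) -> "SizeDistribution":
        total = self.weights.sum()
        if total == 0:
            raise ValueError("cannot normalize an all-zero distribution")
        return SizeDistribution(self.d_h, self.weights / total, self.weighting, self.bin_width)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"d_h_nm": self.d_h, "weight": self.weights}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, weighting: str = "intensity") -> "SizeDistribution":
        df = pd.read_csv(path)
        return cls(df["d_h_nm"].to_numpy(), df["weight"].to_numpy(), weighting)


@dataclass
class ClusterSizeHistogram:
    """Frequencies of cluster occupancy n (molecules per cluster) obtained
    from a hydrodynamic-diameter distribution under a spherical packing
    model with packing fraction p."""

    n: np.ndarray
    frequencies: np.ndarray
    packing_fraction: float
    monomer_diameter: float  # nm

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if not (0 < self.packing_fraction <= 0.74):
            raise ValueError("packing fraction must be in (0, 0.74]")
        if np.any(self.n <= 0):
            raise ValueError("cluster occupancies must be positive")


@dataclass
class IntensityTrace:
    """Binned photon-count trace, optionally with per-photon delay times."""

    bin_times: np.ndarray  # s, left edges, uniform
    counts: np.ndarray  # photons per bin
    bin_width: float  # ms
    photon_delays: np.ndarray | None = None  # ns, per-photon TCSPC delays

    def __post_init__(self) -> None:
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_times.shape != self.counts.shape:
            raise ValueError("bin_times and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_times.size > 1:
            steps = np.diff(self.bin_times)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise ValueError("bins must be uniform")

    def __len__(self) -> int:
        return self.counts.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.bin_times, "counts": self.counts}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, bin_width_ms: float | None = None) -> "IntensityTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if bin_width_ms is None:
            bin_width_ms = float(np.diff(t)[0] * 1e3) if t.size > 1 else 1.0
        return cls(t, df["counts"].to_numpy(), bin_width_ms)


@dataclass
class MeltingCurve:
    """Temperature ramp of the intrinsic-fluorescence 350/330 nm ratio."""

    temperature: np.ndarray  # deg C, strictly increasing
    ratio: np.ndarray  # F350/F330
    replicate: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.temperature.size < 5:
            raise ValueError("melting curve needs at least 5 temperature points")
        if self.temperature.shape != self.ratio.shape:
            raise ValueError("temperature and ratio must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if np.any(~np.isfinite(self.ratio)):
            raise ValueError("ratio values must be finite")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"temp_C": self.temperature, "ratio": self.ratio}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, replicate: str = "") -> "MeltingCurve":
        df = pd.read_csv(path)
        if "ratio" in df.columns:
            ratio = df["ratio"].to_numpy()
        else:
            ratio = df["f350"].to_numpy() / df["f330"].to_numpy()
        return cls(df["temp_C"].to_numpy(), ratio, replicate)


@dataclass
class Frame:
    """One coordinate frame: peptide sites plus ion and water positions in an
    orthorhombic periodic box. Positions in nm, masses in amu."""

    peptide_xyz: np.ndarray  # (n_sites, 3)
    peptide_masses: np.ndarray  # (n_sites,)
    anion_xyz: np.ndarray
    cation_xyz: np.ndarray
    water_xyz: np.ndarray  # oxygen-site positions
    box: np.ndarray  # (3,) edge lengths, nm

    def __post_init__(self) -> None:
        for name in ("peptide_xyz", "anion_xyz", "cation_xyz", "water_xyz"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(-1, 3)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite positions")
        self.peptide_masses = np.asarray(self.peptide_masses, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if self.peptide_masses.size != self.peptide_xyz.shape[0]:
            raise ValueError("one mass per peptide site required")

    def center_of_mass(self) -> np.ndarray:
        m = self.peptide_masses
        return (self.peptide_xyz * m[:, None]).sum(axis=0) / m.sum()


@dataclass
class TrajectoryFrameSet:
    """A set of frames from one or more replicates of the same system.

    ``replicates`` maps a replicate label to its list of frames; species
    counts are constant within a replicate. ``net_charge`` is the peptide
    net charge Z in elementary charges. ``ground_truth`` optionally carries
    analytic expectations attached by the synthetic generator.
    """

    replicates: dict[str, list[Frame]]
    net_charge: float = 0.0
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("at least one replicate required")
        for label, frames in self.replicates.items():
            if not frames:
                raise ValueError(f"replicate {label!r} has no frames")
            counts = {(f.anion_xyz.shape[0], f.cation_xyz.shape[0], f.water_xyz.shape[0]) for f in frames}
            if len(counts) != 1:
                raise ValueError(f"species counts vary across frames of replicate {label!r}")

    @property
    def all_frames(self) -> list[Frame]:
        return [f for frames in self.replicates.values() for f in frames]

    def write_xyz(self, path: str | Path) -> None:
        """Write all frames to a plain-text XYZ-like format: one block per
        frame, header comment carries the box edges and replicate label."""
        with open(path, "w") as fh:
            for label, frames in self.replicates.items():
                for frame in frames:
                    n = (
                        frame.peptide_xyz.shape[0]
                        + frame.anion_xyz.shape[0]
                        + frame.cation_xyz.shape[0]
                        + frame.water_xyz.shape[0]
                    )
                    fh.write(f"{n}\n")
                    bx, by, bz = frame.box
                    fh.write(f"# box {bx:.6f} {by:.6f} {bz:.6f} replicate {label} Z {self.net_charge}\n")
                    for xyz, mass in zip(frame.peptide_xyz, frame.peptide_masses):
                        fh.write(f"P {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f} {mass:.4f}\n")
                    for tag, arr in (("A", frame.anion_xyz), ("C", frame.cation_xyz), ("W", frame.water_xyz)):
                        for xyz in arr:
                            fh.write(f"{tag} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")

    @classmethod
    def read_xyz(cls, path: str | Path) -> "TrajectoryFrameSet":
        replicates: dict[str, list[Frame]] = {}
        net_charge = 0.0
        with open(path) as fh:
            lines = fh.read().split("\n")
        i = 0
        while i < len(lines) and lines[i].strip():
            n = int(lines[i])
            header = lines[i + 1].split()
            box = np.array([float(header[2]), float(header[3]), float(header[4])])
            label = header[6]
            net_charge = float(header[8])
            pep, masses, ani, cat, wat = [], [], [], [], []
            for row in lines[i + 2 : i + 2 + n]:
                parts = row.split()
                xyz = [float(parts[1]), float(parts[2]), float(parts[3])]
                if parts[0] == "P":
                    pep.append(xyz)
                    masses.append(float(parts[4]))
                elif parts[0] == "A":
                    ani.append(xyz)
                elif parts[0] == "C":
                    cat.append(xyz)
                else:
                    wat.append(xyz)
            frame = Frame(
                np.array(pep), np.array(masses), np.array(ani) if ani else np.empty((0, 3)),
                np.array(cat) if cat else np.empty((0, 3)),
                np.array(wat) if wat else np.empty((0, 3)), box,
            )
            replicates.setdefault(label, []).append(frame)
            i += 2 + n
        return cls(replicates, net_charge=net_charge)
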