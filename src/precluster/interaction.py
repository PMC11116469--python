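"""Preferential interaction coefficients and radial distribution functions
from particle coordinate frames.

The local-bulk partitioning formalism quantifies the excess of a cosolute
species near a solute relative to its bulk ratio with water:

    Gamma_ion(r) = N_ion(r) - N_H2O(r) * (N_ion,bulk / N_H2O,bulk)

where N_X(r) is the cumulative number of X within distance r of the
peptide's center of mass and the bulk ratio comes from a spherical shell
far from the peptide (2.5-3.38 nm by default). Negative Gamma means
preferential exclusion. The whole-salt coefficient combines the ion
profiles with the peptide net charge Z:

    Gamma_salt(r) = 0.5 * (Gamma_anion(r) + Gamma_cation(r) - |Z|)

Distances use the minimum-image convention in orthorhombic boxes; water
positions are the oxygen sites. Profiles are binned at 0.2 A by default
and errors are the standard error of the mean over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .containers import Frame, TrajectoryFrameSet

__all__ = [
    "GammaProfile",
    "minimum_image_distances",
    "radial_counts",
    "gamma_ion_profile",
    "gamma_salt",
    "rdf",
]

_SPECIES_ATTR = {"anion": "anion_xyz", "cation": "cation_xyz", "water": "water_xyz"}


def minimum_image_distances(positions: np.ndarray, center: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distances from ``center`` in an orthorhombic box."""
    delta = positions - center
    delta -= box * np.round(delta / box)
    return np.linalg.norm(delta, axis=1)


def _r_edges(r_max_A: float, bin_A: float) -> np.ndarray:
    n_bins = int(np.ceil(r_max_A / bin_A))
    return np.arange(n_bins + 1) * bin_A


def radial_counts(
    frames: TrajectoryFrameSet | list[Frame],
    species: str,
    bin_A: float = 0.2,
    r_max_A: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative species counts N(r) around the peptide center of mass.

    Returns (r_edges_A[1:], counts) with ``counts`` of shape
    (n_frames, n_bins): per-frame cumulative counts within each outer bin
    edge. Warns if the grid extends beyond half the box edge, where the
    minimum-image distance is ambiguous.
    """
    frame_list = frames.all_frames if isinstance(frames, TrajectoryFrameSet) else frames
    if species not in _SPECIES_ATTR:
        raise ValueError(f"species must be one of {sorted(_SPECIES_ATTR)}")
    box_min = min(f.box.min() for f in frame_list)
    if r_max_A is None:
        r_max_A = box_min / 2.0 * 10.0  # nm -> A
    if r_max_A > box_min / 2.0 * 10.0 + 1e-9:
        warnings.warn("r grid exceeds half the box edge: minimum-image distances are ambiguous")
    edges = _r_edges(r_max_A, bin_A)
    out = np.empty((len(frame_list), edges.size - 1))
    for i, frame in enumerate(frame_list):
        pos = getattr(frame, _SPECIES_ATTR[species])
        dist_A = minimum_image_distances(pos, frame.center_of_mass(), frame.box) * 10.0
        hist, _ = np.histogram(dist_A, bins=edges)
        out[i] = np.cumsum(hist)
    return edges[1:], out


@dataclass
class GammaProfile:
    r_A: np.ndarray
    gamma: np.ndarray
    sem: np.ndarray
    bulk_ratio: float
    species: str

    def __post_init__(self) -> None:
        if np.any(self.sem < 0):
            raise ValueError("SEM must be non-negative")


def gamma_ion_profile(
    frames: TrajectoryFrameSet,
    species: str,
    bulk_shell_nm: tuple[float, float] = (2.5, 3.38),
    bin_A: float = 0.2,
    r_max_A: float | None = None,
    per_frame_ratio: bool = False,
) -> GammaProfile:
    """Preferential interaction coefficient profile Gamma_species(r).

    Each replicate is analysed independently: its bulk ion/water ratio is
    pooled over that replicate's frames (``per_frame_ratio=True`` switches
    to per-frame ratios), Gamma is computed per frame and averaged within
    the replicate, and the SEM is taken across the independent replicate
    means (across frames if there is only one replicate). Keeping the
    ratio within-replicate makes the replicate means iid, so the SEM
    covers the bulk-ratio uncertainty as well.
    """
    lo_A, hi_A = bulk_shell_nm[0] * 10.0, bulk_shell_nm[1] * 10.0
    replicate_means = []
    ratios = []
    r_out = None
    single_rep_frames = None
    for label, frame_list in frames.replicates.items():
        r, n_ion = radial_counts(frame_list, species, bin_A, r_max_A)
        _, n_wat = radial_counts(frame_list, "water", bin_A, r_max_A)
        r_out = r
        # map the shell bounds to the nearest cumulative-count edges
        i_lo = int(round(lo_A / bin_A)) - 1
        i_hi = min(int(round(hi_A / bin_A)) - 1, r.size - 1)
        if not (0 <= i_lo < i_hi):
            raise ValueError("bulk shell does not fit the radial grid")
        shell_ion = n_ion[:, i_hi] - n_ion[:, i_lo]
        shell_wat = n_wat[:, i_hi] - n_wat[:, i_lo]
        if shell_wat.sum() == 0:
            raise ValueError("bulk shell contains no water molecules")
        rep_ratio = shell_ion.sum() / shell_wat.sum()
        ratios.append(rep_ratio)
        if per_frame_ratio:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(shell_wat > 0, shell_ion / np.maximum(shell_wat, 1), rep_ratio)
            gamma_frames = n_ion - n_wat * ratio[:, None]
        else:
            gamma_frames = n_ion - n_wat * rep_ratio
        replicate_means.append(gamma_frames.mean(axis=0))
        single_rep_frames = gamma_frames
    stack = np.vstack(replicate_means)
    if stack.shape[0] > 1:
        gamma = stack.mean(axis=0)
        sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    else:
        gamma_frames = single_rep_frames
        gamma = gamma_frames.mean(axis=0)
        nf = gamma_frames.shape[0]
        sem = gamma_frames.std(axis=0, ddof=1) / np.sqrt(nf) if nf > 1 else np.zeros_like(gamma)
    return GammaProfile(
        r_A=r_out, gamma=gamma, sem=sem, bulk_ratio=float(np.mean(ratios)), species=species
    )


def gamma_salt(anion: GammaProfile, cation: GammaProfile, net_charge: float) -> GammaProfile:
    """Whole-salt coefficient 0.5 (Gamma_anion + Gamma_cation - |Z|); SEM
    propagated in quadrature."""
    if anion.r_A.shape != cation.r_A.shape or not np.allclose(anion.r_A, cation.r_A):
        raise ValueError("anion and cation profiles must share the same r grid")
    gamma = 0.5 * (anion.gamma + cation.gamma - abs(net_charge))
    sem = 0.5 * np.sqrt(anion.sem**2 + cation.sem**2)
    return GammaProfile(r_A=anion.r_A, gamma=gamma, sem=sem,
                        bulk_ratio=float("nan"), species="salt")


def _pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray, same: bool) -> np.ndarray:
    delta = a[:, None, :] - b[None, :, :]
    delta -= box * np.round(delta / box)
    d = np.linalg.norm(delta, axis=-1)
    if same:
        iu = np.triu_indices(d.shape[0], k=1)
        return d[iu]
    return d.ravel()


def rdf(
    frames: TrajectoryFrameSet | list[Frame],
    species_a: str,
    species_b: str,
    bin_A: float = 0.2,
    r_max_A: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g_AB(r) between two species.

    Standard ideal-gas shell normalization at the observed number density;
    self-pairs are excluded when A and B are the same species. Returns
    (bin centers in A, g values).
    """
    frame_list = frames.all_frames if isinstance(frames, TrajectoryFrameSet) else frames
    same = species_a == species_b
    box_min = min(f.box.min() for f in frame_list)
    if r_max_A is None:
        r_max_A = box_min / 2.0 * 10.0
    edges = _r_edges(r_max_A, bin_A)
    counts = np.zeros(edges.size - 1)
    norm = 0.0
    for frame in frame_list:
        a = getattr(frame, _SPECIES_ATTR[species_a])
        b = getattr(frame, _SPECIES_ATTR[species_b])
        if a.shape[0] == 0 or b.shape[0] == 0:
            raise ValueError("empty selection for rdf")
        d_A = _pair_distances(a, b, frame.box, same) * 10.0
        hist, _ = np.histogram(d_A, bins=edges)
        counts += hist
        vol_A3 = np.prod(frame.box) * 1e3  # nm^3 -> A^3
        n_pairs = a.shape[0] * (b.shape[0] - 1) / 2.0 if same else a.shape[0] * b.shape[0]
        norm += n_pairs / vol_A3
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = norm * shell_vol
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g
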