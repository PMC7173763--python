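"""Per-frame gating order parameters for a tetrameric pore domain.

Three observables distinguish the open (conducting) from the closed pore:

* the number of water molecules inside the central cavity — a wetted cavity
  marks the open channel, a dewetted one the closed channel;
* the S6 kink dihedral, the torsion of four Cα atoms spanning the PVP hinge
  (L393, L400, V408, Y415): ~130° for a bent (open) helix, a secondary
  population near 245° for a straightened (closed) helix;
* the inter-subunit R326-H418 nearest-atom distance, which lengthens when
  protonation breaks the salt-bridge network (~6 Å open, ~15 Å closed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import EmptyInputError, GeometryError, ResidueResolutionError
from .io import (
    WATER_RESIDUE_NAMES,
    AnalysisConfig,
    ResidueSpec,
    StructureFrame,
)

logger = logging.getLogger(__name__)

_COLLINEAR_TOL = 1e-9


@dataclass(frozen=True)
class CavityRegion:
    """A cylindrical cavity selection.

    Axial coordinates are projections onto ``axis_direction`` (a unit
    vector); a point belongs to the region when its axial coordinate lies in
    ``[z_low, z_high]`` and its radial distance from the axis line through
    ``axis_point`` is at most ``radius`` (boundaries inclusive).
    """

    axis_point: tuple[float, float, float]
    axis_direction: tuple[float, float, float]
    z_low: float
    z_high: float
    radius: float

    def __post_init__(self) -> None:
        d = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise GeometryError("axis_direction must be unit-norm")
        if self.radius <= 0:
            raise GeometryError("radius must be > 0")
        if not self.z_low < self.z_high:
            raise GeometryError("z_low must be < z_high")


def _residue_ca_centroid(
    frame: StructureFrame, residue_numbers: Sequence[int], chains: Sequence[str]
) -> np.ndarray:
    coords = []
    for res in residue_numbers:
        for chain in chains:
            coords.append(ResidueSpec(chain, res, "CA").resolve(frame).mean(axis=0))
    return np.mean(coords, axis=0)


def define_cavity_region(frame: StructureFrame, config: AnalysisConfig) -> CavityRegion:
    """Build the cavity cylinder from marker residues of one frame.

    The axis point is the centroid of the four axis-residue Cα atoms (one
    per chain); the upper/lower axial bounds are the axial coordinates of
    the Cα centroids of the filter-base and gate residue sets.
    """
    chains = config.ring_order
    d = np.asarray(config.axis_direction, dtype=float)
    axis_point = _residue_ca_centroid(frame, [config.cavity_axis_residue_number], chains)
    upper = _residue_ca_centroid(frame, config.cavity_filter_residue_numbers, chains)
    lower = _residue_ca_centroid(frame, config.cavity_gate_residue_numbers, chains)
    z_high = float(upper @ d)
    z_low = float(lower @ d)
    if z_low > z_high:
        z_low, z_high = z_high, z_low
    return CavityRegion(
        axis_point=tuple(axis_point),
        axis_direction=tuple(d),
        z_low=z_low,
        z_high=z_high,
        radius=config.cavity_radius,
    )


def count_cavity_waters(frame: StructureFrame, region: CavityRegion) -> int:
    """Number of water oxygens inside the cavity cylinder (bounds inclusive)."""
    water = np.isin(frame.residue_names, list(WATER_RESIDUE_NAMES)) & (
        frame.elements == "O"
    )
    if not water.any():
        logger.warning(
            "frame %d contains no water oxygen atoms", frame.frame_index
        )
        return 0
    p = frame.coords[water]
    d = np.asarray(region.axis_direction)
    a = np.asarray(region.axis_point)
    z = p @ d
    radial = np.linalg.norm((p - a) - np.outer((p - a) @ d, d), axis=1)
    inside = (z >= region.z_low) & (z <= region.z_high) & (radial <= region.radius)
    return int(inside.sum())


def torsion_angle_deg(p1, p2, p3, p4) -> float:
    """Signed torsion of four points, mapped into [0, 360) degrees.

    Uses the plane-normal convention: b1 = p2-p1, b2 = p3-p2, b3 = p4-p3;
    the angle between n1 = b1 x b2 and n2 = b2 x b3 with the sign taken from
    the component of n1 x n2 along b2.  A planar cis arrangement gives 0°,
    trans gives 180°.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise GeometryError("collinear bond vectors: torsion undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ b2n)
    theta = np.degrees(np.arctan2(y, x))
    return float(theta % 360.0)


def compute_kink_dihedral(
    frame: StructureFrame,
    residue_numbers: Sequence[int],
    chain: str,
) -> float:
    """S6 kink dihedral (degrees in [0, 360)) from four Cα atoms of one chain."""
    if len(residue_numbers) != 4:
        raise ValueError("exactly four residues define the kink dihedral")
    points = []
    for res in residue_numbers:
        coords = ResidueSpec(chain, res, "CA").resolve(frame)
        if coords.shape[0] != 1:
            raise ResidueResolutionError(
                f"residue {chain}:{res} resolves to {coords.shape[0]} Cα atoms "
                f"(expected exactly 1) in frame {frame.frame_index}"
            )
        points.append(coords[0])
    return torsion_angle_deg(*points)


def compute_pair_min_distance(
    frame: StructureFrame,
    spec_a: ResidueSpec,
    spec_b: ResidueSpec,
) -> float:
    """Minimum Euclidean distance (Å) over all atom pairs of two selections."""
    a = spec_a.resolve(frame)
    b = spec_b.resolve(frame)
    return float(cdist(a, b).min())


def extract_series(
    frames: Sequence[StructureFrame],
    config: AnalysisConfig,
    variant_label: str = "",
) -> pd.DataFrame:
    """Compute all order parameters for every frame of one trajectory.

    Returns a wide DataFrame with one row per frame: the cavity water count,
    the kink dihedral of each chain, and the nearest-atom distance for every
    ordered adjacent chain pair ``(i -> next)`` in the ring (R326 of chain i
    against H418 of the next chain).
    """
    if len(frames) == 0:
        raise EmptyInputError("extract_series requires at least one frame")
    pairs = config.adjacent_pairs()
    records = []
    for frame in frames:
        region = define_cavity_region(frame, config)
        rec: dict = {
            "frame_index": frame.frame_index,
            "time_ns": frame.time_ns if frame.time_ns is not None else float(frame.frame_index),
            "variant": variant_label,
            "n_waters": count_cavity_waters(frame, region),
        }
        for chain in config.ring_order:
            rec[f"dihedral_deg_{chain}"] = compute_kink_dihedral(
                frame, config.dihedral_residue_numbers, chain
            )
        for ca, cb in pairs:
            rec[f"dist_A_{ca}{cb}"] = compute_pair_min_distance(
                frame,
                ResidueSpec(ca, config.distance_residue_a, config.distance_atom_subset),
                ResidueSpec(cb, config.distance_residue_b, config.distance_atom_subset),
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)
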