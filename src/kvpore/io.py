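"""Reading and writing of trajectory frames, energy tables, series and configs.

Trajectory frames travel as multi-model PDB files (the common interchange
format for ensemble structures), per-microstate energies as flat CSV tables,
order-parameter series as tidy CSV, and run configuration as flat YAML.
PDB parsing and writing are delegated to biotite; a line-level pre-scan
enforces the fixed-column dialect and produces errors that name the
offending line.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import biotite.structure as struc
import numpy as np
import pandas as pd
import yaml
from biotite.structure.io.pdb import PDBFile

from .errors import (
    ConfigError,
    EmptyInputError,
    EnergyTableError,
    PDBFormatError,
    ResidueResolutionError,
)

#: Residue names recognised as water (covers common MD exporters).
WATER_RESIDUE_NAMES = frozenset({"HOH", "TIP3", "SOL", "WAT"})

KJ_PER_KCAL = 4.184


# ---------------------------------------------------------------------------
# Structure frames
# ---------------------------------------------------------------------------

@dataclass
class StructureFrame:
    """One trajectory frame: per-atom identity arrays plus coordinates in Å.

    All identity arrays have equal length ``n_atoms``; ``coords`` has shape
    ``(n_atoms, 3)``.  Atom ordering is meaningful and must be stable across
    the frames of one trajectory.
    """

    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    frame_index: int = 0
    time_ns: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.chain_ids)
        for name in ("residue_numbers", "residue_names", "atom_names", "elements"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match chain_ids")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(np.asarray(self.residue_numbers) < 1):
            raise ValueError("residue numbers are 1-based (must be >= 1)")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    def atom_mask(
        self,
        chain_id: str | None = None,
        residue_number: int | None = None,
        atom_subset: str | Sequence[str] | None = None,
    ) -> np.ndarray:
        """Boolean mask over atoms matching the given selection."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        if residue_number is not None:
            mask &= self.residue_numbers == residue_number
        if atom_subset is not None:
            if isinstance(atom_subset, str):
                if atom_subset == "heavy":
                    mask &= self.elements != "H"
                elif atom_subset == "all":
                    pass
                else:
                    mask &= self.atom_names == atom_subset
            else:
                mask &= np.isin(self.atom_names, list(atom_subset))
        return mask

    def same_ordering(self, other: "StructureFrame") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.chain_ids, other.chain_ids)
            and np.array_equal(self.residue_numbers, other.residue_numbers)
            and np.array_equal(self.atom_names, other.atom_names)
        )


@dataclass(frozen=True)
class ResidueSpec:
    """A residue selection: chain + residue number + optional atom subset.

    ``atom_subset`` may be ``None``/"all" (every atom), "heavy" (non-hydrogen),
    a single atom name such as "CA", or an explicit tuple of atom names.
    """

    chain_id: str
    residue_number: int
    atom_subset: str | tuple[str, ...] | None = None

    def resolve(self, frame: StructureFrame) -> np.ndarray:
        """Coordinates (k, 3) of the matching atoms; error if none match."""
        mask = frame.atom_mask(self.chain_id, self.residue_number, self.atom_subset)
        if not mask.any():
            raise ResidueResolutionError(
                f"residue {self.chain_id}:{self.residue_number} "
                f"(atoms={self.atom_subset!r}) matches no atom "
                f"in frame {frame.frame_index}"
            )
        return frame.coords[mask]


# ---------------------------------------------------------------------------
# Multi-model PDB I/O
# ---------------------------------------------------------------------------

def _prescan_pdb_lines(lines: Iterable[str]) -> int:
    """Validate ATOM/HETATM records; return the number of coordinate lines."""
    n_coord = 0
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        n_coord += 1
        if len(line.rstrip("\n")) < 54:
            raise PDBFormatError(
                f"line {lineno}: ATOM record shorter than coordinate fields"
            )
        if line[16] not in (" ", ""):
            raise PDBFormatError(
                f"line {lineno}: alternate locations are not supported "
                f"(altloc {line[16]!r})"
            )
        if line[26] not in (" ", ""):
            raise PDBFormatError(
                f"line {lineno}: insertion codes are not supported "
                f"(icode {line[26]!r})"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBFormatError(
                    f"line {lineno}: malformed {what} coordinate {line[lo:hi]!r}"
                ) from None
        try:
            int(line[22:26])
        except ValueError:
            raise PDBFormatError(
                f"line {lineno}: malformed residue number {line[22:26]!r}"
            ) from None
    return n_coord


def read_multimodel_pdb(path: str | Path) -> list[StructureFrame]:
    """Read a (multi-model) PDB file into one StructureFrame per MODEL.

    A file without MODEL records yields a single frame.  Atom ordering is
    preserved exactly; coordinates carry the PDB fixed-column precision
    (0.001 Å).
    """
    path = Path(path)
    text = path.read_text()
    if _prescan_pdb_lines(text.splitlines()) == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records (zero models)")
    pdb = PDBFile.read(_io.StringIO(text))
    stack = pdb.get_structure(model=None)
    frames = []
    for i in range(stack.stack_depth()):
        arr = stack[i]
        frames.append(
            StructureFrame(
                chain_ids=np.asarray(arr.chain_id),
                residue_numbers=np.asarray(arr.res_id, dtype=int),
                residue_names=np.asarray(arr.res_name),
                atom_names=np.asarray(arr.atom_name),
                elements=np.asarray(arr.element),
                coords=np.asarray(arr.coord, dtype=float),
                frame_index=i,
            )
        )
    return frames


def _frame_to_atom_array(frame: StructureFrame) -> struc.AtomArray:
    arr = struc.AtomArray(frame.n_atoms)
    arr.chain_id = np.asarray(frame.chain_ids, dtype="U4")
    arr.res_id = np.asarray(frame.residue_numbers, dtype=int)
    arr.res_name = np.asarray(frame.residue_names, dtype="U5")
    arr.atom_name = np.asarray(frame.atom_names, dtype="U6")
    arr.element = np.asarray(frame.elements, dtype="U2")
    arr.hetero = np.isin(frame.residue_names, list(WATER_RESIDUE_NAMES))
    arr.coord = np.asarray(frame.coords, dtype=np.float32)
    return arr


def write_multimodel_pdb(frames: Sequence[StructureFrame], path: str | Path) -> None:
    """Write frames as a standard multi-model PDB (round-trips to 0.001 Å)."""
    if len(frames) == 0:
        raise EmptyInputError("cannot write a trajectory with zero frames")
    first = frames[0]
    for f in frames[1:]:
        if not first.same_ordering(f):
            raise ValueError(
                f"frame {f.frame_index} does not share atom ordering with "
                f"frame {first.frame_index}"
            )
    stack = struc.stack([_frame_to_atom_array(f) for f in frames])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------

@dataclass
class EnergyTable:
    """Energies (kcal/mol) of protonation microstates across structures.

    ``microstates`` is an (M, S) 0/1 matrix over ``sites``; ``energies`` is
    (M, K) over ``structures``.  Dense: every (microstate, structure)
    combination has exactly one value.
    """

    sites: list[str]
    microstates: np.ndarray
    structures: list[str]
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.microstates = np.asarray(self.microstates, dtype=np.int8)
        self.energies = np.asarray(self.energies, dtype=float)
        m, s = self.microstates.shape
        if s != len(self.sites):
            raise EnergyTableError("microstate width does not match site count")
        if self.energies.shape != (m, len(self.structures)):
            raise EnergyTableError("energy matrix shape mismatch")
        if not np.all(np.isfinite(self.energies)):
            raise EnergyTableError("energies must be finite")
        if not np.isin(self.microstates, (0, 1)).all():
            raise EnergyTableError("microstate entries must be 0 or 1")
        if len({tuple(row) for row in self.microstates}) != m:
            raise EnergyTableError("duplicate microstate vectors")

    @property
    def n_microstates(self) -> int:
        return self.microstates.shape[0]

    @property
    def n_structures(self) -> int:
        return len(self.structures)


def read_energy_table(path: str | Path, energy_unit: str = "kcal/mol") -> EnergyTable:
    """Read a long-format CSV energy table.

    Expected columns: one binary 0/1 column per titratable site, a
    ``structure`` label column and an ``energy`` column.  Energies given in
    kJ/mol (``energy_unit="kJ/mol"``) are converted to kcal/mol on read.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("structure", "energy"):
        if col not in df.columns:
            raise EnergyTableError(f"{path}: missing required column {col!r}")
    site_cols = [c for c in df.columns if c not in ("structure", "energy")]
    if not site_cols:
        raise EnergyTableError(f"{path}: no site columns found")
    for c in site_cols:
        vals = df[c].unique()
        if not np.isin(vals, (0, 1)).all():
            raise EnergyTableError(
                f"{path}: site column {c!r} has non-binary entries "
                f"{sorted(set(vals) - {0, 1})}"
            )
    if energy_unit == "kJ/mol":
        df = df.assign(energy=df["energy"] / KJ_PER_KCAL)
    elif energy_unit != "kcal/mol":
        raise EnergyTableError(f"unknown energy unit {energy_unit!r}")

    key_cols = site_cols + ["structure"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        first = df[dup].iloc[0]
        raise EnergyTableError(
            f"{path}: duplicate (microstate, structure) row: "
            f"{tuple(first[key_cols])}"
        )
    structures = sorted(df["structure"].astype(str).unique())
    micro_df = df[site_cols].drop_duplicates().sort_values(site_cols)
    microstates = micro_df.to_numpy(dtype=np.int8)
    pivot = df.pivot_table(
        index=site_cols, columns="structure", values="energy", aggfunc="first"
    )
    if pivot.isna().any().any():
        gaps = [
            (idx, col)
            for idx, row in pivot.iterrows()
            for col, v in row.items()
            if pd.isna(v)
        ]
        raise EnergyTableError(
            f"{path}: incomplete table; missing (microstate, structure) "
            f"combinations: {gaps[:10]}"
        )
    # align pivot rows to `microstates` and columns to sorted structure labels
    index_keys = [tuple(int(v) for v in row) for row in microstates]
    row_sel = [k[0] for k in index_keys] if len(site_cols) == 1 else index_keys
    pivot = pivot.loc[row_sel]
    col_labels = [str(c) for c in pivot.columns]
    col_order = [col_labels.index(s) for s in structures]
    energies = pivot.to_numpy(dtype=float)[:, col_order]
    return EnergyTable(
        sites=site_cols,
        microstates=microstates,
        structures=structures,
        energies=energies,
    )


def write_energy_table(table: EnergyTable, path: str | Path) -> None:
    """Write an EnergyTable to long-format CSV (kcal/mol)."""
    rows = []
    for i in range(table.n_microstates):
        for j, structure in enumerate(table.structures):
            rec = {s: int(table.microstates[i, k]) for k, s in enumerate(table.sites)}
            rec["structure"] = structure
            rec["energy"] = repr(float(table.energies[i, j]))
            rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Order-parameter series CSV
# ---------------------------------------------------------------------------

def write_series_csv(series: pd.DataFrame, path: str | Path) -> None:
    """Export a wide per-frame series as tidy CSV.

    Columns of the tidy file: frame, time_ns, variant, parameter, value.
    """
    id_cols = ["frame_index", "time_ns", "variant"]
    value_cols = [c for c in series.columns if c not in id_cols]
    tidy = series.melt(
        id_vars=id_cols, value_vars=value_cols, var_name="parameter", value_name="value"
    ).rename(columns={"frame_index": "frame"})
    tidy.to_csv(path, index=False)


def read_series_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy series CSV back into the wide per-frame form."""
    tidy = pd.read_csv(path)
    wide = tidy.pivot_table(
        index=["frame", "time_ns", "variant"],
        columns="parameter",
        values="value",
        aggfunc="first",
    ).reset_index()
    wide = wide.rename(columns={"frame": "frame_index"})
    wide.columns.name = None
    wide["frame_index"] = wide["frame_index"].astype(int)
    return wide.sort_values("frame_index").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

#: Reference-compound pKa values used when a config does not supply its own.
DEFAULT_MODEL_PKAS = {
    "GLU": 4.25,
    "HIS": 6.54,
    "ASP": 3.71,
    "LYS": 10.40,
    "ARG": 12.10,
    "CTR": 3.80,
    "NTR": 8.00,
}


@dataclass
class AnalysisConfig:
    """Validated flat configuration for the whole pipeline.

    Residue numbers follow the Kv1.2 pore-domain numbering (312-421): the S6
    kink dihedral uses the Cα atoms of L393/L400/V408/Y415, the inter-subunit
    contact pairs R326 of one chain with H418 of the next chain around the
    ring, and the cavity cylinder is bounded by the selectivity-filter base
    (T374) above and the bundle-crossing gate (V410) below.
    """

    ring_order: tuple[str, ...] = ("A", "B", "C", "D")
    dihedral_residue_numbers: tuple[int, ...] = (393, 400, 408, 415)
    distance_residue_a: int = 326
    distance_residue_b: int = 418
    distance_atom_subset: str = "heavy"
    cavity_axis_residue_number: int = 374
    cavity_filter_residue_numbers: tuple[int, ...] = (374,)
    cavity_gate_residue_numbers: tuple[int, ...] = (410,)
    cavity_radius: float = 5.0
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    wet_threshold: int = 10
    window_fraction: float = 0.25
    stride: int = 1
    ph_min: float = 3.0
    ph_max: float = 8.0
    ph_step: float = 0.01
    temperature_K: float = 310.0
    dominant_weight_threshold: float = 1e-12
    energy_unit: str = "kcal/mol"
    correlation_method: str = "pearson"
    bin_width_dihedral_deg: float = 2.0
    bin_width_distance_A: float = 0.25
    bin_width_waters: float = 1.0
    mode_smooth_window: int = 5
    mode_prominence: float = 0.05
    model_pkas: dict = field(default_factory=lambda: dict(DEFAULT_MODEL_PKAS))
    # synthetic-suite knobs consumed by the CLI `synth` stage
    synth_variants: tuple[str, ...] = ("toy",)
    synth_n_trajectories: int = 5
    synth_n_frames: int = 2000

    def __post_init__(self) -> None:
        if not (0.0 < self.window_fraction <= 1.0):
            raise ConfigError("window_fraction must be in (0, 1]")
        if self.ph_min >= self.ph_max:
            raise ConfigError("ph_min must be < ph_max")
        if self.ph_step <= 0:
            raise ConfigError("ph_step must be > 0")
        if self.cavity_radius <= 0:
            raise ConfigError("cavity_radius must be > 0")
        if self.temperature_K <= 0:
            raise ConfigError("temperature_K must be > 0")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        if not (0.0 <= self.dominant_weight_threshold < 1.0):
            raise ConfigError("dominant_weight_threshold must be in [0, 1)")
        if self.wet_threshold < 0:
            raise ConfigError("wet_threshold must be >= 0")
        if len(self.dihedral_residue_numbers) != 4:
            raise ConfigError("dihedral_residue_numbers must list 4 residues")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ConfigError("correlation_method must be pearson or spearman")
        if self.energy_unit not in ("kcal/mol", "kJ/mol"):
            raise ConfigError("energy_unit must be kcal/mol or kJ/mol")
        d = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ConfigError("axis_direction must be non-zero")
        self.axis_direction = tuple(float(v) for v in d / n)

    @property
    def ph_grid(self) -> np.ndarray:
        n = int(round((self.ph_max - self.ph_min) / self.ph_step)) + 1
        return self.ph_min + self.ph_step * np.arange(n)

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        """Ordered adjacent chain pairs around the tetramer ring."""
        ring = self.ring_order
        return [(ring[i], ring[(i + 1) % len(ring)]) for i in range(len(ring))]

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


_LIST_FIELDS = {
    "ring_order",
    "dihedral_residue_numbers",
    "cavity_filter_residue_numbers",
    "cavity_gate_residue_numbers",
    "axis_direction",
    "synth_variants",
}


def read_config(path: str | Path) -> AnalysisConfig:
    """Load a flat YAML config, filling defaults and validating every field."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _LIST_FIELDS:
            if not isinstance(value, (list, tuple)):
                raise ConfigError(f"{path}: {key} must be a list")
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return AnalysisConfig(**kwargs)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
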