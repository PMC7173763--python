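"""Ensemble statistics over gating order parameters.

Pools the equilibrated tail of each trajectory, classifies frames as wetted
or dewetted, builds 1D distributions with mode detection (circular for
dihedrals), 2D log-population heat maps, and correlation coefficients
between order parameters — the per-variant summaries used to compare
protonated/mutated channel conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyInputError
from .io import AnalysisConfig


@dataclass
class PooledEnsemble:
    """Order-parameter records pooled from the last window of >=1 trajectories."""

    records: pd.DataFrame
    window_fraction: float
    variant_label: str


def pool_window(
    series_collections: list[pd.DataFrame], window_fraction: float
) -> PooledEnsemble:
    """Retain the final ``ceil(window_fraction * n_frames)`` records per
    trajectory and concatenate across trajectories of one variant."""
    if not (0.0 < window_fraction <= 1.0):
        raise ValueError("window_fraction must be in (0, 1]")
    if not series_collections:
        raise EmptyInputError("no series to pool")
    labels = {str(s["variant"].iloc[0]) for s in series_collections}
    for s in series_collections:
        if s["variant"].nunique() > 1:
            raise ValueError("a single series carries mixed variant labels")
    if len(labels) > 1:
        raise ValueError(f"mixed variant labels in pooled window: {sorted(labels)}")
    kept = []
    for s in series_collections:
        n = len(s)
        if n == 0:
            raise EmptyInputError("a trajectory has no frames in the window")
        k = math.ceil(window_fraction * n)
        kept.append(s.iloc[n - k :])
    return PooledEnsemble(
        records=pd.concat(kept, ignore_index=True),
        window_fraction=window_fraction,
        variant_label=labels.pop(),
    )


def classify_hydration(n_waters, wet_threshold: int):
    """"wet" iff the cavity holds at least ``wet_threshold`` waters (inclusive).

    Accepts a scalar or an array; returns str or an object array of str.
    """
    if wet_threshold < 0:
        raise ValueError("wet_threshold must be >= 0")
    arr = np.asarray(n_waters)
    out = np.where(arr >= wet_threshold, "wet", "dewet")
    return str(out[()]) if out.ndim == 0 else out


@dataclass
class Distribution:
    """A normalised 1D histogram (bin masses sum to 1)."""

    edges: np.ndarray
    mass: np.ndarray
    circular: bool = False

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def histogram_1d(
    values,
    bin_width: float,
    value_range: tuple[float, float] | None = None,
    circular: bool = False,
) -> Distribution:
    """Normalised histogram with fixed bin width.

    For circular observables pass ``value_range=(0, 360)``; without an
    explicit range the bins cover the data, aligned to multiples of
    ``bin_width``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyInputError("histogram_1d requires at least one value")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if value_range is None:
        lo = math.floor(values.min() / bin_width) * bin_width
        hi = math.ceil(values.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = value_range
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    total = counts.sum()
    if total == 0:
        raise ValueError("all values fall outside the requested range")
    return Distribution(edges=edges, mass=counts / total, circular=circular)


@dataclass
class ModeSet:
    """Locations (ascending, observable units) and relative heights of modes."""

    locations: list[float] = field(default_factory=list)
    prominences: list[float] = field(default_factory=list)


def find_modes(
    distribution: Distribution,
    smooth_window: int = 5,
    prominence_frac: float = 0.05,
) -> ModeSet:
    """Local maxima of the moving-average-smoothed histogram.

    A bin is a mode when its smoothed mass strictly exceeds both neighbours
    and reaches at least ``prominence_frac`` of the global smoothed maximum.
    Circular distributions wrap at the ends; linear ones treat the outside
    as empty.
    """
    mass = distribution.mass
    n = len(mass)
    w = max(1, int(smooth_window))
    if w % 2 == 0:
        w += 1
    half = w // 2
    if distribution.circular:
        padded = np.concatenate([mass[-half:], mass, mass[:half]]) if half else mass
    else:
        padded = np.concatenate([np.zeros(half), mass, np.zeros(half)])
    kernel = np.ones(w) / w
    smoothed = np.convolve(padded, kernel, mode="valid")
    assert len(smoothed) == n
    peak = smoothed.max()
    if peak <= 0:
        return ModeSet()
    locations, proms = [], []
    for i in range(n):
        if distribution.circular:
            left = smoothed[(i - 1) % n]
            right = smoothed[(i + 1) % n]
        else:
            left = smoothed[i - 1] if i > 0 else -np.inf
            right = smoothed[i + 1] if i < n - 1 else -np.inf
        if smoothed[i] > left and smoothed[i] > right:
            rel = smoothed[i] / peak
            if rel >= prominence_frac:
                locations.append(float(distribution.centers[i]))
                proms.append(float(rel))
    order = np.argsort(locations)
    return ModeSet(
        locations=[locations[i] for i in order],
        prominences=[proms[i] for i in order],
    )


@dataclass
class HeatMap2D:
    """2D population histogram plus the Pearson r of the raw pairs.

    ``counts`` are raw occupancies (log10 is applied only when rendering);
    ``pearson_r`` is NaN when either marginal is degenerate.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    pearson_r: float
    n_points: int


def correlation(x, y, method: str = "pearson") -> float:
    """Pearson (default) or Spearman correlation; NaN on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def heatmap_log2d(x_values, y_values, x_edges, y_edges) -> HeatMap2D:
    """Bin paired values on a 2D grid; correlation is computed unbinned."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    if ((x < x_edges[0]) | (x > x_edges[-1])).any() or (
        (y < y_edges[0]) | (y > y_edges[-1])
    ).any():
        raise ValueError("values fall outside the bin edges; widen the grid")
    counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    return HeatMap2D(
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts.astype(int),
        pearson_r=correlation(x, y, "pearson"),
        n_points=len(x),
    )


def render_heatmap(heatmap: HeatMap2D, path, x_label="", y_label="") -> None:
    """Write a log10-population rendering (empty bins masked) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    masked = np.ma.masked_where(heatmap.counts == 0, heatmap.counts)
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(
        heatmap.x_edges,
        heatmap.y_edges,
        np.ma.log10(masked).T,
        shading="auto",
    )
    fig.colorbar(mesh, ax=ax, label="log10 population")
    ax.set_xlabel(x_label)
    ax.set_ylabel(y_label)
    if np.isfinite(heatmap.pearson_r):
        ax.set_title(f"r = {heatmap.pearson_r:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stacked_pairs(records: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Flatten per-chain observables into (distance, dihedral, n_waters) rows.

    Each ordered adjacent pair (i -> j) contributes one row per frame: the
    pair's R326(i)-H418(j) distance matched with the kink dihedral of the
    H418-carrying chain j and the frame's cavity water count.
    """
    rows = []
    for ca, cb in config.adjacent_pairs():
        sub = pd.DataFrame(
            {
                "distance": records[f"dist_A_{ca}{cb}"],
                "dihedral": records[f"dihedral_deg_{cb}"],
                "n_waters": records["n_waters"],
            }
        )
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def variant_report(
    pooled_by_variant: dict[str, PooledEnsemble], config: AnalysisConfig
) -> pd.DataFrame:
    """Per-variant summary: correlations, hydration occupancy and modes.

    Correlations stack all four (pair distance, partner-chain dihedral)
    combinations; modes come from the pooled circular dihedral and linear
    distance distributions.
    """
    if not pooled_by_variant:
        raise EmptyInputError("variant_report requires at least one variant")
    rows = []
    for label, pooled in pooled_by_variant.items():
        rec = pooled.records
        pairs = _stacked_pairs(rec, config)
        if len(rec) < 2:
            # a one-frame ensemble has no ensemble variation to correlate
            r_dist = r_wat = float("nan")
        else:
            r_dist = correlation(pairs["distance"], pairs["dihedral"], config.correlation_method)
            r_wat = correlation(pairs["n_waters"], pairs["dihedral"], config.correlation_method)
        wet = classify_hydration(rec["n_waters"].to_numpy(), config.wet_threshold)
        occupancy = float(np.mean(wet == "wet"))
        dih_modes = find_modes(
            histogram_1d(
                pairs["dihedral"],
                config.bin_width_dihedral_deg,
                value_range=(0.0, 360.0),
                circular=True,
            ),
            config.mode_smooth_window,
            config.mode_prominence,
        )
        dist_modes = find_modes(
            histogram_1d(pairs["distance"], config.bin_width_distance_A),
            config.mode_smooth_window,
            config.mode_prominence,
        )
        rows.append(
            {
                "variant": label,
                "n_records": len(rec),
                "r_distance_dihedral": r_dist,
                "r_waters_dihedral": r_wat,
                "wet_occupancy": occupancy,
                "dihedral_modes_deg": ";".join(f"{m:.1f}" for m in dih_modes.locations),
                "distance_modes_A": ";".join(f"{m:.2f}" for m in dist_modes.locations),
            }
        )
    return pd.DataFrame(rows)
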