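"""Ensemble-based multi-site titration from microstate energy tables.

The channel's titratable residues define a set of protonation microstates
x ∈ {0,1}^S.  Given microstate energies E(x, m) evaluated over an ensemble
of structures m, the semi-grand partition function at a given pH is
reconstructed from the ensemble-averaged energies ⟨E⟩(x) with the standard
constant-pH coupling: each bound proton contributes ln(10)·RT·(pH − pKa_model)
to the microstate free energy,

    G(x; pH) = ⟨E⟩(x) + ln(10)·RT · Σ_i x_i (pH − pKa_model,i).

Protonation fractions are Boltzmann averages θ_i(pH) = ⟨x_i⟩ computed in the
log domain, the pKa of a site is the pH where θ_i crosses 1/2, and the
spread of E(x, m) across the structural ensemble is propagated into a pKa
uncertainty band by re-titrating at ⟨E⟩ ± k·σ for k = 0.1 … 1.0.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .errors import CapabilityError, EnergyTableError
from .io import DEFAULT_MODEL_PKAS, AnalysisConfig, EnergyTable

logger = logging.getLogger(__name__)

#: Gas constant in kcal/(mol·K).
R_KCAL = 0.0019872
LN10 = np.log(10.0)

#: σ multipliers of the uncertainty sweep.
UNCERTAINTY_KS = tuple(round(0.1 * k, 1) for k in range(1, 11))

_MAX_EXACT_SITES = 20


def rt_kcal(temperature_K: float) -> float:
    """Thermal energy RT in kcal/mol."""
    return R_KCAL * temperature_K


@dataclass(frozen=True)
class TitrationSite:
    """One titratable residue and its reference-compound pKa."""

    site_id: str
    model_pka: float
    site_class: str = "acid"  # "acid" | "base"; charge bookkeeping metadata

    def __post_init__(self) -> None:
        if not np.isfinite(self.model_pka):
            raise ValueError("model_pka must be finite")
        if self.site_class not in ("acid", "base"):
            raise ValueError("site_class must be 'acid' or 'base'")


def default_site(site_id: str) -> TitrationSite:
    """Build a TitrationSite from an id like "E327.A" using default model pKas."""
    resname = {"E": "GLU", "D": "ASP", "H": "HIS", "K": "LYS", "R": "ARG"}.get(
        site_id[0].upper()
    )
    if resname is None or resname not in DEFAULT_MODEL_PKAS:
        raise ValueError(f"cannot infer a model pKa for site {site_id!r}")
    site_class = "base" if resname in ("HIS", "LYS", "ARG") else "acid"
    return TitrationSite(site_id, DEFAULT_MODEL_PKAS[resname], site_class)


@dataclass
class TitrationModel:
    """Microstate energy statistics over the structural ensemble.

    ``energy_mean``/``energy_sd`` are the row-wise mean and sample standard
    deviation of an EnergyTable (sd = 0 for a single-structure table).
    """

    sites: list[TitrationSite]
    microstates: np.ndarray  # (M, S) 0/1
    energy_mean: np.ndarray  # (M,) kcal/mol
    energy_sd: np.ndarray  # (M,) kcal/mol
    temperature_K: float = 310.0

    def __post_init__(self) -> None:
        self.microstates = np.asarray(self.microstates, dtype=np.int8)
        self.energy_mean = np.asarray(self.energy_mean, dtype=float)
        self.energy_sd = np.asarray(self.energy_sd, dtype=float)
        m, s = self.microstates.shape
        if s != len(self.sites):
            raise ValueError("microstate width does not match number of sites")
        if self.energy_mean.shape != (m,) or self.energy_sd.shape != (m,):
            raise ValueError("energy statistics shape mismatch")
        if np.any(self.energy_sd < 0):
            raise ValueError("energy_sd must be >= 0")
        if not (
            np.all(np.isfinite(self.energy_mean))
            and np.all(np.isfinite(self.energy_sd))
        ):
            raise ValueError("energy statistics must be finite")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def model_pkas(self) -> np.ndarray:
        return np.array([s.model_pka for s in self.sites])

    def site_index(self, site_id: str) -> int:
        for i, s in enumerate(self.sites):
            if s.site_id == site_id:
                return i
        raise KeyError(f"unknown site {site_id!r}")

    @classmethod
    def from_energy_table(
        cls,
        table: EnergyTable,
        sites: list[TitrationSite] | None = None,
        temperature_K: float = 310.0,
    ) -> "TitrationModel":
        if sites is None:
            sites = [default_site(s) for s in table.sites]
        if [s.site_id for s in sites] != list(table.sites):
            raise EnergyTableError(
                "site list does not match energy-table columns: "
                f"{[s.site_id for s in sites]} vs {list(table.sites)}"
            )
        mean = table.energies.mean(axis=1)
        if table.n_structures > 1:
            sd = table.energies.std(axis=1, ddof=1)
        else:
            sd = np.zeros(table.n_microstates)
            logger.warning(
                "energy table has a single structure; uncertainty bands collapse"
            )
        return cls(
            sites=sites,
            microstates=table.microstates,
            energy_mean=mean,
            energy_sd=sd,
            temperature_K=temperature_K,
        )


def microstate_free_energy(model: TitrationModel, ph: float) -> np.ndarray:
    """G(x; pH) in kcal/mol for every microstate of the model (vectorised)."""
    rt = rt_kcal(model.temperature_K)
    n_prot = model.microstates.sum(axis=1)
    pka_term = model.microstates @ model.model_pkas
    return model.energy_mean + LN10 * rt * (ph * n_prot - pka_term)


def protonation_fraction(
    model: TitrationModel,
    site_id: str,
    ph: float,
    subset: np.ndarray | None = None,
) -> float:
    """Boltzmann-averaged probability that ``site_id`` is protonated at ``ph``.

    ``subset`` is an index array into the model's microstates; all states
    are used when omitted.  Evaluated with log-domain accumulation so that
    arbitrary energy offsets cannot overflow.
    """
    rt = rt_kcal(model.temperature_K)
    idx = np.arange(model.microstates.shape[0]) if subset is None else np.asarray(subset)
    g = microstate_free_energy(model, ph)[idx]
    logw = -g / rt
    prot = model.microstates[idx, model.site_index(site_id)].astype(bool)
    if not prot.any():
        return 0.0
    if prot.all():
        return 1.0
    return float(np.exp(logsumexp(logw[prot]) - logsumexp(logw)))


def select_dominant_states(
    model: TitrationModel,
    ph_grid: np.ndarray,
    weight_threshold: float,
) -> np.ndarray:
    """Indices of microstates dominant somewhere on the pH grid.

    At each grid point the normalised Boltzmann weights are computed by
    exact enumeration; states with weight >= ``weight_threshold`` are kept,
    and the top-weight state at each point is always included.  Returns the
    sorted union.
    """
    if model.n_sites > _MAX_EXACT_SITES:
        raise CapabilityError(
            f"{model.n_sites} sites exceed the exact-enumeration limit "
            f"({_MAX_EXACT_SITES}); a sampling fallback is out of scope"
        )
    if not (0.0 <= weight_threshold < 1.0):
        raise ValueError("weight_threshold must be in [0, 1)")
    rt = rt_kcal(model.temperature_K)
    selected: set[int] = set()
    for ph in np.asarray(ph_grid, dtype=float):
        logw = -microstate_free_energy(model, ph) / rt
        logw = logw - logsumexp(logw)
        selected.add(int(np.argmax(logw)))
        if weight_threshold > 0.0:
            hits = np.nonzero(logw >= np.log(weight_threshold))[0]
        else:
            hits = np.arange(len(logw))
        selected.update(int(i) for i in hits)
    return np.array(sorted(selected), dtype=int)


def estimate_pka(fractions: np.ndarray, ph_grid: np.ndarray) -> tuple[float | None, bool]:
    """pH of the first θ = 0.5 crossing (linear interpolation between grid
    points); returns ``(None, False)`` when θ never reaches 0.5.

    The second element flags multiple crossings on the grid.
    """
    ph = np.asarray(ph_grid, dtype=float)
    theta = np.asarray(fractions, dtype=float)
    if np.any(np.diff(ph) <= 0):
        raise ValueError("ph_grid must be strictly ascending")
    d = theta - 0.5
    crossings: list[float] = []
    i = 0
    while i < len(d):
        if d[i] == 0.0:
            crossings.append(float(ph[i]))
            i += 1
            continue
        if i + 1 < len(d) and d[i] * d[i + 1] < 0:
            frac = d[i] / (d[i] - d[i + 1])
            crossings.append(float(ph[i] + frac * (ph[i + 1] - ph[i])))
        i += 1
    if not crossings:
        return None, False
    return min(crossings), len(crossings) > 1


def pka_uncertainty(
    model: TitrationModel,
    site_id: str,
    ph_grid: np.ndarray,
    subset: np.ndarray | None = None,
    ks: tuple[float, ...] = UNCERTAINTY_KS,
) -> dict[float, tuple[float | None, float | None]]:
    """pKa band per σ multiplier k.

    For each k the titration is repeated with every microstate's energy set
    to ⟨E⟩ + k·σ(x) and to ⟨E⟩ − k·σ(x) (a common sign applied to all
    states); the band is the (min, max) of the two resulting pKas.  A band
    endpoint is None when the shifted curve never crosses θ = 0.5.
    """
    if np.all(model.energy_sd == 0):
        logger.warning("all energy sds are zero; bands collapse to the point estimate")
    bands: dict[float, tuple[float | None, float | None]] = {}
    for k in ks:
        pkas = []
        for sign in (+1.0, -1.0):
            shifted = replace(
                model, energy_mean=model.energy_mean + sign * k * model.energy_sd
            )
            theta = np.array(
                [protonation_fraction(shifted, site_id, ph, subset) for ph in ph_grid]
            )
            pka, _ = estimate_pka(theta, ph_grid)
            pkas.append(pka)
        if any(p is None for p in pkas):
            known = [p for p in pkas if p is not None]
            lo = min(known) if known else None
            hi = max(known) if known else None
            bands[k] = (lo, hi)
        else:
            bands[k] = (min(pkas), max(pkas))
    return bands


@dataclass
class TitrationCurve:
    """Protonation fraction vs pH for one site, with pKa point and bands."""

    site_id: str
    ph_grid: np.ndarray
    fraction: np.ndarray
    pka_point: float | None
    pka_band: dict[float, tuple[float | None, float | None]] = field(default_factory=dict)
    multi_crossing: bool = False


def run_titration(
    table: EnergyTable,
    sites: list[TitrationSite] | None = None,
    config: AnalysisConfig | None = None,
) -> dict[str, TitrationCurve]:
    """Full titration pipeline: model → dominant states → θ(pH), pKa, bands."""
    config = config or AnalysisConfig()
    model = TitrationModel.from_energy_table(
        table, sites, temperature_K=config.temperature_K
    )
    ph_grid = config.ph_grid
    subset = select_dominant_states(model, ph_grid, config.dominant_weight_threshold)
    curves: dict[str, TitrationCurve] = {}
    for site in model.sites:
        theta = np.array(
            [protonation_fraction(model, site.site_id, ph, subset) for ph in ph_grid]
        )
        pka, multi = estimate_pka(theta, ph_grid)
        bands = pka_uncertainty(model, site.site_id, ph_grid, subset)
        curves[site.site_id] = TitrationCurve(
            site_id=site.site_id,
            ph_grid=ph_grid,
            fraction=theta,
            pka_point=pka,
            pka_band=bands,
            multi_crossing=multi,
        )
    return curves


def enumerate_microstates(n_sites: int) -> np.ndarray:
    """All 2^n binary protonation vectors (n <= 20), in lexicographic order."""
    if n_sites > _MAX_EXACT_SITES:
        raise CapabilityError(f"{n_sites} sites exceed the exact-enumeration limit")
    return np.array(
        list(itertools.product((0, 1), repeat=n_sites)), dtype=np.int8
    )
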