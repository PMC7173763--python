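"""Synthetic two-state channel ensembles and microstate energy tables.

The toy trajectory generator emulates the gating behaviour seen in pore-
domain simulations: a hidden open/closed state follows a two-state Markov
chain, and all three order parameters co-vary through it — the S6 kink
dihedral is drawn around 130° (bent, open) or 245° (straight, closed), the
R326-H418 inter-subunit distance around 6.0 Å or 14.7 Å, and the cavity
water count is Poisson with a high (wetted) or low (dewetted) rate.  Frames
are genuine StructureFrame objects, so the geometry module measures them
exactly like real trajectory frames.

The energy generator builds microstate tables E(x, m) from per-site field
terms, pairwise couplings and per-structure Gaussian noise, with ground-
truth titration curves obtained by direct enumeration of the noiseless
model (an independent code path from the titration module's log-domain
evaluation).

What the generator does NOT emulate: helix geometry beyond the four torsion
Cα atoms, excluded volume for waters, ions, lipids, or any force-field
energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CapabilityError
from .geometry import CavityRegion
from .io import EnergyTable, StructureFrame
from .titration import LN10, enumerate_microstates, rt_kcal

_CHAIN_ANGLES = {"A": 0.0, "B": 90.0, "C": 180.0, "D": 270.0}
_HELIX_RESIDUES = ((393, "LEU"), (400, "LEU"), (408, "VAL"), (415, "TYR"))
_HELIX_BOND = 6.0  # Å between consecutive torsion Cα atoms
_HELIX_ANGLE_DEG = 70.0  # planar angle at the inner torsion atoms


@dataclass
class ToyChannelSpec:
    """Parameters of the synthetic two-state gating ensemble.

    Defaults reproduce the characteristic open/closed signatures of the
    Kv1.2 pore domain: dihedral populations at 130° (bent S6) and 245°
    (straight S6), inter-subunit distances of 6.0 Å and 14.7 Å, and wetted
    vs dewetted cavity water counts of about 25 vs 3.
    """

    n_frames: int = 2000
    p_switch: float = 0.02
    p_open_to_closed: float | None = None
    p_closed_to_open: float | None = None
    initial_state: str = "open"
    dihedral_mean_open_deg: float = 130.0
    dihedral_mean_closed_deg: float = 245.0
    dihedral_sd_deg: float = 10.0
    distance_mean_open_A: float = 6.0
    distance_mean_closed_A: float = 14.7
    distance_sd_A: float = 1.0
    water_rate_open: float = 25.0
    water_rate_closed: float = 3.0
    cavity_radius_A: float = 5.0
    cavity_height_A: float = 10.0
    ring_radius_A: float = 10.0
    jitter_sd_A: float = 0.05
    frame_dt_ns: float = 1.0
    seed: int = 0
    variant_label: str = "toy"

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("dihedral_sd_deg", "distance_sd_A", "jitter_sd_A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dihedral_sd_deg == 0 or self.distance_sd_A == 0:
            raise ValueError("dihedral and distance sds must be > 0")
        if min(self.water_rate_open, self.water_rate_closed) < 0:
            raise ValueError("water rates must be >= 0")
        if min(self.distance_mean_open_A, self.distance_mean_closed_A) <= 0:
            raise ValueError("distance means must be > 0")
        for p in (self.p_switch, self.p_o2c, self.p_c2o):
            if not (0.0 <= p < 1.0):
                raise ValueError("switch probabilities must be in [0, 1)")
        if self.initial_state not in ("open", "closed"):
            raise ValueError("initial_state must be 'open' or 'closed'")
        for name in ("dihedral_mean_open_deg", "dihedral_mean_closed_deg"):
            if not (0.0 <= getattr(self, name) < 360.0):
                raise ValueError(f"{name} must lie in [0, 360)")

    @property
    def p_o2c(self) -> float:
        return self.p_switch if self.p_open_to_closed is None else self.p_open_to_closed

    @property
    def p_c2o(self) -> float:
        return self.p_switch if self.p_closed_to_open is None else self.p_closed_to_open

    def cavity_region(self) -> CavityRegion:
        """The exact cavity cylinder the generator places its waters in."""
        h = self.cavity_height_A
        return CavityRegion(
            axis_point=(0.0, 0.0, h / 2),
            axis_direction=(0.0, 0.0, 1.0),
            z_low=-h / 2,
            z_high=h / 2,
            radius=self.cavity_radius_A,
        )


def _helix_points(torsion_deg: float) -> np.ndarray:
    """Four points whose signed torsion equals ``torsion_deg`` exactly."""
    L = _HELIX_BOND
    a = np.radians(_HELIX_ANGLE_DEG)
    t = np.radians(torsion_deg)
    p2 = np.zeros(3)
    p3 = np.array([L, 0.0, 0.0])
    p1 = p2 + L * np.array([np.cos(a), np.sin(a), 0.0])
    p4 = p3 + L * np.array(
        [-np.cos(a), np.sin(a) * np.cos(t), np.sin(a) * np.sin(t)]
    )
    return np.stack([p1, p2, p3, p4])


def _rot_z(angle_deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _simulate_states(spec: ToyChannelSpec, rng: np.random.Generator) -> np.ndarray:
    """0 = open, 1 = closed; a two-state Markov chain over frames."""
    states = np.empty(spec.n_frames, dtype=np.int8)
    states[0] = 0 if spec.initial_state == "open" else 1
    u = rng.random(spec.n_frames)
    for i in range(1, spec.n_frames):
        p = spec.p_o2c if states[i - 1] == 0 else spec.p_c2o
        states[i] = states[i - 1] ^ (u[i] < p)
    return states


def generate_toy_trajectory(
    spec: ToyChannelSpec,
) -> tuple[list[StructureFrame], pd.DataFrame]:
    """Generate frames plus the ground-truth table behind them.

    Returns ``(frames, truth)`` where ``truth`` holds, per frame, the latent
    state label and the sampled (pre-jitter) observables: cavity water
    count, per-chain dihedral and per-pair distance.  Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    states = _simulate_states(spec, rng)
    chains = list(_CHAIN_ANGLES)
    pairs = [(chains[i], chains[(i + 1) % 4]) for i in range(4)]
    h = spec.cavity_height_A
    marker_r = spec.cavity_radius_A + 3.0
    n_water_total = int(
        max(spec.water_rate_open, spec.water_rate_closed)
        + 10.0 * np.sqrt(max(spec.water_rate_open, spec.water_rate_closed, 1.0))
        + 5
    )

    frames: list[StructureFrame] = []
    truth_rows = []
    for fi in range(spec.n_frames):
        closed = bool(states[fi])
        dih_mean = spec.dihedral_mean_closed_deg if closed else spec.dihedral_mean_open_deg
        dist_mean = spec.distance_mean_closed_A if closed else spec.distance_mean_open_A
        rate = spec.water_rate_closed if closed else spec.water_rate_open

        chain_ids, res_nums, res_names, atom_names, elements, coords = (
            [], [], [], [], [], []
        )

        def add(chain, resnum, resname, atomname, element, pos):
            chain_ids.append(chain)
            res_nums.append(resnum)
            res_names.append(resname)
            atom_names.append(atomname)
            elements.append(element)
            coords.append(np.asarray(pos, dtype=float))

        truth = {"frame": fi, "state": "closed" if closed else "open"}

        # torsion helices (wrapped-normal dihedral per chain)
        for chain in chains:
            theta = float((rng.normal(dih_mean, spec.dihedral_sd_deg)) % 360.0)
            truth[f"dihedral_deg_{chain}"] = theta
            pts = _helix_points(theta) @ _rot_z(_CHAIN_ANGLES[chain]).T
            center = _rot_z(_CHAIN_ANGLES[chain]) @ np.array(
                [spec.ring_radius_A + 6.0, 0.0, 6.0]
            )
            pts = pts + center
            pts = pts + rng.normal(0.0, spec.jitter_sd_A, size=pts.shape)
            for (resnum, resname), p in zip(_HELIX_RESIDUES, pts):
                add(chain, resnum, resname, "CA", "C", p)

        # inter-subunit contact proxies on the chord between chain centers
        proxy: dict[tuple[str, int], np.ndarray] = {}
        for ca, cb in pairs:
            d = float(rng.normal(dist_mean, spec.distance_sd_A))
            d = max(d, 0.2)
            truth[f"dist_A_{ca}{cb}"] = d
            c_a = _rot_z(_CHAIN_ANGLES[ca]) @ np.array([spec.ring_radius_A, 0.0, -4.0])
            c_b = _rot_z(_CHAIN_ANGLES[cb]) @ np.array([spec.ring_radius_A, 0.0, -4.0])
            mid = 0.5 * (c_a + c_b)
            e = (c_b - c_a) / np.linalg.norm(c_b - c_a)
            proxy[(ca, 326)] = mid - 0.5 * d * e
            proxy[(cb, 418)] = mid + 0.5 * d * e
        jit = {k: v + rng.normal(0.0, spec.jitter_sd_A, size=3) for k, v in proxy.items()}
        for chain in chains:
            add(chain, 326, "ARG", "NH1", "N", jit[(chain, 326)])
            add(chain, 418, "HIS", "NE2", "N", jit[(chain, 418)])
            # cavity scaffold markers (exact: they define the counting region)
            base = _rot_z(_CHAIN_ANGLES[chain]) @ np.array([marker_r, 0.0, 0.0])
            add(chain, 374, "THR", "CA", "C", base + np.array([0.0, 0.0, h / 2]))
            add(chain, 410, "VAL", "CA", "C", base + np.array([0.0, 0.0, -h / 2]))

        # waters: n_in inside the cavity cylinder, the rest parked outside
        n_in = int(min(rng.poisson(rate), n_water_total))
        truth["n_cavity_waters"] = n_in
        r_in = spec.cavity_radius_A * np.sqrt(rng.random(n_in))
        phi_in = 2 * np.pi * rng.random(n_in)
        z_in = rng.uniform(-h / 2, h / 2, size=n_in)
        n_out = n_water_total - n_in
        r_out = rng.uniform(spec.cavity_radius_A + 2.0, spec.cavity_radius_A + 6.0, n_out)
        phi_out = 2 * np.pi * rng.random(n_out)
        z_out = rng.uniform(-h / 2, h / 2, size=n_out)
        r = np.concatenate([r_in, r_out])
        phi = np.concatenate([phi_in, phi_out])
        z = np.concatenate([z_in, z_out])
        for wi in range(n_water_total):
            add(
                "W",
                1000 + wi,
                "HOH",
                "O",
                "O",
                (r[wi] * np.cos(phi[wi]), r[wi] * np.sin(phi[wi]), z[wi]),
            )

        frames.append(
            StructureFrame(
                chain_ids=np.array(chain_ids),
                residue_numbers=np.array(res_nums),
                residue_names=np.array(res_names),
                atom_names=np.array(atom_names),
                elements=np.array(elements),
                coords=np.stack(coords),
                frame_index=fi,
                time_ns=fi * spec.frame_dt_ns,
            )
        )
        truth_rows.append(truth)
    return frames, pd.DataFrame(truth_rows)


def stationary_open_fraction(spec: ToyChannelSpec) -> float:
    """Stationary P(open) of the latent Markov chain."""
    a, b = spec.p_o2c, spec.p_c2o
    if a + b == 0:
        return 1.0 if spec.initial_state == "open" else 0.0
    return b / (a + b)


def latent_mixture_correlations(spec: ToyChannelSpec, p_open: float) -> dict[str, float]:
    """Correlations induced by the shared latent state, in closed form.

    For observables conditionally independent given the state, the mixture
    covariance is p(1-p)·Δμ_x·Δμ_y and the mixture variance adds p(1-p)·Δμ²
    to the within-state variance (the Poisson water count contributes its
    state-dependent rate as within-state variance).
    """
    q = 1.0 - p_open
    pq = p_open * q
    d_th = spec.dihedral_mean_closed_deg - spec.dihedral_mean_open_deg
    d_d = spec.distance_mean_closed_A - spec.distance_mean_open_A
    d_w = spec.water_rate_closed - spec.water_rate_open
    var_th = spec.dihedral_sd_deg**2 + pq * d_th**2
    var_d = spec.distance_sd_A**2 + pq * d_d**2
    var_w = p_open * spec.water_rate_open + q * spec.water_rate_closed + pq * d_w**2
    return {
        "r_distance_dihedral": pq * d_d * d_th / np.sqrt(var_d * var_th),
        "r_waters_dihedral": pq * d_w * d_th / np.sqrt(var_w * var_th),
    }


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------

@dataclass
class ToyEnergySpec:
    """Ground-truth model behind a synthetic microstate energy table.

    ``sites`` lists (site_id, model_pka, field_shift kcal/mol); a positive
    shift penalises protonation and lowers the effective pKa by
    shift/(ln10·RT).  ``couplings`` is a symmetric zero-diagonal matrix of
    pairwise protonation-protonation energies.
    """

    sites: list[tuple[str, float, float]]
    couplings: np.ndarray | None = None
    n_structures: int = 50
    noise_sd: float = 0.3
    temperature_K: float = 310.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sites) > 20:
            raise CapabilityError("more than 20 sites: exact enumeration unsupported")
        s = len(self.sites)
        if self.couplings is None:
            self.couplings = np.zeros((s, s))
        self.couplings = np.asarray(self.couplings, dtype=float)
        if self.couplings.shape != (s, s):
            raise ValueError("couplings must be (n_sites, n_sites)")
        if not np.allclose(self.couplings, self.couplings.T):
            raise ValueError("couplings must be symmetric")
        if not np.allclose(np.diag(self.couplings), 0.0):
            raise ValueError("couplings must have zero diagonal")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")

    @property
    def site_ids(self) -> list[str]:
        return [s[0] for s in self.sites]

    @property
    def model_pkas(self) -> np.ndarray:
        return np.array([s[1] for s in self.sites])

    @property
    def shifts(self) -> np.ndarray:
        return np.array([s[2] for s in self.sites])


def shift_for_target_pka(model_pka: float, target_pka: float, temperature_K: float = 310.0) -> float:
    """Field shift (kcal/mol) that moves a lone site's pKa to ``target_pka``."""
    return (model_pka - target_pka) * LN10 * rt_kcal(temperature_K)


def noiseless_energies(spec: ToyEnergySpec) -> tuple[np.ndarray, np.ndarray]:
    """(microstates, E0) of the noise-free model over all 2^S states."""
    micro = enumerate_microstates(len(spec.sites))
    x = micro.astype(float)
    e0 = x @ spec.shifts + 0.5 * np.einsum("mi,ij,mj->m", x, spec.couplings, x)
    return micro, e0


def ground_truth_curves(spec: ToyEnergySpec, ph_grid: np.ndarray) -> dict[str, np.ndarray]:
    """θ(pH) per site by direct enumeration of the noiseless model.

    Deliberately written as a plain Boltzmann sum (no log-domain tricks) so
    it serves as an independent oracle for the titration module.
    """
    micro, e0 = noiseless_energies(spec)
    rt = rt_kcal(spec.temperature_K)
    curves = {sid: np.empty(len(ph_grid)) for sid in spec.site_ids}
    for gi, ph in enumerate(np.asarray(ph_grid, dtype=float)):
        g = e0 + LN10 * rt * (
            ph * micro.sum(axis=1) - micro.astype(float) @ spec.model_pkas
        )
        w = np.exp(-(g - g.min()) / rt)
        z = w.sum()
        for si, sid in enumerate(spec.site_ids):
            curves[sid][gi] = float(w[micro[:, si] == 1].sum() / z)
    return curves


def generate_energy_table(spec: ToyEnergySpec) -> tuple[EnergyTable, np.ndarray]:
    """Synthesise E(x, m) = field terms + couplings + structure noise.

    Returns the table plus the noiseless per-microstate energies E0 (the
    ground truth the noisy table scatters around).  Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    micro, e0 = noiseless_energies(spec)
    noise = rng.normal(0.0, spec.noise_sd, size=(len(e0), spec.n_structures))
    if spec.noise_sd == 0:
        noise = np.zeros_like(noise)
    energies = e0[:, None] + noise
    structures = [f"s{m:03d}" for m in range(spec.n_structures)]
    table = EnergyTable(
        sites=list(spec.site_ids),
        microstates=micro,
        structures=structures,
        energies=energies,
    )
    return table, e0


# ---------------------------------------------------------------------------
# Variant suites
# ---------------------------------------------------------------------------

#: The nine channel conditions studied: unprotonated wild type, single/multi
#: protonations and the charge-mimicking mutants.
DEFAULT_VARIANT_LABELS = (
    "WT-unprotonated",
    "Hp418",
    "Ep327-Hp418",
    "Ep420",
    "Ep327-Hp418-Ep420",
    "H418R",
    "E327A-H418R",
    "E420A",
    "E327A-H418R-E420A",
)

_OPEN_BIASED_KINETICS = {"p_open_to_closed": 0.0005, "p_closed_to_open": 0.05}
_CLOSING_KINETICS = {"p_open_to_closed": 0.01, "p_closed_to_open": 0.002}


def make_variant_suite(
    variants: Sequence[str] | dict[str, dict] | None = None,
    n_trajectories: int = 5,
    base_spec: ToyChannelSpec | None = None,
    master_seed: int = 0,
) -> dict[str, list[tuple[list[StructureFrame], pd.DataFrame]]]:
    """Generate ``n_trajectories`` seeded trajectories per labelled variant.

    ``variants`` may be a list of labels (wild-type-like labels — those
    containing "WT" or "unprotonated" — stay open; all others transition
    open → closed) or a mapping label → ToyChannelSpec overrides.  Seeds are
    derived deterministically from ``master_seed``.
    """
    if variants is None:
        variants = list(DEFAULT_VARIANT_LABELS)
    if isinstance(variants, dict):
        items = list(variants.items())
    else:
        labels = list(variants)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate variant labels")
        items = []
        for label in labels:
            wt_like = "wt" in label.lower() or "unprotonated" in label.lower()
            items.append(
                (label, dict(_OPEN_BIASED_KINETICS if wt_like else _CLOSING_KINETICS))
            )
    if len({label for label, _ in items}) != len(items):
        raise ValueError("duplicate variant labels")

    base = base_spec or ToyChannelSpec()
    base_kwargs = {f.name: getattr(base, f.name) for f in fields(ToyChannelSpec)}
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(items) * n_trajectories)
    out: dict[str, list[tuple[list[StructureFrame], pd.DataFrame]]] = {}
    ci = 0
    for label, overrides in items:
        runs = []
        for _ in range(n_trajectories):
            seed = int(children[ci].generate_state(1)[0] % (2**31))
            ci += 1
            kwargs = dict(base_kwargs)
            kwargs.update(overrides)
            kwargs["seed"] = seed
            kwargs["variant_label"] = label
            runs.append(generate_toy_trajectory(ToyChannelSpec(**kwargs)))
        out[label] = runs
    return out


def default_energy_spec(
    n_structures: int = 50, noise_sd: float = 0.3, seed: int = 0
) -> ToyEnergySpec:
    """A channel-like titration model for the key pore-domain residues.

    E327 and H418 carry field shifts placing their effective pKa near 6.0
    (the protonation-prone regime of the closed pore), E420 sits lower, and
    a weak repulsive coupling links the E327/H418 contact partners.
    """
    t = 310.0
    sites = [
        ("E327.A", 4.25, shift_for_target_pka(4.25, 6.0, t)),
        ("E327.C", 4.25, shift_for_target_pka(4.25, 6.0, t)),
        ("H418.A", 6.54, shift_for_target_pka(6.54, 6.0, t)),
        ("H418.C", 6.54, shift_for_target_pka(6.54, 6.0, t)),
        ("E420.A", 4.25, shift_for_target_pka(4.25, 4.8, t)),
    ]
    couplings = np.zeros((5, 5))
    couplings[0, 2] = couplings[2, 0] = 0.2
    couplings[1, 3] = couplings[3, 1] = 0.2
    return ToyEnergySpec(
        sites=sites,
        couplings=couplings,
        n_structures=n_structures,
        noise_sd=noise_sd,
        temperature_K=t,
        seed=seed,
    )
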