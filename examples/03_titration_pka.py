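"""Ensemble-based pKa estimation from a microstate energy table.

Synthesises a noisy energy table for five pore-domain titratable sites
(known ground truth), reconstructs the partition function over protonation
microstates, and prints each site's titration midpoint with its +-1 sigma
uncertainty band.
"""

import numpy as np

import kvpore as kp

espec = kp.default_energy_spec(n_structures=50, noise_sd=0.3, seed=3)
table, e0 = kp.generate_energy_table(espec)
print(
    f"energy table: {table.n_microstates} microstates x "
    f"{table.n_structures} structures"
)

config = kp.AnalysisConfig()  # pH 3-8, step 0.01, 310 K
sites = [
    kp.TitrationSite(sid, pka, "base" if sid.startswith("H") else "acid")
    for sid, pka, _ in espec.sites
]
curves = kp.run_titration(table, sites, config)

grid = np.arange(3.0, 8.0001, 0.01)
truth = kp.ground_truth_curves(espec, grid)
print(f"{'site':>8} {'model pKa':>9} {'truth':>7} {'estimate':>8} {'band(k=1)':>16}")
for site in sites:
    c = curves[site.site_id]
    pka_true, _ = kp.estimate_pka(truth[site.site_id], grid)
    lo, hi = c.pka_band[1.0]
    print(
        f"{site.site_id:>8} {site.model_pka:9.2f} {pka_true:7.2f} "
        f"{c.pka_point:8.2f} [{lo:6.3f}, {hi:6.3f}]"
    )

# The estimate is the pH where the Boltzmann-averaged protonation fraction
# crosses 1/2; it matches the noiseless ground truth to a few hundredths of
# a pH unit at this noise level.  The band re-titrates at <E> +- 1 sigma:
# because the global shift is common to all microstates, only the
# state-to-state variation of sigma moves the midpoint.
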