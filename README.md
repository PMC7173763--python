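# kvpore

Analysis tools for pH-dependent gating of the Kv1.2 potassium-channel pore
domain: per-frame gating order parameters from trajectory ensembles, their
distributions and correlations across channel variants, and an
ensemble-based multi-site titration estimator that reconstructs the
partition function over protonation microstates to produce residue pKa
values with structural-fluctuation uncertainty.

It is written for structural bioinformaticians post-processing MD ensembles
of tetrameric pore domains (residues 312–421 of Kv1.2 and homologues),
where the questions are: *is the cavity wetted or dewetted, is S6 bent or
straight, is the R326–H418 inter-subunit contact intact, and which
titratable residues switch charge in the physiological pH range?*

## What it computes

**Gating order parameters**, per trajectory frame:

- *Cavity water count* — water oxygens inside a cylinder bounded by the
  selectivity-filter base above and the bundle-crossing gate below
  (default radius 5 Å). Wetted cavity ⇔ open pore; dewetted ⇔ closed.
- *S6 kink dihedral* — the torsion θ ∈ [0°, 360°) of the Cα atoms of
  L393, L400, V408, Y415. A bent helix sits near 130°, a straightened one
  near 245°.
- *R326–H418 inter-subunit distance* — minimum heavy-atom distance between
  R326 of one subunit and H418 of the adjacent subunit (~6 Å when the
  contact holds, ~15 Å when protonation breaks it).

**Ensemble statistics**: last-window pooling across trajectories,
wet/dewet classification, circular/linear histograms with mode detection,
2D log-population heat maps, and Pearson (or Spearman) correlations
between order parameters, summarised per channel variant.

**Titration**: given microstate energies E(x, m) over an ensemble of
structures m, the free energy of protonation microstate x ∈ {0,1}^S at a
given pH is

    G(x; pH) = ⟨E⟩(x) + ln(10)·RT·Σᵢ xᵢ·(pH − pKaᵢ,model),

and the protonation fraction of site i is the Boltzmann average
θᵢ(pH) = Σₓ xᵢ e^(−G/RT) / Σₓ e^(−G/RT), evaluated in the log domain over
the microstates dominant anywhere on the pH grid. The pKa is the pH where
θᵢ crosses ½; re-titrating at ⟨E⟩ ± kσ for k = 0.1 … 1.0 propagates the
structural spread of the energies into a pKa uncertainty band.

**Synthetic data**: because real trajectories and electrostatics energies
are bulky and setup-specific, a generator produces toy tetramer ensembles
whose three order parameters co-vary through a hidden open/closed Markov
state (with exactly known ground truth), and microstate energy tables with
known field terms, pairwise couplings and structure noise. All tests and
examples run from these.

## Worked example

```
$ python examples/03_titration_pka.py
energy table: 32 microstates x 50 structures
    site model pKa   truth estimate        band(k=1)
  E327.A      4.25    5.93     5.92 [ 5.915,  5.928]
  E327.C      4.25    5.93     5.91 [ 5.888,  5.935]
  H418.A      6.54    5.93     5.97 [ 5.963,  5.978]
  H418.C      6.54    5.93     5.92 [ 5.913,  5.926]
  E420.A      4.25    4.80     4.80 [ 4.797,  4.804]
```

The synthetic table gives E327 and H418 effective pKa values near 6 — the
regime in which mild intracellular acidification protonates them — and the
estimator recovers the enumerated ground truth to a few hundredths of a pH
unit at 0.3 kcal/mol structure noise. `examples/01_order_parameters.py`
and `examples/02_gating_statistics.py` show the geometric and statistical
layers; a closing variant drops to ~0 wet occupancy, gains the 245° helix
mode and shows strong distance–dihedral correlation, while an always-open
variant shows none.

A thin CLI wires the stages together for shell use:

```
kvpore synth --out run/synth --seed 1
kvpore orderparams run/synth/toy_traj*.pdb --out run/series
kvpore gating run/series/*_series.csv --out run/gating
kvpore pka --energy run/synth/energies.csv --sites run/synth/sites.csv --out run/pka
```

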