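# Methods

## Scope and model

`kvpore` post-processes conformational ensembles of a tetrameric
potassium-channel pore domain (Kv1.2 numbering, residues 312–421). It does
not run molecular dynamics and does not solve Poisson–Boltzmann
electrostatics: trajectories arrive as multi-model PDB files and
protonation-microstate energies as CSV tables (from any electrostatics /
force-field workflow, or from the built-in synthetic generator). The
dielectric/ionic-strength settings such workflows use are carried as
metadata only.

## Gating order parameters

**Cavity water count.** The "water cavity" has no unique geometric
definition; we use the simplest reproducible region consistent with its
location below the selectivity filter: a cylinder whose axis is the
membrane normal (config, default +z), whose axial bounds are the Cα
centroids of a filter-base residue set (default T374) and a gate residue
set (default V410), and whose radius defaults to 5.0 Å. A water counts if
its oxygen lies inside, boundaries inclusive. Water residues are
recognised by name (HOH/TIP3/SOL/WAT). All of this is configurable, which
also absorbs the ambiguity of whether waters between the gate bundle
crossing and the intracellular mouth should count.

**S6 kink dihedral.** The signed torsion of the Cα atoms of four S6
residues (default L393, L400, V408, Y415), computed with the standard
plane-normal/atan2 formula and mapped into [0°, 360°) by adding 360° to
negative angles. The non-conventional range is deliberate: the
straightened-helix population sits near 245°, which the conventional
(−180°, 180°] range would split. Collinear bond vectors (cross-product
norm < 1e−9) raise a degenerate-geometry error.

**Inter-subunit distance.** The minimum distance over all atom pairs of
R326 in one chain and H418 in the *next* chain of the ring order
(default A→B→C→D→A; all four ordered pairs are computed, since the
domain-swapped chain mapping is a convention, not a measurement). The
default atom subset is heavy atoms: nearest-atom distances over heavy
atoms are insensitive to the hydrogen placements that differ between the
very protonation states under study. A distance-residue pair other than
R326/H418 (e.g. E327/H418) is a config change.

**Invariances.** All three observables are invariant under common rigid
transformations (for the cavity count, the configured membrane normal must
be transformed along with the frame — it is part of the lab frame, not of
the structure); mirror reflection maps θ → 360° − θ and leaves counts and
distances unchanged. These are enforced by tests.

## Ensemble statistics

Trajectories are pooled by retaining the final ceil(w·n) frames of each
(default window fraction w = 0.25, i.e. the last quarter — the
equilibrated tail), then concatenating across the trajectories of one
variant. Hydration is classified wet iff the count reaches the threshold
(default 10 waters, inclusive); the threshold is a config knob because the
wet/dewet separatrix is drawn, not derived. Dihedral histograms are
circular with 2° bins; distances use 0.25 Å bins; counts 1-water bins.
Modes are strict local maxima of a moving-average-smoothed histogram
(default 5-bin window) that reach a prominence fraction (default 0.05) of
the global maximum; circular observables wrap. Correlations are Pearson by
default (Spearman via config) and are computed on the *pooled* ensemble,
not per trajectory and averaged (a per-trajectory alternative is a one-line
loop for the caller). For the per-variant summary, the four (pair distance,
dihedral) combinations are stacked, each pair distance matched with the
kink dihedral of its H418-carrying chain; a single-frame ensemble has no
ensemble variation, so its correlations are reported as undefined. 2D heat
maps store raw counts (conserving the pooled record count) with Pearson r
computed on the unbinned pairs; log10 scaling and empty-bin masking are
applied only at rendering.

## Titration

With S titratable sites, microstate x ∈ {0,1}^S and ensemble-averaged
energy ⟨E⟩(x) (arithmetic mean over structures; sample sd σ(x), zero for a
single structure), the semi-grand free energy at pH is

G(x; pH) = ⟨E⟩(x) + ln(10)·RT·Σᵢ xᵢ(pH − pKaᵢ,model),  RT = 0.0019872·T,

the standard proton-binding convention of constant-pH statistical
mechanics; acids and bases are distinguished only through their model pKa
and the supplied energies. Default model pKas (Glu 4.25, His 6.54, Asp
3.71, Lys 10.40, Arg 12.10, C-term 3.80, N-term 8.00) apply only when the
sites file omits them. Temperature defaults to 310 K and RT is always
computed, never hard-coded.

θᵢ(pH) is a Boltzmann average evaluated with log-sum-exp accumulation, so
adding ±500 kcal/mol to every energy changes nothing (gauge invariance,
tested to 1e−10). Exact enumeration is used up to 20 sites; beyond that a
capability error is raised (Monte-Carlo titration is out of scope). A
dominant-state subset — the union over the pH grid of states whose
normalised Boltzmann weight reaches a threshold (default 1e−12), plus the
top state per grid point — bounds the work without visible truncation
error at the default threshold.

The pKa is the smallest pH where θ crosses ½, located by linear
interpolation between grid points (default grid 3–8, step 0.01); curves
that never cross report no pKa, and multiple crossings are flagged.

**Uncertainty.** For k = 0.1 … 1.0 the titration is repeated with every
microstate's energy set to ⟨E⟩ + kσ(x) and to ⟨E⟩ − kσ(x) (one common
sign across all microstates per evaluation); the band is the min/max of
the two pKas. Because a *common* shift is pure gauge when σ is
state-independent, only the state-to-state variation of σ moves the
midpoint: a table with i.i.d. structure noise therefore yields very narrow
bands, while genuinely conformation-dependent energy spreads widen them
(single-site closed form: half-width = k·σ₀/(RT·ln10) when only the
protonated state fluctuates — 0.705 pH units per kcal/mol at 310 K). The
granularity of the shift (global, per-microstate, per-structure) is a
genuine design fork; the global choice is recorded in the CLI log, and the
alternative schemes were left out to keep the band interpretable as a
worst-case coherent shift.

## Synthetic generator

The toy channel emulates two-state gating: a per-frame latent open/closed
state shared by all four chains follows a two-state Markov chain
(directed switch probabilities default to a symmetric 0.02/frame — a
handful of transitions per 2000-frame trajectory, slow gating that still
mixes; variant suites use open-biased or closing-biased kinetics).
Conditional on the state, each chain's four-point pseudo-helix is built
with its torsion drawn from a wrapped normal (means 130°/245°, sd 10°),
single-atom R326/H418 proxies are placed on the chord between adjacent
chain centres at a normal separation (means 6.0/14.7 Å, sd 1.0 Å), and a
fixed population of waters is split between the cavity cylinder (Poisson
count, rates 25/3) and a shell strictly outside it, so atom ordering stays
constant across frames. Gaussian jitter (default 0.05 Å) is added to helix
and proxy atoms; the cavity scaffold markers are placed exactly, so the
measured counting region equals the generator's bookkeeping. Defaults are
the characteristic open/closed signatures of the Kv1.2 pore domain and are
not meant to be tuned per run.

What passing tests on these ensembles show: the measurement and statistics
pipeline recovers known distributional structure, correlations induced by
a shared latent state, and known titration behaviour. What they do not
show: correctness of any cavity-geometry convention against real pore
shapes, realistic water structure or residence, per-chain (2-fold
symmetric) gating, or force-field energetics — real data can violate the
conditional-independence and Gaussian/Poisson assumptions the closed-form
expectations rely on.

Energy tables are E(x, m) = Σᵢ xᵢ·shiftᵢ + Σᵢ<ⱼ Wᵢⱼxᵢxⱼ + ε(x, m) with
ε i.i.d. normal; ground-truth θ(pH) comes from direct enumeration of the
noiseless model through a deliberately independent plain-sum code path,
and a field shift of (pKa_model − pKa_target)·ln(10)·RT dials a site's
effective pKa exactly. The default 5-site table places E327/H418 sites
near pKa 6 with a weak repulsive contact coupling (0.2 kcal/mol), which
lowers their midpoints slightly below 6 — visible in the examples.

## Numerical choices and problem sizes

Boundary conventions are inclusive everywhere (cylinder membership, wet
threshold). Histogram masses sum to 1 within 1e−12. Energy tables
round-trip exactly through CSV (repr-precision floats, round-trip parser);
PDB coordinates round-trip to the fixed-column 0.001 Å. kJ/mol tables are
converted by 1/4.184 on read. The test suite and the acceptance script run
on deliberately desk-sized problems — trajectories of 40–2000 frames (the
full gating recovery uses 5 × 2000 frames with last-25 % pooling, ~10⁴
measured frames), 8-site (256-state) titration oracles, 50-structure
energy tables — sizes at which every brute-force oracle is exact and the
whole suite completes in a couple of minutes.

## Known limitations

- No insertion codes, altlocs or binary trajectory formats (XTC/DCD); no
  pore-radius profiling or solvent density maps.
- The cavity is a cylinder; strongly tilted or kinked pores would need the
  configurable axis or a different region entirely.
- Titration assumes the structural ensemble is fixed (no reweighting of
  conformations by protonation state) and is exact only up to 20 sites.
- The uncertainty band reflects coherent ±kσ energy shifts, not a full
  posterior over pKa.
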