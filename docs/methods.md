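# Methods

## The model

`ccphase` simulates designed multivalent coiled-coil (CC) polypeptides as
sticker–spacer associative polymers at one bead per residue (C-α level).
Each chain is an ordered list of CC "sticker" segments (3-heptad Sh coils,
4-heptad Pf coils, or the homodimeric 3-heptad coils APHh3/GCNh3) joined by
flexible Gly/Ser linkers (8 residues; a 40-residue variant exists).
Fluorescent-protein tags that appear in construct names are not part of the
model.

Interactions:

* **Bonds.** Harmonic, r0 = 0.38 nm (C-α spacing), k = 4000 kJ/mol/nm².
* **Coil rigidity.** A cosine bending term U = k(1 + cos θ) with
  k = 100 kJ/mol on coil-internal triplets keeps stickers rod-like; linker
  beads carry no bending term (fully flexible spacers).
* **Excluded volume.** WCA (12-6 truncated at its minimum and shifted) on
  every non-complementary bead pair, σ_rep = 0.57 nm, ε_rep = 1 kJ/mol.
  The core is deliberately commensurate with the sticky contact distance:
  a much smaller core lets third chains reach through a satisfied dimer
  interface and produces spurious bundling.
* **Sticky attraction.** A truncated-shifted 12-6 well with σ = 0.570 nm,
  ε = 7.5 kJ/mol per complementary bead pair, cutoff 2.5 σ.  Only
  *complementary* pairs attract: the coil types must be designed partners
  (S1h–S2h, S3h–S4h, P5f–P6f, P13f–P14f, APHh3–APHh3, GCNh3–GCNh3), the
  registries must match the pair's orientation (parallel: equal registry;
  antiparallel: mirrored registry, equal lengths), and the two coil axes
  (end-to-end unit vectors) must point the right way within a 60° band.
  This registry-plus-axis gate is this package's concrete mechanism for
  orientation-specific CC pairing; it keeps dimer interfaces in-register
  and lets parallel- vs antiparallel-pairing homodimers frustrate the
  wrong contacts in single-chain designs.
* **1:1 valence saturation.** A bead's sticky attraction acts only toward
  its nearest gated complementary bead, and only when the choice is mutual.
  CC dimerization is stoichiometrically exclusive; with purely pairwise
  additive wells, two fully zipped dimers would still gain the entire
  zipper energy again by stacking in register (four-helix bundling), which
  the designed peptides do not do.  Mutual-nearest-partner selection makes
  a satisfied interface chemically inert, which is the property the designs
  rely on.  The selection (like the axis gate) introduces measure-zero
  force discontinuities at switch points; away from those boundaries forces
  are the exact negative energy gradient.
* **Overlap handling.** Both 12-6 forms switch to a constant-force linear
  continuation below a floor distance (0.50 nm sticky, 0.44 nm WCA), so
  packing overlaps relax under bounded forces instead of diverging.

Per-pair well depths carry calibrated scale factors fitted so that each
pair's simulated two-chain dissociation constant tracks its measured value
(isothermal titration calorimetry: S1h–S2h 2.3 mM, S3h–S4h 0.34 mM,
P5f–P6f 5.9 µM, P13f–P14f 2.3 µM).  Binding free energy is strongly
sublinear in total contact energy — the bound ensemble is dominated by
partial zippers, so an analytic ΔΔU = RT·ln(Kd ratio) offset badly
overestimates the affinity gain of longer or stronger coils — hence the
scales are fitted by short two-chain simulations rather than derived:
S1h–S2h 1.00 (the anchor), S3h–S4h 1.10, P5f–P6f 1.12, P13f–P14f 1.16.
Homodimeric coils, which have no measured affinity, keep scale 1.

## Temperature scale

The simulation runs on its own temperature scale, fixed by matching the
*single coil-pair* dimer equilibrium to the measured dissociation
constants: two single-coil chains in a periodic box, bound-state occupancy
θ read off complementary contacts, and Kd = (1−θ)²·C_total/θ (two-molecule
convention; C_total is the total chain concentration).  Scanning the model
temperature places the simulated S1h–S2h Kd at its measured 2.3 mM
near 625 K on the model scale; the package therefore maps the experimental
310 K regime to 625 K and the 298 K regime to 605 K
(`ccphase.slab.MODEL_TEMPERATURE`).  Desk-scale slab runs use the 298 K
regime by default.  The mapping is approximate by
construction — only relative affinities and qualitative phase behaviour
are meaningful, not absolute temperatures.

## Units and integration

GROMACS-style units (nm, ps, kJ/mol, amu, K); every bead has the average
residue mass of 110 amu (dynamics comparisons are relative).  Dynamics is
Langevin: velocity Verlet with an Ornstein–Uhlenbeck velocity kick applied
every 5 steps (BAOAB in the every-step limit, NVE at zero friction),
dt = 0.01–0.02 ps, friction 0.1–1 /ps depending on preset.  Friction sets
the diffusive timescale, not the equilibrium, so desk presets use low
friction (0.1 /ps) to reach assembly/disassembly regimes quickly.  Kernels
are numba-compiled with strict IEEE arithmetic so trajectories are
reproducible bit-for-bit for a given seed across machines; center-of-mass
motion is removed every 100 steps.

Neighbor search keeps two Verlet lists refreshed when any bead moves half
the 0.3 nm skin: a cell-list scan with the short WCA cutoff, and a distance
filter over the statically complementary bead pairs (enumerated once per
topology from types and registries) with the long sticky cutoff.

## Slab protocol

Phase coexistence uses the standard slab workflow: (1) relax each packing
unit in isolation in a small periodic cube; (2) pack relaxed units on a
jittered grid at 0.8 beads/nm³ and energy-minimize (L-BFGS); (3) compress
the box along z in 5 deterministic affine stages (chain centers rescaled,
internal geometry untouched) with re-equilibration between stages, to
1.5 beads/nm³ — a barostat-free stand-in for pressure-coupled
compression; (4) expand z by the expansion factor (desk default 6)
leaving coordinates fixed, creating vacuum around the slab; (5) NVT
production.

Packing units are bound-pair configurations wherever a pair can bind:
hetero pairs for two-component 1:1 systems, homo pairs for
single-component systems whose chains can homodimerize, single chains
otherwise.  A pair is laid as two rods, either parallel or reversed
(the sense that the coils' designed orientation permits), at a sampled
registration stagger: layout (sense, k) is drawn with weight
exp(1.5·matches), where matches counts coil positions whose types are
designed partners in the orientation that layout realizes.  This emulates
packing pair configurations drawn from isolated-pair equilibrium: matched
arrangements enter the slab predominantly as fully aligned
(valence-satisfied) dimers, while mismatched arrangements enter with
diverse partial registrations and dangling coils.  The weight 1.5 per
matched coil is a desk-scale compromise — higher weights under-diversify
mismatched pairs (letting small systems close into inert oligomers),
lower weights under-align matched dimers.

## Analysis

* **Density profile.** Chain-COM number density along z, each frame
  recentered on the circular mean (the slab center under periodic
  boundaries).  Dense density = mean of the tenth of bins nearest the
  center; dilute = mean of the farthest quarter.
* **Clusters.** Two chains are connected when they share a *realized*
  complementary contact within 1.5 σ_sticky — registry-compatible,
  orientation-gated, and mutually nearest, exactly the pairs the sticky
  potential counts as bound.  (The purely geometric criterion merges a
  crowded slab of satisfied dimers into one component, which erases the
  dimer-poisoning signal at small chain counts.)  Species statistics
  (sizes, the dominant class, dimer dominance) use the instantaneous
  graph; the largest-cluster mass fraction — the "nearly all chains in one
  droplet" question — uses a ±5-frame union of edges, since a chain
  momentarily between partners inside the droplet still belongs to it.
  The dominant species per frame is the size class holding the plurality
  of chains (ties to the larger size); the dimer-dominance fraction is
  the fraction of equilibrated frames whose dominant class is size 2.
* **Phase call.** condensate ⟺ dense/dilute ratio ≥ 5 AND largest-cluster
  mass fraction ≥ 0.8; else dimer ⟺ dimer-dominance ≥ 0.5; else diffuse.
* **Diffusion.** Chain-COM MSD averaged over time origins, lags up to a
  quarter of the window; D = slope/6 fitted over lags between 10% and 50%
  of the maximum lag; bootstrap over chains (200 resamples) for the
  standard deviation; fits with R² < 0.9 are flagged subdiffusive.
* **Engagement.** A coil is engaged in a frame when ≥ 50% of its beads are
  within the contact cutoff of complementary beads of a single partner
  coil; unique partners are counted over the window.
* **Equilibrated window.** The final 50% of production frames.

## Desk scale

The published protocol (tens of microseconds, hundreds of chains, three
replicates) is retained as the `full` preset but is far beyond interactive
budgets.  The desk presets used by the test-suite and the acceptance
script run 8–12 chains per system for ~3 ns of model time (production
150 000 steps at dt = 0.02 ps, friction 0.1/ps), with majority votes over
three seeds for the central mismatched/matched arrangement contrast and
single seeds elsewhere.  At this scale the
slab is only ~10 chains across, so single phase calls are noisy;
the design-rule contrasts (network vs dimer vs diffuse, fast vs arrested
droplets, more vs fewer unique partners) are preserved, but absolute
quantities (densities, diffusion coefficients, engaged-time percentages)
are not expected to match the published full-scale numbers.

## What the synthetic inputs do and do not emulate

The construct library generates every design combination studied
(two-component Sh and Pf pairs, matched-arrangement controls, the
orientation-patterned single chains, and the third-chain inhibition
triples) with the experimentally observed phase labels as expected
outcomes.  The model captures valency, arrangement, linker length, pairing
specificity, orientation, and relative affinity.  It does not capture
sequence-level energetics, helicity coupling, electrostatics, crowding, or
fluorescent-protein tags — so passing desk-scale tests demonstrates that
the design rules are reproduced by sticker–spacer physics, not that any
particular cellular quantity is predicted.

## Desk-scale failure modes

Three published contrasts are not reproduced at desk scale, and the
corresponding checks are expected to fail there:

* The segregated single-chain arrangement (six parallel-pairing coils
  followed by four antiparallel-pairing ones) reads condensate.  Its
  experimental dispersal requires annealing into block-zipped dimers with
  intramolecular hairpins; at 12 chains / 3 ns the antiparallel blocks
  crosslink between pairs long before they fold back, and the gel cannot
  anneal away on a timescale ~1e4 shorter than the published runs.
* The blind-challenge pair of the alternating 3-heptad chain with a
  four-coil single-type partner reads diffuse: half the alternating
  chain's coils have no partner type in the system at all, and the halved
  valency keeps the largest cluster below the "nearly all" threshold at
  12 chains.
* The 3- vs 4-heptad diffusion contrast is not resolved: the 4-heptad
  system freezes into several small irreversibly bonded clusters rather
  than one droplet, and small clusters diffuse freely, so its measured
  coefficient reflects cluster diffusion rather than in-droplet arrest.
  The engagement contrasts (engaged-time fraction higher, unique partners
  fewer for 4-heptad coils) are reproduced.

## Known limitations

* The desk-scale cluster graph is a strict instantaneous-contact criterion;
  near the percolation threshold single phase calls flip between seeds,
  which is why panel calls use majority votes.
* The temperature mapping is a one-dimensional calibration against dimer
  Kd; it cannot make all four pairs match their measurements
  simultaneously at one temperature (two length classes, one scale).
* The compression stages are deterministic rescalings, not a barostat; the
  slab density target is a parameter, not an observable.
* Registration-stagger sampling substitutes for long pair-equilibration
  runs; its weight (2 per matched coil position) is a desk-scale choice.
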