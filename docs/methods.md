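# Methods

This note documents the models, conventions, parameter defaults, and design
choices behind remdkit, and states explicitly what the synthetic ensembles
do and do not emulate.

## Conventions

Coordinates are stored in nm (PDB I/O converts to/from Å; the
hydrogen-bond energy and all energetics formulas evaluate distances in Å).
Energies are in kcal/mol, times in ps, temperatures in K, charges in e.
Residue numbering is 1-based and contiguous within each chain. The region
scheme on the 42-mer is NTR 1–16, CHC 17–21, turn 22–29, CTR 30–42, with
the derived preCHC 11–16; the four primary regions partition 1–42.

Topologies carry heavy atoms plus the backbone amide H only. Side-chain
hydrogens appear in no analysis here: contacts and SASA are defined on
heavy atoms, and the amide H is the single hydrogen the assignment needs.

## Production-window selection

`select_production` keeps frames in the half-open time window
(start, end] at times start + k·stride. Half-open is the only convention
under which a 140 ns window sampled every 50 ps gives exactly 2,800 frames
per replica (and 33,600 over twelve replicas); a closed window would give
2,801. The stride must be a multiple of the source sampling interval —
anything else silently aliases and is rejected.

## Secondary-structure assignment

The assigner implements the Kabsch–Sander electrostatic model:
E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, a bond when
E < −0.5, with at most the two lowest-energy acceptors kept per donor and a
clash guard (any distance < 0.5 Å → +∞). The amide H is taken from the
frame when present and otherwise placed 1.01 Å from N, anti to the
preceding carbonyl (C→O direction reversed) — the convention reference DSSP
implementations use internally, which matters because a differently placed
H shifts borderline bond energies. Same-chain donor–acceptor pairs with
|i−j| < 3 are excluded: no pattern uses them, and the covalently bonded
neighbour would otherwise score spuriously through its tiny r_CN.

Pattern rules: two consecutive i→i+4 turns make an α-helix (residues
i..i+3), i→i+3 turns a 3₁₀-helix, Kabsch–Sander parallel/antiparallel
bridge patterns make strand, turn interiors and Cα bends (>70° over i±2)
make turn. The eight-class bookkeeping folds to five classes as H→ALPHA,
G→THREE10, E and isolated bridge B→STRAND, T and bend S→TURN, rest→COIL;
priority H > E > G > T/S. Bend is folded into turn because disordered-
peptide ensembles are conventionally reported that way (mean turn contents
near 50% are only reachable with S included). Helical patterns never span
chain breaks; bridges may (inter-chain sheets are how the hexapeptide can
acquire strand content). π-helices and polyproline-II are not classified.

Fidelity is checked against mdtraj's DSSP implementation (test-only
dependency): ≥95% per-residue agreement on ideal helices, the bundled
β-ladder templates, and reconstructed toy-sampler frames.

## Geometry and contacts

- Cα contact cutoff: 0.65 nm default (the field-standard Cα definition);
  intramolecular maps zero |i−j| < 3.
- Heavy-atom contact and salt-bridge cutoff: 0.40 nm minimum-distance
  default. D23–K28 uses carboxylate oxygens × side-chain nitrogens.
- Reaction coordinates: nbeta = (#strand residues in CHC∪CTR)/18;
  ncontact = (#CHC–CTR Cα pairs < 0.65 nm)/65, clipped to [0,1]. The
  normalization 65 = 5×13 is the theoretical maximum pair count; both the
  cutoff and the normalization are configuration, not claims about any
  particular published protocol.
- RMSD uses the proper-rotation branch of Kabsch superposition (determinant
  correction), so mirror-related selections never produce an improper fit.
- Moving averages are centred on the time axis and truncated at the series
  edges.
- SASA is a Shrake–Rupley quadrature on a golden-spiral point lattice
  (default 960 points, probe 1.4 Å, Bondi-style vdW radii). Coincident
  equal-radius atoms are de-duplicated (the lowest index keeps the
  surface), which makes the overlapping-atom limit exact rather than a
  quadrature tie. The hydrophobic subset sums C and S heavy-atom
  contributions.

## Landscape

The 2D PMF is W(bin) = −k_B·T·ln(count/count_max) on a 20×20 grid over
[0,1]² by default; occupied minimum exactly 0, empty bins NaN (never 0).
k_B = 0.0019872 kcal/mol/K; the display temperature defaults to 300 K and
is configuration (the PMF shape is temperature-independent up to scale).
State populations are evaluated on the raw coordinates, not the histogram,
so they are independent of binning. Rectangles are closed-left/open-right
with the right edge at 1.0 closed, so a layout can tile [0,1]² exactly;
overlapping rectangles are rejected by name before any computation.

The bundled S1–S6 rectangle layout is calibrated to the discrete
(nbeta, ncontact) levels the synthetic templates realise — boundaries sit
at midpoints between levels (nbeta cuts at 0.11, 0.28, 0.50; ncontact cut
at 0.05), with S6 the high-nbeta/high-ncontact hairpin corner and the
high-nbeta/zero-contact corner left to "Others" for the preCHC-sheet +
CTR-hairpin template. Real-data layouts are runtime configuration.

Block standard errors split a time-sorted series into n contiguous
equal-length blocks (default 4), truncating any remainder;
SE = sd(block means, ddof=1)/√n. `ss_propensity` instead requires an exact
split and reports the remainder — a propensity profile silently dropping
frames is harder to notice than a rejected call.

## Clustering

Gromos greedy clustering: repeatedly take the unassigned frame with the
most unassigned neighbours (distance strictly < cutoff; ties broken by
lowest frame index), remove it and its neighbours as a cluster. The centre
is the max-neighbour frame, clusters are ordered by size then centre index,
and the algorithm is deterministic. Default cutoff 0.3 nm pairwise Cα-RMSD
over the 42-mer only (a bound hexapeptide samples too diffusely to anchor
an RMSD fit).

## Energetics (MM-GB/SA)

Single-trajectory approximation: complex, receptor, and ligand geometries
come from the same frame, so intra-chain MM terms cancel and only
cross-chain pairs enter ΔE_elec (Coulomb, k_e = 332.0636 kcal·Å/mol/e²,
no cutoff) and ΔE_VdW (Lennard-Jones, Lorentz–Berthelot combination).
1–4 exclusions never arise because no intra-chain pair is evaluated.

Polar solvation is generalized Born with Hawkins–Cramer–Truhlar pairwise
descreening (scale 0.8 on neighbour radii, no offset) and the Still pair
function f_GB = √(r² + R_iR_j·exp(−r²/4R_iR_j)); effective radii are
recomputed per species. The single-atom limit reproduces the Born formula
exactly (q = 1 e, R = 2 Å, ε_out = 80 → −81.98 kcal/mol), which anchors
the implementation analytically. Defaults: ε_in = 1, ε_out = 80. The
nonpolar term is γ·SASA + b per molecule with γ = 0.00542 kcal/mol/Å²,
b = 0.92 kcal/mol; counting b per molecule (the complex holds two) makes
every component vanish for infinitely separated chains. ΔG_bind is the
exact sum of the component means; no configurational-entropy term is
estimated. A Poisson–Boltzmann backend could replace the GB term without
changing the report schema, but a grid solver is out of scope here.

The bundled peptide charge set is deliberately schematic: neutral backbone
(N −0.35, H +0.25, CA +0.10, C +0.50, O −0.50; H-less residues fold the H
charge into N), integer formal charges on Asp/Glu/Lys/Arg side-chain
groups, histidine neutral unless protonation is requested. It is a
synthetic parameter set for exercising the machinery, not a published
force field.

## Synthetic ensembles

### Toy replica-exchange sampler

A bead chain (default virtual bond 0.38 nm, springs 1000 kcal/mol/nm²)
sampled by single-bead Gaussian Metropolis moves on a geometric temperature
ladder T_k = T_min·(T_max/T_min)^(k/(n−1)) (defaults 276.0–592.3 K), with
neighbour exchanges accepted at min(1, exp[(β_i−β_j)(E_i−E_j)]) every 50
steps (alternating even/odd pairs) and pseudo-time 1 ps per step. Optional
dihedral bias terms k·(1−cos(φ−φ0)) and square contact wells provide
structure. Two analytic anchors validate the sampler: harmonic
equipartition (mean spring energy → k_BT/2 for stiff springs; the radial
Jacobian correction is O((σ/r₀)²) ≈ 0.8% at the defaults, far below the
statistical error of the runs used) and the radial Boltzmann quadrature
for square-well occupancy. For assignment tests a crude backbone is
rebuilt from the Cα trace; both the in-package assigner and the reference
implementation see the same reconstructed coordinates, so the comparison
is like-for-like.

### State-mixture generator

Each frame draws a state (multinomial over planted fractions), a structural
motif, a salt-bridge indicator, then builds coordinates from cached
ideal-geometry templates: helices at (φ,ψ) = (−57°,−47°), strands at
(−140°,135°), quasi-extended polyproline-II-like coil at (−75°,145°).
β-ladders are real: a mobile ideal strand is rigidly fitted so the
alternating double hydrogen bonds of an antiparallel sheet form with proper
register (target positions laid along the fixed strand's C=O and N–H
directions make the least-squares fit essentially convex), and amide
hydrogens are recomputed globally with the anti-to-carbonyl convention
after assembly. Chain breaks between segments are tolerated; the analyses
are hydrogen-bond- and distance-based and never differentiate through a
junction. Schematic heavy side chains are marched outward from Cβ; for
bound systems interchain overlaps below 0.30 nm are relaxed by moving
side-chain atoms only, preserving the fitted hydrogen-bond geometry.

The eight motifs realise distinct, noise-stable (nbeta, ncontact) levels:
coil and helix (0,0); a collapsed CTR-on-CHC packing with Cα contacts but
no hydrogen-bond register (0, ~0.09); one-, two-, and three-double-bond
CHC–CTR ladders at nbeta ≈ 0.22, 0.44, 0.56 with rising contact counts
(for the short ladders the pre-strand tail of the mobile segment is coiled
into a helix so the extended remainder cannot ladder up beyond the intended
pairs); a CTR-internal hairpin (0.33, 0); and a preCHC–CHC sheet plus
CTR-hairpin combination (0.56, 0) landing outside every rectangle. At the
default coordinate noise (σ = 0.005 nm, plus a random rigid motion per
frame) no label flips were observed in thousands of frames, so planted and
recovered populations differ only by multinomial sampling error.

Ground-truth secondary-structure labels are the assignment of the
noise-free template, computed once per template. Frame-level truths (state
identity, salt-bridge indicator, contact placement) are exact draws. Strand
plantings are realised only through hydrogen-bonded pairings — an unpaired
extended segment has no bridge partner and no strand assignment, so "strand
without a partner" is not a constructible planting.

The salt bridge is planted by placing K28's NZ at 0.30 nm (bridged) or
0.80 nm (unbridged) from D23's OD1 along the template direction — margins
of ≥0.1 nm on either side of the 0.40 nm cutoff make the planting robust
to noise. Bound topologies dock an extended hexapeptide 5.5 Å from NTR
residues 2–7.

### What the generator does not emulate

The generator targets statistical structure, not physics: no Boltzmann
weighting, no realistic Rg or SASA scale (the templates are more extended
than a collapsed disordered monomer), no rotamer realism, no solvent.
Passing recovery tests demonstrates that the analysis stack measures what
was planted at realistic sample sizes and error levels; it does not
demonstrate force-field-level realism, and quantities the generator does
not plant are not comparable to experimental or published simulation
values.

## Problem sizes

Recovery analyses use 4,000-frame mixtures with four-block errors (the
block SE of a 47% population at this size is ≈0.5–1%); toy-sampler checks
use 2–5-bead chains for equilibrium statistics and a 42-bead chain for
assignment frames; oracle-equivalence fixtures stay at ≤20 frames and ≤60
atoms where exhaustive enumeration is exact. The numbered analysis scripts
run 2,000 frames per system. These sizes were chosen so every statistical
check operates well inside its error budget while the full study remains a
desk-scale computation.
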