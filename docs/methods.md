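# Methods

This note records the models and procedures implemented in `seipincg`, their
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.  Internal units are nm, ps, g/mol and kJ/mol;
spring constants are accepted in kcal/mol/Å² (the elastic-network
convention) and converted on input.

## Reduced-resolution mapping

Atomistic molecules are coarsened to chemically meaningful groups before
any interaction analysis: POPC becomes 11 groups (choline head, phosphate,
glycerol moiety, four tail groups per acyl chain), triolein 13 groups
(glycerol moiety plus four tail groups per each of three chains), and each
protein residue a backbone and a side-chain group.  Group positions are
**mass-weighted** centers of their member atoms — the mapping then conserves
every molecule's center of mass exactly, which the geometric alternative
would not; this is our documented choice where either convention could be
argued.  Acyl-chain carbons are split into four contiguous blocks per chain,
as evenly as possible with the extra carbons assigned to the terminal-most
blocks, and the ester/carbonyl atoms go with the glycerol moiety so the
hydrophilic unit stays intact.  The shipped atom-name table uses CHARMM-style
heavy-atom names; hydrogens are assumed folded into their parent heavy
atoms unless explicit per-atom masses are passed.  Unknown names fail
loudly with the molecule and atom identified.  Glycine side chains (no
heavy atoms) are not representable by the default residue scheme; pass a
custom scheme for glycine-containing selections.

## Coordination statistic

For each residue the side-chain group probes all lipid groups of a species
through the rational switching function s(r) = [1−(r/r₀)⁶]/[1−(r/r₀)¹²]
with r₀ = 0.4 nm, evaluated as the algebraically identical 1/(1+(r/r₀)⁶) to
remove the spurious singularity at r = r₀.  Distances use the minimum-image
convention in the orthorhombic box (the formula's source is silent on
periodicity; at typical box sizes image contributions are ≤ 10⁻⁶).  No
distance cutoff is applied by default — the summand decays as (r₀/r)⁶ — but
one can be set for speed.  Normalisations: per molecule (÷ species molecule
count) and per grouped atom (÷ 12 tail or 1 glycerol group per TG).  Block
statistics use three equal-length trajectory blocks; trailing frames beyond
a whole multiple are dropped with a logged warning.

## Diffusion

Lateral (XY) displacements only: the lipids of interest surround a membrane
protein and the radial classification is planar, so a 2-D Einstein fit
(D = slope/4) is the consistent choice; coordinates must be unwrapped
before recentering (performed in that order).  The three radial classes are
< 3.5 nm, 3.5–7.0 nm and > 7.0 nm from the recentered protein origin, with
boundary ties assigned inward.  The MSD is time- and ensemble-averaged over
all origins (FFT form of the time average).  The default fit window spans
10–50% of the available lags; no window is prescribed by the method's
source, and the choice trades statistical noise at long lags against
short-time ballistic/cage effects.  Confinement is flagged by comparing the
late-lag slope (last 30%) against the initial slope (first 5% of lags);
a ratio below 0.1 marks a plateau, in which case the fitted D is reported
as statistically indistinguishable from zero rather than as a mobility.

## CG model

Every CG bead has mass 200 g/mol and zero charge.  Lipids are linear
four-site molecules — PL: head, interfacial, tail, tail; TG: glycerol plus
three tails.  These per-bead counts are our reading of the published
coloring of the four-site models; bonds use the energy k(r−r₀)² (no ½
prefactor) with k = 500 kJ/mol/nm², r₀ = 0.75 nm, and PL carries two
harmonic angles of 0.5 k_BT (310 K) about 180°; TG has no angle terms.
Protein beads cover four consecutive residues each (mass-weighted centers;
a 243-residue subunit gives 61 beads, the last covering three residues).

Elastic networks: the uniform ENM connects every bead pair closer than
15 Å with spring constant 0.2 (default) or 2 kcal/mol/Å², rest length =
build-time distance.  The heterogeneous ENM (hENM) is built by iterative
fluctuation matching against an aligned ensemble: candidate pairs are those
with mean distance < 12 Å; each pair's constant is updated multiplicatively,
k ← k·(σ²_model/σ²_target)^α (α = 0.7), until the model's pair fluctuations
match the ensemble's to 0.5% (configurable), with springs matched to
k < 1 kJ/mol/nm² pruned and close pairs (< 11 Å) left without a spring
back-filled at 0.1 kcal/mol/Å².  Two numerical choices matter here.
First, the matched statistic is the **bond-projected** distance fluctuation
var(n̂·(x_j−x_i)) with n̂ the mean bond direction — the exact statistic a
harmonic model predicts (n̂ᵀ(C_ii+C_jj−2C_ij)n̂); matching the raw var(|x_j−x_i|)
instead imports transverse anharmonic contributions and biases stiff
springs by tens of percent.  Second, per-spring identifiability requires a
network without redundant constraints: on a statically determinate
framework (exactly 3N−6 springs, e.g. the stacked-tetrahedra truss shipped
in `synth.gen_spring_truss`) 5 000 samples recover every constant to a few
percent, while on redundant networks several spring sets produce nearly
identical fluctuations and individual constants are genuinely not
identifiable to that precision even though the reproduced fluctuations and
RMSF are.

The idealized cage generator supplies the protein geometry: an 11-subunit
ring with a lumenal-domain blob per subunit, an HH arc at lumenal-leaflet
depth on a ring of radius ~2 nm, and two TM segments spanning the membrane
whose terminal-tip circle (~13 nm diameter by default) matches the
experimentally reported ER–LD neck range of 13–17 nm.  Annotation flags
drive the attraction scaling: hydrophobic-phase protein beads ↔ PL tails at
factor 1.0; interfacial protein beads ↔ PL interfacial at 1.5; the two HH
beads and the four central beads of each TM segment ↔ TG at 1.5; TM
terminal tips ↔ PL interfacial/head at a configurable factor r (default
1.5) — the quantity varied in the tip-charge computational experiments.
Twenty-four proteinized PLs are placed on a sunflower spiral inside the HH
ring, oriented like lumenal-leaflet lipids, and tied into the elastic
network at 0.1 kcal/mol/Å² within 11 Å.  Bead annotations are assigned from
depth in the reference membrane frame (membrane half-thickness 2.25 nm),
with override lists accepted.

Spherical bilayers place leaflet head shells on Fibonacci lattices with
leaflet counts proportional to shell areas at 0.7 nm² per lipid
(configurable; not a published value), TG dispersed in the midplane shell
at the requested mole percent (n_TG = round(f/(1−f)·n_PL)), and clash
removal deletes whole lipids within 0.5 nm of any protein bead (the
atomistic protocol's 0.09 nm criterion is not transferable to beads of this
size).

## Nonbonded model and Langevin engine

The production-scale force field of this model family lives in tabulated
pair potentials; the package ships one documented parametric family so the
engine is self-contained: a WCA repulsive core (σ = 0.65 nm, ε_rep =
2.5 kJ/mol) plus a cos² attractive well from r_m = 2^{1/6}σ to the 1.5 nm
cutoff whose depth and force scale linearly with the pair's scaling factor
(ε_att = 4.5 kJ/mol ≈ 1.75 k_BT at factor 1).  σ and ε_att were chosen so
that the four-site bilayer is a stable, fluid membrane at 310 K under the
production time step; the well shape guarantees a purely repulsive
potential at factor 0 and exact linear scaling of depth and force.
Externally supplied tables can be evaluated in place of the closed form,
and the exporter writes the scaled tables (1 200 uniform points per class
pair), a LAMMPS `real`-units data file and an input-script skeleton
(50 fs step, 310 K/100 ps Langevin, 15 Å cutoff).

The integrator is velocity Verlet with BAOAB Langevin splitting: friction
γ = m/τ with τ = 100 ps and Gaussian noise satisfying
fluctuation–dissipation at the target temperature; with the thermostat
disabled it reduces to plain velocity Verlet (energy drift < 10⁻⁴ relative
over 10⁴ steps at 5 fs on the test systems).  Noise comes from a
counter-based Philox stream keyed by (seed, step) with draws in bead order,
so runs are bit-identical for identical seeds on one platform.  Nonbonded
pairs come from a periodic k-d tree with a 0.3 nm skin, rebuilt when any
bead has moved half a skin, and validated against an all-pairs scan;
exclusions cover bonded 1-2, angle 1-3 and elastic-spring pairs.  Beads
closer than 0.05 nm (below the table range) abort the run with the pair
identified.  Freshly built configurations carry packing stress, so
`equilibrated_run` prepends a short warmup at dt = 5 fs with a 1 ps
coupling before the production parameters take over.

## Lens metrics

TG molecules are clustered by single linkage with molecule–molecule
distance = minimum over bead pairs and a 2 nm cutoff — the most inclusive
reading of "any two TG molecules within 2 nm", and the one that reproduces
the described lens-merging behaviour.  Nucleation percentage is the largest
cluster's share of all TG molecules.  Shape anisotropy is
κ² = (3/2)(λ₁²+λ₂²+λ₃²)/(λ₁+λ₂+λ₃)² − 1/2 over the **gyration-tensor**
eigenvalues (mass-weighted): the inertia and gyration tensors share
eigenvectors and the κ² form is the one whose limits are exactly 0 for a
sphere and 0.25 for a thin plane, which pins the choice.  The ER–LD neck
diameter is twice the mean in-plane radial distance of the TM terminal-tip
beads from the complex axis, taken as the gyration-tensor eigenvector of
the protein beads with the smallest eigenvalue (the symmetry axis of an
oblate ring); no circle-fitting procedure is prescribed by the source.
Growth-mechanism tags on the nucleation time series are labelled
heuristics: a jump of more than 10 percentage points between consecutive
frames marks a coalescence candidate, sustained slow positive growth marks
Ostwald-ripening-like behaviour.

## Synthetic data and what passing tests show

The generators emulate the statistical structure the analyses assume —
controlled TG fractions and shapes, Brownian walkers with known D (exact
Ornstein–Uhlenbeck updates under confinement), exact thermal ensembles of
known spring networks, and the idealized cage — with a mandatory seed and
ground truth returned alongside the data.  They do not emulate force-field
chemistry, hydrodynamics, membrane undulations or protein conformational
change, so passing recovery tests demonstrates the correctness of the
estimators and builders, not the realism of any particular force field.

## Scaled-down nucleation comparison

The production observation — dissolved TG nucleates only in the
seipin-containing system — required ~10⁸-step simulations of 40–60 nm
vesicles with the original tabulated potentials, which is out of desk
scope.  The shipped comparison (`seipincg.demo`) is a deliberately small
analogue: a 12 nm flat patch with sixteen dissolved TG molecules inserted
at identical random positions in a bare copy and in a copy carrying a
laterally compacted rigid cage whose TG-attractive sites form one connected
capture zone; both run 2×10⁴ production steps from a common warmup, and the
time-averaged nucleation percentage over the second half of the caged run
is compared with the bare run at matched steps.  The cage wins through the
two mechanisms the full-scale systems exhibit: adsorption of TG onto its
HH/TM sites concentrates molecules within linking distance of one another,
and its excluded footprint constrains the XY area the remaining TG can
explore.  At this scale the bare patch retains a substantial
random-proximity baseline (sixteen TG in ~140 nm²), so the comparison is
stochastic and reported as a qualitative ordering, not a phase boundary.  Problem sizes throughout the test suite (patch
dimensions, walker counts, sample counts, step counts) are chosen as the
smallest at which each estimator's statistical error is comfortably below
the asserted tolerance.

## Known limitations

- The nonbonded family is a stand-in parameterisation: quantitative phase
  behaviour (e.g. the exact critical TG concentration) is not expected to
  match the production model, only qualitative ordering.
- hENM per-spring recovery guarantees hold on determinate networks;
  redundant networks reproduce fluctuations/RMSF but not unique constants.
- The default residue scheme cannot map glycine; the mapping assumes
  hydrogens are folded into heavy atoms unless masses are given.
- The engine targets 10²–10⁴ beads on one core; production-scale systems
  are meant to be exported, not integrated in-process.
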