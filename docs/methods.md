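# Methods

## Model

`cgap` simulates multi-site autophosphorylation of a dimeric receptor
tyrosine kinase as a sequence of *binding events*: excursions of
phosphorylation-site tyrosines (P-sites), carried on long disordered
C-terminal (CT) tails, into the catalytic site of the active ("receiver")
kinase of the asymmetric dimer.  The receptor is coarse-grained to one
pseudo-atom per residue, centered on the C-alpha; a bound
AMPPNP·2Mg<sup>2+</sup> substrate complex is represented by nine
finer-grained beads (adenine C2/C6/N9, deoxyribose C4′, the three
phosphorus atoms, the two Mg ions) connected by a complete graph of
harmonic bonds.  Because every pairwise distance in that graph is
restrained, separate angle terms for the complex would be redundant and
are not assigned.

The energy model is structure-based (Gō):

* **Bonded terms.** Harmonic bonds `k_bond (r − r_eq)²` and angles
  `k_angle (θ − θ_eq)²`, with reference values measured on the input
  structure, plus 1-fold and 3-fold cosine dihedrals
  `½V₁(1+cos(φ−φ₁)) + ½V₃(1+cos(3φ−φ₃))` whose phases are chosen as
  `φ₁ = φ_native + π`, `φ₃ = 3φ_native + π` so the native dihedral is the
  energy minimum.  Harmonic constants act as printed — `k(Δ)²` without a
  factor ½ — so a bond stretched 1 Å at `k_bond = 20 kcal/mol/Å²` costs
  exactly 20 kcal/mol.  Defaults: `k_bond = 20 kcal/mol/Å²`,
  `k_angle = 10 kcal/mol/rad²`, `V₁ = 0.5`, `V₃ = 0.25 kcal/mol`.
* **Native contacts.** Residue pairs of the structured regions whose
  all-atom minimum distance is within 5.5 Å in the reference, with
  sequence separation ≥ 3, attract through the 12-10-6 well
  `ε[13(σ/r)¹² − 18(σ/r)¹⁰ + 4(σ/r)⁶]` (minimum −ε at `r = σ`, a small
  ~0.14 ε desolvation barrier near 1.5 σ); `ε = 0.6 kcal/mol`; `σ` is the
  reference pseudo-atom separation — the energy acts between pseudo-atoms,
  so the pseudo-atom distance is the only consistent well minimum even
  though detection is all-atom.  A plain 12-10 well is selectable
  (`contact_form`).
* **Excluded volume.** All other non-bonded pairs (separation ≥ 3) repel
  via `ε(σ_vdw/r)¹²` with `σ_vdw = 4 Å`, `ε = 0.6 kcal/mol`.
* **Electrostatics.** Debye–Hückel,
  `332.0637 q_i q_j exp(−r/λ_D)/(ε_s r)` with `ε_s = 78.4` and the
  screening length derived from the ionic strength (0.15 M) and
  temperature — `λ_D ≈ 7.85 Å` at 298 K — with no distance cutoff.
  Charges are assigned at pH 7.6: Asp/Glu −1, Lys/Arg +1, free termini
  +1/−1, His by Henderson–Hasselbalch (pKa 6.0) and then zeroed below the
  significance threshold |q| < 0.1; side chains whose pKa lies well above
  the simulation pH (Cys, Tyr) are treated as neutral rather than
  titrated.  Phosphate beads carry −4/3 each and Mg +2, making the
  nucleotide complex net-neutral.  Electrostatics apply to non-bonded
  pairs only (same ≥ 3 separation rule as the other non-bonded terms).
* **Membrane.** Two planes normal to z at ±16.5 Å.  Transmembrane beads
  are restrained to their reference z (`k = 5 kcal/mol/Å²`); extracellular
  beads feel a half-harmonic penalty below the outer plane and
  intracellular plus nucleotide beads above the inner plane (same k).
  Structured/modeled segments are assigned a membrane side by the sign of
  their reference z.

## P-site groups and the binding-event trigger

Each P-site is a nine-residue window (N−4…N+4 around the tyrosine).  Its
docked-complex contacts are supplied once per site and mirrored onto the
P-site copies of both chains and onto both active sites, with identical σ.
The *trigger* is the set of tyrosine/active-site contacts (nine); a trial
terminates when all of them are formed simultaneously at a contact check.
A contact is counted as formed when `r ≤ 1.35 σ` — a Q-style criterion
chosen within the conventional 1.2–1.5 band so that a genuinely bound pose
registers robustly at the 6 ps check cadence despite thermal fluctuation
of the loosest trigger contact.  Window contacts beyond the tyrosine
("auxiliary") carry attractive terms but do not gate the trigger; the
γ-phosphate contacts of a docked tyrosine are treated the same way.
Groups monitoring the activator's (non-catalytic) active site are
attractive but never terminate a trial.

## Dynamics

Propagation is overdamped (Brownian) Euler–Maruyama:
`Δx = (Δt/k_BT) D F + √(2Δt) B ξ`, `B Bᵀ = D`.  Default mobility is
free-draining Stokes–Einstein per bead (hydrodynamic radii 5.3 Å for
residues, 3.5 Å for nucleotide beads; water viscosity 0.89 mPa·s at
298 K — the temperature and viscosity are configurable, as neither is
fixed by the model).  An optional pairwise mode builds the
Rotne–Prager–Yamakawa tensor, refreshed every 24 ps, with correlated
noise from either an exact Cholesky factor or the Geyer–Winter
truncated-expansion approximation (`rpy-cholesky` / `rpy-tea`).

Schedules: 125 fs step; short-range non-bonded pairs (≤ 12.5 Å at list
build) every step; medium-range pairs (12.5–25 Å) every 1 ps with forces
held in between; list rebuild every 6 ps; electrostatics every step with
no cutoff; snapshots every 100 ps; event checks at the rebuild cadence
(the check interval is configurable; the original work states only that
checks were periodic).

Numerical safeguards, chosen once and applied everywhere:

* The production loop iterates only repulsive pairs within 10.5 Å of the
  last list build; beyond that the r⁻¹² term is below 10⁻⁵ kcal/mol and
  thermal drift cannot close the gap within one rebuild interval.  The
  NumPy reference implementation keeps every scheduled pair, and the
  compiled kernel is validated against it to ~10⁻¹³.
* Per-step displacements are clamped at 0.75 Å (≈ 7× the per-step thermal
  rms).  The clamp never touches equilibrium dynamics; it arrests the
  runaway oscillation an explicit first-order step can develop on steep
  r⁻¹² inner walls.  Raw displacements above 10 Å still raise an
  instability error.
* Dihedral torques are zeroed below sin θ = 0.02 of either flanking bond
  angle, where the dihedral gradient (∝ 1/sin θ) is ill-conditioned.
* The first-order integrator's stationary distribution carries an O(Δt)
  variance inflation on stiff terms (≈ 4% in bond-length variance at the
  production step).  Distributional validation tests (Boltzmann sampling,
  equipartition) therefore run at a 10 fs step, inside the integrator's
  convergent regime; schedule-cadence and event tests use the production
  step.
* Campaign start structures are relaxed by a short clamped steepest
  descent before propagation: restoring P-site attractions on an ensemble
  frame can leave restored contact pairs inside their wells' inner walls.

## Experiment designs

*Randomization ensembles.*  Start structures are harvested from
trajectories run with every P-site attractive term removed, which
precludes stable P-site/active-site docking while the tails randomize.
The production-scale design is 5 trajectories × 10 µs sampled every
0.1 µs (500 members); desk-scale runs shrink all three numbers and state
the sizes used.

*First-event campaigns.*  Each trial draws a start uniformly (seeded
`seed + trial`), restores attractions, and runs to the first productive
event or a timeout (default 5 µs, configurable; the original simulations
ran until events occurred, so the timeout is an artifact decision —
timeouts are reported separately and excluded from frequency counts).

*Charge variants.*  `zero_ct_charges` zeroes the CT-tail charges (ranges
968–1186/960–1186 for receiver/activator in the real receptor) leaving
attractions intact — the frequencies from such campaigns isolate
topological factors and feed the v_phos prediction.

*Second-event campaigns.*  Starts are bound-state frames for a first
site; that site's phosphorylation is mimicked by adding a formal −1 to
its tyrosine bead (a −2 variant is available via `charge_delta`) and
removing every attractive term involving its nine window residues, so
each trial begins with the release of the phosphorylated site.

*Nonproductive binding.*  Tyrosine-to-activator-site distance traces are
segmented into episodes: open after the distance holds ≤ 12 Å for a dwell
time (default 1 ns — the plateaus in the original analysis were read by
eye, so the dwell is our debounce choice), close on a sustained exit.

## Statistics

The cis/trans significance test is an exact equiprobable multinomial
goodness-of-fit: two categories use the exact two-sided binomial
(minimum-likelihood two-sidedness convention); more categories use exact
enumeration up to n = 60, otherwise seeded Monte Carlo (10⁵ draws by
default) with the same likelihood ordering and a reported standard
error.  Whether the original per-site claims used pairwise or omnibus
comparisons is not stated; both are available and the campaign summary
reports the two-category cis/trans test (with optional site exclusion,
e.g. removing the kinase-proximal site from the comparison).

Proximity censuses (40 Å ball around the γ-phosphate) and distance
distributions (30 Å subset around the catalytic aspartate) use closed
balls — boundary included.

`v_phos = k'_intra · (kcat/KM)` combines the relative per-site binding
frequency from a charge-stripped campaign (cis+trans summed, normalized
to sum 1 — any positive scaling gives the same relative values) with the
published peptide catalytic efficiencies shipped in
`cgap/data/psite_kinetics.tsv`.  Sites without kinetics are flagged.

The start-structure correlation audit compares same-site event pairs'
start sample-time gaps (same randomization trajectory only) against the
triangular null `p(Δt) = (2/T)(1 − Δt/T)` for two times drawn uniformly
from [0, T].

## Synthetic toy systems

The generator emulates the topology the method assumes, not any real
receptor's geometry: two pseudo-kinase folds (serpentine bead paths
through a 3×2×3 template at 5.0 Å spacing — a typical non-bonded
C-alpha neighbor distance, which also keeps the summed contact stiffness
inside the overdamped-Euler stability margin at the 125 fs step) glued
into an asymmetric dimer by interface contacts; coarse α-helical TM
anchors (22 beads, 1.5 Å rise) confined between the walls with short
extracellular stubs; and self-avoiding random-coil tails carrying
P-sites at configurable tether distances, decorated with acidic charges
(−1 every 5th bead, echoing the acidic character of real CT tails).
Fixture native contacts use a 7.5 Å pseudo-atom cutoff since generated
toys have no all-atom reference.  The catalytic patch is a 3×3 fold
face; the docked pose sits 4.5 Å above its center, defining the nine
trigger σ values, and the flanking window residues (±1…±4) carry
auxiliary contacts to patch beads within 10 Å of their docked positions
— mirroring how real docked windows contact the active site and giving
the docking funnel realistic width.  One patch bead doubles as the
catalytic-aspartate stand-in and another as the γ-phosphate stand-in for
the analysis anchors.

Bound-state starts are constructed without elastic strain: the tail is
rigidly rotated about its anchor (preserving all internal angles and
dihedrals), the tyrosine is pulled onto the pose by a steered descent
whose target tracks the current patch geometry, and the state is relaxed
freely; construction fails loudly if the tether contour cannot span the
anchor-pose distance or the pose does not hold.  The "near-docked"
fixture pins a state at eight of nine contacts permanently by giving one
trigger pair a reference separation below the excluded-volume contact
distance: it can never register as formed, which exercises the strict
all-contacts-simultaneous trigger.

What the toys do *not* reproduce: real fold architecture and contact
maps, sequence-specific docking energetics, the 16-P-site competition of
the real receptor, or µs-scale tail relaxation (toy tails are ~20–70
residues against ~225).  Passing toy campaigns therefore demonstrates
that the machinery — randomization, event detection, cis/trans
accounting, phosphorylation mimicry — behaves correctly and that the
expected topological biases (sequence-proximal P-sites bind their own
catalytic site more often) emerge; they do not validate quantitative
rate predictions for any real receptor.

Toy tails inherit the reference-biased bonded terms of the model, so
their conformational memory is long relative to desk-scale trajectories;
campaign statistics consequently lean on start-structure diversity from
the randomization ensemble, exactly as the production protocol does.

## Desk-scale problem sizes

The package's own test and acceptance campaigns use: a randomization
ensemble of 5 × 60 ns sampled every 2 ns (150 members); a first-event
campaign of 140 trials with a 12 ns timeout on a toy dimer of ~220 beads
carrying both a tether-10 and a tether-60 P-site per chain (the two sites
compete within each trial, as sites of one CT tail do in the real
receptor); free-diffusion checks on a 1000-replicate bead gas over 10⁵
steps.  These sizes are the package's choice of a desk-scale analogue;
the production-scale numbers above remain the defaults of the respective
configuration objects.

## Known limitations

* First-order integration with the production step slightly inflates
  stiff-mode variances (see above); event statistics are insensitive to
  this, but users measuring fine distributional properties should reduce
  the step.
* The free-draining default ignores hydrodynamic coupling; the tensor
  mode is exact in its covariances (Cholesky) but O(N²)–O(N³) and not
  numba-accelerated.
* Charge assignment is formal (integer charges plus His titration); no
  structure-based pKa prediction.
* The per-step displacement clamp makes extreme-force configurations
  relax non-physically (but deterministically); it is a stability device,
  not a sampling claim.
* mmCIF input, loop closure between fixed anchors, and automated peptide
  docking are out of scope; docked contact lists are inputs.
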