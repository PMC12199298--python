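# Methods

This note documents the models, conventions and numerical choices behind
`qosite`, and what the synthetic generators do and do not emulate.

## Geometry conventions

All lengths are nanometres, all angles degrees wrapped to the half-open
interval (−180°, 180°]. Torsions follow the IUPAC sign convention and are
invariant under quartet reversal. χ1 uses the N–Cα–Cβ–Cγ quartet for every
residue type; χ2 uses the conventional next-bond quartet (Glu Cα–Cβ–Cγ–Cδ,
Tyr …–Cδ1, His …–Nδ1, Asp …–Oδ1). Periodic minimum-image distances support
triclinic boxes; the implementation reduces the displacement by the rounded
fractional shift and then searches the 27 neighbouring lattice images, which
is exact for any non-degenerate cell and bit-identical to the plain
Euclidean distance whenever no wrap is needed. Periodicity is opt-in per
call: experimental structure surveys are always non-periodic (crystal cells
are not meaningful for these intramolecular measurements), trajectory
analyses pass the frame's box.

## Conformer classification and the mode survey

Side-chain conformers *t*, *g*, −*g* are defined by three 120°-wide bins
centred on 180°, +60° and −60°. Only the centres are physically meaningful;
the boundaries (±120° and 0°) are a convention chosen to make classification
a total function, with boundary angles assigned as |χ| ≥ 120° → *t* and
0° → *g*. A torsional mode is the joint tuple (Y147 χ1, E295 χ1, E295 χ2,
Y297 χ1); modes are counted over all monomer models, sorted by descending
count with lexicographic tie-break, and lettered A, B, C, … Models in which
any of the four torsions cannot be computed are reported as skipped, never
silently dropped.

Experimental-model handling: multi-model files expand to one surveyed model
per model record, dimers to one per chain; for duplicated atom names the
highest-occupancy alternate location is taken; waters are recognised by
residue name (HOH/WAT/H2O) and only their oxygens are counted. The
role→(chain, residue) mapping is an explicit TSV input — cross-organism
residue numbering is curation, not computation, so the package never guesses
it from sequence.

## Contact criteria and statistics

A direct H-bond is a heavy-atom minimum group distance strictly below the
cutoff (default 0.35 nm). A *k*-water bridge requires an ordered chain of
*k* distinct water oxygens with every consecutive link strictly below the
same cutoff. No angular criterion is applied — the distance-only definition
is the one the analyses are built on. Bridge state is defined frame by
frame and is agnostic to water identity: if the bridging water exchanges
with an immediate replacement within one frame, the contact remains formed.
Connections that would need more than two bridging waters are never used in
wire assembly (see below), though `bridge_order=3` detection exists as a
diagnostic.

Occupancy θ is the fraction of formed frames. Lifetimes are
continuous-with-tolerance: maximal formed runs, where interruptions no
longer than the gap tolerance (default: one frame interval) do not break an
event, and an event's duration spans its first to last formed frame
inclusive. The estimator the underlying data would ideally justify is not
uniquely defined; both the tolerant default and the strict tolerance-0
variant are exposed, and the mean lifetime is monotone non-decreasing in
the tolerance. Moving averages use a centred rectangular window (default
1 ns) with truncated, renormalised edge windows; with this definition the
window-size-weighted mean of the smoothed series equals the raw occupancy
exactly (the unweighted mean differs only by edge effects of order
window/length).

Trajectories can be supplied as in-memory frames or loaded from standard MD
formats (PDB/GRO topology with XTC/TRR/DCD or multi-model PDB coordinates)
via MDAnalysis; frames with missing atoms abort the run rather than being
skipped, since silent gaps would corrupt θ.

## Free-energy profiles and metadynamics reweighting

Profiles are weighted histograms mapped through ΔG_b = −kT ln p_b and
shifted so the minimum over non-empty bins is zero. kT is fixed at
R·310 K = 2.5775 kJ/mol. Empty bins are masked and never interpolated;
barriers are not read across masked gaps. Default bin widths are 5° for
angles and 0.025 nm for distances — artifact choices, configurable.
Angular histograms treat the domain as periodic, and metadynamics hill
evaluation uses periodic Gaussian images.

Bias removal uses final-bias reweighting: weights w_i ∝ exp(+V_final(s_i)/kT)
with the last accumulated bias evaluated at each sample's CV value. This is
the simplest estimator consistent with a well-tempered run, in which hill
heights decay and the bias shape converges; time-dependent estimators are
out of scope. Because early samples are collected while the bias is still
far from converged, analyses here discard the first 20% of a biased
trajectory before reweighting — a standard equilibration discard whose
effect shrinks as runs lengthen. Replicas on identical binning combine into
a per-bin mean with SE = sd/√n; with the usual n = 2 independent runs that
SE is itself noisy and is reported with that caveat.

When biased and unbiased trajectories are pooled into one surface, each
trajectory's weights are first normalised to its own frame count, so
replicas contribute in proportion to simulated time.

## Proton-wire enumeration

The contact graph has donor nodes (the quinol oxygens Q O1/Q O4), relay
nodes (Y147, E295, Y297, H276) and release nodes (H152, PRA, D278). Edges
carry mechanism sets drawn from {direct, 1-water, 2-water}; any mechanism
requiring more than two bridging waters is rejected at graph assembly, on
the grounds that a wire's stability falls quickly with the number of mobile
waters that must align simultaneously. When the graph is built from contact
statistics rather than a declared edge list, an edge is admitted if any
mechanism's occupancy reaches θ_min (default 0.05 — comfortably below the
weakest admitted bridge in the shipped instance, which runs at 16%); the
shipped instance is insensitive to any θ_min ≤ 0.16.

A wire is a simple path from a donor to a release node in which release
nodes are terminal sinks — a pathway may not pass through one release group
en route to another, which would otherwise generate spurious continuations
beyond the propionate. Wires are deduplicated by node sequence; a hop's
alternative mechanisms (direct vs. bridged) do not multiply wires but are
reported per edge. H152 is modelled as a release node because its proton
leaves the site by Rieske-domain motion rather than through this network.
Output order is deterministic (donor, then path length, then lexicographic),
and a report ranks wires by bottleneck = minimum edge occupancy, with
unmeasured bottlenecks ranked last.

## MSA conservation

Rows whose gap fraction strictly exceeds 25% are removed (the reference
row is protected; a reference above the threshold is an error). Conservation
of residue X at a reference position is 100 × (rows carrying X) / (rows
without a gap there): gaps are excluded from numerator and denominator, a
choice surfaced in output metadata since reasonable alternatives exist. The
column→reference-number map comes from the reference row's gap structure.
The queried residue is an explicit argument, so consensus-residue and
reference-residue conservation can both be computed. The per-column
frequency table (for logo rendering) uses the all-rows denominator instead,
so its rows sum to 100% over residues plus gap.

## Synthetic generators: what they emulate

The generators reproduce the statistical structure each analysis stage
assumes, not the physics of the solvated complex.

* **Torsion samplers** draw from exp(−U/kT) on the periodic angle domain by
  Metropolis Monte Carlo (step auto-tuned to 30–50% acceptance during
  burn-in; default burn-in 2000 steps). Designed potentials are sums of
  cosine wells; the standard test case is a double well with a 10 kJ/mol
  barrier and 3 kJ/mol asymmetry. Only distributional correctness matters
  downstream — the samples carry no kinetic meaning.
* **Metadynamics** deposits well-tempered hills h_k = h₀ exp(−V(s_k)/((γ−1)kT))
  with h₀ = 0.6 kJ/mol, width σ = 0.4 rad (the natural unit for torsional
  CVs), bias factor γ = 15 and one hill per 1000 sampler steps, mirroring a
  deposition every 2 ps of 2 fs steps. The accumulated bias lives on a
  0.25° periodic grid (interpolation error negligible at σ ≈ 23°) and the
  long-run bias approaches −(1 − 1/γ)(U − min U), which the tests verify.
* **Telegraph contact series** are discrete-time two-state chains with
  switch probabilities k·dt (validated k·dt ≤ 0.1), giving stationary
  occupancy k_on/(k_on+k_off) and geometric on-dwells of mean 1/k_off.
* **Model ensembles** build PDB files atom by atom from internal coordinates
  (NeRF placement), so planted χ angles and planted water/substrate
  distances are exact up to the 0.001 Å PDB coordinate precision (≲ 0.03°
  and ≲ 0.0005 nm). An optional rigid rotation + translation jitter changes
  nothing internal, which is precisely the invariance the survey must
  respect. The residues are spatially separated fragments — these files
  exercise the same readers and measurements as real structures but are not
  physical protein models.
* **Alignments** are per-column multinomial draws with planted frequencies
  and exact planted per-row gap fractions; the reference row is gap-free
  consensus.

Consequently, passing tests demonstrate that the measurement machinery is
correct on data with known ground truth; they do not validate force fields,
sampling convergence on the real μs-scale system, or the curated residue
mapping of real PDB entries. Trajectory-level observables of the real
system (bridge occupancies, nanosecond lifetimes, hydration medians,
barrier heights) require those simulations and are outside what the
synthetic conditions can reproduce.

## Problem sizes used in the shipped analyses

The standard runs use 79 planted survey models (matching the experimental
ensemble size), 10⁵ telegraph frames, 4 × 2.5·10⁵ metadynamics steps
(10⁶ total, analysed after the 20% discard), and 10⁴ alignment rows —
sizes at which the 3-standard-error recovery checks are well inside their
asymptotic regime.

## Known limitations

* Final-bias reweighting carries a transient systematic error that the
  equilibration discard reduces but does not remove; block-averaged or
  time-dependent estimators are deliberately out of scope.
* The H-bond criterion has no angular term; at 0.35 nm heavy-atom cutoff
  this slightly over-counts bent geometries.
* Alternate-location handling (highest occupancy) and water naming in
  experimental files are assumptions surfaced in output headers; insertion
  codes beyond the first are ignored.
* SE from two replicas is reported as-is and is itself highly uncertain.
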