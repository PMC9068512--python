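# Methods

This note records the models, conventions and numerical choices behind
`porestate`, in the spirit of a package methods appendix: what each stage
assumes, which parameters matter, and what the synthetic generators do and do
not emulate.

## Coordinate frame and structure handling

All analyses run in a gate-centred frame: the centre of mass of the reference
residue's Cα atoms (T625 by default, one per receptor chain) is translated to
the origin, and the pore axis is rotated onto z. The axis is the principal
(largest-variance) direction of the gate Cα cloud (residues S614–T625 over the
four chains), signed so that the selectivity-filter backbone (residues
586–590) lies at negative z; the extracellular side is therefore positive z
and downward water flow is −z. The rotation is the minimal rotation carrying
the axis onto z, so an already-aligned frame is left untouched and the
transform is always proper (det = +1, chirality preserved). Residue numbers
are taken verbatim from the file; chains map to subunit positions A–D by
chain ID unless a mapping is supplied. Alternate locations collapse to the
highest-occupancy conformer (count logged). PDB and mmCIF are both read
through gemmi; multi-model files become frame series with a constant atom
order, which is checked.

## Pore radius and conductance classes

The pore radius at axial position z is the radius of the largest sphere
centred anywhere in the perpendicular plane (within a lateral search bound,
default 2.5 Å of the axis) that overlaps no atom:
r(z) = max over centres of [min over atoms (distance − vdW radius)].
The centre search is a deterministic 0.1 Å grid refined by a Nelder–Mead
polish clamped to the search bound; this replaces the Monte Carlo annealing
of classic pore-profiling tools so that repeated runs are bit-identical.
Van der Waals radii default to the Bondi set. Where no atoms bound the
sphere the radius is capped (default 10 Å) and flagged. The gate window is
the z-span of the T617–T625 Cα atoms, the filter window the span of the
586–590 backbone; both are configurable because different structures place
these residues at slightly different depths.

The minimum gate radius maps to a conductance class by thresholds anchored at
the water radius: C when R_min ≤ 1.4 Å, O1 when 1.4 Å < R_min ≤ 2.3 Å, O2
when R_min > 2.3 Å. Boundaries are inclusive downward, so exactly 1.4 Å is
still closed. The package ships no experimental coordinates; the pore tests
use synthetic tetramer stand-ins (`conductance_standins`) whose ring radii
place the true inscribed-sphere radius mid-band for each class (about 1.1,
1.9 and 3.0 Å), so classification is exercised away from the knife edges.

## Permeation counting

A passage scores under a two-plane hysteresis rule: the counter arms when the
particle crosses the entry plane in the counting direction (water default
entry −6 Å, exit −16 Å), fires when the exit plane is reached, and disarms on
a backward re-cross of the entry plane. Partial excursions score nothing;
completed passages cannot double-count; a particle may score repeatedly after
re-entry. Crossings are detected by sign change between consecutive samples
(with linear interpolation for event times), so passages faster than the
snapshot stride still count. One rule is ours: a displacement larger than a
wrap threshold (default 25 Å, far beyond any physical per-stride motion but
smaller than a periodic-box hop) is treated as reservoir re-entry and resets
the state machine rather than scoring. Without it, a particle returning to
the upper reservoir through the periodic boundary after a completed passage
would register a spurious reverse event; with it, counted events equal
planted events exactly on the synthetic traces.

Rates are events per ns, whole-trace or in repeated blocks (default 40-ns
blocks every 200 ns). Snapshot-interval recalibration regresses fine-stride
counts on matched coarse-stride counts by ordinary least squares; because the
functional form of that map is a free choice, both the intercept fit and the
through-origin slope are reported. Occupancy maps histogram samples over
z ∈ (−45, 10) Å and time, with an optional 5 Å lateral cylinder when 3-D
positions are available; binning uses direct floor-indexing so samples on bin
boundaries land deterministically and totals reconcile exactly. A gate is
"continuously open" while every z-cell of the gate window is occupied; open
intervals are maximal such runs. Ion counts under an applied voltage convert
to conductance as G = N·q·e/(T·V), reported in pS.

## Gate features and angle encoding

Dihedrals use the standard IUPAC-signed atan2 form (χ1 of T617 from
N–Cα–Cβ–Oγ); the implementation is cross-checked in the tests against
mdtraj/MDAnalysis conventions and an independent projection formula. The M3
bend angle fits principal directions to the Cα runs below and above the hinge
(A618), both oriented by residue order; a straight helix scores 0°. Pore
areas are shoelace areas of the four Cα vertices projected perpendicular to
the pore axis, azimuthally ordered so input order is irrelevant. Gate RMSD is
the minimum RMSD of the S614–T625 backbone (C, O, N, Cα, Cβ) after Kabsch
superposition. Clamshell closure α is defined operationally as the residual
rigid rotation of the D2 lobe after superposing a subunit's D1 lobe onto an
apo reference — a declared substitute for the unpublished measurement
procedure, exact on constructed rotations. d635 is the Cα–Cα distance of the
declared D2 marker within each LBD dimer; L and H are the horizontal and
vertical positions of the D2 centre of mass in the gate frame.

For clustering, distances are standardised to unit variance and each angle
becomes a (sin, cos) pair scaled by one joint factor giving the pair unit
total variance — distances and angles then carry equal weight, the encoding
is invertible (atan2 recovers the angle), and circular neighbours such as
179° and −179° stay adjacent. Zero-variance columns are dropped with a
warning since they carry no clustering information.

## Cluster identification

The pipeline embeds the encoded features with t-SNE (perplexity 30, PCA
initialisation, fixed seed; deterministic), seeds clusters with flat-kernel
mean-shift at a deliberately small bandwidth (2% of the embedding
bounding-box diagonal), deduplicates converged modes at bandwidth/2, then
merges seeds with a two-cutoff rule: a pair merges when centroids are within
one cutoff and any cross-pair of points within a second; merges propagate
transitively via union-find. The defaults make the point-pair cutoff the
discriminating barrier (2× bandwidth) under a generous centroid pre-filter
(12× bandwidth): measured embedding geometry on planted data shows t-SNE
sheds small same-conformation islets about one bandwidth from their parent
cluster, while genuinely distinct conformations stay several bandwidths
apart, so a tight centroid cutoff fragments states and a tight point cutoff
strands islets. Final clusters are labelled alphabetically by descending
size. Cluster statistics use circular means and SDs (√(−2 ln R̄)) for angles;
the representative frame minimises the periodicity-aware distance to the
cluster mean, ties resolving to the earliest frame. A coarse k-means pass
(k = 10 default, k-means++ under the given seed) is available over feature
vectors or gate coordinates; in coordinate mode frames are iteratively
superposed onto the evolving mean so the Euclidean metric approximates
pairwise-superposed RMSD.

t-SNE layouts are not comparable across implementations or seeds; nothing
downstream depends on the layout, only on neighbourhood structure.

## Umbrella sampling and WHAM

WHAM iterates the self-consistent equations on a 0.1 Å histogram grid to a
10⁻⁸ kcal/mol tolerance on the window constants (10⁵ iteration cap), in
log-space throughout to avoid under/overflow, and reports F = −kT ln p with
the minimum anchored at zero (mean-anchoring is available for bin-wise
comparisons). kT is 0.596 kcal/mol (300 K) unless configured. Window sample
counts entering the denominators are the in-range counts, so restricting the
grid does not bias the window weights. Interior bins with no samples raise a
coverage-gap error naming the gap. Error bars come from a Monte Carlo
bootstrap honouring serial correlation: each window of N samples with
autocorrelation time t (smallest lag where the normalised autocorrelation
falls to e⁻²) is resampled with replacement at size ⌊N/t⌋ and WHAM re-run;
the per-bin SD across replicates is reported. Convergence is the maximum
absolute difference between PMFs from the first and second halves of every
window, mean-anchored on a common grid spanning the anchors.

## State assignment

Clusters group into conductance states by water permittivity (passages per ns
at zero voltage) — the one metric available for every equilibrium cluster —
using an exact dynamic-programming minimum-variance 1-D partition
(Fisher–Jenks) into n states (default 4), labelled C, O1, O2, O3 in
increasing order. Ion conductance and PMF barriers are carried as
corroborating columns; a barrier that rises with the state label flags the
report as inconsistent, since a higher barrier must mean lower conductance.
O4 is a reserved label only: it is never assigned automatically, reflecting
that the widest-gate conformation is expected to need far longer sampling
than these analyses assume. With fewer clusters than states, or all-equal
permittivities, the state count is reduced with a warning.

## Synthetic data: what it does and does not emulate

The generators provide every input with exact ground truth emitted alongside
the data, never re-derived from it, and all are byte-reproducible under a
fixed seed.

- The toy gate is a marker-atom model: per subunit, backbone markers
  (N, Cα, C, O, Cβ) for residues 614–625 on rings of configurable radius
  (1.5 Å rise per residue), χ1-defining side-chain atoms at the T617/T625
  analogues placed by exact internal-coordinate construction, a short
  586–590 filter segment below, and two flanking wall markers per residue
  closing the pore wall azimuthally. Bent subunits displace markers above
  the hinge radially outward on a linear ramp — a genuine kink of angle
  arctan(offset / 10.5 Å). This suffices for every downstream feature while
  keeping all oracles analytic; it does not emulate helical side-chain
  packing, partial unwinding, or real pore chemistry.
- Particle traces are 1-D in z at a fixed stride. Planted passages descend
  continuously through both counting planes into the lower reservoir and
  return via a single large jump emulating periodic re-entry; distractor
  excursions (default rate equal to the total crossing rate) dip past the
  entry plane only. Event counts per particle are Poisson; scheduling places
  events in non-overlapping windows, which caps feasible rates — the
  generator refuses rates whose events cannot fit. Lateral motion,
  multi-particle correlations and dwell-time physics are not modelled.
- Langevin sampling is overdamped Euler–Maruyama with unit mobility
  (dz = −U′ dt + √(2 kT dt) ξ, dt = 10⁻³ reduced units by default) whose
  stationary law is Boltzmann in the small-dt limit; the stability condition
  dt × (maximum stiffness) < 1 is enforced. Umbrella windows follow the
  study layout: 0.4 Å anchor spacing, 25 kcal mol⁻¹ Å⁻² spring. The
  double-well form B((z/z₀)² − 1)² has its barrier height as an explicit
  parameter.
- Markov state trajectories emit centroid + noise features with wrapped
  angular noise (a state at 179° produces values near −179°) and record true
  labels per frame. The default demo scenario plants four states with χ1
  rotamers at −60°/60°/180°/−170° (one straddling the wrap), cross-tetramer
  distances widening by 3 Å per state, 8° angular and 0.25 Å distance noise
  (≤ 1/6 of the separations), and slow switching (stay probability 0.995 at
  a 250 ps frame stride).

Passing tests on these generators show the machinery is correct under the
stated models; they do not show robustness to force-field artefacts,
alignment drift in crowded membranes, or water wires that violate the 1-D
crossing picture.

## Problem sizes and tolerances in the checks

The shipped checks use desk-scale sizes chosen as the package's own test
conditions: 1,000 traces × 100 seeds for counter exactness (exact equality);
11 umbrella windows × 6,000 samples for barrier recovery (±0.3 kcal/mol on a
3 kcal/mol barrier) and split-half convergence (< 0.2 kcal/mol); 50 repeats
× 20 bootstrap replicates for band coverage (55–80% of bins); AR(1) series
of 10⁵ frames for the autocorrelation rule (9 ± 1 frames at φ = 0.8); and
5,000-frame, 4-state trajectories over 10 seeds for clustering recovery
(exactly 4 clusters, purity ≥ 0.95). Geometry and circular-statistics
oracles are exact to 10⁻⁹ except the inscribed-sphere grid search (0.05 Å,
the grid resolution).

## Known limitations

- The inscribed-sphere search assumes the pore is near the z-axis within the
  lateral bound; strongly kinked pores need a larger bound or a tracking
  search.
- Coordinate-mode k-means approximates pairwise-superposed RMSD by
  superposition onto an evolving mean; for highly heterogeneous ensembles
  the metric degrades.
- WHAM is 1-D; no multistate reweighting, 2-D PMFs or replica exchange.
- The LBD closure angle is an operational definition against a declared apo
  reference, not a reproduction of any published measurement procedure.
- t-SNE cluster counts depend on bandwidth/cutoff defaults; these are
  calibrated on the synthetic scenario and exposed as parameters, not
  guaranteed for arbitrary embeddings.
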