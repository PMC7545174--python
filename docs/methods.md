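# Methods

This note records the models implemented in `fibmech`, their assumptions,
the parameters that matter, and the numerical and design choices made where
the design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The reduced pulling model

The package analyses constant-velocity pulling experiments in which a
harmonic steering spring of stiffness k_s, attached to a pulled coordinate
x, moves at speed v while the accumulated external work is recorded. The
synthetic generator replaces the all-atom engine with the simplest dynamics
that preserves the statistics the estimators rely on: **overdamped
(Brownian) Langevin motion** of a single coordinate in an analytic
background potential U(x),

    dx = [ −U'(x) + k_s (z(t) − x) ] dt/γ + √(2 kT dt/γ) ξ,   z(t) = z₀ + v t,

integrated with Euler–Maruyama. Units are Å, kcal/mol, ns, K; forces are
reported in pN (1 kcal/mol/Å = 69.48 pN, kT = 0.5962 kcal/mol at 300 K;
both fixed in `constants.py`).

Assumptions and consequences:

* **Overdamped limit.** Inertia is dropped. The Jarzynski identity holds
  for this dynamics exactly, so the free-energy estimator can be validated
  against closed forms without simulating atomistic detail.
* **Work convention.** dW = k_s (z − x) v dt with the spring centre taken
  at the start of each step (left-endpoint rule). Work profiles start at
  exactly 0 and are recorded on the steering grid z ∈ {0, Δz, …, d} with
  Δz = v × output_interval.
* **Friction sets the dissipation scale.** Dragging at speed v over
  distance d dissipates ≈ γ v d even with an infinitely stiff spring.
  "Quasi-static" therefore means γ v d ≲ kT, not merely small v.
* **Initial state.** Each replicate starts from the equilibrium
  distribution of the combined trap-plus-potential system (exact for
  harmonic backgrounds, local-curvature Gaussian otherwise); this is
  required for the Jarzynski identity and is deterministic at T = 0.
* **Stability.** Euler–Maruyama with a harmonic force of stiffness k is
  stable for dt < 2γ/k; the package enforces the conservative bound
  dt ≤ 0.2 γ/k_eff with k_eff = k_s + max|U''| over the pulled range, and
  raises a configuration error otherwise.

Background potentials: `flat` (U = 0), `harmonic` (½κx²), `double_well`
(quartic, minima separated by s, barrier b at the midpoint:
U = 16 b u²(u−s)²/s⁴). `analytic_pmf` returns U(z₀+z) − U(z₀), the exact
stiff-spring reference. For a harmonic background the trap-system free
energy is ½·κk_s/(κ+k_s)·z², so a stiff spring under-reads ½κz² by the
factor k_s/(κ+k_s); with k_s/κ = 100 that is a 1 % effect, the dominant
term in the benchmark residual.

**Benchmark conditions** (`synthetic.harmonic_benchmark`): κ = 1
kcal/mol/Å², k_s = 100 kcal/mol/Å², γ = 1 kcal·ns/mol/Å², T = 300 K,
d = 5 Å at v = 0.1 Å/ns, dt = 0.001 ns, n = 100 replicates. These were
chosen once as a desk-scale quasi-static setting: dissipation
γvd ≈ 0.5 kcal/mol ≈ 0.84 kT. The default pulling protocol elsewhere in
the package (k_s = 7.4 kcal/mol/Å², v = 0.1 Å/ns, R = 100 kcal/mol/Å²
terminal restraint, n = 100, T = 300 K) mirrors the standard experimental
setup those analyses come from; the restraint constant is provenance
metadata only, since the 1-D model pulls the relative coordinate with the
anchored terminus implicit.

**Seeding.** Replicate i of any ensemble draws from NumPy SeedSequence
`(master_seed, i)`, so streams are independent of ensemble size, a
one-replicate ensemble is bit-identical to a single-trajectory run, and
all generators are reproducible bit for bit.

## 2. Jarzynski estimation and force profiles

ΔG(z) = −kT ln[(1/n) Σᵢ exp(−Wᵢ(z)/kT)] is evaluated per grid point with a
max-shifted log-sum-exp, so works of thousands of kT neither overflow nor
underflow; a replicate with overwhelmingly large work changes the estimate
by exactly kT ln((n+1)/n). Structural properties (tested): ΔG(0) = 0;
Jensen bound ΔG ≤ mean work pointwise; ΔG ≤ min-work + kT ln n; replicate
permutation invariance; identity at n = 1.

Force profiles are the distance derivative of the PMF. The pulling
literature states its smoothing window in time (10 ns); on the extension
axis this is v × 10 ns (1 Å at 0.1 Å/ns). The implementation smooths the
PMF with a centred moving average of that width (odd point support,
shrinking symmetric windows at the edges), differentiates with central
finite differences, then smooths the force once more with the same window
— matching a displayed-trace smoothing applied after differentiation.
Whether the original analyses smoothed once or twice is not recoverable;
both the window and the `window=0` (no smoothing) path are exposed, and
the unsmoothed force integrates back to the PMF to 1e-6 relative.

Scalar summaries: ΔG at a strain in percent by linear interpolation
(strain = extension / L_ref; L_ref defaults to 60 Å, the calcium-bound
equilibrium length scale, and is always an explicit parameter because the
source value is typo-ambiguous); windowed force means over half-open
strain windows [lo, hi), default 0–20 % and 20–50 %; global peak with
location; percent change 100·(ref − cmp)/ref rounded half-away-from-zero
to integer, matching printed precision. The ΔG₅₀ histogram reports
per-replicate endpoint works (not jackknifed estimates — the alternative
reading is not implemented) with a sample-moment normal fit (ddof = 1).

`convergence_study` tabulates endpoint estimates over a speed × sample-size
grid, re-timing the protocol so the extension grid is identical at every
speed. The bias ordering (faster pulling ⇒ larger expected bias) is a
statistical property asserted over seed-averaged repeats, never per run.

## 3. Conformational metrics

Length: 2 × |COM_a − COM_b| with mass-weighted centres over all atoms of
each domain's residue range (not Cα-only, since the defining quantity is a
centre of mass without qualification). Straightness: −û·v̂ with û, v̂ the
unit vectors from the combined COM to the two domain COMs. A subtlety: if
the combined COM is taken over exactly the union of the two domains it
lies on the segment joining their COMs and the metric is identically +1.
The implementation therefore takes the combined COM over the contiguous
residue span covering both domains, so linker atoms between them move it
off the segment; with no intervening atoms the metric degenerates to +1,
which is documented behaviour.

Apparent stiffness: K = kT·L/⟨(L₀ − L)²⟩, converted to pN. ⟨·⟩ is an
ensemble average, so the population (1/n) variance is the default; ddof = 1
is available. K is exactly linear in T and inversely linear in the
variance (asserted in tests); zero variance raises an explicit
infinite-stiffness error. On Ornstein–Uhlenbeck series with effective
stiffness κ_eff the estimator recovers K = κ_eff·L (stationary variance
kT/κ_eff). The OU generator mirrors equilibrium trajectory practice with a
configurable burn-in fraction (default: discard the first half) and
replicate count (default 10).

Statistical comparisons: the t-test defaults to Welch, because the
accompanying F-test interrogates variance equality and a pooled test would
be self-inconsistent when that F-test rejects; `pooled=True` reproduces
the classical test since the original choice is not documented. The
F-test uses larger-over-smaller sample variances with the corresponding
(n−1, n−1) degrees of freedom and a doubled upper tail capped at 1, making
it symmetric in sample order.

## 4. Binding observables

Contacts: partner atoms strictly closer than 4.0 Å to the ligand. Partners
default to oxygen atoms (coordination chemistry; the observable is
calcium–oxygen contacts), with an all-atoms option.

SASA: Shrake–Rupley with test points from a deterministic golden-angle
(Fibonacci) lattice — 960 points by default, reproducible without RNG. A
point on the target's expanded sphere (r + 1.4 Å probe) is buried if
inside any neighbour's expanded sphere. The calcium radius is fixed at
1.5 Å so the isolated ion reads 4π(2.9)² = 105.68 Å², consistent with the
105.7 Å² reference used for percent normalisation (clipped at 100 % with
a warning if quadrature overshoots). Other radii come from a standard vdW
table, overridable per element. Quadrature error against the two-sphere
closed form decreases monotonically over 240/960/3840 points, and an
independent Shrake–Rupley implementation (biotite) agrees within a few
percent in tests.

Work-weighted averages: wᵢ = exp(−Wᵢ/kT)/Σⱼ exp(−Wⱼ/kT) via a stable
shifted exponential; weights sum to 1 and the average is shift-invariant
in the works. Weights are formed **per strain point** by default — the
only reading that uses W(strain) consistently when observables are plotted
against strain — with a global per-replicate (endpoint-work) alternative.

## 5. Toy structures

`build_toy_structure` places a Ca²⁺ bead at the origin; n_contacts oxygen
beads sit on a golden-angle sphere at radii staggered ±15 % around 2.4 Å
(all < 4 Å), of which the first n_hairpin are β-hairpin beads whose radial
distances scale as (1 + strain); the remaining N-terminal-loop beads hold
their radii by default (configurable gain). Two carbon-bead domains give
COM separation 30 Å at zero strain (length 60 Å), growing linearly with
strain. With zero noise, contacts are non-increasing and ligand SASA
non-decreasing along any non-decreasing strain grid by construction — the
level at which "calcium binding is mechanosensitive" is literally
testable. What this deliberately does **not** emulate: real coordination
geometry, cooperative unfolding, refolding, or solvent structure; passing
tests demonstrate correctness of the measurement pipeline, not biology.

## 6. Mutation cohorts

Inclusion filtering matches disease labels exactly and case-sensitively,
with neonatal keywords ("neonatal MFS", the registry's as-published
"intantil MFS", and the presumably intended "infantile MFS") tested before
the generic "MFS" — precedence is the only consistent reading since "MFS"
is a substring of the neonatal labels. Unmatched labels are excluded;
every record lands in exactly one of nMFS/cMFS/excluded.

Residue classes: calcium-binding (annotated ligand set), cysteine (mapped
to disulfide bond 1/2/3 via the conserved ordinal pairing {1,3}/{2,4}/
{5,6} — mutating either partner counts toward the bond), other. A record
claiming a cysteine wild type at an unannotated position raises a
data-inconsistency error. Percentages carry binomial SE √(p(1−p)/n); bond
percentages are taken out of each cohort's cysteine records. Cohort
comparisons use the 2×2 chi-squared without continuity correction (the
common default of the original analysis environment), with a Yates flag.
The uniform-random baseline is the analytic sequence-share expectation,
with an optional Monte-Carlo draw supplying SE bars.

The shipped fibrillin-1 domain map (`data/fbn1_domain_map_synthetic.yaml`)
annotates cbEGF12 (D1070–M1112) and cbEGF13 (D1113–I1154) in detail. The
documented anchors are the mutation→bond assignments (C1074/C1081 first
cysteines of bonds 1 and 2 in cbEGF12; C1086→bond 1, C1111→bond 3;
C1117→bond 1 and C1138→bond 2 in cbEGF13) and the β-hairpin calcium
ligands (N1088/T1089/D1092; N1131/T1132/S1135). The remaining cysteine
ordinals and the N-terminal-loop ligands are representative completions —
hence the *synthetic* label — and calcium-binding sets for other domains
are user-supplied. The neonatal region is cbEGF11–cbEGF18. One known
source discrepancy is deliberately left unresolved: a caption places
C1138R in cbEGF12 while the residue range and body text place it in
cbEGF13; the map follows the range.

The synthetic cohort generator apportions class counts by largest
remainder (floors plus units by descending fractional remainder, ties in
class order), so counts sum exactly and every generated record
re-classifies to its generating class under the same map.

## 7. Problem sizes and defaults

Test and acceptance runs use the benchmark conditions above (100
replicates × 50 000 steps), 20 master seeds × 2 speeds × 10 replicates
for the bias ordering, 10⁵ Gaussian draws for the stiffness check, 1000
random ensembles for the Jensen sweep, and an 11-point strain grid for
the toy series — sizes chosen so the full suite completes in well under a
minute of simulation time while keeping Monte-Carlo tolerances
comfortable. The pipeline defaults (`RunConfig`) keep the standard
protocol values: T = 300 K, k_s = 7.4 kcal/mol/Å², v = 0.1 Å/ns, n = 100,
10 ns window, 4.0 Å cutoff, 1.4 Å probe, L_ref = 60 Å.

## 8. Known limitations

* The 1-D overdamped generator has no inertial, solvent or multi-dimensional
  effects; it validates estimators, not force fields.
* The Jarzynski estimator's finite-n bias grows exponentially with
  dissipation; the package reports no error bars beyond the endpoint-work
  histogram, matching the scope of the analyses it implements.
* Straightness is only informative when atoms exist between the two
  domain selections (see §3).
* The domain map outside cbEGF12/13 is a coarse placeholder; quantitative
  domain-level cohort statistics for the full protein require a
  user-supplied map.
* SASA is computed for a single target atom (the ion); there is no
  per-residue decomposition.
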