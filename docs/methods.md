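# Methods

## Polymerization model

The simulator implements the multicomponent Mayo–Lewis *terminal* model of
radical copolymerization: the probability of the next monomer depends only
on the chain's terminal unit and the instantaneous pool composition,

p(j|i) = (x_j / r_ij) / Σ_k (x_k / r_ik),  r_ij = k_ii / k_ij.

Assumptions: no penultimate-unit effects, no depolymerization, no
termination by combination, and a well-mixed pool shared by all chains.
Kinetic time is not modeled — only the sequence of propagation events
matters.  The first unit of each chain is drawn from the bare pool
fractions, since no terminal unit exists to bias it; this initiation rule
is a package convention.

Chains grow *concurrently*: each propagation step picks a living chain
uniformly at random, which is the in-silico analogue of RDRP "livingness".
All chains therefore experience the same compositional drift trajectory,
and alpha ends are statistically synchronized while omega ends are not.
Sequential whole-chain growth would instead freeze each chain at a single
point of the drift trajectory and is deliberately not offered.

### Dispersity and conversion control

Each chain is assigned a termination length before growth, drawn from a
Schulz–Zimm (gamma) distribution with shape a = 1/(PDI_target − 1) and mean
DP_target, the standard chain-length law for controlled radical
polymerization; PDI_target = 1 degenerates to constant lengths.  Under the
equal-monomer-mass approximation used throughout (DP_w = Σℓ²/Σℓ), the
first two moments give PDI ≈ 1 + σ²/μ², so the two targets are controlled
directly.

The initial pool holds round(NC·DP_target/conversion) units split by the
feed fractions with largest-remainder rounding.  Because the sum of NC
sampled lengths only fluctuates around the conversion unit budget, the raw
sampling would miss the conversion target by O(√NC) units about half the
time.  The sampled lengths are therefore conditioned on the exact budget by
±1 adjustments on uniformly chosen chains (a total correction of order
√NC spread across NC chains, negligible for the distribution shape).  As a
result realized conversion equals the target to within one monomer
addition, DP_n equals DP_target by construction, and the realized PDI sits
at the Schulz–Zimm value just below the target.  If chains retire early for
any other reason the run ends and the realized conversion is logged.

Determinism: all randomness derives from the config seed.  Chain lengths
and conditioning use a numpy PCG64 generator; the scalar draws of the
growth loop use a stdlib Mersenne generator seeded from that stream (one
seed lineage, two engines chosen for speed).  Identical config + seed
reproduces a batch bit for bit.

## HLB chemistry

Side-chain hydrophobicity uses group-contribution HLB,
HLB = 7 + Σ nᵢ·HLBᵢ; lower is more hydrophobic.  The package ships the
five reference monomers with literature totals (MMA 8.45, EHMA 5.12,
OEGMA 11.4, SPMA 18.5, STY 4.865); the functional-group decompositions
behind those totals are not tabulated here, so new monomers require a
user-supplied HLB (or group list).  Binarization uses a single strict
inequality: hydrophobic iff HLB < threshold (default 9), so a value exactly
at the threshold counts hydrophilic.  The tie rule is a convention — the
default monomer set never lands on the boundary.

Reactivity ratios default to all ones (ideal copolymerization).  Published
ratio sets for specific chemistries are supplied through the YAML config.

## Analysis metrics

**Chemical heterogeneity.**  Per-chain mole fractions feed a Gaussian KDE
(`scipy.stats.gaussian_kde`, Scott bandwidth) evaluated on a 512-point grid
over [0, 1].  FWHM is measured on the *global-maximum* peak only, with
half-maximum crossings located by linear interpolation and clipped at the
domain edge; minor peaks — a finite-NC artifact — never contaminate the
width.  nFWHM divides by the monomer's feed fraction.  Scott's rule adds a
~1% positive bias to the width at NC = 15000 (bandwidth ≈ σ·NC^(−1/5)),
well inside the tolerances used anywhere in the package.

**Segments.**  Maximal-run extraction over the binarized labels; sequence
level reports average run counts per chain, batch level the summed counts
(identically sequence level × NC).  The highlighted length sets {1, 3, 5,
10} (runs) and {5, 8, 10, 13} (motifs) are plotting conventions only; full
distributions are always computed.  The motif search scans maximal runs
over the alphabet {hydrophobic monomers} ∪ {marker}: a run matches iff it
contains exactly one marker with at least `end_gap` (default 2) non-marker
units strictly between the marker and *each* run end.  "Two or more away
from the end" is read exclusively (gap counted in non-marker monomers);
runs with ≥ 2 markers yield no match rather than being split — the
embedded-single-marker reading.

**Hydropathy.**  Odd window w, full spans only: a chain of length L yields
L − w + 1 values, each assigned to the span's center monomer; no padding or
truncated windows at the ends.  Batch position statistics are
alpha-anchored (position 0 = first full-window center), use every chain
long enough to define a position, and report the contributor count, which
is non-increasing and explains the noisier omega-end statistics of
polydisperse batches.  Pooled mean/variance aggregate all window values
regardless of position.

**Protein bridge.**  The default residue map groups by
hydrophobicity/charge: {V,L,I,M,F,W}→EHMA, {A,G,P,C}→MMA,
{S,T,N,Q,Y,H}→OEGMA, {D,E,K,R}→SPMA, with aromatics {F,W,Y}→STY when
styrene is in the system.  It is a configurable package default, not a
measured mapping.  Segmentation is fixed-length (default 100) with start
offset 10; a trailing partial segment is dropped so every segment is
DP-matched to the simulated chains.  Non-standard residues (X, B, Z, *)
are errors with the offending position, never silently skipped.

**Recipe.**  Standard RDRP stoichiometry: n_total = mass/Σfᵢ·MWᵢ,
n_CTA = n_total·conversion/DP_target (so the mean DP at the stated
conversion hits the target), initiator from the CTA:initiator ratio, chain
count = n_CTA·N_A.  Solvent volume comes from a user-supplied target
monomer molarity; it is never inferred.

## What the synthetic data does and does not show

Test batches are produced by the simulator itself (plus i.i.d. Bernoulli
and handcrafted fixtures with closed-form statistics).  They emulate ideal
RDRP: perfect livingness, a shared well-mixed pool, equal monomer masses in
DP_w, and exact Schulz–Zimm lengths.  They do not emulate chain-transfer
side reactions, diffusion-limited kinetics, monomer-specific molar masses
in dispersity, or sequence-correlated termination — so passing tests
validate the model's internal consistency and its closed-form limits
(copolymer equation, geometric run law, binomial composition widths), not
agreement with any particular wet synthesis.

## Problem sizes and numerical choices

The reference batch is NC = 15000 chains at DP 100 — the sample size at
which nFWHM of the lowest-feed monomer stabilizes; the convergence test
compares NC 15000 against NC 100000 relative to the batch-to-batch
fluctuation at NC 100 (standard deviation over 5 seeds).  Low-conversion
limits (copolymer equation, geometric runs) use conversion 0.01 with a few
thousand chains, giving ≥ 10⁵ propagation events while keeping pool
depletion below 1%.  Statistical assertions use 3 Monte-Carlo standard
errors or chi-square at p > 10⁻³ on fixed seeds.  Degenerate inputs fail
loudly: empty batches, all-identical KDE samples, even windows, depleted
pools, unmapped residues and malformed batch files all raise typed errors.

## Known limitations

Terminal model only (no penultimate effects); equal-mass DP_w; HLB group
tables not bundled beyond the five reference monomers; the residue map is
a heuristic default; recipe output ignores solubility/safety; the motif
engine handles exactly the embedded-single-marker pattern, not general
motifs.
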