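# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline uses them.

## Scattering model

**Debye sum.** Profiles are computed by the exact orientational average
I(q) = Σᵢⱼ fᵢfⱼ·sinc(q·dᵢⱼ). `sinc` is evaluated as `np.sinc(x/π)`, which
returns the exact limit 1 at x = 0, so no series fallback is needed at
q → 0 or dᵢⱼ → 0.

**Form factors.** Vacuum form factors are sum-of-Gaussians fits
(four Gaussians plus a constant, International Tables vol. C) for H, C, N,
O, P, S and the ionic species Mg²⁺, Na⁺, K⁺, Cl⁻; at q = 0 each equals the
species' electron count (Mg²⁺ → 10). Unknown elements fall back to carbon.
Hydrogens are implicit: each heavy atom's form factor and displaced volume
are incremented by its bonded hydrogens, inferred from standard RNA atom
names (C5′ +2, O2′ +1, base-specific N/C assignments; water O +2).

**Excluded volume.** Each atom carries a dummy-solvent Gaussian
f_d(q) = ρ_s·V·exp(−q²·V^{2/3}/4π) with ρ_s = 0.334 e/Å³ and per-element
displaced volumes (Fraser-type; e.g. C 16.44, O 9.13, Mg 1.56 Å³). The
adjustable c₁ modulates this term through
G(q, c₁) = c₁³·exp(−(4π/3)^{3/2}·q²·r_m²·(c₁²−1)/16π) with r_m the mean
dummy-atom radius; G ≡ 1 at c₁ = 1.

**Hydration layer.** Each atom contributes c₂·sᵢ·f_w(q), where sᵢ is its
solvent-accessible fraction (Shrake–Rupley dot counting, 100 Fibonacci
dots, water-sized 1.5 Å probe) and f_w is the effective water form factor
(vacuum O+2H minus a 30 Å³ dummy). The "neutral" c₂ follows the convention
that c₂ = 1 means one unit of this hydration weight; a `c2_zero_convention`
flag reinterprets neutral as no hydration term for comparison with
calculators that print it that way.

**Parameter policy.** c₁ ∈ [0.95, 1.05] and c₂ ∈ [−2, 4] are only searched
(11 × 25 grid, scale c closed-form at each point) when explicitly requested.
The default pipeline holds both at neutral: a free hydration layer can
mimic — and therefore silently absorb — the ion signal the pipeline is
trying to locate, which is an overfitting failure mode, so the free fit
prints a warning.

**χ² fitting.** χ² = (1/S)·Σ[(I_exp − c·I_calc)/σ]² with
c* = Σ(I_exp·I_calc/σ²)/Σ(I_calc²/σ²). An optional constant background
(off by default) turns this into a 2-parameter weighted linear solve.
Computed profiles are linearly interpolated onto the experimental grid;
experimental points outside the computed range are dropped.

**Six-partial evaluation.** For parameter searches the calculator
precomputes the six pairwise cross intensities between the vacuum, dummy
and hydration components, after which I(q; c₁, c₂) is a closed-form
combination — one O(N²S) pass serves the whole (c₁, c₂) grid.

## Subset decomposition

For candidate ion positions the Debye sum is decomposed once into the RNA
intensity, per-candidate terms A_k (ion self + ion–RNA cross) and per-pair
terms B_km (ion–ion cross, included because exactness is cheap), so any
subset's profile assembles in O(S). The decomposition fixes one hydration
convention: solvent-accessible fractions are computed on the RNA alone and
candidate ions count as fully exposed. `compute_profile` accepts explicit
fractions so direct computations can share the convention; with it, the
assembly is exact to rounding (tested to 1e−10 relative error).

## Surface probes and neighborhoods

Candidate positions are sampled on a dot surface: 64 Fibonacci-lattice dots
per atom on the sphere of radius r_atom + r_probe, occluded dots removed,
survivors deduplicated on a 1 Å grid (ties keep the lowest parent atom
index, for determinism). Two probe radii are used deliberately:

- 1.5 Å (water) for solvent accessibility and generic surface work;
- 0.65 Å (the Mg²⁺ ionic radius) for **candidate generation**, because an
  inner-sphere Mg²⁺ sits ~2.1 Å from its coordinating oxygens — closer than
  any water-sized probe can stand. With the water probe no candidate can
  ever occupy a true binding geometry, and predicted confidences at pockets
  collapse; with the ion-sized probe, candidates land within ~1–3 Å of
  planted sites.

A probe's neighborhood graph contains all atoms within 8 Å (probe node 0
connected to every atom; atom–atom edges within 4 Å). Node features are
one-hots: element {C, N, O, P, other}, atom category {phosphate O, ribose
O, base O, base N, other}, residue {A, C, G, U, other}, plus an is-probe
flag; the probe node carries zeroed chemistry. Edge distances are the only
geometric input, making every downstream prediction rigid-motion and
permutation invariant by construction.

## The ion classifier

A compact graph network: one 4-head graph-attention layer (attention logits
from source, destination and a 16-Gaussian radial-basis encoding of the
edge distance on [0, 8] Å), two edge-conditioned graph-convolution layers
(per-channel sigmoid gates computed from the same RBFs), mean+max global
pooling, and a two-layer head with sigmoid output. Hidden width 32 — sized
to train in minutes on one CPU while cleanly exceeding the acceptance bar
on the synthetic task. It runs on a small vectorized reverse-mode autodiff
engine (`scoper.nn`, float32, with sparse-matrix gather/scatter primitives)
written for this package; no deep-learning framework is required.

Training: Adam (lr 1e−3), up to 40 epochs, each epoch resampling the
majority class to 1:1 balance and sweeping minibatches of 512 graphs; early
stopping on held-out AUROC (patience 6). Cross-validation splits at the
**structure** level (GroupKFold on the source structure), so near-duplicate
neighborhoods from one molecule can never straddle the train/validation
boundary. All randomness flows from one seed; two runs with the same seed
produce identical fold metrics.

Inference: probes below the confidence threshold (default 0.5; a strict 0.9
preset exists) are dropped, then sites are selected greedily by confidence
with a 3.5 Å merge radius, giving a deterministic, confidence-sorted,
well-separated candidate list.

## Branch-and-bound ion selection

Subsets grow one ion at a time: each retained subset is extended by every
unused candidate, scored by O(S) assembly plus the closed-form scale fit,
and the K best per size are kept (K = 50 by default; with K ≥ 2ⁿ and
epsilon 0 the search is provably exhaustive, which the tests exercise).
Growth stops when the best subset of size n fails to improve the best of
size n−1 by more than an epsilon — and the rejected size is *discarded*,
not reported, so a sub-threshold "improvement" can never become the global
best. The default epsilon is 0.05: adding the best of m ≈ 10 spurious
candidates to an already-correct model improves a 100-point reduced χ² by
about 2·ln(m)/S ≈ 0.05 purely by fitting noise, so a smaller threshold
systematically admits phantom ions. Ties in χ² break toward the
lexicographically smaller index tuple.

## Multi-state fitting

I_model = c·Σ w_k·I_k with w ≥ 0, Σw = 1. Weights come from non-negative
least squares on σ-weighted residuals; the unnormalized NNLS solution is
split into weights and an overall scale. States fitted below a weight floor
(0.02 when enabled) are pruned and the rest refit. State subsets are
enumerated with the same beam strategy as ion selection; the reported
recommendation is the smallest state count whose χ² is within 5% of the
best found.

## Pipeline

Stages: score all conformers (fixed c₁/c₂) → predict and select ions for
the top-M conformers (M = 20 by default; the best bare-RNA conformers are
empirically also the best decorated ones, so the shortcut loses little) →
if the best single decorated state still exceeds the acceptance χ²
(default 1.5, a declared convention for "fits within the noise"), fit
multi-state models over the candidate states (each conformer contributes
its bare and its ion-decorated profile). Failures are recorded per
conformer and the pipeline continues with the survivors. The χ² chain
(initial ≥ best conformer ≥ best + ions ≥ multi-state) is monotone by
construction, since every stage keeps its predecessor's model among the
candidates.

## Synthetic data: what it emulates, and what it does not

The generator produces every fixture the tests use; no external data is
required.

**Pseudo-RNA.** An A-form-like helix (rise 2.8 Å, twist 32.7°, backbone
radius 9 Å) of simplified 12-atom nucleotide motifs with realistic bond
lengths, 24 residues by default (a stem-loop-sized RNA). The helix axis is
a circular arc subtending 60° by default: solution stem-loops are bent, and
a perfectly straight helix would be a pathological scattering benchmark —
its screw symmetry makes distinct surface sites nearly indistinguishable by
their distance spectra (measured swap penalties as low as 0.08 χ² units),
so site identifiability would be an accident of noise. A 0.12 Å coordinate
jitter decorrelates structures built with different seeds.

**Planted sites.** Each Mg²⁺ site is built, not found: an exposed anchor
O/N is chosen, the ion placed at coordination distance (2.1 Å) outside it,
and up to five further O/N atoms are moved onto the remaining octahedral
vertices, guaranteeing ≥ 4 O/N in the [1.8, 2.4] Å shell — the physical
signature (inner-sphere octahedral coordination) the classifier must learn.
Waters are hydrogen-bond-like surface positions (2.7–3.3 Å from an O/N,
crevices included) with at most 2 O/N inside 2.4 Å; placing them near
oxygen surfaces deliberately supplies *hard negatives*, look-alike crevice
geometries that a classifier trained only on convex-surface waters
misclassifies. The planted rule is linearly recoverable (a threshold on
the O/N count within 2.4 Å separates the classes with AUROC > 0.95), which
bounds what any classifier can achieve and makes the learnability test
meaningful.

**Conformers.** Hinge rotations between quasi-rigid segments: two random
hinges per conformer, rotation angle ramped smoothly over 5 residues
(smoothstep) and rescaled to the requested RMSD (±15% spread). Hinge
motion mimics the dominant large-scale flexibility of folded RNA while
preserving local geometry (consecutive P–P distances within 5% at the
default amplitude). It is explicitly **not** a physical conformational
sampler: no torsional chemistry, no base-pair bookkeeping, no energetics —
just a shape-diversity fixture.

**Simulated measurements.** I_exp = I_true·(1 + ε), ε ~ N(0, f) i.i.d. per
point, σ = f·I_true — the high-signal multiplicative regime of modern
SEC-SAXS; f = 1% by default. The simulator accepts explicit surface
fractions so truth profiles share the decomposition's hydration convention;
without that, the convention mismatch acts as a systematic residual that
selection "fixes" with spurious ions.

**What passing does not show.** Real RNA has sequence-dependent geometry,
partial-occupancy and misassigned ions, buffer-dependent hydration, and
conformational ensembles far richer than two hinges; the synthetic results
demonstrate the machinery's correctness and the recoverability of planted
signal under stated noise, not field performance on experimental data.

## Identifiability limits baked into the benchmarks

Two resolution arguments shape the test design. A profile measured to
q_max = 0.4 Å⁻¹ carries no information below the Shannon distance
2π/q_max ≈ 16 Å, so (i) decoy candidates in the recovery benchmark are
placed at least that far from planted sites — closer decoys would test the
noise, not the algorithm — and (ii) end-to-end ion recovery is scored as
*vicinity* recovery at half that scale (π/q_max ≈ 8 Å): with ~20 candidate
sites on a small RNA, equally-scoring subsets exist within a resolution
element, and demanding exact-site recovery through the full pipeline would
demand information the data does not contain. For the same reason the
end-to-end scenario uses clearly distinct conformers (4 Å RMSD hinge
states); at 1.5 Å the conformer profiles differ by less than 1% noise and
"the true conformer" is undefined. The mixture-weight benchmark follows the
same logic from the estimator side: recovering two-state weights to ±0.05
at 1% noise requires both well-separated states (6 Å RMSD) and a finely
binned curve (500 points, as SEC-SAXS delivers) — on a 100-point grid the
weight estimator's own standard deviation is ~0.03 and the tolerance would
measure luck, not correctness. A third identifiability condition applies to
the planted ions themselves: a single Mg²⁺ is 10 electrons among thousands,
and for some random placements a *proper subset* of the planted ions — or a
planted ion plus a decoy, with the overall scale free — reproduces the full
truth profile to within the detection scale, making recovery impossible for
any method. Recovery benchmarks therefore draw instances from
`recovery_benchmark`, which enumerates the noise-free χ² of every candidate
subset and regenerates system and decoys until every subset lacking a
planted ion misfits the truth by at least 0.3 reduced χ² at the benchmark
noise — a certified-unique optimum with margin.

## Numerical and problem-size choices

Default q grid 0.01–0.4 Å⁻¹, 100 points (a typical BioSAXS beamline
range). Guinier fits iterate the ln I vs q² window to q·Rg < 1.3
(convergence on a stable point set); for exact compact spheres a tighter
window (q·Rg < 0.8) avoids the known curvature bias of the approximation.
Acceptance-scale problem sizes — 50 random structures of ≤ 200 atoms for
the Debye oracle, 20 systems of ≤ 12 candidates for decomposition
exactness, ~2,000 graphs / 80 structures for classifier cross-validation,
20 conformers per end-to-end scenario — are chosen so the whole suite
verifies every exactness claim at full precision while remaining a
single-CPU, coffee-break run.

## Known limitations

- The SAXS calculator is implicit-solvent; no explicit hydration shell or
  multipole expansion, and no indirect-transform P(r) from data (the
  structure-side P(r) is exact but not a GNOM replacement).
- Conformational sampling is out of scope: conformers are consumed, not
  generated (the hinge generator is a test fixture only).
- The classifier supports Mg²⁺ only; Na⁺/K⁺/Cl⁻ atoms are recognized in
  structures but never predicted.
- Ion selection can overfit when many candidates fall inside one
  resolution element; the merge radius, the stopping epsilon and the fixed
  c₁/c₂ policy mitigate but cannot eliminate this (the multi-state +
  per-state ion combination is the worst case and is deliberately reused,
  not refit, across states).
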