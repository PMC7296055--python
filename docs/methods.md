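# Methods

## Signature statistic

The compositional signature of a sequence window is the vector of
oligonucleotide relative abundances, ρ(w) = f(w) / ∏ᵢ f(wᵢ), for all 4ᵏ
k-mers w, k ∈ {2, 3, 4}. Counting uses overlapping windows at step 1 on the
deposited strand; any window containing a non-ACGT letter is skipped, and
f(w) is the count divided by the number of windows actually counted, so
Σ f(w) = 1 under ambiguity skipping. The mononucleotide frequencies in the
denominator come from the same window (segment or whole plasmid), not from
the whole chromosome: the model treats each 5-kb segment as an independent
observation of the chromosome's local composition. Normalization by
mononucleotide frequencies is used for all k; it removes GC-content
differences but deliberately not lower-order k-mer structure.

An optional `strand="both"` mode adds reverse-complement counts (and
symmetrizes the mononucleotide counts) before normalization, giving
strand-symmetric signatures; the default is the given strand only, and the
choice is exposed end to end. A window in which some base never occurs has
undefined entries (0/0); such vectors keep their computable entries but are
flagged invalid, and invalid segments are dropped from composition
matrices (tallied in `n_invalid_segments`).

## Segmentation

Chromosomes are cut into contiguous, non-overlapping windows of
`window_bp` (default 5000) in sequence order; the trailing partial window
is discarded and its length recorded, so a replicon of length L yields
exactly ⌊L / window⌋ segments (580,076 bp → 116). No circular wraparound
is applied: segments and k-mer windows never span the origin, which keeps
coordinates simple and matches linear division counts. Ambiguous bases are
left in place (coordinates preserved) and handled at composition time.

## Segment Mahalanobis model

For one chromosome at one k, the segment rho vectors form an n × p matrix
(p = 4ᵏ). The model is the sample mean μ and covariance S with the
unbiased denominator n − 1; this choice makes the identity
Σᵢ D²(Cᵢ) = p (n − 1) hold exactly for full-rank S, which the tests
exploit as an oracle. The model is *available* only when n > p; otherwise
every downstream quantity is NA — a state, not an error — mirroring how
short chromosomes drop out of tetranucleotide screens.

S is inverted through one SVD. If the reciprocal condition number
s_min/s_max falls below 1e-12, or s_max itself is below a cancellation
noise floor of n·p·(ε·max|X|)², a Moore–Penrose pseudo-inverse with
tolerance max(p·ε·s_max, noise floor) is substituted and flagged
(`used_pseudoinverse`); the noise floor prevents exactly-degenerate data
(e.g. identical segments) from having their round-off residuals inverted.
Quadratic forms are clamped at zero against symmetric round-off. No
shrinkage estimator is used: near-degeneracy is expected for p = 256 with
small n and the pseudo-inverse fallback is the documented behavior.

## Empirical P

P = #{i : D²(Cᵢ) > D²(query)} / n, with strict inequality so ties count
against the query; P therefore takes values on the grid {0, 1/n, …, 1},
and a segment scored against its own model produces exactly the uniform
grid {0, 1/n, …, (n−1)/n} for continuous data. Tables carry P both as a
float and as the exact fraction string "m/n" to avoid rounding ambiguity.

## Screen and ranking

The screen scores one plasmid against every chromosome at each requested
k. Metadata policies are applied from flags, not inferred from sequence:
an optional `organism` column triggers the largest-chromosome-per-organism
rule, and a truthy `exclude` column drops rows (e.g. *Candidatus* or
partial entries). "Top X%" ranking is computed over non-NA rows only, with
the cutoff count ⌈fraction · N_nonNA⌉ per k; a row qualifies under the
default `any_k` policy if it ranks within the cutoff at any scored k
(a `per_k` policy is available, since published top-fraction lists do not
always state which convention was used). Ties at the cutoff are broken by
accession lexicographic order for reproducibility. A genus is "listed" in
the top fraction if at least one of its chromosomes qualifies.

## Group statistics

Rows are labeled Transconjugants / Others / Unlabeled by genus membership.
Cliff's delta is computed by exact pair counting (sort + binary search);
δ = 2U/(nm) − 1 against the Mann–Whitney U is verified in tests. The WMW
test uses mid-ranks, tie-corrected variance n₁n₂/12 · [(n+1) −
Σ(t³−t)/(n(n−1))], a normal approximation and a two-sided p, with no
continuity correction by default (switchable); its type-I error at
α = 0.05 is verified by simulation. NA rows are dropped per k before
testing; a group with fewer than two usable rows raises an explicit
insufficient-data error. No multiple-testing correction is applied across
the three k values.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:
genus-specific compositional signatures plus a plasmid whose composition
has partially converged toward its hosts'. Each synthetic genus gets an
order-m Markov chain whose transition rows are drawn from a symmetric
Dirichlet; sequences are sampled exactly from the chain (a jit-compiled
inner loop; byte-identical across runs for a fixed seed, with all child
seeds derived from one `SeedSequence`). Amelioration is modeled as convex
mixing of transition matrices, transitions = (1−α)·plasmid + α·host,
because the biological process is directional drift of composition toward
the host; mixing gives a single interpretable knob with exact endpoints.

Defaults: chain order 2, so genuine trinucleotide-context structure
survives rho normalization at every scored k (an order-0 chain's bias is
removed by rho by construction, and order is capped at 2 because k ≤ 4);
Dirichlet concentration 2.0, giving transition-probability spread
(sd ≈ 0.14 about 0.25) comparable to the signature variation seen across
distant prokaryotic taxa — strong but not pathological bias; scenario
scale 10 Transconjugant + 10 Other hosts of 500 kb (100 segments, so
n ≫ p at k = 2 and n > p at k = 3) with a 50-kb plasmid, which keeps a
full screen near one second while exercising every stage. The plasmid is
ameliorated toward the *equal mixture* of the Transconjugant-host chains,
emulating a broad-host-range plasmid whose composition reflects residence
in many hosts.

What the generator does not emulate: real taxonomies (one chromosome per
invented genus), repeated elements, GC skew, mobile-element insertions,
within-genus signature correlation, or conjugation dynamics. Passing tests
therefore demonstrate that the statistical machinery recovers planted
compositional convergence under the model's own assumptions, not that the
screen's accuracy on real genomes is reproduced.

A consequence of the mixture design worth stating plainly: mixing toward
the average of 10 hosts caps the plasmid's shared component with any
single host at α/10, which bounds the group effect size near δ ≈ −0.3 at
α = 0.9. That matches the effect sizes real screens report, but a WMW test
on 10-vs-10 hosts has only ~10% power at that effect — group significance
per replicate at this toy scale is not expected, and the power/calibration
simulations report exactly what is computed. The planted signal is instead
validated by the effect-size monotonicity in α, the null calibration at
α = 0, and single-host scenarios (one Transconjugant host, no mixture
dilution), where the true host lands in the top decile of D² essentially
always.

## Problem sizes and numerical conventions

Simulation-backed tests use 20 seeded replicates per condition at the
scenario scale above; law-of-large-numbers checks use 10⁵–10⁶ bp
sequences; the WMW calibration uses 2,000 null simulations of 30 vs 30.
Table floats are written with 6 significant digits and NA is spelled
"NA"; empirical P additionally as "m/n". All analysis paths are
deterministic given inputs and configuration; randomness exists only in
the generator and is fully seed-derived.

## Known limitations

- Signature comparison assumes segments are exchangeable observations;
  highly mosaic chromosomes (prophages, genomic islands) violate this and
  inflate S.
- At p = 256 with a few hundred segments the covariance estimate is noisy
  even when n > p; D² values at k = 4 carry substantial estimation
  variance (no shrinkage is applied by design).
- Empirical P has resolution 1/n, so short chromosomes give coarse P
  values.
- Whether deposited-strand or strand-symmetrized counting matches any
  particular published screen is not always documented; both are
  implemented, and results at small k can differ.
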