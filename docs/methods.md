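# Methods

## Sequence model and coordinates

All coding sequences are stored in the RNA alphabet {A, C, G, U, N};
T on input is normalised to U because the same statistics are applied to
maxicircle genes (DNA) and edited mRNAs. Internal coordinates are 0-based
half-open; every report is 1-based. Codon positions are counted from a
record's `frame_offset` (0–2); a trailing partial codon is dropped with a
warning for walks, composition and translation. N counts as a site but
never as a U, takes the −1 step in walks, and turns its codon into X on
translation. These conventions keep every counting identity exact
(walk finals, per-position partitions, U balance under editing).

## U walks and hydropathy profiles

The walk statistic is s[k] = Σᵢ₌₁..k x[i], x[i] = +1 if the i-th used
position carries the target base (default U) and −1 otherwise. Restricted
walks use the ascending index list of one codon position; both the rank
within the class and the absolute mRNA coordinate are reported so
per-position walks can be plotted against mRNA position. The cumulative
hydropathy profile is the running sum of per-residue Kyte–Doolittle
values (X contributes 0), with residue i assigned mRNA coordinate 3i + 1
(1-based) so protein and nucleotide profiles share an axis. Windowed or
smoothed hydropathy is deliberately out of scope — only cumulative sums
are used.

## Chi-square machinery

The homogeneity test of U counts across codon positions is a goodness-of-
fit chi-square with expected count at position i proportional to that
position's site total (identical to the uniform 1/3 expectation when the
span is a multiple of 3, robust otherwise), df = 2. For df = 2 the
p-value has the closed form exp(−χ²/2), which the test suite uses as an
independent oracle against the scipy implementation. The inserted-U
variant uses equal expected counts per position: applying it to the
published per-codon-position insertion counts of the pan-edited
*T. brucei* mRNAs reproduces the published p-values to two decimals,
whereas site-total weighting does not (e.g. ATP6 gives ≈ 0.9 instead of
0.28), so equal weighting is demonstrably the published convention.
Between-species U-content comparisons are 2×2 chi-squares (U vs non-U ×
species) on whole-CDS counts, df = 1, without Yates correction or
multiple-testing adjustment — this reproduces the raw-asterisk reporting
convention (* < 0.05, ** < 0.01, *** < 0.001). Windowed SDs are
population SDs of U proportions over consecutive non-overlapping 30-base
windows, with the trailing remainder dropped.

## Editing inference

Pure U-indel editing preserves the non-U bases and their order, so the
non-U characters of cryptogene and edited mRNA are matched one-to-one as
anchors; a mismatch or count difference raises an "editing-incompatible
pair" error with both coordinates. Each inter-anchor region is a run of
Us in both sequences whose length difference is a single signed count —
the net insertions (or deletions) in that run. Which Us within a run are
genomic and which were inserted is not identifiable from sequence; under
the default `genomic_left` convention the retained genomic Us occupy the
5′-most slots and inserted Us the 3′-most (the `genomic_right`
alternative is computed for sensitivity — the two differ by at most the
number of runs containing both genomic and inserted Us). Inserted Us take
the codon position of their edited-mRNA coordinate, `(index − frame) mod
3 + 1`, including a trailing partial codon, so generator truth and
inference agree exactly site by site.

## Protein statistics

Translation defaults to NCBI genetic code 4 (mold/protozoan
mitochondrial), in which UGA reads as tryptophan as it does in
kinetoplastid mitochondria; the code id is configurable. The hydrophobic
set is {F, L, I, V, M, W, Y} throughout; hydrophobic fractions exclude X
from the denominator. The default order/disorder classification is order
{W, C, F, I, Y, V, L, N}, disorder {A, R, G, Q, S, P, E, K}, ambiguous
{D, H, M, T}, and is fully configurable. Survey rankings use dense
descending ranks (ties share a rank) with the mean and population SD of
the fraction vector. Coevolution summaries consume an externally computed
symmetric score matrix and count unordered pairs with sequence separation
≤ 5 (inclusive) scoring strictly > 0.8 by default; computing the scores
themselves is out of scope. The inclusive-≤5 / strict-> 0.8 reading of
"within a five amino acid distance, scored > 0.8" is an assumption and
both knobs are exposed.

## Hydrophobic cluster analysis

Residue i sits at x = i with helical phase (i / 3.6) mod 1; the net is
drawn twice (offset one turn) for visual continuity. Cluster connectivity
is a parameterised approximation of the classic drawn-net contours: two
hydrophobic residues connect iff their sequence separation is ≤ 4 and no
proline lies strictly between them; clusters are connected components,
and hydrophilic gaps are maximal runs of ≥ 4 consecutive non-hydrophobic
residues. C is order-promoting but not hydrophobic here, matching the
sequence-analysis set. Because published net drawings judge cluster edges
by eye, the package instead reports distances from annotated sites
(substitutions, purifying-selection hits) to the nearest cluster boundary
and leaves interpretation to the user. Plots follow the conventional
symbols (stars P, squares S/T, diamonds G, red acidic/amide, blue basic);
bit-exact reproduction of legacy renderers is a non-goal.

## SASA, exposure and interfaces

SASA is Shrake–Rupley: each heavy atom is sampled with n points (default
960, Fibonacci lattice) on the sphere of radius r + probe (probe 1.4 Å;
element radii C 1.70, N 1.55, O 1.52, S 1.80 Å; hydrogens ignored); a
point is accessible iff outside every other atom's extended sphere.
Relative SASA divides residue SASA by the Tien et al. theoretical maximum
for the residue type, and "exposed" means strictly > 0.30. The original
analyses used a web service whose parameters are unrecoverable; all of
the above are explicit and configurable, and relative-SASA-dependent
counts may shift with a different max-ASA reference (flagged in reports).
At 960 points the sampler is within 1% of the single-sphere closed form
and within 2% of the two-sphere spherical-cap closed form, with error
decreasing in n. Interface residues lose SASA when their chain is
evaluated in the two-chain complex rather than alone; the threshold is
ΔSASA > ε with ε = 0.1 Ų rather than strictly > 0 because point sampling
makes the zero boundary flip across point counts.

Site-wise homolog comparison takes an explicit residue pairing (real
homolog pairings are inputs; a BLOSUM62 global aligner with gap open 11 /
extend 1 is provided for synthetic tests only), flags each gapless pair
where the query residue's Kyte–Doolittle value strictly exceeds the
subject's, and contrasts the increase fraction inside vs outside a
stratum (exposed / interface) with the 2×2 chi-square above; gapped sites
are excluded. An optional parallel contrast compares per-site editing
frequency by stratum.

## Synthetic generators

All generators are pure functions of (parameters, seed).

**Editing pairs.** The cryptogene is iid over {A, C, G, U} with default
composition (0.30, 0.25, 0.30, 0.15) — U-poor and G-rich, as expected for
a sequence whose mRNA gains most of its Us by editing. The edited mRNA is
built left to right: per inter-anchor region, each genomic U is deleted
with probability `deletion_rate` (default 0.05), retained Us are emitted
first, and inserted Us are appended after them — so the simulated
placement *is* the `genomic_left` convention and recovery can be asserted
exactly. Without position bias, each gap receives a geometric run (mean
1/`run_length_q`, default 2) with probability `insertion_rate ×
run_length_q`; the default `insertion_rate` 1.5 per gap yields an edited
mRNA of roughly 60% U with ~90% of its Us inserted, matching the regime
of pan-edited genes. With `position_bias`, insertions are decided one U
at a time with per-codon-position acceptance probabilities; because a
run's positions are consecutive, run-length geometry and exact bias
cannot both hold, so the acceptance probabilities are calibrated
numerically against the stationary distribution of the gap-position
Markov chain (gap start = previous rejection + anchor + retained genomic
Us) until the expected per-position insertion counts equal the requested
weights. Per-run truth is recorded as the net signed count — insertions
and deletions in one run cancel to the net, which is all an anchored
inference can ever see.

**Divergence.** Species diverge independently from the root; each site
substitutes with probability equal to its codon-position rate (position
2 divided by `purifying_strength`, default 10) to a uniformly chosen
different base. A single-hit Bernoulli model is used instead of literal
multi-hit events so the observed-difference ratio between positions is
centred exactly on the rate ratio (multi-hit models inflate it through
back-substitution); at the test's scale (10 kb root, 20 species, rate
0.1) the measured position-2/position-1 ratio falls within 3σ of 0.1.

**Toy complexes.** Two poly-alanine chains, one Cα sphere per residue,
run as parallel straight rods 3.0 Å apart in sequence and 5.8 Å apart
laterally, axially shifted so exactly k = round(contact_fraction ×
min(nA, nB)) residue pairs face each other one-to-one; coordinates get
±0.05 Å jitter. The geometry is chosen so that every cross-chain pair is
either clearly inside the SASA-occlusion cutoff (r_i + r_j + 2·probe =
6.2 Å, with ≥ 0.4 Å margin and an unoccluded occlusion cap of ~4 Ų) or
clearly outside it — no borderline contacts — which is what lets
interface recovery be asserted as exact equality. Ground truth is
computed from the jittered coordinates with the same cutoff. These rods
idealise helix axes; they are not meant to look like real helices, only
to make contact geometry unambiguous.

What the generators do **not** emulate: phylogenetic tree structure
(divergence is a star), selection on the protein beyond the position-2
rate shrinkage, gRNA anchoring or the 3′→5′ polarity of real editing,
partial-editing intermediates, and real side-chain packing. Passing tests
therefore demonstrate the correctness of the statistics and inference on
data satisfying the model's assumptions, not the biological conclusions
on real data — those require the user's GenBank sequences and deposited
structures, which the same code paths accept.

## Problem sizes and determinism

Default verification scales: 1,000 editing pairs of 200 codons for the
round trip, 10,000 random sequences for walk conservation, ≥ 5,000
insertions for bias recovery, 10 kb × 20 species for the divergence
contrast, 960 sphere points for SASA checks — each chosen so the binomial
or Poisson error bands in the corresponding assertions are decisive.
Every stochastic test and the acceptance script derive all randomness
from explicit seeds; hypothesis-based property tests run derandomised.
CLI outputs use fixed 6-decimal float formatting and manifests omit
timestamps so reruns are byte-identical.
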