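# Methods

## Scope and model

`ssmnet` implements the desk-scale core of a blank-aware molecular
networking analysis for untargeted positive-mode LC–MS/MS metabolomics.
The underlying model is standard for the field: an MS/MS spectrum is a
fingerprint of a compound's fragmentation; structurally related compounds
share fragments (directly, or offset by the mass difference of their
precursors), so a graph whose edges are high spectral cosine similarity
groups compound families into connected components. A second, orthogonal
graph — the ionization-variant network — links features that are the *same*
compound seen as different ions (adducts, isotopologues, dimers), and is
the right substrate for contaminant removal: if a feature shows up in a
chromatographic blank, every ionization variant of it is equally suspect.

## Spectral similarity

Peaks are weighted by √intensity and scaled to unit Euclidean norm before
matching; the square root keeps base peaks from dominating and makes the
self-similarity exactly 1. Candidate fragment pairs match directly when
|Δm/z| ≤ `frag_tol` (default 0.025 Da, consistent with Q-TOF fragment
accuracy and the ±0.01 Da precursor windows used elsewhere), or, in
modified-cosine mode, when offset by the difference of the two precursor
masses. The alignment is greedy: candidate pairs sorted by descending
weight product, each peak used at most once.

Tie-breaking: tied products are ordered by (min m/z, max m/z, kind). This
deviates from ordering by (m/z of the first spectrum, m/z of the second):
that ordering is not invariant under swapping the arguments and can
produce asymmetric scores when tied candidate pairs share a peak. The
chosen key is both deterministic and symmetric, which the test suite
asserts to 1e-9.

Greedy matching is a heuristic; `oracle_similarity` computes the true
maximum-score one-to-one alignment by branch-and-bound over candidate-pair
subsets (restricted to ≤ 16 total peaks). The suite verifies the greedy
score never exceeds the oracle and equals it on ≥ 95% of random 6-peak
pairs; matchms' `ModifiedCosine` serves as a second, independent reference
implementation in one cross-check test.

A nonzero SSMN edge additionally requires ≥ 4 matched peak pairs
(`min_matched`), preventing single-peak coincidences from wiring unrelated
chemistry together.

## Clustering into nodes

Single linkage over pairs with |Δprecursor| ≤ 0.05 Da, |Δrt| ≤ 0.2 min and
direct cosine ≥ 0.6. Single linkage was chosen over centroid linkage for
determinism and order-invariance (spectra are pre-sorted by precursor, rt,
id; the union-find result is a function of the pair set only); it is the
simplest rule that keeps replicate scans of one feature together across
samples. The rt tolerance must stay well below 0.8 min so that the two
stereoisomers of the dihydro C20 epoxyketone (6.6 vs 7.4 min, identical
precursor) remain distinct nodes — the suite pins this. Consensus spectra
merge fragment peaks chained within `frag_tol` (intensity-weighted mean
m/z, summed intensity); the consensus precursor is the TIC-weighted mean.

## IVAMN: variant linking, representatives, blank removal

Rule set: `[M+H]+`, `[M+Na]+` (Δ 21.981944), `[M+NH4]+` (Δ 17.026549),
`M+1` (Δ 1.003355 on top of protonation) and `[2M+H]+` — the dominant
positive-mode variants. Two co-eluting nodes (|Δrt| ≤ 0.1 min, tighter
than the clustering window because true variants co-elute exactly) are
linked when some ordered rule pair explains both m/z values from one
neutral mass: M is inferred exactly from one endpoint's rule and the
partner must sit within `prec_tol` (0.01 Da) of its predicted m/z, checked
in both orientations. This is a deterministic, slightly stricter reading
of "there exists an M fitting both within tolerance"; at 0.01 Da the rule
pairs are mutually exclusive (closest distinct pair deltas differ by
≈ 1.003 Da), which the suite asserts. Variant linking requires no spectral
similarity by default — adducts can fragment differently — but the mass
arithmetic plus exact co-elution keeps false links rare at these
tolerances.

The protonated representative of a variant group is chosen by hypothesis
scoring: assume a member is `[M+H]+`, count how many other members any
other rule then explains; the best-explaining member wins (ties: larger
total area, then node id). Singletons flag themselves; groups with no
consistent `[M+H]+` fall back to the highest-total-area member. Exactly
one flag per group is an asserted invariant.

Blank removal discards blank-detected nodes and their *first* IVAMN
neighbors — one hop, no further propagation. Blank detection defaults to
any spectrum count > 0 in any BLANK sample (the strictest reading), with a
`min_blank_relative_area` option to require a minimum blank share of the
node's total area for noisy real data.

## SSMN filters

Defaults: minimum edge cosine 0.6, maximum degree 15, maximum component
size 200. The degree cap removes, for the first offending node in id
order, its lowest-scoring incident edge and re-checks; the component
filter removes the lowest-scoring edge inside an oversized component (ties
lexicographic). The degree cap runs before the component split — hubs are
usually the reason components balloon, and shedding their weakest edges
first splits components along low-confidence links; `mutual_top_k_filter`
is available as the GNPS-style alternative neighbor limit, and the filter
order is config-selectable. BED-node and singleton pruning runs once, in
that order, automated behind `prune_bed` (a manual curation step in
practice). All filters are edge-removal only, so no post-filter edge can
fall below the raw threshold, and all are deterministic: identical input
and config yield byte-identical edge lists.

## Differential analysis

Areas are normalised per node by the row maximum (each detected node peaks
at exactly 1.0 somewhere), so profiles compare *where* a compound appears
rather than how strongly it ionizes. Node-to-node profile similarity is
plain cosine; the heat-map leaf order comes from average-linkage
hierarchical clustering on 1 − cosine (node-wise, with the transposed
culture-wise analysis available by passing the transposed matrix). Fold
changes compare per-condition means against a reference condition with a
pseudo-count of 5% of the smallest nonzero area (keeps absences finite
without swamping real signals); flags use a symmetric threshold of 2.
No significance testing is performed — with two replicates per condition
the flags are descriptive, as in the experimental practice this mirrors.

## Extracted-ion chromatograms

EIC windows are absolute Da (default ± 0.01), not ppm, matching how
narrow-window chromatograms are quoted for this instrument class. Each
MS1 scan contributes one point: the sum of in-window peak intensities.
Where a feature *area* is needed the EIC is integrated trapezoidally;
apex counting reports contiguous regions above 10% of the trace maximum,
which cleanly separates chromatographic peaks ≥ ~0.5 min apart at the
default peak width.

## Synthetic experiment

The generator emulates the study design the package targets: four culture
media (A1, TSB, TSBY, ISP2) × 2 replicates, 2 blank injections, 2 medium
controls; 25 planted compounds in six families. The epoxyketone-like
family has congeners C20H36N2O6 / C20H34N2O6 / C16H28N2O6 / C16H26N2O6
([M+H]+ 401.26 / 399.25 / 345.20 / 343.19, the 2H and C4H8 relations) with
the C20 dihydro compound planted twice (rt 6.6 and 7.4 min) as a
stereoisomer pair distinguishable only by fragment intensities; it is
up-regulated in A1 (effects 1.0 / 0.2 / 0.1 / 0.1). Decoy families
(lipopeptide-, macrolactam-, macrolide-, diketopiperazine-,
carotenoid-like) carry opposing or null media preferences, including
sub-2-fold effects that must *not* be flagged. Three plasticizer-like
contaminants appear in blanks and all culture samples; three media ions
appear in medium controls and all culture samples.

Family fragment fingerprints come from a shared 12-fragment backbone
ladder per family: each member shifts 4 fragments by its mass offset from
the first member (so ≥ 60% of fragment m/z are shared directly, the rest
modulo the family offset and recovered by the modified cosine), drops 2,
and rescales intensities log-normally — yielding planted within-family
cosines of roughly 0.6–0.97 (stereoisomer pair ≈ 0.83). Fingerprints are
drawn from a fixed internal stream: structure is experimental design, not
per-run noise, and stays identical across seeds.

Noise model and defaults: compound yield per sample is log-normal with
CV 0.2 (mean-corrected); fragment intensities wobble with CV 0.05; all
m/z jitter with σ = 0.002 Da; retention apexes with σ = 0.01 min; three
uniform noise peaks at 0.5–2% of base are added per spectrum. Ionization
variants beyond `[M+H]+` are drawn once per compound (Na 0.6, NH4 0.4,
M+1 0.9, 2M+H 0.25) with fixed intensity factors (0.3 / 0.2 / 0.25 / 0.1).
The detection floor is 1% of the compound's own base intensity: a
condition-adjusted, noise-realised variant below it is simply absent from
that sample, which produces the "trace amounts under most conditions"
phenotype for weakly expressed compounds. MS1 traces are Gaussian elution
profiles (σ = 0.04 min) on a 0.02-min scan grid, with a constant
background ion anchoring every scan. One integer seed drives hierarchical
RNG streams (variant draw, yields, MS/MS emission, MS1), so a bundle is
byte-identical across regenerations.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: chromatographic tailing and rt drift across
runs, isotope envelopes beyond M+1, in-source fragmentation, charge
states > 1, detector saturation, and real blank variability. The recovery
metrics (100% blank removal, ≥ 90% family co-clustering, ≥ 95% fold-change
sensitivity at the default noise) certify the pipeline's logic under the
stated noise model, not instrument-grade performance.

## Problem sizes and numerical choices

The default experiment (12 samples, ~750 MS/MS spectra, ~90 nodes) runs
end to end in a few seconds; the exhaustive oracle benchmark uses 1,000
six-peak pairs. These sizes give the acceptance quantities stable values
across seeds while keeping the whole suite interactive. Degenerate inputs
are defined rather than crashed on: empty MGF → empty list, all-zero
intensity vectors are rejected with a clear error, zero-signal EICs have
no apex regions, all-zero abundance rows stay zero under normalisation and
score 0 against every other profile. Scores are clipped to [0, 1] against
float accumulation; all tie-breaks are lexicographic so every stage is
reproducible bit-for-bit.

## Known limitations

- Hypothesis scoring for representatives can mis-pick in groups where no
  true `[M+H]+` was ever acquired (falls back to abundance, which is the
  best available guess, and is reported as such in the count table).
- Single-linkage clustering can chain distinct features under heavy rt
  overlap; tolerances are config-exposed for such data.
- The IVAMN links by mass arithmetic and co-elution only; an optional
  cosine gate would be needed for chromatographically crowded real data.
- Library matching supports user-supplied MGF libraries only; no external
  database clients are included.
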