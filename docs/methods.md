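# Methods

This note documents the models, defaults, and numerical choices behind
`immunopep`, and what the synthetic-data generator does and does not emulate.

## Peptide identity

All set comparisons use the modification-stripped, uppercase peptide
sequence. Modifications are recorded on records and contribute to
monoisotopic mass, but never to identity or to GRAVY. I/L collapsing
(every I → L) is an explicit opt-in (`il_collapse`), default **off**:
fragment spectra cannot distinguish the leucine/isoleucine isomers, but
search engines report concrete sequences, and collapsing is a lossy choice
the caller should make deliberately. Coordinates are 1-based inclusive
throughout (matching `PROT_304-313` style window notation).

## Physicochemical properties

Monoisotopic masses use the standard residue table (pyteomics), water
= 18.010565 Da, proton = 1.007276 Da. GRAVY is the arithmetic mean of
Kyte–Doolittle hydropathy values (Biopython's table — the scale the common
web calculators implement). Reported-area normalization is within-sample
percentile ranking (ties share the mean rank): scale-free and therefore
comparable across instruments with different absolute intensity scales; the
"lower rank" split defaults to the median and is configurable, since no
canonical split exists. Population coverage assumes Hardy–Weinberg
equilibrium and independent loci: per locus with covered-allele mass p the
carried-copy PMF is ((1−p)², 2p(1−p), p²), loci combine by convolution, and
coverage-at-least-one is 1 − Π(1−p_l)².

## Proteolytic-artifact filter

**Scores** (all in [0,1], larger = more artifact-like):

* `protein_coverage` — for each source protein, the fraction of its
  positions covered by the union of all identified peptides mapped to it
  (exact substring placement, every occurrence); the maximum over source
  proteins is returned. Degradation blankets a region of a protein;
  presentation samples it sparsely.
* `peptide_coverage` — the fraction of the peptide's own residues covered by
  at least one *other* identified peptide, maximized over placements. A lone
  peptide scores exactly 0; a fully nested peptide scores 1.
* `nonligand_propensity` — 1 − max over the sample's HLA allotypes of
  predicted ligand-likeness. The default predictor is a position-weight
  matrix over the canonical class I anchor positions (position 2 and the
  C-terminus); externally precomputed predictions plug in through
  `TablePredictor`. Exact formulas for such scores vary between published
  implementations; each is isolated behind its own function so alternates
  can be swapped.

**Mixture deconvolution.** Per score (pooled per sample, matching per-sample
artifact reporting; cohort pooling available), a 1-D two-component Gaussian
mixture is fitted by EM: responsibilities in log space, weighted
mean/variance/weight updates, variances floored at 1e-6, stop when the
log-likelihood improves by <1e-8, maximum 1000 iterations, components
relabeled so μ₀ ≤ μ₁. Initialization is a deterministic median split with
moment matching per half; optional random restarts exist but default to
**zero** for threshold fitting, deliberately: scores with an exact point
mass (peptide coverage 0 for lone peptides) admit degenerate
floor-variance components whose likelihood diverges, and restarts reliably
find them. The median-split basin is the intended, well-behaved fit.

Flag semantics: `converged` tracks log-likelihood convergence; `collapsed`
marks a component resting on the variance floor. A collapsed-but-stable fit
is normal for zero-inflated scores and remains usable; only non-converged
fits (including the fully degenerate all-identical input) are rejected by
the threshold solver.

**FDR threshold.** With component 0 (lower mean) as the ligand-like null,
FDR(t) = w₀S₀(t) / (w₀S₀(t) + w₁S₁(t)) decreases monotonically between the
modes; the smallest t with FDR(t) ≤ α is found by 200-step bisection over
[μ₀−6σ₀, μ₁+6σ₁] using log-survival arithmetic for stability. Limits: α ≥ 1
→ −∞ (everything callable); w₁ = 0 → +∞ (nothing callable); FDR never ≤ α
→ +∞. A score axis whose mixture is fully degenerate contributes a +∞
threshold (no calls on that axis).

**Decision rule.** Proteolytic ⇔ the peptide *strictly* exceeds at least two
of the three thresholds ("exceeds" read as strict inequality).

## Spectral validation

Theoretical fragments are singly charged b/y ions by default; internal ions
are not scored (they may be annotated for display, but the correlation
statistic uses b and y only). An isotope label adds its delta mass to every
ion whose span contains the labelled position, so each complementary
(b_i, y_{n−i}) pair carries the label on exactly one side. Matching uses the
nearest peak within min(20 ppm, 0.02 Da) — ties break toward the lower-mz
peak — and one peak may satisfy several fragments. The correlation is
Pearson r on **raw intensities** of ions matched in **both** spectra
(intersection): zero-filling absent ions would inflate r when many ions are
missing, and r is already scale-invariant, so no transform is applied.
Fewer than 2 shared ions or a zero-variance vector yields an explicit
undefined flag rather than an error.

## Comparative profiling

A sample is *positive* for a peptide if any technical replicate contains it
(union). Benign exclusion is sequence-level only — allotype logic applies to
frequency denominators, never to exclusion. The display floor keeps
peptides at exactly 5% (the rule hides peptides on *fewer than* 5% of
samples); the broad-presentation tier is ≥ 20%. Replicate-overlap fractions
are computed over the union set and sum to 1; donor-tissue overlap reports,
per multi-sample donor, the fractions of the donor's union found in exactly
one and in all tissues plus a pairwise shared-peptide matrix.

## Synthetic-data generator

The generator emulates the statistical structure this pipeline consumes,
with exact bookkeeping so tests have a ground-truth oracle:

* **Proteome**: 3000 proteins of 300–400 aa, i.i.d. residues, uniform
  background composition. The size is chosen so peptides-per-protein ≈ 1,
  as in real immunopeptidomes against a full proteome; a small proteome
  would create spurious peptide pile-ups that mimic degradation ladders.
* **Ligands**: rejection-sampled proteome windows whose PWM ligand-likeness
  reaches 0.5 for at least one sample allotype; class I lengths weighted
  with 9-mers at 70%. The PWM anchor weights decay smoothly over the full
  alphabet so the propensity score has a continuous, unimodal null — the
  regime the two-Gaussian deconvolution assumes.
* **Artifacts**: ladders of ≥4 (typically 15) overlapping fragments of
  8–16 aa within a 50-aa hotspot, adjacent start offsets 2–3 residues apart,
  no motif constraint. This gives high peptide- and protein-coverage scores
  by construction.
* **Replicates**: each peptide detected independently per replicate with
  p = 0.8; peptides detected nowhere are dropped. Conditioned on detection,
  the all-3-replicates fraction is p³/(1−(1−p)³) ≈ 52%, matching the ~54%
  reported for real technical triplicates.
* **Cohorts**: a housekeeping pool shared by benign and tumor samples
  (tumor samples draw only pool peptides actually realized in the benign
  cohort, so every non-artifact tumor-only peptide is a deliberate plant);
  tumor-exclusive peptides planted at **exact sample counts** (not
  Bernoulli), so profiling recovery is exact and set-logic bugs cannot hide
  behind sampling noise; allotype-restricted plants go only to matching
  samples. Non-integer frequency × sample-count products are rounded with a
  recorded warning.
* **Spectra**: b/y peaks at theoretical m/z (synthetic copy label-shifted),
  one shared log-normal intensity profile, independent multiplicative noise
  per spectrum, Poisson-rate uniform-m/z noise peaks.

Everything derives from a single integer seed; emitted files are
byte-identical across runs. Default cohort sizes (10 benign / 20 tumor
samples, 400 peptides per sample, 5% artifact fraction) keep a full pipeline
run at a few seconds while leaving each sample enough peptides (~400) for
stable per-sample mixture fits.

**What passing tests show — and don't.** The generator validates the
*logic*: score computation, mixture deconvolution, threshold solving, set
algebra, frequency accounting, and fragment arithmetic. It does not emulate
chromatography, ion mobility, chimeric spectra, search-engine score
distributions, shared peptides between unrelated proteins, post-translational
modification landscapes, or real HLA motif complexity; performance numbers
measured on synthetic cohorts (e.g. artifact recall/FDR) therefore
characterize the method under the stated generative model, not on any real
dataset.

## Known limitations

* The three artifact scores are committed interpretations of score *names*
  from the literature; published implementations may differ in detail. The
  per-operation isolation makes swapping definitions cheap.
* The two-Gaussian model is a deliberate simplification; heavily
  multi-modal or zero-inflated score distributions are handled through the
  variance floor and collapsed-fit semantics, not by a richer mixture.
* The default PWM predictor is a deliberately simple anchor model meant for
  synthetic data and plumbing tests; real analyses should supply external
  predictions through the adapter.
* Benign-reference comparison is sequence-identity only; no HLA-restriction
  matching is attempted during exclusion.
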