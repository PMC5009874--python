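# Methods

## Model and assumptions

`kineticsbin` treats isoform-level FPKM tables (fragments per kilobase of
transcript per million mapped fragments) as its primitive input. Gene
expression is the sum of a gene's constituent isoform FPKMs; no
renormalization is applied after aggregation. All downstream decisions are
deterministic rules over these values:

* **Expression.** A gene or isoform is expressed in a sample when its FPKM
  is at or above `expression_fpkm` (default 1.0). The threshold is
  inclusive: values exactly at 1 FPKM count as expressed, since only the
  "below threshold" side defines non-expression. The same threshold is
  used at the gene and isoform level.
* **Differential representation.** Only genes expressed in both samples
  are tested. The consensus call requires all three of: fold change
  (computed on gene FPKM, no pseudocount — both values are ≥ 1 when the
  test runs) at or above `fold` (default 2.0, inclusive); a two-sided
  Fisher's exact test p below `fisher_alpha` (default 0.01, raw p-values,
  no multiplicity correction) on the 2×2 table of estimated fragments per
  kilobase for the gene versus a housekeeping gene (default `Gapdh`); and
  a concordant call from an external DE method read from a file. Direction
  comes from the fold sign, not the test. Fragments/kb are recovered as
  `round(FPKM × mapped_fragments / 1e6)` (half away from zero) — FPKM is
  already per-kilobase, so gene lengths are not re-derived from the
  annotation. Without an external call file the consensus degrades to
  fold + Fisher with a logged warning.
* **Splice categories.** `SI` is defined by annotated isoform count = 1
  (not "one isoform expressed"): `MOAT` already covers multi-isoform genes
  with a single above-threshold isoform, and this is the only
  non-overlapping reading of the four categories. A bin's
  "alternatively spliced" fraction is the fraction of its genes whose
  category is `MI` in the bin's *defining sample*: the exclusive sample
  for Only bins, the over-represented sample for OR bins, and the
  higher-FPKM sample for `Non_DR` (ties default to the first sample).
  That defining-sample rule for `Non_DR` is a documented package choice —
  nothing in the binning scheme itself forces it.
* **Kinetics.** Cross-tabulation only requires the two comparisons to
  share a gene universe; they may be A–B/B–C over three samples or two
  time points against a pooled baseline. Pooling two fractions into one
  stage uses the per-gene maximum FPKM by default (a gene expressed in
  either fraction is expressed at that stage); per-gene sum is available
  via `pool_samples(..., how="sum")`. Trajectory labels are a fixed,
  total, injective 6×6 lookup parameterized by the three stage names.
* **Enrichment.** One-sided hypergeometric tail per term against an
  explicit background (recommended: all genes expressed in the relevant
  comparison, for the same reason unexpressed network partners are
  filtered), Benjamini–Hochberg across the tested terms, significance at
  `benjamini_alpha` (default 0.05). The EASE-style overlap-minus-one
  discount is available behind `ease=True`.
* **Network expansion.** A deliberately transparent stand-in for
  black-box partner-discovery services: candidates are ranked by summed
  edge weight to the current list, the top `partners_per_round` (default
  20, a typical service result size) are intersected with the expressed
  gene set, survivors join, and the loop repeats until a round adds
  nothing or `max_iter` (default 10) is hit. Ties are broken
  lexicographically by gene id, making the result invariant to edge and
  seed input order. Seed genes absent from the network are kept (with a
  warning) but contribute no edges. Note that ranking happens *before*
  the expressed filter, so an unexpressed hub can occupy a candidate
  slot; when the per-round candidate count stays below
  `partners_per_round` this is provably equivalent to pre-restricting the
  network to expressed genes.
* **Junction probes.** Junctions are keyed by gene and genome-forward
  (donor_end, acceptor_start) in 0-based half-open coordinates (GTF input
  is converted at the boundary; strand is carried but does not affect
  uniqueness, as a gene is single-stranded). "Flank" is the exon length
  available on each side; when several transcripts share a junction the
  minimum over carriers is used, since a probe must fit all of them. Kept
  probes require a gene with ≥ 2 expressed transcripts, a junction unique
  among them (uniqueness over *expressed* transcripts by default;
  restricting the input transcript list reproduces the all-isoforms
  scope), and both flanks ≥ `min_flank` (default 13 — flanks of ≤ 12
  bases are eliminated).

## Synthetic data: what it emulates and what it does not

`simulate_comparison` plants every gene into a chosen bin and splice
category and draws FPKMs that satisfy the bin's defining inequalities with
margin: no generated gene or isoform value falls within ±5 % of the 1-FPKM
threshold (in practice ≥ 10 % margins are enforced), so floating-point
edges cannot flip a planted call. Defaults describe the study conditions
the pipeline targets: ~1,040 genes across all six bins, isoform counts
1–4 with mass (0.4, 0.3, 0.2, 0.1), splice mix SI/MI/MOAT/MIBT =
(0.4, 0.3, 0.2, 0.1), libraries of 60 and 62 million mapped fragments
(high-depth paired-end sequencing after ~60 % mapping), a 100-FPKM
housekeeping gene, and over-representation folds drawn from 2.5–20× so
planted OR genes clear the 2-fold rule with margin. Planted OR genes are
verified significant under the actual exact test at generation time;
draws that fail are resampled with bounded retries, and configurations
whose library sizes cannot reach significance raise an error rather than
emit inconsistent truth. External calls are generated fully concordant
with the planted truth.

`simulate_network_and_annotations` builds a shelled module — a seed shell
plus (by default) three successive partner shells wired only to the
previous shell — so expansion grows by exactly one shell per round and
performs exactly three growth iterations before detecting convergence. An
unexpressed high-degree decoy hangs off the seed shell; noise edges touch
only non-module genes. The annotation holds 50 terms over a 2,000-gene
background with one planted term supplying 80 % of a 25-gene query (or a
uniform query in the null configuration).

What passing these tests shows: the decision rules, their thresholds and
their symmetries are implemented exactly. What they do not show: behavior
on real quantifier output — the generator draws independent FPKMs with
clean margins and produces no ambiguous near-threshold genes, no
correlated isoform structure across samples, no misassigned multi-mapped
reads, and externally supplied DE calls are noiseless. Dataset-scale gene
counts from real tissue are therefore out of reach of the synthetic
conditions by design.

## Numerical choices

* Fisher's exact test is scipy's two-sided implementation; the test suite
  checks it against exact-rational hypergeometric tail enumeration for
  every 2×2 table with total ≤ 60 (agreement well below 1e-10; the
  acceptance script reports the measured maximum at total ≤ 40 to keep
  its runtime short).
* Fragment counts are rounded half away from zero before the exact test;
  proportional tables return p = 1 exactly; an all-zero table is an
  error.
* Benjamini–Hochberg q-values come from statsmodels; q ≥ p always holds
  and q is monotone in p-rank. Results are sorted by (q, p, term id) for
  determinism.
* Gene aggregation conserves total FPKM to 1e-9 (pure summation); TSV
  round-trips are exact because floats are written with shortest
  round-trip repr.
* Missing FPKM values are rejected, not imputed — the upstream quantifier
  always emits a number.
* All simulation randomness flows through one `numpy.random.default_rng`
  seeded from the configuration; identical config + seed give
  byte-identical output files.

## Problem sizes

The default test and acceptance workloads are sized for a single CPU:
ten planted comparisons of ~1,040 genes for recovery, fifty seeds each for
enrichment recovery and the null configuration, fifty random toy
annotations for the junction-filter oracle, and exhaustive Fisher
enumeration to table total 60 in the suite (40 in the acceptance script).

## Known limitations

* The consensus is only as good as the external method's calls; the
  package deliberately does not reimplement any posterior fold-change
  model, and single-method mode is a degraded fallback.
* Enrichment treats annotations as flat sets (no ontology-graph
  propagation) and the expansion scoring is a transparent heuristic, not
  a reimplementation of any service's label propagation.
* Flank checks are on exon lengths, not probe thermodynamics; no
  cross-hybridization screening is attempted.
* FPKM-based testing inherits FPKM's compositional caveats; the
  housekeeping row mitigates but does not remove them.
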