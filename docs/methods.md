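# Methods

## Problem and model

`quant16s` quantifies bacterial taxa in clinical specimens from 16S rRNA
amplicon OTU tables in *absolute* units — 16S rRNA gene copies per extract —
rather than relative abundances. Absolute quantification rests on a spike-in
internal calibrator (IC): a known number of *Synechococcus* 16S gene copies
is added to every DNA extract before amplification. Because emulsion
(micelle) PCR amplifies template molecules clonally, read counts are
proportional to input copies, so for every OTU

    copies = reads × (initial IC copies / IC reads)

The IC's own OTU(s) are excluded from output after an internal
self-consistency check (the calibrator must map back onto its own spike
exactly). If the calibrator is split over several OTUs by 97% clustering,
their reads are summed; zero calibrator reads is an "IC dropout" hard error
because the conversion is then undefined.

Contamination from reagents and the laboratory environment is removed by
processing a negative extraction control (NEC) — blank elution buffer —
through the identical pipeline and subtracting its calibrated consensus
profile from each sample profile, per OTU, clamped at zero. This works
because both are expressed in absolute copies: contaminant input is a
property of the reagent lots, shared between sample and NEC extracts, so it
cancels in copy space regardless of sequencing depth. Finally a limit of
detection (LOD) removes OTUs below 25 copies; the boundary is inclusive
(the LOD is the smallest detectable value).

## Pipeline stages and parameters

For each sample, processed in technical triplicate (NEC likewise):

1. **Subsampling** (optional, off by default): exactly `depth` reads drawn
   without replacement (multivariate hypergeometric), seeded. Default off
   because calibration is already depth-invariant; subsampling exists to
   bound compute on very deep runs.
2. **Calibration** per replicate, as above. `ic_initial_copies` defaults to
   1000 (the spike for extracts normalized to 10,000 copies/µL; use 100 for
   low-biomass extracts); `nec_ic_initial_copies` defaults to 100.
3. **Replicate consensus**: default policy `all` retains an OTU only if it
   has positive copies in every replicate and reports the arithmetic mean;
   triplicates thereby act as an accuracy/contamination filter. Policy
   `any` (union, absences averaged as zero) is available because the
   upstream description ("average of triplicate results") does not fix the
   retention rule; `all` was chosen as the stricter, contamination-robust
   reading.
4. **NEC subtraction** on the consensus maps (sample mean minus NEC mean),
   not per replicate: order-stable and matching the view that the NEC
   quantifies a per-lot contamination profile. Clamped at zero; OTUs
   reduced to zero are dropped.
5. **LOD filter**: retain copies ≥ `lod_copies` (default 25). Idempotent.

Every filtering stage appends a `QcRecord` (stage, units in, units out,
detail), so the result carries a complete audit trail into the report's
quality-control tab. Copies are kept as reals internally and rounded
half-up to integers only for display.

Genus-level aggregation sums copies over OTUs sharing a genus; OTUs whose
genus is unresolved aggregate at the deepest resolved rank with a `*`
marker (e.g. `Enterobacteriaceae*`), since some families cannot be split
at 97% identity.

## Diversity

Alpha diversity is computed on the integer-rounded consensus copies *after*
decontamination and LOD filtering — i.e. on the community the report
presents. (Computing on raw read counts instead would describe the
pre-correction library, contaminants included; for a clinical report the
corrected community is the meaningful one.) Conventions follow mothur's
defaults: bias-corrected Chao1 `S_obs + f1(f1−1)/(2(f2+1))`; Shannon with
natural log; Simpson as the unbiased dominance `D = Σ n_i(n_i−1)/(N(N−1))`
with the complement `1−D` also emitted. Empty communities are an error
("undefined diversity"), surfaced in the report as an explicit absence
statement rather than a zero.

## Concordance statistics

- **Fold difference** between two positive biomass estimates is
  `max(a,b)/min(a,b)` (≥ 1, symmetric). Sets of folds are summarized as
  median ± median absolute deviation or mean ± sample standard deviation;
  the MAD/SD pairing is a package convention since "±" is otherwise
  ambiguous.
- ***S. aureus* qPCR conversion**: the Martineau fragment is single-copy
  per genome while the genome carries six 16S operons, so genome copies ×6
  gives comparable 16S copies.
- **Genus-level culture concordance**: for each cultured genus, TP when
  the pipeline detects that genus in the same sample, FN otherwise;
  negatives are samples without that cultured genus, excluding
  commensal-flora samples for aerobic genera (any aerobic detection there
  is explained by the commensal growth). Positive anaerobic cultures are
  scored as one pooled taxon, matched by any obligate-anaerobe detection.
  Commensal-flora rows score TP when any aerobic OTU is detected. Pooled
  counts are sums over taxa. Aerobe/anaerobe status is a configurable
  lookup (`DEFAULT_AEROBIC_GENERA` / `DEFAULT_AEROBIC_FAMILIES`) because it
  is clinical knowledge, not derivable from the data; everything outside
  the aerobic sets is treated as an obligate anaerobe.
- **Sample-level detection**: a sample is culture-positive if it has any
  non-negative culture row and pipeline-positive if any OTU survives the
  pipeline. Rates are exact confusion-count arithmetic; no printed rate is
  hard-coded anywhere.
- Total-biomass comparisons against 16S qPCR should use consensus copies
  after NEC subtraction but before the LOD (totals are biomass estimates,
  not detections).

## Synthetic data generator

`quant16s.simulate` generates studies with known ground truth. A replicate
is one multinomial draw at the configured depth with probabilities
proportional to input copies (biological taxa + contamination + IC). This
pure-multinomial noise model encodes the quantitative fidelity of clonal
emulsion amplification; an optional per-taxon `efficiency` multiplier can
emulate the template-specific bias of conventional bulk PCR for contrast
experiments, and is off by default (it is not calibrated to any real
dataset). Defaults mirror the wet-lab conventions: IC 1000 copies into
samples, 100 into the NEC; the positive control is the four-species
community (*Moraxella*, *Staphylococcus*, *Haemophilus*, *Clostridium*) at
10,000 copies each; contamination (default: *Ralstonia* 300 +
*Bradyrhizobium* 150 copies, typical kit contaminants at realistic low
levels) is identical in expectation between samples and NEC — exactly the
assumption NEC subtraction requires.

OTU ids are keyed by genus (`Otu_<genus>`) and therefore stable across all
replicates, NEC and PC of a study, as joint OTU clustering would produce;
NEC subtraction matches contaminant OTUs by id and depends on this.

What the simulator does **not** model: sequence-level error, chimeras,
replicate-to-replicate overdispersion beyond multinomial, taxon dropout
from extraction, or cross-sample index bleed. Passing recovery tests on
simulated data therefore demonstrates the correctness of the calibration
arithmetic and the decontamination logic under the stated noise model, not
robustness to those real-data artifacts.

## Numerical and degenerate-input choices

- Counts are integers end to end; fractional read counts in input files
  are hard errors (corruption detector), never rounded.
- Display rounding is half-up (ties away from zero) via `decimal`.
- Subsampling and simulation use `numpy.random.default_rng`; per-replicate
  seeds derive from the run seed via `SeedSequence`, so identical inputs
  and seed give byte-identical result JSON (keys sorted).
- Empty NEC is a no-op; an empty sample result is valid and reported as
  "no bacterial DNA detected"; sunburst children are ordered by copies
  descending then name, making report bytes deterministic.
- Lineages shorter than six ranks are right-padded with `unclassified`;
  confidence suffixes are optional and absent means unset, not zero.

## Problem sizes used in the test and acceptance runs

Chosen as comfortable desk-scale sizes for the statistical checks: the
positive-control recovery property uses depth 40,000 and 20 seeds (median
fold difference recovered-vs-true ≤ 1.1; observed ≈ 1.02); single-taxon
recovery uses 10,000 true copies at depth 20,000 over 20 seeds (<10%
relative error); sampling-expectation checks use 200–500 seeds. Diversity
oracle equivalence runs 100 random communities against scikit-bio at 1e-9.

## Known limitations

- Species-level identification and antibiotic-susceptibility inference are
  out of scope; reporting stops at genus (family fallback).
- The aerobe/anaerobe lookup ships with defaults covering common clinical
  genera; site-specific organisms may need additions.
- The sample-level specificity is reported as exact arithmetic from the
  confusion counts; no adjustment or alternative derivation is applied.
- The `any` consensus policy and per-replicate NEC subtraction orderings
  are plausible alternatives to the defaults; both default choices are
  order-stable and stricter against contamination.
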