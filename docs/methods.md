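# Methods

## The evaluation model

The package models a reference-based external proficiency test for
high-resolution HLA typing. Each year a panel of samples (default 12) is
resolved to full-length allele names by a reference laboratory; participants
submit per-locus genotypes in a GL-string-like dialect together with any
explicitly excluded null alleles, the database release used, and the typing
method. Every submitted call receives exactly one grade.

### Resolution groups

All ambiguity reasoning reduces to equivalence groups over catalogue
sequences:

* **ARD groups** (high-resolution mode): two alleles are equivalent iff
  their antigen-recognition-domain sequences are identical character for
  character — exons 2+3 for class I loci (A, B, C), exon 2 for class II
  (DRB1, DRB3/4/5, DQB1, DQA1, DPB1, DPA1). Alleles in one group form an
  *allele ambiguity* (reportable as a slash list); alleles of different
  groups in one reported slot form an unresolved *genotype ambiguity*.
* **Allelic-resolution groups**: equivalence over the full coding sequence
  (exons, plus any stored introns) and the flanking windows 50 nt before the
  start codon and 500 nt after the stop codon. Stored UTRs are first cut to
  the window. Because different releases store UTRs of different lengths,
  alleles whose stored UTRs are shorter compare over the overlap only; to
  keep the relation an equivalence, grouping is the transitive closure
  (union–find) of that pairwise overlap relation. With UTRs stored at full
  window length this degenerates to exact string equality.

Allelic groups refine ARD groups, since the ARD exons lie inside the coding
sequence; a property test asserts this on generated catalogues.

### Null alleles

An N-suffixed allele *lurks* under a reported designation when the
designation subsumes it by name (`A*03:01` subsumes `A*03:01:01:02N`) — such
nulls must be excluded, either explicitly or implicitly by reporting a
resolution (≥3 fields) that separates them. A null is **unexcludable** when
its sequences are identical to an expressed allele over every region the
null still possesses (the exon-1-deleted pattern typified by DQB1*03:276N,
indistinguishable from DQB1*03:01 from exon 2 onward by any molecular
typing); not excluding such a null is never an error. A null that is itself
part of the reference genotype is truly present and likewise requires no
exclusion. The null registry (`nulls_under`) is ARD-group-aware: it reports
both name-subsumed N siblings and N alleles ARD-identical to the expansion,
because the exon-1-deleted pattern hides under a typing result without
sharing its name.

### The decision procedure

For one call, slots are first assigned to reference slots by exhaustive
search over the (at most two) pairings, maximizing the number of slots whose
designation expansion contains the assigned reference allele; ties prefer
the assignment with the least severe resulting grade, then input order. The
severity order used for this tie-break is correct < error2 < error1 <
error3 < error4 (an omitted exclusion is the mildest defect, a structural
fault the gravest); the published material assigns one category per
incorrect sample but never ranks severities, so this ordering is a package
design choice.

Categories are then tested in the fixed precedence **error4 → error3 →
error1 → error2** (structural validity before content, definite mistype
before unresolved ambiguity before omitted exclusion):

1. **error 4** — any one-field designation; any name absent from the
   catalogue release (graded, not raised); *mis-paired slash lists*: the
   union of the two submitted lists re-partitions by resolution group into
   exactly the complete per-chromosome lists, but the submitted slots mix
   groups; *incomplete lists*: a same-group slash list containing the
   reference allele but missing another expressed two-field designation of
   the group; a database release more than 365 days older than the shipment
   (boundary inclusive; behind the `strict_release` switch, since the
   published rules do not say whether a stale release invalidated results or
   was merely noted); unparseable typings quarantined by the reader.
2. **error 3** — slot-count mismatches (missing or extra allele; a
   single-detection allele reported twice — homozygosity is unprovable
   without family data); a matched slot whose expansion, after removing
   excluded alleles, does not contain the reference allele; a null reference
   allele reported without its N identity (the B*07:161N → B*07:02 pattern).
3. **error 1** — a slot's effective expansion spans more than one resolution
   group, or the reported genotype alternatives imply more than one
   group-level genotype. In allelic mode the group function is the allelic
   one, so an ARD-complete slash list whose members differ inside the window
   becomes error 1 — allelic grading is strictly stricter.
4. **error 2** — an excludable null subsumed by a matched designation that
   is neither part of the reference genotype, nor separated by the submitted
   resolution, nor covered by the exclusion list.

Complete-list and mis-pairing checks consider *expressed* two-field
designations only; N-suffixed designations are optional in slash lists (a
plain homozygous two-field report must stay correct when the only group-mate
is an unexcludable null). Singleton slots are never treated as incomplete
lists: a single designation containing the reference is a resolved claim.

Two readings exist for a reference null reported without its N: mistype
(error 3) or missed exclusion (error 2). The package grades it error 3 and
reserves error 2 for an expressed reference with an unexcluded lurking null.

### Scheme statistics

Percentages are rounded to one decimal, half away from zero. The EFI
criterion is strict: a (lab, locus) passes iff correct/tested **> 0.90**
(90.0% exactly fails) and tested ≥ 10. Overview lines per year: **A** = %
of labs with zero incorrect calls across all submitted loci; **B** = % of
labs meeting the >90% rule on every submitted locus — judged on the
percentage alone, so an all-correct laboratory counts regardless of sample
count and A ≤ B holds structurally; **C** = % of (lab, locus) pairs passing
the full criterion, with under-sampled pairs counted as failing by default
(`insufficient_fails_c` switch; the published material is silent here).
Certificates report, per locus, samples tested, correct/incorrect counts and
percent concordance.

## The synthetic generator

`SimulationConfig` defaults are the study conditions: 12 samples per year, 8
loci (A, B, C, DRB1, DRB4, DQB1, DPB1, DQA1), 24 participating laboratories
(within the scheme's historical 18–30 range), per-category injection rates
(2%, 2%, 3%, 2%) of the order seen in the published error breakdowns, a
methods mix dominated by NGS, and a database release dated weeks before the
May 31 shipment.

Each locus gets `groups_per_locus` (6) ARD groups of short random region
sequences (10–40 nt; one long 510-nt 3'UTR per locus to place an
allele pair differing only beyond the +500 window — nothing assumes
biological lengths). Every group has two expressed two-field designations
(same ARD, different exon 1 — the DPB1*03:01/104:01 allele-ambiguity
pattern); each two-field designation independently carries an excludable
four-field N sibling with probability `null_fraction` (0.8); loci listed in
`unexcludable_null_loci` (default DQB1) additionally get an exon-1-deleted
two-field null. References are drawn from geometric allele frequencies;
a small fraction are single-detection (one slot) or carry an excludable null
allele. Coincidentally homozygous draws are emitted as single-detection
references, since homozygosity cannot be proven for shipped DNA samples; the
unexcludable null is never drawn as a reference allele because the grading
rules do not define what a reference laboratory could report for it.

Error injections are built **constructively from catalogue structure** —
never by querying the grader — so grader output can be cross-validated
against the truth labels: e1 = a slash list spanning two ARD groups or a
discordant genotype alternative; e2 = a two-field report whose lurking null
exclusion is omitted (the partner slot is reported at full resolution so no
exclusion list is needed at all); e3 = swap to a different designation, drop
an allele, add an extra allele, or duplicate a single detection; e4 = a
one-field typing, crossed complete slash lists, an unknown allele, or a
typing with the `*` separators removed (quarantined by the reader). Category
sampling is exclusive per call and drawn before the concrete perturbation;
when a category is inapplicable to the sample at hand the draw repeats from
the residual distribution and the truth label records the realized category.
All randomness flows from one mandatory seed through per-stage derived
streams; identical configurations produce byte-identical files.

What the generator does *not* emulate: realistic HLA population frequencies,
linkage between loci, method-dependent error profiles, clerical error
clustering within laboratories, or real IPD-IMGT/HLA release content.
Passing tests therefore demonstrate the correctness of the grading logic and
statistics on structurally faithful inputs, not performance on real-world
submission streams.

## Validation strategy

The real scheme's two decades of submissions are not public, so the
published multi-year tables cannot be recomputed; validation is
property-based instead:

* ten canonical mistype scenarios on a hand-built toy catalogue
  (`hla_ept.examples`) reproduce their published outcomes exactly;
* the engine agrees 100% with an independent brute-force oracle grader
  (`tests/oracle_grader.py`) that rebuilds groups by pairwise raw-string
  comparison and expands designations by linear scan, on hundreds of random
  synthetic calls;
* every injected perturbation grades to its labelled category (≥1,000
  injections across a five-year, 30-lab scheme);
* injected rates are recovered within three binomial standard errors over
  30 labs × 12 samples × 8 loci;
* statistic invariants: counts re-sum exactly pre-rounding; line A ≤ line B
  over 100 seeded schemes; the EFI boundary sits between 11/12 and 10/12;
  the pipeline is byte-deterministic under a fixed seed.

Problem sizes in the test suite and acceptance script (3–30 labs, 1–5
years, 2–8 loci) were chosen to exercise every code path at desk scale; the
whole suite runs in well under a minute.

## Numerical and degenerate-input choices

* Field tokens compare as zero-padded strings, never as integers; the parser
  left-pads single-digit fields. Slash lists sort by numeric field value.
* The release window is 365 days, boundary inclusive ("not more than one
  year" leaves leap years undefined).
* Rounding: one decimal, half away from zero, via `decimal.Decimal`.
* An empty effective expansion (everything excluded) fails containment and
  grades error 3.
* Duplicate alleles within a slash list are collapsed on parsing; duplicate
  submission keys are rejected with line-numbered diagnostics; a submission
  referencing an unknown sample is a hard error (a sample-tracking failure
  must not be silently graded).
* Catalogues loaded from the two-column allele-list dialect validate names
  only; group queries on them raise, they never silently grade.

## Known limitations

* Low-resolution grading is not implemented (no rules are given for it).
* Serological nomenclature and pre-2010 four-digit names are out of scope
  beyond the parser's alias hooks.
* G-group/P-group official names are not emitted; internal group
  identifiers serve that role.
* The grader trusts the reference panel; discordance of the reference
  itself is outside the model.
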