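# hla-ept

Grading and reporting engine for **high-resolution HLA external proficiency
testing (EPT)** schemes, for scheme organizers and H&I laboratories that need
a nomenclature-aware, reference-based evaluation of HLA genotype submissions.

In a reference-based EPT, DNA samples are shipped yearly (12 per year here)
to participating laboratories; each submits per-locus HLA genotypes which are
compared against an independent reference typing rather than a participant
consensus. This package implements that comparison and everything around it:

* **Nomenclature** (`hla_ept.nomenclature`) — WHO-style allele designations
  `LOCUS*f1:f2[:f3[:f4]][N|L|S|Q|A|C]` and a GL-string-like genotype dialect
  (`/` allele alternatives, `+` chromosomal slots, `|` whole-genotype
  alternatives), with canonical formatting and round-trip parsing.
* **Allele catalogue** (`hla_ept.catalog`) — per-allele region sequences,
  antigen-recognition-domain (ARD) equivalence groups (exons 2+3 for class I,
  exon 2 for class II), allelic-resolution groups over the coding sequence
  plus −50/+500 nt flanking windows, designation expansion, a null-allele
  registry with excludability, and the one-year database-release rule.
* **Grading engine** (`hla_ept.grading`) — classifies each submitted call as
  `correct` or one of four error categories:
  * **error 1** — unresolved genotype ambiguity (reported alternatives span
    more than one ARD group);
  * **error 2** — an excludable null allele subsumed by the reported
    designation (e.g. `A*03:01:01:02N` under `A*03:01`) was not excluded;
  * **error 3** — typing differs from the reference: wrong, missing or extra
    allele, or an allele reported twice though detected only once;
  * **error 4** — nomenclature/structural faults: one-field typings, unknown
    names, mis-paired or incomplete slash lists, stale database release.
* **Scheme statistics** (`hla_ept.stats`) — per-locus-per-year percent
  correct, error breakdowns, the strict EFI criterion (>90% correct on ≥10
  samples per locus), the three overview lines (A: labs 100% correct, B: labs
  meeting the criterion on all submitted loci, C: submitted loci meeting the
  criterion), participation/method summaries and per-laboratory certificates.
* **Synthetic data** (`hla_ept.simulate`) — deterministic generation of
  catalogues, reference panels and lab submissions with constructively
  injected, truth-labelled errors of each category, so the entire pipeline is
  testable without any database download.

## Worked example

Simulate a small scheme (3 loci, 6 laboratories, 12 samples), grade it, and
report:

```sh
$ printf 'loci: [A, B, DQB1]\nn_labs: 6\n' > config.yaml
$ hla-ept simulate --config config.yaml --seed 11 --out scheme
scheme written to scheme
$ hla-ept grade --catalog scheme/catalog.csv --panel scheme/panel.tsv \
    --submissions scheme/submissions.tsv --out grades.tsv
WARNING line 95: typing quarantined (grades error4): missing '*' separator in 'A02:31:01:01'
graded 216 calls (22 not correct) -> grades.tsv
$ hla-ept report --grades grades.tsv --submissions scheme/submissions.tsv --out report
report written to report
$ hla-ept certify --grades grades.tsv --lab L01 --year 2022
External proficiency testing certificate — laboratory L01, 2022

locus       n_tested  n_correct  n_incorrect  % concordance   EFI
A                 12         10            2           83.3  fail
B                 12         11            1           91.7  pass
DQB1              12         12            0          100.0  pass
```

The 216 graded calls are 6 labs × 12 samples × 3 loci. The quarantine
warning is an injected nomenclature corruption (a typing missing its `*`
separator) that is kept and graded error 4 rather than dropped. On the
certificate, 11/12 (91.7%) passes the strict >90% EFI rule while 10/12
(83.3%) fails — with 12 samples per locus, at most one incorrect result is
tolerated. `report/percent_correct.csv` holds the locus×year concordance
table (here A 87.5, B 88.9, DQB1 93.1) and `report/overview_lines.csv` the
three overview lines.

The same pipeline is available as library calls (`generate_catalog`,
`generate_panel`, `generate_submissions`, `grade_scheme`, `build_report`);
`--mode allelic` grades at allelic resolution, where ambiguities within
−50/+500 nt of the coding sequence must also be resolved.

## Layout

```
src/hla_ept/        library (nomenclature, catalog, grading, stats, simulate, io, cli)
src/hla_ept/examples.py   hand-built toy catalogue + canonical grading scenarios
tests/              pytest suite, incl. the independent brute-force oracle grader
scripts/acceptance.py     end-to-end validation, JSON output
docs/methods.md     model, rules, parameters, design choices, limitations
```
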