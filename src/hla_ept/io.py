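"""File dialects: reference-panel TSV, submission TSV, grade TSV, report output.

All files are UTF-8, tab-separated with a required header (typing strings
contain slashes and plus signs but never tabs).  Submission records that fail
structural validation (duplicate keys, unknown locus) are rejected with a
line-numbered diagnostic; records whose typing string merely fails to parse
are kept and later graded error4 by the grading engine (quarantine).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

from .grading import GradeResult, ReferenceCall
from .nomenclature import KNOWN_LOCI, NomenclatureError, format_allele, parse_genotype
from .stats import SchemeReport

__all__ = [
    "SubmissionRecord",
    "Diagnostic",
    "read_submissions",
    "write_submissions",
    "read_panel",
    "write_panel",
    "read_grades",
    "write_grades",
    "write_report",
]


@dataclass(frozen=True)
class SubmissionRecord:
    """One laboratory's typing for one sample x locus, as submitted."""

    lab_id: str
    year: int
    sample_id: str
    locus: str
    typing: str
    excluded_nulls: str = ""
    db_release: str = ""
    method: str = ""


@dataclass(frozen=True)
class Diagnostic:
    line: int
    message: str


_SUBMISSION_HEADER = [
    "lab_id", "year", "sample_id", "locus", "typing", "excluded_nulls", "db_release", "method",
]
_PANEL_HEADER = ["year", "sample_id", "locus", "genotype"]
_GRADES_HEADER = [
    "lab_id", "year", "sample_id", "locus", "category", "reason", "detail", "mode",
]


def _open_tsv(path, expected_header: list[str]):
    fh = open(path, newline="", encoding="utf-8")
    reader = csv.reader(fh, delimiter="\t")
    header = next(reader, None)
    if header is None or [h.strip() for h in header] != expected_header:
        fh.close()
        raise ValueError(
            f"{path}: expected header {expected_header}, got {header}"
        )
    return fh, reader


def write_submissions(records, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_SUBMISSION_HEADER)
        for r in records:
            w.writerow(
                [r.lab_id, r.year, r.sample_id, r.locus, r.typing,
                 r.excluded_nulls, r.db_release, r.method]
            )


def read_submissions(path) -> tuple[list[SubmissionRecord], list[Diagnostic]]:
    """Read submission records with line-numbered diagnostics.

    Duplicate (lab, year, sample, locus) keys and unknown loci reject the
    record; an unparseable typing string only produces a diagnostic — the
    record stays and grades error4 downstream.
    """
    records: list[SubmissionRecord] = []
    diagnostics: list[Diagnostic] = []
    seen: set[tuple] = set()
    fh, reader = _open_tsv(path, _SUBMISSION_HEADER)
    with fh:
        for lineno, row in enumerate(reader, start=2):
            if not any(c.strip() for c in row):
                continue
            if len(row) != len(_SUBMISSION_HEADER):
                diagnostics.append(Diagnostic(lineno, f"expected {len(_SUBMISSION_HEADER)} columns, got {len(row)}"))
                continue
            lab, year_s, sample, locus, typing, excl, release, method = (c.strip() for c in row)
            try:
                year = int(year_s)
            except ValueError:
                diagnostics.append(Diagnostic(lineno, f"bad year {year_s!r}"))
                continue
            if locus.upper() not in KNOWN_LOCI:
                diagnostics.append(Diagnostic(lineno, f"unknown locus {locus!r}"))
                continue
            key = (lab, year, sample, locus.upper())
            if key in seen:
                diagnostics.append(Diagnostic(lineno, f"duplicate record for {key}"))
                continue
            seen.add(key)
            try:
                parse_genotype(typing, locus=locus.upper(), excluded_nulls_text=excl)
            except NomenclatureError as err:
                diagnostics.append(
                    Diagnostic(lineno, f"typing quarantined (grades error4): {err}")
                )
            records.append(
                SubmissionRecord(lab, year, sample, locus.upper(), typing, excl, release, method)
            )
    return records, diagnostics


def write_panel(panel, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_PANEL_HEADER)
        ordered = sorted(panel, key=lambda r: (r.year, r.sample_id, r.locus))
        for r in ordered:
            w.writerow(
                [r.year, r.sample_id, r.locus, "+".join(format_allele(a) for a in r.slots)]
            )


def read_panel(path) -> list[ReferenceCall]:
    refs = []
    fh, reader = _open_tsv(path, _PANEL_HEADER)
    with fh:
        for lineno, row in enumerate(reader, start=2):
            if not any(c.strip() for c in row):
                continue
            year_s, sample, locus, genotype = (c.strip() for c in row)
            call = parse_genotype(genotype, locus=locus)
            slots = []
            for slot in call.slots:
                if len(slot) != 1:
                    raise ValueError(
                        f"{path} line {lineno}: reference slots must be single resolved alleles"
                    )
                slots.append(slot[0])
            refs.append(
                ReferenceCall(
                    locus=locus, slots=tuple(slots), sample_id=sample, year=int(year_s)
                )
            )
    return refs


def write_grades(results, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_GRADES_HEADER)
        for r in results:
            w.writerow(
                [r.lab_id, r.year, r.sample_id, r.locus, r.category, r.reason, r.detail, r.mode]
            )


def read_grades(path) -> list[GradeResult]:
    out = []
    fh, reader = _open_tsv(path, _GRADES_HEADER)
    with fh:
        for row in reader:
            if not any(c.strip() for c in row):
                continue
            lab, year_s, sample, locus, category, reason, detail, mode = row
            out.append(
                GradeResult(lab, int(year_s), sample, locus, category, reason, detail, mode)
            )
    return out


def write_report(report: SchemeReport, outdir) -> None:
    """Write the scheme report as JSON plus flat CSV tables and certificates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    # percent-correct table: years as rows, loci as columns
    loci = sorted({s.locus for s in report.stats})
    years = sorted({s.year for s in report.stats})
    cell = {(s.locus, s.year): s.percent_correct for s in report.stats}
    with open(outdir / "percent_correct.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["year", *loci])
        for year in years:
            w.writerow([year, *[cell.get((locus, year), "") for locus in loci]])

    with open(outdir / "error_breakdown.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["locus", "year", "category", "percent"])
        for s in report.stats:
            for cat, pct in sorted(s.error_percentages.items()):
                w.writerow([s.locus, s.year, cat, pct])

    with open(outdir / "overview_lines.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["year", "line_a", "line_b", "line_c"])
        for year, ln in sorted(report.lines.items()):
            w.writerow([year, ln.a, ln.b, ln.c])

    with open(outdir / "participation.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["kind", "name", "year", "percent_labs"])
        for (locus, year), pct in sorted(report.locus_participation.items()):
            w.writerow(["locus", locus, year, pct])
        for (method, year), pct in sorted(report.method_participation.items()):
            w.writerow(["method", method, year, pct])

    certdir = outdir / "certificates"
    certdir.mkdir(exist_ok=True)
    for cert in report.certificates:
        stem = f"{cert.lab_id}_{cert.year}"
        (certdir / f"{stem}.txt").write_text(cert.render_text(), encoding="utf-8")
        with open(certdir / f"{stem}.json", "w", encoding="utf-8") as fh:
            json.dump(cert.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
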