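"""Scheme-level statistics: concordance tables, error breakdowns, EFI compliance,
overview lines and per-laboratory certificates.

Percentages are reported to one decimal, rounded half away from zero.  The
EFI external-proficiency criterion is strict: a laboratory passes a locus when
*more than* 90% of its results are correct and at least ``min_samples``
(default 10) samples were graded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .grading import CATEGORIES, CORRECT

__all__ = [
    "PASS",
    "FAIL",
    "INSUFFICIENT_N",
    "round_half_away",
    "results_frame",
    "LocusYearStat",
    "percent_correct_table",
    "error_breakdown",
    "Compliance",
    "efi_compliance",
    "OverviewLines",
    "overview_lines",
    "participation_summary",
    "CertificateRow",
    "Certificate",
    "make_certificate",
    "SchemeReport",
    "build_report",
]

PASS = "pass"
FAIL = "fail"
INSUFFICIENT_N = "insufficient_n"

EFI_THRESHOLD = 0.90
EFI_MIN_SAMPLES = 10

_ERROR_CATEGORIES = tuple(c for c in CATEGORIES if c != CORRECT)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (Table-style one-decimal percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def results_frame(results) -> pd.DataFrame:
    """Graded results as a tidy DataFrame (one row per lab x sample x locus)."""
    return pd.DataFrame(
        [
            {
                "lab_id": r.lab_id,
                "year": r.year,
                "sample_id": r.sample_id,
                "locus": r.locus,
                "category": r.category,
                "reason": r.reason,
                "mode": r.mode,
            }
            for r in results
        ]
    )


@dataclass(frozen=True)
class LocusYearStat:
    locus: str
    year: int
    n_submitted: int
    n_correct: int
    percent_correct: float
    error_counts: dict[str, int] = field(compare=False)
    error_percentages: dict[str, float] = field(compare=False)


def _locus_year_groups(results):
    frame = results_frame(results)
    if frame.empty:
        raise ValueError("no graded results")
    return frame.groupby(["locus", "year"], sort=True)


def percent_correct_table(results) -> list[LocusYearStat]:
    """Percentage of samples correctly typed, per locus and year."""
    stats = []
    for (locus, year), grp in _locus_year_groups(results):
        n = len(grp)
        counts = grp["category"].value_counts().to_dict()
        n_correct = counts.get(CORRECT, 0)
        stats.append(
            LocusYearStat(
                locus=locus,
                year=int(year),
                n_submitted=n,
                n_correct=n_correct,
                percent_correct=round_half_away(100.0 * n_correct / n),
                error_counts={c: int(counts.get(c, 0)) for c in _ERROR_CATEGORIES},
                error_percentages={
                    c: round_half_away(100.0 * counts.get(c, 0) / n)
                    for c in _ERROR_CATEGORIES
                },
            )
        )
    return stats


def error_breakdown(results) -> dict[tuple[str, int], dict[str, float]]:
    """Per (locus, year): percentage of graded calls in each error category."""
    return {
        (s.locus, s.year): dict(s.error_percentages) for s in percent_correct_table(results)
    }


@dataclass(frozen=True)
class Compliance:
    status: str  # pass | fail | insufficient_n
    n_tested: int
    n_correct: int
    fraction_correct: float


def efi_compliance(
    results, threshold: float = EFI_THRESHOLD, min_samples: int = EFI_MIN_SAMPLES
) -> dict[tuple[str, int, str], Compliance]:
    """EFI EPT criterion per (lab, year, locus): strictly more than
    ``threshold`` of results correct, on at least ``min_samples`` samples."""
    out = {}
    frame = results_frame(results)
    if frame.empty:
        return out
    for (lab, year, locus), grp in frame.groupby(["lab_id", "year", "locus"], sort=True):
        n = len(grp)
        n_correct = int((grp["category"] == CORRECT).sum())
        frac = n_correct / n
        if n < min_samples:
            status = INSUFFICIENT_N
        elif frac > threshold:
            status = PASS
        else:
            status = FAIL
        out[(lab, int(year), locus)] = Compliance(status, n, n_correct, frac)
    return out


@dataclass(frozen=True)
class OverviewLines:
    """The three overview percentages for one scheme year.

    A: laboratories 100% correct over all their submitted loci.
    B: laboratories meeting the >threshold criterion on every submitted locus
       (judged on the percentage alone, so an all-correct laboratory always
       counts regardless of sample count).
    C: (lab, locus) pairs passing the full EFI criterion; pairs with fewer
       than ``min_samples`` samples count as failing when
       ``insufficient_fails_c`` is set (default).
    """

    a: float
    b: float
    c: float


def overview_lines(
    results,
    year: int,
    threshold: float = EFI_THRESHOLD,
    min_samples: int = EFI_MIN_SAMPLES,
    insufficient_fails_c: bool = True,
) -> OverviewLines:
    frame = results_frame(results)
    frame = frame[frame["year"] == year]
    if frame.empty:
        raise ValueError(f"no graded results for year {year}")
    comp = efi_compliance(
        [r for r in results if r.year == year], threshold=threshold, min_samples=min_samples
    )
    labs = sorted(frame["lab_id"].unique())
    per_lab = {lab: [c for (l, _, _), c in comp.items() if l == lab] for lab in labs}
    n_labs = len(labs)
    a = sum(all(c.n_correct == c.n_tested for c in sub) for sub in per_lab.values())
    b = sum(
        all(c.fraction_correct > threshold for c in sub) for sub in per_lab.values()
    )
    if insufficient_fails_c:
        pairs = list(comp.values())
    else:
        pairs = [c for c in comp.values() if c.status != INSUFFICIENT_N]
    c_num = sum(c.status == PASS for c in pairs)
    return OverviewLines(
        a=round_half_away(100.0 * a / n_labs),
        b=round_half_away(100.0 * b / n_labs),
        c=round_half_away(100.0 * c_num / len(pairs)) if pairs else 100.0,
    )


def participation_summary(records):
    """Percentage of laboratories submitting each locus, and using each method,
    per year.  Each laboratory counts once per locus/method per year."""
    frame = pd.DataFrame(
        [
            {
                "lab_id": r.lab_id,
                "year": r.year,
                "locus": r.locus,
                "method": r.method,
            }
            for r in records
        ]
    )
    if frame.empty:
        raise ValueError("no submission records")
    locus_pct: dict[tuple[str, int], float] = {}
    method_pct: dict[tuple[str, int], float] = {}
    for year, ygrp in frame.groupby("year", sort=True):
        n_labs = ygrp["lab_id"].nunique()
        for locus, lgrp in ygrp.groupby("locus", sort=True):
            locus_pct[(locus, int(year))] = round_half_away(
                100.0 * lgrp["lab_id"].nunique() / n_labs
            )
        for method, mgrp in ygrp.groupby("method", sort=True):
            method_pct[(method, int(year))] = round_half_away(
                100.0 * mgrp["lab_id"].nunique() / n_labs
            )
    return locus_pct, method_pct


@dataclass(frozen=True)
class CertificateRow:
    locus: str
    n_tested: int
    n_correct: int
    n_incorrect: int
    percent_concordance: float
    efi_pass: bool


@dataclass(frozen=True)
class Certificate:
    lab_id: str
    year: int
    rows: tuple[CertificateRow, ...]

    def render_text(self) -> str:
        lines = [
            f"External proficiency testing certificate — laboratory {self.lab_id}, {self.year}",
            "",
            f"{'locus':<10}{'n_tested':>10}{'n_correct':>11}{'n_incorrect':>13}{'% concordance':>15}{'EFI':>6}",
        ]
        for r in self.rows:
            lines.append(
                f"{r.locus:<10}{r.n_tested:>10}{r.n_correct:>11}{r.n_incorrect:>13}"
                f"{r.percent_concordance:>15.1f}{('pass' if r.efi_pass else 'fail'):>6}"
            )
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "lab_id": self.lab_id,
            "year": self.year,
            "loci": [
                {
                    "locus": r.locus,
                    "n_tested": r.n_tested,
                    "n_correct": r.n_correct,
                    "n_incorrect": r.n_incorrect,
                    "percent_concordance": r.percent_concordance,
                    "efi_pass": r.efi_pass,
                }
                for r in self.rows
            ],
        }


def make_certificate(
    results,
    lab_id: str,
    year: int,
    threshold: float = EFI_THRESHOLD,
    min_samples: int = EFI_MIN_SAMPLES,
) -> Certificate:
    """Per-laboratory certificate: samples tested, correct/incorrect counts and
    percent concordance with the reference, per locus."""
    mine = [r for r in results if r.lab_id == lab_id and r.year == year]
    if not mine:
        raise ValueError(f"no graded results for lab {lab_id!r} in {year}")
    comp = efi_compliance(mine, threshold=threshold, min_samples=min_samples)
    rows = []
    for (lab, yr, locus), c in sorted(comp.items()):
        rows.append(
            CertificateRow(
                locus=locus,
                n_tested=c.n_tested,
                n_correct=c.n_correct,
                n_incorrect=c.n_tested - c.n_correct,
                percent_concordance=round_half_away(100.0 * c.n_correct / c.n_tested),
                efi_pass=c.status == PASS,
            )
        )
    return Certificate(lab_id=lab_id, year=year, rows=tuple(rows))


@dataclass
class SchemeReport:
    """Aggregated scheme statistics over all graded years."""

    stats: list[LocusYearStat]
    lines: dict[int, OverviewLines]
    compliance: dict[tuple[str, int, str], Compliance]
    locus_participation: dict[tuple[str, int], float]
    method_participation: dict[tuple[str, int], float]
    certificates: list[Certificate]

    def to_dict(self) -> dict:
        return {
            "locus_year": [
                {
                    "locus": s.locus,
                    "year": s.year,
                    "n_submitted": s.n_submitted,
                    "n_correct": s.n_correct,
                    "percent_correct": s.percent_correct,
                    "error_counts": s.error_counts,
                    "error_percentages": s.error_percentages,
                }
                for s in self.stats
            ],
            "overview_lines": {
                str(year): {"A": ln.a, "B": ln.b, "C": ln.c}
                for year, ln in sorted(self.lines.items())
            },
            "efi_compliance": [
                {
                    "lab_id": lab,
                    "year": year,
                    "locus": locus,
                    "status": c.status,
                    "n_tested": c.n_tested,
                    "n_correct": c.n_correct,
                }
                for (lab, year, locus), c in sorted(self.compliance.items())
            ],
            "locus_participation": [
                {"locus": locus, "year": year, "percent_labs": pct}
                for (locus, year), pct in sorted(self.locus_participation.items())
            ],
            "method_participation": [
                {"method": m, "year": year, "percent_labs": pct}
                for (m, year), pct in sorted(self.method_participation.items())
            ],
            "certificates": [c.to_dict() for c in self.certificates],
        }


def build_report(
    results,
    records=None,
    threshold: float = EFI_THRESHOLD,
    min_samples: int = EFI_MIN_SAMPLES,
    insufficient_fails_c: bool = True,
) -> SchemeReport:
    """Assemble the full scheme report from graded results (and, optionally,
    the raw submission records for participation/method summaries)."""
    stats = percent_correct_table(results)
    years = sorted({s.year for s in stats})
    lines = {
        y: overview_lines(
            results,
            y,
            threshold=threshold,
            min_samples=min_samples,
            insufficient_fails_c=insufficient_fails_c,
        )
        for y in years
    }
    comp = efi_compliance(results, threshold=threshold, min_samples=min_samples)
    if records is not None:
        locus_pct, method_pct = participation_summary(records)
    else:
        locus_pct, method_pct = {}, {}
    certs = [
        make_certificate(results, lab, year, threshold=threshold, min_samples=min_samples)
        for (lab, year) in sorted({(r.lab_id, r.year) for r in results})
    ]
    return SchemeReport(
        stats=stats,
        lines=lines,
        compliance=comp,
        locus_participation=locus_pct,
        method_participation=method_pct,
        certificates=certs,
    )
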