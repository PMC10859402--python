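"""Canonical grading scenarios on a hand-built toy catalogue.

The catalogue reproduces, with short synthetic sequences, the classic
structures every EPT grader must handle:

* ``A*03:01`` with the excludable null sibling ``A*03:01:01:02N``;
* ``B*07:161N`` as a null reference allele commonly mistyped as ``B*07:02``;
* ``B*15:01``/``B*15:25`` allele ambiguity and ``B*15:11`` differing within
  exons 2-3 (genotype ambiguity);
* ``DPB1*03:01`` vs ``DPB1*104:01`` — identical exon 2, different exon 3;
* ``DQB1*06:03/06:41`` and ``DQB1*06:04/06:39`` allele-ambiguity pairs whose
  slash lists can be mis-paired across chromosomes;
* ``DRB4*01:03`` with the null sibling ``DRB4*01:03:01:02N``;
* ``DQB1*03:276N`` — exon-1-deleted, indistinguishable from ``DQB1*03:01``
  from exon 2 on, hence *unexcludable*.

The sequences are desk-scale stand-ins, not real gene sequences; only the
identity relations between them matter.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

from .catalog import Catalog, CatalogEntry
from .grading import ReferenceCall
from .nomenclature import parse_allele

__all__ = ["worked_example_catalog", "worked_examples", "WorkedExample"]


def _mk(seed_char: str, n: int) -> str:
    # deterministic letter-block sequences; distinct blocks differ everywhere
    return {"A": "ACGT", "B": "CGTA", "C": "GTAC", "D": "TACG", "E": "AACG",
            "F": "CCGA", "G": "GGTA", "H": "TTAC", "I": "ACCA", "J": "CATG"}[seed_char] * (n // 4 + 1)


def _entry(name: str, **regions: str) -> CatalogEntry:
    return CatalogEntry(parse_allele(name), dict(regions))


def worked_example_catalog() -> Catalog:
    """Toy catalogue (synthetic sequences) for the canonical scenarios."""
    e = []
    # ---- HLA-A ----
    a_common = dict(utr5=_mk("A", 20), exon2=_mk("B", 24), exon3=_mk("C", 24),
                    exon4=_mk("D", 16), utr3=_mk("E", 20))
    e.append(_entry("A*03:01:01:01", exon1=_mk("A", 12), **a_common))
    e.append(_entry("A*03:01:01:02N", exon1=_mk("B", 12), **a_common))  # differs in exon 1
    e.append(_entry("A*24:02:01:01", utr5=_mk("A", 20), exon1=_mk("C", 12),
                    exon2=_mk("D", 24), exon3=_mk("E", 24), exon4=_mk("D", 16),
                    utr3=_mk("E", 20)))
    # ---- HLA-B ----
    b7 = dict(utr5=_mk("A", 20), exon2=_mk("F", 24),
              exon4=_mk("D", 16), utr3=_mk("E", 20))
    e.append(_entry("B*07:02:01:01", exon1=_mk("A", 12), exon3=_mk("G", 24), **b7))
    # null with its own ARD (differs in exon 3): no lurking-null burden on B*07:02
    e.append(_entry("B*07:161N", exon1=_mk("D", 12), exon3=_mk("H", 24), **b7))
    b15 = dict(utr5=_mk("A", 20), exon2=_mk("H", 24), exon3=_mk("I", 24), utr3=_mk("E", 20))
    e.append(_entry("B*15:01:01:01", exon1=_mk("A", 12), exon4=_mk("A", 16), **b15))
    e.append(_entry("B*15:01:01:02N", exon1=_mk("F", 12), exon4=_mk("A", 16), **b15))
    e.append(_entry("B*15:25:01:01", exon1=_mk("A", 12), exon4=_mk("B", 16), **b15))  # outside-ARD sibling
    e.append(_entry("B*15:11:01:01", exon1=_mk("A", 12), exon4=_mk("A", 16),
                    utr5=_mk("A", 20), exon2=_mk("J", 24), exon3=_mk("I", 24),
                    utr3=_mk("E", 20)))  # differs within exon 2
    # ---- DRB4 (class II: ARD = exon 2) ----
    drb4 = dict(utr5=_mk("A", 20), exon2=_mk("B", 24), exon3=_mk("C", 20), utr3=_mk("E", 20))
    e.append(_entry("DRB4*01:03:01:01", exon1=_mk("A", 12), **drb4))
    e.append(_entry("DRB4*01:03:01:02N", exon1=_mk("G", 12), **drb4))
    e.append(_entry("DRB4*01:01:01:01", utr5=_mk("A", 20), exon1=_mk("A", 12),
                    exon2=_mk("D", 24), exon3=_mk("C", 20), utr3=_mk("E", 20)))
    # ---- DQB1 ----
    q63 = dict(utr5=_mk("A", 20), exon2=_mk("F", 24), utr3=_mk("E", 20))
    e.append(_entry("DQB1*06:03:01:01", exon1=_mk("A", 12), exon3=_mk("A", 20), **q63))
    e.append(_entry("DQB1*06:41:01:01", exon1=_mk("A", 12), exon3=_mk("B", 20), **q63))
    q64 = dict(utr5=_mk("A", 20), exon2=_mk("G", 24), utr3=_mk("E", 20))
    e.append(_entry("DQB1*06:04:01:01", exon1=_mk("A", 12), exon3=_mk("A", 20), **q64))
    e.append(_entry("DQB1*06:39:01:01", exon1=_mk("A", 12), exon3=_mk("C", 20), **q64))
    q31 = dict(exon2=_mk("H", 24), exon3=_mk("A", 20), utr3=_mk("E", 20))
    e.append(_entry("DQB1*03:01:01:01", utr5=_mk("A", 20), exon1=_mk("A", 12), **q31))
    # exon-1-deleted null: identical to DQB1*03:01 over every region it possesses
    e.append(_entry("DQB1*03:276N", **q31))
    # ---- DPB1 ----
    dp = dict(utr5=_mk("A", 20), exon1=_mk("A", 12), exon2=_mk("I", 24), utr3=_mk("E", 20))
    e.append(_entry("DPB1*03:01:01:01", exon3=_mk("A", 20), **dp))
    e.append(_entry("DPB1*104:01:01:01", exon3=_mk("B", 20), **dp))  # differs in exon 3 only
    e.append(_entry("DPB1*01:01:01:01", utr5=_mk("A", 20), exon1=_mk("A", 12),
                    exon2=_mk("J", 24), exon3=_mk("A", 20), utr3=_mk("E", 20)))
    return Catalog(e, release_label="toy-1.0", release_date=_dt.date(2022, 4, 14))


@dataclass(frozen=True)
class WorkedExample:
    slug: str
    locus: str
    reference: tuple[str, ...]
    typing: str
    excluded_nulls: str
    expected_category: str
    note: str


#: the canonical grading scenarios, each with its expected category
_EXAMPLES: tuple[WorkedExample, ...] = (
    WorkedExample(
        "null_not_excluded", "A", ("A*03:01:01:01", "A*24:02:01:01"),
        "A*03:01+A*24:02", "", "error2",
        "two-field A*03:01 subsumes the excludable null A*03:01:01:02N",
    ),
    WorkedExample(
        "null_excluded", "A", ("A*03:01:01:01", "A*24:02:01:01"),
        "A*03:01+A*24:02", "A*03:01:01:02N", "correct",
        "the same typing with the null declared excluded",
    ),
    WorkedExample(
        "null_reference_mistyped", "B", ("B*07:161N", "B*15:11:01:01"),
        "B*07:02+B*15:11", "", "error3",
        "the null reference allele reported as its expressed ARD twin",
    ),
    WorkedExample(
        "allele_ambiguity_missed", "DPB1", ("DPB1*104:01:01:01", "DPB1*01:01:01:01"),
        "DPB1*03:01+DPB1*01:01", "", "error3",
        "DPB1*03:01 alone does not cover the exon-3-distinct reference DPB1*104:01",
    ),
    WorkedExample(
        "allele_ambiguity_listed", "DPB1", ("DPB1*104:01:01:01", "DPB1*01:01:01:01"),
        "DPB1*03:01/104:01+DPB1*01:01", "", "correct",
        "the complete same-ARD-group slash list is a correct high-resolution report",
    ),
    WorkedExample(
        "mis_paired_lists", "DQB1", ("DQB1*06:03:01:01", "DQB1*06:04:01:01"),
        "DQB1*06:03/39+DQB1*06:04/41", "", "error4",
        "slash-list members paired with the wrong chromosome",
    ),
    WorkedExample(
        "one_field_typing", "A", ("A*03:01:01:01", "A*24:02:01:01"),
        "A*03+A*24:02", "A*03:01:01:02N", "error4",
        "a one-field designation is not a high-resolution result",
    ),
    WorkedExample(
        "genotype_ambiguity", "B", ("B*15:01:01:01", "B*07:02:01:01"),
        "B*15:01/15:11+B*07:02", "B*15:01:01:02N", "error1",
        "B*15:01 and B*15:11 differ within exons 2-3: unresolved genotype ambiguity",
    ),
    WorkedExample(
        "single_detection_duplicated", "DQB1", ("DQB1*03:01:01:01",),
        "DQB1*03:01+DQB1*03:01", "", "error3",
        "the allele was detected once but reported twice (no family data)",
    ),
    WorkedExample(
        "unexcludable_null_tolerated", "DQB1", ("DQB1*03:01:01:01",),
        "DQB1*03:01", "", "correct",
        "DQB1*03:276N lacks exon 1 and cannot be excluded; not excluding it is correct",
    ),
)


def worked_examples() -> tuple[WorkedExample, ...]:
    return _EXAMPLES


def example_reference(ex: WorkedExample, year: int = 2022, sample_id: str = "S-01") -> ReferenceCall:
    return ReferenceCall(
        locus=ex.locus,
        slots=tuple(parse_allele(a) for a in ex.reference),
        sample_id=sample_id,
        year=year,
    )
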