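"""Grade submitted HLA typings against the reference into the four EPT error categories.

Categories
----------
``correct``
    The submission subsumes the reference genotype, all remaining ambiguity is
    allele ambiguity (outside the ARD, or outside the -50/+500 window in
    allelic mode), and every excludable lurking null is excluded.
``error1``
    Unresolved genotype ambiguity: a reported slot (or the set of reported
    genotype alternatives) spans more than one resolution group.
``error2``
    A reported designation subsumes an excludable null allele that is neither
    the reference allele, nor separated by the reported resolution, nor
    declared excluded.
``error3``
    Typing different from the reference: wrong allele, missing or extra
    allele, an allele reported twice though detected only once, or a null
    reference reported without its N identity.
``error4``
    Structural/nomenclature faults: unknown allele names, one-field typings,
    mis-paired slash lists, incomplete allele-ambiguity lists, stale database
    release, unparseable typings.

When several defects co-occur a single category is assigned with detection
precedence error4 -> error3 -> error1 -> error2 (structural validity before
content, definite mistype before unresolved ambiguity before omitted
exclusion).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

from .catalog import Catalog, UnknownAlleleError, release_within_window
from .nomenclature import (
    AlleleName,
    GenotypeCall,
    NomenclatureError,
    parse_genotype,
    truncate,
)

__all__ = [
    "CORRECT",
    "ERROR1",
    "ERROR2",
    "ERROR3",
    "ERROR4",
    "CATEGORIES",
    "SEVERITY",
    "HIGH_RESOLUTION",
    "ALLELIC_RESOLUTION",
    "GradingError",
    "ReferenceCall",
    "GradeResult",
    "SlotMatching",
    "match_slots",
    "grade_locus",
    "grade_scheme",
]

log = logging.getLogger(__name__)

CORRECT = "correct"
ERROR1 = "error1"
ERROR2 = "error2"
ERROR3 = "error3"
ERROR4 = "error4"
CATEGORIES = (CORRECT, ERROR1, ERROR2, ERROR3, ERROR4)

#: severity used for tie-breaking slot assignments (least to most severe)
SEVERITY = {CORRECT: 0, ERROR2: 1, ERROR1: 2, ERROR3: 3, ERROR4: 4}

HIGH_RESOLUTION = "high_resolution"
ALLELIC_RESOLUTION = "allelic_resolution"


class GradingError(ValueError):
    """Hard failure while grading (locus mismatch, unknown sample, ...)."""


@dataclass(frozen=True)
class ReferenceCall:
    """The resolved truth for one sample x locus.

    Two slots mean both alleles were detected; a single slot means the allele
    was detected only once and homozygosity is unproven (no family data).
    """

    locus: str
    slots: tuple[AlleleName, ...]
    sample_id: str
    year: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.slots) <= 2:
            raise GradingError(f"reference must have 1 or 2 slots, got {len(self.slots)}")
        for a in self.slots:
            if a.locus != self.locus:
                raise GradingError(f"reference allele {a} does not match locus {self.locus}")


@dataclass(frozen=True)
class GradeResult:
    lab_id: str
    year: int
    sample_id: str
    locus: str
    category: str
    reason: str
    detail: str
    mode: str


@dataclass(frozen=True)
class SlotMatching:
    """An unordered assignment of submitted slots to reference slots."""

    pairs: tuple[tuple[int, int], ...]
    unmatched_sub: tuple[int, ...]
    unmatched_ref: tuple[int, ...]


def _candidate_pairings(n_sub: int, n_ref: int) -> list[tuple[tuple[int, int], ...]]:
    if n_sub == 1 and n_ref == 1:
        return [((0, 0),)]
    if n_sub == 2 and n_ref == 2:
        return [((0, 0), (1, 1)), ((0, 1), (1, 0))]
    if n_sub == 2 and n_ref == 1:
        return [((0, 0),), ((1, 0),)]
    return [((0, 0),), ((0, 1),)]  # 1 submitted vs 2 reference slots


def _matching_from(pairs, n_sub: int, n_ref: int) -> SlotMatching:
    used_s = {i for i, _ in pairs}
    used_r = {j for _, j in pairs}
    return SlotMatching(
        pairs=tuple(pairs),
        unmatched_sub=tuple(i for i in range(n_sub) if i not in used_s),
        unmatched_ref=tuple(j for j in range(n_ref) if j not in used_r),
    )


def _excluded_expansion(call: GenotypeCall, catalog: Catalog) -> frozenset[AlleleName]:
    out = set(call.excluded_nulls)
    for e in call.excluded_nulls:
        out.update(catalog.expand(e, missing_ok=True))
    return frozenset(out)


def _slot_expansion(slot, catalog: Catalog) -> set[AlleleName]:
    out: set[AlleleName] = set()
    for d in slot:
        out.update(catalog.expand(d, missing_ok=True))
    return out


def _two_field(name: AlleleName, catalog: Catalog) -> AlleleName:
    return truncate(name, min(2, len(name.fields)), catalog)


def _complete_expressed_designations(gid: tuple, catalog: Catalog) -> frozenset[AlleleName]:
    """Every expressed two-field designation of a resolution group."""
    return frozenset(
        _two_field(m, catalog) for m in catalog.group_members(gid) if m.suffix != "N"
    )


def _classify(
    sub: GenotypeCall,
    ref: ReferenceCall,
    catalog: Catalog,
    mode: str,
    matching: SlotMatching,
) -> tuple[str, str, str]:
    group_of = catalog.ard_group if mode == HIGH_RESOLUTION else catalog.allelic_group
    all_genotypes = (sub.slots,) + sub.genotype_alternatives

    # ---- error 4: structural and nomenclature checks -------------------------
    for slots in all_genotypes:
        for slot in slots:
            for a in slot:
                if len(a.fields) == 1:
                    return ERROR4, "one_field_typing", f"{a} is a one-field designation"
    for slots in all_genotypes:
        for slot in slots:
            for a in slot:
                try:
                    catalog.expand(a)
                except UnknownAlleleError:
                    return ERROR4, "unknown_allele", f"{a} is not in the catalogue release"

    excluded = _excluded_expansion(sub, catalog)

    def effective(slot) -> set[AlleleName]:
        return _slot_expansion(slot, catalog) - excluded

    # mis-pairing: the union of the submitted slash lists re-partitions by
    # resolution group into the correct per-slot alternative sets, but the
    # submitted slots mix groups
    if len(sub.slots) == 2 and len(ref.slots) == 2:
        g_ref = [group_of(r) for r in ref.slots]
        if g_ref[0] != g_ref[1]:
            des_group: dict[AlleleName, tuple] = {}
            unambiguous = True
            for slot in sub.slots:
                for d in slot:
                    gs = {group_of(x) for x in catalog.expand(d, missing_ok=True)}
                    if len(gs) != 1:
                        unambiguous = False
                        break
                    des_group[d] = next(iter(gs))
            if unambiguous:
                union = set(sub.slots[0]) | set(sub.slots[1])
                part = {g: frozenset(d for d in union if des_group[d] == g) for g in g_ref}
                covers = part[g_ref[0]] | part[g_ref[1]] == union
                if (
                    covers
                    and part[g_ref[0]] == _complete_expressed_designations(g_ref[0], catalog)
                    and part[g_ref[1]] == _complete_expressed_designations(g_ref[1], catalog)
                    and {frozenset(s) for s in sub.slots} != set(part.values())
                ):
                    return (
                        ERROR4,
                        "mis_paired_slash_lists",
                        "slash-list members are paired with the wrong chromosome",
                    )

    # incomplete allele-ambiguity list: a same-group slash list containing the
    # reference allele must cover every expressed two-field designation of the
    # group present in the catalogue release
    for i, j in matching.pairs:
        slot, r = sub.slots[i], ref.slots[j]
        expressed = [d for d in slot if d.suffix != "N"]
        if len(slot) < 2 or not expressed:
            continue
        try:
            r_gid = group_of(r)
        except UnknownAlleleError:
            raise GradingError(f"reference allele {r} not in catalogue") from None
        same_group = all(
            {group_of(x) for x in catalog.expand(d, missing_ok=True)} == {r_gid}
            for d in expressed
        )
        if same_group and r in _slot_expansion(slot, catalog):
            listed = frozenset(_two_field(d, catalog) for d in expressed)
            if listed != _complete_expressed_designations(r_gid, catalog):
                return (
                    ERROR4,
                    "incomplete_allele_list",
                    "slash list omits a same-group designation of the catalogue release",
                )

    # ---- error 3: content differs from the reference -------------------------
    if len(sub.slots) > len(ref.slots):
        r = ref.slots[0]
        if all(r in effective(slot) for slot in sub.slots):
            return (
                ERROR3,
                "allele_reported_twice",
                f"{r} was detected only once but reported twice",
            )
        return ERROR3, "extra_allele", "an allele absent from the reference was reported"
    if len(sub.slots) < len(ref.slots):
        missing = ref.slots[matching.unmatched_ref[0]]
        return ERROR3, "missing_allele", f"reference allele {missing} was not reported"
    for i, j in matching.pairs:
        slot, r = sub.slots[i], ref.slots[j]
        if r not in effective(slot):
            return (
                ERROR3,
                "allele_mismatch",
                f"reported {'/'.join(map(str, slot))} does not cover reference {r}",
            )
        if r.suffix == "N":
            named = any(
                d.suffix == "N" and r in catalog.expand(d, missing_ok=True) for d in slot
            )
            if not named:
                return (
                    ERROR3,
                    "null_not_reported_as_null",
                    f"reference null {r} reported without its N identity",
                )

    # ---- error 1: unresolved genotype ambiguity -------------------------------
    for slots in all_genotypes:
        for slot in slots:
            groups = {group_of(a) for a in effective(slot)}
            if len(groups) > 1:
                return (
                    ERROR1,
                    "unresolved_genotype_ambiguity",
                    f"slot {'/'.join(map(str, slot))} spans {len(groups)} resolution groups",
                )

    def group_genotype(slots) -> tuple:
        return tuple(
            sorted(tuple(sorted({group_of(a) for a in effective(slot)})) for slot in slots)
        )

    if len({group_genotype(g) for g in all_genotypes}) > 1:
        return (
            ERROR1,
            "discordant_genotype_alternatives",
            "genotype alternatives imply more than one group-level genotype",
        )

    # ---- error 2: excludable null not excluded --------------------------------
    # a null that is itself part of the reference genotype is truly present and
    # must not be "excluded"
    ref_alleles = set(ref.slots)
    lurking: set[AlleleName] = set()
    for i, j in matching.pairs:
        slot = sub.slots[i]
        for d in slot:
            for a in catalog.expand(d, missing_ok=True):
                if (
                    a.suffix == "N"
                    and a not in ref_alleles
                    and a not in excluded
                    and catalog.excludable(a)
                ):
                    lurking.add(a)
    if lurking:
        names = ", ".join(sorted(map(str, lurking)))
        return ERROR2, "null_not_excluded", f"excludable null allele(s) not excluded: {names}"

    return CORRECT, "", ""


def match_slots(
    sub: GenotypeCall, ref: ReferenceCall, catalog: Catalog, mode: str = HIGH_RESOLUTION
) -> SlotMatching:
    """Assign submitted slots to reference slots.

    Maximizes the number of slots whose expansion contains the assigned
    reference allele; ties prefer the assignment with the least severe final
    grade, then lexicographic order.
    """
    excluded = _excluded_expansion(sub, catalog)
    candidates = _candidate_pairings(len(sub.slots), len(ref.slots))
    best = None
    for idx, pairs in enumerate(candidates):
        matching = _matching_from(pairs, len(sub.slots), len(ref.slots))
        score = sum(
            ref.slots[j] in (_slot_expansion(sub.slots[i], catalog) - excluded)
            for i, j in pairs
        )
        category, _, _ = _classify(sub, ref, catalog, mode, matching)
        key = (-score, SEVERITY[category], idx)
        if best is None or key < best[0]:
            best = (key, matching)
    return best[1]


def grade_locus(
    sub: GenotypeCall,
    ref: ReferenceCall,
    catalog: Catalog,
    mode: str = HIGH_RESOLUTION,
    lab_id: str = "",
) -> GradeResult:
    """Grade one submitted locus call against the reference."""
    if sub.locus != ref.locus:
        raise GradingError(f"locus mismatch: submission {sub.locus} vs reference {ref.locus}")
    if mode not in (HIGH_RESOLUTION, ALLELIC_RESOLUTION):
        raise GradingError(f"unknown grading mode {mode!r}")
    matching = match_slots(sub, ref, catalog, mode)
    category, reason, detail = _classify(sub, ref, catalog, mode, matching)
    return GradeResult(
        lab_id=lab_id,
        year=ref.year,
        sample_id=ref.sample_id,
        locus=ref.locus,
        category=category,
        reason=reason,
        detail=detail,
        mode=mode,
    )


def grade_scheme(
    submissions,
    panel,
    catalog: Catalog,
    mode: str = HIGH_RESOLUTION,
    shipment_date: _dt.date | None = None,
    release_dates: dict[str, _dt.date] | None = None,
    strict_release: str = "error4",
) -> list[GradeResult]:
    """Batch-grade a whole scheme.

    ``submissions`` are record objects with ``lab_id``/``year``/``sample_id``/
    ``locus``/``typing``/``excluded_nulls``/``db_release``/``method``
    attributes (see :class:`hla_ept.io.SubmissionRecord`).  Typing strings
    that fail to parse are graded error4 (quarantined records).  When a
    shipment date is given, submissions citing a database release more than a
    year old are graded error4 for the whole lab-year (``strict_release=
    "error4"``) or merely logged (``"warn"``).
    """
    if strict_release not in ("error4", "warn"):
        raise GradingError(f"unknown strict_release policy {strict_release!r}")
    index: dict[tuple, ReferenceCall] = {}
    for r in panel:
        key = (r.year, r.sample_id, r.locus)
        if key in index:
            raise GradingError(f"duplicate reference entry for {key}")
        index[key] = r

    rel_dates = dict(release_dates or {})
    if catalog.release_label and catalog.release_date is not None:
        rel_dates.setdefault(catalog.release_label, catalog.release_date)

    stale: set[tuple] = set()
    if shipment_date is not None:
        for rec in submissions:
            d = rel_dates.get(rec.db_release)
            if d is not None and not release_within_window(d, shipment_date):
                stale.add((rec.lab_id, rec.year))

    results = []
    ordered = sorted(
        submissions, key=lambda r: (r.lab_id, r.year, r.sample_id, r.locus)
    )
    for rec in ordered:
        key = (rec.year, rec.sample_id, rec.locus)
        ref = index.get(key)
        if ref is None:
            raise GradingError(f"submission references unknown sample {key}")

        def fail4(reason: str, detail: str) -> GradeResult:
            return GradeResult(
                rec.lab_id, rec.year, rec.sample_id, rec.locus, ERROR4, reason, detail, mode
            )

        if (rec.lab_id, rec.year) in stale:
            if strict_release == "error4":
                results.append(
                    fail4("stale_database", f"release {rec.db_release} older than one year")
                )
                continue
            log.warning(
                "lab %s year %s used stale release %s", rec.lab_id, rec.year, rec.db_release
            )
        try:
            call = parse_genotype(
                rec.typing,
                locus=rec.locus,
                excluded_nulls_text=rec.excluded_nulls,
                db_release=rec.db_release,
                method=rec.method,
            )
        except NomenclatureError as err:
            results.append(fail4("malformed_typing", str(err)))
            continue
        if call.locus != rec.locus:
            results.append(fail4("wrong_locus", f"typing is for locus {call.locus}"))
            continue
        result = grade_locus(call, ref, catalog, mode=mode, lab_id=rec.lab_id)
        results.append(result)
    for res in results:
        if res.category != CORRECT:
            log.info(
                "%s %s %s %s: %s (%s) %s",
                res.lab_id, res.year, res.sample_id, res.locus,
                res.category, res.reason, res.detail,
            )
    return results
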