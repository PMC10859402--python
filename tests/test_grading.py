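"""The grading engine: worked scenarios, slot matching, batch grading, invariants."""

import datetime as dt

import pytest

from hla_ept.examples import example_reference, worked_examples
from hla_ept.grading import (
    ALLELIC_RESOLUTION,
    CORRECT,
    GradingError,
    ReferenceCall,
    grade_locus,
    grade_scheme,
    match_slots,
)
from hla_ept.io import SubmissionRecord
from hla_ept.nomenclature import parse_allele, parse_genotype
from hla_ept.simulate import (
    SimulationConfig,
    generate_catalog,
    generate_panel,
    generate_submissions,
)

from oracle_grader import oracle_grade


@pytest.mark.parametrize("ex", worked_examples(), ids=lambda ex: ex.slug)
def test_canonical_scenarios(toy_catalog, ex):
    call = parse_genotype(ex.typing, locus=ex.locus, excluded_nulls_text=ex.excluded_nulls)
    result = grade_locus(call, example_reference(ex), toy_catalog)
    assert result.category == ex.expected_category, ex.note


def test_correctly_paired_lists_grade_correct(toy_catalog):
    ref = ReferenceCall(
        "DQB1",
        (parse_allele("DQB1*06:03:01:01"), parse_allele("DQB1*06:04:01:01")),
        "S-01", 2022,
    )
    call = parse_genotype("DQB1*06:03/41+DQB1*06:04/39")
    assert grade_locus(call, ref, toy_catalog).category == CORRECT


def test_grading_invariant_to_slot_and_slash_order(toy_catalog):
    ref = ReferenceCall(
        "A", (parse_allele("A*03:01:01:01"), parse_allele("A*24:02:01:01")), "S-01", 2022
    )
    variants = [
        "A*03:01+A*24:02",
        "A*24:02+A*03:01",
        "HLA-A*24:02+HLA-A*03:01",
    ]
    categories = {
        grade_locus(parse_genotype(v, locus="A"), ref, toy_catalog).category
        for v in variants
    }
    assert categories == {"error2"}


def test_resolved_three_field_separates_null(toy_catalog):
    """Exclusion may be implicit: a >=3-field typing that splits off the null."""
    ref = ReferenceCall(
        "A", (parse_allele("A*03:01:01:01"), parse_allele("A*24:02:01:01")), "S-01", 2022
    )
    call = parse_genotype("A*03:01:01:01+A*24:02")
    assert grade_locus(call, ref, toy_catalog).category == CORRECT


def test_partial_same_group_list_is_error4(toy_catalog):
    """A same-group slash list containing the reference but missing another
    group member is an incomplete allele-ambiguity listing."""
    ref = ReferenceCall(
        "B", (parse_allele("B*15:01:01:01"), parse_allele("B*07:02:01:01")), "S-01", 2022
    )
    # the group of B*15:01 also holds B*15:25: a slash list that stays inside
    # the group but never mentions 15:25 is an incomplete ambiguity listing
    call = parse_genotype(
        "B*15:01/B*15:01:01:01+B*07:02", excluded_nulls_text="B*15:01:01:02N"
    )
    assert grade_locus(call, ref, toy_catalog).category == "error4"


def test_allelic_mode_is_stricter(toy_catalog):
    """An ARD-complete slash list is correct at high resolution but an
    unresolved ambiguity at allelic resolution (members differ within the
    coding sequence outside the ARD)."""
    ref = ReferenceCall(
        "B", (parse_allele("B*15:01:01:01"), parse_allele("B*07:02:01:01")), "S-01", 2022
    )
    call = parse_genotype("B*15:01/15:25+B*07:02", excluded_nulls_text="B*15:01:01:02N")
    assert grade_locus(call, ref, toy_catalog).category == CORRECT
    assert grade_locus(call, ref, toy_catalog, mode=ALLELIC_RESOLUTION).category == "error1"


def test_unknown_allele_is_error4_not_exception(toy_catalog):
    ref = ReferenceCall(
        "A", (parse_allele("A*03:01:01:01"), parse_allele("A*24:02:01:01")), "S-01", 2022
    )
    call = parse_genotype("A*97:97+A*24:02")
    res = grade_locus(call, ref, toy_catalog)
    assert (res.category, res.reason) == ("error4", "unknown_allele")


def test_locus_mismatch_is_hard_error(toy_catalog):
    ref = ReferenceCall("A", (parse_allele("A*03:01:01:01"),), "S-01", 2022)
    with pytest.raises(GradingError):
        grade_locus(parse_genotype("B*07:02"), ref, toy_catalog)


def test_match_slots_crossed_assignment(toy_catalog):
    ref = ReferenceCall(
        "A", (parse_allele("A*24:02:01:01"), parse_allele("A*03:01:01:01")), "S-01", 2022
    )
    call = parse_genotype("A*24:02+A*03:01")  # canonical order: 03:01 first
    m = match_slots(call, ref, toy_catalog)
    assigned = {(str(call.slots[i][0]), str(ref.slots[j])) for i, j in m.pairs}
    assert assigned == {("A*03:01", "A*03:01:01:01"), ("A*24:02", "A*24:02:01:01")}


def test_match_slots_two_versus_one(toy_catalog):
    ref = ReferenceCall("A", (parse_allele("A*03:01:01:01"),), "S-01", 2022)
    call = parse_genotype("A*03:01+A*24:02")
    m = match_slots(call, ref, toy_catalog)
    assert len(m.pairs) == 1 and len(m.unmatched_sub) == 1
    i, j = m.pairs[0]
    assert str(call.slots[i][0]) == "A*03:01"


def test_match_slots_agrees_with_permutation_search():
    """On random synthetic calls the chosen assignment equals exhaustive search."""
    config = SimulationConfig(seed=17, n_labs=2, error_rates=(0.1, 0.1, 0.1, 0.1))
    catalog = generate_catalog(config)
    panel = generate_panel(catalog, config)
    records, _ = generate_submissions(panel, catalog, config)
    index = {(r.year, r.sample_id, r.locus): r for r in panel}
    checked = 0
    for rec in records[:150]:
        try:
            call = parse_genotype(rec.typing, locus=rec.locus,
                                  excluded_nulls_text=rec.excluded_nulls)
        except Exception:
            continue
        ref = index[(rec.year, rec.sample_id, rec.locus)]
        m = match_slots(call, ref, catalog)
        # exhaustive: no other candidate has strictly more containment
        def contains(i, j):
            exp = set()
            for d in call.slots[i]:
                exp.update(catalog.expand(d, missing_ok=True))
            return ref.slots[j] in exp
        best_score = max(
            sum(contains(i, j) for i, j in pairs)
            for pairs in _all_pairings(len(call.slots), len(ref.slots))
        )
        assert sum(contains(i, j) for i, j in m.pairs) == best_score
        checked += 1
    assert checked >= 100


def _all_pairings(n_sub, n_ref):
    if n_sub == n_ref == 2:
        return [((0, 0), (1, 1)), ((0, 1), (1, 0))]
    if n_sub == 2:
        return [((0, 0),), ((1, 0),)]
    if n_ref == 2:
        return [((0, 0),), ((0, 1),)]
    return [((0, 0),)]


def test_identity_submissions_grade_correct(default_scheme):
    """Any submission equal to the full-resolution reference grades correct
    (expressed alleles; null references reported with their N identity)."""
    _, catalog, panel, _, _ = default_scheme
    for ref in panel[:200]:
        typing = "+".join(str(a) for a in ref.slots)
        call = parse_genotype(typing, locus=ref.locus)
        assert grade_locus(call, ref, catalog).category == CORRECT


def test_corrupting_a_correct_call_never_stays_correct(default_scheme):
    """Monotone severity: a nomenclature corruption can only hurt."""
    _, catalog, panel, _, _ = default_scheme
    for ref in panel[:50]:
        typing = "+".join(str(a) for a in ref.slots)
        corrupt = typing.replace(":", "", 1)  # glue first two fields together
        try:
            call = parse_genotype(corrupt, locus=ref.locus)
        except Exception:
            continue  # unparseable corruption quarantines to error4 downstream
        assert grade_locus(call, ref, catalog).category != CORRECT


def test_oracle_agreement_sample(small_scheme):
    """Spot-check engine vs brute-force oracle (full check in acceptance)."""
    _, catalog, panel, records, _ = small_scheme
    index = {(r.year, r.sample_id, r.locus): r for r in panel}
    for rec in records[:80]:
        try:
            call = parse_genotype(rec.typing, locus=rec.locus,
                                  excluded_nulls_text=rec.excluded_nulls)
        except Exception:
            continue
        ref = index[(rec.year, rec.sample_id, rec.locus)]
        assert grade_locus(call, ref, catalog).category == oracle_grade(call, ref, catalog)


# ---- batch grading ---------------------------------------------------------


def _records_for(panel, typing_fn, lab="L01", release="toy-1.0"):
    return [
        SubmissionRecord(lab, r.year, r.sample_id, r.locus, typing_fn(r), "", release, "NGS")
        for r in panel
    ]


def test_grade_scheme_all_identical(toy_catalog):
    panel = [
        ReferenceCall("DPB1", (parse_allele("DPB1*01:01:01:01"),
                               parse_allele("DPB1*104:01:01:01")), f"S-{i:02d}", 2022)
        for i in range(1, 13)
    ]
    recs = _records_for(panel, lambda r: "+".join(str(a) for a in r.slots))
    results = grade_scheme(recs, panel, toy_catalog)
    assert len(results) == 12 and all(r.category == CORRECT for r in results)


def test_grade_scheme_unknown_sample_is_hard_error(toy_catalog):
    panel = [ReferenceCall("A", (parse_allele("A*03:01:01:01"),), "S-01", 2022)]
    rec = SubmissionRecord("L01", 2022, "S-99", "A", "A*03:01", "", "", "NGS")
    with pytest.raises(GradingError, match="unknown sample"):
        grade_scheme([rec], panel, toy_catalog)


def test_grade_scheme_quarantines_malformed_typing(toy_catalog):
    panel = [ReferenceCall("A", (parse_allele("A*03:01:01:01"),), "S-01", 2022)]
    rec = SubmissionRecord("L01", 2022, "S-01", "A", "A03:01", "", "", "NGS")
    (res,) = grade_scheme([rec], panel, toy_catalog)
    assert (res.category, res.reason) == ("error4", "malformed_typing")


def test_stale_release_policy(toy_catalog):
    panel = [ReferenceCall("A", (parse_allele("A*03:01:01:01"),), "S-01", 2022)]
    rec = SubmissionRecord("L01", 2022, "S-01", "A", "A*03:01:01:01", "", "old-3.0", "NGS")
    dates = {"old-3.0": dt.date(2020, 1, 1)}
    (res,) = grade_scheme(
        [rec], panel, toy_catalog,
        shipment_date=dt.date(2022, 5, 31), release_dates=dates,
    )
    assert (res.category, res.reason) == ("error4", "stale_database")
    (res,) = grade_scheme(
        [rec], panel, toy_catalog,
        shipment_date=dt.date(2022, 5, 31), release_dates=dates, strict_release="warn",
    )
    assert res.category == CORRECT
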