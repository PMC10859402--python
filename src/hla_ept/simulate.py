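"""Synthetic EPT schemes: catalogues, reference panels and lab submissions with
category-labelled injected errors.

The generator emulates the structure the grading rules exercise without any
database download: every locus gets several ARD-equivalence groups, each group
two expressed two-field designations (the DPB1*03:01/104:01 allele-ambiguity
pattern), most primary designations an excludable four-field null sibling (the
A*03:01:01:02N pattern), selected loci an exon-1-deleted *unexcludable* null
(the DQB1*03:276N pattern), and one allele pair differing only beyond the
+500 nt allelic window.  Region sequences are short random strings; none of
the grouping machinery assumes biological lengths.

Error injections are built **constructively from catalogue structure** — the
generator never queries the grader — so grader output can be cross-validated
against the recorded truth labels.  Injection is exclusive per call: one
category is drawn up front; if it cannot be realized for the sample at hand
(e.g. error 2 with no lurking null) the draw is repeated from the residual
distribution and the truth label records the realized category.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .catalog import Catalog, CatalogEntry, write_catalog
from .grading import CORRECT, ERROR1, ERROR2, ERROR3, ERROR4, ReferenceCall
from .io import SubmissionRecord, write_panel, write_submissions
from .nomenclature import (
    CLASS_I_LOCI,
    AlleleName,
    format_allele,
    format_genotype,
    make_call,
    truncate,
)

__all__ = [
    "SimulationConfig",
    "InjectionTruth",
    "generate_catalog",
    "validate_generated_catalog",
    "panel_allele_frequencies",
    "generate_panel",
    "generate_submissions",
    "write_scheme",
    "write_truth",
    "read_truth",
]

DEFAULT_LOCI = ("A", "B", "C", "DRB1", "DRB4", "DQB1", "DPB1", "DQA1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated scheme.

    The defaults mirror the real exercise: 12 samples shipped per year, a
    field of a few dozen laboratories, small per-category error rates of the
    order seen in mature scheme years.
    """

    seed: int
    loci: tuple[str, ...] = DEFAULT_LOCI
    groups_per_locus: int = 6
    extra_two_field_per_group: int = 1  # ambiguity siblings besides the primary designation
    null_fraction: float = 0.8  # fraction of primary designations given an N sibling
    unexcludable_null_loci: tuple[str, ...] = ("DQB1",)
    n_samples: int = 12
    n_labs: int = 24
    years: tuple[int, ...] = (2022,)
    error_rates: tuple[float, float, float, float] = (0.02, 0.02, 0.03, 0.02)
    single_detection_fraction: float = 0.08
    null_reference_rate: float = 0.04
    method_mix: tuple[tuple[str, float], ...] = (("NGS", 0.7), ("SBT", 0.2), ("NGS/SBT", 0.1))
    release_label: str = "3.48.0"
    release_date: _dt.date = _dt.date(2022, 4, 14)
    shipment_date: _dt.date = _dt.date(2022, 5, 31)

    def __post_init__(self) -> None:
        if self.groups_per_locus < 2 or self.groups_per_locus > 90:
            raise ValueError("groups_per_locus must be between 2 and 90")
        if self.extra_two_field_per_group < 1 or self.extra_two_field_per_group > 20:
            raise ValueError("extra_two_field_per_group must be between 1 and 20")
        if any(p < 0 for p in self.error_rates) or sum(self.error_rates) > 1:
            raise ValueError("error rates must be non-negative and sum to at most 1")
        if not 0 <= self.null_fraction <= 1:
            raise ValueError("null_fraction must be in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        if not self.loci:
            raise ValueError("at least one locus required")
        if abs(sum(p for _, p in self.method_mix) - 1.0) > 1e-9:
            raise ValueError("method_mix probabilities must sum to 1")


@dataclass(frozen=True)
class InjectionTruth:
    """The realized category and perturbation injected into one call."""

    lab_id: str
    year: int
    sample_id: str
    locus: str
    intended_category: str
    perturbation: str


# ---------------------------------------------------------------------------
# catalogue generation
# ---------------------------------------------------------------------------

_REGION_LENGTHS = {"utr5": 30, "exon1": 15, "exon2": 24, "exon3": 24, "exon4": 18, "utr3": 24}


def _seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _distinct_seq(rng: np.random.Generator, n: int, taken: set[str]) -> str:
    while True:
        s = _seq(rng, n)
        if s not in taken:
            taken.add(s)
            return s


def generate_catalog(config: SimulationConfig) -> Catalog:
    """Build a deterministic toy catalogue with the structures grading needs."""
    rng = np.random.default_rng([config.seed, 1])
    entries: list[CatalogEntry] = []
    for locus in config.loci:
        is_class_i = locus in CLASS_I_LOCI
        ard_labels = ("exon2", "exon3") if is_class_i else ("exon2",)
        nonard_exons = ("exon1", "exon4") if is_class_i else ("exon1", "exon3")
        seen_ard: set[str] = set()
        for g in range(1, config.groups_per_locus + 1):
            ff = f"{g:02d}"
            ard = {r: None for r in ard_labels}
            # ARD sequences distinct across groups (genotype-ambiguity material)
            joined = _distinct_seq(rng, sum(_REGION_LENGTHS[r] for r in ard_labels), seen_ard)
            off = 0
            for r in ard_labels:
                ard[r] = joined[off : off + _REGION_LENGTHS[r]]
                off += _REGION_LENGTHS[r]
            exon1_taken: set[str] = set()
            base = {r: ard[r] for r in ard_labels}
            base["utr5"] = _seq(rng, _REGION_LENGTHS["utr5"])
            base["utr3"] = (
                _seq(rng, 510) if g == 2 else _seq(rng, _REGION_LENGTHS["utr3"])
            )
            for r in nonard_exons:
                base[r] = (
                    _distinct_seq(rng, _REGION_LENGTHS[r], exon1_taken)
                    if r == "exon1"
                    else _seq(rng, _REGION_LENGTHS[r])
                )
            primary = AlleleName(locus, (ff, "01", "01", "01"))
            entries.append(CatalogEntry(primary, dict(base)))
            # allele-ambiguity siblings: same ARD, different exon 1
            sibling_regions = []
            for k in range(config.extra_two_field_per_group):
                sib = dict(base)
                sib["exon1"] = _distinct_seq(rng, _REGION_LENGTHS["exon1"], exon1_taken)
                entries.append(
                    CatalogEntry(AlleleName(locus, (ff, f"{31 + k}", "01", "01")), sib)
                )
                sibling_regions.append((f"{31 + k}", sib))
            # excludable null siblings: each two-field designation carries one
            # with probability null_fraction (forced for the first primary so
            # every locus has at least one)
            for second, template in [("01", base)] + sibling_regions:
                if (g == 1 and second == "01") or rng.random() < config.null_fraction:
                    nreg = dict(template)
                    nreg["exon1"] = _distinct_seq(rng, _REGION_LENGTHS["exon1"], exon1_taken)
                    entries.append(
                        CatalogEntry(AlleleName(locus, (ff, second, "01", "02"), "N"), nreg)
                    )
            if g == 2:
                # pair differing only beyond the +500 window
                wreg = dict(base)
                wreg["utr3"] = base["utr3"][:500] + _seq(rng, 10)
                entries.append(
                    CatalogEntry(AlleleName(locus, (ff, "01", "01", "03")), wreg)
                )
            if g == 1 and locus in config.unexcludable_null_loci:
                # exon-1-deleted null, sequence-identical to the primary from exon 2 on
                ureg = {r: s for r, s in base.items() if r not in ("utr5", "exon1")}
                entries.append(CatalogEntry(AlleleName(locus, (ff, "76"), "N"), ureg))
    return Catalog(
        entries,
        release_label=config.release_label,
        release_date=config.release_date,
    )


def validate_generated_catalog(catalog: Catalog, config: SimulationConfig) -> None:
    """Assert the structural postconditions of :func:`generate_catalog`."""
    for locus in config.loci:
        groups: dict[tuple, list[AlleleName]] = {}
        for a in catalog.alleles(locus):
            groups.setdefault(catalog.ard_group(a), []).append(a)
        if len(groups) < 2:
            raise AssertionError(f"{locus}: fewer than two ARD groups")
        if not any(
            len({truncate(m, 2, catalog) for m in members if m.suffix != "N"}) >= 2
            for members in groups.values()
        ):
            raise AssertionError(f"{locus}: no group with two expressed two-field designations")
        nulls = [r for a in catalog.alleles(locus) if a.suffix == "N"
                 for r in catalog.nulls_under(a)]
        if not any(r.excludable for r in nulls):
            raise AssertionError(f"{locus}: no excludable null")
        if locus in config.unexcludable_null_loci and not any(
            not r.excludable for r in nulls
        ):
            raise AssertionError(f"{locus}: missing unexcludable null")
        window_pair = False
        for members in groups.values():
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    ea, eb = catalog.lookup(a), catalog.lookup(b)
                    if (
                        catalog.allelic_group(a) == catalog.allelic_group(b)
                        and ea.regions != eb.regions
                    ):
                        window_pair = True
        if not window_pair:
            raise AssertionError(f"{locus}: no pair differing only outside the allelic window")


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------

def panel_allele_frequencies(catalog: Catalog, locus: str) -> dict[AlleleName, float]:
    """Geometric population frequencies over the expressed alleles of a locus."""
    expressed = sorted(
        (a for a in catalog.alleles(locus) if a.suffix != "N"), key=lambda a: a.sort_key
    )
    weights = np.array([0.7**i for i in range(len(expressed))])
    weights /= weights.sum()
    return dict(zip(expressed, weights))


def generate_panel(catalog: Catalog, config: SimulationConfig) -> list[ReferenceCall]:
    """Draw the yearly reference panels (12 samples/year by default)."""
    rng = np.random.default_rng([config.seed, 2])
    refs: list[ReferenceCall] = []
    freq = {locus: panel_allele_frequencies(catalog, locus) for locus in config.loci}
    nulls = {
        locus: sorted(
            (a for a in catalog.alleles(locus) if a.suffix == "N" and len(a.fields) == 4),
            key=lambda a: a.sort_key,
        )
        for locus in config.loci
    }
    for year in config.years:
        for i in range(1, config.n_samples + 1):
            sample_id = f"{year}-{i:02d}"
            for locus in config.loci:
                names = list(freq[locus])
                probs = np.array([freq[locus][a] for a in names])

                def draw() -> AlleleName:
                    if nulls[locus] and rng.random() < config.null_reference_rate:
                        return nulls[locus][rng.integers(len(nulls[locus]))]
                    return names[rng.choice(len(names), p=probs)]

                a1, a2 = draw(), draw()
                if a1 == a2 or rng.random() < config.single_detection_fraction:
                    slots: tuple[AlleleName, ...] = (a1,)
                else:
                    slots = tuple(sorted((a1, a2), key=lambda a: a.sort_key))
                refs.append(ReferenceCall(locus, slots, sample_id, year))
    return refs


# ---------------------------------------------------------------------------
# submission generation with constructive injections
# ---------------------------------------------------------------------------

class _SchemeBuilder:
    def __init__(self, catalog: Catalog, config: SimulationConfig, rng: np.random.Generator):
        self.catalog = catalog
        self.config = config
        self.rng = rng
        self.expressed: dict[str, list[AlleleName]] = {}
        self.groups: dict[str, dict[tuple, list[AlleleName]]] = {}
        for locus in config.loci:
            self.expressed[locus] = sorted(
                (a for a in catalog.alleles(locus) if a.suffix != "N"),
                key=lambda a: a.sort_key,
            )
            by_gid: dict[tuple, set[AlleleName]] = {}
            for a in self.expressed[locus]:
                by_gid.setdefault(catalog.ard_group(a), set()).add(truncate(a, 2, catalog))
            self.groups[locus] = {
                gid: sorted(des, key=lambda a: a.sort_key) for gid, des in by_gid.items()
            }

    # -- faithful constructions ----------------------------------------------

    def _lurking(self, designation: AlleleName, ref: ReferenceCall) -> set[AlleleName]:
        # nulls that are part of the reference genotype are truly present and
        # need no exclusion
        return {
            a
            for a in self.catalog.expand(designation, missing_ok=True)
            if a.suffix == "N" and a not in ref.slots and self.catalog.excludable(a)
        }

    def faithful_slot(self, r: AlleleName, ref: ReferenceCall, style: str | None = None):
        """A slot guaranteed to grade correct, plus the exclusions it needs."""
        if r.suffix == "N":
            return [r], set(), "full_null"
        if style is None:
            style = ["full", "twofield", "slashlist"][
                self.rng.choice(3, p=[0.35, 0.45, 0.2])
            ]
        if style == "full":
            return [r], set(), style
        if style == "twofield":
            d = truncate(r, 2, self.catalog)
            return [d], self._lurking(d, ref), style
        listed = self.groups[r.locus][self.catalog.ard_group(r)]
        excl: set[AlleleName] = set()
        for d in listed:
            excl |= self._lurking(d, ref)
        return list(listed), excl, style

    # -- per-category builders: return (slots, exclusions, desc) or None ------

    def build_correct(self, ref: ReferenceCall):
        slots, excl, styles = [], set(), []
        for r in ref.slots:
            alts, e, style = self.faithful_slot(r, ref)
            slots.append(alts)
            excl |= e
            styles.append(style)
        return slots, excl, "correct:" + "+".join(styles)

    def build_error1(self, ref: ReferenceCall):
        target = int(self.rng.integers(len(ref.slots)))
        r = ref.slots[target]
        own = self.catalog.ard_group(r)
        foreign_gids = [g for g in self.groups[ref.locus] if g != own]
        if not foreign_gids:
            return None
        gid = foreign_gids[int(self.rng.integers(len(foreign_gids)))]
        foreign_des = self.groups[ref.locus][gid]
        if self.rng.random() < 0.5:
            # slash list spanning two ARD groups
            head = truncate(r, 2, self.catalog) if r.suffix != "N" else r
            alien = foreign_des[int(self.rng.integers(len(foreign_des)))]
            slots = []
            for i, rr in enumerate(ref.slots):
                if i == target:
                    slots.append([head, alien])
                else:
                    alts, _, _ = self.faithful_slot(rr, ref)
                    slots.append(alts)
            return slots, set(), "error1:slash_span"
        # genotype alternative implying a second group-level genotype
        primary = [[rr] for rr in ref.slots]
        alien_full = min(
            (a for a in self.expressed[ref.locus] if self.catalog.ard_group(a) == gid),
            key=lambda a: a.sort_key,
        )
        alternative = [list(s) for s in primary]
        alternative[target] = [alien_full]
        return (primary, set(), "error1:genotype_alternative", [alternative])

    def build_error2(self, ref: ReferenceCall):
        applicable = [
            i
            for i, r in enumerate(ref.slots)
            if r.suffix != "N" and self._lurking(truncate(r, 2, self.catalog), ref)
        ]
        if not applicable:
            return None
        target = applicable[int(self.rng.integers(len(applicable)))]
        slots, omitted = [], set()
        for i, r in enumerate(ref.slots):
            if i == target:
                d = truncate(r, 2, self.catalog)
                slots.append([d])
                omitted = self._lurking(d, ref)
            else:
                # plain full-resolution here so no exclusion list is needed at
                # all and the omitted null stays unexcluded
                alts, _, _ = self.faithful_slot(r, ref, style="full")
                slots.append(alts)
        names = "/".join(sorted(map(str, omitted)))
        return slots, set(), f"error2:unexcluded:{names}"

    def build_error3(self, ref: ReferenceCall):
        variants = ["swap", "drop"] if len(ref.slots) == 2 else ["swap", "extra", "duplicate"]
        variant = variants[int(self.rng.integers(len(variants)))]
        if variant == "swap":
            target = int(self.rng.integers(len(ref.slots)))
            r = ref.slots[target]
            r2f = truncate(r, min(2, len(r.fields)), self.catalog)
            pool = [
                a
                for a in self.expressed[ref.locus]
                if truncate(a, 2, self.catalog) != AlleleName(r2f.locus, r2f.fields)
            ]
            wrong = pool[int(self.rng.integers(len(pool)))]
            rep = [wrong] if self.rng.random() < 0.5 else [truncate(wrong, 2, self.catalog)]
            slots = []
            for i, rr in enumerate(ref.slots):
                if i == target:
                    slots.append(rep)
                else:
                    alts, _, _ = self.faithful_slot(rr, ref, style="full")
                    slots.append(alts)
            return slots, set(), "error3:swap"
        if variant == "drop":
            keep = int(self.rng.integers(2))
            alts, excl, _ = self.faithful_slot(ref.slots[keep], ref)
            return [alts], excl, "error3:missing_allele"
        if variant == "extra":
            r = ref.slots[0]
            r2f_fields = truncate(r, min(2, len(r.fields)), self.catalog).fields
            pool = [
                a
                for a in self.expressed[ref.locus]
                if truncate(a, 2, self.catalog).fields != r2f_fields
            ]
            extra = pool[int(self.rng.integers(len(pool)))]
            alts, excl, _ = self.faithful_slot(r, ref)
            return [alts, [extra]], excl, "error3:extra_allele"
        return [[ref.slots[0]], [ref.slots[0]]], set(), "error3:reported_twice"

    def build_error4(self, ref: ReferenceCall):
        variants = ["one_field", "corrupt"]
        gids = [self.catalog.ard_group(r) for r in ref.slots]
        if len(ref.slots) == 2 and gids[0] != gids[1]:
            variants.append("mispair")
        variant = variants[int(self.rng.integers(len(variants)))]
        if variant == "one_field":
            target = int(self.rng.integers(len(ref.slots)))
            slots = []
            for i, r in enumerate(ref.slots):
                if i == target:
                    slots.append([AlleleName(ref.locus, (r.fields[0],))])
                else:
                    alts, _, _ = self.faithful_slot(r, ref, style="full")
                    slots.append(alts)
            return slots, set(), "error4:one_field"
        if variant == "mispair":
            c1 = list(self.groups[ref.locus][gids[0]])
            c2 = list(self.groups[ref.locus][gids[1]])
            x1, x2 = c1[-1], c2[-1]
            s1 = [d for d in c1 if d != x1] + [x2]
            s2 = [d for d in c2 if d != x2] + [x1]
            return [s1, s2], set(), "error4:mis_paired_lists"
        if self.rng.random() < 0.5:
            # drop the asterisks: unparseable, quarantined at grading
            typing = "+".join(format_allele(r).replace("*", "") for r in ref.slots)
            return ("raw", typing, "", "error4:malformed")
        slots = []
        target = int(self.rng.integers(len(ref.slots)))
        for i, r in enumerate(ref.slots):
            if i == target:
                slots.append([AlleleName(ref.locus, ("97", "97"))])
            else:
                alts, _, _ = self.faithful_slot(r, ref, style="full")
                slots.append(alts)
        return slots, set(), "error4:unknown_allele"


def generate_submissions(
    panel, catalog: Catalog, config: SimulationConfig
) -> tuple[list[SubmissionRecord], list[InjectionTruth]]:
    """Emit one submission per lab x sample x locus, with truth labels.

    Returns flat :class:`~hla_ept.io.SubmissionRecord` rows (raw typing
    strings, so nomenclature corruptions are representable) alongside the
    injection truth for parameter-recovery and cross-validation tests.
    """
    rng = np.random.default_rng([config.seed, 3])
    builder = _SchemeBuilder(catalog, config, rng)
    labs = [f"L{i:02d}" for i in range(1, config.n_labs + 1)]
    methods = [m for m, _ in config.method_mix]
    method_p = np.array([p for _, p in config.method_mix])
    p1, p2, p3, p4 = config.error_rates
    base_probs = {
        ERROR1: p1, ERROR2: p2, ERROR3: p3, ERROR4: p4, CORRECT: 1.0 - (p1 + p2 + p3 + p4),
    }
    builders = {
        ERROR1: builder.build_error1,
        ERROR2: builder.build_error2,
        ERROR3: builder.build_error3,
        ERROR4: builder.build_error4,
        CORRECT: builder.build_correct,
    }
    panel_sorted = sorted(panel, key=lambda r: (r.year, r.sample_id, r.locus))
    records: list[SubmissionRecord] = []
    truths: list[InjectionTruth] = []
    for lab in labs:
        lab_methods = {
            year: methods[rng.choice(len(methods), p=method_p)] for year in config.years
        }
        for ref in panel_sorted:
            remaining = dict(base_probs)
            while True:
                cats = list(remaining)
                probs = np.array([remaining[c] for c in cats])
                total = probs.sum()
                if total <= 0:
                    category, built = CORRECT, builders[CORRECT](ref)
                    break
                category = cats[rng.choice(len(cats), p=probs / total)]
                built = builders[category](ref)
                if built is not None:
                    break
                del remaining[category]
            if built[0] == "raw":
                _, typing, excluded_text, desc = built
            else:
                if len(built) == 4:
                    slots, excl, desc, alternatives = built
                else:
                    slots, excl, desc = built
                    alternatives = []
                call = make_call(
                    ref.locus, slots, genotype_alternatives=alternatives,
                    excluded_nulls=frozenset(excl),
                )
                typing = format_genotype(call)
                excluded_text = ",".join(sorted(map(format_allele, excl)))
            records.append(
                SubmissionRecord(
                    lab_id=lab,
                    year=ref.year,
                    sample_id=ref.sample_id,
                    locus=ref.locus,
                    typing=typing,
                    excluded_nulls=excluded_text,
                    db_release=config.release_label,
                    method=lab_methods[ref.year],
                )
            )
            truths.append(
                InjectionTruth(lab, ref.year, ref.sample_id, ref.locus, category, desc)
            )
    return records, truths


# ---------------------------------------------------------------------------
# scheme files
# ---------------------------------------------------------------------------

_TRUTH_HEADER = ["lab_id", "year", "sample_id", "locus", "intended_category", "perturbation"]


def write_truth(truths, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TRUTH_HEADER)
        for t in truths:
            w.writerow(
                [t.lab_id, t.year, t.sample_id, t.locus, t.intended_category, t.perturbation]
            )


def read_truth(path) -> list[InjectionTruth]:
    import csv

    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if [h.strip() for h in header] != _TRUTH_HEADER:
            raise ValueError(f"{path}: unexpected truth header {header}")
        for row in reader:
            if not any(c.strip() for c in row):
                continue
            lab, year_s, sample, locus, category, desc = row
            out.append(InjectionTruth(lab, int(year_s), sample, locus, category, desc))
    return out


def write_scheme(outdir, config: SimulationConfig):
    """Generate and write a complete scheme (catalogue, panel, submissions, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = generate_catalog(config)
    panel = generate_panel(catalog, config)
    records, truths = generate_submissions(panel, catalog, config)
    write_catalog(catalog, outdir / "catalog.csv")
    write_panel(panel, outdir / "panel.tsv")
    write_submissions(records, outdir / "submissions.tsv")
    write_truth(truths, outdir / "truth.tsv")
    return catalog, panel, records, truths
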