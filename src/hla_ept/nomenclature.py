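"""WHO-style HLA allele nomenclature: parsing, validation and canonical formatting.

An allele designation is ``LOCUS*f1:f2[:f3[:f4]][X]`` where the colon-separated
fields are fixed-width digit strings and ``X`` is an optional expression suffix
(``N`` null, ``L`` low, ``S`` secreted, ``Q`` questionable, ``A``/``C``
aberrant/cytoplasmic).  Genotypes use a GL-string-like dialect:

* ``/``  separates allele alternatives within one chromosomal slot,
* ``+``  separates the (at most two) slots of a genotype,
* ``|``  separates whole-genotype alternatives.

Slash alternatives may be written in shorthand, inheriting the locus and any
leading fields from the head of the list: ``DQB1*06:03/41`` denotes
``{DQB1*06:03, DQB1*06:41}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

__all__ = [
    "KNOWN_LOCI",
    "CLASS_I_LOCI",
    "CLASS_II_LOCI",
    "EXPRESSION_SUFFIXES",
    "NomenclatureError",
    "AlleleName",
    "GenotypeCall",
    "parse_allele",
    "parse_genotype",
    "format_allele",
    "format_genotype",
    "make_call",
    "truncate",
]

KNOWN_LOCI: tuple[str, ...] = (
    "A", "B", "C",
    "DRB1", "DRB3", "DRB4", "DRB5",
    "DQB1", "DQA1", "DPB1", "DPA1",
)
CLASS_I_LOCI = frozenset({"A", "B", "C"})
CLASS_II_LOCI = frozenset(KNOWN_LOCI) - CLASS_I_LOCI

EXPRESSION_SUFFIXES = frozenset("NLSQAC")

#: bare "3*"/"4*"/"5*" prefixes seen on DRB3/4/5 submission forms
_DRB_SHORT = {"3": "DRB3", "4": "DRB4", "5": "DRB5"}


class NomenclatureError(ValueError):
    """Raised for malformed allele designations or genotype strings."""


@dataclass(frozen=True)
class AlleleName:
    """A parsed HLA allele designation.

    ``fields`` keeps the digit tokens exactly as written (zero padding is
    significant: field tokens compare as strings, never as integers).  ``raw``
    preserves the original input text and does not take part in equality.
    """

    locus: str
    fields: tuple[str, ...]
    suffix: str = ""
    raw: str = _field(default="", compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.fields or len(self.fields) > 4:
            raise NomenclatureError(
                f"allele must have 1-4 fields, got {len(self.fields)} in {self.describe()!r}"
            )
        for tok in self.fields:
            if not tok.isdigit() or len(tok) < 2:
                raise NomenclatureError(f"bad field token {tok!r} in {self.describe()!r}")
        if self.suffix and self.suffix not in EXPRESSION_SUFFIXES:
            raise NomenclatureError(f"unknown expression suffix {self.suffix!r}")

    def describe(self) -> str:
        return f"{self.locus}*{':'.join(self.fields)}{self.suffix}"

    def __str__(self) -> str:  # canonical text
        return self.describe()

    @property
    def sort_key(self) -> tuple:
        # fields ordered numerically (ascending field order), suffix last
        return (self.locus, tuple(int(f) for f in self.fields), self.suffix)

    def __lt__(self, other: "AlleleName") -> bool:
        return self.sort_key < other.sort_key


@dataclass(frozen=True)
class GenotypeCall:
    """A submitted per-locus typing.

    ``slots`` holds one or two slot entries, each an ordered tuple of
    slash-alternatives.  ``genotype_alternatives`` holds additional
    whole-genotype readings ("|" dialect).  ``excluded_nulls`` are the
    N-suffixed alleles the laboratory explicitly declared excluded.
    """

    locus: str
    slots: tuple[tuple[AlleleName, ...], ...]
    genotype_alternatives: tuple[tuple[tuple[AlleleName, ...], ...], ...] = ()
    excluded_nulls: frozenset[AlleleName] = frozenset()
    db_release: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.slots) <= 2:
            raise NomenclatureError(f"genotype must have 1 or 2 slots, got {len(self.slots)}")
        for slots in (self.slots,) + self.genotype_alternatives:
            for slot in slots:
                if not slot:
                    raise NomenclatureError("empty slot")
                for a in slot:
                    if a.locus != self.locus:
                        raise NomenclatureError(
                            f"mixed loci in one call: {a} vs locus {self.locus}"
                        )
        for a in self.excluded_nulls:
            if a.suffix != "N":
                raise NomenclatureError(f"excluded allele {a} does not carry suffix N")

    def all_alleles(self):
        """Every allele in every slot of every genotype reading."""
        for slots in (self.slots,) + self.genotype_alternatives:
            for slot in slots:
                yield from slot


def _normalize_locus(locus: str) -> str:
    up = locus.strip().upper()
    if up in _DRB_SHORT:
        up = _DRB_SHORT[up]
    if up not in KNOWN_LOCI:
        raise NomenclatureError(f"unknown locus {locus!r}")
    return up


def _parse_fields(body: str, original: str) -> tuple[tuple[str, ...], str]:
    if not body:
        raise NomenclatureError(f"empty allele designation in {original!r}")
    tokens = body.split(":")
    suffix = ""
    last = tokens[-1]
    if last and last[-1].isalpha():
        suffix = last[-1].upper()
        if suffix not in EXPRESSION_SUFFIXES:
            raise NomenclatureError(
                f"unknown expression suffix {last[-1]!r} in {original!r}"
            )
        tokens[-1] = last[:-1]
    fields = []
    for tok in tokens:
        if not tok or not tok.isdigit():
            raise NomenclatureError(f"malformed field token {tok!r} in {original!r}")
        # normalize single-digit fields by left-padding (fixed-width nomenclature)
        fields.append(tok.zfill(2) if len(tok) < 2 else tok)
    if len(fields) > 4:
        raise NomenclatureError(f"more than 4 fields in {original!r}")
    return tuple(fields), suffix


def parse_allele(text: str, locus_context: str | None = None) -> AlleleName:
    """Parse one allele designation.

    ``HLA-`` prefixes are accepted and stripped, ``3*``/``4*``/``5*`` map to
    DRB3/DRB4/DRB5, and a bare ``*xx:yy`` is resolved through
    ``locus_context``.
    """
    s = text.strip()
    if not s:
        raise NomenclatureError("empty allele designation")
    if s[:4].upper() == "HLA-":
        s = s[4:]
    if "*" not in s:
        raise NomenclatureError(f"missing '*' separator in {text!r}")
    prefix, _, body = s.partition("*")
    prefix = prefix.strip()
    if prefix == "":
        if locus_context is None:
            raise NomenclatureError(f"bare designation {text!r} needs a locus context")
        locus = _normalize_locus(locus_context)
    else:
        locus = _normalize_locus(prefix)
    fields, suffix = _parse_fields(body.strip(), text)
    return AlleleName(locus, fields, suffix, raw=text)


def _expand_shorthand(token: str, head: AlleleName, original: str) -> AlleleName:
    """Resolve a locus-less slash alternative against the list head.

    A shorthand with *k* trailing fields replaces the last *k* fields of the
    head: ``06:03/41`` -> 06:41; ``15:01/15:25`` -> 15:25.
    """
    fields, suffix = _parse_fields(token, original)
    if len(fields) > len(head.fields):
        raise NomenclatureError(
            f"shorthand {token!r} has more fields than list head {head} in {original!r}"
        )
    merged = head.fields[: len(head.fields) - len(fields)] + fields
    return AlleleName(head.locus, merged, suffix, raw=token)


def _parse_slot(text: str, locus: str | None, original: str) -> tuple[AlleleName, ...]:
    tokens = [t.strip() for t in text.split("/")]
    if any(not t for t in tokens):
        raise NomenclatureError(f"empty slash alternative in {original!r}")
    head = parse_allele(tokens[0], locus)
    alleles = [head]
    for tok in tokens[1:]:
        if "*" in tok or tok[:4].upper() == "HLA-":
            a = parse_allele(tok, head.locus)
        else:
            a = _expand_shorthand(tok, head, original)
        if a.locus != head.locus:
            raise NomenclatureError(f"mixed loci within one slot in {original!r}")
        alleles.append(a)
    # canonical: sorted, duplicates collapsed
    return tuple(sorted(set(alleles), key=lambda a: a.sort_key))


def _parse_single_genotype(
    text: str, locus: str | None, original: str
) -> tuple[tuple[AlleleName, ...], ...]:
    slot_texts = [s.strip() for s in text.split("+")]
    if any(not s for s in slot_texts):
        raise NomenclatureError(f"empty slot in {original!r}")
    if len(slot_texts) > 2:
        raise NomenclatureError(f"more than two slots in {original!r}")
    slots = [_parse_slot(s, locus, original) for s in slot_texts]
    loci = {a.locus for slot in slots for a in slot}
    if len(loci) > 1:
        raise NomenclatureError(f"mixed loci in one genotype in {original!r}")
    return tuple(sorted(slots, key=lambda slot: slot[0].sort_key))


def _parse_excluded(text: str, locus: str | None) -> frozenset[AlleleName]:
    text = text.strip()
    if not text or text == "-":
        return frozenset()
    out = set()
    for tok in text.replace(";", ",").split(","):
        tok = tok.strip()
        if not tok:
            continue
        a = parse_allele(tok, locus)
        if a.suffix != "N":
            raise NomenclatureError(f"malformed null in exclusion list: {tok!r}")
        out.add(a)
    return frozenset(out)


def parse_genotype(
    text: str,
    locus: str | None = None,
    excluded_nulls_text: str = "",
    db_release: str = "",
    method: str = "",
) -> GenotypeCall:
    """Parse a full GL-style typing string into a canonical :class:`GenotypeCall`."""
    if not text or not text.strip():
        raise NomenclatureError("empty typing string")
    geno_texts = [g.strip() for g in text.split("|")]
    if any(not g for g in geno_texts):
        raise NomenclatureError(f"empty genotype alternative in {text!r}")
    genotypes = [_parse_single_genotype(g, locus, text) for g in geno_texts]
    call_locus = genotypes[0][0][0].locus
    for g in genotypes[1:]:
        if g[0][0].locus != call_locus:
            raise NomenclatureError(f"mixed loci across genotype alternatives in {text!r}")
    excluded = _parse_excluded(excluded_nulls_text, call_locus)
    return GenotypeCall(
        locus=call_locus,
        slots=genotypes[0],
        genotype_alternatives=tuple(genotypes[1:]),
        excluded_nulls=excluded,
        db_release=db_release,
        method=method,
    )


def make_call(
    locus: str,
    slots,
    genotype_alternatives=(),
    excluded_nulls=frozenset(),
    db_release: str = "",
    method: str = "",
) -> GenotypeCall:
    """Build a canonical GenotypeCall from unsorted slot lists."""

    def canon(slot_list):
        return tuple(
            sorted(
                (tuple(sorted(set(s), key=lambda a: a.sort_key)) for s in slot_list),
                key=lambda slot: slot[0].sort_key,
            )
        )

    return GenotypeCall(
        locus=locus,
        slots=canon(slots),
        genotype_alternatives=tuple(canon(g) for g in genotype_alternatives),
        excluded_nulls=frozenset(excluded_nulls),
        db_release=db_release,
        method=method,
    )


def format_allele(name: AlleleName) -> str:
    return name.describe()


def _format_slot(slot: tuple[AlleleName, ...]) -> str:
    head = slot[0]
    parts = [format_allele(head)]
    for a in slot[1:]:
        if len(a.fields) == len(head.fields):
            j = 0
            while j < len(a.fields) - 1 and a.fields[j] == head.fields[j]:
                j += 1
            parts.append(":".join(a.fields[j:]) + a.suffix)
        else:
            parts.append(format_allele(a))
    return "/".join(parts)


def format_genotype(call: GenotypeCall) -> str:
    """Deterministic canonical text: slots sorted by first allele, slash lists
    ascending, locus prefix on slot heads only, shorthand for shared leading
    fields."""
    out = "+".join(_format_slot(s) for s in call.slots)
    for alt in call.genotype_alternatives:
        out += "|" + "+".join(_format_slot(s) for s in alt)
    return out


def truncate(name: AlleleName, n_fields: int, catalog) -> AlleleName:
    """Truncate a designation to its first ``n_fields`` fields.

    The expression suffix is retained only when, in the catalogue, every
    allele under the truncated designation shares it (e.g. a null whose N
    already lives at field two); otherwise it is dropped because expressed
    siblings hide under the shorter designation.
    """
    if not 1 <= n_fields <= len(name.fields):
        raise NomenclatureError(
            f"cannot truncate {name} to {n_fields} fields (has {len(name.fields)})"
        )
    if n_fields == len(name.fields):
        return AlleleName(name.locus, name.fields, name.suffix)
    fields = name.fields[:n_fields]
    if not name.suffix:
        return AlleleName(name.locus, fields)
    kin = catalog.expand(AlleleName(name.locus, fields), missing_ok=True)
    if kin and not all(a.suffix == name.suffix for a in kin):
        return AlleleName(name.locus, fields)
    return AlleleName(name.locus, fields, name.suffix)
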