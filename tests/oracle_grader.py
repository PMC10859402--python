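"""Brute-force reference grader used as an independent oracle in tests.

Re-derives every grading decision from raw catalogue region strings by full
enumeration: no precomputed groups, no expansion caches, no shared helpers
with the engine.  Ambiguity groups are rebuilt on every call by pairwise
sequence comparison plus breadth-first transitive closure; designation
expansion is a linear scan.  Deliberately slow and simple.
"""

from __future__ import annotations

from hla_ept.nomenclature import AlleleName, GenotypeCall

_SEVERITY = {"correct": 0, "error2": 1, "error1": 2, "error3": 3, "error4": 4}


def _entries(catalog, locus):
    return sorted(
        (e for e in catalog.entries.values() if e.name.locus == locus),
        key=lambda e: e.name.sort_key,
    )


def _scan(catalog, name: AlleleName) -> list[AlleleName]:
    k = len(name.fields)
    out = []
    for e in _entries(catalog, name.locus):
        if e.name.fields[:k] != name.fields:
            continue
        if name.suffix and e.name.suffix != name.suffix:
            continue
        out.append(e.name)
    return out


def _ard_same(catalog, e1, e2) -> bool:
    labels = ("exon2", "exon3") if catalog.locus_class(e1.name.locus) == "I" else ("exon2",)
    return all(e1.regions.get(r) == e2.regions.get(r) for r in labels)


def _window_same(catalog, e1, e2) -> bool:
    lo, hi = catalog.allelic_window
    inner1 = {r: s for r, s in e1.regions.items() if r not in ("utr5", "utr3")}
    inner2 = {r: s for r, s in e2.regions.items() if r not in ("utr5", "utr3")}
    if inner1 != inner2:
        return False
    a, b = e1.regions.get("utr5", "")[lo:], e2.regions.get("utr5", "")[lo:]
    if not (a.endswith(b) or b.endswith(a)):
        return False
    a, b = e1.regions.get("utr3", "")[:hi], e2.regions.get("utr3", "")[:hi]
    return a.startswith(b) or b.startswith(a)


def group_partition(catalog, locus, mode) -> list[set[str]]:
    """Partition a locus into resolution groups by pairwise comparison + BFS closure."""
    same = _ard_same if mode == "high_resolution" else _window_same
    members = _entries(catalog, locus)
    unassigned = list(range(len(members)))
    parts: list[set[str]] = []
    while unassigned:
        seed = unassigned.pop(0)
        component = {seed}
        frontier = [seed]
        while frontier:
            i = frontier.pop()
            for j in list(unassigned):
                if same(catalog, members[i], members[j]):
                    unassigned.remove(j)
                    component.add(j)
                    frontier.append(j)
        parts.append({str(members[i].name) for i in component})
    return parts


def _group_index(catalog, locus, mode) -> dict[str, int]:
    out = {}
    for gi, part in enumerate(group_partition(catalog, locus, mode)):
        for key in part:
            out[key] = gi
    return out


def _two_field(catalog, name: AlleleName) -> AlleleName:
    if len(name.fields) <= 2:
        return name
    short = AlleleName(name.locus, name.fields[:2])
    if name.suffix:
        kin = _scan(catalog, short)
        if kin and all(a.suffix == name.suffix for a in kin):
            return AlleleName(name.locus, name.fields[:2], name.suffix)
    return short


def _excludable(catalog, null_name: AlleleName) -> bool:
    ne = catalog.entries[str(null_name)]
    for e in _entries(catalog, null_name.locus):
        if e.name.suffix == "N":
            continue
        if all(r in e.regions and e.regions[r] == ne.regions[r] for r in ne.regions):
            return False
    return True


def _pairings(n_sub, n_ref):
    if n_sub == 1 and n_ref == 1:
        return [((0, 0),)]
    if n_sub == 2 and n_ref == 2:
        return [((0, 0), (1, 1)), ((0, 1), (1, 0))]
    if n_sub == 2 and n_ref == 1:
        return [((0, 0),), ((1, 0),)]
    return [((0, 0),), ((0, 1),)]


def _classify(sub: GenotypeCall, ref, catalog, mode, pairs) -> str:
    gindex = _group_index(catalog, ref.locus, mode)
    all_genotypes = (sub.slots,) + sub.genotype_alternatives

    for slots in all_genotypes:
        for slot in slots:
            for a in slot:
                if len(a.fields) == 1:
                    return "error4"
    for slots in all_genotypes:
        for slot in slots:
            for a in slot:
                if not _scan(catalog, a):
                    return "error4"

    excluded = set()
    for e in sub.excluded_nulls:
        excluded.add(e)
        excluded.update(_scan(catalog, e))

    def expansion(slot):
        out = set()
        for d in slot:
            out.update(_scan(catalog, d))
        return out

    def effective(slot):
        return expansion(slot) - excluded

    def groups_of(names):
        return {gindex[str(a)] for a in names}

    def complete_expressed(gi):
        return {
            _two_field(catalog, e.name)
            for e in _entries(catalog, ref.locus)
            if gindex[str(e.name)] == gi and e.name.suffix != "N"
        }

    # mis-paired slash lists
    if len(sub.slots) == 2 and len(ref.slots) == 2:
        g_ref = [gindex[str(r)] for r in ref.slots]
        if g_ref[0] != g_ref[1]:
            des_group = {}
            ok = True
            for slot in sub.slots:
                for d in slot:
                    gs = groups_of(_scan(catalog, d))
                    if len(gs) != 1:
                        ok = False
                    else:
                        des_group[d] = gs.pop()
            if ok:
                union = set(sub.slots[0]) | set(sub.slots[1])
                part = {
                    g: frozenset(d for d in union if des_group[d] == g) for g in g_ref
                }
                if (
                    part[g_ref[0]] | part[g_ref[1]] == union
                    and part[g_ref[0]] == frozenset(complete_expressed(g_ref[0]))
                    and part[g_ref[1]] == frozenset(complete_expressed(g_ref[1]))
                    and {frozenset(s) for s in sub.slots} != set(part.values())
                ):
                    return "error4"

    # incomplete same-group slash list
    for i, j in pairs:
        slot, r = sub.slots[i], ref.slots[j]
        expressed = [d for d in slot if d.suffix != "N"]
        if len(slot) < 2 or not expressed:
            continue
        r_gi = gindex[str(r)]
        if all(groups_of(_scan(catalog, d)) == {r_gi} for d in expressed):
            if r in expansion(slot):
                listed = {_two_field(catalog, d) for d in expressed}
                if listed != complete_expressed(r_gi):
                    return "error4"

    # content vs reference
    if len(sub.slots) > len(ref.slots):
        return "error3"
    if len(sub.slots) < len(ref.slots):
        return "error3"
    for i, j in pairs:
        slot, r = sub.slots[i], ref.slots[j]
        if r not in effective(slot):
            return "error3"
        if r.suffix == "N" and not any(
            d.suffix == "N" and r in _scan(catalog, d) for d in slot
        ):
            return "error3"

    # unresolved genotype ambiguity
    for slots in all_genotypes:
        for slot in slots:
            if len(groups_of(effective(slot))) > 1:
                return "error1"
    group_genotypes = {
        tuple(sorted(tuple(sorted(groups_of(effective(slot)))) for slot in slots))
        for slots in all_genotypes
    }
    if len(group_genotypes) > 1:
        return "error1"

    # unexcluded excludable null
    for i, j in pairs:
        for d in sub.slots[i]:
            for a in _scan(catalog, d):
                if (
                    a.suffix == "N"
                    and a not in ref.slots
                    and a not in excluded
                    and _excludable(catalog, a)
                ):
                    return "error2"
    return "correct"


def oracle_grade(sub: GenotypeCall, ref, catalog, mode: str = "high_resolution") -> str:
    """Category assigned by exhaustive enumeration over raw region strings."""
    excluded = set()
    for e in sub.excluded_nulls:
        excluded.add(e)
        excluded.update(_scan(catalog, e))
    best = None
    for idx, pairs in enumerate(_pairings(len(sub.slots), len(ref.slots))):
        score = 0
        for i, j in pairs:
            exp = set()
            for d in sub.slots[i]:
                exp.update(_scan(catalog, d))
            if ref.slots[j] in exp - excluded:
                score += 1
        category = _classify(sub, ref, catalog, mode, pairs)
        key = (-score, _SEVERITY[category], idx)
        if best is None or key < best[0]:
            best = (key, category)
    return best[1]
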