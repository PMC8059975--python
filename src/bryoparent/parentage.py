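"""Multi-locus parentage assignment from depth-gated consensus haplotypes.

Each sporophyte yields two consensus haplotypes per locus (labelled a/b,
the labels being arbitrary per locus). A haplotype is matched to the parent
panel by N-tolerant similarity restricted to the locus's diagnostic
positions (plus any position where the sequences genuinely differ); the
per-locus candidate sets are then chained across loci into two multi-locus
"bundles" — one per true parent — by candidate-set consistency, and each
bundle's candidate intersection names the parent. Parents that are
indistinguishable at every diagnostic position form an ambiguity class and
can only ever be named as the merged class (the "F6'" mechanism). Foreign
haplotypes (matching no panel parent at some locus) are reported as
unknown, never imputed, with stable anonymous ids when a registry is used.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .genotyping import HaplotypePair
from .panel import FEMALE, MALE, ParentPanel, class_id
from .util import N_CODE, encode

UNKNOWN = "unknown"
AMBIGUOUS = "ambiguous"

RESOLVED = "resolved"
CLASS_RESOLVED = "class-resolved"
STATUS_AMBIGUOUS = "ambiguous"
UNKNOWN_PARENT = "unknown-parent"
CONFLICT = "conflict"


@dataclass(frozen=True)
class LocusMatch:
    sporophyte_id: str
    locus_id: str
    hap_label: str                 # "a" | "b"
    candidates: frozenset          # empty = unknown/foreign or insufficient
    n_compared_sites: int
    n_mismatch: int
    insufficient: bool = False     # too few non-N diagnostic comparisons


@dataclass
class ParentageAssignment:
    sporophyte_id: str
    mother: str
    father: str
    status: str
    evidence: list[LocusMatch] = field(default_factory=list)


def match_haplotype(
    hap: str,
    panel: ParentPanel,
    locus_id: str,
    max_mismatch: int = 0,
    min_overlap: int = 5,
    sporophyte_id: str = "",
    hap_label: str = "a",
) -> LocusMatch:
    """Match one consensus haplotype against every panel parent at a locus.

    Distance to a parent counts mismatches over positions where both
    sequences are non-N, restricted to the locus's diagnostic positions
    plus any further position where the two sequences differ (so a foreign
    haplotype is penalised for its private variants). If fewer than
    ``min(min_overlap, n diagnostic positions)`` diagnostic positions are
    comparable, the locus abstains (insufficient data, no candidates): the
    cap means a fully observed locus never abstains merely for carrying few
    diagnostic sites, while missing data still triggers abstention.
    Candidates are the minimal-distance parents with distance <=
    ``max_mismatch``.
    """
    locus = panel.locus(locus_id)
    if len(hap) != locus.length:
        raise ValueError(f"haplotype length {len(hap)} != locus length {locus.length}")
    h = encode(hap)
    non_n = h != N_CODE
    vp = np.asarray(locus.variant_positions, dtype=np.int64)
    comparable_vp = vp[non_n[vp]] if vp.size else vp
    n_compared = int(comparable_vp.size)
    if n_compared < min(min_overlap, len(vp)) or n_compared == 0:
        return LocusMatch(sporophyte_id, locus_id, hap_label, frozenset(), n_compared, 0, True)

    dists = {}
    for pid in panel.parent_ids:
        p = encode(panel.haplotype(pid, locus_id))
        diff = (h != p) & non_n
        # positions in scope: diagnostic sites plus observed differences
        d = int(diff[comparable_vp].sum()) if comparable_vp.size else 0
        extra = diff.copy()
        extra[vp] = False
        d += int(extra.sum())
        dists[pid] = d
    dmin = min(dists.values())
    if dmin > max_mismatch:
        return LocusMatch(sporophyte_id, locus_id, hap_label, frozenset(), n_compared, dmin, False)
    cands = frozenset(pid for pid, d in dists.items() if d == dmin)
    return LocusMatch(sporophyte_id, locus_id, hap_label, cands, n_compared, dmin, False)


class UnknownRegistry:
    """Stable anonymous ids (U1, U2, ...) for recurring foreign haplotypes,
    keyed by an exact-sequence hash of the multi-locus haplotype bundle."""

    def __init__(self):
        self._ids: dict[str, str] = {}

    def id_for(self, bundle_seqs: dict[str, str]) -> str:
        h = hashlib.sha256()
        for locus_id in sorted(bundle_seqs):
            h.update(locus_id.encode())
            h.update(bundle_seqs[locus_id].encode())
        key = h.hexdigest()
        if key not in self._ids:
            self._ids[key] = f"U{len(self._ids) + 1}"
        return self._ids[key]


def _bundle_identity(matches: list[LocusMatch], panel: ParentPanel):
    """Resolve one multi-locus bundle to (identity, sexes, kind).

    kind in {resolved, class, ambiguous, unknown, conflict, nodata}.
    A single sufficient-data locus where no parent matches excludes every
    panel parent, so the bundle is foreign (unknown).
    """
    informative = [m for m in matches if m.candidates]
    foreign = [m for m in matches if not m.candidates and not m.insufficient]
    if foreign:
        return None, set(), UNKNOWN, frozenset()
    if not informative:
        return None, set(), "nodata", frozenset()
    inter = frozenset.intersection(*(m.candidates for m in informative))
    if not inter:
        return None, set(), CONFLICT, frozenset()
    sexes = {panel.sex_of(p) for p in inter}
    if len(inter) == 1:
        return next(iter(inter)), sexes, RESOLVED, inter
    if inter in panel.ambiguity_groups:
        return class_id(inter), sexes, "class", inter
    return inter, sexes, AMBIGUOUS, inter


def assign_parentage(
    matches: list[LocusMatch],
    panel: ParentPanel,
    unknown_registry: UnknownRegistry | None = None,
    bundle_seqs: dict[str, dict[str, str]] | None = None,
) -> ParentageAssignment:
    """Combine per-locus matches into one maternal + one paternal call.

    Per-locus a/b labels carry no linkage, so the two multi-locus bundles
    are chosen over all label orientations to maximise candidate-set
    consistency (sum of the two bundles' intersection sizes), preferring
    orientations whose bundles are single- and opposite-sexed; orientations
    tying at the top with different outcomes yield an ambiguous call.
    ``bundle_seqs`` optionally maps hap label -> {locus_id: sequence} so
    foreign bundles can receive stable registry ids.
    """
    by_locus: dict[str, dict[str, LocusMatch]] = {}
    for m in matches:
        by_locus.setdefault(m.locus_id, {})[m.hap_label] = m
    loci = sorted(by_locus)
    if not loci:
        raise ValueError("no locus matches supplied")
    sporophyte_id = matches[0].sporophyte_id
    if not any(m.candidates for m in matches):
        if all(m.insufficient for m in matches):
            raise ValueError(f"{sporophyte_id}: zero informative loci")

    outcomes = {}
    for bits in product((0, 1), repeat=max(len(loci) - 1, 0)):
        orient = (0,) + bits
        bundle1, bundle2, labels1 = [], [], {}
        for locus_id, flip in zip(loci, orient):
            pair = by_locus[locus_id]
            a = pair.get("a")
            b = pair.get("b")
            first, second = (b, a) if flip else (a, b)
            if first is not None:
                bundle1.append(first)
                labels1[locus_id] = first.hap_label
            if second is not None:
                bundle2.append(second)
        id1, sex1, kind1, inter1 = _bundle_identity(bundle1, panel)
        id2, sex2, kind2, inter2 = _bundle_identity(bundle2, panel)
        # rank orientations. A chaining that names the SAME parent (or class)
        # for both bundles is degenerate — the parents are haploid and of
        # opposite sexes, one individual cannot contribute both haplotypes —
        # so it is dominated by everything else. Then prefer more precise
        # identifications (singleton or class), fewer cross-locus conflicts,
        # the most specific consistent reading (smallest total candidate
        # intersection), and lastly the absence of a same-sex clash.
        precise1 = kind1 in (RESOLVED, "class")
        precise2 = kind2 in (RESOLVED, "class")
        degenerate = precise1 and precise2 and id1 == id2
        sex_clash = len(sex1) == 1 and len(sex2) == 1 and sex1 == sex2
        n_conflict = (kind1 == CONFLICT) + (kind2 == CONFLICT)

        rank = (
            not degenerate,
            precise1 + precise2,
            -n_conflict,
            -(len(inter1) + len(inter2)),
            not sex_clash,
        )
        key = frozenset(
            [(str(id1), kind1, frozenset(sex1)), (str(id2), kind2, frozenset(sex2))]
        )
        outcomes[orient] = (rank, key, (id1, sex1, kind1), (id2, sex2, kind2), labels1)

    best = max(outcomes.values(), key=lambda o: o[0])
    top = [o for o in outcomes.values() if o[0] == best[0]]
    distinct = {o[1] for o in top}
    if len(distinct) > 1:
        return ParentageAssignment(sporophyte_id, AMBIGUOUS, AMBIGUOUS,
                                   STATUS_AMBIGUOUS, matches)

    _, _, (id1, sex1, kind1), (id2, sex2, kind2), labels1 = best

    def finalize(ident, sexes, kind, bundle_labels):
        if kind == UNKNOWN:
            if unknown_registry is not None and bundle_seqs is not None and bundle_labels:
                seqs = {
                    locus_id: bundle_seqs[lab][locus_id]
                    for locus_id, lab in bundle_labels.items()
                    if lab in bundle_seqs and locus_id in bundle_seqs[lab]
                }
                if seqs:
                    return unknown_registry.id_for(seqs), None
            return UNKNOWN, None
        if kind in ("nodata", AMBIGUOUS):
            sex = next(iter(sexes)) if len(sexes) == 1 else None
            return AMBIGUOUS, sex
        if kind == CONFLICT:
            return CONFLICT, None
        sex = next(iter(sexes))
        return ident, sex

    labels2 = {
        locus_id: ("a" if lab == "b" else "b") for locus_id, lab in labels1.items()
    }
    name1, s1 = finalize(id1, sex1, kind1, labels1)
    name2, s2 = finalize(id2, sex2, kind2, labels2)

    if kind1 == CONFLICT or kind2 == CONFLICT:
        return ParentageAssignment(sporophyte_id, CONFLICT, CONFLICT, CONFLICT, matches)
    if s1 is not None and s1 == s2:
        return ParentageAssignment(sporophyte_id, CONFLICT, CONFLICT, CONFLICT, matches)

    # orient to (mother, father) using whatever sex information exists
    if s1 == FEMALE or s2 == MALE:
        mother, father = name1, name2
        kinds = (kind1, kind2)
    elif s1 == MALE or s2 == FEMALE:
        mother, father = name2, name1
        kinds = (kind2, kind1)
    else:
        mother, father = name1, name2
        kinds = (kind1, kind2)

    if UNKNOWN in (kind1, kind2):
        status = UNKNOWN_PARENT
    elif kind1 in ("nodata", AMBIGUOUS) or kind2 in ("nodata", AMBIGUOUS):
        status = STATUS_AMBIGUOUS
    elif "class" in (kind1, kind2):
        status = CLASS_RESOLVED
    else:
        status = RESOLVED
    return ParentageAssignment(sporophyte_id, mother, father, status, matches)


def match_pool(
    sporophyte_id: str,
    haplotype_pairs: dict[str, HaplotypePair],
    panel: ParentPanel,
    max_mismatch: int = 0,
    min_overlap: int = 5,
    unknown_registry: UnknownRegistry | None = None,
) -> ParentageAssignment:
    """Convenience: match both consensus haplotypes at every locus and
    assign parentage for one sporophyte."""
    matches: list[LocusMatch] = []
    bundle_seqs: dict[str, dict[str, str]] = {"a": {}, "b": {}}
    for locus_id, pair in haplotype_pairs.items():
        for label, hap in (("a", pair.hap_a), ("b", pair.hap_b)):
            matches.append(
                match_haplotype(
                    hap, panel, locus_id,
                    max_mismatch=max_mismatch, min_overlap=min_overlap,
                    sporophyte_id=sporophyte_id, hap_label=label,
                )
            )
            bundle_seqs[label][locus_id] = hap
    return assign_parentage(matches, panel, unknown_registry=unknown_registry,
                            bundle_seqs=bundle_seqs)


# ------------------------------------------------------------- cross table


@dataclass
class CrossTable:
    """Long-format sporophyte counts by (mother-or-class, father, treatment,
    mesocosm), with unresolved assignments tallied separately."""

    counts: pd.DataFrame
    excluded: dict
    total: int

    def by(self, *cols) -> pd.Series:
        return self.counts.groupby(list(cols))["count"].sum()

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def tabulate_crosses(
    assignments: list[ParentageAssignment],
    sheet: pd.DataFrame,
) -> CrossTable:
    """Count resolved and class-resolved sporophytes per cross; conserve the
    grand total (every assignment is either counted or tallied as excluded)."""
    frame = sheet.frame if hasattr(sheet, "frame") else sheet
    meta = frame.set_index("sample_id")
    missing = [a.sporophyte_id for a in assignments if a.sporophyte_id not in meta.index]
    if missing:
        raise ValueError(f"assignments missing from sample sheet: {missing[:5]}")
    rows = []
    excluded: dict[str, int] = {}
    for a in assignments:
        if a.status in (RESOLVED, CLASS_RESOLVED):
            m = meta.loc[a.sporophyte_id]
            rows.append(
                {
                    "mother": a.mother,
                    "father": a.father,
                    "treatment": m["treatment"],
                    "mesocosm_id": m["mesocosm_id"],
                }
            )
        else:
            excluded[a.status] = excluded.get(a.status, 0) + 1
    if rows:
        counts = (
            pd.DataFrame(rows)
            .groupby(["mother", "father", "treatment", "mesocosm_id"])
            .size()
            .reset_index(name="count")
        )
    else:
        counts = pd.DataFrame(columns=["mother", "father", "treatment", "mesocosm_id", "count"])
    return CrossTable(counts=counts, excluded=excluded, total=len(assignments))


def assignments_frame(assignments: list[ParentageAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        informative = sum(1 for m in a.evidence if m.candidates)
        rows.append(
            {
                "sporophyte_id": a.sporophyte_id,
                "mother": str(a.mother),
                "father": str(a.father),
                "status": a.status,
                "n_informative_locus_matches": informative,
                "n_locus_matches": len(a.evidence),
            }
        )
    return pd.DataFrame(rows)
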