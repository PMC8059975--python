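"""Parent panels: sexed haploid parents with per-locus amplicon haplotypes.

In a moss mating experiment each parent is a haploid gametophyte, so a
parent contributes exactly one haplotype per locus and every sporophyte
(diploid offspring) carries exactly two parental haplotypes at each locus.
A :class:`ParentPanel` records each parent's haplotype at each amplicon
locus and derives the diagnostic structure of the design: which parents
cannot be told apart by the variant positions (ambiguity classes, the
mechanism behind merged maternal identities such as "F6'").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import encode

MALE = "male"
FEMALE = "female"


@dataclass(frozen=True)
class LocusSpec:
    """One amplicon locus: its reference sequence and diagnostic positions."""

    locus_id: str
    length: int
    reference_seq: str
    variant_positions: tuple[int, ...]

    def __post_init__(self):
        if self.length < 150:
            raise ValueError(f"locus {self.locus_id}: length must be >= 150")
        if len(self.reference_seq) != self.length:
            raise ValueError(f"locus {self.locus_id}: reference length mismatch")
        vp = tuple(self.variant_positions)
        if list(vp) != sorted(set(vp)):
            raise ValueError(f"locus {self.locus_id}: variant positions must be strictly increasing")
        if vp and (vp[0] < 0 or vp[-1] >= self.length):
            raise ValueError(f"locus {self.locus_id}: variant position out of range")
        if set(self.reference_seq) - set("ACGT"):
            raise ValueError(f"locus {self.locus_id}: reference must be over ACGT")
        object.__setattr__(self, "variant_positions", vp)


@dataclass(frozen=True)
class Parent:
    parent_id: str
    sex: str  # "male" | "female"
    haplotypes: dict  # locus_id -> nucleotide string

    def __post_init__(self):
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"{self.parent_id}: sex must be 'male' or 'female'")


class ParentPanel:
    """The known parents of a mesocosm experiment.

    Ambiguity groups are *computed*, never asserted: parents whose alleles
    agree at every variant position of every locus form one group, and such
    a group can only ever be resolved as a merged class.
    """

    def __init__(self, parents: list[Parent], loci: list[LocusSpec]):
        ids = [p.parent_id for p in parents]
        if len(set(ids)) != len(ids):
            raise ValueError("parent ids must be unique")
        for p in parents:
            for locus in loci:
                hap = p.haplotypes.get(locus.locus_id)
                if hap is None:
                    raise ValueError(f"{p.parent_id} lacks a haplotype for {locus.locus_id}")
                if len(hap) != locus.length:
                    raise ValueError(
                        f"{p.parent_id}/{locus.locus_id}: haplotype length "
                        f"{len(hap)} != locus length {locus.length}"
                    )
        self.parents = list(parents)
        self.loci = list(loci)
        self._by_id = {p.parent_id: p for p in self.parents}
        self._loci_by_id = {l.locus_id: l for l in self.loci}
        self.ambiguity_groups = self._compute_ambiguity_groups()
        self._class_of = {}
        for g in self.ambiguity_groups:
            cid = class_id(g)
            for pid in g:
                self._class_of[pid] = cid

    # ------------------------------------------------------------ accessors

    @property
    def parent_ids(self) -> list[str]:
        return [p.parent_id for p in self.parents]

    def males(self) -> list[str]:
        return [p.parent_id for p in self.parents if p.sex == MALE]

    def females(self) -> list[str]:
        return [p.parent_id for p in self.parents if p.sex == FEMALE]

    def sex_of(self, parent_id: str) -> str:
        return self._by_id[parent_id].sex

    def haplotype(self, parent_id: str, locus_id: str) -> str:
        return self._by_id[parent_id].haplotypes[locus_id]

    def locus(self, locus_id: str) -> LocusSpec:
        return self._loci_by_id[locus_id]

    def variant_profile(self, parent_id: str) -> tuple:
        """Alleles of a parent at every variant position across all loci."""
        prof = []
        for locus in self.loci:
            hap = self.haplotype(parent_id, locus.locus_id)
            prof.extend(hap[p] for p in locus.variant_positions)
        return tuple(prof)

    def ambiguity_class_of(self, parent_id: str) -> str | None:
        """Merged class id if this parent belongs to an ambiguity group."""
        return self._class_of.get(parent_id)

    def _compute_ambiguity_groups(self) -> list[frozenset]:
        by_profile: dict[tuple, list[str]] = {}
        for p in self.parents:
            by_profile.setdefault(self.variant_profile(p.parent_id), []).append(p.parent_id)
        return sorted(
            (frozenset(g) for g in by_profile.values() if len(g) > 1),
            key=lambda g: sorted(g),
        )

    # ------------------------------------------------------------------- I/O

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records = [
            SeqRecord(Seq(p.haplotypes[l.locus_id]), id=f"{p.parent_id}|{l.locus_id}",
                      description="")
            for p in self.parents
            for l in self.loci
        ]
        SeqIO.write(records, str(out_dir / "panel.fasta"), "fasta")
        pd.DataFrame(
            {"parent_id": [p.parent_id for p in self.parents],
             "sex": [p.sex for p in self.parents]}
        ).to_csv(out_dir / "parents.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "locus_id": [l.locus_id for l in self.loci],
                "length": [l.length for l in self.loci],
                "variant_positions": [
                    ",".join(map(str, l.variant_positions)) for l in self.loci
                ],
                "reference_seq": [l.reference_seq for l in self.loci],
            }
        ).to_csv(out_dir / "loci.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, in_dir) -> "ParentPanel":
        in_dir = Path(in_dir)
        meta = pd.read_csv(in_dir / "parents.tsv", sep="\t")
        loci_tab = pd.read_csv(in_dir / "loci.tsv", sep="\t")
        loci = [
            LocusSpec(
                locus_id=str(r.locus_id),
                length=int(r.length),
                reference_seq=str(r.reference_seq),
                variant_positions=tuple(
                    int(x) for x in str(r.variant_positions).split(",") if x != ""
                ),
            )
            for r in loci_tab.itertuples()
        ]
        haps: dict[str, dict[str, str]] = {}
        for rec in SeqIO.parse(str(in_dir / "panel.fasta"), "fasta"):
            pid, locus_id = rec.id.split("|", 1)
            haps.setdefault(pid, {})[locus_id] = str(rec.seq)
        parents = [
            Parent(parent_id=str(r.parent_id), sex=str(r.sex), haplotypes=haps[str(r.parent_id)])
            for r in meta.itertuples()
        ]
        return cls(parents, loci)


def class_id(group) -> str:
    """Merged identity for an ambiguity group (e.g. {F8, F9} -> "F9'")."""
    return sorted(group)[-1] + "'"


def encoded_haplotypes(panel: ParentPanel, locus_id: str) -> dict:
    """uint8-encoded haplotypes of every parent at one locus."""
    return {p.parent_id: encode(p.haplotypes[locus_id]) for p in panel.parents}
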