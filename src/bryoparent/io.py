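"""Read containers and FASTQ I/O.

Reads are held column-wise in a :class:`ReadBatch`: one uint8 matrix for
sequence codes, one for Phred qualities, plus a per-read length vector so
that trimmed reads of unequal length share the same storage. Dual indexes
(i5/i7) travel with the batch and are serialised in the FASTQ description
using the Casava convention ``<mate>:N:0:<i7>+<i5>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import N_CODE, decode, encode


@dataclass
class ReadBatch:
    """A batch of (possibly trimmed) sequencing reads.

    ``seq``/``qual`` are (n, width) uint8 matrices; row i is valid up to
    ``length[i]``. ``i5``/``i7`` are per-read index strings (or None), and
    ``mate`` is 1/2 for paired output, 0 for single-end.
    """

    ids: list[str]
    seq: np.ndarray
    qual: np.ndarray
    length: np.ndarray
    i5: list[str] | None = None
    i7: list[str] | None = None
    mate: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.seq.shape != self.qual.shape or self.seq.shape[0] != n:
            raise ValueError("inconsistent batch shapes")
        self.length = np.asarray(self.length, dtype=np.int32)

    @property
    def n(self) -> int:
        return len(self.ids)

    def read_seq(self, i: int) -> np.ndarray:
        return self.seq[i, : self.length[i]]

    def read_qual(self, i: int) -> np.ndarray:
        return self.qual[i, : self.length[i]]

    def subset(self, idx) -> "ReadBatch":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        take = lambda lst: [lst[i] for i in idx] if lst is not None else None
        return ReadBatch(
            ids=[self.ids[i] for i in idx],
            seq=self.seq[idx],
            qual=self.qual[idx],
            length=self.length[idx],
            i5=take(self.i5),
            i7=take(self.i7),
            mate=self.mate[idx] if self.mate is not None else None,
        )

    @classmethod
    def empty(cls, width: int = 0) -> "ReadBatch":
        z = np.zeros((0, width), dtype=np.uint8)
        return cls(ids=[], seq=z, qual=z.copy(), length=np.zeros(0, np.int32),
                   i5=[], i7=[], mate=np.zeros(0, np.uint8))

    @classmethod
    def concat(cls, batches: list["ReadBatch"]) -> "ReadBatch":
        batches = [b for b in batches if b.n]
        if not batches:
            return cls.empty()
        width = max(b.seq.shape[1] for b in batches)
        n = sum(b.n for b in batches)
        seq = np.full((n, width), N_CODE, dtype=np.uint8)
        qual = np.zeros((n, width), dtype=np.uint8)
        ids: list[str] = []
        i5: list[str] = []
        i7: list[str] = []
        lengths = []
        mates = []
        have_idx = all(b.i5 is not None for b in batches)
        have_mate = all(b.mate is not None for b in batches)
        row = 0
        for b in batches:
            seq[row : row + b.n, : b.seq.shape[1]] = b.seq
            qual[row : row + b.n, : b.qual.shape[1]] = b.qual
            ids.extend(b.ids)
            lengths.append(b.length)
            if have_idx:
                i5.extend(b.i5)
                i7.extend(b.i7)
            if have_mate:
                mates.append(b.mate)
            row += b.n
        return cls(
            ids=ids,
            seq=seq,
            qual=qual,
            length=np.concatenate(lengths),
            i5=i5 if have_idx else None,
            i7=i7 if have_idx else None,
            mate=np.concatenate(mates) if have_mate else None,
        )

    # ------------------------------------------------------------------ FASTQ

    def to_records(self):
        for i in range(self.n):
            rec = SeqRecord(
                Seq(decode(self.read_seq(i))),
                id=self.ids[i],
                description=self._description(i),
            )
            rec.letter_annotations["phred_quality"] = [int(q) for q in self.read_qual(i)]
            yield rec

    def _description(self, i: int) -> str:
        mate = int(self.mate[i]) if self.mate is not None else 0
        if self.i5 is not None and self.i7 is not None:
            return f"{self.ids[i]} {mate or 1}:N:0:{self.i7[i]}+{self.i5[i]}"
        return self.ids[i]

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            SeqIO.write(self.to_records(), fh, "fastq")

    @classmethod
    def from_fastq(cls, path) -> "ReadBatch":
        ids, seqs, quals, i5s, i7s, mates = [], [], [], [], [], []
        for rec in SeqIO.parse(str(path), "fastq"):
            ids.append(rec.id)
            seqs.append(encode(str(rec.seq)))
            quals.append(np.asarray(rec.letter_annotations["phred_quality"], dtype=np.uint8))
            mate, i5, i7 = _parse_casava(rec.description)
            mates.append(mate)
            i5s.append(i5)
            i7s.append(i7)
        if not ids:
            return cls.empty()
        width = max(len(s) for s in seqs)
        seq = np.full((len(ids), width), N_CODE, dtype=np.uint8)
        qual = np.zeros((len(ids), width), dtype=np.uint8)
        length = np.zeros(len(ids), dtype=np.int32)
        for i, (s, q) in enumerate(zip(seqs, quals)):
            seq[i, : len(s)] = s
            qual[i, : len(q)] = q
            length[i] = len(s)
        have_idx = all(x is not None for x in i5s)
        return cls(
            ids=ids,
            seq=seq,
            qual=qual,
            length=length,
            i5=i5s if have_idx else None,
            i7=i7s if have_idx else None,
            mate=np.asarray(mates, dtype=np.uint8),
        )


def _parse_casava(description: str):
    """Parse ``<id> <mate>:N:0:<i7>+<i5>`` descriptions; tolerate absence."""
    parts = description.split()
    if len(parts) < 2:
        return 0, None, None
    comment = parts[-1].split(":")
    mate = 0
    if comment and comment[0].isdigit():
        mate = int(comment[0])
    if "+" in comment[-1]:
        i7, i5 = comment[-1].split("+", 1)
        return mate, i5, i7
    return mate, None, None


def write_tsv(frame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
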