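"""Demultiplexing and quality trimming of dual-indexed amplicon reads.

Demultiplexing assigns a read to a sample iff BOTH its i5 and i7 indexes
are within ``max_mismatch`` (default 1) Hamming distance of that sample's
indexes; everything else lands in an "undetermined" bin and total read
count is conserved. Trimming scans 5'->3' with a sliding window (default
10 bp, step 1) and cuts the read at the first base of the first window
whose mean Phred quality falls below the threshold (default Q30); reads
shorter than ``min_len`` after the cut are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ReadBatch
from .util import encode

logger = logging.getLogger(__name__)

UNDETERMINED = "undetermined"

SHEET_COLUMNS = [
    "sample_id", "i5_index", "i7_index",
    "mesocosm_id", "treatment", "distance_cm", "angle_deg",
]


class IndexCollisionError(ValueError):
    """Two samples in the sheet cannot be told apart at the mismatch tolerance."""


@dataclass
class SampleSheet:
    """Sample metadata with dual-index assignments (one row per sporophyte)."""

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SHEET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet lacks columns: {missing}")
        ids = self.frame["sample_id"]
        if ids.duplicated().any():
            raise ValueError("sample ids must be unique")
        pairs = list(zip(self.frame["i5_index"], self.frame["i7_index"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("(i5, i7) index pairs must be unique")
        for col in ("i5_index", "i7_index"):
            bad = [s for s in self.frame[col] if set(str(s)) - set("ACGT")]
            if bad:
                raise ValueError(f"{col} contains non-ACGT sequences: {bad[:3]}")

    @property
    def index_length(self) -> int:
        return len(str(self.frame["i5_index"].iloc[0]))

    def check_collisions(self, max_mismatch: int) -> None:
        """A read within tolerance of two samples would be ambiguous; that
        requires both index distances <= 2*max_mismatch, so demand that at
        least one index separate every sample pair by more than that."""
        i5 = [encode(str(s)) for s in self.frame["i5_index"]]
        i7 = [encode(str(s)) for s in self.frame["i7_index"]]
        ids = list(self.frame["sample_id"])
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                d5 = int(np.count_nonzero(i5[a] != i5[b]))
                d7 = int(np.count_nonzero(i7[a] != i7[b]))
                if d5 <= 2 * max_mismatch and d7 <= 2 * max_mismatch:
                    raise IndexCollisionError(
                        f"samples {ids[a]} and {ids[b]} collide at "
                        f"max_mismatch={max_mismatch} (d_i5={d5}, d_i7={d7})"
                    )

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _index_matrix(values: list[str], width: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack equal-length index strings into a code matrix; flag misfits."""
    ok = np.array([isinstance(s, str) and len(s) == width for s in values], dtype=bool)
    mat = np.zeros((len(values), width), dtype=np.uint8)
    if ok.all() and len(values):
        return encode("".join(values)).reshape(len(values), width), ok
    for i, s in enumerate(values):
        if ok[i]:
            mat[i] = encode(s)
    return mat, ok


def demultiplex(
    reads: ReadBatch,
    sheet: SampleSheet | pd.DataFrame,
    max_mismatch: int = 1,
) -> tuple[dict[str, ReadBatch], pd.DataFrame]:
    """Assign reads to samples by dual-index matching.

    Returns ``(bins, report)`` where ``bins`` maps sample_id -> ReadBatch
    (plus the ``"undetermined"`` bin) and ``report`` counts per-sample
    totals and how many reads needed the mismatch rescue.
    """
    if isinstance(sheet, pd.DataFrame):
        sheet = SampleSheet(sheet)
    sample_ids = list(sheet.frame["sample_id"])
    if not sample_ids:
        return {UNDETERMINED: reads}, pd.DataFrame(
            [{"sample_id": UNDETERMINED, "n_reads": reads.n, "n_mismatch_rescued": 0}]
        )
    sheet.check_collisions(max_mismatch)
    width = sheet.index_length
    if UNDETERMINED in sample_ids:
        raise ValueError(f"sample id {UNDETERMINED!r} is reserved")

    if reads.i5 is None or reads.i7 is None:
        raise ValueError("reads carry no index information")

    s5 = np.stack([encode(str(s)) for s in sheet.frame["i5_index"]])
    s7 = np.stack([encode(str(s)) for s in sheet.frame["i7_index"]])

    r5, ok5 = _index_matrix(reads.i5, width)
    r7, ok7 = _index_matrix(reads.i7, width)
    valid = ok5 & ok7
    n_malformed = int((~valid).sum())
    if n_malformed:
        logger.warning("%d reads with malformed index length sent to undetermined", n_malformed)

    assignment = np.full(reads.n, -1, dtype=np.int64)
    exact = np.zeros(reads.n, dtype=bool)

    # fast path: exact (i5, i7) pair lookup
    pair_lookup = {
        (str(r.i5_index), str(r.i7_index)): k
        for k, r in enumerate(sheet.frame.itertuples())
    }
    undecided = []
    for i in range(reads.n):
        if not valid[i]:
            continue
        hit = pair_lookup.get((reads.i5[i], reads.i7[i]))
        if hit is not None:
            assignment[i] = hit
            exact[i] = True
        else:
            undecided.append(i)

    if undecided and max_mismatch > 0:
        idx = np.asarray(undecided)
        d5 = (r5[idx][:, None, :] != s5[None, :, :]).sum(axis=2)
        d7 = (r7[idx][:, None, :] != s7[None, :, :]).sum(axis=2)
        match = (d5 <= max_mismatch) & (d7 <= max_mismatch)
        n_hits = match.sum(axis=1)
        hit_rows = np.flatnonzero(n_hits == 1)
        assignment[idx[hit_rows]] = np.argmax(match[hit_rows], axis=1)

    bins: dict[str, ReadBatch] = {}
    report_rows = []
    for k, sid in enumerate(sample_ids):
        sel = assignment == k
        bins[sid] = reads.subset(sel)
        report_rows.append(
            {
                "sample_id": sid,
                "n_reads": int(sel.sum()),
                "n_mismatch_rescued": int((sel & ~exact).sum()),
            }
        )
    undet = assignment == -1
    bins[UNDETERMINED] = reads.subset(undet)
    report_rows.append(
        {"sample_id": UNDETERMINED, "n_reads": int(undet.sum()), "n_mismatch_rescued": 0}
    )
    return bins, pd.DataFrame(report_rows)


# ----------------------------------------------------------------- trimming


@dataclass
class TrimmedRead:
    read_id: str
    sequence: str
    qualities: list[int]
    kept: bool


def _retained_length(quals: np.ndarray, window: int, min_mean_q: int) -> int:
    """Length kept after the first failing sliding window (full read if none)."""
    n = len(quals)
    if n == 0:
        return 0
    if n < window:
        return n  # no complete window to evaluate
    cs = np.concatenate([[0], np.cumsum(quals.astype(np.int64))])
    wsum = cs[window:] - cs[:-window]  # sums of windows starting at 0..n-window
    failing = np.flatnonzero(wsum < min_mean_q * window)
    return int(failing[0]) if failing.size else n


def trim_read(
    read_id: str,
    sequence: str,
    qualities,
    window: int = 10,
    min_mean_q: int = 30,
    min_len: int = 50,
) -> TrimmedRead:
    """Sliding-window quality trim of a single read (windows step by 1 bp;
    the cut point is the first base of the first window whose mean quality
    drops below ``min_mean_q``)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    quals = np.asarray(qualities, dtype=np.int64)
    if len(sequence) != len(quals):
        raise ValueError("sequence and qualities must have equal length")
    keep = _retained_length(quals, window, min_mean_q)
    return TrimmedRead(
        read_id=read_id,
        sequence=sequence[:keep],
        qualities=[int(q) for q in quals[:keep]],
        kept=keep >= min_len,
    )


def trim_batch(
    reads: ReadBatch,
    window: int = 10,
    min_mean_q: int = 30,
    min_len: int = 50,
) -> tuple[ReadBatch, int]:
    """Vectorised trim of a whole batch; returns (kept reads, n dropped)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if reads.n == 0:
        return reads, 0
    q = reads.qual.astype(np.int64)
    n, width = q.shape
    lens = reads.length.astype(np.int64)
    if width >= window:
        cs = np.concatenate([np.zeros((n, 1), np.int64), np.cumsum(q, axis=1)], axis=1)
        wsum = cs[:, window:] - cs[:, :-window]  # window starting at column s
        starts = np.arange(width - window + 1)
        fail = wsum < min_mean_q * window
        # windows that extend past a read's end do not exist for that read
        fail &= starts[None, :] <= (lens - window)[:, None]
        any_fail = fail.any(axis=1)
        first = np.where(any_fail, np.argmax(fail, axis=1), lens)
        keep_len = np.minimum(first, lens).astype(np.int32)
    else:
        keep_len = lens.astype(np.int32)

    kept_mask = keep_len >= min_len
    out = reads.subset(kept_mask)
    out.length = keep_len[kept_mask]
    return out, int((~kept_mask).sum())
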