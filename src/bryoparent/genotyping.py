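"""Pooled-read genotyping: per-amplicon alignment, variant-site detection,
two-haplotype read phasing, and depth-gated consensus.

A sporophyte's pooled progeny carry exactly two parental haplotypes at each
amplicon locus, so the genotyping problem is: place each read on its locus,
find the diagnostic sites, split the reads into the two parental groups by
their alleles at those sites, and call one consensus sequence per group —
emitting ``N`` wherever a group's read depth falls below ``min_depth``
(default 25), the depth gate that marks positions without sufficient
sequencing support.

Alignment is substitution-only (the pools contain no indels): reads are
seeded by exact k-mer lookup against both strands of every amplicon and
verified by mismatch count, with an exhaustive all-offset scan as fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .io import ReadBatch
from .panel import LocusSpec
from .util import BASES, N_CODE, decode, revcomp

logger = logging.getLogger(__name__)


class PhasingError(RuntimeError):
    """More than two stable read clusters — possible contamination."""


# ---------------------------------------------------------------- alignment


@dataclass
class AlignedRead:
    read_id: str
    offset: int            # 0-based start on the locus (locus-forward)
    seq: np.ndarray        # codes, oriented locus-forward
    qual: np.ndarray
    strand: int = 1        # +1 forward, -1 reverse-complemented onto the locus
    mismatches: int = 0


@dataclass
class LocusAlignment:
    locus: LocusSpec
    reads: list[AlignedRead] = field(default_factory=list)

    @property
    def locus_id(self) -> str:
        return self.locus.locus_id

    @cached_property
    def depth(self) -> np.ndarray:
        d = np.zeros(self.locus.length, dtype=np.int64)
        for r in self.reads:
            d[r.offset : r.offset + len(r.seq)] += 1
        return d

    def base_counts(self, read_indices=None) -> np.ndarray:
        """(length, 5) per-position base counts over the given reads."""
        indices = range(len(self.reads)) if read_indices is None else read_indices
        chunks = []
        for i in indices:
            r = self.reads[i]
            # flat index position*5 + base, tallied in one bincount
            chunks.append(np.arange(r.offset * 5, (r.offset + len(r.seq)) * 5, 5) + r.seq)
        if not chunks:
            return np.zeros((self.locus.length, 5), dtype=np.int64)
        flat = np.concatenate(chunks)
        return np.bincount(flat, minlength=self.locus.length * 5).reshape(-1, 5)


@dataclass
class AlignmentResult:
    alignments: dict[str, LocusAlignment]
    unaligned: list[str]

    def __getitem__(self, locus_id: str) -> LocusAlignment:
        return self.alignments[locus_id]


class AmpliconIndex:
    """Exact k-mer index over both strands of every amplicon."""

    def __init__(self, loci: list[LocusSpec], k: int = 21):
        self.k = k
        self.loci = sorted(loci, key=lambda l: l.locus_id)
        self.fwd = [None] * len(self.loci)
        self.rc = [None] * len(self.loci)
        self.kmers: dict[bytes, list[tuple[int, int, int]]] = {}
        from .util import encode

        for li, locus in enumerate(self.loci):
            f = encode(locus.reference_seq)
            self.fwd[li] = f
            self.rc[li] = revcomp(f)
            for strand, arr in ((1, self.fwd[li]), (-1, self.rc[li])):
                for p in range(len(arr) - k + 1):
                    self.kmers.setdefault(arr[p : p + k].tobytes(), []).append((li, p, strand))


def _verify(read: np.ndarray, locus_arr: np.ndarray, offset: int) -> int | None:
    """Mismatch count of a fully contained placement, else None."""
    if offset < 0 or offset + len(read) > len(locus_arr):
        return None
    return int(np.count_nonzero(read != locus_arr[offset : offset + len(read)]))


def _brute_force(read: np.ndarray, index: AmpliconIndex):
    """All offsets on both strands of every locus; best placement or None."""
    best = None
    for li, locus in enumerate(index.loci):
        for strand, arr in ((1, index.fwd[li]), (-1, index.rc[li])):
            if len(read) > len(arr):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, len(read))
            mm = (windows != read[None, :]).sum(axis=1)
            off = int(np.argmin(mm))
            cand = (int(mm[off]), li, strand, off)
            if best is None or cand < best:
                best = cand
    return best


def align_reads(
    reads: ReadBatch,
    loci: list[LocusSpec],
    min_identity: float = 0.9,
    k: int = 21,
    index: AmpliconIndex | None = None,
) -> AlignmentResult:
    """Assign each read to its best-scoring amplicon placement.

    A read is kept iff its best placement has identity >= ``min_identity``;
    ties break deterministically by lowest locus_id, then leftmost offset
    (forward strand preferred). Substitutions only.
    """
    if not loci:
        raise ValueError("no loci to align against")
    if index is None:
        index = AmpliconIndex(loci, k=k)
    alignments = {l.locus_id: LocusAlignment(locus=l) for l in index.loci}
    unaligned: list[str] = []

    for i in range(reads.n):
        seq = reads.read_seq(i)
        n = len(seq)
        best = None  # (mismatches, locus_idx, -strand_pref, offset)
        if n >= index.k:
            candidates = None
            for anchor in range(0, n - index.k + 1, index.k):
                hits = index.kmers.get(seq[anchor : anchor + index.k].tobytes())
                if hits:
                    candidates = [(li, p - anchor, strand) for (li, p, strand) in hits]
                    break
            if candidates:
                for li, off, strand in candidates:
                    arr = index.fwd[li] if strand == 1 else index.rc[li]
                    mm = _verify(seq, arr, off)
                    if mm is None:
                        continue
                    cand = (mm, li, strand, off)
                    if best is None or _placement_key(cand, index, n) < _placement_key(best, index, n):
                        best = cand
        if best is None:
            best = _brute_force(seq, index)
            if best is not None:
                best = (best[0], best[1], best[2], best[3])

        if best is None or 1.0 - best[0] / n < min_identity:
            unaligned.append(reads.ids[i])
            continue
        mm, li, strand, off = best
        if strand == 1:
            oriented, oq, fwd_off = seq, reads.read_qual(i), off
        else:
            locus_len = index.loci[li].length
            oriented = revcomp(seq)
            oq = reads.read_qual(i)[::-1]
            fwd_off = locus_len - off - n
        alignments[index.loci[li].locus_id].reads.append(
            AlignedRead(
                read_id=reads.ids[i],
                offset=int(fwd_off),
                seq=oriented.copy(),
                qual=oq.copy(),
                strand=strand,
                mismatches=mm,
            )
        )
    if unaligned:
        logger.info("%d reads unaligned at min_identity=%.2f", len(unaligned), min_identity)
    return AlignmentResult(alignments=alignments, unaligned=unaligned)


def _placement_key(cand, index: AmpliconIndex, read_len: int):
    """Order placements: fewest mismatches, then locus id, then the leftmost
    forward offset (forward strand preferred on an exact tie)."""
    mm, li, strand, off = cand
    if strand == 1:
        fwd_off = off
    else:
        fwd_off = index.loci[li].length - off - read_len
    return (mm, index.loci[li].locus_id, fwd_off, 0 if strand == 1 else 1)


# ------------------------------------------------------------- variant sites


@dataclass(frozen=True)
class VariantSite:
    locus_id: str
    position: int           # 0-based
    counts: tuple           # (A, C, G, T) counts among aligned bases
    major: str
    minor: str
    multiallelic: bool = False

    @property
    def depth(self) -> int:
        return int(sum(self.counts))


def call_variant_sites(
    aln: LocusAlignment,
    min_minor_frac: float = 0.2,
    min_site_depth: int = 10,
) -> list[VariantSite]:
    """Detect biallelic variant positions in a pooled alignment.

    A position is a site when >= 2 bases each reach ``min_minor_frac`` of
    the aligned depth and the depth is >= ``min_site_depth``. Positions
    where more than two alleles qualify are returned flagged
    ``multiallelic`` and are excluded from phasing.
    """
    counts = aln.base_counts()[:, :4]
    depth = counts.sum(axis=1)
    qualifies = (counts >= min_minor_frac * depth[:, None]) & (counts > 0)
    candidate = (depth >= min_site_depth) & (qualifies.sum(axis=1) >= 2)
    sites: list[VariantSite] = []
    for pos in np.flatnonzero(candidate):
        c = counts[pos]
        qualifying = np.flatnonzero(qualifies[pos])
        order = sorted(qualifying, key=lambda b: (-c[b], b))  # ties -> lexicographic
        sites.append(
            VariantSite(
                locus_id=aln.locus_id,
                position=int(pos),
                counts=tuple(int(x) for x in c),
                major=BASES[order[0]],
                minor=BASES[order[1]],
                multiallelic=len(qualifying) > 2,
            )
        )
    return sites


# ------------------------------------------------------------------ phasing


@dataclass
class PhaseResult:
    """Read partition into the two parental haplotype groups.

    Fields hold indices into ``aln.reads``. ``blind_a``/``blind_b`` are
    site-blind reads (covering no variant site) distributed proportionally
    to group support; they contribute sequencing depth to the consensus but
    never vote at variant sites.
    """

    a: list[int]
    b: list[int]
    unassigned: list[int]
    blind_a: list[int]
    blind_b: list[int]

    def swapped(self) -> "PhaseResult":
        return PhaseResult(self.b, self.a, self.unassigned, self.blind_b, self.blind_a)


def _allele_matrix(aln: LocusAlignment, sites: list[VariantSite]) -> np.ndarray:
    """(n_reads, n_sites) base codes; -1 where a read does not cover a site."""
    pos = np.array([s.position for s in sites], dtype=np.int64)
    m = np.full((len(aln.reads), len(sites)), -1, dtype=np.int8)
    for i, r in enumerate(aln.reads):
        covered = (pos >= r.offset) & (pos < r.offset + len(r.seq))
        m[i, covered] = r.seq[pos[covered] - r.offset]
    m[m == N_CODE] = -1
    return m


def phase_reads(
    aln: LocusAlignment,
    sites: list[VariantSite],
    max_iter: int = 25,
    cluster_warn_frac: float = 0.3,
) -> PhaseResult:
    """Partition pooled reads into the two parental haplotype groups.

    The phasing unit is the *fragment*: aligned reads sharing a read id
    (mate pairs) derive from one template molecule, hence one parent, so
    their site coverage is pooled — which is what links diagnostic sites
    that no single read spans. Groups are seeded from the two alleles of
    the highest-depth usable site, then fragments are iteratively
    reassigned to whichever group's consensus allele vector they agree
    with at the majority of the sites they cover; ties and zero overlap
    leave a fragment unassigned. With zero usable sites the pool is
    homogeneous: every read goes to group A.

    Raises :class:`PhasingError` when more than ``cluster_warn_frac`` of
    site-covering fragments fit neither group's consensus — the signature
    of a third haplotype (contamination), which must not be silently
    merged.
    """
    n_reads = len(aln.reads)
    usable = [s for s in sites if not s.multiallelic]
    if not usable:
        return PhaseResult(a=list(range(n_reads)), b=[], unassigned=[], blind_a=[], blind_b=[])

    m_reads = _allele_matrix(aln, usable)

    # collapse mate pairs (same read id) into fragments
    frag_rows: dict[str, list[int]] = {}
    for i, r in enumerate(aln.reads):
        frag_rows.setdefault(r.read_id, []).append(i)
    frag_ids = list(frag_rows)
    n = len(frag_ids)
    m = np.full((n, len(usable)), -1, dtype=np.int8)
    for fi, fid in enumerate(frag_ids):
        for i in frag_rows[fid]:
            row = m_reads[i]
            take = (m[fi] < 0) & (row >= 0)
            m[fi, take] = row[take]

    covers = (m >= 0).sum(axis=1)
    blind = np.flatnonzero(covers == 0)
    covering = np.flatnonzero(covers > 0)

    def consensus_vec(members: np.ndarray) -> np.ndarray:
        """Per-site majority allele over a group; -1 where no votes."""
        out = np.full(len(usable), -1, dtype=np.int8)
        sub = m[members]
        for j in range(len(usable)):
            col = sub[:, j]
            col = col[col >= 0]
            if col.size:
                vals, cnts = np.unique(col, return_counts=True)
                out[j] = vals[np.argmax(cnts)]  # np.unique sorts: ties -> smaller code
        return out

    def disagreement(group: np.ndarray) -> int:
        """Observations disagreeing with their group's per-site majority."""
        cost = 0
        for g in (1, 2):
            sub = m[group == g]
            for j in range(len(usable)):
                col = sub[:, j]
                col = col[col >= 0]
                if col.size:
                    _, cnts = np.unique(col, return_counts=True)
                    cost += int(col.size - cnts.max())
        return cost

    def run_from_seed(seed_idx: int):
        seed_major = BASES.index(usable[seed_idx].major)
        seed_minor = BASES.index(usable[seed_idx].minor)
        group = np.zeros(n, dtype=np.int8)  # 0 unassigned, 1 -> A, 2 -> B
        group[m[:, seed_idx] == seed_major] = 1
        group[m[:, seed_idx] == seed_minor] = 2
        agree_a = agree_b = np.zeros(n)
        for _ in range(max_iter):
            in_a = np.flatnonzero(group == 1)
            in_b = np.flatnonzero(group == 2)
            cons_a = consensus_vec(in_a) if in_a.size else np.full(len(usable), -1, np.int8)
            cons_b = consensus_vec(in_b) if in_b.size else np.full(len(usable), -1, np.int8)
            agree_a = ((m == cons_a[None, :]) & (m >= 0)).sum(axis=1)
            agree_b = ((m == cons_b[None, :]) & (m >= 0)).sum(axis=1)
            new_group = np.zeros(n, dtype=np.int8)
            new_group[(agree_a > agree_b)] = 1
            new_group[(agree_b > agree_a)] = 2
            new_group[covers == 0] = 0
            if np.array_equal(new_group, group):
                break
            group = new_group
        return group, agree_a, agree_b

    # restart from every site (highest-depth first) and keep the partition
    # with the least within-group disagreement; deterministic tie-break on
    # the seed order
    seed_order = sorted(range(len(usable)), key=lambda j: (-usable[j].depth, j))
    group = agree_a = agree_b = None
    best_cost = None
    for seed_idx in seed_order:
        g, aa, ab = run_from_seed(seed_idx)
        cost = disagreement(g)
        if best_cost is None or cost < best_cost:
            group, agree_a, agree_b, best_cost = g, aa, ab, cost

    # contamination guard: fragments that fit neither consensus at most sites
    if covering.size:
        best_agree = np.maximum(agree_a, agree_b)[covering]
        # agreement at no more than half the covered sites marks a fragment
        # that fits neither haplotype (e.g. a chimera or third genotype)
        misfit = best_agree <= 0.5 * covers[covering]
        frac = float(misfit.sum()) / covering.size
        if frac > cluster_warn_frac:
            raise PhasingError(
                f"{frac:.0%} of site-covering fragments fit neither haplotype group "
                f"(> {cluster_warn_frac:.0%}); possible third haplotype"
            )

    def expand(frag_indices) -> list[int]:
        out: list[int] = []
        for fi in frag_indices:
            out.extend(frag_rows[frag_ids[fi]])
        return sorted(out)

    part_a = expand(np.flatnonzero(group == 1))
    part_b = expand(np.flatnonzero(group == 2))
    unassigned = expand([fi for fi in covering if group[fi] == 0])

    # site-blind fragments: split by group support for depth purposes only
    support_a, support_b = len(part_a), len(part_b)
    if support_a + support_b == 0:
        n_to_a = (len(blind) + 1) // 2
    else:
        n_to_a = int(round(len(blind) * support_a / (support_a + support_b)))
    blind_a = expand(blind[:n_to_a])
    blind_b = expand(blind[n_to_a:])
    return PhaseResult(a=part_a, b=part_b, unassigned=unassigned,
                       blind_a=blind_a, blind_b=blind_b)


# ---------------------------------------------------------------- consensus


@dataclass
class HaplotypePair:
    locus_id: str
    hap_a: str
    hap_b: str
    support_a: int
    support_b: int
    depth_a: np.ndarray
    depth_b: np.ndarray


def _group_consensus(
    aln: LocusAlignment,
    members: list[int],
    blind: list[int],
    variant_positions: np.ndarray,
    min_depth: int,
) -> tuple[str, np.ndarray]:
    L = aln.locus.length
    votes = aln.base_counts(members)
    depth = votes[:, :4].sum(axis=1)
    if blind:
        blind_counts = aln.base_counts(blind)
        depth = depth + blind_counts[:, :4].sum(axis=1)
        # site-blind reads add depth everywhere but never vote at variant sites
        blind_counts[variant_positions] = 0
        votes = votes + blind_counts
    votes = votes[:, :4]
    hap = np.full(L, N_CODE, dtype=np.uint8)
    called = (depth >= min_depth) & (votes.sum(axis=1) > 0)
    maj = np.argmax(votes, axis=1)  # argmax takes the lowest index: lexicographic ties
    hap[called] = maj[called].astype(np.uint8)
    n_ties = int((np.sort(votes[called], axis=1)[:, -1] == np.sort(votes[called], axis=1)[:, -2]).sum())
    if n_ties:
        logger.info("%s: %d consensus ties broken lexicographically", aln.locus_id, n_ties)
    return decode(hap), depth


def consensus_haplotypes(
    aln: LocusAlignment,
    partition_a,
    partition_b=None,
    min_depth: int = 25,
    blind_a=(),
    blind_b=(),
    variant_positions=(),
) -> HaplotypePair:
    """Depth-gated majority consensus of each phased read group.

    Per position and group: the majority base if the group's read depth is
    >= ``min_depth`` (strictly below -> ``N``, i.e. depth 24 masks, depth
    25 calls). Ties break to the lexicographically smallest base and are
    logged. An empty partition yields an all-N haplotype.

    ``partition_a``/``partition_b`` may be lists of read indices or a
    :class:`PhaseResult` passed as ``consensus_haplotypes(aln, phase)``.
    """
    if isinstance(partition_a, PhaseResult):
        phase = partition_a
        if partition_b is not None:
            raise ValueError("pass either a PhaseResult or two partitions")
        partition_a, partition_b = phase.a, phase.b
        blind_a, blind_b = phase.blind_a, phase.blind_b
    elif partition_b is None:
        partition_b = []
    set_a, set_b = set(partition_a), set(partition_b)
    if set_a & set_b:
        raise ValueError("partitions must be disjoint")
    vp = np.asarray(list(variant_positions), dtype=np.int64)
    hap_a, depth_a = _group_consensus(aln, list(partition_a), list(blind_a), vp, min_depth)
    hap_b, depth_b = _group_consensus(aln, list(partition_b), list(blind_b), vp, min_depth)
    if not partition_a or not partition_b:
        # expected whenever the two parents share this locus's profile
        logger.debug("%s: empty haplotype partition -> all-N consensus", aln.locus_id)
    return HaplotypePair(
        locus_id=aln.locus_id,
        hap_a=hap_a,
        hap_b=hap_b,
        support_a=len(partition_a) + len(blind_a),
        support_b=len(partition_b) + len(blind_b),
        depth_a=depth_a,
        depth_b=depth_b,
    )


def genotype_pool(
    reads: ReadBatch,
    loci: list[LocusSpec],
    min_identity: float = 0.9,
    min_minor_frac: float = 0.2,
    min_site_depth: int = 10,
    min_depth: int = 25,
    index: AmpliconIndex | None = None,
) -> dict[str, tuple[HaplotypePair, list[VariantSite]]]:
    """Full genotyping of one sporophyte pool: align, call sites, phase,
    and emit a depth-gated haplotype pair per locus."""
    result = align_reads(reads, loci, min_identity=min_identity, index=index)
    out: dict[str, tuple[HaplotypePair, list[VariantSite]]] = {}
    for locus in loci:
        aln = result[locus.locus_id]
        if not aln.reads:
            empty = "N" * locus.length
            out[locus.locus_id] = (
                HaplotypePair(locus.locus_id, empty, empty, 0, 0,
                              np.zeros(locus.length, np.int64), np.zeros(locus.length, np.int64)),
                [],
            )
            continue
        sites = call_variant_sites(aln, min_minor_frac=min_minor_frac,
                                   min_site_depth=min_site_depth)
        phase = phase_reads(aln, sites)
        pair = consensus_haplotypes(
            aln, phase.a, phase.b, min_depth=min_depth,
            blind_a=phase.blind_a, blind_b=phase.blind_b,
            variant_positions=[s.position for s in sites],
        )
        out[locus.locus_id] = (pair, sites)
    return out


# ------------------------------------------------------------------ exports


def write_sam(aln: LocusAlignment, phase: PhaseResult, path) -> None:
    """Minimal SAM export with read-group tags hapA/hapB/unassigned."""
    group_of = {}
    for i in phase.a + phase.blind_a:
        group_of[i] = "hapA"
    for i in phase.b + phase.blind_b:
        group_of[i] = "hapB"
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{aln.locus_id}\tLN:{aln.locus.length}\n")
        for rg in ("hapA", "hapB", "unassigned"):
            fh.write(f"@RG\tID:{rg}\tSM:pool\n")
        for i, r in enumerate(aln.reads):
            flag = 16 if r.strand == -1 else 0
            qual = "".join(chr(int(q) + 33) for q in r.qual)
            fh.write(
                f"{r.read_id}\t{flag}\t{aln.locus_id}\t{r.offset + 1}\t60\t"
                f"{len(r.seq)}M\t*\t0\t0\t{decode(r.seq)}\t{qual}\t"
                f"RG:Z:{group_of.get(i, 'unassigned')}\n"
            )


def write_vcf(sites: list[VariantSite], loci: list[LocusSpec], path) -> None:
    """Minimal VCF export of detected variant sites (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for locus in loci:
            fh.write(f"##contig=<ID={locus.locus_id},length={locus.length}>\n")
        fh.write("##INFO=<ID=DP,Number=1,Type=Integer,Description=\"Aligned depth\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sites:
            flt = "multiallelic" if s.multiallelic else "PASS"
            fh.write(
                f"{s.locus_id}\t{s.position + 1}\t.\t{s.major}\t{s.minor}\t.\t{flt}\tDP={s.depth}\n"
            )
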