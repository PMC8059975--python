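"""Synthetic mesocosm generator.

Emulates the statistical structure of a moss mating experiment in which
haploid male gametophytes grow in a central disc and haploid females in the
surrounding annulus of a round pot. Sporophytes (diploid offspring) arise
from a mother × father cross; the distance of each sporophyte from the pot
centre is a proxy for sperm dispersal and is drawn from a per-father
dispersal kernel truncated to the annulus. Progeny of one sporophyte are
pooled before sequencing, so at each amplicon locus a pool contains reads
from exactly the two parental haplotypes.

Everything downstream (demultiplexing, trimming, phasing, consensus,
parentage, statistics) is exercised against this generator, whose truth
records and per-read source sidecar make every result checkable.

Default study conditions: 9 females + 6 males, 5 amplicon loci with 3
diagnostic SNPs each, 8 mesocosms per treatment arm, paired 2 x 250 bp
reads, and a lognormal dispersal kernel (median ~10 cm) truncated to the
annulus between the 5.25 cm male disc edge and the 18 cm pot wall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ReadBatch
from .panel import FEMALE, MALE, LocusSpec, Parent, ParentPanel
from .util import child_seed, decode, encode, revcomp

ARTHROPOD = "arthropod"
CONTROL = "control"

# stage tags for fanning one run seed out to independent substreams
_STAGE_PANEL, _STAGE_CROSS, _STAGE_READS, _STAGE_INDEX, _STAGE_TRAITS = 1, 2, 3, 4, 5


# --------------------------------------------------------------------- panel


def simulate_panel(
    n_males: int,
    n_females: int,
    n_loci: int = 5,
    locus_length: int = 300,
    snps_per_locus: int = 3,
    force_ambiguous_female_pair: bool = False,
    seed: int = 0,
) -> ParentPanel:
    """Draw a parent panel with diagnostic biallelic SNPs.

    Every parent receives a distinct multi-locus allele vector over the
    ``n_loci * snps_per_locus`` variant positions, so any two parents are
    distinguishable at >= 1 position — except, when
    ``force_ambiguous_female_pair`` is set, the last two females, which
    share one vector and therefore form an ambiguity group (the "F6'"
    situation).

    Raises ValueError when the biallelic SNP capacity ``2**(n_loci *
    snps_per_locus)`` cannot give every parent a distinct vector.
    """
    if n_males < 2 or n_females < 2:
        raise ValueError("need at least 2 parents of each sex")
    if n_loci < 1 or snps_per_locus < 1:
        raise ValueError("need n_loci >= 1 and snps_per_locus >= 1")
    if force_ambiguous_female_pair and n_females < 2:
        raise ValueError("forced ambiguous pair requires >= 2 females")

    rng = np.random.default_rng(seed)
    n_parents = n_males + n_females
    n_distinct = n_parents - (1 if force_ambiguous_female_pair else 0)
    k = n_loci * snps_per_locus
    if k < 63 and 2**k < n_distinct:
        raise ValueError(
            f"{k} biallelic diagnostic SNPs can distinguish at most 2**{k} "
            f"parents; {n_distinct} distinct genotypes requested"
        )

    margin = 10  # keep diagnostic sites away from the extreme amplicon ends
    loci: list[LocusSpec] = []
    alts: list[list[tuple[int, str]]] = []  # per locus: (pos, alt_base)
    for j in range(n_loci):
        ref = rng.integers(0, 4, locus_length).astype(np.uint8)
        positions = np.sort(
            rng.choice(np.arange(margin, locus_length - margin), size=snps_per_locus, replace=False)
        )
        ref_str = decode(ref)
        locus = LocusSpec(
            locus_id=f"L{j + 1}",
            length=locus_length,
            reference_seq=ref_str,
            variant_positions=tuple(int(p) for p in positions),
        )
        loci.append(locus)
        alt_list = []
        for p in positions:
            choices = [b for b in "ACGT" if b != ref_str[p]]
            alt_list.append((int(p), choices[rng.integers(0, 3)]))
        alts.append(alt_list)

    # distinct allele vectors over all variant positions
    if k <= 24:
        codes = rng.choice(2**k, size=n_distinct, replace=False)
    else:
        seen: set[int] = set()
        codes = []
        while len(codes) < n_distinct:
            c = int(rng.integers(0, 2**k))
            if c not in seen:
                seen.add(c)
                codes.append(c)
        codes = np.asarray(codes)
    vectors = [[(int(c) >> b) & 1 for b in range(k)] for c in codes]

    ids = [f"M{i + 1}" for i in range(n_males)] + [f"F{i + 1}" for i in range(n_females)]
    sexes = [MALE] * n_males + [FEMALE] * n_females
    assigned = list(vectors)
    if force_ambiguous_female_pair:
        assigned = assigned + [assigned[-1]]  # last two females share a vector

    parents = []
    for pid, sex, vec in zip(ids, sexes, assigned):
        haps = {}
        off = 0
        for locus, alt_list in zip(loci, alts):
            hap = list(locus.reference_seq)
            for (pos, alt), bit in zip(alt_list, vec[off : off + len(alt_list)]):
                if bit:
                    hap[pos] = alt
            off += len(alt_list)
            haps[locus.locus_id] = "".join(hap)
        parents.append(Parent(parent_id=pid, sex=sex, haplotypes=haps))
    return ParentPanel(parents, loci)


# ------------------------------------------------------------------- design


@dataclass(frozen=True)
class DispersalKernel:
    """Sperm dispersal distance model (cm from the pot centre).

    For the lognormal family ``mu``/``sigma`` parameterise log-distance;
    for the normal family they are the distance mean/sd directly. Defaults
    give a median dispersal of ~10 cm, comfortably inside the annulus
    between the male disc edge (5.25 cm) and the pot wall (18 cm).
    """

    family: str = "lognormal"
    mu: float = 2.3
    sigma: float = 0.4

    def __post_init__(self):
        if self.family not in ("lognormal", "normal"):
            raise ValueError("kernel family must be 'lognormal' or 'normal'")
        if self.sigma <= 0:
            raise ValueError("kernel sigma must be positive")

    def _dist(self):
        if self.family == "lognormal":
            return sps.lognorm(s=self.sigma, scale=math.exp(self.mu))
        return sps.norm(loc=self.mu, scale=self.sigma)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "lognormal":
            return rng.lognormal(self.mu, self.sigma, size=n)
        return rng.normal(self.mu, self.sigma, size=n)

    def cdf(self, x) -> np.ndarray:
        return self._dist().cdf(x)

    def sample_truncated(self, n: int, rng: np.random.Generator,
                         lo: float, hi: float, max_rounds: int = 200) -> np.ndarray:
        """Rejection-sample the kernel restricted to [lo, hi]."""
        out = np.empty(0)
        for _ in range(max_rounds):
            if out.size >= n:
                break
            draw = self.sample(max(2 * (n - out.size), 64), rng)
            out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
        if out.size < n:
            raise RuntimeError(
                f"kernel places too little mass in [{lo}, {hi}] for rejection sampling"
            )
        return out[:n]


@dataclass
class MesocosmDesign:
    """Crossing design of one experiment (both treatment arms).

    ``n_sporophytes`` is either an integer (a fixed experiment-wide total,
    split across mesocosms in proportion to the treatment effect) or a float
    (a per-control-mesocosm Poisson rate; arthropod mesocosms use rate x
    ``treatment_effect``). ``fertility_weights`` gives relative fertility
    per parent; fathers in the arthropod arm may use the distinct
    ``arthropod_father_weights``, which is what lets treatment flip the
    rank order of male fitness.
    """

    female_ids: list[str]
    male_ids: list[str]
    fertility_weights: dict = field(default_factory=dict)
    dispersal: DispersalKernel | dict = field(default_factory=DispersalKernel)
    n_sporophytes: int | float = 100
    treatment_effect: float = 839 / 228
    arthropod_father_weights: dict | None = None
    n_mesocosms_per_treatment: int = 8
    disc_radius: float = 5.25
    pot_radius: float = 18.0

    def __post_init__(self):
        if not self.disc_radius < self.pot_radius:
            raise ValueError("disc_radius must be smaller than pot_radius")
        if self.treatment_effect <= 0:
            raise ValueError("treatment_effect must be positive")
        for sex_ids, label in ((self.female_ids, "female"), (self.male_ids, "male")):
            if not sex_ids:
                raise ValueError(f"no {label} ids in design")
            w = [self.fertility_weights.get(i, 1.0) for i in sex_ids]
            if any(x < 0 for x in w):
                raise ValueError("fertility weights must be non-negative")
            if sum(w) == 0:
                raise ValueError(f"all {label} fertility weights are zero")

    def kernel_for(self, male_id: str) -> DispersalKernel:
        if isinstance(self.dispersal, DispersalKernel):
            return self.dispersal
        return self.dispersal[male_id]

    def father_weights(self, treatment: str) -> np.ndarray:
        src = self.fertility_weights
        if treatment == ARTHROPOD and self.arthropod_father_weights is not None:
            src = self.arthropod_father_weights
        w = np.array([src.get(m, 1.0) for m in self.male_ids], dtype=float)
        if w.sum() == 0:
            raise ValueError("all father weights are zero in one treatment arm")
        return w / w.sum()

    def mother_weights(self) -> np.ndarray:
        w = np.array([self.fertility_weights.get(f, 1.0) for f in self.female_ids], dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class TruthRecord:
    sporophyte_id: str
    mesocosm_id: str
    treatment: str
    mother_id: str
    father_id: str
    distance_cm: float
    angle_deg: float


def truth_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sporophyte_id": [t.sporophyte_id for t in truth],
            "mesocosm_id": [t.mesocosm_id for t in truth],
            "treatment": [t.treatment for t in truth],
            "mother_id": [t.mother_id for t in truth],
            "father_id": [t.father_id for t in truth],
            "distance_cm": [t.distance_cm for t in truth],
            "angle_deg": [t.angle_deg for t in truth],
        }
    )


def simulate_crosses(panel: ParentPanel, design: MesocosmDesign, seed: int = 0) -> list[TruthRecord]:
    """Draw the mother, father, position and mesocosm of every sporophyte."""
    unknown = (set(design.female_ids) | set(design.male_ids)) - set(panel.parent_ids)
    if unknown:
        raise ValueError(f"design references parents not in panel: {sorted(unknown)}")
    females = [f for f in design.female_ids if panel.sex_of(f) == FEMALE]
    males = [m for m in design.male_ids if panel.sex_of(m) == MALE]
    if len(females) != len(design.female_ids) or len(males) != len(design.male_ids):
        raise ValueError("design sex labels disagree with panel")

    rng = np.random.default_rng(child_seed(seed, _STAGE_CROSS))
    m = design.n_mesocosms_per_treatment
    mesocosms = [(f"A{i + 1}", ARTHROPOD) for i in range(m)] + [
        (f"C{i + 1}", CONTROL) for i in range(m)
    ]
    mult = np.array([design.treatment_effect if t == ARTHROPOD else 1.0 for _, t in mesocosms])

    if isinstance(design.n_sporophytes, (int, np.integer)):
        counts = rng.multinomial(int(design.n_sporophytes), mult / mult.sum())
    else:
        counts = rng.poisson(float(design.n_sporophytes) * mult)

    mother_w = design.mother_weights()
    truth: list[TruthRecord] = []
    serial = 0
    for (mes_id, treatment), n in zip(mesocosms, counts):
        if n == 0:
            continue
        father_w = design.father_weights(treatment)
        mothers = rng.choice(len(females), size=n, p=mother_w)
        fathers = rng.choice(len(males), size=n, p=father_w)
        angles = rng.uniform(0.0, 360.0, size=n)
        # distances drawn per father so each male can carry its own kernel
        distances = np.empty(n)
        for fi in np.unique(fathers):
            sel = fathers == fi
            kern = design.kernel_for(males[fi])
            distances[sel] = kern.sample_truncated(
                int(sel.sum()), rng, design.disc_radius, design.pot_radius
            )
        for i in range(n):
            serial += 1
            truth.append(
                TruthRecord(
                    sporophyte_id=f"S{serial:04d}",
                    mesocosm_id=mes_id,
                    treatment=treatment,
                    mother_id=females[mothers[i]],
                    father_id=males[fathers[i]],
                    distance_cm=float(distances[i]),
                    angle_deg=float(angles[i]),
                )
            )
    return truth


# -------------------------------------------------------------------- reads


@dataclass(frozen=True)
class QualityModel:
    """Phred profile: linear decay from ``q_start`` at the 5' end to
    ``q_end`` at the 3' end, Gaussian jitter, clamped to [2, 40]."""

    q_start: float = 38.0
    q_end: float = 32.0
    jitter_sd: float = 3.0

    def sample(self, n_reads: int, read_length: int, rng: np.random.Generator) -> np.ndarray:
        profile = np.linspace(self.q_start, self.q_end, read_length)
        q = profile[None, :] + rng.normal(0.0, self.jitter_sd, size=(n_reads, read_length))
        return np.clip(np.rint(q), 2, 40).astype(np.uint8)


def _apply_substitutions(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. per-base substitution errors, uniform over the 3 other bases."""
    if rate <= 0:
        return seq
    mask = rng.random(seq.shape) < rate
    shift = rng.integers(1, 4, size=seq.shape, dtype=np.uint8)
    out = seq.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def _mutate_indexes(index: str, n: int, rate: float, rng: np.random.Generator) -> list[str]:
    """n copies of an index sequence with per-base substitution errors."""
    if rate <= 0:
        return [index] * n
    codes = np.tile(encode(index), (n, 1))
    codes = _apply_substitutions(codes, rate, rng)
    flat = decode(codes.ravel())
    w = len(index)
    return [flat[i * w : (i + 1) * w] for i in range(n)]


def simulate_pool_reads(
    panel: ParentPanel,
    truth: TruthRecord,
    depth_per_locus: int = 100,
    read_length: int = 250,
    substitution_error: float = 0.005,
    quality: QualityModel = QualityModel(),
    index_pair: tuple[str, str] | None = None,
    index_error_rate: float = 0.001,
    seed: int = 0,
    paired: bool = True,
    parent_skew: float = 0.0,
) -> tuple[ReadBatch, pd.DataFrame]:
    """Simulate the pooled-progeny amplicon reads of one sporophyte.

    ``depth_per_locus`` counts sequenced fragments per locus; paired mode
    emits an R1 anchored at the amplicon start and a reverse-complemented
    R2 anchored at the amplicon end for each fragment (amplicon reads start
    at the primer sites, so coverage is uniform rather than randomly
    tiled). Each fragment derives from the maternal or paternal haplotype
    with probability 0.5 +/- ``parent_skew``.

    Returns the reads and a truth sidecar (one row per fragment recording
    its source parent).
    """
    if not 0 <= substitution_error < 0.25:
        raise ValueError("substitution_error must be in [0, 0.25)")
    if depth_per_locus < 1:
        raise ValueError("depth_per_locus must be >= 1")
    if not -0.5 <= parent_skew <= 0.5:
        raise ValueError("parent_skew must be in [-0.5, 0.5]")
    short = [l.locus_id for l in panel.loci if read_length > l.length]
    if short:
        raise ValueError(
            f"read_length {read_length} exceeds locus length for {short} "
            "and no padding policy is configured"
        )

    rng = np.random.default_rng(child_seed(seed, _STAGE_READS))
    i5, i7 = index_pair if index_pair is not None else ("", "")
    batches: list[ReadBatch] = []
    sidecar_rows = []
    for locus in panel.loci:
        mother = encode(panel.haplotype(truth.mother_id, locus.locus_id))
        father = encode(panel.haplotype(truth.father_id, locus.locus_id))
        n = depth_per_locus
        from_mother = rng.random(n) < (0.5 + parent_skew)

        segments = [(1, slice(0, read_length), False)]
        if paired:
            segments.append((2, slice(locus.length - read_length, locus.length), True))

        for mate, sl, rc in segments:
            template = np.where(from_mother[:, None], mother[sl][None, :], father[sl][None, :])
            if rc:
                template = template[:, ::-1]
                template = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[template]
            seq = _apply_substitutions(template.astype(np.uint8), substitution_error, rng)
            qual = quality.sample(n, read_length, rng)
            ids = [f"{truth.sporophyte_id}:{locus.locus_id}:{i:04d}" for i in range(n)]
            i5s = _mutate_indexes(i5, n, index_error_rate, rng) if i5 else None
            i7s = _mutate_indexes(i7, n, index_error_rate, rng) if i7 else None
            batches.append(
                ReadBatch(
                    ids=ids,
                    seq=seq,
                    qual=qual,
                    length=np.full(n, read_length, np.int32),
                    i5=i5s,
                    i7=i7s,
                    mate=np.full(n, mate, np.uint8),
                )
            )
        sidecar_rows.extend(
            {
                "read_id": f"{truth.sporophyte_id}:{locus.locus_id}:{i:04d}",
                "sporophyte_id": truth.sporophyte_id,
                "locus_id": locus.locus_id,
                "source_parent": truth.mother_id if from_mother[i] else truth.father_id,
            }
            for i in range(n)
        )
    return ReadBatch.concat(batches), pd.DataFrame(sidecar_rows)


# ------------------------------------------------------------ dual indexing


def generate_index_set(n: int, rng: np.random.Generator, length: int = 8,
                       min_dist: int = 3) -> list[str]:
    """Random index sequences with pairwise Hamming distance >= ``min_dist``,
    so one-mismatch demultiplexing is collision-free."""
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 20000 * max(n, 1):
            raise RuntimeError("could not build an index set at the requested distance")
        cand = rng.integers(0, 4, length).astype(np.uint8)
        if all(int(np.count_nonzero(cand != c)) >= min_dist for c in chosen):
            chosen.append(cand)
    return [decode(c) for c in chosen]


def make_sample_sheet(truth: list[TruthRecord], seed: int = 0) -> pd.DataFrame:
    """Assign a unique (i5, i7) dual-index pair to every sporophyte.

    Uses combinatorial dual indexing: two pools of indexes (each with
    internal pairwise distance >= 3) crossed to produce unique pairs, as in
    a typical several-hundred-library amplicon run.
    """
    columns = ["sample_id", "i5_index", "i7_index", "mesocosm_id",
               "treatment", "distance_cm", "angle_deg"]
    if not truth:
        return pd.DataFrame(columns=columns)
    rng = np.random.default_rng(child_seed(seed, _STAGE_INDEX))
    n = len(truth)
    side = max(2, math.ceil(math.sqrt(n)))
    i5_pool = generate_index_set(side, rng)
    i7_pool = generate_index_set(side, rng)
    rows = []
    for k, t in enumerate(truth):
        rows.append(
            {
                "sample_id": t.sporophyte_id,
                "i5_index": i5_pool[k // side],
                "i7_index": i7_pool[k % side],
                "mesocosm_id": t.mesocosm_id,
                "treatment": t.treatment,
                "distance_cm": t.distance_cm,
                "angle_deg": t.angle_deg,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- traits


def simulate_traits(
    truth: list[TruthRecord],
    seed: int = 0,
    height_mean_mm: float = 25.0,
    height_sd_mm: float = 4.0,
    father_height_sd_mm: float = 2.0,
    spore_count_mean: float = 4000.0,
    germination_alpha: float = 8.0,
    germination_beta: float = 2.0,
) -> pd.DataFrame:
    """Per-sporophyte offspring traits (height, spore count, germination).

    Heights get a random per-father intercept so paternal effects are
    recoverable by ANOVA; spore counts are Poisson around a lognormal
    per-sporophyte rate; germination fractions are Beta distributed.
    """
    rng = np.random.default_rng(child_seed(seed, _STAGE_TRAITS))
    fathers = sorted({t.father_id for t in truth})
    father_fx = dict(zip(fathers, rng.normal(0.0, father_height_sd_mm, len(fathers))))
    rows = []
    for t in truth:
        lam = spore_count_mean * rng.lognormal(0.0, 0.3)
        rows.append(
            {
                "sporophyte_id": t.sporophyte_id,
                "height_mm": max(
                    1.0, height_mean_mm + father_fx[t.father_id] + rng.normal(0, height_sd_mm)
                ),
                "spore_count": int(rng.poisson(lam)),
                "germination_frac": float(rng.beta(germination_alpha, germination_beta)),
                "distance_cm": t.distance_cm,
                "treatment": t.treatment,
                "mother": t.mother_id,
                "father": t.father_id,
            }
        )
    return pd.DataFrame(rows)
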