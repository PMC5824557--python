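"""Synthetic full-sib crosses and rearranged comparison genomes.

Everything the mapping pipeline consumes can be simulated here with known
ground truth: a true map (linkage groups with locus positions in cM), a
full-sib family segregating CP-type markers with genotyping error and
missingness, comparison-genome anchor positions with configurable
inversions/translocations, and external feature sequences falling inside
(or outside) the induced synteny blocks.

The crossover process is a Poisson point process along each linkage group
(one event per Morgan on average), i.e. Haldane's no-interference model,
which keeps the simulator analytically checkable: the expected observed
recombination fraction between loci d cM apart is ``(1 - exp(-d/50)) / 2``.
A chi-square interference model is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .markers import FamilyData, MarkerGenotypes, SegType, producible_genotypes

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

# canonical parental allele pairs of each CP segregation type
SEG_PARENTS = {
    SegType.AB_CD: (("a", "b"), ("c", "d")),
    SegType.EF_EG: (("e", "f"), ("e", "g")),
    SegType.HK_HK: (("h", "k"), ("h", "k")),
    SegType.LM_LL: (("l", "m"), ("l", "l")),
    SegType.NN_NP: (("n", "n"), ("n", "p")),
}


@dataclass
class TrueMap:
    """Ground-truth map: per LG, ordered locus ids with true cM positions."""

    linkage_groups: list  # of (lg_id, length_cM, [(locus_id, cM), ...])

    def __post_init__(self):
        seen = set()
        for lg_id, length, loci in self.linkage_groups:
            pos = [p for _, p in loci]
            if any(b < a for a, b in zip(pos, pos[1:])):
                raise ValueError(f"{lg_id}: positions must be non-decreasing")
            if pos and pos[0] != 0:
                raise ValueError(f"{lg_id}: first position must be 0")
            for l, _ in loci:
                if l in seen:
                    raise ValueError(f"duplicate locus id {l}")
                seen.add(l)

    @property
    def lg_ids(self) -> list:
        return [lg for lg, _, _ in self.linkage_groups]

    @property
    def locus_ids(self) -> list:
        return [l for _, _, loci in self.linkage_groups for l, _ in loci]

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def total_length(self) -> float:
        return float(sum(length for _, length, _ in self.linkage_groups))

    def positions(self) -> dict:
        """locus_id -> (lg_id, cM)."""
        return {
            l: (lg, p)
            for lg, _, loci in self.linkage_groups
            for l, p in loci
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (l, lg, p)
            for lg, _, loci in self.linkage_groups
            for l, p in loci
        ]
        return pd.DataFrame(rows, columns=["locus_id", "lg", "position_cM"])


@dataclass
class CrossSpec:
    """Parameters of one simulated full-sib cross.

    Defaults emulate the mapping-family design the pipeline targets:
    ~160 genotyped offspring per cross, a mix of one- and two-parent
    informative CP marker types dominated by single-parent types (as is
    typical for reduced-representation SNP data in outbred crosses),
    0.5% genotyping error and 5% missing calls.
    """

    n_offspring: int = 160
    seg_type_mix: dict = field(default_factory=lambda: {
        SegType.AB_CD: 0.10,
        SegType.EF_EG: 0.15,
        SegType.HK_HK: 0.25,
        SegType.LM_LL: 0.25,
        SegType.NN_NP: 0.25,
    })
    error_rate: float = 0.005
    missing_rate: float = 0.05
    crossover_model: str = "haldane"  # "haldane" | "chi2-interference"
    seed: int = 0

    def __post_init__(self):
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        tot = sum(self.seg_type_mix.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("seg_type_mix proportions must sum to 1")
        for r in (self.error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.crossover_model not in ("haldane", "chi2-interference"):
            raise ValueError(f"unknown crossover model {self.crossover_model!r}")


@dataclass
class SimTruth:
    """Everything recorded pre-noise for one simulated family."""

    true_map: TrueMap
    breakpoints: dict  # (offspring_id, parent) -> {lg_id: sorted cM array}
    gamete_start: dict  # (offspring_id, parent) -> {lg_id: 0|1}
    true_family: FamilyData  # error-free, complete genotype matrix
    seg_types: dict  # locus_id -> SegType


@dataclass
class RearrangementSpec:
    """Structural differences between the mapped genome and a comparison
    genome: inversions and translocations of cM intervals, plus the physical
    scale (bp per cM) used to lay anchors down."""

    events: list = field(default_factory=list)
    # events: ("inversion", lg_id, (lo_cM, hi_cM)) or
    #         ("translocation", lg_id, (lo_cM, hi_cM), target_chromosome)
    bp_per_cM: float = 500_000.0
    genome_id: str = "simgenome"

    def __post_init__(self):
        if self.bp_per_cM <= 0:
            raise ValueError("bp_per_cM must be positive")
        by_lg: dict = {}
        for ev in self.events:
            kind, lg, iv = ev[0], ev[1], ev[2]
            if kind not in ("inversion", "translocation"):
                raise ValueError(f"unknown event kind {kind!r}")
            if iv[0] >= iv[1]:
                raise ValueError("event interval must have lo < hi")
            for lo, hi in by_lg.get(lg, []):
                if iv[0] < hi and lo < iv[1]:
                    raise ValueError(f"overlapping events on {lg}")
            by_lg.setdefault(lg, []).append(iv)


@dataclass
class TrueBlock:
    """A ground-truth syntenic block: ordered (by cM) anchored members."""

    lg: str
    chromosome: str
    orientation: str  # "+" | "-"
    members: list  # of (locus_id, cM, bp)

    @property
    def locus_ids(self) -> tuple:
        return tuple(l for l, _, _ in self.members)


def simulate_true_map(
    n_lg: int,
    lengths_cM: Sequence[float] | float,
    loci_per_lg: int,
    seed: int = 0,
) -> TrueMap:
    """Lay ``loci_per_lg`` loci per linkage group: the first locus anchors
    0 cM, the rest fall uniformly at random along the group (sorted)."""
    if n_lg < 1:
        raise ValueError("n_lg must be >= 1")
    if np.isscalar(lengths_cM):
        lengths = [float(lengths_cM)] * n_lg
    else:
        lengths = [float(x) for x in lengths_cM]
        if len(lengths) != n_lg:
            raise ValueError("lengths_cM must have n_lg entries")
    if any(x <= 0 for x in lengths):
        raise ValueError("LG lengths must be positive")
    if loci_per_lg < 1:
        raise ValueError("loci_per_lg must be >= 1")
    rng = np.random.default_rng(seed)
    groups = []
    for g, length in enumerate(lengths, start=1):
        pos = np.sort(rng.uniform(0.0, length, size=loci_per_lg - 1))
        pos = np.concatenate([[0.0], pos])
        loci = [(f"LG{g:02d}_L{i:04d}", float(p)) for i, p in enumerate(pos, start=1)]
        groups.append((f"LG{g}", length, loci))
    return TrueMap(groups)


def _crossover_points(rng: np.random.Generator, length_cM: float, model: str) -> np.ndarray:
    if model == "haldane":
        k = rng.poisson(length_cM / 100.0)
        return np.sort(rng.uniform(0.0, length_cM, size=k))
    # chi2-interference: gamma(shape=2) inter-event distances on the
    # four-strand bundle, thinned by 1/2 to the recovered chromatid
    pts, x = [], 0.0
    while True:
        x += rng.gamma(2.0, 25.0)  # mean 50 cM between bundle events
        if x > length_cM:
            break
        if rng.random() < 0.5:
            pts.append(x)
    return np.asarray(pts)


def _gamete_indices(
    rng: np.random.Generator, positions: np.ndarray, length: float, model: str
) -> tuple[int, np.ndarray, np.ndarray]:
    """One meiosis along a LG: returns (start strand, breakpoints,
    transmitted allele index per locus)."""
    start = int(rng.integers(2))
    bps = _crossover_points(rng, length, model)
    n_before = np.searchsorted(bps, positions, side="right")
    return start, bps, (start + n_before) % 2


def simulate_family(truth: TrueMap, spec: CrossSpec) -> tuple[FamilyData, SimTruth]:
    """Simulate one full-sib family on a true map.

    Each offspring receives one recombinant gamete per parent; crossovers
    per meiosis per LG are Poisson(length in Morgans) under the default
    no-interference model. Genotyping errors (symmetric re-draw among the
    genotypes producible for the locus's segregation type) and missingness
    are applied independently per call; the returned :class:`SimTruth`
    records the noise-free matrix and every breakpoint.
    """
    rng = np.random.default_rng(spec.seed)
    offspring_ids = [f"{'off'}{i + 1:03d}" for i in range(spec.n_offspring)]

    seg_types_order = list(spec.seg_type_mix)
    probs = np.array([spec.seg_type_mix[t] for t in seg_types_order])

    seg_of: dict = {}
    for lg_id, length, loci in truth.linkage_groups:
        draws = rng.choice(len(seg_types_order), size=len(loci), p=probs)
        for (locus, _), d in zip(loci, draws):
            seg_of[locus] = seg_types_order[d]

    # meioses: per offspring x parent x LG
    breakpoints: dict = {}
    starts: dict = {}
    maternal_idx: dict = {}  # lg_id -> (n_off, n_loci) array
    paternal_idx: dict = {}
    for lg_id, length, loci in truth.linkage_groups:
        pos = np.array([p for _, p in loci])
        mi = np.empty((spec.n_offspring, len(loci)), dtype=np.int8)
        pi = np.empty_like(mi)
        for o, oid in enumerate(offspring_ids):
            for parent, arr in (("mother", mi), ("father", pi)):
                start, bps, idx = _gamete_indices(rng, pos, length, spec.crossover_model)
                arr[o] = idx
                breakpoints.setdefault((oid, parent), {})[lg_id] = bps
                starts.setdefault((oid, parent), {})[lg_id] = start
        maternal_idx[lg_id] = mi
        paternal_idx[lg_id] = pi

    clean = FamilyData("sim", offspring_ids)
    noisy = FamilyData("sim", offspring_ids)
    for lg_id, length, loci in truth.linkage_groups:
        mi, pi = maternal_idx[lg_id], paternal_idx[lg_id]
        for j, (locus, _) in enumerate(loci):
            seg = seg_of[locus]
            mother, father = SEG_PARENTS[seg]
            calls = [
                tuple(sorted((mother[mi[o, j]], father[pi[o, j]])))
                for o in range(spec.n_offspring)
            ]
            clean.add(MarkerGenotypes(locus, locus, "sim", mother, father, list(calls)))
            possible = producible_genotypes(mother, father)
            noisy_calls: list = []
            for c in calls:
                g = tuple(sorted(c))
                if spec.error_rate > 0 and rng.random() < spec.error_rate and len(possible) > 1:
                    alts = [x for x in possible if x != g]
                    g = alts[int(rng.integers(len(alts)))]
                if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
                    g = None
                noisy_calls.append(g)
            noisy.add(MarkerGenotypes(locus, locus, "sim", mother, father, noisy_calls))

    sim_truth = SimTruth(truth, breakpoints, starts, clean, seg_of)
    return noisy, sim_truth


def _event_for(events_on_lg: list, cM: float):
    for i, ev in enumerate(events_on_lg):
        lo, hi = ev[2]
        if lo <= cM <= hi:
            return i, ev
    return None, None


def simulate_genome_anchors(
    truth: TrueMap,
    spec: RearrangementSpec,
    seed: int = 0,
    min_block: int = 2,
) -> tuple[pd.DataFrame, list]:
    """Anchor every locus on a comparison genome collinear with its cM
    position, except inside rearranged intervals, and emit a 12-column
    similarity-hit table plus the ground-truth block list.

    Chromosome ``chrN`` corresponds to the N-th linkage group; bp positions
    are 1-based, ``cM * bp_per_cM + 1`` before rearrangement. Inversions
    reflect bp within their interval; translocations move the interval's
    loci to the target chromosome (internal order preserved).
    """
    del seed  # anchor layout is deterministic; parameter kept for API symmetry
    s = spec.bp_per_cM
    base_chr = {lg: f"chr{i + 1}" for i, (lg, _, _) in enumerate(truth.linkage_groups)}
    chrom_max_bp: dict = {}
    records = []  # (locus, lg, cM, chromosome, bp, label, orientation)
    for lg_id, length, loci in truth.linkage_groups:
        events_on_lg = [ev for ev in spec.events if ev[1] == lg_id]
        for locus, cM in loci:
            bp = int(round(cM * s)) + 1
            chrom = base_chr[lg_id]
            label: Optional[int] = None
            orient = "+"
            i, ev = _event_for(events_on_lg, cM)
            if ev is not None:
                label = i
                lo, hi = ev[2]
                if ev[0] == "inversion":
                    bp = int(round(lo * s)) + int(round(hi * s)) + 2 - bp
                    orient = "-"
                else:  # translocation
                    chrom = ev[3]
                    bp = int(round((cM - lo) * s)) + 1  # offset applied below
            records.append([locus, lg_id, cM, chrom, bp, label, orient])
        chrom_max_bp[base_chr[lg_id]] = int(round(length * s)) + 1

    # offset translocated intervals beyond existing content on the target
    for lg_id, _, _ in truth.linkage_groups:
        for ev in spec.events:
            if ev[0] == "translocation" and ev[1] == lg_id:
                target = ev[3]
                offset = chrom_max_bp.get(target, 0) + 1_000_000
                span = 0
                for r in records:
                    if r[1] == lg_id and r[5] is not None and r[3] == target:
                        i, e = _event_for([x for x in spec.events if x[1] == lg_id], r[2])
                        if e is ev:
                            r[4] += offset
                            span = max(span, r[4])
                chrom_max_bp[target] = max(chrom_max_bp.get(target, 0), span)

    # ground-truth blocks: maximal runs of loci with the same event label
    blocks: list[TrueBlock] = []
    for lg_id, _, loci in truth.linkage_groups:
        recs = [r for r in records if r[1] == lg_id]
        run: list = []
        run_label: object = "sentinel"
        for r in recs:
            if r[5] != run_label and run_label != "sentinel":
                if len(run) >= min_block:
                    blocks.append(
                        TrueBlock(lg_id, run[0][3], run[0][6], [(x[0], x[2], x[4]) for x in run])
                    )
                run = []
            run_label = r[5]
            run.append(r)
        if len(run) >= min_block:
            blocks.append(
                TrueBlock(lg_id, run[0][3], run[0][6], [(x[0], x[2], x[4]) for x in run])
            )

    qlen = 150
    rows = []
    for locus, _, _, chrom, bp, _, _ in records:
        rows.append([locus, chrom, 100.0, qlen, 0, 0, 1, qlen, bp, bp + qlen - 1, 1e-80, 280.0])
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return hits, blocks


def simulate_external_features(
    true_blocks: list,
    n_inside: int,
    n_outside: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop external feature sequences onto the comparison genome.

    Inside-features land strictly between two adjacent anchored loci of a
    randomly chosen block; their true cM is the bp-fraction linear
    interpolation between the flanks. Outside-features land far beyond any
    anchored region of a block's chromosome. Returns the 12-column feature
    hit table and a truth table (feature_id, lg, true_cM; empty for
    outside features).
    """
    if n_inside > 0 and not true_blocks:
        raise ValueError("need at least one block to place inside-features")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    usable = [b for b in true_blocks if len(b.members) >= 2]
    if n_inside > 0 and not usable:
        raise ValueError("no block with >= 2 members")
    for i in range(n_inside):
        b = usable[int(rng.integers(len(usable)))]
        j = int(rng.integers(len(b.members) - 1))
        (l1, c1, bp1), (l2, c2, bp2) = b.members[j], b.members[j + 1]
        lo, hi = (bp1, bp2) if bp1 < bp2 else (bp2, bp1)
        if hi - lo < 2:
            bp = lo + 1
        else:
            bp = int(rng.integers(lo + 1, hi))
        frac = (bp - bp1) / (bp2 - bp1)
        cm = c1 + frac * (c2 - c1)
        fid = f"feat_in{i + 1:03d}"
        rows.append([fid, b.chromosome, 100.0, 120, 0, 0, 1, 120, bp, bp + 119, 1e-60, 220.0])
        truth_rows.append([fid, b.lg, float(cm)])
    max_bp: dict = {}
    for b in true_blocks:
        for _, _, bp in b.members:
            max_bp[b.chromosome] = max(max_bp.get(b.chromosome, 0), bp)
    chroms = sorted(max_bp) or ["chrU"]
    for i in range(n_outside):
        chrom = chroms[i % len(chroms)]
        bp = max_bp.get(chrom, 0) + 5_000_000 + i * 10_000
        fid = f"feat_out{i + 1:03d}"
        rows.append([fid, chrom, 100.0, 120, 0, 0, 1, 120, bp, bp + 119, 1e-60, 220.0])
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["feature_id", "lg", "true_cM"])
    return hits, truth
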