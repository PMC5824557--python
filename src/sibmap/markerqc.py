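"""Per-family marker QC ahead of linkage mapping.

Order of application mirrors the map-building workflow: drop
high-missingness individuals, then loci below the call-rate floor, then
loci below the minor-allele-frequency floor (recomputed within the family
from parental plus offspring alleles), then loci with Bonferroni-significant
segregation distortion. Finally, loci with byte-identical segregation
signatures (zero observed recombination, missing pattern included) are
collapsed into co-segregation bins; one representative per bin is mapped
and the passengers are re-attached at its final position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .markers import FamilyData, MarkerGenotypes, SegType


@dataclass
class SegregationTest:
    """Pearson chi-square of offspring genotype-class counts against the
    Mendelian ratio of the locus's segregation type."""

    locus_id: str
    observed: dict
    expected_ratio: dict
    chi2: float
    p: float
    n_tests: int = 1

    @property
    def significant(self) -> bool:
        """Distorted at the 5% level after Bonferroni correction."""
        return self.p < 0.05 / self.n_tests


@dataclass
class CosegBin:
    representative: str
    members: list
    signature: str


def test_segregation_distortion(marker: MarkerGenotypes) -> SegregationTest:
    """Chi-square test of segregation distortion for one informative locus.

    Classes are the producible offspring genotypes (so HK x HK is tested on
    the 1:2:1 genotype classes); p is the upper tail of chi-square with
    (classes - 1) df, no continuity correction.
    """
    if marker.seg_type is SegType.UNINFORMATIVE:
        raise ValueError(f"{marker.locus_id}: uninformative locus has no segregation test")
    classes = list(marker.expected_ratio)
    obs = {g: 0 for g in classes}
    n = 0
    for c in marker.calls:
        if c is None:
            continue
        g = tuple(sorted(c))
        if g in obs:  # Mendelian-inconsistent calls are not a class
            obs[g] += 1
            n += 1
    if n == 0:
        raise ValueError(f"{marker.locus_id}: all offspring missing, test undefined")
    f_obs = np.array([obs[g] for g in classes], dtype=float)
    f_exp = np.array([marker.expected_ratio[g] * n for g in classes])
    chi2, p = stats.chisquare(f_obs, f_exp)
    return SegregationTest(marker.locus_id, obs, dict(marker.expected_ratio), float(chi2), float(p))


def filter_markers(
    family: FamilyData,
    min_call_rate: float = 0.90,
    max_indiv_missing: float = 0.50,
    min_maf: float = 0.05,
    alpha: float = 0.05,
) -> tuple[FamilyData, pd.DataFrame]:
    """Apply the genotype-level filters and return (kept family, removal log).

    Removal log columns: item, kind ('individual'|'locus'), reason, value.
    Raises ``ValueError`` if no informative markers survive.
    """
    log = []

    # 1. individuals by missingness across loci
    n_loci = len(family)
    miss_count = {o: 0 for o in family.offspring_ids}
    for m in family:
        for oid, c in zip(family.offspring_ids, m.calls):
            if c is None:
                miss_count[oid] += 1
    keep_off = []
    for oid in family.offspring_ids:
        frac = miss_count[oid] / n_loci if n_loci else 0.0
        if frac > max_indiv_missing:
            log.append((oid, "individual", "indiv_missing", frac))
        else:
            keep_off.append(oid)
    fam = family.subset_offspring(keep_off) if len(keep_off) != family.n_offspring else family

    # 2. unclassifiable / uninformative loci, then call rate, then MAF
    keep = []
    for m in fam:
        if m.seg_type is SegType.UNINFORMATIVE:
            log.append((m.locus_id, "locus", "uninformative", np.nan))
            continue
        cr = m.call_rate
        if cr < min_call_rate:
            log.append((m.locus_id, "locus", "call_rate", cr))
            continue
        maf = _family_maf(m)
        if maf < min_maf:
            log.append((m.locus_id, "locus", "maf", maf))
            continue
        keep.append(m.locus_id)

    # 3. segregation distortion, Bonferroni over the loci tested in this build
    n_tests = len(keep)
    kept = []
    for lid in keep:
        try:
            t = test_segregation_distortion(fam[lid])
        except ValueError:
            log.append((lid, "locus", "all_missing", np.nan))
            continue
        t.n_tests = n_tests
        if t.significant:
            log.append((lid, "locus", "distorted", t.p))
        else:
            kept.append(lid)

    if not kept:
        raise ValueError("no markers survive filtering")
    out = fam.subset_loci(kept)
    return out, pd.DataFrame(log, columns=["item", "kind", "reason", "value"])


def _family_maf(marker: MarkerGenotypes) -> float:
    counts: dict = {}
    for allele in (*marker.mother, *marker.father):
        counts[allele] = counts.get(allele, 0) + 1
    for c in marker.calls:
        if c is None:
            continue
        for allele in c:
            counts[allele] = counts.get(allele, 0) + 1
    total = sum(counts.values())
    return min(counts.values()) / total


def bin_cosegregating(family: FamilyData) -> list[CosegBin]:
    """Group loci whose full call vectors (including missingness positions)
    are identical; the lexicographically smallest locus id represents each
    bin. Bins partition the locus set."""
    by_sig: dict = {}
    for m in family:
        by_sig.setdefault((m.seg_type, m.mother, m.father, m.signature()), []).append(m.locus_id)
    bins = []
    for (seg, mo, fa, sig), members in by_sig.items():
        members = sorted(members)
        bins.append(CosegBin(members[0], members, sig))
    bins.sort(key=lambda b: b.representative)
    return bins
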