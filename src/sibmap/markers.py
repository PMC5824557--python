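"""Core marker containers for full-sib (CP) cross genotypes.

A *locus* here is a haplotyped, SNP-containing fragment; each family is a
full-sib cross (two outbred parents plus offspring). Parental genotypes
determine a CP segregation type:

===========  ==================  ===================  ==========
type         parents             offspring classes    ratio
===========  ==================  ===================  ==========
``AB x CD``  ab x cd             ac, ad, bc, bd       1:1:1:1
``EF x EG``  ef x eg             ee, eg, ef, fg       1:1:1:1
``HK x HK``  hk x hk             hh, hk, kk           1:2:1
``LM x LL``  lm x ll             ll, lm               1:1
``NN x NP``  nn x np             nn, np               1:1
===========  ==================  ===================  ==========

Transmission of a parental allele is encoded per offspring as a 4-bit mask
over (maternal allele index, paternal allele index) pairs compatible with
the observed genotype; bit ``2*m + p`` is set when the offspring genotype
could have arisen from maternal allele ``m`` and paternal allele ``p``.
This mask is the unit the two-point likelihood machinery consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

MISSING = None

Genotype = Optional[tuple]  # unordered pair of allele labels, or None


class SegType(str, Enum):
    """CP segregation types of a full-sib outcross."""

    AB_CD = "AB x CD"
    EF_EG = "EF x EG"
    HK_HK = "HK x HK"
    LM_LL = "LM x LL"
    NN_NP = "NN x NP"
    UNINFORMATIVE = "uninformative"

    @property
    def informative_mother(self) -> bool:
        return self in (SegType.AB_CD, SegType.EF_EG, SegType.HK_HK, SegType.LM_LL)

    @property
    def informative_father(self) -> bool:
        return self in (SegType.AB_CD, SegType.EF_EG, SegType.HK_HK, SegType.NN_NP)

    @property
    def fully_informative(self) -> bool:
        return self.informative_mother and self.informative_father


def classify_segregation(mother: Genotype, father: Genotype):
    """Classify a locus into a CP segregation type.

    Returns ``(SegType, expected_ratio)`` where ``expected_ratio`` maps each
    producible offspring genotype (a sorted allele tuple) to its Mendelian
    expected proportion. Raises ``ValueError`` on a missing parent genotype
    (the locus is unclassifiable and must be excluded upstream).
    """
    if mother is None or father is None:
        raise ValueError("missing parent genotype: locus unclassifiable")
    m, f = tuple(mother), tuple(father)
    m_het = m[0] != m[1]
    f_het = f[0] != f[1]
    if not m_het and not f_het:
        return SegType.UNINFORMATIVE, {}
    if m_het and f_het:
        shared = set(m) & set(f)
        if set(m) == set(f):
            seg = SegType.HK_HK
        elif len(shared) == 1:
            seg = SegType.EF_EG
        else:
            seg = SegType.AB_CD
    elif m_het:
        seg = SegType.LM_LL
    else:
        seg = SegType.NN_NP
    ratio: dict = {}
    for a in m:
        for b in f:
            g = tuple(sorted((a, b)))
            ratio[g] = ratio.get(g, 0.0) + 0.25
    return seg, ratio


def producible_genotypes(mother: Genotype, father: Genotype) -> list:
    """Distinct offspring genotypes producible by the parents."""
    out = []
    for a in mother:
        for b in father:
            g = tuple(sorted((a, b)))
            if g not in out:
                out.append(g)
    return out


def transmission_mask(mother: Genotype, father: Genotype, call: Genotype) -> int:
    """4-bit mask of (maternal index m, paternal index p) pairs compatible
    with the offspring ``call``; bit ``2*m + p``. 0 for missing or
    Mendelian-inconsistent calls."""
    if call is None:
        return 0
    want = tuple(sorted(call))
    mask = 0
    for m in (0, 1):
        for p in (0, 1):
            if tuple(sorted((mother[m], father[p]))) == want:
                mask |= 1 << (2 * m + p)
    return mask


@dataclass
class MarkerGenotypes:
    """One locus of one family: parents, segregation type, offspring calls."""

    locus_id: str
    contig_id: str
    family_id: str
    mother: tuple
    father: tuple
    calls: list  # one Genotype per offspring
    seg_type: SegType = field(init=False)
    expected_ratio: dict = field(init=False)

    def __post_init__(self):
        self.seg_type, self.expected_ratio = classify_segregation(self.mother, self.father)

    @property
    def n_offspring(self) -> int:
        return len(self.calls)

    @property
    def n_called(self) -> int:
        return sum(c is not None for c in self.calls)

    @property
    def call_rate(self) -> float:
        return self.n_called / len(self.calls) if self.calls else 0.0

    def masks(self) -> np.ndarray:
        return np.array(
            [transmission_mask(self.mother, self.father, c) for c in self.calls],
            dtype=np.uint8,
        )

    def signature(self) -> str:
        """Exact co-segregation signature: canonical genotype string per
        offspring, missing included. Two loci co-segregate iff equal."""
        parts = []
        for c in self.calls:
            parts.append("-" if c is None else "/".join(sorted(c)))
        return "|".join(parts)


class FamilyData:
    """Genotypes of one full-sib family at many loci.

    Thin ordered collection of :class:`MarkerGenotypes` with array views used
    by the estimation code. Offspring order is shared across loci.
    """

    def __init__(self, family_id: str, offspring_ids: Sequence[str], markers: Sequence[MarkerGenotypes] = ()):
        self.family_id = family_id
        self.offspring_ids = list(offspring_ids)
        self._markers: dict[str, MarkerGenotypes] = {}
        for m in markers:
            self.add(m)

    def add(self, marker: MarkerGenotypes) -> None:
        if marker.locus_id in self._markers:
            raise ValueError(f"duplicated locus id: {marker.locus_id}")
        if len(marker.calls) != len(self.offspring_ids):
            raise ValueError(
                f"locus {marker.locus_id}: {len(marker.calls)} calls for "
                f"{len(self.offspring_ids)} offspring"
            )
        self._markers[marker.locus_id] = marker

    def __len__(self) -> int:
        return len(self._markers)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._markers

    def __getitem__(self, locus_id: str) -> MarkerGenotypes:
        return self._markers[locus_id]

    def __iter__(self):
        return iter(self._markers.values())

    @property
    def locus_ids(self) -> list:
        return list(self._markers)

    @property
    def n_offspring(self) -> int:
        return len(self.offspring_ids)

    def subset_loci(self, locus_ids: Sequence[str]) -> "FamilyData":
        return FamilyData(
            self.family_id, self.offspring_ids, [self._markers[l] for l in locus_ids]
        )

    def subset_offspring(self, keep: Sequence[str]) -> "FamilyData":
        idx = [self.offspring_ids.index(o) for o in keep]
        fam = FamilyData(self.family_id, list(keep))
        for m in self:
            fam.add(
                MarkerGenotypes(
                    m.locus_id, m.contig_id, m.family_id, m.mother, m.father,
                    [m.calls[i] for i in idx],
                )
            )
        return fam

    def mask_call(self, locus_id: str, offspring_index: int) -> None:
        """Set one offspring call to missing (used by order QC)."""
        self._markers[locus_id].calls[offspring_index] = None
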