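"""Two-point recombination-fraction estimation in full-sib (CP) crosses.

For a pair of loci the data are, per offspring, the set of (maternal,
paternal) allele transmissions compatible with the two observed genotypes
(see :mod:`sibmap.markers`). A parent contributes an informative meiosis
for the pair only when it is heterozygous at both loci. Given a linkage
phase per informative parent (coupling/repulsion of the allele orderings at
the two loci), an offspring's probability is the sum over compatible
transmission combinations of ``r^R (1-r)^(K-R)`` up to a constant, where
``K`` is the number of informative parents and ``R`` the number of
recombinant meioses in the combination — a single sex-averaged ``r``.

The likelihood is maximized by EM jointly over ``r`` and, by enumeration,
over the admissible phase configurations (simultaneous estimation of
linkage and linkage phase). LOD is the base-10 log likelihood ratio of
``(r_hat, phase_hat)`` against ``r = 1/2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .markers import MarkerGenotypes

# _LUT[mask1, mask2, rm, rp] = number of transmission combinations with
# maternal recombination indicator rm and paternal indicator rp
_LUT = np.zeros((16, 16, 2, 2), dtype=np.int64)
for _m1 in range(16):
    for _m2 in range(16):
        for _b1 in range(4):
            if not (_m1 >> _b1) & 1:
                continue
            for _b2 in range(4):
                if not (_m2 >> _b2) & 1:
                    continue
                _rm = ((_b1 >> 1) ^ (_b2 >> 1)) & 1
                _rp = (_b1 ^ _b2) & 1
                _LUT[_m1, _m2, _rm, _rp] += 1

_LN10 = np.log(10.0)


@dataclass
class TwoPointResult:
    """Maximum-likelihood two-point estimate for one locus pair."""

    locus_a: str
    locus_b: str
    rf: float
    lod: float
    phase: tuple  # (maternal phase, paternal phase); None where uninformative
    n_informative: int
    loglik: float  # natural-log likelihood at (rf, phase), up to a constant
    phase_confident: bool = True  # False when runner-up phase within 0.1 LOD


def _em(coefs: np.ndarray, counts: np.ndarray, K: int,
        rf_init: float = 0.25, tol: float = 1e-6, max_iter: int = 2000,
        trace: Optional[list] = None) -> tuple[float, float]:
    """EM for r on per-pattern polynomial coefficients.

    ``coefs[p, j]`` counts transmission combinations of pattern ``p`` with
    ``j`` recombinant meioses; ``counts[p]`` is that pattern's offspring
    count. Returns (r_hat, log-likelihood). The E-step takes the expected
    recombinant meioses per offspring; the M-step divides by ``K`` meioses
    per offspring.
    """
    j = np.arange(K + 1, dtype=float)
    r = rf_init
    ll_old = -np.inf
    n_tot = counts.sum() * K
    for _ in range(max_iter):
        w = coefs * np.power(r, j) * np.power(1.0 - r, K - j)
        s = w.sum(axis=1)
        ll = float(np.dot(counts, np.log(s)))
        if trace is not None:
            trace.append(ll)
        e_r = (w @ j) / s
        r_new = float(np.dot(counts, e_r)) / n_tot
        r_new = min(max(r_new, 1e-9), 0.5)
        # converged only when both the log-likelihood and the estimate settle
        # (near rf = 0.5 the likelihood is flat while rf still drifts)
        if abs(ll - ll_old) < tol and abs(r_new - r) < 1e-7:
            r = r_new
            ll_old = ll
            break
        r, ll_old = r_new, ll
    return r, ll_old


def estimate_two_point(
    a: MarkerGenotypes,
    b: MarkerGenotypes,
    scope: str = "both",
    rf_init: float = 0.25,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> Optional[TwoPointResult]:
    """Estimate rf, LOD and phase for one locus pair.

    ``scope`` restricts which parent's meioses carry linkage information:
    ``"female"`` (maternal only), ``"male"``, or ``"both"``. Returns None
    when the pair is uninformative under the scope or no offspring is
    genotyped at both loci.
    """
    masks_a = a.masks()
    masks_b = b.masks()
    return estimate_from_masks(
        a.locus_id, b.locus_id, masks_a, masks_b,
        a.seg_type.informative_mother and b.seg_type.informative_mother,
        a.seg_type.informative_father and b.seg_type.informative_father,
        scope, rf_init, tol, max_iter,
    )


def estimate_from_masks(
    id_a: str,
    id_b: str,
    masks_a: np.ndarray,
    masks_b: np.ndarray,
    mother_informative: bool,
    father_informative: bool,
    scope: str = "both",
    rf_init: float = 0.25,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> Optional[TwoPointResult]:
    if scope not in ("both", "female", "male"):
        raise ValueError(f"unknown scope {scope!r}")
    use_m = mother_informative and scope in ("both", "female")
    use_p = father_informative and scope in ("both", "male")
    K = int(use_m) + int(use_p)
    if K == 0:
        return None
    valid = (masks_a > 0) & (masks_b > 0)
    if not valid.any():
        return None
    codes = masks_a[valid].astype(np.int32) * 16 + masks_b[valid].astype(np.int32)
    uniq, counts = np.unique(codes, return_counts=True)
    t = _LUT[uniq // 16, uniq % 16]  # (P, 2, 2) combo counts over (rm, rp)
    counts = counts.astype(float)
    n_valid = int(valid.sum())

    phases_m = (0, 1) if use_m else (None,)
    phases_p = (0, 1) if use_p else (None,)

    best = None
    lls = []
    for pm in phases_m:
        for pp in phases_p:
            coefs = _phase_coefs(t, use_m, use_p, pm, pp, K)
            r, ll = _em(coefs, counts, K, rf_init, tol, max_iter)
            lls.append(ll)
            # strict > keeps the first (coupling-most) phase on ties
            if best is None or ll > best[1] + 1e-12:
                best = (r, ll, (pm, pp), coefs)
    r_hat, ll_hat, phase, coefs = best
    if r_hat < 1e-7:  # numerical floor of the EM, genuinely zero recombination
        r_hat = 0.0
    ll_null = float(np.dot(counts, np.log(coefs.sum(axis=1) * 0.5**K)))
    lod = max(0.0, (ll_hat - ll_null) / _LN10)
    lls_sorted = sorted(lls, reverse=True)
    confident = bool(len(lls_sorted) < 2 or (lls_sorted[0] - lls_sorted[1]) / _LN10 > 0.1)
    return TwoPointResult(
        id_a, id_b, float(min(max(r_hat, 0.0), 0.5)), float(lod), phase,
        n_informative=K * n_valid, loglik=ll_hat, phase_confident=confident,
    )


def _phase_coefs(t: np.ndarray, use_m: bool, use_p: bool, pm, pp, K: int) -> np.ndarray:
    """Collapse per-pattern (rm, rp) combo counts into coefficients of
    r^j (1-r)^(K-j) under a phase assignment."""
    P = t.shape[0]
    coefs = np.zeros((P, K + 1))
    for rm in range(2):
        for rp in range(2):
            j = 0
            if use_m:
                j += rm ^ pm
            if use_p:
                j += rp ^ pp
            coefs[:, j] += t[:, rm, rp]
    return coefs


def grid_loglik(
    a: MarkerGenotypes,
    b: MarkerGenotypes,
    rf_grid: np.ndarray,
    scope: str = "both",
) -> tuple[np.ndarray, float]:
    """Brute-force profile log10-likelihood over a grid of rf values,
    maximized over phases. Independent check of the EM path."""
    masks_a, masks_b = a.masks(), b.masks()
    use_m = a.seg_type.informative_mother and b.seg_type.informative_mother and scope in ("both", "female")
    use_p = a.seg_type.informative_father and b.seg_type.informative_father and scope in ("both", "male")
    K = int(use_m) + int(use_p)
    if K == 0:
        raise ValueError("uninformative pair")
    valid = (masks_a > 0) & (masks_b > 0)
    codes = masks_a[valid].astype(np.int32) * 16 + masks_b[valid].astype(np.int32)
    uniq, counts = np.unique(codes, return_counts=True)
    t = _LUT[uniq // 16, uniq % 16]
    counts = counts.astype(float)
    j = np.arange(K + 1, dtype=float)
    best = np.full(len(rf_grid), -np.inf)
    for pm in ((0, 1) if use_m else (None,)):
        for pp in ((0, 1) if use_p else (None,)):
            coefs = _phase_coefs(t, use_m, use_p, pm, pp, K)
            # (G, P): per grid point per pattern
            pw = np.power.outer(rf_grid, j) * np.power.outer(1 - rf_grid, K - j)
            ll = (np.log(np.maximum(pw @ coefs.T, 1e-300)) @ counts)
            best = np.maximum(best, ll)
    rf_best = float(rf_grid[int(np.argmax(best))])
    return best, rf_best


def pairwise_table(
    family,
    locus_ids=None,
    scope: str = "both",
    **kw,
):
    """Estimate all pairwise two-point results for a family.

    Returns ``(results, index)`` where ``results[i][j]`` (i<j) is the
    :class:`TwoPointResult` or None, and ``index`` maps locus id -> row.
    """
    ids = list(locus_ids) if locus_ids is not None else family.locus_ids
    n = len(ids)
    masks = {}
    inf_m = {}
    inf_p = {}
    for lid in ids:
        m = family[lid]
        masks[lid] = m.masks()
        inf_m[lid] = m.seg_type.informative_mother
        inf_p[lid] = m.seg_type.informative_father
    results: dict = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            res = estimate_from_masks(
                a, b, masks[a], masks[b],
                inf_m[a] and inf_m[b], inf_p[a] and inf_p[b], scope, **kw,
            )
            if res is not None:
                results[(a, b)] = res
    return results, {lid: k for k, lid in enumerate(ids)}
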