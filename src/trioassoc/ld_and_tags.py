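"""Pairwise linkage disequilibrium from unphased genotypes, and tag-SNP bins.

Two-locus haplotype frequencies are estimated by the standard EM algorithm
over the double-heterozygote phase ambiguity (all other genotype pairs
resolve to known haplotype pairs).  r2 and D' are then computed from the
fitted frequencies, matching the convention of the usual LD-visualisation
tools.  Tag selection is greedy: the marker covering the most unbinned
neighbours above the r2 threshold becomes a tag, with ties broken by
genomic position for determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes_io import Cohort

_EM_TOL = 1e-10
_EM_MAX_ITER = 1000


@dataclass
class EMResult:
    """Fitted two-locus haplotype frequencies.

    ``freqs`` is ordered (minor-minor, minor-major, major-minor,
    major-major) with respect to the two markers' minor alleles.
    """

    freqs: np.ndarray
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    flagged_monomorphic: bool = False
    n_pairs: int = 0


def _pair_genotype_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    ga = np.asarray(ga)
    gb = np.asarray(gb)
    ok = (ga >= 0) & (gb >= 0)
    ga, gb = ga[ok], gb[ok]
    counts = np.zeros((3, 3), dtype=float)
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((ga == i) & (gb == j))
    return counts


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    f11, f10, f01, f00 = f
    # genotype-pair probabilities under random union of haplotypes
    prob = np.empty((3, 3))
    prob[2, 2] = f11 ** 2
    prob[2, 1] = 2 * f11 * f10
    prob[2, 0] = f10 ** 2
    prob[1, 2] = 2 * f11 * f01
    prob[1, 1] = 2 * f11 * f00 + 2 * f10 * f01
    prob[1, 0] = 2 * f10 * f00
    prob[0, 2] = f01 ** 2
    prob[0, 1] = 2 * f01 * f00
    prob[0, 0] = f00 ** 2
    with np.errstate(divide="ignore"):
        ll = np.where(counts > 0, counts * np.log(np.maximum(prob, 1e-300)), 0.0)
    return float(ll.sum())


def em_haplotype_freqs(ga: np.ndarray, gb: np.ndarray) -> EMResult:
    """Maximum-likelihood two-locus haplotype frequencies by EM.

    ``ga``/``gb`` are minor-allele dosages at the two markers (missing
    < 0); only individuals complete at both markers contribute.
    Initialisation is at linkage equilibrium (products of allele
    frequencies); iteration stops when the largest frequency change drops
    below 1e-10 or after 1000 iterations.
    """
    counts = _pair_genotype_counts(ga, gb)
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least two individuals complete at both markers")
    nhap = 2.0 * n

    pa = (2 * counts[2, :].sum() + counts[1, :].sum()) / nhap
    pb = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / nhap
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
        return EMResult(
            freqs=f, n_iter=0, converged=True, flagged_monomorphic=True, n_pairs=int(n)
        )

    # haplotype contributions fixed by unambiguous genotype pairs
    c11 = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    c10 = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    c01 = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    c00 = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    dh = counts[1, 1]  # double heterozygotes: phase unknown

    f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    trace = [_loglik(counts, f)]
    converged = False
    it = 0
    for it in range(1, _EM_MAX_ITER + 1):
        f11, f10, f01, f00 = f
        cis = f11 * f00
        trans = f10 * f01
        q = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        new = np.array(
            [c11 + q * dh, c10 + (1 - q) * dh, c01 + (1 - q) * dh, c00 + q * dh]
        ) / nhap
        delta = np.abs(new - f).max()
        f = new
        trace.append(_loglik(counts, f))
        if delta < _EM_TOL:
            converged = True
            break
    return EMResult(freqs=f, n_iter=it, converged=converged, loglik_trace=trace, n_pairs=int(n))


@dataclass(frozen=True)
class LDResult:
    marker_a: str
    marker_b: str
    freqs: tuple[float, float, float, float]  #: (mm, mM, Mm, MM) haplotypes
    r2: float
    dprime: float
    flagged: bool = False  #: monomorphic / degenerate pair


def pairwise_ld(
    ga: np.ndarray, gb: np.ndarray, marker_a: str = "A", marker_b: str = "B"
) -> LDResult:
    """r2 and D' for one marker pair from unphased genotypes.

    D = f(mm) - pA*pB; r2 = D^2 / (pA(1-pA) pB(1-pB)); D' = |D| / D_max
    with D_max the admissible bound given the allele frequencies.
    Monomorphic pairs are flagged with r2 = 0.
    """
    em = em_haplotype_freqs(ga, gb)
    f11, f10, f01, f00 = em.freqs
    pa = f11 + f10
    pb = f11 + f01
    d = f11 - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    if em.flagged_monomorphic or denom <= 0:
        return LDResult(marker_a, marker_b, tuple(em.freqs), 0.0, 0.0, flagged=True)
    r2 = d * d / denom
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    return LDResult(
        marker_a, marker_b, tuple(em.freqs), float(min(r2, 1.0)), float(min(dprime, 1.0))
    )


def ld_matrix(
    cohort: Cohort,
    marker_ids: list[str] | None = None,
    groups: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise r2 and D' matrices over a marker set (defaults to panel order).

    By default LD should be computed on a control sample, since case LD is
    distorted wherever markers are associated with disease.
    """
    if marker_ids is None:
        marker_ids = [m.id for m in cohort.markers]
    rows = cohort.group_indices(groups)
    cols = [cohort.marker_index(m) for m in marker_ids]
    g = cohort.genotypes[np.ix_(rows, cols)]
    k = len(cols)
    r2 = np.eye(k)
    dp = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            res = pairwise_ld(g[:, i], g[:, j], marker_ids[i], marker_ids[j])
            r2[i, j] = r2[j, i] = res.r2
            dp[i, j] = dp[j, i] = res.dprime
    idx = pd.Index(marker_ids)
    return pd.DataFrame(r2, index=idx, columns=idx), pd.DataFrame(dp, index=idx, columns=idx)


@dataclass(frozen=True)
class TagBin:
    tag: str
    members: tuple[str, ...]  #: includes the tag itself


@dataclass(frozen=True)
class TagBins:
    bins: tuple[TagBin, ...]

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(b.tag for b in self.bins)


def select_tag_snps(
    r2: pd.DataFrame | np.ndarray,
    positions: dict[str, int] | list[int],
    threshold: float = 0.8,
) -> TagBins:
    """Greedy r2 binning: cluster markers with pairwise r2 over ``threshold``.

    Repeatedly picks the unassigned marker with the most unassigned
    neighbours above the threshold (ties broken by smallest base-pair
    position), forms a bin from it plus those neighbours, and makes the
    picked marker the bin's tag.  Singletons tag themselves.
    """
    if isinstance(r2, pd.DataFrame):
        names = list(r2.index)
        mat = r2.to_numpy(dtype=float)
    else:
        mat = np.asarray(r2, dtype=float)
        names = [str(i) for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("r2 matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("r2 matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-6):
        raise ValueError("r2 matrix must have unit diagonal")
    if isinstance(positions, dict):
        pos = [positions[n] for n in names]
    else:
        pos = list(positions)
        if len(pos) != len(names):
            raise ValueError("positions length mismatch")

    k = mat.shape[0]
    unassigned = set(range(k))
    above = mat > threshold
    np.fill_diagonal(above, False)
    bins: list[TagBin] = []
    while unassigned:
        best = min(
            unassigned,
            key=lambda i: (-sum(1 for j in unassigned if above[i, j]), pos[i]),
        )
        members = [best] + [j for j in sorted(unassigned) if above[best, j] and j != best]
        members_sorted = sorted(members, key=lambda j: pos[j])
        bins.append(
            TagBin(tag=names[best], members=tuple(names[j] for j in members_sorted))
        )
        unassigned -= set(members)
    bins.sort(key=lambda b: min(pos[names.index(m)] for m in b.members))
    return TagBins(bins=tuple(bins))
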