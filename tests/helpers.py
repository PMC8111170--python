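"""Shared fixture builders and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

from trioassoc.genotypes_io import Cohort, Individual, Marker, TrioSet


def cohort_from_dosages(
    dosages,
    groups: list[str] | None = None,
    minor: str = "A",
    major: str = "G",
) -> Cohort:
    """Build a Cohort with auto-generated marker/individual metadata."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    markers = [Marker(f"m{j + 1}", "1", 100 * (j + 1), minor, major) for j in range(m)]
    if groups is None:
        groups = ["CASE"] * n
    individuals = [
        Individual(iid=f"i{i + 1}", fid=f"f{i + 1}", sex=1, group=g)
        for i, g in enumerate(groups)
    ]
    return Cohort(markers=markers, individuals=individuals, genotypes=dosages)


def trio_cohort(trio_dosages: list[tuple[int, int, int]], n_markers: int = 1):
    """Cohort + TrioSet from per-trio (father, mother, child) dosages at one marker."""
    rows = []
    trios = []
    for t, (f, m, c) in enumerate(trio_dosages):
        base = 3 * t
        rows += [[f] * n_markers, [m] * n_markers, [c] * n_markers]
        trios.append((base, base + 1, base + 2))
    cohort = cohort_from_dosages(np.array(rows))
    return cohort, TrioSet(trios=tuple(trios))


# ---------------------------------------------------------------------------
# independent oracles


@lru_cache(maxsize=None)
def hwe_enumeration_probs(n: int, rare: int) -> tuple[tuple[int, float], ...]:
    """Exact conditional P(het | n, rare) by integer enumeration.

    Counts configurations with multinomial coefficients n! / (a! h! b!)
    weighted by 2^h, using exact integer arithmetic before a single final
    normalisation.
    """
    weights: dict[int, int] = {}
    start = rare % 2
    for h in range(start, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        if hom_c < 0:
            continue
        weights[h] = math.comb(n, h) * math.comb(n - h, hom_r) * 2**h
    total = sum(weights.values())
    return tuple((h, w / total) for h, w in sorted(weights.items()))


def hwe_exact_oracle(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Two-sided exact HWE p by brute-force enumeration."""
    n = n_hom_minor + n_het + n_hom_major
    minor = 2 * n_hom_minor + n_het
    rare = min(minor, 2 * n - minor)
    if rare == 0:
        return 1.0
    probs = dict(hwe_enumeration_probs(n, rare))
    p_obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


def pearson_chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Textbook Pearson chi-square via expected counts (no correction)."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    exp = rows @ cols / obs.sum()
    if (exp == 0).any():
        return 0.0
    return float(((obs - exp) ** 2 / exp).sum())


def exhaustive_maxt_oracle(dosages: np.ndarray, n_case: int) -> np.ndarray:
    """Exact max-T adjusted p by enumerating every case-label assignment.

    Works directly on a complete dosage matrix (no missing values); allelic
    chi-square per marker computed cell by cell.
    """
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape

    def chi2_for(case_idx: set[int]) -> np.ndarray:
        out = np.zeros(m)
        for j in range(m):
            a = sum(dosages[i, j] for i in case_idx)
            b = 2 * n_case - a
            c = dosages[:, j].sum() - a
            d = 2 * (n - n_case) - c
            if (a + c) == 0 or (b + d) == 0:
                out[j] = 0.0
            else:
                out[j] = pearson_chi2_2x2(a, b, c, d)
        return out

    observed = chi2_for(set(range(n_case)))
    exceed = np.zeros(m)
    total = 0
    for combo in itertools.combinations(range(n), n_case):
        mx = chi2_for(set(combo)).max()
        exceed += mx >= observed - 1e-9
        total += 1
    return exceed / total


def phased_haplotype_freqs(h1: np.ndarray, h2: np.ndarray, a: int, b: int) -> np.ndarray:
    """Two-locus haplotype frequencies by direct counting on known phase.

    ``h1``/``h2`` are the two phased haplotype matrices of a sample
    (individuals x markers, 0/1); returns (mm, mM, Mm, MM) frequencies for
    markers ``a`` and ``b``.
    """
    haps = np.vstack([h1[:, [a, b]], h2[:, [a, b]]])
    freqs = np.empty(4)
    for k, (x, y) in enumerate([(1, 1), (1, 0), (0, 1), (0, 0)]):
        freqs[k] = np.mean((haps[:, 0] == x) & (haps[:, 1] == y))
    return freqs
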