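"""Synthetic trio and case/control genotype data with controllable LD.

Haplotypes are drawn from a latent-Gaussian (Gaussian copula) threshold
model: within each LD block the latent variables follow a first-order
autoregressive process with correlation ``within_block_rho`` between
adjacent markers, and blocks are mutually independent.  Thresholding the
latent value at the normal quantile of the target MAF yields a binary
minor-allele indicator whose marginal frequency converges to that MAF.
This induces realistic, monotonically decaying pairwise r2 inside blocks —
enough structure to exercise EM-based LD estimation, tag-SNP binning and
correlation-aware gene-level combination — while staying analytically
tractable (the pairwise haplotype distribution is a bivariate-normal
orthant probability).

Disease risk is logistic and log-additive across markers:

    logit P(affected) = logit(baseline_prevalence) + sum_m g_m * ln(psi_m)

with ``g_m`` the minor-allele dosage and ``psi_m`` the per-allele odds
ratio.  The default baseline prevalence is 0.05: low enough that odds
ratios approximate relative risks, the usual reading of case-control
effect sizes for uncommon disorders.

Every operation takes an explicit seed; one seed yields one reproducible
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .genotypes_io import Cohort, Individual, Marker, TrioSet


class SamplingError(RuntimeError):
    """Requested case/control counts unattainable under the disease model."""


@dataclass
class HaplotypePool:
    """A population of phased haplotypes over a marker panel."""

    markers: list[Marker]
    haplotypes: np.ndarray  # (n_haplotypes, n_markers) 0/1 minor-allele indicator
    block_assignments: np.ndarray  # (n_markers,) block id per marker

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.block_assignments = np.asarray(self.block_assignments)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.markers):
            raise ValueError("haplotype matrix does not match marker panel")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotypes must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class DiseaseModel:
    """Log-additive logistic disease model on minor-allele dosages."""

    baseline_prevalence: float = 0.05
    per_allele_or: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        for mid, psi in self.per_allele_or.items():
            if psi <= 0:
                raise ValueError(f"odds ratio for {mid} must be positive, got {psi}")

    def beta(self, markers: list[Marker]) -> np.ndarray:
        """Per-marker log odds ratio vector aligned to ``markers``."""
        return np.array([np.log(self.per_allele_or.get(m.id, 1.0)) for m in markers])

    def affection_probability(self, dosages: np.ndarray, markers: list[Marker]) -> np.ndarray:
        eta = logit(self.baseline_prevalence) + np.asarray(dosages, dtype=float) @ self.beta(markers)
        return expit(eta)


def _default_markers(n: int) -> list[Marker]:
    return [Marker(f"snp{j + 1}", "1", 1000 * (j + 1), "A", "G") for j in range(n)]


def simulate_haplotype_pool(
    panel_spec: list[tuple[float, int]],
    n_haplotypes: int,
    within_block_rho: float = 0.8,
    seed: int = 0,
    markers: list[Marker] | None = None,
) -> HaplotypePool:
    """Draw a haplotype pool from the latent-Gaussian AR(1) block model.

    Parameters
    ----------
    panel_spec
        One ``(maf, block id)`` pair per marker, in panel order.
    n_haplotypes
        Pool size (>= 2).
    within_block_rho
        Latent AR(1) correlation between adjacent markers of a block,
        in [0, 1).  0 gives linkage equilibrium.
    markers
        Optional marker metadata; autogenerated when omitted.
    """
    if not 0.0 <= within_block_rho < 1.0:
        raise ValueError(f"within_block_rho must be in [0, 1), got {within_block_rho}")
    if n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    mafs = np.array([m for m, _ in panel_spec], dtype=float)
    if ((mafs <= 0) | (mafs >= 1)).any():
        raise ValueError("every maf must be in (0, 1)")
    blocks = np.array([b for _, b in panel_spec])
    if markers is None:
        markers = _default_markers(len(panel_spec))
    if len(markers) != len(panel_spec):
        raise ValueError("markers and panel_spec length mismatch")

    rng = np.random.default_rng(seed)
    n_markers = len(panel_spec)
    z = np.empty((n_haplotypes, n_markers))
    rho = within_block_rho
    prev_block = None
    for j in range(n_markers):
        eps = rng.standard_normal(n_haplotypes)
        if blocks[j] == prev_block:
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1.0 - rho**2) * eps
        else:
            z[:, j] = eps
        prev_block = blocks[j]

    haplotypes = (z < norm.ppf(mafs)).astype(np.int8)
    return HaplotypePool(markers=list(markers), haplotypes=haplotypes, block_assignments=blocks)


def _draw_genotypes(pool: HaplotypePool, n: int, rng: np.random.Generator) -> np.ndarray:
    """Genotypes of ``n`` individuals as sums of two random pool haplotypes."""
    i = rng.integers(pool.n_haplotypes, size=n)
    j = rng.integers(pool.n_haplotypes, size=n)
    return pool.haplotypes[i] + pool.haplotypes[j]


def _cohort_from(
    pool: HaplotypePool, genotypes: np.ndarray, groups: list[str], prefix: str
) -> Cohort:
    individuals = [
        Individual(iid=f"{prefix}{i + 1}", fid=f"{prefix}{i + 1}", sex=1, group=g)
        for i, g in enumerate(groups)
    ]
    return Cohort(markers=list(pool.markers), individuals=individuals, genotypes=genotypes)


def simulate_case_control(
    pool: HaplotypePool,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
    case_label: str = "CASE",
    control_label: str = "CONTROL",
    max_attempts: int = 1000,
) -> Cohort:
    """Rejection-sample unrelated cases and controls from the pool.

    Individuals are formed from two random pool haplotypes; affection is
    Bernoulli with the model's logistic probability; sampling repeats in
    batches until both requested counts are met.
    """
    rng = np.random.default_rng(seed)
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    got_cases = got_controls = 0
    prev = model.baseline_prevalence
    for _ in range(max_attempts):
        if got_cases >= n_cases and got_controls >= n_controls:
            break
        need_c = max(n_cases - got_cases, 0)
        need_u = max(n_controls - got_controls, 0)
        batch = int(max(1024, 1.5 * (need_c / max(prev, 1e-6) + need_u / max(1 - prev, 1e-6))))
        g = _draw_genotypes(pool, batch, rng)
        p = model.affection_probability(g, pool.markers)
        affected = rng.random(batch) < p
        if need_c:
            cases.append(g[affected][:need_c])
            got_cases += len(cases[-1])
        if need_u:
            controls.append(g[~affected][:need_u])
            got_controls += len(controls[-1])
    else:
        raise SamplingError(
            f"could not draw {n_cases} cases / {n_controls} controls "
            f"in {max_attempts} batches (prevalence {prev})"
        )

    parts = ([np.vstack(cases)] if n_cases else []) + ([np.vstack(controls)] if n_controls else [])
    genotypes = np.vstack(parts) if parts else np.empty((0, pool.n_markers), dtype=np.int8)
    groups = [case_label] * n_cases + [control_label] * n_controls
    return _cohort_from(pool, genotypes, groups, prefix="cc")


def simulate_trios(
    pool: HaplotypePool,
    model: DiseaseModel,
    n_trios: int,
    seed: int = 0,
    ascertain_affected_child: bool = True,
    child_label: str = "CASE",
    parent_label: str = "FOUNDER",
    max_attempts: int = 1000,
) -> tuple[Cohort, TrioSet]:
    """Simulate nuclear-family trios, optionally ascertained on an affected child.

    Parents are random pool individuals; the child inherits one uniformly
    chosen haplotype from each parent, so every trio is Mendel-consistent by
    construction.  Individuals are laid out father, mother, child per trio.
    """
    rng = np.random.default_rng(seed)
    kept_f: list[np.ndarray] = []
    kept_m: list[np.ndarray] = []
    kept_c: list[np.ndarray] = []
    got = 0
    prev = model.baseline_prevalence
    rate = prev if ascertain_affected_child else 1.0
    for _ in range(max_attempts):
        if got >= n_trios:
            break
        need = n_trios - got
        batch = int(max(1024, 1.5 * need / max(rate, 1e-6)))
        f1 = pool.haplotypes[rng.integers(pool.n_haplotypes, size=batch)]
        f2 = pool.haplotypes[rng.integers(pool.n_haplotypes, size=batch)]
        m1 = pool.haplotypes[rng.integers(pool.n_haplotypes, size=batch)]
        m2 = pool.haplotypes[rng.integers(pool.n_haplotypes, size=batch)]
        from_f = np.where(rng.integers(2, size=batch)[:, None].astype(bool), f1, f2)
        from_m = np.where(rng.integers(2, size=batch)[:, None].astype(bool), m1, m2)
        child = from_f + from_m
        if ascertain_affected_child:
            p = model.affection_probability(child, pool.markers)
            keep = rng.random(batch) < p
        else:
            keep = np.ones(batch, dtype=bool)
        take = min(need, int(keep.sum()))
        idx = np.flatnonzero(keep)[:take]
        kept_f.append((f1 + f2)[idx])
        kept_m.append((m1 + m2)[idx])
        kept_c.append(child[idx])
        got += take
    else:
        raise SamplingError(
            f"could not ascertain {n_trios} affected-child trios in "
            f"{max_attempts} batches (prevalence {prev})"
        )

    fathers = np.vstack(kept_f)
    mothers = np.vstack(kept_m)
    children = np.vstack(kept_c)

    genotypes = np.empty((3 * n_trios, pool.n_markers), dtype=np.int8)
    individuals: list[Individual] = []
    trios: list[tuple[int, int, int]] = []
    for t in range(n_trios):
        fi, mi, ci = 3 * t, 3 * t + 1, 3 * t + 2
        genotypes[fi] = fathers[t]
        genotypes[mi] = mothers[t]
        genotypes[ci] = children[t]
        fam = f"fam{t + 1}"
        individuals.append(Individual(iid=f"{fam}_f", fid=fam, sex=1, group=parent_label))
        individuals.append(Individual(iid=f"{fam}_m", fid=fam, sex=2, group=parent_label))
        individuals.append(Individual(iid=f"{fam}_c", fid=fam, sex=1, group=child_label))
        trios.append((fi, mi, ci))

    cohort = Cohort(markers=list(pool.markers), individuals=individuals, genotypes=genotypes)
    return cohort, TrioSet(trios=tuple(trios))


def latent_model_r2(maf_a: float, maf_b: float, rho: float) -> float:
    """Haplotype r2 implied by the latent-Gaussian threshold model.

    Computed by numeric evaluation of the bivariate-normal orthant
    probability at the two thresholds; serves as the analytic counterpart
    of the empirical LD the simulator produces.
    """
    from scipy.stats import multivariate_normal

    ta, tb = norm.ppf(maf_a), norm.ppf(maf_b)
    p11 = multivariate_normal.cdf([ta, tb], mean=[0, 0], cov=[[1, rho], [rho, 1]])
    d = p11 - maf_a * maf_b
    denom = maf_a * (1 - maf_a) * maf_b * (1 - maf_b)
    return float(d * d / denom)
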