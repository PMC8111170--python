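"""Per-SNP case-control association: chi-square tests, odds ratios,
family-wise max-T permutation correction, and analytic power.

All 2x2 tests use the Pearson chi-square statistic without continuity
correction (df 1).  Odds ratios come with Woolf (log-scale) 95% confidence
intervals; when any cell of the table is zero, Haldane's +0.5 is added to
every cell for the OR and its interval (the chi-square is computed on the
raw table).  The effect allele is always the panel minor allele, so odds
ratios below 1 read as protective.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chi2_contingency, norm

from .genotypes_io import Cohort, GenotypeCounts

#: z quantile used for all 95% confidence intervals
Z95 = 1.959964

_MODEL_PRECEDENCE = {"allelic": 0, "dominant": 1, "recessive": 2}


@dataclass(frozen=True)
class AssociationResult:
    marker: str
    model: str  # allelic | dominant | recessive
    effect_allele: str
    or_hat: float
    ci95: tuple[float, float]
    chi2: float
    df: int
    p: float
    flagged: bool = False  #: degenerate table (empty margin or zero cell)


def _pearson_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        return math.nan, math.nan
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return chi2, float(chi2_dist.sf(chi2, 1))


def _odds_ratio_ci(a: float, b: float, c: float, d: float) -> tuple[float, tuple[float, float], bool]:
    haldane = min(a, b, c, d) == 0
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_hat = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_hat) - Z95 * se)
    hi = math.exp(math.log(or_hat) + Z95 * se)
    return or_hat, (lo, hi), haldane


def table_test(
    a: int,
    b: int,
    c: int,
    d: int,
    marker: str = "",
    model: str = "allelic",
    effect_allele: str = "",
) -> AssociationResult:
    """Association test on an explicit 2x2 table.

    Rows are case/control, columns effect/other — ``a`` = case effect
    count, ``b`` = case other, ``c`` = control effect, ``d`` = control
    other.  Accepts allele counts (allelic model) or collapsed genotype
    counts (dominant/recessive).  An empty row (no counted individuals on
    one side) yields an undefined result flag; an empty column still
    admits a Haldane-corrected odds ratio but no chi-square.
    """
    if (a + b) <= 0 or (c + d) <= 0:
        return AssociationResult(
            marker, model, effect_allele, math.nan, (math.nan, math.nan),
            math.nan, 1, math.nan, flagged=True,
        )
    chi2, p = _pearson_2x2(a, b, c, d)
    or_hat, ci, haldane = _odds_ratio_ci(a, b, c, d)
    return AssociationResult(
        marker, model, effect_allele, or_hat, ci, chi2, 1, p,
        flagged=haldane or math.isnan(chi2),
    )


def allelic_test(
    case: GenotypeCounts,
    control: GenotypeCounts,
    marker: str = "",
    effect_allele: str = "",
) -> AssociationResult:
    """Allelic chi-square test on the 2x2 minor/major allele-count table."""
    return table_test(
        case.allele_count_minor,
        case.allele_count_major,
        control.allele_count_minor,
        control.allele_count_major,
        marker=marker,
        model="allelic",
        effect_allele=effect_allele,
    )


def genotypic_test(
    case: GenotypeCounts,
    control: GenotypeCounts,
    model: str,
    marker: str = "",
    effect_allele: str = "",
) -> AssociationResult:
    """Dominant or recessive test on genotype counts collapsed to 2x2.

    Dominant: carriers of the minor allele (het + hom-minor) vs hom-major.
    Recessive: hom-minor vs the rest.
    """
    if model == "dominant":
        a, b = case.n_het + case.n_hom_minor, case.n_hom_major
        c, d = control.n_het + control.n_hom_minor, control.n_hom_major
    elif model == "recessive":
        a, b = case.n_hom_minor, case.n_het + case.n_hom_major
        c, d = control.n_hom_minor, control.n_het + control.n_hom_major
    else:
        raise ValueError(f"model must be 'dominant' or 'recessive', got {model!r}")
    return table_test(a, b, c, d, marker=marker, model=model, effect_allele=effect_allele)


def best_model(results: list[AssociationResult]) -> AssociationResult:
    """Most significant model; ties broken allelic > dominant > recessive."""
    if not results:
        raise ValueError("no results to choose from")
    usable = [r for r in results if not math.isnan(r.p)]
    pool = usable or results
    return min(pool, key=lambda r: (r.p, _MODEL_PRECEDENCE.get(r.model, 99)))


def multigroup_allele_test(counts: list[GenotypeCounts]) -> tuple[float, int, float]:
    """Pearson chi-square on the k x 2 allele-count table; df = k - 1."""
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    table = np.array(
        [[c.allele_count_minor, c.allele_count_major] for c in counts], dtype=float
    )
    df = len(counts) - 1
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return math.nan, df, math.nan
    chi2, p, df_out, _ = chi2_contingency(table, correction=False)
    return float(chi2), int(df_out), float(p)


# ---------------------------------------------------------------------------
# max-T permutation


@dataclass(frozen=True)
class PermutationResult:
    markers: tuple[str, ...]
    raw_chi2: np.ndarray
    adjusted_p: np.ndarray  #: family-wise adjusted p per marker
    n_perm: int
    seed: int | None
    exhaustive: bool = False


def _allelic_chi2_rows(case_rows: np.ndarray, dos0: np.ndarray, nonmiss: np.ndarray,
                       tot_minor: np.ndarray, tot_alleles: np.ndarray) -> np.ndarray:
    """Allelic chi-square per marker for each case-indicator row.

    ``case_rows``: (R, n) 0/1; ``dos0``: (n, m) dosages with missing as 0;
    ``nonmiss``: (n, m) 0/1.  Missing genotypes are complete-cased per
    marker.  Returns (R, m); degenerate margins give 0.
    """
    am = case_rows @ dos0  # case minor-allele count
    at = 2.0 * (case_rows @ nonmiss)  # case allele total
    cm = tot_minor - am
    ct = tot_alleles - at
    a, b = am, at - am
    c, d = cm, ct - cm
    n = at + ct
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / (at * ct * (a + c) * (b + d))
    return np.where(np.isfinite(chi2), chi2, 0.0)


def maxT_permutation(
    cohort: Cohort,
    marker_ids: list[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    case_groups: tuple[str, ...] = ("CASE",),
    control_groups: tuple[str, ...] | None = None,
    exhaustive: bool = False,
    chunk: int = 2048,
) -> PermutationResult:
    """Family-wise max-T adjusted p-values under case/control label swapping.

    Genotype rows (and hence inter-marker LD) are held fixed while the
    case/control labels are permuted uniformly; each permutation records
    the maximum allelic chi-square across markers, and the adjusted p for
    marker m is ``(1 + #{perm: max >= observed_m}) / (n_perm + 1)``.

    With ``exhaustive=True`` every distinct case-label assignment is
    enumerated instead (only sensible for tiny samples) and the adjusted p
    is the exact fraction ``#{assignment: max >= observed_m} / total``.
    """
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if marker_ids is None:
        marker_ids = [m.id for m in cohort.markers]

    case_rows_idx = cohort.group_indices(case_groups)
    if control_groups is None:
        all_groups = cohort.group_labels()
        control_groups = tuple(sorted(all_groups - set(case_groups)))
    control_rows_idx = cohort.group_indices(control_groups)
    if len(case_rows_idx) == 0 or len(control_rows_idx) == 0:
        raise ValueError("both case and control individuals are required")

    rows = np.concatenate([case_rows_idx, control_rows_idx])
    cols = [cohort.marker_index(m) for m in marker_ids]
    g = cohort.genotypes[np.ix_(rows, cols)].astype(float)
    nonmiss = (g >= 0).astype(float)
    dos0 = np.where(g >= 0, g, 0.0)
    tot_minor = dos0.sum(axis=0)
    tot_alleles = 2.0 * nonmiss.sum(axis=0)

    n = len(rows)
    k = len(case_rows_idx)
    observed_ind = np.zeros((1, n))
    observed_ind[0, :k] = 1.0
    observed = _allelic_chi2_rows(observed_ind, dos0, nonmiss, tot_minor, tot_alleles)[0]

    eps = 1e-9

    if exhaustive:
        exceed = np.zeros(len(cols))
        total = 0
        batch: list[np.ndarray] = []
        for combo in itertools.combinations(range(n), k):
            row = np.zeros(n)
            row[list(combo)] = 1.0
            batch.append(row)
            if len(batch) == chunk:
                mx = _allelic_chi2_rows(np.array(batch), dos0, nonmiss, tot_minor, tot_alleles).max(axis=1)
                exceed += (mx[:, None] >= observed[None, :] - eps).sum(axis=0)
                total += len(batch)
                batch = []
        if batch:
            mx = _allelic_chi2_rows(np.array(batch), dos0, nonmiss, tot_minor, tot_alleles).max(axis=1)
            exceed += (mx[:, None] >= observed[None, :] - eps).sum(axis=0)
            total += len(batch)
        adjusted = exceed / total
        return PermutationResult(
            tuple(marker_ids), observed, adjusted, n_perm=total, seed=None, exhaustive=True
        )

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(cols))
    done = 0
    base = np.zeros(n)
    base[:k] = 1.0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.empty((b, n))
        for i in range(b):
            perms[i] = rng.permutation(base)
        mx = _allelic_chi2_rows(perms, dos0, nonmiss, tot_minor, tot_alleles).max(axis=1)
        exceed += (mx[:, None] >= observed[None, :] - eps).sum(axis=0)
        done += b
    adjusted = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationResult(tuple(marker_ids), observed, adjusted, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# analytic power


@dataclass(frozen=True)
class PowerParams:
    """Scenario for the two-proportion allelic test power approximation."""

    n_case: int
    n_control: int
    p0: float  #: control minor-allele frequency
    psi: float  #: per-allele odds ratio
    alpha: float = 0.001  #: two-sided significance level

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be in (0, 1)")
        if self.psi <= 0:
            raise ValueError("psi must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("sample sizes must be positive")


def allelic_power(params: PowerParams) -> float:
    """Power of the two-sided allelic chi-square test, normal approximation.

    The case allele frequency is obtained by applying the per-allele odds
    ratio to the control allele odds, ``p1 = psi*odds0 / (1 + psi*odds0)``.
    Allele totals are twice the individual counts.  The null standard error
    pools the two frequencies weighted by allele counts; the alternative
    standard error uses each group's own frequency.  Both rejection tails
    are accumulated, so at psi = 1 the power equals alpha.
    """
    p0 = params.p0
    odds1 = params.psi * p0 / (1.0 - p0)
    p1 = odds1 / (1.0 + odds1)
    m1 = 2.0 * params.n_case
    m0 = 2.0 * params.n_control
    pbar = (m1 * p1 + m0 * p0) / (m1 + m0)
    se0 = math.sqrt(pbar * (1.0 - pbar) * (1.0 / m1 + 1.0 / m0))
    se1 = math.sqrt(p1 * (1.0 - p1) / m1 + p0 * (1.0 - p0) / m0)
    z = norm.ppf(1.0 - params.alpha / 2.0)
    delta = abs(p1 - p0)
    upper = norm.cdf((delta - z * se0) / se1)
    lower = norm.cdf((-delta - z * se0) / se1)
    return float(upper + lower)
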