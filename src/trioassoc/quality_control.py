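"""Per-SNP quality-control filters: MAF, missingness, HWE, Mendel errors.

Exclusion thresholds are strict inequalities throughout — a marker is
removed when its MAF is *below* the minimum, its missing rate is *above*
the maximum, its Hardy-Weinberg exact p is *below* the minimum, or its
trio Mendel-error rate is *above* the maximum; boundary values pass.

Hardy-Weinberg equilibrium is assessed on samples expected to satisfy it:
the unrelated control group and the trio founders (parents), separately.
Pseudo-controls are synthetic genotypes and are never used for HWE.  A
marker fails the HWE filter if either evaluated sample falls below the
threshold — the conservative choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes_io import Cohort, GenotypeCounts, TrioSet

#: relative tolerance when comparing configuration probabilities to the
#: observed one, so that exactly tied configurations (e.g. symmetric
#: tables) are included regardless of floating-point summation order
_HWE_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.05
    miss_max: float = 0.10
    hwe_p_min: float = 0.001
    mendel_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("maf_min", "miss_max", "hwe_p_min", "mendel_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    the observed configuration's (the classic exact formulation; no mid-p).
    Monomorphic markers return 1 by convention.
    """
    n = counts.n_genotyped
    if n < 1:
        raise ValueError("need at least one non-missing genotype")
    rare = min(counts.allele_count_minor, counts.allele_count_major)
    if rare == 0:
        return 1.0
    obs_het = counts.n_het
    probs = _hwe_het_probabilities(n, rare)
    p_obs = probs[obs_het]
    p = sum(p_h for p_h in probs.values() if p_h <= p_obs * (1.0 + _HWE_TIE_RTOL))
    return min(1.0, p)


def _hwe_het_probabilities(n: int, rare: int) -> dict[int, float]:
    """Normalized P(het = h | n genotypes, ``rare`` copies of the rarer allele).

    Uses the standard two-directional recurrence from the modal heterozygote
    count, which is numerically stable for large n.
    """
    mid = int(rare * (2 * n - rare) / (2.0 * n))
    if mid % 2 != rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downwards: h -> h - 2
    h, p = mid, 1.0
    while h >= 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        p *= h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        probs[h] = p
    # upwards: h -> h + 2
    h, p = mid, 1.0
    while h + 2 <= rare:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        if hom_r == 0 or hom_c == 0:
            break
        p *= 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
        probs[h] = p
    total = math.fsum(probs.values())
    return {h: p / total for h, p in probs.items()}


#: dosages a child can carry given one parent's dosage
_TRANSMISSIBLE = {0: (0,), 1: (0, 1), 2: (1,)}
_CONSISTENT = {
    (f, m): frozenset(a + b for a in _TRANSMISSIBLE[f] for b in _TRANSMISSIBLE[m])
    for f in (0, 1, 2)
    for m in (0, 1, 2)
}


def is_mendel_consistent(father: int, mother: int, child: int) -> bool:
    """Whether a child dosage is attainable from the parents' dosages."""
    return child in _CONSISTENT[(father, mother)]


@dataclass(frozen=True)
class MendelResult:
    rate: float | None  #: None when no trio could be evaluated
    n_evaluated: int
    flagged_trios: tuple[int, ...]  #: indices into the TrioSet


def mendel_error_rate(trioset: TrioSet, cohort: Cohort, marker_id: str) -> MendelResult:
    """Fraction of fully observed trios whose child genotype is impossible.

    Trios with any missing member at the marker are skipped and excluded
    from the denominator.
    """
    trioset.validate(cohort)
    j = cohort.marker_index(marker_id)
    g = cohort.genotypes[:, j]
    flagged: list[int] = []
    evaluated = 0
    for t, (f, m, c) in enumerate(trioset.trios):
        gf, gm, gc = int(g[f]), int(g[m]), int(g[c])
        if min(gf, gm, gc) < 0:
            continue
        evaluated += 1
        if not is_mendel_consistent(gf, gm, gc):
            flagged.append(t)
    rate = len(flagged) / evaluated if evaluated else None
    return MendelResult(rate=rate, n_evaluated=evaluated, flagged_trios=tuple(flagged))


@dataclass
class QCReport:
    """Per-marker QC statistics, verdicts, and the surviving marker list."""

    table: pd.DataFrame
    thresholds: QCThresholds
    survivors: list[str]
    notes: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def apply_qc(
    cohort: Cohort,
    trioset: TrioSet | None = None,
    thresholds: QCThresholds = QCThresholds(),
    control_groups: tuple[str, ...] = ("CONTROL",),
) -> QCReport:
    """Evaluate all four filters for every marker and assign verdicts.

    MAF and missingness are computed on all individuals; HWE on the control
    group(s) and on trio founders separately (failing if either is below
    threshold); the Mendel-error rate on the supplied trios.  Survivors are
    ordered by chromosome and position.
    """
    if cohort.n_individuals == 0:
        raise ValueError("empty cohort")

    present_controls = tuple(g for g in control_groups if g in cohort.group_labels())
    founder_rows = trioset.founder_indices() if trioset is not None and len(trioset) else None

    notes = [
        "HWE evaluated on control group(s) "
        f"{list(present_controls) or 'none present'} and trio founders "
        f"({0 if founder_rows is None else len(founder_rows)} individuals) separately; "
        "a marker fails if either sample is below threshold."
    ]

    records = []
    for m in cohort.markers:
        j = cohort.marker_index(m.id)
        all_counts = GenotypeCounts.from_dosages(cohort.genotypes[:, j])
        maf = all_counts.maf
        miss = all_counts.missing_rate

        hwe_ps: dict[str, float | None] = {"controls": None, "founders": None}
        if present_controls:
            cc = GenotypeCounts.from_dosages(
                cohort.genotypes[cohort.group_indices(present_controls), j]
            )
            if cc.n_genotyped:
                hwe_ps["controls"] = hwe_exact_test(cc)
        if founder_rows is not None:
            fc = GenotypeCounts.from_dosages(cohort.genotypes[founder_rows, j])
            if fc.n_genotyped:
                hwe_ps["founders"] = hwe_exact_test(fc)
        evaluated_hwe = [p for p in hwe_ps.values() if p is not None]
        hwe_min = min(evaluated_hwe) if evaluated_hwe else None

        if trioset is not None and len(trioset):
            mendel = mendel_error_rate(trioset, cohort, m.id).rate
        else:
            mendel = None

        fails = []
        if maf is not None and maf < thresholds.maf_min:
            fails.append("maf")
        if miss > thresholds.miss_max:
            fails.append("missing")
        if hwe_min is not None and hwe_min < thresholds.hwe_p_min:
            fails.append("hwe")
        if mendel is not None and mendel > thresholds.mendel_max:
            fails.append("mendel")

        records.append(
            {
                "marker": m.id,
                "chrom": m.chrom,
                "pos": m.pos,
                "maf": maf,
                "missing_rate": miss,
                "hwe_p_controls": hwe_ps["controls"],
                "hwe_p_founders": hwe_ps["founders"],
                "mendel_rate": mendel,
                "fails": ",".join(fails),
                "verdict": "fail" if fails else "pass",
            }
        )

    table = pd.DataFrame.from_records(records)
    passed = table[table["verdict"] == "pass"].sort_values(["chrom", "pos"])
    return QCReport(
        table=table,
        thresholds=thresholds,
        survivors=passed["marker"].tolist(),
        notes=notes,
    )
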