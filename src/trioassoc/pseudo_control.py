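"""Pseudo-control construction from trios (haplotype-relative-risk design).

For each trio and marker, the two parental alleles *not* transmitted to the
affected child form the genotype of a synthetic unrelated control.  On the
dosage scale this is the allele-multiset identity

    pseudo = father + mother - child,

which is algebraically equivalent to the non-transmitted-pair definition
and — unlike per-parent phase assignment — has no ambiguous
double-heterozygote case, so the construction is deterministic.

Trio-markers that are Mendel-inconsistent or incompletely observed yield a
missing pseudo-control genotype at that marker (the trio itself is kept).
"""

from __future__ import annotations

import logging

import numpy as np

from .genotypes_io import MISSING, Cohort, Individual, TrioSet
from .quality_control import is_mendel_consistent

logger = logging.getLogger(__name__)


def construct_pseudo_controls(
    trioset: TrioSet, cohort: Cohort, group_label: str = "PSEUDO"
) -> Cohort:
    """Build one pseudo-control individual per trio.

    Returns a new Cohort on the same marker panel containing only the
    pseudo-controls, labelled ``group_label``.
    """
    trioset.validate(cohort)
    n_markers = cohort.n_markers
    genotypes = np.full((len(trioset), n_markers), MISSING, dtype=np.int8)
    n_inconsistent = 0

    for t, (f, m, c) in enumerate(trioset.trios):
        gf = cohort.genotypes[f]
        gm = cohort.genotypes[m]
        gc = cohort.genotypes[c]
        observed = (gf >= 0) & (gm >= 0) & (gc >= 0)
        for j in np.flatnonzero(observed):
            if is_mendel_consistent(int(gf[j]), int(gm[j]), int(gc[j])):
                genotypes[t, j] = gf[j] + gm[j] - gc[j]
            else:
                n_inconsistent += 1
                logger.warning(
                    "trio %d marker %s: Mendel-inconsistent genotypes "
                    "(father %d, mother %d, child %d); pseudo-control set missing",
                    t,
                    cohort.markers[j].id,
                    gf[j],
                    gm[j],
                    gc[j],
                )

    if n_inconsistent:
        logger.warning(
            "%d Mendel-inconsistent trio-marker(s) set to missing", n_inconsistent
        )

    child_fids = [cohort.individuals[c].fid for _, _, c in trioset.trios]
    individuals = [
        Individual(iid=f"{fid}_pseudo", fid=fid, sex=0, group=group_label)
        for fid in child_fids
    ]
    return Cohort(markers=list(cohort.markers), individuals=individuals, genotypes=genotypes)
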