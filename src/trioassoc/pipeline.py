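"""End-to-end study pipeline: load/simulate -> QC -> pseudo-controls ->
group contrasts -> permutation correction -> LD -> gene-level combination.

The stage order mirrors the family-based candidate-gene design the package
implements: trios contribute affected children to the clinical sample and
pseudo-controls to the control sample; the aggregated clinical-vs-control
contrast ("primary") drives best-model selection and the family-wise
permutation correction, and the finer per-group contrasts are reported
alongside.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2 as chi2_dist

from . import published
from .association_tests import (
    AssociationResult,
    PermutationResult,
    _allelic_chi2_rows,
    allelic_test,
    best_model,
    genotypic_test,
    maxT_permutation,
    multigroup_allele_test,
)
from .gene_level import GeneResult, gates_pvalue
from .genotypes_io import Cohort, GenotypeCounts, TrioSet, genotype_counts, read_pedmap
from .ld_and_tags import ld_matrix, select_tag_snps
from .pseudo_control import construct_pseudo_controls
from .quality_control import QCReport, QCThresholds, apply_qc
from .synthetic_cohort import DiseaseModel, simulate_case_control, simulate_haplotype_pool, simulate_trios


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class Contrast:
    name: str
    kind: str  # "two" or "multi"
    case_groups: tuple[str, ...] = ()
    control_groups: tuple[str, ...] = ()
    groups: tuple[str, ...] = ()  # for multi-group tests


def default_contrast_plan() -> list[Contrast]:
    """The study's eight comparison columns.

    Control-vs-pseudo-control and the three-way clinical comparison first
    (the homogeneity checks justifying aggregation), then the aggregated
    primary contrast and the finer case-group contrasts.
    """
    C = published.CONTROL_GROUPS
    return [
        Contrast("control_vs_pseudo", "two", ("CONTROL",), ("PSEUDO",)),
        Contrast("adhd_vs_asd_vs_both", "multi", groups=("ADHD", "ASD", "ADHD_ASD")),
        Contrast("clinical_vs_controls", "two", ("ADHD", "ASD", "ADHD_ASD"), C),
        Contrast("adhd_vs_controls", "two", ("ADHD",), C),
        Contrast("asd_vs_controls", "two", ("ASD",), C),
        Contrast("both_vs_controls", "two", ("ADHD_ASD",), C),
        Contrast("adhd_or_both_vs_controls", "two", ("ADHD", "ADHD_ASD"), C),
        Contrast("asd_or_both_vs_controls", "two", ("ASD", "ADHD_ASD"), C),
    ]


@dataclass
class SyntheticSpec:
    """Synthetic-cohort generation matching the study's sample structure."""

    n_trios: int = published.N_TRIOS
    n_extra_adhd: int = published.GROUP_SIZES["ADHD"] - published.N_TRIOS
    n_asd: int = published.GROUP_SIZES["ASD"]
    n_adhd_asd: int = published.GROUP_SIZES["ADHD_ASD"]
    n_controls: int = published.GROUP_SIZES["CONTROL"]
    pool_haplotypes: int = 20_000
    within_block_rho: float = 0.8
    baseline_prevalence: float = 0.05
    #: per-allele odds ratios; None -> the study's published significant ORs
    per_allele_or: dict[str, float] | None = None

    def disease_model(self) -> DiseaseModel:
        ors = self.per_allele_or
        if ors is None:
            ors = dict(published.PUBLISHED_OR)
        return DiseaseModel(baseline_prevalence=self.baseline_prevalence, per_allele_or=ors)


@dataclass
class RunConfig:
    seed: int = 0
    n_perm: int = 10_000
    sig_threshold: float = 0.05  #: nominal threshold gating best-model analysis
    qc: QCThresholds = field(default_factory=QCThresholds)
    synthetic: SyntheticSpec | None = field(default_factory=SyntheticSpec)
    #: list of (group label, ped path, map path); trios inferred from the PED
    inputs: list[tuple[str, str, str]] | None = None
    contrasts: list[Contrast] = field(default_factory=default_contrast_plan)
    primary_contrast: str = "clinical_vs_controls"
    #: gene name -> marker id list; None derives genes from marker chromosomes
    genes: dict[str, list[str]] | None = None
    gene_n_perm: int = 0  #: >0 adds a permuted gene p for the primary contrast
    ld_groups: tuple[str, ...] = ("CONTROL", "PSEUDO")
    tag_r2_threshold: float = 0.8

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict[str, Any]) -> "RunConfig":
        cfg = RunConfig()
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.n_perm = int(raw.get("n_perm", cfg.n_perm))
        cfg.sig_threshold = float(raw.get("sig_threshold", cfg.sig_threshold))
        cfg.gene_n_perm = int(raw.get("gene_n_perm", cfg.gene_n_perm))
        if "qc" in raw:
            cfg.qc = QCThresholds(**raw["qc"])
        if "inputs" in raw:
            cfg.inputs = [(d["label"], d["ped"], d["map"]) for d in raw["inputs"]]
            cfg.synthetic = None
        elif "synthetic" in raw:
            cfg.synthetic = SyntheticSpec(**raw["synthetic"])
        if "genes" in raw:
            cfg.genes = {k: list(v) for k, v in raw["genes"].items()}
        if "contrasts" in raw and raw["contrasts"] != "default":
            cfg.contrasts = [
                Contrast(
                    name=d["name"],
                    kind=d.get("kind", "two"),
                    case_groups=tuple(d.get("case_groups", ())),
                    control_groups=tuple(d.get("control_groups", ())),
                    groups=tuple(d.get("groups", ())),
                )
                for d in raw["contrasts"]
            ]
        if "primary_contrast" in raw:
            cfg.primary_contrast = raw["primary_contrast"]
        return cfg

    def validate(self) -> None:
        if not self.contrasts:
            raise ValueError("comparison plan is empty")
        names = [c.name for c in self.contrasts]
        if self.primary_contrast not in names:
            raise ValueError(f"primary contrast {self.primary_contrast!r} not in plan")
        if self.synthetic is None and not self.inputs:
            raise ValueError("either synthetic spec or input files are required")


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: Cohort  #: post-QC cohort including pseudo-controls
    trioset: TrioSet
    qc_report: QCReport
    snp_table: pd.DataFrame
    model_table: pd.DataFrame
    gene_table: pd.DataFrame
    ld_r2: pd.DataFrame
    ld_dprime: pd.DataFrame
    tag_bins: Any
    permutation: PermutationResult
    log: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.qc_report.table.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        self.snp_table.to_csv(out / "snp_table.tsv", sep="\t", index=False)
        self.model_table.to_csv(out / "model_table.tsv", sep="\t", index=False)
        self.gene_table.to_csv(out / "gene_table.tsv", sep="\t", index=False)
        self.ld_r2.to_csv(out / "ld_r2.tsv", sep="\t")
        self.ld_dprime.to_csv(out / "ld_dprime.tsv", sep="\t")
        (out / "log.txt").write_text("\n".join(self.log) + "\n")


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _load_stage(config: RunConfig) -> tuple[Cohort, TrioSet, list[str]]:
    log: list[str] = []
    if config.synthetic is not None:
        spec = config.synthetic
        panel_spec, markers = published.panel_spec()
        seeds = _derive_seeds(config.seed, 6)
        pool = simulate_haplotype_pool(
            panel_spec,
            spec.pool_haplotypes,
            within_block_rho=spec.within_block_rho,
            seed=seeds[0],
            markers=markers,
        )
        model = spec.disease_model()
        trio_cohort, trioset = simulate_trios(
            pool, model, spec.n_trios, seed=seeds[1], ascertain_affected_child=True,
            child_label="ADHD", parent_label="FOUNDER",
        )
        parts = [trio_cohort]
        for n, label, s in (
            (spec.n_extra_adhd, "ADHD", seeds[2]),
            (spec.n_asd, "ASD", seeds[3]),
            (spec.n_adhd_asd, "ADHD_ASD", seeds[4]),
        ):
            if n:
                parts.append(
                    simulate_case_control(pool, model, n, 0, seed=s, case_label=label)
                )
        if spec.n_controls:
            parts.append(
                simulate_case_control(
                    pool, model, 0, spec.n_controls, seed=seeds[5], control_label="CONTROL"
                )
            )
        cohort = Cohort.concat(parts)
        log.append(
            f"simulated cohort: {cohort.n_individuals} individuals "
            f"({spec.n_trios} trios), {cohort.n_markers} markers, seed {config.seed}"
        )
        return cohort, trioset, log

    cohorts: list[Cohort] = []
    all_trios: list[tuple[int, int, int]] = []
    offset = 0
    for label, ped, mp in config.inputs or []:
        c, t = read_pedmap(ped, mp)
        c = Cohort(
            markers=c.markers,
            individuals=[
                dataclasses.replace(ind, group=label if ind.group == "UNKNOWN" else ind.group)
                for ind in c.individuals
            ],
            genotypes=c.genotypes,
        )
        all_trios += [(f + offset, m + offset, ch + offset) for f, m, ch in t.trios]
        offset += c.n_individuals
        cohorts.append(c)
        log.append(f"loaded {ped}: {c.n_individuals} individuals, {len(t)} trios")
    cohort = Cohort.concat(cohorts)
    return cohort, TrioSet(trios=tuple(all_trios)), log


def _contrast_counts(
    cohort: Cohort, marker_id: str, groups: tuple[str, ...]
) -> GenotypeCounts:
    present = [g for g in groups if g in cohort.group_labels()]
    total = GenotypeCounts(0, 0, 0, 0)
    for g in present:
        total = total + genotype_counts(cohort, marker_id, (g,))
    return total


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow; any stage failure aborts with a stage name."""
    config.validate()
    log: list[str] = [f"config: seed={config.seed} n_perm={config.n_perm}"]

    try:
        cohort, trioset, stage_log = _load_stage(config)
        log += stage_log
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("load", e) from e

    try:
        qc_report = apply_qc(cohort, trioset, config.qc)
        cohort = cohort.select_markers(qc_report.survivors)
        log.append(
            f"qc: {len(qc_report.survivors)}/{len(qc_report.table)} markers pass"
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("qc", e) from e

    try:
        if len(trioset):
            pseudo = construct_pseudo_controls(trioset, cohort)
            cohort = Cohort.concat([cohort, pseudo])
            log.append(f"pseudo-controls: {pseudo.n_individuals} constructed")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("pseudo", e) from e

    marker_ids = [m.id for m in cohort.markers]
    effect = {m.id: m.allele_minor for m in cohort.markers}
    primary = next(c for c in config.contrasts if c.name == config.primary_contrast)

    try:
        rows = []
        primary_results: dict[str, AssociationResult] = {}
        for mid in marker_ids:
            marker = cohort.markers[cohort.marker_index(mid)]
            row: dict[str, Any] = {
                "marker": mid,
                "chrom": marker.chrom,
                "pos": marker.pos,
                "minor": marker.allele_minor,
                "major": marker.allele_major,
            }
            for g in sorted(cohort.group_labels()):
                if g == "FOUNDER":
                    continue
                cnt = genotype_counts(cohort, mid, (g,))
                row[f"maf_{g}"] = cnt.maf
            for con in config.contrasts:
                if con.kind == "multi":
                    counts = [_contrast_counts(cohort, mid, (g,)) for g in con.groups]
                    _, _, p = multigroup_allele_test(counts)
                    row[f"p_{con.name}"] = p
                else:
                    res = allelic_test(
                        _contrast_counts(cohort, mid, con.case_groups),
                        _contrast_counts(cohort, mid, con.control_groups),
                        marker=mid,
                        effect_allele=effect[mid],
                    )
                    row[f"p_{con.name}"] = res.p
                    if con.name == config.primary_contrast:
                        primary_results[mid] = res
                        row["or_primary"] = res.or_hat
                        row["or_ci_low"] = res.ci95[0]
                        row["or_ci_high"] = res.ci95[1]
            rows.append(row)
        snp_table = pd.DataFrame(rows)
        log.append(f"association: {len(rows)} markers x {len(config.contrasts)} contrasts")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("association", e) from e

    try:
        perm_seed = _derive_seeds(config.seed + 1, 1)[0]
        permutation = maxT_permutation(
            cohort,
            marker_ids=marker_ids,
            n_perm=config.n_perm,
            seed=perm_seed,
            case_groups=primary.case_groups,
            control_groups=primary.control_groups,
        )
        snp_table["p_permuted"] = [
            permutation.adjusted_p[permutation.markers.index(m)] for m in snp_table["marker"]
        ]
        log.append(f"permutation: n_perm={permutation.n_perm}")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("permutation", e) from e

    try:
        model_rows = []
        for mid in marker_ids:
            res = primary_results[mid]
            if math.isnan(res.p) or res.p >= config.sig_threshold:
                continue
            case_counts = _contrast_counts(cohort, mid, primary.case_groups)
            ctrl_counts = _contrast_counts(cohort, mid, primary.control_groups)
            candidates = [
                res,
                genotypic_test(case_counts, ctrl_counts, "dominant", marker=mid,
                               effect_allele=effect[mid]),
                genotypic_test(case_counts, ctrl_counts, "recessive", marker=mid,
                               effect_allele=effect[mid]),
            ]
            best = best_model(candidates)
            model_rows.append(
                {
                    "marker": mid,
                    "allelic_or": res.or_hat,
                    "allelic_p": res.p,
                    "best_model": best.model,
                    "best_or": best.or_hat,
                    "best_ci_low": best.ci95[0],
                    "best_ci_high": best.ci95[1],
                    "best_p": best.p,
                    "p_permuted": snp_table.loc[snp_table["marker"] == mid, "p_permuted"].iloc[0],
                }
            )
        model_table = pd.DataFrame(
            model_rows,
            columns=[
                "marker", "allelic_or", "allelic_p", "best_model", "best_or",
                "best_ci_low", "best_ci_high", "best_p", "p_permuted",
            ],
        )
        log.append(f"best-model: {len(model_rows)} markers below {config.sig_threshold}")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("best_model", e) from e

    try:
        ld_groups = tuple(g for g in config.ld_groups if g in cohort.group_labels())
        r2, dprime = ld_matrix(cohort, marker_ids, groups=ld_groups or None)
        positions = {m.id: m.pos for m in cohort.markers}
        tag_bins = select_tag_snps(r2, positions, threshold=config.tag_r2_threshold)
        log.append(f"ld: {len(marker_ids)}x{len(marker_ids)} matrix, {len(tag_bins.bins)} tag bins")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("ld", e) from e

    try:
        genes = config.genes
        if genes is None:
            genes = {}
            panel_genes = {s.id: s.gene for s in published.PANEL}
            for m in cohort.markers:
                genes.setdefault(panel_genes.get(m.id, f"chr{m.chrom}"), []).append(m.id)
        gene_rows = []
        ld_rows = cohort.group_indices(ld_groups or None)
        for gene, mids in genes.items():
            mids = [m for m in mids if m in marker_ids]
            if not mids:
                continue
            cols = [cohort.marker_index(m) for m in mids]
            g = cohort.genotypes[np.ix_(ld_rows, cols)].astype(float)
            g[g < 0] = np.nan
            corr = pd.DataFrame(g).corr().to_numpy()
            corr = np.nan_to_num(corr, nan=0.0)
            np.fill_diagonal(corr, 1.0)
            row: dict[str, Any] = {"gene": gene, "n_snps": len(mids)}
            for con in config.contrasts:
                if con.kind != "two":
                    continue
                ps = snp_table.set_index("marker").loc[mids, f"p_{con.name}"].to_numpy()
                ps = np.clip(ps, 1e-300, 1.0)
                res = gates_pvalue(ps, corr, gene=gene)
                row[f"p_{con.name}"] = res.p_gene
            if config.gene_n_perm > 0:
                row["p_permuted_primary"] = _gene_permuted_p(
                    cohort, mids, corr, primary, config.gene_n_perm,
                    _derive_seeds(config.seed + 2, 1)[0],
                )
            gene_rows.append(row)
        gene_table = pd.DataFrame(gene_rows)
        log.append(f"gene-level: {len(gene_rows)} genes")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("gene_level", e) from e

    return PipelineResult(
        config=config,
        cohort=cohort,
        trioset=trioset,
        qc_report=qc_report,
        snp_table=snp_table,
        model_table=model_table,
        gene_table=gene_table,
        ld_r2=r2,
        ld_dprime=dprime,
        tag_bins=tag_bins,
        permutation=permutation,
        log=log,
    )


def _gene_permuted_p(
    cohort: Cohort,
    marker_ids: list[str],
    corr: np.ndarray,
    contrast: Contrast,
    n_perm: int,
    seed: int,
) -> float:
    """Permutation p for the gene statistic under case/control label swapping.

    The genotype correlation matrix is held fixed at its observed-control
    estimate; per permutation the per-SNP allelic p-values are recomputed
    and recombined by GATES.  This mirrors the SNP-level max-T scheme
    applied to the gene statistic (an interpretation: the original analysis
    does not document its gene-level permutation).
    """
    case_rows = cohort.group_indices(contrast.case_groups)
    ctrl_rows = cohort.group_indices(contrast.control_groups)
    rows = np.concatenate([case_rows, ctrl_rows])
    cols = [cohort.marker_index(m) for m in marker_ids]
    g = cohort.genotypes[np.ix_(rows, cols)].astype(float)
    nonmiss = (g >= 0).astype(float)
    dos0 = np.where(g >= 0, g, 0.0)
    tot_minor = dos0.sum(axis=0)
    tot_alleles = 2.0 * nonmiss.sum(axis=0)
    n, k = len(rows), len(case_rows)

    def gene_p(ind_rows: np.ndarray) -> np.ndarray:
        chi2 = _allelic_chi2_rows(ind_rows, dos0, nonmiss, tot_minor, tot_alleles)
        ps = chi2_dist.sf(chi2, 1)
        out = np.empty(ind_rows.shape[0])
        for i in range(ind_rows.shape[0]):
            out[i] = gates_pvalue(np.clip(ps[i], 1e-300, 1.0), corr).p_gene
        return out

    obs_ind = np.zeros((1, n))
    obs_ind[0, :k] = 1.0
    observed = gene_p(obs_ind)[0]

    rng = np.random.default_rng(seed)
    base = np.zeros(n)
    base[:k] = 1.0
    perms = np.array([rng.permutation(base) for _ in range(n_perm)])
    perm_p = gene_p(perms)
    return float((1.0 + np.sum(perm_p <= observed + 1e-12)) / (n_perm + 1.0))
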