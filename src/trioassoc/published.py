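"""Published summary statistics of the SHANK2/SHANK3 candidate-gene study.

The study this pipeline models genotyped a tag-SNP panel over *SHANK2*
(chr11) and *SHANK3* (chr22) in four samples of boys — ADHD (n = 298,
including 256 complete trios), ASD (n = 134), comorbid ADHD + ASD
(n = 109) and typically developing community controls (n = 232) — plus 256
pseudo-controls built from the trios' non-transmitted parental alleles.
Individual-level genotypes are not deposited, but the published per-group
minor-allele frequencies, group sizes and per-SNP odds ratios are, which is
enough to reconstruct the aggregated case/control allele tables exactly to
printed precision.  This module holds that summary table as plain data so
that the rest of the package can (a) rebuild those allele tables, and
(b) parameterise the synthetic cohort generator with the study's own marker
panel and allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genotypes_io import Marker

CLINICAL_GROUPS = ("ADHD", "ASD", "ADHD_ASD")
CONTROL_GROUPS = ("CONTROL", "PSEUDO")

GROUP_SIZES: dict[str, int] = {
    "ADHD": 298,
    "ASD": 134,
    "ADHD_ASD": 109,
    "CONTROL": 232,
    "PSEUDO": 256,
}

N_TRIOS = 256


@dataclass(frozen=True)
class SummarySNP:
    gene: str
    id: str
    chrom: str
    pos: int
    allele_minor: str
    allele_major: str
    #: per-group minor-allele frequency (3-decimal published values)
    maf: dict[str, float]

    def marker(self) -> Marker:
        return Marker(self.id, self.chrom, self.pos, self.allele_minor, self.allele_major)


def _snp(gene, chrom, snp, pos, minor, major, adhd, asd, both, ctrl, pseudo):
    return SummarySNP(
        gene=gene,
        id=snp,
        chrom=chrom,
        pos=pos,
        allele_minor=minor,
        allele_major=major,
        maf={
            "ADHD": adhd,
            "ASD": asd,
            "ADHD_ASD": both,
            "CONTROL": ctrl,
            "PSEUDO": pseudo,
        },
    )


#: the 20 post-QC panel SNPs with their published per-group MAFs
PANEL: tuple[SummarySNP, ...] = (
    _snp("SHANK2", "11", "rs2000605", 70353848, "T", "C", 0.463, 0.455, 0.472, 0.439, 0.422),
    _snp("SHANK2", "11", "rs11826745", 70376203, "C", "T", 0.405, 0.444, 0.419, 0.416, 0.413),
    _snp("SHANK2", "11", "rs11236570", 70379131, "A", "G", 0.416, 0.405, 0.392, 0.421, 0.390),
    _snp("SHANK2", "11", "rs7113016", 70385037, "A", "G", 0.391, 0.371, 0.407, 0.446, 0.430),
    _snp("SHANK2", "11", "rs4550246", 70390048, "A", "C", 0.365, 0.362, 0.362, 0.412, 0.396),
    _snp("SHANK2", "11", "rs1073294", 70401985, "G", "A", 0.448, 0.428, 0.441, 0.400, 0.367),
    _snp("SHANK2", "11", "rs11236616", 70403442, "A", "G", 0.309, 0.308, 0.367, 0.373, 0.390),
    _snp("SHANK2", "11", "rs7106631", 70405829, "T", "G", 0.385, 0.407, 0.387, 0.457, 0.484),
    _snp("SHANK2", "11", "rs10899158", 70405952, "T", "C", 0.460, 0.459, 0.516, 0.438, 0.416),
    _snp("SHANK2", "11", "rs9888288", 70419246, "T", "A", 0.384, 0.407, 0.458, 0.452, 0.484),
    _snp("SHANK2", "11", "rs12363289", 70445161, "T", "C", 0.345, 0.338, 0.257, 0.334, 0.312),
    _snp("SHANK2", "11", "rs948191", 70452995, "G", "A", 0.325, 0.362, 0.372, 0.336, 0.348),
    _snp("SHANK2", "11", "rs563532", 70492408, "G", "C", 0.398, 0.432, 0.471, 0.420, 0.437),
    _snp("SHANK3", "22", "rs1001469", 51138753, "A", "G", 0.411, 0.451, 0.421, 0.405, 0.380),
    _snp("SHANK3", "22", "rs2341011", 51139635, "T", "C", 0.325, 0.320, 0.351, 0.344, 0.362),
    _snp("SHANK3", "22", "rs739365", 51140316, "C", "T", 0.305, 0.267, 0.248, 0.316, 0.287),
    _snp("SHANK3", "22", "rs2040487", 51147015, "A", "G", 0.404, 0.410, 0.393, 0.386, 0.390),
    _snp("SHANK3", "22", "rs5770820", 51150473, "G", "A", 0.502, 0.485, 0.429, 0.487, 0.494),
    _snp("SHANK3", "22", "rs6010065", 51158017, "G", "C", 0.411, 0.399, 0.392, 0.450, 0.415),
    _snp("SHANK3", "22", "rs8137951", 51165664, "A", "G", 0.424, 0.428, 0.481, 0.407, 0.449),
)

#: published aggregated-contrast allelic odds ratios for the SNPs the study
#: reported as significant (aggregated clinical vs aggregated control sample)
PUBLISHED_OR: dict[str, float] = {
    "rs7113016": 0.819,
    "rs1073294": 1.275,
    "rs11236616": 0.762,
    "rs7106631": 0.720,
    "rs10899158": 1.194,
    "rs9888288": 0.770,
}

#: analytic power scenarios the study quotes: cases vs aggregated controls
#: at per-allele OR 1.5, control MAF 0.4, two-sided alpha 0.001
POWER_SCENARIOS: tuple[tuple[str, int, int, int], ...] = (
    # (contrast, n_case, n_control, published power %)
    ("aggregate", 541, 488, 90),
    ("ADHD", 298, 488, 72),
    ("ASD", 134, 488, 36),
    ("ADHD_ASD", 109, 488, 28),
)


def snp(snp_id: str) -> SummarySNP:
    for s in PANEL:
        if s.id == snp_id:
            return s
    raise KeyError(f"unknown panel SNP {snp_id!r}")


def reconstruct_allele_table(
    snp_id: str,
    case_groups: tuple[str, ...] = CLINICAL_GROUPS,
    control_groups: tuple[str, ...] = CONTROL_GROUPS,
) -> tuple[int, int, int, int]:
    """Aggregated 2x2 allele table (case minor/major, control minor/major).

    Expected allele counts are group size x 2 x published frequency, summed
    over the aggregated groups and rounded to the nearest whole allele; the
    published frequencies carry three decimals, so the rounding error per
    cell is below one allele.
    """
    s = snp(snp_id)

    def cells(groups: tuple[str, ...]) -> tuple[int, int]:
        minor = sum(2 * GROUP_SIZES[g] * s.maf[g] for g in groups)
        total = sum(2 * GROUP_SIZES[g] for g in groups)
        a = round(minor)
        return a, total - a

    a, b = cells(case_groups)
    c, d = cells(control_groups)
    return a, b, c, d


def panel_spec(
    maf_group: str = "CONTROL",
) -> tuple[list[tuple[float, int]], list[Marker]]:
    """Synthetic-panel specification mirroring the study's marker panel.

    Returns ``(spec, markers)`` where ``spec`` is a list of (maf, block id)
    using the chosen group's published frequencies, with one LD block per
    gene (the two genes sit on different chromosomes, hence independent).
    """
    blocks = {"SHANK2": 0, "SHANK3": 1}
    spec = [(s.maf[maf_group], blocks[s.gene]) for s in PANEL]
    markers = [s.marker() for s in PANEL]
    return spec, markers
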