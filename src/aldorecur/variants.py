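"""Cohort-level variant searches for a rare monogenic phenotype.

Three search strategies over a cohort variant table:

* *recurrent novel variants* — protein-altering variants absent from every
  reference database that occur in more than one unrelated subject (the
  signature of a recurrent dominant mutation);
* *gene burden* — per-gene carrier counts in cases versus a sequenced
  control cohort, compared by Fisher's exact test;
* recessive searches are expressed through the same burden interface with
  carriers defined as homozygous or putative compound-heterozygous subjects.

The table is a thin, validated wrapper around a pandas DataFrame with
VCF-style 1-based coordinates and minimally normalized alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

__all__ = [
    "CohortVariantTable",
    "BurdenResult",
    "PROTEIN_ALTERING",
    "recurrent_novel_variants",
    "gene_burden_test",
    "read_variant_tsv",
    "read_variant_vcf",
]

#: Consequence classes counted as protein-altering (configurable per call).
PROTEIN_ALTERING = frozenset(
    {
        "missense",
        "nonsense",
        "stop_gained",
        "frameshift",
        "splice",
        "splice_donor",
        "splice_acceptor",
        "inframe_indel",
        "inframe_insertion",
        "inframe_deletion",
        "stop_lost",
    }
)

REQUIRED_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "subject",
    "gene",
    "consequence",
    "known",
    "genotype",
]


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation of an allele pair (shared suffix, then prefix).

    Left-alignment against a reference sequence is out of scope; trimming to
    the minimal representation is sufficient to make equal variants compare
    equal across input dialects.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class CohortVariantTable:
    """Per-subject variant calls for a cohort.

    ``df`` columns: ``chrom, pos (1-based), ref, alt, subject, gene,
    consequence, known (bool: present in any reference database), genotype
    ({"het", "hom"})``.  (variant, subject) pairs must be unique after allele
    normalization.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        df = self.df.copy()
        norm = [
            normalize_alleles(int(p), r, a)
            for p, r, a in zip(df["pos"], df["ref"], df["alt"])
        ]
        df["pos"] = [n[0] for n in norm]
        df["ref"] = [n[1] for n in norm]
        df["alt"] = [n[2] for n in norm]
        df["known"] = df["known"].astype(bool)
        if (df["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        bad_gt = set(df["genotype"]) - {"het", "hom"}
        if bad_gt:
            raise ValueError(f"unknown genotypes: {sorted(bad_gt)}")
        key = df[["chrom", "pos", "ref", "alt", "subject"]]
        if key.duplicated().any():
            raise ValueError("(variant, subject) pairs must be unique")
        self.df = df.reset_index(drop=True)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.df["subject"].unique())


def recurrent_novel_variants(
    table: CohortVariantTable,
    min_subjects: int = 2,
    protein_altering: frozenset[str] = PROTEIN_ALTERING,
) -> pd.DataFrame:
    """Previously unreported protein-altering variants seen in >=`min_subjects`.

    Returns one row per qualifying variant with its distinct-subject count,
    sorted by descending count then (chrom, pos).
    """
    df = table.df
    mask = df["consequence"].isin(protein_altering) & ~df["known"]
    hits = (
        df[mask]
        .groupby(["chrom", "pos", "ref", "alt", "gene"], as_index=False)
        .agg(n_subjects=("subject", "nunique"))
    )
    hits = hits[hits["n_subjects"] >= min_subjects]
    return hits.sort_values(
        ["n_subjects", "chrom", "pos"], ascending=[False, True, True]
    ).reset_index(drop=True)


@dataclass(frozen=True)
class BurdenResult:
    """Fisher-exact comparison of carrier counts for one gene."""

    gene: str
    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int
    p_value: float
    p_adjusted: float
    mode: str = "dominant"
    odds_ratio: float = float("nan")


def gene_burden_test(
    case_carriers: int,
    case_n: int,
    ctrl_carriers: int,
    ctrl_n: int,
    mode: str = "dominant",
    gene: str = "",
    n_genes_tested: int = 1,
) -> BurdenResult:
    """Two-sided Fisher exact test on a 2x2 carrier table.

    ``mode`` records how carriers were defined upstream (``dominant``: >=1
    qualifying heterozygous variant; ``recessive``: homozygous or >=2
    qualifying variants); it does not change the arithmetic.  The two-sided
    p-value sums all tables with point probability <= that of the observed
    table.  ``p_adjusted`` is Bonferroni over ``n_genes_tested``.
    """
    if case_n <= 0 or ctrl_n <= 0:
        raise ValueError("cohort totals must be positive")
    if not (0 <= case_carriers <= case_n and 0 <= ctrl_carriers <= ctrl_n):
        raise ValueError("carrier counts must not exceed totals")
    if mode not in ("dominant", "recessive"):
        raise ValueError("mode must be 'dominant' or 'recessive'")
    table = [
        [case_carriers, case_n - case_carriers],
        [ctrl_carriers, ctrl_n - ctrl_carriers],
    ]
    res = stats.fisher_exact(table, alternative="two-sided")
    p = float(res.pvalue)
    return BurdenResult(
        gene=gene,
        case_carriers=case_carriers,
        case_total=case_n,
        control_carriers=ctrl_carriers,
        control_total=ctrl_n,
        p_value=p,
        p_adjusted=min(1.0, p * n_genes_tested),
        mode=mode,
        odds_ratio=float(res.statistic),
    )


def read_variant_tsv(path) -> CohortVariantTable:
    """Read the TSV dialect (one call per row, headers as in REQUIRED_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return CohortVariantTable(df)


def read_variant_vcf(path) -> CohortVariantTable:
    """Read a minimal annotated VCF into a cohort variant table.

    Requires per-record INFO keys ``GENE``, ``CSQ`` (consequence class) and
    ``KNOWN`` (0/1 reference-database membership) and per-sample GT fields;
    only non-reference sample genotypes become rows.  Uses cyvcf2.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    for rec in vcf:
        gene = rec.INFO.get("GENE", "")
        csq = rec.INFO.get("CSQ", "")
        known = bool(int(rec.INFO.get("KNOWN", 0)))
        for sample, gt in zip(samples, rec.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            n_alt = sum(1 for a in alleles if a > 0)
            if n_alt == 0:
                continue
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": rec.ALT[0],
                    "subject": sample,
                    "gene": gene,
                    "consequence": csq,
                    "known": known,
                    "genotype": "hom" if n_alt >= 2 else "het",
                }
            )
    return CohortVariantTable(pd.DataFrame(rows))
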