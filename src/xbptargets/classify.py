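"""XBP1-dependency classification from a genes x conditions fold-change matrix.

The matrix has the validated-panel shape: per gene, fold changes under XBP1s
induction, Tg and Tm stress vs control, XBP1 silencing during each stress vs
control, and the two derived silencing-vs-stress ratios, plus a parallel
boolean significance matrix. One distinguished row (``XBP1s``) carries the
transcription factor's own profile.

A gene is called XBP1-dependent when it responds significantly in at least
two of the three independent experimental approaches (induction; silencing
during Tg; silencing during Tm). Dependent genes are split by the sign of
the Pearson correlation of their profile with the XBP1s profile — positive
means XBP1-activated, negative XBP1-repressed. Genes whose silencing
responses point in opposite directions under the two stressors (both
significant) are demoted to ``model_dependent``: their levels track the
stress model, not XBP1 alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError, XbpTargetsError
from .expression import GeneSet

#: Canonical fold-change columns, in panel order.
PROFILE_COLUMNS = [
    "induced_xbp1s",
    "tg_vs_ctrl",
    "tg_sixbp1_vs_ctrl",
    "tg_sixbp1_vs_tg",
    "tm_vs_ctrl",
    "tm_sixbp1_vs_ctrl",
    "tm_sixbp1_vs_tm",
]

#: Columns entering the profile correlation: the induction response and the
#: four vs-control responses. The derived vs-stress ratios are excluded to
#: avoid counting the same measurements twice.
CORRELATION_COLUMNS = [
    "induced_xbp1s",
    "tg_vs_ctrl",
    "tg_sixbp1_vs_ctrl",
    "tm_vs_ctrl",
    "tm_sixbp1_vs_ctrl",
]

REFERENCE_GENE = "XBP1s"

CLASSES = ("activated", "repressed", "model_dependent", "unclassified")


@dataclass(frozen=True)
class CorrelationResult:
    gene_id: str
    r: float
    p_value: float
    n_conditions: int


@dataclass(frozen=True)
class ClassificationResult:
    gene_id: str
    gene_class: str
    n_significant_approaches: int
    r: float  # NaN when the correlation is undefined


def validate_matrix(matrix: pd.DataFrame, reference_gene: str = REFERENCE_GENE) -> None:
    missing = [c for c in PROFILE_COLUMNS if c not in matrix.columns]
    if missing:
        raise XbpTargetsError(f"profile matrix lacks columns {missing}")
    if reference_gene not in matrix.index:
        raise XbpTargetsError(f"reference row {reference_gene!r} absent from matrix")
    fc = matrix[PROFILE_COLUMNS].astype(float)
    if (fc <= 0).any().any():
        bad = fc.index[(fc <= 0).any(axis=1)][0]
        raise XbpTargetsError(f"non-positive fold change in row {bad!r}")


def profile_correlation(
    matrix: pd.DataFrame,
    gene: str,
    reference_gene: str = REFERENCE_GENE,
    columns: list[str] | None = None,
    log2: bool = False,
) -> CorrelationResult:
    """Pearson correlation of a gene's profile with the XBP1s profile.

    Fold changes are correlated raw by default (``log2=True`` transforms
    both profiles first). Two-sided p from the t-distribution on n - 2 df.
    Zero variance in either profile raises
    :class:`UndefinedCorrelationError`.
    """
    cols = columns if columns is not None else CORRELATION_COLUMNS
    if len(cols) < 3:
        raise XbpTargetsError("need >= 3 columns for a profile correlation")
    x = matrix.loc[gene, cols].astype(float).values
    y = matrix.loc[reference_gene, cols].astype(float).values
    if log2:
        x, y = np.log2(x), np.log2(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in profile of {gene!r} or {reference_gene!r}"
        )
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(gene, float(r), float(p), len(cols))


def concordance_count(
    significance: pd.DataFrame,
    gene: str,
    rule: str = "or",
) -> int:
    """How many of the three experimental approaches respond significantly.

    Approach 1 is the induction experiment; approaches 2 and 3 are the
    silencing arms under Tg and Tm. Under the default ``or`` rule a
    silencing arm fires when either of its printed comparisons (vs control,
    vs stress alone) is significant; ``vs_ctrl_only`` / ``vs_stress_only``
    restrict it to a single column.
    """
    row = significance.loc[gene]
    arms = {
        "or": (
            ["tg_sixbp1_vs_ctrl", "tg_sixbp1_vs_tg"],
            ["tm_sixbp1_vs_ctrl", "tm_sixbp1_vs_tm"],
        ),
        "vs_ctrl_only": (["tg_sixbp1_vs_ctrl"], ["tm_sixbp1_vs_ctrl"]),
        "vs_stress_only": (["tg_sixbp1_vs_tg"], ["tm_sixbp1_vs_tm"]),
    }
    if rule not in arms:
        raise XbpTargetsError(f"unknown concordance rule {rule!r}")
    tg_cols, tm_cols = arms[rule]
    n = int(bool(row["induced_xbp1s"]))
    n += int(any(bool(row[c]) for c in tg_cols))
    n += int(any(bool(row[c]) for c in tm_cols))
    return n


def classify_gene(
    matrix: pd.DataFrame,
    significance: pd.DataFrame,
    gene: str,
    reference_gene: str = REFERENCE_GENE,
    min_approaches: int = 2,
    rule: str = "or",
    correlation_columns: list[str] | None = None,
    log2: bool = False,
) -> ClassificationResult:
    """Assign one gene to activated / repressed / model_dependent / unclassified.

    Genes below ``min_approaches`` concordant significant approaches are
    unclassified. Otherwise the sign of the profile correlation decides
    activated (r > 0) vs repressed (r < 0); r exactly 0 or undefined is
    unclassified. Before the sign test, a gene whose two silencing-vs-stress
    ratios are both significant and point in opposite directions (one > 1,
    one < 1) is demoted to model_dependent.
    """
    n_sig = concordance_count(significance, gene, rule=rule)
    try:
        corr = profile_correlation(
            matrix, gene, reference_gene, columns=correlation_columns, log2=log2
        )
        r = corr.r
    except UndefinedCorrelationError:
        r = float("nan")
    if n_sig < min_approaches:
        return ClassificationResult(gene, "unclassified", n_sig, r)
    tg_ratio = float(matrix.loc[gene, "tg_sixbp1_vs_tg"])
    tm_ratio = float(matrix.loc[gene, "tm_sixbp1_vs_tm"])
    both_sig = bool(significance.loc[gene, "tg_sixbp1_vs_tg"]) and bool(
        significance.loc[gene, "tm_sixbp1_vs_tm"]
    )
    opposite = (tg_ratio > 1 and tm_ratio < 1) or (tg_ratio < 1 and tm_ratio > 1)
    if both_sig and opposite:
        return ClassificationResult(gene, "model_dependent", n_sig, r)
    if np.isnan(r) or r == 0:
        return ClassificationResult(gene, "unclassified", n_sig, r)
    gene_class = "activated" if r > 0 else "repressed"
    return ClassificationResult(gene, gene_class, n_sig, r)


def classify_matrix(
    matrix: pd.DataFrame,
    significance: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    min_approaches: int = 2,
    rule: str = "or",
    log2: bool = False,
) -> list[ClassificationResult]:
    """Classify every non-reference gene of the matrix."""
    validate_matrix(matrix, reference_gene)
    if list(significance.index) != list(matrix.index) or list(
        significance.columns
    ) != [c for c in matrix.columns if c in PROFILE_COLUMNS]:
        significance = significance.reindex(
            index=matrix.index, columns=PROFILE_COLUMNS
        ).fillna(False)
    return [
        classify_gene(
            matrix,
            significance,
            gene,
            reference_gene,
            min_approaches=min_approaches,
            rule=rule,
            log2=log2,
        )
        for gene in matrix.index
        if gene != reference_gene
    ]


def summarize_classes(
    results: list[ClassificationResult],
) -> tuple[dict[str, GeneSet], pd.DataFrame]:
    """Group classification results per class and build a delimited report.

    Genes are sorted lexicographically within class; the report has one row
    per gene with its class, correlation and approach count.
    """
    sets = {
        cls: GeneSet(cls, frozenset(r.gene_id for r in results if r.gene_class == cls))
        for cls in CLASSES
    }
    rows = sorted(results, key=lambda r: (r.gene_class, r.gene_id))
    report = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "class": [r.gene_class for r in rows],
            "r": [r.r for r in rows],
            "n_significant_approaches": [r.n_significant_approaches for r in rows],
        }
    )
    return sets, report
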