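"""Relative qPCR quantification by the 2^-ddCt method with dual references.

A Ct table holds one row per well: sample, condition, gene, biological
experiment index, technical replicate index, and the threshold cycle. Per
biological experiment, dCt = Ct(target) - mean Ct(references); the default
references are GAPDH and RPLP0, combined by the arithmetic mean of their Cts
(the geometric mean in expression space). ddCt is the difference of the
cross-experiment mean dCt between a condition and its baseline, and the
fold change is 2^-ddCt under the usual perfect-efficiency premise.

Statistics are computed on per-experiment dCt values only — technical
replicates are averaged first and never inflate n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingReferenceError, XbpTargetsError

DEFAULT_REFERENCES = ("GAPDH", "RPLP0")

#: Required columns of a Ct table.
CT_COLUMNS = ["sample_id", "condition_id", "gene_id", "experiment", "technical", "ct"]


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR well: threshold cycle for a gene in a replicate."""

    sample_id: str
    condition_id: str
    gene_id: str
    experiment: int
    technical: int
    ct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct):
            raise XbpTargetsError(f"non-finite Ct for {self.gene_id}")
        if self.experiment < 1 or self.technical < 1:
            raise XbpTargetsError("replicate indices are 1-based (>= 1)")


def measurements_to_table(measurements) -> pd.DataFrame:
    """Build a Ct table DataFrame from :class:`CtMeasurement` records."""
    return pd.DataFrame([vars(m) for m in measurements], columns=CT_COLUMNS)


@dataclass(frozen=True)
class ConditionDescriptor:
    """Experimental condition metadata for a Ct table.

    ``treatment`` is one of vehicle / Tm / Tg / doxycycline-induction;
    ``dose`` carries its unit in ``dose_unit`` (ug/ml for Tm, nM for Tg);
    ``silencing`` names the siRNA arm; ``baseline_of`` optionally points at
    the condition this one is compared against.
    """

    condition_id: str
    treatment: str
    dose: float
    dose_unit: str = ""
    time_h: float = 6.0
    silencing: str = "none"
    baseline_of: str | None = None

    def __post_init__(self) -> None:
        if self.treatment == "vehicle" and self.dose != 0:
            raise XbpTargetsError(
                f"vehicle condition {self.condition_id!r} must have dose 0"
            )
        if self.dose < 0:
            raise XbpTargetsError("dose must be >= 0")


@dataclass(frozen=True)
class RelativeExpression:
    """One gene/condition fold change relative to a baseline condition."""

    gene_id: str
    condition_id: str
    baseline_id: str
    fold_change: float
    sd: float
    p_value: float
    n: int
    delta_ct: float
    delta_delta_ct: float


@dataclass(frozen=True)
class SignificanceResult:
    p_value: float
    significant: bool
    zero_variance: bool
    method: str


def _per_experiment_delta_ct(
    cts: pd.DataFrame, target: str, refs: tuple[str, ...], condition: str
) -> pd.Series:
    """dCt per biological experiment for one gene in one condition."""
    sub = cts[cts["condition_id"] == condition]
    if sub.empty:
        raise XbpTargetsError(f"no measurements for condition {condition!r}")
    tgt = sub[sub["gene_id"] == target]
    if tgt.empty:
        raise XbpTargetsError(
            f"no measurements for target {target!r} in condition {condition!r}"
        )
    # technical replicates averaged within experiment first
    tgt_ct = tgt.groupby("experiment")["ct"].mean()
    ref_means = []
    for ref in refs:
        r = sub[sub["gene_id"] == ref]
        if r.empty:
            raise MissingReferenceError(
                f"reference gene {ref!r} missing in condition {condition!r}"
            )
        ref_means.append(r.groupby("experiment")["ct"].mean())
    ref_ct = pd.concat(ref_means, axis=1).mean(axis=1)
    dct = tgt_ct - ref_ct
    if dct.isna().any():
        missing = sorted(dct[dct.isna()].index)
        raise XbpTargetsError(
            f"target/reference experiments do not align for {target!r} in "
            f"{condition!r} (experiments {missing})"
        )
    return dct


def delta_delta_ct(
    cts: pd.DataFrame,
    target: str,
    condition: str,
    baseline_condition: str,
    refs: tuple[str, ...] = DEFAULT_REFERENCES,
    method: str = "student_t",
    alpha: float = 0.05,
) -> RelativeExpression:
    """Fold change of ``target`` in ``condition`` vs ``baseline_condition``.

    Returns a :class:`RelativeExpression` whose ``sd`` is the spread of the
    per-experiment fold changes (each experiment's dCt compared with the
    baseline mean dCt) and whose ``p_value`` comes from
    :func:`significance_test` on the per-experiment dCt values.
    """
    dct_cond = _per_experiment_delta_ct(cts, target, tuple(refs), condition)
    dct_base = _per_experiment_delta_ct(cts, target, tuple(refs), baseline_condition)
    ddct = float(dct_cond.mean() - dct_base.mean())
    fold = 2.0 ** (-ddct)
    per_exp_fold = 2.0 ** (-(dct_cond - dct_base.mean()))
    sd = float(per_exp_fold.std(ddof=1)) if len(per_exp_fold) > 1 else 0.0
    if len(dct_cond) >= 2 and len(dct_base) >= 2:
        sig = significance_test(dct_cond.values, dct_base.values, method=method, alpha=alpha)
        p = sig.p_value
    else:
        p = float("nan")
    return RelativeExpression(
        gene_id=target,
        condition_id=condition,
        baseline_id=baseline_condition,
        fold_change=fold,
        sd=sd,
        p_value=p,
        n=len(dct_cond),
        delta_ct=float(dct_cond.mean()),
        delta_delta_ct=ddct,
    )


def significance_test(
    values_a,
    values_b,
    method: str = "student_t",
    alpha: float = 0.05,
) -> SignificanceResult:
    """Two-sided test between two groups of per-experiment values.

    ``student_t`` is the pooled-variance Student's t-test; ``anova_on_ranks``
    is the Kruskal-Wallis H test (its two-group form). Degenerate input in
    which every value is identical returns p = 1 with the zero-variance flag
    set rather than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise XbpTargetsError("need >= 2 values per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        return SignificanceResult(1.0, False, True, method)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # noise-free groups at different levels: separation is exact
        return SignificanceResult(0.0, True, True, method)
    if method == "student_t":
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    elif method == "anova_on_ranks":
        p = float(stats.kruskal(a, b).pvalue)
    else:
        raise XbpTargetsError(f"unknown method {method!r}")
    if math.isnan(p):
        return SignificanceResult(1.0, False, True, method)
    return SignificanceResult(p, p <= alpha, False, method)


def rebase_fold_change(fc_vs_ctrl: float, fc_baseline_vs_ctrl: float) -> float:
    """Convert a vs-control fold change to a vs-stress-baseline fold change.

    Both arguments are fold changes against the same control; the result is
    their ratio, algebraically 2^-(ddCt1 - ddCt2). Used to derive the
    "FC vs Tg" / "FC vs Tm" silencing columns from the printed vs-Ctrl ones.
    """
    if fc_vs_ctrl <= 0 or fc_baseline_vs_ctrl <= 0:
        raise XbpTargetsError("fold changes must be positive")
    return fc_vs_ctrl / fc_baseline_vs_ctrl


@dataclass(frozen=True)
class MildDoseResult:
    stressor: str
    dose: float | None  # None when no dose qualifies
    threshold_fold: float


def select_mild_dose(
    dose_response: pd.DataFrame,
    threshold_fold: float = 2.0,
) -> dict[str, MildDoseResult]:
    """Lowest dose inducing every reporter by >= ``threshold_fold``.

    ``dose_response`` has columns ``stressor, dose, gene_id, fold_change``
    (one row per reporter; the reporters are typically XBP1s, HSPA5 and
    DDIT3 at 6 h). Doses at which any reporter is unmeasured do not qualify.
    A stressor with no qualifying dose maps to ``dose=None``.
    """
    if dose_response.empty:
        raise XbpTargetsError("empty dose-response table")
    required = {"stressor", "dose", "gene_id", "fold_change"}
    if not required.issubset(dose_response.columns):
        raise XbpTargetsError(f"dose-response table needs columns {sorted(required)}")
    reporters = set(dose_response["gene_id"])
    out: dict[str, MildDoseResult] = {}
    for stressor, sub in dose_response.groupby("stressor"):
        chosen = None
        for dose in sorted(sub["dose"].unique()):
            at = sub[sub["dose"] == dose]
            if set(at["gene_id"]) == reporters and (
                at["fold_change"] >= threshold_fold
            ).all():
                chosen = float(dose)
                break
        out[str(stressor)] = MildDoseResult(str(stressor), chosen, threshold_fold)
    return out
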