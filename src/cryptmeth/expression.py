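"""Relative expression (ΔΔCt), reporter normalization, and regulatory calls.

``ddct_fold`` implements the standard ΔΔCt method: per sample
ΔCt = Ct(target) − Ct(reference gene); per condition
ΔΔCt = mean ΔCt(condition) − mean ΔCt(reference condition);
fold = 2^(−ΔΔCt).  Standard errors are propagated on the ΔΔCt (log2) scale
and exponentiated; significance per condition is an unpaired two-tailed t
test of ΔCt against the reference condition (Student's by default).

``luciferase_relative`` normalizes firefly counts to the Renilla
co-transfection control per well, then compares the transcription-factor
(+) and empty-vector (−) conditions per construct.

``call_regulation`` integrates binding (peak presence per group) with the
perturbation arms: a gene whose expression falls under knockdown and rises
under overexpression is an activated target; the mirrored pattern is a
repressed target; anything else (including discordant significant arms) is
no_regulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConditionFold",
    "RegulatoryCall",
    "ddct_fold",
    "luciferase_relative",
    "call_regulation",
]


@dataclass(frozen=True)
class ConditionFold:
    """Fold change of one condition relative to the reference condition."""

    condition: str
    fold: float
    se_log2: float  # SE of ΔΔCt, log2 scale
    n: int
    t_p: float  # t-test p of ΔCt vs reference condition (NaN for reference)


@dataclass(frozen=True)
class RegulatoryCall:
    gene: str
    peak_in_case: bool
    peak_in_control: bool
    knockdown_direction: str  # down | up | ns
    overexpression_direction: str
    call: str  # activated_target | repressed_target | no_regulation
    discordant: bool = False


def ddct_fold(
    records: pd.DataFrame, target: str, reference_condition: str,
    equal_var: bool = True,
) -> dict[str, ConditionFold]:
    """Per-condition 2^(−ΔΔCt) fold changes for one target gene.

    ``records`` needs columns sample_id, condition, target_gene, ct_target,
    ct_reference.  Rows for other targets are ignored.
    """
    sub = records[records["target_gene"] == target]
    if sub.empty:
        raise ValueError(f"no Ct records for target {target!r}")
    ct = sub["ct_target"].to_numpy(dtype=float)
    ct_ref_gene = sub["ct_reference"].to_numpy(dtype=float)
    if ((ct <= 0) | (ct >= 45) | (ct_ref_gene <= 0) | (ct_ref_gene >= 45)).any():
        raise ValueError("Ct values must lie in (0, 45)")
    dct = pd.Series(ct - ct_ref_gene, index=sub.index)
    by_cond = {c: dct[sub["condition"] == c].to_numpy() for c in sub["condition"].unique()}
    if reference_condition not in by_cond:
        raise ValueError(f"reference condition {reference_condition!r} absent from records")
    ref = by_cond[reference_condition]
    ref_mean = ref.mean()
    ref_se2 = ref.var(ddof=1) / len(ref) if len(ref) > 1 else 0.0

    out = {}
    for cond, x in by_cond.items():
        ddct = x.mean() - ref_mean
        se2 = (x.var(ddof=1) / len(x) if len(x) > 1 else 0.0)
        if cond == reference_condition:
            fold, se, p = 1.0, float(np.sqrt(2 * se2)), float("nan")
        else:
            fold = float(2.0 ** (-ddct))
            se = float(np.sqrt(se2 + ref_se2))
            if len(x) > 1 and len(ref) > 1:
                with warnings.catch_warnings():
                    # zero-variance replicates (exact closed-form fixtures) are fine
                    warnings.simplefilter("ignore", RuntimeWarning)
                    p = float(stats.ttest_ind(x, ref, equal_var=equal_var).pvalue)
            else:
                p = float("nan")
        out[cond] = ConditionFold(cond, fold, se, len(x), p)
    return out


def luciferase_relative(
    readings: pd.DataFrame,
    empty_vector_condition: str,
    active_condition: str | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Renilla-normalized fold activation per construct.

    ``readings`` needs columns construct, condition, firefly, renilla; wells
    with renilla <= 0 are excluded with a warning.  Returns one row per
    construct: fold = mean(firefly/renilla | active) / mean(... | empty),
    with a two-sided t-test p across replicate wells.
    """
    bad = readings["renilla"] <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} well(s) with non-positive Renilla signal")
        readings = readings[~bad]
    readings = readings.assign(ratio=readings["firefly"] / readings["renilla"])
    rows = []
    for construct, sub in readings.groupby("construct", sort=False):
        conditions = [c for c in sub["condition"].unique() if c != empty_vector_condition]
        if active_condition is not None:
            conditions = [active_condition]
        if len(conditions) != 1:
            raise ValueError(
                f"construct {construct!r}: expected one active condition, got {conditions}"
            )
        active = sub.loc[sub["condition"] == conditions[0], "ratio"].to_numpy()
        empty = sub.loc[sub["condition"] == empty_vector_condition, "ratio"].to_numpy()
        if len(active) == 0 or len(empty) == 0:
            raise ValueError(f"construct {construct!r}: missing a condition arm")
        if len(active) > 1 and len(empty) > 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(stats.ttest_ind(active, empty, equal_var=equal_var).pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "construct": construct,
                "fold": float(active.mean() / empty.mean()),
                "n_active": len(active),
                "n_empty": len(empty),
                "t_p": p,
            }
        )
    return pd.DataFrame(rows)


def _direction(fold: float, p: float, alpha: float) -> str:
    if not np.isnan(p) and p < alpha:
        if fold > 1.0:
            return "up"
        if fold < 1.0:
            return "down"
    return "ns"


def call_regulation(
    peak_presence: dict[str, tuple[bool, bool]],
    perturbation_folds: dict[str, dict[str, tuple[float, float]]],
    alpha: float = 0.05,
) -> list[RegulatoryCall]:
    """Classify genes as activated/repressed targets from perturbation concordance.

    ``peak_presence`` maps gene -> (peak_in_case, peak_in_control);
    ``perturbation_folds`` maps gene -> {"knockdown": (fold, p),
    "overexpression": (fold, p)}.  Genes missing either arm are skipped with
    a warning.  Significant same-sense directions in both arms (e.g. down
    under both knockdown and overexpression) are flagged discordant and
    called no_regulation.
    """
    calls = []
    for gene, arms in perturbation_folds.items():
        if "knockdown" not in arms or "overexpression" not in arms:
            warnings.warn(f"{gene}: missing a perturbation arm, call withheld")
            continue
        kd = _direction(*arms["knockdown"], alpha)
        oe = _direction(*arms["overexpression"], alpha)
        discordant = kd != "ns" and kd == oe
        if kd == "down" and oe == "up":
            call = "activated_target"
        elif kd == "up" and oe == "down":
            call = "repressed_target"
        else:
            call = "no_regulation"
        in_case, in_control = peak_presence.get(gene, (False, False))
        calls.append(
            RegulatoryCall(
                gene=gene,
                peak_in_case=in_case,
                peak_in_control=in_control,
                knockdown_direction=kd,
                overexpression_direction=oe,
                call=call,
                discordant=discordant,
            )
        )
    return calls
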