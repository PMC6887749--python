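"""Hormone-induction and tissue-expression summarization.

Relative expression follows the standard 2^-ddCt model: the target gene's
Ct is normalized against an internal reference gene (dCt), and treated
samples are compared against controls (ddCt).  Fold-change matrices are
log2-transformed for reporting, and induction calls use a configurable
fold threshold (default 2-fold, inclusive) — the threshold is the
package's operationalization of "strongly induced", stated as policy in
every report, not a measured constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class InductionProfile:
    gene: str
    treatment: str
    timepoints: list[float]     # hours, strictly increasing
    log2fc: list[float]
    induced: bool
    peak_timepoint: float | None


def ddct_fold_change(ct_target_treated: float, ct_ref_treated: float,
                     ct_target_control: float, ct_ref_control: float) -> float:
    """2^-ddCt relative fold change from four cycle-threshold values."""
    ddct = ((ct_target_treated - ct_ref_treated)
            - (ct_target_control - ct_ref_control))
    return float(2.0 ** -ddct)


def log2fc_matrix(treated: pd.DataFrame, control: pd.DataFrame,
                  pseudocount: float = 0.0) -> pd.DataFrame:
    """log2((treated + pc) / (control + pc)); swapping inputs negates it."""
    if treated.shape != control.shape or list(treated.index) != list(control.index) \
            or list(treated.columns) != list(control.columns):
        raise ValueError("treated and control matrices must share genes and samples")
    return np.log2((treated + pseudocount) / (control + pseudocount))


def fold_changes_from_ct(ct_table: pd.DataFrame,
                         control_label: str = "control") -> pd.DataFrame:
    """Long-format Ct table -> fold changes per (gene, treatment, timepoint).

    Expected columns: gene, ct, reference_flag (truthy for the internal
    reference gene), treatment, timepoint.  Replicate rows are averaged on
    Ct before the ddCt arithmetic.
    """
    required = {"gene", "ct", "reference_flag", "treatment", "timepoint"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns {sorted(missing)}")
    df = ct_table.copy()
    df["reference_flag"] = df["reference_flag"].astype(bool)

    mean_ct = (df.groupby(["gene", "treatment", "timepoint", "reference_flag"])
               ["ct"].mean().reset_index())
    ref = mean_ct[mean_ct["reference_flag"]]
    tgt = mean_ct[~mean_ct["reference_flag"]]
    ref_lookup = ref.set_index(["treatment", "timepoint"])["ct"]

    rows = []
    for (gene, treatment, timepoint), sub in tgt.groupby(
            ["gene", "treatment", "timepoint"]):
        if treatment == control_label:
            continue
        ct_tt = float(sub["ct"].iloc[0])
        try:
            ct_rt = float(ref_lookup.loc[(treatment, timepoint)])
            ct_tc = float(tgt[(tgt["gene"] == gene)
                              & (tgt["treatment"] == control_label)
                              & (tgt["timepoint"] == timepoint)]["ct"].iloc[0])
            ct_rc = float(ref_lookup.loc[(control_label, timepoint)])
        except (KeyError, IndexError) as exc:
            raise ValueError(
                f"missing reference/control Ct for gene {gene}, "
                f"treatment {treatment}, timepoint {timepoint}") from exc
        rows.append({
            "gene": gene, "treatment": treatment, "timepoint": timepoint,
            "fold_change": ddct_fold_change(ct_tt, ct_rt, ct_tc, ct_rc),
        })
    return pd.DataFrame(rows, columns=["gene", "treatment", "timepoint",
                                       "fold_change"])


def call_induced(fold_changes: pd.DataFrame,
                 threshold_fold: float = 2.0) -> list[InductionProfile]:
    """Induction calls per (gene, treatment) across timepoints.

    Input columns: gene, treatment, timepoint, fold_change.  A profile is
    induced when any timepoint's fold change reaches the threshold
    (inclusive); the maximizing timepoint is recorded.
    """
    required = {"gene", "treatment", "timepoint", "fold_change"}
    if not required.issubset(fold_changes.columns):
        raise ValueError(f"fold-change table lacks columns {sorted(required)}")
    profiles = []
    for (gene, treatment), sub in fold_changes.groupby(["gene", "treatment"]):
        sub = sub.sort_values("timepoint")
        folds = sub["fold_change"].to_numpy(dtype=float)
        times = sub["timepoint"].to_numpy(dtype=float)
        induced = bool((folds >= threshold_fold).any())
        peak = float(times[int(np.argmax(folds))]) if induced else None
        profiles.append(InductionProfile(
            gene=gene, treatment=treatment,
            timepoints=[float(t) for t in times],
            log2fc=[float(np.log2(f)) if f > 0 else float("-inf") for f in folds],
            induced=induced, peak_timepoint=peak,
        ))
    return profiles
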