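"""Dependency matrix: internal-control normalisation and significance calls.

Every field of view contains both wild-type and deletion cells, so each
deletion cell's background-corrected compartment signal is divided by
the mean of the control cells *from the same field*. This cancels
field-to-field nuisance variation (illumination, focus, mounting)
exactly: multiplying all intensities of a field by any constant leaves
every normalised value unchanged. Control cells are normalised by the
same field mean, so their normalised values average 1 per field by
construction.

Per (marker, deletion, compartment) the arms are compared with a Welch
(unequal-variance) t-test on log-transformed normalised values — the
intensity ratios are right-skewed — and the relative difference
``rel_diff = mean(deletion)/mean(control) - 1`` is reported.
Benjamini-Hochberg adjustment is applied across the whole matrix
jointly, and an entry is called an increase/decrease only when q <= alpha
AND |rel_diff| >= min_effect.

The monopolar-to-bipolar (NETO) shift is tested separately per
combination with a rank-based two-sample test on the per-cell
bipolarity index (End2/End1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthgen import CONTROL, DELETION

log = logging.getLogger(__name__)

COMPARTMENTS = ("end1", "end2", "cyto")
INCREASE, DECREASE, NS = "increase", "decrease", "ns"


class MissingArmError(ValueError):
    """A combination lacks cells in one genotype arm."""


class MatrixIntegrityError(ValueError):
    """Duplicate (marker, deletion, compartment) entries."""


@dataclass(frozen=True)
class MatrixCell:
    """One dependency-matrix entry (before or after adjustment)."""

    marker: str
    deletion: str
    compartment: str
    n_del: int
    n_ctrl: int
    rel_diff: float
    p_value: float
    q_value: float = np.nan
    call: str = NS
    underpowered: bool = False


def normalize_to_controls(cells: pd.DataFrame, statistic: str = "mean"
                          ) -> pd.DataFrame:
    """Per-field internal-control normalisation.

    ``cells`` is a measurement table (one row per analysed cell) with
    corrected columns ``end1_<stat>``, ``end2_<stat>``, ``cyto_<stat>``.
    Returns the table with ``norm_end1/norm_end2/norm_cyto`` columns
    added; fields without control cells, or whose control mean is not
    positive in some compartment, are dropped with a logged warning.
    """
    if statistic not in ("mean", "max"):
        raise ValueError("statistic must be 'mean' or 'max'")
    value_cols = {c: f"{c}_{statistic}" for c in COMPARTMENTS}
    out_frames = []
    for field_id, grp in cells.groupby("field_id", sort=False):
        ctrl = grp[grp["genotype"] == CONTROL]
        if ctrl.empty:
            log.warning("field %s dropped: no control cells", field_id)
            continue
        means = {c: ctrl[col].mean() for c, col in value_cols.items()}
        if min(means.values()) <= 0:
            log.warning("field %s dropped: non-positive control mean",
                        field_id)
            continue
        grp = grp.copy()
        for c, col in value_cols.items():
            grp[f"norm_{c}"] = grp[col] / means[c]
        out_frames.append(grp)
    if not out_frames:
        return cells.iloc[0:0].assign(
            **{f"norm_{c}": [] for c in COMPARTMENTS})
    return pd.concat(out_frames, ignore_index=True)


def _welch_log_p(del_vals: np.ndarray, ctrl_vals: np.ndarray) -> float:
    """Two-sided Welch t on log values; non-positive values dropped."""
    a = np.log(del_vals[del_vals > 0])
    b = np.log(ctrl_vals[ctrl_vals > 0])
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def summarize_combination(records: pd.DataFrame, compartment: str,
                          min_cells: int = 100) -> MatrixCell:
    """Arm comparison for one (marker, deletion) and one compartment.

    ``records`` must be the normalised table restricted to one
    combination. The entry is flagged underpowered (not dropped) if
    either arm has fewer than ``min_cells`` analysed cells.
    """
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    col = f"norm_{compartment}"
    dels = records.loc[records["genotype"] == DELETION, col].to_numpy(float)
    ctrls = records.loc[records["genotype"] == CONTROL, col].to_numpy(float)
    if len(dels) == 0 or len(ctrls) == 0:
        raise MissingArmError("one genotype arm is empty")
    marker = records["marker"].iat[0]
    deletion = records["deletion"].iat[0]
    rel_diff = float(dels.mean() / ctrls.mean() - 1.0)
    return MatrixCell(
        marker=marker, deletion=deletion, compartment=compartment,
        n_del=len(dels), n_ctrl=len(ctrls), rel_diff=rel_diff,
        p_value=_welch_log_p(dels, ctrls),
        underpowered=min(len(dels), len(ctrls)) < min_cells)


def summarize_all(normalized: pd.DataFrame,
                  min_cells: int = 100) -> list[MatrixCell]:
    entries = []
    for (marker, deletion), grp in normalized.groupby(
            ["marker", "deletion"], sort=True):
        for compartment in COMPARTMENTS:
            entries.append(summarize_combination(grp, compartment,
                                                 min_cells=min_cells))
    return entries


def build_matrix(entries: list[MatrixCell] | pd.DataFrame,
                 alpha: float = 0.05,
                 min_effect: float = 0.10) -> pd.DataFrame:
    """BH-adjust all entries jointly and call increase/decrease/ns.

    Returns the long-form matrix (one row per marker x deletion x
    compartment) sorted by (marker, deletion, compartment).
    """
    if isinstance(entries, pd.DataFrame):
        df = entries.copy()
    else:
        df = pd.DataFrame([vars(e) for e in entries])
    if df.empty:
        raise ValueError("no matrix entries")
    keys = df[["marker", "deletion", "compartment"]].apply(tuple, axis=1)
    if keys.duplicated().any():
        dupes = sorted(set(keys[keys.duplicated()]))
        raise MatrixIntegrityError(f"duplicate entries: {dupes[:5]}")
    pvals = df["p_value"].to_numpy(float)
    finite = np.isfinite(pvals)
    q = np.full_like(pvals, np.nan)
    if finite.any():
        q[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    df["q_value"] = q
    sig = (df["q_value"] <= alpha) & (df["rel_diff"].abs() >= min_effect)
    df["call"] = NS
    df.loc[sig & (df["rel_diff"] > 0), "call"] = INCREASE
    df.loc[sig & (df["rel_diff"] < 0), "call"] = DECREASE
    return df.sort_values(["marker", "deletion", "compartment"],
                          ignore_index=True)


def matrix_pivot(matrix: pd.DataFrame, compartment: str,
                 value: str = "rel_diff") -> pd.DataFrame:
    """Wide view (rows = markers, columns = deletions) of one compartment;
    impossible self combinations appear as NaN."""
    sub = matrix[matrix["compartment"] == compartment]
    markers = sorted(sub["marker"].unique())
    deletions = sorted(sub["deletion"].unique())
    return (sub.pivot(index="marker", columns="deletion", values=value)
            .reindex(index=markers, columns=deletions))


# ---------------------------------------------------------------------------
# NETO (monopolar -> bipolar) shift calls

def neto_shift_test(normalized: pd.DataFrame, alpha: float = 0.05,
                    bipolar_threshold: float = 0.5) -> pd.DataFrame:
    """Rank-based two-sample test of the bipolarity index per combination.

    Returns one row per (marker, deletion) with the median difference
    (deletion - control), Mann-Whitney p, BH q across all combinations,
    the fraction of cells classified bipolar (index >= threshold) in each
    arm, and the ``shifted`` flag (q <= alpha).
    """
    rows = []
    for (marker, deletion), grp in normalized.groupby(
            ["marker", "deletion"], sort=True):
        dels = grp.loc[grp["genotype"] == DELETION,
                       "bipolarity_index"].to_numpy(float)
        ctrls = grp.loc[grp["genotype"] == CONTROL,
                        "bipolarity_index"].to_numpy(float)
        if len(dels) == 0 or len(ctrls) == 0:
            raise MissingArmError(f"empty arm for ({marker}, {deletion})")
        if np.ptp(np.concatenate([dels, ctrls])) == 0:
            p = 1.0  # identical constant distributions
        else:
            p = float(stats.mannwhitneyu(dels, ctrls,
                                         alternative="two-sided").pvalue)
        rows.append({
            "marker": marker, "deletion": deletion,
            "delta_bipolarity": float(np.median(dels) - np.median(ctrls)),
            "p_value": p,
            "prop_bipolar_del": float((dels >= bipolar_threshold).mean()),
            "prop_bipolar_ctrl": float((ctrls >= bipolar_threshold).mean()),
            "n_del": len(dels), "n_ctrl": len(ctrls),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        raise MissingArmError("no combinations with cells in both arms")
    out["q_value"] = multipletests(out["p_value"].to_numpy(),
                                   method="fdr_bh")[1]
    out["shifted"] = out["q_value"] <= alpha
    return out
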