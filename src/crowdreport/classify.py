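"""Trial-wise error taxonomy: far-gap splitting, re-centering, and
nearest-model labelling into target / average / substitution reports.

Each report error is compared with three model predictions on the error
axis: 0 (target report), delta/2 (average of target and flanker gap) and
delta (substitution of the flanker gap), where delta is the relevant
flanker-gap offset. The datum is labelled by the nearest prediction under
circular distance; exact ties resolve by the fixed priority
target > average > substitution so runs are reproducible.

In the two-gap condition, reports with absolute error greater than 90 deg
are classed as far-gap reports; that subset is re-centred by subtracting
180 deg from both the error and the far-gap offset, after which it is
analysed with the same three-model scheme against the re-centred far gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import BootstrapCI, bootstrap_ci, wrap_deg
from .design import TWO_GAP

__all__ = [
    "LABELS",
    "FarGapSplit",
    "LabelSummary",
    "compute_errors",
    "split_far_gap",
    "recenter_far",
    "nearest_model_label",
    "label_proportions",
]

logger = logging.getLogger(__name__)

LABELS = ("target", "average", "substitution")
DEFAULT_GROUPING = ("observer_id", "flanker_type", "edge_separation_deg")


def compute_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Fill the derived wrapped-difference columns of a trial table.

    error_deg = wrap(report - target); positive errors are clockwise of the
    target. delta1/delta2 are the flanker-gap offsets wrap(gap - target).
    Rows with a missing report are dropped with a log entry.
    """
    df = trials.copy()
    missing = df["report_deg"].isna()
    if missing.any():
        logger.warning("dropping %d trial(s) with missing report", int(missing.sum()))
        df = df.loc[~missing].copy()
    df["error_deg"] = wrap_deg((df["report_deg"] - df["target_deg"]).to_numpy())
    for gap, delta in (("gap1_deg", "delta1_deg"), ("gap2_deg", "delta2_deg")):
        vals = np.full(len(df), np.nan)
        if gap in df.columns:
            ok = df[gap].notna().to_numpy()
            if ok.any():
                vals[ok] = wrap_deg((df.loc[ok, gap] - df.loc[ok, "target_deg"]).to_numpy())
        df[delta] = vals
    return df


@dataclass
class FarGapSplit:
    """Outcome of partitioning two-gap trials at the far-gap threshold."""

    threshold_deg: float
    is_far: pd.Series
    proportion_far: float
    ci: BootstrapCI | None
    by_condition: pd.DataFrame  # per-condition proportion_far, n, CI bounds


def split_far_gap(trials: pd.DataFrame, threshold_deg: float = 90.0,
                  n_boot: int = 1000, level: float = 0.95, seed=None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, FarGapSplit]:
    """Partition two-gap trials into near (|error| <= 90) and far subsets.

    The threshold rule is strict: |error| exactly at the threshold counts as
    near. Returns (near, far, summary); the summary carries the pooled
    far proportion with a percentile bootstrap CI and a per-condition table.
    """
    if not (trials["flanker_type"] == TWO_GAP).all():
        raise ValueError("split_far_gap expects two-gap trials only")
    if "error_deg" not in trials.columns or trials["error_deg"].isna().any():
        raise ValueError("errors must be computed before splitting (compute_errors)")
    err = trials["error_deg"].to_numpy()
    is_far = pd.Series(np.abs(err) > threshold_deg, index=trials.index, name="is_far")
    prop = float(is_far.mean())
    ci = bootstrap_ci(is_far.to_numpy().astype(float), np.mean,
                      n_boot=n_boot, level=level, seed=seed) if len(trials) else None

    rows = []
    for (sep,), grp in trials.groupby(["edge_separation_deg"], dropna=False):
        flags = is_far.loc[grp.index].to_numpy().astype(float)
        gci = bootstrap_ci(flags, np.mean, n_boot=n_boot, level=level, seed=seed)
        rows.append({"edge_separation_deg": sep, "proportion_far": float(flags.mean()),
                     "n": len(grp), "ci_lower": gci.lower, "ci_upper": gci.upper})
    by_cond = pd.DataFrame(rows)
    split = FarGapSplit(threshold_deg=threshold_deg, is_far=is_far,
                        proportion_far=prop, ci=ci, by_condition=by_cond)
    return trials.loc[~is_far].copy(), trials.loc[is_far].copy(), split


def recenter_far(far: pd.DataFrame) -> pd.DataFrame:
    """Re-centre a far-gap subset by subtracting 180 deg.

    Both the report error and the far-gap offset (delta2) are shifted so
    that 0 corresponds to a report of the target's polar opposite; data on
    the unity line are then reports of the far flanker gap.
    """
    if "delta2_deg" not in far.columns or far["delta2_deg"].isna().any():
        raise ValueError("far-gap re-centering requires delta2 for every trial")
    df = far.copy()
    df["error_deg"] = wrap_deg(df["error_deg"].to_numpy() - 180.0)
    df["delta2_deg"] = wrap_deg(df["delta2_deg"].to_numpy() - 180.0)
    return df


def nearest_model_label(error_deg, delta_deg):
    """Label error(s) by the nearest of the three model predictions.

    Circular distances to 0 (target), delta/2 (average) and delta
    (substitution); ties resolve target > average > substitution. Accepts
    scalars or aligned arrays; returns a str or an object array of strs.
    """
    e = np.atleast_1d(np.asarray(error_deg, dtype=float))
    d = np.atleast_1d(np.asarray(delta_deg, dtype=float))
    e, d = np.broadcast_arrays(e, d)
    d_target = np.abs(wrap_deg(e))
    d_average = np.abs(wrap_deg(e - d / 2.0))
    d_sub = np.abs(wrap_deg(e - d))
    labels = np.where(
        d_target <= np.minimum(d_average, d_sub), "target",
        np.where(d_average <= d_sub, "average", "substitution"),
    )
    if np.ndim(error_deg) == 0 and np.ndim(delta_deg) == 0:
        return str(labels.ravel()[0])
    return labels


@dataclass
class LabelSummary:
    """Per-trial labels and per-group report-type proportions."""

    labels: pd.Series
    proportions: pd.DataFrame  # one row per group: p_target, p_average, p_substitution, n_trials
    grouping: tuple[str, ...]


def label_proportions(trials: pd.DataFrame,
                      grouping=DEFAULT_GROUPING,
                      delta_col: str = "delta1_deg",
                      n_boot: int = 0, level: float = 0.95, seed=None,
                      ) -> LabelSummary:
    """Nearest-model labels and their per-condition proportions.

    ``delta_col`` selects the model axis: delta1 for one-gap (and two-gap
    near-subset) analyses, re-centred delta2 for far-gap analyses. The
    three proportions sum to 1 in every non-empty group. With ``n_boot > 0``
    percentile bootstrap CIs are attached per proportion.
    """
    if trials[delta_col].isna().any():
        raise ValueError(f"labelling requires {delta_col} for every trial")
    labels = pd.Series(
        nearest_model_label(trials["error_deg"].to_numpy(), trials[delta_col].to_numpy()),
        index=trials.index, name="label",
    )
    grouping = tuple(grouping)
    rows = []
    if len(trials):
        grouped = trials.groupby(list(grouping), dropna=False, sort=True)
    else:
        grouped = ()
    for key, grp in grouped:
        key = key if isinstance(key, tuple) else (key,)
        lab = labels.loc[grp.index]
        n = len(grp)
        row = dict(zip(grouping, key))
        row["n_trials"] = n
        for name in LABELS:
            p = float((lab == name).mean()) if n else np.nan
            row[f"p_{name}"] = p
            if n_boot and n:
                flags = (lab == name).to_numpy().astype(float)
                ci = bootstrap_ci(flags, np.mean, n_boot=n_boot, level=level, seed=seed)
                row[f"p_{name}_lower"], row[f"p_{name}_upper"] = ci.lower, ci.upper
        rows.append(row)
    proportions = pd.DataFrame(rows)
    return LabelSummary(labels=labels, proportions=proportions, grouping=grouping)
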