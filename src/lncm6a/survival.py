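"""Median-split survival comparison: log-rank test and univariate Cox PH.

For each lncRNA, patients are split at the median log2 expression (strictly
above goes high), the two overall-survival curves are compared by the
two-group log-rank test, and a univariate Cox proportional-hazards model on
the high/low indicator gives the hazard ratio.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .core_io import ClinicalTable, ExpressionMatrix
from .stats import bh_adjust

SURVIVAL_COLUMNS = [
    "lncrna_id", "n_high", "n_low", "chi2", "p_logrank",
    "hr", "p_cox", "q_logrank", "q_cox",
]


def median_split(x) -> np.ndarray:
    """Boolean high-group labels: strictly above the median goes high."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples for a median split")
    if np.all(x == x[0]):
        raise ValueError("cannot median-split a constant vector")
    high = x > np.median(x)
    if not high.any() or high.all():
        raise ValueError("median split produced an empty group")
    return high


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value.

    ``groups`` is a boolean (or 0/1) high-group indicator.  Each group must
    contain at least one observed event; otherwise the observed-minus-
    expected contrast is degenerate and an error is raised.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=bool)
    if not (times.shape == events.shape == groups.shape):
        raise ValueError("times, events and groups must be aligned")
    for label, mask in (("high", groups), ("low", ~groups)):
        if events[mask].sum() == 0:
            raise ValueError(f"{label} group has no observed event")
    res = logrank_test(
        times[groups], times[~groups], events[groups], events[~groups]
    )
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(times, events, covariate) -> tuple[float, float]:
    """Univariate Cox PH fit: hazard ratio exp(beta) and Wald p-value."""
    covariate = np.asarray(covariate, dtype=float)
    if np.all(covariate == covariate[0]):
        raise ValueError("covariate is constant")
    events = np.asarray(events, dtype=int)
    if events.sum() < 2:
        raise ValueError("need at least 2 observed events")
    df = pd.DataFrame(
        {"time": np.asarray(times, dtype=float), "event": events, "x": covariate}
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as e:
        raise RuntimeError(f"Cox fit did not converge: {e}") from None
    beta = float(cph.params_["x"])
    if abs(beta) > 20:  # monotone likelihood / perfect separation
        raise RuntimeError("Cox fit diverged (perfect separation)")
    return float(np.exp(beta)), float(cph.summary.loc["x", "p"])


def survival_panel(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    lncrnas: list[str] | None = None,
    covariate_mode: str = "median_split",
) -> pd.DataFrame:
    """Per-lncRNA log-rank + Cox results with BH q over the panel.

    ``covariate_mode`` selects the Cox covariate: the high/low indicator
    (default, matching the median-split grouping) or the continuous log2
    expression (``"continuous"``).
    """
    if covariate_mode not in ("median_split", "continuous"):
        raise ValueError("covariate_mode must be 'median_split' or 'continuous'")
    clin = clinical.table.set_index("sample_id")
    samples = [s for s in expr.sample_ids if s in clin.index]
    if len(samples) < 4:
        raise ValueError("fewer than 4 samples shared with clinical table")
    times = clin.loc[samples, "time_days"].to_numpy(dtype=float)
    events = clin.loc[samples, "event"].to_numpy(dtype=int)
    if lncrnas is None:
        lncrnas = expr.genes_with_role("lncRNA")
    rows = []
    for lnc in lncrnas:
        x = expr.values.loc[lnc, samples].to_numpy(dtype=float)
        try:
            high = median_split(x)
            chi2, p_lr = logrank(times, events, high)
            cov = high.astype(float) if covariate_mode == "median_split" else x
            hr, p_cox = cox_univariate(times, events, cov)
        except (ValueError, RuntimeError):
            continue
        rows.append(
            dict(lncrna_id=lnc, n_high=int(high.sum()),
                 n_low=int((~high).sum()), chi2=chi2, p_logrank=p_lr,
                 hr=hr, p_cox=p_cox)
        )
    out = pd.DataFrame(rows, columns=SURVIVAL_COLUMNS[:7])
    if not out.empty:
        out["q_logrank"] = bh_adjust(out["p_logrank"].to_numpy())
        out["q_cox"] = bh_adjust(out["p_cox"].to_numpy())
    else:
        out["q_logrank"] = []
        out["q_cox"] = []
    return out
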