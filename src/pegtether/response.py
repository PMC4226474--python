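"""T-cell response-rate analysis for tethered-ligand stimulation series.

IL2-producing cell fractions measured over a stimulation time course are
normalised to the highest value within each experiment, averaged across
experiments after normalisation, and summarised by the slope of an ordinary
least-squares line through the time course — the response rate.  Rates are
then related to tether size (Flory radius) or to simulated binding rates by
rank (Spearman) and linear (Pearson) correlation, after scaling against a
reference linker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RateFit", "normalize_response", "fit_rate", "correlate_rates"]


@dataclass(frozen=True)
class RateFit:
    """OLS line through a normalized response time course."""

    linker: str
    slope: float  # normalized response per hour
    intercept: float
    r_squared: float
    stderr: float
    n_points: int
    flory_radius: float = float("nan")


def normalize_response(
    table: pd.DataFrame,
    value_col: str = "percent_il2",
    experiment_col: str = "experiment_id",
) -> pd.DataFrame:
    """Divide responses by the maximum within each experiment.

    Each experiment is normalised independently, so its highest response
    maps to exactly 1.0; the result is stored in ``normalized_response``.
    Idempotent: normalising twice changes nothing.
    """
    if value_col not in table.columns or experiment_col not in table.columns:
        raise KeyError(f"table must have columns {value_col!r} and {experiment_col!r}")
    if (table[value_col] < 0).any():
        raise ValueError("responses must be non-negative")
    out = table.copy()
    maxima = out.groupby(experiment_col)[value_col].transform("max")
    zero_exps = out.loc[maxima <= 0, experiment_col].unique()
    if len(zero_exps):
        raise ValueError(
            f"experiments with all-zero responses cannot be normalized: "
            f"{sorted(map(str, zero_exps))}"
        )
    out["normalized_response"] = out[value_col] / maxima
    return out


def fit_rate(
    timepoints,
    normalized_response,
    linker: str = "",
    flory_radius: float = float("nan"),
) -> RateFit:
    """OLS fit with free intercept; the slope is the response rate per hour."""
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(normalized_response, dtype=float)
    if t.shape != y.shape:
        raise ValueError("timepoints and responses must have equal length")
    if t.size < 3:
        raise ValueError(f"need at least 3 timepoints, got {t.size}")
    if np.ptp(t) == 0:
        raise ValueError("all timepoints identical; slope is undefined")
    res = stats.linregress(t, y)
    return RateFit(
        linker=linker,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr),
        n_points=int(t.size),
        flory_radius=flory_radius,
    )


def correlate_rates(
    fits: dict[str, RateFit] | dict[str, float],
    paired: dict[str, float],
    reference: str | None = None,
) -> dict:
    """Associate response rates with a paired per-linker quantity.

    ``paired`` maps each linker to the quantity to correlate against (a
    Flory radius or a scaled simulated rate).  Returns Spearman and Pearson
    coefficients with p-values, plus a table of rates scaled against the
    ``reference`` linker (default: the linker with the largest rate, i.e.
    the shortest tether under the usual inverse trend).  Degenerate
    (constant) inputs yield NaN coefficients with ``degenerate=True``.
    """
    rates = {
        k: (v.slope if isinstance(v, RateFit) else float(v)) for k, v in fits.items()
    }
    unmatched = sorted(set(rates) ^ set(paired))
    if unmatched:
        raise KeyError(f"labels present on one side only: {unmatched}")
    labels = sorted(rates)
    if len(labels) < 3:
        raise ValueError(f"need at least 3 paired observations, got {len(labels)}")
    x = np.array([rates[k] for k in labels])
    y = np.array([paired[k] for k in labels])

    degenerate = bool(np.ptp(x) == 0 or np.ptp(y) == 0)
    if degenerate:
        spearman = pearson = (float("nan"), float("nan"))
    else:
        sp = stats.spearmanr(x, y)
        pe = stats.pearsonr(x, y)
        spearman = (float(sp.statistic), float(sp.pvalue))
        pearson = (float(pe.statistic), float(pe.pvalue))

    if reference is None:
        reference = labels[int(np.argmax(x))]
    if rates[reference] == 0:
        raise ValueError(f"reference linker {reference!r} has zero rate")
    scaled = pd.DataFrame(
        {
            "linker": labels,
            "rate": x,
            "scaled_rate": x / rates[reference],
            "paired_value": y,
        }
    )
    return {
        "spearman": spearman[0],
        "spearman_p": spearman[1],
        "pearson": pearson[0],
        "pearson_p": pearson[1],
        "degenerate": degenerate,
        "reference": reference,
        "scaled_table": scaled,
    }
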