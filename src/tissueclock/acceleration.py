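"""Age-acceleration statistics: delta-age, group medians, strain contrasts,
lifespan-normalized acceleration, and per-timepoint strain comparisons.

Delta-age is epigenetic minus chronological age,

    dAge = DNAge - chronological age  (months),

positive when a tissue is epigenetically older than its chronological age.
"Median difference" between strains is the difference of group medians
(AD minus B6). Lifespan normalization expresses a median delta-age as a
percentage of the strain's mean lifespan, signed: positive = acceleration,
negative = deceleration.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClockModel, MethylationMatrix
from .clock import predict_dnage


def delta_age(dnage, age):
    """dAge = DNAge - chronological age (exact subtraction, months)."""
    return np.asarray(dnage, dtype=float) - np.asarray(age, dtype=float)


def build_delta_age_table(model: ClockModel, m: MethylationMatrix) -> pd.DataFrame:
    """Predict DNAge for every sample and tabulate per-sample dAge."""
    dnage = predict_dnage(model, m)
    df = m.sample_frame()
    df["dnage"] = dnage
    df["delta_age"] = delta_age(dnage, df["age"].to_numpy())
    return df


def group_median_delta(table: pd.DataFrame, by) -> pd.Series:
    """Median dAge per group (even n: mean of the central pair).

    ``by`` is a list of grouping columns, e.g. ["tissue", "strain"].
    Empty groups are omitted with a warning.
    """
    if isinstance(by, str):
        by = [by]
    grouped = table.groupby(by, observed=True)["delta_age"]
    med = grouped.median()
    sizes = grouped.size()
    empty = sizes[sizes == 0]
    if len(empty):
        warnings.warn(f"empty group(s) omitted: {list(empty.index)}", stacklevel=2)
        med = med[sizes > 0]
    return med


def strain_median_difference(table: pd.DataFrame, tissue: str,
                             strains: tuple[str, str] = ("AD", "B6")) -> float:
    """median(dAge | first strain, tissue) - median(dAge | second strain, tissue)."""
    sub = table[table["tissue"] == tissue]
    meds = {}
    for s in strains:
        vals = sub.loc[sub["strain"] == s, "delta_age"]
        if vals.empty:
            raise ValueError(f"no {s} samples for tissue {tissue!r}")
        meds[s] = float(vals.median())
    return meds[strains[0]] - meds[strains[1]]


def lifespan_fraction(median_delta: float, lifespan: float) -> float:
    """100 * median_delta / lifespan (percent of mean lifespan).

    Positive values are lifespan-fraction accelerations, negative values
    decelerations.
    """
    if not lifespan > 0:
        raise ValueError(f"lifespan must be positive, got {lifespan}")
    return 100.0 * median_delta / lifespan


# Mean lifespans (months) of the two strains, caller-overridable.
DEFAULT_LIFESPANS = {"AD": 17.0, "B6": 25.0}


def per_timepoint_comparison(table: pd.DataFrame, tissue: str,
                             strains: tuple[str, str] = ("AD", "B6")) -> pd.DataFrame:
    """Welch two-sample comparison of dAge between strains at each age.

    Returns one row per distinct age with the difference of means
    (first minus second strain), the Welch t statistic, two-sided p-value
    and group sizes; p-values are raw (the number of tests is the row count,
    so callers can correct). Identical groups short-circuit to p = 1.
    """
    sub = table[table["tissue"] == tissue]
    rows = []
    for age in sorted(sub["age"].unique()):
        a = sub.loc[(sub["age"] == age) & (sub["strain"] == strains[0]), "delta_age"].to_numpy()
        b = sub.loc[(sub["age"] == age) & (sub["strain"] == strains[1]), "delta_age"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >= 2 samples per strain at age {age}")
        diff = float(a.mean() - b.mean())
        if np.array_equal(np.sort(a), np.sort(b)) and np.ptp(a) == 0:
            t, p = 0.0, 1.0  # degenerate: identical constant groups
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"age": age, "mean_difference": diff, "t_statistic": float(t),
                     "p_value": float(p), "n_a": len(a), "n_b": len(b)})
    return pd.DataFrame(rows)


def acceleration_report(table: pd.DataFrame,
                        lifespans: dict[str, float] | None = None) -> dict:
    """Summary bundle: group medians, strain median differences per tissue,
    and lifespan fractions per tissue x strain."""
    lifespans = lifespans or DEFAULT_LIFESPANS
    medians = group_median_delta(table, ["tissue", "strain"])
    out = {"group_median_delta": {f"{t}/{s}": float(v) for (t, s), v in medians.items()},
           "strain_median_difference": {}, "lifespan_fraction_pct": {}}
    for tissue in table["tissue"].unique():
        try:
            out["strain_median_difference"][tissue] = strain_median_difference(table, tissue)
        except ValueError:
            pass
        for strain in table.loc[table["tissue"] == tissue, "strain"].unique():
            if strain in lifespans:
                med = float(medians.loc[(tissue, strain)])
                out["lifespan_fraction_pct"][f"{tissue}/{strain}"] = lifespan_fraction(
                    med, lifespans[strain]
                )
    return out
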