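"""Phenotype summaries: broad-sense heritability and relative trait values.

Broad-sense heritability is estimated on the plot (single-replicate) basis
from a one-way random-effects ANOVA over replicated lines:

    sigma2_G = max(0, (MS_line - MS_error) / r_bar),   r_bar harmonic-mean
    H2 = sigma2_G / (sigma2_G + sigma2_E),             sigma2_E = MS_error

The simulator calibrates noise with the same convention, so recovery of a
target heritability is well posed.  Relative trait values express each
group mean as a percentage of a reference group (control = 100), rounded
half-up to one decimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import PhenotypeTable

__all__ = ["HeritabilityEstimate", "GroupSummary", "broad_h2", "relative_trait"]


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    genetic_variance: float
    residual_variance: float
    n_lines: int
    mean_replicates: float


def broad_h2(phenos: PhenotypeTable) -> HeritabilityEstimate:
    """Plot-basis broad-sense heritability from replicated line values.

    Lines with a single replicate are excluded (warned); at least two
    usable lines are required.  Negative genetic-variance estimates are
    clamped to zero, so H2 is always in [0, 1]."""
    df = phenos.records
    counts = df.groupby("line_id")["value"].count()
    single = counts[counts < 2].index
    if len(single):
        warnings.warn(f"excluding {len(single)} line(s) with a single replicate")
        df = df[~df["line_id"].isin(single)]
    groups = df.groupby("line_id")["value"]
    a = groups.ngroups
    if a < 2:
        raise ValueError("need at least two lines with >= 2 replicates")
    n = len(df)
    grand = df["value"].mean()
    ss_between = float((groups.count() * (groups.mean() - grand) ** 2).sum())
    ss_within = float(((df["value"] - groups.transform("mean")) ** 2).sum())
    ms_line = ss_between / (a - 1)
    ms_error = ss_within / (n - a)
    r_bar = a / float((1.0 / groups.count()).sum())  # harmonic mean replicates
    sigma_g = max(0.0, (ms_line - ms_error) / r_bar)
    h2 = sigma_g / (sigma_g + ms_error) if (sigma_g + ms_error) > 0 else 0.0
    return HeritabilityEstimate(h2, sigma_g, ms_error, a, r_bar)


@dataclass(frozen=True)
class GroupSummary:
    group: str
    mean: float
    sd: float
    n: int
    percent_of_reference: float


def relative_trait(
    groups: dict[str, np.ndarray] | pd.DataFrame,
    reference: str,
    value_col: str = "value",
    group_col: str = "group",
) -> list[GroupSummary]:
    """Per-group mean, sd and percentage of the reference group mean.

    ``groups`` is either a mapping label -> values or a long DataFrame.
    Percentages are rounded half-up to one decimal (control = 100.0)."""
    if isinstance(groups, pd.DataFrame):
        data = {str(g): sub[value_col].to_numpy(float) for g, sub in groups.groupby(group_col)}
    else:
        data = {str(g): np.asarray(v, float) for g, v in groups.items()}
    if reference not in data or len(data[reference]) == 0:
        raise ValueError(f"reference group {reference!r} missing or empty")
    ref_mean = float(np.mean(data[reference]))
    if ref_mean == 0:
        raise ValueError("reference group mean is zero")
    out = []
    for label, values in data.items():
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        pct = float(
            Decimal(100.0 * mean / ref_mean).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
        )
        out.append(GroupSummary(label, mean, sd, len(values), pct))
    return out
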