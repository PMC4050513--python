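"""Temporal adjustment of multi-campaign passive-sampler data (difference method).

Short campaigns under- or over-shoot the annual mean depending on season.  With
a few week-long campaigns per site and occasional missing tubes, the
ESCAPE-style difference correction computes, over the *complete* sites only,
each campaign's mean concentration A_c and their grand mean A-bar, subtracts
Delta_c = A_c - A-bar from every measurement, and averages the adjusted values
per site.  For a complete site the corrections cancel exactly (sum_c Delta_c =
0), so its adjusted annual mean equals its raw 4-campaign mean; for incomplete
sites the seasonal bias of the missing campaigns is removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AdjustedAnnualMeans", "campaign_corrections", "annual_site_means"]

logger = logging.getLogger(__name__)


@dataclass
class AdjustedAnnualMeans:
    annual: pd.DataFrame            # site_id, annual_ugm3, n_campaigns_used
    corrections: pd.Series          # Delta_c indexed by campaign
    complete_sites: list
    n_clipped: int = 0              # adjusted values clipped at 0


def _pivot(measurements: pd.DataFrame) -> pd.DataFrame:
    required = {"site_id", "campaign", "conc_ugm3"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    return measurements.pivot_table(index="site_id", columns="campaign",
                                    values="conc_ugm3", aggfunc="mean")


def campaign_corrections(measurements: pd.DataFrame) -> pd.Series:
    """Per-campaign corrections Delta_c from the complete sites.

    Delta_c = A_c - mean_c(A_c), where A_c is the mean concentration of
    campaign c over sites with every campaign measured.  The corrections sum
    to zero by construction.
    """
    wide = _pivot(measurements)
    complete = wide.dropna()
    if complete.empty:
        raise ValueError("cannot anchor temporal adjustment: no site has all campaigns")
    a_c = complete.mean(axis=0)
    return a_c - a_c.mean()


def annual_site_means(measurements: pd.DataFrame, corrections: pd.Series | None = None) -> AdjustedAnnualMeans:
    """Adjusted annual mean per site: mean over campaigns of (y - Delta_c).

    Negative adjusted values are clipped to zero (counted and warned); sites
    with no measurement at all are dropped with a warning.
    """
    wide = _pivot(measurements)
    if corrections is None:
        corrections = campaign_corrections(measurements)
    corrections = corrections.reindex(wide.columns)
    if corrections.isna().any():
        raise ValueError("corrections missing for some campaigns present in the data")

    adjusted = wide.sub(corrections, axis=1)
    n_clipped = int((adjusted < 0).sum().sum())
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} negative adjusted concentration(s) to 0", stacklevel=2)
        adjusted = adjusted.clip(lower=0.0)

    n_used = adjusted.notna().sum(axis=1)
    empty = n_used == 0
    if empty.any():
        warnings.warn(f"dropped {int(empty.sum())} site(s) with no measurements", stacklevel=2)
    annual = pd.DataFrame({
        "site_id": adjusted.index[~empty],
        "annual_ugm3": adjusted.loc[~empty].mean(axis=1).to_numpy(),
        "n_campaigns_used": n_used[~empty].to_numpy(),
    }).reset_index(drop=True)
    complete_sites = wide.dropna().index.tolist()
    return AdjustedAnnualMeans(annual=annual, corrections=corrections,
                               complete_sites=complete_sites, n_clipped=n_clipped)
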