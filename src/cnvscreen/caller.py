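"""Threshold-based carrier calling on the two-feature plane.

Because a rare heterozygous deletion produces one tiny cluster next to a
huge main cluster, off-the-shelf clustering is fragile here; explicit
thresholds on the two features are used instead:

* ``ambiguous``  if piecewise_mad > mad_max (noisy, unclassifiable sample);
* else ``carrier`` if median_difference <= diff_max;
* else ``negative``;
* ``no_call`` when the features themselves are missing.

The ambiguous test takes precedence over the carrier test: a high-variance
sample may reach far-negative median differences by chance, and calling it
either way would corrupt downstream precision accounting.

Default thresholds (diff_max=-2.0, mad_max=1.5, standard-normal units) sit
between the main cluster (centered at 0 with sub-unit spread) and the
analytic carrier location (a lone carrier among >=10^3 samples normalizes
to about -3.3).  :func:`suggest_thresholds` offers a reproducible
data-driven alternative to eyeballing the cluster plot; it is returned,
never silently applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CALLS",
    "CallThresholds",
    "CallSet",
    "classify",
    "call_cohort",
    "suggest_thresholds",
]

log = logging.getLogger(__name__)

CALLS = ("carrier", "negative", "ambiguous", "no_call")

DEFAULT_DIFF_MAX = -2.0
DEFAULT_MAD_MAX = 1.5


@dataclass(frozen=True)
class CallThresholds:
    """Carrier-calling thresholds on the feature plane.

    ``diff_max``: call carrier when median_difference <= diff_max (must be
    negative — carriers lie left of the main cluster).
    ``mad_max``: call ambiguous when piecewise_mad > mad_max (must be
    positive).
    """

    diff_max: float = DEFAULT_DIFF_MAX
    mad_max: float = DEFAULT_MAD_MAX
    provenance: str = "default"

    def __post_init__(self) -> None:
        if not self.diff_max < 0:
            raise ValueError(f"diff_max must be < 0, got {self.diff_max}")
        if not self.mad_max > 0:
            raise ValueError(f"mad_max must be > 0, got {self.mad_max}")
        if self.provenance not in ("default", "user", "suggested"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class CallSet:
    """Per-sample calls with the features and thresholds that produced them."""

    frame: pd.DataFrame  # sample_id, call, median_difference, piecewise_mad
    thresholds: CallThresholds
    config_hash: str = ""

    @property
    def counts(self) -> dict[str, int]:
        c = self.frame["call"].value_counts()
        return {k: int(c.get(k, 0)) for k in CALLS}

    def __len__(self) -> int:
        return len(self.frame)


def classify(
    median_difference: float, piecewise_mad: float, thresholds: CallThresholds
) -> str:
    """Classify one feature pair; ambiguous takes precedence over carrier."""
    if np.isnan(median_difference) or np.isnan(piecewise_mad):
        return "no_call"
    if piecewise_mad > thresholds.mad_max:
        return "ambiguous"
    if median_difference <= thresholds.diff_max:
        return "carrier"
    return "negative"


def call_cohort(
    features: pd.DataFrame, thresholds: CallThresholds, config_hash: str = ""
) -> CallSet:
    """Vectorized element-wise :func:`classify` over a feature table."""
    diff = features["median_difference"].to_numpy(dtype=float)
    mad = features["piecewise_mad"].to_numpy(dtype=float)
    call = np.where(
        np.isnan(diff) | np.isnan(mad), "no_call",
        np.where(mad > thresholds.mad_max, "ambiguous",
                 np.where(diff <= thresholds.diff_max, "carrier", "negative")),
    )
    frame = pd.DataFrame({
        "sample_id": features["sample_id"],
        "call": call,
        "median_difference": diff,
        "piecewise_mad": mad,
        "diff_max": thresholds.diff_max,
        "mad_max": thresholds.mad_max,
    })
    cs = CallSet(frame, thresholds, config_hash)
    n = len(cs)
    n_car = cs.counts["carrier"]
    prev = 100.0 * n_car / n if n else 0.0
    log.info("called %d samples: %d carriers (%.3f%%), %d ambiguous, %d no_call",
             n, n_car, prev, cs.counts["ambiguous"], cs.counts["no_call"])
    return cs


def suggest_thresholds(features: pd.DataFrame, min_samples: int = 100) -> CallThresholds:
    """Data-driven thresholds replacing visual cluster-plot inspection.

    mad_max is a Tukey-style outer fence, Q3 + 3*IQR of piecewise_mad;
    diff_max is min(-2.0, median - 5 * 1.4826*MAD) of median_difference
    among the samples passing the mad fence.  Suitable for cohorts where
    carriers are a vanishing minority, so robust statistics of the whole
    cohort describe the main cluster.  Returned with
    provenance="suggested"; applying them is the caller's explicit choice.
    """
    ok = features.dropna(subset=["median_difference", "piecewise_mad"])
    if len(ok) < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples with features, got {len(ok)}"
        )
    mad_vals = ok["piecewise_mad"].to_numpy(dtype=float)
    q1, q3 = np.percentile(mad_vals, [25, 75])
    iqr = q3 - q1
    mad_max = q3 + 3.0 * iqr

    diff_vals = ok.loc[mad_vals <= mad_max, "median_difference"].to_numpy(dtype=float)
    center = np.median(diff_vals)
    spread = 1.4826 * np.median(np.abs(diff_vals - center))
    if iqr == 0 and spread == 0:
        raise ValueError("degenerate cohort: zero spread in both features")
    diff_max = min(-2.0, center - 5.0 * spread)
    return CallThresholds(diff_max=float(diff_max), mad_max=float(mad_max),
                          provenance="suggested")


def write_calls(callset: CallSet, path) -> None:
    out = callset.frame.copy()
    for col in ("median_difference", "piecewise_mad", "diff_max", "mad_max"):
        out[col] = out[col].map(
            lambda v: "NA" if pd.isna(v) else format(float(v), ".10g")
        )
    out.to_csv(path, sep="\t", index=False)


def read_calls(path) -> CallSet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "call": str},
                     na_values=["NA"])
    thr = CallThresholds(diff_max=float(df["diff_max"].iloc[0]),
                         mad_max=float(df["mad_max"].iloc[0]),
                         provenance="user")
    return CallSet(df, thr)
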