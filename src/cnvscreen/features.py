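"""Per-sample clustering features: median difference and piecewise MAD.

Each sample is reduced to the two coordinates used for carrier clustering:

* ``median_difference`` — median of the sample's normalized values over
  deletion-region loci minus the median over all flanking loci (left and
  right pooled).  A heterozygous deletion pulls this strongly negative.
* ``piecewise_mad`` — a robust within-sample dispersion: absolute
  deviations of each locus value from *its own region's* median (deletion
  and pooled flanks each contribute their own center), pooled across both
  regions, then the median of the pooled deviations is taken.  Computing
  the deviations piecewise keeps a genuine carrier — two tight bands at
  different levels — at low MAD, while a noisy sample scattered across
  both regions scores high.  No normal-consistency constant (1.4826) is
  applied; the features feed threshold rules, not a variance estimate.

Alternative single-number MAD combinations ("max" of the two region MADs,
locus-count-"weighted" mean of them) are selectable for sensitivity checks.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .locus_model import LocusMap
from .normalize import LocusMatrix

__all__ = [
    "MAD_RULES",
    "median_difference",
    "piecewise_mad",
    "compute_features",
]

log = logging.getLogger(__name__)

MAD_RULES = ("piecewise", "max", "weighted")

FEATURE_COLS = [
    "sample_id", "median_difference", "piecewise_mad",
    "n_deletion_loci_used", "n_flank_loci_used", "flag",
]


def _split_regions(
    row: Sequence[float], locus_map: LocusMap
) -> tuple[np.ndarray, np.ndarray]:
    vals = np.asarray(row, dtype=float)
    is_del = np.array([l.region == "deletion" for l in locus_map.loci])
    d = vals[is_del]
    f = vals[~is_del]
    return d[~np.isnan(d)], f[~np.isnan(f)]


def median_difference(row: Sequence[float], locus_map: LocusMap) -> float:
    """Deletion-region median minus pooled flanking median for one sample.

    NaN when either region has no non-missing locus.  The median of an
    even count is the mean of the two central values.
    """
    d, f = _split_regions(row, locus_map)
    if len(d) == 0 or len(f) == 0:
        return float("nan")
    return float(np.median(d) - np.median(f))


def piecewise_mad(
    row: Sequence[float], locus_map: LocusMap, rule: str = "piecewise"
) -> float:
    """Within-sample MAD with deviations taken from region-own medians."""
    if rule not in MAD_RULES:
        raise ValueError(f"rule {rule!r} not one of {MAD_RULES}")
    d, f = _split_regions(row, locus_map)
    if len(d) == 0 or len(f) == 0:
        return float("nan")
    dev_d = np.abs(d - np.median(d))
    dev_f = np.abs(f - np.median(f))
    if rule == "piecewise":
        return float(np.median(np.concatenate([dev_d, dev_f])))
    mad_d, mad_f = float(np.median(dev_d)), float(np.median(dev_f))
    if rule == "max":
        return max(mad_d, mad_f)
    return (len(d) * mad_d + len(f) * mad_f) / (len(d) + len(f))


def compute_features(
    matrix: LocusMatrix, locus_map: LocusMap, mad_rule: str = "piecewise"
) -> pd.DataFrame:
    """Compute the (median_difference, piecewise_mad) pair for every sample.

    Requires a normalized matrix (guards against using raw sums).  Samples
    whose deletion or flanking region is entirely missing get NaN features
    and flag="missing_region"; they are kept, not dropped.
    """
    if matrix.stage != "normalized":
        raise ValueError(
            f"features require stage='normalized', got {matrix.stage!r}"
        )
    if list(matrix.locus_ids) != locus_map.locus_ids:
        raise ValueError("matrix loci do not match the locus map")

    vals = matrix.values.to_numpy(dtype=float)
    is_del = np.array([l.region == "deletion" for l in locus_map.loci])
    d = vals[:, is_del]
    f = vals[:, ~is_del]
    n_d = (~np.isnan(d)).sum(axis=1)
    n_f = (~np.isnan(f)).sum(axis=1)

    import warnings as _warnings
    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
        med_d = np.nanmedian(np.where(np.isnan(d), np.nan, d), axis=1)
        med_f = np.nanmedian(np.where(np.isnan(f), np.nan, f), axis=1)
        diff = med_d - med_f
        dev = np.concatenate(
            [np.abs(d - med_d[:, None]), np.abs(f - med_f[:, None])], axis=1
        )
        if mad_rule == "piecewise":
            mad = np.nanmedian(dev, axis=1)
        else:
            mad_d = np.nanmedian(np.abs(d - med_d[:, None]), axis=1)
            mad_f = np.nanmedian(np.abs(f - med_f[:, None]), axis=1)
            if mad_rule == "max":
                mad = np.maximum(mad_d, mad_f)
            elif mad_rule == "weighted":
                mad = (n_d * mad_d + n_f * mad_f) / np.maximum(n_d + n_f, 1)
            else:
                raise ValueError(f"rule {mad_rule!r} not one of {MAD_RULES}")

    empty = (n_d == 0) | (n_f == 0)
    diff[empty] = np.nan
    mad[empty] = np.nan
    if empty.any():
        log.warning("%d samples with an all-missing region; features missing",
                    int(empty.sum()))

    return pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "median_difference": diff,
        "piecewise_mad": mad,
        "n_deletion_loci_used": n_d,
        "n_flank_loci_used": n_f,
        "flag": np.where(empty, "missing_region", ""),
    })


def write_features(features: pd.DataFrame, path) -> None:
    out = features.copy()
    for col in ("median_difference", "piecewise_mad"):
        out[col] = out[col].map(
            lambda v: "NA" if pd.isna(v) else format(v, ".10g")
        )
    out.to_csv(path, sep="\t", index=False)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     na_values=["NA"], keep_default_na=True)
    df["flag"] = df["flag"].fillna("")
    return df


def plot_features(features: pd.DataFrame, path, calls: pd.DataFrame | None = None):
    """Scatter of the two features (the cluster-plot view); optional call colors."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if calls is not None:
        merged = features.merge(calls[["sample_id", "call"]], on="sample_id")
        colors = {"carrier": "crimson", "negative": "steelblue",
                  "ambiguous": "darkorange", "no_call": "gray"}
        for call, grp in merged.groupby("call"):
            ax.scatter(grp["median_difference"], grp["piecewise_mad"],
                       s=8, alpha=0.6, label=f"{call} (n={len(grp)})",
                       color=colors.get(call, "black"))
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.scatter(features["median_difference"], features["piecewise_mad"],
                   s=8, alpha=0.5, color="steelblue")
    ax.set_xlabel("median difference (deletion - flank), SD units")
    ax.set_ylabel("piecewise MAD, SD units")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
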