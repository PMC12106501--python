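"""Locus-level summation and per-locus inverse-normal quantile normalization.

Two steps turn raw per-allele probe intensities into sample-comparable
copy-number signal:

1. **Summation** — for each sample and locus, the intensities of both
   alleles of every probe set interrogating that locus are summed into one
   total chromosomal signal value.
2. **Inverse-normal transform** — each locus's totals are mapped, across
   samples, onto standard-normal quantiles by rank:
   ``z = Phi^-1((r - c) / (N + d))`` with average ranks for ties.  The
   default offset is Hazen (``(r - 0.5) / N``), which is symmetric and
   bounded; Blom and van der Waerden variants are available.

After the transform a heterozygous deletion carrier sits in the extreme
lower tail at every deleted locus (about ``Phi^-1(k / 2N)`` for k carriers
among N samples), while population-wide scale differences between samples
and probe sets are removed.  The transform is rank-based, hence invariant
to any strictly increasing distortion of a locus's raw values — and, by
the same token, blind to a shift shared by *all* samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .intensity_io import IntensityTable
from .locus_model import LocusMap, LocusMapError

__all__ = [
    "QUANTILE_OFFSETS",
    "LocusMatrix",
    "sum_to_locus",
    "inverse_normal_transform",
    "read_locus_matrix",
    "write_locus_matrix",
]

#: rank -> probability offsets: p = (r - c) / (N + d)
QUANTILE_OFFSETS: dict[str, tuple[float, float]] = {
    "hazen": (0.5, 0.0),
    "blom": (0.375, 0.25),
    "vdw": (0.0, 1.0),  # van der Waerden
}


@dataclass
class LocusMatrix:
    """Samples x loci matrix of total intensities, raw or normalized.

    ``values`` is indexed by sample_id with locus_id columns in genomic
    position order; missing entries are NaN.  ``stage`` is ``"summed"``
    or ``"normalized"`` and guards against computing features on raw sums.
    """

    values: pd.DataFrame
    stage: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in ("summed", "normalized"):
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.values.columns)

    def __repr__(self) -> str:
        n, m = self.values.shape
        return f"LocusMatrix({n} samples x {m} loci, stage={self.stage})"


def sum_to_locus(table: IntensityTable, locus_map: LocusMap) -> LocusMatrix:
    """Collapse per-allele probe-set records into one total per (sample, locus).

    A locus value is the sum over both alleles of every probe set of that
    locus present on the sample's array version; it is missing (NaN) when
    the sample has no records at all for the locus.  Absent probe sets on
    the other array version contribute nothing and do not create missing
    values on their own.
    """
    bad = [
        l.locus_id for l in locus_map.loci
        if all(len(vs) == 0 for vs in l.array_versions)
    ]
    if bad:
        raise LocusMapError(
            f"locus {bad[0]!r}: none of its probe sets is on any array version"
        )

    df = table.frame
    locus_ids = locus_map.locus_ids

    # canonical probe order: locus by locus, probe sets in map order
    probe_order: list[str] = []
    probe_cols_of_locus: list[list[int]] = []
    for locus in locus_map.loci:
        probe_cols_of_locus.append(
            list(range(len(probe_order), len(probe_order) + len(locus.probe_set_ids)))
        )
        probe_order.extend(locus.probe_set_ids)
    probe_idx = {ps: j for j, ps in enumerate(probe_order)}

    sample_codes, sample_index = pd.factorize(df["sample_id"])
    probe_codes = df["probe_set_id"].map(probe_idx).to_numpy(dtype=np.int64)

    n, p, m = len(sample_index), len(probe_order), len(locus_ids)
    # two-stage summation: alleles within probe set, then probe sets within
    # locus in fixed order — keeps results independent of record order
    probe_tot = np.zeros((n, p))
    probe_cnt = np.zeros((n, p), dtype=np.int64)
    np.add.at(probe_tot, (sample_codes, probe_codes),
              df["intensity"].to_numpy(dtype=float))
    np.add.at(probe_cnt, (sample_codes, probe_codes), 1)

    totals = np.zeros((n, m))
    counts = np.zeros((n, m), dtype=np.int64)
    for j, cols in enumerate(probe_cols_of_locus):
        acc = np.zeros(n)
        for col in cols:
            acc = acc + probe_tot[:, col]
            counts[:, j] += probe_cnt[:, col]
        totals[:, j] = acc
    totals[counts == 0] = np.nan

    values = pd.DataFrame(totals, index=pd.Index(sample_index, name="sample_id"),
                          columns=locus_ids)
    return LocusMatrix(values.sort_index(), stage="summed")


def inverse_normal_transform(
    matrix: LocusMatrix,
    offset: str = "hazen",
    group_by: pd.Series | None = None,
) -> LocusMatrix:
    """Quantile-normalize each locus to the standard normal across samples.

    Ranks are ascending with average ranks for ties, computed over the
    non-missing samples of each locus (missing stays missing).  A locus
    with fewer than two non-missing values is set to all-missing with a
    warning.  ``group_by`` (sample_id -> group, e.g. array version)
    normalizes within each group separately; the default is one joint pool
    of all samples.
    """
    if matrix.stage != "summed":
        raise ValueError(f"expected stage='summed', got {matrix.stage!r}")
    if offset not in QUANTILE_OFFSETS:
        raise ValueError(
            f"offset {offset!r} not one of {sorted(QUANTILE_OFFSETS)}"
        )
    vals = matrix.values.to_numpy(dtype=float)
    if np.any(np.isinf(vals)):
        raise ValueError("non-finite (infinite) values in summed matrix")

    out = np.full_like(vals, np.nan)
    if group_by is None:
        groups = [np.arange(vals.shape[0])]
    else:
        g = pd.Series(matrix.values.index.map(group_by))
        groups = [np.flatnonzero((g == lvl).to_numpy()) for lvl in g.dropna().unique()]

    c, d = QUANTILE_OFFSETS[offset]
    for rows in groups:
        sub = matrix.values.iloc[rows]
        ranks = sub.rank(axis=0, method="average", na_option="keep")
        n_obs = ranks.notna().sum(axis=0).to_numpy(dtype=float)
        thin = n_obs < 2
        if thin.any():
            for lid in np.asarray(sub.columns)[thin]:
                warnings.warn(
                    f"locus {lid!r}: fewer than 2 non-missing values; "
                    "normalized to all-missing",
                    stacklevel=2,
                )
        p = (ranks.to_numpy() - c) / (n_obs + d)
        z = ndtri(p)
        z[:, thin] = np.nan
        out[rows] = z

    values = pd.DataFrame(out, index=matrix.values.index,
                          columns=matrix.values.columns)
    return LocusMatrix(values, stage="normalized",
                       params={"offset": offset,
                               "pooling": "grouped" if group_by is not None
                               else "joint"})


# -- TSV I/O -------------------------------------------------------------

def write_locus_matrix(matrix: LocusMatrix, path: str | Path) -> None:
    path = Path(path)
    meta = "; ".join(f"{k}={v}" for k, v in sorted(matrix.params.items()))
    header = f"# stage={matrix.stage}" + (f"; {meta}" if meta else "")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        out = matrix.values.copy()
        out = out.map(lambda v: "NA" if pd.isna(v) else format(v, ".10g"))
        out.to_csv(fh, sep="\t", index_label="sample_id")


def read_locus_matrix(path: str | Path) -> LocusMatrix:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("# stage="):
            raise ValueError(f"{path}: missing '# stage=' metadata line")
        parts = [p.strip() for p in first[2:].split(";")]
        meta = dict(p.split("=", 1) for p in parts if "=" in p)
        stage = meta.pop("stage")
        df = pd.read_csv(fh, sep="\t", index_col="sample_id", na_values=["NA"])
    return LocusMatrix(df, stage=stage, params=meta)
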