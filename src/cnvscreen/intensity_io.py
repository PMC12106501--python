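"""I/O for raw probe-set intensity tables and sample manifests.

The package consumes post-extraction intensities: one non-negative
fluorescence value per (sample, probe set, allele), in the long/tidy TSV
produced upstream by vendor intensity-extraction tooling.  The long format
is canonical on disk because the two array versions carry overlapping but
unequal probe-set content, which a wide matrix represents awkwardly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .locus_model import LocusMap

__all__ = [
    "ALLELES",
    "TRUTH_LABELS",
    "IntensityError",
    "SampleManifest",
    "IntensityTable",
    "read_manifest",
    "write_manifest",
    "read_intensities",
    "write_intensities",
    "completeness_report",
]

log = logging.getLogger(__name__)

ALLELES = ("A", "B")
TRUTH_LABELS = ("carrier", "negative")

_MANIFEST_COLS = ["sample_id", "array_version", "truth_label"]
_INTENSITY_COLS = ["sample_id", "probe_set_id", "allele", "intensity"]


class IntensityError(ValueError):
    """Raised for malformed manifests or intensity tables."""


@dataclass
class SampleManifest:
    """Cohort roster: one row per sample with its array version.

    ``truth_label`` is optional ("carrier"/"negative"/missing) and is used
    only for evaluation against simulated or diagnostically confirmed truth.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _MANIFEST_COLS if c not in df.columns]
        if missing:
            raise IntensityError(f"manifest missing columns {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise IntensityError(f"duplicate sample_id {dup!r} in manifest")
        bad = df["truth_label"].dropna()
        bad = bad[~bad.isin(TRUTH_LABELS)]
        if len(bad):
            raise IntensityError(
                f"truth_label {bad.iloc[0]!r} not in {TRUTH_LABELS}"
            )
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Series:
        return self.frame["sample_id"]

    def version_of(self) -> pd.Series:
        """sample_id -> array_version mapping."""
        return self.frame.set_index("sample_id")["array_version"]

    def truth(self) -> pd.Series:
        """sample_id -> truth_label (NaN where unknown)."""
        return self.frame.set_index("sample_id")["truth_label"]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class IntensityTable:
    """Long-format intensities: (sample_id, probe_set_id, allele) -> value.

    Invariants: intensities finite and >= 0; at most one record per key.
    Array-version membership (a sample only has records for probe sets on
    its array) is checked in :func:`read_intensities`, where the manifest
    and locus map are in hand.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _INTENSITY_COLS if c not in df.columns]
        if missing:
            raise IntensityError(f"intensity table missing columns {missing}")
        vals = df["intensity"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            i = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise IntensityError(f"non-finite intensity at record {i}")
        if np.any(vals < 0):
            i = int(np.flatnonzero(vals < 0)[0])
            raise IntensityError(
                f"negative intensity {vals[i]} at record {i}"
            )
        bad_allele = ~df["allele"].isin(ALLELES)
        if bad_allele.any():
            raise IntensityError(
                f"allele {df.loc[bad_allele, 'allele'].iloc[0]!r} not in {ALLELES}"
            )
        if self._has_duplicate_keys(df):
            raise IntensityError(
                "duplicate (sample_id, probe_set_id, allele) record"
            )
        self.frame = df.reset_index(drop=True)

    @staticmethod
    def _codes(col: pd.Series) -> tuple[np.ndarray, int]:
        if isinstance(col.dtype, pd.CategoricalDtype):
            return col.cat.codes.to_numpy(np.int64), len(col.cat.categories)
        codes, uniques = pd.factorize(col)
        return codes.astype(np.int64), max(len(uniques), 1)

    @classmethod
    def _has_duplicate_keys(cls, df: pd.DataFrame) -> bool:
        # integer-encode the key triple; a sort beats hashing 3 string cols
        if not len(df):
            return False
        s, _ = cls._codes(df["sample_id"])
        p, n_p = cls._codes(df["probe_set_id"])
        a, n_a = cls._codes(df["allele"])
        key = np.sort((s * n_p + p) * n_a + a)
        return bool(np.any(np.diff(key) == 0))

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityTable):
            return NotImplemented
        cols = _INTENSITY_COLS
        a = self.frame[cols].sort_values(cols[:3]).reset_index(drop=True)
        b = other.frame[cols].sort_values(cols[:3]).reset_index(drop=True)
        return bool(
            (a[cols[:3]].astype(str) == b[cols[:3]].astype(str)).all().all()
            and np.allclose(a["intensity"], b["intensity"])
        ) if len(a) == len(b) else False


# -- manifest I/O --------------------------------------------------------

def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.frame.to_csv(path, sep="\t", index=False, na_rep="")


def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "array_version": str,
                               "truth_label": str},
        keep_default_na=False, na_values=[""],
    )
    return SampleManifest(df)


# -- intensity I/O -------------------------------------------------------

def write_intensities(table: IntensityTable, path: str | Path) -> None:
    out = table.frame.copy()
    out["intensity"] = out["intensity"].map(lambda v: format(v, ".6g"))
    out.to_csv(path, sep="\t", index=False)


def read_intensities(
    path: str | Path,
    manifest: SampleManifest,
    locus_map: LocusMap,
) -> IntensityTable:
    """Read and validate an intensity TSV against the manifest and locus map.

    Records for probe sets absent from the locus map are dropped (count
    logged).  A record for a probe set not carried by the sample's array
    version, an unknown sample, or a malformed value is an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t",
            dtype={"sample_id": str, "probe_set_id": str, "allele": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise IntensityError(f"{path}: {exc}") from exc
    missing = [c for c in _INTENSITY_COLS if c not in df.columns]
    if missing:
        raise IntensityError(f"{path}: missing columns {missing}")

    known = set(manifest.sample_ids)
    unknown = ~df["sample_id"].isin(known)
    if unknown.any():
        sid = df.loc[unknown, "sample_id"].iloc[0]
        raise IntensityError(f"{path}: sample {sid!r} not in manifest")

    in_map = df["probe_set_id"].isin(locus_map.probe_to_locus())
    n_dropped = int((~in_map).sum())
    if n_dropped:
        log.info("dropped %d records for probe sets outside the locus map",
                 n_dropped)
        df = df[in_map].reset_index(drop=True)

    table = validate_membership(IntensityTable(df), manifest, locus_map)
    return table


def validate_membership(
    table: IntensityTable, manifest: SampleManifest, locus_map: LocusMap
) -> IntensityTable:
    """Check each record's probe set is on the sample's array version."""
    df = table.frame
    if not len(df):
        return table
    versions = manifest.version_of()
    probe_versions = locus_map.probe_versions()
    sample_v = df["sample_id"].map(versions)
    ok = np.fromiter(
        (sv in probe_versions.get(ps, frozenset())
         for sv, ps in zip(sample_v, df["probe_set_id"])),
        dtype=bool, count=len(df),
    )
    if not ok.all():
        i = int(np.flatnonzero(~ok)[0])
        row = df.iloc[i]
        raise IntensityError(
            f"record {i}: probe set {row['probe_set_id']!r} is not on array "
            f"version {sample_v.iloc[i]!r} of sample {row['sample_id']!r}"
        )
    return table


def completeness_report(
    table: IntensityTable,
    locus_map: LocusMap,
    manifest: SampleManifest,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Per-sample fraction of expected (probe set, allele) records present.

    The expectation is version-aware: a v1 sample is only expected to have
    records for probe sets carried by v1.  Samples below ``threshold`` are
    flagged; downstream normalization treats their absent loci as missing
    rather than imputing them.
    """
    probe_versions = locus_map.probe_versions()
    expected_per_version: dict[str, int] = {}
    all_versions = set().union(*probe_versions.values()) if probe_versions else set()
    for v in all_versions:
        expected_per_version[v] = 2 * sum(
            1 for vs in probe_versions.values() if v in vs
        )

    counts = table.frame.groupby("sample_id", observed=True).size() if len(table) \
        else pd.Series(dtype=int)
    rows = []
    for sid, version in zip(manifest.frame["sample_id"],
                            manifest.frame["array_version"]):
        expected = expected_per_version.get(version, 0)
        present = int(counts.get(sid, 0))
        frac = present / expected if expected else 0.0
        rows.append((sid, version, expected, present, frac, frac < threshold))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "array_version", "n_expected", "n_present",
                 "completeness", "flagged"],
    )
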