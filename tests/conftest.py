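import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cnvscreen.intensity_io import IntensityTable, SampleManifest
from cnvscreen.locus_model import GenomicRegion, Locus, LocusMap

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BOTH = frozenset({"v1", "v2"})


def make_regions():
    return [
        GenomicRegion("3", 37_034_575, 37_044_574, "flank_left"),
        GenomicRegion("3", 37_044_575, 37_048_112, "deletion"),
        GenomicRegion("3", 37_048_113, 37_058_112, "flank_right"),
    ]


def make_locus_map(n_del=3, n_flank=2, v2_only_probe=False):
    """Tiny map: n_del deletion loci (first one with two probe sets) and
    n_flank loci per side.  Optionally the second deletion probe set is
    v2-only, to exercise version-aware summation."""
    regions = make_regions()
    loci = []
    for i in range(n_del):
        probes = [f"PSD{i}a"]
        versions = [BOTH]
        if i == 0:
            probes.append("PSD0b")
            versions.append(frozenset({"v2"}) if v2_only_probe else BOTH)
        loci.append(Locus(f"DEL{i}", "3", 37_044_600 + 100 * i, "deletion",
                          tuple(probes), tuple(versions)))
    for side, base, label in (("L", 37_034_600, "flank_left"),
                              ("R", 37_048_200, "flank_right")):
        for i in range(n_flank):
            loci.append(Locus(f"FL{side}{i}", "3", base + 100 * i, label,
                              (f"PSF{side}{i}",), (BOTH,)))
    return LocusMap(regions, loci)


def make_manifest(sample_ids, versions=None, truth=None):
    n = len(sample_ids)
    return SampleManifest(pd.DataFrame({
        "sample_id": list(sample_ids),
        "array_version": versions if versions is not None else ["v1"] * n,
        "truth_label": truth if truth is not None else [np.nan] * n,
    }))


def make_table(records):
    """records: iterable of (sample_id, probe_set_id, allele, intensity)."""
    return IntensityTable(pd.DataFrame(
        records, columns=["sample_id", "probe_set_id", "allele", "intensity"]
    ))


@pytest.fixture
def tiny_map():
    return make_locus_map()


@pytest.fixture
def regions():
    return make_regions()
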