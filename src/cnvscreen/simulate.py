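"""Synthetic SNP-array intensity cohorts with planted heterozygous deletions.

The generator emulates the statistical structure the detection method
relies on, not the physics of a real array:

* two array versions ("v1", "v2") with overlapping probe-set content —
  all flanking probe sets are shared, a small configurable minority of
  deletion-region probe sets is version-specific;
* a deletion region interrogated by 21 probe sets over 18 unique loci
  (three loci carry two probe sets each) and 25 flanking loci per side;
* multiplicative lognormal noise: per-record intensity =
  ``baseline(probe set) x sample_scale x copy_factor x exp(N(0, sd))``,
  where ``copy_factor`` is ``deletion_signal_ratio`` (0.5 for a
  heterozygous deletion) at deletion-region probe sets of carrier samples
  and 1 otherwise;
* a minority class of "noisy" samples whose per-record log-scale noise is
  inflated by ``noisy_extra_sd`` — these emulate the high-variance
  unclassifiable samples a real cohort contains;
* each probe set's total is split between A and B alleles by a Beta draw;
  only the A+B sum matters downstream, the split keeps the I/O schema
  honest.

All randomness flows from one ``numpy.random.default_rng(rng_seed)``
stream, so a config is a complete recipe: same config, same bytes out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .intensity_io import IntensityTable, SampleManifest
from .locus_model import (
    GenomicRegion,
    Locus,
    LocusMap,
    MLH1_EX16_CHROM,
    MLH1_EX16_END,
    MLH1_EX16_START,
)

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "default_locus_map",
    "simulate_cohort",
    "assign_sample_classes",
    "expected_feature_location",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Recipe for one synthetic cohort.

    ``carrier_fraction`` defaults to the 0.024% carrier prevalence of the
    target founder deletion; set ``n_carriers`` to plant an exact count
    instead of a binomial draw.  ``v1_fraction`` defaults to the 28% /
    72% split between the two array versions.  Noise defaults are chosen
    so that the halved carrier signal (log 0.5 ~ -0.69) is several times
    the per-locus noise scale, giving the qualitative cluster geometry
    the method expects; see the methods note for the reasoning.
    """

    n_samples: int = 10_000
    carrier_fraction: float = 0.00024
    n_carriers: int | None = None
    noisy_fraction: float = 0.001
    n_deletion_loci: int = 18
    n_probe_sets_deletion: int = 21
    n_flank_per_side: int = 25
    baseline_mean: float = 1000.0
    probe_baseline_sd: float = 0.2
    sample_scale_sd: float = 0.05
    probe_noise_sd: float = 0.15
    deletion_signal_ratio: float = 0.5
    noisy_extra_sd: float = 0.45
    v1_fraction: float = 0.28
    n_version_specific_deletion: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("carrier_fraction", "noisy_fraction", "v1_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.carrier_fraction + self.noisy_fraction > 1.0:
            raise ValueError("carrier_fraction + noisy_fraction must be <= 1")
        if not 0.0 < self.deletion_signal_ratio <= 1.0:
            raise ValueError("deletion_signal_ratio must be in (0, 1]")
        if self.n_deletion_loci < 1 or self.n_flank_per_side < 1:
            raise ValueError("locus counts must be positive")
        if self.n_probe_sets_deletion < self.n_deletion_loci:
            raise ValueError(
                "n_probe_sets_deletion must be >= n_deletion_loci"
            )
        if self.n_version_specific_deletion > (
            self.n_probe_sets_deletion - self.n_deletion_loci
        ):
            raise ValueError(
                "version-specific probe sets must come from the surplus "
                "(beyond one shared probe set per locus)"
            )
        for name in ("baseline_mean",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("probe_baseline_sd", "sample_scale_sd", "probe_noise_sd",
                     "noisy_extra_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_carriers is not None and not (
            0 <= self.n_carriers <= self.n_samples
        ):
            raise ValueError("n_carriers must be in [0, n_samples]")


@dataclass
class SimulatedCohort:
    manifest: SampleManifest
    intensities: IntensityTable
    locus_map: LocusMap
    config: SimulationConfig

    @property
    def truth(self) -> pd.Series:
        return self.manifest.truth()


def default_locus_map(config: SimulationConfig) -> LocusMap:
    """Build the simulated array design around the target deletion.

    Deletion loci are spaced evenly inside the deletion region; flanking
    loci evenly over windows of ten times the deletion length on each
    side.  Surplus deletion probe sets (beyond one per locus) go to the
    first loci; the first ``n_version_specific_deletion`` of those
    surplus probe sets alternate v1-only / v2-only, so every locus keeps
    at least one probe set shared by both arrays.
    """
    chrom = MLH1_EX16_CHROM
    del_start, del_end = MLH1_EX16_START, MLH1_EX16_END
    del_len = del_end - del_start + 1
    flank_span = 10 * del_len
    regions = [
        GenomicRegion(chrom, del_start - flank_span, del_start - 1, "flank_left"),
        GenomicRegion(chrom, del_start, del_end, "deletion"),
        GenomicRegion(chrom, del_end + 1, del_end + flank_span, "flank_right"),
    ]

    both = frozenset({"v1", "v2"})
    loci: list[Locus] = []

    n_extra = config.n_probe_sets_deletion - config.n_deletion_loci
    del_pos = np.linspace(del_start + 1, del_end - 1,
                          config.n_deletion_loci).astype(int)
    del_pos = np.unique(del_pos)
    if len(del_pos) < config.n_deletion_loci:
        raise ValueError("deletion region too small for requested locus count")
    spec_left = config.n_version_specific_deletion
    for i, pos in enumerate(del_pos):
        probes = [f"PSD{i:03d}a"]
        versions = [both]
        if i < n_extra:
            probes.append(f"PSD{i:03d}b")
            if spec_left > 0:
                versions.append(frozenset({"v1" if spec_left % 2 else "v2"}))
                spec_left -= 1
            else:
                versions.append(both)
        loci.append(Locus(f"DEL{i:03d}", chrom, int(pos), "deletion",
                          tuple(probes), tuple(versions)))

    for side, reg in (("L", regions[0]), ("R", regions[2])):
        pos_arr = np.unique(np.linspace(reg.start + 1, reg.end - 1,
                                        config.n_flank_per_side).astype(int))
        for i, pos in enumerate(pos_arr):
            loci.append(Locus(f"FL{side}{i:03d}", chrom, int(pos),
                              reg.label, (f"PSF{side}{i:03d}",), (both,)))

    return LocusMap(regions, loci)


def assign_sample_classes(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (is_carrier, is_noisy, is_v1) for every sample.

    Carrier and noisy classes are disjoint.  With ``n_carriers`` unset,
    carrier status is an independent Bernoulli(carrier_fraction) draw per
    sample (so the count is Binomial(n, p)); otherwise exactly
    ``n_carriers`` samples are chosen without replacement.
    """
    n = config.n_samples
    u = rng.random(n)
    if config.n_carriers is None:
        is_carrier = u < config.carrier_fraction
        is_noisy = (~is_carrier) & (
            u < config.carrier_fraction + config.noisy_fraction
        )
    else:
        is_carrier = np.zeros(n, dtype=bool)
        if config.n_carriers:
            is_carrier[rng.choice(n, size=config.n_carriers, replace=False)] = True
        is_noisy = (~is_carrier) & (u < config.noisy_fraction)
    is_v1 = rng.random(n) < config.v1_fraction
    return is_carrier, is_noisy, is_v1


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort: manifest, long intensity table, locus map.

    Deterministic given ``config.rng_seed``; carriers have expected total
    deletion-locus signal equal to ``deletion_signal_ratio`` times the
    non-carrier expectation before noise.
    """
    rng = np.random.default_rng(config.rng_seed)
    locus_map = default_locus_map(config)

    n = config.n_samples
    width = max(6, len(str(n)))
    sample_ids = np.array([f"S{i:0{width}d}" for i in range(n)])
    is_carrier, is_noisy, is_v1 = assign_sample_classes(config, rng)
    version = np.where(is_v1, "v1", "v2")

    probe_ids: list[str] = []
    probe_is_del: list[bool] = []
    probe_versions: list[frozenset[str]] = []
    for locus in locus_map.loci:
        for ps, vs in zip(locus.probe_set_ids, locus.array_versions):
            probe_ids.append(ps)
            probe_is_del.append(locus.region == "deletion")
            probe_versions.append(vs)
    p = len(probe_ids)
    probe_is_del_arr = np.array(probe_is_del)

    baseline = config.baseline_mean * np.exp(
        rng.normal(0.0, config.probe_baseline_sd, p)
    )
    sample_scale = np.exp(rng.normal(0.0, config.sample_scale_sd, n))
    noise_sd = np.where(is_noisy,
                        config.probe_noise_sd + config.noisy_extra_sd,
                        config.probe_noise_sd)
    noise = np.exp(rng.normal(0.0, 1.0, (n, p)) * noise_sd[:, None])
    copy_factor = np.where(
        is_carrier[:, None] & probe_is_del_arr[None, :],
        config.deletion_signal_ratio, 1.0,
    )
    total = baseline[None, :] * sample_scale[:, None] * copy_factor * noise

    # membership mask: record exists iff the probe set is on the sample's array
    on_v1 = np.array(["v1" in vs for vs in probe_versions])
    on_v2 = np.array(["v2" in vs for vs in probe_versions])
    mask = np.where(is_v1[:, None], on_v1[None, :], on_v2[None, :])

    frac_a = rng.beta(5.0, 5.0, (n, p))

    si, pi = np.nonzero(mask)
    tot = total[si, pi]
    fa = frac_a[si, pi]
    # compute the larger allele share by product and the smaller as the
    # exact difference, so A + B reproduces the total bit-exactly (keeps
    # deliberately identical samples identical after allele summation)
    big = tot * np.maximum(fa, 1.0 - fa)
    small = tot - big
    a_share = np.where(fa >= 0.5, big, small)
    b_share = np.where(fa >= 0.5, small, big)
    m = len(si)
    frame = pd.DataFrame({
        "sample_id": pd.Categorical.from_codes(
            np.repeat(si, 2), categories=list(sample_ids)
        ),
        "probe_set_id": pd.Categorical.from_codes(
            np.repeat(pi, 2), categories=probe_ids
        ),
        "allele": pd.Categorical.from_codes(
            np.tile(np.array([0, 1], dtype=np.int8), m), categories=["A", "B"]
        ),
        "intensity": np.stack([a_share, b_share], axis=1).ravel(),
    })

    manifest = SampleManifest(pd.DataFrame({
        "sample_id": sample_ids,
        "array_version": version,
        "truth_label": np.where(is_carrier, "carrier", "negative"),
    }).assign(is_noisy=is_noisy))

    return SimulatedCohort(
        manifest=manifest,
        intensities=IntensityTable(frame),
        locus_map=locus_map,
        config=config,
    )


def expected_feature_location(
    config: SimulationConfig, n_carriers: int | None = None
) -> tuple[float, float]:
    """Analytic feature-plane location of an ideal noiseless carrier.

    With k carriers among N samples and no noise, every carrier ties at
    the bottom of each deletion locus; average ranks give each carrier
    rank (k+1)/2, so the Hazen-normalized value is ``Phi^-1(k / 2N)``
    (for k=1, N=1000: about -3.29).  Flank loci are all tied and map to
    0, so median_difference equals that quantile and the piecewise MAD of
    a noiseless sample is 0.  Degenerate limits: with
    ``deletion_signal_ratio`` = 1 or k = N the transform sees no
    between-sample difference and the expected location is (0, 0).
    """
    k = n_carriers if n_carriers is not None else (
        config.n_carriers if config.n_carriers is not None
        else round(config.carrier_fraction * config.n_samples)
    )
    if k == 0:
        raise ValueError("expected carrier location undefined for k=0")
    n = config.n_samples
    if not 0 < k <= n:
        raise ValueError(f"k must be in (0, n_samples], got {k}")
    if config.deletion_signal_ratio == 1.0 or k == n:
        return 0.0, 0.0
    return float(ndtri(k / (2.0 * n))), 0.0
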