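"""Genomic model of the target deletion and its flanking baseline.

The screening method compares array probe intensities inside a candidate
deletion region against loci flanking it on both sides.  This module holds
the coordinate model: three labelled regions (``deletion``, ``flank_left``,
``flank_right``), the loci interrogated by the array, and the mapping from
probe sets to loci.  All coordinates are GRCh38, 1-based and inclusive at
both ends, so a region's length is ``end - start + 1`` (the target MLH1
exon 16 deletion, 3:37044575-37048112, is 3 538 bp under this convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "REGION_LABELS",
    "GenomicRegion",
    "Locus",
    "LocusMap",
    "LocusMapError",
    "region_length",
    "assign_region",
    "read_locus_map",
    "write_locus_map",
    "read_regions",
    "write_regions",
]

REGION_LABELS = ("deletion", "flank_left", "flank_right")

#: GRCh38 coordinates of the MLH1 exon 16 founder deletion.
MLH1_EX16_CHROM = "3"
MLH1_EX16_START = 37_044_575
MLH1_EX16_END = 37_048_112


class LocusMapError(ValueError):
    """Raised for invalid region/locus configurations or unparseable files."""


@dataclass(frozen=True)
class GenomicRegion:
    """A labelled genomic interval, 1-based inclusive at both ends."""

    chrom: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise LocusMapError(
                f"region label {self.label!r} not one of {REGION_LABELS}"
            )
        if self.start < 1:
            raise LocusMapError(f"region start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise LocusMapError(
                f"region start {self.start} > end {self.end} ({self.label})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def region_length(region: GenomicRegion) -> int:
    """Length of a 1-based inclusive region in base pairs."""
    return region.length


def assign_region(
    pos: int,
    regions: Mapping[str, GenomicRegion] | Sequence[GenomicRegion],
    chrom: str | None = None,
) -> str:
    """Assign a position to ``deletion`` / ``flank_left`` / ``flank_right`` or ``outside``.

    Regions must not overlap (flanks may abut the deletion).  Boundary
    positions are inclusive on both ends.
    """
    if pos < 1:
        raise LocusMapError(f"position must be >= 1, got {pos}")
    regs = list(regions.values()) if isinstance(regions, Mapping) else list(regions)
    _check_disjoint(regs)
    for reg in regs:
        if chrom is not None and chrom != reg.chrom:
            continue
        if reg.start <= pos <= reg.end:
            return reg.label
    return "outside"


def _check_disjoint(regions: Sequence[GenomicRegion]) -> None:
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for reg in regions:
        by_chrom.setdefault(reg.chrom, []).append(reg)
    for regs in by_chrom.values():
        regs = sorted(regs, key=lambda r: r.start)
        for a, b in zip(regs, regs[1:]):
            if b.start <= a.end:
                raise LocusMapError(
                    f"regions {a.label} and {b.label} overlap on chr{a.chrom}"
                )


@dataclass(frozen=True)
class Locus:
    """A unique genomic position interrogated by one or more probe sets.

    ``array_versions`` is parallel to ``probe_set_ids``: for each probe set,
    the set of array versions (e.g. ``{"v1", "v2"}``) whose manifest carries
    it.  Multiple probe sets at the same position must share one locus.
    """

    locus_id: str
    chrom: str
    pos: int
    region: str
    probe_set_ids: tuple[str, ...]
    array_versions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if self.region not in REGION_LABELS:
            raise LocusMapError(
                f"locus {self.locus_id}: region {self.region!r} invalid"
            )
        if not self.probe_set_ids:
            raise LocusMapError(f"locus {self.locus_id}: no probe sets")
        if len(self.array_versions) != len(self.probe_set_ids):
            raise LocusMapError(
                f"locus {self.locus_id}: array_versions not parallel to probe_set_ids"
            )
        if len(set(self.probe_set_ids)) != len(self.probe_set_ids):
            raise LocusMapError(f"locus {self.locus_id}: duplicate probe set ids")

    def versions_of(self, probe_set_id: str) -> frozenset[str]:
        return self.array_versions[self.probe_set_ids.index(probe_set_id)]


class LocusMap:
    """Regions plus the position-ordered loci they contain.

    Invariants enforced at construction:

    * each locus's position lies inside its assigned region;
    * locus ids are unique; positions are unique (probe sets at one
      position share a locus);
    * probe set ids are unique across loci;
    * loci are stored sorted by (chrom, pos, locus_id).
    """

    def __init__(self, regions: Iterable[GenomicRegion], loci: Iterable[Locus]):
        regs = list(regions)
        labels = [r.label for r in regs]
        if sorted(labels) != sorted(REGION_LABELS):
            raise LocusMapError(
                f"need exactly the three regions {REGION_LABELS}, got {labels}"
            )
        _check_disjoint(regs)
        self.regions: dict[str, GenomicRegion] = {r.label: r for r in regs}

        loci = sorted(loci, key=lambda l: (l.chrom, l.pos, l.locus_id))
        seen_ids: set[str] = set()
        seen_pos: set[tuple[str, int]] = set()
        seen_probes: set[str] = set()
        for locus in loci:
            if locus.locus_id in seen_ids:
                raise LocusMapError(f"duplicate locus_id {locus.locus_id!r}")
            seen_ids.add(locus.locus_id)
            if (locus.chrom, locus.pos) in seen_pos:
                raise LocusMapError(
                    f"two loci at {locus.chrom}:{locus.pos}; probe sets at one "
                    "position must share a locus"
                )
            seen_pos.add((locus.chrom, locus.pos))
            for ps in locus.probe_set_ids:
                if ps in seen_probes:
                    raise LocusMapError(f"probe set {ps!r} assigned to two loci")
                seen_probes.add(ps)
            reg = self.regions[locus.region]
            if not reg.contains(locus.chrom, locus.pos):
                raise LocusMapError(
                    f"locus {locus.locus_id} at {locus.chrom}:{locus.pos} lies "
                    f"outside its assigned region {locus.region} "
                    f"({reg.chrom}:{reg.start}-{reg.end})"
                )
        self.loci: list[Locus] = loci

    # -- queries ---------------------------------------------------------

    def loci_in(self, region: str) -> list[Locus]:
        return [l for l in self.loci if l.region == region]

    @property
    def deletion_loci(self) -> list[Locus]:
        return self.loci_in("deletion")

    @property
    def flank_loci(self) -> list[Locus]:
        return [l for l in self.loci if l.region != "deletion"]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def probe_to_locus(self) -> dict[str, str]:
        return {ps: l.locus_id for l in self.loci for ps in l.probe_set_ids}

    def probe_versions(self) -> dict[str, frozenset[str]]:
        return {
            ps: vs
            for l in self.loci
            for ps, vs in zip(l.probe_set_ids, l.array_versions)
        }

    def __len__(self) -> int:
        return len(self.loci)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LocusMap):
            return NotImplemented
        return self.regions == other.regions and self.loci == other.loci

    def __repr__(self) -> str:
        n_del = len(self.deletion_loci)
        return (
            f"LocusMap({len(self.loci)} loci: {n_del} deletion, "
            f"{len(self.loci) - n_del} flanking)"
        )


# -- TSV I/O -------------------------------------------------------------

_LOCUS_HEADER = ["chrom", "pos", "locus_id", "region", "probe_set_ids", "array_versions"]
_REGION_HEADER = ["chrom", "start", "end", "label"]
_REGION_COMMENT = "# coordinates are 1-based, inclusive at both ends (not BED 0-based half-open)"


def write_regions(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    path = Path(path)
    lines = [_REGION_COMMENT, "\t".join(_REGION_HEADER)]
    for reg in sorted(regions, key=lambda r: (r.chrom, r.start)):
        lines.append(f"{reg.chrom}\t{reg.start}\t{reg.end}\t{reg.label}")
    path.write_text("\n".join(lines) + "\n")


def read_regions(path: str | Path) -> list[GenomicRegion]:
    path = Path(path)
    regions: list[GenomicRegion] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != _REGION_HEADER:
                    raise LocusMapError(
                        f"{path}:{lineno}: expected header {_REGION_HEADER}, got {fields}"
                    )
                header_seen = True
                continue
            if len(fields) != 4:
                raise LocusMapError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, label = fields
            try:
                regions.append(GenomicRegion(chrom, int(start), int(end), label))
            except (ValueError, LocusMapError) as exc:
                raise LocusMapError(f"{path}:{lineno}: {exc}") from exc
    if not regions:
        raise LocusMapError(f"{path}: no regions found")
    return regions


def write_locus_map(locus_map: LocusMap, locus_path: str | Path,
                    region_path: str | Path | None = None) -> None:
    """Write the locus table (and optionally the region table) as TSV."""
    locus_path = Path(locus_path)
    lines = ["\t".join(_LOCUS_HEADER)]
    for locus in locus_map.loci:
        probes = ",".join(locus.probe_set_ids)
        versions = ",".join(
            ";".join(sorted(vs)) for vs in locus.array_versions
        )
        lines.append(
            f"{locus.chrom}\t{locus.pos}\t{locus.locus_id}\t{locus.region}\t"
            f"{probes}\t{versions}"
        )
    locus_path.write_text("\n".join(lines) + "\n")
    if region_path is not None:
        write_regions(locus_map.regions.values(), region_path)


def read_locus_map(locus_path: str | Path, region_path: str | Path) -> LocusMap:
    """Read a locus map from its locus TSV plus region TSV.

    Loci are re-sorted by position on read; all LocusMap invariants are
    enforced, with file/line locations in error messages.
    """
    regions = read_regions(region_path)
    locus_path = Path(locus_path)
    loci: list[Locus] = []
    header_seen = False
    with open(locus_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != _LOCUS_HEADER:
                    raise LocusMapError(
                        f"{locus_path}:{lineno}: expected header {_LOCUS_HEADER}"
                    )
                header_seen = True
                continue
            if len(fields) != 6:
                raise LocusMapError(
                    f"{locus_path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            chrom, pos, locus_id, region, probes_s, versions_s = fields
            probe_set_ids = tuple(p for p in probes_s.split(",") if p)
            array_versions = tuple(
                frozenset(v for v in entry.split(";") if v)
                for entry in versions_s.split(",")
            )
            try:
                loci.append(
                    Locus(locus_id, chrom, int(pos), region, probe_set_ids,
                          array_versions)
                )
            except (ValueError, LocusMapError) as exc:
                raise LocusMapError(f"{locus_path}:{lineno}: {exc}") from exc
    if not loci:
        raise LocusMapError(f"{locus_path}: no loci found")
    try:
        return LocusMap(regions, loci)
    except LocusMapError as exc:
        raise LocusMapError(f"{locus_path}: {exc}") from exc
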