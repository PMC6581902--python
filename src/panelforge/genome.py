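"""Genome model: contigs, regions, X-region maps, and VCF/BED/config I/O.

Coordinates are 1-based inclusive everywhere (VCF convention).  BED input is
converted at the boundary from 0-based half-open.  Contig order is the order
declared in the genome configuration, never lexicographic, so that chunking
and merge order are deterministic.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam
import yaml

CATEGORIES = ("autosome", "chrX", "chrY", "mito")

__all__ = [
    "Contig",
    "Region",
    "XRegionMap",
    "GenomeBuild",
    "SampleSiteRecord",
    "GRCH37_X_REGIONS",
    "genotype_order",
    "partition_contig",
    "read_sample_vcf",
    "write_panel_vcf",
    "read_panel_vcf",
    "read_bed",
    "load_genome_config",
]


class VcfParseError(ValueError):
    """A VCF body line could not be interpreted."""


class SampleIdentityError(ValueError):
    """The sample present in a file is not the sample we expected."""


@dataclass(frozen=True)
class Contig:
    name: str
    length: int
    circular: bool = False
    category: str = "autosome"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.name}: length must be >= 1")
        if self.category not in CATEGORIES:
            raise ValueError(f"contig {self.name}: unknown category {self.category!r}")
        if self.circular and self.category != "mito":
            raise ValueError(f"contig {self.name}: only mitochondria may be circular")


@dataclass(frozen=True, order=True)
class Region:
    """Closed interval [start, end] on one contig, 1-based."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad region {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos <= self.end

    def intersection(self, other: "Region") -> "Region | None":
        if other.contig != self.contig:
            return None
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return Region(self.contig, lo, hi) if lo <= hi else None

    def positions(self) -> range:
        return range(self.start, self.end + 1)


# GRCh37 coordinates of the X pseudoautosomal regions and the X-transposed
# region, as used for the full-scale panel.
GRCH37_X_REGIONS = {
    "par1": (60_001, 2_699_520),
    "xtr": (88_456_802, 92_375_509),
    "par2": (154_931_044, 155_260_560),
}

TWO_PAR = "TWO_PAR"
THREE_PAR = "THREE_PAR"


@dataclass(frozen=True)
class XRegionMap:
    """Named X sub-regions and the convention for treating the XTR.

    Under ``TWO_PAR`` only PAR1/PAR2 behave pseudoautosomally (diploid in
    males); under ``THREE_PAR`` the XTR does as well.
    """

    par1: Region
    xtr: Region
    par2: Region
    mode: str = TWO_PAR

    def __post_init__(self) -> None:
        if self.mode not in (TWO_PAR, THREE_PAR):
            raise ValueError(f"unknown PAR mode {self.mode!r}")
        if not (self.par1.end < self.xtr.start and self.xtr.end < self.par2.start):
            raise ValueError("X regions must be ordered PAR1 < XTR < PAR2 and disjoint")

    @classmethod
    def grch37(cls, mode: str = TWO_PAR, contig: str = "X") -> "XRegionMap":
        return cls(
            par1=Region(contig, *GRCH37_X_REGIONS["par1"]),
            xtr=Region(contig, *GRCH37_X_REGIONS["xtr"]),
            par2=Region(contig, *GRCH37_X_REGIONS["par2"]),
            mode=mode,
        )

    def with_mode(self, mode: str) -> "XRegionMap":
        return XRegionMap(self.par1, self.xtr, self.par2, mode)

    def classify(self, pos: int, contig_length: int | None = None) -> str:
        """Classify an X position as PAR1, XTR, PAR2, or NONPAR.

        In TWO_PAR mode XTR positions are reported as NONPAR, matching the
        ploidy they receive under that convention.
        """
        if pos < 1 or (contig_length is not None and pos > contig_length):
            raise ValueError(f"position {pos} outside X contig")
        if self.par1.start <= pos <= self.par1.end:
            return "PAR1"
        if self.xtr.start <= pos <= self.xtr.end:
            return "XTR" if self.mode == THREE_PAR else "NONPAR"
        if self.par2.start <= pos <= self.par2.end:
            return "PAR2"
        return "NONPAR"

    def is_diploid_in_males(self, pos: int) -> bool:
        return self.classify(pos) in ("PAR1", "XTR", "PAR2")


@dataclass
class GenomeBuild:
    """Ordered contig set plus the X region map, loaded from a config file."""

    contigs: list[Contig]
    x_regions: XRegionMap | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {c.name: i for i, c in enumerate(self.contigs)}
        if len(self._index) != len(self.contigs):
            raise ValueError("duplicate contig names in genome build")

    def contig(self, name: str) -> Contig:
        return self.contigs[self._index[name]]

    def order(self, name: str) -> int:
        return self._index[name]

    def sort_key(self, contig: str, pos: int) -> tuple[int, int]:
        return (self._index[contig], pos)


@dataclass(frozen=True, slots=True)
class SampleSiteRecord:
    """One sample's evidence at one site (a GVCF-style row).

    ``genotype`` is a tuple of allele indices of length ``ploidy`` (0 = ref),
    or ``None`` for a no-call.  ``likelihoods`` are phred-scaled genotype
    likelihoods in canonical VCF genotype order for the declared ploidy and
    allele count, normalised so the minimum is 0.  ``strand_counts`` holds
    one (forward, reverse) pair per allele (ref first).
    """

    sample: str
    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, ...] | None
    ploidy: int
    likelihoods: tuple[int, ...] | None = None
    depth: int | None = None
    allele_depths: tuple[int, ...] | None = None
    strand_counts: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        n_alleles = 1 + len(self.alts)
        if self.genotype is not None:
            if len(self.genotype) != self.ploidy:
                raise ValueError(
                    f"{self.sample} {self.contig}:{self.pos}: genotype arity "
                    f"{len(self.genotype)} != ploidy {self.ploidy}"
                )
            if any(a >= n_alleles or a < 0 for a in self.genotype):
                raise ValueError(
                    f"{self.sample} {self.contig}:{self.pos}: allele index out of range"
                )
        if self.likelihoods is not None:
            expected = len(genotype_order(self.ploidy, n_alleles))
            if len(self.likelihoods) != expected:
                raise ValueError(
                    f"{self.sample} {self.contig}:{self.pos}: PL length "
                    f"{len(self.likelihoods)} != {expected} for ploidy {self.ploidy}"
                )
            if min(self.likelihoods) != 0:
                raise ValueError(
                    f"{self.sample} {self.contig}:{self.pos}: PL minimum is not 0"
                )


@functools.lru_cache(maxsize=None)
def genotype_order(ploidy: int, n_alleles: int) -> list[tuple[int, ...]]:
    """Canonical VCF genotype ordering for the given ploidy and allele count.

    For diploids this is the familiar (0,0),(0,1),(1,1),(0,2),... sequence
    with index F(j,k) = k(k+1)/2 + j.
    """
    if ploidy == 1:
        return [(a,) for a in range(n_alleles)]
    if ploidy == 2:
        return [(j, k) for k in range(n_alleles) for j in range(k + 1)]
    # general recursive form, rarely needed
    out: list[tuple[int, ...]] = []

    def rec(max_allele: int, p: int) -> Iterable[tuple[int, ...]]:
        if p == 0:
            yield ()
            return
        for a in range(max_allele + 1):
            for rest in rec(a, p - 1):
                yield rest + (a,)

    for k in range(n_alleles):
        out.extend(g for g in rec(k, ploidy) if max(g) == k)
    return out


def partition_contig(length: int, chunk_size: int, overlap: int) -> list[Region]:
    """Split ``[1, length]`` into chunks overlapping by exactly ``overlap``.

    Consecutive chunks share their ``overlap`` trailing/leading bases so that
    calls inside the shared zone can be cross-checked; the last chunk may be
    shorter.  Raises if the overlap is as large as the chunk itself.
    """
    if length < 1:
        raise ValueError("contig length must be >= 1")
    if overlap < 0 or overlap >= chunk_size:
        raise ValueError("require 0 <= overlap < chunk size")
    regions: list[Region] = []
    start = 1
    while True:
        end = min(start + chunk_size - 1, length)
        regions.append(Region("_", start, end))
        if end >= length:
            break
        start = end - overlap + 1
    return regions


def partition_contig_named(contig: Contig, chunk_size: int, overlap: int) -> list[Region]:
    return [
        Region(contig.name, r.start, r.end)
        for r in partition_contig(contig.length, chunk_size, overlap)
    ]


# ---------------------------------------------------------------------------
# VCF I/O (pysam-backed)
# ---------------------------------------------------------------------------

_SAC_DESC = "Per-allele strand counts (fwd,rev per allele including REF)"


def _sample_vcf_header(sample: str, contigs: Sequence[Contig]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in contigs:
        h.contigs.add(c.name, length=c.length)
    h.formats.add("GT", 1, "String", "Genotype")
    h.formats.add("PL", "G", "Integer", "Phred-scaled genotype likelihoods")
    h.formats.add("DP", 1, "Integer", "Read depth")
    h.formats.add("AD", "R", "Integer", "Allelic depths")
    h.formats.add("SAC", ".", "Integer", _SAC_DESC)
    h.add_sample(sample)
    return h


def write_sample_vcf(records: Sequence[SampleSiteRecord], contigs: Sequence[Contig], path: str) -> None:
    """Write one sample's records as a single-sample VCF 4.2 file."""
    if not records:
        raise ValueError("no records to write")
    sample = records[0].sample
    header = _sample_vcf_header(sample, contigs)
    with pysam.VariantFile(path, "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.contig, start=r.pos - 1, stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, *r.alts),
            )
            if r.genotype is None:
                rec.samples[sample]["GT"] = (None,) * r.ploidy
            else:
                rec.samples[sample]["GT"] = tuple(r.genotype)
            if r.likelihoods is not None:
                rec.samples[sample]["PL"] = list(r.likelihoods)
            if r.depth is not None:
                rec.samples[sample]["DP"] = r.depth
            if r.allele_depths is not None:
                rec.samples[sample]["AD"] = list(r.allele_depths)
            if r.strand_counts is not None:
                rec.samples[sample]["SAC"] = list(
                    itertools.chain.from_iterable(r.strand_counts)
                )
            out.write(rec)


def read_sample_vcf(path: str, expected_sample: str | None = None) -> list[SampleSiteRecord]:
    """Read a single-sample VCF into coordinate-sorted SampleSiteRecords.

    Ploidy is inferred from the GT arity.  Optional FORMAT fields absent from
    a record are returned as ``None``.  A sample-name mismatch raises
    :class:`SampleIdentityError`; a malformed body line raises
    :class:`VcfParseError` naming the line.
    """
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as e:
        raise VcfParseError(f"{path}: cannot open as VCF: {e}") from e
    with vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise SampleIdentityError(f"{path}: expected 1 sample, found {len(samples)}")
        sample = samples[0]
        if expected_sample is not None and sample != expected_sample:
            raise SampleIdentityError(
                f"{path}: sample {sample!r} does not match expected {expected_sample!r}"
            )
        n_header = sum(1 for line in str(vf.header).splitlines())
        records: list[SampleSiteRecord] = []
        contig_order = {name: i for i, name in enumerate(vf.header.contigs)}
        it = vf.fetch() if vf.index is not None else iter(vf)
        lineno = n_header
        while True:
            lineno += 1
            try:
                rec = next(it)
            except StopIteration:
                break
            except (OSError, ValueError) as e:
                raise VcfParseError(f"{path} line {lineno}: {e}") from e
            try:
                records.append(_record_from_pysam(rec, sample))
            except (KeyError, TypeError, ValueError) as e:
                raise VcfParseError(f"{path} line {lineno}: {e}") from e
    records.sort(key=lambda r: (contig_order.get(r.contig, len(contig_order)), r.pos))
    return records


def _record_from_pysam(rec: "pysam.VariantRecord", sample: str) -> SampleSiteRecord:
    fmt = rec.samples[sample]
    gt = fmt.get("GT")
    if gt is None:
        raise ValueError("record lacks GT")
    ploidy = len(gt)
    genotype = None if any(a is None for a in gt) else tuple(int(a) for a in gt)
    alts = tuple(rec.alts) if rec.alts else ()
    pl = fmt.get("PL")
    likelihoods = None
    if pl is not None and not all(v is None for v in pl):
        vals = [int(v) for v in pl if v is not None]
        likelihoods = tuple(vals)
    ad = fmt.get("AD")
    allele_depths = None
    if ad is not None and not all(v is None for v in ad):
        allele_depths = tuple(int(v) for v in ad)
    sac = fmt.get("SAC")
    strand = None
    if sac is not None and not all(v is None for v in sac):
        flat = [int(v) for v in sac]
        strand = tuple((flat[i], flat[i + 1]) for i in range(0, len(flat), 2))
    dp = fmt.get("DP")
    return SampleSiteRecord(
        sample=sample, contig=rec.contig, pos=rec.pos, ref=rec.ref, alts=alts,
        genotype=genotype, ploidy=ploidy, likelihoods=likelihoods,
        depth=None if dp is None else int(dp), allele_depths=allele_depths,
        strand_counts=strand,
    )


def write_panel_vcf(entries, contigs: Sequence[Contig], path: str) -> None:
    """Write panel entries as a sites-only VCF 4.2 with AC/AN/AF INFO fields.

    Entries must arrive sorted by (declared contig order, position);
    multiallelic sites are emitted as one record with comma-separated ALTs.
    """
    order = {c.name: i for i, c in enumerate(contigs)}
    last = None
    h = pysam.VariantHeader()
    for c in contigs:
        h.contigs.add(c.name, length=c.length)
    h.info.add("AC", "A", "Integer", "Alternate allele count")
    h.info.add("AN", 1, "Integer", "Total called allele number")
    h.info.add("AF", "A", "Float", "Alternate allele frequency")
    h.filters.add("FAIL", None, None, "Failed a configured hard filter")
    with pysam.VariantFile(path, "w", header=h) as out:
        for e in entries:
            key = (order[e.contig], e.pos)
            if last is not None and key < last:
                raise ValueError(
                    f"panel entries not sorted at {e.contig}:{e.pos}"
                )
            last = key
            filt = getattr(e, "filter", "PASS") or "PASS"
            if filt != "PASS" and filt not in h.filters:
                h.filters.add(filt, None, None, "Failed hard filter")
            rec = out.new_record(
                contig=e.contig, start=e.pos - 1, stop=e.pos - 1 + len(e.ref),
                alleles=(e.ref, *e.alts),
            )
            rec.info["AC"] = tuple(int(c) for c in e.ac)
            rec.info["AN"] = int(e.an)
            rec.info["AF"] = tuple(float(f) for f in e.af)
            rec.filter.add(filt)
            out.write(rec)


def read_panel_vcf(path: str):
    """Read a panel VCF written by :func:`write_panel_vcf` back into entries."""
    from .joint_panel import PanelEntry  # local import to avoid a cycle

    out = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            ac = tuple(int(v) for v in rec.info["AC"])
            an = int(rec.info["AN"])
            af = tuple(round(float(v), 6) for v in rec.info["AF"])
            filt = list(rec.filter.keys())
            out.append(
                PanelEntry(
                    contig=rec.contig, pos=rec.pos, ref=rec.ref,
                    alts=tuple(rec.alts or ()), ac=ac, an=an, af=af,
                    multiallelic=len(rec.alts or ()) > 1,
                    filter=filt[0] if filt else "PASS",
                )
            )
    return out


def read_bed(path: str) -> list[Region]:
    """Read a BED file into 1-based inclusive Regions (named or not)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            regions.append(Region(contig, start0 + 1, end0))
    return regions


def load_genome_config(path: str) -> GenomeBuild:
    """Load a YAML genome config listing contigs and optional X regions.

    Expected shape::

        contigs:
          - {name: "1", length: 10000000, circular: false, category: autosome}
        x_regions:
          par1: [60001, 2699520]
          xtr: [88456802, 92375509]
          par2: [154931044, 155260560]
          mode: TWO_PAR
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    contigs = [
        Contig(
            name=str(c["name"]), length=int(c["length"]),
            circular=bool(c.get("circular", False)),
            category=str(c.get("category", "autosome")),
        )
        for c in cfg["contigs"]
    ]
    xmap = None
    if "x_regions" in cfg:
        xr = cfg["x_regions"]
        xname = next((c.name for c in contigs if c.category == "chrX"), "X")
        xmap = XRegionMap(
            par1=Region(xname, *xr["par1"]),
            xtr=Region(xname, *xr["xtr"]),
            par2=Region(xname, *xr["par2"]),
            mode=str(xr.get("mode", TWO_PAR)),
        )
    return GenomeBuild(contigs=contigs, x_regions=xmap)
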