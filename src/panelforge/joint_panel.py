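"""Joint genotype aggregation, chunked execution, site annotation and the
allele-frequency panel.

The joint "caller" here is a likelihood-argmax aggregation over per-sample
site records: it merges allele lists across samples, re-expresses each
sample's most likely genotype in the merged indexing, and keeps every
position where at least one sample presents an alternative allele.  It does
not realign or reassemble reads.  Chunked execution splits a contig into
fixed-size chunks with a short shared overlap; calls inside the overlap are
cross-checked between adjacent chunks and any disagreement (including a call
present in only one chunk) is removed from the panel and reported.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .genome import (
    Contig,
    Region,
    SampleSiteRecord,
    genotype_order,
    partition_contig_named,
)

PloidyMapFn = Callable[[str, str, int], int]

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

QUAL_CAP_PER_SAMPLE = 99


class PloidyConflictError(ValueError):
    """A record's ploidy contradicts the ploidy map."""


class FilterConfigError(ValueError):
    """A hard-filter threshold references an unknown annotation."""


@dataclass
class SiteAnnotations:
    """Hard-filter annotations for one site.

    ``qd`` is the site quality proxy normalised by the depth of alt-carrying
    samples; ``fs`` is the phred-scaled two-sided Fisher strand-bias p-value;
    ``sor`` the symmetric odds-ratio strand test; ``inbreeding_coeff`` is
    1 - observed/expected heterozygotes among diploid called samples (``None``
    when no diploid sample is called).  ``extra`` carries pass-through
    annotations (e.g. alignment-derived MQ) supplied from outside.
    """

    qd: float
    dp: int
    fs: float
    sor: float
    inbreeding_coeff: float | None
    het_count: int
    hom_alt_count: int
    extra: dict[str, float] = field(default_factory=dict)

    def value(self, name: str) -> float | None:
        lname = name.lower()
        if lname in ("qd", "dp", "fs", "sor"):
            return getattr(self, lname)
        if lname in ("inbreedingcoeff", "inbreeding_coeff"):
            return self.inbreeding_coeff
        if name in self.extra:
            return self.extra[name]
        raise FilterConfigError(f"unknown annotation {name!r}")


@dataclass
class VariantSite:
    """A joint-genotyped site across the cohort.

    ``genotypes`` maps every cohort sample to an allele-index tuple in the
    merged allele indexing (0 = ref) or ``None`` for a no-call.  Pooled
    per-allele strand counts and depth sums are retained for annotation.
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, tuple[int, ...] | None]
    qual: float = 0.0
    depth_sum: int = 0
    alt_depth_sum: int = 0
    strand: tuple[tuple[int, int], ...] = ()
    annotations: SiteAnnotations | None = None
    filter: str = "PASS"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def signature(self) -> tuple:
        """Order-independent call signature used for overlap reconciliation:
        reference, alt set, and the full genotype vector expressed as allele
        strings so that allele reordering between runs cannot masquerade as
        discordance."""
        alleles = (self.ref, *self.alts)
        gts = tuple(
            (s, None if g is None else tuple(sorted(alleles[a] for a in g)))
            for s, g in sorted(self.genotypes.items())
        )
        return (self.ref, frozenset(self.alts), gts)

    def summary(self) -> str:
        called = sum(1 for g in self.genotypes.values() if g is not None)
        return f"{self.ref}>{','.join(self.alts)} called={called}"


@dataclass
class DiscordanceRecord:
    contig: str
    pos: int
    summary_a: str
    summary_b: str


@dataclass
class DiscordanceReport:
    removed: list[DiscordanceRecord] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.removed)

    def extend(self, other: "DiscordanceReport") -> None:
        self.removed.extend(other.removed)

    def to_rows(self) -> list[dict]:
        return [
            {"contig": r.contig, "pos": r.pos, "chunk_a": r.summary_a, "chunk_b": r.summary_b}
            for r in self.removed
        ]


@dataclass
class PanelEntry:
    """One row of the allele-frequency panel: AC/AN/AF per ALT at a site."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    ac: tuple[int, ...]
    an: int
    af: tuple[float, ...]
    multiallelic: bool = False
    filter: str = "PASS"

    def __post_init__(self) -> None:
        if sum(self.ac) > self.an:
            raise ValueError(f"{self.contig}:{self.pos}: sum(AC) exceeds AN")
        if any(not 0.0 <= f <= 1.0 for f in self.af):
            raise ValueError(f"{self.contig}:{self.pos}: AF outside [0, 1]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


def diploid_everywhere(sample: str, contig: str, pos: int) -> int:
    """Ploidy map for purely autosomal cohorts."""
    return 2


def _argmax_genotype(rec: SampleSiteRecord) -> tuple[int, ...] | None:
    """Most likely genotype under the record's own allele indexing.

    Uses the PL vector when present (ties broken toward the lower genotype
    index); otherwise trusts the stated GT.
    """
    if rec.likelihoods is None:
        return rec.genotype
    order = genotype_order(rec.ploidy, 1 + len(rec.alts))
    best = min(range(len(rec.likelihoods)), key=lambda i: (rec.likelihoods[i], i))
    return order[best]


def slice_records(records: Sequence[SampleSiteRecord], region: Region) -> Sequence[SampleSiteRecord]:
    """Records of one contig-sorted sample list falling inside a region."""
    positions = [r.pos for r in records]
    lo = bisect.bisect_left(positions, region.start)
    hi = bisect.bisect_right(positions, region.end)
    return records[lo:hi]


def joint_genotype_region(
    records_by_sample: Mapping[str, Sequence[SampleSiteRecord]],
    region: Region,
    ploidy_map: PloidyMapFn = diploid_everywhere,
) -> list[VariantSite]:
    """Aggregate per-sample records inside a region into cohort variant sites.

    A site is emitted wherever at least one sample's most likely genotype
    carries an alternative allele.  Merged alt alleles are ordered by pooled
    allele depth (descending, ties by allele string); samples without a
    record at a position are no-calls at the ploidy the map resolves.
    """
    by_pos: dict[int, list[SampleSiteRecord]] = {}
    for sample, records in records_by_sample.items():
        for rec in slice_records(records, region):
            if rec.contig != region.contig:
                continue
            expected = ploidy_map(sample, rec.contig, rec.pos)
            if rec.ploidy != expected:
                raise PloidyConflictError(
                    f"sample {rec.sample} at {rec.contig}:{rec.pos}: record ploidy "
                    f"{rec.ploidy} contradicts ploidy map ({expected})"
                )
            by_pos.setdefault(rec.pos, []).append(rec)

    all_samples = list(records_by_sample)
    sites: list[VariantSite] = []
    for pos in sorted(by_pos):
        recs = by_pos[pos]
        ref = recs[0].ref
        if any(r.ref != ref for r in recs):
            raise ValueError(f"{region.contig}:{pos}: inconsistent REF across samples")

        calls: dict[str, tuple[tuple[int, ...] | None, SampleSiteRecord]] = {}
        pooled_ad: dict[str, int] = {}
        for rec in recs:
            gt = _argmax_genotype(rec)
            calls[rec.sample] = (gt, rec)
            if rec.allele_depths is not None:
                for ai, alt in enumerate(rec.alts, start=1):
                    if ai < len(rec.allele_depths):
                        pooled_ad[alt] = pooled_ad.get(alt, 0) + int(rec.allele_depths[ai])

        # alleles actually presented by at least one call
        presented: set[str] = set()
        for gt, rec in calls.values():
            if gt is None:
                continue
            for a in gt:
                if a > 0:
                    presented.add(rec.alts[a - 1])
        if not presented:
            continue

        merged_alts = tuple(
            sorted(presented, key=lambda a: (-pooled_ad.get(a, 0), a))
        )
        alt_index = {a: i + 1 for i, a in enumerate(merged_alts)}

        genotypes: dict[str, tuple[int, ...] | None] = {}
        qual = 0.0
        depth_sum = 0
        alt_depth_sum = 0
        strand = [[0, 0] for _ in range(1 + len(merged_alts))]
        for sample in all_samples:
            if sample not in calls:
                genotypes[sample] = None
                continue
            gt, rec = calls[sample]
            if gt is None:
                genotypes[sample] = None
            else:
                genotypes[sample] = tuple(
                    0 if a == 0 else alt_index[rec.alts[a - 1]] for a in gt
                )
            if rec.depth is not None:
                depth_sum += rec.depth
            carries_alt = gt is not None and any(a > 0 for a in gt)
            if carries_alt:
                if rec.depth is not None:
                    alt_depth_sum += rec.depth
                if rec.likelihoods is not None and len(rec.likelihoods) > 1:
                    srt = sorted(rec.likelihoods)
                    qual += min(srt[1] - srt[0], QUAL_CAP_PER_SAMPLE)
            if rec.strand_counts is not None:
                for ai, (f, r) in enumerate(rec.strand_counts):
                    allele = ref if ai == 0 else rec.alts[ai - 1]
                    mi = 0 if ai == 0 else alt_index.get(allele)
                    if mi is not None:
                        strand[mi][0] += f
                        strand[mi][1] += r

        sites.append(
            VariantSite(
                contig=region.contig, pos=pos, ref=ref, alts=merged_alts,
                genotypes=genotypes, qual=qual, depth_sum=depth_sum,
                alt_depth_sum=alt_depth_sum,
                strand=tuple((f, r) for f, r in strand),
            )
        )
    return sites


def reconcile_overlaps(
    sites_a: Sequence[VariantSite],
    sites_b: Sequence[VariantSite],
    overlap: Region,
) -> tuple[list[VariantSite], DiscordanceReport]:
    """Cross-check two chunk call sets over their shared overlap region.

    Sites inside the overlap must agree between the chunks (same reference,
    alt set and full genotype vector) to be kept; a disagreement — or a site
    called in only one chunk — is removed from the panel and reported.
    Sites outside the overlap pass through untouched.
    """
    report = DiscordanceReport()
    out: list[VariantSite] = []
    in_a = {s.pos: s for s in sites_a if overlap.contains(s.contig, s.pos)}
    in_b = {s.pos: s for s in sites_b if overlap.contains(s.contig, s.pos)}
    out.extend(s for s in sites_a if not overlap.contains(s.contig, s.pos))
    out.extend(s for s in sites_b if not overlap.contains(s.contig, s.pos))

    for pos in sorted(set(in_a) | set(in_b)):
        a, b = in_a.get(pos), in_b.get(pos)
        if a is not None and b is not None and a.signature() == b.signature():
            out.append(a)
        else:
            report.removed.append(
                DiscordanceRecord(
                    contig=overlap.contig, pos=pos,
                    summary_a=a.summary() if a else "absent",
                    summary_b=b.summary() if b else "absent",
                )
            )
    out.sort(key=lambda s: s.pos)
    return out, report


def run_chunked(
    records_by_sample: Mapping[str, Sequence[SampleSiteRecord]],
    contig: Contig,
    chunk_size: int,
    overlap: int,
    ploidy_map: PloidyMapFn = diploid_everywhere,
    caller: Callable[..., list[VariantSite]] | None = None,
) -> tuple[list[VariantSite], DiscordanceReport]:
    """Joint-genotype a contig in overlapping chunks and merge the results.

    Equivalent, for a deterministic caller, to a single pass over the whole
    contig; the returned report lists every overlap-zone disagreement that
    was removed.  ``caller`` exists so tests can inject perturbed chunk
    callers; it defaults to :func:`joint_genotype_region`.
    """
    call = caller or joint_genotype_region
    regions = partition_contig_named(contig, chunk_size, overlap)
    merged: list[VariantSite] | None = None
    prev_region: Region | None = None
    report = DiscordanceReport()
    for region in regions:
        chunk_sites = call(records_by_sample, region, ploidy_map)
        if merged is None:
            merged = chunk_sites
        else:
            assert prev_region is not None
            ov = Region(contig.name, region.start, prev_region.end)
            merged, rep = reconcile_overlaps(merged, chunk_sites, ov)
            report.extend(rep)
        prev_region = region
    merged = merged or []
    merged.sort(key=lambda s: s.pos)
    deduped: list[VariantSite] = []
    for s in merged:
        if deduped and deduped[-1].pos == s.pos:
            continue
        deduped.append(s)
    return deduped, report


# ---------------------------------------------------------------------------
# Site annotations
# ---------------------------------------------------------------------------


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p on a 2x2 table.

    Sums, over the hypergeometric distribution fixed by the margins, the
    probabilities of all tables no more likely than the observed one (the
    standard definition, with the customary 1+1e-7 relative slack at the
    inclusion boundary; not mid-p).
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    lg = gammaln
    logpmf = (
        lg(row1 + 1) - lg(support + 1) - lg(row1 - support + 1)
        + lg(n - row1 + 1) - lg(col1 - support + 1) - lg(n - row1 - col1 + support + 1)
        - (lg(n + 1) - lg(col1 + 1) - lg(n - col1 + 1))
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[a - support[0]]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def compute_site_annotations(site: VariantSite) -> SiteAnnotations:
    """QD, DP, FS, SOR and the inbreeding coefficient for one site.

    FS pools all alternative alleles into a single ref-vs-alt 2x2 strand
    table; SOR follows the symmetric odds-ratio form with +1 pseudocounts.
    The inbreeding coefficient compares observed to Hardy-Weinberg-expected
    heterozygote counts among diploid called samples and is ``None`` when no
    diploid sample is called.
    """
    ref_f, ref_r = site.strand[0] if site.strand else (0, 0)
    alt_f = sum(f for f, _ in site.strand[1:])
    alt_r = sum(r for _, r in site.strand[1:])

    p_fisher = fisher_exact_two_sided([[ref_f, ref_r], [alt_f, alt_r]])
    fs = max(0.0, -10.0 * math.log10(max(p_fisher, 1e-300)))

    rf, rr, af_, ar = ref_f + 1, ref_r + 1, alt_f + 1, alt_r + 1
    ratio = (rf * ar) / (rr * af_)
    sor = (
        math.log(ratio + 1.0 / ratio)
        + math.log(min(rf, rr) / max(rf, rr))
        - math.log(min(af_, ar) / max(af_, ar))
    )

    qd = site.qual / site.alt_depth_sum if site.alt_depth_sum > 0 else 0.0

    het = 0
    hom_alt = 0
    n_diploid = 0
    alt_alleles = 0
    total_alleles = 0
    for gt in site.genotypes.values():
        if gt is None:
            continue
        if len(gt) == 2:
            n_diploid += 1
            if gt[0] != gt[1]:
                het += 1
            elif gt[0] != 0:
                hom_alt += 1
            alt_alleles += sum(1 for a in gt if a != 0)
            total_alleles += 2
        elif gt[0] != 0:
            hom_alt += 1
    if n_diploid > 0 and total_alleles > 0:
        p = alt_alleles / total_alleles
        expected_het = 2.0 * p * (1.0 - p) * n_diploid
        inbreeding = 1.0 - het / expected_het if expected_het > 0 else 0.0
    else:
        inbreeding = None

    return SiteAnnotations(
        qd=qd, dp=site.depth_sum, fs=fs, sor=sor,
        inbreeding_coeff=inbreeding, het_count=het, hom_alt_count=hom_alt,
    )


def annotate_sites(sites: Iterable[VariantSite]) -> None:
    for s in sites:
        s.annotations = compute_site_annotations(s)


# Direction each annotation is filtered in: "max" fails above the threshold,
# "min" fails below it (GATK hard-filter conventions).
FILTER_DIRECTIONS = {
    "QD": "min", "DP": "min", "FS": "max", "SOR": "max",
    "InbreedingCoeff": "min", "MQ": "min", "MQRankSum": "min",
    "ReadPosRankSum": "min",
}


def apply_hard_filters(
    sites: Sequence[VariantSite],
    snv_thresholds: Mapping[str, float] | None = None,
    indel_thresholds: Mapping[str, float] | None = None,
) -> None:
    """Set PASS / named-filter status from per-annotation hard thresholds.

    SNV and INDEL threshold sets are independent; a site fails with the names
    of every violated annotation (semicolon-joined).  Referencing an unknown
    annotation raises :class:`FilterConfigError`; an annotation that is
    undefined for a particular site (e.g. the inbreeding coefficient with no
    diploid calls) is not evaluated there.
    """
    snv_thresholds = dict(snv_thresholds or {})
    indel_thresholds = dict(indel_thresholds or {})
    for name in (*snv_thresholds, *indel_thresholds):
        if name not in FILTER_DIRECTIONS:
            raise FilterConfigError(f"unknown annotation {name!r} in threshold set")
    for site in sites:
        if site.annotations is None:
            site.annotations = compute_site_annotations(site)
        thresholds = snv_thresholds if site.is_snv else indel_thresholds
        failed = []
        for name, cut in thresholds.items():
            try:
                val = site.annotations.value(name)
            except FilterConfigError:
                raise
            if val is None:
                continue
            if FILTER_DIRECTIONS[name] == "max" and val > cut:
                failed.append(name)
            elif FILTER_DIRECTIONS[name] == "min" and val < cut:
                failed.append(name)
        site.filter = ";".join(sorted(failed)) if failed else "PASS"


# ---------------------------------------------------------------------------
# Frequencies, Ts/Tv, accessibility
# ---------------------------------------------------------------------------


def compute_frequencies(
    sites: Sequence[VariantSite],
    ploidy_map: PloidyMapFn = diploid_everywhere,
) -> list[PanelEntry]:
    """Ploidy-aware AC/AN/AF per site.

    AN sums the resolved ploidy over called samples only (no-calls drop out
    entirely); AC counts alternative allele occurrences per ALT.  Multiallelic
    sites are retained as single entries with per-ALT vectors.
    """
    entries: list[PanelEntry] = []
    for site in sites:
        an = 0
        ac = [0] * len(site.alts)
        for sample, gt in site.genotypes.items():
            if gt is None:
                continue
            expected = ploidy_map(sample, site.contig, site.pos)
            if len(gt) != expected:
                raise PloidyConflictError(
                    f"sample {sample} at {site.contig}:{site.pos}: genotype arity "
                    f"{len(gt)} vs resolved ploidy {expected}"
                )
            an += len(gt)
            for a in gt:
                if a > 0:
                    ac[a - 1] += 1
        af = tuple(c / an if an > 0 else 0.0 for c in ac)
        entries.append(
            PanelEntry(
                contig=site.contig, pos=site.pos, ref=site.ref, alts=site.alts,
                ac=tuple(ac), an=an, af=af,
                multiallelic=len(site.alts) > 1, filter=site.filter,
            )
        )
    return entries


def _count_tstv(pairs: Iterable[tuple[str, str]]) -> tuple[int, int]:
    ts = tv = 0
    for ref, alt in pairs:
        if len(ref) != 1 or len(alt) != 1:
            continue
        if ref == alt or ref not in "ACGT" or alt not in "ACGT":
            continue
        if (ref, alt) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    return ts, tv


def tstv(entries: Sequence[PanelEntry], group_by: Callable[[PanelEntry], str] | None = None):
    """Transition/transversion ratio, per group when a grouping is given.

    Each ALT of a multiallelic SNV contributes separately.  The ratio is
    ``None`` (undefined, not 0) for groups without transversions.  Returns a
    float (or None) without grouping, else a dict group -> ratio.
    """
    if group_by is None:
        ts, tv = _count_tstv(
            (e.ref, a) for e in entries if e.is_snv for a in e.alts
        )
        return ts / tv if tv else None
    groups: dict[str, list[tuple[str, str]]] = {}
    for e in entries:
        if not e.is_snv:
            continue
        g = group_by(e)
        groups.setdefault(g, []).extend((e.ref, a) for a in e.alts)
    out = {}
    for g, pairs in groups.items():
        ts, tv = _count_tstv(pairs)
        out[g] = ts / tv if tv else None
    return out


def per_sample_tstv(
    sites: Sequence[VariantSite],
    sex: Mapping[str, str] | None = None,
    x_contigs: frozenset[str] | set[str] = frozenset({"X"}),
) -> dict[str, float | None]:
    """Per-sample Ts/Tv over the alt alleles each sample carries.

    On X-chromosome contigs only female samples contribute, matching the
    convention that male hemizygous X calls are excluded from per-sample
    X Ts/Tv statistics.
    """
    pairs: dict[str, list[tuple[str, str]]] = {}
    for site in sites:
        if not site.is_snv:
            continue
        on_x = site.contig in x_contigs
        for sample, gt in site.genotypes.items():
            if gt is None:
                continue
            if on_x and sex is not None and sex.get(sample) != "female":
                continue
            for a in set(gt):
                if a > 0:
                    pairs.setdefault(sample, []).append((site.ref, site.alts[a - 1]))
    out: dict[str, float | None] = {}
    for sample, pp in pairs.items():
        ts, tv = _count_tstv(pp)
        out[sample] = ts / tv if tv else None
    return out


def mean_depth_track(
    all_reads: np.ndarray, mapq20: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-base mean depth over samples under both MAPQ policies.

    Input arrays are (n_samples, length); returns (mean_all, mean_mapq20,
    difference).  An elevated difference marks bases where reads multi-map
    (MAPQ 0) and accessibility is doubtful.
    """
    all_reads = np.asarray(all_reads, dtype=float)
    mapq20 = np.asarray(mapq20, dtype=float)
    if all_reads.shape != mapq20.shape:
        raise ValueError(
            f"depth track spans differ: {all_reads.shape} vs {mapq20.shape}"
        )
    mean_all = all_reads.mean(axis=0)
    mean_q20 = mapq20.mean(axis=0)
    return mean_all, mean_q20, mean_all - mean_q20
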