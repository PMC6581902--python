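"""Synthetic cohort generator.

Builds, from a single seed, a miniature whole-genome-sequencing cohort with
the statistical structure the panel pipeline assumes: Beta-distributed
population allele frequencies, Hardy-Weinberg genotypes, sex-linked ploidy
(diploid female X, haploid male non-PAR X, haploid mitochondria), Mendelian
relatives and duplicates, per-genotype phred likelihoods, negative-binomial
read depth with a MAPQ-0 mixture, binomial strand splits, and an array-style
genotype table with its own error and no-call processes.

Everything is deterministic in the spec seed.  Distinct subsystems (genotype
errors, depths, likelihood jitter, the recalibration-like likelihood
perturbation, array errors) draw from independent seeded streams, so toggling
one never changes the output of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import (
    Contig,
    GRCH37_X_REGIONS,
    Region,
    SampleSiteRecord,
    THREE_PAR,
    TWO_PAR,
    XRegionMap,
    genotype_order,
    write_sample_vcf,
)

_BASES = ("A", "C", "G", "T")

RELATIONSHIPS = ("duplicate", "parent_offspring", "full_sibling")


class CohortSpecError(ValueError):
    """The cohort specification is internally inconsistent."""


def scaled_x_region_map(factor: int = 100, contig: str = "X", mode: str = TWO_PAR) -> XRegionMap:
    """PAR1/XTR/PAR2 at 1/``factor`` of their GRCh37 coordinates.

    Keeps the relative layout of the named regions while letting a desk-scale
    X contig of ~1.6 Mb (factor 100) run in seconds.
    """
    def scale(bounds: tuple[int, int]) -> tuple[int, int]:
        s, e = bounds
        return ((s - 1) // factor + 1, max((s - 1) // factor + 1, e // factor))

    return XRegionMap(
        par1=Region(contig, *scale(GRCH37_X_REGIONS["par1"])),
        xtr=Region(contig, *scale(GRCH37_X_REGIONS["xtr"])),
        par2=Region(contig, *scale(GRCH37_X_REGIONS["par2"])),
        mode=mode,
    )


def scaled_x_length(factor: int = 100) -> int:
    return GRCH37_X_REGIONS["par2"][1] // factor + 100


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``contig_plan`` lists (category, length) pairs; contigs are named
    "1", "2", ... for autosomes, "X" and "MT" for the others.  ``n_sites``
    applies per contig.  The relative plan lists (relationship, count) with
    relationships drawn from {duplicate, parent_offspring, full_sibling};
    derived samples occupy the tail of the sample list.
    """

    n_samples: int = 50
    sex_ratio: float = 0.5
    contig_plan: tuple[tuple[str, int], ...] = (("autosome", 1_000_000),)
    n_sites: int = 500
    af_alpha: float = 0.8
    af_beta: float = 0.8
    genotype_error: float = 0.001
    array_marker_fraction: float = 0.5
    array_no_call_rate: float = 0.01
    array_error: float | None = None  # defaults to genotype_error
    relative_plan: tuple[tuple[str, int], ...] = ()
    depth_mean: float = 30.0
    depth_overdispersion: float = 10.0
    mapq0_fraction: float = 0.02
    repeat_mapq0_fraction: float = 0.6
    repeat_fraction: float = 0.1
    multiallelic_fraction: float = 0.0
    male_xtr_diploid: bool = True
    x_scale_factor: int = 100
    pl_scale: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sex_ratio", "genotype_error", "array_marker_fraction",
            "array_no_call_rate", "mapq0_fraction", "repeat_mapq0_fraction",
            "repeat_fraction", "multiallelic_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortSpecError(f"{name} must be in [0, 1], got {v}")
        if self.n_samples < 2:
            raise CohortSpecError("need at least 2 samples")
        if any(length < 100 for _, length in self.contig_plan):
            raise CohortSpecError("contig lengths must be >= 100")
        for rel, count in self.relative_plan:
            if rel not in RELATIONSHIPS:
                raise CohortSpecError(f"unknown relationship {rel!r}")
            if count < 0:
                raise CohortSpecError("relationship counts must be >= 0")


@dataclass(frozen=True)
class SiteTruth:
    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    afs: tuple[float, ...]  # one per alt; ref frequency is 1 - sum


@dataclass
class CohortTruth:
    """True genotypes, sexes and pedigree for one simulated cohort.

    ``genotypes[contig]`` has shape (n_sites, n_samples, 2) with allele
    indices (0 = ref); the second slot is -9 wherever the sample is haploid
    at that site.
    """

    spec: CohortSpec
    samples: list[str]
    sex: dict[str, str]
    pedigree: list[tuple[str, tuple[str, ...]]]
    contigs: list[Contig]
    x_map: XRegionMap | None
    sites: dict[str, list[SiteTruth]]
    genotypes: dict[str, np.ndarray]
    repeat_regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def contig_category(self, name: str) -> str:
        for c in self.contigs:
            if c.name == name:
                return c.category
        raise KeyError(name)

    def male_diploid_x(self, pos: int) -> bool:
        """Whether the simulated truth treats males as diploid at this X position."""
        assert self.x_map is not None
        region = self.x_map.with_mode(THREE_PAR).classify(pos)
        if region in ("PAR1", "PAR2"):
            return True
        return region == "XTR" and self.spec.male_xtr_diploid

    def ploidy(self, sample: str, contig: str, pos: int) -> int:
        cat = self.contig_category(contig)
        if cat == "mito":
            return 1
        if cat == "chrX" and self.sex[sample] == "male":
            return 2 if self.male_diploid_x(pos) else 1
        return 2

    def true_af(self, contig: str) -> np.ndarray:
        """Realised alt-allele frequency (first alt) per site over the cohort."""
        g = self.genotypes[contig]
        called = g >= 0
        return (g == 1).sum(axis=(1, 2)) / np.maximum(called.sum(axis=(1, 2)), 1)


def _derived_count(plan: Sequence[tuple[str, int]]) -> int:
    total = 0
    for rel, count in plan:
        total += count * (2 if rel == "full_sibling" else 1)
    return total


def _plan_contigs(spec: CohortSpec) -> tuple[list[Contig], XRegionMap | None]:
    contigs: list[Contig] = []
    x_map = None
    auto_i = 0
    for category, length in spec.contig_plan:
        if category == "autosome":
            auto_i += 1
            contigs.append(Contig(str(auto_i), length, category="autosome"))
        elif category == "chrX":
            x_map = scaled_x_region_map(spec.x_scale_factor)
            if length < x_map.par2.end:
                raise CohortSpecError(
                    f"chrX length {length} shorter than scaled PAR2 end {x_map.par2.end}"
                )
            contigs.append(Contig("X", length, category="chrX"))
        elif category == "chrY":
            contigs.append(Contig("Y", length, category="chrY"))
        elif category == "mito":
            contigs.append(Contig("MT", length, circular=True, category="mito"))
        else:
            raise CohortSpecError(f"unknown contig category {category!r}")
    return contigs, x_map


def _sample_positions(rng: np.random.Generator, contig: Contig,
                      x_map: XRegionMap | None, n_sites: int) -> np.ndarray:
    """Distinct 1-based site positions; X sites are stratified over the named
    regions (20% each in PAR1/XTR/PAR2, 40% non-PAR) so every ploidy context
    is exercised even at small site counts."""
    if contig.category != "chrX" or x_map is None:
        return np.sort(rng.choice(contig.length, size=min(n_sites, contig.length),
                                  replace=False) + 1)
    shares = [(x_map.par1, 0.2), (x_map.xtr, 0.2), (x_map.par2, 0.2)]
    chosen: list[np.ndarray] = []
    n_named = 0
    for region, share in shares:
        k = min(int(round(n_sites * share)), len(region))
        n_named += k
        offs = rng.choice(len(region), size=k, replace=False)
        chosen.append(region.start + offs)
    # remaining sites fall outside the named regions
    need = n_sites - n_named
    named = set(np.concatenate(chosen).tolist())
    pool: set[int] = set()
    while len(pool) < need:
        cand = rng.integers(1, contig.length + 1, size=4 * need)
        for p in cand.tolist():
            if p in named or p in pool:
                continue
            r = x_map.with_mode(THREE_PAR).classify(p)
            if r == "NONPAR":
                pool.add(p)
            if len(pool) >= need:
                break
    chosen.append(np.fromiter(pool, dtype=np.int64))
    return np.sort(np.concatenate(chosen))


def simulate_truth(spec: CohortSpec) -> CohortTruth:
    """Draw the true cohort: sites, allele frequencies, sexes, genotypes.

    Founder genotypes are independent Hardy-Weinberg draws from each site's
    allele frequencies (two draws in diploid contexts, one in haploid).
    Children receive one allele from each parent (Mendelian transmission,
    sex-aware on X and maternal on MT); duplicates are exact copies.
    """
    rng = np.random.default_rng([spec.seed, 0])
    contigs, x_map = _plan_contigs(spec)

    n = spec.n_samples
    n_derived = _derived_count(spec.relative_plan)
    n_founders = n - n_derived
    instances: list[tuple[str, int]] = []  # (relationship, instance index)
    parents_needed = 0
    for rel, count in spec.relative_plan:
        for _ in range(count):
            instances.append((rel, len(instances)))
            parents_needed = max(parents_needed, 2 if rel != "duplicate" else 1)
    if n_founders < max(2, parents_needed):
        raise CohortSpecError(
            f"relative plan needs more founders than available "
            f"({n_founders} founders for {n} samples)"
        )

    samples = [f"S{i:04d}" for i in range(n)]
    founders = samples[:n_founders]

    # pedigree wiring: parents/sources chosen round-robin among founders
    pedigree: list[tuple[str, tuple[str, ...]]] = []
    sex: dict[str, str] = {}
    next_derived = n_founders
    fi = 0
    for rel, _ in instances:
        if rel == "duplicate":
            src = founders[fi % n_founders]; fi += 1
            dup = samples[next_derived]; next_derived += 1
            pedigree.append(("duplicate", (src, dup)))
        else:
            mother = founders[fi % n_founders]; fi += 1
            father = founders[fi % n_founders]; fi += 1
            sex[mother] = "female"
            sex[father] = "male"
            kids = 1 if rel == "parent_offspring" else 2
            members = [mother, father]
            for _ in range(kids):
                child = samples[next_derived]; next_derived += 1
                members.append(child)
            pedigree.append((rel, tuple(members)))

    for s in samples:
        if s not in sex:
            sex[s] = "female" if rng.random() < spec.sex_ratio else "male"
    for rel, members in pedigree:
        if rel == "duplicate":
            sex[members[1]] = sex[members[0]]

    sexes = np.array([sex[s] == "male" for s in samples])  # True = male

    sites: dict[str, list[SiteTruth]] = {}
    genos: dict[str, np.ndarray] = {}
    repeats: dict[str, list[tuple[int, int]]] = {}

    for contig in contigs:
        if contig.category == "chrY":
            sites[contig.name] = []
            genos[contig.name] = np.empty((0, n, 2), dtype=np.int8)
            continue
        positions = _sample_positions(rng, contig, x_map, spec.n_sites)
        site_list: list[SiteTruth] = []
        g = np.full((len(positions), n, 2), -9, dtype=np.int8)
        for si, pos in enumerate(positions.tolist()):
            ref = _BASES[rng.integers(4)]
            alts = [_BASES[int(rng.choice([b for b in range(4) if _BASES[b] != ref]))]]
            afs = [float(rng.beta(spec.af_alpha, spec.af_beta))]
            if rng.random() < spec.multiallelic_fraction:
                second = rng.choice([b for b in _BASES if b != ref and b not in alts])
                alts.append(str(second))
                afs.append(float(rng.beta(spec.af_alpha, spec.af_beta)) * (1 - afs[0]) * 0.5)
            probs = np.array([1.0 - sum(afs)] + afs)
            probs = np.clip(probs, 1e-9, None)
            probs /= probs.sum()
            draw = rng.choice(len(probs), size=(n, 2), p=probs).astype(np.int8)
            g[si] = draw
            # haploid contexts keep only the first draw
            if contig.category == "mito":
                g[si, :, 1] = -9
            elif contig.category == "chrX":
                assert x_map is not None
                diploid_male = (
                    x_map.with_mode(THREE_PAR).classify(int(pos)) in ("PAR1", "PAR2")
                    or (spec.male_xtr_diploid
                        and x_map.with_mode(THREE_PAR).classify(int(pos)) == "XTR")
                )
                if not diploid_male:
                    g[si, sexes, 1] = -9
            site_list.append(SiteTruth(contig.name, int(pos), ref, tuple(alts), tuple(afs)))
        sites[contig.name] = site_list
        genos[contig.name] = g
        if spec.repeat_fraction > 0:
            span = int(contig.length * spec.repeat_fraction)
            mid = contig.length // 2
            repeats[contig.name] = [(mid - span // 2 + 1, mid - span // 2 + span)]
        else:
            repeats[contig.name] = []

    truth = CohortTruth(
        spec=spec, samples=samples, sex=sex, pedigree=pedigree, contigs=contigs,
        x_map=x_map, sites=sites, genotypes=genos, repeat_regions=repeats,
    )
    _apply_pedigree(truth, rng)
    return truth


def _pick(rng: np.random.Generator, alleles: np.ndarray) -> int:
    """One transmitted allele from a parent's (a1, a2) pair; haploid -> a1."""
    if alleles[1] < 0:
        return int(alleles[0])
    return int(alleles[rng.integers(2)])


def _apply_pedigree(truth: CohortTruth, rng: np.random.Generator) -> None:
    spec = truth.spec
    idx = {s: i for i, s in enumerate(truth.samples)}
    for rel, members in truth.pedigree:
        if rel == "duplicate":
            src, dup = members
            for name in truth.genotypes:
                truth.genotypes[name][:, idx[dup], :] = truth.genotypes[name][:, idx[src], :]
            continue
        mother, father = members[0], members[1]
        for child in members[2:]:
            ci, mi, fi = idx[child], idx[mother], idx[father]
            child_male = truth.sex[child] == "male"
            for contig in truth.contigs:
                if contig.name not in truth.genotypes:
                    continue
                g = truth.genotypes[contig.name]
                if g.shape[0] == 0:
                    continue
                cat = contig.category
                for si, site in enumerate(truth.sites[contig.name]):
                    if cat == "mito":
                        g[si, ci] = (g[si, mi, 0], -9)
                        continue
                    m_allele = _pick(rng, g[si, mi])
                    if cat == "autosome":
                        g[si, ci] = sorted((m_allele, _pick(rng, g[si, fi])))
                    elif cat == "chrX":
                        if child_male and not truth.male_diploid_x(site.pos):
                            g[si, ci] = (m_allele, -9)
                        elif child_male:
                            # male child in a pseudoautosomal context: paternal
                            # allele recombines in from the Y-borne PAR copy
                            g[si, ci] = sorted((m_allele, _pick(rng, g[si, fi])))
                        else:
                            f_allele = _pick(rng, g[si, fi])
                            g[si, ci] = sorted((m_allele, f_allele))


# ---------------------------------------------------------------------------
# Observation layer: sequencing-like records with error, depth and strand
# ---------------------------------------------------------------------------


def _flip_diploid(gt: tuple[int, int], n_alleles: int, r: float) -> tuple[int, int]:
    """Symmetric single-step genotype error: hom <-> het."""
    a, b = gt
    if a == b:  # hom -> het with a uniformly chosen other allele
        others = [x for x in range(n_alleles) if x != a]
        other = others[int(r * len(others)) % len(others)]
        return tuple(sorted((a, other)))  # type: ignore[return-value]
    # het -> hom on a uniformly chosen side
    return (a, a) if r < 0.5 else (b, b)


def observe(truth: CohortTruth, *, bqsr_like: bool = False,
            stream: int = 1) -> dict[str, list[SampleSiteRecord]]:
    """Produce per-sample site records (GT/PL/DP/AD/strand) from the truth.

    The observed genotype is the true genotype flipped with probability
    ``genotype_error`` using symmetric single-step flips.  PLs place 0 at the
    observed genotype and ``pl_scale`` plus small jitter elsewhere; the
    ``bqsr_like`` switch adds a further jitter to the non-minimal entries
    without ever moving the argmax, emulating a base-quality recalibration
    that leaves calls unchanged.  All randomness is seeded from the cohort
    seed plus ``stream``; two calls with the same arguments are identical.
    """
    spec = truth.spec
    rng_err = np.random.default_rng([spec.seed, stream, 1])
    rng_depth = np.random.default_rng([spec.seed, stream, 2])
    rng_pl = np.random.default_rng([spec.seed, stream, 3])
    rng_bqsr = np.random.default_rng([spec.seed, stream, 4])

    k = spec.depth_overdispersion
    p_nb = k / (k + spec.depth_mean)

    out: dict[str, list[SampleSiteRecord]] = {s: [] for s in truth.samples}
    for contig in truth.contigs:
        name = contig.name
        site_list = truth.sites.get(name, [])
        if not site_list:
            continue
        g = truth.genotypes[name]
        ns, n = g.shape[0], g.shape[1]
        flip = rng_err.random((ns, n)) < spec.genotype_error
        flip_aux = rng_err.random((ns, n))
        depth = rng_depth.negative_binomial(k, p_nb, size=(ns, n)).astype(np.int64) + 1
        het_split = rng_depth.binomial(depth, 0.5)
        jitter = rng_pl.integers(0, 10, size=(ns, n))
        bq = rng_bqsr.integers(1, 6, size=(ns, n)) if bqsr_like else None

        for si, site in enumerate(site_list):
            n_alleles = 1 + len(site.alts)
            orders = {
                pl: genotype_order(pl, n_alleles) for pl in (1, 2)
            }
            for xi, sample in enumerate(truth.samples):
                a1, a2 = int(g[si, xi, 0]), int(g[si, xi, 1])
                haploid = a2 < 0
                if haploid:
                    gt: tuple[int, ...] = (a1,)
                    if flip[si, xi]:
                        others = [x for x in range(n_alleles) if x != a1]
                        gt = (others[int(flip_aux[si, xi] * len(others)) % len(others)],)
                else:
                    gt = (min(a1, a2), max(a1, a2))
                    if flip[si, xi]:
                        gt = _flip_diploid(gt, n_alleles, float(flip_aux[si, xi]))
                order = orders[1 if haploid else 2]
                gt_index = order.index(gt)
                base = spec.pl_scale + int(jitter[si, xi])
                pls = [0 if i == gt_index else base + (i % 3) for i in range(len(order))]
                if bq is not None:
                    step = int(bq[si, xi])
                    pls = [0 if v == 0 else v + step for v in pls]
                dp = int(depth[si, xi])
                ad = [0] * n_alleles
                if haploid or gt[0] == gt[1]:
                    ad[gt[0]] = dp
                else:
                    n1 = int(het_split[si, xi])
                    ad[gt[0]] = n1
                    ad[gt[1]] = dp - n1
                strand = []
                for ai in range(n_alleles):
                    if ad[ai] == 0:
                        strand.append((0, 0))
                    else:
                        fwd = int(rng_depth.binomial(ad[ai], 0.5))
                        strand.append((fwd, ad[ai] - fwd))
                out[sample].append(
                    SampleSiteRecord(
                        sample=sample, contig=name, pos=site.pos, ref=site.ref,
                        alts=site.alts, genotype=gt, ploidy=1 if haploid else 2,
                        likelihoods=tuple(pls), depth=dp,
                        allele_depths=tuple(ad), strand_counts=tuple(strand),
                    )
                )
    return out


def emit_sample_vcfs(truth: CohortTruth, out_dir: str | Path, *,
                     bqsr_like: bool = False) -> dict[str, Path]:
    """Write one single-sample VCF per cohort member; returns sample -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = observe(truth, bqsr_like=bqsr_like)
    paths: dict[str, Path] = {}
    for sample, recs in records.items():
        path = out_dir / f"{sample}.vcf"
        write_sample_vcf(recs, truth.contigs, str(path))
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# Array genotypes
# ---------------------------------------------------------------------------

ARRAY_STATES = ("0/0", "0/1", "1/1", "NoCall")


def emit_array_genotypes(truth: CohortTruth, *, stream: int = 2):
    """Marker x sample genotype table emulating a SNP-array run.

    Markers are a random fraction of the biallelic autosomal/X sites; entries
    are the true genotypes passed through independent single-step error and
    no-call processes.  Haploid truth (male non-PAR X) is reported in the
    array's diploid vocabulary as the corresponding homozygote, as array
    callers do.  Returns a pandas DataFrame with columns contig, pos, ref,
    alt, then one column per sample.
    """
    import pandas as pd

    spec = truth.spec
    rng = np.random.default_rng([spec.seed, stream, 7])
    err = spec.genotype_error if spec.array_error is None else spec.array_error
    rows = []
    for contig in truth.contigs:
        if contig.category in ("mito", "chrY"):
            continue
        for si, site in enumerate(truth.sites.get(contig.name, [])):
            if len(site.alts) != 1:
                continue
            if rng.random() >= spec.array_marker_fraction:
                continue
            g = truth.genotypes[contig.name][si]
            row: dict[str, object] = {
                "contig": contig.name, "pos": site.pos,
                "ref": site.ref, "alt": site.alts[0],
            }
            for xi, sample in enumerate(truth.samples):
                a1, a2 = int(g[xi, 0]), int(g[xi, 1])
                if a2 < 0:
                    a2 = a1  # haploid rendered as homozygote
                dose = a1 + a2
                if rng.random() < err:
                    u = rng.random()
                    if dose in (0, 2):
                        dose = 1
                    else:
                        dose = 0 if u < 0.5 else 2
                state = ARRAY_STATES[dose]
                if rng.random() < spec.array_no_call_rate:
                    state = "NoCall"
                row[sample] = state
            rows.append(row)
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", *truth.samples])


# ---------------------------------------------------------------------------
# Depth tracks
# ---------------------------------------------------------------------------


@dataclass
class DepthTracks:
    """Per-sample per-base depth under two MAPQ policies (same shape arrays)."""

    contig: str
    all_reads: np.ndarray   # (n_samples, length)
    mapq20: np.ndarray      # (n_samples, length), elementwise <= all_reads
    repeat_regions: list[tuple[int, int]]


def _depth_scale(category: str, is_male: bool) -> float:
    if category == "chrY":
        return 0.5 if is_male else 0.02
    if category == "chrX":
        return 0.5 if is_male else 1.0
    return 1.0


def emit_depth_tracks(truth: CohortTruth, contig_names: Iterable[str] | None = None,
                      *, stream: int = 3) -> dict[str, DepthTracks]:
    """Per-base depth pairs (all reads vs MAPQ>=20) for the chosen contigs.

    Designated repeat regions receive an elevated MAPQ-0 read fraction, so the
    difference between the two tracks localises there — the signature used to
    flag likely multi-mapping in accessibility analysis.  Sex scales coverage
    on X and Y (males at half X depth, females at background Y depth).
    """
    spec = truth.spec
    rng = np.random.default_rng([spec.seed, stream, 11])
    wanted = set(contig_names) if contig_names is not None else {c.name for c in truth.contigs}
    out: dict[str, DepthTracks] = {}
    for contig in truth.contigs:
        if contig.name not in wanted:
            continue
        L = contig.length
        n = len(truth.samples)
        frac = np.full(L, spec.mapq0_fraction)
        for s, e in truth.repeat_regions.get(contig.name, []):
            frac[s - 1:e] = spec.repeat_mapq0_fraction
        all_reads = np.empty((n, L), dtype=np.int32)
        mapq20 = np.empty((n, L), dtype=np.int32)
        for xi, sample in enumerate(truth.samples):
            scale = _depth_scale(contig.category, truth.sex[sample] == "male")
            d = rng.poisson(spec.depth_mean * scale, size=L)
            keep = rng.binomial(d, 1.0 - frac)
            all_reads[xi] = d
            mapq20[xi] = keep
        out[contig.name] = DepthTracks(
            contig=contig.name, all_reads=all_reads, mapq20=mapq20,
            repeat_regions=list(truth.repeat_regions.get(contig.name, [])),
        )
    return out


def write_bedgraph(values: np.ndarray, contig: str, path: str | Path) -> None:
    """Write a per-base value vector as a run-length-collapsed BedGraph."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        start = 0
        cur = values[0]
        for i in range(1, len(values)):
            if values[i] != cur:
                fh.write(f"{contig}\t{start}\t{i}\t{cur:g}\n")
                start = i
                cur = values[i]
        fh.write(f"{contig}\t{start}\t{len(values)}\t{cur:g}\n")


def read_bedgraph(path: str | Path, length: int) -> np.ndarray:
    out = np.zeros(length)
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            _, s, e, v = line.split("\t")
            out[int(s):int(e)] = float(v)
    return out


def simulate_ibd_pair(
    freqs: np.ndarray, z: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Dosage vectors for one diploid pair with a prescribed IBD profile.

    ``z`` gives the probabilities of sharing 0/1/2 alleles identical by
    descent at a marker (e.g. (0.75, 0.25, 0) for third-degree relatives,
    expected PIHAT 0.125).  Non-shared alleles are fresh Hardy-Weinberg
    draws from ``freqs``.
    """
    freqs = np.asarray(freqs, dtype=float)
    m = len(freqs)
    if not np.isclose(sum(z), 1.0):
        raise ValueError("IBD state probabilities must sum to 1")
    a = (rng.random((m, 2)) < freqs[:, None]).astype(np.int8)
    state = rng.choice(3, size=m, p=np.asarray(z))
    b = (rng.random((m, 2)) < freqs[:, None]).astype(np.int8)
    shared = a[np.arange(m), rng.integers(2, size=m)]
    b[state == 1, 0] = shared[state == 1]
    b[state == 2] = a[state == 2]
    return a.sum(axis=1).astype(float), b.sum(axis=1).astype(float)


def simulate_divergent_cohorts(
    n_per_pop: int, n_sites: int, delta: float, seed: int,
    *, contig: str = "1",
):
    """Two subpopulations whose allele frequencies differ by ``delta``.

    Ancestral frequencies are uniform on (0.2, 0.8); each population shifts
    them by +/- delta/2 and draws Hardy-Weinberg genotypes.  Returns a
    GenotypeMatrix with samples labelled ``A*`` and ``B*`` plus the true
    population labels — the fixture for population-structure recovery checks.
    """
    from .structure_pca import GenotypeMatrix

    rng = np.random.default_rng([seed, 17])
    p_anc = rng.uniform(0.2, 0.8, n_sites)
    p1 = np.clip(p_anc + delta / 2.0, 0.01, 0.99)
    p2 = np.clip(p_anc - delta / 2.0, 0.01, 0.99)
    g1 = rng.binomial(2, p1[:, None], size=(n_sites, n_per_pop))
    g2 = rng.binomial(2, p2[:, None], size=(n_sites, n_per_pop))
    samples = [f"A{i:03d}" for i in range(n_per_pop)] + [f"B{i:03d}" for i in range(n_per_pop)]
    labels = np.array([0] * n_per_pop + [1] * n_per_pop)
    matrix = GenotypeMatrix(
        samples=samples,
        variants=[(contig, i + 1, "A", "G") for i in range(n_sites)],
        dosages=np.concatenate([g1, g2], axis=1).astype(float),
    )
    return matrix, labels


def truth_to_dosage(truth: CohortTruth, contig: str) -> np.ndarray:
    """(n_sites, n_samples) alt-dosage matrix for biallelic sites on a contig;
    haploid genotypes count their single allele (dose 0 or 1)."""
    g = truth.genotypes[contig]
    keep = [i for i, s in enumerate(truth.sites[contig]) if len(s.alts) == 1]
    g = g[keep]
    dose = (g == 1).sum(axis=2).astype(float)
    return dose
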