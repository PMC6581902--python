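"""X-chromosome region-aware calling and circular-mitochondria handling.

The X chromosome is genotyped under two conventions: TWO_PAR, where only
PAR1/PAR2 are treated as pseudoautosomal (diploid in males), and THREE_PAR,
where the X-transposed region (XTR) is treated that way too.  At full scale
the distinction is realised by remapping reads to an XTR-masked reference;
at record level we realise the same contrast by reclassifying XTR positions
in the ploidy map and collapsing male XTR evidence to haploid under TWO_PAR.

The mitochondrial genome is circular; variants are called on two
linearizations — the reference breakpoint and one shifted by 10,000 bases —
and merged so that positions near the reference breakpoint are taken from
the shifted call set, where they are far from any edge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .genome import (
    Contig,
    Region,
    SampleSiteRecord,
    THREE_PAR,
    TWO_PAR,
    XRegionMap,
)
from .joint_panel import (
    PloidyConflictError,
    VariantSite,
    joint_genotype_region,
)

MT_LENGTH = 16_569          # rCRS
MT_SHIFT = 10_000
DEFAULT_EDGE_MARGIN = 300   # ~ read-length scale


@dataclass(frozen=True)
class MtLinearization:
    length: int
    shift: int
    label: str  # "primary" | "shifted"

    def __post_init__(self) -> None:
        if not 0 < self.shift < self.length:
            raise ValueError("require 0 < shift < genome length")


@dataclass(frozen=True)
class PloidyMap:
    """Resolves (sample sex, contig category, position) to ploidy 1 or 2.

    Females are diploid everywhere on X; males are diploid only in the
    pseudoautosomal regions the mode recognises; everyone is haploid on the
    mitochondrial genome.
    """

    sex: Mapping[str, str]
    x_map: XRegionMap | None
    categories: Mapping[str, str]  # contig name -> category
    mode: str = TWO_PAR

    def ploidy(self, sample: str, contig: str, pos: int) -> int:
        cat = self.categories.get(contig, "autosome")
        if cat == "mito":
            return 1
        if cat == "chrX" and self.sex.get(sample) == "male":
            assert self.x_map is not None, "X ploidy needs an X region map"
            region = self.x_map.with_mode(self.mode).classify(pos)
            return 2 if region in ("PAR1", "XTR", "PAR2") else 1
        if cat == "chrY":
            return 1
        return 2

    def __call__(self, sample: str, contig: str, pos: int) -> int:
        return self.ploidy(sample, contig, pos)


def classify_x_region(pos: int, x_map: XRegionMap, mode: str | None = None,
                      contig_length: int | None = None) -> str:
    """PAR1 / XTR / PAR2 / NONPAR membership of an X position.

    Under TWO_PAR the XTR reports as NONPAR, mirroring the ploidy it receives.
    """
    m = x_map if mode is None else x_map.with_mode(mode)
    return m.classify(pos, contig_length)


def _haploidize(rec: SampleSiteRecord) -> SampleSiteRecord:
    """Collapse a diploid record to haploid, the desk-scale counterpart of
    remapping male XTR reads to a masked reference.  The kept allele is the
    one with higher allele depth (ties toward the lower allele index)."""
    if rec.ploidy == 1:
        return rec
    gt = rec.genotype
    if gt is None:
        allele = None
    elif gt[0] == gt[1]:
        allele = gt[0]
    elif rec.allele_depths is not None:
        allele = max(gt, key=lambda a: (rec.allele_depths[a], -a))
    else:
        allele = min(gt)
    n_alleles = 1 + len(rec.alts)
    if rec.likelihoods is not None and allele is not None:
        pls = [0 if (a,) == (allele,) else max(rec.likelihoods) or 60
               for a in range(n_alleles)]
    else:
        pls = None
    return replace(
        rec,
        genotype=None if allele is None else (allele,),
        ploidy=1,
        likelihoods=None if pls is None else tuple(pls),
    )


def prepare_x_records(
    records_by_sample: Mapping[str, Sequence[SampleSiteRecord]],
    sex: Mapping[str, str],
    x_map: XRegionMap,
    mode: str,
) -> dict[str, list[SampleSiteRecord]]:
    """Adjust male X records to the ploidy the mode dictates.

    Diploid male records at positions the mode treats as non-PAR (notably the
    XTR under TWO_PAR) are collapsed to haploid.  A heterozygous male record
    at a position that is non-PAR under *both* modes is invalid input and
    raises a ploidy conflict.
    """
    strict = x_map.with_mode(THREE_PAR)
    m = x_map.with_mode(mode)
    out: dict[str, list[SampleSiteRecord]] = {}
    for sample, records in records_by_sample.items():
        if sex.get(sample) != "male":
            out[sample] = list(records)
            continue
        fixed = []
        for rec in records:
            region = m.classify(rec.pos)
            if region in ("PAR1", "XTR", "PAR2"):
                fixed.append(rec)
            elif rec.ploidy == 2:
                if strict.classify(rec.pos) == "NONPAR" and rec.genotype is not None \
                        and rec.genotype[0] != rec.genotype[1]:
                    raise PloidyConflictError(
                        f"male heterozygote outside any pseudoautosomal region: "
                        f"{sample} {rec.contig}:{rec.pos}"
                    )
                fixed.append(_haploidize(rec))
            else:
                fixed.append(rec)
        out[sample] = fixed
    return out


def build_x_panels(
    records_by_sample: Mapping[str, Sequence[SampleSiteRecord]],
    sex: Mapping[str, str],
    x_contig: Contig,
    x_map: XRegionMap,
) -> tuple[list[VariantSite], list[VariantSite]]:
    """Joint-genotype the X chromosome under both PAR conventions.

    Returns (TWO_PAR sites, THREE_PAR sites).  The two differ only at XTR
    positions, where TWO_PAR collapses male evidence to haploid.
    Ambiguous-sex samples must have been excluded upstream.
    """
    region = Region(x_contig.name, 1, x_contig.length)
    categories = {x_contig.name: "chrX"}
    panels = []
    for mode in (TWO_PAR, THREE_PAR):
        prepared = prepare_x_records(records_by_sample, sex, x_map, mode)
        pm = PloidyMap(sex=sex, x_map=x_map, categories=categories, mode=mode)
        panels.append(joint_genotype_region(prepared, region, pm))
    return panels[0], panels[1]


def xtr_heterozygosity_scan(
    array_table,
    male_samples: Sequence[str],
    x_map: XRegionMap,
    window: int = 20,
    x_contig: str = "X",
):
    """Male heterozygosity rate in non-overlapping windows of X array markers.

    High male heterozygosity marks regions that behave pseudoautosomally;
    windows are annotated with the named region they overlap.  Returns a
    pandas DataFrame (start, end, n_calls, het_rate, region); the rate is NaN
    for windows without callable genotypes.
    """
    import pandas as pd

    if not male_samples:
        raise ValueError("need at least one male sample")
    t = array_table[array_table["contig"] == x_contig].sort_values("pos")
    rows = []
    strict = x_map.with_mode(THREE_PAR)
    positions = t["pos"].to_numpy()
    values = t[list(male_samples)].to_numpy()
    for w0 in range(0, len(t), window):
        chunk = values[w0:w0 + window]
        pos_chunk = positions[w0:w0 + window]
        called = (chunk != "NoCall").sum()
        het = (chunk == "0/1").sum()
        regions = {strict.classify(int(p)) for p in pos_chunk}
        rows.append({
            "start": int(pos_chunk[0]),
            "end": int(pos_chunk[-1]),
            "n_calls": int(called),
            "het_rate": het / called if called else np.nan,
            # every overlapped region, so pure windows are distinguishable
            # from boundary windows that mix non-PAR markers in
            "region": ",".join(sorted(regions)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mitochondria
# ---------------------------------------------------------------------------


def mt_remap(pos: int, length: int = MT_LENGTH, shift: int = MT_SHIFT) -> int:
    """Map a position on the shifted linearization back to primary coordinates.

    The shifted linearization starts ``shift`` bases into the primary one, so
    shifted position 1 is primary position shift+1; the map is a bijection of
    [1, length] onto itself.
    """
    if not 1 <= pos <= length:
        raise ValueError(f"position {pos} outside [1, {length}]")
    return (pos + shift - 1) % length + 1


def mt_inverse_remap(pos: int, length: int = MT_LENGTH, shift: int = MT_SHIFT) -> int:
    """Primary coordinates back to the shifted linearization."""
    if not 1 <= pos <= length:
        raise ValueError(f"position {pos} outside [1, {length}]")
    return (pos - shift - 1) % length + 1


def call_mt_panel(
    primary_records: Mapping[str, Sequence[SampleSiteRecord]],
    shifted_records: Mapping[str, Sequence[SampleSiteRecord]],
    mt_contig: Contig,
    *,
    shift: int = MT_SHIFT,
    edge_margin: int = DEFAULT_EDGE_MARGIN,
) -> list[VariantSite]:
    """Haploid mitochondrial call set merged across two linearizations.

    Both inputs are joint-genotyped haploid; shifted calls are remapped to
    primary coordinates.  Positions within ``edge_margin`` of either end of
    the primary linearization are taken from the shifted call set (which is
    breakpoint-distant there); all other positions come from the primary set.
    A diploid genotype anywhere raises a ploidy conflict.
    """
    L = mt_contig.length

    def haploid_map(sample: str, contig: str, pos: int) -> int:
        return 1

    for recs in list(primary_records.values()) + list(shifted_records.values()):
        for r in recs:
            if r.ploidy != 1:
                raise PloidyConflictError(
                    f"diploid mitochondrial record: {r.sample} {r.contig}:{r.pos}"
                )

    region = Region(mt_contig.name, 1, L)
    primary_sites = joint_genotype_region(primary_records, region, haploid_map)
    shifted_sites = joint_genotype_region(shifted_records, region, haploid_map)

    remapped: dict[int, VariantSite] = {}
    for s in shifted_sites:
        new_pos = mt_remap(s.pos, L, shift)
        remapped[new_pos] = replace(s, pos=new_pos)
    primary_by_pos = {s.pos: s for s in primary_sites}

    def near_edge(pos: int) -> bool:
        return pos <= edge_margin or pos > L - edge_margin

    merged: dict[int, VariantSite] = {}
    for pos, site in primary_by_pos.items():
        if not near_edge(pos):
            merged[pos] = site
    for pos, site in remapped.items():
        if near_edge(pos):
            merged[pos] = site
    return [merged[p] for p in sorted(merged)]


def shifted_mt_records(
    primary_records: Mapping[str, Sequence[SampleSiteRecord]],
    length: int = MT_LENGTH,
    shift: int = MT_SHIFT,
) -> dict[str, list[SampleSiteRecord]]:
    """Re-express primary-coordinate MT records on the shifted linearization.

    Used by the synthetic pipeline to emulate the second alignment pass, and
    by rotation-invariance checks.
    """
    out: dict[str, list[SampleSiteRecord]] = {}
    for sample, recs in primary_records.items():
        moved = [replace(r, pos=mt_inverse_remap(r.pos, length, shift)) for r in recs]
        moved.sort(key=lambda r: r.pos)
        out[sample] = moved
    return out
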