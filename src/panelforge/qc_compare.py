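"""Evaluation machinery: WGS-vs-array genotype concordance and cross-panel
allele-frequency comparison.

Concordance cross-tabulates, marker by marker and sample by sample, the
genotype state seen by whole-genome sequencing against the state reported by
a SNP array, over five states: NotObserved (no call and no site at all),
NoCall (site known, genotype missing), HomRef, Het, HomAlt.  The concordance
ratio is the diagonal fraction of the jointly-called 3x3 genotype block.

Panel comparison matches two allele-frequency panels per (contig, pos, ref,
alt) key — attempting a ref/alt swap with frequency complementation before
declaring a mismatch — and reports the Pearson correlation of shared
frequencies plus any pair differing by at least a configurable threshold,
annotated with overlapping region masks (e.g. low-complexity BEDs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import Region
from .joint_panel import PanelEntry, VariantSite

STATES = ("NotObserved", "NoCall", "HomRef", "Het", "HomAlt")
_GT_STATES = ("HomRef", "Het", "HomAlt")


@dataclass
class ConcordanceMatrix:
    """5x5 WGS-state x array-state contingency table."""

    counts: np.ndarray  # (5, 5) int, rows = WGS, cols = array
    scope: str = "pooled"
    excluded_markers: list[tuple] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(STATES), columns=list(STATES))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ConcordanceMatrix) and np.array_equal(
            self.counts, other.counts
        )


def _dose_state(gt: tuple[int, ...], allele_index: int, swapped: bool) -> str:
    dose = sum(1 for a in gt if a == allele_index)
    if swapped:
        dose = len(gt) - dose
    if len(gt) == 1:  # hemizygous calls reported in diploid vocabulary
        dose *= 2
    return _GT_STATES[min(dose, 2)]


def _harmonize(site: VariantSite, ref: str, alt: str) -> tuple[int, bool] | None:
    """Locate the array allele in the site; returns (alt index, swapped)."""
    if site.ref == ref and alt in site.alts:
        return site.alts.index(alt) + 1, False
    if site.ref == alt and ref in site.alts:
        # array and WGS disagree on which allele is reference
        return site.alts.index(ref) + 1, True
    return None


def concordance_matrix(
    wgs_sites: Sequence[VariantSite],
    array_table: pd.DataFrame,
    samples: Sequence[str] | None = None,
    marker_universe: Sequence[tuple[str, int, str, str]] | None = None,
) -> ConcordanceMatrix:
    """Pooled WGS-vs-array concordance over a marker universe.

    The universe defaults to the union of array markers and biallelic WGS
    sites.  Every (marker, sample) observation lands in exactly one cell;
    markers whose alleles cannot be harmonized even after a ref/alt swap are
    excluded and listed on the result.
    """
    sample_cols = [c for c in array_table.columns if c not in ("contig", "pos", "ref", "alt")]
    if samples is None:
        samples = sample_cols
    site_by_pos = {(s.contig, s.pos): s for s in wgs_sites}
    array_by_key: dict[tuple, pd.Series] = {}
    for _, row in array_table.iterrows():
        array_by_key[(row["contig"], int(row["pos"]), row["ref"], row["alt"])] = row

    if marker_universe is None:
        universe = set(array_by_key)
        for s in wgs_sites:
            if len(s.alts) == 1:
                universe.add((s.contig, s.pos, s.ref, s.alts[0]))
        marker_universe = sorted(universe)

    idx = {st: i for i, st in enumerate(STATES)}
    counts = np.zeros((5, 5), dtype=np.int64)
    excluded: list[tuple] = []
    for key in marker_universe:
        contig, pos, ref, alt = key
        row = array_by_key.get(key)
        site = site_by_pos.get((contig, pos))
        harmonized = None
        if site is not None:
            harmonized = _harmonize(site, ref, alt)
            if harmonized is None:
                excluded.append(key)
                continue
        for sample in samples:
            if row is None:
                a_state = "NotObserved"
            else:
                val = row[sample]
                a_state = "NoCall" if val == "NoCall" else _GT_STATES[val.count("1")]
            if site is None:
                w_state = "NotObserved"
            else:
                gt = site.genotypes.get(sample)
                if gt is None:
                    w_state = "NoCall"
                else:
                    w_state = _dose_state(gt, *harmonized)
            if a_state == w_state == "NotObserved":
                continue  # the undefined corner cell
            counts[idx[w_state], idx[a_state]] += 1
    return ConcordanceMatrix(counts=counts, excluded_markers=excluded)


def concordance_by_sample(
    wgs_sites: Sequence[VariantSite],
    array_table: pd.DataFrame,
) -> dict[str, ConcordanceMatrix]:
    sample_cols = [c for c in array_table.columns if c not in ("contig", "pos", "ref", "alt")]
    return {
        s: ConcordanceMatrix(
            counts=concordance_matrix(wgs_sites, array_table, samples=[s]).counts,
            scope=s,
        )
        for s in sample_cols
    }


def concordance_ratio(matrix: ConcordanceMatrix) -> float | None:
    """Diagonal fraction of the jointly-called genotype block.

    Rows/columns for NoCall and NotObserved are excluded from the
    denominator; with no jointly-called observation the ratio is undefined
    and ``None`` is returned.
    """
    gt_idx = [STATES.index(s) for s in _GT_STATES]
    block = matrix.counts[np.ix_(gt_idx, gt_idx)]
    total = block.sum()
    if total == 0:
        return None
    return float(np.trace(block) / total)


# ---------------------------------------------------------------------------
# Panel comparison
# ---------------------------------------------------------------------------


@dataclass
class Outlier:
    contig: str
    pos: int
    ref: str
    alt: str
    af_a: float
    af_b: float
    annotation: str


@dataclass
class PanelComparison:
    shared: list[tuple[tuple, float, float]]  # (key, af_a, af_b)
    a_only: list[tuple]
    b_only: list[tuple]
    pearson_r: float | None
    outliers: list[Outlier]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Position": f"{o.contig}:{o.pos}", "Ref/Alt": f"{o.ref}/{o.alt}",
                    "AF_a": o.af_a, "AF_b": o.af_b, "annotation": o.annotation,
                }
                for o in self.outliers
            ]
        )


def _per_alt_afs(panel: Sequence[PanelEntry]) -> dict[tuple, float]:
    out: dict[tuple, float] = {}
    for e in panel:
        for alt, af in zip(e.alts, e.af):
            out[(e.contig, e.pos, e.ref, alt)] = af
    return out


def compare_panels(
    panel_a: Sequence[PanelEntry],
    panel_b: Sequence[PanelEntry],
    outlier_threshold: float = 0.3,
    masks: Mapping[str, Sequence[Region]] | None = None,
) -> PanelComparison:
    """Match two panels per (contig, pos, ref, alt) and compare frequencies.

    Multiallelic entries enter per ALT as separate keys.  A key missing from
    one panel is retried with ref and alt swapped (complementing that panel's
    frequency) before being declared one-sided.  Shared pairs feed a Pearson
    correlation (undefined below two pairs); pairs differing by at least
    ``outlier_threshold`` are reported with the names of any overlapping
    masks, or "Unknown".
    """
    if not 0.0 < outlier_threshold <= 1.0:
        raise ValueError("outlier threshold must be in (0, 1]")
    afs_a = _per_alt_afs(panel_a)
    afs_b = _per_alt_afs(panel_b)

    shared: list[tuple[tuple, float, float]] = []
    matched_b: set[tuple] = set()
    a_only: list[tuple] = []
    for key, af_a in afs_a.items():
        contig, pos, ref, alt = key
        if key in afs_b:
            shared.append((key, af_a, afs_b[key]))
            matched_b.add(key)
            continue
        swapped = (contig, pos, alt, ref)
        if swapped in afs_b:
            shared.append((key, af_a, 1.0 - afs_b[swapped]))
            matched_b.add(swapped)
            continue
        a_only.append(key)
    b_only = [k for k in afs_b if k not in matched_b]

    if len(shared) >= 2:
        xs = np.array([a for _, a, _ in shared])
        ys = np.array([b for _, _, b in shared])
        if xs.std() > 0 and ys.std() > 0:
            r = float(np.corrcoef(xs, ys)[0, 1])
        else:
            r = None
        pearson = r
    else:
        pearson = None

    outliers: list[Outlier] = []
    for (contig, pos, ref, alt), af_a, af_b in shared:
        if abs(af_a - af_b) >= outlier_threshold:
            names = []
            for name, regions in (masks or {}).items():
                if any(r.contains(contig, pos) for r in regions):
                    names.append(name)
            outliers.append(
                Outlier(contig=contig, pos=pos, ref=ref, alt=alt,
                        af_a=af_a, af_b=af_b,
                        annotation=";".join(sorted(names)) if names else "Unknown")
            )
    return PanelComparison(
        shared=shared, a_only=a_only, b_only=b_only,
        pearson_r=pearson, outliers=outliers,
    )
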