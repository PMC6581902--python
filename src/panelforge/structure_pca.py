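"""Population-structure toolkit: variant filters, the Hardy-Weinberg exact
test, LD pruning, dataset merging on common variants, PCA, and the
outlier-cluster relatedness check.

The workflow mirrors the standard PLINK chain: filter on minor allele
frequency, exact-test Hardy-Weinberg p-value and missing rate; prune to
approximately independent variants with a sliding window over variant counts
(the ``--indep-pairwise`` convention); then run PCA on frequency-standardized
dosages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sample_qc import IBDEstimate, estimate_ibd

VariantKey = tuple[str, int, str, str]  # (contig, pos, ref, alt)


class MergeError(ValueError):
    """The two genotype matrices cannot be combined."""


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix: variants x samples, entries 0/1/2 or NaN."""

    samples: list[str]
    variants: list[VariantKey]
    dosages: np.ndarray  # (n_variants, n_samples) float

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_freqs(self) -> np.ndarray:
        return np.nanmean(self.dosages, axis=1) / 2.0

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def subset_variants(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in keep],
            dosages=self.dosages[keep],
        )


def genotype_matrix_from_sites(sites, samples: Sequence[str] | None = None) -> GenotypeMatrix:
    """Dosage matrix from joint-genotyped biallelic sites (diploid calls only;
    haploid or missing genotypes become NaN)."""
    sites = [s for s in sites if len(s.alts) == 1]
    if not sites:
        raise ValueError("no biallelic sites")
    if samples is None:
        samples = sorted(sites[0].genotypes)
    dosages = np.full((len(sites), len(samples)), np.nan)
    variants: list[VariantKey] = []
    for i, s in enumerate(sites):
        variants.append((s.contig, s.pos, s.ref, s.alts[0]))
        for j, sample in enumerate(samples):
            gt = s.genotypes.get(sample)
            if gt is not None and len(gt) == 2:
                dosages[i, j] = sum(1 for a in gt if a > 0)
    return GenotypeMatrix(samples=list(samples), variants=variants, dosages=dosages)


@dataclass
class PcaResult:
    samples: list[str]
    coordinates: np.ndarray       # (n_samples, k)
    eigenvalues: np.ndarray       # (k,), descending, non-negative
    loadings: np.ndarray | None = None


def hwe_exact_test(hom_ref: int, het: int, hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value for one biallelic variant.

    Conditions on the observed allele counts: the heterozygote count then has
    a hypergeometric-type distribution over counts of matching parity, and
    the p-value sums the probabilities of all heterozygote counts no more
    probable than the observed one.  Monomorphic input returns 1.
    """
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_ref + het + hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    rare = min(2 * hom_ref + het, 2 * hom_alt + het)
    if rare == 0:
        return 1.0

    probs = np.zeros(rare + 1)
    # start at the distribution mode (approximately rare*common/(2n)), with
    # the parity forced to match the observed heterozygote count
    mid = int(rare * (2 * n - rare) / (2.0 * n))
    if (rare - mid) % 2 != 0:
        mid += 1 if mid < rare else -1
    mid = min(max(mid, rare % 2), rare)
    probs[mid] = 1.0
    h, hom_r, hom_c = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while h > 1:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        hom_r += 1
        hom_c += 1
    h, hom_r, hom_c = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while h <= rare - 2:
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
        hom_r -= 1
        hom_c -= 1
    probs /= probs.sum()
    p_obs = probs[het]
    p = float(probs[probs <= p_obs * (1.0 + 1e-10)].sum())
    return min(p, 1.0)


def _genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    d = dosages[np.isfinite(dosages)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def filter_variants(
    matrix: GenotypeMatrix,
    maf_min: float,
    hwe_p_min: float,
    missing_max: float,
) -> tuple[GenotypeMatrix, list[tuple[VariantKey, str]]]:
    """Apply the MAF / HWE / missing-rate filter chain.

    A variant survives iff MAF >= ``maf_min`` and HWE exact p >= ``hwe_p_min``
    and missing fraction <= ``missing_max`` (MAF on non-missing dosages).
    The log lists the first failing criterion for each removed variant.
    Filtering is idempotent: re-filtering a filtered matrix removes nothing.
    """
    if matrix.n_variants == 0:
        raise ValueError("empty genotype matrix")
    keep: list[int] = []
    log: list[tuple[VariantKey, str]] = []
    for i, key in enumerate(matrix.variants):
        row = matrix.dosages[i]
        called = np.isfinite(row)
        missing = 1.0 - called.mean()
        if not called.any():
            log.append((key, "missing"))
            continue
        af = float(row[called].mean()) / 2.0
        maf = min(af, 1.0 - af)
        if maf < maf_min:
            log.append((key, "maf"))
            continue
        if hwe_exact_test(*_genotype_counts(row)) < hwe_p_min:
            log.append((key, "hwe"))
            continue
        if missing > missing_max:
            log.append((key, "missing"))
            continue
        keep.append(i)
    return matrix.subset_variants(keep), log


def merge_on_common(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Combine two cohorts on their shared variants.

    Variants match on (contig, pos, ref, alt); a variant carried by ``b``
    with ref and alt swapped is harmonized by complementing its dosages
    (d -> 2 - d).  Sample sets must be disjoint; columns are ordered a then b.
    """
    dup = set(a.samples) & set(b.samples)
    if dup:
        raise MergeError(f"duplicate sample ids across inputs: {sorted(dup)[:5]}")
    index_b = {k: i for i, k in enumerate(b.variants)}
    rows = []
    keys = []
    for i, key in enumerate(a.variants):
        contig, pos, ref, alt = key
        j = index_b.get(key)
        flip = False
        if j is None:
            j = index_b.get((contig, pos, alt, ref))
            flip = j is not None
        if j is None:
            continue
        row_b = b.dosages[j]
        if flip:
            row_b = 2.0 - row_b
        rows.append(np.concatenate([a.dosages[i], row_b]))
        keys.append(key)
    if not rows:
        raise MergeError("no common variants between the two matrices")
    return GenotypeMatrix(
        samples=list(a.samples) + list(b.samples),
        variants=keys,
        dosages=np.vstack(rows),
    )


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = 200,
    step: int = 4,
    r2_threshold: float = 0.1,
) -> list[int]:
    """Sliding-window pairwise LD pruning over variant counts.

    Within each window of ``window`` variants (advancing by ``step``), while
    any kept pair has squared dosage correlation above the threshold, the
    member with the lower MAF is dropped (ties: the later position).  The
    kept set is re-audited window by window before returning.  Returns kept
    variant indices into the input matrix.
    """
    if not (window > step >= 1):
        raise ValueError("require window > step >= 1")
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2 threshold must be in (0, 1]")
    n = matrix.n_variants
    d = matrix.dosages.copy()
    # mean-impute for correlation purposes only
    means = np.nanmean(d, axis=1)
    nan_mask = np.isnan(d)
    d[nan_mask] = np.take(means, np.nonzero(nan_mask)[0])
    freqs = means / 2.0
    mafs = np.minimum(freqs, 1.0 - freqs)
    kept = np.ones(n, dtype=bool)

    def window_r2(idx: np.ndarray) -> np.ndarray:
        sub = d[idx]
        std = sub.std(axis=1)
        safe = std > 0
        r2 = np.zeros((len(idx), len(idx)))
        if safe.sum() >= 2:
            c = np.corrcoef(sub[safe])
            r2[np.ix_(np.nonzero(safe)[0], np.nonzero(safe)[0])] = c ** 2
        np.fill_diagonal(r2, 0.0)
        return r2

    for start in range(0, max(n - 1, 1), step):
        idx = np.nonzero(kept[start:start + window])[0] + start
        if len(idx) < 2:
            continue
        r2 = window_r2(idx)
        alive = np.ones(len(idx), dtype=bool)
        while True:
            masked = r2 * np.outer(alive, alive)
            i, j = np.unravel_index(np.argmax(masked), masked.shape)
            if masked[i, j] <= r2_threshold:
                break
            gi, gj = idx[i], idx[j]
            if mafs[gi] < mafs[gj]:
                drop = i
            elif mafs[gj] < mafs[gi]:
                drop = j
            else:
                drop = i if matrix.variants[gi][1] > matrix.variants[gj][1] else j
            alive[drop] = False
        kept[idx[~alive]] = False

    kept_idx = np.nonzero(kept)[0]
    # audit: no surviving within-window pair above the threshold
    for start in range(0, max(n - 1, 1), step):
        idx = kept_idx[(kept_idx >= start) & (kept_idx < start + window)]
        if len(idx) < 2:
            continue
        r2 = window_r2(idx)
        assert r2.max() <= r2_threshold + 1e-12, "LD pruning post-condition violated"
    return kept_idx.tolist()


def pca(matrix: GenotypeMatrix, n_components: int = 10,
        compute_loadings: bool = False) -> PcaResult:
    """PCA of frequency-standardized dosages.

    Missing dosages are mean-imputed per variant (run the filters first so
    the missing rate is small).  Each variant is centred at 2p and scaled by
    sqrt(2p(1-p)); components come from the eigendecomposition of the
    sample x sample covariance of the standardized matrix.  Sign convention:
    the largest-magnitude coordinate of every component is positive.
    """
    if len(matrix.samples) < 2 or matrix.n_variants < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variants")
    d = matrix.dosages.copy()
    means = np.nanmean(d, axis=1)
    nan_mask = np.isnan(d)
    d[nan_mask] = np.take(means, np.nonzero(nan_mask)[0])
    p = means / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    if np.any(d.std(axis=1) == 0) or np.any(scale == 0):
        raise ValueError("zero-variance variant reached PCA; filter first")
    x = ((d - 2.0 * p[:, None]) / scale[:, None]).T  # samples x variants
    cov = x @ x.T / matrix.n_variants
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    k = min(n_components, len(eigvals))
    eigvals = np.clip(eigvals[order][:k], 0.0, None)
    vecs = eigvecs[:, order][:, :k]
    coords = vecs * np.sqrt(eigvals)[None, :]
    for c in range(k):
        peak = np.argmax(np.abs(coords[:, c]))
        if coords[peak, c] < 0:
            coords[:, c] = -coords[:, c]
            vecs[:, c] = -vecs[:, c]
    loadings = None
    if compute_loadings:
        with np.errstate(divide="ignore", invalid="ignore"):
            loadings = x.T @ vecs / np.where(eigvals > 0, np.sqrt(eigvals), np.inf)
    return PcaResult(
        samples=list(matrix.samples), coordinates=coords,
        eigenvalues=eigvals, loadings=loadings,
    )


def cluster_ibd_check(
    subset: Sequence[str],
    matrix: GenotypeMatrix,
    *,
    min_markers: int = 500,
) -> tuple[float, tuple[str, str], list[IBDEstimate]]:
    """Maximum pairwise PIHAT within a sample subset (e.g. a PCA cluster).

    Frequencies come from the full matrix; returns (max pihat, attaining
    pair, all pairwise estimates).
    """
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 samples")
    cols = {s: matrix.samples.index(s) for s in subset}
    freqs = matrix.alt_freqs()
    allele_total = 2 * len(matrix.samples)
    estimates: list[IBDEstimate] = []
    for i, s1 in enumerate(subset):
        for s2 in subset[i + 1:]:
            estimates.append(
                estimate_ibd(
                    (s1, s2),
                    matrix.dosages[:, cols[s1]],
                    matrix.dosages[:, cols[s2]],
                    freqs,
                    allele_total=allele_total,
                    min_markers=min_markers,
                )
            )
    best = max(estimates, key=lambda e: e.pihat)
    return best.pihat, best.pair, estimates
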