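"""Sample-level QC: sex inference, karyotype-anomaly screening, and
relatedness pruning.

Sex is called from the method-of-moments inbreeding coefficient F on
non-pseudoautosomal X markers (hemizygous males show F near 1, diploid
females near 0), cross-checked against the ratio of mean Y depth to mean
autosomal depth so that anomalies such as an XO karyotype — homozygous X but
no Y coverage — surface as ambiguous rather than as confident males.

Relatedness uses the classic method-of-moments IBD decomposition on
identity-by-state counts over (LD-pruned) autosomal markers, with the
finite-sample frequency corrections of the PLINK ``--genome`` estimator,
yielding Z0/Z1/Z2 and PIHAT = Z2 + Z1/2.  Pairs closer than a configurable
PIHAT cutoff are broken up greedily.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

DEFAULT_PIHAT_THRESHOLD = 0.1875  # midpoint of expected 2nd (0.25) and 3rd (0.125) degree
DEFAULT_F_MALE = 0.8
DEFAULT_F_FEMALE = 0.2
DEFAULT_Y_RATIO_MALE = 0.3
DEFAULT_Y_RATIO_FEMALE = 0.1
MIN_SEX_MARKERS = 50
MIN_IBD_MARKERS = 500


class InsufficientDataError(ValueError):
    """Too few informative markers to produce an estimate."""


class DegenerateFrequencyError(ValueError):
    """All supplied markers are monomorphic; the estimator is undefined."""


@dataclass(frozen=True)
class SexInference:
    sample: str
    x_inbreeding_f: float
    y_depth_ratio: float | None
    call: str  # "male" | "female" | "ambiguous"


@dataclass(frozen=True)
class IBDEstimate:
    pair: tuple[str, str]
    z0: float
    z1: float
    z2: float
    pihat: float

    def __post_init__(self) -> None:
        if not (abs(self.z0 + self.z1 + self.z2 - 1.0) < 1e-9):
            raise ValueError("Z0+Z1+Z2 must be 1 after renormalization")
        if not 0.0 <= self.pihat <= 1.0 + 1e-12:
            raise ValueError("PIHAT outside [0, 1]")


def x_inbreeding_f(dosages: np.ndarray, freqs: np.ndarray,
                   min_markers: int = MIN_SEX_MARKERS) -> float:
    """Method-of-moments inbreeding F on X-marker dosages.

    ``dosages`` are 0/1/2 alt counts (negative or NaN = missing); ``freqs``
    the alt allele frequencies.  F = (observed hom - expected hom) /
    (markers - expected hom) with expected hom = sum(1 - 2p(1-p)) over the
    informative (non-missing, polymorphic) markers.
    """
    dosages = np.asarray(dosages, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    ok = np.isfinite(dosages) & (dosages >= 0) & (freqs > 0) & (freqs < 1)
    if ok.sum() < min_markers:
        raise InsufficientDataError(
            f"only {int(ok.sum())} informative X markers (< {min_markers})"
        )
    d = dosages[ok]
    p = freqs[ok]
    m = len(d)
    obs_hom = float(np.sum(d != 1))
    exp_hom = float(np.sum(1.0 - 2.0 * p * (1.0 - p)))
    denom = m - exp_hom
    if denom <= 0:
        return 1.0
    return (obs_hom - exp_hom) / denom


def infer_sex(
    sample: str,
    x_dosages: np.ndarray,
    x_freqs: np.ndarray,
    y_mean_depth: float | None = None,
    autosome_mean_depth: float | None = None,
    *,
    f_male: float = DEFAULT_F_MALE,
    f_female: float = DEFAULT_F_FEMALE,
    y_ratio_male: float = DEFAULT_Y_RATIO_MALE,
    y_ratio_female: float = DEFAULT_Y_RATIO_FEMALE,
    min_markers: int = MIN_SEX_MARKERS,
) -> SexInference:
    """Call sample sex from non-PAR X heterozygosity plus Y depth support.

    F at or above ``f_male`` suggests male, at or below ``f_female`` female,
    anything between is ambiguous.  When Y and autosome depths are supplied,
    the Y/autosome ratio must agree with the F-based call (>= ``y_ratio_male``
    for males, <= ``y_ratio_female`` for females); a contradiction — e.g. a
    fully homozygous X with no Y coverage, as in an XO karyotype — demotes
    the call to ambiguous so such samples can be excluded.
    """
    f = x_inbreeding_f(x_dosages, x_freqs, min_markers=min_markers)
    ratio = None
    if y_mean_depth is not None and autosome_mean_depth:
        ratio = y_mean_depth / autosome_mean_depth
    if f >= f_male:
        call = "male"
    elif f <= f_female:
        call = "female"
    else:
        call = "ambiguous"
    if ratio is not None:
        if call == "male" and ratio < y_ratio_male:
            call = "ambiguous"
        elif call == "female" and ratio > y_ratio_female:
            call = "ambiguous"
    return SexInference(sample=sample, x_inbreeding_f=f, y_depth_ratio=ratio, call=call)


def _falling(x: np.ndarray | float, k: int):
    out = x
    for i in range(1, k):
        out = out * (x - i)
    return out


def estimate_ibd(
    pair: tuple[str, str],
    dosages_a: np.ndarray,
    dosages_b: np.ndarray,
    freqs: np.ndarray,
    *,
    allele_total: int | None = None,
    min_markers: int = MIN_IBD_MARKERS,
) -> IBDEstimate:
    """Method-of-moments IBD estimate for one sample pair.

    Counts markers by identity-by-state (0/1/2) and solves for the prior
    probabilities Z0/Z1/Z2 of sharing 0/1/2 alleles identical by descent,
    using the expected IBS composition implied by the allele frequencies.
    ``allele_total`` is the number of alleles the frequencies were estimated
    from; when given, the estimator applies the finite-sample
    (falling-factorial) bias corrections used by PLINK's ``--genome``.
    Z values are clipped to [0, 1] and renormalised; PIHAT = Z2 + Z1/2.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    p = np.asarray(freqs, dtype=float)
    ok = (
        np.isfinite(a) & np.isfinite(b) & (a >= 0) & (b >= 0)
    )
    poly = (p > 0) & (p < 1)
    if not poly[ok].any():
        if ok.sum() >= min_markers:
            raise DegenerateFrequencyError("all shared markers are monomorphic")
    ok &= poly
    if ok.sum() < min_markers:
        raise InsufficientDataError(
            f"only {int(ok.sum())} usable shared markers (< {min_markers})"
        )
    a, b, p = a[ok], b[ok], p[ok]
    m = len(p)

    diff = np.abs(a - b)
    ibs0 = (diff == 2)
    ibs2 = (diff == 0)
    n0 = float(ibs0.sum())
    n2 = float(ibs2.sum())
    n1 = m - n0 - n2

    q = 1.0 - p
    if allele_total is not None:
        t = float(allele_total)
        x = p * t
        y = q * t
        d4 = _falling(t, 4)
        d3 = _falling(t, 3)
        e00 = 2.0 * _falling(x, 2) * _falling(y, 2) / d4
        e01 = 4.0 * (_falling(x, 3) * y + x * _falling(y, 3)) / d4
        e02 = (_falling(x, 4) + _falling(y, 4) + 4.0 * _falling(x, 2) * _falling(y, 2)) / d4
        e11 = 2.0 * (_falling(x, 2) * y + x * _falling(y, 2)) / d3
    else:
        e00 = 2.0 * p * p * q * q
        e01 = 4.0 * (p ** 3 * q + p * q ** 3)
        e02 = p ** 4 + q ** 4 + 4.0 * p * p * q * q
        e11 = 2.0 * p * q
    E00 = float(np.sum(e00))
    E01 = float(np.sum(e01))
    E02 = float(np.sum(e02))
    E11 = float(np.sum(e11))
    E12 = m - E11

    z0 = n0 / E00 if E00 > 0 else 0.0
    z1 = (n1 - z0 * E01) / E11 if E11 > 0 else 0.0
    z2 = (n2 - z0 * E02 - z1 * E12) / m

    z = np.clip(np.array([z0, z1, z2]), 0.0, 1.0)
    total = z.sum()
    z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
    pihat = float(z[2] + z[1] / 2.0)
    return IBDEstimate(pair=pair, z0=float(z[0]), z1=float(z[1]), z2=float(z[2]),
                       pihat=min(pihat, 1.0))


@dataclass(frozen=True)
class Exclusion:
    sample: str
    triggering_pair: tuple[str, str]
    pihat: float


def prune_relatives(
    estimates: Sequence[IBDEstimate],
    threshold: float = DEFAULT_PIHAT_THRESHOLD,
    call_rates: Mapping[str, float] | None = None,
) -> tuple[list[str], list[Exclusion]]:
    """Greedy removal of samples until no kept pair reaches the PIHAT cutoff.

    Repeatedly drops the sample participating in the most over-threshold
    pairs; ties are broken toward the lower genotype call rate, then the
    lexicographically later id.  Each exclusion records the over-threshold
    pair (the highest-PIHAT one) that triggered it.  The result is audited:
    no kept pair may remain at or above the threshold.
    """
    samples = sorted({s for e in estimates for s in e.pair})
    over = [e for e in estimates if e.pihat >= threshold]
    adj: dict[str, list[IBDEstimate]] = {s: [] for s in samples}
    for e in over:
        adj[e.pair[0]].append(e)
        adj[e.pair[1]].append(e)

    removed: list[Exclusion] = []
    active = set(samples)

    def degree(s: str) -> int:
        return sum(1 for e in adj[s] if e.pair[0] in active and e.pair[1] in active)

    while True:
        degrees = {s: degree(s) for s in active}
        worst = max(degrees.values(), default=0)
        if worst == 0:
            break
        candidates = [s for s, d in degrees.items() if d == worst]
        if call_rates:
            lowest = min(call_rates.get(s, 1.0) for s in candidates)
            candidates = [s for s in candidates if call_rates.get(s, 1.0) == lowest]
        victim = max(candidates)  # lexicographically later id removed
        live = [e for e in adj[victim] if e.pair[0] in active and e.pair[1] in active]
        trigger = max(live, key=lambda e: e.pihat)
        removed.append(Exclusion(sample=victim, triggering_pair=trigger.pair,
                                 pihat=trigger.pihat))
        active.discard(victim)

    kept = sorted(active)
    kept_set = set(kept)
    for e in estimates:  # post-hoc soundness audit
        if e.pair[0] in kept_set and e.pair[1] in kept_set:
            assert e.pihat < threshold, (
                f"pruning left pair {e.pair} at PIHAT {e.pihat:.4f} >= {threshold}"
            )
    return kept, removed
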