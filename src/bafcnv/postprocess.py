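"""Steps 3 & 4 — merge raw calls and (optionally) filter by quality.

Raw calls from overlapping or nearby windows usually describe one event.
Two calls merge when they report the same CNV type on the same chromosome,
their cell fractions agree within ``cf_sd_mult`` pooled standard deviations,
and they either overlap or sit within ``max_gap`` (default 20 Mb — wide
enough to bridge a centromere, which is at most ~7.4 Mb) with no significant
"no CNV" region of the same type strictly in between. Merging is the
transitive closure of this pairwise relation (union-find), so the result
does not depend on call order.

The merged region's CF is re-estimated over the union of all supporting
SNPs; this can drop below the detection threshold, in which case the call is
flagged rather than discarded (such regions always contain >= 2 raw calls
that individually passed).

Call quality is -log10 of the best constituent window p-value (capped at
300). The shipped default filtration threshold of 10.76 is a configuration
value whose separation of true from false calls should be re-established on
data resembling the user's own; the synthetic-data module provides the
harness for that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import RawCall, WindowResult, estimate_region_cf, trim_support, _neglog10

QUALITY_CAP = 300.0


@dataclass
class MergeParams:
    """max_gap: largest bridgeable gap in bp; cf_sd_mult: CF-similarity
    multiplier on the pooled sd; cf_margin: threshold slack on re-estimated CF."""

    max_gap: int = 20_000_000
    cf_sd_mult: float = 3.0
    cf_margin: float = 0.05

    def __post_init__(self):
        if self.max_gap <= 0 or self.cf_sd_mult <= 0:
            raise ValueError("max_gap and cf_sd_mult must be > 0")


@dataclass(frozen=True)
class MergedCall:
    """A merged region: RawCall fields plus provenance."""

    chrom: str
    start: int
    end: int
    cnv_type: str
    cf: float
    cf_sd: float
    p_value: float
    quality: float
    n_snps: int
    cov_ind_low: float
    cov_ind_high: float
    cov_ind_class: str
    support: np.ndarray
    n_raw: int
    below_threshold_flag: bool


def _cf_similar(a, b, mult: float) -> bool:
    pooled = np.sqrt(np.nan_to_num(a.cf_sd) ** 2 + np.nan_to_num(b.cf_sd) ** 2)
    return abs(a.cf - b.cf) <= mult * pooled


def _blocked(a, b, blockers) -> bool:
    """Does a same-type significant no-CNV region lie strictly in the gap?"""
    lo, hi = a.end, b.start
    for blk in blockers:
        if (
            getattr(blk, "cnv_type", a.cnv_type) == a.cnv_type
            and blk.chrom == a.chrom
            and blk.start > lo
            and blk.end < hi
        ):
            return True
    return False


def should_merge(a, b, blockers, params: MergeParams) -> bool:
    """Pairwise merge decision; ``a`` starts at or before ``b``.

    ``blockers`` are the no-CNV regions of the same type as the calls
    (a "no duplication" verdict says nothing about deletions).
    """
    if a.cnv_type != b.cnv_type or a.chrom != b.chrom:
        return False
    if a.start > b.start:
        a, b = b, a
    if not _cf_similar(a, b, params.cf_sd_mult):
        return False
    if b.start <= a.end:  # overlap
        return True
    gap = b.start - a.end - 1
    if gap >= params.max_gap:
        return False
    return not _blocked(a, b, blockers)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def no_cnv_regions(windows: list[WindowResult], cnv_type: str):
    """Supporting-SNP spans of significant no-CNV windows for one type."""
    regions = []
    for w in windows:
        if w.cnv_type == cnv_type and w.verdict == "no_cnv" and w.support.size:
            regions.append(w)
    return regions


def merge_calls(
    raw: list[RawCall],
    blockers: list,
    gated: pd.DataFrame,
    thresholds: dict,
    params: MergeParams | None = None,
) -> list[MergedCall]:
    """Merge raw calls per (chromosome, type) by transitive closure.

    The merged CF/sd and coverage indicator are recomputed over the union of
    supporting SNPs; quality and p-value come from the best constituent.
    Idempotent: re-merging the output leaves it unchanged.
    """
    from .calling import coverage_indicator, depth_size_factors

    params = params or MergeParams()
    calls = sorted(raw, key=lambda c: (c.chrom, c.cnv_type, c.start, c.end))
    if not calls:
        return []
    uf = _UnionFind(len(calls))
    for i, a in enumerate(calls):
        for j in range(i + 1, len(calls)):
            b = calls[j]
            if (b.chrom, b.cnv_type) != (a.chrom, a.cnv_type):
                break
            if b.start - a.end - 1 >= params.max_gap:
                break
            blk = [r for r in blockers if r.cnv_type == a.cnv_type]
            if should_merge(a, b, blk, params):
                uf.union(i, j)

    groups: dict[int, list[RawCall]] = {}
    for i, c in enumerate(calls):
        groups.setdefault(uf.find(i), []).append(c)

    sf = depth_size_factors(gated)
    merged = []
    for members in groups.values():
        support = np.unique(np.concatenate([m.support for m in members]))
        cnv_type = members[0].cnv_type
        if len(members) > 1:
            support = trim_support(support, gated)
        cf, sd = estimate_region_cf(support, gated, cnv_type)
        p_min = float(min(m.p_value for m in members))
        lo, hi, cls = coverage_indicator(support, gated, sf)
        profile = thresholds[cnv_type]
        below = bool(
            profile.reachable and cf < profile.cf_min - params.cf_margin and len(members) >= 2
        )
        merged.append(
            MergedCall(
                chrom=members[0].chrom,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                cnv_type=cnv_type,
                cf=cf,
                cf_sd=sd,
                p_value=p_min,
                quality=score_quality([m.p_value for m in members]),
                n_snps=int(support.size),
                cov_ind_low=lo,
                cov_ind_high=hi,
                cov_ind_class=cls,
                support=support,
                n_raw=len(members),
                below_threshold_flag=below,
            )
        )
    merged.sort(key=lambda c: (c.chrom, c.start, c.end, c.cnv_type))
    return merged


def score_quality(p_values) -> float:
    """Call quality: -log10 of the smallest constituent window p-value.

    Capped at 300; missing p-values score 0. Strictly decreasing in the
    minimum p, so merging (a min over more windows) never lowers quality.
    """
    ps = [p for p in np.atleast_1d(np.asarray(p_values, dtype=float)) if np.isfinite(p)]
    if not ps:
        return 0.0
    return _neglog10(min(ps), QUALITY_CAP)


def filter_calls(calls: list[MergedCall], threshold: float = 10.76) -> list[MergedCall]:
    """Keep calls with quality >= threshold, preserving order (monotone)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [c for c in calls if c.quality >= threshold]
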