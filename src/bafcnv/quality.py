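"""Step 1 — per-sample detection thresholds for CNV calling.

Before calling anything, the sample pair is profiled: for every candidate
cell fraction we find the smallest number of heterozygous SNPs (min_SNP)
whose coverage-weighted t-test reaches a target sensitivity, translate that
SNP count into a genomic window size via the observed SNP spacing, and pick
the operating point. The output is four thresholds per sample —
(CF_Del, W_Del) and (CF_Dup, W_Dup) — below which calls are not attempted.

Two routes to min_SNP exist: the *simulation* approach draws depths from a
fitted log-normal coverage model and repeats each window ``n_reps`` times;
the *exact* approach slides over the sample's real SNP list, using observed
depths (and, by default, observed control VAFs), simulating only the case
allele counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CNV_TYPES,
    CoverageModel,
    cf_from_vaf,
    expected_vaf,
    fit_coverage_model,
    weighted_welch,
)

UNREACHABLE = -1  # table sentinel for "no SNP count in range attains the target"

_TYPE_CODE = {t: i for i, t in enumerate(CNV_TYPES)}

MODE_TRADE_OFF = "trade_off"
MODE_MIN_CF = "min_cf"
MODE_MIN_W = "min_w"


def _default_cf_grid() -> np.ndarray:
    return np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 2)


@dataclass
class QualityParams:
    """Tunables of the threshold estimation.

    cf_grid: cell fractions evaluated (default 5–100% in 5% steps).
    snp_range: candidate SNP counts (default 1–100).
    n_reps: simulated windows per (cf, n) grid point (default 500).
    target_sens: required rejection rate (default 0.95).
    alpha: per-test significance level (default 0.05/4 = 0.0125).
    percentile: quantile of region lengths defining the window size W.
    mode: threshold selection rule — trade_off | min_cf | min_w.
    """

    cf_grid: np.ndarray = field(default_factory=_default_cf_grid)
    snp_range: np.ndarray = field(default_factory=lambda: np.arange(1, 101))
    n_reps: int = 500
    target_sens: float = 0.95
    alpha: float = 0.0125
    percentile: float = 0.95
    mode: str = MODE_TRADE_OFF

    def __post_init__(self):
        self.cf_grid = np.asarray(self.cf_grid, dtype=float)
        self.snp_range = np.asarray(self.snp_range, dtype=int)
        if not np.all(np.diff(self.cf_grid) > 0) or np.any(
            (self.cf_grid <= 0) | (self.cf_grid > 1)
        ):
            raise ValueError("cf_grid must be strictly increasing within (0, 1]")
        if not np.all(np.diff(self.snp_range) > 0) or np.any(self.snp_range < 1):
            raise ValueError("snp_range must be strictly increasing positive integers")
        if not 0 < self.target_sens < 1:
            raise ValueError("target_sens must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in (MODE_TRADE_OFF, MODE_MIN_CF, MODE_MIN_W):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ThresholdProfile:
    """Detection thresholds for one CNV type.

    ``table`` holds the full cf -> (min_snp, window_bp) grid (min_snp == -1
    marks unreachable entries); ``cf_min``/``window_bp``/``min_snp`` are the
    selected operating point, or None when no grid entry is reachable, in
    which case the sample is not apt for calling this CNV type.
    """

    cnv_type: str
    cf_min: float | None
    window_bp: float | None
    min_snp: int | None
    table: pd.DataFrame

    @property
    def reachable(self) -> bool:
        return self.cf_min is not None


def _substream(seed: int, cnv_type: str, cf: float, n: int) -> np.random.Generator:
    """Deterministic per-(type, cf, n) RNG so grid order cannot matter."""
    ss = np.random.SeedSequence(
        [int(seed), _TYPE_CODE[cnv_type], int(round(cf * 1000)), int(n)]
    )
    return np.random.default_rng(ss)


def _simulate_batch(
    n_snps: int,
    cnv_type: str,
    cf: float,
    control_model: CoverageModel,
    case_model: CoverageModel,
    rng: np.random.Generator,
    n_reps: int,
):
    """(n_reps, n_snps) arrays of case/control CFs and depth weights."""
    shape = (n_reps, n_snps)
    d_ctrl = control_model.sample(rng, shape)
    d_case = case_model.sample(rng, shape)
    alt_ctrl = rng.binomial(d_ctrl, 0.5)
    v_case = expected_vaf(cnv_type, cf)
    alt_case = rng.binomial(d_case, v_case)
    cf_ctrl = cf_from_vaf(cnv_type, alt_ctrl / d_ctrl)
    cf_case = cf_from_vaf(cnv_type, alt_case / d_case)
    return cf_case, d_case.astype(float), cf_ctrl, d_ctrl.astype(float)


def simulate_snp_pair(n_snps, cnv_type, cf, cov_model, rng, case_model=None):
    """Simulate one case/control window of ``n_snps`` heterozygous SNPs.

    Control allele counts are Binomial(depth, 0.5); case counts are
    Binomial(depth, expected_vaf(cnv_type, cf)); both are converted to CFs
    under ``cnv_type`` and weighted by their depths. Returns
    ``(case, control)`` as (values, weights) pairs.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    case_model = case_model or cov_model
    cf_case, w_case, cf_ctrl, w_ctrl = _simulate_batch(
        n_snps, cnv_type, cf, cov_model, case_model, rng, 1
    )
    return (cf_case[0], w_case[0]), (cf_ctrl[0], w_ctrl[0])


def _rejection_rate_sim(n, cnv_type, cf, control_model, case_model, params, rng):
    cf_case, w_case, cf_ctrl, w_ctrl = _simulate_batch(
        n, cnv_type, cf, control_model, case_model, rng, params.n_reps
    )
    _, p = weighted_welch(cf_case, w_case, cf_ctrl, w_ctrl, "greater")
    return float(np.mean(np.nan_to_num(p, nan=1.0) <= params.alpha))


def _sliding(arr: np.ndarray, n: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(arr, n)


def _rejection_rate_exact(n, cnv_type, cf, snps: pd.DataFrame, params, rng, simulate_control_vaf):
    """Rejection rate over all runs of ``n`` consecutive observed SNPs.

    Observed depths are used on both sides; case allele counts (and,
    optionally, control counts) are simulated once per SNP and shared by the
    overlapping windows.
    """
    d_ctrl = snps["depth_control"].to_numpy(float)
    d_case = snps["depth_case"].to_numpy(float)
    if simulate_control_vaf:
        alt_ctrl = rng.binomial(d_ctrl.astype(int), 0.5)
        v_ctrl = alt_ctrl / d_ctrl
    else:
        v_ctrl = snps["alt_control"].to_numpy(float) / d_ctrl
    alt_case = rng.binomial(d_case.astype(int), expected_vaf(cnv_type, cf))
    cf_ctrl = cf_from_vaf(cnv_type, v_ctrl)
    cf_case = cf_from_vaf(cnv_type, alt_case / d_case)

    ps = []
    for _, grp in snps.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if idx.size < n:
            continue
        win = _sliding(np.arange(idx.size), n)
        loc = idx[win]
        _, p = weighted_welch(cf_case[loc], d_case[loc], cf_ctrl[loc], d_ctrl[loc], "greater")
        ps.append(np.atleast_1d(p))
    if not ps:
        return np.nan
    p = np.concatenate(ps)
    return float(np.mean(np.nan_to_num(p, nan=1.0) <= params.alpha))


def _pava_nondecreasing(y: np.ndarray):
    """Pool-adjacent-violators fit of a non-decreasing sequence.

    Returns the fitted values and, per position, the number of grid points
    pooled into its block (the effective replication of the estimate).
    """
    blocks = []  # [value, weight]
    for v in map(float, y):
        blocks.append([v, 1])
        while len(blocks) > 1 and blocks[-2][0] > blocks[-1][0]:
            v1, w1 = blocks.pop()
            v0, w0 = blocks.pop()
            blocks.append([(v0 * w0 + v1 * w1) / (w0 + w1), w0 + w1])
    fitted, pooled = [], []
    for v, w in blocks:
        fitted.extend([v] * w)
        pooled.extend([w] * w)
    return np.asarray(fitted), np.asarray(pooled, dtype=float)


def estimate_min_snp(
    cnv_type: str,
    cf: float,
    params: QualityParams,
    source,
    approach: str = "simulation",
    seed: int = 0,
    case_model: CoverageModel | None = None,
):
    """Smallest SNP count reaching the target sensitivity at cell fraction cf.

    ``source`` is a :class:`CoverageModel` (simulation approach) or the
    observed SNP table (exact approach). Returns an int from
    ``params.snp_range`` or None if no candidate attains ``target_sens``.

    The Monte-Carlo rejection rates are noisy while the true power is
    monotone in the SNP count, so the scanned rate curve is pooled by
    isotonic (non-decreasing) regression; the returned n is the smallest
    whose pooled rate minus one binomial standard error reaches the target,
    confirmed by two further grid points. Stopping at the first raw
    crossing instead systematically overstates the power at the returned n
    (selection on upward noise) and would break the sensitivity guarantee
    the thresholds exist to provide.
    """
    if approach not in ("simulation", "exact"):
        raise ValueError("approach must be 'simulation' or 'exact'")
    rates: list[float] = []
    candidate_idx = None
    ns = [int(n) for n in params.snp_range]
    for i, n in enumerate(ns):
        rng = _substream(seed, cnv_type, cf, n)
        if approach == "simulation":
            rate = _rejection_rate_sim(
                n, cnv_type, cf, source, case_model or source, params, rng
            )
        else:
            rate = _rejection_rate_exact(
                n, cnv_type, cf, source, params, rng, simulate_control_vaf=False
            )
        rates.append(0.0 if np.isnan(rate) else rate)
        iso, pooled = _pava_nondecreasing(np.asarray(rates))
        se = np.sqrt(np.clip(iso * (1.0 - iso), 0.0, None) / (pooled * params.n_reps))
        hits = np.flatnonzero(iso - se >= params.target_sens)
        candidate_idx = int(hits[0]) if hits.size else None
        if candidate_idx is not None and i - candidate_idx >= 2:
            return ns[candidate_idx]
    return ns[candidate_idx] if candidate_idx is not None else None


def window_size_for_n(positions_by_chrom: dict, n: int, percentile: float = 0.95):
    """Genomic span expected to contain >= n heterozygous SNPs.

    For every run of ``n`` consecutive SNPs on a chromosome the region length
    is ``pos[i+n-1] - pos[i] + 1``; the pooled ``percentile`` quantile of
    those lengths is the window size. Returns None when no chromosome holds
    ``n`` SNPs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lengths = []
    for pos in positions_by_chrom.values():
        pos = np.asarray(pos)
        if pos.size < n:
            continue
        lengths.append(pos[n - 1 :] - pos[: pos.size - n + 1] + 1)
    if not lengths:
        return None
    return float(np.quantile(np.concatenate(lengths), percentile))


def select_thresholds(table: pd.DataFrame, params: QualityParams):
    """Pick the operating point (cf_min, window_bp, min_snp) from the grid.

    trade_off (default): min-max normalise the window sizes of reachable
    entries to [0, 1] and pick the cf minimising |cf - w_norm| — the point
    where "low cell fraction" and "small window" balance. min_cf / min_w
    force the extreme of either axis. Ties break toward smaller cf.
    Returns None when no entry is reachable.
    """
    ok = table[(table["min_snp"] != UNREACHABLE) & table["window_bp"].notna()]
    if ok.empty:
        return None
    ok = ok.sort_values("cf")
    cf = ok["cf"].to_numpy(float)
    w = ok["window_bp"].to_numpy(float)
    if params.mode == MODE_MIN_CF:
        i = 0
    elif params.mode == MODE_MIN_W:
        i = int(np.lexsort((cf, w))[0])
    else:
        span = w.max() - w.min()
        w_norm = (w - w.min()) / span if span > 0 else np.zeros_like(w)
        i = int(np.lexsort((cf, np.abs(cf - w_norm)))[0])
    row = ok.iloc[i]
    return float(row["cf"]), float(row["window_bp"]), int(row["min_snp"])


def run_quality_analysis(
    snps: pd.DataFrame,
    params: QualityParams | None = None,
    approach: str = "simulation",
    seed: int = 0,
) -> dict:
    """Full step-1 analysis: one :class:`ThresholdProfile` per CNV type.

    ``snps`` is the gated heterozygous SNP table (columns chrom, pos,
    depth_control, alt_control, depth_case). For the simulation approach a
    log-normal coverage model is fitted to each sample's observed depths;
    the exact approach slides over the table itself. Window sizes always
    come from the observed SNP positions.
    """
    params = params or QualityParams()
    if snps.empty:
        raise ValueError("no SNPs available for quality analysis")
    snps = snps.reset_index(drop=True)
    positions = {c: g["pos"].to_numpy(np.int64) for c, g in snps.groupby("chrom", sort=False)}

    if approach == "simulation":
        control_model = fit_coverage_model(snps["depth_control"])
        case_model = fit_coverage_model(snps["depth_case"])
        source = control_model
    else:
        source = snps
        case_model = None

    profiles = {}
    for cnv_type in CNV_TYPES:
        rows = []
        w_cache: dict[int, float | None] = {}
        for cf in params.cf_grid:
            m = estimate_min_snp(
                cnv_type, float(cf), params, source, approach, seed, case_model
            )
            if m is None:
                rows.append((float(cf), UNREACHABLE, np.nan))
                continue
            if m not in w_cache:
                w_cache[m] = window_size_for_n(positions, m, params.percentile)
            w = w_cache[m]
            rows.append((float(cf), m, np.nan if w is None else w))
        table = pd.DataFrame(rows, columns=["cf", "min_snp", "window_bp"])
        sel = select_thresholds(table, params)
        if sel is None:
            profiles[cnv_type] = ThresholdProfile(cnv_type, None, None, None, table)
        else:
            cf_min, w, m = sel
            profiles[cnv_type] = ThresholdProfile(cnv_type, cf_min, w, m, table)
    return profiles
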