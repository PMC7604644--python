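"""End-to-end orchestration: gate -> thresholds -> scan -> calls -> merge -> filter."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import calling, postprocess, quality
from .io import RunConfig


@dataclass
class PipelineResult:
    """Everything one run produces, in order of derivation."""

    gated: pd.DataFrame
    thresholds: dict
    windows: list = field(default_factory=list)
    raw: list = field(default_factory=list)
    merged: list = field(default_factory=list)
    filtered: list = field(default_factory=list)


def run_pipeline(table: pd.DataFrame, config: RunConfig | None = None,
                 thresholds: dict | None = None) -> PipelineResult:
    """Run the full two-step analysis on a paired variant table.

    Precomputed thresholds may be supplied to skip step 1 (e.g. when calling
    repeatedly on panels from the same sample pair).
    """
    config = config or RunConfig()
    gated = calling.gate_snps(table, config.ci_level, config.include_chrX)
    if thresholds is None:
        thresholds = quality.run_quality_analysis(
            gated, config.quality_params(), config.approach, config.seed
        )

    windows: list = []
    for cnv_type in calling.CNV_TYPES:
        profile = thresholds[cnv_type]
        if not profile.reachable:
            continue
        windows.extend(
            calling.scan_windows(gated, cnv_type, profile.window_bp, config.per_test_alpha)
        )

    raw = calling.build_raw_calls(windows, gated, thresholds, config.cf_margin)
    blockers = [w for w in windows if w.verdict == calling.VERDICT_NO_CNV and w.support.size]
    merged = postprocess.merge_calls(raw, blockers, gated, thresholds, config.merge_params())
    filtered = postprocess.filter_calls(merged, config.quality_threshold)
    return PipelineResult(
        gated=gated, thresholds=thresholds, windows=windows,
        raw=raw, merged=merged, filtered=filtered,
    )
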