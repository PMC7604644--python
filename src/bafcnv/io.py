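"""Ingest, configuration and report writing.

The caller consumes per-site paired allele observations, not reads: either a
combined tab-separated SNP table or a pair of VCFs (control and case) from
any variant caller carrying allele-depth annotations. Heterozygosity is
re-derived downstream from the counts themselves (exact binomial CI), so the
upstream caller's genotype calls are irrelevant.

Coordinates are 1-based inclusive internally and in TSV reports; BED output
converts to 0-based half-open. Chromosome names are normalised by stripping
a leading "chr".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "depth_control", "alt_control", "depth_case", "alt_case",
]
# legacy aliases accepted on read
_COLUMN_ALIASES = {"alt_count_control": "alt_control", "alt_count_case": "alt_case"}

CALL_COLUMNS = [
    "chrom", "start", "end", "cnv_type", "cf", "cf_sd", "p_value", "quality",
    "n_snps", "cov_ind_low", "cov_ind_high", "cov_ind_class",
]


@dataclass
class RunConfig:
    """All user-facing knobs of the pipeline with their shipped defaults."""

    ci_level: float = 0.99
    family_alpha: float = 0.05
    n_hypotheses: int = 4
    cf_margin: float = 0.05
    quality_threshold: float = 10.76
    include_chrX: bool = False
    seed: int = 0
    approach: str = "simulation"
    target_sens: float = 0.95
    n_reps: int = 500
    percentile: float = 0.95
    mode: str = "trade_off"
    cf_grid_start: float = 0.05
    cf_grid_stop: float = 1.0
    cf_grid_step: float = 0.05
    max_snp: int = 100
    max_gap: int = 20_000_000
    cf_sd_mult: float = 3.0

    def __post_init__(self):
        for name in ("ci_level", "family_alpha", "target_sens", "percentile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.approach not in ("simulation", "exact"):
            raise ValueError("approach must be 'simulation' or 'exact'")

    @property
    def per_test_alpha(self) -> float:
        """Bonferroni-adjusted level over the 4 one-tailed hypothesis families."""
        return self.family_alpha / self.n_hypotheses

    def quality_params(self):
        from .quality import QualityParams

        grid = np.round(
            np.arange(self.cf_grid_start, self.cf_grid_stop + 1e-9, self.cf_grid_step), 10
        )
        return QualityParams(
            cf_grid=grid,
            snp_range=np.arange(1, self.max_snp + 1),
            n_reps=self.n_reps,
            target_sens=self.target_sens,
            alpha=self.per_test_alpha,
            percentile=self.percentile,
            mode=self.mode,
        )

    def merge_params(self):
        from .postprocess import MergeParams

        return MergeParams(
            max_gap=self.max_gap, cf_sd_mult=self.cf_sd_mult, cf_margin=self.cf_margin
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load overrides from a YAML or JSON mapping."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def normalize_chrom(name: str) -> str:
    n = str(name)
    return n[3:] if n.lower().startswith("chr") else n


def _finalize_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    # drop mitochondrial / alternate contigs; gonosome handling is downstream
    main = {str(i) for i in range(1, 23)} | {"X", "Y"}
    df = df[df["chrom"].isin(main)]
    for col in ("pos", "depth_control", "alt_control", "depth_case", "alt_case"):
        df[col] = df[col].astype(np.int64)
    bad = (df["alt_control"] > df["depth_control"]) | (df["alt_case"] > df["depth_case"])
    if bad.any():
        raise ValueError(
            f"alt count exceeds depth at rows {df.index[bad].tolist()[:5]}"
        )
    df = df.sort_values(["chrom", "pos", "alt"]).drop_duplicates(["chrom", "pos", "alt"])
    return df[TABLE_COLUMNS].reset_index(drop=True)


def read_snp_table(path) -> pd.DataFrame:
    """Read the combined TSV dialect (header: chrom, pos, ref, alt,
    depth_control, alt_control, depth_case, alt_case)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.rename(columns=_COLUMN_ALIASES)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df[["pos", "depth_control", "alt_control", "depth_case", "alt_case"]].isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: malformed row at line {bad + 2}")
    try:
        return _finalize_table(df)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def _vcf_observations(path) -> pd.DataFrame:
    """Extract per-site depth/alt-count from the first sample of a VCF.

    Allele-depth (AD) fields are preferred; without AD the total depth
    (DP) is used with a warning and the alt count taken from AO if present.
    Multi-allelic records are split into one row per alternate allele.
    """
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    if len(vcf.samples) < 1:
        raise ValueError(f"{path}: VCF has no sample columns")
    warned = False
    for rec in vcf:
        ad = rec.format("AD")
        for ai, alt in enumerate(rec.ALT):
            if ad is not None:
                counts = ad[0]
                ref_n = max(int(counts[0]), 0)
                alt_n = max(int(counts[ai + 1]), 0) if len(counts) > ai + 1 else 0
                depth = ref_n + sum(max(int(c), 0) for c in counts[1:])
            else:
                if not warned:
                    logger.warning("%s: no AD field; falling back to DP/AO", path)
                    warned = True
                dp = rec.format("DP")
                ao = rec.format("AO")
                if dp is None:
                    raise ValueError(f"{path}: neither AD nor DP FORMAT field present")
                depth = int(dp[0][0])
                alt_n = int(ao[0][ai]) if ao is not None else 0
            if depth <= 0:
                continue
            rows.append((rec.CHROM, rec.POS, rec.REF, alt, depth, min(alt_n, depth)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "depth", "alt_count"])


def read_pair_vcf(control_path, case_path) -> pd.DataFrame:
    """Join a control and a case VCF on (chrom, pos, ref, alt).

    Sites present in only one file are dropped with a logged count (the
    test needs both observations).
    """
    ctrl = _vcf_observations(control_path).rename(
        columns={"depth": "depth_control", "alt_count": "alt_control"}
    )
    case = _vcf_observations(case_path).rename(
        columns={"depth": "depth_case", "alt_count": "alt_case"}
    )
    merged = ctrl.merge(case, on=["chrom", "pos", "ref", "alt"], how="inner")
    lost = max(len(ctrl), len(case)) - len(merged)
    if lost:
        logger.warning("%d sites present in only one VCF were dropped", lost)
    if merged.empty:
        raise ValueError("no shared sites between control and case VCFs")
    return _finalize_table(merged)


def write_snp_table(df: pd.DataFrame, path) -> None:
    df[TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def thresholds_frame(profiles: dict) -> pd.DataFrame:
    rows = []
    for cnv_type, prof in profiles.items():
        for _, r in prof.table.iterrows():
            rows.append({
                "cnv_type": cnv_type,
                "cf": r["cf"],
                "min_snp": int(r["min_snp"]),
                "window_bp": r["window_bp"],
                "reachable": r["min_snp"] >= 0 and np.isfinite(r["window_bp"]),
                "selected": prof.reachable and r["cf"] == prof.cf_min,
            })
    return pd.DataFrame(rows)


def write_thresholds(profiles: dict, path) -> None:
    thresholds_frame(profiles).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_thresholds(path) -> dict:
    """Rebuild ThresholdProfile objects from a threshold report TSV."""
    from .quality import ThresholdProfile

    df = pd.read_csv(path, sep="\t")
    profiles = {}
    for cnv_type, grp in df.groupby("cnv_type"):
        table = grp[["cf", "min_snp", "window_bp"]].reset_index(drop=True)
        sel = grp[grp["selected"]]
        if sel.empty:
            profiles[cnv_type] = ThresholdProfile(cnv_type, None, None, None, table)
        else:
            r = sel.iloc[0]
            profiles[cnv_type] = ThresholdProfile(
                cnv_type, float(r["cf"]), float(r["window_bp"]), int(r["min_snp"]), table
            )
    return profiles


def calls_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {k: getattr(c, k) for k in CALL_COLUMNS}
        for extra in ("n_raw", "below_threshold_flag"):
            if hasattr(c, extra):
                row[extra] = getattr(c, extra)
        rows.append(row)
    cols = CALL_COLUMNS + [c for c in ("n_raw", "below_threshold_flag") if rows and c in rows[0]]
    return pd.DataFrame(rows, columns=cols if rows else CALL_COLUMNS)


def write_calls(calls, path) -> None:
    calls_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_bed(calls, path) -> None:
    """BED export: 0-based half-open, name = type:cf, score = min(1000, quality*10)."""
    with open(path, "w") as fh:
        for c in calls:
            score = int(min(1000, round(c.quality * 10)))
            fh.write(
                f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.cnv_type}:{c.cf:.4f}\t{score}\n"
            )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: RunConfig, inputs: list, out_path) -> None:
    manifest = {
        "config": asdict(config),
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
    }
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_reports(thresholds, raw, merged, filtered, out_dir, config=None, inputs=()):
    """Write the full deterministic report set into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_thresholds(thresholds, out / "thresholds.tsv")
    write_calls(raw, out / "raw_calls.tsv")
    write_calls(merged, out / "merged_calls.tsv")
    write_calls(filtered, out / "filtered_calls.tsv")
    write_bed(filtered, out / "filtered_calls.bed")
    if config is not None:
        write_manifest(config, list(inputs), out / "manifest.json")
    return out
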