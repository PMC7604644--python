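"""Synthetic matched case/control SNP panels with implanted CNVs.

Emulates what the pipeline actually consumes from a matched whole-exome
pair: per-site depths (log-normal, independently per sample), binomial
allele counts around VAF 0.5 in the control, exon-like *clustered* SNP
positions (heterozygous SNPs are not uniform along the genome — capture
targets bunch them), and deletions/duplications implanted at specified cell
fractions. A machine-readable truth set is emitted beside every panel so
detection and CF recovery can be scored exactly.

Inside an event of type ``t`` at cell fraction ``cf``, the case VAF
expectation is ``expected_vaf(t, cf)`` or its mirror ``1 - expected_vaf``
depending on which haplotype the event hit; the haplotype is drawn once per
event, producing the realistic mixture of 33%- and 67%-centred SNP tracks
across events.

Not modelled: read-level errors (the caller consumes allele counts, not
reads), GC/mappability bias, germline CNVs and contamination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CNV_TYPES, CoverageModel, expected_vaf

_BASES = np.array(list("ACGT"))


def _default_chroms() -> dict:
    return {"1": 120_000_000, "2": 100_000_000}


def _default_coverage() -> dict:
    m = CoverageModel(meanlog=float(np.log(100.0)), sdlog=0.5)
    return {"control": m, "case": m}


@dataclass
class SimSpec:
    """Parameters of one synthetic panel.

    snp_density is heterozygous SNPs per Mb (~3.5/Mb matches the per-sample
    het-SNP yield of typical exomes); clustering is controlled by the mean
    number of SNPs per cluster and the mean within-cluster gap in bp.
    ``cnvs`` is a list of (chrom, start, end, cnv_type, cf) tuples.
    """

    chrom_lengths: dict = field(default_factory=_default_chroms)
    snp_density: float = 3.5
    coverage: dict = field(default_factory=_default_coverage)
    cnvs: list = field(default_factory=list)
    seed: int = 0
    cluster_size_mean: float = 3.0
    cluster_gap_mean: float = 150.0

    def __post_init__(self):
        seen = {t: [] for t in CNV_TYPES}
        for chrom, start, end, cnv_type, cf in self.cnvs:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"CNV on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= self.chrom_lengths[chrom]):
                raise ValueError("CNV interval outside chromosome bounds")
            if not 0 < cf <= 1:
                raise ValueError("CNV cell fraction must lie in (0, 1]")
            for s, e in seen[cnv_type]:
                if chrom == s[0] and not (end < s[1] or start > e):
                    raise ValueError("same-type CNV intervals must not overlap")
            seen[cnv_type].append(((chrom, start), end))


@dataclass
class SyntheticTruth:
    """Implanted events plus per-SNP annotation (event index, haplotype)."""

    cnvs: list
    snp_event: np.ndarray   # -1 outside any event, else index into cnvs
    haplotypes: list        # per event: 0 -> minor-allele track, 1 -> mirrored

    def to_json(self) -> str:
        return json.dumps(
            {
                "cnvs": [
                    {"chrom": c, "start": int(s), "end": int(e), "cnv_type": t, "cf": float(f)}
                    for c, s, e, t, f in self.cnvs
                ],
                "haplotypes": [int(h) for h in self.haplotypes],
                "snp_event": [int(i) for i in self.snp_event],
            },
            indent=0,
        )


def _clustered_positions(length: int, density: float, size_mean: float,
                         gap_mean: float, rng: np.random.Generator) -> np.ndarray:
    """Bursty point process: Poisson cluster count, geometric cluster sizes
    and within-cluster gaps — a cheap stand-in for exon targeting."""
    expected = density * length / 1e6
    n_clusters = rng.poisson(max(expected / size_mean, 1.0))
    if n_clusters == 0:
        return np.empty(0, dtype=np.int64)
    centers = np.sort(rng.integers(1, length + 1, size=n_clusters))
    sizes = rng.geometric(1.0 / size_mean, size=n_clusters)
    pos = []
    for c, k in zip(centers, sizes):
        gaps = rng.geometric(1.0 / gap_mean, size=k)
        pos.append(c + np.cumsum(gaps) - gaps[0])
    pos = np.concatenate(pos)
    pos = pos[(pos >= 1) & (pos <= length)]
    return np.unique(pos)


def generate_panel(spec: SimSpec):
    """Generate a paired variant table and its ground truth.

    Returns ``(table, truth)``; the table has the combined-TSV columns
    (chrom, pos, ref, alt, depth_control, alt_control, depth_case,
    alt_case) and is byte-stable for a fixed spec/seed.
    """
    rng = np.random.default_rng(spec.seed)
    haplotypes = [int(rng.integers(0, 2)) for _ in spec.cnvs]

    frames = []
    events = []
    for chrom in sorted(spec.chrom_lengths, key=str):
        length = spec.chrom_lengths[chrom]
        pos = _clustered_positions(
            length, spec.snp_density, spec.cluster_size_mean, spec.cluster_gap_mean, rng
        )
        if pos.size == 0:
            continue
        n = pos.size
        d_ctrl = spec.coverage["control"].sample(rng, n)
        d_case = spec.coverage["case"].sample(rng, n)
        a_ctrl = rng.binomial(d_ctrl, 0.5)

        v_case = np.full(n, 0.5)
        event_id = np.full(n, -1, dtype=np.int64)
        for k, (c, start, end, cnv_type, cf) in enumerate(spec.cnvs):
            if str(c) != str(chrom):
                continue
            inside = (pos >= start) & (pos <= end)
            v = expected_vaf(cnv_type, cf)
            v_case[inside] = v if haplotypes[k] == 0 else 1.0 - v
            event_id[inside] = k
        a_case = rng.binomial(d_case, v_case)

        ref_idx = rng.integers(0, 4, size=n)
        ref = _BASES[ref_idx]
        alt = _BASES[(ref_idx + rng.integers(1, 4, size=n)) % 4]
        frames.append(pd.DataFrame({
            "chrom": str(chrom), "pos": pos, "ref": ref, "alt": alt,
            "depth_control": d_ctrl, "alt_control": a_ctrl,
            "depth_case": d_case, "alt_case": a_case,
        }))
        events.append(event_id)

    if not frames:
        raise ValueError("spec produced no SNPs")
    table = pd.concat(frames, ignore_index=True)
    truth = SyntheticTruth(
        cnvs=list(spec.cnvs), snp_event=np.concatenate(events), haplotypes=haplotypes
    )
    return table, truth


def recovery_harness(spec: SimSpec, config=None, thresholds=None):
    """Run the full pipeline on a generated panel and score it against truth.

    A call is a true positive if it overlaps >= 1 implanted event of the
    same type; an event counts as *detectable* only when the sample's own
    thresholds admit it (cf above the type's minimum CF and span at least
    the window size). Returns per-event rows plus sensitivity (over
    detectable events), PPV, and CF recovery errors.
    """
    from .pipeline import run_pipeline
    from .io import RunConfig

    config = config or RunConfig(seed=spec.seed)
    table, truth = generate_panel(spec)
    result = run_pipeline(table, config, thresholds=thresholds)
    calls = result.merged

    rows = []
    for (chrom, start, end, cnv_type, cf) in truth.cnvs:
        profile = result.thresholds[cnv_type]
        detectable = bool(
            profile.reachable
            and cf >= profile.cf_min
            and (end - start + 1) >= profile.window_bp
        )
        overlapping = [
            c for c in calls
            if c.cnv_type == cnv_type and c.chrom == str(chrom)
            and c.start <= end and c.end >= start
        ]
        if overlapping:
            best = max(overlapping, key=lambda c: min(c.end, end) - max(c.start, start))
            ov = (min(best.end, end) - max(best.start, start) + 1) / (end - start + 1)
            cf_err = best.cf - cf
        else:
            ov, cf_err = 0.0, np.nan
        rows.append({
            "chrom": str(chrom), "start": start, "end": end, "cnv_type": cnv_type,
            "cf_true": cf, "detectable": detectable, "detected": bool(overlapping),
            "overlap_fraction": ov, "cf_error": cf_err,
        })
    report = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "cnv_type", "cf_true", "detectable",
                 "detected", "overlap_fraction", "cf_error"],
    )

    n_true_calls = sum(
        any(r["cnv_type"] == c.cnv_type and r["chrom"] == c.chrom
            and c.start <= r["end"] and c.end >= r["start"] for _, r in report.iterrows())
        for c in calls
    )
    detectable = report[report["detectable"]]
    sens = float(detectable["detected"].mean()) if len(detectable) else np.nan
    ppv = n_true_calls / len(calls) if calls else np.nan
    return {
        "events": report,
        "sensitivity": sens,
        "ppv": ppv,
        "n_calls": len(calls),
        "result": result,
    }
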