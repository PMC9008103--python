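"""Endpoint extraction and comparison statistics.

The endpoint is the striatal non-displaceable binding potential
(BP_ND) from an SRTM fit with the cerebellum as reference.  Endpoints
from two scanners (or two sessions) are compared with the percent
difference

    PD = 100 * |a - b| / ((a + b) / 2)

which serves both the inter-scanner comparison and the within-scanner
test-retest comparison (PD_T/RT) — one formula, two call sites.  The
report aggregates per-subject PDs into means +- SD (sample SD, n-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonization import DynamicImage
from .kinetics import SRTMFitConfig, TAC, srtm_fit

log = logging.getLogger(__name__)

__all__ = [
    "EndpointRecord",
    "extract_roi_tac",
    "compute_bp",
    "percent_difference",
    "validation_report",
    "CONDITIONS",
]

#: Canonical condition labels for the validation study.
CONDITIONS = ("hires", "hires_harmonized", "lores", "test", "retest")


@dataclass(frozen=True)
class EndpointRecord:
    """One striatal BP_ND measurement: subject, condition, value."""

    subject: str
    condition: str
    bp_nd: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.bp_nd):
            raise ValueError(f"bp_nd must be finite, got {self.bp_nd}")


def extract_roi_tac(dyn: DynamicImage, mask: np.ndarray) -> TAC:
    """Per-frame unweighted mean over the mask voxels."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        mask = mask > 0
    if mask.shape != dyn.dims:
        raise ValueError(f"mask shape {mask.shape} does not match image {dyn.dims}")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    values = dyn.values[mask].mean(axis=0)
    return TAC(dyn.schedule, values)


def compute_bp(
    dyn: DynamicImage,
    striatum_mask: np.ndarray,
    cereb_mask: np.ndarray,
    config: SRTMFitConfig | None = None,
) -> float:
    """Striatal BP_ND: extract the striatum and cerebellum TACs and fit SRTM."""
    target = extract_roi_tac(dyn, striatum_mask)
    ref = extract_roi_tac(dyn, cereb_mask)
    fit = srtm_fit(target, ref, config)
    log.info(
        "compute_bp: BP_ND=%.4f R1=%.4f k2=%.4f k2a=%.4g RSS=%.4g",
        fit.params.bp_nd, fit.params.r1, fit.params.k2, fit.k2a, fit.rss,
    )
    return fit.params.bp_nd


def percent_difference(bp_a: float, bp_b: float, signed: bool = False) -> float:
    """Percent difference relative to the pair mean.

    ``PD = 100 * |a - b| / ((a + b) / 2)``; with ``signed=True`` the
    absolute value is not taken (positive when a > b).
    """
    mean = (bp_a + bp_b) / 2.0
    if mean <= 0:
        raise ValueError(f"mean of the pair must be > 0, got {mean}")
    diff = bp_a - bp_b
    if not signed:
        diff = abs(diff)
    return 100.0 * diff / mean


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def validation_report(records, outdir=None):
    """Aggregate endpoint records into the study's comparison tables.

    Expects, per inter-scanner subject, conditions ``hires``,
    ``hires_harmonized`` and ``lores``; test-retest subjects carry
    ``test`` and ``retest``.  Incomplete subjects are skipped and
    listed.  Writes per-subject and summary TSV tables and a plot when
    ``outdir`` is given; returns a dict of DataFrames and summary stats.
    """
    df = pd.DataFrame(
        [
            {"subject": r.subject, "condition": r.condition, "bp_nd": r.bp_nd}
            for r in records
        ]
    )
    if df.empty:
        raise ValueError("no endpoint records supplied")
    dup = df.duplicated(subset=["subject", "condition"])
    if dup.any():
        raise ValueError("condition labels must be unique per subject")

    wide = df.pivot(index="subject", columns="condition", values="bp_nd")

    inter_rows, trt_rows, skipped = [], [], []
    for subject, row in wide.iterrows():
        has_inter = all(
            c in row and np.isfinite(row.get(c, np.nan))
            for c in ("hires", "hires_harmonized", "lores")
        )
        has_trt = all(
            c in row and np.isfinite(row.get(c, np.nan)) for c in ("test", "retest")
        )
        if has_inter:
            inter_rows.append(
                {
                    "subject": subject,
                    "bp_hires": row["hires"],
                    "bp_hires_harmonized": row["hires_harmonized"],
                    "bp_lores": row["lores"],
                    "pd_unfiltered": percent_difference(row["hires"], row["lores"]),
                    "pd_harmonized": percent_difference(
                        row["hires_harmonized"], row["lores"]
                    ),
                }
            )
        if has_trt:
            trt_rows.append(
                {
                    "subject": subject,
                    "bp_test": row["test"],
                    "bp_retest": row["retest"],
                    "pd_trt": percent_difference(row["test"], row["retest"]),
                }
            )
        if not has_inter and not has_trt:
            skipped.append(subject)
            log.warning("subject %s lacks a complete condition set; skipped", subject)

    inter = pd.DataFrame(inter_rows)
    trt = pd.DataFrame(trt_rows)

    summary_rows = []
    if not inter.empty:
        for col, label in (
            ("pd_unfiltered", "PD unfiltered"),
            ("pd_harmonized", "PD harmonized"),
        ):
            m, s = _mean_sd(inter[col])
            summary_rows.append(
                {"metric": label, "mean": m, "sd": s, "n": len(inter)}
            )
    if not trt.empty:
        m, s = _mean_sd(trt["pd_trt"])
        summary_rows.append({"metric": "PD test-retest", "mean": m, "sd": s, "n": len(trt)})
    summary = pd.DataFrame(summary_rows)

    out = {
        "records": df,
        "interscanner": inter,
        "test_retest": trt,
        "summary": summary,
        "skipped_subjects": skipped,
    }
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "endpoints.tsv", sep="\t", index=False)
        inter.to_csv(outdir / "interscanner_pd.tsv", sep="\t", index=False)
        trt.to_csv(outdir / "test_retest_pd.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        if skipped:
            (outdir / "skipped_subjects.txt").write_text("\n".join(skipped) + "\n")
        _plot_report(inter, trt, outdir / "pd_comparison.png")
    return out


def _plot_report(inter: pd.DataFrame, trt: pd.DataFrame, path):
    """Strip plot of per-subject PDs: unfiltered and harmonized
    inter-scanner differences next to the test-retest benchmark."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    groups = []
    if not inter.empty:
        groups += [
            ("unfiltered", inter["pd_unfiltered"].to_numpy(), "o"),
            ("harmonized", inter["pd_harmonized"].to_numpy(), "s"),
        ]
    if not trt.empty:
        groups.append(("test-retest", trt["pd_trt"].to_numpy(), "^"))
    for i, (label, vals, marker) in enumerate(groups):
        x = np.full(len(vals), i, dtype=float)
        ax.plot(x, vals, marker, ls="", alpha=0.7, label=label)
        ax.hlines(vals.mean(), i - 0.25, i + 0.25, color="k")
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels([g[0] for g in groups])
    ax.set_ylabel("percent difference in striatal BP$_{ND}$ (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
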