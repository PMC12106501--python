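"""Scoring calls against truth labels and cohort-level reporting.

Ambiguous and no-call samples are excluded from the 2x2 confusion table —
they were never classified — but are always counted and reported
alongside it, so precision/sensitivity cannot be inflated by silently
discarding hard samples.  Ratios with empty denominators are reported as
undefined (None), never as 0.

Percentages are rounded half-up at fixed precisions (prevalence to three
decimals, proportions to whole percent), with the raw fractions retained
next to every rounded figure.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .caller import CallSet
from .intensity_io import SampleManifest, TRUTH_LABELS

__all__ = ["ConfusionSummary", "confusion", "summarize_run", "round_half_up"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionSummary:
    """Exact confusion counts plus derived precision/sensitivity."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_ambiguous_excluded: int
    n_no_call: int

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def n_with_truth(self) -> int:
        return (self.tp + self.fp + self.tn + self.fn
                + self.n_ambiguous_excluded + self.n_no_call)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["ppv"] = self.ppv
        d["sensitivity"] = self.sensitivity
        return d


def confusion(calls: CallSet, truth: pd.Series) -> ConfusionSummary:
    """Score calls against a sample_id -> {carrier, negative} truth series.

    Only samples present in ``truth`` (non-missing label) are scored.
    Ambiguous and no_call samples among them are tallied separately and
    excluded from the 2x2 table.
    """
    truth = truth.dropna()
    if len(truth) == 0:
        raise ValueError("no samples with truth labels")
    bad = truth[~truth.isin(TRUTH_LABELS)]
    if len(bad):
        raise ValueError(
            f"truth label {bad.iloc[0]!r} not in {TRUTH_LABELS}"
        )
    df = calls.frame.merge(
        truth.rename("truth"), left_on="sample_id", right_index=True,
        how="inner",
    )
    call, t = df["call"], df["truth"]
    return ConfusionSummary(
        tp=int(((call == "carrier") & (t == "carrier")).sum()),
        fp=int(((call == "carrier") & (t == "negative")).sum()),
        tn=int(((call == "negative") & (t == "negative")).sum()),
        fn=int(((call == "negative") & (t == "carrier")).sum()),
        n_ambiguous_excluded=int((call == "ambiguous").sum()),
        n_no_call=int((call == "no_call").sum()),
    )


def summarize_run(calls: CallSet, manifest: SampleManifest) -> dict:
    """Cohort report: call-class counts, prevalence, per-array-version
    breakdown, and the fraction of called carriers already labelled as
    carriers in the manifest (the previously-identified analogue)."""
    n = len(calls)
    counts = calls.counts
    n_car = counts["carrier"]
    report: dict = {
        "n_samples": n,
        "counts": counts,
        "prevalence_raw": n_car / n if n else 0.0,
        "prevalence_pct": round_half_up(100.0 * n_car / n, 3) if n else 0.0,
        "thresholds": {"diff_max": calls.thresholds.diff_max,
                       "mad_max": calls.thresholds.mad_max,
                       "provenance": calls.thresholds.provenance},
    }

    merged = calls.frame.merge(manifest.frame, on="sample_id", how="left")
    by_version = (
        merged.groupby("array_version")["call"].value_counts().unstack(fill_value=0)
    )
    report["by_array_version"] = {
        str(v): {k: int(row.get(k, 0)) for k in counts}
        for v, row in by_version.iterrows()
    }

    if n_car > 0:
        carriers = merged[merged["call"] == "carrier"]
        n_known = int((carriers["truth_label"] == "carrier").sum())
        report["carriers_previously_identified"] = {
            "n": n_known,
            "raw": n_known / n_car,
            "pct": round_half_up(100.0 * n_known / n_car, 0),
        }
        report["carriers_novel"] = {
            "n": n_car - n_known,
            "raw": (n_car - n_known) / n_car,
            "pct": round_half_up(100.0 * (n_car - n_known) / n_car, 0),
        }
    return report


def render_report(report: dict, conf: ConfusionSummary | None = None) -> str:
    """Human-readable text block for a cohort run."""
    lines = [
        f"samples analyzed: {report['n_samples']}",
        "calls: " + ", ".join(f"{k}={v}" for k, v in report["counts"].items()),
        f"carrier prevalence: {report['prevalence_pct']:.3f}% "
        f"(raw {report['prevalence_raw']:.6g})",
        f"thresholds: diff_max={report['thresholds']['diff_max']:g}, "
        f"mad_max={report['thresholds']['mad_max']:g} "
        f"({report['thresholds']['provenance']})",
    ]
    for v, row in sorted(report["by_array_version"].items()):
        lines.append(f"  array {v}: " + ", ".join(f"{k}={n}" for k, n in row.items()))
    if "carriers_previously_identified" in report:
        pi = report["carriers_previously_identified"]
        nov = report["carriers_novel"]
        lines.append(
            f"carriers previously identified: {pi['n']} ({pi['pct']:.0f}%); "
            f"novel: {nov['n']} ({nov['pct']:.0f}%)"
        )
    if conf is not None:
        ppv = "undefined" if conf.ppv is None else f"{100 * conf.ppv:.0f}%"
        sens = ("undefined" if conf.sensitivity is None
                else f"{100 * conf.sensitivity:.0f}%")
        lines.append(
            f"truth evaluation: tp={conf.tp} fp={conf.fp} tn={conf.tn} "
            f"fn={conf.fn} ambiguous_excluded={conf.n_ambiguous_excluded} "
            f"no_call={conf.n_no_call}; PPV={ppv}, sensitivity={sens}"
        )
    return "\n".join(lines) + "\n"
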