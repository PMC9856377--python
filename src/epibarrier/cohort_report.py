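"""Two-group statistics and end-to-end cohort orchestration.

Per-subject metrics from every modality are compared between arms with
Student's t-test (pooled-variance by default, Welch by option). Values are
reported as mean and SD, and significance is labelled with the three-star
convention: n.s. (p >= 0.05), * (p < 0.05), ** (p < 0.01), *** (p < 0.001).
No multiple-testing correction is applied across metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .impedance import OnePathModel
from .morphometry import apoptosis_rate, surface_ratio
from .permeability import fit_calibration, flux_from_series
from .tj_localization import aggregate_subject, ttj_btj_ratio
from .transport import amiloride_jna, baseline_isc, bumetanide_response, isc_to_molar_flux

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "significance_label",
    "two_group_ttest",
    "ttest_from_summary",
    "analyze_subject",
    "analyze_cohort",
    "run_pipeline",
    "CohortReport",
]


def significance_label(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass(frozen=True)
class GroupComparison:
    """One metric compared between two groups."""

    metric: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    label: str
    variant: str

    def __post_init__(self):
        if self.label != significance_label(self.p_value):
            raise ValidationError("significance label inconsistent with p-value")


def ttest_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "pooled",
    metric: str = "",
) -> GroupComparison:
    """Two-sided t-test from group summaries (mean, SD, n).

    For the pooled variant this is algebraically identical to running
    :func:`two_group_ttest` on any raw data with these summaries.
    """
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValidationError("SDs must be >= 0")
    va, vb = sd_a**2, sd_b**2
    if variant == "pooled":
        df = n_a + n_b - 2
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    elif variant == "welch":
        se = np.sqrt(va / n_a + vb / n_b)
        df = (va / n_a + vb / n_b) ** 2 / (
            (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
        ) if se > 0 else n_a + n_b - 2
    else:
        raise ValidationError(f"unknown variant {variant!r}; use 'pooled' or 'welch'")
    if se == 0:
        t = 0.0 if mean_a == mean_b else np.inf * np.sign(mean_a - mean_b)
        p = 1.0 if mean_a == mean_b else 0.0
    else:
        t = (mean_a - mean_b) / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return GroupComparison(
        metric=metric,
        mean_a=float(mean_a), sd_a=float(sd_a), n_a=int(n_a),
        mean_b=float(mean_b), sd_b=float(sd_b), n_b=int(n_b),
        t_statistic=float(t), p_value=float(p),
        label=significance_label(float(p)), variant=variant,
    )


def two_group_ttest(values_a, values_b, variant: str = "pooled",
                    metric: str = "") -> GroupComparison:
    """Two-sided Student's t-test on raw per-subject values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("values must be finite")
    return ttest_from_summary(
        float(a.mean()), float(a.std(ddof=1)), a.size,
        float(b.mean()), float(b.std(ddof=1)), b.size,
        variant=variant, metric=metric,
    )


# --------------------------------------------------------------------------
# per-subject metric extraction


def analyze_subject(subj) -> dict[str, float]:
    """Compute every available per-subject metric; missing modalities are
    skipped with a logged warning."""
    metrics: dict[str, float] = {}

    def attempt(name, fn):
        try:
            metrics[name] = float(fn())
        except Exception as exc:  # noqa: BLE001 - per-metric isolation by design
            logger.warning("subject %s: metric %s skipped (%s)",
                           subj.subject_id, name, exc)

    if subj.spectrum is not None:
        try:
            fit = OnePathModel(subj.spectrum).fit()
            metrics["r_epi"] = fit.r_epi
            metrics["r_sub"] = fit.r_sub
            metrics["r_t"] = fit.r_t
            metrics["cap_uf"] = fit.cap * 1e6
        except Exception as exc:  # noqa: BLE001
            logger.warning("subject %s: impedance fit skipped (%s)",
                           subj.subject_id, exc)
    if subj.isc_trace is not None:
        attempt("baseline_isc", lambda: baseline_isc(subj.isc_trace))
        attempt("delta_isc_bumetanide",
                lambda: bumetanide_response(subj.isc_trace).delta_isc)
    if subj.enac_trace is not None:
        attempt("j_na", lambda: isc_to_molar_flux(
            amiloride_jna(subj.enac_trace).delta_isc))
    for tracer, pair in subj.flux.items():
        series, cal = pair
        def _perm(series=series, cal=cal):
            calib = None
            if cal is not None:
                calib = fit_calibration(cal.concentrations, cal.readings)
            return flux_from_series(series, calib).permeability_cm_s
        attempt(f"p_{tracer}", _perm)
    if subj.profiles:
        def _ratio():
            by_section: dict[str, list[float]] = {}
            for p in subj.profiles:
                r, _ = ttj_btj_ratio(p)
                by_section.setdefault(p.section_id or "S1", []).append(r)
            return aggregate_subject(by_section, subj.subject_id).subject_mean
        attempt("ttj_ratio", _ratio)
    if subj.geometry is not None:
        attempt("surface_ratio", lambda: surface_ratio(subj.geometry))
    if subj.nuclei is not None:
        attempt("apoptosis_rate", lambda: apoptosis_rate(subj.nuclei))
    return metrics


#: Metrics compared between arms, in report order.
REPORT_METRICS = (
    "baseline_isc", "delta_isc_bumetanide", "j_na",
    "r_t", "r_sub", "r_epi", "cap_uf",
    "p_fluorescein", "p_fd4",
    "ttj_ratio", "surface_ratio", "apoptosis_rate",
)


@dataclass
class CohortReport:
    """Result bundle of the end-to-end pipeline."""

    metrics: pd.DataFrame  # one row per subject
    comparisons: pd.DataFrame  # one row per metric
    regulators: pd.DataFrame | None = None

    def comparison(self, metric: str) -> pd.Series:
        row = self.comparisons[self.comparisons["metric"] == metric]
        if row.empty:
            raise ValidationError(f"metric {metric!r} not in the report")
        return row.iloc[0]

    def summary(self) -> str:
        lines = ["Cohort group comparison (control vs IBS-M)", "-" * 78]
        lines.append(f"{'metric':<22}{'control':>18}{'IBS-M':>18}{'p':>10}  label")
        for _, r in self.comparisons.iterrows():
            lines.append(
                f"{r['metric']:<22}"
                f"{r['mean_control']:>11.4g} ± {r['sd_control']:<6.3g}"
                f"{r['mean_ibsm']:>11.4g} ± {r['sd_ibsm']:<6.3g}"
                f"{r['p_value']:>8.3g}  {r['label']}"
            )
        if self.regulators is not None and len(self.regulators):
            lines.append("")
            lines.append("Top upstream regulators (overlap p ascending)")
            for _, r in self.regulators.head(5).iterrows():
                lines.append(
                    f"  {r['regulator']:<8} p={r['overlap_p']:.3g}  z={r['z_score']:.2f}"
                    f"  overlap {r['n_overlap']}/{r['n_targets']}"
                )
        return "\n".join(lines)

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics_per_subject.tsv", sep="\t", index=False)
        self.comparisons.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
        if self.regulators is not None:
            self.regulators.to_csv(out / "regulators.tsv", sep="\t", index=False)
        summary = {
            "n_subjects": int(len(self.metrics)),
            "comparisons": self.comparisons.to_dict(orient="records"),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        (out / "run.log").write_text(self.summary() + "\n")
        return out


def analyze_cohort(cohort, variant: str = "pooled",
                   enrichment_kwargs: dict | None = None) -> CohortReport:
    """Per-subject metrics, two-group comparisons and (optional) regulator
    ranking for a simulated or loaded cohort."""
    rows = []
    for subj in cohort.subjects:
        row = {"subject": subj.subject_id, "group": subj.group}
        row.update(analyze_subject(subj))
        rows.append(row)
    metrics = pd.DataFrame(rows)

    comparisons = []
    for metric in REPORT_METRICS:
        if metric not in metrics.columns:
            logger.warning("metric %s missing for all subjects; skipped", metric)
            continue
        a = metrics.loc[metrics["group"] == "control", metric].dropna()
        b = metrics.loc[metrics["group"] == "ibsm", metric].dropna()
        if len(a) < 2 or len(b) < 2:
            logger.warning("metric %s: not enough subjects per group; skipped", metric)
            continue
        c = two_group_ttest(a, b, variant=variant, metric=metric)
        comparisons.append({
            "metric": metric,
            "mean_control": c.mean_a, "sd_control": c.sd_a, "n_control": c.n_a,
            "mean_ibsm": c.mean_b, "sd_ibsm": c.sd_b, "n_ibsm": c.n_b,
            "t_statistic": c.t_statistic, "p_value": c.p_value,
            "label": c.label, "variant": c.variant,
        })
    comparisons_df = pd.DataFrame(
        comparisons,
        columns=["metric", "mean_control", "sd_control", "n_control",
                 "mean_ibsm", "sd_ibsm", "n_ibsm", "t_statistic", "p_value",
                 "label", "variant"],
    )

    regulators = None
    if cohort.de_table is not None and cohort.network is not None:
        from .enrichment_stats import rank_regulators

        try:
            ranked = rank_regulators(cohort.de_table, cohort.network,
                                     **(enrichment_kwargs or {}))
            regulators = pd.DataFrame([
                {k: v for k, v in asdict(r).items() if k != "target_directions"}
                for r in ranked
            ])
        except ValidationError as exc:
            logger.warning("regulator ranking skipped (%s)", exc)

    return CohortReport(metrics=metrics, comparisons=comparisons_df,
                        regulators=regulators)


def run_pipeline(cohort_or_dir, out_dir=None, variant: str = "pooled") -> CohortReport:
    """End-to-end: load (or accept) a cohort, compute all metrics and group
    comparisons, optionally write the report bundle."""
    from .synthetic_data import CohortData, load_cohort

    cohort = cohort_or_dir if isinstance(cohort_or_dir, CohortData) \
        else load_cohort(cohort_or_dir)
    report = analyze_cohort(cohort, variant=variant)
    if out_dir is not None:
        report.write(out_dir)
    return report
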