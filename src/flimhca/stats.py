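"""Per-strain lifetime statistics and query-vs-control comparisons.

Image-wise lifetimes that pass QC are pooled per strain (across wells,
plates and runs), summarized with box-plot conventions (median, quartiles
by linear interpolation, notch-style 95% CI of the median, whiskers at
1.5 x IQR), and each query strain is compared against the single
donor-only negative control of its group with a two-sided Wilcoxon
rank-sum test.  Within a group of m query strains the significance level
alpha = 0.05 is Bonferroni-corrected to alpha/m; positive controls are
tested identically but never counted in m.  Comparisons never cross
groups.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .plate_io import PlateLayout

log = logging.getLogger(__name__)

__all__ = [
    "StrainSummary",
    "GroupComparison",
    "ALPHA",
    "summarize_strain",
    "rank_sum_test",
    "compare_group",
    "build_report",
]

ALPHA = 0.05

#: Box-plot notch half-width constant: ci95 = median +/- 1.57 * IQR / sqrt(n),
#: the standard normal-assumption convention for the 95% CI of the median.
NOTCH_CONSTANT = 1.57


@dataclass
class StrainSummary:
    strain_id: str
    group_id: str = ""
    role: str = ""
    lifetimes_ns: np.ndarray = field(default_factory=lambda: np.array([]))
    n_fov: int = 0
    median_ns: float = float("nan")
    iqr_ns: float = float("nan")
    ci95_ns: tuple[float, float] = (float("nan"), float("nan"))
    q1_ns: float = float("nan")
    q3_ns: float = float("nan")
    whisker_low_ns: float = float("nan")
    whisker_high_ns: float = float("nan")
    outliers_ns: np.ndarray = field(default_factory=lambda: np.array([]))
    ci_defined: bool = True


@dataclass
class GroupComparison:
    query_strain: str
    control_strain: str
    group_id: str
    role: str
    p_value: float
    alpha_corrected: float
    n_comparisons_in_group: int
    significant: bool
    delta_median_ps: float
    n_query: int
    n_control: int


def summarize_strain(
    lifetimes_ns,
    strain_id: str = "",
    group_id: str = "",
    role: str = "",
) -> StrainSummary:
    """Box-plot style summary of one strain's image-wise lifetimes.

    Quartiles use linear interpolation; the 95% CI of the median is the
    box-plot notch ``median +/- 1.57 * IQR / sqrt(n)``.  With fewer than 3
    values the CI is undefined and flagged.
    """
    x = np.sort(np.asarray(lifetimes_ns, dtype=float))
    n = x.size
    s = StrainSummary(
        strain_id=strain_id, group_id=group_id, role=role, lifetimes_ns=x, n_fov=n
    )
    if n == 0:
        s.ci_defined = False
        return s
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    s.median_ns, s.q1_ns, s.q3_ns, s.iqr_ns = float(med), float(q1), float(q3), float(iqr)
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    s.whisker_low_ns = float(inside.min()) if inside.size else float(med)
    s.whisker_high_ns = float(inside.max()) if inside.size else float(med)
    s.outliers_ns = x[(x < lo_fence) | (x > hi_fence)]
    if n >= 3:
        half = NOTCH_CONSTANT * iqr / np.sqrt(n)
        s.ci95_ns = (float(med - half), float(med + half))
    else:
        s.ci_defined = False
    return s


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both samples have n <= 10 and there are no
    ties; otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and no_ties) else "asymptotic"
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def compare_group(
    summaries: list[StrainSummary], alpha: float = ALPHA
) -> list[GroupComparison]:
    """Compare every query (and positive-control) strain of one group with
    the group's single negative control.

    ``m`` is the number of *query* strains; positive controls are tested
    at the same corrected level but do not inflate m.
    """
    controls = [s for s in summaries if s.role == "negative_control"]
    if len(controls) != 1:
        group = summaries[0].group_id if summaries else "?"
        raise ValueError(
            f"group {group!r} needs exactly one negative_control, "
            f"found {len(controls)}"
        )
    control = controls[0]
    m = sum(1 for s in summaries if s.role == "query")
    alpha_corr = alpha / m if m else alpha
    out = []
    for s in summaries:
        if s.role == "negative_control":
            continue
        p = rank_sum_test(s.lifetimes_ns, control.lifetimes_ns)
        out.append(
            GroupComparison(
                query_strain=s.strain_id,
                control_strain=control.strain_id,
                group_id=s.group_id,
                role=s.role,
                p_value=p,
                alpha_corrected=alpha_corr,
                n_comparisons_in_group=m,
                significant=bool(p < alpha_corr),
                delta_median_ps=float((s.median_ns - control.median_ns) * 1e3),
                n_query=s.n_fov,
                n_control=control.n_fov,
            )
        )
    return out


def _fov_results_frame(fov_results) -> pd.DataFrame:
    if isinstance(fov_results, pd.DataFrame):
        return fov_results
    return pd.DataFrame([vars(r) for r in fov_results])


def build_report(
    fov_results,
    layout: PlateLayout,
    out_dir: str | Path | None = None,
    alpha: float = ALPHA,
    extra_report: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Pool QC-passing lifetimes by strain and emit summary tables.

    ``fov_results`` is a sequence of :class:`~flimhca.fitting.FOVResult`
    (or an equivalent DataFrame, e.g. pooled from several runs).  Returns
    (per-strain table, comparisons table, JSON-able report); when
    ``out_dir`` is given the tables are written as CSV plus a
    ``report.json``.
    """
    df = _fov_results_frame(fov_results)
    passing = df[df["qc_pass"] & np.isfinite(df["tau_fit_ns"])]
    summaries: dict[str, StrainSummary] = {}
    for strain in layout.strain_ids:
        taus = passing.loc[passing["strain_id"] == strain, "tau_fit_ns"].to_numpy()
        if taus.size == 0:
            log.warning("strain %s: no QC-passing FOVs, excluded", strain)
            continue
        summaries[strain] = summarize_strain(
            taus,
            strain_id=strain,
            group_id=layout.strain_group(strain),
            role=layout.strain_role(strain),
        )

    comparisons: list[GroupComparison] = []
    for gid in layout.group_ids:
        group_sums = [s for s in summaries.values() if s.group_id == gid]
        if not any(s.role == "negative_control" for s in group_sums):
            log.warning("group %s: control missing or all-failed, skipped", gid)
            continue
        comparisons.extend(compare_group(group_sums, alpha=alpha))

    strain_rows = [
        {
            "strain_id": s.strain_id,
            "group_id": s.group_id,
            "role": s.role,
            "n_fov": s.n_fov,
            "median_ns": s.median_ns,
            "q1_ns": s.q1_ns,
            "q3_ns": s.q3_ns,
            "iqr_ns": s.iqr_ns,
            "ci95_low_ns": s.ci95_ns[0],
            "ci95_high_ns": s.ci95_ns[1],
            "whisker_low_ns": s.whisker_low_ns,
            "whisker_high_ns": s.whisker_high_ns,
            "n_outliers": int(s.outliers_ns.size),
        }
        for s in summaries.values()
    ]
    strain_table = pd.DataFrame(strain_rows)
    comp_table = pd.DataFrame([vars(c) for c in comparisons])

    report = {
        "alpha": alpha,
        "n_fov_total": int(len(df)),
        "n_fov_qc_pass": int(len(passing)),
        "n_fov_qc_fail": int(len(df) - len(passing)),
        "strains": {s.strain_id: s.n_fov for s in summaries.values()},
        "n_comparisons": len(comparisons),
        "n_significant": int(sum(c.significant for c in comparisons)),
    }
    if extra_report:
        report.update(extra_report)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        strain_table.to_csv(out_dir / "strain_summary.csv", index=False)
        comp_table.to_csv(out_dir / "group_comparisons.csv", index=False)
        df.to_csv(out_dir / "fov_results.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return strain_table, comp_table, report


def plot_strain_boxes(strain_table: pd.DataFrame, path: str | Path) -> None:
    """Render the per-strain box-plot quantities to a figure file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(strain_table) + 2, 4))
    for i, row in strain_table.reset_index(drop=True).iterrows():
        ax.broken_barh(
            [(i - 0.3, 0.6)], (row["q1_ns"], row["iqr_ns"]), facecolors="#9ecae1"
        )
        ax.plot([i - 0.3, i + 0.3], [row["median_ns"]] * 2, "k-", lw=2)
        ax.plot([i, i], [row["whisker_low_ns"], row["q1_ns"]], "k-", lw=1)
        ax.plot([i, i], [row["q3_ns"], row["whisker_high_ns"]], "k-", lw=1)
        ax.plot(
            [i, i], [row["ci95_low_ns"], row["ci95_high_ns"]], "r-", lw=4, alpha=0.5
        )
    ax.set_xticks(range(len(strain_table)))
    ax.set_xticklabels(strain_table["strain_id"], rotation=45, ha="right")
    ax.set_ylabel("donor lifetime (ns)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
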