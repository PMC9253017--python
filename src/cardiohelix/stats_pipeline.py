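"""Cohort-level statistics and the end-to-end analysis pipeline.

Group comparisons use classic pooled-variance unpaired t-tests; multi-factor
designs (exercise x genotype) use type-II two-way ANOVA with Tukey HSD post
hoc; the spatial link between CITED4 expression and microstructure is a
simple linear regression of helicity on the CITED4/DAPI ratio pooled across
groups.  ``run_pipeline`` chains simulation, tensor fitting, LV geometry,
helicity, FISH quantification and statistics into one deterministic report.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import helicity as hx
from . import lv_geometry as geo
from . import synthetic_data as syn
from . import tensor_model as tm
from .fish_quant import quantify

__all__ = [
    "TestResult",
    "RegressionResult",
    "ReportBundle",
    "unpaired_ttest",
    "two_way_anova_tukey",
    "regress_cited4_helicity",
    "percent_change",
    "analyze_animal",
    "run_pipeline",
]


@dataclasses.dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    mean_reference: float
    mean_comparison: float
    percent_change: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ReportBundle:
    cohort_table: pd.DataFrame
    stats: dict
    out_dir: Path | None = None


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """(comparison - reference) / |reference| x 100."""
    if reference_mean == 0:
        raise ValueError("percent change undefined for a zero reference mean")
    return (comparison_mean - reference_mean) / abs(reference_mean) * 100.0


def unpaired_ttest(
    values_a, values_b, welch: bool = False
) -> TestResult:
    """Two-tailed unpaired t-test; group A is the reference for the percent
    change.  Pooled-variance (Student) by default, Welch by flag."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("each group needs >= 2 finite values")
    ma, mb = float(a.mean()), float(b.mean())
    pct = percent_change(ma, mb) if ma != 0 else float("nan")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if ma == mb:
            return TestResult(0.0, a.size + b.size - 2, 1.0, ma, mb, pct)
        return TestResult(
            float("inf"), a.size + b.size - 2, 0.0, ma, mb, pct, degenerate=True
        )
    t, p = scipy.stats.ttest_ind(a, b, equal_var=not welch)
    df = (
        a.size + b.size - 2
        if not welch
        else scipy.stats.ttest_ind(a, b, equal_var=False).df
    )
    return TestResult(float(t), float(df), float(p), ma, mb, pct)


def two_way_anova_tukey(
    table: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = ("activity", "genotype"),
    alpha: float = 0.05,
) -> dict:
    """Type-II two-way ANOVA with interaction plus Tukey HSD over the cells.

    Returns ``{'anova': {term: {'F', 'p'}}, 'tukey': [...]}``.  Raises when a
    factor cell has fewer than 2 observations, naming it.
    """
    f1, f2 = factors
    counts = table.groupby([f1, f2]).size()
    lvl1 = table[f1].nunique()
    lvl2 = table[f2].nunique()
    if lvl1 < 2 or lvl2 < 2:
        raise ValueError("each factor needs >= 2 levels")
    for a in table[f1].unique():
        for b in table[f2].unique():
            if counts.get((a, b), 0) < 2:
                raise ValueError(f"cell ({a}, {b}) has < 2 observations")
    if np.ptp(table[response].to_numpy(dtype=float)) == 0:
        terms = {
            t: {"F": 0.0, "p": 1.0} for t in (f1, f2, f"{f1} x {f2}")
        }
        cells = sorted((table[f1].astype(str) + "/" + table[f2].astype(str)).unique())
        tukey = [
            {"group1": a, "group2": b, "meandiff": 0.0, "p_adj": 1.0, "reject": False}
            for i, a in enumerate(cells)
            for b in cells[i + 1 :]
        ]
        return {"anova": terms, "tukey": tukey}
    df = table.rename(columns={response: "_y"})
    model = smf.ols(f"_y ~ C({f1}) * C({f2})", data=df).fit()
    aov = anova_lm(model, typ=2)
    terms = {}
    for name, row in aov.iterrows():
        if name == "Residual":
            continue
        key = (
            name.replace(f"C({f1})", f1)
            .replace(f"C({f2})", f2)
            .replace(":", " x ")
        )
        terms[key] = {"F": float(row["F"]), "p": float(row["PR(>F)"])}
    cells = table[f1].astype(str) + "/" + table[f2].astype(str)
    tk = pairwise_tukeyhsd(table[response].to_numpy(), cells.to_numpy(), alpha=alpha)
    tukey = [
        {
            "group1": str(r[0]),
            "group2": str(r[1]),
            "meandiff": float(r[2]),
            "p_adj": float(r[3]),
            "reject": bool(r[6]),
        }
        for r in tk.summary().data[1:]
    ]
    return {"anova": terms, "tukey": tukey}


def regress_cited4_helicity(
    table: pd.DataFrame, scope: str = "total"
) -> RegressionResult:
    """OLS of helicity on the CITED4/DAPI ratio, pooled across groups.

    ``scope`` selects the paired columns ``helicity_<scope>`` and
    ``cited4_<scope>`` (septal, lateral or total).
    """
    cols = (f"cited4_{scope}", f"helicity_{scope}")
    sub = table[list(cols)].dropna()
    if len(sub) < 3:
        raise ValueError("need >= 3 paired observations")
    x = sub[cols[0]].to_numpy(dtype=float)
    y = sub[cols[1]].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the CITED4/DAPI ratio")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(len(sub)),
    )


# --------------------------------------------------------------------------
# End-to-end per-animal analysis
# --------------------------------------------------------------------------


def analyze_animal(
    dwi: tm.DWIVolume,
    mask: np.ndarray | None = None,
    reference_angle: float = 0.0,
    fish: tuple | None = None,
    fish_nuclei_params: dict | None = None,
) -> dict:
    """Run the full measurement chain on one animal's data.

    DWI -> myocardium mask (Otsu if not given) -> WLS tensor fit -> eigen
    system -> local frame -> transmural depth -> 5 rings + 6 AHA segments ->
    helix angles -> helicity per segment/region, plus morphometry; the FISH
    pair (dapi, cited4, truth, rois) is quantified into regional
    CITED4/DAPI ratios when supplied.
    """
    if mask is not None:
        mm = geo.MyocardiumMask(mask=mask, voxel_size=dwi.voxel_size)
    else:
        mm = geo.segment_myocardium(dwi.b0_mean(), dwi.voxel_size)
    tf = tm.fit_tensor_wls(dwi, mask=mm.mask)
    es = tm.eigendecompose(tf)
    frame = geo.compute_local_frame(mm)
    depth = geo.compute_transmural_depth(mm)
    rings = geo.make_rings(depth)
    aha = geo.make_aha_segments(mm, reference_angle=reference_angle)
    hmap = hx.helix_angle_map(es, frame, mm.mask)
    profile = hx.ring_means(hmap, rings, aha, depth)
    result = hx.helicity_slope(profile)
    morpho = geo.mask_morphometry(mm)

    out: dict = {
        "helicity_global": result.global_,
        "wall_thickness_mm": morpho.wall_thickness_mm,
        "lv_mass_mg": morpho.lv_mass_mg,
    }
    for s in range(1, 7):
        out[f"helicity_seg{s}"] = float(result.per_segment.get(s, np.nan))
    for name in ("septal", "lateral", "total"):
        out[f"helicity_{name}"] = result.regions[name]
        out[f"helicity_{name}_abs"] = result.regions_abs[name]
    if fish is not None:
        dapi, cited4, _truth, rois = fish
        counts = quantify(dapi, cited4, rois, nuclei_params=fish_nuclei_params)
        for _, row in counts.regions.iterrows():
            out[f"cited4_{row['region']}"] = float(row["ratio"])
        for _, row in counts.per_segment.iterrows():
            out[f"cited4_seg{int(row['segment'])}"] = float(row["ratio"])
    return out


DEFAULT_CONFIG: dict = {
    "cohort": {},
    "phantom": {},
    "fish": {},
    "acquisition": {},
    "noise": {"kind": "rician", "snr": 25.0},
    "stats": {"alpha": 0.05, "welch": False},
}


def _merge_config(config: dict | None) -> dict:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in (config or {}).items():
        cfg.setdefault(key, {})
        cfg[key].update(val or {})
    return cfg


def run_pipeline(
    config: dict | None = None, seed: int = 0, out_dir: str | Path | None = None
) -> ReportBundle:
    """Simulate a cohort, analyze every animal, and run the group statistics.

    Deterministic given ``seed``.  Writes ``cohort_table.csv``,
    ``stats.json`` and ``report.md`` (plus an SVG scatter of the pooled
    regression) under ``out_dir`` when given.
    """
    cfg = _merge_config(config)
    cohort = syn.CohortSpec(**{**cfg["cohort"], "seed": seed})
    phantom = syn.PhantomSpec(**cfg["phantom"])
    fish = syn.FishSpec(**cfg["fish"])
    scheme = tm.default_scheme(**cfg["acquisition"])
    noise = syn.NoiseModel(**{**cfg["noise"], "seed": seed})

    if cohort.n_per_group < 3:
        import warnings

        warnings.warn(
            "n_per_group < 3: confidence intervals will be wide and the "
            "group tests underpowered",
            stacklevel=2,
        )

    records = syn.make_cohort(
        cohort, phantom_template=phantom, fish_template=fish, scheme=scheme, noise=noise
    )
    rows = []
    for rec in records:
        measured = analyze_animal(
            rec.dwi,
            mask=None,
            reference_angle=rec.phantom_spec.reference_angle,
            fish=rec.fish,
            fish_nuclei_params=fish.nuclei_detection_params(),
        )
        row = {
            "animal_id": rec.animal_id,
            "activity": rec.activity,
            "genotype": rec.genotype,
            **measured,
        }
        for key in ("helicity_total", "helicity_septal", "helicity_lateral"):
            row[f"true_{key}"] = rec.truth[key]
        rows.append(row)
    table = pd.DataFrame(rows)
    if table["animal_id"].duplicated().any():
        raise AssertionError("duplicate animal ids in cohort table")

    stats = _cohort_statistics(table, cfg["stats"])
    bundle = ReportBundle(cohort_table=table, stats=stats)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort_table.csv", index=False)
        meta = {"seed": seed, "config": {k: _jsonable(v) for k, v in cfg.items()}}
        (out / "stats.json").write_text(
            json.dumps({"stats": stats, "meta": meta}, indent=2, default=float)
        )
        _write_report(out, table, stats)
        _plot_regression(out, table)
        bundle.out_dir = out
    return bundle


def _jsonable(v):
    if isinstance(v, dict):
        return {str(k): _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, (np.floating, np.integer)):
        return float(v)
    return v


def _cohort_statistics(table: pd.DataFrame, stats_cfg: dict) -> dict:
    welch = bool(stats_cfg.get("welch", False))
    out: dict = {"group_comparisons": {}, "regressions": {}}
    wt = table[table["genotype"].isin(["wildtype", "flfl"])]
    sed = wt[wt["activity"] == "sedentary"]
    exe = wt[wt["activity"] == "exercise"]
    endpoints = [
        ("helicity_total_abs", "helicity_total"),
        ("helicity_septal_abs", "helicity_septal"),
        ("helicity_lateral_abs", "helicity_lateral"),
        ("cited4_total", "cited4_total"),
        ("cited4_septal", "cited4_septal"),
        ("cited4_lateral", "cited4_lateral"),
        ("wall_thickness_mm", "wall_thickness"),
        ("lv_mass_mg", "lv_mass"),
    ]
    if len(sed) >= 2 and len(exe) >= 2:
        for col, name in endpoints:
            if col not in table.columns:
                continue
            a = sed[col].dropna()
            b = exe[col].dropna()
            if len(a) >= 2 and len(b) >= 2:
                out["group_comparisons"][name] = unpaired_ttest(a, b, welch).to_dict()
    for scope in ("septal", "lateral", "total"):
        cols = {f"cited4_{scope}", f"helicity_{scope}_abs"}
        if cols <= set(wt.columns):
            sub = pd.DataFrame(
                {
                    f"cited4_{scope}": wt[f"cited4_{scope}"],
                    f"helicity_{scope}": wt[f"helicity_{scope}_abs"],
                }
            )
            try:
                out["regressions"][scope] = regress_cited4_helicity(sub, scope).to_dict()
            except ValueError:
                pass
    # two-way design when both factors have two levels with filled cells
    if table["genotype"].nunique() >= 2 and table["activity"].nunique() >= 2:
        try:
            out["two_way_anova"] = two_way_anova_tukey(
                table.assign(hmag=table["helicity_total_abs"]), "hmag"
            )
        except ValueError as exc:
            out["two_way_anova"] = {"error": str(exc)}
    return out


def _write_report(out: Path, table: pd.DataFrame, stats: dict) -> None:
    lines = ["# Cohort analysis report", ""]
    lines.append(f"Animals: {len(table)}")
    lines.append("")
    lines.append("## Group comparisons (exercise vs sedentary)")
    for name, res in stats.get("group_comparisons", {}).items():
        lines.append(
            f"- {name}: {res['mean_reference']:.3f} -> {res['mean_comparison']:.3f} "
            f"({res['percent_change']:+.1f}%), t={res['statistic']:.2f}, "
            f"p={res['p_value']:.4g}"
        )
    lines.append("")
    lines.append("## Helicity vs CITED4/DAPI regressions (pooled)")
    for scope, res in stats.get("regressions", {}).items():
        lines.append(
            f"- {scope}: slope={res['slope']:.2f}, R^2={res['r_squared']:.3f}, "
            f"p={res['p_value']:.4g}, n={res['n']}"
        )
    if "two_way_anova" in stats:
        lines.append("")
        lines.append("## Two-way ANOVA (|helicity| total)")
        for term, res in stats["two_way_anova"].get("anova", {}).items():
            lines.append(f"- {term}: F={res['F']:.2f}, p={res['p']:.4g}")
    (out / "report.md").write_text("\n".join(lines) + "\n")


def _plot_regression(out: Path, table: pd.DataFrame) -> None:
    cols = {"cited4_total", "helicity_total_abs"}
    if not cols <= set(table.columns):
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    for act, color in (("sedentary", "black"), ("exercise", "red")):
        sub = table[table["activity"] == act]
        ax.scatter(sub["cited4_total"], sub["helicity_total_abs"], c=color, label=act)
    sub = table.dropna(subset=list(cols))
    if len(sub) >= 3 and np.ptp(sub["cited4_total"]) > 0:
        coef = np.polyfit(sub["cited4_total"], sub["helicity_total_abs"], 1)
        xs = np.linspace(sub["cited4_total"].min(), sub["cited4_total"].max(), 50)
        ax.plot(xs, np.polyval(coef, xs), color="tab:blue")
    ax.set_xlabel("CITED4/DAPI ratio (total)")
    ax.set_ylabel("|helicity| (deg / unit depth)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "regression_total.svg")
    plt.close(fig)
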