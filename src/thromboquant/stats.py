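"""Aggregation, 0–10 scaling, paired testing, and subtraction heatmaps.

The averaging hierarchy mirrors the assay protocol: parameter values of the
2–3 corresponding images in a run are averaged, duplicate runs are averaged
to one parameter set per (donor, condition, microspot, shear), and condition
means over donors feed the presentation layer.  For heatmaps each parameter
is univariate normalized to 0–10 across the conditions of a microspot/shear
group (or against the assay's fixed observed ranges).  Conditions are
compared against control per donor with a two-sided paired Student t-test on
the unscaled per-donor means; subtraction heatmaps show scaled
condition-minus-control deltas with a conventional significance filter at
p < 0.05 (no multiplicity correction by default; Benjamini–Hochberg is
available as an option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import (
    BRIGHTFIELD_PARAMETERS,
    FLUORESCENCE_PARAMETERS,
    PARAMETERS,
)

__all__ = [
    "TABLE_RANGES",
    "KEY_COLUMNS",
    "ComparisonResult",
    "ScaledMatrix",
    "average_images_to_run",
    "average_runs_to_donor",
    "scale_univariate",
    "scaled_matrix",
    "cumulative_scaled",
    "paired_t_test",
    "subtraction_heatmap",
    "plot_heatmap",
    "plot_cumulative",
]

#: Observed parameter ranges of the assay, used as the fixed scaling frame.
TABLE_RANGES: Dict[str, Tuple[float, float]] = {
    "P1": (0.0, 71.7),
    "P2": (0.0, 29.8),
    "P3": (0.0, 4.75),
    "P4": (0.0, 2.75),
    "P5": (0.0, 2.75),
    "P6": (0.0, 22.2),
    "P7": (0.0, 71.7),
    "P8": (0.0, 45.7),
}

KEY_COLUMNS = ("donor", "condition", "microspot", "shear_rate")
RUN_KEY = KEY_COLUMNS + ("run_id",)


def average_images_to_run(per_image: pd.DataFrame) -> pd.DataFrame:
    """Average per-image parameter rows into one row per run.

    ``per_image`` must carry the run key columns, ``image_role``
    ('brightfield'/'fluorescence'), and parameter columns.  P1–P5 are averaged
    over brightfield rows and P6–P8 over fluorescence rows; a parameter with
    no contributing image stays NaN (missing, not zero).  Provenance counts
    (``n_brightfield``, ``n_fluorescence``) are recorded.
    """
    required = set(RUN_KEY) | {"image_role"}
    missing = required - set(per_image.columns)
    if missing:
        raise ValueError(f"per-image table lacks columns: {sorted(missing)}")
    if per_image.empty:
        raise ValueError("per-image table is empty")

    rows = []
    for key, grp in per_image.groupby(list(RUN_KEY), sort=True):
        bf = grp[grp["image_role"] == "brightfield"]
        fl = grp[grp["image_role"] == "fluorescence"]
        row = dict(zip(RUN_KEY, key))
        for p in BRIGHTFIELD_PARAMETERS:
            row[p] = float(bf[p].mean()) if p in bf and len(bf) else np.nan
        for p in FLUORESCENCE_PARAMETERS:
            row[p] = float(fl[p].mean()) if p in fl and len(fl) else np.nan
        row["n_brightfield"] = int(len(bf))
        row["n_fluorescence"] = int(len(fl))
        rows.append(row)
    return pd.DataFrame(rows)


def average_runs_to_donor(per_run: pd.DataFrame) -> pd.DataFrame:
    """Average duplicate runs to one parameter set per donor/condition/microspot/shear."""
    missing = set(KEY_COLUMNS) - set(per_run.columns)
    if missing:
        raise ValueError(f"per-run table lacks columns: {sorted(missing)}")
    agg = {p: "mean" for p in PARAMETERS if p in per_run.columns}
    agg["run_id"] = "nunique"
    out = (
        per_run.groupby(list(KEY_COLUMNS), sort=True)
        .agg(agg)
        .rename(columns={"run_id": "n_runs"})
        .reset_index()
    )
    if "n_brightfield" in per_run.columns:
        counts = per_run.groupby(list(KEY_COLUMNS), sort=True)[
            ["n_brightfield", "n_fluorescence"]
        ].sum()
        out = out.merge(counts.reset_index(), on=list(KEY_COLUMNS))
    return out


def scale_univariate(
    values: Sequence[float],
    mode: str = "dataset",
    parameter: Optional[str] = None,
    frame: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Affine 0–10 scaling of one parameter's values across conditions.

    ``dataset`` mode maps the observed [min, max] to [0, 10]; a constant
    vector maps to all zeros with a warning.  ``fixed`` mode uses the assay's
    observed ranges (:data:`TABLE_RANGES`, or an explicit ``frame``) and
    clips out-of-frame values into [0, 10] with a warning.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("cannot scale an empty vector")
    if mode == "dataset":
        lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
        if hi == lo:
            warnings.warn(
                "constant parameter vector: scaled to all zeros", stacklevel=2
            )
            return np.zeros_like(x), (lo, hi)
        return 10.0 * (x - lo) / (hi - lo), (lo, hi)
    if mode == "fixed":
        if frame is None:
            if parameter is None or parameter not in TABLE_RANGES:
                raise ValueError("fixed mode needs a parameter name or explicit frame")
            frame = TABLE_RANGES[parameter]
        lo, hi = map(float, frame)
        if hi <= lo:
            raise ValueError("fixed frame must have max > min")
        scaled = 10.0 * (x - lo) / (hi - lo)
        if np.nanmin(scaled) < -1e-9 or np.nanmax(scaled) > 10.0 + 1e-9:
            warnings.warn("values outside the fixed frame were clipped", stacklevel=2)
        return np.clip(scaled, 0.0, 10.0), (lo, hi)
    raise ValueError(f"unknown scaling mode {mode!r}")


@dataclass
class ScaledMatrix:
    """Condition × parameter 0–10 values per (microspot, shear) group."""

    entries: pd.DataFrame  # long form: microspot, shear_rate, condition, parameter, scaled
    frames: pd.DataFrame   # microspot, shear_rate, parameter, lo, hi

    def row(self, microspot: str, shear_rate: float, condition: str) -> pd.Series:
        sel = self.entries[
            (self.entries["microspot"] == microspot)
            & (self.entries["shear_rate"] == shear_rate)
            & (self.entries["condition"] == condition)
        ]
        return sel.set_index("parameter")["scaled"]


def scaled_matrix(
    donor_summary: pd.DataFrame,
    mode: str = "dataset",
    pooled: bool = False,
) -> ScaledMatrix:
    """Scale condition means (over donors) to 0–10 per parameter.

    By default each (microspot, shear) group carries its own scaling frame;
    ``pooled=True`` scales across the pooled groups instead.
    """
    means = (
        donor_summary.groupby(["condition", "microspot", "shear_rate"], sort=True)[
            list(PARAMETERS)
        ]
        .mean()
        .reset_index()
    )
    group_cols = [] if pooled else ["microspot", "shear_rate"]
    entry_rows, frame_rows = [], []
    groups = [((), means)] if pooled else list(means.groupby(group_cols, sort=True))
    for gkey, grp in groups:
        for p in PARAMETERS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scaled, (lo, hi) = scale_univariate(grp[p].to_numpy(), mode=mode, parameter=p)
            for (_, row), s in zip(grp.iterrows(), scaled):
                entry_rows.append(
                    dict(
                        microspot=row["microspot"],
                        shear_rate=row["shear_rate"],
                        condition=row["condition"],
                        parameter=p,
                        mean=row[p],
                        scaled=float(s),
                    )
                )
            frame_rows.append(
                dict(
                    **({} if pooled else dict(zip(group_cols, gkey if isinstance(gkey, tuple) else (gkey,)))),
                    parameter=p,
                    lo=lo,
                    hi=hi,
                )
            )
    return ScaledMatrix(entries=pd.DataFrame(entry_rows), frames=pd.DataFrame(frame_rows))


def cumulative_scaled(scaled_row: Mapping[str, float] | pd.Series) -> float:
    """Sum of the eight scaled parameters for one condition (0–80)."""
    total = 0.0
    for p in PARAMETERS:
        if p not in scaled_row or pd.isna(scaled_row[p]):
            raise ValueError(f"missing scaled parameter {p}")
        total += float(scaled_row[p])
    return total


@dataclass(frozen=True)
class ComparisonResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    n_pairs: int
    mean_difference: float


def paired_t_test(
    control: Sequence[float], treated: Sequence[float]
) -> ComparisonResult:
    """Two-sided paired Student t-test on donor-aligned value vectors.

    The statistic is computed on the pairwise differences treated − control.
    If every difference is exactly zero, the convention t = 0, p = 1 applies
    (the test is vacuous, not undefined).
    """
    a = np.asarray(list(control), dtype=float)
    b = np.asarray(list(treated), dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("control and treated must be equal-length 1-D vectors")
    if a.size < 2:
        raise ValueError("paired test needs at least 2 donors")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing values in paired vectors")
    d = b - a
    n = d.size
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean_d == 0.0:
            return ComparisonResult(0.0, n - 1, 1.0, n, 0.0)
        t = np.inf if mean_d > 0 else -np.inf
        return ComparisonResult(float(t), n - 1, 0.0, n, mean_d)
    t = mean_d / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return ComparisonResult(float(t), n - 1, min(p, 1.0), n, mean_d)


def subtraction_heatmap(
    donor_summary: pd.DataFrame,
    control: str,
    mode: str = "dataset",
    alpha: float = 0.05,
    adjust: Optional[str] = None,
    pooled: bool = False,
) -> pd.DataFrame:
    """Control-subtracted scaled deltas with a significance filter.

    Returns a long table with one row per (microspot, shear, condition ≠
    control, parameter): the scaled delta (condition − control), the paired-t
    p-value on unscaled per-donor values, and the significance flag
    (p < ``alpha``).  Non-significant cells keep their raw delta in the
    table; rendering is where the mask is applied.  ``adjust='bh'`` applies a
    Benjamini–Hochberg correction across the parameters of each group.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("significance threshold must lie in (0, 1)")
    conditions = donor_summary["condition"].unique()
    if control not in conditions:
        raise ValueError(f"control condition {control!r} absent from data")
    sm = scaled_matrix(donor_summary, mode=mode, pooled=pooled)

    rows = []
    for (microspot, shear), grp in donor_summary.groupby(
        ["microspot", "shear_rate"], sort=True
    ):
        ctrl = grp[grp["condition"] == control].set_index("donor")
        for cond in sorted(set(grp["condition"]) - {control}):
            trt = grp[grp["condition"] == cond].set_index("donor")
            donors = sorted(set(ctrl.index) & set(trt.index))
            scaled_c = sm.row(microspot, shear, control)
            scaled_t = sm.row(microspot, shear, cond)
            pvals = {}
            for p in PARAMETERS:
                res = paired_t_test(
                    ctrl.loc[donors, p].to_numpy(), trt.loc[donors, p].to_numpy()
                )
                pvals[p] = res.p_value
            if adjust == "bh":
                from statsmodels.stats.multitest import multipletests

                adj = multipletests(list(pvals.values()), method="fdr_bh")[1]
                pvals = dict(zip(pvals.keys(), adj))
            elif adjust not in (None, "none"):
                raise ValueError(f"unknown adjustment {adjust!r}")
            for p in PARAMETERS:
                delta = float(scaled_t[p] - scaled_c[p])
                rows.append(
                    dict(
                        microspot=microspot,
                        shear_rate=shear,
                        condition=cond,
                        parameter=p,
                        delta=delta,
                        p_value=pvals[p],
                        significant=bool(pvals[p] < alpha),
                        n_donors=len(donors),
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Figures


def plot_heatmap(heatmap: pd.DataFrame, path, mask_nonsignificant: bool = True):
    """Render a subtraction heatmap: green = decrease, red = increase vs control.

    Non-significant cells are drawn neutral (white) when masking is on.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "decrease-increase", ["#1a9850", "#ffffff", "#d73027"]
    )
    groups = list(heatmap.groupby(["microspot", "shear_rate"], sort=True))
    fig, axes = plt.subplots(
        1, len(groups), figsize=(3.2 * len(groups) + 1, 3.2), squeeze=False
    )
    for ax, ((microspot, shear), grp) in zip(axes[0], groups):
        pivot = grp.pivot(index="condition", columns="parameter", values="delta")
        pivot = pivot[list(PARAMETERS)]
        data = pivot.to_numpy(dtype=float)
        if mask_nonsignificant:
            sig = (
                grp.pivot(index="condition", columns="parameter", values="significant")
                .reindex(pivot.index)[list(PARAMETERS)]
                .to_numpy(dtype=bool)
            )
            data = np.where(sig, data, 0.0)
        ax.imshow(data, cmap=cmap, vmin=-10, vmax=10, aspect="auto")
        ax.set_xticks(range(len(PARAMETERS)), PARAMETERS, fontsize=7)
        ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=7)
        ax.set_title(f"{microspot} @ {shear:g} s⁻¹", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cumulative(scaled: ScaledMatrix, path):
    """Stacked cumulative bars of the scaled parameters per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(scaled.entries.groupby(["microspot", "shear_rate"], sort=True))
    fig, axes = plt.subplots(
        1, len(groups), figsize=(2.8 * len(groups) + 1, 3.2), squeeze=False
    )
    for ax, ((microspot, shear), grp) in zip(axes[0], groups):
        pivot = grp.pivot(index="condition", columns="parameter", values="scaled")
        bottom = np.zeros(len(pivot))
        for p in PARAMETERS:
            ax.bar(pivot.index, pivot[p].to_numpy(), bottom=bottom, label=p)
            bottom += pivot[p].to_numpy()
        ax.set_ylim(0, 80)
        ax.set_ylabel("cumulative scaled value")
        ax.tick_params(axis="x", rotation=45, labelsize=7)
        ax.set_title(f"{microspot} @ {shear:g} s⁻¹", fontsize=8)
    axes[0][-1].legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
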