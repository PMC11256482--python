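"""ROI statistics: group/time ANOVA with Fisher LSD, and correlation matrices.

Per-subject ROI means of the parametric maps (JD, CBV, MD, AD, RD) feed a
two-way (group x time) ANOVA with Type II sums of squares and Fisher LSD
group contrasts per timepoint, and Pearson correlation matrices whose
p-values come from the Fisher z transform (z = atanh(r) * sqrt(n - 3),
two-sided normal tail).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .imageio import Volume

PARAMETERS = ("JD", "CBV", "MD", "AD", "RD")


def extract_roi_means(volume: Volume, roi: np.ndarray) -> float:
    """Arithmetic mean of the map over the ROI, NaNs excluded (count warned)."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    vals = np.asarray(volume.data, dtype=float)[roi]
    n_nan = int(np.isnan(vals).sum())
    if n_nan:
        warnings.warn(f"extract_roi_means: excluding {n_nan} NaN voxels")
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError("ROI contains only NaN values")
    return float(vals.mean())


@dataclass
class AnovaResult:
    table: pd.DataFrame        # effect, sum_sq, df, F, p
    lsd: pd.DataFrame          # timepoint, mean difference, t, p
    mse: float
    df_resid: float


def two_way_anova_lsd(
    table: pd.DataFrame,
    response: str,
    group_col: str = "group",
    time_col: str = "timepoint",
) -> AnovaResult:
    """Two-way ANOVA (group, time, interaction; Type II SS) + Fisher LSD.

    The LSD post-hoc compares the two groups at each timepoint with a plain
    t-test using the pooled residual MSE of the full model (no multiplicity
    correction — that is the LSD convention). Requires >= 2 observations per
    cell; empty cells are reported by name.
    """
    df = table.copy()
    for col in (response, group_col, time_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from table")
    counts = df.groupby([group_col, time_col], observed=True)[response].count()
    groups = df[group_col].unique()
    times = df[time_col].unique()
    empty = [
        (g, t) for g in groups for t in times
        if (g, t) not in counts.index or counts.loc[(g, t)] < 2
    ]
    if empty:
        raise ValueError(f"cells with fewer than 2 observations: {empty}")
    if len(groups) < 2 or len(times) < 2:
        raise ValueError("need >= 2 levels per factor")

    if df.groupby([group_col, time_col], observed=True)[response].var().max() == 0 and df[response].var() == 0:
        tbl = pd.DataFrame(
            {"effect": [group_col, time_col, "interaction"], "sum_sq": 0.0, "df": np.nan,
             "F": np.nan, "p": np.nan}
        )
        return AnovaResult(table=tbl, lsd=pd.DataFrame(), mse=0.0, df_resid=np.nan)

    model = smf.ols(f"Q('{response}') ~ C(Q('{group_col}')) * C(Q('{time_col}'))", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    effects = {0: group_col, 1: time_col, 2: "interaction", 3: "residual"}
    tbl = pd.DataFrame(
        {
            "effect": [effects[i] for i in range(len(aov))],
            "sum_sq": aov["sum_sq"].to_numpy(),
            "df": aov["df"].to_numpy(),
            "F": aov["F"].to_numpy(),
            "p": aov["PR(>F)"].to_numpy(),
        }
    )
    mse = float(model.mse_resid)
    df_resid = float(model.df_resid)

    g1, g2 = sorted(groups)
    rows = []
    for t in times:
        a = df[(df[group_col] == g1) & (df[time_col] == t)][response].to_numpy(dtype=float)
        b = df[(df[group_col] == g2) & (df[time_col] == t)][response].to_numpy(dtype=float)
        diff = a.mean() - b.mean()
        se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
        tstat = diff / se if se > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(tstat), df_resid) if np.isfinite(tstat) else np.nan
        rows.append({"timepoint": t, "contrast": f"{g1} - {g2}", "difference": diff,
                     "t": tstat, "df": df_resid, "p": p})
    return AnovaResult(table=tbl, lsd=pd.DataFrame(rows), mse=mse, df_resid=df_resid)


def fisher_z_pvalue(r: float, n: int) -> float:
    """Two-sided p for Pearson r via z = atanh(r) * sqrt(n - 3)."""
    if n <= 3:
        return np.nan
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    z = np.arctanh(r) * np.sqrt(n - 3)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.p < self.alpha


def pearson_matrix(
    table: pd.DataFrame,
    parameters: tuple[str, ...] = PARAMETERS,
    alpha: float = 0.05,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson matrix over parameter columns (pooled rows).

    Rows pool all subjects and timepoints present in the table (the
    'confounding time and group' scheme). Pairs with n < 4 keep their r but
    p is NaN with a warning (the Fisher z test is undefined at n <= 3).
    """
    k = len(parameters)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = table[parameters[i]].notna().sum()
        for j in range(i + 1, k):
            sub = table[[parameters[i], parameters[j]]].dropna()
            nij = len(sub)
            n[i, j] = n[j, i] = nij
            if nij < 2 or sub.iloc[:, 0].std() == 0 or sub.iloc[:, 1].std() == 0:
                rij = np.nan
            else:
                rij = float(np.corrcoef(sub.iloc[:, 0], sub.iloc[:, 1])[0, 1])
            r[i, j] = r[j, i] = rij
            if nij < 4:
                warnings.warn(f"pair ({parameters[i]}, {parameters[j]}): n={nij} < 4, p undefined")
                pij = np.nan
            else:
                pij = fisher_z_pvalue(rij, nij) if np.isfinite(rij) else np.nan
            p[i, j] = p[j, i] = pij
    idx = list(parameters)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        alpha=alpha,
    )


def plot_correlation_heatmap(cm: CorrelationMatrix, path, annotate: bool = True):
    """Write the r-matrix as a heatmap PNG; significant cells get a marker."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = cm.r.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(1.0 + 0.8 * r.shape[1], 1.0 + 0.8 * r.shape[0]))
    im = ax.imshow(r, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(r.shape[1]), cm.r.columns, rotation=45, ha="right")
    ax.set_yticks(range(r.shape[0]), cm.r.index)
    if annotate:
        sig = cm.p.to_numpy(dtype=float) < cm.alpha
        for i in range(r.shape[0]):
            for j in range(r.shape[1]):
                if np.isfinite(r[i, j]):
                    mark = "*" if sig[i, j] else ""
                    ax.text(j, i, f"{r[i, j]:.2f}{mark}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def anchored_matrix(
    table: pd.DataFrame,
    anchor_param: str = "JD",
    anchor_time: str = "1M",
    parameters: tuple[str, ...] = ("CBV", "MD"),
    alpha: float = 0.05,
) -> CorrelationMatrix:
    """Time-anchored correlations: anchor_param at anchor_time vs each
    parameter at every timepoint, paired within subject.

    Mirrors the 'reference point' scheme where the morphometric change at the
    time of its dominant cluster is correlated against the other parameters
    across the longitudinal series.
    """
    wide = table.pivot_table(index="subject_id", columns="timepoint", observed=True,
                             values=list({anchor_param, *parameters}), aggfunc="mean")
    if (anchor_param, anchor_time) not in wide.columns:
        raise ValueError(f"{anchor_param} at {anchor_time} absent from table")
    anchor = wide[(anchor_param, anchor_time)]
    times = sorted(table["timepoint"].unique())
    cols, rvals, pvals, nvals = [], [], [], []
    for param in parameters:
        for t in times:
            if (param, t) not in wide.columns:
                continue
            other = wide[(param, t)]
            sub = pd.concat([anchor, other], axis=1).dropna()
            nij = len(sub)
            if nij < 2 or sub.iloc[:, 0].std() == 0 or sub.iloc[:, 1].std() == 0:
                rij = np.nan
            else:
                rij = float(np.corrcoef(sub.iloc[:, 0], sub.iloc[:, 1])[0, 1])
            pij = fisher_z_pvalue(rij, nij) if (nij >= 4 and np.isfinite(rij)) else np.nan
            if nij < 4:
                warnings.warn(f"anchored pair ({param}@{t}): n={nij} < 4, p undefined")
            cols.append(f"{param}@{t}")
            rvals.append(rij)
            pvals.append(pij)
            nvals.append(nij)
    idx = [f"{anchor_param}@{anchor_time}"]
    return CorrelationMatrix(
        r=pd.DataFrame([rvals], index=idx, columns=cols),
        p=pd.DataFrame([pvals], index=idx, columns=cols),
        n=pd.DataFrame([nvals], index=idx, columns=cols),
        alpha=alpha,
    )
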