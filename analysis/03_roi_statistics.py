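"""Group/time statistics and correlation matrices in the DBM-defined ROIs.

From the study table produced by 02_run_dbm.py: per-parameter two-way ANOVA
(group x time) with Fisher LSD post-hoc contrasts, the pooled Pearson
correlation matrix, and the time-anchored JD-vs-parameter correlations that
probe whether early macrostructural change tracks early microstructural
change. Tables land in results/.

Run after 02_run_dbm.py:  python analysis/03_roi_statistics.py
"""

from pathlib import Path

import pandas as pd

from morphorad.roi_analysis import (
    anchored_matrix,
    pearson_matrix,
    plot_correlation_heatmap,
    two_way_anova_lsd,
)

PARAMS = ("JD", "CBV", "MD", "AD", "RD")


def main() -> None:
    res = Path("results")
    table = pd.read_csv(res / "study_table.csv")
    for roi in sorted(table["roi"].unique()):
        sub = table[table["roi"] == roi]
        print(f"\n=== ROI {roi} ({len(sub)} subject-sessions) ===")
        for param in PARAMS:
            try:
                out = two_way_anova_lsd(sub, param)
            except ValueError as exc:
                print(f"  {param}: ANOVA not computable ({exc})")
                continue
            out.table.to_csv(res / f"anova_{roi}_{param}.csv", index=False)
            out.lsd.to_csv(res / f"lsd_{roi}_{param}.csv", index=False)
            ps = dict(zip(out.table["effect"], out.table["p"]))
            print(f"  {param}: p(group)={ps.get('group', float('nan')):.3g} "
                  f"p(time)={ps.get('timepoint', float('nan')):.3g} "
                  f"p(interaction)={ps.get('interaction', float('nan')):.3g}")
        pooled = pearson_matrix(sub, parameters=PARAMS)
        pooled.r.to_csv(res / f"pearson_r_{roi}.csv")
        pooled.p.to_csv(res / f"pearson_p_{roi}.csv")
        plot_correlation_heatmap(pooled, res / f"pearson_heatmap_{roi}.png")
        anchor_tp = roi.split("-")[-1]
        try:
            anc = anchored_matrix(sub, anchor_param="JD", anchor_time=anchor_tp,
                                  parameters=("CBV", "MD"))
            anc.r.to_csv(res / f"anchored_r_{roi}.csv")
            anc.p.to_csv(res / f"anchored_p_{roi}.csv")
            print(f"  anchored JD@{anchor_tp}: " + "  ".join(
                f"{c}: r={anc.r.iloc[0][c]:+.2f} (p={anc.p.iloc[0][c]:.3g})"
                for c in anc.r.columns))
        except ValueError as exc:
            print(f"  anchored correlations unavailable: {exc}")


if __name__ == "__main__":
    main()
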