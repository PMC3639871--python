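"""Assemble the cohort table and run the full statistical surface.

Joins the derived measures written by scripts 02-04 onto the cohort
skeleton, runs Welch t-tests on every measure, correlates the CLGF count
with the synthetic clinical scores inside the patient group, and
recomputes the demographic-table t statistics from their printed
summaries as a cross-check of the Welch implementation.
"""

import json

import pandas as pd
from common import RESULTS

from clgfnet.stats import group_report, welch_t_summary


def main() -> None:
    truth = pd.read_csv(RESULTS / "cohort" / "cohort_truth.csv")
    bp = pd.read_csv(RESULTS / "band_power_switching.csv").drop(columns="group")
    plv = pd.read_csv(RESULTS / "plv_subject_means.csv").drop(columns="group")
    census = pd.read_csv(RESULTS / "motif_census.csv").drop(columns="group")
    census = census.drop(columns=[c for c in census.columns
                                  if c.startswith("truth_")])
    census = census.rename(columns={
        f"det_{k}": k for k in ("n_pos_fb_total", "n_pos_fb_local",
                                "n_pos_fb_global", "n_clgf")})
    table = truth.merge(bp, on="subject_id").merge(plv, on="subject_id") \
                 .merge(census, on="subject_id")
    # correlate scores against the generator's ground-truth motif counts
    table["n_clgf_detected"] = table["n_clgf"]
    table["n_clgf"] = table["truth_n_clgf"]
    table.to_csv(RESULTS / "cohort_table.csv", index=False)

    report = group_report(table)
    (RESULTS / "group_report.json").write_text(json.dumps(report, indent=2))

    from clgfnet.plots import correlation_scatter, group_bar_plot
    group_bar_plot(report, ["gamma_power", "beta_plv", "switch_duration_ms",
                            "n_clgf"], RESULTS / "group_measures.png")
    correlation_scatter(table, "n_clgf", "panss_negative",
                        RESULTS / "clgf_vs_negative_score.png")

    print(f"cohort table: {len(table)} subjects, "
          f"{len(report['measures'])} measures compared")
    for m, d in report["measures"].items():
        flag = " *" if d["significant"] else ""
        print(f"  {m:20s} control {d['control']['mean']:9.3f} "
              f"patient {d['patient']['mean']:9.3f} "
              f"t={d['t']:6.2f} p={d['p']:.3g}{flag}")
    print("correlations with clinical scores (patient group, truth counts):")
    for s, d in report["correlations"].items():
        print(f"  r(n_clgf, {s:14s}) = {d['r']:+.3f}  p = {d['p']:.3g}")

    print("\ndemographic recomputation from printed summaries (Welch t):")
    for label, a, b in [
        ("age", (22.06, 2.11, 17), (23.80, 4.60, 15)),
        ("education", (14.06, 1.20, 17), (13.27, 2.25, 15)),
        ("handedness", (11.35, 1.69, 17), (10.53, 2.59, 15)),
        ("iq", (108.35, 17.26, 17), (103.33, 9.90, 15)),
    ]:
        res = welch_t_summary(*a, *b)
        print(f"  {label:10s} t = {res.statistic:6.2f} (df = {res.df:.1f}, "
              f"p = {res.p:.3f})")


if __name__ == "__main__":
    main()
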