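"""Group-level mixed ANOVAs on wetness perception.

Two families, mirroring the study's statistical plan:

* per site x stimulus quality under the thermoneutral session:
  group (MS vs CTR) x stimulation mode (static vs dynamic) - the dynamic
  increment shows up as a large mode main effect with no group effect;
* dynamic ratings collapsed over site and quality:
  group x session (neutral/heat/cold) with Greenhouse-Geisser correction,
  followed by paired session contrasts and a Tukey HSD across sessions.
"""

from pathlib import Path

import pandas as pd

from cohort_config import tested_cohort_config
from hygroqst.anova import mixed_anova, paired_contrast, tukey_hsd
from hygroqst.data_model import Quality, Site
from hygroqst.pipeline import anova_frame, mode_design, session_design
from hygroqst.synthetic import generate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results" / "tables"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(tested_cohort_config())

    rows = []
    for site in Site:
        for quality in Quality:
            table = mixed_anova(mode_design(cohort, site, quality))
            for effect in ("group", "within", "interaction"):
                e = table[effect]
                rows.append({"site": site.name, "quality": quality.name,
                             "effect": effect if effect != "within" else "mode",
                             "F": e.f, "df1": e.df_corrected,
                             "df2": table[e.error_term].df, "p": e.p,
                             "percent_total": e.percent_total})
    mode_tables = pd.DataFrame(rows)
    mode_tables.to_csv(RESULTS / "anova_mode_by_cell.csv", index=False)
    sig_mode = mode_tables[(mode_tables["effect"] == "mode") & (mode_tables["p"] < 0.05)]
    sig_group = mode_tables[(mode_tables["effect"] == "group") & (mode_tables["p"] < 0.05)]
    print(f"mode main effect significant in {len(sig_mode)}/9 cells; "
          f"group main effect significant in {len(sig_group)}/9 cells")

    design = session_design(cohort)
    table = mixed_anova(design)
    frame = anova_frame(table)
    frame.to_csv(RESULTS / "anova_session_collapsed.csv", index=False)
    print(f"\nsession ANOVA (collapsed dynamic wetness): "
          f"F({table['within'].df_corrected:.1f}, "
          f"{table['within_error'].df_corrected:.1f}) = {table['within'].f:.2f}, "
          f"p = {table['within'].p:.4f}, epsilon = {table.epsilon:.3f}")

    idx = {lvl: i for i, lvl in enumerate(design.within_levels)}
    contrasts = []
    for a, b in (("HEAT", "NEUTRAL"), ("COLD", "NEUTRAL"), ("HEAT", "COLD")):
        res = paired_contrast(design.responses[:, idx[a]], design.responses[:, idx[b]])
        contrasts.append({"comparison": f"{a} - {b}", "mean_difference": res.difference,
                          "ci_low": res.ci_low, "ci_high": res.ci_high,
                          "p": res.p_adjusted})
    pd.DataFrame(contrasts).to_csv(RESULTS / "session_contrasts.csv", index=False)
    print("paired session contrasts (mm):")
    print(pd.DataFrame(contrasts).round(2).to_string(index=False))

    means = design.responses.mean(axis=0)
    hsd = tukey_hsd(means, [design.responses.shape[0]] * 3,
                    ms_error=table["within_error"].ms,
                    df_error=table["within_error"].df,
                    labels=design.within_levels)
    hsd_df = pd.DataFrame([{"comparison": r.comparison, "difference": r.difference,
                            "ci_low": r.ci_low, "ci_high": r.ci_high,
                            "p_adjusted": r.p_adjusted} for r in hsd])
    hsd_df.to_csv(RESULTS / "session_tukey.csv", index=False)
    print("Tukey HSD across sessions:")
    print(hsd_df.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
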