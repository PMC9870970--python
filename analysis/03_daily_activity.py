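"""Daily and seasonal activity statistics.

Aggregates processed records to per sensor x date x period summaries,
computes the treatment differences in microclimate and % activity, the
photosynthesis-permitting-light (PAR >= 70) activity variant, and the
proportion of days with more than 50% activity per season.  Writes
results/activity/.
"""

import argparse
from pathlib import Path

from crustpam import (
    proportion_active_days,
    report_summary_tables,
    summarize_campaign,
    treatment_difference,
)
from crustpam.io import read_processed_csv, write_table_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", default="results/campaign/processed.csv")
    ap.add_argument("--out", default="results/activity")
    args = ap.parse_args()

    processed = read_processed_csv(args.input)
    summaries = summarize_campaign(processed)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    write_table_csv(summaries, out / "daily_summaries.csv")

    sensor_days = summaries.groupby(["sensor_id", "date"]).ngroups
    print(f"{len(summaries)} period summaries over {sensor_days} sensor-days")

    for var, unit in [("mean_temperature", "degC"), ("mean_moisture", "%"),
                      ("pct_activity", "% points")]:
        for period in ("diurnal", "nocturnal"):
            diff = treatment_difference(summaries, var, period=period)
            print(f"  warming - control, {var} ({period}): {diff:+.2f} {unit}")
    for season in ("autumn", "winter", "spring"):
        diff = treatment_difference(
            summaries, "pct_activity", period="diurnal", season=season
        )
        print(f"  diurnal activity deficit, {season}: {diff:+.2f} % points")

    prop = proportion_active_days(summaries[summaries["period"] == "diurnal"])
    write_table_csv(prop, out / "proportion_active_days.csv")
    print("proportion of diurnal sensor-days with > 50% activity:")
    print(prop.to_string(index=False))

    report = report_summary_tables(summaries)
    write_table_csv(report, out / "season_treatment_report.csv")
    print(f"wrote tables under {out}")


if __name__ == "__main__":
    main()
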