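"""Process the raw fluorescence records to activity flags.

Applies the instrument noise filter (Ft >= 10, Fm >= 50 units), computes
PSII efficiency (Yield by day, Fv/Fm by night, standard saturation-pulse
formula), splits diurnal/nocturnal on PAR = 0, and flags metabolic
activity at efficiency >= 0.1.  Writes results/campaign/processed.csv.
"""

import argparse
from pathlib import Path

from crustpam import ProcessingParams, process_records
from crustpam.io import read_monitoring_csv, write_table_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", default="results/campaign/monitoring.csv")
    ap.add_argument("--out", default="results/campaign/processed.csv")
    args = ap.parse_args()

    records = read_monitoring_csv(args.input)
    processed = process_records(records, ProcessingParams())
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    write_table_csv(processed, args.out)

    n = len(processed)
    kept = processed["efficiency"].notna().sum()
    active = int(processed["active"].sum())
    print(f"{n} records; {kept} pass the noise filter, {active} active")
    for period, grp in processed.groupby("period"):
        print(
            f"  {period}: {len(grp)} records, "
            f"{100 * grp['active'].mean():.1f}% active, "
            f"mean efficiency of active records "
            f"{grp.loc[grp['active'], 'efficiency'].mean():.3f}"
        )
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
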