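"""Generate the reference synthetic monitoring campaign.

Six sensors (three control microcosms, three under simulated warming),
30-minute records for the 247-day campaign window, with the latent truth
table (water status, hydration flag, noise-free PSII efficiency) kept for
recovery checks.  Writes results/campaign/.
"""

import argparse
from pathlib import Path

from crustpam import SimConfig, campaign_day_count, simulate_campaign
from crustpam.io import write_monitoring_csv, write_table_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/campaign")
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed)
    records, truth = simulate_campaign(cfg, return_truth=True)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    write_monitoring_csv(records, out / "monitoring.csv")
    write_table_csv(truth, out / "truth.csv")

    days = campaign_day_count(cfg.start_date, cfg.end_date)
    print(f"campaign: {cfg.start_date} .. {cfg.end_date} = {days} days")
    print(
        f"{records['sensor_id'].nunique()} sensors x {days} days x "
        f"{cfg.records_per_day} records/day -> {len(records)} records"
    )
    wet_pct = 100.0 * truth["is_wet"].mean()
    print(f"latent hydration: thalli wet on {wet_pct:.1f}% of all records")
    print(f"wrote {out / 'monitoring.csv'} and {out / 'truth.csv'}")


if __name__ == "__main__":
    main()
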