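"""Calibrate the two radiocarbon determinations on the hominin bone.

The determinations (VIE-1203: 39,858 +/- 736 BP, ultrafiltration;
VIE-1541: 43,212 +/- 295 BP, XAD-2 amino acids) are calibrated and their
68.3% / 95.4% HPD intervals extracted. By default a synthetic
identity-plus-wiggles curve stands in for a published calibration curve;
pass --curve path/to/intcal20.14c to calibrate against the real IntCal20
file if you have downloaded it (intcal.org). On the synthetic curve the
intervals are internally consistent but are NOT the published calendar
ranges, which require IntCal20.

Writes results/radiocarbon/intervals.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from paleotrail import calibration, datasets, synth

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--curve", default=None,
                    help="IntCal-format curve file (default: synthetic curve)")
    ap.add_argument("--out", default=ROOT / "results" / "radiocarbon")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    if args.curve:
        curve = calibration.load_curve(args.curve)
        label = Path(args.curve).name
    else:
        curve = synth.make_calcurve(30_000, 60_000, wiggle_amplitude=150.0,
                                    curve_error=120.0, seed=args.seed)
        label = "synthetic"
    print(f"curve: {label}, cal BP span {curve.t_span[0]:.0f}-{curve.t_span[1]:.0f}")

    rows = []
    for lab, date in datasets.radiocarbon_dates().items():
        density = calibration.calibrate_date(date, curve)
        for level in (0.683, 0.954):
            hpd = calibration.hpd_intervals(density, level)
            for older, younger in hpd.intervals:
                rows.append({"lab_code": lab, "c14_age": date.age,
                             "sigma": date.sigma, "level_pct": level * 100,
                             "older_cal_bp": older, "younger_cal_bp": younger})
            print(f"{lab} ({date.age} +/- {date.sigma:.0f} BP) at "
                  f"{level * 100:.1f}%: "
                  + "; ".join(f"{o:.0f} to {y:.0f} cal BP"
                              for o, y in hpd.intervals))
    pd.DataFrame(rows).to_csv(out / "intervals.csv", index=False)


if __name__ == "__main__":
    main()
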