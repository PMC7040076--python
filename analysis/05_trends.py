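"""Per-stand loess trends in I_flav with 95% CI overlap comparison.

Fits a local quadratic trend of the flavonol index over DOY for each
stand on a shared daily grid and reports where any two stands' 95%
confidence bands fail to overlap — the campaign's criterion for a
stand-level difference in the seasonal trend.
"""

from pathlib import Path

import pandas as pd

from photodose.pipeline import trend_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = pd.read_csv(ROOT / "sim" / "iflav.csv")
    _, rows, overlap = trend_table(records, span=1.0, degree=2)
    rows.to_csv(ROOT / "trends.csv", index=False)
    overlap.to_csv(ROOT / "ci_nonoverlap_intervals.csv", index=False)

    print(f"fitted {rows['stand'].nunique()} stand trends on "
          f"DOY {int(rows['doy'].min())}-{int(rows['doy'].max())}")
    if len(overlap):
        print("non-overlapping 95% CI intervals (stand pair: DOY range):")
        for _, r in overlap.iterrows():
            print(f"  {r.stand_a} vs {r.stand_b}: "
                  f"{int(r.doy_start)}-{int(r.doy_end)}")
    else:
        print("all stand trends overlap everywhere (no detectable difference).")
    print("the evergreen stand's flat light climate should separate it from "
          "the deciduous stands during the pre-leaf-out spring window.")


if __name__ == "__main__":
    main()
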