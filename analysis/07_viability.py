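"""Resazurin viability normalisation on an illustrative plate layout.

The readings are synthetic (no plate-reader export is available) and mimic
the qualitative outcome of the cytotoxicity screen: all hydrogel-treated
wells near or above the untreated control, some above 100% (metabolic
stimulation)."""

from pathlib import Path

import pandas as pd

from gelphys import PlateReadings, viability_pct

OUT = Path(__file__).resolve().parents[1] / "results"

# synthetic plate: blank/negative/positive controls + six treated wells
PLATE = PlateReadings(
    f_blank=100.0,
    f_negative=1100.0,
    f_positive=150.0,
    f_samples=[1080.0, 1150.0, 1220.0, 1010.0, 1130.0, 1250.0],
)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    pcts = viability_pct(PLATE)
    df = pd.DataFrame(
        {"well": [f"S{i + 1}" for i in range(len(pcts))], "viability_pct": pcts}
    )
    df.to_csv(OUT / "viability.csv", index=False)
    above = sum(p > 100 for p in pcts)
    print(
        f"viability {min(pcts):.0f}-{max(pcts):.0f}% across {len(pcts)} wells; "
        f"{above} wells above 100%"
    )


if __name__ == "__main__":
    main()
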