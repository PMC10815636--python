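"""Gel/sol fractions of the three formulations from washing-mass pairs.

The mass pairs are constructed to the measured gel contents (82/77/66% for
PEG-400/1000/2000 crosslinkers): shorter crosslinkers couple more
efficiently, so less material washes out."""

from pathlib import Path

import pandas as pd

from gelphys import SolGelMasses, gel_sol_fraction

OUT = Path(__file__).resolve().parents[1] / "results"

MASS_PAIRS = [
    SolGelMasses("PEG-400", 100.0, 82.0),
    SolGelMasses("PEG-1000", 100.0, 77.0),
    SolGelMasses("PEG-2000", 100.0, 66.0),
]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for m in MASS_PAIRS:
        gel, sol = gel_sol_fraction(m)  # mass_retained convention
        rows.append((m.sample_id, "mass_retained", gel, sol))
        print(f"{m.sample_id}: gel {gel:.0f}%, sol {sol:.0f}%")
    pd.DataFrame(
        rows, columns=["sample_id", "convention", "gel_pct", "sol_pct"]
    ).to_csv(OUT / "solgel_summary.csv", index=False)
    print("gel fraction decreases with crosslinker chain length")


if __name__ == "__main__":
    main()
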