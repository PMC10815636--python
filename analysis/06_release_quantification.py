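"""Fluorescence calibration and cumulative release with aliquot correction
on the simulated release experiment.

Finding: the fitted calibration line recovers the configured response, and
the corrected cumulative-release curve tracks the generator's true
released fraction (~42% at 4 h under the default burst settings); the
uncorrected raw concentrations increasingly underestimate release as
aliquots remove solute."""

from pathlib import Path

import pandas as pd
import yaml

from gelphys import cumulative_release, fit_calibration, load_table

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    sim = OUT / "sim"
    cal = fit_calibration(load_table(sim / "calibration.csv", "calibration"))
    print(
        f"calibration: slope {cal.slope:.1f} a.u./(ug/mL), "
        f"intercept {cal.intercept:.1f} a.u., r^2 = {cal.r_squared:.4f}"
    )
    (exp,) = load_table(sim / "release.csv", "release")
    profile = cumulative_release(exp, cal)
    truth = yaml.safe_load((sim / "ground_truth.yaml").read_text())
    df = profile.points.copy()
    df["release_pct_true"] = [100 * f for f in truth["release_f_true"]]
    df.to_csv(OUT / "release_profile.csv", index=False)
    for _, row in df.iterrows():
        print(
            f"t = {row.t_h:5.1f} h: release {row.release_pct:5.1f}% "
            f"(true {row.release_pct_true:5.1f}%)"
        )


if __name__ == "__main__":
    main()
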