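"""Generate the synthetic study datasets (gravimetric swelling, GPC,
fluorescence calibration, release aliquots) with known ground truth.

Writes CSVs under results/sim/ via the gelphys CLI machinery."""

from pathlib import Path

import yaml

from gelphys import SimConfig, gen_calibration, gen_gpc, gen_release, gen_swelling, write_table

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    write_table(gen_swelling(cfg), OUT / "swelling.csv")
    write_table(gen_gpc(cfg), OUT / "gpc.csv")
    points, truth = gen_calibration(cfg)
    write_table(points, OUT / "calibration.csv")
    exp, f_true = gen_release(cfg)
    write_table([exp], OUT / "release.csv")
    (OUT / "ground_truth.yaml").write_text(
        yaml.safe_dump(
            {
                "seed": SEED,
                "q_inf": cfg.swelling.q_inf,
                "k_hydrolysis": cfg.gpc.k_hydrolysis,
                "calibration": {"slope": truth.slope, "intercept": truth.intercept},
                "release_f_true": [float(f) for f in f_true],
            },
            sort_keys=False,
        )
    )
    print(f"simulated 4 datasets (seed {SEED}) -> {OUT}")


if __name__ == "__main__":
    main()
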