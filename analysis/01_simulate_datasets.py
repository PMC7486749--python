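"""Generate the three synthetic study datasets with known ground truth.

Writes, under results/data/:
  suspension.tsv            duplicate 0/4/8/12/24 h control + PKCi lipidomes
  knockdown_{24,48,72}h.tsv triplicate siScramble/siELOVL1/siSLC27A1 lipidomes
  screen.tsv                quadruplicate two-condition 258-target siRNA screen
  truth.json                every planted species / hit

All downstream scripts read these files through the package's own readers,
exactly as they would read real exported tables.
"""

import json
from pathlib import Path

from lipidisc.core import write_lipidomics_long
from lipidisc.screen import wells_to_frame
from lipidisc.simulate import simulate_knockdown, simulate_screen, simulate_suspension

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    suspension, susp_truth = simulate_suspension(seed=SEED)
    write_lipidomics_long(suspension, OUT / "suspension.tsv")
    print(f"suspension: {len(suspension.designs)} samples × "
          f"{len(suspension.species)} species, "
          f"{len(susp_truth.planted_species)} planted species")

    knockdown, kd_truth = simulate_knockdown(seed=SEED)
    for tp, ds in sorted(knockdown.items()):
        write_lipidomics_long(ds, OUT / f"knockdown_{int(tp)}h.tsv")
    print(f"knockdown: 3 timepoints × {len(knockdown[48.0].designs)} samples, "
          f"{len(kd_truth.planted_species)} planted species "
          f"({sum(p.control_zero for p in kd_truth.planted_species)} "
          f"control-undetectable)")

    wells, screen_truth = simulate_screen(seed=SEED)
    wells_to_frame(wells).to_csv(OUT / "screen.tsv", sep="\t", index=False)
    print(f"screen: {len(wells)} wells, planted hits: "
          f"{sorted(g for g, _, _ in screen_truth.planted_hits)}")

    (OUT / "truth.json").write_text(json.dumps({
        "suspension": susp_truth.to_dict(),
        "knockdown": kd_truth.to_dict(),
        "screen": screen_truth.to_dict(),
    }, indent=2))
    print(f"wrote ground truth to {OUT / 'truth.json'}")


if __name__ == "__main__":
    main()
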