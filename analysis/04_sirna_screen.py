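"""siRNA screen scoring: modified Z pooling, QC, volcano hit calls.

Reads results/data/screen.tsv, pools both culture conditions after modified
Z-score transformation, checks replicate reproducibility, computes per-plate
fold changes against nontargeting controls and calls hits at FC < 0.6 /
FC > 2.5 with p < 0.05 (Welch t).  Calls are compared with the planted
truth.
"""

import json
from pathlib import Path

from lipidisc.screen import call_hits, read_screen_table, replicate_correlation

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    wells = read_screen_table(BASE / "data" / "screen.tsv")
    truth = json.loads((BASE / "data" / "truth.json").read_text())["screen"]
    out = BASE / "screen"
    out.mkdir(parents=True, exist_ok=True)

    corr = replicate_correlation(wells)
    corr.to_frame().to_csv(out / "replicate_correlation.tsv", sep="\t")
    print("replicate-vs-mean Pearson r: "
          + ", ".join(f"{v:.3f}" for v in corr))

    hits = call_hits(wells)
    hits.to_csv(out / "hit_calls.tsv", sep="\t", index=False)
    called = hits[hits["call"].isin(["inducer", "inhibitor"])]
    planted = {g: (d, m) for g, d, m in truth["planted_hits"]}
    print(f"\n{len(called)} hits of {len(hits)} targets:")
    for row in called.sort_values("fold_change").itertuples():
        tag = "planted" if row.target in planted else "FALSE POSITIVE"
        print(f"  {row.target}: {row.call}  FC={row.fold_change:.2f} "
              f"p={row.p_value:.2e}  [{tag}]")
    missed = set(planted) - set(called["target"])
    print(f"missed planted hits: {sorted(missed) if missed else 'none'}")


if __name__ == "__main__":
    main()
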