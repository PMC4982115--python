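"""OR repertoire expression statistics, human versus mouse.

Expressed fractions at FPKM >= 0.01, intact-vs-pseudogene distribution
tests, rank/cumulative skew curves with the half-fraction statistic, the
class I/II contrast, the functionality-score association, and the
segregating-pseudogene sensitivity rerun.
"""

import argparse

from olfscreen.pipeline import PipelineConfig, run_pipeline
from olfscreen.repertoire import score_expression_association


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, out_dir=args.out)
    state = run_pipeline(cfg, ["simulate", "repertoire"])
    table = state["repertoire_table"].set_index(["species", "gene_set"])
    for species in ("human", "mouse"):
        row = table.loc[(species, "all")]
        print(f"{species}:")
        print(f"  expressed intact/pseudo:   "
              f"{row['expressed_fraction_intact']:.1%} / "
              f"{row['expressed_fraction_pseudo']:.1%}")
        print(f"  mean FPKM intact/pseudo:   "
              f"{row['mean_fpkm_intact']:.2f} / {row['mean_fpkm_pseudo']:.2f}"
              f"  (KS p = {row['ks_p_intact_vs_pseudo']:.2e})")
        print(f"  half-fraction (skew):      {row['half_fraction']:.1%}")
        nos = table.loc[(species, "no_segregating")]
        print(f"  ... without segregating loci: half-fraction "
              f"{nos['half_fraction']:.1%}")
    m = state["human_floored"]
    p = score_expression_association(m, state["human"].catalog,
                                     m.samples_in_group("OE"))
    print(f"functionality-score vs expression (median-split KS p): {p:.2e}")


if __name__ == "__main__":
    main()
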