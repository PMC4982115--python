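"""OR transcript curation, structure statistics and aberrant-splice calls.

Curates the simulated assembly (class codes, FPKM and isoform-fraction
filters), decomposes each retained transcript into 5'UTR / CDS / 3'UTR and
reports aberrant (ORF-start-skipping) transcripts against the planted truth.
"""

import argparse

from olfscreen.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed, out_dir=args.out)
    state = run_pipeline(cfg, ["structure"])
    models = state["structure_models"]
    kept = state["structure_kept"]
    truth = state["structure_truth"]
    print(f"assembled transcripts: {len(models)}; after curation: "
          f"{len(kept)}")
    summ = state["structure_summary"]
    for col, label in (("transcript_length", "transcript length"),
                       ("genomic_span", "genomic span"),
                       ("cds_length", "ORF length"),
                       ("utr5_length", "5'UTR length"),
                       ("utr3_length", "3'UTR length")):
        mean, sd = summ[col]
        print(f"  {label:18s} {mean:7.0f} +/- {sd:.0f} bp")
    table = state["structure_table"]
    called = set(table.index[table["aberrant"]])
    planted = set(truth.planted_aberrant_transcript_ids) & set(table.index)
    print(f"aberrant transcripts among curated: called {len(called)}, "
          f"planted {len(planted)}, agreement "
          f"{len(called & planted)}/{len(called | planted) or 1}")
    classes = state["gene_class"]
    mixed = sum(1 for v in classes.values() if v == "mixed")
    print(f"genes with functional + aberrant isoform co-existence: {mixed}")


if __name__ == "__main__":
    main()
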