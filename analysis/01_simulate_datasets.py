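#!/usr/bin/env python
"""Generate the four synthetic datasets the downstream analyses consume.

Writes, under results/data/: the ex vivo active/inactive feature table with
planted JA and 12-OH-JA conversions, the per-genotype MRM signal table with
jasmonate-free aos blanks, the in vitro relative-activity assay, and a toy
differential-expression table — each with its ground truth.
"""

import json
from pathlib import Path

import pandas as pd

from jaspipe.features import write_feature_table, write_sample_meta
from jaspipe.synth import (
    GeneratorConfig,
    gen_de_table,
    gen_exvivo_table,
    gen_invitro_assay,
    gen_quant_dataset,
)

SEED = 0
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(seed=SEED)

    table, truth = gen_exvivo_table(cfg)
    write_feature_table(table, OUT / "exvivo_features.csv")
    write_sample_meta(table.samples, OUT / "exvivo_samples.csv")
    pd.DataFrame(
        [
            {"substrate_feature_id": a, "product_feature_id": b,
             "substrate": s, "product": p, "shift": sh}
            for a, b, s, p, sh in truth.pairs
        ]
    ).to_csv(OUT / "exvivo_ground_truth.csv", index=False)
    print(f"ex vivo: {len(table.features)} features "
          f"({len(truth.pairs)} planted pairs), {len(table.samples)} samples")

    samples, blanks, qtruth = gen_quant_dataset(cfg)
    rows = []
    for s in samples + blanks:
        for analyte, (area, height) in sorted(s.signals.items()):
            rows.append({"sample_id": s.sample_id, "genotype": s.genotype,
                         "matrix": s.matrix, "fresh_weight": s.fresh_weight,
                         "analyte": analyte, "area": area, "height": height})
    pd.DataFrame(rows).to_csv(OUT / "quant_signals.csv", index=False)
    (OUT / "quant_ground_truth.json").write_text(
        json.dumps(qtruth.extra["effect_map"], indent=1, sort_keys=True))
    print(f"quant: {len(samples)} samples + {len(blanks)} aos blanks")

    assay, atruth = gen_invitro_assay(cfg)
    assay.to_csv(OUT / "invitro_assay.csv", index=False)
    print(f"in vitro: {len(assay)} assay rows")

    de, dtruth = gen_de_table(n_up=37, n_down=127, n_null=1000, seed=SEED)
    de.to_csv(OUT / "de_table.csv", index=False)
    print(f"DE: {len(de)} genes, planted {dtruth.true_de_counts}")


if __name__ == "__main__":
    main()
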