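#!/usr/bin/env python
"""Apply the differential-expression filter to the toy transcriptome table.

Splits genes at |log2 fold change| >= 2 with p < 0.01 (fold-change boundary
inclusive, p strict) and writes the up/down lists under results/.
"""

from pathlib import Path

import pandas as pd

from jaspipe.quant import filter_de_table

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    df = pd.read_csv(DATA / "de_table.csv")
    up, down = filter_de_table(df, up_lfc=2.0, down_lfc=-2.0, alpha=0.01)
    up.to_csv(OUT / "de_up.csv", index=False)
    down.to_csv(OUT / "de_down.csv", index=False)
    print(f"{len(up)} genes up, {len(down)} genes down "
          f"of {len(df)} total (|log2FC| >= 2, p < 0.01)")


if __name__ == "__main__":
    main()
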