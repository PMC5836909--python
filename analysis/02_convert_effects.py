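#!/usr/bin/env python
"""Convert reported statistics to Fisher's Zr effect sizes.

Reads results/data/effects.csv (chi-square, F, odds-ratio, Cohen's d,
contingency-table and raw-r records), derives signed Zr with sampling
variance 1/(n-3), and writes the annotated table plus a breakdown of
effect-magnitude classes on the back-transformed correlations.
"""

from collections import Counter
from pathlib import Path

from provmeta.data_io import read_effect_table, write_effect_table
from provmeta.effect_conversion import classify_effect, derive_effect_sizes, zr_to_r

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent / "effects_annotated.csv"


def main():
    records = derive_effect_sizes(read_effect_table(DATA / "effects.csv"))
    write_effect_table(records, OUT)
    kinds = Counter(r.stat_kind for r in records)
    classes = Counter(
        classify_effect(zr_to_r(r.zr)) for r in records if r.zr is not None
    )
    print(f"annotated {len(records)} records -> {OUT}")
    print(f"reported-statistic formats: {dict(kinds)}")
    print(f"effect-magnitude classes (|r|): {dict(classes)}")


if __name__ == "__main__":
    main()
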