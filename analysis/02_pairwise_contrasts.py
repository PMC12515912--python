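"""Constituent-ratio odds-ratio matrices per endpoint from the published
contingency cells.

Writes one 8x8 OR matrix per endpoint plus the long-format table with CIs
and significance marks under results/pairwise/, and prints the headline
citalopram contrasts for the QT prolongation/TdP endpoint.
"""
from pathlib import Path

import pandas as pd

import faerspv as pv

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "pairwise"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables = pv.load_counts_csv(pv.table2_counts_path())
    drugs = list(dict.fromkeys(d for d, _ in tables))
    endpoints = list(dict.fromkeys(e for _, e in tables))

    frames = []
    for endpoint in endpoints:
        pairs = pv.all_pairs(endpoint, drugs, "constituent-ratio", tables=tables)
        pv.or_matrix(pairs).round(4).to_csv(OUT / f"or_matrix_{endpoint}.csv")
        frames.append(pv.pairs_frame(pairs))
    long = pd.concat(frames, ignore_index=True)
    long.to_csv(OUT / "constituent_ratio_long.csv", index=False)

    print("citalopram constituent-ratio contrasts, QT prolongation/TdP:")
    qt = long[(long.endpoint == "qt_tdp") & (long.drug_i == "citalopram")
              & (long.drug_j != "citalopram")]
    for _, row in qt.iterrows():
        mark = "*" if row.significant else " "
        print(f"  vs {row.drug_j:<13} OR {row['or']:5.2f} "
              f"({row.low:.2f}, {row.high:.2f}){mark}")
    print(f"\nwrote {len(endpoints)} matrices and the long table to {OUT}")


if __name__ == "__main__":
    main()
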