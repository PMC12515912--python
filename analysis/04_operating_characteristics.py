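"""Operating characteristics of the estimators on synthetic databases:
parameter recovery over a grid of planted reporting-rate ratios, and the
null false-flag rate of the IC credibility criterion.

Writes results/operating_characteristics.csv.
"""
from math import log2
from pathlib import Path

import pandas as pd

import faerspv as pv
from faerspv.simulate import DrugSpec, SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "operating_characteristics.csv"


def recovery_row(planted: float, n: int, seed: int) -> dict:
    config = SimulationConfig(
        seed=seed, n_reports=n,
        drug_catalog=[DrugSpec(name="target", share=0.03)],
        endpoint_rates={"ep1": 0.01},
        endpoint_terms={"ep1": ["Synthetic event one"]},
        planted_rrr={"target": {"ep1": planted}},
        indication_share=1.0, duplicate_fraction=0.0)
    cohort = pv.build_cohort(
        pv.deduplicate(pv.generate(config)),
        pv.DrugDictionary.from_mapping({"target": []}),
        pv.EndpointDictionary.from_mapping({"ep1": ["Synthetic event one"]}))
    r = pv.evaluate_table("target", "ep1", pv.make_tables(cohort)[("target", "ep1")])
    return {"planted_rrr": planted, "n_reports": n, "a": r.table.a,
            "ror": r.ror.value, "ror_low": r.ror.low, "ror_high": r.ror.high,
            "ic": r.ic.value, "ic025": r.ic.low, "ic975": r.ic.high,
            "log2_planted": log2(planted)}


def null_flag_rate(seed: int) -> float:
    names = [f"drug{i:02d}" for i in range(25)]
    terms = {f"ep{k}": [f"Synthetic event {k}"] for k in range(8)}
    config = SimulationConfig(
        seed=seed, n_reports=60_000,
        drug_catalog=[DrugSpec(name=n, share=0.03) for n in names],
        endpoint_rates={ep: 0.004 for ep in terms},
        endpoint_terms={ep: list(p) for ep, p in terms.items()},
        indication_share=1.0, duplicate_fraction=0.0)
    cohort = pv.build_cohort(
        pv.deduplicate(pv.generate(config)),
        pv.DrugDictionary.from_mapping({n: [] for n in names}),
        pv.EndpointDictionary.from_mapping(terms))
    results = pv.evaluate_all(pv.make_tables(cohort))
    return sum(r.ic_signal for r in results) / len(results)


def main() -> None:
    rows = []
    for planted in (0.25, 1.0, 2.0, 4.0):
        for n in (50_000, 200_000):
            rows.append(recovery_row(planted, n, seed=11))
    frame = pd.DataFrame(rows)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    frame.round(4).to_csv(OUT, index=False)
    print(frame.round(3).to_string(index=False))
    rate = null_flag_rate(seed=12)
    print(f"\nnull IC025>0 false-flag rate over 200 pairs: {rate:.1%} (<= 5% expected)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
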