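"""Sweep objective functions x flexibilities, with and without parsimony.

Reproduces the shape of the central experiment: which optimisation
strategies produce wildtype cells (20-30 divisions, 1.5-2.3 h mean
generation time)? The grid is deliberately reduced (two epsilon1 values,
one epsilon2, five objective combinations) so the whole sweep stays under
~15 minutes on one core; the directional conclusions do not depend on
grid density.

Writes results/objective_sweep.tsv and a wildtype-count table.
"""
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from agefba.reference import load_reference
from agefba.simulate import sweep

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

OBJECTIVE_PAIRS = [
    ("max_growth", None),
    ("max_growth", "max_ngam"),
    ("max_ngam", "max_growth"),
    ("max_atp_production", "max_growth"),
    ("min_glucose_uptake", None),
]
EPSILON1 = [0.0, 0.3]
EPSILON2 = [0.05]


def main() -> None:
    model, _, regulation, ageing = load_reference()
    # 80 h is ~1.5x the reference lifespan; strategies that have not divided
    # by then never will (damage only accumulates)
    table = sweep(model, OBJECTIVE_PAIRS, EPSILON1, EPSILON2, [False, True],
                  ageing, regulation_config=regulation, max_time=80.0)
    table.to_csv(OUT / "objective_sweep.tsv", sep="\t", index=False)

    counts = (table.groupby(["first", "second", "parsimonious"], dropna=False)
              ["wildtype"].sum().reset_index()
              .rename(columns={"wildtype": "n_wildtype"}))
    counts.to_csv(OUT / "wildtype_counts.tsv", sep="\t", index=False)

    print(table.to_string(index=False))
    print("\nWildtype counts per strategy (out of "
          f"{len(EPSILON1) * len(EPSILON2)} parameter combinations):")
    print(counts.to_string(index=False))
    no_growth = table[~table["first"].str.contains("growth")
                      & ~table["second"].fillna("").str.contains("growth")]
    print(f"\nStrategies without a growth objective reached at most "
          f"{no_growth['rls'].max()} divisions.")


if __name__ == "__main__":
    main()
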