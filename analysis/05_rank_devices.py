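"""Estimate usability rank probabilities per stratum.

At every posterior iteration the seven devices are ordered by their anchored
GUS level (rank 1 = highest usability); the fraction of iterations a device
spends at each rank gives its rank-probability profile, the Bayesian
analogue of the published ranking histograms.  The fixed-effect model is
used (selected by DIC in the previous step).

Writes results/rank_matrix_<stratum>.csv and results/rank_long_<stratum>.csv.
"""

from pathlib import Path

from dpi_usability import io
from dpi_usability.bayes import (
    MCMCConfig, ModelSpec, fit_model, rank_long, rank_probabilities,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
CONFIG = dict(chains=2, iterations=12_000, burn_in=2_000)
SEED = 202  # same fits as the DIC step: identical seed and config


def main() -> None:
    records = io.load_records(RESULTS / "cohort.csv")
    for offset, stratum in enumerate(("experienced", "naive")):
        subset = [r for r in records if r.stratum == stratum]
        config = MCMCConfig(seed=SEED + offset, **CONFIG)
        draws = fit_model(subset, ModelSpec("FE"), config)
        matrix = rank_probabilities(draws)
        matrix.to_csv(RESULTS / f"rank_matrix_{stratum}.csv", index_label="device")
        rank_long(matrix).to_csv(
            RESULTS / f"rank_long_{stratum}.csv", index=False
        )
        modal = matrix.idxmax(axis=1)
        first = matrix[1].idxmax()
        print(f"{stratum}: P({first} ranks 1st) = {matrix.loc[first, 1]:.2f}")
        print("  modal ranks: "
              + ", ".join(f"{dev}:{rank}" for dev, rank in modal.items()))
    print(f"wrote rank matrices to {RESULTS}")


if __name__ == "__main__":
    main()
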