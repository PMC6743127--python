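"""Build the device-comparison evidence network.

Every respondent who tested two devices contributes one head-to-head
comparison to the edge between them; Breezhaler sits in all three groups and
connects the network, which is what lets one joint indirect-comparison model
cover all seven devices.  Counts are reported per stratum, mirroring the
published network figure's labelling (experienced counts with naive counts
alongside).

Writes results/network_edges.csv and results/design_summary.csv.
"""

from pathlib import Path

from dpi_usability import io
from dpi_usability.network import assert_connected, build_network, design_summary

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    records = io.load_records(RESULTS / "cohort.csv")
    net = build_network(records)
    net.to_frame().to_csv(RESULTS / "network_edges.csv", index=False)
    design_summary(net).to_csv(RESULTS / "design_summary.csv", index=False)

    for stratum in ("experienced", "naive"):
        assert_connected(net, stratum)
        print(f"{stratum}: network connected via Breezhaler")
    bs = net.edge_count("Breezhaler", "Spiromax")
    print(f"Breezhaler-Spiromax edge carries {bs} respondents "
          f"({net.edge_count('Breezhaler','Spiromax','experienced')} experienced, "
          f"{net.edge_count('Breezhaler','Spiromax','naive')} naive)")
    print(f"Breezhaler-Genuair edge: "
          f"{net.edge_count('Breezhaler','Genuair','experienced')} experienced, "
          f"{net.edge_count('Breezhaler','Genuair','naive')} naive")
    print(f"wrote {RESULTS/'network_edges.csv'}")


if __name__ == "__main__":
    main()
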