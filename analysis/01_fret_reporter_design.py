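"""Reporter-design numbers: why a quench reporter beats conventional FRET here.

Computes the expected FRET efficiencies for the modelled mean dye separations
of the two activation-loop conformations (Alexa488/Alexa568, R0 = 62 A) and
classifies the residue-residue distances against the contact-quenching band.
Both conformations sit high on the FRET curve (~100% vs ~87%), whereas the
quench readout is binary — which is the design argument for the assay.

Writes results/fret_design.csv.
"""

from pathlib import Path

import pandas as pd

from auroraloop.fret import ReporterGeometry, forster_efficiency, quench_classification

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    g = ReporterGeometry()
    rows = [
        {
            "conformation": "active",
            "dye_distance_A": g.distance_active,
            "fret_efficiency_pct": 100 * forster_efficiency(g.distance_active, g.forster_radius),
            "residue_distance_A": g.residue_distance_active,
            "quench_state": quench_classification(g.residue_distance_active, g.quench_band),
        },
        {
            "conformation": "inactive",
            "dye_distance_A": g.distance_inactive,
            "fret_efficiency_pct": 100 * forster_efficiency(g.distance_inactive, g.forster_radius),
            "residue_distance_A": g.residue_distance_inactive,
            "quench_state": quench_classification(g.residue_distance_inactive, g.quench_band),
        },
    ]
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "fret_design.csv", index=False)
    print(df.to_string(index=False))
    print(
        f"\nFRET would report {df.fret_efficiency_pct.round().astype(int).tolist()} % for "
        "[active, inactive]: both high-FRET, poorly separated; the quench reporter "
        f"instead reads {df.quench_state.tolist()}."
    )


if __name__ == "__main__":
    main()
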