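"""Required ligand discrimination to drive the loop to 99/95/90% inactive.

For each starting condition (phosphorylated, unphosphorylated, each with and
without TPX2) computes the discrimination K_d,inactive/K_d,active a
saturating ligand would need to reach target inactive populations, with the
fold preference (1/discrimination).  Reaching 99% inactive takes an 88-fold
preference from the unphosphorylated apo enzyme and 331-fold from the
phosphorylated one, rising to 608-fold with TPX2 bound.  The published
unphosphorylated+TPX2 row is reproducible only from the inverted equilibrium
constant (56/46 instead of the measured 46/56), so that row is emitted in
both conventions and flagged.

Writes results/required_discrimination.csv.
"""

from pathlib import Path

from auroraloop.pipeline import reproduce_table2

OUT = Path(__file__).resolve().parents[1] / "results"

KEQ_START = {
    "phosphorylated": 23 / 77,
    "unphosphorylated": 52 / 46,
    "phosphorylated+TPX2": 14 / 86,
    "unphosphorylated+TPX2": 46 / 56,
}


def main() -> None:
    df = reproduce_table2(KEQ_START, flagged_inverted=("unphosphorylated+TPX2",))
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "required_discrimination.csv", index=False)
    cols = ["condition", "convention"] + [
        f"{q}_{p}_display" for p in (99, 95, 90) for q in ("discrimination", "fold")
    ]
    print(df[cols].to_string(index=False))
    print(
        "\nNote: the unphosphorylated+TPX2 'inverted_keq' row matches the published "
        "values (81/16/7-fold), indicating the published row used the inverse "
        "equilibrium constant."
    )


if __name__ == "__main__":
    main()
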