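"""Regenerate the bundled default quantile tables.

Builds mono/i-th isotope ratio quantile tables (window size 50 Da,
isotope indices 1..5) from 20,000 synthetic formulas spanning
50-1000 Da with the default element profile, and writes them to the
package data directory.  Run from the repository root:

    python scripts/build_default_quantiles.py
"""

from pathlib import Path

from isopick.quantiles import build_quantile_tables, compound_ratios
from isopick.simulate import simulate_formula_db
from isopick.workflow import DEFAULT_TABLES_RESOURCE, save_tables

N_FORMULAS = 20_000
MASS_RANGE = (50.0, 1000.0)
WINDOW_SIZE = 50.0
SEED = 1


def main() -> None:
    formulas = simulate_formula_db(N_FORMULAS, MASS_RANGE, seed=SEED)
    records = compound_ratios(formulas)
    tables = build_quantile_tables(
        records,
        window_size=WINDOW_SIZE,
        source_name=f"synthetic-{N_FORMULAS}-seed{SEED}",
    )
    out = (
        Path(__file__).resolve().parents[1]
        / "src" / "isopick" / "data" / DEFAULT_TABLES_RESOURCE
    )
    save_tables(tables, out)
    print(f"wrote {out} ({out.stat().st_size / 1024:.1f} KiB)")


if __name__ == "__main__":
    main()
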