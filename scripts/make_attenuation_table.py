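"""Regenerate the shipped CZT attenuation table (src/cztpet/data/czt_attenuation.csv).

See cztpet.materials for the provenance of the underlying model.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from cztpet.materials import compute_attenuation_table


def main() -> None:
    table = compute_attenuation_table()
    out = pathlib.Path(__file__).resolve().parents[1] / "src" / "cztpet" / "data"
    out.mkdir(parents=True, exist_ok=True)
    path = out / "czt_attenuation.csv"
    np.savetxt(
        path,
        table,
        delimiter=",",
        header="energy_keV,photoelectric_cm1,incoherent_cm1,coherent_cm1,total_cm1",
        comments="",
        fmt="%.8g",
    )
    print(f"wrote {path} ({table.shape[0]} rows)")


if __name__ == "__main__":
    main()
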