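"""List-mode file I/O (HDF5 container) and CSV export.

Layout (format ``cztpet-listmode-1``): groups ``/events``, ``/photons``,
``/sites`` hold the structure-of-arrays columns; the optional ``/truth``
group carries simulation ground truth (random label, emission point,
first-site index) and is simply absent in experimental-style files.  The
header (units, seed, pairing window, geometry hash, ...) is stored as root
attributes with nested values JSON-encoded.  Writing then reading a dataset
is the identity on every stored field.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .simulate import ListModeData

FORMAT = "cztpet-listmode-1"
EXPECTED_UNITS = {"length": "mm", "energy": "keV", "time": "ns"}


def write_listmode(data: ListModeData, path, include_truth: bool = True) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = FORMAT
        header = dict(data.header)
        header.setdefault("units", EXPECTED_UNITS)
        fh.attrs["header_json"] = json.dumps(header)
        for group, table in (("events", data.events), ("photons", data.photons),
                             ("sites", data.sites)):
            g = fh.create_group(group)
            for k, v in table.items():
                g.create_dataset(k, data=np.asarray(v))
        if include_truth and data.truth is not None:
            g = fh.create_group("truth")
            for k, v in data.truth.items():
                g.create_dataset(k, data=np.asarray(v))


def read_listmode(path) -> ListModeData:
    with h5py.File(path, "r") as fh:
        fmt = fh.attrs.get("format")
        if fmt is None:
            raise ValueError("not a list-mode file: missing 'format' attribute")
        if fmt != FORMAT:
            raise ValueError(f"unsupported list-mode format version: {fmt!r}")
        try:
            header = json.loads(fh.attrs["header_json"])
        except KeyError as exc:
            raise ValueError("corrupted header: missing 'header_json'") from exc
        units = header.get("units")
        if units and units != EXPECTED_UNITS:
            raise ValueError(f"unit mismatch: file declares {units}, "
                             f"expected {EXPECTED_UNITS}")
        out = {}
        for group in ("events", "photons", "sites"):
            if group not in fh:
                raise ValueError(f"truncated file: missing group '{group}'")
            out[group] = {k: fh[group][k][()] for k in fh[group]}
        truth = None
        if "truth" in fh:
            truth = {k: fh["truth"][k][()] for k in fh["truth"]}
    return ListModeData(events=out["events"], photons=out["photons"],
                        sites=out["sites"], truth=truth, header=header)


def export_csv(data: ListModeData, path) -> None:
    """Flat per-site CSV export for interoperability."""
    import pandas as pd
    counts = np.asarray(data.photons["site_count"], int)
    rows = np.repeat(np.arange(counts.size), counts)
    df = pd.DataFrame({
        "event": np.asarray(data.photons["event"])[rows],
        "side": np.asarray(data.photons["side"])[rows],
        "panel": np.asarray(data.photons["panel"])[rows],
        "time_ns": np.asarray(data.photons["time"])[rows],
        "x_mm": data.sites["x"], "y_mm": data.sites["y"],
        "z_mm": data.sites["z"], "energy_keV": data.sites["energy"],
        "module": data.sites["module"],
    })
    df.to_csv(path, index=False)
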