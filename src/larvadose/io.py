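"""File input/output: Touchstone one-port sweeps, cohort and temperature CSVs.

The chamber characterization accepts either a directory of Touchstone v1
``.s1p`` files (one per stirrer position, named so the two angle indices can
be parsed) or a single long-format CSV with columns
``frequency_hz, stirrer1_idx, stirrer2_idx, re_s11, im_s11``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .devstats import RECORD_COLUMNS, CohortTable
from .rc import S11Sweep

__all__ = [
    "read_touchstone_s1p",
    "read_sweep_dir",
    "read_sweep_csv",
    "write_sweep_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_temperatures_csv",
    "write_temperatures_csv",
]

_POS_RE = re.compile(r"(\d+)\D+(\d+)")


def read_touchstone_s1p(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a Touchstone v1 one-port file; returns (frequencies_hz, s11).

    Supports the RI, MA and DB formats and the standard frequency-unit
    keywords of the option line.
    """
    unit_scale = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}
    scale, fmt = 1e9, "MA"  # Touchstone defaults
    freqs, vals = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            toks = line[1:].upper().split()
            for t in toks:
                if t in unit_scale:
                    scale = unit_scale[t]
                if t in ("RI", "MA", "DB"):
                    fmt = t
            continue
        parts = [float(t) for t in line.split()]
        if len(parts) < 3:
            raise ValueError(f"malformed data line in {path}: {raw!r}")
        f, a, b = parts[:3]
        if fmt == "RI":
            s = complex(a, b)
        elif fmt == "MA":
            s = a * np.exp(1j * np.deg2rad(b))
        else:  # DB
            s = 10 ** (a / 20.0) * np.exp(1j * np.deg2rad(b))
        freqs.append(f * scale)
        vals.append(s)
    if not freqs:
        raise ValueError(f"no data in Touchstone file {path}")
    return np.asarray(freqs), np.asarray(vals)


def read_sweep_dir(directory: str | Path, pattern: str = "*.s1p") -> S11Sweep:
    """Assemble an S11Sweep from one Touchstone file per stirrer position.

    Position indices are parsed as the first two integers in each file name
    (e.g. ``pos_03_12.s1p``).
    """
    files = sorted(Path(directory).glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} files in {directory}")
    positions, values, freqs = [], [], None
    for f in files:
        m = _POS_RE.search(f.stem)
        if not m:
            raise ValueError(f"cannot parse stirrer indices from {f.name}")
        fr, s = read_touchstone_s1p(f)
        if freqs is None:
            freqs = fr
        elif not np.allclose(fr, freqs):
            raise ValueError(f"frequency grid of {f.name} differs from the first file")
        positions.append((int(m.group(1)), int(m.group(2))))
        values.append(s)
    return S11Sweep(freqs, positions, np.vstack(values))


def read_sweep_csv(path: str | Path) -> S11Sweep:
    df = pd.read_csv(path)
    need = {"frequency_hz", "stirrer1_idx", "stirrer2_idx", "re_s11", "im_s11"}
    if not need <= set(df.columns):
        raise ValueError(f"sweep CSV needs columns {sorted(need)}")
    freqs = np.sort(df["frequency_hz"].unique())
    positions = sorted(
        {(int(a), int(b)) for a, b in zip(df["stirrer1_idx"], df["stirrer2_idx"])}
    )
    pos_index = {p: i for i, p in enumerate(positions)}
    f_index = {f: j for j, f in enumerate(freqs)}
    values = np.full((len(positions), len(freqs)), np.nan, dtype=complex)
    for row in df.itertuples(index=False):
        i = pos_index[(int(row.stirrer1_idx), int(row.stirrer2_idx))]
        j = f_index[row.frequency_hz]
        values[i, j] = complex(row.re_s11, row.im_s11)
    if np.isnan(values.view(float)).any():
        raise ValueError("sweep CSV does not cover every position x frequency")
    return S11Sweep(freqs, positions, values)


def write_sweep_csv(sweep: S11Sweep, path: str | Path) -> None:
    rows = []
    for (p1, p2), vals in zip(sweep.positions, sweep.values):
        for f, v in zip(sweep.frequencies, vals):
            rows.append((f, p1, p2, v.real, v.imag))
    pd.DataFrame(
        rows, columns=["frequency_hz", "stirrer1_idx", "stirrer2_idx", "re_s11", "im_s11"]
    ).to_csv(path, index=False)


def read_cohort_csv(records_path: str | Path, temps_path: str | Path | None = None) -> CohortTable:
    df = pd.read_csv(records_path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    temps = read_temperatures_csv(temps_path) if temps_path else {}
    return CohortTable(records=df, temperatures=temps)


def write_cohort_csv(cohort: CohortTable, records_path: str | Path,
                     temps_path: str | Path | None = None) -> None:
    cohort.records.to_csv(records_path, index=False)
    if temps_path:
        write_temperatures_csv(cohort.temperatures, temps_path)


def read_temperatures_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    if not {"condition", "temperature_c"} <= set(df.columns):
        raise ValueError("temperatures CSV needs columns condition, temperature_c")
    return {
        str(cond): g["temperature_c"].to_numpy(float)
        for cond, g in df.groupby("condition")
    }


def write_temperatures_csv(temps: dict[str, np.ndarray], path: str | Path) -> None:
    rows = [(c, t) for c, arr in temps.items() for t in np.asarray(arr).ravel()]
    pd.DataFrame(rows, columns=["condition", "temperature_c"]).to_csv(path, index=False)
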