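"""Reading and writing PLUMED-dialect COLVAR and HILLS text files.

Both formats are whitespace-delimited tables introduced by a
``#! FIELDS ...`` header line naming the columns.  Unknown columns are
preserved round-trip as opaque extras.
"""
from __future__ import annotations

import numpy as np

from .sampling import BiasState, Trajectory


class PlumedFormatError(ValueError):
    pass


def _read_table(path):
    fields = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#!"):
                parts = line.split()
                if len(parts) >= 2 and parts[1] == "FIELDS":
                    fields = parts[2:]
                continue
            if fields is None:
                raise PlumedFormatError(
                    f"{path}: data before '#! FIELDS' header (line {lineno})")
            vals = line.split()
            if len(vals) != len(fields):
                raise PlumedFormatError(
                    f"{path}: line {lineno} has {len(vals)} columns, "
                    f"expected {len(fields)}")
            rows.append([float(v) for v in vals])
    if fields is None:
        raise PlumedFormatError(f"{path}: missing '#! FIELDS' header")
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(fields))
    return fields, data


def _write_table(path, fields, columns):
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        arr = np.column_stack(columns) if columns else np.empty((0, len(fields)))
        for row in arr:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


# ----------------------------------------------------------------------
# COLVAR

def write_colvar(trajectory: Trajectory, path, cv_names=None) -> None:
    names = list(cv_names or trajectory.cv_names)
    if len(names) != trajectory.cv_values.shape[1]:
        raise ValueError("cv_names length does not match trajectory CVs")
    dt = trajectory.params.dt if trajectory.params is not None else 1.0
    time = trajectory.steps * dt
    fields = ["time"] + names + ["bias"]
    cols = [time] + [trajectory.cv_values[:, k] for k in range(len(names))] \
                  + [trajectory.bias]
    for key, col in trajectory.extras.items():
        fields.append(key)
        cols.append(np.asarray(col, float))
    _write_table(path, fields, cols)


def read_colvar(path) -> Trajectory:
    """Read a COLVAR file into a coordinate-free :class:`Trajectory`.

    Columns named ``time`` and ``bias`` are mapped to the corresponding
    trajectory fields; every other column is treated as a CV unless it is
    unknown metadata, which is kept in ``extras``.
    """
    fields, data = _read_table(path)
    cols = {f: data[:, i] for i, f in enumerate(fields)}
    time = cols.pop("time", np.arange(len(data), dtype=float))
    bias = cols.pop("bias", np.zeros(len(data)))
    cv_names = list(cols)
    cv_arr = np.column_stack([cols[n] for n in cv_names]) if cv_names \
        else np.empty((len(data), 0))
    return Trajectory(walker_id=0, steps=time, coords=None, cv_values=cv_arr,
                      bias=bias, params=None, cv_names=cv_names)


# ----------------------------------------------------------------------
# HILLS

def write_hills(bias: BiasState, path, cv_names=None) -> None:
    names = list(cv_names) if cv_names else [f"cv{i+1}" for i in range(bias.n_cv)]
    fields = (["time"] + names + [f"sigma_{n}" for n in names]
              + ["height", "biasf"])
    hills = bias.hills
    cols = [np.array([h.time for h in hills])]
    for k in range(bias.n_cv):
        cols.append(np.array([h.center[k] for h in hills]))
    for k in range(bias.n_cv):
        cols.append(np.array([h.widths[k] for h in hills]))
    cols.append(np.array([h.height for h in hills]))
    cols.append(np.full(len(hills), bias.gamma))
    _write_table(path, fields, cols)


def read_hills(path, gamma: float | None = None, RT=None) -> BiasState:
    """Read a HILLS file into a :class:`BiasState`.

    The bias factor is taken from the ``biasf`` column when present
    (first row), else from ``gamma``.
    """
    from .constants import RT_310

    fields, data = _read_table(path)
    cols = {f: i for i, f in enumerate(fields)}
    if "height" not in cols:
        raise PlumedFormatError(f"{path}: no 'height' column")
    cv_names = [f for f in fields
                if f not in ("time", "height", "biasf")
                and not f.startswith("sigma_")]
    sigma_names = [f"sigma_{n}" for n in cv_names]
    for sn in sigma_names:
        if sn not in cols:
            raise PlumedFormatError(f"{path}: missing column {sn}")
    if "biasf" in cols and len(data):
        gamma = float(data[0, cols["biasf"]])
    if gamma is None:
        raise PlumedFormatError(f"{path}: no biasf column and no gamma given")
    bias = BiasState(n_cv=len(cv_names), gamma=gamma,
                     RT=RT_310 if RT is None else RT)
    for row in data:
        center = np.array([row[cols[n]] for n in cv_names])
        widths = np.array([row[cols[sn]] for sn in sigma_names])
        t = row[cols["time"]] if "time" in cols else 0.0
        bias.add_hill(t, center, row[cols["height"]], widths)
    return bias
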