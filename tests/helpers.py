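"""Shared builders for hand-constructed patients and grids."""

import numpy as np

from tbidyn.preprocessing import CensoredPatient, VitalsGrid, derive_cpp


def grid(channel, t, v, pid="P0"):
    return VitalsGrid(pid, channel, np.asarray(t, dtype=np.int64), np.asarray(v, float))


def make_patient(grids, age=48.0, label=False, usable_end=None, start=None, pid="P0",
                 death_hour=None):
    """Hand-built censored patient around explicit grids."""
    icp = grids["icp"]
    return CensoredPatient(
        patient_id=pid,
        grids=grids,
        label=label,
        usable_end=float(usable_end if usable_end is not None else icp.t[-1]),
        monitoring_start=float(start if start is not None else icp.t[0]),
        death_hour=death_hour,
        baseline={"age": age},
    )


def constant_patient(value=12.0, hours=120, age=48.0, pid="P0", map_value=85.0):
    """Patient with constant ICP/MAP on a dense 5-min grid over `hours` hours."""
    t = np.arange(0, hours * 60 + 1, 5)
    g = {
        "icp": grid("icp", t, np.full(t.size, value), pid),
        "map": grid("map", t, np.full(t.size, map_value), pid),
    }
    g["cpp"] = derive_cpp(g["icp"], g["map"])
    return make_patient(g, age=age, pid=pid)
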