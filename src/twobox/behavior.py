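"""Behavioral compartment preference.

PI = (T_V - T_L) / (T_V + T_L), where T_V and T_L are the times spent in the
vanilla and lemon compartments.  Positive values indicate a vanilla
preference; the index is only defined for two-compartment (door-open) trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BoxGeometry
from .synth import Trajectory


@dataclass
class PreferenceIndex:
    trial_id: str
    t_vanilla: float  # s
    t_lemon: float  # s
    pi: float


def preference_index(
    traj: Trajectory,
    geometry: BoxGeometry,
    trial_id: str = "",
    door_open: bool = True,
) -> PreferenceIndex:
    """Dwell-time preference from a box-frame trajectory.

    Each position sample contributes one sample interval to its compartment;
    samples in the doorway belong to the compartment with the nearest
    centroid.  Door-closed trials are refused (the animal cannot choose).
    """

    if not door_open:
        raise ValueError("preference index is defined only for door-open trials")
    comp = geometry.compartment_of(traj.x)
    dt = traj.dt
    dwell = {c: float(np.sum(comp == c)) * dt for c in (1, 2)}
    t_v = dwell[geometry.compartment_for_odor("vanilla")]
    t_l = dwell[geometry.compartment_for_odor("lemon")]
    total = t_v + t_l
    pi = (t_v - t_l) / total if total > 0 else float("nan")
    return PreferenceIndex(trial_id=trial_id, t_vanilla=t_v, t_lemon=t_l, pi=pi)
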