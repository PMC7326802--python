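"""Centralised unit conventions.

Frame schedules and on-disk file formats carry time in *seconds*; all
kinetic math (K1, k2, fine grids) runs in *minutes*.  Every conversion in
the package goes through this module.
"""

from __future__ import annotations

SECONDS_PER_MINUTE = 60.0

#: Physical half-lives in minutes (nuclide registry constants).
HALF_LIVES_MIN: dict[str, float] = {
    "68Ga": 67.71,
    "11C": 20.36,
    "15O": 2.037,
    "18F": 109.77,
    "68Ge": 270.8 * 24.0 * 60.0,
}


def seconds_to_minutes(t_s):
    return t_s / SECONDS_PER_MINUTE


def minutes_to_seconds(t_min):
    return t_min * SECONDS_PER_MINUTE
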