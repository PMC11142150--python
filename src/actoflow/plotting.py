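"""Static figures: flow profiles, stress balance, kymographs."""
from __future__ import annotations

import numpy as np

from .solver import StressDecomposition, VelocityProfile
from .synthetic import SyntheticKymograph

__all__ = ["plot_flow", "plot_stresses", "plot_kymograph"]


def plot_flow(profile: VelocityProfile, ax=None, **kwargs):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.positions, profile.velocities, **kwargs)
    ax.axhline(0.0, color="0.7", lw=0.6)
    ax.set_xlabel("position (um)")
    ax.set_ylabel("velocity")
    return ax


def plot_stresses(dec: StressDecomposition, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(dec.positions, dec.motor, label="motor $F_m$")
    ax.plot(dec.positions, dec.viscous, label=r"viscous $\mu v''$")
    ax.plot(dec.positions, dec.traction, label=r"traction $\xi v$")
    ax.axhline(0.0, color="0.7", lw=0.6)
    ax.set_xlabel("position (um)")
    ax.set_ylabel("stress")
    ax.legend()
    return ax


def plot_kymograph(kymo: SyntheticKymograph, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = (0.0, kymo.intensity.shape[1] * kymo.pixel_size,
              kymo.intensity.shape[0] * kymo.frame_interval, 0.0)
    ax.imshow(1.0 - kymo.intensity, cmap="gray", aspect="auto", extent=extent)
    ax.set_xlabel("position (um)")
    ax.set_ylabel("time")
    return ax
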