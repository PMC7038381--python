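"""Quick-look plots: excitation programme, electrode responses, sweeps."""

from __future__ import annotations

import numpy as np

from .dataset import SensorResponseMatrix
from .simulate import ExcitationSpec, build_excitation

__all__ = ["plot_excitation", "plot_response", "plot_sweep"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_excitation(spec: ExcitationSpec | None = None, ax=None):
    """The multi-frequency pulse waveform over one cycle."""
    spec = spec or ExcitationSpec()
    wave = build_excitation(spec)
    t = np.arange(wave.size) / spec.effective_rate
    ax = _ax(ax)
    ax.step(t, wave, where="post", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("solution voltage (V)")
    ax.set_title("MLAPV excitation")
    return ax


def plot_response(sample: SensorResponseMatrix, sampling_rate: float = 150.0,
                  ax=None):
    """All electrode traces of one sample (log-magnitude friendly scales)."""
    ax = _ax(ax)
    t = np.arange(sample.n_points) / sampling_rate
    for eid, row in zip(sample.electrode_ids, sample.values):
        ax.plot(t, row, lw=0.6, label=eid)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("response (a.u.)")
    ax.legend(fontsize="x-small", ncol=3)
    if sample.label is not None:
        ax.set_title(f"{sample.label} (c={sample.concentration})")
    return ax


def plot_sweep(points, parameter: str = "sigma", ax=None):
    """Accuracy vs parameter on a log axis; failed points marked at 0."""
    ax = _ax(ax)
    xs = [p.value for p in points]
    ys = [p.result.mean_accuracy if p.result else 0.0 for p in points]
    es = [p.result.std_accuracy if p.result else 0.0 for p in points]
    ax.errorbar(xs, ys, yerr=es, marker="o", capsize=3)
    for p in points:
        if p.error:
            ax.annotate("x", (p.value, 0.0), color="red", ha="center")
    ax.set_xscale("log")
    ax.set_xlabel(parameter)
    ax.set_ylabel("accuracy (%)")
    ax.set_ylim(-5, 105)
    return ax
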