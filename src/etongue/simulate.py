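"""Synthetic multi-frequency large-amplitude pulse voltammetry (MLAPV) data.

The generator emulates a six-working-electrode voltammetric e-tongue driven
by a 60 s excitation cycle of three square-pulse frequency segments (0.2, 1
and 2 Hz), each containing five pulses of decreasing solution voltage (1.0
down to 0.2 V, 50% duty cycle), separated by blank cooling-off gaps, sampled
at 150 Hz — 9000 points per electrode.

Each electrode response is a superposition of

* a **common-mode** term: one shared excitation-locked transient template,
  identical on every electrode (what paired differencing cancels);
* a **specificity** term: a per-electrode transient whose pulse-by-pulse
  gains depend on the sample's class and scale with concentration; and
* Gaussian channel noise (an absolute input-referred instrument floor,
  identical on every channel).

Transients are first-order RC charge/discharge responses to the pulse
edges. Electrode sensitivities span several decades (noble metals pass far
larger currents than passivated ones), so pairwise response distances cover
a wide dynamic range — the property that makes kernel-width choice
uncritical downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .dataset import LabeledDataset, SensorResponseMatrix
from .exceptions import ParameterError

__all__ = [
    "ExcitationSpec",
    "ElectrodeModel",
    "DatasetSpec",
    "BEVERAGES",
    "BENCHMARK_LIQUIDS",
    "build_excitation",
    "build_excitation_components",
    "simulate_electrode_response",
    "generate_beverage_dataset",
    "generate_benchmark_mimic",
]

BEVERAGES = (
    "red wine", "white spirit", "beer", "oolong tea",
    "black tea", "maofeng tea", "pu'er tea",
)

BENCHMARK_LIQUIDS = (
    "beer", "red wine", "white spirit", "black tea", "maofeng tea",
    "pu'er tea", "oolong tea", "coffee", "milk", "cola", "vinegar",
    "medicine", "salt",
)


@dataclass
class ExcitationSpec:
    """Square-pulse excitation programme.

    Per frequency segment the waveform steps through every listed amplitude
    once (one pulse period each, 50% duty). Non-pulse time is distributed as
    zero-valued blanks between segments (trailing blank if only one
    segment). ``n_points`` overrides the sample count (e.g. 2050-point
    benchmark recordings); otherwise it is cycle_duration x sampling_rate.
    """

    segment_frequencies: tuple = (0.2, 1.0, 2.0)  # Hz
    pulse_amplitudes: tuple = (1.0, 0.8, 0.6, 0.4, 0.2)  # V in solution
    cycle_duration: float = 60.0  # s
    sampling_rate: float = 150.0  # Hz
    n_points: int | None = None

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.segment_frequencies):
            raise ParameterError("frequencies must be positive")
        if self.cycle_duration <= 0 or self.sampling_rate <= 0:
            raise ParameterError("cycle_duration and sampling_rate must be positive")
        active = sum(len(self.pulse_amplitudes) / f for f in self.segment_frequencies)
        if active > self.cycle_duration:
            raise ParameterError(
                f"active pulse time {active:.2f}s exceeds cycle {self.cycle_duration}s"
            )

    @property
    def n_samples(self) -> int:
        if self.n_points is not None:
            return int(self.n_points)
        return int(round(self.cycle_duration * self.sampling_rate))

    @property
    def effective_rate(self) -> float:
        """Samples per second actually realized (differs from
        ``sampling_rate`` when ``n_points`` overrides the count)."""
        return self.n_samples / self.cycle_duration


def build_excitation_components(spec: ExcitationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Waveform plus its per-amplitude decomposition.

    Returns ``(excitation, components)`` where ``components[a]`` contains
    only the pulses of ``pulse_amplitudes[a]`` (so they sum to the full
    waveform).
    """
    n = spec.n_samples
    fs = spec.effective_rate
    wave = np.zeros(n)
    comps = np.zeros((len(spec.pulse_amplitudes), n))
    seg_lengths = []
    for f in spec.segment_frequencies:
        per = int(round(fs / f))
        seg_lengths.append(per * len(spec.pulse_amplitudes))
    blanks = n - sum(seg_lengths)
    if blanks < 0:
        raise ParameterError("segments do not fit in the cycle at this rate")
    n_gaps = max(len(spec.segment_frequencies) - 1, 1)
    gap_sizes = [blanks // n_gaps + (1 if g < blanks % n_gaps else 0)
                 for g in range(n_gaps)]
    cursor = 0
    for s, f in enumerate(spec.segment_frequencies):
        per = int(round(fs / f))
        on = max(int(round(per / 2)), 1) if per > 0 else 0
        for a, amp in enumerate(spec.pulse_amplitudes):
            wave[cursor:cursor + on] = amp
            comps[a, cursor:cursor + on] = amp
            cursor += per
        if s < len(spec.segment_frequencies) - 1:
            cursor += gap_sizes[s]
    return wave, comps


def build_excitation(spec: ExcitationSpec | None = None) -> np.ndarray:
    """The MLAPV excitation waveform for one cycle."""
    return build_excitation_components(spec or ExcitationSpec())[0]


@dataclass
class ElectrodeModel:
    """Response model of the working-electrode array.

    sensitivities : per-electrode specificity current scale (instrument
        units per volt). Defaults span ~4 decades — a strongly catalytic
        noble electrode down to passivated valve metals — so pairwise
        response distances cover the kernel-width decades of interest.
    decay_constants : per-electrode RC time constants (s) of the pulse-edge
        transients.
    common_mode_gain : scale of the shared excitation-locked template;
        default 1000 = 10x the largest specificity amplitude, so the
        common mode dominates every raw trace.
    common_mode_decay : time constant (s) of the shared template.
    noise_sd : absolute Gaussian noise sd (instrument units) — an
        input-referred amplifier/ADC floor common to all channels; default
        ~1% of the weakest electrode's specificity amplitude.
    class_gain_spread : log-sd of the per-class pulse gains
        (gains are log-normal: exp(spread * N(0,1)) — electrode/analyte
        electrochemical couplings vary over orders of magnitude between
        analytes).
    concentration_exponent : specificity amplitude scales as
        concentration ** exponent; default 0.1, a strongly sublinear
        (adsorption-saturated) concentration-response law.
    concentration_modulation : strength of the class-specific change in
        response *shape* with dilution: effective gains are
        class_gains * exp(modulation * (1 - conc) * M) with a per-class
        direction tensor M ~ N(0,1). Dilution does not merely shrink a
        beverage's fingerprint, it deforms it.
    class_gains : optional explicit (n_classes, m, n_amplitudes) gain array;
        drawn from the dataset seed when None.
    conc_gain_directions : optional explicit modulation tensor M (same
        shape as class_gains); drawn alongside them when None.
    """

    n_electrodes: int = 6
    electrode_ids: tuple = ("Au", "Pt", "Pd", "Ag", "W", "Ti")
    sensitivities: tuple = (100.0, 3.0, 0.08, 0.012, 0.009, 0.006)
    decay_constants: tuple = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35)
    common_mode_gain: float = 1000.0
    common_mode_decay: float = 1.0
    noise_sd: float = 3e-5
    class_gain_spread: float = 3.0
    concentration_exponent: float = 0.1
    concentration_modulation: float = 0.4
    class_gains: np.ndarray | None = None
    conc_gain_directions: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = self.n_electrodes
        if m < 2:
            raise ParameterError("need at least 2 electrodes")
        for name in ("electrode_ids", "sensitivities", "decay_constants"):
            if len(getattr(self, name)) != m:
                raise ParameterError(f"{name} must have length {m}")
        if any(t <= 0 for t in self.decay_constants) or self.common_mode_decay <= 0:
            raise ParameterError("decay constants must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if any(s <= 0 for s in self.sensitivities):
            raise ParameterError("sensitivities must be positive")
        if self.class_gains is not None:
            self.class_gains = np.asarray(self.class_gains, dtype=float)
            if not np.all(np.isfinite(self.class_gains)):
                raise ParameterError("class_gains must be finite")


def _rc_transient(drive: np.ndarray, tau: float, fs: float) -> np.ndarray:
    """First-order RC edge response: charge on rise, discharge on fall."""
    a = np.exp(-1.0 / (fs * tau))
    return lfilter([1.0, -1.0], [1.0, -a], drive)


def draw_class_gains(model: ElectrodeModel, n_classes: int, n_amplitudes: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-class log-normal pulse gains and the concentration-modulation
    directions, both (n_classes, m, n_amplitudes)."""
    shape = (n_classes, model.n_electrodes, n_amplitudes)
    gains = np.exp(model.class_gain_spread * rng.standard_normal(shape))
    directions = rng.standard_normal(shape)
    return gains, directions


def simulate_electrode_response(
    excitation: np.ndarray,
    model: ElectrodeModel,
    class_id: int,
    concentration: float,
    rng: np.random.Generator,
    sampling_rate: float = 150.0,
    label=None,
    sample_id: str = "",
    replicate: int | None = None,
) -> SensorResponseMatrix:
    """One sample's m x d response matrix for a given class and concentration.

    The waveform is decomposed into its amplitude plateaus (descending
    unique nonzero levels) so each pulse amplitude can carry its own
    class-dependent gain. Deterministic given the rng state.
    """
    if not 0 < concentration <= 1:
        raise ParameterError(f"concentration must be in (0, 1], got {concentration}")
    if model.class_gains is None:
        raise ParameterError(
            "model.class_gains is unset; draw it (draw_class_gains) or use a "
            "dataset generator"
        )
    excitation = np.asarray(excitation, dtype=float)
    d = excitation.size
    gains = model.class_gains[class_id]  # (m, n_amp)
    if model.conc_gain_directions is not None and model.concentration_modulation:
        gains = gains * np.exp(
            model.concentration_modulation
            * (1.0 - concentration)
            * model.conc_gain_directions[class_id]
        )
    levels = np.unique(excitation[excitation != 0.0])[::-1]  # descending
    if levels.size > gains.shape[1]:
        raise ParameterError(
            f"waveform has {levels.size} amplitude levels but gains cover "
            f"{gains.shape[1]}"
        )
    comps = np.array([np.where(np.isclose(excitation, lv), excitation, 0.0)
                      for lv in levels])
    common = model.common_mode_gain * _rc_transient(
        excitation, model.common_mode_decay, sampling_rate
    )
    scale = concentration ** model.concentration_exponent
    V = np.empty((model.n_electrodes, d))
    for e in range(model.n_electrodes):
        drive = gains[e, : len(levels)] @ comps if len(levels) else np.zeros(d)
        spec_part = model.sensitivities[e] * scale * _rc_transient(
            drive, model.decay_constants[e], sampling_rate
        )
        V[e] = common + spec_part
        if model.noise_sd > 0:
            V[e] += rng.normal(0.0, model.noise_sd, d)
    return SensorResponseMatrix(
        values=V,
        electrode_ids=list(model.electrode_ids),
        label=label,
        sample_id=sample_id,
        concentration=concentration,
        replicate=replicate,
    )


@dataclass
class DatasetSpec:
    """Full recipe for a simulated dataset (beverage or benchmark design)."""

    class_names: tuple = BEVERAGES
    concentrations: tuple = (0.14, 0.25, 1.00)
    replicates: int = 3
    excitation: ExcitationSpec = field(default_factory=ExcitationSpec)
    electrode_model: ElectrodeModel = field(default_factory=ElectrodeModel)
    seed: int = 0
    total_samples: int | None = None  # benchmark-mimic designs only

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if not self.class_names:
            raise ParameterError("need at least one class")
        if any(not 0 < c <= 1 for c in self.concentrations):
            raise ParameterError("concentrations must lie in (0, 1]")

    def summary_dict(self) -> dict:
        return {
            "classes": list(self.class_names),
            "concentrations": list(self.concentrations),
            "replicates": self.replicates,
            "n_points": self.excitation.n_samples,
            "seed": self.seed,
            "total_samples": self.total_samples,
        }


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """All randomness flows from one seed: stream 0 draws class gains,
    stream 1 draws measurement noise (consumed in sample order)."""
    gains_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(gains_ss), np.random.default_rng(noise_ss)


def _resolve_gains(spec: DatasetSpec, rng: np.random.Generator) -> ElectrodeModel:
    model = spec.electrode_model
    if model.class_gains is None:
        gains, directions = draw_class_gains(
            model, len(spec.class_names), len(spec.excitation.pulse_amplitudes), rng
        )
        dirs = model.conc_gain_directions
        model = replace(model, class_gains=gains,
                        conc_gain_directions=dirs if dirs is not None else directions)
    return model


def generate_beverage_dataset(spec: DatasetSpec | None = None) -> LabeledDataset:
    """The beverage design: |classes| x |concentrations| x replicates samples
    (7 x 3 x 3 = 63 by default, each 6 x 9000), fully determined by the seed.
    """
    spec = spec or DatasetSpec()
    gains_rng, noise_rng = _streams(spec.seed)
    model = _resolve_gains(spec, gains_rng)
    excitation = build_excitation(spec.excitation)
    fs = spec.excitation.effective_rate
    samples = []
    for ci, cls in enumerate(spec.class_names):
        for conc in spec.concentrations:
            for rep in range(spec.replicates):
                samples.append(
                    simulate_electrode_response(
                        excitation, model, ci, conc, noise_rng, fs,
                        label=cls,
                        sample_id=f"{cls}_c{conc:g}_r{rep + 1}",
                        replicate=rep + 1,
                    )
                )
    return LabeledDataset(
        samples=samples,
        provenance={"generator": "beverage", **spec.summary_dict()},
    )


def benchmark_spec(seed: int = 0, **overrides) -> DatasetSpec:
    """Default recipe mimicking the public 13-liquid benchmark:
    114 samples of 6 x 2050 points."""
    kw = dict(
        class_names=BENCHMARK_LIQUIDS,
        concentrations=(1.0,),
        replicates=1,
        excitation=ExcitationSpec(n_points=2050),
        total_samples=114,
        seed=seed,
    )
    kw.update(overrides)
    return DatasetSpec(**kw)


def generate_benchmark_mimic(spec: DatasetSpec | None = None) -> LabeledDataset:
    """Benchmark-mimic design: a stated total spread as evenly as possible
    over the classes (114 over 13 -> ten classes of 9, three of 8), single
    concentration, class sizes all >= 4 so fourfold grouping can cover every
    class in every group.
    """
    spec = spec or benchmark_spec()
    if spec.total_samples is None:
        raise ParameterError("benchmark design requires total_samples")
    C = len(spec.class_names)
    base, extra = divmod(spec.total_samples, C)
    if base < 4:
        raise ParameterError(
            f"{spec.total_samples} samples over {C} classes leaves classes with "
            f"{base} < 4 samples; every class must reach every fourfold group"
        )
    sizes = [base + 1 if k < extra else base for k in range(C)]
    gains_rng, noise_rng = _streams(spec.seed)
    model = _resolve_gains(spec, gains_rng)
    excitation = build_excitation(spec.excitation)
    fs = spec.excitation.effective_rate
    conc = spec.concentrations[0]
    samples = []
    for ci, (cls, n_c) in enumerate(zip(spec.class_names, sizes)):
        for rep in range(n_c):
            samples.append(
                simulate_electrode_response(
                    excitation, model, ci, conc, noise_rng, fs,
                    label=cls,
                    sample_id=f"{cls}_r{rep + 1}",
                    replicate=rep + 1,
                )
            )
    return LabeledDataset(
        samples=samples,
        provenance={"generator": "benchmark_mimic", **spec.summary_dict()},
    )
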