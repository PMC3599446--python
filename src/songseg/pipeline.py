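"""End-to-end segmentation: noise floor -> pulses -> culls -> model ->
sines -> trains/bouts -> per-recording statistics.

``SegmentConfig`` gathers every tunable of the chain with the defaults
documented in each stage's module; it can be loaded from / serialized to
plain dicts (and therefore YAML/JSON) for reproducible runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from songseg.audio_io import Recording, SongAnnotation
from songseg import pulse_detect, pulse_model, sine_detect, song_structure
from songseg.pulse_model import InsufficientPulsesError

__all__ = ["SegmentConfig", "SegmentationResult", "segment"]


@dataclass
class WaveletConfig:
    fmin_hz: float = 100.0
    fmax_hz: float = 900.0
    n_scales: int = 25
    family: str = "cmor1.5-1.0"


@dataclass
class DetectConfig:
    k_sigma: float = 4.0
    refractory_ms: float = 10.0
    window_ms: float = 10.0
    transient_factor: float = 2.0


@dataclass
class CullConfig:
    amp_factor: float = 3.0
    ipi_min_ms: float = 15.0
    ipi_max_ms: float = 100.0
    min_run: int = 2
    min_pulses_for_model: int = 100


@dataclass
class SineConfig:
    frame_ms: float = 100.0
    step_ms: float = 50.0
    nw: float = 4.0
    k_tapers: int = 7
    band_hz: tuple[float, float] = (100.0, 300.0)
    criterion: str = "power"
    alpha: float = 0.05
    power_factor: float = 8.0
    max_jump_hz: float = 30.0
    min_len_frames: int = 3
    bridge_frames: int = 1


@dataclass
class SegmentConfig:
    noise_window_s: float = 1.0
    noise_quantile: float = 0.1
    train_break_s: float = 0.25
    bout_gap_s: float = 0.5
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    cull: CullConfig = field(default_factory=CullConfig)
    sine: SineConfig = field(default_factory=SineConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentConfig":
        kwargs = dict(d)
        for name, sub in [
            ("wavelet", WaveletConfig),
            ("detect", DetectConfig),
            ("cull", CullConfig),
            ("sine", SineConfig),
        ]:
            if name in kwargs and isinstance(kwargs[name], dict):
                sub_kwargs = dict(kwargs[name])
                if "band_hz" in sub_kwargs:
                    sub_kwargs["band_hz"] = tuple(sub_kwargs["band_hz"])
                kwargs[name] = sub(**sub_kwargs)
        return cls(**kwargs)


@dataclass
class SegmentationResult:
    noise: pulse_detect.NoiseEstimate
    candidates: list
    amp_culled: list
    ipi_culled: list
    model_culled: list
    model: pulse_model.PulseModel | None
    sine_trains: list
    pulse_trains: list
    bouts: list
    pauses: list
    annotation: SongAnnotation
    excluded: bool  # too few pulses for a pulse model

    @property
    def final_pulses(self) -> list:
        """Pulses after the last cull that could be applied."""
        return self.model_culled if self.model is not None else self.ipi_culled


def segment(rec: Recording, cfg: SegmentConfig | None = None) -> SegmentationResult:
    """Run the full segmentation chain on one recording channel.

    Recordings whose IPI-culled pulse count falls below
    ``cfg.cull.min_pulses_for_model`` skip the likelihood cull and are
    flagged ``excluded`` (no stable pulse model can be built), mirroring
    the exclusion applied to real individuals.
    """
    if cfg is None:
        cfg = SegmentConfig()
    noise = pulse_detect.estimate_noise_floor(
        rec, window_s=cfg.noise_window_s, quantile=cfg.noise_quantile
    )
    cands = pulse_detect.detect_pulse_candidates(
        rec,
        noise,
        fmin_hz=cfg.wavelet.fmin_hz,
        fmax_hz=cfg.wavelet.fmax_hz,
        n_scales=cfg.wavelet.n_scales,
        wavelet=cfg.wavelet.family,
        k_sigma=cfg.detect.k_sigma,
        refractory_s=cfg.detect.refractory_ms / 1000.0,
        window_s=cfg.detect.window_ms / 1000.0,
        transient_factor=cfg.detect.transient_factor,
    )
    amp = pulse_detect.amp_cull(cands, noise, amp_factor=cfg.cull.amp_factor)
    ipi = pulse_detect.ipi_cull(
        amp,
        ipi_min_s=cfg.cull.ipi_min_ms / 1000.0,
        ipi_max_s=cfg.cull.ipi_max_ms / 1000.0,
        min_run=cfg.cull.min_run,
    )
    model = None
    culled = []
    excluded = True
    try:
        model = pulse_model.build_pulse_model(
            ipi, noise, rec.sample_rate, min_pulses=cfg.cull.min_pulses_for_model
        )
        culled = pulse_model.model_cull(ipi, model)
        excluded = False
    except InsufficientPulsesError:
        pass

    final = culled if model is not None else ipi
    masked = sine_detect.mask_pulses(
        rec, final, window_s=cfg.detect.window_ms / 1000.0
    )
    sines = sine_detect.detect_sine_trains(
        masked,
        noise,
        frame_s=cfg.sine.frame_ms / 1000.0,
        step_s=cfg.sine.step_ms / 1000.0,
        nw=cfg.sine.nw,
        k_tapers=cfg.sine.k_tapers,
        band_hz=cfg.sine.band_hz,
        criterion=cfg.sine.criterion,
        alpha=cfg.sine.alpha,
        power_factor=cfg.sine.power_factor,
        max_jump_hz=cfg.sine.max_jump_hz,
        min_len_frames=cfg.sine.min_len_frames,
        bridge_frames=cfg.sine.bridge_frames,
    )
    pulse_times = np.array([p.center_time_s for p in final])
    trains = song_structure.build_pulse_trains(pulse_times, break_s=cfg.train_break_s)
    typed = [("pulse", (tr.start_s, tr.stop_s)) for tr in trains] + [
        ("sine", (s.start_s, s.stop_s)) for s in sines
    ]
    typed = _drop_overlaps(typed)
    bouts, pauses = song_structure.build_bouts(typed, gap_s=cfg.bout_gap_s)

    ann = SongAnnotation(
        pulses=pulse_times,
        sine_trains=[(s.start_s, s.stop_s) for s in sines],
        pulse_trains=[
            {"start_s": tr.start_s, "stop_s": tr.stop_s, "pulse_indices": tr.pulse_indices}
            for tr in trains
        ],
        bouts=[(b.start_s, b.stop_s) for b in bouts],
        source="automated",
    )
    return SegmentationResult(
        noise=noise,
        candidates=cands,
        amp_culled=amp,
        ipi_culled=ipi,
        model_culled=culled,
        model=model,
        sine_trains=sines,
        pulse_trains=trains,
        bouts=bouts,
        pauses=pauses,
        annotation=ann,
        excluded=excluded,
    )


def _drop_overlaps(typed: list[tuple[str, tuple[float, float]]]):
    """Resolve rare boundary overlaps between detected train intervals.

    Sine frames are 100 ms wide, so a detected sine train can spill a few
    tens of ms into an adjacent pulse train; the later interval is
    trimmed to start at the earlier one's stop (dropped if consumed).
    """
    out: list[tuple[str, tuple[float, float]]] = []
    for typ, (a, b) in sorted(typed, key=lambda x: x[1][0]):
        if out and a < out[-1][1][1]:
            a = out[-1][1][1]
            if b - a <= 0:
                continue
        out.append((typ, (a, b)))
    return out
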