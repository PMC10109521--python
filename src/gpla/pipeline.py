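"""Configuration and the end-to-end GPLA pipeline.

`run_pipeline` sequences the analysis steps — band-pass + analytic signal,
optional reduced-rank whitening, coupling matrix, SVD, phase conventions,
significance test — for each requested band, and records every normalization
choice in the output metadata.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import core, preprocess, significance
from .coupling import SpikeTrainSet, build_coupling_matrix
from .preprocess import RawLFP

__all__ = ["RunConfig", "run_pipeline", "analyze_band"]


@dataclass
class RunConfig:
    """Single source of truth for one analysis run; YAML round-trippable."""

    bands: list[tuple[float, float]] = field(default_factory=lambda: [(15.0, 30.0)])
    mode: str = "plv"
    whiten: bool = False
    variance_threshold: float = 0.99
    edge_margin_cycles: float = 3.0
    min_spikes: int = 50
    sig_method: str = "surrogate"  # surrogate | analytic | none
    jitter_kind: str = "interval"
    n_surrogates: int = 99
    seed: int = 0
    lfp_path: str | None = None
    spike_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.bands = [tuple(float(f) for f in b) for b in self.bands]
        if self.sig_method == "analytic" and not (self.whiten and self.mode == "c"):
            raise ValueError(
                "analytic significance requires whiten=True and mode='c'"
            )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def analyze_band(
    raw: RawLFP,
    spikes: SpikeTrainSet,
    band: tuple[float, float],
    config: RunConfig,
) -> tuple[core.GPLAResult, significance.SignificanceReport | None]:
    """Run the full GPLA chain for one frequency band."""
    analytic = preprocess.bandpass_analytic(raw, band)
    margin = preprocess.edge_margin_samples(analytic, config.edge_margin_cycles)

    unwhitening = None
    lfp_for_coupling = analytic
    if config.whiten:
        model = preprocess.fit_whitening(analytic, config.variance_threshold)
        whitened = preprocess.apply_whitening(analytic, model)
        unwhitening = preprocess.fit_unwhitening(whitened, analytic)
        lfp_for_coupling = whitened

    C = build_coupling_matrix(
        spikes,
        lfp_for_coupling,
        mode=config.mode,
        whitened=config.whiten,
        min_spikes=config.min_spikes,
        edge_margin=margin,
    )
    result = core.decompose(C)
    counts = C.unit_counts if config.mode == "c" else None
    result = core.apply_conventions(result, unwhitening=unwhitening, counts=counts)

    report = None
    if config.sig_method == "analytic":
        report = significance.analytic_test(C)
        result.n_significant = report.n_significant
    elif config.sig_method == "surrogate":
        report = significance.surrogate_test(
            spikes,
            lfp_for_coupling,
            n_surrogates=config.n_surrogates,
            jitter_kind=config.jitter_kind,
            mode=config.mode,
            min_spikes=config.min_spikes,
            edge_margin=margin,
            seed=config.seed,
        )
    return result, report


def run_pipeline(
    config: RunConfig,
    raw: RawLFP | None = None,
    spikes: SpikeTrainSet | None = None,
) -> list[tuple[core.GPLAResult, significance.SignificanceReport | None]]:
    """Analyze every configured band; optionally load inputs and write outputs."""
    from . import io  # local import to keep module import light

    if raw is None:
        if config.lfp_path is None:
            raise ValueError("either pass RawLFP or set lfp_path")
        raw = io.read_lfp(config.lfp_path)
    if spikes is None:
        if config.spike_path is None:
            raise ValueError("either pass SpikeTrainSet or set spike_path")
        lengths = [t.shape[1] for t in raw.trials]
        spikes = io.read_spikes(config.spike_path, raw.fs, lengths)

    out = [analyze_band(raw, spikes, band, config) for band in config.bands]

    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        for band, (result, report) in zip(config.bands, out):
            stem = out_dir / f"gpla_{band[0]:g}-{band[1]:g}Hz"
            io.write_result(result, report, stem)
    return out
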