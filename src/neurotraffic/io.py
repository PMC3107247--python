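"""Recording I/O, pipeline configuration, and orchestration.

Recordings travel either as standard EDF (read via mne, condition labels
supplied separately or as a JSON sidecar) or as a plain binary matrix
(raw float64, epochs x channels x samples) with a JSON sidecar carrying
the sampling rate and epoch labels.  The full pipeline — preprocess,
scalogram, trough detection, interval pooling, distribution fits, PLS —
is driven by a single serializable configuration and is deterministic
given its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .departures import extract_idt_table, idt_table_to_frame
from .distfit import (
    DegenerateSampleError,
    InsufficientSampleError,
    chi_square_gof,
    fit_gamma_mle,
    fit_weibull_mle,
)
from .pls import PLSResult, build_pls_dataset, run_pls
from .recording import EpochedRecording
from .synth import SynthSpec, generate_preprocessed_epochs
from .timefreq import WaveletSpec, morlet_scalogram

log = logging.getLogger("neurotraffic")

__all__ = [
    "read_recording",
    "write_recording",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]


def write_recording(rec: EpochedRecording, path: str | Path) -> Path:
    """Write a recording as raw float64 ``<path>.dat`` + ``<path>.json``.

    The sidecar records shape, sampling rate, condition labels, subject
    and channel names; the binary is C-order (epochs, channels, samples).
    """
    path = Path(path)
    dat = path.with_suffix(".dat")
    rec.data.astype("<f8").tofile(dat)
    meta = {
        "format": "neurotraffic-matrix-v1",
        "dtype": "<f8",
        "shape": list(rec.data.shape),
        "sfreq": rec.sfreq,
        "condition_labels": list(rec.condition_labels),
        "subject": rec.subject,
        "channel_names": list(rec.channel_names),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return dat


def _read_matrix(path: Path) -> EpochedRecording:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar {sidecar}: {exc}") from exc
    for key in ("shape", "sfreq", "condition_labels"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing required field {key!r}")
    shape = tuple(meta["shape"])
    data = np.fromfile(path.with_suffix(".dat"), dtype=meta.get("dtype", "<f8"))
    expected = int(np.prod(shape))
    if data.size != expected:
        raise ValueError(
            f"truncated or oversized data file {path.with_suffix('.dat')}: "
            f"got {data.size} values, sidecar promises {expected}"
        )
    return EpochedRecording(
        data=data.reshape(shape),
        sfreq=float(meta["sfreq"]),
        condition_labels=tuple(meta["condition_labels"]),
        subject=meta.get("subject", "s0"),
        channel_names=tuple(meta.get("channel_names", ())),
    )


def _read_edf(
    path: Path,
    epoch_duration: float | None,
    condition_labels: tuple | None,
    subject: str,
) -> EpochedRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires mne (pip install mne)") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    x = raw.get_data()
    sidecar = path.with_suffix(".json")
    if condition_labels is None and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        condition_labels = tuple(meta.get("condition_labels", ()))
        epoch_duration = epoch_duration or meta.get("epoch_duration")
    if not condition_labels:
        raise ValueError(
            "EDF carries no condition labels: pass condition_labels= or "
            "provide a JSON sidecar"
        )
    n_epochs = len(condition_labels)
    if epoch_duration is None:
        samples_per_epoch = x.shape[1] // n_epochs
    else:
        samples_per_epoch = int(round(epoch_duration * sfreq))
    if samples_per_epoch * n_epochs > x.shape[1]:
        raise ValueError("EDF shorter than the requested epoching")
    epochs = x[:, : samples_per_epoch * n_epochs]
    epochs = epochs.reshape(x.shape[0], n_epochs, samples_per_epoch)
    return EpochedRecording(
        data=np.moveaxis(epochs, 0, 1),
        sfreq=sfreq,
        condition_labels=tuple(condition_labels),
        subject=subject,
        channel_names=tuple(raw.ch_names),
    )


def read_recording(
    path: str | Path,
    format: str | None = None,
    epoch_duration: float | None = None,
    condition_labels: tuple | None = None,
    subject: str = "s0",
) -> EpochedRecording:
    """Load an epoched recording from EDF or the matrix+sidecar format.

    ``format`` is inferred from the suffix (.edf vs .dat/.json) when not
    given.  EDF files need per-epoch condition labels — passed explicitly
    or found in a ``<stem>.json`` sidecar.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _read_edf(path, epoch_duration, condition_labels, subject)
    if format == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown recording format {format!r}")


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on, serializable to YAML."""

    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    threshold_ratio: float = 0.05
    candidates: tuple = ("gamma", "weibull")
    min_fit_n: int = 10
    n_permutations: int = 500
    n_bootstraps: int = 500
    br_threshold: float = 2.57
    seed: int = 0
    band_pass: tuple = (0.5, 55.0)
    notch_hz: float | None = 60.0
    trim: tuple | None = (5.0, 25.0)
    input_paths: tuple = ()
    output_dir: str | None = None
    synth: SynthSpec | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.threshold_ratio < 1:
            raise ValueError("threshold_ratio must lie in [0, 1)")
        if self.n_permutations < 1 or self.n_bootstraps < 1:
            raise ValueError("resampling counts must be >= 1")

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["wavelet"] = dataclasses.asdict(self.wavelet)
        if self.synth is not None:
            d["synth"] = dataclasses.asdict(self.synth)
        text = yaml.safe_dump(_tuples_to_lists(d), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        if "wavelet" in d and isinstance(d["wavelet"], dict):
            w = d["wavelet"]
            w["analysis_frequencies"] = tuple(w.get("analysis_frequencies", ()))
            d["wavelet"] = WaveletSpec(**w)
        if d.get("synth") is not None:
            s = dict(d["synth"])
            for key in ("bands", "effect_channels", "condition_names"):
                if key in s:
                    s[key] = _to_tuple(s[key])
            d["synth"] = SynthSpec(**s)
        for key in ("candidates", "band_pass", "trim", "input_paths"):
            if d.get(key) is not None:
                d[key] = _to_tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _to_tuple(x):
    return tuple(_to_tuple(v) if isinstance(v, list) else v for v in x)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


@dataclass
class PipelineResult:
    """Fit tables, per-parameter PLS results and run provenance."""

    fits: pd.DataFrame
    pls: dict[str, PLSResult]
    provenance: dict
    output_dir: Path | None = None


def fit_idt_cells(
    idt_table: dict, candidates=("gamma", "weibull"), min_fit_n: int = 10
) -> pd.DataFrame:
    """Fit each (subject, condition, channel, frequency) interval sample.

    Cells below the minimum sample size (or with zero variance) are kept
    as rows with NaN parameters and flagged ``missing`` — never
    fabricated.
    """
    rows = []
    for (subject, condition, channel, freq), sample in sorted(idt_table.items()):
        row = {
            "subject": subject, "condition": condition,
            "channel": channel, "frequency_hz": freq, "n": sample.n,
            "missing": False,
        }
        try:
            gfit = fit_gamma_mle(sample, min_n=min_fit_n)
            row.update(shape=gfit.shape, scale=gfit.scale, cv=gfit.cv,
                       loglik=gfit.log_likelihood)
            try:
                gof = chi_square_gof(sample, gfit)
                row.update(chi2=gof.statistic, chi2_df=gof.degrees_of_freedom)
            except ValueError:
                row.update(chi2=np.nan, chi2_df=np.nan)
            if "weibull" in candidates:
                wfit = fit_weibull_mle(sample, min_n=min_fit_n)
                row.update(weibull_shape=wfit.params[0], weibull_scale=wfit.params[1],
                           weibull_loglik=wfit.log_likelihood)
        except (InsufficientSampleError, DegenerateSampleError) as exc:
            log.debug("cell %s flagged missing: %s", (subject, condition, channel,
                                                      freq), exc)
            row.update(shape=np.nan, scale=np.nan, cv=np.nan, loglik=np.nan,
                       chi2=np.nan, chi2_df=np.nan, missing=True)
        rows.append(row)
    return pd.DataFrame(rows)


def compute_scalograms(
    recordings: list[EpochedRecording], wavelet: WaveletSpec
) -> dict:
    """Scalogram per (subject, condition, epoch) of every recording."""
    out = {}
    for rec in recordings:
        for e in range(rec.n_epochs):
            key = (rec.subject, rec.condition_labels[e], e)
            out[key] = morlet_scalogram(rec.data[e], rec.sample_interval, wavelet)
    return out


def run_pipeline(
    config: PipelineConfig,
    recordings: list[EpochedRecording] | None = None,
) -> PipelineResult:
    """Execute preprocess -> scalogram -> departures -> fits -> PLS.

    Recordings come from ``config.input_paths``, the ``recordings``
    argument, or — when neither is given — the synthetic generator in
    ``config.synth``.  Results are written under ``config.output_dir``
    when set: ``fits_shape.tsv``, ``fits_scale.tsv``, ``fits_full.tsv``,
    ``pls_shape/``, ``pls_scale/`` and ``provenance.json``.
    """
    if recordings is None:
        if config.input_paths:
            recordings = [read_recording(p) for p in config.input_paths]
            from .preprocess import preprocess_recording

            recordings = [
                preprocess_recording(r, *config.band_pass,
                                     notch_freq=config.notch_hz, trim=config.trim)
                for r in recordings
            ]
        elif config.synth is not None:
            log.info("generating %d synthetic subjects", config.synth.n_subjects)
            recordings = generate_preprocessed_epochs(
                config.synth,
                low=config.band_pass[0], high=config.band_pass[1],
                notch_freq=config.notch_hz, trim=config.trim,
            )
        else:
            raise ValueError("no input: set input_paths, synth, or pass recordings")

    log.info("stage scalogram: %d recordings x %d epochs",
             len(recordings), recordings[0].n_epochs)
    scalograms = compute_scalograms(recordings, config.wavelet)
    log.info("stage departures/IDT: threshold_ratio=%g", config.threshold_ratio)
    idt = extract_idt_table(scalograms, config.threshold_ratio)
    log.info("stage fits: %d cells", len(idt))
    fits = fit_idt_cells(idt, config.candidates, config.min_fit_n)

    pls_results: dict[str, PLSResult] = {}
    # an element enters PLS only if every subject/condition cell fitted;
    # elements with any missing cell are dropped and recorded
    bad = fits.loc[fits["missing"], ["channel", "frequency_hz"]].drop_duplicates()
    bad_keys = set(map(tuple, bad.to_numpy()))
    if bad_keys:
        log.info("dropping %d element(s) with missing cells from PLS", len(bad_keys))
    keep = ~fits.set_index(["channel", "frequency_hz"]).index.isin(bad_keys)
    usable = fits[keep]
    for parameter in ("shape", "scale"):
        try:
            ds = build_pls_dataset(usable, parameter)
        except ValueError as exc:
            raise RuntimeError(f"stage pls({parameter}) failed: {exc}") from exc
        log.info("stage pls(%s): %d subjects x %d conditions x %d elements",
                 parameter, ds.n_subjects, ds.n_conditions, ds.n_elements)
        pls_results[parameter] = run_pls(
            ds, config.n_permutations, config.n_bootstraps,
            seed=config.seed, threshold=config.br_threshold,
        )

    provenance = {
        "package": "neurotraffic",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_recordings": len(recordings),
        "n_cells": len(idt),
        "n_missing_cells": int(fits["missing"].sum()),
        "dropped_elements": sorted(map(list, bad_keys)),
    }

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        fits.to_csv(out_dir / "fits_full.tsv", sep="\t", index=False)
        base = ["subject", "condition", "channel", "frequency_hz"]
        fits[base + ["shape"]].to_csv(out_dir / "fits_shape.tsv", sep="\t",
                                      index=False)
        fits[base + ["scale"]].to_csv(out_dir / "fits_scale.tsv", sep="\t",
                                      index=False)
        for parameter, res in pls_results.items():
            sub = out_dir / f"pls_{parameter}"
            sub.mkdir(exist_ok=True)
            res.lv_table().to_csv(sub / "latent_variables.tsv", sep="\t",
                                  index=False)
            res.salience_table(0).to_csv(sub / "saliences_lv1.tsv", sep="\t",
                                         index=False)
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))

    return PipelineResult(fits=fits, pls=pls_results, provenance=provenance,
                          output_dir=out_dir)


def write_idt_table(idt_table: dict, path: str | Path) -> None:
    """Export pooled intervals as delimited text (one row per interval)."""
    idt_table_to_frame(idt_table).to_csv(path, sep="\t", index=False)
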