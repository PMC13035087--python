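"""File formats and configuration.

A recording travels as a three-file text bundle in one directory:

* ``signals.csv`` — long format: time_s, channel (1..8), wavelength_nm
  (760|850), intensity
* ``events.csv`` — label, onset_s, duration_s
* ``metadata.json`` — subject_id, visit, age_years, sampling_rate_hz,
  excluded_spans

Signals are written with 9 significant digits so a write/read round trip is
lossless at the declared precision. A minimal read-only SNIRF (HDF5) mapper
covers continuous-wave amplitude recordings with the same montage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .hemodynamics import HrfParams
from .optics import DEFAULT_PATHLENGTH_CM, DPF_COEFFS, DEFAULT_EXTINCTION
from .preprocess import FilterParams, MotionParams, RawRecording
from .protocol import Block

SIGNAL_FMT = "%.9g"


def write_recording(raw: RawRecording, bundle_dir: str | Path) -> Path:
    """Write the three-file bundle; returns the bundle directory."""
    d = Path(bundle_dir)
    d.mkdir(parents=True, exist_ok=True)
    n_ch, n_wl, n_t = raw.intensity.shape
    t = np.arange(n_t) / raw.sampling_rate
    frames = []
    for c in range(n_ch):
        for iw in range(n_wl):
            frames.append(pd.DataFrame({
                "time_s": t,
                "channel": c + 1,
                "wavelength_nm": int(raw.wavelengths[iw]),
                "intensity": raw.intensity[c, iw],
            }))
    sig = pd.concat(frames, ignore_index=True)
    sig.to_csv(d / "signals.csv", index=False,
               float_format=SIGNAL_FMT)
    ev = pd.DataFrame(
        [(b.label, b.onset, b.duration) for b in raw.events],
        columns=["label", "onset_s", "duration_s"],
    )
    ev.to_csv(d / "events.csv", index=False, float_format=SIGNAL_FMT)
    meta = {
        "subject_id": raw.subject_id,
        "visit": raw.visit,
        "age_years": raw.subject_age,
        "sampling_rate_hz": raw.sampling_rate,
        "excluded_spans": [list(s) for s in raw.excluded_spans],
        "wavelengths_nm": list(raw.wavelengths),
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=1))
    return d


def read_recording(bundle_dir: str | Path) -> RawRecording:
    """Read and validate a bundle; schema violations name file and field."""
    d = Path(bundle_dir)
    for fname in ("signals.csv", "events.csv", "metadata.json"):
        if not (d / fname).exists():
            raise InvalidInputError(f"{d}: missing bundle file {fname}")
    meta = json.loads((d / "metadata.json").read_text())
    for key in ("age_years", "sampling_rate_hz"):
        if key not in meta:
            raise InvalidInputError(f"metadata.json: missing field {key!r}")
    fs = float(meta["sampling_rate_hz"])
    wavelengths = tuple(float(w) for w in meta.get("wavelengths_nm", (760, 850)))

    sig = pd.read_csv(d / "signals.csv")
    need = {"time_s", "channel", "wavelength_nm", "intensity"}
    if not need <= set(sig.columns):
        raise InvalidInputError(
            f"signals.csv: missing columns {sorted(need - set(sig.columns))}"
        )
    channels = sorted(sig["channel"].unique())
    if channels != list(range(1, len(channels) + 1)):
        raise InvalidInputError(f"signals.csv: channel ids must be 1..N, got {channels}")
    n_ch = len(channels)
    intensity = None
    n_t = None
    for c in range(n_ch):
        for iw, w in enumerate(wavelengths):
            tr = sig[(sig["channel"] == c + 1) & (sig["wavelength_nm"] == int(w))]
            tr = tr.sort_values("time_s")
            if len(tr) == 0:
                raise InvalidInputError(
                    f"signals.csv: no samples for channel {c + 1} at {w:.0f} nm"
                )
            if not np.all(np.diff(tr["time_s"].to_numpy()) > 0):
                raise InvalidInputError(
                    f"signals.csv: time not strictly increasing for channel "
                    f"{c + 1} at {w:.0f} nm"
                )
            if intensity is None:
                n_t = len(tr)
                intensity = np.empty((n_ch, len(wavelengths), n_t))
            if len(tr) != n_t:
                raise InvalidInputError("signals.csv: ragged channel lengths")
            intensity[c, iw] = tr["intensity"].to_numpy()

    ev = pd.read_csv(d / "events.csv")
    if not {"label", "onset_s", "duration_s"} <= set(ev.columns):
        raise InvalidInputError("events.csv: missing columns")
    events = [Block(str(r.label), float(r.onset_s), float(r.duration_s))
              for r in ev.itertuples()]
    return RawRecording(
        intensity=intensity, sampling_rate=fs, events=events,
        subject_age=float(meta["age_years"]),
        excluded_spans=[tuple(s) for s in meta.get("excluded_spans", [])],
        wavelengths=wavelengths,
        subject_id=str(meta.get("subject_id", "S00")),
        visit=str(meta.get("visit", "pre")),
    )


def read_snirf(path: str | Path) -> RawRecording:
    """Map a continuous-wave SNIRF file's amplitude/wavelength/stim
    structures onto a RawRecording (read-only, /nirs/data1)."""
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        data = nirs["data1"]
        td = np.asarray(data["time"])
        if td.size == 2:  # [start, step] convention
            fs = 1.0 / float(td[1])
            n_t = np.asarray(data["dataTimeSeries"]).shape[0]
        else:
            fs = 1.0 / float(np.median(np.diff(td)))
            n_t = td.size
        dts = np.asarray(data["dataTimeSeries"])  # (time, measurements)
        wls = np.asarray(nirs["probe"]["wavelengths"], dtype=float)
        # measurementList<k> corresponds to column k-1 of dataTimeSeries
        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        src, det, wli = [], [], []
        for k in ml_names:
            ml = data[k]
            src.append(int(np.asarray(ml["sourceIndex"])))
            det.append(int(np.asarray(ml["detectorIndex"])))
            wli.append(int(np.asarray(ml["wavelengthIndex"])))
        pairs = sorted(set(zip(src, det)))
        n_ch = len(pairs)
        intensity = np.empty((n_ch, len(wls), n_t))
        for m, (s, dt, w) in enumerate(zip(src, det, wli)):
            ch = pairs.index((s, dt))
            intensity[ch, w - 1] = dts[:, m]
        events = []
        for k in sorted(nirs.keys()):
            if k.startswith("stim"):
                st = nirs[k]
                name = st["name"][()]
                if isinstance(name, bytes):
                    name = name.decode()
                for row in np.atleast_2d(np.asarray(st["data"])):
                    events.append(Block(str(name), float(row[0]), float(row[1])))
        events.sort(key=lambda b: b.onset)
        meta = nirs.get("metaDataTags", {})
        age = 47.0
        if "age_years" in meta:
            age = float(np.asarray(meta["age_years"]))
    return RawRecording(
        intensity=intensity, sampling_rate=fs, events=events, subject_age=age,
        wavelengths=tuple(wls),
    )


@dataclass
class PipelineConfig:
    """Every analysis parameter, embeddable in outputs."""

    motion: MotionParams = field(default_factory=MotionParams)
    filter: FilterParams = field(default_factory=FilterParams)
    hrf: HrfParams = field(default_factory=HrfParams)
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM
    dpf_coeffs: dict = field(default_factory=lambda: dict(DPF_COEFFS))
    extinction: dict = field(default_factory=lambda: {
        str(int(k)): dict(v) for k, v in DEFAULT_EXTINCTION.items()
    })
    baseline_window_s: float = 10.0
    d_denominator: str = "pooled"      # pooled | baseline
    fisher_z_fc: bool = True
    qc_invalid_ceiling: float = 0.5
    seed: int = 0

    def resolved(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.resolved(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "motion" in kwargs:
            kwargs["motion"] = MotionParams(**kwargs["motion"])
        if "filter" in kwargs:
            kwargs["filter"] = FilterParams(**kwargs["filter"])
        if "hrf" in kwargs:
            kwargs["hrf"] = HrfParams(**kwargs["hrf"])
        return cls(**kwargs)


def write_metrics_table(df: pd.DataFrame, path: str | Path,
                        config: PipelineConfig | None = None) -> None:
    """Write a tidy table; the resolved config hash rides in a header
    comment so outputs are traceable to their parameter set."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
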