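"""Reading and writing recordings, manifests, and pipeline artifacts.

All traces travel as delimited text (CSV) with a fixed 9-significant-digit
float format so write/read round-trips are stable.  Recorded data is read
through a manifest (YAML) that maps file columns to channels, declares the
sampling rate and time unit, and optionally carries the anesthesia-level
schedule — the deposited recordings' internal layout is not assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .radar_model import (
    IQTrace,
    RadarConfig,
    ReferenceTrace,
    get_preset,
    simulate_recording,
    SCENARIO_PRESETS,
)

__all__ = [
    "FLOAT_FORMAT",
    "DatasetManifest",
    "write_iq_csv",
    "read_iq_csv",
    "write_reference_csv",
    "read_reference_csv",
    "write_rate_csv",
    "read_recording",
    "make_fixture",
]

FLOAT_FORMAT = "%.9g"


@dataclass
class DatasetManifest:
    """Column mapping and acquisition metadata for one recording.

    ``columns`` maps logical channels (``time``, ``i``, ``q``,
    ``displacement``) to column names in the files.  ``time_unit`` is
    ``'seconds'`` or ``'samples'`` (sample indices are divided by
    ``sampling_rate``).  ``schedule`` is a list of ``{duration_s, label}``
    dicts partitioning the recording into protocol levels.
    """

    radar_file: str | None = None
    reference_file: str | None = None
    columns: dict[str, str] = field(
        default_factory=lambda: {
            "time": "time_s",
            "i": "i",
            "q": "q",
            "displacement": "displacement_m",
        }
    )
    sampling_rate: float = 1092.0
    time_unit: str = "seconds"
    subject: str = ""
    schedule: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.time_unit not in ("seconds", "samples"):
            raise ValueError("time_unit must be 'seconds' or 'samples'")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"manifest {path} does not parse as a mapping")
        known = cls.__dataclass_fields__.keys()
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown manifest keys: {sorted(unknown)}")
        return cls(**data)

    def schedule_windows(self) -> list[tuple[float, str]]:
        return [(float(s["duration_s"]), str(s["label"])) for s in self.schedule]


# ---------------------------------------------------------------------------
# Trace CSV round-trips
# ---------------------------------------------------------------------------

def write_iq_csv(path: str | Path, trace: IQTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "i": trace.i_channel, "q": trace.q_channel}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_iq_csv(path: str | Path) -> IQTrace:
    df = pd.read_csv(path)
    return IQTrace(
        times=df["time_s"].to_numpy(),
        i_channel=df["i"].to_numpy(),
        q_channel=df["q"].to_numpy(),
    )


def write_reference_csv(path: str | Path, trace: ReferenceTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "displacement_m": trace.displacement}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_reference_csv(path: str | Path) -> ReferenceTrace:
    df = pd.read_csv(path)
    return ReferenceTrace(times=df["time_s"].to_numpy(), displacement=df["displacement_m"].to_numpy())


def write_rate_csv(path: str | Path, series) -> None:
    """Write an InstantRateSeries' uniform-grid output (time, bpm, quality)."""
    pd.DataFrame(
        {"time_s": series.grid_times, "bpm": series.bpm, "quality": series.quality_interp}
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Manifest-driven reading
# ---------------------------------------------------------------------------

def _load_columns(path: Path, colmap: dict[str, str], wanted: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    df = pd.read_csv(path)
    missing = [colmap[w] for w in wanted if colmap.get(w) not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path.name}: {missing}")
    sub = df[[colmap[w] for w in wanted]].copy()
    sub.columns = wanted
    bad = sub.index[sub.isna().any(axis=1)]
    if len(bad):
        rows = ", ".join(str(r + 2) for r in bad[:10])  # +2: header + 1-based
        raise ValueError(f"unparseable/NaN rows in {path.name} at file rows {rows}")
    return sub


def _validated_time_grid(
    time: np.ndarray, manifest: DatasetManifest, name: str
) -> tuple[np.ndarray, bool]:
    """Return times in seconds; flag whether resampling is required.

    Within 1% per-sample jitter of the declared rate the stored timestamps
    are treated as the nominal grid (they may carry text-format rounding)
    and snapped onto an exact uniform grid at the declared rate; beyond
    that the caller must resample the values.
    """
    t = np.asarray(time, dtype=float)
    if manifest.time_unit == "samples":
        t = t / manifest.sampling_rate
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError(f"{name}: too few samples")
    nonmono = np.nonzero(dt <= 0)[0]
    if len(nonmono):
        raise ValueError(f"{name}: non-monotone time at file row {nonmono[0] + 3}")
    declared_dt = 1.0 / manifest.sampling_rate
    jitter_ok = np.all(np.abs(dt - declared_dt) <= 0.01 * declared_dt)
    if jitter_ok:
        t = t[0] + np.arange(len(t)) / manifest.sampling_rate
    return t, not jitter_ok


def read_recording(
    manifest: DatasetManifest, base_dir: str | Path | None = None
) -> tuple[IQTrace | None, ReferenceTrace | None, list[tuple[float, str]]]:
    """Read a recording through its manifest onto validated uniform grids.

    Each declared file's time column must be strictly increasing; if the
    observed grid deviates from the declared sampling rate by more than 1%
    jitter, the channels are resampled onto the declared rate (with a
    warning).  Returns whichever of (radar, reference) the manifest
    declares, plus the level schedule.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    colmap = manifest.columns
    iq = ref = None

    if manifest.radar_file:
        df = _load_columns(base / manifest.radar_file, colmap, ["time", "i", "q"])
        t, needs_resample = _validated_time_grid(
            df["time"].to_numpy(), manifest, Path(manifest.radar_file).name
        )
        i_v, q_v = df["i"].to_numpy(float), df["q"].to_numpy(float)
        if needs_resample:
            warnings.warn(
                f"{manifest.radar_file}: time grid deviates >1% from declared "
                f"{manifest.sampling_rate} Hz; resampling",
                stacklevel=2,
            )
            grid = np.arange(int(np.floor((t[-1] - t[0]) * manifest.sampling_rate)) + 1)
            grid = t[0] + grid / manifest.sampling_rate
            i_v, q_v = np.interp(grid, t, i_v), np.interp(grid, t, q_v)
            t = grid
        iq = IQTrace(times=t, i_channel=i_v, q_channel=q_v)

    if manifest.reference_file:
        df = _load_columns(base / manifest.reference_file, colmap, ["time", "displacement"])
        t, needs_resample = _validated_time_grid(
            df["time"].to_numpy(), manifest, Path(manifest.reference_file).name
        )
        d_v = df["displacement"].to_numpy(float)
        if needs_resample:
            warnings.warn(
                f"{manifest.reference_file}: time grid deviates >1% from declared "
                f"{manifest.sampling_rate} Hz; resampling",
                stacklevel=2,
            )
            grid = np.arange(int(np.floor((t[-1] - t[0]) * manifest.sampling_rate)) + 1)
            grid = t[0] + grid / manifest.sampling_rate
            d_v = np.interp(grid, t, d_v)
            t = grid
        ref = ReferenceTrace(times=t, displacement=d_v)

    if iq is None and ref is None:
        raise ValueError("manifest declares neither a radar file nor a reference file")
    return iq, ref, manifest.schedule_windows()


# ---------------------------------------------------------------------------
# Fixture generator
# ---------------------------------------------------------------------------

def make_fixture(
    name: str,
    seed: int,
    out_dir: str | Path,
    config: RadarConfig | None = None,
    duration_scale: float = 1.0,
) -> DatasetManifest:
    """Write a complete synthetic recording for a named scenario preset.

    Produces ``radar.csv``, ``reference.csv`` and ``manifest.yaml`` under
    ``out_dir``; byte-identical for the same preset, seed, config and
    scale.  Unknown presets raise with the list of available ones.
    """
    preset = get_preset(name, seed=seed, duration_scale=duration_scale)
    if config is None:
        config = RadarConfig(noise_sd=0.05)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iq, ref = simulate_recording(preset.scenario, config)
    write_iq_csv(out / "radar.csv", iq)
    write_reference_csv(out / "reference.csv", ref)
    manifest = DatasetManifest(
        radar_file="radar.csv",
        reference_file="reference.csv",
        sampling_rate=config.sampling_rate,
        subject=f"synthetic:{name}",
        schedule=[{"duration_s": float(d), "label": lab} for d, lab in preset.schedule],
    )
    manifest.save(out / "manifest.yaml")
    return manifest
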