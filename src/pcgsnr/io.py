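"""Reading and writing the formats the pipeline touches.

Paired recordings travel either as two WAV files (PCG + ECG, float32
PCM) with an optional JSON ground-truth sidecar, or as a single CSV with
columns ``t,pcg,ecg`` from which the sampling rate is inferred.  Result
tables are CSV/JSON; a missing threshold ("N/A") is serialized as an
empty CSV cell and a JSON null.  All indices are 0-based sample indices
internally; all reported times are in ms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .simulate import GroundTruth, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "RecordSource",
    "EcgRequiredError",
    "read_recording",
    "write_recording",
    "write_beat_snr_table",
    "write_table",
    "write_json",
]


class EcgRequiredError(ValueError):
    """The method is ECG-referenced: a recording without ECG is unusable."""


@dataclass
class RecordSource:
    """Pointer to a stored recording.

    ``fmt`` is "wav" (``pcg_path`` + ``ecg_path``) or "csv" (a single
    ``pcg_path`` with columns ``t,pcg,ecg``).
    """

    pcg_path: str | Path
    ecg_path: str | Path | None = None
    fmt: str = "wav"
    fs_override: float | None = None


def _read_wav(path: Path) -> tuple[float, np.ndarray]:
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return float(fs), np.asarray(data, dtype=float)


def read_recording(source: RecordSource) -> Recording:
    """Read a paired recording, length-aligned at a single rate.

    If the two WAV headers disagree on the rate, the lower-rate channel
    is resampled up to the higher rate (logged).  A CSV source must hold
    ``t``, ``pcg`` and ``ecg`` columns; the rate is the reciprocal of the
    median time step unless ``fs_override`` is given.
    """
    if source.fmt == "csv":
        df = pd.read_csv(source.pcg_path)
        df.columns = [c.strip().lower() for c in df.columns]
        if "ecg" not in df.columns:
            raise EcgRequiredError("ECG required: CSV has no 'ecg' column")
        if "pcg" not in df.columns:
            raise ValueError("CSV has no 'pcg' column")
        if source.fs_override is not None:
            fs = float(source.fs_override)
        elif "t" in df.columns:
            fs = 1.0 / float(np.median(np.diff(df["t"].to_numpy())))
        else:
            raise ValueError("CSV needs a 't' column or an fs override")
        return Recording(df["pcg"].to_numpy(float), df["ecg"].to_numpy(float),
                         fs, label=Path(source.pcg_path).stem)
    if source.fmt == "wav":
        if source.ecg_path is None:
            raise EcgRequiredError(
                "ECG required: the method is ECG-referenced")
        fs_p, pcg = _read_wav(Path(source.pcg_path))
        fs_e, ecg = _read_wav(Path(source.ecg_path))
        fs = source.fs_override or max(fs_p, fs_e)
        for name, (f, x) in (("pcg", (fs_p, pcg)), ("ecg", (fs_e, ecg))):
            if f != fs:
                up, down = int(round(fs)), int(round(f))
                logger.info("resampling %s from %g to %g Hz", name, f, fs)
                x = resample_poly(x, up, down)
                if name == "pcg":
                    pcg = x
                else:
                    ecg = x
        n = min(len(pcg), len(ecg))
        gt = _read_truth_sidecar(Path(source.pcg_path))
        return Recording(pcg[:n], ecg[:n], float(fs), ground_truth=gt,
                         label=Path(source.pcg_path).stem.removesuffix("_pcg"))
    raise ValueError(f"unknown format {source.fmt!r}")


def _truth_to_json(gt: GroundTruth) -> dict:
    return {
        "beat_latencies_ms": {k: list(map(float, v))
                              for k, v in gt.beat_latencies_ms.items()},
        "subject_latencies_ms": gt.subject_latencies_ms,
        "sigma0": gt.sigma0,
        "s1_p2p": gt.s1_p2p,
        "s2_p2p": gt.s2_p2p,
        "r_peak_indices": list(map(int, gt.r_peak_indices)),
        "target_snr_db": gt.target_snr_db,
    }


def _read_truth_sidecar(pcg_path: Path) -> GroundTruth | None:
    sidecar = pcg_path.with_name(
        pcg_path.stem.removesuffix("_pcg") + "_truth.json")
    if not sidecar.exists():
        return None
    d = json.loads(sidecar.read_text())
    return GroundTruth(
        beat_latencies_ms={k: np.asarray(v)
                           for k, v in d["beat_latencies_ms"].items()},
        subject_latencies_ms=d["subject_latencies_ms"],
        sigma0=d["sigma0"], s1_p2p=d["s1_p2p"], s2_p2p=d["s2_p2p"],
        r_peak_indices=np.asarray(d["r_peak_indices"], dtype=int),
        target_snr_db=d.get("target_snr_db"),
    )


def write_recording(recording: Recording, out_dir: str | Path,
                    fmt: str = "wav") -> list[Path]:
    """Write a recording (and its ground truth, when present) to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    label = recording.label or "recording"
    paths: list[Path] = []
    if fmt == "wav":
        for chan, data in (("pcg", recording.pcg), ("ecg", recording.ecg)):
            p = out_dir / f"{label}_{chan}.wav"
            wavfile.write(p, int(round(recording.fs_hz)),
                          np.asarray(data, dtype=np.float32))
            paths.append(p)
    elif fmt == "csv":
        p = out_dir / f"{label}.csv"
        t = np.arange(len(recording.pcg)) / recording.fs_hz
        pd.DataFrame({"t": t, "pcg": recording.pcg, "ecg": recording.ecg}
                     ).to_csv(p, index=False)
        paths.append(p)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if recording.ground_truth is not None:
        p = out_dir / f"{label}_truth.json"
        p.write_text(json.dumps(_truth_to_json(recording.ground_truth)))
        paths.append(p)
    return paths


def write_beat_snr_table(recording_snr, path: str | Path) -> Path:
    """Per-beat SNR table: beat index, amplitudes, sigma, SNRs in dB."""
    path = Path(path)
    rows = [{
        "beat_index": b.beat_index, "a_s1": b.a_s1, "a_s2": b.a_s2,
        "sigma_n": b.sigma_n, "snr_s1_db": b.snr_s1_db,
        "snr_s2_db": b.snr_s2_db,
    } for b in recording_snr.beats]
    pd.DataFrame(rows, columns=["beat_index", "a_s1", "a_s2", "sigma_n",
                                "snr_s1_db", "snr_s2_db"]).to_csv(
        path, index=False, na_rep="")
    return path


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table; missing values become empty cells."""
    path = Path(path)
    df.to_csv(path, index=False, na_rep="")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_json(obj, path: str | Path) -> Path:
    """Write results as JSON; non-finite numbers become null."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=2))
    return path
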