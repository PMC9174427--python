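"""Standard-format I/O for pipeline artifacts.

WAV for audio (32-bit float mono), CSV for tables and S2 matrices, JSON for
models and reports, multi-page TIFF for Z-stacks.  Readers raise with the
offending file named rather than returning partial data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from scipy.io import wavfile

from .s2_features import S2Record
from .valve_imaging import LeafletStack


def write_wav(path, samples: np.ndarray, rate_hz: float) -> None:
    wavfile.write(str(path), int(round(rate_hz)), np.asarray(samples, dtype=np.float32))


def read_wav(path) -> Tuple[np.ndarray, float]:
    """Read a mono WAV; raises with the path on malformed/truncated input."""
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # re-raise with file context
        raise ValueError(f"cannot parse WAV file {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    return data.astype(float), float(rate)


def write_s2_matrix(path_matrix, path_meta, records: Sequence[S2Record]) -> None:
    """Persist S2 waveforms as a CSV matrix plus a sidecar metadata CSV."""
    mat = np.stack([r.waveform for r in records])
    np.savetxt(str(path_matrix), mat, delimiter=",")
    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "session_id": [r.session_id for r in records],
            "label": [r.label for r in records],
        }
    )
    meta.to_csv(str(path_meta), index=False)


def read_s2_matrix(path_matrix, path_meta) -> List[S2Record]:
    mat = np.loadtxt(str(path_matrix), delimiter=",", ndmin=2)
    meta = pd.read_csv(str(path_meta))
    if len(mat) != len(meta):
        raise ValueError(
            f"{path_matrix}: {len(mat)} waveforms but {len(meta)} metadata rows in {path_meta}"
        )
    return [
        S2Record(
            waveform=row,
            subject_id=str(m.subject_id),
            session_id=str(m.session_id),
            label=str(m.label),
        )
        for row, m in zip(mat, meta.itertuples())
    ]


def write_stack(path_osteo, path_auto, stack: LeafletStack) -> None:
    tifffile.imwrite(str(path_osteo), stack.osteo_channel.astype(np.float32))
    tifffile.imwrite(str(path_auto), stack.auto_channel.astype(np.float32))


def read_stack(path_osteo, path_auto, cusp: str = "", subject_id: str = "") -> LeafletStack:
    try:
        osteo = tifffile.imread(str(path_osteo)).astype(float)
        auto = tifffile.imread(str(path_auto)).astype(float)
    except Exception as exc:
        raise ValueError(f"cannot parse TIFF stack ({path_osteo}, {path_auto}): {exc}") from exc
    return LeafletStack(osteo_channel=osteo, auto_channel=auto, cusp=cusp, subject_id=subject_id)


def write_feature_space(path, space) -> None:
    """Persist a PCA feature space as JSON (mean, modes, fractions)."""
    from .s2_features import FeatureSpace  # local import avoids cycle at module load

    assert isinstance(space, FeatureSpace)
    write_json(path, {
        "mean_waveform": space.mean_waveform,
        "components": space.components,
        "explained_fractions": space.explained_fractions,
        "retained_indices": space.retained_indices,
        "variance_threshold": space.variance_threshold,
    })


def read_feature_space(path):
    from .s2_features import FeatureSpace

    d = read_json(path)
    return FeatureSpace(
        mean_waveform=np.asarray(d["mean_waveform"]),
        components=np.asarray(d["components"]),
        explained_fractions=np.asarray(d["explained_fractions"]),
        retained_indices=np.asarray(d["retained_indices"], dtype=np.int64),
        variance_threshold=d["variance_threshold"],
    )


def write_json(path, payload: Dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def read_json(path) -> Dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
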