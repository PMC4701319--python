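"""Reading and writing recordings.

Two on-disk forms are supported:

* a plain numeric matrix (CSV or TSV, channels x samples) together with a
  YAML sidecar holding ``fs`` and ``labels`` — this is the text-friendly
  interchange format the synthetic generator writes;
* EDF, read through MNE when it is installed (EDF export additionally needs
  MNE's EDF writer backend and raises a clear error when unavailable).

Channel labels are matched case-insensitively against the 10-20 names by
downstream region grouping.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .preprocess import MultichannelRecording

__all__ = [
    "read_recording",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_edf",
    "sidecar_path",
]


def sidecar_path(matrix_path: str | Path) -> Path:
    return Path(matrix_path).with_suffix(".yaml")


def read_matrix_csv(
    path: str | Path, sidecar: str | Path | None = None
) -> MultichannelRecording:
    """Channels x samples matrix with a ``{fs, labels}`` YAML sidecar."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"sidecar {sidecar} not found (needs keys 'fs' and 'labels')"
        )
    meta = yaml.safe_load(sidecar.read_text())
    if not isinstance(meta, dict) or "fs" not in meta or "labels" not in meta:
        raise ValueError(f"sidecar {sidecar} must define 'fs' and 'labels'")
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    return MultichannelRecording(
        data=data, fs=float(meta["fs"]), labels=[str(x) for x in meta["labels"]]
    )


def write_matrix_csv(
    rec: MultichannelRecording, path: str | Path, fmt: str = "%.6f"
) -> tuple[Path, Path]:
    """Write the matrix CSV and its YAML sidecar; returns both paths."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, rec.data, delimiter=",", fmt=fmt)
    side = sidecar_path(path)
    side.write_text(
        yaml.safe_dump({"fs": float(rec.fs), "labels": list(rec.labels)})
    )
    return path, side


def read_edf(path: str | Path) -> MultichannelRecording:
    """Read an EDF recording via MNE; amplitudes converted to microvolts."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env without mne
        raise ImportError(
            "reading EDF requires the 'mne' package (install mwtselect[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads volts
    return MultichannelRecording(
        data=data, fs=float(raw.info["sfreq"]), labels=list(raw.ch_names)
    )


def read_recording(
    path: str | Path, sidecar: str | Path | None = None
) -> MultichannelRecording:
    """Dispatch on extension: ``.edf`` via MNE, else CSV/TSV + sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    return read_matrix_csv(path, sidecar)
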