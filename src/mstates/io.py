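"""Reading and writing the pipeline's exchange formats.

Recordings travel as EDF or as plain TSV matrices (header row of channel
names, one row per sample, microvolts); montages as ``.sfp``-style text
(``label x y z`` per line). EDF reading goes through MNE; writing uses a
minimal EDF(+-free) writer (16-bit, per-channel physical scaling) since
round-trip fidelity at EDF's native precision is all the pipeline needs.
Leadfield/parcellation bundles, connectivity matrices, edge lists and
tidy parameter tables are TSV; manifests and models are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, Leadfield, Parcellation
from .recording import EEGRecording, Montage

__all__ = [
    "read_sfp",
    "write_sfp",
    "read_tsv_recording",
    "write_tsv_recording",
    "read_edf",
    "write_edf",
    "read_recording",
    "write_recording",
    "write_leadfield_bundle",
    "read_leadfield_bundle",
    "write_connectivity_matrix",
    "write_json",
]


# ---------------------------------------------------------------------------
# Montage


def read_sfp(path) -> Montage:
    names, pos = [], []
    for line in Path(path).read_text().strip().splitlines():
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"malformed .sfp line: {line!r}")
        names.append(parts[0])
        pos.append([float(v) for v in parts[1:4]])
    return Montage(channel_names=names, positions=np.array(pos))


def write_sfp(montage: Montage, path) -> None:
    lines = [
        f"{n}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}"
        for n, p in zip(montage.channel_names, montage.positions)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _match_montage(names: list[str], montage: Montage) -> list[int]:
    """Row order mapping montage channels onto file channels (case-insensitive)."""
    lowered = [n.lower() for n in names]
    order = []
    for ch in montage.channel_names:
        if ch.lower() not in lowered:
            raise KeyError(f"montage channel {ch!r} not found in file")
        order.append(lowered.index(ch.lower()))
    return order


# ---------------------------------------------------------------------------
# TSV recordings


def write_tsv_recording(rec: EEGRecording, path) -> None:
    df = pd.DataFrame(rec.data.T, columns=rec.montage.channel_names)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_tsv_recording(path, montage: Montage, sfreq: float) -> EEGRecording:
    df = pd.read_csv(path, sep="\t")
    order = _match_montage(list(df.columns), montage)
    data = df.to_numpy(dtype=float).T[order]
    return EEGRecording(data=data, sfreq=sfreq, montage=montage)


# ---------------------------------------------------------------------------
# EDF


def write_edf(rec: EEGRecording, path) -> None:
    """Write a minimal EDF file (int16, per-channel physical scaling).

    Record duration is 1 s when the sample count divides evenly, else
    one sample per record, so every sample is preserved exactly.
    """
    sfreq = rec.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    sfreq = int(round(sfreq))
    C, T = rec.data.shape
    if T % sfreq == 0:
        spr, n_rec, rec_dur = sfreq, T // sfreq, "1"
    else:
        spr, n_rec, rec_dur = 1, T, f"{1.0 / sfreq:.8f}"[:8]
    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    # round-trip through the 8-char ascii header field so the scaling the
    # reader reconstructs is exactly the one used to digitise
    phys_str = [f"{m:.5g}"[:7] for m in phys_max]
    phys_max = np.array([float(s) for s in phys_str])
    phys_max = np.maximum(phys_max, 1e-6)
    scale = 32767.0 / phys_max
    digital = np.clip(
        np.round(rec.data * scale[:, None]), -32768, 32767
    ).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + C)), 8),
            pad("EDF", 44),
            pad(str(n_rec), 8),
            pad(rec_dur, 8),
            pad(str(C), 4),
        ]
    )
    fields = [
        [pad(n, 16) for n in rec.montage.channel_names],  # label
        [pad("AgAgCl electrode", 80)] * C,  # transducer
        [pad("uV", 8)] * C,  # physical dimension
        [pad(f"-{s}"[:8], 8) for s in phys_str],  # physical min
        [pad(s, 8) for s in phys_str],  # physical max
        [pad("-32768", 8)] * C,  # digital min
        [pad("32767", 8)] * C,  # digital max
        [pad("", 80)] * C,  # prefiltering
        [pad(str(spr), 8)] * C,  # samples per record
        [pad("", 32)] * C,  # reserved
    ]
    header += b"".join(b"".join(f) for f in fields)
    body = (
        digital.reshape(C, n_rec, spr)
        .transpose(1, 0, 2)  # record-major, channel blocks inside
        .tobytes()
    )
    Path(path).write_bytes(header + body)


def read_edf(path, montage: Montage | None = None) -> EEGRecording:
    """Read an EDF recording via MNE; amplitudes normalised to microvolts."""
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as err:  # malformed header etc.
        raise ValueError(f"could not parse EDF file {path}: {err}") from err
    data = raw.get_data() * 1e6  # MNE loads volts
    names = list(raw.ch_names)
    if montage is None:
        n = len(names)
        pos = np.zeros((n, 3))
        pos[:, 2] = 1.0
        pos[:, 0] = np.linspace(-1, 1, n)
        montage = Montage(names, pos)
        order = list(range(n))
    else:
        order = _match_montage(names, montage)
    return EEGRecording(
        data=data[order], sfreq=float(raw.info["sfreq"]), montage=montage
    )


# ---------------------------------------------------------------------------
# Dispatch


def read_recording(
    path, montage_path=None, montage: Montage | None = None, sfreq: float | None = None
) -> EEGRecording:
    """Read EDF or TSV by extension; TSV requires an explicit ``sfreq``."""
    path = Path(path)
    if montage is None and montage_path is not None:
        montage = read_sfp(montage_path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return read_edf(path, montage)
    if suffix in (".tsv", ".txt"):
        if montage is None:
            raise ValueError("TSV recordings need a montage")
        if sfreq is None:
            raise ValueError("TSV recordings need an explicit sampling rate")
        return read_tsv_recording(path, montage, sfreq)
    raise ValueError(f"unsupported recording format {suffix!r}")


def write_recording(rec: EEGRecording, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        write_edf(rec, path)
    else:
        write_tsv_recording(rec, path)


# ---------------------------------------------------------------------------
# Leadfield / parcellation / connectivity tables


def write_leadfield_bundle(
    lf: Leadfield, parc: Parcellation, directory
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(lf.gain).to_csv(
        directory / "gain.tsv", sep="\t", index=False, header=False
    )
    pd.DataFrame(lf.source_positions, columns=["x", "y", "z"]).assign(
        region=[parc.region_names[r] for r in parc.region_of_source]
    ).to_csv(directory / "sources.tsv", sep="\t", index=False)
    (directory / "meta.json").write_text(
        json.dumps({"alpha": lf.alpha, "region_names": parc.region_names})
    )


def read_leadfield_bundle(directory) -> tuple[Leadfield, Parcellation]:
    directory = Path(directory)
    gain = pd.read_csv(directory / "gain.tsv", sep="\t", header=None).to_numpy()
    src = pd.read_csv(directory / "sources.tsv", sep="\t")
    meta = json.loads((directory / "meta.json").read_text())
    lf = Leadfield(
        gain=gain,
        source_positions=src[["x", "y", "z"]].to_numpy(),
        alpha=float(meta["alpha"]),
    )
    names = list(meta["region_names"])
    parc = Parcellation(
        region_of_source=[names.index(r) for r in src["region"]],
        region_names=names,
    )
    return lf, parc


def write_connectivity_matrix(cm: ConnectivityMatrix, path) -> None:
    pd.DataFrame(
        cm.values, index=cm.region_names, columns=cm.region_names
    ).to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serialisable: {type(o)}")
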