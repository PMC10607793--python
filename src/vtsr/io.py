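"""File formats: NIfTI volumes, WAV audio, JSON sidecars, CSV tables.

Dynamic slice series are stored as 4D NIfTI (x, y, 1, t) with the frame
period in the TR header slot and a JSON sidecar carrying the acquisition
geometry ({slice_position_mm, thickness_mm, frame_period_s, ...}); the
sidecar replaces the scanner's TTL event log, including the audio marker
indices.  Super-resolved series are 4D NIfTI with isotropic spacing.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.io import wavfile

from vtsr.audio_align import AudioTrack, FrameMap
from vtsr.core import SliceTimeSeries
from vtsr.phantom import SyntheticAudio
from vtsr.registration import RegistrationResult
from vtsr.superres import SRVolume

__all__ = [
    "read_slice_series",
    "write_slice_series",
    "write_sr_series",
    "read_sr_series",
    "read_audio",
    "write_audio",
    "write_frame_map",
    "read_frame_map",
    "write_transforms",
]

log = logging.getLogger("vtsr")

DEFAULT_FRAME_PERIOD_S = 0.020


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_slice_series(
    series: SliceTimeSeries, path: str | Path, voxel_mm: float = 1.6, extra: dict | None = None
) -> None:
    path = Path(path)
    arr = series.data.transpose(2, 1, 0)[:, :, None, :]  # (x, y, 1, t)
    img = nib.Nifti1Image(arr.astype(np.float32), affine=np.diag([voxel_mm, voxel_mm, series.thickness_mm, 1.0]))
    img.header.set_zooms((voxel_mm, voxel_mm, series.thickness_mm, series.frame_period_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    sidecar = {
        "slice_position_mm": series.slice_position_mm,
        "thickness_mm": series.thickness_mm,
        "frame_period_s": series.frame_period_s,
        "slice_index": series.slice_index,
        "repetition": series.repetition,
    }
    if extra:
        sidecar.update(extra)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_slice_series(path: str | Path) -> SliceTimeSeries:
    """Read a 4D slice series plus its JSON sidecar; axis order is
    normalized to (time, y, x)."""
    path = Path(path)
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 4 or arr.shape[2] != 1:
        raise ValueError(f"expected (x, y, 1, t) NIfTI, got shape {arr.shape}")
    data = arr[:, :, 0, :].transpose(2, 1, 0)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FileNotFoundError(f"missing sidecar {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    for field in ("slice_position_mm", "thickness_mm"):
        if field not in sidecar:
            raise ValueError(f"sidecar {sc_path} missing required field {field!r}")
    frame_period = sidecar.get("frame_period_s")
    if frame_period is None:
        frame_period = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if frame_period <= 0:
            log.warning("no frame period in sidecar or TR header; defaulting to %.3f s",
                        DEFAULT_FRAME_PERIOD_S)
            frame_period = DEFAULT_FRAME_PERIOD_S
    return SliceTimeSeries(
        data=data,
        slice_position_mm=float(sidecar["slice_position_mm"]),
        thickness_mm=float(sidecar["thickness_mm"]),
        frame_period_s=float(frame_period),
        slice_index=int(sidecar.get("slice_index", 0)),
        repetition=int(sidecar.get("repetition", 0)),
        meta=sidecar,
    )


def write_sr_series(
    volumes: list[SRVolume], path: str | Path, frame_period_s: float = DEFAULT_FRAME_PERIOD_S
) -> None:
    """Write a list of SR volumes as 4D NIfTI (isotropic spacing in the
    header) plus a JSON log of per-volume solver settings."""
    if not volumes:
        raise ValueError("empty volume list")
    shapes = {v.data.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError("volumes must share one shape")
    path = Path(path)
    vx = volumes[0].voxel_mm
    arr = np.stack([v.data.transpose(2, 1, 0) for v in volumes], axis=-1)  # (x, y, z, t)
    img = nib.Nifti1Image(arr.astype(np.float32), affine=np.diag([vx, vx, vx, 1.0]))
    img.header.set_zooms((vx, vx, vx, frame_period_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    logrec = [
        {
            "iterations": v.iterations_used,
            "residual": v.final_residual,
            **{k: val for k, val in v.meta.items()},
        }
        for v in volumes
    ]
    _sidecar_path(path).write_text(json.dumps(logrec, indent=1, sort_keys=True))


def read_sr_series(path: str | Path) -> list[SRVolume]:
    path = Path(path)
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 4:
        raise ValueError(f"expected 4D NIfTI, got shape {arr.shape}")
    vx = float(img.header.get_zooms()[0])
    sc_path = _sidecar_path(path)
    meta = json.loads(sc_path.read_text()) if sc_path.exists() else [{}] * arr.shape[-1]
    out = []
    for t in range(arr.shape[-1]):
        m = dict(meta[t]) if t < len(meta) else {}
        out.append(
            SRVolume(
                data=arr[:, :, :, t].transpose(2, 1, 0).astype(float),
                voxel_mm=vx,
                iterations_used=int(m.pop("iterations", 0)),
                final_residual=float(m.pop("residual", float("nan"))),
                meta=m,
            )
        )
    return out


def write_audio(audio: SyntheticAudio | AudioTrack, path: str | Path) -> None:
    path = Path(path)
    wavfile.write(str(path), int(audio.rate_hz), audio.samples.astype(np.float32))
    markers = getattr(audio, "markers", np.array([], dtype=int))
    # sidecar keeps the .wav suffix to avoid clashing with image sidecars
    path.with_name(path.name + ".json").write_text(
        json.dumps({"markers": [int(m) for m in markers], "rate_hz": int(audio.rate_hz)})
    )


def read_audio(path: str | Path) -> AudioTrack:
    path = Path(path)
    rate, samples = wavfile.read(str(path))
    if samples.dtype.kind == "i":
        samples = samples / float(np.iinfo(samples.dtype).max)
    markers: list[int] = []
    sc = path.with_name(path.name + ".json")
    if sc.exists():
        markers = json.loads(sc.read_text()).get("markers", [])
    return AudioTrack(samples=np.asarray(samples, dtype=float), rate_hz=int(rate),
                      markers=np.asarray(markers, dtype=int))


def write_frame_map(fmap: FrameMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ref_frame", "query_frame"])
        for i, q in enumerate(fmap.mapping):
            w.writerow([i, int(q)])


def read_frame_map(path: str | Path) -> FrameMap:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))[1:]
    return FrameMap(mapping=np.array([int(r[1]) for r in rows]))


def write_transforms(results: list[RegistrationResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["slice", "tx_mm", "ty_mm", "phi_deg", "corr_before", "corr_after"])
        for s, r in enumerate(results):
            t = r.transform
            w.writerow([s, f"{t.tx_mm:.6f}", f"{t.ty_mm:.6f}", f"{t.phi_deg:.6f}",
                        f"{r.corr_before:.6f}", f"{r.corr_after:.6f}"])
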