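"""NIfTI and sidecar I/O for echo series, maps and B0 maps.

Complex multi-echo series are written as a pair of 4-D NIfTI volumes (real
and imaginary parts, echo as the 4th dimension) plus a JSON sidecar with
echo times in ms, field strength and generator provenance. A
magnitude/phase pair is accepted as an alternative on-disk dialect.
Internally echo series keep the echo axis first, ``(n_echo, ny, nx)``;
NIfTI stores spatial axes first, so arrays are transposed on the way
through.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantoms import EchoSeries
from .phasecorr import B0Map
from .signal import AcquisitionProtocol

__all__ = [
    "save_echo_series",
    "load_echo_series",
    "save_map",
    "load_map",
    "save_b0_map",
    "load_b0_map",
]


def _to_nifti_order(data: np.ndarray) -> np.ndarray:
    # (echo, ny, nx) -> (nx, ny, 1, echo): x fastest on disk, echo last
    return np.ascontiguousarray(np.transpose(data, (2, 1, 0))[:, :, None, :])


def _from_nifti_order(vol: np.ndarray) -> np.ndarray:
    if vol.ndim != 4:
        raise ValueError("expected a 4-D echo volume")
    return np.transpose(vol[:, :, 0, :], (2, 1, 0))


def save_echo_series(series: EchoSeries, stem) -> None:
    """Write ``<stem>_real.nii.gz``, ``<stem>_imag.nii.gz`` and ``<stem>.json``."""
    stem = Path(stem)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(_to_nifti_order(series.data.real), affine),
             str(stem) + "_real.nii.gz")
    nib.save(nib.Nifti1Image(_to_nifti_order(series.data.imag), affine),
             str(stem) + "_imag.nii.gz")
    sidecar = {
        "te_ms": [t * 1e3 for t in series.protocol.te],
        "b0": series.protocol.b0,
        "readout_axis": series.protocol.readout_axis,
        "phase_encode_axis": series.protocol.phase_encode_axis,
        "protocol_name": series.protocol.name,
        "noise_sd": series.noise_sd,
        "provenance": series.provenance,
    }
    Path(str(stem) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_echo_series(stem) -> EchoSeries:
    """Read an echo series written by :func:`save_echo_series`.

    Accepts either a real/imag pair (``<stem>_real/_imag``) or a
    magnitude/phase pair (``<stem>_mag/_phase``, phase in radians).
    """
    stem = Path(stem)
    sidecar = json.loads(Path(str(stem) + ".json").read_text())
    real_p = Path(str(stem) + "_real.nii.gz")
    if real_p.exists():
        re = np.asarray(nib.load(str(real_p)).dataobj, dtype=float)
        im = np.asarray(nib.load(str(stem) + "_imag.nii.gz").dataobj, dtype=float)
        data = _from_nifti_order(re) + 1j * _from_nifti_order(im)
    else:
        mag = np.asarray(nib.load(str(stem) + "_mag.nii.gz").dataobj, dtype=float)
        ph = np.asarray(nib.load(str(stem) + "_phase.nii.gz").dataobj, dtype=float)
        data = _from_nifti_order(mag) * np.exp(1j * _from_nifti_order(ph))
    protocol = AcquisitionProtocol(
        b0=sidecar["b0"],
        te=tuple(t * 1e-3 for t in sidecar["te_ms"]),
        readout_axis=sidecar.get("readout_axis", "x"),
        phase_encode_axis=sidecar.get("phase_encode_axis", "y"),
        name=sidecar.get("protocol_name", ""),
    )
    return EchoSeries(data=data, protocol=protocol,
                      noise_sd=sidecar.get("noise_sd", 0.0),
                      provenance=sidecar.get("provenance", {}))


def save_map(map_: np.ndarray, path) -> None:
    """Write a single 2-D map as NIfTI, (ny, nx) -> (nx, ny, 1)."""
    vol = np.ascontiguousarray(map_.T[:, :, None]).astype(np.float64)
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))


def load_map(path) -> np.ndarray:
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if vol.ndim == 3 and vol.shape[2] == 1:
        vol = vol[:, :, 0]
    return vol.T


def save_b0_map(b0map: B0Map, stem) -> None:
    """Write Hz map + validity mask volumes and a JSON sidecar."""
    stem = str(stem)
    save_map(b0map.delta_f, stem + "_hz.nii.gz")
    save_map(b0map.valid_mask.astype(float), stem + "_mask.nii.gz")
    Path(stem + ".json").write_text(json.dumps(
        {"te_pair_ms": [t * 1e3 for t in b0map.te_pair]}, indent=2))


def load_b0_map(stem) -> B0Map:
    stem = str(stem)
    sidecar = json.loads(Path(stem + ".json").read_text())
    return B0Map(
        delta_f=load_map(stem + "_hz.nii.gz"),
        valid_mask=load_map(stem + "_mask.nii.gz") > 0.5,
        te_pair=tuple(t * 1e-3 for t in sidecar["te_pair_ms"]),
    )
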