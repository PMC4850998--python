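"""File formats: grayscale images, photon streams, network parameters, IDX.

Intensity images travel as 8-bit grayscale PGM/PNG with 255 mapping to
intensity 1.0.  Photon streams and trained networks are stored as NumPy
``.npz`` containers whose field layout is documented on the functions below.
The IDX reader handles the big-endian dialect used by the standard
handwritten-digit benchmark files.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .classify import Layer, LayeredNet
from .sensor import NoiseModel, PhotonStream

__all__ = [
    "read_image",
    "write_image",
    "save_stream",
    "load_stream",
    "save_net",
    "load_net",
    "read_idx",
    "write_idx",
    "read_idx_dataset",
]

_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.dtype(">i2"),
               0x0C: np.dtype(">i4"), 0x0D: np.dtype(">f4"),
               0x0E: np.dtype(">f8")}


def read_image(path) -> np.ndarray:
    """Read a grayscale PGM/PNG as intensities in [0, 1]."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    return arr.astype(float) / scale


def write_image(path, image) -> None:
    """Write intensities in [0, 1] as 8-bit grayscale (format from suffix)."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 255.0).astype(np.uint8))


def save_stream(path, stream: PhotonStream) -> None:
    """Persist a photon stream.

    Container fields: ``frames`` (T, H, W), ``delta_t``, ``noise`` (the five
    noise parameters in declaration order), ``seed`` (-1 if unknown),
    ``fpn_map``.
    """
    n = stream.noise
    np.savez_compressed(
        path, frames=stream.frames, delta_t=stream.delta_t,
        noise=np.array([n.lambda_max, n.eps_dc, n.sigma_r, n.sigma_fpn,
                        n.sigma_dc]),
        seed=np.array(-1 if stream.seed is None else stream.seed),
        fpn_map=(np.zeros(stream.frames.shape[1:])
                 if stream.fpn_map is None else stream.fpn_map))


def load_stream(path) -> PhotonStream:
    with np.load(path) as z:
        noise = NoiseModel(*z["noise"].tolist())
        seed = int(z["seed"])
        return PhotonStream(z["frames"], float(z["delta_t"]), noise,
                            seed=None if seed < 0 else seed,
                            fpn_map=z["fpn_map"])


def save_net(path, net: LayeredNet) -> None:
    """Persist network parameters, pooling groups and training metadata.

    Per layer ``i``: ``W_i``, ``b_i``, ``groups_i`` (concatenated group
    indices), ``starts_i`` (group boundaries), optional ``wtie_i``/``btie_i``;
    plus ``n_layers`` and a JSON ``meta`` string.
    """
    fields = {"n_layers": np.array(len(net.layers)),
              "meta": np.array(json.dumps(net.meta))}
    for i, layer in enumerate(net.layers):
        fields[f"W_{i}"] = layer.W
        fields[f"b_{i}"] = layer.b
        fields[f"groups_{i}"] = layer.perm
        fields[f"starts_{i}"] = layer.starts
        if layer.w_tie is not None:
            fields[f"wtie_{i}"] = layer.w_tie
            fields[f"btie_{i}"] = layer.b_tie
    np.savez_compressed(path, **fields)


def load_net(path) -> LayeredNet:
    with np.load(path) as z:
        layers = []
        for i in range(int(z["n_layers"])):
            perm = z[f"groups_{i}"]
            starts = z[f"starts_{i}"]
            bounds = np.append(starts, len(perm))
            groups = [perm[bounds[k]:bounds[k + 1]]
                      for k in range(len(starts))]
            layers.append(Layer(
                z[f"W_{i}"], z[f"b_{i}"], groups,
                w_tie=z[f"wtie_{i}"] if f"wtie_{i}" in z else None,
                b_tie=z[f"btie_{i}"] if f"btie_{i}" in z else None))
        return LayeredNet(layers, meta=json.loads(str(z["meta"])))


def read_idx(path) -> np.ndarray:
    """Read one IDX-format array (big-endian; magic ``\\x00\\x00<type><ndim>``)."""
    raw = Path(path).read_bytes()
    if len(raw) < 4:
        raise ValueError("truncated IDX header")
    zero1, zero2, dtype_code, ndim = struct.unpack(">BBBB", raw[:4])
    if zero1 or zero2 or dtype_code not in _IDX_DTYPES:
        raise ValueError(f"bad IDX magic number {raw[:4]!r}")
    if len(raw) < 4 + 4 * ndim:
        raise ValueError("truncated IDX dimension header")
    dims = struct.unpack(f">{ndim}I", raw[4:4 + 4 * ndim])
    dtype = np.dtype(_IDX_DTYPES[dtype_code])
    expected = int(np.prod(dims)) * dtype.itemsize
    payload = raw[4 + 4 * ndim:]
    if len(payload) < expected:
        raise ValueError("truncated IDX payload")
    return np.frombuffer(payload[:expected], dtype=dtype).reshape(dims).copy()


def write_idx(path, array) -> None:
    """Write an array in IDX format (uint8 data)."""
    arr = np.ascontiguousarray(array, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, 0x08, arr.ndim))
        fh.write(struct.pack(f">{arr.ndim}I", *arr.shape))
        fh.write(arr.tobytes())


def read_idx_dataset(images_path, labels_path):
    """Read paired IDX image/label files as (intensities in [0,1], labels).

    Pixel value 255 maps to intensity 1.0.  The number of labels must match
    the number of images.
    """
    images = read_idx(images_path).astype(float) / 255.0
    labels = read_idx(labels_path).astype(int)
    if len(images) != len(labels):
        raise ValueError(
            f"image/label count mismatch: {len(images)} vs {len(labels)}")
    return images, labels
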