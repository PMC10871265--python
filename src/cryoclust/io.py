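"""File formats: MRC2014 volumes/stacks, PNG directories, TSV tables.

The MRC reader/writer is a minimal MRC2014 implementation (1024-byte
header, modes 0/1/2/6, optional extended header skipped on read) covering
what projection sorting needs: ``.mrcs`` image stacks and ``.mrc``
single volumes, float32 little-endian on write.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .simulate import ProjectionSet, SyntheticVolume

__all__ = [
    "read_mrc",
    "write_mrc",
    "read_projections",
    "write_projections",
    "read_volume",
    "import_png_dir",
    "export_png_dir",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_embedding_tsv",
    "write_embedding_tsv",
    "read_cluster_file",
    "write_cluster_file",
]

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC2014 file -> (data with shape (nz, ny, nx), pixel size)."""
    raw = Path(path).read_bytes()
    if len(raw) < 1024:
        raise ValueError(f"{path}: not an MRC file (truncated header)")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx = struct.unpack_from("<i", raw, 28)[0]
    xlen = struct.unpack_from("<f", raw, 40)[0]
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    if mode not in _MODE_DTYPES:
        raise ValueError(f"{path}: unsupported MRC mode {mode}")
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    offset = 1024 + nsymbt
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    pixel = xlen / mx if mx > 0 and xlen > 0 else 1.0
    return data.reshape(nz, ny, nx).astype(np.float64), float(pixel)


def write_mrc(path, data: np.ndarray, pixel_size: float = 1.0) -> None:
    """Write data (nz, ny, nx) as float32 MRC2014."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    nz, ny, nx = data.shape
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()),
        float(data.mean()),
    )
    struct.pack_into("<i", header, 88, 1)  # ispg: image stack / 2D
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0, 0])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 1)
    header[224:224 + 10] = b"cryoclust "
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_projections(path, labels_path=None) -> ProjectionSet:
    data, pixel = read_mrc(path)
    labels = read_labels_tsv(labels_path, n=len(data)) if labels_path else None
    return ProjectionSet(
        images=data, labels=labels, pixel_size=pixel, source=str(path)
    )


def write_projections(path, ps: ProjectionSet) -> None:
    write_mrc(path, ps.images, ps.pixel_size)


def read_volume(path, shape_id: str = "user") -> SyntheticVolume:
    data, _ = read_mrc(path)
    return SyntheticVolume(grid=np.clip(data, 0, None), shape_id=shape_id,
                           seed=0)


def import_png_dir(dirpath, labels_path=None) -> ProjectionSet:
    """Read all PNG/TIFF images (sorted by filename) as one stack."""
    from skimage.io import imread

    files = sorted(
        p for p in Path(dirpath).iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not files:
        raise ValueError(f"no PNG/TIFF images in {dirpath}")
    imgs = [np.asarray(imread(f, as_gray=True), dtype=float) for f in files]
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"images differ in size: {shapes}")
    labels = read_labels_tsv(labels_path, n=len(imgs)) if labels_path else None
    return ProjectionSet(images=np.stack(imgs), labels=labels,
                         source=str(dirpath))


def export_png_dir(dirpath, ps: ProjectionSet) -> None:
    from skimage.io import imsave

    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(ps.images):
        lo, hi = img.min(), img.max()
        scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
        imsave(d / f"projection_{i:05d}.png",
               (scaled * 255).astype(np.uint8), check_contrast=False)


def read_labels_tsv(path, n: int | None = None) -> np.ndarray:
    """Two-column TSV (0-based image index, complex id) -> label array."""
    pairs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        idx, lab = line.split("\t")[:2]
        pairs[int(idx)] = lab
    if n is None:
        n = max(pairs) + 1
    labels = np.array([pairs.get(i, "") for i in range(n)], dtype=object)
    if "" in labels:
        raise ValueError("labels TSV does not cover every image index")
    return labels


def write_labels_tsv(path, labels) -> None:
    with open(path, "w") as fh:
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{lab}\n")


def write_embedding_tsv(path, emb: np.ndarray) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(np.asarray(emb)):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_embedding_tsv(path) -> np.ndarray:
    rows = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        rows[int(parts[0])] = [float(v) for v in parts[1:]]
    return np.array([rows[i] for i in range(len(rows))])


def write_cluster_file(path, labels, noise_label=-1) -> None:
    """One line per cluster (space-separated image indices); noise under a
    reserved ``#NOISE`` header line."""
    labels = np.asarray(labels)
    with open(path, "w") as fh:
        for lab in sorted({l for l in labels.tolist() if l != noise_label},
                          key=repr):
            members = np.flatnonzero(labels == lab)
            fh.write(" ".join(map(str, members)) + "\n")
        noise = np.flatnonzero(labels == noise_label)
        if len(noise):
            fh.write("#NOISE " + " ".join(map(str, noise)) + "\n")


def read_cluster_file(path) -> list[set]:
    """Read a cluster file -> partition (noise items become singletons)."""
    part: list[set] = []
    noise: list[int] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#NOISE"):
            noise.extend(int(t) for t in line.split()[1:])
        elif not line.startswith("#"):
            part.append({int(t) for t in line.split()})
    return part + [{i} for i in noise]
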