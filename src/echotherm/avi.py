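"""Uncompressed 8-bit grayscale AVI (RIFF / 'DIB ' codec) reader and writer.

Handles exactly the codec-free container ultrasound consoles commonly export:
palette-indexed 8-bit device-independent bitmap frames inside a RIFF 'AVI '
file.  Compressed streams are rejected with a clear error; use a frame
directory for anything else.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["write_avi", "read_avi"]


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    pad = b"\x00" if len(payload) % 2 else b""
    return fourcc + struct.pack("<I", len(payload)) + payload + pad


def _list(list_type: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", list_type + payload)


def write_avi(path, frames: np.ndarray, fps: float) -> None:
    """Write (n, rows, cols) uint8 frames as an uncompressed grayscale AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.dtype != np.uint8:
        raise ValueError("frames must be a (n, rows, cols) uint8 array")
    n, rows, cols = frames.shape
    stride = (cols + 3) & ~3  # DIB rows padded to 4-byte boundaries
    frame_bytes = stride * rows

    avih = struct.pack(
        "<14I",
        int(round(1e6 / fps)),        # dwMicroSecPerFrame
        frame_bytes * int(np.ceil(fps)),  # dwMaxBytesPerSec
        0, 0,                          # padding granularity, flags
        n, 0, 1, frame_bytes,          # total frames, initial, streams, buf
        cols, rows, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sI2H8IhhHH",
        b"vids", b"DIB ",
        0,                             # dwFlags
        0, 0,                          # wPriority, wLanguage
        0,                             # dwInitialFrames
        1000, int(round(fps * 1000)),  # dwScale, dwRate
        0, n, frame_bytes, 0xFFFFFFFF, 0,
        0, 0, cols, rows,              # rcFrame
    )
    # BITMAPINFOHEADER + 256-entry grayscale palette
    bmih = struct.pack(
        "<IiiHHIIiiII", 40, cols, rows, 1, 8, 0, frame_bytes, 0, 0, 256, 256
    )
    palette = b"".join(struct.pack("<BBBB", i, i, i, 0) for i in range(256))
    strf = bmih + palette

    hdrl = _list(
        b"hdrl",
        _chunk(b"avih", avih)
        + _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf)),
    )

    movi_frames = []
    for frame in frames:
        dib = np.zeros((rows, stride), dtype=np.uint8)
        dib[:, :cols] = frame[::-1]  # bottom-up row order
        movi_frames.append(_chunk(b"00db", dib.tobytes()))
    movi = _list(b"movi", b"".join(movi_frames))

    body = b"AVI " + hdrl + movi
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos:pos + 4]
        size = struct.unpack("<I", buf[pos + 4:pos + 8])[0]
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path) -> tuple[np.ndarray, float]:
    """Read an uncompressed 8-bit AVI; returns (frames, fps)."""
    buf = Path(path).read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise ValueError(f"{path}: not an AVI file")

    micro_per_frame = None
    scale = rate = None
    cols = rows = None
    bit_count = compression = None
    frame_chunks: list[tuple[int, int]] = []

    def walk(start: int, end: int):
        nonlocal micro_per_frame, scale, rate, cols, rows, bit_count, compression
        for fourcc, off, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(off + 4, off + size)
            elif fourcc == b"avih":
                micro_per_frame = struct.unpack("<I", buf[off:off + 4])[0]
            elif fourcc == b"strh" and buf[off:off + 4] == b"vids":
                scale, rate = struct.unpack("<II", buf[off + 20:off + 28])
            elif fourcc == b"strf" and cols is None:
                (_sz, w, h, _pl, bc, comp) = struct.unpack(
                    "<IiiHHI", buf[off:off + 20]
                )
                cols, rows, bit_count, compression = w, abs(h), bc, comp
            elif fourcc in (b"00db", b"00dc"):
                frame_chunks.append((off, size))

    walk(12, len(buf))

    if cols is None or not frame_chunks:
        raise ValueError(f"{path}: no video frames found")
    if compression != 0 or bit_count != 8:
        raise ValueError(
            f"{path}: only uncompressed 8-bit AVI is supported "
            f"(biCompression={compression}, biBitCount={bit_count}); "
            "export raw frames or use a frame directory"
        )
    if scale and rate:
        fps = rate / scale
    elif micro_per_frame:
        fps = 1e6 / micro_per_frame
    else:
        raise ValueError(f"{path}: frame rate missing from headers")

    stride = (cols + 3) & ~3
    frames = np.empty((len(frame_chunks), rows, cols), dtype=np.uint8)
    for i, (off, size) in enumerate(frame_chunks):
        if size < stride * rows:
            raise ValueError(f"{path}: truncated frame {i}")
        dib = np.frombuffer(buf, dtype=np.uint8, count=stride * rows, offset=off)
        frames[i] = dib.reshape(rows, stride)[::-1, :cols]
    return frames, float(fps)
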