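"""PhysioNet-style record I/O and the record/beat-type filters.

Implements a minimal WFDB-compatible subset: text ``.hea`` headers,
format-16 (little-endian int16, channel-interleaved) ``.dat`` signals and
the MIT annotation byte format (6-bit type code + 10-bit time delta per
word, with SKIP escapes for long gaps). This covers QTDB/MITDB/NSRDB-style
directories as well as the synthetic writer's output.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np

from .preprocess import FiducialLabels

# MIT annotation type codes (subset)
SYMBOL_TO_CODE = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8,
    "S": 9, "E": 10, "j": 11, "/": 12, "Q": 13, "|": 16,
    "p": 24, "t": 27, "u": 29, "(": 39, ")": 40,
}
CODE_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_CODE.items()}
#: annotation symbols that mark a beat (QRS) rather than a wave boundary
BEAT_SYMBOLS = frozenset("NLRaVFJASEj/Q")
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

#: default analog-to-digital gain (adu per mV) for the format-16 writer
DEFAULT_GAIN = 200.0


@dataclass
class EcgRecord:
    """A multi-lead record in millivolts."""

    record_id: str
    signals: np.ndarray          # (n_samples, n_leads)
    fs: float
    leads: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] < self.signals.shape[1]:
            raise ValueError("signals must be (n_samples, n_leads)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.leads:
            self.leads = [f"lead{i}" for i in range(self.signals.shape[1])]

    def lead(self, index_or_name):
        if isinstance(index_or_name, str):
            index_or_name = self.leads.index(index_or_name)
        return self.signals[:, index_or_name]


@dataclass
class AnnotationSet:
    """Annotation stream: sample positions and their symbols."""

    positions: np.ndarray
    symbols: list[str]

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=int)
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("annotation positions must be non-decreasing")
        if len(self.symbols) != self.positions.size:
            raise ValueError("positions and symbols must align")

    @property
    def beat_types(self) -> list[str]:
        return [s for s in self.symbols if s in BEAT_SYMBOLS]


# ---------------------------------------------------------------------------
# WFDB subset: writing
# ---------------------------------------------------------------------------

def write_wfdb_record(directory, name, signals, fs, lead_names=None,
                      gain=DEFAULT_GAIN):
    """Write ``name.hea`` + format-16 ``name.dat``; ``signals`` is
    (n_samples, n_leads) in mV."""
    os.makedirs(directory, exist_ok=True)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.ndim != 2:
        raise ValueError("signals must be 2D (n_samples, n_leads)")
    n, k = signals.shape
    lead_names = lead_names or [f"lead{i}" for i in range(k)]
    digital = np.clip(np.rint(signals * gain), -32768, 32767).astype("<i2")
    with open(os.path.join(directory, f"{name}.dat"), "wb") as fh:
        fh.write(digital.reshape(-1).tobytes())   # row-major = interleaved
    lines = [f"{name} {k} {fs:g} {n}"]
    for i in range(k):
        first = int(digital[0, i])
        lines.append(f"{name}.dat 16 {gain:g} 16 0 {first} 0 0 "
                     f"{lead_names[i]}")
    with open(os.path.join(directory, f"{name}.hea"), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_wfdb_annotations(directory, name, positions, symbols, ext="atr"):
    """Write an MIT-format annotation file from positions + symbols."""
    order = np.argsort(np.asarray(positions), kind="stable")
    positions = np.asarray(positions)[order]
    symbols = [symbols[i] for i in order]
    words = bytearray()
    prev = 0
    for pos, sym in zip(positions, symbols):
        if sym not in SYMBOL_TO_CODE:
            raise ValueError(f"unsupported annotation symbol {sym!r}")
        delta = int(pos) - prev
        if delta > 1023 or delta < 0:
            words += struct.pack("<H", _SKIP << 10)
            words += struct.pack("<h", delta >> 16)
            words += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        words += struct.pack("<H", (SYMBOL_TO_CODE[sym] << 10) | delta)
        prev = int(pos)
    words += struct.pack("<H", 0)
    with open(os.path.join(directory, f"{name}.{ext}"), "wb") as fh:
        fh.write(bytes(words))


# ---------------------------------------------------------------------------
# WFDB subset: reading
# ---------------------------------------------------------------------------

def read_wfdb_record(directory, name) -> EcgRecord:
    header = os.path.join(directory, f"{name}.hea")
    with open(header) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    n_leads, fs = int(head[1]), float(head[2])
    n_samples = int(head[3]) if len(head) > 3 else -1
    gains, leads, fmts, fname = [], [], [], None
    for ln in lines[1: 1 + n_leads]:
        parts = ln.split()
        fname = parts[0]
        fmts.append(parts[1])
        gain = float(parts[2].split("(")[0].split("/")[0]) if len(parts) > 2 \
            else DEFAULT_GAIN
        gains.append(gain or DEFAULT_GAIN)
        leads.append(parts[8] if len(parts) > 8 else f"lead{len(leads)}")
    if any(f != "16" for f in fmts):
        raise ValueError(f"unsupported signal format(s) {set(fmts)}; "
                         "only format 16 is implemented")
    raw = np.fromfile(os.path.join(directory, fname), dtype="<i2")
    usable = (raw.size // n_leads) * n_leads
    digital = raw[:usable].reshape(-1, n_leads).astype(float)
    if n_samples > 0:
        digital = digital[:n_samples]
    signals = digital / np.asarray(gains)[None, :]
    return EcgRecord(name, signals, fs, leads)


def read_wfdb_annotations(directory, name, ext="atr") -> AnnotationSet:
    with open(os.path.join(directory, f"{name}.{ext}"), "rb") as fh:
        data = fh.read()
    positions, symbols = [], []
    time = 0
    i = 0
    pending_skip = 0
    while i + 2 <= len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        if word == 0:
            break
        code, delta = word >> 10, word & 0x3FF
        if code == _SKIP and delta == 0:
            (hi,) = struct.unpack_from("<h", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            pending_skip = (hi << 16) | lo
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += delta + (delta & 1)
            continue
        time += delta + pending_skip
        pending_skip = 0
        positions.append(time)
        symbols.append(CODE_TO_SYMBOL.get(code, "?"))
    return AnnotationSet(np.asarray(positions, dtype=int), symbols)


def read_record_with_annotations(directory, name, ext="atr"):
    return (read_wfdb_record(directory, name),
            read_wfdb_annotations(directory, name, ext=ext))


def list_records(directory):
    return sorted(os.path.splitext(f)[0] for f in os.listdir(directory)
                  if f.endswith(".hea"))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def annotated_point_types(ann: AnnotationSet) -> set:
    """Which of the 8 fiducial point types appear in an annotation stream.

    A '(' / ')' is attributed to the wave symbol it brackets, so e.g.
    "P-on" requires a '(' immediately before a 'p'."""
    present = set()
    syms = ann.symbols
    for i, s in enumerate(syms):
        if s == "p":
            present.add("P-peak")
            if i > 0 and syms[i - 1] == "(":
                present.add("P-on")
            if i + 1 < len(syms) and syms[i + 1] == ")":
                present.add("P-off")
        elif s in BEAT_SYMBOLS:
            present.add("R-peak")
            if i > 0 and syms[i - 1] == "(":
                present.add("QRS-on")
            if i + 1 < len(syms) and syms[i + 1] == ")":
                present.add("QRS-off")
        elif s == "t":
            present.add("T-peak")
            if i + 1 < len(syms) and syms[i + 1] == ")":
                present.add("T-off")
    return present


ALL_POINT_TYPES = frozenset({"P-on", "P-peak", "P-off", "QRS-on", "R-peak",
                             "QRS-off", "T-peak", "T-off"})


def filter_records(records):
    """Keep only records whose annotations contain every one of the 8
    fiducial point types at least once. Idempotent."""
    return [(rec, ann) for rec, ann in records
            if annotated_point_types(ann) >= ALL_POINT_TYPES]


def select_beats_by_type(record: EcgRecord, ann: AnnotationSet,
                         beat_type: str) -> np.ndarray:
    """R-peak sample indices of beats annotated with ``beat_type``,
    in temporal order. Unknown codes yield an empty array."""
    mask = [s == beat_type and s in BEAT_SYMBOLS for s in ann.symbols]
    return ann.positions[np.asarray(mask, dtype=bool)] \
        if any(mask) else np.empty(0, dtype=int)


def extract_annotated_beats(ann: AnnotationSet):
    """Group a QTDB-style annotation stream into complete beats.

    A complete beat is the symbol run ``( p ) ( B ) [(] t )`` with ``B``
    any beat symbol (the T onset bracket is optional, mirroring sources
    that do not annotate it). Returns a list of (r_peak, FiducialLabels).
    """
    syms, pos = ann.symbols, ann.positions
    beats = []
    i = 0
    n = len(syms)
    while i < n:
        if syms[i] == "(" and i + 5 < n and syms[i + 1] == "p" \
                and syms[i + 2] == ")" and syms[i + 3] == "(" \
                and syms[i + 4] in BEAT_SYMBOLS and syms[i + 5] == ")":
            j = i + 6
            if j < n and syms[j] == "(":
                j += 1
            if j + 1 < n and syms[j] == "t" and syms[j + 1] == ")":
                p8 = [pos[i], pos[i + 1], pos[i + 2], pos[i + 3], pos[i + 4],
                      pos[i + 5], pos[j], pos[j + 1]]
                try:
                    beats.append((int(pos[i + 4]),
                                  FiducialLabels(np.asarray(p8, dtype=float))))
                except ValueError:
                    pass  # degenerate annotation; skip the beat
                i = j + 2
                continue
        i += 1
    return beats
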